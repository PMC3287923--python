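"""Variance-component linkage: likelihood, ML fitting, LOD scores,
family-specific LOD decomposition, and the boundary null mixture.

Model. Within family f with trait vector ``y_f`` (length n_f), the trait is
multivariate normal with mean ``mu * 1`` and covariance

    Omega_f = var_q * Pi_f + var_a * 2*Phi_f + var_e * I

where ``Pi_f`` is the pairwise IBD-proportion matrix at the tested locus,
``Phi_f`` the kinship matrix, ``var_q`` the locus (QTL) variance, ``var_a``
the residual polygenic variance and ``var_e`` the environmental variance.
Families are independent, so the sample log-likelihood is the sum of the
family terms. The LOD score is the log10 likelihood ratio of the full model
against the null model with ``var_q = 0``; because the null pins a variance
at the boundary of its parameter space, the null distribution of
``2*ln(10)*LOD`` is the half-half mixture of a chi-square with 1 degree of
freedom and a point mass at 0.

The family-specific LOD is family f's log-likelihood-ratio contribution
evaluated at the *whole-sample* ML estimates of both models, so the
per-family scores sum exactly to the total LOD.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .pedigree import KinshipMatrix
from .simulate import IBDMatrix

__all__ = [
    "LinkageError",
    "VCParams",
    "VCFit",
    "FamilyData",
    "FamilyLODProfile",
    "loglik",
    "fit",
    "lod",
    "family_lod",
    "null_expected_lod",
    "lod_pvalue",
    "sample_null_lod",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)
LOD_CLAMP = 1e-6  # nested-model numerics: LOD in [-1e-6, 0) is treated as 0
_JITTER = 1e-8
_COND_LIMIT = 1e12


class LinkageError(RuntimeError):
    """Linkage-stage failure (non-PD covariance, non-convergence, data mismatch)."""


@dataclass(frozen=True)
class VCParams:
    """Variance-component parameters (trait units / trait units squared)."""

    mu: float
    var_q: float
    var_a: float
    var_e: float

    def __post_init__(self) -> None:
        if min(self.var_q, self.var_a, self.var_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.var_q + self.var_a + self.var_e <= 0:
            raise ValueError("at least one variance component must be positive")

    @property
    def total_variance(self) -> float:
        return self.var_q + self.var_a + self.var_e


@dataclass
class FamilyData:
    """One family's trait vector and relationship matrices, aligned by id."""

    fid: str
    y: np.ndarray
    kinship2: np.ndarray  # 2 * Phi
    ibd: np.ndarray | None = None  # Pi at the tested locus; None for null-only use

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.kinship2 = np.asarray(self.kinship2, dtype=float)
        n = len(self.y)
        if self.kinship2.shape != (n, n):
            raise ValueError(f"family {self.fid!r}: kinship shape mismatch")
        if self.ibd is not None:
            self.ibd = np.asarray(self.ibd, dtype=float)
            if self.ibd.shape != (n, n):
                raise ValueError(f"family {self.fid!r}: IBD shape mismatch")

    @classmethod
    def from_matrices(
        cls,
        fid: str,
        ids: Sequence[str],
        y: Sequence[float],
        kin: KinshipMatrix,
        ibd: IBDMatrix | None,
    ) -> "FamilyData":
        return cls(
            fid=fid,
            y=np.asarray(y, dtype=float),
            kinship2=2.0 * kin.subset(ids),
            ibd=None if ibd is None else ibd.subset(ids),
        )


def data_fingerprint(families: Sequence[FamilyData]) -> str:
    """Digest of the trait data and kinship structure (the locus IBD is not
    part of the data identity: the null model never sees it)."""
    h = hashlib.sha1()
    for fam in families:
        h.update(fam.fid.encode())
        h.update(np.ascontiguousarray(fam.y).tobytes())
        h.update(np.ascontiguousarray(fam.kinship2).tobytes())
    return h.hexdigest()


def _factor(omega: np.ndarray, fid: str):
    """Cholesky with a logged diagonal jitter for near-singular covariance."""
    try:
        c, low = cho_factor(omega, lower=True, check_finite=False)
        d = np.diag(c)
        if (d.max() / max(d.min(), 1e-300)) ** 2 > _COND_LIMIT:
            raise np.linalg.LinAlgError("ill-conditioned")
        return (c, low)
    except (np.linalg.LinAlgError, ValueError):
        pass
    logger.debug("family %s: covariance near-singular, adding %.0e jitter", fid, _JITTER)
    try:
        return cho_factor(omega + _JITTER * np.eye(omega.shape[0]), lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        raise LinkageError(f"family {fid!r}: covariance matrix is not positive definite") from None


def _family_omega(params: VCParams, fam: FamilyData) -> np.ndarray:
    n = len(fam.y)
    omega = params.var_a * fam.kinship2 + params.var_e * np.eye(n)
    if params.var_q != 0.0:
        if fam.ibd is None:
            raise LinkageError(f"family {fam.fid!r}: var_q > 0 requires a locus IBD matrix")
        omega += params.var_q * fam.ibd
    return omega


def family_loglik(params: VCParams, fam: FamilyData) -> float:
    """Log-likelihood contribution of one family, in nats."""
    omega = _family_omega(params, fam)
    factor = _factor(omega, fam.fid)
    r = fam.y - params.mu
    u = cho_solve(factor, r, check_finite=False)
    logdet = 2.0 * np.log(np.diag(factor[0])).sum()
    n = len(fam.y)
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + float(r @ u))


def loglik(params: VCParams, families: Sequence[FamilyData]) -> float:
    """Sample log-likelihood (nats): sum of independent family contributions."""
    return sum(family_loglik(params, fam) for fam in families)


# -- ML fitting ----------------------------------------------------------


def _nll_and_grad(theta: np.ndarray, families: Sequence[FamilyData], full: bool):
    """Negative log-likelihood and gradient on (mu, log var_a, log var_e[, log var_q])."""
    mu = theta[0]
    va, ve = math.exp(theta[1]), math.exp(theta[2])
    vq = math.exp(theta[3]) if full else 0.0
    ll = 0.0
    g_mu = g_va = g_ve = g_vq = 0.0
    for fam in families:
        n = len(fam.y)
        omega = va * fam.kinship2 + ve * np.eye(n)
        if full:
            omega += vq * fam.ibd
        factor = _factor(omega, fam.fid)
        ainv = cho_solve(factor, np.eye(n), check_finite=False)
        r = fam.y - mu
        u = ainv @ r
        logdet = 2.0 * np.log(np.diag(factor[0])).sum()
        ll += -0.5 * (n * math.log(2.0 * math.pi) + logdet + float(r @ u))
        g_mu += float(u.sum())
        g_va += -0.5 * (float((ainv * fam.kinship2).sum()) - float(u @ fam.kinship2 @ u))
        g_ve += -0.5 * (float(np.trace(ainv)) - float(u @ u))
        if full:
            g_vq += -0.5 * (float((ainv * fam.ibd).sum()) - float(u @ fam.ibd @ u))
    grad = [g_mu, g_va * va, g_ve * ve]  # chain rule onto the log scale
    if full:
        grad.append(g_vq * vq)
    return -ll, -np.asarray(grad)


@dataclass
class VCFit:
    """A fitted variance-component model."""

    params: VCParams
    loglik: float
    converged: bool
    model: str  # "null" or "full"
    fingerprint: str
    n_obs: int = 0


_FULL_STARTS = [(0.1, 0.8, 0.1), (0.3, 0.3, 0.4), (0.0, 0.5, 0.5)]  # (q, a, e) shares
_NULL_STARTS = [(0.9, 0.1), (0.5, 0.5), (0.1, 0.9)]  # (a, e) shares
_LOG_EPS = 1e-9  # share floor on the log scale


def fit(
    families: Sequence[FamilyData],
    model: str = "full",
    *,
    tol: float = 1e-8,
    max_iter: int = 500,
    boundary_probe: "VCFit | None" = None,
) -> VCFit:
    """Maximum-likelihood fit with non-negativity enforced via a log-variance
    parameterization, multi-start (3 starts at fixed variance splits of the
    pooled trait variance), and — for the full model — an explicit probe of
    the ``var_q = 0`` boundary (the null-model optimum), keeping whichever
    log-likelihood is best.

    ``boundary_probe`` may pass a previously computed null fit on the same
    data to avoid refitting it.
    """
    if model not in ("null", "full"):
        raise ValueError("model must be 'null' or 'full'")
    if not families:
        raise ValueError("need at least one family")
    full = model == "full"
    if full and any(fam.ibd is None for fam in families):
        raise LinkageError("full model requires a locus IBD matrix for every family")

    pooled = np.concatenate([fam.y for fam in families])
    s2 = max(float(pooled.var(ddof=1)), 1e-12)
    mu0 = float(pooled.mean())
    log_lb, log_ub = math.log(s2) - 30.0, math.log(s2) + 5.0
    bounds = [(None, None)] + [(log_lb, log_ub)] * (3 if full else 2)

    def pack(shares: tuple[float, ...]) -> np.ndarray:
        logs = [math.log(s2 * max(sh, _LOG_EPS)) for sh in shares]
        if full:
            q, a, e = logs
            return np.asarray([mu0, a, e, q])
        return np.asarray([mu0] + logs)

    best = None
    for shares in _FULL_STARTS if full else _NULL_STARTS:
        res = optimize.minimize(
            _nll_and_grad,
            pack(shares),
            args=(families, full),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise LinkageError(f"{model} model: all optimization starts failed")

    theta = best.x
    params = VCParams(
        mu=float(theta[0]),
        var_q=float(math.exp(theta[3])) if full else 0.0,
        var_a=float(math.exp(theta[1])),
        var_e=float(math.exp(theta[2])),
    )
    result = VCFit(
        params=params,
        loglik=-float(best.fun),
        converged=bool(best.success),
        model=model,
        fingerprint=data_fingerprint(families),
        n_obs=len(pooled),
    )
    if not result.converged:
        logger.warning("%s model fit did not fully converge: %s", model, best.message)

    if full:
        probe = boundary_probe if boundary_probe is not None else fit(families, "null", tol=tol, max_iter=max_iter)
        if probe.fingerprint != result.fingerprint:
            raise LinkageError("boundary probe was fitted on different data")
        if probe.loglik >= result.loglik:
            result = VCFit(
                params=VCParams(
                    mu=probe.params.mu, var_q=0.0, var_a=probe.params.var_a, var_e=probe.params.var_e
                ),
                loglik=probe.loglik,
                converged=probe.converged,
                model="full",
                fingerprint=result.fingerprint,
                n_obs=result.n_obs,
            )
    return result


# -- LOD scores ----------------------------------------------------------


def lod(fit_full: VCFit, fit_null: VCFit) -> float:
    """Total LOD score: (lnL_full - lnL_null) / ln 10, with small negative
    numerical noise (within 1e-6 of 0) clamped to 0."""
    if fit_full.model != "full" or fit_null.model != "null":
        raise ValueError("lod() expects (full fit, null fit)")
    if fit_full.fingerprint != fit_null.fingerprint:
        raise LinkageError("full and null fits were computed on different data")
    value = (fit_full.loglik - fit_null.loglik) / LN10
    if value < -LOD_CLAMP:
        raise LinkageError(
            f"full-model log-likelihood is below the null by {-value:.3g} LOD; "
            "the full fit failed to reach the boundary optimum"
        )
    return max(value, 0.0)


@dataclass
class FamilyLODProfile:
    """Per-family LOD contributions; they sum to the total LOD."""

    fids: list[str]
    lods: np.ndarray

    def __post_init__(self) -> None:
        self.lods = np.asarray(self.lods, dtype=float)

    @property
    def total(self) -> float:
        return float(self.lods.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.fids, map(float, self.lods)))


def family_lod(
    fit_full: VCFit, fit_null: VCFit, families: Sequence[FamilyData]
) -> FamilyLODProfile:
    """Family-specific LOD scores: each family's log-likelihood-ratio
    contribution evaluated at the whole-sample ML estimates of the full and
    null models. By construction the profile sums to the total LOD."""
    if fit_full.fingerprint != fit_null.fingerprint:
        raise LinkageError("full and null fits were computed on different data")
    if data_fingerprint(families) != fit_full.fingerprint:
        raise LinkageError("families do not match the data the fits were computed on")
    lods = [
        (family_loglik(fit_full.params, fam) - family_loglik(fit_null.params, fam)) / LN10
        for fam in families
    ]
    return FamilyLODProfile(fids=[fam.fid for fam in families], lods=np.asarray(lods))


# -- null mixture utilities ----------------------------------------------


def null_expected_lod() -> float:
    """Expected LOD under the boundary null: the LRT statistic 2*ln(10)*LOD
    is a half-half mixture of chi-square(1) and a point mass at 0, so
    E[LOD] = (1/2) * E[chi2_1] / (2 ln 10) = 1 / (4 ln 10) ~= 0.109."""
    return 1.0 / (4.0 * LN10)


def sample_null_lod(n: int, seed: int | np.random.SeedSequence | np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of the null LOD mixture (1/2 at 0, 1/2 chi2_1-based)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.chisquare(1, size=n) / (2.0 * LN10)
    draws[rng.random(n) < 0.5] = 0.0
    return draws


def lod_pvalue(lod_score: float) -> float:
    """One-sided p-value of a LOD score under the half-half mixture null:
    p = (1/2) P(chi2_1 >= 2 ln 10 * LOD) for LOD > 0, and 0.5 at LOD = 0."""
    if lod_score < 0:
        raise ValueError("LOD score must be non-negative")
    if lod_score == 0:
        return 0.5
    return 0.5 * float(stats.chi2.sf(2.0 * LN10 * lod_score, df=1))
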