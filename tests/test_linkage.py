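import math

import numpy as np
import pytest
from scipy import stats

from famlod.linkage import (
    LN10,
    FamilyData,
    LinkageError,
    VCFit,
    VCParams,
    family_lod,
    family_loglik,
    fit,
    lod,
    lod_pvalue,
    loglik,
    null_expected_lod,
    sample_null_lod,
    data_fingerprint,
)
from famlod.pedigree import kinship
from famlod.simulate import PedigreeTemplate, build_pedigrees, gene_drop, ibd_from_labels


def family_structures(n_fams=8, size=12, founders=4, seed=0):
    """Small pedigrees with kinship and a gene-dropped locus IBD matrix."""
    peds = build_pedigrees([PedigreeTemplate(str(k), size, founders) for k in range(n_fams)])
    out = []
    for k, ped in enumerate(peds):
        kin2 = 2.0 * kinship(ped).values
        ibd = ibd_from_labels(ped, gene_drop(ped, [], seed=seed * 1000 + k)).values
        out.append((ped.fid, kin2, ibd))
    return out


def simulate_families(structures, params: VCParams, rng) -> list[FamilyData]:
    fams = []
    for fid, kin2, ibd in structures:
        n = kin2.shape[0]
        omega = params.var_q * ibd + params.var_a * kin2 + params.var_e * np.eye(n)
        y = params.mu + np.linalg.cholesky(omega) @ rng.standard_normal(n)
        fams.append(FamilyData(fid=fid, y=y, kinship2=kin2, ibd=ibd))
    return fams


class TestLoglik:
    def test_standard_normal_singleton(self):
        fam = FamilyData(fid="1", y=[0.0], kinship2=[[1.0]], ibd=[[1.0]])
        p = VCParams(mu=0.0, var_q=0.0, var_a=0.0, var_e=1.0)
        assert loglik(p, [fam]) == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-12)

    def test_block_additivity(self):
        rng = np.random.default_rng(1)
        fams = [
            FamilyData(fid=str(k), y=rng.standard_normal(1), kinship2=[[1.0]], ibd=[[1.0]])
            for k in range(2)
        ]
        p = VCParams(mu=0.3, var_q=0.2, var_a=0.1, var_e=0.5)
        assert loglik(p, fams) == pytest.approx(sum(loglik(p, [f]) for f in fams), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_multivariate_normal(self, seed):
        """Cholesky-based likelihood equals an independent dense MVN density."""
        (struct,) = family_structures(n_fams=1, size=5, founders=2, seed=seed)
        rng = np.random.default_rng(seed)
        p = VCParams(mu=0.2, var_q=0.4, var_a=0.3, var_e=0.6)
        (fam,) = simulate_families([struct], p, rng)
        omega = p.var_q * fam.ibd + p.var_a * fam.kinship2 + p.var_e * np.eye(len(fam.y))
        oracle = stats.multivariate_normal(mean=np.full(len(fam.y), p.mu), cov=omega)
        assert family_loglik(p, fam) == pytest.approx(oracle.logpdf(fam.y), abs=1e-9)

    def test_non_positive_definite_names_family(self):
        fam = FamilyData(fid="bad", y=[0.0, 0.0], kinship2=[[1.0, 2.0], [2.0, 1.0]], ibd=None)
        with pytest.raises(LinkageError, match="bad"):
            loglik(VCParams(mu=0, var_q=0, var_a=1.0, var_e=0.0), [fam])


@pytest.fixture(scope="module")
def small_structures():
    return family_structures(n_fams=8, size=12, founders=4, seed=7)


class TestFit:
    def test_nested_models_ordered(self, small_structures):
        rng = np.random.default_rng(2)
        fams = simulate_families(
            small_structures, VCParams(mu=0, var_q=0.3, var_a=0.3, var_e=0.4), rng
        )
        f_null = fit(fams, "null")
        f_full = fit(fams, "full", boundary_probe=f_null)
        assert f_full.loglik >= f_null.loglik - 1e-6

    def test_boundary_estimates_under_null(self, small_structures):
        """With no locus effect, the QTL variance MLE piles up at zero."""
        rng = np.random.default_rng(3)
        truth = VCParams(mu=0, var_q=0.0, var_a=0.3, var_e=0.7)
        ratios, boundary = [], 0
        for _ in range(200):
            fams = simulate_families(small_structures, truth, rng)
            f_full = fit(fams, "full")
            ratio = f_full.params.var_q / f_full.params.total_variance
            ratios.append(ratio)
            boundary += ratio < 1e-8
        assert np.median(ratios) < 0.02
        assert boundary >= 0.40 * 200

    def test_parameter_recovery_with_qtl(self):
        """The fitted QTL variance share is consistent for the simulated share."""
        structures = family_structures(n_fams=8, size=20, founders=6, seed=5)
        truth = VCParams(mu=0, var_q=0.5, var_a=0.2, var_e=0.3)
        rng = np.random.default_rng(6)
        shares = []
        for _ in range(200):
            fams = simulate_families(structures, truth, rng)
            f_full = fit(fams, "full")
            shares.append(f_full.params.var_q / f_full.params.total_variance)
        shares = np.asarray(shares)
        se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert abs(shares.mean() - 0.5) <= 3 * se

    def test_local_optimality_spot_check(self, small_structures):
        rng = np.random.default_rng(8)
        fams = simulate_families(
            small_structures[:2], VCParams(mu=0.1, var_q=0.2, var_a=0.3, var_e=0.5), rng
        )
        best = fit(fams, "full")
        for _ in range(200):
            p = VCParams(
                mu=rng.uniform(-1, 1),
                var_q=rng.uniform(0, 2),
                var_a=rng.uniform(0, 2),
                var_e=rng.uniform(0.01, 2),
            )
            assert loglik(p, fams) <= best.loglik + 1e-9


class TestLOD:
    def _fits(self, ll_full, ll_null):
        p = VCParams(mu=0, var_q=0.1, var_a=0.1, var_e=0.8)
        p0 = VCParams(mu=0, var_q=0.0, var_a=0.1, var_e=0.9)
        mk = lambda ll, m, prm: VCFit(
            params=prm, loglik=ll, converged=True, model=m, fingerprint="x"
        )
        return mk(ll_full, "full", p), mk(ll_null, "null", p0)

    def test_zero_and_unit_conversion(self):
        f, n = self._fits(-10.0, -10.0)
        assert lod(f, n) == 0.0
        f, n = self._fits(-10.0, -10.0 - math.log(10))
        assert lod(f, n) == pytest.approx(1.0, abs=1e-12)

    def test_small_negative_clamped_large_negative_raises(self):
        f, n = self._fits(-10.0 - 1e-7, -10.0)
        assert lod(f, n) == 0.0
        f, n = self._fits(-11.0, -10.0)
        with pytest.raises(LinkageError):
            lod(f, n)

    def test_fingerprint_mismatch(self, small_structures):
        rng = np.random.default_rng(9)
        truth = VCParams(mu=0, var_q=0.0, var_a=0.3, var_e=0.7)
        fams_a = simulate_families(small_structures[:2], truth, rng)
        fams_b = simulate_families(small_structures[:2], truth, rng)
        with pytest.raises(LinkageError, match="different data"):
            lod(fit(fams_a, "full"), fit(fams_b, "null"))


class TestFamilyLOD:
    def test_single_family_equals_total(self, small_structures):
        rng = np.random.default_rng(10)
        fams = simulate_families(
            small_structures[:1], VCParams(mu=0, var_q=0.4, var_a=0.2, var_e=0.4), rng
        )
        f_null = fit(fams, "null")
        f_full = fit(fams, "full", boundary_probe=f_null)
        profile = family_lod(f_full, f_null, fams)
        assert len(profile.fids) == 1
        assert profile.total == pytest.approx(lod(f_full, f_null), abs=1e-9)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_decomposition_identity(self, small_structures, seed):
        """Per-family LOD contributions sum to the total LOD."""
        rng = np.random.default_rng(seed)
        fams = simulate_families(
            small_structures, VCParams(mu=0, var_q=0.3, var_a=0.3, var_e=0.4), rng
        )
        f_null = fit(fams, "null")
        f_full = fit(fams, "full", boundary_probe=f_null)
        profile = family_lod(f_full, f_null, fams)
        assert profile.total == pytest.approx(lod(f_full, f_null), abs=1e-6)

    def test_requires_matching_families(self, small_structures):
        rng = np.random.default_rng(14)
        truth = VCParams(mu=0, var_q=0.0, var_a=0.5, var_e=0.5)
        fams = simulate_families(small_structures[:2], truth, rng)
        other = simulate_families(small_structures[:2], truth, rng)
        f_null = fit(fams, "null")
        f_full = fit(fams, "full", boundary_probe=f_null)
        with pytest.raises(LinkageError, match="families"):
            family_lod(f_full, f_null, other)


class TestNullMixture:
    def test_closed_form(self):
        assert null_expected_lod() == pytest.approx(1.0 / (4.0 * LN10), abs=1e-15)
        assert round(null_expected_lod(), 2) == 0.11

    def test_monte_carlo_agrees_with_closed_form(self):
        """Independent mixture draws (scipy chi2 + fair coin) match 1/(4 ln 10)."""
        rng = np.random.default_rng(15)
        n = 1_000_000
        draws = stats.chi2.rvs(1, size=n, random_state=rng) / (2 * LN10)
        draws[rng.random(n) < 0.5] = 0.0
        se = draws.std(ddof=1) / np.sqrt(n)
        assert abs(draws.mean() - null_expected_lod()) <= 3 * se
        # point mass of 1/2 at zero puts the median at (or next to) zero
        assert np.median(draws) == pytest.approx(0.0, abs=1e-5)
        assert (draws == 0).mean() == pytest.approx(0.5, abs=0.005)

    def test_sampler_matches_mixture(self):
        draws = sample_null_lod(200_000, seed=16)
        assert abs((draws == 0).mean() - 0.5) < 0.01
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - null_expected_lod()) <= 3 * se

    def test_lod_pvalue(self):
        assert lod_pvalue(0.0) == 0.5
        # independent oracle: half the normal two-sided tail at z = sqrt(2 ln10 * lod)
        z = math.sqrt(2 * LN10 * 3.0)
        assert lod_pvalue(3.0) == pytest.approx(stats.norm.sf(z), rel=1e-10)
        assert lod_pvalue(3.0) == pytest.approx(1.0e-4, rel=0.02)
        grid = np.linspace(0.01, 5, 50)
        pv = [lod_pvalue(x) for x in grid]
        assert np.all(np.diff(pv) < 0)
        with pytest.raises(ValueError):
            lod_pvalue(-0.1)


def test_fingerprint_sensitive_to_data(small_structures):
    rng = np.random.default_rng(17)
    truth = VCParams(mu=0, var_q=0.0, var_a=0.5, var_e=0.5)
    fams = simulate_families(small_structures[:2], truth, rng)
    fp = data_fingerprint(fams)
    fams[0].y = fams[0].y + 1e-9
    assert data_fingerprint(fams) != fp
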