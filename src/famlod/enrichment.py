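"""Max-LOD family selection and rare-allele enrichment evaluation.

In every phenotype replicate, the family with the largest family-specific
LOD score is "selected for sequencing". Over replicates, the observed rate
at which the selected family carries at least one causal minor allele of a
gene is compared against the expected probability for a randomly chosen
family (the number of carrier families divided by the number of families),
with a one-sided one-sample proportion test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .linkage import FamilyLODProfile
from .simulate import RareAlleleCounts

__all__ = [
    "SelectionRecord",
    "EnrichmentResult",
    "select_family",
    "expected_probability",
    "observed_hit_rate",
    "enrichment_pvalue",
    "summarize",
]


@dataclass(frozen=True)
class SelectionRecord:
    """Outcome of selecting the max-LOD family in one replicate for one gene."""

    gene: str
    replicate: int
    family: str
    family_lod: float
    carrier: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-gene enrichment summary (the Table-2-style row)."""

    gene: str
    mean_lod: float
    mean_max_family_lod: float
    expected: float
    observed: float
    p_value: float  # NaN when expected is 0 or 1 (analysis under the null / trivial)
    null_gene: bool = False


def select_family(profile: FamilyLODProfile) -> str:
    """The family with the largest family-specific LOD; ties go to the
    lexicographically smallest family id (deterministic)."""
    if len(profile.fids) == 0:
        raise ValueError("empty family LOD profile")
    top = profile.lods.max()
    tied = [fid for fid, v in zip(profile.fids, profile.lods) if v == top]
    return min(tied)


def expected_probability(counts: Mapping[str, int] | Sequence[int], k: int | None = None) -> float:
    """Probability that a randomly drawn family carries >= 1 minor-allele
    copy: the number of carrier families divided by the number of families."""
    values = list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    k = k if k is not None else len(values)
    if k < 1:
        raise ValueError("need at least one family")
    if len(values) != k:
        raise ValueError(f"got counts for {len(values)} families, expected {k}")
    return sum(1 for c in values if c >= 1) / k


def observed_hit_rate(selections: Sequence[SelectionRecord]) -> float:
    """Fraction of replicates in which the selected family is a carrier."""
    if not selections:
        raise ValueError("need at least one selection record")
    return sum(rec.carrier for rec in selections) / len(selections)


def enrichment_pvalue(
    observed: float, expected: float, n: int, method: str = "ztest"
) -> float:
    """One-sided test of enrichment over random family selection.

    ``ztest`` (default): upper-tail normal-approximation one-sample
    proportion test without continuity correction,
    z = (observed - expected) / sqrt(expected * (1 - expected) / n).
    ``binomial``: exact one-sided binomial tail.

    Returns NaN when expected is 0 or 1 (no informative comparison exists;
    a gene with no carrier families is analyzed under the null hypothesis).
    """
    if not 0.0 <= observed <= 1.0:
        raise ValueError(f"observed proportion must be in [0, 1], got {observed}")
    if not 0.0 <= expected <= 1.0:
        raise ValueError(f"expected proportion must be in [0, 1], got {expected}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if expected in (0.0, 1.0):
        return math.nan
    if method == "ztest":
        z = (observed - expected) / math.sqrt(expected * (1.0 - expected) / n)
        return float(stats.norm.sf(z))
    if method == "binomial":
        hits = round(observed * n)
        return float(stats.binom.sf(hits - 1, n, expected))
    raise ValueError(f"unknown method {method!r}; use 'ztest' or 'binomial'")


def summarize(
    lod_table: pd.DataFrame,
    selections: Sequence[SelectionRecord],
    counts: Mapping[str, RareAlleleCounts],
    n_families: int,
    method: str = "ztest",
) -> list[EnrichmentResult]:
    """Per-gene Table-2-style summary.

    ``lod_table`` has one row per (gene, replicate) with columns ``gene``,
    ``replicate``, ``lod`` and one ``lod_<fid>`` column per family. The mean
    LOD and the mean of the per-replicate *largest* family LOD are averaged
    over replicates (the max can come from different families across
    replicates, so mean-of-max >= max-of-mean).
    """
    genes = list(dict.fromkeys(lod_table["gene"]))
    missing = [g for g in genes if g not in counts]
    if missing:
        raise KeyError(f"genes missing from allele counts: {missing}")
    fam_cols = [c for c in lod_table.columns if c.startswith("lod_")]
    by_gene_sel: dict[str, list[SelectionRecord]] = {}
    for rec in selections:
        by_gene_sel.setdefault(rec.gene, []).append(rec)

    out: list[EnrichmentResult] = []
    for gene in genes:
        sub = lod_table[lod_table["gene"] == gene]
        recs = by_gene_sel.get(gene)
        if not recs:
            raise KeyError(f"gene {gene!r} has no selection records")
        expected = expected_probability(counts[gene].per_family, n_families)
        observed = observed_hit_rate(recs)
        out.append(
            EnrichmentResult(
                gene=gene,
                mean_lod=float(sub["lod"].mean()),
                mean_max_family_lod=float(sub[fam_cols].max(axis=1).mean()),
                expected=expected,
                observed=observed,
                p_value=enrichment_pvalue(observed, expected, len(recs), method=method),
                null_gene=expected == 0.0,
            )
        )
    return out


def results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabular (TSV-ready) form of the enrichment summary."""
    return pd.DataFrame(
        [
            (r.gene, r.mean_lod, r.mean_max_family_lod, r.expected, r.observed, r.p_value,
             "null-hypothesis gene" if r.null_gene else "")
            for r in results
        ],
        columns=["gene", "mean_LOD", "mean_LODmax", "expected", "observed", "p_value", "note"],
    )
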