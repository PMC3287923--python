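"""Effect-size accounting: per-gene additive scores, percent phenotypic
variance explained per family and overall, and allele-frequency helpers.

A gene's additive score for an individual is ``sum_v c_v * beta_v`` over the
gene's causal variants (c = minor-allele count). The percent of phenotypic
variance a gene explains in a group is the variance of that fixed score in
the group divided by the group's total phenotypic variance, averaged over
replicates — which is why a rare variant that is negligible in the general
population can explain a large share within the one family segregating it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import GenotypeTable, PhenotypeReplicate, VariantSpec

__all__ = [
    "GeneScore",
    "VarianceShare",
    "gene_score",
    "pct_variance",
    "minor_allele_frequency",
]

TOTAL_GROUP = "total"


@dataclass
class GeneScore:
    """Per-individual additive genetic value of one gene (trait units)."""

    gene: str
    values: pd.Series  # index (FID, IID)

    def group(self, fid: str) -> np.ndarray:
        if fid == TOTAL_GROUP:
            return self.values.to_numpy(dtype=float)
        return self.values.xs(fid, level="FID").to_numpy(dtype=float)


@dataclass(frozen=True)
class VarianceShare:
    """Percent of phenotypic variance explained by a gene in a group."""

    gene: str
    group: str  # family id or "total"
    percent: float


def gene_score(genotypes: GenotypeTable, variants: Sequence[VariantSpec]) -> GeneScore:
    """Weighted allele-count sum over the gene's variants."""
    genes = {v.gene for v in variants}
    if len(genes) != 1:
        raise ValueError(f"variants must belong to one gene, got {sorted(genes)}")
    (gene,) = genes
    missing = [v.variant for v in variants if v.variant not in genotypes.frame.columns]
    if missing:
        raise KeyError(f"variants missing from genotype table: {missing}")
    indexed = genotypes.frame.set_index(["FID", "IID"])
    values = sum(v.beta * indexed[v.variant] for v in variants)
    return GeneScore(gene=gene, values=values.astype(float))


def pct_variance(
    score: GeneScore,
    phenotypes: Sequence[PhenotypeReplicate],
    group: str,
    trait: str,
    use_adjusted: bool = False,
) -> VarianceShare:
    """Mean over replicates of Var_group(score) / Var_group(trait) * 100.

    The score is fixed across replicates; only the trait (denominator)
    varies. ``group`` is a family id or ``"total"``. The denominator is the
    raw trait variance by default; ``use_adjusted`` switches it to the
    ``<trait>_adj`` standardized-residual column.
    """
    if not phenotypes:
        raise ValueError("need at least one phenotype replicate")
    column = f"{trait}_adj" if use_adjusted else trait
    s = score.group(group)
    if len(s) < 2:
        raise ValueError(f"group {group!r} needs at least 2 members")
    num = float(np.var(s, ddof=1))
    ratios = []
    for rep in phenotypes:
        frame = rep.frame if group == TOTAL_GROUP else rep.frame[rep.frame["FID"] == group]
        if column not in frame.columns:
            raise KeyError(f"replicate {rep.index}: trait column {column!r} missing")
        denom = float(frame[column].to_numpy(dtype=float).var(ddof=1))
        if denom <= 0:
            raise ValueError(f"replicate {rep.index}: zero trait variance in group {group!r}")
        ratios.append(num / denom)
    return VarianceShare(gene=score.gene, group=group, percent=100.0 * float(np.mean(ratios)))


def minor_allele_frequency(copy_count: int, n_individuals: int, percent: bool = False) -> float:
    """MAF = minor-allele copies / (2 * number of diploid individuals).

    One copy among 697 individuals gives 1/1394 ~= 0.0717%.
    """
    if n_individuals < 1:
        raise ValueError("need at least one individual")
    if not 0 <= copy_count <= 2 * n_individuals:
        raise ValueError(f"copy count {copy_count} outside [0, {2 * n_individuals}]")
    maf = copy_count / (2.0 * n_individuals)
    return 100.0 * maf if percent else maf
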