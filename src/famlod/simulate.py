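"""GAW17-style family simulation: rare founder variants, gene dropping,
exact locus IBD, covariates, and replicated phenotypes.

The generator emulates the simulated mini-exome family design used at
Genetic Analysis Workshop 17: a fixed set of extended pedigrees (default
8 pedigrees, 697 individuals, 202 founders), rare causal variants planted
in founders (down to a single copy), Mendelian gene dropping to the
descendants, exact identity-by-descent sharing at each gene treated as a
point locus, and 200 phenotype replicates in which genotypes and
covariates stay fixed while polygenic and environmental noise is redrawn.

Everything is seeded; the same seed reproduces byte-identical genotypes,
IBD matrices and phenotypes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Individual, KinshipMatrix, Pedigree, kinship

__all__ = [
    "VariantSpec",
    "FounderAlleles",
    "AlleleLabelTable",
    "IBDMatrix",
    "GenotypeTable",
    "CovariateModel",
    "PhenotypeReplicate",
    "RareAlleleCounts",
    "PedigreeTemplate",
    "SingleCarrierSpec",
    "SimulationConfig",
    "SimulatedDataset",
    "assign_founder_alleles",
    "plant_single_copy",
    "gene_drop",
    "gene_drop_conditional",
    "ibd_from_labels",
    "build_genotype_table",
    "draw_covariates",
    "simulate_phenotypes",
    "count_rare_alleles",
    "extended_pedigree",
    "build_pedigrees",
    "default_config",
    "simulate_dataset",
]

#: A founder-allele label: (founder individual id, parental copy 0 or 1).
Label = tuple[str, int]


@dataclass(frozen=True)
class VariantSpec:
    """A causal variant: gene membership, founder MAF, and additive effect."""

    variant: str
    gene: str
    maf: float
    beta: float
    trait: str = "Q1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"variant {self.variant!r}: MAF must be in [0, 0.5], got {self.maf}")
        if not math.isfinite(self.beta):
            raise ValueError(f"variant {self.variant!r}: beta must be finite")


@dataclass(frozen=True)
class FounderAlleles:
    """Minor/major state of every founder allele copy for one variant."""

    variant: str
    minor_labels: frozenset[Label]

    @property
    def n_minor(self) -> int:
        return len(self.minor_labels)


def founder_labels(peds: Sequence[Pedigree]) -> list[Label]:
    """All founder allele labels across pedigrees, in pedigree order."""
    return [(ind.iid, c) for ped in peds for ind in ped.founders for c in (0, 1)]


def assign_founder_alleles(
    peds: Sequence[Pedigree], variant: VariantSpec, seed: int | np.random.SeedSequence
) -> FounderAlleles:
    """Each founder allele copy is minor independently with probability MAF."""
    rng = np.random.default_rng(seed)
    labels = founder_labels(peds)
    draws = rng.random(len(labels)) < variant.maf
    return FounderAlleles(
        variant=variant.variant,
        minor_labels=frozenset(lab for lab, hit in zip(labels, draws) if hit),
    )


def plant_single_copy(
    peds: Sequence[Pedigree], variant: VariantSpec, founder_iid: str
) -> FounderAlleles:
    """Single-carrier mode: exactly one minor copy, in the chosen founder.

    Among N unrelated individuals the population MAF of such a variant is
    1 / (2N) — e.g. 0.0717% for one copy in 697 unrelateds.
    """
    all_founders = {ind.iid for ped in peds for ind in ped.founders}
    if founder_iid not in all_founders:
        raise ValueError(f"{founder_iid!r} is not a founder in any supplied pedigree")
    return FounderAlleles(variant=variant.variant, minor_labels=frozenset({(founder_iid, 0)}))


@dataclass
class AlleleLabelTable:
    """Founder-allele labels carried by each member of one pedigree at one locus.

    Labels record the full transmission history of the locus, so both
    genotypes (given per-variant founder allele states) and exact IBD
    sharing derive from this table. All variants of a gene share one
    table because the gene is treated as a point locus.
    """

    fid: str
    gene: str
    labels: dict[str, tuple[Label, Label]]
    founder_alleles: tuple[FounderAlleles, ...] = ()

    def genotype(self, fa: FounderAlleles) -> dict[str, int]:
        """Minor-allele count per individual for one variant."""
        return {
            iid: int(pair[0] in fa.minor_labels) + int(pair[1] in fa.minor_labels)
            for iid, pair in self.labels.items()
        }

    def carriers(self, fa: FounderAlleles) -> set[str]:
        return {iid for iid, c in self.genotype(fa).items() if c > 0}


def gene_drop(
    ped: Pedigree,
    founder_alleles: Sequence[FounderAlleles],
    seed: int | np.random.SeedSequence,
    gene: str | None = None,
) -> AlleleLabelTable:
    """Drop labeled founder alleles through one pedigree (one meiosis per
    parent-offspring link, independent across offspring)."""
    rng = np.random.default_rng(seed)
    labels: dict[str, tuple[Label, Label]] = {}
    nonfounders = [ind for ind in ped.members if not ind.is_founder]
    picks = rng.integers(0, 2, size=(len(nonfounders), 2))
    k = 0
    for ind in ped.members:
        if ind.is_founder:
            labels[ind.iid] = ((ind.iid, 0), (ind.iid, 1))
        else:
            pat = labels[ind.father][picks[k, 0]]
            mat = labels[ind.mother][picks[k, 1]]
            labels[ind.iid] = (pat, mat)
            k += 1
    return AlleleLabelTable(
        fid=ped.fid,
        gene=gene or (founder_alleles[0].variant if founder_alleles else "locus"),
        labels=labels,
        founder_alleles=tuple(founder_alleles),
    )


def gene_drop_conditional(
    ped: Pedigree,
    founder_alleles: Sequence[FounderAlleles],
    target_descendant_carriers: int,
    seed: int | np.random.SeedSequence,
    gene: str | None = None,
    condition_on: FounderAlleles | None = None,
    max_tries: int = 100_000,
) -> AlleleLabelTable:
    """Rejection-sample gene drops until the number of non-founder carriers
    of ``condition_on`` (default: the first variant) equals the target.

    Reproduces scenarios such as one founder's rare allele reaching a fixed
    number of descendants. Deterministic given the seed; raises RuntimeError
    if the target is not hit within ``max_tries`` drops.
    """
    fa = condition_on or founder_alleles[0]
    nonfounder_ids = {ind.iid for ind in ped.nonfounders}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(max_tries)
    for attempt in range(max_tries):
        table = gene_drop(ped, founder_alleles, streams[attempt], gene=gene)
        n_carriers = len(table.carriers(fa) & nonfounder_ids)
        if n_carriers == target_descendant_carriers:
            return table
    raise RuntimeError(
        f"family {ped.fid!r}: no gene drop with exactly {target_descendant_carriers} "
        f"descendant carriers of {fa.variant!r} found in {max_tries} tries"
    )


@dataclass
class IBDMatrix:
    """Pairwise proportion of alleles shared identical by descent at a locus."""

    fid: str
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("IBD matrix shape does not match ids")

    def pi_hat(self, i: str, j: str) -> float:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        return float(self.values[idx[i], idx[j]])

    def subset(self, ids: Sequence[str]) -> np.ndarray:
        idx = {iid: k for k, iid in enumerate(self.ids)}
        pos = [idx[i] for i in ids]
        return self.values[np.ix_(pos, pos)]


def ibd_from_labels(ped: Pedigree, labels: AlleleLabelTable) -> IBDMatrix:
    """Exact locus IBD from inheritance labels.

    pi_hat(i, j) = m / 2 where m is the size of a maximum matching between
    i's and j's two allele labels under label equality (for two alleles a
    side, the max over the two possible pairings).
    """
    missing = [ind.iid for ind in ped.members if ind.iid not in labels.labels]
    if missing:
        raise ValueError(f"family {ped.fid!r}: individuals missing allele labels: {missing}")
    ids = ped.ids
    # integer-encode labels for vectorized comparison
    codes: dict[Label, int] = {}
    a = np.empty((len(ids), 2), dtype=np.int64)
    for k, iid in enumerate(ids):
        for c in (0, 1):
            a[k, c] = codes.setdefault(labels.labels[iid][c], len(codes))
    a1, a2 = a[:, 0], a[:, 1]
    straight = (a1[:, None] == a1[None, :]).astype(np.int64) + (a2[:, None] == a2[None, :])
    crossed = (a1[:, None] == a2[None, :]).astype(np.int64) + (a2[:, None] == a1[None, :])
    m = np.maximum(straight, crossed)
    return IBDMatrix(fid=ped.fid, ids=list(ids), values=m / 2.0)


@dataclass
class GenotypeTable:
    """Minor-allele counts (0/1/2): one row per individual, one column per variant."""

    frame: pd.DataFrame  # columns: FID, IID, <variant columns>

    @property
    def variants(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("FID", "IID")]

    def counts(self, variant: str) -> pd.Series:
        if variant not in self.frame.columns:
            raise KeyError(f"variant {variant!r} not in genotype table")
        return self.frame.set_index(["FID", "IID"])[variant]

    def family(self, fid: str) -> pd.DataFrame:
        return self.frame[self.frame["FID"] == fid]


def build_genotype_table(
    peds: Sequence[Pedigree],
    label_tables: Mapping[tuple[str, str], AlleleLabelTable],
    variants: Sequence[VariantSpec],
    founder_alleles: Mapping[str, FounderAlleles],
) -> GenotypeTable:
    """Assemble the genotype table from per-(gene, family) label tables."""
    rows = {"FID": [], "IID": []}
    for ped in peds:
        rows["FID"].extend([ped.fid] * len(ped))
        rows["IID"].extend(ped.ids)
    frame = pd.DataFrame(rows)
    for v in variants:
        col = np.zeros(len(frame), dtype=np.int64)
        pos = 0
        for ped in peds:
            table = label_tables[(v.gene, ped.fid)]
            geno = table.genotype(founder_alleles[v.variant])
            col[pos : pos + len(ped)] = [geno[iid] for iid in ped.ids]
            pos += len(ped)
        frame[v.variant] = col
    return GenotypeTable(frame=frame)


# -- covariates and phenotypes ------------------------------------------


@dataclass(frozen=True)
class CovariateModel:
    """Fixed-effect covariate model for the simulated traits.

    Ages are uniform over ``age_range`` (years), smoking is Bernoulli with
    rate ``smoking_rate``, sex comes from the pedigree file (coded 0 = male,
    1 = female in the design matrix). Effects are in trait units.
    """

    age_range: tuple[float, float] = (30.0, 75.0)
    smoking_rate: float = 0.3
    beta_age: float = 0.01
    beta_sex: float = 0.1
    beta_smoke: float = 0.2
    mu: float = 0.0


def draw_covariates(
    peds: Sequence[Pedigree], model: CovariateModel, seed: int | np.random.SeedSequence
) -> pd.DataFrame:
    """One covariate draw per individual (fixed across phenotype replicates)."""
    rng = np.random.default_rng(seed)
    rows = []
    for ped in peds:
        for ind in ped.members:
            rows.append((ped.fid, ind.iid, ind.sex))
    frame = pd.DataFrame(rows, columns=["FID", "IID", "sex_code"])
    lo, hi = model.age_range
    frame["age"] = rng.uniform(lo, hi, size=len(frame)).round(1)
    frame["sex"] = (frame["sex_code"] == FEMALE).astype(int)
    frame["smoke"] = (rng.random(len(frame)) < model.smoking_rate).astype(int)
    return frame[["FID", "IID", "age", "sex", "smoke"]]


@dataclass
class PhenotypeReplicate:
    """One replicate of simulated traits (genotypes and covariates fixed)."""

    index: int
    frame: pd.DataFrame  # columns: FID, IID, age, sex, smoke, <trait columns>

    def trait(self, name: str) -> pd.Series:
        return self.frame.set_index(["FID", "IID"])[name]


def simulate_phenotypes(
    peds: Sequence[Pedigree],
    genotypes: GenotypeTable,
    variants: Sequence[VariantSpec],
    covariates: pd.DataFrame,
    model: CovariateModel,
    var_a: float,
    var_e: float,
    n_replicates: int,
    seed: int | np.random.SeedSequence,
    kinships: Mapping[str, KinshipMatrix] | None = None,
) -> list[PhenotypeReplicate]:
    """Simulate trait replicates under the additive model

        y = mu + b_age*age + b_sex*sex + b_smoke*smoke + sum_v beta_v c_v + g + e

    with polygenic g ~ N(0, 2*Phi*var_a) jointly per family and independent
    environmental e ~ N(0, var_e). Only g and e are redrawn across replicates.
    """
    if var_a < 0 or var_e < 0:
        raise ValueError("variance components must be non-negative")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    kinships = kinships or {ped.fid: kinship(ped) for ped in peds}

    base = covariates.merge(genotypes.frame, on=["FID", "IID"], how="left", validate="one_to_one")
    traits = sorted({v.trait for v in variants}) or ["Q1"]
    fixed: dict[str, np.ndarray] = {}
    covariate_part = (
        model.mu
        + model.beta_age * base["age"].to_numpy()
        + model.beta_sex * base["sex"].to_numpy()
        + model.beta_smoke * base["smoke"].to_numpy()
    )
    for t in traits:
        genetic = np.zeros(len(base))
        for v in variants:
            if v.trait == t:
                genetic += v.beta * base[v.variant].to_numpy()
        fixed[t] = covariate_part + genetic

    # per-family Cholesky of 2*Phi, aligned to the covariate row order
    fam_slices: list[tuple[slice, np.ndarray]] = []
    pos = 0
    for ped in peds:
        sl = slice(pos, pos + len(ped))
        assert list(base["IID"].iloc[sl]) == ped.ids, "row order must follow pedigrees"
        two_phi = 2.0 * kinships[ped.fid].subset(ped.ids)
        try:
            chol = np.linalg.cholesky(two_phi)
        except np.linalg.LinAlgError:  # semi-definite (e.g. duplicated genomes)
            chol = np.linalg.cholesky(two_phi + 1e-10 * np.eye(len(ped)))
        fam_slices.append((sl, chol))
        pos += len(ped)

    n = len(base)
    out: list[PhenotypeReplicate] = []
    sd_a, sd_e = math.sqrt(var_a), math.sqrt(var_e)
    for r in range(1, n_replicates + 1):
        frame = base[["FID", "IID", "age", "sex", "smoke"]].copy()
        for t in traits:
            g = np.zeros(n)
            if sd_a > 0:
                for sl, chol in fam_slices:
                    g[sl] = sd_a * (chol @ rng.standard_normal(chol.shape[0]))
            e = sd_e * rng.standard_normal(n)
            frame[t] = fixed[t] + g + e
        out.append(PhenotypeReplicate(index=r, frame=frame))
    return out


# -- rare-allele bookkeeping --------------------------------------------


@dataclass
class RareAlleleCounts:
    """Per-family minor-allele copy counts for one gene, split founder vs descendant."""

    gene: str
    per_family: dict[str, int]
    founder_per_family: dict[str, int]
    descendant_per_family: dict[str, int]

    @property
    def founder_total(self) -> int:
        return sum(self.founder_per_family.values())

    @property
    def descendant_total(self) -> int:
        return sum(self.descendant_per_family.values())

    @property
    def total(self) -> int:
        return sum(self.per_family.values())

    @property
    def carrier_families(self) -> set[str]:
        return {fid for fid, c in self.per_family.items() if c > 0}


def count_rare_alleles(
    genotypes: GenotypeTable,
    peds: Sequence[Pedigree],
    variants: Sequence[VariantSpec],
    gene: str,
) -> RareAlleleCounts:
    """Minor-allele copy counts per family for a gene, and the founder /
    descendant split of those copies (the Table-1-style bookkeeping)."""
    gene_variants = [v for v in variants if v.gene == gene]
    if not gene_variants:
        raise KeyError(f"gene {gene!r} has no variants in the panel")
    per_family: dict[str, int] = {}
    founder_pf: dict[str, int] = {}
    desc_pf: dict[str, int] = {}
    for ped in peds:
        fam = genotypes.family(ped.fid).set_index("IID")
        founder_ids = [ind.iid for ind in ped.founders]
        total = founders = 0
        for v in gene_variants:
            col = fam[v.variant]
            total += int(col.sum())
            founders += int(col.loc[founder_ids].sum())
        per_family[ped.fid] = total
        founder_pf[ped.fid] = founders
        desc_pf[ped.fid] = total - founders
    return RareAlleleCounts(
        gene=gene,
        per_family=per_family,
        founder_per_family=founder_pf,
        descendant_per_family=desc_pf,
    )


# -- pedigree templates --------------------------------------------------


@dataclass(frozen=True)
class PedigreeTemplate:
    """Size specification for one extended pedigree."""

    fid: str
    n_members: int
    n_founders: int


def extended_pedigree(fid: str, n_members: int, n_founders: int) -> Pedigree:
    """Deterministically build a multigenerational pedigree of the given size.

    Construction: one founding couple; descendants marry founder spouses in
    the order they are born (breadth-first), each couple receiving an
    even-as-possible share of the remaining children, until the target
    founder and member counts are met. Yields 3-5 generations for
    GAW17-scale families (~87 members, ~25 founders).
    """
    if n_founders < 2:
        raise ValueError("need at least the founding couple")
    n_desc = n_members - n_founders
    n_couples = n_founders - 1  # founding couple + one couple per married-in spouse
    if n_desc < n_couples - 1:
        raise ValueError(
            f"family {fid!r}: {n_desc} descendants cannot supply {n_couples - 1} marrying members"
        )
    base, extra = divmod(n_desc, n_couples)
    children_per_couple = [base + (1 if k < extra else 0) for k in range(n_couples)]

    members: list[Individual] = []
    f1, f2 = f"{fid}-F1", f"{fid}-F2"
    members.append(Individual(iid=f1, fid=fid, father=None, mother=None, sex=MALE))
    members.append(Individual(iid=f2, fid=fid, father=None, mother=None, sex=FEMALE))
    couples: list[tuple[str, str]] = [(f1, f2)]
    pool: list[Individual] = []  # unmarried descendants, FIFO
    n_children = 0
    n_spouses = 0
    for ci in range(n_couples):
        if ci > 0:
            child = pool.pop(0)
            n_spouses += 1
            spouse_sex = FEMALE if child.sex == MALE else MALE
            spouse = Individual(
                iid=f"{fid}-S{n_spouses}", fid=fid, father=None, mother=None, sex=spouse_sex
            )
            members.append(spouse)
            father, mother = (child.iid, spouse.iid) if child.sex == MALE else (spouse.iid, child.iid)
            couples.append((father, mother))
        father, mother = couples[ci]
        for _ in range(children_per_couple[ci]):
            n_children += 1
            kid = Individual(
                iid=f"{fid}-I{n_children}",
                fid=fid,
                father=father,
                mother=mother,
                sex=MALE if n_children % 2 else FEMALE,
            )
            members.append(kid)
            pool.append(kid)
    ped = Pedigree(fid, members, sort=False)
    assert len(ped) == n_members and len(ped.founders) == n_founders
    return ped


def build_pedigrees(templates: Sequence[PedigreeTemplate]) -> list[Pedigree]:
    return [extended_pedigree(t.fid, t.n_members, t.n_founders) for t in templates]


# -- whole-dataset simulation --------------------------------------------


@dataclass(frozen=True)
class SingleCarrierSpec:
    """Plant exactly one minor copy in one founder and (optionally) condition
    the gene drop on an exact number of descendant carriers."""

    family: str
    founder: str | None = None  # default: first founder of the family
    descendant_carriers: int | None = None


@dataclass
class SimulationConfig:
    """Full study-design description for one simulated dataset."""

    templates: list[PedigreeTemplate]
    variants: list[VariantSpec]
    covariates: CovariateModel = field(default_factory=CovariateModel)
    var_a: float = 0.3
    var_e: float = 0.5
    n_replicates: int = 200
    seed: int = 17
    single_carrier: dict[str, SingleCarrierSpec] = field(default_factory=dict)
    max_condition_tries: int = 100_000

    @property
    def genes(self) -> list[str]:
        seen: list[str] = []
        for v in self.variants:
            if v.gene not in seen:
                seen.append(v.gene)
        return seen

    @property
    def traits(self) -> list[str]:
        return sorted({v.trait for v in self.variants})


def default_config(seed: int = 17, n_replicates: int = 200) -> SimulationConfig:
    """The default GAW17-like study: 8 extended pedigrees, 697 individuals,
    202 founders, 200 replicates, and a panel of four scenario genes.

    * ``SINGLE1`` — one minor copy in a founder of family 7, conditioned to
      reach exactly 30 descendant carriers; beta 1.0 (the strong
      single-carrier-family scenario).
    * ``MULTI1`` — three rare variants segregating in several families.
    * ``NULL1`` — monomorphic gene: no minor alleles, analysis runs under
      the null hypothesis.
    * ``SPARSE1`` — a second-trait gene with few copies.
    """
    templates = [
        PedigreeTemplate(fid=str(k), n_members=87, n_founders=25) for k in range(1, 7)
    ] + [
        PedigreeTemplate(fid="7", n_members=87, n_founders=26),
        PedigreeTemplate(fid="8", n_members=88, n_founders=26),
    ]
    variants = [
        VariantSpec("SINGLE1_V1", "SINGLE1", maf=0.0, beta=1.0, trait="Q1"),
        VariantSpec("MULTI1_V1", "MULTI1", maf=0.012, beta=0.35, trait="Q1"),
        VariantSpec("MULTI1_V2", "MULTI1", maf=0.008, beta=0.45, trait="Q1"),
        VariantSpec("MULTI1_V3", "MULTI1", maf=0.005, beta=0.30, trait="Q1"),
        VariantSpec("NULL1_V1", "NULL1", maf=0.0, beta=0.8, trait="Q1"),
        VariantSpec("SPARSE1_V1", "SPARSE1", maf=0.004, beta=0.40, trait="Q2"),
        VariantSpec("SPARSE1_V2", "SPARSE1", maf=0.004, beta=0.40, trait="Q2"),
    ]
    return SimulationConfig(
        templates=templates,
        variants=variants,
        n_replicates=n_replicates,
        seed=seed,
        single_carrier={"SINGLE1": SingleCarrierSpec(family="7", descendant_carriers=30)},
    )


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces."""

    config: SimulationConfig
    pedigrees: list[Pedigree]
    kinships: dict[str, KinshipMatrix]
    founder_alleles: dict[str, FounderAlleles]  # by variant id
    label_tables: dict[tuple[str, str], AlleleLabelTable]  # by (gene, fid)
    genotypes: GenotypeTable
    ibd: dict[tuple[str, str], IBDMatrix]  # by (gene, fid)
    covariates: pd.DataFrame
    phenotypes: list[PhenotypeReplicate]

    def counts(self, gene: str) -> RareAlleleCounts:
        return count_rare_alleles(self.genotypes, self.pedigrees, self.config.variants, gene)


def _seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(int(master),) + tuple(int(k) for k in key))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: pedigrees -> founder alleles -> gene drops ->
    genotypes -> exact IBD -> covariates -> phenotype replicates.

    Seeds for every stage derive from ``config.seed`` by a counter scheme,
    so any stage is reproducible in isolation.
    """
    peds = build_pedigrees(config.templates)
    kinships = {ped.fid: kinship(ped) for ped in peds}
    genes = config.genes
    variants_by_gene = {g: [v for v in config.variants if v.gene == g] for g in genes}

    founder_alleles: dict[str, FounderAlleles] = {}
    for vi, v in enumerate(config.variants):
        sc = config.single_carrier.get(v.gene)
        if sc is not None:
            ped = next(p for p in peds if p.fid == sc.family)
            founder = sc.founder or ped.founders[0].iid
            founder_alleles[v.variant] = plant_single_copy(peds, v, founder)
        else:
            founder_alleles[v.variant] = assign_founder_alleles(peds, v, _seed(config.seed, 1, vi))

    label_tables: dict[tuple[str, str], AlleleLabelTable] = {}
    ibd: dict[tuple[str, str], IBDMatrix] = {}
    for gi, gene in enumerate(genes):
        fas = [founder_alleles[v.variant] for v in variants_by_gene[gene]]
        sc = config.single_carrier.get(gene)
        for pi, ped in enumerate(peds):
            key = _seed(config.seed, 2, gi, pi)
            if sc is not None and sc.descendant_carriers is not None and ped.fid == sc.family:
                table = gene_drop_conditional(
                    ped,
                    fas,
                    sc.descendant_carriers,
                    key,
                    gene=gene,
                    max_tries=config.max_condition_tries,
                )
            else:
                table = gene_drop(ped, fas, key, gene=gene)
            label_tables[(gene, ped.fid)] = table
            ibd[(gene, ped.fid)] = ibd_from_labels(ped, table)

    genotypes = build_genotype_table(peds, label_tables, config.variants, founder_alleles)
    covariates = draw_covariates(peds, config.covariates, _seed(config.seed, 3))
    phenotypes = simulate_phenotypes(
        peds,
        genotypes,
        config.variants,
        covariates,
        config.covariates,
        config.var_a,
        config.var_e,
        config.n_replicates,
        _seed(config.seed, 4),
        kinships=kinships,
    )
    return SimulatedDataset(
        config=config,
        pedigrees=peds,
        kinships=kinships,
        founder_alleles=founder_alleles,
        label_tables=label_tables,
        genotypes=genotypes,
        ibd=ibd,
        covariates=covariates,
        phenotypes=phenotypes,
    )


# -- TSV writers / readers (the on-disk exchange formats) ----------------


def write_genotypes(genotypes: GenotypeTable, path: str | Path) -> None:
    genotypes.frame.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeTable:
    frame = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    return GenotypeTable(frame=frame)


def write_ibd(ibd: Mapping[tuple[str, str], IBDMatrix], path: str | Path) -> None:
    """MERLIN-style pairwise layout with a gene (locus) column:
    gene, FID, ID1, ID2, pi_hat — upper triangle including the diagonal."""
    rows = []
    for (gene, fid), mat in ibd.items():
        n = len(mat.ids)
        for i in range(n):
            for j in range(i, n):
                rows.append((gene, fid, mat.ids[i], mat.ids[j], mat.values[i, j]))
    pd.DataFrame(rows, columns=["gene", "FID", "ID1", "ID2", "pi_hat"]).to_csv(
        path, sep="\t", index=False
    )


def read_ibd(path: str | Path) -> dict[tuple[str, str], IBDMatrix]:
    frame = pd.read_csv(path, sep="\t", dtype={"FID": str, "ID1": str, "ID2": str, "gene": str})
    out: dict[tuple[str, str], IBDMatrix] = {}
    for (gene, fid), grp in frame.groupby(["gene", "FID"], sort=False):
        ids: list[str] = []
        for iid in pd.concat([grp["ID1"], grp["ID2"]]):
            if iid not in ids:
                ids.append(iid)
        idx = {iid: k for k, iid in enumerate(ids)}
        values = np.zeros((len(ids), len(ids)))
        for _, row in grp.iterrows():
            i, j = idx[row["ID1"]], idx[row["ID2"]]
            values[i, j] = values[j, i] = row["pi_hat"]
        out[(gene, fid)] = IBDMatrix(fid=fid, ids=ids, values=values)
    return out


def write_phenotypes(replicates: Sequence[PhenotypeReplicate], path: str | Path) -> None:
    frames = []
    for rep in replicates:
        frame = rep.frame.copy()
        frame.insert(0, "replicate", rep.index)
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | Path) -> list[PhenotypeReplicate]:
    frame = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    return [
        PhenotypeReplicate(index=int(r), frame=grp.drop(columns="replicate").reset_index(drop=True))
        for r, grp in frame.groupby("replicate", sort=True)
    ]


def write_variants(variants: Sequence[VariantSpec], path: str | Path) -> None:
    pd.DataFrame(
        [(v.gene, v.variant, v.maf, v.beta, v.trait) for v in variants],
        columns=["gene", "variant", "maf", "beta", "trait"],
    ).to_csv(path, sep="\t", index=False)


def read_variants(path: str | Path) -> list[VariantSpec]:
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant": str, "trait": str})
    return [
        VariantSpec(
            variant=row["variant"],
            gene=row["gene"],
            maf=float(row["maf"]),
            beta=float(row["beta"]),
            trait=row["trait"],
        )
        for _, row in frame.iterrows()
    ]
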