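# famlod

Variance-component linkage with **family-specific LOD decomposition**, for
choosing which pedigree to sequence when hunting rare causal variants.

## The problem

Rare variants with large effects are prime suspects for the heritability
that genome-wide association studies leave unexplained, but sequencing
families at random is wasteful: a variant carried by one founder in one
pedigree is simply absent from most families you could draw. If a locus is
already implicated (say, by a prior association signal), linkage evidence
computed *per family* can point at the pedigrees in which the causal allele
is actually segregating — those are the families worth sequencing.

`famlod` implements and evaluates that strategy on simulated data modeled
on the Genetic Analysis Workshop 17 family design (8 extended pedigrees,
697 individuals of whom 202 are founders, 200 phenotype replicates on fixed
genotypes):

1. **Simulate** rare founder variants (down to a single copy), drop them
   through the pedigrees (Mendelian gene dropping), record exact
   identity-by-descent (IBD) sharing at each gene, and draw replicated
   quantitative traits with additive variant effects, age/sex/smoking
   covariates, polygenic and environmental variance.
2. **Adjust** each trait for age, sex and smoking by OLS and standardize the
   residuals.
3. **Fit** the variance-component linkage model per replicate. Within family
   *f* the trait is multivariate normal with covariance

   ```
   Ω_f = σ²_q Π_f + σ²_a 2Φ_f + σ²_e I
   ```

   (Π = pairwise IBD proportions at the locus, Φ = kinship). The LOD score
   is the log₁₀ likelihood ratio of this model against the null with
   σ²_q = 0; the **family-specific LOD** is family *f*'s log-likelihood-ratio
   contribution evaluated at the whole-sample ML estimates, so the
   per-family scores sum exactly to the total LOD.
4. **Select** the family with the largest family-specific LOD in each
   replicate, and **evaluate** enrichment: how often does the selected
   family carry ≥ 1 causal minor allele, versus the probability
   (#carrier families / #families) for a random pick? A one-sided
   proportion z-test quantifies the difference.

Under the no-linkage null, 2·ln(10)·LOD follows the half-half mixture of a
χ²₁ and a point mass at 0, so the expected null LOD is 1/(4 ln 10) ≈ 0.11 —
the package ships closed-form and Monte-Carlo utilities for this mixture.

## Worked example

```python
from famlod import default_config, simulate_dataset, adjust_replicates
from famlod.pipeline import linkage_scan
from famlod import select_family, expected_probability, enrichment_pvalue

cfg = default_config(seed=313, n_replicates=200)   # 8 pedigrees, 697 people
ds = simulate_dataset(cfg)
adjust_replicates(ds.phenotypes, ["Q1"])

# scan the single-carrier gene: one founder copy in family 7,
# conditioned to reach exactly 30 descendant carriers
table, profiles = linkage_scan(ds.pedigrees, ds.kinships,
                               ds.phenotypes, ds.ibd, {"SINGLE1": "Q1"})
carriers = ds.counts("SINGLE1").carrier_families          # {'7'}
picks = [select_family(p) for p in profiles.values()]
observed = sum(p in carriers for p in picks) / len(picks)
expected = expected_probability(ds.counts("SINGLE1").per_family)
print(f"mean LOD {table['lod'].mean():.2f}  expected {expected:.3f}  "
      f"observed {observed:.3f}  p {enrichment_pvalue(observed, expected, 200):.2e}")
```

Output:

```
mean LOD 1.57  expected 0.125  observed 0.970  p 3.35e-286
```

A randomly chosen family would carry the rare allele 12.5% of the time
(1 carrier family out of 8); picking the max-LOD family finds it in 97% of
the 200 replicates. On the same run, `pct_variance` reports that the gene
explains ≈ 23% of the phenotypic variance within the carrier family but
only ≈ 4.9% in the whole sample — the dilution that makes carrier families
so valuable for sequencing.

The same workflow is available from the shell:

```bash
famlod run-all --seed 313 --replicates 200 --genes SINGLE1 --out results/
famlod simulate --seed 1 --out data/      # stage-wise execution also works
```

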