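# seleffect

Cancer effect sizes — population-genetic scaled selection coefficients —
for somatic single-nucleotide variants in tumor cohorts.

Recurrently mutated genes are usually ranked by how often they are
mutated, but prevalence confounds two things: how often a substitution
*arises* (mutation) and how strongly it is *selected* once it arises.
`seleffect` separates them. For each substitution it models the per-tumor
neutral mutation rate μ_ij from trinucleotide-context signatures and
gene-level silent-mutation rates, then asks how much that rate must be
scaled by a selection coefficient γ to explain the substitution's
recurrence across the cohort. A rare substitution arising on a tiny
mutation rate can carry a far larger cancer effect than a common one in a
mutation hotspot.

## Model

Mutations at a site arrive as a Poisson flux with per-tumor intensity
γ·μ_ij, but a selected substitution is observed at most once per tumor,
so tumor j contributes a Bernoulli observation with

    P(substitution present in tumor j) = 1 − exp(−γ μ_ij)

Across independent tumors the log-likelihood

    ℓ(γ) = Σ_{j mutated} log(1 − exp(−γ μ_ij)) − γ Σ_{j not mutated} μ_ij

is unimodal; γ̂ is its maximizer and 95% confidence intervals are
profile-likelihood intervals (the points where ℓ drops χ²₁(0.95)/2 ≈ 1.92
below the maximum). Gene-level effects share one γ across all of a
gene's substitutions observed in the cohort and are reported for genes
with more than four cohort substitutions.

The per-tumor rates μ_ij come from three layers:

1. **Signature attribution** — each tumor's 96-channel spectrum is
   decomposed over a signature catalog (COSMIC-layout CSV) by
   non-negative least squares; low-mutation tumors inherit the pooled
   cohort fit; configured signatures are excluded before fitting.
2. **Gene neutral rates** — each gene's expected neutral substitutions
   per tumor, estimated from cohort silent-mutation counts with
   context-aware silent opportunity and gamma-Poisson empirical-Bayes
   shrinkage across genes.
3. **Site rates** — the gene rate is spread over every (site, alternate
   allele) pair proportionally to the tumor's context profile, so that
   site rates within a gene sum exactly to the gene rate.

A fully specified synthetic-cohort generator (`seleffect.simulate`)
produces reference FASTA, gene models, MAF-dialect variant tables and
ground-truth tables from the same generative model, so every stage is
testable without external data.

## Worked example

Simulate a 423-tumor cohort with four planted drivers and analyze it end
to end:

```python
from seleffect.report import run_pipeline

result = run_pipeline({"simulate": {"n_samples": 423, "seed": 1076067307}}, "out/")
print(result.report[["gene_id", "prevalence", "gamma_hat",
                     "ci95_low", "ci95_high"]].head(4).to_string())
```

```
  gene_id  prevalence    gamma_hat     ci95_low    ci95_high
0  NOTCH1    0.288416  1212.645158  1012.237259  1437.926071
1  PIK3R1    0.096927   428.578677   310.421907   573.478492
2   RPL10    0.073286   256.460681   176.448529   357.631427
3    NRAS    0.066194   189.778912   127.882501   269.006939
```

The four genes carrying planted drivers top the table. `prevalence` is
the fraction of tumors with at least one nonsilent substitution in the
gene; `gamma_hat` is the shared scaled selection coefficient (γ = 1
would mean substitutions fix at the neutral rate) with its 95% profile
CI. Note PIK3R1: three times rarer than NOTCH1 yet still a strong
effect — exactly the kind of gene prevalence ranking under-weights.
`out/` additionally contains every intermediate (annotated variants,
signature weights, context profiles, gene rates, variant-level effects).

The same pipeline runs on real data from files:

```
seleffect run --config analysis.yaml --out out/
```

with a config pointing at `maf`, `fasta`, `genes`, `catalog` (and
optionally a cohort `samples` list and per-gene `covariates`) under an
`inputs:` block. Stage-at-a-time subcommands (`simulate`, `annotate`,
`signatures`, `rates`, `effects`, `report`, `cooccur`) expose the
intermediates.

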