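# Methods

## The selection model

The quantity estimated for every substitution is a scaled selection
coefficient γ: the factor by which the substitution's neutral mutation
rate must be multiplied to account for how often it is observed, fixed,
in independent tumors. The observation model treats each tumor as one
Bernoulli trial. Mutation (and fixation) events at a site form a Poisson
flux with per-tumor intensity γ·μ_ij, but a site is recorded at most
once per tumor, so the presence probability is 1 − exp(−γ μ_ij) and the
cohort log-likelihood is

    ℓ(γ) = Σ_{j∈carriers} log(1 − exp(−γ μ_ij)) − γ Σ_{j∉carriers} μ_ij.

Assumptions worth keeping in mind:

- tumors are independent and exchangeable (no weighting by purity,
  coverage, or clonality);
- μ_ij is treated as known when γ is estimated — uncertainty in the rate
  layers below is *not* propagated into the CI;
- γ is constant over the tumor's evolution (no epoch structure) and over
  the sites pooled in a gene-level estimate;
- silent substitutions are neutral and nonsilent substitutions at
  distinct sites are independent.

Maximization is 1-D on log γ over the fixed bracket [1e−3, 1e9]
(scipy bounded Brent, tolerance 1e−8 in log space; fully deterministic).
With no carriers the MLE is the γ = 0 boundary; with every tumor a
carrier the likelihood is unbounded above and the bracket top is
returned, flagged. 95% CIs are profile-likelihood intervals: bracketed
root-finding (brentq on log γ) for the two points where ℓ falls
χ²₁(0.95)/2 ≈ 1.9207 below the maximum; a side whose root escapes the
search range reports that bound. In the homogeneous special case
(uniform μ, k of n tumors mutated) the MLE has the closed form
−ln(1 − k/n)/μ and the CI is the exact transform of the binomial profile
interval; both are pinned by tests.

Gene-level estimates share one γ across the gene's substitutions
observed in the cohort; sites never seen mutated do not enter the
product, while each observed substitution contributes all tumors'
presence/absence terms. Genes enter the gene-level output only with
more than four tumor-level substitution events (configurable
`min_substitutions`, default 5); events, not distinct sites, are
counted. Silent variants are never scored for selection — they are the
training data of the rate model, and scoring them would be circular.

## Context rates (96 channels) and signature attribution

SNVs are classed by pyrimidine-collapsed trinucleotide context — 6
substitution types × 16 flank pairs — with purine-reference events
mapped through the reverse complement, matching COSMIC SBS practice.
Channel collapse is genome-strand based and independent of gene strand.

Per-tumor spectra are fitted against a signature catalog by plain
non-negative least squares on raw counts (`scipy.optimize.nnls`); the
strict fit, no bootstrapping or relaxation. Exclusion lists (e.g.
treatment-associated processes known to be absent from a cohort) remove
catalog columns *before* fitting; the default exclusion list is empty
and user-supplied. Tumors with fewer than `min_mutations` (default 50)
annotatable SNVs take the profile fitted to the element-wise sum of all
cohort spectra — the simplest whole-cohort pooling rule. The fitted
mixture pushed through the catalog, normalized, is the tumor's relative
context-rate profile.

The packaged catalog is synthetic: five signatures with partially
disjoint channel support, generated once from a fixed constant seed.
Partial disjointness keeps NNLS identifiable so that mixture-recovery
tests measure the method, not catalog degeneracy. Real COSMIC v3.2 CSVs
load through the same reader; nothing is fetched from the network.

## Gene neutral rates

`mu_gene` is the expected number of neutral substitutions per tumor over
the gene's whole coding footprint. With per-tumor silent fraction
f_gj = s_gj/t_gj (profile mass on silent vs. all site-alternate pairs)
and E_g its cohort mean, the method-of-moments estimate is
n_silent/(n·E_g). Because silent counts per gene are small, a
gamma-Poisson empirical-Bayes layer is fitted by maximizing the marginal
negative-binomial likelihood across genes (Nelder-Mead on log-dispersion
and log prior mean; covariates, when given, enter the prior mean
log-linearly after standardization). The posterior mean
(n_silent + α)/(n·E_g + α/m̄) shrinks sparse genes toward the prior
mean; the reported `shrinkage_weight` is the data share of that convex
combination.

This layer is a deliberately simple, documented stand-in for full
covariate-regularized dN/dS machinery (trinucleotide rate-matrix
regression, expression/chromatin covariates): the pipeline needs
gene-level neutral rates, not that machinery's internals. Two
consequences are documented rather than hidden: (i) the posterior mean
is conditionally biased toward the prior for genes far from it — with a
10× spread of true rates and no covariates we measure ≈ −13% for
high-rate genes, while the method-of-moments route is unbiased within a
few percent — and (ii) with rates spanning 10× across 50 genes and 500
tumors, rank recovery (Spearman) sits around 0.8–0.86 per cohort.

## Site rates

A gene's rate is distributed over its 3L site-alternate pairs in
proportion to the tumor's profile value at each pair's channel,
normalized within the gene, so conservation Σ μ_ij = mu_gene holds to
float precision for every (gene, tumor) — audited by tests at 1e−9
relative. Rates are per (site, alternate) triple so the selection model
addresses a specific substitution. Context at exon boundaries uses
genomic flanking bases, not spliced neighbors; coding sites lacking a
flank on the contig (possible only in degenerate fixtures) are excluded
with zero rate.

## The synthetic cohort generator

The generator draws, per cohort: codon-wise random coding sequences (61
sense codons, so no internal stops; strands alternate), Dirichlet
signature mixtures per tumor (concentration 1.5 — moderately
heterogeneous mixtures), Poisson neutral mutations per (tumor, site)
with the exact site-rate model above (collapsed to presence, alternate
drawn proportionally to the tumor's channel rates), and planted driver
substitutions present with probability 1 − exp(−γ_true μ_ij). All
randomness flows from one integer seed; identical seeds give
byte-identical artifacts.

Defaults emulate a pediatric leukemia cohort at desk scale: 423 tumors;
ten recurrently mutated leukemia genes with scaled-down footprints
(52–180 codons); per-gene neutral rates of 2e−4 per codon per tumor, so
a 100-codon gene expects 0.02 neutral substitutions per tumor — chosen
so cohort-wide silent counts per gene (a handful to tens) match what the
real genes' full-length footprints accumulate in cohorts of this size;
and four planted drivers with γ between 2.5e3 and 8e3, putting carrier
prevalence between roughly 4% and 25%.

What the generator does *not* emulate — and hence what passing recovery
tests do and do not show: no sequencing error or variant-calling noise,
no copy-number or fusion events, no clonal structure or subclonal
fractions, identical sample lists with no missingness, and a coding
footprint thousands of times smaller than an exome. The last point has a
visible consequence: planted drivers contribute a large share of all
simulated mutations, so fitted context profiles are partly driven by the
drivers' own channels and driver-site rates are overestimated, deflating
full-pipeline γ̂ by up to ~2× at strong drivers. Ranking is unaffected
(the planted drivers top the effect table), and the calibration
experiment that feeds the truth-table rates to the likelihood shows the
inference itself is calibrated (≈94% CI coverage, median |log(γ̂/γ)| ≈
0.1 at n = 1000). In real exomes, genome-wide passengers dominate
spectra and this contamination is negligible.

## Numerical and design choices

- Coordinates are 1-based closed (MAF convention); the FASTA is the
  single source of truth for reference alleles; mismatching rows are
  rejected and tallied, indel/MNV rows skipped and tallied.
- The standard genetic code is hand-written in `io.py`; tests verify
  consequence calls against Biopython translation as an independent
  oracle.
- NNLS weights are in count units and are not forced to sum to the
  spectrum total; profiles are normalized after mixing.
- Degenerate inputs fail loudly: all-zero spectra are routed to pooling,
  zero silent mutations cohort-wide is fatal (rates unidentifiable),
  a profile with no mass on any of a gene's channels is fatal for that
  (gene, tumor) pair, and CDS lengths not divisible by 3 are fatal per
  gene.
- Ties in the report table break by gene name; the bubble-area column is
  proportional to carrier count.
- Sample lists: rates are per tumor, so the cohort list (including
  tumors with zero SNVs) should be supplied; when it is not, the samples
  present in the MAF are used and a warning is logged.

## Known limitations

- Rate uncertainty is not propagated into effect CIs (CIs are slightly
  anticonservative under the full pipeline).
- The neutral-rate layer ignores indels, noncoding regions, and
  sub-gene covariates such as replication timing.
- Gene-level γ pools sites with genuinely different effects into one
  number; the variant-level table is the finer view.
- Co-occurrence tallies take deletion calls as an input list; no
  copy-number inference is attempted.
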