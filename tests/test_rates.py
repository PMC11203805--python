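"""Gene-level neutral rate estimation from silent substitutions."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from seleffect import (
    ModelFitError,
    SimulationConfig,
    VariantRecord,
    build_site_table,
    estimate_gene_rates,
    generate_cohort,
    silent_opportunity,
)
from seleffect.channels import N_CHANNELS
from seleffect.io import Consequence, SENSE_CODONS, variants_from_frame
from seleffect.report import annotate_cohort
from seleffect.signatures import ContextRateProfile

from conftest import make_gene_reference

UNIFORM = ContextRateProfile("U", np.full(N_CHANNELS, 1 / 96))


def toy_gene_table(seed=0, n_codons=30, strand="+"):
    rng = np.random.default_rng(seed)
    cds = "".join(rng.choice(np.array(SENSE_CODONS), size=n_codons))
    ref, gene = make_gene_reference(cds, strand=strand)
    return ref, gene, build_site_table(gene, ref)


class TestSilentOpportunity:
    def test_uniform_profile_counts_silent_pairs(self):
        _, _, table = toy_gene_table(1)
        ok = table.channel >= 0
        expect = (table.silent & ok).sum() / 96
        assert silent_opportunity(table, UNIFORM) == pytest.approx(expect, rel=1e-12)

    def test_tryptophan_codons_have_no_silent_changes(self):
        # TGG is the only Trp codon: every substitution is nonsilent
        ref, gene = make_gene_reference("TGG" * 10)
        table = build_site_table(gene, ref)
        assert silent_opportunity(table, UNIFORM) == 0.0

    def test_linear_in_profile_weight(self):
        """Doubling the profile mass on channels that only hit silent
        pairs doubles their contribution."""
        _, _, table = toy_gene_table(2)
        ok = table.channel >= 0
        silent_only = set(table.channel[ok & table.silent]) - set(
            table.channel[ok & ~table.silent]
        )
        assert silent_only, "fixture gene needs silent-only channels"
        base = np.full(N_CHANNELS, 1.0)
        boosted = base.copy()
        idx = np.array(sorted(silent_only))
        boosted[idx] *= 2
        from seleffect.rates import opportunity_sums

        s_base, _ = opportunity_sums(table, base)
        s_boost, _ = opportunity_sums(table, boosted)
        counts = np.bincount(table.channel[ok & table.silent], minlength=N_CHANNELS)
        contribution = counts[idx].sum() * 1.0
        assert s_boost - s_base == pytest.approx(contribution, rel=1e-12)


def _silent_variants(gene_id, table, samples, k):
    """k silent variant records for a gene, cycling over samples."""
    rows = np.flatnonzero(table.silent & (table.channel >= 0))
    out = []
    for i in range(k):
        r = int(rows[i % len(rows)])
        out.append(
            VariantRecord(
                sample_id=samples[i % len(samples)],
                chrom="ctg",
                pos=int(table.gpos[r]),
                ref_allele=str(table.ref_g[r]),
                alt_allele=str(table.alt_g[r]),
                gene_id=gene_id,
                consequence=Consequence.SILENT,
                channel=int(table.channel[r]),
            )
        )
    return out


class TestEstimateGeneRates:
    def test_closed_form_without_shrinkage(self):
        """mu = n_silent / (n_samples * silent_fraction) exactly."""
        _, _, table = toy_gene_table(3)
        samples = [f"S{i}" for i in range(40)]
        profiles = {s: UNIFORM for s in samples}
        variants = _silent_variants("TOY", table, samples, k=7)
        [rate] = estimate_gene_rates(
            variants, {"TOY": table}, profiles, samples, shrinkage=False
        )
        ok = table.channel >= 0
        frac = (table.silent & ok).sum() / ok.sum()
        assert rate.mu_gene == pytest.approx(7 / (40 * frac), rel=1e-9)
        assert rate.shrinkage_weight == 1.0
        assert rate.n_silent_observed == 7

    def test_identical_genes_identical_estimates(self):
        _, _, table = toy_gene_table(4)
        samples = [f"S{i}" for i in range(30)]
        profiles = {s: UNIFORM for s in samples}
        variants = _silent_variants("G1", table, samples, 5) + _silent_variants(
            "G2", table, samples, 5
        )
        rates = estimate_gene_rates(
            variants, {"G1": table, "G2": table}, profiles, samples, shrinkage=True
        )
        by_gene = {r.gene_id: r for r in rates}
        assert by_gene["G1"].mu_gene == pytest.approx(by_gene["G2"].mu_gene, rel=1e-12)

    def test_zero_silent_cohortwide_fatal(self):
        _, _, table = toy_gene_table(5)
        samples = ["S0", "S1"]
        profiles = {s: UNIFORM for s in samples}
        with pytest.raises(ModelFitError):
            estimate_gene_rates([], {"TOY": table}, profiles, samples)

    def test_shrinkage_compresses_toward_prior_mean(self):
        """Shrunk estimates sit between the raw estimate and the prior
        mean, never beyond the raw value."""
        tables = {}
        variants = []
        samples = [f"S{i}" for i in range(50)]
        profiles = {s: UNIFORM for s in samples}
        counts = {"G0": 1, "G1": 4, "G2": 9, "G3": 25}
        for i, (g, k) in enumerate(counts.items()):
            _, _, t = toy_gene_table(10 + i)
            tables[g] = t
            variants += _silent_variants(g, t, samples, k)
        raw = {
            r.gene_id: r.mu_gene
            for r in estimate_gene_rates(
                variants, tables, profiles, samples, shrinkage=False
            )
        }
        shrunk = estimate_gene_rates(variants, tables, profiles, samples, shrinkage=True)
        mean_raw = np.mean(list(raw.values()))
        for r in shrunk:
            lo, hi = sorted([raw[r.gene_id], mean_raw])
            assert lo - 1e-9 <= r.mu_gene <= hi + 1e-9
            assert 0.0 <= r.shrinkage_weight <= 1.0


def _cohort_recovery(seed):
    genes = tuple((f"G{i:02d}", 60) for i in range(50))
    mu_true = dict(
        zip((g for g, _ in genes), np.logspace(np.log10(0.01), np.log10(0.1), 50))
    )
    cfg = SimulationConfig(
        n_samples=500, genes=genes, gene_rates_true=mu_true, driver_sites=(), seed=seed
    )
    cohort = generate_cohort(cfg)
    variants = annotate_cohort(
        variants_from_frame(cohort.maf, cohort.reference).variants,
        cohort.reference,
        cohort.genes,
    )
    profiles = {
        s: ContextRateProfile(s, cohort.truth.profiles[j])
        for j, s in enumerate(cohort.truth.samples)
    }
    return cohort, variants, profiles, mu_true


class TestRecovery:
    def test_rank_recovery_across_tenfold_rate_range(self):
        """Estimated gene rates rank-correlate with truth (rates spanning
        10x, 50 genes, 500 tumors; mean over 5 cohorts)."""
        rhos = []
        for seed in range(5):
            cohort, variants, profiles, mu_true = _cohort_recovery(300 + seed)
            rates = estimate_gene_rates(
                variants, cohort.site_tables, profiles, cohort.truth.samples
            )
            est = {r.gene_id: r.mu_gene for r in rates}
            rho = spearmanr(
                [mu_true[g] for g in est], [est[g] for g in est]
            ).statistic
            rhos.append(rho)
        assert np.mean(rhos) >= 0.8

    def test_raw_estimator_unbiased_where_counts_are_informative(self):
        """Mean relative bias of the method-of-moments rate is within 10%
        for genes expecting at least 5 silent events (500 tumors, 50
        replicate cohorts)."""
        rels = []
        for seed in range(50):
            cohort, variants, profiles, mu_true = _cohort_recovery(600 + seed)
            rates = estimate_gene_rates(
                variants,
                cohort.site_tables,
                profiles,
                cohort.truth.samples,
                shrinkage=False,
            )
            for r in rates:
                lam = 500 * r.opportunity
                if lam * mu_true[r.gene_id] >= 5:
                    rels.append((r.mu_gene - mu_true[r.gene_id]) / mu_true[r.gene_id])
        assert abs(np.mean(rels)) <= 0.10
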