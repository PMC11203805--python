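"""Pipeline orchestration, effect tables, and co-occurrence tallies.

Runs annotate → signature attribution → neutral rates → selection
inference over a configuration that points at real inputs (MAF, FASTA,
gene models, signature catalog) or at a simulation block, writes every
intermediate as TSV, and produces the prevalence-vs-effect table that
backs bubble plots of gene-level cancer effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .catalogs import synthetic_signature_catalog
from .io import (
    Consequence,
    GeneModel,
    InputError,
    MafReadResult,
    SignatureCatalog,
    SiteTable,
    VariantRecord,
    annotate_context,
    build_site_table,
    classify_consequence,
    count_spectrum,
    read_fasta,
    read_gene_models,
    read_maf,
)
from .rates import GeneRate, estimate_gene_rates, gene_rates_to_frame
from .selection import (
    DEFAULT_MIN_SUBSTITUTIONS,
    SelectionEstimate,
    estimate_gene_effect,
    estimate_variant_effect,
)
from .signatures import (
    AttributionResult,
    DEFAULT_MIN_MUTATIONS,
    pool_sparse_samples,
)
from .simulate import SimulationConfig, generate_cohort, write_cohort
from .siterates import site_rate_matrix

log = logging.getLogger(__name__)


@dataclass
class CooccurrenceTally:
    """Per-gene overlap between substitution carriers and a deletion
    call set: of the samples with at least one substitution in the gene,
    how many are also listed as carrying a focal deletion."""

    gene_id: str
    n_substitution_carriers: int
    n_with_codeletion: int

    def __post_init__(self) -> None:
        if self.n_with_codeletion > self.n_substitution_carriers:
            raise InputError("co-deleted samples cannot exceed substitution carriers")


def cooccurrence(
    variants: Iterable[VariantRecord],
    deletions: Iterable[tuple[str, str]],
    gene_id: str,
) -> CooccurrenceTally:
    """Tally substitution/deletion co-occurrence for one gene.

    ``deletions`` are (sample_id, gene_id) pairs from an external
    copy-number call set.
    """
    carriers = {v.sample_id for v in variants if v.gene_id == gene_id}
    deleted = {s for s, g in deletions if g == gene_id}
    return CooccurrenceTally(
        gene_id=gene_id,
        n_substitution_carriers=len(carriers),
        n_with_codeletion=len(carriers & deleted),
    )


def annotate_cohort(
    variants: Iterable[VariantRecord],
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
) -> list[VariantRecord]:
    """Assign gene, trinucleotide channel, and consequence to every SNV.

    Gene assignment is positional: the first gene model whose coding
    intervals contain the variant's position on its contig. Variants
    outside every coding interval are noncoding (they still contribute to
    spectra via their channel).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for v in variants:
        v = annotate_context(v, reference)
        gene = next(
            (g for g in by_chrom.get(v.chrom, []) if g.contains(v.pos)), None
        )
        if gene is None:
            v = _io.replace(v, gene_id=None, consequence=Consequence.NONCODING)
        else:
            v = _io.replace(
                v,
                gene_id=gene.gene_id,
                consequence=classify_consequence(v, gene, reference),
            )
        out.append(v)
    return out


def variants_to_frame(variants: Sequence[VariantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "gene_id": v.gene_id if v.gene_id is not None else "",
                "consequence": v.consequence.value if v.consequence else "",
                "channel": v.channel if v.channel is not None else -1,
            }
            for v in variants
        ]
    )


def variants_from_annotated_frame(df: pd.DataFrame) -> list[VariantRecord]:
    out = []
    for rec in df.to_dict(orient="records"):
        out.append(
            VariantRecord(
                sample_id=str(rec["sample_id"]),
                chrom=str(rec["chrom"]),
                pos=int(rec["pos"]),
                ref_allele=str(rec["ref"]),
                alt_allele=str(rec["alt"]),
                gene_id=str(rec["gene_id"]) or None,
                consequence=Consequence(rec["consequence"]) if rec["consequence"] else None,
                channel=int(rec["channel"]) if int(rec["channel"]) >= 0 else None,
            )
        )
    return out


def cohort_spectra(
    variants: Sequence[VariantRecord], samples: Sequence[str]
) -> list[_io.MutationalSpectrum]:
    """One spectrum per cohort sample (zero vectors for unmutated tumors)."""
    by_sample: dict[str, list[VariantRecord]] = {s: [] for s in samples}
    for v in variants:
        if v.sample_id in by_sample:
            by_sample[v.sample_id].append(v)
    return [count_spectrum(by_sample[s], sample_id=s) for s in samples]


@dataclass
class EffectResults:
    variant_effects: list[SelectionEstimate]
    gene_effects: list[SelectionEstimate]
    skipped_genes: dict[str, int]  # gene -> substitution count below threshold


def estimate_effects(
    variants: Sequence[VariantRecord],
    site_tables: Mapping[str, SiteTable],
    gene_rates: Sequence[GeneRate],
    attribution: AttributionResult,
    samples: Sequence[str],
    min_substitutions: int = DEFAULT_MIN_SUBSTITUTIONS,
) -> EffectResults:
    """Variant- and gene-level selection estimates for nonsilent SNVs.

    Silent substitutions are the neutral-rate training data and are not
    scored for selection. Variant-level estimates use every tumor's
    presence/absence at the site; gene-level estimates share one gamma
    across the gene's observed substitutions and require at least
    ``min_substitutions`` cohort events.
    """
    n = len(samples)
    sample_index = {s: i for i, s in enumerate(samples)}
    rate_by_gene = {r.gene_id: r for r in gene_rates}
    profile_matrix = np.vstack([attribution.profiles[s].rates for s in samples])

    by_gene: dict[str, dict[tuple[int, str], np.ndarray]] = {}
    for v in variants:
        if (
            v.consequence == Consequence.NONSILENT
            and v.gene_id in rate_by_gene
            and v.channel is not None
        ):
            key = (v.pos, v.alt_allele)
            gene_map = by_gene.setdefault(v.gene_id, {})
            if key not in gene_map:
                gene_map[key] = np.zeros(n, dtype=bool)
            j = sample_index.get(v.sample_id)
            if j is None:
                raise InputError(
                    f"variant sample {v.sample_id!r} missing from cohort sample list"
                )
            gene_map[key][j] = True

    variant_effects: list[SelectionEstimate] = []
    gene_effects: list[SelectionEstimate] = []
    skipped: dict[str, int] = {}
    for gene_id in sorted(by_gene):
        table = site_tables[gene_id]
        mu_matrix = site_rate_matrix(
            table, rate_by_gene[gene_id].mu_gene, profile_matrix
        )
        row_of = {
            (int(table.gpos[r]), str(table.alt_g[r])): r
            for r in range(len(table.gpos))
        }
        rate_blocks, mutated_blocks = [], []
        for (pos, alt), indicator in sorted(by_gene[gene_id].items()):
            r = row_of.get((pos, alt))
            if r is None or table.channel[r] < 0:
                log.warning(
                    "%s:%d>%s not in gene site table or lacks context; skipped",
                    gene_id,
                    pos,
                    alt,
                )
                continue
            rates_j = mu_matrix[:, r]
            variant_effects.append(
                estimate_variant_effect(
                    rates_j, indicator, identifier=f"{gene_id}:{pos}:{alt}"
                )
            )
            rate_blocks.append(rates_j)
            mutated_blocks.append(indicator)
        est = estimate_gene_effect(
            rate_blocks,
            mutated_blocks,
            identifier=gene_id,
            n_samples=n,
            min_substitutions=min_substitutions,
        )
        if est is None:
            skipped[gene_id] = int(sum(m.sum() for m in mutated_blocks))
        else:
            gene_effects.append(est)
    return EffectResults(variant_effects, gene_effects, skipped)


def effects_to_frame(estimates: Sequence[SelectionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scope": e.scope,
                "identifier": e.identifier,
                "n_substitutions": e.n_substitutions,
                "prevalence": e.prevalence,
                "gamma_hat": e.gamma_hat,
                "ci95_low": e.ci95_low,
                "ci95_high": e.ci95_high,
                "boundary_flag": e.boundary_flag,
            }
            for e in estimates
        ],
        columns=[
            "scope",
            "identifier",
            "n_substitutions",
            "prevalence",
            "gamma_hat",
            "ci95_low",
            "ci95_high",
            "boundary_flag",
        ],
    )


def bubble_table(
    gene_effects: Sequence[SelectionEstimate],
    n_samples: int,
    known_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Plot-ready prevalence-vs-effect table, sorted by effect.

    ``highlighted`` marks genes *not* in the user's previously identified
    list; ``circle_area`` is proportional to the carrier count.
    """
    known = set(known_genes)
    rows = []
    for e in sorted(gene_effects, key=lambda e: (-e.gamma_hat, e.identifier)):
        carriers = int(round(e.prevalence * n_samples))
        rows.append(
            {
                "gene_id": e.identifier,
                "prevalence": e.prevalence,
                "n_carriers": carriers,
                "gamma_hat": e.gamma_hat,
                "ci95_low": e.ci95_low,
                "ci95_high": e.ci95_high,
                "highlighted": e.identifier not in known,
                "circle_area": float(carriers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "prevalence",
            "n_carriers",
            "gamma_hat",
            "ci95_low",
            "ci95_high",
            "highlighted",
            "circle_area",
        ],
    )


def plot_bubbles(table: pd.DataFrame, path: str | Path) -> None:
    """Optional headless bubble plot: effect (x, log scale) with CI bars,
    circle area proportional to carrier count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(table), 4) + 1.5))
    y = np.arange(len(table))[::-1]
    area = 20 + 180 * table["circle_area"] / max(table["circle_area"].max(), 1)
    ax.hlines(y, table["ci95_low"].clip(lower=1e-3), table["ci95_high"], color="0.7")
    ax.scatter(table["gamma_hat"].clip(lower=1e-3), y, s=area, zorder=3)
    ax.set_yticks(y)
    ax.set_yticklabels(table["gene_id"])
    ax.set_xscale("log")
    ax.set_xlabel("scaled selection coefficient (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    samples: list[str]
    variants: list[VariantRecord]
    read_stats: MafReadResult | None
    attribution: AttributionResult
    gene_rates: list[GeneRate]
    effects: EffectResults
    report: pd.DataFrame


def _load_inputs(config: Mapping) -> tuple[
    dict[str, str], list[GeneModel], MafReadResult, SignatureCatalog, list[str], dict | None
]:
    if "simulate" in config:
        sim = dict(config["simulate"])
        sim_cfg = SimulationConfig(
            n_samples=int(sim.get("n_samples", SimulationConfig.n_samples)),
            seed=int(sim.get("seed", 0)),
            mixture_concentration=float(
                sim.get("mixture_concentration", SimulationConfig.mixture_concentration)
            ),
        )
        cohort = generate_cohort(sim_cfg)
        catalog = synthetic_signature_catalog()
        maf = _io.variants_from_frame(cohort.maf, cohort.reference)
        return (
            cohort.reference,
            cohort.genes,
            maf,
            catalog,
            cohort.truth.samples,
            None,
        )
    try:
        inputs = config["inputs"]
        reference = read_fasta(inputs["fasta"])
        genes = read_gene_models(inputs["genes"])
        maf = read_maf(inputs["maf"], reference, config.get("maf_columns"))
        catalog = SignatureCatalog.from_csv(inputs["catalog"])
    except KeyError as exc:
        raise InputError(f"config missing required input: {exc}") from exc
    if "samples" in inputs:
        samples = (
            pd.read_csv(inputs["samples"], sep="\t")["sample_id"].astype(str).tolist()
        )
    else:
        samples = sorted({v.sample_id for v in maf.variants})
        log.warning(
            "no cohort sample list supplied; using the %d samples present in "
            "the MAF (tumors with zero SNVs are invisible)",
            len(samples),
        )
    covariates = None
    if "covariates" in inputs:
        cov_df = pd.read_csv(inputs["covariates"], sep="\t")
        covariates = {
            str(r[0]): [float(x) for x in r[1:]] for r in cov_df.itertuples(index=False)
        }
    return reference, genes, maf, catalog, samples, covariates


def run_pipeline(config: Mapping, outdir: str | Path) -> PipelineResult:
    """Execute the full analysis; every intermediate is written as TSV.

    Deterministic given inputs: reruns produce byte-identical artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference, genes, maf, catalog, samples, covariates = _load_inputs(config)
    log.info(
        "inputs: %d SNVs (%d skipped, %d ref-mismatch), %d genes, %d samples",
        len(maf.variants),
        maf.n_skipped_non_snv,
        maf.n_rejected_ref_mismatch,
        len(genes),
        len(samples),
    )

    variants = annotate_cohort(maf.variants, reference, genes)
    variants_to_frame(variants).to_csv(
        outdir / "variants_annotated.tsv", sep="\t", index=False
    )

    sig_cfg = config.get("signatures", {})
    spectra = cohort_spectra(variants, samples)
    attribution = pool_sparse_samples(
        spectra,
        catalog,
        min_mutations=int(sig_cfg.get("min_mutations", DEFAULT_MIN_MUTATIONS)),
        exclusion_list=sig_cfg.get("exclude", ()),
    )
    wrows = []
    for s in samples:
        w = attribution.weights[s]
        row = {"sample_id": s, "pooled": s in attribution.pooled_samples}
        row.update(w.as_dict())
        row["residual_norm"] = w.residual_norm
        wrows.append(row)
    pd.DataFrame(wrows).to_csv(outdir / "signature_weights.tsv", sep="\t", index=False)
    prof = pd.DataFrame(
        np.vstack([attribution.profiles[s].rates for s in samples]),
        columns=list(_io.CHANNEL_LABELS),
    )
    prof.insert(0, "sample_id", samples)
    prof.to_csv(outdir / "context_profiles.tsv", sep="\t", index=False)

    site_tables = {g.gene_id: build_site_table(g, reference) for g in genes}
    rates_cfg = config.get("rates", {})
    gene_rates = estimate_gene_rates(
        variants,
        site_tables,
        attribution.profiles,
        samples,
        covariates=covariates,
        shrinkage=bool(rates_cfg.get("shrinkage", True)),
    )
    gene_rates_to_frame(gene_rates).to_csv(
        outdir / "gene_rates.tsv", sep="\t", index=False
    )

    eff_cfg = config.get("effects", {})
    effects = estimate_effects(
        variants,
        site_tables,
        gene_rates,
        attribution,
        samples,
        min_substitutions=int(
            eff_cfg.get("min_substitutions", DEFAULT_MIN_SUBSTITUTIONS)
        ),
    )
    effects_to_frame(effects.variant_effects).to_csv(
        outdir / "effects_variant.tsv", sep="\t", index=False
    )
    effects_to_frame(effects.gene_effects).to_csv(
        outdir / "effects_gene.tsv", sep="\t", index=False
    )

    rep_cfg = config.get("report", {})
    report = bubble_table(
        effects.gene_effects, len(samples), rep_cfg.get("known_genes", ())
    )
    report.to_csv(outdir / "effects_report.tsv", sep="\t", index=False)
    if rep_cfg.get("plot"):
        plot_bubbles(report, outdir / "effects_bubbles.png")

    log.info(
        "effects: %d variant-level, %d gene-level (%d genes below threshold)",
        len(effects.variant_effects),
        len(effects.gene_effects),
        len(effects.skipped_genes),
    )
    return PipelineResult(
        samples=list(samples),
        variants=variants,
        read_stats=maf,
        attribution=attribution,
        gene_rates=gene_rates,
        effects=effects,
        report=report,
    )
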