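"""Synthetic somatic-substitution cohorts with known ground truth.

The generator is the generative counterpart of the inference model. Each
tumor draws a signature mixture; mixtures pushed through the catalog give
per-tumor context profiles; each gene's neutral rate is spread over its
site-alternate pairs proportionally to the tumor's profile (conserving
the gene total); neutral mutation counts per site are Poisson with that
mean, collapsed to presence/absence (a site mutated more than once in a
tumor is recorded once); planted driver substitutions are present with
probability 1 - exp(-gamma * mu_ij). The emitted artifacts — FASTA
reference, gene-model TSV, MAF-dialect variant table, and truth tables —
feed the pipeline exactly like real inputs.

Defaults emulate a pediatric leukemia cohort at desk scale: a few hundred
tumors, a handful of recurrently mutated genes with scaled-down coding
footprints, low per-gene neutral rates, and drivers whose scaled
selection coefficients put their prevalence in the few-percent range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import synthetic_signature_catalog
from .channels import COMPLEMENT, N_CHANNELS, revcomp
from .io import (
    DEFAULT_MAF_COLUMNS,
    GeneModel,
    InputError,
    SENSE_CODONS,
    SignatureCatalog,
    SiteTable,
    build_site_table,
    write_fasta,
    write_gene_models,
)

log = logging.getLogger(__name__)

_PAD = 10  # flanking bases around each gene so every coding site has context

#: default toy gene set: leukemia driver names with scaled-down lengths
DEFAULT_GENES: tuple[tuple[str, int], ...] = (
    ("CDKN2A", 52),
    ("FBXW7", 140),
    ("IL7R", 120),
    ("KRAS", 63),
    ("NOTCH1", 180),
    ("NRAS", 63),
    ("PIK3R1", 120),
    ("RPL10", 120),
    ("TOX", 100),
    ("XBP1", 87),
)

#: default neutral rate per codon (expected substitutions per tumor)
DEFAULT_RATE_PER_CODON = 2e-4


@dataclass(frozen=True)
class DriverSite:
    """A planted positively selected substitution: 1-based nucleotide
    index within the gene's coding sequence, and its true scaled
    selection coefficient."""

    gene_id: str
    cds_site: int
    gamma: float


DEFAULT_DRIVERS: tuple[DriverSite, ...] = (
    DriverSite("NOTCH1", 250, 8.0e3),
    DriverSite("NRAS", 35, 2.5e3),
    DriverSite("PIK3R1", 170, 4.0e3),
    DriverSite("RPL10", 292, 3.0e3),
)


@dataclass
class SimulationConfig:
    """Cohort-level generative parameters; all randomness flows from
    ``seed``."""

    n_samples: int = 423
    genes: tuple[tuple[str, int], ...] = DEFAULT_GENES
    gene_rates_true: Mapping[str, float] | None = None
    signature_mixtures: np.ndarray | None = None  # (n_samples, S), rows sum to 1
    mixture_concentration: float = 1.5  # Dirichlet parameter for random mixtures
    driver_sites: tuple[DriverSite, ...] = DEFAULT_DRIVERS
    seed: int = 0

    def resolved_gene_rates(self) -> dict[str, float]:
        if self.gene_rates_true is not None:
            rates = dict(self.gene_rates_true)
        else:
            rates = {g: n * DEFAULT_RATE_PER_CODON for g, n in self.genes}
        for g, r in rates.items():
            if r < 0:
                raise InputError(f"{g}: negative neutral rate")
        return rates


@dataclass
class TruthTable:
    """Ground truth of a generated cohort."""

    samples: list[str]
    signature_names: tuple[str, ...]
    weights: np.ndarray  # (n_samples, S) realized mixtures
    profiles: np.ndarray  # (n_samples, 96) context profiles
    gene_mu: dict[str, float]
    drivers: tuple[DriverSite, ...]
    driver_alts: dict[tuple[str, int], str]  # forward-strand alt per driver
    site_tables: dict[str, SiteTable]

    def site_rate_truth(self, gene_id: str, row: int) -> np.ndarray:
        """True per-sample mu_ij for one site-table row of a gene."""
        table = self.site_tables[gene_id]
        ok = table.channel >= 0
        w = np.zeros((len(self.samples), len(table.channel)))
        w[:, ok] = self.profiles[:, table.channel[ok]]
        return self.gene_mu[gene_id] * w[:, row] / w.sum(axis=1)

    def driver_row(self, driver: DriverSite) -> int:
        table = self.site_tables[driver.gene_id]
        alt = self.driver_alts[(driver.gene_id, driver.cds_site)]
        rows = np.flatnonzero((table.site == driver.cds_site) & (table.alt_g == alt))
        return int(rows[0])


@dataclass
class CohortData:
    reference: dict[str, str]
    genes: list[GeneModel]
    site_tables: dict[str, SiteTable]
    maf: pd.DataFrame
    truth: TruthTable


def _build_reference(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, str], list[GeneModel], dict[str, SiteTable]]:
    """Deterministically draw contigs and gene models from the rng stream.

    Coding sequences are sampled codon-wise from the 61 sense codons, so
    every CDS translates without internal stops; triplet composition is
    rich enough to populate all 96 channels at cohort scale. Strands
    alternate so both orientations are exercised.
    """
    reference: dict[str, str] = {}
    genes: list[GeneModel] = []
    bases = np.array(list("ACGT"))
    codons = np.array(SENSE_CODONS)
    for idx, (gene_id, n_codons) in enumerate(config.genes):
        if n_codons < 2:
            raise InputError(f"{gene_id}: gene must have at least 2 codons")
        cds = "".join(rng.choice(codons, size=n_codons))
        strand = "+" if idx % 2 == 0 else "-"
        segment = cds if strand == "+" else revcomp(cds)
        pad5 = "".join(rng.choice(bases, size=_PAD))
        pad3 = "".join(rng.choice(bases, size=_PAD))
        chrom = f"ctg_{gene_id}"
        reference[chrom] = pad5 + segment + pad3
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                intervals=((_PAD + 1, _PAD + len(segment)),),
                strand=strand,
            )
        )
    tables = {g.gene_id: build_site_table(g, reference) for g in genes}
    return reference, genes, tables


def _draw_weights(
    config: SimulationConfig, rng: np.random.Generator, n_signatures: int
) -> np.ndarray:
    if config.signature_mixtures is not None:
        w = np.asarray(config.signature_mixtures, dtype=float)
        if w.shape != (config.n_samples, n_signatures):
            raise InputError(
                f"signature_mixtures shape {w.shape} != "
                f"({config.n_samples}, {n_signatures})"
            )
        if (w < 0).any() or not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
            raise InputError("signature mixtures must be non-negative rows summing to 1")
        return w
    alpha = np.full(n_signatures, config.mixture_concentration)
    return rng.dirichlet(alpha, size=config.n_samples)


def generate_cohort(
    config: SimulationConfig, catalog: SignatureCatalog | None = None
) -> CohortData:
    """Draw a full cohort; identical seeds give byte-identical artifacts."""
    if catalog is None:
        catalog = synthetic_signature_catalog()
    if config.n_samples < 1:
        raise InputError("n_samples must be at least 1")
    rng = np.random.default_rng(config.seed)
    reference, genes, tables = _build_reference(config, rng)
    gene_mu = config.resolved_gene_rates()
    unknown = set(gene_mu) - {g for g, _ in config.genes}
    if unknown:
        raise InputError(f"gene_rates_true for unknown genes: {sorted(unknown)}")

    weights = _draw_weights(config, rng, catalog.n_signatures)
    profiles = weights @ catalog.matrix.T
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    n = config.n_samples
    samples = [f"S{j:04d}" for j in range(n)]

    driver_by_gene: dict[str, list[DriverSite]] = {}
    for d in sorted(config.driver_sites, key=lambda d: (d.gene_id, d.cds_site)):
        if d.gamma <= 0:
            raise InputError(f"driver at {d.gene_id}:{d.cds_site} needs gamma > 0")
        driver_by_gene.setdefault(d.gene_id, []).append(d)

    rows: list[tuple[str, str, int, str, str, str]] = []
    driver_alts: dict[tuple[str, int], str] = {}
    for gene in genes:
        table = tables[gene.gene_id]
        mu_g = gene_mu[gene.gene_id]
        ok = table.channel >= 0
        w = np.zeros((n, len(table.channel)))
        w[:, ok] = profiles[:, table.channel[ok]]
        totals = w.sum(axis=1)
        mu = mu_g * w / totals[:, None]  # (n, 3L)
        L = table.n_sites
        mu3 = mu.reshape(n, L, 3)

        # pick each driver's substitution: lowest forward-strand alternate
        # among the nonsilent alternates of its site
        driver_rows: dict[int, DriverSite] = {}
        for d in driver_by_gene.get(gene.gene_id, []):
            if not 1 <= d.cds_site <= L:
                raise InputError(
                    f"driver site {d.cds_site} outside {gene.gene_id} "
                    f"({L} coding sites)"
                )
            cand = np.flatnonzero(
                (table.site == d.cds_site) & ~table.silent & (table.channel >= 0)
            )
            if len(cand) == 0:
                raise InputError(
                    f"driver site {gene.gene_id}:{d.cds_site} has no "
                    "annotatable nonsilent alternate"
                )
            row = int(cand[np.argsort(table.alt_g[cand])[0]])
            driver_rows[row] = d
            driver_alts[(d.gene_id, d.cds_site)] = str(table.alt_g[row])

        driver_site_idx = {(r // 3) for r in driver_rows}

        # neutral flux: Poisson counts per (tumor, site), recorded once
        site_tot = mu3.sum(axis=2)
        counts = rng.poisson(site_tot)
        present = counts > 0
        for si in driver_site_idx:
            present[:, si] = False  # driver sites follow the selection model

        hit_j, hit_i = np.nonzero(present)
        for j, i in zip(hit_j, hit_i):
            p = mu3[j, i] / site_tot[j, i]
            a = int(rng.choice(3, p=p))
            row = 3 * i + a
            rows.append(
                (
                    gene.gene_id,
                    gene.chrom,
                    int(table.gpos[row]),
                    str(table.ref_g[row]),
                    str(table.alt_g[row]),
                    samples[j],
                )
            )

        for row, d in sorted(driver_rows.items()):
            p_present = 1.0 - np.exp(-d.gamma * mu[:, row])
            carriers = np.nonzero(rng.random(n) < p_present)[0]
            for j in carriers:
                rows.append(
                    (
                        gene.gene_id,
                        gene.chrom,
                        int(table.gpos[row]),
                        str(table.ref_g[row]),
                        str(table.alt_g[row]),
                        samples[int(j)],
                    )
                )

    maf = pd.DataFrame(
        rows,
        columns=[
            DEFAULT_MAF_COLUMNS["gene"],
            DEFAULT_MAF_COLUMNS["chrom"],
            DEFAULT_MAF_COLUMNS["pos"],
            DEFAULT_MAF_COLUMNS["ref"],
            DEFAULT_MAF_COLUMNS["alt"],
            DEFAULT_MAF_COLUMNS["sample"],
        ],
    ).sort_values(
        [
            DEFAULT_MAF_COLUMNS["sample"],
            DEFAULT_MAF_COLUMNS["chrom"],
            DEFAULT_MAF_COLUMNS["pos"],
            DEFAULT_MAF_COLUMNS["alt"],
        ],
        kind="mergesort",
    ).reset_index(drop=True)

    truth = TruthTable(
        samples=samples,
        signature_names=catalog.names,
        weights=weights,
        profiles=profiles,
        gene_mu=gene_mu,
        drivers=tuple(
            d for ds in driver_by_gene.values() for d in ds
        ),
        driver_alts=driver_alts,
        site_tables=tables,
    )
    log.info(
        "simulated cohort: %d tumors, %d genes, %d SNVs (%d driver sites)",
        n,
        len(genes),
        len(maf),
        len(driver_alts),
    )
    return CohortData(
        reference=reference, genes=genes, site_tables=tables, maf=maf, truth=truth
    )


def spectrum_expectation(
    config: SimulationConfig, catalog: SignatureCatalog | None = None
) -> np.ndarray:
    """Expected per-sample 96-channel Poisson counts under the config.

    The expectation accounts for the realized reference's context
    availability: channel c's mean for tumor j sums, over genes, the gene
    rate times the fraction of the tumor's in-gene profile mass sitting on
    channel-c site-alternate pairs. Collapse of multiple hits at one site
    is ignored (per-site means are tiny at the simulated scale).
    """
    if catalog is None:
        catalog = synthetic_signature_catalog()
    rng = np.random.default_rng(config.seed)
    _, _, tables = _build_reference(config, rng)
    weights = _draw_weights(config, rng, catalog.n_signatures)
    profiles = weights @ catalog.matrix.T
    profiles = profiles / profiles.sum(axis=1, keepdims=True)
    gene_mu = config.resolved_gene_rates()

    expected = np.zeros((config.n_samples, N_CHANNELS))
    for gene_id, table in tables.items():
        ok = table.channel >= 0
        counts = np.bincount(table.channel[ok], minlength=N_CHANNELS).astype(float)
        z = profiles @ counts  # (n,) total profile mass on the gene
        expected += gene_mu[gene_id] * (profiles * counts) / z[:, None]
    return expected


def write_cohort(cohort: CohortData, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort's artifacts as plain-text files; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.tsv",
        "maf": outdir / "cohort.maf",
        "samples": outdir / "samples.tsv",
        "truth_gene_rates": outdir / "truth_gene_rates.tsv",
        "truth_weights": outdir / "truth_signature_weights.tsv",
        "truth_drivers": outdir / "truth_drivers.tsv",
    }
    write_fasta(cohort.reference, paths["reference"])
    write_gene_models(cohort.genes, paths["genes"])
    cohort.maf.to_csv(paths["maf"], sep="\t", index=False)
    pd.DataFrame({"sample_id": cohort.truth.samples}).to_csv(
        paths["samples"], sep="\t", index=False
    )
    pd.DataFrame(
        [(g, mu) for g, mu in cohort.truth.gene_mu.items()],
        columns=["gene_id", "mu_true"],
    ).to_csv(paths["truth_gene_rates"], sep="\t", index=False)
    wdf = pd.DataFrame(cohort.truth.weights, columns=list(cohort.truth.signature_names))
    wdf.insert(0, "sample_id", cohort.truth.samples)
    wdf.to_csv(paths["truth_weights"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "cds_site": d.cds_site,
                "alt": cohort.truth.driver_alts[(d.gene_id, d.cds_site)],
                "gamma_true": d.gamma,
            }
            for d in cohort.truth.drivers
        ],
        columns=["gene_id", "cds_site", "alt", "gamma_true"],
    ).to_csv(paths["truth_drivers"], sep="\t", index=False)
    return paths
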