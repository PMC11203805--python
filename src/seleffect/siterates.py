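"""Distributing a gene's neutral rate over its individual substitutions.

Selection is inferred per specific substitution (site and alternate
allele), so the gene-level neutral rate must be spread over all 3L
possible substitutions of an L-site coding sequence. For sample j with
context profile w_j, the rate assigned to site-alternate pair (i, a) is

    mu_ij = mu_gene * w_j(channel(i, a)) / sum over the gene of w_j

which conserves the gene total exactly: the per-sample site rates of a
gene always sum to ``mu_gene``. Context at exon boundaries uses the
genomic flanking bases, not spliced neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import ModelFitError, SiteTable
from .signatures import ContextRateProfile


@dataclass(frozen=True)
class SiteRate:
    """Expected mutations per tumor for one specific substitution in one
    sample."""

    gene_id: str
    site: int  # 1-based index within the coding sequence
    pos: int  # genomic position
    sample_id: str
    alt_allele: str  # forward genome strand
    mu_ij: float


def site_rate_vector(
    site_table: SiteTable, mu_gene: float, rates96: np.ndarray
) -> np.ndarray:
    """Per-(site, alternate) rates for one sample, aligned with the site
    table rows; rows without context (contig edge) get rate 0."""
    ok = site_table.channel >= 0
    w = np.zeros(len(site_table.channel))
    w[ok] = rates96[site_table.channel[ok]]
    total = w.sum()
    if total <= 0:
        raise ModelFitError(
            f"{site_table.gene_id}: context profile assigns zero rate to "
            "every channel present in the gene"
        )
    return mu_gene * w / total


def site_rate_matrix(
    site_table: SiteTable, mu_gene: float, profile_matrix: np.ndarray
) -> np.ndarray:
    """Rates for all samples at once: (n_samples, 3L) with rows aligned to
    ``profile_matrix`` and columns to the site table."""
    ok = site_table.channel >= 0
    w = np.zeros((profile_matrix.shape[0], len(site_table.channel)))
    w[:, ok] = profile_matrix[:, site_table.channel[ok]]
    totals = w.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise ModelFitError(
            f"{site_table.gene_id}: sample index {bad} has zero profile mass "
            "on the gene's channels"
        )
    return mu_gene * w / totals[:, None]


def site_rates(
    site_table: SiteTable,
    mu_gene: float,
    profile: ContextRateProfile,
) -> list[SiteRate]:
    """Materialized per-substitution rates for one (gene, sample) pair."""
    mu = site_rate_vector(site_table, mu_gene, profile.rates)
    return [
        SiteRate(
            gene_id=site_table.gene_id,
            site=int(site_table.site[r]),
            pos=int(site_table.gpos[r]),
            sample_id=profile.sample_id,
            alt_allele=str(site_table.alt_g[r]),
            mu_ij=float(mu[r]),
        )
        for r in range(len(mu))
    ]
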