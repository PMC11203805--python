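"""Per-sample signature attribution and context-rate profiles.

Each sample's 96-channel spectrum is decomposed as a non-negative mixture
of catalog signatures by non-negative least squares (NNLS) on raw counts —
the strict-fit objective. Signatures known to be inapplicable to the
cohort (e.g. treatment-associated processes) are removed from the catalog
*before* fitting, not zeroed afterwards. The fitted mixture, pushed back
through the catalog, gives the sample's normalized relative substitution
rates over the 96 channels; samples with too few mutations to support a
stable fit inherit the profile fitted to the pooled cohort spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.optimize

from .channels import N_CHANNELS
from .io import InputError, MutationalSpectrum, SignatureCatalog

log = logging.getLogger(__name__)

#: below this many annotatable SNVs a sample is pooled with the cohort
DEFAULT_MIN_MUTATIONS = 50


@dataclass
class SignatureWeights:
    """NNLS solution for one sample: non-negative weight per signature,
    in mutation-count units (weights need not sum to the spectrum total)."""

    sample_id: str
    signature_names: tuple[str, ...]
    weights: np.ndarray
    residual_norm: float

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signature_names, map(float, self.weights)))


@dataclass
class ContextRateProfile:
    """Normalized relative substitution rates over the 96 channels."""

    sample_id: str
    rates: np.ndarray
    pooled: bool = False

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (N_CHANNELS,):
            raise InputError("profile must have 96 channel rates")
        if (self.rates < 0).any():
            raise InputError("profile rates must be non-negative")
        total = self.rates.sum()
        if not np.isclose(total, 1.0, atol=1e-8):
            raise InputError(f"profile rates sum to {total}, expected 1")


def fit_signatures(
    spectrum: MutationalSpectrum, catalog: SignatureCatalog
) -> SignatureWeights:
    """Fit w ≥ 0 minimizing ‖counts − catalog·w‖₂ (non-negative least squares)."""
    if spectrum.total == 0:
        raise InputError(
            f"sample {spectrum.sample_id!r} has an all-zero spectrum; "
            "route it to cohort pooling"
        )
    weights, residual = scipy.optimize.nnls(
        catalog.matrix, spectrum.counts.astype(float)
    )
    return SignatureWeights(
        sample_id=spectrum.sample_id,
        signature_names=catalog.names,
        weights=weights,
        residual_norm=float(residual),
    )


def exclude_and_refit(
    spectrum: MutationalSpectrum,
    catalog: SignatureCatalog,
    exclusion_list: Iterable[str],
) -> SignatureWeights:
    """NNLS against the catalog with the excluded signatures removed."""
    return fit_signatures(spectrum, catalog.without(exclusion_list))


def context_profile(
    weights: SignatureWeights, catalog: SignatureCatalog
) -> ContextRateProfile:
    """Relative context rates implied by a signature mixture: catalog·w,
    normalized to sum to 1."""
    if tuple(weights.signature_names) != tuple(catalog.names):
        catalog = catalog.without(set(catalog.names) - set(weights.signature_names))
        if tuple(weights.signature_names) != tuple(catalog.names):
            raise InputError("weights and catalog name mismatch")
    raw = catalog.matrix @ weights.weights
    total = raw.sum()
    if total <= 0:
        raise InputError(
            f"sample {weights.sample_id!r} has zero total signature weight; "
            "route it to cohort pooling"
        )
    return ContextRateProfile(sample_id=weights.sample_id, rates=raw / total)


@dataclass
class AttributionResult:
    """Cohort-wide attribution: per-sample profiles and weights, plus the
    set of samples that received the pooled-cohort profile."""

    profiles: dict[str, ContextRateProfile]
    weights: dict[str, SignatureWeights]
    pooled_samples: frozenset[str]
    pooled_profile: ContextRateProfile | None


def pool_sparse_samples(
    spectra: Sequence[MutationalSpectrum],
    catalog: SignatureCatalog,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    exclusion_list: Iterable[str] = (),
) -> AttributionResult:
    """Fit every sample, giving low-mutation samples the pooled-cohort fit.

    Samples with fewer than ``min_mutations`` annotatable SNVs receive the
    profile fitted to the element-wise sum of all cohort spectra; the rest
    keep their own NNLS fit. If the whole cohort is below threshold, every
    sample gets the pooled profile.
    """
    retained = catalog.without(exclusion_list)
    pooled_counts = np.sum([s.counts for s in spectra], axis=0)
    needs_pool = [s.sample_id for s in spectra if s.total < min_mutations]

    pooled_weights = None
    pooled_profile = None
    if needs_pool:
        if pooled_counts.sum() == 0:
            raise InputError("cohort has no annotatable mutations to pool")
        pooled_spectrum = MutationalSpectrum(sample_id="<cohort>", counts=pooled_counts)
        pooled_weights = fit_signatures(pooled_spectrum, retained)
        pooled_profile = context_profile(pooled_weights, retained)
        log.info(
            "pooled %d of %d samples below %d mutations",
            len(needs_pool),
            len(spectra),
            min_mutations,
        )

    profiles: dict[str, ContextRateProfile] = {}
    weights: dict[str, SignatureWeights] = {}
    for spec in spectra:
        if spec.sample_id in set(needs_pool):
            weights[spec.sample_id] = SignatureWeights(
                sample_id=spec.sample_id,
                signature_names=pooled_weights.signature_names,
                weights=pooled_weights.weights.copy(),
                residual_norm=pooled_weights.residual_norm,
            )
            profiles[spec.sample_id] = ContextRateProfile(
                sample_id=spec.sample_id,
                rates=pooled_profile.rates.copy(),
                pooled=True,
            )
        else:
            w = fit_signatures(spec, retained)
            weights[spec.sample_id] = w
            profiles[spec.sample_id] = context_profile(w, retained)
    return AttributionResult(
        profiles=profiles,
        weights=weights,
        pooled_samples=frozenset(needs_pool),
        pooled_profile=pooled_profile,
    )
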