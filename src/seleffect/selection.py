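"""Maximum-likelihood estimation of scaled selection coefficients.

The cancer effect of a substitution is the scaled selection coefficient
gamma that rescales its neutral mutation rate into the rate at which the
substitution arises *and fixes* in a tumor lineage. Mutations arrive as a
Poisson flux, but a selected substitution is observed at most once per
site per tumor, so the observation for tumor j is Bernoulli:

    P(substitution present in tumor j) = 1 - exp(-gamma * mu_ij)

with mu_ij the tumor-specific neutral rate of that substitution. Tumors
are independent, giving the log-likelihood

    l(gamma) = sum_{j mutated} log(1 - exp(-gamma mu_ij))
             - gamma * sum_{j not mutated} mu_ij

which is unimodal in gamma. The MLE is found by bounded scalar
optimization on log-gamma; 95% confidence intervals are profile-likelihood
intervals, the points where l drops chi2(1, 0.95)/2 ~ 1.92 below its
maximum. gamma = 1 means the substitution fixes at the neutral rate;
large gamma means strong positive selection.

Gene-level effects share one gamma across all of the gene's substitutions
observed in the cohort (sites never seen mutated do not enter the
product), and are only reported for genes with more than four cohort
substitutions by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.optimize
from scipy.stats import chi2

log = logging.getLogger(__name__)

#: search bracket for gamma (log-scale bounded optimization)
GAMMA_LOWER = 1e-3
GAMMA_UPPER = 1e9

#: log-likelihood drop defining the 95% profile interval: chi2_1(0.95)/2
CI_DROP = float(chi2.ppf(0.95, df=1) / 2.0)

_LOG_XATOL = 1e-8

#: default gene inclusion threshold: more than four cohort substitutions
DEFAULT_MIN_SUBSTITUTIONS = 5


@dataclass
class SelectionEstimate:
    """A scaled selection coefficient with its 95% profile-likelihood CI.

    ``n_substitutions`` counts tumor-level substitution events across the
    cohort; ``prevalence`` is the fraction of cohort tumors carrying at
    least one qualifying substitution. ``boundary_flag`` records MLEs
    pinned at the search bracket ('lower' for gamma = 0 when nothing is
    mutated, 'upper' when every tumor is mutated and gamma is unbounded).
    """

    scope: str  # "variant" or "gene"
    identifier: str
    gamma_hat: float
    ci95_low: float
    ci95_high: float
    n_substitutions: int
    prevalence: float
    loglik_at_mle: float
    boundary_flag: str = "none"


def variant_loglik(
    gamma: float, rates: np.ndarray, mutated: np.ndarray
) -> float:
    """Log-likelihood of per-tumor presence/absence at one substitution.

    At gamma = 0 with any tumor mutated the observation is impossible and
    -inf is returned.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    rates = np.asarray(rates, dtype=float)
    mutated = np.asarray(mutated, dtype=bool)
    if rates.shape != mutated.shape:
        raise ValueError("rates and mutation indicators must align")
    if np.any(rates <= 0):
        raise ValueError("all per-sample rates must be positive")
    lam = gamma * rates
    if gamma == 0.0:
        return -math.inf if mutated.any() else 0.0
    with np.errstate(divide="ignore"):
        # log(1 - exp(-lam)) computed stably as log(-expm1(-lam))
        present = np.log(-np.expm1(-lam[mutated]))
    return float(present.sum() - lam[~mutated].sum())


def _pooled_loglik(
    rate_blocks: Sequence[np.ndarray], mutated_blocks: Sequence[np.ndarray]
) -> tuple[Callable[[float], float], np.ndarray, np.ndarray]:
    rates = np.concatenate([np.asarray(r, dtype=float) for r in rate_blocks])
    mutated = np.concatenate([np.asarray(m, dtype=bool) for m in mutated_blocks])
    return (lambda g: variant_loglik(g, rates, mutated)), rates, mutated


def _maximize(loglik: Callable[[float], float]) -> tuple[float, float, str]:
    """Bounded 1-D maximization on log-gamma over [GAMMA_LOWER, GAMMA_UPPER]."""
    lo, hi = math.log(GAMMA_LOWER), math.log(GAMMA_UPPER)
    res = scipy.optimize.minimize_scalar(
        lambda t: -loglik(math.exp(t)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": _LOG_XATOL},
    )
    t_hat = float(res.x)
    flag = "none"
    if t_hat - lo < 1e-6:
        flag = "lower"
    elif hi - t_hat < 1e-6:
        flag = "upper"
    gamma_hat = math.exp(t_hat)
    return gamma_hat, float(-res.fun), flag


def profile_ci(
    loglik: Callable[[float], float],
    gamma_hat: float,
    loglik_at_mle: float | None = None,
) -> tuple[float, float]:
    """95% profile-likelihood interval around an interior MLE.

    Root-finding is on log-gamma; a side whose root lies outside the
    search range returns the range bound for that side.
    """
    if loglik_at_mle is None:
        loglik_at_mle = loglik(gamma_hat)
    target = loglik_at_mle - CI_DROP

    def deficit(t: float) -> float:
        return loglik(math.exp(t)) - target

    t_hat = math.log(gamma_hat)

    # lower side: expand downward until the likelihood falls below target
    t_lo = t_hat
    low_floor = math.log(1e-15)
    step = 1.0
    while deficit(t_lo) > 0:
        t_lo -= step
        step *= 2
        if t_lo < low_floor:
            t_lo = low_floor
            break
    if deficit(t_lo) > 0:
        low = 0.0
    else:
        low = math.exp(scipy.optimize.brentq(deficit, t_lo, t_hat, xtol=1e-10))

    t_hi = t_hat
    hi_ceil = math.log(GAMMA_UPPER)
    step = 1.0
    while deficit(t_hi) > 0:
        t_hi += step
        step *= 2
        if t_hi > hi_ceil:
            t_hi = hi_ceil
            break
    if deficit(t_hi) > 0:
        high = GAMMA_UPPER
    else:
        high = math.exp(scipy.optimize.brentq(deficit, t_hat, t_hi, xtol=1e-10))
    return low, high


def _estimate(
    rate_blocks: Sequence[np.ndarray],
    mutated_blocks: Sequence[np.ndarray],
    scope: str,
    identifier: str,
    n_samples: int,
    n_carriers: int,
) -> SelectionEstimate:
    loglik, rates, mutated = _pooled_loglik(rate_blocks, mutated_blocks)
    k = int(mutated.sum())
    n = len(mutated)
    prevalence = n_carriers / n_samples if n_samples else 0.0

    if k == 0:
        # likelihood -gamma * sum(mu) is maximized at the gamma = 0 boundary
        total = float(rates.sum())
        return SelectionEstimate(
            scope=scope,
            identifier=identifier,
            gamma_hat=0.0,
            ci95_low=0.0,
            ci95_high=min(CI_DROP / total, GAMMA_UPPER),
            n_substitutions=0,
            prevalence=prevalence,
            loglik_at_mle=0.0,
            boundary_flag="lower",
        )
    if k == n:
        # likelihood increases without bound; report the bracket top
        ll_top = loglik(GAMMA_UPPER)
        low, _ = profile_ci(loglik, GAMMA_UPPER, ll_top)
        return SelectionEstimate(
            scope=scope,
            identifier=identifier,
            gamma_hat=GAMMA_UPPER,
            ci95_low=low,
            ci95_high=GAMMA_UPPER,
            n_substitutions=k,
            prevalence=prevalence,
            loglik_at_mle=ll_top,
            boundary_flag="upper",
        )

    gamma_hat, ll_max, flag = _maximize(loglik)
    low, high = profile_ci(loglik, gamma_hat, ll_max)
    return SelectionEstimate(
        scope=scope,
        identifier=identifier,
        gamma_hat=gamma_hat,
        ci95_low=low,
        ci95_high=high,
        n_substitutions=k,
        prevalence=prevalence,
        loglik_at_mle=ll_max,
        boundary_flag=flag,
    )


def estimate_variant_effect(
    rates: np.ndarray,
    mutated: np.ndarray,
    identifier: str = "",
    n_samples: int | None = None,
) -> SelectionEstimate:
    """MLE of gamma for one substitution from per-tumor rates and
    presence/absence indicators across the cohort."""
    mutated = np.asarray(mutated, dtype=bool)
    n = n_samples if n_samples is not None else len(mutated)
    return _estimate(
        [rates], [mutated], "variant", identifier, n, int(mutated.sum())
    )


def estimate_gene_effect(
    rate_blocks: Sequence[np.ndarray],
    mutated_blocks: Sequence[np.ndarray],
    identifier: str,
    n_samples: int,
    min_substitutions: int = DEFAULT_MIN_SUBSTITUTIONS,
) -> SelectionEstimate | None:
    """Shared gamma across a gene's cohort-observed substitutions.

    Each block is one observed substitution's per-tumor (rates,
    indicators). Genes whose total substitution events across the cohort
    fall below ``min_substitutions`` are skipped (None) with a logged
    reason.
    """
    total_events = int(sum(np.asarray(m, dtype=bool).sum() for m in mutated_blocks))
    if total_events < min_substitutions:
        log.info(
            "%s: %d substitutions < required %d; gene-level effect skipped",
            identifier,
            total_events,
            min_substitutions,
        )
        return None
    carriers = np.zeros(n_samples, dtype=bool)
    for m in mutated_blocks:
        carriers |= np.asarray(m, dtype=bool)
    return _estimate(
        rate_blocks,
        mutated_blocks,
        "gene",
        identifier,
        n_samples,
        int(carriers.sum()),
    )
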