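"""Maximum-likelihood scaled selection coefficients and profile CIs."""

import math

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st

from seleffect.selection import (
    CI_DROP,
    GAMMA_UPPER,
    estimate_gene_effect,
    estimate_variant_effect,
    profile_ci,
    variant_loglik,
)


def direct_bernoulli_loglik(gamma, rates, mutated):
    """Independent oracle: product of per-tumor Bernoulli terms, written
    without shared code with the implementation."""
    total = 0.0
    for mu, m in zip(rates, mutated):
        p = 1.0 - math.exp(-gamma * mu)
        total += math.log(p) if m else math.log(1.0 - p)
    return total


def grid_mle(rates, mutated, n_points=401, rounds=3):
    """Exhaustive log-grid search with local refinement."""
    lo, hi = math.log(1e-3), math.log(1e9)
    for _ in range(rounds):
        ts = np.linspace(lo, hi, n_points)
        lls = [variant_loglik(math.exp(t), rates, mutated) for t in ts]
        i = int(np.argmax(lls))
        lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, n_points - 1)]
    return math.exp(ts[i])


class TestVariantLoglik:
    def test_gamma_zero_with_mutation_impossible(self):
        rates = np.full(10, 1e-5)
        mutated = np.zeros(10, dtype=bool)
        mutated[0] = True
        assert variant_loglik(0.0, rates, mutated) == -math.inf

    def test_no_mutations_linear_decay(self):
        rates = np.array([1e-5, 2e-5, 3e-5])
        mutated = np.zeros(3, dtype=bool)
        for gamma in [0.0, 10.0, 1e4]:
            assert variant_loglik(gamma, rates, mutated) == pytest.approx(
                -gamma * rates.sum()
            )

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            variant_loglik(-1.0, np.array([1e-5]), np.array([True]))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_bernoulli_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        rates = rng.uniform(1e-6, 1e-4, size=n)
        mutated = rng.random(n) < 0.3
        gamma = float(rng.uniform(1.0, 1e5))
        got = variant_loglik(gamma, rates, mutated)
        want = direct_bernoulli_loglik(gamma, rates, mutated)
        assert got == pytest.approx(want, abs=1e-10, rel=1e-10)


class TestVariantMLE:
    @pytest.mark.parametrize(
        "n,k,mu",
        [(100, 10, 1e-5), (100, 1, 1e-5), (1000, 50, 2e-6), (50, 25, 1e-4)],
    )
    def test_homogeneous_closed_form(self, n, k, mu):
        """With uniform rates, gamma_hat = -ln(1 - k/n) / mu exactly."""
        rates = np.full(n, mu)
        mutated = np.zeros(n, dtype=bool)
        mutated[:k] = True
        est = estimate_variant_effect(rates, mutated)
        expect = -math.log(1.0 - k / n) / mu
        assert est.gamma_hat == pytest.approx(expect, rel=1e-6)
        assert est.boundary_flag == "none"
        assert est.prevalence == k / n

    def test_no_mutations_boundary_zero(self):
        rates = np.full(20, 1e-5)
        est = estimate_variant_effect(rates, np.zeros(20, dtype=bool))
        assert est.gamma_hat == 0.0
        assert est.boundary_flag == "lower"
        assert est.ci95_low == 0.0
        # CI top is where the likelihood has dropped by the chi-square cut
        assert est.ci95_high == pytest.approx(CI_DROP / rates.sum())

    def test_all_mutated_upper_boundary(self):
        rates = np.full(5, 1e-5)
        est = estimate_variant_effect(rates, np.ones(5, dtype=bool))
        assert est.boundary_flag == "upper"
        assert est.gamma_hat == GAMMA_UPPER
        assert est.ci95_high == GAMMA_UPPER
        assert est.ci95_low < GAMMA_UPPER

    def test_monotone_in_prevalence(self):
        rates = np.full(100, 1e-5)
        prev = -1.0
        for k in range(1, 100, 7):
            mutated = np.zeros(100, dtype=bool)
            mutated[:k] = True
            g = estimate_variant_effect(rates, mutated).gamma_hat
            assert g > prev
            prev = g

    def test_monotone_decreasing_in_rate_scale(self):
        mutated = np.zeros(60, dtype=bool)
        mutated[:9] = True
        gammas = []
        for scale in [0.5, 1.0, 2.0, 4.0]:
            rates = np.full(60, scale * 1e-5)
            gammas.append(estimate_variant_effect(rates, mutated).gamma_hat)
        assert all(a > b for a, b in zip(gammas, gammas[1:]))

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_log_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        rates = rng.uniform(1e-6, 2e-4, size=n)
        k = int(rng.integers(1, n))
        mutated = np.zeros(n, dtype=bool)
        mutated[rng.choice(n, size=k, replace=False)] = True
        est = estimate_variant_effect(rates, mutated)
        oracle = grid_mle(rates, mutated)
        assert est.gamma_hat == pytest.approx(oracle, rel=5e-3)


class TestGeneMLE:
    def test_four_substitutions_skipped_five_kept(self):
        n = 100
        rates = np.full(n, 2e-5)
        m4 = np.zeros(n, dtype=bool)
        m4[:4] = True
        assert (
            estimate_gene_effect([rates], [m4], identifier="G", n_samples=n) is None
        )
        m5 = np.zeros(n, dtype=bool)
        m5[:5] = True
        est = estimate_gene_effect([rates], [m5], identifier="G", n_samples=n)
        assert est is not None
        assert est.n_substitutions == 5

    def test_symmetric_sites_equal_single_site(self):
        """Identical rates and counts at two sites give the same shared
        gamma as either site alone."""
        n = 200
        rates = np.full(n, 1e-5)
        m = np.zeros(n, dtype=bool)
        m[:6] = True
        single = estimate_variant_effect(rates, m)
        shared = estimate_gene_effect(
            [rates, rates], [m.copy(), m.copy()], identifier="G", n_samples=n
        )
        assert shared.gamma_hat == pytest.approx(single.gamma_hat, rel=1e-6)

    def test_two_site_grid_oracle(self):
        rng = np.random.default_rng(17)
        n = 80
        r1 = rng.uniform(1e-6, 5e-5, size=n)
        r2 = rng.uniform(1e-6, 5e-5, size=n)
        m1 = np.zeros(n, dtype=bool)
        m1[rng.choice(n, 5, replace=False)] = True
        m2 = np.zeros(n, dtype=bool)
        m2[rng.choice(n, 3, replace=False)] = True
        est = estimate_gene_effect([r1, r2], [m1, m2], identifier="G", n_samples=n)
        oracle = grid_mle(np.concatenate([r1, r2]), np.concatenate([m1, m2]))
        assert est.gamma_hat == pytest.approx(oracle, rel=5e-3)

    def test_prevalence_counts_carriers_not_events(self):
        n = 50
        rates = np.full(n, 1e-5)
        m1 = np.zeros(n, dtype=bool)
        m1[:4] = True
        m2 = np.zeros(n, dtype=bool)
        m2[2:6] = True  # overlaps two carriers of site 1
        est = estimate_gene_effect([rates, rates], [m1, m2], identifier="G", n_samples=n)
        assert est.n_substitutions == 8
        assert est.prevalence == pytest.approx(6 / 50)


class TestProfileCI:
    def binomial_profile_ci(self, n, k):
        """Independent oracle: 95% profile-likelihood CI for the binomial
        presence probability p, found by direct root finding."""

        def ll(p):
            return k * math.log(p) + (n - k) * math.log(1 - p)

        p_hat = k / n
        target = ll(p_hat) - CI_DROP
        lo = scipy.optimize.brentq(lambda p: ll(p) - target, 1e-12, p_hat)
        hi = scipy.optimize.brentq(lambda p: ll(p) - target, p_hat, 1 - 1e-12)
        return lo, hi

    @pytest.mark.parametrize("n,k,mu", [(100, 10, 1e-5), (400, 8, 5e-6)])
    def test_homogeneous_ci_transforms_binomial_ci(self, n, k, mu):
        """With uniform rates the model is a reparameterized binomial, so
        the gamma CI is the transform of the binomial profile CI."""
        rates = np.full(n, mu)
        mutated = np.zeros(n, dtype=bool)
        mutated[:k] = True
        est = estimate_variant_effect(rates, mutated)
        p_lo, p_hi = self.binomial_profile_ci(n, k)
        assert est.ci95_low == pytest.approx(-math.log(1 - p_lo) / mu, rel=1e-5)
        assert est.ci95_high == pytest.approx(-math.log(1 - p_hi) / mu, rel=1e-5)

    def test_ci_contains_mle_and_narrows_with_n(self):
        widths = {}
        for n in (100, 1000):
            k = n // 10
            rates = np.full(n, 1e-5)
            mutated = np.zeros(n, dtype=bool)
            mutated[:k] = True
            est = estimate_variant_effect(rates, mutated)
            assert est.ci95_low <= est.gamma_hat <= est.ci95_high
            widths[n] = math.log(est.ci95_high / est.ci95_low)
        assert widths[1000] < widths[100]


class TestRecovery:
    def test_effect_ordering_of_two_drivers(self):
        """Two drivers whose true coefficients differ tenfold are ranked
        correctly in at least 95 of 100 simulated cohorts."""
        rng = np.random.default_rng(2024)
        n = 500
        correct = 0
        for _ in range(100):
            mu1 = rng.uniform(1e-5, 3e-5, size=n)
            mu2 = rng.uniform(1e-5, 3e-5, size=n)
            g1, g2 = 800.0, 8000.0
            m1 = rng.random(n) < 1 - np.exp(-g1 * mu1)
            m2 = rng.random(n) < 1 - np.exp(-g2 * mu2)
            e1 = estimate_variant_effect(mu1, m1).gamma_hat
            e2 = estimate_variant_effect(mu2, m2).gamma_hat
            correct += e2 > e1
        assert correct >= 95
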