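"""Estimation tests: published-value reproduction, closed-form and
grid-search oracle agreement, invariance properties, and the comparison
estimator variants."""

import math

import numpy as np
import pytest

from tetralink.inference import (
    PhenotypeCounts,
    fit_population,
    likelihood_ratio,
    log_likelihood,
    mle_alpha_marginal,
    mle_disomic,
    mle_r_tetrasomic,
    moment_estimate,
    observed_information_se,
)
from tetralink.models import (
    disomic_phenotype_probs,
    green_marginal_probs,
    tetrasomic_phenotype_probs,
)
from tetralink.simulate import SimulationConfig, simulate_counts
from tetralink.models import DisomicParams, TetrasomicParams

from conftest import grid_search_mle


class TestLogLikelihood:
    def test_diploid_at_mle_matches_published(self, diploid_counts):
        ll = log_likelihood(diploid_counts, disomic_phenotype_probs(0.1643))
        assert ll == pytest.approx(-4177.79, abs=0.005)

    def test_single_certain_class_is_zero(self):
        assert log_likelihood(PhenotypeCounts(1, 0, 0, 0), (1.0, 0.0, 0.0, 0.0)) == 0.0

    def test_autotetraploid_comparison_point(self, autotetraploid_counts):
        ll = log_likelihood(autotetraploid_counts, tetrasomic_phenotype_probs(0.0, 0.205))
        assert ll == pytest.approx(-21010.0, abs=0.05)

    def test_impossible_class_gives_neg_inf(self):
        counts = PhenotypeCounts(10, 5, 0, 0)
        assert log_likelihood(counts, (0.5, 0.0, 0.25, 0.25)) == -math.inf

    def test_zero_count_class_ignores_zero_probability(self):
        counts = PhenotypeCounts(10, 0, 0, 0)
        assert math.isfinite(log_likelihood(counts, (1.0, 0.0, 0.0, 0.0)))


class TestDisomicMLE:
    def test_diploid_published_values(self, diploid_counts):
        est = mle_disomic(diploid_counts)
        assert est.value == pytest.approx(0.1643, abs=5e-5)
        assert est.se == pytest.approx(0.0062, abs=5e-5)
        assert est.loglik == pytest.approx(-4177.79, abs=0.005)
        assert est.n_roots_in_domain == 1  # uniqueness of the interior root
        assert not est.at_boundary

    def test_allotetraploid_published_values(self, allotetraploid_counts):
        est = mle_disomic(allotetraploid_counts)
        assert est.value == pytest.approx(0.2770, abs=5e-5)
        assert est.se == pytest.approx(0.0110, abs=5e-5)
        assert est.loglik == pytest.approx(-2553.43, abs=0.005)

    def test_no_recombinants_hits_lower_boundary(self):
        est = mle_disomic(PhenotypeCounts(750, 0, 0, 250))
        assert est.value == 0.0
        assert est.at_boundary
        assert est.se is None

    def test_count_scaling_invariance(self, diploid_counts):
        base = mle_disomic(diploid_counts)
        scaled = mle_disomic(diploid_counts.scaled(4))
        assert scaled.value == pytest.approx(base.value, abs=1e-10)
        assert scaled.loglik == pytest.approx(4 * base.loglik, rel=1e-10)
        assert scaled.se == pytest.approx(base.se / 2.0, rel=1e-5)

    def test_score_vanishes_at_interior_mle(self, diploid_counts, allotetraploid_counts):
        for counts in (diploid_counts, allotetraploid_counts):
            est = mle_disomic(counts)
            h = 1e-6
            ll = lambda r: log_likelihood(counts, disomic_phenotype_probs(r))
            deriv = (ll(est.value + h) - ll(est.value - h)) / (2 * h)
            assert abs(deriv) <= 1e-6 * counts.n


class TestAlphaMarginal:
    def test_published_values(self, autotetraploid_counts):
        est = mle_alpha_marginal(autotetraploid_counts)
        assert autotetraploid_counts.ng == 14575 and autotetraploid_counts.n0 == 5314
        assert est.value == pytest.approx(0.0676, abs=5e-5)
        assert est.se == pytest.approx(0.0121, abs=5e-5)

    def test_exact_three_quarters_margin_gives_zero(self):
        est = mle_alpha_marginal(PhenotypeCounts(6000, 1500, 1500, 1000))  # ng/n = 0.75
        assert est.value == 0.0
        assert est.at_boundary

    def test_closed_form_inversion(self):
        # p0(a) = 0.3  =>  a = 4 sqrt(0.3) - 2
        est = mle_alpha_marginal(PhenotypeCounts(5000, 2000, 2000, 1000))
        assert est.value == pytest.approx(4 * math.sqrt(0.3) - 2, abs=1e-12)

    def test_moment_self_consistency(self, autotetraploid_counts):
        est = mle_alpha_marginal(autotetraploid_counts)
        _, p0 = green_marginal_probs(est.value)
        assert p0 == pytest.approx(autotetraploid_counts.n0 / autotetraploid_counts.n, abs=1e-10)

    def test_marginal_mle_matches_grid_oracle(self, autotetraploid_counts):
        grid = np.linspace(0.0, 0.25, 250001)
        ng, n0 = autotetraploid_counts.ng, autotetraploid_counts.n0
        ll = ng * np.log((12 - 4 * grid - grid**2) / 16) + n0 * np.log((2 + grid) ** 2 / 16)
        est = mle_alpha_marginal(autotetraploid_counts)
        assert est.value == pytest.approx(grid[np.argmax(ll)], abs=2e-6)


class TestTetrasomicRMLE:
    def test_published_values(self, autotetraploid_counts):
        alpha = mle_alpha_marginal(autotetraploid_counts).value
        est = mle_r_tetrasomic(autotetraploid_counts, alpha)
        assert est.value == pytest.approx(0.3048, abs=5e-5)
        assert est.se == pytest.approx(0.0051, abs=5e-5)
        assert est.loglik == pytest.approx(-20815.3, abs=0.05)
        assert est.n_roots_in_domain == 1  # the score has a single root

    def test_boundary_with_no_recombinant_classes(self):
        est = mle_r_tetrasomic(PhenotypeCounts(3000, 0, 0, 1000), 0.0)
        assert est.value == 0.0
        assert est.at_boundary

    def test_consistency_at_large_n(self):
        config = SimulationConfig(
            model="tetrasomic",
            params=TetrasomicParams(alpha=0.05, r=0.10),
            n=1_000_000,
            replicates=1,
            seed=2012,
        )
        counts = simulate_counts(config)[0]
        est = mle_r_tetrasomic(counts, 0.05)
        assert est.value == pytest.approx(0.10, abs=0.005)


class TestFitPopulation:
    def test_tetrasomic_two_step(self, autotetraploid_counts):
        fit = fit_population(autotetraploid_counts, "tetrasomic")
        assert fit.alpha.value == pytest.approx(0.0676, abs=5e-5)
        assert fit.r.value == pytest.approx(0.3048, abs=5e-5)
        assert fit.beta.beta == pytest.approx(0.1857, abs=5e-5)
        assert fit.r.loglik == pytest.approx(-20815.3, abs=0.05)
        assert fit.moment_r == pytest.approx(0.205, abs=5e-4)

    def test_disomic_has_no_alpha_or_beta(self, diploid_counts):
        fit = fit_population(diploid_counts, "disomic")
        assert fit.alpha is None and fit.beta is None
        assert fit.r.value == pytest.approx(0.1643, abs=5e-5)

    def test_unknown_model_rejected(self, diploid_counts):
        with pytest.raises(ValueError):
            fit_population(diploid_counts, "hexasomic")


class TestLikelihoodRatio:
    def test_mle_versus_proportion_estimate(self, diploid_counts):
        r_hat = mle_disomic(diploid_counts).value
        lr = likelihood_ratio(diploid_counts, "disomic", r_hat, 0.154)
        assert lr.ratio == pytest.approx(4.1103, abs=1e-3)
        assert lr.log_ratio == pytest.approx(math.log(lr.ratio), abs=1e-12)

    def test_identity_and_antisymmetry(self, diploid_counts):
        same = likelihood_ratio(diploid_counts, "disomic", 0.2, 0.2)
        assert same.ratio == 1.0
        fwd = likelihood_ratio(diploid_counts, "disomic", 0.1643, 0.154)
        rev = likelihood_ratio(diploid_counts, "disomic", 0.154, 0.1643)
        assert fwd.ratio * rev.ratio == pytest.approx(1.0, rel=1e-12)


class TestMomentEstimate:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            ((2805, 322, 333, 791), 655 / 4251),
            ((1484, 275, 298, 320), 573 / 2377),
            ((12707, 1868, 2216, 3098), 4084 / 19889),
        ],
    )
    def test_proportion_variant_reproduces_original_report(self, counts, expected):
        assert moment_estimate(PhenotypeCounts(*counts)) == pytest.approx(expected)

    def test_printed_equation_variant_differs(self, diploid_counts):
        r = moment_estimate(diploid_counts, "printed_equation")
        assert r == pytest.approx(1 - math.sqrt(1 - 2 * 655 / 4251), abs=1e-12)
        assert abs(r - 0.154) > 0.01  # the literal equation does not give 0.154

    def test_no_recombinant_classes(self):
        counts = PhenotypeCounts(30, 0, 0, 10)
        assert moment_estimate(counts, "proportion") == 0.0
        assert moment_estimate(counts, "printed_equation") == 0.0


class TestObservedInformation:
    def test_gaussian_curvature_identity(self):
        ll = lambda t: -((t - 0.3) ** 2) / (2 * 0.01**2)
        assert observed_information_se(ll, 0.3) == pytest.approx(0.01, rel=1e-6)

    def test_rejects_non_maximum(self):
        with pytest.raises(ValueError):
            observed_information_se(lambda t: (t - 0.3) ** 2, 0.3)


@pytest.mark.parametrize("model", ["disomic", "tetrasomic"])
def test_mle_agrees_with_grid_oracle_on_random_counts(model):
    """Score-equation estimates match an exhaustive grid search of the
    log-likelihood on random count vectors (light version; the full
    50-vector sweep runs with the acceptance checks)."""
    rng = np.random.default_rng(1234 if model == "disomic" else 4321)
    for _ in range(8):
        n = int(rng.integers(100, 1_000_000))
        if model == "disomic":
            r_true = rng.uniform(0.02, 0.48)
            f = np.asarray(disomic_phenotype_probs(r_true))
            counts = PhenotypeCounts(*map(int, rng.multinomial(n, f)))
            est = mle_disomic(counts).value
            oracle = grid_search_mle(counts, "disomic", step=1e-4)
        else:
            a_true = rng.uniform(0.0, 0.25)
            r_true = rng.uniform(0.02, 0.7)
            f = np.asarray(tetrasomic_phenotype_probs(a_true, r_true))
            counts = PhenotypeCounts(*map(int, rng.multinomial(n, f)))
            alpha_hat = mle_alpha_marginal(counts).value
            est = mle_r_tetrasomic(counts, alpha_hat).value
            oracle = grid_search_mle(counts, "tetrasomic", alpha=alpha_hat, step=1e-4)
        assert est == pytest.approx(oracle, abs=1e-4)
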