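"""Competition, redundancy and allocation metrics: closed forms, identities,
and posterior propagation."""

import math

import numpy as np
import pytest

import ttdcomp as tc
from ttdcomp.inference import PosteriorSamples
from ttdcomp.metrics import AnalysisWindow, MetricSummary

from test_distributions import FAMILY_PARAMS, random_params


def expo(rate):
    return tc.TimeDistribution("exponential", rate)


def cii_exponential_closed_form(psiB, lamA, lamB, v):
    """Independent closed form: psi_B [1 - e^{-lamA v}
    - lamA/(lamA+lamB) (1 - e^{-(lamA+lamB) v})]."""
    if math.isinf(v):
        return psiB * lamB / (lamA + lamB)
    s = lamA + lamB
    return psiB * (1.0 - math.exp(-lamA * v)
                   - lamA / s * (1.0 - math.exp(-s * v)))


def ones(u):
    return np.ones_like(np.asarray(u, dtype=float))


class TestCompetitionIntensity:
    def test_zero_rival_occupancy(self):
        assert tc.competition_intensity(0.0, expo(0.4), expo(0.2)) == 0.0

    def test_symmetric_rivals_split_evenly(self):
        # identical rates: the rival arrives first with probability 1/2
        val = tc.competition_intensity(0.8, expo(0.3), expo(0.3))
        assert val == pytest.approx(0.4, abs=1e-10)

    @pytest.mark.parametrize("v", [3.0, 14.0, np.inf])
    def test_exponential_closed_form(self, v):
        psiB, lamA, lamB = 0.28, 0.39, 0.21
        val = tc.competition_intensity(psiB, expo(lamA), expo(lamB),
                                       AnalysisWindow(v))
        assert val == pytest.approx(
            cii_exponential_closed_form(psiB, lamA, lamB, v), abs=1e-8
        )

    def test_published_scavenger_plugin_value(self):
        # rate-0.39 searcher vs rate-0.21 rival at 0.28 occupancy: the rival
        # preempts psi_B lam_B/(lam_A+lam_B) = 0.098 of the resource
        val = tc.competition_intensity(0.28, expo(0.39), expo(0.21))
        assert val == pytest.approx(0.098, abs=1e-10)

    def test_nondecreasing_in_window(self):
        distA = tc.TimeDistribution("lognormal", 2.16, 0.64)
        distB = tc.TimeDistribution("lognormal", 2.48, 0.72)
        vals = [tc.competition_intensity(0.48, distA, distB, AnalysisWindow(v))
                for v in [2.0, 5.0, 10.0, 30.0, 120.0, np.inf]]
        assert np.all(np.diff(vals) >= 0)

    def test_infinite_window_matches_truncated(self):
        # the 1-1e-10 quantile truncation plus tail bound must agree with
        # the untruncated exponential closed form
        val = tc.competition_intensity(0.9, expo(0.05), expo(1.5))
        assert val == pytest.approx(0.9 * 1.5 / 1.55, abs=1e-8)

    def test_range_bound(self):
        rng = np.random.default_rng(5)
        for family in FAMILY_PARAMS:
            dA = tc.TimeDistribution(family, *random_params(family, rng))
            dB = tc.TimeDistribution(family, *random_params(family, rng))
            psiB = rng.uniform(0, 1)
            val = tc.competition_intensity(psiB, dA, dB,
                                           AnalysisWindow(rng.uniform(1, 50)))
            assert 0.0 <= val <= psiB + 1e-12


class TestFunctionalContributions:
    def test_pfc_infinite_window_is_occupancy(self):
        assert tc.potential_functional_contribution(0.52, expo(0.39)) == 0.52

    def test_pfc_nest_window(self):
        val = tc.potential_functional_contribution(0.52, expo(0.39), 14.0)
        assert val == pytest.approx(0.52 * (1 - math.exp(-5.46)), rel=1e-12)
        assert val == pytest.approx(0.517788, abs=5e-7)

    def test_pfc_nondecreasing_in_window(self):
        dist = tc.TimeDistribution("gamma", 1.8, 0.35)
        vals = [tc.potential_functional_contribution(0.7, dist, v)
                for v in np.linspace(0.5, 60, 40)]
        assert np.all(np.diff(vals) >= 0)

    def test_ufc_no_rival_equals_pfc(self):
        ufc = tc.unique_functional_contribution(0.52, expo(0.39), 0.0, expo(0.21))
        assert ufc == tc.potential_functional_contribution(0.52, expo(0.39))

    def test_ufc_infinite_window(self):
        ufc = tc.unique_functional_contribution(0.74, expo(1.0), 0.48, expo(1.0))
        assert ufc == pytest.approx(0.74 * (1 - 0.48), rel=1e-12)

    def test_ufc_plus_redundancy_is_pfc(self):
        rng = np.random.default_rng(9)
        for family in FAMILY_PARAMS:
            dA = tc.TimeDistribution(family, *random_params(family, rng))
            dB = tc.TimeDistribution(family, *random_params(family, rng))
            psiA, psiB = rng.uniform(0, 1, 2)
            w = AnalysisWindow(rng.uniform(1, 40))
            ufc = tc.unique_functional_contribution(psiA, dA, psiB, dB, w)
            red = tc.functional_redundancy(psiA, dA, psiB, dB, w)
            pfc = tc.potential_functional_contribution(psiA, dA, w)
            assert ufc + red == pytest.approx(pfc, rel=1e-12)


class TestResourceAllocation:
    def test_worthless_resource(self):
        val = tc.resource_allocation(
            0.6, 0.4, expo(0.4), expo(0.2),
            lambda u: np.zeros_like(np.asarray(u, dtype=float)), 20.0,
        )
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_sole_consumer_of_undecayed_resource(self):
        val = tc.resource_allocation(0.6, 0.0, expo(0.4), expo(0.2), ones)
        assert val == pytest.approx(0.6, abs=1e-8)

    @pytest.mark.parametrize("family", FAMILY_PARAMS)
    def test_undecayed_identity_links_cii_and_pfc(self, family):
        """allocation(g=1) + psi_A * CII_A = PFC_A, for random parameters."""
        rng = np.random.default_rng(17)
        for _ in range(3):
            dA = tc.TimeDistribution(family, *random_params(family, rng))
            dB = tc.TimeDistribution(family, *random_params(family, rng))
            psiA, psiB = rng.uniform(0.05, 1.0, 2)
            for w in (AnalysisWindow(rng.uniform(2, 30)), AnalysisWindow()):
                alloc = tc.resource_allocation(psiA, psiB, dA, dB, ones, w)
                cii = tc.competition_intensity(psiB, dA, dB, w)
                pfc = tc.potential_functional_contribution(psiA, dA, w)
                assert alloc + psiA * cii == pytest.approx(pfc, abs=1e-8)

    def test_decaying_resource_worth_less_than_undecayed(self, decay_truth):
        undecayed = tc.resource_allocation(0.74, 0.48, expo(0.2), expo(0.3), ones)
        decayed = tc.resource_allocation(0.74, 0.48, expo(0.2), expo(0.3),
                                         decay_truth)
        assert decay_truth.gamma_asymptote * undecayed < decayed < undecayed

    def test_wayward_decay_function_warned(self):
        with pytest.warns(UserWarning, match="decay"):
            tc.resource_allocation(0.5, 0.5, expo(0.4), expo(0.2),
                                   lambda u: 2.0 * ones(u), 10.0)


class TestWindow:
    def test_invalid_window(self):
        with pytest.raises(ValueError):
            AnalysisWindow(0.0)
        with pytest.raises(ValueError):
            AnalysisWindow(-3.0)

    def test_infinite_is_default_and_flagged(self):
        assert not AnalysisWindow().finite
        assert AnalysisWindow(14.0).finite

    def test_summary_ordering_enforced(self):
        with pytest.raises(ValueError):
            MetricSummary("cii", 0.5, 0.6, 0.7, np.array([0.5]))


def degenerate_posterior(psiA, lamA, psiB, lamB, n=40):
    names = ["psi[A]", "rate[A]", "psi[B]", "rate[B]"]
    row = np.array([psiA, lamA, psiB, lamB])
    draws = np.tile(row, (2, n, 1))
    return PosteriorSamples(draws=draws, parameter_names=names,
                            meta={"family": "exponential",
                                  "species": ["A", "B"]})


class TestPosteriorMetric:
    def test_degenerate_posterior_equals_deterministic(self):
        post = degenerate_posterior(0.52, 0.39, 0.28, 0.21)
        w = AnalysisWindow(14.0)
        for name, direct in [
            ("cii", tc.competition_intensity(0.28, expo(0.39), expo(0.21), w)),
            ("pfc", tc.potential_functional_contribution(0.52, expo(0.39), w)),
            ("ufc", tc.unique_functional_contribution(0.52, expo(0.39), 0.28,
                                                      expo(0.21), w)),
            ("redundancy", tc.functional_redundancy(0.52, expo(0.39), 0.28,
                                                    expo(0.21), w)),
        ]:
            ms = tc.posterior_metric(post, name, "A", "B", window=w)
            assert ms.point == pytest.approx(direct, abs=1e-10)
            assert ms.ci_low == pytest.approx(ms.ci_high, abs=1e-12)

    def test_cii_draws_respect_range_bound(self, exp_pair_posterior):
        ms = tc.posterior_metric(exp_pair_posterior, "cii", "A", "B",
                                 max_draws=300)
        psi_b_max = exp_pair_posterior.get("psi[B]").max()
        assert np.all(ms.draws >= 0)
        assert np.all(ms.draws <= psi_b_max + 1e-12)

    def test_posterior_cii_recovers_truth(self, exp_pair_posterior,
                                          exp_pair_truth):
        true_cii = tc.competition_intensity(
            exp_pair_truth["B"].psi, exp_pair_truth["A"].ttd,
            exp_pair_truth["B"].ttd,
        )
        ms = tc.posterior_metric(exp_pair_posterior, "cii", "A", "B",
                                 max_draws=500)
        assert ms.ci_low < true_cii < ms.ci_high

    def test_unknown_metric_and_species_rejected(self, exp_pair_posterior):
        with pytest.raises(ValueError, match="unknown metric"):
            tc.posterior_metric(exp_pair_posterior, "share", "A", "B")
        with pytest.raises(KeyError, match="C"):
            tc.posterior_metric(exp_pair_posterior, "cii", "A", "C")

    def test_allocation_requires_decay(self, exp_pair_posterior):
        with pytest.raises(ValueError, match="decay"):
            tc.posterior_metric(exp_pair_posterior, "allocation", "A", "B")


class TestPredictiveHistogram:
    def test_absent_species_never_wins(self, decay_posterior):
        post = degenerate_posterior(0.0, 0.4, 0.5, 0.2)
        h = tc.predictive_allocation_histogram(post, decay_posterior, "A", "B",
                                               nsim=500, seed=0)
        assert np.all(h == 0.0)

    def test_outcomes_clipped_to_unit_interval(self, exp_pair_posterior,
                                               decay_posterior):
        h = tc.predictive_allocation_histogram(
            exp_pair_posterior, decay_posterior, "A", "B", nsim=4000, seed=1
        )
        assert h.shape == (4000,)
        assert np.all((h >= 0.0) & (h <= 1.0))
        assert (h == 0.0).any()  # absences and lost races

    def test_mean_matches_allocation_integral(self, decay_truth):
        """Law of large numbers: the noiseless predictive mean converges to
        the allocation integral at the same parameters."""
        post = degenerate_posterior(0.6, 0.25, 0.4, 0.15)
        decay_names = ["alpha", "beta", "gamma", "dispersion"]
        decay_row = np.array([decay_truth.alpha, decay_truth.beta,
                              decay_truth.gamma_asymptote,
                              decay_truth.dispersion])
        dpost = PosteriorSamples(np.tile(decay_row, (2, 20, 1)),
                                 parameter_names=decay_names)
        n = 200_000
        h = tc.predictive_allocation_histogram(post, dpost, "A", "B", nsim=n,
                                               seed=3, observation_noise=False)
        direct = tc.resource_allocation(0.6, 0.4, expo(0.25), expo(0.15),
                                        decay_truth)
        se = h.std(ddof=1) / math.sqrt(n)
        assert abs(h.mean() - direct) < 2.0 * se
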