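"""Multi-host force of infection: formula, likelihood, components."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from foidecomp import (
    FieldObservation,
    FOIComponents,
    FOIParams,
    SentinelTrial,
    foi_from_components,
    foi_multi_host,
    make_sentinel_loglik,
    prob_infested,
    sentinel_loglik,
)
from foidecomp.foi import PairingError, pair_trials_to_fields


def _field_pair(week, n_f, i_f, n_a, i_a):
    return [
        FieldObservation(week, "s0", "focal", n_f, i_f),
        FieldObservation(week, "s0", "alternative", n_a, i_a),
    ]


class TestFOIMultiHost:
    def test_direct_evaluation(self):
        params = FOIParams(beta_FF=0.2, k_FF=1.0, beta_FA=0.02, k_FA=0.5)
        # 0.2*10*0.5 + 0.02*sqrt(4)*0.5
        assert foi_multi_host(params, 10, 5, 4, 2) == pytest.approx(1.02, abs=1e-12)

    def test_no_infectious_hosts(self):
        params = FOIParams(0.5, 0.7, 0.5, 0.7)
        assert foi_multi_host(params, 10, 0, 4, 0) == 0.0

    def test_density_and_frequency_limits(self):
        # k = 1: term is beta * I; k = 0: term is beta * I/N
        dd = FOIParams(beta_FF=0.3, k_FF=1.0)
        assert foi_multi_host(dd, 8, 2, 0, 0) == pytest.approx(0.3 * 2)
        fd = FOIParams(beta_FF=0.3, k_FF=0.0)
        assert foi_multi_host(fd, 8, 2, 0, 0) == pytest.approx(0.3 * 2 / 8)

    def test_zero_density_species_contributes_zero(self):
        params = FOIParams(0.2, 1.0, 0.9, 0.0)
        assert foi_multi_host(params, 10, 5, 0, 0) == pytest.approx(0.2 * 5)

    def test_infested_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            foi_multi_host(FOIParams(0.1, 1.0), 5, 6, 0, 0)

    @given(
        beta=st.floats(0, 2),
        k=st.floats(0.01, 1),
        n=st.floats(0.1, 30),
        frac=st.floats(0, 1),
        scale=st.floats(1, 3),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_beta_infested_and_density(self, beta, k, n, frac, scale):
        i = n * frac
        base = foi_multi_host(FOIParams(beta, k), n, i, 0, 0)
        # nondecreasing in beta
        assert foi_multi_host(FOIParams(min(beta * 1.5, 2.0), k), n, i, 0, 0) >= base - 1e-12
        # nondecreasing in I at fixed N
        assert foi_multi_host(FOIParams(beta, k), n, min(i * 1.2, n), 0, 0) >= base - 1e-12
        # at fixed prevalence, nondecreasing in N when k > 0
        assert foi_multi_host(FOIParams(beta, k), n * scale, i * scale, 0, 0) >= base - 1e-9


class TestProbInfested:
    def test_zero_limits(self):
        assert prob_infested(0.0, 7.0) == 0.0
        assert prob_infested(0.3, 0.0) == 0.0

    def test_saturation(self):
        assert prob_infested(100.0, 7.0) == pytest.approx(1.0, abs=1e-12)

    def test_one_week_exposure(self):
        assert prob_infested(0.1, 7) == pytest.approx(1 - math.exp(-0.7), rel=1e-12)

    def test_strictly_increasing(self):
        assert prob_infested(0.2, 5) > prob_infested(0.1, 5) > prob_infested(0.1, 2)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            prob_infested(-0.1, 7)


class TestSentinelLoglik:
    def test_matches_exact_binomial_pmf(self):
        # FOI = beta = -ln(0.7) with N=I=1, so p = 0.3 after one day
        beta = -math.log(0.7)
        params = FOIParams(beta_FF=beta, k_FF=1.0)
        trials = [SentinelTrial("t", 0, 10, 3, 1.0)]
        fields = _field_pair(0, 1, 1, 1, 0)
        ll = sentinel_loglik(params, trials, fields)
        assert ll == pytest.approx(binom.logpmf(3, 10, 0.3), abs=1e-10)
        assert ll == pytest.approx(-1.3212, abs=5e-5)

    def test_impossible_data_under_zero_foi_guarded(self):
        params = FOIParams(0.0, 0.5, 0.0, 0.5)
        trials = [SentinelTrial("t", 0, 10, 3, 7.0)]
        ll = sentinel_loglik(params, trials, _field_pair(0, 10, 5, 5, 2))
        assert np.isfinite(ll) and ll < -50  # clamped, very unlikely

    def test_duplicating_trials_doubles_loglik(self):
        params = FOIParams(0.1, 1.0, 0.01, 0.5)
        trials = [SentinelTrial("a", 0, 20, 7, 7.0), SentinelTrial("b", 1, 20, 2, 7.0)]
        fields = _field_pair(0, 10, 5, 5, 2) + _field_pair(1, 8, 2, 12, 6)
        single = sentinel_loglik(params, trials, fields)
        doubled = sentinel_loglik(
            params,
            trials + [SentinelTrial(t.trial_id + "x", t.week_index, t.n_exposed, t.n_infested, t.duration_days) for t in trials],
            fields,
        )
        assert doubled == pytest.approx(2 * single, rel=1e-12)

    def test_per_trial_oracle_on_random_data(self, rng):
        params = FOIParams(0.15, 0.8, 0.05, 0.3)
        trials, fields, expected = [], [], 0.0
        for wk in range(6):
            n_f, i_f = rng.integers(1, 20), 0
            i_f = int(rng.integers(0, n_f + 1))
            n_a = int(rng.integers(1, 20))
            i_a = int(rng.integers(0, n_a + 1))
            fields += _field_pair(wk, n_f, i_f, n_a, i_a)
            n_exp = int(rng.integers(5, 50))
            foi = foi_multi_host(params, n_f, i_f, n_a, i_a)
            p = prob_infested(foi, 7.0)
            n_inf = int(rng.binomial(n_exp, min(max(p, 0), 1)))
            trials.append(SentinelTrial(f"t{wk}", wk, n_exp, n_inf, 7.0))
            expected += binom.logpmf(n_inf, n_exp, np.clip(p, 1e-12, 1 - 1e-12))
        assert sentinel_loglik(params, trials, fields) == pytest.approx(expected, abs=1e-8)

    def test_single_host_reduction(self):
        # beta_FA = 0 makes the multi-host likelihood the focal-only one
        trials = [SentinelTrial("a", 0, 20, 7, 7.0)]
        fields = _field_pair(0, 10, 5, 5, 2)
        full = make_sentinel_loglik(trials, fields)
        single = make_sentinel_loglik(trials, fields, single_host=True)
        theta = np.array([0.12, 0.7])
        assert single(theta) == pytest.approx(full(np.array([0.12, 0.7, 0.0, 0.5])), rel=1e-14)

    def test_unmatched_week_raises_pairing_error(self):
        trials = [SentinelTrial("a", 3, 20, 7, 7.0)]
        with pytest.raises(PairingError, match="3"):
            pair_trials_to_fields(trials, _field_pair(0, 10, 5, 5, 2))

    def test_site_aggregation_is_mean(self):
        fields = [
            FieldObservation(0, "s0", "focal", 10, 4),
            FieldObservation(0, "s1", "focal", 20, 6),
            FieldObservation(0, "s0", "alternative", 4, 2),
        ]
        cov = pair_trials_to_fields([SentinelTrial("a", 0, 5, 1, 7.0)], fields)
        assert cov[0] == (15.0, 5.0, 4.0, 2.0)


class TestFOIFromComponents:
    def test_single_species_product(self):
        comp = FOIComponents(contact_rate=0.5, success_prob=0.1, prevalence=0.5)
        assert foi_from_components([comp]) == pytest.approx(0.025)

    def test_additivity_and_susceptible_scaling(self):
        comp = FOIComponents(0.5, 0.1, 0.5)
        assert foi_from_components([comp, comp]) == pytest.approx(2 * 0.025)
        assert foi_from_components([comp], susceptibles=40) == pytest.approx(40 * 0.025)

    def test_multiplicative_zero(self):
        comps = [FOIComponents(0.0, 0.5, 0.9), FOIComponents(1.2, 0.5, 0.0)]
        assert foi_from_components(comps) == 0.0

    def test_component_invariants(self):
        with pytest.raises(ValueError):
            FOIComponents(-0.1, 0.5, 0.5)
        with pytest.raises(ValueError):
            FOIComponents(0.1, 1.5, 0.5)
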