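"""Markov engine: transition structure, propagation, rewards."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdcheck.markov import (
    IDX_DEAD,
    IDX_EVENT,
    IDX_NOCVD,
    IDX_POST,
    N_STATES,
    SUBTYPES,
    MarkovParameters,
    StateTrace,
    UtilitySet,
    annualize,
    build_transition_matrix,
    life_years,
    propagate,
    qalys,
    run_cohort,
    split_by_subtype,
)


def _toy_params(incidence=0.0, mortality=0.0, smr=1.0, cycles=50):
    alloc = {"UA": 0.2, "SA": 0.2, "MI": 0.2, "Stroke": 0.2, "TIA": 0.2}
    bands = {(45, 94): mortality if mortality > 0 else 1e-12}
    inc = {(45, 94): {s: incidence / 5 for s in SUBTYPES}}
    return MarkovParameters(
        sex="male",
        arm_incidence_5yr={"usual_care": incidence, "health_check": incidence},
        allocation=alloc,
        incidence=inc,
        mortality=bands,
        smr={s: smr for s in SUBTYPES},
        start_age=45,
        cycles=cycles,
    )


class TestAnnualize:
    def test_zero(self):
        assert annualize(0.0) == 0.0

    def test_known_value(self):
        # independent arithmetic: 1 - (1 - 0.037)**0.2
        assert annualize(0.037) == pytest.approx(1 - (1 - 0.037) ** 0.2, rel=1e-14)
        assert annualize(0.037) == pytest.approx(0.0075120, abs=5e-7)

    @given(p=st.floats(0.0, 0.9))
    def test_round_trip_identity(self, p):
        a = annualize(p)
        assert 1 - (1 - a) ** 5 == pytest.approx(p, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            annualize(1.0)


class TestSplitBySubtype:
    def test_shares_sum_to_input(self, config):
        out = split_by_subtype(0.0075, config.allocation["male"])
        assert sum(out.values()) == pytest.approx(0.0075)

    def test_male_mi_share(self, config):
        # MI takes 42.87% of incident events at 45-49 (renormalised share)
        alloc = config.allocation["male"]
        out = split_by_subtype(0.0075, alloc)
        assert out["MI"] / 0.0075 == pytest.approx(alloc["MI"])
        assert alloc["MI"] == pytest.approx(0.4287 / 0.9539, rel=1e-6)

    def test_zero_probability(self, config):
        out = split_by_subtype(0.0, config.allocation["female"])
        assert all(v == 0.0 for v in out.values())

    def test_uniform_allocation(self):
        out = split_by_subtype(0.05, {s: 0.2 for s in SUBTYPES})
        assert all(v == pytest.approx(0.01) for v in out.values())


class TestTransitionMatrix:
    @pytest.mark.parametrize("arm", ["usual_care", "health_check"])
    def test_rows_stochastic_every_cycle(self, config, arm):
        for sex in ("male", "female"):
            params = config.markov_parameters(sex)
            for cycle in range(1, params.cycles + 1):
                m = build_transition_matrix(cycle, params, arm)
                np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(m >= 0)

    def test_dead_is_absorbing(self, male_params):
        m = build_transition_matrix(10, male_params, "usual_care")
        expected = np.zeros(N_STATES)
        expected[IDX_DEAD] = 1.0
        np.testing.assert_array_equal(m[IDX_DEAD], expected)

    def test_arms_identical_from_cycle_six(self, config):
        params = config.markov_parameters("male")
        for cycle in (6, 20, 50):
            a = build_transition_matrix(cycle, params, "usual_care")
            b = build_transition_matrix(cycle, params, "health_check")
            np.testing.assert_array_equal(a, b)
        a5 = build_transition_matrix(5, params, "usual_care")
        b5 = build_transition_matrix(5, params, "health_check")
        assert not np.array_equal(a5, b5)

    def test_post_mi_death_is_smr_times_background(self, config):
        # male age 67: 0.01628 background x SMR 2.28 = 0.0371184
        params = config.markov_parameters("male")
        cycle = 67 - params.start_age + 1
        m = build_transition_matrix(cycle, params, "usual_care")
        assert m[IDX_POST["MI"], IDX_DEAD] == pytest.approx(0.01628 * 2.28)

    def test_no_repeat_events(self, male_params):
        m = build_transition_matrix(3, male_params, "usual_care")
        for s in SUBTYPES:
            row = m[IDX_POST[s]]
            allowed = {IDX_POST[s], IDX_DEAD}
            nonzero = set(np.nonzero(row)[0])
            assert nonzero <= allowed
            # tunnel states flow only to their post state or death
            row = m[IDX_EVENT[s]]
            nonzero = set(np.nonzero(row)[0])
            assert nonzero <= {IDX_POST[s], IDX_DEAD}

    def test_smr_capped_at_one(self):
        params = _toy_params(incidence=0.05, mortality=0.5, smr=5.0)
        m = build_transition_matrix(1, params, "usual_care")
        assert m[IDX_POST["MI"], IDX_DEAD] == 1.0


class TestRunCohort:
    def test_occupancy_conserved_and_dead_monotone(self, config):
        for sex in ("male", "female"):
            params = config.markov_parameters(sex)
            trace = run_cohort(params, "usual_care")
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(np.diff(trace.occupancy[:, IDX_DEAD]) >= -1e-12)

    def test_all_dead_stays_dead(self, male_params):
        initial = np.zeros(N_STATES)
        initial[IDX_DEAD] = 1.0
        trace = run_cohort(male_params, "usual_care", initial=initial)
        assert np.all(trace.occupancy[:, IDX_DEAD] == 1.0)

    def test_zero_rates_leave_cohort_untouched(self):
        params = _toy_params(incidence=0.0, mortality=0.0)
        trace = run_cohort(params, "usual_care")
        np.testing.assert_allclose(trace.occupancy[:, IDX_NOCVD], 1.0, atol=1e-9)
        assert life_years(trace, 0.0) == pytest.approx(50.0)

    def test_matches_matrix_power_oracle(self):
        # constant random transition matrix: propagation must equal the
        # closed-form matrix power applied to the initial vector
        rng = np.random.default_rng(7)
        for n in (3, 12):
            m = rng.random((n, n))
            m /= m.sum(axis=1, keepdims=True)
            initial = rng.random(n)
            initial /= initial.sum()
            out = propagate(initial, [m] * 20)
            for t in (1, 5, 20):
                expected = initial @ np.linalg.matrix_power(m, t)
                np.testing.assert_allclose(out[t - 1], expected, atol=1e-12)

    def test_ages_advance_from_entry(self, male_params):
        trace = run_cohort(male_params, "usual_care")
        assert trace.ages[0] == male_params.start_age
        assert trace.ages[-1] == male_params.start_age + male_params.cycles - 1

    def test_trace_validation(self):
        bad = np.zeros((3, N_STATES))
        bad[:, 0] = 0.9  # rows don't sum to 1
        with pytest.raises(ValueError):
            StateTrace(bad, np.array([45, 46, 47]))


class TestRewards:
    def test_single_cycle_qaly_discounting(self):
        occ = np.zeros((1, N_STATES))
        occ[0, IDX_NOCVD] = 1.0
        trace = StateTrace(occ, np.array([45]))
        utils = UtilitySet(
            "male",
            population={(40, 120): 0.8},
            acute={s: 1.0 for s in SUBTYPES},
        )
        assert qalys(trace, utils, 0.05) == pytest.approx(0.8 / 1.05)

    def test_discount_monotonicity(self, config, male_utils):
        trace = run_cohort(config.markov_parameters("male"), "usual_care")
        assert life_years(trace, 0.05) <= life_years(trace, 0.035) <= life_years(trace, 0.0)
        assert (
            qalys(trace, male_utils, 0.05)
            <= qalys(trace, male_utils, 0.035)
            <= qalys(trace, male_utils, 0.0)
        )

    def test_tia_carries_no_decrement(self, config):
        utils = config.utility_set("male")
        u = utils.state_utilities(50)
        pop = utils.population_at(50)
        assert u[IDX_EVENT["TIA"]] == pytest.approx(pop)
        assert u[IDX_POST["TIA"]] == pytest.approx(pop)
        assert u[IDX_EVENT["Stroke"]] < u[IDX_EVENT["MI"]] < pop

    def test_post_event_reduction_interpolates(self, config):
        from dataclasses import replace

        utils = config.utility_set("male")
        pop = utils.population_at(60)
        full = replace(utils, post_event_disutility_reduction=0.0)
        none = replace(utils, post_event_disutility_reduction=1.0)
        assert none.state_utilities(60)[IDX_POST["MI"]] == pytest.approx(pop)
        assert full.state_utilities(60)[IDX_POST["MI"]] == pytest.approx(
            full.state_utilities(60)[IDX_EVENT["MI"]]
        )

    def test_arm_ordering(self, config, male_utils):
        params = config.markov_parameters("male")
        t_c = run_cohort(params, "usual_care")
        t_i = run_cohort(params, "health_check")
        assert life_years(t_i, 0.0) >= life_years(t_c, 0.0)
        assert qalys(t_i, male_utils, 0.05) >= qalys(t_c, male_utils, 0.05)
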