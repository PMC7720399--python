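import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hospavoid import (
    ArmParameters,
    CohortOutcomes,
    ModelConfig,
    Param,
    annualise_equipment,
    build_transition_matrix,
    incremental_analysis,
    run_cohort,
)
from hospavoid.markov import transition_matrix_from_probs
from hospavoid.parameters import INTERVENTION, USUAL_CARE

S, SA, H, D = range(4)

UC_PROBS = {"p_death": 0.0011, "p_admit_direct": 0.001, "p_discharge": 0.151}
INT_PROBS = {
    "p_death": 0.0011, "p_subacute_onset": 0.003, "p_treat_in_facility": 0.670,
    "p_admit_from_subacute": 0.722, "p_discharge": 0.283,
}
NEUTRAL_ECON = {
    "cost_racf_bed_day": 194.0, "cost_hospital_bed_day": 1807.0,
    "cost_ambulance": 649.0, "equipment_annual": 0.0,
    "utility_racf": 0.514, "utility_hospital": 0.44,
}

prob_st = st.floats(0.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# Independent oracle: expected finite-horizon tallies by repeated matrix
# powers (and, for the infinite horizon, fundamental-matrix algebra).
# ---------------------------------------------------------------------------

def matrix_power_expectations(m, n_residents, horizon):
    """Expected cumulative admissions / episodes / bed days via explicit
    matrix powers, independent of the engine's incremental loop."""
    v0 = np.array([float(n_residents), 0.0, 0.0, 0.0])
    adm = epi = bed = 0.0
    for t in range(horizon):
        occ_t = v0 @ np.linalg.matrix_power(m, t)
        adm += occ_t[S] * m[S, H] + occ_t[SA] * m[SA, H]
        epi += occ_t[S] * m[S, SA]
        occ_next = v0 @ np.linalg.matrix_power(m, t + 1)
        bed += occ_next[H]
    return adm, epi, bed


def fundamental_matrix_admissions(m, n_residents):
    """Infinite-horizon expected admissions per cohort from N = (I-Q)^-1."""
    q = m[:3, :3]  # transient block (STABLE, SUBACUTE, HOSPITAL)
    n = np.linalg.inv(np.eye(3) - q)
    visits = n[S, :]  # expected visits to each transient state from STABLE
    return n_residents * (visits[S] * m[S, H] + visits[SA] * m[SA, H])


class TestTransitionMatrix:
    def test_zero_probabilities_give_identity_dynamics(self):
        m = transition_matrix_from_probs(USUAL_CARE, dict.fromkeys(UC_PROBS, 0.0))
        assert np.array_equal(m, np.eye(4))

    def test_rows_sum_to_one_base_cases(self):
        for arm, probs in ((USUAL_CARE, UC_PROBS), (INTERVENTION, INT_PROBS)):
            m = transition_matrix_from_probs(arm, probs)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= 0).all()
            assert m[D, D] == 1.0 and m[D, :3].sum() == 0.0

    def test_death_competes_first_composition(self):
        m = transition_matrix_from_probs(USUAL_CARE, UC_PROBS)
        assert m[S, H] == pytest.approx((1 - 0.0011) * 0.001, abs=1e-15)
        mi = transition_matrix_from_probs(INTERVENTION, INT_PROBS)
        # per-episode admission probability (untreated and admitted)
        assert mi[SA, H] == pytest.approx((1 - 0.0011) * (1 - 0.670) * 0.722, abs=1e-15)
        assert (1 - 0.670) * 0.722 == pytest.approx(0.23826)

    @given(
        p_death=prob_st, p_admit=prob_st, p_disch=prob_st,
        p_onset=prob_st, p_treat=prob_st, p_sub=prob_st,
    )
    @settings(max_examples=200, deadline=None)
    def test_rows_sum_to_one_property(self, p_death, p_admit, p_disch, p_onset, p_treat, p_sub):
        uc = transition_matrix_from_probs(
            USUAL_CARE,
            {"p_death": p_death, "p_admit_direct": p_admit, "p_discharge": p_disch},
        )
        iv = transition_matrix_from_probs(
            INTERVENTION,
            {"p_death": p_death, "p_subacute_onset": p_onset,
             "p_treat_in_facility": p_treat, "p_admit_from_subacute": p_sub,
             "p_discharge": p_disch},
        )
        for m in (uc, iv):
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-9)
            assert (m >= -1e-12).all()


class TestCohortEngine:
    def test_event_free_cohort_closed_form(self):
        # No deaths, no events: QALYs = 96*0.514, cost = 96*365*194.
        probs = dict.fromkeys(UC_PROBS, 0.0)
        _, out = run_cohort(probs, NEUTRAL_ECON, ModelConfig(), arm=USUAL_CARE)
        assert out.total_qalys == pytest.approx(96 * 0.514, abs=1e-9)
        assert out.total_cost == pytest.approx(96 * 365 * 194, abs=1e-6)
        assert out.admissions == 0 and out.hospital_bed_days == 0

    @pytest.mark.parametrize(
        "arm,probs",
        [(USUAL_CARE, UC_PROBS), (INTERVENTION, INT_PROBS)],
        ids=["usual_care", "intervention"],
    )
    def test_matches_matrix_power_oracle(self, arm, probs):
        trace, out = run_cohort(probs, NEUTRAL_ECON, ModelConfig(), arm=arm)
        m = transition_matrix_from_probs(arm, probs)
        adm, epi, bed = matrix_power_expectations(m, 96, 365)
        assert out.admissions == pytest.approx(adm, abs=1e-9)
        assert out.subacute_episodes == pytest.approx(epi, abs=1e-9)
        assert out.hospital_bed_days == pytest.approx(bed, abs=1e-9)

    def test_long_run_admissions_approach_fundamental_matrix(self):
        m = transition_matrix_from_probs(USUAL_CARE, UC_PROBS)
        total = fundamental_matrix_admissions(m, 96)
        _, out = run_cohort(
            UC_PROBS, NEUTRAL_ECON, ModelConfig(horizon_days=30_000), arm=USUAL_CARE
        )
        assert out.admissions == pytest.approx(total, rel=1e-6)

    def test_occupancy_conserved_each_cycle(self):
        trace, _ = run_cohort(INT_PROBS, NEUTRAL_ECON, ModelConfig(), arm=INTERVENTION)
        sums = trace.occupancy.sum(axis=1)
        np.testing.assert_allclose(sums, 96.0, atol=1e-9)
        assert (trace.occupancy >= -1e-12).all()
        for cum in (trace.cum_admissions, trace.cum_bed_days, trace.cum_episodes):
            assert (np.diff(cum) >= -1e-12).all()

    def test_cost_components_sum_to_total(self):
        _, out = run_cohort(INT_PROBS, {**NEUTRAL_ECON, "equipment_annual": 2342.0},
                            ModelConfig(), arm=INTERVENTION)
        assert out.total_cost == pytest.approx(sum(out.cost_components.values()))
        assert out.cost_components["equipment"] == 2342.0

    def test_monotonic_in_hospital_cost(self):
        outs = [
            run_cohort(UC_PROBS, {**NEUTRAL_ECON, "cost_hospital_bed_day": c},
                       ModelConfig(), arm=USUAL_CARE)[1].total_cost
            for c in (1000.0, 1807.0, 3000.0)
        ]
        assert outs == sorted(outs)

    def test_qalys_decrease_with_mortality(self):
        qalys = [
            run_cohort({**UC_PROBS, "p_death": p}, NEUTRAL_ECON,
                       ModelConfig(), arm=USUAL_CARE)[1].total_qalys
            for p in (0.0, 0.0011, 0.01)
        ]
        assert qalys == sorted(qalys, reverse=True)

    def test_admissions_increase_with_admission_probability(self):
        adm = [
            run_cohort({**UC_PROBS, "p_admit_direct": p}, NEUTRAL_ECON,
                       ModelConfig(), arm=USUAL_CARE)[1].admissions
            for p in (0.0, 0.001, 0.01)
        ]
        assert adm == sorted(adm)

    def test_low_event_limit_recovers_full_health_time(self):
        probs = {"p_death": 1e-9, "p_admit_direct": 1e-9, "p_discharge": 0.151}
        _, out = run_cohort(probs, NEUTRAL_ECON, ModelConfig(), arm=USUAL_CARE)
        assert out.total_qalys == pytest.approx(96 * 0.514, rel=1e-5)


class TestAnnualisation:
    def test_recovers_tabled_equipment_cost(self):
        # $11,998 purchase over 7 years -> the tabled $1,714 annual cost
        assert annualise_equipment(11_998, 7) == pytest.approx(1714.0)
        assert annualise_equipment(1714.0 * 7, 7) == pytest.approx(1714.0)

    @pytest.mark.parametrize("purchase,life,expected", [(0, 7, 0), (7, 7, 1)])
    def test_simple_cases(self, purchase, life, expected):
        assert annualise_equipment(purchase, life) == expected

    def test_nonpositive_life_rejected(self):
        with pytest.raises(ValueError):
            annualise_equipment(100, 0)


def _outcomes(cost, qalys, arm=INTERVENTION, n=96):
    return CohortOutcomes(
        arm=arm, admissions=0.0, hospital_bed_days=0.0, subacute_episodes=0.0,
        total_cost=cost, total_qalys=qalys, cost_components={}, n_residents=n,
        horizon_days=365,
    )


class TestIncrementalAnalysis:
    def test_reported_nmb_identity(self):
        # Cost saving of $249,000 with 0.06 QALYs gained over 96 residents
        interv = _outcomes(6_190_000 - 249_000, 39.69 + 0.06)
        usual = _outcomes(6_190_000, 39.69, arm=USUAL_CARE)
        ce = incremental_analysis(interv, usual, wtp_per_qaly=28_000)
        assert ce.classification == "dominant"
        assert ce.nmb_per_resident == pytest.approx((28_000 * 0.06 + 249_000) / 96)
        assert ce.nmb_per_resident == pytest.approx(2611.25, abs=0.01)
        ce0 = incremental_analysis(interv, usual, wtp_per_qaly=0)
        assert ce0.nmb_per_resident == pytest.approx(2593.75, abs=0.01)

    @pytest.mark.parametrize(
        "d_cost,d_q,expected",
        [
            (-1.0, 1.0, "dominant"),
            (1.0, -1.0, "dominated"),
            (0.0, 0.0, "equivalent"),
            (1.0, 1.0, "icer"),
            (-1.0, -1.0, "cost-saving-less-effective"),
            (0.0, 1.0, "icer"),
            (0.0, -1.0, "cost-saving-less-effective"),
            (1.0, 0.0, "icer"),
            (-1.0, 0.0, "cost-saving-less-effective"),
        ],
    )
    def test_dominance_sign_grid(self, d_cost, d_q, expected):
        usual = _outcomes(1_000.0, 10.0, arm=USUAL_CARE)
        interv = _outcomes(1_000.0 + d_cost, 10.0 + d_q)
        ce = incremental_analysis(interv, usual, wtp_per_qaly=28_000)
        assert ce.classification == expected
        if expected == "icer" and d_q > 0:
            assert ce.icer == pytest.approx(d_cost / d_q)
        if expected == "icer" and d_q == 0:
            assert math.isinf(ce.icer)

    def test_mismatched_configs_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            incremental_analysis(
                _outcomes(1.0, 1.0, n=96), _outcomes(1.0, 1.0, arm=USUAL_CARE, n=94)
            )


def test_structured_parameters_equal_plain_probabilities(base_params):
    usual, interv, econ = base_params
    m1 = build_transition_matrix(interv)
    m2 = transition_matrix_from_probs(INTERVENTION, INT_PROBS)
    np.testing.assert_allclose(m1, m2, atol=1e-15)
    _, o1 = run_cohort(interv, econ, ModelConfig())
    _, o2 = run_cohort(
        INT_PROBS,
        {**NEUTRAL_ECON, "equipment_annual": econ.equipment_annual_total},
        ModelConfig(),
        arm=INTERVENTION,
    )
    assert o1.total_cost == pytest.approx(o2.total_cost)
    assert o1.total_qalys == pytest.approx(o2.total_qalys)
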