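"""Daily-cycle Markov cohort engine and incremental cost-effectiveness analysis.

Four health states: STABLE (in the facility), SUBACUTE (a one-day episode of
deterioration managed in the facility), HOSPITAL, and absorbing DEAD.  Each
daily cycle death competes first: every alive resident dies with probability
p_death, and the care transitions apply to survivors via a (1 − p_death)·p
factorisation, so each transition-matrix row sums to one without
renormalisation.

The engine evolves the expected state-occupancy vector of a closed cohort
(deaths are not replaced) over 365 one-day cycles, tallying expected
admissions (flow into HOSPITAL), hospital bed days (HOSPITAL occupancy summed
over cycles) and sub-acute episodes (flow into SUBACUTE).  Costs accrue as
facility per diems for all alive residents (the facility bed is retained
during hospital stays), hospital per diems per bed day, an ambulance transfer
per admission, and — intervention arm only — the annualised diagnostic
equipment cost added once.  QALYs weight person-time by the state utilities
(facility/sub-acute vs hospital) with 365 days = 1 year.  No half-cycle
correction and no discounting are applied over the 12-month horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    INTERVENTION,
    STATES,
    USUAL_CARE,
    ArmParameters,
    EconParameters,
    ModelConfig,
)

__all__ = [
    "CohortTrace",
    "CohortOutcomes",
    "CEResult",
    "build_transition_matrix",
    "transition_matrix_from_probs",
    "run_cohort",
    "annualise_equipment",
    "incremental_analysis",
]

S, SA, H, D = range(4)
_ROW_TOL = 1e-12


def transition_matrix_from_probs(arm: str, probs: dict[str, float]) -> np.ndarray:
    """Transition matrix for one arm from plain probability values.

    ``probs`` uses the :class:`~hospavoid.parameters.ArmParameters` field
    names.  Death is drawn first each cycle, so every care transition is
    scaled by the daily survival probability (1 − p_death).
    """
    pd_ = probs["p_death"]
    surv = 1.0 - pd_
    m = np.zeros((4, 4))
    m[:, D] = pd_
    if arm == USUAL_CARE:
        m[S, H] = surv * probs["p_admit_direct"]
        m[S, S] = 1.0 - m[S, D] - m[S, H]
        m[SA, SA] = surv  # state unreachable under usual care; kept inert
    elif arm == INTERVENTION:
        m[S, SA] = surv * probs["p_subacute_onset"]
        m[S, S] = 1.0 - m[S, D] - m[S, SA]
        p_admit_episode = (1.0 - probs["p_treat_in_facility"]) * probs["p_admit_from_subacute"]
        m[SA, H] = surv * p_admit_episode
        m[SA, S] = 1.0 - m[SA, D] - m[SA, H]
    else:
        raise ValueError(f"unknown arm {arm!r}")
    m[H, S] = surv * probs["p_discharge"]
    m[H, H] = 1.0 - m[H, D] - m[H, S]
    m[D, :] = 0.0
    m[D, D] = 1.0
    if np.abs(m.sum(axis=1) - 1.0).max() > _ROW_TOL or (m < -_ROW_TOL).any():
        raise ValueError("internal consistency error: transition rows must sum to 1")
    return m


def build_transition_matrix(params: ArmParameters) -> np.ndarray:
    """Base-case transition matrix (rows/columns ordered STABLE, SUBACUTE, HOSPITAL, DEAD)."""
    return transition_matrix_from_probs(params.arm, params.means())


@dataclass(frozen=True)
class CohortTrace:
    """Expected state occupancy and cumulative event tallies per cycle.

    ``occupancy[t]`` is the expected head count per state at the end of day
    ``t`` (row 0 is the initial all-STABLE cohort); the cumulative arrays are
    aligned with it.
    """

    occupancy: np.ndarray  # (horizon+1, 4)
    cum_admissions: np.ndarray
    cum_bed_days: np.ndarray
    cum_episodes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(STATES))
        df.insert(0, "day", np.arange(len(df)))
        df["cum_admissions"] = self.cum_admissions
        df["cum_hospital_bed_days"] = self.cum_bed_days
        df["cum_subacute_episodes"] = self.cum_episodes
        return df


@dataclass(frozen=True)
class CohortOutcomes:
    """Expected one-year totals for one arm of the model."""

    arm: str
    admissions: float
    hospital_bed_days: float
    subacute_episodes: float
    total_cost: float
    total_qalys: float
    cost_components: dict[str, float] = field(default_factory=dict)
    n_residents: int = 96
    horizon_days: int = 365

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.admissions, self.hospital_bed_days,
                                       self.total_cost, self.total_qalys))):
            raise ValueError("non-finite cohort outcome")


def run_cohort(
    params: ArmParameters | dict[str, float],
    econ: EconParameters | dict[str, float],
    config: ModelConfig = ModelConfig(),
    arm: str | None = None,
) -> tuple[CohortTrace, CohortOutcomes]:
    """Evolve the expected cohort and accrue costs and QALYs.

    ``params`` and ``econ`` may be the structured objects (base-case means
    are used) or plain ``{name: value}`` dictionaries (as drawn by the
    probabilistic sensitivity analysis).  Economic value names:
    ``cost_racf_bed_day, cost_hospital_bed_day, cost_ambulance,
    equipment_annual, utility_racf, utility_hospital``.
    """
    if isinstance(params, ArmParameters):
        arm = params.arm
        probs = params.means()
    else:
        if arm is None:
            raise ValueError("arm must be given when params is a plain dict")
        probs = params
    if isinstance(econ, EconParameters):
        evals = {
            "cost_racf_bed_day": econ.cost_racf_bed_day.mean,
            "cost_hospital_bed_day": econ.cost_hospital_bed_day.mean,
            "cost_ambulance": econ.cost_ambulance.mean,
            "equipment_annual": econ.equipment_annual_total,
            "utility_racf": econ.utility_racf.mean,
            "utility_hospital": econ.utility_hospital.mean,
        }
    else:
        evals = econ

    m = transition_matrix_from_probs(arm, probs)
    t_max = config.horizon_days
    n = config.n_residents

    occ = np.zeros((t_max + 1, 4))
    occ[0, S] = float(n)
    cum_adm = np.zeros(t_max + 1)
    cum_bed = np.zeros(t_max + 1)
    cum_epi = np.zeros(t_max + 1)

    racf_days = 0.0  # person-days alive in STABLE or SUBACUTE
    bed_days = 0.0
    v = occ[0].copy()
    for t in range(1, t_max + 1):
        inflow_h = v[S] * m[S, H] + v[SA] * m[SA, H]
        inflow_sa = v[S] * m[S, SA]
        v = v @ m
        occ[t] = v
        cum_adm[t] = cum_adm[t - 1] + inflow_h
        cum_epi[t] = cum_epi[t - 1] + inflow_sa
        bed_days += v[H]
        cum_bed[t] = bed_days
        racf_days += v[S] + v[SA]

    admissions = cum_adm[-1]
    episodes = cum_epi[-1]
    alive_days = racf_days + bed_days

    components = {
        "racf_per_diem": evals["cost_racf_bed_day"] * alive_days,
        "hospital": evals["cost_hospital_bed_day"] * bed_days,
        "ambulance": evals["cost_ambulance"] * admissions,
        "equipment": evals["equipment_annual"] if arm == INTERVENTION else 0.0,
    }
    total_cost = sum(components.values())
    qalys = (
        racf_days * evals["utility_racf"] + bed_days * evals["utility_hospital"]
    ) / 365.0

    trace = CohortTrace(occ, cum_adm, cum_bed, cum_epi)
    outcomes = CohortOutcomes(
        arm=arm,
        admissions=admissions,
        hospital_bed_days=bed_days,
        subacute_episodes=episodes,
        total_cost=total_cost,
        total_qalys=qalys,
        cost_components=components,
        n_residents=n,
        horizon_days=t_max,
    )
    return trace, outcomes


def annualise_equipment(purchase_cost: float, life_years: float) -> float:
    """Straight-line annualisation of a capital purchase over its useful life."""
    if life_years <= 0:
        raise ValueError("life_years must be positive")
    if purchase_cost < 0:
        raise ValueError("purchase_cost must be non-negative")
    return purchase_cost / life_years


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the intervention against usual care.

    ``classification`` follows the cost-effectiveness plane: "dominant"
    requires strictly positive incremental QALYs and strictly negative
    incremental cost; "dominated" the reverse; same-sign quadrants report an
    ICER or a cost-saving-but-less-effective trade-off.
    """

    delta_cost: float
    delta_qalys: float
    classification: str
    icer: float | None
    wtp_per_qaly: float
    nmb_total: float
    nmb_per_resident: float
    n_residents: int


def _classify(delta_cost: float, delta_qalys: float) -> tuple[str, float | None]:
    if delta_qalys > 0 and delta_cost < 0:
        return "dominant", None
    if delta_qalys < 0 and delta_cost > 0:
        return "dominated", None
    if delta_cost == 0 and delta_qalys == 0:
        return "equivalent", None
    if delta_cost <= 0 and delta_qalys <= 0:
        return "cost-saving-less-effective", None
    # remaining: delta_cost >= 0, delta_qalys >= 0, not both zero
    icer = math.inf if delta_qalys == 0 else delta_cost / delta_qalys
    return "icer", icer


def incremental_analysis(
    intervention: CohortOutcomes,
    usual_care: CohortOutcomes,
    wtp_per_qaly: float = 28_000.0,
) -> CEResult:
    """Incremental cost, incremental QALYs, dominance classification and NMB.

    NMB_total = wtp·ΔQALY − ΔCost; NMB per resident divides by the cohort
    size.  Raises if the two arms were run under different cohort settings.
    """
    if (intervention.n_residents, intervention.horizon_days) != (
        usual_care.n_residents,
        usual_care.horizon_days,
    ):
        raise ValueError("mismatched cohort configurations between arms")
    d_cost = intervention.total_cost - usual_care.total_cost
    d_q = intervention.total_qalys - usual_care.total_qalys
    classification, icer = _classify(d_cost, d_q)
    nmb = wtp_per_qaly * d_q - d_cost
    return CEResult(
        delta_cost=d_cost,
        delta_qalys=d_q,
        classification=classification,
        icer=icer,
        wtp_per_qaly=wtp_per_qaly,
        nmb_total=nmb,
        nmb_per_resident=nmb / intervention.n_residents,
        n_residents=intervention.n_residents,
    )
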