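"""Model parameters: transition probabilities, unit costs and utilities.

Every parameter carries a base-case mean and a standard deviation used by
the probabilistic sensitivity analysis.  The package ships a default
parameter table describing a prospective pre–post evaluation of a
nurse-led hospital-avoidance program in a 96-bed Australian residential
aged care facility (RACF): under usual care residents are transferred to
hospital directly, while under the intervention deteriorating residents
enter a "sub-acute" episode that nursing staff can often manage within the
facility.  Costs are 2018 Australian dollars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Param",
    "ArmParameters",
    "EquipmentItem",
    "EconParameters",
    "ModelConfig",
    "USUAL_CARE",
    "INTERVENTION",
    "default_parameters",
    "load_parameter_table",
    "save_parameter_table",
    "parameter_frame",
]

USUAL_CARE = "usual_care"
INTERVENTION = "intervention"

STATES = ("STABLE", "SUBACUTE", "HOSPITAL", "DEAD")


@dataclass(frozen=True)
class Param:
    """A scalar model input with uncertainty: base-case mean and SD."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _check_prob(name: str, p: Param | None) -> None:
    if p is not None and not 0.0 <= p.mean <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p.mean}")


@dataclass(frozen=True)
class ArmParameters:
    """Daily transition probabilities for one study arm.

    Usual care: stable residents are admitted to hospital directly with
    daily probability ``p_admit_direct``.  Intervention: stable residents
    enter a one-day sub-acute episode with daily probability
    ``p_subacute_onset``; an episode is managed within the facility with
    probability ``p_treat_in_facility`` and otherwise leads to a hospital
    admission with probability ``p_admit_from_subacute``.  Hospital stays
    end in discharge with daily probability ``p_discharge``; all alive
    residents die with daily probability ``p_death`` regardless of state.
    """

    arm: str
    p_death: Param
    p_discharge: Param
    p_admit_direct: Param | None = None
    p_subacute_onset: Param | None = None
    p_treat_in_facility: Param | None = None
    p_admit_from_subacute: Param | None = None

    def __post_init__(self) -> None:
        if self.arm not in (USUAL_CARE, INTERVENTION):
            raise ValueError(f"unknown arm {self.arm!r}")
        for name in (
            "p_death",
            "p_discharge",
            "p_admit_direct",
            "p_subacute_onset",
            "p_treat_in_facility",
            "p_admit_from_subacute",
        ):
            _check_prob(name, getattr(self, name))
        if self.arm == USUAL_CARE:
            if self.p_admit_direct is None:
                raise ValueError("usual_care arm requires p_admit_direct")
            if any(
                getattr(self, n) is not None
                for n in ("p_subacute_onset", "p_treat_in_facility", "p_admit_from_subacute")
            ):
                raise ValueError("sub-acute pathway parameters are intervention-only")
        else:
            if self.p_admit_direct is not None:
                raise ValueError("p_admit_direct is usual-care-only")
            for n in ("p_subacute_onset", "p_treat_in_facility", "p_admit_from_subacute"):
                if getattr(self, n) is None:
                    raise ValueError(f"intervention arm requires {n}")

    def means(self) -> dict[str, float]:
        """Base-case probability values keyed by field name (None fields omitted)."""
        out = {}
        for name in (
            "p_death",
            "p_discharge",
            "p_admit_direct",
            "p_subacute_onset",
            "p_treat_in_facility",
            "p_admit_from_subacute",
        ):
            p = getattr(self, name)
            if p is not None:
                out[name] = p.mean
        return out


@dataclass(frozen=True)
class EquipmentItem:
    """One item of diagnostic equipment with its annualised cost."""

    name: str
    annual_cost: Param


@dataclass(frozen=True)
class EconParameters:
    """Unit costs (AUD) and health-state utilities.

    The RACF per diem accrues for every alive resident (the facility bed is
    retained during a hospital stay); the hospital per diem accrues per
    hospital bed day; the ambulance cost attaches to each admission.
    Equipment costs are capital purchases annualised straight-line over
    ``equipment_life_years`` and added once per modelled year to the
    intervention arm.
    """

    cost_racf_bed_day: Param
    cost_hospital_bed_day: Param
    cost_ambulance: Param
    utility_racf: Param
    utility_hospital: Param
    equipment: tuple[EquipmentItem, ...] = ()
    equipment_life_years: float = 7.0
    currency_year: int = 2018

    def __post_init__(self) -> None:
        for name in ("cost_racf_bed_day", "cost_hospital_bed_day", "cost_ambulance"):
            if getattr(self, name).mean < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("utility_racf", "utility_hospital"):
            _check_prob(name, getattr(self, name))
        if self.equipment_life_years <= 0:
            raise ValueError("equipment_life_years must be positive")

    @property
    def equipment_annual_total(self) -> float:
        return sum(item.annual_cost.mean for item in self.equipment)


@dataclass(frozen=True)
class ModelConfig:
    """Cohort and evaluation settings.

    A closed cohort of ``n_residents`` is followed in daily cycles over
    ``horizon_days`` (one year); deaths are not replaced.  ``wtp_per_qaly``
    is the willingness to pay used for Net Monetary Benefit.  No
    discounting is applied over the 12-month horizon.
    """

    n_residents: int = 96
    horizon_days: int = 365
    cycle_length_days: int = 1
    wtp_per_qaly: float = 28_000.0
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residents < 1:
            raise ValueError("n_residents must be >= 1")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.wtp_per_qaly < 0:
            raise ValueError("wtp_per_qaly must be >= 0")


# ---------------------------------------------------------------------------
# Parameter-table I/O.  The on-disk mirror is a flat table with columns
# (name, arm, mean, sd, family, source); "arm" is empty for shared rows.
# ---------------------------------------------------------------------------

_PROB_FIELDS = {
    "p_death",
    "p_discharge",
    "p_admit_direct",
    "p_subacute_onset",
    "p_treat_in_facility",
    "p_admit_from_subacute",
}
_COST_FIELDS = {"cost_racf_bed_day", "cost_hospital_bed_day", "cost_ambulance"}
_UTIL_FIELDS = {"utility_racf", "utility_hospital"}


def _rows_to_objects(rows: Iterable[dict], equipment_life_years: float, currency_year: int):
    by_arm: dict[str, dict[str, Param]] = {USUAL_CARE: {}, INTERVENTION: {}}
    shared: dict[str, Param] = {}
    equipment: list[EquipmentItem] = []
    for r in rows:
        name = r["name"]
        p = Param(float(r["mean"]), float(r.get("sd", 0.0) or 0.0))
        arm = r.get("arm") or ""
        if name.startswith("equipment:"):
            equipment.append(EquipmentItem(name.split(":", 1)[1], p))
        elif arm in by_arm and name in _PROB_FIELDS:
            by_arm[arm][name] = p
        elif name in _PROB_FIELDS | _COST_FIELDS | _UTIL_FIELDS:
            shared[name] = p
        else:
            raise ValueError(f"unrecognised parameter row {name!r} (arm={arm!r})")

    def arm_param(arm: str, name: str) -> Param | None:
        return by_arm[arm].get(name, shared.get(name) if name == "p_death" else None)

    missing = [f for f in _COST_FIELDS | _UTIL_FIELDS if f not in shared]
    if "p_death" not in shared and not all("p_death" in by_arm[a] for a in by_arm):
        missing.append("p_death")
    if missing:
        raise ValueError(f"parameter table is missing required fields: {sorted(missing)}")

    usual = ArmParameters(
        arm=USUAL_CARE,
        p_death=arm_param(USUAL_CARE, "p_death"),
        p_discharge=by_arm[USUAL_CARE]["p_discharge"],
        p_admit_direct=by_arm[USUAL_CARE]["p_admit_direct"],
    )
    interv = ArmParameters(
        arm=INTERVENTION,
        p_death=arm_param(INTERVENTION, "p_death"),
        p_discharge=by_arm[INTERVENTION]["p_discharge"],
        p_subacute_onset=by_arm[INTERVENTION]["p_subacute_onset"],
        p_treat_in_facility=by_arm[INTERVENTION]["p_treat_in_facility"],
        p_admit_from_subacute=by_arm[INTERVENTION]["p_admit_from_subacute"],
    )
    econ = EconParameters(
        cost_racf_bed_day=shared["cost_racf_bed_day"],
        cost_hospital_bed_day=shared["cost_hospital_bed_day"],
        cost_ambulance=shared["cost_ambulance"],
        utility_racf=shared["utility_racf"],
        utility_hospital=shared["utility_hospital"],
        equipment=tuple(equipment),
        equipment_life_years=equipment_life_years,
        currency_year=currency_year,
    )
    return usual, interv, econ


def _objects_to_rows(usual: ArmParameters, interv: ArmParameters, econ: EconParameters):
    rows = []

    def add(name, arm, p: Param, family, source=""):
        rows.append(
            {"name": name, "arm": arm, "mean": p.mean, "sd": p.sd,
             "family": family, "source": source}
        )

    add("p_death", "", usual.p_death, "beta", "study data")
    for armobj in (interv, usual):
        for name in (
            "p_subacute_onset",
            "p_treat_in_facility",
            "p_admit_from_subacute",
            "p_admit_direct",
            "p_discharge",
        ):
            p = getattr(armobj, name)
            if p is not None:
                add(name, armobj.arm, p, "beta", "study data")
    add("cost_racf_bed_day", "", econ.cost_racf_bed_day, "normal", "fee schedule")
    add("cost_ambulance", "", econ.cost_ambulance, "normal", "published tariff")
    add("cost_hospital_bed_day", "", econ.cost_hospital_bed_day, "gamma",
        "published estimate, inflated to 2018 AUD")
    for item in econ.equipment:
        add(f"equipment:{item.name}", "", item.annual_cost, "normal", "study data")
    add("utility_racf", "", econ.utility_racf, "beta", "published estimate")
    add("utility_hospital", "", econ.utility_hospital, "beta", "published estimate")
    return rows


def default_parameters() -> tuple[ArmParameters, ArmParameters, EconParameters]:
    """The shipped base-case parameter table (usual care, intervention, economics)."""
    with resources.files("hospavoid.data").joinpath("default_parameters.json").open() as fh:
        doc = json.load(fh)
    return _rows_to_objects(
        doc["parameters"], doc["equipment_life_years"], doc["currency_year"]
    )


def load_parameter_table(path: str | Path):
    """Read a parameter table from JSON (structured) or CSV (flat mirror)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        return _rows_to_objects(
            doc["parameters"],
            doc.get("equipment_life_years", 7.0),
            doc.get("currency_year", 2018),
        )
    df = pd.read_csv(path, keep_default_na=False)
    return _rows_to_objects(df.to_dict("records"), 7.0, 2018)


def save_parameter_table(
    path: str | Path,
    usual: ArmParameters,
    interv: ArmParameters,
    econ: EconParameters,
) -> None:
    path = Path(path)
    rows = _objects_to_rows(usual, interv, econ)
    if path.suffix.lower() == ".json":
        doc = {
            "currency_year": econ.currency_year,
            "equipment_life_years": econ.equipment_life_years,
            "parameters": rows,
        }
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        pd.DataFrame(rows).to_csv(path, index=False)


def parameter_frame(
    usual: ArmParameters, interv: ArmParameters, econ: EconParameters
) -> pd.DataFrame:
    """The parameter table as a tidy DataFrame (one row per parameter)."""
    return pd.DataFrame(_objects_to_rows(usual, interv, econ))
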