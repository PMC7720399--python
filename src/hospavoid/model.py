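"""Model/Results interface over the cohort engine and sensitivity analysis.

    >>> from hospavoid import CostEffectivenessModel
    >>> model = CostEffectivenessModel.from_defaults()
    >>> res = model.fit()                      # deterministic base case
    >>> print(res.summary())
    >>> psa = model.fit_psa(n_draws=1000, seed=42)
    >>> psa.prob_cost_effective(28_000)

`fit()` evaluates both arms deterministically and returns
:class:`BaseCaseResults`; `fit_psa()` propagates parameter uncertainty and
returns :class:`PSAResults`.  Both Results objects expose ``summary()``
tables and CSV/JSON export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import psa as _psa
from .markov import (
    CEResult,
    CohortOutcomes,
    CohortTrace,
    incremental_analysis,
    run_cohort,
)
from .parameters import (
    INTERVENTION,
    USUAL_CARE,
    ArmParameters,
    EconParameters,
    ModelConfig,
    default_parameters,
    load_parameter_table,
    parameter_frame,
)

__all__ = ["CostEffectivenessModel", "BaseCaseResults", "PSAResults"]

_TABLE_ROWS = (
    ("Number of admissions", "admissions", 0),
    ("Total hospital bed days", "hospital_bed_days", 0),
    ("Total costs ($000's)", "total_cost", 3),  # scaled, see _table_value
    ("Total QALYs", "total_qalys", 2),
)


class CostEffectivenessModel:
    """Daily-cycle Markov cohort comparison of a hospital-avoidance program
    against usual care in a residential aged care facility.

    Parameters
    ----------
    usual_care, intervention : ArmParameters
    econ : EconParameters
    config : ModelConfig
        Cohort size (96), horizon (365 daily cycles) and default
        willingness to pay ($28,000/QALY).
    """

    def __init__(
        self,
        usual_care: ArmParameters,
        intervention: ArmParameters,
        econ: EconParameters,
        config: ModelConfig = ModelConfig(),
    ) -> None:
        if usual_care.arm != USUAL_CARE or intervention.arm != INTERVENTION:
            raise ValueError("arms passed in the wrong order")
        self.usual_care = usual_care
        self.intervention = intervention
        self.econ = econ
        self.config = config

    @classmethod
    def from_defaults(cls, config: ModelConfig = ModelConfig()) -> "CostEffectivenessModel":
        """Model built from the shipped base-case parameter table."""
        usual, interv, econ = default_parameters()
        return cls(usual, interv, econ, config)

    @classmethod
    def from_parameter_table(
        cls, path: str | Path, config: ModelConfig = ModelConfig()
    ) -> "CostEffectivenessModel":
        usual, interv, econ = load_parameter_table(path)
        return cls(usual, interv, econ, config)

    def parameter_table(self) -> pd.DataFrame:
        return parameter_frame(self.usual_care, self.intervention, self.econ)

    def parameter_hash(self) -> str:
        """SHA-256 of the parameter table and config, for run manifests."""
        payload = json.dumps(
            {
                "parameters": self.parameter_table().to_dict("records"),
                "config": asdict(self.config),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    def fit(self, wtp_per_qaly: float | None = None) -> "BaseCaseResults":
        """Deterministic base-case evaluation of both arms."""
        wtp = self.config.wtp_per_qaly if wtp_per_qaly is None else wtp_per_qaly
        uc_trace, uc_out = run_cohort(self.usual_care, self.econ, self.config)
        int_trace, int_out = run_cohort(self.intervention, self.econ, self.config)
        ce = incremental_analysis(int_out, uc_out, wtp)
        return BaseCaseResults(self, uc_trace, uc_out, int_trace, int_out, ce)

    def fit_psa(
        self,
        n_draws: int = 1000,
        seed: int = 0,
        wtp_values: tuple[float, ...] = (28_000.0, 0.0),
        shared_arm_draws: bool = True,
    ) -> "PSAResults":
        """Probabilistic sensitivity analysis (Monte Carlo over all parameters)."""
        cfg = _psa.PSAConfig(
            n_draws=n_draws,
            rng_seed=seed,
            wtp_values=tuple(wtp_values),
            shared_arm_draws=shared_arm_draws,
        )
        raw = _psa.run_psa(self.usual_care, self.intervention, self.econ, self.config, cfg)
        return PSAResults(self, raw, cfg)


@dataclass
class BaseCaseResults:
    """Deterministic outcomes for both arms plus the incremental comparison."""

    model: CostEffectivenessModel
    usual_care_trace: CohortTrace
    usual_care: CohortOutcomes
    intervention_trace: CohortTrace
    intervention: CohortOutcomes
    incremental: CEResult

    def outcomes_table(self, scale_costs: bool = True) -> pd.DataFrame:
        """Outcomes per arm and their difference (costs in $000's when scaled)."""
        rows = {}
        for label, attr, dp in _TABLE_ROWS:
            a = getattr(self.intervention, attr)
            b = getattr(self.usual_care, attr)
            if attr == "total_cost" and scale_costs:
                a, b = a / 1000.0, b / 1000.0
            rows[label] = {
                "Intervention": a,
                "Usual care": b,
                "Difference": a - b,
            }
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        ce = self.incremental
        table = self.outcomes_table().round(
            {"Intervention": 2, "Usual care": 2, "Difference": 2}
        )
        lines = [
            "Cost-effectiveness base case "
            f"({ce.n_residents} residents, {self.model.config.horizon_days} daily cycles)",
            "=" * 72,
            table.to_string(),
            "-" * 72,
            f"Incremental cost:  ${ce.delta_cost:,.0f}",
            f"Incremental QALYs: {ce.delta_qalys:.4f}",
            f"Classification:    {ce.classification}"
            + (f" (ICER ${ce.icer:,.0f}/QALY)" if ce.icer is not None else ""),
            f"NMB at ${ce.wtp_per_qaly:,.0f}/QALY: ${ce.nmb_total:,.0f} total, "
            f"${ce.nmb_per_resident:,.2f} per resident",
        ]
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            "outcomes": {
                arm.arm: {
                    "admissions": arm.admissions,
                    "hospital_bed_days": arm.hospital_bed_days,
                    "subacute_episodes": arm.subacute_episodes,
                    "total_cost": arm.total_cost,
                    "total_qalys": arm.total_qalys,
                    "cost_components": arm.cost_components,
                }
                for arm in (self.intervention, self.usual_care)
            },
            "incremental": {
                "delta_cost": self.incremental.delta_cost,
                "delta_qalys": self.incremental.delta_qalys,
                "classification": self.incremental.classification,
                "icer": self.incremental.icer,
                "wtp_per_qaly": self.incremental.wtp_per_qaly,
                "nmb_total": self.incremental.nmb_total,
                "nmb_per_resident": self.incremental.nmb_per_resident,
            },
        }


@dataclass
class PSAResults:
    """Monte Carlo results: per-draw outcomes, NMB summaries, acceptability."""

    model: CostEffectivenessModel
    raw: _psa.PSAResult
    config: _psa.PSAConfig

    @property
    def draws(self) -> pd.DataFrame:
        return self.raw.draws

    def mean_nmb(self, wtp: float) -> float:
        return self.raw.mean_nmb(wtp)

    def sd_nmb(self, wtp: float) -> float:
        return self.raw.sd_nmb(wtp)

    def prob_cost_effective(self, wtp: float) -> float:
        return _psa.prob_cost_effective(self.raw, wtp)

    def histogram(self, bin_width: float = 1000.0, wtp: float = 28_000.0) -> pd.DataFrame:
        return _psa.nmb_histogram(self.raw, bin_width, wtp)

    def mean_outcomes_table(self, scale_costs: bool = True) -> pd.DataFrame:
        """Monte Carlo mean outcomes per arm and their difference."""
        d = self.draws
        rows = {}
        for label, attr, _ in _TABLE_ROWS:
            key = {
                "admissions": "admissions",
                "hospital_bed_days": "bed_days",
                "total_cost": "cost",
                "total_qalys": "qalys",
            }[attr]
            a = float(d[f"int_{key}"].mean())
            b = float(d[f"uc_{key}"].mean())
            if attr == "total_cost" and scale_costs:
                a, b = a / 1000.0, b / 1000.0
            rows[label] = {"Intervention": a, "Usual care": b, "Difference": a - b}
        return pd.DataFrame(rows).T

    def summary(self) -> str:
        lines = [
            f"Probabilistic sensitivity analysis ({len(self.draws)} draws, "
            f"seed {self.config.rng_seed}, "
            f"{'shared' if self.config.shared_arm_draws else 'independent'} cross-arm draws)",
            "=" * 72,
            "Mean outcomes over draws:",
            self.mean_outcomes_table().round(2).to_string(),
            "-" * 72,
        ]
        for w in self.config.wtp_values:
            lines.append(
                f"NMB at ${w:,.0f}/QALY: mean ${self.mean_nmb(w):,.0f} per resident "
                f"(SD ${self.sd_nmb(w):,.0f}); "
                f"P(cost-effective) = {100 * self.prob_cost_effective(w):.1f}%"
            )
        if self.raw.n_excluded:
            lines.append(f"Excluded non-finite draws: {self.raw.n_excluded}")
        return "\n".join(lines)

    def summary_dict(self) -> dict:
        return self.raw.summary_dict()
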