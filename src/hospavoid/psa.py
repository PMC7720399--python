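"""Probabilistic sensitivity analysis over the full parameter set.

Distribution assignments follow the conventions of the base-case table:

* beta (moment-matched on the tabled mean and SD) for every transition
  probability and utility;
* normal for unit costs, with SD set so the 95 % CI spans ±20 % of the
  base case, truncated at zero by resampling — except the hospital bed-day
  cost, which keeps a gamma distribution moment-matched on its tabled
  mean and SD (1807, 1028);
* each equipment item is drawn with the normal ±20 % rule and the draws
  summed into the annual equipment cost.

Per draw, both arms are run through the cohort engine and the incremental
analysis is evaluated at each willingness-to-pay value.  Parameters shared
between arms (death probability, unit costs, utilities) receive the same
draw in both arms within a realisation — the conventional choice, avoiding
spurious incremental noise — while arm-specific rates are drawn
independently; ``shared_arm_draws=False`` disables the sharing.

Several of the tabled rate SDs are large relative to their means (e.g.
SD 0.004 on a mean daily admission probability of 0.001), so the matched
beta distributions are extremely right-skewed (α ≪ 1): most draws are near
zero with a long upper tail.  The resulting NMB distribution inherits that
shape — a negative median with a heavy positive tail — and its Monte Carlo
mean converges slowly.  See docs/methods.md for discussion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import (
    DistributionSpec,
    beta_from_moments,
    gamma_from_moments,
    normal_sd_from_20pct,
)
from .markov import CEResult, incremental_analysis, run_cohort
from .parameters import (
    INTERVENTION,
    USUAL_CARE,
    ArmParameters,
    EconParameters,
    ModelConfig,
    Param,
)

__all__ = [
    "PSAConfig",
    "PSAResult",
    "build_distribution_specs",
    "sample_parameters",
    "run_psa",
    "prob_cost_effective",
    "nmb_histogram",
]


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: 1000 draws, NMB at $28,000 and $0 per QALY."""

    n_draws: int = 1000
    rng_seed: int = 0
    wtp_values: tuple[float, ...] = (28_000.0, 0.0)
    shared_arm_draws: bool = True

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if any(w < 0 for w in self.wtp_values):
            raise ValueError("willingness-to-pay values must be >= 0")


def _cost_spec(p: Param) -> DistributionSpec:
    """Normal spec for a cost with 95 % CI spanning ±20 % of the mean.

    A tabled SD of exactly zero means "no uncertainty" and yields a
    degenerate spec (so an all-SDs-zero analysis collapses onto the
    deterministic base case).
    """
    if p.sd == 0:
        return DistributionSpec("normal", p.mean, 0.0, {})
    sd = normal_sd_from_20pct(p.mean)
    return DistributionSpec("normal", p.mean, sd, {"mu": p.mean, "sigma": sd})


def build_distribution_specs(
    usual: ArmParameters, interv: ArmParameters, econ: EconParameters
) -> dict[str, DistributionSpec]:
    """One sampling distribution per model parameter.

    Keys: ``uc_``/``int_``-prefixed arm rates, plus shared ``p_death``,
    cost and utility names, and one ``equipment:<item>`` entry per item.
    """
    specs: dict[str, DistributionSpec] = {}
    specs["p_death"] = beta_from_moments(usual.p_death.mean, usual.p_death.sd)
    specs["uc_p_admit_direct"] = beta_from_moments(
        usual.p_admit_direct.mean, usual.p_admit_direct.sd
    )
    specs["uc_p_discharge"] = beta_from_moments(
        usual.p_discharge.mean, usual.p_discharge.sd
    )
    specs["int_p_subacute_onset"] = beta_from_moments(
        interv.p_subacute_onset.mean, interv.p_subacute_onset.sd
    )
    specs["int_p_treat_in_facility"] = beta_from_moments(
        interv.p_treat_in_facility.mean, interv.p_treat_in_facility.sd
    )
    specs["int_p_admit_from_subacute"] = beta_from_moments(
        interv.p_admit_from_subacute.mean, interv.p_admit_from_subacute.sd
    )
    specs["int_p_discharge"] = beta_from_moments(
        interv.p_discharge.mean, interv.p_discharge.sd
    )
    specs["cost_racf_bed_day"] = _cost_spec(econ.cost_racf_bed_day)
    specs["cost_ambulance"] = _cost_spec(econ.cost_ambulance)
    specs["cost_hospital_bed_day"] = gamma_from_moments(
        econ.cost_hospital_bed_day.mean, econ.cost_hospital_bed_day.sd
    )
    for item in econ.equipment:
        specs[f"equipment:{item.name}"] = _cost_spec(item.annual_cost)
    specs["utility_racf"] = beta_from_moments(
        econ.utility_racf.mean, econ.utility_racf.sd
    )
    specs["utility_hospital"] = beta_from_moments(
        econ.utility_hospital.mean, econ.utility_hospital.sd
    )
    return specs


def sample_parameters(
    specs: dict[str, DistributionSpec],
    rng: np.random.Generator,
    n_draws: int = 1,
) -> pd.DataFrame:
    """Draw ``n_draws`` complete parameter realisations (one row each).

    Cost draws are truncated at zero by resampling.  Draw order follows the
    (sorted) spec keys so a given seed always yields the same matrix.
    """
    cols = {}
    for name in sorted(specs):
        spec = specs[name]
        truncate = spec.family == "normal"
        cols[name] = np.asarray(spec.sample(rng, size=n_draws, truncate_at_zero=truncate))
    return pd.DataFrame(cols)


@dataclass
class PSAResult:
    """Per-draw incremental outcomes and their summaries.

    ``draws`` holds one row per Monte Carlo draw: every sampled parameter,
    both arms' outcomes (admissions, bed days, cost, QALYs), the incremental
    cost and QALYs, and the per-resident NMB at each willingness-to-pay
    value (columns ``nmb_per_resident@<wtp>``).
    """

    draws: pd.DataFrame
    wtp_values: tuple[float, ...]
    n_residents: int
    base_case: dict[float, CEResult] = field(default_factory=dict)
    n_excluded: int = 0

    def nmb_column(self, wtp: float) -> pd.Series:
        col = f"nmb_per_resident@{wtp:g}"
        if col not in self.draws:
            raise KeyError(f"no NMB column for willingness to pay {wtp!r}")
        return self.draws[col]

    def mean_nmb(self, wtp: float) -> float:
        return float(self.nmb_column(wtp).mean())

    def sd_nmb(self, wtp: float) -> float:
        return float(self.nmb_column(wtp).std(ddof=1))

    def summary_dict(self) -> dict:
        out = {
            "n_draws": int(len(self.draws)),
            "n_excluded": self.n_excluded,
            "mean_outcomes": {
                arm: {
                    "admissions": float(self.draws[f"{tag}_admissions"].mean()),
                    "hospital_bed_days": float(self.draws[f"{tag}_bed_days"].mean()),
                    "total_cost": float(self.draws[f"{tag}_cost"].mean()),
                    "total_qalys": float(self.draws[f"{tag}_qalys"].mean()),
                }
                for arm, tag in ((USUAL_CARE, "uc"), (INTERVENTION, "int"))
            },
            "incremental": {
                "mean_delta_cost": float(self.draws["delta_cost"].mean()),
                "mean_delta_qalys": float(self.draws["delta_qalys"].mean()),
            },
            "nmb": {},
        }
        for w in self.wtp_values:
            out["nmb"][f"{w:g}"] = {
                "mean_per_resident": self.mean_nmb(w),
                "sd_per_resident": self.sd_nmb(w),
                "prob_cost_effective": prob_cost_effective(self, w),
            }
        return out


def run_psa(
    usual: ArmParameters,
    interv: ArmParameters,
    econ: EconParameters,
    model_config: ModelConfig = ModelConfig(),
    psa_config: PSAConfig = PSAConfig(),
) -> PSAResult:
    """Run the full Monte Carlo: sample, evaluate both arms, summarise.

    Deterministic given ``psa_config.rng_seed``.  Draws producing non-finite
    outcomes are excluded with a count kept on the result (zero in the base
    configuration).
    """
    specs = build_distribution_specs(usual, interv, econ)
    rng = np.random.default_rng(psa_config.rng_seed)
    draws = sample_parameters(specs, rng, psa_config.n_draws)
    if not psa_config.shared_arm_draws:
        # Independent-arms mode: redraw the shared parameters for the
        # intervention arm from the same stream.
        shared = [k for k in sorted(specs) if not k.startswith(("uc_", "int_"))]
        for name in shared:
            spec = specs[name]
            draws[f"int_only_{name}"] = np.asarray(
                spec.sample(rng, size=psa_config.n_draws,
                            truncate_at_zero=spec.family == "normal")
            )

    equip_cols = [c for c in draws.columns if c.startswith("equipment:")]
    records = []
    kept_idx: list[int] = []
    n_excluded = 0
    for i in range(psa_config.n_draws):
        row = draws.iloc[i]

        def shared_val(name: str) -> float:
            if not psa_config.shared_arm_draws:
                return float(row[f"int_only_{name}"])
            return float(row[name])

        uc_probs = {
            "p_death": float(row["p_death"]),
            "p_admit_direct": float(row["uc_p_admit_direct"]),
            "p_discharge": float(row["uc_p_discharge"]),
        }
        int_probs = {
            "p_death": shared_val("p_death"),
            "p_subacute_onset": float(row["int_p_subacute_onset"]),
            "p_treat_in_facility": float(row["int_p_treat_in_facility"]),
            "p_admit_from_subacute": float(row["int_p_admit_from_subacute"]),
            "p_discharge": float(row["int_p_discharge"]),
        }
        uc_econ = {
            "cost_racf_bed_day": float(row["cost_racf_bed_day"]),
            "cost_hospital_bed_day": float(row["cost_hospital_bed_day"]),
            "cost_ambulance": float(row["cost_ambulance"]),
            "equipment_annual": 0.0,
            "utility_racf": float(row["utility_racf"]),
            "utility_hospital": float(row["utility_hospital"]),
        }
        int_econ = {
            "cost_racf_bed_day": shared_val("cost_racf_bed_day"),
            "cost_hospital_bed_day": shared_val("cost_hospital_bed_day"),
            "cost_ambulance": shared_val("cost_ambulance"),
            "equipment_annual": float(
                sum(shared_val(c) for c in equip_cols)
            ),
            "utility_racf": shared_val("utility_racf"),
            "utility_hospital": shared_val("utility_hospital"),
        }
        try:
            _, uc_out = run_cohort(uc_probs, uc_econ, model_config, arm=USUAL_CARE)
            _, int_out = run_cohort(int_probs, int_econ, model_config, arm=INTERVENTION)
        except ValueError:  # non-finite accumulation in a pathological draw
            n_excluded += 1
            continue
        rec = {
            "uc_admissions": uc_out.admissions,
            "uc_bed_days": uc_out.hospital_bed_days,
            "uc_cost": uc_out.total_cost,
            "uc_qalys": uc_out.total_qalys,
            "int_admissions": int_out.admissions,
            "int_bed_days": int_out.hospital_bed_days,
            "int_cost": int_out.total_cost,
            "int_qalys": int_out.total_qalys,
            "delta_cost": int_out.total_cost - uc_out.total_cost,
            "delta_qalys": int_out.total_qalys - uc_out.total_qalys,
        }
        for w in psa_config.wtp_values:
            ce = incremental_analysis(int_out, uc_out, w)
            rec[f"nmb_per_resident@{w:g}"] = ce.nmb_per_resident
        if not all(np.isfinite(v) for v in rec.values()):
            n_excluded += 1
            continue
        records.append(rec)
        kept_idx.append(i)

    out = pd.concat(
        [draws.iloc[kept_idx].reset_index(drop=True), pd.DataFrame(records)], axis=1
    )
    base = {
        w: incremental_analysis(
            run_cohort(interv, econ, model_config)[1],
            run_cohort(usual, econ, model_config)[1],
            w,
        )
        for w in psa_config.wtp_values
    }
    return PSAResult(
        draws=out,
        wtp_values=psa_config.wtp_values,
        n_residents=model_config.n_residents,
        base_case=base,
        n_excluded=n_excluded,
    )


def prob_cost_effective(result: PSAResult, wtp: float) -> float:
    """Fraction of draws with strictly positive NMB at the given willingness to pay.

    Draws with NMB exactly zero count as not cost-effective.
    """
    nmb = result.nmb_column(wtp)
    return float((nmb > 0).mean())


def nmb_histogram(
    result: PSAResult, bin_width: float, wtp: float = 28_000.0
) -> pd.DataFrame:
    """Counts of per-resident NMB draws over uniform bins spanning their range.

    Returns a frame with columns (bin_left, bin_right, count); counts sum to
    the number of draws.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    nmb = result.nmb_column(wtp).to_numpy()
    lo, hi = float(nmb.min()), float(nmb.max())
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # ensure the top draw is included
    counts, edges = np.histogram(nmb, bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
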