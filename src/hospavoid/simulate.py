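"""Per-resident microsimulation of daily facility event logs.

Generates the kind of data the estimation layer consumes: one record per
resident per day with the resident's state and any event (sub-acute onset,
hospital admission, discharge, death).  The generative rules mirror the
cohort engine's transition structure exactly — per-resident Bernoulli draws
instead of expected-value flows — so event-count means over many seeds agree
with the deterministic cohort expectations on identical parameters.

The cohort is closed: 96 beds, no replacement of residents who die.  Day 0
is the initial all-stable day; transitions are evaluated at the start of
each subsequent day, death first (a resident cannot die and transfer on the
same day).  All draws come from a single ``numpy.random.Generator`` stream
in a fixed order — per day: death uniforms for residents 0..n−1, then
primary transition uniforms (onset / direct admission / treated-in-facility
/ discharge) for residents 0..n−1, then secondary uniforms (admission from
an untreated episode) — so identical seeds give identical logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .parameters import INTERVENTION, STATES, USUAL_CARE

__all__ = ["SimScenario", "EventLog", "simulate_event_log"]

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}
S, SA, H, D = range(4)

EVENT_NONE = ""
EVENT_ONSET = "subacute_onset"
EVENT_ADMISSION = "admission"
EVENT_DISCHARGE = "discharge"
EVENT_DEATH = "death"


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated arm-year.

    Defaults describe the study facility: 96 beds, a 365-day period, and an
    average occupancy of 94 used as the person-day denominator when the log
    is summarised.  Usual-care scenarios ignore the sub-acute pathway
    fields (admissions are direct).
    """

    arm: str = USUAL_CARE
    n_beds: int = 96
    occupancy_mean: float = 94.0
    horizon_days: int = 365
    p_subacute_onset: float = 0.0
    p_treat_in_facility: float = 0.0
    p_admit: float = 0.0
    p_discharge: float = 0.0
    p_death: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in (USUAL_CARE, INTERVENTION):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.n_beds < 1:
            raise ValueError("n_beds must be >= 1")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.occupancy_mean <= 0:
            raise ValueError("occupancy_mean must be positive")
        for name in (
            "p_subacute_onset",
            "p_treat_in_facility",
            "p_admit",
            "p_discharge",
            "p_death",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a finite probability in [0, 1], got {v!r}")


@dataclass
class EventLog:
    """Tidy per-resident daily log.

    ``frame`` columns: resident_id, day (0-based), state (STABLE / SUBACUTE /
    HOSPITAL / DEAD), event ('' or subacute_onset / admission / discharge /
    death) and episode_id (−1 when the day belongs to no sub-acute episode;
    an episode's onset and any resulting admission share an id).  Exactly one
    record per resident per day; DEAD is absorbing.
    """

    frame: pd.DataFrame
    arm: str
    n_beds: int
    horizon_days: int
    occupancy_mean: float = field(default=94.0)

    def validate(self) -> None:
        """Raise ValueError if the log violates its structural invariants."""
        df = self.frame
        expected = {"resident_id", "day", "state", "event", "episode_id"}
        if not expected.issubset(df.columns):
            raise ValueError(f"log is missing columns {sorted(expected - set(df.columns))}")
        counts = df.groupby("resident_id")["day"].agg(["count", "min", "max"])
        if (
            (counts["count"] != self.horizon_days).any()
            or (counts["min"] != 0).any()
            or (counts["max"] != self.horizon_days - 1).any()
        ):
            raise ValueError("malformed log: each resident needs one record per day")
        if not set(df["state"].unique()) <= set(STATES):
            raise ValueError("malformed log: unknown state labels")
        wide = df.pivot(index="day", columns="resident_id", values="state").to_numpy()
        dead = wide == "DEAD"
        if (dead[:-1] & ~dead[1:]).any():
            raise ValueError("malformed log: DEAD must be absorbing")

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        arm: str,
        occupancy_mean: float = 94.0,
    ) -> "EventLog":
        df = pd.read_csv(path, keep_default_na=False)
        df["episode_id"] = df["episode_id"].astype(int)
        log = cls(
            frame=df,
            arm=arm,
            n_beds=int(df["resident_id"].nunique()),
            horizon_days=int(df["day"].max()) + 1,
            occupancy_mean=occupancy_mean,
        )
        log.validate()
        return log


def simulate_event_log(scenario: SimScenario) -> EventLog:
    """Simulate one arm-year of per-resident daily events.

    Deterministic given ``scenario.rng_seed``.  Under the intervention arm a
    stable resident starts a one-day sub-acute episode with probability
    ``p_subacute_onset``; the episode is treated within the facility with
    probability ``p_treat_in_facility`` and otherwise leads to a hospital
    admission with probability ``p_admit``.  Under usual care stable
    residents are admitted directly with probability ``p_admit``.  Hospital
    days end in discharge with probability ``p_discharge``; every alive
    resident dies with probability ``p_death`` each day, evaluated before
    any care transition.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    n, t_max = scenario.n_beds, scenario.horizon_days
    interv = scenario.arm == INTERVENTION

    state = np.full(n, S, dtype=np.int8)
    episode = np.full(n, -1, dtype=np.int64)  # id of the episode a day belongs to
    next_episode = 0

    states_out = np.empty((t_max, n), dtype=np.int8)
    events_out = np.zeros((t_max, n), dtype=np.int8)  # index into _EVENT_LABELS
    episodes_out = np.full((t_max, n), -1, dtype=np.int64)
    states_out[0] = state

    for t in range(1, t_max):
        u_death = rng.random(n)
        u_primary = rng.random(n)
        u_secondary = rng.random(n)

        new_state = state.copy()
        new_event = np.zeros(n, dtype=np.int8)
        new_episode = np.full(n, -1, dtype=np.int64)

        alive = state != D
        dies = alive & (u_death < scenario.p_death)
        new_state[dies] = D
        new_event[dies] = 4  # death

        survivors = alive & ~dies
        stable = survivors & (state == S)
        if interv:
            onset = stable & (u_primary < scenario.p_subacute_onset)
            new_state[onset] = SA
            new_event[onset] = 1  # subacute_onset
            ids = np.nonzero(onset)[0]
            new_episode[ids] = next_episode + np.arange(ids.size)
            next_episode += ids.size

            sub = survivors & (state == SA)
            treated = sub & (u_primary < scenario.p_treat_in_facility)
            untreated = sub & ~treated
            admitted = untreated & (u_secondary < scenario.p_admit)
            new_state[sub] = S
            new_state[admitted] = H
            new_event[admitted] = 2  # admission
            new_episode[admitted] = episode[admitted]
        else:
            admitted = stable & (u_primary < scenario.p_admit)
            new_state[admitted] = H
            new_event[admitted] = 2

        hosp = survivors & (state == H)
        discharged = hosp & (u_primary < scenario.p_discharge)
        new_state[discharged] = S
        new_event[discharged] = 3  # discharge

        state, episode = new_state, new_episode
        states_out[t] = state
        events_out[t] = new_event
        episodes_out[t] = new_episode

    labels = np.array(STATES)
    event_labels = np.array(
        [EVENT_NONE, EVENT_ONSET, EVENT_ADMISSION, EVENT_DISCHARGE, EVENT_DEATH]
    )
    days = np.repeat(np.arange(t_max), n)
    residents = np.tile(np.arange(n), t_max)
    frame = pd.DataFrame(
        {
            "resident_id": residents,
            "day": days,
            "state": labels[states_out.ravel()],
            "event": event_labels[events_out.ravel()],
            "episode_id": episodes_out.ravel(),
        }
    ).sort_values(["resident_id", "day"], kind="stable", ignore_index=True)
    return EventLog(
        frame=frame,
        arm=scenario.arm,
        n_beds=n,
        horizon_days=t_max,
        occupancy_mean=scenario.occupancy_mean,
    )
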