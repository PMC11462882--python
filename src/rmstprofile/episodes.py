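"""Construction of time-to-first-noncompliance episodes from claims tables.

A patient is followed from index discharge (day 0) and is "in compliance"
while a running stock of dispensed therapy days covers each outpatient day.
Cessation is declared when, after the day the stock runs out (the
*exhaustion day*), no rescuing refill restores coverage within a grace
window (default 30 days).  Days spent in hospital do not consume stock
(inpatient therapy is managed by the hospital) and each hospital discharge
credits a small tolerance (default 2 days); an exhaustion day therefore
never falls on an inpatient day.

Conventions (fixed and documented):

* all intervals are half-open ``[start, end)`` in integer days;
* supply pooling: early refills stockpile, and uncovered days inside a
  grace gap are borrowed against the next fill, so a rescuing fill must
  leave at least one net day of supply after repaying the gap;
* the recorded noncompliance time is the supply-exhaustion day (grace days
  are not days in compliance); ``event_time="exhaustion_plus_grace"``
  records the end of the grace window instead;
* a cessation is declared only when the whole grace window lies inside the
  observed follow-up; a terminal event or administrative censoring during
  the window takes precedence;
* same-day ties: competing event beats cessation; censoring loses to both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EpisodeParams:
    """Tunable rules of the episode sweep (all in days)."""

    tau_days: int = 365
    grace_days: int = 30
    inpatient_tolerance_days: int = 2
    event_time: str = "exhaustion"  # or "exhaustion_plus_grace"

    def __post_init__(self) -> None:
        if self.tau_days <= 0:
            raise ValueError("tau_days must be positive")
        if self.grace_days < 0 or self.inpatient_tolerance_days < 0:
            raise ValueError("grace/tolerance days must be non-negative")
        if self.event_time not in ("exhaustion", "exhaustion_plus_grace"):
            raise ValueError(f"unknown event_time convention {self.event_time!r}")


def compute_days_supplied(
    n_packages: float, package_size: float, dose_per_unit: float, daily_dose: float
) -> float:
    """Days of therapy covered by one fill: the dispensed quantity
    (packages x units per package x dose per unit) divided by the reference
    daily dose."""
    for name, v in (
        ("n_packages", n_packages),
        ("package_size", package_size),
        ("dose_per_unit", dose_per_unit),
        ("daily_dose", daily_dose),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return n_packages * package_size * dose_per_unit / daily_dose


def _merge_stays(stays) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(stays):
        a, b = int(a), int(b)
        if b <= a or a < 0:
            raise ValueError(f"invalid stay interval [{a}, {b})")
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _sweep(
    fills,
    stays,
    horizon: int,
    grace_days: int,
    tolerance_days: int,
):
    """Day-by-day supply-pooling sweep over observed days [0, horizon).

    ``fills`` is an iterable of (fill_day, days_supplied); ``stays`` of
    (admit_day, discharge_day) half-open intervals.  Returns
    (first_exhaustion_day, cessation_day) where either may be None:
    first_exhaustion_day is None when supply covers every observed
    outpatient day, cessation_day is None when every exhaustion is rescued
    by a fill within the grace window (or the window is not fully
    observed).
    """
    stays = _merge_stays(stays)
    credits: dict[int, float] = {}
    for day, supply in fills:
        day = int(day)
        if day < 0:
            raise ValueError("fill_day must be non-negative")
        if supply <= 0:
            raise ValueError("days supplied must be positive")
        credits[day] = credits.get(day, 0.0) + float(supply)
    for _, b in stays:
        credits[b] = credits.get(b, 0.0) + float(tolerance_days)

    inpatient = np.zeros(max(horizon, 1), dtype=bool)
    for a, b in stays:
        inpatient[a : min(b, horizon)] = True

    stock = 0.0
    pending: int | None = None  # current unresolved exhaustion day
    first_exhaustion: int | None = None
    for day in range(horizon):
        if day in credits:
            stock += credits[day]
        if stock >= 1.0:
            # a fill (or discharge credit) restoring net positive stock ends
            # any open gap, also when it arrives during a hospital stay
            pending = None
        if not inpatient[day]:
            if stock < 1.0 and pending is None:
                pending = day
                if first_exhaustion is None:
                    first_exhaustion = day
            stock -= 1.0  # gap days borrow against the next fill
        if pending is not None and day - pending >= grace_days:
            return first_exhaustion, pending
    return first_exhaustion, None


def coverage_end_day(
    claims: pd.DataFrame | list,
    stays: pd.DataFrame | list,
    inpatient_tolerance_days: int = 2,
    horizon: int = 5 * 365,
) -> float:
    """First day on which the pooled supply stock is exhausted.

    Returns ``inf`` when the stock lasts through every observable day
    (i.e. beyond ``horizon``).  An empty claim list exhausts at day 0.
    """
    fills = _claims_to_fills(claims)
    stay_list = _stays_to_intervals(stays)
    first, _ = _sweep(fills, stay_list, horizon, grace_days=horizon + 1,
                      tolerance_days=inpatient_tolerance_days)
    return math.inf if first is None else float(first)


def _claims_to_fills(claims) -> list[tuple[int, float]]:
    if isinstance(claims, pd.DataFrame):
        if claims.empty:
            return []
        supplied = (
            claims["n_packages"].to_numpy(float)
            * claims["package_size"].to_numpy(float)
            * claims["dose_per_unit"].to_numpy(float)
            / claims["daily_dose"].to_numpy(float)
        )
        if np.any(supplied <= 0):
            raise ValueError("non-positive days supplied in claims")
        return list(zip(claims["fill_day"].astype(int), supplied))
    return [(int(d), float(s)) for d, s in claims]


def _stays_to_intervals(stays) -> list[tuple[int, int]]:
    if isinstance(stays, pd.DataFrame):
        if stays.empty:
            return []
        return list(zip(stays["admit_day"].astype(int), stays["discharge_day"].astype(int)))
    return [(int(a), int(b)) for a, b in stays]


def derive_episode(
    censor_day: int,
    claims,
    stays,
    terminal_day: float = math.inf,
    params: EpisodeParams = EpisodeParams(),
) -> tuple[int, str]:
    """Episode (time_days, status) for one patient.

    The episode is the earliest of confirmed therapy cessation
    (``noncompliance``), death or recurrent index event (``competing``),
    administrative censoring, or the restriction time tau (both
    ``censored``).  Noncompliance is absorbing: fills after a confirmed
    cessation are irrelevant because the sweep stops at the first
    unrescued exhaustion.
    """
    if censor_day < 0:
        raise ValueError("censoring day must be non-negative")
    if terminal_day < 0:
        raise ValueError("terminal event before day 0")
    end_of_observation = int(min(censor_day, terminal_day)) if terminal_day < math.inf else int(censor_day)
    # nothing beyond tau + grace can change an episode: any exhaustion at or
    # after tau is censored by restriction, and a pre-tau exhaustion is
    # confirmed or rescued no later than tau - 1 + grace
    sweep_end = min(end_of_observation, params.tau_days + params.grace_days + 1)
    fills = _claims_to_fills(claims)
    stay_list = _stays_to_intervals(stays)
    _, cessation = _sweep(
        fills, stay_list, sweep_end,
        grace_days=params.grace_days,
        tolerance_days=params.inpatient_tolerance_days,
    )

    tau = params.tau_days
    if cessation is not None:
        event_day = cessation if params.event_time == "exhaustion" else cessation + params.grace_days
        if event_day < tau:
            return int(event_day), "noncompliance"
    if terminal_day <= censor_day and terminal_day < tau:
        return int(terminal_day), "competing"
    return int(min(censor_day, tau)), "censored"


def build_cohort_episodes(bundle, params: EpisodeParams = EpisodeParams()) -> pd.DataFrame:
    """One episode per patient of a claims bundle.

    Deterministic given its inputs; returns a table with columns
    patient_id, time_days, status, entity.
    """
    patients = bundle.patients
    if patients["patient_id"].duplicated().any():
        raise ValueError("duplicate patient_id in patients table")

    rx = bundle.prescriptions
    supplied = (
        rx["n_packages"].to_numpy(float) * rx["package_size"].to_numpy(float)
        * rx["dose_per_unit"].to_numpy(float) / rx["daily_dose"].to_numpy(float)
    )
    if np.any(supplied <= 0):
        raise ValueError("non-positive days supplied in claims")
    fills_by_pid: dict = {}
    for pid, day, sup in zip(rx["patient_id"], rx["fill_day"].to_numpy(int), supplied):
        fills_by_pid.setdefault(pid, []).append((int(day), float(sup)))
    stays_by_pid: dict = {}
    st = bundle.stays
    for pid, a, b in zip(st["patient_id"], st["admit_day"].to_numpy(int),
                         st["discharge_day"].to_numpy(int)):
        stays_by_pid.setdefault(pid, []).append((int(a), int(b)))
    term = bundle.terminal_events
    term_day = term.groupby("patient_id")["event_day"].min() if len(term) else pd.Series(dtype=float)

    rows = []
    empty: list = []
    for pid, entity, censor in zip(
        patients["patient_id"], patients["entity_id"], patients["censor_day"]
    ):
        t_day = float(term_day.get(pid, math.inf))
        time_days, status = derive_episode(
            int(censor), fills_by_pid.get(pid, empty), stays_by_pid.get(pid, empty),
            t_day, params,
        )
        rows.append((pid, time_days, status, entity))
    return pd.DataFrame(rows, columns=["patient_id", "time_days", "status", "entity"])
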