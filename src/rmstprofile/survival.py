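"""Nonparametric all-cause survival, cause-specific cumulative incidence, and
their exact integrals on [0, tau]: restricted mean survival time (RMST) and
restricted mean time lost (RMTL) decomposed by cause.

The estimand triple satisfies the decomposition identity

    RMST(tau) + sum_j RMTL_j(tau) = tau

exactly, because the Aalen-Johansen cumulative incidence functions and the
product-limit survival curve satisfy S(t) = 1 - sum_j F_j(t) at every time
point, and both sides are integrated by the same exact step-function rule.

Times are measured in days from the index discharge (day 0).  Statuses use
the string codes ``noncompliance`` (event of interest: therapy cessation),
``competing`` (death or recurrent index event) and ``censored``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: status string -> integer code used internally (0 must be "censored")
STATUS_CODES = {"censored": 0, "noncompliance": 1, "competing": 2}
STATUS_NAMES = {v: k for k, v in STATUS_CODES.items()}
CAUSES = ("noncompliance", "competing")


def episodes_to_arrays(episodes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (times, status codes) arrays from an episode table.

    Accepts either string statuses or already-coded integers.
    """
    times = np.asarray(episodes["time_days"], dtype=float)
    status = episodes["status"]
    if status.dtype == object or str(status.dtype).startswith("str"):
        codes = status.map(STATUS_CODES)
        if codes.isna().any():
            bad = sorted(set(status[codes.isna()]))
            raise ValueError(f"unknown episode status values: {bad}")
        codes = codes.to_numpy(dtype=np.int64)
    else:
        codes = np.asarray(status, dtype=np.int64)
    if times.size == 0:
        raise ValueError("empty episode table")
    if np.any(times < 0):
        raise ValueError("negative episode times")
    return times, codes


@dataclass
class StepFunction:
    """Right-continuous step function on [0, inf).

    ``values[k]`` is the level on [jump_times[k], jump_times[k+1]); the level
    on [0, jump_times[0]) is ``initial``.
    """

    jump_times: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.jump_times.ndim != 1 or self.jump_times.shape != self.values.shape:
            raise ValueError("jump_times and values must be 1-d and aligned")
        if self.jump_times.size > 1 and np.any(np.diff(self.jump_times) <= 0):
            raise ValueError("jump_times must be strictly increasing")

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        if self.jump_times.size == 0:
            out = np.full(t.shape, self.initial)
            return out if out.ndim else float(out)
        idx = np.searchsorted(self.jump_times, t, side="right") - 1
        out = np.where(idx < 0, self.initial, self.values[np.clip(idx, 0, None)])
        return out if out.ndim else float(out)

    def integrate(self, upper: float) -> float:
        """Exact rectangle integral over [0, upper] (no quadrature error)."""
        if upper <= 0:
            raise ValueError("integration bound must be positive")
        knots = np.concatenate([[0.0], self.jump_times, [np.inf]])
        levels = np.concatenate([[self.initial], self.values])
        lo = np.minimum(knots[:-1], upper)
        hi = np.minimum(knots[1:], upper)
        return float(np.sum((hi - lo) * levels))


@dataclass
class CIFSet:
    """All-cause survival plus one cumulative incidence function per cause."""

    survival: StepFunction
    cifs: dict[str, StepFunction]
    n_at_risk: np.ndarray = field(default_factory=lambda: np.array([]))

    def check_identity(self, atol: float = 1e-10) -> None:
        t = self.survival.jump_times
        total = self.survival(t) + sum(f(t) for f in self.cifs.values())
        if t.size and np.max(np.abs(total - 1.0)) > atol:
            raise AssertionError("S(t) + sum_j F_j(t) != 1")


# ---------------------------------------------------------------------------
# count-based core (shared with the fast jackknife in pseudo.py)
# ---------------------------------------------------------------------------

def risk_table(times: np.ndarray, codes: np.ndarray):
    """Unique observed times with per-time event/censor counts and risk sets.

    Returns (unique_times, n_at_risk, d) where d has one column per cause in
    ``CAUSES`` order.  n_at_risk counts subjects with T >= t (events and
    censorings tied at t are both still at risk at t: events-first
    convention).
    """
    order = np.argsort(times, kind="stable")
    ts, cs = times[order], codes[order]
    ut, start = np.unique(ts, return_index=True)
    k, n = ut.size, ts.size
    d = np.zeros((k, len(CAUSES)), dtype=np.int64)
    idx = np.searchsorted(ut, ts)
    for j in range(len(CAUSES)):
        np.add.at(d[:, j], idx[cs == j + 1], 1)
    n_at_risk = n - start  # subjects with T >= ut[k]
    return ut, n_at_risk.astype(np.int64), d


def curves_from_counts(ut: np.ndarray, n_at_risk: np.ndarray, d: np.ndarray):
    """Product-limit survival and Aalen-Johansen CIF values at ``ut``.

    Returns (surv, cif) with cif of shape (len(ut), n_causes); values are the
    right-continuous levels at each unique time.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(n_at_risk > 0, d.sum(axis=1) / n_at_risk, 0.0)
    surv = np.cumprod(1.0 - frac)
    s_prev = np.concatenate([[1.0], surv[:-1]])
    with np.errstate(divide="ignore", invalid="ignore"):
        jumps = np.where(n_at_risk[:, None] > 0, s_prev[:, None] * d / n_at_risk[:, None], 0.0)
    cif = np.cumsum(jumps, axis=0)
    return surv, cif


def restricted_means_from_counts(
    ut: np.ndarray, n_at_risk: np.ndarray, d: np.ndarray, tau: float
) -> np.ndarray:
    """(rmst, rmtl_cause_1, ..., rmtl_cause_J) at tau from a risk table."""
    surv, cif = curves_from_counts(ut, n_at_risk, d)
    seg_lo = np.minimum(np.concatenate([[0.0], ut]), tau)
    seg_hi = np.minimum(np.concatenate([ut, [np.inf]]), tau)
    widths = seg_hi - seg_lo
    s_levels = np.concatenate([[1.0], surv])
    out = [np.sum(widths * s_levels)]  # dtype-preserving (extended precision
    for j in range(d.shape[1]):        # callers pass longdouble counts)
        f_levels = np.concatenate([[0.0], cif[:, j]])
        out.append(np.sum(widths * f_levels))
    return np.array(out)


# ---------------------------------------------------------------------------
# public estimators
# ---------------------------------------------------------------------------

def kaplan_meier(episodes: pd.DataFrame, any_event: bool = True) -> StepFunction:
    """Product-limit estimator of all-cause survival S(t) = P(Y > t).

    With ``any_event`` (the default) every non-censored status counts as an
    event, which is the relevant survival function when competing causes are
    folded into "no longer in compliance for any reason".
    """
    times, codes = episodes_to_arrays(episodes)
    if not any_event:
        codes = np.where(codes == STATUS_CODES["noncompliance"], 1, 0)
    ut, n_at_risk, d = risk_table(times, codes)
    surv, _ = curves_from_counts(ut, n_at_risk, d)
    keep = d.sum(axis=1) > 0
    return StepFunction(ut[keep], surv[keep], initial=1.0)


def aalen_johansen(episodes: pd.DataFrame) -> CIFSet:
    """Aalen-Johansen estimator of the cause-specific cumulative incidences.

    F_j jumps at cause-j event times by S(t-) d_j / n_at_risk, so the
    identity S = 1 - sum_j F_j holds exactly at every jump.
    """
    times, codes = episodes_to_arrays(episodes)
    ut, n_at_risk, d = risk_table(times, codes)
    surv, cif = curves_from_counts(ut, n_at_risk, d)
    any_ev = d.sum(axis=1) > 0
    survival = StepFunction(ut[any_ev], surv[any_ev], initial=1.0)
    cifs = {}
    for j, cause in enumerate(CAUSES):
        keep = d[:, j] > 0
        cifs[cause] = StepFunction(ut[keep], cif[keep, j], initial=0.0)
    return CIFSet(survival=survival, cifs=cifs, n_at_risk=n_at_risk)


def rmst(surv: StepFunction, tau_days: float) -> float:
    """Area under the survival step function on [0, tau]: expected time in
    compliance before tau."""
    if tau_days <= 0:
        raise ValueError("tau_days must be positive")
    return surv.integrate(tau_days)


def rmtl_by_cause(cifset: CIFSet, tau_days: float) -> dict[str, float]:
    """Cause-decomposed restricted mean time lost mu_j = int_0^tau F_j.

    Returns one entry per cause plus ``total`` = sum_j mu_j = tau - RMST.
    """
    if tau_days <= 0:
        raise ValueError("tau_days must be positive")
    out = {cause: f.integrate(tau_days) for cause, f in cifset.cifs.items()}
    out["total"] = sum(out.values())
    return out


def restricted_means(episodes: pd.DataFrame, tau_days: float) -> dict[str, float]:
    """One-shot (rmst, rmtl per cause) summary of an episode table."""
    times, codes = episodes_to_arrays(episodes)
    vals = restricted_means_from_counts(*risk_table(times, codes), tau_days)
    out = {"rmst": vals[0]}
    for j, cause in enumerate(CAUSES):
        out[f"rmtl_{cause}"] = vals[j + 1]
    return out


def plot_stacked_cifs(cifset: CIFSet, tau_days: float, ax=None):
    """Stacked cumulative-incidence plot: the area below the lower curve is
    time lost to noncompliance, the band between curves time lost to
    competing events, and the area above the upper curve (up to 1) the
    restricted mean time in compliance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.linspace(0, tau_days, 500)
    lower = np.asarray(cifset.cifs[CAUSES[0]](grid))
    upper = lower + np.asarray(cifset.cifs[CAUSES[1]](grid))
    ax.fill_between(grid, 0, lower, step="post", alpha=0.5, label="lost: noncompliance")
    ax.fill_between(grid, lower, upper, step="post", alpha=0.5, label="lost: competing")
    ax.fill_between(grid, upper, 1, step="post", alpha=0.3, label="in compliance")
    ax.set(xlabel="days since discharge", ylabel="cumulative incidence", ylim=(0, 1))
    ax.legend()
    return ax
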