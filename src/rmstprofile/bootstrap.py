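"""Bias-corrected bootstrap intervals for per-entity estimates.

Patients are resampled with replacement, keeping the original cohort size;
the chosen standardization estimator is re-run in full on every replicate.
Intervals use the bias-corrected (BC, not BCa) percentile method: with
z0 = Phi^-1(fraction of replicates below the point estimate), the interval
endpoints are the Phi(2 z0 -+ z_{alpha/2}) percentiles of the replicate
distribution.  Family-wise coverage over m entities is controlled by
Bonferroni: each entity's interval is computed at level 1 - (1 - level)/m.

With a few hundred replicates the Bonferroni-adjusted percentile levels
fall outside the empirical grid of order statistics; percentiles are then
linearly interpolated (type-7) and clamped to the replicate range, and a
warning notes that such extreme quantiles are extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


def bonferroni_levels(m: int, family_level: float = 0.95) -> float:
    """Per-entity two-sided confidence level controlling family-wise
    coverage ``family_level`` across m entities."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < family_level <= 1:
        raise ValueError("family_level must be in (0, 1]")
    return 1.0 - (1.0 - family_level) / m


def bc_interval(replicates: np.ndarray, point: float, level: float) -> tuple[float, float]:
    """Bias-corrected percentile interval from bootstrap replicates.

    Ties at the point estimate count half toward the median-bias fraction.
    All replicates identical yields the degenerate interval (point, point).
    """
    reps = np.asarray(replicates, dtype=float)
    reps = reps[~np.isnan(reps)]
    if reps.size < 20:
        raise ValueError(f"need >= 20 non-missing replicates, got {reps.size}")
    if np.all(reps == reps[0]):
        return float(reps[0]), float(reps[0])
    frac = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / reps.size
    frac = min(max(frac, 0.5 / reps.size), 1 - 0.5 / reps.size)
    z0 = norm.ppf(frac)
    zcrit = norm.ppf(0.5 + level / 2.0)
    a_lo = norm.cdf(2 * z0 - zcrit)
    a_hi = norm.cdf(2 * z0 + zcrit)
    grid_lo, grid_hi = 0.5 / reps.size, 1 - 0.5 / reps.size
    if a_lo < grid_lo or a_hi > grid_hi:
        warnings.warn(
            f"BC percentile levels ({a_lo:.2e}, {a_hi:.2e}) outside the "
            f"empirical grid of B={reps.size} replicates; extreme quantiles "
            "are extrapolated from the replicate range"
        )
    lo = float(np.percentile(reps, 100 * a_lo))  # type-7 linear interpolation
    hi = float(np.percentile(reps, 100 * a_hi))
    return lo, hi


@dataclass
class BootstrapResult:
    """Replicates and BC intervals for a per-entity estimate table."""

    point: pd.DataFrame              # entity-indexed point estimates
    replicates: dict[str, np.ndarray]  # column -> (B, m) replicate matrix
    intervals: pd.DataFrame          # entity, column, point, lower, upper, level
    B: int
    seed: int
    family_level: float
    n_missing: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))


def bootstrap_estimates(
    data: pd.DataFrame,
    estimator_fn,
    B: int = 250,
    seed: int = 0,
    family_level: float = 0.95,
    value_columns: tuple[str, ...] = ("rmtl_noncompliance", "rmtl_competing", "rmst"),
    bonferroni: bool = True,
) -> BootstrapResult:
    """Patient-level bootstrap of an entity-estimate function.

    ``estimator_fn(frame)`` must return a table with an ``entity`` column
    and the requested value columns (e.g. any of the standardization
    estimators composed with episode construction).  Replicates in which
    an entity has no sampled patients are recorded as missing for that
    entity and excluded from its interval, with the count logged.
    """
    rng = np.random.default_rng(seed)
    point = estimator_fn(data).set_index("entity")
    entities = point.index.to_numpy()
    m = len(entities)
    reps = {c: np.full((B, m), np.nan) for c in value_columns if c in point.columns}
    n = len(data)
    for b in range(B):
        idx = rng.integers(0, n, n)
        boot = data.iloc[idx].reset_index(drop=True)
        est = estimator_fn(boot).set_index("entity")
        est = est.reindex(entities)
        for c in reps:
            reps[c][b] = est[c].to_numpy(dtype=float)

    level = bonferroni_levels(m, family_level) if bonferroni else family_level
    rows = []
    missing = {}
    for c, mat in reps.items():
        for k, z in enumerate(entities):
            col = mat[:, k]
            miss = int(np.isnan(col).sum())
            missing[z] = max(missing.get(z, 0), miss)
            lo, hi = bc_interval(col, float(point.loc[z, c]), level)
            rows.append({"entity": z, "quantity": c, "point": float(point.loc[z, c]),
                         "lower": lo, "upper": hi, "level": level, "B": B,
                         "n_missing": miss})
    n_missing = pd.Series(missing, name="n_missing")
    if int(n_missing.sum()) > 0:
        warnings.warn(
            f"{int(n_missing.sum())} bootstrap replicates dropped an entity "
            "entirely; affected intervals use fewer replicates"
        )
    return BootstrapResult(point, reps, pd.DataFrame(rows), B, seed, family_level, n_missing)
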