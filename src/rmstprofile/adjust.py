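"""Entity-standardized restricted means with confounder adjustment.

Three estimators of the standardized (potential-outcome) restricted mean
time lost per entity, all operating on jackknife pseudo-values P_i:

* IPTW: Hajek-weighted within-entity mean with weights 1 / e_z(X_i), where
  e_z(X) are multinomial propensity scores fitted by ridge-penalized
  logistic regression (penalty chosen by 10-fold cross-validated
  multinomial deviance).
* Outcome regression (g-computation): linear model of the pseudo-values on
  entity intercepts plus shared confounder coefficients, averaged over the
  whole cohort counterfactually assigned to each entity.
* Doubly robust (AIPW): the g-computation estimate plus an inverse
  probability weighted residual correction; consistent when either the
  propensity model or the outcome model is correct.

Centering subtracts the unweighted mean of the per-entity estimates, so a
centered value is an entity's excess time lost relative to the overall
risk-adjusted average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrix
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

PSEUDO_COLUMNS = ("pseudo_rmtl_noncompliance", "pseudo_rmtl_competing")
POSITIVITY_FLOOR = 1e-6


@dataclass
class DesignMatrix:
    """Confounder design: intercept, natural-spline age basis (4 df), sex,
    age-spline x sex interaction, index-year indicators, binary flags."""

    frame: pd.DataFrame  # includes the intercept column

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def without_intercept(self) -> np.ndarray:
        cols = [c for c in self.frame.columns if c != "intercept"]
        return self.frame[cols].to_numpy(dtype=float)


def build_design_matrix(patients: pd.DataFrame, spline_df: int = 4,
                        age_sex_interaction: bool = True) -> DesignMatrix:
    """Deterministic confounder design matrix for a patients table.

    The age spline is a natural cubic basis with ``spline_df`` degrees of
    freedom and knots at cohort age quantiles; categorical confounders are
    reference-coded; constant columns are dropped with a warning.
    """
    if "age" not in patients or "sex" not in patients:
        raise ValueError("patients table must contain age and sex")
    out = pd.DataFrame(index=patients.index)
    out["intercept"] = 1.0
    age = np.asarray(patients["age"], dtype=float)
    # cr() is a partition-of-unity basis, so its df+1 columns span the
    # constant; dropping one yields spline_df columns that are full rank
    # next to an intercept while spanning the same natural-spline space
    spline = np.asarray(dmatrix(f"cr(x, df={spline_df + 1}) - 1", {"x": age}))[:, 1:]
    for k in range(spline.shape[1]):
        out[f"age_ns{k + 1}"] = spline[:, k]
    female = (patients["sex"].astype(str) == "F").astype(float).to_numpy()
    out["sex_F"] = female
    if age_sex_interaction:
        for k in range(spline.shape[1]):
            out[f"age_ns{k + 1}:sex_F"] = spline[:, k] * female
    if "index_year" in patients:
        years = pd.Categorical(patients["index_year"])
        for lvl in years.categories[1:]:  # first level is the reference
            out[f"year_{lvl}"] = (patients["index_year"] == lvl).astype(float).to_numpy()
    for col in patients.columns:
        if col.startswith("cf_"):
            out[col] = pd.to_numeric(patients[col]).to_numpy(dtype=float)
    constant = [c for c in out.columns if c != "intercept" and out[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant design columns: {constant}")
        out = out.drop(columns=constant)
    if np.isnan(out.to_numpy(dtype=float)).any():
        raise ValueError("design matrix contains missing values")
    return DesignMatrix(out)


# ---------------------------------------------------------------------------
# propensity model
# ---------------------------------------------------------------------------

@dataclass
class PropensityFit:
    """Fitted multinomial ridge propensity model."""

    probs: pd.DataFrame       # n x m fitted probabilities, columns = entities
    lambda_: float            # selected ridge penalty (1 / sklearn C)
    cv_deviance: pd.Series | None  # mean CV deviance per candidate lambda
    coef: np.ndarray
    entities: np.ndarray

    def check_positivity(self, labels: np.ndarray, floor: float = POSITIVITY_FLOOR) -> None:
        own = self.probs.to_numpy()[np.arange(len(labels)),
                                    self.probs.columns.get_indexer(labels)]
        if np.any(own < floor):
            raise ValueError(
                f"positivity violation: fitted propensity below {floor} for "
                f"{int(np.sum(own < floor))} patients"
            )

    def diagnostics(self) -> pd.DataFrame:
        """Per-entity quantiles of the fitted propensities over the whole
        cohort (overlap summary)."""
        qs = [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99]
        rows = {z: np.quantile(self.probs[z], qs) for z in self.probs.columns}
        return pd.DataFrame(rows, index=[f"q{int(q * 100):02d}" for q in qs]).T


def _cv_folds(labels: np.ndarray, n_folds: int, seed):
    counts = pd.Series(labels).value_counts()
    folds = n_folds
    if counts.min() < n_folds:
        folds = max(2, int(counts.min()))
        warnings.warn(
            f"entity with only {int(counts.min())} patients: reducing CV folds "
            f"from {n_folds} to {folds}"
        )
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def fit_propensity_ridge(
    design: DesignMatrix,
    entity_labels,
    lambda_grid: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> PropensityFit:
    """Ridge multinomial propensity scores with CV-selected penalty.

    The penalty applies to standardized confounder coefficients only
    (intercepts unpenalized); the selected lambda minimizes the 10-fold
    cross-validated multinomial deviance.
    """
    labels = np.asarray(entity_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("propensity model needs at least 2 entities")
    X = design.without_intercept()
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    if lambda_grid is None:
        lambda_grid = np.logspace(-4, 4, 17)
    Cs = 1.0 / np.asarray(lambda_grid, dtype=float)
    order = np.argsort(Cs)
    cv = _cv_folds(labels, n_folds, seed)
    model = LogisticRegressionCV(
        Cs=Cs[order], cv=cv, penalty="l2", solver="lbfgs",
        scoring="neg_log_loss", max_iter=5000, refit=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, labels)
    lam = 1.0 / model.C_[0]
    # scores_ maps each class to folds x Cs mean log-likelihood; identical
    # across classes for the multinomial objective
    scores = next(iter(model.scores_.values()))
    cv_dev = pd.Series(-2.0 * scores.mean(axis=0), index=1.0 / Cs[order],
                       name="cv_deviance")
    probs = pd.DataFrame(model.predict_proba(Xs), columns=model.classes_,
                         index=design.frame.index)
    return PropensityFit(probs, lam, cv_dev, model.coef_, model.classes_)


def fit_propensity_fixed(design: DesignMatrix, entity_labels, lambda_: float) -> PropensityFit:
    """Ridge multinomial propensity fit at a fixed penalty (no CV)."""
    labels = np.asarray(entity_labels)
    X = StandardScaler().fit_transform(design.without_intercept())
    C = 1.0 / lambda_ if lambda_ > 0 else 1e12
    model = LogisticRegression(C=C, penalty="l2", solver="lbfgs", max_iter=20000,
                               tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, labels)
    probs = pd.DataFrame(model.predict_proba(X), columns=model.classes_,
                         index=design.frame.index)
    return PropensityFit(probs, float(lambda_), None, model.coef_, model.classes_)


# ---------------------------------------------------------------------------
# outcome model
# ---------------------------------------------------------------------------

@dataclass
class OutcomeFit:
    """Per-functional linear pseudo-value model with entity intercepts.

    Confounder coefficients are shared across entities by default (chosen
    for estimability at small per-entity sample sizes); with
    ``entity_slopes`` every entity gets its own slope vector, i.e. a
    separate regression per entity."""

    entities: np.ndarray
    entity_slopes: bool = False
    alpha: dict[str, np.ndarray] = field(default_factory=dict)   # entity intercepts
    beta: dict[str, np.ndarray] = field(default_factory=dict)    # (p,) or (p, m)
    columns: list[str] = field(default_factory=list)

    def predict(self, functional: str, design: DesignMatrix) -> np.ndarray:
        """m_hat_z(X_i) for every (patient, entity) pair: n x m array."""
        X = design.without_intercept()
        beta = self.beta[functional]
        Xb = X @ beta if self.entity_slopes else np.repeat((X @ beta)[:, None],
                                                           len(self.entities), axis=1)
        return Xb + self.alpha[functional][None, :]


def fit_outcome_model(pseudo: pd.DataFrame, design: DesignMatrix, entity_labels,
                      entity_slopes: bool = False) -> OutcomeFit:
    """Least-squares pseudo-value regressions, one per cause-specific RMTL."""
    labels = np.asarray(entity_labels)
    entities = np.unique(labels)
    m = len(entities)
    dummies = (labels[:, None] == entities[None, :]).astype(float)
    Xc = design.without_intercept()
    if entity_slopes:
        blocks = [dummies] + [dummies[:, [k]] * Xc for k in range(m)]
        M = np.hstack(blocks)
    else:
        M = np.hstack([dummies, Xc])
    if M.shape[0] <= M.shape[1]:
        raise ValueError("outcome model not estimable: n <= p + m")
    fit = OutcomeFit(entities=entities, entity_slopes=entity_slopes,
                     columns=[c for c in design.columns if c != "intercept"])
    rank = None
    p = Xc.shape[1]
    for col in PSEUDO_COLUMNS:
        y = pseudo[col].to_numpy(dtype=float)
        coef, _, rank, _ = np.linalg.lstsq(M, y, rcond=None)
        fit.alpha[col] = coef[:m]
        fit.beta[col] = (coef[m:].reshape(m, p).T if entity_slopes else coef[m:])
    if rank is not None and rank < M.shape[1]:
        warnings.warn("rank-deficient outcome design; pseudo-inverse solution used")
    return fit


# ---------------------------------------------------------------------------
# standardized estimators
# ---------------------------------------------------------------------------

def _finalize(df: pd.DataFrame, tau_days: float, estimator: str) -> pd.DataFrame:
    """Attach the decomposition-completing RMST and the estimator tag."""
    df = df.copy()
    df["rmst"] = tau_days - df["rmtl_noncompliance"] - df["rmtl_competing"]
    df["estimator"] = estimator
    return df.reset_index(drop=True)


def unadjusted_estimates(episodes: pd.DataFrame, tau_days: float) -> pd.DataFrame:
    """Per-entity Aalen-Johansen restricted means, no adjustment."""
    from .survival import restricted_means

    rows = []
    for z, grp in episodes.groupby("entity", sort=True):
        vals = restricted_means(grp, tau_days)
        rows.append({"entity": z, "n_z": len(grp),
                     "rmtl_noncompliance": vals["rmtl_noncompliance"],
                     "rmtl_competing": vals["rmtl_competing"]})
    return _finalize(pd.DataFrame(rows), tau_days, "unadjusted")


def iptw_estimates(pseudo: pd.DataFrame, propensity: PropensityFit,
                   entity_labels, tau_days: float) -> pd.DataFrame:
    """Hajek-weighted within-entity means of pseudo-values, weight
    1 / e_z(X_i) for patients of entity z."""
    labels = np.asarray(entity_labels)
    propensity.check_positivity(labels)
    rows = []
    for z in propensity.probs.columns:
        mask = labels == z
        if not mask.any():
            continue
        w = 1.0 / propensity.probs.loc[mask, z].to_numpy()
        row = {"entity": z, "n_z": int(mask.sum())}
        for col in PSEUDO_COLUMNS:
            p = pseudo.loc[mask, col].to_numpy(dtype=float)
            row[col.replace("pseudo_", "")] = float(np.sum(w * p) / np.sum(w))
        rows.append(row)
    return _finalize(pd.DataFrame(rows), tau_days, "iptw")


def gcomp_estimates(fit: OutcomeFit, design: DesignMatrix, tau_days: float,
                    n_z: pd.Series | None = None) -> pd.DataFrame:
    """Outcome-regression standardization: average the model prediction of
    every patient counterfactually assigned to each entity."""
    rows = []
    for k, z in enumerate(fit.entities):
        row = {"entity": z, "n_z": int(n_z.get(z, 0)) if n_z is not None else 0}
        for col in PSEUDO_COLUMNS:
            row[col.replace("pseudo_", "")] = float(fit.predict(col, design)[:, k].mean())
        rows.append(row)
    return _finalize(pd.DataFrame(rows), tau_days, "or")


def dr_estimates(pseudo: pd.DataFrame, propensity: PropensityFit, fit: OutcomeFit,
                 design: DesignMatrix, entity_labels, tau_days: float) -> pd.DataFrame:
    """Augmented IPW: g-computation plus weighted residual correction."""
    labels = np.asarray(entity_labels)
    propensity.check_positivity(labels)
    n = len(labels)
    rows = []
    for z in fit.entities:
        k = int(np.where(fit.entities == z)[0][0])
        in_z = (labels == z).astype(float)
        e_z = propensity.probs[z].to_numpy()
        row = {"entity": z, "n_z": int(in_z.sum())}
        for col in PSEUDO_COLUMNS:
            m_hat = fit.predict(col, design)[:, k]
            p = pseudo[col].to_numpy(dtype=float)
            aug = in_z / e_z * (p - m_hat) + m_hat
            row[col.replace("pseudo_", "")] = float(aug.sum() / n)
        rows.append(row)
    return _finalize(pd.DataFrame(rows), tau_days, "dr")


def center_estimates(estimates: pd.DataFrame) -> pd.DataFrame:
    """Add centered columns: estimate minus the unweighted mean across
    entities (the overall risk-adjusted reference).  Centered values sum
    to zero exactly."""
    out = estimates.copy()
    for col in ("rmtl_noncompliance", "rmtl_competing", "rmst"):
        if col in out:
            out[f"centered_{col}"] = out[col] - out[col].mean()
    return out
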