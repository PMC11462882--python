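"""Synthetic claims cohorts with known standardized estimands.

The generator emulates the structure of social-insurance claims used for
medication-persistence profiling: a patients table with entity (region)
assignment and baseline confounders, a prescription-fill stream with
days-supplied, optional hospital stays, terminal events (death / recurrent
index event), and administrative censoring.

Data-generating model
---------------------
Confounders X are drawn i.i.d. per patient.  Entity membership follows a
multinomial logit whose linear predictor is an entity loading u_z (an
equispaced grid on [-1, 1]) times a scalar confounder score s(X); this
creates measured confounding between entities and outcomes.  The latent
time to therapy cessation is exponential with hazard

    h1(X, z) = cessation_hazard * exp(entity_effect[z] + b' X_std),

the competing time (death or recurrent event) exponential with constant
hazard h2 = competing_hazard, both rounded up to whole days.  The fill
stream is then constructed so that the episode builder's supply-pooling
sweep exhausts exactly on the latent cessation day: back-to-back fills up
to the cessation day, then no further fills.  This separates generator
correctness from builder correctness and makes latent-time recovery exact.

The standardized estimands (the average potential outcome had the whole
population been assigned to entity z) are produced by an oracle that is
independent of the claims/episode path: it draws confounders afresh and
evaluates the conditional restricted means *exactly* in time (geometric
sums over whole days, including the grace-window interaction between
cessation and competing events), so Monte-Carlo error comes only from the
confounder draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Confounder:
    """One baseline covariate with its distribution and effect sizes.

    ``entity_coef`` multiplies the standardized covariate in the scalar
    confounder score driving entity assignment; ``outcome_coef`` is its
    coefficient on the log cessation hazard.  ``dist`` is one of
    ``normal`` (params mean, sd), ``bernoulli`` (param p), ``categorical``
    (params levels, probs; must carry zero effects).
    """

    name: str
    dist: str
    params: tuple
    entity_coef: float = 0.0
    outcome_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.dist not in ("normal", "bernoulli", "categorical"):
            raise ValueError(f"unknown distribution {self.dist!r}")
        if self.dist == "categorical" and (self.entity_coef or self.outcome_coef):
            raise ValueError("categorical confounders must have zero effects")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "normal":
            mean, sd = self.params
            return rng.normal(mean, sd, n)
        if self.dist == "bernoulli":
            (p,) = self.params
            return (rng.random(n) < p).astype(float)
        levels, probs = self.params
        return rng.choice(np.asarray(levels), size=n, p=np.asarray(probs, dtype=float))

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Center and scale by the *theoretical* moments so that effect
        sizes (and hence the ground truth) do not depend on the sample."""
        if self.dist == "normal":
            mean, sd = self.params
            return (np.asarray(x, float) - mean) / sd
        if self.dist == "bernoulli":
            (p,) = self.params
            return (np.asarray(x, float) - p) / math.sqrt(p * (1 - p))
        return np.zeros(len(x))


def default_confounders() -> list[Confounder]:
    """Scaled-down stand-in for a rich administrative confounder set:
    age, sex, index year, and ten binary comorbidity/co-medication flags."""
    out = [
        Confounder("age", "normal", (68.0, 14.0), entity_coef=0.5, outcome_coef=0.35),
        Confounder("sex_female", "bernoulli", (0.36,), entity_coef=0.35, outcome_coef=-0.25),
        Confounder("index_year", "categorical",
                   ((2012, 2013, 2014, 2015), (0.25, 0.25, 0.25, 0.25))),
    ]
    prevalences = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.12)
    for k, p in enumerate(prevalences, start=1):
        sign = 1.0 if k % 2 else -1.0
        out.append(Confounder(f"cf_{k:02d}", "bernoulli", (p,),
                              entity_coef=sign * 0.25, outcome_coef=sign * 0.20))
    return out


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    Baseline hazards are per day.  The defaults reproduce headline
    magnitudes typical of post-infarction statin persistence over 12
    months: roughly half the restricted time lost to nonadherence and a
    tenth of patients hit by a competing event.
    """

    n_patients: int
    n_entities: int
    seed: int
    tau_days: int = 365
    cessation_hazard: float = 0.0055
    competing_hazard: float = 0.0011
    entity_effect_vector: tuple[float, ...] | None = None
    confounders: tuple[Confounder, ...] = field(default_factory=lambda: tuple(default_confounders()))
    censor_day_range: tuple[int, int] = (420, 1095)
    grace_days: int = 30
    fill_interval_days: int = 30
    stay_rate: float = 0.0  # expected hospital stays per patient
    death_share: float = 0.7  # competing events split death vs recurrent

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_entities < 2:
            raise ValueError("need at least 2 entities")
        if self.tau_days <= 0:
            raise ValueError("tau_days must be positive")
        if self.cessation_hazard < 0 or self.competing_hazard < 0 or self.stay_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.grace_days < 0 or self.fill_interval_days <= 0:
            raise ValueError("invalid grace/fill interval")
        lo, hi = self.censor_day_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid censor_day_range")
        names = [c.name for c in self.confounders]
        if len(set(names)) != len(names):
            raise ValueError("duplicate confounder names")
        if self.entity_effect_vector is not None and len(self.entity_effect_vector) != self.n_entities:
            raise ValueError("entity_effect_vector length must equal n_entities")

    @property
    def entity_effects(self) -> np.ndarray:
        if self.entity_effect_vector is None:
            return np.zeros(self.n_entities)
        return np.asarray(self.entity_effect_vector, dtype=float)

    @property
    def entity_loadings(self) -> np.ndarray:
        return np.linspace(-1.0, 1.0, self.n_entities)


@dataclass
class ClaimsBundle:
    """The four relational claims tables plus cohort metadata.

    ``latent`` carries simulation-only diagnostics (latent day of
    cessation/competing event, true propensities); it is absent for
    real-shaped data read from disk.
    """

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    stays: pd.DataFrame
    terminal_events: pd.DataFrame
    meta: dict = field(default_factory=dict)
    latent: pd.DataFrame | None = None


@dataclass
class GroundTruth:
    """Per-entity standardized restricted means of the generating model."""

    entities: np.ndarray
    standardized_rmtl_noncompliance: np.ndarray
    standardized_rmtl_competing: np.ndarray
    standardized_rmst: np.ndarray
    mc_se: np.ndarray  # per-entity MC s.e. of the noncompliance RMTL
    method: str = "oracle_mc"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "entity": self.entities,
            "rmtl_noncompliance": self.standardized_rmtl_noncompliance,
            "rmtl_competing": self.standardized_rmtl_competing,
            "rmst": self.standardized_rmst,
            "mc_se": self.mc_se,
        })


# ---------------------------------------------------------------------------
# confounder machinery
# ---------------------------------------------------------------------------

def _draw_confounders(cfg: SimConfig, rng: np.random.Generator, n: int):
    raw = {}
    score = np.zeros(n)
    outcome_lp = np.zeros(n)
    for c in cfg.confounders:
        x = c.draw(rng, n)
        raw[c.name] = x
        if c.entity_coef or c.outcome_coef:
            xs = c.standardize(x)
            score += c.entity_coef * xs
            outcome_lp += c.outcome_coef * xs
    return raw, score, outcome_lp


def _entity_probs(cfg: SimConfig, score: np.ndarray) -> np.ndarray:
    eta = np.outer(score, cfg.entity_loadings)  # n x m
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# exact-in-time conditional restricted means (shared by the oracle)
# ---------------------------------------------------------------------------

def _geom_sums(r: np.ndarray, a: int, b: int):
    """(sum_{y=a}^{b} r^{y-1}, sum_{y=a}^{b} y r^{y-1}) with the r -> 1 limit."""
    if b < a:
        z = np.zeros_like(r)
        return z, z
    r = np.asarray(r, dtype=float)
    near1 = np.isclose(r, 1.0, atol=1e-12)
    rs = np.where(near1, 0.5, r)  # placeholder to avoid 0/0
    g0 = (rs ** (a - 1) - rs**b) / (1.0 - rs)
    # sum y r^{y-1} over [a, b] via the antiderivative of the geometric tail
    def s1_upto(m):  # sum_{y=1}^{m} y r^{y-1}
        return (1 - (m + 1) * rs**m + m * rs ** (m + 1)) / (1 - rs) ** 2
    g1 = s1_upto(b) - s1_upto(a - 1)
    count = b - a + 1
    g0 = np.where(near1, float(count), g0)
    g1 = np.where(near1, (a + b) * count / 2.0, g1)
    return g0, g1


def _conditional_restricted_means(h1, h2, tau: int, grace: int):
    """E[(tau - Y) 1{D=j}] and E[min(Y, tau)] given daily hazards.

    Whole-day mechanism: cessation day L1 = ceil(Exp(h1)), competing day
    L2 = ceil(Exp(h2)).  Cessation counts (D=1, Y=L1) only when the whole
    grace window is competing-free (L1 + grace < L2); otherwise the
    competing event is recorded (D=2, Y=L2).  This mirrors the episode
    builder exactly, including same-day ties going to the competing event.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.broadcast_to(np.asarray(h2, dtype=float), h1.shape)
    r1 = np.exp(-h1)
    r2 = np.exp(-h2)
    r12 = r1 * r2

    # D=1: P(Y=y, D=1) = (1-r1) r2^{grace+1} (r1 r2)^{y-1}
    g0, g1 = _geom_sums(r12, 1, tau)
    rmtl1 = (1.0 - r1) * r2 ** (grace + 1) * (tau * g0 - g1)

    # D=2, early part y <= grace+1: P = (1-r2) r2^{y-1}
    b_early = min(grace + 1, tau)
    g0e, g1e = _geom_sums(r2, 1, b_early)
    early = (1.0 - r2) * (tau * g0e - g1e)
    # D=2, late part y >= grace+2: P = (1-r2) r1^{y-grace-1} r2^{y-1}
    g0l, g1l = _geom_sums(r12, grace + 2, tau)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(r1 > 0, r1 ** (-float(grace)), 0.0)
    late = (1.0 - r2) * scale * (tau * g0l - g1l)
    late = np.where(g0l > 0, late, 0.0)
    rmtl2 = early + late

    rmst = tau - rmtl1 - rmtl2
    return rmst, rmtl1, rmtl2


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def generate_population(config: SimConfig) -> ClaimsBundle:
    """Draw a full synthetic claims bundle with referential integrity."""
    rng = np.random.default_rng(config.seed)
    n, m, tau = config.n_patients, config.n_entities, config.tau_days

    raw, score, outcome_lp = _draw_confounders(config, rng, n)
    probs = _entity_probs(config, score)
    u = rng.random(n)
    entity = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)

    h1 = config.cessation_hazard * np.exp(config.entity_effects[entity] + outcome_lp)
    with np.errstate(divide="ignore"):
        t1 = np.where(h1 > 0, rng.exponential(1.0, n) / np.where(h1 > 0, h1, 1.0), np.inf)
        h2 = config.competing_hazard
        t2 = np.where(h2 > 0, rng.exponential(1.0, n) / max(h2, 1e-300), np.inf)
    L1 = np.where(np.isfinite(t1), np.ceil(t1), np.inf)
    L2 = np.where(np.isfinite(t2), np.ceil(t2), np.inf)

    lo, hi = config.censor_day_range
    censor = rng.integers(lo, hi + 1, n)

    patients = pd.DataFrame({
        "patient_id": np.arange(n, dtype=np.int64),
        "entity_id": entity.astype(np.int64),
        "age": np.round(raw["age"], 1) if "age" in raw else np.nan,
        "sex": np.where(raw.get("sex_female", np.zeros(n)) > 0, "F", "M"),
        "index_year": raw.get("index_year", np.full(n, 2012)).astype(int),
        "discharge_day": np.zeros(n, dtype=int),
        "censor_day": censor.astype(np.int64),
    })
    for c in config.confounders:
        if c.name.startswith("cf_"):
            patients[c.name] = raw[c.name].astype(int)

    prescriptions = _build_fill_stream(config, L1, L2, censor)
    stays = _build_stays(config, rng, censor)
    terminal = _build_terminal_events(config, rng, L2, censor)

    latent = pd.DataFrame({
        "patient_id": patients["patient_id"],
        "entity_id": entity,
        "latent_cessation_day": L1,
        "latent_competing_day": L2,
        "outcome_lp": outcome_lp,
        "confounder_score": score,
    })
    for z in range(m):
        latent[f"propensity_{z}"] = probs[:, z]

    meta = {"tau_days": tau, "grace_days": config.grace_days, "seed": config.seed,
            "n_entities": m}
    return ClaimsBundle(patients, prescriptions, stays, terminal, meta, latent)


def _build_fill_stream(config: SimConfig, L1, L2, censor) -> pd.DataFrame:
    """Back-to-back fills whose pooled supply exhausts exactly on the
    latent cessation day; no fills are observable after death/censoring."""
    step = config.fill_interval_days
    pids, days, sizes = [], [], []
    for i, (l1, l2, c) in enumerate(zip(L1, L2, censor)):
        observable_end = min(l2, float(c))  # fills exist strictly before this day
        total = l1  # pooled days supplied should equal the latent cessation day
        day = 0
        while day < total and day < observable_end:
            supply = min(step, total - day)
            pids.append(i)
            days.append(int(day))
            sizes.append(float(supply))
            day += step
    return pd.DataFrame({
        "patient_id": np.array(pids, dtype=np.int64),
        "fill_day": np.array(days, dtype=np.int64),
        "n_packages": np.ones(len(pids), dtype=np.int64),
        "package_size": np.array(sizes),
        "dose_per_unit": np.ones(len(pids)),
        "daily_dose": np.ones(len(pids)),
    })


def _build_stays(config: SimConfig, rng: np.random.Generator, censor) -> pd.DataFrame:
    """Optional hospital stays, independent of outcomes; they exist solely
    to exercise the inpatient no-consumption/tolerance rules."""
    n = len(censor)
    counts = rng.poisson(config.stay_rate, n)
    pids, admits, discharges = [], [], []
    for i, k in enumerate(counts):
        for _ in range(int(k)):
            a = int(rng.integers(1, max(int(censor[i]) - 1, 2)))
            length = int(rng.integers(1, 11))
            pids.append(i)
            admits.append(a)
            discharges.append(a + length)
    return pd.DataFrame({
        "patient_id": np.array(pids, dtype=np.int64),
        "admit_day": np.array(admits, dtype=np.int64),
        "discharge_day": np.array(discharges, dtype=np.int64),
    })


def _build_terminal_events(config: SimConfig, rng: np.random.Generator, L2, censor) -> pd.DataFrame:
    """Death / recurrent-event rows for competing days inside the data
    window; the death-vs-recurrent split is cosmetic (both are pooled as a
    single competing cause downstream)."""
    obs = np.isfinite(L2) & (L2 <= censor)
    idx = np.where(obs)[0]
    types = np.where(rng.random(idx.size) < config.death_share, "death", "recurrent")
    return pd.DataFrame({
        "patient_id": idx.astype(np.int64),
        "event_day": L2[idx].astype(np.int64),
        "event_type": types,
    })


def true_standardized_estimands(
    config: SimConfig,
    n_mc: int = 500_000,
    seed: int | None = None,
    method: str = "oracle_mc",
) -> GroundTruth:
    """Standardized per-entity restricted means of the generating model.

    Every draw of the confounder population is counterfactually assigned
    to each entity in turn; the conditional restricted means given the
    hazards are evaluated exactly in time, so only the confounder draw
    contributes Monte-Carlo error (reported as ``mc_se``).  With no
    confounder effects on the outcome the result is closed-form exact
    (``method='closed_form'``).
    """
    m, tau, grace = config.n_entities, config.tau_days, config.grace_days
    has_outcome_conf = any(c.outcome_coef for c in config.confounders)
    if method == "closed_form":
        if has_outcome_conf:
            raise ValueError("closed_form oracle requires zero confounder->outcome effects")
        outcome_lp = np.zeros(1)
    elif method == "oracle_mc":
        rng = np.random.default_rng(config.seed + 1_000_003 if seed is None else seed)
        _, _, outcome_lp = _draw_confounders(config, rng, n_mc)
    else:
        raise ValueError(f"unknown oracle method {method!r}")

    rmst = np.empty(m)
    rmtl1 = np.empty(m)
    rmtl2 = np.empty(m)
    se = np.empty(m)
    for z in range(m):
        h1 = config.cessation_hazard * np.exp(config.entity_effects[z] + outcome_lp)
        s, l1, l2 = _conditional_restricted_means(h1, config.competing_hazard, tau, grace)
        rmst[z] = s.mean()
        rmtl1[z] = l1.mean()
        rmtl2[z] = l2.mean()
        se[z] = l1.std(ddof=1) / math.sqrt(l1.size) if l1.size > 1 else 0.0
    return GroundTruth(np.arange(m), rmtl1, rmtl2, rmst, se, method=method)


def true_conditional_means(config: SimConfig, outcome_lp: np.ndarray) -> dict[str, np.ndarray]:
    """True conditional restricted means m(X, z) for given confounder linear
    predictors: one (n, m_entities) array per functional.  These are the
    oracle regression surfaces; feeding them to an outcome model as
    features yields an exactly specified model in simulation studies."""
    lp = np.asarray(outcome_lp, dtype=float)
    m = config.n_entities
    out = {k: np.empty((lp.size, m)) for k in ("rmst", "rmtl_noncompliance", "rmtl_competing")}
    for z in range(m):
        h1 = config.cessation_hazard * np.exp(config.entity_effects[z] + lp)
        s, l1, l2 = _conditional_restricted_means(h1, config.competing_hazard,
                                                  config.tau_days, config.grace_days)
        out["rmst"][:, z] = s
        out["rmtl_noncompliance"][:, z] = l1
        out["rmtl_competing"][:, z] = l2
    return out


def latent_episodes(bundle: ClaimsBundle, tau_days: int, grace_days: int) -> pd.DataFrame:
    """Episode table derived directly from the latent times (bypassing the
    claims tables); used for fast simulation studies once the episode
    builder's exact recovery has been established separately."""
    if bundle.latent is None:
        raise ValueError("bundle has no latent diagnostics")
    lat = bundle.latent
    L1 = lat["latent_cessation_day"].to_numpy()
    L2 = lat["latent_competing_day"].to_numpy()
    censor = bundle.patients["censor_day"].to_numpy()
    nc = (L1 + grace_days < np.minimum(L2, censor)) & (L1 < tau_days)
    comp = ~nc & (L2 <= censor) & (L2 < tau_days)
    time = np.where(nc, L1, np.where(comp, L2, np.minimum(censor, tau_days)))
    status = np.where(nc, "noncompliance", np.where(comp, "competing", "censored"))
    return pd.DataFrame({
        "patient_id": bundle.patients["patient_id"],
        "time_days": time.astype(int),
        "status": status,
        "entity": bundle.patients["entity_id"],
    })
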