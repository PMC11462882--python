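"""End-to-end orchestration: claims tables (real-shaped or synthetic) to
estimate/interval reports.

All randomness flows from one seed through named substreams (simulation,
CV folds, bootstrap), so a run is reproducible byte-for-byte.  The
bootstrap resamples patients and re-runs the whole estimation path per
replicate -- design-matrix construction (spline knots re-estimated),
pseudo-values, propensity refit, and standardization; episode
construction is per-patient deterministic, so resampling the per-patient
episode rows is equivalent to rebuilding episodes from resampled claims.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust, bootstrap as bst, comparators, io, pseudo, survival
from .episodes import EpisodeParams, build_cohort_episodes
from .simulate import ClaimsBundle, SimConfig, generate_population, true_standardized_estimands

KNOWN_ESTIMATORS = ("unadjusted", "iptw", "or", "dr")


@dataclass
class PipelineConfig:
    """Everything a run needs; accepted as a YAML/JSON mapping by the CLI."""

    seed: int
    input_dir: str | None = None          # read the four CSVs from here ...
    simulate: dict | None = None          # ... or generate a synthetic cohort
    tau_days: int = 365
    grace_days: int = 30
    inpatient_tolerance_days: int = 2
    event_time: str = "exhaustion"
    estimators: tuple[str, ...] = ("unadjusted", "iptw", "or", "dr")
    bootstrap_reps: int = 250
    family_level: float = 0.95
    folds: int = 10
    spline_df: int = 4
    fixed_lambda: float | None = None     # skip per-replicate CV when set
    min_entity_size: int = 10

    def __post_init__(self) -> None:
        unknown = set(self.estimators) - set(KNOWN_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimator name(s): {sorted(unknown)}; "
                             f"expected a subset of {KNOWN_ESTIMATORS}")
        if (self.input_dir is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of input_dir / simulate")
        if self.bootstrap_reps < 0 or self.folds < 2:
            raise ValueError("invalid bootstrap_reps or folds")


def _substream_seeds(seed: int, n: int = 3) -> list[int]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31 - 1)) for c in children]


def _analysis_frame(bundle: ClaimsBundle, params: EpisodeParams) -> pd.DataFrame:
    """Per-patient row joining the episode with baseline covariates; the
    resampling unit of the bootstrap."""
    episodes = build_cohort_episodes(bundle, params)
    covars = bundle.patients.drop(columns=["discharge_day"], errors="ignore")
    return episodes.merge(covars, on="patient_id", validate="1:1")


def _estimate_once(frame: pd.DataFrame, cfg: PipelineConfig, ps_seed: int,
                   estimators: tuple[str, ...], lambda_override: float | None = None):
    """All requested standardized estimates from one analysis frame."""
    out = []
    pseudo_mat = None
    design = None
    labels = frame["entity"].to_numpy()
    if "unadjusted" in estimators:
        out.append(adjust.unadjusted_estimates(frame, cfg.tau_days))
    needs_model = set(estimators) & {"iptw", "or", "dr"}
    prop = fit = None
    if needs_model:
        pseudo_mat = pseudo.pseudo_matrix(frame, cfg.tau_days,
                                          min_entity_size=cfg.min_entity_size)
        design = adjust.build_design_matrix(frame, spline_df=cfg.spline_df)
        if {"iptw", "dr"} & needs_model:
            lam = lambda_override if lambda_override is not None else cfg.fixed_lambda
            if lam is not None:
                prop = adjust.fit_propensity_fixed(design, labels, lam)
            else:
                prop = adjust.fit_propensity_ridge(design, labels,
                                                   n_folds=cfg.folds, seed=ps_seed)
        if {"or", "dr"} & needs_model:
            fit = adjust.fit_outcome_model(pseudo_mat, design, labels)
    if "iptw" in estimators:
        out.append(adjust.iptw_estimates(pseudo_mat, prop, labels, cfg.tau_days))
    if "or" in estimators:
        n_z = frame["entity"].value_counts()
        out.append(adjust.gcomp_estimates(fit, design, cfg.tau_days, n_z))
    if "dr" in estimators:
        out.append(adjust.dr_estimates(pseudo_mat, prop, fit, design, labels, cfg.tau_days))
    est = pd.concat([adjust.center_estimates(e) for e in out], ignore_index=True)
    return est, pseudo_mat, prop


def _comparator_table(frame: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for z, grp in frame.groupby("entity", sort=True):
        try:
            binom = comparators.binomial_compliance(grp, cfg.tau_days)
        except ValueError:
            binom = {"estimate": np.nan, "lower": np.nan, "upper": np.nan, "n": 0}
        inten = comparators.poisson_intensity(grp, cfg.tau_days)
        km = comparators.km_compliance_prob(grp, cfg.tau_days)
        rmst_z = survival.restricted_means(grp, cfg.tau_days)["rmst"]
        rows.append({
            "entity": z,
            "binomial_compliance": binom["estimate"],
            "binomial_lower": binom["lower"], "binomial_upper": binom["upper"],
            "compliance_intensity": inten["estimate"],
            "km_compliance_prob": km,
            "rmst_days": rmst_z,
            "rmst_fraction_pct": comparators.rmst_fraction(rmst_z, cfg.tau_days),
        })
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> Path:
    """Run the full analysis and write all report CSVs; returns outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed, ps_seed, boot_seed = _substream_seeds(cfg.seed)

    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", sim_seed)
        sim_cfg = SimConfig(**sim_kwargs)
        bundle = generate_population(sim_cfg)
        truth = true_standardized_estimands(sim_cfg)
        truth.as_frame().to_csv(outdir / "ground_truth.csv", index=False)
        io.write_bundle(bundle, outdir / "tables")
    else:
        problems = io.validate_tables(cfg.input_dir)
        if problems:
            raise ValueError("input validation failed:\n" + "\n".join(problems))
        bundle = io.read_bundle(cfg.input_dir)

    params = EpisodeParams(cfg.tau_days, cfg.grace_days,
                           cfg.inpatient_tolerance_days, cfg.event_time)
    frame = _analysis_frame(bundle, params)
    frame[["patient_id", "time_days", "status", "entity"]].to_csv(
        outdir / "episodes.csv", index=False)

    estimates, pseudo_mat, prop = _estimate_once(frame, cfg, ps_seed, cfg.estimators)
    _months(estimates).to_csv(outdir / "estimates.csv", index=False)
    if pseudo_mat is not None:
        pseudo_mat.to_csv(outdir / "pseudo_values.csv", index=False)
    if prop is not None:
        prop.diagnostics().rename_axis("entity").to_csv(outdir / "propensity_diagnostics.csv")
    _comparator_table(frame, cfg).to_csv(outdir / "comparators.csv", index=False)

    if cfg.bootstrap_reps > 0:
        lam = cfg.fixed_lambda  # None -> honest per-replicate CV re-selection
        intervals = []
        for name in cfg.estimators:
            def one(f, _name=name):
                est, _, _ = _estimate_once(f.reset_index(drop=True), cfg, ps_seed,
                                           (_name,), lambda_override=lam)
                return est
            res = bst.bootstrap_estimates(
                frame, one, B=cfg.bootstrap_reps, seed=boot_seed,
                family_level=cfg.family_level,
                value_columns=("rmtl_noncompliance", "rmtl_competing", "rmst",
                               "centered_rmtl_noncompliance"),
            )
            iv = res.intervals
            iv["estimator"] = name
            intervals.append(iv)
        pd.concat(intervals, ignore_index=True).to_csv(outdir / "intervals.csv", index=False)

    meta = {
        "seed": cfg.seed,
        "substreams": {"simulation": sim_seed, "cv_folds": ps_seed, "bootstrap": boot_seed},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_patients": int(len(frame)),
        "n_entities": int(frame["entity"].nunique()),
        "selected_lambda": None if prop is None else prop.lambda_,
    }
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return outdir


def _months(estimates: pd.DataFrame) -> pd.DataFrame:
    """Report both days and months (days x 12/365)."""
    out = estimates.copy()
    for col in list(out.columns):
        if col.startswith(("rmtl", "rmst", "centered_")):
            out[col + "_months"] = out[col] * 12.0 / 365.0
    return out
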