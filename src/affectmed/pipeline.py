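"""End-to-end orchestration: simulate -> QC -> preprocess -> scale ->
manipulation check -> mediation, from one config, with a reproducible
report of Table-1-style descriptives.

Artifacts are JSON for machine consumption, CSV for tables and a single
Markdown report for humans; every artifact carries the config hash so a
run can be tied to its exact configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .factor import build_disruption_scale
from .mediation import (
    DEFAULT_COVARIATES,
    BootstrapSpec,
    indirect_contrast,
    prepare_analysis_frame,
    total_effect,
    wild_bootstrap_mediation,
)
from .mixed import fit_rating_lmm, trials_to_long
from .preprocessing import boxcox_apply, boxcox_lambda, transform_mediators
from .screening import apply_exclusions
from .synthetic import CONDITIONS, SCALES, StudyConfig, generate_study, write_study


@dataclass
class RunConfig:
    """One pipeline run: study generation parameters, stage thresholds,
    bootstrap settings and a master seed."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    study: dict = field(default_factory=dict)     # StudyConfig overrides
    sd_cutoff: float = 10.0
    attention_tolerance: float = 0.0
    loading_threshold: float = 0.5
    boxcox_shift: float = 1.0
    lambda_grid: tuple = (-2.0, 2.0)
    grid_step: float = 0.01
    tukey_k: float = 3.0
    bootstrap: dict = field(default_factory=lambda: {"n_iterations": 10_000})
    stages: dict = field(default_factory=dict)    # stage name -> bool
    mancheck_transform: bool = True

    def validate(self) -> None:
        if self.sd_cutoff < 0 or self.tukey_k <= 0:
            raise ValueError("thresholds out of bounds")
        if not 0.0 < self.loading_threshold < 1.0:
            raise ValueError("loading_threshold must be in (0, 1)")
        lo, hi = self.lambda_grid
        if not lo < hi:
            raise ValueError("lambda_grid must be (low, high) with low < high")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_grid"] = list(self.lambda_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "lambda_grid" in d:
            d["lambda_grid"] = tuple(d["lambda_grid"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def content_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def study_analysis_frame(
    study,
    mediator_cols=None,
    loading_threshold: float = 0.5,
    boxcox_shift: float = 1.0,
) -> pd.DataFrame:
    """Build the person-level analysis frame for a (clean) study without
    running the QC stage: condition means, Box-Cox on the requested
    mediators (all 12 by default), disruption scoring, covariate merge.

    Useful for simulation studies where screening is known to be a no-op
    and only a subset of mediators is analysed.
    """
    from .preprocessing import MEDIATOR_COLS, BoxCoxNormalizer, condition_means

    cols = list(mediator_cols) if mediator_cols is not None else list(MEDIATOR_COLS)
    wide = condition_means(study.trials)
    norm = BoxCoxNormalizer(shift=boxcox_shift)
    transformed = norm.fit_transform(wide[cols])
    mediators = pd.concat([wide[["participant_id"]], transformed], axis=1)
    items = study.participants[[f"item_{j}" for j in range(1, 11)]]
    scores, _, _ = build_disruption_scale(items, loading_threshold)
    return prepare_analysis_frame(study.participants, mediators, scores)


def _stage_on(config: RunConfig, name: str) -> bool:
    return bool(config.stages.get(name, True))


def descriptives(participants: pd.DataFrame, scores=None) -> pd.DataFrame:
    """Sample descriptives: n/mean/SD/min/median/max for continuous
    variables, counts and percentages for categoricals."""
    if len(participants) == 0:
        raise ValueError("empty sample")
    rows = []
    cont = {"age": participants["age"]}
    if scores is not None:
        cont["pandemic_disruption"] = pd.Series(np.asarray(scores, dtype=float))
    for name, v in cont.items():
        v = v.astype(float)
        rows.append({
            "variable": name, "level": "", "n": int(v.notna().sum()),
            "percent": np.nan, "mean": v.mean(), "sd": v.std(ddof=1),
            "min": v.min(), "median": v.median(), "max": v.max(),
        })
    cats = {
        "gender_female": participants.get("gender_female"),
        "race_nonwhite": participants.get("race_nonwhite"),
        "ethnicity_hispanic": participants.get("ethnicity_hispanic"),
        "income": participants.get("income"),
        "education": participants.get("education"),
        "diagnosed": participants.get("diagnosed"),
        "image_set": participants.get("image_set"),
    }
    n_total = len(participants)
    for name, v in cats.items():
        if v is None:
            continue
        counts = v.value_counts().sort_index()
        for level, cnt in counts.items():
            rows.append({
                "variable": name, "level": str(level), "n": int(cnt),
                "percent": 100.0 * cnt / n_total, "mean": np.nan, "sd": np.nan,
                "min": np.nan, "median": np.nan, "max": np.nan,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write all artifacts under
    ``config.out_dir``.  Returns the run report as a dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.content_hash()
    report: dict = {"config_hash": chash, "seed": config.seed}

    # --- simulate -----------------------------------------------------
    study_kwargs = dict(config.study)
    study_kwargs.setdefault("seed", config.seed)
    sconfig = StudyConfig(**study_kwargs)
    study = generate_study(sconfig)
    if _stage_on(config, "simulate"):
        write_study(study, out)

    # --- qc -----------------------------------------------------------
    retained, excl = apply_exclusions(
        study.participants, study.trials, study.attention,
        sd_cutoff=config.sd_cutoff,
        attention_tolerance=config.attention_tolerance,
    )
    excl.to_json(out / "exclusion_report.json")
    report["exclusions"] = dict(excl.__dict__, excluded_ids_by_step=None)
    kept_ids = set(retained["participant_id"])
    trials = study.trials[study.trials["participant_id"].isin(kept_ids)].reset_index(drop=True)
    retained = retained.sort_values("participant_id").reset_index(drop=True)

    # --- preprocess ---------------------------------------------------
    mediators, lam_table = transform_mediators(
        trials, shift=config.boxcox_shift, lambda_grid=config.lambda_grid,
        grid_step=config.grid_step,
        n_trials_per_condition=sconfig.n_trials_per_condition,
    )
    mediators.to_csv(out / "mediators.csv", index=False)
    lam_table.to_csv(out / "lambda_table.csv", index=False)
    report["boxcox_lambdas"] = dict(zip(lam_table["mediator"], lam_table["lambda"]))

    # --- disruption scale ---------------------------------------------
    items = retained[[f"item_{j}" for j in range(1, 11)]]
    scores, first_fit, refit = build_disruption_scale(items, config.loading_threshold)
    factor_out = {
        "eigenvalues": list(map(float, first_fit.eigenvalues)),
        "reduced_eigenvalues": list(map(float, first_fit.reduced_eigenvalues)),
        "loadings": list(map(float, first_fit.loadings)),
        "retained_items": [int(i) for i in refit.retained_items],
        "refit_eigenvalues": list(map(float, refit.eigenvalues)),
        "refit_reduced_eigenvalues": list(map(float, refit.reduced_eigenvalues)),
        "refit_loadings": list(map(float, refit.loadings)),
        "fit_method": "minres",
        "config_hash": chash,
    }
    (out / "factor_solution.json").write_text(json.dumps(factor_out, indent=2))
    pd.DataFrame({
        "participant_id": retained["participant_id"], "disruption": scores,
    }).to_csv(out / "disruption_scores.csv", index=False)
    report["factor"] = {
        "first_eigenvalue": factor_out["eigenvalues"][0],
        "second_eigenvalue": factor_out["eigenvalues"][1],
        "n_retained_items": len(refit.retained_items),
    }

    # --- manipulation check -------------------------------------------
    mancheck: dict = {}
    if _stage_on(config, "mancheck"):
        for scale in SCALES:
            long = trials_to_long(trials, scale)
            if config.mancheck_transform:
                fit = boxcox_lambda(long["rating"].to_numpy(), grid=config.lambda_grid,
                                    grid_step=config.grid_step, shift=config.boxcox_shift)
                long = long.assign(
                    rating=boxcox_apply(long["rating"].to_numpy(), fit.lam, fit.shift)
                )
            res = fit_rating_lmm(long, reference="neutral")
            mancheck[scale] = {
                "fixed_effects": res.fixed_effects,
                "random_intercept_variance": res.random_intercept_variance,
                "residual_variance": res.residual_variance,
                "n_obs": res.n_obs,
                "n_participants": res.n_participants,
            }
        (out / "manipulation_check.json").write_text(
            json.dumps({"config_hash": chash, "models": mancheck}, indent=2)
        )
    report["manipulation_check"] = mancheck

    # --- mediation ----------------------------------------------------
    mediation_rows = []
    contrasts = []
    totals = {}
    if _stage_on(config, "mediate"):
        spec = BootstrapSpec(seed=config.seed, **config.bootstrap)
        frame = prepare_analysis_frame(retained, mediators, scores)
        for cond in CONDITIONS:
            for scale in SCALES:
                res = wild_bootstrap_mediation(frame, f"{scale}_{cond}", spec)
                mediation_rows.append(res.to_dict())
        for scale in ("disgust", "sickness"):
            for c1, c2 in (("neutral", "infection"), ("neutral", "harm"),
                           ("infection", "harm")):
                con = indirect_contrast(frame, f"{scale}_{c1}", f"{scale}_{c2}", spec)
                contrasts.append({
                    "mediator_1": con.mediator_1, "mediator_2": con.mediator_2,
                    "difference": con.difference, "ci_low": con.ci95[0],
                    "ci_high": con.ci95[1], "r2_difference": con.r2_difference,
                    "significant": con.significant,
                })
        for label, with_cov in (("with_covariates", True), ("without_covariates", False)):
            est, ci = total_effect(frame, with_covariates=with_cov, spec=spec)
            totals[label] = {"beta": est.beta, "ci_low": ci[0], "ci_high": ci[1]}
        med_table = pd.DataFrame(mediation_rows)
        med_table.to_csv(out / "mediation_table.csv", index=False)
        (out / "mediation_results.json").write_text(json.dumps({
            "config_hash": chash,
            "n_tests": len(mediation_rows),
            "covariates": list(DEFAULT_COVARIATES),
            "standardization": "continuous z-scored on analysis sample; 0/1 dummies untouched",
            "bootstrap": dataclasses.asdict(spec),
            "mediation": mediation_rows,
            "contrasts": contrasts,
            "total_effects": totals,
        }, indent=2))
    report["mediation"] = mediation_rows
    report["contrasts"] = contrasts
    report["total_effects"] = totals

    # --- descriptives + human report ----------------------------------
    desc = descriptives(retained, scores)
    desc.to_csv(out / "descriptives.csv", index=False)
    report["n_final"] = int(len(retained))
    _write_markdown_report(out / "report.md", config, report, desc)
    (out / "run_report.json").write_text(json.dumps(_jsonable(report), indent=2))
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _write_markdown_report(path: Path, config: RunConfig, report: dict,
                           desc: pd.DataFrame) -> None:
    lines = [
        "# Pipeline run report",
        "",
        f"- config hash: `{report['config_hash']}`",
        f"- master seed: {report['seed']}",
        f"- final sample: {report.get('n_final', 'n/a')}",
        "",
        "## Exclusion cascade",
    ]
    exc = report.get("exclusions", {})
    for key in ("n_enrolled", "n_attention_failed", "n_low_variance",
                "n_unaligned", "n_incomplete_demographics", "n_final"):
        lines.append(f"- {key}: {exc.get(key)}")
    lines += ["", "## Disruption factor"]
    fac = report.get("factor", {})
    lines.append(
        f"- first/second eigenvalue: {fac.get('first_eigenvalue', float('nan')):.3f} / "
        f"{fac.get('second_eigenvalue', float('nan')):.3f}"
    )
    lines.append(f"- items retained: {fac.get('n_retained_items')}")
    med = report.get("mediation", [])
    if med:
        lines += ["", f"## Mediation ({len(med)} tests, no multiplicity correction)", ""]
        lines.append("| mediator | a | b | a*b | 95% CI | sig |")
        lines.append("|---|---|---|---|---|---|")
        for m in med:
            lines.append(
                f"| {m['mediator']} | {m['a_beta']:.3f} | {m['b_beta']:.3f} | "
                f"{m['indirect']:.3f} | [{m['ci_low']:.3f}, {m['ci_high']:.3f}] | "
                f"{'*' if m['significant'] else ''} |"
            )
    lines += ["", "## Descriptives", "", desc.to_string(index=False), ""]
    path.write_text("\n".join(lines))
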