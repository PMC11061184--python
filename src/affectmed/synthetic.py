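"""Synthetic affect-rating studies with known ground truth.

Emulates the statistical structure of an online image-rating experiment:
an unbalanced binary exposure (prior COVID-19 diagnosis, ~18.7% of the
sample), right-skewed bounded 0-100 ratings of three image-type conditions
(neutral, threat-of-infection, threat-of-harm) on four scales (disgust,
fear, sickness risk, harm risk), a 10-item single-factor Likert
questionnaire of pandemic disruption, demographic covariates, and optional
careless/bot responders for exercising the quality-control cascade.

The generative model is a standard latent-variable mediation scheme.  For
participant i, condition c and rating scale s, the person-level reactivity

    Z[i, c, s] = a[c, s] * D[i] + s0 * (sqrt(rho) * G[i]
                                        + sqrt(1 - rho) * eps[i, c, s])

has unit variance (s0 chosen accordingly), where D is the 0/1 diagnosis
indicator, G a shared "general negativity" factor inducing correlation rho
between the 12 condition x scale cells, and a[c, s] the standardized a-path
(mean difference between diagnosis groups in SD units).  Trial ratings are
a lognormal-type link of Z plus condition shifts,

    rating = clip(base * exp(log_scale * (shift[c] + Z)) + trial noise, 0, 100),

which produces the right skew that motivates Box-Cox normalisation
downstream while keeping the person-level condition mean, on the log scale,
affine in Z to good approximation.  The disruption factor is

    F[i] = sum_cs b[c, s] * Z[i, c, s] + gamma' X_std[i] + e[i],

scaled to unit variance, and the 10 Likert items are congeneric indicators
of F (loadings in [0, 1]) discretised to 1..5.  The b[c, s] are structural
weights: with several correlated mediators carrying non-zero weights, the
marginal per-mediator association recovered downstream exceeds the
structural value; recovery tests therefore use single-mediator configs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CONDITIONS = ("neutral", "infection", "harm")
SCALES = ("disgust", "fear", "sickness", "harm_appraisal")

#: covariate columns, in the order matched by ``StudyConfig.covariate_effects``
COVARIATE_COLS = (
    "age",
    "gender_female",
    "race_nonwhite",
    "ethnicity_hispanic",
    "income",
    "education",
)

ATTENTION_TARGETS = (10, 40, 70)

# Final-sample margins of the emulated MTurk study, used as parametric
# stand-ins for the covariate distributions.
_AGE_MEAN, _AGE_SD = 39.57, 11.12
_P_FEMALE = 0.436
_P_NONWHITE = 1.0 - 0.8338
_P_HISPANIC = 0.1117
_INCOME_P = (0.0368, 0.0681, 0.0409, 0.1008, 0.1553, 0.1907, 0.2480, 0.1213, 0.0381)
_EDUCATION_P = (0.0027, 0.1839, 0.1172, 0.5245, 0.1717)

# Likert discretisation thresholds on the unit-variance item latent;
# chosen to give a right-of-centre mean near the observed 3.48 (SD ~0.9).
_ITEM_THRESHOLDS = (-2.0, -1.0, -0.2, 0.8)


def _default_a_paths() -> dict:
    """Standardized diagnosis -> rating effects, in the 0.06-0.20 band
    reported for such studies; disgust-to-infection deliberately weakest."""
    return {
        ("neutral", "disgust"): 0.20,
        ("infection", "disgust"): 0.06,
        ("harm", "disgust"): 0.12,
        ("neutral", "sickness"): 0.15,
        ("infection", "sickness"): 0.09,
        ("harm", "sickness"): 0.12,
        ("neutral", "fear"): 0.19,
        ("infection", "fear"): 0.10,
        ("harm", "fear"): 0.07,
        ("neutral", "harm_appraisal"): 0.12,
        ("infection", "harm_appraisal"): 0.10,
        ("harm", "harm_appraisal"): 0.00,
    }


def _default_b_paths() -> dict:
    # structural weights; marginal per-mediator slopes land near 0.2-0.4
    # once the rho-induced mediator correlation is folded in
    return {(c, s): 0.06 for c in CONDITIONS for s in SCALES}


def _default_item_loadings() -> tuple:
    # nine strong indicators plus one weak item (index 6, "item 7"),
    # mirroring the loading pattern the scale-construction stage must detect
    return (0.72, 0.75, 0.70, 0.74, 0.78, 0.71, 0.43, 0.76, 0.73, 0.70)


def _default_condition_shift() -> dict:
    return {"neutral": 0.0, "harm": 0.7, "infection": 1.2}


@dataclass
class StudyConfig:
    """Parameters of one synthetic study.

    ``a_paths`` / ``b_paths`` map ``(condition, scale)`` to standardized
    effects; ``condition_shift`` maps a condition name (or a
    ``(condition, scale)`` pair for scale-specific orderings) to a latent
    mean shift.  ``covariate_effects`` are standardized effects of the six
    covariates, in ``COVARIATE_COLS`` order, on the disruption factor.
    """

    n_participants: int = 734
    p_diagnosed: float = 0.1866
    a_paths: Mapping = field(default_factory=_default_a_paths)
    b_paths: Mapping = field(default_factory=_default_b_paths)
    covariate_effects: tuple = (-0.05, 0.15, 0.0, 0.0, -0.05, 0.0)
    item_loadings: tuple = field(default_factory=_default_item_loadings)
    trial_noise_sd: float = 16.0
    condition_shift: Mapping = field(default_factory=_default_condition_shift)
    n_careless: int = 0
    n_attention_fail: int = 0
    seed: int = 0
    # generator shape knobs (not study effects)
    mediator_correlation: float = 0.4
    rating_base: float = 18.0
    latent_log_scale: float = 0.5
    n_trials_per_condition: int = 30

    def validate(self) -> None:
        if not 0.0 <= self.p_diagnosed <= 1.0:
            raise ValueError(f"p_diagnosed must be in [0, 1], got {self.p_diagnosed}")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if len(self.item_loadings) != 10:
            raise ValueError("exactly 10 item loadings required")
        if any(not 0.0 <= l <= 1.0 for l in self.item_loadings):
            raise ValueError("item loadings must lie in [0, 1]")
        for name, count in (
            ("n_careless", self.n_careless),
            ("n_attention_fail", self.n_attention_fail),
        ):
            if count < 0:
                raise ValueError(f"{name} must be non-negative")
        for paths, label in ((self.a_paths, "a_paths"), (self.b_paths, "b_paths")):
            missing = [
                (c, s) for c in CONDITIONS for s in SCALES if (c, s) not in paths
            ]
            if missing:
                raise ValueError(f"{label} missing keys: {missing}")
        if not 0.0 <= self.mediator_correlation < 1.0:
            raise ValueError("mediator_correlation must be in [0, 1)")


@dataclass
class SyntheticStudy:
    """Generated study: wide participant table, long trial table, attention
    check responses, and the ground truth used to generate them."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    attention: pd.DataFrame
    truth: dict

    def copy(self) -> "SyntheticStudy":
        return SyntheticStudy(
            participants=self.participants.copy(),
            trials=self.trials.copy(),
            attention=self.attention.copy(),
            truth=json.loads(json.dumps({k: v for k, v in self.truth.items() if k != "latent"}))
            | ({"latent": self.truth["latent"].copy()} if "latent" in self.truth else {}),
        )


def _expanded_shift(condition_shift: Mapping) -> dict:
    """Expand per-condition shifts to (condition, scale) keys."""
    out = {}
    for c in CONDITIONS:
        for s in SCALES:
            if (c, s) in condition_shift:
                out[(c, s)] = float(condition_shift[(c, s)])
            elif c in condition_shift:
                out[(c, s)] = float(condition_shift[c])
            else:
                out[(c, s)] = 0.0
    return out


def _cells() -> list:
    return [(c, s) for c in CONDITIONS for s in SCALES]


def generate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a full synthetic study, deterministically for a given seed.

    Careless responders (``n_careless``, constant-response mode) and
    attention-check failures (``n_attention_fail``) requested in the config
    are injected before returning.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    p = config.p_diagnosed
    cells = _cells()
    n_cells = len(cells)

    diagnosed = (rng.random(n) < p).astype(int)

    # --- person-level latent reactivity, unit variance per cell ---
    a_vec = np.array([float(config.a_paths[c]) for c in cells])
    rho = config.mediator_correlation
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, n_cells))
    noise = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
    resid_sd = np.sqrt(np.clip(1.0 - a_vec**2 * p * (1.0 - p), 0.05, None))
    z = a_vec[None, :] * diagnosed[:, None] + resid_sd[None, :] * noise

    # --- covariates ---
    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 18, 80)
    gender = (rng.random(n) < _P_FEMALE).astype(int)
    race = (rng.random(n) < _P_NONWHITE).astype(int)
    ethnicity = (rng.random(n) < _P_HISPANIC).astype(int)
    income = rng.choice(len(_INCOME_P), size=n, p=_INCOME_P)
    education = rng.choice(len(_EDUCATION_P), size=n, p=_EDUCATION_P)
    image_set = rng.integers(1, 4, size=n)
    cov = np.column_stack([age, gender, race, ethnicity, income, education]).astype(float)
    cov_std = (cov - cov.mean(axis=0)) / np.where(cov.std(axis=0) > 0, cov.std(axis=0), 1.0)

    # --- disruption factor and Likert items ---
    b_vec = np.array([float(config.b_paths[c]) for c in cells])
    gamma = np.asarray(config.covariate_effects, dtype=float)
    # latent covariance of z across cells (exact, by construction)
    r_latent = (
        np.outer(a_vec, a_vec) * p * (1.0 - p)
        + np.outer(resid_sd, resid_sd) * rho
    )
    np.fill_diagonal(r_latent, 1.0)
    signal_var = float(b_vec @ r_latent @ b_vec + gamma @ gamma)
    if signal_var > 0.9:
        raise ValueError(
            f"b_paths/covariate_effects imply signal variance {signal_var:.2f} > 0.9; "
            "reduce the structural weights"
        )
    e_sd = np.sqrt(1.0 - signal_var)
    factor = z @ b_vec + cov_std @ gamma + e_sd * rng.standard_normal(n)

    loadings = np.asarray(config.item_loadings, dtype=float)
    item_latent = loadings[None, :] * factor[:, None] + np.sqrt(
        1.0 - loadings**2
    )[None, :] * rng.standard_normal((n, 10))
    items = 1 + np.searchsorted(np.asarray(_ITEM_THRESHOLDS), item_latent).reshape(n, 10)

    # --- trial ratings ---
    shift = _expanded_shift(config.condition_shift)
    k = config.n_trials_per_condition
    n_trials = 3 * k
    # condition labels randomized per participant across trial positions
    cond_labels = np.tile(np.repeat(np.arange(3), k), (n, 1))
    perm = rng.permuted(cond_labels, axis=1)

    rating_cols = {s: np.empty((n, n_trials)) for s in SCALES}
    shift_arr = {s: np.array([shift[(c, s)] for c in CONDITIONS]) for s in SCALES}
    for si, s in enumerate(SCALES):
        # z columns for this scale, indexed by condition
        z_s = np.stack([z[:, cells.index((c, s))] for c in CONDITIONS], axis=1)
        lat = shift_arr[s][perm] + np.take_along_axis(z_s, perm, axis=1)
        raw = config.rating_base * np.exp(config.latent_log_scale * lat)
        raw = raw + config.trial_noise_sd * rng.standard_normal((n, n_trials))
        rating_cols[s] = np.clip(raw, 0.0, 100.0)

    pid = np.array([f"P{i:05d}" for i in range(1, n + 1)])
    trials = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, n_trials),
            "trial_index": np.tile(np.arange(1, n_trials + 1), n),
            "image_type": np.array(CONDITIONS)[perm].ravel(),
            "image_set": np.repeat(image_set, n_trials),
            **{s: rating_cols[s].ravel() for s in SCALES},
        }
    )

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "diagnosed": diagnosed,
            "age": age,
            "gender_female": gender,
            "race_nonwhite": race,
            "ethnicity_hispanic": ethnicity,
            "income": income,
            "education": education,
            "image_set": image_set,
            "survey_code": [f"{c:05d}" for c in rng.integers(0, 100000, n)],
            **{f"item_{j + 1}": items[:, j] for j in range(10)},
        }
    )

    attention = pd.DataFrame(
        {
            "participant_id": np.repeat(pid, 3),
            "check_index": np.tile([1, 2, 3], n),
            "target": np.tile(ATTENTION_TARGETS, n),
            "response": np.tile(ATTENTION_TARGETS, n).astype(float),
        }
    )

    truth = {
        "a_paths": {f"{c}_{s}": float(config.a_paths[(c, s)]) for c, s in cells},
        "b_paths": {f"{c}_{s}": float(config.b_paths[(c, s)]) for c, s in cells},
        "covariate_effects": list(map(float, gamma)),
        "item_loadings": list(map(float, loadings)),
        "condition_shift": {f"{c}_{s}": v for (c, s), v in shift.items()},
        "seed": config.seed,
        "careless_ids": [],
        "attention_fail_ids": [],
        "unaligned_ids": [],
        "incomplete_ids": [],
        "latent": pd.DataFrame(
            {"participant_id": pid, "factor": factor}
            | {f"z_{c}_{s}": z[:, cells.index((c, s))] for c, s in cells}
        ),
    }

    study = SyntheticStudy(participants, trials, attention, truth)
    if config.n_careless:
        study = inject_careless(study, config.n_careless, "constant_response",
                                seed=config.seed + 1)
    if config.n_attention_fail:
        study = inject_careless(study, config.n_attention_fail, "attention_fail",
                                seed=config.seed + 2)
    return study


def inject_careless(
    study: SyntheticStudy,
    n_careless: int,
    mode: str,
    seed: int = 0,
) -> SyntheticStudy:
    """Overwrite ``n_careless`` participants with careless-responder patterns.

    ``constant_response`` replaces all 360 rating responses with a single
    value plus jitter of SD well below 10; ``attention_fail`` corrupts at
    least one of the three attention-check responses.  Participants already
    flagged in the study's truth are not re-selected, so successive
    injections target disjoint sets.  Returns a new study; flags are
    recorded in ``truth``.
    """
    if n_careless == 0:
        return study
    if mode not in ("constant_response", "attention_fail"):
        raise ValueError(f"unknown careless mode: {mode!r}")
    if n_careless > len(study.participants):
        raise ValueError("n_careless exceeds number of participants")
    rng = np.random.default_rng(seed)
    out = study.copy()
    already = set(
        out.truth["careless_ids"]
        + out.truth["attention_fail_ids"]
        + out.truth["unaligned_ids"]
        + out.truth["incomplete_ids"]
    )
    eligible = [p for p in out.participants["participant_id"] if p not in already]
    if n_careless > len(eligible):
        raise ValueError("not enough unflagged participants to corrupt")
    chosen = list(rng.choice(eligible, size=n_careless, replace=False))

    if mode == "constant_response":
        for pid_ in chosen:
            pm = (out.trials["participant_id"] == pid_).to_numpy()
            base = rng.uniform(20, 80)
            for s in SCALES:
                jitter = rng.normal(0.0, 2.0, pm.sum())
                out.trials.loc[pm, s] = np.clip(base + jitter, 0, 100)
        out.truth["careless_ids"] = out.truth["careless_ids"] + chosen
    else:
        for pid_ in chosen:
            pm = (out.attention["participant_id"] == pid_).to_numpy()
            idx = np.flatnonzero(pm)[rng.integers(0, 3)]
            target = out.attention.loc[idx, "target"]
            out.attention.loc[idx, "response"] = float(target) + rng.uniform(5, 30)
        out.truth["attention_fail_ids"] = out.truth["attention_fail_ids"] + chosen
    return out


def inject_unaligned(study: SyntheticStudy, n: int, seed: int = 0) -> SyntheticStudy:
    """Blank the survey code of ``n`` participants so their questionnaire rows
    cannot be aligned with their rating data."""
    if n == 0:
        return study
    rng = np.random.default_rng(seed)
    out = study.copy()
    flagged = set(
        out.truth["careless_ids"] + out.truth["attention_fail_ids"]
        + out.truth["unaligned_ids"] + out.truth["incomplete_ids"]
    )
    eligible = [p for p in out.participants["participant_id"] if p not in flagged]
    chosen = list(rng.choice(eligible, size=n, replace=False))
    out.participants.loc[
        out.participants["participant_id"].isin(chosen), "survey_code"
    ] = ""
    out.truth["unaligned_ids"] = out.truth["unaligned_ids"] + chosen
    return out


def inject_incomplete(study: SyntheticStudy, n: int, seed: int = 0) -> SyntheticStudy:
    """Blank one demographic covariate for ``n`` participants (incomplete
    demographics exclusion step)."""
    if n == 0:
        return study
    rng = np.random.default_rng(seed)
    out = study.copy()
    flagged = set(
        out.truth["careless_ids"] + out.truth["attention_fail_ids"]
        + out.truth["unaligned_ids"] + out.truth["incomplete_ids"]
    )
    eligible = [p for p in out.participants["participant_id"] if p not in flagged]
    chosen = list(rng.choice(eligible, size=n, replace=False))
    cols = list(COVARIATE_COLS)
    for pid_ in chosen:
        col = cols[rng.integers(0, len(cols))]
        out.participants.loc[
            out.participants["participant_id"] == pid_, col
        ] = np.nan
    out.truth["incomplete_ids"] = out.truth["incomplete_ids"] + chosen
    return out


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write participants.csv, trials.csv, attention.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.participants.to_csv(outdir / "participants.csv", index=False)
    study.trials.to_csv(outdir / "trials.csv", index=False)
    study.attention.to_csv(outdir / "attention.csv", index=False)
    truth = {k: v for k, v in study.truth.items() if k != "latent"}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_study(indir: str | Path) -> SyntheticStudy:
    """Load a study previously written by :func:`write_study`."""
    indir = Path(indir)
    participants = pd.read_csv(indir / "participants.csv",
                               dtype={"survey_code": str}, keep_default_na=True)
    participants["survey_code"] = participants["survey_code"].fillna("")
    trials = pd.read_csv(indir / "trials.csv")
    attention = pd.read_csv(indir / "attention.csv")
    truth_path = indir / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else {}
    return SyntheticStudy(participants, trials, attention, truth)
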