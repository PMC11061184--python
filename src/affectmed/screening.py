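"""Participant exclusion cascade for online rating studies.

Four sequential filters, applied in a fixed order so that a participant
failing several criteria is only counted under the first one that catches
them:

1. attention — failed at least one of the three embedded slider checks;
2. low variance — pooled sample SD of all rating responses below a cutoff
   (default 10 rating units), a straight-lining / bot signature;
3. unaligned — questionnaire responses that cannot be matched to rating
   data (missing survey code; optionally duplicated participant IDs);
4. incomplete demographics — missing values in any covariate column.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import COVARIATE_COLS, SCALES


@dataclass
class ExclusionReport:
    """Auditable record of the exclusion cascade."""

    n_enrolled: int
    n_attention_failed: int
    n_low_variance: int
    n_unaligned: int
    n_incomplete_demographics: int
    n_final: int
    excluded_ids_by_step: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = (
            self.n_attention_failed
            + self.n_low_variance
            + self.n_unaligned
            + self.n_incomplete_demographics
        )
        if self.n_final != self.n_enrolled - total:
            raise ValueError(
                "conservation violated: n_final != n_enrolled - sum(exclusions)"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def rating_sd(trials_for_one_participant: pd.DataFrame | np.ndarray) -> float:
    """Pooled sample standard deviation (n-1 denominator) of all rating
    responses of one participant.

    Accepts either the participant's long trial table (the four rating
    columns are pooled — 90 trials x 4 scales = 360 responses) or a flat
    array of responses.
    """
    if isinstance(trials_for_one_participant, pd.DataFrame):
        values = trials_for_one_participant[list(SCALES)].to_numpy(dtype=float).ravel()
    else:
        values = np.asarray(trials_for_one_participant, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("rating SD requires at least 2 responses")
    return float(np.std(values, ddof=1))


def _pooled_sds(trials: pd.DataFrame) -> pd.Series:
    """Per-participant pooled rating SD, via the same numpy path as
    :func:`rating_sd` so filter and statistic agree bit-for-bit."""
    values = trials[list(SCALES)].to_numpy(dtype=float)
    ids = trials["participant_id"].to_numpy()
    order = np.argsort(ids, kind="mergesort")  # stable: keeps trial order
    ids_sorted = ids[order]
    values = values[order]
    uniq, starts = np.unique(ids_sorted, return_index=True)
    bounds = np.append(starts, len(ids_sorted))
    sds = [
        float(np.std(values[bounds[i]: bounds[i + 1]].ravel(), ddof=1))
        for i in range(len(uniq))
    ]
    return pd.Series(sds, index=pd.Index(uniq, name="participant_id"))


def apply_exclusions(
    participants: pd.DataFrame,
    trials: pd.DataFrame,
    attention_results: pd.DataFrame,
    sd_cutoff: float = 10.0,
    attention_tolerance: float = 0.0,
    duplicates: str = "error",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Run the four-step cascade and return (retained participants, report).

    ``attention_results`` must hold three checks per participant with
    ``target`` and ``response`` columns; a check passes when
    ``|response - target| <= attention_tolerance`` (default: slider exactly
    on the number).  The SD filter excludes strictly below ``sd_cutoff``
    (a participant at exactly the cutoff is retained).  Duplicate
    participant IDs raise by default; with ``duplicates="unaligned"`` all
    their rows are instead routed to the unaligned step.
    """
    ids = participants["participant_id"]
    dup_ids: list = []
    if ids.duplicated().any():
        dup_ids = sorted(ids[ids.duplicated(keep=False)].unique())
        if duplicates == "error":
            raise ValueError(f"duplicate participant IDs: {dup_ids}")
        if duplicates != "unaligned":
            raise ValueError(f"unknown duplicates policy: {duplicates!r}")

    n_enrolled = int(ids.nunique())
    remaining = set(ids.unique())
    steps: dict[str, list] = {}

    # 1. attention checks
    counts = attention_results.groupby("participant_id").size()
    bad_counts = counts[counts != 3]
    if len(bad_counts):
        raise ValueError(
            f"expected 3 attention checks per participant; offenders: "
            f"{list(bad_counts.index[:5])}"
        )
    failed = (
        (attention_results["response"] - attention_results["target"]).abs()
        > attention_tolerance
    )
    att_fail = set(attention_results.loc[failed, "participant_id"]) & remaining
    steps["attention"] = sorted(att_fail)
    remaining -= att_fail

    # 2. low pooled rating SD
    sds = _pooled_sds(trials[trials["participant_id"].isin(remaining)])
    low_var = set(sds.index[sds < sd_cutoff]) & remaining
    steps["low_variance"] = sorted(low_var)
    remaining -= low_var

    # 3. unalignable survey responses
    code = participants.set_index("participant_id")["survey_code"] if not ids.duplicated().any() else None
    if code is not None:
        blank = code.isna() | (code.astype(str).str.strip() == "")
        unaligned = set(blank.index[blank]) & remaining
    else:
        per_id = participants.groupby("participant_id")["survey_code"].first()
        blank = per_id.isna() | (per_id.astype(str).str.strip() == "")
        unaligned = (set(per_id.index[blank]) | set(dup_ids)) & remaining
    steps["unaligned"] = sorted(unaligned)
    remaining -= unaligned

    # 4. incomplete demographics
    demo = participants.drop_duplicates("participant_id").set_index("participant_id")
    incomplete = set(
        demo.index[demo[list(COVARIATE_COLS)].isna().any(axis=1)]
    ) & remaining
    steps["incomplete_demographics"] = sorted(incomplete)
    remaining -= incomplete

    report = ExclusionReport(
        n_enrolled=n_enrolled,
        n_attention_failed=len(steps["attention"]),
        n_low_variance=len(steps["low_variance"]),
        n_unaligned=len(steps["unaligned"]),
        n_incomplete_demographics=len(steps["incomplete_demographics"]),
        n_final=len(remaining),
        excluded_ids_by_step=steps,
    )
    retained = participants[participants["participant_id"].isin(remaining)].copy()
    return retained, report
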