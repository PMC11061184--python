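"""Manipulation check: random-intercept multilevel models on trial ratings.

Each rating scale is modelled at the trial level with a participant random
intercept (to absorb the repeated-measures structure) and two dummy-coded
fixed effects contrasting the non-reference image types against the
reference condition.  Estimation is restricted maximum likelihood via
statsmodels MixedLM; confidence intervals are two-tailed 95% Wald
intervals from the REML fit.  Refitting with a different reference level
yields the third pairwise contrast; by linear reparameterization it equals
the difference of the original two contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

from .synthetic import CONDITIONS


@dataclass
class MixedModelResult:
    """REML random-intercept fit summary for one rating scale."""

    fixed_effects: dict  # contrast name -> {"beta", "se", "ci_low", "ci_high"}
    random_intercept_variance: float
    residual_variance: float
    n_obs: int
    n_participants: int
    reference: str


class RandomInterceptContrasts(BaseEstimator):
    """Random-intercept linear mixed model with dummy-coded condition contrasts.

    Parameters
    ----------
    reference : image type used as the dummy-coding reference (default
        "neutral", so the two contrasts are infection-vs-neutral and
        harm-vs-neutral).
    rating_col : name of the response column in the long table.

    Fitted attributes: ``fixed_effects_``, ``random_intercept_variance_``,
    ``residual_variance_``, ``n_obs_``, ``n_participants_``, ``result_``
    (the statsmodels results object).
    """

    def __init__(self, reference: str = "neutral", rating_col: str = "rating"):
        self.reference = reference
        self.rating_col = rating_col

    def fit(self, X: pd.DataFrame, y=None):
        data = X
        levels = set(data["image_type"].unique())
        if self.reference not in levels:
            raise ValueError(f"reference level {self.reference!r} not present in data")
        if len(levels) < 2:
            raise ValueError("need at least 2 image-type conditions")
        if data["participant_id"].nunique() < 2:
            raise ValueError("random intercept unidentifiable with a single participant")
        data = data.rename(columns={self.rating_col: "_rating"})
        formula = f"_rating ~ C(image_type, Treatment(reference='{self.reference}'))"
        with warnings.catch_warnings():
            # REML fits near a zero variance boundary emit convergence noise
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, data, groups=data["participant_id"])
            result = model.fit(reml=True, method=["lbfgs"])
            ci = result.conf_int(alpha=0.05)
            bse = result.bse_fe
        fixed = {}
        for name in result.fe_params.index:
            if name == "Intercept":
                label = "intercept"
            else:
                level = name.split("[T.")[-1].rstrip("]")
                label = f"{level}_vs_{self.reference}"
            fixed[label] = {
                "beta": float(result.fe_params[name]),
                "se": float(bse[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
            }
        self.result_ = result
        self.fixed_effects_ = fixed
        self.random_intercept_variance_ = float(result.cov_re.iloc[0, 0])
        self.residual_variance_ = float(result.scale)
        self.n_obs_ = int(len(data))
        self.n_participants_ = int(data["participant_id"].nunique())
        return self

    def result_summary(self) -> MixedModelResult:
        return MixedModelResult(
            fixed_effects=self.fixed_effects_,
            random_intercept_variance=self.random_intercept_variance_,
            residual_variance=self.residual_variance_,
            n_obs=self.n_obs_,
            n_participants=self.n_participants_,
            reference=self.reference,
        )


def fit_rating_lmm(
    long_ratings: pd.DataFrame,
    reference: str = "neutral",
    rating_col: str = "rating",
) -> MixedModelResult:
    """Fit the random-intercept model and return its summary."""
    est = RandomInterceptContrasts(reference=reference, rating_col=rating_col)
    return est.fit(long_ratings).result_summary()


def recode_reference(long_ratings: pd.DataFrame, new_reference: str) -> pd.DataFrame:
    """Return the long table with the image-type factor releveled so that
    ``new_reference`` is the dummy-coding baseline on refit."""
    levels = list(pd.unique(long_ratings["image_type"]))
    if new_reference not in levels:
        raise ValueError(f"unknown image type: {new_reference!r}")
    ordered = [new_reference] + [l for l in CONDITIONS if l in levels and l != new_reference]
    out = long_ratings.copy()
    out["image_type"] = pd.Categorical(out["image_type"], categories=ordered)
    out.attrs["reference"] = new_reference
    return out


def trials_to_long(trials: pd.DataFrame, scale: str) -> pd.DataFrame:
    """Extract one rating scale from the wide trial table as a long frame
    with columns participant_id, image_type, rating."""
    if scale not in trials.columns:
        raise ValueError(f"unknown rating scale: {scale!r}")
    return trials[["participant_id", "image_type", scale]].rename(
        columns={scale: "rating"}
    )
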