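"""Aggregation of trial ratings to mediator variables and Box-Cox normalisation.

Trial-level 0-100 ratings are averaged within participant for each
image-type condition x rating-scale cell, giving the 12 person-level
mediator variables.  Because slider ratings are strongly right-skewed,
each mediator is Box-Cox transformed with its own lambda chosen by profile
likelihood; a fixed shift of +1 keeps zero ratings inside the transform's
domain.  Extreme values are flagged (never removed) by Tukey's rule with
k = 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic import CONDITIONS, SCALES

#: mediator column names, condition-major
MEDIATOR_COLS = tuple(f"{s}_{c}" for c in CONDITIONS for s in SCALES)


def condition_means(trials: pd.DataFrame, n_trials_per_condition: int = 30) -> pd.DataFrame:
    """Per-participant mean rating for each condition x scale cell.

    Returns a wide frame indexed-free with ``participant_id`` plus the 12
    columns of :data:`MEDIATOR_COLS`.  Raises if any participant is missing
    a condition or has a trial count different from
    ``n_trials_per_condition`` in any cell.
    """
    counts = trials.groupby(["participant_id", "image_type"]).size().unstack(fill_value=0)
    missing = [c for c in CONDITIONS if c not in counts.columns]
    if missing:
        raise ValueError(f"conditions absent from trials: {missing}")
    bad = counts[(counts[list(CONDITIONS)] != n_trials_per_condition).any(axis=1)]
    if len(bad):
        raise ValueError(
            f"participants with wrong trial counts (expected "
            f"{n_trials_per_condition}/condition): {list(bad.index[:5])}"
        )
    means = trials.groupby(["participant_id", "image_type"])[list(SCALES)].mean()
    wide = means.unstack("image_type")
    wide.columns = [f"{scale}_{cond}" for scale, cond in wide.columns]
    wide = wide[list(MEDIATOR_COLS)].reset_index()
    return wide


@dataclass
class BoxCoxFit:
    """Fitted Box-Cox transform for one variable: the selected lambda, the
    additive shift applied before transforming, and the profile
    log-likelihood over the search grid for inspection."""

    lam: float
    shift: float
    loglik_profile: np.ndarray  # columns: lambda, log-likelihood

    @property
    def lambda_(self) -> float:
        return self.lam


def boxcox_apply(x, lam: float, shift: float = 0.0) -> np.ndarray:
    """Box-Cox power transform: ((x+shift)^lam - 1)/lam, or ln(x+shift) at
    lam = 0.  Raises when any shifted value is non-positive."""
    x = np.asarray(x, dtype=float) + shift
    if np.any(x <= 0):
        raise ValueError("Box-Cox domain violation: non-positive values after shift")
    if lam == 0.0:
        return np.log(x)
    # expm1 keeps the power form accurate down to lam -> 0
    return np.expm1(lam * np.log(x)) / lam


def _boxcox_llf_grid(lams: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Profile log-likelihood of the Box-Cox lambda over a grid, vectorised.

    llf(lam) = (lam - 1) * sum(log x) - n/2 * log(var_mle(x_lam)); agrees
    with scipy.stats.boxcox_llf at every grid point.
    """
    logx = np.log(x)
    slog = logx.sum()
    n = x.size
    out = np.empty(len(lams))
    for i, lam in enumerate(lams):
        y = logx if lam == 0.0 else (np.exp(lam * logx) - 1.0) / lam
        out[i] = (lam - 1.0) * slog - 0.5 * n * np.log(y.var())
    return out


def boxcox_lambda(
    x,
    grid: tuple[float, float] = (-2.0, 2.0),
    grid_step: float = 0.01,
    shift: float = 0.0,
) -> BoxCoxFit:
    """Profile-likelihood estimate of the Box-Cox lambda.

    Scans the grid with :func:`scipy.stats.boxcox_llf`, then refines around
    the best grid point with bounded scalar optimisation.  Requires at
    least 10 strictly positive (after shift) and non-constant values.
    """
    x = np.asarray(x, dtype=float) + shift
    if x.size < 10:
        raise ValueError("Box-Cox fitting requires n >= 10")
    if np.any(x <= 0):
        raise ValueError("Box-Cox requires strictly positive values after shift")
    if np.ptp(x) == 0:
        raise ValueError("Box-Cox lambda undefined for constant input")
    lo, hi = grid
    lams = np.arange(lo, hi + grid_step / 2, grid_step)
    llf = _boxcox_llf_grid(lams, x)
    best = int(np.argmax(llf))
    a = lams[max(best - 1, 0)]
    b = lams[min(best + 1, len(lams) - 1)]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x), bounds=(a, b), method="bounded",
        options={"xatol": 1e-8},
    )
    lam = float(res.x) if -res.fun >= llf[best] else float(lams[best])
    return BoxCoxFit(lam=lam, shift=shift, loglik_profile=np.column_stack([lams, llf]))


class BoxCoxNormalizer(TransformerMixin, BaseEstimator):
    """Column-wise Box-Cox normaliser with profile-likelihood lambdas.

    Parameters
    ----------
    shift : additive constant applied before transforming (default 1.0,
        suitable for 0-100 slider ratings that may contain exact zeros).
    lambda_grid : (low, high) search range for lambda.
    grid_step : grid resolution before scalar refinement.

    Attributes
    ----------
    lambdas_ : ndarray of fitted lambdas, one per column.
    fits_ : list of :class:`BoxCoxFit` with the profiles.
    columns_ : column names seen at fit (when given a DataFrame).
    """

    def __init__(self, shift: float = 1.0, lambda_grid: tuple = (-2.0, 2.0),
                 grid_step: float = 0.01):
        self.shift = shift
        self.lambda_grid = lambda_grid
        self.grid_step = grid_step

    def fit(self, X, y=None):
        X_arr, cols = self._coerce(X)
        self.fits_ = [
            boxcox_lambda(X_arr[:, j], grid=tuple(self.lambda_grid),
                          grid_step=self.grid_step, shift=self.shift)
            for j in range(X_arr.shape[1])
        ]
        self.lambdas_ = np.array([f.lam for f in self.fits_])
        self.columns_ = cols
        self.n_features_in_ = X_arr.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "lambdas_")
        X_arr, cols = self._coerce(X)
        if X_arr.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch with fit")
        out = np.column_stack([
            boxcox_apply(X_arr[:, j], self.lambdas_[j], self.shift)
            for j in range(X_arr.shape[1])
        ])
        if cols is not None:
            return pd.DataFrame(out, columns=cols, index=X.index)
        return out

    @staticmethod
    def _coerce(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return X, None


def tukey_extreme_flags(x, k: float = 3.0) -> np.ndarray:
    """Boolean flags for values outside [Q1 - k*IQR, Q3 + k*IQR].

    Quartiles use the linear-interpolation (type-7) convention.  With the
    default k = 3 these are Tukey's *extreme* (far-out) fences.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("Tukey fences require n >= 4")
    q1, q3 = np.percentile(x, [25, 75])  # numpy default = linear = type 7
    iqr = q3 - q1
    return (x < q1 - k * iqr) | (x > q3 + k * iqr)


def transform_mediators(
    trials: pd.DataFrame,
    shift: float = 1.0,
    lambda_grid: tuple = (-2.0, 2.0),
    grid_step: float = 0.01,
    n_trials_per_condition: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing step: condition means, per-mediator Box-Cox, and
    Tukey extreme-value flags.

    Returns ``(mediators, lambda_table)`` where ``mediators`` holds the 12
    transformed person-level variables and ``lambda_table`` the fitted
    lambda, shift and extreme-flag count per mediator.
    """
    wide = condition_means(trials, n_trials_per_condition)
    norm = BoxCoxNormalizer(shift=shift, lambda_grid=lambda_grid, grid_step=grid_step)
    transformed = norm.fit_transform(wide[list(MEDIATOR_COLS)])
    out = pd.concat([wide[["participant_id"]], transformed], axis=1)
    lam_table = pd.DataFrame(
        {
            "mediator": MEDIATOR_COLS,
            "lambda": norm.lambdas_,
            "shift": shift,
            "n_extreme_raw": [
                int(tukey_extreme_flags(wide[c].to_numpy()).sum()) for c in MEDIATOR_COLS
            ],
            "n_extreme_transformed": [
                int(tukey_extreme_flags(transformed[c].to_numpy()).sum())
                for c in MEDIATOR_COLS
            ],
        }
    )
    return out, lam_table
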