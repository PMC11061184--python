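"""Single-factor scale construction by minimum-residual factor analysis.

The pandemic-disruption questionnaire is reduced to one score per
participant in the sequence the field's scale-construction practice
prescribes: extract a single factor by minimum residual (unweighted least
squares on the off-diagonal correlations), inspect the eigenvalue drop for
unidimensionality, drop items whose loading falls below a threshold, refit
on the retained items, and average them.

Minres minimises

    sum_{i<j} (r_ij - l_i l_j)^2

over the loading vector l, i.e. it reproduces the observed correlations as
well as possible without constraining the diagonal (communalities are free).
Eigenvalues of the raw sample correlation matrix are reported for the scree
decision; eigenvalues of the reduced matrix (diagonal replaced by fitted
communalities) are also exposed, since published "eigenvalue" figures may
follow either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


@dataclass
class FactorSolution:
    """One-factor minres solution."""

    eigenvalues: np.ndarray          # raw correlation matrix, descending
    reduced_eigenvalues: np.ndarray  # communality-adjusted, descending
    loadings: np.ndarray
    n_factors: int = 1
    retained_items: list = field(default_factory=list)
    fit_method: str = "minres"

    @property
    def communalities(self) -> np.ndarray:
        return self.loadings**2


def _minres_loadings(r: np.ndarray) -> np.ndarray:
    """Minimise the off-diagonal residual SSQ for a single factor."""
    p = r.shape[0]
    offmask = ~np.eye(p, dtype=bool)
    evals, evecs = np.linalg.eigh(r)
    l0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-6))
    if l0.mean() < 0:
        l0 = -l0

    def objective(l):
        resid = (r - np.outer(l, l))[offmask]
        return float(resid @ resid)

    def gradient(l):
        resid = r - np.outer(l, l)
        np.fill_diagonal(resid, 0.0)
        return -4.0 * resid @ l

    res = optimize.minimize(
        objective, l0, jac=gradient, method="L-BFGS-B",
        bounds=[(-0.9999, 0.9999)] * p,
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    loadings = res.x
    if loadings.mean() < 0:
        loadings = -loadings
    return loadings


class MinresFactorAnalysis(TransformerMixin, BaseEstimator):
    """Single-factor exploratory factor analysis by minimum residual.

    ``fit`` expects a participants x items matrix (DataFrame or array) of
    numeric item responses.  ``transform`` returns regression factor scores
    (Thomson's method) — a convenience; scale *scoring* for the disruption
    index uses plain item averaging, see :func:`score_disruption`.

    Attributes
    ----------
    loadings_ : item loadings, sign-aligned so their mean is positive.
    eigenvalues_ : eigenvalues of the sample correlation matrix, descending.
    reduced_eigenvalues_ : eigenvalues of the correlation matrix with fitted
        communalities on the diagonal, descending.
    communalities_ : squared loadings.
    scree_ratio_ : first over second raw eigenvalue, for the scree decision.
    """

    def __init__(self, n_factors: int = 1):
        self.n_factors = n_factors

    def fit(self, X, y=None):
        if self.n_factors != 1:
            raise ValueError("only single-factor extraction is supported")
        X_arr, cols = self._coerce(X)
        n, p = X_arr.shape
        if p < 3:
            raise ValueError("factor analysis requires at least 3 items")
        if n <= p:
            raise ValueError("need more participants than items")
        sds = X_arr.std(axis=0, ddof=1)
        if np.any(sds == 0):
            zero = [cols[j] if cols else j for j in np.flatnonzero(sds == 0)]
            raise ValueError(f"constant items make the correlation matrix singular: {zero}")
        r = np.corrcoef(X_arr, rowvar=False)
        if not np.all(np.isfinite(r)) or np.linalg.matrix_rank(r) < p:
            raise ValueError("singular correlation matrix")
        self.corr_ = r
        self.eigenvalues_ = np.sort(np.linalg.eigvalsh(r))[::-1]
        self.loadings_ = _minres_loadings(r)
        self.communalities_ = self.loadings_**2
        reduced = r.copy()
        np.fill_diagonal(reduced, self.communalities_)
        self.reduced_eigenvalues_ = np.sort(np.linalg.eigvalsh(reduced))[::-1]
        self.scree_ratio_ = float(self.eigenvalues_[0] / self.eigenvalues_[1])
        self.columns_ = cols
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X_arr, _ = self._coerce(X)
        z = (X_arr - X_arr.mean(axis=0)) / X_arr.std(axis=0, ddof=1)
        weights = np.linalg.solve(self.corr_, self.loadings_)
        return (z @ weights)[:, None]

    def solution_(self) -> FactorSolution:
        check_is_fitted(self, "loadings_")
        return FactorSolution(
            eigenvalues=self.eigenvalues_.copy(),
            reduced_eigenvalues=self.reduced_eigenvalues_.copy(),
            loadings=self.loadings_.copy(),
            retained_items=list(range(self.n_features_in_)),
        )

    @staticmethod
    def _coerce(X):
        if isinstance(X, pd.DataFrame):
            return X.to_numpy(dtype=float), list(X.columns)
        return np.asarray(X, dtype=float), None


def efa_minres(item_matrix, n_factors: int = 1) -> FactorSolution:
    """Functional wrapper over :class:`MinresFactorAnalysis`."""
    return MinresFactorAnalysis(n_factors=n_factors).fit(item_matrix).solution_()


def retain_items(solution: FactorSolution | np.ndarray, threshold: float = 0.5) -> list:
    """Indices of items whose |loading| meets the threshold.

    Raises when no item survives (an empty scale cannot be scored).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    loadings = solution.loadings if isinstance(solution, FactorSolution) else np.asarray(solution)
    kept = [i for i, l in enumerate(loadings) if abs(l) >= threshold]
    if not kept:
        raise ValueError(f"no item loads at |loading| >= {threshold}")
    return kept


def score_disruption(item_matrix, retained_items) -> pd.Series | np.ndarray:
    """Per-participant mean of the retained items (1-5 Likert units)."""
    if len(retained_items) == 0:
        raise ValueError("retained item set is empty")
    if isinstance(item_matrix, pd.DataFrame):
        sub = item_matrix.iloc[:, list(retained_items)]
        if sub.isna().any().any():
            raise ValueError("missing item responses")
        return sub.mean(axis=1)
    arr = np.asarray(item_matrix, dtype=float)[:, list(retained_items)]
    if np.isnan(arr).any():
        raise ValueError("missing item responses")
    return arr.mean(axis=1)


def build_disruption_scale(
    item_matrix: pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[pd.Series | np.ndarray, FactorSolution, FactorSolution]:
    """Full scale-construction flow: fit, drop weak items, refit, average.

    Returns ``(scores, initial_solution, refit_solution)``; the refit
    solution's ``retained_items`` indexes into the original item order.
    """
    first = efa_minres(item_matrix)
    kept = retain_items(first, threshold)
    sub = (
        item_matrix.iloc[:, kept]
        if isinstance(item_matrix, pd.DataFrame)
        else np.asarray(item_matrix)[:, kept]
    )
    refit = efa_minres(sub)
    refit.retained_items = kept
    first.retained_items = kept
    scores = score_disruption(item_matrix, kept)
    return scores, first, refit
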