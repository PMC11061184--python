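"""Product-of-coefficients mediation with wild-bootstrap percentile CIs.

The exposure (prior diagnosis, 0/1) is linked to the outcome (disruption
score) through each person-level rating mediator in turn:

    a path:  mediator ~ exposure + covariates
    b path:  outcome  ~ mediator + exposure + covariates

both ordinary least squares on a semi-standardized scale — continuous
variables z-scored on the analysis sample, binary dummies left 0/1 — so
that for the binary exposure the a-path beta is the group mean difference
in mediator SD units.  The indirect effect is the product of the two focal
betas; its sampling distribution comes from a wild bootstrap: each path's
outcome is regenerated as fitted values plus sign/scale-perturbed
residuals (Rademacher weights by default, one weight per participant
shared across the two paths), both models are refit, and the product
recorded.  The two-tailed percentile interval of the recorded products
tests the indirect effect against zero; the wild scheme is robust to the
heteroscedasticity that an unbalanced binary exposure induces.

Because the design matrices are unchanged under the wild scheme, each
refit has the exact closed form

    beta* = beta + h @ (w * resid),    h = focal row of (X'X)^{-1} X',

which the implementation evaluates as a single matrix product over all
iterations; this is the OLS refit itself, not an approximation.

Effect sizes: partial eta squared t^2/(t^2 + df) per path (identical to
the squared partial correlation of the focal predictor), and the product
of the two squared partial correlations for the indirect effect.
Contrasts of indirect effects between two mediators bootstrap the raw
difference of the products with weights shared across all four models.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from sklearn.base import BaseEstimator

#: default covariate set for the emulated study design
DEFAULT_COVARIATES = (
    "age",
    "gender_female",
    "race_nonwhite",
    "ethnicity_hispanic",
    "income",
    "education",
    "image_set_2",
    "image_set_3",
)


@dataclass
class PathEstimate:
    """Standardized OLS estimate of one focal predictor."""

    beta: float
    se: float
    t_stat: float
    df_resid: int
    partial_r2: float
    partial_eta2: float
    outcome: str = ""
    focal: str = ""


@dataclass
class MediationResult:
    path_a: PathEstimate
    path_b: PathEstimate
    indirect: float
    ci95: tuple
    significant: bool
    r2_indirect: float
    mediator_label: str
    draws: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator_label,
            "a_beta": self.path_a.beta,
            "a_eta2": self.path_a.partial_eta2,
            "b_beta": self.path_b.beta,
            "b_eta2": self.path_b.partial_eta2,
            "indirect": self.indirect,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "significant": self.significant,
            "r2_indirect": self.r2_indirect,
        }


@dataclass
class IndirectContrast:
    difference: float
    ci95: tuple
    r2_difference: float
    mediator_1: str = ""
    mediator_2: str = ""
    significant: bool = False
    degenerate: bool = False
    draws: np.ndarray | None = None


@dataclass
class BootstrapSpec:
    """Wild-bootstrap settings."""

    n_iterations: int = 10_000
    weight_scheme: str = "rademacher"
    seed: int = 0
    ci_level: float = 0.95
    pairing: str = "shared_weights"

    def validate(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.weight_scheme not in ("rademacher", "mammen", "normal"):
            raise ValueError(f"unknown weight scheme: {self.weight_scheme!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")
        if self.pairing not in ("shared_weights", "independent_weights"):
            raise ValueError(f"unknown pairing: {self.pairing!r}")
        if self.n_iterations < 1000:
            warnings.warn(
                "fewer than 1000 bootstrap iterations: inference will be noisy",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# design construction


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values[~np.isnan(values)])
    return set(u).issubset({0.0, 1.0})


def _standardize_columns(data: pd.DataFrame, cols) -> pd.DataFrame:
    """z-score continuous columns on the analysis sample; leave 0/1 dummies."""
    out = {}
    for c in cols:
        v = data[c].to_numpy(dtype=float)
        if _is_binary(v):
            out[c] = v
        else:
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"column {c!r} is constant")
            out[c] = (v - v.mean()) / sd
    return pd.DataFrame(out, index=data.index)


def _design(data: pd.DataFrame, outcome: str, focal: str, covariates) -> tuple:
    cols = [outcome, focal, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from data: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("incomplete cases in design; drop or impute first")
    z = _standardize_columns(data, cols)
    y = z[outcome].to_numpy()
    X = np.column_stack([np.ones(len(z)), z[focal].to_numpy()]
                        + [z[c].to_numpy() for c in covariates])
    names = ["const", focal, *covariates]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = _qr(X, mode="economic", pivoting=True)
        dropped = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {dropped}")
    return y, X, names


def _ols(y: np.ndarray, X: np.ndarray) -> tuple:
    xtx_inv = np.linalg.inv(X.T @ X)
    hat = xtx_inv @ X.T                      # p x n projector
    beta = hat @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return beta, se, resid, hat, df


def fit_path(
    data: pd.DataFrame,
    outcome: str,
    focal_predictor: str,
    covariates=(),
) -> PathEstimate:
    """Semi-standardized OLS estimate of ``focal_predictor`` on ``outcome``.

    Continuous variables (including the outcome) are z-scored on the
    analysis sample; 0/1 dummies are left as is.  Returns the focal beta
    with classical t, residual df, and partial statistics
    (t^2 / (t^2 + df), reported both as squared partial correlation and
    partial eta squared — the two coincide in OLS).
    """
    y, X, _ = _design(data, outcome, focal_predictor, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError("need n > number of predictors")
    beta, se, _, _, df = _ols(y, X)
    t = beta[1] / se[1]
    pr2 = partial_eta_sq(t, df)
    return PathEstimate(
        beta=float(beta[1]), se=float(se[1]), t_stat=float(t), df_resid=df,
        partial_r2=pr2, partial_eta2=pr2, outcome=outcome, focal=focal_predictor,
    )


def partial_eta_sq(t_stat: float, df_resid: int) -> float:
    """Partial eta squared from a regression t statistic: t^2/(t^2 + df)."""
    if df_resid <= 0:
        raise ValueError("df_resid must be positive")
    t2 = float(t_stat) ** 2
    return t2 / (t2 + df_resid)


def indirect_effect(a: PathEstimate, b: PathEstimate) -> tuple:
    """Product-method indirect effect and its R^2 (product of the two
    squared partial correlations)."""
    return a.beta * b.beta, a.partial_r2 * b.partial_r2


# ---------------------------------------------------------------------------
# wild bootstrap


def _draw_weights(rng: np.random.Generator, scheme: str, shape) -> np.ndarray:
    if scheme == "rademacher":
        return rng.integers(0, 2, size=shape) * 2.0 - 1.0
    if scheme == "mammen":
        golden = (np.sqrt(5.0) + 1.0) / 2.0
        p_neg = golden / np.sqrt(5.0)        # P(w = -(golden-1)) = (sqrt5+1)/(2 sqrt5)
        lo, hi = 1.0 - golden, golden
        return np.where(rng.random(shape) < p_neg, lo, hi)
    if scheme == "normal":
        return rng.standard_normal(shape)
    raise ValueError(f"unknown weight scheme: {scheme!r}")


def _substream(seed: int, label: str) -> np.random.Generator:
    """Per-mediator RNG substream: stable under adding/removing mediators."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])


class _PathSystem:
    """Point fit plus the pieces needed for closed-form wild refits."""

    def __init__(self, data, outcome, focal, covariates):
        y, X, names = _design(data, outcome, focal, covariates)
        if len(y) <= X.shape[1]:
            raise ValueError("need n > number of predictors")
        beta, se, resid, hat, df = _ols(y, X)
        if np.allclose(resid, 0.0):
            raise ValueError(f"degenerate residuals (all zero) in {outcome!r} model")
        t = beta[1] / se[1]
        pr2 = partial_eta_sq(t, df)
        self.estimate = PathEstimate(
            beta=float(beta[1]), se=float(se[1]), t_stat=float(t), df_resid=df,
            partial_r2=pr2, partial_eta2=pr2, outcome=outcome, focal=focal,
        )
        self.resid = resid
        self.h_focal = hat[1]  # row projecting a perturbed outcome onto the focal beta

    def draws(self, weights: np.ndarray) -> np.ndarray:
        """Focal betas refit under outcome* = fitted + w*resid, all iterations
        at once: beta* = beta + h'(w * resid)."""
        return self.estimate.beta + self.h_focal @ (self.resid[:, None] * weights)


def _percentile_ci(draws: np.ndarray, level: float) -> tuple:
    alpha = 1.0 - level
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def _sorted_frame(data: pd.DataFrame) -> pd.DataFrame:
    # weights are drawn per participant; canonical row order makes results
    # invariant to the input's row order
    if "participant_id" in data.columns:
        return data.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    return data.sort_index().reset_index(drop=True)


class WildBootstrapMediation(BaseEstimator):
    """Single-mediator product-method mediation with wild-bootstrap CI.

    Parameters
    ----------
    mediator, outcome, exposure : column names in the analysis frame.
    covariates : columns entered in both path models.
    b_includes_exposure : include the exposure in the b-path model
        (standard product-method practice; default True).
    n_iterations, weight_scheme, seed, ci_level, pairing : see
        :class:`BootstrapSpec`.  The seed is a master seed; each mediator
        gets its own substream, so results for one mediator do not depend
        on which others are analysed.

    Fitted attributes: ``path_a_``, ``path_b_``, ``indirect_``, ``ci95_``,
    ``significant_``, ``r2_indirect_``, ``draws_``.
    """

    def __init__(
        self,
        mediator: str,
        outcome: str = "disruption",
        exposure: str = "diagnosed",
        covariates=DEFAULT_COVARIATES,
        b_includes_exposure: bool = True,
        n_iterations: int = 10_000,
        weight_scheme: str = "rademacher",
        seed: int = 0,
        ci_level: float = 0.95,
        pairing: str = "shared_weights",
    ):
        self.mediator = mediator
        self.outcome = outcome
        self.exposure = exposure
        self.covariates = covariates
        self.b_includes_exposure = b_includes_exposure
        self.n_iterations = n_iterations
        self.weight_scheme = weight_scheme
        self.seed = seed
        self.ci_level = ci_level
        self.pairing = pairing

    def _spec(self) -> BootstrapSpec:
        spec = BootstrapSpec(
            n_iterations=self.n_iterations,
            weight_scheme=self.weight_scheme,
            seed=self.seed,
            ci_level=self.ci_level,
            pairing=self.pairing,
        )
        spec.validate()
        return spec

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        data = _sorted_frame(X)
        if self.mediator not in data.columns:
            raise ValueError(f"mediator column {self.mediator!r} not in data")
        cov = list(self.covariates)
        path_a = _PathSystem(data, self.mediator, self.exposure, cov)
        b_cov = ([self.exposure] if self.b_includes_exposure else []) + cov
        path_b = _PathSystem(data, self.outcome, self.mediator, b_cov)

        n = len(data)
        rng = _substream(spec.seed, self.mediator)
        wa = _draw_weights(rng, spec.weight_scheme, (n, spec.n_iterations))
        wb = wa if spec.pairing == "shared_weights" else _draw_weights(
            rng, spec.weight_scheme, (n, spec.n_iterations)
        )
        draws = path_a.draws(wa) * path_b.draws(wb)
        ci = _percentile_ci(draws, spec.ci_level)

        self.path_a_ = path_a.estimate
        self.path_b_ = path_b.estimate
        self.indirect_ = path_a.estimate.beta * path_b.estimate.beta
        self.ci95_ = ci
        self.significant_ = not (ci[0] <= 0.0 <= ci[1])
        self.r2_indirect_ = path_a.estimate.partial_r2 * path_b.estimate.partial_r2
        self.draws_ = draws
        return self

    def result_(self, keep_draws: bool = False) -> MediationResult:
        return MediationResult(
            path_a=self.path_a_,
            path_b=self.path_b_,
            indirect=self.indirect_,
            ci95=self.ci95_,
            significant=self.significant_,
            r2_indirect=self.r2_indirect_,
            mediator_label=self.mediator,
            draws=self.draws_ if keep_draws else None,
        )


def wild_bootstrap_mediation(
    data: pd.DataFrame,
    mediator: str,
    spec: BootstrapSpec | None = None,
    outcome: str = "disruption",
    exposure: str = "diagnosed",
    covariates=DEFAULT_COVARIATES,
    b_includes_exposure: bool = True,
    keep_draws: bool = False,
) -> MediationResult:
    """Functional wrapper over :class:`WildBootstrapMediation`."""
    spec = spec or BootstrapSpec()
    est = WildBootstrapMediation(
        mediator=mediator, outcome=outcome, exposure=exposure,
        covariates=covariates, b_includes_exposure=b_includes_exposure,
        n_iterations=spec.n_iterations, weight_scheme=spec.weight_scheme,
        seed=spec.seed, ci_level=spec.ci_level, pairing=spec.pairing,
    )
    return est.fit(data).result_(keep_draws=keep_draws)


def indirect_contrast(
    data: pd.DataFrame,
    mediator_1: str,
    mediator_2: str,
    spec: BootstrapSpec | None = None,
    outcome: str = "disruption",
    exposure: str = "diagnosed",
    covariates=DEFAULT_COVARIATES,
    b_includes_exposure: bool = True,
    keep_draws: bool = False,
) -> IndirectContrast:
    """Bootstrap the raw difference of two indirect effects.

    One participant weight vector per iteration is shared across all four
    path models so the two products are perturbed jointly.
    """
    spec = spec or BootstrapSpec()
    spec.validate()
    data = _sorted_frame(data)
    cov = list(covariates)
    b_cov_extra = [exposure] if b_includes_exposure else []

    def system_pair(med):
        a = _PathSystem(data, med, exposure, cov)
        b = _PathSystem(data, outcome, med, b_cov_extra + cov)
        return a, b

    a1, b1 = system_pair(mediator_1)
    degenerate = mediator_1 == mediator_2
    if degenerate:
        point = 0.0
        r2_diff = 0.0
        ci = (0.0, 0.0)
        draws = np.zeros(spec.n_iterations)
    else:
        a2, b2 = system_pair(mediator_2)
        n = len(data)
        rng = _substream(spec.seed, f"{mediator_1}|{mediator_2}")
        w = _draw_weights(rng, spec.weight_scheme, (n, spec.n_iterations))
        draws = a1.draws(w) * b1.draws(w) - a2.draws(w) * b2.draws(w)
        point = (
            a1.estimate.beta * b1.estimate.beta
            - a2.estimate.beta * b2.estimate.beta
        )
        r2_diff = (
            a1.estimate.partial_r2 * b1.estimate.partial_r2
            - a2.estimate.partial_r2 * b2.estimate.partial_r2
        )
        ci = _percentile_ci(draws, spec.ci_level)
    return IndirectContrast(
        difference=float(point),
        ci95=ci,
        r2_difference=float(r2_diff),
        mediator_1=mediator_1,
        mediator_2=mediator_2,
        significant=not (ci[0] <= 0.0 <= ci[1]),
        degenerate=degenerate,
        draws=draws if keep_draws else None,
    )


def total_effect(
    data: pd.DataFrame,
    with_covariates: bool = True,
    spec: BootstrapSpec | None = None,
    outcome: str = "disruption",
    exposure: str = "diagnosed",
    covariates=DEFAULT_COVARIATES,
) -> tuple[PathEstimate, tuple]:
    """Total effect of the exposure on the outcome (c path), with a
    wild-bootstrap percentile CI.  Returns ``(estimate, ci)``."""
    spec = spec or BootstrapSpec()
    spec.validate()
    data = _sorted_frame(data)
    cov = list(covariates) if with_covariates else []
    system = _PathSystem(data, outcome, exposure, cov)
    n = len(data)
    rng = _substream(spec.seed, f"total|{'cov' if with_covariates else 'nocov'}")
    w = _draw_weights(rng, spec.weight_scheme, (n, spec.n_iterations))
    ci = _percentile_ci(system.draws(w), spec.ci_level)
    return system.estimate, ci


def effect_decomposition(
    data: pd.DataFrame,
    mediators,
    outcome: str = "disruption",
    exposure: str = "diagnosed",
    covariates=DEFAULT_COVARIATES,
) -> dict:
    """OLS decomposition c = c' + sum_m a_m * b_m.

    ``b_m`` comes from the joint outcome model containing the exposure and
    all mediators; with a common covariate set and per-variable scalings
    the identity is exact.
    """
    mediators = list(mediators)
    cov = list(covariates)
    c = fit_path(data, outcome, exposure, cov)
    # joint outcome model: exposure focal, mediators + covariates adjusted
    a_list = [fit_path(data, m, exposure, cov) for m in mediators]
    direct = fit_path(data, outcome, exposure, mediators + cov)
    b_list = [
        fit_path(data, outcome, m, [exposure] + [x for x in mediators if x != m] + cov)
        for m in mediators
    ]
    indirect_sum = sum(a.beta * b.beta for a, b in zip(a_list, b_list))
    return {
        "total": c,
        "direct": direct,
        "a_paths": a_list,
        "b_paths": b_list,
        "indirect_sum": float(indirect_sum),
        "identity_gap": float(c.beta - direct.beta - indirect_sum),
    }


def prepare_analysis_frame(
    participants: pd.DataFrame,
    mediators: pd.DataFrame,
    scores,
) -> pd.DataFrame:
    """Merge participant covariates, transformed mediators and disruption
    scores into one analysis frame; expands image_set into two dummies."""
    part = participants.reset_index(drop=True)
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(part):
        raise ValueError("scores must align with participants (same length/order)")
    scores = pd.Series(scores, index=part.index, name="disruption")
    part = pd.concat([part, scores], axis=1)
    part["image_set_2"] = (part["image_set"] == 2).astype(float)
    part["image_set_3"] = (part["image_set"] == 3).astype(float)
    merged = part.merge(mediators, on="participant_id", how="inner")
    return merged
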