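"""Main-effect residualization and phenotypic truncation.

Step 1 of the pipeline: fit the additive main-effect model

    Y_i = mu + sum_j X_ij beta_j + eps_i

with an elastic-net penalty, keep the residuals eps_hat, and split samples
into low/high groups at the tails of either the raw phenotype or the residual.
Removing the main effects before truncation restores the zero-mean condition
the differential-network sign logic relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .io import ExpressionMatrix, PhenotypeVector

__all__ = ["ResidualFit", "GroupAssignment", "fit_main_effects", "assign_groups"]


@dataclass(frozen=True)
class ResidualFit:
    """An elastic-net main-effect fit and its residual vector.

    The penalty follows the glmnet convention
    ``lambda * [(1 - alpha)/2 * ||beta||^2 + alpha * ||beta||_1]`` where
    ``mixing`` is the L1 share alpha and ``penalty`` the selected lambda.
    """

    intercept: float
    coefficients: np.ndarray
    residuals: np.ndarray
    mixing: float
    penalty: float
    cv_folds: int
    seed: int


@dataclass(frozen=True)
class GroupAssignment:
    """Low/high sample masks for a truncation point ``a`` in ]0, 0.5]."""

    a: float
    low_mask: np.ndarray
    high_mask: np.ndarray
    basis: Literal["phenotype", "residual"]

    def __post_init__(self) -> None:
        if np.any(self.low_mask & self.high_mask):
            raise ValueError("low and high groups overlap")
        # network estimation needs >= 4 samples per group and checks that
        # itself; the assignment only requires non-empty tails
        if self.low_mask.sum() < 1 or self.high_mask.sum() < 1:
            raise ValueError("each group needs at least 1 sample")

    @property
    def n_low(self) -> int:
        return int(self.low_mask.sum())

    @property
    def n_high(self) -> int:
        return int(self.high_mask.sum())


def fit_main_effects(
    X: ExpressionMatrix,
    y: PhenotypeVector,
    mixing: float = 1 / 3,
    cv_folds: int = 10,
    seed: int = 0,
    penalty: float | None = None,
) -> ResidualFit:
    """Fit y on all genes (no interaction terms) with an elastic net.

    The penalty lambda is chosen by K-fold cross-validation minimizing mean
    squared prediction error unless ``penalty`` pins it explicitly.  The
    intercept is always fitted and unpenalized.  Fold assignment is derived
    from ``seed`` so the fit is reproducible.
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be at least 2")
    if not X.standardized:
        raise ValueError("fit_main_effects requires a standardized matrix")
    yv = y.values
    if yv.shape[0] != X.n:
        raise ValueError("phenotype length does not match expression rows")
    if X.n < cv_folds:
        raise ValueError("need at least cv_folds samples")

    if penalty is not None:
        model = ElasticNet(alpha=penalty, l1_ratio=mixing, fit_intercept=True,
                           max_iter=50_000)
        model.fit(X.values, yv)
        lam = float(penalty)
    elif np.allclose(yv, yv[0]):
        # constant response: CV over a degenerate path is ill-posed
        model = ElasticNet(alpha=1.0, l1_ratio=mixing, fit_intercept=True)
        model.fit(X.values, yv)
        lam = 1.0
    else:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        model = ElasticNetCV(l1_ratio=mixing, cv=cv, fit_intercept=True,
                             alphas=100, max_iter=50_000)
        model.fit(X.values, yv)
        lam = float(model.alpha_)

    coef = np.asarray(model.coef_, dtype=float)
    intercept = float(model.intercept_)
    residuals = yv - intercept - X.values @ coef
    return ResidualFit(
        intercept=intercept,
        coefficients=coef,
        residuals=residuals,
        mixing=mixing,
        penalty=lam,
        cv_folds=cv_folds,
        seed=seed,
    )


def assign_groups(
    values: np.ndarray,
    a: float = 0.5,
    basis: Literal["phenotype", "residual"] = "phenotype",
) -> GroupAssignment:
    """Split samples into low/high tails at the a and 1-a quantiles.

    For a < 0.5: low group = values <= empirical a-quantile, high group =
    values >= empirical (1-a)-quantile (linear-interpolation quantiles, the R
    type-7 convention); samples in between are unassigned.  For a = 0.5 the
    sample is rank-split into two halves so every sample belongs to exactly
    one group; with odd n the median sample goes to the low group.  Exact
    value ties are broken deterministically by index.
    """
    values = np.asarray(values, dtype=float).ravel()
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if not (0 < a <= 0.5):
        raise ValueError("a must lie in ]0, 0.5]")
    if np.all(values == values[0]):
        raise ValueError("all values identical: no truncation possible")
    n = values.shape[0]
    low = np.zeros(n, dtype=bool)
    high = np.zeros(n, dtype=bool)
    if a == 0.5:
        order = np.argsort(values, kind="stable")
        n_low = (n + 1) // 2
        low[order[:n_low]] = True
        high[order[n_low:]] = True
    else:
        q_low = np.quantile(values, a)
        q_high = np.quantile(values, 1 - a)
        low = values <= q_low
        high = values >= q_high
    return GroupAssignment(a=a, low_mask=low, high_mask=high, basis=basis)
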