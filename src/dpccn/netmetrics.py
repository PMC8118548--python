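"""Group-wise dependency matrices: correlation and truncated part-correlation.

The part-correlation of a gene pair (j, k) in a phenotype-truncated group is
the within-group Pearson correlation between the predictor column X_k and the
residual eps_{j|k} of the *full-sample* regression of X_j on X_k.  Removing
the full-sample linear relationship first restores the independence condition
that makes opposite-signed group dependencies diagnostic of a product-type
interaction, even when the two genes are strongly collinear to begin with.

Residual vectors are never materialized per pair: with the full-sample OLS
slope b_{jk} = cov(X_j, X_k)/var(X_k), every within-group moment of
eps_{j|k} = X_j - b_{jk} X_k - a_{jk} follows in closed form from the
within-group covariance matrix, so all p^2 entries are computed with a few
p x p matrix operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .io import ExpressionMatrix

__all__ = [
    "GroupNetwork",
    "PartResidualSet",
    "ZeroRule",
    "group_correlation",
    "part_residuals",
    "part_correlation",
    "part_correlation_pair",
    "is_zero",
    "zero_mask",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupNetwork:
    """A symmetric per-group dependency matrix with zeroed diagonal."""

    values: np.ndarray
    metric: Literal["correlation", "part_correlation"]
    group: Literal["low", "high", "full"]
    a: float = 0.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("group network must be square")
        if np.nanmax(np.abs(v)) > 1 + 1e-12:
            raise ValueError("dependency entries must lie in [-1, 1]")


@dataclass(frozen=True)
class ZeroRule:
    """Decision rule for declaring a dependency entry zero.

    ``hard_threshold`` zeroes any entry with magnitude below ``r``;
    ``bonferroni`` zeroes entries whose two-sided correlation t-test p-value
    exceeds ``alpha_level / n_tests``.
    """

    method: Literal["hard_threshold", "bonferroni"] = "hard_threshold"
    r: float = 0.1
    alpha_level: float = 0.05
    n_tests: int = 1

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("threshold r must be positive")
        if not (0 < self.alpha_level < 1):
            raise ValueError("alpha_level must lie in ]0, 1[")
        if self.n_tests < 1:
            raise ValueError("n_tests must be positive")


class PartResidualSet:
    """Full-sample pairwise OLS fits, with residuals available on demand.

    For each ordered pair (j, k) the slope and intercept of the regression of
    X_j on X_k over all n samples are stored as p x p matrices; the residual
    vector ``eps_{j|k}`` is reconstructed lazily from them so that memory
    stays O(p^2) rather than O(n p^2).
    """

    def __init__(self, X: ExpressionMatrix):
        if X.n < 4:
            raise ValueError("need at least 4 samples")
        self._X = X
        V = X.values
        self.means = V.mean(axis=0)
        C = np.cov(V, rowvar=False, ddof=1)
        var = np.diag(C).copy()
        if np.any(var == 0):
            raise ValueError("constant column in expression matrix")
        # slope[j, k]: regression of X_j (response) on X_k (predictor)
        self.slope = C / var[np.newaxis, :]
        self.intercept = self.means[:, np.newaxis] - self.slope * self.means[np.newaxis, :]
        self.cov = C
        self.var = var
        self.corr = C / np.sqrt(np.outer(var, var))

    @property
    def p(self) -> int:
        return self._X.p

    def residual(self, j: int, k: int) -> np.ndarray:
        """Residual vector eps_{j|k} of regressing X_j on X_k (full sample)."""
        V = self._X.values
        return V[:, j] - self.intercept[j, k] - self.slope[j, k] * V[:, k]


def group_correlation(
    X: ExpressionMatrix,
    mask: np.ndarray,
    group: Literal["low", "high", "full"] = "full",
    a: float = 0.5,
) -> GroupNetwork:
    """Pearson correlation matrix over the masked rows, re-centered in-group."""
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise ValueError("group must contain at least 4 samples")
    sub = X.values[mask]
    sd = sub.std(axis=0, ddof=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        names = [X.gene_names[i] for i in constant]
        raise ValueError(f"constant within group: {names}")
    corr = np.corrcoef(sub, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 0.0)
    return GroupNetwork(values=corr, metric="correlation", group=group, a=a)


def part_residuals(X: ExpressionMatrix) -> PartResidualSet:
    """Fit every ordered pairwise regression on the full (non-truncated) sample."""
    return PartResidualSet(X)


def _part_corr_raw(X: ExpressionMatrix, mask: np.ndarray, res: PartResidualSet) -> np.ndarray:
    """Asymmetric part-correlation matrix: entry [j, k] = cor_g(X_k, eps_{j|k}).

    Computed in closed form from the within-group covariance matrix S and the
    full-sample slopes b:

        cov_g(X_k, eps_{j|k}) = S[j,k] - b[j,k] S[k,k]
        var_g(eps_{j|k})      = S[j,j] - 2 b[j,k] S[j,k] + b[j,k]^2 S[k,k]
    """
    mask = np.asarray(mask, dtype=bool)
    n_g = int(mask.sum())
    if n_g < 4:
        raise ValueError("group must contain at least 4 samples")
    sub = X.values[mask]
    S = np.cov(sub, rowvar=False, ddof=1)
    v = np.diag(S).copy()
    b = res.slope
    cov_ke = S - b * v[np.newaxis, :]
    var_e = v[:, np.newaxis] - 2.0 * b * S + b ** 2 * v[np.newaxis, :]
    var_e = np.maximum(var_e, 0.0)
    denom = np.sqrt(var_e * v[np.newaxis, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = cov_ke / denom
    degenerate = denom == 0
    if degenerate.any():
        off_diag = degenerate.copy()
        np.fill_diagonal(off_diag, False)
        if off_diag.any():
            logger.warning(
                "zero-variance residual within group for %d pair(s); entries set to 0",
                int(off_diag.sum()),
            )
        phi[degenerate] = 0.0
    phi = np.clip(phi, -1.0, 1.0)
    np.fill_diagonal(phi, 0.0)
    return phi


def _symmetrize(phi: np.ndarray, orientation: str, other: np.ndarray | None = None):
    """Collapse the two orientations of an asymmetric part-correlation matrix."""
    if orientation == "average":
        return (phi + phi.T) / 2.0
    if orientation == "max_diff":
        if other is None:
            raise ValueError("max_diff orientation needs both group matrices")
        diff = np.abs(phi - other)
        use_transpose = diff.T > diff
        out = np.where(use_transpose, phi.T, phi)
        return np.triu(out, 1) + np.triu(out, 1).T
    raise ValueError(f"unknown orientation {orientation!r}")


def part_correlation(
    X: ExpressionMatrix,
    mask: np.ndarray,
    residuals: PartResidualSet,
    orientation: Literal["average"] = "average",
) -> GroupNetwork:
    """Truncated part-correlation matrix for one group, averaged symmetrization.

    For the paired ``max_diff`` orientation rule (which needs both groups at
    once) use :func:`part_correlation_pair`.
    """
    phi = _part_corr_raw(X, mask, residuals)
    sym = _symmetrize(phi, orientation)
    np.fill_diagonal(sym, 0.0)
    return GroupNetwork(values=sym, metric="part_correlation", group="full")


def part_correlation_pair(
    X: ExpressionMatrix,
    high_mask: np.ndarray,
    low_mask: np.ndarray,
    residuals: PartResidualSet,
    orientation: Literal["max_diff", "average"] = "max_diff",
    a: float = 0.5,
) -> tuple[GroupNetwork, GroupNetwork]:
    """High and low truncated part-correlation matrices, jointly symmetrized.

    Entry [j, k] of the raw matrix is cor_g(X_k, eps_{j|k}); the two
    orientations (j on k vs k on j) generally differ.  Under ``max_diff`` the
    orientation with the larger |high - low| gap is used for *both* group
    matrices of a pair, which keeps the two entries mutually consistent for
    the downstream sign logic; ``average`` simply averages the orientations
    per group.
    """
    phi_high = _part_corr_raw(X, high_mask, residuals)
    phi_low = _part_corr_raw(X, low_mask, residuals)
    if orientation == "average":
        h = _symmetrize(phi_high, "average")
        l = _symmetrize(phi_low, "average")
    else:
        diff = np.abs(phi_high - phi_low)
        use_transpose = diff.T > diff
        h = np.where(use_transpose, phi_high.T, phi_high)
        l = np.where(use_transpose, phi_low.T, phi_low)
        h = np.triu(h, 1) + np.triu(h, 1).T
        l = np.triu(l, 1) + np.triu(l, 1).T
    np.fill_diagonal(h, 0.0)
    np.fill_diagonal(l, 0.0)
    high = GroupNetwork(values=h, metric="part_correlation", group="high", a=a)
    low = GroupNetwork(values=l, metric="part_correlation", group="low", a=a)
    return high, low


def _bonferroni_p(value: float | np.ndarray, n_group: int) -> np.ndarray:
    v = np.clip(np.asarray(value, dtype=float), -1 + 1e-15, 1 - 1e-15)
    t = v * np.sqrt(n_group - 2) / np.sqrt(1.0 - v ** 2)
    return 2.0 * stats.t.sf(np.abs(t), df=n_group - 2)


def is_zero(value: float, rule: ZeroRule, n_group: int) -> bool:
    """Decide whether a dependency entry is to be treated as zero."""
    if abs(value) > 1 + 1e-12:
        raise ValueError("correlation-type value outside [-1, 1]")
    if rule.method == "hard_threshold":
        return bool(abs(value) < rule.r)
    if n_group < 3:
        raise ValueError("bonferroni rule needs a group of at least 3")
    p = float(_bonferroni_p(value, n_group))
    return p > rule.alpha_level / rule.n_tests


def zero_mask(values: np.ndarray, rule: ZeroRule, n_group: int) -> np.ndarray:
    """Vectorized :func:`is_zero` over a matrix of dependency entries."""
    values = np.asarray(values, dtype=float)
    if rule.method == "hard_threshold":
        return np.abs(values) < rule.r
    if n_group < 3:
        raise ValueError("bonferroni rule needs a group of at least 3")
    return _bonferroni_p(values, n_group) > rule.alpha_level / rule.n_tests


def write_network_tsv(net: GroupNetwork, gene_names, path) -> None:
    """Dump a group network as a square TSV with a gene-name header."""
    import pandas as pd

    pd.DataFrame(net.values, index=list(gene_names), columns=list(gene_names)).to_csv(
        path, sep="\t", float_format="%.12g"
    )
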