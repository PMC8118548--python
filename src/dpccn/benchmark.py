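"""ROC/AUC evaluation and the reference methods for recovery benchmarks.

Scores every unordered gene pair, sweeps a decision threshold over the score
range, and summarizes recovery of the simulated true interaction pairs as the
area under the ROC curve plus a truncated (partial) AUC at a false-positive
bound, normalized by the bound so a perfect classifier scores 1.

Reference methods: the sign-adjusted differential correlation network (dCCN)
and an exhaustive penalized search — L1-penalized regression of the phenotype
on all main-effect columns plus all p(p-1)/2 standardized product columns,
scoring each pair by the magnitude of its product-term coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import KFold

from .diffnet import model_diffnet
from .io import ExpressionMatrix, PhenotypeVector, standardize
from .netmetrics import ZeroRule
from .simulate import (
    BackboneSpec,
    SimulationTruth,
    generate_backbone,
    simulate_model_A,
    simulate_model_B,
)

__all__ = [
    "RocResult",
    "roc",
    "partial_auc",
    "exhaustive_lasso",
    "run_benchmark",
    "pair_scores",
]

METHODS = ("sign_dPCCN", "sign_dCCN", "exhaustive_lasso")


@dataclass(frozen=True)
class RocResult:
    """An ROC curve with its full and truncated areas."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    pauc_bound: float
    pauc_normalized: float


def roc(
    scores: np.ndarray,
    positive: np.ndarray,
    pauc_bound: float = 0.2,
) -> RocResult:
    """ROC curve over per-pair scores against a boolean truth indicator.

    The threshold sweeps the distinct score values (ties grouped); FPR is
    false positives over the number of negative pairs.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    if scores.shape != positive.shape:
        raise ValueError("scores and truth lengths differ")
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise ValueError("need at least one positive pair")
    if n_pos == positive.size:
        raise ValueError("need at least one negative pair")
    fpr, tpr, _ = _sk_roc_curve(positive.astype(int), scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pauc = _partial_auc_from_curve(fpr, tpr, pauc_bound)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, pauc_bound=pauc_bound,
                     pauc_normalized=pauc)


def _partial_auc_from_curve(fpr: np.ndarray, tpr: np.ndarray, bound: float) -> float:
    if not (0 < bound <= 1):
        raise ValueError("bound must lie in ]0, 1]")
    # keep the actual curve vertices up to the bound (repeated fpr values
    # mark vertical segments and must not be interpolated away), then close
    # the region with an interpolated point exactly at the bound
    keep = fpr <= bound
    grid, tpr_grid = fpr[keep], tpr[keep]
    if grid.size == 0 or grid[-1] < bound:
        grid = np.append(grid, bound)
        tpr_grid = np.append(tpr_grid, np.interp(bound, fpr, tpr))
    area = float(np.trapezoid(tpr_grid, grid))
    # standardized partial AUC (McClish): chance maps to 0.5, perfect to 1,
    # and at bound = 1 it reduces exactly to the full AUC
    a_min = bound**2 / 2.0
    a_max = bound
    return 0.5 * (1.0 + (area - a_min) / (a_max - a_min))


def partial_auc(result: RocResult, bound: float = 0.2) -> float:
    """Standardized truncated AUC over FPR in [0, bound].

    Uses the McClish transformation of the raw partial area, so a chance-level
    classifier scores 0.5 and a perfect one 1.0 at any bound, and
    ``partial_auc(res, 1.0) == res.auc`` exactly.
    """
    return _partial_auc_from_curve(result.fpr, result.tpr, bound)


def pair_scores(net) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Flatten a differential network into (pair list, |Q_sgn| score vector)."""
    return net.pairs(), net.edge_scores()


def truth_indicator(
    pairs: Sequence[tuple[int, int]], positives: Iterable[tuple[int, int]]
) -> np.ndarray:
    pos = {(min(j, k), max(j, k)) for j, k in positives}
    return np.array([(min(j, k), max(j, k)) in pos for j, k in pairs], dtype=bool)


def exhaustive_lasso(
    X: ExpressionMatrix,
    y: PhenotypeVector,
    cv_folds: int = 10,
    seed: int = 0,
    max_pairs: int = 50_000,
    n_alphas: int = 60,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Exhaustive product-term search with an L1 penalty.

    Design matrix: all p main-effect columns plus all p(p-1)/2 product
    columns, each product z-scored; lambda picked by K-fold cross-validation.
    Pair score = |coefficient of the product term|.
    """
    n_pairs = X.p * (X.p - 1) // 2
    if n_pairs > max_pairs:
        raise MemoryError(
            f"{n_pairs} product columns exceed the cap of {max_pairs}; "
            "raise max_pairs explicitly to proceed"
        )
    Xs = X if X.standardized else standardize(X)
    V = Xs.values
    pairs = list(combinations(range(X.p), 2))
    prods = np.empty((X.n, n_pairs))
    for idx, (j, k) in enumerate(pairs):
        prods[:, idx] = V[:, j] * V[:, k]
    sd = prods.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    prods = (prods - prods.mean(axis=0)) / sd
    design = np.hstack([V, prods])
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    model = LassoCV(cv=cv, alphas=n_alphas, fit_intercept=True, max_iter=20_000)
    model.fit(design, y.values)
    scores = np.abs(model.coef_[X.p:])
    return pairs, scores


def _method_scores(
    method: str,
    X: ExpressionMatrix,
    y: PhenotypeVector,
    a: float,
    rule: ZeroRule,
    residual_adjust: bool,
    mixing: float,
    cv_folds: int,
    seed: int,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    if method == "sign_dPCCN":
        net = model_diffnet(X, y, a=a, metric="dPCCN", residual_adjust=residual_adjust,
                            rule=rule, mixing=mixing, cv_folds=cv_folds, seed=seed)
        return net.pairs(), net.edge_scores()
    if method == "sign_dCCN":
        net = model_diffnet(X, y, a=a, metric="dCCN", residual_adjust=residual_adjust,
                            rule=rule, mixing=mixing, cv_folds=cv_folds, seed=seed)
        return net.pairs(), net.edge_scores()
    if method == "exhaustive_lasso":
        return exhaustive_lasso(X, y, cv_folds=cv_folds, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def run_benchmark(
    methods: Sequence[str] = METHODS,
    backbone: BackboneSpec | ExpressionMatrix = BackboneSpec(),
    model: Literal["A", "B"] = "A",
    replicates: int = 10,
    seed: int = 0,
    a: float = 0.5,
    rule: ZeroRule | None = None,
    pauc_bound: float = 0.2,
    mixing: float = 1 / 3,
    cv_folds: int = 10,
    layout=None,
) -> pd.DataFrame:
    """Mean full and truncated AUCs per method over simulated replicates.

    The backbone is fixed; each replicate re-simulates the phenotype (and the
    phenotype-dependent expression overwrites).  Model A scores pairs against
    groups on the raw phenotype (no residual adjustment); Model B applies the
    residual adjustment first.  Positives are all simulated interaction pairs
    regardless of type.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    X0 = backbone if isinstance(backbone, ExpressionMatrix) else generate_backbone(backbone)
    if rule is None:
        rule = ZeroRule(method="hard_threshold", r=0.1, n_tests=X0.p * (X0.p - 1))
    residual_adjust = model == "B"
    root = np.random.default_rng(seed)
    rep_seeds = root.integers(2 ** 31, size=replicates)

    rows = {m: {"auc": [], "pauc": []} for m in methods}
    for rep, rep_seed in enumerate(rep_seeds):
        if model == "A":
            y, truth, X_rep = simulate_model_A(X0, seed=int(rep_seed), layout=layout)
        else:
            y, truth, X_rep = simulate_model_B(X0, seed=int(rep_seed), layout=layout)
        positives = truth.positive_pairs()
        for method in methods:
            pairs, scores = _method_scores(
                method, X_rep, y, a, rule, residual_adjust, mixing, cv_folds,
                seed=int(rep_seed),
            )
            indicator = truth_indicator(pairs, positives)
            result = roc(scores, indicator, pauc_bound=pauc_bound)
            rows[method]["auc"].append(result.auc)
            rows[method]["pauc"].append(result.pauc_normalized)
    table = pd.DataFrame(
        {
            "method": list(methods),
            f"auc_{pauc_bound:g}_fpr": [float(np.mean(rows[m]["pauc"])) for m in methods],
            "auc_full": [float(np.mean(rows[m]["auc"])) for m in methods],
        }
    )
    table.insert(1, "model", model)
    return table
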