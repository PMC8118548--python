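"""Differential networks, sign adjustment and interaction-type labels.

The differential network is Q = |Phi_high - Phi_low| elementwise.  Its
sign-adjusted version Q_sgn = Q * Pi(Phi_high, Phi_low) encodes the parametric
interpretation of each edge:

* Pi = +1 when both group entries are nonzero with opposite signs — evidence
  of a product-type ("type I") interaction in the underlying additive model;
* Pi = -1 when exactly one group entry is nonzero — evidence of a one-sided
  activation/deactivation ("type II") interaction;
* Pi = 0 when both entries are zero — no interaction evidence.

A dependency entry counts as zero under a configurable rule (hard threshold
or Bonferroni-corrected correlation test).  The both-nonzero-same-sign
pattern indicates a phenotype-independent association and maps to Pi = 0 by
default (configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .io import EdgeRecord, ExpressionMatrix, PhenotypeVector, standardize
from .netmetrics import (
    GroupNetwork,
    ZeroRule,
    group_correlation,
    part_correlation_pair,
    part_residuals,
    zero_mask,
)
from .residualize import GroupAssignment, ResidualFit, assign_groups, fit_main_effects

__all__ = [
    "DifferentialNetwork",
    "differential",
    "pi_value",
    "sign_adjust",
    "sparsify",
    "model_diffnet",
]

LABELS = ("type_I", "type_II", "none")
SameSignPolicy = Literal["zero", "keep_positive"]


@dataclass
class DifferentialNetwork:
    """A differential co-expression network with per-edge interaction labels."""

    q: np.ndarray
    q_signed: np.ndarray
    labels: np.ndarray  # dtype <U7, entries in LABELS
    metric: Literal["dCCN", "dPCCN"]
    a: float
    zero_rule: ZeroRule
    residual_adjusted: bool
    gene_names: tuple[str, ...] = ()
    # intermediate objects, retrievable for inspection
    groups: GroupAssignment | None = None
    high: GroupNetwork | None = None
    low: GroupNetwork | None = None
    fit: ResidualFit | None = None

    @property
    def p(self) -> int:
        return self.q.shape[0]

    def edge_scores(self) -> np.ndarray:
        """Per-pair ranking score |Q_sgn| over the upper triangle."""
        iu = np.triu_indices(self.p, 1)
        return np.abs(self.q_signed[iu])

    def pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.p, 1)
        return list(zip(iu[0].tolist(), iu[1].tolist()))


def differential(high: GroupNetwork, low: GroupNetwork) -> np.ndarray:
    """Elementwise |high - low| of two same-metric group networks."""
    if high.metric != low.metric:
        raise ValueError(f"metric mismatch: {high.metric} vs {low.metric}")
    if high.values.shape != low.values.shape:
        raise ValueError("group networks differ in shape")
    return np.abs(high.values - low.values)


def pi_value(
    phi_high: float,
    phi_low: float,
    rule: ZeroRule,
    n_high: int,
    n_low: int,
    same_sign: SameSignPolicy = "zero",
) -> int:
    """Sign-adjustment value for a single pair: one of {-1, 0, +1}."""
    from .netmetrics import is_zero

    zh = is_zero(phi_high, rule, n_high)
    zl = is_zero(phi_low, rule, n_low)
    if zh and zl:
        return 0
    if zh != zl:
        return -1
    if np.sign(phi_high) == -np.sign(phi_low):
        return 1
    return 1 if same_sign == "keep_positive" else 0


def _pi_matrix(
    high: np.ndarray,
    low: np.ndarray,
    rule: ZeroRule,
    n_high: int,
    n_low: int,
    same_sign: SameSignPolicy,
) -> np.ndarray:
    zh = zero_mask(high, rule, n_high)
    zl = zero_mask(low, rule, n_low)
    pi = np.zeros(high.shape, dtype=int)
    one_sided = zh != zl
    pi[one_sided] = -1
    both = ~zh & ~zl
    opposite = both & (np.sign(high) == -np.sign(low))
    pi[opposite] = 1
    if same_sign == "keep_positive":
        pi[both & ~opposite] = 1
    return pi


def sign_adjust(
    high: GroupNetwork,
    low: GroupNetwork,
    rule: ZeroRule,
    n_high: int,
    n_low: int,
    a: float = 0.5,
    residual_adjusted: bool = False,
    same_sign: SameSignPolicy = "zero",
    gene_names: Sequence[str] = (),
) -> DifferentialNetwork:
    """Build the sign-adjusted differential network and its edge labels."""
    q = differential(high, low)
    pi = _pi_matrix(high.values, low.values, rule, n_high, n_low, same_sign)
    q_signed = q * pi
    labels = np.full(q.shape, "none", dtype="<U7")
    labels[q_signed > 0] = "type_I"
    labels[q_signed < 0] = "type_II"
    np.fill_diagonal(labels, "none")
    metric = "dPCCN" if high.metric == "part_correlation" else "dCCN"
    return DifferentialNetwork(
        q=q,
        q_signed=q_signed,
        labels=labels,
        metric=metric,
        a=a,
        zero_rule=rule,
        residual_adjusted=residual_adjusted,
        gene_names=tuple(gene_names),
        high=high,
        low=low,
    )


def sparsify(net: DifferentialNetwork, max_edges_per_type: int = 70) -> list[EdgeRecord]:
    """Keep, per interaction type, the edges with largest |Q_sgn| up to a cap.

    Unlabeled ("none") pairs never produce edges.  Ties are broken by the
    lexicographic gene-name pair, so output is deterministic.
    """
    if max_edges_per_type < 1:
        raise ValueError("max_edges_per_type must be at least 1")
    names = net.gene_names or tuple(f"g{i + 1}" for i in range(net.p))
    records: list[EdgeRecord] = []
    iu = np.triu_indices(net.p, 1)
    for label in ("type_I", "type_II"):
        hits = [
            (abs(net.q_signed[j, k]), names[j], names[k], j, k)
            for j, k in zip(*iu)
            if net.labels[j, k] == label
        ]
        hits.sort(key=lambda h: (-h[0], h[1], h[2]))
        for _, ga, gb, j, k in hits[:max_edges_per_type]:
            records.append(
                EdgeRecord(
                    gene_a=ga,
                    gene_b=gb,
                    q_value=float(net.q[j, k]),
                    q_signed=float(net.q_signed[j, k]),
                    label=label,
                )
            )
    records.sort(key=lambda e: (-abs(e.q_signed), e.gene_a, e.gene_b))
    return records


def model_diffnet(
    X: ExpressionMatrix,
    y: PhenotypeVector,
    a: float = 0.5,
    metric: Literal["dPCCN", "dCCN"] = "dPCCN",
    residual_adjust: bool = True,
    rule: ZeroRule | None = None,
    mixing: float = 1 / 3,
    cv_folds: int = 10,
    seed: int = 0,
    orientation: Literal["max_diff", "average"] = "max_diff",
    same_sign: SameSignPolicy = "zero",
) -> DifferentialNetwork:
    """End-to-end trait-specific differential network estimation.

    Pipeline: z-score columns on the full sample; optionally residualize the
    phenotype against all main effects (elastic net); split samples into
    low/high tails at the a / 1-a quantiles of the phenotype or residual;
    estimate the two group networks with the chosen metric; difference and
    sign-adjust them into interaction-type labels.
    """
    if not (0 < a <= 0.5):
        raise ValueError("truncation point a must lie in ]0, 0.5]")
    if rule is None:
        rule = ZeroRule(method="hard_threshold", r=0.1,
                        n_tests=X.p * (X.p - 1))
    if y.values.shape[0] != X.n:
        raise ValueError("phenotype length does not match expression rows")
    Xs = X if X.standardized else standardize(X)

    fit: ResidualFit | None = None
    if residual_adjust:
        fit = fit_main_effects(Xs, y, mixing=mixing, cv_folds=cv_folds, seed=seed)
        basis_values, basis = fit.residuals, "residual"
    else:
        basis_values, basis = y.values, "phenotype"
    groups = assign_groups(basis_values, a=a, basis=basis)

    if metric == "dPCCN":
        res = part_residuals(Xs)
        high, low = part_correlation_pair(
            Xs, groups.high_mask, groups.low_mask, res, orientation=orientation, a=a
        )
    elif metric == "dCCN":
        high = group_correlation(Xs, groups.high_mask, group="high", a=a)
        low = group_correlation(Xs, groups.low_mask, group="low", a=a)
    else:
        raise ValueError(f"unknown metric {metric!r}")

    net = sign_adjust(
        high,
        low,
        rule,
        n_high=groups.n_high,
        n_low=groups.n_low,
        a=a,
        residual_adjusted=residual_adjust,
        same_sign=same_sign,
        gene_names=Xs.gene_names,
    )
    net.groups = groups
    net.fit = fit
    return net
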