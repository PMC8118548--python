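"""Parametric and survival follow-up of estimated network edges.

Once the differential network nominates candidate interactions, they are
validated back in the parametric world:

* type-I candidates via the Aiken-West moderation test — OLS of the outcome
  on both genes and their product, requiring the product-term p-value to beat
  both main-effect p-values and a significance level;
* prognostic value via quantile risk grouping on the interaction product,
  a combined two-pair classifier, Kaplan-Meier curves and the log-rank test.

Censored observations are dropped before OLS (the log-rank step handles them
properly).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .io import SurvivalDataset

__all__ = [
    "InteractionTestResult",
    "RiskGroups",
    "KaplanMeierResult",
    "aiken_west",
    "risk_classify",
    "combine_risk",
    "kaplan_meier",
    "log_rank",
]


@dataclass(frozen=True)
class InteractionTestResult:
    """Aiken-West moderation test output for one gene pair."""

    beta_k: float
    beta_l: float
    beta_kl: float
    p_k: float
    p_l: float
    p_kl: float
    relevant: bool


@dataclass(frozen=True)
class RiskGroups:
    """Per-sample risk labels from a quantile split of an interaction term."""

    assignment: np.ndarray  # entries in {"low_risk", "high_risk", "excluded"}
    q: float
    direction: int

    def mask(self, label: str) -> np.ndarray:
        return self.assignment == label

    def __len__(self) -> int:
        return self.assignment.shape[0]


@dataclass(frozen=True)
class KaplanMeierResult:
    """Product-limit survival estimate for one group."""

    timeline: np.ndarray
    survival: np.ndarray
    median: float  # inf when S(t) never reaches 0.5
    n: int
    n_events: int


def aiken_west(
    xk: np.ndarray,
    xl: np.ndarray,
    y: np.ndarray,
    alpha_level: float = 0.05,
) -> InteractionTestResult:
    """Moderation test: OLS of y on x_k, x_l and their product, with intercept.

    The interaction is deemed relevant when its two-sided t-test p-value is
    below ``alpha_level`` *and* below both main-effect p-values.
    """
    xk = np.asarray(xk, dtype=float).ravel()
    xl = np.asarray(xl, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if not (xk.shape == xl.shape == y.shape):
        raise ValueError("inputs must have equal length")
    if y.shape[0] < 5:
        raise ValueError("need at least 5 observations")
    design = sm.add_constant(np.column_stack([xk, xl, xk * xl]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear design: interaction test is not identified")
    fit = sm.OLS(y, design).fit()
    p_k, p_l, p_kl = fit.pvalues[1], fit.pvalues[2], fit.pvalues[3]
    relevant = bool(p_kl < p_k and p_kl < p_l and p_kl < alpha_level)
    return InteractionTestResult(
        beta_k=float(fit.params[1]),
        beta_l=float(fit.params[2]),
        beta_kl=float(fit.params[3]),
        p_k=float(p_k),
        p_l=float(p_l),
        p_kl=float(p_kl),
        relevant=relevant,
    )


def risk_classify(
    interaction_values: np.ndarray,
    effect_sign: Literal["+", "-"] | int = "+",
    q: float = 2 / 3,
) -> RiskGroups:
    """Quantile risk grouping on an interaction term's per-patient values.

    With a positive (risk-increasing) effect, patients below the q-quantile
    of the term are low risk; with a negative effect, patients above the
    (1-q)-quantile are low risk.  Ties at the threshold go to high risk.
    """
    values = np.asarray(interaction_values, dtype=float).ravel()
    if not (0 < q < 1):
        raise ValueError("q must lie in ]0, 1[")
    if np.all(values == values[0]):
        raise ValueError("constant interaction values cannot be split")
    direction = 1 if effect_sign in ("+", 1) else -1
    if direction == 1:
        low = values < np.quantile(values, q)
    else:
        low = values > np.quantile(values, 1 - q)
    assignment = np.where(low, "low_risk", "high_risk").astype("<U9")
    return RiskGroups(assignment=assignment, q=q, direction=direction)


def combine_risk(g1: RiskGroups, g2: RiskGroups) -> RiskGroups:
    """Intersect two classifiers: concordant labels survive, others excluded."""
    if len(g1) != len(g2):
        raise ValueError("risk groups cover different cohorts")
    out = np.full(len(g1), "excluded", dtype="<U9")
    both_low = (g1.assignment == "low_risk") & (g2.assignment == "low_risk")
    both_high = (g1.assignment == "high_risk") & (g2.assignment == "high_risk")
    out[both_low] = "low_risk"
    out[both_high] = "high_risk"
    return RiskGroups(assignment=out, q=g1.q, direction=0)


def kaplan_meier(
    data: SurvivalDataset, groups: RiskGroups
) -> dict[str, KaplanMeierResult]:
    """Product-limit survival estimate per risk group (excluded rows dropped).

    The median is the first time at which S(t) <= 0.5, infinite when the
    curve never reaches it.
    """
    if len(data) != len(groups):
        raise ValueError("survival data and risk groups cover different cohorts")
    out: dict[str, KaplanMeierResult] = {}
    for label in ("low_risk", "high_risk"):
        mask = groups.mask(label)
        if not mask.any():
            raise ValueError(f"empty group: {label}")
        t, e = data.time[mask], data.event[mask]
        km = KaplanMeierFitter()
        km.fit(t, event_observed=e)
        timeline = km.survival_function_.index.to_numpy(dtype=float)
        survival = km.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        median = float(km.median_survival_time_)
        out[label] = KaplanMeierResult(
            timeline=timeline,
            survival=survival,
            median=median,
            n=int(mask.sum()),
            n_events=int(e.sum()),
        )
    return out


def log_rank(data: SurvivalDataset, groups: RiskGroups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    if len(data) != len(groups):
        raise ValueError("survival data and risk groups cover different cohorts")
    low = groups.mask("low_risk")
    high = groups.mask("high_risk")
    if not low.any() or not high.any():
        raise ValueError("log-rank requires two non-empty groups")
    res = logrank_test(
        data.time[low], data.time[high],
        event_observed_A=data.event[low], event_observed_B=data.event[high],
    )
    return float(res.test_statistic), float(res.p_value)
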