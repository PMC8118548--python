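"""Synthetic expression backbones and phenotype simulation with ground truth.

The generator emulates a reverse-phase protein-array style dataset: n
individuals by p proteins with standard-normal marginals (defaults n=191,
p=231) and optional block correlation structure.  Phenotypes follow two
additive interaction models:

* Model A — six product ("type I") interaction terms, two rectified
  linear-unit (ReLU) activation terms, Gaussian noise (sd 1.75), no main
  effects; plus six disrupted co-expression (C+/-) pairs written into the
  expression matrix for individuals in the upper phenotype tail, and two
  collinearity inductions (r ~ 0.95) on top of product-term pairs.
* Model B — Model A plus six strong main effects (coefficient 2) and an
  additional independent noise term.

Ground truth (which pairs carry which effect) is returned alongside so
benchmarks can score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np

from .io import ExpressionMatrix, PhenotypeVector, standardize

__all__ = [
    "BackboneSpec",
    "ModelLayout",
    "SimulationTruth",
    "paper_layout",
    "scaled_layout",
    "generate_backbone",
    "relu_term",
    "apply_collinearity",
    "apply_disruption",
    "simulate_model_A",
    "simulate_model_B",
    "write_replicate",
]


@dataclass(frozen=True)
class BackboneSpec:
    """Shape and correlation structure of a simulated expression backbone."""

    n: int = 191
    p: int = 231
    structure: str = "independent"  # or "block"
    block_size: int = 10
    rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("need n >= 8")
        if self.p < 2:
            raise ValueError("need p >= 2")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1[")
        if self.structure not in ("independent", "block"):
            raise ValueError(f"unknown structure {self.structure!r}")


@dataclass(frozen=True)
class ModelLayout:
    """Index sets (0-based) defining where the simulated effects sit."""

    type1_pairs: tuple[tuple[int, int], ...]
    relu_pairs: tuple[tuple[int, int], ...]
    disrupted_pairs: tuple[tuple[int, int, int], ...]  # (j, k, sign)
    collinear_pairs: tuple[tuple[int, int], ...]  # (target, source)
    main_effect_indices: tuple[int, ...]
    main_effect_beta: float = 2.0


def paper_layout() -> ModelLayout:
    """The canonical index layout for a p >= 231 backbone (1-based in prose).

    Type-I product pairs (75,150), (100,200), (125,215), (25,52), (33,66),
    (88,144); ReLU pairs (12,183), (109,54); disrupted pairs C-(2,170),
    C-(50,115), C-(44,99), C+(12,180), C+(60,125), C+(211,222); collinearity
    overwrites X125 <- X215 and X75 <- X150; Model-B main effects on genes
    {10, 30, 50, 70, 90, 100} with coefficient 2.
    """
    z = lambda i: i - 1
    return ModelLayout(
        type1_pairs=tuple(
            (z(a), z(b)) for a, b in [(75, 150), (100, 200), (125, 215),
                                      (25, 52), (33, 66), (88, 144)]
        ),
        relu_pairs=((z(12), z(183)), (z(109), z(54))),
        disrupted_pairs=tuple(
            (z(a), z(b), s)
            for a, b, s in [(2, 170, -1), (50, 115, -1), (44, 99, -1),
                            (12, 180, +1), (60, 125, +1), (211, 222, +1)]
        ),
        collinear_pairs=((z(125), z(215)), (z(75), z(150))),
        main_effect_indices=tuple(z(i) for i in (10, 30, 50, 70, 90, 100)),
    )


def scaled_layout(p: int) -> ModelLayout:
    """A deterministic remapping of the canonical layout into p < 231 genes.

    Keeps the same effect counts (6 product pairs, 2 ReLU pairs, 6 disrupted
    pairs, 2 collinearity overwrites on product-pair members, 6 main effects)
    on disjoint low indices, with main effects on the last six columns.
    Requires p >= 34.
    """
    if p >= 231:
        return paper_layout()
    if p < 34:
        raise ValueError("scaled layout needs p >= 34")
    type1 = tuple((2 * i, 2 * i + 1) for i in range(6))            # 0..11
    relu = ((12, 13), (14, 15))
    signs = (-1, -1, -1, +1, +1, +1)
    disrupted = tuple((16 + 2 * i, 17 + 2 * i, s) for i, s in enumerate(signs))  # 16..27
    collinear = ((0, 1), (2, 3))  # overwrite one member of two product pairs
    mains = tuple(range(p - 6, p))
    return ModelLayout(
        type1_pairs=type1,
        relu_pairs=relu,
        disrupted_pairs=disrupted,
        collinear_pairs=collinear,
        main_effect_indices=mains,
    )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth effect locations and settings of a simulated phenotype."""

    type1_pairs: tuple[tuple[int, int], ...]
    relu_pairs: tuple[tuple[int, int], ...]
    disrupted_pairs: tuple[tuple[int, int, int], ...]
    collinear_pairs: tuple[tuple[int, int], ...]
    main_effects: dict = field(default_factory=dict)
    noise_sd: float = 1.75
    disruption_quantile: float = 4 / 5
    disruption_noise_sd: float = 0.25

    def positive_pairs(self) -> set[tuple[int, int]]:
        """All true interaction pairs as canonically ordered (j < k) tuples."""
        pairs = set()
        for j, k in self.type1_pairs:
            pairs.add((min(j, k), max(j, k)))
        for j, k in self.relu_pairs:
            pairs.add((min(j, k), max(j, k)))
        for j, k, _ in self.disrupted_pairs:
            pairs.add((min(j, k), max(j, k)))
        return pairs

    def to_json(self) -> str:
        return json.dumps(
            {
                "type1_pairs": [list(t) for t in self.type1_pairs],
                "relu_pairs": [list(t) for t in self.relu_pairs],
                "disrupted_pairs": [list(t) for t in self.disrupted_pairs],
                "collinear_pairs": [list(t) for t in self.collinear_pairs],
                "main_effects": {str(k): v for k, v in self.main_effects.items()},
                "noise_sd": self.noise_sd,
                "disruption_quantile": self.disruption_quantile,
                "disruption_noise_sd": self.disruption_noise_sd,
            },
            indent=2,
        )


def generate_backbone(spec: BackboneSpec) -> ExpressionMatrix:
    """Simulate an n x p expression backbone with standard-normal marginals.

    Block structure uses the one-factor construction
    X = sqrt(rho) * F_block + sqrt(1 - rho) * E, which gives exact
    within-block correlation rho and unit marginal variance.  Columns are
    z-scored on the simulated sample afterwards.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.structure == "independent" or spec.rho == 0:
        values = rng.standard_normal((spec.n, spec.p))
    else:
        values = np.empty((spec.n, spec.p))
        for start in range(0, spec.p, spec.block_size):
            stop = min(start + spec.block_size, spec.p)
            f = rng.standard_normal((spec.n, 1))
            e = rng.standard_normal((spec.n, stop - start))
            values[:, start:stop] = np.sqrt(spec.rho) * f + np.sqrt(1 - spec.rho) * e
    X = ExpressionMatrix(
        values=values,
        gene_names=[f"g{i + 1}" for i in range(spec.p)],
        sample_ids=[f"s{i + 1}" for i in range(spec.n)],
    )
    return standardize(X)


def relu_term(xj: np.ndarray, xk: np.ndarray) -> np.ndarray:
    """Rectified product: X_j*X_k where it reaches its empirical median, else 0."""
    xj = np.asarray(xj, dtype=float)
    xk = np.asarray(xk, dtype=float)
    if xj.shape != xk.shape:
        raise ValueError("vectors must have equal length")
    prod = xj * xk
    med = np.median(prod)
    return np.where(prod >= med, prod, 0.0)


def apply_collinearity(
    X: ExpressionMatrix,
    pairs: tuple[tuple[int, int], ...],
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ExpressionMatrix:
    """Overwrite target columns as source + noise to induce strong correlation.

    With a unit-variance source and noise_sd = 0.25 the induced correlation is
    (1 + 0.0625)^(-1/2) ~ 0.97.  Applied to all rows, before any phenotypic
    truncation.
    """
    targets = [t for t, _ in pairs]
    if len(set(targets)) != len(targets):
        raise ValueError("overlapping collinearity targets")
    rng = np.random.default_rng(seed)
    out = X.values.copy()
    for target, source in pairs:
        if target == source:
            raise ValueError("pair members must be distinct")
        out[:, target] = out[:, source] + rng.normal(0.0, noise_sd, X.n)
    return X.with_values(out, standardized=False)


def apply_disruption(
    X: ExpressionMatrix,
    y: np.ndarray,
    pairs_with_sign: tuple[tuple[int, int, int], ...],
    cut_quantile: float = 4 / 5,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ExpressionMatrix:
    """Write a C+/- disrupted co-expression pattern into the upper tail.

    For rows whose phenotype is at or above the empirical ``cut_quantile`` of
    y, the *second* member of each pair is overwritten as
    sign * (first member) + noise.  Other rows and columns are untouched; y
    itself is never recomputed.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    if not (0 < cut_quantile <= 1):
        raise ValueError("cut_quantile must lie in ]0, 1]")
    out = X.values.copy()
    if cut_quantile == 1:  # degenerate: empty upper tail
        return X.with_values(out)
    rows = y >= np.quantile(y, cut_quantile)
    rng = np.random.default_rng(seed)
    for j, k, sign in pairs_with_sign:
        out[rows, k] = sign * out[rows, j] + rng.normal(0.0, noise_sd, int(rows.sum()))
    return X.with_values(out, standardized=False)


def _simulate(
    X: ExpressionMatrix,
    seed: int,
    noise_sd: float,
    layout: ModelLayout | None,
    with_main_effects: bool,
    extra_noise: bool,
    cut_quantile: float,
    disruption_noise_sd: float,
    collinear_noise_sd: float,
    collinear_first: bool,
) -> tuple[PhenotypeVector, SimulationTruth, ExpressionMatrix]:
    if layout is None:
        layout = paper_layout() if X.p >= 231 else scaled_layout(X.p)
    max_idx = max(
        [i for pair in layout.type1_pairs for i in pair]
        + [i for pair in layout.relu_pairs for i in pair]
        + [i for j, k, _ in layout.disrupted_pairs for i in (j, k)]
        + [i for pair in layout.collinear_pairs for i in pair]
        + list(layout.main_effect_indices)
    )
    if max_idx >= X.p:
        raise ValueError(f"layout index {max_idx} out of range for p={X.p}")
    rng = np.random.default_rng(seed)
    sub = rng.spawn(3)

    X_work = X
    if collinear_first and layout.collinear_pairs:
        X_work = apply_collinearity(
            X_work, layout.collinear_pairs, noise_sd=collinear_noise_sd,
            seed=int(sub[0].integers(2 ** 31)),
        )
    V = X_work.values
    y = np.zeros(X.n)
    for j, k in layout.type1_pairs:
        y += V[:, j] * V[:, k]
    for j, k in layout.relu_pairs:
        y += relu_term(V[:, j], V[:, k])
    main_effects: dict[int, float] = {}
    if with_main_effects:
        for j in layout.main_effect_indices:
            y += layout.main_effect_beta * V[:, j]
            main_effects[j] = layout.main_effect_beta
    y = y + rng.normal(0.0, noise_sd, X.n)
    if with_main_effects and extra_noise:
        y = y + rng.normal(0.0, noise_sd, X.n)

    X_out = apply_disruption(
        X_work, y, layout.disrupted_pairs, cut_quantile=cut_quantile,
        noise_sd=disruption_noise_sd, seed=int(sub[1].integers(2 ** 31)),
    )
    if not collinear_first and layout.collinear_pairs:
        X_out = apply_collinearity(
            X_out, layout.collinear_pairs, noise_sd=collinear_noise_sd,
            seed=int(sub[2].integers(2 ** 31)),
        )
    truth = SimulationTruth(
        type1_pairs=layout.type1_pairs,
        relu_pairs=layout.relu_pairs,
        disrupted_pairs=layout.disrupted_pairs,
        collinear_pairs=layout.collinear_pairs,
        main_effects=main_effects,
        noise_sd=noise_sd,
        disruption_quantile=cut_quantile,
        disruption_noise_sd=disruption_noise_sd,
    )
    name = "model_B" if with_main_effects else "model_A"
    return PhenotypeVector(values=y, name=name), truth, X_out


def simulate_model_A(
    X: ExpressionMatrix,
    seed: int = 0,
    noise_sd: float = 1.75,
    layout: ModelLayout | None = None,
    cut_quantile: float = 4 / 5,
    disruption_noise_sd: float = 0.25,
    collinear_noise_sd: float = 0.25,
    collinear_first: bool = True,
) -> tuple[PhenotypeVector, SimulationTruth, ExpressionMatrix]:
    """Simulate the no-main-effect phenotype model on a given backbone.

    Order of operations: (1) collinearity overwrites, (2) phenotype from the
    six product terms, two ReLU terms and Gaussian noise, (3) C+/- disruption
    of the upper phenotype tail.  Returns the phenotype, the ground truth
    (14 positive pairs under the default layout) and the modified matrix.
    """
    return _simulate(
        X, seed, noise_sd, layout, with_main_effects=False, extra_noise=False,
        cut_quantile=cut_quantile, disruption_noise_sd=disruption_noise_sd,
        collinear_noise_sd=collinear_noise_sd, collinear_first=collinear_first,
    )


def simulate_model_B(
    X: ExpressionMatrix,
    seed: int = 0,
    noise_sd: float = 1.75,
    layout: ModelLayout | None = None,
    extra_noise: bool = True,
    cut_quantile: float = 4 / 5,
    disruption_noise_sd: float = 0.25,
    collinear_noise_sd: float = 0.25,
    collinear_first: bool = True,
) -> tuple[PhenotypeVector, SimulationTruth, ExpressionMatrix]:
    """Model A plus six strong main effects (coefficient 2) and extra noise."""
    return _simulate(
        X, seed, noise_sd, layout, with_main_effects=True, extra_noise=extra_noise,
        cut_quantile=cut_quantile, disruption_noise_sd=disruption_noise_sd,
        collinear_noise_sd=collinear_noise_sd, collinear_first=collinear_first,
    )


def write_replicate(
    X: ExpressionMatrix, y: PhenotypeVector, truth: SimulationTruth, out_dir
) -> None:
    """Write a simulated replicate as TSVs with a JSON truth sidecar."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(X.values, columns=list(X.gene_names)).to_csv(
        out / "expression.tsv", sep="\t", index=False, float_format="%.12g"
    )
    pd.DataFrame({y.name: y.values}).to_csv(
        out / "phenotype.tsv", sep="\t", index=False, float_format="%.12g"
    )
    (out / "truth.json").write_text(truth.to_json())
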