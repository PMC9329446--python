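"""Variation partitioning of one response matrix among 2-3 predictor matrices.

Fractions live on the adjusted-R² scale (Ezekiel), obtained by
inclusion-exclusion over the adjusted R² of all simple (non-partial) models —
the Peres-Neto convention, which is what makes unique and shared fractions
additive and lets them be negative.  Negative fractions are preserved; only
the diagram layer may floor them.  Shared fractions carry no test statistic:
only simple and conditional (unique) effects are testable by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .inference import PermutationDesign, TestResult, permutation_test
from .ordination import rda_matrices
from .tables_io import SampleTable

_CLOSURE_TOL = 1e-12


def subset_key(labels: Sequence[str]) -> str:
    """Canonical key for a predictor subset ("E", "ES", "A+E" for long labels)."""
    labels = list(labels)
    joiner = "" if all(len(l) == 1 for l in labels) else "+"
    return joiner.join(labels)


@dataclass
class VarpartResult:
    response_label: str
    predictor_labels: list[str]
    fractions: dict[str, float]  # non-empty predictor subset -> adj-R² fraction
    residual: float
    total_variance: float
    scale: str = "proportion"

    def __post_init__(self) -> None:
        s = sum(self.fractions.values()) + self.residual
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"fractions + residual = {s}, expected 1")

    def in_variance_units(self) -> dict[str, float]:
        out = {k: v * self.total_variance for k, v in self.fractions.items()}
        out["residual"] = self.residual * self.total_variance
        return out

    def to_dict(self) -> dict:
        return {
            "response": self.response_label,
            "predictors": self.predictor_labels,
            "fractions": dict(self.fractions),
            "residual": self.residual,
            "total_variance": self.total_variance,
            "scale": self.scale,
        }


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    classes: list[str]
    observed: np.ndarray
    expected: np.ndarray
    p_value: float


def _model_matrix(t: SampleTable) -> np.ndarray:
    return t.to_model_matrix().to_numpy()


def _adj(Y: np.ndarray, Xs: Sequence[np.ndarray]) -> float:
    return rda_matrices(Y, np.hstack(Xs)).adj_r2


def _check_aligned(y: SampleTable, xs: Sequence[SampleTable]) -> None:
    for x in xs:
        if x.row_ids != y.row_ids:
            raise ValueError("tables are not row-aligned; call align_rows first")


def _total_variance(y: SampleTable) -> float:
    Y = _model_matrix(y)
    return float(Y.var(axis=0, ddof=1).sum())


def varpart2(
    y: SampleTable,
    x1: SampleTable,
    x2: SampleTable,
    labels: Sequence[str] = ("X1", "X2"),
    response_label: str = "Y",
) -> VarpartResult:
    """Partition y's adjusted explained variance between two predictor matrices."""
    _check_aligned(y, (x1, x2))
    Y = _model_matrix(y)
    M1, M2 = _model_matrix(x1), _model_matrix(x2)
    a1, a2, a12 = _adj(Y, [M1]), _adj(Y, [M2]), _adj(Y, [M1, M2])
    l1, l2 = labels
    fractions = {
        subset_key([l1]): a12 - a2,
        subset_key([l2]): a12 - a1,
        subset_key([l1, l2]): a1 + a2 - a12,
    }
    return VarpartResult(response_label, list(labels), fractions, 1.0 - a12, _total_variance(y))


def varpart3(
    y: SampleTable,
    x1: SampleTable,
    x2: SampleTable,
    x3: SampleTable,
    labels: Sequence[str] = ("X1", "X2", "X3"),
    response_label: str = "Y",
) -> VarpartResult:
    """Partition y's adjusted explained variance among three predictor matrices.

    The seven fractions (3 unique, 3 pairwise-shared, 1 triple-shared) follow
    by inclusion-exclusion from the adjusted R² of the seven simple models.
    """
    _check_aligned(y, (x1, x2, x3))
    Y = _model_matrix(y)
    Ms = [_model_matrix(t) for t in (x1, x2, x3)]
    f: dict[frozenset, float] = {}
    for r in (1, 2, 3):
        for combo in combinations(range(3), r):
            f[frozenset(combo)] = _adj(Y, [Ms[i] for i in combo])
    all3 = f[frozenset({0, 1, 2})]
    # triple intersection by inclusion-exclusion on the union measure
    g = (
        f[frozenset({0})] + f[frozenset({1})] + f[frozenset({2})]
        - f[frozenset({0, 1})] - f[frozenset({0, 2})] - f[frozenset({1, 2})]
        + all3
    )
    fractions: dict[str, float] = {}
    for i in range(3):
        others = frozenset({0, 1, 2} - {i})
        fractions[subset_key([labels[i]])] = all3 - f[others]
    for i, j in combinations(range(3), 2):
        k = ({0, 1, 2} - {i, j}).pop()
        pair_only = (
            f[frozenset({i, k})] + f[frozenset({j, k})] - f[frozenset({k})] - all3
        )
        fractions[subset_key([labels[i], labels[j]])] = pair_only
    fractions[subset_key(list(labels))] = g
    return VarpartResult(response_label, list(labels), fractions, 1.0 - all3, _total_variance(y))


def test_fractions(
    y: SampleTable,
    xs: Sequence[SampleTable],
    labels: Sequence[str] | None = None,
    design: PermutationDesign | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Permutation tests of each simple and each unique (conditional) effect.

    Returns a map keyed by ``"simple:<label>"`` for simple effects and by the
    fraction key ``"<label>"`` for unique effects; shared fractions are not
    testable and are absent from the map.
    """
    if not 1 <= len(xs) <= 3:
        raise ValueError("test_fractions accepts 1-3 predictor matrices")
    _check_aligned(y, xs)
    labels = list(labels) if labels is not None else [f"X{i+1}" for i in range(len(xs))]
    Y = _model_matrix(y)
    Ms = [_model_matrix(t) for t in xs]
    rng = np.random.default_rng(seed)
    out: dict[str, TestResult] = {}
    for i, lab in enumerate(labels):
        child = int(rng.integers(2 ** 31))
        out[f"simple:{lab}"] = permutation_test(Y, Ms[i], None, design, n_perm, child)
        others = [Ms[j] for j in range(len(Ms)) if j != i]
        child = int(rng.integers(2 ** 31))
        w = np.hstack(others) if others else None
        out[subset_key([lab])] = permutation_test(Y, Ms[i], w, design, n_perm, child)
    return out


def chisq_fraction_compare(
    observed: Sequence[float],
    expected: Sequence[float],
    labels: Sequence[str] | None = None,
) -> ChiSqResult:
    """Chi-squared comparison of two distributions of explained-variance classes."""
    O = np.asarray(observed, dtype=float)
    E = np.asarray(expected, dtype=float)
    if O.shape != E.shape or O.ndim != 1 or O.size < 2:
        raise ValueError("observed and expected must be equal-length vectors of >= 2 classes")
    if (E <= 0).any():
        raise ValueError("expected class values must be positive")
    labels = list(labels) if labels is not None else [f"class{i+1}" for i in range(O.size)]
    stat = float(((O - E) ** 2 / E).sum())
    df = O.size - 1
    return ChiSqResult(stat, df, labels, O, E, float(chi2.sf(stat, df)))
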