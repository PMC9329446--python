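"""Gower (mixed-type) and Euclidean dissimilarity matrices.

Gower's coefficient averages per-variable dissimilarities: quantitative and
ordinal variables contribute |x_i - x_j| / range (ordinals as integer ranks,
range-normalized like quantitative variables; the Podani ordinal correction
is deliberately not applied),
factor and binary variables contribute 0/1 disagreement.  Missing values are
handled by pairwise deletion: a variable missing in either row of a pair is
excluded and the weight sum renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables_io import SampleTable

_SYM_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarities among ordered ids, zero on the diagonal."""

    ids: list
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("dimension does not match number of ids")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > _SYM_TOL:
            raise ValueError("distance matrix diagonal is not zero")
        if v.size and v.min() < -_SYM_TOL:
            raise ValueError("negative distances")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, index_label="id"
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index), df.to_numpy(dtype=float))


def gower_matrix(table: SampleTable) -> DistanceMatrix:
    """Gower dissimilarity among the rows of a mixed-type table.

    d(i,j) = sum_k w_k * delta_k(i,j) * s_k(i,j) / sum_k w_k * delta_k(i,j),
    with delta_k = 0 whenever either value is missing; all d in [0, 1].
    """
    if table.n_rows < 2:
        raise ValueError("Gower needs at least two rows")
    n = table.n_rows
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    used_any = False
    for name in table.data.columns:
        spec = table.schema[name]
        if spec.weight == 0:
            continue
        used_any = True
        col = table.data[name]
        if spec.kind in ("quantitative", "ordinal"):
            x = col.to_numpy(dtype=float)
            ok = ~np.isnan(x)
            if not ok.any():
                raise ValueError(f"column {name!r} is entirely missing")
            rng = np.nanmax(x) - np.nanmin(x)
            diff = np.abs(x[:, None] - x[None, :])
            s = diff / rng if rng > 0 else np.zeros((n, n))
        else:  # factor or binary: simple disagreement
            vals = col.to_numpy(dtype=object)
            ok = pd.notna(col).to_numpy()
            s = (vals[:, None] != vals[None, :]).astype(float)
        comparable = np.outer(ok, ok).astype(float)
        num += spec.weight * np.where(comparable > 0, s, 0.0)
        den += spec.weight * comparable
    if not used_any:
        raise ValueError("no column with a positive weight")
    np.fill_diagonal(den, 1.0)  # diagonal distance is 0 regardless
    np.fill_diagonal(num, 0.0)
    if (den <= 0).any():
        i, j = np.argwhere(den <= 0)[0]
        raise ValueError(
            f"rows {table.row_ids[i]!r} and {table.row_ids[j]!r} share no "
            "comparable (non-missing) columns"
        )
    d = num / den
    return DistanceMatrix(
        table.row_ids,
        d,
        metadata={
            "metric": "gower",
            "ordinal_treatment": "integer ranks, range-normalized (no Podani correction)",
            "missing": "pairwise deletion with weight renormalization",
        },
    )


def euclidean_matrix(table: SampleTable) -> DistanceMatrix:
    """Euclidean distances among rows of an all-quantitative, complete table."""
    bad = [c for c in table.data.columns if table.schema[c].kind != "quantitative"]
    if bad:
        raise ValueError(f"euclidean_matrix requires quantitative columns; got {bad}")
    x = table.numeric()
    if np.isnan(x).any():
        raise ValueError("euclidean_matrix does not accept missing values")
    return DistanceMatrix(table.row_ids, squareform(pdist(x)), metadata={"metric": "euclidean"})
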