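"""Distance-based Moran Eigenvector Maps (db-MEM) from site coordinates.

The classical construction: Euclidean distances among sites, truncation at a
threshold t (distances beyond t replaced by 4t), PCoA of the truncated
matrix, retention of positive-eigenvalue axes.  The automatic threshold is
the largest edge of the minimum spanning tree of the distance graph — the
smallest t keeping the graph connected, which reduces to the maximum
nearest-neighbour gap on a 1-D transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .dissimilarity import euclidean_matrix
from .ordination import orth_basis, pcoa
from .tables_io import SampleTable

TRUNCATION_FACTOR = 4.0


@dataclass
class MemBasis:
    scores: SampleTable          # columns MEM1..MEMk, centered, orthogonal
    eigenvalues: np.ndarray      # positive, non-increasing
    truncation_threshold: float


def dbmem(
    coords: SampleTable, threshold: float | None = None, detrend: bool = False
) -> MemBasis:
    """Build db-MEM spatial eigenfunctions from 1- or 2-D site coordinates.

    ``threshold=None`` selects the automatic (MST largest-edge) truncation
    distance.  ``detrend`` additionally removes the linear coordinate trend
    from the eigenfunctions (off by default).
    """
    ncol = len(coords.data.columns)
    if ncol not in (1, 2):
        raise ValueError("coordinates must have 1 or 2 quantitative columns")
    if coords.n_rows < 3:
        raise ValueError("db-MEM needs at least 3 sites")
    d = euclidean_matrix(coords)
    if threshold is None:
        mst = minimum_spanning_tree(d.values).toarray()
        threshold = float(mst.max())
    if threshold <= 0:
        raise ValueError("degenerate spanning tree: zero truncation threshold")
    trunc = np.where(d.values <= threshold, d.values, TRUNCATION_FACTOR * threshold)
    np.fill_diagonal(trunc, 0.0)
    ord_ = pcoa(type(d)(d.ids, trunc), keep="positive")
    scores = ord_.scores.numeric()
    eigval = ord_.eigenvalues
    if detrend and scores.shape[1]:
        xy = coords.numeric()
        xyc = xy - xy.mean(axis=0)
        q = orth_basis(xyc)
        resid = scores - q @ (q.T @ scores)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        keep = s > 1e-8 * s[0] if s.size else np.array([], dtype=bool)
        scores = (u * s)[:, keep]
        eigval = (s[keep] ** 2) / 1.0
    cols = [f"MEM{i + 1}" for i in range(scores.shape[1])]
    table = SampleTable.from_numeric(pd.DataFrame(scores, index=coords.row_ids, columns=cols))
    return MemBasis(table, eigval, threshold)
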