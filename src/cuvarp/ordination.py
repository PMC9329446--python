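"""Ordination core: PCoA, PCA total variance, (partial) RDA, adjusted R².

RDA here is multivariate least squares of a centered response matrix on a
predictor matrix (optionally after residualizing both on covariates), with
explained variance measured as the trace ratio of fitted to total sums of
squares.  Rank deficiency is handled by a rank-revealing (SVD) fit; the
effective predictor count m_eff is the post-residualization rank, and the
Ezekiel adjustment uses m_eff.  Partial adjusted R² values are never produced
by plugging m+q into Ezekiel; the varpart module obtains them by subtraction
of simple-model adjusted R²s (the Peres-Neto convention), which is what makes
variation-partitioning fractions additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix
from .tables_io import SampleTable

#: relative eigenvalue tolerance: eigenvalues below this fraction of the
#: largest magnitude are treated as zero under every keep policy
EIG_REL_TOL = 1e-8

_RANK_TOL = 1e-10


@dataclass
class Ordination:
    ids: list
    eigenvalues: np.ndarray  # kept eigenvalues, non-increasing
    scores: SampleTable      # columns Axis1..AxisK
    kept_axis_policy: str


@dataclass
class RdaFit:
    r2: float
    adj_r2: float            # Ezekiel; NaN when covariates are present
    pseudo_f: float
    df_model: int
    df_resid: int
    n: int
    m: int                   # effective (rank) predictor count
    q: int                   # effective covariate count
    fitted_variance: float
    residual_variance: float


# ---------------------------------------------------------------------------
# numeric helpers (shared with inference/varpart)

def center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0, keepdims=True)


def orth_basis(M: np.ndarray, ref_scale: float | None = None) -> np.ndarray:
    """Orthonormal basis (n x rank) of the column space of M via SVD.

    ``ref_scale`` sets the scale against which singular values are judged
    negligible; pass the norm of a matrix *before* residualization so that a
    predictor block absorbed entirely by covariates reports rank 0 instead of
    a basis of numerical dust.
    """
    if M.size == 0:
        return np.empty((M.shape[0], 0))
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.empty((M.shape[0], 0))
    scale = max(s[0], ref_scale if ref_scale is not None else 0.0)
    rank = int((s > _RANK_TOL * scale).sum())
    return u[:, :rank]


def rda_matrices(Y: np.ndarray, X: np.ndarray, W: np.ndarray | None = None) -> RdaFit:
    """RDA on plain numeric matrices; see module docstring for conventions."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] == Y.shape[0]:
        X = X.T
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("response and predictors have different row counts")
    Yc = center(Y)
    ss_y = float((Yc ** 2).sum())
    if ss_y <= 1e-12 * max(1.0, float((Y ** 2).sum())):
        raise ValueError("constant response")
    Xc = center(X)
    x_scale = float(np.linalg.norm(Xc))
    q_eff = 0
    if W is not None and np.asarray(W).size:
        W = np.atleast_2d(np.asarray(W, dtype=float))
        if W.shape[0] == 1 and W.shape[1] == n:
            W = W.T
        Qw = orth_basis(center(W))
        q_eff = Qw.shape[1]
        Yc = Yc - Qw @ (Qw.T @ Yc)
        Xc = Xc - Qw @ (Qw.T @ Xc)
    Qx = orth_basis(Xc, ref_scale=x_scale)
    m_eff = Qx.shape[1]
    if n <= m_eff + q_eff + 1:
        raise ValueError(
            f"too few rows (n={n}) for m={m_eff} predictors and q={q_eff} covariates"
        )
    ss_tot = float((Yc ** 2).sum())
    if m_eff == 0:
        r2, pseudo_f = 0.0, 0.0
        ss_fit = 0.0
    else:
        fitted = Qx @ (Qx.T @ Yc)
        ss_fit = float((fitted ** 2).sum())
        r2 = ss_fit / ss_tot
        df_resid = n - m_eff - q_eff - 1
        pseudo_f = (r2 / m_eff) / ((1.0 - r2) / df_resid) if r2 < 1.0 else np.inf
    adj = adjusted_r2(min(r2, 1.0), n, m_eff) if q_eff == 0 else float("nan")
    return RdaFit(
        r2=r2,
        adj_r2=adj,
        pseudo_f=pseudo_f,
        df_model=m_eff,
        df_resid=n - m_eff - q_eff - 1,
        n=n,
        m=m_eff,
        q=q_eff,
        fitted_variance=ss_fit / (n - 1),
        residual_variance=(ss_tot - ss_fit) / (n - 1),
    )


# ---------------------------------------------------------------------------
# public operations

def pcoa(d: DistanceMatrix, keep: str = "positive") -> Ordination:
    """Principal coordinates of a distance matrix.

    Gower double-centering G = -1/2 J D^2 J, eigendecomposition, retention of
    eigenvalues above ``EIG_REL_TOL`` x max|eigenvalue| ("positive" and
    "nonzero" keep policies coincide under this tolerance), scores =
    eigenvector * sqrt(eigenvalue).  Axis signs are fixed so that each axis's
    largest-magnitude loading is positive.
    """
    if keep not in ("positive", "nonzero"):
        raise ValueError(f"unknown keep policy {keep!r}")
    D = d.values
    n = d.n
    if n < 2:
        raise ValueError("PCoA needs at least two objects")
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = EIG_REL_TOL * (np.abs(eigval).max() if n else 0.0)
    kept = eigval > tol
    eigval, eigvec = eigval[kept], eigvec[:, kept]
    for k in range(eigvec.shape[1]):
        imax = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[imax, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    scores = eigvec * np.sqrt(eigval)
    cols = [f"Axis{i + 1}" for i in range(scores.shape[1])]
    score_table = SampleTable.from_numeric(pd.DataFrame(scores, index=d.ids, columns=cols))
    return Ordination(list(d.ids), eigval, score_table, kept_axis_policy=keep)


def pca_total_variance(t: SampleTable) -> float:
    """Total PCA variance of a quantitative table = sum of column variances (n-1)."""
    bad = [c for c in t.data.columns if t.schema[c].kind != "quantitative"]
    if bad:
        raise ValueError(f"pca_total_variance requires quantitative columns; got {bad}")
    if t.n_rows < 2:
        raise ValueError("need at least two rows to estimate variance")
    x = t.numeric()
    if np.isnan(x).any():
        raise ValueError("missing values in variance computation")
    return float(x.var(axis=0, ddof=1).sum())


def rda(y: SampleTable, x: SampleTable, w: SampleTable | None = None) -> RdaFit:
    """(Partial) redundancy analysis of SampleTables (factors dummy-coded)."""
    if y.row_ids != x.row_ids or (w is not None and y.row_ids != w.row_ids):
        raise ValueError("tables are not row-aligned; call align_rows first")
    W = w.to_model_matrix().to_numpy() if w is not None else None
    return rda_matrices(y.to_model_matrix().to_numpy(), x.to_model_matrix().to_numpy(), W)


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment 1 - (1-R²)(n-1)/(n-m-1); may be negative."""
    if not (0.0 <= r2 <= 1.0):
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if n <= m + 1:
        raise ValueError(f"adjusted R² undefined for n={n}, m={m}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)
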