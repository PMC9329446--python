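"""Permutation inference for (partial) RDA: restricted schemes, Monte Carlo
tests, FDR adjustment, and forward selection with a double stopping rule.

Partial tests permute residuals of the reduced model (Freedman-Lane); without
covariates the raw (centered) response rows are permuted.  Four permutation
schemes are supported:

``free``
    unrestricted permutation of all rows;
``blocks``
    independent free permutation within each block;
``series``
    a single cyclic shift within each block, suited to time series and linear
    transects (optionally also mirrored);
``split_plot``
    whole plots (equal-sized blocks) exchanged freely while each plot's
    internal series order is preserved (or cyclically shifted when
    ``shift_within`` is set) — the hierarchical scheme for sector-by-period
    designs.

When the orbit of achievable permutations is no larger than the requested
number of random draws, the test switches to exhaustive enumeration and the
p-value is exact.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ordination import center, orth_basis, rda_matrices
from .tables_io import SampleTable

_F_TOL = 1e-12


@dataclass
class PermutationDesign:
    kind: str = "free"
    block_labels: Sequence | None = None
    allow_mirror: bool = False
    whole_plot_order: Sequence | None = None
    shift_within: bool = False

    def summary(self) -> str:
        parts = [self.kind]
        if self.block_labels is not None:
            parts.append(f"{len(set(self.block_labels))} blocks")
        if self.allow_mirror:
            parts.append("mirrored")
        if self.kind == "split_plot" and self.shift_within:
            parts.append("within-plot shifts")
        return ", ".join(parts)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int
    scheme: str
    exhaustive: bool = False


@dataclass
class SelectionStep:
    candidate: str
    adj_r2_gain: float
    p_raw: float
    p_fdr: float


@dataclass
class SelectionResult:
    selected: list[str]
    steps: list[SelectionStep]
    stop_reason: str  # alpha_fail | adjr2_ceiling | exhausted
    adj_r2: float = 0.0
    full_adj_r2: float = 0.0


# ---------------------------------------------------------------------------
# permutation generation

def _block_indices(design: PermutationDesign, n: int) -> list[np.ndarray]:
    labels = design.block_labels
    if labels is None:
        return [np.arange(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError(f"{len(labels)} block labels for {n} rows")
    order = design.whole_plot_order
    if order is None:
        order = list(dict.fromkeys(labels))
    elif set(order) != set(labels):
        raise ValueError("whole_plot_order does not match block labels")
    blocks = [np.flatnonzero(np.asarray(labels, dtype=object) == lab) for lab in order]
    if design.kind in ("series", "split_plot"):
        for lab, b in zip(order, blocks):
            if len(b) and not (np.diff(b) == 1).all():
                raise ValueError(f"rows of block {lab!r} are not contiguous")
    return blocks


def _series_arrangement(idx: np.ndarray, shift: int, mirror: bool) -> np.ndarray:
    arr = idx[::-1] if mirror else idx
    return np.roll(arr, -shift)


def generate_permutation(
    design: PermutationDesign, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw one permutation (an index vector) under the design's restrictions."""
    if design.kind == "free":
        return rng.permutation(n)
    blocks = _block_indices(design, n)
    perm = np.arange(n)
    if design.kind == "blocks":
        for b in blocks:
            perm[b] = b[rng.permutation(len(b))]
        return perm
    if design.kind == "series":
        for b in blocks:
            mirror = design.allow_mirror and bool(rng.integers(2))
            shift = int(rng.integers(len(b)))
            perm[b] = _series_arrangement(b, shift, mirror)
        return perm
    if design.kind == "split_plot":
        sizes = {len(b) for b in blocks}
        if len(sizes) > 1:
            raise ValueError("split_plot requires equal-sized whole plots")
        order = rng.permutation(len(blocks))
        for slot, src in zip(blocks, (blocks[i] for i in order)):
            rows = src
            if design.shift_within:
                mirror = design.allow_mirror and bool(rng.integers(2))
                shift = int(rng.integers(len(src)))
                rows = _series_arrangement(src, shift, mirror)
            perm[slot] = rows
        return perm
    raise ValueError(f"unknown permutation kind {design.kind!r}")


def _series_orbit(idx: np.ndarray, mirror: bool) -> list[tuple]:
    arrs = [tuple(_series_arrangement(idx, s, False)) for s in range(len(idx))]
    if mirror:
        arrs += [tuple(_series_arrangement(idx, s, True)) for s in range(len(idx))]
    return list(dict.fromkeys(arrs))


def naive_orbit_size(design: PermutationDesign, n: int) -> int:
    """Upper bound on the number of achievable permutations."""
    if design.kind == "free":
        return math.factorial(n)
    blocks = _block_indices(design, n)
    if design.kind == "blocks":
        return math.prod(math.factorial(len(b)) for b in blocks)
    if design.kind == "series":
        return math.prod(
            (2 * len(b) if design.allow_mirror else len(b)) for b in blocks
        )
    if design.kind == "split_plot":
        within = 1
        if design.shift_within:
            within = math.prod(
                (2 * len(b) if design.allow_mirror else len(b)) for b in blocks
            )
        return math.factorial(len(blocks)) * within
    raise ValueError(f"unknown permutation kind {design.kind!r}")


def enumerate_orbit(design: PermutationDesign, n: int) -> np.ndarray:
    """All distinct achievable permutations (rows of the returned array)."""
    if design.kind == "free":
        perms = [np.array(p) for p in itertools.permutations(range(n))]
        return np.array(perms)
    blocks = _block_indices(design, n)
    out: set[tuple] = set()
    if design.kind == "blocks":
        per_block = [
            [b[np.array(p)] for p in itertools.permutations(range(len(b)))]
            for b in blocks
        ]
        for combo in itertools.product(*per_block):
            perm = np.arange(n)
            for slot, rows in zip(blocks, combo):
                perm[slot] = rows
            out.add(tuple(perm))
    elif design.kind == "series":
        per_block = [
            [np.array(a) for a in _series_orbit(b, design.allow_mirror)] for b in blocks
        ]
        for combo in itertools.product(*per_block):
            perm = np.arange(n)
            for slot, rows in zip(blocks, combo):
                perm[slot] = rows
            out.add(tuple(perm))
    elif design.kind == "split_plot":
        sizes = {len(b) for b in blocks}
        if len(sizes) > 1:
            raise ValueError("split_plot requires equal-sized whole plots")
        within_opts = [
            [np.array(a) for a in _series_orbit(b, design.allow_mirror)]
            if design.shift_within
            else [b]
            for b in blocks
        ]
        for order in itertools.permutations(range(len(blocks))):
            for combo in itertools.product(*(within_opts[i] for i in order)):
                perm = np.arange(n)
                for slot, rows in zip(blocks, combo):
                    perm[slot] = rows
                out.add(tuple(perm))
    else:
        raise ValueError(f"unknown permutation kind {design.kind!r}")
    return np.array(sorted(out))


# ---------------------------------------------------------------------------
# Monte Carlo test

def _as_matrix(a) -> np.ndarray:
    if isinstance(a, SampleTable):
        return a.to_model_matrix().to_numpy()
    m = np.asarray(a, dtype=float)
    return m[:, None] if m.ndim == 1 else m


def _perm_f_stats(
    R: np.ndarray,
    Qx: np.ndarray,
    Qw: np.ndarray | None,
    perms: np.ndarray,
    df_resid: int,
) -> np.ndarray:
    """Pseudo-F for each permutation of the reduced-model residual rows R."""
    m = Qx.shape[1]
    Rp = R[perms]  # (B, n, p)
    ss_fit = (np.tensordot(Rp, Qx, axes=(1, 0)) ** 2).sum(axis=(1, 2))
    ss_r = (Rp ** 2).sum(axis=(1, 2))
    if Qw is not None and Qw.shape[1]:
        ss_r = ss_r - (np.tensordot(Rp, Qw, axes=(1, 0)) ** 2).sum(axis=(1, 2))
    ss_res = np.maximum(ss_r - ss_fit, 0.0)
    with np.errstate(divide="ignore"):
        return np.where(ss_res > 0, (ss_fit / m) / (ss_res / df_resid), np.inf)


def permutation_test(
    y,
    x,
    w=None,
    design: PermutationDesign | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> TestResult:
    """Monte Carlo (or exhaustive) test of a (partial) RDA pseudo-F.

    With covariates, permutes Freedman-Lane residuals of the reduced model;
    without, permutes the centered response rows directly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    design = design or PermutationDesign()
    Y, X = _as_matrix(y), _as_matrix(x)
    W = _as_matrix(w) if w is not None else None
    fit = rda_matrices(Y, X, W)  # validates and gives the observed statistic
    n = Y.shape[0]
    Yc = center(Y)
    Xc = center(X)
    x_scale = float(np.linalg.norm(Xc))
    if W is not None and W.size:
        Qw = orth_basis(center(W))
        R = Yc - Qw @ (Qw.T @ Yc)
        Xres = Xc - Qw @ (Qw.T @ Xc)
    else:
        Qw, R, Xres = None, Yc, Xc
    Qx = orth_basis(Xres, ref_scale=x_scale)
    if Qx.shape[1] == 0:
        return TestResult(0.0, 1.0, n_perm, seed, design.summary())
    f_obs = fit.pseudo_f
    if naive_orbit_size(design, n) <= n_perm:
        perms = enumerate_orbit(design, n)
        f_all = _perm_f_stats(R, Qx, Qw, perms, fit.df_resid)
        p = float((f_all >= f_obs - _F_TOL * max(1.0, abs(f_obs))).mean())
        return TestResult(f_obs, p, len(perms), seed, design.summary(), exhaustive=True)
    rng = np.random.default_rng(seed)
    perms = np.array([generate_permutation(design, n, rng) for _ in range(n_perm)])
    f_perm = _perm_f_stats(R, Qx, Qw, perms, fit.df_resid)
    exceed = int((f_perm >= f_obs - _F_TOL * max(1.0, abs(f_obs))).sum())
    p = (exceed + 1) / (n_perm + 1)
    return TestResult(f_obs, p, n_perm, seed, design.summary())


# ---------------------------------------------------------------------------
# FDR

def fdr_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# forward selection

def forward_select(
    y,
    candidates: SampleTable,
    w=None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    design: PermutationDesign | None = None,
) -> SelectionResult:
    """Greedy forward selection of candidate columns with double stopping.

    At each step every remaining candidate is tested by a partial permutation
    test conditioning on the already-selected columns (and covariates); the
    Benjamini-Hochberg adjustment is anchored to the full candidate roster
    (not the shrinking remainder), so late steps keep their multiplicity
    protection, and among candidates passing ``alpha`` the one with the
    largest adjusted-R² gain enters (ties broken by column order).  Selection stops when no candidate passes, once the
    cumulative adjusted R² reaches that of the full all-candidate model, or
    when candidates are exhausted.
    """
    if len(candidates.data.columns) < 1:
        raise ValueError("need at least one candidate column")
    Y = _as_matrix(y)
    W = _as_matrix(w) if w is not None else None
    n = Y.shape[0]
    cand_cols = {
        name: candidates.select([name]).to_model_matrix().to_numpy()
        for name in candidates.data.columns
    }

    def cond_adj(names: Sequence[str]) -> float:
        """Adjusted R² of the named set beyond the covariates (by subtraction)."""
        if not names:
            return 0.0
        X = np.hstack([cand_cols[nm] for nm in names])
        if W is None or not W.size:
            return rda_matrices(Y, X).adj_r2
        full = rda_matrices(Y, np.hstack([X, W]))
        base = rda_matrices(Y, W)
        return full.adj_r2 - base.adj_r2

    full_adj = cond_adj(list(cand_cols))
    rng = np.random.default_rng(seed)
    selected: list[str] = []
    steps: list[SelectionStep] = []
    remaining = list(cand_cols)
    adj_sel = 0.0
    stop_reason = "exhausted"
    while remaining:
        cov_parts = [cand_cols[nm] for nm in selected]
        if W is not None and W.size:
            cov_parts.append(W)
        W_step = np.hstack(cov_parts) if cov_parts else None
        p_raw, gains = [], []
        for nm in remaining:
            child = int(rng.integers(2 ** 31))
            tr = permutation_test(Y, cand_cols[nm], W_step, design, n_perm, child)
            p_raw.append(tr.p_value)
            gains.append(cond_adj(selected + [nm]) - adj_sel)
        # anchor the BH denominator to the full roster by padding with p=1
        pad = len(cand_cols) - len(remaining)
        p_fdr = fdr_adjust(list(p_raw) + [1.0] * pad)[: len(remaining)]
        best = None
        for i, nm in enumerate(remaining):  # column order breaks ties
            if p_fdr[i] <= alpha and (best is None or gains[i] > gains[best]):
                best = i
        if best is None:
            stop_reason = "alpha_fail"
            break
        name = remaining[best]
        steps.append(SelectionStep(name, gains[best], p_raw[best], float(p_fdr[best])))
        selected.append(name)
        adj_sel += gains[best]
        remaining.remove(name)
        # double stopping: once the cumulative adjusted R² reaches the full
        # all-candidate model's, further entries can only chase noise
        if remaining and adj_sel >= full_adj - 1e-12:
            stop_reason = "adjr2_ceiling"
            break
    return SelectionResult(selected, steps, stop_reason, adj_sel, full_adj)
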