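"""Taxonomic diversity, trait space, Rao quadratic entropy, and CWM.

Shannon entropy uses natural logarithms; Pielou's evenness J = H / ln(S) is
reported as missing for monocultures (0/0).  Rao's Q is the abundance-
weighted sum of pairwise trait distances over ordered species pairs,
Q = sum_ij d_ij p_i p_j, computed on plain (not squared) Euclidean distances
between species in trait-PCoA space.  Community-weighted means (CWM)
abundance-weight quantitative/ordinal traits and expand factor traits into
per-level proportion columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dissimilarity import DistanceMatrix, euclidean_matrix, gower_matrix
from .ordination import pcoa
from .tables_io import ColumnSpec, SampleTable, VariableSchema


@dataclass
class DiversityRecord:
    S: int                  # species richness
    H: float                # Shannon entropy (nats)
    J: float                # Pielou evenness; NaN for monocultures
    N2: float               # Hill inverse-Simpson effective species number
    Q: float | None = None  # Rao quadratic entropy, if trait distances given


@dataclass
class TraitSpace:
    species_scores: SampleTable      # trait-PCoA axes
    species_distance: DistanceMatrix  # Euclidean distances in score space


def taxonomic_indices(counts) -> DiversityRecord:
    """Richness, Shannon, Pielou, and Hill N2 of one abundance vector."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("abundances must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = c[c > 0] / total
    S = int(p.size)
    H = float(-(p * np.log(p)).sum())
    N2 = float(1.0 / (p ** 2).sum())
    J = H / np.log(S) if S >= 2 else float("nan")
    return DiversityRecord(S=S, H=H, J=float(J), N2=N2)


def trait_space(traits: SampleTable) -> TraitSpace:
    """Embed species in trait space: Gower distances -> PCoA -> Euclidean."""
    if traits.n_rows < 2:
        raise ValueError("trait space needs at least two species")
    ord_ = pcoa(gower_matrix(traits), keep="nonzero")
    return TraitSpace(ord_.scores, euclidean_matrix(ord_.scores))


def rao_q(counts, d: DistanceMatrix) -> float:
    """Rao quadratic entropy Q = sum over ordered pairs of d_ij p_i p_j."""
    if isinstance(counts, pd.Series):
        if list(counts.index) != list(d.ids):
            raise ValueError("abundance ids do not match distance-matrix ids")
        c = counts.to_numpy(dtype=float)
    else:
        c = np.asarray(counts, dtype=float)
        if c.size != d.n:
            raise ValueError("abundance vector length does not match distance matrix")
    if (c < 0).any() or c.sum() <= 0:
        raise ValueError("abundances must be non-negative with a positive total")
    p = c / c.sum()
    return float(p @ d.values @ p)


def cwm(community: SampleTable, traits: SampleTable) -> SampleTable:
    """Community-weighted means of traits per site.

    Sites with zero total abundance get an all-missing row.  Factor traits
    expand into one column per level holding the community proportion of
    species carrying that level (columns sum to 1 per site).
    """
    species = list(community.data.columns)
    if species != traits.row_ids:
        raise ValueError("community species columns must equal trait table rows")
    A = community.numeric()
    if (A < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = A.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = A / totals[:, None]
    cols: dict[str, np.ndarray] = {}
    specs: list[ColumnSpec] = []
    for name in traits.data.columns:
        spec = traits.schema[name]
        if spec.kind == "factor":
            levels = spec.levels or tuple(pd.unique(traits.data[name].dropna()))
            for lev in levels:
                ind = (traits.data[name] == lev).to_numpy(dtype=float)
                cname = f"{name}_{lev}"
                cols[cname] = P @ ind
                specs.append(ColumnSpec(cname, "quantitative"))
        else:
            x = traits.data[name].to_numpy(dtype=float)
            cols[name] = P @ x
            specs.append(ColumnSpec(name, "quantitative"))
    out = pd.DataFrame(cols, index=community.row_ids)
    out.loc[totals <= 0, :] = np.nan
    return SampleTable(out, VariableSchema(specs))


def diversity_table(
    community: SampleTable,
    traits: SampleTable | None = None,
    origin: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Per-site diversity summary (S, H, J, N2, and Rao Q when traits given).

    With an ``origin`` map (species -> "NAT"/"AIS"), Q is also reported
    separately for the native and alien community subsets.
    """
    species = list(community.data.columns)
    dist = None
    if traits is not None:
        dist = trait_space(traits).species_distance
        if list(dist.ids) != species:
            raise ValueError("trait table rows must match community species columns")
    origin = pd.Series(origin) if origin is not None else None
    rows = []
    for site, counts in community.data.iterrows():
        c = counts.to_numpy(dtype=float)
        rec: dict = {"site": site}
        if c.sum() > 0:
            div = taxonomic_indices(c)
            rec.update(S=div.S, H=div.H, J=div.J, N2=div.N2)
            if dist is not None:
                rec["Q_all"] = rao_q(c, dist)
        if dist is not None and origin is not None:
            for label, key in (("NAT", "Q_natives"), ("AIS", "Q_aliens")):
                members = [s for s in species if origin.get(s) == label]
                sub = counts[members].to_numpy(dtype=float)
                if sub.sum() > 0:
                    idx = [species.index(s) for s in members]
                    subd = DistanceMatrix(members, dist.values[np.ix_(idx, idx)])
                    rec[key] = rao_q(sub, subd)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("site")
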