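"""Cumulative variation partitioning with multiple response and predictor
matrices (CUVARP), in five steps:

1. Each community (natives H, aliens A) and the environment table E is turned
   into principal-coordinate scores of its Gower distances; the spatial
   coordinates S become db-MEM eigenfunctions.  Positive-eigenvalue axes are
   kept ("H-all", "A-all", "E-all", "S-all").
2. An automated consensus of reciprocal forward selections reduces each
   role's axes to the ones significantly related to at least one other role.
3. The total variance of each reduced table (PCA total = sum of column
   variances) is computed and summed into the grand total.
4. Each role in turn serves as response in a three-predictor variation
   partitioning against the other three.
5. The four partitionings are assembled into one diagram over the subsets of
   {H, A, E, S}: the non-overlap region of a role is its residual variance,
   and every overlap region accumulates, from each member role taken as
   response, that response's fraction keyed by the other members, in variance
   units.  Regions sum exactly to the grand total.

The CWM variant replaces the community tables by community-weighted trait
means; its "average" diagram (AVARP) reports each region as the mean over
member responses of the fraction as a percent of that response's own total,
instead of the variance-unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .dissimilarity import gower_matrix
from .diversity_traits import cwm
from .inference import PermutationDesign, TestResult, forward_select
from .ordination import pca_total_variance, pcoa
from .spatial_mem import dbmem
from .tables_io import SampleTable, align_rows
from .varpart import VarpartResult, subset_key, test_fractions, varpart3

ROLE_ORDER = ("H", "A", "E", "S")


def as_percent(value: float, total: float, decimals: int = 2) -> float:
    """Percentage of a total, rounded half-up to the printed precision."""
    from decimal import ROUND_HALF_UP, Decimal

    pct = Decimal(str(value)) / Decimal(str(total)) * 100
    return float(pct.quantize(Decimal(f"1.{'0' * decimals}"), rounding=ROUND_HALF_UP))


@dataclass
class ComponentSet:
    role: str
    full_scores: SampleTable
    source: str  # "pcoa" | "dbmem"
    eigenvalues: np.ndarray


@dataclass
class SelectedComponents:
    axes: dict[str, list[int]]           # role -> 1-based chosen axis indices
    scores: dict[str, SampleTable]       # role -> reduced score table
    selection_log: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class ReciprocalVarpart:
    varparts: dict[str, VarpartResult]
    totals: dict[str, float]
    grand_total: float
    tests: dict[str, dict[str, TestResult]] | None = None


@dataclass
class CuvarpResult:
    roles: list[str]
    varparts: dict[str, VarpartResult]
    totals: dict[str, float]
    grand_total: float
    regions: dict[str, dict[str, float]]  # subset key -> {value, percent}
    explained_sum: float
    residual_sum: float
    mode: str = "cumulative"              # "cumulative" | "average"

    def to_dict(self) -> dict:
        return {
            "roles": self.roles,
            "mode": self.mode,
            "totals": self.totals,
            "grand_total": self.grand_total,
            "explained_sum": self.explained_sum,
            "residual_sum": self.residual_sum,
            "regions": self.regions,
            "varparts": {r: v.to_dict() for r, v in self.varparts.items()},
        }


@dataclass
class DiagramSpec:
    regions: list[dict]
    title: str = "CUVARP diagram"
    scale_note: str = "variance units; percents of grand total"

    def to_json_dict(self) -> dict:
        return {"title": self.title, "scale_note": self.scale_note, "regions": self.regions}

    @classmethod
    def from_json_dict(cls, d: dict) -> "DiagramSpec":
        return cls(regions=d["regions"], title=d["title"], scale_note=d["scale_note"])


# ---------------------------------------------------------------------------
# steps 1-2

def build_components(
    native: SampleTable,
    alien: SampleTable,
    environment: SampleTable,
    coords: SampleTable,
) -> dict[str, ComponentSet]:
    """Step 1: H-all/A-all/E-all via Gower+PCoA, S-all via db-MEM."""
    tables = {"H": native, "A": alien, "E": environment, "S": coords}
    ids = native.row_ids
    for role, t in tables.items():
        if t.row_ids != ids:
            raise ValueError(f"table for role {role} is not row-aligned with the others")
    out: dict[str, ComponentSet] = {}
    for role in ("H", "A", "E"):
        ord_ = pcoa(gower_matrix(tables[role]), keep="positive")
        out[role] = ComponentSet(role, ord_.scores, "pcoa", ord_.eigenvalues)
    mem = dbmem(coords)
    out["S"] = ComponentSet("S", mem.scores, "dbmem", mem.eigenvalues)
    return out


def select_axes(
    components: dict[str, ComponentSet],
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    design: PermutationDesign | None = None,
    max_axes: int | None = None,
) -> SelectedComponents:
    """Step 2: automated consensus across reciprocal forward selections.

    For every ordered pair of roles, the predictor role's axes are forward-
    selected against the response role's full scores; an axis is retained for
    a role when selected in at least one analysis where that role predicts
    another.  Roles ending empty fall back to axis 1 with a logged warning.
    """
    roles = [r for r in ROLE_ORDER if r in components]
    rng = np.random.default_rng(seed)
    retained: dict[str, set[int]] = {r: set() for r in roles}
    log: list[dict] = []
    warnings: list[str] = []

    def limited(role: str) -> SampleTable:
        t = components[role].full_scores
        cols = list(t.data.columns)
        if max_axes is not None:
            cols = cols[:max_axes]
        return t.select(cols)

    for pred in roles:
        for resp in roles:
            if pred == resp:
                continue
            child = int(rng.integers(2 ** 31))
            sel = forward_select(
                limited(resp), limited(pred), None, alpha, n_perm, child, design
            )
            chosen = [list(components[pred].full_scores.data.columns).index(c) + 1
                      for c in sel.selected]
            retained[pred].update(chosen)
            log.append(
                {
                    "predictor": pred,
                    "response": resp,
                    "selected_axes": sorted(chosen),
                    "stop_reason": sel.stop_reason,
                    "adj_r2": sel.adj_r2,
                    "seed": child,
                }
            )
    axes: dict[str, list[int]] = {}
    scores: dict[str, SampleTable] = {}
    for r in roles:
        if not retained[r]:
            retained[r] = {1}
            warnings.append(f"role {r}: no axis selected in any analysis; fallback to axis 1")
        axes[r] = sorted(retained[r])
        cols = [components[r].full_scores.data.columns[i - 1] for i in axes[r]]
        scores[r] = components[r].full_scores.select(cols)
    return SelectedComponents(axes, scores, log, warnings)


# ---------------------------------------------------------------------------
# steps 3-4

def reciprocal_varpart(
    selected: SelectedComponents,
    design: PermutationDesign | None = None,
    n_perm: int = 0,
    seed: int = 0,
) -> ReciprocalVarpart:
    """Steps 3-4: each role as response against the other three; totals by PCA.

    With ``n_perm > 0`` every simple and unique effect also receives a
    permutation test.
    """
    roles = [r for r in ROLE_ORDER if r in selected.scores]
    if len(roles) != 4:
        raise ValueError(f"reciprocal varpart needs the four roles, got {roles}")
    rng = np.random.default_rng(seed)
    varparts: dict[str, VarpartResult] = {}
    totals: dict[str, float] = {}
    tests: dict[str, dict[str, TestResult]] = {}
    for r in roles:
        others = [o for o in roles if o != r]
        xs = [selected.scores[o] for o in others]
        varparts[r] = varpart3(
            selected.scores[r], *xs, labels=others, response_label=r
        )
        totals[r] = pca_total_variance(selected.scores[r])
        if n_perm > 0:
            child = int(rng.integers(2 ** 31))
            tests[r] = test_fractions(
                selected.scores[r], xs, others, design, n_perm, child
            )
    return ReciprocalVarpart(
        varparts, totals, float(sum(totals.values())), tests if n_perm > 0 else None
    )


# ---------------------------------------------------------------------------
# step 5

def _subsets(roles: Sequence[str]):
    for r in range(1, len(roles) + 1):
        yield from combinations(roles, r)


def assemble_cuvarp(
    varparts: dict[str, VarpartResult],
    totals: dict[str, float],
    mode: str = "cumulative",
) -> CuvarpResult:
    """Step 5: map the four reciprocal partitionings onto diagram regions."""
    if mode not in ("cumulative", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    roles = [r for r in ROLE_ORDER if r in varparts]
    if set(roles) != set(varparts) or set(roles) != set(totals):
        raise ValueError("varparts and totals must cover the same roles")
    for r in roles:
        expect = [o for o in roles if o != r]
        if list(varparts[r].predictor_labels) != expect:
            raise ValueError(
                f"response {r}: predictors {varparts[r].predictor_labels} "
                f"inconsistent with roles {expect}"
            )
    grand_total = float(sum(totals.values()))
    regions: dict[str, dict[str, float]] = {}
    residual_sum = 0.0
    for sub in _subsets(roles):
        key = subset_key(sub)
        if len(sub) == 1:
            r = sub[0]
            if mode == "cumulative":
                value = varparts[r].residual * totals[r]
                regions[key] = {"value": value, "percent": value / grand_total * 100.0}
                residual_sum += value
            else:
                pct = varparts[r].residual * 100.0
                regions[key] = {"value": pct, "percent": pct}
            continue
        contribs = []
        for r in sub:
            rest = [o for o in varparts[r].predictor_labels if o in sub]
            frac = varparts[r].fractions[subset_key(rest)]
            contribs.append(frac * totals[r] if mode == "cumulative" else frac * 100.0)
        if mode == "cumulative":
            value = float(sum(contribs))
            regions[key] = {"value": value, "percent": value / grand_total * 100.0}
        else:
            value = float(np.mean(contribs))
            regions[key] = {"value": value, "percent": value}
    if mode == "average":
        residual_sum = float(np.mean([varparts[r].residual for r in roles]) * 100.0)
        explained_sum = 100.0 - residual_sum
    else:
        explained_sum = grand_total - residual_sum
    return CuvarpResult(
        roles, varparts, dict(totals), grand_total, regions,
        explained_sum, residual_sum, mode,
    )


def cwm_avarp(
    native: SampleTable,
    alien: SampleTable,
    native_traits: SampleTable,
    alien_traits: SampleTable,
    environment: SampleTable,
    coords: SampleTable,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed: int = 0,
    design: PermutationDesign | None = None,
    max_axes: int | None = None,
) -> CuvarpResult:
    """CWM-AVARP: CUVARP on community-weighted trait means, averaged diagram."""
    h_cwm = cwm(native, native_traits)
    a_cwm = cwm(alien, alien_traits)
    keep = ~(h_cwm.data.isna().any(axis=1) | a_cwm.data.isna().any(axis=1))
    ids = [i for i, k in zip(h_cwm.row_ids, keep) if k]
    tables = []
    for t in (h_cwm, a_cwm, environment, coords):
        tables.append(SampleTable(t.data.loc[ids].copy(), t.schema))
    h_cwm, a_cwm, environment, coords = align_rows(tables)[0]
    comps = build_components(h_cwm, a_cwm, environment, coords)
    sel = select_axes(comps, alpha, n_perm, seed, design, max_axes)
    recip = reciprocal_varpart(sel, design, 0, seed)
    return assemble_cuvarp(recip.varparts, recip.totals, mode="average")


# ---------------------------------------------------------------------------
# diagram export

_ELLIPSES = {  # non-proportional 4-set layout (cx, cy, rx, ry, angle)
    "H": (170, 180, 130, 70, -40),
    "A": (240, 150, 130, 70, -40),
    "E": (310, 150, 130, 70, 40),
    "S": (380, 180, 130, 70, 40),
}
_COLORS = {"H": "#1b9e77", "A": "#d95f02", "E": "#7570b3", "S": "#e7298a"}


def export_diagram(
    result: CuvarpResult, floor_negatives: bool = True
) -> tuple[DiagramSpec, str]:
    """Region spec (for proportional-Euler renderers) plus a labeled SVG.

    Zero-valued regions — and negative ones when ``floor_negatives`` — are
    flagged ``rendered=false`` and omitted from the drawing; negative values
    stay unaltered in the spec itself.
    """
    regions = []
    for key, rv in result.regions.items():
        value = rv["value"]
        floored = value < 0 and floor_negatives
        rendered = not (value == 0 or floored)
        regions.append(
            {
                "subset": key,
                "value": value,
                "percent": rv["percent"],
                "rendered": rendered,
            }
        )
    unit = "%" if result.mode == "average" else ""
    spec = DiagramSpec(
        regions,
        title=f"CUVARP diagram ({result.mode})",
        scale_note=(
            "average of per-response percents" if result.mode == "average"
            else "variance units; percents of grand total"
        ),
    )
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="560" height="{260 + 16 * len(regions)}">',
        f'<text x="20" y="24" font-size="15" font-family="sans-serif">{spec.title}</text>',
    ]
    for role in result.roles:
        cx, cy, rx, ry, ang = _ELLIPSES[role]
        lines.append(
            f'<ellipse cx="{cx}" cy="{cy}" rx="{rx}" ry="{ry}" '
            f'transform="rotate({ang} {cx} {cy})" fill="{_COLORS[role]}" '
            'fill-opacity="0.25" stroke="black"/>'
        )
        lines.append(
            f'<text x="{cx}" y="{cy}" font-size="14" font-family="sans-serif">{role}</text>'
        )
    y = 290
    for reg in regions:
        if not reg["rendered"]:
            continue
        lines.append(
            f'<text x="30" y="{y}" font-size="12" font-family="monospace">'
            f'{reg["subset"]}: {reg["value"]:.3f}{unit} ({reg["percent"]:.2f}%)</text>'
        )
        y += 16
    lines.append("</svg>")
    return spec, "\n".join(lines)
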