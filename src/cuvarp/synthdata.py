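"""Synthetic riverscape datasets with known variance structure.

The generator emulates a 1-D river transect: site coordinates, a mixed-type
environment table (habitat factor, ordinal impact and flow scores, a
quantitative distance-to-dam), count/gaussian/binary community tables for a
native and an alien component, and mixed-type species trait tables.

Variance design.  Per community, latent site signals are built as
sqrt-share-weighted sums of four mutually orthogonal unit-variance channels:
an environment-only channel (aspatial gradient), a space-only channel (a
combination of db-MEM eigenfunctions not expressed in the environment), a
shared channel (spatially structured *and* expressed in the environment
table), and pure noise.  Because the channels are orthogonalized exactly,
the realized variance shares equal the design shares on the latent scale.
Species are linear loadings on the latents, optionally pushed through a
Poisson or threshold link; the recovery guarantees are stated for the
gaussian-latent model, since count/binary links degrade the shares.
Both communities respond to the *same* environment/space/shared channels —
only their shares (aliens noisier by default, mirroring weaker environmental
control of invasives) and species loadings differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial_mem import dbmem
from .tables_io import ColumnSpec, SampleTable, VariableSchema
from .varpart import subset_key

#: trait definitions mimicking a freshwater-mollusk functional trait set
TRAIT_DEFS: list[tuple[str, str, tuple]] = [
    ("SizeM", "ordinal", (1, 2, 3, 4, 5, 6)),
    ("Sexes", "factor", ("S", "H")),
    ("Ovipos", "factor", ("OV", "CAP", "BE", "No")),
    ("Nooff", "ordinal", (1, 2, 3, 4)),
    ("Sexmat", "ordinal", (1, 2, 3)),
    ("FeedT", "factor", ("SCR", "SS", "SF", "F", "SEDF")),
    ("Food", "factor", ("DAP", "CDA", "MAB")),
    ("Light", "ordinal", (1, 2, 3)),
    ("Taxon", "factor", ("PG", "G", "U", "V")),
    ("Origin", "factor", ("NAT", "AIS")),
    ("Habitat", "factor", ("Rheo", "Lent", "Phyt", "Ubi")),
]

RESPONSE_MODELS = ("gaussian-latent", "poisson-counts", "binary-threshold")


@dataclass(frozen=True)
class SynthParams:
    """Study-condition parameters of the synthetic riverscape."""

    n_sites: int = 200
    n_native: int = 22
    n_alien: int = 6
    native_shares: tuple[float, float, float, float] = (0.30, 0.20, 0.10, 0.40)
    alien_shares: tuple[float, float, float, float] = (0.15, 0.10, 0.05, 0.70)
    response_model: str = "gaussian-latent"
    n_env_vars: int = 4
    transect: str = "regular"
    n_traits: int = 11
    n_latents: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("native_shares", "alien_shares"):
            s = getattr(self, name)
            if len(s) != 4 or any(v < 0 for v in s):
                raise ValueError(f"{name} must be 4 non-negative values")
            if abs(sum(s) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(s)}")
        if self.response_model not in RESPONSE_MODELS:
            raise ValueError(f"unknown response model {self.response_model!r}")
        if self.n_native < 1 or self.n_alien < 1 or self.n_sites < 10:
            raise ValueError("need at least 10 sites and 1 species per community")
        if self.transect not in ("regular", "irregular"):
            raise ValueError(f"unknown transect kind {self.transect!r}")


@dataclass
class SynthBundle:
    native: SampleTable
    alien: SampleTable
    environment: SampleTable
    coords: SampleTable
    native_traits: SampleTable
    alien_traits: SampleTable
    truth: dict = field(default_factory=dict)

    def env_channel_table(self) -> SampleTable:
        """True env-side channels (env-only + shared), the E oracle predictors."""
        ch = self.truth["channels"]
        cols = {f"e{i+1}": ch["E"][:, i] for i in range(ch["E"].shape[1])}
        cols.update({f"es{i+1}": ch["ES"][:, i] for i in range(ch["ES"].shape[1])})
        return SampleTable.from_numeric(pd.DataFrame(cols, index=self.coords.row_ids))

    def space_channel_table(self) -> SampleTable:
        """True space-side channels (space-only + shared), the S oracle predictors."""
        ch = self.truth["channels"]
        cols = {f"s{i+1}": ch["S"][:, i] for i in range(ch["S"].shape[1])}
        cols.update({f"es{i+1}": ch["ES"][:, i] for i in range(ch["ES"].shape[1])})
        return SampleTable.from_numeric(pd.DataFrame(cols, index=self.coords.row_ids))


def _std(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) channel")
    return v / sd


def _orth_std(v: np.ndarray, others: list[np.ndarray]) -> np.ndarray:
    """Center v, project out `others`, return unit-variance residual."""
    v = v - v.mean()
    if others:
        B = np.column_stack(others)
        coef, *_ = np.linalg.lstsq(B, v, rcond=None)
        v = v - B @ coef
    return _std(v)


def _ordinal_bins(g: np.ndarray, levels: tuple) -> np.ndarray:
    """Quantile-bin a gradient into the given ordered levels."""
    ranks = pd.Series(g).rank(method="first").to_numpy()
    codes = np.ceil(ranks / len(g) * len(levels)).astype(int) - 1
    return np.asarray(levels, dtype=float)[codes]


def simulate_riverscape(params: SynthParams) -> SynthBundle:
    """Generate a four-table dataset with the designed variance shares."""
    rng = np.random.default_rng(params.seed)
    n, L = params.n_sites, params.n_latents
    site_ids = [f"site{i+1:03d}" for i in range(n)]

    # coordinates along the transect
    if params.transect == "regular":
        x = np.arange(n, dtype=float)
    else:
        x = np.sort(rng.uniform(0.0, float(n), n))
        x += np.arange(n) * 1e-6  # guarantee distinct positions
    coords = SampleTable.from_numeric(pd.DataFrame({"x": x}, index=site_ids))

    # spatial eigenfunction basis; leading (broad-scale) axes feed the channels
    mem = dbmem(coords)
    M = mem.scores.numeric()
    M = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    pool = min(M.shape[1], 12)
    space_axes = np.arange(0, pool, 2)
    shared_axes = np.arange(1, pool, 2)

    e_ch = np.empty((n, L))
    s_ch = np.empty((n, L))
    es_ch = np.empty((n, L))
    for l in range(L):
        s_ch[:, l] = _std(M[:, space_axes] @ rng.normal(size=space_axes.size))
        es_ch[:, l] = _std(M[:, shared_axes] @ rng.normal(size=shared_axes.size))
        e_ch[:, l] = _orth_std(rng.normal(size=n), [s_ch[:, l], es_ch[:, l]])

    def community(n_species: int, shares, prefix: str) -> tuple[SampleTable, np.ndarray]:
        se, ss, ssh, sn = shares
        latents = np.empty((n, L))
        for l in range(L):
            noise = _orth_std(
                rng.normal(size=n), [e_ch[:, l], s_ch[:, l], es_ch[:, l]]
            )
            latents[:, l] = (
                np.sqrt(se) * e_ch[:, l]
                + np.sqrt(ss) * s_ch[:, l]
                + np.sqrt(ssh) * es_ch[:, l]
                + np.sqrt(sn) * noise
            )
        loadings = rng.normal(size=(L, n_species))
        raw = latents @ loadings
        z = raw / np.sqrt((loadings ** 2).sum(axis=0))
        if params.response_model == "gaussian-latent":
            values = raw
        elif params.response_model == "poisson-counts":
            values = rng.poisson(np.exp(1.0 + 0.8 * z)).astype(float)
        else:  # binary-threshold
            values = (z > rng.uniform(-1.0, 1.0, size=n_species)).astype(float)
        cols = [f"{prefix}{j+1:02d}" for j in range(n_species)]
        table = SampleTable.from_numeric(pd.DataFrame(values, index=site_ids, columns=cols))
        return table, latents

    native, native_latents = community(params.n_native, params.native_shares, "nat")
    alien, alien_latents = community(params.n_alien, params.alien_shares, "ais")

    environment = _environment_table(params, rng, site_ids, e_ch, es_ch)
    native_traits = _trait_table(params, rng, "nat", params.n_native, "NAT")
    alien_traits = _trait_table(params, rng, "ais", params.n_alien, "AIS")

    def realized(latents: np.ndarray) -> dict[str, float]:
        out = {"env": 0.0, "space": 0.0, "shared": 0.0, "noise": 0.0}
        for l in range(L):
            y = latents[:, l] / latents[:, l].std(ddof=1)
            for key, ch in (("env", e_ch[:, l]), ("space", s_ch[:, l]), ("shared", es_ch[:, l])):
                out[key] += float(np.corrcoef(y, ch)[0, 1] ** 2) / L
        out["noise"] = 1.0 - out["env"] - out["space"] - out["shared"]
        return out

    truth = {
        "params": params,
        "channels": {"E": e_ch, "S": s_ch, "ES": es_ch},
        "latents": {"native": native_latents, "alien": alien_latents},
        "realized_shares": {
            "native": realized(native_latents),
            "alien": realized(alien_latents),
        },
        "mem_threshold": mem.truncation_threshold,
    }
    return SynthBundle(native, alien, environment, coords, native_traits, alien_traits, truth)


def _environment_table(params, rng, site_ids, e_ch, es_ch) -> SampleTable:
    """Mixed-type env table whose columns span the env-side channels."""
    channels = np.column_stack([e_ch, es_ch])
    k = channels.shape[1]

    def gradient() -> np.ndarray:
        w = rng.normal(size=k)
        return _std(channels @ w + 0.2 * rng.normal(size=len(site_ids)))

    cols: dict[str, np.ndarray | list] = {}
    specs: list[ColumnSpec] = []
    base = [
        ("Dis_dam", "quantitative", None),
        ("Impact", "ordinal", (0, 1, 2, 3, 4, 5, 6, 7)),
        ("Flow", "ordinal", (1, 2, 3, 4, 5)),
        ("Hab", "factor", ("R", "L", "C")),
    ]
    for i in range(params.n_env_vars):
        if i < len(base):
            name, kind, levels = base[i]
        else:
            name, kind, levels = f"Env{i+1}", "quantitative", None
        g = gradient()
        if kind == "quantitative":
            cols[name] = 2000.0 + 800.0 * g
        elif kind == "ordinal":
            cols[name] = _ordinal_bins(g, levels)
        else:
            terciles = _ordinal_bins(g, (0, 1, 2)).astype(int)
            cols[name] = [levels[t] for t in terciles]
        specs.append(ColumnSpec(name, kind, levels))
    return SampleTable(pd.DataFrame(cols, index=site_ids), VariableSchema(specs))


def _trait_table(params, rng, prefix: str, n_species: int, origin: str) -> SampleTable:
    """Species traits drawn from archetype mixtures of the mollusk-like trait set."""
    defs = TRAIT_DEFS[: params.n_traits]
    n_arch = 3
    arch = rng.integers(n_arch, size=n_species)
    cols: dict[str, list] = {}
    specs: list[ColumnSpec] = []
    for name, kind, levels in defs:
        if name == "Origin":
            cols[name] = [origin] * n_species
            specs.append(ColumnSpec(name, kind, levels))
            continue
        if kind == "factor":
            probs = rng.dirichlet(np.ones(len(levels)), size=n_arch)
            draw = [levels[rng.choice(len(levels), p=probs[a])] for a in arch]
            cols[name] = draw
        else:  # ordinal
            lv = np.asarray(levels, dtype=float)
            centers = rng.uniform(lv.min(), lv.max(), size=n_arch)
            vals = np.round(np.clip(rng.normal(centers[arch], 1.0), lv.min(), lv.max()))
            cols[name] = vals.astype(int).tolist()
        specs.append(ColumnSpec(name, kind, levels))
    ids = [f"{prefix}{j+1:02d}" for j in range(n_species)]
    return SampleTable(pd.DataFrame(cols, index=ids), VariableSchema(specs))


def expected_fractions(params: SynthParams, block: str = "native") -> dict[str, float]:
    """Design shares in the fraction-key layout of a 2-predictor varpart."""
    shares = params.native_shares if block == "native" else params.alien_shares
    env, space, shared, noise = shares
    return {
        subset_key(["E"]): env,
        subset_key(["S"]): space,
        subset_key(["E", "S"]): shared,
        "residual": noise,
    }
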