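"""Run configuration, end-to-end pipeline execution, and run reports.

A run reads four delimited tables plus one YAML schema sidecar (top-level
keys ``native``, ``alien``, ``environment``, ``coords``, each a column -> kind
map), executes the full CUVARP pipeline deterministically for the configured
seed, and writes ``result.json``, ``diagram.json``, ``diagram.svg``,
``selection.log`` and ``run.log`` into the output directory.  Every default
in force is echoed into the logs so runs are self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .inference import PermutationDesign
from .pipeline import (
    as_percent,
    assemble_cuvarp,
    build_components,
    export_diagram,
    reciprocal_varpart,
    select_axes,
)
from .tables_io import VariableSchema, align_rows, load_table1_fixture, read_table


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


@dataclass
class RunConfig:
    native: str
    alien: str
    environment: str
    coords: str
    schema: str
    out: str
    seed: int
    alpha: float = 0.05
    n_perm: int = 999
    design_kind: str = "free"
    design_blocks: str | None = None  # env column holding block labels
    mirror: bool = False
    keep_policy: str = "positive"
    floor_negatives: bool = True
    detrend: bool = False
    max_axes: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm > 0 and self.seed is None:
            raise ValueError("a seed is mandatory for any stochastic run")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig):
    """Execute tables_io -> components -> selection -> varpart -> diagram."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"config: {json.dumps(config.__dict__, default=str, sort_keys=True)}"]

    schema_path = Path(config.schema)
    if not schema_path.exists():
        raise StageError(f"stage 'tables_io' failed: schema file not found: {schema_path}")
    with open(schema_path) as fh:
        schemas = yaml.safe_load(fh)
    tables = {}
    for key in ("native", "alien", "environment", "coords"):
        if key not in schemas:
            raise StageError(f"stage 'tables_io' failed: schema key {key!r} missing "
                             f"from {schema_path}")
        schema = VariableSchema.from_dict(schemas[key])
        tables[key] = _stage("tables_io", read_table, getattr(config, key), schema)
    aligned, dropped = _stage("tables_io", align_rows, list(tables.values()))
    native, alien, environment, coords = aligned
    for key, d in zip(tables, dropped):
        if d:
            log_lines.append(f"align: dropped {len(d)} row(s) from {key}: {d}")

    design = None
    if config.design_kind != "free":
        labels = None
        if config.design_blocks:
            labels = list(environment.data[config.design_blocks])
        design = PermutationDesign(
            kind=config.design_kind, block_labels=labels, allow_mirror=config.mirror
        )
    log_lines.append(
        f"defaults in force: alpha={config.alpha}, n_perm={config.n_perm}, "
        f"keep={config.keep_policy}, db-MEM threshold=auto (MST largest edge), "
        f"design={design.summary() if design else 'free'}, "
        f"negative fractions floored at render time={config.floor_negatives}"
    )

    comps = _stage("build_components", build_components, native, alien, environment, coords)
    sel = _stage(
        "select_axes", select_axes, comps, config.alpha, config.n_perm,
        config.seed, design, config.max_axes,
    )
    recip = _stage("reciprocal_varpart", reciprocal_varpart, sel, design,
                   config.n_perm, config.seed)
    result = _stage("assemble_cuvarp", assemble_cuvarp, recip.varparts, recip.totals)
    spec, svg = _stage("export_diagram", export_diagram, result, config.floor_negatives)

    payload = {
        "config": {
            "alpha": config.alpha, "n_perm": config.n_perm, "seed": config.seed,
            "design": design.summary() if design else "free",
        },
        "selected_axes": sel.axes,
        "result": result.to_dict(),
        "explained_percent": as_percent(result.explained_sum, result.grand_total),
        "residual_percent": as_percent(result.residual_sum, result.grand_total),
    }
    validate_result_json(payload)
    (out / "result.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    (out / "diagram.json").write_text(json.dumps(spec.to_json_dict(), indent=2, sort_keys=True))
    (out / "diagram.svg").write_text(svg)
    sel_lines = [json.dumps(rec, sort_keys=True) for rec in sel.selection_log]
    sel_lines += [f"warning: {w}" for w in sel.warnings]
    (out / "selection.log").write_text("\n".join(sel_lines) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return result


# ---------------------------------------------------------------------------
# result.json schema validation (minimal JSON-schema subset)

def _validate(obj, schema, path="$") -> list[str]:
    errs: list[str] = []
    t = schema.get("type")
    type_map = {
        "object": dict, "array": list, "string": str,
        "number": (int, float), "integer": int, "boolean": bool,
    }
    if t and not isinstance(obj, type_map[t]):
        return [f"{path}: expected {t}, got {type(obj).__name__}"]
    if t == "integer" and isinstance(obj, bool):
        return [f"{path}: expected integer, got bool"]
    if "enum" in schema and obj not in schema["enum"]:
        errs.append(f"{path}: {obj!r} not in {schema['enum']}")
    if t == "object":
        for req in schema.get("required", []):
            if req not in obj:
                errs.append(f"{path}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in obj:
                errs += _validate(obj[key], sub, f"{path}.{key}")
    if t == "array" and "items" in schema:
        for i, item in enumerate(obj):
            errs += _validate(item, schema["items"], f"{path}[{i}]")
    return errs


def validate_result_json(payload: dict) -> None:
    """Check a result payload against the shipped JSON schema."""
    with resources.files("cuvarp.data").joinpath("result.schema.json").open() as fh:
        schema = json.load(fh)
    errs = _validate(payload, schema)
    if errs:
        raise ValueError("result.json does not validate: " + "; ".join(errs))


# ---------------------------------------------------------------------------
# fixture report

def table1_checks() -> list[tuple[str, int, int, bool]]:
    """Recompute the packaged occurrence-table marginals against the printed
    values; returns (description, computed, expected, pass) rows."""
    fx = load_table1_fixture()
    checks = [
        ("total species", len(fx.records), 28),
        ("gastropods", fx.count(taxon_class="gastropod"), 17),
        ("bivalves", fx.count(taxon_class="bivalve"), 11),
        ("alien invasive species", fx.count(origin="AIS"), 6),
        ("gastropods present in T3", fx.count(taxon_class="gastropod", T3=1), 15),
        ("bivalves present in T3", fx.count(taxon_class="bivalve", T3=1), 8),
    ]
    return [(name, got, want, got == want) for name, got, want in checks]
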