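"""Row-identified mixed-type tables and their delimited-text I/O.

Community (sites x species), environment, coordinate, and trait data all
travel through the same carrier, a :class:`SampleTable`: a pandas DataFrame
indexed by row ids plus a :class:`VariableSchema` declaring, per column,
whether it is quantitative, ordinal, factor, or binary, and its Gower weight.
Missing values are kept missing (NaN) and resolved downstream by pairwise
deletion in the Gower computation, never silently zero-filled.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

VALID_KINDS = ("quantitative", "ordinal", "factor", "binary")

#: strings interpreted as missing in delimited files
NA_MARKERS = ("", "NA")


class SchemaError(ValueError):
    """A table does not conform to its declared variable schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared type of one table column.

    ``levels`` is the ordered level list for ordinals (integer codes) and the
    admissible level set for factors; ``weight`` is the non-negative Gower
    weight (default 1).
    """

    name: str
    kind: str
    levels: tuple | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise SchemaError(
                f"column {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {VALID_KINDS}"
            )
        if not (self.weight >= 0):
            raise SchemaError(f"column {self.name!r}: negative weight {self.weight}")


class VariableSchema:
    """Ordered collection of :class:`ColumnSpec`, one per table column."""

    def __init__(self, columns: Sequence[ColumnSpec]):
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate schema column(s): {dup}")
        if columns and not any(c.weight > 0 for c in columns):
            raise SchemaError("at least one column must have a positive weight")
        self._columns = {c.name: c for c in columns}

    @property
    def names(self) -> list[str]:
        return list(self._columns)

    def __getitem__(self, name: str) -> ColumnSpec:
        return self._columns[name]

    def __contains__(self, name: str) -> bool:
        return name in self._columns

    def __len__(self) -> int:
        return len(self._columns)

    def __iter__(self):
        return iter(self._columns.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, VariableSchema) and list(self) == list(other)

    def subset(self, names: Iterable[str]) -> "VariableSchema":
        return VariableSchema([self._columns[n] for n in names])

    @classmethod
    def all_quantitative(cls, names: Iterable[str]) -> "VariableSchema":
        return cls([ColumnSpec(n, "quantitative") for n in names])

    # -- YAML/JSON sidecar -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        cols = []
        for name, spec in d.items():
            if isinstance(spec, str):
                spec = {"kind": spec}
            levels = spec.get("levels")
            cols.append(
                ColumnSpec(
                    name,
                    spec["kind"],
                    tuple(levels) if levels is not None else None,
                    float(spec.get("weight", 1.0)),
                )
            )
        return cls(cols)

    def to_dict(self) -> dict:
        out: dict = {}
        for c in self:
            entry: dict = {"kind": c.kind}
            if c.levels is not None:
                entry["levels"] = list(c.levels)
            if c.weight != 1.0:
                entry["weight"] = c.weight
            out[c.name] = entry
        return out

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _coerce_column(values: pd.Series, spec: ColumnSpec) -> pd.Series:
    """Coerce one raw column per its spec; raise naming the offending cell."""
    if spec.kind in ("quantitative", "ordinal", "binary"):
        out = pd.to_numeric(values, errors="coerce")
        bad = out.isna() & values.notna()
        if bad.any():
            row = bad.idxmax()
            raise SchemaError(
                f"column {spec.name!r}, row {row!r}: cannot coerce "
                f"{values[row]!r} to {spec.kind}"
            )
        present = out.dropna()
        if spec.kind == "ordinal":
            if not np.allclose(present, np.round(present)):
                row = present[present != np.round(present)].index[0]
                raise SchemaError(
                    f"column {spec.name!r}, row {row!r}: ordinal value "
                    f"{present[row]!r} is not an integer"
                )
            if spec.levels is not None:
                outside = present[~present.isin(spec.levels)]
                if len(outside):
                    row = outside.index[0]
                    raise SchemaError(
                        f"column {spec.name!r}, row {row!r}: value {outside.iloc[0]!r} "
                        f"outside declared levels {list(spec.levels)}"
                    )
        if spec.kind == "binary":
            outside = present[~present.isin((0, 1))]
            if len(outside):
                row = outside.index[0]
                raise SchemaError(
                    f"column {spec.name!r}, row {row!r}: binary value "
                    f"{outside.iloc[0]!r} is not 0/1"
                )
        return out.astype(float)
    # factor
    out = values.astype(object).where(values.notna(), other=np.nan)
    if spec.levels is not None:
        present = out.dropna()
        outside = present[~present.isin(spec.levels)]
        if len(outside):
            row = outside.index[0]
            raise SchemaError(
                f"column {spec.name!r}, row {row!r}: level {outside.iloc[0]!r} "
                f"outside declared levels {list(spec.levels)}"
            )
    return out


@dataclass
class SampleTable:
    """A row-identified table of mixed-type variables with a schema."""

    data: pd.DataFrame
    schema: VariableSchema

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = sorted(set(idx[idx.duplicated()]))
            raise SchemaError(f"duplicate row id(s): {dup}")
        missing = [c for c in self.data.columns if c not in self.schema]
        if missing:
            raise SchemaError(f"column(s) {missing} present in table but absent from schema")
        absent = [c for c in self.schema.names if c not in self.data.columns]
        if absent:
            raise SchemaError(f"schema column(s) {absent} absent from table")
        coerced = {c: _coerce_column(self.data[c], self.schema[c]) for c in self.data.columns}
        self.data = pd.DataFrame(coerced, index=idx)[list(self.data.columns)]

    # -- basic views -------------------------------------------------------
    @property
    def row_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_rows(self) -> int:
        return len(self.data)

    def column_kind(self, name: str) -> str:
        return self.schema[name].kind

    @classmethod
    def from_numeric(cls, data: pd.DataFrame) -> "SampleTable":
        """Wrap an all-quantitative DataFrame (e.g. ordination scores)."""
        return cls(data, VariableSchema.all_quantitative(data.columns))

    def numeric(self) -> np.ndarray:
        """Numeric matrix of all non-factor columns (factors rejected)."""
        factors = [c for c in self.data.columns if self.schema[c].kind == "factor"]
        if factors:
            raise SchemaError(f"factor column(s) {factors} have no direct numeric view")
        return self.data.to_numpy(dtype=float)

    def to_model_matrix(self) -> pd.DataFrame:
        """Numeric design matrix: factors expanded to dummies (first level dropped)."""
        parts = []
        for c in self.data.columns:
            spec = self.schema[c]
            if spec.kind == "factor":
                levels = spec.levels
                if levels is None:
                    levels = tuple(pd.unique(self.data[c].dropna()))
                for lev in levels[1:]:
                    parts.append((self.data[c] == lev).astype(float).rename(f"{c}[{lev}]"))
            else:
                parts.append(self.data[c].astype(float))
        return pd.concat(parts, axis=1) if parts else pd.DataFrame(index=self.data.index)

    def select(self, columns: Sequence[str]) -> "SampleTable":
        return SampleTable(self.data[list(columns)].copy(), self.schema.subset(columns))


# ---------------------------------------------------------------------------
# delimited-text I/O

def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_table(path: str | Path, schema: VariableSchema) -> SampleTable:
    """Read a delimited table (first column = row id, header mandatory)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    raw = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, dtype=str,
        na_values=list(NA_MARKERS), keep_default_na=False,
    )
    if raw.index.has_duplicates:
        dup = sorted(set(raw.index[raw.index.duplicated()]))
        raise SchemaError(f"{path}: duplicate row id(s): {dup}")
    raw.index.name = None
    return SampleTable(raw, schema)


def write_table(table: SampleTable, path: str | Path) -> None:
    out = table.data.copy()
    # integral numeric kinds written without a trailing .0
    for c in out.columns:
        if table.schema[c].kind in ("ordinal", "binary"):
            out[c] = out[c].astype("Int64")
    out.to_csv(path, sep=_sep_for(path), index_label="id", na_rep="NA")


def align_rows(tables: Sequence[SampleTable]) -> tuple[list[SampleTable], list[list]]:
    """Restrict tables to their common row ids, in the first table's order.

    Returns the aligned tables and, per input table, the list of row ids that
    were dropped from it.
    """
    if len(tables) < 2:
        raise ValueError("align_rows needs at least two tables")
    common = set(tables[0].row_ids)
    for t in tables[1:]:
        common &= set(t.row_ids)
    if not common:
        raise ValueError("tables share no common row ids")
    order = [r for r in tables[0].row_ids if r in common]
    aligned, dropped = [], []
    for t in tables:
        dropped.append([r for r in t.row_ids if r not in common])
        aligned.append(SampleTable(t.data.loc[order].copy(), t.schema))
    return aligned, dropped


# ---------------------------------------------------------------------------
# packaged species-occurrence fixture

@dataclass
class Table1Fixture:
    """The packaged 28-species occurrence list (code, class, T1-T3, origin)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["code", "taxon_class", "T1", "T2", "T3", "origin"]
        if list(self.records.columns) != req:
            raise ValueError(f"fixture columns must be {req}")
        if len(self.records) != 28:
            raise ValueError(f"fixture must hold exactly 28 records, got {len(self.records)}")
        if self.records["code"].duplicated().any():
            raise ValueError("fixture species codes must be unique")
        occ = self.records[["T1", "T2", "T3"]].to_numpy()
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occurrence values must be binary")

    def count(self, **criteria) -> int:
        """Count records matching all column == value criteria."""
        mask = pd.Series(True, index=self.records.index)
        for col, val in criteria.items():
            mask &= self.records[col] == val
        return int(mask.sum())

    def community_table(self, period: str) -> pd.DataFrame:
        """One-row presence/absence vector for a period ('T1'|'T2'|'T3')."""
        return self.records.set_index("code")[[period]].T


def load_table1_fixture() -> Table1Fixture:
    with resources.files("cuvarp.data").joinpath("table1.csv").open() as fh:
        records = pd.read_csv(io.StringIO(fh.read()))
    return Table1Fixture(records)
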