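"""Typed, chunk-friendly I/O for wide variant-annotation tables.

Annotation exports from pipelines that stack VEP/OpenCravat-style tools are
wide CSVs mixing numerical scores, categorical annotations and free-text
keyword fields, with heavy and inconsistent missing-value conventions. This
module reads such tables against a declared per-column schema, normalises
missingness, and degrades dirty cells gracefully (coercion failures become
missing, counted, never fatal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Cell contents treated as missing unless a ColumnSpec overrides them.
DEFAULT_MISSING_TOKENS = ("", "NA", "N/A", ".", "-")

COLUMN_KINDS = (
    "numerical",
    "categorical_ordinal",
    "categorical_nominal",
    "keyword",
    "label",
    "identifier",
)


class SchemaError(ValueError):
    """A table does not match its declared column schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declared type and missing-value convention for one column."""

    name: str
    kind: str
    ordinal_order: tuple[str, ...] | None = None
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS

    def __post_init__(self) -> None:
        if self.kind not in COLUMN_KINDS:
            raise SchemaError(
                f"column {self.name!r}: unknown kind {self.kind!r}; "
                f"expected one of {COLUMN_KINDS}"
            )
        if self.kind == "categorical_ordinal":
            if not self.ordinal_order:
                raise SchemaError(
                    f"ordinal column {self.name!r} needs an ordinal_order"
                )
            if len(set(self.ordinal_order)) != len(self.ordinal_order):
                raise SchemaError(
                    f"ordinal column {self.name!r}: duplicate categories in order"
                )


@dataclass
class AnnotatedVariantTable:
    """One row per variant; typed columns with explicit missingness.

    Numerical columns are float64 with NaN for missing; all other kinds are
    pandas ``string`` dtype with ``pd.NA`` for missing.
    """

    specs: list[ColumnSpec]
    data: pd.DataFrame
    coercion_failures: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        spec_names = [s.name for s in self.specs]
        if list(self.data.columns) != spec_names:
            raise SchemaError(
                f"data columns {list(self.data.columns)} do not match "
                f"specs {spec_names}"
            )

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def spec(self, name: str) -> ColumnSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)

    def columns_of_kind(self, *kinds: str) -> list[str]:
        return [s.name for s in self.specs if s.kind in kinds]

    @property
    def feature_columns(self) -> list[str]:
        return self.columns_of_kind(
            "numerical", "categorical_ordinal", "categorical_nominal", "keyword"
        )

    @property
    def label_column(self) -> str | None:
        cols = self.columns_of_kind("label")
        return cols[0] if cols else None

    def subset_rows(self, index: np.ndarray) -> "AnnotatedVariantTable":
        return AnnotatedVariantTable(
            specs=list(self.specs),
            data=self.data.iloc[np.asarray(index)].reset_index(drop=True),
            coercion_failures=dict(self.coercion_failures),
        )

    def select_columns(self, names: Sequence[str]) -> "AnnotatedVariantTable":
        keep = set(names)
        specs = [s for s in self.specs if s.name in keep]
        return AnnotatedVariantTable(
            specs=specs,
            data=self.data[[s.name for s in specs]].copy(),
            coercion_failures=dict(self.coercion_failures),
        )

    def write_csv(self, path: str | Path) -> None:
        """Serialise with empty string as the missing marker."""
        self.data.to_csv(path, index=False, na_rep="")


def _coerce_column(
    raw: pd.Series, spec: ColumnSpec
) -> tuple[pd.Series, int]:
    """Apply a spec to one raw string column; returns (typed, n_failures)."""
    s = raw.astype("string")
    missing = s.isna() | s.isin(list(spec.missing_tokens))
    s = s.mask(missing)
    if spec.kind == "numerical":
        out = pd.to_numeric(s, errors="coerce").astype("float64")
        failures = int((out.isna() & ~s.isna()).sum())
        return out, failures
    return s, 0


def read_annotation_csv(
    path: str | Path,
    specs: Sequence[ColumnSpec],
    chunk_rows: int = 50_000,
) -> AnnotatedVariantTable:
    """Read a CSV in chunks against a declared schema.

    Columns absent from ``specs`` are skipped with a warning; cells matching a
    spec's missing tokens, or failing numeric coercion, become missing (the
    latter counted in ``coercion_failures``). The result is independent of
    ``chunk_rows``.
    """
    if chunk_rows < 1:
        raise ValueError("chunk_rows must be >= 1")
    path = Path(path)
    header = pd.read_csv(path, nrows=0, dtype=str)
    file_cols = list(header.columns)
    spec_by_name = {s.name: s for s in specs}
    missing_cols = [n for n in spec_by_name if n not in file_cols]
    if missing_cols:
        label_missing = [
            n for n in missing_cols if spec_by_name[n].kind == "label"
        ]
        if label_missing:
            raise SchemaError(
                f"label column(s) {label_missing} not present in {path}"
            )
        raise SchemaError(f"columns {missing_cols} not present in {path}")
    skipped = [c for c in file_cols if c not in spec_by_name]
    if skipped:
        logger.warning("skipping %d unspecified columns: %s", len(skipped), skipped)

    ordered_specs = [spec_by_name[c] for c in file_cols if c in spec_by_name]
    use_cols = [s.name for s in ordered_specs]

    chunks: list[pd.DataFrame] = []
    failures = {s.name: 0 for s in ordered_specs}
    reader = pd.read_csv(
        path,
        usecols=use_cols,
        dtype=str,
        chunksize=chunk_rows,
        keep_default_na=False,
    )
    for raw in reader:
        typed = {}
        for spec in ordered_specs:
            col, n_fail = _coerce_column(raw[spec.name], spec)
            typed[spec.name] = col
            failures[spec.name] += n_fail
        chunks.append(pd.DataFrame(typed, index=raw.index)[use_cols])
    if chunks:
        data = pd.concat(chunks, axis=0).reset_index(drop=True)
    else:
        data = pd.DataFrame(
            {s.name: pd.Series([], dtype="float64" if s.kind == "numerical" else "string")
             for s in ordered_specs}
        )
    total_failures = {k: v for k, v in failures.items() if v}
    if total_failures:
        logger.warning("type-coercion failures (set missing): %s", total_failures)
    return AnnotatedVariantTable(
        specs=ordered_specs, data=data, coercion_failures=total_failures
    )


def sigmoid(logits: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(logits, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out if out.ndim else float(out)


def write_predictions(
    table: AnnotatedVariantTable,
    logits: np.ndarray,
    path: str | Path,
    identifier_column: str | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Write per-variant predictions (logit, probability, binary call).

    The binary call is ``pathogenic`` iff probability > ``threshold``; a
    probability exactly at the threshold is called benign (ties go to the
    benign side, matching a strict > rule on the pathogenic call).
    """
    logits = np.asarray(logits, dtype=float).ravel()
    if logits.shape[0] != table.n_rows:
        raise ValueError(
            f"got {logits.shape[0]} logits for {table.n_rows} rows"
        )
    probs = sigmoid(logits)
    if identifier_column is None:
        id_cols = table.columns_of_kind("identifier")
        identifier_column = id_cols[0] if id_cols else None
    ids = (
        table.data[identifier_column]
        if identifier_column
        else pd.Series(np.arange(table.n_rows), name="row_id").astype("string")
    )
    label_col = table.label_column
    out = pd.DataFrame(
        {
            "identifier": ids.reset_index(drop=True),
            "original_label": (
                table.data[label_col].reset_index(drop=True)
                if label_col
                else pd.Series([pd.NA] * table.n_rows, dtype="string")
            ),
            "logit": logits,
            "probability": probs,
            "call": np.where(probs > threshold, "pathogenic", "benign"),
        }
    )
    out.to_csv(path, index=False, float_format="%.17g")
    return out


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        dtype={"identifier": str, "original_label": str, "call": str},
        keep_default_na=False,
        na_values=[""],
    )


def load_schema(path: str | Path) -> list[ColumnSpec]:
    """Load column specs from a YAML/JSON mapping of column -> kind or options."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for name, val in raw.items():
        if isinstance(val, str):
            specs.append(ColumnSpec(name=name, kind=val))
        else:
            specs.append(
                ColumnSpec(
                    name=name,
                    kind=val["kind"],
                    ordinal_order=tuple(val.get("ordinal_order", ()) or ()) or None,
                    missing_tokens=tuple(
                        val.get("missing_tokens", DEFAULT_MISSING_TOKENS)
                    ),
                )
            )
    return specs


def dump_schema(specs: Iterable[ColumnSpec], path: str | Path) -> None:
    out = {}
    for s in specs:
        entry: dict = {"kind": s.kind}
        if s.ordinal_order:
            entry["ordinal_order"] = list(s.ordinal_order)
        if tuple(s.missing_tokens) != DEFAULT_MISSING_TOKENS:
            entry["missing_tokens"] = list(s.missing_tokens)
        out[s.name] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
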