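"""Train-fitted preprocessing for annotation tables.

The pipeline mirrors what annotation matrices need before a tabular deep
model: drop columns that are mostly missing, impute (worst-case fill where a
domain direction is known, otherwise mean/median by a moment heuristic),
scale (standard for roughly normal columns, min-max otherwise), binarize
keyword columns, integer-encode categoricals with reserved missing/unknown
codes, and drop near-constant columns. All statistics are learned on the
training split only; ``apply_preprocessor`` never recomputes them.

Stage order at fit time: missingness filter -> imputation -> removal of
exactly-constant columns (a constant column admits no scaler) -> scaling ->
encoding -> threshold variance filter on the scaled/encoded values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .table_io import AnnotatedVariantTable, SchemaError

#: Columns whose training missing fraction strictly exceeds this are dropped.
DEFAULT_MISSINGNESS_THRESHOLD = 0.25
#: Scaled/encoded columns with variance <= this (or a majority category with
#: frequency > 1 - this) are dropped.
DEFAULT_VARIANCE_THRESHOLD = 1e-4
#: Substrings whose case-insensitive presence sets a keyword column to 1.
DEFAULT_KEYWORDS = ("pathogenic", "damaging", "deleterious")

MISSING_CATEGORY = "__missing__"

#: Moment heuristic: a column is "normal enough" for mean imputation and
#: standard scaling iff |skewness| < 1 and excess kurtosis < 3.
SKEWNESS_LIMIT = 1.0
EXCESS_KURTOSIS_LIMIT = 3.0


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class ImputationRule:
    kind: str  # worst_case | mean | median
    fill_value: float
    worst_case_direction: str | None = None  # low_is_worst | high_is_worst

    def __post_init__(self) -> None:
        if self.kind == "worst_case" and self.worst_case_direction not in (
            "low_is_worst",
            "high_is_worst",
        ):
            raise ContractError("worst_case imputation needs a direction")


@dataclass(frozen=True)
class ScalerRule:
    kind: str  # standard | min_max
    params: tuple[float, float]  # (mean, sd) or (min, max)

    def transform(self, values: np.ndarray) -> np.ndarray:
        a, b = self.params
        if self.kind == "standard":
            return (values - a) / b
        # out-of-range apply-time values pass through unclipped
        return (values - a) / (b - a)


@dataclass(frozen=True)
class CategoricalEncoding:
    """category -> integer code; missing has its own category, unseen values
    map to the reserved unknown code (== n_categories)."""

    categories: tuple[str, ...]

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def unknown_code(self) -> int:
        return len(self.categories)

    def encode(self, values: pd.Series) -> np.ndarray:
        mapping = {c: i for i, c in enumerate(self.categories)}
        filled = values.astype("string").fillna(MISSING_CATEGORY)
        return np.array(
            [mapping.get(v, self.unknown_code) for v in filled], dtype=np.int64
        )


@dataclass(frozen=True)
class KeywordRule:
    keywords: tuple[str, ...]

    def encode(self, values: pd.Series) -> np.ndarray:
        """1 iff any keyword occurs case-insensitively; missing counts as 0."""
        lowered = values.astype("string").str.lower()
        hit = np.zeros(len(values), dtype=float)
        for kw in self.keywords:
            hit = np.maximum(hit, lowered.str.contains(kw.lower(), regex=False)
                             .fillna(False).to_numpy(dtype=float))
        return hit


@dataclass
class PreprocessConfig:
    missingness_threshold: float = DEFAULT_MISSINGNESS_THRESHOLD
    variance_threshold: float = DEFAULT_VARIANCE_THRESHOLD
    worst_case_hints: dict[str, str] = field(default_factory=dict)
    keyword_rules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    one_hot_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.missingness_threshold < 1.0:
            raise ContractError("missingness_threshold must be in (0, 1)")
        if self.variance_threshold < 0:
            raise ContractError("variance_threshold must be >= 0")


@dataclass
class DesignMatrices:
    """Model-ready output: dense numerical block + integer categorical codes."""

    X_num: np.ndarray  # (n, p_num) float64, no NaN
    X_cat: np.ndarray  # (n, p_cat) int64
    numerical_names: list[str]
    categorical_names: list[str]
    categorical_cardinalities: list[int]  # excludes the reserved unknown code


def drop_high_missingness(
    table: AnnotatedVariantTable, threshold: float = DEFAULT_MISSINGNESS_THRESHOLD
) -> tuple[AnnotatedVariantTable, list[str]]:
    """Drop feature columns whose missing fraction strictly exceeds threshold."""
    if not 0.0 < threshold < 1.0:
        raise ContractError("threshold must be in (0, 1)")
    frac = table.missing_mask.mean(axis=0)
    dropped = [c for c in table.feature_columns if frac[c] > threshold]
    keep = [s.name for s in table.specs if s.name not in set(dropped)]
    return table.select_columns(keep), dropped


def _moments_accept_normal(values: np.ndarray) -> bool:
    if values.size < 3 or np.allclose(values, values[0]):
        return False
    skew = stats.skew(values)
    kurt = stats.kurtosis(values)  # excess (Fisher)
    return abs(skew) < SKEWNESS_LIMIT and kurt < EXCESS_KURTOSIS_LIMIT


def choose_imputation(
    values: np.ndarray, domain_hint: str | None = None
) -> ImputationRule:
    """Pick an imputation rule from observed (non-missing) values.

    A domain hint forces worst-case fill at the observed extreme in the hinted
    direction (e.g. an allele-frequency column where rare is worst fills with
    the minimum). Otherwise the moment heuristic picks mean (normal-looking)
    or median.
    """
    observed = np.asarray(values, dtype=float)
    observed = observed[~np.isnan(observed)]
    if observed.size == 0:
        raise ContractError("all-missing column should have been dropped")
    if observed.size < 2:
        raise ContractError("need >= 2 observed values to choose imputation")
    if domain_hint is not None:
        if domain_hint not in ("low_is_worst", "high_is_worst"):
            raise ContractError(f"unknown worst-case direction {domain_hint!r}")
        fill = float(observed.min() if domain_hint == "low_is_worst" else observed.max())
        return ImputationRule("worst_case", fill, domain_hint)
    if _moments_accept_normal(observed):
        return ImputationRule("mean", float(observed.mean()))
    return ImputationRule("median", float(np.median(observed)))


def choose_scaler(values: np.ndarray) -> ScalerRule:
    """Standard scaling for normal-looking columns, min-max otherwise.

    Expects imputed (complete) training values; constant columns are the
    variance filter's job and are rejected here.
    """
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ContractError("choose_scaler expects imputed values")
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        raise ContractError("constant column reached choose_scaler")
    if _moments_accept_normal(values):
        mean = float(values.mean())
        sd = float(values.std(ddof=0))
        return ScalerRule("standard", (mean, sd))
    return ScalerRule("min_max", (lo, hi))


def variance_filter(
    numeric: pd.DataFrame,
    categorical_codes: pd.DataFrame,
    threshold: float = DEFAULT_VARIANCE_THRESHOLD,
) -> list[str]:
    """Names of columns to drop: scaled numericals with variance <= threshold,
    encoded categoricals whose majority category frequency exceeds
    1 - threshold."""
    if threshold < 0:
        raise ContractError("variance threshold must be >= 0")
    dropped = [
        c for c in numeric.columns
        if float(numeric[c].to_numpy().var()) <= threshold
    ]
    for c in categorical_codes.columns:
        counts = categorical_codes[c].value_counts()
        if counts.iloc[0] / len(categorical_codes) > 1.0 - threshold:
            dropped.append(c)
    return dropped


@dataclass
class FittedPreprocessor:
    """Everything learned at fit time, sufficient to transform any table."""

    config: PreprocessConfig
    kept_numerical: list[str]
    kept_categorical: list[str]
    kept_keyword: list[str]
    dropped_missingness: list[str]
    dropped_variance: list[str]
    imputation: dict[str, ImputationRule]
    scaling: dict[str, ScalerRule]
    encodings: dict[str, CategoricalEncoding]
    keyword_encoders: dict[str, KeywordRule]
    one_hot_maps: dict[str, CategoricalEncoding]
    unknown_counts: dict[str, int] = field(default_factory=dict)

    @property
    def categorical_cardinalities(self) -> list[int]:
        return [self.encodings[c].n_categories for c in self.kept_categorical]

    def to_json(self) -> str:
        def enc(obj):
            return obj.__dict__ if hasattr(obj, "__dict__") else obj

        payload = {
            "config": {
                "missingness_threshold": self.config.missingness_threshold,
                "variance_threshold": self.config.variance_threshold,
                "worst_case_hints": self.config.worst_case_hints,
                "keyword_rules": {
                    k: list(v) for k, v in self.config.keyword_rules.items()
                },
                "one_hot_columns": list(self.config.one_hot_columns),
            },
            "kept_numerical": self.kept_numerical,
            "kept_categorical": self.kept_categorical,
            "kept_keyword": self.kept_keyword,
            "dropped_missingness": self.dropped_missingness,
            "dropped_variance": self.dropped_variance,
            "imputation": {
                k: {"kind": v.kind, "fill_value": v.fill_value,
                    "worst_case_direction": v.worst_case_direction}
                for k, v in self.imputation.items()
            },
            "scaling": {
                k: {"kind": v.kind, "params": list(v.params)}
                for k, v in self.scaling.items()
            },
            "encodings": {
                k: list(v.categories) for k, v in self.encodings.items()
            },
            "keyword_encoders": {
                k: list(v.keywords) for k, v in self.keyword_encoders.items()
            },
            "one_hot_maps": {
                k: list(v.categories) for k, v in self.one_hot_maps.items()
            },
            "unknown_counts": self.unknown_counts,
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FittedPreprocessor":
        d = json.loads(text)
        cfg = d["config"]
        return cls(
            config=PreprocessConfig(
                missingness_threshold=cfg["missingness_threshold"],
                variance_threshold=cfg["variance_threshold"],
                worst_case_hints=dict(cfg["worst_case_hints"]),
                keyword_rules={k: tuple(v) for k, v in cfg["keyword_rules"].items()},
                one_hot_columns=tuple(cfg["one_hot_columns"]),
            ),
            kept_numerical=list(d["kept_numerical"]),
            kept_categorical=list(d["kept_categorical"]),
            kept_keyword=list(d["kept_keyword"]),
            dropped_missingness=list(d["dropped_missingness"]),
            dropped_variance=list(d["dropped_variance"]),
            imputation={
                k: ImputationRule(v["kind"], v["fill_value"], v["worst_case_direction"])
                for k, v in d["imputation"].items()
            },
            scaling={
                k: ScalerRule(v["kind"], tuple(v["params"]))
                for k, v in d["scaling"].items()
            },
            encodings={
                k: CategoricalEncoding(tuple(v)) for k, v in d["encodings"].items()
            },
            keyword_encoders={
                k: KeywordRule(tuple(v)) for k, v in d["keyword_encoders"].items()
            },
            one_hot_maps={
                k: CategoricalEncoding(tuple(v)) for k, v in d["one_hot_maps"].items()
            },
            unknown_counts=dict(d.get("unknown_counts", {})),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "FittedPreprocessor":
        return cls.from_json(Path(path).read_text())


def _fit_categorical_encoding(
    values: pd.Series, ordinal_order: tuple[str, ...] | None
) -> CategoricalEncoding:
    if ordinal_order:
        cats = list(ordinal_order)  # declared ranking fixes the codes
    else:
        cats = sorted(values.dropna().astype("string").unique().tolist())
    if MISSING_CATEGORY not in cats:
        cats.append(MISSING_CATEGORY)
    return CategoricalEncoding(tuple(cats))


def fit_preprocessor(
    train_table: AnnotatedVariantTable,
    config: PreprocessConfig | None = None,
) -> FittedPreprocessor:
    """Learn the full per-column plan from training rows only."""
    config = config or PreprocessConfig()
    table, dropped_missing = drop_high_missingness(
        train_table, config.missingness_threshold
    )

    numerical = table.columns_of_kind("numerical")
    nominal = table.columns_of_kind("categorical_nominal")
    ordinal = table.columns_of_kind("categorical_ordinal")
    keyword = table.columns_of_kind("keyword")
    one_hot = [c for c in nominal if c in set(config.one_hot_columns)]
    embed_nominal = [c for c in nominal if c not in set(one_hot)]

    imputation: dict[str, ImputationRule] = {}
    scaling: dict[str, ScalerRule] = {}
    numeric_block: dict[str, np.ndarray] = {}
    kept_numerical: list[str] = []
    constant_dropped: list[str] = []
    for col in numerical:
        raw = table.data[col].to_numpy(dtype=float)
        rule = choose_imputation(raw, config.worst_case_hints.get(col))
        imputation[col] = rule
        filled = np.where(np.isnan(raw), rule.fill_value, raw)
        if filled.max() <= filled.min():
            constant_dropped.append(col)  # constant after imputation: no scaler
            continue
        scaler = choose_scaler(filled)
        scaling[col] = scaler
        numeric_block[col] = scaler.transform(filled)
        kept_numerical.append(col)

    keyword_encoders: dict[str, KeywordRule] = {}
    for col in keyword:
        rule = KeywordRule(tuple(config.keyword_rules.get(col, DEFAULT_KEYWORDS)))
        keyword_encoders[col] = rule
        numeric_block[col] = rule.encode(table.data[col])

    one_hot_maps: dict[str, CategoricalEncoding] = {}
    for col in one_hot:
        enc = _fit_categorical_encoding(table.data[col], None)
        one_hot_maps[col] = enc
        codes = enc.encode(table.data[col])
        for i, cat in enumerate(enc.categories):
            numeric_block[f"{col}={cat}"] = (codes == i).astype(float)

    encodings: dict[str, CategoricalEncoding] = {}
    cat_block: dict[str, np.ndarray] = {}
    for col in embed_nominal + ordinal:
        enc = _fit_categorical_encoding(
            table.data[col],
            table.spec(col).ordinal_order if col in set(ordinal) else None,
        )
        encodings[col] = enc
        cat_block[col] = enc.encode(table.data[col])

    numeric_df = pd.DataFrame(numeric_block)
    cat_df = pd.DataFrame(cat_block)
    dropped_var = variance_filter(numeric_df, cat_df, config.variance_threshold)
    dropped_var_set = set(dropped_var)

    kept_num_final = [
        c for c in kept_numerical + keyword + [
            f"{col}={cat}" for col in one_hot for cat in one_hot_maps[col].categories
        ]
        if c in numeric_df.columns and c not in dropped_var_set
    ]
    kept_cat_final = [c for c in embed_nominal + ordinal if c not in dropped_var_set]

    return FittedPreprocessor(
        config=config,
        kept_numerical=[c for c in kept_num_final if c in set(kept_numerical)],
        kept_categorical=kept_cat_final,
        kept_keyword=[c for c in keyword if c not in dropped_var_set],
        dropped_missingness=dropped_missing,
        dropped_variance=sorted(dropped_var_set | set(constant_dropped)),
        imputation={c: imputation[c] for c in kept_numerical if c not in dropped_var_set},
        scaling={c: scaling[c] for c in kept_numerical if c not in dropped_var_set},
        encodings={c: encodings[c] for c in kept_cat_final},
        keyword_encoders={
            c: keyword_encoders[c] for c in keyword if c not in dropped_var_set
        },
        one_hot_maps=one_hot_maps,
    )


def apply_preprocessor(
    fitted: FittedPreprocessor, table: AnnotatedVariantTable
) -> DesignMatrices:
    """Transform any table with fitted parameters only; output has no missing
    values and unseen categories map to each column's reserved unknown code."""
    needed = (
        fitted.kept_numerical
        + fitted.kept_categorical
        + fitted.kept_keyword
        + list(fitted.one_hot_maps)
    )
    absent = [c for c in needed if c not in table.data.columns]
    if absent:
        raise SchemaError(f"table is missing kept columns: {absent}")

    num_cols: list[np.ndarray] = []
    num_names: list[str] = []
    for col in fitted.kept_numerical:
        raw = table.data[col].to_numpy(dtype=float)
        rule = fitted.imputation[col]
        filled = np.where(np.isnan(raw), rule.fill_value, raw)
        num_cols.append(fitted.scaling[col].transform(filled))
        num_names.append(col)
    for col in fitted.kept_keyword:
        num_cols.append(fitted.keyword_encoders[col].encode(table.data[col]))
        num_names.append(col)
    drop_var = set(fitted.dropped_variance)
    for col, enc in fitted.one_hot_maps.items():
        codes = enc.encode(table.data[col])
        for i, cat in enumerate(enc.categories):
            name = f"{col}={cat}"
            if name in drop_var:
                continue
            num_cols.append((codes == i).astype(float))
            num_names.append(name)

    unknown_counts: dict[str, int] = {}
    cat_cols: list[np.ndarray] = []
    for col in fitted.kept_categorical:
        enc = fitted.encodings[col]
        codes = enc.encode(table.data[col])
        n_unknown = int((codes == enc.unknown_code).sum())
        if n_unknown:
            unknown_counts[col] = n_unknown
        cat_cols.append(codes)
    fitted.unknown_counts = unknown_counts

    n = table.n_rows
    X_num = (
        np.column_stack(num_cols) if num_cols else np.zeros((n, 0), dtype=float)
    )
    X_cat = (
        np.column_stack(cat_cols) if cat_cols else np.zeros((n, 0), dtype=np.int64)
    )
    if np.isnan(X_num).any():
        raise ContractError("apply produced missing values; imputation incomplete")
    return DesignMatrices(
        X_num=X_num,
        X_cat=X_cat,
        numerical_names=num_names,
        categorical_names=list(fitted.kept_categorical),
        categorical_cardinalities=fitted.categorical_cardinalities,
    )
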