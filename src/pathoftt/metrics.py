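"""Evaluation panel: six-category confusion matrix, collapsed 2x2, binary
metrics, and pre-sigmoid logit distribution summaries.

The six-category table cross-tabulates original clinical labels against the
binary calls. For the 2x2 panel the pathogenic side pools Pathogenic and
Likely Pathogenic, the benign side pools Benign auto, Benign and Likely
Benign, and VUS rows are excluded (they have no binary ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .labels import CATEGORY_ORDER, parse_category

#: Default collapse convention for the 2x2 panel.
POSITIVE_CATEGORIES = frozenset({"Pathogenic", "Likely Pathogenic"})
NEGATIVE_CATEGORIES = frozenset({"Benign auto", "Benign", "Likely Benign"})

METRIC_NAMES = (
    "sensitivity", "specificity", "fpr", "accuracy", "precision", "f1", "mcc"
)


class ContractError(ValueError):
    pass


def confusion_by_source(
    original_labels, binary_calls
) -> pd.DataFrame:
    """6x2 cross-tabulation: rows = original categories (all six, in canonical
    order, zero rows allowed), columns = predicted benign (0) / pathogenic (1)."""
    labels = np.asarray(original_labels, dtype=object)
    calls = np.asarray(binary_calls, dtype=int)
    if labels.shape[0] != calls.shape[0]:
        raise ContractError("labels and calls differ in length")
    cats = [parse_category(v).value for v in labels]
    out = pd.DataFrame(
        0,
        index=pd.Index([c.value for c in CATEGORY_ORDER], name="original"),
        columns=pd.Index(["benign", "pathogenic"], name="predicted"),
    )
    for cat, call in zip(cats, calls):
        out.loc[cat, "pathogenic" if call == 1 else "benign"] += 1
    return out


def collapse_confusion(
    confusion: pd.DataFrame,
    positive: frozenset[str] | set[str] = POSITIVE_CATEGORIES,
    negative: frozenset[str] | set[str] = NEGATIVE_CATEGORIES,
) -> tuple[int, int, int, int]:
    """Pool categories into (TP, FN, FP, TN); excluded categories are ignored."""
    positive, negative = set(positive), set(negative)
    if positive & negative:
        raise ContractError(
            f"positive/negative sets overlap: {positive & negative}"
        )
    pos = [parse_category(c).value for c in positive]
    neg = [parse_category(c).value for c in negative]
    tp = int(confusion.loc[pos, "pathogenic"].sum()) if pos else 0
    fn = int(confusion.loc[pos, "benign"].sum()) if pos else 0
    fp = int(confusion.loc[neg, "pathogenic"].sum()) if neg else 0
    tn = int(confusion.loc[neg, "benign"].sum()) if neg else 0
    return tp, fn, fp, tn


@dataclass(frozen=True)
class BinaryMetrics:
    sensitivity: float
    specificity: float
    fpr: float
    accuracy: float
    precision: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float, name: str) -> float:
    """Zero denominators yield NaN with a warning, never a silent 0."""
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning,
                      stacklevel=3)
        return float("nan")
    return num / den


def binary_metrics(tp: int, fn: int, fp: int, tn: int) -> BinaryMetrics:
    """Standard 2x2 panel; all inputs are raw counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); FPR = FP/(TN+FP);
    accuracy = (TP+TN)/all; precision = TP/(TP+FP); F1 = harmonic mean of
    precision and sensitivity; MCC = (TP*TN - FP*FN)/sqrt of the four
    marginal products. Undefined ratios are NaN with a warning.
    """
    if min(tp, fn, fp, tn) < 0:
        raise ContractError("confusion counts must be non-negative")
    total = tp + fn + fp + tn
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    fpr = _ratio(fp, tn + fp, "fpr")
    acc = _ratio(tp + tn, total, "accuracy")
    prec = _ratio(tp, tp + fp, "precision")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "f1")
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        warnings.warn("mcc undefined (zero marginal)", RuntimeWarning, stacklevel=2)
        mcc = float("nan")
    else:
        mcc = float((float(tp) * tn - float(fp) * fn) / np.sqrt(denom))
    return BinaryMetrics(sens, spec, fpr, acc, prec, f1, mcc)


def logit_distribution_summary(
    logits: np.ndarray,
    original_labels,
    interval: tuple[float, float] = (-2.0, 2.0),
) -> pd.DataFrame:
    """Per-category logit quantiles and the fraction strictly inside
    ``interval`` (the near-decision-boundary zone); data for a violin plot."""
    logits = np.asarray(logits, dtype=float)
    if logits.size and not np.isfinite(logits).all():
        raise ContractError("logits must be finite")
    labels = np.asarray(original_labels, dtype=object)
    cats = np.array([parse_category(v).value for v in labels], dtype=object)
    lo, hi = interval
    rows = []
    for cat in [c.value for c in CATEGORY_ORDER]:
        vals = logits[cats == cat]
        if vals.size:
            q = np.quantile(vals, [0.0, 0.25, 0.5, 0.75, 1.0])
            frac = float(((vals > lo) & (vals < hi)).mean())
        else:
            q = [np.nan] * 5
            frac = np.nan
        rows.append({
            "category": cat, "n": int(vals.size),
            "min": q[0], "q25": q[1], "median": q[2], "q75": q[3], "max": q[4],
            "fraction_in_interval": frac,
        })
    return pd.DataFrame(rows).set_index("category")


def evaluation_report(
    original_labels, binary_calls, logits=None
) -> dict:
    """Bundle the full panel as JSON-serialisable plain types."""
    conf = confusion_by_source(original_labels, binary_calls)
    tp, fn, fp, tn = collapse_confusion(conf)
    metrics = binary_metrics(tp, fn, fp, tn)
    report = {
        "confusion_by_source": {
            cat: {"benign": int(conf.loc[cat, "benign"]),
                  "pathogenic": int(conf.loc[cat, "pathogenic"])}
            for cat in conf.index
        },
        "collapsed": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
        "binary_metrics": metrics.as_dict(),
    }
    if logits is not None:
        summary = logit_distribution_summary(np.asarray(logits), original_labels)
        report["logit_summary"] = json_safe(
            summary.reset_index().to_dict(orient="records")
        )
    return json_safe(report)


def json_safe(obj):
    """Recursively convert NumPy scalars and NaN to JSON-friendly values."""
    if isinstance(obj, dict):
        return {k: json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    return obj
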