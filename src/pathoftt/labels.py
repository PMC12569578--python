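"""ACMG-style label handling: binarization, smoothing, stratified splits.

Clinical variant classification assigns one of six categories. Three are
treated as ground truth ("hard": Benign auto, Benign, Pathogenic) and three
carry residual uncertainty ("soft": Likely Benign, VUS, Likely Pathogenic).
For the binary benign/pathogenic task, hard rows supply fixed targets while
soft rows are labelled dynamically by pseudo-labeling; the mapping here only
records an advisory hint for the likely-* categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd


class AcmgCategory(str, Enum):
    BENIGN_AUTO = "Benign auto"
    BENIGN = "Benign"
    LIKELY_BENIGN = "Likely Benign"
    VUS = "VUS"
    LIKELY_PATHOGENIC = "Likely Pathogenic"
    PATHOGENIC = "Pathogenic"


CATEGORY_ORDER = (
    AcmgCategory.BENIGN_AUTO,
    AcmgCategory.BENIGN,
    AcmgCategory.LIKELY_BENIGN,
    AcmgCategory.VUS,
    AcmgCategory.LIKELY_PATHOGENIC,
    AcmgCategory.PATHOGENIC,
)

HARD_CATEGORIES = frozenset(
    {AcmgCategory.BENIGN_AUTO, AcmgCategory.BENIGN, AcmgCategory.PATHOGENIC}
)

_ALIASES = {
    "benign auto": AcmgCategory.BENIGN_AUTO,
    "benign_auto": AcmgCategory.BENIGN_AUTO,
    "benign-auto": AcmgCategory.BENIGN_AUTO,
    "benign": AcmgCategory.BENIGN,
    "likely benign": AcmgCategory.LIKELY_BENIGN,
    "likely_benign": AcmgCategory.LIKELY_BENIGN,
    "vus": AcmgCategory.VUS,
    "variant of uncertain significance": AcmgCategory.VUS,
    "uncertain significance": AcmgCategory.VUS,
    "likely pathogenic": AcmgCategory.LIKELY_PATHOGENIC,
    "likely_pathogenic": AcmgCategory.LIKELY_PATHOGENIC,
    "pathogenic": AcmgCategory.PATHOGENIC,
}


class LabelParseError(ValueError):
    pass


def parse_category(value: str | AcmgCategory) -> AcmgCategory:
    """Case-insensitive parse with common aliases."""
    if isinstance(value, AcmgCategory):
        return value
    key = str(value).strip().lower()
    try:
        return _ALIASES[key]
    except KeyError:
        raise LabelParseError(
            f"unknown label {value!r}; expected one of "
            f"{[c.value for c in CATEGORY_ORDER]}"
        ) from None


@dataclass(frozen=True)
class LabelPartition:
    """Binary target (or unknown) + hardness for one variant."""

    binary: int | None  # 0 benign, 1 pathogenic, None unknown
    hardness: str  # "hard" | "soft"
    source: AcmgCategory
    hint: int | None = None  # advisory lean for likely-* soft rows


_BINARIZE = {
    AcmgCategory.BENIGN_AUTO: (0, "hard", None),
    AcmgCategory.BENIGN: (0, "hard", None),
    AcmgCategory.PATHOGENIC: (1, "hard", None),
    AcmgCategory.LIKELY_BENIGN: (None, "soft", 0),
    AcmgCategory.LIKELY_PATHOGENIC: (None, "soft", 1),
    AcmgCategory.VUS: (None, "soft", None),
}


def binarize(source: str | AcmgCategory) -> LabelPartition:
    """Map a six-category label to the binary target with hardness.

    Hard categories carry a fixed 0/1 target; likely-* categories carry only
    an advisory hint (their training labels come from pseudo-labeling); VUS is
    fully unknown.
    """
    cat = parse_category(source)
    binary, hardness, hint = _BINARIZE[cat]
    return LabelPartition(binary=binary, hardness=hardness, source=cat, hint=hint)


def binarize_column(labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Vectorised binarize: frame with binary (float, NaN=unknown), hardness,
    source and hint columns, aligned with the input."""
    parts = [binarize(v) for v in np.asarray(labels, dtype=object)]
    return pd.DataFrame(
        {
            "binary": [np.nan if p.binary is None else float(p.binary) for p in parts],
            "hardness": [p.hardness for p in parts],
            "source": [p.source.value for p in parts],
            "hint": [np.nan if p.hint is None else float(p.hint) for p in parts],
        }
    )


def smooth_targets(y: np.ndarray, alpha: float) -> np.ndarray:
    """Two-class label smoothing: y' = y(1-alpha) + alpha/2.

    With K=2 classes, uniform smoothing moves each one-hot target alpha/2
    toward the opposite class, so targets live in [alpha/2, 1 - alpha/2].
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    y = np.asarray(y, dtype=float)
    return y * (1.0 - alpha) + alpha / 2.0


def stratified_split(
    labels: pd.Series | np.ndarray,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> pd.Series:
    """Assign train/validation/test per row, stratified by the six categories.

    Within each category, split counts follow ``ratios`` by largest-remainder
    apportionment (so each count is within one row of exact), with assignment
    order randomised by ``seed``. Categories with fewer than 3 rows fall where
    the remainders put them — in practice into the training split first.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("empty label vector")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    cats = np.array([parse_category(v).value for v in labels], dtype=object)
    rng = np.random.default_rng(seed)
    split = np.empty(labels.size, dtype=object)
    names = ("train", "validation", "test")
    for cat in [c.value for c in CATEGORY_ORDER]:
        idx = np.flatnonzero(cats == cat)
        if idx.size == 0:
            continue
        idx = rng.permutation(idx)
        exact = np.array(ratios) * idx.size
        counts = np.floor(exact).astype(int)
        remainder = idx.size - counts.sum()
        # hand leftover rows to the splits with the largest fractional parts,
        # ties resolved in (train, validation, test) order
        order = np.argsort(-(exact - counts), kind="stable")
        for k in order[:remainder]:
            counts[k] += 1
        bounds = np.cumsum(counts)
        split[idx[: bounds[0]]] = names[0]
        split[idx[bounds[0]: bounds[1]]] = names[1]
        split[idx[bounds[1]:]] = names[2]
    return pd.Series(split, name="split", dtype="string")
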