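"""Semi-supervised training: supervised warm start + pseudo-labeling loop.

Training starts from the hard-labeled rows only (Benign auto / Benign = 0,
Pathogenic = 1, targets label-smoothed). The trained model then scores the
remaining soft rows; rows whose confidence max(p, 1-p) strictly exceeds the
confidence threshold are promoted into their own split's pool with their
predicted label (train-split soft rows enter the training pool, validation-
split rows the validation pool — never across splits and never the test
split). The model is retrained on the expanded pools and the cycle repeats
until no new row clears the threshold or the iteration cap is reached.
Pseudo-labels are frozen once assigned; labeled and pseudo-labeled losses are
weighted equally by default.

The optimizer is Adam with decoupled weight decay, written on NumPy arrays.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ftt_core import FTTConfig, FTTModel, backward, bce_with_logits, forward, init_model
from .labels import smooth_targets
from .preprocess import DesignMatrices, FittedPreprocessor, apply_preprocessor
from .table_io import AnnotatedVariantTable, sigmoid

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization and pseudo-labeling hyperparameters.

    Defaults: Adam(lr 1e-4, decoupled weight decay 1e-5), label smoothing
    0.05, confidence threshold 0.95, at most 10 pseudo-labeling iterations,
    equal weight for labeled and pseudo-labeled losses.
    """

    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    label_smoothing: float = 0.05
    confidence_threshold: float = 0.95
    max_ssl_iterations: int = 10
    pseudo_loss_weight: float = 1.0
    batch_size: int | None = 64  # None = full batch
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    retrain_from_scratch: bool = False
    rescore_pseudo_labels: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.confidence_threshold <= 1.0:
            raise ConfigurationError(
                "confidence_threshold must be in (0.5, 1]: confidence "
                "max(p, 1-p) is always > 0.5"
            )
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ConfigurationError("label_smoothing must be in [0, 1)")
        if self.pseudo_loss_weight < 0:
            raise ConfigurationError("pseudo_loss_weight must be >= 0")
        if self.max_ssl_iterations < 0 or self.max_epochs < 1 or self.patience < 1:
            raise ConfigurationError("iteration/epoch budgets must be positive")


class AdamW:
    """Adam with decoupled weight decay on NumPy parameter dicts."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                            + self.weight_decay * p)


@dataclass
class SplitData:
    """Model-ready matrices plus label bookkeeping for one split."""

    X_num: np.ndarray
    X_cat: np.ndarray
    binary: np.ndarray  # float; NaN = no hard target
    hardness: np.ndarray  # "hard" | "soft"
    source: np.ndarray  # original six-category strings
    row_ids: np.ndarray  # global row indices, for audit trails

    def __post_init__(self) -> None:
        n = self.X_num.shape[0]
        for arr in (self.X_cat, self.binary, self.hardness, self.source, self.row_ids):
            if arr.shape[0] != n:
                raise ContractError("SplitData arrays have inconsistent lengths")

    @property
    def n_rows(self) -> int:
        return self.X_num.shape[0]

    @property
    def hard_mask(self) -> np.ndarray:
        return self.hardness == "hard"


def make_split_data(
    design: DesignMatrices, label_frame, row_ids: np.ndarray
) -> SplitData:
    return SplitData(
        X_num=design.X_num,
        X_cat=design.X_cat,
        binary=label_frame["binary"].to_numpy(dtype=float),
        hardness=label_frame["hardness"].to_numpy(dtype=object),
        source=label_frame["source"].to_numpy(dtype=object),
        row_ids=np.asarray(row_ids),
    )


@dataclass
class _Pool:
    """Mutable training/validation pool: indices into a SplitData + targets."""

    indices: list[int]
    targets: list[float]
    weights: list[float]

    def arrays(self, data: SplitData):
        idx = np.asarray(self.indices, dtype=int)
        return (
            data.X_num[idx],
            data.X_cat[idx],
            np.asarray(self.targets),
            np.asarray(self.weights),
        )


def train_supervised(
    model: FTTModel,
    train: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[FTTModel, dict]:
    """Fit on (X_num, X_cat, y, weight) tuples with early stopping.

    Targets are smoothed here (y' = y(1-alpha) + alpha/2); the loss is
    weighted binary cross-entropy; the returned model carries the parameters
    of the best validation epoch.
    """
    Xn, Xc, y, w = train
    if Xn.shape[0] == 0:
        raise ContractError("empty training set")
    classes = np.unique(np.round(y))
    if classes.size < 2:
        logger.warning("training pool contains a single class: %s", classes)
    Xn_val, Xc_val, y_val, w_val = val
    y_s = smooth_targets(y, config.label_smoothing)
    y_val_s = smooth_targets(y_val, config.label_smoothing)
    rng = rng or np.random.default_rng(config.seed)

    opt = AdamW(model.params, config.learning_rate, config.weight_decay)
    n = Xn.shape[0]
    batch = n if config.batch_size is None else min(config.batch_size, n)
    best_val = np.inf
    best_params = {k: v.copy() for k, v in model.params.items()}
    best_epoch = 0
    since_best = 0
    train_losses: list[float] = []
    val_losses: list[float] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        epoch_loss = 0.0
        for start in range(0, n, batch):
            sel = order[start: start + batch]
            logits, cache = forward(
                model.params, model.config, Xn[sel], Xc[sel], train=True, rng=rng
            )
            loss, dlogits = bce_with_logits(logits, y_s[sel], w[sel])
            grads = backward(model.params, model.config, cache, dlogits)
            opt.step(model.params, grads)
            epoch_loss += loss * sel.size
        train_losses.append(epoch_loss / n)

        if Xn_val.shape[0]:
            val_logits = model.predict_logits(Xn_val, Xc_val)
            val_loss, _ = bce_with_logits(val_logits, y_val_s, w_val)
        else:
            val_loss = train_losses[-1]
        val_losses.append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = {k: v.copy() for k, v in model.params.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.params = best_params
    return model, {
        "train_losses": train_losses,
        "val_losses": val_losses,
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
    }


def select_pseudo_labels(
    probabilities: np.ndarray,
    threshold: float,
    row_ids: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promotions among unpromoted soft rows.

    Confidence is max(p, 1-p); a row is promoted iff confidence strictly
    exceeds the threshold ("exceeding", so p exactly at the threshold stays
    out); its label is 1 iff p > 0.5. Returns (row_ids, labels, confidences)
    of the promoted rows.
    """
    p = np.asarray(probabilities, dtype=float)
    ids = np.arange(p.size) if row_ids is None else np.asarray(row_ids)
    conf = np.maximum(p, 1.0 - p)
    keep = conf > threshold
    labels = (p > 0.5).astype(int)
    return ids[keep], labels[keep], conf[keep]


@dataclass
class IterationRecord:
    iteration: int
    n_candidates: int
    n_promoted: int
    promoted_train_ids: list[int]
    promoted_val_ids: list[int]
    labels: dict[int, int]
    confidences: dict[int, float]
    train_pool_size: int
    val_pool_size: int
    best_val_loss: float


@dataclass
class PseudoLabelHistory:
    """Audit trail of the pseudo-labeling loop."""

    iterations: list[IterationRecord] = field(default_factory=list)
    termination_reason: str = ""

    def promoted_ids(self) -> list[int]:
        out: list[int] = []
        for rec in self.iterations:
            out.extend(rec.promoted_train_ids)
            out.extend(rec.promoted_val_ids)
        return out

    def to_json_lines(self) -> str:
        lines = []
        for rec in self.iterations:
            lines.append(json.dumps({
                "iteration": rec.iteration,
                "n_candidates": rec.n_candidates,
                "n_promoted": rec.n_promoted,
                "promoted_train_ids": rec.promoted_train_ids,
                "promoted_val_ids": rec.promoted_val_ids,
                "labels": {str(k): v for k, v in rec.labels.items()},
                "confidences": {str(k): v for k, v in rec.confidences.items()},
                "train_pool_size": rec.train_pool_size,
                "val_pool_size": rec.val_pool_size,
                "best_val_loss": rec.best_val_loss,
            }))
        lines.append(json.dumps({"termination_reason": self.termination_reason}))
        return "\n".join(lines) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json_lines())


def run_semisupervised(
    train: SplitData,
    val: SplitData,
    model_config: FTTConfig,
    train_config: TrainConfig,
    dtype=np.float32,
) -> tuple[FTTModel, PseudoLabelHistory]:
    """Warm start on hard rows, then iterative pseudo-labeling.

    Promotion is split-respecting: train-split soft rows join the training
    pool, validation-split soft rows the validation pool. Promoted rows keep
    their first assigned label (frozen) unless ``rescore_pseudo_labels`` is
    set, in which case labels and confidences are refreshed each iteration.
    Retraining continues from the previous checkpoint by default.
    """
    seeds = np.random.SeedSequence(train_config.seed).spawn(
        train_config.max_ssl_iterations + 2
    )
    model = init_model(
        model_config, seed=int(seeds[0].generate_state(1)[0]) % 2**31, dtype=dtype
    )

    train_pool = _Pool(
        indices=list(np.flatnonzero(train.hard_mask)),
        targets=[float(t) for t in train.binary[train.hard_mask]],
        weights=[1.0] * int(train.hard_mask.sum()),
    )
    val_pool = _Pool(
        indices=list(np.flatnonzero(val.hard_mask)),
        targets=[float(t) for t in val.binary[val.hard_mask]],
        weights=[1.0] * int(val.hard_mask.sum()),
    )

    def fit(iteration: int) -> dict:
        nonlocal model
        if train_config.retrain_from_scratch and iteration > 0:
            model = init_model(
                model_config,
                seed=int(seeds[0].generate_state(1)[0]) % 2**31,
                dtype=dtype,
            )
        rng = np.random.default_rng(seeds[iteration + 1])
        _, info = train_supervised(
            model, train_pool.arrays(train), val_pool.arrays(val),
            train_config, rng=rng,
        )
        return info

    info = fit(0)  # supervised warm start on hard labels only
    history = PseudoLabelHistory()
    remaining = {
        "train": set(np.flatnonzero(~train.hard_mask)),
        "validation": set(np.flatnonzero(~val.hard_mask)),
    }

    for iteration in range(1, train_config.max_ssl_iterations + 1):
        promoted_total = 0
        rec = IterationRecord(
            iteration=iteration,
            n_candidates=len(remaining["train"]) + len(remaining["validation"]),
            n_promoted=0,
            promoted_train_ids=[],
            promoted_val_ids=[],
            labels={},
            confidences={},
            train_pool_size=len(train_pool.indices),
            val_pool_size=len(val_pool.indices),
            best_val_loss=float(info["best_val_loss"]),
        )
        for split_name, data, pool in (
            ("train", train, train_pool),
            ("validation", val, val_pool),
        ):
            cand = np.array(sorted(remaining[split_name]), dtype=int)
            if cand.size == 0:
                continue
            probs = model.predict_proba(data.X_num[cand], data.X_cat[cand])
            ids, labels, confs = select_pseudo_labels(
                probs, train_config.confidence_threshold, row_ids=cand
            )
            for i, lab, conf in zip(ids, labels, confs):
                pool.indices.append(int(i))
                pool.targets.append(float(lab))
                pool.weights.append(train_config.pseudo_loss_weight)
                remaining[split_name].discard(int(i))
                global_id = int(data.row_ids[i])
                rec.labels[global_id] = int(lab)
                rec.confidences[global_id] = float(conf)
                (rec.promoted_train_ids if split_name == "train"
                 else rec.promoted_val_ids).append(global_id)
            promoted_total += int(ids.size)

        rec.n_promoted = promoted_total
        rec.train_pool_size = len(train_pool.indices)
        rec.val_pool_size = len(val_pool.indices)
        history.iterations.append(rec)
        if promoted_total == 0:
            history.termination_reason = "no_new_promotions"
            break
        if train_config.rescore_pseudo_labels:
            _rescore(model, train, train_pool)
            _rescore(model, val, val_pool)
        info = fit(iteration)
    else:
        history.termination_reason = "max_iterations"
    return model, history


def _rescore(model: FTTModel, data: SplitData, pool: _Pool) -> None:
    """Optional mode: refresh pseudo-labels of already-promoted soft rows."""
    idx = np.asarray(pool.indices, dtype=int)
    soft = ~data.hard_mask[idx]
    if not soft.any():
        return
    probs = model.predict_proba(data.X_num[idx[soft]], data.X_cat[idx[soft]])
    new_labels = (probs > 0.5).astype(float)
    j = 0
    for k, is_soft in enumerate(soft):
        if is_soft:
            pool.targets[k] = float(new_labels[j])
            j += 1


def predict(
    model: FTTModel,
    fitted: FittedPreprocessor,
    table: AnnotatedVariantTable,
    threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eval-mode logits, probabilities and binary calls for every row."""
    design = apply_preprocessor(fitted, table)
    logits = model.predict_logits(design.X_num, design.X_cat)
    probs = sigmoid(logits)
    calls = (probs > threshold).astype(int)
    return logits, probs, calls
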