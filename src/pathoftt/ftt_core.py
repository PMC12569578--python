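"""Feature Tokenizer Transformer (FTT) in pure NumPy.

Each tabular feature becomes one d-dimensional token: numerical feature j is
mapped affinely (b_j + x_j * W_j), categorical feature j looks up an embedding
row (plus a per-feature bias), and a learned [CLS] token is prepended. The
token stack passes through prenorm transformer blocks

    u = u + Drop(Attn(LN(u)))
    u = u + Drop(FFN_geglu(LN(u)))

and a final LayerNorm + linear head reads the [CLS] position into a single
pre-sigmoid logit. The feed-forward nonlinearity is the gated GELU (GEGLU):
the first projection produces a value half and a gate half, and the hidden
activation is value * GELU(gate).

Forward, backward and dropout are implemented by hand on NumPy arrays; the
backward pass is exercised against finite differences in the test suite.
Shapes are (batch, tokens, dim) throughout.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .table_io import sigmoid

__all__ = [
    "FTTConfig",
    "FTTModel",
    "init_model",
    "tokenize",
    "forward",
    "backward",
    "bce_with_logits",
    "parameter_count",
]


class ConfigurationError(ValueError):
    pass


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class FTTConfig:
    """Architecture hyperparameters.

    Defaults: 64-dimensional tokens, three transformer layers with four
    attention heads each and a 456-wide GEGLU feed-forward (per branch), all
    dropout rates 0.1, prenormalization.
    """

    n_numerical: int
    categorical_cardinalities: tuple[int, ...] = ()
    token_dim: int = 64
    n_layers: int = 3
    n_heads: int = 4
    ffn_hidden: int = 456
    dropout_attention: float = 0.1
    dropout_ffn: float = 0.1
    dropout_residual: float = 0.1

    def __post_init__(self) -> None:
        if self.n_numerical < 0 or self.n_numerical + len(
            self.categorical_cardinalities
        ) == 0:
            raise ConfigurationError("need at least one feature")
        if self.token_dim % self.n_heads != 0:
            raise ConfigurationError(
                f"token_dim {self.token_dim} not divisible by n_heads {self.n_heads}"
            )
        for p in (self.dropout_attention, self.dropout_ffn, self.dropout_residual):
            if not 0.0 <= p < 1.0:
                raise ConfigurationError(f"dropout {p} outside [0, 1)")
        if min(self.n_layers, self.ffn_hidden, self.token_dim, self.n_heads) < 1:
            raise ConfigurationError("dimensions must be positive")

    @property
    def n_tokens(self) -> int:
        return 1 + self.n_numerical + len(self.categorical_cardinalities)


def _uniform(rng, shape, fan_in, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def init_model(
    config: FTTConfig, seed: int = 0, dtype: np.dtype = np.float32
) -> "FTTModel":
    """Kaiming-style uniform fan-in initialization, deterministic in seed.

    float32 is the working precision (the arrays are large and the pass is
    memory-bound); float64 is available for gradient checking.
    """
    rng = np.random.default_rng(seed)
    d, f = config.token_dim, config.ffn_hidden
    p: dict[str, np.ndarray] = {}
    if config.n_numerical:
        p["num_weight"] = _uniform(rng, (config.n_numerical, d), d, dtype)
        p["num_bias"] = _uniform(rng, (config.n_numerical, d), d, dtype)
    for j, card in enumerate(config.categorical_cardinalities):
        # +1 embedding row for the reserved unknown code
        p[f"cat{j}_emb"] = _uniform(rng, (card + 1, d), d, dtype)
        p[f"cat{j}_bias"] = _uniform(rng, (d,), d, dtype)
    p["cls"] = _uniform(rng, (d,), d, dtype)
    for layer in range(config.n_layers):
        pre = f"l{layer}_"
        p[pre + "ln1_g"] = np.ones(d, dtype)
        p[pre + "ln1_b"] = np.zeros(d, dtype)
        for name in ("Wq", "Wk", "Wv", "Wo"):
            p[pre + name] = _uniform(rng, (d, d), d, dtype)
        for name in ("bq", "bk", "bv", "bo"):
            p[pre + name] = np.zeros(d, dtype)
        p[pre + "ln2_g"] = np.ones(d, dtype)
        p[pre + "ln2_b"] = np.zeros(d, dtype)
        p[pre + "W1"] = _uniform(rng, (d, 2 * f), d, dtype)
        p[pre + "b1"] = np.zeros(2 * f, dtype)
        p[pre + "W2"] = _uniform(rng, (f, d), f, dtype)
        p[pre + "b2"] = np.zeros(d, dtype)
    p["lnf_g"] = np.ones(d, dtype)
    p["lnf_b"] = np.zeros(d, dtype)
    p["head_w"] = _uniform(rng, (d,), d, dtype)
    p["head_b"] = np.zeros(1, dtype)
    return FTTModel(config=config, params=p, seed=seed)


def parameter_count(config: FTTConfig) -> int:
    """Closed-form number of learnable scalars for a configuration."""
    d, f = config.token_dim, config.ffn_hidden
    n = 2 * config.n_numerical * d  # per-feature weight + bias vectors
    n += sum((card + 1) * d + d for card in config.categorical_cardinalities)
    n += d  # [CLS]
    per_layer = (
        4 * d  # two LayerNorms
        + 4 * (d * d + d)  # q, k, v, o projections
        + d * 2 * f + 2 * f  # GEGLU in-projection (value + gate halves)
        + f * d + d  # FFN out-projection
    )
    n += config.n_layers * per_layer
    n += 2 * d  # final LayerNorm
    n += d + 1  # head
    return n


# ---------------------------------------------------------------------------
# primitive ops (forward + hand-written vjps)
# ---------------------------------------------------------------------------

_LN_EPS = 1e-5


def _layer_norm(x, g, b):
    mu = x.mean(-1, keepdims=True)
    var = x.var(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _LN_EPS)
    xhat = (x - mu) * inv
    return g * xhat + b, (xhat, inv)


def _layer_norm_backward(dy, g, cache):
    xhat, inv = cache
    dxhat = dy * g
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    mean_dxhat = dxhat.mean(-1, keepdims=True)
    mean_dxhat_xhat = (dxhat * xhat).mean(-1, keepdims=True)
    dx = (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv
    return dx, dg, db


# tanh-form GELU (the standard fast approximation; exact to ~1e-3)
_GELU_C = np.sqrt(2.0 / np.pi)
_GELU_A = 0.044715


def _gelu(x):
    t = np.tanh(_GELU_C * (x + _GELU_A * x * x * x))
    return 0.5 * x * (1.0 + t), t


def _gelu_grad(x, t):
    inner_grad = _GELU_C * (1.0 + 3.0 * _GELU_A * x * x)
    return 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * inner_grad


def _dropout_mask(rng, shape, p, dtype):
    if p == 0.0 or rng is None:
        return None
    mask = (rng.random(shape, dtype=np.float32) >= p).astype(dtype)
    mask *= 1.0 / (1.0 - p)
    return mask


def _apply_mask(x, mask):
    return x if mask is None else x * mask


def tokenize(
    params: dict[str, np.ndarray],
    config: FTTConfig,
    X_num: np.ndarray,
    X_cat: np.ndarray,
) -> np.ndarray:
    """Build the (batch, k+1, d) token stack: [CLS], numerical, categorical."""
    dtype = params["cls"].dtype
    X_num = np.atleast_2d(np.asarray(X_num, dtype=dtype))
    X_cat = np.atleast_2d(np.asarray(X_cat, dtype=np.int64))
    B = max(X_num.shape[0], X_cat.shape[0])
    if X_num.shape[1] != config.n_numerical:
        raise ContractError(
            f"expected {config.n_numerical} numerical features, got {X_num.shape[1]}"
        )
    k_cat = len(config.categorical_cardinalities)
    if X_cat.shape[1] != k_cat:
        raise ContractError(
            f"expected {k_cat} categorical features, got {X_cat.shape[1]}"
        )
    d = config.token_dim
    tokens = np.empty((B, config.n_tokens, d), dtype=dtype)
    tokens[:, 0] = params["cls"]
    if config.n_numerical:
        tokens[:, 1: 1 + config.n_numerical] = (
            params["num_bias"][None] + X_num[:, :, None] * params["num_weight"][None]
        )
    for j, card in enumerate(config.categorical_cardinalities):
        codes = X_cat[:, j]
        if codes.min(initial=0) < 0 or codes.max(initial=0) > card:
            raise ContractError(
                f"categorical feature {j}: codes must lie in [0, {card}] "
                "(the top code is the reserved unknown)"
            )
        tokens[:, 1 + config.n_numerical + j] = (
            params[f"cat{j}_emb"][codes] + params[f"cat{j}_bias"]
        )
    return tokens


def forward(
    params: dict[str, np.ndarray],
    config: FTTConfig,
    X_num: np.ndarray,
    X_cat: np.ndarray,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Full forward pass; returns (logits of shape (B,), cache for backward).

    ``train=True`` draws dropout masks from ``rng``; evaluation mode is
    deterministic (all dropout off).
    """
    if train and rng is None and (
        config.dropout_attention or config.dropout_ffn or config.dropout_residual
    ):
        raise ContractError("training mode with dropout needs an rng")
    drop_rng = rng if train else None
    dtype = params["cls"].dtype
    d, H = config.token_dim, config.n_heads
    dh = d // H
    scale = 1.0 / np.sqrt(dh)

    u = tokenize(params, config, X_num, X_cat)
    B, T, _ = u.shape
    cache: dict[str, Any] = {
        "X_num": np.atleast_2d(np.asarray(X_num, dtype=dtype)),
        "X_cat": np.atleast_2d(np.asarray(X_cat, dtype=np.int64)),
        "layers": [],
        "B": B,
        "T": T,
    }

    for layer in range(config.n_layers):
        pre = f"l{layer}_"
        lc: dict[str, Any] = {"u_in": u}
        h, lc["ln1"] = _layer_norm(u, params[pre + "ln1_g"], params[pre + "ln1_b"])
        lc["h1"] = h
        q = (h @ params[pre + "Wq"] + params[pre + "bq"]).reshape(B, T, H, dh)
        k = (h @ params[pre + "Wk"] + params[pre + "bk"]).reshape(B, T, H, dh)
        v = (h @ params[pre + "Wv"] + params[pre + "bv"]).reshape(B, T, H, dh)
        q, k, v = (a.transpose(0, 2, 1, 3) for a in (q, k, v))  # (B,H,T,dh)
        scores = (q @ k.swapaxes(-1, -2)) * scale
        scores -= scores.max(-1, keepdims=True)
        exps = np.exp(scores)
        probs = exps / exps.sum(-1, keepdims=True)
        attn_mask = _dropout_mask(drop_rng, probs.shape, config.dropout_attention, dtype)
        probs_d = _apply_mask(probs, attn_mask)
        ctx = probs_d @ v
        merged = ctx.transpose(0, 2, 1, 3).reshape(B, T, d)
        out = merged @ params[pre + "Wo"] + params[pre + "bo"]
        res_mask1 = _dropout_mask(drop_rng, out.shape, config.dropout_residual, dtype)
        u = u + _apply_mask(out, res_mask1)
        lc.update(
            q=q, k=k, v=v, probs=probs, attn_mask=attn_mask, merged=merged,
            res_mask1=res_mask1,
        )

        lc["u_mid"] = u
        h2, lc["ln2"] = _layer_norm(u, params[pre + "ln2_g"], params[pre + "ln2_b"])
        lc["h2"] = h2
        z1 = h2 @ params[pre + "W1"] + params[pre + "b1"]
        f = config.ffn_hidden
        value, gate = z1[..., :f], z1[..., f:]
        act, gate_t = _gelu(gate)
        hidden = value * act
        ffn_mask = _dropout_mask(drop_rng, hidden.shape, config.dropout_ffn, dtype)
        hidden_d = _apply_mask(hidden, ffn_mask)
        z2 = hidden_d @ params[pre + "W2"] + params[pre + "b2"]
        res_mask2 = _dropout_mask(drop_rng, z2.shape, config.dropout_residual, dtype)
        u = u + _apply_mask(z2, res_mask2)
        lc.update(
            value=value, gate=gate, act=act, gate_t=gate_t, hidden_d=hidden_d,
            ffn_mask=ffn_mask, res_mask2=res_mask2,
        )
        cache["layers"].append(lc)

    cache["u_final"] = u
    cls_final = u[:, 0]
    hf, cache["lnf"] = _layer_norm(cls_final, params["lnf_g"], params["lnf_b"])
    cache["hf"] = hf
    cache["cls_final"] = cls_final
    logits = hf @ params["head_w"] + params["head_b"][0]
    return logits, cache


def backward(
    params: dict[str, np.ndarray],
    config: FTTConfig,
    cache: dict[str, Any],
    dlogits: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vector-Jacobian products for every parameter given dL/dlogit."""
    d, H = config.token_dim, config.n_heads
    dh = d // H
    scale = 1.0 / np.sqrt(dh)
    B, T = cache["B"], cache["T"]
    grads = {k: np.zeros_like(v) for k, v in params.items()}

    dlogits = np.asarray(dlogits, dtype=params["cls"].dtype).reshape(B)
    grads["head_w"] += cache["hf"].T @ dlogits
    grads["head_b"] += np.array([dlogits.sum()])
    dhf = dlogits[:, None] * params["head_w"][None]
    dcls, dg, db = _layer_norm_backward(dhf, params["lnf_g"], cache["lnf"])
    grads["lnf_g"] += dg
    grads["lnf_b"] += db
    du = np.zeros((B, T, d), dtype=params["cls"].dtype)
    du[:, 0] = dcls

    for layer in reversed(range(config.n_layers)):
        pre = f"l{layer}_"
        lc = cache["layers"][layer]
        f = config.ffn_hidden

        # FFN block: u = u_mid + Drop2(Drop_ffn(value*gelu(gate)) @ W2 + b2)
        dz2 = _apply_mask(du, lc["res_mask2"])
        grads[pre + "W2"] += lc["hidden_d"].reshape(-1, f).T @ dz2.reshape(-1, d)
        grads[pre + "b2"] += dz2.sum((0, 1))
        dhidden_d = dz2 @ params[pre + "W2"].T
        dhidden = _apply_mask(dhidden_d, lc["ffn_mask"])
        dvalue = dhidden * lc["act"]
        dgate = dhidden * lc["value"] * _gelu_grad(lc["gate"], lc["gate_t"])
        dz1 = np.concatenate([dvalue, dgate], axis=-1)
        grads[pre + "W1"] += lc["h2"].reshape(-1, d).T @ dz1.reshape(-1, 2 * f)
        grads[pre + "b1"] += dz1.sum((0, 1))
        dh2 = dz1 @ params[pre + "W1"].T
        dumid, dg, db = _layer_norm_backward(dh2, params[pre + "ln2_g"], lc["ln2"])
        grads[pre + "ln2_g"] += dg
        grads[pre + "ln2_b"] += db
        du = du + dumid

        # attention block: u_mid = u_in + Drop1(merge(softmax(qk)v) @ Wo + bo)
        dout = _apply_mask(du, lc["res_mask1"])
        grads[pre + "Wo"] += lc["merged"].reshape(-1, d).T @ dout.reshape(-1, d)
        grads[pre + "bo"] += dout.sum((0, 1))
        dmerged = dout @ params[pre + "Wo"].T
        dctx = dmerged.reshape(B, T, H, dh).transpose(0, 2, 1, 3)
        dprobs_d = dctx @ lc["v"].swapaxes(-1, -2)
        dv = _apply_mask(lc["probs"], lc["attn_mask"]).swapaxes(-1, -2) @ dctx
        dprobs = _apply_mask(dprobs_d, lc["attn_mask"])
        probs = lc["probs"]
        dscores = probs * (dprobs - (dprobs * probs).sum(-1, keepdims=True))
        dq = (dscores @ lc["k"]) * scale
        dk = (dscores.swapaxes(-1, -2) @ lc["q"]) * scale

        h1 = lc["h1"]
        dh1 = np.zeros_like(h1)
        for name, grad4 in (("Wq", dq), ("Wk", dk), ("Wv", dv)):
            flat = grad4.transpose(0, 2, 1, 3).reshape(B, T, d)
            grads[pre + name] += h1.reshape(-1, d).T @ flat.reshape(-1, d)
            grads[pre + "b" + name[1].lower()] += flat.sum((0, 1))
            dh1 += flat @ params[pre + name].T
        duin, dg, db = _layer_norm_backward(dh1, params[pre + "ln1_g"], lc["ln1"])
        grads[pre + "ln1_g"] += dg
        grads[pre + "ln1_b"] += db
        du = du + duin

    # tokenizer
    grads["cls"] += du[:, 0].sum(0)
    if config.n_numerical:
        dnum = du[:, 1: 1 + config.n_numerical]  # (B, k_num, d)
        grads["num_bias"] += dnum.sum(0)
        grads["num_weight"] += np.einsum("bk,bkd->kd", cache["X_num"], dnum)
    for j in range(len(config.categorical_cardinalities)):
        dtok = du[:, 1 + config.n_numerical + j]
        codes = cache["X_cat"][:, j]
        np.add.at(grads[f"cat{j}_emb"], codes, dtok)
        grads[f"cat{j}_bias"] += dtok.sum(0)
    return grads


def bce_with_logits(
    logits: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted-mean binary cross-entropy against (possibly smoothed) targets.

    Returns (loss, dL/dlogits). The normalizer is the sum of weights (batch
    size when unweighted), so a zero-weight row contributes nothing at all —
    neither loss nor gradient nor normalization.
    """
    logits = np.asarray(logits, dtype=float)
    targets = np.asarray(targets, dtype=float)
    per = np.maximum(logits, 0.0) - logits * targets + np.log1p(
        np.exp(-np.abs(logits))
    )
    dl = sigmoid(logits) - targets
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        per = per * weights
        dl = dl * weights
        norm = float(weights.sum())
        if norm <= 0:
            raise ContractError("weights sum to zero; loss undefined")
    else:
        norm = float(logits.shape[0])
    return float(per.sum() / norm), dl / norm


@dataclass
class FTTModel:
    """Config + parameters; forward is deterministic in evaluation mode."""

    config: FTTConfig
    params: dict[str, np.ndarray]
    seed: int = 0

    def copy(self) -> "FTTModel":
        return FTTModel(
            config=self.config,
            params={k: v.copy() for k, v in self.params.items()},
            seed=self.seed,
        )

    def predict_logits(self, X_num, X_cat, batch_size: int = 4096) -> np.ndarray:
        """Eval-mode logits, identical for any batch size."""
        X_num = np.atleast_2d(np.asarray(X_num, dtype=self.params["cls"].dtype))
        X_cat = np.atleast_2d(np.asarray(X_cat, dtype=np.int64))
        n = max(X_num.shape[0], X_cat.shape[0])
        out = np.empty(n)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            out[sl], _ = forward(
                self.params, self.config, X_num[sl], X_cat[sl], train=False
            )
        return out

    def predict_proba(self, X_num, X_cat) -> np.ndarray:
        return sigmoid(self.predict_logits(X_num, X_cat))

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: config JSON + parameter arrays."""
        cfg = asdict(self.config)
        cfg["categorical_cardinalities"] = list(
            cfg["categorical_cardinalities"]
        )
        with open(path, "wb") as fh:  # explicit handle: no .npz suffix games
            np.savez(
                fh,
                __config__=np.frombuffer(
                    json.dumps({"config": cfg, "seed": self.seed}).encode(),
                    dtype=np.uint8,
                ),
                **self.params,
            )

    @classmethod
    def load(cls, path: str | Path) -> "FTTModel":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__config__"].tobytes()).decode())
            params = {k: archive[k] for k in archive.files if k != "__config__"}
        cfg = meta["config"]
        cfg["categorical_cardinalities"] = tuple(cfg["categorical_cardinalities"])
        return cls(config=FTTConfig(**cfg), params=params, seed=meta["seed"])
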