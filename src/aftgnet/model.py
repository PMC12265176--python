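"""Attention-based MLP classifier over tokenized fused feature vectors.

The 2,560-dim fused descriptor is segmented into 8 tokens of 320 entries and
passed through multi-head self-attention (8 heads) with a residual
connection; during training additive zero-mean Gaussian noise (std 0.05) is
injected after attention as a lightweight augmentation. The attended tokens
are flattened and classified by two ReLU dense layers with dropout and a
2-unit softmax head.

The network, its backward pass, the AdamW optimizer (decoupled weight decay)
and the cosine-annealed learning-rate schedule are implemented directly in
numpy; the analytic gradients are validated against finite differences in
the test suite. Training keeps the parameter snapshot with the best
validation accuracy, and every stochastic element (init, shuffling, noise,
dropout) is driven by one seed.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fusion import FUSED_DIM


@dataclass
class AttnMLPConfig:
    n_tokens: int = 8
    token_dim: int = 320
    n_heads: int = 8
    noise_std: float = 0.05
    hidden_dims: tuple[int, int] = (512, 128)
    dropout_rate: float = 0.3
    lr: float = 1e-4
    epochs: int = 500
    weight_decay: float = 1e-2
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.token_dim % self.n_heads:
            raise ValueError("token_dim must be divisible by n_heads")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")

    @property
    def input_dim(self) -> int:
        return self.n_tokens * self.token_dim


def tokenize(fused: np.ndarray, n_tokens: int = 8, token_dim: int = 320) -> np.ndarray:
    """Segment a fused vector (or batch of them) into contiguous tokens.

    Token i holds entries [token_dim * i, token_dim * (i + 1)); flattening the
    result row-major recovers the input exactly.
    """
    fused = np.asarray(fused, dtype=np.float64)
    expected = n_tokens * token_dim
    if fused.shape[-1] != expected:
        raise ValueError(f"expected feature dimension {expected}, got {fused.shape[-1]}")
    return fused.reshape(*fused.shape[:-1], n_tokens, token_dim)


def _init_params(cfg: AttnMLPConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    D = cfg.token_dim
    h1, h2 = cfg.hidden_dims
    flat = cfg.input_dim

    def glorot(n_in, n_out):
        s = math.sqrt(2.0 / (n_in + n_out))
        return rng.normal(0.0, s, size=(n_in, n_out))

    def he(n_in, n_out):
        return rng.normal(0.0, math.sqrt(2.0 / n_in), size=(n_in, n_out))

    return {
        "Wq": glorot(D, D), "bq": np.zeros(D),
        "Wk": glorot(D, D), "bk": np.zeros(D),
        "Wv": glorot(D, D), "bv": np.zeros(D),
        "Wo": glorot(D, D), "bo": np.zeros(D),
        "W1": he(flat, h1), "b1": np.zeros(h1),
        "W2": he(h1, h2), "b2": np.zeros(h2),
        "W3": glorot(h2, 2), "b3": np.zeros(2),
    }


def _split_heads(x: np.ndarray, n_heads: int) -> np.ndarray:
    B, T, D = x.shape
    return x.reshape(B, T, n_heads, D // n_heads).transpose(0, 2, 1, 3)


def _merge_heads(x: np.ndarray) -> np.ndarray:
    B, H, T, dh = x.shape
    return x.transpose(0, 2, 1, 3).reshape(B, T, H * dh)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _forward(
    params: dict[str, np.ndarray],
    tokens: np.ndarray,
    cfg: AttnMLPConfig,
    training: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, dict]:
    """Forward pass on a (B, n_tokens, token_dim) batch; returns class
    probabilities (B, 2) and the cache needed for the backward pass."""
    X = tokens
    B = X.shape[0]
    H = cfg.n_heads
    dh = cfg.token_dim // H
    scale = 1.0 / math.sqrt(dh)

    Qm = X @ params["Wq"] + params["bq"]
    Km = X @ params["Wk"] + params["bk"]
    Vm = X @ params["Wv"] + params["bv"]
    Q, K, V = (_split_heads(m, H) for m in (Qm, Km, Vm))
    S = (Q @ K.transpose(0, 1, 3, 2)) * scale
    A = _softmax(S)
    Oh = A @ V
    Om = _merge_heads(Oh)
    attn_out = Om @ params["Wo"] + params["bo"]
    Y = X + attn_out  # residual

    if training and cfg.noise_std > 0:
        Y = Y + rng.normal(0.0, cfg.noise_std, size=Y.shape)

    F = Y.reshape(B, cfg.input_dim)
    Z1 = F @ params["W1"] + params["b1"]
    H1 = np.maximum(Z1, 0.0)
    if training and cfg.dropout_rate > 0:
        mask1 = (rng.random(H1.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
        H1 = H1 * mask1
    else:
        mask1 = None
    Z2 = H1 @ params["W2"] + params["b2"]
    H2 = np.maximum(Z2, 0.0)
    if training and cfg.dropout_rate > 0:
        mask2 = (rng.random(H2.shape) >= cfg.dropout_rate) / (1.0 - cfg.dropout_rate)
        H2 = H2 * mask2
    else:
        mask2 = None
    logits = H2 @ params["W3"] + params["b3"]
    probs = _softmax(logits)
    cache = dict(X=X, Q=Q, K=K, V=V, A=A, Om=Om, F=F, Z1=Z1, H1=H1, Z2=Z2, H2=H2,
                 mask1=mask1, mask2=mask2, scale=scale, probs=probs)
    return probs, cache


def _backward(
    params: dict[str, np.ndarray], cache: dict, y: np.ndarray, cfg: AttnMLPConfig
) -> dict[str, np.ndarray]:
    """Gradients of the mean cross-entropy loss w.r.t. every parameter."""
    B = cache["X"].shape[0]
    H = cfg.n_heads
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B

    g: dict[str, np.ndarray] = {}
    g["W3"] = cache["H2"].T @ dlogits
    g["b3"] = dlogits.sum(0)
    dH2 = dlogits @ params["W3"].T
    if cache["mask2"] is not None:
        dH2 = dH2 * cache["mask2"]
    dZ2 = dH2 * (cache["Z2"] > 0)
    g["W2"] = cache["H1"].T @ dZ2
    g["b2"] = dZ2.sum(0)
    dH1 = dZ2 @ params["W2"].T
    if cache["mask1"] is not None:
        dH1 = dH1 * cache["mask1"]
    dZ1 = dH1 * (cache["Z1"] > 0)
    g["W1"] = cache["F"].T @ dZ1
    g["b1"] = dZ1.sum(0)
    dF = dZ1 @ params["W1"].T
    dY = dF.reshape(cache["X"].shape)

    # residual: dY flows to both X and the attention branch
    dattn = dY
    Om2 = cache["Om"].reshape(-1, cfg.token_dim)
    dattn2 = dattn.reshape(-1, cfg.token_dim)
    g["Wo"] = Om2.T @ dattn2
    g["bo"] = dattn2.sum(0)
    dOm = dattn @ params["Wo"].T
    dOh = _split_heads(dOm, H)

    A, V, Q, K = cache["A"], cache["V"], cache["Q"], cache["K"]
    dA = dOh @ V.transpose(0, 1, 3, 2)
    dV = A.transpose(0, 1, 3, 2) @ dOh
    dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
    dQ = (dS @ K) * cache["scale"]
    dK = (dS.transpose(0, 1, 3, 2) @ Q) * cache["scale"]
    dQm, dKm, dVm = (_merge_heads(d) for d in (dQ, dK, dV))

    X2 = cache["X"].reshape(-1, cfg.token_dim)
    for name, dm in (("Wq", dQm), ("Wk", dKm), ("Wv", dVm)):
        dm2 = dm.reshape(-1, cfg.token_dim)
        g[name] = X2.T @ dm2
        g["b" + name[1]] = dm2.sum(0)
    return g


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-np.log(p).mean())


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr toward 0 over the training run."""
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / max(total_epochs, 1)))


class AttnMLP:
    """Trained attention-MLP; inference is deterministic (no noise/dropout)."""

    def __init__(self, cfg: AttnMLPConfig, params: dict[str, np.ndarray]):
        self.cfg = cfg
        self.params = params

    @classmethod
    def initialize(cls, cfg: AttnMLPConfig, rng: Optional[np.random.Generator] = None) -> "AttnMLP":
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        return cls(cfg, _init_params(cfg, rng))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        tokens = tokenize(X, self.cfg.n_tokens, self.cfg.token_dim)
        if tokens.ndim == 2:
            tokens = tokens[None]
        probs, _ = _forward(self.params, tokens, self.cfg, training=False)
        return probs

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= threshold).astype(np.int64)

    def save(self, path: str) -> None:
        meta = {f"param_{k}": v for k, v in self.params.items()}
        meta["cfg"] = np.array(
            [self.cfg.n_tokens, self.cfg.token_dim, self.cfg.n_heads, self.cfg.seed], dtype=np.int64
        )
        meta["cfg_float"] = np.array(
            [self.cfg.noise_std, self.cfg.dropout_rate, self.cfg.lr, self.cfg.weight_decay]
        )
        meta["hidden"] = np.array(self.cfg.hidden_dims, dtype=np.int64)
        np.savez(path, **meta)

    @classmethod
    def load(cls, path: str) -> "AttnMLP":
        data = np.load(path)
        ci, cf = data["cfg"], data["cfg_float"]
        cfg = AttnMLPConfig(
            n_tokens=int(ci[0]), token_dim=int(ci[1]), n_heads=int(ci[2]), seed=int(ci[3]),
            noise_std=float(cf[0]), dropout_rate=float(cf[1]), lr=float(cf[2]),
            weight_decay=float(cf[3]), hidden_dims=tuple(int(h) for h in data["hidden"]),
        )
        params = {k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")}
        return cls(cfg, params)


@dataclass
class TrainHistory:
    epoch: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_acc: float = -1.0


def train(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: AttnMLPConfig,
) -> tuple[AttnMLP, TrainHistory]:
    """Train with cross-entropy + AdamW + cosine annealing, retaining the
    parameter snapshot with the best validation accuracy.

    Weight decay is decoupled and applied to weight matrices only. Raises if
    the training split contains a single class.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or np.any(counts < 2):
        raise ValueError("training split needs at least 2 samples of each class")

    rng = np.random.default_rng(cfg.seed)
    params = _init_params(cfg, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v_ = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    tokens_all = tokenize(X, cfg.n_tokens, cfg.token_dim)
    tokens_val = tokenize(X_val, cfg.n_tokens, cfg.token_dim)
    y_val = np.asarray(y_val, dtype=np.int64)
    n = len(y)

    hist = TrainHistory()
    best_params = copy.deepcopy(params)

    for epoch in range(cfg.epochs):
        lr_t = cosine_lr(cfg.lr, epoch, cfg.epochs)
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = tokens_all[idx], y[idx]
            probs, cache = _forward(params, xb, cfg, training=True, rng=rng)
            losses.append(cross_entropy(probs, yb) * len(idx))
            correct += int((probs.argmax(1) == yb).sum())
            grads = _backward(params, cache, yb, cfg)
            step += 1
            for k in params:
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v_[k] = beta2 * v_[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v_[k] / (1 - beta2 ** step)
                params[k] -= lr_t * mhat / (np.sqrt(vhat) + eps)
                if k.startswith("W"):
                    params[k] -= lr_t * cfg.weight_decay * params[k]

        val_probs, _ = _forward(params, tokens_val, cfg, training=False)
        val_acc = float((val_probs.argmax(1) == y_val).mean())
        hist.epoch.append(epoch)
        hist.train_loss.append(sum(losses) / n)
        hist.train_acc.append(correct / n)
        hist.val_acc.append(val_acc)
        hist.lr.append(lr_t)
        if val_acc > hist.best_val_acc:
            hist.best_val_acc = val_acc
            hist.best_epoch = epoch
            best_params = copy.deepcopy(params)

    return AttnMLP(cfg, best_params), hist
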