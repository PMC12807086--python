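"""A small transformer encoder-classifier over event windows, in pure NumPy.

The network follows the standard encoder recipe: ``n_layers`` blocks, each a
multi-head self-attention sub-layer followed by a position-wise feed-forward
sub-layer, every sub-layer wrapped in a residual connection with layer
normalization (pre-norm ordering, which trains stably at these tiny widths).
The encoder output at the centre row of the window is passed through
FC(d_model -> d_model), ReLU, FC(d_model -> 2) and a softmax, yielding
(p_unmethylated, p_methylated) for the centre event.  An event is called
methylated iff p_methylated > 0.5; a probability of exactly 0.5 is called
unmethylated.

Forward, backward and the Adam optimizer are implemented explicitly; the
backward pass is validated against finite differences in the test suite.
All arithmetic is float64, and initialization, minibatch shuffling and
dropout are driven by seeded generators, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from .features import N_EVENT_FEATURES
from .positional import ConfigError, PEConfig, positional_encoding

LN_EPS = 1e-5


@dataclass
class ModelConfig:
    """Architecture hyper-parameters.

    ``d_model`` must be even and a multiple of ``n_heads``; with concatenated
    position embeddings ``d_model = n_pe + 7``.  ``d_ff`` defaults to
    ``4 * d_model``.  ``window`` is the (odd) number of events per input.
    """

    d_model: int = 16
    n_heads: int = 2
    n_layers: int = 2
    d_ff: Optional[int] = None
    window: int = 21
    pe: Optional[PEConfig] = None
    dropout: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_ff is None:
            self.d_ff = 4 * self.d_model
        if self.pe is None:
            self.pe = PEConfig(mode="concat", n_pe=self.d_model - N_EVENT_FEATURES,
                               d_model=self.d_model)
        if self.d_model % 2 != 0:
            raise ConfigError(f"d_model must be an even integer, got {self.d_model}")
        if self.d_model % self.n_heads != 0:
            raise ConfigError(
                f"d_model ({self.d_model}) must be a multiple of the number of "
                f"attention heads ({self.n_heads})"
            )
        if self.window % 2 == 0 or self.window < 1:
            raise ConfigError(f"window must be a positive odd integer, got {self.window}")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.pe.d_model != self.d_model:
            raise ConfigError(
                f"pe.d_model ({self.pe.d_model}) disagrees with d_model ({self.d_model})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        pe = d.pop("pe", None)
        cfg = cls(**d, pe=PEConfig(**pe) if isinstance(pe, dict) else pe)
        return cfg


def call_methylation(prob: float) -> int:
    """Hard call from a methylation probability: 1 iff prob > 0.5."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} outside [0, 1]")
    return int(prob > 0.5)


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _flat_matmul_grad(x: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """dW for y = x @ W with arbitrary leading batch axes."""
    xf = x.reshape(-1, x.shape[-1])
    dyf = dy.reshape(-1, dy.shape[-1])
    return xf.T @ dyf


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


class TransformerNet:
    """Parameter container plus explicit forward/backward passes."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        d, dff = cfg.d_model, cfg.d_ff
        rng = np.random.default_rng(cfg.seed)
        p: Dict[str, np.ndarray] = {}
        if cfg.pe.mode == "sum":
            p["input.W"] = _xavier(rng, N_EVENT_FEATURES, d)
            p["input.b"] = np.zeros(d)
        for l in range(cfg.n_layers):
            pre = f"enc{l}."
            p[pre + "ln1.g"] = np.ones(d)
            p[pre + "ln1.b"] = np.zeros(d)
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + "attn." + name] = _xavier(rng, d, d)
            # no key bias: softmax scores are invariant to a constant shift,
            # so a key bias would be a zero-gradient null direction
            for name in ("bq", "bv", "bo"):
                p[pre + "attn." + name] = np.zeros(d)
            p[pre + "ln2.g"] = np.ones(d)
            p[pre + "ln2.b"] = np.zeros(d)
            p[pre + "ffn.W1"] = _xavier(rng, d, dff)
            p[pre + "ffn.b1"] = np.zeros(dff)
            p[pre + "ffn.W2"] = _xavier(rng, dff, d)
            p[pre + "ffn.b2"] = np.zeros(d)
        p["final_ln.g"] = np.ones(d)
        p["final_ln.b"] = np.zeros(d)
        p["head.W1"] = _xavier(rng, d, d)
        p["head.b1"] = np.zeros(d)
        p["head.W2"] = _xavier(rng, d, 2)
        p["head.b2"] = np.zeros(2)
        self.params = p
        # fixed input standardization (per feature column, set from training
        # data by the estimator; identity until then).  Not trainable.
        self.input_loc = np.zeros(N_EVENT_FEATURES)
        self.input_scale = np.ones(N_EVENT_FEATURES)
        self.pe_matrix = positional_encoding(cfg.window, cfg.pe.pe_width, cfg.pe.w0)

    def set_input_stats(self, loc: np.ndarray, scale: np.ndarray) -> None:
        """Set the fixed per-feature standardization applied before the encoder."""
        loc = np.asarray(loc, dtype=float)
        scale = np.asarray(scale, dtype=float)
        if loc.shape != (N_EVENT_FEATURES,) or scale.shape != (N_EVENT_FEATURES,):
            raise ValueError("input stats must have shape (7,)")
        if np.any(scale <= 0):
            raise ValueError("input scales must be positive")
        self.input_loc = loc
        self.input_scale = scale

    # ---------------------------------------------------------------- embed

    def _embed(self, X: np.ndarray, zero_pe: bool) -> np.ndarray:
        """(B, w, 7) raw feature windows -> (B, w, d_model) encoder input."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != N_EVENT_FEATURES:
            raise ValueError(f"expected (B, w, 7) windows, got {X.shape}")
        if X.shape[1] != self.cfg.window:
            raise ValueError(
                f"window length {X.shape[1]} does not match model window "
                f"{self.cfg.window}"
            )
        X = (X - self.input_loc) / self.input_scale
        pe = np.zeros_like(self.pe_matrix) if zero_pe else self.pe_matrix
        if self.cfg.pe.mode == "concat":
            B = X.shape[0]
            return np.concatenate(
                [X, np.broadcast_to(pe, (B,) + pe.shape)], axis=2
            )
        return X @ self.params["input.W"] + self.params["input.b"] + pe

    # ------------------------------------------------------------- sublayers

    @staticmethod
    def _ln_forward(x, g, b):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + LN_EPS)
        xhat = xc * inv
        return g * xhat + b, (xhat, inv)

    @staticmethod
    def _ln_backward(dy, cache, g):
        xhat, inv = cache
        axes = tuple(range(dy.ndim - 1))
        dg = (dy * xhat).sum(axis=axes)
        db = dy.sum(axis=axes)
        dxhat = dy * g
        dx = inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )
        return dx, dg, db

    def _attn_forward(self, x, l, train, rng):
        p = self.params
        pre = f"enc{l}.attn."
        cfg = self.cfg
        B, w, d = x.shape
        h, dh = cfg.n_heads, d // cfg.n_heads
        q = x @ p[pre + "Wq"] + p[pre + "bq"]
        k = x @ p[pre + "Wk"]
        v = x @ p[pre + "Wv"] + p[pre + "bv"]
        qh = q.reshape(B, w, h, dh).transpose(0, 2, 1, 3)
        kh = k.reshape(B, w, h, dh).transpose(0, 2, 1, 3)
        vh = v.reshape(B, w, h, dh).transpose(0, 2, 1, 3)
        scores = qh @ kh.transpose(0, 1, 3, 2) / np.sqrt(dh)
        A = _softmax(scores, axis=-1)
        if train and cfg.dropout > 0.0:
            keep = rng.random(A.shape) >= cfg.dropout
            Ad = A * keep / (1.0 - cfg.dropout)
        else:
            keep = None
            Ad = A
        ctx = (Ad @ vh).transpose(0, 2, 1, 3).reshape(B, w, d)
        out = ctx @ p[pre + "Wo"] + p[pre + "bo"]
        cache = (x, qh, kh, vh, A, keep, ctx)
        return out, cache

    def _attn_backward(self, dout, cache, l, grads):
        p = self.params
        pre = f"enc{l}.attn."
        cfg = self.cfg
        x, qh, kh, vh, A, keep, ctx = cache
        B, w, d = x.shape
        h, dh = cfg.n_heads, d // cfg.n_heads
        grads[pre + "Wo"] = _flat_matmul_grad(ctx, dout)
        grads[pre + "bo"] = dout.sum(axis=(0, 1))
        dctx = (dout @ p[pre + "Wo"].T).reshape(B, w, h, dh).transpose(0, 2, 1, 3)
        dAd = dctx @ vh.transpose(0, 1, 3, 2)
        dvh = A.transpose(0, 1, 3, 2) @ dctx if keep is None else (
            (A * keep / (1.0 - cfg.dropout)).transpose(0, 1, 3, 2) @ dctx
        )
        if keep is not None:
            dA = dAd * keep / (1.0 - cfg.dropout)
        else:
            dA = dAd
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        dS = dS / np.sqrt(dh)
        dqh = dS @ kh
        dkh = dS.transpose(0, 1, 3, 2) @ qh
        dq = dqh.transpose(0, 2, 1, 3).reshape(B, w, d)
        dk = dkh.transpose(0, 2, 1, 3).reshape(B, w, d)
        dv = dvh.transpose(0, 2, 1, 3).reshape(B, w, d)
        grads[pre + "Wq"] = _flat_matmul_grad(x, dq)
        grads[pre + "bq"] = dq.sum(axis=(0, 1))
        grads[pre + "Wk"] = _flat_matmul_grad(x, dk)
        grads[pre + "Wv"] = _flat_matmul_grad(x, dv)
        grads[pre + "bv"] = dv.sum(axis=(0, 1))
        dx = dq @ p[pre + "Wq"].T + dk @ p[pre + "Wk"].T + dv @ p[pre + "Wv"].T
        return dx

    def _ffn_forward(self, x, l):
        p = self.params
        pre = f"enc{l}.ffn."
        z1 = x @ p[pre + "W1"] + p[pre + "b1"]
        a1 = np.maximum(z1, 0.0)
        out = a1 @ p[pre + "W2"] + p[pre + "b2"]
        return out, (x, z1, a1)

    def _ffn_backward(self, dout, cache, l, grads):
        p = self.params
        pre = f"enc{l}.ffn."
        x, z1, a1 = cache
        grads[pre + "W2"] = _flat_matmul_grad(a1, dout)
        grads[pre + "b2"] = dout.sum(axis=(0, 1))
        da1 = dout @ p[pre + "W2"].T
        dz1 = da1 * (z1 > 0.0)
        grads[pre + "W1"] = _flat_matmul_grad(x, dz1)
        grads[pre + "b1"] = dz1.sum(axis=(0, 1))
        return dz1 @ p[pre + "W1"].T

    @staticmethod
    def _dropout(x, p_drop, train, rng):
        if not train or p_drop <= 0.0:
            return x, None
        keep = rng.random(x.shape) >= p_drop
        return x * keep / (1.0 - p_drop), keep

    # ---------------------------------------------------------------- passes

    def _forward(self, X, train=False, rng=None, zero_pe=False):
        cfg = self.cfg
        p = self.params
        cache: Dict[str, object] = {}
        x = self._embed(X, zero_pe)
        cache["x0"] = x
        cache["Xstd"] = (np.asarray(X, dtype=float) - self.input_loc) / self.input_scale
        for l in range(cfg.n_layers):
            h1, ln1_cache = self._ln_forward(x, p[f"enc{l}.ln1.g"], p[f"enc{l}.ln1.b"])
            attn, attn_cache = self._attn_forward(h1, l, train, rng)
            attn, m1 = self._dropout(attn, cfg.dropout, train, rng)
            x1 = x + attn
            h2, ln2_cache = self._ln_forward(x1, p[f"enc{l}.ln2.g"], p[f"enc{l}.ln2.b"])
            ffn, ffn_cache = self._ffn_forward(h2, l)
            ffn, m2 = self._dropout(ffn, cfg.dropout, train, rng)
            x = x1 + ffn
            cache[f"layer{l}"] = (ln1_cache, attn_cache, m1, x1, ln2_cache, ffn_cache, m2)
        xf, lnf_cache = self._ln_forward(x, p["final_ln.g"], p["final_ln.b"])
        cache["lnf"] = lnf_cache
        center = cfg.window // 2
        c = xf[:, center, :]
        cache["c"] = c
        z1 = c @ p["head.W1"] + p["head.b1"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ p["head.W2"] + p["head.b2"]
        cache["head"] = (z1, a1)
        cache["shape"] = xf.shape
        return logits, cache

    def forward(self, X, zero_pe: bool = False) -> np.ndarray:
        """Deterministic evaluation-mode probabilities, shape (B, 2).

        Column 0 is p_unmethylated, column 1 p_methylated; each row sums
        to 1.  ``zero_pe`` replaces the position-embedding block with zeros
        (diagnostic probe: attention without PE is order-agnostic).
        """
        logits, _ = self._forward(X, train=False, zero_pe=zero_pe)
        return _softmax(logits, axis=-1)

    def predict_proba(self, X, batch_size: int = 2048, zero_pe: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        outs = [
            self.forward(X[i : i + batch_size], zero_pe=zero_pe)
            for i in range(0, X.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0) if outs else np.empty((0, 2))

    def loss_and_grads(self, X, y, rng=None, train: bool = True):
        """Mean cross-entropy and gradients for a labeled minibatch."""
        y = np.asarray(y, dtype=int)
        logits, cache = self._forward(X, train=train, rng=rng)
        B = logits.shape[0]
        logp = _log_softmax(logits)
        loss = -logp[np.arange(B), y].mean()
        probs = np.exp(logp)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = self._backward(dlogits, cache)
        return loss, grads

    def _backward(self, dlogits, cache):
        cfg = self.cfg
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        z1, a1 = cache["head"]
        c = cache["c"]
        grads["head.W2"] = a1.T @ dlogits
        grads["head.b2"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["head.W2"].T
        dz1 = da1 * (z1 > 0.0)
        grads["head.W1"] = c.T @ dz1
        grads["head.b1"] = dz1.sum(axis=0)
        dc = dz1 @ p["head.W1"].T
        dxf = np.zeros(cache["shape"])
        dxf[:, cfg.window // 2, :] = dc
        dx, dg, db = self._ln_backward(dxf, cache["lnf"], p["final_ln.g"])
        grads["final_ln.g"] = dg
        grads["final_ln.b"] = db
        for l in reversed(range(cfg.n_layers)):
            ln1_cache, attn_cache, m1, x1, ln2_cache, ffn_cache, m2 = cache[f"layer{l}"]
            dffn = dx if m2 is None else dx * m2 / (1.0 - cfg.dropout)
            dh2 = self._ffn_backward(dffn, ffn_cache, l, grads)
            dx1, dg, db = self._ln_backward(dh2, ln2_cache, p[f"enc{l}.ln2.g"])
            grads[f"enc{l}.ln2.g"] = dg
            grads[f"enc{l}.ln2.b"] = db
            dx1 = dx1 + dx  # residual
            dattn = dx1 if m1 is None else dx1 * m1 / (1.0 - cfg.dropout)
            dh1 = self._attn_backward(dattn, attn_cache, l, grads)
            dx0, dg, db = self._ln_backward(dh1, ln1_cache, p[f"enc{l}.ln1.g"])
            grads[f"enc{l}.ln1.g"] = dg
            grads[f"enc{l}.ln1.b"] = db
            dx = dx0 + dx1  # residual
        if cfg.pe.mode == "sum":
            grads["input.W"] = _flat_matmul_grad(cache["Xstd"], dx)
            grads["input.b"] = dx.sum(axis=(0, 1))
        return grads

    # ------------------------------------------------------------- utilities

    @property
    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def copy_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_(self, params: Dict[str, np.ndarray]) -> None:
        if set(params) != set(self.params):
            raise ValueError("parameter names do not match the architecture")
        for k, v in params.items():
            if v.shape != self.params[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            self.params[k] = np.array(v, dtype=float)


def expected_n_parameters(cfg: ModelConfig) -> int:
    """Closed-form parameter count used as an independent cross-check."""
    d, dff = cfg.d_model, cfg.d_ff
    per_layer = (4 * d * d + 3 * d) + 2 * (2 * d) + (d * dff + dff) + (dff * d + d)
    total = cfg.n_layers * per_layer + 2 * d + (d * d + d) + (d * 2 + 2)
    if cfg.pe.mode == "sum":
        total += N_EVENT_FEATURES * d + d
    return total


class Adam:
    """Adam optimizer over a named-parameter dictionary."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1.0 - b1) * g
            self.v[k] = b2 * self.v[k] + (1.0 - b2) * (g * g)
            mhat = self.m[k] / bias1
            vhat = self.v[k] / bias2
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ------------------------------------------------------------------ checkpoint

def save_checkpoint(path: str | os.PathLike, net: TransformerNet,
                    metadata: Optional[dict] = None) -> None:
    """Serialize config + parameters + training metadata to one .npz archive."""
    payload = {
        "config_json": np.frombuffer(
            json.dumps(net.cfg.to_dict(), sort_keys=True).encode(), dtype=np.uint8
        ),
        "metadata_json": np.frombuffer(
            json.dumps(metadata or {}, sort_keys=True).encode(), dtype=np.uint8
        ),
    }
    payload["input_loc"] = net.input_loc
    payload["input_scale"] = net.input_scale
    for k, v in net.params.items():
        payload["param/" + k] = v
    with open(path, "wb") as fh:
        np.savez(fh, **payload)


def load_checkpoint(path: str | os.PathLike) -> Tuple[TransformerNet, dict]:
    """Rebuild a network bit-exactly from a checkpoint archive."""
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["config_json"]).decode()))
        metadata = json.loads(bytes(data["metadata_json"]).decode())
        net = TransformerNet(cfg)
        net.set_params_(
            {k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")}
        )
        if "input_loc" in data.files:
            net.set_input_stats(data["input_loc"], data["input_scale"])
    return net, metadata
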