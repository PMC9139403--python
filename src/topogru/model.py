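"""The compact CNN-GRU classifier.

Architecture (six layers): one convolution layer (3×3×3 kernels, 32
filters, valid padding) with Leaky-ReLU activation, one 3×3 max-pooling
layer (stride 3), a single-layer GRU over the per-frame feature vectors,
dropout, a dense layer, and a 2-class softmax.  For a 28×28×3 input the
convolution yields 26×26×32, pooling 8×8×32, and each frame flattens to a
2048-vector fed to the GRU.

The GRU cell follows

    r_t = σ(W_r x_t + U_r h_{t-1} + b_r)
    z_t = σ(W_z x_t + U_z h_{t-1} + b_z)
    h̃_t = tanh(W x_t + U (r_t ⊙ h_{t-1}) + b)
    h_t = (1 − z_t) ⊙ h_{t-1} + z_t ⊙ h̃_t

with the update gate gating the *candidate* (the source formulation this
package reproduces; note it swaps z relative to the more common
convention — the cell is equivalent up to relabelling z ↔ 1−z).

Everything — forward, backward, Adam — is plain numpy: the network is
small enough that a framework would add more surface than speed, and the
nested-loop oracles in the test suite can check the vectorised arithmetic
to machine precision.  Training minimises binary cross-entropy and is
deterministic given the seed (single-threaded numpy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

logger = logging.getLogger("topogru")


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass
class CnnConfig:
    """Convolutional front-end parameters."""

    input_shape: tuple[int, int, int] = (28, 28, 3)
    kernel_size: int = 3
    conv_filters: tuple[int, ...] = (32,)   # one entry per conv layer
    leaky_alpha: float = 0.01
    pool_size: int = 3
    pool_stride: int = 3
    padding: str = "valid"

    def __post_init__(self) -> None:
        if any(f < 1 for f in self.conv_filters):
            raise ValueError("filter counts must be ≥ 1")
        if self.padding != "valid":
            raise ValueError("only valid padding is supported")

    @property
    def n_layers(self) -> int:
        return len(self.conv_filters)

    def feature_dim(self) -> int:
        """Flattened per-frame feature size after conv stack + pooling."""
        h, w, _ = self.input_shape
        k = self.kernel_size
        for _f in self.conv_filters:
            h, w = h - k + 1, w - k + 1
        ph = (h - self.pool_size) // self.pool_stride + 1
        pw = (w - self.pool_size) // self.pool_stride + 1
        return ph * pw * self.conv_filters[-1]


@dataclass
class ModelConfig:
    """Full network: front-end + recurrence + head."""

    cnn: CnnConfig = field(default_factory=CnnConfig)
    frontend: str = "cnn"         # "cnn" | "flat" (frames are vectors already)
    flat_dim: int = 0             # per-frame input dim when frontend="flat"
    use_gru: bool = True          # False → mean over frames, dense head only
    hidden_size: int = 64
    dropout_rate: float = 0.5
    n_classes: int = 2

    def input_dim(self) -> int:
        return self.cnn.feature_dim() if self.frontend == "cnn" else self.flat_dim


@dataclass
class TrainConfig:
    """Optimisation settings (the source protocol leaves these open)."""

    optimizer: str = "adam"       # "adam" | "sgd"
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0
    patience: int = 10            # early stopping on validation loss
    val_fraction: float = 0.15
    min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size, epochs must be positive")


@dataclass
class GruWeights:
    """Weight matrices and biases of the GRU cell (input×hidden layout)."""

    W_r: np.ndarray
    W_z: np.ndarray
    W: np.ndarray
    U_r: np.ndarray
    U_z: np.ndarray
    U: np.ndarray
    b_r: np.ndarray
    b_z: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        d, h = self.W.shape
        for m, shape in [(self.W_r, (d, h)), (self.W_z, (d, h)),
                         (self.U_r, (h, h)), (self.U_z, (h, h)),
                         (self.U, (h, h)), (self.b_r, (h,)),
                         (self.b_z, (h,)), (self.b, (h,))]:
            if m.shape != shape:
                raise ValueError(f"inconsistent GRU weight shapes: "
                                 f"{m.shape} vs expected {shape}")
        for m in (self.W_r, self.W_z, self.W, self.U_r, self.U_z, self.U,
                  self.b_r, self.b_z, self.b):
            if not np.isfinite(m).all():
                raise ValueError("non-finite GRU weights")

    @property
    def hidden_size(self) -> int:
        return self.W.shape[1]


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------

def conv2d_forward(x: np.ndarray, kernels: np.ndarray,
                   bias: np.ndarray | float = 0.0,
                   padding: str = "valid") -> np.ndarray:
    """2-D cross-correlation of an H×W×C input with F kernels k×k×C.

    ``kernels`` has shape (F, kh, kw, C); output is H'×W'×F with
    H' = H−kh+1 (valid padding).  This is the sliding-kernel "convolution"
    of CNN practice (no kernel flip).
    """
    if padding != "valid":
        raise ValueError("only valid padding is supported")
    x = np.asarray(x, dtype=np.float64)
    kernels = np.asarray(kernels, dtype=np.float64)
    if x.ndim == 2:
        x = x[:, :, None]
    if kernels.ndim == 3:
        kernels = kernels[None]
    f, kh, kw, c = kernels.shape
    if c != x.shape[2]:
        raise ValueError(f"kernel depth {c} != input channels {x.shape[2]}")
    if kh > x.shape[0] or kw > x.shape[1]:
        raise ValueError("kernel larger than input")
    out = _conv_batch(x[None], kernels, np.broadcast_to(
        np.asarray(bias, dtype=np.float64), (f,)))[0]
    return out


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(M, H, W, C) → (M, H'·W', kh·kw·C) patch matrix."""
    w = sliding_window_view(x, (kh, kw), axis=(1, 2))  # (M,H',W',C,kh,kw)
    m, hh, ww, c = w.shape[:4]
    return np.ascontiguousarray(w.transpose(0, 1, 2, 4, 5, 3)).reshape(
        m, hh * ww, kh * kw * c), (hh, ww)


def _conv_batch(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray):
    f, kh, kw, c = kernels.shape
    cols, (hh, ww) = _im2col(x, kh, kw)
    out = cols @ kernels.reshape(f, kh * kw * c).T + bias
    return out.reshape(x.shape[0], hh, ww, f)


def leaky_relu(x: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """y = x for x ≥ 0, α·x otherwise (elementwise)."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x >= 0, x, alpha * x)


def max_pool(x: np.ndarray, k: int = 3, stride: int | None = None) -> np.ndarray:
    """Window-maximum pooling over the two leading spatial axes of H×W(×F).

    Incomplete trailing windows are dropped: output side floor((H−k)/s)+1.
    """
    stride = k if stride is None else stride
    x = np.asarray(x, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    h, w, f = x.shape
    if k > h or k > w:
        raise ValueError("pooling window larger than input")
    nh = (h - k) // stride + 1
    nw = (w - k) // stride + 1
    out = np.empty((nh, nw, f))
    for i in range(nh):
        for j in range(nw):
            out[i, j] = x[i * stride:i * stride + k,
                          j * stride:j * stride + k].max(axis=(0, 1))
    return out[:, :, 0] if squeeze else out


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def gru_cell_step(x_t: np.ndarray, h_prev: np.ndarray,
                  weights: GruWeights) -> np.ndarray:
    """One step of the GRU cell (module docstring equations)."""
    single = np.asarray(x_t).ndim == 1
    x_t = np.atleast_2d(np.asarray(x_t, dtype=np.float64))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=np.float64))
    if x_t.shape[1] != weights.W.shape[0] or h_prev.shape[1] != weights.hidden_size:
        raise ValueError("input/hidden dimensions do not match the weights")
    r = sigmoid(x_t @ weights.W_r + h_prev @ weights.U_r + weights.b_r)
    z = sigmoid(x_t @ weights.W_z + h_prev @ weights.U_z + weights.b_z)
    h_cand = np.tanh(x_t @ weights.W + (r * h_prev) @ weights.U + weights.b)
    h_t = (1.0 - z) * h_prev + z * h_cand
    return h_t[0] if single else h_t


def gru_forward(xs, weights: GruWeights, h_0: np.ndarray | None = None) -> np.ndarray:
    """Left fold of :func:`gru_cell_step` over a sequence; returns h_n."""
    xs = np.asarray(xs, dtype=np.float64)
    single = xs.ndim == 2          # (T, D) vs (B, T, D)
    if single:
        xs = xs[None]
    b, t, _d = xs.shape
    h = (np.zeros((b, weights.hidden_size)) if h_0 is None
         else np.broadcast_to(h_0, (b, weights.hidden_size)).copy())
    for step in range(t):
        h = gru_cell_step(xs[:, step], h, weights)
    return h[0] if single else h


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) if len(shape) > 1 else shape[0]
    fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class CnnGruModel:
    """All learnable tensors of the network, with fit/predict methods.

    Parameters live in ``self.params`` (a name → ndarray dict) so the
    optimiser, serialisation and parameter counting can treat them
    uniformly.
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0,
                 train_config: TrainConfig | None = None):
        self.config = config or ModelConfig()
        self.train_config = train_config or TrainConfig(seed=seed)
        self.seed = seed
        self.norm_stats: dict = {}
        self.history: dict = {}
        self._init_params(np.random.default_rng(seed))

    # -- construction ------------------------------------------------------

    def _init_params(self, rng: np.random.Generator) -> None:
        cfg = self.config
        p: dict[str, np.ndarray] = {}
        if cfg.frontend == "cnn":
            c_in = cfg.cnn.input_shape[2]
            k = cfg.cnn.kernel_size
            for li, f in enumerate(cfg.cnn.conv_filters):
                p[f"conv{li}_K"] = _glorot(rng, (f, k, k, c_in)).astype(np.float64)
                p[f"conv{li}_b"] = np.zeros(f)
                c_in = f
        d = cfg.input_dim()
        h = cfg.hidden_size
        if cfg.use_gru:
            for name in ("W_r", "W_z", "W"):
                p[f"gru_{name}"] = _glorot(rng, (d, h))
            for name in ("U_r", "U_z", "U"):
                p[f"gru_{name}"] = _glorot(rng, (h, h))
            for name in ("b_r", "b_z", "b"):
                p[f"gru_{name}"] = np.zeros(h)
            head_in = h
        else:
            head_in = d
        # output layer starts near zero so the untrained softmax is almost
        # uniform (initial loss ≈ log 2) while staying non-degenerate
        p["dense_W"] = 0.01 * _glorot(rng, (head_in, cfg.n_classes))
        p["dense_b"] = np.zeros(cfg.n_classes)
        self.params = p

    @property
    def gru_weights(self) -> GruWeights:
        p = self.params
        return GruWeights(p["gru_W_r"], p["gru_W_z"], p["gru_W"],
                          p["gru_U_r"], p["gru_U_z"], p["gru_U"],
                          p["gru_b_r"], p["gru_b_z"], p["gru_b"])

    # -- forward -----------------------------------------------------------

    def _frontend_forward(self, X: np.ndarray, cache: dict | None = None):
        """(B, T, H, W, C) → per-frame features (B, T, D)."""
        cfg = self.config
        if cfg.frontend != "cnn":
            return np.asarray(X, dtype=np.float64)
        b, t = X.shape[:2]
        a = np.asarray(X, dtype=np.float64).reshape(b * t, *X.shape[2:])
        if cache is not None:
            cache["conv"] = []
        for li in range(cfg.cnn.n_layers):
            K = self.params[f"conv{li}_K"]
            bias = self.params[f"conv{li}_b"]
            cols, (hh, ww) = _im2col(a, K.shape[1], K.shape[2])
            pre = (cols @ K.reshape(K.shape[0], -1).T + bias).reshape(
                a.shape[0], hh, ww, K.shape[0])
            act = leaky_relu(pre, cfg.cnn.leaky_alpha)
            if cache is not None:
                cache["conv"].append({"in_shape": a.shape, "cols": cols,
                                      "pre": pre})
            a = act
        pooled, pool_cache = _max_pool_batch(a, cfg.cnn.pool_size,
                                             cfg.cnn.pool_stride)
        if cache is not None:
            cache["pool"] = pool_cache
            cache["pool_in_shape"] = a.shape
        return pooled.reshape(b, t, -1)

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        """Full forward pass; returns (probs, cache)."""
        cfg = self.config
        cache: dict = {}
        feats = self._frontend_forward(X, cache)
        cache["feats"] = feats
        b, t, d = feats.shape
        if cfg.use_gru:
            h = np.zeros((b, cfg.hidden_size))
            steps = []
            w = self.gru_weights
            for s in range(t):
                x_t = feats[:, s]
                r = sigmoid(x_t @ w.W_r + h @ w.U_r + w.b_r)
                z = sigmoid(x_t @ w.W_z + h @ w.U_z + w.b_z)
                hc = np.tanh(x_t @ w.W + (r * h) @ w.U + w.b)
                h_new = (1.0 - z) * h + z * hc
                steps.append({"x": x_t, "h_prev": h, "r": r, "z": z, "hc": hc})
                h = h_new
            cache["gru_steps"] = steps
            head_in = h
        else:
            head_in = feats.mean(axis=1)
        if train and cfg.dropout_rate > 0:
            if rng is None:
                raise ValueError("rng required for dropout during training")
            keep = (rng.random(head_in.shape) >= cfg.dropout_rate)
            head_in = head_in * keep / (1.0 - cfg.dropout_rate)
            cache["drop_mask"] = keep
        cache["head_in"] = head_in
        logits = head_in @ self.params["dense_W"] + self.params["dense_b"]
        probs = softmax(logits)
        cache["probs"] = probs
        return probs, cache

    def forward(self, sequence: np.ndarray) -> np.ndarray:
        """Class probabilities for one frame sequence (dropout disabled)."""
        seq = np.asarray(sequence, dtype=np.float64)
        probs, _ = self._forward(seq[None], train=False)
        return probs[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.asarray(X, dtype=np.float64), train=False)
        return probs

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    # -- backward ----------------------------------------------------------

    def _backward(self, X: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        cfg = self.config
        b = len(y)
        probs = cache["probs"]
        onehot = np.eye(cfg.n_classes)[y]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - onehot) / b
        grads["dense_W"] = cache["head_in"].T @ dlogits
        grads["dense_b"] = dlogits.sum(axis=0)
        dhead = dlogits @ self.params["dense_W"].T
        if "drop_mask" in cache:
            dhead = dhead * cache["drop_mask"] / (1.0 - cfg.dropout_rate)

        feats = cache["feats"]
        if cfg.use_gru:
            w = self.gru_weights
            for name in ("W_r", "W_z", "W", "U_r", "U_z", "U",
                         "b_r", "b_z", "b"):
                grads[f"gru_{name}"] = np.zeros_like(self.params[f"gru_{name}"])
            dfeats = np.zeros_like(feats)
            dh = dhead
            for s in reversed(range(feats.shape[1])):
                st = cache["gru_steps"][s]
                x_t, h_prev = st["x"], st["h_prev"]
                r, z, hc = st["r"], st["z"], st["hc"]
                dhc = dh * z
                dz = dh * (hc - h_prev)
                dh_prev = dh * (1.0 - z)
                da_h = dhc * (1.0 - hc**2)
                grads["gru_W"] += x_t.T @ da_h
                grads["gru_b"] += da_h.sum(axis=0)
                drh = da_h @ w.U.T
                grads["gru_U"] += (r * h_prev).T @ da_h
                dr = drh * h_prev
                dh_prev += drh * r
                da_z = dz * z * (1.0 - z)
                grads["gru_W_z"] += x_t.T @ da_z
                grads["gru_U_z"] += h_prev.T @ da_z
                grads["gru_b_z"] += da_z.sum(axis=0)
                dh_prev += da_z @ w.U_z.T
                da_r = dr * r * (1.0 - r)
                grads["gru_W_r"] += x_t.T @ da_r
                grads["gru_U_r"] += h_prev.T @ da_r
                grads["gru_b_r"] += da_r.sum(axis=0)
                dh_prev += da_r @ w.U_r.T
                dfeats[:, s] = da_h @ w.W.T + da_z @ w.W_z.T + da_r @ w.W_r.T
                dh = dh_prev
        else:
            dfeats = np.repeat(dhead[:, None, :] / feats.shape[1],
                               feats.shape[1], axis=1)

        if cfg.frontend == "cnn":
            bt = feats.shape[0] * feats.shape[1]
            dpooled = dfeats.reshape(bt, -1)
            da = _max_pool_backward(dpooled, cache["pool"],
                                    cache["pool_in_shape"],
                                    cfg.cnn.pool_size, cfg.cnn.pool_stride)
            for li in reversed(range(cfg.cnn.n_layers)):
                cv = cache["conv"][li]
                K = self.params[f"conv{li}_K"]
                f, kh, kw, c = K.shape
                dpre = da * np.where(cv["pre"] >= 0, 1.0, cfg.cnn.leaky_alpha)
                m, hh, ww, _ = dpre.shape
                dpre_r = dpre.reshape(m, hh * ww, f)
                grads[f"conv{li}_K"] = np.einsum(
                    "mpf,mpc->fc", dpre_r, cv["cols"]).reshape(K.shape)
                grads[f"conv{li}_b"] = dpre_r.sum(axis=(0, 1))
                if li > 0:
                    dcols = dpre_r @ K.reshape(f, -1)
                    da = _col2im(dcols, cv["in_shape"], kh, kw)
        return grads

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None,
                       train: bool = True):
        probs, cache = self._forward(X, train=train, rng=rng)
        loss = cross_entropy(probs, y)
        return loss, self._backward(X, y, cache)

    # -- training ----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            train_config: TrainConfig | None = None) -> dict:
        self.history = train(self, X, y, train_config or self.train_config)
        return self.history

    # -- serialisation -----------------------------------------------------

    def save(self, path) -> None:
        """Architecture + weights + normalisation metadata in one .npz."""
        import json
        from dataclasses import asdict
        meta = {"config": asdict(self.config), "seed": self.seed,
                "norm_stats": self.norm_stats}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path) -> "CnnGruModel":
        import json
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"].tobytes()).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        ccfg = meta["config"].pop("cnn")
        ccfg["input_shape"] = tuple(ccfg["input_shape"])
        ccfg["conv_filters"] = tuple(ccfg["conv_filters"])
        cfg = ModelConfig(cnn=CnnConfig(**ccfg), **meta["config"])
        model = cls(cfg, seed=meta["seed"])
        model.params = params
        model.norm_stats = meta["norm_stats"]
        return model


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean binary/categorical cross-entropy of softmax outputs."""
    eps = 1e-12
    return float(-np.log(probs[np.arange(len(y)), y] + eps).mean())


def _max_pool_batch(x: np.ndarray, k: int, stride: int):
    """Non-overlap-friendly batched max pool; returns (out, argmax cache)."""
    m, h, w, f = x.shape
    nh = (h - k) // stride + 1
    nw = (w - k) // stride + 1
    # gather windows as (m, nh, nw, f, k*k)
    idx_i = (np.arange(nh) * stride)[:, None] + np.arange(k)[None, :]
    idx_j = (np.arange(nw) * stride)[:, None] + np.arange(k)[None, :]
    win = x[:, idx_i[:, :, None, None], idx_j[None, None, :, :], :]
    # win: (m, nh, k, nw, k, f) → (m, nh, nw, f, k*k)
    win = win.transpose(0, 1, 3, 5, 2, 4).reshape(m, nh, nw, f, k * k)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    return out, arg


def _max_pool_backward(dflat: np.ndarray, arg: np.ndarray,
                       in_shape: tuple, k: int, stride: int) -> np.ndarray:
    m, h, w, f = in_shape
    nh, nw = arg.shape[1], arg.shape[2]
    dout = dflat.reshape(m, nh, nw, f)
    dx = np.zeros(in_shape)
    ki, kj = np.unravel_index(arg, (k, k))
    mi = np.arange(m)[:, None, None, None]
    fi = np.arange(f)[None, None, None, :]
    rows = (np.arange(nh) * stride)[None, :, None, None] + ki
    cols = (np.arange(nw) * stride)[None, None, :, None] + kj
    np.add.at(dx, (mi, rows, cols, fi), dout)
    return dx


def _col2im(dcols: np.ndarray, in_shape: tuple, kh: int, kw: int) -> np.ndarray:
    m, h, w, c = in_shape
    hh, ww = h - kh + 1, w - kw + 1
    d = dcols.reshape(m, hh, ww, kh, kw, c)
    dx = np.zeros(in_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, i:i + hh, j:j + ww, :] += d[:, :, :, i, j, :]
    return dx


# ---------------------------------------------------------------------------
# Optimiser and training loop
# ---------------------------------------------------------------------------

def train(model: CnnGruModel, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig | None = None) -> dict:
    """Minimise binary cross-entropy; returns per-epoch history.

    A seeded fraction of the data is held out for early stopping on
    validation loss (best weights restored); with ``val_fraction=0`` the
    stopper watches the training loss instead.  Deterministic given the
    seed under single-threaded execution.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(cfg.seed)

    n = len(y)
    n_val = int(round(cfg.val_fraction * n))
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    if len(np.unique(y[tr_idx])) < 2:   # tiny sets: skip the holdout
        tr_idx, val_idx = perm, perm[:0]
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    state = {k: {"m": np.zeros_like(v), "v": np.zeros_like(v)}
             for k, v in model.params.items()}
    t_step = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    history = {"loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []}
    best_loss, best_params, wait = np.inf, None, 0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ytr))
        ep_loss, ep_correct = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            bidx = order[start:start + cfg.batch_size]
            probs, cache = model._forward(Xtr[bidx], train=True, rng=rng)
            loss = cross_entropy(probs, ytr[bidx])
            grads = model._backward(Xtr[bidx], ytr[bidx], cache)
            ep_loss += loss * len(bidx)
            ep_correct += int((probs.argmax(1) == ytr[bidx]).sum())
            t_step += 1
            for k, g in grads.items():
                if cfg.optimizer == "adam":
                    st = state[k]
                    st["m"] = beta1 * st["m"] + (1 - beta1) * g
                    st["v"] = beta2 * st["v"] + (1 - beta2) * g * g
                    mhat = st["m"] / (1 - beta1**t_step)
                    vhat = st["v"] / (1 - beta2**t_step)
                    model.params[k] -= cfg.learning_rate * mhat / (
                        np.sqrt(vhat) + eps)
                elif cfg.optimizer == "sgd":
                    model.params[k] -= cfg.learning_rate * g
                else:
                    raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
        history["loss"].append(ep_loss / len(ytr))
        history["accuracy"].append(ep_correct / len(ytr))

        if len(yval):
            vprobs = model.predict_proba(Xval)
            vloss = cross_entropy(vprobs, yval)
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(
                float((vprobs.argmax(1) == yval).mean()))
            watch = vloss
        else:
            watch = history["loss"][-1]
        if watch < best_loss - cfg.min_delta:
            best_loss, wait = watch, 0
            best_params = {k: v.copy() for k, v in model.params.items()}
        else:
            wait += 1
            if wait >= cfg.patience:
                logger.info("early stop at epoch %d (best loss %.4f)",
                            epoch + 1, best_loss)
                break
    if best_params is not None:
        model.params = best_params
    return history


# ---------------------------------------------------------------------------
# Introspection
# ---------------------------------------------------------------------------

def count_parameters(obj, scope: str = "total") -> int:
    """Trainable parameter count of a model or configuration.

    ``scope="conv_layer"`` counts the first convolution layer only
    (k·k·c_in·F + F); ``scope="total"`` sums every tensor.
    """
    if isinstance(obj, CnnGruModel):
        if scope == "conv_layer":
            if "conv0_K" not in obj.params:
                raise ValueError("model has no convolution layer")
            return obj.params["conv0_K"].size + obj.params["conv0_b"].size
        if scope == "total":
            return int(sum(v.size for v in obj.params.values()))
        raise ValueError(f"unknown scope {scope!r}")
    cfg = obj.cnn if isinstance(obj, ModelConfig) else obj
    if scope == "conv_layer":
        k = cfg.kernel_size
        return k * k * cfg.input_shape[2] * cfg.conv_filters[0] + cfg.conv_filters[0]
    if scope == "total":
        if not isinstance(obj, ModelConfig):
            raise ValueError("total count needs a ModelConfig")
        return count_parameters(CnnGruModel(obj, seed=0), "total")
    raise ValueError(f"unknown scope {scope!r}")


def describe(config: ModelConfig | None = None) -> str:
    """Layer/parameter table in the style of a depth-sweep report."""
    cfg = config or ModelConfig()
    model = CnnGruModel(cfg, seed=0)
    rows = []
    if cfg.frontend == "cnn":
        for li, f in enumerate(cfg.cnn.conv_filters):
            n = model.params[f"conv{li}_K"].size + model.params[f"conv{li}_b"].size
            rows.append((f"conv{li + 1} ({cfg.cnn.kernel_size}×"
                         f"{cfg.cnn.kernel_size}, {f} filters)", n))
        rows.append((f"max-pool ({cfg.cnn.pool_size}×{cfg.cnn.pool_size})", 0))
    if cfg.use_gru:
        n = sum(model.params[k].size for k in model.params if k.startswith("gru_"))
        rows.append((f"GRU (hidden {cfg.hidden_size})", n))
    rows.append((f"dropout (p={cfg.dropout_rate})", 0))
    rows.append(("dense", model.params["dense_W"].size
                 + model.params["dense_b"].size))
    rows.append(("softmax", 0))
    width = max(len(r[0]) for r in rows)
    lines = [f"{'Layer':<{width}}  Parameters",
             "-" * (width + 12)]
    for name, n in rows:
        lines.append(f"{name:<{width}}  {n:>10,}")
    lines.append("-" * (width + 12))
    lines.append(f"{'total':<{width}}  {count_parameters(model):>10,}")
    return "\n".join(lines)
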