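"""1-D convolutional EMG-to-torque regression.

Maps a short two-channel surface-EMG window (tibialis anterior, soleus) to
the ankle joint torque it reflects, with plantar flexion positive and
dorsiflexion negative.  The network is three convolution+max-pool stages
followed by a five-layer perceptron whose Tanh output is scaled to the
physiological torque range:

    conv(128, k=13) - pool(6) - conv(128, k=9) - pool(4) - conv(128, k=6)
    - pool(2) - flatten - 129 - 128 - 128 - 64 - 1(Tanh) - x tau_max

All layers use stride 1 and ReLU except the Tanh output.  Training uses
Adam on a mean-squared-error loss with early stopping on a validation
split.  The implementation is plain numpy (im2col convolutions, float32),
fully deterministic under a fixed seed.

The public surface is the sklearn-style :class:`CnnTorqueRegressor`
(``fit`` / ``predict`` / ``get_params``); the module-level ``build_model``,
``train`` and ``estimate_torque`` functions are thin wrappers over it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "CnnConfig",
    "EmgTorqueDataset",
    "TorqueEstimate",
    "CnnTorqueRegressor",
    "build_model",
    "train",
    "estimate_torque",
    "peak_accuracy",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyperparameters of the torque regressor."""

    conv_filters: tuple[int, ...] = (128, 128, 128)
    kernel_sizes: tuple[int, ...] = (13, 9, 6)
    pool_sizes: tuple[int, ...] = (6, 4, 2)
    mlp_widths: tuple[int, ...] = (129, 128, 128, 64, 1)
    input_channels: int = 2
    window_len: int = 288
    tau_max: float = 60.0  # Nm; Tanh output is scaled to [-tau_max, tau_max]
    lr: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 120
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            len(self.conv_filters) == len(self.kernel_sizes) == len(self.pool_sizes)
        ):
            raise ValueError("conv_filters, kernel_sizes, pool_sizes must align")
        if min(self.conv_filters + self.kernel_sizes + self.pool_sizes) <= 0:
            raise ValueError("layer sizes must be positive")
        if self.mlp_widths[-1] != 1:
            raise ValueError("last MLP width must be 1 (scalar torque)")
        self.feature_lengths()  # raises if the window is too short

    def feature_lengths(self) -> list[int]:
        """Sequence length after each conv and pool stage; validates window_len."""
        L = self.window_len
        lengths = []
        for k, p in zip(self.kernel_sizes, self.pool_sizes, strict=True):
            L = L - k + 1
            if L <= 0:
                raise ValueError(
                    f"window_len {self.window_len} too short for kernel chain"
                )
            L //= p
            if L <= 0:
                raise ValueError(
                    f"window_len {self.window_len} too short for pooling chain"
                )
            lengths.append(L)
        return lengths

    @property
    def flatten_len(self) -> int:
        return self.conv_filters[-1] * self.feature_lengths()[-1]


@dataclass(frozen=True)
class TorqueEstimate:
    """A single torque estimate, plantar flexion positive (Nm)."""

    tau: float
    bound: float = 150.0  # physiological magnitude bound

    def __post_init__(self) -> None:
        if not np.isfinite(self.tau) or abs(self.tau) > self.bound:
            raise ValueError(f"torque estimate {self.tau} outside +/-{self.bound} Nm")


@dataclass
class EmgTorqueDataset:
    """Aligned EMG windows and torque targets with a train/val/test split."""

    windows: np.ndarray  # (n, channels, window_len)
    torques: np.ndarray  # (n,), Nm, plantar flexion positive
    split_ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    split_seed: int = 0

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.float32)
        self.torques = np.asarray(self.torques, dtype=np.float32).ravel()
        if len(self.windows) != len(self.torques):
            raise ValueError("windows and torques must be aligned")
        if abs(sum(self.split_ratio) - 1.0) > 1e-9:
            raise ValueError("split_ratio must sum to 1")

    def splits(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Disjoint train/val/test index arrays (seeded shuffle)."""
        n = len(self.torques)
        rng = np.random.default_rng(self.split_seed)
        order = rng.permutation(n)
        n_train = int(round(self.split_ratio[0] * n))
        n_val = int(round(self.split_ratio[1] * n))
        return (
            order[:n_train],
            order[n_train : n_train + n_val],
            order[n_train + n_val :],
        )


# ---------------------------------------------------------------------------
# numpy network internals


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Valid 1-D convolution, stride 1.

    x: (B, C, L); W: (C*k, F); returns (col, y) with col (B, L', C*k) and
    y (B, F, L').
    """
    k = W.shape[0] // x.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (B, C, L', k)
    col = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(
        x.shape[0], -1, W.shape[0]
    )
    y = col @ W + b  # (B, L', F)
    return col, y.transpose(0, 2, 1)


def _conv1d_backward(dy: np.ndarray, col: np.ndarray, W: np.ndarray, x_shape, k: int):
    """Gradients of the valid convolution. dy: (B, F, L')."""
    dy_t = dy.transpose(0, 2, 1)  # (B, L', F)
    dW = np.tensordot(col, dy_t, axes=([0, 1], [0, 1]))  # (C*k, F)
    db = dy_t.sum(axis=(0, 1))
    dcol = dy_t @ W.T  # (B, L', C*k)
    B, C, L = x_shape
    Lp = dcol.shape[1]
    dcol = dcol.reshape(B, Lp, C, k)
    dx = np.zeros(x_shape, dtype=dcol.dtype)
    for j in range(k):
        dx[:, :, j : j + Lp] += dcol[:, :, :, j].transpose(0, 2, 1)
    return dx, dW, db


def _maxpool_forward(x: np.ndarray, p: int):
    """Non-overlapping max pooling along the last axis (truncating)."""
    B, F, L = x.shape
    Lp = L // p
    xr = x[:, :, : Lp * p].reshape(B, F, Lp, p)
    idx = xr.argmax(axis=3)
    return xr.max(axis=3), idx, L

def _maxpool_backward(dy: np.ndarray, idx: np.ndarray, p: int, L: int):
    B, F, Lp = dy.shape
    dx = np.zeros((B, F, Lp, p), dtype=dy.dtype)
    bi, fi, li = np.ogrid[:B, :F, :Lp]
    dx[bi, fi, li, idx] = dy
    dx = dx.reshape(B, F, Lp * p)
    if Lp * p < L:
        dx = np.pad(dx, ((0, 0), (0, 0), (0, L - Lp * p)))
    return dx


def _relu(x):
    return np.maximum(x, 0.0)


class _Network:
    """Parameter container with forward/backward passes and Adam updates."""

    def __init__(self, config: CnnConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = config.input_channels
        for i, (f, k) in enumerate(
            zip(config.conv_filters, config.kernel_sizes, strict=True)
        ):
            fan_in = c_in * k
            self.params[f"Wc{i}"] = (
                rng.standard_normal((fan_in, f)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            self.params[f"bc{i}"] = np.zeros(f, dtype=np.float32)
            c_in = f
        widths = (config.flatten_len,) + config.mlp_widths
        n_dense = len(config.mlp_widths)
        for i, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:], strict=True)):
            # He init for the ReLU layers; the Tanh output layer starts small
            # so the scaled output begins near zero instead of saturated
            scale = np.sqrt(2.0 / w_in) if i < n_dense - 1 else 0.1 / np.sqrt(w_in)
            self.params[f"Wd{i}"] = (
                rng.standard_normal((w_in, w_out)) * scale
            ).astype(np.float32)
            self.params[f"bd{i}"] = np.zeros(w_out, dtype=np.float32)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def checksum(self) -> float:
        return float(sum(np.abs(v).sum() for v in self.params.values()))

    def forward(self, x: np.ndarray, keep: bool = False):
        """x: (B, C, window_len) normalized; returns torque (B,) in Nm."""
        cfg = self.config
        cache: dict = {"x": x}
        h = x
        for i, p in enumerate(cfg.pool_sizes):
            col, z = _conv1d_forward(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = _relu(z)
            pooled, idx, L = _maxpool_forward(a, p)
            if keep:
                cache[f"h{i}"] = h
                cache[f"col{i}"] = col
                cache[f"z{i}"] = z
                cache[f"idx{i}"] = idx
                cache[f"L{i}"] = L
            h = pooled
        flat = h.reshape(h.shape[0], -1)
        if keep:
            cache["pooled_shape"] = h.shape
        a = flat
        n_dense = len(cfg.mlp_widths)
        for i in range(n_dense):
            z = a @ self.params[f"Wd{i}"] + self.params[f"bd{i}"]
            if keep:
                cache[f"da{i}"] = a
                cache[f"dz{i}"] = z
            a = np.tanh(z) if i == n_dense - 1 else _relu(z)
        out = cfg.tau_max * a[:, 0]
        if keep:
            cache["tanh"] = a
            self._cache = cache
        return out

    def backward(self, dout: np.ndarray):
        """dout: (B,) gradient of loss wrt the torque output."""
        cfg = self.config
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        n_dense = len(cfg.mlp_widths)
        da = (dout[:, None] * cfg.tau_max * (1.0 - cache["tanh"] ** 2)).astype(
            np.float32
        )
        for i in range(n_dense - 1, -1, -1):
            if i != n_dense - 1:
                da = da * (cache[f"dz{i}"] > 0)
            a_prev = cache[f"da{i}"]
            grads[f"Wd{i}"] = a_prev.T @ da
            grads[f"bd{i}"] = da.sum(axis=0)
            da = da @ self.params[f"Wd{i}"].T
        dh = da.reshape(cache["pooled_shape"])
        for i in range(len(cfg.pool_sizes) - 1, -1, -1):
            dh = _maxpool_backward(dh, cache[f"idx{i}"], cfg.pool_sizes[i], cache[f"L{i}"])
            dh = dh * (cache[f"z{i}"] > 0)
            dh, grads[f"Wc{i}"], grads[f"bc{i}"] = _conv1d_backward(
                dh,
                cache[f"col{i}"],
                self.params[f"Wc{i}"],
                cache[f"h{i}"].shape,
                cfg.kernel_sizes[i],
            )
        return grads

    def adam_step(self, grads: dict[str, np.ndarray]):
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        self._adam_t += 1
        t = self._adam_t
        lr = self.config.lr
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m += (1 - beta1) * (g - m)
            v += (1 - beta2) * (g * g - v)
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)


# ---------------------------------------------------------------------------
# estimator


class CnnTorqueRegressor(RegressorMixin, BaseEstimator):
    """EMG-window to ankle-torque regressor (numpy 1-D CNN).

    Parameters mirror :class:`CnnConfig`; inputs to ``fit``/``predict`` are
    arrays of shape (n, channels, window_len) or flattened
    (n, channels*window_len).  Per-channel z-score normalization statistics
    are computed on the training data.

    Attributes (after ``fit``)
    --------------------------
    network_ : the trained parameter container
    norm_mean_, norm_std_ : per-channel normalization statistics
    history_ : per-epoch train/validation loss log
    n_epochs_ : epochs actually run before early stopping
    """

    def __init__(
        self,
        window_len: int = 288,
        input_channels: int = 2,
        tau_max: float = 60.0,
        lr: float = 1e-3,
        batch_size: int = 64,
        max_epochs: int = 120,
        patience: int = 10,
        seed: int = 0,
    ):
        self.window_len = window_len
        self.input_channels = input_channels
        self.tau_max = tau_max
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def _config(self) -> CnnConfig:
        return CnnConfig(
            input_channels=self.input_channels,
            window_len=self.window_len,
            tau_max=self.tau_max,
            lr=self.lr,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            patience=self.patience,
            seed=self.seed,
        )

    def _shape(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X.reshape(len(X), self.input_channels, self.window_len)
        if X.shape[1:] != (self.input_channels, self.window_len):
            raise ValueError(
                f"expected windows of shape (n, {self.input_channels}, "
                f"{self.window_len}), got {X.shape}"
            )
        return X

    def fit(self, X, y, validation_data=None):
        cfg = self._config()
        X = self._shape(X)
        y = np.asarray(y, dtype=np.float32).ravel()
        if len(X) != len(y) or len(X) == 0:
            raise ValueError("X and y must be non-empty and aligned")
        rng = np.random.default_rng(cfg.seed + 1)
        if validation_data is None:
            n_val = max(1, int(0.25 * len(X)))
            order = rng.permutation(len(X))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            Xv, yv = X[val_idx], y[val_idx]
            X, y = X[tr_idx], y[tr_idx]
        else:
            Xv = self._shape(validation_data[0])
            yv = np.asarray(validation_data[1], dtype=np.float32).ravel()
        self.norm_mean_ = X.mean(axis=(0, 2), keepdims=True)
        self.norm_std_ = X.std(axis=(0, 2), keepdims=True) + np.float32(1e-8)
        Xn = (X - self.norm_mean_) / self.norm_std_
        Xvn = (Xv - self.norm_mean_) / self.norm_std_

        net = _Network(cfg)
        best = {k: v.copy() for k, v in net.params.items()}
        best_val = np.inf
        stale = 0
        self.history_ = []
        n = len(Xn)
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xn[idx], y[idx]
                pred = net.forward(xb, keep=True)
                err = pred - yb
                loss = float(np.mean(err**2))
                if not np.isfinite(loss):
                    raise FloatingPointError("training loss diverged (non-finite)")
                train_loss += loss * len(idx)
                grads = net.backward((2.0 / len(idx)) * err)
                net.adam_step(grads)
            val_loss = float(np.mean((self._forward_batched(net, Xvn) - yv) ** 2))
            self.history_.append(
                {"epoch": epoch, "train_mse": train_loss / n, "val_mse": val_loss}
            )
            if val_loss < best_val - 1e-7:
                best_val = val_loss
                best = {k: v.copy() for k, v in net.params.items()}
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        net.params = best
        self.network_ = net
        self.n_epochs_ = len(self.history_)
        self.best_val_mse_ = best_val
        return self

    @staticmethod
    def _forward_batched(net: _Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
        outs = [net.forward(X[i : i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(outs) if outs else np.empty(0)

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "network_"):
            raise RuntimeError("regressor is not fitted")
        X = self._shape(X)
        Xn = (X - self.norm_mean_) / self.norm_std_
        return self._forward_batched(self.network_, Xn).astype(float)

    def score_rmse(self, X, y) -> float:
        return float(np.sqrt(np.mean((self.predict(X) - np.asarray(y).ravel()) ** 2)))


# ---------------------------------------------------------------------------
# functional wrappers


def build_model(config: CnnConfig) -> CnnTorqueRegressor:
    """Unfitted regressor from a config (the network itself is seeded and
    instantiated lazily at ``fit``; initial parameter checksums for a config
    are available via ``initial_checksum``)."""
    return CnnTorqueRegressor(
        window_len=config.window_len,
        input_channels=config.input_channels,
        tau_max=config.tau_max,
        lr=config.lr,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
    )


def initial_checksum(config: CnnConfig) -> float:
    """Checksum of the freshly initialized (untrained) parameters."""
    return _Network(config).checksum()


def train(
    model: CnnTorqueRegressor,
    dataset: EmgTorqueDataset,
    max_epochs: int | None = None,
    patience: int | None = None,
) -> tuple[CnnTorqueRegressor, dict[str, float]]:
    """Train on the dataset's train/val splits; metrics on the test split.

    Returns the fitted model and ``{"rmse": Nm, "peak_accuracy": %,
    "correlation": r, "n_epochs": int}``.
    """
    if max_epochs is not None:
        model.max_epochs = max_epochs
    if patience is not None:
        model.patience = patience
    tr, va, te = dataset.splits()
    model.fit(
        dataset.windows[tr],
        dataset.torques[tr],
        validation_data=(dataset.windows[va], dataset.torques[va]),
    )
    pred = model.predict(dataset.windows[te])
    true = dataset.torques[te].astype(float)
    metrics = {
        "rmse": float(np.sqrt(np.mean((pred - true) ** 2))),
        "peak_accuracy": peak_accuracy(pred, true),
        "correlation": float(np.corrcoef(pred, true)[0, 1]),
        "n_epochs": model.n_epochs_,
    }
    return model, metrics


def estimate_torque(model: CnnTorqueRegressor, window: np.ndarray) -> TorqueEstimate:
    """Torque estimate for a single 2-channel EMG window."""
    window = np.asarray(window, dtype=np.float32)
    if window.ndim != 2:
        raise ValueError("window must be a 2-D array (channels, window_len)")
    tau = float(model.predict(window[None])[0])
    return TorqueEstimate(tau=tau)


def peak_accuracy(predicted: np.ndarray, true: np.ndarray) -> float:
    """Agreement of peak torque magnitudes, in percent.

        100 * (1 - | max|pred| - max|true| | / max|true| ), clamped to [0, 100].
    """
    predicted = np.asarray(predicted, dtype=float)
    true = np.asarray(true, dtype=float)
    if predicted.shape != true.shape:
        raise ValueError("series must be aligned")
    peak_true = float(np.max(np.abs(true)))
    if peak_true == 0.0:
        raise ValueError("peak accuracy undefined for an all-zero true series")
    peak_pred = float(np.max(np.abs(predicted)))
    acc = 100.0 * (1.0 - abs(peak_pred - peak_true) / peak_true)
    return float(min(max(acc, 0.0), 100.0))


def save_model(model: CnnTorqueRegressor, path: str) -> None:
    """Write a fitted model to a single ``.npz`` checkpoint with its config."""
    if not hasattr(model, "network_"):
        raise RuntimeError("cannot save an unfitted model")
    payload = {f"param_{k}": v for k, v in model.network_.params.items()}
    payload["norm_mean"] = model.norm_mean_
    payload["norm_std"] = model.norm_std_
    payload["config_json"] = np.frombuffer(
        json.dumps(asdict(model.network_.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_model(path: str) -> CnnTorqueRegressor:
    """Load a checkpoint written by :func:`save_model`."""
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    for key in ("conv_filters", "kernel_sizes", "pool_sizes", "mlp_widths"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = CnnConfig(**cfg_dict)
    model = build_model(config)
    net = _Network(config)
    net.params = {
        k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
    }
    model.network_ = net
    model.norm_mean_ = data["norm_mean"]
    model.norm_std_ = data["norm_std"]
    model.history_ = []
    model.n_epochs_ = 0
    return model
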