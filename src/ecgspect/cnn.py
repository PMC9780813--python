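"""A compact convolutional network for 64x64 grayscale inputs, in NumPy.

Architecture: four 3x3 convolution blocks (64, 128, 256, 64 filters, each
with bias and ReLU, followed by 2x2 max pooling; dropout 0.25 after blocks
1, 3 and 4), flatten, a dense layer of width 8 (ReLU), and a single
sigmoid output unit with an L1 activity regularizer.  With unpadded
convolutions the feature maps run 64 -> 62 -> 31 -> 29 -> 14 -> 12 -> 6 ->
4 -> 2, the flatten width is 2*2*64 = 256, and the trainable-parameter
total is 519,249 (0.52 million).

Forward and backward passes are written against im2col matrix
multiplication; gradients are exact (verified against finite differences
in the test suite).  All stochastic elements (initialization, dropout)
draw from explicit seeded generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ModelSpec", "SmallCnn", "build_model", "count_parameters"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically safe for large |z|
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


@dataclass(frozen=True)
class ModelSpec:
    """Layer-by-layer description; the parameter count is a pure function
    of this spec."""

    input_size: tuple[int, int] = (64, 64)
    conv_filters: tuple[int, ...] = (64, 128, 256, 64)
    dropout_rates: tuple[float, ...] = (0.25, 0.0, 0.25, 0.25)
    kernel: int = 3
    pool: int = 2
    dense_units: int = 8
    padding: str = "valid"  # or "same"
    l1_activity: float = 1e-4

    def __post_init__(self) -> None:
        if len(self.conv_filters) != len(self.dropout_rates):
            raise ValueError("one dropout rate per conv block required")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {self.padding!r}")

    def feature_shapes(self) -> list[tuple[int, int, int]]:
        """(height, width, channels) after each conv+pool block."""
        h, w = self.input_size
        c = 1
        shapes = []
        for f in self.conv_filters:
            if self.padding == "valid":
                h, w = h - (self.kernel - 1), w - (self.kernel - 1)
            if h < 1 or w < 1:
                raise ValueError(
                    f"input {self.input_size} too small for "
                    f"{len(self.conv_filters)} conv/pool stages"
                )
            h, w = h // self.pool, w // self.pool
            if h < 1 or w < 1:
                raise ValueError(
                    f"input {self.input_size} too small for "
                    f"{len(self.conv_filters)} conv/pool stages"
                )
            c = f
            shapes.append((h, w, c))
        return shapes

    @property
    def flatten_width(self) -> int:
        h, w, c = self.feature_shapes()[-1]
        return h * w * c


def count_parameters(spec: ModelSpec) -> int:
    """Closed-form trainable-parameter count.

    Each conv block contributes ``k*k*c_in*c_out + c_out``; the dense path
    contributes ``flatten*units + units`` and ``units*1 + 1``.
    """
    k = spec.kernel
    total = 0
    c_in = 1
    for c_out in spec.conv_filters:
        total += k * k * c_in * c_out + c_out
        c_in = c_out
    if spec.conv_filters:
        flat = spec.flatten_width
    else:
        flat = spec.input_size[0] * spec.input_size[1]
    total += flat * spec.dense_units + spec.dense_units
    total += spec.dense_units * 1 + 1
    return total


def _glorot(rng, shape, fan_in, fan_out, dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    # x: (B, H, W, C) -> (B*(H-k+1)*(W-k+1), C*k*k), window order (C, ki, kj)
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (B,H',W',C,k,k)
    b, hp, wp = win.shape[:3]
    return win.reshape(b * hp * wp, x.shape[3] * k * k)


def _kernel_matrix(w: np.ndarray) -> np.ndarray:
    # (k,k,Cin,F) -> (Cin*k*k, F) matching the _im2col window order
    k = w.shape[0]
    return w.transpose(2, 0, 1, 3).reshape(-1, w.shape[-1])


class SmallCnn:
    """Realized network with seeded weights and exact gradients."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype  # float64 makes finite-difference checks sharp
        rng = np.random.default_rng(seed)
        k = spec.kernel
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = 1
        for f in spec.conv_filters:
            fan_in = k * k * c_in
            self.conv_w.append(_glorot(rng, (k, k, c_in, f), fan_in, f, dtype))
            self.conv_b.append(np.zeros(f, dtype=dtype))
            c_in = f
        flat = spec.flatten_width if spec.conv_filters else (
            spec.input_size[0] * spec.input_size[1]
        )
        self.w1 = _glorot(rng, (flat, spec.dense_units), flat, spec.dense_units, dtype)
        self.b1 = np.zeros(spec.dense_units, dtype=dtype)
        self.w2 = _glorot(rng, (spec.dense_units, 1), spec.dense_units, 1, dtype)
        self.b2 = np.zeros(1, dtype=dtype)

    # -- parameter plumbing -------------------------------------------------
    @property
    def parameters(self) -> list[np.ndarray]:
        return [*self.conv_w, *self.conv_b, self.w1, self.b1, self.w2, self.b2]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.conv_w)
        self.conv_w = [p.astype(self.dtype) for p in params[:n]]
        self.conv_b = [p.astype(self.dtype) for p in params[n : 2 * n]]
        self.w1, self.b1, self.w2, self.b2 = (
            p.astype(self.dtype) for p in params[2 * n :]
        )

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters))

    # -- forward ------------------------------------------------------------
    def _conv_forward(self, x, w, b):
        k = self.spec.kernel
        if self.spec.padding == "same":
            p = (k - 1) // 2
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        cols = _im2col(x, k)
        bsz, hp, wp = x.shape[0], x.shape[1] - k + 1, x.shape[2] - k + 1
        out = cols @ _kernel_matrix(w) + b
        return out.reshape(bsz, hp, wp, -1), (x.shape, cols)

    def _conv_backward(self, dout, w, cache):
        xshape, cols = cache
        k = self.spec.kernel
        c_in, f = w.shape[2], w.shape[3]
        bsz, hp, wp = dout.shape[:3]
        dflat = dout.reshape(-1, f)
        dw = (cols.T @ dflat).reshape(c_in, k, k, f).transpose(1, 2, 0, 3)
        db = dflat.sum(axis=0)
        # dx via one matmul into per-tap slabs, then a 9-way scatter-add
        taps = (dflat @ _kernel_matrix(w).T).reshape(bsz, hp, wp, c_in, k, k)
        dx = np.zeros(xshape, dtype=self.dtype)
        for di in range(k):
            for dj in range(k):
                dx[:, di : di + hp, dj : dj + wp, :] += taps[:, :, :, :, di, dj]
        if self.spec.padding == "same":
            p = (k - 1) // 2
            dx = dx[:, p : dx.shape[1] - p, p : dx.shape[2] - p, :]
        return dx, dw, db

    @staticmethod
    def _pool_forward(x, p):
        b, h, w, c = x.shape
        h2, w2 = h // p, w // p
        xt = x[:, : h2 * p, : w2 * p, :].reshape(b, h2, p, w2, p, c)
        windows = xt.transpose(0, 1, 3, 2, 4, 5).reshape(b, h2, w2, p * p, c)
        idx = windows.argmax(axis=3)
        out = np.take_along_axis(windows, idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :
        ]
        return out, (x.shape, idx)

    @staticmethod
    def _pool_backward(dout, p, cache):
        shape, idx = cache
        b, h, w, c = shape
        h2, w2 = h // p, w // p
        dwin = np.zeros((b, h2, w2, p * p, c), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = np.zeros(shape, dtype=dout.dtype)
        dx[:, : h2 * p, : w2 * p, :] = (
            dwin.reshape(b, h2, w2, p, p, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, h2 * p, w2 * p, c)
        )
        return dx

    def forward(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Logits for a batch ``x`` of shape (B, H, W) or (B, H, W, 1).

        In training mode dropout masks are drawn from ``rng``; caches for
        the backward pass are retained on the instance.
        """
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 3:
            x = x[..., None]
        self._cache = {"input": x, "conv": [], "drop": []}
        a = x
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            z, conv_cache = self._conv_forward(a, w, b)
            relu_mask = z > 0
            a = z * relu_mask
            a, pool_cache = self._pool_forward(a, self.spec.pool)
            rate = self.spec.dropout_rates[i]
            if training and rate > 0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng")
                mask = (rng.random(a.shape) >= rate).astype(self.dtype) / (
                    1.0 - rate
                )
                a = a * mask
            else:
                mask = None
            self._cache["conv"].append((conv_cache, relu_mask, pool_cache))
            self._cache["drop"].append(mask)
        bsz = a.shape[0]
        flat = a.reshape(bsz, -1)
        z1 = flat @ self.w1 + self.b1
        h1 = np.maximum(z1, 0.0)
        logits = h1 @ self.w2 + self.b2
        self._cache.update(flat=flat, z1=z1, h1=h1, pooled_shape=a.shape)
        return logits[:, 0]

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Sigmoid outputs in inference mode."""
        x = np.asarray(x, dtype=self.dtype)
        probs = []
        for i in range(0, len(x), batch_size):
            logits = self.forward(x[i : i + batch_size], training=False)
            probs.append(_sigmoid(logits))
        return np.concatenate(probs)

    def loss_and_gradients(
        self,
        x: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ) -> tuple[float, list[np.ndarray]]:
        """Mean binary cross-entropy (+ L1 activity penalty) and gradients.

        Returns ``(loss, grads)`` with ``grads`` ordered like
        :attr:`parameters`.
        """
        y = np.asarray(y, dtype=self.dtype)
        logits = self.forward(x, training=training, rng=rng)
        p = _sigmoid(logits)
        eps = 1e-12
        bce = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
        lam = self.spec.l1_activity
        loss = float(bce + lam * np.mean(np.abs(p)))
        bsz = len(y)
        # d(loss)/d(logit): BCE gives (p - y)/B; the L1 term on the sigmoid
        # activation (which is non-negative) adds lam * p(1-p)/B.
        dz = (p - y) / bsz + lam * p * (1 - p) / bsz
        dz = dz.astype(self.dtype)[:, None]

        c = self._cache
        dw2 = c["h1"].T @ dz
        db2 = dz.sum(axis=0)
        dh1 = dz @ self.w2.T
        dz1 = dh1 * (c["z1"] > 0)
        dw1 = c["flat"].T @ dz1
        db1 = dz1.sum(axis=0)
        da = (dz1 @ self.w1.T).reshape(c["pooled_shape"])

        dconv_w: list[np.ndarray] = [None] * len(self.conv_w)
        dconv_b: list[np.ndarray] = [None] * len(self.conv_w)
        for i in range(len(self.conv_w) - 1, -1, -1):
            mask = c["drop"][i]
            if mask is not None:
                da = da * mask
            conv_cache, relu_mask, pool_cache = c["conv"][i]
            da = self._pool_backward(da, self.spec.pool, pool_cache)
            da = da * relu_mask
            da, dw, db = self._conv_backward(da, self.conv_w[i], conv_cache)
            dconv_w[i], dconv_b[i] = dw, db
        grads = [*dconv_w, *dconv_b, dw1, db1, dw2, db2]
        return loss, [g.astype(self.dtype) for g in grads]


    # -- persistence --------------------------------------------------------
    def save_weights(self, path) -> None:
        """Checkpoint all parameter arrays (and the spec) to ``.npz``."""
        import json

        arrays = {f"p{i}": p for i, p in enumerate(self.parameters)}
        spec_json = json.dumps(
            {
                "input_size": list(self.spec.input_size),
                "conv_filters": list(self.spec.conv_filters),
                "dropout_rates": list(self.spec.dropout_rates),
                "kernel": self.spec.kernel,
                "pool": self.spec.pool,
                "dense_units": self.spec.dense_units,
                "padding": self.spec.padding,
                "l1_activity": self.spec.l1_activity,
            }
        )
        np.savez(path, spec=np.array(spec_json), **arrays)

    @classmethod
    def load_weights(cls, path) -> "SmallCnn":
        import json

        data = np.load(path, allow_pickle=False)
        raw = json.loads(str(data["spec"]))
        spec = ModelSpec(
            input_size=tuple(raw["input_size"]),
            conv_filters=tuple(raw["conv_filters"]),
            dropout_rates=tuple(raw["dropout_rates"]),
            kernel=raw["kernel"],
            pool=raw["pool"],
            dense_units=raw["dense_units"],
            padding=raw["padding"],
            l1_activity=raw["l1_activity"],
        )
        model = cls(spec)
        model.set_parameters(
            [data[f"p{i}"] for i in range(len(model.parameters))]
        )
        return model


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> tuple[SmallCnn, int]:
    """Realize the network and return it with its parameter count.

    The count returned is the closed-form :func:`count_parameters` value;
    it always equals the realized model's own total.
    """
    spec = spec or ModelSpec()
    spec.feature_shapes()  # validates the input is large enough
    model = SmallCnn(spec, seed=seed)
    n = count_parameters(spec)
    assert n == model.n_parameters()
    return model, n
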