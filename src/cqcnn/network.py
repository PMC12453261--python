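"""The hybrid classical-quantum convolutional network.

Architecture (for 128x128 single-channel input):

    Conv(1->2, 5x5, stride 1, no padding) -> ReLU -> MaxPool 2x2
    Conv(2->4, 5x5, stride 1, no padding) -> ReLU -> MaxPool 2x2
    Dropout2D -> Flatten (3364)
    Dense(3364->4) -> ReLU -> Dense(4->omega)
    quantum branch:   squash -> PQC (per-sample o1) -> Dense(1->1)
    classical branch: tanh -> Dense(omega->1, no bias) -> logistic -> Dense(1->1)
    logistic -> gamma = (o1, 1 - o1)

The classical-control branch replaces the quantum layer with a classical
block of exactly the same trainable-parameter count (5w for Dense2, w for
the bias-free bridge matching the w circuit angles, 2 for the output layer),
so quantum-vs-classical comparisons hold parameters fixed.

The final linear layer is followed by a logistic squash so that o1 is a
valid probability and the (o1, 1-o1) output head stays on the simplex;
cross-entropy is then well-defined for any weight values.

Everything is plain numpy; gradients for the classical layers are exact
backpropagation, the circuit angles get parameter-shift gradients and the
encoded inputs central finite differences, chained through the squash.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, asdict
from typing import Dict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .quantum import (EncodingSpec, input_grad, parameter_shift_grad,
                      pqc_forward)

VARIANTS = ("quantum", "classical-control")

_FORMAT_VERSION = 1
_KERNEL = 5


class ModelError(ValueError):
    """Bad model configuration, input shape, or checkpoint format."""


@dataclass
class ModelConfig:
    """Configuration of one CQ-CNN instance.

    ``omega`` is the number of qubits (2 or 3 in the reference experiments;
    any small count works).  ``image_side=128`` reproduces the reference
    layer shapes exactly.
    """

    image_side: int = 128
    omega: int = 2
    dropout_rate: float = 0.25
    dialect: str = "zz-interaction"
    feature_scaling: str = "tanh"
    observable: str = "parity"
    repetitions: int = 1
    seed: int = 0
    variant: str = "quantum"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ModelError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.omega < 1:
            raise ModelError(f"omega must be >= 1, got {self.omega}")
        self.encoding = EncodingSpec(n_qubits=self.omega, dialect=self.dialect,
                                     feature_scaling=self.feature_scaling)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("encoding", None)
        return d


def shape_chain(side: int) -> dict:
    """Intermediate feature-map shapes of the convolutional front-end."""
    c1 = side - (_KERNEL - 1)
    p1 = c1 // 2
    c2 = p1 - (_KERNEL - 1)
    p2 = c2 // 2
    if c1 < 1 or c2 < 1 or p2 < 1:
        raise ModelError(f"image_side={side} too small for the conv stack")
    return {
        "conv1": (2, c1, c1),
        "pool1": (2, p1, p1),
        "conv2": (4, c2, c2),
        "pool2": (4, p2, p2),
        "flatten": 4 * p2 * p2,
    }


@dataclass
class ParameterCount:
    per_layer: Dict[str, int]
    fixed_total: int
    omega_term: int
    pqc_term: int
    grand_total: int


def count_parameters(cfg: ModelConfig) -> ParameterCount:
    """Closed-form trainable-parameter accounting.

    conv: (kh*kw*in + 1)*out; dense: (in + 1)*out.  The qubit-dependent
    terms are omega_term = (4 x w) + w (Dense2) and pqc_term = w x
    repetitions (the circuit angles, or the bias-free classical bridge).
    """
    w = cfg.omega
    flat = shape_chain(cfg.image_side)["flatten"]
    per_layer = {
        "conv1": (_KERNEL * _KERNEL * 1 + 1) * 2,
        "conv2": (_KERNEL * _KERNEL * 2 + 1) * 4,
        "dense1": (flat + 1) * 4,
        "dense2": (4 + 1) * w,
        "pqc": w * cfg.repetitions,
        "output": (1 + 1) * 1,
    }
    fixed_total = per_layer["conv1"] + per_layer["conv2"] + per_layer["dense1"] + per_layer["output"]
    omega_term = (4 * w) + w
    pqc_term = w * cfg.repetitions
    return ParameterCount(per_layer=per_layer, fixed_total=fixed_total,
                          omega_term=omega_term, pqc_term=pqc_term,
                          grand_total=fixed_total + omega_term + pqc_term)


# ---------------------------------------------------------------------------
# layer primitives

def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (B,C,H,W), w: (F,C,k,k) -> (B,F,H-k+1,W-k+1); valid cross-correlation
    win = sliding_window_view(x, (w.shape[2], w.shape[3]), axis=(2, 3))
    return np.einsum("bchwij,fcij->bfhw", win, w, optimize=True) + b[None, :, None, None]


def _conv2d_backward(x, w, dout):
    win = sliding_window_view(x, (w.shape[2], w.shape[3]), axis=(2, 3))
    dw = np.einsum("bfhw,bchwij->fcij", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    k = w.shape[2]
    pad = k - 1
    dpad = np.pad(dout, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    wflip = w[:, :, ::-1, ::-1]
    dwin = sliding_window_view(dpad, (k, k), axis=(2, 3))
    dx = np.einsum("bfhwij,fcij->bchw", dwin, wflip, optimize=True)
    return dx, dw, db


def _maxpool2(x: np.ndarray):
    b, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, :, : h2 * 2, : w2 * 2]
    blocks = xc.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
    arg = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, arg[..., None], axis=-1)[..., 0]
    return out, (arg, x.shape)


def _maxpool2_backward(dout: np.ndarray, cache):
    arg, xshape = cache
    b, c, h, w = xshape
    h2, w2 = h // 2, w // 2
    dblocks = np.zeros((b, c, h2, w2, 4), dtype=dout.dtype)
    np.put_along_axis(dblocks, arg[..., None], dout[..., None], axis=-1)
    dx = np.zeros(xshape, dtype=dout.dtype)
    dx[:, :, : h2 * 2, : w2 * 2] = (
        dblocks.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 * 2, w2 * 2)
    )
    return dx


def _sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class CQCNNNetwork:
    """Trainable network instance: parameters, forward pass, gradients."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        self.shapes = shape_chain(cfg.image_side)
        self.flat = self.shapes["flatten"]
        rng = np.random.default_rng(cfg.seed)
        w = cfg.omega
        self.params: Dict[str, np.ndarray] = {}

        def uinit(shape, fan_in):
            bound = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-bound, bound, size=shape)

        self.params["conv1.W"] = uinit((2, 1, _KERNEL, _KERNEL), _KERNEL * _KERNEL * 1)
        self.params["conv1.b"] = uinit((2,), _KERNEL * _KERNEL * 1)
        self.params["conv2.W"] = uinit((4, 2, _KERNEL, _KERNEL), _KERNEL * _KERNEL * 2)
        self.params["conv2.b"] = uinit((4,), _KERNEL * _KERNEL * 2)
        self.params["dense1.W"] = uinit((self.flat, 4), self.flat)
        self.params["dense1.b"] = uinit((4,), self.flat)
        self.params["dense2.W"] = uinit((4, w), 4)
        self.params["dense2.b"] = uinit((w,), 4)
        if cfg.variant == "quantum":
            # circuit angles span one Ry half-period
            self.params["theta"] = rng.uniform(0.0, np.pi, size=(w * cfg.repetitions,))
        else:
            self.params["bridge.W"] = uinit((w, 1), w)
        # identity-like calibration init: the 1->1 output layer maps the
        # circuit probability q in [0,1] to a logit centred at q = 0.5, so
        # the decision threshold starts aligned instead of at a random
        # offset that the scalar path would need many steps to undo
        self.params["output.W"] = np.array([[4.0]])
        self.params["output.b"] = np.array([-2.0])

    # -- bookkeeping --------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def clone_params(self) -> Dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def _validate_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        side = self.cfg.image_side
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2] != side or x.shape[3] != side:
            raise ModelError(
                f"expected input of shape (B, 1, {side}, {side}), got {x.shape}"
            )
        return x

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Run the network; returns ``(gamma, cache)``.

        gamma is ``(B, 2)`` with rows ``(o1, 1-o1)`` on the simplex.  With
        ``training=True`` the Dropout2D mask is drawn from *rng*.
        """
        x = self._validate_input(x)
        p = self.params
        cache: Dict[str, np.ndarray] = {"x": x}

        a = _conv2d(x, p["conv1.W"], p["conv1.b"])
        cache["conv1"] = a
        r = np.maximum(a, 0.0)
        pool1, cache["pool1"] = _maxpool2(r)
        cache["relu1"] = a > 0

        a2c = _conv2d(pool1, p["conv2.W"], p["conv2.b"])
        cache["pool1_out"] = pool1
        cache["conv2"] = a2c
        r2 = np.maximum(a2c, 0.0)
        pool2, cache["pool2"] = _maxpool2(r2)
        cache["relu2"] = a2c > 0

        if training and self.cfg.dropout_rate > 0:
            if rng is None:
                rng = np.random.default_rng(self.cfg.seed)
            keep = (rng.random((pool2.shape[0], pool2.shape[1], 1, 1))
                    >= self.cfg.dropout_rate)
            mask = keep / (1.0 - self.cfg.dropout_rate)
        else:
            mask = np.ones((pool2.shape[0], pool2.shape[1], 1, 1))
        cache["drop_mask"] = mask
        dropped = pool2 * mask

        z0 = dropped.reshape(x.shape[0], -1)
        cache["z0"] = z0
        a1 = z0 @ p["dense1.W"] + p["dense1.b"]
        cache["a1"] = a1
        r1 = np.maximum(a1, 0.0)
        cache["r1"] = r1
        a2 = r1 @ p["dense2.W"] + p["dense2.b"]
        cache["a2"] = a2

        if self.cfg.variant == "quantum":
            angles = self.cfg.encoding.scale(a2)
            cache["angles"] = angles
            q = pqc_forward(angles, p["theta"], self.cfg.encoding,
                            observable=self.cfg.observable,
                            repetitions=self.cfg.repetitions)
        else:
            h = np.tanh(a2)
            cache["h"] = h
            u1 = (h @ p["bridge.W"])[:, 0]
            cache["u1"] = u1
            q = _sigmoid(u1)
        cache["q"] = q

        u = q * p["output.W"][0, 0] + p["output.b"][0]
        cache["u"] = u
        o1 = _sigmoid(u)
        cache["o1"] = o1
        gamma = np.stack([o1, 1.0 - o1], axis=1)
        return gamma, cache

    def backward(self, cache: Dict[str, np.ndarray], d_o1: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradients of a scalar loss w.r.t. every parameter, given dL/d o1."""
        p = self.params
        grads: Dict[str, np.ndarray] = {}
        o1 = cache["o1"]
        du = d_o1 * o1 * (1.0 - o1)
        q = cache["q"]
        grads["output.W"] = np.array([[np.sum(du * q)]])
        grads["output.b"] = np.array([np.sum(du)])
        dq = du * p["output.W"][0, 0]

        if self.cfg.variant == "quantum":
            angles = cache["angles"]
            ps = parameter_shift_grad(angles, p["theta"], self.cfg.encoding,
                                      observable=self.cfg.observable,
                                      repetitions=self.cfg.repetitions)
            grads["theta"] = (dq[:, None] * ps).sum(axis=0)
            ig = input_grad(angles, p["theta"], self.cfg.encoding,
                            observable=self.cfg.observable,
                            repetitions=self.cfg.repetitions)
            dangles = dq[:, None] * ig
            da2 = dangles * self.cfg.encoding.scale_grad(cache["a2"])
        else:
            qc = q
            du1 = dq * qc * (1.0 - qc)
            h = cache["h"]
            grads["bridge.W"] = (h * du1[:, None]).sum(axis=0)[:, None]
            dh = du1[:, None] * p["bridge.W"][:, 0][None, :]
            da2 = dh * (1.0 - h ** 2)

        r1 = cache["r1"]
        grads["dense2.W"] = r1.T @ da2
        grads["dense2.b"] = da2.sum(axis=0)
        dr1 = da2 @ p["dense2.W"].T
        da1 = dr1 * (cache["a1"] > 0)
        z0 = cache["z0"]
        grads["dense1.W"] = z0.T @ da1
        grads["dense1.b"] = da1.sum(axis=0)
        dz0 = da1 @ p["dense1.W"].T

        b = z0.shape[0]
        ddropped = dz0.reshape((b,) + self.shapes["pool2"])
        dpool2 = ddropped * cache["drop_mask"]
        dr2 = _maxpool2_backward(dpool2, cache["pool2"])
        dconv2 = dr2 * cache["relu2"]
        dpool1, grads["conv2.W"], grads["conv2.b"] = _conv2d_backward(
            cache["pool1_out"], p["conv2.W"], dconv2)
        dr = _maxpool2_backward(dpool1, cache["pool1"])
        dconv1 = dr * cache["relu1"]
        _, grads["conv1.W"], grads["conv1.b"] = _conv2d_backward(
            cache["x"], p["conv1.W"], dconv1)
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode class probabilities (gamma), batched."""
        x = self._validate_input(x)
        out = []
        for start in range(0, x.shape[0], batch_size):
            gamma, _ = self.forward(x[start:start + batch_size], training=False)
            out.append(gamma)
        return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpoint I/O

def storage_size_mb(n_params: int, precision_bits: int = 32) -> float:
    """Parameter storage footprint in MB at the given float precision."""
    return round(n_params * (precision_bits // 8) / 2 ** 20, 2)


def serialize(model: CQCNNNetwork, path) -> dict:
    """Write a single-file checkpoint; returns a small size report."""
    payload = {k: v for k, v in model.params.items()}
    header = {
        "format_version": _FORMAT_VERSION,
        "config": model.cfg.to_dict(),
    }
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("header.json", json.dumps(header))
        buf = io.BytesIO()
        np.savez(buf, **payload)
        zf.writestr("params.npz", buf.getvalue())
    counts = count_parameters(model.cfg)
    return {
        "n_parameters": model.n_parameters(),
        "fixed_parameters": counts.fixed_total,
        "size_mb": storage_size_mb(counts.fixed_total),
        "size_mb_total": storage_size_mb(model.n_parameters()),
    }


def deserialize(path) -> CQCNNNetwork:
    """Load a checkpoint written by :func:`serialize`."""
    try:
        with zipfile.ZipFile(path, "r") as zf:
            header = json.loads(zf.read("header.json"))
            with zf.open("params.npz") as fh:
                data = np.load(io.BytesIO(fh.read()))
                params = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError, OSError, ValueError) as exc:
        raise ModelError(f"unreadable checkpoint {path}: {exc}") from exc
    if header.get("format_version") != _FORMAT_VERSION:
        raise ModelError(
            f"checkpoint format version {header.get('format_version')} "
            f"not supported (expected {_FORMAT_VERSION})"
        )
    cfg = ModelConfig(**header["config"])
    model = CQCNNNetwork(cfg)
    expected = set(model.params)
    if set(params) != expected:
        raise ModelError(f"checkpoint parameter set {sorted(params)} does not "
                         f"match model {sorted(expected)}")
    for k in expected:
        if params[k].shape != model.params[k].shape:
            raise ModelError(f"shape mismatch for {k} in {path}")
        model.params[k] = params[k].astype(np.float64)
    return model


def build_model(cfg: ModelConfig) -> CQCNNNetwork:
    """Construct a network from a config (alias kept for API symmetry)."""
    return CQCNNNetwork(cfg)
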