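"""Exact statevector simulation of the model's parameterized quantum circuit.

The circuit is the ZZ-feature-map family: every qubit is put into
superposition with a Hadamard, a data-dependent phase ``P(2*x[i])`` is applied
per qubit, and pairwise entangling phases couple the qubits.  A single layer
of trainable ``Ry(theta_i)`` rotations (the ansatz) follows, and the register
is measured in the computational basis.  The scalar read-out is

    o1 = (1 - <M>) / 2,      <M> = sum_i l_i p_i,

with ``l_i = (-1)^popcount(i)`` the all-qubit Pauli-Z parity eigenvalue, so
``o1`` always lands in [0, 1].

Conventions (fixed so amplitudes are bit-exact against a dense-matrix
product): qubit 0 is the least-significant bit of the basis index, and
``Ry(theta) = [[cos(t/2), -sin(t/2)], [sin(t/2), cos(t/2)]]``.

All gate helpers accept amplitude arrays with an optional leading batch
dimension ``(..., 2**N)``; gradients use the parameter-shift rule for theta
and central finite differences for the encoded angles.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

DIALECTS = ("eq3-cz", "zz-interaction")
OBSERVABLES = ("parity", "first-qubit")


class CircuitError(ValueError):
    """Inconsistent qubit index, register size or parameter length."""


@dataclass
class QubitState:
    """Normalized complex amplitude vector of an N-qubit register."""

    amplitudes: np.ndarray
    n_qubits: int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.complex128)
        if self.amplitudes.shape[-1] != 2 ** self.n_qubits:
            raise CircuitError(
                f"amplitude vector of length {self.amplitudes.shape[-1]} does "
                f"not match {self.n_qubits} qubits (need {2 ** self.n_qubits})"
            )
        norm = np.abs(self.amplitudes) ** 2
        if abs(norm.sum(axis=-1) - 1.0).max() > 1e-8:
            raise CircuitError("state is not normalized")


def ground_state(n_qubits: int, batch: int | None = None) -> np.ndarray:
    """|0...0> amplitudes, optionally replicated along a batch axis."""
    shape = (2 ** n_qubits,) if batch is None else (batch, 2 ** n_qubits)
    amps = np.zeros(shape, dtype=np.complex128)
    amps[..., 0] = 1.0
    return amps


def _n_qubits(amps: np.ndarray) -> int:
    n = int(np.log2(amps.shape[-1]))
    if 2 ** n != amps.shape[-1]:
        raise CircuitError(f"amplitude length {amps.shape[-1]} is not a power of 2")
    return n


def _check_qubit(amps: np.ndarray, q: int) -> int:
    n = _n_qubits(amps)
    if not 0 <= q < n:
        raise CircuitError(f"qubit index {q} out of range for {n} qubits")
    return n


def _apply_1q(amps: np.ndarray, q: int, mat: np.ndarray) -> np.ndarray:
    """Apply a 2x2 matrix to qubit *q* (LSB = qubit 0) of ``(..., 2^N)`` amps."""
    n = _check_qubit(amps, q)
    lead = amps.shape[:-1]
    a = amps.reshape(lead + (2 ** (n - q - 1), 2, 2 ** q))
    a = np.einsum("ij,...jk->...ik", mat, a)
    return a.reshape(lead + (2 ** n,))


def apply_h(amps: np.ndarray, q: int) -> np.ndarray:
    h = np.array([[1, 1], [1, -1]], dtype=np.complex128) / np.sqrt(2.0)
    return _apply_1q(amps, q, h)


def apply_h_all(amps: np.ndarray) -> np.ndarray:
    out = amps
    for q in range(_n_qubits(amps)):
        out = apply_h(out, q)
    return out


def apply_phase(amps: np.ndarray, q: int, phi: float) -> np.ndarray:
    """P(phi) = diag(1, e^{i phi}) on qubit q."""
    n = _check_qubit(amps, q)
    idx = np.arange(2 ** n)
    phase = np.where((idx >> q) & 1, np.exp(1j * phi), 1.0)
    return amps * phase


def apply_cz(amps: np.ndarray, i: int, j: int) -> np.ndarray:
    """Controlled-Z: flip the sign of every basis state with bits i and j set."""
    n = _check_qubit(amps, i)
    _check_qubit(amps, j)
    if i == j:
        raise CircuitError(f"CZ needs two distinct qubits, got ({i}, {j})")
    idx = np.arange(2 ** n)
    both = ((idx >> i) & 1) & ((idx >> j) & 1)
    return amps * np.where(both, -1.0, 1.0)


def apply_cphase(amps: np.ndarray, i: int, j: int, phi) -> np.ndarray:
    """Controlled phase: multiply the |1_i 1_j> components by e^{i phi}.

    *phi* may be a scalar or an array broadcastable against the batch axes.
    """
    n = _check_qubit(amps, i)
    _check_qubit(amps, j)
    if i == j:
        raise CircuitError(f"controlled phase needs distinct qubits, got ({i}, {j})")
    idx = np.arange(2 ** n)
    both = (((idx >> i) & 1) & ((idx >> j) & 1)).astype(bool)
    phi = np.asarray(phi, dtype=np.float64)[..., None]
    factor = np.where(both, np.exp(1j * phi), 1.0)
    return amps * factor


def apply_ry(amps: np.ndarray, q: int, theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2.0), np.sin(theta / 2.0)
    mat = np.array([[c, -s], [s, c]], dtype=np.complex128)
    return _apply_1q(amps, q, mat)


@dataclass
class EncodingSpec:
    """Data-encoding configuration of the feature map.

    ``dialect`` selects the entangling block: ``eq3-cz`` applies plain CZ
    gates after the per-qubit data phases; ``zz-interaction`` (default)
    applies a pairwise phase of ``2*(pi - x_i)*(pi - x_j)`` on the |11>
    component of every pair, the standard ZZ interaction term.

    ``feature_scaling`` maps raw features into phase angles before encoding;
    the default squash ``x -> pi * tanh(x)`` keeps angles in (-pi, pi) and
    avoids phase aliasing.  Set to ``"identity"`` to pass features through.
    """

    n_qubits: int
    dialect: str = "zz-interaction"
    feature_scaling: str = "tanh"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise CircuitError(f"unknown dialect {self.dialect!r}; choose from {DIALECTS}")
        if self.feature_scaling not in ("tanh", "identity"):
            raise CircuitError(f"unknown feature_scaling {self.feature_scaling!r}")

    def scale(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if self.feature_scaling == "tanh":
            return np.pi * np.tanh(x)
        return x

    def scale_grad(self, x: np.ndarray) -> np.ndarray:
        """d scale / dx, used to chain gradients into the classical layers."""
        x = np.asarray(x, dtype=np.float64)
        if self.feature_scaling == "tanh":
            return np.pi * (1.0 - np.tanh(x) ** 2)
        return np.ones_like(x)


@dataclass
class AnsatzSpec:
    """Trainable single-qubit Ry layer(s): len(theta) = n_qubits * repetitions."""

    theta: np.ndarray
    repetitions: int = 1

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=np.float64).ravel()


@dataclass
class MeasurementResult:
    probabilities: np.ndarray
    eigenvalues: np.ndarray
    expectation: float
    o1: float


def encode(x: np.ndarray, spec: EncodingSpec) -> np.ndarray:
    """Encode pre-scaled angles *x* into an entangled state.

    *x* has shape ``(N,)`` or ``(batch, N)``; features are assumed to already
    be on the angle scale (apply ``spec.scale`` first for raw features).
    Returns amplitudes of shape ``(..., 2^N)``.
    """
    x = np.asarray(x, dtype=np.float64)
    n = spec.n_qubits
    if x.shape[-1] != n:
        raise CircuitError(
            f"feature vector length {x.shape[-1]} does not match {n} qubits"
        )
    batch = None if x.ndim == 1 else x.shape[0]
    amps = apply_h_all(ground_state(n, batch))
    for q in range(n):
        # batched per-qubit data phase
        idx = np.arange(2 ** n)
        bit = ((idx >> q) & 1).astype(bool)
        phi = 2.0 * x[..., q, None]
        amps = amps * np.where(bit, np.exp(1j * phi), 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            if spec.dialect == "eq3-cz":
                amps = apply_cz(amps, i, j)
            else:
                phi = 2.0 * (np.pi - x[..., i]) * (np.pi - x[..., j])
                amps = apply_cphase(amps, i, j, phi)
    return amps


def apply_ansatz(amps: np.ndarray, spec: AnsatzSpec) -> np.ndarray:
    n = _n_qubits(amps)
    if spec.theta.size != n * spec.repetitions:
        raise CircuitError(
            f"ansatz has {spec.theta.size} parameters but needs "
            f"{n} x {spec.repetitions} = {n * spec.repetitions}"
        )
    out = amps
    for r in range(spec.repetitions):
        for q in range(n):
            out = apply_ry(out, q, spec.theta[r * n + q])
    return out


def parity_eigenvalues(n_qubits: int) -> np.ndarray:
    """All-qubit Pauli-Z eigenvalues l_i = (-1)^popcount(i)."""
    idx = np.arange(2 ** n_qubits)
    pop = np.array([bin(i).count("1") for i in idx])
    return (-1.0) ** pop


def measure(amps: np.ndarray, observable: str = "parity",
            shots: int | None = None, rng: np.random.Generator | None = None):
    """Computational-basis measurement of ``(..., 2^N)`` amplitudes.

    Exact by default (probabilities are the squared magnitudes); with
    *shots* set, probabilities are empirical frequencies drawn from the
    exact distribution using *rng*.  Returns a :class:`MeasurementResult`
    for a single state, or arrays of expectations/o1 for a batch.
    """
    n = _n_qubits(amps)
    probs = np.abs(amps) ** 2
    if shots is not None:
        if rng is None:
            rng = np.random.default_rng()
        if probs.ndim != 1:
            raise CircuitError("shot sampling supports single states only")
        counts = rng.multinomial(shots, probs / probs.sum())
        probs = counts / shots
    if observable == "parity":
        eig = parity_eigenvalues(n)
    elif observable == "first-qubit":
        idx = np.arange(2 ** n)
        eig = np.where(idx & 1, -1.0, 1.0)
    else:
        raise CircuitError(f"unknown observable {observable!r}; choose from {OBSERVABLES}")
    expectation = (probs * eig).sum(axis=-1)
    o1 = (1.0 - expectation) / 2.0
    if probs.ndim == 1:
        return MeasurementResult(probabilities=probs, eigenvalues=eig,
                                 expectation=float(expectation), o1=float(o1))
    return expectation, o1


def pqc_forward(x: np.ndarray, theta: np.ndarray, spec: EncodingSpec,
                observable: str = "parity", repetitions: int = 1) -> np.ndarray:
    """Full circuit: encode -> ansatz -> measure; returns o1.

    *x* holds pre-scaled angles with shape ``(N,)`` or ``(batch, N)``; the
    return is a float (or a ``(batch,)`` array).  Deterministic (exact
    expectation, no shot noise).
    """
    amps = encode(x, spec)
    amps = apply_ansatz(amps, AnsatzSpec(theta=theta, repetitions=repetitions))
    if amps.ndim == 1:
        return measure(amps, observable=observable).o1
    return measure(amps, observable=observable)[1]


def parameter_shift_grad(x: np.ndarray, theta: np.ndarray, spec: EncodingSpec,
                         observable: str = "parity", repetitions: int = 1) -> np.ndarray:
    """Exact gradient d o1 / d theta via the parameter-shift rule.

    Component i is ``[o1(theta_i + pi/2) - o1(theta_i - pi/2)] / 2``, exact
    for Ry rotations.  Shapes follow :func:`pqc_forward`: ``(len(theta),)``
    for a single x, ``(batch, len(theta))`` for batched x.
    """
    theta = np.asarray(theta, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    grads = []
    for i in range(theta.size):
        shift = np.zeros_like(theta)
        shift[i] = np.pi / 2.0
        plus = pqc_forward(x, theta + shift, spec, observable, repetitions)
        minus = pqc_forward(x, theta - shift, spec, observable, repetitions)
        grads.append((plus - minus) / 2.0)
    g = np.stack(grads, axis=-1)
    return g if not single else np.asarray(g)


def input_grad(x: np.ndarray, theta: np.ndarray, spec: EncodingSpec,
               observable: str = "parity", repetitions: int = 1,
               h: float = 1e-4) -> np.ndarray:
    """d o1 / d x by central finite differences on the encoded angles."""
    x = np.asarray(x, dtype=np.float64)
    grads = []
    for k in range(x.shape[-1]):
        step = np.zeros_like(x)
        step[..., k] = h
        plus = pqc_forward(x + step, theta, spec, observable, repetitions)
        minus = pqc_forward(x - step, theta, spec, observable, repetitions)
        grads.append((plus - minus) / (2.0 * h))
    return np.stack(grads, axis=-1)
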