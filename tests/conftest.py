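"""Shared fixtures and the dense-matrix circuit oracle.

The oracle builds the full 2^N x 2^N unitary of the feature-map + ansatz
circuit by explicit Kronecker products and matrix multiplication — an
independent path against which the tensor-contraction simulator is checked.
"""

import numpy as np
import pytest

from cqcnn.synthetic import ClassPairRecipe, make_class_pair


# ---------------------------------------------------------------------------
# dense-matrix oracle (qubit 0 = least-significant bit of the basis index)

H1 = np.array([[1, 1], [1, -1]], dtype=complex) / np.sqrt(2)


def op_on_qubit(u: np.ndarray, q: int, n: int) -> np.ndarray:
    """Embed a single-qubit operator at qubit q (LSB ordering)."""
    out = np.eye(1, dtype=complex)
    for k in range(n - 1, -1, -1):
        out = np.kron(out, u if k == q else np.eye(2, dtype=complex))
    return out


def phase_mat(phi: float) -> np.ndarray:
    return np.diag([1.0, np.exp(1j * phi)])


def ry_mat(theta: float) -> np.ndarray:
    c, s = np.cos(theta / 2), np.sin(theta / 2)
    return np.array([[c, -s], [s, c]], dtype=complex)


def diag_pair_phase(i: int, j: int, phi: float, n: int) -> np.ndarray:
    """Diagonal operator applying e^{i phi} where bits i and j are both set."""
    idx = np.arange(2 ** n)
    both = ((idx >> i) & 1) & ((idx >> j) & 1)
    return np.diag(np.where(both, np.exp(1j * phi), 1.0))


def dense_circuit_state(x: np.ndarray, theta: np.ndarray, n: int,
                        dialect: str) -> np.ndarray:
    """Amplitudes of ansatz(encode(x)) by dense matrix products."""
    u = np.eye(2 ** n, dtype=complex)
    for q in range(n):
        u = op_on_qubit(H1, q, n) @ u
    for q in range(n):
        u = op_on_qubit(phase_mat(2.0 * x[q]), q, n) @ u
    for i in range(n):
        for j in range(i + 1, n):
            if dialect == "eq3-cz":
                u = diag_pair_phase(i, j, np.pi, n) @ u
            else:
                phi = 2.0 * (np.pi - x[i]) * (np.pi - x[j])
                u = diag_pair_phase(i, j, phi, n) @ u
    for q in range(n):
        u = op_on_qubit(ry_mat(theta[q]), q, n) @ u
    e0 = np.zeros(2 ** n, dtype=complex)
    e0[0] = 1.0
    return u @ e0


def dense_o1(x, theta, n, dialect):
    amps = dense_circuit_state(np.asarray(x, float), np.asarray(theta, float),
                               n, dialect)
    probs = np.abs(amps) ** 2
    pop = np.array([bin(i).count("1") for i in range(2 ** n)])
    return (1.0 - (probs * (-1.0) ** pop).sum()) / 2.0


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_pair():
    """Small separable two-class set at side 32 for fast training tests."""
    return make_class_pair(ClassPairRecipe(n_per_class=30, side=32,
                                           delta=8.0, seed=7))
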