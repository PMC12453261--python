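"""Statevector-simulator correctness against closed forms and a dense oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cqcnn.quantum import (AnsatzSpec, CircuitError, EncodingSpec, apply_ansatz,
                           apply_cz, apply_h_all, apply_phase, apply_ry, encode,
                           ground_state, input_grad, measure,
                           parameter_shift_grad, parity_eigenvalues,
                           pqc_forward)

from conftest import dense_circuit_state, dense_o1


class TestGates:
    def test_hadamard_on_ground_state(self):
        amps = apply_h_all(ground_state(1))
        assert np.allclose(amps, [1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_identity_ry_leaves_state(self):
        amps = apply_ry(ground_state(1), 0, 0.0)
        assert np.allclose(amps, [1, 0])

    def test_ry_pi_flips_ground_state(self):
        amps = apply_ry(ground_state(1), 0, np.pi)
        assert np.allclose(amps, [0, 1])

    def test_cz_phases_only_the_11_component(self):
        amps = np.zeros(4, dtype=complex)
        amps[3] = 1.0  # |11>
        out = apply_cz(amps, 0, 1)
        assert np.allclose(out, [0, 0, 0, -1])
        # other basis states untouched
        for b in range(3):
            e = np.zeros(4, dtype=complex)
            e[b] = 1.0
            assert np.allclose(apply_cz(e, 0, 1), e)

    def test_cz_symmetric_in_qubits(self, rng):
        amps = rng.normal(size=8) + 1j * rng.normal(size=8)
        amps /= np.linalg.norm(amps)
        assert np.allclose(apply_cz(amps, 0, 2), apply_cz(amps, 2, 0))

    def test_index_out_of_range_raises(self):
        with pytest.raises(CircuitError):
            apply_phase(ground_state(2), 2, 0.1)
        with pytest.raises(CircuitError):
            apply_cz(ground_state(2), 0, 0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(1, 4), st.integers(0, 10 ** 6))
    def test_gates_preserve_norm(self, n, seed):
        rng = np.random.default_rng(seed)
        amps = rng.normal(size=2 ** n) + 1j * rng.normal(size=2 ** n)
        amps /= np.linalg.norm(amps)
        amps = apply_h_all(amps)
        for q in range(n):
            amps = apply_phase(amps, q, rng.uniform(-np.pi, np.pi))
            amps = apply_ry(amps, q, rng.uniform(-np.pi, np.pi))
        if n > 1:
            amps = apply_cz(amps, 0, n - 1)
        assert abs((np.abs(amps) ** 2).sum() - 1.0) < 1e-10


class TestEncoding:
    def test_zero_features_eq3cz_gives_uniform_probabilities(self):
        spec = EncodingSpec(n_qubits=2, dialect="eq3-cz", feature_scaling="identity")
        amps = encode(np.zeros(2), spec)
        assert np.allclose(np.abs(amps) ** 2, 0.25)

    @pytest.mark.parametrize("dialect", ["eq3-cz", "zz-interaction"])
    def test_single_qubit_probabilities_are_half(self, dialect):
        # with one qubit there is no entangler; phases never move magnitudes
        spec = EncodingSpec(n_qubits=1, dialect=dialect, feature_scaling="identity")
        amps = encode(np.array([0.83]), spec)
        assert np.allclose(np.abs(amps) ** 2, 0.5)

    @pytest.mark.parametrize("dialect", ["eq3-cz", "zz-interaction"])
    def test_encode_matches_dense_matrix_oracle(self, dialect, rng):
        spec = EncodingSpec(n_qubits=2, dialect=dialect, feature_scaling="identity")
        x = np.array([np.pi / 2, np.pi / 3])
        amps = apply_ansatz(encode(x, spec), AnsatzSpec(theta=np.zeros(2)))
        ref = dense_circuit_state(x, np.zeros(2), 2, dialect)
        assert np.abs(amps - ref).max() < 1e-12

    def test_feature_length_mismatch_raises(self):
        spec = EncodingSpec(n_qubits=3)
        with pytest.raises(CircuitError):
            encode(np.zeros(2), spec)

    def test_tanh_scaling_bounds_angles(self):
        spec = EncodingSpec(n_qubits=2)
        scaled = spec.scale(np.array([100.0, -100.0]))
        assert np.all(np.abs(scaled) <= np.pi)


class TestFullCircuitOracle:
    @pytest.mark.parametrize("n,dialect", [
        (n, d) for n in (1, 2, 3, 4) for d in ("eq3-cz", "zz-interaction")
    ])
    def test_statevector_equals_dense_unitary_product(self, n, dialect):
        rng = np.random.default_rng(1000 + n)
        spec = EncodingSpec(n_qubits=n, dialect=dialect, feature_scaling="identity")
        worst = 0.0
        for _ in range(15):
            x = rng.uniform(-np.pi, np.pi, size=n)
            theta = rng.uniform(-np.pi, np.pi, size=n)
            amps = apply_ansatz(encode(x, spec), AnsatzSpec(theta=theta))
            ref = dense_circuit_state(x, theta, n, dialect)
            worst = max(worst, np.abs(amps - ref).max())
        assert worst < 1e-10

    def test_ansatz_with_zero_angles_is_identity(self, rng):
        amps = rng.normal(size=8) + 1j * rng.normal(size=8)
        amps /= np.linalg.norm(amps)
        assert np.allclose(apply_ansatz(amps, AnsatzSpec(theta=np.zeros(3))), amps)

    def test_ansatz_parameter_length_mismatch_raises(self):
        with pytest.raises(CircuitError):
            apply_ansatz(ground_state(2), AnsatzSpec(theta=np.zeros(3)))


class TestMeasurement:
    def test_ground_state_has_unit_parity(self):
        res = measure(ground_state(3))
        assert res.expectation == pytest.approx(1.0)
        assert res.o1 == pytest.approx(0.0)

    def test_equal_superposition_single_qubit(self):
        res = measure(apply_h_all(ground_state(1)))
        assert np.allclose(res.probabilities, [0.5, 0.5])
        assert res.expectation == pytest.approx(0.0, abs=1e-12)
        assert res.o1 == pytest.approx(0.5)

    @pytest.mark.parametrize("theta", [0.3, 1.2, 2.9])
    def test_ry_expectation_closed_form(self, theta):
        # <Z> of Ry(theta)|0> is cos(theta)
        res = measure(apply_ry(ground_state(1), 0, theta))
        assert res.expectation == pytest.approx(np.cos(theta), abs=1e-12)

    def test_parity_eigenvalues_are_popcount_signs(self):
        assert list(parity_eigenvalues(2)) == [1, -1, -1, 1]

    def test_probabilities_form_a_simplex(self, rng):
        for n in (1, 2, 3):
            amps = rng.normal(size=2 ** n) + 1j * rng.normal(size=2 ** n)
            amps /= np.linalg.norm(amps)
            res = measure(amps)
            assert np.all(res.probabilities >= 0)
            assert res.probabilities.sum() == pytest.approx(1.0, abs=1e-10)
            assert abs(res.expectation) <= 1 + 1e-12
            assert 0 - 1e-12 <= res.o1 <= 1 + 1e-12

    def test_shot_sampling_converges_to_exact_probabilities(self):
        shots = 10 ** 5
        amps = apply_ry(apply_h_all(ground_state(2)), 0, 0.7)
        exact = measure(amps).probabilities
        emp = measure(amps, shots=shots,
                      rng=np.random.default_rng(11)).probabilities
        sigma = np.sqrt(exact * (1 - exact) / shots)
        assert np.all(np.abs(emp - exact) <= 3 * sigma + 1e-12)

    def test_first_qubit_observable_is_marginal(self):
        amps = apply_ry(ground_state(2), 0, 1.1)
        res = measure(amps, observable="first-qubit")
        # o1 = P(qubit0 = 1) = sin^2(theta/2)
        assert res.o1 == pytest.approx(np.sin(1.1 / 2) ** 2, abs=1e-12)


class TestGradients:
    def test_forward_is_deterministic(self):
        spec = EncodingSpec(n_qubits=2)
        x, th = np.array([0.2, -0.4]), np.array([1.0, 0.3])
        assert pqc_forward(x, th, spec) == pqc_forward(x, th, spec)

    @pytest.mark.parametrize("n", [2, 3])
    def test_parameter_shift_equals_finite_difference(self, n):
        spec = EncodingSpec(n_qubits=n, feature_scaling="identity")
        rng = np.random.default_rng(42 + n)
        h = 1e-5
        for _ in range(25):
            x = rng.uniform(-np.pi, np.pi, size=n)
            th = rng.uniform(-np.pi, np.pi, size=n)
            ps = parameter_shift_grad(x, th, spec)
            fd = np.empty(n)
            for i in range(n):
                e = np.zeros(n)
                e[i] = h
                fd[i] = (pqc_forward(x, th + e, spec)
                         - pqc_forward(x, th - e, spec)) / (2 * h)
            assert np.abs(ps - fd).max() < 1e-6

    def test_parameter_shift_matches_dense_oracle_value(self):
        spec = EncodingSpec(n_qubits=2, feature_scaling="identity")
        x, th = np.array([0.5, -0.3]), np.array([0.9, 1.7])
        o1 = pqc_forward(x, th, spec)
        assert o1 == pytest.approx(dense_o1(x, th, 2, "zz-interaction"), abs=1e-12)

    def test_gradient_periodic_in_2pi(self):
        spec = EncodingSpec(n_qubits=2, feature_scaling="identity")
        x, th = np.array([0.1, 0.2]), np.array([0.6, -1.1])
        g1 = parameter_shift_grad(x, th, spec)
        g2 = parameter_shift_grad(x, th + 2 * np.pi, spec)
        assert np.allclose(g1, g2, atol=1e-10)

    def test_stationary_at_theta_zero_without_encoding(self):
        # d<Z>/dtheta = -sin(theta) = 0 at theta = 0 for the bare Ry circuit
        amps = apply_ry(ground_state(1), 0, np.pi / 2 + 0.0)
        # parameter-shift on the o1 of Ry(theta)|0>: o1 = sin^2(theta/2)
        def o1(t):
            return measure(apply_ry(ground_state(1), 0, t)).o1
        g = (o1(np.pi / 2) - o1(-np.pi / 2)) / 2
        assert g == pytest.approx(np.sin(0.0) / 2, abs=1e-12)

    def test_input_grad_matches_richardson_extrapolation(self):
        spec = EncodingSpec(n_qubits=2, feature_scaling="identity")
        x, th = np.array([0.4, 1.1]), np.array([0.2, -0.8])
        g = input_grad(x, th, spec)
        assert g.shape == (2,)
        for k in range(2):
            e = np.zeros(2)
            def d(h):
                e_k = e.copy()
                e_k[k] = h
                return (pqc_forward(x + e_k, th, spec)
                        - pqc_forward(x - e_k, th, spec)) / (2 * h)
            rich = (4 * d(5e-4) - d(1e-3)) / 3.0
            assert g[k] == pytest.approx(rich, abs=1e-5)

    def test_batched_forward_matches_per_sample(self, rng):
        spec = EncodingSpec(n_qubits=3, feature_scaling="identity")
        xb = rng.uniform(-1, 1, size=(5, 3))
        th = rng.uniform(-np.pi, np.pi, size=3)
        batched = pqc_forward(xb, th, spec)
        singles = np.array([pqc_forward(x, th, spec) for x in xb])
        assert np.allclose(batched, singles, atol=1e-12)
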