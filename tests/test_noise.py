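"""Kraus channels, density-matrix simulation and its independent oracles."""

import numpy as np
import pytest

from quanvnet.noise import (
    DensityMatrix,
    NoiseModel,
    apply_channel,
    channel_coefficients,
    noisy_run,
)
from quanvnet.reservoir import (
    GateSpec,
    ReservoirCircuit,
    apply_circuit,
    measure_probabilities,
    sample_g3_circuit,
)

X = np.array([[0, 1], [1, 0]], dtype=complex)
Y = np.array([[0, -1j], [1j, 0]])
Z = np.diag([1.0, -1.0]).astype(complex)


def kraus_operators(model: NoiseModel):
    """Independent operator-sum representation of each channel."""
    p = model.p
    if model.kind == "depolarizing":
        g = p / 4.0
        return [np.sqrt(1 - 3 * g) * np.eye(2), np.sqrt(g) * X,
                np.sqrt(g) * Y, np.sqrt(g) * Z]
    if model.kind == "amplitude_damping":
        return [np.diag([1, np.sqrt(1 - p)]),
                np.sqrt(p) * np.array([[0, 1], [0, 0]], dtype=complex)]
    return [np.diag([1, np.sqrt(1 - p)]), np.diag([0, np.sqrt(p)])]


def embed(op: np.ndarray, qubit: int, q: int) -> np.ndarray:
    mats = [np.eye(2, dtype=complex)] * q
    mats[qubit] = op
    full = mats[0]
    for m in mats[1:]:
        full = np.kron(full, m)
    return full


def kraus_apply(rho, model, qubit, q):
    out = np.zeros_like(rho)
    for K in kraus_operators(model):
        Kf = embed(K, qubit, q)
        out += Kf @ rho @ Kf.conj().T
    return out


class TestApplyChannel:
    @pytest.mark.parametrize("kind", ["depolarizing", "amplitude_damping",
                                      "phase_damping"])
    def test_p_zero_identity(self, kind, random_state):
        psi = random_state(2, seed=1)
        rho = np.outer(psi, psi.conj())
        out = apply_channel(rho, NoiseModel(kind, 0.0), 0)
        np.testing.assert_allclose(out, rho, atol=1e-14)

    def test_full_depolarizing_maximally_mixes(self, random_state):
        # an error event with probability 1 leaves the qubit fully mixed
        psi = random_state(1, seed=2)
        rho = np.outer(psi, psi.conj())
        out = apply_channel(rho, NoiseModel("depolarizing", 1.0), 0)
        np.testing.assert_allclose(out, np.eye(2) / 2, atol=1e-12)

    def test_amplitude_damping_closed_form(self):
        rho = np.diag([0.0, 1.0]).astype(complex)
        out = apply_channel(rho, NoiseModel("amplitude_damping", 0.3), 0)
        np.testing.assert_allclose(out, np.diag([0.3, 0.7]), atol=1e-14)

    @pytest.mark.parametrize("kind,p", [
        ("depolarizing", 0.05), ("amplitude_damping", 0.2),
        ("phase_damping", 0.4),
    ])
    def test_matches_kraus_oracle(self, kind, p, random_state):
        q = 3
        psi = random_state(q, seed=7)
        rho = np.outer(psi, psi.conj())
        model = NoiseModel(kind, p)
        for qubit in range(q):
            ours = apply_channel(rho, model, qubit)
            oracle = kraus_apply(rho, model, qubit, q)
            np.testing.assert_allclose(ours, oracle, atol=1e-12)

    @pytest.mark.parametrize("kind,p", [
        ("depolarizing", 0.1), ("amplitude_damping", 0.5),
        ("phase_damping", 0.9),
    ])
    def test_cptp_output(self, kind, p, random_state):
        psi = random_state(3, seed=3)
        rho = np.outer(psi, psi.conj())
        out = apply_channel(rho, NoiseModel(kind, p), 1)
        DensityMatrix(out).validate()

    def test_coefficient_consistency(self, random_state):
        # closed-form block coefficients reproduce the Kraus action
        psi = random_state(1, seed=4)
        rho = np.outer(psi, psi.conj())
        for kind, p in [("depolarizing", 0.08), ("amplitude_damping", 0.15),
                        ("phase_damping", 0.25)]:
            model = NoiseModel(kind, p)
            caa, cad, cda, cdd, co = channel_coefficients(model)
            expected = np.array(
                [[caa * rho[0, 0] + cad * rho[1, 1], co * rho[0, 1]],
                 [co * rho[1, 0], cda * rho[0, 0] + cdd * rho[1, 1]]])
            np.testing.assert_allclose(kraus_apply(rho, model, 0, 1), expected,
                                       atol=1e-12)

    def test_bad_qubit_index(self):
        with pytest.raises(ValueError):
            apply_channel(np.eye(4) / 4, NoiseModel("depolarizing", 0.1), 5)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            NoiseModel("depolarizing", 1.2)
        with pytest.raises(ValueError):
            NoiseModel("bit_flip", 0.1)


class TestNoisyRun:
    def test_p_zero_reduces_to_noiseless(self, random_state):
        circ = sample_g3_circuit(4, 40, seed=2)
        psi = random_state(4, seed=2)
        noiseless = measure_probabilities(apply_circuit(psi, circ))
        for engine in ("numpy", "numba"):
            out = noisy_run(circ, psi, NoiseModel("depolarizing", 0.0),
                            engine=engine)
            np.testing.assert_allclose(out, noiseless, atol=1e-10)

    @pytest.mark.parametrize("kind", ["depolarizing", "amplitude_damping",
                                      "phase_damping"])
    def test_valid_distribution(self, kind, random_state):
        circ = sample_g3_circuit(3, 30, seed=5)
        psi = random_state(3, seed=6)
        out = noisy_run(circ, psi, NoiseModel(kind, 0.05))
        assert (out >= 0).all()
        assert abs(out.sum() - 1.0) < 1e-12

    @pytest.mark.parametrize("kind,p", [
        ("depolarizing", 0.02), ("amplitude_damping", 0.03),
        ("phase_damping", 0.05),
    ])
    def test_engines_agree(self, kind, p, random_state):
        circ = sample_g3_circuit(4, 60, seed=8)
        psi = random_state(4, seed=9)
        model = NoiseModel(kind, p)
        a = noisy_run(circ, psi, model, engine="numpy")
        b = noisy_run(circ, psi, model, engine="numba")
        c = noisy_run(circ, psi, model, engine="numba", dtype=np.complex64)
        np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_allclose(a, c, atol=1e-6)

    def test_exact_dm_on_known_circuit(self):
        # H then phase damping on one qubit: rho = (|0>+|1>)/sqrt2 dephased
        circ = ReservoirCircuit((GateSpec("H", (0,)),), 1)
        out = noisy_run(circ, np.array([1.0, 0.0], dtype=complex),
                        NoiseModel("phase_damping", 0.36))
        np.testing.assert_allclose(out, [0.5, 0.5], atol=1e-12)

    def test_unnormalized_initial_rejected(self):
        circ = sample_g3_circuit(2, 5, seed=0)
        with pytest.raises(ValueError):
            noisy_run(circ, np.array([1.0, 1.0, 0, 0], dtype=complex),
                      NoiseModel("depolarizing", 0.01))

    def test_amplitude_loss_monotone_in_p(self, random_state):
        # stronger depolarizing pulls the output closer to uniform
        circ = sample_g3_circuit(5, 100, seed=3)
        psi = random_state(5, seed=1)
        clean = measure_probabilities(apply_circuit(psi, circ))
        dists = []
        for p in (0.001, 0.01, 0.03):
            noisy = noisy_run(circ, psi, NoiseModel("depolarizing", p))
            dists.append(np.linalg.norm(noisy - clean))
        assert dists[0] < dists[1] < dists[2]


def trajectory_oracle(circuit, psi0, p, n_traj, seed):
    """Monte-Carlo Kraus unravelling of per-gate depolarizing noise.

    Complete depolarization at parameter p unravels to applying X, Y or Z
    each with probability p/4 on the acted qubit (identity with 1 - 3p/4):
    the identity branch of the "error event with probability p" picks up
    weight p/4.
    """
    from quanvnet.reservoir import _apply_gate_tensor

    q = circuit.n_qubits
    dim = 1 << q
    rng = np.random.default_rng(seed)
    states = np.tile(psi0, (n_traj, 1)).reshape((n_traj,) + (2,) * q)
    for gate in circuit.gates:
        # batched gate application: the trajectory axis leads, so shifting
        # the qubit indices by one reuses the state-vector kernel
        shifted = GateSpec(gate.kind, tuple(qb + 1 for qb in gate.qubits))
        _apply_gate_tensor(states, shifted, q + 1)
        for qb in gate.qubits:
            kinds = np.where(rng.random(n_traj) < 0.75 * p,
                             rng.integers(1, 4, size=n_traj), 0)
            axis = qb + 1
            i0 = (slice(None),) * axis + (0,)
            i1 = (slice(None),) * axis + (1,)
            for code in (1, 2, 3):
                idx = np.flatnonzero(kinds == code)
                if len(idx) == 0:
                    continue
                sub = states[idx]
                if code == 1:  # X
                    tmp = sub[i0].copy()
                    sub[i0] = sub[i1]
                    sub[i1] = tmp
                elif code == 2:  # Y
                    tmp = sub[i0].copy()
                    sub[i0] = -1j * sub[i1]
                    sub[i1] = 1j * tmp
                else:  # Z
                    sub[i1] = -sub[i1]
                states[idx] = sub
    probs = np.abs(states.reshape(n_traj, dim)) ** 2
    return probs.mean(axis=0), probs.std(axis=0) / np.sqrt(n_traj)


def test_noisy_run_matches_trajectory_monte_carlo(random_state):
    """Dense density-matrix evolution vs a 1e5-trajectory Kraus unravelling."""
    circ = sample_g3_circuit(3, 20, seed=17)
    psi = random_state(3, seed=17)
    exact = noisy_run(circ, psi, NoiseModel("depolarizing", 0.01))
    mc_mean, mc_sem = trajectory_oracle(circ, psi, 0.01, 100_000, seed=4)
    assert (np.abs(exact - mc_mean) <= 3 * mc_sem + 1e-12).all()
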