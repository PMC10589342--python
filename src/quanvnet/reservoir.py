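"""Fixed quantum-reservoir transformations.

A quantum reservoir here is a *non-trained* quantum operation used as a
convolution filter: either a random circuit drawn from the G3 = {CNOT, H, T}
gate family (maximally complex under the majorization criterion) or the time
evolution of a random transverse-field Ising Hamiltonian.  The reservoir is
fixed once at construction; measuring the evolved state in the computational
basis yields the feature vector that feeds the classical part of the network.

Qubit convention: qubit 0 is the *most significant* bit of a basis index, so
for a state vector ``psi`` of ``q`` qubits, basis index ``b`` has qubit ``k``
equal to bit ``(q - 1 - k)`` of ``b``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GateSpec",
    "ReservoirCircuit",
    "IsingParams",
    "sample_g3_circuit",
    "apply_circuit",
    "circuit_unitary",
    "measure_probabilities",
    "sample_ising",
    "ising_hamiltonian",
    "ising_evolve",
    "ising_unitary",
]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_T_PHASE = np.exp(1j * np.pi / 4.0)

G3_KINDS = ("CNOT", "H", "T")


@dataclass(frozen=True)
class GateSpec:
    """One gate from the G3 family.

    ``qubits`` holds one index for H/T and the ordered (control, target)
    pair for CNOT.
    """

    kind: str
    qubits: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in G3_KINDS:
            raise ValueError(f"unknown gate kind {self.kind!r}")
        n_expected = 2 if self.kind == "CNOT" else 1
        if len(self.qubits) != n_expected:
            raise ValueError(f"{self.kind} takes {n_expected} qubit(s)")
        if self.kind == "CNOT" and self.qubits[0] == self.qubits[1]:
            raise ValueError("CNOT control and target must differ")


@dataclass(frozen=True)
class ReservoirCircuit:
    """An ordered, frozen list of G3 gates on ``n_qubits`` qubits."""

    gates: tuple[GateSpec, ...]
    n_qubits: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for g in self.gates:
            if any(qb < 0 or qb >= self.n_qubits for qb in g.qubits):
                raise ValueError(f"gate {g} out of range for {self.n_qubits} qubits")

    def __len__(self) -> int:
        return len(self.gates)

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "n_qubits": self.n_qubits,
                "seed": self.seed,
                "gates": [[g.kind, list(g.qubits)] for g in self.gates],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ReservoirCircuit":
        obj = json.loads(text)
        gates = tuple(GateSpec(k, tuple(q)) for k, q in obj["gates"])
        return cls(gates=gates, n_qubits=int(obj["n_qubits"]), seed=obj.get("seed"))

    def to_qasm(self) -> str:
        """OpenQASM 2.0 export, for cross-checking in external simulators."""
        lines = [
            "OPENQASM 2.0;",
            'include "qelib1.inc";',
            f"qreg q[{self.n_qubits}];",
        ]
        for g in self.gates:
            if g.kind == "H":
                lines.append(f"h q[{g.qubits[0]}];")
            elif g.kind == "T":
                lines.append(f"t q[{g.qubits[0]}];")
            else:
                lines.append(f"cx q[{g.qubits[0]}],q[{g.qubits[1]}];")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class IsingParams:
    """Parameters of a random transverse-field Ising reservoir.

    H = sum_{i<j} J_ij Z_i Z_j + h sum_i X_i, with J_ij ~ U(-Js/2, Js/2)
    and a constant transverse field fixed by the ratio h/Js = 0.1; the
    state is evolved for time T_evolve = 10 (hbar = 1).
    """

    J: np.ndarray
    h: float
    Js: float
    T_evolve: float = 10.0

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=float)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError("J must be a square matrix")
        if not np.allclose(J, J.T):
            raise ValueError("J must be symmetric")
        if np.any(np.abs(np.diag(J)) > 0):
            raise ValueError("J must have zero diagonal")
        if np.any(np.abs(J) > self.Js / 2 + 1e-12):
            raise ValueError("J entries must lie in [-Js/2, Js/2]")
        object.__setattr__(self, "J", J)

    @property
    def n_qubits(self) -> int:
        return self.J.shape[0]


# ---------------------------------------------------------------------------
# circuit construction
# ---------------------------------------------------------------------------

def sample_g3_circuit(n_qubits: int, n_gates: int, seed: int) -> ReservoirCircuit:
    """Draw a random circuit from the G3 family.

    Gate kinds are sampled uniformly from {CNOT, H, T}; the target qubit of a
    one-qubit gate is uniform, and CNOT picks an ordered (control, target)
    pair uniformly without replacement.  Deterministic given ``seed``.
    """
    if n_qubits < 1:
        raise ValueError("n_qubits must be >= 1")
    if n_gates < 0:
        raise ValueError("n_gates must be >= 0")
    if n_qubits < 2 and n_gates > 0:
        # CNOT needs two qubits; with one qubit the family degenerates.
        raise ValueError("need n_qubits >= 2 to sample from the full G3 family")
    rng = np.random.default_rng(seed)
    gates: list[GateSpec] = []
    for _ in range(n_gates):
        kind = G3_KINDS[rng.integers(3)]
        if kind == "CNOT":
            control, target = rng.choice(n_qubits, size=2, replace=False)
            gates.append(GateSpec("CNOT", (int(control), int(target))))
        else:
            gates.append(GateSpec(kind, (int(rng.integers(n_qubits)),)))
    return ReservoirCircuit(gates=tuple(gates), n_qubits=n_qubits, seed=seed)


def sample_ising(n_qubits: int, Js: float = 1.0, seed: int = 0) -> IsingParams:
    """Draw random Ising couplings J_ij ~ U(-Js/2, Js/2) for all pairs i<j.

    The transverse field is fixed by the optimal reservoir ratio h/Js = 0.1
    and the evolution time is T = 10.
    """
    if Js <= 0:
        raise ValueError("Js must be > 0")
    rng = np.random.default_rng(seed)
    J = np.zeros((n_qubits, n_qubits))
    iu = np.triu_indices(n_qubits, k=1)
    J[iu] = rng.uniform(-Js / 2.0, Js / 2.0, size=len(iu[0]))
    J = J + J.T
    return IsingParams(J=J, h=0.1 * Js, Js=Js)


# ---------------------------------------------------------------------------
# state-vector simulation
# ---------------------------------------------------------------------------

def _apply_gate_tensor(psi: np.ndarray, gate: GateSpec, q: int) -> None:
    """Apply ``gate`` in place to ``psi`` viewed as a (2,)*q tensor."""
    if gate.kind == "H":
        k = gate.qubits[0]
        idx0 = (slice(None),) * k + (0,)
        idx1 = (slice(None),) * k + (1,)
        a0 = psi[idx0].copy()
        a1 = psi[idx1]
        psi[idx0] = (a0 + a1) * _INV_SQRT2
        psi[idx1] = (a0 - a1) * _INV_SQRT2
    elif gate.kind == "T":
        k = gate.qubits[0]
        psi[(slice(None),) * k + (1,)] *= _T_PHASE
    else:  # CNOT
        c, t = gate.qubits
        # swap target bit within the control=1 subspace
        idx_c1 = (slice(None),) * c + (1,)
        sub = psi[idx_c1]
        t_ax = t if t < c else t - 1
        i0 = (slice(None),) * t_ax + (0,)
        i1 = (slice(None),) * t_ax + (1,)
        tmp = sub[i0].copy()
        sub[i0] = sub[i1]
        sub[i1] = tmp


def apply_circuit(state: np.ndarray, circuit: ReservoirCircuit) -> np.ndarray:
    """Run ``circuit`` on a state vector; returns a new array (input untouched)."""
    state = np.asarray(state)
    dim = 1 << circuit.n_qubits
    if state.shape != (dim,):
        raise ValueError(
            f"state dimension {state.shape} does not match 2^{circuit.n_qubits}"
        )
    psi = state.astype(np.complex128).reshape((2,) * circuit.n_qubits)
    for gate in circuit.gates:
        _apply_gate_tensor(psi, gate, circuit.n_qubits)
    return psi.reshape(dim)


def circuit_unitary(circuit: ReservoirCircuit) -> np.ndarray:
    """Dense unitary of the whole circuit (columns = images of basis states)."""
    dim = 1 << circuit.n_qubits
    # apply the circuit to every basis state at once: treat the extra axis
    # as a batch dimension trailing the qubit axes
    u = np.eye(dim, dtype=np.complex128).reshape((2,) * circuit.n_qubits + (dim,))
    for gate in circuit.gates:
        _apply_gate_tensor(u, gate, circuit.n_qubits)
    return u.reshape(dim, dim)


def measure_probabilities(
    state: np.ndarray,
    shots: int | None = None,
    rng: np.random.Generator | None = None,
    atol: float = 1e-6,
) -> np.ndarray:
    """Computational-basis measurement distribution of ``state``.

    With ``shots`` set, draws a multinomial sample and returns normalized
    counts (a seeded ``rng`` keeps this reproducible); otherwise returns the
    exact Born probabilities |amplitude|^2.
    """
    state = np.asarray(state)
    p = np.abs(state) ** 2
    total = p.sum()
    if abs(total - 1.0) > atol:
        raise ValueError(f"state norm^2 = {total:.6g} is not 1 within {atol}")
    p = p / total
    if shots is None:
        return p
    if shots <= 0:
        raise ValueError("shots must be positive")
    if rng is None:
        rng = np.random.default_rng()
    counts = rng.multinomial(shots, p)
    return counts / float(shots)


# ---------------------------------------------------------------------------
# Ising evolution
# ---------------------------------------------------------------------------

def ising_hamiltonian(params: IsingParams) -> np.ndarray:
    """Dense 2^q x 2^q transverse-field Ising Hamiltonian."""
    q = params.n_qubits
    dim = 1 << q
    # diagonal ZZ part: z_k(b) = +1 if qubit k is 0, -1 if 1
    bits = ((np.arange(dim)[:, None] >> np.arange(q - 1, -1, -1)[None, :]) & 1)
    z = 1.0 - 2.0 * bits  # (dim, q)
    # sum over pairs i<j counted once: 0.5 z^T J z with J symmetric, zero diag
    diag = 0.5 * np.einsum("bi,ij,bj->b", z, params.J, z)
    H = np.diag(diag).astype(np.complex128)
    # off-diagonal transverse field: h * X_i flips one bit
    idx = np.arange(dim)
    for k in range(q):
        flipped = idx ^ (1 << (q - 1 - k))
        H[idx, flipped] += params.h
    if not np.allclose(H, H.conj().T, atol=1e-12):
        raise ValueError("assembled Hamiltonian is not Hermitian")
    return H


def ising_unitary(params: IsingParams) -> np.ndarray:
    """exp(-i H T) via eigendecomposition (exact dense exponentiation)."""
    H = ising_hamiltonian(params)
    w, v = np.linalg.eigh(H)
    return (v * np.exp(-1j * w * params.T_evolve)) @ v.conj().T


def ising_evolve(state: np.ndarray, params: IsingParams) -> np.ndarray:
    """Evolve a state vector under the Ising Hamiltonian for time T_evolve."""
    state = np.asarray(state, dtype=np.complex128)
    dim = 1 << params.n_qubits
    if state.shape != (dim,):
        raise ValueError("state dimension does not match Ising system size")
    return ising_unitary(params) @ state
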