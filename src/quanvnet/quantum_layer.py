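"""The quantum convolutional layer: per-block reservoir features.

Each (n x n x n) block of every channel is FRQI-encoded, pushed through one
fixed reservoir transformation (a random G3 circuit or an Ising evolution -
the quantum analogue of a shared convolution filter), and measured.  The
2 n^3 leading basis probabilities of a block (color bit 0 and 1 for each of
its n^3 positions) are written back to the block's sub-volume, turning each
input channel into two output channels.  For the reference geometry
(C = 19, N = 48, n = 4) this issues 19 * (48/4)^3 = 32,832 per-block circuit
executions per sample.

Because the reservoir is fixed, the whole layer is one dense unitary applied
to a batch of block state vectors; features are precomputed once per dataset
and treated as non-trainable network inputs.
"""

from __future__ import annotations

import numpy as np

from .complexes import FeatureGrid
from .frqi import normalize_to_angles, partition_blocks, qubit_count
from .reservoir import IsingParams, ReservoirCircuit, circuit_unitary, ising_unitary

__all__ = [
    "n_block_circuits",
    "reservoir_unitary",
    "quantum_conv_layer",
    "precompute_quantum_features",
]


def n_block_circuits(C: int, N: int, n: int) -> int:
    """Circuit executions needed to span one (C, N, N, N) sample."""
    if N % n != 0:
        raise ValueError("block side must divide grid side")
    return C * (N // n) ** 3


def reservoir_unitary(reservoir: ReservoirCircuit | IsingParams) -> np.ndarray:
    if isinstance(reservoir, ReservoirCircuit):
        return circuit_unitary(reservoir)
    if isinstance(reservoir, IsingParams):
        return ising_unitary(reservoir)
    raise TypeError("reservoir must be a ReservoirCircuit or IsingParams")


def quantum_conv_layer(
    grid: FeatureGrid | np.ndarray,
    reservoir: ReservoirCircuit | IsingParams,
    n: int = 4,
    range_mode: str = "published",
    rescale: bool = True,
) -> np.ndarray:
    """Apply the quantum convolutional layer to one sample.

    Returns a (2C, N, N, N) array: input channel c yields output channels
    2c (color bit 0) and 2c + 1 (color bit 1).  With ``rescale`` the
    per-block probabilities are multiplied by n^3 so voxel magnitudes are
    O(1) for the downstream network.
    """
    values = grid.values if isinstance(grid, FeatureGrid) else np.asarray(grid)
    C, N = values.shape[0], values.shape[1]
    q = qubit_count(n)
    dim = 1 << q
    half = dim >> 1
    n3 = n**3
    U = reservoir_unitary(reservoir)
    if U.shape != (dim, dim):
        raise ValueError(
            f"reservoir dimension {U.shape[0]} does not match block qubits {q}")

    angles = normalize_to_angles(values, range_mode=range_mode)
    blocks = partition_blocks(angles, n)
    thetas = np.stack([b.theta for b in blocks])          # (nb, n^3)
    states = np.zeros((len(blocks), dim), dtype=np.complex128)
    z = 1.0 / np.sqrt(n3)
    states[:, :n3] = z * np.cos(thetas)
    states[:, half: half + n3] = z * np.sin(thetas)
    probs = np.abs(states @ U.T) ** 2                      # (nb, 2^q)

    out = np.zeros((2 * C, N, N, N), dtype=np.float64)
    scale = float(n3) if rescale else 1.0
    nb_side = N // n
    for b, block in enumerate(blocks):
        c, bx, by, bz = block.block_index
        sl = (slice(bx * n, (bx + 1) * n),
              slice(by * n, (by + 1) * n),
              slice(bz * n, (bz + 1) * n))
        out[(2 * c,) + sl] = (probs[b, :n3] * scale).reshape(n, n, n)
        out[(2 * c + 1,) + sl] = (probs[b, half: half + n3] * scale).reshape(n, n, n)
    assert len(blocks) == n_block_circuits(C, N, n)
    return out


def precompute_quantum_features(
    grids: list[FeatureGrid] | list[np.ndarray] | np.ndarray,
    reservoir: ReservoirCircuit | IsingParams,
    n: int = 4,
    range_mode: str = "published",
    rescale: bool = True,
) -> np.ndarray:
    """Quantum feature channels for a dataset, as one (B, 2C, N, N, N) array."""
    return np.stack(
        [quantum_conv_layer(g, reservoir, n=n, range_mode=range_mode,
                            rescale=rescale).astype(np.float32)
         for g in grids]
    )
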