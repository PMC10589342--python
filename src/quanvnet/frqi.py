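"""Flexible Representation of Quantum Images (FRQI) for 3D voxel blocks.

FRQI stores a normalized image in a quantum state by entangling a single
"color" qubit with the position register: for a block of n^3 voxels whose
values have been mapped to angles theta_i,

    |B> = Z * sum_i (cos theta_i |0> + sin theta_i |1>) (x) |i>,

on ceil(log2(n^3)) + 1 qubits.  Because cos^2 + sin^2 = 1 for every i, the
prefactor that makes ||B|| = 1 is Z = 1 / sqrt(n^3); the states here are
built directly as amplitude vectors (gate-level preparation circuits are a
separate concern and out of scope).

Unlike per-block amplitude encoding, the angle normalization is *global*
over the whole sample (all channels jointly), so different blocks of one
complex remain comparable after encoding.  Two angle ranges are supported:

* ``published`` - values mapped affinely to [0, 2*pi), the published FRQI
                  convention; cos/sin are then not injective in the angle.
* ``injective`` - values mapped to [0, pi/2], making the encoding exactly
                  invertible via atan2 (useful for round-trip checks).

Layout conventions (fixed for reproducibility): the color qubit is the most
significant qubit, so basis index c * 2^(q-1) + i holds color c of position
i; within a block, position i = x*n^2 + y*n + z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .complexes import FeatureGrid

__all__ = [
    "BlockAngles",
    "FRQIState",
    "normalize_to_angles",
    "partition_blocks",
    "encode_block",
    "decode_block",
    "qubit_count",
    "assemble_block_grid",
]

RANGE_MODES = ("published", "injective")
_PUBLISHED_MAX = 2.0 * np.pi * (1.0 - 1e-9)


@dataclass(frozen=True)
class BlockAngles:
    """Angles of one (n x n x n) sub-volume of a single channel."""

    theta: np.ndarray
    block_index: tuple[int, int, int, int]  # (channel, bx, by, bz)
    n: int

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=np.float64)
        if theta.shape != (self.n**3,):
            raise ValueError(f"theta must have length n^3 = {self.n**3}")
        if np.any(theta < 0.0) or np.any(theta >= 2.0 * np.pi):
            raise ValueError("angles must lie in [0, 2*pi)")
        object.__setattr__(self, "theta", theta)


@dataclass(frozen=True)
class FRQIState:
    """FRQI amplitude vector of one block on ceil(log2(n^3)) + 1 qubits."""

    amplitudes: np.ndarray
    n: int

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=np.complex128)
        q = qubit_count(self.n)
        if amp.shape != (1 << q,):
            raise ValueError(f"amplitudes must have length 2^{q}")
        if abs(np.linalg.norm(amp) - 1.0) > 1e-10:
            raise ValueError("state is not normalized")
        half = 1 << (q - 1)
        if np.any(amp[self.n**3: half] != 0) or np.any(amp[half + self.n**3:] != 0):
            raise ValueError("amplitudes beyond n^3 positions must be zero")
        object.__setattr__(self, "amplitudes", amp)

    @property
    def n_qubits(self) -> int:
        return qubit_count(self.n)


def qubit_count(n: int) -> int:
    """Qubits needed to FRQI-encode an (n x n x n) block."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return int(np.ceil(np.log2(n**3))) + 1


def normalize_to_angles(
    grid: FeatureGrid | np.ndarray, range_mode: str = "published"
) -> np.ndarray:
    """Affine min-max map of the whole sample's voxel values to angles.

    The minimum and maximum are taken jointly over all channels of the
    sample, so the map is one global rescaling; a constant grid maps to
    all-zero angles.
    """
    if range_mode not in RANGE_MODES:
        raise ValueError(f"range_mode must be one of {RANGE_MODES}")
    values = grid.values if isinstance(grid, FeatureGrid) else np.asarray(grid)
    values = values.astype(np.float64)
    if not np.isfinite(values).all():
        raise ValueError("grid values must be finite")
    vmin = values.min()
    vmax = values.max()
    if vmax == vmin:
        return np.zeros_like(values)
    top = _PUBLISHED_MAX if range_mode == "published" else np.pi / 2.0
    return (values - vmin) * (top / (vmax - vmin))


def partition_blocks(angles: np.ndarray, n: int) -> list[BlockAngles]:
    """Split a (C, N, N, N) angle grid into per-channel (n x n x n) blocks.

    Blocks are non-overlapping and ordered by (channel, bx, by, bz); within a
    block the flattened position index is i = x*n^2 + y*n + z.
    """
    angles = np.asarray(angles)
    if angles.ndim != 4:
        raise ValueError("angle grid must have shape (C, N, N, N)")
    C, N = angles.shape[0], angles.shape[1]
    if angles.shape[1:] != (N, N, N):
        raise ValueError("angle grid must be cubic")
    if N % n != 0:
        raise ValueError(f"block side {n} does not divide grid side {N}")
    nb = N // n
    blocks = []
    for c in range(C):
        for bx in range(nb):
            for by in range(nb):
                for bz in range(nb):
                    sub = angles[c,
                                 bx * n:(bx + 1) * n,
                                 by * n:(by + 1) * n,
                                 bz * n:(bz + 1) * n]
                    blocks.append(
                        BlockAngles(theta=sub.reshape(-1), block_index=(c, bx, by, bz), n=n)
                    )
    return blocks


def assemble_block_grid(
    block_values: dict[tuple[int, int, int, int], np.ndarray],
    n: int,
    C: int,
    N: int,
) -> np.ndarray:
    """Inverse of :func:`partition_blocks` for per-block flattened vectors."""
    out = np.zeros((C, N, N, N))
    for (c, bx, by, bz), vec in block_values.items():
        out[c,
            bx * n:(bx + 1) * n,
            by * n:(by + 1) * n,
            bz * n:(bz + 1) * n] = np.asarray(vec).reshape(n, n, n)
    return out


def encode_block(block: BlockAngles) -> FRQIState:
    """Direct amplitude construction of the FRQI state of one block."""
    n3 = block.n**3
    q = qubit_count(block.n)
    half = 1 << (q - 1)
    amp = np.zeros(2 * half, dtype=np.complex128)
    z = 1.0 / np.sqrt(n3)
    amp[:n3] = z * np.cos(block.theta)
    amp[half: half + n3] = z * np.sin(block.theta)
    return FRQIState(amplitudes=amp, n=block.n)


def decode_block(state: FRQIState) -> np.ndarray:
    """Recover angles from an FRQI state via atan2 (exact in injective mode)."""
    n3 = state.n**3
    half = 1 << (state.n_qubits - 1)
    cos_part = state.amplitudes[:n3].real
    sin_part = state.amplitudes[half: half + n3].real
    theta = np.arctan2(sin_part, cos_part)
    return np.where(theta < 0, theta + 2.0 * np.pi, theta)
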