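"""Synthetic protein-ligand complexes and their voxel featurization.

Real binding-affinity pipelines featurize each protein-ligand complex as a
dense 4D tensor of shape (C, N, N, N): a cubic box of side 48 Angstrom at
1 Angstrom voxel resolution (N = 48), with C = 19 chemical features per
voxel.  Each atom writes its 19-feature vector into every voxel whose center
lies within the atom's Van der Waals radius (overlaps add element-wise), and
a Gaussian blur with sigma = 1 densifies the sparse occupancy.

The synthetic generator emulates that geometry without any external
structure files: a ligand cluster sits in a pocket surrounded by a shell of
protein atoms, and the affinity label (pK units, -log(k_d/k_I) scale) is a
noisy linear function of the number of protein-ligand atom pairs closer than
4 Angstrom, so that the contact signal a scoring network should pick up is
present by construction:

    affinity = A0 + B_CONTACT * n_contacts + Normal(0, NOISE_SD), clipped to [0, 12].

Feature layout (channel order):
    0-8   one-hot element: B, C, N, O, P, S, Se, halogen, metal
    9     hybridization (1, 2, 3 for sp, sp2, sp3)
    10    number of heavy-atom bonds
    11    number of hetero-atom bonds
    12-16 structural flags: hydrophobic, aromatic, acceptor, donor, ring
    17    partial charge
    18    molecule type: -1 protein, +1 ligand
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "AtomRecord",
    "FeatureGrid",
    "SplitSpec",
    "ELEMENTS",
    "N_FEATURES",
    "generate_complex",
    "feature_vector",
    "voxelize",
    "gaussian_blur",
    "stratified_split",
    "make_dataset",
]

ELEMENTS = ("B", "C", "N", "O", "P", "S", "Se", "halogen", "metal")
N_FEATURES = 19
DEFAULT_BOX = 48.0

# Bondi-style Van der Waals radii (Angstrom); halogen/metal are class averages
VDW_RADII = {
    "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80,
    "S": 1.80, "Se": 1.90, "halogen": 1.80, "metal": 2.00,
}

# affinity model constants of the generator
A0 = 2.0
B_CONTACT = 0.05
NOISE_SD = 0.3
CONTACT_CUTOFF = 4.0  # Angstrom

_PROTEIN_ELEMENT_P = {"C": 0.55, "N": 0.17, "O": 0.22, "S": 0.03, "P": 0.02, "metal": 0.01}
_LIGAND_ELEMENT_P = {"C": 0.58, "N": 0.12, "O": 0.18, "S": 0.03, "P": 0.02, "halogen": 0.05, "B": 0.02}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a complex with the 19-feature chemistry annotation."""

    element: str
    position: tuple[float, float, float]
    vdw_radius: float
    hybridization: int
    heavy_bonds: int
    hetero_bonds: int
    structural_flags: tuple[bool, bool, bool, bool, bool]
    partial_charge: float
    molecule_type: int  # -1 protein, +1 ligand

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be > 0")
        if self.hybridization not in (1, 2, 3):
            raise ValueError("hybridization must be 1, 2 or 3")
        if self.heavy_bonds < 0 or self.hetero_bonds < 0:
            raise ValueError("bond counts must be non-negative")
        if len(self.structural_flags) != 5:
            raise ValueError("structural_flags must have length 5")
        if self.molecule_type not in (-1, 1):
            raise ValueError("molecule_type must be -1 (protein) or +1 (ligand)")


@dataclass
class FeatureGrid:
    """Dense (C, N, N, N) voxel feature tensor with its affinity label."""

    values: np.ndarray
    affinity: float
    sample_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 4 or v.shape[0] != N_FEATURES:
            raise ValueError(f"values must have shape ({N_FEATURES}, N, N, N)")
        if not (v.shape[1] == v.shape[2] == v.shape[3]):
            raise ValueError("grid must be cubic")
        if not np.isfinite(v).all():
            raise ValueError("grid values must be finite")
        if not np.isfinite(self.affinity):
            raise ValueError("affinity must be finite")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SplitSpec:
    """A train/validation partition of sample ids, quintile-stratified."""

    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation ids overlap")

    def to_json(self) -> str:
        return json.dumps(
            {"train_ids": list(self.train_ids),
             "validation_ids": list(self.validation_ids),
             "seed": self.seed}
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitSpec":
        obj = json.loads(text)
        return cls(tuple(obj["train_ids"]), tuple(obj["validation_ids"]),
                   int(obj["seed"]))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_position(rng, center, scale_fn, box_size, margin):
    """Rejection-sample a position inside the box (never silently clipped)."""
    for _ in range(1000):
        pos = scale_fn(rng)
        if np.all(pos >= margin) and np.all(pos <= box_size - margin):
            return pos
    raise RuntimeError("could not place atom inside the box")


def _sample_elements(rng, table, size):
    names = list(table)
    probs = np.array([table[k] for k in names])
    probs = probs / probs.sum()
    return rng.choice(names, size=size, p=probs)


def _make_atom(rng, element: str, pos: np.ndarray, molecule_type: int) -> AtomRecord:
    hyb = int(rng.choice([1, 2, 3], p=[0.05, 0.35, 0.60]))
    heavy = int(rng.integers(1, 5))
    hetero = int(rng.integers(0, 3))
    flags = (
        element == "C" and rng.random() < 0.7,        # hydrophobic
        bool(rng.random() < 0.3),                      # aromatic
        element in ("N", "O") and rng.random() < 0.6,  # acceptor
        bool(rng.random() < 0.25),                     # donor
        bool(rng.random() < 0.4),                      # ring
    )
    return AtomRecord(
        element=element,
        position=tuple(float(x) for x in pos),
        vdw_radius=VDW_RADII[element],
        hybridization=hyb,
        heavy_bonds=heavy,
        hetero_bonds=hetero,
        structural_flags=tuple(bool(f) for f in flags),
        partial_charge=float(rng.normal(0.0, 0.2)),
        molecule_type=molecule_type,
    )


def generate_complex(
    seed: int,
    n_protein_atoms: int,
    n_ligand_atoms: int,
    box_size: float = DEFAULT_BOX,
) -> tuple[list[AtomRecord], float]:
    """Generate one synthetic complex and its affinity label.

    The ligand is a compact cluster in the pocket at the box center; protein
    atoms form a loose shell around it.  Deterministic given ``seed``.
    """
    if n_protein_atoms < 1 or n_ligand_atoms < 1:
        raise ValueError("atom counts must be >= 1")
    rng = np.random.default_rng(seed)
    center = np.full(3, box_size / 2.0)
    margin = 0.1

    ligand_positions = [
        _draw_position(
            rng, center,
            lambda r: center + r.normal(0.0, 2.5, size=3),
            box_size, margin,
        )
        for _ in range(n_ligand_atoms)
    ]

    def protein_pos(r):
        direction = r.normal(size=3)
        direction /= np.linalg.norm(direction)
        radius = r.uniform(3.0, min(14.0, box_size / 2.0 - 1.0))
        return center + direction * radius + r.normal(0.0, 1.0, size=3)

    protein_positions = [
        _draw_position(rng, center, protein_pos, box_size, margin)
        for _ in range(n_protein_atoms)
    ]

    atoms: list[AtomRecord] = []
    for el, pos in zip(
        _sample_elements(rng, _PROTEIN_ELEMENT_P, n_protein_atoms), protein_positions
    ):
        atoms.append(_make_atom(rng, str(el), pos, molecule_type=-1))
    for el, pos in zip(
        _sample_elements(rng, _LIGAND_ELEMENT_P, n_ligand_atoms), ligand_positions
    ):
        atoms.append(_make_atom(rng, str(el), pos, molecule_type=+1))

    prot = np.array(protein_positions)
    lig = np.array(ligand_positions)
    d2 = ((prot[:, None, :] - lig[None, :, :]) ** 2).sum(-1)
    n_contacts = int((d2 < CONTACT_CUTOFF**2).sum())
    affinity = A0 + B_CONTACT * n_contacts + rng.normal(0.0, NOISE_SD)
    affinity = float(np.clip(affinity, 0.0, 12.0))
    return atoms, affinity


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def feature_vector(atom: AtomRecord) -> np.ndarray:
    """The 19-entry per-atom feature vector, in channel order."""
    v = np.zeros(N_FEATURES, dtype=np.float64)
    v[ELEMENTS.index(atom.element)] = 1.0
    v[9] = atom.hybridization
    v[10] = atom.heavy_bonds
    v[11] = atom.hetero_bonds
    v[12:17] = np.asarray(atom.structural_flags, dtype=np.float64)
    v[17] = atom.partial_charge
    v[18] = atom.molecule_type
    if v.shape != (N_FEATURES,):  # pragma: no cover - construction guarantee
        raise ValueError("feature vector has wrong length")
    return v


def voxelize(
    atoms: list[AtomRecord],
    box_size: float = DEFAULT_BOX,
    voxel_size: float = 1.0,
    affinity: float = 0.0,
    sample_id: str = "",
) -> FeatureGrid:
    """Write each atom's features into all voxels whose center lies within
    its Van der Waals radius; overlapping atoms add element-wise.

    Voxel (i, j, k) has its center at ((i+0.5), (j+0.5), (k+0.5)) * voxel_size.
    """
    n = int(round(box_size / voxel_size))
    grid = np.zeros((N_FEATURES, n, n, n), dtype=np.float64)
    centers = (np.arange(n) + 0.5) * voxel_size
    for atom in atoms:
        pos = np.asarray(atom.position)
        if np.any(pos < 0) or np.any(pos > box_size):
            raise ValueError(f"atom at {tuple(pos)} outside the box")
        r = atom.vdw_radius
        lo = np.maximum(np.floor((pos - r) / voxel_size - 0.5).astype(int), 0)
        hi = np.minimum(np.ceil((pos + r) / voxel_size - 0.5).astype(int) + 1, n)
        cx = centers[lo[0]:hi[0]] - pos[0]
        cy = centers[lo[1]:hi[1]] - pos[1]
        cz = centers[lo[2]:hi[2]] - pos[2]
        d2 = (cx[:, None, None] ** 2 + cy[None, :, None] ** 2
              + cz[None, None, :] ** 2)
        mask = d2 <= r * r
        feats = feature_vector(atom)
        sub = grid[:, lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub += feats[:, None, None, None] * mask[None]
    return FeatureGrid(values=grid.astype(np.float32), affinity=affinity,
                       sample_id=sample_id)


def gaussian_blur(grid: FeatureGrid, sigma: float = 1.0) -> FeatureGrid:
    """Per-channel 3D Gaussian blur (kernel truncated at 4 sigma, zero padding)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    blurred = np.stack(
        [gaussian_filter(ch.astype(np.float64), sigma=sigma, truncate=4.0,
                         mode="constant", cval=0.0)
         for ch in grid.values]
    )
    return FeatureGrid(values=blurred.astype(np.float32),
                       affinity=grid.affinity, sample_id=grid.sample_id)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    grids: list[FeatureGrid], seed: int, validation_fraction: float = 0.1
) -> SplitSpec:
    """Quintile-stratified split: bin affinities at the empirical 20/40/60/80
    percentiles and move ``validation_fraction`` of each quintile (rounded
    down, at least one member when the quintile is non-empty) to validation.

    Boundary ties are assigned to the lower quintile.
    """
    ids = [g.sample_id for g in grids]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids")
    affinities = np.array([g.affinity for g in grids])
    if len(np.unique(affinities)) < 5:
        raise ValueError("need at least 5 grids with distinct affinities")
    edges = np.percentile(affinities, [20, 40, 60, 80])
    bins = np.searchsorted(edges, affinities, side="left")
    rng = np.random.default_rng(seed)
    validation: list[str] = []
    for b in range(5):
        members = [ids[i] for i in np.flatnonzero(bins == b)]
        if not members:
            continue
        k = max(1, int(len(members) * validation_fraction))
        chosen = rng.choice(len(members), size=k, replace=False)
        validation.extend(members[i] for i in sorted(chosen))
    val_set = set(validation)
    train = [i for i in ids if i not in val_set]
    return SplitSpec(tuple(train), tuple(validation), seed)


# ---------------------------------------------------------------------------
# dataset convenience
# ---------------------------------------------------------------------------

def make_dataset(
    n_complexes: int,
    seed: int,
    box_size: float = DEFAULT_BOX,
    n_protein_range: tuple[int, int] = (40, 80),
    n_ligand_range: tuple[int, int] = (8, 24),
    sigma: float = 1.0,
) -> list[FeatureGrid]:
    """Generate, voxelize and blur ``n_complexes`` synthetic complexes.

    Atom counts vary per complex (uniform over the given ranges) so that
    contact counts - and hence affinities - spread over a learnable range.
    """
    rng = np.random.default_rng(seed)
    grids = []
    for i in range(n_complexes):
        n_prot = int(rng.integers(*n_protein_range))
        n_lig = int(rng.integers(*n_ligand_range))
        atom_seed = int(rng.integers(0, 2**31 - 1))
        atoms, affinity = generate_complex(atom_seed, n_prot, n_lig, box_size)
        g = voxelize(atoms, box_size=box_size, affinity=affinity,
                     sample_id=f"synth-{seed}-{i:05d}")
        grids.append(gaussian_blur(g, sigma=sigma))
    return grids
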