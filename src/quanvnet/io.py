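"""HDF5 / JSON persistence for grids, quantum features and mitigation data."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .complexes import FeatureGrid

__all__ = [
    "save_grids",
    "load_grids",
    "save_quantum_features",
    "load_quantum_features",
    "save_mitigation_table",
]


def save_grids(path: str | Path, grids: list[FeatureGrid]) -> None:
    """One HDF5 group per sample: /<id>/values (C,N,N,N) f32 + affinity attr."""
    with h5py.File(path, "w") as f:
        for g in grids:
            grp = f.create_group(g.sample_id)
            grp.create_dataset("values", data=g.values.astype(np.float32),
                               compression="gzip", compression_opts=1)
            grp.attrs["affinity"] = g.affinity
            grp.attrs["C"] = g.values.shape[0]
            grp.attrs["N"] = g.values.shape[1]


def load_grids(path: str | Path) -> list[FeatureGrid]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in f:
            grp = f[sid]
            out.append(FeatureGrid(values=grp["values"][...],
                                   affinity=float(grp.attrs["affinity"]),
                                   sample_id=sid))
    return out


def save_quantum_features(path: str | Path, features: np.ndarray,
                          sample_ids: list[str]) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.astype(np.float32),
                         compression="gzip", compression_opts=1)
        f.create_dataset("sample_ids",
                         data=np.array(sample_ids, dtype=h5py.string_dtype()))


def load_quantum_features(path: str | Path) -> tuple[np.ndarray, list[str]]:
    with h5py.File(path, "r") as f:
        feats = f["features"][...]
        ids = [s.decode() if isinstance(s, bytes) else str(s)
               for s in f["sample_ids"][...]]
    return feats, ids


def save_mitigation_table(path: str | Path, rows: list[dict]) -> None:
    """Noise-study results as a CSV-compatible table (pandas-ready)."""
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, index=False)


def save_mitigation_records(path: str | Path, records, *,
                            kind: str, p: float, alpha: float | None = None,
                            seed: int | None = None) -> None:
    """Paired noisy/noiseless (and mitigated) distributions as HDF5 tables."""
    noiseless = np.stack([r.y_noiseless for r in records])
    noisy = np.stack([r.y_noisy for r in records])
    with h5py.File(path, "w") as f:
        f.create_dataset("y_noiseless", data=noiseless)
        f.create_dataset("y_noisy", data=noisy)
        if all(r.y_mitigated is not None for r in records):
            f.create_dataset("y_mitigated",
                             data=np.stack([r.y_mitigated for r in records]))
        f.attrs["kind"] = kind
        f.attrs["p"] = p
        if alpha is not None:
            f.attrs["alpha"] = alpha
        if seed is not None:
            f.attrs["seed"] = seed


def load_mitigation_records(path: str | Path):
    """Inverse of :func:`save_mitigation_records`; returns (records, attrs)."""
    from .mitigation import MitigationRecord

    with h5py.File(path, "r") as f:
        noiseless = f["y_noiseless"][...]
        noisy = f["y_noisy"][...]
        mitigated = f["y_mitigated"][...] if "y_mitigated" in f else None
        attrs = dict(f.attrs)
    records = [
        MitigationRecord(c, x, None if mitigated is None else m)
        for c, x, m in zip(noiseless, noisy,
                           mitigated if mitigated is not None
                           else [None] * len(noisy))
    ]
    return records, attrs
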