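"""Labelled matrix and profile writers/loaders (TSV and NumPy binary)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_matrix_npz",
    "read_matrix_npz",
    "write_profile_tsv",
]


def write_matrix_tsv(matrix: np.ndarray, labels, path) -> None:
    """Write an N×N matrix with "chain:resnum" labels on both axes."""
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_matrix_npz(matrix: np.ndarray, labels, path) -> None:
    """Compact binary companion of the TSV matrix format (NumPy .npz)."""
    np.savez_compressed(path, matrix=np.asarray(matrix), labels=np.asarray(labels, dtype=object))


def read_matrix_npz(path) -> tuple[np.ndarray, list[str]]:
    data = np.load(path, allow_pickle=True)
    return data["matrix"], [str(x) for x in data["labels"]]


def write_profile_tsv(values, labels, path, columns=("value",)) -> None:
    """Per-residue profile TSV: residue label plus one or more value columns."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] != len(columns):
        arr = arr.T
    pd.DataFrame(dict(zip(columns, arr)), index=pd.Index(labels, name="residue")).to_csv(path, sep="\t")
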