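"""Delimited-text matrix, profile and region-map I/O.

Matrices travel as tab-delimited text with node IDs in the first row and
column, written at "%.10g" precision. Symmetry is enforced on read (max
absolute asymmetry 1e-8, else an error).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

SYMMETRY_TOL = 1e-8


def write_matrix(M, path, ids=None) -> None:
    """Write a square matrix as TSV with row/column IDs."""
    M = np.asarray(M, dtype=float)
    if ids is None:
        ids = [f"n{i}" for i in range(M.shape[0])]
    df = pd.DataFrame(M, index=ids, columns=ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_matrix(path, symmetric: bool = True):
    """Read a TSV matrix; returns ``(array, ids)``.

    Symmetric matrices are checked to within 1e-8 max absolute
    asymmetry and symmetrized exactly.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    M = df.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({M.shape})")
    if symmetric:
        asym = float(np.abs(M - M.T).max())
        if asym > SYMMETRY_TOL:
            raise ValueError(
                f"{path}: matrix asymmetry {asym:g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        M = (M + M.T) / 2.0
    return M, list(df.index.astype(str))


def write_profiles(P, path, ids=None) -> None:
    """Write depth-intensity profiles (rows = regions, cols = depth samples)."""
    P = np.asarray(P, dtype=float)
    if ids is None:
        ids = [f"n{i}" for i in range(P.shape[0])]
    cols = [f"depth{j}" for j in range(P.shape[1])]
    pd.DataFrame(P, index=ids, columns=cols).to_csv(path, sep="\t",
                                                    float_format="%.10g")


def read_profiles(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), list(df.index.astype(str))


def write_region_map(labels, path) -> None:
    """Write a two-column TSV (vertex_index, region_id), 0-based."""
    labels = np.asarray(labels, dtype=np.int64)
    df = pd.DataFrame({"vertex_index": np.arange(len(labels)), "region_id": labels})
    df.to_csv(path, sep="\t", index=False)


def read_region_map(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if not {"vertex_index", "region_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns vertex_index, region_id")
    df = df.sort_values("vertex_index")
    if not np.array_equal(df["vertex_index"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: vertex indices must be contiguous from 0")
    labels = df["region_id"].to_numpy(dtype=np.int64)
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(len(uniq))):
        raise ValueError(f"{path}: region ids must be contiguous from 0")
    return labels


def file_digest(path) -> str:
    """SHA-256 digest of a file, for run-record provenance."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
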