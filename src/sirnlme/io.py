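"""Readers and writers for the tabular interchange formats.

Covariance matrices come in as plain CSV (header row of parameter names,
square numeric body) or in the NONMEM ``.cov`` table dialect (a ``TABLE``
banner line, then a whitespace-separated table with a ``NAME`` column).
Parameter-vector sets use a one-row-per-vector CSV with parameter-name
columns and an optional ``ofv`` column (the rawres layout).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_covariance_csv",
    "write_covariance_csv",
    "read_nonmem_cov",
    "read_vectors_csv",
    "write_vectors_csv",
]


def read_covariance_csv(path) -> tuple[list[str], np.ndarray]:
    """Plain-CSV covariance: header = parameter names, square numeric body."""
    frame = pd.read_csv(path)
    names = [str(c) for c in frame.columns]
    # tolerate a leading label column mirroring the header
    if frame.shape[1] == frame.shape[0] + 1 and not pd.api.types.is_numeric_dtype(
        frame.iloc[:, 0]
    ):
        frame = frame.iloc[:, 1:]
        names = names[1:]
    mat = frame.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f"covariance body is {mat.shape}, expected square")
    return names, mat


def write_covariance_csv(path, names: list[str], cov: np.ndarray) -> None:
    pd.DataFrame(np.asarray(cov, dtype=float), columns=list(names)).to_csv(
        path, index=False
    )


def read_nonmem_cov(path) -> tuple[list[str], np.ndarray]:
    """NONMEM .cov table: TABLE banner line, NAME column, whitespace-separated."""
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and lines[0].lstrip().upper().startswith("TABLE"):
        lines = lines[1:]
    frame = pd.read_csv(
        _io.StringIO("\n".join(lines)), sep=r"\s+", engine="python"
    )
    name_col = next((c for c in frame.columns if c.upper() == "NAME"), None)
    if name_col is None:
        raise ValueError("NONMEM .cov table has no NAME column")
    names = [str(n) for n in frame[name_col]]
    body = frame.drop(columns=[name_col])
    mat = body.to_numpy(dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise ValueError(f".cov body is {mat.shape}, expected square")
    return names, mat


def read_vectors_csv(path) -> tuple[list[str], np.ndarray, np.ndarray | None]:
    """Parameter-vector set: one row per vector, optional ``ofv`` column.

    Returns (parameter names, values array, ofv array or None).
    """
    frame = pd.read_csv(path)
    ofv_col = next((c for c in frame.columns if c.lower() == "ofv"), None)
    ofv = None
    if ofv_col is not None:
        ofv = frame[ofv_col].to_numpy(dtype=float)
        frame = frame.drop(columns=[ofv_col])
    names = [str(c) for c in frame.columns]
    return names, frame.to_numpy(dtype=float), ofv


def write_vectors_csv(path, names: list[str], values: np.ndarray,
                      ofv: np.ndarray | None = None, **extra_columns) -> None:
    frame = pd.DataFrame(np.asarray(values, dtype=float), columns=list(names))
    if ofv is not None:
        frame["ofv"] = np.asarray(ofv, dtype=float)
    for key, col in extra_columns.items():
        frame[key] = col
    frame.to_csv(path, index=False)
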