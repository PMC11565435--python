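"""Delimited-text matrix I/O and the fitted-model bundle format.

Feature matrices are exchanged as CSV/TSV with samples as rows (header
optional); internally all math runs features-by-columns, so the readers
transpose.  A fitted model is stored as a directory bundle: hyperparameters
and metadata in ``model.json`` plus the projection, the two decision heads,
the class centers and the centering vector as CSV matrices, written with 17
significant digits so numeric round trips are exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import ClassCenters
from .model import EDPCState, Hyperparams

__all__ = [
    "read_matrix",
    "read_labels",
    "write_matrix",
    "write_labels",
    "save_model",
    "load_model",
]

_FMT = "%.17g"


class MatrixParseError(ValueError):
    """A delimited matrix file failed validation."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_matrix(path: str | Path, orientation: str = "rows") -> np.ndarray:
    """Read a delimited numeric matrix.

    ``orientation='rows'`` (default) declares samples as rows; the returned
    array is transposed to the internal features-by-samples layout.
    ``orientation='columns'`` reads the file as-is.  Non-numeric or NaN
    cells raise :class:`MatrixParseError` naming the offending coordinate.
    """
    path = Path(path)
    if orientation not in ("rows", "columns"):
        raise ValueError("orientation must be 'rows' or 'columns'")
    sep = _sniff_sep(path)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"{path}: ragged or malformed rows ({exc})") from exc
    # optional header row: drop it if any cell in row 0 is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise MatrixParseError(f"{path}: no data rows")
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(arr))
    if bad.size:
        i, j = bad[0]
        raise MatrixParseError(
            f"{path}: non-numeric or NaN cell at row {i + 1}, column {j + 1}"
        )
    return arr.T if orientation == "rows" else arr


def read_labels(path: str | Path, n_classes: int | None = None) -> np.ndarray:
    """Read a single-column file of 1-based integer class ids."""
    raw = read_matrix(path, orientation="columns")
    vec = raw.ravel()
    labels = vec.astype(int)
    if np.any(labels != vec):
        raise MatrixParseError(f"{path}: labels must be integers")
    if np.any(labels < 1):
        raise MatrixParseError(f"{path}: labels must be 1-based class ids")
    if n_classes is not None and np.any(labels > n_classes):
        raise MatrixParseError(
            f"{path}: label exceeds declared class count C={n_classes}"
        )
    return labels


def write_matrix(path: str | Path, X: np.ndarray, orientation: str = "rows") -> None:
    """Write a matrix as CSV at 17 significant digits (lossless round trip)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if orientation == "rows":
        X = X.T
    np.savetxt(path, X, delimiter=",", fmt=_FMT)


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int)[:, None], fmt="%d")


def labels_to_onehot(labels: np.ndarray, n_classes: int | None = None) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    C = n_classes or int(labels.max())
    Y = np.zeros((labels.size, C))
    Y[np.arange(labels.size), labels - 1] = 1.0
    return Y


def save_model(state: EDPCState, out_dir: str | Path) -> None:
    """Write the fitted-model bundle (JSON metadata + CSV matrices)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "format": "edpc-model-bundle/1",
        "hyperparams": state.hp.to_dict(),
        "n": state.n,
        "m": state.m,
        "C": state.C,
        "r": int(state.P.shape[1]),
        "d": int(state.P.shape[0]),
        "converged": bool(state.converged),
        "centers_delta": float(state.centers.delta),
        "kernel_mode": state.kernel_ref is not None,
        "objective_trace": [float(v) for v in state.objective_trace],
    }
    with open(out / "model.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    write_matrix(out / "P.csv", state.P, orientation="columns")
    write_matrix(out / "W.csv", state.W, orientation="columns")
    write_matrix(out / "Ws.csv", state.Ws, orientation="columns")
    write_matrix(out / "centers.csv", state.centers.mu, orientation="columns")
    write_matrix(out / "centering.csv", state.center_vec[:, None], orientation="columns")
    if state.kernel_ref is not None:
        write_matrix(out / "kernel_ref.csv", state.kernel_ref, orientation="columns")


def load_model(bundle_dir: str | Path) -> EDPCState:
    """Load a model bundle into a state usable by :func:`edpc.model.predict`."""
    bundle = Path(bundle_dir)
    with open(bundle / "model.json") as fh:
        meta = json.load(fh)
    if meta.get("format") != "edpc-model-bundle/1":
        raise ValueError(f"{bundle}: not an EDPC model bundle")
    hp = Hyperparams(**meta["hyperparams"])
    P = read_matrix(bundle / "P.csv", orientation="columns")
    W = read_matrix(bundle / "W.csv", orientation="columns")
    Ws = read_matrix(bundle / "Ws.csv", orientation="columns")
    mu = read_matrix(bundle / "centers.csv", orientation="columns")
    center_vec = read_matrix(bundle / "centering.csv", orientation="columns").ravel()
    kernel_ref = None
    if meta.get("kernel_mode"):
        kernel_ref = read_matrix(bundle / "kernel_ref.csv", orientation="columns")
    n, m, C = meta["n"], meta["m"], meta["C"]
    state = EDPCState(
        P=P,
        W=W,
        Ws=Ws,
        Lam=np.ones((n + m, C + 1)),
        Y=np.zeros((n + m, C)),
        pseudo_labels=np.ones(m, dtype=int),
        centers=ClassCenters(mu=mu, delta=meta["centers_delta"]),
        Mrep=None,  # not needed for prediction
        L=None,
        X=None,
        center_vec=center_vec,
        hp=hp,
        n=n,
        m=m,
        C=C,
        objective_trace=list(meta.get("objective_trace", [])),
        converged=bool(meta["converged"]),
        kernel_ref=kernel_ref,
    )
    return state
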