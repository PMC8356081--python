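"""Compact storage of A and the summary statistics reported on it.

Relationship matrices are symmetric and often written to disk; supported
representations are row-major packed lower-triangle vectors (element (i,j),
i >= j, 1-based, at position i(i-1)/2 + j), tabular-sparse triplet tables,
MatrixMarket coordinate files, and a small packed binary container.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "PackedLowerTriangle",
    "packed_index",
    "to_packed",
    "from_packed",
    "to_triplets",
    "from_triplets",
    "nrm_summary",
    "rmse_lower",
    "write_matrix",
    "read_matrix",
]

_MAGIC = b"NRMP"
_VERSION = 1


def packed_index(i: int, j: int, n: int | None = None) -> int:
    """1-based position of element (i, j), j <= i, in the packed vector."""
    if j > i or j < 1:
        raise ValueError(f"need 1 <= j <= i, got (i={i}, j={j})")
    if n is not None and i > n:
        raise ValueError(f"row {i} exceeds matrix size {n}")
    return i * (i - 1) // 2 + j


@dataclass(frozen=True)
class PackedLowerTriangle:
    """Row-major packed lower triangle of a symmetric n×n matrix."""

    n: int
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.ascontiguousarray(self.values, dtype=np.float64)
        )
        expect = self.n * (self.n + 1) // 2
        if self.values.size != expect:
            raise ValueError(
                f"packed vector has {self.values.size} entries, expected {expect}"
            )

    def __getitem__(self, ij: tuple[int, int]) -> float:
        i, j = ij
        if j > i:
            i, j = j, i
        return float(self.values[packed_index(i, j, self.n) - 1])


def to_packed(A: np.ndarray) -> PackedLowerTriangle:
    """Pack the lower triangle (incl. diagonal) of a symmetric matrix."""
    A = np.asarray(A)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("matrix must be square")
    idx = np.tril_indices(n)
    return PackedLowerTriangle(n=n, values=A[idx])


def from_packed(p: PackedLowerTriangle) -> np.ndarray:
    """Expand a packed lower triangle back to a dense symmetric matrix."""
    A = np.zeros((p.n, p.n))
    idx = np.tril_indices(p.n)
    A[idx] = p.values
    A[(idx[1], idx[0])] = p.values
    return A


def to_triplets(A, threshold: float = 0.0) -> pd.DataFrame:
    """Tabular-sparse form: lower-triangle entries with |value| > threshold.

    Returns a DataFrame with 1-based ``row >= col`` indices; exact zeros
    (and entries at or below the threshold) are dropped.
    """
    A = np.asarray(A.todense()) if sp.issparse(A) else np.asarray(A)
    i, j = np.tril_indices(A.shape[0])
    v = A[i, j]
    keep = np.abs(v) > threshold
    return pd.DataFrame(
        {"row": i[keep] + 1, "col": j[keep] + 1, "value": v[keep]}
    )


def from_triplets(t: pd.DataFrame, n: int) -> np.ndarray:
    """Dense symmetric matrix from a lower-triangle triplet table."""
    rows = t["row"].to_numpy() - 1
    cols = t["col"].to_numpy() - 1
    if np.any((rows < 0) | (rows >= n) | (cols < 0) | (cols >= n)):
        raise ValueError("triplet index outside 1..n")
    A = np.zeros((n, n))
    A[rows, cols] = t["value"].to_numpy()
    A[cols, rows] = t["value"].to_numpy()
    return A


def nrm_summary(A, zero_tol: float = 0.0) -> dict:
    """Off-diagonal sparsity (%), mean of nonzero off-diagonals, and max.

    Sparsity counts entries with |value| <= zero_tol over all n(n-1)
    off-diagonal positions; direct constructions produce exact zeros
    (relationships are dyadic rationals), solver output may need a small
    tolerance.
    """
    A = np.asarray(A.todense()) if sp.issparse(A) else np.asarray(A)
    n = A.shape[0]
    if n < 2:
        raise ValueError("need at least a 2x2 matrix")
    off = A[~np.eye(n, dtype=bool)]
    nonzero = np.abs(off) > zero_tol
    return {
        "n": n,
        "offdiag_sparsity_pct": 100.0 * float(np.mean(~nonzero)),
        "mean_nonzero_offdiag": float(off[nonzero].mean()) if nonzero.any() else 0.0,
        "max_offdiag": float(off.max()) if n > 1 else 0.0,
    }


def rmse_lower(A_est: np.ndarray, A_ref: np.ndarray) -> float:
    """Root mean squared error over the lower triangle, diagonal included."""
    A_est = np.asarray(A_est)
    A_ref = np.asarray(A_ref)
    if A_est.shape != A_ref.shape:
        raise ValueError("shape mismatch")
    i, j = np.tril_indices(A_est.shape[0])
    d = A_est[i, j] - A_ref[i, j]
    return float(np.sqrt(np.mean(d * d)))


def _write_packed_binary(A: np.ndarray, path: Path) -> None:
    p = to_packed(A)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<B", _VERSION))
        fh.write(struct.pack("<Q", p.n))
        fh.write(p.values.astype("<f8").tobytes())


def _read_packed_binary(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != _MAGIC:
            raise ValueError(f"{path}: not a packed relationship-matrix file")
        (version,) = struct.unpack("<B", fh.read(1))
        if version != _VERSION:
            raise ValueError(f"{path}: unsupported version {version}")
        (n,) = struct.unpack("<Q", fh.read(8))
        data = fh.read()
    expect = n * (n + 1) // 2 * 8
    if len(data) != expect:
        raise ValueError(f"{path}: truncated payload ({len(data)} of {expect} bytes)")
    values = np.frombuffer(data, dtype="<f8")
    return from_packed(PackedLowerTriangle(n=int(n), values=values))


def write_matrix(M, path, format: str = "matrixmarket") -> None:
    """Write a (symmetric) matrix: 'matrixmarket', 'packed_binary', 'triplet_tsv'.

    MatrixMarket uses coordinate/symmetric storage at full float64
    precision; triplet TSV stores the 1-based lower triangle; the packed
    binary container is magic 'NRMP', a version byte, little-endian uint64
    n, then the n(n+1)/2 row-major lower-triangle float64 values.
    """
    path = Path(path)
    if format == "matrixmarket":
        dense = np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M)
        coo = sp.coo_array(np.tril(dense))
        with open(path, "wb") as fh:  # mmwrite appends .mtx to bare paths
            scipy.io.mmwrite(fh, coo, symmetry="symmetric", precision=17)
    elif format == "packed_binary":
        dense = np.asarray(M.todense()) if sp.issparse(M) else np.asarray(M)
        _write_packed_binary(dense, path)
    elif format == "triplet_tsv":
        to_triplets(M).to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_matrix(path, format: str | None = None, sparse: bool = False):
    """Read a matrix written by :func:`write_matrix`.

    The format is sniffed from the file when not given. Returns a dense
    ndarray unless ``sparse`` (MatrixMarket only).
    """
    path = Path(path)
    if format is None:
        with open(path, "rb") as fh:
            head = fh.read(14)
        if head.startswith(_MAGIC):
            format = "packed_binary"
        elif head.startswith(b"%%MatrixMarket"):
            format = "matrixmarket"
        else:
            format = "triplet_tsv"
    if format == "matrixmarket":
        m = scipy.io.mmread(path)
        if sp.issparse(m):
            m = sp.csr_array(m)
            return m if sparse else np.asarray(m.todense())
        return np.asarray(m)
    if format == "packed_binary":
        return _read_packed_binary(path)
    if format == "triplet_tsv":
        t = pd.read_csv(path, sep="\t")
        n = int(max(t["row"].max(), t["col"].max()))
        return from_triplets(t, n)
    raise ValueError(f"unknown format {format!r}")
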