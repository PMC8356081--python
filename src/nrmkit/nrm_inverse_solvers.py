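"""Recovering A from its sparse inverse, and matrix-free products with A.

A⁻¹ is cheap to build directly from the pedigree (Henderson's rules) and is
extremely sparse; these routines go the other way: dense direct solve,
independent per-column solves A⁻¹x = e_i, preconditioned conjugate
gradients with the three diagonal preconditioners (Jacobi on A⁻¹, D, D0),
forward/backward substitution against the Cholesky factor of A⁻¹,
inversion via the Cholesky factor, and Colleau's linear-time product A·v
computed through the triangular factors without forming A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from joblib import Parallel, delayed

from . import kinship_factors as kf
from .pedigree_core import PedigreeTable

__all__ = [
    "nrm_solve",
    "nrm_solve_columns",
    "pcg",
    "PCGResult",
    "make_preconditioner",
    "nrm_pcg",
    "nrm_fbs",
    "nrm_chol_inv",
    "a_times_vector",
]


def _as_csc(ainv) -> sp.csc_array:
    m = sp.csc_array(ainv)
    if m.shape[0] != m.shape[1]:
        raise ValueError("A-inverse must be square")
    return m


def nrm_solve(ainv) -> np.ndarray:
    """Direct solve of A⁻¹·A = I via a sparse LU factorization."""
    ainv = _as_csc(ainv)
    lu = spla.splu(ainv.tocsc())
    return lu.solve(np.eye(ainv.shape[0]))


def nrm_solve_columns(ainv, workers: int = 1, chunk: int = 256) -> np.ndarray:
    """Column-wise solve: column i of A solves A⁻¹x = e_i.

    The factorization is computed once and shared read-only; columns are
    independent, so the result is identical for any worker count or
    completion order (columns are assembled by index).
    """
    ainv = _as_csc(ainv)
    n = ainv.shape[0]
    lu = spla.splu(ainv.tocsc())
    starts = range(0, n, chunk)

    def solve_chunk(lo: int) -> np.ndarray:
        e = np.zeros((n, min(chunk, n - lo)))
        e[lo : lo + e.shape[1]] = np.eye(e.shape[1])
        return lu.solve(e)

    if workers == 1:
        blocks = [solve_chunk(lo) for lo in starts]
    else:
        blocks = Parallel(n_jobs=workers, prefer="threads")(
            delayed(solve_chunk)(lo) for lo in starts
        )
    return np.hstack(blocks)


@dataclass(frozen=True)
class PCGResult:
    """Solution of one (preconditioned) conjugate-gradient solve."""

    x: np.ndarray
    iterations: int
    residual: float
    converged: bool


def pcg(
    ainv,
    b: np.ndarray,
    minv: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int | None = None,
    x0: np.ndarray | None = None,
) -> PCGResult:
    """Preconditioned conjugate gradient for A⁻¹x = b.

    ``minv`` is the diagonal of the preconditioner M⁻¹ (None = plain
    conjugate gradient). Convergence: Euclidean norm of the residual
    b − A⁻¹x below ``tol``. Non-convergence is reported in the result,
    not raised.
    """
    ainv = sp.csr_array(ainv)
    n = b.size
    if max_iter is None:
        max_iter = 10 * n
    if minv is not None:
        minv = np.asarray(minv, dtype=float)
        if np.any(minv <= 0):
            raise ValueError("preconditioner diagonal must be positive")
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    r = b - ainv @ x
    z = r if minv is None else minv * r
    p = z.copy()
    rz = float(r @ z)
    res = float(np.linalg.norm(r))
    it = 0
    while res >= tol and it < max_iter:
        q = ainv @ p
        alpha = rz / float(p @ q)
        x += alpha * p
        r -= alpha * q
        z = r if minv is None else minv * r
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
        res = float(np.linalg.norm(r))
        it += 1
    return PCGResult(x=x, iterations=it, residual=res, converged=res < tol)


def make_preconditioner(
    kind: str,
    ainv=None,
    ped: PedigreeTable | None = None,
    F: np.ndarray | None = None,
) -> np.ndarray | None:
    """Diagonal of M⁻¹ for :func:`pcg`.

    'jacobi': 1/diag(A⁻¹); 'D': Mendelian sampling variances (needs the
    pedigree, and F unless it should be computed); 'D0': the
    inbreeding-free variant; 'none': no preconditioning.
    """
    if kind == "none":
        return None
    if kind == "jacobi":
        if ainv is None:
            raise ValueError("jacobi preconditioner needs A-inverse")
        diag = sp.csr_array(ainv).diagonal()
        if np.any(diag == 0):
            raise ValueError("zero diagonal in A-inverse")
        return 1.0 / diag
    if kind in ("D", "d"):
        if ped is None:
            raise ValueError("preconditioner D needs the pedigree")
        return kf.build_d(ped, F)
    if kind in ("D0", "d0"):
        if ped is None:
            raise ValueError("preconditioner D0 needs the pedigree")
        return kf.build_d0(ped)
    raise ValueError(f"unknown preconditioner kind {kind!r}")


def nrm_pcg(
    ainv,
    minv: np.ndarray | None = None,
    tol: float = 1e-5,
    max_iter: int | None = None,
    workers: int = 1,
    symmetrize: bool = False,
) -> tuple[np.ndarray, dict]:
    """A column by column via PCG on A⁻¹x = e_i.

    Every column starts cold from x0 = e_i (no warm start from previously
    solved columns), keeping columns independent and the result invariant
    to scheduling. Returns (A, info) with per-column iteration counts and
    the indices of any non-converged columns.
    """
    ainv = sp.csr_array(ainv)
    n = ainv.shape[0]

    def solve_col(i: int) -> PCGResult:
        b = np.zeros(n)
        b[i] = 1.0
        return pcg(ainv, b, minv=minv, tol=tol, max_iter=max_iter, x0=b)

    if workers == 1:
        results = [solve_col(i) for i in range(n)]
    else:
        results = Parallel(n_jobs=workers, prefer="threads")(
            delayed(solve_col)(i) for i in range(n)
        )
    A = np.column_stack([r.x for r in results])
    if symmetrize:
        A = (A + A.T) / 2.0
    info = {
        "iterations": np.array([r.iterations for r in results]),
        "failed_columns": [i for i, r in enumerate(results) if not r.converged],
    }
    return A, info


def nrm_fbs(ainv) -> np.ndarray:
    """Forward/backward substitution against the Cholesky factor of A⁻¹.

    With A⁻¹ = KK' (K lower triangular), each column solves Kc = e_i then
    K'x = c; the triangular solves are batched over all columns.
    """
    ainv = _as_csc(ainv)
    K = np.linalg.cholesky(ainv.todense())
    C = scipy.linalg.solve_triangular(K, np.eye(ainv.shape[0]), lower=True)
    return scipy.linalg.solve_triangular(K.T, C, lower=False)


def nrm_chol_inv(ainv) -> np.ndarray:
    """Inversion from the Cholesky decomposition A⁻¹ = U'U.

    A = U⁻¹(U⁻¹)' computed by LAPACK's triangular inverse-and-multiply
    (dpotri), which fills one triangle; the result is mirrored.
    """
    ainv = _as_csc(ainv)
    U = np.linalg.cholesky(ainv.todense()).T  # upper factor
    inv, info = scipy.linalg.lapack.dpotri(U, lower=0)
    if info != 0:
        raise np.linalg.LinAlgError(f"dpotri failed with code {info}")
    return np.triu(inv) + np.triu(inv, 1).T


def a_times_vector(
    ped: PedigreeTable,
    v: np.ndarray,
    F: np.ndarray | None = None,
) -> np.ndarray:
    """Colleau's indirect product A·v in time linear in the pedigree size.

    Uses A = T D T' through the sparse factor T⁻¹ only: u = T'v by back
    substitution against (T⁻¹)', scaling by D, then T·(Du) by forward
    substitution against T⁻¹. A is never formed.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != ped.n:
        raise ValueError("vector length does not match pedigree")
    tinv = kf.build_tinv(ped)
    D = kf.build_d(ped, F)
    u = spla.spsolve_triangular(
        tinv.T.tocsr(), v, lower=False, unit_diagonal=True
    )
    if u.ndim == 1:
        u = u * D
    else:
        u = u * D[:, None]
    return spla.spsolve_triangular(tinv.tocsr(), u, lower=True, unit_diagonal=True)
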