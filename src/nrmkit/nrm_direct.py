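"""Direct pedigree constructions of the numerator relationship matrix A.

Seven routes to the same matrix: the element-wise tabular recurrence, its
vectorized column (array) form, Thompson's A = TDT' (with T built by
recurrence or by inverting T⁻¹), iterative updating of D without inbreeding
coefficients, Henderson's A = LL', and generation-by-generation enlargement.
All return a dense symmetric ndarray with diag(A) = 1 + F; the tabular
method is the reference oracle for the others. Block extraction and the
dummy-progeny relationship avoid forming the full matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import kinship_factors as kf
from .pedigree_core import PedigreeTable, append_individual, stratify_generations

__all__ = [
    "nrm_tabular",
    "nrm_tabular_array",
    "nrm_tdt",
    "nrm_tdt_via_tinv",
    "nrm_iter_d",
    "nrm_llt",
    "nrm_by_generation",
    "nrm_block",
    "relationship_dummy_progeny",
    "IterDState",
]


def nrm_tabular(ped: PedigreeTable) -> np.ndarray:
    """Element-wise tabular method.

    Looping over rows j and columns i < j:
    A_ij = (A_si + A_di)/2 (unknown parent contributes 0) and
    A_jj = 1 + A_sd/2 when both parents are known. n(n+1)/2 scalar steps;
    simple, and the correctness oracle for every other construction.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j] - 1, ped.dam[j] - 1
        for i in range(j):
            a = 0.0
            if s >= 0:
                a += A[s, i]
            if d >= 0:
                a += A[d, i]
            a /= 2.0
            A[i, j] = A[j, i] = a
        A[j, j] = 1.0 + (A[s, d] / 2.0 if (s >= 0 and d >= 0) else 0.0)
    return A


def nrm_tabular_array(ped: PedigreeTable) -> np.ndarray:
    """Array-tabular method: one vectorized slice per individual.

    The relationships of j with all predecessors are formed in a single
    operation as the half-sum of the sire and dam slices, replacing the
    inner column loop of :func:`nrm_tabular`; results are identical.
    """
    n = ped.n
    A = np.zeros((n, n))
    for j in range(n):
        s, d = ped.sire[j] - 1, ped.dam[j] - 1
        if s >= 0 or d >= 0:
            col = A[:j, s] if s >= 0 else np.zeros(j)
            if d >= 0:
                col = col + A[:j, d] if s >= 0 else A[:j, d]
            col = col / 2.0
            A[:j, j] = col
            A[j, :j] = col
        A[j, j] = 1.0 + (A[s, d] / 2.0 if (s >= 0 and d >= 0) else 0.0)
    return A


def nrm_tdt(ped: PedigreeTable, F: np.ndarray | None = None) -> np.ndarray:
    """Thompson's method: A = T·D·T' with T from the row recurrence."""
    T = kf.build_t(ped, method="recurrence")
    D = kf.build_d(ped, F)
    return np.asarray((T @ sp.diags_array(D) @ T.T).todense())


def nrm_tdt_via_tinv(ped: PedigreeTable, F: np.ndarray | None = None) -> np.ndarray:
    """Thompson's method with T obtained by sparse inversion of T⁻¹.

    T⁻¹ = I − J is assembled in one pass with no row dependencies; the
    price is a triangular inversion before the TDT' product.
    """
    T = kf.build_t(ped, method="invert")
    D = kf.build_d(ped, F)
    return np.asarray((T @ sp.diags_array(D) @ T.T).todense())


@dataclass
class IterDState:
    """Progress of the iterative-D construction."""

    iterations: int
    converged: bool
    tol: float
    d: np.ndarray  # final Mendelian sampling variances
    max_diag_excess: float  # max_j A_jj − candidate_j at the last sweep


def nrm_iter_d(
    ped: PedigreeTable,
    tol: float = 1e-5,
    max_iter: int | None = None,
) -> tuple[np.ndarray, IterDState]:
    """Thompson's method with D updated iteratively, no F required.

    Starts from D0 (inbreeding ignored) and alternates A = TDT' with
    diagonal updates: the candidate diagonal is 1 + 2·diag(Js·A·Jd'), i.e.
    1 + A_sd/2 per individual. D_jj is reset to 1 − (A_ss + A_dd)/4
    (unknown parents contribute 0) for individuals whose diagonal still
    exceeds its candidate while both parents' diagonals have stabilized —
    inbreeding propagates one generation per sweep. Stops when no diagonal
    exceeds its candidate by more than ``tol``.
    """
    n = ped.n
    T = np.asarray(kf.build_t(ped).todense())
    d = kf.build_d0(ped).astype(float)
    s0, d0 = ped.sire - 1, ped.dam - 1
    both = (s0 >= 0) & (d0 >= 0)
    if max_iter is None:
        max_iter = stratify_generations(ped).n_generations + 5

    A = np.empty((n, n))
    state = IterDState(0, False, tol, d, np.inf)
    for it in range(1, max_iter + 1):
        A = (T * d) @ T.T
        diag = np.diagonal(A)
        # candidate diagonal: 1 + A_sd/2 where both parents known, else 1
        candidate = np.ones(n)
        candidate[both] = 1.0 + 0.5 * A[s0[both], d0[both]]
        excess = diag - candidate
        state = IterDState(it, bool(np.max(excess) <= tol), tol, d, float(np.max(excess)))
        if state.converged:
            break
        # parent diagonals stable (unknown parent counts as stable, A_pp = 0)
        stable = np.abs(excess) <= tol
        p_stable = np.ones(n, dtype=bool)
        p_diag_sum = np.zeros(n)
        for par in (s0, d0):
            known = par >= 0
            p_stable[known] &= stable[par[known]]
            p_diag_sum[known] += diag[par[known]]
        update = (excess > tol) & p_stable
        d = d.copy()
        d[update] = 1.0 - p_diag_sum[update] / 4.0
        state.d = d
    if not state.converged:
        raise RuntimeError(
            f"iterative D did not converge in {max_iter} sweeps "
            f"(max diagonal excess {state.max_diag_excess:.3g})"
        )
    return A, state


def nrm_llt(ped: PedigreeTable) -> np.ndarray:
    """Henderson's method: A = L·L' from the indirect Cholesky factor."""
    L = kf.build_l(ped)
    return np.asarray((L @ L.T).todense())


def nrm_by_generation(ped: PedigreeTable) -> np.ndarray:
    """Enlarge A generation by generation.

    A over the base generation is the identity. For generation i the
    cross block is J_i·A_{i−1} and the within block J_i·A_{i−1}·J_i' plus
    the diagonal residual o = 1 + 2·diag(Js·A·Jd') − diag(J·A·J'). The
    incidence products reduce to row gathers: each progeny row is the
    half-sum of its parents' rows, so no J matrix is ever formed.
    """
    n = ped.n
    strata = stratify_generations(ped)
    gen = strata.gen
    # work in generation order (parents precede progeny a fortiori), then
    # permute back, so individuals of one generation occupy a contiguous block
    perm = np.argsort(gen, kind="stable")
    rank = np.empty(n, dtype=np.int64)
    rank[perm] = np.arange(n)
    sire = np.where(ped.sire > 0, rank[ped.sire - 1] + 1, 0)[perm]
    dam = np.where(ped.dam > 0, rank[ped.dam - 1] + 1, 0)[perm]
    gen_sorted = gen[perm]

    A = np.zeros((n, n))
    n_base = int(np.sum(gen_sorted == 0))
    A[np.arange(n_base), np.arange(n_base)] = 1.0
    for g in range(1, strata.n_generations):
        g_ids0 = np.nonzero(gen_sorted == g)[0]
        m = int(g_ids0[0])  # prior individuals are 0..m-1
        s0 = sire[g_ids0] - 1
        d0 = dam[g_ids0] - 1
        # cross block J_i A_{i-1}: gather parent rows over prior columns
        R = np.zeros((g_ids0.size, m))
        ks = s0 >= 0
        kd = d0 >= 0
        R[ks] += 0.5 * A[s0[ks], :m]
        R[kd] += 0.5 * A[d0[kd], :m]
        # within block J_i A J_i' by gathering columns of the cross block
        W = np.zeros((g_ids0.size, g_ids0.size))
        W[:, ks] += 0.5 * R[:, s0[ks]]
        W[:, kd] += 0.5 * R[:, d0[kd]]
        # o = 1 + 2 diag(Js A Jd') - diag(J A J')
        o = 1.0 - np.diagonal(W).copy()
        both = ks & kd
        o[both] += 0.5 * A[s0[both], d0[both]]
        A[g_ids0, :m] = R
        A[:m, g_ids0] = R.T
        A[np.ix_(g_ids0, g_ids0)] = W + np.diag(o)
    return A[np.ix_(rank, rank)]


def nrm_block(
    ped: PedigreeTable,
    rows,
    cols,
    F: np.ndarray | None = None,
    method: str = "thompson",
) -> np.ndarray:
    """A[rows, cols] without forming the full matrix.

    ``method='thompson'`` computes T[rows]·D·T[cols]', ``'henderson'``
    computes L[rows]·L[cols]'; rows/cols are 1-based id sequences.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    if rows.size == 0 or cols.size == 0:
        raise ValueError("empty row or column id set")
    for idx in (rows, cols):
        if np.any((idx < 1) | (idx > ped.n)):
            raise ValueError("id outside pedigree")
    if method == "thompson":
        T = kf.build_t(ped)
        D = sp.diags_array(kf.build_d(ped, F))
        block = T[rows - 1, :] @ D @ T[cols - 1, :].T
    elif method == "henderson":
        L = kf.build_l(ped)
        block = L[rows - 1, :] @ L[cols - 1, :].T
    else:
        raise ValueError(f"unknown method {method!r}")
    return np.asarray(block.todense())


def relationship_dummy_progeny(ped: PedigreeTable, i: int, j: int) -> float:
    """A_ij as twice the inbreeding coefficient of a dummy progeny of i and j.

    Appends a phantom individual with parents i and j, computes its F and
    returns 2F; the input pedigree is left unmodified. Undefined for i = j.
    """
    if i == j:
        raise ValueError("relationship via dummy progeny requires two individuals")
    for k in (i, j):
        if not 1 <= k <= ped.n:
            raise ValueError(f"id {k} outside pedigree")
    extended = append_individual(ped, i, j)
    return 2.0 * float(kf.inbreeding(extended)[-1])
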