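"""Sparse Cholesky factorization with a reusable symbolic analysis.

The Gibbs sampler refactorizes the latent-field precision matrix once per
iteration; only its numerical values change, never its sparsity pattern.
We therefore separate the work: ordering (fill-reducing permutation via
SuperLU's minimum-degree on A^T+A), symbolic analysis (elimination tree and
column counts) and a numba-compiled up-looking numeric factorization that
is re-run per iteration, plus triangular solves for conditional means and
for sampling N(0, Q^-1) via L^-T z.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


@njit(cache=True)
def _etree(n, Ap, Ai):
    parent = np.full(n, -1, np.int64)
    ancestor = np.full(n, -1, np.int64)
    for k in range(n):
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i != -1 and i < k:
                inext = ancestor[i]
                ancestor[i] = k
                if inext == -1:
                    parent[i] = k
                i = inext
    return parent


@njit(cache=True)
def _ereach(n, k, Ap, Ai, parent, s, w):
    """Pattern of row k of L (topological order) in s[top:n]; w is a
    version-stamped visited marker (w[i] == k means visited this row)."""
    top = n
    w[k] = k
    for p in range(Ap[k], Ap[k + 1]):
        i = Ai[p]
        if i > k:
            continue
        ln = 0
        while w[i] != k:
            s[ln] = i
            ln += 1
            w[i] = k
            i = parent[i]
        while ln > 0:
            ln -= 1
            top -= 1
            s[top] = s[ln]
    return top


@njit(cache=True)
def _row_patterns(n, Ap, Ai, parent, s, w):
    """Flattened row patterns of L (excluding the diagonal), topological
    order per row: returns (rowptr, rowidx)."""
    counts = np.zeros(n, np.int64)
    for k in range(n):
        top = _ereach(n, k, Ap, Ai, parent, s, w)
        counts[k] = n - top
    rowptr = np.zeros(n + 1, np.int64)
    rowptr[1:] = np.cumsum(counts)
    rowidx = np.empty(rowptr[n], np.int64)
    for i in range(n):
        w[i] = -1
    for k in range(n):
        top = _ereach(n, k, Ap, Ai, parent, s, w)
        base = rowptr[k]
        for t in range(top, n):
            rowidx[base + (t - top)] = s[t]
    return rowptr, rowidx


@njit(cache=True, fastmath=True)
def _chol_numeric(n, Ap, Ai, Ax, rowptr, rowidx, Lp, Li, Lx, c, x):
    """Up-looking Cholesky of the (full symmetric) CSC matrix A into the
    preallocated CSC skeleton L, using precomputed row patterns.  Returns
    -(k+1) if the leading (k+1)-minor is not positive definite, else 0."""
    for k in range(n):
        c[k] = Lp[k]
    for k in range(n):
        x[k] = 0.0
        for p in range(Ap[k], Ap[k + 1]):
            if Ai[p] <= k:
                x[Ai[p]] = Ax[p]
        d = x[k]
        x[k] = 0.0
        for t in range(rowptr[k], rowptr[k + 1]):
            i = rowidx[t]
            lki = x[i] / Lx[Lp[i]]
            x[i] = 0.0
            for p in range(Lp[i] + 1, c[i]):
                x[Li[p]] -= Lx[p] * lki
            d -= lki * lki
            p = c[i]
            c[i] += 1
            Li[p] = k
            Lx[p] = lki
        if d <= 0.0:
            return -(k + 1)
        p = c[k]
        c[k] += 1
        Li[p] = k
        Lx[p] = np.sqrt(d)
    return 0


@njit(cache=True)
def _lsolve(n, Lp, Li, Lx, x):
    """x := L^-1 x (diagonal entry stored first in each column)."""
    for j in range(n):
        x[j] /= Lx[Lp[j]]
        xj = x[j]
        for p in range(Lp[j] + 1, Lp[j + 1]):
            x[Li[p]] -= Lx[p] * xj


@njit(cache=True)
def _ltsolve(n, Lp, Li, Lx, x):
    """x := L^-T x."""
    for j in range(n - 1, -1, -1):
        acc = x[j]
        for p in range(Lp[j] + 1, Lp[j + 1]):
            acc -= Lx[p] * x[Li[p]]
        x[j] = acc / Lx[Lp[j]]


@njit(cache=True)
def _bsearch(Li, lo, hi, r):
    while lo < hi:
        mid = (lo + hi) // 2
        if Li[mid] < r:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _takahashi_plan(n, Lp, Li):
    """Precomputed lookup positions for the Takahashi recursion: for each
    column j (descending), each target row i (descending) and each k in
    column j, the storage position of S(k, i).  Pattern-determined, so it is
    built once and reused across numeric passes."""
    total = 0
    for j in range(n):
        cj = Lp[j + 1] - Lp[j]
        total += cj * (cj - 1)
    pos = np.empty(total, np.int64)
    t = 0
    for j in range(n - 1, -1, -1):
        pj0 = Lp[j]
        pj1 = Lp[j + 1]
        for pi in range(pj1 - 1, pj0 - 1, -1):
            i = Li[pi]
            for pk in range(pj0 + 1, pj1):
                k = Li[pk]
                if k == i:
                    pos[t] = Lp[i]
                elif k < i:
                    pos[t] = _bsearch(Li, Lp[k], Lp[k + 1], i)
                else:
                    pos[t] = _bsearch(Li, Lp[i], Lp[i + 1], k)
                t += 1
    return pos


@njit(cache=True, fastmath=True)
def _takahashi(n, Lp, Lx, Sx, pos):
    """Partial inverse (Takahashi equations): entries of S = (L L^T)^-1 on
    the pattern of L, stored in Sx parallel to L's CSC storage."""
    t = 0
    for j in range(n - 1, -1, -1):
        pj0 = Lp[j]
        pj1 = Lp[j + 1]
        ljj = Lx[pj0]
        inv_dj = 1.0 / (ljj * ljj)
        for pi in range(pj1 - 1, pj0 - 1, -1):
            acc = 0.0
            for pk in range(pj0 + 1, pj1):
                acc += (Lx[pk] / ljj) * Sx[pos[t]]
                t += 1
            if pi == pj0:
                Sx[pi] = inv_dj - acc
            else:
                Sx[pi] = -acc


class SparseCholesky:
    """Repeated Cholesky factorizations over one fixed sparsity pattern.

    Parameters
    ----------
    representative
        A symmetric positive-definite CSC matrix carrying the pattern (full
        symmetric storage).  Its values are used once to choose the
        fill-reducing permutation when none is supplied.
    perm
        Optional explicit fill-reducing permutation (new order = old[perm]).
        Pedigree precision matrices factor with near-zero fill in reverse
        pedigree order, so callers that know the pedigree should pass that
        ordering rather than rely on generic minimum degree.
    """

    def __init__(self, representative: sp.csc_matrix, perm=None):
        Q = representative.tocsc()
        Q.sort_indices()
        n = Q.shape[0]
        self.n = n
        if perm is None:
            lu = sp.linalg.splu(Q, permc_spec="MMD_AT_PLUS_A",
                                options={"SymmetricMode": True})
            perm = np.asarray(lu.perm_c)
        self.perm = np.asarray(perm, dtype=np.int64)
        self.iperm = np.empty(n, dtype=np.int64)
        self.iperm[self.perm] = np.arange(n)

        coo = Q.tocoo()
        reorder = sp.coo_matrix(
            (np.arange(coo.nnz, dtype=np.int64) + 1,
             (self.iperm[coo.row], self.iperm[coo.col])), shape=(n, n)).tocsc()
        reorder.sort_indices()
        self._value_map = reorder.data.astype(np.int64) - 1
        self._Ap = reorder.indptr.astype(np.int64)
        self._Ai = reorder.indices.astype(np.int64)
        self._Ax = np.empty(coo.nnz)
        self._s = np.empty(n, dtype=np.int64)
        self._w = np.full(n, -1, dtype=np.int64)
        self._c = np.empty(n, dtype=np.int64)
        self._x = np.zeros(n)
        self.parent = _etree(n, self._Ap, self._Ai)
        self._rowptr, self._rowidx = _row_patterns(
            n, self._Ap, self._Ai, self.parent, self._s, self._w)
        col_counts = np.ones(n, dtype=np.int64)
        np.add.at(col_counts, self._rowidx, 1)
        self.Lp = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(col_counts, out=self.Lp[1:])
        self.Li = np.empty(self.Lp[-1], dtype=np.int64)
        self.Lx = np.empty(self.Lp[-1])
        self.nnz_L = int(self.Lp[-1])
        self._tak_pos = None
        self._factored = False

    def factor(self, values: np.ndarray) -> None:
        """Numeric factorization; ``values`` aligned to the pattern's
        CSC data order (sorted indices)."""
        self._Ax[:] = values[self._value_map]
        info = _chol_numeric(self.n, self._Ap, self._Ai, self._Ax,
                             self._rowptr, self._rowidx,
                             self.Lp, self.Li, self.Lx, self._c, self._x)
        if info != 0:
            raise NotPositiveDefiniteError(
                f"matrix not positive definite at pivot {-info}")
        self._factored = True

    def solve(self, b: np.ndarray) -> np.ndarray:
        x = b[self.perm].astype(float)
        _lsolve(self.n, self.Lp, self.Li, self.Lx, x)
        _ltsolve(self.n, self.Lp, self.Li, self.Lx, x)
        return x[self.iperm]

    def solve_and_sample(self, b: np.ndarray, rng) -> np.ndarray:
        """One draw from N(Q^-1 b, Q^-1) using the current factor."""
        return self.solve(b) + self.sample_zero_mean(rng)

    def sample_zero_mean(self, rng) -> np.ndarray:
        """One draw from N(0, Q^-1) via a back-substitution of white noise."""
        u = rng.standard_normal(self.n)
        _ltsolve(self.n, self.Lp, self.Li, self.Lx, u)
        return u[self.iperm]

    def clone(self) -> "SparseCholesky":
        """A second factor over the same pattern (shared symbolic arrays,
        private numeric buffers) -- lets a Metropolis step keep the current
        factor while factorizing a proposal."""
        other = object.__new__(SparseCholesky)
        for attr in ("n", "perm", "iperm", "_value_map", "_Ap", "_Ai",
                     "_s", "_w", "parent", "_rowptr", "_rowidx",
                     "Lp", "Li", "nnz_L"):
            setattr(other, attr, getattr(self, attr))
        other._Ax = np.empty_like(self._Ax)
        other.Lx = np.empty_like(self.Lx)
        other._c = np.empty_like(self._c)
        other._x = np.zeros_like(self._x)
        other._tak_pos = getattr(self, "_tak_pos", None)
        other._factored = False
        return other

    def logdet(self) -> float:
        """log det Q = 2 sum log diag L."""
        return 2.0 * float(np.sum(np.log(self.Lx[self.Lp[:-1]])))

    def partial_inverse(self) -> np.ndarray:
        """Entries of Q^-1 on the factor's pattern (permuted indices),
        parallel to the CSC storage of L (Takahashi equations)."""
        if getattr(self, "_tak_pos", None) is None:
            self._tak_pos = _takahashi_plan(self.n, self.Lp, self.Li)
        Sx = np.empty_like(self.Lx)
        _takahashi(self.n, self.Lp, self.Lx, Sx, self._tak_pos)
        return Sx

    def pattern_position(self, row: int, col: int) -> int:
        """Storage position of entry (row, col), permuted indices, row >= col
        in the lower factor; -1 if absent from the pattern."""
        r, c = (row, col) if row >= col else (col, row)
        p = int(_bsearch(self.Li, self.Lp[c], self.Lp[c + 1], r))
        if p < self.Lp[c + 1] and self.Li[p] == r:
            return p
        return -1

    def entry_positions(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`pattern_position` over ORIGINAL (unpermuted)
        index pairs."""
        pr = self.iperm[np.asarray(rows)]
        pc = self.iperm[np.asarray(cols)]
        lo = np.minimum(pr, pc)
        hi = np.maximum(pr, pc)
        out = np.empty(len(lo), dtype=np.int64)
        for t in range(len(lo)):
            out[t] = self.pattern_position(int(hi[t]), int(lo[t]))
        return out


def aligned_values(component: sp.spmatrix, pattern: sp.csc_matrix) -> np.ndarray:
    """Values of ``component`` scattered into the CSC data order of
    ``pattern`` (whose sparsity must contain the component's)."""
    C = component.tocsc()
    C.sort_indices()
    out = np.zeros(pattern.nnz)
    Pp, Pi = pattern.indptr, pattern.indices
    for j in range(pattern.shape[1]):
        cs, ce = C.indptr[j], C.indptr[j + 1]
        if cs == ce:
            continue
        ps, pe = Pp[j], Pp[j + 1]
        pos = ps + np.searchsorted(Pi[ps:pe], C.indices[cs:ce])
        if np.any(Pi[pos] != C.indices[cs:ce]):
            raise ValueError("component pattern not contained in target pattern")
        out[pos] = C.data[cs:ce]
    return out
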