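"""Autosomal (A) and sex-linked (Z) relationship matrices and their sparse inverses.

A is the numerator relationship matrix: twice the coefficient of coancestry
for autosomal loci.  Z is its sex-chromosome analogue, in units of the
base-population additive variance of the homogametic sex (males under ZW).
Transmission differs from the autosomal case: under ZW a female carries a
single Z received from her sire, while a male receives one Z from his sire
and his dam's single Z in full.  Consequently noninbred females have
Z-diagonal 1/2 (exactly 1/2 for every female, inbred or not) and noninbred
males 1.

Both inverses are sparse with the pedigree pattern (self, parent-offspring,
mates) because offspring values are conditionally independent given parents;
they are assembled from Mendelian-sampling variances, Henderson-style.
A Monte-Carlo gene-dropping oracle is provided to validate Z independently
of the recursions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree_io import FEMALE, MALE, Pedigree, PedigreeError

DENSE_GUARD = 5000
GENE_DROP_GUARD = 500


@dataclass
class SparseSPD:
    """A symmetric positive-definite sparse matrix tied to pedigree ids."""

    n: int
    matrix: sp.csc_matrix           # full symmetric storage
    ids: np.ndarray

    def to_triplets(self) -> np.ndarray:
        """(row, col, value) with 1-based indices, one unordered pair per line."""
        coo = sp.triu(self.matrix).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order] + 1, coo.col[order] + 1,
                                coo.data[order]])

    def write_triplets(self, path, id_map_path=None) -> None:
        trips = self.to_triplets()
        with open(path, "w") as fh:
            for r, c, v in trips:
                fh.write(f"{int(r)} {int(c)} {float(v)!r}\n")
        if id_map_path is not None:
            with open(id_map_path, "w") as fh:
                for k, iid in enumerate(self.ids):
                    fh.write(f"{k + 1} {iid}\n")

    @classmethod
    def read_triplets(cls, path, id_map_path=None) -> "SparseSPD":
        rows, cols, vals = [], [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                r, c, v = line.split()
                rows.append(int(r) - 1)
                cols.append(int(c) - 1)
                vals.append(float(v))
        n = max(max(rows), max(cols)) + 1 if rows else 0
        upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        full = upper + sp.triu(upper, k=1).T
        ids = np.arange(1, n + 1).astype(object)
        if id_map_path is not None:
            pairs = {}
            with open(id_map_path) as fh:
                for line in fh:
                    if line.strip():
                        k, iid = line.split(None, 1)
                        pairs[int(k) - 1] = iid.strip()
            ids = np.array([pairs[k] for k in range(n)], dtype=object)
        return cls(n=n, matrix=full.tocsc(), ids=ids)

    def check_spd(self) -> bool:
        lu = sp.linalg.splu(self.matrix.tocsc(), permc_spec="MMD_AT_PLUS_A",
                            diag_pivot_thresh=0.0,
                            options={"SymmetricMode": True})
        return bool(np.all(lu.U.diagonal() > 0))


@dataclass
class RelationshipTable:
    """Dense relationship coefficients (small-pedigree oracle)."""

    n: int
    values: np.ndarray
    ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# path-coefficient machinery
#
# Both A and Z admit a gene-flow decomposition x = L phi with independent
# Mendelian innovations phi (Var phi_j = mendel_j), where row i of the unit
# lower-triangular L holds the expected transmission coefficients from every
# ancestor.  Covariances restricted to an ancestor set follow as
# x_i x_k = sum_j L_ij L_kj mendel_j, which we evaluate by an upward walk --
# exact, and never needs dense n x n storage.

def _expand_row(start, p1, p2, c1, c2):
    """Accumulated path coefficients L[start, j] for all ancestors j of start.

    p1/p2: parent position arrays (-1 unknown); c1/c2: per-individual
    transmission coefficients toward p1/p2.
    """
    acc = {start: 1.0}
    out = {}
    heap = [-start]
    while heap:
        j = -heapq.heappop(heap)
        if j in out:
            continue
        c = acc.pop(j)
        out[j] = c
        for p, cc in ((p1[j], c1[j]), (p2[j], c2[j])):
            if p >= 0 and cc != 0.0:
                if p not in acc:
                    acc[p] = 0.0
                    heapq.heappush(heap, -int(p))
                acc[p] += c * cc
    return out


def _path_covariance(i, k, p1, p2, c1, c2, mendel):
    ri = _expand_row(i, p1, p2, c1, c2)
    rk = _expand_row(k, p1, p2, c1, c2) if k != i else ri
    if len(rk) < len(ri):
        ri, rk = rk, ri
    return sum(c * rk[j] * mendel[j] for j, c in ri.items() if j in rk)


# ---------------------------------------------------------------------------
# autosomal

def inbreeding_coefficients(ped: Pedigree) -> np.ndarray:
    """Autosomal inbreeding coefficients F_i = A(sire, dam)/2; founders 0.

    Computed by exact ancestor-restricted path walks, so it scales to large
    pedigrees without dense storage.
    """
    n = ped.n
    F = np.zeros(n)
    mendel = np.zeros(n)  # Mendelian sampling variance in units of sigma2_a
    half_s = np.where(ped.sire >= 0, 0.5, 0.0)
    half_d = np.where(ped.dam >= 0, 0.5, 0.0)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            a_sd = _path_covariance(s, d, ped.sire, ped.dam, half_s, half_d, mendel)
            F[i] = 0.5 * a_sd
            mendel[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mendel[i] = 0.75 - 0.25 * F[p]
        else:
            mendel[i] = 1.0
    return F


def autosomal_mendelian_variances(ped: Pedigree, F=None) -> np.ndarray:
    """Var of the autosomal Mendelian-sampling deviation, in units of sigma2_a."""
    if F is None:
        F = inbreeding_coefficients(ped)
    n = ped.n
    v = np.empty(n)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            v[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            v[i] = 0.75 - 0.25 * F[s if s >= 0 else d]
        else:
            v[i] = 1.0
    return v


def build_A(ped: Pedigree, max_n: int = DENSE_GUARD) -> RelationshipTable:
    """Dense numerator relationship matrix by the tabular recursion (oracle)."""
    n = ped.n
    if n > max_n:
        raise PedigreeError(f"dense A guard exceeded: n={n} > {max_n}")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipTable(n=n, values=A, ids=ped.ids)


def build_A_inverse(ped: Pedigree) -> SparseSPD:
    """Sparse A^-1 from Mendelian-sampling variances (Henderson's rules,
    exact for inbred pedigrees via the inbreeding coefficients)."""
    F = inbreeding_coefficients(ped)
    v = autosomal_mendelian_variances(ped, F)
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        parents = [(p, 0.5) for p in (ped.sire[i], ped.dam[i]) if p >= 0]
        w = 1.0 / v[i]
        rows.append(i); cols.append(i); vals.append(w)
        for p, c in parents:
            rows += [i, p]; cols += [p, i]; vals += [-c * w, -c * w]
        for p, c in parents:
            for q, e in parents:
                rows.append(p); cols.append(q); vals.append(c * e * w)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsc()
    mat.eliminate_zeros()   # exact cancellations (e.g. parent-offspring mating)
    return SparseSPD(n=ped.n, matrix=mat, ids=ped.ids)


# ---------------------------------------------------------------------------
# sex-linked

def _z_roles(ped: Pedigree):
    """Transmission structure for the shared sex chromosome.

    hom_parent is the parent with two copies of the shared chromosome (the
    sire under ZW, the dam under XY) and transmits a random one of them
    (coefficient 1/2).  het_parent carries a single copy and transmits it in
    full (coefficient 1) -- but only to homogametic offspring.
    """
    het_sex = ped.heterogametic_sex
    if het_sex == FEMALE:        # ZW: females carry one Z from the sire
        hom_parent, het_parent = ped.sire, ped.dam
    else:                        # XY: males carry one X from the dam
        hom_parent, het_parent = ped.dam, ped.sire
    is_het = ped.sex == het_sex
    c_hp = np.where(hom_parent >= 0, 0.5, 0.0)
    c_tp = np.where((het_parent >= 0) & ~is_het, 1.0, 0.0)
    return hom_parent, het_parent, is_het, c_hp, c_tp


def z_mendelian_structure(ped: Pedigree):
    """Per-individual sex-linked structure: (hom_parent, het_parent, is_het,
    c_hp, c_tp, v, zdiag) with v the Mendelian-sampling variance and zdiag
    the diagonal of Z, both in units of sigma2_z (male scale).

    Heterogametic individuals always have zdiag exactly 1/2 (one copy).
    Homogametic diagonals are 1 + cov(parents) and need mate covariances,
    obtained by ancestor-restricted path walks.
    """
    if not np.all((ped.sex == FEMALE) | (ped.sex == MALE)):
        raise PedigreeError("all individuals need a sex to build Z")
    n = ped.n
    hp, tp, is_het, c_hp, c_tp = _z_roles(ped)
    v = np.empty(n)
    zdiag = np.empty(n)
    for i in range(n):
        h, t = hp[i], tp[i]
        if is_het[i]:
            v[i] = 0.5 - (0.25 * zdiag[h] if h >= 0 else 0.0)
            zdiag[i] = 0.5
        else:
            if h >= 0 and t >= 0:
                v[i] = 0.5 - 0.25 * zdiag[h]
            elif h >= 0:
                v[i] = 1.0 - 0.25 * zdiag[h]
            elif t >= 0:
                v[i] = 0.5
            else:
                v[i] = 1.0
            cov_pq = 0.0
            if h >= 0 and t >= 0:
                cov_pq = _path_covariance(h, t, hp, tp, c_hp, c_tp, v)
            zdiag[i] = (v[i]
                        + (0.25 * zdiag[h] if h >= 0 else 0.0)
                        + (zdiag[t] if t >= 0 else 0.0)
                        + cov_pq)
    return hp, tp, is_het, c_hp, c_tp, v, zdiag


def build_Z(ped: Pedigree, max_n: int = DENSE_GUARD) -> RelationshipTable:
    """Dense sex-linked relationship matrix by the gametic recursion (oracle).

    Under ZW: female i with sire s has Z_ij = Z_sj / 2 and Z_ii = 1/2;
    male i has Z_ij = Z_sj / 2 + Z_dj and Z_ii = 1 + Z_sd.
    """
    n = ped.n
    if n > max_n:
        raise PedigreeError(f"dense Z guard exceeded: n={n} > {max_n}")
    if not np.all((ped.sex == FEMALE) | (ped.sex == MALE)):
        raise PedigreeError("all individuals need a sex to build Z")
    hp, tp, is_het, c_hp, c_tp = _z_roles(ped)
    Z = np.zeros((n, n))
    for i in range(n):
        h, t = hp[i], tp[i]
        row = np.zeros(i)
        if c_hp[i] != 0.0:
            row += c_hp[i] * Z[h, :i]
        if c_tp[i] != 0.0:
            row += c_tp[i] * Z[t, :i]
        Z[i, :i] = row
        Z[:i, i] = row
        if is_het[i]:
            Z[i, i] = 0.5
        else:
            Z[i, i] = 1.0 + (Z[h, t] if (h >= 0 and t >= 0) else 0.0)
    return RelationshipTable(n=n, values=Z, ids=ped.ids)


def build_Z_inverse(ped: Pedigree) -> SparseSPD:
    """Sparse Z^-1 directly from pedigree and sex information.

    Assembled as sum_i (1/v_i)(e_i - c_hp e_hp - c_tp e_tp)(...)^T with the
    transmission coefficients of :func:`z_mendelian_structure`.  The result is
    cross-validated against the gene-dropping oracle in the test suite.
    """
    hp, tp, is_het, c_hp, c_tp, v, zdiag = z_mendelian_structure(ped)
    rows, cols, vals = [], [], []
    for i in range(ped.n):
        parents = [(p, c) for p, c in ((hp[i], c_hp[i]), (tp[i], c_tp[i])) if c != 0.0]
        w = 1.0 / v[i]
        rows.append(i); cols.append(i); vals.append(w)
        for p, c in parents:
            rows += [i, p]; cols += [p, i]; vals += [-c * w, -c * w]
        for p, c in parents:
            for q, e in parents:
                rows.append(p); cols.append(q); vals.append(c * e * w)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n)).tocsc()
    mat.eliminate_zeros()   # exact cancellations (e.g. parent-offspring mating)
    return SparseSPD(n=ped.n, matrix=mat, ids=ped.ids)


# ---------------------------------------------------------------------------
# gene-dropping oracle

def gene_drop_covariance(ped: Pedigree, n_rep: int, seed,
                         chromosome: str = "z") -> np.ndarray:
    """Empirical relationship matrix from Monte-Carlo allele transmission.

    Base alleles are drawn N(0, 1/2); each homogametic individual carries two
    (one from each parent under the sex-linked rules), each heterogametic
    individual one.  The returned matrix is the empirical covariance of the
    summed allelic values, in units of the base male variance -- an estimate
    of Z (or of A for ``chromosome="autosomal"``, where everyone carries two
    alleles and each parent transmits a random one of theirs).
    """
    if n_rep < 1000:
        raise ValueError("n_rep < 1000 is too noisy to serve as an oracle")
    if ped.n > GENE_DROP_GUARD:
        raise PedigreeError(f"gene-drop guard exceeded: n={ped.n} > {GENE_DROP_GUARD}")
    rng = np.random.default_rng(seed)
    n = ped.n
    sd0 = np.sqrt(0.5)
    value = np.empty((n, n_rep))

    if chromosome == "autosomal":
        a0 = np.empty((n, n_rep))
        a1 = np.empty((n, n_rep))
        for i in range(n):
            for slot, p in ((a0, ped.sire[i]), (a1, ped.dam[i])):
                if p >= 0:
                    pick = rng.integers(0, 2, n_rep).astype(bool)
                    slot[i] = np.where(pick, a0[p], a1[p])
                else:
                    slot[i] = rng.normal(0.0, sd0, n_rep)
            value[i] = a0[i] + a1[i]
    elif chromosome == "z":
        hp, tp, is_het, _, _ = _z_roles(ped)
        if not np.all((ped.sex == FEMALE) | (ped.sex == MALE)):
            raise PedigreeError("all individuals need a sex for sex-linked gene drop")
        a0 = np.empty((n, n_rep))   # copy from the homogametic parent
        a1 = np.zeros((n, n_rep))   # copy from the heterogametic parent
        for i in range(n):
            h, t = hp[i], tp[i]
            if h >= 0:
                pick = rng.integers(0, 2, n_rep).astype(bool)
                a0[i] = np.where(pick, a0[h], a1[h])
            else:
                a0[i] = rng.normal(0.0, sd0, n_rep)
            if not is_het[i]:
                if t >= 0:
                    a1[i] = a0[t]   # the het parent's single copy, in full
                else:
                    a1[i] = rng.normal(0.0, sd0, n_rep)
                value[i] = a0[i] + a1[i]
            else:
                value[i] = a0[i]
    else:
        raise ValueError(f"unknown chromosome {chromosome!r}")
    return (value @ value.T) / n_rep


def gene_drop_standard_errors(expected: np.ndarray, n_rep: int) -> np.ndarray:
    """MC standard error of each empirical covariance given the expected matrix
    (Gaussian fourth-moment formula: Var = (Z_ii Z_jj + Z_ij^2)/n_rep)."""
    d = np.diag(expected)
    return np.sqrt((np.outer(d, d) + expected ** 2) / n_rep)
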