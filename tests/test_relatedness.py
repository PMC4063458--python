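import numpy as np
import pytest

from animalz.pedigree_io import PedigreeError, pedigree_from_records
from animalz.relatedness import (SparseSPD, build_A, build_A_inverse, build_Z,
                                 build_Z_inverse, gene_drop_covariance,
                                 gene_drop_standard_errors,
                                 inbreeding_coefficients)

from conftest import FEMALE, MALE, random_pedigree, rec

TRIO_A = np.array([[1, 0, .5], [0, 1, .5], [.5, .5, 1]])
TRIO_A_INV = np.array([[1.5, .5, -1], [.5, 1.5, -1], [-1, -1, 2]])
TRIO_Z_SON = np.array([[1, 0, .5], [0, .5, .5], [.5, .5, 1]])
TRIO_Z_SON_INV = np.array([[2, 2, -2], [2, 6, -4], [-2, -4, 4]])
TRIO_Z_DAU = np.array([[1, 0, .5], [0, .5, 0], [.5, 0, .5]])
TRIO_Z_DAU_INV = np.array([[2, 0, -2], [0, 2, 0], [-2, 0, 4]])


# ---------------------------------------------------------------------------
# inbreeding

def test_inbreeding_founders_zero(sib_pedigree):
    assert np.all(inbreeding_coefficients(sib_pedigree) == 0.0)


def test_inbreeding_full_sib_and_parent_offspring_mating():
    full_sib = pedigree_from_records([
        rec("M1"), rec("F1", sex=FEMALE),
        rec("B", "M1", "F1", MALE), rec("S", "M1", "F1", FEMALE),
        rec("X", "B", "S", MALE)])
    assert inbreeding_coefficients(full_sib)[-1] == pytest.approx(0.25)
    par_off = pedigree_from_records([
        rec("M1"), rec("F1", sex=FEMALE),
        rec("D", "M1", "F1", FEMALE), rec("X", "M1", "D", MALE)])
    assert inbreeding_coefficients(par_off)[-1] == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# autosomal matrices

def test_A_trio_and_inverse(trio_son):
    assert np.allclose(build_A(trio_son).values, TRIO_A)
    assert np.allclose(build_A_inverse(trio_son).matrix.toarray(), TRIO_A_INV)


def test_A_unrelated_founders_identity():
    ped = pedigree_from_records([rec(f"I{k}") for k in range(5)])
    assert np.allclose(build_A(ped).values, np.eye(5))
    assert np.allclose(build_A_inverse(ped).matrix.toarray(), np.eye(5))


def test_A_full_sibs_half(sib_pedigree):
    A = build_A(sib_pedigree).values
    assert A[2, 3] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# sex-linked matrices

def test_Z_trio_frozen_values(trio_son, trio_daughter):
    assert np.allclose(build_Z(trio_son).values, TRIO_Z_SON)
    assert np.allclose(build_Z_inverse(trio_son).matrix.toarray(),
                       TRIO_Z_SON_INV)
    assert np.allclose(build_Z(trio_daughter).values, TRIO_Z_DAU)
    assert np.allclose(build_Z_inverse(trio_daughter).matrix.toarray(),
                       TRIO_Z_DAU_INV)


def test_Z_single_female_founder_inverse():
    ped = pedigree_from_records([rec("F1", sex=FEMALE)])
    assert np.allclose(build_Z_inverse(ped).matrix.toarray(), [[2.0]])


def test_Z_relative_pair_coefficients(sib_pedigree):
    Z = build_Z(sib_pedigree).values
    ix = {iid: sib_pedigree.index_of(iid) for iid in sib_pedigree.ids}
    assert Z[ix["B1"], ix["B2"]] == pytest.approx(0.75)   # full brothers
    assert Z[ix["S1"], ix["S2"]] == pytest.approx(0.25)   # full sisters
    assert Z[ix["B1"], ix["S1"]] == pytest.approx(0.25)   # brother-sister
    assert Z[ix["F1"], ix["S1"]] == pytest.approx(0.0)    # mother-daughter
    assert Z[ix["M1"], ix["S1"]] == pytest.approx(0.5)    # father-daughter


def test_Z_female_diagonal_always_half(inbred_pedigree):
    Z = build_Z(inbred_pedigree).values
    females = inbred_pedigree.is_female
    assert np.allclose(np.diag(Z)[females], 0.5)


def test_Z_inbred_male_diagonal(inbred_pedigree):
    Z = build_Z(inbred_pedigree).values
    ix = inbred_pedigree.index_of("X1")
    s, d = inbred_pedigree.index_of("M1"), inbred_pedigree.index_of("D1")
    assert Z[ix, ix] == pytest.approx(1.0 + Z[s, d])
    assert Z[s, d] == pytest.approx(0.5)


def test_Z_does_not_reduce_to_A(trio_son):
    # dam transmits at coefficient 1 to sons, not 1/2: Z differs from A
    assert not np.allclose(build_Z(trio_son).values, build_A(trio_son).values)


def test_population_z_variance_three_quarters():
    ped = pedigree_from_records(
        [rec(f"M{k}") for k in range(30)]
        + [rec(f"F{k}", sex=FEMALE) for k in range(30)])
    Z = build_Z(ped).values
    assert np.diag(Z).mean() == pytest.approx(0.75)


def test_xy_system_mirrors_roles():
    # XY: the dam carries two X copies, males a single maternal X
    ped = pedigree_from_records(
        [rec("M1"), rec("F1", sex=FEMALE), rec("S1", "M1", "F1", MALE)],
        heterogametic_sex=MALE)
    Z = build_Z(ped).values
    assert Z[ped.index_of("M1"), ped.index_of("M1")] == pytest.approx(0.5)
    assert Z[ped.index_of("F1"), ped.index_of("F1")] == pytest.approx(1.0)
    # son's X comes from the dam only
    assert Z[ped.index_of("S1"), ped.index_of("M1")] == pytest.approx(0.0)
    assert Z[ped.index_of("S1"), ped.index_of("F1")] == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# property tests over random pedigrees

@pytest.mark.parametrize("seed", range(12))
def test_inverse_times_matrix_is_identity(seed):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(rng, n_founders=rng.integers(5, 25),
                          n_offspring=rng.integers(30, 170),
                          p_unknown_parent=float(rng.uniform(0, 0.3)))
    A = build_A(ped).values
    Ainv = build_A_inverse(ped).matrix.toarray()
    assert np.abs(Ainv @ A - np.eye(ped.n)).max() < 1e-8
    Z = build_Z(ped).values
    Zinv = build_Z_inverse(ped).matrix.toarray()
    assert np.abs(Zinv @ Z - np.eye(ped.n)).max() < 1e-8


def test_inverse_sparsity_is_pedigree_pattern():
    rng = np.random.default_rng(7)
    ped = random_pedigree(rng, n_founders=12, n_offspring=60)
    allowed = set()
    for i in range(ped.n):
        allowed.add((i, i))
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                allowed.add((min(i, p), max(i, p)))
        if ped.sire[i] >= 0 and ped.dam[i] >= 0:
            s, d = sorted((ped.sire[i], ped.dam[i]))
            allowed.add((s, d))
    for spd in (build_A_inverse(ped), build_Z_inverse(ped)):
        coo = spd.matrix.tocoo()
        for r, c, v in zip(coo.row, coo.col, coo.data):
            if v != 0.0:
                assert (min(r, c), max(r, c)) in allowed


def test_matrix_values_in_range():
    rng = np.random.default_rng(11)
    ped = random_pedigree(rng, n_founders=10, n_offspring=80)
    A = build_A(ped).values
    assert A.min() >= 0.0 and A.max() <= 2.0
    assert np.allclose(np.diag(build_A(ped).values)[ped.founders()], 1.0)
    Z = build_Z(ped).values
    zf = np.diag(Z)[ped.is_female]
    assert np.allclose(zf, 0.5)


# ---------------------------------------------------------------------------
# gene-dropping oracle

def test_gene_drop_founders_base_variances():
    ped = pedigree_from_records(
        [rec(f"M{k}") for k in range(5)]
        + [rec(f"F{k}", sex=FEMALE) for k in range(5)])
    emp = gene_drop_covariance(ped, 20000, seed=1)
    expect = np.diag(np.where(ped.is_male, 1.0, 0.5))
    se = gene_drop_standard_errors(expect + 1e-12 * np.eye(10), 20000)
    assert np.all(np.abs(emp - expect) <= 3 * np.maximum(se, 0.02))


def test_gene_drop_matches_recursion_trio(trio_son):
    emp = gene_drop_covariance(trio_son, 100000, seed=2)
    se = gene_drop_standard_errors(TRIO_Z_SON, 100000)
    assert np.all(np.abs(emp - TRIO_Z_SON) <= 3 * se)


def test_gene_drop_inbred_male(inbred_pedigree):
    Z = build_Z(inbred_pedigree).values
    emp = gene_drop_covariance(inbred_pedigree, 100000, seed=3)
    se = gene_drop_standard_errors(Z, 100000)
    assert np.all(np.abs(emp - Z) <= 3 * se)


def test_gene_drop_autosomal_matches_A(sib_pedigree):
    A = build_A(sib_pedigree).values
    emp = gene_drop_covariance(sib_pedigree, 50000, seed=4,
                               chromosome="autosomal")
    se = gene_drop_standard_errors(A, 50000)
    assert np.all(np.abs(emp - A) <= 3 * se)


def test_gene_drop_guards(trio_son):
    with pytest.raises(ValueError, match="too noisy"):
        gene_drop_covariance(trio_son, 100, seed=0)
    rng = np.random.default_rng(0)
    big = random_pedigree(rng, n_founders=200, n_offspring=400)
    with pytest.raises(PedigreeError, match="guard"):
        gene_drop_covariance(big, 2000, seed=0)


# ---------------------------------------------------------------------------
# export

def test_triplet_roundtrip(tmp_path, trio_son):
    spd = build_Z_inverse(trio_son)
    spd.write_triplets(tmp_path / "z.txt", tmp_path / "ids.txt")
    back = SparseSPD.read_triplets(tmp_path / "z.txt", tmp_path / "ids.txt")
    assert np.allclose(back.matrix.toarray(), spd.matrix.toarray())
    assert list(back.ids) == list(spd.ids)
    assert back.check_spd()


def test_dense_guard():
    rng = np.random.default_rng(0)
    ped = random_pedigree(rng, n_founders=10, n_offspring=30)
    with pytest.raises(PedigreeError, match="guard"):
        build_A(ped, max_n=10)
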