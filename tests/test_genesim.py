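import numpy as np
import pytest

from animalz.genesim import (GeneratorConfig, VarianceParams,
                             draw_missing_mask, generate_pedigree,
                             grid_parameters, simulate_breeding_values,
                             simulate_phenotypes, study_preset)
from animalz.relatedness import build_A, build_Z

from conftest import FEMALE, MALE


# ---------------------------------------------------------------------------
# parameter grid

def test_grid_reproduces_printed_values():
    grid = grid_parameters(0.6, 1.0, [0.0, 0.2, 0.8])
    assert grid[0].sigma2_a == pytest.approx(0.6)
    assert grid[1].sigma2_a == pytest.approx(0.450)
    assert grid[2].sigma2_a == pytest.approx(0.0)
    assert all(vp.sigma2_e == pytest.approx(0.4) for vp in grid)


def test_grid_full_nine_point_decomposition():
    szs = [0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8]
    grid = grid_parameters(0.6, 1.0, szs)
    expect_a = [0.6, 0.525, 0.450, 0.375, 0.3, 0.225, 0.150, 0.075, 0]
    for vp, ea in zip(grid, expect_a):
        assert vp.sigma2_a == pytest.approx(ea)
        assert vp.sigma2_a + 0.75 * vp.sigma2_z + vp.sigma2_e \
            == pytest.approx(1.0)
        assert vp.h2 == pytest.approx(0.6)


def test_grid_rejects_negative_autosomal_variance():
    with pytest.raises(ValueError, match="negative"):
        grid_parameters(0.6, 1.0, [0.9])


def test_variance_params_validation_and_derived():
    vp = VarianceParams(0.45, 0.2, 0.4)
    assert vp.sigma2_z_female == pytest.approx(0.1)
    assert vp.sigma2_z_population == pytest.approx(0.15)
    with pytest.raises(ValueError):
        VarianceParams(-0.1, 0.2, 0.4)
    with pytest.raises(ValueError):
        VarianceParams(0.1, 0.2, 0.0)


# ---------------------------------------------------------------------------
# pedigree generator

def test_generator_deterministic_by_seed():
    a = generate_pedigree(study_preset(seed=5))
    b = generate_pedigree(study_preset(seed=5))
    assert list(a.ids) == list(b.ids)
    assert np.array_equal(a.sire, b.sire) and np.array_equal(a.dam, b.dam)
    c = generate_pedigree(study_preset(seed=6))
    assert list(a.ids) != list(c.ids) or not np.array_equal(a.sire, c.sire)


def test_generator_zero_cohorts_gives_no_offspring():
    ped = generate_pedigree(GeneratorConfig(n_cohorts=0, seed=0))
    assert np.all(ped.sire < 0) and np.all(ped.dam < 0)


def test_study_preset_matches_target_bookkeeping(study_pedigree):
    assert abs(study_pedigree.n - 2999) / 2999 < 0.10
    f_frac = study_pedigree.n_female / study_pedigree.n
    assert abs(f_frac - 1550 / 2999) < 0.05
    cohorts = set(int(c) for c in study_pedigree.cohort)
    assert cohorts == set(range(1996, 2008))


def test_generator_config_validation():
    with pytest.raises(ValueError):
        GeneratorConfig(sex_ratio=1.5)
    with pytest.raises(ValueError):
        GeneratorConfig(pairs_per_cohort=0)


# ---------------------------------------------------------------------------
# breeding values

def test_zero_z_variance_gives_zero_z(sib_pedigree):
    bv = simulate_breeding_values(sib_pedigree, VarianceParams(0.5, 0.0, 0.4),
                                  seed=0)
    assert np.all(bv.z == 0.0)
    assert np.std(bv.a) > 0


def test_gene_flow_covariance_matches_Z_and_A(trio_son):
    vp = VarianceParams(0.5, 0.8, 0.4)
    n_rep = 20000
    A = build_A(trio_son).values * vp.sigma2_a
    Z = build_Z(trio_son).values * vp.sigma2_z
    draws_a = np.empty((n_rep, 3))
    draws_z = np.empty((n_rep, 3))
    ss = np.random.SeedSequence(42).spawn(n_rep)
    for r in range(n_rep):
        bv = simulate_breeding_values(trio_son, vp, ss[r])
        draws_a[r] = bv.a
        draws_z[r] = bv.z
    emp_a = draws_a.T @ draws_a / n_rep
    emp_z = draws_z.T @ draws_z / n_rep
    se_a = np.sqrt((np.outer(np.diag(A), np.diag(A)) + A ** 2) / n_rep)
    se_z = np.sqrt((np.outer(np.diag(Z), np.diag(Z)) + Z ** 2) / n_rep)
    assert np.all(np.abs(emp_a - A) <= 3 * se_a)
    assert np.all(np.abs(emp_z - Z) <= 3 * se_z)


def test_sex_specific_base_variances():
    from animalz.pedigree_io import pedigree_from_records
    from conftest import rec
    ped = pedigree_from_records(
        [rec(f"M{k}") for k in range(2000)]
        + [rec(f"F{k}", sex=FEMALE) for k in range(2000)])
    bv = simulate_breeding_values(ped, VarianceParams(0.0, 0.4, 0.4), seed=3)
    vm = np.var(bv.z[ped.is_male])
    vf = np.var(bv.z[ped.is_female])
    assert vm == pytest.approx(0.4, abs=0.05)
    assert vf == pytest.approx(0.2, abs=0.025)


def test_simulation_deterministic(study_pedigree):
    vp = VarianceParams(0.375, 0.3, 0.4)
    a = simulate_breeding_values(study_pedigree, vp, 9)
    b = simulate_breeding_values(study_pedigree, vp, 9)
    assert np.array_equal(a.a, b.a) and np.array_equal(a.z, b.z)


# ---------------------------------------------------------------------------
# phenotypes

def test_phenotypes_no_noise_limit(sib_pedigree):
    vp = VarianceParams(0.5, 0.3, 1e-12)
    bv = simulate_breeding_values(sib_pedigree, vp, 1)
    tab = simulate_phenotypes(sib_pedigree, bv, 1e-12, seed=2)
    assert np.allclose(tab.y, bv.a + bv.z, atol=1e-4)


def test_phenotypes_all_missing(sib_pedigree):
    vp = VarianceParams(0.5, 0.3, 0.4)
    bv = simulate_breeding_values(sib_pedigree, vp, 1)
    tab = simulate_phenotypes(sib_pedigree, bv, 0.4, seed=2, missing_rate=1.0)
    assert tab.n_d == 0


def test_phenotype_variance_near_one_at_grid_point(study_pedigree):
    vp = grid_parameters(0.6, 1.0, [0.3])[0]
    bv = simulate_breeding_values(study_pedigree, vp, 21)
    tab = simulate_phenotypes(study_pedigree, bv, vp.sigma2_e, 22)
    assert np.var(tab.y) == pytest.approx(1.0, abs=0.12)


def test_explicit_missing_mask_and_covariates(study_pedigree, study_mask):
    vp = VarianceParams(0.45, 0.2, 0.4)
    bv = simulate_breeding_values(study_pedigree, vp, 5)
    tab = simulate_phenotypes(study_pedigree, bv, vp.sigma2_e, 6,
                              missing_mask=study_mask, sex_effect=-1.0)
    assert np.array_equal(np.isnan(tab.y), study_mask)
    obs = tab.observed
    males = obs & study_pedigree.is_male
    females = obs & study_pedigree.is_female
    gap = tab.y[males].mean() - tab.y[females].mean()
    assert gap == pytest.approx(-1.0, abs=0.15)
    assert set(tab.data.columns) >= {"y", "sex", "cohort"}
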