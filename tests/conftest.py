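import numpy as np
import pytest

from animalz.genesim import generate_pedigree, study_preset
from animalz.pedigree_io import pedigree_from_records
from animalz.relatedness import build_A_inverse, build_Z_inverse

FEMALE, MALE = "female", "male"


def rec(iid, sire=None, dam=None, sex=MALE, cohort=None):
    return (iid, sire, dam, sex, cohort)


@pytest.fixture
def trio_son():
    """Sire M1, dam F1, male offspring S1."""
    return pedigree_from_records(
        [rec("M1"), rec("F1", sex=FEMALE), rec("S1", "M1", "F1", MALE)])


@pytest.fixture
def trio_daughter():
    return pedigree_from_records(
        [rec("M1"), rec("F1", sex=FEMALE), rec("D1", "M1", "F1", FEMALE)])


@pytest.fixture
def sib_pedigree():
    """Two founders with two sons and two daughters."""
    return pedigree_from_records([
        rec("M1"), rec("F1", sex=FEMALE),
        rec("B1", "M1", "F1", MALE), rec("B2", "M1", "F1", MALE),
        rec("S1", "M1", "F1", FEMALE), rec("S2", "M1", "F1", FEMALE)])


@pytest.fixture
def inbred_pedigree():
    """Four generations with a sire-daughter mating (inbred male X1)."""
    return pedigree_from_records([
        rec("M1"), rec("F1", sex=FEMALE),
        rec("D1", "M1", "F1", FEMALE),
        rec("X1", "M1", "D1", MALE),
        rec("F2", sex=FEMALE),
        rec("Y1", "X1", "F2", FEMALE),
        rec("Y2", "X1", "F2", MALE)])


def random_pedigree(rng, n_founders=20, n_offspring=80, p_male=0.5,
                    p_unknown_parent=0.1, n_cohorts=4):
    """A random multi-generation pedigree for property tests."""
    records = []
    males, females = [], []
    for k in range(n_founders):
        sex = MALE if rng.random() < p_male else FEMALE
        iid = f"I{k}"
        records.append(rec(iid, sex=sex, cohort=0))
        (males if sex == MALE else females).append(iid)
    for k in range(n_offspring):
        iid = f"I{n_founders + k}"
        sire = males[rng.integers(len(males))] \
            if males and rng.random() > p_unknown_parent else None
        dam = females[rng.integers(len(females))] \
            if females and rng.random() > p_unknown_parent else None
        sex = MALE if rng.random() < p_male else FEMALE
        records.append(rec(iid, sire, dam, sex,
                           int(1 + (k * n_cohorts) // max(n_offspring, 1))))
        (males if sex == MALE else females).append(iid)
    return pedigree_from_records(records)


@pytest.fixture(scope="session")
def study_pedigree():
    """The synthetic emulation of the study pedigree (~3000 individuals)."""
    return generate_pedigree(study_preset(seed=1))


@pytest.fixture(scope="session")
def study_matrices(study_pedigree):
    """Precomputed sparse A^-1 and Z^-1 for the emulation pedigree."""
    return (build_A_inverse(study_pedigree).matrix,
            build_Z_inverse(study_pedigree).matrix)


@pytest.fixture(scope="session")
def study_mask(study_pedigree):
    """One fixed missing-phenotype structure at the study's ~15% rate."""
    from animalz.genesim import draw_missing_mask
    return draw_missing_mask(study_pedigree, 0.152, 99)
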