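"""Relationship matrices for a parent-offspring trio, autosomal and Z-linked.

Builds the numerator relationship matrix A and its sex-linked analogue Z
for a sire, a dam and their son under the avian ZW system, prints their
sparse inverses, and cross-checks Z against a gene-dropping simulation.
"""

import numpy as np

from animalz import (build_A, build_A_inverse, build_Z, build_Z_inverse,
                     gene_drop_covariance, pedigree_from_records)

ped = pedigree_from_records([
    ("M1", None, None, "male", None),      # sire (ZZ)
    ("F1", None, None, "female", None),    # dam (ZW)
    ("S1", "M1", "F1", "male", None),      # son
])

print("A (autosomal relationships):")
print(build_A(ped).to_frame())
print("\nZ (sex-linked, units of the male base variance):")
print(build_Z(ped).to_frame())
# Note the dam's Z-diagonal of 1/2 (a single Z copy) and her full
# transmission to the son, versus the sire's coefficient of 1/2.

print("\nA^-1 (sparse, Henderson-style assembly):")
print(build_A_inverse(ped).matrix.toarray())
print("\nZ^-1 (sparse, from pedigree + sex information):")
print(build_Z_inverse(ped).matrix.toarray())

emp = gene_drop_covariance(ped, n_rep=100000, seed=1)
print("\nGene-dropping estimate of Z (100000 allele transmissions):")
print(np.round(emp, 3))
print("Max |empirical - recursion| =",
      round(float(np.abs(emp - build_Z(ped).values).max()), 4),
      "(Monte-Carlo error only)")
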