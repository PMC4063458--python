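"""Assembly of the latent Gaussian animal model.

The linear predictor for a phenotyped individual i is
``eta_i = x_fixed(i)' beta + a_i [+ z_i]``: the AI model carries the
autosomal breeding value only, the AZI model adds the sex-linked one.
The latent field x = (a, z, beta) is a Gaussian Markov random field whose
prior precision is block diagonal: tau_a A^-1, tau_z Z^-1, and a vague
diagonal on the fixed effects.  Breeding values exist for every pedigree
member, phenotyped or not; unphenotyped individuals contribute through the
pedigree alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pedigree_io import Pedigree, PhenotypeTable
from .relatedness import build_A_inverse, build_Z_inverse

#: variance ~ invGamma(1, 0.001), i.e. precision ~ Gamma(shape=1, rate=0.001)
DEFAULT_VARIANCE_PRIOR = (1.0, 0.001)
DEFAULT_FIXED_PRIOR_VARIANCE = 1000.0


@dataclass(frozen=True)
class ModelSpec:
    """Which terms the animal model carries, and their priors."""

    fixed_terms: tuple = ("intercept",)
    include_autosomal: bool = True
    include_zlinked: bool = True
    variance_priors: dict = field(default_factory=lambda: {
        "sigma2_a": DEFAULT_VARIANCE_PRIOR,
        "sigma2_z": DEFAULT_VARIANCE_PRIOR,
        "sigma2_e": DEFAULT_VARIANCE_PRIOR,
    })
    fixed_effect_prior_variance: float = DEFAULT_FIXED_PRIOR_VARIANCE

    def __post_init__(self):
        if "intercept" not in self.fixed_terms:
            object.__setattr__(self, "fixed_terms",
                               ("intercept",) + tuple(self.fixed_terms))
        if self.fixed_effect_prior_variance <= 0:
            raise ValueError("fixed-effect prior variance must be positive")
        for name, (a, b) in self.variance_priors.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"prior for {name} must have positive shape/rate")

    @property
    def label(self) -> str:
        parts = [t for t in self.fixed_terms if t != "intercept"]
        if self.include_autosomal:
            parts.append("autosomal")
        if self.include_zlinked:
            parts.append("zlinked")
        return " + ".join(parts) if parts else "intercept-only"


def ai_spec(fixed_terms=("intercept",), **kw) -> ModelSpec:
    """Autosomal-inheritance model (no sex-linked term)."""
    return ModelSpec(fixed_terms=tuple(fixed_terms), include_autosomal=True,
                     include_zlinked=False, **kw)


def azi_spec(fixed_terms=("intercept",), **kw) -> ModelSpec:
    """Autosomal plus sex-linked (Z/X) inheritance model."""
    return ModelSpec(fixed_terms=tuple(fixed_terms), include_autosomal=True,
                     include_zlinked=True, **kw)


@dataclass
class LatentStructure:
    """The assembled GMRF: response, incidence and prior precision blocks.

    Latent layout: autosomal block (n_p, if present), then sex-linked block
    (n_p, if present), then the expanded fixed-effect columns -- fixed
    effects last so the near-dense rows they induce cannot cause fill-in.
    """

    spec: ModelSpec
    ped: Pedigree
    y: np.ndarray                 # observed responses (N_d,)
    obs_index: np.ndarray         # pedigree position of each observation
    W: sp.csr_matrix              # (N_d, dim) incidence
    X_fixed: np.ndarray           # dense (N_d, m) fixed design (same as W's tail)
    fixed_names: list
    A_inv: sp.csc_matrix | None
    Z_inv: sp.csc_matrix | None

    @property
    def n_p(self) -> int:
        return self.ped.n

    @property
    def n_d(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return len(self.fixed_names)

    @property
    def dim(self) -> int:
        blocks = int(self.spec.include_autosomal) + int(self.spec.include_zlinked)
        return blocks * self.n_p + self.n_fixed

    @property
    def a_slice(self) -> slice | None:
        return slice(0, self.n_p) if self.spec.include_autosomal else None

    @property
    def z_slice(self) -> slice | None:
        if not self.spec.include_zlinked:
            return None
        off = self.n_p if self.spec.include_autosomal else 0
        return slice(off, off + self.n_p)

    @property
    def fixed_slice(self) -> slice:
        return slice(self.dim - self.n_fixed, self.dim)

    def prior_precision(self, tau_a=1.0, tau_z=1.0) -> sp.csc_matrix:
        """Block-diagonal prior precision of the latent field."""
        blocks = []
        if self.spec.include_autosomal:
            blocks.append(tau_a * self.A_inv)
        if self.spec.include_zlinked:
            blocks.append(tau_z * self.Z_inv)
        blocks.append(sp.eye(self.n_fixed, format="csc")
                      / self.spec.fixed_effect_prior_variance)
        return sp.block_diag(blocks, format="csc")

    def with_response(self, y_full: np.ndarray) -> "LatentStructure":
        """Same skeleton, new phenotype vector (pedigree order, NaN = missing).

        The observed/missing structure must match, so design matrices and the
        symbolic factorization can be reused across simulated datasets.
        """
        y_full = np.asarray(y_full, dtype=float)
        obs = ~np.isnan(y_full)
        if not np.array_equal(np.flatnonzero(obs), self.obs_index):
            raise ValueError("missing-data structure differs; rebuild the model")
        return LatentStructure(
            spec=self.spec, ped=self.ped, y=y_full[self.obs_index],
            obs_index=self.obs_index, W=self.W, X_fixed=self.X_fixed,
            fixed_names=self.fixed_names, A_inv=self.A_inv, Z_inv=self.Z_inv)


def _expand_fixed(spec: ModelSpec, tab: PhenotypeTable, obs_index) -> tuple:
    """Dense fixed-effect design over observations.

    String-valued covariates become treatment-coded factors with the first
    (sorted) level as reference -- for a hatch-year factor that is the first
    cohort.  Numeric covariates enter linearly.
    """
    cols, names = [np.ones(len(obs_index))], ["intercept"]
    for term in spec.fixed_terms:
        if term == "intercept":
            continue
        if term not in tab.data.columns:
            raise ValueError(f"covariate {term!r} not present in the phenotype table")
        vals = tab.data[term].to_numpy()[obs_index]
        isnull = pd.isnull(vals)
        if isnull.any():
            bad = tab.data.index[obs_index[isnull]][0]
            raise ValueError(
                f"covariate {term!r} missing for phenotyped individual {bad!r}")
        if np.issubdtype(np.asarray(vals).dtype, np.number):
            cols.append(np.asarray(vals, dtype=float))
            names.append(term)
        else:
            # string-valued covariates (sex, hatch year, ...) are factors,
            # treatment-coded against the first sorted level
            vals = np.asarray(vals, dtype=object)
            levels = sorted(set(vals))
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{term}[{lev}]")
    return np.column_stack(cols), names


def build_model(spec: ModelSpec, ped: Pedigree, tab: PhenotypeTable,
                A_inv=None, Z_inv=None) -> LatentStructure:
    """Assemble the latent structure for an AI or AZI animal model.

    Relationship-matrix inverses are built from the pedigree unless supplied
    (pass precomputed ones when fitting many models on one pedigree).
    """
    obs_index = np.flatnonzero(tab.observed)
    y = tab.y[obs_index]
    X, names = _expand_fixed(spec, tab, obs_index)
    n, m, nd = ped.n, X.shape[1], len(obs_index)

    if spec.include_autosomal and A_inv is None:
        A_inv = build_A_inverse(ped).matrix
    if spec.include_zlinked and Z_inv is None:
        Z_inv = build_Z_inverse(ped).matrix

    n_blocks = int(spec.include_autosomal) + int(spec.include_zlinked)
    dim = n_blocks * n + m
    rows, cols, vals = [], [], []
    off = 0
    if spec.include_autosomal:
        rows.append(np.arange(nd)); cols.append(obs_index + off)
        vals.append(np.ones(nd))
        off += n
    if spec.include_zlinked:
        rows.append(np.arange(nd)); cols.append(obs_index + off)
        vals.append(np.ones(nd))
        off += n
    r, c = np.nonzero(X)
    rows.append(r); cols.append(c + off); vals.append(X[r, c])
    W = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(nd, dim))
    return LatentStructure(spec=spec, ped=ped, y=y, obs_index=obs_index, W=W,
                           X_fixed=X, fixed_names=names,
                           A_inv=None if not spec.include_autosomal else A_inv.tocsc(),
                           Z_inv=None if not spec.include_zlinked else Z_inv.tocsc())
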