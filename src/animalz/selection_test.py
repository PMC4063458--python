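"""Model comparison for sex-linked inheritance: ΔDIC and its calibration.

Whether a trait carries sex-linked additive variance is decided by fitting
both the autosomal-only (AI) and the autosomal-plus-sex-linked (AZI) model
to the same data and computing ΔDIC = DIC(AI) - DIC(AZI); a difference
above 10 is taken as decisive.  Because the sampling distribution of ΔDIC
depends on the pedigree and the missing-data structure, the decision rule
is calibrated by simulation on the study pedigree itself: the proportion of
ΔDIC > 10 over datasets simulated without sex-linked variance estimates the
type-I error, and over datasets simulated with it, the power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .animal_model import ModelSpec, ai_spec, azi_spec, build_model
from .genesim import VarianceParams, draw_missing_mask, simulate_breeding_values, \
    simulate_phenotypes
from .inference import (DICResult, GibbsEngine, MCMCConfig, compute_dic,
                        gibbs_fit, marginal_fit, mass_sim_config,
                        summarize_posterior)
from .pedigree_io import Pedigree
from .relatedness import build_A_inverse, build_Z_inverse

DEFAULT_THRESHOLD = 10.0


def delta_dic(fit_ai: DICResult, fit_azi: DICResult) -> float:
    """DIC(AI) - DIC(AZI); positive values favour the sex-linked model."""
    return fit_ai.dic - fit_azi.dic


@dataclass
class TestResult:
    """Replicated ΔDIC sample and the exceedance proportion.

    Under a generating model without sex-linked variance the proportion
    estimates the type-I error of the ΔDIC > threshold rule; with sex-linked
    variance it estimates power.  Ties count as NOT exceeding (the rule is
    strict).
    """

    delta_dic_samples: np.ndarray
    threshold: float
    generating_params: VarianceParams
    n_failed: int = 0

    @property
    def S(self) -> int:
        return len(self.delta_dic_samples)

    @property
    def proportion_exceeding(self) -> float:
        return float(np.mean(self.delta_dic_samples > self.threshold))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# replicate\tdelta_dic\n")
            for s, d in enumerate(self.delta_dic_samples):
                fh.write(f"{s + 1}\t{d!r}\n")
            fh.write(f"# threshold={self.threshold}\n")
            fh.write(f"# S={self.S} failed={self.n_failed}\n")
            fh.write(f"# proportion_exceeding={self.proportion_exceeding}\n")


def simulate_test(ped: Pedigree, vp: VarianceParams, S: int,
                  threshold: float = DEFAULT_THRESHOLD,
                  cfg: MCMCConfig | None = None, seed: int = 0,
                  missing_rate: float = 0.0, missing_mask=None,
                  keep_summaries: bool = False, fit_method: str = "marginal",
                  progress=None) -> TestResult:
    """Simulate S datasets from ``vp`` on ``ped``, fit AI and AZI to each,
    and collect ΔDIC.

    The observed/missing structure is held fixed across replicates (drawn
    once from ``missing_rate`` unless an explicit mask is given), matching a
    calibration study that imposes the real dataset's missingness on every
    simulated dataset.  Per-replicate seeds derive deterministically from
    ``seed``.  ``keep_summaries`` additionally retains per-replicate
    posterior summaries of both fits for bias/coverage analysis.

    ``fit_method="marginal"`` (default) computes each replicate's DICs by
    the deterministic quadrature fit, so the ΔDIC sample carries no
    sampling-algorithm noise -- essential when comparing a spread of ΔDIC
    values against a fixed decision threshold.  ``fit_method="mcmc"`` uses
    the (slower, noisier) chains configured by ``cfg`` instead.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if fit_method not in ("marginal", "mcmc"):
        raise ValueError("fit_method must be 'marginal' or 'mcmc'")
    cfg = cfg if cfg is not None else mass_sim_config()
    root = np.random.SeedSequence(seed)
    mask_seed, *rep_seeds = root.spawn(S + 1)
    if missing_mask is None:
        missing_mask = draw_missing_mask(ped, missing_rate, mask_seed)

    A_inv = build_A_inverse(ped).matrix
    Z_inv = build_Z_inverse(ped).matrix
    # one skeleton per model; replicates swap in new responses
    probe = simulate_phenotypes(
        ped, simulate_breeding_values(ped, vp, 0), vp.sigma2_e, 0,
        missing_mask=missing_mask)
    ls_ai = build_model(ai_spec(), ped, probe, A_inv=A_inv)
    ls_azi = build_model(azi_spec(), ped, probe, A_inv=A_inv, Z_inv=Z_inv)
    eng_ai = GibbsEngine(ls_ai)
    eng_azi = GibbsEngine(ls_azi)

    deltas, summaries = [], {"AI": [], "AZI": []}
    n_failed = 0
    for s in range(S):
        child = rep_seeds[s].spawn(4)
        try:
            bv = simulate_breeding_values(ped, vp, child[0])
            tab = simulate_phenotypes(ped, bv, vp.sigma2_e, child[1],
                                      missing_mask=missing_mask)
            dics = {}
            for name, ls, eng, chain_seed in (
                    ("AI", ls_ai, eng_ai, child[2]),
                    ("AZI", ls_azi, eng_azi, child[3])):
                ls_s = ls.with_response(tab.y)
                if fit_method == "marginal":
                    mf = marginal_fit(ls_s, engine=eng)
                    dics[name] = mf.dic
                    if keep_summaries:
                        summaries[name].append(mf.variance_table)
                else:
                    cfg_s = cfg.with_seed(
                        int(chain_seed.generate_state(1)[0] % (2 ** 31)))
                    ps = gibbs_fit(ls_s, cfg_s, engine=eng, store_latent=False)
                    dics[name] = compute_dic(ps, method="rao_blackwell")
                    if keep_summaries:
                        summaries[name].append(summarize_posterior(ps))
            deltas.append(delta_dic(dics["AI"], dics["AZI"]))
        except (np.linalg.LinAlgError, FloatingPointError) as exc:  # pragma: no cover
            n_failed += 1
            warnings.warn(f"replicate {s} failed and was excluded: {exc}")
            if n_failed > 0.05 * S:
                raise RuntimeError(
                    f"more than 5% of replicates failed ({n_failed}/{S})") from exc
        if progress is not None:
            progress(s + 1, S)

    result = TestResult(delta_dic_samples=np.array(deltas), threshold=threshold,
                        generating_params=vp, n_failed=n_failed)
    if keep_summaries:
        result.summaries = summaries
    return result


# ---------------------------------------------------------------------------
# bias and coverage

@dataclass(frozen=True)
class BiasCoverageRow:
    model: str
    parameter: str
    true_value: float
    mean_estimate: float
    bias: float
    coverage: float


def bias_coverage(replicate_summaries: dict, true_vp: VarianceParams) -> pd.DataFrame:
    """Bias and 95%-interval coverage of the variance components.

    ``replicate_summaries`` maps a model label ("AI", "AZI") to a list of
    posterior-summary frames, one per simulated replicate.  Bias is the mean
    posterior mean minus the generating value; coverage the proportion of
    replicates whose equal-tailed 95% interval contains it.
    """
    truths = {"sigma2_a": true_vp.sigma2_a, "sigma2_z": true_vp.sigma2_z,
              "sigma2_e": true_vp.sigma2_e}
    rows = []
    for model, frames in replicate_summaries.items():
        if len(frames) < 2:
            raise ValueError("need at least 2 replicates per model")
        params = [p for p in truths if p in frames[0].index]
        for p in params:
            est = np.array([f.loc[p, "mean"] for f in frames])
            lo = np.array([f.loc[p, "lower"] for f in frames])
            hi = np.array([f.loc[p, "upper"] for f in frames])
            inside = (lo <= truths[p]) & (truths[p] <= hi)
            rows.append(BiasCoverageRow(
                model=model, parameter=p, true_value=truths[p],
                mean_estimate=float(est.mean()),
                bias=float(est.mean() - truths[p]),
                coverage=float(inside.mean())))
    return pd.DataFrame([r.__dict__ for r in rows])


# ---------------------------------------------------------------------------
# stepwise DIC model search

def _spec_from_terms(fixed, random_terms) -> ModelSpec:
    return ModelSpec(fixed_terms=("intercept",) + tuple(fixed),
                     include_autosomal="autosomal" in random_terms,
                     include_zlinked="zlinked" in random_terms)


def stepwise_model_comparison(candidate_fixed, candidate_random, ped, tab,
                              A_inv=None, Z_inv=None) -> pd.DataFrame:
    """Backward stepwise model search ranked by (deterministic) DIC.

    Starts from the full model (all candidate fixed and random terms); at
    each step every model with one term removed is fitted and the lowest-DIC
    one is kept, until nothing remains.  Returns one row per examined model
    with its step, formula and DIC; the overall best model is flagged.
    """
    if not (list(candidate_fixed) or list(candidate_random)):
        raise ValueError("no candidate terms")
    if A_inv is None and "autosomal" in candidate_random:
        A_inv = build_A_inverse(ped).matrix
    if Z_inv is None and "zlinked" in candidate_random:
        Z_inv = build_Z_inverse(ped).matrix

    def fit(fixed, random_terms):
        spec = _spec_from_terms(fixed, random_terms)
        ls = build_model(spec, ped, tab, A_inv=A_inv, Z_inv=Z_inv)
        return marginal_fit(ls).dic.dic, spec.label

    rows = []
    current = (tuple(candidate_fixed), tuple(candidate_random))
    step = 0
    dic, label = fit(*current)
    rows.append(dict(step=step, model=label, dic=dic, kept=True))
    while sum(len(t) for t in current) > 0:
        step += 1
        cands = []
        fixed, rnd = current
        for t in fixed:
            cands.append((tuple(x for x in fixed if x != t), rnd))
        for t in rnd:
            cands.append((fixed, tuple(x for x in rnd if x != t)))
        fits = [(fit(f, r), (f, r)) for f, r in cands]
        fits.sort(key=lambda fr: fr[0][0])
        for k, ((d, lab), cand) in enumerate(fits):
            rows.append(dict(step=step, model=lab, dic=d, kept=(k == 0)))
        current = fits[0][1]
    out = pd.DataFrame(rows)
    out["best_overall"] = out["dic"] == out["dic"].min()
    return out
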