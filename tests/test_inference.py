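import numpy as np
import pytest

from animalz.animal_model import ModelSpec, ai_spec, azi_spec, build_model
from animalz.genesim import VarianceParams, simulate_breeding_values, \
    simulate_phenotypes
from animalz.inference import (MCMCConfig, PosteriorSamples, compute_dic,
                               convergence_report, draw_precision, gibbs_fit,
                               marginal_fit, summarize_posterior)
from animalz.pedigree_io import pedigree_from_records, phenotypes_from_arrays

from conftest import FEMALE, MALE, random_pedigree, rec


def _fit_ready(ped, vp, seed, missing_rate=0.1, **spec_kw):
    bv = simulate_breeding_values(ped, vp, seed)
    tab = simulate_phenotypes(ped, bv, vp.sigma2_e, seed + 1,
                              missing_rate=missing_rate)
    return build_model(azi_spec(**spec_kw), ped, tab)


def _fake_ps(sigma2, beta=None, names=("intercept",)):
    """Hand-built PosteriorSamples for summary/trend unit tests."""
    nc, nk = next(iter(sigma2.values())).shape
    beta = beta if beta is not None else np.zeros((nc, nk, len(names)))
    return PosteriorSamples(
        sigma2=sigma2, beta=beta, fixed_names=list(names),
        deviance=np.zeros((nc, nk)), deviance_rb=np.zeros((nc, nk)),
        eta_mean=np.zeros(1), eta_mean_rb=np.zeros(1),
        a_draws=None, z_draws=None, ls=None, cfg=None)


# ---------------------------------------------------------------------------
# exactness against closed forms

def test_intercept_posterior_matches_conjugate_closed_form():
    # y_i ~ N(beta0, s2e) with known s2e and prior beta0 ~ N(0, V):
    # posterior N(Vn * sum(y)/s2e, Vn), Vn = 1/(n/s2e + 1/V)
    rng = np.random.default_rng(0)
    ped = pedigree_from_records(
        [rec(f"I{k}", sex=MALE if k % 2 else FEMALE) for k in range(60)])
    y = 1.7 + 0.5 * rng.standard_normal(60)
    tab = phenotypes_from_arrays(ped, y)
    spec = ModelSpec(include_autosomal=False, include_zlinked=False,
                     fixed_effect_prior_variance=1000.0)
    ls = build_model(spec, ped, tab)
    s2e = 0.25
    cfg = MCMCConfig(n_iter=4000, burn_in=500, n_chains=1, seed=1,
                     latent_thin=10 ** 9)
    ps = gibbs_fit(ls, cfg, fix_variances=VarianceParams(0.0, 0.0, s2e),
                   store_latent=False)
    vn = 1.0 / (60 / s2e + 1.0 / 1000.0)
    mean_n = vn * y.sum() / s2e
    draws = ps.beta[0, :, 0]
    assert draws.mean() == pytest.approx(mean_n, abs=4 * np.sqrt(vn / 3500))
    assert draws.var() == pytest.approx(vn, rel=0.15)


def test_fixed_variance_latent_matches_dense_gaussian():
    """Tiny pedigree, variances clamped: the Gibbs draws of the latent field
    must match the closed-form Gaussian conditional (dense solve)."""
    ped = pedigree_from_records([
        rec("M1"), rec("F1", sex=FEMALE),
        rec("S1", "M1", "F1", MALE), rec("D1", "M1", "F1", FEMALE),
        rec("G1", "S1", None, FEMALE)])
    vp = VarianceParams(0.5, 0.3, 0.4)
    bv = simulate_breeding_values(ped, vp, 3)
    tab = simulate_phenotypes(ped, bv, vp.sigma2_e, 4, missing_rate=0.0)
    ls = build_model(azi_spec(), ped, tab)
    P0 = ls.prior_precision(tau_a=1 / vp.sigma2_a, tau_z=1 / vp.sigma2_z)
    W = ls.W.toarray()
    Q = P0.toarray() + W.T @ W / vp.sigma2_e
    mean = np.linalg.solve(Q, W.T @ ls.y / vp.sigma2_e)
    cov = np.linalg.inv(Q)

    cfg = MCMCConfig(n_iter=20000, burn_in=0, n_chains=1, seed=5,
                     latent_thin=1)
    ps = gibbs_fit(ls, cfg, fix_variances=vp, store_latent=True)
    draws = np.hstack([ps.a_draws, ps.z_draws, ps.beta[0]])
    n_eff = draws.shape[0]   # independent draws given fixed variances
    se_mean = np.sqrt(np.diag(cov) / n_eff)
    assert np.all(np.abs(draws.mean(axis=0) - mean) <= 4 * se_mean)
    emp_cov = np.cov(draws.T)
    se_cov = np.sqrt((np.outer(np.diag(cov), np.diag(cov)) + cov ** 2) / n_eff)
    assert np.all(np.abs(emp_cov - cov) <= 5 * se_cov)


def test_precision_full_conditional_is_stated_gamma():
    # draws of tau from draw_precision must match Gamma(a*+n/2, b*+q/2)
    rng = np.random.default_rng(8)
    a, b, n, q = 1.0, 0.001, 40, 12.0
    draws = np.array([draw_precision(rng, a, b, n, q) for _ in range(40000)])
    shape, rate = a + n / 2, b + q / 2
    assert draws.mean() == pytest.approx(shape / rate, rel=0.02)
    assert draws.var() == pytest.approx(shape / rate ** 2, rel=0.06)


# ---------------------------------------------------------------------------
# DIC

def test_dic_identity_and_single_draw_degeneracy():
    rng = np.random.default_rng(1)
    ped = random_pedigree(rng, n_founders=8, n_offspring=40)
    ls = _fit_ready(ped, VarianceParams(0.5, 0.3, 0.4), seed=2)
    cfg = MCMCConfig(n_iter=50, burn_in=49, n_chains=1, seed=3,
                     latent_thin=10 ** 9)
    ps = gibbs_fit(ls, cfg, store_latent=False)   # a single kept draw
    dic = compute_dic(ps)
    assert dic.p_d == pytest.approx(0.0, abs=1e-8)
    assert dic.dic == pytest.approx(dic.dhat, abs=1e-8)
    cfg2 = MCMCConfig(n_iter=400, burn_in=100, n_chains=1, seed=3,
                      latent_thin=10 ** 9)
    ps2 = gibbs_fit(ls, cfg2, store_latent=False)
    d2 = compute_dic(ps2)
    assert d2.dic == pytest.approx(2 * d2.dbar - d2.dhat, abs=1e-10)


def test_intercept_only_pd_is_about_one():
    rng = np.random.default_rng(2)
    ped = pedigree_from_records(
        [rec(f"I{k}", sex=MALE if k % 2 else FEMALE) for k in range(600)])
    y = 0.3 + rng.standard_normal(600)
    tab = phenotypes_from_arrays(ped, y)
    spec = ModelSpec(include_autosomal=False, include_zlinked=False)
    ls = build_model(spec, ped, tab)
    cfg = MCMCConfig(n_iter=4000, burn_in=500, n_chains=1, seed=4,
                     latent_thin=10 ** 9)
    ps = gibbs_fit(ls, cfg, fix_variances=VarianceParams(0.0, 0.0, 1.0),
                   store_latent=False)
    assert compute_dic(ps).p_d == pytest.approx(1.0, abs=0.25)


def test_richer_model_fits_better_in_dbar():
    rng = np.random.default_rng(5)
    ped = random_pedigree(rng, n_founders=10, n_offspring=120)
    vp = VarianceParams(0.5, 0.3, 0.4)
    bv = simulate_breeding_values(ped, vp, 6)
    tab = simulate_phenotypes(ped, bv, vp.sigma2_e, 7, missing_rate=0.0)
    cfg = MCMCConfig(n_iter=1200, burn_in=300, n_chains=1, seed=8,
                     latent_thin=10 ** 9, update="collapsed")
    ls_rich = build_model(azi_spec(), ped, tab)
    spec0 = ModelSpec(include_autosomal=False, include_zlinked=False)
    ls_null = build_model(spec0, ped, tab)
    d_rich = compute_dic(gibbs_fit(ls_rich, cfg, store_latent=False))
    d_null = compute_dic(gibbs_fit(ls_null, cfg, store_latent=False))
    assert d_rich.dbar <= d_null.dbar


# ---------------------------------------------------------------------------
# reproducibility and the two update schemes

def test_seeded_runs_bit_reproducible():
    rng = np.random.default_rng(9)
    ped = random_pedigree(rng, n_founders=8, n_offspring=50)
    ls = _fit_ready(ped, VarianceParams(0.4, 0.3, 0.4), seed=10)
    for update in ("gibbs", "collapsed"):
        cfg = MCMCConfig(n_iter=300, burn_in=100, n_chains=2, seed=11,
                         latent_thin=50, update=update)
        a = gibbs_fit(ls, cfg)
        b = gibbs_fit(ls, cfg)
        assert np.array_equal(a.sigma2["sigma2_z"], b.sigma2["sigma2_z"])
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.deviance, b.deviance)


def test_collapsed_and_gibbs_agree():
    """The two update schemes target the same posterior."""
    rng = np.random.default_rng(12)
    ped = random_pedigree(rng, n_founders=30, n_offspring=370)
    vp = VarianceParams(0.45, 0.3, 0.4)
    ls = _fit_ready(ped, vp, seed=13, missing_rate=0.1)
    ps_g = gibbs_fit(ls, MCMCConfig(n_iter=6000, burn_in=1500, n_chains=1,
                                    seed=14, latent_thin=10 ** 9),
                     store_latent=False)
    ps_c = gibbs_fit(ls, MCMCConfig(n_iter=2000, burn_in=300, n_chains=1,
                                    seed=15, latent_thin=10 ** 9,
                                    update="collapsed"),
                     store_latent=False)
    sg = summarize_posterior(ps_g)
    sc = summarize_posterior(ps_c)
    for par in ("sigma2_a", "sigma2_z", "sigma2_e"):
        tol = 4 * max(sg.loc[par, "sd"], sc.loc[par, "sd"]) / np.sqrt(50)
        assert abs(sg.loc[par, "mean"] - sc.loc[par, "mean"]) < max(tol, 0.03)


def test_marginal_fit_agrees_with_mcmc():
    """Deterministic quadrature and MCMC are independent routes to the same
    posterior: variance means and DIC must agree within MC error."""
    rng = np.random.default_rng(16)
    ped = random_pedigree(rng, n_founders=30, n_offspring=370)
    vp = VarianceParams(0.45, 0.3, 0.4)
    ls = _fit_ready(ped, vp, seed=17, missing_rate=0.1)
    mf = marginal_fit(ls)
    ps = gibbs_fit(ls, MCMCConfig(n_iter=5000, burn_in=1000, n_chains=1,
                                  seed=18, latent_thin=10 ** 9,
                                  update="collapsed"), store_latent=False)
    summ = summarize_posterior(ps)
    for par in ("sigma2_a", "sigma2_z", "sigma2_e"):
        assert mf.sigma2_mean[par] == pytest.approx(
            summ.loc[par, "mean"], abs=max(0.03, summ.loc[par, "sd"] / 3))
    d_mc = compute_dic(ps, method="rao_blackwell")
    assert mf.dic.dic == pytest.approx(d_mc.dic, abs=12.0)
    assert mf.dic.p_d == pytest.approx(d_mc.p_d, abs=12.0)
    # determinism: the quadrature fit has no seed to vary
    mf2 = marginal_fit(ls)
    assert mf2.dic.dic == mf.dic.dic


# ---------------------------------------------------------------------------
# summaries and diagnostics

def test_summary_constant_chain_collapses():
    ps = _fake_ps({"sigma2_e": np.full((1, 100), 0.4),
                   "sigma2_a": np.full((1, 100), 0.6)})
    s = summarize_posterior(ps)
    assert s.loc["sigma2_e", "sd"] == pytest.approx(0.0, abs=1e-12)
    assert s.loc["sigma2_e", "lower"] == pytest.approx(0.4)
    assert s.loc["sigma2_e", "upper"] == pytest.approx(0.4)


def test_summary_female_variance_is_half_male_scale():
    rng = np.random.default_rng(20)
    z = rng.gamma(4.0, 0.07, size=(1, 4000))
    ps = _fake_ps({"sigma2_e": np.full((1, 4000), 0.4),
                   "sigma2_a": np.full((1, 4000), 0.45),
                   "sigma2_z": z})
    s = summarize_posterior(ps)
    for col in ("mean", "lower", "upper"):
        assert s.loc["sigma2_z_female", col] == \
            pytest.approx(s.loc["sigma2_z", col] / 2)
        assert s.loc["sigma2_z_population", col] == \
            pytest.approx(0.75 * s.loc["sigma2_z", col])


def test_summary_h2_is_drawwise_definitional():
    s2a = np.array([[0.4, 0.5]])
    s2z = np.array([[0.2, 0.1]])
    s2e = np.array([[0.4, 0.4]])
    ps = _fake_ps({"sigma2_a": s2a, "sigma2_z": s2z, "sigma2_e": s2e})
    s = summarize_posterior(ps)
    h2 = (s2a + 0.75 * s2z) / (s2a + 0.75 * s2z + s2e)
    assert s.loc["h2", "mean"] == pytest.approx(h2.mean())


def test_convergence_report_flags_unmixed_chains():
    rng = np.random.default_rng(21)
    good = rng.standard_normal((2, 800)) * 0.1 + 0.5
    bad = np.vstack([np.full(800, 0.2), np.full(800, 0.9)])
    bad = bad + rng.standard_normal((2, 800)) * 1e-4
    ps = _fake_ps({"sigma2_e": good, "sigma2_a": bad})
    rep = convergence_report(ps)
    assert rep.loc["sigma2_e", "rhat"] == pytest.approx(1.0, abs=0.02)
    assert rep.loc["sigma2_a", "rhat"] > 1.5
    assert bool(rep.loc["sigma2_a", "flagged"])


def test_convergence_report_single_chain_omits_rhat():
    rng = np.random.default_rng(22)
    ps = _fake_ps({"sigma2_e": rng.standard_normal((1, 600)) * 0.1 + 1.0})
    rep = convergence_report(ps)
    assert np.isnan(rep.loc["sigma2_e", "rhat"])
    assert rep.loc["sigma2_e", "ess"] > 200


def test_ai_on_azi_data_absorbs_z_variance(study_pedigree, study_matrices,
                                           study_mask):
    """Fitting autosomal-only to sex-linked data recovers the TOTAL additive
    variance sigma2_a + 3/4 sigma2_z, not sigma2_a."""
    Ainv, Zinv = study_matrices
    vp = VarianceParams(0.375, 0.3, 0.4)   # total additive = 0.6
    bv = simulate_breeding_values(study_pedigree, vp, 30)
    tab = simulate_phenotypes(study_pedigree, bv, vp.sigma2_e, 31,
                              missing_mask=study_mask)
    ls = build_model(ai_spec(), study_pedigree, tab, A_inv=Ainv)
    mf = marginal_fit(ls)
    assert mf.sigma2_mean["sigma2_a"] == pytest.approx(0.6, abs=0.12)
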