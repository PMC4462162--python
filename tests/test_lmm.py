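import numpy as np
import pytest

import famvar as fv
from famvar.lmm import fit_lmm_nested, lmm_residuals, lrt_family_variance, residual_icc


def _balanced_oneway(seed=1, k=20, m=5, s2f=0.6, s2e=1.0):
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(k), m)
    y = 2.0 + rng.normal(0, np.sqrt(s2f), k)[fam] + rng.normal(0, np.sqrt(s2e), k * m)
    return y, np.ones((k * m, 1)), fam, k, m


def test_reml_matches_balanced_anova_closed_form():
    y, X, fam, k, m = _balanced_oneway()
    fit = fit_lmm_nested(y, X, fam)
    means = np.array([y[fam == i].mean() for i in range(k)])
    msb = m * np.sum((means - y.mean()) ** 2) / (k - 1)
    msw = np.sum((y - means[fam]) ** 2) / (k * (m - 1))
    assert fit.sigma2_e == pytest.approx(msw, abs=1e-6)
    assert fit.sigma2_family == pytest.approx((msb - msw) / m, abs=1e-6)


def test_reml_matches_statsmodels_three_level(family_table):
    import statsmodels.api as sm
    import pandas as pd

    table, _ = family_table
    y = fv.sqrt_aao(table["aao"])
    X = np.column_stack([np.ones(len(table)), table["sex"]])
    fit = fit_lmm_nested(y, X, table["family_id"].to_numpy(),
                         table["center_id"].to_numpy())
    df = pd.DataFrame({"y": y, "sex": table["sex"],
                       "cen": table["center_id"], "fam": table["family_id"]})
    mf = sm.MixedLM.from_formula(
        "y ~ sex", groups="cen", re_formula="1",
        vc_formula={"fam": "0 + C(fam)"}, data=df,
    ).fit(reml=True)
    assert fit.sigma2_e == pytest.approx(float(mf.scale), rel=1e-4)
    assert fit.sigma2_family == pytest.approx(float(mf.vcomp[0]), rel=1e-3)
    assert np.allclose(fit.beta, np.asarray(mf.fe_params), atol=1e-5)


def test_null_family_component_hits_boundary():
    rng = np.random.default_rng(2)
    n_fam = 1000
    fam = np.repeat(np.arange(n_fam), 4)
    y = rng.normal(0, 1, 4 * n_fam)
    fit = fit_lmm_nested(y, np.ones((y.size, 1)), fam)
    assert fit.sigma2_family < 0.02


def test_parameter_recovery_with_standard_errors():
    # direct nested-Gaussian simulation at (s2c, s2f, s2e) = (0.2, 1, 3)
    rng = np.random.default_rng(13)
    n_fam, n_cen = 3000, 8
    sizes = rng.integers(2, 6, n_fam)
    fam = np.repeat(np.arange(n_fam), sizes)
    cen_of_fam = rng.integers(0, n_cen, n_fam)
    n = fam.size
    y = (
        1.0
        + rng.normal(0, np.sqrt(0.2), n_cen)[cen_of_fam][fam]
        + rng.normal(0, 1.0, n_fam)[fam]
        + rng.normal(0, np.sqrt(3.0), n)
    )
    X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
    fit = fit_lmm_nested(y, X, fam, cen_of_fam[fam])
    se = np.sqrt(np.diag(fit.varpar_cov))
    assert abs(fit.sigma2_family - 1.0) < 3 * se[1]
    assert abs(fit.sigma2_e - 3.0) < 3 * se[2]
    assert abs(fit.sigma2_center - 0.2) < 3 * se[0] + 0.05  # only 8 centers


def test_lrt_boundary_mixture_reference_values():
    fit = fit_lmm_nested(*_balanced_oneway()[:3])
    # p from the statistic alone: exercise the mixture formula directly
    from scipy.stats import chi2

    assert 0.5 * chi2.sf(2.706, 1) == pytest.approx(0.05, abs=1e-3)
    stat, p = lrt_family_variance(fit, fit)
    assert stat == 0.0 and p == 0.5


def test_lrt_rejects_on_different_data():
    y, X, fam, *_ = _balanced_oneway()
    f1 = fit_lmm_nested(y, X, fam)
    f2 = fit_lmm_nested(y[:-5], X[:-5], fam[:-5])
    with pytest.raises(ValueError):
        lrt_family_variance(f1, f2)


def test_residual_icc_definition_and_boundary():
    y, X, fam, *_ = _balanced_oneway(seed=3, s2f=1.0, s2e=3.0, k=200)
    fit = fit_lmm_nested(y, X, fam)
    icc = residual_icc(fit)
    expected = fit.sigma2_family / (fit.sigma2_family + fit.sigma2_e)
    assert icc.icc == pytest.approx(expected, abs=1e-12)
    assert icc.ci_low <= icc.icc <= icc.ci_high
    fit.sigma2_family = 0.0
    icc0 = residual_icc(fit)
    assert icc0.icc == 0.0 and icc0.ci_low == 0.0


def test_icc_conventions_include_center():
    y, X, fam, *_ = _balanced_oneway(seed=4)
    cen = fam % 5
    # regroup so families nest in centers
    cen = fam // 4
    fit = fit_lmm_nested(y, X, fam, cen)
    full = residual_icc(fit, include_center=True)
    cond = residual_icc(fit, include_center=False)
    assert full.icc >= cond.icc - 1e-12


def test_icc_matches_pairwise_sibling_correlation():
    truth = fv.SimTruth(aao_sigma2_center=0.0, aao_sigma2_family=0.278,
                        aao_sigma2_e=0.722, aao_beta_sex=0.0)
    table, tr = fv.simulate_family_phenotypes(
        n_families=4000, truth=truth, seed=14,
        size_weights={2: 1.0},
    )
    y = fv.sqrt_aao(table["aao"])
    fit = fit_lmm_nested(y, np.ones((len(table), 1)),
                         table["family_id"].to_numpy())
    icc = residual_icc(fit)
    # oracle: correlation across sibling pairs
    v = np.asarray(y).reshape(-1, 2)
    r = np.corrcoef(np.concatenate([v[:, 0], v[:, 1]]),
                    np.concatenate([v[:, 1], v[:, 0]]))[0, 1]
    assert icc.icc == pytest.approx(r, abs=0.02)
    assert icc.icc == pytest.approx(tr.icc_aao_true, abs=3 * icc.se + 0.02)


def test_loglik_invariant_to_design_reparameterization():
    y, X, fam, *_ = _balanced_oneway(seed=5)
    X2 = np.column_stack([X, np.zeros_like(y)])  # would be rank deficient
    with pytest.raises(ValueError):
        fit_lmm_nested(y, X2, fam)
    rng = np.random.default_rng(0)
    X3 = np.column_stack([X[:, 0], rng.normal(0, 1, y.size)])
    T = np.array([[2.0, 0.3], [0.0, -1.5]])
    f1 = fit_lmm_nested(y, X3, fam)
    f2 = fit_lmm_nested(y, X3 @ T, fam)
    assert f1.loglik_reml == pytest.approx(f2.loglik_reml, abs=1e-5)
    assert f1.sigma2_family == pytest.approx(f2.sigma2_family, rel=1e-4, abs=1e-8)


def test_duplicated_rows_preserve_variance_ratio():
    y, X, fam, *_ = _balanced_oneway(seed=6, s2f=1.0, s2e=2.0, k=100)
    f1 = fit_lmm_nested(y, X, fam)
    idx = np.repeat(np.arange(y.size), 2)
    f2 = fit_lmm_nested(y[idx], X[idx], fam[idx])
    r1 = f1.sigma2_family / (f1.sigma2_family + f1.sigma2_e)
    r2 = f2.sigma2_family / (f2.sigma2_family + f2.sigma2_e)
    # duplication halves apparent residual noise but the family share of the
    # family+residual total stays put only approximately; check stability
    assert r2 == pytest.approx(r1, abs=0.12)


def test_residuals_identity_and_centering():
    y, X, fam, *_ = _balanced_oneway(seed=7)
    fit = fit_lmm_nested(y, X, fam)
    r = lmm_residuals(fit)
    assert abs(r.mean()) < 1e-8  # X contains an intercept
    rc = lmm_residuals(fit, conditional=True)
    assert np.var(rc) < np.var(r) + 1e-12
    # zero effects: residuals equal y
    fit.beta = np.zeros_like(fit.beta)
    fit.sigma2_family = 0.0
    assert np.allclose(lmm_residuals(fit, conditional=True), y)


def test_non_nested_clusters_rejected():
    y, X, fam, *_ = _balanced_oneway()
    cen = np.arange(y.size) % 3  # families straddle centers
    with pytest.raises(ValueError):
        fit_lmm_nested(y, X, fam, cen)
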