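import numpy as np
import pytest

import famvar as fv
from famvar.nbglmm import (
    fit_nb_glm,
    fit_nb_glmm,
    lrt_family_variance_nb,
    nb_deviance_residuals,
    poisson_vs_nb_comparison,
)


def _sim_counts(seed, n_fam=200, size=2, beta0=-1.0, alpha=0.5, s2=0.3,
                beta_x=0.2):
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(n_fam), size)
    n = fam.size
    x = rng.integers(0, 2, n).astype(float)
    off = np.log(rng.uniform(5.0, 30.0, n))
    b = rng.normal(0.0, np.sqrt(s2), n_fam)
    m = np.exp(beta0 + beta_x * x + off + b[fam])
    if alpha > 0:
        y = rng.poisson(rng.gamma(1 / alpha, alpha * m)).astype(float)
    else:
        y = rng.poisson(m).astype(float)
    return y, np.column_stack([np.ones(n), x]), off, fam


def test_collapses_to_plain_nb2_on_singletons():
    import statsmodels.api as sm

    y, X, off, _ = _sim_counts(seed=8, n_fam=2000, size=1, s2=0.0)
    fit = fit_nb_glmm(y, X, off, np.arange(y.size))
    ref = sm.NegativeBinomial(y, X, offset=off).fit(disp=0)
    bse = np.asarray(ref.bse)
    assert abs(fit.beta[0] - ref.params[0]) < 3 * bse[0]
    assert abs(fit.beta[1] - ref.params[1]) < 3 * bse[1]
    assert abs(fit.alpha - ref.params[-1]) < 3 * bse[-1] + 0.03


def test_aghq_seven_close_to_high_order():
    y, X, off, fam = _sim_counts(seed=9, n_fam=30, size=4)
    f7 = fit_nb_glmm(y, X, off, fam, n_quad=7)
    f51 = fit_nb_glmm(y, X, off, fam, n_quad=51)
    assert abs(f7.loglik - f51.loglik) < 1e-4
    # accuracy improves monotonically towards a very high order reference
    from famvar.nbglmm import _Marginal

    ref = _Marginal(y, X, off, fam, 101, "nb").loglik(
        f51.beta, f51.alpha, f51.sigma2_family
    )[0]
    errs = []
    for q in (3, 7, 15):
        ll = _Marginal(y, X, off, fam, q, "nb").loglik(
            f51.beta, f51.alpha, f51.sigma2_family
        )[0]
        errs.append(abs(ll - ref))
    assert errs[0] >= errs[1] >= errs[2] - 1e-12


def test_parameter_recovery():
    y, X, off, fam = _sim_counts(seed=10, n_fam=3000, size=2,
                                 beta0=0.5, alpha=0.5, s2=0.3)
    fit = fit_nb_glmm(y, X, off, fam)
    se = np.sqrt(np.diag(fit.varpar_cov))
    p = fit.beta.size
    assert abs(fit.beta[0] - 0.5) < 3 * se[0]
    assert abs(np.log(fit.alpha) - np.log(0.5)) < 3 * se[p]
    assert abs(np.log(fit.sigma2_family) - np.log(0.3)) < 3 * se[p + 1]


def test_poisson_limit_of_nb_likelihood():
    y, X, off, fam = _sim_counts(seed=11, n_fam=40, size=3, alpha=0.0)
    fp = fit_nb_glmm(y, X, off, fam, family="poisson")
    from famvar.nbglmm import _Marginal

    m = _Marginal(y, X, off, fam, 7, "nb")
    gaps = [
        abs(m.loglik(fp.beta, a, fp.sigma2_family)[0] - fp.loglik)
        for a in (1e-2, 1e-4, 1e-6, 1e-8)
    ]
    assert gaps[0] > gaps[1] > gaps[2] >= gaps[3]
    assert gaps[-1] < 1e-4


def test_overdispersion_lrt_nesting_and_power():
    # NB likelihood never below Poisson; strong overdispersion detected
    y, X, off, fam = _sim_counts(seed=12, n_fam=500, size=2, alpha=1.0)
    fit_p, fit_nb, (stat, p) = poisson_vs_nb_comparison(y, X, off, fam)
    assert fit_nb.loglik >= fit_p.loglik - 1e-9
    assert p < 1e-6


def test_family_variance_lrt_detects_clustering():
    y, X, off, fam = _sim_counts(seed=13, n_fam=600, size=3, s2=0.5)
    glmm = fit_nb_glmm(y, X, off, fam)
    glm = fit_nb_glm(y, X, off)
    stat, p = lrt_family_variance_nb(glmm, glm)
    assert stat > 0 and p < 1e-4


def test_deviance_residual_reference_value():
    # d for y=5, m=2, alpha=0.5 from the closed-form NB2 deviance
    fit = _fit_stub(y=np.array([5.0]), m=np.array([2.0]), alpha=0.5)
    d = nb_deviance_residuals(fit)
    assert d[0] == pytest.approx(1.1525, abs=1e-3)


def _fit_stub(y, m, alpha):
    from famvar.nbglmm import NbGlmmFit

    n = y.size
    return NbGlmmFit(
        beta=np.log(m), alpha=alpha, sigma2_family=0.0, loglik=0.0,
        varpar_cov=np.eye(n + 2), n_quad=7, n_obs=n, n_families=n,
        converged=True, blups=np.zeros(n), _y=y, _X=np.eye(n),
        _offset=np.zeros(n), _fam_idx=np.arange(n),
    )


def test_deviance_residual_zero_at_perfect_fit_and_poisson_limit():
    fit = _fit_stub(y=np.array([3.0]), m=np.array([3.0]), alpha=0.7)
    assert nb_deviance_residuals(fit)[0] == pytest.approx(0.0, abs=1e-6)
    # y = 0 handled; alpha -> 0 equals Poisson deviance
    fit0 = _fit_stub(y=np.array([0.0, 4.0]), m=np.array([2.0, 2.0]), alpha=0.0)
    d = nb_deviance_residuals(fit0)
    pois = np.sign([-1, 1]) * np.sqrt(
        2 * (np.array([0.0, 4 * np.log(2.0)]) - np.array([-2.0, 2.0]))
    )
    assert np.allclose(d, pois, atol=1e-10)


def test_deviance_residuals_shrink_with_covariates():
    y, X, off, fam = _sim_counts(seed=14, n_fam=400, size=2, beta_x=0.8)
    full = fit_nb_glm(y, X, off)
    null = fit_nb_glm(y, X[:, :1], off)
    assert np.sum(nb_deviance_residuals(full) ** 2) < np.sum(
        nb_deviance_residuals(null) ** 2
    )


def test_estimates_invariant_to_relabelling():
    y, X, off, fam = _sim_counts(seed=15, n_fam=100, size=3)
    fit = fit_nb_glmm(y, X, off, fam)
    rng = np.random.default_rng(0)
    perm = rng.permutation(y.size)
    relabel = {f: chr(65 + (f * 7) % 90) + str(f * 13 % 97) for f in set(fam)}
    fam2 = np.array([relabel[f] for f in fam])[perm]
    fit2 = fit_nb_glmm(y[perm], X[perm], off[perm], fam2)
    assert fit.loglik == pytest.approx(fit2.loglik, abs=1e-5)
    assert fit.sigma2_family == pytest.approx(fit2.sigma2_family, rel=1e-3)


def test_input_validation():
    y, X, off, fam = _sim_counts(seed=16, n_fam=20, size=2)
    with pytest.raises(ValueError):
        fit_nb_glmm(-y, X, off, fam)
    with pytest.raises(ValueError):
        fit_nb_glmm(y, X, np.full_like(off, np.inf), fam)
    with pytest.raises(ValueError):
        fit_nb_glmm(np.full_like(y, 2.0), X, off, fam)
    with pytest.raises(ValueError):
        fit_nb_glmm(y, X, off, fam, n_quad=2)
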