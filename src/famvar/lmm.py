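"""REML fitting of nested random-intercept linear mixed models.

The models here have the shape used for familiality analysis of quantitative
subphenotypes: a Gaussian response with fixed covariates and one or two
nested random intercepts (subjects within families, families optionally
nested within recruitment centers),

    y = X b + Z_c u_c + Z_f u_f + e,
    u_c ~ N(0, s2c I),  u_f ~ N(0, s2f I),  e ~ N(0, s2e I).

Because both random effects are scalar intercepts on disjoint nested
clusters, V = s2e I + s2f Z_f Z_f' + s2c Z_c Z_c' has a closed-form inverse:
a per-family Woodbury step followed by a per-center rank-one update.  All
REML quantities are therefore O(n) per evaluation, and the restricted
likelihood is maximised by profiling the residual variance and optimising
over the (log) variance ratios, with explicit refits on the s2=0 boundaries.

The reported REML log-likelihood includes the +0.5 log|X'X| constant, which
makes it invariant to reparameterisations of the fixed-effect column basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .icc import IccEstimate, _logit_ci

__all__ = [
    "LmmFit",
    "fit_lmm_nested",
    "lrt_family_variance",
    "residual_icc",
    "lmm_residuals",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class LmmFit:
    """Converged REML fit of the nested random-intercept model."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_center: float
    sigma2_family: float
    sigma2_e: float
    loglik_reml: float
    varpar_cov: np.ndarray  # 3x3, order (center, family, residual)
    n_obs: int
    n_families: int
    n_centers: int
    converged: bool
    boundary: dict = field(default_factory=dict)
    has_center: bool = True
    # data retained for residual extraction / refits
    _y: np.ndarray = field(default=None, repr=False)
    _X: np.ndarray = field(default=None, repr=False)
    _fam_idx: np.ndarray = field(default=None, repr=False)
    _cen_idx: np.ndarray = field(default=None, repr=False)


class _Structure:
    """Index bookkeeping for the nested design; validates nesting."""

    def __init__(self, family_ids, center_ids=None):
        family_ids = np.asarray(family_ids)
        self.fam_codes, self.fam_idx = np.unique(family_ids, return_inverse=True)
        self.n_fam = self.fam_codes.size
        self.fam_sizes = np.bincount(self.fam_idx)
        if center_ids is None:
            self.cen_idx = None
            self.n_cen = 0
            self.cen_of_fam = None
        else:
            center_ids = np.asarray(center_ids)
            if center_ids.shape != family_ids.shape:
                raise ValueError("family_ids and center_ids length mismatch")
            self.cen_codes, self.cen_idx = np.unique(center_ids, return_inverse=True)
            self.n_cen = self.cen_codes.size
            cof = np.full(self.n_fam, -1, dtype=int)
            for f, c in zip(self.fam_idx, self.cen_idx):
                if cof[f] == -1:
                    cof[f] = c
                elif cof[f] != c:
                    raise ValueError(
                        "clusters are not nested: family "
                        f"{self.fam_codes[f]!r} spans multiple centers"
                    )
            self.cen_of_fam = cof

    @property
    def has_center(self):
        return self.cen_idx is not None


def _vinv_apply(U, s2c, s2f, s2e, st: _Structure):
    """Compute V^{-1} U and log|V| via Woodbury; U is (n,) or (n, q)."""
    U = np.atleast_2d(U.T).T  # (n, q)
    n = U.shape[0]
    d = s2e + st.fam_sizes * s2f  # (F,)
    famsum = np.empty((st.n_fam, U.shape[1]))
    for j in range(U.shape[1]):
        famsum[:, j] = np.bincount(st.fam_idx, weights=U[:, j], minlength=st.n_fam)
    # D^{-1} U with D = s2e I + s2f per-family J
    A = U / s2e - (s2f / (s2e * d))[st.fam_idx, None] * famsum[st.fam_idx, :]
    logdet = float(np.sum((st.fam_sizes - 1) * np.log(s2e) + np.log(d)))
    if st.has_center and s2c > 0:
        # rank-one update per center: V = D + s2c 1_k 1_k'
        g = np.bincount(st.cen_of_fam, weights=st.fam_sizes / d, minlength=st.n_cen)
        c = s2c / (1.0 + s2c * g)  # (K,)
        censum = np.empty((st.n_cen, U.shape[1]))
        for j in range(U.shape[1]):
            censum[:, j] = np.bincount(st.cen_idx, weights=A[:, j], minlength=st.n_cen)
        dinv_one = (1.0 / d)[st.fam_idx]  # D^{-1} 1 per row
        A = A - c[st.cen_idx, None] * censum[st.cen_idx, :] * dinv_one[:, None]
        logdet += float(np.sum(np.log1p(s2c * g)))
    return A, logdet


def _reml_loglik(y, X, s2c, s2f, s2e, st: _Structure, logdet_xtx):
    n, p = X.shape
    VX, logdetV = _vinv_apply(X, s2c, s2f, s2e, st)
    Vy, _ = _vinv_apply(y, s2c, s2f, s2e, st)
    Vy = Vy[:, 0]
    XtVX = X.T @ VX
    XtVy = X.T @ Vy
    L = np.linalg.cholesky(XtVX)
    beta = np.linalg.solve(XtVX, XtVy)
    quad = float(y @ Vy - beta @ XtVy)
    logdet_xvx = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (logdetV + logdet_xvx + quad + (n - p) * np.log(2 * np.pi))
    ll += 0.5 * logdet_xtx
    return ll, beta, XtVX, quad


def _profiled_objective(log_gammas, y, X, st, include_center):
    """Negative profiled REML (s2e profiled out) over log variance ratios."""
    n, p = X.shape
    if include_center:
        gc, gf = np.exp(log_gammas)
    else:
        gc, gf = 0.0, float(np.exp(log_gammas[0]))
    VX, logdetR = _vinv_apply(X, gc, gf, 1.0, st)
    Vy, _ = _vinv_apply(y, gc, gf, 1.0, st)
    Vy = Vy[:, 0]
    XtVX = X.T @ VX
    XtVy = X.T @ Vy
    try:
        beta = np.linalg.solve(XtVX, XtVy)
        s, logdet_xvx = np.linalg.slogdet(XtVX)
        if s <= 0:
            return 1e12
    except np.linalg.LinAlgError:
        return 1e12
    rss = float(y @ Vy - beta @ XtVy)
    if rss <= 0:
        return 1e12
    s2e_hat = rss / (n - p)
    return 0.5 * ((n - p) * np.log(s2e_hat) + logdetR + logdet_xvx)


def _optimize_ratios(y, X, st, include_center):
    """Grid start + Nelder-Mead over log variance ratios."""
    grid = np.linspace(-7.0, 2.0, 7)
    best, best_val = None, np.inf
    if include_center:
        for a in grid:
            for b in grid:
                v = _profiled_objective((a, b), y, X, st, True)
                if v < best_val:
                    best, best_val = np.array([a, b]), v
    else:
        for b in grid:
            v = _profiled_objective((b,), y, X, st, False)
            if v < best_val:
                best, best_val = np.array([b]), v
    res = minimize(
        _profiled_objective,
        best,
        args=(y, X, st, include_center),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000, "maxfev": 4000},
    )
    return res


def fit_lmm_nested(y, X, family_ids, center_ids=None) -> LmmFit:
    """REML fit of y = Xb + (center) + (family) + e with nested clusters.

    ``center_ids=None`` fits the two-level model (family random intercept
    only).  Variance components are constrained non-negative; estimates on
    the zero boundary are refit with the component removed and flagged in
    ``fit.boundary``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X length mismatch")
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design X is rank deficient")
    st = _Structure(family_ids, center_ids)
    if st.fam_idx.size != n:
        raise ValueError("cluster label length mismatch")
    logdet_xtx = float(np.linalg.slogdet(X.T @ X)[1])

    include_center = st.has_center
    res = _optimize_ratios(y, X, st, include_center)
    if include_center:
        gc, gf = np.exp(res.x)
    else:
        gc, gf = 0.0, float(np.exp(res.x[0]))
    boundary = {}
    # boundary refits: a ratio driven to ~0 means the component is at zero
    if gf < 1e-7:
        gf, boundary["family"] = 0.0, True
    if include_center and gc < 1e-7:
        gc, boundary["center"] = 0.0, True
        if gf > 0:  # re-optimise family ratio without the center component
            res2 = _optimize_ratios(y, X, st, False)
            gf = float(np.exp(res2.x[0]))
            if gf < 1e-7:
                gf, boundary["family"] = 0.0, True

    # back out the natural-scale variances at the profiled optimum
    Vy, _ = _vinv_apply(y, gc, gf, 1.0, st)
    VX, _ = _vinv_apply(X, gc, gf, 1.0, st)
    XtVX = X.T @ VX
    beta = np.linalg.solve(XtVX, X.T @ Vy[:, 0])
    rss = float(y @ Vy[:, 0] - beta @ (X.T @ Vy[:, 0]))
    s2e = rss / (n - p)
    s2f = gf * s2e
    s2c = gc * s2e

    ll, beta, XtVX, _ = _reml_loglik(y, X, s2c, s2f, s2e, st, logdet_xtx)
    beta_cov = np.linalg.inv(XtVX)
    varpar_cov = _varpar_cov(y, X, s2c, s2f, s2e, st, logdet_xtx, boundary,
                             include_center)
    return LmmFit(
        beta=beta,
        beta_cov=beta_cov,
        sigma2_center=s2c,
        sigma2_family=s2f,
        sigma2_e=s2e,
        loglik_reml=ll,
        varpar_cov=varpar_cov,
        n_obs=n,
        n_families=st.n_fam,
        n_centers=st.n_cen,
        converged=bool(res.success),
        boundary=boundary,
        has_center=include_center,
        _y=y,
        _X=X,
        _fam_idx=st.fam_idx,
        _cen_idx=st.cen_idx,
    )


def _varpar_cov(y, X, s2c, s2f, s2e, st, logdet_xtx, boundary, include_center):
    """Sampling covariance of (s2c, s2f, s2e) from the numeric REML Hessian.

    Components fixed on the zero boundary (or absent) get zero rows/columns.
    """
    active = []
    vals = [s2c, s2f, s2e]
    if include_center and not boundary.get("center"):
        active.append(0)
    if not boundary.get("family"):
        active.append(1)
    active.append(2)

    def f(theta_active):
        v = list(vals)
        for k, idx in enumerate(active):
            v[idx] = theta_active[k]
        return _reml_loglik(y, X, v[0], v[1], v[2], st, logdet_xtx)[0]

    x0 = np.array([vals[i] for i in active])
    h = np.maximum(1e-5, 1e-4 * np.abs(x0))
    m = len(active)
    H = np.zeros((m, m))
    f0 = f(x0)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    cov_active = np.linalg.pinv(-H)
    cov = np.zeros((3, 3))
    for a, ia in enumerate(active):
        for b, ib in enumerate(active):
            cov[ia, ib] = cov_active[a, b]
    return cov


def lrt_family_variance(fit_full: LmmFit, fit_reduced: LmmFit):
    """Boundary LRT for the family variance component.

    The null value sits on the parameter-space boundary, so the statistic is
    referred to the 50:50 mixture of chi2_0 and chi2_1.
    """
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("full and reduced fits use different data")
    from scipy.stats import chi2

    stat = max(0.0, 2.0 * (fit_full.loglik_reml - fit_reduced.loglik_reml))
    p = 0.5 if stat == 0.0 else 0.5 * float(chi2.sf(stat, df=1))
    return stat, p


def residual_icc(fit: LmmFit, include_center: bool = False) -> IccEstimate:
    """Family-level residual intraclass correlation from a fitted LMM.

    Default (``include_center=False``): icc = s2f / (s2f + s2e), the sibling
    correlation conditional on center.  With ``include_center=True``:
    icc = (s2c + s2f) / (s2c + s2f + s2e).  Delta-method SE from the
    variance-parameter covariance; 95% CI on the logit scale.
    """
    s2c, s2f, s2e = fit.sigma2_center, fit.sigma2_family, fit.sigma2_e
    num = s2f + (s2c if include_center else 0.0)
    den = s2f + s2e + (s2c if include_center else 0.0)
    if den <= 0:
        raise ValueError("all variance components are zero")
    icc = num / den
    # gradient of icc wrt (s2c, s2f, s2e)
    if include_center:
        g = np.array([s2e / den**2, s2e / den**2, -num / den**2])
    else:
        g = np.array([0.0, s2e / den**2, -num / den**2])
    se = float(np.sqrt(max(0.0, g @ fit.varpar_cov @ g)))
    lo, hi = _logit_ci(icc, se)
    return IccEstimate(icc=icc, se=se, ci_low=lo, ci_high=hi, method="lmm_residual")


def _blups(fit: LmmFit):
    st = _Structure(fit._fam_idx, fit._cen_idx)
    r = fit._y - fit._X @ fit.beta
    Vr, _ = _vinv_apply(r, fit.sigma2_center, fit.sigma2_family, fit.sigma2_e, st)
    Vr = Vr[:, 0]
    u_f = fit.sigma2_family * np.bincount(st.fam_idx, weights=Vr, minlength=st.n_fam)
    if st.has_center:
        u_c = fit.sigma2_center * np.bincount(
            st.cen_idx, weights=Vr, minlength=st.n_cen
        )
    else:
        u_c = None
    return r, u_f, u_c, st


def lmm_residuals(fit: LmmFit, conditional: bool = False):
    """Residuals from a fitted LMM.

    ``conditional=False``: marginal residuals y - X beta_hat.
    ``conditional=True``: additionally subtract the BLUPs of every random
    effect present in the model (for the GREML residualisation workflow the
    model carries only a center intercept, so this subtracts fixed effects
    and center BLUPs).
    """
    r, u_f, u_c, st = _blups(fit)
    if not conditional:
        return r
    out = r - u_f[st.fam_idx]
    if u_c is not None:
        out = out - u_c[st.cen_idx]
    return out
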