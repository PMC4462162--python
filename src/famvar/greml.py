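"""Self-contained GREML: GRM construction, relatedness pruning, PCA, AI-REML.

SNP heritability is estimated under y = Xb + g + e with g ~ N(0, A s2g),
e ~ N(0, I s2e), where A is the genetic relationship matrix built from
standardized genotypes:

    A_jk = (1 / M_jk) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

over the M_jk SNPs non-missing in both individuals.  REML maximisation uses
average-information (AI) updates with EM fallback steps, components
constrained non-negative, and a one-sided boundary LRT for s2g > 0 against
the 50:50 chi2_0/chi2_1 mixture.

All REML linear algebra runs in the eigenbasis of A (computed once per
fit), where V = s2g D + s2e I is diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import chi2

__all__ = [
    "GenotypeMatrix",
    "GRM",
    "GremlResult",
    "compute_grm",
    "prune_relatedness",
    "grm_pca",
    "fit_greml",
]


@dataclass
class GenotypeMatrix:
    """Additive genotype codes (counts of allele A1) for N individuals x M SNPs.

    ``codes`` is float with NaN for missing.  ``snps`` is a record of per-SNP
    metadata arrays (id, chrom, bp, a1, a2).
    """

    ids: np.ndarray  # (N,) individual identifiers
    codes: np.ndarray  # (N, M) in {0, 1, 2, nan}
    snp_ids: np.ndarray
    chrom: np.ndarray
    bp: np.ndarray
    a1: np.ndarray
    a2: np.ndarray

    @property
    def freqs(self) -> np.ndarray:
        """Estimated A1 allele frequencies (missing-aware)."""
        return np.nanmean(self.codes, axis=0) / 2.0

    @property
    def n_ind(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.codes.shape[1]


@dataclass
class GRM:
    ids: np.ndarray  # (N,)
    values: np.ndarray  # (N, N) symmetric relatedness
    pair_n: np.ndarray  # (N, N) SNPs used per pair

    @property
    def n(self) -> int:
        return self.ids.size

    def subset(self, keep_idx) -> "GRM":
        keep_idx = np.asarray(keep_idx)
        return GRM(
            ids=self.ids[keep_idx],
            values=self.values[np.ix_(keep_idx, keep_idx)],
            pair_n=self.pair_n[np.ix_(keep_idx, keep_idx)],
        )


@dataclass
class GremlResult:
    sigma2_g: float
    sigma2_e: float
    h2: float
    se_h2: float
    lrt: float
    p: float
    n_used: int
    loglik: float
    loglik_null: float
    n_iter: int
    converged: bool
    ai_cov: np.ndarray = field(default=None, repr=False)


def compute_grm(g: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """Genetic relationship matrix from additive codes.

    Allele frequencies are estimated from the full input sample; SNPs with
    minor allele frequency below ``maf_min`` are excluded; missing genotypes
    contribute neither to the numerator nor to the per-pair SNP counts.
    """
    if g.n_ind < 2:
        raise ValueError("need at least two individuals")
    p = g.freqs
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if not np.any(keep):
        raise ValueError("no SNPs pass the MAF filter")
    x = g.codes[:, keep]
    p = p[keep]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    w = (x - 2.0 * p) / denom
    obs = np.isfinite(w)
    w = np.where(obs, w, 0.0)
    pair_n = obs.astype(np.float64) @ obs.astype(np.float64).T
    vals = (w @ w.T) / np.maximum(pair_n, 1.0)
    vals[pair_n == 0] = 0.0
    return GRM(ids=np.asarray(g.ids).copy(), values=vals, pair_n=pair_n)


def prune_relatedness(grm: GRM, cutoff: float = 0.025) -> np.ndarray:
    """Greedy pruning so no retained off-diagonal pair exceeds ``cutoff``.

    While any pair exceeds the cutoff, the individual participating in the
    most offending pairs is dropped (ties resolved by input order).
    Returns the retained indices (input order preserved).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = grm.n
    A = grm.values.copy()
    np.fill_diagonal(A, 0.0)
    active = np.ones(n, dtype=bool)
    offending = (np.abs(A) > 0) & (A > cutoff)
    deg = offending.sum(axis=1)
    while True:
        deg_active = np.where(active, deg, -1)
        worst = int(np.argmax(deg_active))
        if deg_active[worst] <= 0:
            break
        active[worst] = False
        hit = offending[worst] & active
        deg[hit] -= 1
        offending[worst, :] = False
        offending[:, worst] = False
        deg[worst] = 0
    retained = np.flatnonzero(active)
    if retained.size == 0:
        raise ValueError("all individuals removed by relatedness pruning")
    return retained


def grm_pca(grm: GRM, k: int = 10) -> np.ndarray:
    """Top-k principal component scores of the GRM.

    Eigenvectors scaled by sqrt(eigenvalue); sign fixed so each component's
    largest-magnitude loading is positive.
    """
    if k >= grm.n:
        raise ValueError("k must be smaller than the number of individuals")
    vals, vecs = np.linalg.eigh(grm.values)
    order = np.argsort(vals)[::-1][:k]
    vals = np.maximum(vals[order], 0.0)
    vecs = vecs[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs * np.sqrt(vals)


def _reml_loglik_eig(d, yt, Xt, s2g, s2e):
    """Restricted log-likelihood in the GRM eigenbasis (V diagonal)."""
    v = s2g * d + s2e
    if np.any(v <= 0):
        return -np.inf, None, None
    vinv_y = yt / v
    vinv_X = Xt / v[:, None]
    XtVX = Xt.T @ vinv_X
    XtVy = Xt.T @ vinv_y
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf, None, None
    beta = np.linalg.solve(XtVX, XtVy)
    quad = float(yt @ vinv_y - beta @ XtVy)
    n, p = Xt.shape
    ll = -0.5 * (np.sum(np.log(v)) + logdet_xvx + quad + (n - p) * np.log(2 * np.pi))
    return float(ll), beta, XtVX


def _py_eig(d, yt, Xt, s2g, s2e):
    """P y and the projection pieces, all in the eigenbasis."""
    v = s2g * d + s2e
    vinv_y = yt / v
    vinv_X = Xt / v[:, None]
    XtVX = Xt.T @ vinv_X
    beta = np.linalg.solve(XtVX, Xt.T @ vinv_y)
    py = vinv_y - vinv_X @ beta
    return py, v, vinv_X, XtVX


def fit_greml(
    y,
    covariates,
    grm: GRM,
    max_iter: int = 100,
    tol_loglik: float = 1e-6,
    tol_grad: float = 1e-4,
) -> GremlResult:
    """AI-REML estimation of (s2g, s2e) and h2 = s2g / (s2g + s2e).

    ``covariates`` is the fixed-effect design (an intercept is appended if
    absent).  Starts at s2g = s2e = var(y)/2; AI steps with EM fallback when
    the proposed step leaves the feasible region or the AI matrix is not
    positive definite; components clipped at 1e-8 * var(y) during
    iteration.  ``se_h2`` by the delta method from the inverse AI matrix.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if grm.n != n:
        raise ValueError("GRM and phenotype dimensions differ")
    if np.var(y) == 0:
        raise ValueError("phenotype has zero variance")
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.size == 0:
        X = np.ones((n, 1))
    if X.shape[0] != n:
        X = X.T
    if not np.any(np.all(X == X[0, :], axis=0) & (X[0, :] != 0)):
        X = np.column_stack([np.ones(n), X])

    d, U = np.linalg.eigh(grm.values)
    if d.min() < -1e-6 * max(1.0, d.max()):
        d = np.maximum(d, 0.0)  # tolerate slight indefiniteness from pair_n
    yt = U.T @ y
    Xt = U.T @ X

    vary = float(np.var(y, ddof=1))
    floor = 1e-8 * vary
    s2g = s2e = vary / 2.0
    ll_old, _, _ = _reml_loglik_eig(d, yt, Xt, s2g, s2e)
    n_iter = 0
    converged = False
    AI = np.eye(2)
    for n_iter in range(1, max_iter + 1):
        py, v, vinv_X, XtVX = _py_eig(d, yt, Xt, s2g, s2e)
        # traces of P V_i via the eigenbasis (V_g = diag(d), V_e = I)
        XtVX_inv = np.linalg.inv(XtVX)
        for_dg = d / v
        for_de = 1.0 / v
        tr_pg = float(np.sum(for_dg)) - float(
            np.einsum("ij,ik,kj->", XtVX_inv, vinv_X.T * d, vinv_X)
        )
        tr_pe = float(np.sum(for_de)) - float(
            np.einsum("ij,ik,kj->", XtVX_inv, vinv_X.T, vinv_X)
        )
        apy = d * py
        # P applied again (for y'P V_i P V_j P y): project V_i P y
        def P(z):
            vz = z / v
            return vz - (Xt / v[:, None]) @ np.linalg.solve(XtVX, Xt.T @ vz)
        p_apy = P(apy)
        p_py = P(py)
        grad = np.array(
            [
                -0.5 * (tr_pg - float(py @ apy)),
                -0.5 * (tr_pe - float(py @ py)),
            ]
        )
        AI = 0.5 * np.array(
            [
                [float(apy @ p_apy), float(apy @ p_py)],
                [float(apy @ p_py), float(py @ p_py)],
            ]
        )
        step_ok = False
        try:
            delta = np.linalg.solve(AI, grad)
            cand = np.array([s2g, s2e]) + delta
            if np.all(np.isfinite(cand)) and np.min(np.linalg.eigvalsh(AI)) > 0:
                cand = np.maximum(cand, floor)
                ll_new, _, _ = _reml_loglik_eig(d, yt, Xt, cand[0], cand[1])
                if np.isfinite(ll_new):
                    step_ok = True
        except np.linalg.LinAlgError:
            pass
        if not step_ok or ll_new < ll_old - 1e-4:
            # EM fallback step
            s2g_new = s2g + (s2g**2 / n) * (float(py @ apy) - tr_pg)
            s2e_new = s2e + (s2e**2 / n) * (float(py @ py) - tr_pe)
            cand = np.maximum(np.array([s2g_new, s2e_new]), floor)
            ll_new, _, _ = _reml_loglik_eig(d, yt, Xt, cand[0], cand[1])
        s2g, s2e = float(cand[0]), float(cand[1])
        if (
            abs(ll_new - ll_old) < tol_loglik
            and float(np.linalg.norm(grad)) < tol_grad * max(1.0, abs(ll_new))
        ):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    ll, beta, _ = _reml_loglik_eig(d, yt, Xt, s2g, s2e)

    tot = s2g + s2e
    h2 = s2g / tot
    try:
        ai_cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        ai_cov = np.linalg.pinv(AI)
    g = np.array([s2e, -s2g]) / tot**2
    se_h2 = float(np.sqrt(max(0.0, g @ ai_cov @ g)))

    # null model: s2g = 0 -> OLS residual variance (REML)
    ll_null = _null_reml_loglik(y, X)
    lrt = max(0.0, 2.0 * (ll - ll_null))
    p = 0.5 if lrt == 0.0 else 0.5 * float(chi2.sf(lrt, df=1))
    p = min(max(p, np.nextafter(0, 1)), 0.5)
    return GremlResult(
        sigma2_g=s2g,
        sigma2_e=s2e,
        h2=h2,
        se_h2=se_h2,
        lrt=lrt,
        p=p,
        n_used=n,
        loglik=ll,
        loglik_null=ll_null,
        n_iter=n_iter,
        converged=converged,
        ai_cov=ai_cov,
    )


def _null_reml_loglik(y, X):
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    rss = float(r @ r)
    s2 = rss / (n - p)
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)
    ll = -0.5 * (
        n * np.log(s2)
        + (logdet_xtx - p * np.log(s2))
        + (n - p)
        + (n - p) * np.log(2 * np.pi)
    )
    return float(ll)
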