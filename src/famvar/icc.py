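"""Intraclass correlations for clustered count data and the shared ICC type.

For the count track the family ICC follows a variance decomposition of the
negative-binomial / log-normal random-intercept model.  With a family
intercept b ~ N(0, s2) on the log scale and conditional NB2 counts with
mean m = mu0 * exp(b) (per unit exposure) and variance m + alpha m^2, the
marginal expectation is mu = mu0 * exp(s2/2) and

    between-family variance  V_b = mu^2 (exp(s2) - 1)
    total variance           V_t = mu + alpha mu^2 exp(s2) + V_b

so icc = V_b / V_t — the expected correlation of two siblings' episode
rates.  An optional center variance s2_c extends the shared latent variance:
siblings share both family and center effects, giving
V_b = mu^2 exp(s2_c) (exp(s2) - 1) with total latent variance s2 + s2_c.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

__all__ = [
    "IccEstimate",
    "nb_lognormal_icc",
    "carrasco_icc",
    "empirical_icc_counts",
]


@dataclass(frozen=True)
class IccEstimate:
    """An intraclass correlation with its uncertainty and provenance."""

    icc: float
    se: float
    ci_low: float
    ci_high: float
    method: str  # lmm_residual | nb_carrasco | empirical
    mu_marginal: Optional[float] = None

    def __post_init__(self):
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not self.ci_low <= self.icc <= self.ci_high:
            raise ValueError("CI must bracket the point estimate")


def _logit_ci(icc: float, se: float, level: float = 0.95):
    """95% CI computed on the logit scale and back-transformed.

    Degenerate at the icc = 0 boundary, where the lower bound is pinned to 0.
    """
    z = norm.ppf(0.5 + level / 2)
    if icc <= 0.0 or se == 0.0:
        return 0.0 if icc <= 0 else icc, icc if se == 0 else icc
    if icc >= 1.0:
        return icc, 1.0
    lo_logit = np.log(icc / (1 - icc)) - z * se / (icc * (1 - icc))
    hi_logit = np.log(icc / (1 - icc)) + z * se / (icc * (1 - icc))
    return float(1 / (1 + np.exp(-lo_logit))), float(1 / (1 + np.exp(-hi_logit)))


def nb_lognormal_icc(
    mu: float, sigma2: float, alpha: float, sigma2_center: float = 0.0
) -> float:
    """Closed-form family ICC of the NB–log-normal random-intercept model.

    ``mu`` is the *marginal* count expectation (already including the
    exp(latent variance / 2) inflation).
    """
    if mu <= 0:
        raise ValueError("marginal expectation mu must be positive")
    if sigma2 < 0 or alpha < 0 or sigma2_center < 0:
        raise ValueError("variance parameters must be non-negative")
    s_tot = sigma2 + sigma2_center
    v_b = mu**2 * np.exp(sigma2_center) * (np.exp(sigma2) - 1.0)
    v_t = mu + alpha * mu**2 * np.exp(s_tot) + mu**2 * (np.exp(s_tot) - 1.0)
    if v_t == 0:
        return 0.0
    return float(v_b / v_t)


def carrasco_icc(
    fit,
    mu_mode: str = "model_marginal",
    center_variance: Optional[float] = None,
    offset_value: float = 0.0,
) -> IccEstimate:
    """Count-data family ICC from a fitted NB GLMM, with delta-method SE.

    ``fit`` is an :class:`~famvar.nbglmm.NbGlmmFit`.  ``mu_mode``:

    - ``"model_marginal"`` (default): mu = exp(beta0 + offset_value + s2/2)
      — evaluated per unit exposure (offset_value = 0, rate scale) so the
      ICC is exposure-free; pass the mean observed log offset to evaluate at
      the sample's average exposure instead.
    - ``"empirical_mean"``: mu = mean observed rate y / exp(offset), treated
      as a constant in the delta method.

    The SE propagates the fit's (beta, ln alpha, ln s2) covariance through
    the closed form; the 95% CI is on the logit scale.
    """
    if fit.alpha < 0 or fit.sigma2_family < 0:
        raise ValueError("fit has negative variance parameters")
    s2c = float(center_variance) if center_variance is not None else 0.0
    p = fit.beta.size

    def icc_of(params):
        beta0 = params[0]
        alpha = np.exp(params[p])
        s2 = np.exp(params[p + 1])
        if mu_mode == "model_marginal":
            mu = np.exp(beta0 + offset_value + 0.5 * (s2 + s2c))
        elif mu_mode == "empirical_mean":
            mu = float(np.mean(fit._y / np.exp(fit._offset)))
        else:
            raise ValueError(f"unknown mu_mode {mu_mode!r}")
        return nb_lognormal_icc(mu, s2, alpha, sigma2_center=s2c), mu

    packed = np.concatenate(
        [
            fit.beta,
            [np.log(max(fit.alpha, 1e-12)), np.log(max(fit.sigma2_family, 1e-12))],
        ]
    )
    icc, mu = icc_of(packed)
    grad = np.zeros(packed.size)
    h = 1e-5
    for i in list(range(1)) + [p, p + 1]:  # icc depends on beta0, ln a, ln s2 only
        e = np.zeros(packed.size)
        e[i] = h
        grad[i] = (icc_of(packed + e)[0] - icc_of(packed - e)[0]) / (2 * h)
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError("non-finite delta-method gradient")
    se = float(np.sqrt(max(0.0, grad @ fit.varpar_cov @ grad)))
    lo, hi = _logit_ci(icc, se)
    icc = min(max(icc, 0.0), 1.0 - 1e-12)
    return IccEstimate(
        icc=icc, se=se, ci_low=min(lo, icc), ci_high=max(hi, icc),
        method="nb_carrasco", mu_marginal=float(mu),
    )


def empirical_icc_counts(
    table, rate: bool = True, duration_floor: float = 0.5, n_batches: int = 20
) -> IccEstimate:
    """Moment (one-way ANOVA) family ICC of the observed episode rates.

    The model-free simulation oracle for :func:`carrasco_icc`: with k
    families of sizes n_i, grand size N and n0 the ANOVA average size,
    icc = (MSB - MSW) / (MSB + (n0 - 1) MSW).  The SE is the spread of
    per-batch estimates over ``n_batches`` family batches.
    """
    fam = np.asarray(table["family_id"])
    counts = np.asarray(table["episode_count"], dtype=float)
    if rate and "duration" in getattr(table, "columns", []):
        x = counts / np.maximum(np.asarray(table["duration"], float), duration_floor)
    else:
        x = counts
    codes, idx = np.unique(fam, return_inverse=True)
    sizes = np.bincount(idx)
    if np.all(sizes < 2):
        raise ValueError("need families with >= 2 members")
    keep = sizes[idx] >= 2
    x, idx = x[keep], idx[keep]
    codes2, idx = np.unique(idx, return_inverse=True)
    point = _anova_icc(x, idx)
    # batch families for a Monte-Carlo SE
    k = codes2.size
    rng = np.random.default_rng(0)
    perm = rng.permutation(k)
    batch_of_fam = np.empty(k, dtype=int)
    batch_of_fam[perm] = np.arange(k) % n_batches
    vals = []
    for b in range(n_batches):
        m = batch_of_fam[idx] == b
        if np.unique(idx[m]).size >= 2:
            _, sub = np.unique(idx[m], return_inverse=True)
            vals.append(_anova_icc(x[m], sub))
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
    icc = float(np.clip(point, 0.0, 1.0 - 1e-12))
    lo, hi = icc - 1.96 * se, icc + 1.96 * se
    return IccEstimate(
        icc=icc, se=se, ci_low=min(lo, icc), ci_high=max(hi, icc), method="empirical"
    )


def _anova_icc(x, idx):
    k = int(idx.max()) + 1
    sizes = np.bincount(idx, minlength=k).astype(float)
    N = x.size
    means = np.bincount(idx, weights=x, minlength=k) / sizes
    grand = x.mean()
    msb = float(np.sum(sizes * (means - grand) ** 2) / (k - 1))
    msw_num = float(np.sum((x - means[idx]) ** 2))
    if N - k == 0:
        return 1.0
    msw = msw_num / (N - k)
    n0 = (N - np.sum(sizes**2) / N) / (k - 1)
    if msw == 0.0:
        return 1.0
    return (msb - msw) / (msb + (n0 - 1) * msw)
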