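"""Analytic power for GREML SNP-heritability estimation in unrelated samples.

In a sample of n conventionally unrelated individuals the sampling variance
of the GREML heritability estimate is approximately

    var(h2_hat) = 2 / (n^2 * var(A_jk)),

where var(A_jk) is the variance of the off-diagonal entries of the genetic
relationship matrix (~2e-5 for common-SNP panels in European-ancestry
samples; ~1/M for M independent SNPs).  A true heritability h2 then yields a
noncentral chi-square test statistic with NCP = h2^2 / var(h2_hat), from
which power and the minimum detectable h2 follow in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import chi2, ncx2, norm

#: default off-diagonal GRM variance for dense common-SNP panels
DEFAULT_VAR_AIJ = 2e-5


@dataclass(frozen=True)
class PowerSpec:
    n: int
    h2: float = 0.0
    var_aij: float = DEFAULT_VAR_AIJ
    alpha: float = 0.05
    sidedness: str = "two"  # "one" | "two"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.var_aij <= 0:
            raise ValueError("var_aij must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.sidedness not in ("one", "two"):
            raise ValueError("sidedness must be 'one' or 'two'")


def h2_sampling_variance(n: int, var_aij: float = DEFAULT_VAR_AIJ) -> float:
    """Approximate sampling variance of the GREML h2 estimate."""
    return 2.0 / (n * n * var_aij)


def greml_power(spec: PowerSpec) -> float:
    """Power to detect ``spec.h2`` at test size ``spec.alpha``."""
    var = h2_sampling_variance(spec.n, spec.var_aij)
    ncp = spec.h2**2 / var
    if spec.sidedness == "two":
        crit = chi2.ppf(1.0 - spec.alpha, df=1)
        return float(ncx2.sf(crit, df=1, nc=ncp))
    z = norm.ppf(1.0 - spec.alpha)
    return float(norm.sf(z - spec.h2 / var**0.5))


def detectable_h2(
    n: int,
    var_aij: float = DEFAULT_VAR_AIJ,
    target_power: float = 0.8,
    alpha: float = 0.05,
    sidedness: str = "two",
) -> float:
    """Smallest h2 detectable with ``target_power`` at size ``alpha``.

    Inverts :func:`greml_power`; for the two-sided test
    h2 = sqrt(NCP(target_power, alpha) * var(h2_hat)).
    """
    if not alpha < target_power < 1:
        raise ValueError("target_power must lie in (alpha, 1)")
    var = h2_sampling_variance(n, var_aij)
    if sidedness == "two":
        crit = chi2.ppf(1.0 - alpha, df=1)
        ncp = brentq(
            lambda c: ncx2.sf(crit, df=1, nc=c) - target_power, 1e-10, 1e4
        )
        return float((ncp * var) ** 0.5)
    z = norm.ppf(1.0 - alpha)
    return float((z - norm.ppf(1.0 - target_power)) * var**0.5)
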