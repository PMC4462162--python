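"""Translate full-sibling intraclass correlations into heritability bounds.

Under standard quantitative-genetic assumptions the phenotypic covariance of
full siblings decomposes as

    COV_FS = 1/2 V_A + 1/4 V_D + V_C

(additive, dominance, shared-environment variance; epistasis ignored), and
their correlation is ICC = COV_FS / V_P.  Twice the sibling ICC therefore
equals the narrow-sense heritability V_A/V_P only when V_D and V_C are
negligible, and in general is an upper bound — the "maximal heritability".
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SibVarianceDecomposition:
    """Variance components of a quantitative trait among full siblings."""

    V_A: float  # additive genetic variance
    V_D: float  # dominance variance
    V_C: float  # shared (common) environment variance
    V_P: float  # total phenotypic variance

    def __post_init__(self):
        for name in ("V_A", "V_D", "V_C", "V_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.V_A + self.V_D + self.V_C > self.V_P * (1 + 1e-12):
            raise ValueError("V_A + V_D + V_C cannot exceed V_P")


def fullsib_covariance(d: SibVarianceDecomposition) -> tuple[float, float]:
    """Expected full-sibling covariance and correlation (ICC).

    Returns ``(cov_fs, icc)`` with cov_fs = 0.5 V_A + 0.25 V_D + V_C and
    icc = cov_fs / V_P.
    """
    if d.V_P == 0:
        raise ValueError("phenotypic variance V_P must be positive")
    cov_fs = 0.5 * d.V_A + 0.25 * d.V_D + d.V_C
    return cov_fs, cov_fs / d.V_P


def maximal_heritability(icc: float) -> float:
    """Upper-bound ("maximal") narrow-sense heritability from a sibling ICC.

    h2_max = min(2 * icc, 1).  Confidence-interval bounds are transformed by
    applying this same function to each bound.
    """
    if not 0.0 <= icc <= 1.0:
        raise ValueError("icc must lie in [0, 1]")
    return min(2.0 * icc, 1.0)
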