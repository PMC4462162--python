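"""Deterministic phenotype transforms shared across the analysis stages.

Age at onset (AAO) is positively skewed and is analysed on the square-root
scale.  Episode frequency is the lifetime episode count divided by illness
duration (age - AAO); it is analysed either as a count with a log-duration
offset or, after a natural-log transform, as a Gaussian response.  Residuals
destined for GREML are rank-normalised with Blom scores.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm, rankdata

#: years; keeps log(duration) finite for subjects whose onset is at interview age
DEFAULT_DURATION_FLOOR = 0.5


def sqrt_aao(aao):
    """Square-root transform of age at onset (years)."""
    aao = np.asarray(aao, dtype=float)
    if np.any(aao < 0):
        raise ValueError("age at onset must be non-negative")
    return np.sqrt(aao)


def ln_episode_frequency(count, duration, floor: float = DEFAULT_DURATION_FLOOR):
    """Natural log of episode frequency = count / max(duration, floor).

    ``count`` must be >= 1 (recurrent ascertainment guarantees at least one
    lifetime episode), otherwise the log is undefined.
    """
    count = np.asarray(count, dtype=float)
    duration = np.asarray(duration, dtype=float)
    if np.any(count < 1):
        raise ValueError("episode count must be >= 1 for log frequency")
    if np.any(duration < 0):
        raise ValueError("duration must be non-negative")
    return np.log(count / np.maximum(duration, floor))


def log_duration_offset(duration, floor: float = DEFAULT_DURATION_FLOOR):
    """ln(max(duration, floor)) — the exposure offset of the count model."""
    duration = np.asarray(duration, dtype=float)
    if np.any(duration < 0):
        raise ValueError("duration must be non-negative")
    return np.log(np.maximum(duration, floor))


def blom_rank_normalize(x):
    """Blom rank-based inverse-normal transform.

    z_i = Phi^{-1}((r_i - 3/8) / (n + 1/4)) with r_i the (average, for ties)
    rank of x_i.  Invariant under strictly monotone transforms of ``x``.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two observations to rank-normalize")
    if np.all(x == x[0]):
        raise ValueError("all input values identical: ranks are degenerate")
    r = rankdata(x, method="average")
    return norm.ppf((r - 3.0 / 8.0) / (n + 0.25))
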