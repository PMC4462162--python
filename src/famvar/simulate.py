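"""Synthetic family-phenotype tables and genotype-phenotype panels.

The family generator emulates an affected-full-sibling study of recurrent
major depression: families of 2-5 affected siblings nested within
recruitment centers, with a positively skewed age at onset (generated on
the square-root scale from a nested random-intercept Gaussian model) and an
overdispersed lifetime episode count (NB2 with a family intercept on the
log scale and illness duration as exposure).  All ground-truth parameters
travel with the table in a :class:`SimTruth`, enabling recovery tests.

The genotype generator draws independent SNPs under Hardy-Weinberg
equilibrium with a polygenic quantitative phenotype of known SNP
heritability; optional planted sibling pairs (expected relatedness 0.5)
exercise relatedness pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .greml import GenotypeMatrix
from .icc import nb_lognormal_icc

__all__ = [
    "SimTruth",
    "simulate_family_phenotypes",
    "simulate_genotype_phenotype",
    "write_phenotypes",
    "read_phenotypes",
    "PHENOTYPE_COLUMNS",
]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "family_id",
    "center_id",
    "sex",
    "age",
    "aao",
    "episode_count",
]

#: default family-size weights over sizes 2..5 (sibship composition not
#: published for the motivating study; smaller sibships dominate such samples)
DEFAULT_SIZE_WEIGHTS = {2: 0.55, 3: 0.25, 4: 0.13, 5: 0.07}

AAO_FLOOR = 5.0  # years; earliest admissible onset
AGE_RANGE = (18.0, 75.0)
AGE_MEAN, AGE_SD = 45.0, 12.0
DURATION_FLOOR = 0.5  # years; keeps ln(duration) finite


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth generative parameters for one simulated study.

    The AAO track lives on the square-root-years scale; the episode track on
    the log-rate (per-year) scale.
    """

    # sqrt(AAO) linear model
    aao_intercept: float = 5.0
    aao_beta_sex: float = -0.15
    aao_beta_age: float = 0.0  # >0 couples AAO to age (censoring-like pattern)
    aao_sigma2_center: float = 0.05
    aao_sigma2_family: float = 0.25
    aao_sigma2_e: float = 0.65
    # episode-count NB2 model, log rate per year of illness
    epi_intercept: float = -1.2
    epi_beta_sex: float = 0.05
    epi_beta_age: float = 0.005
    epi_alpha: float = 0.6
    epi_sigma2_family: float = 0.29
    epi_sigma2_center: float = 0.0
    # within-family correlation of chronological age
    age_icc: float = 0.3
    # filled in by the genotype generator
    h2_snp_true: float = float("nan")

    def __post_init__(self):
        for name in (
            "aao_sigma2_center", "aao_sigma2_family", "aao_sigma2_e",
            "epi_alpha", "epi_sigma2_family", "epi_sigma2_center",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.age_icc < 1.0:
            raise ValueError("age_icc must lie in [0, 1)")

    @property
    def icc_aao_true(self) -> float:
        """Family ICC of sqrt(AAO) conditional on center."""
        denom = self.aao_sigma2_family + self.aao_sigma2_e
        return self.aao_sigma2_family / denom if denom > 0 else 0.0

    @property
    def icc_epi_true(self) -> float:
        """Closed-form family ICC of the episode rate at reference covariates."""
        s_tot = self.epi_sigma2_family + self.epi_sigma2_center
        mu = float(np.exp(self.epi_intercept + 0.5 * s_tot))
        return nb_lognormal_icc(
            mu, self.epi_sigma2_family, self.epi_alpha, self.epi_sigma2_center
        )


def _draw_nb2(rng, mean, alpha):
    """NB2 draws via the gamma-Poisson mixture; alpha = 0 is Poisson."""
    if alpha < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / alpha
    lam = rng.gamma(shape=r, scale=mean / r)
    return rng.poisson(lam)


def simulate_family_phenotypes(
    n_families: int = 691,
    size_weights: dict | None = None,
    n_centers: int = 8,
    truth: SimTruth | None = None,
    seed: int = 0,
    recurrent: bool = True,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an affected-sibling family phenotype table.

    ``size_weights`` maps sibship sizes to probabilities (default
    :data:`DEFAULT_SIZE_WEIGHTS` over 2..5).  ``recurrent=True`` zero-
    truncates episode counts (resample until >= 1), mimicking recurrent-MDD
    ascertainment.  Identical seeds give bit-identical tables.
    """
    if n_families < 2:
        raise ValueError("need at least two families")
    truth = truth or SimTruth()
    weights = dict(size_weights or DEFAULT_SIZE_WEIGHTS)
    sizes_avail = np.array(sorted(weights))
    probs = np.array([weights[s] for s in sizes_avail], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("size weights must sum to 1")
    if np.any(sizes_avail < 1):
        raise ValueError("family sizes must be positive")

    root = np.random.SeedSequence(seed)
    rng_struct, rng_demo, rng_aao, rng_epi = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    sizes = rng_struct.choice(sizes_avail, size=n_families, p=probs)
    center_of_family = rng_struct.integers(0, n_centers, size=n_families)
    fam_idx = np.repeat(np.arange(n_families), sizes)
    n = fam_idx.size

    # demographics: sex (1 = female, the majority in MDD samples) and age
    # with a family-shared component so siblings' ages correlate
    sex = (rng_demo.random(n) < 0.68).astype(int)
    age_fam = rng_demo.normal(0.0, np.sqrt(truth.age_icc) * AGE_SD, n_families)
    age = AGE_MEAN + age_fam[fam_idx] + rng_demo.normal(
        0.0, np.sqrt(1 - truth.age_icc) * AGE_SD, n
    )
    age = np.clip(age, *AGE_RANGE)

    # sqrt(AAO): nested Gaussian model, then squared with floor/cap
    u_c = rng_aao.normal(0.0, np.sqrt(truth.aao_sigma2_center), n_centers)
    u_f = rng_aao.normal(0.0, np.sqrt(truth.aao_sigma2_family), n_families)
    e = rng_aao.normal(0.0, np.sqrt(truth.aao_sigma2_e), n)
    sqrt_aao = (
        truth.aao_intercept
        + truth.aao_beta_sex * sex
        + truth.aao_beta_age * (age - AGE_MEAN)
        + u_c[center_of_family[fam_idx]]
        + u_f[fam_idx]
        + e
    )
    aao = np.clip(sqrt_aao, 0.1, None) ** 2
    aao = np.clip(aao, AAO_FLOOR, age - DURATION_FLOOR)
    duration = age - aao

    # episode counts: NB2 with log-duration exposure and family intercept
    v_f = rng_epi.normal(0.0, np.sqrt(truth.epi_sigma2_family), n_families)
    v_c = rng_epi.normal(0.0, np.sqrt(truth.epi_sigma2_center), n_centers)
    log_m = (
        truth.epi_intercept
        + truth.epi_beta_sex * sex
        + truth.epi_beta_age * (age - AGE_MEAN)
        + np.log(np.maximum(duration, DURATION_FLOOR))
        + v_f[fam_idx]
        + v_c[center_of_family[fam_idx]]
    )
    mean = np.exp(log_m)
    counts = _draw_nb2(rng_epi, mean, truth.epi_alpha)
    if recurrent:
        for _ in range(1000):
            zero = counts == 0
            if not np.any(zero):
                break
            counts[zero] = _draw_nb2(rng_epi, mean[zero], truth.epi_alpha)
        counts = np.maximum(counts, 1)

    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "family_id": [f"F{f:05d}" for f in fam_idx],
            "center_id": [f"C{c}" for c in center_of_family[fam_idx]],
            "sex": sex,
            "age": age,
            "aao": aao,
            "episode_count": counts.astype(int),
            "duration": duration,
        }
    )
    return df, truth


def simulate_genotype_phenotype(
    n_ind: int,
    n_snp: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    h2_snp: float = 0.5,
    n_causal: int | None = None,
    seed: int = 0,
    n_sib_pairs: int = 0,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, np.ndarray, SimTruth]:
    """Simulate a genotype panel and a polygenic quantitative phenotype.

    Genotypes are drawn per SNP under Hardy-Weinberg at a MAF uniform in
    ``maf_range``; the phenotype is a standardized-genotype polygenic score
    scaled to variance ``h2_snp`` plus Gaussian noise of variance
    ``1 - h2_snp``.  The first ``2 * n_sib_pairs`` individuals are full-sib
    pairs drawn through simulated parents (expected GRM entry 0.5).  The
    realized (empirical) heritability is recorded in the returned truth.
    """
    if n_ind < 2:
        raise ValueError("need at least two individuals")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not 0.0 <= h2_snp < 1.0:
        raise ValueError("h2_snp must lie in [0, 1)")
    n_causal = n_snp if n_causal is None else n_causal
    if n_causal > n_snp:
        raise ValueError("n_causal cannot exceed n_snp")
    if 2 * n_sib_pairs > n_ind:
        raise ValueError("too many sib pairs for n_ind")

    root = np.random.SeedSequence(seed)
    rng_geno, rng_pheno = (np.random.default_rng(s) for s in root.spawn(2))
    mafs = rng_geno.uniform(lo, hi, size=n_snp)
    x = rng_geno.binomial(2, mafs, size=(n_ind, n_snp)).astype(float)
    for k in range(n_sib_pairs):
        father = rng_geno.random((2, n_snp)) < mafs
        mother = rng_geno.random((2, n_snp)) < mafs
        for child in (2 * k, 2 * k + 1):
            pf = rng_geno.integers(0, 2, n_snp)
            pm = rng_geno.integers(0, 2, n_snp)
            x[child] = (
                father[pf, np.arange(n_snp)].astype(float)
                + mother[pm, np.arange(n_snp)]
            )
    if missing_rate > 0:
        x[rng_geno.random(x.shape) < missing_rate] = np.nan

    p_hat = np.nanmean(x, axis=0) / 2.0
    p_hat = np.clip(p_hat, 1e-6, 1 - 1e-6)
    w = (np.nan_to_num(x, nan=0.0) - 2 * p_hat) / np.sqrt(2 * p_hat * (1 - p_hat))
    causal = rng_pheno.choice(n_snp, size=n_causal, replace=False)
    effects = rng_pheno.normal(0.0, 1.0, n_causal)
    u = w[:, causal] @ effects
    if h2_snp > 0 and np.var(u) > 0:
        u = u * np.sqrt(h2_snp / np.var(u))
    else:
        u = np.zeros(n_ind)
    eps = rng_pheno.normal(0.0, np.sqrt(1.0 - h2_snp), n_ind)
    y = u + eps
    realized = float(np.var(u) / np.var(y)) if np.var(y) > 0 else 0.0

    g = GenotypeMatrix(
        ids=np.array([f"I{i:06d}" for i in range(n_ind)]),
        codes=x,
        snp_ids=np.array([f"snp{j}" for j in range(n_snp)]),
        chrom=np.array(["1"] * n_snp),
        bp=np.arange(1, n_snp + 1) * 1000,
        a1=np.array(["A"] * n_snp),
        a2=np.array(["G"] * n_snp),
    )
    truth = replace(SimTruth(), h2_snp_true=realized)
    return g, y, truth


def write_phenotypes(df: pd.DataFrame, path: str) -> None:
    """Write the fixed-header tab-separated phenotype table (NA for missing)."""
    df[PHENOTYPE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes(path: str) -> pd.DataFrame:
    """Read a phenotype table; derives the duration column (age - aao)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    df["duration"] = df["age"] - df["aao"]
    return df
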