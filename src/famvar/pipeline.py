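"""End-to-end orchestration of the two analysis tracks.

Track 1 (familiality, sibling families): nested mixed models for sqrt(AAO)
and episode counts, family-level ICCs with CIs, boundary LRTs for the
family variance, and the 2xICC maximal-heritability bound.

Track 2 (SNP heritability, unrelated cases): residualise the phenotype for
covariates, optionally Blom rank-normalise, build the GRM, prune related
pairs, compute principal components, and run AI-REML.

Both emit JSON-serialisable report fragments with full provenance (seed,
config hash, package version) and per-stage filter bookkeeping.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from . import __version__
from .greml import GRM, GenotypeMatrix, compute_grm, fit_greml, grm_pca, prune_relatedness
from .heritability import maximal_heritability
from .icc import carrasco_icc
from .lmm import fit_lmm_nested, lmm_residuals, lrt_family_variance, residual_icc
from .nbglmm import (
    fit_nb_glm,
    fit_nb_glmm,
    lrt_family_variance_nb,
    nb_deviance_residuals,
    poisson_vs_nb_comparison,
)
from .transforms import (
    blom_rank_normalize,
    ln_episode_frequency,
    log_duration_offset,
    sqrt_aao,
)

__all__ = ["DEFAULT_CONFIG", "run_familiality", "run_snp_h2", "write_report"]

DEFAULT_CONFIG = {
    "maf_min": 0.01,
    "grm_cutoff": 0.025,
    "n_pcs": 10,
    "n_quad": 7,
    "duration_floor": 0.5,
    "alpha": 0.05,
    "rank_normalize_counts": True,
}


def _config(overrides):
    cfg = dict(DEFAULT_CONFIG)
    if overrides:
        cfg.update(overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _provenance(cfg, seed=None):
    return {
        "software": "famvar",
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "seed": seed,
    }


def _icc_block(icc, extra=None):
    d = {
        "icc": icc.icc,
        "se": icc.se,
        "ci_low": icc.ci_low,
        "ci_high": icc.ci_high,
        "method": icc.method,
        "h2_max": maximal_heritability(icc.icc),
        "h2_max_ci": [
            maximal_heritability(max(icc.ci_low, 0.0)),
            maximal_heritability(min(icc.ci_high, 1.0)),
        ],
    }
    if icc.mu_marginal is not None:
        d["mu_marginal"] = icc.mu_marginal
    if extra:
        d.update(extra)
    return d


def _center_dummies(center_codes):
    codes, idx = np.unique(center_codes, return_inverse=True)
    if codes.size < 2:
        return np.empty((idx.size, 0))
    D = np.zeros((idx.size, codes.size - 1))
    for k in range(1, codes.size):
        D[idx == k, k - 1] = 1.0
    return D


def run_familiality(table: pd.DataFrame, config: dict | None = None, seed=None) -> dict:
    """Familiality analysis of AAO and episodicity on a family table.

    Fits the sqrt(AAO) nested LMM (sex-only and sex+age covariate sets), the
    episode-count NB GLMM (full covariates and a reduced model feeding the
    count ICC), and the ln(episode frequency) LMM.  Per-phenotype failures
    are captured in the fragment rather than aborting the run.
    """
    cfg = _config(config)
    report = {"provenance": _provenance(cfg, seed), "phenotypes": {}}
    out = report["phenotypes"]

    age_c = np.asarray(table["age"], float) - float(np.mean(table["age"]))
    sex = np.asarray(table["sex"], float)

    # --- AAO track -------------------------------------------------------
    aao_ok = table["aao"].notna() & table["age"].notna() & table["sex"].notna()
    try:
        sub = table[aao_ok]
        y = sqrt_aao(sub["aao"])
        fam = sub["family_id"].to_numpy()
        cen = sub["center_id"].to_numpy()
        designs = {
            "sqrt_aao_sex": np.column_stack([np.ones(len(sub)), sub["sex"]]),
            "sqrt_aao_sex_age": np.column_stack(
                [np.ones(len(sub)), sub["sex"], age_c[aao_ok.to_numpy()]]
            ),
        }
        for name, X in designs.items():
            fit = fit_lmm_nested(y, X, fam, cen)
            fit_red = fit_lmm_nested(y, X, cen)  # center-only random effect
            stat, p = lrt_family_variance(fit, fit_red)
            icc = residual_icc(fit)
            out[name] = {
                "model": "lmm_nested",
                "n": int(len(sub)),
                "n_dropped": int((~aao_ok).sum()),
                "sigma2_center": fit.sigma2_center,
                "sigma2_family": fit.sigma2_family,
                "sigma2_e": fit.sigma2_e,
                "lrt_family": stat,
                "p_family": p,
                **_icc_block(icc),
            }
    except Exception as err:  # pragma: no cover - defensive per-track guard
        out["sqrt_aao_sex"] = {"status": "failed", "error": str(err)}

    # --- episode count track (NB GLMM) ----------------------------------
    epi_ok = (
        table["episode_count"].notna()
        & table["aao"].notna()
        & table["age"].notna()
        & table["sex"].notna()
    )
    if not epi_ok.any():
        out["episodicity_nb"] = {"status": "skipped", "reason": "no episode data"}
        out["episodicity_lnfreq"] = {"status": "skipped", "reason": "no episode data"}
        return report
    try:
        sub = table[epi_ok]
        yc = sub["episode_count"].to_numpy(dtype=float)
        dur = sub["age"].to_numpy(float) - sub["aao"].to_numpy(float)
        off = log_duration_offset(dur, floor=cfg["duration_floor"])
        fam = sub["family_id"].to_numpy()
        D = _center_dummies(sub["center_id"].to_numpy())
        X_full = np.column_stack(
            [np.ones(len(sub)), sub["sex"], age_c[epi_ok.to_numpy()], D]
        )
        X_reduced = np.column_stack([np.ones(len(sub)), D])
        fit_p, fit_full, (stat_a, p_a) = poisson_vs_nb_comparison(
            yc, X_full, off, fam, n_quad=cfg["n_quad"]
        )
        glm_full = fit_nb_glm(yc, X_full, off)
        stat_f, p_f = lrt_family_variance_nb(fit_full, glm_full)
        fit_reduced = fit_nb_glmm(yc, X_reduced, off, fam, n_quad=cfg["n_quad"])
        icc = carrasco_icc(fit_reduced)
        out["episodicity_nb"] = {
            "model": "nb_glmm_aghq",
            "n": int(len(sub)),
            "n_dropped": int((~epi_ok).sum()),
            "alpha": fit_full.alpha,
            "sigma2_family": fit_full.sigma2_family,
            "sigma2_family_reduced": fit_reduced.sigma2_family,
            "alpha_reduced": fit_reduced.alpha,
            "lrt_family": stat_f,
            "p_family": p_f,
            "lrt_overdispersion": stat_a,
            "p_overdispersion": p_a,
            **_icc_block(icc),
        }
    except Exception as err:
        out["episodicity_nb"] = {"status": "failed", "error": str(err)}

    # --- ln(episode frequency) track (LMM) -------------------------------
    try:
        sub = table[epi_ok]
        dur = sub["age"].to_numpy(float) - sub["aao"].to_numpy(float)
        ylf = ln_episode_frequency(
            sub["episode_count"], dur, floor=cfg["duration_floor"]
        )
        X = np.column_stack([np.ones(len(sub)), sub["sex"], age_c[epi_ok.to_numpy()]])
        fam = sub["family_id"].to_numpy()
        cen = sub["center_id"].to_numpy()
        fit = fit_lmm_nested(ylf, X, fam, cen)
        fit_red = fit_lmm_nested(ylf, X, cen)
        stat, p = lrt_family_variance(fit, fit_red)
        icc = residual_icc(fit)
        out["episodicity_lnfreq"] = {
            "model": "lmm_nested",
            "n": int(len(sub)),
            "sigma2_center": fit.sigma2_center,
            "sigma2_family": fit.sigma2_family,
            "sigma2_e": fit.sigma2_e,
            "lrt_family": stat,
            "p_family": p,
            **_icc_block(icc),
        }
    except Exception as err:
        out["episodicity_lnfreq"] = {"status": "failed", "error": str(err)}
    return report


def _residualize(table, trait, cfg):
    """Adjusted (and optionally rank-normalised) phenotype for GREML."""
    has_sex = "sex" in table and table["sex"].notna().all()
    has_age = "age" in table and table["age"].notna().all()
    has_center = "center_id" in table and table["center_id"].nunique() > 1
    n = len(table)
    X_cols = [np.ones(n)]
    if has_sex:
        X_cols.append(table["sex"].to_numpy(float))

    if trait == "sqrt_aao":
        y = sqrt_aao(table["aao"])
        X = np.column_stack(X_cols)
        if has_center:
            fit = fit_lmm_nested(y, X, table["center_id"].to_numpy())
            return lmm_residuals(fit, conditional=True)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    if trait in ("episodicity_nb", "episodicity_lnfreq"):
        dur = table["age"].to_numpy(float) - table["aao"].to_numpy(float)
        if has_age:
            X_cols.append(table["age"].to_numpy(float) - table["age"].mean())
        X = np.column_stack(X_cols)
        if trait == "episodicity_nb":
            off = log_duration_offset(dur, floor=cfg["duration_floor"])
            yc = table["episode_count"].to_numpy(float)
            if has_center:
                fit = fit_nb_glmm(
                    yc, X, off, table["center_id"].to_numpy(), n_quad=cfg["n_quad"]
                )
            else:
                fit = fit_nb_glm(yc, X, off)
            r = nb_deviance_residuals(fit)
        else:
            ylf = ln_episode_frequency(
                table["episode_count"], dur, floor=cfg["duration_floor"]
            )
            if has_center:
                fit = fit_lmm_nested(ylf, X, table["center_id"].to_numpy())
                r = lmm_residuals(fit, conditional=True)
            else:
                beta, *_ = np.linalg.lstsq(X, ylf, rcond=None)
                r = ylf - X @ beta
        return blom_rank_normalize(r) if cfg["rank_normalize_counts"] else r

    if trait == "generic":
        y = table["phenotype"].to_numpy(float)
        if has_center:
            fit = fit_lmm_nested(
                y, np.column_stack(X_cols), table["center_id"].to_numpy()
            )
            return lmm_residuals(fit, conditional=True)
        X = np.column_stack(X_cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return y - X @ beta

    raise ValueError(f"unknown trait {trait!r}")


def run_snp_h2(
    genotypes: GenotypeMatrix,
    pheno_table: pd.DataFrame,
    trait: str = "sqrt_aao",
    config: dict | None = None,
    seed=None,
    grm: GRM | None = None,
) -> dict:
    """SNP-heritability chain: residualise -> GRM -> prune -> PCs -> GREML.

    ``pheno_table`` must carry ``subject_id`` matching the genotype ids plus
    the columns the chosen ``trait`` needs (``aao``/``age``/
    ``episode_count``/``sex``/``center_id``, or ``phenotype`` for
    ``trait="generic"``).  Precomputed ``grm`` may be supplied to skip GRM
    construction.
    """
    cfg = _config(config)
    log = []
    ids = np.asarray(genotypes.ids)
    pheno_ids = pheno_table["subject_id"].to_numpy()
    common = np.intersect1d(ids, pheno_ids)
    if common.size == 0:
        raise ValueError("no overlapping ids between genotypes and phenotypes")
    table = (
        pheno_table.set_index("subject_id").loc[common].reset_index()
    )
    resid = _residualize(table, trait, cfg)
    n_snps_in = genotypes.n_snp
    if grm is None:
        grm = compute_grm(genotypes, maf_min=cfg["maf_min"])
    n_snps_used = int(np.max(grm.pair_n)) if grm.pair_n.size else 0
    log.append({"stage": "grm", "snps_in": n_snps_in, "snps_used": n_snps_used,
                "snps_maf_filtered": n_snps_in - n_snps_used})

    geno_order = {v: i for i, v in enumerate(ids)}
    keep_geno = np.array([geno_order[v] for v in common])
    grm_c = grm.subset(keep_geno) if grm.n != common.size else grm
    retained = prune_relatedness(grm_c, cutoff=cfg["grm_cutoff"])
    log.append(
        {
            "stage": "prune",
            "individuals_in": int(common.size),
            "individuals_pruned": int(common.size - retained.size),
            "individuals_used": int(retained.size),
        }
    )
    grm_u = grm_c.subset(retained)
    y = np.asarray(resid)[retained]
    pcs = grm_pca(grm_u, k=min(cfg["n_pcs"], grm_u.n - 1))
    res = fit_greml(y, pcs, grm_u)
    return {
        "provenance": _provenance(cfg, seed),
        "trait": trait,
        "h2": res.h2,
        "se_h2": res.se_h2,
        "sigma2_g": res.sigma2_g,
        "sigma2_e": res.sigma2_e,
        "lrt": res.lrt,
        "p": res.p,
        "n_used": res.n_used,
        "n_iter": res.n_iter,
        "converged": res.converged,
        "stages": log,
    }


def write_report(report: dict, path: str) -> None:
    """Serialise a report fragment as stable, human-readable JSON."""

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
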