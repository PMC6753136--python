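"""Two-step genome-wide meQTL mapping.

Step one pre-adjusts methylation beta values for fixed covariates and the
pedigree (linear mixed model with a kinship random effect) and runs fast
simple-regression scans of the residuals against SNP dosages, keeping pairs
below liberal class-specific prefilter p-values (1e-6 cis, 1e-10 trans).
Step two refits the retained pairs with the full mixed model (SNP as fixed
effect, kinship random effect) and applies Bonferroni significance
thresholds computed from the configured test universes.

SNP-CpG pairs are classified by distance: cis within +/-1 Mb (inclusive),
long-range cis in (1 Mb, 5 Mb] on the same chromosome (excluded from both
the cis and trans significance sets), intrachromosomal trans beyond 5 Mb,
and interchromosomal trans.  Utilities for greedy LD pruning, the genomic
control inflation factor, and cross-cohort replication concordance live here
as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.varcomp import _BlockedREML, _design, MatrixError, RankError

__all__ = [
    "ScanConfig",
    "classify_pair",
    "classify_pairs",
    "residualize_methylation",
    "fast_linear_scan",
    "lme_refit",
    "apply_significance",
    "ld_prune",
    "genomic_control",
    "replication_concordance",
]

log = logging.getLogger(__name__)

CHI2_1_MEDIAN = stats.chi2.median(1)  # 0.45493642...


@dataclass
class ScanConfig:
    """Windows, prefilter thresholds and test universes of a meQTL scan."""

    cis_window: int = 1_000_000
    long_range_limit: int = 5_000_000
    prefilter_cis_p: float = 1e-6
    prefilter_trans_p: float = 1e-10
    alpha: float = 0.05
    n_cis_tests: float = 2.5e9
    n_trans_tests: float = 3.5e12
    maf_min: float = 0.01

    def __post_init__(self):
        if self.cis_window >= self.long_range_limit:
            raise ValueError("cis_window must be smaller than long_range_limit")


def classify_pair(chrom_snp, pos_snp, chrom_cpg, pos_cpg, config: ScanConfig | None = None) -> str:
    """Distance class of one SNP-CpG pair (cis / long_range_cis / trans_intra / trans_inter)."""
    config = config or ScanConfig()
    if chrom_snp != chrom_cpg:
        return "trans_inter"
    d = abs(int(pos_snp) - int(pos_cpg))
    if d <= config.cis_window:
        return "cis"
    if d <= config.long_range_limit:
        return "long_range_cis"
    return "trans_intra"


def classify_pairs(chrom_snp, pos_snp, chrom_cpg, pos_cpg, config: ScanConfig | None = None):
    """Vectorized :func:`classify_pair` over aligned arrays."""
    config = config or ScanConfig()
    chrom_snp = np.asarray(chrom_snp)
    chrom_cpg = np.asarray(chrom_cpg)
    d = np.abs(np.asarray(pos_snp, dtype=np.int64) - np.asarray(pos_cpg, dtype=np.int64))
    out = np.where(
        chrom_snp != chrom_cpg,
        "trans_inter",
        np.where(
            d <= config.cis_window,
            "cis",
            np.where(d <= config.long_range_limit, "long_range_cis", "trans_intra"),
        ),
    )
    return out


def residualize_methylation(cpgs, covariates, kinship: np.ndarray) -> pd.DataFrame:
    """Step-one residuals: per CpG, conditional residuals of the mixed model
    with fixed covariates and a kinship random effect.

    CpGs whose REML fit fails fall back to ordinary least-squares residuals
    (logged as a downgrade).  Residuals are mean-zero by construction.
    """
    betas = cpgs.betas if hasattr(cpgs, "betas") else cpgs
    n = betas.shape[0]
    X = _design(covariates, n)
    model = _BlockedREML(X, [np.asarray(kinship, float)])
    out = np.empty(betas.shape)
    n_downgraded = 0
    if not model.identifiable:
        # kinship indistinguishable from the residual (e.g. identity): the
        # mixed model collapses to ordinary least squares
        Q, _ = np.linalg.qr(X)
        out = betas.to_numpy(dtype=float)
        out = out - Q @ (Q.T @ out)
        return pd.DataFrame(out, index=betas.index, columns=betas.columns)
    for j, cpg_id in enumerate(betas.columns):
        y = betas[cpg_id].to_numpy(dtype=float)
        try:
            sig, *_ = model.fit(y)
            out[:, j] = model.conditional_residuals(y, sig)
        except (np.linalg.LinAlgError, RankError, MatrixError):
            beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
            out[:, j] = y - X @ beta_ols
            n_downgraded += 1
    if n_downgraded:
        log.warning("residualize_methylation: %d CpGs downgraded to OLS residuals", n_downgraded)
    return pd.DataFrame(out, index=betas.index, columns=betas.columns)


def fast_linear_scan(
    residuals: pd.DataFrame,
    cpg_map: pd.DataFrame,
    genotypes,
    config: ScanConfig | None = None,
) -> pd.DataFrame:
    """Step-one scan: simple linear regression of every CpG residual on every
    SNP dosage, retaining pairs below the class-specific prefilter p-value.

    Long-range-cis pairs are admitted at the trans prefilter (they are
    separated out, and excluded from significance calls, downstream).
    Zero-variance SNPs or CpGs are skipped and counted in the log.
    """
    config = config or ScanConfig()
    maf = genotypes.snp_map["maf"].to_numpy()
    snp_keep = maf >= config.maf_min
    G = genotypes.dosages.to_numpy(dtype=float)[:, snp_keep]
    snp_map = genotypes.snp_map[snp_keep]
    R = residuals.to_numpy(dtype=float)
    n = R.shape[0]

    sx = G.std(axis=0)
    sy = R.std(axis=0)
    ok_snp = sx > 0
    ok_cpg = sy > 0
    n_skipped = int((~ok_snp).sum() + (~ok_cpg).sum())
    if n_skipped:
        log.info("fast_linear_scan: skipped %d zero-variance SNPs/CpGs", n_skipped)
    G = G[:, ok_snp]
    snp_map = snp_map[ok_snp]
    Rv = R[:, ok_cpg]
    cpg_ids = residuals.columns[ok_cpg]
    sx, sy = sx[ok_snp], sy[ok_cpg]

    Gz = (G - G.mean(axis=0)) / sx
    Rz = (Rv - Rv.mean(axis=0)) / sy
    r = (Rz.T @ Gz) / n  # (C, S) correlation
    df = n - 2
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    cls = classify_pairs(
        np.broadcast_to(snp_map["chrom"].to_numpy(), (len(cpg_ids), len(snp_map))),
        np.broadcast_to(snp_map["pos"].to_numpy(), (len(cpg_ids), len(snp_map))),
        cpg_map.loc[cpg_ids, "chrom"].to_numpy()[:, None],
        cpg_map.loc[cpg_ids, "pos"].to_numpy()[:, None],
        config,
    )
    thresh = np.where(cls == "cis", config.prefilter_cis_p, config.prefilter_trans_p)
    ci, si = np.nonzero(p < thresh)
    if ci.size == 0:
        return _empty_records()

    slope = r[ci, si] * sy[ci] / sx[si]
    tv = t[ci, si]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.abs(slope) / np.abs(tv)
    rec = pd.DataFrame(
        {
            "snp_id": snp_map.index.to_numpy()[si],
            "cpg_id": cpg_ids.to_numpy()[ci],
            "snp_chrom": snp_map["chrom"].to_numpy()[si],
            "snp_pos": snp_map["pos"].to_numpy()[si],
            "cpg_chrom": cpg_map.loc[cpg_ids, "chrom"].to_numpy()[ci],
            "cpg_pos": cpg_map.loc[cpg_ids, "pos"].to_numpy()[ci],
            "beta": slope,
            "se": se,
            "t": tv,
            "p": p[ci, si],
            "class": cls[ci, si],
            "stage": "prefilter",
        }
    )
    return rec.reset_index(drop=True)


def _empty_records() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "snp_id", "cpg_id", "snp_chrom", "snp_pos", "cpg_chrom", "cpg_pos",
            "beta", "se", "t", "p", "class", "stage",
        ]
    )


def lme_refit(
    prefiltered: pd.DataFrame,
    cpgs,
    covariates,
    kinship: np.ndarray,
    genotypes=None,
) -> pd.DataFrame:
    """Step-two refit: for each prefiltered pair, the SNP fixed-effect
    estimate, standard error and Wald p from the mixed model with a kinship
    random effect, methylation as the outcome.

    Non-converged fits are flagged (``converged`` column) and should be
    excluded from significance calls.
    """
    if prefiltered.empty:
        out = _empty_records()
        out["converged"] = pd.Series(dtype=bool)
        return out
    betas = cpgs.betas if hasattr(cpgs, "betas") else cpgs
    n = betas.shape[0]
    Xbase = _design(covariates, n)
    K = np.asarray(kinship, float)
    # kinship indistinguishable from the residual: the per-pair mixed model
    # is ordinary least squares (exact t reference distribution)
    degenerate = np.allclose(K, np.eye(n))
    rows = []
    for _, pair in prefiltered.iterrows():
        y = betas[pair["cpg_id"]].to_numpy(dtype=float)
        g = genotypes.dosages[pair["snp_id"]].to_numpy(dtype=float)
        X = np.column_stack([Xbase, g])
        try:
            if degenerate:
                beta, se, tval, p = _ols_last_coef(X, y)
                converged = True
            else:
                model = _BlockedREML(X, [K])
                sig, converged, *_ = model.fit(y)
                bhat, cov = model.fixed_effects(y, sig)
                beta, se = float(bhat[-1]), float(np.sqrt(cov[-1, -1]))
                tval = beta / se
                p = 2.0 * stats.norm.sf(abs(tval))
        except (np.linalg.LinAlgError, RankError, MatrixError):
            beta = se = tval = p = np.nan
            converged = False
        rows.append(
            {
                **{k: pair[k] for k in ["snp_id", "cpg_id", "snp_chrom", "snp_pos",
                                         "cpg_chrom", "cpg_pos", "class"]},
                "beta": beta, "se": se, "t": tval, "p": p,
                "stage": "final", "converged": converged,
            }
        )
    return pd.DataFrame(rows)


def _ols_last_coef(X: np.ndarray, y: np.ndarray):
    """OLS estimate, se, t and p (t distribution) for the last column of X."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    coef = XtX_inv @ (X.T @ y)
    resid = y - X @ coef
    s2 = float(resid @ resid) / (n - p)
    se = float(np.sqrt(s2 * XtX_inv[-1, -1]))
    tval = float(coef[-1]) / se
    pval = 2.0 * stats.t.sf(abs(tval), n - p)
    return float(coef[-1]), se, tval, float(pval)


def apply_significance(records: pd.DataFrame, config: ScanConfig) -> tuple[pd.DataFrame, dict]:
    """Bonferroni filter: cis threshold ``alpha/n_cis_tests``, trans threshold
    ``alpha/n_trans_tests``; long-range-cis records are excluded from both."""
    cis_thr = config.alpha / config.n_cis_tests
    trans_thr = config.alpha / config.n_trans_tests
    ok = records.get("converged", pd.Series(True, index=records.index))
    is_cis = records["class"] == "cis"
    is_trans = records["class"].isin(["trans_intra", "trans_inter"])
    keep = ok & (
        (is_cis & (records["p"] < cis_thr)) | (is_trans & (records["p"] < trans_thr))
    )
    thresholds = {"cis": cis_thr, "trans": trans_thr}
    return records[keep].reset_index(drop=True), thresholds


def ld_prune(
    snp_ids,
    genotypes,
    r2_threshold: float,
    p_values=None,
    rank_by_p: bool = True,
) -> list[str]:
    """Greedy LD pruning of a SNP list.

    SNPs are visited in ascending p-value (ties broken by position, then id;
    position/id order alone when ``rank_by_p`` is False or no p-values are
    given) and retained iff their dosage r^2 with every already-retained SNP
    is below ``r2_threshold``.  Output preserves retention order.
    """
    snp_ids = list(snp_ids)
    avail = [s for s in snp_ids if s in genotypes.dosages.columns]
    dropped = set(snp_ids) - set(avail)
    if dropped:
        log.warning("ld_prune: %d SNPs missing from genotypes, dropped", len(dropped))
    if not avail:
        return []
    pos = genotypes.snp_map.loc[avail, "pos"].to_dict()
    if rank_by_p and p_values is not None:
        pv = dict(zip(snp_ids, p_values)) if not isinstance(p_values, dict) else p_values
        order = sorted(avail, key=lambda s: (pv.get(s, 1.0), pos[s], s))
    else:
        order = sorted(avail, key=lambda s: (pos[s], s))
    dos = {s: genotypes.dosages[s].to_numpy(dtype=float) for s in avail}
    kept: list[str] = []
    for s in order:
        g = dos[s]
        if g.std() == 0:
            continue
        indep = True
        for k in kept:
            r = np.corrcoef(g, dos[k])[0, 1]
            if r * r >= r2_threshold:
                indep = False
                break
        if indep:
            kept.append(s)
    return kept


def genomic_control(p_values) -> float:
    """Genomic inflation factor: median observed chi^2(1) quantile divided by
    the null chi^2(1) median (0.4549...)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def replication_concordance(
    discovery: pd.DataFrame, replication: pd.DataFrame, alpha: float = 0.05
) -> dict:
    """Directional concordance and replication rates for matched SNP-CpG pairs.

    Returns the fraction of matched pairs whose effect signs agree, and the
    fractions replicating at nominal ``alpha`` and at Bonferroni
    ``alpha / n_matched``.
    """
    merged = discovery.merge(
        replication, on=["snp_id", "cpg_id"], suffixes=("_disc", "_rep")
    )
    if merged.empty:
        log.warning("replication_concordance: no matched pairs")
        return {"n_matched": 0, "concordance": np.nan,
                "rate_nominal": np.nan, "rate_bonferroni": np.nan}
    m = len(merged)
    same_sign = np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"])
    return {
        "n_matched": m,
        "concordance": float(same_sign.mean()),
        "rate_nominal": float((merged["p_rep"] < alpha).mean()),
        "rate_bonferroni": float((merged["p_rep"] < alpha / m).mean()),
    }
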