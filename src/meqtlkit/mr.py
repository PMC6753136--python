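"""Two-sample Mendelian randomization of methylation (or expression) on traits.

The exposure side supplies per-SNP effects ``gamma_j`` on a CpG (its
independent cis-meQTLs, LD-pruned at r^2 < 0.01); the outcome side supplies
GWAS summary effects ``Gamma_j``.  The causal effect is the inverse-variance
weighted (IVW) average of the per-IV Wald ratios ``Gamma_j / gamma_j`` with
first-order standard errors.  Validity diagnostics are Cochran's Q
heterogeneity test and the MR-Egger intercept test for directional
pleiotropy; while either diagnostic p-value is below 0.05 the IV with the
largest Q contribution is excluded and the fit repeated, stopping before the
IV count drops under three.  Correlated CpGs within 2 Mb are either pruned
to the best-p index CpG (r^2 >= 0.5) or jointly modeled by multivariable MR
(0 < r^2 < 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.meqtl import ld_prune

__all__ = [
    "MRResult",
    "select_ivs",
    "harmonize",
    "ivw_mr",
    "cochran_q",
    "egger_intercept",
    "stepwise_iv_refinement",
    "prune_cpgs",
    "multivariable_mr",
    "mr_for_expression",
    "wald_ratio",
]

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
MIN_IVS = 3
DIAG_ALPHA = 0.05


class CollinearityError(ValueError):
    """Exposure effect columns are linearly dependent."""


@dataclass
class MRResult:
    """Causal estimate for one exposure-outcome pair with its IV audit trail."""

    theta: float = float("nan")
    se_theta: float = float("nan")
    p_mr: float = float("nan")
    or_value: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    q_stat: float = float("nan")
    p_heter: float = float("nan")
    egger_intercept: float = float("nan")
    p_pleio: float = float("nan")
    n_iv_initial: int = 0
    n_iv_final: int = 0
    excluded_ivs: list[str] = field(default_factory=list)
    status: str = "insufficient_ivs"


def select_ivs(cis_records: pd.DataFrame, genotypes, r2_threshold: float = 0.01):
    """Independent cis-meQTL instruments for one CpG: LD pruning at
    ``r^2 < r2_threshold`` ranked by association p-value.

    Returns ``(snp_ids, insufficient)`` where ``insufficient`` flags fewer
    than three surviving instruments.
    """
    kept = ld_prune(
        cis_records["snp_id"].tolist(),
        genotypes,
        r2_threshold,
        p_values=cis_records["p"].tolist(),
    )
    return kept, len(kept) < MIN_IVS


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_maf=(0.42, 0.58)) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Matching alleles are kept; swapped alleles flip the sign of the outcome
    beta; palindromic SNPs (A/T or C/G) with MAF inside ``palindromic_maf``
    are dropped as strand-ambiguous; SNPs absent from the outcome are
    dropped.  The action taken is recorded per IV.
    """
    out_by_id = outcome.set_index("snp_id")
    rows = []
    for _, e in exposure.iterrows():
        sid = e["snp_id"]
        action = "dropped_unmatched"
        Gamma = se_G = np.nan
        if sid in out_by_id.index:
            o = out_by_id.loc[sid]
            ea_e, oa_e = str(e["effect_allele"]), str(e["other_allele"])
            ea_o, oa_o = str(o["effect_allele"]), str(o["other_allele"])
            maf = float(o.get("maf", e.get("maf", 0.0)))
            if (ea_e, oa_e) in PALINDROMIC and palindromic_maf[0] <= maf <= palindromic_maf[1]:
                action = "dropped_palindromic"
            elif (ea_o, oa_o) == (ea_e, oa_e):
                action = "kept"
                Gamma, se_G = float(o["beta"]), float(o["se"])
            elif (ea_o, oa_o) == (oa_e, ea_e):
                action = "sign_flipped"
                Gamma, se_G = -float(o["beta"]), float(o["se"])
            else:
                action = "dropped_unmatched"
        rows.append(
            {
                "snp_id": sid,
                "gamma": float(e["beta"]),
                "se_gamma": float(e["se"]),
                "Gamma": Gamma,
                "se_Gamma": se_G,
                "maf": float(e.get("maf", np.nan)),
                "harmonization_action": action,
            }
        )
    table = pd.DataFrame(rows)
    return table


def _kept(table: pd.DataFrame) -> pd.DataFrame:
    if "harmonization_action" in table.columns:
        table = table[table["harmonization_action"].isin(["kept", "sign_flipped"])]
    return table[table["gamma"] != 0.0]


def ivw_mr(table: pd.DataFrame, random_effects: bool = False) -> tuple[float, float, float]:
    """Fixed-effect IVW estimate from per-IV Wald ratios.

    ``beta_j = Gamma_j / gamma_j`` with first-order ``se_j = se_Gamma_j /
    |gamma_j|``; the estimate is the inverse-variance weighted mean.  With
    ``random_effects`` the standard error is scaled by
    ``max(1, sqrt(Q/(J-1)))``.
    """
    t = _kept(table)
    if len(t) < 2:
        raise ValueError("IVW requires at least 2 usable IVs")
    ratio = t["Gamma"].to_numpy() / t["gamma"].to_numpy()
    se = t["se_Gamma"].to_numpy() / np.abs(t["gamma"].to_numpy())
    w = se**-2
    theta = float(np.sum(ratio * w) / np.sum(w))
    se_theta = float(np.sum(w) ** -0.5)
    if random_effects:
        q = float(np.sum(w * (ratio - theta) ** 2))
        se_theta *= max(1.0, np.sqrt(q / (len(t) - 1)))
    p = 2.0 * stats.norm.sf(abs(theta / se_theta))
    return theta, se_theta, float(p)


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float):
    """Single-IV fallback: ratio estimate ``Gamma/gamma`` with first-order se."""
    if gamma == 0:
        raise ValueError("Wald ratio undefined for gamma = 0")
    theta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return theta, se, float(p)


def cochran_q(table: pd.DataFrame, theta: float):
    """Cochran's Q heterogeneity statistic, its chi^2(J-1) p-value and the
    per-IV contributions used to rank outliers."""
    t = _kept(table)
    ratio = t["Gamma"].to_numpy() / t["gamma"].to_numpy()
    se = t["se_Gamma"].to_numpy() / np.abs(t["gamma"].to_numpy())
    qj = (ratio - theta) ** 2 / se**2
    q = float(qj.sum())
    dof = len(t) - 1
    p = float(stats.chi2.sf(q, dof)) if dof > 0 else 1.0
    return q, p, pd.Series(qj, index=t["snp_id"].to_numpy())


def egger_intercept(table: pd.DataFrame):
    """MR-Egger regression: after orienting all gamma_j >= 0, a weighted
    regression ``Gamma = b0 + b1 * gamma`` with weights ``se_Gamma^-2``.

    Returns ``(intercept, se_intercept, p_pleio, slope)``; the pleiotropy
    p-value is a t-test on the intercept with J-2 degrees of freedom.
    """
    t = _kept(table)
    J = len(t)
    if J < MIN_IVS:
        raise ValueError("Egger regression requires at least 3 IVs")
    flip = np.sign(t["gamma"].to_numpy())
    g = t["gamma"].to_numpy() * flip
    G = t["Gamma"].to_numpy() * flip
    w = t["se_Gamma"].to_numpy() ** -2.0
    if np.allclose(g, g[0]):
        raise CollinearityError("all exposure effects identical after orientation")
    X = np.column_stack([np.ones(J), g])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ G)
    resid = G - X @ coef
    dof = J - 2
    s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else np.nan
    cov = s2 * np.linalg.inv(XtWX)
    se0 = float(np.sqrt(cov[0, 0]))
    tstat = coef[0] / se0
    p = 2.0 * stats.t.sf(abs(tstat), dof) if dof > 0 else np.nan
    return float(coef[0]), se0, float(p), float(coef[1])


def _diagnose(table: pd.DataFrame, random_effects: bool):
    theta, se_theta, p_mr = ivw_mr(table, random_effects=random_effects)
    q, p_heter, qj = cochran_q(table, theta)
    try:
        b0, _, p_pleio, _ = egger_intercept(table)
    except CollinearityError:
        # identical exposure effects: the pleiotropy test is undefined and
        # cannot be passed
        b0, p_pleio = float("nan"), float("nan")
    return theta, se_theta, p_mr, q, p_heter, b0, p_pleio, qj


def stepwise_iv_refinement(table: pd.DataFrame, random_effects: bool = False) -> MRResult:
    """IVW with stepwise exclusion of invalid instruments.

    Loop: fit IVW, Cochran's Q and the Egger intercept; if both diagnostic
    p-values are at least 0.05 stop, otherwise drop the IV with the largest
    Q contribution and refit.  Stops with ``insufficient_ivs`` before the IV
    count falls below three.  ``status = significant`` here means the fit
    passed both diagnostics with >= 3 IVs; trait-level Bonferroni filtering
    is the caller's concern.
    """
    work = _kept(table).reset_index(drop=True)
    res = MRResult(n_iv_initial=len(work))
    if len(work) < MIN_IVS:
        return res
    excluded: list[str] = []
    while True:
        theta, se_theta, p_mr, q, p_heter, b0, p_pleio, qj = _diagnose(work, random_effects)
        res.theta, res.se_theta, res.p_mr = theta, se_theta, p_mr
        res.q_stat, res.p_heter = q, p_heter
        res.egger_intercept, res.p_pleio = b0, p_pleio
        res.or_value = float(np.exp(theta))
        res.ci_low = float(np.exp(theta - 1.96 * se_theta))
        res.ci_high = float(np.exp(theta + 1.96 * se_theta))
        res.n_iv_final = len(work)
        res.excluded_ivs = excluded.copy()
        if p_heter >= DIAG_ALPHA and p_pleio >= DIAG_ALPHA:
            res.status = "significant"
            return res
        if len(work) - 1 < MIN_IVS:
            res.status = "diagnostics_failed"
            return res
        worst = qj.idxmax()
        excluded.append(worst)
        work = work[work["snp_id"] != worst].reset_index(drop=True)


def prune_cpgs(
    cpg_positions: pd.DataFrame,
    correlation: pd.DataFrame,
    mr_p: dict,
    window: int = 2_000_000,
    r2_threshold: float = 0.5,
) -> tuple[list[str], dict]:
    """Collapse highly correlated nearby CpGs to an index CpG.

    CpG pairs on the same chromosome within ``window`` and with squared
    correlation >= ``r2_threshold`` are clustered (transitively); each
    cluster reports the member with the lowest MR p-value as its index.
    Returns ``(kept, pointer)`` where ``pointer`` maps pruned CpGs to their
    index CpG.
    """
    ids = list(cpg_positions.index)
    parent = {c: c for c in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if cpg_positions.loc[a, "chrom"] != cpg_positions.loc[b, "chrom"]:
                continue
            if abs(int(cpg_positions.loc[a, "pos"]) - int(cpg_positions.loc[b, "pos"])) > window:
                continue
            r = float(correlation.loc[a, b])
            if r * r >= r2_threshold:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for c in ids:
        clusters.setdefault(find(c), []).append(c)
    kept, pointer = [], {}
    for members in clusters.values():
        index_cpg = min(members, key=lambda c: (mr_p.get(c, 1.0), c))
        kept.append(index_cpg)
        for m in members:
            if m != index_cpg:
                pointer[m] = index_cpg
    return sorted(kept), pointer


def multivariable_mr(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Multivariable MR of several correlated exposures on one outcome.

    ``tables`` maps exposure id -> aligned IV table over a shared IV union;
    the outcome effects are regressed on the matrix of exposure effects
    without an intercept, weights ``se_Gamma^-2``.  Returns per-exposure
    conditional estimates.
    """
    exposures = list(tables)
    K = len(exposures)
    first = tables[exposures[0]]
    snps = first["snp_id"].tolist()
    J = len(snps)
    if J < K + 1:
        raise ValueError("multivariable MR needs more IVs than exposures")
    Gm = first.set_index("snp_id")
    Gamma = Gm.loc[snps, "Gamma"].to_numpy(dtype=float)
    w = Gm.loc[snps, "se_Gamma"].to_numpy(dtype=float) ** -2.0
    X = np.column_stack(
        [tables[e].set_index("snp_id").loc[snps, "gamma"].to_numpy(dtype=float) for e in exposures]
    )
    if np.linalg.matrix_rank(X) < K:
        raise CollinearityError(f"collinear exposure effects among {exposures}")
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ Gamma)
    resid = Gamma - X @ coef
    dof = J - K
    s2 = float(np.sum(w * resid**2) / dof)
    cov = s2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    return pd.DataFrame({"exposure": exposures, "theta": coef, "se": se, "p": p})


def mr_for_expression(
    eqtl_records: pd.DataFrame,
    outcome: pd.DataFrame,
    genotypes,
    alpha: float = 0.05,
    n_genes_tested: int = 1,
    random_effects: bool = False,
) -> tuple[MRResult, float]:
    """MR with gene expression as exposure, cis-eQTLs as instruments.

    Same engine as the CpG path; with fewer than three independent eQTLs the
    single strongest variant is used as a Wald-ratio fallback.  Returns the
    result and the Bonferroni threshold ``alpha / n_genes_tested``.
    """
    threshold = alpha / n_genes_tested
    kept = ld_prune(
        eqtl_records["snp_id"].tolist(), genotypes, 0.01,
        p_values=eqtl_records["p"].tolist(),
    )
    sub = eqtl_records[eqtl_records["snp_id"].isin(kept)]
    table = harmonize(sub, outcome)
    usable = _kept(table)
    if len(usable) >= MIN_IVS:
        return stepwise_iv_refinement(table, random_effects=random_effects), threshold
    res = MRResult(n_iv_initial=len(usable))
    if len(usable) >= 1:
        top = usable.iloc[0]
        theta, se, p = wald_ratio(top["gamma"], top["se_gamma"], top["Gamma"], top["se_Gamma"])
        res.theta, res.se_theta, res.p_mr = theta, se, p
        res.or_value = float(np.exp(theta))
        res.ci_low = float(np.exp(theta - 1.96 * se))
        res.ci_high = float(np.exp(theta + 1.96 * se))
        res.n_iv_final = 1
        res.status = "single_iv_wald"
    return res, threshold
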