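"""eQTM scanning and trans-meQTL hotspot detection.

An eQTM is a CpG whose methylation associates with a transcript's
expression; pairs are tested by linear regression of pre-adjusted residual
matrices, Bonferroni-corrected at the realized scan size, and flagged cis
when the CpG lies within 1 Mb of the gene's TSS.

A trans-meQTL hotspot is an index SNP whose genome-wide significant trans
associations cover at least 30 CpGs.  SNPs within 1 Mb of each other or in
LD (r^2 >= 0.2) are merged into one hotspot whose index is the member with
the most targets.  Hotspots are then linked to nearby eGenes (genes with a
significant cis-eQTL among the hotspot members), and the hotspot's target
CpGs are tested for enrichment among all CpGs associated with those eGenes
- the mediation signature of a cis gene driving remote methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from meqtlkit.enrich import hypergeom_enrichment

__all__ = [
    "Hotspot",
    "eqtm_scan",
    "detect_hotspots",
    "link_hotspot_egenes",
    "egene_transcpg_enrichment",
]

log = logging.getLogger(__name__)

TRANS_CLASSES = ("trans_intra", "trans_inter")


@dataclass
class Hotspot:
    hotspot_id: str
    index_snp: str
    member_snps: set = field(default_factory=set)
    target_cpgs: set = field(default_factory=set)
    linked_egenes: set = field(default_factory=set)
    egene_target_pairs: pd.DataFrame | None = None


def _pairwise_regression(Y: np.ndarray, X: np.ndarray):
    """All-pairs simple regression of columns of Y on columns of X.

    Returns (slope, se, t, p) arrays of shape (X columns, Y columns).
    """
    n = Y.shape[0]
    sx = X.std(axis=0)
    sy = Y.std(axis=0)
    Xz = (X - X.mean(axis=0)) / np.where(sx > 0, sx, 1.0)
    Yz = (Y - Y.mean(axis=0)) / np.where(sy > 0, sy, 1.0)
    r = (Xz.T @ Yz) / n
    r = np.clip(r, -0.999999999, 0.999999999)
    df = n - 2
    t = r * np.sqrt(df / (1 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    slope = r * (sy[None, :] / np.where(sx > 0, sx, 1.0)[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(t != 0, np.abs(slope / t), np.nan)
    return slope, se, t, p, sx > 0, sy > 0


def eqtm_scan(
    meth_resid: pd.DataFrame,
    expr_resid: pd.DataFrame,
    cpg_map: pd.DataFrame,
    tss_map: pd.DataFrame,
    alpha: float = 0.05,
    cis_window: int = 1_000_000,
) -> tuple[pd.DataFrame, float]:
    """Pairwise CpG-transcript association scan on residual matrices.

    The significance threshold is ``alpha / (n_cpg * n_gene)`` computed from
    the realized scan dimensions.  Returns the significant records and the
    threshold used.
    """
    common = meth_resid.index.intersection(expr_resid.index)
    M = meth_resid.loc[common].to_numpy(dtype=float)
    E = expr_resid.loc[common].to_numpy(dtype=float)
    slope, se, t, p, ok_cpg, ok_gene = _pairwise_regression(E, M)
    n_skip = int((~ok_cpg).sum() + (~ok_gene).sum())
    if n_skip:
        log.info("eqtm_scan: %d zero-variance rows skipped", n_skip)
    n_tests = int(ok_cpg.sum()) * int(ok_gene.sum())
    threshold = alpha / max(n_tests, 1)

    ci, gi = np.nonzero((p < threshold) & ok_cpg[:, None] & ok_gene[None, :])
    cpg_ids = meth_resid.columns.to_numpy()[ci]
    gene_ids = expr_resid.columns.to_numpy()[gi]
    cpg_chrom = cpg_map.loc[cpg_ids, "chrom"].to_numpy()
    cpg_pos = cpg_map.loc[cpg_ids, "pos"].to_numpy()
    gene_chrom = tss_map.loc[gene_ids, "chrom"].to_numpy()
    tss = tss_map.loc[gene_ids, "tss"].to_numpy()
    cis_flag = (cpg_chrom == gene_chrom) & (np.abs(cpg_pos - tss) <= cis_window)
    rec = pd.DataFrame(
        {
            "cpg_id": cpg_ids,
            "gene_id": gene_ids,
            "beta": slope[ci, gi],
            "se": se[ci, gi],
            "t": t[ci, gi],
            "p": p[ci, gi],
            "cis_flag": cis_flag,
        }
    )
    return rec, threshold


def detect_hotspots(
    trans_records: pd.DataFrame,
    genotypes,
    min_targets: int = 30,
    merge_window: int = 1_000_000,
    merge_r2: float = 0.2,
) -> list[Hotspot]:
    """Group significant trans associations into hotspots.

    SNPs are merged when within ``merge_window`` of each other on the same
    chromosome or when their dosage r^2 is at least ``merge_r2``; the merged
    hotspot's index SNP is the member with the largest trans target count
    (ties broken by smallest best p-value, then position).  A hotspot is
    retained only when the index targets at least ``min_targets`` CpGs.
    """
    rec = trans_records[trans_records["class"].isin(TRANS_CLASSES)]
    if rec.empty:
        return []
    per_snp = rec.groupby("snp_id").agg(
        n_targets=("cpg_id", "nunique"), best_p=("p", "min")
    )
    snps = sorted(per_snp.index)
    pos = genotypes.snp_map.loc[snps, "pos"].to_dict()
    chrom = genotypes.snp_map.loc[snps, "chrom"].to_dict()

    parent = {s: s for s in snps}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, a in enumerate(snps):
        ga = genotypes.dosages[a].to_numpy(dtype=float)
        for b in snps[i + 1:]:
            near = chrom[a] == chrom[b] and abs(pos[a] - pos[b]) <= merge_window
            if not near:
                gb = genotypes.dosages[b].to_numpy(dtype=float)
                if ga.std() > 0 and gb.std() > 0:
                    near = np.corrcoef(ga, gb)[0, 1] ** 2 >= merge_r2
            if near:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for s in snps:
        clusters.setdefault(find(s), []).append(s)

    hotspots = []
    for members in clusters.values():
        index = min(
            members,
            key=lambda s: (-per_snp.loc[s, "n_targets"], per_snp.loc[s, "best_p"], pos[s], s),
        )
        targets = set(rec.loc[rec["snp_id"] == index, "cpg_id"])
        if len(targets) >= min_targets:
            hotspots.append(
                Hotspot(
                    hotspot_id="",
                    index_snp=index,
                    member_snps=set(members),
                    target_cpgs=targets,
                )
            )
    hotspots.sort(key=lambda h: (chrom[h.index_snp], pos[h.index_snp]))
    for i, h in enumerate(hotspots):
        h.hotspot_id = f"H{i + 1}"
    return hotspots


def link_hotspot_egenes(
    hotspot: Hotspot,
    cis_eqtl_records: pd.DataFrame,
    tss_map: pd.DataFrame,
    genotypes,
    window: int = 1_000_000,
) -> set:
    """eGenes of a hotspot: genes with a significant cis-eQTL among the
    hotspot's member SNPs, with the TSS within ``window`` of that SNP."""
    egenes = set()
    rec = cis_eqtl_records[cis_eqtl_records["snp_id"].isin(hotspot.member_snps)]
    for _, row in rec.iterrows():
        gene = row["gene_id"]
        if gene not in tss_map.index:
            continue
        snp = genotypes.snp_map.loc[row["snp_id"]]
        g = tss_map.loc[gene]
        if g["chrom"] == snp["chrom"] and abs(int(g["tss"]) - int(snp["pos"])) <= window:
            egenes.add(gene)
    hotspot.linked_egenes |= egenes
    return egenes


def egene_transcpg_enrichment(
    egene_expr: pd.DataFrame,
    meth_resid: pd.DataFrame,
    target_cpgs: set,
    alpha: float = 0.05,
):
    """Are a hotspot's trans-target CpGs enriched among eGene-associated CpGs?

    Tests every CpG against every linked eGene's expression
    (Bonferroni-corrected at the realized scan size), then runs a
    hypergeometric enrichment of the hotspot targets within the
    eGene-associated CpG set, against the universe of all scanned CpGs.
    Returns (association table, fold, p_hyper).
    """
    if not target_cpgs:
        return pd.DataFrame(), np.nan, np.nan
    common = meth_resid.index.intersection(egene_expr.index)
    M = meth_resid.loc[common].to_numpy(dtype=float)
    E = egene_expr.loc[common].to_numpy(dtype=float)
    slope, se, t, p, ok_g, ok_c = _pairwise_regression(M, E)
    n_tests = M.shape[1] * E.shape[1]
    thr = alpha / max(n_tests, 1)
    gi, ci = np.nonzero(p < thr)
    assoc = pd.DataFrame(
        {
            "gene_id": egene_expr.columns.to_numpy()[gi],
            "cpg_id": meth_resid.columns.to_numpy()[ci],
            "beta": slope[gi, ci],
            "p": p[gi, ci],
        }
    )
    egene_cpgs = set(assoc["cpg_id"])
    universe = set(meth_resid.columns)
    res = hypergeom_enrichment(
        foreground=egene_cpgs,
        universe=universe,
        annotation_sets={"trans_targets": set(target_cpgs) & universe},
        n_annotations=1,
        alpha=alpha,
    )[0]
    return assoc, res.fold, res.p
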