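"""Feature-set enrichment of CpGs and SNPs.

Two testing modes: an exact two-sided hypergeometric test for membership
annotations (CpG island, promoter, gene body, ...) with a fold-change gate
(significant only when fold > 1.2 or < 0.8 at Bonferroni-corrected p), and
a MAF-matched permutation test for interval annotations such as chromatin
states: permutation SNP sets are drawn from a pool with the same per-MAF-bin
counts as the tested set, the fold change is observed overlap over mean
permuted overlap, and empirical add-one p-values are FDR-adjusted across
states (Benjamini-Hochberg, significant at FDR < 0.05).

MAF bins are left-open right-closed: (0.01, 0.05], (0.05, 0.1],
(0.1, 0.2], (0.2, 0.5].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "maf_bin",
    "maf_matched_permutation",
    "bh_fdr",
    "snps_in_intervals",
]

MAF_BIN_EDGES = (0.01, 0.05, 0.1, 0.2, 0.5)


@dataclass
class EnrichmentResult:
    annotation_id: str
    n_universe: int
    n_annotated: int
    n_foreground: int
    n_overlap: int
    fold: float
    p: float
    fdr_or_bonf: float = float("nan")
    significant: bool = False
    fold_defined: bool = True


def hypergeom_enrichment(
    foreground,
    universe,
    annotation_sets: dict,
    fold_hi: float = 1.2,
    fold_lo: float = 0.8,
    alpha: float = 0.05,
    n_annotations: int | None = None,
) -> list[EnrichmentResult]:
    """Two-sided hypergeometric enrichment of a foreground set.

    p is the doubled smaller tail, capped at 1; an annotation is significant
    only when the fold change passes the gate (> ``fold_hi`` or < ``fold_lo``)
    AND p is below the Bonferroni level ``alpha / n_annotations``.
    """
    fg = set(foreground)
    uni = set(universe)
    if not fg <= uni:
        raise ValueError("foreground must be a subset of the universe")
    n_annotations = n_annotations if n_annotations is not None else max(1, len(annotation_sets))
    bonf = alpha / n_annotations
    out = []
    N, n_fg = len(uni), len(fg)
    for ann_id, members in annotation_sets.items():
        ann = set(members) & uni
        K = len(ann)
        k = len(ann & fg)
        if n_fg == 0 or K == 0:
            out.append(EnrichmentResult(ann_id, N, K, n_fg, k, np.nan, 1.0,
                                        fold_defined=False))
            continue
        fold = (k / n_fg) / (K / N)
        upper = stats.hypergeom.sf(k - 1, N, K, n_fg)
        lower = stats.hypergeom.cdf(k, N, K, n_fg)
        p = min(1.0, 2.0 * min(upper, lower))
        sig = (fold > fold_hi or fold < fold_lo) and p < bonf
        out.append(EnrichmentResult(ann_id, N, K, n_fg, k, float(fold), float(p),
                                    fdr_or_bonf=bonf, significant=bool(sig)))
    return out


def maf_bin(maf: float) -> int:
    """Four left-open right-closed MAF bins, 1-based:
    (0.01,0.05] -> 1, (0.05,0.1] -> 2, (0.1,0.2] -> 3, (0.2,0.5] -> 4."""
    if not (MAF_BIN_EDGES[0] < maf <= MAF_BIN_EDGES[-1]):
        raise ValueError(f"MAF {maf} outside (0.01, 0.5]")
    for b, hi in enumerate(MAF_BIN_EDGES[1:], start=1):
        if maf <= hi:
            return b
    raise AssertionError("unreachable")


def snps_in_intervals(positions, chroms, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of SNP points falling in half-open [start, end) intervals.

    ``intervals`` has columns chrom, start, end in BED convention (0-based
    half-open); SNP ``positions`` are 1-based points.
    """
    positions = np.asarray(positions, dtype=np.int64)
    chroms = np.asarray(chroms)
    mask = np.zeros(positions.size, dtype=bool)
    for chrom, sub in intervals.groupby("chrom"):
        starts = np.sort(sub["start"].to_numpy(dtype=np.int64))
        ends = sub.sort_values("start")["end"].to_numpy(dtype=np.int64)
        sel = chroms == chrom
        # 1-based point pos falls in [start, end) iff start < pos <= end
        zero_based = positions[sel] - 1
        idx = np.searchsorted(starts, zero_based, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(sel.sum(), dtype=bool)
        hit[ok] = zero_based[ok] < ends[idx[ok]]
        mask[sel] = hit
    return mask


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def maf_matched_permutation(
    test_snps: pd.DataFrame,
    pool_snps: pd.DataFrame,
    annotations: dict[str, pd.DataFrame],
    n_perm: int = 1000,
    seed: int = 0,
    fdr_alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """MAF-matched permutation enrichment of a SNP set in interval annotations.

    ``test_snps`` and ``pool_snps`` need columns snp_id, chrom, pos, maf; the
    pool must exclude the test set and contain at least as many SNPs per MAF
    bin as the test set.  Each permutation draws, per bin, exactly the test
    set's count.  Per state: fold = observed overlap / mean permuted overlap;
    enrichment p = (1 + #{perm >= obs}) / (n_perm + 1), mirrored for
    depletion, reported as the smaller (one-sided) tail; BH-FDR across
    states; significant iff FDR < ``fdr_alpha``.
    """
    rng = np.random.default_rng(seed)
    test_bins = test_snps["maf"].map(maf_bin)
    pool_bins = pool_snps["maf"].map(maf_bin)
    need = test_bins.value_counts()
    pool_by_bin = {b: np.flatnonzero(pool_bins.to_numpy() == b) for b in need.index}
    for b, cnt in need.items():
        if len(pool_by_bin.get(b, ())) < cnt:
            raise ValueError(f"insufficient pool SNPs in MAF bin {b}")

    # precompute overlap masks over the pool once per annotation
    pool_pos = pool_snps["pos"].to_numpy()
    pool_chrom = pool_snps["chrom"].to_numpy()
    test_pos = test_snps["pos"].to_numpy()
    test_chrom = test_snps["chrom"].to_numpy()

    # draw all permutation index sets up front (per bin, stacked)
    perm_idx = np.empty((n_perm, len(test_snps)), dtype=np.int64)
    col = 0
    for b, cnt in need.items():
        pool_b = pool_by_bin[b]
        draws = np.stack([rng.choice(pool_b, size=cnt, replace=False) for _ in range(n_perm)])
        perm_idx[:, col:col + cnt] = draws
        col += cnt

    results = []
    for ann_id, intervals in annotations.items():
        obs = int(snps_in_intervals(test_pos, test_chrom, intervals).sum())
        pool_mask = snps_in_intervals(pool_pos, pool_chrom, intervals)
        perm_overlaps = pool_mask[perm_idx].sum(axis=1)
        mean_perm = float(perm_overlaps.mean())
        fold = obs / mean_perm if mean_perm > 0 else np.nan
        p_enrich = (1 + int((perm_overlaps >= obs).sum())) / (n_perm + 1)
        p_deplete = (1 + int((perm_overlaps <= obs).sum())) / (n_perm + 1)
        p = min(p_enrich, p_deplete)
        results.append(
            EnrichmentResult(
                ann_id, len(pool_snps), int(pool_mask.sum()), len(test_snps), obs,
                float(fold), float(p), fold_defined=mean_perm > 0,
            )
        )
    fdr = bh_fdr([r.p for r in results])
    for r, q in zip(results, fdr):
        r.fdr_or_bonf = float(q)
        r.significant = bool(q < fdr_alpha)
    return results
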