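"""End-to-end orchestration of the synthetic meQTL analysis chain.

Stages run in dependency order: cohort simulation (or ingest) ->
heritability scan -> two-step meQTL mapping -> [MR, colocalization, eQTM,
hotspot detection, enrichment].  Every output TSV carries a header comment
with package version, seed and config hash; stage toggles skip downstream
outputs without disturbing independent branches.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from meqtlkit import coloc as coloc_mod
from meqtlkit import eqtm as eqtm_mod
from meqtlkit import enrich as enrich_mod
from meqtlkit import io as io_mod
from meqtlkit import meqtl as meqtl_mod
from meqtlkit import mr as mr_mod
from meqtlkit import synthetic as syn
from meqtlkit import varcomp as vc

__all__ = ["PipelineConfig", "run_pipeline", "cis_eqtl_scan"]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Stage toggles plus per-stage settings for one pipeline run."""

    sim: syn.SimConfig = dataclasses.field(default_factory=syn.SimConfig)
    scan: meqtl_mod.ScanConfig = dataclasses.field(
        default_factory=lambda: meqtl_mod.ScanConfig(n_cis_tests=0, n_trans_tests=0)
    )
    seed: int = 0
    run_mr: bool = True
    run_coloc: bool = True
    run_eqtm: bool = True
    run_hotspots: bool = True
    run_enrich: bool = True
    mr_iv_r2: float = 0.01
    coloc_priors: coloc_mod.ColocPriors = coloc_mod.DEFAULT_PRIORS
    n_perm: int = 200

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = syn.SimConfig(**{
            k: tuple(v) if isinstance(v, list) and k not in ("hotspot_spec", "coloc_spec", "chrom_layout") else v
            for k, v in raw.pop("sim", {}).items()
        })
        if sim.hotspot_spec:
            sim.hotspot_spec = [tuple(h) for h in sim.hotspot_spec]
        if sim.coloc_spec:
            sim.coloc_spec = [tuple(c) for c in sim.coloc_spec]
        if sim.chrom_layout:
            sim.chrom_layout = [tuple(c) for c in sim.chrom_layout]
        scan = meqtl_mod.ScanConfig(**raw.pop("scan", {}))
        pri = raw.pop("coloc_priors", None)
        cfg = cls(sim=sim, scan=scan, **raw)
        if pri:
            cfg.coloc_priors = coloc_mod.ColocPriors(**pri)
        return cfg


def cis_eqtl_scan(expression, genotypes, window: int = 1_000_000,
                  alpha: float = 1e-4) -> pd.DataFrame:
    """Cis-eQTL associations: expression of each gene on every SNP within the
    window around its TSS, retaining pairs with p below ``alpha``."""
    rows = []
    snp_map = genotypes.snp_map
    E = expression.values
    for gene in E.columns:
        g = expression.gene_map.loc[gene]
        near = snp_map[
            (snp_map["chrom"] == g["chrom"]) & (np.abs(snp_map["pos"] - g["tss"]) <= window)
        ]
        if near.empty:
            continue
        slope, se, t, p, ok_s, _ = eqtm_mod._pairwise_regression(
            E[[gene]].to_numpy(dtype=float),
            genotypes.dosages[near.index].to_numpy(dtype=float),
        )
        for k, snp_id in enumerate(near.index):
            if ok_s[k] and p[k, 0] < alpha:
                rows.append(
                    {
                        "gene_id": gene, "snp_id": snp_id,
                        "snp_chrom": near.loc[snp_id, "chrom"],
                        "snp_pos": int(near.loc[snp_id, "pos"]),
                        "beta": slope[k, 0], "se": se[k, 0], "p": p[k, 0],
                        "maf": near.loc[snp_id, "maf"],
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "snp_id", "snp_chrom", "snp_pos", "beta", "se", "p", "maf"]
    )


def _write(df: pd.DataFrame, out_dir: Path, name: str, header: str):
    io_mod.write_matrix_tsv(df, out_dir / name, header_comment=header)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the configured stages on a synthetic cohort; returns the
    in-memory stage results and writes one TSV per stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = io_mod.output_header(config.seed, repr(config))
    results: dict = {}

    sim = dataclasses.replace(config.sim, seed=config.seed)
    ped, K, H = syn.simulate_pedigree(sim)
    genotypes = syn.simulate_genotypes(sim, ped)
    cpgs, truth = syn.simulate_methylation(genotypes, K, H, sim)
    expression, truth = syn.simulate_expression(genotypes, cpgs, sim, truth)
    results.update(pedigree=ped, genotypes=genotypes, cpgs=cpgs,
                   expression=expression, truth=truth)
    ped.to_csv(out_dir / "pedigree.tsv", sep="\t", index=False)
    _write(truth.cpg_truth, out_dir, "truth_cpgs.tsv", header)

    # heritability
    herit, counts = vc.heritability_scan(cpgs, None, K, H)
    results["heritability"] = herit
    results["heritability_bins"] = counts
    _write(herit, out_dir, "heritability.tsv", header)

    # meQTL two-step scan
    resid = meqtl_mod.residualize_methylation(cpgs, None, K)
    prefilter = meqtl_mod.fast_linear_scan(resid, cpgs.cpg_map, genotypes, config.scan)
    final = meqtl_mod.lme_refit(prefilter, cpgs, None, K, genotypes)
    scan_cfg = config.scan
    if scan_cfg.n_cis_tests <= 0 or scan_cfg.n_trans_tests <= 0:
        n_pairs = len(cpgs.betas.columns) * genotypes.n_snps
        cls_all = meqtl_mod.classify_pairs(
            np.broadcast_to(genotypes.snp_map["chrom"].to_numpy(), (cpgs.betas.shape[1], genotypes.n_snps)),
            np.broadcast_to(genotypes.snp_map["pos"].to_numpy(), (cpgs.betas.shape[1], genotypes.n_snps)),
            cpgs.cpg_map["chrom"].to_numpy()[:, None],
            cpgs.cpg_map["pos"].to_numpy()[:, None],
            scan_cfg,
        )
        n_cis = int((cls_all == "cis").sum())
        n_trans = int(np.isin(cls_all, ["trans_intra", "trans_inter"]).sum())
        scan_cfg = dataclasses.replace(
            scan_cfg, n_cis_tests=max(n_cis, 1), n_trans_tests=max(n_trans, 1)
        )
        log.info("realized test counts: cis=%d trans=%d", n_cis, n_trans)
    significant, thresholds = meqtl_mod.apply_significance(final, scan_cfg)
    results.update(meqtl_prefilter=prefilter, meqtl_final=final,
                   meqtl_significant=significant, thresholds=thresholds,
                   residuals=resid)
    _write(final, out_dir, "meqtl_final.tsv", header)
    _write(significant, out_dir, "meqtl_significant.tsv", header)

    cis_sig = significant[significant["class"] == "cis"]
    eqtl = cis_eqtl_scan(expression, genotypes)
    results["cis_eqtl"] = eqtl

    if config.run_mr:
        results["mr"] = _mr_stage(cis_sig, genotypes, truth, sim, config, out_dir, header)
    if config.run_coloc:
        results["coloc"] = _coloc_stage(
            prefilter, eqtl, truth, cpgs, expression, config, out_dir, header,
            genotypes=genotypes,
        )
    if config.run_eqtm:
        expr_resid = expression.values - expression.values.mean()
        eqtm_rec, eqtm_thr = eqtm_mod.eqtm_scan(
            resid, expr_resid, cpgs.cpg_map, expression.gene_map
        )
        results["eqtm"] = eqtm_rec
        results["eqtm_threshold"] = eqtm_thr
        _write(eqtm_rec, out_dir, "eqtm.tsv", header)
    if config.run_hotspots:
        hotspots = eqtm_mod.detect_hotspots(
            significant[significant["class"].isin(eqtm_mod.TRANS_CLASSES)], genotypes
        )
        for h in hotspots:
            eqtm_mod.link_hotspot_egenes(h, eqtl, expression.gene_map, genotypes)
        results["hotspots"] = hotspots
        hs = pd.DataFrame(
            [
                {
                    "hotspot_id": h.hotspot_id, "index_snp": h.index_snp,
                    "n_members": len(h.member_snps), "n_targets": len(h.target_cpgs),
                    "egenes": ";".join(sorted(h.linked_egenes)),
                }
                for h in hotspots
            ],
            columns=["hotspot_id", "index_snp", "n_members", "n_targets", "egenes"],
        ).set_index("hotspot_id")
        _write(hs, out_dir, "hotspots.tsv", header)
    if config.run_enrich:
        ann = {
            "island": set(cpgs.cpg_map.index[cpgs.cpg_map["island"]]),
            "promoter": set(cpgs.cpg_map.index[cpgs.cpg_map["promoter"]]),
        }
        fg = set(cis_sig["cpg_id"])
        enr = enrich_mod.hypergeom_enrichment(fg, set(cpgs.cpg_map.index), ann)
        enr_df = pd.DataFrame([dataclasses.asdict(e) for e in enr]).set_index("annotation_id")
        results["enrichment"] = enr_df
        _write(enr_df, out_dir, "enrichment.tsv", header)

    return results


def _mr_stage(cis_sig, genotypes, truth, sim, config, out_dir, header):
    rows = []
    by_cpg = dict(tuple(cis_sig.groupby("cpg_id")))
    exposure_frames = []
    for cpg_id, rec in by_cpg.items():
        kept, insufficient = mr_mod.select_ivs(rec, genotypes, config.mr_iv_r2)
        if insufficient:
            continue
        sub = rec[rec["snp_id"].isin(kept)].copy()
        sub["effect_allele"] = genotypes.snp_map.loc[sub["snp_id"], "effect_allele"].to_numpy()
        sub["other_allele"] = genotypes.snp_map.loc[sub["snp_id"], "other_allele"].to_numpy()
        sub["maf"] = genotypes.snp_map.loc[sub["snp_id"], "maf"].to_numpy()
        exposure_frames.append(sub)
    if not exposure_frames:
        empty = pd.DataFrame(columns=["exposure_id", "theta", "se", "p_mr", "status"])
        _write(empty.set_index("exposure_id"), out_dir, "mr.tsv", header)
        return empty
    all_exposures = pd.concat(exposure_frames)
    outcome = syn.simulate_outcome_gwas(
        truth, all_exposures[["snp_id", "cpg_id", "maf"]].assign(
            effect_allele=all_exposures["effect_allele"],
            other_allele=all_exposures["other_allele"],
        ),
        sim, genotypes,
    ).drop_duplicates("snp_id")
    n_tested = len(exposure_frames)
    for sub in exposure_frames:
        cpg_id = sub["cpg_id"].iloc[0]
        table = mr_mod.harmonize(sub, outcome)
        res = mr_mod.stepwise_iv_refinement(table)
        rows.append(
            {
                "exposure_id": cpg_id, "n_iv_initial": res.n_iv_initial,
                "n_iv_final": res.n_iv_final, "theta": res.theta,
                "se": res.se_theta, "p_mr": res.p_mr, "or": res.or_value,
                "ci_low": res.ci_low, "ci_high": res.ci_high,
                "q": res.q_stat, "p_heter": res.p_heter,
                "egger_intercept": res.egger_intercept, "p_pleio": res.p_pleio,
                "status": res.status,
                "excluded_ivs": ";".join(res.excluded_ivs),
                "bonferroni_p": min(1.0, res.p_mr * n_tested) if np.isfinite(res.p_mr) else np.nan,
            }
        )
    mr_df = pd.DataFrame(rows).set_index("exposure_id") if rows else pd.DataFrame()
    _write(mr_df, out_dir, "mr.tsv", header)
    return mr_df


def regional_stats(trait: np.ndarray, genotypes, chrom, center: int,
                   window: int = 2_000_000, trait_name: str = "trait") -> pd.DataFrame:
    """Marginal association of one trait with every SNP in a window: the
    unfiltered per-SNP summary statistics a colocalization region needs."""
    half = window // 2
    snp_map = genotypes.snp_map
    near = snp_map[
        (snp_map["chrom"] == chrom)
        & (snp_map["pos"] >= center - half)
        & (snp_map["pos"] <= center + half)
    ]
    slope, se, t, p, ok_s, _ = eqtm_mod._pairwise_regression(
        np.asarray(trait, dtype=float)[:, None],
        genotypes.dosages[near.index].to_numpy(dtype=float),
    )
    return pd.DataFrame(
        {
            "snp_id": near.index,
            "snp_pos": near["pos"].to_numpy(),
            "beta": slope[:, 0],
            "se": se[:, 0],
            "p": p[:, 0],
            "maf": near["maf"].to_numpy(),
        }
    )[ok_s].reset_index(drop=True)


def _coloc_stage(prefilter, eqtl, truth, cpgs, expression, config, out_dir, header,
                 genotypes=None):
    rows = []
    gene_iter = truth.gene_truth.iterrows() if not truth.gene_truth.empty else []
    for gene_id, spec_row in gene_iter:
        cpg_id = spec_row.get("paired_cpg", "")
        if not cpg_id:
            continue
        center_snp = spec_row["causal_snp"]
        chrom = genotypes.snp_map.loc[center_snp, "chrom"]
        center = int(genotypes.snp_map.loc[center_snp, "pos"])
        me = regional_stats(cpgs.betas[cpg_id].to_numpy(), genotypes, chrom, center)
        eq_stats = regional_stats(expression.values[gene_id].to_numpy(), genotypes, chrom, center)
        region, reason = coloc_mod.build_region(cpg_id, gene_id, me, eq_stats, window=2_000_000)
        if region is None:
            rows.append({"cpg_id": cpg_id, "gene_id": gene_id, "n_snps": 0,
                         "pp0": np.nan, "pp1": np.nan, "pp2": np.nan,
                         "pp3": np.nan, "pp4": np.nan,
                         "colocalized": False, "note": reason})
            continue
        l1 = coloc_mod.wakefield_labf(region["beta1"], region["se1"])
        l2 = coloc_mod.wakefield_labf(region["beta2"], region["se2"])
        res = coloc_mod.coloc_posterior(l1, l2, config.coloc_priors)
        rows.append(
            {
                "cpg_id": cpg_id, "gene_id": gene_id, "n_snps": res.n_snps,
                "pp0": res.pp0, "pp1": res.pp1, "pp2": res.pp2,
                "pp3": res.pp3, "pp4": res.pp4,
                "colocalized": coloc_mod.call_colocalized(res), "note": "ok",
            }
        )
    coloc_df = pd.DataFrame(
        rows, columns=["cpg_id", "gene_id", "n_snps", "pp0", "pp1", "pp2",
                       "pp3", "pp4", "colocalized", "note"],
    )
    _write(coloc_df.set_index("cpg_id") if not coloc_df.empty else coloc_df,
           out_dir, "coloc.tsv", header)
    return coloc_df
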