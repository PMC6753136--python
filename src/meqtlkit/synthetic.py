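"""Synthetic pedigreed cohort generator with recorded ground truth.

Generates family-structured genotypes, CpG methylation, gene expression and
outcome-GWAS summary statistics whose generative parameters are retained in a
:class:`TruthTable`, so that heritability estimation, meQTL mapping, MR,
colocalization and hotspot detection can all be validated against known truth.

Model sketch
------------
* Pedigrees are nuclear families (configurable number of parents and a
  sibship-size range) plus unrelated singletons.  The additive relationship
  matrix ``K`` uses co-ancestry 0.5 for parent-offspring and full-sib pairs
  and 0 otherwise; the household matrix ``H`` is 1 within a family.
* Founder haplotypes follow a first-order Markov chain along each chromosome
  calibrated so that the squared correlation of adjacent SNPs is
  ``adjacent_ld_r2``; offspring receive recombined parental haplotypes.
* Per-CpG latent trait ``z = sum_k beta_k g_k + a + c + e`` with
  ``a ~ N(0, sigma2_A K)``, ``c ~ N(0, sigma2_h H)``, ``e ~ N(0, sigma2_e I)``;
  ``z`` is squashed into (0.02, 0.98) by a gentle logistic map so that beta
  values remain nearly linear in the latent scale.
* Trans-meQTL hotspots are mediated: hotspot SNP -> cis gene expression ->
  remote target CpGs, which is the mechanism the hotspot detector and the
  eGene linkage step are designed to recover.
* Outcome GWAS effects are ``Gamma_j = theta * gamma_j + alpha_j + eps_j``
  with ``gamma_j`` the model-implied true SNP->CpG effect, ``alpha_j``
  directional pleiotropy and ``eps_j`` sampling noise at the configured GWAS
  sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "TruthTable",
    "GenotypeMatrix",
    "CpGMatrix",
    "ExpressionMatrix",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_expression",
    "simulate_outcome_gwas",
]


class ConfigurationError(ValueError):
    """Raised when a SimConfig requests an impossible cohort."""


class GenerationError(RuntimeError):
    """Raised when a requested structure cannot be realized (e.g. no low-LD
    partner SNP for a distinct-causal-variant region)."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Sample-by-SNP dosage matrix plus the SNP map.

    ``dosages`` is a DataFrame (rows = sample ids, columns = snp ids) with
    values in [0, 2] counting copies of the effect allele.  ``snp_map`` is
    indexed by snp id with columns ``chrom``, ``pos`` (1-based), ``effect_allele``,
    ``other_allele`` and ``maf``.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]


@dataclass
class CpGMatrix:
    """Sample-by-CpG beta-value matrix plus the CpG map (chrom, pos, features)."""

    betas: pd.DataFrame
    cpg_map: pd.DataFrame


@dataclass
class ExpressionMatrix:
    """Sample-by-gene expression matrix plus the gene map (chrom, tss)."""

    values: pd.DataFrame
    gene_map: pd.DataFrame


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults describe a modest family cohort: 200 nuclear families of two
    parents and two full sibs plus 200 unrelated singletons, 1000 SNPs on two
    chromosomes with moderate adjacent LD, cis effects explaining 10% of
    latent CpG variance, additive heritabilities drawn from (0.05, 0.6) and
    household fractions from (0, 0.1).
    """

    seed: int = 0
    n_families: int = 200
    sibs_per_family: tuple[int, int] = (2, 2)
    parents_per_family: int = 2
    n_unrelated: int = 200
    n_snps: int = 1000
    n_cpgs: int = 200
    n_genes: int = 40
    maf_range: tuple[float, float] = (0.05, 0.5)
    adjacent_ld_r2: float = 0.3
    chrom_layout: list[tuple[str, int, int]] | None = None
    p_cis_qtl: float = 0.5
    cis_effect_r2: float = 0.10
    # number of (mutually low-LD) causal cis SNPs per cis-regulated CpG; the
    # cis_effect_r2 budget is split equally among them
    n_cis_snps_per_cpg: int = 3
    h2_additive_range: tuple[float, float] = (0.05, 0.6)
    household_var_range: tuple[float, float] = (0.0, 0.1)
    hotspot_spec: list[tuple[int, int, float]] = field(default_factory=list)
    coloc_spec: list[tuple[int, int, bool]] = field(default_factory=list)
    theta_causal: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    gwas_n: int = 50_000
    allele_swap_fraction: float = 0.0
    # gentleness of the latent->beta logistic squash; small values keep the
    # map nearly linear over the bulk of the latent distribution
    squash_scale: float = 0.25
    # variance of mediating-gene expression explained by its hotspot SNP
    hotspot_gene_r2: float = 0.5
    # variance of gene expression explained by its causal SNP in coloc regions
    expr_cis_r2: float = 0.15
    recomb_rate_per_bp: float = 1e-8

    def layout(self) -> list[tuple[str, int, int]]:
        if self.chrom_layout is not None:
            if sum(n for _, n, _ in self.chrom_layout) != self.n_snps:
                raise ConfigurationError("chrom_layout SNP counts must sum to n_snps")
            return list(self.chrom_layout)
        half = self.n_snps // 2
        return [("chr1", half, 60_000_000), ("chr2", self.n_snps - half, 60_000_000)]

    def validate(self) -> None:
        if self.n_families < 0 or self.n_unrelated < 0:
            raise ConfigurationError("negative cohort sizes")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ConfigurationError(f"degenerate maf_range {self.maf_range}")
        if not (0.0 <= self.adjacent_ld_r2 < 1.0):
            raise ConfigurationError("adjacent_ld_r2 must be in [0, 1)")
        if self.gwas_n < 10:
            raise ConfigurationError("gwas_n < 10 cannot support summary statistics")


@dataclass
class TruthTable:
    """Ground truth recorded by the generators.

    ``cpg_truth`` (per CpG): h2, household_var, residual_var, causal SNP ids
    and betas on the latent scale, theta (true causal effect on the outcome),
    hotspot membership.  ``gene_truth`` (per gene): causal eQTL SNP and beta.
    ``hotspots``: per hotspot the SNP, mediating gene and target CpG set.
    ``mediators``: realized mediating-expression vectors keyed by gene id.
    """

    cpg_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    hotspots: list[dict] = field(default_factory=list)
    mediators: dict[str, np.ndarray] = field(default_factory=dict)
    causal_betas: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"cpg_truth": self.cpg_truth, "gene_truth": self.gene_truth}


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per generation stage
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,)))


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build a pedigree of nuclear families plus singletons.

    Returns the pedigree table, the additive relationship matrix ``K``
    (co-ancestry 0.5 for parent-offspring and sib pairs, 1 on the diagonal)
    and the shared-household matrix ``H`` (1 within a family including the
    diagonal, 0 elsewhere).  Both matrices are symmetric and block diagonal
    by family.
    """
    config.validate()
    rng = _rng(config, 0)
    lo, hi = config.sibs_per_family
    if lo < 1 or hi < lo:
        raise ConfigurationError("sibs_per_family must satisfy 1 <= min <= max")

    rows = []
    for f in range(config.n_families):
        fam = f"F{f:04d}"
        parents = []
        for p in range(config.parents_per_family):
            pid = f"{fam}_P{p}"
            parents.append(pid)
            rows.append((pid, fam, ".", ".", "parent"))
        father = parents[0] if len(parents) >= 1 else "."
        mother = parents[1] if len(parents) >= 2 else "."
        n_sibs = int(rng.integers(lo, hi + 1))
        for s in range(n_sibs):
            rows.append((f"{fam}_S{s}", fam, father, mother, "sib"))
    for u in range(config.n_unrelated):
        rows.append((f"U{u:04d}", f"U{u:04d}", ".", ".", "singleton"))

    ped = pd.DataFrame(rows, columns=["sample_id", "family_id", "father_id", "mother_id", "role"])
    n = len(ped)
    if n < 2:
        raise ConfigurationError("pedigree must contain at least 2 samples")

    K = np.eye(n)
    H = np.zeros((n, n))
    fam_groups = ped.groupby("family_id", sort=False).indices
    role = ped["role"].to_numpy()
    for idx in fam_groups.values():
        idx = np.asarray(idx)
        H[np.ix_(idx, idx)] = 1.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                pair = {role[i], role[j]}
                # parent-offspring and sib-sib share 0.5; spouses are unrelated
                if pair == {"parent", "sib"} or pair == {"sib"}:
                    K[i, j] = K[j, i] = 0.5
    return ped, K, H


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _founder_haplotypes(rng, p: np.ndarray, chrom_slices, rho: float, n_hap: int) -> np.ndarray:
    """First-order Markov haplotypes with adjacent-allele correlation ``rho``."""
    m = p.size
    hap = np.zeros((n_hap, m), dtype=np.int8)
    u = rng.random((n_hap, m))
    for sl in chrom_slices:
        cols = range(sl.start, sl.stop)
        first = sl.start
        hap[:, first] = u[:, first] < p[first]
        for k in cols:
            if k == first:
                continue
            pk, pprev = p[k], p[k - 1]
            s = np.sqrt(pk * (1 - pk) * pprev * (1 - pprev))
            # largest correlation attainable without clipping the
            # conditional probabilities (keeps marginals exact)
            cap = min(pprev * (1 - pk), (1 - pprev) * pk) / s
            cov = min(rho, 0.999 * cap) * s
            p_given1 = pk + cov / pprev
            p_given0 = pk - cov / (1 - pprev)
            prev = hap[:, k - 1]
            thresh = np.where(prev == 1, p_given1, p_given0)
            hap[:, k] = u[:, k] < thresh
    return hap


def _transmit(rng, hap_a: np.ndarray, hap_b: np.ndarray, chrom_slices, rec_prob: np.ndarray) -> np.ndarray:
    """One gamete from a parent's two haplotypes with Markov recombination."""
    m = hap_a.size
    choose = np.zeros(m, dtype=bool)
    switches = rng.random(m) < rec_prob
    for sl in chrom_slices:
        start = bool(rng.integers(0, 2))
        sw = switches[sl].copy()
        sw[0] = False
        parity = np.cumsum(sw) % 2
        choose[sl] = np.logical_xor(start, parity)
    return np.where(choose, hap_b, hap_a)


def _distinct_positions(rng, span: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions in [1, span] without materializing
    the full range."""
    if n > span:
        raise ConfigurationError(f"cannot place {n} SNPs in a {span} bp span")
    draw = np.unique(rng.integers(1, span + 1, size=int(2.2 * n) + 8))
    while draw.size < n:
        draw = np.unique(np.concatenate([draw, rng.integers(1, span + 1, size=n)]))
    return np.sort(rng.choice(draw, size=n, replace=False))


def simulate_genotypes(config: SimConfig, pedigree: pd.DataFrame) -> GenotypeMatrix:
    """LD-structured founder haplotypes plus Mendelian transmission.

    Founders (parents and singletons) draw haplotypes from a first-order
    Markov chain whose allele correlation is ``sqrt(adjacent_ld_r2)`` so the
    squared dosage correlation of adjacent SNPs matches ``adjacent_ld_r2``;
    offspring receive one recombined haplotype from each parent.
    """
    config.validate()
    rng = _rng(config, 1)
    layout = config.layout()
    lo, hi = config.maf_range

    snp_ids, chroms, positions, slices = [], [], [], []
    start = 0
    for chrom, n_on_chrom, span in layout:
        if span <= 0:
            raise ConfigurationError(f"non-positive span for {chrom}")
        pos = _distinct_positions(rng, span, n_on_chrom)
        positions.append(pos)
        chroms.extend([chrom] * n_on_chrom)
        snp_ids.extend(f"{chrom}_snp{i}" for i in range(n_on_chrom))
        slices.append(slice(start, start + n_on_chrom))
        start += n_on_chrom
    positions = np.concatenate(positions)
    m = len(snp_ids)

    # effect-allele frequencies follow a reflected random walk inside the MAF
    # range so that adjacent SNPs have similar frequencies (as in real LD
    # blocks) and the target adjacent correlation is attainable
    p = np.empty(m)
    step = 0.1 * (hi - lo)
    for sl in slices:
        p[sl.start] = rng.uniform(lo, hi)
        for k in range(sl.start + 1, sl.stop):
            prop = p[k - 1] + step * rng.standard_normal()
            while prop < lo or prop > hi:
                prop = lo + abs(prop - lo) if prop < lo else hi - abs(prop - hi)
            p[k] = prop
    rho = float(np.sqrt(config.adjacent_ld_r2))

    samples = pedigree["sample_id"].to_numpy()
    sample_idx = {s: i for i, s in enumerate(samples)}
    is_founder = (pedigree["father_id"] == ".") & (pedigree["mother_id"] == ".")

    hap1 = np.zeros((len(samples), m), dtype=np.int8)
    hap2 = np.zeros((len(samples), m), dtype=np.int8)
    founder_rows = np.flatnonzero(is_founder.to_numpy())
    fh = _founder_haplotypes(rng, p, slices, rho, 2 * len(founder_rows))
    hap1[founder_rows] = fh[: len(founder_rows)]
    hap2[founder_rows] = fh[len(founder_rows):]

    # per-SNP recombination probability from the gap to the previous SNP
    rec_prob = np.zeros(m)
    for sl in slices:
        gaps = np.diff(positions[sl.start:sl.stop], prepend=positions[sl.start])
        rec_prob[sl.start:sl.stop] = 1.0 - np.exp(-config.recomb_rate_per_bp * gaps)

    for i in np.flatnonzero(~is_founder.to_numpy()):
        fa = sample_idx[pedigree.iloc[i]["father_id"]]
        mo = sample_idx[pedigree.iloc[i]["mother_id"]]
        hap1[i] = _transmit(rng, hap1[fa], hap2[fa], slices, rec_prob)
        hap2[i] = _transmit(rng, hap1[mo], hap2[mo], slices, rec_prob)

    dosage = (hap1 + hap2).astype(float)
    af = dosage.mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)

    snp_map = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions.astype(int),
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf,
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    dosages = pd.DataFrame(dosage, index=pd.Index(samples, name="sample_id"), columns=snp_ids)
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _family_draw(rng, cov: np.ndarray, chol_cache: dict, key: str) -> np.ndarray:
    if key not in chol_cache:
        n = cov.shape[0]
        try:
            chol_cache[key] = np.linalg.cholesky(cov + 1e-8 * np.eye(n))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(f"covariance matrix {key} is not PSD") from exc
    L = chol_cache[key]
    return L @ rng.standard_normal(cov.shape[0])


def squash_to_beta(z: np.ndarray, scale: float = 0.25) -> np.ndarray:
    """Monotone logistic map of a latent trait into the open beta interval (0.02, 0.98)."""
    return 0.02 + 0.96 / (1.0 + np.exp(-scale * z))


def simulate_methylation(
    genotypes: GenotypeMatrix,
    kinship: np.ndarray,
    household: np.ndarray,
    config: SimConfig,
) -> tuple[CpGMatrix, TruthTable]:
    """Draw per-CpG latent traits and squash them into beta values.

    For each CpG the latent trait is a weighted sum of (optionally) a cis
    causal dosage, a family-structured additive deviate, a shared-household
    deviate and white noise, with weights chosen so the realized variance
    fractions equal the configured (cis_effect_r2, h2, household) exactly in
    the generator's algebra.  Hotspot target CpGs are instead driven by the
    mediating gene's expression (see module docstring).
    """
    config.validate()
    rng = _rng(config, 2)
    n = genotypes.n_samples
    if kinship.shape != (n, n) or household.shape != (n, n):
        raise ValueError("kinship/household must be n x n")
    chol_cache: dict[str, np.ndarray] = {}

    layout = config.layout()
    spans = {c: s for c, _, s in layout}
    chrom_names = [c for c, _, _ in layout]
    # place CpGs uniformly, proportional to chromosome span
    probs = np.array([spans[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()
    cpg_chrom = rng.choice(chrom_names, size=config.n_cpgs, p=probs)
    cpg_pos = np.array([rng.integers(1, spans[c] + 1) for c in cpg_chrom])
    cpg_ids = [f"cg{i:06d}" for i in range(config.n_cpgs)]
    island = rng.random(config.n_cpgs) < 0.3
    promoter = rng.random(config.n_cpgs) < 0.2

    snp_map = genotypes.snp_map
    snp_chrom = snp_map["chrom"].to_numpy()
    snp_pos = snp_map["pos"].to_numpy()
    snp_ids = snp_map.index.to_numpy()
    dos = genotypes.dosages.to_numpy()

    h2_lo, h2_hi = config.h2_additive_range
    hh_lo, hh_hi = config.household_var_range

    coloc_cpg_idx = {c for c, _, _ in config.coloc_spec}
    # coloc-paired CpGs must carry a cis effect: relocate them next to a SNP
    for j in coloc_cpg_idx:
        if not np.any(
            (snp_chrom == cpg_chrom[j]) & (np.abs(snp_pos - cpg_pos[j]) <= 1_000_000)
        ):
            k = int(rng.integers(0, len(snp_ids)))
            cpg_chrom[j] = snp_chrom[k]
            cpg_pos[j] = max(1, snp_pos[k] + int(rng.integers(-500_000, 500_000)))

    # ---- hotspot machinery: mediating-gene expression driven by hotspot SNPs
    mediators: dict[str, np.ndarray] = {}
    hotspot_records: list[dict] = []
    target_of: dict[int, tuple[int, float]] = {}  # cpg index -> (hotspot no, mediation r2)
    taken = set()
    for h_no, (snp_index, n_targets, mediation_r2) in enumerate(config.hotspot_spec):
        if not (0 <= snp_index < len(snp_ids)):
            raise ConfigurationError(f"hotspot snp_index {snp_index} outside genotype map")
        g = _standardize(dos[:, snp_index])
        noise = rng.standard_normal(n)
        gr2 = config.hotspot_gene_r2
        med = np.sqrt(gr2) * g + np.sqrt(1 - gr2) * _standardize(noise)
        gene_id = f"hotspot_gene{h_no}"
        mediators[gene_id] = med
        # targets: CpGs trans to the hotspot SNP (other chromosome or > 5 Mb)
        is_trans = (cpg_chrom != snp_chrom[snp_index]) | (
            np.abs(cpg_pos - snp_pos[snp_index]) > 5_000_000
        )
        candidates = [
            i for i in np.flatnonzero(is_trans) if i not in taken and i not in coloc_cpg_idx
        ]
        if len(candidates) < n_targets:
            raise GenerationError(
                f"hotspot {h_no}: only {len(candidates)} trans CpGs available for {n_targets} targets"
            )
        chosen = rng.choice(candidates, size=n_targets, replace=False)
        taken.update(int(i) for i in chosen)
        for i in chosen:
            target_of[int(i)] = (h_no, mediation_r2)
        hotspot_records.append(
            {
                "hotspot_no": h_no,
                "snp_id": snp_ids[snp_index],
                "snp_index": snp_index,
                "gene_id": gene_id,
                "gene_r2": gr2,
                "mediation_r2": mediation_r2,
                "target_cpgs": [cpg_ids[int(i)] for i in chosen],
            }
        )

    betas = np.empty((n, config.n_cpgs))
    truth_rows = []
    causal_betas: dict[str, dict[str, float]] = {}

    for j in range(config.n_cpgs):
        cid = cpg_ids[j]
        if j in target_of:
            h_no, mr2 = target_of[j]
            med = _standardize(mediators[hotspot_records[h_no]["gene_id"]])
            e = _standardize(rng.standard_normal(n))
            z = np.sqrt(mr2) * med + np.sqrt(1 - mr2) * e
            b = squash_to_beta(z, config.squash_scale)
            truth_rows.append(
                {
                    "cpg_id": cid, "chrom": cpg_chrom[j], "pos": int(cpg_pos[j]),
                    "h2": 0.0, "household_var": 0.0, "cis_r2": 0.0,
                    "residual_var": 1 - mr2, "causal_snps": "", "theta": 0.0,
                    "hotspot": h_no, "mediation_r2": mr2,
                    "squash_slope": float(np.cov(z, b)[0, 1] / np.var(z)),
                }
            )
            betas[:, j] = b
            continue

        h2 = rng.uniform(h2_lo, h2_hi)
        hh = rng.uniform(hh_lo, hh_hi)
        want_cis = (rng.random() < config.p_cis_qtl) or (j in coloc_cpg_idx)
        cis_r2 = 0.0
        causal: dict[str, float] = {}
        g_term = np.zeros(n)
        if want_cis:
            near = np.flatnonzero(
                (snp_chrom == cpg_chrom[j]) & (np.abs(snp_pos - cpg_pos[j]) <= 1_000_000)
            )
            if near.size:
                # greedily pick up to n_cis mutually low-LD causal SNPs;
                # coloc-paired CpGs stay single-causal (the colocalization
                # model assumes one causal variant per trait per region)
                n_cis = 1 if j in coloc_cpg_idx else config.n_cis_snps_per_cpg
                chosen_k: list[int] = []
                for k in rng.permutation(near):
                    if dos[:, k].std() == 0:
                        continue
                    if all(
                        np.corrcoef(dos[:, k], dos[:, q])[0, 1] ** 2 < 0.05
                        for q in chosen_k
                    ):
                        chosen_k.append(int(k))
                    if len(chosen_k) >= n_cis:
                        break
                if chosen_k:
                    cis_r2 = config.cis_effect_r2
                    share = cis_r2 / len(chosen_k)
                    for k in chosen_k:
                        beta_k = np.sqrt(share) / dos[:, k].std()
                        causal[snp_ids[k]] = beta_k
                        g_term = g_term + beta_k * (dos[:, k] - dos[:, k].mean())
        if cis_r2 + h2 + hh >= 1.0:
            h2 = max(0.0, min(h2, 0.98 - cis_r2 - hh))
        resid = 1.0 - cis_r2 - h2 - hh

        a = _standardize(_family_draw(rng, kinship, chol_cache, "K"))
        c = _standardize(_family_draw(rng, household, chol_cache, "H"))
        e = _standardize(rng.standard_normal(n))
        z = g_term + np.sqrt(h2) * a + np.sqrt(hh) * c + np.sqrt(resid) * e
        b = squash_to_beta(z, config.squash_scale)
        causal_betas[cid] = causal
        truth_rows.append(
            {
                "cpg_id": cid, "chrom": cpg_chrom[j], "pos": int(cpg_pos[j]),
                "h2": h2, "household_var": hh, "cis_r2": cis_r2,
                "residual_var": resid,
                "causal_snps": ";".join(f"{s}:{v:.6g}" for s, v in causal.items()),
                "theta": config.theta_causal if causal else 0.0,
                "hotspot": -1, "mediation_r2": 0.0,
                "squash_slope": float(np.cov(z, b)[0, 1] / np.var(z)),
            }
        )
        betas[:, j] = b

    cpg_map = pd.DataFrame(
        {
            "chrom": cpg_chrom,
            "pos": cpg_pos.astype(int),
            "island": island,
            "promoter": promoter,
        },
        index=pd.Index(cpg_ids, name="cpg_id"),
    )
    cpg_matrix = CpGMatrix(
        betas=pd.DataFrame(betas, index=genotypes.dosages.index, columns=cpg_ids),
        cpg_map=cpg_map,
    )
    truth = TruthTable(
        cpg_truth=pd.DataFrame(truth_rows).set_index("cpg_id"),
        hotspots=hotspot_records,
        mediators=mediators,
        causal_betas=causal_betas,
    )
    return cpg_matrix, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(
    genotypes: GenotypeMatrix,
    methylation: CpGMatrix,
    config: SimConfig,
    truth: TruthTable | None = None,
) -> tuple[ExpressionMatrix, TruthTable]:
    """Gene expression with shared / distinct causal variants and mediators.

    ``coloc_spec`` entries (cpg_index, gene_index, shared) control whether a
    gene is driven by the same causal SNP as its paired CpG (shared, the H4
    configuration) or by a different regional SNP with pairwise r^2 < 0.05
    (distinct, the H3 configuration).  Hotspot mediating genes recorded in
    ``truth`` are emitted with the exact expression vectors used to build
    their target CpGs.  All remaining genes are pure noise.
    """
    config.validate()
    rng = _rng(config, 3)
    n = genotypes.n_samples
    truth = truth if truth is not None else TruthTable()
    dos = genotypes.dosages.to_numpy()
    snp_map = genotypes.snp_map
    snp_ids = snp_map.index.to_numpy()
    snp_chrom = snp_map["chrom"].to_numpy()
    snp_pos = snp_map["pos"].to_numpy()

    layout = config.layout()
    spans = {c: s for c, _, s in layout}
    chrom_names = [c for c, _, _ in layout]
    probs = np.array([spans[c] for c in chrom_names], dtype=float)
    probs /= probs.sum()

    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]
    gene_chrom = rng.choice(chrom_names, size=config.n_genes, p=probs).astype(object)
    gene_tss = np.array([rng.integers(1, spans[c] + 1) for c in gene_chrom])

    expr = rng.standard_normal((n, config.n_genes))
    gene_rows = []
    cpg_map = methylation.cpg_map

    for cpg_index, gene_index, shared in config.coloc_spec:
        cid = cpg_map.index[cpg_index]
        crow = truth.cpg_truth.loc[cid] if not truth.cpg_truth.empty else None
        causal = truth.causal_betas.get(cid, {})
        if not causal:
            raise GenerationError(f"coloc_spec CpG {cid} has no causal cis SNP")
        cpg_snp = next(iter(causal))
        k_cpg = int(np.flatnonzero(snp_ids == cpg_snp)[0])
        # place the gene's TSS inside the CpG's cis region
        gene_chrom[gene_index] = snp_chrom[k_cpg]
        gene_tss[gene_index] = int(
            np.clip(snp_pos[k_cpg] + int(rng.integers(-200_000, 200_000)),
                    1, spans[str(snp_chrom[k_cpg])])
        )
        if shared:
            k_gene = k_cpg
        else:
            region = np.flatnonzero(
                (snp_chrom == snp_chrom[k_cpg]) & (np.abs(snp_pos - snp_pos[k_cpg]) <= 1_000_000)
            )
            g_cpg = dos[:, k_cpg]
            k_gene = -1
            for cand in rng.permutation(region):
                if cand == k_cpg:
                    continue
                gc = dos[:, cand]
                if gc.std() == 0:
                    continue
                r2 = np.corrcoef(g_cpg, gc)[0, 1] ** 2
                if r2 < 0.05:
                    k_gene = int(cand)
                    break
            if k_gene < 0:
                raise GenerationError(
                    f"no low-LD partner SNP in region of {cpg_snp} for distinct pair"
                )
        g = _standardize(dos[:, k_gene])
        e = _standardize(rng.standard_normal(n))
        r2 = config.expr_cis_r2
        expr[:, gene_index] = np.sqrt(r2) * g + np.sqrt(1 - r2) * e
        gene_rows.append(
            {
                "gene_id": gene_ids[gene_index],
                "causal_snp": snp_ids[k_gene],
                "effect_r2": r2,
                "paired_cpg": cid,
                "shared": bool(shared),
            }
        )

    # hotspot mediating genes: append as extra genes carrying their vectors
    for rec in truth.hotspots:
        gid = rec["gene_id"]
        gene_ids.append(gid)
        k = rec["snp_index"]
        gene_chrom = np.append(gene_chrom, snp_chrom[k])
        tss = int(np.clip(snp_pos[k] + 10_000, 1, spans[str(snp_chrom[k])]))
        gene_tss = np.append(gene_tss, tss)
        expr = np.column_stack([expr, truth.mediators[gid]])
        gene_rows.append(
            {
                "gene_id": gid,
                "causal_snp": rec["snp_id"],
                "effect_r2": rec["gene_r2"],
                "paired_cpg": "",
                "shared": True,
            }
        )

    gene_map = pd.DataFrame(
        {"chrom": gene_chrom, "tss": gene_tss.astype(int)},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    truth.gene_truth = (
        pd.DataFrame(gene_rows).set_index("gene_id") if gene_rows else pd.DataFrame()
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(expr, index=genotypes.dosages.index, columns=gene_ids),
        gene_map=gene_map,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# outcome GWAS
# ---------------------------------------------------------------------------

def true_gamma(
    truth: TruthTable, cpg_id: str, snp_ids: Sequence[str], genotypes: GenotypeMatrix | None = None
) -> np.ndarray:
    """Model-implied SNP->CpG effects, on the measured beta-value scale.

    For a causal SNP the recorded generative (latent-scale) effect is scaled
    by the CpG's realized latent-to-beta squash slope; for a non-causal SNP,
    the LD-projected effect ``beta_k * cov(g_j, g_k)/var(g_j)`` when
    genotypes are available, else 0.
    """
    causal = truth.causal_betas.get(cpg_id, {})
    slope = 1.0
    if not truth.cpg_truth.empty and "squash_slope" in truth.cpg_truth.columns \
            and cpg_id in truth.cpg_truth.index:
        slope = float(truth.cpg_truth.loc[cpg_id, "squash_slope"])
    causal = {s: b * slope for s, b in causal.items()}
    out = np.zeros(len(snp_ids))
    for i, sid in enumerate(snp_ids):
        if sid in causal:
            out[i] = causal[sid]
        elif genotypes is not None and causal:
            gj = genotypes.dosages[sid].to_numpy()
            vj = gj.var()
            if vj > 0:
                out[i] = sum(
                    b * np.cov(gj, genotypes.dosages[s].to_numpy())[0, 1] / vj
                    for s, b in causal.items()
                )
    return out


def simulate_outcome_gwas(
    truth: TruthTable,
    meqtl_summary: pd.DataFrame,
    config: SimConfig,
    genotypes: GenotypeMatrix | None = None,
) -> pd.DataFrame:
    """Second-sample GWAS summary statistics for the outcome trait.

    For each SNP j appearing in ``meqtl_summary`` (columns must include
    ``snp_id``, ``cpg_id`` and ``maf``), the outcome effect is
    ``Gamma_j = theta * gamma_j + alpha_j + eps_j`` where ``gamma_j`` is the
    true SNP->exposure effect, ``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2)``
    and ``eps_j`` has the sampling standard error implied by ``gwas_n`` and
    the allele frequency under a standardized trait.  A configurable fraction
    of rows is emitted with swapped alleles (and negated beta) so that
    downstream harmonization is exercised.
    """
    config.validate()
    rng = _rng(config, 4)
    rows = []
    maf = meqtl_summary["maf"].to_numpy(dtype=float)
    se = 1.0 / np.sqrt(config.gwas_n * 2.0 * maf * (1.0 - maf))
    swap = rng.random(len(meqtl_summary)) < config.allele_swap_fraction
    for i, (_, rec) in enumerate(meqtl_summary.iterrows()):
        gamma = true_gamma(truth, rec["cpg_id"], [rec["snp_id"]], genotypes)[0]
        alpha = config.pleiotropy_mean + config.pleiotropy_sd * rng.standard_normal()
        beta = config.theta_causal * gamma + alpha + se[i] * rng.standard_normal()
        ea, oa = rec.get("effect_allele", "A"), rec.get("other_allele", "G")
        if swap[i]:
            ea, oa, beta = oa, ea, -beta
        rows.append(
            {
                "snp_id": rec["snp_id"],
                "chrom": rec.get("chrom", "."),
                "pos": rec.get("pos", 0),
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta,
                "se": se[i],
                "p": 2 * norm.sf(abs(beta / se[i])),
                "n": config.gwas_n,
                "maf": maf[i],
            }
        )
    return pd.DataFrame(rows)
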