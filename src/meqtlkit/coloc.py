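"""Bayesian colocalization of methylation and expression association signals.

Given per-SNP association summaries for a CpG (trait 1) and a transcript
(trait 2) in a 2 Mb region, computes Wakefield approximate Bayes factors per
SNP and the posterior probabilities of the five causal configurations:

* H0 - no causal variant for either trait,
* H1 / H2 - a causal variant for one trait only,
* H3 - two distinct causal variants,
* H4 - a single shared causal variant.

Default priors follow the blood meQTL/eQTL setting: per-SNP probability
``p1 = 2e-11`` of affecting methylation only, ``p2 = 1e-7`` of affecting
expression only, and ``p12 = 0.1 * p1`` of affecting both; an alternative
conventional preset (1e-4 / 1e-4 / 1e-5) is available.  A region is called
colocalized when PP4 >= 0.80.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "ColocPriors",
    "ColocResult",
    "wakefield_labf",
    "coloc_posterior",
    "build_region",
    "call_colocalized",
    "DEFAULT_PRIORS",
    "CONVENTIONAL_PRIORS",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    p1: float = 2e-11
    p2: float = 1e-7
    p12: float = 2e-12  # p1 * 10%


DEFAULT_PRIORS = ColocPriors()
CONVENTIONAL_PRIORS = ColocPriors(p1=1e-4, p2=1e-4, p12=1e-5)


@dataclass
class ColocResult:
    """Posterior probabilities over the five colocalization hypotheses."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int

    @property
    def colocalized(self) -> bool:
        return call_colocalized(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_labf(beta, se, prior_sd: float = 0.15):
    """Log approximate Bayes factor for a single-SNP association.

    With ``V = se^2``, ``z = beta/se`` and shrinkage ``r = W/(W+V)`` where
    ``W = prior_sd^2``: ``lABF = 0.5*log(1-r) + 0.5*z^2*r``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("standard errors and prior_sd must be positive")
    V = se**2
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + V)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def coloc_posterior(
    labf1, labf2, priors: ColocPriors = DEFAULT_PRIORS
) -> ColocResult:
    """Posterior configuration probabilities from two lABF vectors.

    Sums over single-causal-variant configurations per hypothesis (computed
    in log space): ``S1 = p1 * sum_i ABF1_i``, ``S2 = p2 * sum_i ABF2_i``,
    ``S3 = p1*p2 * (sum_i ABF1_i * sum_j ABF2_j - sum_i ABF1_i*ABF2_i)``
    (distinct variants), ``S4 = p12 * sum_i ABF1_i*ABF2_i``; ``S0 = 1``.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.size == 0:
        raise ValueError("lABF vectors must be equal-length and non-empty")
    s1 = logsumexp(l1)
    s2 = logsumexp(l2)
    s12 = logsumexp(l1 + l2)

    logS = np.full(5, -np.inf)
    logS[0] = 0.0
    logS[1] = np.log(priors.p1) + s1
    logS[2] = np.log(priors.p2) + s2
    # S3: cross terms minus the shared-SNP diagonal; exactly 0 for a
    # single-SNP region, clamped at 0 under floating cancellation
    if l1.size == 1 or s12 >= s1 + s2:
        diff = -np.inf
        if l1.size > 1:
            log.info("coloc_posterior: S3 clamped at 0 (floating cancellation)")
    else:
        diff = s1 + s2 + np.log1p(-np.exp(s12 - s1 - s2))
    if np.isfinite(diff):
        logS[3] = np.log(priors.p1) + np.log(priors.p2) + diff
    logS[4] = np.log(priors.p12) + s12

    denom = logsumexp(logS)
    pp = np.exp(logS - denom)
    return ColocResult(*[float(x) for x in pp], n_snps=int(l1.size))


def build_region(
    cpg_id: str,
    gene_id: str,
    meqtl_records: pd.DataFrame,
    eqtl_records: pd.DataFrame,
    center: int | None = None,
    window: int = 2_000_000,
    dnam_p: float = 1e-6,
    expr_p: float = 1e-4,
    filter_mode: str = "gate",
) -> tuple[pd.DataFrame | None, str]:
    """Assemble the per-SNP input table for one CpG-gene colocalization.

    Intersects the SNPs of the CpG's meQTL records and the gene's eQTL
    records within ``window`` of ``center`` (half-window on each side).  The
    region is eligible only if the methylation side has at least one SNP at
    ``p < dnam_p`` and the expression side one at ``p < expr_p``.  With
    ``filter_mode='gate'`` (default) the p-value filters gate eligibility
    only and all intersected SNPs enter the posterior computation; with
    ``'restrict'`` only filter-passing SNPs are retained.

    Returns ``(region_stats, reason)`` with ``region_stats=None`` and a
    skip reason when ineligible.
    """
    me = meqtl_records[meqtl_records["cpg_id"] == cpg_id] if "cpg_id" in meqtl_records else meqtl_records
    eq = eqtl_records[eqtl_records["gene_id"] == gene_id] if "gene_id" in eqtl_records else eqtl_records
    if center is not None:
        half = window // 2
        me = me[(me["snp_pos"] >= center - half) & (me["snp_pos"] <= center + half)]
        eq = eq[(eq["snp_pos"] >= center - half) & (eq["snp_pos"] <= center + half)]
    common = sorted(set(me["snp_id"]) & set(eq["snp_id"]))
    if not common:
        log.info("coloc region %s/%s skipped: empty intersection", cpg_id, gene_id)
        return None, "empty_intersection"
    me = me.set_index("snp_id").loc[common]
    eq = eq.set_index("snp_id").loc[common]
    if not (me["p"] < dnam_p).any():
        return None, "dnam_filter"
    if not (eq["p"] < expr_p).any():
        return None, "expr_filter"
    if filter_mode == "restrict":
        keep = (me["p"] < dnam_p) & (eq["p"] < expr_p)
        me, eq = me[keep], eq[keep]
    region = pd.DataFrame(
        {
            "snp_id": me.index,
            "beta1": me["beta"].to_numpy(),
            "se1": me["se"].to_numpy(),
            "beta2": eq["beta"].to_numpy(),
            "se2": eq["se"].to_numpy(),
            "maf": me["maf"].to_numpy() if "maf" in me else np.nan,
        }
    ).reset_index(drop=True)
    return region, "ok"


def call_colocalized(result: ColocResult, threshold: float = 0.80) -> bool:
    """Shared-causal-variant call: PP4 at or above the threshold (inclusive)."""
    return bool(result.pp4 >= threshold)
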