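"""Readers and writers for the pipeline's external formats.

Tabular data is TSV throughout (one header line, tab-delimited, '.' for
missing).  Genotypes are accepted either as VCF 4.2 with a ``DS`` FORMAT
field (parsed with cyvcf2) or as a sample-by-SNP dosage matrix TSV with a
SNP-map sidecar.  CpG and TSS annotations use BED (0-based half-open),
converted to 1-based point coordinates internally.  GWAS summary statistics
are TSV with columns snp_id, chrom, pos, effect_allele, other_allele, beta,
se, p, n.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from meqtlkit.synthetic import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_vcf",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_bed_points",
    "write_bed_points",
    "read_gwas",
    "output_header",
]

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as VCF 4.2 with a single FORMAT field ``DS``."""
    path = Path(path)
    samples = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the effect allele">\n')
        for chrom in dict.fromkeys(genotypes.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        dosage = genotypes.dosages.to_numpy()
        for j, (snp_id, row) in enumerate(genotypes.snp_map.iterrows()):
            vals = "\t".join(f"{d:.3f}" for d in dosage[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tDS\t{vals}\n"
            )


def read_genotypes(path, maf_min: float = 0.01, snp_map_path=None) -> GenotypeMatrix:
    """Load genotype dosages from VCF (DS field) or TSV matrix + SNP map.

    SNPs with realized MAF below ``maf_min`` are dropped (logged count).
    """
    path = Path(path)
    if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz"):
        gm = _read_vcf(path)
    else:
        if snp_map_path is None:
            raise FormatError("TSV genotype input requires a SNP-map sidecar")
        dosages = read_matrix_tsv(path)
        snp_map = pd.read_csv(snp_map_path, sep="\t", index_col=0)
        gm = GenotypeMatrix(dosages=dosages, snp_map=snp_map)
    af = gm.dosages.to_numpy().mean(axis=0) / 2.0
    maf = np.minimum(af, 1 - af)
    keep = maf >= maf_min
    dropped = int((~keep).sum())
    if dropped:
        log.info("read_genotypes: dropped %d SNPs with MAF < %g", dropped, maf_min)
    gm.snp_map = gm.snp_map[keep].copy()
    gm.snp_map["maf"] = maf[keep]
    gm.dosages = gm.dosages.loc[:, keep]
    return gm


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, chroms, pos, ref, alt, rows = [], [], [], [], [], []
    for i, var in enumerate(vcf):
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is None:
            raise FormatError(f"variant {var.ID or var.POS}: missing DS FORMAT field")
        rows.append(np.asarray(ds, dtype=float).ravel())
        snp_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0] if var.ALT else ".")
    dosages = pd.DataFrame(
        np.column_stack(rows) if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=snp_ids,
    )
    snp_map = pd.DataFrame(
        {"chrom": chroms, "pos": pos, "effect_allele": alt, "other_allele": ref,
         "maf": np.nan},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(dosages=dosages, snp_map=snp_map)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Sample-by-feature matrix TSV: first column sample ids, header row of
    feature ids; comment lines starting with '#' are ignored."""
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def write_matrix_tsv(df: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", na_rep=".")


def read_bed_points(path) -> pd.DataFrame:
    """BED intervals to 1-based point positions (interval start + 1).

    Returns a frame indexed by the BED name column with ``chrom`` and
    ``pos`` columns.
    """
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    return pd.DataFrame(
        {"chrom": bed["chrom"].to_numpy(), "pos": bed["start"].to_numpy() + 1},
        index=pd.Index(bed["name"], name="name"),
    )


def write_bed_points(points: pd.DataFrame, path, pos_col: str = "pos") -> None:
    """1-based point coordinates to single-base BED intervals [pos-1, pos)."""
    with open(path, "w") as fh:
        for name, row in points.iterrows():
            p = int(row[pos_col])
            fh.write(f"{row['chrom']}\t{p - 1}\t{p}\t{name}\n")


def read_gwas(path) -> pd.DataFrame:
    gwas = pd.read_csv(path, sep="\t", comment="#")
    required = {"snp_id", "effect_allele", "other_allele", "beta", "se", "p"}
    missing = required - set(gwas.columns)
    if missing:
        raise FormatError(f"GWAS summary file lacks columns: {sorted(missing)}")
    return gwas


def output_header(seed: int, config_repr: str = "") -> str:
    """Version/seed/config-hash comment line stamped on every output TSV."""
    from meqtlkit import __version__

    digest = hashlib.sha256(config_repr.encode()).hexdigest()[:12]
    return f"meqtlkit {__version__} seed={seed} config={digest}"
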