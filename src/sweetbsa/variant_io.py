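"""Reading and filtering of the pipeline's inputs.

The central in-memory container is the *allele-depth table*: a pandas
DataFrame with one row per biallelic variant and columns

    chrom, pos, ref, alt,
    p1_ref, p1_alt, p2_ref, p2_alt, high_ref, high_alt, low_ref, low_alt,
    variant_class ("SNP"/"InDel"), impact (HIGH/MODERATE/LOW/MODIFIER/NA)

Positions are 1-based and strictly increasing within a chromosome; read
depths are non-negative integers.  Coordinates are 1-based inclusive
throughout the package (VCF/GFF3 convention).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SAMPLES = ("P1", "P2", "HIGH_BULK", "LOW_BULK")
_SAMPLE_PREFIX = {"P1": "p1", "P2": "p2", "HIGH_BULK": "high", "LOW_BULK": "low"}

TABLE_COLUMNS = ["chrom", "pos", "ref", "alt",
                 "p1_ref", "p1_alt", "p2_ref", "p2_alt",
                 "high_ref", "high_alt", "low_ref", "low_alt",
                 "variant_class", "impact"]


def read_vcf(path: str | Path, samples: tuple[str, ...] = SAMPLES) -> pd.DataFrame:
    """Read a 4-sample VCF (two parents, two bulks) into an allele-depth table.

    Requires the FORMAT AD field for every sample.  Multiallelic records are
    dropped with a logged warning.  The per-variant impact is taken from the
    INFO key ``IMPACT`` if present, else from the first record of a
    SnpEff-style ``ANN`` field, else ``NA``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    missing = [s for s in samples if s not in vcf.samples]
    if missing:
        raise ValueError(f"sample(s) {missing} not found in {path}; "
                         f"VCF has {vcf.samples}")
    idx = [vcf.samples.index(s) for s in samples]

    rows: list[tuple] = []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"FORMAT AD missing at {v.CHROM}:{v.POS} for samples {samples}")
        ad = np.maximum(np.asarray(ad, dtype=np.int64), 0)  # cyvcf2 encodes missing as <0
        impact = v.INFO.get("IMPACT")
        if impact is None:
            ann = v.INFO.get("ANN")
            impact = ann.split("|")[2] if ann and ann.count("|") >= 2 else "NA"
        vtype = v.INFO.get("TYPE")
        if vtype is not None:
            vclass = "SNP" if str(vtype).upper() == "SNP" else "InDel"
        else:
            vclass = "SNP" if v.is_snp else "InDel"
        depths = [int(ad[i, j]) for i in idx for j in (0, 1)]
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], *depths, vclass, impact))
    vcf.close()
    if n_multi:
        log.warning("dropped %d multiallelic record(s) from %s", n_multi, path)

    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if table.empty:
        table = pd.DataFrame(columns=TABLE_COLUMNS)
    return table


def filter_loci(table: pd.DataFrame,
                min_depth_parent: int = 4,
                min_depth_bulk: int = 10,
                homozygosity_tol: float = 0.1,
                snp_only: bool = True) -> pd.DataFrame:
    """Quality and parental-polymorphism filter for genome-scan loci.

    A locus is retained when

    * both parents have depth >= ``min_depth_parent`` and each parent is
      effectively homozygous (minor-allele read fraction <=
      ``homozygosity_tol``) for a *different* allele,
    * both bulks have depth >= ``min_depth_bulk``,
    * ``variant_class == "SNP"`` when ``snp_only`` (InDels are kept out of the
      scans but remain available in the unfiltered table for the
      effective-variant interval filter).

    The filter is idempotent and preserves row order.  Per-rule removal
    counts are logged.
    """
    dp1 = table["p1_ref"] + table["p1_alt"]
    dp2 = table["p2_ref"] + table["p2_alt"]
    dph = table["high_ref"] + table["high_alt"]
    dpl = table["low_ref"] + table["low_alt"]

    ok_parent_depth = (dp1 >= min_depth_parent) & (dp2 >= min_depth_parent)
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(dp1 > 0, table["p1_alt"] / dp1, np.nan)
        f2 = np.where(dp2 > 0, table["p2_alt"] / dp2, np.nan)
    hom_ref1, hom_alt1 = f1 <= homozygosity_tol, f1 >= 1 - homozygosity_tol
    hom_ref2, hom_alt2 = f2 <= homozygosity_tol, f2 >= 1 - homozygosity_tol
    ok_poly = (hom_ref1 & hom_alt2) | (hom_alt1 & hom_ref2)
    ok_bulk_depth = (dph >= min_depth_bulk) & (dpl >= min_depth_bulk)
    ok_class = (table["variant_class"] == "SNP") if snp_only else np.ones(len(table), bool)

    keep = ok_parent_depth & ok_poly & ok_bulk_depth & ok_class
    log.info("filter_loci: %d in; removed %d (parent depth), %d (not a "
             "homozygous parental polymorphism), %d (bulk depth), %d "
             "(non-SNP); %d retained",
             len(table), int((~ok_parent_depth).sum()), int((~ok_poly).sum()),
             int((~ok_bulk_depth).sum()), int((~ok_class).sum()), int(keep.sum()))
    return table.loc[keep].reset_index(drop=True)


def sample_summaries(stats: pd.DataFrame) -> dict[str, float]:
    """Arithmetic means of per-sample sequencing summaries.

    ``stats`` needs a ``depth`` column (realized mean coverage per sample)
    and may carry a ``mapped_ratio`` column (percent).  Means are reported to
    2 decimal places (round-half-even).
    """
    if stats.empty:
        raise ValueError("no samples")
    out = {"mean_depth": round(float(stats["depth"].mean()), 2)}
    if "mapped_ratio" in stats.columns:
        out["mean_mapped_ratio"] = round(float(stats["mapped_ratio"].mean()), 2)
    return out


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 into a table of 1-based inclusive
    intervals (gene_id, chrom, start, end)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique")
    rows = [(g.id, g.seqid, g.start, g.end) for g in db.features_of_type("gene")]
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    if (genes["start"] > genes["end"]).any():
        raise ValueError("malformed gene interval with start > end")
    return genes


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype TSV: line_id, sugar_0h, sugar_8h, sugar_72h (mg/g)."""
    df = pd.read_csv(path, sep="\t")
    required = {"line_id", "sugar_0h", "sugar_72h"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene_id plus one FPKM column per tissue."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError("expression table needs a gene_id column")
    return df.set_index("gene_id")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """qPCR CT TSV: sample, gene, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "gene", "ct_target", "ct_reference"}
    if not required <= set(df.columns):
        raise ValueError(f"CT table needs columns {sorted(required)}")
    return df
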