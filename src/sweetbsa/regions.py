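"""Candidate-interval calling from thresholded genome scans.

Above-threshold loci are grouped into maximal runs (runs separated by more
than ``merge_gap`` bp stay separate), each run becomes a closed interval
[first locus, last locus], and intervals supported by fewer than
``min_loci`` above-threshold loci are discarded — a guard against isolated
noise peaks in sparse marker regions.  Retained intervals are then screened
for *effective variants* (any SNP or InDel with HIGH or MODERATE predicted
impact inside the interval), and finally the interval sets of the two scan
methods are intersected into consensus regions.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .bsa_stats import GenomeScan

log = logging.getLogger(__name__)


def span_mb(start: int, end: int) -> float:
    """Interval span (end - start) in megabases, 2 dp (round-half-even)."""
    return round((end - start) / 1e6, 2)


@dataclasses.dataclass
class CandidateRegion:
    """A candidate interval on one chromosome (1-based, closed)."""

    chrom: str
    start: int
    end: int
    method: str                       # "ED4", "Gprime" or "consensus"
    n_loci_above_threshold: int
    n_effective_variants: int | None = None
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")

    @property
    def span_mb(self) -> float:
        return span_mb(self.start, self.end)

    def overlaps(self, other: "CandidateRegion") -> bool:
        return (self.chrom == other.chrom
                and self.start <= other.end and other.start <= self.end)


def call_regions(scan: GenomeScan, merge_gap: int = 1_000_000,
                 min_loci: int = 10) -> list[CandidateRegion]:
    """Group above-threshold loci into candidate regions.

    Consecutive above-threshold loci are merged while separated by at most
    ``merge_gap`` bp; region boundaries are the first/last above-threshold
    locus positions.  Regions with fewer than ``min_loci`` supporting loci
    are discarded (logged).
    """
    regions: list[CandidateRegion] = []
    n_discarded = 0
    above = scan.loci.loc[scan.loci["above_threshold"]]
    for chrom, sub in above.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_gap) + 1
        for run in np.split(pos, breaks):
            if run.size >= min_loci:
                regions.append(CandidateRegion(
                    chrom=str(chrom), start=int(run[0]), end=int(run[-1]),
                    method=scan.method, n_loci_above_threshold=int(run.size)))
            else:
                n_discarded += 1
    if n_discarded:
        log.info("%s: discarded %d region(s) with fewer than %d "
                 "above-threshold loci", scan.method, n_discarded, min_loci)
    return regions


def annotate_effective_variants(regions: list[CandidateRegion],
                                table: pd.DataFrame) -> list[CandidateRegion]:
    """Record ``n_effective_variants`` on each region without filtering.

    Used for consensus intersections, which inherit effective-variant support
    from both parent region sets by construction and are therefore reported,
    not re-screened."""
    eff = table.loc[table["impact"].isin(("HIGH", "MODERATE"))]
    out = []
    for region in regions:
        n = int(((eff["chrom"] == region.chrom)
                 & (eff["pos"] >= region.start)
                 & (eff["pos"] <= region.end)).sum())
        out.append(dataclasses.replace(region, n_effective_variants=n))
    return out


def effective_variant_filter(regions: list[CandidateRegion],
                             table: pd.DataFrame) -> list[CandidateRegion]:
    """Retain only regions containing at least one effective variant.

    An effective variant is any SNP or InDel in the (unfiltered) allele-depth
    table with predicted impact HIGH or MODERATE whose position lies inside
    the closed region interval.  ``n_effective_variants`` is recorded on the
    retained regions.  The filter is idempotent.
    """
    eff = table.loc[table["impact"].isin(("HIGH", "MODERATE"))]
    retained: list[CandidateRegion] = []
    for region in regions:
        sub = eff.loc[(eff["chrom"] == region.chrom)
                      & (eff["pos"] >= region.start)
                      & (eff["pos"] <= region.end)]
        if len(sub) >= 1:
            retained.append(dataclasses.replace(region,
                                                n_effective_variants=len(sub)))
    if len(retained) < len(regions):
        log.info("effective-variant filter: removed %d of %d region(s) "
                 "lacking HIGH/MODERATE variants",
                 len(regions) - len(retained), len(regions))
    return retained


def intersect_regions(ed_regions: list[CandidateRegion],
                      gprime_regions: list[CandidateRegion]) -> list[CandidateRegion]:
    """Consensus regions: pairwise interval intersections of the two sets.

    For every overlapping pair on the same chromosome the intersection
    interval is emitted; regions supported by only one method are dropped.
    The supporting-locus count carried over is the smaller of the pair's.
    """
    consensus: list[CandidateRegion] = []
    for ed in ed_regions:
        for gp in gprime_regions:
            if ed.overlaps(gp):
                consensus.append(CandidateRegion(
                    chrom=ed.chrom,
                    start=max(ed.start, gp.start),
                    end=min(ed.end, gp.end),
                    method="consensus",
                    n_loci_above_threshold=min(ed.n_loci_above_threshold,
                                               gp.n_loci_above_threshold)))
    consensus.sort(key=lambda r: (r.chrom, r.start))
    return consensus


def count_genes(regions: list[CandidateRegion],
                genes: pd.DataFrame) -> list[CandidateRegion]:
    """Attach the genes overlapping each region (closed-interval overlap;
    any extent of overlap, including a single base pair, counts)."""
    out: list[CandidateRegion] = []
    for region in regions:
        hit = genes.loc[(genes["chrom"] == region.chrom)
                        & (genes["start"] <= region.end)
                        & (genes["end"] >= region.start)]
        out.append(dataclasses.replace(region, gene_ids=list(hit["gene_id"])))
    return out


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """BED-like summary table of a region list."""
    rows = [{
        "chrom": r.chrom, "start": r.start, "end": r.end, "method": r.method,
        "span_mb": r.span_mb, "n_loci": r.n_loci_above_threshold,
        "n_effective": r.n_effective_variants,
        "n_genes": len(r.gene_ids) if r.gene_ids is not None else None,
    } for r in regions]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "method",
                                       "span_mb", "n_loci", "n_effective",
                                       "n_genes"])


def write_regions(regions: list[CandidateRegion], path: str | Path) -> Path:
    path = Path(path)
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)
    return path
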