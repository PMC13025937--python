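"""End-to-end orchestration: simulate -> filter -> scan -> call -> report.

``RunConfig`` gathers every tunable of the pipeline; it is loaded from a
flat YAML file (unknown keys are rejected) and the resolved configuration is
written next to every run's outputs.  ``analyze`` is the in-memory core used
by the CLI, the test-suite and the acceptance script alike; the ``run_*``
functions add file I/O around it.

The run summary logs the locus/region funnel: loci in, loci surviving each
filter, regions called, regions removed by the >=10-locus and
effective-variant rules, and the final consensus list.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import candidates as cand
from . import regions as reg
from . import simulate as sim
from . import variant_io as vio
from .bsa_stats import GenomeScan, genome_scan

log = logging.getLogger(__name__)


def _default_sim() -> sim.SimConfig:
    # one major QTL (28 mg/g homozygote-class difference, the parental
    # contrast) mid-chromosome-4; baseline centres the population mean at
    # 13.79 mg/g given the expected QTL dosage of 1/2
    return sim.SimConfig(
        qtl_list=(sim.Qtl("chr4", 30_000_000, 28.0, "P2"),),
        baseline=13.79 - 14.0,
    )


@dataclasses.dataclass
class RunConfig:
    sim: sim.SimConfig = dataclasses.field(default_factory=_default_sim)
    min_depth_parent: int = 4
    min_depth_bulk: int = 10
    homozygosity_tol: float = 0.1
    snp_only: bool = True
    window_bp: int = 1_000_000
    step_bp: int = 50_000
    threshold_quantile: float = 0.995
    merge_gap_bp: int = 1_000_000
    min_loci_ed: int = 10
    min_loci_gprime: int = 1          # the >=10-locus rule is an ED-side guard
    expression_cutoff: float = 1.0
    expression_tissues: tuple[str, ...] = cand.DEFAULT_TISSUES
    keywords: tuple[str, ...] = cand.DEFAULT_KEYWORDS
    expression_path: str | None = None
    annotation_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        if "sim" in kwargs:
            sim_data = dict(kwargs["sim"])
            sim_known = {f.name for f in dataclasses.fields(sim.SimConfig)}
            sim_unknown = set(sim_data) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config key(s): {sorted(sim_unknown)}")
            qtls = tuple(sim.Qtl(**q) for q in sim_data.pop("qtl_list", ()))
            if "impact_probs" in sim_data:
                sim_data["impact_probs"] = tuple(sim_data["impact_probs"])
            sim_cfg = sim.SimConfig(**sim_data)
            sim_cfg = dataclasses.replace(sim_cfg, qtl_list=qtls)
            kwargs["sim"] = sim_cfg
        for key in ("expression_tissues", "keywords"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        data = dataclasses.asdict(self)
        data["sim"]["qtl_list"] = [dataclasses.asdict(q) for q in self.sim.qtl_list]
        data["sim"]["impact_probs"] = list(self.sim.impact_probs)
        data["expression_tissues"] = list(self.expression_tissues)
        data["keywords"] = list(self.keywords)
        path = Path(path)
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        return path


@dataclasses.dataclass
class AnalysisResult:
    truth: sim.SimTruth | None
    table: pd.DataFrame
    scan_loci: pd.DataFrame
    ed_scan: GenomeScan
    gprime_scan: GenomeScan
    ed_regions: list[reg.CandidateRegion]
    gprime_regions: list[reg.CandidateRegion]
    consensus: list[reg.CandidateRegion]
    funnel: dict[str, int]


def analyze(cfg: RunConfig, table: pd.DataFrame | None = None,
            truth: sim.SimTruth | None = None,
            genes: pd.DataFrame | None = None) -> AnalysisResult:
    """Run the association analysis on a simulated or provided variant table."""
    if table is None:
        truth, table = sim.simulate_experiment(cfg.sim)

    scan_loci = vio.filter_loci(table, cfg.min_depth_parent, cfg.min_depth_bulk,
                                cfg.homozygosity_tol, cfg.snp_only)
    ed_scan = genome_scan(scan_loci, "ED4", cfg.window_bp, cfg.step_bp,
                          cfg.threshold_quantile)
    gp_scan = genome_scan(scan_loci, "Gprime", cfg.window_bp, cfg.step_bp,
                          cfg.threshold_quantile)

    ed_called = reg.call_regions(ed_scan, cfg.merge_gap_bp, cfg.min_loci_ed)
    gp_called = reg.call_regions(gp_scan, cfg.merge_gap_bp, cfg.min_loci_gprime)
    ed_regions = reg.effective_variant_filter(ed_called, table)
    gp_regions = reg.effective_variant_filter(gp_called, table)
    # consensus regions inherit effective-variant support from both parent
    # region sets by construction; the intersection is not re-screened
    consensus = reg.intersect_regions(ed_regions, gp_regions)
    consensus = reg.annotate_effective_variants(consensus, table)
    if genes is not None:
        ed_regions = reg.count_genes(ed_regions, genes)
        gp_regions = reg.count_genes(gp_regions, genes)
        consensus = reg.count_genes(consensus, genes)

    funnel = {
        "loci_in_vcf": len(table),
        "scan_loci": len(scan_loci),
        "ed_loci_above_threshold": int(ed_scan.loci["above_threshold"].sum()),
        "gprime_loci_above_threshold": int(gp_scan.loci["above_threshold"].sum()),
        "ed_regions_called": len(ed_called),
        "ed_regions_retained": len(ed_regions),
        "gprime_regions_called": len(gp_called),
        "gprime_regions_retained": len(gp_regions),
        "consensus_regions": len(consensus),
    }
    log.info("funnel: %s", funnel)
    return AnalysisResult(truth=truth, table=table, scan_loci=scan_loci,
                          ed_scan=ed_scan, gprime_scan=gp_scan,
                          ed_regions=ed_regions, gprime_regions=gp_regions,
                          consensus=consensus, funnel=funnel)


# ---------------------------------------------------------------------------
# file-level stages


def run_simulate(cfg: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate an experiment and write VCF, GFF3, truth and phenotype files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth, table = sim.simulate_experiment(cfg.sim)
    paths = {
        "vcf": sim.write_vcf(table, cfg.sim, outdir / "variants.vcf"),
        "gff3": sim.write_gene_annotation(cfg.sim, outdir / "genes.gff3"),
        "phenotypes": sim.write_phenotype_table(truth, outdir / "phenotypes.tsv"),
        "config": cfg.to_yaml(outdir / "config.resolved.yaml"),
    }
    paths.update(sim.write_truth(truth, outdir))
    return paths


def _load_inputs(cfg: RunConfig, outdir: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    vcf = outdir / "variants.vcf"
    gff = outdir / "genes.gff3"
    if not vcf.exists():
        run_simulate(cfg, outdir)
    table = vio.read_vcf(vcf)
    genes = vio.read_gff3(gff)
    return table, genes


def run_scan(cfg: RunConfig, outdir: str | Path) -> AnalysisResult:
    """Scan stage: filter loci, compute both tracks, write TSVs and plots."""
    outdir = Path(outdir)
    table, genes = _load_inputs(cfg, outdir)
    result = analyze(cfg, table=table, genes=genes)
    result.ed_scan.write_track(outdir / "scan_ed4.tsv")
    result.gprime_scan.write_track(outdir / "scan_gprime.tsv")
    try:
        from .plotting import plot_scan
        plot_scan(result.ed_scan, outdir / "scan_ed4.png")
        plot_scan(result.gprime_scan, outdir / "scan_gprime.png")
    except Exception as exc:  # plotting must never sink a run
        log.warning("scan plots skipped: %s", exc)
    cfg.to_yaml(outdir / "config.resolved.yaml")
    return result


def run_call(cfg: RunConfig, outdir: str | Path) -> AnalysisResult:
    """Region stage: call, filter, intersect and annotate candidate regions."""
    outdir = Path(outdir)
    result = run_scan(cfg, outdir)
    reg.write_regions(result.ed_regions, outdir / "regions_ed4.tsv")
    reg.write_regions(result.gprime_regions, outdir / "regions_gprime.tsv")
    reg.write_regions(result.consensus, outdir / "regions_consensus.tsv")
    gene_rows = [{"chrom": r.chrom, "start": r.start, "end": r.end,
                  "gene_id": g}
                 for r in result.consensus for g in (r.gene_ids or [])]
    pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene_id"]) \
        .to_csv(outdir / "consensus_genes.tsv", sep="\t", index=False)
    return result


def _synthetic_gene_tables(gene_ids: list[str], seed: int
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic FPKM matrix and annotation table for the report stage.

    Stand-ins for a public expression atlas and a functional annotation:
    log-normal FPKM per tissue and mostly uninformative descriptions with a
    small sugar-metabolism fraction.  Clearly synthetic; used only when the
    run supplies no real tables.
    """
    import numpy as np

    rng = np.random.default_rng(seed + 3)
    tissues = ["seed", "endosperm", "leaf", "root"]
    fpkm = pd.DataFrame(
        rng.lognormal(mean=-0.5, sigma=1.5, size=(len(gene_ids), len(tissues))),
        index=pd.Index(gene_ids, name="gene_id"), columns=tissues).round(3)
    descs = np.where(rng.random(len(gene_ids)) < 0.05,
                     "FGGY carbohydrate kinase family protein (synthetic annotation)",
                     "hypothetical protein (synthetic annotation)")
    ann = pd.DataFrame({"gene_id": gene_ids, "description": descs})
    return fpkm, ann


def run_report(cfg: RunConfig, outdir: str | Path) -> pd.DataFrame:
    """Report stage: candidate-gene screens over the consensus regions plus a
    plain-text run summary."""
    outdir = Path(outdir)
    result = run_call(cfg, outdir)
    gene_ids = sorted({g for r in result.consensus for g in (r.gene_ids or [])})

    if cfg.expression_path:
        fpkm = vio.read_expression(cfg.expression_path)
    else:
        fpkm = None
    if cfg.annotation_path:
        ann = pd.read_csv(cfg.annotation_path, sep="\t")
    else:
        ann = None
    if fpkm is None or ann is None:
        syn_fpkm, syn_ann = _synthetic_gene_tables(gene_ids, cfg.sim.seed)
        fpkm = syn_fpkm if fpkm is None else fpkm
        ann = syn_ann if ann is None else ann

    expr = cand.expression_screen(gene_ids, fpkm, cfg.expression_tissues,
                                  cfg.expression_cutoff)
    kw = cand.keyword_screen(gene_ids, ann, cfg.keywords)
    report = expr.merge(kw, on="gene_id")
    report = cand.rank_candidates(report)
    report.to_csv(outdir / "candidate_report.tsv", sep="\t", index=False)

    lines = ["sweetbsa run summary", "====================", ""]
    for key, value in result.funnel.items():
        lines.append(f"{key:32s} {value}")
    lines.append("")
    lines.append("consensus regions:")
    for r in result.consensus:
        lines.append(f"  {r.chrom}:{r.start}-{r.end}  span {r.span_mb} Mb  "
                     f"loci {r.n_loci_above_threshold}  "
                     f"effective {r.n_effective_variants}  "
                     f"genes {len(r.gene_ids or [])}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return report


def run_all(cfg: RunConfig, outdir: str | Path) -> pd.DataFrame:
    Path(outdir).mkdir(parents=True, exist_ok=True)
    run_simulate(cfg, outdir)
    return run_report(cfg, outdir)
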