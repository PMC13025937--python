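"""Simulation of an F6 RIL bulked-segregant sequencing experiment.

The generator emulates the design behind a sweet-corn shelf-life mapping
study: two fully inbred parents (P1, P2) crossed to an F1, selfed for five
generations to give an F6 recombinant inbred line (RIL) population, a
quantitative phenotype (postharvest soluble-sugar reduction, mg per g fresh
weight over 0-72 h) controlled by zero or more additive QTLs plus Gaussian
noise, extreme-tail bulks of the population, and short-read allele depths
for the two parents (~10x) and the two bulks (~30x).

Two classes of variant are emitted:

* *segregating* loci — the parents carry different alleles; these are the
  loci a strict parental-polymorphism filter retains and the genome scans
  use.  The P1 allele is written as REF, the P2 allele as ALT.
* *background* loci — both parents share the same non-reference allele
  (variants against the reference genome that are monomorphic in the
  cross).  Real resequencing call sets are dominated by these; they fail
  the polymorphism filter but still carry functional-impact annotations and
  therefore matter for the effective-variant (HIGH/MODERATE) interval
  filter.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator``, so every output (including the VCF and GFF3
text) is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
SAMPLES = ("P1", "P2", "HIGH_BULK", "LOW_BULK")

_BASES = np.array(list("ACGT"))


@dataclasses.dataclass(frozen=True)
class Qtl:
    """One additive QTL.

    ``effect`` is the phenotype difference (mg/g) between the two homozygote
    classes; ``origin`` names the parent whose allele raises the trait.
    """

    chrom: str
    position_bp: int
    effect: float
    origin: str = "P2"


@dataclasses.dataclass
class SimConfig:
    n_lines: int = 204
    n_bulk: int = 30
    n_chromosomes: int = 10
    chrom_length_bp: int = 60_000_000
    n_snps: int = 650                 # segregating loci per chromosome
    n_background: int = 7500          # cross-monomorphic variants per chromosome
    n_selfing_generations: int = 5    # F6 = F1 + 5 selfing rounds
    cm_per_mb: float = 3.0            # 180 cM per 60 Mb chromosome (map conserved under physical scaling)
    qtl_list: tuple[Qtl, ...] = ()
    baseline: float = 13.79           # mg/g sugar-reduction intercept
    phenotype_noise_sd: float = 6.0   # mg/g
    content_0h_mean: float = 84.47    # mg/g soluble sugar at harvest
    content_0h_sd: float = 5.0
    parent_depth_mean: float = 10.0   # reads
    bulk_depth_mean: float = 30.0     # reads
    seq_error_rate: float = 0.001     # per-read allele flip probability
    indel_fraction: float = 0.1
    impact_probs: tuple[float, float, float, float] = (0.002, 0.01, 0.05, 0.938)
    seed: int = 0

    @property
    def chroms(self) -> list[str]:
        return [f"chr{i}" for i in range(1, self.n_chromosomes + 1)]

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_snps < 1:
            raise ValueError("need at least one chromosome and one locus")
        if self.n_lines < 1:
            raise ValueError("n_lines must be positive")
        if 2 * self.n_bulk > self.n_lines:
            raise ValueError("bulks may not overlap: 2*n_bulk must be <= n_lines")
        if abs(sum(self.impact_probs) - 1.0) > 1e-9:
            raise ValueError("impact_probs must sum to 1")
        if self.parent_depth_mean <= 0 or self.bulk_depth_mean <= 0:
            raise ValueError("sequencing depths must be positive")
        if not 0 <= self.indel_fraction <= 1:
            raise ValueError("indel_fraction must lie in [0, 1]")
        for q in self.qtl_list:
            if q.chrom not in self.chroms:
                raise ValueError(f"QTL chromosome {q.chrom!r} not simulated")
            if not 1 <= q.position_bp <= self.chrom_length_bp:
                raise ValueError("QTL position outside chromosome")
            if q.origin not in ("P1", "P2"):
                raise ValueError("QTL origin must be 'P1' or 'P2'")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``genotypes`` is (n_lines, n_loci) with codes 0 = P1 homozygote,
    1 = heterozygote, 2 = P2 homozygote, over the segregating loci listed in
    ``loci`` (columns ``chrom``, ``pos``).  ``bulk_membership`` is +1 for
    high-bulk lines, -1 for low-bulk lines, 0 otherwise.
    """

    config: SimConfig
    loci: pd.DataFrame
    genotypes: np.ndarray
    phenotypes: np.ndarray | None = None
    contents: pd.DataFrame | None = None
    bulk_membership: np.ndarray | None = None
    qtl_list: tuple[Qtl, ...] = ()


# ---------------------------------------------------------------------------
# genotypes


def _unique_sorted_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct 1-based positions, sorted, on a chromosome of given length."""
    if n > length:
        raise ValueError("more loci than base pairs")
    draw = n
    while True:
        pos = np.unique(rng.integers(1, length + 1, size=draw))
        if pos.size >= n:
            return np.sort(rng.choice(pos, size=n, replace=False))
        draw *= 2


def _switch_probabilities(loci: pd.DataFrame, cm_per_mb: float) -> np.ndarray:
    """Per-locus probability that a gamete switches parental phase.

    Haldane map: r = (1 - exp(-2d))/2 with d in Morgans between adjacent
    loci.  The first locus of each chromosome gets 0.5 (independent phase).
    """
    pos = loci["pos"].to_numpy()
    d_bp = np.diff(pos, prepend=pos[:1])
    d_m = d_bp * cm_per_mb / 1e6 / 100.0
    r = 0.5 * (1.0 - np.exp(-2.0 * d_m))
    first = np.r_[True, loci["chrom"].to_numpy()[1:] != loci["chrom"].to_numpy()[:-1]]
    r[first] = 0.5
    return r


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    switches = rng.random(hap_a.shape) < switch_p
    phase = np.cumsum(switches, axis=1) & 1
    return np.where(phase == 0, hap_a, hap_b).astype(np.uint8)


def simulate_ril_genotypes(config: SimConfig, rng: np.random.Generator | None = None) -> SimTruth:
    """Simulate F6 RIL genotypes at the segregating loci.

    Each line starts as an F1 (one haplotype from each parent) and is selfed
    ``n_selfing_generations`` times; each selfing draws two independent
    gametes with one Haldane-model recombination process per chromosome.
    Residual heterozygosity per locus is (1/2)^n_selfing_generations in
    expectation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    frames = []
    for chrom in config.chroms:
        pos = _unique_sorted_positions(rng, config.chrom_length_bp, config.n_snps)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    loci = pd.concat(frames, ignore_index=True)
    switch_p = _switch_probabilities(loci, config.cm_per_mb)

    n_loci = len(loci)
    hap_a = np.zeros((config.n_lines, n_loci), dtype=np.uint8)
    hap_b = np.ones((config.n_lines, n_loci), dtype=np.uint8)
    for _ in range(config.n_selfing_generations):
        hap_a, hap_b = (_meiosis(hap_a, hap_b, switch_p, rng),
                        _meiosis(hap_a, hap_b, switch_p, rng))
    genotypes = (hap_a + hap_b).astype(np.int8)
    return SimTruth(config=config, loci=loci, genotypes=genotypes,
                    qtl_list=config.qtl_list)


# ---------------------------------------------------------------------------
# phenotypes and bulks


def _snap_qtls(truth: SimTruth) -> tuple[tuple[Qtl, ...], list[int]]:
    """Snap each configured QTL to the nearest simulated locus."""
    snapped, idx = [], []
    loci = truth.loci
    for q in truth.config.qtl_list:
        on = loci.index[loci["chrom"] == q.chrom]
        if on.empty:
            raise ValueError(f"QTL chromosome {q.chrom!r} has no loci")
        j = on[np.argmin(np.abs(loci.loc[on, "pos"].to_numpy() - q.position_bp))]
        snapped.append(Qtl(q.chrom, int(loci.at[j, "pos"]), q.effect, q.origin))
        idx.append(int(j))
    return tuple(snapped), idx


def simulate_phenotypes(truth: SimTruth, rng: np.random.Generator | None = None) -> SimTruth:
    """Attach phenotypes: baseline + sum of QTL effect*dosage + Gaussian noise.

    Dosage of the trait-raising allele is 0 / 0.5 / 1 for the two homozygote
    classes and the heterozygote.  Also derives per-line soluble-sugar
    contents at 0/8/72 h: content_0h drawn around ``content_0h_mean``,
    content_72h = content_0h - reduction, content_8h on the way down
    (60% of the 72 h reduction realised by 8 h, matching the parental
    trajectory the phenotype emulates).
    """
    cfg = truth.config
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    qtls, idx = _snap_qtls(truth)
    pheno = np.full(cfg.n_lines, cfg.baseline, dtype=float)
    for q, j in zip(qtls, idx):
        dosage = truth.genotypes[:, j] / 2.0
        if q.origin == "P1":
            dosage = 1.0 - dosage
        pheno = pheno + q.effect * dosage
    if cfg.phenotype_noise_sd > 0:
        pheno = pheno + rng.normal(0.0, cfg.phenotype_noise_sd, cfg.n_lines)

    c0 = np.maximum(rng.normal(cfg.content_0h_mean, cfg.content_0h_sd, cfg.n_lines), 0.0)
    contents = pd.DataFrame({
        "line_id": [f"RIL{i + 1:03d}" for i in range(cfg.n_lines)],
        "sugar_0h": c0,
        "sugar_8h": c0 - 0.6 * pheno,
        "sugar_72h": c0 - pheno,
    })
    truth.qtl_list = qtls
    truth.phenotypes = pheno
    truth.contents = contents
    return truth


def select_bulks(phenotypes: np.ndarray, n_bulk: int) -> np.ndarray:
    """Extreme-tail bulk membership: +1 = high bulk, -1 = low bulk, 0 = neither.

    The high bulk holds the ``n_bulk`` largest sugar-reduction lines, the low
    bulk the smallest.  Ties are broken by line index (stable sort), so with
    all-equal phenotypes the first/last ``n_bulk`` lines by index are taken.
    """
    phenotypes = np.asarray(phenotypes, dtype=float)
    if 2 * n_bulk > phenotypes.size:
        raise ValueError("bulks may not overlap: 2*n_bulk must be <= number of lines")
    order = np.argsort(phenotypes, kind="stable")
    membership = np.zeros(phenotypes.size, dtype=np.int8)
    membership[order[:n_bulk]] = -1
    membership[order[-n_bulk:]] = 1
    return membership


# ---------------------------------------------------------------------------
# sequencing


def _random_alleles(rng: np.random.Generator, n: int, is_indel: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    ref = _BASES[rng.integers(0, 4, size=n)]
    shift = rng.integers(1, 4, size=n)
    alt = _BASES[(np.searchsorted(_BASES, ref) + shift) % 4]
    ins = _BASES[rng.integers(0, 4, size=n)]
    ref = ref.astype(object)
    alt = alt.astype(object)
    alt[is_indel] = ref[is_indel] + ins[is_indel]  # simple 1-bp insertions
    return ref.astype(str), alt.astype(str)


def _observed_alt_reads(rng, freq, depth, err):
    f_obs = freq * (1.0 - err) + (1.0 - freq) * err
    return rng.binomial(depth, f_obs)


def simulate_allele_depths(truth: SimTruth, rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Simulate read depths for P1, P2 and the two bulks at every variant.

    Segregating loci: the true bulk ALT (P2-allele) frequency is the mean
    allele dosage over the bulk members; read depth is Poisson per sample
    (``parent_depth_mean`` / ``bulk_depth_mean``) and ALT reads are Binomial
    in the error-adjusted frequency.  Background loci are fixed ALT in every
    sample.  Zero-depth loci are permitted and emitted; downstream filters
    handle them.
    """
    cfg = truth.config
    if truth.bulk_membership is None:
        raise ValueError("bulk membership not set; run select_bulks first")
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng

    high = truth.bulk_membership == 1
    low = truth.bulk_membership == -1
    dosage = truth.genotypes / 2.0
    seg = truth.loci.copy()
    seg["f_p1"] = 0.0
    seg["f_p2"] = 1.0
    seg["f_high"] = dosage[high].mean(axis=0)
    seg["f_low"] = dosage[low].mean(axis=0)
    seg["segregating"] = True

    frames = [seg]
    if cfg.n_background > 0:
        for chrom in cfg.chroms:
            taken = set(seg.loc[seg["chrom"] == chrom, "pos"])
            pos = _unique_sorted_positions(rng, cfg.chrom_length_bp,
                                           cfg.n_background + len(taken))
            pos = pos[~np.isin(pos, sorted(taken))][:cfg.n_background]
            frames.append(pd.DataFrame({
                "chrom": chrom, "pos": pos,
                "f_p1": 1.0, "f_p2": 1.0, "f_high": 1.0, "f_low": 1.0,
                "segregating": False,
            }))
    table = pd.concat(frames, ignore_index=True)
    order = {c: i for i, c in enumerate(cfg.chroms)}
    table = table.sort_values(["chrom", "pos"],
                              key=lambda s: s.map(order) if s.name == "chrom" else s,
                              kind="stable").reset_index(drop=True)

    n = len(table)
    is_indel = rng.random(n) < cfg.indel_fraction
    table["variant_class"] = np.where(is_indel, "InDel", "SNP")
    table["impact"] = rng.choice(IMPACT_LEVELS, size=n, p=cfg.impact_probs)
    ref, alt = _random_alleles(rng, n, is_indel)
    table["ref"], table["alt"] = ref, alt

    err = cfg.seq_error_rate
    for sample, mean, col in (("p1", cfg.parent_depth_mean, "f_p1"),
                              ("p2", cfg.parent_depth_mean, "f_p2"),
                              ("high", cfg.bulk_depth_mean, "f_high"),
                              ("low", cfg.bulk_depth_mean, "f_low")):
        depth = rng.poisson(mean, size=n)
        alt_reads = _observed_alt_reads(rng, table[col].to_numpy(), depth, err)
        table[f"{sample}_alt"] = alt_reads
        table[f"{sample}_ref"] = depth - alt_reads

    cols = ["chrom", "pos", "ref", "alt",
            "p1_ref", "p1_alt", "p2_ref", "p2_alt",
            "high_ref", "high_alt", "low_ref", "low_alt",
            "variant_class", "impact", "segregating"]
    return table[cols]


def simulate_experiment(config: SimConfig) -> tuple[SimTruth, pd.DataFrame]:
    """Full generator: genotypes -> phenotypes -> bulks -> allele depths."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_ril_genotypes(config, rng)
    truth = simulate_phenotypes(truth, rng)
    truth.bulk_membership = select_bulks(truth.phenotypes, config.n_bulk)
    table = simulate_allele_depths(truth, rng)
    return truth, table


# ---------------------------------------------------------------------------
# file output


def write_vcf(table: pd.DataFrame, config: SimConfig, path: str | Path) -> Path:
    """Write the allele-depth table as a VCF 4.2 with FORMAT AD for the four
    samples (P1, P2, HIGH_BULK, LOW_BULK) and INFO keys IMPACT and TYPE."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2",
             "##source=sweetbsa-simulator"]
    for chrom in config.chroms:
        lines.append(f"##contig=<ID={chrom},length={config.chrom_length_bp}>")
    lines += [
        '##INFO=<ID=IMPACT,Number=1,Type=String,Description="Predicted functional impact">',
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant class (SNP or INDEL)">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Read depths for ref and alt alleles">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(SAMPLES),
    ]
    body = []
    for row in table.itertuples(index=False):
        info = (f"IMPACT={row.impact};TYPE="
                f"{'INDEL' if row.variant_class == 'InDel' else 'SNP'}")
        body.append("\t".join([
            row.chrom, str(row.pos), ".", row.ref, row.alt, ".", "PASS", info, "AD",
            f"{row.p1_ref},{row.p1_alt}", f"{row.p2_ref},{row.p2_alt}",
            f"{row.high_ref},{row.high_alt}", f"{row.low_ref},{row.low_alt}",
        ]))
    path.write_text("\n".join(lines + body) + "\n")
    return path


def write_gene_annotation(config: SimConfig, path: str | Path,
                          gene_spacing: int = 40_000, gene_length: int = 3_000) -> Path:
    """Write a synthetic GFF3 of non-overlapping gene intervals tiled along
    each chromosome (default one 3 kb gene every 40 kb, ~25 genes/Mb)."""
    path = Path(path)
    lines = ["##gff-version 3"]
    for chrom in config.chroms:
        lines.append(f"##sequence-region {chrom} 1 {config.chrom_length_bp}")
    for chrom in config.chroms:
        start, i = 5_001, 1
        while start + gene_length - 1 <= config.chrom_length_bp:
            gid = f"SYNG_{chrom}_{i:05d}"
            lines.append("\t".join([
                chrom, "sweetbsa_sim", "gene", str(start),
                str(start + gene_length - 1), ".", "+", ".",
                f"ID={gid};Name={gid}",
            ]))
            start += gene_spacing
            i += 1
    path.write_text("\n".join(lines) + "\n")
    return path


def write_truth(truth: SimTruth, outdir: str | Path) -> dict[str, Path]:
    """Write ground-truth TSVs: genotypes, loci, phenotypes/bulks, QTLs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    loci = truth.loci.copy()
    paths["loci"] = outdir / "truth_loci.tsv"
    loci.to_csv(paths["loci"], sep="\t", index=False)

    geno = pd.DataFrame(truth.genotypes,
                        columns=[f"{c}:{p}" for c, p in
                                 zip(loci["chrom"], loci["pos"])])
    geno.insert(0, "line_id", [f"RIL{i + 1:03d}" for i in range(len(geno))])
    paths["genotypes"] = outdir / "truth_genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", index=False)

    if truth.phenotypes is not None:
        pheno = truth.contents.copy()
        pheno["sugar_reduction_0_72"] = truth.phenotypes
        if truth.bulk_membership is not None:
            pheno["bulk"] = np.select(
                [truth.bulk_membership == 1, truth.bulk_membership == -1],
                ["high", "low"], "none")
        paths["phenotypes"] = outdir / "truth_phenotypes.tsv"
        pheno.to_csv(paths["phenotypes"], sep="\t", index=False,
                     float_format="%.4f")

    qtl = pd.DataFrame([dataclasses.asdict(q) for q in truth.qtl_list],
                       columns=["chrom", "position_bp", "effect", "origin"])
    paths["qtl"] = outdir / "truth_qtl.tsv"
    qtl.to_csv(paths["qtl"], sep="\t", index=False)
    return paths


def write_phenotype_table(truth: SimTruth, path: str | Path) -> Path:
    """Phenotype input table (line_id, sugar_0h, sugar_8h, sugar_72h in mg/g)."""
    path = Path(path)
    truth.contents.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path
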