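"""Seeded synthetic data with planted methylation and expression effects.

The generator emulates the statistical structure of a two-genotype
(wild type vs. demethylase mutant) bisulfite + mRNA-seq study over a cohort
of NLR-like genes: a random genome at plant-like GC content, non-overlapping
gene models with clean upstream windows, per-cytosine reports with
beta-binomial methylation counts around region-level true methylation,
Poisson read coverage (zero-coverage cytosines are still written, as real
cytosine reports do), FPKM tables with multiplicative lognormal noise, and
replicate qPCR Ct tables.  Planted effects — mutant hypermethylation deltas
per (gene, region kind, context) and expression ratios per gene — are
recorded in a TruthTable for recovery testing.

Every generator is deterministic under a fixed seed: each step draws from its
own child stream of the configured seed, so outputs are byte-identical across
runs and independent of call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from nlr_methylome.exceptions import ConfigurationError
from nlr_methylome.levels import PROFILE_COLUMNS
from nlr_methylome.methylome import CONTEXTS, REPORT_COLUMNS, enumerate_cytosines
from nlr_methylome.regions import GeneModel, RegionSpec, derive_all_regions

# fixed child-stream keys so each generator is order-independent
_STREAM_GENOME = 0
_STREAM_ANNOTATION = 1
_STREAM_METH_WT = 2
_STREAM_METH_MUT = 3
_STREAM_EXPRESSION = 4
_STREAM_QPCR = 5

_BASELINE_DEFAULT = {"CG": 0.20, "CHG": 0.08, "CHH": 0.03}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic two-genotype experiment.

    Defaults describe a compact but realistic cohort: 144 NLR-like genes of
    1-3 kb on two 400-kb chromosomes at GC 0.36, context baselines
    CG 0.20 / CHG 0.08 / CHH 0.03 (high / mid / low), mean coverage 50 reads
    per cytosine and beta-binomial concentration kappa = 20 for
    within-region heterogeneity (kappa -> infinity recovers the binomial).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length_bp: int = 400_000
    n_genes: int = 144
    gene_length_range: tuple[int, int] = (1_000, 3_000)
    fraction_minus_strand: float = 0.5
    gc_fraction: float = 0.36
    min_intergenic_gap_bp: int = 600
    coverage_lambda: float = 50.0
    baseline_levels: dict[str, float] = field(default_factory=lambda: dict(_BASELINE_DEFAULT))
    dispersion_kappa: float = 20.0
    planted_dm: list[tuple[str, str, str, float]] = field(default_factory=list)
    planted_expr: list[tuple[str, float]] = field(default_factory=list)
    baseline_fpkm_median: float = 10.0
    fpkm_log_sigma: float = 1.0
    expr_noise_sigma: float = 0.05
    qpcr_replicates: int = 3
    qpcr_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.coverage_lambda <= 0:
            raise ConfigurationError("coverage_lambda must be positive")
        if not 0 <= self.gc_fraction <= 1:
            raise ConfigurationError("gc_fraction must lie in [0, 1]")
        if not 0 <= self.fraction_minus_strand <= 1:
            raise ConfigurationError("fraction_minus_strand must lie in [0, 1]")
        if self.dispersion_kappa <= 0:
            raise ConfigurationError("dispersion_kappa must be positive")
        for ctx, level in self.baseline_levels.items():
            if ctx not in CONTEXTS or not 0 <= level <= 1:
                raise ConfigurationError(f"bad baseline level {ctx}={level}")
        for gene_id, kind, ctx, delta_pp in self.planted_dm:
            if ctx not in CONTEXTS or kind not in ("UPR200", "UPR500", "GBR"):
                raise ConfigurationError(f"bad planted effect ({gene_id}, {kind}, {ctx})")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class TruthTable:
    """Planted ground truth: per-region true levels and per-gene ratios."""

    methylation: pd.DataFrame  # gene_id, kind, context, true_level_wt, true_level_mut
    expression: pd.DataFrame  # gene_id, true_ratio

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.methylation.to_csv(directory / "truth_methylation.tsv", sep="\t", index=False, na_rep="NA")
        self.expression.to_csv(directory / "truth_expression.tsv", sep="\t", index=False)


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random uppercase genome at the configured GC fraction."""
    rng = config.rng(_STREAM_GENOME)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for i in range(config.n_chromosomes):
        draw = rng.choice(bases, size=config.chrom_length_bp, p=probs)
        genome[f"chr{i + 1}"] = draw.tobytes().decode("ascii")
    return genome


def simulate_annotation(
    config: SimulationConfig, genome: dict[str, str]
) -> tuple[list[GeneModel], list[str]]:
    """Place non-overlapping genes with clean upstream windows.

    Genes are spread round-robin over chromosomes and separated by at least
    ``min_intergenic_gap_bp`` (>= 600 bp by default so UPR500 windows never
    touch a neighbouring gene); leftover space is distributed randomly among
    the gaps.  Returns the gene models and the NLR gene-ID list (the whole
    cohort by default).
    """
    rng = config.rng(_STREAM_ANNOTATION)
    chroms = list(genome)
    per_chrom: dict[str, int] = {c: 0 for c in chroms}
    for i in range(config.n_genes):
        per_chrom[chroms[i % len(chroms)]] += 1

    lo, hi = config.gene_length_range
    gap = config.min_intergenic_gap_bp
    genes: list[GeneModel] = []
    gene_no = 0
    for chrom in chroms:
        k = per_chrom[chrom]
        if k == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=k)
        needed = int(lengths.sum()) + (k + 1) * gap
        chrom_len = len(genome[chrom])
        if needed > chrom_len:
            raise ConfigurationError(
                f"cannot pack {k} genes of {lo}-{hi} bp with {gap}-bp gaps into {chrom_len} bp"
            )
        slack = chrom_len - needed
        extra = rng.multinomial(slack, np.full(k + 1, 1.0 / (k + 1)))
        pos = 0
        for j in range(k):
            pos += gap + int(extra[j])
            start = pos
            end = start + int(lengths[j])
            pos = end
            gene_no += 1
            strand = "-" if rng.random() < config.fraction_minus_strand else "+"
            genes.append(GeneModel(f"GENE{gene_no:04d}", chrom, start, end, strand))
    nlr_ids = [g.gene_id for g in genes]
    return genes, nlr_ids


def genes_to_gff3(genes: Sequence[GeneModel], chrom_lengths: dict[str, int]) -> str:
    lines = ["##gff-version 3"]
    for chrom, length in chrom_lengths.items():
        lines.append(f"##sequence-region {chrom} 1 {length}")
    for g in genes:
        lines.append(
            "\t".join(
                [g.chrom, "sim", "gene", str(g.start + 1), str(g.end), ".", g.strand, ".", f"ID={g.gene_id}"]
            )
        )
    return "\n".join(lines) + "\n"


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _position_truth(
    sites: pd.DataFrame,
    regions: Sequence[RegionSpec],
    config: SimulationConfig,
    mutant: bool,
) -> np.ndarray:
    """True methylation probability per cytosine site.

    Wild-type sites sit at the context baseline everywhere.  In the mutant,
    planted deltas raise (or lower) whole windows; where windows nest
    (UPR200 inside UPR500) the most specific planted window wins, applied by
    painting GBR, then UPR500, then UPR200.
    """
    baseline = np.array([config.baseline_levels.get(c, 0.0) for c in CONTEXTS])
    ctx_code = sites["context"].map({c: i for i, c in enumerate(CONTEXTS)}).to_numpy()
    truth = baseline[ctx_code].astype(float)
    if not mutant or not config.planted_dm:
        return truth

    by_key = {(r.gene_id, r.kind): r for r in regions}
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    for kind_pass in ("GBR", "UPR500", "UPR200"):
        for gene_id, kind, ctx, delta_pp in config.planted_dm:
            if kind != kind_pass:
                continue
            region = by_key.get((gene_id, kind))
            if region is None:
                raise ConfigurationError(f"planted effect at unknown region ({gene_id}, {kind})")
            mask = (
                (chrom_arr == region.chrom)
                & (pos_arr > region.start)
                & (pos_arr <= region.end)
                & (ctx_code == CONTEXTS.index(ctx))
            )
            truth[mask] = np.clip(config.baseline_levels.get(ctx, 0.0) + delta_pp / 100.0, 0.0, 1.0)
    return truth


def _sample_counts(
    truth: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Beta-binomial counts: p_i ~ Beta(p*kappa, (1-p)*kappa), cov ~ Poisson."""
    kappa = config.dispersion_kappa
    p_site = np.where(
        (truth > 0) & (truth < 1),
        rng.beta(np.clip(truth, 1e-9, None) * kappa, np.clip(1 - truth, 1e-9, None) * kappa),
        truth,
    )
    coverage = rng.poisson(config.coverage_lambda, size=truth.size)
    meth = rng.binomial(coverage, p_site)
    return meth, coverage - meth


def simulate_methylomes(
    config: SimulationConfig,
    genome: dict[str, str],
    genes: Sequence[GeneModel],
) -> tuple[dict[str, pd.DataFrame], TruthTable]:
    """Cytosine reports for wild type and mutant plus the truth table.

    The truth table's per-region levels are the per-site true probabilities
    averaged over the window's cytosines of each context — exactly the
    quantity the weighted methylation level estimates.
    """
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    regions = derive_all_regions(genes, chrom_lengths)
    sites = pd.concat(
        [enumerate_cytosines(seq, chrom) for chrom, seq in genome.items()], ignore_index=True
    )

    reports: dict[str, pd.DataFrame] = {}
    truth_by_genotype: dict[str, np.ndarray] = {}
    for genotype, mutant, stream in (("wt", False, _STREAM_METH_WT), ("mut", True, _STREAM_METH_MUT)):
        truth = _position_truth(sites, regions, config, mutant)
        truth_by_genotype[genotype] = truth
        meth, unmeth = _sample_counts(truth, config, config.rng(stream))
        report = sites[["chrom", "pos", "strand"]].copy()
        report["count_meth"] = meth
        report["count_unmeth"] = unmeth
        report["context"] = sites["context"]
        report["trinucleotide"] = sites["trinucleotide"]
        reports[genotype] = report[REPORT_COLUMNS]

    truth_rows = []
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    for region in regions:
        in_region = (
            (chrom_arr == region.chrom) & (pos_arr > region.start) & (pos_arr <= region.end)
        )
        for ctx in CONTEXTS:
            mask = in_region & (ctx_arr == ctx)
            if mask.any():
                wt_level = float(truth_by_genotype["wt"][mask].mean())
                mut_level = float(truth_by_genotype["mut"][mask].mean())
            else:
                wt_level = mut_level = float("nan")
            truth_rows.append((region.gene_id, region.kind, ctx, wt_level, mut_level))
    truth_meth = pd.DataFrame(
        truth_rows, columns=["gene_id", "kind", "context", "true_level_wt", "true_level_mut"]
    )
    truth_expr = _expression_truth(config, [g.gene_id for g in genes])
    return reports, TruthTable(methylation=truth_meth, expression=truth_expr)


def _expression_truth(config: SimulationConfig, gene_ids: Sequence[str]) -> pd.DataFrame:
    planted = dict(config.planted_expr)
    return pd.DataFrame(
        {"gene_id": list(gene_ids), "true_ratio": [planted.get(g, 1.0) for g in gene_ids]}
    )


def simulate_expression(
    config: SimulationConfig, gene_ids: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table (gene_id, fpkm_wt, fpkm_mut) and the truth ratios.

    Wild-type FPKMs are lognormal around the configured median; mutant FPKMs
    multiply in the planted ratio and lognormal noise of scale
    ``expr_noise_sigma``.
    """
    rng = config.rng(_STREAM_EXPRESSION)
    n = len(gene_ids)
    truth = _expression_truth(config, gene_ids)
    wt = rng.lognormal(mean=np.log(config.baseline_fpkm_median), sigma=config.fpkm_log_sigma, size=n)
    noise = (
        rng.lognormal(mean=0.0, sigma=config.expr_noise_sigma, size=n)
        if config.expr_noise_sigma > 0
        else np.ones(n)
    )
    mut = wt * truth["true_ratio"].to_numpy() * noise
    table = pd.DataFrame({"gene_id": list(gene_ids), "fpkm_wt": wt, "fpkm_mut": mut})
    return table, truth


def simulate_ct_table(
    config: SimulationConfig, transcripts: Sequence[tuple[str, float]]
) -> pd.DataFrame:
    """Replicate qPCR Ct rows for transcripts with known true fold changes.

    The reference gene sits at Ct 20 in both conditions; the target sits at
    Ct 25 in the control and shifts by -log2(fold) in the test condition.
    Gaussian cycle noise of sd ``qpcr_noise_sd`` is added per replicate.
    """
    rng = config.rng(_STREAM_QPCR)
    rows = []
    for transcript_id, fold in transcripts:
        if fold <= 0:
            raise ConfigurationError(f"fold change must be positive for {transcript_id}")
        means = {
            ("control", "reference"): 20.0,
            ("test", "reference"): 20.0,
            ("control", "target"): 25.0,
            ("test", "target"): 25.0 - float(np.log2(fold)),
        }
        for (condition, role), mean in means.items():
            for rep in range(1, config.qpcr_replicates + 1):
                ct = mean + rng.normal(0.0, config.qpcr_noise_sd)
                rows.append((transcript_id, condition, role, rep, round(float(ct), 4)))
    return pd.DataFrame(rows, columns=["transcript_id", "condition", "role", "replicate", "ct"])


@dataclass
class SyntheticStudy:
    """Everything one simulated experiment produces, in memory."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    nlr_ids: list[str]
    regions: list[RegionSpec]
    reports: dict[str, pd.DataFrame]
    truth: TruthTable
    fpkm_table: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Run every generator for one config (genome through expression)."""
    genome = simulate_genome(config)
    genes, nlr_ids = simulate_annotation(config, genome)
    regions = derive_all_regions(genes, {c: len(s) for c, s in genome.items()})
    reports, truth = simulate_methylomes(config, genome, genes)
    fpkm_table, _ = simulate_expression(config, nlr_ids)
    return SyntheticStudy(config, genome, genes, nlr_ids, regions, reports, truth, fpkm_table)


def write_study(study: SyntheticStudy, directory: str | Path) -> None:
    """Write FASTA, GFF3, gene list, cytosine reports, FPKM table and truth."""
    from nlr_methylome.methylome import write_cytosine_report

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_fasta(study.genome, directory / "genome.fa")
    (directory / "annotation.gff3").write_text(genes_to_gff3(study.genes, study.chrom_lengths))
    (directory / "nlr_genes.txt").write_text("".join(f"{g}\n" for g in study.nlr_ids))
    for genotype, report in study.reports.items():
        write_cytosine_report(report, directory / f"cytosine_report_{genotype}.tsv")
    study.fpkm_table.to_csv(directory / "fpkm.tsv", sep="\t", index=False, float_format="%.6g")
    study.truth.write(directory)
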