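"""Synthetic-study generators: determinism, packing, planted truth."""

import numpy as np
import pandas as pd
import pytest

from nlr_methylome.exceptions import ConfigurationError
from nlr_methylome.expression import classify_expression_table
from nlr_methylome.methylome import call_context
from nlr_methylome.simulate import (
    SimulationConfig,
    genes_to_gff3,
    simulate_annotation,
    simulate_ct_table,
    simulate_expression,
    simulate_genome,
    simulate_methylomes,
    simulate_study,
    write_study,
)
from tests.conftest import small_config


def test_generators_are_deterministic_per_seed(tmp_path):
    a = simulate_study(small_config(seed=3))
    b = simulate_study(small_config(seed=3))
    assert a.genome == b.genome
    assert a.genes == b.genes
    for genotype in ("wt", "mut"):
        pd.testing.assert_frame_equal(a.reports[genotype], b.reports[genotype])
    pd.testing.assert_frame_equal(a.fpkm_table, b.fpkm_table)
    # and a different seed actually changes the data
    c = simulate_study(small_config(seed=4))
    assert c.genome != a.genome


def test_written_outputs_are_byte_identical_under_a_repeated_seed(tmp_path):
    dirs = []
    for name in ("run1", "run2"):
        out = tmp_path / name
        write_study(simulate_study(small_config(seed=5)), out)
        dirs.append(out)
    files = sorted(p.name for p in dirs[0].iterdir())
    assert "cytosine_report_wt.tsv" in files and "genome.fa" in files
    for name in files:
        assert (dirs[0] / name).read_bytes() == (dirs[1] / name).read_bytes()


def test_genome_respects_gc_fraction_limits():
    config = small_config(gc_fraction=0.0)
    genome = simulate_genome(config)
    assert set("".join(genome.values())) <= {"A", "T"}
    assert all(len(seq) == config.chrom_length_bp for seq in genome.values())
    assert len(genome) == config.n_chromosomes


def test_annotation_packs_genes_with_clean_gaps():
    config = small_config()
    genome = simulate_genome(config)
    genes, nlr_ids = simulate_annotation(config, genome)
    assert len(genes) == config.n_genes
    assert nlr_ids == [g.gene_id for g in genes]
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom_genes in by_chrom.values():
        chrom_genes.sort(key=lambda g: g.start)
        assert chrom_genes[0].start >= config.min_intergenic_gap_bp
        for left, right in zip(chrom_genes, chrom_genes[1:]):
            assert right.start - left.end >= config.min_intergenic_gap_bp


def test_all_plus_when_minus_fraction_zero():
    config = small_config(fraction_minus_strand=0.0)
    genes, _ = simulate_annotation(config, simulate_genome(config))
    assert all(g.strand == "+" for g in genes)


def test_infeasible_packing_is_a_configuration_error():
    config = small_config(n_genes=60)  # 60 kb of genes into 30 kb
    with pytest.raises(ConfigurationError):
        simulate_annotation(config, simulate_genome(config))


def test_gff_roundtrips_through_the_parser():
    import io

    from nlr_methylome.regions import load_gene_models

    config = small_config()
    genome = simulate_genome(config)
    genes, _ = simulate_annotation(config, genome)
    text = genes_to_gff3(genes, {c: len(s) for c, s in genome.items()})
    parsed = load_gene_models(io.StringIO(text))
    assert parsed == genes


def test_report_contexts_agree_with_the_genome(small_study):
    report = small_study.reports["wt"]
    sample = report.sample(n=200, random_state=0)
    for row in sample.itertuples():
        assert call_context(small_study.genome, row.chrom, row.pos, row.strand) == row.context


def test_planted_deltas_enter_the_truth_table():
    config = small_config()
    genome = simulate_genome(config)
    genes, _ = simulate_annotation(config, genome)
    target = genes[0].gene_id
    config = small_config(planted_dm=[(target, "UPR500", "CG", 40.0)])
    _, truth = simulate_methylomes(config, genome, genes)
    tm = truth.methylation.set_index(["gene_id", "kind", "context"])
    baseline = config.baseline_levels["CG"]
    assert tm.loc[(target, "UPR500", "CG"), "true_level_mut"] == pytest.approx(baseline + 0.4)
    assert tm.loc[(target, "UPR500", "CG"), "true_level_wt"] == pytest.approx(baseline)
    # the 200-bp window nests inside the planted 500-bp window
    assert tm.loc[(target, "UPR200", "CG"), "true_level_mut"] == pytest.approx(baseline + 0.4)
    # other contexts and the gene body stay at baseline
    assert tm.loc[(target, "UPR500", "CHG"), "true_level_mut"] == pytest.approx(
        config.baseline_levels["CHG"]
    )
    assert tm.loc[(target, "GBR", "CG"), "true_level_mut"] == pytest.approx(baseline)
    untouched = tm.loc[(genes[1].gene_id, "UPR500", "CG")]
    assert untouched["true_level_mut"] == pytest.approx(baseline)


def test_planted_effect_at_unknown_gene_is_rejected():
    config = small_config()
    genome = simulate_genome(config)
    genes, _ = simulate_annotation(config, genome)
    bad = small_config(planted_dm=[("NOPE", "UPR500", "CG", 40.0)])
    with pytest.raises(ConfigurationError):
        simulate_methylomes(bad, genome, genes)


def test_zero_coverage_cytosines_are_written():
    study = simulate_study(small_config(coverage_lambda=1.5))
    report = study.reports["wt"]
    coverage = report["count_meth"] + report["count_unmeth"]
    assert (coverage == 0).any()
    # the coverage filter, not the writer, removes them
    from nlr_methylome.methylome import filter_by_coverage

    assert len(filter_by_coverage(report)) < len(report)


def test_expression_planting_without_noise_is_exact():
    gene_ids = [f"G{i}" for i in range(10)]
    config = SimulationConfig(seed=1, planted_expr=[("G3", 1.97)], expr_noise_sigma=0.0)
    table, truth = simulate_expression(config, gene_ids)
    classified = classify_expression_table(table, min_fpkm=0.0)
    by_gene = dict(zip(classified["gene_id"], classified["change"]))
    assert by_gene["G3"] == "up"
    assert all(v == "unchanged" for g, v in by_gene.items() if g != "G3")
    ratio = table.set_index("gene_id").eval("fpkm_mut / fpkm_wt")
    assert ratio["G3"] == pytest.approx(1.97)
    assert truth.set_index("gene_id")["true_ratio"]["G3"] == 1.97


def test_ct_table_recovers_planted_folds_without_noise():
    from nlr_methylome.expression import ddct_table, read_ct_table
    import io

    config = SimulationConfig(seed=1, qpcr_noise_sd=0.0)
    table = simulate_ct_table(config, [("tx_down", 0.5), ("tx_up", 4.0)])
    assert len(table) == 2 * 4 * config.qpcr_replicates
    csv = io.StringIO(table.to_csv(index=False))
    folds = ddct_table(read_ct_table(csv)).set_index("transcript_id")["fold_change"]
    assert folds["tx_down"] == pytest.approx(0.5)
    assert folds["tx_up"] == pytest.approx(4.0)
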