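"""Coverage-filter both genotypes' cytosine reports and profile every region.

Reads the raw study (from scratch/study/ if script 01 ran, otherwise
regenerated from the seed), applies the >=4-read coverage filter and writes
one long-format weighted-level table per genotype under results/.
"""

import pandas as pd

from common import RESULTS, SCRATCH, get_study

from nlr_methylome.levels import profile_genome, write_profile
from nlr_methylome.methylome import filter_by_coverage, read_cytosine_report
from nlr_methylome.regions import derive_all_regions, load_gene_models


def load_inputs():
    gff = SCRATCH / "annotation.gff3"
    if gff.exists():
        with open(gff) as fh:
            genes = load_gene_models(fh)
        lengths = _pragma_lengths(gff)
        regions = derive_all_regions(genes, lengths)
        reports = {
            genotype: read_cytosine_report(SCRATCH / f"cytosine_report_{genotype}.tsv")
            for genotype in ("wt", "mut")
        }
        return regions, reports
    study = get_study()
    return study.regions, study.reports


def _pragma_lengths(gff):
    lengths = {}
    for line in open(gff):
        if line.startswith("##sequence-region"):
            _, chrom, _, end = line.split()[:4]
            lengths[chrom] = int(end)
    return lengths


def main() -> None:
    regions, reports = load_inputs()
    RESULTS.mkdir(exist_ok=True)
    for genotype, report in reports.items():
        covered = filter_by_coverage(report, min_cov=4)
        profile = profile_genome(covered, regions)
        write_profile(profile, RESULTS / f"methylation_profile_{genotype}.tsv")
        kept = 100 * len(covered) / len(report)
        print(f"{genotype}: {kept:.1f}% of cytosines pass the coverage filter")
        cg = profile.loc[profile["context"] == "CG"].groupby("kind")["level"].mean()
        print(
            f"{genotype}: mean CG level UPR200 {cg['UPR200']:.3f}, "
            f"UPR500 {cg['UPR500']:.3f}, GBR {cg['GBR']:.3f}"
        )
    print(f"profiles written to {RESULTS}")


if __name__ == "__main__":
    main()
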