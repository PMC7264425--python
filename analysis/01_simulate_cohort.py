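"""Simulate the two-genotype NLR cohort and write its raw inputs.

Writes the genome FASTA, GFF3 annotation, NLR gene list, per-genotype
cytosine reports, FPKM table and the planted-truth tables under
scratch/study/ (raw data) and copies the truth tables to results/ so the
downstream scripts' recoveries can be checked against them.
"""

import shutil

from common import RESULTS, SCRATCH, get_study, study_config

from nlr_methylome.simulate import write_study


def main() -> None:
    config = study_config()
    study = get_study()
    write_study(study, SCRATCH)
    RESULTS.mkdir(exist_ok=True)
    for name in ("truth_methylation.tsv", "truth_expression.tsv"):
        shutil.copy(SCRATCH / name, RESULTS / name)

    n_sites = len(study.reports["wt"])
    print(f"simulated {len(study.genes)} genes on {len(study.genome)} chromosomes")
    print(f"{n_sites} strand-specific cytosines per genotype report")
    print(f"planted effects: {len(config.planted_dm)} methylation, {len(config.planted_expr)} expression")
    print(f"raw study written to {SCRATCH}")


if __name__ == "__main__":
    main()
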