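"""Classify mutant-vs-wild-type expression changes and qPCR fold changes.

Applies the expressed-gene filter (>=1 FPKM in at least one genotype) and
the 1.1x / 0.9x ratio rule to the study's FPKM table, then quantifies a
small qPCR panel with the comparative-Ct method, and checks both against the
planted truth.
"""

import io

import pandas as pd

from common import RESULTS, SCRATCH, get_study, planted_sets, study_config

from nlr_methylome.expression import classify_expression_table, ddct_table, read_ct_table
from nlr_methylome.pipeline import expression_recovery
from nlr_methylome.simulate import simulate_ct_table


def main() -> None:
    fpkm_path = SCRATCH / "fpkm.tsv"
    table = (
        pd.read_csv(fpkm_path, sep="\t") if fpkm_path.exists() else get_study().fpkm_table
    )
    classified = classify_expression_table(table)
    classified.to_csv(
        RESULTS / "expression_changes.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    print(classified["change"].value_counts().to_string())

    config = study_config()
    planted = planted_sets(config)
    up = expression_recovery(table, planted["expr_up"])
    print(f"induced genes recovered as up: recall {up['recall']:.2f} (n={up['n_eligible']})")
    down_sub = classified.loc[classified["gene_id"].isin(planted["expr_down"])]
    n_down = int((down_sub["change"] == "down").sum())
    print(f"repressed genes recovered as down: {n_down}/{len(planted['expr_down'])}")

    # qPCR panel: two repressed transcripts, one unchanged, one induced
    panel = [("tx_half", 0.5), ("tx_same", 1.0), ("tx_quad", 4.0)]
    ct = simulate_ct_table(config, panel)
    folds = ddct_table(read_ct_table(io.StringIO(ct.to_csv(index=False))))
    folds.to_csv(RESULTS / "qpcr_folds.tsv", sep="\t", index=False, float_format="%.4f")
    for row in folds.itertuples():
        print(f"{row.transcript_id}: 2^-ddCt fold change {row.fold_change:.3f}")
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
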