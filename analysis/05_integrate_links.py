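"""Link differential-methylation calls to expression changes.

Builds the UPR500/CG and GBR/CG link tables (negative = hypermethylated and
repressed or hypomethylated and induced), and partitions genes by direction
agreement against a second, independently seeded mutant — the analogue of
asking which genes respond the same way in two different demethylase
mutants.
"""

import pandas as pd

from common import RESULTS, get_study, study_config

from nlr_methylome.expression import classify_expression_table
from nlr_methylome.integrate import consistent_direction_genes, link_summary, methylation_expression_links
from nlr_methylome.simulate import simulate_expression


def main() -> None:
    comparison = pd.read_csv(RESULTS / "dm_calls.tsv", sep="\t", na_values=["NA"])
    classified = pd.read_csv(RESULTS / "expression_changes.tsv", sep="\t", na_values=["NA"])
    expr_changes = dict(zip(classified["gene_id"], classified["change"]))

    for kind in ("UPR500", "GBR"):
        sub = comparison.loc[(comparison["kind"] == kind) & (comparison["context"] == "CG")]
        dm_calls = dict(zip(sub["gene_id"], sub["call"]))
        links, counts = methylation_expression_links(dm_calls, expr_changes, kind, "CG")
        links.to_csv(RESULTS / f"links_{kind.lower()}_cg.tsv", sep="\t", index=False)
        summary = link_summary(links)
        negative = int(summary.loc[summary["link"] == "negative", "n_genes"].iloc[0])
        positive = int(summary.loc[summary["link"] == "positive", "n_genes"].iloc[0])
        print(f"{kind} CG: {negative} negative / {positive} positive links over {counts['shared']} genes")

    # second mutant: same cohort, independently drawn expression effects
    config = study_config()
    second = study_config(seed=config.seed + 1)
    gene_ids = list(classified["gene_id"])
    table2, _ = simulate_expression(second, gene_ids)
    changes2 = classify_expression_table(table2)
    sets = consistent_direction_genes(
        expr_changes, dict(zip(changes2["gene_id"], changes2["change"]))
    )
    pd.DataFrame(
        {"set": list(sets), "n_genes": [len(v) for v in sets.values()],
         "genes": [",".join(sorted(v)) for v in sets.values()]}
    ).to_csv(RESULTS / "cross_mutant_consistency.tsv", sep="\t", index=False)
    print(
        "cross-mutant direction agreement: "
        + ", ".join(f"{k}={len(v)}" for k, v in sets.items())
    )
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
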