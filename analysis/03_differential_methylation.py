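"""Call hyper/hypomethylated regions and summarise group structure.

Joins the two genotype profiles from script 02, calls differential
methylation (10 pp for upstream windows, 5 pp for gene bodies), writes the
comparison table, per-kind group-1/group-2 proportions and the CG heatmap
matrices, and checks the calls against the planted truth.
"""

import pandas as pd

from common import RESULTS, SCRATCH, planted_sets, study_config

from nlr_methylome.compare import compare_profiles, group_proportions, heatmap_matrix, plot_heatmap
from nlr_methylome.levels import read_profile
from nlr_methylome.pipeline import dm_recovery


def main() -> None:
    wt = read_profile(RESULTS / "methylation_profile_wt.tsv")
    mut = read_profile(RESULTS / "methylation_profile_mut.tsv")
    comparison = compare_profiles(wt, mut)
    comparison.to_csv(
        RESULTS / "dm_calls.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )
    counts = comparison.groupby(["kind", "context"])["call"].value_counts().unstack(fill_value=0)
    print(counts.loc[[("UPR200", "CG"), ("UPR500", "CG"), ("GBR", "CG")]])

    rows = []
    for genotype, profile in (("wt", wt), ("mut", mut)):
        for kind in ("UPR200", "UPR500", "GBR"):
            sub = profile.loc[(profile["kind"] == kind) & (profile["context"] == "CG"), "level"]
            props = group_proportions(sub)
            rows.append((genotype, kind, props["group1_frac"], props["group2_frac"], props["n_defined"]))
    pd.DataFrame(
        rows, columns=["genotype", "kind", "group1_frac", "group2_frac", "n_defined"]
    ).to_csv(RESULTS / "group_proportions.tsv", sep="\t", index=False, float_format="%.4f")

    for context in ("CG", "CHG", "CHH"):
        matrix = heatmap_matrix(wt, mut, "UPR500", context)
        matrix.to_csv(RESULTS / f"heatmap_upr500_{context.lower()}.tsv", sep="\t", na_rep="NA")
    figures = SCRATCH.parent / "figures"
    figures.mkdir(parents=True, exist_ok=True)
    plot_heatmap(
        heatmap_matrix(wt, mut, "UPR500", "CG"), figures / "heatmap_upr500_cg.png",
        title="UPR500 CG levels",
    )

    config = study_config()
    planted = planted_sets(config)["dm"]
    # a UPR500 effect also covers the nested UPR200 window, and a UPR200
    # effect dilutes into its enclosing UPR500 window
    nested = {(g, "UPR200", c) for g, k, c in planted if k == "UPR500"}
    diluted = {(g, "UPR500", c) for g, k, c in planted if k == "UPR200"}
    strata = [
        ("UPR500", "hyper", {k for k in planted if k[1] == "UPR500"}, diluted),
        ("UPR200", "hyper", nested, {k for k in planted if k[1] == "UPR200"}),
        ("UPR200", "hypo", {k for k in planted if k[1] == "UPR200"}, nested),
        ("GBR", "hyper", {k for k in planted if k[1] == "GBR"}, set()),
    ]
    for kind, direction, stratum, exclude in strata:
        rec = dm_recovery(comparison, stratum, kind, "CG", direction, exclude)
        print(
            f"{kind} CG {direction}: recall {rec['recall']:.2f} "
            f"(n={rec['n_planted']}), FPR {rec['fpr']:.3f} (n={rec['n_null']})"
        )
    print(f"tables written to {RESULTS}")


if __name__ == "__main__":
    main()
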