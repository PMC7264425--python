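"""Cross-genotype consistency sets and methylation-expression link tables.

A link is "negative" when hypermethylation coincides with downregulation (or
hypomethylation with upregulation), "positive" when the directions agree, and
"none" otherwise.  Links are evaluated for one (region kind, context) pair at
a time — upstream-window and gene-body links are biologically distinct and
are never aggregated.  Gene universes are intersected, never imputed; the
number of genes dropped from either side is reported alongside.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

LINK_COLUMNS = ["gene_id", "kind", "context", "dm_call", "expr_change", "link"]


def consistent_direction_genes(
    labels_mut1: Mapping[str, str],
    labels_mut2: Mapping[str, str],
) -> dict[str, set[str]]:
    """Partition genes by direction agreement across two mutants.

    up_both / down_both collect genes labelled "up" (resp. "down") in both
    maps; discordant collects genes called up in one and down in the other;
    everything else over the union universe (unchanged, not_expressed,
    undefined, or missing from one map) lands in other.
    """
    universe = set(labels_mut1) | set(labels_mut2)
    out: dict[str, set[str]] = {"up_both": set(), "down_both": set(), "discordant": set(), "other": set()}
    for gene in universe:
        a = labels_mut1.get(gene)
        b = labels_mut2.get(gene)
        if a == "up" and b == "up":
            out["up_both"].add(gene)
        elif a == "down" and b == "down":
            out["down_both"].add(gene)
        elif {a, b} == {"up", "down"}:
            out["discordant"].add(gene)
        else:
            out["other"].add(gene)
    return out


def link_label(dm_call: str, expr_change: str) -> str:
    if (dm_call == "hyper" and expr_change == "down") or (dm_call == "hypo" and expr_change == "up"):
        return "negative"
    if (dm_call == "hyper" and expr_change == "up") or (dm_call == "hypo" and expr_change == "down"):
        return "positive"
    return "none"


def methylation_expression_links(
    dm_calls: Mapping[str, str],
    expr_changes: Mapping[str, str],
    kind: str,
    context: str,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One LinkRecord per gene present in both inputs.

    Returns the link table and a sidecar count of genes present on only one
    side (``dm_only`` / ``expr_only``) plus the shared count.
    """
    shared = [g for g in dm_calls if g in expr_changes]
    table = pd.DataFrame(
        {
            "gene_id": shared,
            "kind": kind,
            "context": context,
            "dm_call": [dm_calls[g] for g in shared],
            "expr_change": [expr_changes[g] for g in shared],
        }
    )
    table["link"] = [link_label(d, e) for d, e in zip(table["dm_call"], table["expr_change"])]
    counts = {
        "shared": len(shared),
        "dm_only": len(set(dm_calls) - set(expr_changes)),
        "expr_only": len(set(expr_changes) - set(dm_calls)),
    }
    return table[LINK_COLUMNS], counts


def link_summary(links: pd.DataFrame) -> pd.DataFrame:
    """Set sizes by link label (negative / positive / none)."""
    counts = links["link"].value_counts()
    return pd.DataFrame(
        {"link": ["negative", "positive", "none"],
         "n_genes": [int(counts.get(k, 0)) for k in ("negative", "positive", "none")]}
    )
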