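"""Mutant-versus-wild-type methylation comparison.

Genes are binned by CG level into group 1 (level > 0.1) and group 2
(level <= 0.1; the boundary itself falls in group 2 since group 1 is defined
strictly).  Differential calls use absolute percentage-point deltas,
100 x (mutant - wild type), with inclusive thresholds: the defaults are
10 pp for upstream windows and 5 pp for gene bodies.  Genes with an
undefined level in either genotype are carried through as "undefined",
never silently dropped.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from nlr_methylome.exceptions import ConfigurationError

GROUP_THRESHOLD = 0.1
DEFAULT_UPR_THRESHOLD_PP = 10.0
DEFAULT_GBR_THRESHOLD_PP = 5.0

COMPARISON_COLUMNS = ["gene_id", "kind", "context", "level_wt", "level_mut", "delta_pp", "call"]


def classify_group(level: float) -> str:
    """group1 iff level > 0.1; group2 otherwise; NaN passes through."""
    if level is None or math.isnan(level):
        return "undefined"
    return "group1" if level > GROUP_THRESHOLD else "group2"


def methylation_delta(level_mut: float, level_wt: float) -> float:
    """Percentage-point change, 100 x (mutant - wild type); NaN-propagating."""
    return 100.0 * (level_mut - level_wt)


def call_differential(delta_pp: float, threshold_pp: float) -> str:
    """hyper / hypo / unchanged at an inclusive percentage-point threshold."""
    if threshold_pp <= 0:
        raise ValueError("threshold_pp must be positive")
    if math.isnan(delta_pp):
        return "undefined"
    if delta_pp >= threshold_pp:
        return "hyper"
    if delta_pp <= -threshold_pp:
        return "hypo"
    return "unchanged"


def threshold_for_kind(
    kind: str,
    upr_threshold_pp: float = DEFAULT_UPR_THRESHOLD_PP,
    gbr_threshold_pp: float = DEFAULT_GBR_THRESHOLD_PP,
) -> float:
    return gbr_threshold_pp if kind == "GBR" else upr_threshold_pp


def compare_profiles(
    profile_wt: pd.DataFrame,
    profile_mut: pd.DataFrame,
    upr_threshold_pp: float = DEFAULT_UPR_THRESHOLD_PP,
    gbr_threshold_pp: float = DEFAULT_GBR_THRESHOLD_PP,
) -> pd.DataFrame:
    """Join two genotype profiles and call hyper/hypomethylation per row.

    Both profiles must cover the same (gene, kind, context) triples.
    """
    key = ["gene_id", "kind", "context"]
    left = profile_wt[key + ["level"]].rename(columns={"level": "level_wt"})
    right = profile_mut[key + ["level"]].rename(columns={"level": "level_mut"})
    if len(left) != len(right):
        raise ConfigurationError("profiles cover different numbers of regions")
    merged = left.merge(right, on=key, how="inner")
    if len(merged) != len(left):
        raise ConfigurationError("profiles cover different (gene, kind, context) triples")
    merged["delta_pp"] = 100.0 * (merged["level_mut"] - merged["level_wt"])
    thresholds = merged["kind"].map(
        lambda k: threshold_for_kind(k, upr_threshold_pp, gbr_threshold_pp)
    )
    merged["call"] = [
        call_differential(d, t) if not math.isnan(d) else "undefined"
        for d, t in zip(merged["delta_pp"], thresholds)
    ]
    return merged[COMPARISON_COLUMNS]


def group_proportions(levels: Iterable[float]) -> dict[str, float]:
    """Fractions of group 1 / group 2 over genes with a defined level."""
    arr = np.asarray(list(levels), dtype=float)
    defined = arr[~np.isnan(arr)]
    n = defined.size
    if n == 0:
        return {"group1_frac": float("nan"), "group2_frac": float("nan"), "n_defined": 0}
    g1 = float(np.mean(defined > GROUP_THRESHOLD))
    return {"group1_frac": g1, "group2_frac": 1.0 - g1, "n_defined": int(n)}


def heatmap_matrix(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    kind: str,
    context: str,
    genes: Sequence[str] | None = None,
    labels: tuple[str, str] = ("wt", "mut"),
) -> pd.DataFrame:
    """Gene x genotype matrix of levels for one (kind, context) pair.

    Row order follows ``genes`` when given, otherwise the first profile's
    gene order; the two profiles must cover the same gene set.
    """
    cols = {}
    gene_order = None
    for label, profile in zip(labels, (profile_a, profile_b)):
        sub = profile.loc[(profile["kind"] == kind) & (profile["context"] == context)]
        series = sub.set_index("gene_id")["level"]
        if series.index.has_duplicates:
            raise ConfigurationError(f"duplicate genes in {label} profile")
        cols[label] = series
        if gene_order is None:
            gene_order = list(series.index)
    if genes is not None:
        gene_order = list(genes)
    for label, series in cols.items():
        if set(series.index) != set(gene_order):
            raise ConfigurationError(f"gene list mismatch in {label} profile")
    return pd.DataFrame({label: cols[label].reindex(gene_order) for label in labels})


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a levels matrix to PNG (rows = genes, columns = genotypes)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3 + 0.5 * matrix.shape[1], max(3, 0.06 * len(matrix))))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(matrix)} genes")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="methylation level")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
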