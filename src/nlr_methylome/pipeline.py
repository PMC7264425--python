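"""End-to-end convenience drivers: simulate -> profile -> compare -> recover.

These functions glue the per-module operations together the way the analysis
scripts and the acceptance checks use them; no science lives here that the
individual modules do not already implement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nlr_methylome.compare import compare_profiles
from nlr_methylome.expression import classify_expression_table
from nlr_methylome.levels import profile_genome
from nlr_methylome.methylome import filter_by_coverage
from nlr_methylome.simulate import SyntheticStudy


def profile_study(study: SyntheticStudy, min_cov: int = 4) -> dict[str, pd.DataFrame]:
    """Coverage-filter each genotype's report and profile every region."""
    return {
        genotype: profile_genome(filter_by_coverage(report, min_cov), study.regions)
        for genotype, report in study.reports.items()
    }


def compare_study(
    study: SyntheticStudy,
    min_cov: int = 4,
    upr_threshold_pp: float = 10.0,
    gbr_threshold_pp: float = 5.0,
) -> pd.DataFrame:
    profiles = profile_study(study, min_cov)
    return compare_profiles(profiles["wt"], profiles["mut"], upr_threshold_pp, gbr_threshold_pp)


def dm_recovery(
    comparison: pd.DataFrame,
    planted: set[tuple[str, str, str]],
    kind: str,
    context: str,
    direction: str = "hyper",
    exclude: set[tuple[str, str, str]] = frozenset(),
) -> dict[str, float]:
    """Recall and false-positive rate of differential calls for one stratum.

    ``planted`` holds (gene_id, kind, context) keys of the true effects;
    recall is the fraction of planted regions called in the planted
    direction, FPR the fraction of unplanted regions called hyper or hypo.
    ``exclude`` drops regions from the null set that carry a genuine effect
    of another direction or inherited from an enclosing window (a 500-bp
    upstream effect also covers the nested 200-bp window).
    """
    sub = comparison.loc[(comparison["kind"] == kind) & (comparison["context"] == context)]
    keys = [(g, kind, context) for g in sub["gene_id"]]
    is_planted = np.array([k in planted for k in keys])
    is_null = np.array([k not in planted and k not in exclude for k in keys])
    calls = sub["call"].to_numpy()
    n_planted = int(is_planted.sum())
    n_null = int(is_null.sum())
    recall = float(np.mean(calls[is_planted] == direction)) if n_planted else float("nan")
    fpr = (
        float(np.mean(np.isin(calls[is_null], ["hyper", "hypo"]))) if n_null else float("nan")
    )
    return {"recall": recall, "fpr": fpr, "n_planted": n_planted, "n_null": n_null}


def expression_recovery(
    fpkm_table: pd.DataFrame,
    planted_up: set[str],
    min_fpkm: float = 1.0,
) -> dict[str, float]:
    """Recall of "up" labels among planted, expressed genes.

    The ratio classification is only defined on the expressed universe (the
    >= min_fpkm filter precedes it), so recall is computed over planted genes
    passing that filter; the number filtered out is reported alongside.
    """
    classified = classify_expression_table(fpkm_table, min_fpkm=min_fpkm)
    planted_mask = classified["gene_id"].isin(planted_up).to_numpy()
    expressed = (classified["change"] != "not_expressed").to_numpy()
    eligible = planted_mask & expressed
    n_eligible = int(eligible.sum())
    recall = (
        float(np.mean(classified.loc[eligible, "change"] == "up")) if n_eligible else float("nan")
    )
    return {
        "recall": recall,
        "n_planted": int(planted_mask.sum()),
        "n_eligible": n_eligible,
        "n_not_expressed": int((planted_mask & ~expressed).sum()),
    }
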