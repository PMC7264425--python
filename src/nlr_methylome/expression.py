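"""FPKM arithmetic, expression-change classification and qPCR fold changes.

Expression changes are called on FPKM ratios between mutant and wild type:
a gene must be expressed (at least one genotype with FPKM >= 1 by default),
and the ratio must leave the (0.9, 1.1) band to count as down/up.  The
differential-expression filter applied to external DE output requires a more
than twofold change (strict) and FDR <= 0.05 (inclusive).  qPCR fold changes
follow the comparative-Ct (2^-ddCt) method with per-condition mean Ct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_FPKM = 1.0
DEFAULT_UP_RATIO = 1.1
DEFAULT_DOWN_RATIO = 0.9


def fpkm(fragment_count: int, transcript_length_bp: int, total_mapped_fragments: int) -> float:
    """Fragments per kilobase of transcript per million mapped fragments."""
    if transcript_length_bp <= 0:
        raise ValueError("transcript_length_bp must be positive")
    if total_mapped_fragments <= 0:
        raise ValueError("total_mapped_fragments must be positive")
    if fragment_count < 0:
        raise ValueError("fragment_count must be non-negative")
    return fragment_count * 1e9 / (transcript_length_bp * total_mapped_fragments)


def classify_expression_change(
    fpkm_wt: float,
    fpkm_mut: float,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    up_ratio: float = DEFAULT_UP_RATIO,
    down_ratio: float = DEFAULT_DOWN_RATIO,
) -> str:
    """Label a gene up / down / unchanged / not_expressed.

    not_expressed when both FPKMs fall below ``min_fpkm``; a gene silent in
    the wild type but expressed in the mutant is "up" (its ratio is
    undefined).
    """
    if not (0 < down_ratio < 1 < up_ratio):
        raise ValueError("thresholds must satisfy 0 < down_ratio < 1 < up_ratio")
    if fpkm_wt < 0 or fpkm_mut < 0:
        raise ValueError("FPKM values must be non-negative")
    if max(fpkm_wt, fpkm_mut) < min_fpkm:
        return "not_expressed"
    if fpkm_wt == 0:
        return "up"
    ratio = fpkm_mut / fpkm_wt
    if ratio >= up_ratio:
        return "up"
    if ratio <= down_ratio:
        return "down"
    return "unchanged"


def classify_expression_table(
    table: pd.DataFrame,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    up_ratio: float = DEFAULT_UP_RATIO,
    down_ratio: float = DEFAULT_DOWN_RATIO,
) -> pd.DataFrame:
    """Vectorised classification of a (gene_id, fpkm_wt, fpkm_mut) table.

    Adds ``ratio`` (NaN when fpkm_wt == 0) and ``change`` columns.
    """
    out = table.copy()
    wt = out["fpkm_wt"].to_numpy(dtype=float)
    mut = out["fpkm_mut"].to_numpy(dtype=float)
    out["ratio"] = np.where(wt > 0, mut / np.where(wt > 0, wt, np.nan), np.nan)
    out["change"] = [
        classify_expression_change(w, m, min_fpkm, up_ratio, down_ratio)
        for w, m in zip(wt, mut)
    ]
    return out


def merge_fpkm_tables(table_wt: pd.DataFrame, table_mut: pd.DataFrame) -> pd.DataFrame:
    """Combine per-genotype (gene_id, fpkm) tables into one wt/mut table."""
    left = table_wt.rename(columns={"fpkm": "fpkm_wt"})
    right = table_mut.rename(columns={"fpkm": "fpkm_mut"})
    return left.merge(right, on="gene_id", how="inner")


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    arr = np.asarray(list(pvalues), dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def apply_de_filter(
    fold_change: float,
    fdr: float,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> bool:
    """True iff the change is more than ``fc_threshold``-fold in either
    direction (strict) and the FDR is at most ``fdr_threshold``."""
    if fold_change <= 0:
        raise ValueError("fold_change must be positive")
    extreme = fold_change > fc_threshold or fold_change < 1.0 / fc_threshold
    return extreme and fdr <= fdr_threshold


@dataclass(frozen=True)
class CtObservation:
    """Replicate-resolved qPCR cycle thresholds for one transcript.

    ``test`` is the genotype under study (e.g. a demethylase mutant),
    ``ctrl`` the wild-type control; ``ref`` is the internal reference gene
    (e.g. ACTIN2).
    """

    transcript_id: str
    ct_target_test: tuple[float, ...] = field(default=())
    ct_ref_test: tuple[float, ...] = field(default=())
    ct_target_ctrl: tuple[float, ...] = field(default=())
    ct_ref_ctrl: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("ct_target_test", "ct_ref_test", "ct_target_ctrl", "ct_ref_ctrl"):
            values = getattr(self, name)
            if len(values) == 0:
                raise ValueError(f"{self.transcript_id}: no replicates for {name}")
            if any(not math.isfinite(v) or v <= 0 for v in values):
                raise ValueError(f"{self.transcript_id}: Ct values must be finite and positive")


def ddct_fold_change(obs: CtObservation) -> float:
    """Comparative-Ct fold change, 2^-((dCt_test) - (dCt_ctrl)).

    Replicates are aggregated by the mean Ct per condition before taking
    differences; the result is invariant to adding a constant cycle offset
    to all four means.
    """
    dct_test = float(np.mean(obs.ct_target_test)) - float(np.mean(obs.ct_ref_test))
    dct_ctrl = float(np.mean(obs.ct_target_ctrl)) - float(np.mean(obs.ct_ref_ctrl))
    return 2.0 ** (-(dct_test - dct_ctrl))


def read_ct_table(source: str | IO[str]) -> list[CtObservation]:
    """Read a Ct CSV: transcript_id, condition in {test, control},
    role in {target, reference}, replicate, ct."""
    df = pd.read_csv(source)
    required = {"transcript_id", "condition", "role", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    out = []
    for tid, sub in df.groupby("transcript_id", sort=False):
        def cts(condition: str, role: str) -> tuple[float, ...]:
            sel = sub.loc[(sub["condition"] == condition) & (sub["role"] == role), "ct"]
            return tuple(float(v) for v in sel)

        out.append(
            CtObservation(
                transcript_id=str(tid),
                ct_target_test=cts("test", "target"),
                ct_ref_test=cts("test", "reference"),
                ct_target_ctrl=cts("control", "target"),
                ct_ref_ctrl=cts("control", "reference"),
            )
        )
    return out


def ddct_table(observations: Iterable[CtObservation]) -> pd.DataFrame:
    obs = list(observations)
    return pd.DataFrame(
        {
            "transcript_id": [o.transcript_id for o in obs],
            "fold_change": [ddct_fold_change(o) for o in obs],
        }
    )
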