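"""Weighted methylation levels per (gene, region kind, context).

The level of a region is the weighted methylation level: total methylated
read calls divided by total read calls over the region's covered cytosines,
pooling counts rather than averaging per-cytosine ratios.  Cytosines on both
DNA strands inside a region contribute, regardless of the gene's strand.
Levels are fractions internally (NaN when no covered cytosine falls in the
region); percent appears only at presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from nlr_methylome.exceptions import ConfigurationError
from nlr_methylome.methylome import CONTEXTS
from nlr_methylome.regions import RegionSpec

PROFILE_COLUMNS = ["gene_id", "kind", "context", "level", "n_cytosines", "meth_reads", "total_reads"]


@dataclass(frozen=True)
class RegionMethylation:
    gene_id: str
    kind: str
    context: str
    level: float  # NaN when undefined
    n_cytosines: int
    meth_reads: int
    total_reads: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.level)


def summarize_region(records: pd.DataFrame, region: RegionSpec, context: str) -> RegionMethylation:
    """Pool counts over one region and context.

    ``records`` should already be coverage-filtered.  Every record of the
    requested context whose 1-based position falls inside the (0-based
    half-open) region counts, on either DNA strand.
    """
    sel = records.loc[
        (records["chrom"] == region.chrom)
        & (records["pos"] > region.start)
        & (records["pos"] <= region.end)
        & (records["context"] == context)
    ]
    meth = int(sel["count_meth"].sum())
    total = meth + int(sel["count_unmeth"].sum())
    level = meth / total if total > 0 else float("nan")
    return RegionMethylation(region.gene_id, region.kind, context, level, len(sel), meth, total)


def profile_genome(records: pd.DataFrame, region_specs: Sequence[RegionSpec]) -> pd.DataFrame:
    """Weighted level for every (gene, kind, context) triple.

    Returns a long-format frame with exactly ``len(region_specs) * 3`` rows;
    regions with no covered cytosine of a context get NaN levels.  Duplicate
    (gene, kind) pairs in ``region_specs`` raise
    :class:`ConfigurationError`.
    """
    seen = set()
    for spec in region_specs:
        key = (spec.gene_id, spec.kind)
        if key in seen:
            raise ConfigurationError(f"duplicate region spec for {key}")
        seen.add(key)

    by_chrom: dict[str, dict[str, np.ndarray]] = {}
    ctx_codes = {c: i for i, c in enumerate(CONTEXTS)}
    for chrom, sub in records.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        by_chrom[str(chrom)] = {
            "pos": sub["pos"].to_numpy(np.int64),
            "meth": sub["count_meth"].to_numpy(np.int64),
            "unmeth": sub["count_unmeth"].to_numpy(np.int64),
            "ctx": sub["context"].map(ctx_codes).to_numpy(np.int64),
        }

    rows = []
    for spec in region_specs:
        data = by_chrom.get(spec.chrom)
        if data is None:
            for context in CONTEXTS:
                rows.append((spec.gene_id, spec.kind, context, float("nan"), 0, 0, 0))
            continue
        lo = np.searchsorted(data["pos"], spec.start + 1, side="left")
        hi = np.searchsorted(data["pos"], spec.end, side="right")
        ctx = data["ctx"][lo:hi]
        meth = data["meth"][lo:hi]
        unmeth = data["unmeth"][lo:hi]
        for context, code in ctx_codes.items():
            mask = ctx == code
            m = int(meth[mask].sum())
            t = m + int(unmeth[mask].sum())
            level = m / t if t > 0 else float("nan")
            rows.append((spec.gene_id, spec.kind, context, level, int(mask.sum()), m, t))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Long-format TSV with ``NA`` for undefined levels."""
    profile.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_profile(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def profile_to_records(profile: pd.DataFrame) -> Iterable[RegionMethylation]:
    for row in profile.itertuples(index=False):
        yield RegionMethylation(
            row.gene_id, row.kind, row.context, float(row.level), int(row.n_cytosines),
            int(row.meth_reads), int(row.total_reads),
        )
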