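"""Per-cytosine methylation reports, context calling and the coverage filter.

The report layout is the standard per-cytosine (CX) output of bisulfite
aligners: seven tab-separated columns — chromosome, 1-based position, strand,
methylated read count, unmethylated read count, context (CG/CHG/CHH) and the
trinucleotide.  Coverage is the sum of the two count columns at one
strand-specific cytosine; strands are never pooled at symmetric CG dyads,
matching the report layout consumed.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd

from nlr_methylome.exceptions import CoordinateError, ReportParseError

CONTEXTS = ("CG", "CHG", "CHH")

REPORT_COLUMNS = ["chrom", "pos", "strand", "count_meth", "count_unmeth", "context", "trinucleotide"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def read_cytosine_report(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a 7-column cytosine report (optionally gzip-compressed).

    Lines are preserved regardless of coverage, so zero-coverage cytosines
    survive parsing and are only removed by :func:`filter_by_coverage`.
    Non-integer counts or an unknown context token raise
    :class:`ReportParseError` naming the offending line.
    """
    if isinstance(source, (str, Path)):
        opener = gzip.open if str(source).endswith(".gz") else open
        with opener(source, "rt") as fh:
            return read_cytosine_report(fh)

    df = pd.read_csv(
        source,
        sep="\t",
        header=None,
        names=REPORT_COLUMNS,
        dtype=str,
        comment=None,
        skip_blank_lines=False,
    )
    if df.shape[1] != 7:
        raise ReportParseError(f"expected 7 tab-separated columns, got {df.shape[1]}")
    for col in ("pos", "count_meth", "count_unmeth"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            raise ReportParseError(f"line {int(np.flatnonzero(bad.to_numpy())[0]) + 1}: non-integer {col}")
        if (converted % 1 != 0).any() or (converted < 0).any():
            lineno = int(np.flatnonzero(((converted % 1 != 0) | (converted < 0)).to_numpy())[0]) + 1
            raise ReportParseError(f"line {lineno}: {col} must be a non-negative integer")
        df[col] = converted.astype(np.int64)
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        lineno = int(np.flatnonzero(bad_ctx.to_numpy())[0]) + 1
        raise ReportParseError(f"line {lineno}: unknown context token {df['context'].iloc[lineno - 1]!r}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        lineno = int(np.flatnonzero(bad_strand.to_numpy())[0]) + 1
        raise ReportParseError(f"line {lineno}: bad strand {df['strand'].iloc[lineno - 1]!r}")
    df["trinucleotide"] = df["trinucleotide"].fillna("NNN")
    return df


def write_cytosine_report(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False, columns=REPORT_COLUMNS)


def filter_by_coverage(records: pd.DataFrame, min_cov: int = 4) -> pd.DataFrame:
    """Keep cytosines covered by at least ``min_cov`` reads (default 4).

    Coverage is ``count_meth + count_unmeth`` per strand-specific cytosine;
    input order is preserved and the operation is idempotent.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    coverage = records["count_meth"] + records["count_unmeth"]
    return records.loc[coverage >= min_cov]


def call_context(genome: Mapping[str, str], chrom: str, pos: int, strand: str) -> str | None:
    """Call CG/CHG/CHH for the cytosine at 1-based ``pos`` on ``strand``.

    On the plus strand the reference base must be C; on the minus strand it
    must be G and the context is read from the complemented upstream bases.
    Returns ``None`` (not-a-cytosine) when the base is wrong, or when the
    bases needed to decide the context run off the sequence end or contain N.
    CG needs only the adjacent base, so a C at the penultimate position
    followed by G is still called CG.
    """
    seq = genome[chrom]
    if pos < 1 or pos > len(seq):
        raise CoordinateError(f"position {pos} outside {chrom} (length {len(seq)})")
    i = pos - 1
    if strand == "+":
        if seq[i] != "C":
            return None
        b1 = seq[i + 1] if i + 1 < len(seq) else "N"
        if b1 == "G":
            return "CG"
        if b1 == "N":
            return None
        b2 = seq[i + 2] if i + 2 < len(seq) else "N"
        if b2 == "N":
            return None
        return "CHG" if b2 == "G" else "CHH"
    if strand == "-":
        if seq[i] != "G":
            return None
        b1 = seq[i - 1].translate(_COMPLEMENT) if i - 1 >= 0 else "N"
        if b1 == "G":
            return "CG"
        if b1 == "N":
            return None
        b2 = seq[i - 2].translate(_COMPLEMENT) if i - 2 >= 0 else "N"
        if b2 == "N":
            return None
        return "CHG" if b2 == "G" else "CHH"
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")


def enumerate_cytosines(seq: str, chrom: str) -> pd.DataFrame:
    """Vectorised context calling over a whole sequence.

    Returns one row per strand-specific cytosine whose context is decidable
    (same rules as :func:`call_context`), with columns chrom, pos (1-based),
    strand, context and trinucleotide; sorted by position then strand.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    n = arr.size
    A, C, G, T, N = (np.uint8(ord(b)) for b in "ACGTN")
    pad = np.full(n + 4, N, dtype=np.uint8)
    pad[2 : n + 2] = arr

    frames = []
    for strand in "+-":
        if strand == "+":
            idx = np.flatnonzero(arr == C)
            b1, b2 = pad[idx + 3], pad[idx + 4]
        else:
            idx = np.flatnonzero(arr == G)
            # complemented upstream bases: ref C complements to G
            b1, b2 = pad[idx + 1], pad[idx]
            comp = np.full(256, N, dtype=np.uint8)
            comp[[A, C, G, T]] = [T, G, C, A]
            b1, b2 = comp[b1], comp[b2]
        context = np.full(idx.size, "", dtype="U3")
        is_cg = b1 == G
        context[is_cg] = "CG"
        rest = ~is_cg & (b1 != N)
        context[rest & (b2 == G)] = "CHG"
        context[rest & (b2 != G) & (b2 != N)] = "CHH"
        keep = context != ""
        idx, context = idx[keep], context[keep]
        tri = _trinucleotides(pad, idx, strand)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": idx + 1,
                    "strand": strand,
                    "context": context,
                    "trinucleotide": tri,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def _trinucleotides(pad: np.ndarray, idx: np.ndarray, strand: str) -> np.ndarray:
    """Trinucleotide read 5'->3' on the cytosine's own strand."""
    if strand == "+":
        stack = np.stack([pad[idx + 2], pad[idx + 3], pad[idx + 4]], axis=1)
    else:
        comp = np.full(256, np.uint8(ord("N")), dtype=np.uint8)
        for a, b in zip("ACGT", "TGCA"):
            comp[ord(a)] = ord(b)
        stack = np.stack([comp[pad[idx + 2]], comp[pad[idx + 1]], comp[pad[idx]]], axis=1)
    return stack.view(dtype="S3").ravel().astype("U3")


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an uppercase in-memory genome via pyfaidx."""
    from pyfaidx import Fasta

    with Fasta(str(path), sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
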