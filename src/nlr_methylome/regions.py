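"""Gene models and the three analysis windows (UPR200, UPR500, GBR).

Coordinates are 0-based half-open everywhere inside the package; GFF3 input
(1-based inclusive) and BED output (natively half-open) convert at the
boundary.  The gene feature line — not any particular mRNA isoform — defines
the transcription start and end sites, so the gene body window (GBR) is simply
the gene span and the upstream windows (UPRs) hang off the strand-appropriate
end of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

from nlr_methylome.exceptions import CoordinateError, GffParseError

REGION_KINDS = ("UPR200", "UPR500", "GBR")
UPSTREAM_LENGTHS = {"UPR200": 200, "UPR500": 500}


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand-aware interval.

    ``start``/``end`` are 0-based half-open.  ``tss`` and ``tes`` are the
    0-based positions of the first and last transcribed base: ``start`` and
    ``end - 1`` on the plus strand, swapped on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"bad gene interval [{self.start}, {self.end}) for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class RegionSpec:
    """A gene-anchored analysis window (0-based half-open).

    A window clipped away entirely at a sequence boundary is emitted with
    ``start == end``; such regions yield undefined methylation downstream
    rather than an error.
    """

    gene_id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        if self.start < 0 or self.start > self.end:
            raise ValueError(f"bad region interval [{self.start}, {self.end})")
        limit = UPSTREAM_LENGTHS.get(self.kind)
        if limit is not None and len(self) > limit:
            raise ValueError(f"{self.kind} window longer than {limit} bp")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def is_empty(self) -> bool:
        return self.start == self.end


def load_gene_models(
    stream: IO[str] | Iterable[str],
    id_filter: set[str] | None = None,
) -> list[GeneModel]:
    """Parse ``gene`` features from a GFF3 stream.

    Only rows whose feature type is ``gene`` and that carry an ``ID``
    attribute are kept; ``id_filter``, when given, restricts the result to
    those identifiers (e.g. an NLR gene list).  A row with the wrong column
    count raises :class:`GffParseError` naming the line number; a gene without
    a usable strand is dropped with a warning.
    """
    genes: list[GeneModel] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GffParseError(f"line {lineno}: expected 9 tab-separated columns, got {len(fields)}")
        if fields[2] != "gene":
            continue
        try:
            start1, end1 = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise GffParseError(f"line {lineno}: non-integer coordinates") from exc
        if start1 < 1 or end1 < start1:
            raise GffParseError(f"line {lineno}: bad coordinates {start1}..{end1}")
        gene_id = _parse_id(fields[8])
        if gene_id is None:
            raise GffParseError(f"line {lineno}: gene feature without an ID attribute")
        strand = fields[6]
        if strand not in ("+", "-"):
            warnings.warn(f"line {lineno}: gene {gene_id} has strand {strand!r}; skipped", stacklevel=2)
            continue
        if id_filter is not None and gene_id not in id_filter:
            continue
        genes.append(GeneModel(gene_id, fields[0], start1 - 1, end1, strand))
    return genes


def _parse_id(attributes: str) -> str | None:
    for item in attributes.split(";"):
        key, _, value = item.strip().partition("=")
        if key == "ID" and value:
            return value
    return None


def read_gene_ids(stream: IO[str] | Iterable[str]) -> list[str]:
    """Read a plain-text gene-ID list, one identifier per line."""
    return [line.strip() for line in stream if line.strip()]


def derive_regions(gene: GeneModel, chrom_length: int) -> list[RegionSpec]:
    """Derive UPR200, UPR500 and GBR windows for one gene.

    The GBR equals the gene span.  A length-L UPR covers the L bases
    immediately upstream of the TSS on the gene's strand, clipped at the
    sequence boundary (possibly to an empty window).  UPR windows are not
    trimmed when they run into a neighbouring gene.
    """
    if chrom_length < gene.end:
        raise CoordinateError(
            f"gene {gene.gene_id} ends at {gene.end} but {gene.chrom} has length {chrom_length}"
        )
    out = []
    for kind, length in UPSTREAM_LENGTHS.items():
        if gene.strand == "+":
            start, end = max(0, gene.start - length), gene.start
        else:
            start, end = gene.end, min(chrom_length, gene.end + length)
        out.append(RegionSpec(gene.gene_id, kind, gene.chrom, start, end, gene.strand))
    out.append(RegionSpec(gene.gene_id, "GBR", gene.chrom, gene.start, gene.end, gene.strand))
    return out


def derive_all_regions(genes: Iterable[GeneModel], chrom_lengths: dict[str, int]) -> list[RegionSpec]:
    specs: list[RegionSpec] = []
    for gene in genes:
        specs.extend(derive_regions(gene, chrom_lengths[gene.chrom]))
    return specs


def regions_to_bed(specs: Iterable[RegionSpec]) -> Iterator[str]:
    """BED6 lines (0-based half-open), name = ``gene_id|kind``."""
    for s in specs:
        yield f"{s.chrom}\t{s.start}\t{s.end}\t{s.gene_id}|{s.kind}\t0\t{s.strand}"


def regions_from_bed(stream: IO[str] | Iterable[str]) -> list[RegionSpec]:
    """Read regions back from the BED6 export."""
    specs = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise GffParseError(f"line {lineno}: expected 6 BED columns, got {len(fields)}")
        gene_id, _, kind = fields[3].partition("|")
        specs.append(RegionSpec(gene_id, kind, fields[0], int(fields[1]), int(fields[2]), fields[5]))
    return specs
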