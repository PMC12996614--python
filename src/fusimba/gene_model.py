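"""Gene annotation handling and breakpoint tables.

A :class:`GeneModel` stores the union of all annotated exons of a gene in
*transcription order*: exon 1 is always the 5'-most exon of the transcript,
which for a minus-strand gene is the genomically rightmost interval.  All
internal coordinates are 0-based half-open; GTF input/output converts
from/to the 1-based inclusive convention at the boundary.

A :class:`BreakpointSpec` partitions a gene's exons into a 5' and a 3' side
at a recurrent (or automatically determined) fusion breakpoint, together
with the side that is expected over-expressed when a fusion is present.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

__all__ = [
    "GeneModel",
    "BreakpointSpec",
    "GtfParseError",
    "parse_gene_annotation",
    "write_gene_annotation",
    "load_breakpoint_table",
    "exon_partition",
]

RETAINED_SIDES = ("5prime", "3prime")


class GtfParseError(ValueError):
    """Raised for malformed GTF input, carrying the offending line number."""


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of a single gene.

    Parameters
    ----------
    gene_id, gene_name : str
        Stable identifier and display symbol.
    chrom : str
        Reference contig name.
    strand : {"+", "-"}
        Genomic strand the transcript is transcribed from.
    exons : tuple of (int, int)
        Non-overlapping 0-based half-open intervals in transcription order
        (exon 1 first).  For "+" genes genomic starts increase with exon
        index; for "-" genes they decrease.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exon list is empty")
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(
                    f"gene {self.gene_id}: invalid exon interval ({start}, {end})"
                )
        starts = [s for s, _ in self.exons]
        ordered = sorted(starts, reverse=(self.strand == "-"))
        if starts != ordered or len(set(starts)) != len(starts):
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) covering all exons."""
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    def exon_containing(self, pos: int) -> int | None:
        """1-based transcription-order index of the exon containing *pos*."""
        for i, (s, e) in enumerate(self.exons, start=1):
            if s <= pos < e:
                return i
        return None


@dataclass(frozen=True)
class BreakpointSpec:
    """A 5'/3' partition point of a gene.

    ``boundary_exon`` = k means the partition lies between exon k and exon
    k+1 in transcription order.  ``retained_side`` names the side expected
    over-expressed when a fusion is present (the side retained in the
    chimeric transcript).
    """

    gene_id: str
    boundary_exon: int
    retained_side: str
    genomic_pos: int | None = None
    source: str = "recurrent"

    def __post_init__(self) -> None:
        if self.boundary_exon < 1:
            raise ValueError(
                f"{self.gene_id}: boundary_exon must be >= 1, got {self.boundary_exon}"
            )
        if self.retained_side not in RETAINED_SIDES:
            raise ValueError(
                f"{self.gene_id}: retained_side must be one of {RETAINED_SIDES}, "
                f"got {self.retained_side!r}"
            )
        if self.source not in ("recurrent", "automatic"):
            raise ValueError(f"unknown breakpoint source {self.source!r}")

    def validate_against(self, gene: GeneModel) -> None:
        if self.gene_id != gene.gene_id and self.gene_id != gene.gene_name:
            raise ValueError(
                f"breakpoint gene {self.gene_id!r} does not match model "
                f"{gene.gene_id!r}"
            )
        if not 1 <= self.boundary_exon < gene.n_exons:
            raise ValueError(
                f"{self.gene_id}: boundary_exon {self.boundary_exon} outside "
                f"valid range 1..{gene.n_exons - 1}"
            )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in attr_field.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union-merge intervals; overlapping or book-ended intervals collapse."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def parse_gene_annotation(
    annotation_stream: IO[str] | str,
    gene_filter: set[str] | Sequence[str],
) -> list[GeneModel]:
    """Read exon features from GTF text and build one model per requested gene.

    Exons of all transcripts of a gene are union-merged into a single
    non-redundant set and numbered in transcription order.  Genes may be
    requested by ``gene_id`` or ``gene_name``.  Requested genes absent from
    the annotation are silently recorded as missing (not fatal) — check the
    returned list against your request.

    Raises
    ------
    GtfParseError
        For a malformed GTF exon line, naming the 1-based line number.
    """
    if isinstance(annotation_stream, str):
        annotation_stream = io.StringIO(annotation_stream)
    wanted = set(gene_filter)
    if not wanted:
        return []

    # key -> (gene_id, gene_name, chrom, strand, [intervals])
    acc: dict[str, tuple[str, str, str, str, list[tuple[int, int]]]] = {}
    order: list[str] = []
    for lineno, line in enumerate(annotation_stream, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 9:
            raise GtfParseError(f"line {lineno}: expected 9 tab-separated fields")
        chrom, _src, feature, start_s, end_s, _score, strand, _frame, attr = fields[:9]
        if feature != "exon":
            continue
        try:
            start = int(start_s) - 1  # GTF is 1-based inclusive
            end = int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
        if strand not in ("+", "-"):
            raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
        attrs = _parse_attributes(attr)
        gene_id = attrs.get("gene_id", "")
        gene_name = attrs.get("gene_name", gene_id)
        if not gene_id:
            raise GtfParseError(f"line {lineno}: exon without gene_id attribute")
        if gene_id not in wanted and gene_name not in wanted:
            continue
        if gene_id not in acc:
            acc[gene_id] = (gene_id, gene_name, chrom, strand, [])
            order.append(gene_id)
        acc[gene_id][4].append((start, end))

    models = []
    for gid in order:
        gene_id, gene_name, chrom, strand, intervals = acc[gid]
        merged = _merge_intervals(intervals)
        if strand == "-":
            merged = merged[::-1]
        models.append(
            GeneModel(gene_id, gene_name, chrom, strand, tuple(merged))
        )
    return models


def write_gene_annotation(genes: Iterable[GeneModel], stream: IO[str]) -> None:
    """Write models back to GTF (one exon feature per exon, 1-based inclusive)."""
    for gene in genes:
        for idx, (start, end) in enumerate(gene.exons, start=1):
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
                f'transcript_id "{gene.gene_id}.merged"; exon_number "{idx}";'
            )
            stream.write(
                f"{gene.chrom}\tfusimba\texon\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\t{attrs}\n"
            )


def load_breakpoint_table(
    table_stream: IO[str] | str,
    gene_models: dict[str, GeneModel] | None = None,
) -> list[BreakpointSpec]:
    """Load a recurrent-breakpoint table.

    Expected TSV columns (header required): ``gene_id``, ``boundary_exon``,
    ``retained_side``; lines starting with ``#`` are comments.  When
    *gene_models* is given (keyed by gene_id or gene_name), each spec is
    validated against its gene's exon range.
    """
    if isinstance(table_stream, str):
        table_stream = io.StringIO(table_stream)
    header: list[str] | None = None
    specs: list[BreakpointSpec] = []
    for line in table_stream:
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            required = {"gene_id", "boundary_exon", "retained_side"}
            missing = required - set(header)
            if missing:
                raise ValueError(
                    f"breakpoint table missing column(s): {sorted(missing)}"
                )
            continue
        row = {k: v.strip() for k, v in zip(header, fields)}
        spec = BreakpointSpec(
            gene_id=row["gene_id"],
            boundary_exon=int(row["boundary_exon"]),
            retained_side=row["retained_side"],
            source="recurrent",
        )
        if gene_models is not None and spec.gene_id in gene_models:
            spec.validate_against(gene_models[spec.gene_id])
        specs.append(spec)
    if header is None:
        raise ValueError("breakpoint table is empty (header required)")
    return specs


def exon_partition(
    gene: GeneModel, bp: BreakpointSpec
) -> tuple[frozenset[int], frozenset[int]]:
    """Split exon indices (1-based, transcription order) at the breakpoint.

    Returns ``({1..k}, {k+1..n})`` for boundary exon k: the 5' set and the
    3' set.  The sets are disjoint and together cover every exon.
    """
    bp.validate_against(gene)
    k = bp.boundary_exon
    n = gene.n_exons
    return frozenset(range(1, k + 1)), frozenset(range(k + 1, n + 1))


def boundary_genomic_interval(gene: GeneModel, bp: BreakpointSpec) -> tuple[int, int]:
    """Genomic coordinates flanking the breakpoint: (last base side closer to 5',
    first coordinate of the 3' side), oriented so positions < cut belong to the
    transcript part nearer the genomic left.

    Returns the genomic cut coordinate as a degenerate interval for '+' genes
    (end of exon k) and for '-' genes (start of exon k), as (pos_5p_edge,
    pos_3p_edge).
    """
    bp.validate_against(gene)
    k = bp.boundary_exon
    if gene.strand == "+":
        return gene.exons[k - 1][1], gene.exons[k][0]
    return gene.exons[k - 1][0], gene.exons[k][1]
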