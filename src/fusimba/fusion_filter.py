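"""Fusion-call parsing, filtering, multi-caller harmonization and truth matching.

Whole-transcriptome fusion calling is run with several callers in parallel
(ARRIBA-style split/discordant-read callers, splicing-event callers); their
tables differ in dialect but all reduce to gene pair + read support.  The
filter applied downstream is a minimum read-support threshold combined with
a clinical gene-set membership test — permissive (1 read) for the validated
diagnostic gene set, stricter (10 reads) for expanded exploratory lists and
panel assays.  Splice variants such as MET exon-14 skipping travel the same
path as fusions with ``gene5 == gene3`` and ``event_type=splice_variant``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

import pandas as pd

__all__ = [
    "FusionCall",
    "GeneSet",
    "ConcordanceRecord",
    "parse_fusion_table",
    "load_gene_set",
    "apply_filters",
    "merge_callers",
    "match_to_truth",
]

CALLERS = ("dragen", "arriba", "ctat_splicing", "panel", "other")
EVENT_TYPES = ("fusion", "splice_variant")
STATUSES = ("raw", "filtered_pass", "filtered_fail")

Breakpoint = tuple[str, int, str]  # (contig, position, strand)


@dataclass(frozen=True)
class FusionCall:
    sample_id: str
    gene5: str
    gene3: str
    support_reads: int
    caller: str = "other"
    event_type: str = "fusion"
    status: str = "raw"
    breakpoint5: Breakpoint | None = None
    breakpoint3: Breakpoint | None = None
    callers: tuple[str, ...] = ()
    manual_review: str = "pending"  # expert review is recorded, never automated

    def __post_init__(self) -> None:
        if self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")
        if not self.gene5 or not self.gene3:
            raise ValueError("gene5/gene3 must be non-empty")
        if self.caller not in CALLERS:
            raise ValueError(f"unknown caller {self.caller!r}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if not self.callers:
            object.__setattr__(self, "callers", (self.caller,))

    @property
    def gene_pair(self) -> frozenset[str]:
        """Unordered gene pair (callers disagree on 5'/3' ordering)."""
        return frozenset((self.gene5, self.gene3))


@dataclass(frozen=True)
class GeneSet:
    """A named clinical gene list with its read-support threshold."""

    name: str
    genes: frozenset[str]
    min_support: int = 1

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass(frozen=True)
class ConcordanceRecord:
    sample_id: str
    expected: FusionCall | None
    observed: tuple[FusionCall, ...]
    outcome: str  # {true_positive, false_negative, true_negative, false_positive}


_ARRIBA_COLUMNS = [
    "gene1",
    "gene2",
    "split_reads1",
    "split_reads2",
    "discordant_mates",
    "breakpoint1",
    "breakpoint2",
]
_GENERIC_COLUMNS = ["sample_id", "gene5", "gene3", "support_reads", "event_type"]


def _parse_breakpoint(text: str | None, strand: str = ".") -> Breakpoint | None:
    if text is None or pd.isna(text) or text in ("", "."):
        return None
    contig, _, pos = str(text).partition(":")
    return (contig, int(pos), strand)


def parse_fusion_table(
    stream: IO[str] | str, dialect: str, sample_id: str = "sample"
) -> list[FusionCall]:
    """Parse a fusion-caller output table into :class:`FusionCall` records.

    ``dialect="arriba"`` expects at least the columns gene1, gene2,
    split_reads1, split_reads2, discordant_mates, breakpoint1, breakpoint2
    (the leading ``#`` of the header is tolerated); support is the sum of
    both split-read columns and the discordant mates.  ``dialect="generic"``
    expects sample_id, gene5, gene3, support_reads, event_type and optional
    breakpoint5/breakpoint3 columns.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    if dialect not in ("arriba", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(stream, sep="\t", dtype=str)
    df.columns = [c.lstrip("#") for c in df.columns]

    required = _ARRIBA_COLUMNS if dialect == "arriba" else _GENERIC_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{dialect} table missing mandatory column {col!r}")

    calls: list[FusionCall] = []
    for _, row in df.iterrows():
        if dialect == "arriba":
            support = (
                int(row["split_reads1"])
                + int(row["split_reads2"])
                + int(row["discordant_mates"])
            )
            strand1 = str(row.get("strand1(gene/fusion)", ".")).split("/")[0]
            strand2 = str(row.get("strand2(gene/fusion)", ".")).split("/")[0]
            calls.append(
                FusionCall(
                    sample_id=row.get("sample_id", sample_id),
                    gene5=row["gene1"],
                    gene3=row["gene2"],
                    support_reads=support,
                    caller="arriba",
                    breakpoint5=_parse_breakpoint(row["breakpoint1"], strand1),
                    breakpoint3=_parse_breakpoint(row["breakpoint2"], strand2),
                )
            )
        else:
            calls.append(
                FusionCall(
                    sample_id=row["sample_id"],
                    gene5=row["gene5"],
                    gene3=row["gene3"],
                    support_reads=int(row["support_reads"]),
                    caller=row.get("caller", "other")
                    if row.get("caller") in CALLERS
                    else "other",
                    event_type=row["event_type"],
                    breakpoint5=_parse_breakpoint(row.get("breakpoint5")),
                    breakpoint3=_parse_breakpoint(row.get("breakpoint3")),
                )
            )
    return calls


def load_gene_set(stream: IO[str] | str, name: str, min_support: int = 1) -> GeneSet:
    """Load a gene set from a one-symbol-per-line file ('#' comments allowed)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genes = {
        line.strip()
        for line in stream
        if line.strip() and not line.lstrip().startswith("#")
    }
    return GeneSet(name=name, genes=frozenset(genes), min_support=min_support)


def apply_filters(calls: Sequence[FusionCall], gene_set: GeneSet) -> list[FusionCall]:
    """Read-support + gene-set filter; order preserved, no call dropped.

    A call passes iff its support reaches the gene set's threshold and at
    least one partner is a member of the set.  Calls are returned with
    status ``filtered_pass``/``filtered_fail``.
    """
    out = []
    for call in calls:
        passes = call.support_reads >= gene_set.min_support and (
            call.gene5 in gene_set.genes or call.gene3 in gene_set.genes
        )
        out.append(
            replace(call, status="filtered_pass" if passes else "filtered_fail")
        )
    return out


def _breakpoints_compatible(
    a: FusionCall, b: FusionCall, tolerance: int
) -> bool:
    # Only compared when both calls report both breakpoints; orientation-free
    # comparison against both pairings since callers disagree on 5'/3' order.
    if None in (a.breakpoint5, a.breakpoint3, b.breakpoint5, b.breakpoint3):
        return True

    def close(x: Breakpoint, y: Breakpoint) -> bool:
        return x[0] == y[0] and abs(x[1] - y[1]) <= tolerance

    direct = close(a.breakpoint5, b.breakpoint5) and close(a.breakpoint3, b.breakpoint3)
    swapped = close(a.breakpoint5, b.breakpoint3) and close(a.breakpoint3, b.breakpoint5)
    return direct or swapped


def merge_callers(
    *call_lists: Sequence[FusionCall], breakpoint_tolerance: int = 10
) -> list[FusionCall]:
    """Deduplicate calls across callers.

    Calls agreeing on the unordered gene pair — and, when both report
    breakpoints, on positions within the tolerance — merge into a single
    record keeping the maximum support and the union of callers.  Nothing
    is lost: incompatible calls stay as separate records.
    """
    merged: list[FusionCall] = []
    for call in (c for lst in call_lists for c in lst):
        for i, existing in enumerate(merged):
            if (
                existing.sample_id == call.sample_id
                and existing.gene_pair == call.gene_pair
                and existing.event_type == call.event_type
                and _breakpoints_compatible(existing, call, breakpoint_tolerance)
            ):
                merged[i] = replace(
                    existing,
                    support_reads=max(existing.support_reads, call.support_reads),
                    callers=tuple(dict.fromkeys(existing.callers + call.callers)),
                    breakpoint5=existing.breakpoint5 or call.breakpoint5,
                    breakpoint3=existing.breakpoint3 or call.breakpoint3,
                )
                break
        else:
            merged.append(call)
    return merged


def _matches(observed: FusionCall, expected: FusionCall) -> bool:
    if observed.event_type != expected.event_type:
        return False
    if expected.event_type == "splice_variant":
        return observed.gene_pair == expected.gene_pair
    return observed.gene_pair == expected.gene_pair


def match_to_truth(
    observed: Sequence[FusionCall],
    expected: FusionCall | None,
    validated_set: GeneSet | None = None,
) -> ConcordanceRecord:
    """Compare filtered observed calls against an (optional) panel truth call.

    Matching is symmetric in gene order; splice variants additionally match
    on event type.  With no expectation, any passing call in the validated
    gene set makes the sample a false positive, otherwise true negative.
    """
    passing = [c for c in observed if c.status == "filtered_pass"]
    sample_id = (
        expected.sample_id
        if expected is not None
        else (observed[0].sample_id if observed else "sample")
    )
    if expected is not None:
        hit = any(_matches(obs, expected) for obs in passing)
        outcome = "true_positive" if hit else "false_negative"
    else:
        relevant = passing
        if validated_set is not None:
            relevant = [
                c
                for c in passing
                if c.gene5 in validated_set.genes or c.gene3 in validated_set.genes
            ]
        outcome = "false_positive" if relevant else "true_negative"
    return ConcordanceRecord(
        sample_id=sample_id,
        expected=expected,
        observed=tuple(observed),
        outcome=outcome,
    )
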