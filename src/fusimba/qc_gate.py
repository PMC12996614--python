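"""Four-criterion QC gate with whole-transcriptome vs targeted-panel routing.

FFPE RNA is fragmented and often diluted by non-tumor cells, so fusion
detection from whole-transcriptome sequencing (WTS) is only reliable above
certain pre- and post-sequencing quality thresholds.  The gate combines two
metadata criteria (pathologist-estimated tumor cell content, RNA input
mass) with two alignment-derived criteria (unique fragments after duplicate
collapsing, median insert size).  Samples failing any criterion are routed
to a targeted fusion panel instead of WTS.

All four thresholds are inclusive (>=); defaults: TCC 40%, 50 ng input,
50 million unique reads, 100 bp median insert.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pysam

from .imbalance import _open_alignment

__all__ = [
    "QCMetrics",
    "QCThresholds",
    "QCDecision",
    "median_insert_size",
    "count_unique_fragments",
    "evaluate_qc",
]


@dataclass(frozen=True)
class QCMetrics:
    """Per-sample QC inputs.

    ``tcc`` (tumor cell content, percent) and ``rna_input`` (ng) come from
    pathology / lab metadata and are never computed from sequence.
    ``unique_reads`` counts fragments after coordinate-based duplicate
    collapsing; ``median_insert_size`` is in bp.  Missing fields are left
    ``None`` and raise at evaluation time rather than passing silently.
    """

    sample_id: str
    tcc: float | None = None
    rna_input: float | None = None
    unique_reads: int | None = None
    median_insert_size: float | None = None

    def __post_init__(self) -> None:
        if self.tcc is not None and not 0 <= self.tcc <= 100:
            raise ValueError(f"{self.sample_id}: TCC must be in [0, 100]")
        if self.rna_input is not None and self.rna_input < 0:
            raise ValueError(f"{self.sample_id}: RNA input must be >= 0")
        if self.unique_reads is not None and self.unique_reads < 0:
            raise ValueError(f"{self.sample_id}: unique reads must be >= 0")
        if self.median_insert_size is not None and self.median_insert_size < 0:
            raise ValueError(f"{self.sample_id}: median insert must be >= 0")


@dataclass(frozen=True)
class QCThresholds:
    min_tcc: float = 40.0
    min_rna_input: float = 50.0
    min_unique_reads: int = 50_000_000
    min_median_insert: float = 100.0

    def __post_init__(self) -> None:
        if min(
            self.min_tcc, self.min_rna_input, self.min_unique_reads, self.min_median_insert
        ) < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class QCDecision:
    sample_id: str
    tcc_ok: bool
    input_ok: bool
    reads_ok: bool
    insert_ok: bool

    @property
    def overall_pass(self) -> bool:
        return self.tcc_ok and self.input_ok and self.reads_ok and self.insert_ok

    @property
    def routing(self) -> str:
        return "WTS" if self.overall_pass else "targeted_panel"

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "tcc_ok": self.tcc_ok,
            "input_ok": self.input_ok,
            "reads_ok": self.reads_ok,
            "insert_ok": self.insert_ok,
            "overall_pass": self.overall_pass,
            "routing": self.routing,
        }


def _primary_pairs(alignments) -> Iterable[pysam.AlignedSegment]:
    handle = _open_alignment(alignments)
    reads = handle.fetch(until_eof=True) if handle is not None else alignments
    for read in reads:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or not read.is_paired
            or not read.is_proper_pair
        ):
            continue
        yield read


def median_insert_size(alignments) -> int:
    """Median absolute template length over primary proper pairs.

    Each pair is counted once via its leftmost mate (positive template
    length).  Even counts use the lower median so the result stays an
    observed integer value.
    """
    tlens = sorted(
        read.template_length
        for read in _primary_pairs(alignments)
        if read.template_length > 0
    )
    if not tlens:
        raise ValueError("no paired data: cannot compute median insert size")
    return tlens[(len(tlens) - 1) // 2]


def count_unique_fragments(alignments, count_reads: bool = False) -> int:
    """Fragments remaining after coordinate-based duplicate collapsing.

    Two fragments are duplicates when they share contig, fragment start,
    fragment end and fragment strand (strand of mate 1).  Counted once per
    pair via the leftmost mate; no UMIs are assumed.  ``count_reads=True``
    reports reads instead (2x the fragment count).
    """
    keys: set[tuple] = set()
    for read in _primary_pairs(alignments):
        if read.template_length <= 0:
            continue
        start = read.reference_start
        end = start + read.template_length
        mate1_reverse = read.is_reverse if read.is_read1 else not read.is_reverse
        keys.add((read.reference_name, start, end, mate1_reverse))
    return 2 * len(keys) if count_reads else len(keys)


def evaluate_qc(metrics: QCMetrics, thresholds: QCThresholds = QCThresholds()) -> QCDecision:
    """Evaluate the four-criterion gate; all comparisons inclusive (>=).

    Raises
    ------
    ValueError
        If any metric is missing.  TCC in particular is mandatory
        pre-analytics — it is never imputed.
    """
    if metrics.tcc is None:
        raise ValueError(f"{metrics.sample_id}: TCC required")
    missing = [
        name
        for name, value in (
            ("rna_input", metrics.rna_input),
            ("unique_reads", metrics.unique_reads),
            ("median_insert_size", metrics.median_insert_size),
        )
        if value is None
    ]
    if missing:
        raise ValueError(f"{metrics.sample_id}: missing QC metric(s): {missing}")
    return QCDecision(
        sample_id=metrics.sample_id,
        tcc_ok=metrics.tcc >= thresholds.min_tcc,
        input_ok=metrics.rna_input >= thresholds.min_rna_input,
        reads_ok=metrics.unique_reads >= thresholds.min_unique_reads,
        insert_ok=metrics.median_insert_size >= thresholds.min_median_insert,
    )
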