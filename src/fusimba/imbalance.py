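"""Stranded 5'/3' expression-imbalance assay.

A gene fusion replaces one end of a transcript with a partner gene, so the
retained portion is driven by the partner's promoter while the lost portion
stays at the wild-type level.  When no junction-spanning (split) read exists,
strongly unequal mean coverage of the exons on the two sides of a recurrent
breakpoint — together with one-sided spliced-read support on the gene's own
strand — still betrays the fusion.  Because unspliced pre-mRNA from a
neighbouring gene on the opposite strand can mimic coverage, all counting
here is strand-aware: only reads whose inferred transcript strand matches
the gene's strand contribute to the sense signal.

The module computes per-exon sense/antisense mean depth, strand-aware
spliced-read counts partitioned at the breakpoint, the fold-change
statistic, an automatic changepoint-based breakpoint, and the final
flag/route decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pysam

from .gene_model import BreakpointSpec, GeneModel, exon_partition

__all__ = [
    "ReadFilter",
    "StrandedCoverage",
    "JunctionCounts",
    "ImbalanceResult",
    "ImbalanceThresholds",
    "stranded_exon_coverage",
    "count_spliced_reads",
    "imbalance_statistic",
    "auto_breakpoint",
    "evaluate_imbalance",
    "run_imbalance",
    "write_report",
]


@dataclass(frozen=True)
class ReadFilter:
    """Pileup hygiene: which alignment records participate in counting."""

    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    exclude_duplicates: bool = True
    exclude_mate_unmapped: bool = True
    min_mapq: int = 1

    def keep(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if self.exclude_mate_unmapped and read.is_paired and read.mate_is_unmapped:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        return True


DEFAULT_FILTER = ReadFilter()


@dataclass
class StrandedCoverage:
    """Per-exon mean depth split by inferred transcript strand.

    Depths are in x coverage: aligned bases overlapping the exon divided by
    exon length.  Arrays follow transcription order (exon 1 first).
    """

    gene_id: str
    sense_mean_depth: np.ndarray
    antisense_mean_depth: np.ndarray
    exon_lengths: np.ndarray

    def __post_init__(self) -> None:
        self.sense_mean_depth = np.asarray(self.sense_mean_depth, dtype=float)
        self.antisense_mean_depth = np.asarray(self.antisense_mean_depth, dtype=float)
        self.exon_lengths = np.asarray(self.exon_lengths, dtype=int)
        n = len(self.exon_lengths)
        if len(self.sense_mean_depth) != n or len(self.antisense_mean_depth) != n:
            raise ValueError("coverage arrays must share the gene's exon count")
        if (self.sense_mean_depth < 0).any() or (self.antisense_mean_depth < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass(frozen=True)
class JunctionCounts:
    """Strand-aware spliced-read tallies relative to the breakpoint.

    ``n5``/``n3``: spliced reads on the gene strand whose splice junctions
    lie entirely within the 5'/3' exon partition.  ``n_spanning``: reads
    with a junction crossing the breakpoint boundary (wild-type style
    evidence, reported but excluded from the one-sided counts).
    """

    n5: int = 0
    n3: int = 0
    n_spanning: int = 0

    def __post_init__(self) -> None:
        if min(self.n5, self.n3, self.n_spanning) < 0:
            raise ValueError("junction counts must be non-negative")


@dataclass(frozen=True)
class ImbalanceThresholds:
    """Decision rule for flagging an imbalance as fusion-suspicious.

    All three conditions must hold: fold-change at least ``min_fold_change``,
    retained-side mean depth at least ``min_retained_mean_depth`` (guards
    against ratios of noise), and an absolute spliced-read difference of at
    least ``min_junction_delta`` between the retained and the other side.
    """

    min_fold_change: float = 10.0
    min_retained_mean_depth: float = 2.0
    min_junction_delta: int = 5
    pseudocount: float = 0.05

    def __post_init__(self) -> None:
        if min(
            self.min_fold_change,
            self.min_retained_mean_depth,
            self.min_junction_delta,
            self.pseudocount,
        ) <= 0:
            raise ValueError("all thresholds must be strictly positive")


@dataclass
class ImbalanceResult:
    gene_id: str
    breakpoint: BreakpointSpec
    mean5: float
    mean3: float
    fold_change: float
    junctions: JunctionCounts
    flagged: bool = False
    recommendation: str = "none"  # {"none", "orthogonal_confirmation"}

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "boundary_exon": self.breakpoint.boundary_exon,
            "retained_side": self.breakpoint.retained_side,
            "source": self.breakpoint.source,
            "mean5": self.mean5,
            "mean3": self.mean3,
            "fold_change": self.fold_change,
            "n5": self.junctions.n5,
            "n3": self.junctions.n3,
            "n_spanning": self.junctions.n_spanning,
            "flagged": self.flagged,
            "recommendation": self.recommendation,
        }


# ---------------------------------------------------------------------------
# alignment access and strand logic
# ---------------------------------------------------------------------------


def _open_alignment(alignments) -> pysam.AlignmentFile | None:
    if isinstance(alignments, (str, Path)):
        return pysam.AlignmentFile(str(alignments))
    if isinstance(alignments, pysam.AlignmentFile):
        return alignments
    return None


def fetch_overlapping(
    alignments, chrom: str, start: int, end: int
) -> Iterable[pysam.AlignedSegment]:
    """Yield alignment records overlapping [start, end) on *chrom*.

    Accepts a path, an open :class:`pysam.AlignmentFile`, or a plain
    iterable of records (as produced by the simulator).  Indexed BAMs use
    random access; SAM text is streamed.
    """
    handle = _open_alignment(alignments)
    if handle is None:
        for read in alignments:
            if (
                not read.is_unmapped
                and read.reference_name == chrom
                and read.reference_start < end
                and read.reference_end is not None
                and read.reference_end > start
            ):
                yield read
        return
    if chrom not in handle.references:
        raise ValueError(f"contig {chrom!r} absent from alignment header")
    try:
        has_index = handle.has_index()
    except (AttributeError, ValueError):
        has_index = False
    if has_index:
        yield from handle.fetch(chrom, start, end)
        return
    if handle.is_bam:
        raise ValueError("coordinate access on BAM requires an index (.bai)")
    for read in handle.fetch(until_eof=True):
        if (
            not read.is_unmapped
            and read.reference_name == chrom
            and read.reference_start < end
            and read.reference_end is not None
            and read.reference_end > start
        ):
            yield read


def transcript_strand(read: pysam.AlignedSegment, library_orientation: str) -> str:
    """Genomic strand of the transcript the read derives from.

    ``RF`` (reverse-stranded, TruSeq stranded convention): mate 2 aligns on
    the transcript strand and mate 1 opposite.  ``FR`` is the mirror
    convention.  Single-end reads are assigned from the alignment strand
    under the same convention.
    """
    if library_orientation not in ("RF", "FR"):
        raise ValueError(f"library_orientation must be 'RF' or 'FR'")
    align_strand = "-" if read.is_reverse else "+"
    if read.is_paired:
        sense_mate_is_read2 = library_orientation == "RF"
        on_transcript = read.is_read2 if sense_mate_is_read2 else read.is_read1
    else:
        on_transcript = library_orientation == "FR"
    if on_transcript:
        return align_strand
    return "-" if align_strand == "+" else "+"


def _aligned_blocks(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    return read.get_blocks()


def _junctions(read: pysam.AlignedSegment) -> list[tuple[int, int]]:
    """Genomic intervals skipped by N operations, as (gap_start, gap_end)."""
    juncs = []
    pos = read.reference_start
    for op, length in read.cigartuples or ():
        if op in (0, 7, 8, 2):  # M, =, X, D consume reference
            pos += length
        elif op == 3:  # N
            juncs.append((pos, pos + length))
            pos += length
    return juncs


# ---------------------------------------------------------------------------
# counting operations
# ---------------------------------------------------------------------------


def stranded_exon_coverage(
    alignments,
    gene: GeneModel,
    library_orientation: str = "RF",
    read_filter: ReadFilter = DEFAULT_FILTER,
) -> StrandedCoverage:
    """Per-exon mean depth, separated into sense and antisense reads.

    For each exon the aligned bases of all overlapping, filter-passing reads
    are summed (gapped N segments do not count) and divided by exon length.
    A read contributes to the sense track iff its inferred transcript strand
    equals the gene's strand — this is what keeps unspliced antisense
    pre-mRNA from a neighbouring gene out of the fusion signal.
    """
    n = gene.n_exons
    sense_bases = np.zeros(n)
    anti_bases = np.zeros(n)
    span = gene.span
    for read in fetch_overlapping(alignments, gene.chrom, *span):
        if not read_filter.keep(read):
            continue
        sense = transcript_strand(read, library_orientation) == gene.strand
        target = sense_bases if sense else anti_bases
        for block_start, block_end in _aligned_blocks(read):
            for i, (es, ee) in enumerate(gene.exons):
                ov = min(block_end, ee) - max(block_start, es)
                if ov > 0:
                    target[i] += ov
    lengths = np.array(gene.exon_lengths, dtype=float)
    return StrandedCoverage(
        gene_id=gene.gene_id,
        sense_mean_depth=sense_bases / lengths,
        antisense_mean_depth=anti_bases / lengths,
        exon_lengths=lengths.astype(int),
    )


def _boundary_cut(gene: GeneModel, bp: BreakpointSpec) -> int:
    """Genomic coordinate separating the two partitions.

    '+' gene: positions < cut are 5'-side; '-' gene: positions >= cut are
    5'-side (the 5' end of a minus-strand transcript is genomically right).
    """
    k = bp.boundary_exon
    if gene.strand == "+":
        return gene.exons[k - 1][1]
    return gene.exons[k - 1][0]


def count_spliced_reads(
    alignments,
    gene: GeneModel,
    bp: BreakpointSpec,
    library_orientation: str = "RF",
    read_filter: ReadFilter = DEFAULT_FILTER,
) -> JunctionCounts:
    """Count spliced reads on the gene strand on each side of the breakpoint.

    A read is spliced iff its CIGAR contains at least one N gap.  Each
    spliced sense read is classified by the exonic bases flanking its
    junction(s): entirely 5' of the boundary, entirely 3', or spanning.
    A read whose junctions fall on both sides also counts as spanning.
    Antisense spliced reads belong to whatever gene lives on the other
    strand and are ignored here.
    """
    bp.validate_against(gene)
    cut = _boundary_cut(gene, bp)
    plus = gene.strand == "+"
    n5 = n3 = n_spanning = 0
    for read in fetch_overlapping(alignments, gene.chrom, *gene.span):
        if not read_filter.keep(read):
            continue
        if transcript_strand(read, library_orientation) != gene.strand:
            continue
        juncs = _junctions(read)
        if not juncs:
            continue
        sides = set()
        for gap_start, gap_end in juncs:
            donor_base, acceptor_base = gap_start - 1, gap_end
            if plus:
                sides.add("5" if donor_base < cut else "3")
                sides.add("5" if acceptor_base < cut else "3")
            else:
                sides.add("5" if donor_base >= cut else "3")
                sides.add("5" if acceptor_base >= cut else "3")
        if len(sides) > 1:
            n_spanning += 1
        elif sides == {"5"}:
            n5 += 1
        else:
            n3 += 1
    return JunctionCounts(n5=n5, n3=n3, n_spanning=n_spanning)


def imbalance_statistic(
    cov: StrandedCoverage,
    partition: tuple[frozenset[int], frozenset[int]],
    retained_side: str,
    epsilon: float = 0.05,
    length_weighted: bool = True,
) -> tuple[float, float, float]:
    """Mean sense depth on each side of the partition and the fold-change.

    Returns ``(mean5, mean3, fold_change)`` with

        fold_change = (mean_retained + eps) / (mean_other + eps).

    The pseudocount *eps* (x coverage) keeps the ratio finite when the lost
    side has zero coverage.  Side means are length-weighted across exons by
    default (set ``length_weighted=False`` for a plain mean of per-exon
    means).
    """
    set5, set3 = partition
    if not set5 or not set3:
        raise ValueError("both partition sides must be non-empty")
    if len(set5 | set3) != len(cov.exon_lengths):
        raise ValueError("partition does not match the gene's exon count")

    def side_mean(indices: frozenset[int]) -> float:
        idx = np.array(sorted(i - 1 for i in indices))
        depths = cov.sense_mean_depth[idx]
        if length_weighted:
            weights = cov.exon_lengths[idx].astype(float)
            return float(np.average(depths, weights=weights))
        return float(depths.mean())

    mean5 = side_mean(set5)
    mean3 = side_mean(set3)
    if retained_side == "3prime":
        retained, other = mean3, mean5
    elif retained_side == "5prime":
        retained, other = mean5, mean3
    else:
        raise ValueError(f"unknown retained_side {retained_side!r}")
    fold_change = (retained + epsilon) / (other + epsilon)
    return mean5, mean3, fold_change


def auto_breakpoint(
    exon_means: Sequence[float], epsilon: float = 0.05
) -> tuple[int, float]:
    """Single changepoint in per-exon depth by an exhaustive step-model fit.

    Fits a piecewise-constant (two-mean) model to ``y_i = log2(depth_i +
    eps)`` at every candidate boundary k in 1..n-1 and returns the k
    minimising the residual sum of squares, with ties broken toward the
    smallest k, together with ``rss_gain = RSS_null - RSS(k*)`` where
    RSS_null is the single-mean fit.  The log2 transform reflects the
    multiplicative nature of coverage.  Exhaustive search is exact for a
    single changepoint and cheap at gene scale (n <= ~100 exons).

    Raises
    ------
    ValueError
        If fewer than 4 exons are supplied (no reliable fit).
    """
    y = np.log2(np.asarray(exon_means, dtype=float) + epsilon)
    n = len(y)
    if n < 4:
        raise ValueError(f"auto breakpoint needs >= 4 exons, got {n}")
    # RSS via prefix sums: RSS(segment) = sum(y^2) - (sum y)^2 / len
    c1 = np.cumsum(y)
    c2 = np.cumsum(y * y)
    total1, total2 = c1[-1], c2[-1]
    ks = np.arange(1, n)
    left1, left2 = c1[:-1], c2[:-1]
    right1, right2 = total1 - left1, total2 - left2
    rss = (left2 - left1**2 / ks) + (right2 - right1**2 / (n - ks))
    rss_null = total2 - total1**2 / n
    k_star = int(ks[np.argmin(rss)])  # argmin takes the first minimum
    gain = float(rss_null - rss[k_star - 1])
    return k_star, max(gain, 0.0)


def evaluate_imbalance(
    result: ImbalanceResult, thresholds: ImbalanceThresholds = ImbalanceThresholds()
) -> ImbalanceResult:
    """Apply the flagging rule and fill recommendation.

    Flagged iff fold-change, retained-side depth, and the retained-vs-other
    spliced-read difference all clear their thresholds; a flagged gene is
    recommended for orthogonal confirmation (e.g. a targeted fusion panel,
    which can also reveal the unknown partner).
    """
    retained_is_3 = result.breakpoint.retained_side == "3prime"
    mean_retained = result.mean3 if retained_is_3 else result.mean5
    n_retained = result.junctions.n3 if retained_is_3 else result.junctions.n5
    n_other = result.junctions.n5 if retained_is_3 else result.junctions.n3
    flagged = (
        result.fold_change >= thresholds.min_fold_change
        and mean_retained >= thresholds.min_retained_mean_depth
        and abs(n_retained - n_other) >= thresholds.min_junction_delta
    )
    return replace(
        result,
        flagged=flagged,
        recommendation="orthogonal_confirmation" if flagged else "none",
    )


def run_imbalance(
    alignments,
    gene: GeneModel,
    bp: BreakpointSpec | None = None,
    library_orientation: str = "RF",
    thresholds: ImbalanceThresholds = ImbalanceThresholds(),
    read_filter: ReadFilter = DEFAULT_FILTER,
    length_weighted: bool = True,
) -> ImbalanceResult:
    """End-to-end assay for one gene: coverage, breakpoint, statistic, flag.

    With ``bp=None`` the breakpoint is determined automatically from the
    sense depth profile; the retained side is then the side with the higher
    mean depth.
    """
    cov = stranded_exon_coverage(alignments, gene, library_orientation, read_filter)
    if bp is None:
        k_star, _ = auto_breakpoint(cov.sense_mean_depth, thresholds.pseudocount)
        m5 = cov.sense_mean_depth[:k_star].mean()
        m3 = cov.sense_mean_depth[k_star:].mean()
        bp = BreakpointSpec(
            gene_id=gene.gene_id,
            boundary_exon=k_star,
            retained_side="3prime" if m3 >= m5 else "5prime",
            source="automatic",
        )
    partition = exon_partition(gene, bp)
    mean5, mean3, fc = imbalance_statistic(
        cov, partition, bp.retained_side, thresholds.pseudocount, length_weighted
    )
    junctions = count_spliced_reads(
        alignments, gene, bp, library_orientation, read_filter
    )
    result = ImbalanceResult(
        gene_id=gene.gene_id,
        breakpoint=bp,
        mean5=mean5,
        mean3=mean3,
        fold_change=fc,
        junctions=junctions,
    )
    return evaluate_imbalance(result, thresholds)


REPORT_COLUMNS = [
    "gene_id",
    "boundary_exon",
    "retained_side",
    "source",
    "mean5",
    "mean3",
    "fold_change",
    "n5",
    "n3",
    "n_spanning",
    "flagged",
    "recommendation",
]


def write_report(results: Sequence[ImbalanceResult], out_prefix: str | Path) -> None:
    """Write the per-(gene, breakpoint) report as TSV plus a JSON twin."""
    out_prefix = Path(out_prefix)
    rows = [r.to_dict() for r in results]
    with open(f"{out_prefix}.imbalance.tsv", "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")
    with open(f"{out_prefix}.imbalance.json", "w") as fh:
        json.dump(rows, fh, indent=2)
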