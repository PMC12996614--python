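"""Shared fixtures: toy gene models, a manual SAM-record builder, and
cohort-ledger constructors used by unit and acceptance tests."""

from __future__ import annotations

import pysam
import pytest

from fusimba.cohort import CohortLedger, LedgerRow
from fusimba.gene_model import BreakpointSpec, GeneModel
from fusimba.qc_gate import QCMetrics


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": "chr1", "LN": 1_000_000}, {"SN": "chr2", "LN": 30_000_000}],
        }
    )


def make_read(
    header,
    name,
    chrom,
    start,
    cigar,
    reverse=False,
    mate=None,  # None = single-end, 1 or 2
    mapq=60,
    secondary=False,
    duplicate=False,
    proper_pair=True,
    tlen=0,
    mate_start=None,
    mate_reverse=False,
):
    """Build one alignment record; cigar like '100M' or '50M200N50M'."""
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_name = chrom
    read.reference_start = start
    read.cigarstring = cigar
    read.query_sequence = "A" * read.infer_query_length()
    read.mapping_quality = mapq
    read.is_reverse = reverse
    read.is_secondary = secondary
    read.is_duplicate = duplicate
    if mate is not None:
        read.is_paired = True
        read.is_proper_pair = proper_pair
        read.is_read1 = mate == 1
        read.is_read2 = mate == 2
        read.next_reference_name = chrom
        read.next_reference_start = mate_start if mate_start is not None else start
        read.mate_is_reverse = mate_reverse
        read.mate_is_unmapped = False
        read.template_length = tlen
    return read


def sense_pair(header, name, chrom, gene_strand, start, cigar, mate_cigar=None,
               mate_start=None):
    """An RF-convention read pair on the transcript strand of a gene.

    Mate 2 carries the gene strand, mate 1 the opposite; positions default
    to both mates at *start* (overlapping mates, legal for short inserts).
    """
    mate_cigar = mate_cigar or cigar
    mate_start = mate_start if mate_start is not None else start
    r2 = make_read(header, name, chrom, start, cigar, reverse=gene_strand == "-",
                   mate=2, mate_start=mate_start, mate_reverse=gene_strand == "+",
                   tlen=150)
    r1 = make_read(header, name, chrom, mate_start, mate_cigar,
                   reverse=gene_strand == "+", mate=1, mate_start=start,
                   mate_reverse=gene_strand == "-", tlen=-150)
    return [r2, r1]


@pytest.fixture
def single_exon_gene():
    return GeneModel("TG1", "TG1", "chr1", "+", ((1000, 1100),))


@pytest.fixture
def plus_gene():
    """6 exons of 100 bp on the plus strand, introns of 400 bp."""
    exons = tuple((1000 + i * 500, 1000 + i * 500 + 100) for i in range(6))
    return GeneModel("PLUS6", "PLUS6", "chr1", "+", exons)


@pytest.fixture
def minus_gene():
    """3 exons on the minus strand: exon 1 genomically rightmost."""
    return GeneModel("MIN3", "MIN3", "chr1", "-", ((500, 600), (300, 400), (100, 200)))


@pytest.fixture
def alk_like_gene():
    """34 exons of 150 bp on the minus strand (ALK-like geometry)."""
    genomic = [(100_000 + i * 650, 100_000 + i * 650 + 150) for i in range(34)]
    return GeneModel("ALK", "ALK", "chr2", "-", tuple(genomic[::-1]))


@pytest.fixture
def alk_breakpoint():
    return BreakpointSpec("ALK", 19, "3prime")


# ---------------------------------------------------------------------------
# cohort ledgers assembled from published summary counts
# ---------------------------------------------------------------------------


def _row(i, tcc, rna, reads, insert, n_exp, n_det, outcome):
    return LedgerRow(
        sample_id=f"s{i:04d}",
        metrics=QCMetrics(f"s{i:04d}", tcc, rna, reads, insert),
        n_fusions_expected=n_exp,
        n_fusions_detected=n_det,
        wts_outcome=outcome,
    )


def evaluation_cohort_ledger() -> CohortLedger:
    """64 samples: 48 fusion-positive (4 missed, at TCC 50/30/30/10), 16 negative."""
    rows = []
    i = 0
    for tcc in (50, 30, 30, 10):
        rows.append(_row(i, tcc, 100, 90_000_000, 135, 1, 0, "missed"))
        i += 1
    for _ in range(44):
        rows.append(_row(i, 60, 100, 90_000_000, 129, 1, 1, "detected"))
        i += 1
    for _ in range(16):
        rows.append(_row(i, 60, 100, 90_000_000, 129, 0, 0, "negative"))
        i += 1
    return CohortLedger(rows)


def validation_cohort_ledger() -> CohortLedger:
    """357 samples, 74 expected fusions, 5 missed (all at TCC 20-30%).

    QC failures: 131 below the TCC threshold, 4 below RNA input, 21 below
    unique reads, overlapping so that 144 samples fail at least one
    criterion and 213 pass all four.
    """
    rows = []
    i = 0
    # 5 missed fusions, low TCC (within the 131 TCC failures)
    for tcc in (20, 20, 30, 30, 30):
        rows.append(_row(i, tcc, 100, 90_000_000, 129, 1, 0, "missed"))
        i += 1
    for _ in range(114):  # TCC-only failures -> 119 with the five above
        rows.append(_row(i, 30, 100, 90_000_000, 129, 0, 0, "negative"))
        i += 1
    for _ in range(12):  # TCC + unique-reads failures
        rows.append(_row(i, 30, 100, 40_000_000, 129, 0, 0, "negative"))
        i += 1
    for _ in range(9):  # unique-reads-only failures
        rows.append(_row(i, 60, 100, 40_000_000, 129, 0, 0, "negative"))
        i += 1
    for _ in range(4):  # RNA-input-only failures
        rows.append(_row(i, 60, 40, 90_000_000, 129, 0, 0, "negative"))
        i += 1
    # 213 QC-pass samples; 67 fusion-positive all detected (2 carry 2 fusions
    # each) -> 69 of 74 fusions called overall
    for k in range(67):
        n = 2 if k < 2 else 1
        rows.append(_row(i, 60, 100, 90_000_000, 129, n, n, "detected"))
        i += 1
    for _ in range(213 - 67):
        rows.append(_row(i, 60, 100, 90_000_000, 129, 0, 0, "negative"))
        i += 1
    return CohortLedger(rows)


def clinical_cohort_ledger() -> CohortLedger:
    """1235 diagnostic samples of which 423 fail QC (low TCC)."""
    rows = [_row(i, 30, 100, 90_000_000, 129, 0, 0, "negative") for i in range(423)]
    rows += [
        _row(423 + i, 60, 100, 90_000_000, 129, 0, 0, "negative") for i in range(812)
    ]
    return CohortLedger(rows)
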