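"""Stranded paired-end RNA-seq simulator with known truth.

Generates coordinate-sorted SAM alignments for a single target gene that
reproduce the data-generating situation the imbalance assay faces in FFPE
tumor samples:

* a fusion transcript expressed only on the retained side of a breakpoint
  (the partner gene is unknown to the assay and is not simulated),
* wild-type full-length background present in all cells,
* tumor-cell-content (TCC) dilution — fusion depth scales with tcc/100,
* unspliced antisense pre-mRNA contamination from a neighbouring gene on
  the opposite strand,
* FFPE-like short log-normal insert sizes,
* the RF (reverse-stranded) library convention: mate 2 carries the
  transcript strand.

Fragment counts are Poisson per transcript class; fragment start positions
are uniform over the transcript, so the expected per-base depth profile is
computable exactly (a deterministic convolution over the discretized
insert-size distribution) and shipped with the truth object.  Identical
seeds give byte-identical SAM output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pysam
from scipy import stats

from .gene_model import BreakpointSpec, GeneModel

__all__ = ["SimConfig", "SimTruth", "simulate_sample", "write_sam", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated sample.

    Depth parameters are in x coverage over the relevant transcript:
    ``fusion_expression`` is the fusion-transcript depth in pure tumor
    (realized depth scales with ``tcc``/100), ``wildtype_expression`` the
    full-length transcript depth in all cells, ``antisense_premrna_depth``
    the depth of unspliced opposite-strand contamination over
    ``antisense_span`` (default: the whole gene span).  ``insert_size`` is
    (median bp, sd bp) of a log-normal, truncated to what the transcript
    can accommodate.
    """

    gene: GeneModel
    breakpoint: BreakpointSpec | None
    seed: int
    tcc: float = 100.0
    fusion_expression: float = 7.37
    wildtype_expression: float = 0.03
    antisense_premrna_depth: float = 0.0
    antisense_span: tuple[int, int] | None = None
    insert_size: tuple[float, float] = (129.0, 30.0)
    read_length: int = 50
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if not 0 <= self.tcc <= 100:
            raise ValueError("tcc must be in [0, 100]")
        if min(
            self.fusion_expression,
            self.wildtype_expression,
            self.antisense_premrna_depth,
        ) < 0:
            raise ValueError("expression depths must be >= 0")
        if self.insert_size[0] < self.read_length:
            raise ValueError("insert median must be >= read length")
        if self.breakpoint is not None:
            self.breakpoint.validate_against(self.gene)


@dataclass
class SimTruth:
    """Ground truth accompanying one simulated sample."""

    config: SimConfig
    n_fusion_fragments: int
    n_wildtype_fragments: int
    n_antisense_fragments: int
    true_boundary_exon: int | None
    expected_sense_depth: np.ndarray  # per exon, transcription order

    def to_json(self) -> str:
        cfg = self.config
        return json.dumps(
            {
                "sample_id": cfg.sample_id,
                "gene_id": cfg.gene.gene_id,
                "seed": cfg.seed,
                "tcc": cfg.tcc,
                "fusion_expression": cfg.fusion_expression,
                "wildtype_expression": cfg.wildtype_expression,
                "antisense_premrna_depth": cfg.antisense_premrna_depth,
                "insert_size": list(cfg.insert_size),
                "read_length": cfg.read_length,
                "true_boundary_exon": self.true_boundary_exon,
                "n_fusion_fragments": self.n_fusion_fragments,
                "n_wildtype_fragments": self.n_wildtype_fragments,
                "n_antisense_fragments": self.n_antisense_fragments,
                "expected_sense_depth": [float(x) for x in self.expected_sense_depth],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# insert-size distribution and analytic depth expectation
# ---------------------------------------------------------------------------


def _lognorm_sigma(median: float, sd: float) -> float:
    # Solve sd^2/median^2 = e^{s^2}(e^{s^2}-1) for the log-scale sigma.
    r2 = (sd / median) ** 2
    es2 = (1.0 + np.sqrt(1.0 + 4.0 * r2)) / 2.0
    return float(np.sqrt(np.log(es2)))


@lru_cache(maxsize=64)
def _fragment_pmf(
    median: float, sd: float, lower: int, upper: int
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Discretized log-normal pmf on integer lengths [lower, upper]."""
    if lower > upper:
        raise ValueError(
            f"infeasible geometry: transcript too short for read length "
            f"(need fragment in [{lower}, {upper}])"
        )
    if sd <= 0:
        return (int(round(median)),), (1.0,)
    sigma = _lognorm_sigma(median, sd)
    dist = stats.lognorm(s=sigma, scale=median)
    lengths = np.arange(lower, upper + 1)
    probs = dist.cdf(lengths + 1) - dist.cdf(lengths)
    total = probs.sum()
    if total <= 0:
        raise ValueError("insert-size distribution has no mass in feasible range")
    return tuple(int(x) for x in lengths), tuple(float(p) for p in probs / total)


@lru_cache(maxsize=64)
def _unit_depth_profile(
    length: int, read_length: int, median: float, sd: float
) -> tuple[float, ...]:
    """Expected per-base depth profile for target mean depth 1.0.

    For a fragment of length F placed uniformly at start s in [0, L-F], the
    two reads cover fragment offsets [0, r) and [F-r, F) with
    r = min(read_length, F); when mates overlap (F < 2r) the overlap is
    counted twice, matching a per-read pileup.  Summing the exact placement
    probabilities over the discretized insert-size pmf gives the expected
    coverage of every transcript base per expected unit of mean depth; edge
    bases receive less than interior bases.
    """
    upper = min(length, int(round(median * 4)))
    lengths, probs = _fragment_pmf(median, sd, read_length, upper)
    lengths_a = np.array(lengths)
    probs_a = np.array(probs)
    covered = 2 * np.minimum(lengths_a, read_length)
    e_covered = float((probs_a * covered).sum())
    n_exp_unit = length / e_covered  # fragments per unit mean depth

    b = np.arange(length)
    profile = np.zeros(length)
    for frag_len, p in zip(lengths, probs):
        r = min(read_length, frag_len)
        n_starts = length - frag_len + 1
        # offset intervals read by each mate; overlap contributes twice
        for o1, o2 in ((0, r), (frag_len - r, frag_len)):
            lo = np.maximum(o1, b - (length - frag_len))
            hi = np.minimum(o2 - 1, b)
            count = np.clip(hi - lo + 1, 0, None)
            profile += (n_exp_unit * p / n_starts) * count
    return tuple(float(x) for x in profile)


# ---------------------------------------------------------------------------
# transcript geometry
# ---------------------------------------------------------------------------


def _tx_to_blocks(
    exons: tuple[tuple[int, int], ...], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to sorted genomic blocks."""
    blocks = []
    offset = 0
    for s, e in exons:
        ln = e - s
        a = max(t0, offset)
        b = min(t1, offset + ln)
        if a < b:
            if strand == "+":
                blocks.append((s + a - offset, s + b - offset))
            else:
                blocks.append((e - (b - offset), e - (a - offset)))
        offset += ln
    blocks.sort()
    return blocks


def _cigar_from_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    cig = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            cig.append((3, gap))  # N
        cig.append((0, e - s))  # M
    return cig


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    blocks: list[tuple[int, int]],
    is_reverse: bool,
    is_read1: bool,
) -> pysam.AlignedSegment:
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_name = chrom
    read.reference_start = blocks[0][0]
    read.cigartuples = _cigar_from_blocks(blocks)
    length = sum(e - s for s, e in blocks)
    read.query_sequence = "A" * length
    read.mapping_quality = 60
    read.is_paired = True
    read.is_proper_pair = True
    read.is_reverse = is_reverse
    read.is_read1 = is_read1
    read.is_read2 = not is_read1
    return read


def _emit_pair(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    exons: tuple[tuple[int, int], ...],
    tx_strand: str,
    frag_start: int,
    frag_len: int,
    read_length: int,
) -> list[pysam.AlignedSegment]:
    """Build an RF-convention read pair for a sense fragment of a transcript.

    Mate 2 reads the fragment from its transcript 5' end and aligns on the
    transcript strand; mate 1 reads from the 3' end on the opposite strand.
    The template length is the RNA fragment length (the insert), signed by
    the genomically leftmost mate.
    """
    r = min(read_length, frag_len)
    read2_blocks = _tx_to_blocks(exons, tx_strand, frag_start, frag_start + r)
    read1_blocks = _tx_to_blocks(
        exons, tx_strand, frag_start + frag_len - r, frag_start + frag_len
    )
    read2 = _make_read(header, name, chrom, read2_blocks, tx_strand == "-", False)
    read1 = _make_read(header, name, chrom, read1_blocks, tx_strand == "+", True)
    for mine, mate in ((read1, read2), (read2, read1)):
        mine.next_reference_name = chrom
        mine.next_reference_start = mate.reference_start
        mine.mate_is_reverse = mate.is_reverse
        mine.mate_is_unmapped = False
    if read1.reference_start <= read2.reference_start:
        left, right = read1, read2
    else:
        left, right = read2, read1
    left.template_length = frag_len
    right.template_length = -frag_len
    return [read1, read2]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _class_exons(config: SimConfig) -> dict[str, tuple[tuple[tuple[int, int], ...], str, float]]:
    """(exons, transcript strand, target depth) per transcript class."""
    gene = config.gene
    classes: dict[str, tuple[tuple[tuple[int, int], ...], str, float]] = {}
    classes["wildtype"] = (gene.exons, gene.strand, config.wildtype_expression)
    if config.breakpoint is not None and config.fusion_expression > 0:
        k = config.breakpoint.boundary_exon
        if config.breakpoint.retained_side == "3prime":
            retained = gene.exons[k:]
        else:
            retained = gene.exons[:k]
        classes["fusion"] = (
            retained,
            gene.strand,
            config.fusion_expression * config.tcc / 100.0,
        )
    span = config.antisense_span or config.gene.span
    anti_strand = "-" if gene.strand == "+" else "+"
    # antisense pre-mRNA is unspliced: a single genomic block
    classes["antisense"] = ((span,), anti_strand, config.antisense_premrna_depth)
    return classes


def _expected_sense_depth(config: SimConfig) -> np.ndarray:
    """Exact expected sense mean depth per exon (transcription order)."""
    gene = config.gene
    median, sd = config.insert_size
    totals = np.zeros(gene.n_exons)
    lengths = np.array(gene.exon_lengths, dtype=float)
    for name, (exons, strand, depth) in _class_exons(config).items():
        if name == "antisense" or depth <= 0:
            continue
        tx_len = sum(e - s for s, e in exons)
        profile = depth * np.array(
            _unit_depth_profile(tx_len, config.read_length, median, sd)
        )
        # attribute transcript bases back to exons
        offset = 0
        first_exon_idx = gene.exons.index(exons[0])
        for j, (s, e) in enumerate(exons):
            ln = e - s
            totals[first_exon_idx + j] += profile[offset : offset + ln].sum()
            offset += ln
    return totals / lengths


def simulate_sample(
    config: SimConfig,
) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader, SimTruth]:
    """Draw one sample: coordinate-sorted alignment records plus truth.

    Fragment counts per transcript class are Poisson with mean chosen so
    that the expected mean depth over the class transcript equals the
    configured target; identical configs (including seed) give identical
    records.
    """
    gene = config.gene
    rng = np.random.default_rng(config.seed)
    median, sd = config.insert_size
    span = config.antisense_span or gene.span
    ref_len = max(gene.span[1], span[1]) + 1000
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": gene.chrom, "LN": ref_len}],
        }
    )

    records: list[pysam.AlignedSegment] = []
    realized = {"fusion": 0, "wildtype": 0, "antisense": 0}
    for name, (exons, tx_strand, depth) in _class_exons(config).items():
        if depth <= 0:
            continue
        tx_len = sum(e - s for s, e in exons)
        if tx_len < config.read_length:
            raise ValueError(
                f"infeasible geometry: {name} transcript ({tx_len} bp) shorter "
                f"than read length {config.read_length}"
            )
        upper = min(tx_len, int(round(median * 4)))
        lengths, probs = _fragment_pmf(median, sd, config.read_length, upper)
        lengths_a = np.array(lengths)
        e_covered = float(
            (np.array(probs) * 2 * np.minimum(lengths_a, config.read_length)).sum()
        )
        n_expected = depth * tx_len / e_covered
        n = int(rng.poisson(n_expected))
        realized[name] = n
        if n == 0:
            continue
        frag_lens = rng.choice(lengths_a, size=n, p=np.array(probs))
        for i in range(n):
            frag_len = int(frag_lens[i])
            start = int(rng.integers(0, tx_len - frag_len + 1))
            records.extend(
                _emit_pair(
                    header,
                    f"{config.sample_id}:{name}:{i}",
                    gene.chrom,
                    exons,
                    tx_strand,
                    start,
                    frag_len,
                    config.read_length,
                )
            )

    records.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    truth = SimTruth(
        config=config,
        n_fusion_fragments=realized["fusion"],
        n_wildtype_fragments=realized["wildtype"],
        n_antisense_fragments=realized["antisense"],
        true_boundary_exon=(
            config.breakpoint.boundary_exon if config.breakpoint else None
        ),
        expected_sense_depth=_expected_sense_depth(config),
    )
    return records, header, truth


def write_sam(
    records: list[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | Path,
) -> None:
    """Write records as plain-text SAM (deterministic for identical input)."""
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in records:
            fh.write(read)


def simulate_cohort(
    n_samples: int,
    gene: GeneModel,
    breakpoint: BreakpointSpec,
    seed: int,
    prevalence: float = 0.5,
    tcc_sampler=None,
    rna_input_sampler=None,
    fusion_expression: float = 7.0,
    wildtype_expression: float = 0.03,
    antisense_premrna_depth: float = 0.0,
    insert_size: tuple[float, float] = (129.0, 30.0),
    read_length: int = 50,
    out_dir: str | Path | None = None,
    thresholds=None,
):
    """Simulate a cohort and assemble its sample ledger.

    Each sample draws a TCC and RNA input from the supplied samplers
    (callables taking a numpy Generator; defaults: constant 50% TCC,
    constant 100 ng) and is fusion-positive with probability *prevalence*.
    The alignment-derived QC metrics (unique fragments, median insert) are
    computed from the generated reads; the imbalance assay is run to record
    the WTS outcome (detected / missed / negative).  With *out_dir* set,
    per-sample SAM and truth-JSON files are written and their paths
    recorded in the ledger.

    Returns a pandas DataFrame in the shared ledger schema.
    """
    import pandas as pd

    from .imbalance import ImbalanceThresholds, run_imbalance
    from .qc_gate import count_unique_fragments, median_insert_size

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    thresholds = thresholds or ImbalanceThresholds()
    tcc_sampler = tcc_sampler or (lambda rng: 50.0)
    rna_input_sampler = rna_input_sampler or (lambda rng: 100.0)
    rng = np.random.default_rng(seed)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for i in range(n_samples):
        sample_id = f"sim{i:04d}"
        tcc = float(tcc_sampler(rng))
        rna_input = float(rna_input_sampler(rng))
        has_fusion = bool(rng.random() < prevalence)
        child_seed = int(rng.integers(0, 2**31 - 1))
        config = SimConfig(
            gene=gene,
            breakpoint=breakpoint if has_fusion else None,
            seed=child_seed,
            tcc=tcc,
            fusion_expression=fusion_expression if has_fusion else 0.0,
            wildtype_expression=wildtype_expression,
            antisense_premrna_depth=antisense_premrna_depth,
            insert_size=insert_size,
            read_length=read_length,
            sample_id=sample_id,
        )
        records, header, truth = simulate_sample(config)
        try:
            med_insert = median_insert_size(records)
        except ValueError:
            med_insert = 0
        unique = count_unique_fragments(records)
        result = run_imbalance(records, gene, breakpoint, thresholds=thresholds)
        if has_fusion:
            outcome = "detected" if result.flagged else "missed"
        else:
            outcome = "negative"
        sam_path = truth_path = ""
        if out_dir is not None:
            sam_path = str(out_dir / f"{sample_id}.sam")
            truth_path = str(out_dir / f"{sample_id}.truth.json")
            write_sam(records, header, sam_path)
            Path(truth_path).write_text(truth.to_json())
        rows.append(
            {
                "sample_id": sample_id,
                "tcc_percent": tcc,
                "rna_input_ng": rna_input,
                "unique_reads": unique,
                "median_insert_bp": med_insert,
                "n_fusions_expected": int(has_fusion),
                "n_fusions_detected": int(has_fusion and result.flagged),
                "wts_outcome": outcome,
                "panel_outcome": "",
                "sam_path": sam_path,
                "truth_path": truth_path,
            }
        )
    return pd.DataFrame(rows)
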