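"""Cohort-level summaries: detection rate, concordance, QC breakdown, routing.

A cohort ledger is one row per sample carrying the four QC metrics, the
expected fusion truth (from an orthogonal targeted panel), and the
whole-transcriptome outcome.  The summary reports both sample-level
concordance (samples whose WTS result agrees with the panel: detected
positives plus confirmed negatives) and fusion-level concordance (individual
fusions called), since a sample may harbour more than one fusion, and the
per-criterion QC failure breakdown that drives WTS-vs-panel routing.

All percentages are rounded half-up to one decimal; the detection rate can
be rendered as an integer percentage where that is the reporting style.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Iterable

import pandas as pd

from .qc_gate import QCDecision, QCMetrics, QCThresholds, evaluate_qc

__all__ = [
    "LedgerRow",
    "CohortLedger",
    "CohortSummary",
    "summarize",
    "route_samples",
    "pct",
]

WTS_OUTCOMES = ("detected", "missed", "negative")


def pct(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100*numerator/denominator, rounded half-up to *decimals* places."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    quant = Decimal(1).scaleb(-decimals)
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LedgerRow:
    sample_id: str
    metrics: QCMetrics
    n_fusions_expected: int
    n_fusions_detected: int
    wts_outcome: str  # {detected, missed, negative}
    panel_outcome: str = ""

    def __post_init__(self) -> None:
        if self.wts_outcome not in WTS_OUTCOMES:
            raise ValueError(f"unknown wts_outcome {self.wts_outcome!r}")
        if self.wts_outcome in ("detected", "missed") and self.n_fusions_expected < 1:
            raise ValueError(
                f"{self.sample_id}: outcome {self.wts_outcome} requires an "
                "expected fusion"
            )
        if not 0 <= self.n_fusions_detected <= self.n_fusions_expected:
            raise ValueError(
                f"{self.sample_id}: detected fusions must be within expected"
            )

    @property
    def fusion_positive(self) -> bool:
        return self.n_fusions_expected > 0

    @property
    def concordant(self) -> bool:
        """Sample-level agreement with the panel, thresholds disregarded."""
        if self.fusion_positive:
            return self.wts_outcome == "detected"
        return self.wts_outcome == "negative"


LEDGER_COLUMNS = [
    "sample_id",
    "tcc_percent",
    "rna_input_ng",
    "unique_reads",
    "median_insert_bp",
    "n_fusions_expected",
    "n_fusions_detected",
    "wts_outcome",
    "panel_outcome",
]


@dataclass
class CohortLedger:
    rows: list[LedgerRow]

    def __post_init__(self) -> None:
        ids = [r.sample_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_id values must be unique")

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortLedger":
        rows = []
        for _, row in df.iterrows():
            rows.append(
                LedgerRow(
                    sample_id=str(row["sample_id"]),
                    metrics=QCMetrics(
                        sample_id=str(row["sample_id"]),
                        tcc=float(row["tcc_percent"]),
                        rna_input=float(row["rna_input_ng"]),
                        unique_reads=int(row["unique_reads"]),
                        median_insert_size=float(row["median_insert_bp"]),
                    ),
                    n_fusions_expected=int(row["n_fusions_expected"]),
                    n_fusions_detected=int(row["n_fusions_detected"]),
                    wts_outcome=str(row["wts_outcome"]),
                    panel_outcome=str(row.get("panel_outcome", "") or ""),
                )
            )
        return cls(rows)

    @classmethod
    def read_tsv(cls, path_or_stream: str | Path | IO[str]) -> "CohortLedger":
        df = pd.read_csv(path_or_stream, sep="\t", comment="#")
        missing = set(LEDGER_COLUMNS[:-1]) - set(df.columns)
        if missing:
            raise ValueError(f"ledger missing column(s): {sorted(missing)}")
        return cls.from_dataframe(df)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.rows],
                "tcc_percent": [r.metrics.tcc for r in self.rows],
                "rna_input_ng": [r.metrics.rna_input for r in self.rows],
                "unique_reads": [r.metrics.unique_reads for r in self.rows],
                "median_insert_bp": [r.metrics.median_insert_size for r in self.rows],
                "n_fusions_expected": [r.n_fusions_expected for r in self.rows],
                "n_fusions_detected": [r.n_fusions_detected for r in self.rows],
                "wts_outcome": [r.wts_outcome for r in self.rows],
                "panel_outcome": [r.panel_outcome for r in self.rows],
            }
        )


@dataclass
class CohortSummary:
    n_samples: int
    n_fusion_positive: int
    n_detected: int
    detection_rate_pct: float | None
    n_concordant_samples: int
    sample_concordance_pct: float
    n_fusions_total: int
    n_fusions_called: int
    fusion_call_rate_pct: float | None
    qc_fail_counts: dict[str, int]
    qc_fail_pcts: dict[str, float]
    n_qc_fail: int
    qc_fail_pct: float
    n_qc_pass: int
    qc_pass_pct: float
    concordance_among_qc_pass_pct: float | None
    n_routed_panel: int
    routed_panel_pct: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _decisions(
    ledger: CohortLedger, thresholds: QCThresholds
) -> list[QCDecision]:
    return [evaluate_qc(r.metrics, thresholds) for r in ledger.rows]


def summarize(
    ledger: CohortLedger,
    thresholds: QCThresholds = QCThresholds(),
    integer_detection_pct: bool = False,
) -> CohortSummary:
    """Compute the full cohort summary.

    ``integer_detection_pct`` renders the detection rate as a whole-number
    percentage (the usual reporting style for small cohorts); every other
    percentage is half-up-rounded to one decimal.  Concordance among
    QC-passing samples is computed only over rows clearing all four gate
    criteria.
    """
    if len(ledger) == 0:
        raise ValueError("empty ledger")
    rows = ledger.rows
    decisions = _decisions(ledger, thresholds)

    n = len(rows)
    positives = [r for r in rows if r.fusion_positive]
    n_pos = len(positives)
    n_detected = sum(1 for r in positives if r.wts_outcome == "detected")
    n_concordant = sum(1 for r in rows if r.concordant)
    n_fusions_total = sum(r.n_fusions_expected for r in rows)
    n_fusions_called = sum(r.n_fusions_detected for r in rows)

    fail_counts = {
        "tcc": sum(1 for d in decisions if not d.tcc_ok),
        "rna_input": sum(1 for d in decisions if not d.input_ok),
        "unique_reads": sum(1 for d in decisions if not d.reads_ok),
        "median_insert": sum(1 for d in decisions if not d.insert_ok),
    }
    n_fail = sum(1 for d in decisions if not d.overall_pass)
    n_pass = n - n_fail
    qc_pass_rows = [r for r, d in zip(rows, decisions) if d.overall_pass]
    concordance_qc_pass = (
        pct(sum(1 for r in qc_pass_rows if r.concordant), len(qc_pass_rows))
        if qc_pass_rows
        else None
    )

    detection_rate = None
    if n_pos:
        detection_rate = pct(n_detected, n_pos, 0 if integer_detection_pct else 1)
    return CohortSummary(
        n_samples=n,
        n_fusion_positive=n_pos,
        n_detected=n_detected,
        detection_rate_pct=detection_rate,
        n_concordant_samples=n_concordant,
        sample_concordance_pct=pct(n_concordant, n),
        n_fusions_total=n_fusions_total,
        n_fusions_called=n_fusions_called,
        fusion_call_rate_pct=(
            pct(n_fusions_called, n_fusions_total) if n_fusions_total else None
        ),
        qc_fail_counts=fail_counts,
        qc_fail_pcts={k: pct(v, n) for k, v in fail_counts.items()},
        n_qc_fail=n_fail,
        qc_fail_pct=pct(n_fail, n),
        n_qc_pass=n_pass,
        qc_pass_pct=pct(n_pass, n),
        concordance_among_qc_pass_pct=concordance_qc_pass,
        n_routed_panel=n_fail,
        routed_panel_pct=pct(n_fail, n),
    )


def route_samples(
    ledger: CohortLedger, thresholds: QCThresholds = QCThresholds()
) -> tuple[pd.DataFrame, dict]:
    """Per-sample routing table plus routing tallies.

    Every sample receives exactly one routing value: WTS when all four QC
    criteria pass, otherwise fallback to a targeted panel.
    """
    decisions = _decisions(ledger, thresholds)
    table = pd.DataFrame([d.to_dict() for d in decisions])
    n_routed = int((table["routing"] == "targeted_panel").sum())
    tallies = {
        "n_samples": len(ledger),
        "n_routed_panel": n_routed,
        "routed_panel_pct": pct(n_routed, len(ledger)),
        "n_wts": len(ledger) - n_routed,
    }
    return table, tallies


def verify_outcomes(
    ledger: CohortLedger, concordance: Iterable
) -> list[str]:
    """Cross-check ledger outcomes against recomputed concordance records.

    *concordance* holds per-sample records (from the fusion-filter truth
    matcher) with ``sample_id`` and ``outcome`` attributes.  Returns the
    sample_ids whose ledger outcome disagrees with the recomputed one;
    an empty list means the ledger is consistent with the raw calls.
    """
    expected_outcome = {
        "detected": "true_positive",
        "missed": "false_negative",
        "negative": "true_negative",
    }
    by_sample = {rec.sample_id: rec.outcome for rec in concordance}
    mismatches = []
    for row in ledger.rows:
        recomputed = by_sample.get(row.sample_id)
        if recomputed is None:
            continue
        if recomputed != expected_outcome[row.wts_outcome]:
            mismatches.append(row.sample_id)
    return mismatches


def write_summary(summary: CohortSummary, out_prefix: str | Path) -> None:
    out_prefix = Path(out_prefix)
    data = summary.to_dict()
    with open(f"{out_prefix}.summary.json", "w") as fh:
        json.dump(data, fh, indent=2)
    flat = {
        k: v for k, v in data.items() if not isinstance(v, dict)
    }
    pd.DataFrame([flat]).to_csv(f"{out_prefix}.summary.tsv", sep="\t", index=False)
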