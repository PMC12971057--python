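"""Benchmarking against curated truth, and census summaries.

Precision = tp/(tp+fp), recall = tp/(tp+fn), and F1 is the harmonic mean
2·(precision·recall)/(precision+recall). A zero denominator makes the
affected metric 0 and sets the ``degenerate`` flag instead of raising, so
batch benchmarking never crashes on an empty prediction set.

Reported values are rounded half-up to match conventional reporting:
precision/recall to two decimals or whole percent, F1 to two decimals.
Census percentages are whole-percent, with one decimal kept below 10%.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .classifiers import ChelatorProfile, ClassificationResult

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CensusSummary",
    "confusion",
    "compute_metrics",
    "f1_score",
    "census_percent",
    "census",
    "combination_counts",
    "round_half_up",
    "format_percent",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.8616 -> 0.86; 92.5 -> 93)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(fraction: float) -> str:
    """Format a fraction in [0,1] as a whole percent, half-up."""
    return f"{round_half_up(100 * fraction):.0f}%"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    degenerate: bool = False

    @property
    def precision_str(self) -> str:
        return f"{round_half_up(self.precision, 2):.2f}"

    @property
    def recall_str(self) -> str:
        return f"{round_half_up(self.recall, 2):.2f}"

    @property
    def f1_str(self) -> str:
        return f"{round_half_up(self.f1, 2):.2f}"

    @property
    def precision_pct(self) -> str:
        return format_percent(self.precision)

    @property
    def recall_pct(self) -> str:
        return format_percent(self.recall)


def confusion(
    predictions: Mapping, truth: Mapping
) -> ConfusionCounts:
    """Tally the 2x2 confusion table over identically-keyed verdict maps."""
    if set(predictions) != set(truth):
        diff = set(predictions).symmetric_difference(truth)
        raise ValueError(f"prediction/truth key mismatch: {sorted(map(str, diff))}")
    tp = fp = fn = tn = 0
    for key, pred in predictions.items():
        true = truth[key]
        if pred and true:
            tp += 1
        elif pred and not true:
            fp += 1
        elif not pred and true:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Precision/recall/F1 from confusion counts (degenerate-safe)."""
    degenerate = False
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        precision, degenerate = 0.0, True
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
    return MetricsReport(precision, recall, f1, degenerate)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic-mean F1 from already-computed precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def census_percent(positives: int, total: int) -> float | None:
    """Percentage at reporting precision: whole percent, one decimal < 10%."""
    if total == 0:
        return None
    pct = 100 * positives / total
    return round_half_up(pct, 1) if pct < 10 else round_half_up(pct)


@dataclass(frozen=True)
class CensusSummary:
    """Per-stratum metallophore counts for each method, plus group combos."""

    totals: Mapping[str, int]  # stratum -> number of NRPS regions
    positives: Mapping[str, Mapping[str, int]]  # method -> stratum -> count
    percentages: Mapping[str, Mapping[str, float | None]]
    combination_counts: Mapping[tuple[str, ...], int]

    METHODS = ("chelator", "transporter", "ensemble")
    STRATA = ("complete", "partial", "total")


def census(results: Iterable[ClassificationResult]) -> CensusSummary:
    """Summarize classification results per method and completeness stratum."""
    results = list(results)
    totals = {
        "complete": sum(1 for r in results if r.complete),
        "partial": sum(1 for r in results if not r.complete),
        "total": len(results),
    }
    flags = {
        "chelator": lambda r: r.chelator_rule,
        "transporter": lambda r: r.transporter_rule,
        "ensemble": lambda r: r.ensemble,
    }
    positives: dict[str, dict[str, int]] = {}
    percentages: dict[str, dict[str, float | None]] = {}
    for method, f in flags.items():
        pos = {
            "complete": sum(1 for r in results if r.complete and f(r)),
            "partial": sum(1 for r in results if not r.complete and f(r)),
        }
        pos["total"] = pos["complete"] + pos["partial"]
        positives[method] = pos
        percentages[method] = {
            s: census_percent(pos[s], totals[s]) for s in CensusSummary.STRATA
        }
    combos = combination_counts(
        r.profile for r in results if r.chelator_rule and r.complete
    )
    return CensusSummary(totals, positives, percentages, combos)


def combination_counts(
    profiles: Iterable[ChelatorProfile],
) -> dict[tuple[str, ...], int]:
    """Tally chelating-group combinations (upset-plot input).

    Each profile with nonempty groups contributes exactly one key: the
    sorted tuple of its groups. Marker-only detections (VibH_like/Cy_tandem
    without chelator biosynthesis) appear as the ("NRPS-domain-marker",)
    class of their own.
    """
    counts: Counter[tuple[str, ...]] = Counter()
    for p in profiles:
        if p.groups:
            counts[tuple(sorted(p.groups))] += 1
    return dict(counts)
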