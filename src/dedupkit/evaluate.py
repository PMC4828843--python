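"""Quality and complexity metrics against a gold standard.

Indexing-aware de-duplication quality is summarized by four standard
quantities:

* pairs quality (PQ, a precision analogue): matching pairs found / candidate
  pairs generated;
* pairs completeness (PC, a recall analogue): matching pairs found / total
  true matching pairs;
* reduction ratio (RR): 1 - candidate pairs / total record pairs C(n, 2);
* F-score: the harmonic mean 2*PC*RR / (PC + RR), trading off completeness
  against comparison cost.

The expected number of true matching pairs of a synthetic dataset follows
from its duplicate ratio DR and duplicates-per-record d:
DR * (n/d) * [d + d(d-1)/2].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .core import GoldStandard

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "DatasetProfile",
    "confusion",
    "metrics",
    "expected_matching_pairs",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN over all C(n, 2) record pairs."""

    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    pq: float
    pc: float
    rr: float
    f_score: float
    candidate_count: int
    match_count: int
    total_pairs: int
    total_true_pairs: int


def confusion(
    reported: set[tuple[str, str]], gold: GoldStandard, n: int
) -> ConfusionMatrix:
    """Confusion matrix of reported match pairs against the gold standard.

    TN is derived: C(n, 2) minus the other three cells.
    """
    true_pairs = gold.true_match_pairs
    tp = len(reported & true_pairs)
    fp = len(reported - true_pairs)
    fn = len(true_pairs - reported)
    total = n * (n - 1) // 2
    return ConfusionMatrix(TP=tp, FP=fp, FN=fn, TN=total - tp - fp - fn)


def metrics(
    candidate_count: int,
    match_count: int,
    total_true_pairs: int,
    n: int,
) -> MetricsReport:
    """PQ, PC, RR and F-score from run counts.

    Zero denominators yield a 0 metric with a warning rather than an error,
    so degenerate runs (no candidates, no true pairs) still produce a report.
    """
    total_pairs = n * (n - 1) // 2
    if candidate_count > total_pairs:
        raise ValueError("candidate_count exceeds total record pairs")
    if match_count > candidate_count:
        raise ValueError("match_count exceeds candidate_count")

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
            return 0.0
        return num / den

    pq = _ratio(match_count, candidate_count, "pairs quality")
    pc = _ratio(match_count, total_true_pairs, "pairs completeness")
    rr = 1.0 - _ratio(candidate_count, total_pairs, "reduction ratio")
    f = 2 * pc * rr / (pc + rr) if (pc + rr) > 0 else 0.0
    return MetricsReport(
        pq=pq,
        pc=pc,
        rr=rr,
        f_score=f,
        candidate_count=candidate_count,
        match_count=match_count,
        total_pairs=total_pairs,
        total_true_pairs=total_true_pairs,
    )


@dataclass(frozen=True)
class DatasetProfile:
    """Duplicate structure of a synthetic dataset: size n, duplicate ratio
    DR (duplicates / n), and duplicates per duplicated original d."""

    n: int
    DR: float
    d: int

    def __post_init__(self) -> None:
        if self.n < 1 or self.d < 1 or not (0.0 <= self.DR <= 1.0):
            raise ValueError("need n >= 1, d >= 1, 0 <= DR <= 1")


def expected_matching_pairs(p: DatasetProfile) -> float:
    """Expected true matching pairs: DR * (n/d) * [d + d(d-1)/2].

    Each of the DR*n/d duplicated originals contributes d original-duplicate
    pairs plus C(d, 2) duplicate-duplicate pairs.
    """
    return p.DR * (p.n / p.d) * (p.d + p.d * (p.d - 1) / 2)
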