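"""Two-threshold classification of scored candidate pairs.

A pair with aggregate score F is a Match when F >= T_U, a Non-Match when
F < T_L, and a Possible Match in between (T_L <= F < T_U). Setting both
thresholds to 1.0 gives the deterministic rule: exact agreement on all
linking fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import Dataset
from .compare import FieldRule, WeightVector, compare_pair

__all__ = [
    "MATCH",
    "POSSIBLE_MATCH",
    "NON_MATCH",
    "Thresholds",
    "ClassificationResult",
    "classify_pair",
    "classify_pairs",
]

MATCH = "match"
POSSIBLE_MATCH = "possible_match"
NON_MATCH = "non_match"

#: Deterministic mode: a match requires exact agreement on every field.
DETERMINISTIC = (1.0, 1.0)


@dataclass(frozen=True)
class Thresholds:
    """Lower/upper classification bounds, 0 <= t_lower <= t_upper <= 1."""

    t_lower: float = 0.5
    t_upper: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_lower <= self.t_upper <= 1.0):
            raise ValueError(
                f"need 0 <= t_lower <= t_upper <= 1, got "
                f"({self.t_lower}, {self.t_upper})"
            )


@dataclass
class ClassificationResult:
    """Partition of the classified pairs into the three outcome classes."""

    matches: set[tuple[str, str]] = field(default_factory=set)
    possible_matches: set[tuple[str, str]] = field(default_factory=set)
    non_matches: set[tuple[str, str]] = field(default_factory=set)
    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    @property
    def labels(self) -> dict[tuple[str, str], str]:
        out = {p: MATCH for p in self.matches}
        out.update({p: POSSIBLE_MATCH for p in self.possible_matches})
        out.update({p: NON_MATCH for p in self.non_matches})
        return out

    @property
    def n_classified(self) -> int:
        return len(self.matches) + len(self.possible_matches) + len(self.non_matches)


def classify_pair(wv: WeightVector, th: Thresholds) -> str:
    """Three-way rule with inclusive upper boundary: F >= T_U is a Match."""
    if wv.F >= th.t_upper:
        return MATCH
    if wv.F < th.t_lower:
        return NON_MATCH
    return POSSIBLE_MATCH


def classify_pairs(
    cands: Iterable[tuple[str, str]],
    ds: Dataset,
    rules: Sequence[FieldRule],
    th: Thresholds,
) -> ClassificationResult:
    """Compare and classify every candidate pair.

    Raises ``KeyError`` if a pair references an unknown rec_id.
    """
    result = ClassificationResult()
    for id_a, id_b in cands:
        try:
            rec_a, rec_b = ds.by_id[id_a], ds.by_id[id_b]
        except KeyError as exc:
            raise KeyError(f"candidate pair references unknown rec_id {exc}") from None
        wv = compare_pair(rec_a, rec_b, rules)
        pair = (id_a, id_b) if id_a < id_b else (id_b, id_a)
        result.scores[pair] = wv.F
        label = classify_pair(wv, th)
        if label == MATCH:
            result.matches.add(pair)
        elif label == POSSIBLE_MATCH:
            result.possible_matches.add(pair)
        else:
            result.non_matches.add(pair)
    return result
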