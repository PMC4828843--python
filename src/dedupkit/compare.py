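"""Field comparators and weight-vector assembly for candidate record pairs.

Each linking field is scored in [0, 1] by an approximate comparator
(edit-distance, q-gram overlap, soundex agreement or prefix agreement); the
per-field similarities form the weight (comparison) vector, aggregated into a
single match score F as the weighted arithmetic mean. F = 1 means full
agreement on every linking field, F = 0 full disagreement.

Missing values: if either side of a field is empty the similarity is 0
(disagreement) by default; with ``missing_ignore`` the field is dropped from
the mean instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import edlib

from .core import Record
from .encodings import soundex, substring_prefix

__all__ = [
    "edit_distance_sim",
    "qgram_sim",
    "soundex_exact_sim",
    "substring_exact_sim",
    "FieldRule",
    "WeightVector",
    "compare_pair",
    "default_rules",
]


def edit_distance_sim(a: str, b: str) -> float:
    """Normalized Levenshtein similarity: 1 - dist(a, b) / max(|a|, |b|).

    Returns 0.0 when either value is missing (empty).
    """
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def _qgrams(s: str, q: int) -> dict[str, int]:
    grams: dict[str, int] = {}
    for k in range(len(s) - q + 1):
        g = s[k : k + q]
        grams[g] = grams.get(g, 0) + 1
    return grams


def qgram_sim(a: str, b: str, q: int = 2) -> float:
    """q-gram overlap similarity: common q-grams over the average q-gram
    count, without padding. 0.0 when either side has no q-grams."""
    if q < 1:
        raise ValueError("q must be >= 1")
    ga, gb = _qgrams(a, q), _qgrams(b, q)
    ca, cb = sum(ga.values()), sum(gb.values())
    if ca == 0 or cb == 0:
        return 0.0
    common = sum(min(cnt, gb.get(g, 0)) for g, cnt in ga.items())
    return common / ((ca + cb) / 2)


def soundex_exact_sim(a: str, b: str) -> float:
    """1.0 iff both values are non-empty and share a soundex code."""
    ca, cb = soundex(a), soundex(b)
    return 1.0 if ca and ca == cb else 0.0


def substring_exact_sim(a: str, b: str, k: int = 4) -> float:
    """1.0 iff both values are non-empty and agree on their first k chars."""
    if not a or not b:
        return 0.0
    return 1.0 if substring_prefix(a, k) == substring_prefix(b, k) else 0.0


@dataclass(frozen=True)
class FieldRule:
    """How one linking field is compared.

    ``q`` applies to the qgram comparator, ``prefix_len`` to substring_exact;
    ``weight`` is the field's contribution to the aggregate mean.
    """

    field: str
    comparator: Literal[
        "edit_distance", "qgram", "soundex_exact", "substring_exact"
    ]
    q: int = 2
    prefix_len: int = 4
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.comparator not in (
            "edit_distance",
            "qgram",
            "soundex_exact",
            "substring_exact",
        ):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")

    def sim(self, a: str, b: str) -> float:
        if self.comparator == "edit_distance":
            return edit_distance_sim(a, b)
        if self.comparator == "qgram":
            return qgram_sim(a, b, self.q)
        if self.comparator == "soundex_exact":
            return soundex_exact_sim(a, b)
        return substring_exact_sim(a, b, self.prefix_len)


@dataclass(frozen=True)
class WeightVector:
    """Per-field similarities for one candidate pair plus the aggregate F."""

    pair: tuple[str, str]
    sims: tuple[float, ...]
    F: float


def compare_pair(
    rec_a: Record,
    rec_b: Record,
    rules: Sequence[FieldRule],
    missing_ignore: bool = False,
) -> WeightVector:
    """Score a candidate pair over the linking-field rules.

    F is the weighted arithmetic mean of the per-field similarities. With
    ``missing_ignore``, fields missing on either side are excluded from the
    mean (their sims are still reported as 0); if every field is excluded,
    F = 0.
    """
    if not rules:
        raise ValueError("need at least one field rule")
    sims: list[float] = []
    num = den = 0.0
    for rule in rules:
        va, vb = rec_a.get(rule.field), rec_b.get(rule.field)
        s = rule.sim(va, vb)
        sims.append(s)
        if missing_ignore and (not va or not vb):
            continue
        num += rule.weight * s
        den += rule.weight
    f = num / den if den > 0 else 0.0
    pair = (rec_a.rec_id, rec_b.rec_id)
    return WeightVector(pair=pair, sims=tuple(sims), F=f)


def default_rules(
    name_comparator: Literal["soundex_exact", "substring_exact"] = "soundex_exact",
    prefix_len: int = 4,
) -> list[FieldRule]:
    """Standard linking-field rules: postcode and soc_sec_id by edit
    distance, address_1 by bigram overlap, given_name and surname by phonetic
    or prefix agreement (mirroring the run's indexing encoding)."""
    return [
        FieldRule("postcode", "edit_distance"),
        FieldRule("address_1", "qgram", q=2),
        FieldRule("soc_sec_id", "edit_distance"),
        FieldRule("given_name", name_comparator, prefix_len=prefix_len),
        FieldRule("surname", name_comparator, prefix_len=prefix_len),
    ]
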