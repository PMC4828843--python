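"""Inverted indexes, candidate-pair generation and comparison-count
estimators.

Two pair-generation strategies are supported on top of the same inverted
index:

* **blocking** — compare only records sharing a bucket (equal encoded key);
* **windowing** (sorted-neighborhood) — sort the buckets by key value and
  slide a fixed window of ``w`` consecutive buckets, comparing every pair of
  records that co-occurs in some window position.

Multiple passes with different keys are combined by set union of their
candidate pairs.

The ``est_*`` functions are the closed-form average-case comparison counts
under the uniform-block-size assumption (each of ``b`` blocks holds ``n/b``
records). They return reals, not integers: they are expectations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .core import Dataset, canonical_pair, pairs_within
from .encodings import KeySpec, build_key

__all__ = [
    "InvertedIndex",
    "ComplexityParams",
    "build_index",
    "block_pairs",
    "window_pairs",
    "multipass_union",
    "est_block_comparisons",
    "est_skb_comparisons",
    "est_ckb_comparisons",
    "est_mpb_comparisons",
    "est_window_comparisons",
]


@dataclass
class InvertedIndex:
    """Map from encoded key value to the ordered list of rec_ids sharing it.

    Records whose key is empty for this pass are excluded by default (they
    carry no usable key); pass ``empty_key_bucket=True`` to
    :func:`build_index` to pool them into a single ``""`` bucket instead.
    """

    buckets: dict[str, list[str]]

    @property
    def sorted_keys(self) -> list[str]:
        return sorted(self.buckets)

    @property
    def b(self) -> int:
        return len(self.buckets)


def build_index(
    ds: Dataset, spec: KeySpec, empty_key_bucket: bool = False
) -> InvertedIndex:
    """Bucket the dataset's records by their encoded blocking-key value."""
    buckets: dict[str, list[str]] = {}
    for rec in ds:
        key = build_key(rec, spec)
        if key == "" and not empty_key_bucket:
            continue
        buckets.setdefault(key, []).append(rec.rec_id)
    return InvertedIndex(buckets)


def block_pairs(ix: InvertedIndex) -> set[tuple[str, str]]:
    """All within-bucket unordered pairs: C(m, 2) per bucket of size m."""
    pairs: set[tuple[str, str]] = set()
    for ids in ix.buckets.values():
        pairs |= pairs_within(ids)
    return pairs


def window_pairs(ix: InvertedIndex, w: int) -> set[tuple[str, str]]:
    """Sorted-neighborhood candidate pairs for window size ``w``.

    Buckets are ordered by ascending key value; a window covers ``w``
    consecutive buckets (a single all-bucket window when ``b <= w``). Two
    records form a candidate pair iff their buckets co-occur in some window
    position, i.e. iff their bucket indices differ by less than ``w``.
    ``w = 1`` degenerates to plain blocking.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    keys = ix.sorted_keys
    lists = [ix.buckets[k] for k in keys]
    pairs: set[tuple[str, str]] = set()
    for i, ids_i in enumerate(lists):
        pairs |= pairs_within(ids_i)
        for j in range(i + 1, min(i + w, len(lists))):
            for a in ids_i:
                for b_id in lists[j]:
                    pairs.add(canonical_pair(a, b_id))
    return pairs


def multipass_union(
    pair_sets: Iterable[set[tuple[str, str]]],
) -> set[tuple[str, str]]:
    """Deduplicated union of per-pass candidate-pair sets."""
    pair_sets = list(pair_sets)
    if not pair_sets:
        raise ValueError("need at least one pair set")
    out: set[tuple[str, str]] = set()
    for s in pair_sets:
        out |= s
    return out


@dataclass(frozen=True)
class ComplexityParams:
    """Inputs to the average-case comparison-count estimators.

    n: dataset size; b: block count; w: window size; i, j: number of distinct
    values of the first and second blocking key (``i >= j``).
    """

    n: int
    b: int = 1
    w: int = 1
    i: int = 1
    j: int = 1

    def __post_init__(self) -> None:
        if self.n < 1 or self.b < 1 or self.w < 1:
            raise ValueError("n, b, w must be >= 1")
        if self.i < self.j or self.j < 1:
            raise ValueError("need i >= j >= 1")


def est_block_comparisons(p: ComplexityParams) -> float:
    """Average comparisons for blocking with ``b`` uniform blocks:
    b * [(n/b)((n/b) - 1)] / 2."""
    s = p.n / p.b
    return p.b * (s * (s - 1)) / 2


def est_skb_comparisons(p: ComplexityParams) -> float:
    """Single-key blocking: ``i`` blocks of average size n/i."""
    s = p.n / p.i
    return p.i * (s * (s - 1)) / 2


def est_ckb_comparisons(p: ComplexityParams) -> float:
    """Composite-key blocking on keys with i and j distinct values:
    on average i*j/2 blocks of size 2n/(i*j)."""
    blocks = p.i * p.j / 2
    s = p.n / blocks
    return blocks * (s * (s - 1)) / 2


def est_mpb_comparisons(p: ComplexityParams) -> float:
    """Two-pass multipass blocking: sum of the single-key costs for the two
    keys (i then j distinct values)."""
    si, sj = p.n / p.i, p.n / p.j
    return p.i * (si * (si - 1)) / 2 + p.j * (sj * (sj - 1)) / 2


def est_window_comparisons(p: ComplexityParams) -> float:
    """Sorted-neighborhood cost with ``b`` uniform blocks and window ``w``.

    First window: C(wn/b, 2) comparisons; each of the remaining ``b - w``
    positions introduces one new block, adding its internal pairs plus its
    cross pairs against the ``w - 1`` blocks retained from the previous
    position. With ``w = 1`` this reduces to the blocking estimate.
    """
    if p.w > p.b:
        raise ValueError("window size must not exceed block count")
    n, b, w = p.n, p.b, p.w
    s = n / b
    first = (w * s) * (w * s - 1) / 2
    per_slide = s * (s - 1) / 2 + (w - 1) * s * s
    return first + (b - w) * per_slide
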