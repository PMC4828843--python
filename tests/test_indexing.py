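"""Pair generation and the closed-form comparison-count estimators, checked
against independent brute-force oracles."""

import itertools
import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dedupkit import (
    ComplexityParams,
    Dataset,
    InvertedIndex,
    KeySpec,
    block_pairs,
    build_index,
    est_block_comparisons,
    est_ckb_comparisons,
    est_mpb_comparisons,
    est_skb_comparisons,
    est_window_comparisons,
    multipass_union,
    window_pairs,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# brute-force oracles, deliberately naive
# ---------------------------------------------------------------------------

def brute_block_pairs(keys: dict[str, str]) -> set[tuple[str, str]]:
    """Candidate iff both keyed and keys equal, over all C(n,2) pairs."""
    return {
        tuple(sorted((a, b)))
        for a, b in itertools.combinations(keys, 2)
        if keys[a] and keys[a] == keys[b]
    }


def brute_window_pairs(keys: dict[str, str], w: int) -> set[tuple[str, str]]:
    """Enumerate every literal window position over the sorted buckets."""
    kvs = sorted({k for k in keys.values() if k})
    buckets = [[r for r, k in keys.items() if k == kv] for kv in kvs]
    if not buckets:
        return set()
    n_windows = max(len(buckets) - w + 1, 1)
    pairs: set[tuple[str, str]] = set()
    for p in range(n_windows):
        members = [r for bucket in buckets[p : p + w] for r in bucket]
        pairs |= {tuple(sorted(x)) for x in itertools.combinations(members, 2)}
    return pairs


def dataset_from_keys(keys: dict[str, str]) -> tuple[Dataset, KeySpec]:
    """Dataset whose substring-key equals the literal key value."""
    ds = Dataset([make_record(r, given_name=k) for r, k in keys.items()])
    return ds, KeySpec(fields=("given_name",), encoder="substring", prefix_len=32)


def random_keys(rng: random.Random, n: int) -> dict[str, str]:
    alphabet = ["", "a", "b", "c", "d", "ab", "ba", "abc", "e"]
    return {f"r{i:02d}": rng.choice(alphabet) for i in range(n)}


# ---------------------------------------------------------------------------
# build_index
# ---------------------------------------------------------------------------

def test_build_index_buckets_and_order():
    ds, spec = dataset_from_keys({"r1": "a", "r2": "a", "r3": "b"})
    ix = build_index(ds, spec)
    assert ix.b == 2
    assert ix.sorted_keys == ["a", "b"]
    assert sorted(map(len, ix.buckets.values())) == [1, 2]


def test_build_index_excludes_empty_keys_by_default():
    ds, spec = dataset_from_keys({"r1": "a", "r2": "", "r3": "a"})
    ix = build_index(ds, spec)
    assert ix.buckets == {"a": ["r1", "r3"]}


def test_build_index_empty_key_bucket_flag_pools():
    ds, spec = dataset_from_keys({"r1": "a", "r2": "", "r3": ""})
    ix = build_index(ds, spec, empty_key_bucket=True)
    assert ix.buckets[""] == ["r2", "r3"]


def test_all_distinct_keys_gives_singleton_buckets():
    ds, spec = dataset_from_keys({f"r{i}": f"k{i}" for i in range(5)})
    ix = build_index(ds, spec)
    assert ix.b == 5
    assert block_pairs(ix) == set()


# ---------------------------------------------------------------------------
# pair generation vs oracle
# ---------------------------------------------------------------------------

def test_block_pairs_single_bucket_is_binomial():
    ix = InvertedIndex({"k": [f"r{i}" for i in range(5)]})
    assert len(block_pairs(ix)) == math.comb(5, 2) == 10


def test_window_pairs_worked_example():
    # sorted buckets [r1,r2], [r3], [r4]; w=2 -> 4 pairs
    ix = InvertedIndex({"a": ["r1", "r2"], "b": ["r3"], "c": ["r4"]})
    assert window_pairs(ix, 2) == {
        ("r1", "r2"),
        ("r1", "r3"),
        ("r2", "r3"),
        ("r3", "r4"),
    }


def test_window_size_one_degenerates_to_blocking():
    rng = random.Random(0)
    for _ in range(10):
        keys = random_keys(rng, 20)
        ds, spec = dataset_from_keys(keys)
        ix = build_index(ds, spec)
        assert window_pairs(ix, 1) == block_pairs(ix)


def test_window_covering_all_buckets_gives_all_pairs():
    ix = InvertedIndex({"a": ["r1", "r2"], "b": ["r3", "r4", "r5"]})
    assert len(window_pairs(ix, 5)) == math.comb(5, 2)


@pytest.mark.parametrize("w", [1, 2, 3, 7])
def test_pair_generation_matches_brute_force(w):
    rng = random.Random(42)
    for n in (0, 1, 5, 20, 50):
        keys = random_keys(rng, n)
        ds, spec = dataset_from_keys(keys)
        ix = build_index(ds, spec)
        assert block_pairs(ix) == brute_block_pairs(keys)
        assert window_pairs(ix, w) == brute_window_pairs(keys, w)


def test_window_pairs_monotone_in_w():
    rng = random.Random(1)
    keys = random_keys(rng, 40)
    ds, spec = dataset_from_keys(keys)
    ix = build_index(ds, spec)
    previous: set = set()
    for w in range(1, ix.b + 1):
        current = window_pairs(ix, w)
        assert current >= previous
        previous = current


def test_multipass_union():
    assert multipass_union([{("a", "b")}, {("b", "c")}]) == {("a", "b"), ("b", "c")}
    assert multipass_union([{("a", "b")}, {("a", "b")}]) == {("a", "b")}
    s1 = {("a", "b"), ("a", "c"), ("a", "d")}
    s2 = {("e", "f"), ("e", "g"), ("e", "h"), ("g", "h")}
    assert len(multipass_union([s1, s2])) == 7
    with pytest.raises(ValueError):
        multipass_union([])


def test_composite_blocking_never_exceeds_single_key(profile_a):
    # blocks on (given_name, surname) refine blocks on given_name alone,
    # for records where both key fields are present (a record missing one
    # field drops out of that single-key pass but can still carry a
    # composite key built from the other field)
    ds, _ = profile_a
    full = ds.subset(
        {
            r.rec_id
            for r in ds
            if r.get("given_name") and r.get("surname")
        }
    )
    comp = KeySpec(fields=("given_name", "surname"), encoder="soundex")
    ckb = block_pairs(build_index(full, comp))
    for f in ("given_name", "surname"):
        skb = block_pairs(build_index(full, KeySpec(fields=(f,), encoder="soundex")))
        assert ckb <= skb


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def exact_uniform_block_count(n: int, b: int) -> float:
    """Enumerated comparisons for b uniform blocks of size n/b."""
    s = n // b
    return b * math.comb(s, 2)


def exact_uniform_window_count(n: int, b: int, w: int) -> int:
    """Enumerated pair count for windowing over b uniform blocks."""
    s = n // b
    keys = {}
    r = 0
    for blk in range(b):
        for _ in range(s):
            keys[f"r{r:04d}"] = f"k{blk:04d}"
            r += 1
    return len(brute_window_pairs(keys, w))


def test_est_block_comparisons_worked_values():
    assert est_block_comparisons(ComplexityParams(n=1000, b=1)) == 499500
    assert est_block_comparisons(ComplexityParams(n=100, b=10)) == 450
    assert est_block_comparisons(ComplexityParams(n=7, b=7)) == 0


def test_est_skb_ckb_mpb_worked_values():
    assert est_skb_comparisons(ComplexityParams(n=1000, i=10, j=1)) == 49500
    assert est_ckb_comparisons(ComplexityParams(n=1000, i=10, j=4)) == 24500
    assert est_mpb_comparisons(ComplexityParams(n=1000, i=10, j=10)) == 99000


def test_est_window_worked_value():
    assert est_window_comparisons(ComplexityParams(n=100, b=10, w=2)) == 1350


def test_est_window_at_w1_equals_blocking():
    for n, b in [(100, 10), (1000, 8), (60, 3), (200, 200)]:
        p = ComplexityParams(n=n, b=b, w=1)
        assert est_window_comparisons(p) == pytest.approx(est_block_comparisons(p))


def test_estimators_match_enumeration_on_uniform_blocks():
    for n in (12, 60, 120, 200):
        for b in (1, 2, 3, 4, 6):
            if n % b:
                continue
            p = ComplexityParams(n=n, b=b)
            assert est_block_comparisons(p) == exact_uniform_block_count(n, b)
            for w in range(1, b + 1):
                pw = ComplexityParams(n=n, b=b, w=w)
                assert est_window_comparisons(pw) == exact_uniform_window_count(
                    n, b, w
                )


def test_est_window_full_window_is_all_pairs():
    p = ComplexityParams(n=120, b=6, w=6)
    assert est_window_comparisons(p) == math.comb(120, 2)


def test_ckb_estimate_below_skb_for_j_at_least_2():
    for i, j in [(10, 2), (10, 4), (50, 50)]:
        p = ComplexityParams(n=1000, i=i, j=j)
        assert est_ckb_comparisons(p) <= est_skb_comparisons(p)


@settings(derandomize=True, max_examples=100)
@given(st.integers(1, 200), st.integers(1, 20))
def test_est_block_nonnegative_and_bounded(n, b):
    if b > n:
        return
    val = est_block_comparisons(ComplexityParams(n=n, b=b))
    assert 0 <= val <= math.comb(n, 2)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ComplexityParams(n=0)
    with pytest.raises(ValueError):
        ComplexityParams(n=10, i=2, j=5)
    with pytest.raises(ValueError):
        est_window_comparisons(ComplexityParams(n=10, b=2, w=3))
    with pytest.raises(ValueError):
        window_pairs(InvertedIndex({}), 0)
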