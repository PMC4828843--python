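"""Hybrid de-duplication pipeline: blocking phases followed by a small-window
sorted-neighborhood phase.

The pipeline runs three successive indexing phases over one dataset:

1. **CKB** — composite-key blocking on two concatenated encoded fields; the
   most restrictive pass, resolving easy duplicates at minimal cost.
2. **MPB** — two single-key blocking passes (one per key field), unioned;
   catches duplicates whose error fell in the other key.
3. **MPW** — two sorted-neighborhood passes with a small window; sweeps up
   residual duplicates whose key errors pushed them into nearby-but-distinct
   buckets.

Because the earlier phases leave the data reasonably de-duplicated, a small
window (default 3) suffices in the last phase, avoiding the large-window cost
a dirty dataset would otherwise demand.

Cross-phase accounting: a global compared-pair cache ensures no unordered
pair is scored twice, and records already resolved as duplicates (every
non-representative member of a matched cluster) can be dropped before the
windowing phase. Both behaviours are flags, on by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Sequence

import networkx as nx

from .core import Dataset, GoldStandard
from .encodings import KeySpec
from .indexing import block_pairs, build_index, multipass_union, window_pairs
from .compare import FieldRule, default_rules
from .classify import ClassificationResult, Thresholds, classify_pairs
from .evaluate import MetricsReport, metrics

__all__ = [
    "FrameworkConfig",
    "PhaseReport",
    "run_framework",
    "transitive_clusters",
]


@dataclass
class FrameworkConfig:
    """Configuration of the three-phase pipeline.

    The encoder setting applies to every phase's keys; by default the
    name-field comparators mirror it (prefix agreement under substring
    encoding, phonetic agreement under soundex).
    """

    encoder: Literal["soundex", "substring"] = "substring"
    prefix_len: int = 4
    ckb_fields: tuple[str, ...] = ("given_name", "surname")
    mpb_pass_fields: tuple[tuple[str, ...], ...] = (("given_name",), ("surname",))
    mpw_pass_fields: tuple[tuple[str, ...], ...] = (("given_name",), ("surname",))
    window_size: int = 3
    thresholds: Thresholds = dc_field(default_factory=Thresholds)
    rules: tuple[FieldRule, ...] | None = None
    cross_phase_cache: bool = True
    remove_matched_records_before_windowing: bool = True
    empty_key_bucket: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        self.ckb_fields = tuple(self.ckb_fields)
        self.mpb_pass_fields = tuple(tuple(p) for p in self.mpb_pass_fields)
        self.mpw_pass_fields = tuple(tuple(p) for p in self.mpw_pass_fields)

    def resolved_rules(self) -> tuple[FieldRule, ...]:
        if self.rules is not None:
            return tuple(self.rules)
        name_cmp = "soundex_exact" if self.encoder == "soundex" else "substring_exact"
        return tuple(default_rules(name_cmp, prefix_len=self.prefix_len))

    def key_spec(self, fields: Sequence[str]) -> KeySpec:
        return KeySpec(
            fields=tuple(fields), encoder=self.encoder, prefix_len=self.prefix_len
        )

    def validate_schema(self, schema: Sequence[str]) -> None:
        known = set(schema)
        used = set(self.ckb_fields)
        for p in self.mpb_pass_fields + self.mpw_pass_fields:
            used |= set(p)
        used |= {r.field for r in self.resolved_rules()}
        unknown = used - known
        if unknown:
            raise ValueError(f"config references unknown fields: {sorted(unknown)}")


@dataclass
class PhaseReport:
    """Per-phase accounting: pairs generated by the phase's index, pairs
    newly compared after cache subtraction, and matches newly found."""

    phase: str
    pairs_generated: int
    new_pairs_compared: int
    matches_found: int
    cumulative_comparisons: int
    cumulative_matches: int


def transitive_clusters(matches: set[tuple[str, str]]) -> list[set[str]]:
    """Connected components of the match graph; every matched id belongs to
    exactly one cluster."""
    g = nx.Graph()
    g.add_edges_from(matches)
    return [set(c) for c in nx.connected_components(g)]


def _merge(total: ClassificationResult, part: ClassificationResult) -> None:
    total.matches |= part.matches
    total.possible_matches |= part.possible_matches
    total.non_matches |= part.non_matches
    total.scores.update(part.scores)


def run_framework(
    ds: Dataset,
    cfg: FrameworkConfig,
    gold: GoldStandard | None = None,
) -> tuple[ClassificationResult, list[PhaseReport], MetricsReport | None]:
    """Run CKB, then two-pass MPB, then two-pass small-window MPW.

    Returns the combined classification over all phases, one report per
    phase, and — when a gold standard is given — the quality metrics of the
    whole run (candidate count = total pairs actually compared).
    """
    cfg.validate_schema(ds.schema)
    rules = cfg.resolved_rules()
    compared: set[tuple[str, str]] = set()
    result = ClassificationResult()
    reports: list[PhaseReport] = []

    def run_phase(name: str, generated: set[tuple[str, str]], data: Dataset) -> None:
        new = generated - compared if cfg.cross_phase_cache else generated
        part = classify_pairs(new, data, rules, cfg.thresholds)
        compared.update(new)
        _merge(result, part)
        reports.append(
            PhaseReport(
                phase=name,
                pairs_generated=len(generated),
                new_pairs_compared=len(new),
                matches_found=len(part.matches),
                cumulative_comparisons=(
                    reports[-1].cumulative_comparisons if reports else 0
                )
                + len(new),
                cumulative_matches=(
                    reports[-1].cumulative_matches if reports else 0
                )
                + len(part.matches),
            )
        )

    # Phase 1: composite-key blocking
    ckb_ix = build_index(ds, cfg.key_spec(cfg.ckb_fields), cfg.empty_key_bucket)
    run_phase("CKB", block_pairs(ckb_ix), ds)

    # Phase 2: multipass single-key blocking
    mpb_sets = [
        block_pairs(build_index(ds, cfg.key_spec(p), cfg.empty_key_bucket))
        for p in cfg.mpb_pass_fields
    ]
    run_phase("MPB", multipass_union(mpb_sets), ds)

    # Phase 3: multipass small-window sorted neighborhood, optionally on the
    # dataset with resolved duplicates removed
    window_ds = ds
    if cfg.remove_matched_records_before_windowing and result.matches:
        drop: set[str] = set()
        for cluster in transitive_clusters(result.matches):
            representative = min(cluster)
            drop |= cluster - {representative}
        window_ds = ds.subset(set(ds.by_id) - drop)
    mpw_sets = [
        window_pairs(
            build_index(window_ds, cfg.key_spec(p), cfg.empty_key_bucket),
            cfg.window_size,
        )
        for p in cfg.mpw_pass_fields
    ]
    run_phase("MPW", multipass_union(mpw_sets), window_ds)

    report = None
    if gold is not None:
        report = metrics(
            candidate_count=len(compared),
            match_count=len(result.matches & gold.true_match_pairs),
            total_true_pairs=gold.n_true_pairs,
            n=ds.n,
        )
    return result, reports, report
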