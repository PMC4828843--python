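"""Read and write Febrl-style CSV datasets, gold standards and pair files.

Datasets are comma-separated RFC 4180 files with a header row containing
``rec_id`` plus the schema fields. Values are normalized at load: lowercased,
outer whitespace stripped, and internal whitespace runs collapsed to a single
space. Missing cells become empty strings.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    FEBRL_SCHEMA,
    Dataset,
    GoldStandard,
    Record,
    entity_from_rec_id,
    normalize_value,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "derive_gold_standard",
    "read_gold_standard",
    "write_gold_standard",
    "write_pairs",
]

def read_dataset(
    path: str | Path, schema: Sequence[str] = FEBRL_SCHEMA
) -> Dataset:
    """Load a dataset from CSV.

    The header must contain ``rec_id`` and every schema field; extra columns
    are ignored. rec_ids are kept verbatim (case preserved); field values are
    normalized.

    Raises ``ValueError`` for a missing ``rec_id`` column, missing schema
    fields, or duplicate rec_ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "rec_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'rec_id' column")
    missing = [f for f in schema if f not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing schema fields {missing}")
    records = [
        Record(
            rec_id=row["rec_id"].strip(),
            values={f: normalize_value(row[f]) for f in schema},
        )
        for row in df.to_dict("records")
    ]
    return Dataset(records, schema=tuple(schema))


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with a ``rec_id`` column followed by the schema
    fields, preserving record order (round-trips with :func:`read_dataset`)."""
    rows = [{"rec_id": r.rec_id, **{f: r.get(f) for f in ds.schema}} for r in ds]
    pd.DataFrame(rows, columns=["rec_id", *ds.schema]).to_csv(path, index=False)


def derive_gold_standard(ds: Dataset) -> GoldStandard:
    """Derive the true entity partition from DBGen record-id conventions.

    Every rec_id must match ``rec-<entity>-org`` or ``rec-<entity>-dup-<k>``;
    records sharing ``<entity>`` belong to the same real-world entity.
    """
    return GoldStandard({r.rec_id: entity_from_rec_id(r.rec_id) for r in ds})


def read_gold_standard(path: str | Path) -> GoldStandard:
    """Load an explicit two-column (rec_id, entity_id) mapping as CSV."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"rec_id", "entity_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns rec_id, entity_id")
    return GoldStandard(dict(zip(df["rec_id"], df["entity_id"])))


def write_gold_standard(gold: GoldStandard, path: str | Path) -> None:
    pd.DataFrame(
        sorted(gold.entity_of.items()), columns=["rec_id", "entity_id"]
    ).to_csv(path, index=False)


def write_pairs(
    pairs: Iterable[tuple[str, str]],
    path: str | Path,
    scores: Mapping[tuple[str, str], float] | None = None,
    labels: Mapping[tuple[str, str], str] | None = None,
) -> None:
    """Write candidate pairs as CSV ``id_a,id_b[,score][,class]``, sorted."""
    rows = []
    for pair in sorted(pairs):
        row: dict[str, object] = {"id_a": pair[0], "id_b": pair[1]}
        if scores is not None:
            row["score"] = scores.get(pair, "")
        if labels is not None:
            row["class"] = labels.get(pair, "")
        rows.append(row)
    cols = ["id_a", "id_b"]
    if scores is not None:
        cols.append("score")
    if labels is not None:
        cols.append("class")
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
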