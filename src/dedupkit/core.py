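"""Core containers for person-record de-duplication.

A :class:`Dataset` is an ordered collection of :class:`Record` objects, each
keyed by a unique ``rec_id`` and carrying string values for a fixed schema of
fields. Candidate pairs and true-match pairs are represented throughout the
package as sets of canonical unordered id pairs ``(id_a, id_b)`` with
``id_a < id_b`` lexicographically.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "FEBRL_SCHEMA",
    "Record",
    "Dataset",
    "GoldStandard",
    "canonical_pair",
    "pairs_within",
    "normalize_value",
]

#: The 12-field person schema used by Febrl-style synthetic datasets.
FEBRL_SCHEMA: tuple[str, ...] = (
    "given_name",
    "surname",
    "street_number",
    "address_1",
    "address_2",
    "suburb",
    "postcode",
    "state",
    "date_of_birth",
    "age",
    "phone_number",
    "soc_sec_id",
)

# Febrl DBGen identifier convention: rec-<entity>-org / rec-<entity>-dup-<k>
_REC_ID_RE = re.compile(r"^rec-(?P<entity>\d+)-(?:org|dup-\d+)$")

_WS_RUN = re.compile(r"\s+")


def normalize_value(value: str) -> str:
    """Lowercase, strip outer whitespace, collapse internal whitespace runs."""
    return _WS_RUN.sub(" ", value.strip()).lower()


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Return the unordered pair in canonical (lexicographically sorted) order.

    Raises ``ValueError`` on a self-pair.
    """
    if id_a == id_b:
        raise ValueError(f"self-pair not allowed: {id_a!r}")
    return (id_a, id_b) if id_a < id_b else (id_b, id_a)


def pairs_within(ids: list[str]) -> set[tuple[str, str]]:
    """All C(m, 2) canonical unordered pairs among a list of distinct ids."""
    return {canonical_pair(a, b) for a, b in itertools.combinations(ids, 2)}


@dataclass(frozen=True)
class Record:
    """One person row: a unique identifier plus normalized field values.

    Missing or blank cells are stored as empty strings. Values are expected to
    be normalized (lowercased, outer whitespace stripped, internal whitespace
    runs collapsed) by the loader or generator.
    """

    rec_id: str
    values: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rec_id:
            raise ValueError("rec_id must be non-empty")

    def get(self, field_name: str) -> str:
        try:
            return self.values[field_name]
        except KeyError:
            raise KeyError(f"unknown field {field_name!r}") from None


@dataclass
class Dataset:
    """An ordered collection of records sharing one schema.

    rec_ids must be unique; ``by_id`` gives O(1) lookup.
    """

    records: list[Record]
    schema: tuple[str, ...] = FEBRL_SCHEMA
    by_id: dict[str, Record] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        self.by_id = {}
        for rec in self.records:
            if rec.rec_id in self.by_id:
                raise ValueError(f"duplicate rec_id {rec.rec_id!r}")
            self.by_id[rec.rec_id] = rec

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep_ids: set[str]) -> "Dataset":
        """New dataset containing only the records whose id is in ``keep_ids``,
        preserving order."""
        return Dataset(
            [r for r in self.records if r.rec_id in keep_ids], schema=self.schema
        )


@dataclass
class GoldStandard:
    """True entity partition of a dataset.

    Two records are a true match iff they map to the same entity id. The full
    set of within-entity unordered pairs is enumerated eagerly; for every
    entity of size ``m`` it contributes C(m, 2) pairs.
    """

    entity_of: dict[str, str]
    true_match_pairs: set[tuple[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        members: dict[str, list[str]] = {}
        for rec_id, ent in self.entity_of.items():
            members.setdefault(ent, []).append(rec_id)
        pairs: set[tuple[str, str]] = set()
        for ids in members.values():
            pairs |= pairs_within(ids)
        self.true_match_pairs = pairs

    @property
    def n_true_pairs(self) -> int:
        return len(self.true_match_pairs)

    def is_match(self, id_a: str, id_b: str) -> bool:
        ea = self.entity_of.get(id_a)
        eb = self.entity_of.get(id_b)
        return ea is not None and ea == eb


def entity_from_rec_id(rec_id: str) -> str:
    """Extract the entity id from a Febrl DBGen-style record identifier.

    Raises ``ValueError`` if the id does not follow the
    ``rec-<entity>-org`` / ``rec-<entity>-dup-<k>`` convention.
    """
    m = _REC_ID_RE.match(rec_id)
    if m is None:
        raise ValueError(
            f"rec_id {rec_id!r} does not follow the rec-<entity>-org / "
            "rec-<entity>-dup-<k> convention; supply an explicit mapping"
        )
    return m.group("entity")
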