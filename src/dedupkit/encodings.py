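"""Indexing-key encodings: American soundex, substring prefixes, and
single/composite blocking-key assembly.

The blocking key (BK) of a record is built by encoding one or more field
values and concatenating the codes; records sharing a blocking key value
(BKV) land in the same inverted-index bucket.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .core import Record

__all__ = ["soundex", "substring_prefix", "KeySpec", "build_key"]

# American soundex digit classes; vowels + h, w, y carry no digit.
_SOUNDEX_CODES = {
    **dict.fromkeys("bfpv", "1"),
    **dict.fromkeys("cgjkqsxz", "2"),
    **dict.fromkeys("dt", "3"),
    "l": "4",
    **dict.fromkeys("mn", "5"),
    "r": "6",
}


def soundex(value: str) -> str:
    """American soundex code: initial letter plus three digits, zero-padded.

    Non-alphabetic characters are stripped first; empty or fully
    non-alphabetic input yields the empty string. Adjacent letters with the
    same digit are coded once; the letters h and w are transparent (they do
    not separate same-coded consonants) whereas vowels do separate them.

    >>> soundex("ullman")
    'U455'
    >>> soundex("jeffrey")
    'J160'
    """
    letters = [c for c in value.lower() if c.isalpha() and c.isascii()]
    if not letters:
        return ""
    digits = []
    prev = _SOUNDEX_CODES.get(letters[0], "")
    for c in letters[1:]:
        code = _SOUNDEX_CODES.get(c, "")
        if code and code != prev:
            digits.append(code)
            if len(digits) == 3:
                break
        if c not in "hw":  # h/w transparent: keep prev across them
            prev = code
    return letters[0].upper() + "".join(digits).ljust(3, "0")


def substring_prefix(value: str, k: int) -> str:
    """First ``min(k, len(value))`` characters of the value.

    Operates on the raw normalized value so digit-bearing fields such as
    postcode keep their digits.
    """
    if k < 1:
        raise ValueError("prefix length must be >= 1")
    return value[:k]


@dataclass(frozen=True)
class KeySpec:
    """How to build a blocking/sorting key from a record.

    ``fields`` of length 1 gives a single key; length >= 2 a composite key.
    Each field value is encoded separately and the codes are concatenated in
    order (optionally with a separator to avoid rare collisions).
    """

    fields: tuple[str, ...]
    encoder: Literal["soundex", "substring"] = "substring"
    prefix_len: int = 4
    separator: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "fields", tuple(self.fields))
        if not self.fields:
            raise ValueError("KeySpec needs at least one field")
        if self.encoder not in ("soundex", "substring"):
            raise ValueError(f"unknown encoder {self.encoder!r}")
        if self.prefix_len < 1:
            raise ValueError("prefix_len must be >= 1")

    def encode(self, value: str) -> str:
        if self.encoder == "soundex":
            return soundex(value)
        return substring_prefix(value, self.prefix_len)


def build_key(rec: Record, spec: KeySpec) -> str:
    """Blocking key value for one record.

    Encodes each constituent field separately and concatenates in spec order.
    If every constituent field is missing (empty), returns the empty string:
    the record carries no key for this pass.
    """
    raw = [rec.get(f) for f in spec.fields]
    if all(v == "" for v in raw):
        return ""
    return spec.separator.join(spec.encode(v) for v in raw)
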