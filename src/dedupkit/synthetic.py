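"""DBGen-style synthetic dirty person datasets with a known gold standard.

The generator emulates the Febrl database generator: it creates clean
"original" records from built-in value pools, then derives "duplicate"
records by applying character-level corruptions (insert, delete, substitute,
transpose, field clear) to copies of randomly chosen originals. Record ids
follow the ``rec-<k>-org`` / ``rec-<k>-dup-<j>`` convention, so the true
entity partition is known exactly.

Two built-in profiles mirror commonly used evaluation conditions:

* **profile A** ("dirty"): 500 originals + 500 duplicates, one duplicate per
  original, exactly one modification per duplicate, at most one per
  attribute;
* **profile C** ("massively dirty"): 600 originals + 400 duplicates, up to 9
  duplicates per original, up to 10 modifications per duplicate, at most 3
  per attribute.

All values are emitted pre-normalized (lowercase). The same config + seed
always yields byte-identical output.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .core import FEBRL_SCHEMA, Dataset, GoldStandard, Record, normalize_value

__all__ = [
    "GeneratorConfig",
    "generate",
    "corrupt_value",
    "dataset_a_config",
    "dataset_c_config",
]

OPERATORS = ("char_insert", "char_delete", "char_substitute", "char_transpose", "field_clear")

_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

# Built-in value pools: compact stand-ins for Febrl's name/address frequency
# tables, large enough to give realistic block-size distributions at n ~ 1000.
GIVEN_NAMES = [
    "james", "john", "robert", "michael", "william", "david", "richard",
    "joseph", "thomas", "charles", "christopher", "daniel", "matthew",
    "anthony", "mark", "donald", "steven", "paul", "andrew", "joshua",
    "kenneth", "kevin", "brian", "george", "timothy", "ronald", "edward",
    "jason", "jeffrey", "ryan", "jacob", "gary", "nicholas", "eric",
    "jonathan", "stephen", "larry", "justin", "scott", "brandon", "mary",
    "patricia", "jennifer", "linda", "elizabeth", "barbara", "susan",
    "jessica", "sarah", "karen", "lisa", "nancy", "betty", "margaret",
    "sandra", "ashley", "kimberly", "emily", "donna", "michelle", "carol",
    "amanda", "dorothy", "melissa", "deborah", "stephanie", "rebecca",
    "sharon", "laura", "cynthia", "kathleen", "amy", "angela", "shirley",
    "anna", "brenda", "pamela", "emma", "nicole", "helen", "samantha",
    "katherine", "christine", "debra", "rachel", "carolyn", "janet",
    "catherine", "maria", "heather", "diane", "ruth", "julie", "olivia",
    "joyce", "virginia", "victoria", "kelly", "lauren", "christina",
]
SURNAMES = [
    "smith", "jones", "williams", "brown", "wilson", "taylor", "johnson",
    "white", "martin", "anderson", "thompson", "nguyen", "thomas", "walker",
    "harris", "lee", "ryan", "robinson", "kelly", "king", "davis", "wright",
    "evans", "roberts", "green", "hall", "wood", "jackson", "clarke",
    "patel", "khan", "lewis", "james", "phillips", "mason", "mitchell",
    "rose", "davies", "rodriguez", "cox", "alexander", "garden", "campbell",
    "johnston", "moore", "smyth", "oneill", "doherty", "stewart", "quinn",
    "murphy", "graham", "mclaughlin", "hamilton", "murray", "hughes",
    "robertson", "thomson", "scott", "macdonald", "reid", "clark", "ross",
    "young", "watson", "paterson", "morrison", "morgan", "griffiths",
    "edwards", "rees", "jenkins", "owen", "price", "moss", "richards",
    "webb", "bell", "hunt", "palmer", "holmes", "mills", "ellis", "carter",
    "fisher", "baker", "turner", "cooper", "parker", "ward", "bennett",
    "gray", "cook", "bailey", "matthews", "simpson", "dixon", "hunter",
]
STREET_NAMES = [
    "george street", "king street", "queen street", "church street",
    "high street", "victoria road", "station road", "park avenue",
    "main road", "elizabeth street", "william street", "albert road",
    "railway parade", "beach road", "forest road", "mill lane",
    "chapel street", "north terrace", "south terrace", "west parade",
    "oxford street", "cambridge avenue", "windsor drive", "rose crescent",
    "acacia avenue", "banksia court", "wattle place", "eucalyptus drive",
    "jacaranda close", "boronia street",
]
ADDRESS_2 = ["", "", "", "flat 1", "flat 2", "unit 3", "unit 7", "villa 2",
             "apartment 5", "suite 12"]
SUBURBS = [
    "richmond", "newtown", "springfield", "fairfield", "clayton",
    "parkville", "brunswick", "footscray", "carlton", "preston",
    "essendon", "kensington", "ashfield", "bankstown", "blacktown",
    "campbelltown", "chatswood", "epping", "hornsby", "hurstville",
    "liverpool", "penrith", "ryde", "sutherland", "toowong", "ipswich",
    "cairns", "mackay", "bundaberg", "gladstone", "woodside", "stirling",
    "salisbury", "elizabeth", "fremantle", "joondalup", "rockingham",
    "mandurah", "launceston", "devonport",
]
STATES = ["nsw", "vic", "qld", "sa", "wa", "tas", "act", "nt"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Corruption-model parameters of one synthetic dataset.

    n_duplicates must not exceed n_original * max_dups_per_original; the
    per-duplicate and per-attribute maxima bound how many character-level
    edits each duplicate accumulates.
    """

    n_original: int
    n_duplicates: int
    max_dups_per_original: int = 1
    max_mods_per_duplicate: int = 1
    max_mods_per_attribute: int = 1
    operators: tuple[str, ...] = OPERATORS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_original < 0 or self.n_duplicates < 0:
            raise ValueError("record counts must be non-negative")
        if self.n_duplicates > self.n_original * self.max_dups_per_original:
            raise ValueError(
                "n_duplicates exceeds n_original * max_dups_per_original"
            )
        if self.n_duplicates > 0:
            if (
                self.max_dups_per_original < 1
                or self.max_mods_per_duplicate < 1
                or self.max_mods_per_attribute < 1
            ):
                raise ValueError("modification maxima must be >= 1")
        unknown = set(self.operators) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        if not self.operators:
            raise ValueError("need at least one modification operator")


def dataset_a_config(seed: int = 0) -> GeneratorConfig:
    """Dirty profile: 1000 records, one lightly modified duplicate per
    duplicated original."""
    return GeneratorConfig(
        n_original=500,
        n_duplicates=500,
        max_dups_per_original=1,
        max_mods_per_duplicate=1,
        max_mods_per_attribute=1,
        seed=seed,
    )


def dataset_c_config(seed: int = 0) -> GeneratorConfig:
    """Massively dirty profile: 1000 records, up to 9 duplicates per
    original with up to 10 modifications each."""
    return GeneratorConfig(
        n_original=600,
        n_duplicates=400,
        max_dups_per_original=9,
        max_mods_per_duplicate=10,
        max_mods_per_attribute=3,
        seed=seed,
    )


def corrupt_value(value: str, op: str, rng: random.Random) -> str:
    """Apply one character-level edit at a uniformly chosen position.

    delete/substitute/transpose require a non-empty value (transpose needs
    length >= 2); substitute always picks a different character and transpose
    a position whose neighbours differ, so the result is guaranteed to differ
    from the input.
    """
    if op == "field_clear":
        return ""
    if op == "char_insert":
        pos = rng.randrange(len(value) + 1)
        return value[:pos] + rng.choice(_ALPHABET) + value[pos:]
    if not value:
        raise ValueError(f"operator {op!r} needs a non-empty value")
    if op == "char_delete":
        pos = rng.randrange(len(value))
        return value[:pos] + value[pos + 1 :]
    if op == "char_substitute":
        pos = rng.randrange(len(value))
        new = rng.choice([c for c in _ALPHABET if c != value[pos]])
        return value[:pos] + new + value[pos + 1 :]
    if op == "char_transpose":
        positions = [k for k in range(len(value) - 1) if value[k] != value[k + 1]]
        if not positions:
            raise ValueError("no transposable position")
        pos = rng.choice(positions)
        return value[:pos] + value[pos + 1] + value[pos] + value[pos + 2 :]
    raise ValueError(f"unknown operator {op!r}")


def _applicable(op: str, value: str) -> bool:
    if op in ("char_delete", "char_substitute", "field_clear"):
        return len(value) > 0
    if op == "char_transpose":
        return any(value[k] != value[k + 1] for k in range(len(value) - 1))
    return True  # char_insert


def _make_original(k: int, rng: random.Random) -> Record:
    dob = (
        f"{rng.randint(1920, 2005):04d}"
        f"{rng.randint(1, 12):02d}{rng.randint(1, 28):02d}"
    )
    values = {
        "given_name": rng.choice(GIVEN_NAMES),
        "surname": rng.choice(SURNAMES),
        "street_number": str(rng.randint(1, 400)),
        "address_1": rng.choice(STREET_NAMES),
        "address_2": rng.choice(ADDRESS_2),
        "suburb": rng.choice(SUBURBS),
        "postcode": f"{rng.randint(2000, 7999):04d}",
        "state": rng.choice(STATES),
        "date_of_birth": dob,
        "age": str(rng.randint(18, 93)),
        "phone_number": f"0{rng.randint(2, 8)} {rng.randint(10000000, 99999999)}",
        "soc_sec_id": f"{rng.randint(1000000, 9999999)}",
    }
    return Record(rec_id=f"rec-{k}-org", values=values)


def _make_duplicate(
    original: Record, dup_index: int, cfg: GeneratorConfig, rng: random.Random
) -> Record:
    entity = original.rec_id.split("-")[1]
    for _ in range(20):  # retry in the rare case edits cancel out
        values = dict(original.values)
        per_attr: dict[str, int] = {}
        n_mods = rng.randint(1, cfg.max_mods_per_duplicate)
        for _ in range(n_mods):
            fields = [
                f
                for f in FEBRL_SCHEMA
                if per_attr.get(f, 0) < cfg.max_mods_per_attribute
                and any(_applicable(op, values[f]) for op in cfg.operators)
            ]
            if not fields:
                break
            f = rng.choice(fields)
            ops = [op for op in cfg.operators if _applicable(op, values[f])]
            # re-normalize: an edit next to a space can leave stray whitespace
            values[f] = normalize_value(corrupt_value(values[f], rng.choice(ops), rng))
            per_attr[f] = per_attr.get(f, 0) + 1
        if values != original.values:
            return Record(rec_id=f"rec-{entity}-dup-{dup_index}", values=values)
    raise RuntimeError("could not produce a modified duplicate")


def generate(cfg: GeneratorConfig) -> tuple[Dataset, GoldStandard]:
    """Generate a dirty dataset and its gold standard.

    Originals get entity indices 0..n_original-1; duplicates are allocated to
    originals by drawing a per-original duplicate count uniformly on
    {1..max_dups_per_original} over a random original order, truncated to hit
    n_duplicates exactly. Records are emitted in shuffled order.
    """
    rng = random.Random(cfg.seed)
    originals = [_make_original(k, rng) for k in range(cfg.n_original)]

    allocation: list[tuple[int, int]] = []  # (original index, dup count)
    remaining = cfg.n_duplicates
    order = list(range(cfg.n_original))
    rng.shuffle(order)
    for k in order:
        if remaining == 0:
            break
        d = min(rng.randint(1, cfg.max_dups_per_original), remaining)
        allocation.append((k, d))
        remaining -= d

    duplicates: list[Record] = []
    for k, d in allocation:
        for j in range(d):
            duplicates.append(_make_duplicate(originals[k], j, cfg, rng))

    records = originals + duplicates
    rng.shuffle(records)
    ds = Dataset(records)
    entity_of = {r.rec_id: r.rec_id.split("-")[1] for r in records}
    return ds, GoldStandard(entity_of)
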