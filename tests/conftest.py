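import pytest

from dedupkit import (
    Dataset,
    Record,
    dataset_a_config,
    dataset_c_config,
    generate,
)


def make_record(rec_id: str, **fields: str) -> Record:
    """Record with every schema field empty except the given ones."""
    from dedupkit import FEBRL_SCHEMA

    values = {f: "" for f in FEBRL_SCHEMA}
    values.update(fields)
    return Record(rec_id=rec_id, values=values)


@pytest.fixture
def toy_dataset() -> Dataset:
    """Four records, two obvious duplicate pairs, with DBGen-style ids."""
    return Dataset(
        [
            make_record(
                "rec-0-org",
                given_name="peter",
                surname="smith",
                postcode="2000",
                address_1="george street",
                soc_sec_id="1234567",
            ),
            make_record(
                "rec-0-dup-0",
                given_name="peter",
                surname="smyth",
                postcode="2000",
                address_1="george street",
                soc_sec_id="1234567",
            ),
            make_record(
                "rec-1-org",
                given_name="maria",
                surname="jones",
                postcode="3051",
                address_1="king street",
                soc_sec_id="7654321",
            ),
            make_record(
                "rec-1-dup-0",
                given_name="marai",
                surname="jones",
                postcode="3051",
                address_1="king street",
                soc_sec_id="7654321",
            ),
        ]
    )


@pytest.fixture(scope="session")
def profile_a():
    """Dirty profile: 500 originals + 500 lightly modified duplicates."""
    return generate(dataset_a_config(seed=7))


@pytest.fixture(scope="session")
def profile_c():
    """Massively dirty profile: 600 originals + 400 heavily modified dups."""
    return generate(dataset_c_config(seed=7))
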