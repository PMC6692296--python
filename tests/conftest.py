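"""Shared fixtures: small structures and the default synthetic family."""

import pytest

from its2cbc import (
    AnnotatedStructure,
    FamilySpec,
    SequenceRecord,
    make_family,
)
from its2cbc.io import parse_dotbracket


def structure(seq: str, db: str, sid: str = "s", regions=()) -> AnnotatedStructure:
    """Build a structure from sequence + dot-bracket (test helper)."""
    return AnnotatedStructure(
        record=SequenceRecord(id=sid, seq=seq, source="test"),
        pairs=parse_dotbracket(db),
        regions=tuple(regions),
    )


@pytest.fixture(scope="session")
def default_family():
    """The default 6-strain, 2-group family with planted 2 CBCs + 2 HCBCs."""
    return make_family(FamilySpec(seed=11))


@pytest.fixture
def hairpin():
    # stem G-C, G-C, C-G, G·U closing an AAAA loop
    return structure("GGCGAAAAUGCC", "((((....))))", "hp")
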