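"""Shared fixtures: a five-rung yeast-style ladder and a hand-enumerated
12-gene orthogroup fixture whose conservation classes and age labels were
worked out by hand and are committed as the expected values."""

import pytest

from agestrat import Orthogroup, OrthogroupTable, Rung, SpeciesLadder


@pytest.fixture(scope="session")
def yeast_ladder() -> SpeciesLadder:
    """Five rungs, youngest first: focal Scer alone on rung 1, one species
    per older rung, divergence times loosely yeast-like."""
    return SpeciesLadder(
        focal_species="Scer",
        rungs=(
            Rung(1, "V", frozenset({"Scer"}), 0.0),
            Rung(2, "IV", frozenset({"Seub"}), 20.0),
            Rung(3, "III", frozenset({"Kmar"}), 120.0),
            Rung(4, "II", frozenset({"Ylip"}), 325.0),
            Rung(5, "I", frozenset({"Ncra"}), 420.0),
        ),
    )


def _og(og_id, **members):
    return Orthogroup(og_id=og_id, members={k: tuple(v) for k, v in members.items()})


@pytest.fixture(scope="session")
def fixture_orthogroups() -> OrthogroupTable:
    """Twelve focal genes: 4 single-core, 4 multi-core (two orthogroups),
    4 non-core (one of which, n4, is in no orthogroup at all)."""
    groups = [
        _og("OG_s1", Scer=["s1"], Seub=["s1_se"], Kmar=["s1_km"], Ylip=["s1_yl"], Ncra=["s1_nc"]),
        _og("OG_s2", Scer=["s2"], Kmar=["s2_km"], Ylip=["s2_yl"]),
        _og("OG_s3", Scer=["s3"], Seub=["s3_se"], Kmar=["s3_km"], Ylip=["s3_yl"]),
        _og("OG_s4", Scer=["s4"], Kmar=["s4_km"], Ylip=["s4_yl"], Ncra=["s4_nc"]),
        _og("OG_m1", Scer=["m1a", "m1b"], Seub=["m1_se1", "m1_se2"], Kmar=["m1_km"], Ylip=["m1_yl"]),
        _og("OG_m2", Scer=["m2a", "m2b"], Seub=["m2_se"], Kmar=["m2_km1", "m2_km2"], Ylip=["m2_yl"]),
        _og("OG_n1", Scer=["n1"], Seub=["n1_se"]),
        _og("OG_n2", Scer=["n2"]),
        _og("OG_n3", Scer=["n3"], Kmar=["n3_km"]),
    ]
    return OrthogroupTable(["Scer", "Seub", "Kmar", "Ylip", "Ncra"], groups)


@pytest.fixture(scope="session")
def fixture_genes() -> list[str]:
    return ["s1", "s2", "s3", "s4", "m1a", "m1b", "m2a", "m2b", "n1", "n2", "n3", "n4"]


#: Hand enumeration, queries = (Kmar, Ylip), noncore mode "any".
EXPECTED_CLASSES = {
    "s1": "single_core", "s2": "single_core", "s3": "single_core", "s4": "single_core",
    "m1a": "multi_core", "m1b": "multi_core", "m2a": "multi_core", "m2b": "multi_core",
    "n1": "non_core", "n2": "non_core", "n3": "non_core", "n4": "non_core",
}

#: Hand enumeration of age labels, dup rule "oldest".
#: Singles: deepest rung with any ortholog (s1->Ncra=I, s2/s3->Ylip=II,
#: s4->Ncra=I, n1->Seub=IV, n2 alone=V, n3->Kmar=III, n4 no orthogroup=V).
#: Multis: oldest rung with a species at the focal copy number 2
#: (m1: Seub has 2 -> IV; m2: Kmar has 2 -> III).
EXPECTED_AGES = {
    "s1": "I", "s2": "II", "s3": "II", "s4": "I",
    "m1a": "IV", "m1b": "IV", "m2a": "III", "m2b": "III",
    "n1": "IV", "n2": "V", "n3": "III", "n4": "V",
}


@pytest.fixture(scope="session")
def expected_classes() -> dict[str, str]:
    return dict(EXPECTED_CLASSES)


@pytest.fixture(scope="session")
def expected_ages() -> dict[str, str]:
    return dict(EXPECTED_AGES)
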