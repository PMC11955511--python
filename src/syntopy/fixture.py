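"""Frozen observed-network fixture for the four-species assemblage.

The published study reports the interaction network only through its
marginals: 33 behavioral interactions among 63 spiders (calcaratus 8F/14M,
coecatus 15F/9M, decorus 7F/8M, orbus 2F), 12 heterospecific edges, 11
same-sex pairs, behavior counts 13 looking / 14 courtship / 4 aggression /
2 other, and a courtship sub-network of 14 edges among 25 spiders
(calcaratus 2F/5M, coecatus 6F/3M, decorus 5F/3M, orbus 1F) with 5
heterospecific edges and exactly three males courting more than one female.
The exact pairings were not published, so this module freezes one edge list
constructed by hand to satisfy every one of those marginals simultaneously,
plus the reported qualitative details (all courtship initiated by males; the
aggression cases: a male-male decorus bout, a female-female coecatus bout,
and two coecatus females attacking courting conspecific males; the two
"other" cases: a coecatus subadult female startling a conspecific female
during a prey capture, and a calcaratus male pursuing a coecatus subadult
male).

Residual ambiguity: the reported per-class heterospecific percentages
over-constrain the 33-edge network once rounding is accounted for. Counting
per-individual interaction incidences, this fixture reproduces the
species-level heterospecific percentages exactly (calcaratus 7/23 = 30%,
coecatus 9/25 = 36%, decorus 6/16 = 38%, orbus 2/2 = 100%) and the courtship
class percentages exactly (males 4/6 = 67% calcaratus, 1/4 = 25% coecatus,
0 decorus; females 0 calcaratus, 3/6 = 50% coecatus, 1/5 = 20% decorus,
1/1 orbus). The full-network sex-by-species percentages for coecatus (17% F,
9% M) are mutually inconsistent with the species-level 36% under any
counting scheme and are therefore not matched. Only the marginals listed in
the first paragraph are treated as the reproducible surface and asserted in
tests.
"""

from __future__ import annotations

from .datamodel import (
    AssemblageDataset,
    InteractionRecord,
    SpiderRecord,
)

__all__ = ["build_observed_fixture", "COURTSHIP_COMPOSITION", "FULL_COMPOSITION"]

#: species -> {sex -> vertex count} of the full observed network
FULL_COMPOSITION = {
    "calcaratus": {"F": 8, "M": 14},
    "coecatus": {"F": 15, "M": 9},
    "decorus": {"F": 7, "M": 8},
    "orbus": {"F": 2, "M": 0},
}

#: species -> {sex -> vertex count} of the courtship sub-network
COURTSHIP_COMPOSITION = {
    "calcaratus": {"F": 2, "M": 5},
    "coecatus": {"F": 6, "M": 3},
    "decorus": {"F": 5, "M": 3},
    "orbus": {"F": 1, "M": 0},
}

_PREFIX = {"calcaratus": "CAL", "coecatus": "COE", "decorus": "DEC", "orbus": "ORB"}

# (spider_a, spider_b, behavior, initiator); initiator "" = unrecorded.
# Courtship is always male-initiated; the three degree-2 vertices are
# CAL-M03, COE-M01 and DEC-M01 (the three multiply-courting males).
_EDGES = [
    # courtship (14)
    ("CAL-M03", "COE-F01", "courtship", "CAL-M03"),
    ("CAL-M03", "COE-F02", "courtship", "CAL-M03"),
    ("CAL-M04", "COE-F03", "courtship", "CAL-M04"),
    ("CAL-M05", "DEC-F01", "courtship", "CAL-M05"),
    ("CAL-M01", "CAL-F01", "courtship", "CAL-M01"),
    ("CAL-M02", "CAL-F02", "courtship", "CAL-M02"),
    ("COE-M01", "COE-F04", "courtship", "COE-M01"),
    ("COE-M01", "ORB-F01", "courtship", "COE-M01"),
    ("COE-M02", "COE-F05", "courtship", "COE-M02"),
    ("COE-M03", "COE-F06", "courtship", "COE-M03"),
    ("DEC-M01", "DEC-F02", "courtship", "DEC-M01"),
    ("DEC-M01", "DEC-F03", "courtship", "DEC-M01"),
    ("DEC-M02", "DEC-F04", "courtship", "DEC-M02"),
    ("DEC-M03", "DEC-F05", "courtship", "DEC-M03"),
    # aggression (4)
    ("DEC-M04", "DEC-M05", "aggression", "DEC-M04"),
    ("COE-F07", "COE-F08", "aggression", "COE-F07"),
    ("COE-F09", "COE-M04", "aggression", "COE-F09"),
    ("COE-F10", "COE-M05", "aggression", "COE-F10"),
    # other (2)
    ("COE-F11", "COE-F12", "other", ""),
    ("CAL-M06", "COE-M06", "other", "CAL-M06"),
    # looking (13)
    ("DEC-M06", "ORB-F02", "looking", ""),
    ("DEC-M07", "COE-F13", "looking", ""),
    ("DEC-M08", "COE-M07", "looking", ""),
    ("DEC-F06", "COE-F14", "looking", ""),
    ("DEC-F07", "CAL-F03", "looking", ""),
    ("CAL-M07", "COE-F15", "looking", ""),
    ("COE-M08", "COE-M09", "looking", ""),
    ("CAL-F04", "CAL-F05", "looking", ""),
    ("CAL-M08", "CAL-M09", "looking", ""),
    ("CAL-M10", "CAL-M11", "looking", ""),
    ("CAL-F06", "CAL-M12", "looking", ""),
    ("CAL-F07", "CAL-M13", "looking", ""),
    ("CAL-F08", "CAL-M14", "looking", ""),
]

# Eight of the 63 interacting spiders were subadults.
_SUBADULTS = {
    "COE-F11",
    "COE-M06",
    "CAL-F04",
    "CAL-M08",
    "COE-F13",
    "COE-M08",
    "DEC-F06",
    "DEC-M06",
}


def _species_of(spider_id: str) -> str:
    code = spider_id.split("-")[0]
    return {v: k for k, v in _PREFIX.items()}[code]


def build_observed_fixture() -> AssemblageDataset:
    """Return the frozen 63-spider / 33-interaction observed network.

    Tracks and light tables are empty: the deposited raw coordinates are not
    part of the package, so only the interaction analyses are reproducible
    from the fixture.
    """
    focal = {e[0] for e in _EDGES}
    ids: list[str] = []
    for sp, bysex in FULL_COMPOSITION.items():
        for sex, n in bysex.items():
            ids.extend(f"{_PREFIX[sp]}-{sex}{i:02d}" for i in range(1, n + 1))
    records = tuple(
        SpiderRecord(
            spider_id=sid,
            species=_species_of(sid),
            sex=sid.split("-")[1][0],
            maturity="subadult" if sid in _SUBADULTS else "adult",
            role="focal" if sid in focal else "attendee",
        )
        for sid in ids
    )
    interactions = tuple(
        InteractionRecord(spider_a=a, spider_b=b, behavior=beh, initiator=init or None)
        for a, b, beh, init in _EDGES
    )
    return AssemblageDataset(
        records=records,
        interactions=interactions,
        metadata={
            "site": "Edge of Appalachia Preserve, Ohio",
            "season": "2021-2022",
            "source": "frozen observed-network fixture (marginal-exact reconstruction)",
        },
    ).validate()
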