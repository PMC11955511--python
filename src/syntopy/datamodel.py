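"""Domain types and validation for focal-follow assemblage datasets.

The data model mirrors a field campaign on a mixed-species assemblage of
jumping spiders: individually identified spiders with species/sex/maturity
labels, per-follow movement tracks in a local planar frame, two-state
(sun/shade) light-environment bout sequences, and pairwise behavioral
interaction records.  An :class:`AssemblageDataset` bundles the four tables
and enforces referential integrity between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "LabelVocabulary",
    "SpiderRecord",
    "Waypoint",
    "Track",
    "LightBout",
    "LightBoutSeries",
    "InteractionRecord",
    "AssemblageDataset",
    "ValidationError",
]

DEFAULT_SPECIES = ("calcaratus", "coecatus", "decorus", "orbus")
SEXES = ("F", "M")
MATURITIES = ("adult", "subadult")
ROLES = ("focal", "attendee")
BEHAVIORS = ("looking", "courtship", "aggression", "other")
LIGHT_STATES = ("sun", "shade")


class ValidationError(ValueError):
    """Raised when a record or dataset violates a data-model invariant."""


@dataclass(frozen=True)
class LabelVocabulary:
    """Declared label sets; species list is extensible beyond the default four."""

    species: tuple[str, ...] = DEFAULT_SPECIES
    sexes: tuple[str, ...] = SEXES
    maturities: tuple[str, ...] = MATURITIES
    behaviors: tuple[str, ...] = BEHAVIORS


@dataclass(frozen=True)
class SpiderRecord:
    """One observed individual (a potential network vertex)."""

    spider_id: str
    species: str
    sex: str
    maturity: str = "adult"
    role: str = "focal"

    def validate(self, vocab: LabelVocabulary, context: str = "") -> None:
        if not self.spider_id:
            raise ValidationError(f"empty spider_id {context}")
        if self.species not in vocab.species:
            raise ValidationError(
                f"unknown species {self.species!r} for {self.spider_id!r} {context}"
            )
        if self.sex not in vocab.sexes:
            raise ValidationError(
                f"unknown sex {self.sex!r} for {self.spider_id!r} {context}"
            )
        if self.maturity not in vocab.maturities:
            raise ValidationError(
                f"unknown maturity {self.maturity!r} for {self.spider_id!r} {context}"
            )
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r} for {self.spider_id!r} {context}"
            )


@dataclass(frozen=True)
class Waypoint:
    """A flagged position (meters, local frame) at ``t`` seconds into the follow."""

    x: float
    y: float
    t: float


@dataclass(frozen=True)
class Track:
    """Ordered waypoints for one individual's focal follow."""

    spider_id: str
    date: str  # ISO-8601 YYYY-MM-DD
    start_time: str  # HH:MM clock time of follow start
    waypoints: tuple[Waypoint, ...]

    def validate(self, context: str = "") -> None:
        if len(self.waypoints) < 1:
            raise ValidationError(f"track for {self.spider_id!r} has no waypoints {context}")
        prev_t = -math.inf
        for wp in self.waypoints:
            if not (math.isfinite(wp.x) and math.isfinite(wp.y) and math.isfinite(wp.t)):
                raise ValidationError(
                    f"non-finite waypoint {wp} in track for {self.spider_id!r} {context}"
                )
            if wp.t <= prev_t:
                raise ValidationError(
                    f"waypoint times not strictly increasing in track for "
                    f"{self.spider_id!r} (t={wp.t} after t={prev_t}) {context}"
                )
            prev_t = wp.t


@dataclass(frozen=True)
class LightBout:
    state: str  # "sun" | "shade"
    start: float  # seconds from follow start
    end: float


@dataclass(frozen=True)
class LightBoutSeries:
    """Contiguous sun/shade bouts over one follow, seconds from follow start."""

    spider_id: str
    bouts: tuple[LightBout, ...]

    def validate(self, context: str = "") -> None:
        if not self.bouts:
            raise ValidationError(f"empty light series for {self.spider_id!r} {context}")
        prev_end = None
        total = 0.0
        for b in self.bouts:
            if b.state not in LIGHT_STATES:
                raise ValidationError(
                    f"unknown light state {b.state!r} for {self.spider_id!r} {context}"
                )
            if not b.end > b.start:
                raise ValidationError(
                    f"bout end {b.end} <= start {b.start} for {self.spider_id!r} {context}"
                )
            if prev_end is not None and not math.isclose(b.start, prev_end, abs_tol=1e-9):
                raise ValidationError(
                    f"non-contiguous bouts (gap/overlap at t={b.start}) for "
                    f"{self.spider_id!r} {context}"
                )
            prev_end = b.end
            total += b.end - b.start
        if not total > 0:
            raise ValidationError(f"zero total duration for {self.spider_id!r} {context}")


@dataclass(frozen=True)
class InteractionRecord:
    """One observed pairwise behavioral interaction (a network edge)."""

    spider_a: str
    spider_b: str
    behavior: str
    initiator: str | None = None

    def validate(self, vocab: LabelVocabulary, context: str = "") -> None:
        if self.spider_a == self.spider_b:
            raise ValidationError(
                f"self-interaction for {self.spider_a!r} {context}"
            )
        if self.behavior not in vocab.behaviors:
            raise ValidationError(
                f"unknown behavior {self.behavior!r} for pair "
                f"({self.spider_a!r}, {self.spider_b!r}) {context}"
            )
        if self.initiator is not None and self.initiator not in (
            self.spider_a,
            self.spider_b,
        ):
            raise ValidationError(
                f"initiator {self.initiator!r} is not a member of the pair "
                f"({self.spider_a!r}, {self.spider_b!r}) {context}"
            )


@dataclass
class AssemblageDataset:
    """The four observation tables plus site metadata, referentially consistent."""

    records: tuple[SpiderRecord, ...] = ()
    tracks: tuple[Track, ...] = ()
    light: tuple[LightBoutSeries, ...] = ()
    interactions: tuple[InteractionRecord, ...] = ()
    metadata: dict = field(default_factory=dict)
    vocab: LabelVocabulary = field(default_factory=LabelVocabulary)

    def validate(self) -> "AssemblageDataset":
        seen: set[str] = set()
        for i, rec in enumerate(self.records):
            rec.validate(self.vocab, context=f"(records row {i})")
            if rec.spider_id in seen:
                raise ValidationError(
                    f"duplicate spider_id {rec.spider_id!r} (records row {i})"
                )
            seen.add(rec.spider_id)
        for i, tr in enumerate(self.tracks):
            tr.validate(context=f"(tracks row {i})")
            if tr.spider_id not in seen:
                raise ValidationError(
                    f"track references unknown spider_id {tr.spider_id!r} (tracks row {i})"
                )
        for i, ls in enumerate(self.light):
            ls.validate(context=f"(light row {i})")
            if ls.spider_id not in seen:
                raise ValidationError(
                    f"light series references unknown spider_id {ls.spider_id!r} "
                    f"(light row {i})"
                )
        for i, ir in enumerate(self.interactions):
            ir.validate(self.vocab, context=f"(interactions row {i})")
            for sid in (ir.spider_a, ir.spider_b):
                if sid not in seen:
                    raise ValidationError(
                        f"interaction references unknown spider_id {sid!r} "
                        f"(interactions row {i})"
                    )
        return self

    def record_by_id(self) -> dict[str, SpiderRecord]:
        return {r.spider_id: r for r in self.records}

    def filter_interactions(self, behaviors: set[str]) -> "AssemblageDataset":
        kept = tuple(ir for ir in self.interactions if ir.behavior in behaviors)
        return replace(self, interactions=kept)
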