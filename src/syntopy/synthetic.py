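"""Synthetic assemblage generator.

Emulates the statistical structure of a focal-follow field campaign on a
multi-species jumping-spider assemblage, so every downstream analysis is
testable without field data:

* per-species isotropic bivariate-normal scatter of observed positions
  around a home center (meters);
* Gaussian seasonal abundance: each individual's observation day-of-year is
  normal around the species' phenology peak, rounded to the day;
* two-state (sun/shade) light bouts from an alternating renewal process with
  exponential sojourns whose means are proportional to (p, 1-p), so the
  long-run sun fraction equals the species' ``sun_preference`` p;
* per-follow path length log-normal with a sex-specific median (males
  scramble-search and travel roughly an order of magnitude farther than
  females);
* interactions drawn among all unordered distinct pairs by weighted sampling
  without replacement, conspecific pairs carrying odds multiplier
  ``conspecific_bias`` (beta = 1 recovers the uniform null; large beta
  drives the heterospecific fraction to zero); behaviors multinomial.

One ``numpy`` generator seeded from ``config.seed`` drives everything; the
draw order is fixed (species in declared order; within a species females
then males; per individual: date, start time, track, light bouts; then
interactions), so a given seed yields a bit-identical dataset across runs.

``default_config()`` encodes the study conditions of the source campaign:
the 108-spider roster, movement medians 276.3 cm (M) / 34 cm (F), sun-use
medians 94%/33% for the most sun- and shade-biased species, early-May and
late-June phenology peaks for the two seasonally shifted species, and 33
interactions with behavior mix 13/14/4/2.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .datamodel import (
    AssemblageDataset,
    BEHAVIORS,
    InteractionRecord,
    LabelVocabulary,
    LightBout,
    LightBoutSeries,
    SpiderRecord,
    Track,
    Waypoint,
)

__all__ = ["SpeciesConfig", "SyntheticConfig", "generate_assemblage", "default_config"]


@dataclass(frozen=True)
class SpeciesConfig:
    """Per-species counts, spatial scatter, phenology, and light preference."""

    n_females: int
    n_males: int
    home_center: tuple[float, float] = (0.0, 0.0)
    home_sd: float = 3.0  # m, isotropic bivariate-normal scatter
    phenology_peak: float = 150.0  # day of year
    phenology_sd: float = 20.0  # days
    sun_preference: float = 0.5  # long-run fraction of follow time in sun

    def validate(self, name: str) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError(f"negative count for species {name!r}")
        if not 0.0 <= self.sun_preference <= 1.0:
            raise ValueError(f"sun_preference out of [0,1] for species {name!r}")
        if self.home_sd <= 0 or self.phenology_sd <= 0:
            raise ValueError(f"non-positive scale for species {name!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    species: dict[str, SpeciesConfig] = field(default_factory=dict)
    movement_median_m: dict[str, float] = field(
        default_factory=lambda: {"F": 0.34, "M": 2.763}
    )
    movement_log_sd: float = 0.9  # shape of the log-normal path-length law
    n_interactions: int = 0
    conspecific_bias: float = 1.0  # odds multiplier beta >= 0 for conspecific pairs
    behavior_mix: dict[str, float] = field(
        default_factory=lambda: {b: 1 / len(BEHAVIORS) for b in BEHAVIORS}
    )
    follow_duration_s: float = 900.0  # 15-min focal follow
    bout_scale_s: float = 240.0  # mean sun+shade cycle length
    year: int = 2021
    seed: int = 0

    def validate(self) -> None:
        for name, sp in self.species.items():
            sp.validate(name)
        if self.n_interactions < 0:
            raise ValueError("n_interactions must be >= 0")
        if self.conspecific_bias < 0:
            raise ValueError("conspecific_bias must be >= 0")
        total = sum(self.behavior_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"behavior_mix sums to {total}, expected 1")
        if any(not 0 <= p <= 1 for p in self.behavior_mix.values()):
            raise ValueError("behavior_mix probabilities must lie in [0,1]")
        if any(m <= 0 for m in self.movement_median_m.values()):
            raise ValueError("movement medians must be positive")


def default_config(seed: int = 0) -> SyntheticConfig:
    """Study-condition defaults (see module docstring)."""
    return SyntheticConfig(
        species={
            "calcaratus": SpeciesConfig(
                n_females=9, n_males=21,
                home_center=(0.0, 0.0), home_sd=2.5,
                phenology_peak=128, phenology_sd=15,
                sun_preference=0.94,
            ),
            "coecatus": SpeciesConfig(
                n_females=21, n_males=14,
                home_center=(4.0, 2.0), home_sd=2.7,
                phenology_peak=176, phenology_sd=15,
                sun_preference=0.60,
            ),
            "decorus": SpeciesConfig(
                n_females=21, n_males=13,
                home_center=(2.0, -2.0), home_sd=8.0,
                phenology_peak=152, phenology_sd=45,
                sun_preference=0.33,
            ),
            "orbus": SpeciesConfig(
                n_females=9, n_males=0,
                home_center=(-3.0, 3.0), home_sd=3.0,
                phenology_peak=160, phenology_sd=45,
                sun_preference=0.50,
            ),
        },
        n_interactions=33,
        conspecific_bias=4.0,
        behavior_mix={
            "looking": 13 / 33,
            "courtship": 14 / 33,
            "aggression": 4 / 33,
            "other": 2 / 33,
        },
        seed=seed,
    )


_PREFIX_LEN = 3


def _spider_id(species: str, sex: str, index: int) -> str:
    return f"{species[:_PREFIX_LEN].upper()}-{sex}{index:02d}"


def _light_bouts(rng: np.random.Generator, p_sun: float, duration: float, scale: float):
    if p_sun <= 0.0 or p_sun >= 1.0:
        state = "sun" if p_sun >= 1.0 else "shade"
        return (LightBout(state=state, start=0.0, end=duration),)
    means = {"sun": scale * p_sun, "shade": scale * (1.0 - p_sun)}
    state = "sun" if rng.random() < p_sun else "shade"
    bouts, t = [], 0.0
    while t < duration:
        sojourn = rng.exponential(means[state])
        end = min(t + max(sojourn, 1e-6), duration)
        bouts.append(LightBout(state=state, start=t, end=end))
        t = end
        state = "shade" if state == "sun" else "sun"
    return tuple(bouts)


def _track(
    rng: np.random.Generator,
    sid: str,
    date: str,
    start_time: str,
    origin: np.ndarray,
    median_length: float,
    log_sd: float,
    duration: float,
) -> Track:
    total = float(rng.lognormal(mean=np.log(median_length), sigma=log_sd))
    n_seg = 1 + int(rng.poisson(4))
    seg = rng.dirichlet(np.ones(n_seg)) * total
    angles = rng.uniform(0, 2 * np.pi, size=n_seg)
    steps = np.column_stack([np.cos(angles), np.sin(angles)]) * seg[:, None]
    xy = np.vstack([origin, origin + np.cumsum(steps, axis=0)])
    gaps = rng.exponential(1.0, size=n_seg + 1)
    t = np.concatenate([[0.0], np.cumsum(gaps[1:]) / gaps[1:].sum() * duration * 0.95])
    wps = tuple(
        Waypoint(x=float(x), y=float(y), t=float(ti)) for (x, y), ti in zip(xy, t)
    )
    return Track(spider_id=sid, date=date, start_time=start_time, waypoints=wps)


def generate_assemblage(config: SyntheticConfig) -> AssemblageDataset:
    """Generate a validated dataset; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    records: list[SpiderRecord] = []
    tracks: list[Track] = []
    light: list[LightBoutSeries] = []

    for species, sp in config.species.items():
        for sex, count in (("F", sp.n_females), ("M", sp.n_males)):
            for i in range(1, count + 1):
                sid = _spider_id(species, sex, i)
                records.append(
                    SpiderRecord(spider_id=sid, species=species, sex=sex)
                )
                doy = int(np.clip(round(rng.normal(sp.phenology_peak, sp.phenology_sd)), 1, 365))
                date = (
                    _dt.date(config.year, 1, 1) + _dt.timedelta(days=doy - 1)
                ).isoformat()
                minutes = int(rng.integers(9 * 60 + 30, 17 * 60 + 30))
                start_time = f"{minutes // 60:02d}:{minutes % 60:02d}"
                origin = rng.normal(sp.home_center, sp.home_sd, size=2)
                tracks.append(
                    _track(
                        rng,
                        sid,
                        date,
                        start_time,
                        origin,
                        config.movement_median_m[sex],
                        config.movement_log_sd,
                        config.follow_duration_s,
                    )
                )
                light.append(
                    LightBoutSeries(
                        spider_id=sid,
                        bouts=_light_bouts(
                            rng,
                            sp.sun_preference,
                            config.follow_duration_s,
                            config.bout_scale_s,
                        ),
                    )
                )

    interactions = _sample_interactions(rng, records, config)

    vocab = LabelVocabulary(species=tuple(config.species))
    return AssemblageDataset(
        records=tuple(records),
        tracks=tuple(tracks),
        light=tuple(light),
        interactions=tuple(interactions),
        metadata={"site": "synthetic", "season": str(config.year), "seed": config.seed},
        vocab=vocab,
    ).validate()


def _sample_interactions(
    rng: np.random.Generator, records: list[SpiderRecord], config: SyntheticConfig
) -> list[InteractionRecord]:
    """Weighted sampling without replacement over all unordered distinct pairs.

    Conspecific pairs carry weight beta, heterospecific pairs weight 1
    (Efraimidis-Spirakis exponential-key scheme, equivalent to successive
    weighted draws without replacement).
    """
    k = config.n_interactions
    if k == 0:
        return []
    n = len(records)
    n_pairs = n * (n - 1) // 2
    if k > n_pairs:
        raise ValueError(
            f"cannot draw {k} interactions from {n_pairs} distinct pairs"
        )
    species = np.array([r.species for r in records])
    iu, ju = np.triu_indices(n, k=1)
    conspecific = species[iu] == species[ju]
    weights = np.where(conspecific, config.conspecific_bias, 1.0)
    # exponential sort keys; zero-weight pairs only ever drawn if unavoidable
    keys = np.full(n_pairs, np.inf)
    pos = weights > 0
    keys[pos] = rng.exponential(1.0, size=int(pos.sum())) / weights[pos]
    if (~pos).any():
        keys[~pos] = 1e18 + rng.random(int((~pos).sum()))
    chosen = np.argsort(keys, kind="stable")[:k]

    behaviors = list(config.behavior_mix)
    probs = np.array([config.behavior_mix[b] for b in behaviors])
    drawn = rng.choice(len(behaviors), size=k, p=probs)
    out = []
    for pair_idx, b_idx in zip(chosen, drawn):
        a, b = records[iu[pair_idx]], records[ju[pair_idx]]
        behavior = behaviors[b_idx]
        initiator = None
        if behavior == "courtship" and {a.sex, b.sex} == {"F", "M"}:
            initiator = a.spider_id if a.sex == "M" else b.spider_id
        out.append(
            InteractionRecord(
                spider_a=a.spider_id,
                spider_b=b.spider_id,
                behavior=behavior,
                initiator=initiator,
            )
        )
    return out
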