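"""CSV readers/writers for assemblage datasets.

One comma-separated file per table with a fixed header:

``records.csv``
    ``spider_id,species,sex,maturity,role``
``tracks.csv``
    ``spider_id,date,start_time,seq,x_m,y_m,t_s`` — one row per waypoint,
    ``seq`` numbering waypoints within a follow.
``light.csv``
    ``spider_id,state,start_s,end_s`` — contiguous sun/shade bouts.
``interactions.csv``
    ``spider_a,spider_b,behavior,initiator`` — ``initiator`` may be blank.

Optional ``metadata.json`` holds site name, season, and the label
vocabulary. Coordinates are planar meters in the site's local frame; times
within a follow are seconds from follow start; dates are ISO-8601.
``read_dataset(write_dataset(d)) == d`` field for field.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import pandas as pd

from .datamodel import (
    AssemblageDataset,
    InteractionRecord,
    LabelVocabulary,
    LightBout,
    LightBoutSeries,
    SpiderRecord,
    Track,
    ValidationError,
    Waypoint,
)

__all__ = ["read_dataset", "write_dataset", "TABLE_FILES"]

TABLE_FILES = {
    "records": "records.csv",
    "tracks": "tracks.csv",
    "light": "light.csv",
    "interactions": "interactions.csv",
}

_SCHEMAS = {
    "records": ["spider_id", "species", "sex", "maturity", "role"],
    "tracks": ["spider_id", "date", "start_time", "seq", "x_m", "y_m", "t_s"],
    "light": ["spider_id", "state", "start_s", "end_s"],
    "interactions": ["spider_a", "spider_b", "behavior", "initiator"],
}


def _resolve_paths(where) -> dict[str, Path]:
    if isinstance(where, (str, os.PathLike)):
        base = Path(where)
        return {k: base / v for k, v in TABLE_FILES.items()}
    return {k: Path(v) for k, v in dict(where).items()}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing {table} table: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{table} table {path} is missing column(s) {missing}; "
            f"expected header {_SCHEMAS[table]}"
        )
    return df


def read_dataset(where) -> AssemblageDataset:
    """Read and validate a dataset from a directory or a ``{table: path}`` mapping.

    Raises :class:`~syntopy.datamodel.ValidationError` with row context on a
    missing column, unknown label, duplicate ``spider_id``, or an interaction
    referencing an unknown individual.
    """
    paths = _resolve_paths(where)
    meta: dict = {}
    vocab = LabelVocabulary()
    meta_path = paths["records"].parent / "metadata.json"
    if meta_path.exists():
        with open(meta_path, encoding="utf-8") as fh:
            payload = json.load(fh)
        meta = payload.get("metadata", {})
        if "species" in payload:
            vocab = LabelVocabulary(species=tuple(payload["species"]))

    rec_df = _read_table(paths["records"], "records")
    records = tuple(
        SpiderRecord(
            spider_id=r.spider_id,
            species=r.species,
            sex=r.sex,
            maturity=r.maturity,
            role=r.role,
        )
        for r in rec_df.itertuples()
    )

    trk_df = _read_table(paths["tracks"], "tracks")
    tracks = []
    if len(trk_df):
        for c in ("x_m", "y_m", "t_s"):
            trk_df[c] = trk_df[c].astype(float)  # float() parse: round-trip exact
        trk_df["seq"] = trk_df["seq"].astype(float).astype(int)
        for (sid, date, start), grp in trk_df.groupby(
            ["spider_id", "date", "start_time"], sort=False
        ):
            grp = grp.sort_values("seq")
            wps = tuple(
                Waypoint(x=float(r.x_m), y=float(r.y_m), t=float(r.t_s))
                for r in grp.itertuples()
            )
            tracks.append(Track(spider_id=sid, date=date, start_time=start, waypoints=wps))

    lt_df = _read_table(paths["light"], "light")
    light = []
    if len(lt_df):
        for c in ("start_s", "end_s"):
            lt_df[c] = lt_df[c].astype(float)
        for sid, grp in lt_df.groupby("spider_id", sort=False):
            grp = grp.sort_values("start_s")
            bouts = tuple(
                LightBout(state=r.state, start=float(r.start_s), end=float(r.end_s))
                for r in grp.itertuples()
            )
            light.append(LightBoutSeries(spider_id=sid, bouts=bouts))

    int_df = _read_table(paths["interactions"], "interactions")
    interactions = tuple(
        InteractionRecord(
            spider_a=r.spider_a,
            spider_b=r.spider_b,
            behavior=r.behavior,
            initiator=r.initiator or None,
        )
        for r in int_df.itertuples()
    )

    return AssemblageDataset(
        records=records,
        tracks=tuple(tracks),
        light=tuple(light),
        interactions=interactions,
        metadata=meta,
        vocab=vocab,
    ).validate()


def write_dataset(dataset: AssemblageDataset, where) -> dict[str, Path]:
    """Write a validated dataset's four tables (plus ``metadata.json``).

    ``where`` is an output directory or a ``{table: path}`` mapping. Returns
    the written paths.
    """
    dataset.validate()
    paths = _resolve_paths(where)
    for p in paths.values():
        p.parent.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            (r.spider_id, r.species, r.sex, r.maturity, r.role)
            for r in dataset.records
        ],
        columns=_SCHEMAS["records"],
    ).to_csv(paths["records"], index=False)

    rows = []
    for tr in dataset.tracks:
        for seq, wp in enumerate(tr.waypoints):
            rows.append((tr.spider_id, tr.date, tr.start_time, seq, wp.x, wp.y, wp.t))
    pd.DataFrame(rows, columns=_SCHEMAS["tracks"]).to_csv(paths["tracks"], index=False)

    rows = []
    for ls in dataset.light:
        for b in ls.bouts:
            rows.append((ls.spider_id, b.state, b.start, b.end))
    pd.DataFrame(rows, columns=_SCHEMAS["light"]).to_csv(paths["light"], index=False)

    pd.DataFrame(
        [
            (ir.spider_a, ir.spider_b, ir.behavior, ir.initiator or "")
            for ir in dataset.interactions
        ],
        columns=_SCHEMAS["interactions"],
    ).to_csv(paths["interactions"], index=False)

    meta_path = paths["records"].parent / "metadata.json"
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(
            {"metadata": dataset.metadata, "species": list(dataset.vocab.species)},
            fh,
            ensure_ascii=False,
            indent=1,
        )
    return paths
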