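"""Stage functions and the end-to-end pipeline.

Each stage reads the documented CSV artifacts and writes its own, so any
stage can be rerun standalone from persisted inputs:

* ``space_stage``  -> ``areas.csv``, ``overlap.csv``, per-group GeoJSON
  isopleths;
* ``activity_stage`` -> ``phenology.csv``, ``light_fractions.csv``,
  ``movement.csv``, ``tests.csv``;
* ``network_stage`` -> ``network_stats.csv``, ``null_distribution.csv``,
  ``model_comparison.csv``, ``edges.csv``;
* ``run_pipeline``  -> all of the above plus ``report.md`` and
  ``manifest.json`` (versions, seeds, input checksums).
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from . import __version__
from .datamodel import AssemblageDataset
from .io import read_dataset, write_dataset
from .activity import (
    dunn_test,
    kruskal_wallis,
    light_fraction,
    path_length,
    phenology_curve,
    scheirer_ray_hare,
)
from .network import (
    build_graph,
    hetero_percentage,
    model_comparison,
    permute_reference,
)
from .space import estimate_kud, isopleth, overlap_matrix, shared_grid
from .synthetic import SpeciesConfig, SyntheticConfig, generate_assemblage

log = logging.getLogger("syntopy")

__all__ = [
    "PipelineConfig",
    "space_stage",
    "activity_stage",
    "network_stage",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Validated YAML-friendly configuration for the full pipeline."""

    data_dir: str | None = None  # read tables from here unless synthetic given
    out_dir: str = "assemblage_out"
    synthetic: SyntheticConfig | None = None
    space: dict = field(
        default_factory=lambda: {
            "group": "species",
            "levels": [50.0, 95.0],
            "grid_cells": 200,
            "bandwidth": "href",
            "extent_pad": 0.5,
            "per_spider_centroid": False,
        }
    )
    activity: dict = field(default_factory=lambda: {"span": 0.75})
    network: dict = field(
        default_factory=lambda: {
            "behaviors": ["all", "courtship"],
            "n_perm": 10_000,
            "seed_base": 1,
            "direction": "less",
        }
    )

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        cfg = cls()
        cfg.data_dir = raw.get("data_dir")
        cfg.out_dir = raw.get("out_dir", cfg.out_dir)
        if "synthetic" in raw:
            syn = dict(raw["synthetic"])
            species = {
                name: SpeciesConfig(**{
                    **params,
                    "home_center": tuple(params.get("home_center", (0.0, 0.0))),
                })
                for name, params in syn.pop("species", {}).items()
            }
            cfg.synthetic = SyntheticConfig(species=species, **syn)
        for block in ("space", "activity", "network"):
            getattr(cfg, block).update(raw.get(block, {}))
        return cfg


def _group_points(dataset: AssemblageDataset, group: str, per_spider_centroid: bool):
    """Waypoint arrays keyed by group label ('species' or 'species_sex')."""
    by_id = dataset.record_by_id()
    points: dict[str, list] = {}
    for tr in dataset.tracks:
        rec = by_id[tr.spider_id]
        label = rec.species if group == "species" else f"{rec.species}_{rec.sex}"
        xy = [(w.x, w.y) for w in tr.waypoints]
        if per_spider_centroid:
            xy = [tuple(np.mean(xy, axis=0))]
        points.setdefault(label, []).extend(xy)
    return {k: np.asarray(v) for k, v in sorted(points.items())}


def space_stage(dataset: AssemblageDataset, out_dir, **opts) -> dict:
    """KUDs, isopleth areas and the pairwise overlap matrix for each group."""
    if not dataset.tracks:
        raise ValueError("space stage requires a tracks table, which is empty/missing")
    opts = {**PipelineConfig().space, **opts}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups = _group_points(dataset, opts["group"], opts["per_spider_centroid"])
    usable = {k: v for k, v in groups.items() if len(v) >= 5}
    for k in set(groups) - set(usable):
        warnings.warn(f"group {k!r} has <5 positions; skipped from space stage")
    if not usable:
        raise ValueError("no group has the 5 positions needed for a KUD")
    grid = shared_grid(
        list(usable.values()),
        grid_cells=opts["grid_cells"],
        extent_pad=opts["extent_pad"],
    )
    kuds = [
        estimate_kud(pts, bandwidth=opts["bandwidth"], grid=grid, label=label)
        for label, pts in usable.items()
    ]

    area_rows, features = [], []
    for kud in kuds:
        for lvl in opts["levels"]:
            _, polys, area = isopleth(kud, lvl)
            area_rows.append((kud.label, lvl, area))
            features.extend(
                {
                    "type": "Feature",
                    "properties": {"group": kud.label, "pct": lvl},
                    "geometry": mapping(poly),
                }
                for poly in polys
            )
    pd.DataFrame(area_rows, columns=["group", "pct", "area_m2"]).to_csv(
        out / "areas.csv", index=False
    )
    with open(out / "isopleths.geojson", "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    ov_rows = []
    overlaps = {}
    for lvl in opts["levels"]:
        ov = overlap_matrix(kuds, lvl)
        overlaps[lvl] = ov
        for i, gi in enumerate(ov.labels):
            for j, gj in enumerate(ov.labels):
                ov_rows.append(
                    (gi, gj, lvl, ov.intersection_areas[i, j], ov.hr[i, j])
                )
    pd.DataFrame(
        ov_rows, columns=["group_i", "group_j", "pct", "A_ij_m2", "HR_ij"]
    ).to_csv(out / "overlap.csv", index=False)
    log.info("space stage: %d groups, levels %s", len(kuds), opts["levels"])
    return {"kuds": kuds, "overlaps": overlaps, "areas": area_rows}


def activity_stage(dataset: AssemblageDataset, out_dir, **opts) -> dict:
    """Phenology smoothing, light/movement summaries, and the rank-test table."""
    opts = {**PipelineConfig().activity, **opts}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_id = dataset.record_by_id()

    dates: dict[str, list[int]] = {}
    for tr in dataset.tracks:
        doy = _dt.date.fromisoformat(tr.date).timetuple().tm_yday
        dates.setdefault(by_id[tr.spider_id].species, []).append(doy)
    phen = None
    if dates:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                phen = phenology_curve(dates, span=opts["span"])
                phen.to_csv(out / "phenology.csv", index=False)
            except ValueError:
                phen = None

    lf_rows = [
        (
            ls.spider_id,
            by_id[ls.spider_id].species,
            by_id[ls.spider_id].sex,
            light_fraction(ls),
        )
        for ls in dataset.light
    ]
    light_df = pd.DataFrame(
        lf_rows, columns=["spider_id", "species", "sex", "sun_fraction"]
    )
    light_df.to_csv(out / "light_fractions.csv", index=False)

    mv: dict[str, float] = {}
    for tr in dataset.tracks:
        mv[tr.spider_id] = mv.get(tr.spider_id, 0.0) + path_length(tr)
    move_df = pd.DataFrame(
        [
            (sid, by_id[sid].species, by_id[sid].sex, dist)
            for sid, dist in mv.items()
        ],
        columns=["spider_id", "species", "sex", "path_m"],
    )
    move_df.to_csv(out / "movement.csv", index=False)

    test_rows = []

    def _battery(df: pd.DataFrame, value: str, name: str) -> None:
        groups = {sp: g[value].to_numpy() for sp, g in df.groupby("species") if len(g)}
        if len(groups) >= 2 and len(df) >= 3:
            kw = kruskal_wallis(list(groups.values()))
            test_rows.append((f"{name}_kruskal_wallis", "species", "H",
                              kw.statistic, kw.df, kw.p, ""))
            for r in dunn_test(groups):
                test_rows.append((f"{name}_dunn", r.comparison, "Z",
                                  r.statistic, "", r.p, r.p_adjusted))
        if df["species"].nunique() >= 2 and df["sex"].nunique() >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                srh = scheirer_ray_hare(
                    df[value].to_numpy(), df["species"].to_numpy(), df["sex"].to_numpy()
                )
            for eff, r in srh.items():
                test_rows.append((f"{name}_scheirer_ray_hare", eff, "H",
                                  r.statistic, r.df, r.p, ""))

    if len(light_df):
        _battery(light_df, "sun_fraction", "light")
    if len(move_df):
        _battery(move_df, "path_m", "movement")
    tests_df = pd.DataFrame(
        test_rows,
        columns=["test", "effect", "statistic_name", "statistic", "df", "p", "p_adj"],
    )
    tests_df.to_csv(out / "tests.csv", index=False)
    log.info("activity stage: %d test rows", len(tests_df))
    return {"phenology": phen, "light": light_df, "movement": move_df, "tests": tests_df}


def network_stage(dataset: AssemblageDataset, out_dir, **opts) -> dict:
    """Observed mixing statistic plus the edge-randomization reference model."""
    opts = {**PipelineConfig().network, **opts}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    behaviors = opts["behaviors"]
    if isinstance(behaviors, str):
        behaviors = [behaviors]

    stats_rows, null_rows, cmp_rows, edge_rows = [], [], [], []
    results = {}
    for tag in behaviors:
        filt = None if tag == "all" else {tag}
        graph = build_graph(dataset, behavior_filter=filt)
        res = permute_reference(
            graph,
            n_perm=opts["n_perm"],
            seed_base=opts["seed_base"],
            direction=opts["direction"],
        )
        results[tag] = (graph, res)
        stats_rows.append(
            (
                tag,
                graph.number_of_nodes(),
                graph.number_of_edges(),
                res.observed_pct,
                res.null_mean,
                res.p_value,
                res.n_perm,
                res.direction,
            )
        )
        null_rows.extend((tag, k + 1, pct) for k, pct in enumerate(res.null_pcts))
        for row in model_comparison(res):
            cmp_rows.append((tag, row["model"], row["reference_pct"],
                             row["observed_pct"], row["p_value"]))
        sp = {v: d["species"] for v, d in graph.nodes(data=True)}
        edge_rows.extend(
            (tag, u, v, d["behavior"], sp[u], sp[v], sp[u] != sp[v])
            for u, v, d in graph.edges(data=True)
        )

    pd.DataFrame(
        stats_rows,
        columns=["network", "n_vertices", "n_edges", "observed_pct",
                 "null_mean_pct", "p_value", "n_perm", "direction"],
    ).to_csv(out / "network_stats.csv", index=False)
    pd.DataFrame(null_rows, columns=["network", "replicate", "hetero_pct"]).to_csv(
        out / "null_distribution.csv", index=False
    )
    pd.DataFrame(
        cmp_rows,
        columns=["network", "model", "reference_pct", "observed_pct", "p_value"],
    ).to_csv(out / "model_comparison.csv", index=False)
    pd.DataFrame(
        edge_rows,
        columns=["network", "spider_a", "spider_b", "behavior",
                 "species_a", "species_b", "heterospecific"],
    ).to_csv(out / "edges.csv", index=False)
    log.info("network stage: %s", {t: r[1].p_value for t, r in results.items()})
    return results


def _checksums(data_dir: Path) -> dict[str, str]:
    out = {}
    for p in sorted(data_dir.glob("*.csv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def run_pipeline(config: PipelineConfig) -> Path:
    """simulate/load -> space -> activity -> network -> report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    if config.synthetic is not None:
        log.info("stage simulate: seed %d", config.synthetic.seed)
        dataset = generate_assemblage(config.synthetic)
        data_dir = out / "data"
        write_dataset(dataset, data_dir)
    elif config.data_dir:
        data_dir = Path(config.data_dir)
        dataset = read_dataset(data_dir)
    else:
        raise ValueError("config needs either a data_dir or a synthetic block")

    report = [
        "# Assemblage analysis report",
        "",
        f"- individuals: {len(dataset.records)}",
        f"- tracks: {len(dataset.tracks)}; light series: {len(dataset.light)}; "
        f"interactions: {len(dataset.interactions)}",
        "",
    ]

    if dataset.tracks:
        try:
            space = space_stage(dataset, out / "space", **config.space)
            report.append("## Space use")
            report.append("")
            report.append("| group | pct | area (m^2) |")
            report.append("|---|---|---|")
            report.extend(
                f"| {g} | {lvl:g} | {a:.1f} |" for g, lvl, a in space["areas"]
            )
            for lvl, ov in space["overlaps"].items():
                report.append("")
                report.append(f"### Overlap HR_ij at {lvl:g}%")
                report.append("")
                report.append("| i \\ j | " + " | ".join(ov.labels) + " |")
                report.append("|---" * (len(ov.labels) + 1) + "|")
                for i, gi in enumerate(ov.labels):
                    cells = " | ".join(f"{ov.hr[i, j]:.2f}" for j in range(len(ov.labels)))
                    report.append(f"| {gi} | {cells} |")
            report.append("")
        except ValueError as exc:
            raise RuntimeError(f"space stage failed: {exc}") from exc

    if dataset.light or dataset.tracks:
        act = activity_stage(dataset, out / "activity", **config.activity)
        if len(act["tests"]):
            report.append("## Rank tests")
            report.append("")
            report.append(act["tests"].to_markdown(index=False))
            report.append("")

    if dataset.interactions:
        nets = network_stage(dataset, out / "network", **config.network)
        report.append("## Interaction networks")
        report.append("")
        for tag, (graph, res) in nets.items():
            report.append(
                f"- **{tag}**: {graph.number_of_edges()} edges among "
                f"{graph.number_of_nodes()} spiders; observed heterospecific "
                f"{res.observed_pct:.1f}% vs null mean {res.null_mean:.1f}% "
                f"(P = {res.p_value:.4g}, direction {res.direction}, "
                f"{res.n_perm} permutations)"
            )
        report.append("")

    (out / "report.md").write_text("\n".join(report), encoding="utf-8")
    manifest = {
        "syntopy_version": __version__,
        "generated": _dt.datetime.now().isoformat(timespec="seconds"),
        "config": {
            "data_dir": str(data_dir),
            "space": config.space,
            "activity": config.activity,
            "network": config.network,
            "synthetic_seed": config.synthetic.seed if config.synthetic else None,
        },
        "input_checksums": _checksums(data_dir),
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log.info("pipeline complete: %s", out)
    return out
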