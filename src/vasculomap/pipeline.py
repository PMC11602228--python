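"""End-to-end pipeline: parse, filter, lay out, route, validate, render.

The two visualisation stages — tile-wise treemap layout of the anatomical
hierarchy, then the vascular overlay routed through the reserved channels —
are chained here behind one configuration object.  Identical inputs and seed
produce byte-identical SVG output.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import io as aio
from .bodyplan import BodyPlan, CHAMBER_IDS, allocate_tile_regions, default_body_plan
from .errors import ConfigError, StageError, VasculomapError
from .render import RenderStyle, render_svg
from .synthetic import DEFAULT_SEED
from .treemap import ALGORITHMS, GridMode, TreemapLayout, layout_grid
from .vascular import VascularLayout, layout_vascular

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run of the visualisation pipeline needs.

    ``algorithm`` selects among the three treemap algorithms (``grid``,
    ``slice_dice``, ``squarified``); ``grid_mode`` only applies to the grid
    algorithm.  ``max_distance`` filters hierarchy nodes farther than this
    from their tile root (valid range 1-16).  ``micro_selection`` optionally
    restricts the vascular contact points to a predefined set.
    """

    hierarchy_file: str | Path
    paths_file: str | Path
    plan: BodyPlan | None = None
    algorithm: str = "grid"
    grid_mode: GridMode = field(default_factory=GridMode.dynamic)
    max_distance: int = 16
    micro_selection: set[str] | None = None
    inset: float = 1.0
    seed: int = DEFAULT_SEED
    out_dir: str | Path | None = None
    style: RenderStyle = field(default_factory=RenderStyle)

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"unknown treemap algorithm {self.algorithm!r}; "
                f"choose from {sorted(ALGORITHMS)}"
            )
        if not isinstance(self.max_distance, int) or not 1 <= self.max_distance <= 16:
            raise ConfigError(
                f"max_distance must be an integer in [1, 16], got {self.max_distance!r}"
            )


@dataclass
class PipelineResult:
    """All artefacts of one pipeline run."""

    forest: aio.AnatomyForest
    plan: BodyPlan
    regions: Mapping[int, object]
    treemap_layouts: dict[int, TreemapLayout]
    retained: list[aio.VascularPath]
    excluded: list[tuple[aio.VascularPath, str]]
    vascular: VascularLayout
    svg: str


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except VasculomapError as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and optionally write artefacts to disk.

    Stages: parse hierarchy -> build forest -> depth filter ->
    microcirculation restriction -> body plan + region allocation -> treemap
    per tile -> parse vascular paths -> endpoint-completeness filter ->
    vascular layout (hubs, internal, external, routing) -> validation ->
    SVG.  Errors carry the name of the stage they arose in.
    """
    config.validate()

    with open(config.hierarchy_file) as fh:
        records = _stage("parse_hierarchy")(aio.parse_hierarchy_table)(fh)
    _log(f"[parse_hierarchy] {len(records)} records")

    # tile roots: ids that never appear as a child
    children = {r.child_id for r in records}
    roots = sorted({r.parent_id for r in records} - children)
    plan = config.plan
    if plan is None:
        if len(roots) != 24:
            raise StageError(
                "body_plan",
                ConfigError(
                    f"default 24-tile plan needs 24 tile roots, found {len(roots)}"
                ),
            )
        plan = default_body_plan(root_ids=roots)

    forest = _stage("build_forest")(aio.build_anatomy_forest)(
        records, roots, microcirculation_ids=set()
    )
    _log(
        f"[build_forest] {len(forest)} nodes, "
        f"{len(forest.dropped_unreachable)} unreachable dropped"
    )

    forest = _stage("depth_filter")(aio.apply_depth_filter)(forest, config.max_distance)

    with open(config.paths_file) as fh:
        paths = _stage("parse_paths")(aio.parse_vascular_paths)(fh)
    _log(f"[parse_paths] {len(paths)} paths")

    # flag microcirculations: every path target present in the forest is a
    # potential contact point, optionally limited to a predefined selection
    for p in paths:
        if p.target_microcirculation in forest.nodes:
            forest.nodes[p.target_microcirculation].is_microcirculation = True
    forest = _stage("restrict_microcirculations")(aio.restrict_microcirculations)(
        forest, config.micro_selection
    )

    regions = _stage("allocate_regions")(allocate_tile_regions)(plan)

    algo = ALGORITHMS[config.algorithm]
    treemap_layouts: dict[int, TreemapLayout] = {}
    for tile in plan.tiles:
        if tile.root_id not in forest.nodes:
            continue
        region = regions[tile.tile_id]
        if config.algorithm == "grid":
            tl = layout_grid(
                forest, tile.root_id, region.treemap_rect, config.grid_mode, config.inset
            )
        else:
            tl = algo(forest, tile.root_id, region.treemap_rect, config.inset)
        treemap_layouts[tile.tile_id] = tl
    n_rects = sum(len(t.rects) for t in treemap_layouts.values())
    _log(f"[treemap] {len(treemap_layouts)} tiles, {n_rects} rectangles")

    retained, excluded = _stage("endpoint_filter")(aio.filter_complete_paths)(
        paths, forest, CHAMBER_IDS
    )
    _log(f"[endpoint_filter] retained {len(retained)}, excluded {len(excluded)}")

    vascular = _stage("vascular_layout")(layout_vascular)(
        plan, regions, forest, treemap_layouts, retained
    )
    rep = vascular.report
    assert rep is not None
    _log(
        f"[vascular] {len(vascular.hubs)} hubs, {len(vascular.edges)} routed edges, "
        f"{len(rep.violations)} violations"
    )

    svg = _stage("render")(render_svg)(
        treemap_layouts, vascular, plan, regions, forest, config.style
    )

    result = PipelineResult(
        forest, plan, regions, treemap_layouts, retained, excluded, vascular, svg
    )
    if config.out_dir is not None:
        _write_artefacts(result, Path(config.out_dir))
    return result


def _write_artefacts(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "layout.svg").write_text(result.svg)
    with open(out_dir / "exclusions.tsv", "w") as fh:
        aio.write_exclusion_report(result.excluded, fh)
    with open(out_dir / "treemap.tsv", "w") as fh:
        fh.write("tile_id\tnode_id\tx\ty\tw\th\tdepth\tis_microcirculation\n")
        for tile_id in sorted(result.treemap_layouts):
            tl = result.treemap_layouts[tile_id]
            for nid in sorted(tl.rects):
                r = tl.rects[nid]
                node = result.forest.nodes[nid]
                fh.write(
                    f"{tile_id}\t{nid}\t{r.x:.3f}\t{r.y:.3f}\t{r.w:.3f}\t{r.h:.3f}"
                    f"\t{node.depth}\t{int(node.is_microcirculation)}\n"
                )
    with open(out_dir / "vascular_nodes.tsv", "w") as fh:
        fh.write("node_id\tx\ty\tkind\n")
        for nid in sorted(result.vascular.node_positions):
            x, y = result.vascular.node_positions[nid]
            kind = (
                "chamber"
                if nid in CHAMBER_IDS
                else ("internal" if nid in result.vascular.node_tiles else "external")
            )
            fh.write(f"{nid}\t{x:.3f}\t{y:.3f}\t{kind}\n")
    with open(out_dir / "vascular_edges.tsv", "w") as fh:
        fh.write("source\ttarget\tvessel_type\tkind\tpoints\n")
        for e in sorted(result.vascular.edges, key=lambda e: (e.kind, e.source, e.target)):
            pts = ";".join(f"{x:.3f},{y:.3f}" for x, y in e.points)
            fh.write(f"{e.source}\t{e.target}\t{e.vessel_type}\t{e.kind}\t{pts}\n")
    rep = result.vascular.report
    if rep is not None:
        import json

        with open(out_dir / "validation.jsonl", "w") as fh:
            fh.write(json.dumps({"counts": rep.counts(), "ok": rep.ok}) + "\n")
            for kind, detail in rep.violations:
                fh.write(json.dumps({"violation": kind, "detail": detail}) + "\n")
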