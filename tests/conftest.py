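"""Shared fixtures: small synthetic scenes built fresh per test."""

from __future__ import annotations

import pytest

from vasculomap import io as aio
from vasculomap.bodyplan import CHAMBER_IDS, allocate_tile_regions, default_body_plan
from vasculomap.synthetic import (
    AnatomyGenConfig,
    VascularGenConfig,
    generate_anatomy,
    generate_vascular_paths,
)
from vasculomap.treemap import GridMode, layout_grid


def build_scene(
    seed: int = 1,
    n_tiles: int = 24,
    max_depth: int = 4,
    n_paths: int = 40,
    incomplete_fraction: float = 0.0,
):
    """Generate anatomy + paths + plan + treemaps for one seed."""
    recs, roots, micro = generate_anatomy(
        AnatomyGenConfig(n_tiles=n_tiles, max_depth=max_depth, seed=seed)
    )
    forest = aio.build_anatomy_forest(recs, roots, micro)
    plan = default_body_plan(root_ids=roots) if n_tiles == 24 else None
    regions = allocate_tile_regions(plan) if plan else None
    layouts = None
    if plan:
        layouts = {
            t.tile_id: layout_grid(
                forest, t.root_id, regions[t.tile_id].treemap_rect, GridMode.dynamic(), 1.0
            )
            for t in plan.tiles
        }
    if n_paths:
        paths = generate_vascular_paths(
            forest,
            CHAMBER_IDS,
            VascularGenConfig(
                n_paths=n_paths, incomplete_fraction=incomplete_fraction, seed=seed
            ),
        )
        retained, excluded = aio.filter_complete_paths(paths, forest, CHAMBER_IDS)
    else:
        paths, retained, excluded = [], [], []
    return {
        "records": recs,
        "roots": roots,
        "micro": micro,
        "forest": forest,
        "plan": plan,
        "regions": regions,
        "layouts": layouts,
        "paths": paths,
        "retained": retained,
        "excluded": excluded,
    }


@pytest.fixture
def small_scene():
    return build_scene(seed=11, n_paths=30, incomplete_fraction=0.2)


@pytest.fixture
def default_plan():
    return default_body_plan()
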