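"""Treemap algorithms: frozen hand-traced layouts plus structural invariants."""

import math

import pytest

from conftest import build_scene
from vasculomap.errors import CapacityError
from vasculomap.io import HierarchyRecord, RelationKind, build_anatomy_forest
from vasculomap.treemap import (
    GridMode,
    Rect,
    layout_grid,
    layout_quality,
    layout_slice_and_dice,
    layout_squarified,
)

UNIT = Rect(0, 0, 1, 1)


def star_forest(k, root="FMA1"):
    records = [
        HierarchyRecord(root, f"FMA{i + 10}", RelationKind.REGIONAL_PART)
        for i in range(k)
    ]
    return build_anatomy_forest(records, [root])


def nested_forest():
    # root -> {X, Y}; X -> {x1, x2}; ids chosen so sorted order matches
    records = [
        HierarchyRecord("FMA1", "FMA2", RelationKind.REGIONAL_PART),  # X
        HierarchyRecord("FMA1", "FMA3", RelationKind.REGIONAL_PART),  # Y
        HierarchyRecord("FMA2", "FMA21", RelationKind.REGIONAL_PART),
        HierarchyRecord("FMA2", "FMA22", RelationKind.REGIONAL_PART),
    ]
    return build_anatomy_forest(records, ["FMA1"])


def approx_rect(r, x, y, w, h, tol=1e-9):
    assert abs(r.x - x) < tol and abs(r.y - y) < tol
    assert abs(r.w - w) < tol and abs(r.h - h) < tol


def assert_invariants(layout, forest, inset):
    """Containment, sibling disjointness, area conservation, equal shares.

    Area conservation at inset 0: slice&dice and squarified tile the parent
    exactly; the grid algorithm assigns each child exactly one of rows*cols
    equal cells, so children jointly cover k/(rows*cols) of the parent with
    trailing cells empty.
    """
    grid = layout.algorithm.startswith("grid")
    for nid, node in forest.nodes.items():
        r = layout.rects[nid]
        kids = node.children
        for kid in kids:
            assert r.contains_rect(layout.rects[kid]), f"{kid} outside {nid}"
        for i, a in enumerate(kids):
            for b in kids[i + 1:]:
                assert not layout.rects[a].interior_overlaps(layout.rects[b])
        if kids and inset == 0:
            k = len(kids)
            total = sum(layout.rects[c].area for c in kids)
            if grid:
                cols = math.ceil(math.sqrt(k))
                rows = math.ceil(k / cols)
                expected = r.area * k / (rows * cols)
            else:
                expected = r.area
            assert math.isclose(total, expected, rel_tol=1e-9, abs_tol=1e-12)
            areas = [layout.rects[c].area for c in kids]
            assert max(areas) - min(areas) <= 1e-9 * max(r.area, 1.0)


class TestSliceAndDice:
    def test_two_children_split_vertically(self):
        layout = layout_slice_and_dice(star_forest(2), "FMA1", UNIT)
        approx_rect(layout.rects["FMA10"], 0, 0, 0.5, 1)
        approx_rect(layout.rects["FMA11"], 0.5, 0, 0.5, 1)

    def test_single_child_fills_parent_minus_inset(self):
        layout = layout_slice_and_dice(star_forest(1), "FMA1", Rect(0, 0, 10, 10), inset=1)
        approx_rect(layout.rects["FMA10"], 1, 1, 8, 8)

    def test_alternating_axis_recursion(self):
        layout = layout_slice_and_dice(nested_forest(), "FMA1", UNIT)
        approx_rect(layout.rects["FMA2"], 0, 0, 0.5, 1)
        approx_rect(layout.rects["FMA21"], 0, 0, 0.5, 0.5)
        approx_rect(layout.rects["FMA22"], 0, 0.5, 0.5, 0.5)


class TestSquarified:
    def test_single_child_fills_parent(self):
        layout = layout_squarified(star_forest(1), "FMA1", UNIT)
        approx_rect(layout.rects["FMA10"], 0, 0, 1, 1)

    def test_four_equal_children_are_quadrants(self):
        layout = layout_squarified(star_forest(4), "FMA1", UNIT)
        sizes = sorted(
            (r.x, r.y) for nid, r in layout.rects.items() if nid != "FMA1"
        )
        assert sizes == [(0, 0), (0, 0.5), (0.5, 0), (0.5, 0.5)]
        for nid, r in layout.rects.items():
            if nid != "FMA1":
                assert abs(r.w - 0.5) < 1e-9 and abs(r.h - 0.5) < 1e-9

    def test_three_equal_children_strip_acceptance(self):
        # greedy strip growth: two cells in a 2/3-wide column, one full-height
        layout = layout_squarified(star_forest(3), "FMA1", UNIT)
        approx_rect(layout.rects["FMA10"], 0, 0, 2 / 3, 0.5)
        approx_rect(layout.rects["FMA11"], 0, 0.5, 2 / 3, 0.5)
        approx_rect(layout.rects["FMA12"], 2 / 3, 0, 1 / 3, 1)


class TestGrid:
    def test_four_children_dynamic_2x2(self):
        layout = layout_grid(star_forest(4), "FMA1", UNIT)
        approx_rect(layout.rects["FMA10"], 0, 0, 0.5, 0.5)
        approx_rect(layout.rects["FMA13"], 0.5, 0.5, 0.5, 0.5)

    def test_five_children_dynamic_3x2(self):
        layout = layout_grid(star_forest(5), "FMA1", UNIT)
        for i in range(5):
            r = layout.rects[f"FMA1{i}"]
            assert abs(r.w - 1 / 3) < 1e-9 and abs(r.h - 0.5) < 1e-9
        approx_rect(layout.rects["FMA13"], 0, 0.5, 1 / 3, 0.5)

    def test_fixed_grid_fills_row_major(self):
        layout = layout_grid(star_forest(3), "FMA1", UNIT, GridMode.fixed(2, 2))
        approx_rect(layout.rects["FMA10"], 0, 0, 0.5, 0.5)
        approx_rect(layout.rects["FMA11"], 0.5, 0, 0.5, 0.5)
        approx_rect(layout.rects["FMA12"], 0, 0.5, 0.5, 0.5)

    def test_fixed_grid_overflow_raises(self):
        with pytest.raises(CapacityError):
            layout_grid(star_forest(5), "FMA1", UNIT, GridMode.fixed(2, 2))


class TestQuality:
    def test_square_leaves_have_unit_aspect(self):
        forest = star_forest(4)
        stats = layout_quality(layout_grid(forest, "FMA1", UNIT), forest)
        assert stats["mean_aspect"] == stats["max_aspect"] == 1.0
        assert stats["leaf_count"] == 4

    def test_two_to_one_leaf(self):
        forest = star_forest(2)
        stats = layout_quality(layout_slice_and_dice(forest, "FMA1", UNIT), forest)
        assert stats["max_aspect"] == 2.0

    def test_empty_layout_errors(self):
        forest = star_forest(1)
        layout = layout_grid(forest, "FMA1", UNIT)
        layout.rects = {}
        with pytest.raises(Exception):
            layout_quality(layout, forest)


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("algo", [layout_slice_and_dice, layout_squarified, layout_grid])
def test_invariants_on_random_trees(seed, algo):
    """Containment, sibling disjointness, area conservation, equal shares."""
    scene = build_scene(seed=seed, n_tiles=1, max_depth=4, n_paths=0)
    forest = scene["forest"]
    root = scene["roots"][0]
    layout = algo(forest, root, Rect(0, 0, 200, 150))
    assert_invariants(layout, forest, inset=0)


def test_grid_beats_slice_and_dice_on_stars():
    """On k-child stars in a square, the grid's worst aspect never exceeds
    slice&dice's k, strictly for k >= 5 (closed-form oracle)."""
    for k in range(4, 26):
        forest = star_forest(k)
        grid_stats = layout_quality(layout_grid(forest, "FMA1", UNIT), forest)
        sd_stats = layout_quality(layout_slice_and_dice(forest, "FMA1", UNIT), forest)
        cols = math.ceil(math.sqrt(k))
        rows = math.ceil(k / cols)
        expected_grid = max(cols / rows, rows / cols)
        assert math.isclose(grid_stats["max_aspect"], expected_grid, rel_tol=1e-9)
        assert math.isclose(sd_stats["max_aspect"], float(k), rel_tol=1e-9)
        assert grid_stats["max_aspect"] <= sd_stats["max_aspect"]
        if k >= 5:
            assert grid_stats["max_aspect"] < sd_stats["max_aspect"]
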