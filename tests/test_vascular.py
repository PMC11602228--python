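"""Vascular engine: graph building, cluster labels, hubs, routing, validation."""

import pytest

from conftest import build_scene
from vasculomap import io as aio
from vasculomap.bodyplan import allocate_tile_regions, default_body_plan
from vasculomap.errors import AmbiguityError, VasculomapError
from vasculomap.io import HierarchyRecord, RelationKind, VascularPath
from vasculomap.treemap import GridMode, layout_grid
from vasculomap.vascular import (
    RoutedEdge,
    build_vascular_graph,
    identify_hubs,
    layout_tile_internal,
    layout_vascular,
    order_tiles_by_heart_distance,
    propagate_cluster_ids,
    tile_node_sets,
    validate_vascular_layout,
)


def rec(p, c):
    return HierarchyRecord(p, c, RelationKind.REGIONAL_PART)


def forest_of(records, roots, micro):
    return aio.build_anatomy_forest(records, roots, micro)


def vpath(pid, chamber, segs, target, vtype="arterial"):
    return VascularPath(pid, chamber, tuple(segs), target, vtype)


class TestGraphBuilding:
    def test_shared_prefix_merges(self):
        forest = forest_of(
            [rec("FMA10", "FMA11"), rec("FMA10", "FMA12")], ["FMA10"], {"FMA11", "FMA12"}
        )
        paths = [
            vpath("p1", "LV", ["FMA500", "FMA501", "FMA10"], "FMA11"),
            vpath("p2", "LV", ["FMA500", "FMA501", "FMA10"], "FMA11"),
        ]
        g = build_vascular_graph(paths, forest, {1: ["FMA10", "FMA11", "FMA12"]})
        assert sorted(g.g.nodes) == ["FMA10", "FMA500", "FMA501", "LV"]
        assert g.g.number_of_edges() == 3

    def test_single_path_is_a_chain(self):
        forest = forest_of([rec("FMA10", "FMA11")], ["FMA10"], {"FMA11"})
        g = build_vascular_graph(
            [vpath("p1", "LV", ["FMA500", "FMA10"], "FMA11")], forest, {1: ["FMA10", "FMA11"]}
        )
        assert [g.g.out_degree(n) for n in ["LV", "FMA500", "FMA10"]] == [1, 1, 0]

    def test_segment_in_two_tiles_is_ambiguous(self):
        forest = forest_of([rec("FMA10", "FMA11")], ["FMA10"], {"FMA11"})
        with pytest.raises(AmbiguityError, match="FMA10"):
            build_vascular_graph(
                [vpath("p1", "LV", ["FMA10"], "FMA11")],
                forest,
                {1: ["FMA10"], 2: ["FMA10"]},
            )


class TestClusterPropagation:
    def test_chain_propagation(self):
        forest = forest_of([rec("FMA10", "FMA11")], ["FMA10"], {"FMA11"})
        g = build_vascular_graph(
            [vpath("p1", "LV", ["FMA500", "FMA501", "FMA10"], "FMA11")],
            forest,
            {1: ["FMA10", "FMA11"]},
        )
        labels = propagate_cluster_ids(g)
        for nid in ["FMA10", "FMA501", "FMA500", "LV"]:
            assert labels[nid] == frozenset({"FMA11"})

    def test_junction_takes_union(self):
        forest = forest_of(
            [rec("FMA10", "FMA11"), rec("FMA10", "FMA12"),
             rec("FMA11", "FMA13"), rec("FMA12", "FMA14")],
            ["FMA10"],
            {"FMA13", "FMA14"},
        )
        paths = [
            vpath("p1", "LV", ["FMA500", "FMA11"], "FMA13"),
            vpath("p2", "LV", ["FMA500", "FMA12"], "FMA14"),
        ]
        g = build_vascular_graph(paths, forest, {1: forest.tree_nodes("FMA10")})
        labels = propagate_cluster_ids(g)
        assert labels["FMA500"] == frozenset({"FMA13", "FMA14"})

    def test_leaf_without_target_errors(self):
        forest = forest_of([rec("FMA10", "FMA11")], ["FMA10"], {"FMA11"})
        g = build_vascular_graph(
            [vpath("p1", "LV", ["FMA500"], "FMA11")], forest, {1: ["FMA10", "FMA11"]}
        )
        del g.leaf_targets["FMA500"]
        with pytest.raises(VasculomapError, match="FMA500"):
            propagate_cluster_ids(g)


class TestHubIdentification:
    def _hubs(self, records, roots, micro, paths, tiles):
        forest = forest_of(records, roots, micro)
        g = build_vascular_graph(paths, forest, tiles)
        return g, identify_hubs(g, propagate_cluster_ids(g))

    def test_highest_in_tile_singleton_is_hub(self):
        # external -> P -> L inside the tile; hub is P, not the deeper L
        records = [rec("FMA10", "FMA11"), rec("FMA11", "FMA12"), rec("FMA12", "FMA13")]
        paths = [vpath("p1", "LV", ["FMA500", "FMA11", "FMA12"], "FMA13")]
        _, hubs = self._hubs(
            records, ["FMA10"], {"FMA13"}, paths, {1: ["FMA10", "FMA11", "FMA12", "FMA13"]}
        )
        assert [(h.node_id, h.tile_id, h.cluster_id) for h in hubs] == [
            ("FMA11", 1, "FMA13")
        ]

    def test_singleton_boundary_below_multilabel_junction(self):
        # J carries {M1, M2}; its children B1, B2 are the hubs
        records = [
            rec("FMA10", "FMA20"), rec("FMA20", "FMA21"), rec("FMA20", "FMA22"),
            rec("FMA21", "FMA31"), rec("FMA22", "FMA32"),
        ]
        paths = [
            vpath("p1", "LV", ["FMA500", "FMA20", "FMA21"], "FMA31"),
            vpath("p2", "LV", ["FMA500", "FMA20", "FMA22"], "FMA32"),
        ]
        _, hubs = self._hubs(
            records, ["FMA10"], {"FMA31", "FMA32"}, paths,
            {1: ["FMA10", "FMA20", "FMA21", "FMA22", "FMA31", "FMA32"]},
        )
        assert {(h.node_id, h.cluster_id) for h in hubs} == {
            ("FMA21", "FMA31"),
            ("FMA22", "FMA32"),
        }

    def test_leaf_is_its_own_hub_when_chain_leaves_tile(self):
        records = [rec("FMA10", "FMA11"), rec("FMA11", "FMA12")]
        paths = [vpath("p1", "LV", ["FMA500", "FMA11"], "FMA12")]
        _, hubs = self._hubs(
            records, ["FMA10"], {"FMA12"}, paths, {1: ["FMA10", "FMA11", "FMA12"]}
        )
        assert [(h.node_id, h.cluster_id) for h in hubs] == [("FMA11", "FMA12")]


def brute_force_hubs(graph):
    """Oracle: test every node against the hub definition, recomputing each
    node's descendant target set by direct traversal."""

    def desc_targets(n):
        out, seen, stack = set(), set(), [n]
        while stack:
            m = stack.pop()
            if m in seen:
                continue
            seen.add(m)
            if m in graph.leaf_targets:
                out.add(graph.leaf_targets[m])
            stack.extend(graph.g.successors(m))
        return out

    hubs = set()
    for n in graph.g.nodes:
        tile = graph.tile_of(n)
        if tile is None:
            continue
        targets = desc_targets(n)
        if len(targets) != 1:
            continue
        if any(
            graph.tile_of(p) == tile and desc_targets(p) == targets
            for p in graph.g.predecessors(n)
        ):
            continue
        hubs.add((n, tile, next(iter(targets))))
    return hubs


@pytest.mark.parametrize("seed", range(20))
def test_hub_oracle_equivalence_on_seeded_graphs(seed):
    scene = build_scene(seed=seed, n_paths=6, max_depth=3)
    graph = build_vascular_graph(
        scene["retained"], scene["forest"], tile_node_sets(scene["forest"], scene["plan"])
    )
    hubs = identify_hubs(graph, propagate_cluster_ids(graph))
    assert {(h.node_id, h.tile_id, h.cluster_id) for h in hubs} == brute_force_hubs(graph)
    # at most one hub per (tile, cluster)
    keys = [(h.tile_id, h.cluster_id) for h in hubs]
    assert len(keys) == len(set(keys))


class TestTileOrdering:
    def test_heart_tile_first_and_ties_by_id(self, small_scene):
        graph = build_vascular_graph(
            small_scene["retained"],
            small_scene["forest"],
            tile_node_sets(small_scene["forest"], small_scene["plan"]),
        )
        order = order_tiles_by_heart_distance(small_scene["plan"], graph)
        assert order[0] == small_scene["plan"].heart_tile.tile_id
        assert sorted(order) == list(range(1, 25))

    def test_untouched_tiles_after_reachable(self):
        scene = build_scene(seed=41, n_paths=3)
        graph = build_vascular_graph(
            scene["retained"], scene["forest"], tile_node_sets(scene["forest"], scene["plan"])
        )
        order = order_tiles_by_heart_distance(scene["plan"], graph)
        touched = {
            graph.tile_of(n) for n in graph.g.nodes if graph.tile_of(n) is not None
        }
        touched.add(scene["plan"].heart_tile.tile_id)
        untouched = [t for t in order if t not in touched]
        if untouched:
            first_untouched = order.index(untouched[0])
            assert all(order.index(t) < first_untouched for t in touched)


class TestInternalLayout:
    def test_tile_without_retained_leaves_is_empty(self, small_scene):
        plan, forest = small_scene["plan"], small_scene["forest"]
        graph = build_vascular_graph(
            small_scene["retained"], forest, tile_node_sets(forest, plan)
        )
        assignment = propagate_cluster_ids(graph)
        hubs = identify_hubs(graph, assignment)
        targeted_tiles = {h.tile_id for h in hubs}
        empty_tile = next(
            t.tile_id for t in plan.tiles if t.tile_id not in targeted_tiles
        )
        part = layout_tile_internal(
            empty_tile,
            small_scene["regions"][empty_tile],
            hubs,
            graph,
            small_scene["layouts"][empty_tile],
            assignment,
        )
        assert part.node_positions == {} and part.edges == []

    def test_leaf_chain_stays_in_channel_with_few_bends(self, small_scene):
        vl = layout_vascular(
            small_scene["plan"],
            small_scene["regions"],
            small_scene["forest"],
            small_scene["layouts"],
            small_scene["retained"],
        )
        for e in vl.edges:
            if e.kind == "anchor":
                assert len(e.bends) <= 2
            if e.kind == "internal":
                assert len(e.bends) <= 2


class TestValidation:
    def _layout(self, scene):
        return layout_vascular(
            scene["plan"], scene["regions"], scene["forest"],
            scene["layouts"], scene["retained"],
        )

    def test_valid_layout_passes_all_checks(self, small_scene):
        vl = self._layout(small_scene)
        rep = vl.report
        assert rep.ok
        assert rep.n_paths_connected == rep.n_paths == len(small_scene["retained"])
        assert rep.n_diagonal == 0 and rep.n_treemap_crossings == 0

    def test_injected_diagonal_is_flagged(self, small_scene):
        vl = self._layout(small_scene)
        vl.edges.append(
            RoutedEdge("X1", "X2", "arterial", ((0.0, 0.0), (10.0, 10.0)), "external")
        )
        rep = validate_vascular_layout(
            vl, small_scene["layouts"], small_scene["regions"],
            small_scene["retained"], small_scene["forest"], small_scene["plan"],
        )
        assert rep.n_diagonal == 1
        assert any(k == "diagonal" for k, _ in rep.violations)

    def test_unrendered_path_breaks_completeness(self, small_scene):
        vl = self._layout(small_scene)
        victim = small_scene["retained"][0]
        vl.edges = [
            e for e in vl.edges
            if not (e.source == victim.segments[-1] and e.kind == "anchor")
        ]
        rep = validate_vascular_layout(
            vl, small_scene["layouts"], small_scene["regions"],
            small_scene["retained"], small_scene["forest"], small_scene["plan"],
        )
        assert rep.n_paths_connected < rep.n_paths
        assert ("completeness", victim.path_id) in rep.violations


def test_tile_independence_under_treemap_perturbation():
    """Growing tile A's anatomy tree must not move tile B's internal vessels."""
    seed = 55
    base = build_scene(seed=seed, n_paths=30)
    layout_a = layout_vascular(
        base["plan"], base["regions"], base["forest"], base["layouts"], base["retained"]
    )

    grown_root = base["roots"][0]  # tile 1
    records = base["records"] + [rec(grown_root, "FMA999999")]
    forest2 = aio.build_anatomy_forest(records, base["roots"], base["micro"])
    layouts2 = {
        t.tile_id: layout_grid(
            forest2, t.root_id, base["regions"][t.tile_id].treemap_rect,
            GridMode.dynamic(), 1.0,
        )
        for t in base["plan"].tiles
    }
    retained2, _ = aio.filter_complete_paths(
        base["paths"], forest2, ("LV", "RV", "LA", "RA")
    )
    layout_b = layout_vascular(
        base["plan"], base["regions"], forest2, layouts2, retained2
    )

    grown_tile = base["plan"].tile_by_root(grown_root).tile_id
    for nid, tile in layout_a.node_tiles.items():
        if tile != grown_tile:
            assert layout_a.node_positions[nid] == layout_b.node_positions[nid]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_routing_suite_on_seeded_scenes(seed):
    """Orthogonality, channel containment, zero crossings, completeness."""
    scene = build_scene(seed=seed, n_paths=40, incomplete_fraction=0.25)
    vl = layout_vascular(
        scene["plan"], scene["regions"], scene["forest"],
        scene["layouts"], scene["retained"],
    )
    rep = vl.report
    assert rep.n_diagonal == 0
    assert rep.n_channel_violations == 0
    assert rep.n_treemap_crossings == 0
    assert rep.n_side_violations == 0
    assert rep.n_paths_connected == len(scene["retained"])
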