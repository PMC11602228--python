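"""Channel-constrained vascular layout over the tiled treemap.

The vascular graph (chambers, vessel segments, leaves adjacent to target
microcirculations) is laid out in four steps:

1. **hub identification** — every leaf is labelled with the id of its target
   microcirculation (its *cluster id*); labels propagate bottom-up by union,
   and the hub of a (tile, cluster) pair is the highest node inside the tile
   still carrying that single cluster id;
2. **internal tile layout** — from each leaf, positions are built bottom-up
   towards the hub inside the tile's vascular channel, evenly spaced, with
   arterial clusters in the top channel and venous in the bottom;
3. **external layout** — nodes not placed inside a tile are positioned along
   per-(chamber, tile) spines that run through the gutters between tiles,
   ordered by distance from the heart;
4. **hub routing** — one orthogonal edge per hub (or unplaced leaf) to its
   parent, confined to channels and gutters.

All geometry is axis-parallel.  Arterial vessels use the top channels, the
left side lanes of their target tile and the corridor band *above* a tile
row; venous vessels mirror this at the bottom/right.  Vessels touch the
treemap only at contact anchors: the projection of a microcirculation
rectangle's centre onto the treemap boundary (top edge for arterial, bottom
for venous), so no routed segment ever crosses a treemap leaf interior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .bodyplan import BodyPlan, TileRegion
from .errors import AmbiguityError, RoutingError, VasculomapError
from .io import AnatomyForest, VascularPath
from .treemap import Rect, TreemapLayout

__all__ = [
    "VascularGraph",
    "ClusterAssignment",
    "Hub",
    "RoutedEdge",
    "VascularLayout",
    "ValidationReport",
    "build_vascular_graph",
    "tile_node_sets",
    "propagate_cluster_ids",
    "identify_hubs",
    "layout_tile_internal",
    "order_tiles_by_heart_distance",
    "layout_external",
    "route_hub_edges",
    "validate_vascular_layout",
    "layout_vascular",
]

Point = tuple[float, float]

_EPS = 1e-6


# ---------------------------------------------------------------------------
# graph construction


class VascularGraph:
    """Merged union of vascular path chains.

    Edges are directed from the chambers toward the periphery.  A node is
    tagged with a tile when its identifier occurs in that tile's anatomy
    tree; otherwise it is *external*.  ``leaf_targets`` maps each path's
    terminal segment to its target microcirculation.
    """

    def __init__(self) -> None:
        self.g = nx.DiGraph()
        self.roots: list[str] = []
        self.leaf_targets: dict[str, str] = {}
        self.target_vessel: dict[str, str] = {}
        self.paths: dict[str, VascularPath] = {}

    @property
    def nodes(self):
        return self.g.nodes

    def tile_of(self, node_id: str) -> int | None:
        return self.g.nodes[node_id].get("tile")

    def children(self, node_id: str) -> list[str]:
        return sorted(self.g.successors(node_id))

    def parents(self, node_id: str) -> list[str]:
        return sorted(self.g.predecessors(node_id))


def tile_node_sets(forest: AnatomyForest, plan: BodyPlan) -> dict[int, set[str]]:
    """Per-tile node-id sets, keyed by tile id, derived from the forest."""
    out: dict[int, set[str]] = {}
    for root in forest.roots:
        tile = plan.tile_by_root(root)
        if tile is None:
            continue
        out[tile.tile_id] = set(forest.tree_nodes(root))
    return out


def build_vascular_graph(
    paths: Iterable[VascularPath],
    forest: AnatomyForest,
    tile_nodes: Mapping[int, Iterable[str]],
) -> VascularGraph:
    """Merge endpoint-filtered path chains into one directed graph.

    ``tile_nodes`` maps tile ids to the node ids of that tile's anatomy
    tree; a segment id claimed by two different tiles raises
    :class:`AmbiguityError`.
    """
    assignment: dict[str, int] = {}
    for tile_id in sorted(tile_nodes):
        for nid in tile_nodes[tile_id]:
            if nid in assignment and assignment[nid] != tile_id:
                raise AmbiguityError(
                    f"segment {nid} claimed by tiles {assignment[nid]} and {tile_id}"
                )
            assignment[nid] = tile_id

    vg = VascularGraph()
    for p in paths:
        vg.paths[p.path_id] = p
        chain = [p.chamber_id, *p.segments]
        if p.chamber_id not in vg.g:
            vg.g.add_node(p.chamber_id, tile=None, chamber=True)
            vg.roots.append(p.chamber_id)
        for nid in p.segments:
            if nid not in vg.g:
                vg.g.add_node(nid, tile=assignment.get(nid), chamber=False)
        for u, v in zip(chain, chain[1:]):
            if vg.g.has_edge(u, v):
                vg.g.edges[u, v]["types"].add(p.vessel_type)
            else:
                vg.g.add_edge(u, v, types={p.vessel_type})
        leaf = p.segments[-1]
        prior = vg.leaf_targets.get(leaf)
        if prior is not None and prior != p.target_microcirculation:
            raise VasculomapError(
                f"segment {leaf} terminates paths to two different "
                f"microcirculations ({prior}, {p.target_microcirculation})"
            )
        vg.leaf_targets[leaf] = p.target_microcirculation
        vg.target_vessel[p.target_microcirculation] = p.vessel_type
    vg.roots.sort()
    return vg


# ---------------------------------------------------------------------------
# cluster labels and hubs


@dataclass
class ClusterAssignment:
    """Bottom-up cluster labels: node id -> set of target microcirculation ids."""

    labels: dict[str, frozenset[str]]

    def __getitem__(self, node_id: str) -> frozenset[str]:
        return self.labels[node_id]


def propagate_cluster_ids(graph: VascularGraph) -> ClusterAssignment:
    """Assign each leaf its target's cluster id and propagate unions upward.

    Labels are computed in reverse topological order, so every parent's label
    is the union of its children's (plus its own target when a node both
    terminates a path and continues others).  A terminal node without a
    target microcirculation is an error.
    """
    try:
        order = list(nx.topological_sort(graph.g))
    except nx.NetworkXUnfeasible as exc:
        raise VasculomapError("vascular graph contains a cycle") from exc
    labels: dict[str, set[str]] = {}
    for nid in reversed(order):
        lab: set[str] = set()
        if nid in graph.leaf_targets:
            lab.add(graph.leaf_targets[nid])
        for child in graph.g.successors(nid):
            lab |= labels[child]
        if not lab and graph.g.out_degree(nid) == 0:
            raise VasculomapError(
                f"vascular leaf {nid} has no target microcirculation"
            )
        labels[nid] = lab
    return ClusterAssignment({n: frozenset(s) for n, s in labels.items()})


@dataclass
class Hub:
    """Transition point between external and internal layout.

    The highest node inside a tile whose descendants all belong to one
    cluster; the cluster id is the target microcirculation's id.  The
    position is filled in by the internal tile layout.
    """

    node_id: str
    tile_id: int
    cluster_id: str
    position: Point | None = None


def identify_hubs(
    graph: VascularGraph, assignment: ClusterAssignment
) -> list[Hub]:
    """Find, per (tile, cluster), the highest in-tile node with that single label.

    A node qualifies when it sits inside a tile, carries exactly one cluster
    id, and no parent inside the same tile carries that same single id (the
    parent is either outside the tile or a multi-cluster junction).  Clusters
    entirely outside any tile yield no hub and are handled by the external
    layout.
    """
    hubs: list[Hub] = []
    for nid in graph.g.nodes:
        tile = graph.tile_of(nid)
        if tile is None:
            continue
        label = assignment[nid]
        if len(label) != 1:
            continue
        covered = any(
            graph.tile_of(p) == tile and assignment[p] == label
            for p in graph.g.predecessors(nid)
        )
        if not covered:
            hubs.append(Hub(nid, tile, next(iter(label))))
    hubs.sort(key=lambda h: (h.tile_id, h.cluster_id, h.node_id))
    return hubs


# ---------------------------------------------------------------------------
# routed edges and layout containers


@dataclass(frozen=True)
class RoutedEdge:
    """An orthogonal polyline realising one graph edge (or an anchor contact)."""

    source: str
    target: str
    vessel_type: str
    points: tuple[Point, ...]
    kind: str  # internal | external | hub | anchor

    @property
    def segments(self) -> list[tuple[Point, Point]]:
        return list(zip(self.points, self.points[1:]))

    @property
    def bends(self) -> tuple[Point, ...]:
        return self.points[1:-1]


@dataclass
class VascularLayout:
    """Node positions, hubs and routed edges of the vascular overlay."""

    node_positions: dict[str, Point] = field(default_factory=dict)
    hubs: list[Hub] = field(default_factory=list)
    edges: list[RoutedEdge] = field(default_factory=list)
    anchors: dict[str, Point] = field(default_factory=dict)
    node_tiles: dict[str, int] = field(default_factory=dict)
    report: "ValidationReport | None" = None


def _dedupe(points: Sequence[Point]) -> tuple[Point, ...]:
    out: list[Point] = []
    for p in points:
        if not out or abs(p[0] - out[-1][0]) > 1e-9 or abs(p[1] - out[-1][1]) > 1e-9:
            out.append(p)
    if len(out) == 1:
        out.append(out[0])
    return tuple(out)


def _poly_len(points: Sequence[Point]) -> float:
    return sum(
        abs(b[0] - a[0]) + abs(b[1] - a[1]) for a, b in zip(points, points[1:])
    )


def _point_at(points: Sequence[Point], arc: float) -> Point:
    remaining = max(0.0, arc)
    for a, b in zip(points, points[1:]):
        seg = abs(b[0] - a[0]) + abs(b[1] - a[1])
        if remaining <= seg + 1e-12:
            if seg == 0:
                return a
            t = remaining / seg
            return (a[0] + (b[0] - a[0]) * t, a[1] + (b[1] - a[1]) * t)
        remaining -= seg
    return points[-1]


def _slice_poly(points: Sequence[Point], s1: float, s2: float) -> tuple[Point, ...]:
    """Sub-polyline between arc lengths s1 and s2 (reversed when s1 > s2)."""
    if s1 > s2:
        return tuple(reversed(_slice_poly(points, s2, s1)))
    out: list[Point] = [_point_at(points, s1)]
    acc = 0.0
    for a, b in zip(points, points[1:]):
        seg = abs(b[0] - a[0]) + abs(b[1] - a[1])
        if acc + seg > s1 + 1e-12 and acc + seg < s2 - 1e-12:
            out.append(b)
        acc += seg
    out.append(_point_at(points, s2))
    return _dedupe(out)


def _join(back: Sequence[Point], fwd: Sequence[Point]) -> tuple[Point, ...]:
    """Concatenate two polyline pieces, inserting an orthogonal corner if
    their junction points do not coincide (robustness for inputs whose
    vascular networks share segments across chambers)."""
    pts = list(back)
    j1, j2 = back[-1], fwd[0]
    if abs(j1[0] - j2[0]) > 1e-9 and abs(j1[1] - j2[1]) > 1e-9:
        pts.append((j2[0], j1[1]))
    pts.extend(fwd)
    return _dedupe(pts)


def _common_prefix_arc(a: Sequence[Point], b: Sequence[Point]) -> float:
    """Arc length of the shared geometric prefix of two polylines."""
    if abs(a[0][0] - b[0][0]) > _EPS or abs(a[0][1] - b[0][1]) > _EPS:
        return 0.0
    arc = 0.0
    ia = ib = 0
    pa: Point = a[0]
    pb: Point = b[0]
    while ia < len(a) - 1 and ib < len(b) - 1:
        va = (a[ia + 1][0] - pa[0], a[ia + 1][1] - pa[1])
        vb = (b[ib + 1][0] - pb[0], b[ib + 1][1] - pb[1])
        la = abs(va[0]) + abs(va[1])
        lb = abs(vb[0]) + abs(vb[1])
        if la < 1e-12:
            ia += 1
            pa = a[ia]
            continue
        if lb < 1e-12:
            ib += 1
            pb = b[ib]
            continue
        da = (va[0] / la, va[1] / la)
        db = (vb[0] / lb, vb[1] / lb)
        if abs(da[0] - db[0]) > _EPS or abs(da[1] - db[1]) > _EPS:
            return arc
        step = min(la, lb)
        arc += step
        pa = (pa[0] + da[0] * step, pa[1] + da[1] * step)
        pb = (pb[0] + db[0] * step, pb[1] + db[1] * step)
        if step >= la - 1e-12:
            ia += 1
            pa = a[ia]
        if step >= lb - 1e-12:
            ib += 1
            pb = b[ib]
    return arc


# ---------------------------------------------------------------------------
# internal tile layout


def _edge_vessel(graph: VascularGraph, u: str, v: str) -> str:
    types = sorted(graph.g.edges[u, v]["types"])
    return types[0]


def _anchor_point(rect: Rect, treemap_rect: Rect, vessel_type: str) -> Point:
    if vessel_type == "arterial":
        return (rect.cx, treemap_rect.y)
    return (rect.cx, treemap_rect.y2)


def layout_tile_internal(
    tile_id: int,
    region: TileRegion,
    hubs: Sequence[Hub],
    graph: VascularGraph,
    treemap_layout: TreemapLayout,
    assignment: ClusterAssignment,
    lane_pitch: float = 3.0,
) -> VascularLayout:
    """Place this tile's hub subtrees inside its vascular channels.

    For each cluster targeting a microcirculation of this tile, the leaf is
    positioned directly above (arterial) or below (venous) its contact
    anchor, the hub at the channel's entry side (left for arterial, right
    for venous), and the nodes along each leaf-to-hub path with evenly
    spaced horizontal offsets on the cluster's lane.  Nodes already laid out
    by an earlier path keep their position (first writer wins).  Every
    segment stays inside the channel; the single anchor segment descends to
    the treemap boundary.
    """
    out = VascularLayout()
    hub_by_cluster = {h.cluster_id: h for h in hubs if h.tile_id == tile_id}

    # clusters whose target microcirculation is drawn in this tile's treemap
    clusters = sorted(
        m for m in graph.target_vessel if m in treemap_layout.rects
    )
    lane_counter = {"arterial": 0, "venous": 0}
    for micro in clusters:
        vessel = graph.target_vessel[micro]
        channel = (
            region.top_channel_rect if vessel == "arterial" else region.bottom_channel_rect
        )
        pad = min(2.0, channel.h / 4) if channel.h > 0 else 0.0
        n_lanes = max(1, int((channel.h - pad) // lane_pitch)) if channel.h > 0 else 1
        k = lane_counter[vessel] % n_lanes
        lane_counter[vessel] += 1
        if vessel == "arterial":
            lane_y = channel.y2 - pad - k * lane_pitch
        else:
            lane_y = channel.y + pad + k * lane_pitch

        micro_rect = treemap_layout.rects[micro]
        anchor = _anchor_point(micro_rect, region.treemap_rect, vessel)
        out.anchors[micro] = anchor

        # the leaf of this cluster: the path segment adjacent to the target
        leaves = sorted(
            n for n, t in graph.leaf_targets.items() if t == micro
        )
        hub = hub_by_cluster.get(micro)
        for leaf in leaves:
            if leaf not in out.node_positions:
                out.node_positions[leaf] = (anchor[0], lane_y)
                out.node_tiles[leaf] = tile_id
            # chain from hub down to leaf through same-cluster in-tile nodes
            if hub is not None and hub.node_id != leaf:
                try:
                    chain = nx.shortest_path(graph.g, hub.node_id, leaf)
                except nx.NetworkXNoPath:
                    chain = [leaf]
                if hub.position is None:
                    hx = (
                        region.tile_rect.x + 3.0
                        if vessel == "arterial"
                        else region.tile_rect.x2 - 3.0
                    )
                    hub.position = (hx, lane_y)
                    out.node_positions[hub.node_id] = hub.position
                    out.node_tiles[hub.node_id] = tile_id
                start = out.node_positions[hub.node_id]
                end = out.node_positions[leaf]
                inner = chain[1:-1]
                for i, nid in enumerate(inner, start=1):
                    if nid not in out.node_positions:
                        t = i / (len(inner) + 1)
                        out.node_positions[nid] = (
                            start[0] + (end[0] - start[0]) * t,
                            lane_y,
                        )
                        out.node_tiles[nid] = tile_id
            elif hub is not None:  # hub == leaf
                hub.position = out.node_positions[leaf]

            # anchor contact: a single vertical descent to the boundary
            lp = out.node_positions[leaf]
            out.edges.append(
                RoutedEdge(
                    leaf,
                    micro,
                    vessel,
                    _dedupe([lp, (anchor[0], lp[1]), anchor]),
                    "anchor",
                )
            )

    # route in-tile edges between positioned nodes of this tile
    placed = set(out.node_positions)
    for u in sorted(placed):
        for v in graph.children(u):
            if v not in placed:
                continue
            pu, pv = out.node_positions[u], out.node_positions[v]
            vessel = _edge_vessel(graph, u, v)
            mid = (pv[0], pu[1])
            out.edges.append(
                RoutedEdge(u, v, vessel, _dedupe([pu, mid, pv]), "internal")
            )
    out.hubs = [h for h in hubs if h.tile_id == tile_id and h.position is not None]
    return out


# ---------------------------------------------------------------------------
# heart distance and external layout


def order_tiles_by_heart_distance(
    plan: BodyPlan, graph: VascularGraph
) -> list[int]:
    """Tile ids sorted by vascular distance from the heart chambers.

    Distance is the minimum number of vascular segments from any chamber to
    any node of the tile; the heart tile always comes first; tiles the
    vascular graph never touches follow all reachable tiles, ordered by
    Manhattan grid distance from the heart tile; ties break by tile id.
    """
    dist: dict[str, int] = {}
    for root in graph.roots:
        for nid, d in nx.single_source_shortest_path_length(graph.g, root).items():
            if nid not in dist or d < dist[nid]:
                dist[nid] = d
    tile_dist: dict[int, int] = {}
    for nid, d in dist.items():
        tile = graph.tile_of(nid)
        if tile is not None and (tile not in tile_dist or d < tile_dist[tile]):
            tile_dist[tile] = d
    heart = plan.heart_tile
    keys = []
    for t in plan.tiles:
        if t.tile_id == heart.tile_id:
            keys.append((0, 0, t.tile_id))
        elif t.tile_id in tile_dist:
            keys.append((1, tile_dist[t.tile_id], t.tile_id))
        else:
            manhattan = abs(t.grid_row - heart.grid_row) + abs(t.grid_col - heart.grid_col)
            keys.append((2, manhattan, t.tile_id))
    return [k[2] for k in sorted(keys)]


def _chamber_anchor(plan: BodyPlan, regions: Mapping[int, TileRegion], chamber: str) -> Point:
    heart = regions[plan.heart_tile.tile_id].tile_rect
    arterial = chamber in ("LV", "RV")
    idx = ("LV", "RV").index(chamber) if arterial else ("LA", "RA").index(chamber)
    x = heart.x + heart.w * (idx + 1) / 3
    return (x, heart.y) if arterial else (x, heart.y2)


class _SpineSet:
    """Per-(chamber, tile) corridor spines and the gutter geometry behind them."""

    def __init__(
        self,
        plan: BodyPlan,
        regions: Mapping[int, TileRegion],
        lane_pitch: float,
    ):
        self.plan = plan
        self.regions = regions
        self.pitch = lane_pitch
        self.g = plan.gutter * plan.scale
        self._cache: dict[tuple[str, int], tuple[Point, ...]] = {}

    def chamber_lane_offset(self, chamber: str) -> float:
        idx = ("LV", "RV", "LA", "RA").index(chamber)
        return (idx % 2 - 0.5) * self.pitch

    def spine(self, chamber: str, tile_id: int) -> tuple[Point, ...]:
        key = (chamber, tile_id)
        if key in self._cache:
            return self._cache[key]
        plan, g = self.plan, self.g
        arterial = chamber in ("LV", "RV")
        heart_rect = self.regions[plan.heart_tile.tile_id].tile_rect
        target = self.regions[tile_id].tile_rect
        off = self.chamber_lane_offset(chamber)
        p0 = _chamber_anchor(plan, self.regions, chamber)
        if arterial:
            y_exit = heart_rect.y - g / 2 + off
            x_lane = target.x - g / 4 + off / 2
            y_appr = target.y - g / 2 + off
        else:
            y_exit = heart_rect.y2 + g / 2 + off
            x_lane = target.x2 + g / 4 + off / 2
            y_appr = target.y2 + g / 2 + off
        pts = [p0, (p0[0], y_exit), (x_lane, y_exit), (x_lane, y_appr)]
        self._cache[key] = _dedupe(pts)
        return self._cache[key]

    def entry(self, chamber: str, tile_id: int, y_target: float) -> list[Point]:
        """Continuation from the spine end into the tile channel at ``y_target``."""
        spine = self.spine(chamber, tile_id)
        x_lane, _ = spine[-1]
        return [spine[-1], (x_lane, y_target)]


def layout_external(
    plan: BodyPlan,
    regions: Mapping[int, TileRegion],
    graph: VascularGraph,
    assignment: ClusterAssignment,
    internal: VascularLayout,
    tile_order: Sequence[int],
    micro_tiles: Mapping[str, int],
    lane_pitch: float = 3.0,
    node_step: float = 12.0,
) -> VascularLayout:
    """Place chambers and all not-yet-laid-out nodes along corridor spines.

    Every remaining node is routed toward the lowest-ordered tile among its
    clusters' target tiles, at an arc proportional to its distance from the
    chamber, so shared trunk nodes sit on the common spine prefix and their
    child edges are covered by the continuation toward the next tile.
    Returns a layout holding the new positions plus the routed edges between
    externally placed nodes.
    """
    out = VascularLayout()
    out.node_positions.update(internal.node_positions)
    spines = _SpineSet(plan, regions, lane_pitch)
    order_rank = {tid: i for i, tid in enumerate(tile_order)}

    # chamber of each node: the lexicographically first chamber reaching it
    chamber_of: dict[str, str] = {}
    for root in graph.roots:
        for nid in nx.descendants(graph.g, root) | {root}:
            if nid not in chamber_of or root < chamber_of[nid]:
                chamber_of[nid] = root
    depth: dict[str, int] = {}
    for root in graph.roots:
        for nid, d in nx.single_source_shortest_path_length(graph.g, root).items():
            if nid not in depth or d < depth[nid]:
                depth[nid] = d

    def steer_tile(nid: str) -> int:
        tiles = sorted(
            (order_rank.get(micro_tiles[m], len(order_rank)), micro_tiles[m])
            for m in assignment[nid]
            if m in micro_tiles
        )
        if not tiles:
            return plan.heart_tile.tile_id
        return tiles[0][1]

    traces: dict[str, tuple[Point, ...]] = {}
    steer: dict[str, int] = {}
    for chamber in graph.roots:
        pos = _chamber_anchor(plan, regions, chamber)
        out.node_positions[chamber] = pos
        traces[chamber] = (pos, pos)
        steer[chamber] = steer_tile(chamber)

    pending = [
        n
        for n in nx.topological_sort(graph.g)
        if n not in out.node_positions
    ]
    for nid in pending:
        chamber = chamber_of.get(nid)
        if chamber is None:
            # unreachable from any chamber; park at origin of first spine
            out.node_positions[nid] = (0.0, 0.0)
            continue
        t = steer_tile(nid)
        steer[nid] = t
        spine = spines.spine(chamber, t)
        end_margin = min(4.0, _poly_len(spine) / 4)
        arc = min(depth.get(nid, 1) * node_step, _poly_len(spine) - end_margin)
        out.node_positions[nid] = _point_at(spine, arc)
        traces[nid] = spine

    # route edges whose child is externally placed
    for u, v in sorted(graph.g.edges):
        if v in internal.node_positions or v not in traces:
            continue
        vessel = _edge_vessel(graph, u, v)
        pu = out.node_positions[u]
        pv = out.node_positions[v]
        spine_v = traces[v]
        arc_v = _arc_of(spine_v, pv)
        if u in traces:
            spine_u = traces[u]
            arc_u = _arc_of(spine_u, pu)
            shared = _common_prefix_arc(spine_u, spine_v)
            if arc_u <= shared + _EPS:
                pts = _slice_poly(spine_v, arc_u, arc_v)
            else:
                back = _slice_poly(spine_u, arc_u, shared)
                fwd = _slice_poly(spine_v, shared, arc_v)
                pts = _join(back, fwd)
        else:
            pts = _dedupe([pu, (pv[0], pu[1]), pv])
        out.edges.append(RoutedEdge(u, v, vessel, pts, "external"))

    out.node_tiles.update(internal.node_tiles)
    out._spines = spines  # type: ignore[attr-defined]  # reused by hub routing
    out._traces = traces  # type: ignore[attr-defined]
    out._chamber_of = chamber_of  # type: ignore[attr-defined]
    return out


def _arc_of(poly: Sequence[Point], p: Point) -> float:
    """Arc length of the first point of ``poly`` coinciding with ``p``."""
    acc = 0.0
    best = None
    for a, b in zip(poly, poly[1:]):
        seg = abs(b[0] - a[0]) + abs(b[1] - a[1])
        if seg > 0:
            # projection onto an axis-parallel segment
            if abs(b[0] - a[0]) > abs(b[1] - a[1]):
                if abs(p[1] - a[1]) < 1e-6 and min(a[0], b[0]) - 1e-6 <= p[0] <= max(a[0], b[0]) + 1e-6:
                    cand = acc + abs(p[0] - a[0])
                    if best is None:
                        best = cand
            else:
                if abs(p[0] - a[0]) < 1e-6 and min(a[1], b[1]) - 1e-6 <= p[1] <= max(a[1], b[1]) + 1e-6:
                    cand = acc + abs(p[1] - a[1])
                    if best is None:
                        best = cand
        acc += seg
    return best if best is not None else acc


def route_hub_edges(
    plan: BodyPlan,
    regions: Mapping[int, TileRegion],
    graph: VascularGraph,
    external: VascularLayout,
    internal_tiles: Mapping[str, int],
) -> list[RoutedEdge]:
    """Create the edge from each externally placed parent into its in-tile child.

    The route follows the parent's corridor spine to the child's tile, drops
    through the tile's side lane (left for arterial, right for venous) and
    enters the vascular channel at the child's lane height.  A child without
    a position is a routing error naming the node.
    """
    spines: _SpineSet = external._spines  # type: ignore[attr-defined]
    traces: Mapping[str, tuple[Point, ...]] = external._traces  # type: ignore[attr-defined]
    chamber_of: Mapping[str, str] = external._chamber_of  # type: ignore[attr-defined]
    edges: list[RoutedEdge] = []
    for u, v in sorted(graph.g.edges):
        if v not in internal_tiles:
            continue
        if v not in external.node_positions:
            raise RoutingError(f"hub {v} has no layout position")
        vessel = _edge_vessel(graph, u, v)
        pv = external.node_positions[v]
        pu = external.node_positions.get(u)
        if pu is None:
            raise RoutingError(f"parent {u} of hub {v} has no layout position")
        if u in internal_tiles:
            # both endpoints inside tiles: channel-local orthogonal hop
            pts = _dedupe([pu, (pv[0], pu[1]), pv])
            edges.append(RoutedEdge(u, v, vessel, pts, "hub"))
            continue
        tile_id = internal_tiles[v]
        chamber = chamber_of.get(u, graph.roots[0] if graph.roots else "LV")
        spine_v = spines.spine(chamber, tile_id)
        arc_end = _poly_len(spine_v)
        if u in traces:
            spine_u = traces[u]
            arc_u = _arc_of(spine_u, pu)
            shared = _common_prefix_arc(spine_u, spine_v)
            if arc_u <= shared + _EPS:
                approach = list(_slice_poly(spine_v, arc_u, arc_end))
            else:
                back = _slice_poly(spine_u, arc_u, shared)
                fwd = _slice_poly(spine_v, shared, arc_end)
                approach = list(_join(back, fwd))
        else:
            approach = [pu, spine_v[-1]]
        x_lane = spine_v[-1][0]
        pts = _dedupe(approach + [(x_lane, pv[1]), pv])
        edges.append(RoutedEdge(u, v, vessel, pts, "hub"))
    return edges


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    """Pass/fail summary of the checkable layout goals."""

    n_segments: int = 0
    n_diagonal: int = 0
    n_channel_violations: int = 0
    n_treemap_crossings: int = 0
    n_side_violations: int = 0
    n_paths: int = 0
    n_paths_connected: int = 0
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return (
            self.n_diagonal == 0
            and self.n_channel_violations == 0
            and self.n_treemap_crossings == 0
            and self.n_side_violations == 0
            and self.n_paths_connected == self.n_paths
        )

    def counts(self) -> dict[str, int]:
        return {
            "segments": self.n_segments,
            "diagonal": self.n_diagonal,
            "channel_violations": self.n_channel_violations,
            "treemap_crossings": self.n_treemap_crossings,
            "side_violations": self.n_side_violations,
            "paths": self.n_paths,
            "paths_connected": self.n_paths_connected,
        }


def _seg_in_rect(a: Point, b: Point, r: Rect, tol: float = _EPS) -> bool:
    return (
        r.x - tol <= min(a[0], b[0])
        and max(a[0], b[0]) <= r.x2 + tol
        and r.y - tol <= min(a[1], b[1])
        and max(a[1], b[1]) <= r.y2 + tol
    )


def _seg_crosses_interior(a: Point, b: Point, r: Rect, tol: float = _EPS) -> bool:
    """True when an axis-parallel segment enters the open interior of r."""
    x1, x2 = sorted((a[0], b[0]))
    y1, y2 = sorted((a[1], b[1]))
    # overlap of the segment with the open rectangle
    ox1, ox2 = max(x1, r.x), min(x2, r.x2)
    oy1, oy2 = max(y1, r.y), min(y2, r.y2)
    if ox1 > ox2 + tol or oy1 > oy2 + tol:
        return False
    if abs(a[1] - b[1]) <= tol:  # horizontal
        return r.y + tol < a[1] < r.y2 - tol and ox2 - ox1 > tol
    if abs(a[0] - b[0]) <= tol:  # vertical
        return r.x + tol < a[0] < r.x2 - tol and oy2 - oy1 > tol
    return True  # diagonal overlapping the box: count as crossing


def validate_vascular_layout(
    layout: VascularLayout,
    treemap_layouts: Mapping[int, TreemapLayout],
    regions: Mapping[int, TileRegion],
    retained: Sequence[VascularPath],
    forest: AnatomyForest,
    plan: BodyPlan,
) -> ValidationReport:
    """Check orthogonality, channel containment, treemap clarity and completeness.

    * every segment must be axis-parallel;
    * any segment entering a tile must stay inside that tile's top channel
      (arterial) or bottom channel (venous);
    * no segment may cross the open interior of a treemap leaf rectangle
      (contact anchors sit on the treemap boundary);
    * vertical gutter runs must respect the side convention: arterial on the
      left flank of a tile column, venous on the right;
    * every retained path must be rendered as a connected chamber-to-anchor
      chain of routed segments.
    """
    rep = ValidationReport()
    g = plan.gutter * plan.scale

    # leaf rectangles per tile for the clarity check
    leaf_rects: dict[int, list[Rect]] = {}
    for tile_id, tl in treemap_layouts.items():
        tile = plan.tile_by_id(tile_id)
        leaves = [
            tl.rects[nid]
            for nid in tl.rects
            if nid in forest.nodes
            and not forest.nodes[nid].children
        ]
        leaf_rects[tile_id] = leaves

    col_edges = sorted({(regions[t.tile_id].tile_rect.x, regions[t.tile_id].tile_rect.x2) for t in plan.tiles})

    for edge in layout.edges:
        for a, b in edge.segments:
            rep.n_segments += 1
            horiz = abs(a[1] - b[1]) <= _EPS
            vert = abs(a[0] - b[0]) <= _EPS
            if not (horiz or vert):
                rep.n_diagonal += 1
                rep.violations.append(("diagonal", f"{edge.source}->{edge.target} {a}->{b}"))
                continue
            for tile_id, region in regions.items():
                tr = region.tile_rect
                if not _seg_crosses_interior(a, b, tr):
                    continue
                channel = (
                    region.top_channel_rect
                    if edge.vessel_type == "arterial"
                    else region.bottom_channel_rect
                )
                # the in-tile portion of the segment must fit the channel
                ix1, ix2 = max(min(a[0], b[0]), tr.x), min(max(a[0], b[0]), tr.x2)
                iy1, iy2 = max(min(a[1], b[1]), tr.y), min(max(a[1], b[1]), tr.y2)
                if not _seg_in_rect((ix1, iy1), (ix2, iy2), channel):
                    rep.n_channel_violations += 1
                    rep.violations.append(
                        ("channel", f"{edge.source}->{edge.target} in tile {tile_id}")
                    )
                # clarity: may not cross any treemap leaf interior
                if _seg_crosses_interior(a, b, region.treemap_rect):
                    for lr in leaf_rects.get(tile_id, ()):
                        if _seg_crosses_interior(a, b, lr):
                            rep.n_treemap_crossings += 1
                            rep.violations.append(
                                ("treemap_crossing", f"{edge.source}->{edge.target} in tile {tile_id}")
                            )
                            break
            # side convention for vertical runs in the gutters between columns
            if vert and not any(
                _seg_crosses_interior(a, b, regions[t.tile_id].tile_rect)
                for t in plan.tiles
            ):
                x = a[0]
                in_left_flank = any(x0 - g / 2 - _EPS <= x < x0 - _EPS for x0, _ in col_edges)
                in_right_flank = any(x1 + _EPS < x <= x1 + g / 2 + _EPS for _, x1 in col_edges)
                if edge.vessel_type == "arterial" and in_right_flank and not in_left_flank:
                    rep.n_side_violations += 1
                    rep.violations.append(("side", f"arterial at x={x:.2f}"))
                if edge.vessel_type == "venous" and in_left_flank and not in_right_flank:
                    rep.n_side_violations += 1
                    rep.violations.append(("side", f"venous at x={x:.2f}"))

    # completeness: each retained path is a connected chamber->anchor chain
    edge_index: dict[tuple[str, str], RoutedEdge] = {}
    for e in layout.edges:
        edge_index.setdefault((e.source, e.target), e)
    rep.n_paths = len(retained)
    for p in retained:
        chain = [p.chamber_id, *p.segments]
        ok = True
        for u, v in zip(chain, chain[1:]):
            e = edge_index.get((u, v))
            if e is None:
                ok = False
                break
            pu = layout.node_positions.get(u)
            pv = layout.node_positions.get(v)
            if pu is None or pv is None:
                ok = False
                break
            if (
                abs(e.points[0][0] - pu[0]) > 1e-3
                or abs(e.points[0][1] - pu[1]) > 1e-3
                or abs(e.points[-1][0] - pv[0]) > 1e-3
                or abs(e.points[-1][1] - pv[1]) > 1e-3
            ):
                ok = False
                break
        anchor_edge = edge_index.get((p.segments[-1], p.target_microcirculation))
        if anchor_edge is None or p.target_microcirculation not in layout.anchors:
            ok = False
        if ok:
            rep.n_paths_connected += 1
        else:
            rep.violations.append(("completeness", p.path_id))
    return rep


# ---------------------------------------------------------------------------
# orchestration


def layout_vascular(
    plan: BodyPlan,
    regions: Mapping[int, TileRegion],
    forest: AnatomyForest,
    treemap_layouts: Mapping[int, TreemapLayout],
    retained: Sequence[VascularPath],
    lane_pitch: float = 3.0,
) -> VascularLayout:
    """Run the four vascular layout steps and validate the result."""
    tiles = tile_node_sets(forest, plan)
    graph = build_vascular_graph(retained, forest, tiles)
    assignment = propagate_cluster_ids(graph)
    hubs = identify_hubs(graph, assignment)

    micro_tiles: dict[str, int] = {}
    for m in graph.target_vessel:
        if m in forest.nodes:
            tile = plan.tile_by_root(forest.tile_of(m))
            if tile is not None:
                micro_tiles[m] = tile.tile_id

    combined = VascularLayout(hubs=hubs)
    for tile_id in sorted(treemap_layouts):
        part = layout_tile_internal(
            tile_id,
            regions[tile_id],
            hubs,
            graph,
            treemap_layouts[tile_id],
            assignment,
            lane_pitch,
        )
        combined.node_positions.update(part.node_positions)
        combined.node_tiles.update(part.node_tiles)
        combined.anchors.update(part.anchors)
        combined.edges.extend(part.edges)

    tile_order = order_tiles_by_heart_distance(plan, graph)
    external = layout_external(
        plan,
        regions,
        graph,
        assignment,
        combined,
        tile_order,
        micro_tiles,
        lane_pitch,
    )
    combined.node_positions = external.node_positions
    combined.edges.extend(external.edges)
    combined.edges.extend(
        route_hub_edges(plan, regions, graph, external, combined.node_tiles)
    )
    rep = validate_vascular_layout(
        combined, treemap_layouts, regions, retained, forest, plan
    )
    combined.report = rep
    return combined
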