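"""Reading, validating, filtering and writing anatomy hierarchies and vascular paths.

The anatomical input is a tab-separated table of ``parent_id  child_id  relation``
triples derived from an FMA-style ontology export, where *relation* is one of the
four hierarchical principles (constitutional part, regional part, direct subclass,
direct instance-of).  Vascular paths live in a separate semicolon-separated file,
one path per line: ``path_id;chamber;seg1,seg2,...;target;vessel_type``.

Because an ontology export mixes several hierarchical principles, a child may be
recorded under more than one parent; :func:`build_anatomy_forest` resolves this
with a fixed relation-kind precedence so the result is a true forest.
"""

from __future__ import annotations

import enum
import io as _io
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Sequence

from .errors import CycleError, ParseError, VasculomapError

__all__ = [
    "RelationKind",
    "HierarchyRecord",
    "ForestNode",
    "AnatomyForest",
    "VascularPath",
    "VESSEL_TYPES",
    "parse_hierarchy_table",
    "write_hierarchy_table",
    "build_anatomy_forest",
    "apply_depth_filter",
    "restrict_microcirculations",
    "parse_vascular_paths",
    "write_vascular_paths",
    "filter_complete_paths",
    "write_exclusion_report",
]

_FMA_ID = re.compile(r"^FMA\d+$")

VESSEL_TYPES = ("arterial", "venous")


class RelationKind(enum.Enum):
    """The four hierarchical principles of the anatomy ontology.

    Listed in precedence order: when a child appears under several parents,
    the edge with the highest-precedence relation wins.
    """

    CONSTITUTIONAL_PART = "constitutional_part"
    REGIONAL_PART = "regional_part"
    SUBCLASS = "subclass"
    INSTANCE_OF = "instance_of"

    @classmethod
    def from_token(cls, token: str) -> "RelationKind":
        try:
            return cls(token)
        except ValueError:
            raise ValueError(f"unknown relation token {token!r}") from None

    @property
    def precedence(self) -> int:
        """Smaller is stronger; constitutional part binds tightest."""
        return _PRECEDENCE[self]


_PRECEDENCE = {
    RelationKind.CONSTITUTIONAL_PART: 0,
    RelationKind.REGIONAL_PART: 1,
    RelationKind.SUBCLASS: 2,
    RelationKind.INSTANCE_OF: 3,
}


def _check_fma_id(value: str, what: str) -> str:
    if not _FMA_ID.match(value):
        raise ValueError(f"{what} {value!r} is not a valid FMA identifier")
    return value


@dataclass(frozen=True)
class HierarchyRecord:
    """One parent/child/relation triple of the hierarchy table."""

    parent_id: str
    child_id: str
    relation: RelationKind

    def __post_init__(self) -> None:
        _check_fma_id(self.parent_id, "parent_id")
        _check_fma_id(self.child_id, "child_id")
        if self.parent_id == self.child_id:
            raise ValueError(f"self-loop on {self.parent_id}")
        if not isinstance(self.relation, RelationKind):
            raise TypeError("relation must be a RelationKind")


@dataclass
class ForestNode:
    """A node of the anatomy forest."""

    id: str
    label: str
    depth: int
    parent: str | None
    tile_root: str
    is_microcirculation: bool = False
    children: list[str] = field(default_factory=list)


class AnatomyForest:
    """A forest of tile-rooted anatomy trees with depths and vascular flags.

    Nodes are keyed by FMA id; each node belongs to exactly one tree and
    carries its depth below that tree's tile root (root depth 0).  Nodes
    flagged as microcirculations are the contact points the vascular layout
    may attach to.
    """

    def __init__(self, nodes: dict[str, ForestNode], roots: Sequence[str]):
        self.nodes = nodes
        self.roots = list(roots)
        # diagnostics populated by build_anatomy_forest
        self.dropped_unreachable: list[str] = []
        self.multiparent_resolutions: list[tuple[str, str, str]] = []

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def children_of(self, node_id: str) -> list[str]:
        return self.nodes[node_id].children

    def tile_of(self, node_id: str) -> str:
        return self.nodes[node_id].tile_root

    def leaves(self) -> list[str]:
        return [n.id for n in self.nodes.values() if not n.children]

    def microcirculation_ids(self) -> list[str]:
        return sorted(n.id for n in self.nodes.values() if n.is_microcirculation)

    def tree_nodes(self, root: str) -> list[str]:
        """All node ids of the tree rooted at ``root`` (preorder)."""
        out: list[str] = []
        stack = [root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def max_depth(self) -> int:
        return max((n.depth for n in self.nodes.values()), default=0)

    def copy(self) -> "AnatomyForest":
        nodes = {
            nid: replace(node, children=list(node.children))
            for nid, node in self.nodes.items()
        }
        out = AnatomyForest(nodes, self.roots)
        out.dropped_unreachable = list(self.dropped_unreachable)
        out.multiparent_resolutions = list(self.multiparent_resolutions)
        return out


@dataclass(frozen=True)
class VascularPath:
    """A blood-vessel path from a heart chamber to a microcirculation.

    ``segments`` is the ordered sequence of vascular segment identifiers the
    path traverses; the last segment is anatomically adjacent to the target
    microcirculation.  The vessel type is carried explicitly because venous
    hierarchies are not derivable from a single ontology principle.
    """

    path_id: str
    chamber_id: str
    segments: tuple[str, ...]
    target_microcirculation: str
    vessel_type: str

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"path {self.path_id}: empty segment list")
        if self.vessel_type not in VESSEL_TYPES:
            raise ValueError(
                f"path {self.path_id}: unknown vessel type {self.vessel_type!r}"
            )


def _as_lines(source: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        return iter(_io.StringIO(source))
    return iter(source)


def parse_hierarchy_table(source: str | IO[str] | Iterable[str]) -> list[HierarchyRecord]:
    """Parse a tab-separated hierarchy table into records, order preserved.

    Empty lines and lines starting with ``#`` are skipped.  Any malformed
    line (wrong field count, bad FMA id, unknown relation token, self-loop)
    raises :class:`ParseError` naming the 1-based line number.
    """
    records: list[HierarchyRecord] = []
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ParseError(
                f"expected 3 tab-separated fields, got {len(fields)}", lineno
            )
        parent, child, token = (f.strip() for f in fields)
        try:
            relation = RelationKind.from_token(token)
            records.append(HierarchyRecord(parent, child, relation))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return records


def write_hierarchy_table(records: Iterable[HierarchyRecord], handle: IO[str]) -> None:
    """Write records as the tab-separated dialect read by :func:`parse_hierarchy_table`."""
    for rec in records:
        handle.write(f"{rec.parent_id}\t{rec.child_id}\t{rec.relation.value}\n")


def build_anatomy_forest(
    records: Iterable[HierarchyRecord],
    tile_roots: Iterable[str],
    microcirculation_ids: Iterable[str] = (),
) -> AnatomyForest:
    """Assemble tile-rooted trees from parent/child records.

    A child recorded under several parents keeps only the edge whose relation
    has the highest precedence (constitutional part > regional part >
    subclass > instance-of; ties broken by first occurrence); the losing
    edges are dropped with a warning.  Nodes unreachable from every tile root
    are dropped and reported on ``forest.dropped_unreachable``.  A directed
    cycle reachable from a tile root raises :class:`CycleError` listing the
    cycle.
    """
    roots = sorted(set(tile_roots))
    if not roots:
        raise VasculomapError("tile_roots must be non-empty")
    micro = set(microcirculation_ids)

    # choose at most one parent edge per child by relation precedence
    best: dict[str, HierarchyRecord] = {}
    resolutions: list[tuple[str, str, str]] = []
    all_ids: set[str] = set()
    for rec in records:
        all_ids.add(rec.parent_id)
        all_ids.add(rec.child_id)
        cur = best.get(rec.child_id)
        if cur is None:
            best[rec.child_id] = rec
        elif rec.relation.precedence < cur.relation.precedence:
            resolutions.append((rec.child_id, cur.parent_id, rec.parent_id))
            best[rec.child_id] = rec
        else:
            resolutions.append((rec.child_id, rec.parent_id, cur.parent_id))

    for child, loser, winner in resolutions:
        warnings.warn(
            f"node {child} has multiple parents; kept edge from {winner}, "
            f"dropped edge from {loser}",
            stacklevel=2,
        )

    children: dict[str, list[str]] = {}
    for rec in best.values():
        children.setdefault(rec.parent_id, []).append(rec.child_id)
    for kids in children.values():
        kids.sort()

    # roots are registered up front so no tree can adopt another tile's root
    nodes: dict[str, ForestNode] = {
        root: ForestNode(root, root, 0, None, root) for root in roots
    }
    for root in roots:
        # iterative DFS with on-path cycle detection
        stack: list[tuple[str, Iterator[str]]] = [(root, iter(children.get(root, ())))]
        on_path = {root}
        while stack:
            nid, it = stack[-1]
            child = next(it, None)
            if child is None:
                stack.pop()
                on_path.discard(nid)
                continue
            if child in on_path:
                cyc = [s for s, _ in stack]
                cyc = cyc[cyc.index(child):] + [child]
                raise CycleError(cyc)
            if child in nodes:
                # already claimed (single parent per child makes this rare:
                # only possible via shared subtree under two roots); keep first
                continue
            node = ForestNode(child, child, nodes[nid].depth + 1, nid, root)
            nodes[child] = node
            nodes[nid].children.append(child)
            stack.append((child, iter(children.get(child, ()))))
            on_path.add(child)

    forest = AnatomyForest(nodes, roots)
    forest.dropped_unreachable = sorted(all_ids - set(nodes))
    forest.multiparent_resolutions = resolutions
    for nid in micro & set(nodes):
        nodes[nid].is_microcirculation = True
    return forest


def apply_depth_filter(forest: AnatomyForest, max_distance: int) -> AnatomyForest:
    """Keep only nodes within ``max_distance`` of their tile root (1..16).

    Microcirculation flags are preserved on surviving nodes.  Idempotent and
    monotone in ``max_distance``.
    """
    if not isinstance(max_distance, int) or not 1 <= max_distance <= 16:
        raise ValueError(f"max_distance must be in [1, 16], got {max_distance!r}")
    nodes: dict[str, ForestNode] = {}
    for nid, node in forest.nodes.items():
        if node.depth <= max_distance:
            nodes[nid] = replace(
                node,
                children=[c for c in node.children if forest.nodes[c].depth <= max_distance],
            )
    return AnatomyForest(nodes, forest.roots)


def restrict_microcirculations(
    forest: AnatomyForest, selection: Iterable[str] | None = None
) -> AnatomyForest:
    """Limit the vascular contact points to a predefined set.

    With ``selection`` absent the forest keeps all its microcirculation flags,
    treating every flagged node as a potential connection point.  Otherwise
    only flags on ids in the selection survive; selected ids missing from the
    forest are warned about and ignored.
    """
    if selection is None:
        return forest.copy()
    wanted = set(selection)
    missing = sorted(wanted - set(forest.nodes))
    for nid in missing:
        warnings.warn(f"selected microcirculation {nid} not in forest; ignored", stacklevel=2)
    out = forest.copy()
    for nid, node in out.nodes.items():
        node.is_microcirculation = node.is_microcirculation and nid in wanted
    return out


def parse_vascular_paths(source: str | IO[str] | Iterable[str]) -> list[VascularPath]:
    """Parse the semicolon/comma vascular-path dialect, one path per line.

    ``path_id;chamber;seg1,seg2,...;target;vessel_type``.  Path ids must be
    unique; an empty segment list, a bad segment id or an unknown vessel-type
    token is a :class:`ParseError`.
    """
    paths: list[VascularPath] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split(";")
        if len(fields) != 5:
            raise ParseError(
                f"expected 5 semicolon-separated fields, got {len(fields)}", lineno
            )
        path_id, chamber, seg_field, target, vtype = (f.strip() for f in fields)
        if not path_id:
            raise ParseError("empty path id", lineno)
        if path_id in seen:
            raise ParseError(f"duplicate path id {path_id!r}", lineno)
        seen.add(path_id)
        segments = tuple(s.strip() for s in seg_field.split(",") if s.strip())
        if not segments:
            raise ParseError(f"path {path_id!r}: empty segment list", lineno)
        try:
            for seg in segments:
                _check_fma_id(seg, "segment")
            _check_fma_id(target, "target")
            paths.append(VascularPath(path_id, chamber, segments, target, vtype))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return paths


def write_vascular_paths(paths: Iterable[VascularPath], handle: IO[str]) -> None:
    """Write paths in the dialect read by :func:`parse_vascular_paths`."""
    for p in paths:
        handle.write(
            f"{p.path_id};{p.chamber_id};{','.join(p.segments)};"
            f"{p.target_microcirculation};{p.vessel_type}\n"
        )


def filter_complete_paths(
    paths: Iterable[VascularPath],
    forest: AnatomyForest,
    chambers: Iterable[str],
) -> tuple[list[VascularPath], list[tuple[VascularPath, str]]]:
    """Partition paths into those with both endpoints in the layout and the rest.

    A path is retained when its chamber is one of the configured chambers and
    its target microcirculation is a flagged node of the forest.  Every input
    path ends up in exactly one of the two outputs; excluded paths carry a
    machine-readable reason (``unknown_chamber`` or ``missing_target``).
    """
    chamber_set = set(chambers)
    retained: list[VascularPath] = []
    excluded: list[tuple[VascularPath, str]] = []
    for p in paths:
        if p.chamber_id not in chamber_set:
            excluded.append((p, "unknown_chamber"))
        elif (
            p.target_microcirculation not in forest
            or not forest.nodes[p.target_microcirculation].is_microcirculation
        ):
            excluded.append((p, "missing_target"))
        else:
            retained.append(p)
    return retained, excluded


def write_exclusion_report(
    excluded: Iterable[tuple[VascularPath, str]], handle: IO[str]
) -> None:
    """Write the exclusion report as TSV ``path_id<TAB>reason``."""
    handle.write("path_id\treason\n")
    for path, reason in excluded:
        handle.write(f"{path.path_id}\t{reason}\n")
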