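"""Seeded generators for FMA-like hierarchies and vascular path sets.

Real anatomy exports are licence-encumbered, so every pipeline stage is
exercised on synthetic forests that reproduce the *shape* of the data: a
forest of 24 tile-rooted trees of bounded depth connected by the four
hierarchical principles, a subset of leaves flagged as microcirculations, and
vascular paths that start in one of the four heart chambers, run through a
shared external trunk, branch towards a tile and end adjacent to a target
microcirculation.  A controllable fraction of paths points at a
microcirculation absent from the forest, emulating the endpoint gaps found in
real ontology extracts.

All randomness flows from a single integer seed (default 1405); identical
configurations yield identical outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .bodyplan import ARTERIAL_CHAMBERS, CHAMBER_IDS, VENOUS_CHAMBERS
from .errors import ConfigError, GenerationError
from .io import AnatomyForest, HierarchyRecord, RelationKind, VascularPath

__all__ = [
    "AnatomyGenConfig",
    "VascularGenConfig",
    "DEFAULT_SEED",
    "generate_anatomy",
    "generate_vascular_paths",
]

DEFAULT_SEED = 1405

# rough mix of the four principles in an anatomy export: partonomy dominates
_RELATION_WEIGHTS = (
    (RelationKind.CONSTITUTIONAL_PART, 0.40),
    (RelationKind.REGIONAL_PART, 0.40),
    (RelationKind.SUBCLASS, 0.15),
    (RelationKind.INSTANCE_OF, 0.05),
)


@dataclass(frozen=True)
class AnatomyGenConfig:
    """Shape parameters of the synthetic anatomy forest.

    ``n_tiles`` trees are grown; each tile draws its depth uniformly from
    ``[1, max_depth]`` and every internal node a child count uniformly from
    ``branching``.  ``microcirculation_fraction`` of the leaves are flagged
    as vascular contact points.
    """

    n_tiles: int = 24
    max_depth: int = 6
    branching: tuple[int, int] = (2, 4)
    microcirculation_fraction: float = 0.35
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_tiles < 1:
            raise ConfigError("n_tiles must be positive")
        if not 1 <= self.max_depth <= 16:
            raise ConfigError(f"max_depth must be in [1, 16], got {self.max_depth}")
        lo, hi = self.branching
        if lo < 1 or lo > hi:
            raise ConfigError(f"branching min must be in [1, max], got {self.branching}")
        if not 0.0 <= self.microcirculation_fraction <= 1.0:
            raise ConfigError("microcirculation_fraction must be in [0, 1]")


@dataclass(frozen=True)
class VascularGenConfig:
    """Shape parameters of the synthetic vascular path set.

    ``incomplete_fraction`` of the paths point at a target absent from the
    forest (emulating missing microcirculations in the base data) and will be
    dropped by the endpoint-completeness filter; the count is exact:
    ``round(n_paths * incomplete_fraction)``.  ``mean_segments`` steers the
    length of the external trunk; ``arterial_fraction`` the arterial/venous
    mix.
    """

    n_paths: int = 100
    incomplete_fraction: float = 0.0
    mean_segments: int = 4
    arterial_fraction: float = 0.5
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_paths < 1:
            raise ConfigError("n_paths must be positive")
        for name in ("incomplete_fraction", "arterial_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.mean_segments < 1:
            raise ConfigError("mean_segments must be positive")


def generate_anatomy(
    config: AnatomyGenConfig = AnatomyGenConfig(),
) -> tuple[list[HierarchyRecord], list[str], set[str]]:
    """Grow a loop-free synthetic forest.

    Returns ``(records, tile_roots, microcirculation_ids)`` ready for
    :func:`~vasculomap.io.build_anatomy_forest`.  Tile roots are emitted in
    tile order; node ids are drawn from a dedicated numeric range so they can
    never collide with the synthetic vascular segment ids.
    """
    rng = random.Random(config.seed)
    relations = [r for r, _ in _RELATION_WEIGHTS]
    weights = [w for _, w in _RELATION_WEIGHTS]

    records: list[HierarchyRecord] = []
    roots: list[str] = []
    leaves: list[str] = []
    next_id = 100000
    lo, hi = config.branching
    for _t in range(config.n_tiles):
        root = f"FMA{next_id}"
        next_id += 1
        roots.append(root)
        tile_depth = rng.randint(1, config.max_depth)
        frontier = [root]
        for depth in range(tile_depth):
            nxt: list[str] = []
            for parent in frontier:
                for _ in range(rng.randint(lo, hi)):
                    child = f"FMA{next_id}"
                    next_id += 1
                    rel = rng.choices(relations, weights)[0]
                    records.append(HierarchyRecord(parent, child, rel))
                    nxt.append(child)
            frontier = nxt
        leaves.extend(frontier)

    micro = {
        leaf for leaf in leaves if rng.random() < config.microcirculation_fraction
    }
    return records, roots, micro


def _chamber_for(vessel_type: str, rng: random.Random) -> str:
    pool = ARTERIAL_CHAMBERS if vessel_type == "arterial" else VENOUS_CHAMBERS
    return pool[rng.randrange(len(pool))]


def generate_vascular_paths(
    forest: AnatomyForest,
    chambers: tuple[str, ...] = CHAMBER_IDS,
    config: VascularGenConfig = VascularGenConfig(),
) -> list[VascularPath]:
    """Emit ``n_paths`` chamber-to-microcirculation paths over the forest.

    Complete paths target flagged microcirculations of the forest, sampled
    without replacement among targets with pairwise distinct parent segments
    so each vascular leaf maps to exactly one microcirculation; when that
    pool runs out, later paths re-target an already-used microcirculation
    (keeping its vessel type and chamber) rather than break the one-leaf,
    one-target property.  Exactly ``round(n_paths * incomplete_fraction)``
    paths target a fresh identifier absent from the forest and are thus
    excluded by the endpoint-completeness filter.

    Each path runs chamber -> shared per-chamber trunk -> per-(chamber, tile)
    branch segment -> in-tile ancestors of the target, ending at the target's
    parent (adjacent to the microcirculation).
    """
    rng = random.Random(config.seed)
    n_incomplete = round(config.n_paths * config.incomplete_fraction)
    n_complete = config.n_paths - n_incomplete

    micros = forest.microcirculation_ids()
    if not micros and n_complete > 0:
        raise GenerationError(
            "forest has no microcirculations but incomplete_fraction < 1"
        )

    # pick targets with pairwise distinct parent segments where possible, so
    # no vascular leaf serves two microcirculations
    targets: list[str] = []
    used_parents: set[str] = set()
    pool = list(micros)
    rng.shuffle(pool)
    for m in pool:
        if len(targets) == n_complete:
            break
        parent = forest.nodes[m].parent
        if parent is None or parent in used_parents:
            continue
        used_parents.add(parent)
        targets.append(m)
    if not targets and n_complete > 0:
        raise GenerationError("no microcirculation with a usable parent segment")

    trunk_len = max(1, config.mean_segments - 2)
    next_vessel = 500000
    trunks: dict[str, list[str]] = {}
    branch_nodes: dict[tuple[str, str], str] = {}

    def trunk(chamber: str) -> list[str]:
        nonlocal next_vessel
        if chamber not in trunks:
            seg = [f"FMA{next_vessel + i}" for i in range(trunk_len)]
            next_vessel += trunk_len
            trunks[chamber] = seg
        return trunks[chamber]

    def branch(chamber: str, tile: str) -> str:
        nonlocal next_vessel
        key = (chamber, tile)
        if key not in branch_nodes:
            branch_nodes[key] = f"FMA{next_vessel}"
            next_vessel += 1
        return branch_nodes[key]

    # interleave complete/incomplete deterministically: the first
    # n_incomplete slots chosen by the rng are incomplete
    slots = list(range(config.n_paths))
    rng.shuffle(slots)
    incomplete_slots = set(slots[:n_incomplete])

    paths: list[VascularPath] = []
    ti = 0
    next_missing = 800000
    target_meta: dict[str, tuple[str, str]] = {}  # micro -> (vessel_type, chamber)
    seg_affinity: dict[str, tuple[str, str]] = {}  # shared tail segment -> claim
    for i in range(config.n_paths):
        vessel_type = "arterial" if rng.random() < config.arterial_fraction else "venous"
        chamber = _chamber_for(vessel_type, rng)
        if i in incomplete_slots:
            # a target the forest does not know about
            target = f"FMA{next_missing}"
            next_missing += 1
            segments = tuple(trunk(chamber)) + (f"FMA{next_missing}",)
            next_missing += 1
        else:
            if ti < len(targets):
                target = targets[ti]
                ti += 1
                target_meta[target] = (vessel_type, chamber)
            else:
                # pool exhausted: revisit an existing target, keeping its
                # vessel type and chamber so the shared chain stays coherent
                target = targets[rng.randrange(len(targets))]
                vessel_type, chamber = target_meta[target]
            tile = forest.tile_of(target)
            # in-tile tail: up to two nearest ancestors, ending at the parent
            # (the segment adjacent to the target microcirculation); the
            # grandparent joins only when it is not already claimed by a
            # different chamber or vessel type, since arterial and venous
            # networks must not share segments
            tail: list[str] = []
            node = forest.nodes[target]
            if node.parent is not None:
                grand = forest.nodes[node.parent].parent
                if grand is not None:
                    claim = seg_affinity.setdefault(grand, (vessel_type, chamber))
                    if claim == (vessel_type, chamber):
                        tail.append(grand)
                tail.append(node.parent)
            else:  # degenerate: a flagged tile root stands in for itself
                tail.append(target)
            segments = tuple(trunk(chamber)) + (branch(chamber, tile),) + tuple(tail)
        paths.append(
            VascularPath(f"p{i + 1}", chamber, segments, target, vessel_type)
        )
    return paths
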