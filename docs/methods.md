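# Methods

## Scope and data model

vasculomap lays out a human-anatomy hierarchy as treemaps inside a 24-tile
body plan and overlays a routed arterial/venous network. The hierarchy is a
forest derived from an FMA-style ontology export: `parent child relation`
triples over `FMA<digits>` identifiers with four relation kinds
(constitutional part, regional part, subclass, instance of). Vascular input
is a separate file of paths, each a chamber of origin, an ordered sequence
of vessel-segment identifiers, a target microcirculation and an explicit
vessel type (`arterial`/`venous`). The vessel type is carried per path
rather than inferred from ontology relations because venous drainage is not
representable by a single relational principle the way arterial supply is.

### Forest construction

A child recorded under several parents keeps only the highest-precedence
edge (`constitutional_part > regional_part > subclass > instance_of`, ties
to first occurrence), with a warning per dropped edge. This turns the mixed
ontology graph into a true forest deterministically; precedence puts
partonomy above classification because the layout's nesting is meant to read
as "part of". Tile roots can never be demoted to children. Cycles reachable
from a tile root abort with the cycle listed; nodes unreachable from every
root are dropped and reported, mirroring the tolerant handling of incomplete
exports. Depth filtering keeps nodes within a maximum root distance
d ∈ [1, 16]; it is idempotent and monotone in d.

## Body plan

The default plan arranges 24 tiles as a lying person on a 4-column × 6-row
grid (head row first, legs last), heart tile at row 1, column 2, fully
overridable through a plan config file. Geometry defaults (all in layout
units; the global `scale` multiplies every output coordinate exactly
linearly):

| parameter | default | role |
|---|---|---|
| tile_width × tile_height | 160 × 120 | tile rectangle before scaling |
| channel_fraction | 0.1 | height of each vascular channel as a fraction of tile height (recommended ≤ 0.4; ≥ 0.5 is a config error since the treemap would vanish) |
| gutter | 24 | spacing between tiles; external vessels run here |
| inset | 1 | padding between a parent border and its children in the treemap |

Each tile splits into a top channel (arterial), the treemap area, and a
bottom channel (venous). The four chamber anchors sit on the heart tile
boundary: ventricles (LV, RV — pumping outward) on the top edge feeding the
arterial side, atria (LA, RA — receiving) on the bottom edge for the venous
side. Default chamber identifiers follow the conventional FMA ids
(FMA7101/7098/7097/7096).

## Treemap algorithms

All three algorithms use uniform child weights and sort siblings
lexicographically by id — the anatomy carries no meaningful size or order,
and fixed ordering makes output deterministic. Containment (child ⊆ parent)
and sibling interior-disjointness hold for all three.

- **Slice & dice**: equal splits, axis alternating per depth (even depth:
  vertical cuts). Children tile the parent exactly.
- **Squarified** (uniform weights): strips grow greedily along the shorter
  side of the remaining rectangle while the worst aspect ratio in the strip
  does not worsen; ties between orientations resolve toward vertical
  strips. The final strip absorbs the remainder exactly, which also removes
  floating-point drift.
- **Grid**: k children fill a cols = ⌈√k⌉, rows = ⌈k/cols⌉ grid row-major in
  equal cells (dynamic mode), or a fixed global grid (capacity error on
  overflow). Trailing cells stay empty, so children jointly cover
  k/(rows·cols) of the parent — each child's cell is exactly
  parent/(rows·cols). Area accounting is therefore exact per algorithm:
  slice&dice and squarified conserve the full parent area; the grid
  conserves cell areas with explicit empty slack.

`layout_quality` reports mean and max leaf aspect ratio
(max(w/h, h/w)); on a k-child star in a square the grid achieves
max(cols/rows, rows/cols) against slice&dice's k, which is the closed-form
oracle used in tests.

## Vascular layout

The vascular graph is the union of retained path chains, edges directed from
the chambers outward. A node is *internal* to a tile when its identifier
occurs in that tile's anatomy tree; the same identifier in two tiles is an
ambiguity error. Each path's terminal segment maps to exactly one target
microcirculation.

**Cluster labels and hubs.** Leaves are labelled with their target's id;
labels propagate to parents by union in reverse topological order. The hub
of (tile, cluster) is any in-tile node with a singleton label whose parents
are all either outside the tile or multi-labelled — the highest point where
the cluster is still "pure" inside the tile. A brute-force re-derivation of
descendant target sets per node serves as the independent oracle in tests.

**Contact anchors.** A vessel cannot reach a microcirculation deep inside a
space-filling treemap without crossing other leaves' interiors, so the
contact anchor is defined as the projection of the microcirculation
rectangle's centre onto the treemap boundary: top edge for arterial, bottom
edge for venous. All vascular geometry then lives in channels, side lanes
and gutters, and the validator's zero-crossing check is a real constraint on
the router, not a tautology. Two microcirculations with the same projected
x in one tile share an anchor x; their drops may coincide visually.

**Internal layout.** Per tile and cluster, the leaf sits directly above
(arterial) or below (venous) its anchor on a per-cluster lane inside the
channel; the hub sits at the channel's entry side (left for arterial, right
for venous); intermediate nodes are spaced evenly between hub and leaf.
Lanes are allocated in cluster-id order with a 3-unit pitch and wrap modulo
the channel capacity, so at high path counts parallel runs may coincide —
a deliberate trade of visual separation for unbounded capacity. A node
already placed by an earlier path keeps its position (first writer wins).
Internal layout depends only on the tile's own region, treemap and
clusters, which is what makes per-tile layouts independent (verified by a
perturbation test: growing one tile's tree moves no other tile's vessels).

**External layout.** Tiles are ordered by vascular distance from the heart
(minimum segment count from any chamber to any node of the tile; heart tile
first; untouched tiles follow by Manhattan grid distance; ties by tile id).
Every node not placed internally — chambers, untiled trunk segments, and
in-tile junctions above the hubs — is positioned along the corridor *spine*
of its chamber and steering tile (the lowest-ordered tile among its
clusters' targets): chamber anchor → band between tile rows → vertical lane
flanking the target column → band adjacent to the target row. Node arc
along the spine grows with graph depth (12-unit steps, capped at the spine
end), so shared trunk nodes lie on the common spine prefix and their child
edges are drawn once, covered by the continuation toward the next tile.
Edges between externally placed nodes follow spine geometry (backtracking to
the shared prefix when two spines diverge); hub edges continue to the spine
end, drop through the side lane and enter the channel at the hub's lane
height. If two joined route pieces do not meet exactly (possible only when
input networks share segments across chambers), an orthogonal corner is
inserted rather than a diagonal.

**Side and channel conventions.** Arterial edges may occupy: top channels,
the right half of the vertical gutter left of a tile column (the tile's left
lane), and the horizontal band above a tile row. Venous edges mirror this:
bottom channels, left half of the gutter right of a column, band below a
row. Crossings between opposite vessel types are permitted (they live in
visually distinct strata); same-type overlap is reduced only by lane
ordering.

**Validation.** The validator checks, per segment: axis-parallelism
(tolerance 1e-6); channel containment — the in-tile portion of any segment
entering a tile must lie inside that tile's vessel-type channel; treemap
clarity — no segment crosses the open interior of any treemap leaf
rectangle (anchors touch only the boundary); side convention for vertical
gutter runs; and, per retained path, connectivity — a chain of routed edges
whose endpoints match the node positions from chamber to anchor. "Shortest
paths" is interpreted routing-model-locally (spines add no detours beyond
lane constraints) and anatomical accuracy is not scored; neither has an
operational metric.

## Synthetic data

The generator emulates the *shape* of FMA-derived data, not its content:

- 24 tile trees (default), per-tile depth uniform on [1, max_depth]
  (default 6), child count uniform on [2, 4] per internal node, relation
  kinds drawn 40/40/15/5 % (partonomy-dominant);
- 35 % of leaves flagged as microcirculations;
- paths composed of a shared per-chamber trunk (length max(1,
  mean_segments − 2), default mean_segments 4), a per-(chamber, tile) branch
  segment, and an in-tile tail of up to two ancestors of the target ending
  at its parent (the segment adjacent to the microcirculation). Ventricles
  originate arterial paths, atria venous, 50/50 by default;
- targets are sampled without replacement among microcirculations with
  pairwise distinct parents (so each vascular leaf maps to exactly one
  target and each (tile, cluster) has one hub); when that pool is exhausted,
  later paths revisit an existing target with its original vessel type and
  chamber. A grandparent joins a tail only if not already claimed by a
  different chamber or vessel type, since real arterial and venous trees do
  not share segments;
- exactly round(n_paths × incomplete_fraction) paths point at fresh
  identifiers absent from the forest, emulating missing microcirculations as
  absent endpoints rather than malformed lines; the endpoint filter excludes
  exactly these.

One integer seed (default 1405) drives all randomness; identical
configurations give identical outputs. What the generator does **not**
emulate: real FMA term names, true vessel topology and calibre, tiles of
heterogeneous size, multi-parent children (the generator grows trees, so the
precedence rule is exercised by handcrafted tests), and label text. Passing
tests therefore demonstrate the layout machinery's guarantees on
structurally realistic data, not fidelity to any particular FMA release.

## Numerical choices and determinism

Coordinates are floats in layout units; SVG output rounds to three decimals
and orders elements deterministically, so identical inputs and seed give
byte-identical bytes. Geometric predicates use 1e-6 tolerances; treemap area
checks 1e-9 relative. Degenerate rectangles (zero extent after insetting)
collapse to the parent centre rather than erroring. Sibling order, cluster
order, lane order and edge emission order are all fixed by sorting on
identifiers.

## Problem sizes used in checks

The self-check script and test suite use desk-scale sizes chosen to exercise
every code path: the use-case mirror runs 925 paths with one third
incomplete over a ~6000-node forest; the treemap sweep runs 100 random
trees (≤ 500 nodes) × 3 algorithms; the hub-oracle comparison 50–200 graphs
of ≤ 50 vascular nodes; the routing sweep 20 full-pipeline fixtures of 40
paths. Headline counts that depend on a specific licensed ontology snapshot
are mirrored structurally (same pipeline, same fractions), not numerically.

## Known limitations

- Aesthetic lane separation degrades gracefully at high path density
  (coincident parallel runs) instead of growing the canvas.
- Anchors project to the treemap boundary; the microcirculation cell itself
  is highlighted by fill, not touched by the vessel polyline.
- Same-vessel-type edge crossings are not minimised globally.
- The body plan is one tile per grid cell; tiles spanning multiple cells are
  not supported.
- Vascular networks that genuinely share segments across chambers are routed
  connectedly and orthogonally, but their shared nodes follow the
  lexicographically first chamber's spine, which can produce backtracking
  detours.
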