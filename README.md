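# vasculomap

Layout of anatomical hierarchies and blood vessels: a 24-tile treemap of an
FMA-derived anatomy forest, overlaid with an arterial/venous network routed
from the four heart chambers to microcirculation contact points through
reserved channels, rendered as deterministic SVG.

The package is aimed at people building circuit-board-style views of human
physiology — ontology curators checking the coverage of vascular path data,
and visualisation researchers combining a superimposed network with a
space-filling layout.

## The model

**Anatomy forest.** The input is a table of `parent_id  child_id  relation`
triples over FMA identifiers, using the four hierarchical principles
(*constitutional part*, *regional part*, *subclass*, *instance of*). Because
an ontology export mixes principles, a child can appear under several
parents; edges are resolved by the fixed precedence
`constitutional_part > regional_part > subclass > instance_of`, yielding a
forest of 24 tile-rooted trees. Cycles reachable from a tile root are
reported as errors; depth can be capped at a global maximum distance
d ∈ [1, 16] from the root.

**Treemap stage.** Each tile's tree is laid out inside its rectangle by one
of three algorithms, all with uniform child weights w_i = 1:

- *slice & dice* — alternate the cut axis per depth; k siblings get equal
  slices, worst leaf aspect ratio max(w/h, h/w) = k;
- *squarified* — greedy strip placement along the shorter side, accepting a
  cell while the strip's worst aspect ratio does not worsen;
- *grid* — k children fill a ⌈√k⌉ × ⌈k/⌈√k⌉⌉ grid of equal cells (or a fixed
  global grid), keeping cells near-square.

**Vascular stage.** Retained paths (chamber → vessel segments → target
microcirculation) are merged into a directed graph and laid out in four
steps: (1) every leaf gets a *cluster id* equal to its target
microcirculation; labels propagate bottom-up by union, and the *hub* of a
(tile, cluster) is the highest in-tile node still carrying a single cluster
id; (2) hub subtrees are placed inside the tile's reserved channel (arterial
on top, venous at the bottom) with evenly spaced nodes; (3) remaining nodes
are placed along per-(chamber, tile) corridor spines through the gutters,
tiles ordered by vascular distance from the heart; (4) one orthogonal edge
per hub connects it to its parent. All segments are axis-parallel; arterial
edges keep to top channels and left side lanes, venous to bottom channels
and right lanes, and vessels touch the treemap only at contact anchors on
the treemap boundary. Paths whose chamber or target is missing from the
treemap are excluded with a machine-readable reason rather than guessed.

## Worked example

```sh
vasculomap simulate --n-paths 120 --incomplete-fraction 0.25 --seed 7 --out fix/
vasculomap run --hierarchy fix/hierarchy.tsv --paths fix/paths.txt --seed 7 --out out/
```

which logs, per stage:

```
[parse_hierarchy] 4457 records
[build_forest] 4481 nodes, 0 unreachable dropped
[parse_paths] 120 paths
[treemap] 24 tiles, 4481 rectangles
[endpoint_filter] retained 90, excluded 30
[vascular] 90 hubs, 385 routed edges, 0 violations
```

30 of 120 paths (the simulated incomplete quarter) point at
microcirculations absent from the hierarchy and are listed in
`out/exclusions.tsv` with reason `missing_target`; the 90 drawable paths are
routed into `out/layout.svg` with zero validation violations — every
segment axis-parallel, arterial red in top channels, venous blue in bottom
channels, no segment crossing a treemap cell. Running the same command twice
produces byte-identical SVG.

The same flow is available from Python — see `examples/`:

- `01_treemap_algorithms.py` — aspect-ratio statistics of the three treemap
  algorithms on one tile;
- `02_full_pipeline.py` — the full pipeline from generated files to SVG;
- `03_endpoint_completeness.py` — the endpoint filter at use-case scale
  (925 paths, one third incomplete: 617 retained / 66.70 %, 308 excluded).

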