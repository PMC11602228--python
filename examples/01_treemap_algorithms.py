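"""Compare the three treemap algorithms on one synthetic anatomy tile.

Builds a single random anatomy tree, lays it out with slice&dice, squarified
and the grid algorithm inside the same rectangle, and prints the aspect-ratio
statistics of the leaf cells.  Lower numbers mean squarer, more readable
cells; 1.0 is a perfect square.
"""

from vasculomap import (
    AnatomyGenConfig,
    Rect,
    build_anatomy_forest,
    generate_anatomy,
    layout_grid,
    layout_quality,
    layout_slice_and_dice,
    layout_squarified,
)

records, roots, micro = generate_anatomy(AnatomyGenConfig(n_tiles=1, max_depth=4, seed=44))
forest = build_anatomy_forest(records, roots, micro)
root = roots[0]
rect = Rect(0, 0, 320, 240)

print(f"tile tree: {len(forest)} nodes, {len(forest.leaves())} leaves\n")
print(f"{'algorithm':<12} {'mean aspect':>12} {'max aspect':>12}")
for name, algo in [
    ("slice_dice", layout_slice_and_dice),
    ("squarified", layout_squarified),
    ("grid", layout_grid),
]:
    stats = layout_quality(algo(forest, root, rect), forest)
    print(f"{name:<12} {stats['mean_aspect']:>12.3f} {stats['max_aspect']:>12.3f}")

print(
    "\nAspect 1.0 would be a perfect square. Slice&dice degrades on nodes "
    "with many children (k children -> aspect k); squarified stays close to "
    "square everywhere; the grid is square on wide nodes but can elongate "
    "through chains of two-child nodes."
)
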