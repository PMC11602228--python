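"""Treemap layout of a tile's anatomy tree inside its rectangle.

Three algorithms are offered, all with uniform child weights (the anatomy
hierarchy carries no size attribute, and ignoring child ordering improves
readability of the nested tiling):

* **slice & dice** — recursively split the reference space along one axis,
  alternating per depth (even depth: vertical cuts, odd: horizontal);
* **squarified** — greedy strip placement along the shorter side, accepting a
  child into the current strip while the worst aspect ratio does not worsen;
* **grid** — children fill an equal-cell grid, either dynamic
  (cols = ceil(sqrt(k))) or a fixed global grid.

Every algorithm honours the two treemap conditions: each child's rectangle
lies inside its parent's, and sibling rectangles have pairwise disjoint
interiors.  An ``inset`` pads children away from the parent border so nested
boundaries stay visible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Callable

from .errors import CapacityError, VasculomapError
from .io import AnatomyForest

__all__ = [
    "Rect",
    "GridMode",
    "TreemapLayout",
    "layout_slice_and_dice",
    "layout_squarified",
    "layout_grid",
    "layout_quality",
    "write_layout_table",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle; origin top-left, y grows downward."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w < 0 or self.h < 0:
            raise ValueError(f"negative extent: {self}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def cx(self) -> float:
        return self.x + self.w / 2

    @property
    def cy(self) -> float:
        return self.y + self.h / 2

    def aspect(self) -> float:
        """max(w/h, h/w); infinity for a degenerate rectangle."""
        if self.w <= 0 or self.h <= 0:
            return math.inf
        return max(self.w / self.h, self.h / self.w)

    def contains_rect(self, other: "Rect", tol: float = 1e-9) -> bool:
        return (
            other.x >= self.x - tol
            and other.y >= self.y - tol
            and other.x2 <= self.x2 + tol
            and other.y2 <= self.y2 + tol
        )

    def contains_point(self, px: float, py: float, tol: float = 1e-9) -> bool:
        return self.x - tol <= px <= self.x2 + tol and self.y - tol <= py <= self.y2 + tol

    def interior_overlaps(self, other: "Rect", tol: float = 1e-9) -> bool:
        """True when the open interiors intersect (shared edges do not count)."""
        return (
            self.x < other.x2 - tol
            and other.x < self.x2 - tol
            and self.y < other.y2 - tol
            and other.y < self.y2 - tol
        )

    def shrink(self, pad: float) -> "Rect":
        """Inset by ``pad`` on all sides, collapsing to the centre if too small."""
        w = max(0.0, self.w - 2 * pad)
        h = max(0.0, self.h - 2 * pad)
        return Rect(self.x + min(pad, self.w / 2), self.y + min(pad, self.h / 2), w, h)

    def scaled(self, s: float) -> "Rect":
        return Rect(self.x * s, self.y * s, self.w * s, self.h * s)


@dataclass(frozen=True)
class GridMode:
    """Grid shape for the grid treemap: dynamic, or a fixed rows x cols grid."""

    kind: str  # "dynamic" | "fixed"
    rows: int = 0
    cols: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("dynamic", "fixed"):
            raise ValueError(f"unknown grid mode {self.kind!r}")
        if self.kind == "fixed" and (self.rows < 1 or self.cols < 1):
            raise ValueError("fixed grid needs rows >= 1 and cols >= 1")

    @classmethod
    def dynamic(cls) -> "GridMode":
        return cls("dynamic")

    @classmethod
    def fixed(cls, rows: int, cols: int) -> "GridMode":
        return cls("fixed", rows, cols)


@dataclass
class TreemapLayout:
    """Node-id -> rectangle mapping produced by one of the algorithms."""

    rects: dict[str, Rect]
    algorithm: str
    inset: float

    def leaf_rects(self, forest: AnatomyForest) -> dict[str, Rect]:
        return {
            nid: r
            for nid, r in self.rects.items()
            if nid in forest.nodes and not forest.nodes[nid].children
        }


def _sorted_children(forest: AnatomyForest, node_id: str) -> list[str]:
    # lexicographic order keeps the layout deterministic; child ordering
    # carries no meaning in the anatomy hierarchy
    return sorted(forest.children_of(node_id))


def _recurse(
    forest: AnatomyForest,
    root: str,
    rect: Rect,
    inset: float,
    place: Callable[[list[str], Rect, int], dict[str, Rect]],
) -> dict[str, Rect]:
    rects = {root: rect}
    stack: list[tuple[str, Rect, int]] = [(root, rect, 0)]
    while stack:
        nid, r, depth = stack.pop()
        kids = _sorted_children(forest, nid)
        if not kids:
            continue
        inner = r.shrink(inset)
        if inner.w <= 0 or inner.h <= 0:
            inner = Rect(r.cx, r.cy, 0.0, 0.0)
        cells = place(kids, inner, depth)
        for kid, cell in cells.items():
            rects[kid] = cell
            stack.append((kid, cell, depth + 1))
    return rects


def layout_slice_and_dice(
    forest: AnatomyForest, root: str, rect: Rect, inset: float = 0.0
) -> TreemapLayout:
    """Alternating-axis equal splits: vertical cuts at even depth, horizontal at odd."""
    if rect.w <= 0 or rect.h <= 0:
        raise VasculomapError(f"layout rectangle must have positive extent: {rect}")

    def place(kids: list[str], r: Rect, depth: int) -> dict[str, Rect]:
        k = len(kids)
        out: dict[str, Rect] = {}
        if depth % 2 == 0:  # vertical cuts -> columns side by side
            w = r.w / k
            for i, kid in enumerate(kids):
                out[kid] = Rect(r.x + i * w, r.y, w, r.h)
        else:  # horizontal cuts -> rows stacked
            h = r.h / k
            for i, kid in enumerate(kids):
                out[kid] = Rect(r.x, r.y + i * h, r.w, h)
        return out

    return TreemapLayout(_recurse(forest, root, rect, inset, place), "slice_dice", inset)


def _squarify_cells(k: int, r: Rect) -> list[Rect]:
    """Place k equal-area cells in r by greedy strip growth (uniform weights).

    The strip runs along the shorter side of the remaining rectangle; a cell
    joins the current strip while the strip's worst aspect ratio does not
    worsen.  Ties between vertical and horizontal resolve toward vertical
    strips.
    """
    cells: list[Rect] = []
    remaining = k
    cur = r
    area = r.area / k if k else 0.0
    while remaining > 0:
        # strip along the shorter side: if the remaining rect is wider than
        # tall, lay a vertical strip (column) against the left edge, else a
        # horizontal strip (row) against the top edge; ties -> column
        column = cur.w >= cur.h

        def worst(n: int) -> float:
            strip_area = n * area
            if column:
                strip_w = strip_area / cur.h
                cell_h = cur.h / n
                return max(strip_w / cell_h, cell_h / strip_w) if strip_w > 0 else math.inf
            strip_h = strip_area / cur.w
            cell_w = cur.w / n
            return max(strip_h / cell_w, cell_w / strip_h) if strip_h > 0 else math.inf

        n = 1
        while n < remaining and worst(n + 1) <= worst(n):
            n += 1
        strip_area = n * area
        last = n == remaining  # final strip consumes the remainder exactly
        if column:
            strip_w = cur.w if last else strip_area / cur.h
            cell_h = cur.h / n
            for i in range(n):
                cells.append(Rect(cur.x, cur.y + i * cell_h, strip_w, cell_h))
            cur = Rect(cur.x + strip_w, cur.y, max(0.0, cur.w - strip_w), cur.h)
        else:
            strip_h = cur.h if last else strip_area / cur.w
            cell_w = cur.w / n
            for i in range(n):
                cells.append(Rect(cur.x + i * cell_w, cur.y, cell_w, strip_h))
            cur = Rect(cur.x, cur.y + strip_h, cur.w, max(0.0, cur.h - strip_h))
        remaining -= n
    return cells


def layout_squarified(
    forest: AnatomyForest, root: str, rect: Rect, inset: float = 0.0
) -> TreemapLayout:
    """Squarified treemap with uniform weights, aiming for aspect ratio one."""
    if rect.w <= 0 or rect.h <= 0:
        raise VasculomapError(f"layout rectangle must have positive extent: {rect}")

    def place(kids: list[str], r: Rect, depth: int) -> dict[str, Rect]:
        if r.w <= 0 or r.h <= 0:
            return {kid: Rect(r.x, r.y, 0.0, 0.0) for kid in kids}
        cells = _squarify_cells(len(kids), r)
        return dict(zip(kids, cells))

    return TreemapLayout(_recurse(forest, root, rect, inset, place), "squarified", inset)


def layout_grid(
    forest: AnatomyForest,
    root: str,
    rect: Rect,
    mode: GridMode = GridMode.dynamic(),
    inset: float = 0.0,
) -> TreemapLayout:
    """Grid treemap: children fill equal grid cells row-major.

    Dynamic mode adapts the grid to each node (cols = ceil(sqrt(k)),
    rows = ceil(k / cols)) so cells stay close to square; fixed mode uses one
    global grid for every node and raises :class:`CapacityError` when a node
    has more children than cells.
    """
    if rect.w <= 0 or rect.h <= 0:
        raise VasculomapError(f"layout rectangle must have positive extent: {rect}")

    def place(kids: list[str], r: Rect, depth: int) -> dict[str, Rect]:
        k = len(kids)
        if mode.kind == "dynamic":
            cols = math.ceil(math.sqrt(k))
            rows = math.ceil(k / cols)
        else:
            rows, cols = mode.rows, mode.cols
            if k > rows * cols:
                raise CapacityError(
                    f"fixed {rows}x{cols} grid cannot hold {k} children of {kids[0]}'s parent"
                )
        cw, ch = r.w / cols, r.h / rows
        out: dict[str, Rect] = {}
        for i, kid in enumerate(kids):
            row, col = divmod(i, cols)
            out[kid] = Rect(r.x + col * cw, r.y + row * ch, cw, ch)
        return out

    tag = "grid_dynamic" if mode.kind == "dynamic" else f"grid_fixed_{mode.rows}x{mode.cols}"
    return TreemapLayout(_recurse(forest, root, rect, inset, place), tag, inset)


ALGORITHMS = {
    "slice_dice": layout_slice_and_dice,
    "squarified": layout_squarified,
    "grid": layout_grid,
}


def layout_quality(layout: TreemapLayout, forest: AnatomyForest) -> dict[str, float]:
    """Aspect-ratio statistics over leaf rectangles with positive extent."""
    leaf = [
        r
        for nid, r in layout.rects.items()
        if nid in forest.nodes
        and not forest.nodes[nid].children
        and r.w > 0
        and r.h > 0
    ]
    if not leaf:
        raise VasculomapError("layout has no leaf rectangles with positive extent")
    aspects = [r.aspect() for r in leaf]
    return {
        "mean_aspect": sum(aspects) / len(aspects),
        "max_aspect": max(aspects),
        "leaf_count": float(len(leaf)),
    }


def write_layout_table(
    layout: TreemapLayout, forest: AnatomyForest, handle: IO[str]
) -> None:
    """Flat TSV interchange: node_id, x, y, w, h, depth, is_microcirculation."""
    handle.write("node_id\tx\ty\tw\th\tdepth\tis_microcirculation\n")
    for nid in sorted(layout.rects):
        r = layout.rects[nid]
        node = forest.nodes[nid]
        handle.write(
            f"{nid}\t{r.x:.3f}\t{r.y:.3f}\t{r.w:.3f}\t{r.h:.3f}"
            f"\t{node.depth}\t{int(node.is_microcirculation)}\n"
        )
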