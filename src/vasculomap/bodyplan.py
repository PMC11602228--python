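"""The 24-tile body plan and per-tile region allocation.

The body is divided into 24 anatomical compartments ("tiles") arranged like a
lying person, head tiles in the top row and legs at the bottom, on a 4-column
by 6-row grid.  Exactly one tile hosts the heart and carries the four chamber
anchors (left/right ventricle feeding arterial channels on its top edge,
left/right atrium receiving venous channels on its bottom edge).

Each tile's rectangle is split vertically into a reserved arterial channel at
the top, the treemap area in the middle, and a reserved venous channel at the
bottom, so routed vessels never interfere with the treemap's visibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Sequence

from .errors import ConfigError, ParseError
from .treemap import Rect

__all__ = [
    "TileSpec",
    "TileRegion",
    "BodyPlan",
    "CHAMBER_IDS",
    "DEFAULT_CHAMBER_FMA",
    "default_body_plan",
    "allocate_tile_regions",
    "read_body_plan",
    "write_body_plan",
]

# chamber short ids and their conventional FMA identifiers
CHAMBER_IDS = ("LV", "RV", "LA", "RA")
DEFAULT_CHAMBER_FMA = {
    "LV": "FMA7101",  # left ventricle
    "RV": "FMA7098",  # right ventricle
    "LA": "FMA7097",  # left atrium
    "RA": "FMA7096",  # right atrium
}
# ventricles pump outward -> arterial (top) side; atria receive -> venous (bottom)
ARTERIAL_CHAMBERS = ("LV", "RV")
VENOUS_CHAMBERS = ("LA", "RA")


@dataclass(frozen=True)
class TileSpec:
    """One of the 24 anatomical compartments of the body plan."""

    tile_id: int
    grid_row: int
    grid_col: int
    label: str
    root_id: str
    heart_flag: bool = False


@dataclass(frozen=True)
class TileRegion:
    """A tile's rectangle split into top channel / treemap / bottom channel."""

    tile_rect: Rect
    treemap_rect: Rect
    top_channel_rect: Rect
    bottom_channel_rect: Rect


@dataclass
class BodyPlan:
    """Tile arrangement plus the global geometry knobs.

    ``scale`` multiplies every output coordinate linearly.  Each vascular
    channel takes ``channel_fraction`` of the tile height (recommended range
    0-0.4; at 0.5 the treemap would vanish).  ``gutter`` is the spacing
    between tiles, in layout units, through which external vessels run.
    """

    tiles: list[TileSpec]
    scale: float = 1.0
    channel_fraction: float = 0.1
    tile_width: float = 160.0
    tile_height: float = 120.0
    gutter: float = 24.0
    chambers: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CHAMBER_FMA))

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigError(f"scale must be positive, got {self.scale}")
        cells = [(t.grid_row, t.grid_col) for t in self.tiles]
        if len(set(cells)) != len(cells):
            raise ConfigError("tile grid cells must be unique")
        hearts = [t for t in self.tiles if t.heart_flag]
        if len(hearts) != 1:
            raise ConfigError(f"exactly one heart tile required, found {len(hearts)}")

    @property
    def heart_tile(self) -> TileSpec:
        return next(t for t in self.tiles if t.heart_flag)

    @property
    def n_rows(self) -> int:
        return max(t.grid_row for t in self.tiles) + 1

    @property
    def n_cols(self) -> int:
        return max(t.grid_col for t in self.tiles) + 1

    def tile_by_id(self, tile_id: int) -> TileSpec:
        return next(t for t in self.tiles if t.tile_id == tile_id)

    def tile_by_root(self, root_id: str) -> TileSpec | None:
        return next((t for t in self.tiles if t.root_id == root_id), None)

    def with_roots(self, root_ids: Sequence[str]) -> "BodyPlan":
        """Re-bind tile roots (in tile-id order) to the given identifiers."""
        if len(root_ids) != len(self.tiles):
            raise ConfigError(
                f"expected {len(self.tiles)} roots, got {len(root_ids)}"
            )
        by_id = sorted(self.tiles, key=lambda t: t.tile_id)
        rebound = {t.tile_id: replace(t, root_id=r) for t, r in zip(by_id, root_ids)}
        return replace(self, tiles=[rebound[t.tile_id] for t in self.tiles])


# the lying-person arrangement: head row first, heart in the thorax row,
# legs at the bottom; 4 columns x 6 rows
_DEFAULT_TILES: list[tuple[int, int, int, str, bool]] = [
    (1, 0, 0, "brain", False),
    (2, 0, 1, "head", False),
    (3, 0, 2, "face", False),
    (4, 0, 3, "neck", False),
    (5, 1, 0, "right arm", False),
    (6, 1, 1, "thorax", False),
    (7, 1, 2, "heart", True),
    (8, 1, 3, "left arm", False),
    (9, 2, 0, "right lung", False),
    (10, 2, 1, "mediastinum", False),
    (11, 2, 2, "left lung", False),
    (12, 2, 3, "vertebral column", False),
    (13, 3, 0, "liver", False),
    (14, 3, 1, "stomach", False),
    (15, 3, 2, "spleen", False),
    (16, 3, 3, "pancreas", False),
    (17, 4, 0, "right kidney", False),
    (18, 4, 1, "intestine", False),
    (19, 4, 2, "left kidney", False),
    (20, 4, 3, "pelvis", False),
    (21, 5, 0, "right leg", False),
    (22, 5, 1, "urinary bladder", False),
    (23, 5, 2, "genitalia", False),
    (24, 5, 3, "left leg", False),
]


def default_body_plan(root_ids: Sequence[str] | None = None, **overrides) -> BodyPlan:
    """The default 24-tile plan on a 4x6 grid with the heart at row 1, col 2.

    ``root_ids`` binds the 24 tile-tree roots in tile-id order; placeholder
    identifiers are used when absent.  Keyword overrides forward to
    :class:`BodyPlan` (scale, channel_fraction, gutter, ...).
    """
    tiles = [
        TileSpec(tid, row, col, label, f"FMA{900000 + tid}", heart)
        for tid, row, col, label, heart in _DEFAULT_TILES
    ]
    plan = BodyPlan(tiles=tiles, **overrides)
    if root_ids is not None:
        plan = plan.with_roots(root_ids)
    return plan


def allocate_tile_regions(
    plan: BodyPlan, canvas: Rect | None = None
) -> dict[int, TileRegion]:
    """Split the canvas grid into tile rectangles and their channel regions.

    Without an explicit canvas, the canvas is derived from the plan's tile
    dimensions, gutters and scale (with a one-gutter margin all round).  Each
    tile is divided into a top channel, the treemap area, and a bottom
    channel; channel heights are ``channel_fraction`` of the tile height.
    """
    if plan.channel_fraction < 0:
        raise ConfigError("channel_fraction must be non-negative")
    if plan.channel_fraction >= 0.5:
        raise ConfigError(
            f"channel_fraction {plan.channel_fraction} leaves no treemap space"
        )
    rows, cols = plan.n_rows, plan.n_cols
    s = plan.scale
    if canvas is None:
        g = plan.gutter * s
        tw, th = plan.tile_width * s, plan.tile_height * s
        origin_x, origin_y = g, g
    else:
        if canvas.w <= 0 or canvas.h <= 0:
            raise ConfigError("canvas must have positive extent")
        g = plan.gutter * s
        tw = (canvas.w - (cols + 1) * g) / cols
        th = (canvas.h - (rows + 1) * g) / rows
        if tw <= 0 or th <= 0:
            raise ConfigError("canvas too small for the tile grid and gutters")
        origin_x, origin_y = canvas.x + g, canvas.y + g

    regions: dict[int, TileRegion] = {}
    ch = plan.channel_fraction * th
    for tile in plan.tiles:
        x = origin_x + tile.grid_col * (tw + g)
        y = origin_y + tile.grid_row * (th + g)
        tile_rect = Rect(x, y, tw, th)
        top = Rect(x, y, tw, ch)
        treemap = Rect(x, y + ch, tw, th - 2 * ch)
        bottom = Rect(x, y + th - ch, tw, ch)
        regions[tile.tile_id] = TileRegion(tile_rect, treemap, top, bottom)
    return regions


def plan_canvas(plan: BodyPlan) -> Rect:
    """The implicit canvas covering the grid plus a one-gutter margin."""
    s = plan.scale
    g = plan.gutter * s
    w = plan.n_cols * (plan.tile_width * s + g) + g
    h = plan.n_rows * (plan.tile_height * s + g) + g
    return Rect(0.0, 0.0, w, h)


def write_body_plan(plan: BodyPlan, handle: IO[str]) -> None:
    """Write the plan as the key-value tile-per-line config dialect."""
    handle.write(f"#scale\t{plan.scale}\n")
    handle.write(f"#channel_fraction\t{plan.channel_fraction}\n")
    handle.write(f"#gutter\t{plan.gutter}\n")
    handle.write("#tile_id\trow\tcol\tlabel\troot_id\theart_flag\n")
    for t in sorted(plan.tiles, key=lambda t: t.tile_id):
        handle.write(
            f"{t.tile_id}\t{t.grid_row}\t{t.grid_col}\t{t.label}\t{t.root_id}"
            f"\t{int(t.heart_flag)}\n"
        )


def read_body_plan(source: IO[str] | Iterable[str]) -> BodyPlan:
    """Parse the config dialect written by :func:`write_body_plan`."""
    tiles: list[TileSpec] = []
    settings: dict[str, float] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if len(parts) == 2 and parts[0] in ("scale", "channel_fraction", "gutter"):
                settings[parts[0]] = float(parts[1])
            continue
        fields = line.split("\t")
        if len(fields) != 6:
            raise ParseError(f"expected 6 tab-separated fields, got {len(fields)}", lineno)
        try:
            tiles.append(
                TileSpec(
                    int(fields[0]), int(fields[1]), int(fields[2]),
                    fields[3], fields[4], bool(int(fields[5])),
                )
            )
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from None
    return BodyPlan(tiles=tiles, **settings)
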