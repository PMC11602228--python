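"""Deterministic SVG rendering of the combined treemap + vascular layout.

Arterial vessels are drawn red and venous blue, matching the convention of
oxygen-rich blood leaving the heart and oxygen-poor blood returning to it.
Element order is fixed (tiles by id, then channels, then treemap rectangles
by node id, then vascular polylines by edge key), and all coordinates are
rounded to three decimals, so identical inputs yield byte-identical SVG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .bodyplan import BodyPlan, TileRegion, plan_canvas
from .io import AnatomyForest
from .treemap import TreemapLayout
from .vascular import VascularLayout

__all__ = ["RenderStyle", "render_svg"]


@dataclass(frozen=True)
class RenderStyle:
    """Colours and stroke parameters of the SVG output."""

    arterial_colour: str = "#CC2222"
    venous_colour: str = "#2244CC"
    tile_border: str = "#333333"
    treemap_border: str = "#999999"
    channel_fill: str = "#F2F2F2"
    tile_stroke_width: float = 1.0
    treemap_stroke_width: float = 0.5
    vessel_stroke_width: float = 1.2
    label_font_size: float = 8.0

    def __post_init__(self) -> None:
        if self.arterial_colour == self.venous_colour:
            raise ValueError("arterial and venous colours must be distinct")


def _fmt(value: float) -> str:
    s = f"{value:.3f}"
    return "0.000" if s == "-0.000" else s


def _rect_el(r, fill: str, stroke: str, width: float, cls: str) -> str:
    return (
        f'<rect class="{cls}" x="{_fmt(r.x)}" y="{_fmt(r.y)}" '
        f'width="{_fmt(r.w)}" height="{_fmt(r.h)}" '
        f'fill="{fill}" stroke="{stroke}" stroke-width="{_fmt(width)}"/>'
    )


def render_svg(
    treemap_layouts: Mapping[int, TreemapLayout],
    vascular_layout: VascularLayout | None,
    plan: BodyPlan,
    regions: Mapping[int, TileRegion],
    forest: AnatomyForest | None = None,
    style: RenderStyle = RenderStyle(),
) -> str:
    """Serialise the layout to an SVG document string.

    One ``rect`` per laid-out treemap node, one ``polyline`` per routed
    vascular edge coloured by vessel type; channels are rendered beneath the
    vessels.  Empty layouts produce a valid document with only tile frames.
    """
    canvas = plan_canvas(plan)
    lines: list[str] = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_fmt(canvas.w)}" '
        f'height="{_fmt(canvas.h)}" viewBox="0 0 {_fmt(canvas.w)} {_fmt(canvas.h)}">',
        f'<rect class="canvas" x="0" y="0" width="{_fmt(canvas.w)}" '
        f'height="{_fmt(canvas.h)}" fill="#FFFFFF"/>',
    ]
    for tile in sorted(plan.tiles, key=lambda t: t.tile_id):
        region = regions[tile.tile_id]
        lines.append(
            _rect_el(region.tile_rect, "none", style.tile_border, style.tile_stroke_width, f"tile tile-{tile.tile_id}")
        )
        if region.top_channel_rect.h > 0:
            lines.append(_rect_el(region.top_channel_rect, style.channel_fill, "none", 0.0, "channel-top"))
        if region.bottom_channel_rect.h > 0:
            lines.append(_rect_el(region.bottom_channel_rect, style.channel_fill, "none", 0.0, "channel-bottom"))
        lines.append(
            f'<text x="{_fmt(region.tile_rect.x + 2)}" y="{_fmt(region.tile_rect.y - 2)}" '
            f'font-size="{_fmt(style.label_font_size)}" fill="{style.tile_border}">'
            f"{tile.label}</text>"
        )
    for tile_id in sorted(treemap_layouts):
        tl = treemap_layouts[tile_id]
        for nid in sorted(tl.rects):
            r = tl.rects[nid]
            is_micro = bool(
                forest and nid in forest.nodes and forest.nodes[nid].is_microcirculation
            )
            fill = "#FFE8E8" if is_micro else "none"
            cls = "micro" if is_micro else "node"
            lines.append(
                _rect_el(r, fill, style.treemap_border, style.treemap_stroke_width, f"{cls} {nid}")
            )
    if vascular_layout is not None:
        ordered = sorted(
            vascular_layout.edges, key=lambda e: (e.kind, e.source, e.target)
        )
        for e in ordered:
            colour = (
                style.arterial_colour if e.vessel_type == "arterial" else style.venous_colour
            )
            pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in e.points)
            lines.append(
                f'<polyline class="vessel {e.kind}" data-edge="{e.source}:{e.target}" '
                f'points="{pts}" fill="none" stroke="{colour}" '
                f'stroke-width="{_fmt(style.vessel_stroke_width)}"/>'
            )
        for nid in sorted(vascular_layout.node_positions):
            x, y = vascular_layout.node_positions[nid]
            lines.append(
                f'<circle class="vnode" cx="{_fmt(x)}" cy="{_fmt(y)}" r="1.2" fill="#444444"/>'
            )
    lines.append("</svg>")
    return "\n".join(lines) + "\n"
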