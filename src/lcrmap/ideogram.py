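"""SVG ideogram rendering of multi-track low-complexity maps.

Each sequence becomes one horizontal bar, scaled so the longest sequence
spans the full drawing width. Regions are colored sub-rectangles at
proportional positions; tracks are drawn in order, so later tracks overlay
earlier ones (e.g. a bounded-cache "local" track on top of a full-memory
"global" track). Regions can be synthetically enlarged about their centers
to stay visible on long sequences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Union
from xml.sax.saxutils import escape

from .segment import Region


@dataclass
class Track:
    """One annotation layer: sequence lengths, regions, and a fill color."""

    name: str
    lengths: Dict[str, int]
    regions: List[Region]
    color: str = "#2e8b57"


@dataclass
class IdeogramStyle:
    width: int = 1200
    thickness: int = 14
    spacing: int = 8
    background: str = "#ffffff"
    bar_fill: str = "#ececec"
    border: str = "#333333"
    corner: str = "round"  # "round" | "strict"
    enlarge: float = 1.0
    show_labels: bool = True
    label_width: int = 120

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.spacing <= 0:
            raise ValueError("thickness and spacing must be positive")
        if self.corner not in ("round", "strict"):
            raise ValueError(f"corner must be 'round' or 'strict', got {self.corner!r}")
        if self.enlarge < 1.0:
            raise ValueError(f"enlarge must be >= 1, got {self.enlarge}")


def _merge_lengths(tracks: Sequence[Track]) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for track in tracks:
        for seq_id, length in track.lengths.items():
            if seq_id in lengths and lengths[seq_id] != length:
                raise ValueError(
                    f"inconsistent length for {seq_id!r}: "
                    f"{lengths[seq_id]} vs {length}"
                )
            lengths.setdefault(seq_id, length)
    return lengths


def render_ideogram(tracks: Sequence[Track], style: IdeogramStyle | None = None) -> str:
    """Render tracks into an SVG 1.1 document string (deterministic order)."""
    if not tracks:
        raise ValueError("at least one track is required")
    style = style or IdeogramStyle()
    lengths = _merge_lengths(tracks)
    drawable = {s: n for s, n in lengths.items() if n > 0}
    for seq_id in lengths:
        if seq_id not in drawable:
            warnings.warn(f"skipping zero-length sequence {seq_id!r}", stacklevel=2)
    if not drawable:
        raise ValueError("no sequence with positive length to draw")
    max_len = max(drawable.values())

    margin = 10
    left = style.label_width if style.show_labels else margin
    plot_w = style.width - left - margin
    row_h = style.thickness + style.spacing
    height = margin * 2 + row_h * len(drawable) - style.spacing
    rx = style.thickness / 2 if style.corner == "round" else 0

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{style.width}" height="{height}">',
        f'<rect x="0" y="0" width="{style.width}" height="{height}" '
        f'fill="{style.background}"/>',
    ]
    rows = {}
    for i, (seq_id, length) in enumerate(drawable.items()):
        y = margin + i * row_h
        rows[seq_id] = y
        bar_w = plot_w * length / max_len
        parts.append(
            f'<rect x="{left}" y="{y}" width="{bar_w:.2f}" '
            f'height="{style.thickness}" rx="{rx:.2f}" fill="{style.bar_fill}" '
            f'stroke="{style.border}" stroke-width="1"/>'
        )
        if style.show_labels:
            ty = y + style.thickness * 0.75
            parts.append(
                f'<text x="{margin}" y="{ty:.2f}" font-size="{style.thickness - 2}" '
                f'font-family="sans-serif">{escape(seq_id)}</text>'
            )
    for track in tracks:
        for region in track.regions:
            if region.seq_id not in lengths:
                raise ValueError(f"region on unknown sequence {region.seq_id!r}")
            length = lengths[region.seq_id]
            if region.end > length:
                raise ValueError(
                    f"region [{region.start}, {region.end}] exceeds "
                    f"{region.seq_id!r} length {length}"
                )
            if region.seq_id not in rows:
                continue  # zero-length sequence, already warned
            y = rows[region.seq_id]
            scale = plot_w / max_len
            x0 = left + (region.start - 1) * scale
            x1 = left + region.end * scale
            if style.enlarge > 1.0:
                center = (x0 + x1) / 2
                half = (x1 - x0) / 2 * style.enlarge
                bar_x0 = left
                bar_x1 = left + length * scale
                x0 = max(bar_x0, center - half)
                x1 = min(bar_x1, center + half)
            parts.append(
                f'<rect x="{x0:.2f}" y="{y}" width="{x1 - x0:.2f}" '
                f'height="{style.thickness}" fill="{track.color}">'
                f'<title>{escape(track.name)} {escape(region.seq_id)}:'
                f'{region.start}-{region.end}</title></rect>'
            )
    parts.append("</svg>")
    return "\n".join(parts)


def write_ideogram(
    tracks: Sequence[Track],
    path: Union[str, Path],
    style: IdeogramStyle | None = None,
) -> None:
    Path(path).write_text(render_ideogram(tracks, style) + "\n")
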