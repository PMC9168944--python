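"""Rendering: compass graph, per-area domain bars, and the group chart.

SVG is the canonical output: documents are built with stable element ids
and fixed-precision coordinates so identical inputs yield byte-identical
files (testable by parsing). PNG is a derived raster via matplotlib.

Geometry convention (the deployed tool's exact geometry is unpublished):
seven equal sectors laid out clockwise from 12 o'clock in mapping order;
each sector is filled with its area band color and carries a color-coded
annulus at its inner edge showing the band of the lowest member score.
"""

from __future__ import annotations

import io as _io
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .cohort import CohortSummary, extent_frequency_table
from .compass import CompassSnapshot
from .errors import ConfigError

DEFAULT_PALETTE = {
    "red": "#D62728",
    "orange": "#FF7F0E",
    "green": "#2CA02C",
    "missing": "#BFBFBF",
}


class RenderSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    format: str = "svg"  # 'svg' | 'png'
    width: int = 600
    height: int = 600
    palette: dict[str, str] = DEFAULT_PALETTE
    #: width of the inner min-value marker band, as a fraction of the radius
    marker_width_frac: float = 0.12
    legend: bool = True

    @model_validator(mode="after")
    def _check(self):
        missing_bands = {"red", "orange", "green", "missing"} - set(self.palette)
        if missing_bands:
            raise ConfigError(
                f"palette must cover bands {sorted(missing_bands)}"
            )
        if not 0 < self.marker_width_frac < 0.5:
            raise ConfigError(
                f"marker_width_frac must be in (0, 0.5), got {self.marker_width_frac}"
            )
        if self.format not in ("svg", "png"):
            raise ConfigError(f"unknown format {self.format!r}")
        return self

    def color(self, band: Optional[str]) -> str:
        key = band if band is not None else "missing"
        if key not in self.palette:
            raise ConfigError(f"band {key!r} not in palette")
        return self.palette[key]


def _fmt(v: float) -> str:
    return f"{v:.3f}"


def _polar(cx: float, cy: float, r: float, angle_deg: float) -> tuple[float, float]:
    # angle measured clockwise from 12 o'clock
    rad = math.radians(angle_deg)
    return cx + r * math.sin(rad), cy - r * math.cos(rad)


def _annular_wedge_path(
    cx: float, cy: float, r_in: float, r_out: float, a0: float, a1: float
) -> str:
    x0o, y0o = _polar(cx, cy, r_out, a0)
    x1o, y1o = _polar(cx, cy, r_out, a1)
    x1i, y1i = _polar(cx, cy, r_in, a1)
    x0i, y0i = _polar(cx, cy, r_in, a0)
    large = 1 if (a1 - a0) > 180 else 0
    return (
        f"M {_fmt(x0o)} {_fmt(y0o)} "
        f"A {_fmt(r_out)} {_fmt(r_out)} 0 {large} 1 {_fmt(x1o)} {_fmt(y1o)} "
        f"L {_fmt(x1i)} {_fmt(y1i)} "
        f"A {_fmt(r_in)} {_fmt(r_in)} 0 {large} 0 {_fmt(x0i)} {_fmt(y0i)} Z"
    )


def _svg_doc(width: int, height: int, body: list[str]) -> str:
    head = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">'
    )
    return "\n".join([head, *body, "</svg>"]) + "\n"


def _legend(spec: RenderSpec, x: float, y: float) -> list[str]:
    parts = ['<g id="legend">']
    for i, key in enumerate(("red", "orange", "green", "missing")):
        yy = y + 22 * i
        parts.append(
            f'<rect id="legend-{key}" x="{_fmt(x)}" y="{_fmt(yy)}" '
            f'width="16" height="16" fill="{spec.color(key)}"/>'
        )
        parts.append(
            f'<text x="{_fmt(x + 22)}" y="{_fmt(yy + 13)}" '
            f'font-size="12" font-family="sans-serif">{key}</text>'
        )
    parts.append("</g>")
    return parts


def render_compass(snapshot: CompassSnapshot, spec: RenderSpec = RenderSpec()):
    """Render the seven-sector compass; returns SVG text or PNG bytes."""
    if spec.format == "png":
        return _png_compass(snapshot, spec)
    cx, cy = spec.width / 2.0, spec.height / 2.0
    r_out = 0.40 * min(spec.width, spec.height)
    r_hub = 0.12 * r_out
    w_marker = spec.marker_width_frac * r_out
    step = 360.0 / len(snapshot.areas)
    body: list[str] = [
        f'<g id="compass" data-respondent="{snapshot.respondent_id}" '
        f'data-timepoint="{snapshot.timepoint}">'
    ]
    for i, area in enumerate(snapshot.areas):
        a0, a1 = i * step, (i + 1) * step
        body.append(
            f'<path id="sector-{area.area_id}" '
            f'd="{_annular_wedge_path(cx, cy, r_hub + w_marker, r_out, a0, a1)}" '
            f'fill="{spec.color(area.area_band)}" stroke="#FFFFFF" '
            f'stroke-width="2" data-score="'
            f'{"" if area.area_score is None else _fmt(area.area_score)}"/>'
        )
        body.append(
            f'<path id="minband-{area.area_id}" '
            f'd="{_annular_wedge_path(cx, cy, r_hub, r_hub + w_marker, a0, a1)}" '
            f'fill="{spec.color(area.min_band)}" stroke="#FFFFFF" '
            f'stroke-width="1" data-score="'
            f'{"" if area.min_score is None else _fmt(area.min_score)}"/>'
        )
        lx, ly = _polar(cx, cy, r_out + 14, (a0 + a1) / 2.0)
        anchor = "middle"
        body.append(
            f'<text id="label-{area.area_id}" x="{_fmt(lx)}" y="{_fmt(ly)}" '
            f'font-size="13" font-family="sans-serif" text-anchor="{anchor}">'
            f"{area.name or area.area_id}</text>"
        )
    body.append("</g>")
    if spec.legend:
        body.extend(_legend(spec, 10, 10))
    return _svg_doc(spec.width, spec.height, body)


def render_domain_bars(
    snapshot: CompassSnapshot, area_id: str, spec: RenderSpec = RenderSpec()
):
    """Bar chart of one area's member domains on a fixed 0-100 axis."""
    area = snapshot.area(area_id)  # KeyError for unknown area
    if spec.format == "png":
        return _png_bars(snapshot, area_id, spec)
    margin, axis_h = 40, spec.height - 80
    n = len(area.members)
    slot = (spec.width - 2 * margin) / max(n, 1)
    bar_w = 0.6 * slot
    base_y = margin + axis_h
    body = [f'<g id="bars-{area_id}">']
    body.append(
        f'<line id="axis" x1="{_fmt(margin)}" y1="{_fmt(base_y)}" '
        f'x2="{_fmt(spec.width - margin)}" y2="{_fmt(base_y)}" stroke="#333333"/>'
    )
    for i, score in enumerate(area.members):
        x = margin + i * slot + (slot - bar_w) / 2.0
        key = f"{score.instrument_id}-{score.domain_id}"
        if score.missing:
            body.append(
                f'<rect id="bar-{key}" x="{_fmt(x)}" y="{_fmt(margin)}" '
                f'width="{_fmt(bar_w)}" height="{_fmt(axis_h)}" '
                f'fill="{spec.color(None)}" fill-opacity="0.4" '
                f'data-missing="true"/>'
            )
        else:
            from .compass import band as _band

            h = axis_h * score.normalized / 100.0
            body.append(
                f'<rect id="bar-{key}" x="{_fmt(x)}" y="{_fmt(base_y - h)}" '
                f'width="{_fmt(bar_w)}" height="{_fmt(h)}" '
                f'fill="{spec.color(_band(score.normalized))}" '
                f'data-score="{_fmt(score.normalized)}"/>'
            )
        body.append(
            f'<text x="{_fmt(x + bar_w / 2)}" y="{_fmt(base_y + 16)}" '
            f'font-size="11" font-family="sans-serif" text-anchor="middle">'
            f"{score.domain_id}</text>"
        )
    body.append("</g>")
    if spec.legend:
        body.extend(_legend(spec, 10, 10))
    return _svg_doc(spec.width, spec.height, body)


def render_group_chart(summary: CohortSummary, spec: RenderSpec = RenderSpec()):
    """Cohort extent/frequency chart: one row per domain, worst median first.

    Bar length encodes the median on a 0-100 axis with 25-75% whiskers;
    the annotation at the row end prints "impaired/n, percent%".
    """
    rows = extent_frequency_table(summary)
    if spec.format == "png":
        return _png_group(summary, spec)
    left, right, top = 150, 110, 30
    row_h = max(18, (spec.height - 2 * top) // max(len(rows), 1))
    axis_w = spec.width - left - right

    def sx(v: float) -> float:
        return left + axis_w * v / 100.0

    body = ['<g id="group-chart">']
    for i, d in enumerate(rows):
        y = top + i * row_h
        key = f"{d.instrument_id}-{d.domain_id}"
        body.append(
            f'<text id="rowlabel-{key}" x="{_fmt(left - 8)}" '
            f'y="{_fmt(y + row_h * 0.65)}" font-size="11" '
            f'font-family="sans-serif" text-anchor="end">'
            f"{d.instrument_id}:{d.domain_id}</text>"
        )
        if d.median is not None:
            from .compass import band as _band

            body.append(
                f'<rect id="row-{key}" x="{_fmt(left)}" '
                f'y="{_fmt(y + row_h * 0.2)}" width="{_fmt(sx(d.median) - left)}" '
                f'height="{_fmt(row_h * 0.6)}" fill="{spec.color(_band(d.median))}" '
                f'data-median="{_fmt(d.median)}"/>'
            )
            yy = y + row_h * 0.5
            body.append(
                f'<line id="iqr-{key}" x1="{_fmt(sx(d.q25))}" y1="{_fmt(yy)}" '
                f'x2="{_fmt(sx(d.q75))}" y2="{_fmt(yy)}" stroke="#333333" '
                f'stroke-width="2" data-q25="{_fmt(d.q25)}" data-q75="{_fmt(d.q75)}"/>'
            )
            annotation = f"{d.impaired_count}/{d.n_scored}, {d.percent}%"
        else:
            body.append(
                f'<rect id="row-{key}" x="{_fmt(left)}" y="{_fmt(y + row_h * 0.2)}" '
                f'width="{_fmt(axis_w)}" height="{_fmt(row_h * 0.6)}" '
                f'fill="{spec.color(None)}" fill-opacity="0.4" data-missing="true"/>'
            )
            annotation = "n/a"
        body.append(
            f'<text id="freq-{key}" x="{_fmt(spec.width - right + 8)}" '
            f'y="{_fmt(y + row_h * 0.65)}" font-size="11" '
            f'font-family="sans-serif">{annotation}</text>'
        )
    body.append("</g>")
    return _svg_doc(spec.width, spec.height, body)


# ---------------------------------------------------------------------------
# PNG (derived raster; geometry mirrors the SVG, not pixel-matched)


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def _png_compass(snapshot: CompassSnapshot, spec: RenderSpec) -> bytes:
    plt = _mpl()
    from matplotlib.patches import Wedge

    fig, ax = plt.subplots(figsize=(spec.width / 100, spec.height / 100))
    step = 360.0 / len(snapshot.areas)
    r_out, r_hub = 1.0, 0.12
    w_marker = spec.marker_width_frac * r_out
    for i, area in enumerate(snapshot.areas):
        # matplotlib angles are CCW from 3 o'clock; ours CW from 12 o'clock
        t1 = 90.0 - (i + 1) * step
        t2 = 90.0 - i * step
        ax.add_patch(
            Wedge((0, 0), r_out, t1, t2, width=r_out - r_hub - w_marker,
                  facecolor=spec.color(area.area_band), edgecolor="white")
        )
        ax.add_patch(
            Wedge((0, 0), r_hub + w_marker, t1, t2, width=w_marker,
                  facecolor=spec.color(area.min_band), edgecolor="white")
        )
        mid = math.radians(90.0 - (i + 0.5) * step)
        ax.text(1.12 * math.cos(mid), 1.12 * math.sin(mid),
                area.name or area.area_id, ha="center", va="center", fontsize=9)
    ax.set_xlim(-1.4, 1.4)
    ax.set_ylim(-1.4, 1.4)
    ax.set_aspect("equal")
    ax.axis("off")
    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return buf.getvalue()


def _png_bars(snapshot: CompassSnapshot, area_id: str, spec: RenderSpec) -> bytes:
    plt = _mpl()
    from .compass import band as _band

    area = snapshot.area(area_id)
    fig, ax = plt.subplots(figsize=(spec.width / 100, spec.height / 100))
    labels = [s.domain_id for s in area.members]
    heights = [0 if s.missing else s.normalized for s in area.members]
    colors = [
        spec.color(None) if s.missing else spec.color(_band(s.normalized))
        for s in area.members
    ]
    ax.bar(labels, heights, color=colors)
    ax.set_ylim(0, 100)
    ax.set_ylabel("score (100 = best)")
    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return buf.getvalue()


def _png_group(summary: CohortSummary, spec: RenderSpec) -> bytes:
    plt = _mpl()
    from .compass import band as _band

    rows = [d for d in extent_frequency_table(summary) if d.median is not None]
    fig, ax = plt.subplots(figsize=(spec.width / 100, spec.height / 100))
    labels = [f"{d.instrument_id}:{d.domain_id}" for d in rows]
    meds = [d.median for d in rows]
    colors = [spec.color(_band(d.median)) for d in rows]
    y = range(len(rows))
    ax.barh(list(y), meds, color=colors)
    for i, d in enumerate(rows):
        ax.plot([d.q25, d.q75], [i, i], color="#333333", lw=2)
        ax.text(101, i, f"{d.impaired_count}/{d.n_scored}, {d.percent}%",
                va="center", fontsize=8)
    ax.set_yticks(list(y), labels, fontsize=8)
    ax.invert_yaxis()
    ax.set_xlim(0, 118)
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return buf.getvalue()
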