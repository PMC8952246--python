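"""Replicate aggregation into condition profiles and profile plotting.

Samples sharing the same group-factor levels and x-axis level form one bin;
the bin's replicates are summarized by their mean and an error-bar spread
(sample standard deviation by default, standard error optionally).  Profiles
are rendered as grouped bars, per-group line panels, or differently colored
curves stacked into a single panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gxp._svg import SvgDoc, fmt, palette_color
from gxp.errors import ValidationError
from gxp.tables_io import ExpressionMatrix, _atomic_write_text

MODES = ("bars", "lines", "stacked_lines")
SPREAD_ESTIMATORS = ("sd", "sem")


@dataclass(frozen=True)
class ProfilePoint:
    """Aggregated replicates of one entity in one (group, x) bin."""

    x_value: str
    group_values: tuple[str, ...]
    mean: float
    spread: float
    n: int
    replicate_values: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "x_value": self.x_value,
            "group_values": list(self.group_values),
            "mean": self.mean,
            "spread": self.spread,
            "n": self.n,
            "replicate_values": list(self.replicate_values),
        }


@dataclass
class ProfileSeries:
    """One plotted curve / bar group: an entity within one group combination."""

    entity_id: str
    group_values: tuple[str, ...]
    points: list[ProfilePoint]
    panel: str = ""
    color: str = "#000000"

    def to_dict(self) -> dict:
        return {
            "entity_id": self.entity_id,
            "group_values": list(self.group_values),
            "points": [p.to_dict() for p in self.points],
            "panel": self.panel,
            "color": self.color,
        }


@dataclass
class PlotSpec:
    mode: str
    series: list[ProfileSeries]
    x_order: list[str]
    unit: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def panels(self) -> list[str]:
        seen: list[str] = []
        for s in self.series:
            if s.panel not in seen:
                seen.append(s.panel)
        return seen

    def to_dict(self) -> dict:
        return {
            "kind": "profile_plot",
            "mode": self.mode,
            "series": [s.to_dict() for s in self.series],
            "x_order": list(self.x_order),
            "unit": self.unit,
            "warnings": list(self.warnings),
        }


def _spread(values: np.ndarray, estimator: str) -> float:
    if len(values) < 2:
        return 0.0
    sd = float(np.std(values, ddof=1))
    if estimator == "sd":
        return sd
    if estimator == "sem":
        return sd / math.sqrt(len(values))
    raise ValidationError(f"unknown spread estimator {estimator!r}")


def aggregate_replicates(
    expr: ExpressionMatrix,
    entity_ids: list[str],
    x_order: list[str] | None = None,
    spread_estimator: str = "sd",
) -> dict[str, list[ProfilePoint]]:
    """Aggregate replicate columns into one ProfilePoint per (group, x) bin.

    Bin order: group combinations in first-appearance column order, and
    within each combination the supplied ``x_order`` (header order when
    omitted).
    """
    if spread_estimator not in SPREAD_ESTIMATORS:
        raise ValidationError(f"unknown spread estimator {spread_estimator!r}")
    header_x = expr.x_order()
    if x_order is None:
        x_order = header_x
    else:
        missing = [x for x in header_x if x not in x_order]
        if missing:
            raise ValidationError(f"x_order lacks levels present in the data: {missing}")

    group_order: list[tuple[str, ...]] = []
    bins: dict[tuple[tuple[str, ...], str], list[int]] = {}
    for j, s in enumerate(expr.samples):
        if s.group_values not in group_order:
            group_order.append(s.group_values)
        bins.setdefault((s.group_values, s.x_value), []).append(j)

    out: dict[str, list[ProfilePoint]] = {}
    for eid in entity_ids:
        row = expr.row(eid)  # raises on unknown id
        points = []
        for g in group_order:
            for x in x_order:
                cols = bins.get((g, x))
                if not cols:
                    continue
                vals = row[cols]
                points.append(
                    ProfilePoint(
                        x_value=x,
                        group_values=g,
                        mean=float(np.mean(vals)),
                        spread=_spread(vals, spread_estimator),
                        n=len(vals),
                        replicate_values=tuple(float(v) for v in vals),
                    )
                )
        out[eid] = points
    return out


def build_plot_spec(
    profiles: dict[str, list[ProfilePoint]],
    mode: str,
    x_order: list[str] | None = None,
    unit: str = "",
) -> PlotSpec:
    """Assign series to panels and colors.

    bars/lines with more than one group combination → one panel per
    combination, colors distinguish entities; stacked_lines → one shared
    panel, colors distinguish (entity, group) curves.  stacked_lines with
    zero group factors degrades to lines with a warning.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown plot mode {mode!r}; choose one of {MODES}")
    if not profiles or all(not pts for pts in profiles.values()):
        raise ValidationError("no profiles to plot")

    group_order: list[tuple[str, ...]] = []
    xs: list[str] = []
    for pts in profiles.values():
        for p in pts:
            if p.group_values not in group_order:
                group_order.append(p.group_values)
            if p.x_value not in xs:
                xs.append(p.x_value)
    if x_order is None:
        x_order = xs

    warnings_out: list[str] = []
    if mode == "stacked_lines" and group_order == [()]:
        warnings_out.append("stacked_lines with no group factor: falling back to lines")
        mode = "lines"

    entity_order = list(profiles)
    series: list[ProfileSeries] = []
    for eid in entity_order:
        by_group: dict[tuple[str, ...], list[ProfilePoint]] = {}
        for p in profiles[eid]:
            by_group.setdefault(p.group_values, []).append(p)
        for g, pts in by_group.items():
            pts = sorted(pts, key=lambda p: x_order.index(p.x_value))
            series.append(ProfileSeries(entity_id=eid, group_values=g, points=pts))

    if mode == "stacked_lines":
        for i, s in enumerate(series):
            s.panel = "all"
            s.color = palette_color(i)
    else:
        single_entity = len(entity_order) == 1
        for s in series:
            s.panel = " / ".join(s.group_values) if s.group_values else "all"
            if single_entity:
                s.color = palette_color(group_order.index(s.group_values))
            else:
                s.color = palette_color(entity_order.index(s.entity_id))
    return PlotSpec(mode=mode, series=series, x_order=x_order, unit=unit, warnings=warnings_out)


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

_PANEL_W = 320.0
_PANEL_H = 260.0
_MARGIN = 52.0
_GAP = 30.0


def _y_scale(spec: PlotSpec) -> tuple[float, float]:
    lo, hi = math.inf, -math.inf
    for s in spec.series:
        for p in s.points:
            lo = min(lo, p.mean - p.spread)
            hi = max(hi, p.mean + p.spread)
    if spec.mode == "bars":
        lo = min(lo, 0.0)
    if lo == hi:
        hi = lo + 1.0
    pad = 0.05 * (hi - lo)
    return lo - pad, hi + pad


def render_profile_svg(spec: PlotSpec, path: str | None = None) -> str:
    """Render a PlotSpec as a static SVG document.

    Returns the SVG text; writes it to ``path`` when given.
    """
    panels = spec.panels
    n_panels = len(panels)
    width = _MARGIN * 2 + n_panels * _PANEL_W + (n_panels - 1) * _GAP
    height = _PANEL_H + 2 * _MARGIN + 30
    doc = SvgDoc(width, height)
    ylo, yhi = _y_scale(spec)

    def ypix(v: float) -> float:
        return _MARGIN + _PANEL_H * (1 - (v - ylo) / (yhi - ylo))

    for pi, panel in enumerate(panels):
        x0 = _MARGIN + pi * (_PANEL_W + _GAP)
        doc.rect(x0, _MARGIN, _PANEL_W, _PANEL_H, fill="none", stroke="#333333")
        doc.text(
            x0 + _PANEL_W / 2,
            _MARGIN - 8,
            panel,
            text_anchor="middle",
            font_size=12,
            class_="panel-title",
        )
        panel_series = [s for s in spec.series if s.panel == panel]
        nx = len(spec.x_order)
        slot = _PANEL_W / max(nx, 1)
        for xi, xv in enumerate(spec.x_order):
            cx = x0 + slot * (xi + 0.5)
            doc.line(cx, _MARGIN + _PANEL_H, cx, _MARGIN + _PANEL_H + 4, stroke="#333333")
            doc.text(
                cx,
                _MARGIN + _PANEL_H + 16,
                xv,
                text_anchor="middle",
                font_size=10,
                class_="x-tick-label",
            )
        if spec.mode == "bars":
            bw = slot / (len(panel_series) + 1)
            for si, s in enumerate(panel_series):
                for p in s.points:
                    xi = spec.x_order.index(p.x_value)
                    cx = x0 + slot * (xi + 0.5) + (si - (len(panel_series) - 1) / 2) * bw
                    top = ypix(max(p.mean, 0.0))
                    base = ypix(min(p.mean, 0.0))
                    doc.rect(
                        cx - bw / 2,
                        top,
                        bw,
                        max(base - top, 0.0),
                        fill=s.color,
                        class_="bar",
                        data_entity=s.entity_id,
                    )
                    if p.n > 1:
                        _error_bar(doc, cx, ypix(p.mean - p.spread), ypix(p.mean + p.spread))
        else:
            for s in panel_series:
                pts = [
                    (x0 + slot * (spec.x_order.index(p.x_value) + 0.5), ypix(p.mean))
                    for p in s.points
                ]
                doc.polyline(pts, stroke=s.color, stroke_width=1.5, class_="series-line",
                             data_entity=s.entity_id)
                for p, (cx, cy) in zip(s.points, pts):
                    doc.circle(cx, cy, 2.5, fill=s.color)
                    if p.n > 1:
                        _error_bar(doc, cx, ypix(p.mean - p.spread), ypix(p.mean + p.spread))
        # y axis ticks: lo / mid / hi
        for v in (ylo, (ylo + yhi) / 2, yhi):
            doc.text(x0 - 6, ypix(v) + 3, f"{v:.3g}", text_anchor="end", font_size=9,
                     class_="y-tick-label")
    ylabel = f"expression [{spec.unit}]" if spec.unit else "expression"
    doc.text(14, _MARGIN + _PANEL_H / 2, ylabel, font_size=11, class_="y-axis-label",
             transform=f"rotate(-90 14 {fmt(_MARGIN + _PANEL_H / 2)})", text_anchor="middle")
    svg = doc.tostring()
    if path is not None:
        _atomic_write_text(path, svg)
    return svg


def _error_bar(doc: SvgDoc, cx: float, y_lo_pix: float, y_hi_pix: float) -> None:
    doc.line(cx, y_lo_pix, cx, y_hi_pix, stroke="#000000", class_="error-bar")
    doc.line(cx - 3, y_lo_pix, cx + 3, y_lo_pix, stroke="#000000", class_="error-bar-cap")
    doc.line(cx - 3, y_hi_pix, cx + 3, y_hi_pix, stroke="#000000", class_="error-bar-cap")
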