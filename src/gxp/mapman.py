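"""Pathway-sketch rendering.

A sketch layout names diagram areas, each responsible for a dot-separated
numeric bin prefix (e.g. ``"1.1"``).  Genes are placed into the most
specific area whose prefix matches one of their bins component-wise, drawn
as small colored squares on a grid, and colored by a numeric value under a
divergent (blue-white-red, symmetric around zero) or sequential (white-red,
quartile-bounded) scale.  A summary strip reports the five-number
distribution of the plotted values.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from gxp._svg import SvgDoc, fmt
from gxp.errors import ValidationError
from gxp.profiles import aggregate_replicates
from gxp.tables_io import ExpressionMatrix, InfoTable, _atomic_write_text

LAYOUT_SCHEMA_VERSION = "1.0"

_BIN_RE = re.compile(r"^\d+(\.\d+)*$")


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


@dataclass
class SketchArea:
    area_id: str
    bin_prefix: str  # dot-separated numeric path, e.g. "1.1.1"
    x: float
    y: float
    grid_width: int
    label: str = ""

    def __post_init__(self) -> None:
        if not _BIN_RE.match(self.bin_prefix):
            raise ValidationError(
                f"area {self.area_id!r}: malformed bin prefix {self.bin_prefix!r}"
            )
        if self.grid_width < 1:
            raise ValidationError(f"area {self.area_id!r}: grid width must be >= 1")


@dataclass
class SketchLayout:
    name: str
    canvas_width: float
    canvas_height: float
    areas: list[SketchArea] = field(default_factory=list)

    def __post_init__(self) -> None:
        prefixes = [a.bin_prefix for a in self.areas]
        if len(set(prefixes)) != len(prefixes):
            raise ValidationError("area bin prefixes must be unique")
        for a in self.areas:
            if not (0 <= a.x <= self.canvas_width and 0 <= a.y <= self.canvas_height):
                raise ValidationError(f"area {a.area_id!r} anchored outside the canvas")

    def to_dict(self) -> dict:
        return {
            "schema_version": LAYOUT_SCHEMA_VERSION,
            "name": self.name,
            "canvas": {"width": self.canvas_width, "height": self.canvas_height},
            "areas": [
                {
                    "id": a.area_id,
                    "bin_prefix": a.bin_prefix,
                    "x": a.x,
                    "y": a.y,
                    "grid_width": a.grid_width,
                    "label": a.label,
                }
                for a in self.areas
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SketchLayout":
        version = d.get("schema_version")
        if version != LAYOUT_SCHEMA_VERSION:
            raise ValidationError(
                f"unsupported layout schema version {version!r} "
                f"(this build reads {LAYOUT_SCHEMA_VERSION!r})"
            )
        return cls(
            name=d["name"],
            canvas_width=float(d["canvas"]["width"]),
            canvas_height=float(d["canvas"]["height"]),
            areas=[
                SketchArea(
                    area_id=a["id"],
                    bin_prefix=a["bin_prefix"],
                    x=float(a["x"]),
                    y=float(a["y"]),
                    grid_width=int(a["grid_width"]),
                    label=a.get("label", ""),
                )
                for a in d["areas"]
            ],
        )

    @classmethod
    def from_json(cls, path: str) -> "SketchLayout":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str) -> None:
        _atomic_write_text(path, json.dumps(self.to_dict(), indent=1) + "\n")


def bin_matches_prefix(bin_id: str, prefix: str) -> bool:
    """Component-wise prefix test: ``"1.1.1.1.1"`` matches ``"1.1"`` but
    ``"1.10"`` does not."""
    bt = bin_id.split(".")
    pt = prefix.split(".")
    return len(bt) >= len(pt) and bt[: len(pt)] == pt


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


@dataclass
class Placement:
    gene_id: str
    area_id: str
    grid_col: int
    grid_row: int
    value: float | None = None
    color: str = "#cccccc"
    description: str = ""


@dataclass
class Unassigned:
    gene_id: str
    reason: str


def assign_genes_to_areas(
    bins: dict[str, list[str]], layout: SketchLayout
) -> tuple[list[Placement], list[Unassigned]]:
    """Place each gene into the most specific matching area.

    A gene joins an area when one of its bins equals the area's prefix or
    extends it by further dot components; among multiple candidates the
    longest prefix wins (layout order breaks exact-length ties).  Genes
    without a match, or with only malformed bins, are reported unassigned.
    Grid cells fill row-major in gene input order.
    """
    fill: dict[str, int] = {a.area_id: 0 for a in layout.areas}
    placements: list[Placement] = []
    unassigned: list[Unassigned] = []
    for gene, gene_bins in bins.items():
        malformed = [b for b in gene_bins if not _BIN_RE.match(b)]
        valid = [b for b in gene_bins if _BIN_RE.match(b)]
        best: SketchArea | None = None
        for area in layout.areas:
            if any(bin_matches_prefix(b, area.bin_prefix) for b in valid):
                if best is None or len(area.bin_prefix.split(".")) > len(
                    best.bin_prefix.split(".")
                ):
                    best = area
        if best is None:
            if malformed and not valid:
                reason = f"malformed bin identifier(s): {malformed}"
            else:
                reason = "no area matches any bin"
            unassigned.append(Unassigned(gene_id=gene, reason=reason))
            continue
        slot = fill[best.area_id]
        fill[best.area_id] += 1
        placements.append(
            Placement(
                gene_id=gene,
                area_id=best.area_id,
                grid_col=slot % best.grid_width,
                grid_row=slot // best.grid_width,
            )
        )
    return placements, unassigned


# ---------------------------------------------------------------------------
# color scale
# ---------------------------------------------------------------------------

_BLUE = (33, 102, 172)
_WHITE = (255, 255, 255)
_RED = (178, 24, 43)


def _lerp(c1, c2, t: float) -> str:
    r = round(c1[0] + (c2[0] - c1[0]) * t)
    g = round(c1[1] + (c2[1] - c1[1]) * t)
    b = round(c1[2] + (c2[2] - c1[2]) * t)
    return f"#{r:02x}{g:02x}{b:02x}"


@dataclass
class ColorScale:
    mode: str  # divergent | sequential
    lo: float
    hi: float

    def position(self, value: float) -> float:
        """Monotone map of a value onto [0, 1], clamped at the domain ends."""
        if self.hi == self.lo:
            return 0.5
        return min(max((value - self.lo) / (self.hi - self.lo), 0.0), 1.0)

    def color(self, value: float) -> str:
        t = self.position(value)
        if self.mode == "divergent":
            if t < 0.5:
                return _lerp(_BLUE, _WHITE, t / 0.5)
            return _lerp(_WHITE, _RED, (t - 0.5) / 0.5)
        return _lerp(_WHITE, _RED, t)


def build_color_scale(
    values: list[float],
    mode: str = "divergent",
    limit: float | None = None,
    sequential_from: str = "zero",
) -> ColorScale:
    """Construct a scale over the plotted values.

    divergent: domain [-limit, +limit] (limit required, > 0).
    sequential: domain [0, Q3] or [Q1, Q3] depending on ``sequential_from``;
    quartiles use linear interpolation between order statistics.
    """
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        raise ValidationError("no finite values to build a color scale from")
    if mode == "divergent":
        if limit is None or limit <= 0:
            raise ValidationError("divergent scale needs a positive limit")
        return ColorScale(mode="divergent", lo=-limit, hi=limit)
    if mode == "sequential":
        q1, q3 = (float(q) for q in np.quantile(vals, [0.25, 0.75]))
        if sequential_from == "zero":
            lo = 0.0
        elif sequential_from == "q1":
            lo = q1
        else:
            raise ValidationError(f"sequential_from must be 'zero' or 'q1', got {sequential_from!r}")
        return ColorScale(mode="sequential", lo=lo, hi=q3)
    raise ValidationError(f"unknown color-scale mode {mode!r}")


# ---------------------------------------------------------------------------
# values
# ---------------------------------------------------------------------------


def mapman_values(
    source: str,
    expr: ExpressionMatrix | None = None,
    info: InfoTable | None = None,
    column: str | None = None,
    x_value: str | None = None,
    group_values: tuple[str, ...] | None = None,
) -> tuple[dict[str, float], list[str]]:
    """Gene -> numeric value mapping for sketch coloring.

    ``source='bin_mean'`` averages the replicates of one experimental
    condition (``x_value`` plus optional ``group_values``);
    ``source='info_column'`` reads a numeric annotation column.  Returns the
    mapping and the list of genes excluded for missing values.
    """
    if source == "info_column":
        if info is None or column is None:
            raise ValidationError("info_column source needs an info table and column name")
        col = info.column(column)
        if col.kind != "numeric":
            raise ValidationError(f"column {column!r} is not numeric")
        values = {}
        excluded = []
        for eid, cell in zip(info.entity_ids, col.cells):
            if cell is None:
                excluded.append(eid)
            else:
                values[eid] = float(cell)
        return values, excluded
    if source == "bin_mean":
        if expr is None or x_value is None:
            raise ValidationError("bin_mean source needs an expression matrix and x_value")
        profiles = aggregate_replicates(expr, expr.entity_ids)
        values = {}
        excluded = []
        for eid, points in profiles.items():
            match = [
                p
                for p in points
                if p.x_value == x_value
                and (group_values is None or p.group_values == tuple(group_values))
            ]
            if not match:
                excluded.append(eid)
            else:
                values[eid] = float(np.mean([p.mean for p in match]))
        return values, excluded
    raise ValidationError(f"unknown value source {source!r}")


# ---------------------------------------------------------------------------
# plot assembly + rendering
# ---------------------------------------------------------------------------


@dataclass
class MapmanPlot:
    layout: SketchLayout
    placements: list[Placement]
    unassigned: list[Unassigned]
    excluded: list[str]  # genes dropped for missing values
    scale: ColorScale
    summary: dict[str, float]  # min, q1, median, q3, max
    box_size: int = 8


def build_mapman_plot(
    bins: dict[str, list[str]],
    values: dict[str, float],
    layout: SketchLayout,
    scale_mode: str = "divergent",
    limit: float | None = None,
    sequential_from: str = "zero",
    box_size: int = 8,
    descriptions: dict[str, str] | None = None,
) -> MapmanPlot:
    """Assemble a complete sketch: placement, coloring and summary.

    Genes lacking a value are excluded (and reported) before placement, so
    every input gene ends up placed exactly once, unassigned, or excluded.
    """
    if box_size < 1:
        raise ValidationError("box size must be a positive integer")
    with_value = {g: bl for g, bl in bins.items() if g in values}
    excluded = [g for g in bins if g not in values]
    placements, unassigned = assign_genes_to_areas(with_value, layout)
    plotted = [values[p.gene_id] for p in placements]
    if not plotted:
        raise ValidationError("no genes could be placed with values")
    scale = build_color_scale(plotted, scale_mode, limit, sequential_from)
    descriptions = descriptions or {}
    for p in placements:
        p.value = values[p.gene_id]
        p.color = scale.color(p.value)
        p.description = descriptions.get(p.gene_id, "")
    qs = np.quantile(plotted, [0.0, 0.25, 0.5, 0.75, 1.0])
    summary = {
        "min": float(qs[0]),
        "q1": float(qs[1]),
        "median": float(qs[2]),
        "q3": float(qs[3]),
        "max": float(qs[4]),
    }
    return MapmanPlot(
        layout=layout,
        placements=placements,
        unassigned=unassigned,
        excluded=excluded,
        scale=scale,
        summary=summary,
        box_size=box_size,
    )


def render_mapman_svg(plot: MapmanPlot, path: str | None = None) -> str:
    """Render the sketch: one square per placed gene, area labels, a legend
    gradient in the top-right corner, and a summary strip."""
    layout = plot.layout
    strip_h = 28.0
    doc = SvgDoc(layout.canvas_width, layout.canvas_height + strip_h)
    bs = float(plot.box_size)
    area_by_id = {a.area_id: a for a in layout.areas}
    for a in layout.areas:
        doc.text(a.x, a.y - 4, a.label or a.area_id, font_size=10, class_="area-label")
    for p in plot.placements:
        a = area_by_id[p.area_id]
        doc.rect(
            a.x + p.grid_col * (bs + 1),
            a.y + p.grid_row * (bs + 1),
            bs,
            bs,
            fill=p.color,
            stroke="#555555",
            stroke_width=0.4,
            class_="gene-box",
            data_gene_id=p.gene_id,
            data_value=f"{p.value:.6g}",
            data_description=p.description,
        )
    # legend: horizontal gradient, top-right
    lw, lh = 120.0, 10.0
    lx, ly = layout.canvas_width - lw - 12, 12.0
    steps = 24
    for k in range(steps):
        v = plot.scale.lo + (plot.scale.hi - plot.scale.lo) * (k + 0.5) / steps
        doc.rect(lx + k * lw / steps, ly, lw / steps, lh, fill=plot.scale.color(v),
                 class_="legend-cell")
    doc.text(lx, ly + lh + 11, f"{plot.scale.lo:.3g}", font_size=9, class_="legend-label")
    doc.text(lx + lw, ly + lh + 11, f"{plot.scale.hi:.3g}", font_size=9,
             text_anchor="end", class_="legend-label")
    s = plot.summary
    doc.text(
        10,
        layout.canvas_height + strip_h - 10,
        (
            f"n={len(plot.placements)}  min={s['min']:.3g}  Q1={s['q1']:.3g}  "
            f"median={s['median']:.3g}  Q3={s['q3']:.3g}  max={s['max']:.3g}  "
            f"unassigned={len(plot.unassigned)}  excluded={len(plot.excluded)}"
        ),
        font_size=10,
        class_="summary-strip",
    )
    svg = doc.tostring()
    if path is not None:
        _atomic_write_text(path, svg)
    return svg
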