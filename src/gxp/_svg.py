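"""Minimal deterministic SVG 1.1 document builder.

Hand-rolled on purpose: output must be byte-stable across runs and
platforms so golden-file tests stay meaningful.  Coordinates are formatted
with a fixed precision.
"""

from __future__ import annotations

from xml.sax.saxutils import escape, quoteattr


def fmt(v: float) -> str:
    s = f"{v:.2f}"
    return "0.00" if s == "-0.00" else s


class SvgDoc:
    def __init__(self, width: float, height: float):
        self.width = width
        self.height = height
        self._parts: list[str] = []
        self._defs: list[str] = []

    def _attrs(self, attrs: dict) -> str:
        out = []
        for k, v in attrs.items():
            if v is None:
                continue
            key = k.rstrip("_").replace("_", "-")
            out.append(f" {key}={quoteattr(str(v))}")
        return "".join(out)

    def add_def(self, raw: str) -> None:
        self._defs.append(raw)

    def rect(self, x, y, w, h, **attrs) -> None:
        self._parts.append(
            f'<rect x="{fmt(x)}" y="{fmt(y)}" width="{fmt(w)}" '
            f'height="{fmt(h)}"{self._attrs(attrs)}/>'
        )

    def line(self, x1, y1, x2, y2, **attrs) -> None:
        self._parts.append(
            f'<line x1="{fmt(x1)}" y1="{fmt(y1)}" x2="{fmt(x2)}" '
            f'y2="{fmt(y2)}"{self._attrs(attrs)}/>'
        )

    def circle(self, cx, cy, r, **attrs) -> None:
        self._parts.append(
            f'<circle cx="{fmt(cx)}" cy="{fmt(cy)}" r="{fmt(r)}"{self._attrs(attrs)}/>'
        )

    def polyline(self, points, **attrs) -> None:
        pts = " ".join(f"{fmt(x)},{fmt(y)}" for x, y in points)
        self._parts.append(f'<polyline points="{pts}" fill="none"{self._attrs(attrs)}/>')

    def text(self, x, y, content, **attrs) -> None:
        self._parts.append(
            f'<text x="{fmt(x)}" y="{fmt(y)}"{self._attrs(attrs)}>'
            f"{escape(str(content))}</text>"
        )

    def tostring(self) -> str:
        defs = f"<defs>{''.join(self._defs)}</defs>" if self._defs else ""
        body = "\n".join(self._parts)
        return (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{fmt(self.width)}" height="{fmt(self.height)}" '
            f'viewBox="0 0 {fmt(self.width)} {fmt(self.height)}">\n'
            f"{defs}\n{body}\n</svg>\n"
        )


# fixed qualitative palette; assignment order = input order
PALETTE = [
    "#1f77b4",
    "#ff7f0e",
    "#2ca02c",
    "#d62728",
    "#9467bd",
    "#8c564b",
    "#e377c2",
    "#7f7f7f",
    "#bcbd22",
    "#17becf",
]


def palette_color(i: int) -> str:
    return PALETTE[i % len(PALETTE)]
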