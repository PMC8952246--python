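"""Likeness analysis: z-transformation, correlation / Euclidean distances,
agglomerative hierarchical clustering with heatmap + dendrogram output, and
PCA with variance-explained scatter output.

Correlation distance follows d = 1 - |c|, so perfect correlation and
perfect anticorrelation are both maximal likeness.  Clustering is a plain
Lance-Williams agglomeration with deterministic tie-breaking: among equally
close cluster pairs the one whose (smallest, then second-smallest) original
leaf indices are lowest merges first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gxp._svg import SvgDoc, palette_color
from gxp.errors import ValidationError
from gxp.tables_io import SampleKey, _atomic_write_text

LINKAGES = ("single", "complete", "average", "ward")


# ---------------------------------------------------------------------------
# z-transformation
# ---------------------------------------------------------------------------


@dataclass
class ZMatrix:
    """Row-wise z-transformed matrix; constant rows are zeroed and flagged."""

    values: np.ndarray
    constant_rows: np.ndarray  # bool per row

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def z_transform(M: np.ndarray) -> ZMatrix:
    """Center and scale every row to mean 0, sample sd 1 (ddof=1).

    Rows with zero variance cannot be scaled; they become all-zero and are
    flagged, keeping the matrix shape stable.
    """
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValidationError("cannot z-transform an empty matrix")
    if not np.all(np.isfinite(M)):
        raise ValidationError("matrix contains non-finite values")
    means = M.mean(axis=1, keepdims=True)
    sds = M.std(axis=1, ddof=1, keepdims=True) if M.shape[1] > 1 else np.zeros_like(means)
    constant = (sds[:, 0] == 0.0)
    safe = np.where(sds == 0.0, 1.0, sds)
    Z = (M - means) / safe
    Z[constant, :] = 0.0
    return ZMatrix(values=Z, constant_rows=constant)


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    labels: list[str]
    metric: str  # correlation | euclidean
    D: np.ndarray
    C: np.ndarray | None = None  # correlation values, present iff metric=correlation

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")

    def to_tsv(self, path: str | None = None) -> str | None:
        lines = ["\t".join([""] + self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append("\t".join([lab] + [repr(float(v)) for v in self.D[i]]))
        text = "\n".join(lines) + "\n"
        if path is None:
            return text
        _atomic_write_text(path, text)
        return None


def _vectors(M: np.ndarray, orientation: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if orientation == "samples":
        return M.T  # one vector per column
    if orientation == "entities":
        return M
    raise ValidationError(f"orientation must be 'samples' or 'entities', got {orientation!r}")


def correlation_distance(
    M: np.ndarray,
    labels: list[str],
    orientation: str = "samples",
    method: str = "pearson",
) -> DistanceMatrix:
    """Pairwise correlation likeness: d = 1 - |c|.

    ``orientation='samples'`` correlates column vectors (replicate QC);
    ``'entities'`` correlates row vectors (the transposed analysis).
    ``method`` is ``pearson`` (default) or ``spearman``.
    """
    V = _vectors(M, orientation)
    if V.shape[0] < 2:
        raise ValidationError("need at least 2 vectors for a distance matrix")
    if len(labels) != V.shape[0]:
        raise ValidationError("label count does not match vector count")
    sds = V.std(axis=1, ddof=1)
    for i, sd in enumerate(sds):
        if sd == 0.0:
            raise ValidationError(
                f"constant vector {labels[i]!r}: correlation undefined"
            )
    if method == "spearman":
        # rank transform with midranks for ties, then Pearson on the ranks
        V = np.apply_along_axis(_midranks, 1, V)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    C = np.corrcoef(V)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    D = 1.0 - np.abs(C)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(labels), metric="correlation", D=D, C=C)


def _midranks(v: np.ndarray) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    ranks = np.empty(len(v), dtype=float)
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def euclidean_distance(
    M: np.ndarray, labels: list[str], orientation: str = "samples"
) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample or entity vectors."""
    V = _vectors(M, orientation)
    if V.shape[0] < 2:
        raise ValidationError("need at least 2 vectors for a distance matrix")
    if len(labels) != V.shape[0]:
        raise ValidationError("label count does not match vector count")
    sq = np.sum(V**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (V @ V.T)
    D = np.sqrt(np.maximum(D2, 0.0))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(labels), metric="euclidean", D=D)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass
class Merge:
    left: int  # node id (leaf: 0..n-1; internal: n, n+1, ...)
    right: int
    height: float


@dataclass
class Dendrogram:
    labels: list[str]
    merges: list[Merge]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def _children(self, node: int) -> tuple[int, int] | None:
        if node < self.n_leaves:
            return None
        m = self.merges[node - self.n_leaves]
        return m.left, m.right

    def leaves_under(self, node: int) -> list[int]:
        kids = self._children(node)
        if kids is None:
            return [node]
        return self.leaves_under(kids[0]) + self.leaves_under(kids[1])

    def leaf_order(self) -> list[int]:
        """Leaf indices in drawing order (left-to-right of the root)."""
        root = self.n_leaves + len(self.merges) - 1
        return self.leaves_under(root)

    def root_split(self) -> tuple[set[str], set[str]]:
        """Label sets of the two subtrees under the last (root) merge."""
        if not self.merges:
            raise ValidationError("dendrogram has no merges")
        root = self.merges[-1]
        left = {self.labels[i] for i in self.leaves_under(root.left)}
        right = {self.labels[i] for i in self.leaves_under(root.right)}
        return left, right

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""

        def height_of(node: int) -> float:
            return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves].height

        def rec(node: int, parent_h: float) -> str:
            bl = max(parent_h - height_of(node), 0.0)
            kids = self._children(node)
            if kids is None:
                return f"{_newick_escape(self.labels[node])}:{bl:.10g}"
            inner = ",".join(rec(k, height_of(node)) for k in kids)
            return f"({inner}):{bl:.10g}"

        root = self.n_leaves + len(self.merges) - 1
        kids = self._children(root)
        if kids is None:
            return f"{_newick_escape(self.labels[root])};"
        inner = ",".join(rec(k, height_of(root)) for k in kids)
        return f"({inner});"

    def to_dict(self) -> dict:
        return {
            "kind": "dendrogram",
            "labels": list(self.labels),
            "linkage": self.linkage,
            "merges": [[m.left, m.right, m.height] for m in self.merges],
        }


def _newick_escape(label: str) -> str:
    if any(ch in label for ch in "():;, '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(dm: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering via Lance-Williams updates.

    Ties on the minimum inter-cluster distance are broken deterministically
    by the lexicographically smallest pair of minimal original leaf indices.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose one of {LINKAGES}")
    n = len(dm.labels)
    if n < 2:
        raise ValidationError("need at least 2 items to cluster")
    # active clusters: id -> (size, min original leaf index)
    D = {frozenset((i, j)): float(dm.D[i, j]) for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    min_leaf = {i: i for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []
    next_id = n
    while len(active) > 1:
        best = None
        for pair, d in D.items():
            a, b = sorted(pair, key=lambda c: min_leaf[c])
            key = (d, min_leaf[a], min_leaf[b])
            if best is None or key < best[0]:
                best = (key, a, b)
        (_, _, _), a, b = best  # type: ignore[misc]
        d_ab = D[frozenset((a, b))]
        merges.append(Merge(left=a, right=b, height=d_ab))
        c = next_id
        next_id += 1
        size[c] = size[a] + size[b]
        min_leaf[c] = min(min_leaf[a], min_leaf[b])
        for o in active:
            if o in (a, b):
                continue
            d_ao = D.pop(frozenset((a, o)))
            d_bo = D.pop(frozenset((b, o)))
            if linkage == "single":
                d_new = min(d_ao, d_bo)
            elif linkage == "complete":
                d_new = max(d_ao, d_bo)
            elif linkage == "average":
                d_new = (size[a] * d_ao + size[b] * d_bo) / (size[a] + size[b])
            else:  # ward
                sa, sb, so = size[a], size[b], size[o]
                t = sa + sb + so
                d_new = math.sqrt(
                    max(
                        ((sa + so) * d_ao**2 + (sb + so) * d_bo**2 - so * d_ab**2) / t,
                        0.0,
                    )
                )
            D[frozenset((c, o))] = d_new
        del D[frozenset((a, b))]
        active.discard(a)
        active.discard(b)
        active.add(c)
    return Dendrogram(labels=list(dm.labels), merges=merges, linkage=linkage)


# ---------------------------------------------------------------------------
# heatmap
# ---------------------------------------------------------------------------


@dataclass
class OrderedHeatmap:
    labels: list[str]  # permuted to dendrogram leaf order
    values: np.ndarray  # C when available, else D, permuted identically
    value_kind: str  # "correlation" | "distance"
    dendrogram: Dendrogram


def heatmap_result(dm: DistanceMatrix, dendrogram: Dendrogram) -> OrderedHeatmap:
    """Permute the likeness matrix to the dendrogram leaf order.

    In correlation mode the displayed cell values are the correlation
    coefficients; in Euclidean mode the distances themselves.
    """
    if dendrogram.labels != dm.labels:
        raise ValidationError("dendrogram labels do not match distance matrix labels")
    order = dendrogram.leaf_order()
    M = dm.C if dm.C is not None else dm.D
    kind = "correlation" if dm.C is not None else "distance"
    return OrderedHeatmap(
        labels=[dm.labels[i] for i in order],
        values=M[np.ix_(order, order)],
        value_kind=kind,
        dendrogram=dendrogram,
    )


def _heat_color(v: float, lo: float, hi: float) -> str:
    t = 0.5 if hi == lo else (v - lo) / (hi - lo)
    t = min(max(t, 0.0), 1.0)
    if t < 0.5:  # blue -> white
        u = t / 0.5
        r, g, b = int(33 + u * (255 - 33)), int(102 + u * (255 - 102)), 255
    else:  # white -> red
        u = (t - 0.5) / 0.5
        r, g, b = 255, int(255 - u * (255 - 33)), int(255 - u * (255 - 33))
    return f"#{r:02x}{g:02x}{b:02x}"


def render_heatmap_svg(hm: OrderedHeatmap, path: str | None = None) -> str:
    """Heatmap with a left-side dendrogram and a color scale."""
    n = len(hm.labels)
    cell = 18.0
    dend_w, label_w, margin, scale_h = 90.0, 110.0, 20.0, 46.0
    width = margin * 2 + dend_w + n * cell + label_w
    height = margin * 2 + n * cell + scale_h + 20
    doc = SvgDoc(width, height)
    x0 = margin + dend_w
    y0 = margin
    lo, hi = float(np.min(hm.values)), float(np.max(hm.values))
    if hm.value_kind == "correlation":
        lo, hi = -1.0, 1.0
    for i in range(n):
        for j in range(n):
            doc.rect(
                x0 + j * cell,
                y0 + i * cell,
                cell,
                cell,
                fill=_heat_color(float(hm.values[i, j]), lo, hi),
                class_="heat-cell",
                data_row=hm.labels[i],
                data_col=hm.labels[j],
                data_value=f"{hm.values[i, j]:.6g}",
            )
        doc.text(x0 + n * cell + 4, y0 + i * cell + cell * 0.7, hm.labels[i],
                 font_size=10, class_="row-label")
    _draw_dendrogram(doc, hm.dendrogram, x0=margin, y0=y0, width=dend_w, cell=cell)
    # color scale
    sy = y0 + n * cell + 24
    steps = 40
    sw = n * cell / steps
    for k in range(steps):
        v = lo + (hi - lo) * (k + 0.5) / steps
        doc.rect(x0 + k * sw, sy, sw, 12, fill=_heat_color(v, lo, hi), class_="scale-cell")
    doc.text(x0, sy + 24, f"{lo:.3g}", font_size=9, class_="scale-label")
    doc.text(x0 + n * cell, sy + 24, f"{hi:.3g}", font_size=9, text_anchor="end",
             class_="scale-label")
    doc.text(x0 + n * cell / 2, sy + 24, hm.value_kind, font_size=9,
             text_anchor="middle", class_="scale-title")
    svg = doc.tostring()
    if path is not None:
        _atomic_write_text(path, svg)
    return svg


def _draw_dendrogram(doc: SvgDoc, dend: Dendrogram, x0: float, y0: float,
                     width: float, cell: float) -> None:
    order = dend.leaf_order()
    ypos = {leaf: y0 + order.index(leaf) * cell + cell / 2 for leaf in order}
    max_h = max((m.height for m in dend.merges), default=1.0) or 1.0

    def xpix(h: float) -> float:
        return x0 + width - (h / max_h) * (width - 4)

    node_y: dict[int, float] = dict(ypos)
    node_h: dict[int, float] = {i: 0.0 for i in range(dend.n_leaves)}
    for k, m in enumerate(dend.merges):
        nid = dend.n_leaves + k
        yl, yr = node_y[m.left], node_y[m.right]
        xl, xr = xpix(node_h[m.left]), xpix(node_h[m.right])
        xm = xpix(m.height)
        doc.line(xl, yl, xm, yl, stroke="#333333", class_="dendro")
        doc.line(xr, yr, xm, yr, stroke="#333333", class_="dendro")
        doc.line(xm, yl, xm, yr, stroke="#333333", class_="dendro")
        node_y[nid] = (yl + yr) / 2
        node_h[nid] = m.height


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAResult:
    scores: np.ndarray  # observations x components
    explained_fraction: list[float]
    component_labels: list[str]
    loadings: np.ndarray  # components x variables

    def to_dict(self) -> dict:
        return {
            "kind": "pca",
            "scores": self.scores.tolist(),
            "explained_fraction": list(self.explained_fraction),
            "component_labels": list(self.component_labels),
        }


def run_pca(M: np.ndarray, scale: bool = False) -> PCAResult:
    """PCA of an observations-by-variables matrix via SVD.

    Data are column-centered (and scaled to unit sample sd when ``scale``;
    constant variables are left centered only).  All observations enter the
    decomposition; no variable filtering is applied.  Component signs are
    fixed by forcing each component's largest-magnitude loading positive.
    """
    X = np.asarray(M, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA needs at least 2 observations")
    Xc = X - X.mean(axis=0, keepdims=True)
    if scale:
        sds = Xc.std(axis=0, ddof=1, keepdims=True)
        Xc = Xc / np.where(sds == 0.0, 1.0, sds)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| coordinate of each component > 0
    for k in range(Vt.shape[0]):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    total = float(np.sum(s**2))
    if total == 0.0:
        frac = [0.0] * len(s)
    else:
        frac = [float(v) for v in (s**2) / total]
    labels = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(scores=scores, explained_fraction=frac,
                     component_labels=labels, loadings=Vt)


@dataclass
class ScatterPoint:
    x: float
    y: float
    label: str
    color_class: str
    color: str


@dataclass
class ScatterSpec:
    points: list[ScatterPoint]
    x_label: str
    y_label: str

    @property
    def color_classes(self) -> list[str]:
        seen: list[str] = []
        for p in self.points:
            if p.color_class not in seen:
                seen.append(p.color_class)
        return seen

    def to_dict(self) -> dict:
        return {
            "kind": "pca_scatter",
            "points": [
                {
                    "x": p.x,
                    "y": p.y,
                    "label": p.label,
                    "color_class": p.color_class,
                    "color": p.color,
                }
                for p in self.points
            ],
            "x_label": self.x_label,
            "y_label": self.y_label,
        }


def pca_plot_spec(res: PCAResult, sample_keys: list[SampleKey]) -> ScatterSpec:
    """First two components as a scatter; replicates of one condition (same
    group levels and x level) share a color; axis labels carry the
    percentage of variance explained."""
    if len(sample_keys) != res.scores.shape[0]:
        raise ValidationError("sample key count does not match PCA observations")
    if res.scores.shape[1] < 2:
        raise ValidationError("need at least 2 components for a scatter")
    classes: list[str] = []
    points = []
    for i, key in enumerate(sample_keys):
        cls = " / ".join(key.group_values + (key.x_value,))
        if cls not in classes:
            classes.append(cls)
        points.append(
            ScatterPoint(
                x=float(res.scores[i, 0]),
                y=float(res.scores[i, 1]),
                label=key.raw_name,
                color_class=cls,
                color=palette_color(classes.index(cls)),
            )
        )
    xl = f"PC1 ({res.explained_fraction[0] * 100:.1f}% of variance)"
    yl = f"PC2 ({res.explained_fraction[1] * 100:.1f}% of variance)"
    return ScatterSpec(points=points, x_label=xl, y_label=yl)


def render_scatter_svg(spec: ScatterSpec, path: str | None = None) -> str:
    w, h, m = 420.0, 360.0, 60.0
    doc = SvgDoc(w, h)
    xs = [p.x for p in spec.points]
    ys = [p.y for p in spec.points]
    xlo, xhi = min(xs), max(xs)
    ylo, yhi = min(ys), max(ys)
    xpad = 0.08 * ((xhi - xlo) or 1.0)
    ypad = 0.08 * ((yhi - ylo) or 1.0)
    xlo, xhi, ylo, yhi = xlo - xpad, xhi + xpad, ylo - ypad, yhi + ypad
    doc.rect(m, m / 2, w - 2 * m, h - 1.5 * m, fill="none", stroke="#333333")
    for p in spec.points:
        px = m + (p.x - xlo) / (xhi - xlo) * (w - 2 * m)
        py = m / 2 + (1 - (p.y - ylo) / (yhi - ylo)) * (h - 1.5 * m)
        doc.circle(px, py, 4, fill=p.color, class_="pca-point",
                   data_label=p.label, data_class=p.color_class)
    doc.text(w / 2, h - 12, spec.x_label, text_anchor="middle", font_size=11,
             class_="x-axis-label")
    doc.text(14, h / 2, spec.y_label, font_size=11, class_="y-axis-label",
             transform=f"rotate(-90 14 {h / 2:.2f})", text_anchor="middle")
    svg = doc.tostring()
    if path is not None:
        _atomic_write_text(path, svg)
    return svg
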