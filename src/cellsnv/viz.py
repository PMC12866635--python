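"""Embedding visualizations: interactive HTML documents and static rasters.

Each interactive plot is a single self-contained HTML file whose data lives
in an embedded JSON block (``<script type="application/json"
id="cellsnv-data">``) rendered client-side by a small inlined SVG scatter
routine.  The JSON block is the contract: it holds exactly one point per
cell in the active view, each with its mapped color, so documents can be
verified programmatically and re-rendered to PNG without a browser.

Cells whose color metric is undefined (e.g. VAF over loci the cell does not
cover) are drawn in a reserved "no signal" grey that never occurs inside
the gradient range, keeping the no-signal / negative-signal distinction
visible.
"""

from __future__ import annotations

import html
import json
import logging
import os
import re
from dataclasses import dataclass, field, replace
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .io import SNVKey
from .matrix import CellSNVMatrix
from .metrics import ALL_METRICS, VAF_METRICS, ClusterMetricsSummary
from .reduce import Embedding

logger = logging.getLogger(__name__)

#: Grey reserved for cells with an undefined metric; outside every gradient.
RESERVED_COLOR = "#bdbdbd"

GRADIENTS = {
    "white-blue": [(1.0, 1.0, 1.0), (0.03, 0.19, 0.42)],  # monochromatic
    "blue-white-red": [(0.13, 0.40, 0.67), (1.0, 1.0, 1.0), (0.70, 0.09, 0.17)],  # bichromatic, mid 0.5
}

CATEGORICAL_FIELDS = ("cluster", "cell_type", "sample_id")
_PALETTE = ("#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
            "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf")


@dataclass(frozen=True)
class PlotSpec:
    """What to color by and how to draw it."""

    metric: str = "n_snvs"
    gradient: str = "white-blue"
    point_size: float = 5.0
    border: bool = False
    show_axes: bool = True
    show_legend: bool = True
    show_labels: bool = True
    dim: int = 2  # 2 or 3
    method: str = "umap"
    log_counts: bool = False  # log10(1+x) scaling for count gradients
    title: str = ""


def _interp_gradient(stops: Sequence[tuple], t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    stops = np.asarray(stops)
    pos = np.linspace(0, 1, len(stops))
    return np.stack([np.interp(t, pos, stops[:, k]) for k in range(3)], axis=1)


def _to_hex(rgb: np.ndarray) -> list[str]:
    return ["#%02x%02x%02x" % tuple(int(round(255 * v)) for v in row) for row in rgb]


def map_colors(values: pd.Series, spec: PlotSpec) -> tuple[list[str], dict]:
    """Map metric values to hex colors; NaN -> reserved color.

    VAF metrics scale over the fixed interval [0, 1]; count metrics over
    [0, observed max], linearly or log10(1+x) if requested.  Categorical
    fields cycle a qualitative palette.
    """
    if spec.metric in CATEGORICAL_FIELDS or values.dtype == object:
        cats = [c for c in pd.unique(values.dropna())]
        lookup = {c: _PALETTE[i % len(_PALETTE)] for i, c in enumerate(cats)}
        colors = [RESERVED_COLOR if pd.isna(v) else lookup[v] for v in values]
        return colors, {"type": "categorical", "categories": {str(k): v for k, v in lookup.items()}}
    vals = values.to_numpy(dtype=float)
    defined = ~np.isnan(vals)
    if spec.metric in VAF_METRICS or (defined.any() and vals[defined].min() >= 0 and vals[defined].max() <= 1):
        lo, hi = 0.0, 1.0
    else:
        lo, hi = 0.0, float(vals[defined].max()) if defined.any() else 1.0
    scaled = np.zeros_like(vals)
    if defined.any():
        v = vals[defined]
        if spec.log_counts and spec.metric not in VAF_METRICS:
            v = np.log10(1 + v)
            hi_s = np.log10(1 + hi) if hi > 0 else 1.0
            scaled[defined] = v / hi_s
        else:
            scaled[defined] = (v - lo) / (hi - lo) if hi > lo else 0.0
    stops = GRADIENTS.get(spec.gradient)
    if stops is None:
        raise ValueError(f"unknown gradient {spec.gradient!r}; available: {sorted(GRADIENTS)}")
    hexes = _to_hex(_interp_gradient(stops, scaled))
    colors = [h if d else RESERVED_COLOR for h, d in zip(hexes, defined)]
    return colors, {"type": "gradient", "domain": [lo, hi], "gradient": spec.gradient}


@dataclass
class CellView:
    """An embedding together with aligned per-cell fields, possibly subset."""

    embedding: Embedding
    data: pd.DataFrame  # one row per embedded cell, in barcode order

    def __post_init__(self) -> None:
        if len(self.data) != len(self.embedding.barcodes):
            raise ValueError("per-cell data misaligned with embedding barcodes")


def make_view(embedding: Embedding, metrics: pd.DataFrame | None = None, **extra_columns) -> CellView:
    """Assemble a CellView by joining per-cell tables on barcode."""
    df = pd.DataFrame({"barcode": embedding.barcodes})
    if embedding.clusters is not None:
        df["cluster"] = embedding.clusters
    if embedding.annotations is not None:
        for c in embedding.annotations.columns:
            df[c] = embedding.annotations[c].to_numpy()
    if metrics is not None:
        df = df.merge(metrics, on="barcode", how="left", suffixes=("", "_metric"))
    for name, values in extra_columns.items():
        df[name] = np.asarray(values)
    return CellView(embedding, df)


def select_cells(view: CellView, predicate: str) -> CellView:
    """Subset a view to the cells satisfying a predicate expression.

    The predicate is a boolean expression over the view's columns (e.g.
    ``"total_vaf >= 0.5"`` or ``"cell_type == 'tumor'"``).  Undefined (NaN)
    values never satisfy a comparison.  Referencing an unknown field raises
    with the list of valid names.
    """
    names = set(re.findall(r"[A-Za-z_][A-Za-z0-9_]*", predicate)) - {"and", "or", "not", "in", "True", "False"}
    unknown = [n for n in names if n not in view.data.columns]
    if unknown:
        raise KeyError(f"unknown field(s) {unknown} in predicate; valid fields: {sorted(view.data.columns)}")
    mask = view.data.eval(predicate)
    mask = mask.fillna(False).astype(bool).to_numpy()
    if not mask.any():
        logger.warning("selection %r matches no cells", predicate)
    emb = view.embedding
    sub = Embedding(
        barcodes=[bc for bc, m in zip(emb.barcodes, mask) if m],
        coordinates={k: c[mask] for k, c in emb.coordinates.items()},
        clusters=emb.clusters[mask] if emb.clusters is not None else None,
        annotations=emb.annotations.loc[mask].reset_index(drop=True) if emb.annotations is not None else None,
    )
    return CellView(sub, view.data.loc[mask].reset_index(drop=True))


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>body{{font-family:sans-serif;margin:1em}} .panel{{display:inline-block;margin:0.5em}}
svg{{background:#fff;border:{border}}} text.axis{{font-size:10px;fill:#555}}</style></head>
<body><h3>{title}</h3><div id="root"></div>
<script type="application/json" id="cellsnv-data">{payload}</script>
<script>
const data = JSON.parse(document.getElementById("cellsnv-data").textContent);
const W = 420, H = 420, PAD = 30;
function extent(pts, k) {{
  let lo = Infinity, hi = -Infinity;
  for (const p of pts) {{ lo = Math.min(lo, p[k]); hi = Math.max(hi, p[k]); }}
  if (!(hi > lo)) {{ hi = lo + 1; }} return [lo, hi];
}}
for (const panel of data.panels) {{
  const div = document.createElement("div"); div.className = "panel";
  const h = document.createElement("h4"); h.textContent = panel.name; div.appendChild(h);
  const svg = document.createElementNS("http://www.w3.org/2000/svg", "svg");
  svg.setAttribute("width", W); svg.setAttribute("height", H);
  const pts = panel.points, ex = extent(pts, "x"), ey = extent(pts, "y");
  for (const p of pts) {{
    const c = document.createElementNS("http://www.w3.org/2000/svg", "circle");
    c.setAttribute("cx", PAD + (W - 2 * PAD) * (p.x - ex[0]) / (ex[1] - ex[0]));
    c.setAttribute("cy", H - PAD - (H - 2 * PAD) * (p.y - ey[0]) / (ey[1] - ey[0]));
    c.setAttribute("r", data.spec.point_size / 2);
    c.setAttribute("fill", p.color);
    if (data.spec.border) c.setAttribute("stroke", "#333");
    const t = document.createElementNS("http://www.w3.org/2000/svg", "title");
    t.textContent = p.barcode + (p.value === null ? " (no signal)" : ": " + p.value);
    c.appendChild(t); svg.appendChild(c);
  }}
  div.appendChild(svg);
  document.getElementById("root").appendChild(div);
}}
</script></body></html>
"""


def _panel(name: str, coords: np.ndarray, barcodes: Sequence[str], values: pd.Series, colors: Sequence[str]) -> dict:
    pts = []
    for i, bc in enumerate(barcodes):
        v = values.iloc[i]
        point = {
            "barcode": bc,
            "x": float(coords[i, 0]),
            "y": float(coords[i, 1]),
            "value": None if pd.isna(v) else (v if isinstance(v, str) else float(v)),
            "color": colors[i],
        }
        if coords.shape[1] > 2:
            point["z"] = float(coords[i, 2])
        pts.append(point)
    return {"name": name, "points": pts}


def _render(panels: list[dict], spec: PlotSpec, legend: dict, path: str | os.PathLike | None) -> str:
    payload = {
        "spec": {
            "metric": spec.metric, "gradient": spec.gradient, "point_size": spec.point_size,
            "border": spec.border, "dim": spec.dim, "method": spec.method,
            "show_axes": spec.show_axes, "show_legend": spec.show_legend, "show_labels": spec.show_labels,
        },
        "reserved_color": RESERVED_COLOR,
        "legend": legend if spec.show_legend else None,
        "panels": panels,
    }
    doc = _HTML_TEMPLATE.format(
        title=html.escape(spec.title or spec.metric),
        border="1px solid #ccc" if spec.border else "none",
        payload=json.dumps(payload),
    )
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(doc)
    return doc


def read_plot_data(doc_or_path: str | os.PathLike) -> dict:
    """Extract the embedded JSON data block from an emitted HTML document."""
    text = str(doc_or_path)
    if "<html" not in text and os.path.exists(text):
        with open(text, encoding="utf-8") as fh:
            text = fh.read()
    m = re.search(r'<script type="application/json" id="cellsnv-data">(.*?)</script>', text, re.S)
    if m is None:
        raise ValueError("document carries no cellsnv data block")
    return json.loads(m.group(1))


def plot_set(view: CellView, spec: PlotSpec | None = None, path: str | os.PathLike | None = None) -> str:
    """One colored point per cell of the view, over the requested embedding."""
    spec = spec or PlotSpec()
    if spec.metric not in view.data.columns:
        valid = [c for c in view.data.columns if c in ALL_METRICS or c in CATEGORICAL_FIELDS]
        raise KeyError(f"unknown metric {spec.metric!r}; valid metrics: {valid}")
    coords = view.embedding.coords(spec.method, spec.dim)  # raises if absent, e.g. 3D on a 2D embedding
    values = view.data[spec.metric]
    if values.isna().all():
        logger.warning("metric %r undefined for every cell in view", spec.metric)
    colors, legend = map_colors(values, spec)
    panel = _panel(spec.metric, coords, view.embedding.barcodes, values, colors)
    return _render([panel], spec, legend, path)


def plot_individual_snv(
    view: CellView,
    m: CellSNVMatrix,
    snv: SNVKey,
    spec: PlotSpec | None = None,
    path: str | os.PathLike | None = None,
) -> str:
    """Three linked panels (N_VAR, N_REF, VAF_RNA) for one SNV.

    No-coverage cells take the reserved color in all three panels; var-only
    cells show VAF 1 and ref-only cells VAF 0, so monoallelic patterns in
    either direction stand out against true absence of expression.
    """
    spec = spec or PlotSpec()
    j = m.snv_index(snv)  # KeyError for unknown SNV
    col_of = {bc: i for i, bc in enumerate(m.cells)}
    rows = [col_of.get(bc) for bc in view.embedding.barcodes]
    if any(r is None for r in rows):
        missing = [bc for bc, r in zip(view.embedding.barcodes, rows) if r is None]
        raise ValueError(f"{len(missing)} view barcodes missing from the SNV matrix, e.g. {missing[0]}")
    idx = np.array(rows)
    nv = m.var_counts[idx, j].astype(float)
    nr = m.ref_counts[idx, j].astype(float)
    obs = m.observed[idx, j]
    nv[~obs] = np.nan
    nr[~obs] = np.nan
    with np.errstate(invalid="ignore"):
        vafs = np.where(obs, m.var_counts[idx, j] / np.maximum(nv + nr, 1), np.nan)
    coords = view.embedding.coords(spec.method, spec.dim)
    panels = []
    legend = None
    for name, vals in (("N_VAR", nv), ("N_REF", nr), ("VAF_RNA", vafs)):
        series = pd.Series(vals)
        metric_name = "total_vaf" if name == "VAF_RNA" else "total_nvar"  # reuse scale rules
        colors, legend = map_colors(series, replace(spec, metric=metric_name))
        panels.append(_panel(name, coords, view.embedding.barcodes, series, colors))
    titled = replace(spec, title=spec.title or f"SNV {snv}")
    return _render(panels, titled, legend, path)


def plot_histograms(
    summaries: dict[str, ClusterMetricsSummary], outdir: str | os.PathLike
) -> dict[str, str]:
    """One static raster per metric, one facet per group; bar heights = bin counts."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    labels = list(summaries)
    for metric in ALL_METRICS:
        fig, axes = plt.subplots(1, max(len(labels), 1), figsize=(3.2 * max(len(labels), 1), 2.8), squeeze=False)
        for ax, label in zip(axes[0], labels):
            edges, counts = summaries[label].histograms[metric]
            ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge", color="#4878a8", edgecolor="white")
            ax.set_title(f"{label} (n={summaries[label].n_cells})", fontsize=9)
            ax.set_xlabel(metric, fontsize=8)
        fig.tight_layout()
        out = os.path.join(outdir, f"hist_{metric}.png")
        fig.savefig(out, dpi=100)
        plt.close(fig)
        paths[metric] = out
    return paths


def export_snapshot(doc_or_path: str | os.PathLike, path: str | os.PathLike, dpi: int = 100) -> str:
    """Render the data block of an interactive document to a static raster."""
    data = read_plot_data(doc_or_path)
    panels = data["panels"]
    fig, axes = plt.subplots(1, len(panels), figsize=(4.2 * len(panels), 4.2), squeeze=False)
    for ax, panel in zip(axes[0], panels):
        pts = panel["points"]
        xs = [p["x"] for p in pts]
        ys = [p["y"] for p in pts]
        cs = [p["color"] for p in pts]
        ax.scatter(xs, ys, c=cs, s=data["spec"]["point_size"] ** 2,
                   edgecolors="#333" if data["spec"]["border"] else "none")
        ax.set_title(panel["name"], fontsize=10)
        if not data["spec"]["show_axes"]:
            ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
    if not (os.path.exists(path) and os.path.getsize(path) > 0):
        raise IOError(f"snapshot export to {path} failed")
    return str(path)
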