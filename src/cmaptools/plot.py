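"""Publication figures: contact maps, alignment coverage, precision curves.

Every figure function writes an image (PNG/SVG/PDF via matplotlib) *and*
returns a plain-data manifest of what was plotted.  The manifest is the
figure's data contract: numeric tests run against it, never against
pixels, and it is invariant to rendering-only parameters (dpi, figure
size, colors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.backends.backend_pdf import FigureCanvasPdf
from matplotlib.backends.backend_svg import FigureCanvasSVG
from matplotlib.figure import Figure

from .core import ContactMap, ContactStatus, SequenceFile
from .msa import per_column_depth
from .structure import EvaluationResult

__all__ = [
    "FigureConfig",
    "contact_map_figure",
    "sequence_coverage_figure",
    "precision_evaluation_figure",
]

_CANVASES = {"png": FigureCanvasAgg, "svg": FigureCanvasSVG, "pdf": FigureCanvasPdf}


@dataclass
class FigureConfig:
    """Rendering parameters shared by all figure generators."""

    output_path: str = "figure.png"
    image_format: str = "png"
    dpi: int = 300
    width: float = 8.0
    height: float = 6.0
    point_size: float = 12.0
    color_tp: str = "#2e8b57"  # green: confirmed contacts
    color_fp: str = "#d62728"  # red: contradicted contacts
    color_unknown: str = "#7f7f7f"  # grey: unevaluable (unresolved residues)
    color_reference: str = "#c8c8c8"  # light grey backdrop
    color_primary: str = "#1f77b4"
    color_secondary: str = "#ff7f0e"

    def __post_init__(self) -> None:
        if self.image_format not in _CANVASES:
            raise ValueError(
                f"image_format must be one of {sorted(_CANVASES)}, "
                f"got {self.image_format!r}"
            )
        if self.dpi < 50:
            raise ValueError(f"dpi must be >= 50, got {self.dpi}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("figure width and height must be positive")


def _new_figure(cfg: FigureConfig):
    fig = Figure(figsize=(cfg.width, cfg.height))
    _CANVASES[cfg.image_format](fig)
    return fig, fig.add_subplot(111)


def _save(fig: Figure, cfg: FigureConfig) -> str:
    fig.savefig(cfg.output_path, format=cfg.image_format, dpi=cfg.dpi)
    return cfg.output_path


def _mirrored(cmap: ContactMap, series: str) -> List[Dict]:
    pts = []
    for c in cmap:
        i, j = c.pair
        pts.append({"x": i, "y": j, "series": series})
        pts.append({"x": j, "y": i, "series": series})
    return pts


def contact_map_figure(
    cmap: ContactMap,
    reference: Optional[ContactMap] = None,
    second: Optional[ContactMap] = None,
    cfg: Optional[FigureConfig] = None,
    resolved: Optional[set] = None,
) -> Tuple[str, List[Dict]]:
    """Scatter the contact map in residue-index space.

    Without a second map the prediction is mirrored across the diagonal;
    with one, the primary map's canonical orientation sits above the
    diagonal and the second map's below.  When a reference (structure) map
    is given the primary map's points are colored by match status and the
    reference is drawn as a backdrop in its own color.  Every series
    contributes both orientations of each pair to the returned manifest,
    so the manifest always holds ``2*(|map| + |second| + |reference|)``
    points.
    """
    if len(cmap) == 0:
        raise ValueError("cannot plot an empty contact map")
    cfg = cfg or FigureConfig()
    manifest: List[Dict] = []

    if reference is not None:
        manifest.extend(_mirrored(reference, "reference"))
        if resolved is None:
            # default: the contiguous span the reference map covers counts
            # as structurally resolved; pass `resolved` for sparser truth
            top_ref = max(i for c in reference for i in c.pair)
            resolved = set(range(1, top_ref + 1))
        matched = cmap.match(reference, resolved)
        by_status = {
            ContactStatus.TRUE_POSITIVE: "tp",
            ContactStatus.FALSE_POSITIVE: "fp",
            ContactStatus.UNKNOWN: "unknown",
        }
        for c in matched:
            i, j = c.pair
            series = by_status[c.status]
            manifest.append({"x": i, "y": j, "series": series})
            manifest.append({"x": j, "y": i, "series": series})
    else:
        manifest.extend(_mirrored(cmap, "map"))
    if second is not None:
        # second map drawn with its canonical orientation below the diagonal
        for c in second:
            i, j = c.pair
            manifest.append({"x": j, "y": i, "series": "second"})
            manifest.append({"x": i, "y": j, "series": "second"})

    colors = {
        "map": cfg.color_primary,
        "second": cfg.color_secondary,
        "reference": cfg.color_reference,
        "tp": cfg.color_tp,
        "fp": cfg.color_fp,
        "unknown": cfg.color_unknown,
    }
    fig, ax = _new_figure(cfg)
    for series in ("reference", "map", "second", "unknown", "fp", "tp"):
        pts = [p for p in manifest if p["series"] == series]
        if not pts:
            continue
        ax.scatter(
            [p["x"] for p in pts],
            [p["y"] for p in pts],
            s=cfg.point_size,
            c=colors[series],
            label=series,
            linewidths=0,
        )
    top = max(max(p["x"], p["y"]) for p in manifest)
    ax.set_xlim(1, top)
    ax.set_ylim(1, top)
    ax.set_aspect("equal")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.legend(loc="upper left", fontsize="small")
    path = _save(fig, cfg)
    return path, manifest


def sequence_coverage_figure(
    aln: SequenceFile, cfg: Optional[FigureConfig] = None
) -> Tuple[str, Dict]:
    """Per-column non-gap depth across an alignment.

    Horizontal guides mark depths of 1x and 5x the alignment length —
    common rules of thumb for when an alignment is deep enough for
    co-evolution analysis — whenever they fall inside the plotted range.
    """
    cfg = cfg or FigureConfig()
    depth = per_column_depth(aln)
    length = len(depth)
    xs = list(range(1, length + 1))
    guides = [m * length for m in (1, 5) if m * length <= max(depth)]
    manifest = {"x": xs, "y": depth, "guides": guides}

    fig, ax = _new_figure(cfg)
    ax.plot(xs, depth, color=cfg.color_primary, lw=1.5)
    ax.fill_between(xs, depth, color=cfg.color_primary, alpha=0.25)
    for g in guides:
        ax.axhline(g, color=cfg.color_fp, ls="--", lw=1.0)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("sequence depth (non-gap count)")
    ax.set_xlim(1, max(length, 2))
    ax.set_ylim(0, max(depth) * 1.05 if depth else 1)
    path = _save(fig, cfg)
    return path, manifest


def precision_evaluation_figure(
    results: List[EvaluationResult], cfg: Optional[FigureConfig] = None
) -> Tuple[str, Dict]:
    """Precision versus ``L``-factor, the stepwise evaluation curve.

    Factors whose precision is undefined (no classifiable contact) appear
    as gaps in the curve and as ``None`` in the manifest.  The y-axis is
    fixed to [0, 1].
    """
    if not results:
        raise ValueError("no evaluation results to plot")
    factors = [r.factor for r in results]
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError("factors must be strictly increasing")
    manifest = {"points": [(r.factor, r.precision) for r in results]}

    cfg = cfg or FigureConfig()
    fig, ax = _new_figure(cfg)
    defined = [(f, p) for f, p in manifest["points"] if p is not None]
    if defined:
        ax.plot(
            [f for f, _ in defined],
            [p for _, p in defined],
            marker="o",
            color=cfg.color_primary,
        )
    ax.set_xlabel("contact cutoff (fraction of L)")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1)
    path = _save(fig, cfg)
    return path, manifest
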