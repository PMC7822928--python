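"""Deterministic rendering of pileups into RGBA images.

Layout convention per row: the focus span (query gene pair for the query row,
an anchor-centered span of equal width for reference rows) maps linearly onto
the central band occupying ``central_fraction`` (default 2/3) of the image
width; the upstream flank compresses into the left margin and the downstream
flank into the right margin, each with its own linear bp-to-pixel map.  Genes
draw as arrows (rectangle body plus triangular head) whose pixel length is
proportional to gene length within its region and whose head points along the
display strand.

Colors encode gene family: the two query-pair families are blue and red in
every row; the next most frequent families get distinct palette colors; all
remaining (and family-less) genes are black.  The whole raster shares one
alpha value equal to the pair's functional-association score, clamped below
at ``default_alpha`` (0.1) when no score exists — a weak association fades
the entire image.

Rendering is a pure function: identical pileup and config give byte-identical
PNG output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw

from .compare_region import Pileup, RegionRow
from .io import FORWARD

BLUE = (0, 0, 255)
RED = (255, 0, 0)
BLACK = (0, 0, 0)
WHITE = (255, 255, 255)

# Distinct, saturated colors excluding blue, red and black.
DEFAULT_PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 158, 115),   # green
    (230, 159, 0),   # orange
    (86, 180, 233),  # sky
    (204, 121, 167), # pink
    (148, 103, 189), # purple
    (140, 86, 75),   # brown
    (0, 190, 190),   # teal
    (188, 189, 34),  # olive
)


class RenderError(ValueError):
    pass


@dataclass
class RenderConfig:
    width_px: int = 512
    row_height_px: int = 32
    central_fraction: float = 2.0 / 3.0
    palette_size: int = 8
    default_alpha: float = 0.1
    palette: tuple[tuple[int, int, int], ...] = DEFAULT_PALETTE

    def __post_init__(self) -> None:
        if not 0.0 < self.central_fraction < 1.0:
            raise RenderError("central_fraction must lie in (0, 1)")
        if not 0.0 < self.default_alpha <= 1.0:
            raise RenderError("default_alpha must lie in (0, 1]")
        if self.palette_size > len(self.palette):
            raise RenderError("palette_size exceeds available palette colors")
        forbidden = {BLUE, RED, BLACK}
        if forbidden & set(self.palette[: self.palette_size]):
            raise RenderError("palette must exclude blue, red and black")
        if len(set(self.palette[: self.palette_size])) < self.palette_size:
            raise RenderError("palette colors must be distinct")

    @property
    def central_band(self) -> tuple[float, float]:
        half_margin = self.width_px * (1.0 - self.central_fraction) / 2.0
        return half_margin, self.width_px - half_margin


@dataclass
class ArrowExtent:
    """Pixel-space placement of one gene arrow within a row band."""

    gene_id: str
    x0: int
    x1: int
    head_right: bool
    color: tuple[int, int, int] = BLACK

    def mirrored(self, width_px: int) -> "ArrowExtent":
        return ArrowExtent(
            self.gene_id, width_px - self.x1, width_px - self.x0,
            not self.head_right, self.color,
        )


@dataclass
class RenderedExample:
    """RGBA raster plus its layout metadata, label and provenance."""

    pixels: np.ndarray  # (H, W, 4) uint8
    layout: list[list[ArrowExtent]]  # per row, in draw order
    label: Optional[str] = None  # "operonic" | "non_operonic"
    provenance: tuple[str, str, str] = ("", "", "")  # genome, gene_a, gene_b

    @property
    def alpha(self) -> float:
        return float(self.pixels[0, 0, 3]) / 255.0

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels, mode="RGBA").save(path, format="PNG")

    def layout_json(self) -> str:
        payload = {
            "provenance": list(self.provenance),
            "label": self.label,
            "rows": [
                [
                    {
                        "gene_id": a.gene_id,
                        "x0": a.x0,
                        "x1": a.x1,
                        "head_right": a.head_right,
                        "color": list(a.color),
                    }
                    for a in row
                ]
                for row in self.layout
            ],
        }
        return json.dumps(payload, indent=1)

    def save_layout(self, path: str | Path) -> None:
        Path(path).write_text(self.layout_json())


def png_name(example: RenderedExample) -> str:
    genome, ga, gb = example.provenance
    safe = lambda s: s.replace(" ", "-")
    return f"{safe(genome)}_{safe(ga)}_{safe(gb)}.png"


def layout_row(
    row: RegionRow,
    focus_span: tuple[int, int],
    cfg: RenderConfig,
) -> list[ArrowExtent]:
    """Map a row's genes to pixel extents via the three-region piecewise map.

    ``focus_span`` is the genomic interval (display coordinates) that fills
    the central band.  Flank intervals each compress into one margin with
    their own linear map.  Extents round to integer columns, half-open.
    """
    contig, w0, w1 = row.window
    if w1 <= w0:
        raise RenderError(f"zero-length window {row.window}")
    s0, s1 = focus_span
    if s1 <= s0:
        raise RenderError(f"zero-length focus span {focus_span}")
    cx0, cx1 = cfg.central_band
    W = cfg.width_px

    def to_px(bp: float) -> float:
        if bp < s0:
            lo = min(w0, s0 - 1)  # degenerate: no left flank
            return (bp - lo) / (s0 - lo) * cx0 if s0 > lo else cx0
        if bp > s1:
            hi = max(w1, s1 + 1)
            return cx1 + (bp - s1) / (hi - s1) * (W - cx1) if hi > s1 else cx1
        return cx0 + (bp - s0) / (s1 - s0) * (cx1 - cx0)

    extents: list[ArrowExtent] = []
    for g in row.genes:
        x0 = int(round(to_px(max(g.start, w0))))
        x1 = int(round(to_px(min(g.end, w1))))
        x0 = max(0, min(x0, W - 1))
        x1 = max(x0 + 1, min(x1, W))
        extents.append(
            ArrowExtent(gene_id=g.gene_id, x0=x0, x1=x1, head_right=g.strand == FORWARD)
        )
    return extents


def assign_colors(pileup: Pileup, cfg: RenderConfig) -> dict[str, tuple[int, int, int]]:
    """Family -> color map: query-pair families blue/red, next most frequent
    families get palette colors, everything else black."""
    g1, g2 = pileup.focus_pair
    fam1, fam2 = g1.family_id, g2.family_id
    counts: dict[str, int] = {}
    for row in pileup.rows:
        for g in row.genes:
            fam = g.family_id
            if fam is None or fam in (fam1, fam2):
                continue
            counts[fam] = counts.get(fam, 0) + 1
    ranked = sorted(counts, key=lambda f: (-counts[f], f))
    colors: dict[str, tuple[int, int, int]] = {}
    if fam1 is not None:
        colors[fam1] = BLUE
    if fam2 is not None and fam2 not in colors:
        colors[fam2] = RED
    for i, fam in enumerate(ranked[: cfg.palette_size]):
        colors[fam] = cfg.palette[i]
    return colors


def _focus_span_for_row(pileup: Pileup, row: RegionRow, is_query: bool) -> tuple[int, int]:
    g1, g2 = pileup.focus_pair
    q0, q1 = min(g1.start, g2.start), max(g1.end, g2.end)
    if is_query:
        return q0, q1
    # Reference rows: a span of the query focus width centered on the anchor.
    half = (q1 - q0) / 2.0
    mid = row.anchor_gene.midpoint
    return int(round(mid - half)), int(round(mid + half))


def _draw_arrow(draw: ImageDraw.ImageDraw, a: ArrowExtent, y0: int, y1: int) -> None:
    length = a.x1 - a.x0
    head = int(min(0.25 * length, 10))
    ymid = (y0 + y1) // 2
    if a.head_right:
        body = (a.x0, y0, max(a.x0, a.x1 - head) , y1)
        tri = [(a.x1 - head, y0), (a.x1 - 1, ymid), (a.x1 - head, y1)]
    else:
        body = (min(a.x1, a.x0 + head), y0, a.x1, y1)
        tri = [(a.x0 + head, y0), (a.x0, ymid), (a.x0 + head, y1)]
    draw.rectangle(body, fill=a.color)
    if head > 0:
        draw.polygon(tri, fill=a.color)


def render(pileup: Pileup, cfg: Optional[RenderConfig] = None) -> RenderedExample:
    """Render a pileup to an RGBA raster; query row topmost, one global alpha."""
    cfg = cfg or RenderConfig()
    rows = pileup.rows
    if not rows:
        raise RenderError("pileup has no rows")
    H = cfg.row_height_px * len(rows)
    img = Image.new("RGB", (cfg.width_px, H), WHITE)
    draw = ImageDraw.Draw(img)
    layouts: list[list[ArrowExtent]] = []
    colors: dict[str, tuple[int, int, int]] = assign_colors(pileup, cfg)
    pad = max(2, cfg.row_height_px // 6)
    for i, row in enumerate(rows):
        extents = layout_row(row, _focus_span_for_row(pileup, row, i == 0), cfg)
        y0 = i * cfg.row_height_px + pad
        y1 = (i + 1) * cfg.row_height_px - pad - 1
        # later-starting genes draw on top: row genes are in display order
        for arrow, gene in zip(extents, row.genes):
            arrow.color = colors.get(gene.family_id, BLACK) if gene.family_id else BLACK
            _draw_arrow(draw, arrow, y0, y1)
        layouts.append(extents)
    score = pileup.pair_score
    alpha = cfg.default_alpha if score is None else max(score, cfg.default_alpha)
    alpha = min(alpha, 1.0)
    rgba = np.dstack(
        [np.asarray(img, dtype=np.uint8),
         np.full((H, cfg.width_px), int(round(alpha * 255)), dtype=np.uint8)]
    )
    g1, g2 = pileup.focus_pair
    return RenderedExample(
        pixels=rgba,
        layout=layouts,
        provenance=(pileup.query_row.genome_id, g1.gene_id, g2.gene_id),
    )


def composite_on_white(pixels: np.ndarray) -> np.ndarray:
    """Flatten RGBA over a white background; the score becomes global fading."""
    if pixels.ndim != 3 or pixels.shape[2] not in (3, 4):
        raise RenderError(f"expected (H, W, 3|4) raster, got {pixels.shape}")
    if pixels.shape[2] == 3:
        return pixels.astype(np.uint8)
    rgb = pixels[..., :3].astype(np.float64)
    a = pixels[..., 3:4].astype(np.float64) / 255.0
    out = a * rgb + (1.0 - a) * 255.0
    return np.round(out).astype(np.uint8)


def mirror_example(example: RenderedExample) -> RenderedExample:
    """Horizontal flip; the only augmentation ever applied.  An involution."""
    W = example.pixels.shape[1]
    return RenderedExample(
        pixels=example.pixels[:, ::-1].copy(),
        layout=[[a.mirrored(W) for a in reversed(row)] for row in example.layout],
        label=example.label,
        provenance=example.provenance,
    )
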