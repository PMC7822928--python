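"""Comparative gene-neighborhood pileups.

A pileup stacks the query region (top row) over homologous regions from
reference genomes.  For each reference carrying a gene of the focus gene's
family, the flanking window around its best-matching such gene becomes one
row; rows are ordered by evolutionary distance to the query genome.  Rows
anchored on a reverse-strand gene are mirrored so the anchor points rightward,
as genome browsers do.

Evolutionary distance defaults to a sequence-free proxy: one minus the Jaccard
similarity of the genomes' gene-family sets.  A user-supplied genome order can
be used instead (``distance_mode="provided_order"``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .io import FORWARD, REVERSE, AdjacencyScores, Gene, GenomeAnnotation


class PileupError(ValueError):
    pass


@dataclass
class PileupConfig:
    flank_bp: int = 5000
    max_rows: int = 10
    distance_mode: str = "family_jaccard"  # or "provided_order"
    genome_order: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise PileupError("flank_bp must be positive")
        if self.max_rows < 1:
            raise PileupError("max_rows must be >= 1")
        if self.distance_mode not in ("family_jaccard", "provided_order"):
            raise PileupError(f"unknown distance_mode {self.distance_mode!r}")


@dataclass
class RegionRow:
    """One genome's slice of the pileup, in display orientation."""

    genome_id: str
    anchor_gene: Gene
    genes: list[Gene]
    window: tuple[str, int, int]  # contig, start, end (display coordinates)
    flipped: bool = False
    distance: float = 0.0

    def __post_init__(self) -> None:
        ids = {g.gene_id for g in self.genes}
        if self.anchor_gene.gene_id not in ids:
            raise PileupError("anchor gene must be among the row's genes")


@dataclass
class Pileup:
    query_row: RegionRow
    reference_rows: list[RegionRow]
    focus_pair: tuple[Gene, Gene]
    pair_score: Optional[float] = None

    @property
    def rows(self) -> list[RegionRow]:
        return [self.query_row, *self.reference_rows]


def _family_set(annotation: GenomeAnnotation, families: Mapping[str, str]) -> set[str]:
    return {families[g.gene_id] for g in annotation.genes if g.gene_id in families}


def genome_distance(
    a: GenomeAnnotation, b: GenomeAnnotation, families: Mapping[str, str]
) -> float:
    """1 - Jaccard similarity of the two genomes' family-id sets."""
    fa, fb = _family_set(a, families), _family_set(b, families)
    if not fa or not fb:
        missing = a.genome_id if not fa else b.genome_id
        raise PileupError(f"genome {missing} has no family assignments")
    return 1.0 - len(fa & fb) / len(fa | fb)


def flip_row(row: RegionRow) -> RegionRow:
    """Mirror a row about its window midpoint; an involution.

    Coordinates reflect within the window, strands toggle, and gene order
    reverses so display order still runs left to right.
    """
    contig, w0, w1 = row.window
    pivot = w0 + w1

    def mirror(g: Gene) -> Gene:
        return replace(
            g,
            start=pivot - g.end,
            end=pivot - g.start,
            strand=REVERSE if g.strand == FORWARD else FORWARD,
        )

    genes = [mirror(g) for g in reversed(row.genes)]
    anchor = mirror(row.anchor_gene)
    return RegionRow(
        genome_id=row.genome_id,
        anchor_gene=anchor,
        genes=genes,
        window=row.window,
        flipped=not row.flipped,
        distance=row.distance,
    )


def _window_genes(
    annotation: GenomeAnnotation, contig: str, start: int, end: int
) -> list[Gene]:
    return [
        g
        for g in annotation.by_contig().get(contig, [])
        if g.start < end and g.end > start
    ]


def _flank_families(
    annotation: GenomeAnnotation,
    anchor: Gene,
    families: Mapping[str, str],
    flank_bp: int,
) -> set[str]:
    genes = _window_genes(
        annotation, anchor.contig_id, anchor.start - flank_bp, anchor.end + flank_bp
    )
    return {
        families[g.gene_id]
        for g in genes
        if g.gene_id in families and g.gene_id != anchor.gene_id
    }


def _pick_anchor(
    annotation: GenomeAnnotation,
    candidates: list[Gene],
    query_flank: set[str],
    families: Mapping[str, str],
    flank_bp: int,
) -> Gene:
    """Among same-family candidates, pick the one whose flanking family set
    best matches the query flank (Jaccard); ties break on lowest gene_id."""

    def score(g: Gene) -> float:
        fl = _flank_families(annotation, g, families, flank_bp)
        union = fl | query_flank
        return len(fl & query_flank) / len(union) if union else 0.0

    return min(candidates, key=lambda g: (-score(g), g.gene_id))


def build_pileup(
    query_pair: tuple[Gene, Gene],
    query: GenomeAnnotation,
    references: Sequence[GenomeAnnotation],
    families: Mapping[str, str],
    scores: Optional[AdjacencyScores] = None,
    cfg: Optional[PileupConfig] = None,
) -> Pileup:
    """Build the comparative pileup for an adjacent query gene pair.

    The first gene of the pair is the focus gene: reference rows anchor on
    their best gene of the focus family.  References lacking that family
    contribute no row.  Rows sort by (genome distance, genome_id) and are
    truncated to ``max_rows - 1``.
    """
    cfg = cfg or PileupConfig()
    g1, g2 = query_pair
    if g1.contig_id != g2.contig_id:
        raise PileupError("query pair must lie on one contig")
    outer_start, outer_end = min(g1.start, g2.start), max(g1.end, g2.end)
    contig = g1.contig_id
    w0 = max(0, outer_start - cfg.flank_bp)
    w1 = outer_end + cfg.flank_bp
    clen = query.contig_lengths.get(contig)
    if clen is not None:
        w1 = min(w1, clen)
    query_row = RegionRow(
        genome_id=query.genome_id,
        anchor_gene=g1,
        genes=_window_genes(query, contig, w0, w1),
        window=(contig, w0, w1),
        flipped=False,
        distance=0.0,
    )

    focus_family = families.get(g1.gene_id, g1.family_id)
    pair_score = scores.get(g1.gene_id, g2.gene_id) if scores is not None else None
    if focus_family is None:
        return Pileup(query_row, [], (g1, g2), pair_score)

    query_flank = _flank_families(query, g1, families, cfg.flank_bp)
    rows: list[RegionRow] = []
    for ref in references:
        candidates = [
            g
            for g in ref.genes
            if families.get(g.gene_id, g.family_id) == focus_family
        ]
        if not candidates:
            continue
        anchor = _pick_anchor(ref, candidates, query_flank, families, cfg.flank_bp)
        r0 = max(0, anchor.start - cfg.flank_bp)
        r1 = anchor.end + cfg.flank_bp
        rlen = ref.contig_lengths.get(anchor.contig_id)
        if rlen is not None:
            r1 = min(r1, rlen)
        row = RegionRow(
            genome_id=ref.genome_id,
            anchor_gene=anchor,
            genes=_window_genes(ref, anchor.contig_id, r0, r1),
            window=(anchor.contig_id, r0, r1),
            flipped=False,
        )
        if cfg.distance_mode == "provided_order" and cfg.genome_order is not None:
            try:
                row.distance = float(cfg.genome_order.index(ref.genome_id) + 1)
            except ValueError:
                raise PileupError(
                    f"genome {ref.genome_id} missing from provided genome order"
                ) from None
        else:
            row.distance = genome_distance(query, ref, families)
        if anchor.strand == REVERSE:
            row = flip_row(row)
        rows.append(row)

    rows.sort(key=lambda r: (r.distance, r.genome_id))
    rows = rows[: cfg.max_rows - 1]
    return Pileup(query_row, rows, (g1, g2), pair_score)
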