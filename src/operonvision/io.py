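"""Domain types and file IO for annotations, family maps, association scores and operons.

Coordinates are stored 0-based half-open internally.  GFF3 files are read as
1-based inclusive and converted on the way in, and converted back on the way
out.  All readers transparently handle gzip-compressed files (``.gz`` suffix).

The intergenic distance of an adjacent gene pair is defined as
``start(downstream) - end(upstream)`` and is kept signed: overlapping genes,
common inside operons, yield negative gaps.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

FORWARD = "+"
REVERSE = "-"
_STRANDS = (FORWARD, REVERSE)


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending line."""


class AnnotationError(ValueError):
    """Raised when an annotation violates a structural invariant."""


@dataclass(frozen=True)
class Gene:
    """One annotated coding feature.

    ``start``/``end`` are 0-based half-open; ``strand`` is ``"+"`` or ``"-"``.
    ``family_id`` groups homologs across genomes (the coloring / anchoring key).
    """

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    family_id: Optional[str] = None
    function_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise AnnotationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


def intergenic_distance(upstream: Gene, downstream: Gene) -> int:
    """Signed gap in bp between two adjacent genes (negative when overlapping)."""
    return downstream.start - upstream.end


@dataclass
class GenomeAnnotation:
    """All genes of one genome, sorted by (contig, start)."""

    genome_id: str
    genes: list[Gene]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig_id, g.start, g.end))
        seen_ids: set[str] = set()
        seen_coords: set[tuple[str, int, int]] = set()
        for g in self.genes:
            if g.gene_id in seen_ids:
                raise AnnotationError(f"duplicate gene_id {g.gene_id} in {self.genome_id}")
            seen_ids.add(g.gene_id)
            coord = (g.contig_id, g.start, g.end)
            if coord in seen_coords:
                raise AnnotationError(f"duplicate coordinates {coord} in {self.genome_id}")
            seen_coords.add(coord)
        for contig, length in self.contig_lengths.items():
            for g in self.by_contig().get(contig, []):
                if g.end > length:
                    raise AnnotationError(
                        f"gene {g.gene_id} ends at {g.end} beyond contig "
                        f"{contig} length {length}"
                    )

    def by_contig(self) -> dict[str, list[Gene]]:
        out: dict[str, list[Gene]] = {}
        for g in self.genes:
            out.setdefault(g.contig_id, []).append(g)
        return out

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._index()[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id} not in genome {self.genome_id}") from None

    def _index(self) -> dict[str, Gene]:
        idx = getattr(self, "_gene_index", None)
        if idx is None or len(idx) != len(self.genes):
            idx = {g.gene_id: g for g in self.genes}
            object.__setattr__(self, "_gene_index", idx)
        return idx

    def __len__(self) -> int:
        return len(self.genes)

    def with_families(self, families: Mapping[str, str]) -> "GenomeAnnotation":
        """Return a copy whose genes carry ``family_id`` from the given map."""
        genes = [
            replace(g, family_id=families.get(g.gene_id, g.family_id)) for g in self.genes
        ]
        return GenomeAnnotation(self.genome_id, genes, dict(self.contig_lengths))


def consecutive_pairs(annotation: GenomeAnnotation) -> list[tuple[Gene, Gene]]:
    """Adjacent gene pairs per contig in coordinate order; never spans contigs."""
    pairs: list[tuple[Gene, Gene]] = []
    for genes in annotation.by_contig().values():
        pairs.extend(zip(genes, genes[1:]))
    return pairs


class AdjacencyScores:
    """Unordered-pair functional-association scores in [0, 1].

    Emulates combined association confidences distributed on a 0-1000 scale;
    the reader normalizes those to [0, 1].  Missing pairs return ``None`` and
    the renderer substitutes its default alpha.
    """

    def __init__(self, mapping: Optional[Mapping[tuple[str, str], float]] = None):
        self._scores: dict[tuple[str, str], float] = {}
        if mapping:
            for (a, b), s in mapping.items():
                self.set(a, b, s)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score for pair ({a}, {b}) outside [0,1]: {score}")
        self._scores[self._key(a, b)] = float(score)

    def get(self, a: str, b: str) -> Optional[float]:
        return self._scores.get(self._key(a, b))

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._scores.items()))

    def __len__(self) -> int:
        return len(self._scores)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AdjacencyScores) and self._scores == other._scores


@dataclass(frozen=True)
class OperonRecord:
    """A known operon: ordered gene ids on one genome, with a provenance tag."""

    genome_id: str
    gene_ids: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValueError("operon record needs at least one gene")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    @property
    def is_multi_gene(self) -> bool:
        return len(self.gene_ids) >= 2


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# GFF3 annotations
# ---------------------------------------------------------------------------

_GFF_TYPES = ("CDS", "gene")


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            continue
        k, v = chunk.split("=", 1)
        attrs[k] = v
    return attrs


def read_annotation(path: str | Path, genome_id: Optional[str] = None) -> GenomeAnnotation:
    """Read a GFF3 annotation into a :class:`GenomeAnnotation`.

    Features of type CDS are used when present, otherwise ``gene`` features.
    1-based inclusive GFF3 coordinates become 0-based half-open.  The genome id
    is taken from a ``##genome-id`` pragma if present, else the file stem.
    """
    path = Path(path)
    contig_lengths: dict[str, int] = {}
    rows: dict[str, list[tuple[str, int, int, str, str, Optional[str]]]] = {
        t: [] for t in _GFF_TYPES
    }
    gid = genome_id
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    contig_lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("##genome-id"):
                parts = line.split(None, 1)
                if len(parts) == 2 and gid is None:
                    gid = parts[1].strip()
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path.name} line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
            if ftype not in _GFF_TYPES:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"{path.name} line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if strand not in _STRANDS:
                raise ParseError(f"{path.name} line {lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attr_s)
            feat_id = attrs.get("ID") or attrs.get("locus_tag")
            if feat_id is None:
                raise ParseError(f"{path.name} line {lineno}: feature without ID/locus_tag")
            rows[ftype].append(
                (seqid, start1 - 1, end1, strand, feat_id, attrs.get("product"))
            )
    use = "CDS" if rows["CDS"] else "gene"
    if not rows[use]:
        raise ParseError(f"{path.name}: no CDS/gene features found (empty annotation)")
    gid = gid or path.name.removesuffix(".gz").rsplit(".", 1)[0]
    genes = [
        Gene(
            gene_id=fid,
            genome_id=gid,
            contig_id=seqid,
            start=s,
            end=e,
            strand=strand,
            function_label=product,
        )
        for seqid, s, e, strand, fid, product in rows[use]
    ]
    return GenomeAnnotation(gid, genes, contig_lengths)


def write_annotation(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write a GFF3 file that :func:`read_annotation` round-trips exactly."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##genome-id {annotation.genome_id}\n")
        for contig, length in sorted(annotation.contig_lengths.items()):
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.function_label:
                attrs += f";product={g.function_label}"
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "operonvision",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Association scores
# ---------------------------------------------------------------------------

def read_scores(path: str | Path, scale: str = "string1000") -> AdjacencyScores:
    """Read a 3-column TSV (gene_a, gene_b, score) of pair association scores.

    ``scale="string1000"`` (default) divides scores by 1000, matching the 0-1000
    combined-score convention; ``scale="unit"`` takes scores already in [0, 1].
    """
    if scale not in ("string1000", "unit"):
        raise ValueError(f"unknown score scale {scale!r}")
    scores = AdjacencyScores()
    path = Path(path)
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path.name} line {lineno}: expected 3 columns")
            a, b, s_raw = cols
            try:
                s = float(s_raw)
            except ValueError:
                raise ParseError(f"{path.name} line {lineno}: bad score {s_raw!r}") from None
            if scale == "string1000":
                s = s / 1000.0
            if not 0.0 <= s <= 1.0:
                raise ValueError(
                    f"{path.name} line {lineno}: score {s} outside [0,1] after normalization"
                )
            scores.set(a, b, s)
    return scores


def write_scores(scores: AdjacencyScores, path: str | Path, scale: str = "unit") -> None:
    with _open(path, "wt") as fh:
        for (a, b), s in scores.items():
            out = s * 1000.0 if scale == "string1000" else s
            fh.write(f"{a}\t{b}\t{out!r}\n")


# ---------------------------------------------------------------------------
# Gene family map
# ---------------------------------------------------------------------------

def read_families(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping gene_id to family_id."""
    families: dict[str, str] = {}
    path = Path(path)
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ParseError(f"{path.name} line {lineno}: expected 2 columns")
            families[cols[0]] = cols[1]
    return families


def write_families(families: Mapping[str, str], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for gid in sorted(families):
            fh.write(f"{gid}\t{families[gid]}\n")


# ---------------------------------------------------------------------------
# Operon lists
# ---------------------------------------------------------------------------

def read_operons(path: str | Path) -> list[OperonRecord]:
    """Read operons from TSV: genome_id <tab> comma-joined gene ids <tab> source."""
    records: list[OperonRecord] = []
    path = Path(path)
    with _open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise ParseError(f"{path.name} line {lineno}: expected 2-3 columns")
            source = cols[2] if len(cols) == 3 else ""
            gene_ids = tuple(g for g in cols[1].split(",") if g)
            if not gene_ids:
                raise ParseError(f"{path.name} line {lineno}: operon with no genes")
            records.append(OperonRecord(cols[0], gene_ids, source))
    return records


def write_operons(records: Iterable[OperonRecord], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f"{rec.genome_id}\t{','.join(rec.gene_ids)}\t{rec.source}\n")


def validate_operons(
    annotation: GenomeAnnotation, records: Iterable[OperonRecord]
) -> None:
    """Check operons are consecutive on one contig; warn on mixed strands.

    Raises :class:`AnnotationError` for records whose genes are missing or not
    consecutive in the annotation.  Strand inconsistency only warns, since
    curated operon lists occasionally include mis-stranded members.
    """
    order = {g.gene_id: i for i, g in enumerate(annotation.genes)}
    contig = {g.gene_id: g.contig_id for g in annotation.genes}
    for rec in records:
        missing = [g for g in rec.gene_ids if g not in order]
        if missing:
            raise AnnotationError(f"operon {rec.gene_ids}: unknown genes {missing}")
        contigs = {contig[g] for g in rec.gene_ids}
        if len(contigs) > 1:
            raise AnnotationError(f"operon {rec.gene_ids}: spans contigs {sorted(contigs)}")
        idx = [order[g] for g in rec.gene_ids]
        if sorted(idx) != list(range(min(idx), max(idx) + 1)) or idx != sorted(idx):
            raise AnnotationError(
                f"operon {rec.gene_ids}: genes not consecutive in annotation order"
            )
        strands = {annotation.gene(g).strand for g in rec.gene_ids}
        if len(strands) > 1:
            warnings.warn(
                f"operon {rec.gene_ids} mixes strands; kept as-is", stacklevel=2
            )
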