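"""Labeled, balanced datasets of operonic and non-operonic gene-pair images.

Labeling convention: every consecutive pair inside a multi-gene known operon
is operonic; the pairs joining an operon boundary gene to its outside neighbor
are non-operonic.  Single-gene operons contribute nothing to training sets but
their two flanking pairs are non-operonic in test sets.  A boundary pair whose
outside neighbor belongs to another multi-gene operon is dropped rather than
labeled, since calling it non-operonic would contradict the other operon.
Pairs not reached by any rule stay unlabeled and are omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import Gene, GenomeAnnotation, OperonRecord, consecutive_pairs, validate_operons
from .render import RenderedExample, mirror_example

OPERONIC = "operonic"
NON_OPERONIC = "non_operonic"


class LabelingError(ValueError):
    pass


class BalanceError(ValueError):
    pass


@dataclass(frozen=True)
class LabeledPair:
    genome_id: str
    gene_a: str
    gene_b: str
    label: str
    source_operon: Optional[OperonRecord] = None


@dataclass
class ManifestEntry:
    image: object  # path string or in-memory RenderedExample
    label: str
    genome_id: str
    gene_a: str
    gene_b: str


@dataclass
class DatasetManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {OPERONIC: 0, NON_OPERONIC: 0}
        for e in self.entries:
            counts[e.label] = counts.get(e.label, 0) + 1
        return counts

    def per_genome_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for e in self.entries:
            out.setdefault(e.genome_id, {OPERONIC: 0, NON_OPERONIC: 0})
            out[e.genome_id][e.label] += 1
        return out

    def genomes(self) -> list[str]:
        return sorted({e.genome_id for e in self.entries})

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("image_path\tlabel\tgenome_id\tgene_a\tgene_b\n")
            for e in self.entries:
                if not isinstance(e.image, str):
                    raise ValueError("only path-backed manifests can be written")
                fh.write(f"{e.image}\t{e.label}\t{e.genome_id}\t{e.gene_a}\t{e.gene_b}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DatasetManifest":
        entries = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("image_path"):
                raise ValueError(f"{path}: missing manifest header")
            for line in fh:
                img, label, genome, ga, gb = line.rstrip("\n").split("\t")
                entries.append(ManifestEntry(img, label, genome, ga, gb))
        return cls(entries)


def label_pairs(
    annotation: GenomeAnnotation,
    operons: Sequence[OperonRecord],
    mode: str = "train",
) -> list[LabeledPair]:
    """Assign operonic / non-operonic labels to consecutive gene pairs."""
    if mode not in ("train", "test"):
        raise ValueError(f"mode must be 'train' or 'test', got {mode!r}")
    multi = [op for op in operons if op.is_multi_gene]
    single = [op for op in operons if not op.is_multi_gene]
    try:
        validate_operons(annotation, operons)
    except Exception as exc:  # re-raise with the offending operon named
        raise LabelingError(str(exc)) from exc

    by_contig = annotation.by_contig()
    position: dict[str, tuple[str, int]] = {}
    for contig, genes in by_contig.items():
        for i, g in enumerate(genes):
            position[g.gene_id] = (contig, i)

    in_multi: dict[str, OperonRecord] = {}
    for op in multi:
        for gid in op.gene_ids:
            if gid in in_multi:
                raise LabelingError(
                    f"gene {gid} belongs to two operons: {in_multi[gid].gene_ids} "
                    f"and {op.gene_ids}"
                )
            in_multi[gid] = op

    labels: dict[tuple[str, str], LabeledPair] = {}

    def neighbor(gid: str, offset: int) -> Optional[Gene]:
        contig, i = position[gid]
        genes = by_contig[contig]
        j = i + offset
        return genes[j] if 0 <= j < len(genes) else None

    def put(a: str, b: str, label: str, source: Optional[OperonRecord]) -> None:
        key = (a, b)
        prior = labels.get(key)
        if prior is not None and prior.label != label:
            raise LabelingError(f"pair {key} labeled both {prior.label} and {label}")
        labels[key] = LabeledPair(annotation.genome_id, a, b, label, source)

    for op in multi:
        # operon gene order may be reverse of coordinate order; normalize
        ordered = sorted(op.gene_ids, key=lambda g: position[g][1])
        for a, b in zip(ordered, ordered[1:]):
            put(a, b, OPERONIC, op)

    def boundary_pair(inside_gid: str, offset: int, source: OperonRecord) -> None:
        out_gene = neighbor(inside_gid, offset)
        if out_gene is None:
            return
        if out_gene.gene_id in in_multi:
            return  # would contradict the other operon: drop
        a, b = (out_gene.gene_id, inside_gid) if offset < 0 else (inside_gid, out_gene.gene_id)
        if (a, b) in labels and labels[(a, b)].label == OPERONIC:
            return
        put(a, b, NON_OPERONIC, source)

    for op in multi:
        ordered = sorted(op.gene_ids, key=lambda g: position[g][1])
        boundary_pair(ordered[0], -1, op)
        boundary_pair(ordered[-1], +1, op)

    if mode == "test":
        for op in single:
            gid = op.gene_ids[0]
            boundary_pair(gid, -1, op)
            boundary_pair(gid, +1, op)

    out: list[LabeledPair] = []
    for g1, g2 in consecutive_pairs(annotation):
        lp = labels.get((g1.gene_id, g2.gene_id))
        if lp is not None:
            out.append(lp)
    return out


def balance(pairs: Sequence[LabeledPair], seed: int) -> list[LabeledPair]:
    """Subsample the majority class uniformly (without replacement) to parity."""
    pos = [p for p in pairs if p.label == OPERONIC]
    neg = [p for p in pairs if p.label == NON_OPERONIC]
    if not pos or not neg:
        raise BalanceError(
            f"both classes required for balancing, got {len(pos)} operonic "
            f"and {len(neg)} non-operonic"
        )
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))

    def sample(items: list[LabeledPair]) -> list[LabeledPair]:
        if len(items) == n:
            return list(items)
        keep = set(rng.choice(len(items), size=n, replace=False).tolist())
        return [p for i, p in enumerate(items) if i in keep]

    kept = set()
    for p in sample(pos) + sample(neg):
        kept.add((p.gene_a, p.gene_b))
    return [p for p in pairs if (p.gene_a, p.gene_b) in kept]


def balance_manifest(manifest: DatasetManifest, seed: int) -> DatasetManifest:
    """Balance a manifest globally (across genomes), preserving entry order."""
    pos = [e for e in manifest.entries if e.label == OPERONIC]
    neg = [e for e in manifest.entries if e.label == NON_OPERONIC]
    if not pos or not neg:
        raise BalanceError("both classes required for balancing")
    rng = np.random.default_rng(seed)
    n = min(len(pos), len(neg))

    def pick(items: list[ManifestEntry]) -> set[int]:
        if len(items) == n:
            return {id(e) for e in items}
        keep = rng.choice(len(items), size=n, replace=False)
        return {id(items[i]) for i in keep}

    kept = pick(pos) | pick(neg)
    return DatasetManifest([e for e in manifest.entries if id(e) in kept])


def augment(example: RenderedExample) -> list[RenderedExample]:
    """The one permitted augmentation: [original, horizontal mirror]."""
    return [example, mirror_example(example)]


def organism_of(genome_id: str) -> str:
    """Organism key for leave-one-out grouping: genus + species prefix."""
    tokens = genome_id.split()
    return " ".join(tokens[:2]) if len(tokens) >= 2 else genome_id


def split_leave_one_genome_out(
    manifest: DatasetManifest, holdout_genome: str
) -> tuple[DatasetManifest, DatasetManifest]:
    """Split so no training image comes from the held-out organism."""
    genomes = set(manifest.genomes())
    if holdout_genome not in genomes and organism_of(holdout_genome) not in {
        organism_of(g) for g in genomes
    }:
        raise ValueError(f"holdout genome {holdout_genome!r} not in manifest")
    org = organism_of(holdout_genome)
    train = [e for e in manifest.entries if organism_of(e.genome_id) != org]
    test = [e for e in manifest.entries if organism_of(e.genome_id) == org]
    return DatasetManifest(train), DatasetManifest(test)


def train_fraction(train: DatasetManifest, test: DatasetManifest) -> float:
    total = len(train) + len(test)
    if total == 0:
        raise ValueError("empty split")
    return len(train) / total


def build_image_manifest(
    annotation: GenomeAnnotation,
    references: Sequence[GenomeAnnotation],
    families: Mapping[str, str],
    scores,
    operons: Sequence[OperonRecord],
    mode: str = "train",
    pileup_cfg=None,
    render_cfg=None,
    image_dir: Optional[str | Path] = None,
) -> DatasetManifest:
    """Label a genome's pairs and render one image per labeled pair.

    With ``image_dir`` set, PNGs (plus layout sidecar JSON) are written and
    the manifest holds paths; otherwise images stay in memory.
    """
    from .compare_region import build_pileup
    from .render import png_name, render

    ann = annotation.with_families(dict(families))
    labeled = label_pairs(ann, operons, mode=mode)
    entries: list[ManifestEntry] = []
    for lp in labeled:
        pair = (ann.gene(lp.gene_a), ann.gene(lp.gene_b))
        pile = build_pileup(pair, ann, references, families, scores, pileup_cfg)
        example = render(pile, render_cfg)
        example.label = lp.label
        image: object = example
        if image_dir is not None:
            image_dir = Path(image_dir)
            image_dir.mkdir(parents=True, exist_ok=True)
            path = image_dir / png_name(example)
            example.to_png(path)
            example.save_layout(path.with_suffix(".json"))
            image = str(path)
        entries.append(
            ManifestEntry(image, lp.label, lp.genome_id, lp.gene_a, lp.gene_b)
        )
    return DatasetManifest(entries)
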