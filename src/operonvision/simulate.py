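"""Synthetic pangenomes with planted operon structure.

The simulator emits everything the pipeline consumes — a query genome
annotation, reference-relative annotations, a gene-family map, pair
association scores, and the truth operon list — with no nucleotide sequence:
the method is purely structural.  Planted operons are co-stranded runs of
2-6 genes with tight (often overlapping) intergenic gaps, strongly conserved
in the reference relatives, and high pair scores; operon boundaries get wide
gaps, frequent strand flips, weak conservation and low scores.  This is the
stated world the classifier is expected to learn.

Reference genomes carry the query's family order with per-gene retention
probability (higher inside operons), gene-length jitter, and novel random
families in the non-conserved slots.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .io import (
    FORWARD,
    REVERSE,
    AdjacencyScores,
    Gene,
    GenomeAnnotation,
    OperonRecord,
    consecutive_pairs,
    write_annotation,
    write_families,
    write_operons,
    write_scores,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Generator parameters; defaults are the stated synthetic world.

    Gaps are in bp and signed (operonic pairs may overlap).  Conservation is
    the per-gene, per-relative probability that a reference genome retains the
    query gene's family at its slot.
    """

    n_reference_genomes: int = 5
    n_contigs: int = 1
    genes_per_contig: int = 60
    operon_lengths: tuple[int, ...] = (2, 3, 4, 5, 6)
    operon_length_probs: tuple[float, ...] = (0.35, 0.30, 0.15, 0.10, 0.10)
    operon_block_prob: float = 0.6
    single_gene_operon_prob: float = 0.1
    operonic_gap_bp: tuple[int, int] = (-10, 30)
    non_operonic_gap_bp: tuple[int, int] = (80, 400)
    gene_length_bp: tuple[int, int] = (300, 1500)
    length_jitter: tuple[float, float] = (0.8, 1.2)
    strand_flip_prob_at_boundary: float = 0.7
    conservation_operon: float = 0.9
    conservation_boundary: float = 0.3
    score_operonic: tuple[float, float] = (0.7, 1.0)
    score_boundary: tuple[float, float] = (0.0, 0.3)
    missing_score_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.operon_block_prob,
            self.single_gene_operon_prob,
            self.strand_flip_prob_at_boundary,
            self.conservation_operon,
            self.conservation_boundary,
            self.missing_score_prob,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise SimulationError("probabilities must lie in [0, 1]")
        if len(self.operon_lengths) != len(self.operon_length_probs):
            raise SimulationError("operon length distribution is misaligned")
        if abs(sum(self.operon_length_probs) - 1.0) > 1e-9:
            raise SimulationError("operon length probabilities must sum to 1")
        if max(self.operon_lengths) > self.genes_per_contig:
            raise SimulationError(
                "infeasible config: an operon would be longer than a contig"
            )
        for lo, hi in (self.operonic_gap_bp, self.non_operonic_gap_bp,
                       self.gene_length_bp):
            if hi < lo:
                raise SimulationError(f"empty range ({lo}, {hi})")


@dataclass
class SimResult:
    query: GenomeAnnotation
    references: list[GenomeAnnotation]
    families: dict[str, str]
    scores: AdjacencyScores
    operons: list[OperonRecord]

    def all_annotations(self) -> list[GenomeAnnotation]:
        return [self.query, *self.references]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ann in self.all_annotations():
            write_annotation(ann, outdir / f"{ann.genome_id.replace(' ', '-')}.gff3")
        write_families(self.families, outdir / "families.tsv")
        write_scores(self.scores, outdir / "scores.tsv")
        write_operons(self.operons, outdir / "operons.tsv")


def _sample_gap(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def simulate(
    cfg: Optional[SimConfig] = None, organism: str = "Simulatus modelus"
) -> SimResult:
    """Generate one pangenome: a query genome plus reference relatives.

    Deterministic for a fixed config (seed included).  Genome ids share the
    ``organism`` prefix so leave-one-organism-out grouping keeps a query and
    its relatives together.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    qid = f"{organism} query"

    genes: list[Gene] = []
    families: dict[str, str] = {}
    operons: list[OperonRecord] = []
    # per-gene block info for reference construction and scoring
    block_of: dict[str, int] = {}
    in_operon: dict[str, bool] = {}

    gene_counter = 0
    block_counter = 0
    for ci in range(cfg.n_contigs):
        contig = f"contig{ci + 1}"
        pos = 100
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        n_in_contig = 0
        first_block = True
        while n_in_contig < cfg.genes_per_contig:
            if not first_block and rng.random() < cfg.strand_flip_prob_at_boundary:
                strand = REVERSE if strand == FORWARD else FORWARD
            is_operon = rng.random() < cfg.operon_block_prob
            if is_operon:
                block_len = int(
                    rng.choice(cfg.operon_lengths, p=cfg.operon_length_probs)
                )
                block_len = min(block_len, cfg.genes_per_contig - n_in_contig)
                is_operon = block_len >= 2
            if not is_operon:
                block_len = 1
            block_ids: list[str] = []
            for j in range(block_len):
                gap = (
                    _sample_gap(rng, cfg.non_operonic_gap_bp)
                    if j == 0
                    else _sample_gap(rng, cfg.operonic_gap_bp)
                )
                start = pos + gap if not (first_block and j == 0) else pos
                start = max(start, (genes[-1].start + 1) if genes else 0)
                length = _sample_gap(rng, cfg.gene_length_bp)
                gid = f"{qid.replace(' ', '_')}_{gene_counter:05d}"
                fam = f"fam{gene_counter:05d}"
                genes.append(
                    Gene(
                        gene_id=gid,
                        genome_id=qid,
                        contig_id=contig,
                        start=start,
                        end=start + length,
                        strand=strand,
                        family_id=fam,
                    )
                )
                families[gid] = fam
                block_of[gid] = block_counter
                in_operon[gid] = is_operon
                block_ids.append(gid)
                pos = start + length
                gene_counter += 1
                n_in_contig += 1
            if is_operon:
                operons.append(OperonRecord(qid, tuple(block_ids), source="planted"))
            elif rng.random() < cfg.single_gene_operon_prob:
                operons.append(OperonRecord(qid, tuple(block_ids), source="planted-single"))
            block_counter += 1
            first_block = False

    contig_lengths = {}
    for g in genes:
        contig_lengths[g.contig_id] = max(
            contig_lengths.get(g.contig_id, 0), g.end + 500
        )
    query = GenomeAnnotation(qid, genes, contig_lengths)

    # ------------------------------------------------------------------ scores
    scores = AdjacencyScores()
    for a, b in consecutive_pairs(query):
        if rng.random() < cfg.missing_score_prob:
            continue
        same_operon = (
            in_operon[a.gene_id]
            and in_operon[b.gene_id]
            and block_of[a.gene_id] == block_of[b.gene_id]
        )
        lo, hi = cfg.score_operonic if same_operon else cfg.score_boundary
        scores.set(a.gene_id, b.gene_id, float(rng.uniform(lo, hi)))

    # -------------------------------------------------------------- references
    references: list[GenomeAnnotation] = []
    for r in range(cfg.n_reference_genomes):
        rid = f"{organism} ref{r + 1}"
        rgenes: list[Gene] = []
        rpos: dict[str, int] = {}
        k = 0
        for contig, qgenes in query.by_contig().items():
            pos = 100
            prev_block: Optional[int] = None
            for qg in qgenes:
                cons_p = (
                    cfg.conservation_operon
                    if in_operon[qg.gene_id]
                    else cfg.conservation_boundary
                )
                conserved = rng.random() < cons_p
                same_block = prev_block is not None and block_of[qg.gene_id] == prev_block
                gap = _sample_gap(
                    rng, cfg.operonic_gap_bp if same_block else cfg.non_operonic_gap_bp
                )
                start = pos + gap if rgenes and rgenes[-1].contig_id == contig else pos
                if rgenes and rgenes[-1].contig_id == contig:
                    start = max(start, rgenes[-1].start + 1)
                if conserved:
                    length = max(
                        50, int(round(qg.length * rng.uniform(*cfg.length_jitter)))
                    )
                    strand = qg.strand
                    fam = families[qg.gene_id]
                else:
                    length = _sample_gap(rng, cfg.gene_length_bp)
                    strand = FORWARD if rng.random() < 0.5 else REVERSE
                    fam = f"novel_{rid.replace(' ', '_')}_{k:05d}"
                gid = f"{rid.replace(' ', '_')}_{k:05d}"
                rgenes.append(
                    Gene(
                        gene_id=gid,
                        genome_id=rid,
                        contig_id=contig,
                        start=start,
                        end=start + length,
                        strand=strand,
                        family_id=fam,
                    )
                )
                families[gid] = fam
                rpos[gid] = start
                pos = start + length
                prev_block = block_of[qg.gene_id]
                k += 1
        rlengths = {}
        for g in rgenes:
            rlengths[g.contig_id] = max(rlengths.get(g.contig_id, 0), g.end + 500)
        references.append(GenomeAnnotation(rid, rgenes, rlengths))

    return SimResult(query, references, families, scores, operons)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

UNIT_SCALE = "unit"
INTEGRATION_SCALE = "integration"


def fixture_config(scale: str, seed: int = 0) -> SimConfig:
    if scale == UNIT_SCALE:
        # 3 genomes x 60 genes: query + 2 relatives
        return SimConfig(n_reference_genomes=2, genes_per_contig=60, seed=seed)
    if scale == INTEGRATION_SCALE:
        # per organism: a 400-gene query + 3 relatives
        return SimConfig(n_reference_genomes=3, genes_per_contig=400, seed=seed)
    raise SimulationError(f"unknown fixture scale {scale!r}")


def make_fixture(
    scale: str,
    outdir: Optional[str | Path] = None,
    seed: int = 0,
    n_organisms: int = 1,
) -> list[SimResult]:
    """Build one or more organisms' pangenomes at a named scale.

    ``integration`` scale with ``n_organisms=6`` is sized so that training on
    five organisms and holding one out finishes in minutes on one CPU while
    leaving enough planted signal to recover operons.  Seeds derive from
    ``seed`` so distinct organisms are independent but reproducible.
    """
    results = []
    for i in range(n_organisms):
        cfg = fixture_config(scale, seed=(seed * 1009 + i * 7919) % (2**31 - 1))
        organism = f"Simulatus org{i + 1}" if n_organisms > 1 else "Simulatus modelus"
        res = simulate(cfg, organism=organism)
        if outdir is not None:
            res.write(Path(outdir) / organism.replace(" ", "-"))
        results.append(res)
    return results
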