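"""Merging per-pair calls into full operon predictions.

Maximal runs of consecutive operonic pair calls on one contig become one
predicted operon each; a predicted operon has at least two genes.  Pairs with
no call at all count as non-operonic, so missing predictions break runs rather
than bridging them.  No post-hoc strand filter is applied: strand is already
encoded in the images the classifier saw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from .classifier import PairCall, PairImageClassifier, predict_pairs
from .compare_region import PileupConfig, build_pileup
from .dataset import OPERONIC
from .io import AdjacencyScores, GenomeAnnotation, consecutive_pairs
from .render import RenderConfig, render


class AssemblyError(ValueError):
    pass


@dataclass(frozen=True)
class OperonPrediction:
    genome_id: str
    contig_id: str
    gene_ids: tuple[str, ...]
    mean_probability: float

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise AssemblyError("a predicted operon needs at least two genes")


def assemble(
    calls: Sequence[PairCall], annotation: GenomeAnnotation
) -> list[OperonPrediction]:
    """Run-length merge operonic pair calls into operon predictions."""
    known = {g.gene_id for g in annotation.genes}
    adjacency = {
        (a.gene_id, b.gene_id) for a, b in consecutive_pairs(annotation)
    }
    call_map: dict[tuple[str, str], PairCall] = {}
    for c in calls:
        if c.gene_a not in known or c.gene_b not in known:
            raise AssemblyError(
                f"call references unknown genes ({c.gene_a}, {c.gene_b})"
            )
        if (c.gene_a, c.gene_b) not in adjacency:
            raise AssemblyError(
                f"call pair ({c.gene_a}, {c.gene_b}) is not an adjacent pair"
            )
        call_map[(c.gene_a, c.gene_b)] = c

    predictions: list[OperonPrediction] = []
    for contig, genes in annotation.by_contig().items():
        run_genes: list[str] = []
        run_probs: list[float] = []

        def flush() -> None:
            if len(run_genes) >= 2:
                predictions.append(
                    OperonPrediction(
                        genome_id=annotation.genome_id,
                        contig_id=contig,
                        gene_ids=tuple(run_genes),
                        mean_probability=sum(run_probs) / len(run_probs),
                    )
                )
            run_genes.clear()
            run_probs.clear()

        for a, b in zip(genes, genes[1:]):
            call = call_map.get((a.gene_id, b.gene_id))
            if call is not None and call.call == OPERONIC:
                if not run_genes:
                    run_genes.append(a.gene_id)
                run_genes.append(b.gene_id)
                run_probs.append(call.probability)
            else:
                flush()
        flush()
    return predictions


def predict_genome(
    annotation: GenomeAnnotation,
    references: Sequence[GenomeAnnotation],
    families: dict[str, str],
    scores: Optional[AdjacencyScores],
    model: PairImageClassifier,
    pileup_cfg: Optional[PileupConfig] = None,
    render_cfg: Optional[RenderConfig] = None,
    threshold: float = 0.5,
) -> tuple[list[OperonPrediction], list[PairCall]]:
    """End-to-end prediction: pairs -> pileups -> images -> calls -> operons."""
    pileup_cfg = pileup_cfg or PileupConfig()
    render_cfg = render_cfg or RenderConfig()
    ann = annotation.with_families(families)
    pairs = consecutive_pairs(ann)
    if not pairs:
        return [], []
    examples = []
    for pair in pairs:
        try:
            pile = build_pileup(pair, ann, references, families, scores, pileup_cfg)
            examples.append(render(pile, render_cfg))
        except Exception as exc:
            raise AssemblyError(
                f"pileup/render failed for pair ({pair[0].gene_id}, "
                f"{pair[1].gene_id}): {exc}"
            ) from exc
    try:
        calls = predict_pairs(model, examples, threshold=threshold)
    except Exception as exc:
        raise AssemblyError(f"classification failed: {exc}") from exc
    return assemble(calls, ann), calls


def write_predictions_tsv(
    predictions: Sequence[OperonPrediction], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome_id\tcontig\tfirst_gene\tlast_gene\tgene_ids\tmean_probability\n"
        )
        for p in predictions:
            fh.write(
                f"{p.genome_id}\t{p.contig_id}\t{p.gene_ids[0]}\t{p.gene_ids[-1]}\t"
                f"{','.join(p.gene_ids)}\t{p.mean_probability:.6f}\n"
            )


def write_predictions_gff3(
    predictions: Sequence[OperonPrediction],
    annotation: GenomeAnnotation,
    path: str | Path,
) -> None:
    """Write predictions as GFF3 ``operon`` features spanning member genes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, p in enumerate(predictions, start=1):
            genes = [annotation.gene(g) for g in p.gene_ids]
            start = min(g.start for g in genes) + 1
            end = max(g.end for g in genes)
            strand = genes[0].strand
            fh.write(
                f"{p.contig_id}\toperonvision\toperon\t{start}\t{end}\t"
                f"{p.mean_probability:.4f}\t{strand}\t.\t"
                f"ID=operon_{i};genes={','.join(p.gene_ids)}\n"
            )
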