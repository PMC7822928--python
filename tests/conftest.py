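import pytest

from operonvision.dataset import DatasetManifest, balance_manifest, build_image_manifest
from operonvision.classifier import train
from operonvision.io import Gene, GenomeAnnotation
from operonvision.simulate import fixture_config, make_fixture, simulate


def build_annotation(spec, genome_id="Testus organismus query", contig_len=None):
    """Build a GenomeAnnotation from (gene_id, contig, start, end, strand) tuples."""
    genes = [
        Gene(gene_id=g, genome_id=genome_id, contig_id=c, start=s, end=e, strand=st)
        for g, c, s, e, st in spec
    ]
    lengths = {}
    for g in genes:
        lengths[g.contig_id] = max(lengths.get(g.contig_id, 0), g.end + 100)
    if contig_len:
        lengths.update(contig_len)
    return GenomeAnnotation(genome_id, genes, lengths)


def evenly_spaced(n, genome_id="Testus organismus query", contig="c1", strand="+",
                  length=900, gap=100, start=100):
    """n same-strand genes g1..gn with uniform spacing on one contig."""
    spec = []
    pos = start
    for i in range(1, n + 1):
        spec.append((f"g{i}", contig, pos, pos + length, strand))
        pos += length + gap
    return build_annotation(spec, genome_id=genome_id)


@pytest.fixture(scope="session")
def unit_sim():
    """One small pangenome: 60-gene query + 2 relatives, planted operons."""
    return simulate(fixture_config("unit", seed=7), organism="Simulatus unitorg")


@pytest.fixture(scope="session")
def small_training_run():
    """Three tiny organisms: a model trained on two, the third held out.

    Returned as (model, balanced training manifest, list of SimResults).
    """
    orgs = make_fixture("unit", n_organisms=3, seed=5)
    entries = []
    for res in orgs[:2]:
        m = build_image_manifest(
            res.query, res.references, res.families, res.scores, res.operons,
            mode="train",
        )
        entries.extend(m.entries)
    manifest = balance_manifest(DatasetManifest(entries), seed=0)
    model = train(manifest)
    return model, manifest, orgs
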