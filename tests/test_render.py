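"""Renderer tests: layout maps, family colors, alpha encoding, purity."""

import io as _io

import numpy as np
import pytest

from operonvision.compare_region import Pileup, RegionRow, build_pileup
from operonvision.io import Gene, consecutive_pairs
from operonvision.render import (
    BLACK,
    BLUE,
    RED,
    RenderConfig,
    RenderError,
    assign_colors,
    composite_on_white,
    layout_row,
    mirror_example,
    render,
)


def _gene(gid, start, end, strand="+", fam=None):
    return Gene(gid, "Q query", "c1", start, end, strand, family_id=fam)


def _single_gene_row(gene, window):
    return RegionRow("Q query", anchor_gene=gene, genes=[gene], window=window)


class TestLayoutRow:
    def test_central_linear_map(self):
        """Hand-computed oracle: width 512, central span [2000, 6000).

        cx0 = 512/6 = 85.33 -> 85; a gene covering the left half of the span
        ends at 85.33 + 0.5 * 341.33 = 256.0 -> 256.
        """
        g = _gene("g", 2000, 4000)
        row = _single_gene_row(g, ("c1", 0, 8000))
        (ext,) = layout_row(row, (2000, 6000), RenderConfig())
        assert (ext.x0, ext.x1) == (85, 256)
        assert ext.head_right

    def test_gene_filling_central_span(self):
        g = _gene("g", 2000, 6000)
        row = _single_gene_row(g, ("c1", 0, 8000))
        (ext,) = layout_row(row, (2000, 6000), RenderConfig())
        # round(512/6), round(512*5/6)
        assert (ext.x0, ext.x1) == (85, 427)

    def test_reverse_strand_head_left(self):
        g = _gene("g", 2000, 4000, strand="-")
        row = _single_gene_row(g, ("c1", 0, 8000))
        (ext,) = layout_row(row, (2000, 6000), RenderConfig())
        assert not ext.head_right

    def test_flank_genes_compress_into_margins(self):
        left = _gene("l", 0, 1000)
        mid = _gene("m", 2000, 6000)
        right = _gene("r", 7000, 8000)
        row = RegionRow("Q query", anchor_gene=mid, genes=[left, mid, right],
                        window=("c1", 0, 8000))
        exts = layout_row(row, (2000, 6000), RenderConfig())
        cfg = RenderConfig()
        cx0, cx1 = cfg.central_band
        assert exts[0].x1 <= round(cx0)
        assert exts[2].x0 >= round(cx1)

    def test_zero_length_window_is_an_error(self):
        g = _gene("g", 10, 20)
        row = RegionRow("Q query", anchor_gene=g, genes=[g], window=("c1", 50, 50))
        with pytest.raises(RenderError, match="window"):
            layout_row(row, (10, 20), RenderConfig())

    def test_pixel_order_follows_display_order(self):
        genes = [_gene(f"g{i}", 1000 * i, 1000 * i + 800) for i in range(6)]
        row = RegionRow("Q query", anchor_gene=genes[2], genes=genes,
                        window=("c1", 0, 6000))
        exts = layout_row(row, (2000, 3800), RenderConfig())
        starts = [e.x0 for e in exts]
        assert starts == sorted(starts)


def _pileup_two_genes(score=None, extra_rows=()):
    g1 = _gene("q1", 2000, 2900, fam="famA")
    g2 = _gene("q2", 3000, 3900, fam="famB")
    row = RegionRow("Q query", anchor_gene=g1, genes=[g1, g2], window=("c1", 0, 6000))
    return Pileup(row, list(extra_rows), (g1, g2), pair_score=score)


class TestAssignColors:
    def test_query_families_blue_red_only(self):
        pile = _pileup_two_genes()
        colors = assign_colors(pile, RenderConfig())
        assert colors["famA"] == BLUE
        assert colors["famB"] == RED
        assert set(colors) == {"famA", "famB"}

    def test_palette_threshold(self):
        """Families beyond palette_size most frequent go black (absent)."""
        rows = []
        counts = {"famX": 5, "famY": 3, "famZ": 1}
        genes = []
        pos = 0
        for fam, n in counts.items():
            for i in range(n):
                genes.append(_gene(f"{fam}_{i}", pos, pos + 50, fam=fam))
                pos += 60
        rows.append(RegionRow("R ref", anchor_gene=genes[0], genes=genes,
                              window=("c1", 0, pos)))
        pile = _pileup_two_genes(extra_rows=rows)
        cfg = RenderConfig(palette_size=2)
        colors = assign_colors(pile, cfg)
        assert "famX" in colors and "famY" in colors
        assert "famZ" not in colors  # rendered black
        assert colors["famX"] != colors["famY"]
        assert not {colors["famX"], colors["famY"]} & {BLUE, RED, BLACK}

    def test_deterministic(self):
        pile = _pileup_two_genes()
        cfg = RenderConfig()
        assert assign_colors(pile, cfg) == assign_colors(pile, cfg)


class TestRender:
    def test_default_alpha_when_score_missing(self):
        ex = render(_pileup_two_genes(score=None))
        assert np.all(ex.pixels[..., 3] == round(0.1 * 255))
        assert ex.alpha == pytest.approx(0.1, abs=0.005)

    def test_full_score_opaque(self):
        ex = render(_pileup_two_genes(score=1.0))
        assert np.all(ex.pixels[..., 3] == 255)

    def test_score_clamped_to_default_minimum(self):
        ex = render(_pileup_two_genes(score=0.03))
        assert np.all(ex.pixels[..., 3] == round(0.1 * 255))

    def test_single_row_height(self):
        cfg = RenderConfig()
        ex = render(_pileup_two_genes(), cfg)
        assert ex.pixels.shape == (cfg.row_height_px, cfg.width_px, 4)

    def test_render_purity_byte_identical(self, unit_sim):
        query = unit_sim.query.with_families(unit_sim.families)
        pair = consecutive_pairs(query)[5]
        def paint():
            pile = build_pileup(pair, query, unit_sim.references,
                                unit_sim.families, unit_sim.scores)
            ex = render(pile)
            buf = _io.BytesIO()
            ex.to_png(buf)
            return ex.pixels, buf.getvalue()
        px1, png1 = paint()
        px2, png2 = paint()
        assert np.array_equal(px1, px2)
        assert png1 == png2

    def test_query_arrows_intersect_central_band(self, unit_sim):
        query = unit_sim.query.with_families(unit_sim.families)
        cfg = RenderConfig()
        cx0, cx1 = cfg.central_band
        for pair in consecutive_pairs(query)[:15]:
            pile = build_pileup(pair, query, unit_sim.references,
                                unit_sim.families, unit_sim.scores)
            ex = render(pile, cfg)
            ids = {pair[0].gene_id, pair[1].gene_id}
            query_arrows = [a for a in ex.layout[0] if a.gene_id in ids]
            assert len(query_arrows) == 2
            for a in query_arrows:
                assert a.x1 > cx0 and a.x0 < cx1

    def test_painted_columns_stay_within_width(self, unit_sim):
        query = unit_sim.query.with_families(unit_sim.families)
        pile = build_pileup(consecutive_pairs(query)[0], query,
                            unit_sim.references, unit_sim.families, unit_sim.scores)
        ex = render(pile)
        cfg = RenderConfig()
        for row in ex.layout:
            painted = set()
            for a in row:
                assert 0 <= a.x0 < a.x1 <= cfg.width_px
                painted.update(range(a.x0, a.x1))
            assert len(painted) <= cfg.width_px

    def test_empty_pileup_rejected(self):
        g1 = _gene("q1", 0, 10)
        with pytest.raises(Exception):
            render(Pileup.__new__(Pileup))  # structurally invalid


def test_config_validation():
    with pytest.raises(RenderError):
        RenderConfig(central_fraction=1.0)
    with pytest.raises(RenderError):
        RenderConfig(default_alpha=0.0)
    with pytest.raises(RenderError):
        RenderConfig(palette=((0, 0, 255),) * 8)


def test_composite_on_white():
    rgba = np.zeros((2, 2, 4), dtype=np.uint8)
    rgba[..., 3] = 128  # half-transparent black
    out = composite_on_white(rgba)
    assert out.shape == (2, 2, 3)
    assert np.all(np.abs(out.astype(int) - 127) <= 1)


def test_mirror_is_involution_and_flips_heads():
    ex = render(_pileup_two_genes(score=0.9))
    mirrored = mirror_example(ex)
    assert not np.array_equal(mirrored.pixels, ex.pixels)
    back = mirror_example(mirrored)
    assert np.array_equal(back.pixels, ex.pixels)
    for row_m, row_o in zip(mirrored.layout, ex.layout):
        for a_m, a_o in zip(row_m, reversed(row_o)):
            assert a_m.gene_id == a_o.gene_id
            assert a_m.head_right != a_o.head_right
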