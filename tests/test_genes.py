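"""Expression quantification and the two gene-eligibility filters."""
import numpy as np
import pytest

from netterm.genes import (GeneModel, quantify_expression, read_genes_bed,
                           select_expressed, select_isolated, write_genes_bed)
from netterm.signal import SignalTrack


def make_track(chrom_sizes, placements, library_size=None):
    """placements: list of (chrom, strand, position, count)."""
    total = sum(c for *_, c in placements)
    track = SignalTrack(chrom_sizes, "three_prime_end",
                        library_size=total if library_size is None else library_size)
    for chrom, strand, pos, count in placements:
        track.data[(chrom, strand)][pos] += count
    return track


class TestGeneModel:
    def test_anchor_derivation(self):
        plus = GeneModel("a", "chr1", 100, 200, "+")
        minus = GeneModel("b", "chr1", 100, 200, "-")
        assert (plus.tss, plus.tes) == (100, 199)
        assert (minus.tss, minus.tes) == (199, 100)

    def test_invalid_span_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("a", "chr1", 200, 200, "+")
        with pytest.raises(ValueError):
            GeneModel("a", "chr1", 100, 200, "?")

    def test_bed_round_trip_longest_isoform(self, tmp_path):
        genes = [GeneModel("a", "chr1", 0, 100, "+"), GeneModel("a", "chr1", 0, 300, "+"),
                 GeneModel("b", "chr1", 500, 600, "-")]
        write_genes_bed(genes, tmp_path / "g.bed")
        back = read_genes_bed(tmp_path / "g.bed")
        assert [(g.gene_id, g.length) for g in back] == [("a", 300), ("b", 100)]


class TestQuantifyExpression:
    def test_single_gene_tpm_is_1e6(self):
        track = make_track({"chr1": 1000}, [("chr1", "+", 50, 7)])
        table = quantify_expression(track, [GeneModel("a", "chr1", 0, 100, "+")])
        assert table.loc["a", "tpm"] == pytest.approx(1e6)

    def test_length_normalization_splits_2_to_1(self):
        track = make_track({"chr1": 10_000},
                           [("chr1", "+", 100, 10), ("chr1", "+", 5000, 10)])
        genes = [GeneModel("short", "chr1", 0, 1000, "+"),
                 GeneModel("long", "chr1", 4000, 6000, "+")]
        table = quantify_expression(track, genes)
        assert table.loc["short", "tpm"] == pytest.approx(2e6 / 3)
        assert table.loc["long", "tpm"] == pytest.approx(1e6 / 3)

    def test_matches_two_pass_recomputation(self, rng):
        N = 50_000
        track = SignalTrack({"chr1": N}, "three_prime_end", library_size=5000)
        for strand in "+-":
            track.data[("chr1", strand)][:] = rng.poisson(0.05, N)
        genes = [GeneModel(f"g{i}", "chr1", int(s), int(s) + int(l), str(st))
                 for i, (s, l, st) in enumerate(zip(rng.integers(0, N - 2000, 20),
                                                    rng.integers(100, 2000, 20),
                                                    rng.choice(["+", "-"], 20)))]
        table = quantify_expression(track, genes)
        # independent two-pass oracle
        counts = {g.gene_id: track.array("chr1", g.strand)[g.start:g.end].sum()
                  for g in genes}
        denom = sum(counts[g.gene_id] / g.length for g in genes)
        for g in genes:
            expected = counts[g.gene_id] / g.length / denom * 1e6
            assert table.loc[g.gene_id, "tpm"] == pytest.approx(expected, rel=1e-9)
        assert table["tpm"].sum() == pytest.approx(1e6, rel=1e-9)

    def test_rpkm_definition(self):
        track = make_track({"chr1": 10_000}, [("chr1", "+", 100, 50)],
                           library_size=1000)
        table = quantify_expression(track, [GeneModel("a", "chr1", 0, 2000, "+")])
        assert table.loc["a", "rpkm"] == pytest.approx(50 * 1e9 / (2000 * 1000))

    def test_unknown_chromosome_raises(self):
        track = make_track({"chr1": 1000}, [])
        with pytest.raises(LookupError):
            quantify_expression(track, [GeneModel("a", "chrX", 0, 100, "+")])


class TestSelectExpressed:
    @pytest.fixture
    def table(self):
        # counts chosen so the three probe genes have TPM 0.5, 1.0 and 3.2
        placements = [("chr1", "+", 10, 5), ("chr1", "+", 1010, 10),
                      ("chr1", "+", 2010, 32), ("chr1", "+", 4500, 9_999_953)]
        track = make_track({"chr1": 1_000_000}, placements)
        genes = [GeneModel("lo", "chr1", 0, 1000, "+"),
                 GeneModel("mid", "chr1", 1000, 2000, "+"),
                 GeneModel("hi", "chr1", 2000, 3000, "+"),
                 GeneModel("bulk", "chr1", 4000, 5000, "+"),
                 GeneModel("silent", "chr1", 6000, 7000, "+")]
        return quantify_expression(track, genes)

    def test_known_tpms(self, table):
        assert table.loc["lo", "tpm"] == pytest.approx(0.5, rel=1e-6)
        assert table.loc["mid", "tpm"] == pytest.approx(1.0, rel=1e-6)
        assert table.loc["hi", "tpm"] == pytest.approx(3.2, rel=1e-6)

    def test_threshold_keeps_boundary(self, table):
        kept = select_expressed(table, min_tpm=1.0)
        assert {"mid", "hi"} <= set(kept) and "lo" not in kept

    def test_zero_threshold_keeps_silent_genes(self, table):
        assert "silent" in select_expressed(table, min_tpm=0.0)

    def test_unreachable_threshold_empty(self, table):
        assert select_expressed(table, min_tpm=2e6) == []


class TestSelectIsolated:
    def test_single_gene_always_kept(self):
        genes = [GeneModel("only", "chr1", 50_000, 52_000, "+")]
        kept, report = select_isolated(genes, ["only"])
        assert [g.gene_id for g in kept] == ["only"]
        assert report.loc["only", "kept"]

    @pytest.mark.parametrize("gap,expect_kept", [(20_000, True), (10_000, False)])
    def test_downstream_gap_threshold(self, gap, expect_kept):
        """A '+' gene is kept iff the next gene starts beyond TES + 15,250."""
        g1 = GeneModel("g1", "chr1", 50_000, 52_000, "+")
        g2 = GeneModel("g2", "chr1", 52_000 + gap, 54_000 + gap, "+")
        kept, _ = select_isolated([g1, g2], ["g1", "g2"])
        assert ("g1" in {g.gene_id for g in kept}) is expect_kept

    def test_order_invariance(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", int(50_000 * i), int(50_000 * i) + 2000,
                           str(s))
                 for i, s in enumerate(rng.choice(["+", "-"], 8), start=1)]
        kept1, _ = select_isolated(genes, [g.gene_id for g in genes])
        shuffled = list(genes)
        rng.shuffle(shuffled)
        kept2, _ = select_isolated(shuffled, [g.gene_id for g in genes])
        assert {g.gene_id for g in kept1} == {g.gene_id for g in kept2}

    def test_window_shrink_monotonicity(self):
        genes = [GeneModel("g1", "chr1", 50_000, 52_000, "+"),
                 GeneModel("g2", "chr1", 62_000, 64_000, "+"),
                 GeneModel("g3", "chr1", 90_000, 92_000, "+")]
        ids = [g.gene_id for g in genes]
        wide, _ = select_isolated(genes, ids, netseq_window=(1250, 15_250))
        narrow, _ = select_isolated(genes, ids, netseq_window=(1250, 5_000))
        assert {g.gene_id for g in wide} <= {g.gene_id for g in narrow}

    def test_strand_mirror_preserves_kept_set(self):
        N = 200_000
        genes = [GeneModel("a", "chr1", 50_000, 52_000, "+"),
                 GeneModel("b", "chr1", 60_000, 62_000, "-"),
                 GeneModel("c", "chr1", 100_000, 103_000, "+")]
        mirrored = [GeneModel(g.gene_id, g.chrom, N - g.end, N - g.start,
                              "-" if g.strand == "+" else "+") for g in genes]
        ids = [g.gene_id for g in genes]
        kept1, _ = select_isolated(genes, ids)
        kept2, _ = select_isolated(mirrored, ids)
        assert {g.gene_id for g in kept1} == {g.gene_id for g in kept2}

    def test_rnaseq_window_overlap(self):
        # windows: [TSS-3000, TES+7000]; spans 10 kb apart on opposite strands
        g1 = GeneModel("g1", "chr1", 50_000, 52_000, "+")  # window 47,000..59,000
        g2 = GeneModel("g2", "chr1", 62_000, 64_000, "-")  # window 55,000..67,000
        kept, report = select_isolated([g1, g2], ["g1", "g2"], mode="rnaseq")
        assert kept == []
        assert "window" in report.loc["g1", "reason"]

    def test_strict_reads_requires_track(self):
        from netterm.genes import ConfigurationError
        g = GeneModel("g1", "chr1", 50_000, 52_000, "+")
        with pytest.raises(ConfigurationError, match="track"):
            select_isolated([g], ["g1"], mode="rnaseq", strict_reads=True)
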