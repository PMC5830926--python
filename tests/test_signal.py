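"""Ingestion filters, 3'-end extraction, coverage, and bedGraph round trips."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_fragments
from netterm.signal import (FormatError, FragmentRecord, ParseError, SignalTrack,
                            build_coverage, extract_three_prime_ends,
                            read_fragments, read_track, write_track)
from netterm.simulate import write_fragments_sam


def write_bed(tmp_path, rows, name="frags.bed"):
    path = tmp_path / name
    path.write_text("".join(f"{c}\t{s}\t{e}\t{n}\t{q}\t{st}\n"
                            for c, s, e, n, q, st in rows))
    return path


class TestReadFragments:
    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        records, report = read_fragments(path)
        assert records == []
        assert report == {"total": 0, "retained": 0, "mapq_dropped": 0,
                          "pair_dropped": 0, "unmapped_dropped": 0}

    def test_mapq_filter_counts(self, tmp_path):
        rows = [("chr1", i * 10, i * 10 + 5, f"f{i}", 10 if i < 3 else 30, "+")
                for i in range(10)]
        records, report = read_fragments(write_bed(tmp_path, rows), mapq_min=30)
        assert len(records) == 7
        assert report["mapq_dropped"] == 3 and report["retained"] == 7

    def test_identity_filter(self, tmp_path):
        rows = [("chr1", i, i + 2, f"f{i}", 0, "-") for i in range(25)]
        records, report = read_fragments(write_bed(tmp_path, rows), mapq_min=0,
                                         require_proper_pair=False)
        assert len(records) == report["total"] == 25

    def test_malformed_line_reports_position(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t0\t10\tf0\t60\t+\nchr1\t5\tnope\tf1\t60\t+\n")
        with pytest.raises(ParseError, match=":2:"):
            read_fragments(path)

    def test_unknown_strand_symbol(self, tmp_path):
        path = write_bed(tmp_path, [("chr1", 0, 10, "f0", 60, "*")])
        with pytest.raises(ParseError, match="strand"):
            read_fragments(path)

    def test_strand_flip_dialect(self, tmp_path):
        path = write_bed(tmp_path, [("chr1", 0, 10, "f0", 60, "+")])
        (rec,), _ = read_fragments(path, strand_is_rna=False, mapq_min=0)
        assert rec.rna_strand == "-"

    def test_sam_round_trip_with_pair_filter(self, tmp_path, rng):
        records = random_fragments(rng, n=200)
        records = [FragmentRecord(r.chrom, r.start, r.end, r.rna_strand, mapq=r.mapq,
                                  proper_pair=(i % 4 != 0), name=f"f{i}")
                   for i, r in enumerate(records)]
        path = tmp_path / "lib.sam"
        write_fragments_sam(records, {"chr1": 10_000}, path)
        back, report = read_fragments(path, dialect="sam_minimal", mapq_min=0,
                                      require_proper_pair=True)
        expected = [r for r in records if r.proper_pair]
        assert report["pair_dropped"] == len(records) - len(expected)
        assert [(r.chrom, r.start, r.end, r.rna_strand, r.mapq) for r in back] == \
               [(r.chrom, r.start, r.end, r.rna_strand, r.mapq) for r in expected]

    def test_filter_monotonicity(self, tmp_path, rng):
        path = tmp_path / "lib.bed"
        rows = [("chr1", int(s), int(s) + 5, f"f{i}", int(q), "+")
                for i, (s, q) in enumerate(zip(rng.integers(0, 100, 50),
                                               rng.integers(0, 61, 50)))]
        write_bed(tmp_path, rows, "lib.bed")
        sizes = [read_fragments(path, mapq_min=q)[1]["retained"]
                 for q in (0, 10, 20, 30, 40, 61)]
        assert sizes == sorted(sizes, reverse=True)


class TestThreePrimeEnds:
    def test_plus_strand_half_open_convention(self):
        track = extract_three_prime_ends(
            [FragmentRecord("chr1", 100, 150, "+")], {"chr1": 200})
        arr = track.array("chr1", "+")
        assert arr[149] == 1 and arr.sum() == 1
        assert track.array("chr1", "-").sum() == 0

    def test_minus_strand_mirror(self):
        track = extract_three_prime_ends(
            [FragmentRecord("chr1", 100, 150, "-")], {"chr1": 200})
        assert track.array("chr1", "-")[100] == 1
        assert track.total() == 1

    def test_matches_brute_force_tally(self, rng):
        records = random_fragments(rng, n=1000)
        track = extract_three_prime_ends(records, {"chr1": 10_000})
        expected = {"+": np.zeros(10_000), "-": np.zeros(10_000)}
        for r in records:
            expected[r.rna_strand][r.end - 1 if r.rna_strand == "+" else r.start] += 1
        for s in "+-":
            assert np.array_equal(track.array("chr1", s), expected[s])

    def test_conservation(self, rng):
        records = random_fragments(rng, n=777)
        track = extract_three_prime_ends(records, {"chr1": 10_000})
        assert track.total() == len(records) == track.library_size

    def test_out_of_bounds_record_named(self):
        from netterm.signal import CoordinateError
        with pytest.raises(CoordinateError, match="chr1"):
            extract_three_prime_ends([FragmentRecord("chr1", 100, 300, "+")],
                                     {"chr1": 200})

    def test_strand_flip_equivariance(self, rng):
        """Flipping strands and reflecting coordinates reflects the track."""
        N = 10_000
        records = random_fragments(rng, chrom_size=N, n=400)
        flipped = [FragmentRecord(r.chrom, N - r.end, N - r.start,
                                  "-" if r.rna_strand == "+" else "+",
                                  mapq=r.mapq) for r in records]
        t1 = extract_three_prime_ends(records, {"chr1": N})
        t2 = extract_three_prime_ends(flipped, {"chr1": N})
        assert np.array_equal(t1.array("chr1", "+"), t2.array("chr1", "-")[::-1])
        assert np.array_equal(t1.array("chr1", "-"), t2.array("chr1", "+")[::-1])


class TestCoverage:
    def test_single_record_mass(self):
        track = build_coverage([FragmentRecord("chr1", 10, 60, "+")], {"chr1": 100})
        assert track.array("chr1", "+").sum() == 50

    def test_additivity(self):
        recs = [FragmentRecord("chr1", 10, 60, "+")] * 2
        track = build_coverage(recs, {"chr1": 100})
        assert np.array_equal(track.array("chr1", "+")[10:60], np.full(50, 2))

    def test_matches_interval_stabbing(self, rng):
        records = random_fragments(rng, n=500)
        track = build_coverage(records, {"chr1": 10_000})
        expected = {"+": np.zeros(10_000), "-": np.zeros(10_000)}
        for r in records:
            expected[r.rna_strand][r.start:r.end] += 1
        for s in "+-":
            assert np.array_equal(track.array("chr1", s), expected[s])


class TestBedGraph:
    def test_zero_track_has_no_data_lines(self, tmp_path):
        track = SignalTrack({"chr1": 100}, "three_prime_end")
        write_track(track, tmp_path / "z")
        assert (tmp_path / "z.plus.bedgraph").read_text() == ""

    def test_single_count_line(self, tmp_path):
        track = extract_three_prime_ends([FragmentRecord("chr1", 100, 150, "+")],
                                         {"chr1": 200})
        write_track(track, tmp_path / "t")
        assert (tmp_path / "t.plus.bedgraph").read_text() == "chr1\t149\t150\t1\n"

    def test_round_trip_identity(self, tmp_path, rng):
        records = random_fragments(rng, n=600)
        track = extract_three_prime_ends(records, {"chr1": 10_000})
        write_track(track, tmp_path / "t")
        assert read_track(tmp_path / "t") == track

    def test_round_trip_float_values(self, tmp_path, rng):
        track = extract_three_prime_ends(random_fragments(rng, n=100),
                                         {"chr1": 10_000}).scaled(1e8 / 100)
        write_track(track, tmp_path / "t")
        back = read_track(tmp_path / "t")
        for key in track.data:
            assert np.array_equal(track.data[key], back.data[key])

    def test_unsorted_input_rejected(self, tmp_path):
        (tmp_path / "t.plus.bedgraph").write_text(
            "chr1\t50\t60\t1\nchr1\t10\t20\t1\n")
        (tmp_path / "t.minus.bedgraph").write_text("")
        with pytest.raises(FormatError, match="unsorted"):
            read_track(tmp_path / "t", chrom_sizes={"chr1": 100})


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 900), st.integers(1, 99),
                          st.sampled_from(["+", "-"])), max_size=40))
def test_conservation_property(frags):
    records = [FragmentRecord("chr1", s, s + l, strand) for s, l, strand in frags]
    track = extract_three_prime_ends(records, {"chr1": 1000})
    assert track.total() == len(records)
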