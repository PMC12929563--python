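"""Fragment ingest, size selection, dyad inference and track building."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nucarray as na
from nucarray.fragments import (
    Fragment,
    FragmentParseError,
    read_chrom_sizes,
    write_chrom_sizes,
    write_bedgraph,
    write_fragments_bed,
)


def make_bed(tmp_path, lines, name="frags.bed"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadFragments:
    def test_bed_line_becomes_fragment(self, tmp_path):
        p = make_bed(tmp_path, ["chrI\t100\t250"])
        assert na.read_fragments(p) == [Fragment("chrI", 100, 250)]

    def test_order_preserved(self, tmp_path):
        p = make_bed(tmp_path, ["chrI\t500\t650", "chrI\t100\t250", "chrII\t0\t150"])
        frags = na.read_fragments(p)
        assert [f.start for f in frags] == [500, 100, 0]

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = make_bed(tmp_path, [])
        assert na.read_fragments(p) == []

    def test_end_not_after_start_is_parse_error_with_line(self, tmp_path):
        p = make_bed(tmp_path, ["chrI\t100\t250", "chrI\t300\t300"])
        with pytest.raises(FragmentParseError, match="line 2"):
            na.read_fragments(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = make_bed(tmp_path, ["chrI\tabc\t250"])
        with pytest.raises(FragmentParseError, match="line 1"):
            na.read_fragments(p)

    def test_unknown_format_rejected(self, tmp_path):
        p = make_bed(tmp_path, ["chrI\t100\t250"])
        with pytest.raises(ValueError, match="unknown fragment format"):
            na.read_fragments(p, format="cram")

    def test_bam_roundtrip(self, tmp_path):
        """Properly paired BAM templates come back as fragment spans."""
        import pysam

        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chrI", "LN": 10000}]}
        sam = tmp_path / "t.sam"
        with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
            for i, (start, tlen) in enumerate([(100, 150), (400, 147)]):
                a = pysam.AlignedSegment(fh.header)
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 50
                a.reference_id = 0
                a.reference_start = start
                a.cigarstring = "50M"
                a.flag = 0x1 | 0x2 | 0x40  # paired, proper, first
                a.next_reference_id = 0
                a.next_reference_start = start + tlen - 50
                a.template_length = tlen
                a.mapping_quality = 60
                fh.write(a)
        bam = tmp_path / "t.bam"
        pysam.sort("-o", str(bam), str(sam))
        pysam.index(str(bam))
        frags = na.read_fragments(bam, format="bam")
        assert frags == [Fragment("chrI", 100, 250), Fragment("chrI", 400, 547)]


class TestMidpoint:
    @pytest.mark.parametrize(
        "start,end,mid", [(100, 250, 175), (100, 251, 175), (0, 2, 1), (0, 1, 0)]
    )
    def test_floor_rule(self, start, end, mid):
        assert na.fragment_midpoint(Fragment("chrI", start, end)) == mid


class TestFilterByLength:
    def test_mononucleosome_bounds_closed_interval(self):
        # closed 140-160 bp interval keeps exactly the boundary lengths
        frags = [Fragment("chrI", 0, L) for L in (139, 140, 150, 160, 161)]
        kept = na.filter_by_length(frags, 140, 160)
        assert [f.length for f in kept] == [140, 150, 160]

    def test_wide_bounds_are_identity(self):
        frags = [Fragment("chrI", 0, L) for L in (1, 100, 10_000)]
        assert na.filter_by_length(frags, 1, 10**9) == frags

    def test_empty_input(self):
        assert na.filter_by_length([], 140, 160) == []

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            na.filter_by_length([], 160, 140)

    @given(
        lengths=st.lists(st.integers(1, 400), max_size=50),
        lo=st.integers(50, 200),
        span=st.integers(0, 100),
    )
    @settings(deadline=None, max_examples=50)
    def test_idempotent(self, lengths, lo, span):
        frags = [Fragment("chrI", 0, L) for L in lengths]
        once = na.filter_by_length(frags, lo, lo + span)
        assert na.filter_by_length(once, lo, lo + span) == once


class TestSubsample:
    def setup_method(self):
        self.frags = [Fragment("chrI", i, i + 150) for i in range(0, 1000, 100)]

    def test_exact_cardinality_and_reproducibility(self):
        a = na.subsample(self.frags, 5, seed=7)
        b = na.subsample(self.frags, 5, seed=7)
        assert len(a) == 5 and a == b
        assert set(a) <= set(self.frags)

    def test_full_draw_is_identity_as_set(self):
        assert set(na.subsample(self.frags, len(self.frags), seed=0)) == set(self.frags)

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError, match="available"):
            na.subsample(self.frags, len(self.frags) + 1, seed=0)


class TestDyadTrack:
    def test_single_dyad_footprint(self, toy_chrom_sizes):
        track = na.build_dyad_track(
            [Fragment("chrI", 100, 250)], toy_chrom_sizes, halfwidth=25
        )
        c = track.counts["chrI"]
        assert c[150:201].tolist() == [1] * 51
        assert c.sum() == 51

    def test_clipping_at_chromosome_start(self, toy_chrom_sizes):
        # dyad at 3: footprint [0, 28] instead of [-22, 28]
        track = na.build_dyad_track(
            [Fragment("chrI", 0, 6)], toy_chrom_sizes, halfwidth=25
        )
        c = track.counts["chrI"]
        assert c[:29].tolist() == [1] * 29 and c.sum() == 29

    def test_overlapping_dyads_add(self, toy_chrom_sizes):
        track = na.build_dyad_track(
            [Fragment("chrI", 100, 250), Fragment("chrI", 110, 260)],
            toy_chrom_sizes,
            halfwidth=25,
        )
        assert track.counts["chrI"].max() == 2

    def test_mass_conservation(self, toy_chrom_sizes, rng):
        starts = rng.integers(0, 9800, size=200)
        frags = [Fragment("chrI", int(s), int(s) + 150) for s in starts]
        track = na.build_dyad_track(frags, toy_chrom_sizes, halfwidth=25)
        expected = sum(
            min(f.midpoint + 25 + 1, 10000) - max(f.midpoint - 25, 0) for f in frags
        )
        assert track.total_signal() == expected

    def test_undeclared_chromosome_names_record(self, toy_chrom_sizes):
        with pytest.raises(ValueError, match="chrX"):
            na.build_dyad_track([Fragment("chrX", 0, 150)], toy_chrom_sizes)

    def test_out_of_bounds_fragment_names_record(self):
        with pytest.raises(ValueError, match="chrI:9900-10050"):
            na.build_dyad_track([Fragment("chrI", 9900, 10050)], {"chrI": 10000})


class TestIO:
    def test_chrom_sizes_roundtrip(self, tmp_path):
        sizes = {"chrI": 230218, "chrII": 813184}
        p = tmp_path / "c.sizes"
        write_chrom_sizes(sizes, p)
        assert read_chrom_sizes(p) == sizes

    def test_fragments_bed_roundtrip(self, tmp_path):
        frags = [Fragment("chrI", 100, 250), Fragment("chrI", 5, 160)]
        p = tmp_path / "f.bed"
        write_fragments_bed(frags, p)
        assert na.read_fragments(p) == frags

    def test_bedgraph_reconstructs_track(self, tmp_path, toy_chrom_sizes):
        frags = [Fragment("chrI", 100, 250), Fragment("chrI", 120, 270)]
        track = na.build_dyad_track(frags, toy_chrom_sizes, halfwidth=25)
        p = tmp_path / "t.bedgraph"
        write_bedgraph(track, p)
        rebuilt = np.zeros(10000, dtype=int)
        for line in p.read_text().splitlines():
            chrom, s, e, v = line.split("\t")
            rebuilt[int(s):int(e)] = int(v)
        assert np.array_equal(rebuilt, track.counts["chrI"])
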