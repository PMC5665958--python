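"""Core data model: coordinates, TSS, gaps, clustering, coverage, I/O."""
import numpy as np
import pandas as pd
import pytest

from linctools.io import (
    read_coverage_bedgraph,
    read_gtf,
    read_methylation_calls,
    write_coverage_bedgraph,
    write_gtf,
    write_methylation_calls,
)
from linctools.model import (
    CoverageTrack,
    GeneLocus,
    GenomicInterval,
    MethylationCallSet,
    TranscriptModel,
    ValidationError,
    cluster_transcripts_into_loci,
    gap_distance,
    tss_of,
)

from conftest import make_transcript, random_transcripts


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
    def test_rejects_degenerate_intervals(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end)

    def test_length_is_end_minus_start(self):
        assert len(GenomicInterval("chr1", 10, 25)) == 15


class TestGapDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (((0, 100)), ((600, 700)), 500),  # "at least 500 bp away" boundary
            (((0, 100)), ((100, 200)), 0),  # adjacent
            (((600, 700)), ((0, 100)), 500),  # order-independent
        ],
    )
    def test_counts_strictly_between_bases(self, a, b, expected):
        ia = GenomicInterval("chr1", *a)
        ib = GenomicInterval("chr1", *b)
        assert gap_distance(ia, ib) == expected
        assert gap_distance(ib, ia) == expected

    def test_overlap_is_flagged_not_numeric(self):
        a = GenomicInterval("chr1", 0, 100)
        b = GenomicInterval("chr1", 50, 150)
        assert gap_distance(a, b) is None

    def test_different_chromosomes_error(self):
        with pytest.raises(ValidationError):
            gap_distance(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10))


class TestTranscriptModel:
    def test_exon_order_and_overlap_enforced(self):
        with pytest.raises(ValidationError):
            make_transcript("t", [(100, 200), (150, 300)])

    def test_length_and_span(self):
        t = make_transcript("t", [(0, 100), (200, 300)])
        assert t.length == 200
        assert (t.span.start, t.span.end) == (0, 300)
        assert [iv.start for iv in t.introns] == [100]

    @pytest.mark.parametrize(
        "strand,expected", [("+", 100), ("-", 499)]
    )
    def test_tss_is_strand_dependent(self, strand, expected):
        t = make_transcript("t", [(100, 250), (400, 500)], strand=strand)
        assert tss_of(t) == ("chr1", expected)

    def test_tss_of_single_exon_transcript(self):
        assert tss_of(make_transcript("t", [(100, 500)], strand="+"))[1] == 100
        assert tss_of(make_transcript("t", [(100, 500)], strand="-"))[1] == 499

    def test_tss_requires_strand(self):
        with pytest.raises(ValidationError):
            tss_of(make_transcript("t", [(0, 100)], strand="."))


def brute_force_loci(transcripts):
    """O(n^2) connected components of the exonic-overlap graph."""

    def exon_overlap(a, b):
        if a.chrom != b.chrom or a.strand != b.strand:
            return False
        return any(
            ea.start < eb.end and eb.start < ea.end for ea in a.exons for eb in b.exons
        )

    n = len(transcripts)
    seen = [False] * n
    components = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            j = stack.pop()
            comp.append(j)
            for k in range(n):
                if not seen[k] and exon_overlap(transcripts[j], transcripts[k]):
                    seen[k] = True
                    stack.append(k)
        components.append(frozenset(transcripts[j].transcript_id for j in comp))
    return set(components)


class TestLocusClustering:
    def test_shared_exon_base_merges(self):
        a = make_transcript("a", [(0, 100)])
        b = make_transcript("b", [(99, 200)])
        assert len(cluster_transcripts_into_loci([a, b])) == 1

    def test_opposite_strands_stay_apart(self):
        a = make_transcript("a", [(0, 100)], strand="+")
        b = make_transcript("b", [(0, 100)], strand="-")
        assert len(cluster_transcripts_into_loci([a, b])) == 2

    def test_intron_only_overlap_does_not_merge(self):
        outer = make_transcript("outer", [(0, 100), (900, 1000)])
        inner = make_transcript("inner", [(300, 400), (500, 600)])
        assert len(cluster_transcripts_into_loci([outer, inner])) == 2

    def test_transitive_chain_forms_one_locus(self):
        a = make_transcript("a", [(0, 100)])
        b = make_transcript("b", [(50, 160)])
        c = make_transcript("c", [(150, 260)])
        loci = cluster_transcripts_into_loci([a, b, c])
        assert len(loci) == 1
        assert brute_force_loci([a, b, c]) == {frozenset("abc")}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        transcripts = random_transcripts(rng, 50, chrom_len=8_000)
        loci = cluster_transcripts_into_loci(transcripts)
        got = {
            frozenset(t.transcript_id for t in g.transcripts) for g in loci
        }
        assert got == brute_force_loci(transcripts)

    def test_locus_ids_follow_leftmost_coordinate(self):
        a = make_transcript("a", [(5000, 5100)])
        b = make_transcript("b", [(0, 100)])
        loci = cluster_transcripts_into_loci([a, b], locus_prefix="L")
        assert [g.gene_id for g in loci] == ["L000001", "L000002"]
        assert loci[0].transcripts[0].transcript_id == "b"


class TestCoverageTrack:
    def test_depth_and_absent_positions(self):
        track = CoverageTrack(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "depth": [5.0]})
        )
        arr = track.depth_array("chr1", 0, 12)
        assert list(arr[:10]) == [5.0] * 10
        assert list(arr[10:]) == [0.0, 0.0]

    def test_rejects_overlapping_intervals(self):
        df = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 5], "end": [10, 15], "depth": [1, 2]}
        )
        with pytest.raises(ValidationError):
            CoverageTrack(df)

    @pytest.mark.parametrize("seed", range(3))
    def test_window_sum_equals_per_base_expansion(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.choice(np.arange(0, 500, 5), size=30, replace=False))
        ends = starts + rng.integers(1, 5, size=30)
        ends = np.minimum(ends, np.append(starts[1:], 10**9))
        keep = ends > starts
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts[keep],
                "end": ends[keep],
                "depth": rng.integers(0, 20, size=keep.sum()),
            }
        )
        track = CoverageTrack(df)
        per_base = {}
        for row in df.itertuples(index=False):
            for p in range(row.start, row.end):
                per_base[p] = row.depth
        for lo, hi in [(0, 600), (13, 87), (499, 520)]:
            expected = sum(per_base.get(p, 0) for p in range(lo, hi))
            assert track.depth_array("chr1", lo, hi).sum() == pytest.approx(expected)


class TestGtfRoundTrip:
    def test_coordinate_convention(self, tmp_path):
        path = tmp_path / "one.gtf"
        path.write_text(
            'chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        loci = read_gtf(path)
        exon = loci[0].transcripts[0].exons[0]
        assert (exon.start, exon.end) == (0, 100)

    def test_two_exon_lines_one_transcript(self, tmp_path):
        path = tmp_path / "two.gtf"
        path.write_text(
            'chr1\ts\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\ts\texon\t201\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        loci = read_gtf(path)
        assert len(loci) == 1
        assert loci[0].transcripts[0].exon_count == 2

    def test_round_trip_preserves_coordinates(self, tmp_path, default_dataset):
        path = tmp_path / "rt.gtf"
        write_gtf(default_dataset.annotation, path)
        loci = read_gtf(path)
        original = {
            t.transcript_id: [(e.start, e.end) for e in t.exons]
            for g in default_dataset.annotation
            for t in g.transcripts
        }
        restored = {
            t.transcript_id: [(e.start, e.end) for e in t.exons]
            for g in loci
            for t in g.transcripts
        }
        assert restored == original
        assert {g.biotype for g in loci} == {"coding", "housekeeping"}

    def test_empty_locus_collection(self, tmp_path):
        path = tmp_path / "empty.gtf"
        write_gtf([], path)
        assert read_gtf(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text("chr1\tonly\tthree\n")
        with pytest.raises(Exception, match=":1:"):
            read_gtf(path)


class TestMethylationCalls:
    def test_position_conversion_and_counts(self, tmp_path):
        path = tmp_path / "calls.tsv"
        path.write_text("chr1\t1001\t+\t3\t1\n")
        calls = read_methylation_calls(path)
        rec = calls.query("chr1", 1000, 1001)
        assert rec["pos"].tolist() == [1000]
        assert rec["m"].tolist() == [3] and rec["u"].tolist() == [1]

    def test_duplicate_records_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("chr1\t10\t+\t1\t1\nchr1\t10\t+\t2\t2\n")
        with pytest.raises(ValidationError):
            read_methylation_calls(path)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [5], "strand": ["+"], "m": [-1], "u": [0]}
        )
        with pytest.raises(ValidationError):
            MethylationCallSet(df)

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(read_methylation_calls(path)) == 0

    def test_round_trip(self, tmp_path, default_dataset):
        calls = default_dataset.methylation["group1"][0]
        path = tmp_path / "rt.tsv"
        write_methylation_calls(calls, path)
        again = read_methylation_calls(path)
        pd.testing.assert_frame_equal(calls.to_frame(), again.to_frame())


class TestBedgraphRoundTrip:
    def test_empty_file_is_all_zero(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        track = read_coverage_bedgraph(path)
        assert track.depth_array("chr1", 0, 100).sum() == 0

    def test_round_trip(self, tmp_path, default_dataset):
        track = CoverageTrack(default_dataset.binding)
        path = tmp_path / "rt.bedgraph"
        write_coverage_bedgraph(track, path)
        again = read_coverage_bedgraph(path)
        pd.testing.assert_frame_equal(track.to_frame(), again.to_frame())
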