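"""TSS metaprofiles against naive per-base oracles; gene methylation."""
import numpy as np
import pandas as pd
import pytest

from linctools.model import (
    CoverageTrack,
    GeneLocus,
    MethylationCallSet,
    ValidationError,
    tss_of,
)
from linctools.profiles import (
    compare_methylation_distributions,
    cpg_oe,
    cpg_oe_profile,
    gc_content_profile,
    gc_fraction,
    gene_methylation_level,
    tss_binding_profile,
    tss_methylation_profile,
)

from conftest import make_transcript

FLANK, BIN = 5000, 100


def calls_from_rows(rows):
    return MethylationCallSet(
        pd.DataFrame(rows, columns=["chrom", "pos", "strand", "m", "u"])
    )


def window_positions(t):
    """5'->3' ordered genomic positions of the TSS window, per bin."""
    _, p = tss_of(t)
    if t.strand == "+":
        positions = np.arange(p - FLANK, p + FLANK)
    else:
        positions = np.arange(p + FLANK, p - FLANK, -1)
    return positions.reshape(100, BIN)


def naive_methylation_profile(transcripts, call_rows):
    lookup = {(c, p): (m, u) for c, p, _s, m, u in call_rows}
    # collapse strands at identical positions
    agg = {}
    for c, p, _s, m, u in call_rows:
        mm, uu = agg.get((c, p), (0, 0))
        agg[(c, p)] = (mm + m, uu + u)
    bins = np.zeros(100)
    for t in transcripts:
        for i, row in enumerate(window_positions(t)):
            m = sum(agg.get((t.chrom, p), (0, 0))[0] for p in row)
            u = sum(agg.get((t.chrom, p), (0, 0))[1] for p in row)
            bins[i] += 0.0 if m == 0 else m / (m + u)
    return bins / len(transcripts)


class TestGeneMethylationLevel:
    @pytest.mark.parametrize("m,u,expected", [(0, 7, 0.0), (3, 1, 0.75), (5, 5, 0.5)])
    def test_level_formula(self, m, u, expected):
        rows = [("chr1", 100, "+", m, u)]
        t = make_transcript("t", [(50, 200)])
        g = GeneLocus(gene_id="g", transcripts=(t,), biotype="lincRNA")
        gm = gene_methylation_level(g, calls_from_rows(rows))
        assert gm.level == expected

    def test_sums_both_strands_within_span(self):
        rows = [
            ("chr1", 100, "+", 2, 0),
            ("chr1", 101, "-", 1, 3),
            ("chr1", 999, "+", 50, 0),  # outside span
        ]
        t = make_transcript("t", [(50, 200)])
        g = GeneLocus(gene_id="g", transcripts=(t,), biotype="coding")
        gm = gene_methylation_level(g, calls_from_rows(rows))
        assert (gm.m, gm.u) == (3, 3)
        assert gm.level == 0.5

    def test_no_calls_in_span_is_zero(self):
        t = make_transcript("t", [(50, 200)])
        g = GeneLocus(gene_id="g", transcripts=(t,), biotype="coding")
        gm = gene_methylation_level(g, calls_from_rows([]))
        assert (gm.m, gm.u, gm.level) == (0, 0, 0.0)


class TestKsComparison:
    def test_identical_samples(self):
        x = [0.1, 0.2, 0.3, 0.4]
        d, _ = compare_methylation_distributions(x, list(x))
        assert d == 0.0

    def test_fully_separated_samples(self):
        d, p = compare_methylation_distributions([0.8, 0.9, 0.95], [0.1, 0.2, 0.3])
        assert d == 1.0
        assert p < 0.2

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            compare_methylation_distributions([0.5], [0.1, 0.2])


class TestMethylationProfile:
    def test_constant_field_gives_constant_profile(self):
        rows = [("chr1", p, "+", 4, 1) for p in range(5000, 15000, 50)]
        t = make_transcript("t", [(10_000, 10_500), (11_000, 11_500)])
        prof = tss_methylation_profile([t], calls_from_rows(rows))
        np.testing.assert_allclose(prof.values, 0.8)
        assert prof.n_bins == 100
        assert prof.n_transcripts == 1

    def test_no_cytosines_gives_all_zero(self):
        t = make_transcript("t", [(10_000, 10_500), (11_000, 11_500)])
        prof = tss_methylation_profile([t], calls_from_rows([]))
        np.testing.assert_allclose(prof.values, 0.0)

    def test_empty_transcript_set_errors(self):
        with pytest.raises(ValidationError):
            tss_methylation_profile([], calls_from_rows([]))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for p in sorted(rng.choice(np.arange(1000, 40_000), size=800, replace=False)):
            rows.append(("chr1", int(p), "+", int(rng.integers(0, 20)), int(rng.integers(0, 20))))
        transcripts = []
        for i in range(10):
            start = int(rng.integers(8_000, 25_000))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                make_transcript(f"t{i}", [(start, start + 300), (start + 700, start + 1200)], strand=strand)
            )
        prof = tss_methylation_profile(transcripts, calls_from_rows(rows))
        oracle = naive_methylation_profile(transcripts, rows)
        np.testing.assert_allclose(prof.values, oracle, atol=1e-12)

    def test_per_covered_mode_ignores_uncovered_transcripts(self):
        rows = [("chr1", p, "+", 1, 1) for p in range(5_000, 15_001, 50)]
        covered = make_transcript("cov", [(10_000, 10_400), (10_800, 11_000)])
        barren = make_transcript("bare", [(200_000, 200_400), (200_800, 201_000)])
        prof = tss_methylation_profile([covered, barren], calls_from_rows(rows), per_covered=True)
        np.testing.assert_allclose(prof.values, 0.5)

    def test_strand_reflection_symmetry(self):
        """Reflecting every coordinate and flipping strands leaves the
        profile unchanged."""
        L = 40_000
        rng = np.random.default_rng(5)
        rows = []
        for p in sorted(rng.choice(np.arange(1000, L - 1000), size=500, replace=False)):
            rows.append(("chr1", int(p), "+", int(rng.integers(0, 9)), int(rng.integers(0, 9))))
        t = make_transcript("t", [(15_000, 15_400), (16_000, 16_500)], strand="+")
        mirrored_rows = [("chr1", L - 1 - p, s, m, u) for (_, p, s, m, u) in rows]
        exons = [(L - 16_500, L - 16_000), (L - 15_400, L - 15_000)]
        t_mirror = make_transcript("t", exons, strand="-")
        a = tss_methylation_profile([t], calls_from_rows(rows))
        b = tss_methylation_profile([t_mirror], calls_from_rows(mirrored_rows))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestBindingProfile:
    def test_constant_depth(self):
        track = CoverageTrack(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [60_000], "depth": [7.0]})
        )
        t = make_transcript("t", [(20_000, 20_500), (21_000, 21_400)])
        prof = tss_binding_profile([t], track)
        np.testing.assert_allclose(prof.values, 7.0)

    def test_single_pulse_arithmetic(self):
        """A 100 bp pulse of depth 50 in the first downstream bin of one of
        ten transcripts contributes 50/10 = 5 to that bin alone."""
        transcripts = [
            make_transcript(f"t{i}", [(50_000 * (i + 1), 50_000 * (i + 1) + 1000)])
            for i in range(10)
        ]
        tss0 = transcripts[0].span.start
        track = CoverageTrack(
            pd.DataFrame(
                {"chrom": ["chr1"], "start": [tss0], "end": [tss0 + 100], "depth": [50.0]}
            )
        )
        prof = tss_binding_profile(transcripts, track)
        assert prof.values[50] == pytest.approx(5.0)
        assert prof.values.sum() == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        starts = np.arange(0, 40_000, 20)
        depths = rng.integers(0, 30, size=len(starts)).astype(float)
        track = CoverageTrack(
            pd.DataFrame(
                {"chrom": "chr1", "start": starts, "end": starts + 20, "depth": depths}
            )
        )
        per_base = np.zeros(60_000)
        for s, d in zip(starts, depths):
            per_base[s : s + 20] = d
        transcripts = []
        for i in range(10):
            start = int(rng.integers(6_000, 30_000))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(make_transcript(f"t{i}", [(start, start + 800)], strand=strand))
        prof = tss_binding_profile(transcripts, track)
        oracle = np.zeros(100)
        for t in transcripts:
            _, p = tss_of(t)
            if t.strand == "+":
                win = per_base[p - FLANK : p + FLANK]
            else:
                lo = p - FLANK + 1
                win = per_base[max(lo, 0) : p + FLANK + 1][::-1]
            oracle += win.reshape(100, BIN).mean(axis=1)
        np.testing.assert_allclose(prof.values, oracle / len(transcripts), atol=1e-12)


class TestSequenceWindows:
    @pytest.mark.parametrize(
        "window,expected",
        [("ATGC" * 25, 0.5), ("G" * 100, 1.0), ("NNNN", float("nan")), ("ANTN", 0.0)],
    )
    def test_gc_fraction(self, window, expected):
        got = gc_fraction(window)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize(
        "window,expected",
        [("CGCG", 2.0), ("AAAA", 0.0), ("CCGG", 1.0), ("NNNN", float("nan"))],
    )
    def test_cpg_oe(self, window, expected):
        got = cpg_oe(window)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(2))
    def test_profiles_match_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        L = 30_000
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=L))}
        transcripts = []
        for i in range(6):
            start = int(rng.integers(6_000, 20_000))
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(make_transcript(f"t{i}", [(start, start + 500)], strand=strand))
        gc = gc_content_profile(transcripts, genome)
        oe = cpg_oe_profile(transcripts, genome)
        seq = genome["chr1"]
        gc_oracle = np.zeros(100)
        oe_oracle = np.zeros(100)
        for t in transcripts:
            _, p = tss_of(t)
            lo = p - FLANK if t.strand == "+" else p - FLANK + 1
            vals_gc, vals_oe = [], []
            for i in range(100):
                w = seq[max(lo + i * BIN, 0) : lo + (i + 1) * BIN]
                n_c, n_g = w.count("C"), w.count("G")
                vals_gc.append((n_c + n_g) / len(w))
                vals_oe.append(
                    0.0 if n_c == 0 or n_g == 0 else w.count("CG") * len(w) / (n_c * n_g)
                )
            if t.strand == "-":
                vals_gc.reverse()
                vals_oe.reverse()
            gc_oracle += vals_gc
            oe_oracle += vals_oe
        np.testing.assert_allclose(gc.values, gc_oracle / len(transcripts), atol=1e-12)
        np.testing.assert_allclose(oe.values, oe_oracle / len(transcripts), atol=1e-12)

    def test_window_off_chromosome_is_excluded(self):
        genome = {"chr1": "ACGT" * 3000}  # 12 kb
        t = make_transcript("t", [(1_000, 1_400)])  # upstream windows overhang
        gc = gc_content_profile([t], genome)
        assert gc.n_bins == 100
        # bins fully outside the chromosome have no contributing window
        assert gc.values[0] == 0.0
        assert gc.values[60] == pytest.approx(0.5)
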