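"""TSS-centred epigenomic metaprofiles and gene-level methylation.

All profile operations share one window geometry: the 10 kb region from
5 kb upstream to 5 kb downstream of each transcript's TSS, divided into
100 bins of 100 bp, ordered 5'->3' in transcription direction (bins of
minus-strand transcripts are reversed so bin 1 is always upstream).

Per transcript t and bin i, the methylation level is
``M_ti = m_ti / (m_ti + u_ti)`` with ``M_ti = 0`` when ``m_ti = 0`` (this
convention also covers bins without any cytosine call), and the binding
intensity is the mean per-base read depth of the bin,
``I_ti = sum_p C_tip / 100``. The profile is the plain average over the n
transcripts: ``V_i = sum_t M_ti / n`` and ``B_i = sum_t I_ti / n``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .model import (
    CoverageTrack,
    GeneLocus,
    MetaProfile,
    MethylationCallSet,
    TranscriptModel,
    ValidationError,
    tss_of,
)


@dataclass(frozen=True)
class GeneMethylation:
    """Methylated/unmethylated totals and level M = m/(m+u) for one gene."""

    gene_id: str
    m: int
    u: int

    @property
    def level(self) -> float:
        # M is zero if m = 0 (covers the fully uncovered gene as well)
        if self.m == 0:
            return 0.0
        return self.m / (self.m + self.u)


def gene_methylation_level(
    gene: GeneLocus, calls: MethylationCallSet
) -> GeneMethylation:
    """Sum methylated/unmethylated calls (both strands) over the gene span."""
    span = gene.span
    rec = calls.query(span.chrom, span.start, span.end)
    return GeneMethylation(
        gene_id=gene.gene_id, m=int(rec["m"].sum()), u=int(rec["u"].sum())
    )


def compare_methylation_distributions(
    lincrna_levels: Sequence[float], coding_levels: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (D, asymptotic p)."""
    if len(lincrna_levels) < 2 or len(coding_levels) < 2:
        raise ValidationError("KS comparison needs >= 2 values per sample")
    res = stats.ks_2samp(lincrna_levels, coding_levels, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _window(t: TranscriptModel, flank: int) -> tuple[str, int, int, bool]:
    """Genomic window around the TSS and whether bins must be reversed.

    The window holds ``flank`` bases on each side of the TSS, with the TSS
    base itself the first base of the downstream half in transcription
    direction; minus-strand windows are shifted by one base so that the
    reversed bin order keeps that alignment exactly.
    """
    chrom, p = tss_of(t)
    if t.strand == "+":
        return chrom, p - flank, p + flank, False
    return chrom, p - flank + 1, p + flank + 1, True


def _require_transcripts(transcripts: Sequence[TranscriptModel]) -> None:
    if not transcripts:
        raise ValidationError("profile requires at least one transcript")


def tss_methylation_profile(
    transcripts: Sequence[TranscriptModel],
    calls: MethylationCallSet,
    bin_width: int = 100,
    flank: int = 5000,
    per_covered: bool = False,
) -> MetaProfile:
    """Average methylation level in TSS-centred bins.

    ``per_covered=False`` (default) averages M_ti over all n transcripts,
    bins without calls contributing 0; ``per_covered=True`` averages each
    bin over the transcripts with at least one call in it.
    """
    _require_transcripts(transcripts)
    n_bins = 2 * flank // bin_width
    level_sum = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    for t in transcripts:
        chrom, start, end, rev = _window(t, flank)
        rec = calls.query(chrom, max(start, 0), end)
        m = np.zeros(n_bins)
        u = np.zeros(n_bins)
        if len(rec["pos"]):
            idx = (rec["pos"] - start) // bin_width
            np.add.at(m, idx, rec["m"])
            np.add.at(u, idx, rec["u"])
        if rev:
            m, u = m[::-1], u[::-1]
        tot = m + u
        with np.errstate(invalid="ignore"):
            level = np.where(m > 0, m / np.where(tot > 0, tot, 1), 0.0)
        level_sum += level
        covered += tot > 0
    if per_covered:
        values = np.where(covered > 0, level_sum / np.where(covered > 0, covered, 1), 0.0)
    else:
        values = level_sum / len(transcripts)
    return MetaProfile(
        values=values,
        n_transcripts=len(transcripts),
        kind="methylation",
        bin_width=bin_width,
        flank=flank,
    )


def tss_binding_profile(
    transcripts: Sequence[TranscriptModel],
    track: CoverageTrack,
    bin_width: int = 100,
    flank: int = 5000,
) -> MetaProfile:
    """Average per-base read depth (binding intensity) in TSS-centred bins."""
    _require_transcripts(transcripts)
    n_bins = 2 * flank // bin_width
    total = np.zeros(n_bins)
    for t in transcripts:
        chrom, start, end, rev = _window(t, flank)
        depth = np.zeros(end - start)
        if end > 0:
            clip_lo = max(start, 0)
            depth[clip_lo - start :] = track.depth_array(chrom, clip_lo, end)
        intensity = depth.reshape(n_bins, bin_width).mean(axis=1)
        if rev:
            intensity = intensity[::-1]
        total += intensity
    return MetaProfile(
        values=total / len(transcripts),
        n_transcripts=len(transcripts),
        kind="binding",
        bin_width=bin_width,
        flank=flank,
    )


def _fetch_window(genome, chrom: str, start: int, end: int) -> str:
    """Upper-case sequence of [start, end), padded with N outside the
    chromosome. ``genome`` is a pyfaidx.Fasta or a mapping chrom -> str."""
    try:
        seq = genome[chrom]
    except KeyError:
        return "N" * (end - start)
    length = len(seq)
    clip_lo, clip_hi = max(start, 0), min(end, length)
    if clip_hi <= clip_lo:
        return "N" * (end - start)
    core = str(seq[clip_lo:clip_hi]).upper()
    return "N" * (clip_lo - start) + core + "N" * (end - clip_hi)


def _sequence_profile(
    transcripts: Sequence[TranscriptModel],
    genome,
    window_fn,
    kind: str,
    bin_width: int,
    flank: int,
    step: int | None = None,
) -> MetaProfile:
    _require_transcripts(transcripts)
    step = step or bin_width  # non-overlapping windows by default
    if (2 * flank) % step:
        raise ValidationError("flank must be a multiple of the window step")
    n_bins = 2 * flank // step
    value_sum = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for t in transcripts:
        chrom, start, end, rev = _window(t, flank)
        seq = _fetch_window(genome, chrom, start, end)
        vals = np.empty(n_bins)
        for i in range(n_bins):
            centre = i * step
            vals[i] = window_fn(seq[centre : centre + bin_width])
        if rev:
            vals = vals[::-1]
        ok = ~np.isnan(vals)
        value_sum[ok] += vals[ok]
        counts += ok
    values = np.where(counts > 0, value_sum / np.where(counts > 0, counts, 1), 0.0)
    # the profile's bin spacing is the step; windows of `bin_width` bases
    # are evaluated at each step (step == bin_width -> non-overlapping tiling)
    return MetaProfile(
        values=values, n_transcripts=len(transcripts), kind=kind,
        bin_width=step, flank=flank,
    )


def gc_fraction(window: str) -> float:
    """(G+C) / (A+C+G+T) of a window; NaN when the window has no ACGT base."""
    gc = window.count("G") + window.count("C")
    acgt = gc + window.count("A") + window.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


def cpg_oe(window: str) -> float:
    """CpG observed/expected ratio: (#CpG * L) / (#C * #G).

    L counts the window's ACGT bases; the ratio is 0 when the window has
    no C or no G, and NaN for an all-N window.
    """
    c = window.count("C")
    g = window.count("G")
    length = c + g + window.count("A") + window.count("T")
    if length == 0:
        return float("nan")
    if c == 0 or g == 0:
        return 0.0
    return window.count("CG") * length / (c * g)


def gc_content_profile(
    transcripts: Sequence[TranscriptModel],
    genome,
    bin_width: int = 100,
    flank: int = 5000,
    step: int | None = None,
) -> MetaProfile:
    """Mean GC content in 100-bp windows around TSSs."""
    return _sequence_profile(
        transcripts, genome, gc_fraction, "gc", bin_width, flank, step
    )


def cpg_oe_profile(
    transcripts: Sequence[TranscriptModel],
    genome,
    bin_width: int = 100,
    flank: int = 5000,
    step: int | None = None,
) -> MetaProfile:
    """Mean CpG observed/expected ratio in 100-bp windows around TSSs."""
    return _sequence_profile(
        transcripts, genome, cpg_oe, "cpg_oe", bin_width, flank, step
    )


def transcripts_of(loci: Iterable[GeneLocus], per_gene: bool = False) -> list[TranscriptModel]:
    """Flatten loci to transcripts; ``per_gene=True`` keeps one canonical
    (longest, then lexicographically first) transcript per locus."""
    out = []
    for g in loci:
        ts = sorted(g.transcripts, key=lambda t: (-t.length, t.transcript_id))
        out.extend(ts[:1] if per_gene else g.transcripts)
    return out
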