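"""Genomic data model and coordinate conventions.

All coordinates are 0-based half-open internally. Format boundaries
(GTF: 1-based closed; Bismark cytosine reports: 1-based positions)
convert on read/write in :mod:`linctools.io`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an object violates a model invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on one strand of one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"empty/inverted interval [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Number of bases strictly between two intervals on one chromosome.

    Returns 0 for adjacent intervals and ``None`` when they overlap.
    ``a`` and ``b`` must lie on the same chromosome; strand is ignored.
    """
    if a.chrom != b.chrom:
        raise ValidationError(
            f"gap_distance across chromosomes {a.chrom!r} vs {b.chrom!r}"
        )
    if a.overlaps(b):
        return None
    if a.start < b.start:
        return b.start - a.end
    return a.start - b.end


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered exons on one strand of one chromosome."""

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValidationError(f"{self.transcript_id}: transcript has no exons")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValidationError(
                f"{self.transcript_id}: exons span multiple chroms/strands"
            )
        prev_end = -1
        for e in self.exons:
            if e.start < prev_end:
                raise ValidationError(
                    f"{self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = e.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        """Exonic (mature-transcript) length in nucleotides."""
        return sum(len(e) for e in self.exons)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for left, right in zip(self.exons, self.exons[1:]):
            if right.start > left.end:
                out.append(
                    GenomicInterval(self.chrom, left.end, right.start, self.strand)
                )
        return tuple(out)


def tss_of(t: TranscriptModel) -> tuple[str, int]:
    """0-based position of the transcription start base.

    Plus strand: leftmost base of the span; minus strand: rightmost.
    """
    if t.strand == "+":
        return t.chrom, t.span.start
    if t.strand == "-":
        return t.chrom, t.span.end - 1
    raise ValidationError(f"{t.transcript_id}: TSS undefined for unstranded transcript")


@dataclass(frozen=True)
class HousekeepingHit:
    """One BLASTN alignment of a candidate against a housekeeping-RNA database."""

    evalue: float
    percent_identity: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValidationError("negative e-value")
        if not 0 <= self.percent_identity <= 100:
            raise ValidationError("percent identity outside [0, 100]")


@dataclass(frozen=True)
class TranscriptEvidence:
    """Per-transcript assembly and scoring evidence.

    ``exon_coverage_fraction`` and ``junction_read_counts`` are ``None`` for
    annotation-derived transcripts (RefSeq/UniGene path), which skip the
    read-support filters. ``coding_potential_score`` follows the CPC sign
    convention: negative means noncoding.
    """

    transcript_id: str
    exon_coverage_fraction: float | None = None
    junction_read_counts: tuple[int, ...] | None = None
    coding_potential_score: float | None = None
    housekeeping_hits: tuple[HousekeepingHit, ...] = ()

    def __post_init__(self) -> None:
        f = self.exon_coverage_fraction
        if f is not None and not 0.0 <= f <= 1.0:
            raise ValidationError(
                f"{self.transcript_id}: exon coverage {f} outside [0, 1]"
            )
        if self.junction_read_counts is not None and any(
            c < 0 for c in self.junction_read_counts
        ):
            raise ValidationError(f"{self.transcript_id}: negative junction count")


BIOTYPES = ("coding", "lincRNA", "housekeeping", "other")


@dataclass(frozen=True)
class GeneLocus:
    """A gene: one or more transcripts sharing a chromosome and strand."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"{self.gene_id}: locus without transcripts")
        if self.biotype not in BIOTYPES:
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if len({(t.chrom, t.strand) for t in self.transcripts}) > 1:
            raise ValidationError(
                f"{self.gene_id}: transcripts on different chroms/strands"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        start = min(t.span.start for t in self.transcripts)
        end = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, start, end, self.strand)


class ExpressionMatrix:
    """Non-negative FPKM values for genes across named tissues.

    Thin wrapper over a pandas DataFrame (genes as rows, tissues as columns)
    that enforces non-negativity and unique tissue labels.
    """

    def __init__(self, values: pd.DataFrame):
        if values.columns.duplicated().any():
            raise ValidationError("duplicate tissue labels")
        if values.index.duplicated().any():
            raise ValidationError("duplicate gene ids")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("NaN expression value")
        if (arr < 0).any():
            raise ValidationError("negative FPKM value")
        self.values = values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.values.columns)

    def collapse_replicates(self, sep: str = ":") -> "ExpressionMatrix":
        """Average replicate columns labelled ``tissue<sep>replicate``.

        Columns without the separator are kept as-is; column order follows
        first appearance of each tissue label.
        """
        tissues = [c.split(sep, 1)[0] for c in self.values.columns]
        grouped = self.values.T.groupby(tissues, sort=False).mean().T
        return ExpressionMatrix(grouped)


class MethylationCallSet:
    """Per-cytosine methylated (m) / unmethylated (u) base-call counts.

    Stored as per-chromosome position-sorted numpy arrays for fast window
    queries; positions are 0-based and unique per (chrom, pos, strand).
    """

    def __init__(self, df: pd.DataFrame):
        required = ["chrom", "pos", "strand", "m", "u"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"call set missing columns {missing}")
        if len(df) and ((df["m"] < 0).any() or (df["u"] < 0).any()):
            raise ValidationError("negative methylation counts")
        if df.duplicated(subset=["chrom", "pos", "strand"]).any():
            raise ValidationError("duplicate (chrom, pos, strand) records")
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("pos", kind="mergesort")
            self._by_chrom[str(chrom)] = {
                "pos": sub["pos"].to_numpy(np.int64),
                "strand": sub["strand"].to_numpy(dtype="U1"),
                "m": sub["m"].to_numpy(np.int64),
                "u": sub["u"].to_numpy(np.int64),
            }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def __len__(self) -> int:
        return sum(len(v["pos"]) for v in self._by_chrom.values())

    def query(self, chrom: str, start: int, end: int) -> dict[str, np.ndarray]:
        """All records with start <= pos < end, both strands, position-sorted."""
        data = self._by_chrom.get(chrom)
        if data is None:
            empty = np.empty(0, np.int64)
            return {
                "pos": empty,
                "strand": np.empty(0, dtype="U1"),
                "m": empty,
                "u": empty,
            }
        lo, hi = np.searchsorted(data["pos"], [start, end])
        return {k: v[lo:hi] for k, v in data.items()}

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": d["pos"],
                    "strand": d["strand"],
                    "m": d["m"],
                    "u": d["u"],
                }
            )
            for chrom, d in sorted(self._by_chrom.items())
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "pos", "strand", "m", "u"])
        return pd.concat(frames, ignore_index=True)


class CoverageTrack:
    """Per-base read depth stored as run-length intervals.

    Positions absent from the track have depth 0. Intervals within a
    chromosome must be sorted and non-overlapping.
    """

    def __init__(self, df: pd.DataFrame):
        required = ["chrom", "start", "end", "depth"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"coverage track missing columns {missing}")
        if len(df) and (df["depth"] < 0).any():
            raise ValidationError("negative depth")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValidationError("empty or inverted coverage interval")
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start", kind="mergesort")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError(f"overlapping coverage intervals on {chrom}")
            self._by_chrom[str(chrom)] = {
                "start": starts,
                "end": ends,
                "depth": sub["depth"].to_numpy(float),
            }

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def depth_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end); start may be negative (depth 0)."""
        if end <= start:
            raise ValidationError("empty query window")
        out = np.zeros(end - start, dtype=float)
        data = self._by_chrom.get(chrom)
        if data is None:
            return out
        lo = np.searchsorted(data["end"], start, side="right")
        hi = np.searchsorted(data["start"], end, side="left")
        for s, e, d in zip(
            data["start"][lo:hi], data["end"][lo:hi], data["depth"][lo:hi]
        ):
            a = max(s, start) - start
            b = min(e, end) - start
            out[a:b] = d
        return out

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"chrom": chrom, "start": d["start"], "end": d["end"], "depth": d["depth"]}
            )
            for chrom, d in sorted(self._by_chrom.items())
        ]
        if not frames:
            return pd.DataFrame(columns=["chrom", "start", "end", "depth"])
        return pd.concat(frames, ignore_index=True)


PROFILE_KINDS = ("methylation", "binding", "gc", "cpg_oe")


@dataclass(frozen=True)
class MetaProfile:
    """A signal averaged over transcripts in 100 bins spanning TSS +/- 5 kb.

    Bins are ordered 5'->3' in transcription direction: bin 0 covers
    offsets -5000..-4901 and bin 99 covers +4900..+4999.
    """

    values: np.ndarray
    n_transcripts: int
    kind: str
    bin_width: int = 100
    flank: int = 5000

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        n_bins = 2 * self.flank // self.bin_width
        if self.values.shape != (n_bins,):
            raise ValidationError(
                f"profile must have {n_bins} bins, got {self.values.shape}"
            )
        if self.kind not in PROFILE_KINDS:
            raise ValidationError(f"unknown profile kind {self.kind!r}")
        if self.kind == "methylation" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValidationError("methylation bin value outside [0, 1]")
        if self.kind != "methylation" and (self.values < 0).any():
            raise ValidationError("negative profile bin value")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the TSS, in bp."""
        return np.arange(self.n_bins) * self.bin_width - self.flank

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(1, self.n_bins + 1),
                "offset_bp": self.offsets,
                "value": self.values,
                "n": self.n_transcripts,
            }
        )


def _exon_overlap_any(a: TranscriptModel, b: TranscriptModel) -> bool:
    for ea in a.exons:
        for eb in b.exons:
            if ea.start < eb.end and eb.start < ea.end:
                return True
    return False


def cluster_transcripts_into_loci(
    transcripts: Iterable[TranscriptModel],
    biotype: str = "other",
    locus_prefix: str = "LOC",
) -> list[GeneLocus]:
    """Single-linkage clustering of transcripts into gene loci.

    Two transcripts share a locus iff they are connected by a chain of pairs
    with >= 1 bp of *exonic* overlap on the same chromosome and strand
    (transcripts overlapping only across introns stay separate). Locus ids
    are assigned deterministically by (chrom, leftmost span coordinate).
    """
    transcripts = list(transcripts)
    parent = list(range(len(transcripts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    # sweep over exons grouped by (chrom, strand): exons overlapping an
    # active exon merge their transcripts
    events: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for idx, t in enumerate(transcripts):
        key = (t.chrom, t.strand)
        for e in t.exons:
            events.setdefault(key, []).append((e.start, e.end, idx))
    for key, exons in events.items():
        exons.sort()
        active: list[tuple[int, int]] = []  # (end, idx)
        for start, end, idx in exons:
            active = [(e, i) for e, i in active if e > start]
            for _, other in active:
                union(idx, other)
            active.append((end, idx))
    groups: dict[int, list[TranscriptModel]] = {}
    for idx, t in enumerate(transcripts):
        groups.setdefault(find(idx), []).append(t)
    loci_members = sorted(
        groups.values(),
        key=lambda ts: (
            ts[0].chrom,
            min(t.span.start for t in ts),
            min(t.transcript_id for t in ts),
        ),
    )
    loci = []
    for k, members in enumerate(loci_members, start=1):
        members = sorted(members, key=lambda t: (t.span.start, t.transcript_id))
        gene_id = f"{locus_prefix}{k:06d}"
        loci.append(
            GeneLocus(
                gene_id=gene_id,
                transcripts=tuple(
                    TranscriptModel(t.transcript_id, gene_id, t.exons) for t in members
                ),
                biotype=biotype,
            )
        )
    return loci


def sort_loci(loci: Iterable[GeneLocus]) -> list[GeneLocus]:
    """Deterministic (chrom, start, gene_id) ordering used by all writers."""
    return sorted(loci, key=lambda g: (g.chrom, g.span.start, g.gene_id))
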