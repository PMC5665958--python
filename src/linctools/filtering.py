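"""The lincRNA-definition filter cascade and interval statistics.

A candidate transcript is kept as a lincRNA only if it

* has at least two exons and an exonic length above 200 nt,
* is supported by assembly evidence (exon read coverage >= 80%, every
  splice junction covered by >= 3 reads) when such evidence exists,
* lies at least 500 bp from any protein-coding or housekeeping gene,
* scores below -1 with a CPC-style coding-potential classifier, and
* has no significant BLASTN alignment to housekeeping RNAs
  (e-value <= 1e-10 at >= 80% identity).

Candidates derived from curated annotation rather than RNA-seq assembly
carry no coverage/junction evidence; those two filters report
"not-evaluated" for them and do not block the cascade.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    GeneLocus,
    TranscriptEvidence,
    TranscriptModel,
    ValidationError,
    cluster_transcripts_into_loci,
    gap_distance,
)

PASS, FAIL, NOT_EVALUATED = "pass", "fail", "not-evaluated"

FILTER_ORDER = (
    "multi_exonic",
    "length",
    "exon_coverage",
    "junction_support",
    "intergenic",
    "coding_potential",
    "housekeeping",
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the cascade; defaults encode the published criteria."""

    min_exon_coverage: float = 0.8  # "at least 80%": inclusive
    min_junction_reads: int = 3  # "at least three reads": inclusive, per intron
    min_exons: int = 2  # "at least two exons"
    min_length_nt: int = 201  # "more than 200 nucleotides": strict
    min_intergenic_gap: int = 500  # "at least 500 bp away": inclusive
    max_cpc_score: float = -1.0  # "less than -1": strict
    hk_max_evalue: float = 1e-10
    hk_min_identity: float = 80.0

    def __post_init__(self) -> None:
        for name in (
            "min_exon_coverage",
            "min_junction_reads",
            "min_exons",
            "min_length_nt",
            "min_intergenic_gap",
            "hk_max_evalue",
            "hk_min_identity",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass
class FilterAudit:
    """Per-transcript record of every filter verdict and the final class."""

    transcript_id: str
    verdicts: dict[str, str] = field(
        default_factory=lambda: {name: NOT_EVALUATED for name in FILTER_ORDER}
    )
    final_class: str = "rejected"

    @property
    def is_lincrna(self) -> bool:
        return self.final_class == "lincRNA"


def filter_exon_coverage(ev: TranscriptEvidence | None, cfg: FilterConfig) -> str:
    if ev is None or ev.exon_coverage_fraction is None:
        return NOT_EVALUATED
    return PASS if ev.exon_coverage_fraction >= cfg.min_exon_coverage else FAIL


def filter_junction_support(
    ev: TranscriptEvidence | None,
    cfg: FilterConfig,
    transcript: TranscriptModel | None = None,
) -> str:
    """Every intron must carry at least ``min_junction_reads`` reads.

    A transcript is passed vacuously when its junction list is empty
    (single-exon candidates are rejected by the structure filter instead).
    """
    if ev is None or ev.junction_read_counts is None:
        return NOT_EVALUATED
    if transcript is not None and len(ev.junction_read_counts) != transcript.exon_count - 1:
        raise ValidationError(
            f"{ev.transcript_id}: {len(ev.junction_read_counts)} junction counts "
            f"for {transcript.exon_count} exons"
        )
    return (
        PASS
        if all(c >= cfg.min_junction_reads for c in ev.junction_read_counts)
        else FAIL
    )


def filter_structure(t: TranscriptModel, cfg: FilterConfig) -> tuple[str, str]:
    """(multi-exonic verdict, length verdict)."""
    multi = PASS if t.exon_count >= cfg.min_exons else FAIL
    length = PASS if t.length >= cfg.min_length_nt else FAIL
    return multi, length


def classify_intergenic(
    t: TranscriptModel,
    annotation: Iterable[GeneLocus],
    cfg: FilterConfig,
    _index: Mapping[str, list[GeneLocus]] | None = None,
) -> str:
    """Intergenic iff the span is >= ``min_intergenic_gap`` bp from every
    coding/housekeeping locus span, on either strand."""
    span = t.span
    if _index is not None:
        candidates = _index.get(t.chrom, [])
    else:
        candidates = [
            g
            for g in annotation
            if g.biotype in ("coding", "housekeeping") and g.chrom == t.chrom
        ]
    for g in candidates:
        d = gap_distance(span, g.span)
        if d is None or d < cfg.min_intergenic_gap:
            return FAIL
    return PASS


def filter_coding_potential(ev: TranscriptEvidence | None, cfg: FilterConfig) -> str:
    if ev is None or ev.coding_potential_score is None:
        return NOT_EVALUATED
    return PASS if ev.coding_potential_score < cfg.max_cpc_score else FAIL


def filter_housekeeping(ev: TranscriptEvidence | None, cfg: FilterConfig) -> str:
    if ev is None:
        return NOT_EVALUATED
    for hit in ev.housekeeping_hits:
        if hit.evalue <= cfg.hk_max_evalue and hit.percent_identity >= cfg.hk_min_identity:
            return FAIL
    return PASS


def _annotation_index(annotation: Iterable[GeneLocus]) -> dict[str, list[GeneLocus]]:
    index: dict[str, list[GeneLocus]] = {}
    for g in annotation:
        if g.biotype in ("coding", "housekeeping"):
            index.setdefault(g.chrom, []).append(g)
    return index


def run_filter_cascade(
    transcripts: Sequence[TranscriptModel],
    evidence: Mapping[str, TranscriptEvidence],
    annotation: Sequence[GeneLocus],
    cfg: FilterConfig | None = None,
    short_circuit: bool = True,
) -> tuple[list[GeneLocus], list[FilterAudit]]:
    """Apply the full cascade and cluster the survivors into loci.

    Filters run in a fixed order (structure, exon coverage, junction
    support, intergenic, coding potential, housekeeping); by default a
    transcript stops at its first failure, leaving later verdicts
    not-evaluated. With ``short_circuit=False`` every filter is evaluated
    regardless — the surviving set is identical because the filters are
    independent predicates.
    """
    cfg = cfg or FilterConfig()
    index = _annotation_index(annotation)
    audits: list[FilterAudit] = []
    survivors: list[TranscriptModel] = []
    for t in transcripts:
        ev = evidence.get(t.transcript_id)
        audit = FilterAudit(transcript_id=t.transcript_id)
        multi, length = filter_structure(t, cfg)
        checks = [
            ("multi_exonic", lambda: multi),
            ("length", lambda: length),
            ("exon_coverage", lambda: filter_exon_coverage(ev, cfg)),
            ("junction_support", lambda: filter_junction_support(ev, cfg, t)),
            ("intergenic", lambda: classify_intergenic(t, annotation, cfg, index)),
            ("coding_potential", lambda: filter_coding_potential(ev, cfg)),
            ("housekeeping", lambda: filter_housekeeping(ev, cfg)),
        ]
        failed = False
        for name, check in checks:
            verdict = check()
            audit.verdicts[name] = verdict
            if verdict == FAIL:
                failed = True
                if short_circuit:
                    break
        if not failed:
            audit.final_class = "lincRNA"
            survivors.append(t)
        audits.append(audit)
    loci = cluster_transcripts_into_loci(
        survivors, biotype="lincRNA", locus_prefix="LINC"
    )
    return loci, audits


def stage_counts(audits: Sequence[FilterAudit]) -> pd.DataFrame:
    """Survivor counts after each stage of the cascade (the funnel)."""
    rows = [{"stage": "input", "surviving": len(audits)}]
    remaining = list(audits)
    for name in FILTER_ORDER:
        remaining = [a for a in remaining if a.verdicts[name] != FAIL]
        rows.append({"stage": name, "surviving": len(remaining)})
    return pd.DataFrame(rows)


def audits_to_frame(audits: Sequence[FilterAudit]) -> pd.DataFrame:
    rows = []
    for a in audits:
        row = {"transcript_id": a.transcript_id}
        row.update(a.verdicts)
        row["final_class"] = a.final_class
        rows.append(row)
    return pd.DataFrame(rows, columns=["transcript_id", *FILTER_ORDER, "final_class"])


# --------------------------------------------------------------------------
# Interval statistics (lincRNA placement relative to coding genes)


def _nearest_gap(span, others) -> int | None:
    """Smallest gap from ``span`` to any interval in ``others`` (same chrom);
    overlap counts as gap 0. None when ``others`` is empty."""
    best = None
    for o in others:
        d = gap_distance(span, o)
        d = 0 if d is None else d
        if best is None or d < best:
            best = d
    return best


def interval_statistics(
    lincrna_loci: Sequence[GeneLocus], coding_loci: Sequence[GeneLocus]
) -> dict:
    """Compare lincRNA–mRNA intervals with mRNA–mRNA intervals and mRNA
    intron lengths.

    Returns per-lincRNA gaps to the nearest coding locus, per-coding-locus
    gaps to the nearest other coding locus, all intron lengths of coding
    transcripts, the median of each sample, and two-sided rank-sum
    (Mann-Whitney) p-values for lincRNA-gap vs coding-gap and lincRNA-gap
    vs intron-length.
    """
    if not lincrna_loci or not coding_loci:
        raise ValidationError("interval statistics need non-empty locus sets")
    coding_by_chrom: dict[str, list] = {}
    for g in coding_loci:
        coding_by_chrom.setdefault(g.chrom, []).append(g.span)
    linc_gaps = []
    for g in lincrna_loci:
        gap = _nearest_gap(g.span, coding_by_chrom.get(g.chrom, []))
        if gap is not None:
            linc_gaps.append(gap)
    coding_gaps = []
    for g in coding_loci:
        others = [s for s in coding_by_chrom.get(g.chrom, []) if s != g.span]
        gap = _nearest_gap(g.span, others)
        if gap is not None:
            coding_gaps.append(gap)
    intron_lengths = [
        len(iv) for g in coding_loci for t in g.transcripts for iv in t.introns
    ]
    out = {
        "lincrna_gap": np.asarray(linc_gaps, float),
        "coding_gap": np.asarray(coding_gaps, float),
        "coding_intron_length": np.asarray(intron_lengths, float),
        "median_lincrna_gap": float(np.median(linc_gaps)) if linc_gaps else float("nan"),
        "median_coding_gap": float(np.median(coding_gaps)) if coding_gaps else float("nan"),
        "median_coding_intron_length": float(np.median(intron_lengths))
        if intron_lengths
        else float("nan"),
    }
    out["p_gap_vs_gap"] = _ranksum_p(out["lincrna_gap"], out["coding_gap"])
    out["p_gap_vs_intron"] = _ranksum_p(out["lincrna_gap"], out["coding_intron_length"])
    return out


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney p: exact when the combined sample is small
    and tie-free, otherwise the tie-corrected normal approximation."""
    if len(x) == 0 or len(y) == 0:
        return float("nan")
    method = "exact" if (len(x) + len(y) <= 20 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def transcript_length_distribution(loci: Sequence[GeneLocus]) -> pd.DataFrame:
    """Exonic length of every transcript, tagged with its locus biotype."""
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "length": t.length,
        }
        for g in loci
        for t in g.transcripts
    ]
    return pd.DataFrame(rows, columns=["transcript_id", "gene_id", "biotype", "length"])
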