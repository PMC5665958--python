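"""Readers and writers for the standard genomic formats.

GTF is 1-based closed on disk and converts to the internal 0-based
half-open convention at this boundary; bedGraph and BED are already
0-based half-open; Bismark-style cytosine reports are 1-based. All text
readers are gzip-transparent (a ``.gz`` suffix triggers decompression).
"""
from __future__ import annotations

import gzip
import io as _io
import os
from collections import OrderedDict
from pathlib import Path
from typing import Iterable

import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    CoverageTrack,
    ExpressionMatrix,
    GeneLocus,
    GenomicInterval,
    HousekeepingHit,
    MethylationCallSet,
    MetaProfile,
    TranscriptEvidence,
    TranscriptModel,
    ValidationError,
    sort_loci,
)


class ParseError(ValueError):
    """Raised for malformed input lines; carries the file and line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _open_text(path, mode: str = "rt"):
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# --------------------------------------------------------------------------
# GTF


def read_gtf(path) -> list[GeneLocus]:
    """Read a GTF annotation into gene loci.

    Only ``exon`` features are used to build transcript structures; the
    gene biotype is taken from a ``gene_biotype`` (or ``gene_type``)
    attribute when present and mapped onto the internal biotype vocabulary,
    else "other".
    """
    exons: "OrderedDict[str, list]" = OrderedDict()
    tx_gene: dict[str, str] = {}
    gene_biotype: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise ParseError(path, lineno, "expected 9 tab-separated columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(path, lineno, f"unparseable GTF line ({exc})")
            if feat.featuretype != "exon":
                continue
            try:
                gid = feat.attributes["gene_id"][0]
                tid = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(path, lineno, f"missing attribute {exc}")
            if feat.end < feat.start:
                raise ValidationError(f"{path}:{lineno}: exon end < start")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons.setdefault(tid, []).append(iv)
            tx_gene[tid] = gid
            bt = feat.attributes.get("gene_biotype") or feat.attributes.get("gene_type")
            if bt:
                gene_biotype[gid] = _map_biotype(bt[0])
    by_gene: "OrderedDict[str, list[TranscriptModel]]" = OrderedDict()
    for tid, ivs in exons.items():
        ivs = sorted(ivs, key=lambda e: e.start)
        gid = tx_gene[tid]
        by_gene.setdefault(gid, []).append(TranscriptModel(tid, gid, tuple(ivs)))
    loci = [
        GeneLocus(
            gene_id=gid,
            transcripts=tuple(sorted(ts, key=lambda t: (t.span.start, t.transcript_id))),
            biotype=gene_biotype.get(gid, "other"),
        )
        for gid, ts in by_gene.items()
    ]
    return sort_loci(loci)


_BIOTYPE_MAP = {
    "protein_coding": "coding",
    "coding": "coding",
    "lincrna": "lincRNA",
    "lincRNA": "lincRNA",
    "trna": "housekeeping",
    "snrna": "housekeeping",
    "snorna": "housekeeping",
    "rrna": "housekeeping",
    "housekeeping": "housekeeping",
}


def _map_biotype(raw: str) -> str:
    return _BIOTYPE_MAP.get(raw, _BIOTYPE_MAP.get(raw.lower(), "other"))


_WRITE_BIOTYPE = {
    "coding": "protein_coding",
    "lincRNA": "lincRNA",
    "housekeeping": "housekeeping",
    "other": "other",
}


def write_gtf(loci: Iterable[GeneLocus], path, source: str = "linctools") -> None:
    """Write loci as an Ensembl-dialect GTF (1-based closed coordinates)."""
    lines = ["##gff-version 2", "#!linctools GTF export"]
    for locus in sort_loci(loci):
        bt = _WRITE_BIOTYPE[locus.biotype]
        for t in locus.transcripts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{locus.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_biotype "{bt}";'
                )
                lines.append(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                )
    with _open_text(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Methylation calls (cytosine-report dialect)

_CALL_COLUMNS = ["chrom", "pos", "strand", "m", "u"]


def read_methylation_calls(path) -> MethylationCallSet:
    """Read a Bismark-style cytosine report.

    Tab-separated columns: chromosome, 1-based position, strand, count of
    methylated calls, count of unmethylated calls. Extra columns (context
    fields of the full Bismark report) are ignored.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=range(5),
            names=_CALL_COLUMNS,
            dtype={"chrom": str, "pos": int, "strand": str, "m": int, "u": int},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_CALL_COLUMNS)
    if len(df):
        df["pos"] = df["pos"] - 1  # 1-based on disk
        if (df["pos"] < 0).any():
            raise ValidationError(f"{path}: non-positive cytosine position")
    try:
        return MethylationCallSet(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")


def write_methylation_calls(calls: MethylationCallSet, path) -> None:
    df = calls.to_frame()
    df = df.assign(pos=df["pos"] + 1)
    df.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# Coverage (bedGraph)


def read_coverage_bedgraph(path) -> CoverageTrack:
    """Read a 0-based half-open bedGraph into a run-length coverage track."""
    try:
        df = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "depth"],
            dtype={"chrom": str, "start": int, "end": int, "depth": float},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["chrom", "start", "end", "depth"])
    try:
        return CoverageTrack(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")


def write_coverage_bedgraph(track: CoverageTrack, path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------------
# Evidence table and housekeeping hits


def read_evidence_table(path) -> dict[str, TranscriptEvidence]:
    """Read the per-transcript evidence TSV.

    Header columns: transcript_id, exon_coverage, junction_reads
    (comma-joined ints), cpc_score. "NA" marks evidence not produced for a
    transcript (annotation-derived candidates).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("NA")
    required = {"transcript_id", "exon_coverage", "junction_reads", "cpc_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: evidence table missing columns {sorted(missing)}")
    out: dict[str, TranscriptEvidence] = {}
    for row in df.itertuples(index=False):
        cov = None if row.exon_coverage == "NA" else float(row.exon_coverage)
        if row.junction_reads == "NA":
            jr = None
        elif row.junction_reads == "":
            jr = ()
        else:
            jr = tuple(int(x) for x in str(row.junction_reads).split(","))
        cpc = None if row.cpc_score == "NA" else float(row.cpc_score)
        out[row.transcript_id] = TranscriptEvidence(
            transcript_id=row.transcript_id,
            exon_coverage_fraction=cov,
            junction_read_counts=jr,
            coding_potential_score=cpc,
        )
    return out


def write_evidence_table(evidence: Iterable[TranscriptEvidence], path) -> None:
    rows = []
    for ev in sorted(evidence, key=lambda e: e.transcript_id):
        rows.append(
            {
                "transcript_id": ev.transcript_id,
                "exon_coverage": "NA"
                if ev.exon_coverage_fraction is None
                else f"{ev.exon_coverage_fraction:.6g}",
                "junction_reads": "NA"
                if ev.junction_read_counts is None
                else ",".join(str(c) for c in ev.junction_read_counts),
                "cpc_score": "NA"
                if ev.coding_potential_score is None
                else f"{ev.coding_potential_score:.6g}",
            }
        )
    pd.DataFrame(
        rows, columns=["transcript_id", "exon_coverage", "junction_reads", "cpc_score"]
    ).to_csv(path, sep="\t", index=False)


_BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_housekeeping_hits(path) -> dict[str, tuple[HousekeepingHit, ...]]:
    """Read a BLAST outfmt-6 hit table keyed by query (transcript) id."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_BLAST6_COLUMNS)
    except pd.errors.EmptyDataError:
        return {}
    out: dict[str, list[HousekeepingHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.qseqid), []).append(
            HousekeepingHit(evalue=float(row.evalue), percent_identity=float(row.pident))
        )
    return {k: tuple(v) for k, v in out.items()}


def write_housekeeping_hits(
    hits: dict[str, tuple[HousekeepingHit, ...]], path
) -> None:
    rows = []
    for tid in sorted(hits):
        for h in hits[tid]:
            rows.append(
                [tid, "hkRNA", f"{h.percent_identity:.2f}", 100, 0, 0, 1, 100, 1, 100,
                 f"{h.evalue:.3g}", 200.0]
            )
    pd.DataFrame(rows, columns=_BLAST6_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# --------------------------------------------------------------------------
# Expression matrix


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes-by-tissues FPKM TSV (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


# --------------------------------------------------------------------------
# DMR BED-like table and profiles


DMR_COLUMNS = ["chrom", "start", "end", "dmr_id", "n_cpg", "mean1", "mean2", "score"]


def read_dmr_bed(path) -> pd.DataFrame:
    """Read DMRs from a BED-like TSV (chrom, start, end[, id, n_cpg, means, score])."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=DMR_COLUMNS)
    df = df.iloc[:, : len(DMR_COLUMNS)]
    df.columns = DMR_COLUMNS[: df.shape[1]]
    for col, default in [
        ("dmr_id", None), ("n_cpg", 0), ("mean1", float("nan")),
        ("mean2", float("nan")), ("score", float("nan")),
    ]:
        if col not in df.columns:
            df[col] = default
    if df["dmr_id"].isna().any():
        df["dmr_id"] = [f"dmr{i + 1}" for i in range(len(df))]
    df["dmr_id"] = df["dmr_id"].astype(str)
    return df[DMR_COLUMNS]


def write_dmr_bed(dmrs: pd.DataFrame, path) -> None:
    dmrs.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_profile(profile: MetaProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def atomic_write(path, write_fn) -> None:
    """Write via a temporary file and rename, so failures never leave
    partial final outputs."""
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp")
    write_fn(tmp)
    os.replace(tmp, path)
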