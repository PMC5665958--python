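"""Differentially methylated regions: a naive per-CpG caller and
DMR-gene overlap reporting.

The caller here is a deliberately simple stand-in for dedicated
beta-binomial DMR software (such as DSS): within each group, replicate
counts are pooled per CpG; each shared CpG gets a two-sided two-proportion
z-test; significant CpGs with a consistent direction are merged into
regions when consecutive ones lie within a merge gap, and regions must
reach a minimum length and CpG count. It is intended for synthetic data
and smoke testing — externally called DMRs can be supplied to
:func:`overlap_dmrs_with_genes` as a BED-like table instead.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import GeneLocus, GenomicInterval, MethylationCallSet, ValidationError


@dataclass(frozen=True)
class DMRRecord:
    interval: GenomicInterval
    dmr_id: str
    n_cpg: int
    mean_level_group1: float
    mean_level_group2: float
    score: float


def overlap_dmrs_with_genes(
    dmrs: pd.DataFrame | Sequence[DMRRecord], loci: Sequence[GeneLocus]
) -> pd.DataFrame:
    """Every (gene, DMR) pair with >= 1 bp overlap between the DMR interval
    and the gene span; strand is ignored. Output is sorted by
    (chrom, gene start, dmr_id)."""
    if not isinstance(dmrs, pd.DataFrame):
        dmrs = records_to_frame(dmrs)
    rows = []
    by_chrom: dict[str, list[GeneLocus]] = {}
    for g in loci:
        by_chrom.setdefault(g.chrom, []).append(g)
    for rec in dmrs.itertuples(index=False):
        for g in by_chrom.get(str(rec.chrom), []):
            span = g.span
            ov = min(int(rec.end), span.end) - max(int(rec.start), span.start)
            if ov > 0:
                rows.append(
                    {
                        "gene_id": g.gene_id,
                        "dmr_id": str(rec.dmr_id),
                        "chrom": g.chrom,
                        "gene_start": span.start,
                        "overlap_bp": ov,
                    }
                )
    df = pd.DataFrame(rows, columns=["gene_id", "dmr_id", "chrom", "gene_start", "overlap_bp"])
    df = df.sort_values(["chrom", "gene_start", "dmr_id"], kind="mergesort").reset_index(drop=True)
    return df[["gene_id", "dmr_id", "overlap_bp"]]


def _pool_counts(call_sets: Sequence[MethylationCallSet]) -> pd.DataFrame:
    frames = [cs.to_frame() for cs in call_sets]
    df = pd.concat(frames, ignore_index=True)
    # pool replicates and both strands of a CpG position
    return df.groupby(["chrom", "pos"], as_index=False)[["m", "u"]].sum()


def two_proportion_pvalues(
    m1: np.ndarray, n1: np.ndarray, m2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Vectorised two-sided two-proportion z-test with pooled variance.

    Sites where the pooled proportion is 0 or 1 (no evidence of any
    difference) get p = 1.
    """
    m1, n1, m2, n2 = (np.asarray(a, float) for a in (m1, n1, m2, n2))
    p1 = m1 / n1
    p2 = m2 / n2
    pooled = (m1 + m2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / np.sqrt(var)
    p = 2 * stats.norm.sf(np.abs(z))
    return np.where(var > 0, p, 1.0)


def call_dmrs_naive(
    group1: Sequence[MethylationCallSet],
    group2: Sequence[MethylationCallSet],
    p_threshold: float = 0.01,
    merge_gap: int = 100,
    min_length: int = 50,
    min_cpg: int = 3,
) -> list[DMRRecord]:
    """Call DMRs between two groups of replicate call sets.

    Counts are pooled within group at every CpG position present in both
    groups; per-CpG differences are tested with a two-sided two-proportion
    z-test; consecutive significant CpGs with the same direction of change
    are merged when <= ``merge_gap`` bp apart; regions are reported when
    spanning >= ``min_length`` bp with >= ``min_cpg`` CpGs.
    """
    if not group1 or not group2:
        raise ValidationError("each group needs at least one replicate")
    pooled1 = _pool_counts(group1)
    pooled2 = _pool_counts(group2)
    merged = pooled1.merge(pooled2, on=["chrom", "pos"], suffixes=("_1", "_2"))
    merged = merged[(merged.m_1 + merged.u_1 > 0) & (merged.m_2 + merged.u_2 > 0)]
    if merged.empty:
        warnings.warn("no shared covered cytosine positions between groups")
        return []
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n1 = (merged.m_1 + merged.u_1).to_numpy(float)
    n2 = (merged.m_2 + merged.u_2).to_numpy(float)
    pvals = two_proportion_pvalues(merged.m_1, n1, merged.m_2, n2)
    level1 = merged.m_1.to_numpy(float) / n1
    level2 = merged.m_2.to_numpy(float) / n2
    diff = level1 - level2
    sig = (pvals < p_threshold) & (diff != 0)
    records: list[DMRRecord] = []
    run: list[int] = []

    def flush(run_idx: list[int]) -> None:
        if len(run_idx) < min_cpg:
            return
        start = int(merged.pos.iloc[run_idx[0]])
        end = int(merged.pos.iloc[run_idx[-1]]) + 1
        if end - start < min_length:
            return
        chrom = str(merged.chrom.iloc[run_idx[0]])
        with np.errstate(divide="ignore"):
            score = float(np.sum(-np.log10(np.maximum(pvals[run_idx], 1e-300))))
        records.append(
            DMRRecord(
                interval=GenomicInterval(chrom, start, end, "."),
                dmr_id="",
                n_cpg=len(run_idx),
                mean_level_group1=float(level1[run_idx].mean()),
                mean_level_group2=float(level2[run_idx].mean()),
                score=score,
            )
        )

    for i in range(len(merged)):
        if not sig[i]:
            continue
        if run:
            prev = run[-1]
            same_chrom = merged.chrom.iloc[i] == merged.chrom.iloc[prev]
            close = merged.pos.iloc[i] - merged.pos.iloc[prev] <= merge_gap
            same_sign = np.sign(diff[i]) == np.sign(diff[prev])
            if not (same_chrom and close and same_sign):
                flush(run)
                run = []
        run.append(i)
    flush(run)
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return [
        DMRRecord(r.interval, f"dmr{i + 1}", r.n_cpg, r.mean_level_group1,
                  r.mean_level_group2, r.score)
        for i, r in enumerate(records)
    ]


def records_to_frame(records: Sequence[DMRRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.interval.chrom,
            "start": r.interval.start,
            "end": r.interval.end,
            "dmr_id": r.dmr_id,
            "n_cpg": r.n_cpg,
            "mean1": r.mean_level_group1,
            "mean2": r.mean_level_group2,
            "score": r.score,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "dmr_id", "n_cpg", "mean1", "mean2", "score"]
    )
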