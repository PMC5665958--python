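"""Jensen-Shannon tissue-specificity scoring.

A gene's expression vector across T tissues is normalised to a density p;
its specificity for tissue t is ``1 - sqrt(JSD(p, e_t))``, where ``e_t``
is the unit density concentrated in tissue t and JSD is the Jensen-Shannon
divergence with base-2 entropy (so JSD and the score both live in [0, 1]).
The gene's JS score is the maximum over tissues; a gene is called
tissue-specific when that maximum exceeds 0.5. A gene expressed in exactly
one tissue scores 1, the perfectly specific case.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ExpressionMatrix, GeneLocus, ValidationError, gap_distance

JS_SPECIFIC_THRESHOLD = 0.5


@dataclass(frozen=True)
class SpecificityResult:
    gene_id: str
    js_score: float
    best_tissue: str
    per_tissue_scores: dict[str, float]
    is_specific: bool
    evaluable: bool = True


def expression_density(x: np.ndarray) -> np.ndarray:
    """Normalise a non-negative expression vector to a probability density.

    Raises for negative entries; an all-zero vector has no density and
    raises (callers treat such genes as not-evaluable).
    """
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValidationError("negative expression value")
    total = x.sum()
    if total <= 0:
        raise ValidationError("all-zero expression vector has no density")
    return x / total


def _entropy_bits(p: np.ndarray) -> float:
    # 0 * log(0) := 0
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen-Shannon divergence in bits: H((p+q)/2) - (H(p)+H(q))/2.

    Symmetric, zero iff p == q, and bounded by 1 for base-2 entropy.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("density length mismatch")
    if (p < 0).any() or (q < 0).any():
        raise ValidationError("negative density entry")
    if abs(p.sum() - 1) > 1e-9 or abs(q.sum() - 1) > 1e-9:
        raise ValidationError("densities must sum to 1")
    jsd = _entropy_bits((p + q) / 2) - (_entropy_bits(p) + _entropy_bits(q)) / 2
    # clip float noise; true range is [0, 1]
    return float(min(max(jsd, 0.0), 1.0))


def specificity_score(p: np.ndarray, tissue_index: int) -> float:
    """``1 - sqrt(JSD(p, e_t))`` for the unit density of one tissue."""
    p = np.asarray(p, dtype=float)
    e_t = np.zeros_like(p)
    e_t[tissue_index] = 1.0
    return 1.0 - float(np.sqrt(js_divergence(p, e_t)))


def score_genes(matrix: ExpressionMatrix) -> list[SpecificityResult]:
    """Score every gene; the argmax tie-break is the lowest tissue index.

    Genes whose expression is zero in every tissue are returned with
    ``evaluable=False`` and a NaN score rather than being scored 0.
    """
    tissues = matrix.tissue_labels
    results: list[SpecificityResult] = []
    values = matrix.values.to_numpy(dtype=float)
    for gene_id, x in zip(matrix.gene_ids, values):
        if x.sum() <= 0:
            results.append(
                SpecificityResult(
                    gene_id=gene_id,
                    js_score=float("nan"),
                    best_tissue="",
                    per_tissue_scores={},
                    is_specific=False,
                    evaluable=False,
                )
            )
            continue
        p = expression_density(x)
        scores = {t: specificity_score(p, i) for i, t in enumerate(tissues)}
        best_idx = int(np.argmax([scores[t] for t in tissues]))  # first max wins
        best = tissues[best_idx]
        results.append(
            SpecificityResult(
                gene_id=gene_id,
                js_score=scores[best],
                best_tissue=best,
                per_tissue_scores=scores,
                is_specific=scores[best] > JS_SPECIFIC_THRESHOLD,
            )
        )
    return results


def results_to_frame(results: list[SpecificityResult]) -> pd.DataFrame:
    tissues: list[str] = []
    for r in results:
        for t in r.per_tissue_scores:
            if t not in tissues:
                tissues.append(t)
    rows = []
    for r in results:
        row = {
            "gene_id": r.gene_id,
            "js_score": r.js_score,
            "best_tissue": r.best_tissue,
            "is_specific": r.is_specific,
            "evaluable": r.evaluable,
        }
        for t in tissues:
            row[f"score_{t}"] = r.per_tissue_scores.get(t, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def nearest_coding_neighbors(
    lincrna_loci: list[GeneLocus], coding_loci: list[GeneLocus]
) -> pd.DataFrame:
    """For each lincRNA locus, the nearest coding locus on its chromosome.

    Distance is the gap between spans (0 for overlap); ties go to the
    leftmost coding locus. LincRNAs on chromosomes without coding loci are
    reported with an absent neighbor.
    """
    coding_by_chrom: dict[str, list[GeneLocus]] = {}
    for g in coding_loci:
        coding_by_chrom.setdefault(g.chrom, []).append(g)
    for lst in coding_by_chrom.values():
        lst.sort(key=lambda g: (g.span.start, g.gene_id))
    rows = []
    for linc in sorted(lincrna_loci, key=lambda g: (g.chrom, g.span.start, g.gene_id)):
        best_gene, best_gap = None, None
        for cand in coding_by_chrom.get(linc.chrom, []):
            d = gap_distance(linc.span, cand.span)
            d = 0 if d is None else d
            if best_gap is None or d < best_gap:
                best_gene, best_gap = cand, d
        rows.append(
            {
                "lincrna_gene_id": linc.gene_id,
                "coding_gene_id": best_gene.gene_id if best_gene else "",
                "gap": best_gap if best_gap is not None else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["lincrna_gene_id", "coding_gene_id", "gap"])
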