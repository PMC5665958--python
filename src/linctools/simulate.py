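"""Seeded generator of a desk-scale dataset with known ground truth.

The generator lays out coding, housekeeping and lincRNA genes plus decoy
candidates on a small multi-chromosome genome and emits every file the
pipeline consumes: annotation and candidate GTFs, the assembly-evidence
and housekeeping-hit tables, a genes-by-tissue FPKM matrix with
replicates, a genome FASTA, per-cytosine methylation reports for two
strain groups, a TF-binding coverage bedGraph, and a BED of planted DMRs
— together with truth tables recording what was planted.

The statistical shape follows the structure reported for real rat data:
lincRNAs are shorter, lower-expressed, further from coding genes and more
tissue-specific than coding genes; methylation dips in a V around every
TSS (a shallower dip for lincRNAs, so their TSS methylation stays
higher); TF binding peaks in an inverted V at the TSS; and differential
methylation is planted between the two groups inside chosen lincRNA loci.
Dips and peaks are triangular rather than Gaussian so tests can predict
bin values analytically.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneLocus,
    GenomicInterval,
    HousekeepingHit,
    MethylationCallSet,
    TranscriptEvidence,
    TranscriptModel,
    ValidationError,
)
from . import io as lio

DEFAULT_TISSUES = (
    "adrenal_gland",
    "brain",
    "heart",
    "kidney",
    "liver",
    "lung",
    "muscle",
    "spleen",
    "thymus",
    "testes",
    "uterus",
)


@dataclass(frozen=True)
class GenomeConfig:
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    gc_background: float = 0.42
    promoter_halfwidth: int = 500  # CpG-island-like region around each TSS
    promoter_cpg_period_coding: int = 8  # a CG dinucleotide every this many bp
    promoter_cpg_period_lincrna: int = 16


@dataclass(frozen=True)
class GeneSetConfig:
    n_coding: int = 300
    n_lincrna: int = 150
    n_housekeeping: int = 20
    # exon counts (uniform ranges, inclusive) and typical element sizes
    coding_exons: tuple[int, int] = (4, 10)
    lincrna_exons: tuple[int, int] = (2, 4)
    coding_exon_bp: tuple[int, int] = (120, 300)
    lincrna_exon_bp: tuple[int, int] = (150, 400)
    coding_intron_log_mean: float = 7.3  # lognormal, median ~1.5 kb
    coding_intron_log_sd: float = 0.6
    lincrna_intron_log_mean: float = 6.6  # median ~0.74 kb
    lincrna_intron_log_sd: float = 0.6
    # intergenic gaps: lognormal with a hard floor; gaps on either side of
    # a lincRNA are scaled up so lincRNA-mRNA intervals are stochastically
    # larger than mRNA-mRNA intervals
    gap_log_mean: float = 8.4  # median ~4.5 kb
    gap_log_sd: float = 0.5
    min_gap: int = 600
    lincrna_gap_factor: float = 2.5


@dataclass(frozen=True)
class ExpressionConfig:
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 2
    coding_log_mean: float = 2.7  # lognormal FPKM baseline, median ~15
    lincrna_log_mean: float = 0.7  # median ~2 (lower than coding)
    baseline_log_sd: float = 0.5  # across-tissue spread of non-specific genes
    replicate_log_sd: float = 0.25
    frac_specific_coding: float = 0.15
    frac_specific_lincrna: float = 0.40
    dominance_fold: float = 50.0
    # share of specific lincRNAs planted in testes, echoing the strong
    # testes bias seen in mammalian lincRNA surveys
    lincrna_testes_weight: float = 0.489


@dataclass(frozen=True)
class EvidenceNoiseConfig:
    # fraction of true lincRNAs handed failing evidence (0 = noise-free)
    frac_fail_coverage: float = 0.0
    frac_fail_junction: float = 0.0
    frac_fail_cpc: float = 0.0
    # fraction of true lincRNAs presented as annotation-derived (RefSeq/
    # UniGene path): no coverage or junction evidence
    frac_annotation_derived: float = 0.2
    # decoy candidates per failure class
    n_single_exon: int = 20
    n_short: int = 20
    n_near_gene: int = 20
    n_coding_potential: int = 20
    n_housekeeping_like: int = 20


@dataclass(frozen=True)
class MethylationConfig:
    cpg_spacing: int = 50
    background_alpha: float = 15.0  # beta prior of per-CpG background level
    background_beta: float = 5.0  # mean 0.75
    dip_depth_coding: float = 0.55
    dip_depth_lincrna: float = 0.35
    dip_halfwidth: int = 1500
    # flat background reduction over coding/housekeeping gene bodies, so
    # lincRNA gene-body methylation ends up higher than coding
    body_delta_coding: float = 0.15
    depth_mean: float = 30.0
    n_replicates: int = 2  # per group
    level_floor: float = 0.02
    level_ceiling: float = 0.98


@dataclass(frozen=True)
class BindingConfig:
    background_depth: float = 2.0
    peak_height: float = 8.0
    peak_halfwidth: int = 1000
    noise_sd: float = 0.4
    step: int = 50


@dataclass(frozen=True)
class DMRConfig:
    n_planted: int = 3
    effect_size: float = 0.4  # group2 level shift inside the DMR
    width: int = 400


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    genes: GeneSetConfig = field(default_factory=GeneSetConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    evidence_noise: EvidenceNoiseConfig = field(default_factory=EvidenceNoiseConfig)
    methylation: MethylationConfig = field(default_factory=MethylationConfig)
    binding: BindingConfig = field(default_factory=BindingConfig)
    dmr: DMRConfig = field(default_factory=DMRConfig)


@dataclass
class TruthTable:
    """Ground truth of one simulated bundle."""

    transcripts: pd.DataFrame  # transcript_id, true_class
    genes: pd.DataFrame  # gene_id, biotype, specific_tissue ('' if none)
    dmrs: pd.DataFrame  # chrom, start, end, dmr_id, target_gene_id
    profile_params: dict  # planted dip/peak parameters


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: list[GeneLocus]
    candidates: list[TranscriptModel]
    evidence: dict[str, TranscriptEvidence]
    housekeeping_hits: dict[str, tuple[HousekeepingHit, ...]]
    expression: ExpressionMatrix
    genome: dict[str, str]
    methylation: dict[str, list[MethylationCallSet]]  # "group1"/"group2"
    binding: pd.DataFrame  # bedGraph-shaped frame
    truth: TruthTable
    paths: dict[str, object] = field(default_factory=dict)


# --------------------------------------------------------------------------
# gene layout


@dataclass
class _GeneSpec:
    kind: str  # coding | housekeeping | lincrna | decoy_*
    gene_id: str
    transcript_id: str
    exon_lengths: list[int]
    intron_lengths: list[int]

    @property
    def span_length(self) -> int:
        return sum(self.exon_lengths) + sum(self.intron_lengths)


def _draw_structure(
    rng: np.random.Generator,
    exon_range: tuple[int, int],
    exon_bp: tuple[int, int],
    intron_log_mean: float,
    intron_log_sd: float,
) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(exon_range[0], exon_range[1] + 1))
    exon_lengths = [int(rng.integers(exon_bp[0], exon_bp[1] + 1)) for _ in range(n_exons)]
    intron_lengths = [
        max(60, int(rng.lognormal(intron_log_mean, intron_log_sd)))
        for _ in range(n_exons - 1)
    ]
    return exon_lengths, intron_lengths


def _make_gene_specs(cfg: SimulationConfig, rng: np.random.Generator) -> list[_GeneSpec]:
    g = cfg.genes
    n = cfg.evidence_noise
    specs: list[_GeneSpec] = []

    def add(kind: str, idx: int, exon_range, exon_bp, ilm, ils, prefix: str) -> None:
        exons, introns = _draw_structure(rng, exon_range, exon_bp, ilm, ils)
        gid = f"{prefix}{idx:05d}"
        specs.append(_GeneSpec(kind, gid, f"{gid}.t1", exons, introns))

    for i in range(g.n_coding):
        add("coding", i + 1, g.coding_exons, g.coding_exon_bp,
            g.coding_intron_log_mean, g.coding_intron_log_sd, "CODG")
    for i in range(g.n_housekeeping):
        add("housekeeping", i + 1, (1, 2), (80, 200), 5.0, 0.4, "HKG")
    for i in range(g.n_lincrna):
        add("lincrna", i + 1, g.lincrna_exons, g.lincrna_exon_bp,
            g.lincrna_intron_log_mean, g.lincrna_intron_log_sd, "LNCG")
    for i in range(n.n_single_exon):
        specs.append(
            _GeneSpec("decoy_single_exon", f"DSEG{i + 1:05d}", f"DSEG{i + 1:05d}.t1",
                      [int(rng.integers(400, 1200))], [])
        )
    for i in range(n.n_short):
        # two exons but total exonic length <= 200 nt
        first = int(rng.integers(40, 120))
        specs.append(
            _GeneSpec("decoy_short", f"DSHG{i + 1:05d}", f"DSHG{i + 1:05d}.t1",
                      [first, int(rng.integers(30, 200 - first))],
                      [int(rng.integers(80, 400))])
        )
    for i in range(n.n_near_gene):
        exons, introns = _draw_structure(
            rng, g.lincrna_exons, g.lincrna_exon_bp,
            g.lincrna_intron_log_mean, g.lincrna_intron_log_sd)
        specs.append(_GeneSpec("decoy_near_gene", f"DNGG{i + 1:05d}",
                               f"DNGG{i + 1:05d}.t1", exons, introns))
    for i in range(n.n_coding_potential):
        exons, introns = _draw_structure(
            rng, g.lincrna_exons, g.lincrna_exon_bp,
            g.lincrna_intron_log_mean, g.lincrna_intron_log_sd)
        specs.append(_GeneSpec("decoy_coding_potential", f"DCPG{i + 1:05d}",
                               f"DCPG{i + 1:05d}.t1", exons, introns))
    for i in range(n.n_housekeeping_like):
        exons, introns = _draw_structure(
            rng, g.lincrna_exons, g.lincrna_exon_bp,
            g.lincrna_intron_log_mean, g.lincrna_intron_log_sd)
        specs.append(_GeneSpec("decoy_housekeeping_like", f"DHKG{i + 1:05d}",
                               f"DHKG{i + 1:05d}.t1", exons, introns))
    rng.shuffle(specs)
    # near-gene decoys must sit close to a coding/housekeeping gene: move
    # each directly after one
    anchored = [s for s in specs if s.kind != "decoy_near_gene"]
    near = [s for s in specs if s.kind == "decoy_near_gene"]
    anchor_positions = [
        i for i, s in enumerate(anchored) if s.kind in ("coding", "housekeeping")
    ]
    if near and not anchor_positions:
        raise ValidationError("near-gene decoys need coding/housekeeping anchors")
    out: list[_GeneSpec] = list(anchored)
    if near:
        chosen = rng.choice(len(anchor_positions), size=len(near), replace=False)
        insert_after = sorted(
            ((anchor_positions[int(c)], s) for c, s in zip(chosen, near)),
            key=lambda x: x[0], reverse=True,
        )
        for pos, s in insert_after:
            out.insert(pos + 1, s)
    return out


def _place_genes(
    cfg: SimulationConfig, specs: list[_GeneSpec], rng: np.random.Generator
) -> pd.DataFrame:
    """Assign genomic coordinates; returns one row per gene."""
    g = cfg.genes
    chroms = [f"chr{i + 1}" for i in range(cfg.genome.n_chroms)]
    per_chrom = int(np.ceil(len(specs) / len(chroms)))
    rows = []
    idx = 0
    for chrom in chroms:
        cursor = 10_000  # leave room for upstream profile windows
        prev_kind = None
        for s in specs[idx : idx + per_chrom]:
            if s.kind == "decoy_near_gene":
                gap = int(rng.integers(50, 499))  # inside the 500 bp buffer
            else:
                gap = max(g.min_gap, int(rng.lognormal(g.gap_log_mean, g.gap_log_sd)))
                if s.kind == "lincrna" or prev_kind == "lincrna":
                    gap = int(gap * g.lincrna_gap_factor)
            start = cursor + gap
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + s.span_length
            if end > cfg.genome.chrom_length - 10_000:
                raise ValidationError(
                    f"genome overcrowded: gene {s.gene_id} does not fit on {chrom}"
                )
            rows.append(
                {
                    "gene_id": s.gene_id,
                    "transcript_id": s.transcript_id,
                    "kind": s.kind,
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "strand": strand,
                    "exon_lengths": ",".join(map(str, s.exon_lengths)),
                    "intron_lengths": ",".join(map(str, s.intron_lengths)),
                }
            )
            cursor = end
            prev_kind = s.kind
        idx += per_chrom
    return pd.DataFrame(rows)


def _build_transcript(row) -> TranscriptModel:
    exon_lengths = [int(x) for x in row.exon_lengths.split(",")]
    intron_lengths = (
        [int(x) for x in row.intron_lengths.split(",")] if row.intron_lengths else []
    )
    exons = []
    pos = row.start
    for i, el in enumerate(exon_lengths):
        exons.append(GenomicInterval(row.chrom, pos, pos + el, row.strand))
        pos += el
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return TranscriptModel(row.transcript_id, row.gene_id, tuple(exons))


# --------------------------------------------------------------------------
# evidence


def _make_evidence(
    cfg: SimulationConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> tuple[dict[str, TranscriptEvidence], dict[str, tuple[HousekeepingHit, ...]]]:
    noise = cfg.evidence_noise
    evidence: dict[str, TranscriptEvidence] = {}
    hk_hits: dict[str, tuple[HousekeepingHit, ...]] = {}
    candidates = layout[layout.kind.str.startswith(("lincrna", "decoy"))]
    for row in candidates.itertuples(index=False):
        n_introns = len(row.intron_lengths.split(",")) if row.intron_lengths else 0
        coverage = float(rng.uniform(0.85, 1.0))
        junctions = tuple(int(3 + rng.poisson(15)) for _ in range(n_introns))
        cpc = float(rng.uniform(-3.5, -1.2))
        annotation_derived = False
        if row.kind == "lincrna":
            if rng.random() < noise.frac_fail_coverage:
                coverage = float(rng.uniform(0.3, 0.79))
            if n_introns and rng.random() < noise.frac_fail_junction:
                junctions = (int(rng.integers(0, 3)),) + junctions[1:]
            if rng.random() < noise.frac_fail_cpc:
                cpc = float(rng.uniform(-0.9, 2.0))
            if rng.random() < noise.frac_annotation_derived:
                annotation_derived = True
        elif row.kind == "decoy_coding_potential":
            cpc = float(rng.uniform(0.5, 4.0))
        elif row.kind == "decoy_housekeeping_like":
            hk_hits[row.transcript_id] = (
                HousekeepingHit(
                    evalue=float(10.0 ** rng.uniform(-40, -12)),
                    percent_identity=float(rng.uniform(85, 100)),
                ),
            )
        evidence[row.transcript_id] = TranscriptEvidence(
            transcript_id=row.transcript_id,
            exon_coverage_fraction=None if annotation_derived else coverage,
            junction_read_counts=None if annotation_derived else junctions,
            coding_potential_score=cpc,
            housekeeping_hits=hk_hits.get(row.transcript_id, ()),
        )
    return evidence, hk_hits


# --------------------------------------------------------------------------
# expression


def simulate_expression_matrix(
    cfg: SimulationConfig, gene_table: pd.DataFrame, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM matrix (with per-tissue replicate columns) for coding and
    lincRNA genes, plus a truth table of planted tissue-specific genes.

    Non-specific genes draw independent lognormal FPKM per tissue; a
    planted-specific gene has one tissue's baseline multiplied by the
    dominance fold. Replicates add lognormal noise around the tissue value.
    """
    e = cfg.expression
    tissues = list(e.tissues)
    columns = [f"{t}:rep{r + 1}" for t in tissues for r in range(e.n_replicates)]
    sub = gene_table[gene_table.kind.isin(["coding", "lincrna"])]
    values = np.zeros((len(sub), len(columns)))
    truth_rows = []
    linc_weights = np.full(len(tissues), np.nan)
    if "testes" in tissues:
        t_idx = tissues.index("testes")
        rest = (1 - e.lincrna_testes_weight) / (len(tissues) - 1)
        linc_weights = np.full(len(tissues), rest)
        linc_weights[t_idx] = e.lincrna_testes_weight
    else:
        linc_weights = np.full(len(tissues), 1 / len(tissues))
    for i, row in enumerate(sub.itertuples(index=False)):
        is_linc = row.kind == "lincrna"
        log_mean = e.lincrna_log_mean if is_linc else e.coding_log_mean
        frac = e.frac_specific_lincrna if is_linc else e.frac_specific_coding
        base = rng.lognormal(log_mean, e.baseline_log_sd, size=len(tissues))
        specific_tissue = ""
        if rng.random() < frac:
            weights = linc_weights if is_linc else np.full(len(tissues), 1 / len(tissues))
            t_i = int(rng.choice(len(tissues), p=weights))
            base[t_i] *= e.dominance_fold
            specific_tissue = tissues[t_i]
        col = 0
        for t_i in range(len(tissues)):
            for _ in range(e.n_replicates):
                values[i, col] = base[t_i] * rng.lognormal(0.0, e.replicate_log_sd)
                col += 1
        truth_rows.append(
            {"gene_id": row.gene_id, "biotype": "lincRNA" if is_linc else "coding",
             "specific_tissue": specific_tissue}
        )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=list(sub.gene_id), columns=columns)
    )
    return matrix, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# genome sequence


def _simulate_genome(
    cfg: SimulationConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> dict[str, str]:
    gcfg = cfg.genome
    genome: dict[str, str] = {}
    p_gc = gcfg.gc_background
    probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
    bases = np.array(["A", "C", "G", "T"])
    for c in range(gcfg.n_chroms):
        chrom = f"chr{c + 1}"
        seq = rng.choice(bases, size=gcfg.chrom_length, p=probs)
        # CpG-island-like promoters: periodic CG dinucleotides around TSSs
        sub = layout[(layout.chrom == chrom) & layout.kind.isin(
            ["coding", "housekeeping", "lincrna"])]
        for row in sub.itertuples(index=False):
            tss = row.start if row.strand == "+" else row.end - 1
            period = (
                gcfg.promoter_cpg_period_lincrna
                if row.kind == "lincrna"
                else gcfg.promoter_cpg_period_coding
            )
            lo = max(0, tss - gcfg.promoter_halfwidth)
            hi = min(gcfg.chrom_length - 2, tss + gcfg.promoter_halfwidth)
            for p in range(lo, hi, period):
                seq[p] = "C"
                seq[p + 1] = "G"
        genome[chrom] = "".join(seq.tolist())
    return genome


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# methylation


def _plant_dmrs(
    cfg: SimulationConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Choose DMR intervals inside true-lincRNA spans."""
    d = cfg.dmr
    lincs = layout[layout.kind == "lincrna"].reset_index(drop=True)
    wide = lincs[(lincs.end - lincs.start) > d.width + 20].reset_index(drop=True)
    if len(wide) < d.n_planted:
        raise ValidationError("not enough lincRNA loci to host planted DMRs")
    chosen = sorted(rng.choice(len(wide), size=d.n_planted, replace=False).tolist())
    rows = []
    for k, i in enumerate(chosen):
        row = wide.iloc[int(i)]
        lo = int(row.start) + 10
        start = int(rng.integers(lo, int(row.end) - d.width - 10))
        rows.append(
            {
                "chrom": row.chrom,
                "start": start,
                "end": start + d.width,
                "dmr_id": f"planted_dmr{k + 1}",
                "target_gene_id": row.gene_id,
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_methylation_calls(
    cfg: SimulationConfig,
    layout: pd.DataFrame,
    planted_dmrs: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict[str, list[MethylationCallSet]], dict]:
    """Two groups of replicate call sets with TSS dips and planted DMRs.

    CpG sites sit on a jittered grid. Each site's true level is a beta-
    distributed background minus a triangular dip centred on every nearby
    TSS (deeper for coding/housekeeping than for lincRNA genes). Group 2
    shifts the level by the DMR effect size inside planted DMR intervals.
    Observed counts are binomial at Poisson-distributed read depth.
    """
    m = cfg.methylation
    chrom_len = cfg.genome.chrom_length
    chroms = [f"chr{i + 1}" for i in range(cfg.genome.n_chroms)]
    groups: dict[str, list[MethylationCallSet]] = {"group1": [], "group2": []}
    site_info: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in chroms:
        grid = np.arange(2000, chrom_len - 2000, m.cpg_spacing)
        jitter = rng.integers(0, m.cpg_spacing // 2, size=len(grid))
        pos = np.unique(grid + jitter)
        level = rng.beta(m.background_alpha, m.background_beta, size=len(pos))
        sub = layout[(layout.chrom == chrom) & layout.kind.isin(
            ["coding", "housekeeping", "lincrna"])]
        for row in sub.itertuples(index=False):
            tss = row.start if row.strand == "+" else row.end - 1
            depth_of_dip = (
                m.dip_depth_lincrna if row.kind == "lincrna" else m.dip_depth_coding
            )
            if row.kind != "lincrna":
                blo, bhi = np.searchsorted(pos, [row.start, row.end])
                level[blo:bhi] -= m.body_delta_coding
            lo, hi = np.searchsorted(pos, [tss - m.dip_halfwidth, tss + m.dip_halfwidth])
            if hi > lo:
                tri = 1 - np.abs(pos[lo:hi] - tss) / m.dip_halfwidth
                level[lo:hi] = level[lo:hi] - depth_of_dip * tri
        level = np.clip(level, m.level_floor, m.level_ceiling)
        level2 = level.copy()
        for row in planted_dmrs[planted_dmrs.chrom == chrom].itertuples(index=False):
            lo, hi = np.searchsorted(pos, [row.start, row.end])
            # shift away from the nearer boundary so clipping cannot eat
            # the planted effect
            direction = -1.0 if level2[lo:hi].mean() > 0.5 else 1.0
            level2[lo:hi] = np.clip(
                level2[lo:hi] + direction * cfg.dmr.effect_size,
                m.level_floor,
                m.level_ceiling,
            )
        site_info[chrom] = (pos, level, level2)
    for group, levels_key in (("group1", 1), ("group2", 2)):
        for _rep in range(m.n_replicates):
            frames = []
            for chrom in chroms:
                pos, level1, level2 = site_info[chrom]
                level = level1 if levels_key == 1 else level2
                depth = rng.poisson(m.depth_mean, size=len(pos)) + 1
                mcount = rng.binomial(depth, level)
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": pos,
                            "strand": "+",
                            "m": mcount,
                            "u": depth - mcount,
                        }
                    )
                )
            groups[group].append(MethylationCallSet(pd.concat(frames, ignore_index=True)))
    truth = {
        "dip_depth_coding": m.dip_depth_coding,
        "dip_depth_lincrna": m.dip_depth_lincrna,
        "dip_halfwidth": m.dip_halfwidth,
        "background_mean": m.background_alpha / (m.background_alpha + m.background_beta),
    }
    return groups, truth


# --------------------------------------------------------------------------
# binding


def _simulate_binding(
    cfg: SimulationConfig, layout: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Step-wise constant coverage: background + triangular TSS peaks."""
    b = cfg.binding
    chrom_len = cfg.genome.chrom_length
    frames = []
    for c in range(cfg.genome.n_chroms):
        chrom = f"chr{c + 1}"
        starts = np.arange(0, chrom_len, b.step)
        centres = starts + b.step / 2
        depth = np.full(len(starts), b.background_depth)
        sub = layout[(layout.chrom == chrom) & layout.kind.isin(
            ["coding", "housekeeping", "lincrna"])]
        for row in sub.itertuples(index=False):
            tss = row.start if row.strand == "+" else row.end - 1
            lo, hi = np.searchsorted(centres, [tss - b.peak_halfwidth, tss + b.peak_halfwidth])
            if hi > lo:
                tri = 1 - np.abs(centres[lo:hi] - tss) / b.peak_halfwidth
                depth[lo:hi] += b.peak_height * tri
        depth = np.maximum(0.0, depth + rng.normal(0, b.noise_sd, size=len(starts)))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + b.step, chrom_len),
                    "depth": np.round(depth, 2),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# orchestration


def simulate_dataset(cfg: SimulationConfig, outdir=None) -> SimulatedDataset:
    """Generate the full bundle; write files when ``outdir`` is given.

    Everything is drawn from one generator seeded with ``cfg.seed``, so a
    given configuration always produces byte-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    specs = _make_gene_specs(cfg, rng)
    layout = _place_genes(cfg, specs, rng)

    annotation = []
    for row in layout[layout.kind.isin(["coding", "housekeeping"])].itertuples(index=False):
        t = _build_transcript(row)
        annotation.append(
            GeneLocus(
                gene_id=row.gene_id,
                transcripts=(t,),
                biotype="coding" if row.kind == "coding" else "housekeeping",
            )
        )
    candidates = [
        _build_transcript(row)
        for row in layout[
            layout.kind.str.startswith(("lincrna", "decoy"))
        ].itertuples(index=False)
    ]
    evidence, hk_hits = _make_evidence(cfg, layout, rng)
    expression, gene_truth = simulate_expression_matrix(cfg, layout, rng)
    genome = _simulate_genome(cfg, layout, rng)
    planted_dmrs = _plant_dmrs(cfg, layout, rng)
    methylation, profile_truth = simulate_methylation_calls(cfg, layout, planted_dmrs, rng)
    binding = _simulate_binding(cfg, layout, rng)
    profile_truth.update(
        {
            "binding_background": cfg.binding.background_depth,
            "binding_peak_height": cfg.binding.peak_height,
            "binding_peak_halfwidth": cfg.binding.peak_halfwidth,
        }
    )
    transcript_truth = layout[["transcript_id", "kind"]].rename(columns={"kind": "true_class"})
    transcript_truth = transcript_truth.assign(
        true_class=transcript_truth.true_class.replace({"lincrna": "lincRNA"})
    ).sort_values("transcript_id", kind="mergesort").reset_index(drop=True)
    truth = TruthTable(
        transcripts=transcript_truth,
        genes=gene_truth,
        dmrs=planted_dmrs,
        profile_params=profile_truth,
    )
    ds = SimulatedDataset(
        config=cfg,
        annotation=annotation,
        candidates=candidates,
        evidence=evidence,
        housekeeping_hits=hk_hits,
        expression=expression,
        genome=genome,
        methylation=methylation,
        binding=binding,
        truth=truth,
    )
    if outdir is not None:
        ds.paths = write_bundle(ds, Path(outdir))
    return ds


def write_bundle(ds: SimulatedDataset, outdir: Path) -> dict[str, object]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    paths["annotation_gtf"] = outdir / "annotation.gtf"
    lio.write_gtf(ds.annotation, paths["annotation_gtf"])
    paths["candidates_gtf"] = outdir / "candidates.gtf"
    candidate_loci = [
        GeneLocus(gene_id=t.gene_id, transcripts=(t,), biotype="other")
        for t in ds.candidates
    ]
    lio.write_gtf(candidate_loci, paths["candidates_gtf"])
    paths["evidence_tsv"] = outdir / "evidence.tsv"
    lio.write_evidence_table(ds.evidence.values(), paths["evidence_tsv"])
    paths["housekeeping_hits_tsv"] = outdir / "housekeeping_hits.tsv"
    lio.write_housekeeping_hits(ds.housekeeping_hits, paths["housekeeping_hits_tsv"])
    paths["expression_tsv"] = outdir / "expression.tsv"
    lio.write_expression_matrix(ds.expression, paths["expression_tsv"])
    paths["genome_fasta"] = outdir / "genome.fa"
    write_fasta(ds.genome, paths["genome_fasta"])
    meth_paths: dict[str, list[Path]] = {}
    for group, call_sets in ds.methylation.items():
        meth_paths[group] = []
        for i, cs in enumerate(call_sets):
            p = outdir / f"methylation_{group}_rep{i + 1}.tsv"
            lio.write_methylation_calls(cs, p)
            meth_paths[group].append(p)
    paths["methylation"] = meth_paths
    paths["binding_bedgraph"] = outdir / "binding.bedgraph"
    ds.binding.to_csv(paths["binding_bedgraph"], sep="\t", header=False, index=False)
    paths["truth_transcripts"] = outdir / "truth_transcripts.tsv"
    ds.truth.transcripts.to_csv(paths["truth_transcripts"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    ds.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    paths["truth_dmrs"] = outdir / "truth_dmrs.bed"
    ds.truth.dmrs.to_csv(paths["truth_dmrs"], sep="\t", index=False, header=False)
    paths["truth_profile_params"] = outdir / "truth_profile_params.json"
    with open(paths["truth_profile_params"], "w") as fh:
        json.dump(ds.truth.profile_params, fh, indent=1, sort_keys=True)
    return paths
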