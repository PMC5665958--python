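import numpy as np
import pandas as pd
import pytest

from linctools.model import GenomicInterval, TranscriptModel
from linctools.simulate import SimulationConfig, simulate_dataset


def make_transcript(
    tid: str,
    exons,
    chrom: str = "chr1",
    strand: str = "+",
    gene_id: str | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"{tid}.g",
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Default desk-scale bundle, generated once per session (in memory)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """Default bundle written to disk, for reader round-trips and the CLI."""
    outdir = tmp_path_factory.mktemp("bundle")
    ds = simulate_dataset(SimulationConfig(seed=1), outdir)
    return outdir, ds


def random_transcripts(rng: np.random.Generator, n: int, chrom_len: int = 50_000):
    """Small random stranded transcripts for oracle comparisons."""
    out = []
    for i in range(n):
        n_exons = int(rng.integers(1, 4))
        pos = int(rng.integers(0, chrom_len - 5000))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(50, 400))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(50, 800))
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = "chr1" if rng.random() < 0.7 else "chr2"
        out.append(make_transcript(f"t{i}", exons, chrom=chrom, strand=strand))
    return out
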