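import numpy as np
import pytest

from chromadapt import GeneModel, GenomeSpec, WindowTrack


@pytest.fixture
def small_genome():
    return GenomeSpec(("chr1", "chr2"), (100_000, 60_000))


@pytest.fixture
def one_chrom():
    return GenomeSpec(("chr1",), (100_000,))


def track_from(genome: GenomeSpec, window: int = 50, fill: float = 0.0,
               value_kind: str = "count") -> WindowTrack:
    t = WindowTrack.zeros(genome, window, value_kind=value_kind)
    if fill:
        for c in t.data:
            t.data[c][:] = fill
    return t


def plus_gene(gene_id="g+", chrom="chr1", start=20_000, end=26_000):
    return GeneModel(gene_id, chrom, "+", start, end)


def minus_gene(gene_id="g-", chrom="chr1", start=40_000, end=46_000):
    return GeneModel(gene_id, chrom, "-", start, end)


def reflect_gene(gene: GeneModel, length: int) -> GeneModel:
    """Mirror a gene through the chromosome midpoint, flipping strand."""
    return GeneModel(
        gene.gene_id,
        gene.chrom,
        "-" if gene.strand == "+" else "+",
        length - gene.end,
        length - gene.start,
    )


def reflect_track(track: WindowTrack) -> WindowTrack:
    return WindowTrack(
        track.window_size,
        {c: v[::-1].copy() for c, v in track.data.items()},
        track.value_kind,
    )
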