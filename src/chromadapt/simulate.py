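"""Synthetic genomes, ChIP read sets, expression counts and polysome traces.

Every generator takes an explicit seed and is bit-reproducible.  The ChIP
simulator draws read positions from a piecewise-constant intensity: a uniform
background multiplied, inside gene bodies and promoter-proximal intervals, by
per-gene enrichment factors.  This emulates a gene-body-enriched histone mark
(H4K20me1-like) and a promoter-proximal factor (MYC-like) without modelling
fragmentation, GC bias or mappability.  The noise model is Poisson
throughout, matching the significance model used by the peak caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomeSpec, ReadSet

__all__ = [
    "ChipSimParams",
    "ExprSimParams",
    "PolysomeTrace",
    "make_genes",
    "simulate_chip",
    "simulate_expression",
    "simulate_polysome_trace",
]


def _per_gene(value, genes: Sequence[GeneModel]) -> dict[str, float]:
    """Broadcast a scalar enrichment factor, or validate a per-gene mapping."""
    if isinstance(value, Mapping):
        out = {g.gene_id: float(value.get(g.gene_id, 1.0)) for g in genes}
    else:
        out = {g.gene_id: float(value) for g in genes}
    if any(v < 0 for v in out.values()):
        raise ValueError("enrichment factors must be >= 0")
    return out


@dataclass
class ChipSimParams:
    """Intensity model for one ChIP sample.

    ``body_enrichment`` and ``promoter_enrichment`` are multiplicative
    factors over the uniform background, either a scalar applied to every
    gene or a mapping gene_id -> factor (genes absent from the mapping get
    1.0).  An input/whole-chromatin control is simulated by setting every
    factor to 1.
    """

    background_rate: float = 1.0
    body_enrichment: float | Mapping[str, float] = 1.0
    promoter_enrichment: float | Mapping[str, float] = 1.0
    promoter_halfwidth: int = 1000
    n_reads: int = 100_000
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.promoter_halfwidth < 0:
            raise ValueError("promoter_halfwidth must be >= 0")

    def as_input(self) -> "ChipSimParams":
        """The matched control: identical except all enrichment factors 1."""
        return ChipSimParams(
            background_rate=self.background_rate,
            body_enrichment=1.0,
            promoter_enrichment=1.0,
            promoter_halfwidth=self.promoter_halfwidth,
            n_reads=self.n_reads,
            read_length=self.read_length,
            seed=self.seed + 1,
        )


@dataclass
class ExprSimParams:
    """Two-condition expression counts with constant-abundance spike-ins."""

    n_genes: int = 200
    n_spikeins: int = 10
    base_mean: float = 100.0
    fold_changes: Sequence[float] | float = 1.0
    library_scale: Sequence[float] = (1.0, 1.0)
    exon_length: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_spikeins < 0:
            raise ValueError("counts must be >= 0")
        if self.base_mean < 0:
            raise ValueError("base_mean must be >= 0")
        fc = np.broadcast_to(
            np.asarray(self.fold_changes, dtype=float), (self.n_genes,)
        ).copy()
        if (fc <= 0).any():
            raise ValueError("fold_changes must be > 0")
        object.__setattr__(self, "fold_changes", fc)
        ls = np.asarray(self.library_scale, dtype=float)
        if ls.shape != (2,) or (ls <= 0).any():
            raise ValueError("library_scale must be two positive factors")


def make_genes(
    genome: GenomeSpec,
    n_genes: int,
    min_len: int = 2000,
    max_len: int = 10000,
    seed: int = 0,
) -> list[GeneModel]:
    """Place ``n_genes`` non-overlapping single-exon genes on the genome.

    Genes are assigned to chromosomes with probability proportional to
    chromosome length, given uniform lengths in [min_len, max_len], and laid
    out by distributing the leftover space as random inter-gene gaps, which
    guarantees non-overlap by construction.  Strands are assigned uniformly.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if not (0 < min_len <= max_len):
        raise ValueError("need 0 < min_len <= max_len")
    rng = np.random.default_rng(seed)
    sizes = genome.sizes
    probs = np.array(list(sizes.values()), dtype=float)
    probs /= probs.sum()
    assignment = rng.choice(len(sizes), size=n_genes, p=probs)

    genes: list[GeneModel] = []
    idx = 0
    for ci, (chrom, length) in enumerate(sizes.items()):
        n_here = int((assignment == ci).sum())
        if n_here == 0:
            continue
        lens = rng.integers(min_len, max_len + 1, size=n_here)
        free = length - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"cannot place {n_here} genes totalling {lens.sum()} bp on "
                f"{chrom} ({length} bp)"
            )
        cuts = np.sort(rng.integers(0, free + 1, size=n_here))
        starts = cuts + np.concatenate(([0], np.cumsum(lens[:-1])))
        strands = rng.choice(["+", "-"], size=n_here)
        for s, l, st in zip(starts, lens, strands):
            genes.append(
                GeneModel(
                    gene_id=f"gene_{idx:04d}",
                    chrom=chrom,
                    strand=str(st),
                    start=int(s),
                    end=int(s + l),
                )
            )
            idx += 1
    return genes


def _segment_weights(
    chrom_len: int,
    genes: Sequence[GeneModel],
    body: dict[str, float],
    promoter: dict[str, float],
    halfwidth: int,
):
    """Breakpoints and per-segment relative intensity for one chromosome.

    The intensity is the product of the factors of all gene-body and
    promoter intervals covering a position (1 outside any interval).
    """
    intervals: list[tuple[int, int, float]] = []
    for g in genes:
        if body[g.gene_id] != 1.0:
            intervals.append((g.start, g.end, body[g.gene_id]))
        if promoter[g.gene_id] != 1.0:
            lo = max(0, g.tss - halfwidth)
            hi = min(chrom_len, g.tss + halfwidth)
            if lo < hi:
                intervals.append((lo, hi, promoter[g.gene_id]))
    bounds = {0, chrom_len}
    for lo, hi, _ in intervals:
        bounds.add(lo)
        bounds.add(hi)
    edges = np.array(sorted(bounds), dtype=np.int64)
    logf = np.zeros(len(edges) - 1)
    for lo, hi, f in intervals:
        i = np.searchsorted(edges, lo)
        j = np.searchsorted(edges, hi)
        logf[i:j] += np.log(f) if f > 0 else -np.inf
    seg_len = np.diff(edges)
    weights = np.exp(logf) * seg_len
    return edges, weights


def simulate_chip(
    genome: GenomeSpec, genes: Sequence[GeneModel], params: ChipSimParams
) -> ReadSet:
    """Draw ``params.n_reads`` fixed-length reads from the enrichment model."""
    for g in genes:
        if g.chrom not in genome.sizes:
            raise ValueError(f"{g.gene_id}: chromosome {g.chrom} not in genome")
        if g.end > genome.sizes[g.chrom]:
            raise ValueError(f"{g.gene_id} extends beyond {g.chrom}")
    rng = np.random.default_rng(params.seed)
    body = _per_gene(params.body_enrichment, genes)
    promoter = _per_gene(params.promoter_enrichment, genes)

    chrom_edges = {}
    chrom_weights = {}
    for chrom, length in genome.sizes.items():
        here = [g for g in genes if g.chrom == chrom]
        edges, weights = _segment_weights(
            length, here, body, promoter, params.promoter_halfwidth
        )
        chrom_edges[chrom] = edges
        chrom_weights[chrom] = weights * params.background_rate

    names = list(genome.sizes)
    all_w = np.concatenate([chrom_weights[c] for c in names])
    if all_w.sum() <= 0:
        raise ValueError("total intensity is zero; cannot place reads")
    seg_chrom = np.concatenate(
        [np.full(len(chrom_weights[c]), i) for i, c in enumerate(names)]
    )
    counts = rng.multinomial(params.n_reads, all_w / all_w.sum())

    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    offset = 0
    for i, c in enumerate(names):
        n_seg = len(chrom_weights[c])
        cnt = counts[offset : offset + n_seg]
        offset += n_seg
        n_here = int(cnt.sum())
        if n_here == 0:
            continue
        edges = chrom_edges[c]
        lo = np.repeat(edges[:-1], cnt)
        hi = np.repeat(edges[1:], cnt)
        pos = rng.integers(lo, hi)
        max_start = genome.sizes[c] - params.read_length
        pos = np.clip(pos, 0, max(max_start, 0))
        chroms.append(np.full(n_here, c, dtype=object))
        starts.append(pos)
    if starts:
        start = np.concatenate(starts)
        chrom = np.concatenate(chroms)
    else:
        start = np.array([], dtype=np.int64)
        chrom = np.array([], dtype=object)
    order = rng.permutation(len(start))
    start = start[order]
    chrom = chrom[order]
    strand = rng.choice(["+", "-"], size=len(start))
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": start.astype(np.int64),
            "end": (start + params.read_length).astype(np.int64),
            "strand": strand.astype(object),
        }
    )
    return ReadSet(df, sample_id="chip_sim")


def simulate_expression(params: ExprSimParams) -> pd.DataFrame:
    """Poisson counts for genes plus constant-abundance spike-ins.

    Returns a table indexed by feature id with columns cond1, cond2,
    exon_length and is_spikein.  Gene means in condition 2 are multiplied by
    the per-gene fold change; spike-in true abundance is identical in both
    conditions.  Both conditions are then scaled by the per-sample library
    factor before Poisson sampling, emulating a global capture/depth shift
    that spike-in normalisation must undo.
    """
    rng = np.random.default_rng(params.seed)
    fc = np.asarray(params.fold_changes, dtype=float)
    lib = np.asarray(params.library_scale, dtype=float)
    gene_mu = np.column_stack(
        [
            np.full(params.n_genes, params.base_mean) * lib[0],
            np.full(params.n_genes, params.base_mean) * fc * lib[1],
        ]
    )
    spike_mu = np.full((params.n_spikeins, 2), params.base_mean) * lib
    mu = np.vstack([gene_mu, spike_mu])
    counts = rng.poisson(mu)
    ids = [f"gene_{i:04d}" for i in range(params.n_genes)] + [
        f"spike_{i:02d}" for i in range(params.n_spikeins)
    ]
    table = pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"),
                         columns=["cond1", "cond2"])
    table["exon_length"] = params.exon_length
    table["is_spikein"] = [False] * params.n_genes + [True] * params.n_spikeins
    return table


@dataclass
class PolysomeTrace:
    """An absorbance (A254-like) trace with designated AUC regions."""

    absorbance: np.ndarray
    dx: float
    mono_region: tuple[int, int]
    poly_region: tuple[int, int]
    true_mono_area: float = field(default=float("nan"))
    true_poly_area: float = field(default=float("nan"))


def _gaussian(x: np.ndarray, center: float, sigma: float, area: float) -> np.ndarray:
    return area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((x - center) / sigma) ** 2
    )


def simulate_polysome_trace(
    mono_area: float,
    poly_area: float,
    n_points: int = 2000,
    seed: int = 0,
    noise_sd: float = 1e-3,
) -> PolysomeTrace:
    """Smooth absorbance trace whose region integrals hit the requested areas.

    The monosome (80S) peak is one Gaussian inside the monosome region; the
    polysome signal is a train of three Gaussians inside the polysome region,
    mimicking discrete polysome peaks.  Peaks sit well inside their regions
    so that the trapezoidal integral over each region reproduces the
    requested area to well within 1% (for the default grid).
    """
    if mono_area < 0 or poly_area < 0:
        raise ValueError("areas must be >= 0")
    if n_points < 10:
        raise ValueError("n_points too small for a meaningful trace")
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 1.0, n_points)
    dx = x[1] - x[0]
    y = _gaussian(x, 0.30, 0.015, mono_area)
    for center, frac in ((0.60, 0.5), (0.70, 0.3), (0.80, 0.2)):
        y += _gaussian(x, center, 0.018, poly_area * frac)
    scale = max(mono_area, poly_area, 1e-12)
    y += rng.normal(0.0, noise_sd * scale, size=n_points)
    mono_region = (int(0.20 * n_points), int(0.42 * n_points))
    poly_region = (int(0.50 * n_points), int(0.92 * n_points))
    return PolysomeTrace(
        absorbance=y,
        dx=float(dx),
        mono_region=mono_region,
        poly_region=poly_region,
        true_mono_area=float(mono_area),
        true_poly_area=float(poly_area),
    )
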