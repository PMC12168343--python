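"""Gene-anchored signal summaries: TSS profiles, scaled metagenes, heat-map
matrices, condition-difference tracks, peak-to-gene association and polysome
AUC ratios.

All profile operations work in transcription orientation: minus-strand genes
are mirrored, so position +x always means x bp downstream of the TSS along
the direction of transcription.  Positions falling off the chromosome
contribute 0 and stay in the averaging denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GeneModel, Peak, WindowTrack

__all__ = [
    "ProfileParams",
    "SignalMatrix",
    "associate_genes",
    "tss_profile",
    "tss_matrix",
    "metagene",
    "heatmap_matrix",
    "differential_track",
    "gene_body_signal",
    "polysome_ratio",
]


@dataclass
class ProfileParams:
    """Geometry of gene-anchored profiles (all units bp)."""

    tss_upstream: int = 1000
    tss_downstream: int = 5000
    body_scaled_length: int = 3000
    flank: int = 1000
    bin: int = 50

    def __post_init__(self) -> None:
        if self.bin < 1:
            raise ValueError("bin must be >= 1")
        for name in ("tss_upstream", "tss_downstream", "body_scaled_length", "flank"):
            if getattr(self, name) % self.bin:
                raise ValueError(f"{name} must be a multiple of bin")


@dataclass
class SignalMatrix:
    """One row of binned signal per gene, plus the bin coordinates.

    ``positions`` are bin centres: distance to the TSS for TSS-anchored
    matrices, or position along the [-flank, scaled body, +flank] axis for
    metagene matrices.
    """

    gene_ids: list[str]
    positions: np.ndarray
    matrix: np.ndarray

    def column_mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


def _orientation_interval(gene: GeneModel, upstream: int, downstream: int):
    """Genomic interval covering [-upstream, +downstream) around the TSS in
    transcription orientation."""
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream, gene.tss + upstream


def associate_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: ProfileParams | None = None,
) -> set[str]:
    """Gene ids with >= 1 peak overlapping the TSS-proximal interval.

    The interval is [-tss_upstream, +tss_downstream) around the TSS in
    transcription orientation (mirrored for minus-strand genes); overlap is
    a nonempty intersection.
    """
    params = params or ProfileParams()
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    hits: set[str] = set()
    for g in genes:
        lo, hi = _orientation_interval(g, params.tss_upstream, params.tss_downstream)
        for p in by_chrom.get(g.chrom, ()):
            if p.start < hi and lo < p.end:
                hits.add(g.gene_id)
                break
    return hits


def _sample_track(track: WindowTrack, chrom: str, positions: np.ndarray) -> np.ndarray:
    """Window value at each genomic position; off-chromosome positions -> 0."""
    values = track.data.get(chrom)
    if values is None:
        return np.zeros(len(positions))
    idx = positions // track.window_size
    ok = (positions >= 0) & (idx < len(values))
    out = np.zeros(len(positions))
    out[ok] = values[idx[ok]]
    return out


def _gene_tss_row(
    track: WindowTrack, gene: GeneModel, upstream: int, downstream: int, bin: int
) -> np.ndarray:
    """Binned signal from -upstream to +downstream of the TSS, 5'->3'.

    Each bin averages the track at window resolution across the bin, so a
    constant track yields the constant in every bin.
    """
    w = track.window_size
    per_bin = max(bin // w, 1)
    n_bins = (upstream + downstream) // bin
    # offsets along transcription direction, sampled at window resolution
    offs = -upstream + (np.arange(n_bins * per_bin) + 0.5) * (bin / per_bin)
    if gene.strand == "+":
        pos = gene.tss + offs
    else:
        pos = gene.tss - offs - 1
    vals = _sample_track(track, gene.chrom, pos.astype(np.int64))
    return vals.reshape(n_bins, per_bin).mean(axis=1)


def tss_matrix(
    track: WindowTrack, genes: Sequence[GeneModel], params: ProfileParams | None = None
) -> SignalMatrix:
    """Per-gene TSS-anchored rows over [-tss_upstream, +tss_downstream)."""
    params = params or ProfileParams()
    if not genes:
        raise ValueError("gene list is empty")
    if params.bin % track.window_size:
        raise ValueError("bin must be a multiple of the track window size")
    n_bins = (params.tss_upstream + params.tss_downstream) // params.bin
    positions = -params.tss_upstream + (np.arange(n_bins) + 0.5) * params.bin
    matrix = np.vstack(
        [
            _gene_tss_row(track, g, params.tss_upstream, params.tss_downstream,
                          params.bin)
            for g in genes
        ]
    )
    return SignalMatrix([g.gene_id for g in genes], positions, matrix)


def tss_profile(
    track: WindowTrack, genes: Sequence[GeneModel], params: ProfileParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Average TSS-anchored profile across genes.

    Returns (positions, profile) with positions as signed distance (bp) of
    each bin centre to the TSS.
    """
    m = tss_matrix(track, genes, params)
    return m.positions, m.column_mean()


def metagene(
    track: WindowTrack,
    genes: Sequence[GeneModel],
    params: ProfileParams | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Average profile over [-flank, TSS .. scaled body .. TTS, +flank].

    Gene bodies are linearly interpolated onto ``body_scaled_length/bin``
    bins regardless of true length; flanks are copied unscaled.  Genes
    shorter than one track window are skipped; their count is returned as
    the third element.

    Returns (positions, profile, n_skipped) where positions are bp on the
    [-flank, body_scaled_length + flank) axis with the TSS at 0.
    """
    params = params or ProfileParams()
    if not genes:
        raise ValueError("gene list is empty")
    w = track.window_size
    if params.bin % w:
        raise ValueError("bin must be a multiple of the track window size")
    n_body = params.body_scaled_length // params.bin
    n_flank = params.flank // params.bin
    target_frac = (np.arange(n_body) + 0.5) / n_body

    rows = []
    skipped = 0
    for g in genes:
        if g.length < w:
            skipped += 1
            continue
        # unscaled flanks, oriented 5'->3'
        up = _gene_tss_row(track, g, params.flank, 0, params.bin)
        if g.strand == "+":
            down_pos = g.tts + (np.arange(n_flank * (params.bin // w)) + 0.5) * w
        else:
            down_pos = g.tts - (np.arange(n_flank * (params.bin // w)) + 0.5) * w - 1
        down = (
            _sample_track(track, g.chrom, down_pos.astype(np.int64))
            .reshape(n_flank, params.bin // w)
            .mean(axis=1)
            if n_flank
            else np.zeros(0)
        )
        # body sampled at window resolution then rescaled to fixed length
        m_src = max(g.length // w, 1)
        src_frac = (np.arange(m_src) + 0.5) / m_src
        src_pos = g.start + (src_frac * g.length).astype(np.int64)
        body_vals = _sample_track(track, g.chrom, src_pos)
        if g.strand == "-":
            body_vals = body_vals[::-1]
        body = np.interp(target_frac, src_frac, body_vals)
        rows.append(np.concatenate([up, body, down]))
    if not rows:
        raise ValueError("no gene is at least one window long")
    profile = np.vstack(rows).mean(axis=0)
    positions = -params.flank + (np.arange(len(profile)) + 0.5) * params.bin
    return positions, profile, skipped


def heatmap_matrix(
    track: WindowTrack,
    genes: Sequence[GeneModel],
    params: ProfileParams | None = None,
    order: Sequence[str] | None = None,
) -> SignalMatrix:
    """TSS-anchored matrix with rows sorted by descending mean signal.

    Pass ``order`` (gene ids from a reference condition's matrix) to reuse a
    reference row order so heat-map panels align across conditions.
    """
    m = tss_matrix(track, genes, params)
    if order is None:
        means = m.matrix.mean(axis=1)
        idx = np.argsort(-means, kind="stable")
    else:
        lookup = {gid: i for i, gid in enumerate(m.gene_ids)}
        missing = [gid for gid in order if gid not in lookup]
        if missing:
            raise ValueError(f"order references unknown genes: {missing[:3]}...")
        idx = np.array([lookup[gid] for gid in order])
    return SignalMatrix(
        [m.gene_ids[i] for i in idx], m.positions, m.matrix[idx]
    )


def gene_body_signal(
    track: WindowTrack, genes: Sequence[GeneModel]
) -> dict[str, float]:
    """Summed window signal over each gene body (windows touching the body)."""
    w = track.window_size
    out = {}
    for g in genes:
        v = track.data.get(g.chrom)
        if v is None:
            out[g.gene_id] = 0.0
            continue
        i, j = g.start // w, -(-g.end // w)
        out[g.gene_id] = float(v[i:j].sum())
    return out


def differential_track(a: WindowTrack, b: WindowTrack) -> WindowTrack:
    """Per-window difference a - b after reads-per-million normalisation.

    With depths already equalized upstream the normalisation is nearly a
    no-op, but it makes the operation safe on unequal-depth inputs.
    """
    if not a.same_grid(b):
        raise ValueError("tracks are on different window grids")
    a_n, b_n = a.rpm(), b.rpm()
    return WindowTrack(
        a.window_size,
        {c: a_n.data[c] - b_n.data[c] for c in a.data},
        "difference",
    )


def polysome_ratio(
    absorbance: np.ndarray,
    mono_region: tuple[int, int],
    poly_region: tuple[int, int],
    dx: float = 1.0,
    baseline: float = 0.0,
) -> float:
    """Polysome-to-monosome ratio from trapezoidal AUC of two trace regions.

    Regions are half-open index intervals into the trace and must be
    disjoint and in bounds.  ``baseline`` is subtracted pointwise before
    integration.
    """
    y = np.asarray(absorbance, dtype=float) - baseline
    for name, (s, e) in (("mono_region", mono_region), ("poly_region", poly_region)):
        if not (0 <= s < e <= len(y)):
            raise ValueError(f"{name} {s, e} out of bounds for trace of {len(y)}")
    ms, me = mono_region
    ps, pe = poly_region
    if ms < pe and ps < me:
        raise ValueError("monosome and polysome regions overlap")
    mono_auc = float(np.trapezoid(y[ms:me], dx=dx))
    poly_auc = float(np.trapezoid(y[ps:pe], dx=dx))
    if mono_auc <= 0:
        raise ValueError("monosome area is zero or negative; cannot form ratio")
    return poly_auc / mono_auc
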