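"""Windowed Poisson enrichment calling for IP vs matched input.

The procedure: remove duplicate reads, randomly subsample IP and input to
equal depth, tile the genome into fixed 50-bp windows, count read midpoints
per window, and test each IP window count against a Poisson expectation
derived from the matched input.  A window is a *candidate* when its Poisson
upper-tail p-value is below alpha; it is *significant* when the same cutoff
is also met in neighbouring windows.  Maximal runs of candidate windows
containing a significant window are merged into peaks.

The Poisson rate for a window is max(matched input count, genome-wide mean
input count per window): a local background with a global floor that
prevents zero-rate artifacts where the input is sparse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .core import GenomeSpec, Peak, ReadSet, WindowTrack

__all__ = [
    "PeakCallParams",
    "SignificanceTracks",
    "deduplicate",
    "equalize_depth",
    "tile_counts",
    "poisson_sf",
    "window_significance",
    "merge_peaks",
    "call_peaks",
]

NEIGHBOR_RULES = ("both", "any_adjacent")


@dataclass
class PeakCallParams:
    """Tuning knobs of the window caller.

    neighbor_rule 'both' requires both immediate flanking windows to pass the
    cutoff; 'any_adjacent' requires at least one flanking window.
    """

    window_size: int = 50
    alpha: float = 1e-3
    neighbor_rule: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.neighbor_rule not in NEIGHBOR_RULES:
            raise ValueError(f"neighbor_rule must be one of {NEIGHBOR_RULES}")


def deduplicate(reads: ReadSet) -> ReadSet:
    """Keep at most one read per (chrom, start, strand).

    With fixed-length single-end reads the end coordinate is redundant, so
    duplicates are identified by start position and strand alone; reads at
    the same position on opposite strands are both retained.
    """
    df = reads.records.drop_duplicates(subset=["chrom", "start", "strand"])
    return ReadSet(df.reset_index(drop=True), sample_id=reads.sample_id)


def equalize_depth(
    ip: ReadSet, input_: ReadSet, seed: int = 0
) -> tuple[ReadSet, ReadSet]:
    """Randomly subsample the deeper of IP/input so both have equal depth.

    Subsampling is without replacement; the smaller set is returned
    unchanged.  Output order follows the original record order.
    """
    if len(ip) == 0 or len(input_) == 0:
        raise ValueError("cannot equalize depth with an empty read set")
    n = min(len(ip), len(input_))
    rng = np.random.default_rng(seed)

    def _sub(rs: ReadSet) -> ReadSet:
        if len(rs) == n:
            return rs
        keep = np.sort(rng.choice(len(rs), size=n, replace=False))
        return ReadSet(rs.records.iloc[keep].reset_index(drop=True), rs.sample_id)

    return _sub(ip), _sub(input_)


def tile_counts(
    reads: ReadSet, genome: GenomeSpec, window_size: int = 50
) -> WindowTrack:
    """Count read midpoints per fixed-width window.

    Each read contributes to exactly one window, the one containing
    floor((start + end) / 2), so window counts sum to the read count.
    """
    reads.validate(genome)
    track = WindowTrack.zeros(genome, window_size)
    df = reads.records
    if len(df):
        mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
        widx = mid // window_size
        for chrom, n in genome.n_windows(window_size).items():
            sel = df["chrom"].to_numpy() == chrom
            if sel.any():
                track.data[chrom] = np.bincount(
                    widx[sel], minlength=n
                ).astype(float)
    return track


def poisson_sf(k, lam):
    """Upper-tail Poisson probability P(X >= k) for X ~ Poisson(lam).

    Vectorised over k and lam; k = 0 returns 1 exactly.
    """
    k = np.asarray(k)
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("lam must be > 0")
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    return stats.poisson.sf(k - 1, lam)


@dataclass
class SignificanceTracks:
    """Per-window p-values plus candidate/significant flags."""

    p: dict[str, np.ndarray]
    candidate: dict[str, np.ndarray]
    significant: dict[str, np.ndarray]
    params: PeakCallParams
    lam_floor: float = field(default=float("nan"))


def window_significance(
    ip_track: WindowTrack,
    input_track: WindowTrack,
    params: PeakCallParams | None = None,
) -> SignificanceTracks:
    """Poisson-test every window of the IP track against the input background.

    Chromosome-edge windows lack a neighbour and can never be significant.
    """
    params = params or PeakCallParams()
    if not ip_track.same_grid(input_track):
        raise ValueError("IP and input tracks are on different window grids")
    n_windows = sum(len(v) for v in input_track.data.values())
    mean_input = input_track.total() / n_windows
    if mean_input <= 0:
        raise ValueError("input track is empty; cannot form a background")

    p: dict[str, np.ndarray] = {}
    cand: dict[str, np.ndarray] = {}
    sig: dict[str, np.ndarray] = {}
    for chrom, ip in ip_track.data.items():
        lam = np.maximum(input_track.data[chrom], mean_input)
        pv = poisson_sf(ip.astype(np.int64), lam)
        c = pv < params.alpha
        s = np.zeros_like(c)
        if len(c) >= 3:
            if params.neighbor_rule == "both":
                s[1:-1] = c[1:-1] & c[:-2] & c[2:]
            else:  # any_adjacent
                s[1:-1] = c[1:-1] & (c[:-2] | c[2:])
        p[chrom] = pv
        cand[chrom] = c
        sig[chrom] = s
    return SignificanceTracks(p, cand, sig, params, lam_floor=mean_input)


def _runs(mask: np.ndarray):
    """Start/end indices of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts, ends))


def merge_peaks(
    tracks: SignificanceTracks,
    ip_track: WindowTrack | None = None,
    input_track: WindowTrack | None = None,
) -> list[Peak]:
    """Merge candidate runs holding at least one significant window into peaks.

    A peak spans a maximal run of >= 3 consecutive candidate windows that
    contains a significant window (under the 'both' rule any significant
    window implies such a run).  Peaks are reported in coordinate order with
    the smallest window p-value and, when count tracks are supplied, the
    mean IP/input window counts over the run.
    """
    w = tracks.params.window_size
    peaks: list[Peak] = []
    for chrom in tracks.candidate:
        cand = tracks.candidate[chrom]
        sig = tracks.significant[chrom]
        pv = tracks.p[chrom]
        for s, e in _runs(cand):
            if e - s < 3 or not sig[s:e].any():
                continue
            peaks.append(
                Peak(
                    chrom=chrom,
                    start=int(s * w),
                    end=int(e * w),
                    n_windows=int(e - s),
                    min_p=float(pv[s:e].min()),
                    mean_ip=(
                        float(ip_track.data[chrom][s:e].mean())
                        if ip_track is not None
                        else float("nan")
                    ),
                    mean_input=(
                        float(input_track.data[chrom][s:e].mean())
                        if input_track is not None
                        else float("nan")
                    ),
                )
            )
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def call_peaks(
    ip: ReadSet,
    input_: ReadSet,
    genome: GenomeSpec,
    params: PeakCallParams | None = None,
) -> tuple[list[Peak], WindowTrack, WindowTrack, SignificanceTracks]:
    """Full calling pipeline: dedup, equalize, tile, test, merge.

    Returns (peaks, ip_track, input_track, significance) where the tracks
    hold the deduplicated, depth-equalized window counts.
    """
    params = params or PeakCallParams()
    ip_d = deduplicate(ip)
    in_d = deduplicate(input_)
    ip_e, in_e = equalize_depth(ip_d, in_d, seed=params.seed)
    ip_track = tile_counts(ip_e, genome, params.window_size)
    in_track = tile_counts(in_e, genome, params.window_size)
    tracks = window_significance(ip_track, in_track, params)
    peaks = merge_peaks(tracks, ip_track, in_track)
    return peaks, ip_track, in_track, tracks
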