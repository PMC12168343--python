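"""Random-gene-set resampling null for TSS-proximal differential binding.

The observed statistic is the mean differential signal in a window around
the TSS, averaged over a target gene set.  The null re-draws gene sets of
the same size from a universe excluding the targets, recomputes the same
statistic per trial, and reports the pointwise min/mean/max envelope of the
trial profiles plus an add-one empirical p-value
p = (1 + #{trials with summary >= observed}) / (n_trials + 1),
which can never be exactly 0.  An exhaustive mode enumerates every subset of
the universe instead of sampling, for exact small-universe checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import GeneModel, WindowTrack
from .profiles import ProfileParams, tss_matrix

__all__ = ["ResamplingParams", "ResamplingResult", "gene_set_summary", "resample_null"]


@dataclass
class ResamplingParams:
    n_trials: int = 100
    tss_halfwidth: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.tss_halfwidth < 1:
            raise ValueError("tss_halfwidth must be >= 1")


@dataclass
class ResamplingResult:
    positions: np.ndarray
    observed_profile: np.ndarray
    null_mean_profile: np.ndarray
    null_min_profile: np.ndarray
    null_max_profile: np.ndarray
    observed_summary: float
    null_summaries: np.ndarray
    empirical_p: float
    n_trials: int
    exhaustive: bool = False


def _profile_params(track: WindowTrack, params: ResamplingParams) -> ProfileParams:
    w = track.window_size
    half = (params.tss_halfwidth // w) * w
    if half < w:
        raise ValueError("tss_halfwidth smaller than one window")
    return ProfileParams(
        tss_upstream=half, tss_downstream=half, flank=half, bin=w
    )


def gene_set_summary(
    diff_track: WindowTrack,
    gene_set: Sequence[GeneModel],
    params: ResamplingParams | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Average TSS-proximal profile of a gene set plus its scalar summary.

    Returns (positions, profile, summary) where the profile covers
    [-tss_halfwidth, +tss_halfwidth) in transcription orientation and the
    summary is the mean over its bins.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    params = params or ResamplingParams()
    m = tss_matrix(diff_track, gene_set, _profile_params(diff_track, params))
    profile = m.column_mean()
    return m.positions, profile, float(profile.mean())


def resample_null(
    diff_track: WindowTrack,
    target_set: Sequence[GeneModel],
    universe: Sequence[GeneModel],
    params: ResamplingParams | None = None,
    exhaustive: bool = False,
) -> ResamplingResult:
    """Compare a target gene set's TSS-proximal signal with random sets.

    ``universe`` must exclude the target genes (mirroring a comparison
    against non-target genes) and be at least as large as the target set.
    Each trial draws |target_set| genes without replacement; draws are
    independent across trials.  With ``exhaustive=True`` all
    C(|universe|, |target_set|) subsets are evaluated instead and n_trials
    is ignored.
    """
    params = params or ResamplingParams()
    if not target_set:
        raise ValueError("target set is empty")
    k = len(target_set)
    if len(universe) < k:
        raise ValueError("universe smaller than target set")
    target_ids = {g.gene_id for g in target_set}
    overlap = [g.gene_id for g in universe if g.gene_id in target_ids]
    if overlap:
        raise ValueError(f"universe contains target genes: {overlap[:3]}")

    pp = _profile_params(diff_track, params)
    target_m = tss_matrix(diff_track, target_set, pp)
    observed_profile = target_m.column_mean()
    observed = float(observed_profile.mean())

    # per-gene rows computed once; every trial is a row-subset average
    uni_m = tss_matrix(diff_track, list(universe), pp).matrix

    if exhaustive:
        n_subsets = math.comb(len(universe), k)
        if n_subsets > 200_000:
            raise ValueError("universe too large for exhaustive enumeration")
        trial_profiles = np.empty((n_subsets, uni_m.shape[1]))
        for t, combo in enumerate(itertools.combinations(range(len(universe)), k)):
            trial_profiles[t] = uni_m[list(combo)].mean(axis=0)
        n_trials = n_subsets
    else:
        rng = np.random.default_rng(params.seed)
        n_trials = params.n_trials
        trial_profiles = np.empty((n_trials, uni_m.shape[1]))
        for t in range(n_trials):
            rows = rng.choice(len(universe), size=k, replace=False)
            trial_profiles[t] = uni_m[rows].mean(axis=0)

    null_summaries = trial_profiles.mean(axis=1)
    empirical_p = (1 + int((null_summaries >= observed).sum())) / (n_trials + 1)
    return ResamplingResult(
        positions=target_m.positions,
        observed_profile=observed_profile,
        null_mean_profile=trial_profiles.mean(axis=0),
        null_min_profile=trial_profiles.min(axis=0),
        null_max_profile=trial_profiles.max(axis=0),
        observed_summary=observed,
        null_summaries=null_summaries,
        empirical_p=float(empirical_p),
        n_trials=n_trials,
        exhaustive=exhaustive,
    )
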