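"""Self-contained simulation studies exercising the whole pipeline.

Each function generates its own synthetic data at fixed study conditions,
runs the relevant pipeline stages and returns a small dictionary of summary
numbers.  These are the computations behind the analysis drivers and the
acceptance checks; only the seed is meant to vary between runs.
"""

from __future__ import annotations

import numpy as np

from .core import GenomeSpec
from .expression import ExpressionTable, classify_de, spikein_normalize
from .peakcall import PeakCallParams, call_peaks, deduplicate, equalize_depth, tile_counts
from .profiles import ProfileParams, associate_genes, gene_body_signal
from .resampling import ResamplingParams, resample_null
from .profiles import differential_track
from .simulate import (
    ChipSimParams,
    ExprSimParams,
    make_genes,
    simulate_chip,
    simulate_expression,
)

__all__ = [
    "global_body_loss",
    "background_calibration",
    "promoter_gain_detection",
    "spikein_recovery",
]


def global_body_loss(
    seed: int = 0,
    chrom_len: int = 5_000_000,
    n_genes: int = 200,
    n_reads: int = 500_000,
    body_enrichment: float = 8.0,
    reduction: float = 0.4,
) -> dict:
    """Genome-wide gene-body signal loss between two conditions.

    Condition 1 carries ``body_enrichment`` at every gene body; condition 2
    the same reduced by ``reduction`` (40% by default).  Genes are associated
    from condition-1 peak calls (-1/+5 kb around the TSS) and the fraction of
    associated genes whose reads-per-million gene-body signal drops in
    condition 2 is reported as a percentage.
    """
    genome = GenomeSpec(("chr1",), (chrom_len,))
    genes = make_genes(genome, n_genes, 2_000, 10_000, seed=seed)
    body1 = body_enrichment
    body2 = body_enrichment * (1 - reduction)
    tracks = {}
    peaks1 = None
    for i, body in enumerate((body1, body2)):
        ip = simulate_chip(genome, genes,
                           ChipSimParams(body_enrichment=body, n_reads=n_reads,
                                         seed=seed * 10 + 1 + 2 * i))
        inp = simulate_chip(genome, genes,
                            ChipSimParams(n_reads=n_reads,
                                          seed=seed * 10 + 2 + 2 * i))
        peaks, ip_track, _, _ = call_peaks(ip, inp, genome,
                                           PeakCallParams(seed=seed))
        tracks[i] = ip_track.rpm()
        if i == 0:
            peaks1 = peaks
    associated = associate_genes(peaks1, genes, ProfileParams())
    assoc_genes = [g for g in genes if g.gene_id in associated]
    sig1 = gene_body_signal(tracks[0], assoc_genes)
    sig2 = gene_body_signal(tracks[1], assoc_genes)
    lower = sum(sig2[g] < sig1[g] for g in sig1)
    return {
        "n_genes": n_genes,
        "n_peaks_cond1": len(peaks1),
        "n_associated": len(assoc_genes),
        "percent_reduced": 100.0 * lower / max(len(assoc_genes), 1),
    }


def background_calibration(
    seed: int = 0,
    chrom_len: int = 5_000_000,
    n_reads: int = 200_000,
    window_size: int = 50,
) -> dict:
    """Candidate rate and peak count on an enrichment-free simulation.

    IP and input are independent draws from the same uniform background at
    equal depth; with a well-calibrated Poisson cutoff the candidate-window
    rate is at most alpha and merged peaks are essentially absent.
    """
    genome = GenomeSpec(("chr1",), (chrom_len,))
    params = PeakCallParams(window_size=window_size, seed=seed)
    ip = simulate_chip(genome, [], ChipSimParams(n_reads=n_reads,
                                                seed=seed * 10 + 1))
    inp = simulate_chip(genome, [], ChipSimParams(n_reads=n_reads,
                                                 seed=seed * 10 + 2))
    peaks, ip_track, in_track, sig = call_peaks(ip, inp, genome, params)
    n_windows = sum(len(v) for v in sig.candidate.values())
    n_cand = int(sum(v.sum() for v in sig.candidate.values()))
    return {
        "n_windows": n_windows,
        "candidate_rate": n_cand / n_windows,
        "n_peaks": len(peaks),
    }


def promoter_gain_detection(
    seed: int = 0,
    chrom_len: int = 2_000_000,
    n_genes: int = 150,
    n_target: int = 50,
    n_reads: int = 200_000,
    promoter_gain: float = 4.0,
    n_trials: int = 100,
) -> dict:
    """Target-set promoter gain versus the random-gene-set null.

    Condition 2 adds ``promoter_gain`` within 1 kb of the TSS at
    ``n_target`` designated genes only; the differential (condition 2 minus
    condition 1, RPM) TSS signal of the target set is compared with
    ``n_trials`` equal-size random sets of the remaining genes.
    """
    genome = GenomeSpec(("chr1",), (chrom_len,))
    genes = make_genes(genome, n_genes, 2_000, 10_000, seed=seed)
    rng = np.random.default_rng(seed + 1)
    target_idx = set(rng.choice(n_genes, size=n_target, replace=False).tolist())
    target = [g for i, g in enumerate(genes) if i in target_idx]
    universe = [g for i, g in enumerate(genes) if i not in target_idx]
    promoter2 = {g.gene_id: promoter_gain for g in target}

    ip1 = simulate_chip(genome, genes,
                        ChipSimParams(n_reads=n_reads, seed=seed * 10 + 1))
    ip2 = simulate_chip(genome, genes,
                        ChipSimParams(promoter_enrichment=promoter2,
                                      promoter_halfwidth=1000,
                                      n_reads=n_reads, seed=seed * 10 + 2))
    a, b = equalize_depth(deduplicate(ip1), deduplicate(ip2), seed=seed)
    t1 = tile_counts(a, genome, 50)
    t2 = tile_counts(b, genome, 50)
    diff = differential_track(t2, t1)
    rr = resample_null(diff, target, universe,
                       ResamplingParams(n_trials=n_trials, tss_halfwidth=1000,
                                        seed=seed))
    return {
        "observed_summary": rr.observed_summary,
        "null_max_summary": float(rr.null_summaries.max()),
        "empirical_p": rr.empirical_p,
        "exceeds_null_max": bool(rr.observed_summary
                                 > rr.null_summaries.max()),
    }


def spikein_recovery(
    seed: int = 0,
    n_genes: int = 300,
    base_mean: float = 200.0,
    library_scale: tuple[float, float] = (1.0, 2.0),
) -> dict:
    """Known fold changes through a 2x library distortion.

    A quarter of genes are 4x up, a quarter 4x down; spike-in normalisation
    must equalise spike sums exactly and fold-change classification at
    cutoff 2 must recover the changed genes.
    """
    rng = np.random.default_rng(seed)
    log2fc = rng.choice([-2.0, 0.0, 2.0], size=n_genes, p=(0.25, 0.5, 0.25))
    table = ExpressionTable.from_frame(simulate_expression(ExprSimParams(
        n_genes=n_genes, n_spikeins=10, base_mean=base_mean,
        fold_changes=2.0 ** log2fc, library_scale=library_scale,
        seed=seed + 1,
    )))
    table = spikein_normalize(table)
    spike_sums = table.adjusted.loc[sorted(table.spikein_ids)].sum(axis=0)
    labels = classify_de(table, fold_cutoff=2.0, min_expr=0.1)
    truth = np.where(log2fc >= 2, "up", np.where(log2fc <= -2, "down", None))
    changed = truth != None  # noqa: E711
    ids = [f"gene_{i:04d}" for i in range(n_genes)]
    correct = sum(
        labels[gid] == truth[i]
        for i, gid in enumerate(ids) if changed[i]
    )
    return {
        "n_changed": int(changed.sum()),
        "recovery_rate": correct / int(changed.sum()),
        "spike_sum_max_rel_dev": float(
            (spike_sums / spike_sums.mean() - 1).abs().max()
        ),
    }
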