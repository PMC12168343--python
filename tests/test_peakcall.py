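"""Dedup, depth equalization, tiling, Poisson significance and peak merging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromadapt import (
    ChipSimParams,
    GenomeSpec,
    PeakCallParams,
    ReadSet,
    WindowTrack,
    call_peaks,
    deduplicate,
    equalize_depth,
    make_genes,
    merge_peaks,
    poisson_sf,
    simulate_chip,
    tile_counts,
    window_significance,
)
from chromadapt.peakcall import SignificanceTracks


def poisson_sf_oracle(k: int, lam: float) -> float:
    """Direct upper-tail summation P(X >= k) = sum_{i>=k} e^-lam lam^i / i!."""
    log_term = -lam + k * math.log(lam) - math.lgamma(k + 1)
    total = 0.0
    i = k
    term = math.exp(log_term)
    while term > total * 1e-18 or i < k + 10:
        total += term
        i += 1
        term *= lam / i
        if i > k + 10_000:
            break
    return total


class TestDeduplicate:
    def test_identical_records_collapse(self):
        rs = ReadSet.from_arrays(["c", "c"], [10, 10], [60, 60], ["+", "+"])
        assert len(deduplicate(rs)) == 1

    def test_opposite_strands_both_kept(self):
        rs = ReadSet.from_arrays(["c", "c"], [10, 10], [60, 60], ["+", "-"])
        assert len(deduplicate(rs)) == 2

    def test_idempotent(self):
        rs = ReadSet.from_arrays(
            ["c", "c", "c", "d"], [10, 10, 20, 10], [60, 60, 70, 60],
            ["+", "+", "+", "+"],
        )
        once = deduplicate(rs)
        twice = deduplicate(once)
        assert once.records.equals(twice.records)


class TestEqualizeDepth:
    def _mk(self, n):
        return ReadSet.from_arrays(
            ["c"] * n, np.arange(n) * 100, np.arange(n) * 100 + 50, ["+"] * n
        )

    def test_sizes_equal_min(self):
        ip, inp = equalize_depth(self._mk(100), self._mk(80), seed=1)
        assert len(ip) == len(inp) == 80

    def test_equal_sizes_unchanged(self):
        a, b = self._mk(50), self._mk(50)
        ip, inp = equalize_depth(a, b, seed=1)
        assert ip.records.equals(a.records) and inp.records.equals(b.records)

    def test_seeded_and_without_replacement(self):
        a, b = self._mk(100), self._mk(60)
        ip1, _ = equalize_depth(a, b, seed=5)
        ip2, _ = equalize_depth(a, b, seed=5)
        assert ip1.records.equals(ip2.records)
        assert not ip1.records.duplicated().any()

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            equalize_depth(self._mk(0), self._mk(10))


class TestTileCounts:
    def test_midpoint_assignment(self, one_chrom):
        # read [60, 110): midpoint 85 -> window index 1 at width 50
        rs = ReadSet.from_arrays(["chr1"], [60], [110], ["+"])
        t = tile_counts(rs, one_chrom, 50)
        assert t.data["chr1"][1] == 1
        assert t.total() == 1

    def test_count_conservation(self, small_genome):
        genes = make_genes(small_genome, 6, seed=1)
        rs = simulate_chip(small_genome, genes,
                           ChipSimParams(body_enrichment=4, n_reads=7000, seed=2))
        t = tile_counts(rs, small_genome, 50)
        assert t.total() == len(rs)

    def test_empty_reads(self, one_chrom):
        rs = ReadSet.from_arrays([], [], [], [])
        assert tile_counts(rs, one_chrom, 50).total() == 0

    def test_read_beyond_chromosome_raises(self, one_chrom):
        rs = ReadSet.from_arrays(["chr1"], [99_990], [100_040], ["+"])
        with pytest.raises(ValueError, match="beyond"):
            tile_counts(rs, one_chrom, 50)


class TestPoissonSf:
    def test_k_zero_is_one(self):
        assert poisson_sf(0, 0.5) == 1.0
        assert poisson_sf(0, 17.0) == 1.0

    def test_known_values(self):
        # 1 - sum_{i<6} e^-1/i!
        assert poisson_sf(6, 1.0) == pytest.approx(5.9418e-4, rel=1e-3)
        assert poisson_sf(1, 2.0) == pytest.approx(1 - math.exp(-2), rel=1e-12)

    def test_matches_summation_oracle(self):
        for lam in (0.1, 0.7, 1.0, 3.0, 8.5, 20.0):
            for k in range(0, 51, 5):
                expected = poisson_sf_oracle(k, lam) if k else 1.0
                assert poisson_sf(k, lam) == pytest.approx(expected, rel=1e-12)

    def test_monotonicity(self):
        ks = np.arange(30)
        p = poisson_sf(ks, 4.0)
        assert (np.diff(p) <= 0).all()
        lams = np.linspace(0.5, 15, 40)
        p = poisson_sf(10, lams)
        assert (np.diff(p) >= 0).all()

    def test_invalid_lam(self):
        with pytest.raises(ValueError):
            poisson_sf(3, 0.0)


def _tracks_from_pattern(pattern, high=20, window=50):
    """IP counts high where pattern is True, 0 elsewhere; input all 1."""
    ip = WindowTrack(window, {"c": np.where(pattern, high, 0).astype(float)})
    inp = WindowTrack(window, {"c": np.ones(len(pattern))})
    return ip, inp


class TestWindowSignificance:
    def test_both_neighbor_rule_enumeration(self):
        ip, inp = _tracks_from_pattern([True, True, True, False])
        s = window_significance(ip, inp)
        assert s.candidate["c"].tolist() == [True, True, True, False]
        assert s.significant["c"].tolist() == [False, True, False, False]

    def test_isolated_candidates_never_significant(self):
        ip, inp = _tracks_from_pattern([True, False, True])
        s = window_significance(ip, inp)
        assert not s.significant["c"].any()

    def test_any_adjacent_rule(self):
        ip, inp = _tracks_from_pattern([True, True, False, False])
        s = window_significance(
            ip, inp, PeakCallParams(neighbor_rule="any_adjacent")
        )
        # window 1 has a candidate left neighbor; edge window 0 still excluded
        assert s.significant["c"].tolist() == [False, True, False, False]

    def test_edge_windows_excluded(self):
        ip, inp = _tracks_from_pattern([True, True, True])
        s = window_significance(ip, inp)
        assert s.significant["c"].tolist() == [False, True, False]

    def test_identical_tracks_nothing_called(self, one_chrom):
        genes = make_genes(one_chrom, 4, seed=3)
        rs = simulate_chip(one_chrom, genes, ChipSimParams(n_reads=50_000, seed=8))
        t = tile_counts(rs, one_chrom, 50)
        s = window_significance(t, t)
        assert not s.significant["chr1"].any()

    def test_grid_mismatch_raises(self):
        a = WindowTrack(50, {"c": np.zeros(4)})
        b = WindowTrack(50, {"c": np.zeros(5)})
        with pytest.raises(ValueError, match="grids"):
            window_significance(a, b)


class TestMergePeaks:
    def _sig(self, cand, sig, p=None, window=50):
        cand = np.asarray(cand, dtype=bool)
        sig_arr = np.asarray(sig, dtype=bool)
        pv = np.where(cand, 1e-5, 1.0) if p is None else np.asarray(p)
        return SignificanceTracks(
            {"c": pv}, {"c": cand}, {"c": sig_arr}, PeakCallParams(window_size=window)
        )

    def test_single_run_becomes_one_peak(self):
        peaks = merge_peaks(self._sig([1, 1, 1], [0, 1, 0]))
        assert len(peaks) == 1
        p = peaks[0]
        assert (p.start, p.end, p.n_windows) == (0, 150, 3)
        assert p.min_p == pytest.approx(1e-5)

    def test_two_runs_split_by_gap(self):
        cand = [1, 1, 1, 0, 1, 1, 1]
        sig = [0, 1, 0, 0, 0, 1, 0]
        peaks = merge_peaks(self._sig(cand, sig))
        assert [(p.start, p.end) for p in peaks] == [(0, 150), (200, 350)]

    def test_runs_without_significant_window_dropped(self):
        peaks = merge_peaks(self._sig([1, 1, 1], [0, 0, 0]))
        assert peaks == []

    def test_no_candidates_empty(self):
        assert merge_peaks(self._sig([0, 0, 0], [0, 0, 0])) == []


class TestRecovery:
    def test_enriched_bodies_recovered(self):
        """>=90% of 8x-enriched gene bodies overlap a called peak and >=95%
        of peaks fall in truly enriched territory."""
        genome = GenomeSpec(("chr1",), (2_000_000,))
        genes = make_genes(genome, 50, 2000, 10_000, seed=21)
        ip = simulate_chip(genome, genes,
                           ChipSimParams(body_enrichment=8.0, n_reads=200_000,
                                         seed=22))
        inp = simulate_chip(genome, genes,
                            ChipSimParams(n_reads=200_000, seed=23))
        peaks, *_ = call_peaks(ip, inp, genome, PeakCallParams(seed=24))
        hit = sum(
            any(p.start < g.end and g.start < p.end for p in peaks)
            for g in genes
        )
        assert hit / len(genes) >= 0.90
        margin = 500  # enriched territory: gene bodies plus half a fragment
        true_pos = sum(
            any(p.start < g.end + margin and g.start - margin < p.end
                for g in genes)
            for p in peaks
        )
        assert true_pos / len(peaks) >= 0.95


@settings(max_examples=30, deadline=None)
@given(
    starts=st.lists(st.integers(0, 990), min_size=1, max_size=60),
    strands=st.lists(st.sampled_from(["+", "-"]), min_size=1, max_size=60),
)
def test_dedup_conservation_property(starts, strands):
    """Dedup keeps exactly one read per distinct (start, strand) key and
    window counts still sum to the deduplicated read count."""
    n = min(len(starts), len(strands))
    starts, strands = starts[:n], strands[:n]
    rs = ReadSet.from_arrays(["c"] * n, starts, [s + 10 for s in starts], strands)
    d = deduplicate(rs)
    assert len(d) == len({(s, t) for s, t in zip(starts, strands)})
    genome = GenomeSpec(("c",), (1_000,))
    assert tile_counts(d, genome, 50).total() == len(d)
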