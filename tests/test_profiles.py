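"""Orientation, scaling and consistency of gene-anchored profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromadapt import (
    GeneModel,
    GenomeSpec,
    Peak,
    ProfileParams,
    WindowTrack,
    associate_genes,
    differential_track,
    heatmap_matrix,
    metagene,
    polysome_ratio,
    tss_matrix,
    tss_profile,
)
from tests.conftest import (
    minus_gene,
    plus_gene,
    reflect_gene,
    reflect_track,
    track_from,
)


def _peak(chrom, start, end):
    return Peak(chrom, start, end, n_windows=(end - start) // 50, min_p=1e-6)


class TestAssociateGenes:
    params = ProfileParams(tss_upstream=1000, tss_downstream=5000)

    def test_plus_strand_downstream_peak(self):
        g = GeneModel("g", "chr1", "+", 10_000, 30_000)
        assert associate_genes([_peak("chr1", 11_000, 11_200)], [g],
                               self.params) == {"g"}

    def test_plus_strand_too_far_upstream(self):
        g = GeneModel("g", "chr1", "+", 10_000, 30_000)
        assert associate_genes([_peak("chr1", 8_000, 8_900)], [g],
                               self.params) == set()

    def test_minus_strand_mirrored_interval(self):
        # minus-strand TSS at 10000: downstream (5' -> 3') runs toward
        # smaller coordinates, so [6000, 6100) lies within +5 kb
        g = GeneModel("g", "chr1", "-", 2_000, 10_000)
        assert associate_genes([_peak("chr1", 6_000, 6_100)], [g],
                               self.params) == {"g"}
        # and [10500, 11500) is within the 1-kb upstream margin
        assert associate_genes([_peak("chr1", 10_500, 10_900)], [g],
                               self.params) == {"g"}
        assert associate_genes([_peak("chr1", 11_500, 12_000)], [g],
                               self.params) == set()

    def test_other_chromosome_ignored(self):
        g = GeneModel("g", "chr1", "+", 10_000, 30_000)
        assert associate_genes([_peak("chr2", 11_000, 11_200)], [g],
                               self.params) == set()


class TestTssProfile:
    def test_constant_track_flat(self, one_chrom):
        t = track_from(one_chrom, fill=3.0)
        pos, prof = tss_profile(t, [plus_gene(), minus_gene()])
        np.testing.assert_allclose(prof, 3.0)
        assert pos[0] == -1000 + 25 and pos[-1] == 5000 - 25

    def test_peak_at_tss_maximal_at_zero(self, one_chrom):
        t = track_from(one_chrom)
        g = plus_gene(start=20_000)
        t.data["chr1"][20_000 // 50] = 9.0
        pos, prof = tss_profile(t, [g])
        assert prof[np.argmax(prof)] == 9.0
        assert pos[np.argmax(prof)] == 25.0  # centre of the TSS window

    def test_reflection_invariance(self, one_chrom):
        """Reversing the genome and flipping strands leaves profiles
        unchanged (orientation correctness)."""
        rng = np.random.default_rng(0)
        t = track_from(one_chrom)
        t.data["chr1"][:] = rng.integers(0, 6, len(t.data["chr1"]))
        genes = [plus_gene(), minus_gene()]
        L = one_chrom.sizes["chr1"]
        mirror_genes = [reflect_gene(g, L) for g in genes]
        mirror_track = reflect_track(t)
        _, a = tss_profile(t, genes)
        _, b = tss_profile(mirror_track, mirror_genes)
        np.testing.assert_allclose(a, b)

    def test_off_chromosome_counts_as_zero(self, one_chrom):
        t = track_from(one_chrom, fill=2.0)
        g = plus_gene(start=200, end=4_000)  # upstream kb mostly off-genome
        _, prof = tss_profile(t, [g])
        assert prof[0] == 0.0  # bin centred at -975
        assert prof[-1] == 2.0

    def test_empty_gene_list_raises(self, one_chrom):
        with pytest.raises(ValueError):
            tss_profile(track_from(one_chrom), [])


class TestMetagene:
    def test_constant_track_flat(self, one_chrom):
        t = track_from(one_chrom, fill=4.0)
        _, prof, skipped = metagene(t, [plus_gene(), minus_gene()])
        np.testing.assert_allclose(prof, 4.0)
        assert skipped == 0

    def test_3kb_gene_identity_scaling(self, one_chrom):
        t = track_from(one_chrom)
        g = plus_gene(start=20_000, end=23_000)
        raw = np.arange(60, dtype=float)
        t.data["chr1"][400:460] = raw
        params = ProfileParams(flank=0, body_scaled_length=3000, bin=50)
        _, prof, _ = metagene(t, [g], params)
        np.testing.assert_allclose(prof, raw)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_step_signal_interpolation(self, one_chrom, strand):
        """6-kb gene with signal h over its 5' half scales to h over the
        first half of the 3-kb body, 0 over the second."""
        t = track_from(one_chrom)
        g = GeneModel("g", "chr1", strand, 20_000, 26_000)
        lo, hi = (20_000, 23_000) if strand == "+" else (23_000, 26_000)
        t.data["chr1"][lo // 50: hi // 50] = 7.0
        params = ProfileParams(flank=0, body_scaled_length=3000, bin=50)
        _, prof, _ = metagene(t, [g], params)
        np.testing.assert_allclose(prof[:30], 7.0)
        np.testing.assert_allclose(prof[30:], 0.0)

    def test_short_gene_skipped_and_reported(self, one_chrom):
        t = track_from(one_chrom, fill=1.0)
        short = GeneModel("s", "chr1", "+", 500, 530)
        _, prof, skipped = metagene(t, [plus_gene(), short])
        assert skipped == 1
        np.testing.assert_allclose(prof, 1.0)

    @settings(max_examples=20, deadline=None)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 18), st.integers(1, 80),
                      st.sampled_from(["+", "-"])),
            min_size=1, max_size=6, unique_by=lambda x: x[0],
        )
    )
    def test_uniform_track_flat_for_any_gene_mix(self, data):
        """Metagene of a uniform track is the uniform value for any mixture
        of gene lengths and strands (genes kept inside the genome)."""
        genome = GenomeSpec(("c",), (200_000,))
        t = WindowTrack(50, {"c": np.full(4000, 2.5)}, "density")
        genes = [
            GeneModel(f"g{i}", "c", strand, 20_000 + slot * 8_000,
                      20_000 + slot * 8_000 + 50 * nwin)
            for i, (slot, nwin, strand) in enumerate(data)
            if 50 * nwin <= 8_000
        ]
        if not genes:
            return
        _, prof, skipped = metagene(t, genes, ProfileParams(flank=1000, bin=50))
        assert skipped == 0
        np.testing.assert_allclose(prof, 2.5)


class TestHeatmap:
    def _random_track(self, genome, seed=0):
        rng = np.random.default_rng(seed)
        t = track_from(genome)
        for c in t.data:
            t.data[c][:] = rng.integers(0, 10, len(t.data[c]))
        return t

    def test_column_mean_equals_profile(self, one_chrom):
        t = self._random_track(one_chrom)
        genes = [plus_gene(), minus_gene(),
                 plus_gene("g3", start=60_000, end=66_000)]
        m = heatmap_matrix(t, genes)
        _, prof = tss_profile(t, genes)
        np.testing.assert_allclose(m.column_mean(), prof)

    def test_rows_sorted_descending(self, one_chrom):
        t = self._random_track(one_chrom)
        genes = [plus_gene(), minus_gene()]
        m = heatmap_matrix(t, genes)
        means = m.matrix.mean(axis=1)
        assert (np.diff(means) <= 0).all()
        again = heatmap_matrix(t, genes)
        assert again.gene_ids == m.gene_ids  # stable

    def test_reference_order_reused(self, one_chrom):
        t1 = self._random_track(one_chrom, seed=1)
        t2 = self._random_track(one_chrom, seed=2)
        genes = [plus_gene(), minus_gene()]
        ref = heatmap_matrix(t1, genes)
        m2 = heatmap_matrix(t2, genes, order=ref.gene_ids)
        assert m2.gene_ids == ref.gene_ids
        direct = tss_matrix(t2, genes)
        row = direct.matrix[direct.gene_ids.index(ref.gene_ids[0])]
        np.testing.assert_allclose(m2.matrix[0], row)


class TestDifferentialTrack:
    def test_equal_tracks_zero(self, one_chrom):
        t = track_from(one_chrom, fill=2.0)
        d = differential_track(t, t)
        assert d.value_kind == "difference"
        for v in d.data.values():
            np.testing.assert_allclose(v, 0.0)

    def test_antisymmetry(self, small_genome):
        rng = np.random.default_rng(3)
        a, b = track_from(small_genome), track_from(small_genome)
        for c in a.data:
            a.data[c][:] = rng.integers(0, 8, len(a.data[c]))
            b.data[c][:] = rng.integers(0, 8, len(b.data[c]))
        ab, ba = differential_track(a, b), differential_track(b, a)
        for c in ab.data:
            np.testing.assert_allclose(ab.data[c], -ba.data[c])

    def test_single_extra_count_positive_only_there(self, one_chrom):
        a = track_from(one_chrom, fill=1.0)
        b = track_from(one_chrom, fill=1.0)
        a.data["chr1"][7] += 1  # equal depth: remove one elsewhere
        a.data["chr1"][1500] -= 1
        d = differential_track(a, b)
        v = d.data["chr1"]
        assert v[7] > 0 and v[1500] < 0
        mask = np.ones(len(v), bool)
        mask[[7, 1500]] = False
        np.testing.assert_allclose(v[mask], 0.0)

    def test_grid_mismatch_raises(self, one_chrom, small_genome):
        with pytest.raises(ValueError):
            differential_track(track_from(one_chrom, fill=1),
                               track_from(small_genome, fill=1))


class TestPolysomeRatio:
    def test_overlapping_regions_rejected(self):
        y = np.ones(100)
        with pytest.raises(ValueError, match="overlap"):
            polysome_ratio(y, (10, 50), (40, 90))

    def test_zero_monosome_area_rejected(self):
        y = np.zeros(100)
        y[60:90] = 1.0
        with pytest.raises(ValueError, match="monosome"):
            polysome_ratio(y, (10, 40), (50, 95))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of bounds"):
            polysome_ratio(np.ones(50), (10, 60), (0, 5))

    def test_baseline_subtraction(self):
        y = np.zeros(200)
        y[40:60] = 2.0   # mono block AUC ~ 40
        y[120:160] = 2.0  # poly block AUC ~ 80
        r0 = polysome_ratio(y, (30, 70), (110, 170))
        r1 = polysome_ratio(y + 0.5, (30, 70), (110, 170), baseline=0.5)
        assert r1 == pytest.approx(r0)
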