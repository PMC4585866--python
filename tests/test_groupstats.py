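"""Group maps, FDR masking, cluster permutation test, weight sets, ROI tests."""

import numpy as np
import pytest

from aci.groupstats import (cluster_permutation_test, extract_weight_sets,
                            group_mean, pixel_ttest_fdr, roi_group_test)

GRID = (12, 12)
TIME_BIN = 0.0156
CFS = np.geomspace(96, 7760, GRID[1])


def noise_maps(n, seed, grid=GRID, sd=1.0):
    return sd * np.random.default_rng(seed).standard_normal((n, *grid))


class TestGroupMean:
    def test_identical_maps(self):
        m = noise_maps(1, 0)[0]
        np.testing.assert_allclose(group_mean([m, m, m]), m)

    def test_map_plus_negation_cancels(self):
        m = noise_maps(1, 1)[0]
        np.testing.assert_allclose(group_mean([m, -m]), np.zeros(GRID),
                                   atol=1e-15)

    def test_order_invariant(self):
        maps = list(noise_maps(5, 2))
        np.testing.assert_allclose(group_mean(maps), group_mean(maps[::-1]))


class TestFDR:
    def test_null_false_positive_fraction_controlled(self):
        # over replicates of 19 pure-noise maps, the average fraction of
        # pixels declared significant stays at or below q
        q, n_reps = 0.05, 200
        fractions = []
        for rep in range(n_reps):
            _, _, mask = pixel_ttest_fdr(noise_maps(19, 1000 + rep), q=q)
            fractions.append(mask.mean())
        assert np.mean(fractions) <= q * 1.3  # sampling slack

    def test_power_to_detect_injected_offset(self):
        rng = np.random.default_rng(5)
        maps = noise_maps(19, 7, sd=0.5)
        pix = [(i, j) for i in range(2, 7) for j in range(3, 5)]
        for i, j in pix:
            maps[:, i, j] += 1.0
        _, _, mask = pixel_ttest_fdr(maps, q=0.01)
        hit = np.mean([mask[i, j] for i, j in pix])
        assert hit >= 0.9
        assert mask.mean() <= len(pix) / mask.size + 0.02

    def test_nested_masks_across_q(self):
        maps = noise_maps(12, 8)
        maps[:, 4:6, 4:6] += 1.2
        *_, strict = pixel_ttest_fdr(maps, q=0.01)
        *_, loose = pixel_ttest_fdr(maps, q=0.05)
        assert np.all(loose[strict])  # strict mask is a subset

    def test_all_zero_maps_warn_with_empty_mask(self):
        with pytest.warns(UserWarning):
            _, _, mask = pixel_ttest_fdr([np.zeros(GRID)] * 5)
        assert not mask.any()

    def test_fewer_than_three_maps_rejected(self):
        with pytest.raises(ValueError):
            pixel_ttest_fdr(noise_maps(2, 0))


class TestClusterPermutation:
    def test_identical_groups_give_empty_result(self):
        maps = noise_maps(6, 10)
        clusters, tmap = cluster_permutation_test(maps, maps.copy(),
                                                  n_permutations=200)
        assert clusters == []
        np.testing.assert_allclose(tmap, 0.0, atol=1e-12)

    def test_detects_localized_group_shift(self):
        rng = np.random.default_rng(11)
        g1 = noise_maps(10, 12)
        g2 = noise_maps(10, 13)
        g2[:, 3:7, 3:7] += 1.6
        clusters, _ = cluster_permutation_test(
            g1, g2, alpha_threshold=0.05, n_permutations=500,
            rng=np.random.default_rng(1))
        assert clusters
        best = clusters[0]
        assert best.p_value < 0.05
        inj = {(i, j) for i in range(3, 7) for j in range(3, 7)}
        assert len(inj & set(best.pixels)) >= len(best.pixels) // 2

    def test_type_i_error_near_nominal(self):
        # 120 null replicates on the reduced grid; reject when the best
        # cluster beats 0.05
        n_reps, rejections = 120, 0
        rng = np.random.default_rng(2)
        for rep in range(n_reps):
            g1 = noise_maps(8, 5000 + rep)
            g2 = noise_maps(8, 9000 + rep)
            clusters, _ = cluster_permutation_test(
                g1, g2, n_permutations=199, rng=rng)
            if clusters and clusters[0].p_value <= 0.05:
                rejections += 1
        rate = rejections / n_reps
        assert 0.0 <= rate <= 0.11  # ~5% within binomial error

    def test_relabeling_both_groups_identically_is_invariant(self):
        g1 = noise_maps(6, 20)
        g2 = noise_maps(6, 21)
        g2[:, 2:5, 2:5] += 1.5
        perm = np.random.default_rng(0).permutation(6)
        c1, t1 = cluster_permutation_test(g1, g2, n_permutations=400,
                                          rng=np.random.default_rng(3))
        c2, t2 = cluster_permutation_test(g1[perm], g2[perm],
                                          n_permutations=400,
                                          rng=np.random.default_rng(3))
        # observed statistics are exactly invariant; p-values agree up to
        # Monte-Carlo error of the permutation null
        np.testing.assert_allclose(t1, t2)
        key = lambda c: (-c.mass, c.pixels)
        c1, c2 = sorted(c1, key=key), sorted(c2, key=key)
        assert [c.pixels for c in c1] == [c.pixels for c in c2]
        for a, b in zip(c1, c2):
            assert a.mass == pytest.approx(b.mass)
            assert a.p_value == pytest.approx(b.p_value, abs=0.07)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            cluster_permutation_test(noise_maps(4, 1), noise_maps(4, 2),
                                     n_permutations=50)


def blob_maps(pixels, n_maps=20, seed=0, effect=1.0, sd=0.05):
    maps = sd * np.random.default_rng(seed).standard_normal((n_maps, *GRID))
    for i, j in pixels:
        maps[:, i, j] += effect
    return maps


class TestWeightSets:
    def test_single_coherent_blob_extracted_exactly(self):
        pix = [(i, j) for i in range(4, 9) for j in range(5, 7)]  # 10 px
        sets = extract_weight_sets(blob_maps(pix), TIME_BIN, CFS)
        assert len(sets) == 1
        assert sets[0].size == 10
        assert set(sets[0].pixels) == set(pix)
        assert sets[0].sign == "positive"

    def test_six_pixel_blob_excluded_by_min_size(self):
        pix = [(i, 5) for i in range(2, 8)]  # 6 px line
        sets = extract_weight_sets(blob_maps(pix), TIME_BIN, CFS)
        assert sets == []

    def test_diagonal_touch_splits_under_4_connectivity(self):
        blob_a = [(i, j) for i in range(1, 5) for j in range(1, 3)]
        blob_b = [(i, j) for i in range(5, 9) for j in range(3, 5)]
        # touch only at corner (4,2)-(5,3)
        maps = blob_maps(blob_a + blob_b, seed=3)
        sets = extract_weight_sets(maps, TIME_BIN, CFS)
        assert len(sets) == 2
        assert {s.size for s in sets} == {8}

    def test_negative_blob_signed_and_annotated(self):
        pix = [(i, j) for i in range(6, 10) for j in range(8, 11)]
        maps = blob_maps(pix, effect=-1.0, seed=4)
        sets = extract_weight_sets(maps, TIME_BIN, CFS)
        assert len(sets) == 1
        s = sets[0]
        assert s.sign == "negative"
        t_idx = np.array([p[0] for p in pix])
        f_idx = np.array([p[1] for p in pix])
        assert s.centroid_ms == pytest.approx(
            (t_idx.mean() + 0.5) * TIME_BIN * 1000)
        assert s.centroid_hz == pytest.approx(CFS[f_idx].mean())
        assert s.extent_ms == pytest.approx(4 * TIME_BIN * 1000)

    def test_pure_noise_yields_no_sets(self):
        sets = extract_weight_sets(noise_maps(20, 9), TIME_BIN, CFS)
        assert sets == []


class TestROI:
    def _sets_and_groups(self):
        pix = [(i, j) for i in range(4, 8) for j in range(4, 7)]
        maps = blob_maps(pix, n_maps=24, seed=6)
        sets = extract_weight_sets(maps, TIME_BIN, CFS)
        return sets, maps[:12], maps[12:]

    def test_report_row_count_matches_sets(self):
        sets, g1, g2 = self._sets_and_groups()
        report = roi_group_test(sets, g1, g2)
        assert len(report) == len(sets)

    def test_identical_groups_not_significant(self):
        sets, g1, _ = self._sets_and_groups()
        report = roi_group_test(sets, g1, g1)
        assert (report["p"] > 0.99).all()  # same data, t = 0

    def test_amplified_group_flagged(self):
        sets, g1, g2 = self._sets_and_groups()
        mask = sets[0].mask(GRID)
        g2 = g2.copy()
        g2[:, mask] *= 1.5
        report = roi_group_test(sets, g1, g2)
        assert report.loc[0, "p"] < 0.01

    def test_empty_set_list_gives_empty_report(self):
        report = roi_group_test([], noise_maps(5, 1), noise_maps(5, 2))
        assert len(report) == 0
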