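"""TFCE, permutation FWE thresholds, local maxima, peak matching."""

from collections import deque

import numpy as np
import pandas as pd
import pytest

from fmriboot.peaks import (
    find_local_maxima,
    local_maxima_mask,
    match_peaks,
    peak_reliability,
    peak_validity,
    permutation_fwe,
    select_top_gold_peaks,
    t_to_z,
    tfce_transform,
)
from fmriboot.synthetic import (
    make_effect_field,
    make_grid_atlas,
    simulate_contrast_maps,
)


def _tfce_bruteforce(stat_map, E=0.5, H=2.0, dh=0.05):
    """Naive TFCE: per-threshold flood fill, no scipy labelling."""
    shape = stat_map.shape
    out = np.zeros(shape)
    neighbors = [(di, dj, dk)
                 for di in (-1, 0, 1) for dj in (-1, 0, 1) for dk in (-1, 0, 1)
                 if (di, dj, dk) != (0, 0, 0)]
    h = dh
    while h <= stat_map.max() + 1e-12:
        supra = stat_map >= h
        seen = np.zeros(shape, bool)
        for start in zip(*np.nonzero(supra)):
            if seen[start]:
                continue
            comp = [start]
            seen[start] = True
            queue = deque([start])
            while queue:
                i, j, k = queue.popleft()
                for di, dj, dk in neighbors:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if (0 <= ni < shape[0] and 0 <= nj < shape[1]
                            and 0 <= nk < shape[2] and supra[ni, nj, nk]
                            and not seen[ni, nj, nk]):
                        seen[ni, nj, nk] = True
                        comp.append((ni, nj, nk))
                        queue.append((ni, nj, nk))
            incr = len(comp) ** E * h**H * dh
            for vox in comp:
                out[vox] += incr
        h += dh
    return out


class TestTfce:
    def test_isolated_voxel_integral(self):
        # extent 1 at every threshold: integral of h^2 over (0,1) -> 1/3
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = 1.0
        v = tfce_transform(m, dh=0.001)
        assert v[2, 2, 2] == pytest.approx(1.0 / 3.0, abs=2e-3)

    def test_scaling_strictly_increases_values(self, rng):
        # default (range-proportional) step keeps the sweep scale-covariant
        m = np.abs(rng.normal(size=(6, 6, 6)))
        a = tfce_transform(m)
        b = tfce_transform(1.5 * m)
        assert np.all(b[a > 0] > a[a > 0])

    def test_matches_bruteforce_on_random_maps(self, rng):
        for _ in range(20):
            m = rng.normal(size=(8, 8, 8))
            ours = tfce_transform(m, dh=0.05)
            ref = _tfce_bruteforce(m, dh=0.05)
            np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_nonpositive_map_is_zero(self):
        assert np.all(tfce_transform(-np.ones((4, 4, 4))) == 0)

    def test_oversized_dh_rejected(self):
        m = np.zeros((4, 4, 4))
        m[1, 1, 1] = 0.5
        with pytest.raises(ValueError):
            tfce_transform(m, dh=1.0)


class TestTToZ:
    def test_quantile_match(self):
        from scipy import stats

        t = np.array([-3.0, -0.5, 0.0, 1.2, 5.0])
        z = t_to_z(t, df=9)
        np.testing.assert_allclose(stats.norm.sf(z), stats.t.sf(t, 9),
                                   rtol=1e-9)

    def test_stable_in_far_tails(self):
        z = t_to_z(np.array([-40.0, 40.0]), df=30)
        assert np.all(np.isfinite(z))
        assert z[0] < -8 and z[1] > 8


class TestPermutationFwe:
    def test_reproducible_and_relabel_invariant(self, rng):
        data = rng.normal(size=(9, 8, 8, 8))
        a = permutation_fwe(data, n_perms=200, seed=5)
        b = permutation_fwe(data, n_perms=200, seed=5)
        assert a.threshold == b.threshold
        # relabeling subjects leaves the sign-flip null unchanged
        c = permutation_fwe(data[::-1], n_perms=200, seed=5)
        assert c.threshold == pytest.approx(a.threshold, rel=0.2)

    def test_exhaustive_enumeration_when_small(self, rng):
        data = rng.normal(size=(7, 6, 6, 6))
        res = permutation_fwe(data, n_perms=200, seed=0)
        assert res.exhaustive and res.n_perms == 128

    def test_monte_carlo_tracks_exhaustive(self, rng):
        data = rng.normal(size=(10, 6, 6, 6)) + 0.3
        exact = permutation_fwe(data, n_perms=1024, seed=0)
        assert exact.exhaustive
        mc = permutation_fwe(data, n_perms=500, seed=1)
        assert not mc.exhaustive
        assert mc.threshold == pytest.approx(exact.threshold, rel=0.25)

    def test_strong_blob_survives(self):
        atlas = make_grid_atlas((10, 10, 10), n_regions=8)
        field = make_effect_field((10, 10, 10), [(5, 5, 5)], 1.5, 6.0)
        hits = 0
        for i in range(10):
            maps = simulate_contrast_maps(atlas, field, 40, seed=100 + i)
            res = permutation_fwe(maps, n_perms=128, seed=i)
            hits += int(res.z_map[5, 5, 5] > 0)
        assert hits == 10

    def test_threshold_is_null_quantile(self, rng):
        data = rng.normal(size=(9, 6, 6, 6))
        res = permutation_fwe(data, alpha=0.05, n_perms=200, seed=2)
        frac_above = np.mean(res.null_max_distribution > res.threshold)
        assert frac_above <= 0.05


class TestLocalMaxima:
    def test_constant_map_empty(self):
        assert len(find_local_maxima(np.ones((5, 5, 5)))) == 0

    def test_single_blob_single_peak(self):
        field = make_effect_field((11, 11, 11), [(5, 5, 5)], 1.0, 6.0)
        table = find_local_maxima(field.d_true, min_height=1e-9,
                                  voxel_size_mm=2.0)
        assert len(table) == 1
        assert tuple(table.iloc[0][["i", "j", "k"]]) == (5, 5, 5)
        assert tuple(table.iloc[0][["x_mm", "y_mm", "z_mm"]]) == (10, 10, 10)

    def test_two_blobs_two_peaks(self):
        field = make_effect_field((16, 16, 16), [(4, 4, 4), (12, 12, 12)],
                                  [1.0, 0.8], 4.0, voxel_size_mm=2.0)
        table = find_local_maxima(field.d_true, min_height=1e-9)
        assert len(table) == 2

    def test_plateau_has_no_peaks(self):
        m = np.zeros((6, 6, 6))
        m[2:4, 2:4, 2:4] = 1.0  # ties: strict inequality excludes all
        assert not local_maxima_mask(m)[2:4, 2:4, 2:4].any()

    def test_edge_voxel_can_be_peak(self):
        m = np.zeros((5, 5, 5))
        m[0, 0, 0] = 2.0
        assert local_maxima_mask(m)[0, 0, 0]


class TestGoldPeakSelection:
    def test_one_peak_per_region_and_top_k(self):
        atlas = make_grid_atlas((12, 12, 12), n_regions=8)
        # two blobs inside one octant: only the taller survives dedup
        field = make_effect_field(
            (12, 12, 12), [(2, 2, 2), (2, 2, 5), (9, 9, 9)],
            [1.0, 0.8, 0.6], 2.0)
        peaks, short = select_top_gold_peaks(field.d_true, atlas, k=10)
        assert short  # fewer than 10 qualifying peaks exist
        regions = peaks["region_id"].tolist()
        assert len(regions) == len(set(regions)) == 2
        assert peaks["height"].iloc[0] == pytest.approx(1.0, abs=0.01)

    def test_ten_blob_field_recovers_all_centers(self):
        atlas = make_grid_atlas((20, 20, 10), n_regions=10)
        centers = [tuple(v.mean(axis=0).round().astype(int))
                   for v in (atlas.region_voxels(r) for r in range(1, 11))]
        field = make_effect_field((20, 20, 10), centers, 1.0, 3.0)
        peaks, short = select_top_gold_peaks(field.d_true, atlas, k=10)
        assert not short and len(peaks) == 10
        assert set(peaks["region_id"]) == set(range(1, 11))


class TestPeakValidityReliability:
    def _table(self, coords_mm):
        coords = np.asarray(coords_mm, dtype=float)
        n = len(coords)
        return pd.DataFrame({
            "i": np.zeros(n, int), "j": np.zeros(n, int),
            "k": np.zeros(n, int),
            "x_mm": coords[:, 0], "y_mm": coords[:, 1], "z_mm": coords[:, 2],
            "height": np.ones(n), "region_id": np.arange(1, n + 1),
            "gold_d": np.ones(n),
        })

    def test_identical_peaks_full_hit(self):
        gold = self._table([(10, 10, 10)])
        validity = peak_validity([gold, gold], gold)
        assert np.all(validity["proportion"] == 1.0)

    def test_proportions_nondecreasing_in_radius(self, rng):
        gold = self._table([(10, 10, 10), (30, 30, 30)])
        studies = [self._table(rng.uniform(0, 40, (3, 3))) for _ in range(10)]
        validity = peak_validity(studies, gold)
        for _, grp in validity.groupby("gold_peak"):
            props = grp.sort_values("radius_mm")["proportion"].to_numpy()
            assert np.all(np.diff(props) >= 0)

    def test_5mm_displacement_straddles_radii(self):
        gold = self._table([(10, 10, 10)])
        study = self._table([(15, 10, 10)])  # exactly 5 mm away
        validity = peak_validity([study], gold)
        by_radius = validity.set_index("radius_mm")["proportion"]
        assert by_radius[4.0] == 0.0 and by_radius[8.0] == 1.0

    def test_empty_studies_stay_in_denominator(self):
        gold = self._table([(10, 10, 10)])
        empty = self._table(np.empty((0, 3)))
        validity = peak_validity([gold, empty], gold)
        assert np.all(validity["proportion"] == 0.5)
        assert np.all(validity["n_empty_studies"] == 1)

    def test_pairwise_distance_345(self):
        gold = self._table([(0, 0, 0)])
        s1 = self._table([(0, 0, 0)])
        s2 = self._table([(3, 4, 0)])
        rel = peak_reliability([s1, s2], gold)
        assert rel["mean_distance_mm"].iloc[0] == pytest.approx(5.0)

    def test_identical_matches_zero_distance(self):
        gold = self._table([(10, 10, 10), (20, 20, 20)])
        rel = peak_reliability([gold, gold, gold], gold)
        np.testing.assert_allclose(rel["p90_distance_mm"], 0.0)

    def test_nearest_match(self):
        gold = self._table([(10, 10, 10)])
        study = self._table([(11, 10, 10), (30, 30, 30)])
        matched = match_peaks(study, gold)
        np.testing.assert_allclose(matched[0], [11, 10, 10])
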