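"""Mask perturbation, Lin's CCC, robustness filtering and feature clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from radhet.errors import InsufficientDataError
from radhet.feature_selection import cluster_features, select_representatives
from radhet.robustness import (
    ball_element,
    concordance_ccc,
    perturb_mask,
    robustness_filter,
)

from oracles import ccc_oracle


def _table(values: dict, n=None):
    n = n or len(next(iter(values.values())))
    return pd.DataFrame({
        "patient_id": "P0",
        "lesion_id": [f"L{i}" for i in range(n)],
        "site_label": "lung",
        **values,
    })


class TestPerturbMask:
    def test_unit_ball_is_seven_voxel_cross(self):
        elem = ball_element(1.0, (1.0, 1.0, 1.0))
        assert elem.shape == (3, 3, 3)
        assert elem.sum() == 7  # center + 6 face neighbors

    def test_dilate_single_voxel_gives_cross(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        out, vanished = perturb_mask(mask, 1.0, "dilate")
        assert not vanished
        assert out.sum() == 7

    def test_erode_single_voxel_vanishes_flagged(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        out, vanished = perturb_mask(mask, 1.0, "erode")
        assert vanished
        assert not out.any()

    def test_closing_contains_original(self):
        rng = np.random.default_rng(0)
        mask = np.zeros((14, 14, 14), bool)
        zz, yy, xx = np.indices(mask.shape)
        mask[(zz - 7) ** 2 + (yy - 7) ** 2 + (xx - 7) ** 2 <= 16] = True
        dilated, _ = perturb_mask(mask, 1.0, "dilate")
        closed, _ = perturb_mask(dilated, 1.0, "erode")
        assert np.all(closed[mask])


class TestCCC:
    def test_perfect_concordance(self):
        x = np.array([1.0, 5.0, 2.0, 8.0])
        assert concordance_ccc(x, x) == pytest.approx(1.0)

    def test_closed_form_slope_two(self):
        assert concordance_ccc([1, 2, 3], [2, 4, 6]) == pytest.approx(8 / 22)

    def test_reversed_is_discordant(self):
        val = concordance_ccc([1, 2, 3], [3, 2, 1])
        assert val < 0
        assert val == pytest.approx(ccc_oracle([1, 2, 3], [3, 2, 1]))

    def test_matches_oracle_on_random_pairs(self, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = 0.5 * x + rng.normal(size=12)
            assert concordance_ccc(x, y) == pytest.approx(ccc_oracle(x, y))

    def test_symmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert concordance_ccc(x, y) == pytest.approx(concordance_ccc(y, x))

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_common_affine_invariance(self, a, b):
        x = np.array([1.0, 4.0, 2.0, 9.0, 3.0])
        y = np.array([2.0, 3.0, 2.5, 8.0, 4.0])
        assert concordance_ccc(a * x + b, a * y + b) == pytest.approx(
            concordance_ccc(x, y), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            concordance_ccc([1, 2], [1, 2, 3])


class TestRobustnessFilter:
    def test_identical_tables_kept_with_ccc_one(self):
        t = _table({"f1": [1.0, 2, 3, 4, 5], "f2": [5.0, 1, 4, 2, 3]})
        report = robustness_filter(t, t.copy(), t.copy())
        assert report.table["kept"].all()
        assert np.allclose(report.table[["ccc_eroded", "ccc_dilated"]], 1.0)

    def test_noise_feature_dropped_reliably(self):
        """A feature replaced by fresh independent noise at n=50 lesions must
        be dropped (CCC >= 0.8 under the null is vanishingly rare)."""
        n, trials, kept = 50, 200, 0
        rng = np.random.default_rng(8)
        for _ in range(trials):
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            if concordance_ccc(x, noise) >= 0.8:
                kept += 1
        assert kept / trials <= 0.01

    def test_filter_drops_noise_keeps_stable(self, rng):
        n = 50
        stable = rng.normal(size=n)
        t_orig = _table({"stable": stable, "noisy": rng.normal(size=n)})
        t_eroded = t_orig.copy()
        t_eroded["stable"] = stable + rng.normal(scale=0.01, size=n)
        t_eroded["noisy"] = rng.normal(size=n)  # fresh independent noise
        t_dilated = t_orig.copy()
        report = robustness_filter(t_orig, t_eroded, t_dilated)
        verdict = report.table.set_index("feature")["kept"]
        assert verdict["stable"]
        assert not verdict["noisy"]

    def test_monotone_in_threshold(self, small_cohort_tables):
        orig, eroded, dilated = small_cohort_tables
        kept_sets = []
        for thr in (0.5, 0.8, 0.95):
            report = robustness_filter(orig, eroded, dilated, threshold=thr)
            kept_sets.append(set(report.kept_features))
        assert kept_sets[2] <= kept_sets[1] <= kept_sets[0]

    def test_vanished_lesions_excluded_and_counted(self):
        t = _table({"f1": [1.0, 2, 3, 4, 5]})
        eroded = t.iloc[:4].copy()  # lesion L4 vanished under erosion
        report = robustness_filter(t, eroded, t.copy())
        assert report.excluded_lesions == ["L4"]

    def test_too_few_lesions(self):
        t = _table({"f1": [1.0, 2]})
        with pytest.raises(InsufficientDataError):
            robustness_filter(t, t.copy(), t.copy())


class TestClustering:
    def test_collinear_features_cluster_together(self, rng):
        x = rng.normal(size=20)
        t = _table({"a": x, "b": 3 * x + 1, "c": rng.normal(size=20),
                    "d": rng.normal(size=20)})
        clustering = cluster_features(t, k=3)
        assert clustering.assignment["a"] == clustering.assignment["b"]

    def test_k_equals_n_features_gives_singletons(self, rng):
        t = _table({f"f{i}": rng.normal(size=15) for i in range(5)})
        clustering = cluster_features(t, k=5)
        assert clustering.n_clusters == 5
        assert sorted(clustering.assignment.values()) == list(range(5))

    def test_constant_feature_becomes_singleton(self, rng):
        t = _table({"a": rng.normal(size=10), "b": rng.normal(size=10),
                    "flat": np.zeros(10)})
        clustering = cluster_features(t, k=2)
        assert clustering.constant_features == ["flat"]
        others = {clustering.assignment["a"], clustering.assignment["b"]}
        assert clustering.assignment["flat"] not in others

    def test_planted_partition_recovered(self):
        """Planted 8-factor structure is recovered exactly (ARI = 1) in at
        least 95% of seeds."""
        from sklearn.metrics import adjusted_rand_score

        from radhet.synthetic import generate_clustered_feature_table

        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            table, labels = generate_clustered_feature_table(
                rng=np.random.default_rng(seed))
            clustering = cluster_features(table, k=8)
            feats = sorted(labels)
            truth = [labels[f] for f in feats]
            found = [clustering.assignment[f] for f in feats]
            if adjusted_rand_score(truth, found) == 1.0:
                hits += 1
        assert hits >= 95


class TestRepresentatives:
    def _clustering(self, groups):
        from radhet.feature_selection import FeatureClustering

        assignment = {f: c for c, members in enumerate(groups) for f in members}
        return FeatureClustering(n_clusters=len(groups), assignment=assignment)

    def test_preference_beats_lexicographic(self):
        clustering = self._clustering([["shape_MeshVolume", "shape_VoxelVolume"]])
        reps = select_representatives(clustering, ["shape_VoxelVolume"])
        assert reps == ["shape_VoxelVolume"]

    def test_lexicographic_fallback(self):
        clustering = self._clustering([["B_feat", "A_feat"]])
        assert select_representatives(clustering) == ["A_feat"]

    def test_one_representative_per_cluster(self, rng):
        t = _table({f"f{i}": rng.normal(size=30) for i in range(10)})
        clustering = cluster_features(t, k=8)
        assert len(select_representatives(clustering)) == clustering.n_clusters
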