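"""Gaze features, selection scores, clustering, scan-path comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeblind.analytics import (auc_change, change_proximity_profile,
                                 cluster_fixations, compute_features,
                                 cross_validated_auc, edit_distance,
                                 edit_distance_normalized, encode_scanpath,
                                 fisher_score, fixation_density, fixation_map,
                                 information_gain, latency_metrics,
                                 map_correlation, remove_outliers,
                                 saccade_matrix_domains, saccade_matrix_topk,
                                 uniform_reference)
from gazeblind.synthetic import GazeRecord


def _record(points, durations=None, onsets=None, outcome="miss"):
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    durations = np.full(n, 200.0) if durations is None else np.asarray(durations)
    onsets = np.arange(n) * 250.0 if onsets is None else np.asarray(onsets)
    fix = pd.DataFrame({"x_px": points[:, 0], "y_px": points[:, 1],
                        "duration_ms": durations, "onset_ms": onsets})
    sac = pd.DataFrame({"amplitude_deg": np.ones(max(n - 1, 0)),
                        "duration_ms": np.full(max(n - 1, 0), 30.0),
                        "peak_speed_deg_s": np.full(max(n - 1, 0), 150.0)})
    return GazeRecord(subject_id="s", trial_id="t", image_id="i",
                      fixations=fix, saccades=sac, outcome=outcome)


class TestOutliers:
    def test_clean_sample_unchanged(self):
        assert remove_outliers([1, 2, 3, 4, 5]).tolist() == [1, 2, 3, 4, 5]

    def test_extreme_value_removed(self):
        assert remove_outliers([1, 2, 3, 4, 100]).tolist() == [1, 2, 3, 4]

    def test_constant_sample_unchanged(self):
        assert remove_outliers([7.0] * 6).tolist() == [7.0] * 6

    def test_short_sample_passes_through_with_warning(self):
        with pytest.warns(UserWarning):
            out = remove_outliers([1, 100])
        assert out.tolist() == [1, 100]


class TestFisherScore:
    def test_hand_arithmetic(self):
        # classes {1,2,3} vs {4,5,6}: grand mean 3.5, class means 2 and 5,
        # numerator 2*(1.5^2)=4.5, unbiased within-class variances 1+1=2
        score = fisher_score([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert score == pytest.approx(2.25)

    def test_zero_when_class_means_equal_grand_mean(self):
        score = fisher_score([1, 3, 1, 3], [0, 0, 1, 1])
        assert score == 0.0

    def test_grows_as_jitter_shrinks(self, rng):
        scores = []
        for jitter in (1.0, 0.3, 0.1):
            a = rng.normal(0, jitter, 200)
            b = rng.normal(1, jitter, 200)
            scores.append(fisher_score(np.r_[a, b],
                                       np.r_[np.zeros(200), np.ones(200)]))
        assert scores[0] < scores[1] < scores[2]

    def test_zero_variance_separated_classes_signalled(self):
        assert fisher_score([0, 0, 1, 1], [0, 0, 1, 1]) == np.inf


class TestInformationGain:
    def test_perfect_balanced_split_is_one_bit(self):
        assert information_gain([1, 2, 3, 4], [0, 0, 1, 1]) \
            == pytest.approx(1.0)

    def test_constant_feature_gains_nothing(self):
        assert information_gain([2, 2, 2, 2], [0, 1, 0, 1]) == 0.0

    def test_uninformative_feature_near_zero(self, rng):
        x = rng.normal(size=400)
        y = rng.integers(0, 2, 400)
        assert information_gain(x, y) < 0.05

    def test_exhaustive_split_oracle(self, rng):
        """Best split equals a brute-force scan over all midpoints."""
        x = rng.normal(size=30)
        y = rng.integers(0, 2, 30)

        def entropy(lbl):
            if lbl.size == 0:
                return 0.0
            p = np.bincount(lbl, minlength=2) / lbl.size
            p = p[p > 0]
            return -(p * np.log2(p)).sum()

        xs = np.unique(x)
        best = min(
            ((y[x > d].size * entropy(y[x > d])
              + y[x < d].size * entropy(y[x < d])) / y.size)
            for d in (xs[:-1] + xs[1:]) / 2)
        assert information_gain(x, y) == pytest.approx(entropy(y) - best)


class TestAUCChange:
    def _two_class(self, rng, n=120):
        y = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        informative = y + rng.normal(0, 0.6, n)
        noise = rng.normal(size=(n, 2))
        return np.column_stack([informative, noise]), y

    def test_random_scores_auc_near_half(self, rng):
        x = rng.normal(size=(300, 3))
        y = rng.integers(0, 2, 300)
        auc = cross_validated_auc(x, y, seed=0)
        assert abs(auc - 0.5) < 3 * np.sqrt(0.25 / 300) * 3

    def test_removing_sole_informative_feature_hurts(self, rng):
        x, y = self._two_class(rng)
        assert auc_change(x, y, 0, seed=1) > 0.1

    def test_removing_duplicate_feature_is_harmless(self, rng):
        x, y = self._two_class(rng)
        x_dup = np.column_stack([x, x[:, 0]])
        assert abs(auc_change(x_dup, y, 3, seed=1)) < 0.05

    def test_single_feature_table_rejected(self, rng):
        with pytest.raises(ValueError):
            auc_change(rng.normal(size=(20, 1)), rng.integers(0, 2, 20), 0)


class TestFixationDensity:
    def test_uniform_lattice_has_unit_density(self):
        pts = uniform_reference(25, (500, 400))
        rho = fixation_density(pts, r=150.0, image_size=(500, 400))
        assert np.allclose(rho, 1.0)

    def test_isolated_point_is_sparser_than_cluster(self, rng):
        cluster = rng.normal(loc=(100, 100), scale=5, size=(19, 2))
        pts = np.vstack([cluster, [[400, 300]]])
        rho = fixation_density(pts, r=40.0, image_size=(500, 400))
        assert rho[-1] < 1.0
        assert rho[:-1].mean() > 1.0

    def test_scale_invariance(self, rng):
        pts = rng.uniform(0, 200, size=(30, 2))
        rho1 = fixation_density(pts, r=30.0, image_size=(200, 200))
        rho2 = fixation_density(pts * 3, r=90.0, image_size=(600, 600))
        assert np.allclose(rho1, rho2)

    def test_no_neighbours_means_zero_density(self):
        pts = np.array([[0.0, 0.0], [500.0, 400.0], [10.0, 0.0]])
        rho = fixation_density(pts, r=20.0, image_size=(600, 500))
        assert rho[1] == 0.0


class TestClustering:
    def test_coincident_points_collapse_to_one_cluster(self):
        pts = np.tile([[50.0, 50.0]], (10, 1))
        model = cluster_fixations(pts, image_size=(200, 200))
        assert model.k == 1

    def test_two_separated_blobs_found(self, rng):
        a = rng.normal((60, 60), 4, (40, 2))
        b = rng.normal((340, 240), 4, (40, 2))
        model = cluster_fixations(np.vstack([a, b]), k_max=6,
                                  image_size=(400, 300), seed=0)
        assert model.k == 2
        got = np.sort(model.centers[:, 0])
        assert got[0] == pytest.approx(60, abs=5)
        assert got[1] == pytest.approx(340, abs=5)

    def test_deterministic_given_seed(self, rng):
        pts = rng.uniform(0, 300, (60, 2))
        m1 = cluster_fixations(pts, image_size=(300, 300), k_max=8, seed=3)
        m2 = cluster_fixations(pts, image_size=(300, 300), k_max=8, seed=3)
        assert m1.k == m2.k and np.allclose(m1.centers, m2.centers)


class TestScanStrings:
    def test_nearest_center_assignment_matches_bruteforce(self, rng):
        from gazeblind.analytics import ClusterModel
        centers = rng.uniform(0, 300, (5, 2))
        model = ClusterModel(centers=centers, sparse_points=np.array([]),
                             bic_profile=pd.DataFrame(), k=5)
        pts = rng.uniform(0, 300, (40, 2))
        labels = model.assign(pts)
        for p, lab in zip(pts, labels):
            dists = np.hypot(*(centers - p).T)
            assert lab == dists.argmin()

    def test_alternating_fixations_encode_abab(self):
        from gazeblind.analytics import ClusterModel
        centers = np.array([[10.0, 10.0], [200.0, 200.0]])
        model = ClusterModel(centers=centers, sparse_points=np.array([]),
                             bic_profile=pd.DataFrame(), k=2)
        rec = _record([[12, 9], [198, 201], [11, 11], [202, 199]])
        assert encode_scanpath(rec, model) == "ABAB"

    def test_single_fixation_single_char(self):
        from gazeblind.analytics import ClusterModel
        model = ClusterModel(centers=np.array([[5.0, 5.0]]),
                             sparse_points=np.array([]),
                             bic_profile=pd.DataFrame(), k=1)
        assert len(encode_scanpath(_record([[5, 5]]), model)) == 1


def brute_force_edit_distance(s1, s2):
    """Exhaustive recursion over edit scripts (lengths <= 6)."""
    if not s1:
        return len(s2)
    if not s2:
        return len(s1)
    sub = brute_force_edit_distance(s1[1:], s2[1:]) + (s1[0] != s2[0])
    ins = brute_force_edit_distance(s1, s2[1:]) + 1
    dele = brute_force_edit_distance(s1[1:], s2) + 1
    return min(sub, ins, dele)


class TestEditDistance:
    def test_textbook_example(self):
        assert edit_distance("kitten", "sitting") == 3
        assert edit_distance_normalized("kitten", "sitting") \
            == pytest.approx(3 / 7)

    def test_identity_and_empty(self):
        assert edit_distance_normalized("ABC", "ABC") == 0.0
        assert edit_distance_normalized("ABC", "") == 1.0
        assert edit_distance_normalized("", "") == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(s1=st.text(alphabet="AB", max_size=6),
           s2=st.text(alphabet="AB", max_size=6))
    def test_dp_equals_exhaustive_search(self, s1, s2):
        assert edit_distance(s1, s2) == brute_force_edit_distance(s1, s2)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(s1=st.text(alphabet="ABC", max_size=8),
           s2=st.text(alphabet="ABC", max_size=8),
           s3=st.text(alphabet="ABC", max_size=8))
    def test_metric_axioms(self, s1, s2, s3):
        d12 = edit_distance(s1, s2)
        assert d12 == edit_distance(s2, s1)
        assert (d12 == 0) == (s1 == s2)
        assert d12 <= edit_distance(s1, s3) + edit_distance(s3, s2)

    def test_matches_edlib_on_random_strings(self, rng):
        import edlib
        letters = np.array(list("ABCDE"))
        for _ in range(25):
            s1 = "".join(rng.choice(letters, rng.integers(1, 30)))
            s2 = "".join(rng.choice(letters, rng.integers(1, 30)))
            assert edit_distance(s1, s2) \
                == edlib.align(s1, s2, task="distance")["editDistance"]


class TestSaccadeMatrices:
    def test_single_domain_path_gives_unit_diagonal(self):
        paths = [[0, 0, 0, 0]]
        durs = [[100.0] * 4]
        m = saccade_matrix_domains(paths, durs, n_clusters=1)
        assert m[0, 0] == 1.0

    def test_columns_normalise(self, rng):
        paths = [rng.integers(0, 8, 50).tolist() for _ in range(4)]
        durs = [(rng.uniform(100, 400, 50)).tolist() for _ in range(4)]
        m = saccade_matrix_domains(paths, durs, n_clusters=8)
        sums = m.sum(axis=0)
        assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))

    def test_two_domain_alternation(self):
        # cluster 0 carries most duration -> domain 0; cluster 1 -> later
        paths = [[0, 1, 0, 1, 0, 1]]
        durs = [[400, 100, 400, 100, 400, 100]]
        m = saccade_matrix_domains(paths, durs, n_clusters=2)
        assert m[1, 0] == 1.0 and m[0, 1] == 1.0

    def test_topk_single_cluster_matrix(self):
        m = saccade_matrix_topk([[0, 0, 0]], [[100.0] * 3], 1, k=1)
        assert m.shape == (1, 1) and m[0, 0] == 1.0

    def test_topk_excludes_other_clusters(self):
        paths = [[0, 5, 1, 0, 1]]
        durs = [[300, 10, 250, 300, 250]]
        m = saccade_matrix_topk(paths, durs, n_clusters=6, k=2)
        # transitions touching cluster 5 were dropped
        assert m.sum() == pytest.approx(m.shape[1] - (m.sum(0) == 0).sum())

    def test_split_half_matrices_correlate(self):
        """Two halves of a long stationary random walk agree."""
        rng = np.random.default_rng(0)
        probs = np.array([0.3, 0.25, 0.2, 0.15, 0.07, 0.03])
        path = rng.choice(6, 4000, p=probs).tolist()
        durs = [100.0] * 4000
        m1 = saccade_matrix_topk([path[:2000]], [durs[:2000]], 6, k=6)
        m2 = saccade_matrix_topk([path[2000:]], [durs[2000:]], 6, k=6)
        r = np.corrcoef(m1.ravel(), m2.ravel())[0, 1]
        assert r > 0.9


class TestMapsAndProximity:
    def test_fixation_map_conserves_counts(self, rng):
        pts = rng.uniform(0, (800, 600), size=(57, 2))
        rec = _record(pts)
        m = fixation_map(rec, (800, 600), tiles=(13, 18))
        assert m.shape == (13, 18)
        assert m.sum() == 57

    def test_self_correlation_is_one(self, rng):
        m = rng.random((13, 18))
        assert map_correlation(m, m) == pytest.approx(1.0)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            map_correlation(np.ones((4, 4)), np.random.rand(4, 4))

    def test_independent_maps_uncorrelated(self):
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(30):
            a = rng.poisson(3.0, (13, 18))
            b = rng.poisson(3.0, (13, 18))
            rs.append(map_correlation(a, b))
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs)) + 0.02

    def test_annulus_binning_matches_distances(self):
        pts = [[300, 300], [330, 300], [300, 240], [460, 300], [300, 90]]
        rec = _record(pts, durations=[100, 200, 300, 400, 500])
        counts, durs = change_proximity_profile(rec, (300, 300), bin_px=50.0)
        # distances: 0, 30, 60, 160, 210 -> annuli 0,0,1,3,4
        assert counts.tolist() == [2, 1, 0, 1, 1]
        assert durs.tolist() == [300.0, 300.0, 0.0, 400.0, 500.0]
        assert counts.sum() == 5

    def test_all_fixations_at_center_fill_first_annulus(self):
        rec = _record([[100, 100]] * 5)
        counts, _ = change_proximity_profile(rec, (100, 100))
        assert counts[0] == 5 and counts.sum() == 5

    def test_latency_metrics(self):
        rec = _record([[0, 0], [50, 50], [200, 200]],
                      onsets=[0.0, 1000.0, 2500.0], outcome="hit")
        t_first, t_detect = latency_metrics(rec, (52, 52), 10.0)
        assert t_first == 1.0
        assert t_detect == 2.5
        t_none, _ = latency_metrics(rec, (400, 400), 5.0)
        assert t_none is None


class TestFeatureTable:
    def test_eight_features_present(self):
        from gazeblind.synthetic import SyntheticGazeSpec, make_gaze_logs
        recs = make_gaze_logs(SyntheticGazeSpec(n_subjects=(2, 2),
                                                n_trials=2, seed=0))
        table = compute_features(recs)
        for col in ["mu_fd", "var_fd", "mu_sa", "var_sa",
                    "mu_sd", "var_sd", "mu_sps", "var_sps"]:
            assert table[col].notna().all()
        assert len(table) == 8

    def test_final_dwell_stripped_from_hits(self):
        pts = [[10, 10], [20, 20], [100, 100]]
        rec = _record(pts, durations=[200.0, 200.0, 3500.0], outcome="hit")
        table = compute_features([rec], strip_hits=True)
        assert table["mu_fd"].iloc[0] == pytest.approx(200.0)
        table2 = compute_features([rec], strip_hits=False)
        assert table2["mu_fd"].iloc[0] > 200.0
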