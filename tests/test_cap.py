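"""CAP core: frame matrix, exemplars, k-means, model selection, ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import capdyn as cd
from capdyn.cap import (
    CapClustering,
    build_frame_matrix,
    fit_cap_model,
    fit_kmeans,
    order_caps,
    select_exemplars,
    select_k,
    zscore_map,
)
from capdyn.types import ValidationError
from conftest import make_run_with_variances


def brute_force_kmeans(x, k):
    """Minimal within-cluster SSE over all set partitions into <= k
    nonempty clusters (global k-means optimum)."""
    n = x.shape[0]
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        labels = np.asarray(assignment)
        sse = 0.0
        for c in np.unique(labels):
            pts = x[labels == c]
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestBuildFrameMatrix:
    def test_stacking_and_row_standardization(self, rng):
        runs = [
            cd.BoldRun(rng.standard_normal((500, 40)), 3.0, f"s{i}")
            for i in range(3)
        ]
        fm = build_frame_matrix(runs)
        assert fm.frames.shape == (120, 500)
        np.testing.assert_allclose(fm.frames.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(fm.frames.std(axis=1, ddof=1), 1.0, atol=1e-10)
        assert fm.frame_index["subject_id"].tolist() == (
            ["s0"] * 40 + ["s1"] * 40 + ["s2"] * 40
        )
        assert fm.frame_index["frame"].iloc[0] == 1  # 1-based

    def test_single_frame_hand_zscore(self):
        # two identical frames of the voxel vector (1, 2, 3)
        run = cd.BoldRun(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]), 3.0, "s")
        fm = build_frame_matrix([run])
        np.testing.assert_allclose(fm.frames, [[-1.0, 0.0, 1.0]] * 2, atol=1e-12)

    def test_constant_frame_error_names_subject_and_frame(self, rng):
        data = rng.standard_normal((20, 5))
        data[:, 2] = 7.0
        with pytest.raises(ValidationError, match=r"sX.*frame 3"):
            build_frame_matrix([cd.BoldRun(data, 3.0, "sX")])

    def test_mismatched_voxel_counts_rejected(self, rng):
        runs = [
            cd.BoldRun(rng.standard_normal((20, 5)), 3.0, "a"),
            cd.BoldRun(rng.standard_normal((21, 5)), 3.0, "b"),
        ]
        with pytest.raises(ValidationError, match="voxels"):
            build_frame_matrix(runs)

    def test_mask_restricts_voxels(self, rng):
        run = cd.BoldRun(rng.standard_normal((30, 6)), 3.0, "a")
        mask = np.zeros(30, dtype=bool)
        mask[:14] = True
        fm = build_frame_matrix([run], mask=mask)
        assert fm.n_voxels == 14


class TestSelectExemplars:
    def test_interior_local_maxima_by_definition(self):
        run = make_run_with_variances([1, 3, 2, 5, 4])
        ex = select_exemplars(run, min_n=1, max_n=15)
        assert ex.frame_numbers.tolist() == [2, 4]
        assert not ex.is_padding.any()

    def test_monotone_series_pads_with_highest_variance_frame(self):
        run = make_run_with_variances([1, 2, 3, 4, 5])
        ex = select_exemplars(run, min_n=1, max_n=15)
        assert ex.frame_numbers.tolist() == [5]
        assert ex.is_padding.tolist() == [True]

    def test_excess_maxima_keep_largest_by_sort_and_slice(self):
        # 20 interior maxima via alternating series with distinct peaks
        rng = np.random.default_rng(1)
        peaks = rng.permutation(np.arange(10.0, 30.0))  # 20 distinct peaks
        v = [1.0]
        for pk in peaks:
            v += [pk, 1.0]
        run = make_run_with_variances(v)
        ex = select_exemplars(run, min_n=1, max_n=15)
        assert ex.count == 15
        expected_peaks = np.sort(peaks)[-15:]
        got = np.asarray(v)[ex.frame_numbers - 1]
        np.testing.assert_allclose(np.sort(got), expected_peaks)

    def test_count_bound_on_realistic_runs(self, small_cohort):
        # 10-15 exemplars whenever T >= 10
        for run in small_cohort.runs:
            ex = select_exemplars(run)
            assert 10 <= ex.count <= 15

    def test_too_short_run_rejected(self):
        with pytest.raises(ValidationError):
            select_exemplars(make_run_with_variances([1, 2]))


class TestFitKmeans:
    def test_k1_closed_form(self, rng):
        x = rng.standard_normal((12, 4))
        c, labels, inertia = fit_kmeans(x, 1, n_restarts=1, seed=0)
        np.testing.assert_allclose(c[0], x.mean(axis=0), atol=1e-12)
        assert np.all(labels == 0)
        assert inertia == pytest.approx(((x - x.mean(axis=0)) ** 2).sum())

    def test_two_planted_groups_recovered_exactly(self, rng):
        a = rng.standard_normal((5, 6)) * 0.1
        b = rng.standard_normal((5, 6)) * 0.1 + 10.0
        x = np.vstack([a, b])
        c, labels, inertia = fit_kmeans(x, 2, n_restarts=10, seed=0)
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]
        means = {labels[0]: a.mean(axis=0), labels[5]: b.mean(axis=0)}
        for cid, mean in means.items():
            np.testing.assert_allclose(c[cid], mean, atol=1e-10)
        assert inertia == pytest.approx(brute_force_kmeans(x, 2))

    def test_matches_exhaustive_partition_optimum(self, rng):
        # small instances: returned inertia equals the global optimum
        for n, k, seed in [(6, 3, 0), (7, 2, 1), (6, 2, 2)]:
            x = np.random.default_rng(seed).standard_normal((n, 3))
            _, _, inertia = fit_kmeans(x, k, n_restarts=50, seed=0)
            assert inertia == pytest.approx(brute_force_kmeans(x, k), rel=1e-9)

    def test_validation_errors(self, rng):
        x = rng.standard_normal((4, 2))
        with pytest.raises(ValidationError):
            fit_kmeans(x, 0)
        with pytest.raises(ValidationError):
            fit_kmeans(x, 5)

    def test_explicit_init_runs_single_pass(self, rng):
        x = rng.standard_normal((20, 3))
        init = x[:2].copy()
        c, labels, inertia = fit_kmeans(x, 2, seed=0, init_centroids=init)
        # centroids are exact member means
        for cid in range(2):
            np.testing.assert_allclose(c[cid], x[labels == cid].mean(axis=0), atol=1e-8)


@pytest.fixture(scope="module")
def fitted_model(small_cohort):
    fm = build_frame_matrix(small_cohort.runs)
    exemplars = [select_exemplars(r) for r in small_cohort.runs]
    model = fit_cap_model(fm, exemplars, k=4, n_restarts=20, seed=0)
    nc = [r.subject_id for r in small_cohort.runs if r.subject_id.startswith("NC")]
    return order_caps(model, nc)


class TestFitCapModel:
    def test_recovers_templates_up_to_bijection(self, small_cohort, fitted_model):
        # Hungarian matching of centroids to generator templates: all
        # matched correlations high and the matching is a bijection
        from scipy.optimize import linear_sum_assignment

        templates = small_cohort.config.templates
        z = fitted_model.zmaps_
        r = np.corrcoef(np.vstack([z, templates]))[:4, 4:]
        rows, cols = linear_sum_assignment(-r)
        assert len(set(cols)) == 4
        assert np.all(r[rows, cols] > 0.95)

    def test_zero_noise_assignments_match_ground_truth(self):
        cfg = cd.default_cohort_config(
            3, n_per_group=2, n_voxels=200, n_frames=50, k_true=4, noise_sd=0.0
        )
        cohort = cd.generate_cohort(cfg)
        fm = build_frame_matrix(cohort.runs)
        ex = [select_exemplars(r) for r in cohort.runs]
        model = fit_cap_model(fm, ex, k=4, n_restarts=20, seed=1)
        truth = np.concatenate([s.labels for s in cohort.ground_truth_sequences])
        assert adjusted_rand_score(truth, model.labels_) == pytest.approx(1.0)

    def test_deterministic_given_seed(self, small_cohort):
        fm = build_frame_matrix(small_cohort.runs)
        ex = [select_exemplars(r) for r in small_cohort.runs]
        a = fit_cap_model(fm, ex, k=3, n_restarts=5, seed=7)
        b = fit_cap_model(fm, ex, k=3, n_restarts=5, seed=7)
        assert np.array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.centroids_, b.centroids_)

    def test_centroids_are_member_means(self, fitted_model, small_cohort):
        fm = build_frame_matrix(small_cohort.runs)
        for cap in range(1, 5):
            members = fm.frames[fitted_model.labels_ == cap]
            np.testing.assert_allclose(
                fitted_model.centroids_[cap - 1], members.mean(axis=0), atol=1e-8
            )

    def test_every_frame_assigned_once(self, fitted_model, small_cohort):
        total = sum(r.n_frames for r in small_cohort.runs)
        assert fitted_model.labels_.size == total
        counts = np.bincount(fitted_model.labels_ - 1, minlength=4)
        assert counts.sum() == total

    def test_seeded_stage2_beats_random_inits(self, small_cohort, fitted_model):
        fm = build_frame_matrix(small_cohort.runs)
        rng = np.random.default_rng(3)
        for _ in range(3):
            init = fm.frames[rng.choice(fm.frames.shape[0], 4, replace=False)]
            _, _, inertia = fit_kmeans(fm.frames, 4, seed=0, init_centroids=init)
            assert fitted_model.inertia_ <= inertia + 1e-6

    def test_k_exceeding_exemplars_rejected(self, small_cohort):
        fm = build_frame_matrix(small_cohort.runs[:1])
        ex = [select_exemplars(small_cohort.runs[0])]
        with pytest.raises(ValidationError, match="exceeds"):
            fit_cap_model(fm, ex, k=16, n_restarts=2, seed=0)

    def test_sklearn_get_set_params_roundtrip(self):
        est = CapClustering(k=5, n_restarts=7, random_state=3)
        from sklearn.base import clone

        assert clone(est).get_params() == est.get_params()


class TestSelectK:
    def test_two_planted_clusters_with_hand_silhouette(self, rng):
        a = rng.standard_normal((8, 4)) * 0.05
        b = rng.standard_normal((8, 4)) * 0.05 + 5.0
        x = np.vstack([a, b])
        runs = [cd.BoldRun(x.T, 3.0, "s")]
        fm = build_frame_matrix(runs, frame_norm="none")
        ex = [cd.ExemplarSet("s", np.arange(1, 17), np.zeros(16, bool), np.ones(16))]
        best, scores = select_k(fm, ex, k_range=range(2, 6), n_restarts=10, seed=0)
        assert best == 2
        assert scores[2] > 0.8
        # independent silhouette oracle at k=2 from the definition
        labels = (np.arange(16) >= 8).astype(int)
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        sil = []
        for i in range(16):
            same = labels == labels[i]
            a_i = d[i, same & (np.arange(16) != i)].mean()
            b_i = d[i, ~same].mean()
            sil.append((b_i - a_i) / max(a_i, b_i))
        assert scores[2] == pytest.approx(np.mean(sil), abs=1e-9)
        assert all(-1.0 <= s <= 1.0 for s in scores.values())

    def test_recovers_true_cluster_number(self, small_cohort):
        fm = build_frame_matrix(small_cohort.runs)
        ex = [select_exemplars(r) for r in small_cohort.runs]
        best, _ = select_k(fm, ex, k_range=range(2, 8), n_restarts=20, seed=0)
        assert best == small_cohort.config.k_true

    def test_empty_range_rejected(self, small_cohort):
        fm = build_frame_matrix(small_cohort.runs)
        ex = [select_exemplars(r) for r in small_cohort.runs]
        with pytest.raises(ValidationError):
            select_k(fm, ex, k_range=[])


class TestZscoreMap:
    def test_hand_computed_example(self):
        z, tern = zscore_map(np.array([2.0, 0.0, 0.0, 0.0, -2.0]))
        sd = np.sqrt(2.0)  # sample sd of the centroid
        np.testing.assert_allclose(z, [2 / sd, 0, 0, 0, -2 / sd])
        assert np.all(tern == 0)  # |z| max ~1.414 < 1.5

    def test_idempotent_on_standardized_input(self, rng):
        c = rng.standard_normal(100)
        c = (c - c.mean()) / c.std(ddof=1)
        z, _ = zscore_map(c)
        np.testing.assert_allclose(z, c, atol=1e-12)

    def test_threshold_sign_pattern(self):
        z, tern = zscore_map(np.concatenate([np.zeros(50), [30.0], [-30.0]]))
        assert tern[50] == 1.0 and tern[51] == -1.0
        assert np.all(tern[:50] == 0)

    def test_constant_centroid_rejected(self):
        with pytest.raises(ValidationError):
            zscore_map(np.full(10, 3.0))


class TestOrderCaps:
    def _model_with_occurrences(self):
        """Hand-built fitted model: NC occurrences by internal id
        (0.1, 0.4, 0.2) plus AD frames that must not influence ordering."""
        model = CapClustering(k=3, n_restarts=1, random_state=0)
        rng = np.random.default_rng(0)
        model._internal_centroids = rng.standard_normal((3, 10))
        nc_labels = np.repeat([0, 1, 2], [2, 8, 4])  # 0.1/0.4/0.2 of 14... use 20
        nc_labels = np.concatenate([np.zeros(2), np.ones(8), np.full(4, 2)]).astype(int)
        nc_labels = np.concatenate([nc_labels, np.full(6, 1)])  # 20 NC frames
        ad_labels = np.zeros(10, dtype=int)
        model._internal_labels = np.concatenate([nc_labels, ad_labels])
        model.frame_index_ = pd.DataFrame(
            {
                "subject_id": ["NC-1"] * 20 + ["AD-1"] * 10,
                "frame": list(range(1, 21)) + list(range(1, 11)),
            }
        )
        model.band_tag_ = "unfiltered"
        model.cap_order_ = np.arange(3)
        model._publish()
        return model

    def test_sorts_by_nc_occurrence_descending(self):
        model = self._model_with_occurrences()
        order_caps(model, ["NC-1"])
        # NC occurrences by internal id: 0=2/20, 1=14/20, 2=4/20
        assert model.cap_order_.tolist() == [1, 2, 0]
        assert np.all(np.diff(model.nc_occurrence_) <= 0)
        # internal 1 -> CAP1: AD frames were internal 0 -> CAP3
        assert np.all(model.labels_[-10:] == 3)

    def test_equal_occurrences_keep_internal_order(self):
        model = CapClustering(k=2, n_restarts=1, random_state=0)
        model._internal_centroids = np.array([[1.0, -1.0], [-1.0, 1.0]])
        model._internal_labels = np.array([0, 1, 0, 1])
        model.frame_index_ = pd.DataFrame(
            {"subject_id": ["NC-1"] * 4, "frame": [1, 2, 3, 4]}
        )
        model.band_tag_ = "unfiltered"
        model.cap_order_ = np.arange(2)
        model._publish()
        order_caps(model, ["NC-1"])
        assert model.cap_order_.tolist() == [0, 1]

    def test_no_control_frames_rejected(self, fitted_model):
        with pytest.raises(ValidationError, match="control"):
            order_caps(fitted_model, ["nobody"])
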