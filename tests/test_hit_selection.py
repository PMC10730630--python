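import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hcscreen as h
from hcscreen.hit_selection import (
    HitSelectionError,
    _gate_conditions,
    condition_frame,
)


class TestDiscriminantAxis:
    def test_identity_covariance_axis_along_mean_difference(self):
        rng = np.random.default_rng(0)
        neg = rng.normal([0, 0], 1.0, size=(3000, 2))
        pos = rng.normal([2, 0], 1.0, size=(3000, 2))
        w = h.fit_discriminant_axis(neg, pos, regularization="none")
        np.testing.assert_allclose(np.abs(w), [1.0, 0.0], atol=0.05)
        assert w[0] > 0

    def test_anisotropic_covariance_closed_form(self):
        # Σ = diag(2, 1), Δμ = (2, 2) → w ∝ Σ⁻¹Δμ = (1, 2)
        rng = np.random.default_rng(1)
        base = rng.normal(size=(4000, 2)) * np.sqrt([2.0, 1.0])
        neg = base[:2000]
        pos = base[2000:] + [2.0, 2.0]
        w = h.fit_discriminant_axis(neg, pos, regularization="none")
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        np.testing.assert_allclose(w, expected, atol=0.05)

    def test_label_swap_flips_the_sign_exactly(self):
        rng = np.random.default_rng(2)
        neg = rng.normal(0, 1, size=(30, 5))
        pos = rng.normal(1, 1, size=(30, 5))
        w1 = h.fit_discriminant_axis(neg, pos, regularization=0.1)
        w2 = h.fit_discriminant_axis(pos, neg, regularization=0.1)
        np.testing.assert_allclose(w1, -w2, atol=1e-12)

    def test_identical_class_means_not_separable(self):
        X = np.random.default_rng(3).normal(size=(10, 3))
        with pytest.raises(HitSelectionError, match="not separable"):
            h.fit_discriminant_axis(X, X.copy())

    @given(st.integers(0, 10_000), st.integers(2, 10))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_pooled_solve(self, seed, dim):
        """Closed-form oracle: w ∝ Σ_pooled⁻¹ Δμ via explicit inverse."""
        rng = np.random.default_rng(seed)
        neg = rng.normal(0, 1, size=(50, dim))
        pos = rng.normal(0.5, 1, size=(50, dim))
        w = h.fit_discriminant_axis(neg, pos, regularization="none")
        mu_n, mu_p = neg.mean(0), pos.mean(0)
        centered = np.vstack([neg - mu_n, pos - mu_p])
        pooled = centered.T @ centered / centered.shape[0]
        expected = np.linalg.inv(pooled) @ (mu_p - mu_n)
        expected /= np.linalg.norm(expected)
        np.testing.assert_allclose(w, expected, atol=1e-8)

    def test_agrees_with_sklearn_lda_direction(self):
        """Independent library cross-check on a well-conditioned problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(4)
        neg = rng.normal(0, 1, size=(200, 4))
        pos = rng.normal([1, 0.5, -0.5, 0], 1, size=(200, 4))
        w = h.fit_discriminant_axis(neg, pos, regularization="none")
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(
            np.vstack([neg, pos]), np.r_[np.zeros(200), np.ones(200)]
        )
        ref = lda.coef_.ravel() / np.linalg.norm(lda.coef_)
        np.testing.assert_allclose(w, ref, atol=1e-6)


def _screen_with_scores(scores_by_cond, n_reps=2):
    """Aligned-table + layouts stub: one feature equal to the desired score."""
    rows, index = [], []
    layouts = []
    for rep in range(n_reps):
        wells = {}
        for i, (cond, rep_scores) in enumerate(sorted(scores_by_cond.items())):
            addr = h.WellAddress("ABCDEFGHIJKLMNOP"[i // 22], i % 22 + 1)
            wells[addr] = (cond, h.ControlRole.sample)
            rows.append([rep_scores[rep]])
            index.append(("P01", f"R{rep + 1}", str(addr)))
        layouts.append(h.PlateLayout("P01", f"R{rep + 1}", wells, 1, 1))
    table = h.FeatureTable.from_array(np.array(rows), index, state=h.TableState.aligned)
    return table, layouts


class TestProjectAndThreshold:
    def test_default_fraction_flags_one_percent(self):
        rng = np.random.default_rng(5)
        scores = {f"c{i:04d}": (v, v) for i, v in enumerate(rng.normal(size=100))}
        table, layouts = _screen_with_scores(scores)
        res = h.project_and_threshold(table, layouts, np.array([1.0]))
        above = (res.per_condition["display_score"] > res.threshold).sum()
        assert above == 1
        assert len(res.hits) == 1

    def test_mean_above_threshold_but_one_replicate_below_is_not_a_hit(self):
        scores = {f"c{i:02d}": (v, v) for i, v in enumerate(np.linspace(-1, 1, 50))}
        scores["borderline"] = (2.5, 1.9)  # mean 2.2
        scores["solid"] = (2.6, 2.7)
        table, layouts = _screen_with_scores(scores)
        res = h.project_and_threshold(table, layouts, np.array([1.0]), hit_fraction=0.02)
        assert res.per_condition.loc["borderline", "display_score"] == pytest.approx(2.2)
        assert 1.9 < res.threshold < 2.2
        assert "borderline" not in res.hits
        assert "solid" in res.hits

    def test_all_identical_scores_yield_zero_hits(self):
        scores = {f"c{i:02d}": (1.0, 1.0) for i in range(50)}
        table, layouts = _screen_with_scores(scores)
        res = h.project_and_threshold(table, layouts, np.array([1.0]))
        assert res.hits == set()

    def test_gating_only_shrinks_the_hit_set(self):
        rng = np.random.default_rng(6)
        scores = {f"c{i:03d}": tuple(rng.normal(size=2)) for i in range(200)}
        table, layouts = _screen_with_scores(scores)
        res = h.project_and_threshold(table, layouts, np.array([1.0]), hit_fraction=0.05)
        mean_hits = set(
            res.per_condition.index[res.per_condition["display_score"] > res.threshold]
        )
        assert res.hits <= mean_hits

    def test_invalid_fraction_rejected(self):
        scores = {f"c{i}": (0.0, 0.0) for i in range(10)}
        table, layouts = _screen_with_scores(scores)
        with pytest.raises(HitSelectionError, match="hit_fraction"):
            h.project_and_threshold(table, layouts, np.array([1.0]), hit_fraction=0.9)


class TestNegativeModel:
    def test_large_sample_identity_covariance(self):
        X = np.random.default_rng(7).normal(size=(20000, 2))
        model = h.fit_negative_model(X, regularization="none")
        np.testing.assert_allclose(model.covariance, np.eye(2), atol=0.05)
        np.testing.assert_allclose(model.mean, 0.0, atol=0.05)

    def test_singular_without_regularization_refuses_shrinkage_succeeds(self):
        X = np.random.default_rng(8).normal(size=(5, 20))  # n < D
        with pytest.raises(HitSelectionError):
            h.fit_negative_model(X, regularization="none")
        model = h.fit_negative_model(X, regularization="auto")
        assert model.shrinkage > 0
        assert np.all(np.linalg.eigvalsh(model.covariance) > 0)

    def test_duplicated_rows_shift_only_the_shrinkage_weighting(self):
        X = np.random.default_rng(9).normal(size=(100, 3))
        m1 = h.fit_negative_model(X, regularization=0.2)
        m2 = h.fit_negative_model(np.vstack([X, X]), regularization=0.2)
        np.testing.assert_allclose(m1.mean, m2.mean, atol=1e-12)
        np.testing.assert_allclose(m1.covariance, m2.covariance, atol=1e-12)

    def test_single_well_is_an_error(self):
        with pytest.raises(HitSelectionError):
            h.fit_negative_model(np.ones((1, 4)))


class TestMahalanobis:
    def test_zero_at_the_mean_and_euclidean_under_identity(self):
        model = h.CovarianceModel(np.zeros(2), np.eye(2), 0.0, 1.0)
        assert model.mahalanobis(np.zeros(2))[0] == pytest.approx(0.0)
        assert model.mahalanobis(np.array([3.0, 4.0]))[0] == pytest.approx(5.0)

    def test_explicit_small_matrix_inverse(self):
        model = h.CovarianceModel(np.zeros(2), np.diag([4.0, 1.0]), 0.0, 4.0)
        assert model.mahalanobis(np.array([2.0, 1.0]))[0] == pytest.approx(np.sqrt(2.0))

    def test_matches_scipy_reference(self):
        from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

        rng = np.random.default_rng(10)
        X = rng.normal(size=(200, 4))
        model = h.fit_negative_model(X, regularization=0.1)
        VI = np.linalg.inv(model.covariance)
        pts = rng.normal(size=(20, 4))
        ours = model.mahalanobis(pts)
        ref = [scipy_mahalanobis(p, model.mean, VI) for p in pts]
        np.testing.assert_allclose(ours, ref, atol=1e-8)

    def test_affine_equivariance(self):
        """Distances are invariant under any invertible affine remap applied
        consistently to data and model."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(300, 3))
        pts = rng.normal(size=(10, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        m1 = h.fit_negative_model(X, regularization="none")
        m2 = h.fit_negative_model(X @ A.T + b, regularization="none")
        np.testing.assert_allclose(
            m1.mahalanobis(pts), m2.mahalanobis(pts @ A.T + b), atol=1e-6
        )

    def test_dimension_mismatch(self):
        model = h.CovarianceModel(np.zeros(2), np.eye(2), 0.0, 1.0)
        with pytest.raises(HitSelectionError, match="dimension"):
            model.mahalanobis(np.ones((1, 3)))


class TestOutlierHits:
    def test_quantile_flags_expected_fraction(self):
        rng = np.random.default_rng(12)
        n = 200
        dist = pd.Series(
            rng.random(n),
            index=pd.MultiIndex.from_tuples(
                [("P01", f"R{r}", f"{'ABCDEFGHIJ'[i // 22]}{i % 22 + 1:02d}") for r in (1, 2) for i in range(n // 2)],
                names=["plate_id", "replicate_id", "well"],
            ),
        )
        ann = pd.DataFrame(
            {
                "condition_id": [f"c{i:03d}" for r in (1, 2) for i in range(n // 2)],
                "role": "sample",
            },
            index=dist.index,
        )
        per_cond, thr, hits = h.call_outlier_hits(dist, ann, hit_fraction=0.05)
        above = (per_cond["distance"] > thr).sum()
        assert above == round(0.05 * (n // 2))

    def test_threshold_above_max_gives_empty_set(self):
        rng = np.random.default_rng(13)
        scores = {f"c{i:02d}": tuple(rng.random(2)) for i in range(20)}
        table, layouts = _screen_with_scores(scores)
        dist = pd.Series(table.data.iloc[:, 0], index=table.data.index)
        ann = condition_frame(table, layouts)
        _, thr, hits = h.call_outlier_hits(dist, ann, distance_threshold=99.0)
        assert hits == set()
        assert thr == 99.0


class TestClusterHits:
    def test_two_separated_blobs_recover_generative_labels(self):
        rng = np.random.default_rng(14)
        a = rng.normal(0, 1, size=(20, 6))
        b = rng.normal(30, 1, size=(20, 6))
        df = pd.DataFrame(
            np.vstack([a, b]), index=[f"c{i:02d}" for i in range(40)]
        )
        labels, reps = h.cluster_hits(df, k=2)
        la = {labels[f"c{i:02d}"] for i in range(20)}
        lb = {labels[f"c{i:02d}"] for i in range(20, 40)}
        assert len(la) == 1 and len(lb) == 1 and la != lb

    def test_k_equals_n_gives_singletons(self):
        df = pd.DataFrame(np.eye(4) * 10, index=list("abcd"))
        labels, reps = h.cluster_hits(df, k=4)
        assert sorted(labels.values()) == [1, 2, 3, 4]
        assert set(reps.values()) == set("abcd")

    def test_representative_is_a_member_closest_to_center(self):
        rng = np.random.default_rng(15)
        X = rng.normal(size=(30, 5))
        df = pd.DataFrame(X, index=[f"c{i:02d}" for i in range(30)])
        labels, reps = h.cluster_hits(df, k=3)
        for cl, rep in reps.items():
            members = [c for c, l in labels.items() if l == cl]
            assert rep in members
            center = df.loc[members].mean()
            dists = {c: np.linalg.norm(df.loc[c] - center) for c in members}
            assert dists[rep] == pytest.approx(min(dists.values()))

    def test_fewer_hits_than_k_lowers_k(self):
        df = pd.DataFrame(np.random.default_rng(16).normal(size=(3, 4)), index=list("abc"))
        labels, reps = h.cluster_hits(df, k=6)
        assert set(labels.values()) == {1, 2, 3}


class TestPerChannelScores:
    @pytest.fixture()
    def two_channel_screen(self):
        rng = np.random.default_rng(17)
        n_neg, n_samp, d = 60, 40, 16  # 2 channels × 8
        wells, rows, index = {}, [], []
        for i in range(n_neg + n_samp):
            addr = h.WellAddress("ABCDEFGHIJKLMNOP"[i // 22], i % 22 + 1)
            role = h.ControlRole.negative if i < n_neg else h.ControlRole.sample
            wells[addr] = (f"c{i:03d}", role)
            rows.append(rng.normal(size=d))
            index.append(("P01", "R1", str(addr)))
        layout = h.PlateLayout("P01", "R1", wells, 1, 2)
        table = h.FeatureTable.from_array(np.array(rows), index, state=h.TableState.aligned)
        return table, [layout]

    def test_displacement_confined_to_one_channel(self, two_channel_screen):
        table, layouts = two_channel_screen
        df = table.data.copy()
        victim = df.index[-1]
        # place the last well exactly at the channel-1 negative mean, displaced on channel 2
        ann = condition_frame(table, layouts)
        neg = df.to_numpy()[(ann["role"] == "negative").to_numpy()]
        df.loc[victim, df.columns[:8]] = neg[:, :8].mean(axis=0)
        df.loc[victim, df.columns[8:]] = neg[:, 8:].mean(axis=0) + 25.0
        shifted = h.FeatureTable(df, state=h.TableState.aligned)
        d1 = h.per_channel_scores(shifted, layouts, 1, regularization=0.3)
        d2 = h.per_channel_scores(shifted, layouts, 2, regularization=0.3)
        assert d1.loc[victim] < 1.0
        assert d2.loc[victim] > 5 * d1.loc[victim]

    def test_symmetric_displacement_gives_similar_distances(self, two_channel_screen):
        table, layouts = two_channel_screen
        df = table.data.copy()
        victim = df.index[-1]
        ann = condition_frame(table, layouts)
        neg = df.to_numpy()[(ann["role"] == "negative").to_numpy()]
        mean = neg.mean(axis=0)
        df.loc[victim] = np.concatenate([mean[:8] + 10.0, mean[8:] + 10.0])
        shifted = h.FeatureTable(df, state=h.TableState.aligned)
        d1 = h.per_channel_scores(shifted, layouts, 1, regularization=0.5)
        d2 = h.per_channel_scores(shifted, layouts, 2, regularization=0.5)
        assert d1.loc[victim] == pytest.approx(d2.loc[victim], rel=0.5)

    def test_channel_out_of_range(self, two_channel_screen):
        table, layouts = two_channel_screen
        with pytest.raises(HitSelectionError, match="out of range"):
            h.per_channel_scores(table, layouts, 3)
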