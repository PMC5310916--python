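"""SVM training: labelling, hyperparameter selection, personalisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fogbench.evaluation import EpisodeSet
from fogbench.features import FEATURE_COLUMNS
from fogbench.models import (
    HYPER_GRID,
    LabelledDataset,
    TrainedModel,
    compute_personal_weights,
    label_windows,
    select_hyperparameters,
    split_personal,
    train_generic,
    train_personalized,
)
from fogbench.preprocess import WindowSeries


def _window_series(n_windows: int, t0: float = 0.0) -> WindowSeries:
    return WindowSeries(
        subject_id="s",
        session="OFF",
        fs=40.0,
        windows=np.zeros((n_windows, 128, 3)),
        start_times=t0 + 1.6 * np.arange(n_windows),
    )


class TestLabelWindows:
    def test_37_percent_overlap_is_negative(self):
        # episode [2, 6) vs window [0, 3.2): 1.2 s = 37.5% < 50%
        lab = label_windows(_window_series(1), EpisodeSet([(2.0, 6.0)]))
        assert lab["label"].tolist() == [-1]

    def test_full_overlap_is_positive(self):
        lab = label_windows(_window_series(1), EpisodeSet([(0.0, 3.2)]))
        assert lab["label"].tolist() == [1]
        assert lab["episode_id"].tolist() == [0]

    def test_no_episodes_all_negative(self):
        lab = label_windows(_window_series(5), EpisodeSet([]))
        assert (lab["label"] == -1).all()

    def test_overlapping_episodes_rejected(self):
        with pytest.raises(ValueError):
            EpisodeSet([(0.0, 5.0), (4.0, 8.0)])


def _clustered_dataset(rng, n_per=60, jitter=1e-3):
    """Two tight, well-separated clusters: trivially separable for every
    hyperparameter pair, including the extreme RBF widths."""
    pos = np.array([3.0] * 55) + jitter * rng.normal(size=(n_per, 55))
    neg = np.array([-3.0] * 55) + jitter * rng.normal(size=(n_per, 55))
    X = np.vstack([pos, neg])
    y = np.array([1] * n_per + [-1] * n_per)
    return X, y


class TestSelectHyperparameters:
    def test_grid_enumerates_25_pairs(self):
        assert len(HYPER_GRID) ** 2 == 25
        np.testing.assert_allclose(HYPER_GRID, [0.01, 0.1, 1, 10, 100])

    def test_separable_clusters_tie_break_smallest_c_then_gamma(self, rng):
        X, y = _clustered_dataset(rng)
        c, g, constrained = select_hyperparameters(X, y, seed=0)
        assert constrained
        # every pair separates the clusters perfectly, so the tie-break
        # must return the smallest C and then the smallest gamma
        assert (c, g) == (0.01, 0.01)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 55))
        with pytest.raises(ValueError):
            select_hyperparameters(X, -np.ones(50, dtype=int), seed=0)

    def test_fold_reduction_on_scarce_positives(self, rng):
        X, y = _clustered_dataset(rng, n_per=60)
        y = y.copy()
        y[:55] = -1  # only 5 positives left -> folds drop to 5
        c, g, _ = select_hyperparameters(X[50:], y[50:], folds=10, seed=0)
        assert c in HYPER_GRID and g in HYPER_GRID


def _make_cohort(rng, subjects=("a", "b", "c"), n_per=40):
    frames = []
    for k, s in enumerate(subjects):
        X_pos = 3.0 + 0.05 * rng.normal(size=(n_per // 2, 55))
        X_neg = -3.0 + 0.05 * rng.normal(size=(n_per // 2, 55))
        X = np.vstack([X_pos, X_neg])
        df = pd.DataFrame(X, columns=FEATURE_COLUMNS)
        df.insert(0, "subject", s)
        df.insert(1, "session", "OFF")
        df.insert(2, "window_start_s", 1.6 * np.arange(n_per))
        df["label"] = [1] * (n_per // 2) + [-1] * (n_per // 2)
        df["episode_id"] = [0] * (n_per // 2) + [-1] * (n_per // 2)
        frames.append(df)
    return LabelledDataset(pd.concat(frames, ignore_index=True))


class TestTrainGeneric:
    def test_heldout_subject_never_in_training(self, rng):
        cohort = _make_cohort(rng)
        model = train_generic(cohort, "b", seed=0)
        assert model.manifest["training_subjects"] == ["a", "c"]
        assert "b" not in model.manifest["training_subjects"]
        assert model.svc.n_support_.sum() <= 80  # only a and c rows available

    def test_training_patterns_reproduced_on_separable_data(self, rng):
        cohort = _make_cohort(rng)
        model = train_generic(cohort, "c", seed=0)
        train_rows = cohort.frame[cohort.frame["subject"] != "c"]
        pred = model.predict(train_rows)
        np.testing.assert_array_equal(pred, train_rows["label"].to_numpy())

    def test_exclusion_equivalent_to_removal(self, rng):
        cohort = _make_cohort(rng, subjects=("a", "b", "c", "d"))
        m1 = train_generic(cohort, "d", seed=0)
        reduced = LabelledDataset(
            pd.concat(
                [
                    cohort.frame[cohort.frame.subject != "d"],
                    # a dummy row set for "d" is irrelevant: train on a,b,c
                    cohort.frame[cohort.frame.subject == "d"],
                ],
                ignore_index=True,
            )
        )
        m2 = train_generic(reduced, "d", seed=0)
        assert (m1.c, m1.gamma) == (m2.c, m2.gamma)
        np.testing.assert_allclose(m1.svc.dual_coef_, m2.svc.dual_coef_)

    def test_missing_test_subject_rejected(self, rng):
        with pytest.raises(ValueError):
            train_generic(_make_cohort(rng), "nope", seed=0)


class TestPersonalWeights:
    def test_published_arithmetic_example(self):
        w_t, w_20 = compute_personal_weights(9000, 1000)
        assert w_t == pytest.approx(0.9)
        assert w_20 == pytest.approx(0.1)
        assert 1000 * w_t == pytest.approx(9000 * w_20)  # balance: 900 = 900

    @given(st.integers(min_value=1, max_value=10**6),
           st.integers(min_value=1, max_value=10**6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_normalisation_and_balance_identities(self, n_20, n_half):
        w_t, w_20 = compute_personal_weights(n_20, n_half)
        assert w_t + w_20 == pytest.approx(1.0)
        assert n_half * w_t == pytest.approx(n_20 * w_20)

    def test_equal_counts_give_half(self):
        assert compute_personal_weights(500, 500) == (0.5, 0.5)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_personal_weights(0, 10)


class TestSplitPersonal:
    def test_four_episode_example(self):
        eps = EpisodeSet([(10, 15), (50, 53), (100, 108), (200, 204)])
        split = split_personal(eps)
        assert len(split.episodes_first) == 2
        assert split.split_time == pytest.approx((53 + 100) / 2)

    def test_odd_count_ceiling_rule(self):
        eps = EpisodeSet([(0, 5), (20, 24), (50, 55)])
        split = split_personal(eps)
        assert len(split.episodes_first) == 2
        assert len(split.episodes_second) == 1

    def test_every_window_in_exactly_one_half(self):
        eps = EpisodeSet([(10, 15), (50, 53), (100, 108), (200, 204)])
        split = split_personal(eps)
        starts = np.arange(0, 250, 1.6)
        first = split.half_mask(starts, "first")
        second = split.half_mask(starts, "second")
        assert np.all(first ^ second)

    def test_single_episode_rejected(self):
        with pytest.raises(ValueError):
            split_personal(EpisodeSet([(0, 5)]))


class TestTrainPersonalized:
    def _cohort_with_split(self, rng):
        cohort = _make_cohort(rng, subjects=("a", "b", "t"), n_per=40)
        # give subject t two episodes so the split is valid; windows 0..19
        # are positive in _make_cohort, so place episodes over them
        eps = EpisodeSet([(0.0, 16.0), (17.6, 33.6)])
        return cohort, eps

    def test_dual_coefficients_respect_weighted_caps(self, rng):
        cohort, eps = self._cohort_with_split(rng)
        split = split_personal(eps)
        model = train_personalized(cohort, "t", split, half="first", seed=0)
        w_t, w_20 = model.manifest["w_t"], model.manifest["w_20"]
        cap = model.c * max(w_t, w_20)
        assert np.all(np.abs(model.svc.dual_coef_) <= cap + 1e-8)

    def test_equal_weights_equal_uniform_cost_cap(self, rng):
        # when both groups have the same pattern count, w_t = w_20 = 1/2 and
        # the weighted problem is exactly the unweighted one at cost C/2
        from sklearn.svm import SVC

        cohort = _make_cohort(rng, subjects=("a", "t"), n_per=40)
        eps = EpisodeSet([(0.0, 16.0), (17.6, 33.6)])
        split = split_personal(eps)
        split.split_time = 64.0  # all 40 of t's windows in the first half
        model = train_personalized(
            cohort, "t", split, half="first", seed=0,
            reselect_hyperparameters=False,
        )
        assert model.manifest["w_t"] == pytest.approx(0.5)
        X = model.scaler.transform(cohort.X)
        plain = SVC(C=model.c * 0.5, gamma=model.gamma, kernel="rbf")
        plain.fit(X, cohort.y)
        np.testing.assert_allclose(model.svc.dual_coef_, plain.dual_coef_,
                                   atol=1e-9)
        np.testing.assert_allclose(model.svc.intercept_, plain.intercept_,
                                   atol=1e-9)

    def test_half_without_episodes_rejected(self, rng):
        cohort, eps = self._cohort_with_split(rng)
        split = split_personal(eps)
        split.episodes_second = EpisodeSet([])
        with pytest.raises(ValueError):
            train_personalized(cohort, "t", split, half="second", seed=0)
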