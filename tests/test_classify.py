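"""Stratified folds, accuracy-to-random metrics, and the nested-CV engine."""

import collections

import numpy as np
import pytest

from nirgrid import (
    CVConfig,
    PipelineSpec,
    Segment,
    accuracy_to_random,
    apply_pipeline,
    nested_cv,
    stratified_folds,
)
from nirgrid.exceptions import ParameterError
from nirgrid.synthetic import DEFAULT_CLASS_SIZES, SyntheticSpec, generate, make_separation_ladder

TABLE_SIZES = DEFAULT_CLASS_SIZES  # {31, 13, 63, 33, 49, 11, 12}


class TestStratifiedFolds:
    def test_study_sizes_give_balanced_folds(self):
        labels = np.concatenate([[k] * v for k, v in TABLE_SIZES.items()])
        folds = stratified_folds(labels, 5, seed=42)
        totals = collections.Counter(folds)
        assert sorted(totals.values()) == [42, 42, 42, 43, 43]
        for cls, n in TABLE_SIZES.items():
            counts = collections.Counter(folds[labels == cls])
            assert len(counts) == 5  # every class in every fold
            assert max(counts.values()) - min(counts.values()) <= 1

    def test_divisible_class_split_exactly(self):
        folds = stratified_folds(["z"] * 10, 5, seed=0)
        assert sorted(collections.Counter(folds).values()) == [2] * 5

    def test_deterministic_given_seed(self):
        labels = ["a"] * 13 + ["b"] * 7
        assert np.array_equal(
            stratified_folds(labels, 4, seed=99), stratified_folds(labels, 4, seed=99)
        )

    def test_needs_two_folds(self):
        with pytest.raises(ParameterError):
            stratified_folds(["a", "b"], 1, seed=0)


class TestAccuracyToRandom:
    def test_seven_class_worked_example(self):
        m = accuracy_to_random(77.00, 7)
        assert round(m.random_rate, 2) == 14.29
        # a/r = 77.00 * 7 / 100
        assert round(m.ratio, 2) == 5.39

    def test_two_class_worked_example(self):
        m = accuracy_to_random(90.0, 2)
        assert m.random_rate == 50.0
        assert m.ratio == pytest.approx(1.8)

    @pytest.mark.parametrize("c", [2, 3, 7, 10])
    def test_chance_accuracy_gives_ratio_one(self, c):
        assert accuracy_to_random(100.0 / c, c).ratio == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            accuracy_to_random(50.0, 1)
        with pytest.raises(ParameterError):
            accuracy_to_random(120.0, 4)


@pytest.fixture(scope="module")
def separable_processed():
    spec = SyntheticSpec(
        class_sizes=(("a", 8), ("b", 8), ("c", 8)),
        replicates_per_sample=3,
        scans_per_replicate=2,
        seed=17,
    )
    spec = make_separation_ladder(spec, [25.0])[0]
    block = generate(spec)
    return apply_pipeline(
        block,
        PipelineSpec(segments=(Segment(8000, 3950),), msc=True, binning_window=20),
    )


class TestNestedCV:
    def test_separable_classes_are_perfectly_classified(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=3, pc_search=(1, 4), seed=2)
        res = nested_cv(separable_processed, cv)
        assert np.all(res.per_rep_accuracy == 1.0)

    def test_confusion_conservation_and_trace_identity(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=3, pc_search=(1, 4), seed=2)
        res = nested_cv(separable_processed, cv)
        for k in range(res.n_classes):
            assert res.confusion[:, k].sum() == res.class_counts[k] * cv.repetitions
        total = res.confusion.sum()
        assert total == separable_processed.n_scans * cv.repetitions
        trace_acc = 100.0 * np.trace(res.confusion) / total
        assert abs(trace_acc - res.accuracy_mean) < 1e-10

    def test_deterministic_given_config(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=2, pc_search=(1, 4), seed=8)
        r1 = nested_cv(separable_processed, cv)
        r2 = nested_cv(separable_processed, cv)
        assert np.array_equal(r1.per_rep_accuracy, r2.per_rep_accuracy)
        assert np.array_equal(r1.confusion, r2.confusion)
        assert r1.chosen_pcs == r2.chosen_pcs

    def test_pc_search_truncated_to_training_size(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=1, pc_search=(1, 200), seed=1)
        res = nested_cv(separable_processed, cv)  # must not raise
        n_train_min = separable_processed.n_scans - separable_processed.n_scans // 4 - 1
        assert max(res.chosen_pcs) <= n_train_min

    def test_scan_level_block_rejected(self):
        spec = SyntheticSpec(
            class_sizes=(("a", 4), ("b", 4)), replicates_per_sample=1,
            scans_per_replicate=3, seed=1,
        )
        block = generate(spec)
        with pytest.raises(ParameterError, match="one spectrum per sample"):
            nested_cv(block, CVConfig(outer_folds=2, inner_folds=2, repetitions=1, seed=0))

    def test_summary_and_confusion_frames(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=2, pc_search=(1, 3), seed=5)
        res = nested_cv(separable_processed, cv)
        s = res.summary()
        assert s["n_classes"] == 3
        assert s["random_rate_pct"] == 33.33
        pct = res.confusion_frame(percentages=True)
        assert np.allclose(pct.sum(axis=0), 100.0)


class TestFoldSafeVariant:
    def test_fold_safe_msc_runs_and_conserves_counts(self):
        spec = SyntheticSpec(
            class_sizes=(("a", 6), ("b", 6), ("c", 6)),
            replicates_per_sample=2, scans_per_replicate=2,
            scatter_a_sd=0.08, scatter_b_range=(0.7, 1.3), seed=12,
        )
        block = generate(spec)
        pspec = PipelineSpec(segments=(Segment(8000, 3950),), msc=True, binning_window=20)
        cv = CVConfig(
            outer_folds=3, inner_folds=3, repetitions=2, pc_search=(1, 4),
            seed=4, fold_safe_msc=True,
        )
        res = nested_cv(block, cv, pipeline_spec=pspec)
        for k in range(res.n_classes):
            assert res.confusion[:, k].sum() == res.class_counts[k] * cv.repetitions

    def test_fold_safe_requires_pipeline_spec(self, separable_processed):
        cv = CVConfig(outer_folds=4, inner_folds=4, repetitions=1, fold_safe_msc=True, seed=0)
        with pytest.raises(ParameterError, match="pipeline_spec"):
            nested_cv(separable_processed, cv)
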