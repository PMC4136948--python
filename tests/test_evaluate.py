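"""Metrics, confusion matrices, the benchmark loop, and repeated k-fold CV."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import spectrabench as sb


class TestMisclassificationRate:
    def test_perfect_prediction(self):
        assert sb.misclassification_rate(["a", "b"], ["a", "b"]) == 0.0

    def test_hand_count(self):
        y = list("aabbccdd")
        pred = list("aabbccxx")
        assert sb.misclassification_rate(y, pred) == 0.25

    def test_total_error(self):
        assert sb.misclassification_rate(["a"] * 5, ["b"] * 5) == 1.0

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            sb.misclassification_rate(["a"], ["a", "b"])
        with pytest.raises(ValueError):
            sb.misclassification_rate([], [])

    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=40))
    def test_rate_bounded(self, labels):
        rate = sb.misclassification_rate(labels, list(reversed(labels)))
        assert 0.0 <= rate <= 1.0


class TestConfusionMatrix:
    def test_perfect_prediction_is_identity(self):
        cm = sb.confusion_matrix(["a", "b", "c"], ["a", "b", "c"], "abc")
        np.testing.assert_allclose(cm.matrix, np.eye(3))

    def test_hand_counted_rows(self):
        cm = sb.confusion_matrix(list("aabb"), list("abbb"), "ab")
        np.testing.assert_allclose(cm.matrix, [[0.5, 0.5], [0.0, 1.0]])

    @given(
        data=st.lists(
            st.tuples(st.sampled_from("abc"), st.sampled_from("abc")),
            min_size=1,
            max_size=50,
        )
    )
    def test_supported_rows_sum_to_one(self, data):
        y, pred = zip(*data)
        cm = sb.confusion_matrix(y, pred, "abc")
        for i, label in enumerate(cm.labels):
            if label in cm.zero_support:
                np.testing.assert_allclose(cm.matrix[i], 0.0)
            else:
                assert cm.matrix[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sb.confusion_matrix(["a"], ["z"], "ab")

    def test_zero_support_rows_flagged_not_normalized(self):
        cm = sb.confusion_matrix(["a", "a"], ["a", "b"], "ab")
        assert cm.zero_support == ("b",)
        np.testing.assert_allclose(cm.matrix[1], 0.0)


class TestAveragedConfusion:
    def test_idempotent_on_identical_matrices(self):
        cm = sb.confusion_matrix(list("aabb"), list("abbb"), "ab")
        avg = sb.average_confusion_matrices([cm, cm, cm])
        np.testing.assert_allclose(avg.matrix, cm.matrix)

    def test_identity_averaged_with_uniform(self):
        ident = sb.ConfusionMatrix(("a", "b"), np.eye(2))
        uniform = sb.ConfusionMatrix(("a", "b"), np.full((2, 2), 0.5))
        avg = sb.average_confusion_matrices([ident, uniform])
        np.testing.assert_allclose(avg.matrix, (np.eye(2) + 0.5) / 2)
        np.testing.assert_allclose(avg.matrix.sum(axis=1), 1.0)

    def test_mismatched_labels_rejected(self):
        a = sb.ConfusionMatrix(("a", "b"), np.eye(2))
        b = sb.ConfusionMatrix(("b", "a"), np.eye(2))
        with pytest.raises(ValueError):
            sb.average_confusion_matrices([a, b])
        with pytest.raises(ValueError):
            sb.average_confusion_matrices([])


class TestQuantiles:
    def test_constant_vector(self):
        np.testing.assert_allclose(sb.summarize_quantiles([0.3] * 7), [0.3] * 5)

    def test_order_statistics(self):
        np.testing.assert_allclose(
            sb.summarize_quantiles([0.1, 0.2, 0.3, 0.4, 0.5]),
            [0.1, 0.2, 0.3, 0.4, 0.5],
        )

    def test_single_element_and_empty(self):
        np.testing.assert_allclose(sb.summarize_quantiles([0.42]), [0.42] * 5)
        with pytest.raises(ValueError):
            sb.summarize_quantiles([])

    def test_quantiles_non_decreasing(self, rng):
        q = sb.summarize_quantiles(rng.random(101))
        assert np.all(np.diff(q) >= 0)


class TestAlgorithmSpecs:
    def test_default_spec_list_is_the_eleven_pairs(self):
        specs = sb.default_algorithm_specs()
        assert len(specs) == 11
        names = {(s.method, s.representation) for s in specs}
        assert ("lda", "pcs") in names and ("qda", "pcs") in names
        assert ("pda", "spectra") in names
        for method in ("knn", "tree", "forest", "nnet"):
            assert (method, "pcs") in names and (method, "spectra") in names

    @pytest.mark.parametrize(
        "method,representation",
        [("lda", "spectra"), ("qda", "spectra"), ("pda", "pcs")],
    )
    def test_forbidden_representations_rejected(self, method, representation):
        with pytest.raises(ValueError):
            sb.AlgorithmSpec("bad", method, representation)


@pytest.fixture(scope="module")
def tiny_run(class_estimates):
    plan = sb.SimulationPlan(n_datasets=2, m_c=24, seed=21)
    specs = [
        sb.AlgorithmSpec("LDA PCs", "lda", "pcs"),
        sb.AlgorithmSpec("PDA spectra", "pda", "spectra"),
        sb.AlgorithmSpec("KNN spectra", "knn", "spectra"),
    ]
    return plan, specs, sb.run_benchmark(class_estimates, plan, specs, seed=6)


class TestRunBenchmark:
    def test_result_shapes(self, tiny_run):
        plan, specs, result = tiny_run
        assert result.rates.shape == (2, 3)
        assert ((result.rates >= 0) & (result.rates <= 1)).all().all()
        assert set(result.confusions) == {s.name for s in specs}
        for cm in result.confusions.values():
            np.testing.assert_allclose(cm.matrix.sum(axis=1), 1.0, atol=1e-12)
        assert result.selected_q.shape == (2,) and np.all(result.selected_q >= 1)

    def test_benchmark_reproducible(self, class_estimates, tiny_run):
        plan, specs, result = tiny_run
        again = sb.run_benchmark(class_estimates, plan, specs, seed=6)
        pd.testing.assert_frame_equal(result.rates, again.rates)
        np.testing.assert_array_equal(result.selected_q, again.selected_q)

    def test_quantile_table_layout(self, tiny_run):
        _, specs, result = tiny_run
        table = result.quantile_table()
        assert list(table.columns) == ["0%", "25%", "50%", "75%", "100%"]
        assert set(table.index) == {s.name for s in specs}
        long = result.rates_long()
        assert set(long.columns) == {"dataset", "algorithm", "rate"}
        assert len(long) == 2 * 3


class TestRepeatedKFoldCV:
    def test_fold_sizes_for_96_rows(self):
        sizes = sb.kfold_sizes(96, 10)
        assert sorted(sizes) == [9, 9, 9, 9, 10, 10, 10, 10, 10, 10]
        assert sum(sizes) == 96
        with pytest.raises(ValueError):
            sb.kfold_sizes(5, 10)

    def test_every_row_in_exactly_one_test_fold(self, rng):
        n, k = 23, 4
        sizes = sb.kfold_sizes(n, k)
        perm = rng.permutation(n)
        seen = np.concatenate(
            [perm[sum(sizes[:i]) : sum(sizes[: i + 1])] for i in range(k)]
        )
        assert sorted(seen) == list(range(n))

    def test_cv_on_preprocessed_table(self, full_preprocessed):
        specs = [
            sb.AlgorithmSpec("LDA PCs", "lda", "pcs"),
            sb.AlgorithmSpec("PDA spectra", "pda", "spectra"),
        ]
        result = sb.repeated_kfold_cv(
            full_preprocessed, specs, k=10, repeats=2, seed=8
        )
        assert result.per_repeat.shape == (2, 2)
        assert ((result.per_repeat >= 0) & (result.per_repeat <= 1)).all().all()
        assert (result.sd >= 0).all()
        # per-repeat rate is total errors / n by construction; with two
        # repeats the mean lies between the per-repeat values
        for name in result.per_repeat:
            lo, hi = sorted(result.per_repeat[name])
            assert lo <= result.mean[name] <= hi

    def test_cv_reproducible(self, full_preprocessed):
        specs = [sb.AlgorithmSpec("LDA PCs", "lda", "pcs")]
        a = sb.repeated_kfold_cv(full_preprocessed, specs, k=10, repeats=2, seed=9)
        b = sb.repeated_kfold_cv(full_preprocessed, specs, k=10, repeats=2, seed=9)
        pd.testing.assert_frame_equal(a.per_repeat, b.per_repeat)


def test_random_guess_rate_analytic():
    assert sb.expected_random_guess_rate(8) == pytest.approx(7 / 8)
    assert sb.expected_random_guess_rate(1) == 0.0
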