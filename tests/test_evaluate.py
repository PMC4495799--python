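"""Confusion tabulation, Cohen's kappa, repeated CV, AUC summaries."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

import methclass as mc
from methclass.evaluate import INCONCLUSIVE

from conftest import make_matrix


class TestConfusion:
    def test_direct_tally(self):
        cm = mc.confusion(["A", "A", "B"], ["A", "B", "B"])
        assert cm.classes == ["A", "B"]
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_identical_vectors_diagonal(self):
        cm = mc.confusion(list("ABCABC"), list("ABCABC"))
        assert np.array_equal(cm.counts, np.eye(3, dtype=int) * 2)

    def test_order_invariance(self):
        t = ["A", "B", "A", "B", "B"]
        p = ["A", "B", "B", "B", "A"]
        perm = [4, 2, 0, 3, 1]
        a = mc.confusion(t, p)
        b = mc.confusion([t[i] for i in perm], [p[i] for i in perm])
        assert np.array_equal(a.counts, b.counts)

    def test_inconclusive_tracked_separately(self):
        cm = mc.confusion(["A", "A", "B"], ["A", INCONCLUSIVE, "B"])
        assert cm.counts.sum() == 2
        assert cm.inconclusive.tolist() == [1, 0]
        assert cm.n_inconclusive == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(mc.InputError):
            mc.confusion(["A"], ["A", "B"])


class TestCohenKappa:
    def test_hand_worked_two_by_two(self):
        cm = mc.ConfusionMatrix(["X", "Y"], np.array([[45, 5], [15, 35]]), np.zeros(2, int))
        res = mc.cohen_kappa(cm)
        # p_o = 0.80, p_e = (50*60 + 50*40)/100^2 = 0.50
        assert res.kappa == pytest.approx(0.60, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(0.8 * 0.2 / (100 * 0.25)), abs=1e-12)
        assert res.ci_low == pytest.approx(0.60 - 1.959964 * 0.08, abs=1e-4)
        assert res.ci_low <= res.kappa <= res.ci_high

    def test_diagonal_matrix_kappa_one(self):
        cm = mc.ConfusionMatrix(["A", "B", "C"], np.diag([5, 3, 2]), np.zeros(3, int))
        assert mc.cohen_kappa(cm).kappa == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 4, size=200).astype(str)
        p = rng.integers(0, 4, size=200).astype(str)
        cm = mc.confusion(t, p, classes=sorted(set(t) | set(p)))
        assert mc.cohen_kappa(cm).kappa == pytest.approx(
            cohen_kappa_score(t, p), abs=1e-12
        )

    def test_permutation_null_centred_on_zero(self):
        rng = np.random.default_rng(99)
        truth = np.repeat(list("ABCD"), 25)
        kappas = []
        for _ in range(500):
            pred = rng.permutation(truth)
            kappas.append(mc.cohen_kappa(mc.confusion(truth, pred)).kappa)
        se = mc.cohen_kappa(mc.confusion(truth, rng.permutation(truth))).se
        assert abs(np.mean(kappas)) < 3 * se

    def test_kappa_below_observed_accuracy_with_errors(self):
        cm = mc.confusion(list("AABB"), list("AABA"))
        res = mc.cohen_kappa(cm)
        assert res.kappa < 1.0
        assert res.kappa <= np.trace(cm.counts) / cm.n

    def test_row_column_permutation_invariance(self):
        counts = np.array([[30, 4, 1], [2, 25, 3], [0, 5, 30]])
        cm1 = mc.ConfusionMatrix(["A", "B", "C"], counts, np.zeros(3, int))
        perm = [2, 0, 1]
        cm2 = mc.ConfusionMatrix(
            [["A", "B", "C"][i] for i in perm],
            counts[np.ix_(perm, perm)],
            np.zeros(3, int),
        )
        assert mc.cohen_kappa(cm1).kappa == pytest.approx(mc.cohen_kappa(cm2).kappa, abs=1e-12)

    def test_degenerate_table_rejected(self):
        cm = mc.ConfusionMatrix(["A", "B"], np.array([[7, 0], [0, 0]]), np.zeros(2, int))
        with pytest.raises(mc.InputError, match="degenerate"):
            mc.cohen_kappa(cm)


class TestRepeatedCV:
    def test_leave_one_out_accounting(self, small_cohort):
        m, labels, _, _ = small_cohort
        rep = mc.repeated_cv(
            m, labels, folds=8, repeats=1, seed=0, n_per_class=10,
            forest_cfg=mc.ForestConfig(n_trees=31, seed=0), tune=False,
        )
        total = rep.confusion.counts.sum() + rep.confusion.inconclusive.sum()
        assert total == len(labels)  # each sample predicted exactly once
        assert len(rep.per_fold) == 8

    def test_pooled_total_is_n_times_repeats(self, small_cohort):
        m, labels, _, _ = small_cohort
        rep = mc.repeated_cv(
            m, labels, folds=3, repeats=2, seed=1, n_per_class=10,
            forest_cfg=mc.ForestConfig(n_trees=31, seed=1), tune=False,
        )
        total = rep.confusion.counts.sum() + rep.confusion.inconclusive.sum()
        assert total == 2 * len(labels)

    def test_same_seed_gives_identical_fold_tables(self, small_cohort):
        m, labels, _, _ = small_cohort
        kwargs = dict(
            folds=3, repeats=2, seed=4, n_per_class=10,
            forest_cfg=mc.ForestConfig(n_trees=31, seed=4),
            tune=True,
        )
        a = mc.repeated_cv(m, labels, **kwargs)
        b = mc.repeated_cv(m, labels, **kwargs)
        assert a.per_fold == b.per_fold
        assert np.array_equal(a.confusion.counts, b.confusion.counts)

    def test_folds_reduced_for_small_classes(self, small_cohort, caplog):
        m, labels, _, _ = small_cohort  # 8 samples/class < 10 folds
        rep = mc.repeated_cv(
            m, labels, folds=10, repeats=1, seed=0, n_per_class=10,
            forest_cfg=mc.ForestConfig(n_trees=31, seed=0), tune=False,
        )
        assert rep.folds == 8

    def test_singleton_class_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((5, 5)))
        labels = mc.LabelMap({"s0": "A", "s1": "A", "s2": "B", "s3": "B", "s4": "C"})
        with pytest.raises(mc.InputError, match="single sample"):
            mc.repeated_cv(m, labels, folds=2, repeats=1, seed=0)

    def test_leaky_selection_differs_from_in_fold(self, small_cohort):
        """Selecting probes on the full data before splitting is a
        different (optimistically biased) procedure; the pooled confusion
        is logged for both so the bias is measurable."""
        m, labels, _, _ = small_cohort
        kwargs = dict(folds=4, repeats=1, seed=2, n_per_class=10,
                      forest_cfg=mc.ForestConfig(n_trees=51, seed=2), tune=False)
        fair = mc.repeated_cv(m, labels, leaky=False, **kwargs)
        leaky = mc.repeated_cv(m, labels, leaky=True, **kwargs)
        assert leaky.error_rate <= fair.error_rate + 1e-9


class TestAucSummary:
    def test_single_probe_per_class(self):
        panel = mc.build_panel(
            {"A": [mc.ProbeScore("x", "A", 0.97, "hyper")]}, n_per_class=1
        )
        stats = mc.auc_summary(panel)["A"]
        assert stats["min"] == stats["median"] == stats["max"] == 0.97
        assert not stats["below_floor"]

    def test_noise_panel_flagged(self):
        rng = np.random.default_rng(10)
        X = rng.random((400, 30))
        labels = mc.LabelMap({f"s{j}": ("A" if j < 15 else "B") for j in range(30)})
        panel = mc.build_panel(mc.rank_all_classes(make_matrix(X), labels), 50)
        stats = mc.auc_summary(panel)
        assert any(v["below_floor"] for v in stats.values())
        assert all(0.5 <= v["median"] <= 0.75 for v in stats.values())
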