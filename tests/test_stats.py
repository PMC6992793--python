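"""ROC/AUC, DeLong, bootstrap, log loss, thresholded accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsitile import stats
from wsitile.labels import ADENOCARCINOMA, ADENOMA, LABELS, NON_NEOPLASTIC


def delong_vs_permutation(seed: int, n: int = 30, n_perm: int = 100_000):
    """One paired instance: (DeLong p, sign-flip permutation p).

    Correlated score pairs over the same subjects; the permutation oracle
    swaps the two scores per subject under the exchangeability null and
    recomputes the absolute AUC difference.
    """
    from scipy.stats import rankdata

    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    base = rng.uniform(size=n)
    a = np.clip(0.25 * y + 0.5 * base + rng.normal(0, 0.25, n), 0, 1)
    b = np.clip(0.20 * y + 0.5 * base + rng.normal(0, 0.25, n), 0, 1)
    _, _, p = stats.delong_test(a, b, y)
    observed = abs(stats.roc_auc(a, y) - stats.roc_auc(b, y))
    swap = rng.random((n_perm, n)) < 0.5
    a_m = np.where(swap, b, a)
    b_m = np.where(swap, a, b)

    def auc_rows(mat):
        ranks = rankdata(mat, axis=1)
        m = y.sum()
        return (ranks[:, y == 1].sum(axis=1) - m * (m + 1) / 2) / (m * (n - m))

    diffs = np.abs(auc_rows(a_m) - auc_rows(b_m))
    p_perm = float((diffs >= observed - 1e-12).mean())
    return p, p_perm


def brute_force_auc(scores, labels):
    """All-pairs Mann–Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation_is_one(self):
        assert stats.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert stats.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_hand_counted_example(self):
        # 3 of 4 positive/negative pairs ranked correctly
        assert stats.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_one_class_absent_is_an_error(self):
        with pytest.raises(ValueError):
            stats.roc_auc([0.1, 0.9], [1, 1])

    @given(st.data())
    @settings(deadline=None, max_examples=100)
    def test_matches_brute_force_pair_counting(self, data):
        n = data.draw(st.integers(4, 50))
        scores = data.draw(
            st.lists(
                st.floats(0, 1, width=32),
                min_size=n,
                max_size=n,
            )
        )
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        auc = stats.roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = stats.roc_auc(scores, labels)
        b = stats.roc_auc(np.exp(3 * scores), labels)
        assert a == pytest.approx(b, abs=1e-12)

    def test_complementing_scores_flips_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.uniform(size=25)
        labels = (rng.uniform(size=25) < 0.4).astype(int)
        labels[:2] = [0, 1]
        assert stats.roc_auc(1 - scores, labels) == pytest.approx(
            1 - stats.roc_auc(scores, labels), abs=1e-12
        )


def _table(scores, true_labels, label=ADENOCARCINOMA):
    df = pd.DataFrame(
        {
            "slide_id": [f"s{i}" for i in range(len(scores))],
            "true_label": true_labels,
        }
    )
    for lab in LABELS:
        df[f"p_{lab}"] = 0.0
    df[f"p_{label}"] = scores
    return df


class TestBootstrap:
    def test_fixed_seed_reproduces_interval(self):
        rng = np.random.default_rng(0)
        t = _table(
            rng.uniform(size=30),
            [ADENOCARCINOMA if x else NON_NEOPLASTIC for x in rng.integers(0, 2, 30)],
        )
        a = stats.bootstrap_auc_ci(t, ADENOCARCINOMA, n_boot=200, seed=5)
        b = stats.bootstrap_auc_ci(t, ADENOCARCINOMA, n_boot=200, seed=5)
        assert a == b

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(3)
        for seed in range(3):
            y = rng.integers(0, 2, 40)
            y[:2] = [0, 1]
            scores = np.clip(0.5 * y + rng.normal(0.3, 0.25, 40), 0, 1)
            labels = [ADENOCARCINOMA if v else NON_NEOPLASTIC for v in y]
            t = _table(scores, labels)
            point = stats.roc_auc(scores, y)
            lo, hi = stats.bootstrap_auc_ci(t, ADENOCARCINOMA, n_boot=1000, seed=seed)
            assert lo <= point <= hi

    def test_degenerate_perfect_table_gives_unit_interval(self):
        t = _table(
            [1.0] * 5 + [0.0] * 5,
            [ADENOCARCINOMA] * 5 + [NON_NEOPLASTIC] * 5,
        )
        assert stats.bootstrap_auc_ci(t, ADENOCARCINOMA, n_boot=50, seed=0) == (1.0, 1.0)


class TestDeLong:
    def test_identical_score_vectors_give_p_one(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(size=20)
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        auc_a, auc_b, p = stats.delong_test(s, s, y)
        assert auc_a == auc_b
        assert p == 1.0

    def test_swapping_sides_preserves_p_and_swaps_aucs(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        a = np.clip(y * 0.4 + rng.uniform(size=30) * 0.6, 0, 1)
        b = np.clip(y * 0.2 + rng.uniform(size=30) * 0.8, 0, 1)
        auc_a1, auc_b1, p1 = stats.delong_test(a, b, y)
        auc_a2, auc_b2, p2 = stats.delong_test(b, a, y)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert (auc_a1, auc_b1) == (auc_b2, auc_a2)

    def test_aucs_equal_roc_auc_on_same_data(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 25)
        y[:2] = [0, 1]
        a, b = rng.uniform(size=25), rng.uniform(size=25)
        auc_a, auc_b, _ = stats.delong_test(a, b, y)
        assert auc_a == pytest.approx(stats.roc_auc(a, y), abs=1e-12)
        assert auc_b == pytest.approx(stats.roc_auc(b, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            stats.delong_test([0.1, 0.2], [0.1], [0, 1])

    def test_agrees_with_paired_permutation_oracle(self):
        """Normal-theory p within 0.02 of a 1e5-replicate permutation p."""
        p, p_perm = delong_vs_permutation(seed=0)
        assert p == pytest.approx(p_perm, abs=0.02)

    def test_matches_reference_implementation_in_r(self, tmp_path):
        """Agreement with pROC's roc.test to numerical precision."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(7)
        n = 30
        y = np.array([0, 1] * (n // 2))
        base = rng.uniform(size=n)
        a = np.clip(0.35 * y + 0.65 * base + rng.normal(0, 0.08, n), 0, 1)
        b = np.clip(0.30 * y + 0.65 * base + rng.normal(0, 0.08, n), 0, 1)
        csv = tmp_path / "scores.csv"
        np.savetxt(csv, np.column_stack([y, a, b]), delimiter=",",
                   header="y,a,b", comments="")
        script = (
            "suppressMessages(library(pROC));"
            f"d <- read.csv('{csv}');"
            "t <- roc.test(roc(d$y, d$a, quiet=TRUE), roc(d$y, d$b, quiet=TRUE),"
            " method='delong'); cat(t$p.value)"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        p_ref = float(out.stdout.strip())
        _, _, p = stats.delong_test(a, b, y)
        assert p == pytest.approx(p_ref, abs=1e-6)


class TestLogLoss:
    def test_perfect_confident_predictions_are_near_zero(self):
        t = _table(
            [1.0, 1.0, 0.0, 0.0],
            [ADENOCARCINOMA] * 2 + [NON_NEOPLASTIC] * 2,
        )
        losses, mean = stats.one_vs_rest_log_loss(t, ADENOCARCINOMA)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_gives_ln2(self):
        t = _table([0.5] * 10, [ADENOCARCINOMA] * 5 + [NON_NEOPLASTIC] * 5)
        _, mean = stats.one_vs_rest_log_loss(t, ADENOCARCINOMA)
        assert mean == pytest.approx(np.log(2), abs=1e-12)

    def test_confident_error_clips_at_minus_ln_eps(self):
        t = _table([0.0], [ADENOCARCINOMA])
        losses, _ = stats.one_vs_rest_log_loss(t, ADENOCARCINOMA, clip_eps=1e-15)
        assert losses[0] == pytest.approx(-np.log(1e-15), rel=1e-9)

    def test_constant_predictor_minimised_at_empirical_rate(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        labels = [ADENOCARCINOMA if v else NON_NEOPLASTIC for v in y]
        rate = y.mean()

        def mean_loss(p):
            t = _table([p] * len(y), labels)
            return stats.one_vs_rest_log_loss(t, ADENOCARCINOMA)[1]

        at_rate = mean_loss(rate)
        assert all(
            at_rate <= mean_loss(p) + 1e-12 for p in np.linspace(0.02, 0.98, 49)
        )


class TestPairedT:
    def test_identical_vectors_give_p_one(self):
        assert stats.paired_log_loss_test([0.2, 0.3, 0.1], [0.2, 0.3, 0.1]) == 1.0

    def test_two_sided_symmetry_under_negation(self):
        a = np.array([0.5, 0.7, 0.6, 0.55])
        b = np.array([0.4, 0.5, 0.45, 0.5])
        assert stats.paired_log_loss_test(a, b) == pytest.approx(
            stats.paired_log_loss_test(b, a), abs=1e-12
        )

    def test_matches_textbook_closed_form(self):
        # differences 0.1, 0.2, 0.15, 0.05: mean 0.125, sd 0.0645497, df 3
        a = np.array([0.1, 0.2, 0.15, 0.05])
        b = np.zeros(4)
        d_mean, d_sd = 0.125, np.std(a, ddof=1)
        t_stat = d_mean / (d_sd / np.sqrt(4))
        from scipy.stats import t as t_dist

        expected = 2 * t_dist.sf(abs(t_stat), df=3)
        assert stats.paired_log_loss_test(a, b) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            stats.paired_log_loss_test([0.1], [0.1, 0.2])


class TestAccuracyAndConfusion:
    def test_all_correct_confident_predictions_are_100(self):
        rows = []
        for lab in LABELS:
            for i in range(3):
                row = {"slide_id": f"{lab}{i}", "true_label": lab}
                for other in LABELS:
                    row[f"p_{other}"] = 0.9 if other == lab else 0.05
                rows.append(row)
        assert stats.accuracy_at_threshold(pd.DataFrame(rows)) == 100.0

    def test_random_uniform_diagnosis_expects_one_third(self):
        """Monte-carlo over random diagnoses on a 15/15/15 cohort."""
        rng = np.random.default_rng(0)
        truth = np.repeat(np.arange(3), 15)
        draws = rng.integers(0, 3, size=(100_000, 45))
        acc = 100.0 * (draws == truth).mean()
        assert acc == pytest.approx(100 / 3, abs=0.5)

    def test_hand_built_six_slide_table(self):
        labs = [ADENOCARCINOMA, ADENOCARCINOMA, ADENOMA, ADENOMA,
                NON_NEOPLASTIC, NON_NEOPLASTIC]
        pred = [ADENOCARCINOMA, ADENOMA, ADENOMA, ADENOMA,
                NON_NEOPLASTIC, ADENOCARCINOMA]
        rows = []
        for i, (t_lab, p_lab) in enumerate(zip(labs, pred)):
            row = {"slide_id": f"s{i}", "true_label": t_lab}
            for other in LABELS:
                row[f"p_{other}"] = 0.9 if other == p_lab else 0.05
            rows.append(row)
        assert stats.accuracy_at_threshold(pd.DataFrame(rows)) == pytest.approx(
            400 / 6, abs=1e-9
        )

    def test_below_threshold_falls_back_to_non_neoplastic(self):
        row = {"slide_id": "s", "true_label": NON_NEOPLASTIC,
               "p_adenocarcinoma": 0.4, "p_adenoma": 0.3, "p_non_neoplastic": 0.3}
        assert stats.accuracy_at_threshold(pd.DataFrame([row]), 0.5) == 100.0

    def test_confusion_matrix_conserves_and_diagonalises(self):
        perfect = stats.confusion_matrix(
            [ADENOCARCINOMA, ADENOMA, NON_NEOPLASTIC],
            [ADENOCARCINOMA, ADENOMA, NON_NEOPLASTIC],
        )
        np.testing.assert_array_equal(perfect, np.eye(3, dtype=int))
        rng = np.random.default_rng(0)
        preds = rng.choice(LABELS, 30)
        truth = rng.choice(LABELS, 30)
        m = stats.confusion_matrix(preds, truth)
        assert m.sum() == 30
        perm = rng.permutation(30)
        np.testing.assert_array_equal(
            m, stats.confusion_matrix(preds[perm], truth[perm])
        )


class TestOptimalThreshold:
    def test_separated_scores_land_mid_gap(self):
        scores = [0.1, 0.2, 0.85, 0.9]
        labels = [0, 0, 1, 1]
        assert stats.optimal_threshold(scores, labels) == pytest.approx(0.525)

    def test_high_negatives_push_threshold_up(self):
        scores = [0.1, 0.95, 0.99, 0.999]
        labels = [0, 0, 1, 1]
        assert stats.optimal_threshold(scores, labels) > 0.9
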