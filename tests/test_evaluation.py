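import numpy as np
import pytest

import mortcode as mc
from mortcode.evaluation import (
    accuracy,
    bootstrap_ci,
    calibration_report,
    chapter_confusion_on_errors,
    compare_with_baseline,
    per_chapter_report,
    second_choice_accuracy_on_errors,
    topk_accuracy,
)
from mortcode.oracle import OracleResult


@pytest.fixture(scope="module")
def small_vocab():
    return mc.make_synthetic_vocabulary(4, 5, seed=3)


def _random_distributions(rng, n, V):
    d = rng.gamma(0.3, 1.0, size=(n, V)) + 1e-9
    return d / d.sum(axis=1, keepdims=True)


class TestAccuracy:
    def test_basic(self):
        assert accuracy(["A00", "B00"], ["A00", "B00"]) == 1.0
        assert accuracy(["A00", "B00", "C00", "D00"], ["A00", "B00", "C00", "X00"]) == 0.75

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            accuracy(["A00"], ["A00", "B00"])
        with pytest.raises(ValueError):
            accuracy([], [])

    def test_agrees_with_naive_loop(self, small_vocab):
        rng = np.random.default_rng(0)
        codes = small_vocab.codes
        preds = [codes[i] for i in rng.integers(0, len(codes), 1000)]
        golds = [codes[i] for i in rng.integers(0, len(codes), 1000)]
        naive = 0
        for p, g in zip(preds, golds):
            if p == g:
                naive += 1
        assert accuracy(preds, golds) == naive / 1000


class TestBootstrapCi:
    def test_degenerate_inputs(self):
        assert bootstrap_ci([1] * 50, B=200, seed=1) == (1.0, 1.0)
        assert bootstrap_ci([0] * 50, B=200, seed=1) == (0.0, 0.0)

    def test_deterministic_under_seed(self):
        flags = [1] * 90 + [0] * 10
        assert bootstrap_ci(flags, B=500, seed=7) == bootstrap_ci(flags, B=500, seed=7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([], B=10)

    def test_half_width_matches_binomial_standard_error(self):
        """At n=80,000 and accuracy 0.978 the 95% interval half-width should
        be about 1.96 * sqrt(p(1-p)/n) ~ 0.001."""
        n, p = 80_000, 0.978
        flags = np.zeros(n, dtype=int)
        flags[: int(round(p * n))] = 1
        lo, hi = bootstrap_ci(flags, B=400, seed=3)
        half = (hi - lo) / 2
        se = 1.96 * np.sqrt(p * (1 - p) / n)
        assert 0.7 * se < half < 1.3 * se


class TestPerChapter:
    def test_single_chapter_all_correct(self, small_vocab):
        code = small_vocab.codes[0]
        rep = per_chapter_report([code] * 5, [code] * 5, small_vocab)
        ch = small_vocab.chapter_of_index(0)
        assert rep.loc[ch, "prevalence"] == 1.0
        assert rep.loc[ch, "error_rate"] == 0.0

    def test_partial_errors(self, small_vocab):
        g = small_vocab.codes[0]
        other = small_vocab.codes[1]
        rep = per_chapter_report([g, other, other], [g, g, g], small_vocab)
        ch = small_vocab.chapter_of_index(0)
        assert rep.loc[ch, "error_rate"] == pytest.approx(2 / 3)

    def test_unobserved_chapters_flagged(self, small_vocab):
        code = small_vocab.codes[0]
        rep = per_chapter_report([code], [code], small_vocab)
        assert (~rep["observed"]).sum() == len(small_vocab.chapters()) - 1

    def test_prevalences_sum_to_one_and_recompose_accuracy(self, small_vocab):
        rng = np.random.default_rng(5)
        codes = small_vocab.codes
        preds = [codes[i] for i in rng.integers(0, len(codes), 400)]
        golds = [codes[i] for i in rng.integers(0, len(codes), 400)]
        rep = per_chapter_report(preds, golds, small_vocab)
        obs = rep[rep["observed"]]
        assert obs["prevalence"].sum() == pytest.approx(1.0)
        recomposed = (obs["prevalence"] * (1 - obs["error_rate"])).sum()
        assert recomposed == pytest.approx(accuracy(preds, golds))


class TestChapterConfusion:
    def test_no_errors_gives_empty_matrix(self, small_vocab):
        code = small_vocab.codes[0]
        mat = chapter_confusion_on_errors([code] * 3, [code] * 3, small_vocab)
        assert mat.values.sum() == 0

    def test_in_chapter_error_hits_diagonal(self, small_vocab):
        a, b = small_vocab.codes[0], small_vocab.codes[1]  # same chapter letter
        assert small_vocab.chapter_of_index(0) == small_vocab.chapter_of_index(1)
        mat = chapter_confusion_on_errors([b], [a], small_vocab)
        ch = small_vocab.chapter_of_index(0)
        assert mat.loc[ch, ch] == 1 and mat.values.sum() == 1

    def test_total_equals_error_count(self, small_vocab):
        rng = np.random.default_rng(6)
        codes = small_vocab.codes
        preds = [codes[i] for i in rng.integers(0, len(codes), 300)]
        golds = [codes[i] for i in rng.integers(0, len(codes), 300)]
        mat = chapter_confusion_on_errors(preds, golds, small_vocab)
        assert mat.values.sum() == sum(p != g for p, g in zip(preds, golds))


class TestTopK:
    def test_top_v_is_exactly_one(self, small_vocab):
        rng = np.random.default_rng(7)
        d = _random_distributions(rng, 50, small_vocab.size)
        golds = [small_vocab.codes[i] for i in rng.integers(0, small_vocab.size, 50)]
        assert topk_accuracy(d, golds, small_vocab, small_vocab.size) == 1.0

    def test_k1_equals_argmax_accuracy(self, small_vocab):
        rng = np.random.default_rng(8)
        d = _random_distributions(rng, 200, small_vocab.size)
        golds = [small_vocab.codes[i] for i in rng.integers(0, small_vocab.size, 200)]
        preds = [small_vocab.code_at(int(i)) for i in d.argmax(axis=1)]
        assert topk_accuracy(d, golds, small_vocab, 1) == accuracy(preds, golds)

    def test_monotone_in_k(self, small_vocab):
        rng = np.random.default_rng(9)
        d = _random_distributions(rng, 200, small_vocab.size)
        golds = [small_vocab.codes[i] for i in rng.integers(0, small_vocab.size, 200)]
        accs = [topk_accuracy(d, golds, small_vocab, k) for k in range(1, 6)]
        assert accs == sorted(accs)

    def test_k_bounds(self, small_vocab):
        d = _random_distributions(np.random.default_rng(1), 5, small_vocab.size)
        golds = [small_vocab.codes[0]] * 5
        for k in (0, small_vocab.size + 1):
            with pytest.raises(ValueError):
                topk_accuracy(d, golds, small_vocab, k)


class TestSecondChoice:
    def test_identity_with_top2(self, small_vocab):
        """top-2 accuracy = accuracy + (1 - accuracy) * second-choice-on-errors."""
        rng = np.random.default_rng(10)
        d = _random_distributions(rng, 500, small_vocab.size)
        golds = [small_vocab.codes[i] for i in rng.integers(0, small_vocab.size, 500)]
        preds = [small_vocab.code_at(int(i)) for i in d.argmax(axis=1)]
        acc = accuracy(preds, golds)
        sc = second_choice_accuracy_on_errors(d, preds, golds, small_vocab)
        top2 = topk_accuracy(d, golds, small_vocab, 2)
        assert top2 == pytest.approx(acc + (1 - acc) * sc)

    def test_undefined_without_errors(self, small_vocab):
        d = np.eye(small_vocab.size)[:3]
        golds = [small_vocab.codes[i] for i in range(3)]
        preds = list(golds)
        with pytest.raises(ValueError, match="undefined"):
            second_choice_accuracy_on_errors(d, preds, golds, small_vocab)


class TestCalibration:
    def test_counts_sum_to_n(self, small_vocab):
        rng = np.random.default_rng(11)
        d = _random_distributions(rng, 300, small_vocab.size)
        golds = [small_vocab.codes[i] for i in rng.integers(0, small_vocab.size, 300)]
        preds = [small_vocab.code_at(int(i)) for i in d.argmax(axis=1)]
        rep = calibration_report(d, preds, golds, n_bins=10)
        assert rep["count_correct"].sum() + rep["count_incorrect"].sum() == 300

    def test_confident_correct_model_fills_top_bin(self, small_vocab):
        n = 20
        d = np.full((n, small_vocab.size), 1e-6)
        d[:, 0] = 1.0
        d /= d.sum(axis=1, keepdims=True)
        golds = [small_vocab.codes[0]] * n
        rep = calibration_report(d, golds, golds, n_bins=10)
        assert rep.iloc[-1]["count_correct"] == n
        assert rep["count_incorrect"].sum() == 0

    def test_n_bins_bound(self, small_vocab):
        with pytest.raises(ValueError):
            calibration_report(np.eye(small_vocab.size), [], [], n_bins=1)


class TestBaselineComparison:
    def test_zero_rejects_accuracies_coincide(self):
        golds = ["A00", "B00", "C00"]
        base = [OracleResult(g, False, ("general_principle",)) for g in golds]
        comp = compare_with_baseline(golds, base, golds)
        assert comp.overall_accuracy == comp.nonrejected_accuracy == 1.0
        assert comp.reject_fraction == 0.0

    def test_half_rejects_all_else_correct(self):
        golds = ["A00"] * 10
        base = [OracleResult("A00", False, ("fallback",))] * 5 + [
            OracleResult(None, True, ("reject",))
        ] * 5
        comp = compare_with_baseline(golds, base, golds)
        assert comp.overall_accuracy == 0.5
        assert comp.nonrejected_accuracy == 1.0
        assert comp.reject_fraction == 0.5

    def test_overall_never_exceeds_nonrejected(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(5, 40))
            golds = ["A00"] * n
            base = []
            for _ in range(n):
                if rng.random() < 0.3:
                    base.append(OracleResult(None, True, ("reject",)))
                else:
                    code = "A00" if rng.random() < 0.7 else "B00"
                    base.append(OracleResult(code, False, ("fallback",)))
            comp = compare_with_baseline(golds, base, golds)
            if comp.reject_fraction > 0 and not np.isnan(comp.nonrejected_accuracy):
                assert comp.overall_accuracy <= comp.nonrejected_accuracy
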