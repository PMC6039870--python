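import itertools

import numpy as np
import pytest
from scipy.stats import hypergeom

import luthy
from luthy.calling import CutoffScheme, cutoff_class, roc_analysis


def make_score(c_bret, c_luc, pair_id="p"):
    s = luthy.InteractionScore(pair_id=pair_id)
    s.replicates["exp1"] = luthy.ReplicateScore(c_bret=c_bret, c_luc=c_luc)
    return s


class TestCutoffClass:
    def test_both_membrane_raises_cutoffs(self):
        ann = luthy.LocalizationAnnotation({"A": "membrane", "B": "membrane",
                                            "C": "non_membrane"})
        assert cutoff_class("A", "B", ann) == "membrane_pair"
        assert cutoff_class("A", "C", ann) == "default"
        assert cutoff_class("X", "Y", ann) == "default"  # unannotated default

    def test_membrane_cutoffs_must_dominate(self):
        with pytest.raises(ValueError):
            CutoffScheme(cbret_default=0.05, cbret_membrane=0.03)


class TestCalling:
    @pytest.mark.parametrize(
        "c_bret, c_luc, cls, bret_pos, luc_pos",
        [
            (0.02, 0.01, "default", True, False),
            (0.02, 0.01, "membrane_pair", False, False),
            (0.01, 0.03, "default", True, True),  # inclusive boundary
            (0.0099, 0.0299, "default", False, False),
            (-0.05, 0.5, "default", False, True),
        ],
    )
    def test_inclusive_localization_stratified_cutoffs(
        self, c_bret, c_luc, cls, bret_pos, luc_pos
    ):
        call = luthy.call_interaction(make_score(c_bret, c_luc), cls=cls)
        assert call.bret_positive is bret_pos
        assert call.luc_positive is luc_pos
        assert call.double_positive == (bret_pos and luc_pos)
        assert call.any_positive == (bret_pos or luc_pos)

    def test_membrane_reclassification_never_creates_positives(self):
        # raising cutoffs can only turn positives off
        for cb, cl in itertools.product([-0.02, 0.0, 0.02, 0.04], repeat=2):
            d = luthy.call_interaction(make_score(cb, cl), cls="default")
            m = luthy.call_interaction(make_score(cb, cl), cls="membrane_pair")
            assert not (m.bret_positive and not d.bret_positive)
            assert not (m.luc_positive and not d.luc_positive)


class TestSummaries:
    def test_counts_and_percentages(self):
        calls = [
            luthy.CallResult("a", "default", True, True),
            luthy.CallResult("b", "default", True, False),
            luthy.CallResult("c", "default", False, False),
            luthy.CallResult("d", "default", False, False),
        ]
        df = luthy.summarize_screen(calls, labels={"a": "pos", "b": "pos",
                                                   "c": "neg", "d": "neg"})
        all_row = df[df["group"] == "all"].iloc[0]
        assert all_row["any_positive"] == 2
        assert all_row["double_positive"] == 1
        assert all_row["any_positive_pct"] == pytest.approx(50.0)
        pos_row = df[df["group"] == "pos"].iloc[0]
        assert pos_row["any_positive_pct"] == pytest.approx(100.0)

    def test_raising_cutoffs_is_monotone_in_positive_counts(self, benchmark):
        _, _, scores, _ = benchmark
        prev = None
        for cut in (0.005, 0.01, 0.03, 0.1):
            scheme = CutoffScheme(cbret_default=cut, cluc_default=cut,
                                  cbret_membrane=max(cut, 0.03),
                                  cluc_membrane=max(cut, 0.05))
            calls = luthy.call_screen(scores, scheme)
            counts = luthy.summarize_screen(calls).iloc[0]
            if prev is not None:
                for key in ("bret_positive", "luc_positive",
                            "double_positive", "any_positive"):
                    assert counts[key] <= prev[key]
            prev = counts

    def test_all_negative_screen_summarizes_to_zero(self):
        calls = [luthy.CallResult(f"p{i}", "default", False, False)
                 for i in range(5)]
        row = luthy.summarize_screen(calls).iloc[0]
        assert row["any_positive"] == 0 and row["any_positive_pct"] == 0.0


def auc_by_pair_counting(scores, labels):
    """Independent oracle: concordant-pair (Mann-Whitney) statistic."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_analysis([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(1.0)
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0

    def test_three_of_four_concordant_pairs(self):
        roc = roc_analysis([0.8, 0.2, 0.6, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = rng.integers(4, 51)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            # mix of continuous scores and heavy ties
            scores = np.round(rng.normal(labels * 0.5, 1.0), rng.integers(0, 3))
            roc = roc_analysis(scores, labels)
            assert roc.auc == pytest.approx(
                auc_by_pair_counting(scores, labels), abs=1e-12
            )

    def test_permutation_null_centers_on_half(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = np.array([1] * 100 + [0] * 100)
        aucs = []
        for _ in range(100):
            rng.shuffle(labels)
            aucs.append(roc_analysis(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([0.1, 0.2], [1, 1])

    def test_youden_threshold_is_an_observed_score(self):
        scores = [0.9, 0.7, 0.3, 0.2, 0.1]
        roc = roc_analysis(scores, [1, 1, 1, 0, 0])
        assert roc.youden_threshold in scores
        assert roc.youden_j == pytest.approx(1.0)  # separable panel


def fisher_by_enumeration(table):
    """Sum hypergeometric probabilities <= observed (minimum-likelihood)."""
    (a, b), (c, d) = table
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    total = 0.0
    for a2 in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = rv.pmf(a2)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisher:
    def test_no_association_gives_p_one(self):
        assert luthy.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_association_10v10(self):
        # 2 / C(20,10) — only the two extreme tables are as unlikely
        assert luthy.fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(
            2.0 / 184756.0, rel=1e-9
        )

    def test_matches_enumeration_for_small_margins(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            t = rng.integers(0, 13, size=(2, 2))
            if t.sum() == 0:
                continue
            assert luthy.fisher_exact_2x2(t) == pytest.approx(
                fisher_by_enumeration(t), rel=1e-9, abs=1e-12
            )

    def test_invariance_under_transposition_and_row_column_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2))
            p = luthy.fisher_exact_2x2(t)
            assert luthy.fisher_exact_2x2(t.T) == pytest.approx(p, rel=1e-12)
            assert luthy.fisher_exact_2x2(t[::-1, ::-1]) == pytest.approx(p, rel=1e-12)

    def test_negative_and_fractional_entries_rejected(self):
        with pytest.raises(ValueError):
            luthy.fisher_exact_2x2([[1, -1], [2, 3]])
        with pytest.raises(ValueError):
            luthy.fisher_exact_2x2([[1.5, 1], [2, 3]])


class TestReplicateCorrelation:
    def test_linear_relation_is_perfect_pearson(self):
        x = np.arange(10.0)
        r, p = luthy.replicate_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_monotone_transform_perfect_spearman_only(self):
        x = np.linspace(0, 5, 12)
        y = np.exp(x)
        rho, _ = luthy.replicate_correlation(x, y, method="spearman")
        r, _ = luthy.replicate_correlation(x, y, method="pearson")
        assert rho == pytest.approx(1.0)
        assert r < 1.0

    def test_matches_rank_based_oracle(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0, 6.0, 5.5, 3.5])
        y = np.array([2.0, 0.5, 3.0, 2.5, 4.0, 8.0, 1.0, 7.0, 6.0, 2.2])
        # brute-force Spearman: Pearson of midranks
        def midrank(v):
            order = np.argsort(v)
            ranks = np.empty(len(v))
            ranks[order] = np.arange(1, len(v) + 1)
            for val in np.unique(v):
                ranks[v == val] = ranks[v == val].mean()
            return ranks
        rx, ry = midrank(x), midrank(y)
        manual = np.corrcoef(rx, ry)[0, 1]
        rho, _ = luthy.replicate_correlation(x, y, method="spearman")
        assert rho == pytest.approx(manual, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            luthy.replicate_correlation([1.0, 1.0, 1.0], [1, 2, 3])
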