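import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from msgddi.corpus_io import DDIRecord, EventClass, LabelResources
from msgddi.eval_classify import (
    LabeledPairSet,
    auroc_score,
    balance_negatives,
    candidate_pairs,
    canonical_pair,
    crossval_auroc,
    label_pairs,
    pair_features,
)


def brute_force_auroc(scores, labels):
    """Fraction of concordant positive-negative pairs, ties counting 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


CDT = EventClass("CDT", ("cardiotox",), "Cardiac disorders")


def make_resources():
    return LabelResources(
        sider_lists={"CDT": frozenset({"D_sider"})},
        toxicity_records=[
            ("D_tox", "Severe CARDIOTOXICITY observed in trials"),
            ("D_other", "mild nausea"),
        ],
        ddi_records=[
            DDIRecord("Mitomycin", "Cyclophosphamide", "may be cardiotoxic together"),
            DDIRecord("A", "B", "benign combination"),
        ],
        soc_map={},
    )


class TestLabelPairs:
    def test_ddi_keyword_fires(self):
        ls = label_pairs([("Mitomycin", "Cyclophosphamide")], make_resources(), CDT)
        p = canonical_pair("Mitomycin", "Cyclophosphamide")
        assert ls.labels[p] == 1 and ls.provenance[p] == {"DDI"}

    def test_toxicity_keyword_fires_case_insensitively(self):
        ls = label_pairs([("D_tox", "X")], make_resources(), CDT)
        p = canonical_pair("D_tox", "X")
        assert ls.labels[p] == 1 and ls.provenance[p] == {"Toxicity"}

    def test_sider_membership_fires(self):
        ls = label_pairs([("D_sider", "X")], make_resources(), CDT)
        assert ls.labels[canonical_pair("D_sider", "X")] == 1

    def test_unmatched_pair_is_negative_with_empty_provenance(self):
        ls = label_pairs([("X", "Y")], make_resources(), CDT)
        p = canonical_pair("X", "Y")
        assert ls.labels[p] == 0 and ls.provenance[p] == frozenset()

    def test_strategy_restriction(self):
        ls = label_pairs(
            [("Mitomycin", "Cyclophosphamide")], make_resources(), CDT, strategies=("SIDER",)
        )
        assert ls.labels[canonical_pair("Mitomycin", "Cyclophosphamide")] == 0

    def test_union_provenance_collects_all_firing_strategies(self):
        res = make_resources()
        res.sider_lists = {"CDT": frozenset({"D_tox"})}
        ls = label_pairs([("D_tox", "X")], res, CDT)
        assert ls.provenance[canonical_pair("D_tox", "X")] == {"SIDER", "Toxicity"}


class TestCandidatePairs:
    def test_only_two_drug_reports_with_listed_drugs(self, tiny_corpus):
        pairs = candidate_pairs(tiny_corpus, {"D1", "D2", "D3"})
        assert pairs == [("D1", "D2")]

    def test_duplicates_collapse_keeping_first_appearance_order(self):
        from msgddi.corpus_io import Report, ReportCorpus

        corpus = ReportCorpus(
            (
                Report(("B", "A"), ()),
                Report(("A", "B"), ()),
                Report(("A", "C"), ()),
            )
        )
        assert candidate_pairs(corpus, {"A", "B", "C"}) == [("A", "B"), ("A", "C")]


class TestPairFeatures:
    def test_elementwise_sum(self):
        vecs = {"D1": np.array([1.0, 2.0]), "D2": np.array([3.0, 4.0])}
        assert np.array_equal(pair_features(vecs, ("D1", "D2")), [4.0, 6.0])

    def test_symmetric_in_pair_order(self):
        rng = np.random.default_rng(0)
        vecs = {"a": rng.normal(size=5), "b": rng.normal(size=5)}
        assert np.array_equal(
            pair_features(vecs, ("a", "b")), pair_features(vecs, ("b", "a"))
        )

    def test_missing_drug_names_token(self):
        with pytest.raises(KeyError, match="ghost"):
            pair_features({"a": np.ones(2)}, ("a", "ghost"))


class TestAurocScore:
    def test_six_point_fold_matches_hand_count(self):
        scores = [0.9, 0.8, 0.8, 0.4, 0.3, 0.1]
        labels = [1, 1, 0, 0, 1, 0]
        assert auroc_score(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels)
        )

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 1)), min_size=4, max_size=12
        ).filter(lambda v: 0 < sum(y for _, y in v) < len(v))
    )
    def test_matches_concordant_pair_oracle(self, data):
        scores = [s for s, _ in data]
        labels = [y for _, y in data]
        assert auroc_score(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )

    @given(st.lists(st.integers(-500, 500), min_size=6, max_size=20))
    def test_invariant_to_monotone_transform(self, raw):
        scores = [s / 100 for s in raw]
        labels = [i % 2 for i in range(len(scores))]
        a1 = auroc_score(scores, labels)
        a2 = auroc_score([3 * s + 7 for s in scores], labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]  # both classes guaranteed
        a = auroc_score(scores, labels)
        assert auroc_score(scores, 1 - labels) == pytest.approx(1 - a, abs=1e-12)


def toy_labelset(n, pos_frac, seed, cls=CDT):
    rng = np.random.default_rng(seed)
    pairs = [(f"a{i}", f"b{i}") for i in range(n)]
    labels = {canonical_pair(*p): int(rng.random() < pos_frac) for p in pairs}
    pairs = [canonical_pair(*p) for p in pairs]
    return LabeledPairSet(
        pairs=pairs, labels=labels, event_class=cls, provenance={p: frozenset() for p in pairs}
    )


class TestCrossvalAuroc:
    def test_separable_features_reach_auroc_one(self):
        ls = toy_labelset(100, 0.5, seed=0)
        feats = {
            p: np.array([ls.labels[p] * 2.0 - 1.0, 0.5]) for p in ls.pairs
        }
        cv = crossval_auroc(feats, ls, n_folds=10, seed=1)
        assert cv.mean_auroc == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(2)
        ls = toy_labelset(2000, 0.5, seed=2)
        feats = {p: rng.normal(size=8) for p in ls.pairs}
        cv = crossval_auroc(feats, ls, n_folds=10, seed=3)
        assert 0.45 <= cv.mean_auroc <= 0.55

    def test_stratification_keeps_fold_positive_fractions_close(self):
        ls = toy_labelset(200, 0.3, seed=5)
        feats = {p: np.random.default_rng(6).normal(size=4) for p in ls.pairs}
        from sklearn.model_selection import StratifiedKFold

        y = np.array([ls.labels[p] for p in ls.pairs])
        global_frac = y.mean()
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=7)
        for _, test_idx in skf.split(np.zeros((len(y), 1)), y):
            assert abs(y[test_idx].mean() - global_frac) <= 1.0 / len(test_idx)

    def test_single_class_fold_raises(self):
        ls = toy_labelset(10, 0.5, seed=8)
        # force 2 positives across 10 folds -> some folds lack positives
        for p in ls.pairs[2:]:
            ls.labels[p] = 0
        for p in ls.pairs[:2]:
            ls.labels[p] = 1
        feats = {p: np.ones(2) for p in ls.pairs}
        with pytest.raises(ValueError, match="single class|fewer folds"):
            crossval_auroc(feats, ls, n_folds=10, seed=9)

    def test_too_few_examples_rejected(self):
        ls = toy_labelset(3, 0.34, seed=10)
        feats = {p: np.ones(2) for p in ls.pairs}
        with pytest.raises(ValueError, match="at least 2"):
            crossval_auroc(feats, ls)

    def test_balance_negatives_matches_positive_count(self):
        ls = toy_labelset(100, 0.2, seed=11)
        bal = balance_negatives(ls, seed=12)
        assert bal.n_negative == bal.n_positive == ls.n_positive
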