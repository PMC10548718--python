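"""Metric definitions against brute-force oracles, CV harness, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hesiagraph.dataset import LabelledPair, PairSet, make_pairset, split_test
from hesiagraph.evaluation import (confusion, cross_validate, metrics,
                                   rank_drugs)
from hesiagraph.hesianet import ChannelConfig, ModelConfig, TrainConfig, \
    init_model


def auc_by_pair_counting(labels, probs):
    """Exhaustive Mann-Whitney oracle: concordant pairs + half ties."""
    pos = [p for y, p in zip(labels, probs) if y == 1]
    neg = [p for y, p in zip(labels, probs) if y == 0]
    score = sum(1.0 if pp > pn else 0.5 if pp == pn else 0.0
                for pp in pos for pn in neg)
    return score / (len(pos) * len(neg))


def auc_pr_by_threshold_sweep(labels, probs):
    """Step-interpolated area via a sweep over all distinct scores."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    thresholds = sorted(set(probs), reverse=True)
    area, prev_recall = 0.0, 0.0
    n_pos = int(labels.sum())
    for thr in thresholds:
        calls = probs >= thr
        tp = int(np.sum(calls & (labels == 1)))
        precision = tp / int(calls.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


class TestConfusion:
    def test_basic_counts(self):
        cm = confusion([1, 1], [0.6, 0.4], 0.5)
        assert (cm.TP, cm.FN, cm.FP, cm.TN) == (1, 1, 0, 0)

    def test_all_correct(self):
        cm = confusion([1, 0, 1], [0.9, 0.1, 0.8], 0.5)
        assert cm.FP == cm.FN == 0 and cm.total == 3

    def test_empty(self):
        cm = confusion([], [], 0.5)
        assert cm.total == 0

    def test_strict_threshold(self):
        cm = confusion([1], [0.5], 0.5)
        assert cm.TP == 0 and cm.FN == 1


class TestMetrics:
    def test_perfect_separation(self):
        rep = metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert rep.auc_roc == 1.0
        assert rep.brier == pytest.approx((0.01 + 0.04 + 0.04 + 0.01) / 4)
        assert rep.acc == 1.0 and rep.mcc == 1.0 and rep.f1 == 1.0

    def test_three_of_four_concordant(self):
        rep = metrics([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1])
        assert rep.auc_roc == pytest.approx(0.75)

    def test_paper_variant_f1_is_half_standard(self):
        std = metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        var = metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1], paper_variant=True)
        assert var.f1 == pytest.approx(std.f1 / 2)

    def test_single_class_undefined_metrics(self):
        rep = metrics([1, 1, 1], [0.9, 0.8, 0.7])
        assert set(rep.undefined) == {"auc_roc", "auc_pr", "mcc"}
        assert np.isnan(rep.auc_roc)
        assert rep.acc == 1.0  # threshold metrics still computed

    def test_mcc_sign_flips_when_predictions_inverted(self):
        labels = [1, 0, 1, 1, 0, 0, 1, 0]
        probs = np.array([0.8, 0.3, 0.7, 0.6, 0.4, 0.2, 0.9, 0.35])
        a = metrics(labels, probs)
        b = metrics(labels, 1 - probs)
        assert b.mcc == pytest.approx(-a.mcc)
        assert b.acc == pytest.approx(1 - a.acc)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.integers(0, 8).map(lambda i: i / 8)),
                    min_size=2, max_size=12))
    def test_auc_roc_equals_pair_counting_oracle(self, data):
        labels = [y for y, _ in data]
        probs = [p for _, p in data]
        if len(set(labels)) < 2:
            return
        rep = metrics(labels, probs)
        assert rep.auc_roc == pytest.approx(
            auc_by_pair_counting(labels, probs), abs=1e-12)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=2, max_size=12))
    def test_auc_pr_equals_threshold_sweep_oracle(self, data):
        labels = [y for y, _ in data]
        probs = [p for _, p in data]
        if len(set(labels)) < 2:
            return
        rep = metrics(labels, probs)
        assert rep.auc_pr == pytest.approx(
            auc_pr_by_threshold_sweep(labels, probs), abs=1e-12)

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(0)
        probs = rng.random(40)
        labels = np.array([1] * 20 + [0] * 20)
        aucs = []
        for _ in range(200):
            rng.shuffle(labels)
            if labels.sum() in (0, len(labels)):
                continue
            aucs.append(metrics(labels, probs).auc_roc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            metrics([1, 0], [0.5])


TINY_CFG = ModelConfig(channel=ChannelConfig(input_dim=8, layer_widths=(6, 4),
                                             dropout_rate=0.0), head_width=3,
                       kl_weight=0.0)
TINY_TRAIN = TrainConfig(learning_rate=1e-3, max_epochs=3,
                         early_stop_patience=5, seed=0)


@pytest.fixture(scope="module")
def tiny_pairset(random_table):
    pos = {(f"r{i}", f"p{i % 4}") for i in range(6)}
    neg = {(f"r{i}", f"p{(i + 1) % 4}") for i in range(6)} - pos
    ps = make_pairset(pos, neg)
    train, test = split_test(ps, 0.34, seed=0)
    return PairSet(train.pairs + test.pairs, train.provenance)


class TestCrossValidate:
    def test_fold_repeat_grid_size(self, tiny_pairset, random_table):
        rep = cross_validate(tiny_pairset, random_table, TINY_CFG, TINY_TRAIN,
                             folds=2, repeats=2, seed=1, balance="RUS")
        assert len(rep) == 4
        assert set(rep.frame["repeat"]) == {0, 1}
        assert set(rep.frame["fold"]) == {0, 1}

    def test_deterministic_under_seed(self, tiny_pairset, random_table):
        a = cross_validate(tiny_pairset, random_table, TINY_CFG, TINY_TRAIN,
                           folds=2, repeats=1, seed=2, balance="RUS")
        b = cross_validate(tiny_pairset, random_table, TINY_CFG, TINY_TRAIN,
                           folds=2, repeats=1, seed=2, balance="RUS")
        assert a.frame.equals(b.frame)

    def test_identical_rows_zero_std(self, tiny_pairset, random_table):
        rep = cross_validate(tiny_pairset, random_table, TINY_CFG, TINY_TRAIN,
                             folds=2, repeats=1, seed=2, balance="RUS")
        dup = type(rep)(rep.frame.iloc[[0, 0, 0]])
        assert dup.std().fillna(0).max() == 0
        assert dup.mean()["acc"] == rep.frame["acc"].iloc[0]

    def test_too_few_folds(self, tiny_pairset, random_table):
        with pytest.raises(ValueError):
            cross_validate(tiny_pairset, random_table, TINY_CFG, TINY_TRAIN,
                           folds=1, repeats=1, seed=0)


class TestRankDrugs:
    def test_sorted_by_probability_with_tie_break(self, random_table):
        model = init_model(TINY_CFG, seed=4)
        # duplicate-vector drugs score identically -> lexicographic order
        drugs = ["r0", "r1", "r2", "r3", "r4", "r5"]
        ranked = rank_drugs(model, random_table, "p0", drugs, top_n=6)
        probs = [p for _, p in ranked]
        assert probs == sorted(probs, reverse=True)
        for (d1, p1), (d2, p2) in zip(ranked, ranked[1:]):
            if p1 == p2:
                assert d1 < d2

    def test_top_n_truncates(self, random_table):
        model = init_model(TINY_CFG, seed=4)
        assert len(rank_drugs(model, random_table, "p0",
                              ["r0", "r1", "r2"], top_n=2)) == 2
        assert len(rank_drugs(model, random_table, "p0",
                              ["r0", "r1"], top_n=10)) == 2

    def test_oov_disease(self, random_table):
        model = init_model(TINY_CFG, seed=4)
        with pytest.raises(KeyError):
            rank_drugs(model, random_table, "unknown", ["r0"], top_n=1)

    def test_tied_scores_stable_across_calls(self, random_table):
        model = init_model(TINY_CFG, seed=4)
        a = rank_drugs(model, random_table, "p1", ["r3", "r1", "r2"], 3)
        b = rank_drugs(model, random_table, "p1", ["r2", "r3", "r1"], 3)
        assert a == b
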