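"""Confusion metrics, RF harness, and group-consistent prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import confusion_recount
from pahtrait.annotate import GenomeProfile
from pahtrait.refdb import CLUSTER_GENES, FAMILY_NAMES
from pahtrait.trait_predict import (
    RFConfig,
    assemble_training_set,
    compute_metrics,
    metrics_from_labels,
    predict_grouped,
    train_and_tune,
)


class TestComputeMetrics:
    def test_worked_example(self):
        m = compute_metrics(tp=3, tn=5, fp=1, fn=1)
        assert m.sn == pytest.approx(0.75)
        assert m.sp == pytest.approx(5 / 6)
        assert m.acc == pytest.approx(0.8)
        assert m.mcc == pytest.approx(14 / 24)

    def test_perfect_classifier(self):
        m = compute_metrics(tp=7, tn=13, fp=0, fn=0)
        assert m.mcc == 1.0
        assert m.acc == 1.0

    def test_undefined_ratios_are_none_not_zero(self):
        m = compute_metrics(tp=0, tn=5, fp=0, fn=0)
        assert m.sn is None
        assert m.mcc is None
        assert m.sp == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 1, 1, 1)

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=60))
    def test_matches_brute_force_recount(self, pairs):
        """Property: metrics from label vectors equal an explicit recount."""
        y_true = [t for t, _ in pairs]
        y_pred = [p for _, p in pairs]
        tp, tn, fp, fn = confusion_recount(y_true, y_pred)
        m = metrics_from_labels(y_true, y_pred)
        assert (m.tp, m.tn, m.fp, m.fn) == (tp, tn, fp, fn)
        ref = compute_metrics(tp, tn, fp, fn)
        assert m == ref
        if m.mcc is not None:
            assert -1 <= m.mcc <= 1

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(*(st.integers(0, 40) for _ in range(4))))
    def test_mcc_invariant_under_class_relabeling(self, cells):
        tp, tn, fp, fn = cells
        if tp + tn + fp + fn == 0:
            return
        a = compute_metrics(tp, tn, fp, fn).mcc
        b = compute_metrics(tn, tp, fn, fp).mcc  # swap positive/negative
        if a is None or b is None:
            return
        assert a == pytest.approx(b)


class TestAssembleTrainingSet:
    @staticmethod
    def _data(n_pos=20, n_neg=200, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"g{i}" for i in range(n_pos + n_neg)]
        X = pd.DataFrame(rng.normal(size=(n_pos + n_neg, 17)),
                         index=idx, columns=list(FAMILY_NAMES))
        y = pd.Series([True] * n_pos + [False] * n_neg, index=idx)
        return X, y

    def test_training_negatives_follow_ratio_arithmetic(self):
        X, y = self._data()
        split = assemble_training_set(X, y, RFConfig(neg_pos_ratio=5, seed=1))
        # round(5 * 20 * 2/3) = 67 training negatives alongside the
        # positive split; test side untouched
        assert int((~split.y_train).sum()) == 67
        assert int(split.y_train.sum()) == round(20 * 2 / 3)
        assert int(split.y_test.sum()) == 20 - round(20 * 2 / 3)
        assert int((~split.y_test).sum()) == 200 - round(200 * 2 / 3)

    def test_ratio_outside_3_to_8_rejected(self):
        with pytest.raises(ValueError):
            RFConfig(neg_pos_ratio=2)
        with pytest.raises(ValueError):
            RFConfig(neg_pos_ratio=9)

    def test_same_seed_identical_split(self):
        X, y = self._data()
        cfg = RFConfig(seed=11)
        a = assemble_training_set(X, y, cfg)
        b = assemble_training_set(X, y, cfg)
        assert list(a.X_train.index) == list(b.X_train.index)
        assert list(a.X_test.index) == list(b.X_test.index)

    def test_too_few_negatives_rejected(self):
        X, y = self._data(n_pos=10, n_neg=2)
        with pytest.raises(ValueError, match="negatives"):
            assemble_training_set(X, y, RFConfig())


def _separable_cohort(n_pos=18, n_neg=90, seed=0, noise=0.0):
    """Degraders carry high nah-gene scores; negatives are zero vectors."""
    rng = np.random.default_rng(seed)
    rows, labels, idx = [], [], []
    for i in range(n_pos + n_neg):
        vec = np.zeros(17)
        pos = i < n_pos
        if pos:
            for f in CLUSTER_GENES["nah"]:
                vec[FAMILY_NAMES.index(f)] = rng.normal(500, 40)
        else:
            if rng.random() < 0.2:  # stray single gene
                vec[rng.integers(17)] = rng.normal(400, 40)
        rows.append(vec)
        labels.append(pos)
        idx.append(f"g{i}")
    y = pd.Series(labels, index=idx)
    if noise:
        flip = rng.random(len(y)) < noise
        y = y ^ flip
    return pd.DataFrame(rows, index=idx, columns=list(FAMILY_NAMES)), y


class TestTrainAndTune:
    def test_separable_cohort_recovers_labels(self):
        X, y = _separable_cohort(seed=1)
        cfg = RFConfig(n_tree=300, m_try_sweep=(1, 2, 3, 5, 8), seed=2)
        tuned = train_and_tune(X, y, cfg)
        assert tuned.test_metrics.mcc >= 0.95
        top2 = set(tuned.importance.index[:2])
        assert top2 <= set(CLUSTER_GENES["nah"])

    def test_mtry_curve_covers_sweep_and_selection_rule(self):
        X, y = _separable_cohort(seed=3)
        cfg = RFConfig(n_tree=200, m_try_sweep=(1, 4, 9), seed=4)
        tuned = train_and_tune(X, y, cfg)
        assert list(tuned.mtry_curve["m_try"]) == [1, 4, 9]
        min_err = tuned.mtry_curve["oob_error"].min()
        sel_err = tuned.mtry_curve.set_index("m_try").loc[tuned.selected_m_try, "oob_error"]
        assert sel_err <= min_err + cfg.mtry_tolerance

    def test_shuffled_labels_give_no_signal(self):
        mccs = []
        for seed in range(5):
            X, y = _separable_cohort(seed=seed)
            rng = np.random.default_rng(100 + seed)
            y_shuf = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            cfg = RFConfig(n_tree=100, m_try_sweep=(4,), seed=seed)
            try:
                tuned = train_and_tune(X, y_shuf, cfg)
            except ValueError:
                continue
            if tuned.test_metrics.mcc is not None:
                mccs.append(tuned.test_metrics.mcc)
        assert mccs and np.mean(np.abs(mccs)) < 0.3

    def test_label_noise_bounded_degradation(self):
        """With flip rate eps <= 5%, held-out MCC stays >= 1 - 4 eps."""
        eps = 0.05
        mccs = []
        for seed in range(3):
            X, y = _separable_cohort(seed=seed, noise=eps)
            cfg = RFConfig(n_tree=200, m_try_sweep=(2, 5), seed=seed)
            tuned = train_and_tune(X, y, cfg)
            mccs.append(tuned.test_metrics.mcc)
        assert np.mean(mccs) >= 1 - 4 * eps

    def test_single_class_training_rejected(self):
        X, y = _separable_cohort(n_pos=6, n_neg=30)
        with pytest.raises(ValueError):
            train_and_tune(X, pd.Series(False, index=y.index), RFConfig(n_tree=50))

    def test_deterministic_given_seed(self):
        X, y = _separable_cohort(seed=5)
        cfg = RFConfig(n_tree=100, m_try_sweep=(3,), seed=6)
        a = train_and_tune(X, y, cfg)
        b = train_and_tune(X, y, cfg)
        assert a.selected_m_try == b.selected_m_try
        assert a.mtry_curve.equals(b.mtry_curve)
        assert (a.model.predict(X.to_numpy()) == b.model.predict(X.to_numpy())).all()


class _FixedModel:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value, dtype=bool)


class TestPredictGrouped:
    @staticmethod
    def _profile(gid, group, families):
        vec = np.zeros(17)
        for f in families:
            vec[FAMILY_NAMES.index(f)] = 200.0
        return GenomeProfile(genome_id=gid, feature_vector=vec, group_tag=group)

    def test_mycobacteriaceae_nah_only_not_output(self):
        # positive model call, but the stratum's pathway evidence is absent
        bundle = {g: _FixedModel(True) for g in
                  ("gram_negative", "gram_positive", "mycobacteriaceae")}
        p = self._profile("m1", "mycobacteriaceae", CLUSTER_GENES["nah"])
        (pred,) = predict_grouped(bundle, [p])
        assert pred.positive and not pred.consistent and not pred.output

    def test_gram_negative_nah_cluster_output(self):
        bundle = {"gram_negative": _FixedModel(True)}
        p = self._profile("g1", "gram_negative", CLUSTER_GENES["nah"])
        (pred,) = predict_grouped(bundle, [p])
        assert pred.output

    def test_negative_call_never_output(self):
        bundle = {"gram_negative": _FixedModel(False)}
        p = self._profile("g1", "gram_negative", CLUSTER_GENES["nah"])
        (pred,) = predict_grouped(bundle, [p])
        assert not pred.output

    def test_gram_positive_accepts_nar_or_nid_phd(self):
        bundle = {"gram_positive": _FixedModel(True)}
        for fams in (CLUSTER_GENES["nar"][:1], CLUSTER_GENES["nid_phd"][:1]):
            (pred,) = predict_grouped(bundle, [self._profile("g", "gram_positive", fams)])
            assert pred.consistent

    def test_missing_group_model_errors(self):
        p = self._profile("g1", "gram_negative", [])
        with pytest.raises(ValueError, match="no model"):
            predict_grouped({}, [p])
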