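"""Genotype-to-phenotype prediction of PAH-degradation capacity.

A random forest is trained per taxonomic stratum (Gram-negative,
Gram-positive, Mycobacteriaceae) on the 17-dimensional per-genome feature
vector of maximum passing bit scores.  The harness around the stock
learner is where the method lives:

* class-imbalance control — training negatives are subsampled to a fixed
  negative:positive ratio (3-8x) while the held-out test set is untouched;
* hyperparameter sweep — ``n_tree`` fixed at 2000, ``m_try`` (features
  per split) swept 1..17 and selected by out-of-bag error (smallest value
  within 0.002 of the minimum, a reproducible reading of "levels off");
* evaluation — sensitivity, specificity, accuracy and Matthews
  correlation coefficient from the confusion matrix;
* group-consistency filtering — a positive call is *output* only when the
  genome carries cluster evidence mechanistically plausible for its
  stratum (Gram-negative: nah; Gram-positive: nar or nid/phd;
  Mycobacteriaceae: nid/phd only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import GROUP_TAGS, GenomeProfile
from .refdb import CLUSTER_GENES, FAMILY_NAMES

#: Cluster evidence admissible per stratum for the consistency filter.
CONSISTENT_CLUSTERS: dict[str, tuple[str, ...]] = {
    "gram_negative": ("nah",),
    "gram_positive": ("nar", "nid_phd"),
    "mycobacteriaceae": ("nid_phd",),
}


# ---------------------------------------------------------------------------
# confusion-matrix metrics


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sn/Sp/Acc/MCC from confusion counts; ``None`` marks an undefined
    ratio (zero denominator) — never silently coerced to 0."""

    tp: int
    tn: int
    fp: int
    fn: int
    sn: float | None
    sp: float | None
    acc: float | None
    mcc: float | None


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Evaluate Sn = TP/(TP+FN), Sp = TN/(TN+FP),
    Acc = (TP+TN)/(TP+TN+FP+FN) and
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TN+FN)(TP+FN)(TN+FP))."""
    cells = (tp, tn, fp, fn)
    if any(c < 0 for c in cells) or any(int(c) != c for c in cells):
        raise ValueError("confusion counts must be non-negative integers")
    if sum(cells) == 0:
        raise ValueError("confusion matrix is empty")

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sn = ratio(tp, tp + fn)
    sp = ratio(tn, tn + fp)
    acc = ratio(tp + tn, sum(cells))
    denom = (tp + fp) * (tn + fn) * (tp + fn) * (tn + fp)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else None
    return ConfusionMetrics(tp, tn, fp, fn, sn, sp, acc, mcc)


def metrics_from_labels(y_true, y_pred) -> ConfusionMetrics:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    tp = int((y_true & y_pred).sum())
    tn = int((~y_true & ~y_pred).sum())
    fp = int((~y_true & y_pred).sum())
    fn = int((y_true & ~y_pred).sum())
    return compute_metrics(tp, tn, fp, fn)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RFConfig:
    n_tree: int = 2000
    m_try_sweep: tuple[int, ...] = tuple(range(1, 18))
    neg_pos_ratio: int = 5
    split_fraction: float = 2 / 3
    seed: int = 0
    #: OOB-error slack under which the smallest m_try is taken.
    mtry_tolerance: float = 0.002

    def __post_init__(self) -> None:
        if not all(1 <= m <= 17 for m in self.m_try_sweep):
            raise ValueError("m_try values must lie in 1..17")
        if not 3 <= self.neg_pos_ratio <= 8:
            raise ValueError("neg_pos_ratio must lie in 3..8")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


@dataclass
class TrainTestSplit:
    X_train: pd.DataFrame
    y_train: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series


def assemble_training_set(
    features: pd.DataFrame, labels: pd.Series, config: RFConfig
) -> TrainTestSplit:
    """Seeded 2/3-1/3 split with training-side negative subsampling.

    The training negatives are subsampled to
    ``round(neg_pos_ratio * n_positives * split_fraction)`` (capped by
    availability); the test side is left untouched so evaluation reflects
    the natural class balance.
    """
    labels = labels.astype(bool).reindex(features.index)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos < 1:
        raise ValueError("need at least one positive genome")
    if n_neg < config.neg_pos_ratio:
        raise ValueError(
            f"need >= neg_pos_ratio ({config.neg_pos_ratio}) negatives, have {n_neg}"
        )
    rng = np.random.default_rng(config.seed)
    pos_idx = labels[labels].index.to_numpy()
    neg_idx = labels[~labels].index.to_numpy()
    rng.shuffle(pos_idx)
    rng.shuffle(neg_idx)
    n_train_pos = int(round(config.split_fraction * n_pos))
    n_train_neg_pool = int(round(config.split_fraction * n_neg))
    if n_train_pos in (0, n_pos) or n_train_neg_pool in (0, n_neg):
        raise ValueError("split leaves an empty train or test class")
    target_neg = int(round(config.neg_pos_ratio * n_pos * config.split_fraction))
    train_ids = np.concatenate(
        [pos_idx[:n_train_pos], neg_idx[: min(target_neg, n_train_neg_pool)]]
    )
    test_ids = np.concatenate([pos_idx[n_train_pos:], neg_idx[n_train_neg_pool:]])
    return TrainTestSplit(
        X_train=features.loc[train_ids],
        y_train=labels.loc[train_ids],
        X_test=features.loc[test_ids],
        y_test=labels.loc[test_ids],
    )


# ---------------------------------------------------------------------------
# training and tuning


@dataclass
class TunedModel:
    model: object
    selected_m_try: int
    mtry_curve: pd.DataFrame  # columns m_try, oob_error
    importance: pd.DataFrame  # mean_decrease_accuracy, mean_decrease_gini
    split: TrainTestSplit
    test_metrics: ConfusionMetrics


def train_and_tune(
    features: pd.DataFrame, labels: pd.Series, config: RFConfig | None = None
) -> TunedModel:
    """Sweep m_try at fixed n_tree, select by OOB error, refit and score.

    Mean decrease accuracy is permutation importance on the held-out
    split; mean decrease Gini is the forest's impurity importance.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    config = config or RFConfig()
    split = assemble_training_set(features, labels, config)
    if split.y_train.nunique() < 2:
        raise ValueError("training set is single-class; cannot fit a classifier")

    max_m = min(17, features.shape[1])
    curve = []
    models = {}
    for m in config.m_try_sweep:
        if m > max_m:
            continue
        rf = RandomForestClassifier(
            n_estimators=config.n_tree, max_features=m, oob_score=True,
            bootstrap=True, random_state=config.seed, n_jobs=1,
        )
        rf.fit(split.X_train.to_numpy(), split.y_train.to_numpy())
        curve.append((m, 1.0 - rf.oob_score_))
        models[m] = rf
    mtry_curve = pd.DataFrame(curve, columns=["m_try", "oob_error"])
    min_err = mtry_curve["oob_error"].min()
    ok = mtry_curve[mtry_curve["oob_error"] <= min_err + config.mtry_tolerance]
    selected = int(ok["m_try"].min())
    model = models[selected]

    perm = permutation_importance(
        model, split.X_test.to_numpy(), split.y_test.to_numpy(),
        n_repeats=10, random_state=config.seed,
    )
    importance = pd.DataFrame(
        {
            "mean_decrease_accuracy": perm.importances_mean,
            "mean_decrease_gini": model.feature_importances_,
        },
        index=list(features.columns),
    ).sort_values("mean_decrease_accuracy", ascending=False)

    y_hat = model.predict(split.X_test.to_numpy())
    metrics = metrics_from_labels(split.y_test.to_numpy(), y_hat)
    return TunedModel(model, selected, mtry_curve, importance, split, metrics)


# ---------------------------------------------------------------------------
# grouped prediction


@dataclass(frozen=True)
class Prediction:
    genome_id: str
    group_tag: str
    positive: bool
    consistent: bool

    @property
    def output(self) -> bool:
        """Only group-consistent positive calls are reported."""
        return self.positive and self.consistent


def _has_consistent_evidence(profile: GenomeProfile, group_tag: str) -> bool:
    present = profile.present_families()
    return any(
        any(g in present for g in CLUSTER_GENES[ct])
        for ct in CONSISTENT_CLUSTERS[group_tag]
    )


def predict_grouped(
    model_bundle: dict[str, object], profiles: list[GenomeProfile]
) -> list[Prediction]:
    """Score each genome with its stratum's model; filter for mechanism.

    ``model_bundle`` maps group tags to fitted classifiers (anything with
    ``predict`` over the 17-feature vector).  A genome whose group has no
    model raises.
    """
    preds = []
    for p in profiles:
        if p.group_tag not in GROUP_TAGS:
            raise ValueError(f"{p.genome_id}: unknown group {p.group_tag!r}")
        model = model_bundle.get(p.group_tag)
        if model is None:
            raise ValueError(f"no model for group {p.group_tag!r}")
        positive = bool(model.predict(p.feature_vector.reshape(1, -1))[0])
        preds.append(
            Prediction(
                genome_id=p.genome_id,
                group_tag=p.group_tag,
                positive=positive,
                consistent=_has_consistent_evidence(p, p.group_tag),
            )
        )
    return preds


def predictions_table(preds: list[Prediction]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.genome_id, p.group_tag, p.positive, p.consistent, p.output) for p in preds],
        columns=["genome_id", "group_tag", "positive", "consistent", "output"],
    )


def features_from_profiles(profiles: list[GenomeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [p.feature_vector for p in profiles],
        columns=list(FAMILY_NAMES),
        index=[p.genome_id for p in profiles],
    )
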