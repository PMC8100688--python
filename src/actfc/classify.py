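"""Linear-SVM comparison of all-FC vs significant-FC (DFC) feature sets.

Subjects are classified from their FC feature vectors with a soft-margin
linear SVM (C = 1) over repeated stratified train/test splits (default
100 repeats at test fraction 0.2). Two selection protocols are provided:

* ``paper`` — the DFC edge subset is computed once on ALL subjects and the
  same subset is reused in every split. This reproduces the original
  protocol but lets the test subjects influence feature selection
  (selection leakage), biasing accuracy upward under the null.
* ``nested`` — the edge-wise test is recomputed inside each training split
  only, so held-out subjects never touch feature selection. This is the
  unbiased protocol and the recommended default for real inference.

A 10-fold cross-validation score on the training portion is exposed as an
optional overfitting diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedShuffleSplit, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .fc import FcFeatures, edgewise_test

logger = logging.getLogger("actfc.classify")

__all__ = ["ClassificationReport", "run_classification", "compare_feature_sets"]


@dataclass
class ClassificationReport:
    """Per-repeat metrics of one classification protocol."""

    feature_set: str
    selection_mode: str
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_repeats: int
    test_fraction: float
    seed: int
    positive_label: str
    edges_used: list[np.ndarray | None] = field(default_factory=list)
    cv_scores: np.ndarray | None = None

    def summary(self) -> dict[str, tuple[float, float]]:
        return {
            name: (float(np.mean(vals)), float(np.std(vals)))
            for name, vals in [
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
            ]
        }


def _feature_matrix(features: list[FcFeatures]) -> tuple[np.ndarray, np.ndarray]:
    edge_index = features[0].edge_index
    for f in features:
        if not np.array_equal(f.edge_index, edge_index):
            raise ValueError("subjects disagree on the edge index")
    x = np.vstack([f.values for f in features])
    y = np.asarray([f.group_id for f in features])
    return x, y


def _select_edges(
    train_feats: list[FcFeatures],
    labels: np.ndarray,
    alpha: float,
    criterion: str,
    top_k: int | None,
) -> np.ndarray:
    groups = np.unique(labels)
    ga = [f for f, l in zip(train_feats, labels) if l == groups[0]]
    gb = [f for f, l in zip(train_feats, labels) if l == groups[1]]
    res = edgewise_test(ga, gb, alpha=alpha)
    if criterion == "top_k":
        if not top_k:
            raise ValueError("top_k selection needs a positive top_k")
        return np.argsort(res.p_value)[:top_k]
    if criterion == "p":
        return np.flatnonzero(res.p_value <= alpha)
    if criterion == "q":
        return np.flatnonzero(res.significant)
    raise ValueError(f"unknown selection criterion {criterion!r}")


def run_classification(
    features: list[FcFeatures],
    edge_subset: np.ndarray | None = None,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    selection_mode: str = "paper",
    C: float = 1.0,
    alpha: float = 0.05,
    selection_criterion: str = "q",
    top_k: int | None = None,
    positive_label: str | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    cv_check: bool = False,
) -> ClassificationReport:
    """Repeated-split linear-SVM evaluation of one feature set.

    ``edge_subset`` (positions into the edge index) restricts the features;
    ``None`` uses all edges. In ``selection_mode="nested"`` the subset is
    recomputed from the training subjects of each split instead, using
    ``selection_criterion`` ("q": FDR-significant, "p": uncorrected
    p <= alpha, "top_k": the top_k smallest p). Features are standardised
    with training-set mean/sd before the SVM. Sensitivity is the recall of
    ``positive_label`` (default: the lexicographically larger group label,
    the condition-of-interest analog), specificity the recall of the other
    class.
    """
    x, y = _feature_matrix(features)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two groups required")
    counts = {c: int((y == c).sum()) for c in classes}
    if min(counts.values()) < 4:
        raise ValueError(f"need >= 4 subjects per class, got {counts}")
    if positive_label is None:
        positive_label = str(classes[-1])
    neg_label = classes[classes != positive_label][0]

    if splits is None:
        splits = make_splits(y, n_repeats, test_fraction, seed)
    n_repeats = len(splits)

    acc = np.empty(n_repeats)
    sens = np.empty(n_repeats)
    spec = np.empty(n_repeats)
    edges_used: list[np.ndarray | None] = []
    cv_scores = np.empty(n_repeats) if cv_check else None
    for i, (tr, te) in enumerate(splits):
        if np.unique(y[tr]).size < 2:  # cannot happen with stratified splits
            raise RuntimeError("single-class training set")
        if selection_mode == "nested":
            sel = _select_edges(
                [features[j] for j in tr], y[tr], alpha, selection_criterion, top_k
            )
            if sel.size == 0:
                sel = _select_edges([features[j] for j in tr], y[tr], alpha, "top_k",
                                    top_k or 1)
        elif selection_mode == "paper":
            sel = edge_subset if edge_subset is not None else np.arange(x.shape[1])
        else:
            raise ValueError(f"unknown selection_mode {selection_mode!r}")
        edges_used.append(None if selection_mode == "paper" and edge_subset is None
                          else np.asarray(sel))
        clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
        clf.fit(x[np.ix_(tr, sel)], y[tr])
        pred = clf.predict(x[np.ix_(te, sel)])
        truth = y[te]
        acc[i] = np.mean(pred == truth)
        pos = truth == positive_label
        neg = truth == neg_label
        sens[i] = np.mean(pred[pos] == positive_label) if pos.any() else np.nan
        spec[i] = np.mean(pred[neg] == neg_label) if neg.any() else np.nan
        if cv_check:
            n_tr = tr.size
            folds = min(10, min(int((y[tr] == c).sum()) for c in classes))
            cv_scores[i] = cross_val_score(
                clf, x[np.ix_(tr, sel)], y[tr], cv=folds
            ).mean()
    return ClassificationReport(
        feature_set="all_fc" if edge_subset is None and selection_mode == "paper" else "dfc",
        selection_mode=selection_mode,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        n_repeats=n_repeats,
        test_fraction=test_fraction,
        seed=seed,
        positive_label=str(positive_label),
        edges_used=edges_used,
        cv_scores=cv_scores,
    )


def make_splits(
    y: np.ndarray, n_repeats: int, test_fraction: float, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified train/test partitions, reusable across arms."""
    sss = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_fraction, random_state=int(seed) % (2**32)
    )
    return [(tr, te) for tr, te in sss.split(np.zeros(len(y)), y)]


def compare_feature_sets(
    features: list[FcFeatures],
    dfc,
    n_repeats: int = 100,
    test_fraction: float = 0.2,
    seed: int = 0,
    C: float = 1.0,
    selection_mode: str = "paper",
    alpha: float = 0.05,
    selection_criterion: str = "q",
    top_k: int | None = None,
    positive_label: str | None = None,
) -> dict:
    """Paired all-FC vs DFC comparison with identical splits in both arms.

    Returns the two reports plus per-repeat paired metric differences
    (DFC minus all-FC) and a paired t test on the accuracy difference.
    With an empty DFC set only the all-FC arm is run, with a notice.
    """
    x, y = _feature_matrix(features)
    splits = make_splits(y, n_repeats, test_fraction, seed)
    all_report = run_classification(
        features, edge_subset=None, seed=seed, C=C, splits=splits,
        test_fraction=test_fraction, positive_label=positive_label,
    )
    sig = np.flatnonzero(dfc.significant) if dfc is not None else np.array([], int)
    if selection_mode == "paper" and sig.size == 0:
        logger.warning("empty DFC set: reporting the all-FC arm only")
        return {"all_fc": all_report, "dfc": None, "notice": "empty DFC set"}
    dfc_report = run_classification(
        features,
        edge_subset=sig if selection_mode == "paper" else None,
        seed=seed, C=C, splits=splits, test_fraction=test_fraction,
        selection_mode=selection_mode, alpha=alpha,
        selection_criterion=selection_criterion, top_k=top_k,
        positive_label=positive_label,
    )
    diffs = {
        m: getattr(dfc_report, m) - getattr(all_report, m)
        for m in ("accuracy", "sensitivity", "specificity")
    }
    tt = stats.ttest_rel(dfc_report.accuracy, all_report.accuracy)
    return {
        "all_fc": all_report,
        "dfc": dfc_report,
        "paired_differences": diffs,
        "paired_accuracy_t": float(tt.statistic),
        "paired_accuracy_p": float(tt.pvalue),
    }
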