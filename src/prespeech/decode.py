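"""Group-level time-resolved semantic-category decoding per cortical area.

Retained channels are concatenated within each (hemisphere, Brodmann area)
across subjects — rows are word-aligned trials, columns channels — and a
stratified fivefold cross-validated classifier produces a 10-window accuracy
curve per area. The default trial policy cross-validates over all
non-rejected word-aligned trials (channel selection saw only the 70% split);
a strict mode restricted to the held-out 30% is available behind
``trial_policy="evaluation"``.

Classifier menu: linear max-margin (compiled fast path, default), linear
discriminant analysis, and a randomized-tree ensemble (both via
scikit-learn).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._fastsvm import cv_accuracy_curve, effective_n_folds, stratified_fold_ids

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierSpec",
    "GroupFeatureMatrix",
    "DecodingCurve",
    "build_group_matrix",
    "decode_timecourse",
    "compare_classifiers",
]

CLASSIFIER_KINDS = ("svm", "lda", "rf")


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str = "svm"
    C: float = 1.0
    n_estimators: int = 500  # randomized-tree ensemble only
    seed: int = 0

    def __post_init__(self):
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")

    def make_estimator(self):
        if self.kind == "lda":
            from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

            return LinearDiscriminantAnalysis()
        if self.kind == "rf":
            from sklearn.ensemble import RandomForestClassifier

            return RandomForestClassifier(
                n_estimators=self.n_estimators, random_state=self.seed
            )
        from sklearn.svm import LinearSVC

        return LinearSVC(C=self.C, loss="hinge", max_iter=100000)


@dataclass
class GroupFeatureMatrix:
    """Word-aligned trials x pooled retained channels, one stack per window.

    ``values`` is (n_windows, n_rows, n_columns); rows are the words retained
    in every contributing subject, columns ordered by (subject, channel id).
    """

    brodmann_area: object
    hemisphere: str
    values: np.ndarray
    labels: np.ndarray  # +1 body / -1 nonbody per row
    word_ids: np.ndarray
    column_channel_ids: list


@dataclass
class DecodingCurve:
    brodmann_area: object
    hemisphere: str
    accuracy: np.ndarray  # (n_windows,)
    fold_accuracy: np.ndarray  # (n_windows, n_folds)
    classifier: str
    window_labels_ms: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def build_group_matrix(
    features,
    retained_channel_ids,
    brodmann_area,
    hemisphere,
    trial_policy: str = "all",
    evaluation_ids=None,
) -> GroupFeatureMatrix | None:
    """Concatenate an area's retained channels across subjects.

    Rows keep only words not rejected for any contributing subject (and,
    under the ``"evaluation"`` policy, only held-out words). Returns ``None``
    with a logged notice when the area has no retained channels.
    """
    retained = set(retained_channel_ids)
    cols = [
        (i, ch)
        for i, ch in enumerate(features.channels)
        if ch.channel_id in retained
        and ch.brodmann_area == brodmann_area
        and ch.hemisphere == hemisphere
    ]
    if not cols:
        logger.info("area (%s, %s): no retained channels, skipped", brodmann_area, hemisphere)
        return None
    cols.sort(key=lambda t: (t[1].subject_id, t[1].channel_id))
    subjects = sorted({ch.subject_id for _, ch in cols})

    keep = np.ones(features.word_ids.size, dtype=bool)
    for sid in subjects:
        keep &= ~features.rejected.loc[sid].values.astype(bool)
    if trial_policy == "evaluation":
        if evaluation_ids is None:
            raise ValueError("evaluation policy requires evaluation_ids")
        keep &= np.isin(features.word_ids, np.asarray(evaluation_ids))
    elif trial_policy != "all":
        raise ValueError(f"unknown trial_policy {trial_policy!r}")

    idx = [i for i, _ in cols]
    vals = features.values[np.flatnonzero(keep)][:, idx, :]  # rows, cols, windows
    values = np.ascontiguousarray(np.moveaxis(vals, 2, 0))  # windows, rows, cols
    labels = np.where(features.word_categories[keep] == "body", 1.0, -1.0)
    return GroupFeatureMatrix(
        brodmann_area=brodmann_area,
        hemisphere=hemisphere,
        values=values,
        labels=labels,
        word_ids=features.word_ids[keep],
        column_channel_ids=[ch.channel_id for _, ch in cols],
    )


def _sklearn_cv_curve(values, y, fold_id, n_folds, spec):
    n_windows = values.shape[0]
    acc = np.zeros(n_windows)
    fold_acc = np.zeros((n_windows, n_folds))
    mu_sd = 1e-12
    for w in range(n_windows):
        X = values[w]
        for f in range(n_folds):
            tr = fold_id != f
            te = ~tr
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd < mu_sd] = 1.0
            est = spec.make_estimator()
            est.fit((X[tr] - mu) / sd, y[tr])
            fold_acc[w, f] = (est.predict((X[te] - mu) / sd) == y[te]).mean()
        acc[w] = fold_acc[w].mean()
    return acc, fold_acc


def decode_timecourse(
    group: GroupFeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec(),
    n_folds: int = 5,
    seed: int | None = None,
) -> DecodingCurve:
    """Stratified cross-validated accuracy per window for one area."""
    y = group.labels
    if np.unique(y).size < 2:
        raise ValueError("both categories must be present")
    seed = spec.seed if seed is None else seed
    n_folds = effective_n_folds(y, n_folds)
    rng = np.random.default_rng(seed)
    fold_id = stratified_fold_ids(y, n_folds, rng)
    if spec.kind == "svm":
        acc, fold_acc = cv_accuracy_curve(group.values, y, fold_id, n_folds, C=spec.C)
    else:
        acc, fold_acc = _sklearn_cv_curve(group.values, y, fold_id, n_folds, spec)
    return DecodingCurve(
        brodmann_area=group.brodmann_area,
        hemisphere=group.hemisphere,
        accuracy=acc,
        fold_accuracy=fold_acc,
        classifier=spec.kind,
    )


def compare_classifiers(
    group: GroupFeatureMatrix,
    specs,
    n_folds: int = 5,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Mean-accuracy table plus pairwise signed-rank tests across classifiers.

    Each spec is evaluated on the identical fold structure; pairs are
    compared over the (window x fold) accuracy values with two-sided Wilcoxon
    signed-rank tests, Benjamini-Hochberg corrected across pairs.
    """
    import pandas as pd
    from scipy.stats import wilcoxon

    from .permstats import bh_fdr

    if len(specs) < 2:
        raise ValueError("need at least two classifier specs")
    curves = {}
    for spec in specs:
        curves[spec.kind] = decode_timecourse(group, spec, n_folds=n_folds, seed=seed)
    table = pd.DataFrame(
        {
            "classifier": list(curves),
            "mean_accuracy": [c.accuracy.mean() for c in curves.values()],
        }
    )
    rows = []
    for a, b in combinations(curves, 2):
        da = curves[a].fold_accuracy.ravel()
        db = curves[b].fold_accuracy.ravel()
        diff = da - db
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            stat, p = wilcoxon(da, db, zero_method="wilcox")
        rows.append({"a": a, "b": b, "mean_diff": diff.mean(), "stat": stat, "p": p})
    pairs = pd.DataFrame(rows)
    rej, q = bh_fdr(pairs["p"].to_numpy(), alpha=alpha)
    pairs["q"] = q
    pairs["significant"] = rej
    return table, pairs, curves
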