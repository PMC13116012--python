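"""Permutation significance for time-resolved decoding curves.

Two complementary nulls guard the curves. The label-shuffle null re-runs the
identical fold/classifier procedure with category labels permuted (default
2,000 draws), giving per-window empirical p-values (add-one formula, so p is
never zero under finite permutations) that are Benjamini-Hochberg corrected
across the 10 windows within each area. The time-shuffle null permutes each
trial's window assignment (one permutation per trial, shared across
channels), destroying temporal alignment while preserving the label
structure; the pooled 95th percentile of the resulting accuracies is the
area's temporal-specificity threshold. Peaks (troughs) are the largest
(smallest) accuracies among windows passing both criteria for the upper
(lower) tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fastsvm import cv_accuracy_curve, effective_n_folds, stratified_fold_ids

__all__ = [
    "StatsConfig",
    "SignificanceResult",
    "label_shuffle_null",
    "empirical_p",
    "bh_fdr",
    "time_shuffle_threshold",
    "find_extremes",
    "evaluate_significance",
]


@dataclass(frozen=True)
class StatsConfig:
    n_label_perms: int = 2000
    n_time_perms: int = 1000
    alpha: float = 0.05
    time_quantile: float = 0.95
    seed: int = 0

    def validate(self):
        if self.n_label_perms < 100 or self.n_time_perms < 100:
            raise ValueError("permutation counts below 100 are statistically meaningless")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class SignificanceResult:
    brodmann_area: object
    hemisphere: str
    accuracy: np.ndarray
    p_upper: np.ndarray
    q_upper: np.ndarray
    p_lower: np.ndarray
    q_lower: np.ndarray
    sig_fdr_upper: np.ndarray
    sig_fdr_lower: np.ndarray
    time_threshold_upper: float
    time_threshold_lower: float
    sig_upper: np.ndarray  # FDR and time-shuffle jointly
    sig_lower: np.ndarray
    peak: tuple | None  # (window index 1-based, accuracy)
    trough: tuple | None
    extras: dict = field(default_factory=dict)


def label_shuffle_null(group, B: int, seed: int, n_folds: int = 5, C: float = 1.0) -> np.ndarray:
    """(B, n_windows) accuracies under uniformly permuted category labels.

    Each draw permutes the labels, re-stratifies the folds, and re-runs the
    identical cross-validated decoding over every window.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    y = group.labels
    n_folds = effective_n_folds(y, n_folds)
    null = np.empty((B, group.values.shape[0]))
    for b in range(B):
        yp = rng.permutation(y)
        fold_id = stratified_fold_ids(yp, n_folds, rng)
        null[b], _ = cv_accuracy_curve(group.values, yp, fold_id, n_folds, C=C)
    return null


def empirical_p(observed, null, tail: str = "upper"):
    """Add-one empirical p: (1 + #{null as or more extreme}) / (B + 1).

    ``observed`` may be a scalar or a vector paired with the columns of a
    (B, k) null matrix.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("null distribution is empty")
    obs = np.asarray(observed, dtype=float)
    B = null.shape[0]
    if tail == "upper":
        count = (null >= obs).sum(axis=0)
    elif tail == "lower":
        count = (null <= obs).sum(axis=0)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    p = (1.0 + count) / (B + 1.0)
    return float(p) if np.isscalar(observed) or obs.ndim == 0 else p


def bh_fdr(p, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (rejected flags, adjusted q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0.0) | (p > 1.0)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    rejected, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, q


def time_shuffle_threshold(
    group,
    B: int,
    seed: int,
    n_folds: int = 5,
    C: float = 1.0,
    quantile: float = 0.95,
):
    """Pooled accuracy quantiles under per-trial window permutation.

    Returns ``(upper, lower, pooled_null)`` where upper/lower are the
    ``quantile`` and ``1-quantile`` pooled percentiles for the area.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    y = group.labels
    n_folds = effective_n_folds(y, n_folds)
    W, n, d = group.values.shape
    pooled = np.empty((B, W))
    fold_id = stratified_fold_ids(y, n_folds, rng)
    scrambled = np.empty_like(group.values)
    for b in range(B):
        for i in range(n):
            perm = rng.permutation(W)
            scrambled[:, i, :] = group.values[perm, i, :]
        pooled[b], _ = cv_accuracy_curve(scrambled, y, fold_id, n_folds, C=C)
    flat = pooled.ravel()
    return (
        float(np.quantile(flat, quantile)),
        float(np.quantile(flat, 1.0 - quantile)),
        pooled,
    )


def find_extremes(curve, sig_mask, mode: str = "peak"):
    """Extreme accuracy among qualifying windows; earliest window on ties.

    Returns ``(window_index_1based, accuracy)`` or ``None`` when no window
    qualifies.
    """
    if mode not in ("peak", "trough"):
        raise ValueError("mode must be 'peak' or 'trough'")
    curve = np.asarray(curve, dtype=float)
    sig_mask = np.asarray(sig_mask, dtype=bool)
    idx = np.flatnonzero(sig_mask)
    if idx.size == 0:
        return None
    vals = curve[idx]
    # argmax/argmin return the first hit, so ties resolve to the earliest window
    best = idx[np.argmax(vals)] if mode == "peak" else idx[np.argmin(vals)]
    return int(best) + 1, float(curve[best])


def evaluate_significance(
    curve,
    group,
    cfg: StatsConfig = StatsConfig(),
    n_folds: int = 5,
    C: float = 1.0,
) -> SignificanceResult:
    """Full dual-permutation assessment of one area's decoding curve."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    label_seed, time_seed = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2))
    null = label_shuffle_null(group, cfg.n_label_perms, label_seed, n_folds=n_folds, C=C)
    acc = curve.accuracy
    p_up = empirical_p(acc, null, tail="upper")
    p_lo = empirical_p(acc, null, tail="lower")
    rej_up, q_up = bh_fdr(p_up, cfg.alpha)
    rej_lo, q_lo = bh_fdr(p_lo, cfg.alpha)
    thr_up, thr_lo, _ = time_shuffle_threshold(
        group, cfg.n_time_perms, time_seed, n_folds=n_folds, C=C, quantile=cfg.time_quantile
    )
    sig_up = rej_up & (acc > thr_up)
    sig_lo = rej_lo & (acc < thr_lo)
    return SignificanceResult(
        brodmann_area=curve.brodmann_area,
        hemisphere=curve.hemisphere,
        accuracy=acc,
        p_upper=p_up,
        q_upper=q_up,
        p_lower=p_lo,
        q_lower=q_lo,
        sig_fdr_upper=rej_up,
        sig_fdr_lower=rej_lo,
        time_threshold_upper=thr_up,
        time_threshold_lower=thr_lo,
        sig_upper=sig_up,
        sig_lower=sig_lo,
        peak=find_extremes(acc, sig_up, "peak"),
        trough=find_extremes(acc, sig_lo, "trough"),
    )
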