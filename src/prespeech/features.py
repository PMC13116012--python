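"""Windowed high-gamma features and leakage-controlled channel selection.

The 0-500 ms prespeech interval is tiled with ten 100 ms windows advanced in
50 ms steps; window k (1-based) covers [50(k-1), 50(k-1)+100) ms and is
labeled by its center, 50k ms. Channel selection runs on a 70% trial split
only (stratified by category), evaluating each channel independently with
fivefold stratified linear max-margin cross-validation and keeping channels
whose mean accuracy strictly exceeds 0.50; the held-out 30% never touches
selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fastsvm import cv_accuracy_curve, effective_n_folds, stratified_fold_ids

__all__ = [
    "WindowGrid",
    "FeatureTensor",
    "SelectionConfig",
    "window_features",
    "split_trials",
    "select_channels",
]


@dataclass(frozen=True)
class WindowGrid:
    window_length_ms: float = 100.0
    step_ms: float = 50.0
    start_ms: float = 0.0
    n_windows: int = 10
    label_convention: str = "center"  # or "start"

    def window_bounds(self, k: int) -> tuple:
        """Half-open [start, stop) of 1-based window k, in ms."""
        if not 1 <= k <= self.n_windows:
            raise ValueError(f"window index {k} outside 1..{self.n_windows}")
        start = self.start_ms + self.step_ms * (k - 1)
        return start, start + self.window_length_ms

    @property
    def labels_ms(self) -> np.ndarray:
        starts = self.start_ms + self.step_ms * np.arange(self.n_windows)
        if self.label_convention == "center":
            return starts + self.window_length_ms / 2.0
        return starts

    @property
    def span_ms(self) -> tuple:
        return self.start_ms, self.start_ms + self.step_ms * (self.n_windows - 1) + self.window_length_ms


@dataclass
class FeatureTensor:
    """(n_words, n_channels, n_windows) mean normalized HG amplitude."""

    values: np.ndarray
    grid: WindowGrid
    channels: list
    word_ids: np.ndarray
    word_categories: np.ndarray
    rejected: object  # per (subject, word) DataFrame

    @property
    def n_windows(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class SelectionConfig:
    selection_fraction: float = 0.70
    n_folds: int = 5
    retain_threshold: float = 0.50  # strict >
    stratified: bool = True
    seed: int = 0

    def validate(self):
        if not 0.0 < self.selection_fraction <= 1.0:
            raise ValueError("selection_fraction must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def window_features(env, grid: WindowGrid = WindowGrid()) -> FeatureTensor:
    """Average the normalized envelope within each sliding window.

    ``env`` is an EnvelopeDataset; the epoch must cover the grid span.
    """
    times = env.times_ms
    lo, hi = grid.span_ms
    if times[0] > lo or times[-1] < hi - 1e-9:
        raise ValueError(
            f"epoch [{times[0]}, {times[-1]}] ms does not cover the window span [{lo}, {hi}) ms"
        )
    n_words, n_channels, _ = env.envelope.shape
    values = np.empty((n_words, n_channels, grid.n_windows))
    for k in range(1, grid.n_windows + 1):
        a, b = grid.window_bounds(k)
        mask = (times >= a) & (times < b)
        values[:, :, k - 1] = env.envelope[:, :, mask].mean(axis=2)
    return FeatureTensor(
        values=values,
        grid=grid,
        channels=env.channels,
        word_ids=env.word_ids,
        word_categories=env.word_categories,
        rejected=env.rejected,
    )


def split_trials(word_ids, categories, cfg: SelectionConfig = SelectionConfig()):
    """Stratified 70/30 split of the word list into selection/evaluation ids.

    Per category the selection share is ceil(fraction * n_c): the fractional
    remainder trial goes to the selection set, with the particular trial
    chosen by seeded draw. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    word_ids = np.asarray(word_ids)
    categories = np.asarray(categories)
    rng = np.random.default_rng(cfg.seed)
    selection, evaluation = [], []
    for cat in np.unique(categories):
        ids = word_ids[categories == cat]
        if ids.size < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 trials")
        n_sel = int(np.floor(cfg.selection_fraction * ids.size + 1e-9))
        if cfg.selection_fraction * ids.size - n_sel > 1e-9:
            n_sel += 1
        perm = rng.permutation(ids)
        selection.extend(perm[:n_sel].tolist())
        evaluation.extend(perm[n_sel:].tolist())
    return np.sort(np.asarray(selection)), np.sort(np.asarray(evaluation))


def select_channels(
    features: FeatureTensor,
    selection_ids,
    cfg: SelectionConfig = SelectionConfig(),
) -> list:
    """Retain channels decodable above chance on the selection split.

    Each channel is scored independently: stratified fivefold CV of a linear
    max-margin classifier on its 10 window features (standardization fitted
    per training fold); retained iff mean fold accuracy > 0.50 (strict).
    Words rejected for the channel's subject are excluded from its folds.
    """
    cfg.validate()
    sel_mask = np.isin(features.word_ids, np.asarray(selection_ids))
    retained = []
    for c_i, ch in enumerate(features.channels):
        rej = features.rejected.loc[ch.subject_id].values.astype(bool)
        keep = sel_mask & ~rej
        y = np.where(features.word_categories[keep] == "body", 1.0, -1.0)
        if np.unique(y).size < 2:
            continue
        F = features.values[keep, c_i, :][None, :, :]  # one "window" stack
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, c_i)))
        n_folds = effective_n_folds(y, cfg.n_folds)
        fold_id = stratified_fold_ids(y, n_folds, rng)
        acc, _ = cv_accuracy_curve(F, y, fold_id, n_folds)
        if acc[0] > cfg.retain_threshold:
            retained.append(ch.channel_id)
    return retained
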