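"""Raw signals to baseline-normalized high-gamma envelopes.

Fixed stage order: common average reference -> notch (60/120/180 Hz) ->
impedance-based channel exclusion -> interictal-discharge trial rejection ->
70-170 Hz analytic envelope -> prestimulus (-300..0 ms) baseline z-scoring.
All filtering is zero-phase (forward-backward) so the 50 ms window grid is
not biased by group delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "PreprocessConfig",
    "EnvelopeDataset",
    "common_average_reference",
    "notch_filter",
    "exclude_bad_channels",
    "robust_background",
    "detect_ied_trials",
    "hg_envelope",
    "baseline_normalize",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class PreprocessConfig:
    notch_freqs: tuple = (60.0, 120.0, 180.0)
    notch_q: float = 35.0
    hg_band: tuple = (70.0, 170.0)
    impedance_max_kohm: float = 10.0
    ied_amp_factor: float = 2.0
    ied_dur_range_ms: tuple = (20.0, 200.0)
    ied_gap_ms: float = 2.0
    ied_smooth_ms: float = 8.0
    baseline_ms: tuple = (-300.0, 0.0)
    envelope_method: str = "hilbert"  # or "wavelet"
    per_trial_baseline: bool = False


@dataclass
class EnvelopeDataset:
    """Baseline-normalized high-gamma amplitude with carried-over metadata.

    ``envelope`` is (n_words, n_channels, n_samples) in baseline z-units and
    keeps only retained (good, low-impedance) channels. Rejected trials are
    flagged per (subject, word) in ``rejected`` but never deleted; downstream
    stages mask them.
    """

    envelope: np.ndarray
    sample_rate: float
    times_ms: np.ndarray
    channels: list
    trials: list
    word_ids: np.ndarray
    word_categories: np.ndarray
    rejected: "object"  # DataFrame indexed by subject_id, columns word_id
    bad_baseline_channels: list = field(default_factory=list)

    def channels_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "subject_id": [c.subject_id for c in self.channels],
                "hemisphere": [c.hemisphere for c in self.channels],
                "brodmann_area": [c.brodmann_area for c in self.channels],
            }
        )

    def rejected_words_for(self, subject_id: str) -> np.ndarray:
        """Word ids rejected for one subject."""
        row = self.rejected.loc[subject_id]
        return np.asarray(row.index[row.values.astype(bool)])


def common_average_reference(signals: np.ndarray, good_channel_mask) -> np.ndarray:
    """Subtract the per-trial, per-sample mean over good channels.

    After referencing, the mean across good channels is zero at every sample.
    """
    good = np.asarray(good_channel_mask, dtype=bool)
    if good.sum() < 2:
        raise ValueError("common average reference requires >= 2 good channels")
    mean = signals[:, good, :].mean(axis=1, keepdims=True)
    return signals - mean


def notch_filter(signals: np.ndarray, sample_rate: float, notch_freqs, q: float = 35.0) -> np.ndarray:
    """Zero-phase IIR notches at the line frequency and harmonics."""
    nyq = sample_rate / 2.0
    out = np.asarray(signals, dtype=np.float64)
    for f in notch_freqs:
        if f >= nyq:
            raise ValueError(f"notch frequency {f} Hz at or above Nyquist {nyq} Hz")
        b, a = sps.iirnotch(f, Q=q, fs=sample_rate)
        out = sps.filtfilt(b, a, out, axis=-1)
    return out


def exclude_bad_channels(channels, impedance_max_kohm: float = 10.0) -> list:
    """Channel ids retained after the impedance rule (strictly > excluded)."""
    retained = []
    for ch in channels:
        if ch.impedance_kohm < 0:
            raise ValueError(f"negative impedance on {ch.channel_id}")
        if ch.is_bad or ch.impedance_kohm > impedance_max_kohm:
            continue
        retained.append(ch.channel_id)
    return retained


def _baseline_mask(times_ms: np.ndarray, baseline_ms=(-300.0, 0.0)) -> np.ndarray:
    mask = (times_ms >= baseline_ms[0]) & (times_ms < baseline_ms[1])
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    return mask


def robust_background(channel_signals: np.ndarray, times_ms: np.ndarray, baseline_ms=(-300.0, 0.0)) -> float:
    """Robust amplitude scale of one channel: 1.4826 * MAD over pooled baselines.

    ``channel_signals`` is (n_trials, n_samples) for a single channel.
    """
    base = channel_signals[:, _baseline_mask(times_ms, baseline_ms)]
    med = np.median(base)
    return 1.4826 * float(np.median(np.abs(base - med)))


def _excursion_runs(above: np.ndarray, gap_samples: int) -> list:
    """Run lengths of True after bridging sub-threshold gaps <= gap_samples."""
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > gap_samples + 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [idx.size - 1]])
    return [idx[b] - idx[a] + 1 for a, b in zip(starts, stops)]


def detect_ied_trials(
    signals: np.ndarray,
    sample_rate: float,
    times_ms: np.ndarray,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> np.ndarray:
    """Flag trials containing an interictal-discharge-like excursion.

    A trial is flagged when any channel shows a contiguous stretch of
    amplitude above ``factor * background`` lasting 20-200 ms. The background
    is the robust MAD scale of the raw trace over that channel's pooled
    baselines; the criterion itself is evaluated on the rectified signal
    smoothed over ~one oscillation cycle (``ied_smooth_ms``), so that an
    ongoing rhythm's zero crossings cannot fragment a genuine sustained
    excursion while brief spikes still wash out. Residual sub-threshold dips
    shorter than ``ied_gap_ms`` are bridged before the duration is measured.
    """
    n_trials, n_channels, _ = signals.shape
    lo_ms, hi_ms = cfg.ied_dur_range_ms
    lo = int(np.ceil(lo_ms / 1000.0 * sample_rate))
    hi = int(np.floor(hi_ms / 1000.0 * sample_rate))
    gap = int(round(cfg.ied_gap_ms / 1000.0 * sample_rate))
    smooth = max(1, int(round(cfg.ied_smooth_ms / 1000.0 * sample_rate)))
    kernel = np.ones(smooth) / smooth
    flags = np.zeros(n_trials, dtype=bool)
    for c in range(n_channels):
        bg = robust_background(signals[:, c, :], times_ms, cfg.baseline_ms)
        if bg < 1e-12:
            warnings.warn(f"constant channel {c}: zero background, skipped", stacklevel=2)
            continue
        thresh = cfg.ied_amp_factor * bg
        for t in range(n_trials):
            if flags[t]:
                continue
            rect = np.convolve(np.abs(signals[t, c, :]), kernel, mode="same")
            runs = _excursion_runs(rect > thresh, gap)
            if any(lo <= r <= hi for r in runs):
                flags[t] = True
    return flags


def hg_envelope(
    signals: np.ndarray,
    sample_rate: float,
    hg_band=(70.0, 170.0),
    method: str = "hilbert",
) -> np.ndarray:
    """Band-limited amplitude envelope, nonnegative, same shape as input.

    ``hilbert``: zero-phase Butterworth band-pass then analytic magnitude.
    ``wavelet``: mean Morlet wavelet amplitude over band center frequencies
    (the time-frequency view of the same quantity).
    """
    lo, hi = hg_band
    nyq = sample_rate / 2.0
    if not lo < hi or hi >= nyq:
        raise ValueError(f"invalid band ({lo}, {hi}) for sample rate {sample_rate}")
    x = np.asarray(signals, dtype=np.float64)
    if method == "hilbert":
        from scipy.fft import next_fast_len

        sos = sps.butter(4, (lo, hi), btype="bandpass", fs=sample_rate, output="sos")
        bp = sps.sosfiltfilt(sos, x, axis=-1)
        n = x.shape[-1]
        analytic = sps.hilbert(bp, N=next_fast_len(n), axis=-1)[..., :n]
        return np.abs(analytic)
    if method == "wavelet":
        # Complex-Morlet filterbank amplitude. Each wavelet is scaled so a
        # unit tone at its center maps to unit amplitude; wavelets are
        # weighted by 1/f (inverse bandwidth, since sigma_f = f / cycles) so
        # the summed tone response is flat across the band interior, and the
        # sum is normalized to 1 at the band center.
        cycles = 7.0
        freqs = np.linspace(lo + 5.0, hi - 5.0, 16)
        weights = 1.0 / freqs
        f_center = 0.5 * (lo + hi)
        sigma_f = freqs / cycles
        bank_gain = float(
            np.sum(weights * np.exp(-((f_center - freqs) ** 2) / (2.0 * sigma_f**2)))
        )
        out = np.zeros_like(x)
        for f, w in zip(freqs, weights):
            sigma_t = cycles / (2.0 * np.pi * f)
            half = int(np.ceil(4.0 * sigma_t * sample_rate))
            t = np.arange(-half, half + 1) / sample_rate
            wav = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
            tone_gain = np.abs(np.sum(wav * np.exp(-2j * np.pi * f * t)))
            wav *= 2.0 / tone_gain
            shape = (1,) * (x.ndim - 1) + (wav.size,)
            resp = sps.fftconvolve(x, wav.reshape(shape), mode="same", axes=-1)
            out += (w / bank_gain) * np.abs(resp)
        return out
    raise ValueError(f"unknown envelope method {method!r}")


def baseline_normalize(
    envelope: np.ndarray,
    times_ms: np.ndarray,
    baseline_ms=(-300.0, 0.0),
    rejected_trials=None,
    per_trial: bool = False,
):
    """Z-score each channel's envelope against its prestimulus baseline.

    Baseline moments are pooled across that channel's non-rejected trials
    (default) or computed per trial. Channels whose baseline SD collapses are
    flagged and left unscaled (division guarded).

    Returns ``(normalized, bad_channel_indices)``.
    """
    mask = _baseline_mask(times_ms, baseline_ms)
    keep = (
        ~np.asarray(rejected_trials, dtype=bool)
        if rejected_trials is not None
        else np.ones(envelope.shape[0], dtype=bool)
    )
    if not keep.any():
        keep = np.ones(envelope.shape[0], dtype=bool)
    bad = []
    if per_trial:
        base = envelope[:, :, mask]
        mu = base.mean(axis=2, keepdims=True)
        sd = base.std(axis=2, keepdims=True)
        collapsed = sd < 1e-12
        if collapsed.any():
            bad = sorted(set(np.where(collapsed)[1].tolist()))
            warnings.warn(f"near-zero per-trial baseline SD on channels {bad}", stacklevel=2)
            sd = np.where(collapsed, 1.0, sd)
        return (envelope - mu) / sd, bad
    base = envelope[np.ix_(keep, np.arange(envelope.shape[1]), np.flatnonzero(mask))]
    mu = base.mean(axis=(0, 2))
    sd = base.std(axis=(0, 2))
    for c in np.flatnonzero(sd < 1e-12):
        bad.append(int(c))
        sd[c] = 1.0
    if bad:
        warnings.warn(f"near-zero baseline SD on channels {bad}; flagged bad", stacklevel=2)
    return (envelope - mu[None, :, None]) / sd[None, :, None], bad


def preprocess_dataset(dataset, cfg: PreprocessConfig = PreprocessConfig()) -> EnvelopeDataset:
    """Full preprocessing pipeline on a word-aligned raw dataset.

    CAR and IED detection operate per subject (a subject's channels form one
    reference group and one artifact-screening group); rejection flags are
    kept per (subject, word).
    """
    import pandas as pd

    times = dataset.times_ms
    subjects = dataset.subject_ids
    ch_subject = np.array([c.subject_id for c in dataset.channels])

    retained_ids = set(exclude_bad_channels(dataset.channels, cfg.impedance_max_kohm))
    keep_idx = np.array(
        [i for i, c in enumerate(dataset.channels) if c.channel_id in retained_ids]
    )
    if keep_idx.size == 0:
        raise ValueError("no channels survive impedance/bad-channel exclusion")

    signals = np.array(dataset.signals, dtype=np.float64, copy=True)
    # CAR uses good channels only, per subject
    good = np.isin(np.arange(len(dataset.channels)), keep_idx)
    for sid in subjects:
        sel = ch_subject == sid
        if (sel & good).sum() >= 2:
            mean = signals[:, sel & good, :].mean(axis=1, keepdims=True)
            signals[:, sel, :] -= mean
        else:
            warnings.warn(f"subject {sid}: fewer than 2 good channels, CAR skipped", stacklevel=2)
    signals = notch_filter(signals, dataset.sample_rate, cfg.notch_freqs, cfg.notch_q)
    signals = signals[:, keep_idx, :]
    channels = [dataset.channels[i] for i in keep_idx]
    ch_subject = ch_subject[keep_idx]

    # per-subject IED trial rejection
    rejected = pd.DataFrame(
        False, index=pd.Index(subjects, name="subject_id"), columns=dataset.word_ids
    )
    for sid in subjects:
        sel = ch_subject == sid
        if not sel.any():
            continue
        flags = detect_ied_trials(signals[:, sel, :], dataset.sample_rate, times, cfg)
        rejected.loc[sid, dataset.word_ids[flags]] = True
    rej_lookup = {
        (sid, int(w)): bool(rejected.loc[sid, w]) for sid in subjects for w in dataset.word_ids
    }
    for t in dataset.trials:
        t.rejected = rej_lookup.get((t.subject_id, t.word_id), False)

    env = hg_envelope(signals, dataset.sample_rate, cfg.hg_band, cfg.envelope_method)
    # pooled baseline moments exclude a word rejected for the channel's subject
    norm = np.empty_like(env)
    bad_baseline: list[int] = []
    for sid in subjects:
        sel = np.flatnonzero(ch_subject == sid)
        if sel.size == 0:
            continue
        rej = rejected.loc[sid].values.astype(bool)
        sub_norm, bad = baseline_normalize(
            env[:, sel, :], times, cfg.baseline_ms, rejected_trials=rej, per_trial=cfg.per_trial_baseline
        )
        norm[:, sel, :] = sub_norm
        bad_baseline.extend(int(sel[b]) for b in bad)

    return EnvelopeDataset(
        envelope=norm,
        sample_rate=dataset.sample_rate,
        times_ms=times,
        channels=channels,
        trials=dataset.trials,
        word_ids=dataset.word_ids,
        word_categories=dataset.word_categories,
        rejected=rejected,
        bad_baseline_channels=bad_baseline,
    )
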