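"""Synthetic trial-structured intracranial dataset generator.

Emulates the recording design the downstream pipeline expects: per subject, a
single presentation of each word in a fixed 34-word list (two semantic
categories, body vs nonbody), epochs spanning -1000..+3000 ms around word
onset, 1/f background, line noise at 60/120/180 Hz, and a high-gamma
(70-170 Hz) carrier whose per-trial envelope gain carries the planted
category effects and cross-region couplings. Speech onsets are drawn from a
truncated normal (mean 881 ms, SD 228 ms, floor 500 ms), matching the
behavioral distribution of the word-reading task.

Signal model, per channel and trial::

    x(t) = pink(t) + sum_f A_f sin(2 pi f t + phi) + G(t) * carrier(t)

``carrier`` is a constant-envelope frequency-modulated tone wandering inside
the high-gamma band, so the piecewise gain profile ``G`` *is* the band
envelope up to background leakage. ``G`` is resolved on a 50 ms segment grid
over 0-550 ms; a 100 ms analysis window covers two segments, and all planted
quantities (Cohen's d of window-mean envelope, coupling R^2 between
window-mean area gains) are calibrated on that window-mean scale.

Trials are word-aligned across subjects: the trials axis of ``signals``
indexes the shared word list while ``TrialInfo`` records (one per subject and
word) carry per-subject metadata such as speech onset and rejection flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats

from .regions import KNOWN_BAS

__all__ = [
    "ChannelInfo",
    "TrialInfo",
    "PlantedEffect",
    "PlantedCoupling",
    "SynthConfig",
    "RawDataset",
    "generate_dataset",
    "sample_speech_onsets",
    "inject_ied",
]

SEG_MS = 50.0
#: 11 gain segments of 50 ms covering 0-550 ms; analysis window k (1-based)
#: spans segments k-1 and k.
N_SEGS = 11


@dataclass(frozen=True)
class ChannelInfo:
    channel_id: str
    subject_id: str
    hemisphere: str  # "L" or "R"
    brodmann_area: object  # int or "other"
    impedance_kohm: float
    is_bad: bool = False


@dataclass
class TrialInfo:
    trial_id: str
    subject_id: str
    word_id: int
    category: str  # "body" or "nonbody"
    speech_onset_ms: float
    rejected: bool = False


@dataclass(frozen=True)
class PlantedEffect:
    """Category-dependent envelope-gain difference (body minus nonbody)."""

    brodmann_area: int
    hemisphere: str
    window_start_ms: float
    window_end_ms: float
    effect_size_d: float


@dataclass(frozen=True)
class PlantedCoupling:
    """Trial-wise latent shared between a source and target region window."""

    source_area: int
    source_hemisphere: str
    target_area: int
    target_hemisphere: str
    source_window_index: int  # 1..10
    target_window_index: int  # 1..10
    target_r2: float


@dataclass(frozen=True)
class SynthConfig:
    n_subjects: int = 2
    areas: tuple = ((9, "L"), (22, "L"), (37, "L"), (40, "L"))
    channels_per_area: int = 5
    n_trials: int = 34
    n_body: int = 17
    sample_rate: float = 1000.0
    epoch_start_ms: float = -1000.0
    epoch_end_ms: float = 3000.0
    pink_exponent: float = 1.0
    background_amp: float = 1.0
    line_noise_freqs: tuple = (60.0, 120.0, 180.0)
    line_noise_amp: tuple = (1.0, 0.5, 0.25)
    hg_band: tuple = (70.0, 170.0)
    carrier_base_gain: float = 2.0
    envelope_gain_sd: float = 0.25  # per-channel gain noise SD
    shared_gain_sd: float = 0.15  # area-shared gain noise SD
    effects: tuple = ()
    couplings: tuple = ()
    # Simulation-calibrated variance of the envelope-extraction measurement
    # noise per channel window-mean, in gain units, under the default noise
    # and preprocessing settings. Enters only the coupling variance budget;
    # the value deliberately under-corrects so that both the gain-level R^2
    # (which overshoots target_r2) and the extracted-envelope R^2 (which
    # undershoots) stay within tolerance of target_r2.
    envelope_meas_var: float = 0.030
    ied_rate: float = 0.0  # per (subject, word) injection probability
    impedance_high_rate: float = 0.05
    onset_mean_ms: float = 881.0
    onset_sd_ms: float = 228.0
    onset_floor_ms: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.hg_band
        if not lo < hi:
            raise ValueError(f"invalid band: low {lo} >= high {hi}")
        if self.sample_rate <= 2.0 * hi:
            raise ValueError(
                f"sample_rate {self.sample_rate} must exceed twice the band "
                f"high edge {hi}"
            )
        for name in ("n_subjects", "channels_per_area", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_body <= self.n_trials:
            raise ValueError("n_body outside 0..n_trials")
        for ba, _hemi in self.areas:
            if ba != "other" and int(ba) not in KNOWN_BAS:
                raise ValueError(f"unknown Brodmann area {ba}")


@dataclass
class RawDataset:
    sample_rate: float
    epoch_start_ms: float
    epoch_end_ms: float
    signals: np.ndarray  # (n_words, n_channels, n_samples), word-aligned
    channels: list
    trials: list
    word_ids: np.ndarray
    word_categories: np.ndarray
    config: SynthConfig | None = None
    injected_ieds: list = field(default_factory=list)

    @property
    def times_ms(self) -> np.ndarray:
        n = self.signals.shape[2]
        return self.epoch_start_ms + 1000.0 * np.arange(n) / self.sample_rate

    @property
    def subject_ids(self) -> list:
        seen: dict = {}
        for ch in self.channels:
            seen.setdefault(ch.subject_id, None)
        return list(seen)

    def channels_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "channel_id": [c.channel_id for c in self.channels],
                "subject_id": [c.subject_id for c in self.channels],
                "hemisphere": [c.hemisphere for c in self.channels],
                "brodmann_area": [c.brodmann_area for c in self.channels],
                "impedance_kohm": [c.impedance_kohm for c in self.channels],
                "is_bad": [c.is_bad for c in self.channels],
            }
        )

    def trials_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial_id": [t.trial_id for t in self.trials],
                "subject_id": [t.subject_id for t in self.trials],
                "word_id": [t.word_id for t in self.trials],
                "category": [t.category for t in self.trials],
                "speech_onset_ms": [t.speech_onset_ms for t in self.trials],
                "rejected": [t.rejected for t in self.trials],
            }
        )


def sample_speech_onsets(
    n: int,
    seed: int,
    mean_ms: float = 881.0,
    sd_ms: float = 228.0,
    floor_ms: float = 500.0,
) -> np.ndarray:
    """Speech-onset latencies: Normal(mean, sd) truncated below at the floor."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd_ms == 0.0:  # degenerate test hook
        return np.full(n, float(mean_ms))
    a = (floor_ms - mean_ms) / sd_ms
    rv = stats.truncnorm(a, np.inf, loc=mean_ms, scale=sd_ms)
    return rv.rvs(size=n, random_state=np.random.default_rng(seed))


def _pink_noise(rng, shape, n_samples, exponent, amp, sample_rate):
    """1/f^exponent noise via spectral shaping, unit-SD then scaled."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sample_rate)
    scale = np.zeros(n_freq)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal(shape + (n_freq,))
        + 1j * rng.standard_normal(shape + (n_freq,))
    ) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return amp * x / sd


def _fm_carrier(rng, shape, n_samples, sample_rate, band):
    """Constant-envelope FM tone wandering inside the band.

    Center frequencies are drawn per trial and channel from two anchors in
    the lower and upper half of the band, each kept clear of the band edges
    (extraction-filter roll-off) and of the 120 Hz line harmonic (the notch
    would otherwise modulate the measured envelope trial by trial).
    """
    lo, hi = band
    span = hi - lo
    anchors = np.array([lo + 0.3 * span, lo + 0.7 * span])
    f_c = anchors[rng.integers(0, 2, size=shape)][..., None]
    f_dev = 0.1 * span
    u = rng.standard_normal(shape + (n_samples,))
    sos = sps.butter(2, 2.0, btype="low", fs=sample_rate, output="sos")
    u = sps.sosfiltfilt(sos, u, axis=-1)
    sd = u.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    u = np.clip(u / sd, -1.2, 1.2)
    freq = f_c + f_dev * u
    phase = 2.0 * np.pi * np.cumsum(freq, axis=-1) / sample_rate
    phase += rng.uniform(0.0, 2.0 * np.pi, size=shape + (1,))
    return np.cos(phase)


def _segments_overlapping(start_ms: float, end_ms: float) -> np.ndarray:
    """Indices of 50 ms gain segments overlapping [start_ms, end_ms)."""
    segs = np.arange(N_SEGS)
    s0 = segs * SEG_MS
    return segs[(s0 < end_ms) & (s0 + SEG_MS > start_ms)]


def _window_segments(window_index: int) -> np.ndarray:
    """Segments covered by 1-based analysis window k = [50(k-1), 50(k-1)+100)."""
    if not 1 <= window_index <= 10:
        raise ValueError(f"window index {window_index} outside 1..10")
    return np.array([window_index - 1, window_index])


def generate_dataset(config: SynthConfig) -> RawDataset:
    """Generate a word-aligned multichannel dataset with planted structure.

    Deterministic given ``config.seed``: identical configs yield
    byte-identical arrays and metadata.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate
    n_samples = int(round((config.epoch_end_ms - config.epoch_start_ms) / 1000.0 * fs))
    n_words = config.n_trials
    times = config.epoch_start_ms + 1000.0 * np.arange(n_samples) / fs

    # --- channels -----------------------------------------------------------
    channels: list[ChannelInfo] = []
    ch_area_idx: list[int] = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        for a_i, (ba, hemi) in enumerate(config.areas):
            for k in range(config.channels_per_area):
                imp = (
                    rng.uniform(11.0, 20.0)
                    if rng.random() < config.impedance_high_rate
                    else rng.uniform(1.0, 8.0)
                )
                channels.append(
                    ChannelInfo(
                        channel_id=f"{sid}-{hemi}{ba}-{k + 1:02d}",
                        subject_id=sid,
                        hemisphere=hemi,
                        brodmann_area=ba,
                        impedance_kohm=float(imp),
                    )
                )
                ch_area_idx.append(a_i)
    n_channels = len(channels)
    ch_area_idx = np.asarray(ch_area_idx)

    # --- word list and trial metadata --------------------------------------
    word_ids = np.arange(1, n_words + 1)
    cats = np.array(["body"] * config.n_body + ["nonbody"] * (n_words - config.n_body))
    rng.shuffle(cats)
    trials: list[TrialInfo] = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        onsets = sample_speech_onsets(
            n_words,
            seed=int(rng.integers(0, 2**31 - 1)),
            mean_ms=config.onset_mean_ms,
            sd_ms=config.onset_sd_ms,
            floor_ms=config.onset_floor_ms,
        )
        for w in range(n_words):
            trials.append(
                TrialInfo(
                    trial_id=f"{sid}-w{word_ids[w]:02d}",
                    subject_id=sid,
                    word_id=int(word_ids[w]),
                    category=str(cats[w]),
                    speech_onset_ms=float(onsets[w]),
                )
            )

    # --- gain fields on the 50 ms segment grid ------------------------------
    n_areas = len(config.areas)
    s_sh, s_ch = config.shared_gain_sd, config.envelope_gain_sd
    shared = rng.normal(0.0, s_sh, size=(n_words, n_areas, N_SEGS))
    chan_noise = rng.normal(0.0, s_ch, size=(n_words, n_channels, N_SEGS))
    n_pool = config.n_subjects * config.channels_per_area  # channels per area

    body_mask = cats == "body"
    # a 100 ms window averages two independent segments
    var_window_chan = (s_sh**2 + s_ch**2) / 2.0
    for eff in config.effects:
        a_i = _area_index(config, eff.brodmann_area, eff.hemisphere)
        segs = _segments_overlapping(eff.window_start_ms, eff.window_end_ms)
        delta = eff.effect_size_d * np.sqrt(var_window_chan)
        shared[np.ix_(body_mask, [a_i], segs)] += delta / 2.0
        shared[np.ix_(~body_mask, [a_i], segs)] -= delta / 2.0

    # area-mean window variance: gain noise plus envelope measurement noise
    var_window_area = (s_sh**2 + s_ch**2 / n_pool) / 2.0 + config.envelope_meas_var / n_pool
    for cpl in config.couplings:
        if not 0.0 <= cpl.target_r2 < 1.0:
            raise ValueError("target_r2 must lie in [0, 1)")
        src = _area_index(config, cpl.source_area, cpl.source_hemisphere)
        tgt = _area_index(config, cpl.target_area, cpl.target_hemisphere)
        rho = np.sqrt(cpl.target_r2)
        a = np.sqrt(rho * var_window_area / (1.0 - rho)) if rho > 0 else 0.0
        z = rng.standard_normal(n_words)
        shared[:, src, _window_segments(cpl.source_window_index)] += a * z[:, None]
        shared[:, tgt, _window_segments(cpl.target_window_index)] += a * z[:, None]

    gain_seg = (
        config.carrier_base_gain
        + shared[:, ch_area_idx, :]
        + chan_noise
    )

    # --- assemble signals ---------------------------------------------------
    pink = _pink_noise(
        rng,
        (n_words, n_channels),
        n_samples,
        config.pink_exponent,
        config.background_amp,
        fs,
    )
    carrier = _fm_carrier(rng, (n_words, n_channels), n_samples, fs, config.hg_band)

    gain = np.full((n_words, n_channels, n_samples), config.carrier_base_gain)
    mod_mask = (times >= 0.0) & (times < N_SEGS * SEG_MS)
    seg_of_sample = np.floor(times[mod_mask] / SEG_MS).astype(int)
    gain[:, :, mod_mask] = gain_seg[:, :, seg_of_sample]
    np.clip(gain, 0.05 * config.carrier_base_gain, None, out=gain)

    signals = pink
    del pink
    for f_i, f in enumerate(config.line_noise_freqs):
        amp = config.line_noise_amp[f_i]
        phi = rng.uniform(0.0, 2.0 * np.pi, size=(n_words, n_channels, 1))
        signals += amp * np.sin(2.0 * np.pi * f * times / 1000.0 + phi)
    signals += gain * carrier
    del carrier, gain

    ds = RawDataset(
        sample_rate=fs,
        epoch_start_ms=config.epoch_start_ms,
        epoch_end_ms=config.epoch_end_ms,
        signals=signals,
        channels=channels,
        trials=trials,
        word_ids=word_ids,
        word_categories=cats,
        config=config,
    )

    # --- occasional interictal-spike artifacts ------------------------------
    if config.ied_rate > 0:
        by_subject: dict[str, list[int]] = {}
        for i, ch in enumerate(channels):
            by_subject.setdefault(ch.subject_id, []).append(i)
        for t in trials:
            if rng.random() < config.ied_rate:
                ch_i = int(rng.choice(by_subject[t.subject_id]))
                start = float(rng.uniform(-500.0, 2000.0))
                dur = float(rng.uniform(30.0, 150.0))
                factor = float(rng.uniform(2.5, 4.0))
                ds = inject_ied(
                    ds,
                    t.trial_id,
                    channels[ch_i].channel_id,
                    amplitude_factor=factor,
                    duration_ms=dur,
                    start_ms=start,
                    in_place=True,
                )
                ds.injected_ieds.append(
                    {
                        "trial_id": t.trial_id,
                        "channel_id": channels[ch_i].channel_id,
                        "start_ms": start,
                        "duration_ms": dur,
                        "amplitude_factor": factor,
                    }
                )
    return ds


def _area_index(config: SynthConfig, ba, hemisphere) -> int:
    for i, (a, h) in enumerate(config.areas):
        if a == ba and h == hemisphere:
            return i
    raise KeyError(f"area ({ba}, {hemisphere}) not present in config.areas")


def _biphasic(n_samp: int) -> np.ndarray:
    """Smoothed biphasic square wave, unit peak amplitude."""
    shape = np.ones(n_samp)
    shape[n_samp // 2 :] = -1.0
    width = max(3, n_samp // 10)
    kernel = np.hanning(width)
    kernel /= kernel.sum()
    out = np.convolve(shape, kernel, mode="same")
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def inject_ied(
    dataset: RawDataset,
    trial_id: str,
    channel_id: str,
    amplitude_factor: float,
    duration_ms: float,
    start_ms: float = 100.0,
    in_place: bool = False,
) -> RawDataset:
    """Add a biphasic transient scaled to the channel's background level.

    Peak absolute amplitude equals ``amplitude_factor`` times the robust
    background of that channel (the same 1.4826*MAD-over-baselines statistic
    the IED trial detector uses). With ``amplitude_factor=0`` the data are
    returned unchanged.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    trial = next((t for t in dataset.trials if t.trial_id == trial_id), None)
    if trial is None:
        raise KeyError(f"unknown trial_id {trial_id!r}")
    ch_i = next(
        (i for i, c in enumerate(dataset.channels) if c.channel_id == channel_id),
        None,
    )
    if ch_i is None:
        raise KeyError(f"unknown channel_id {channel_id!r}")
    word_row = int(np.flatnonzero(dataset.word_ids == trial.word_id)[0])

    from .preprocess import robust_background

    times = dataset.times_ms
    bg = robust_background(dataset.signals[:, ch_i, :], times)
    n_samp = max(2, int(round(duration_ms / 1000.0 * dataset.sample_rate)))
    start_idx = int(np.searchsorted(times, start_ms))
    stop_idx = min(start_idx + n_samp, dataset.signals.shape[2])

    if in_place:
        out = dataset
    else:
        out = replace(
            dataset,
            signals=dataset.signals.copy(),
            injected_ieds=list(dataset.injected_ieds),
        )
    transient = amplitude_factor * bg * _biphasic(n_samp)
    out.signals[word_row, ch_i, start_idx:stop_idx] += transient[: stop_idx - start_idx]
    out.injected_ieds.append(
        {
            "trial_id": trial_id,
            "channel_id": channel_id,
            "amplitude_factor": float(amplitude_factor),
            "duration_ms": float(duration_ms),
            "start_ms": float(start_ms),
        }
    )
    return out
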