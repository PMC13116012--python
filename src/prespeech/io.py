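"""HDF5 persistence for datasets, envelopes, and features.

Layout mirrors the in-memory containers: ``/signals`` (or ``/envelope``,
``/features``) plus ``/channels`` and ``/trials`` groups of column arrays,
with scalar attributes on the root. Channel metadata is also exportable as
TSV.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureTensor, WindowGrid
from .preprocess import EnvelopeDataset
from .synthgen import ChannelInfo, RawDataset, SynthConfig, TrialInfo

__all__ = [
    "save_raw",
    "load_raw",
    "save_envelope",
    "load_envelope",
    "save_features",
    "load_features",
    "channels_to_tsv",
]

_CHANNEL_COLS = ("channel_id", "subject_id", "hemisphere", "brodmann_area", "impedance_kohm", "is_bad")
_TRIAL_COLS = ("trial_id", "subject_id", "word_id", "category", "speech_onset_ms", "rejected")


def _write_table(h5, name, columns, rows):
    grp = h5.create_group(name)
    for col in columns:
        vals = [getattr(r, col if col != "impedance_kohm" else "impedance_kohm") for r in rows]
        arr = np.asarray(vals)
        if arr.dtype.kind in ("U", "O"):
            arr = arr.astype("S")
        grp.create_dataset(col, data=arr)


def _read_table(h5, name, columns):
    grp = h5[name]
    out = {}
    for col in columns:
        arr = grp[col][...]
        if arr.dtype.kind == "S":
            arr = arr.astype(str)
        out[col] = arr
    return out


def save_raw(dataset: RawDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = dataset.sample_rate
        f.attrs["epoch_start_ms"] = dataset.epoch_start_ms
        f.attrs["epoch_end_ms"] = dataset.epoch_end_ms
        f.create_dataset("signals", data=dataset.signals, compression="gzip", compression_opts=1)
        f.create_dataset("word_ids", data=dataset.word_ids)
        f.create_dataset("word_categories", data=dataset.word_categories.astype("S"))
        _write_table(f, "channels", _CHANNEL_COLS, dataset.channels)
        _write_table(f, "trials", _TRIAL_COLS, dataset.trials)


def load_raw(path) -> RawDataset:
    import h5py

    with h5py.File(path, "r") as f:
        ch = _read_table(f, "channels", _CHANNEL_COLS)
        tr = _read_table(f, "trials", _TRIAL_COLS)
        channels = [
            ChannelInfo(
                channel_id=str(ch["channel_id"][i]),
                subject_id=str(ch["subject_id"][i]),
                hemisphere=str(ch["hemisphere"][i]),
                brodmann_area=_maybe_int(ch["brodmann_area"][i]),
                impedance_kohm=float(ch["impedance_kohm"][i]),
                is_bad=bool(np.asarray(ch["is_bad"][i]).astype(bool)),
            )
            for i in range(len(ch["channel_id"]))
        ]
        trials = [
            TrialInfo(
                trial_id=str(tr["trial_id"][i]),
                subject_id=str(tr["subject_id"][i]),
                word_id=int(tr["word_id"][i]),
                category=str(tr["category"][i]),
                speech_onset_ms=float(tr["speech_onset_ms"][i]),
                rejected=bool(np.asarray(tr["rejected"][i]).astype(bool)),
            )
            for i in range(len(tr["trial_id"]))
        ]
        return RawDataset(
            sample_rate=float(f.attrs["sample_rate"]),
            epoch_start_ms=float(f.attrs["epoch_start_ms"]),
            epoch_end_ms=float(f.attrs["epoch_end_ms"]),
            signals=f["signals"][...],
            channels=channels,
            trials=trials,
            word_ids=f["word_ids"][...],
            word_categories=f["word_categories"][...].astype(str),
        )


def _maybe_int(v):
    s = str(v)
    try:
        return int(s)
    except ValueError:
        return s


def save_envelope(env: EnvelopeDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = env.sample_rate
        f.create_dataset("envelope", data=env.envelope, compression="gzip", compression_opts=1)
        f.create_dataset("times_ms", data=env.times_ms)
        f.create_dataset("word_ids", data=env.word_ids)
        f.create_dataset("word_categories", data=env.word_categories.astype("S"))
        _write_table(f, "channels", _CHANNEL_COLS, env.channels)
        _write_table(f, "trials", _TRIAL_COLS, env.trials)
        rej = f.create_group("rejected")
        rej.create_dataset("subject_id", data=np.asarray(env.rejected.index).astype("S"))
        rej.create_dataset("word_id", data=np.asarray(env.rejected.columns, dtype=int))
        rej.create_dataset("flags", data=env.rejected.values.astype(bool))


def load_envelope(path) -> EnvelopeDataset:
    import h5py
    import pandas as pd

    with h5py.File(path, "r") as f:
        ch = _read_table(f, "channels", _CHANNEL_COLS)
        tr = _read_table(f, "trials", _TRIAL_COLS)
        channels = [
            ChannelInfo(
                channel_id=str(ch["channel_id"][i]),
                subject_id=str(ch["subject_id"][i]),
                hemisphere=str(ch["hemisphere"][i]),
                brodmann_area=_maybe_int(ch["brodmann_area"][i]),
                impedance_kohm=float(ch["impedance_kohm"][i]),
                is_bad=bool(np.asarray(ch["is_bad"][i]).astype(bool)),
            )
            for i in range(len(ch["channel_id"]))
        ]
        trials = [
            TrialInfo(
                trial_id=str(tr["trial_id"][i]),
                subject_id=str(tr["subject_id"][i]),
                word_id=int(tr["word_id"][i]),
                category=str(tr["category"][i]),
                speech_onset_ms=float(tr["speech_onset_ms"][i]),
                rejected=bool(np.asarray(tr["rejected"][i]).astype(bool)),
            )
            for i in range(len(tr["trial_id"]))
        ]
        rejected = pd.DataFrame(
            f["rejected/flags"][...].astype(bool),
            index=pd.Index(f["rejected/subject_id"][...].astype(str), name="subject_id"),
            columns=f["rejected/word_id"][...],
        )
        return EnvelopeDataset(
            envelope=f["envelope"][...],
            sample_rate=float(f.attrs["sample_rate"]),
            times_ms=f["times_ms"][...],
            channels=channels,
            trials=trials,
            word_ids=f["word_ids"][...],
            word_categories=f["word_categories"][...].astype(str),
            rejected=rejected,
        )


def save_features(features: FeatureTensor, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=features.values)
        f.attrs["window_length_ms"] = features.grid.window_length_ms
        f.attrs["step_ms"] = features.grid.step_ms
        f.attrs["start_ms"] = features.grid.start_ms
        f.attrs["n_windows"] = features.grid.n_windows
        f.attrs["label_convention"] = features.grid.label_convention
        f.create_dataset("word_ids", data=features.word_ids)
        f.create_dataset("word_categories", data=features.word_categories.astype("S"))
        _write_table(f, "channels", _CHANNEL_COLS, features.channels)
        rej = f.create_group("rejected")
        rej.create_dataset("subject_id", data=np.asarray(features.rejected.index).astype("S"))
        rej.create_dataset("word_id", data=np.asarray(features.rejected.columns, dtype=int))
        rej.create_dataset("flags", data=features.rejected.values.astype(bool))


def load_features(path) -> FeatureTensor:
    import h5py
    import pandas as pd

    with h5py.File(path, "r") as f:
        ch = _read_table(f, "channels", _CHANNEL_COLS)
        channels = [
            ChannelInfo(
                channel_id=str(ch["channel_id"][i]),
                subject_id=str(ch["subject_id"][i]),
                hemisphere=str(ch["hemisphere"][i]),
                brodmann_area=_maybe_int(ch["brodmann_area"][i]),
                impedance_kohm=float(ch["impedance_kohm"][i]),
                is_bad=bool(np.asarray(ch["is_bad"][i]).astype(bool)),
            )
            for i in range(len(ch["channel_id"]))
        ]
        rejected = pd.DataFrame(
            f["rejected/flags"][...].astype(bool),
            index=pd.Index(f["rejected/subject_id"][...].astype(str), name="subject_id"),
            columns=f["rejected/word_id"][...],
        )
        grid = WindowGrid(
            window_length_ms=float(f.attrs["window_length_ms"]),
            step_ms=float(f.attrs["step_ms"]),
            start_ms=float(f.attrs["start_ms"]),
            n_windows=int(f.attrs["n_windows"]),
            label_convention=str(f.attrs["label_convention"]),
        )
        return FeatureTensor(
            values=f["features"][...],
            grid=grid,
            channels=channels,
            word_ids=f["word_ids"][...],
            word_categories=f["word_categories"][...].astype(str),
            rejected=rejected,
        )


def channels_to_tsv(channels, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "channel_id": [c.channel_id for c in channels],
            "subject_id": [c.subject_id for c in channels],
            "hemisphere": [c.hemisphere for c in channels],
            "brodmann_area": [c.brodmann_area for c in channels],
            "impedance_kohm": [c.impedance_kohm for c in channels],
            "is_bad": [c.is_bad for c in channels],
        }
    ).to_csv(path, sep="\t", index=False)
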