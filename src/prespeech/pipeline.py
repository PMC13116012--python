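"""End-to-end orchestration: synth -> preprocess -> features -> decode ->
permutation stats -> cross-temporal coupling -> report tables.

A single global seed fans out to per-stage seeds through a counter-based
``SeedSequence`` scheme, so any stage can be re-run in isolation and still
reproduce. Areas without retained channels appear in the outputs with a
``skipped`` status row rather than vanishing silently; a failure confined to
one area is logged and does not abort the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .decode import ClassifierSpec, build_group_matrix, decode_timecourse
from .features import SelectionConfig, WindowGrid, select_channels, split_trials, window_features
from .permstats import StatsConfig, evaluate_significance
from .preprocess import PreprocessConfig, preprocess_dataset
from .synthgen import SynthConfig, generate_dataset
from .xtcoupling import (
    ClusterConfig,
    aligned_trace_report,
    compute_coupling_map,
    early_late_tag,
    region_timecourse,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Per-stage seed below 2**31, stable in the global seed and stage."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class PipelineConfig:
    output_dir: str = "out"
    input_path: str | None = None  # HDF5 raw container; None -> synthesize
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_folds: int = 5
    trial_policy: str = "all"
    coupling_pairs: str | list = "auto"  # "auto" or explicit (src, tgt) area pairs
    category_scopes: tuple = ("combined", "body", "nonbody")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path):
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict):
        kwargs = dict(raw)
        for key, sub in (
            ("synth", SynthConfig),
            ("preprocess", PreprocessConfig),
            ("selection", SelectionConfig),
            ("stats", StatsConfig),
            ("cluster", ClusterConfig),
            ("classifier", ClassifierSpec),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub_kwargs = kwargs[key]
                if key == "synth":
                    sub_kwargs = _coerce_synth(sub_kwargs)
                try:
                    kwargs[key] = sub(**sub_kwargs)
                except TypeError as exc:
                    raise ValueError(f"invalid field in config section {key!r}: {exc}") from exc
        if "coupling_pairs" in kwargs and isinstance(kwargs["coupling_pairs"], list):
            kwargs["coupling_pairs"] = [tuple(map(tuple, p)) for p in kwargs["coupling_pairs"]]
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc


def _coerce_synth(d: dict) -> dict:
    from .synthgen import PlantedCoupling, PlantedEffect

    d = dict(d)
    if "areas" in d:
        d["areas"] = tuple((a, h) for a, h in d["areas"])
    if "effects" in d:
        d["effects"] = tuple(PlantedEffect(**e) for e in d["effects"])
    if "couplings" in d:
        d["couplings"] = tuple(PlantedCoupling(**c) for c in d["couplings"])
    return d


@dataclass
class RunManifest:
    config_hash: str
    global_seed: int
    stage_seeds: dict
    n_trials_rejected: int = 0
    n_channels_excluded: int = 0
    retained_per_area: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    versions: dict = field(default_factory=dict)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def _config_hash(config) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and write result tables; returns the output dir."""
    import pandas as pd

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(
        ["synth", "selection", "decode", "stats", "coupling"]
    )}
    manifest = RunManifest(
        config_hash=_config_hash(config),
        global_seed=config.seed,
        stage_seeds=seeds,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        versions={"numpy": np.__version__},
    )

    # --- data ---------------------------------------------------------------
    if config.input_path:
        from .io import load_raw

        raw = load_raw(config.input_path)
    else:
        from dataclasses import replace

        raw = generate_dataset(replace(config.synth, seed=seeds["synth"]))
    env = preprocess_dataset(raw, config.preprocess)
    manifest.n_channels_excluded = len(raw.channels) - len(env.channels)
    manifest.n_trials_rejected = int(env.rejected.values.sum())

    # --- features and selection --------------------------------------------
    features = window_features(env, WindowGrid())
    sel_cfg = SelectionConfig(
        selection_fraction=config.selection.selection_fraction,
        n_folds=config.selection.n_folds,
        retain_threshold=config.selection.retain_threshold,
        seed=seeds["selection"],
    )
    selection_ids, evaluation_ids = split_trials(env.word_ids, env.word_categories, sel_cfg)
    retained = select_channels(features, selection_ids, sel_cfg)

    areas = sorted(
        {(c.brodmann_area, c.hemisphere) for c in env.channels},
        key=lambda t: (str(t[1]), str(t[0])),
    )
    grid = WindowGrid()
    curve_rows, sig_rows, peak_rows = [], [], []
    groups, curves, sig_results = {}, {}, {}
    for ba, hemi in areas:
        n_ret = sum(
            1
            for c in env.channels
            if c.channel_id in set(retained) and c.brodmann_area == ba and c.hemisphere == hemi
        )
        manifest.retained_per_area[f"{hemi}-{ba}"] = n_ret
        group = build_group_matrix(
            features, retained, ba, hemi,
            trial_policy=config.trial_policy, evaluation_ids=evaluation_ids,
        )
        if group is None:
            peak_rows.append(
                {"hemisphere": hemi, "brodmann_area": ba, "status": "skipped",
                 "peak_time_ms": np.nan, "peak_accuracy": np.nan, "q_fdr": np.nan}
            )
            continue
        try:
            curve = decode_timecourse(group, config.classifier, n_folds=config.n_folds, seed=seeds["decode"])
            sig = evaluate_significance(
                curve, group,
                StatsConfig(
                    n_label_perms=config.stats.n_label_perms,
                    n_time_perms=config.stats.n_time_perms,
                    alpha=config.stats.alpha,
                    seed=seeds["stats"],
                ),
                n_folds=config.n_folds,
                C=config.classifier.C,
            )
        except Exception:
            logger.exception("area (%s, %s) failed; skipping", ba, hemi)
            peak_rows.append(
                {"hemisphere": hemi, "brodmann_area": ba, "status": "failed",
                 "peak_time_ms": np.nan, "peak_accuracy": np.nan, "q_fdr": np.nan}
            )
            continue
        groups[(ba, hemi)], curves[(ba, hemi)], sig_results[(ba, hemi)] = group, curve, sig
        for w in range(grid.n_windows):
            row = {
                "hemisphere": hemi, "brodmann_area": ba,
                "window_center_ms": grid.labels_ms[w],
                "classifier": curve.classifier,
                "mean_accuracy": curve.accuracy[w],
            }
            for f_i in range(curve.fold_accuracy.shape[1]):
                row[f"fold_{f_i + 1}"] = curve.fold_accuracy[w, f_i]
            curve_rows.append(row)
            sig_rows.append(
                {
                    "hemisphere": hemi, "brodmann_area": ba,
                    "window_center_ms": grid.labels_ms[w],
                    "accuracy": sig.accuracy[w],
                    "p": sig.p_upper[w], "q": sig.q_upper[w],
                    "sig_fdr": bool(sig.sig_fdr_upper[w]),
                    "time_thresh": sig.time_threshold_upper,
                    "sig_time": bool(sig.accuracy[w] > sig.time_threshold_upper),
                    "is_peak": bool(sig.peak and sig.peak[0] == w + 1),
                    "is_trough": bool(sig.trough and sig.trough[0] == w + 1),
                }
            )
        peak_rows.append(
            {
                "hemisphere": hemi, "brodmann_area": ba, "status": "ok",
                "peak_time_ms": grid.labels_ms[sig.peak[0] - 1] if sig.peak else np.nan,
                "peak_accuracy": sig.peak[1] if sig.peak else np.nan,
                "q_fdr": sig.q_upper[sig.peak[0] - 1] if sig.peak else np.nan,
            }
        )

    pd.DataFrame(curve_rows).to_csv(out / "curves.csv", index=False)
    pd.DataFrame(sig_rows).to_csv(out / "significance.csv", index=False)
    pd.DataFrame(peak_rows).to_csv(out / "peak_summary.csv", index=False)

    # --- cross-temporal coupling -------------------------------------------
    pair_list = _choose_pairs(config, sig_results, grid)
    cell_rows, cluster_summaries, trace_pairs = [], [], []
    for (src, tgt) in pair_list:
        for scope in config.category_scopes:
            try:
                s_tc = region_timecourse(features, retained, src[0], src[1], scope)
                t_tc = region_timecourse(features, retained, tgt[0], tgt[1], scope)
                if s_tc is None or t_tc is None:
                    continue
                cmap = compute_coupling_map(s_tc, t_tc, config.cluster, seed=seeds["coupling"])
            except Exception:
                logger.exception("coupling %s->%s (%s) failed; skipping", src, tgt, scope)
                continue
            cell_cluster = {}
            for k, cl in enumerate(cmap.clusters):
                for cell in cl.members:
                    cell_cluster[cell] = k
            for i in range(10):
                for j in range(10):
                    cell_rows.append(
                        {
                            "source_area": src[0], "source_hemisphere": src[1],
                            "target_area": tgt[0], "target_hemisphere": tgt[1],
                            "category_scope": scope,
                            "source_window_ms": grid.labels_ms[i],
                            "target_window_ms": grid.labels_ms[j],
                            "r2": cmap.r2[i, j], "p": cmap.p[i, j], "q": cmap.q[i, j],
                            "cluster_id": cell_cluster.get((i + 1, j + 1), -1),
                        }
                    )
            cluster_summaries.append(
                {
                    "source": list(src), "target": list(tgt), "scope": scope,
                    "clusters": [
                        {"size": c.size, "peak_r2": c.peak_r2, "peak_cell": list(c.peak_cell),
                         "bounding_box": list(c.bounding_box)}
                        for c in cmap.clusters
                    ],
                }
            )
            if scope == "combined":
                trace_pairs.append(
                    {
                        "source": {"timecourse": s_tc, "curve": curves.get(src)},
                        "target": {"timecourse": t_tc, "curve": curves.get(tgt)},
                        "map": cmap,
                    }
                )
    pd.DataFrame(cell_rows).to_csv(out / "coupling_cells.csv", index=False)
    with open(out / "clusters.json", "w") as fh:
        json.dump(cluster_summaries, fh, indent=2)
    aligned_trace_report(trace_pairs, grid.labels_ms).to_csv(out / "aligned_traces.csv", index=False)

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.write(out / "manifest.json")
    return out


def _choose_pairs(config: PipelineConfig, sig_results, grid) -> list:
    if isinstance(config.coupling_pairs, (list, tuple)) and config.coupling_pairs != "auto":
        return list(config.coupling_pairs)
    # auto: early significant peaks feed late ones, within hemisphere
    early, late = [], []
    for (ba, hemi), sig in sig_results.items():
        if not sig.peak:
            continue
        peak_ms = grid.labels_ms[sig.peak[0] - 1]
        (early if early_late_tag(peak_ms) == "early" else late).append((ba, hemi))
    return [(s, t) for s in early for t in late if s[1] == t[1] and s != t]
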