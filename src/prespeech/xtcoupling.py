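"""Cross-temporal regression between region time courses.

For a source and a target region, the trial-wise channel-averaged high-gamma
feature at every source window is regressed (simple OLS) against the target
feature at every target window, giving a 10x10 grid of coefficients of
determination. For simple regression R^2 equals the squared Pearson
correlation of the two columns, so the grid is symmetric under exchanging
the roles; directionality lives in the source/target time ordering, not in
the regression itself. Per-cell significance comes from permuting the trial
correspondence between the regions (1,000 draws by default, add-one upper
tail), Benjamini-Hochberg corrected across the 100 cells of the map.
Clusters are significant cells seeded at R^2 >= 0.20, grown through
8-connected significant neighbors >= 0.10, overlapping growths merged, and
clusters under 5 cells discarded. Regions are tagged early (peak <= 250 ms)
or late (> 250 ms) to steer source -> target pair choices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .permstats import bh_fdr

__all__ = [
    "ClusterConfig",
    "Cluster",
    "RegionTimecourse",
    "CouplingMap",
    "region_timecourse",
    "cross_temporal_r2",
    "coupling_null",
    "find_clusters",
    "compute_coupling_map",
    "aligned_trace_report",
    "early_late_tag",
]

EARLY_LATE_BOUNDARY_MS = 250.0


@dataclass(frozen=True)
class ClusterConfig:
    seed_threshold: float = 0.20
    grow_threshold: float = 0.10
    connectivity: int = 8
    min_size: int = 5
    alpha: float = 0.05
    n_perms: int = 1000

    def validate(self):
        if self.grow_threshold > self.seed_threshold:
            raise ValueError("grow_threshold must not exceed seed_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class Cluster:
    members: list  # (source_window, target_window) 1-based pairs
    size: int
    peak_r2: float
    peak_cell: tuple
    bounding_box: tuple  # (src_min, src_max, tgt_min, tgt_max), 1-based


@dataclass
class RegionTimecourse:
    brodmann_area: object
    hemisphere: str
    values: np.ndarray  # (n_trials, n_windows) channel-averaged features
    labels: np.ndarray  # category per trial
    word_ids: np.ndarray
    category_scope: str = "combined"
    timing_tag: str | None = None  # "early" / "late"


@dataclass
class CouplingMap:
    source: tuple
    target: tuple
    category_scope: str
    r2: np.ndarray
    p: np.ndarray
    q: np.ndarray
    clusters: list
    zero_variance_cells: np.ndarray | None = None
    extras: dict = field(default_factory=dict)


def early_late_tag(peak_window_ms: float) -> str:
    """Early (<= 250 ms) vs late (> 250 ms) label for an area's peak time."""
    return "early" if peak_window_ms <= EARLY_LATE_BOUNDARY_MS else "late"


def region_timecourse(
    features,
    retained_channel_ids,
    brodmann_area,
    hemisphere,
    category_scope: str = "combined",
    timing_tag: str | None = None,
) -> RegionTimecourse | None:
    """Per-trial channel-averaged feature matrix for one region.

    Rows are words not rejected for any contributing subject, optionally
    restricted to one category. Returns ``None`` when the region has no
    retained channels.
    """
    from .decode import build_group_matrix

    group = build_group_matrix(features, retained_channel_ids, brodmann_area, hemisphere)
    if group is None:
        return None
    vals = group.values.mean(axis=2).T  # (trials, windows)
    labels = np.where(group.labels > 0, "body", "nonbody")
    keep = np.ones(vals.shape[0], dtype=bool)
    if category_scope in ("body", "nonbody"):
        keep = labels == category_scope
    elif category_scope != "combined":
        raise ValueError(f"unknown category scope {category_scope!r}")
    return RegionTimecourse(
        brodmann_area=brodmann_area,
        hemisphere=hemisphere,
        values=vals[keep],
        labels=labels[keep],
        word_ids=group.word_ids[keep],
        category_scope=category_scope,
        timing_tag=timing_tag,
    )


def _standardize_columns(x):
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    zero = sd < 1e-12
    sd = np.where(zero, 1.0, sd)
    return xc / sd, zero


def cross_temporal_r2(source: RegionTimecourse, target: RegionTimecourse):
    """R^2 grid: cell (i, j) regresses target window j on source window i.

    Returns ``(r2, zero_variance_mask)``; cells with a degenerate predictor
    or response are set to 0 and flagged.
    """
    xs, ys = source.values, target.values
    if xs.shape[0] != ys.shape[0] or not np.array_equal(source.word_ids, target.word_ids):
        raise ValueError("source and target must share the same trial set and order")
    n = xs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 trials for cross-temporal regression")
    zs, zero_s = _standardize_columns(xs)
    zt, zero_t = _standardize_columns(ys)
    corr = zs.T @ zt / n
    r2 = corr**2
    flagged = zero_s[:, None] | zero_t[None, :]
    r2[flagged] = 0.0
    return r2, flagged


def coupling_null(
    source: RegionTimecourse,
    target: RegionTimecourse,
    cfg: ClusterConfig = ClusterConfig(),
    seed: int = 0,
):
    """Per-cell p and BH-q grids from trial-correspondence permutations."""
    if cfg.n_perms < 100:
        raise ValueError("n_perms must be >= 100")
    r2, flagged = cross_temporal_r2(source, target)
    n = source.values.shape[0]
    zs, _ = _standardize_columns(source.values)
    zt, _ = _standardize_columns(target.values)
    rng = np.random.default_rng(seed)
    count = np.zeros_like(r2)
    for _ in range(cfg.n_perms):
        perm = rng.permutation(n)
        null_r2 = (zs.T @ zt[perm] / n) ** 2
        count += null_r2 >= r2
    p = (1.0 + count) / (cfg.n_perms + 1.0)
    rej, q = bh_fdr(p.ravel(), alpha=cfg.alpha)
    return r2, flagged, p, q.reshape(r2.shape), rej.reshape(r2.shape)


def find_clusters(r2, q, cfg: ClusterConfig = ClusterConfig()) -> list:
    """Seed-and-grow clusters of significant cells on the R^2 grid.

    Seeds: q <= alpha and r2 >= seed threshold. Each seed accretes connected
    cells with q <= alpha and r2 >= grow threshold; overlapping grown sets
    merge. Clusters smaller than ``min_size`` are dropped; the result is
    sorted by peak R^2 descending. Cells are 1-based (source, target) pairs.
    """
    cfg.validate()
    r2 = np.asarray(r2, dtype=float)
    q = np.asarray(q, dtype=float)
    sig = q <= cfg.alpha
    seeds = sig & (r2 >= cfg.seed_threshold)
    growable = sig & (r2 >= cfg.grow_threshold)
    n_r, n_c = r2.shape
    if cfg.connectivity == 8:
        moves = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]

    visited = np.zeros_like(seeds, dtype=bool)
    clusters = []
    for si, sj in zip(*np.nonzero(seeds)):
        if visited[si, sj]:
            continue
        stack = [(si, sj)]
        visited[si, sj] = True
        members = []
        while stack:
            i, j = stack.pop()
            members.append((i, j))
            for di, dj in moves:
                ni, nj = i + di, j + dj
                if 0 <= ni < n_r and 0 <= nj < n_c and growable[ni, nj] and not visited[ni, nj]:
                    visited[ni, nj] = True
                    stack.append((ni, nj))
        if len(members) < cfg.min_size:
            continue
        vals = np.array([r2[i, j] for i, j in members])
        k = int(np.argmax(vals))
        rows = [i for i, _ in members]
        colz = [j for _, j in members]
        clusters.append(
            Cluster(
                members=sorted((i + 1, j + 1) for i, j in members),
                size=len(members),
                peak_r2=float(vals[k]),
                peak_cell=(members[k][0] + 1, members[k][1] + 1),
                bounding_box=(min(rows) + 1, max(rows) + 1, min(colz) + 1, max(colz) + 1),
            )
        )
    clusters.sort(key=lambda c: -c.peak_r2)
    return clusters


def compute_coupling_map(
    source: RegionTimecourse,
    target: RegionTimecourse,
    cfg: ClusterConfig = ClusterConfig(),
    seed: int = 0,
) -> CouplingMap:
    """R^2 grid, permutation p/q grids, and surviving clusters for one pair."""
    r2, flagged, p, q, _ = coupling_null(source, target, cfg, seed=seed)
    clusters = find_clusters(r2, q, cfg)
    return CouplingMap(
        source=(source.brodmann_area, source.hemisphere),
        target=(target.brodmann_area, target.hemisphere),
        category_scope=source.category_scope,
        r2=r2,
        p=p,
        q=q,
        clusters=clusters,
        zero_variance_cells=flagged,
    )


def aligned_trace_report(pairs, window_labels_ms=None):
    """Tidy table aligning decoding accuracy, mean HG activity, and clusters.

    ``pairs`` is an iterable of dicts with keys ``source``/``target`` (each a
    dict with ``timecourse`` (RegionTimecourse or None) and ``curve``
    (DecodingCurve or None)) and optionally ``map`` (CouplingMap). Emits one
    row per pair x role x window; missing inputs yield rows flagged absent.
    """
    import pandas as pd

    if window_labels_ms is None:
        window_labels_ms = 50.0 * np.arange(1, 11)
    rows = []
    for pair_i, pair in enumerate(pairs):
        cmap = pair.get("map")
        spans = {}
        if cmap is not None and cmap.clusters:
            top = cmap.clusters[0]
            spans = {
                "source": (top.bounding_box[0], top.bounding_box[1]),
                "target": (top.bounding_box[2], top.bounding_box[3]),
            }
        for role in ("source", "target"):
            info = pair.get(role) or {}
            tc = info.get("timecourse")
            curve = info.get("curve")
            for w in range(len(window_labels_ms)):
                span = spans.get(role)
                rows.append(
                    {
                        "pair": pair_i,
                        "role": role,
                        "window": w + 1,
                        "window_ms": float(window_labels_ms[w]),
                        "mean_hg": float(tc.values[:, w].mean()) if tc is not None else np.nan,
                        "accuracy": float(curve.accuracy[w]) if curve is not None else np.nan,
                        "in_cluster_span": bool(span and span[0] <= w + 1 <= span[1]),
                        "absent": tc is None and curve is None,
                    }
                )
    columns = [
        "pair",
        "role",
        "window",
        "window_ms",
        "mean_hg",
        "accuracy",
        "in_cluster_span",
        "absent",
    ]
    return pd.DataFrame(rows, columns=columns)
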