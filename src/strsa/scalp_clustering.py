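"""Data-driven scalp electrode clustering from z-transformed topographies.

Voltage deviations from the pre-stimulus baseline are z-scored per
electrode; at each time point, electrodes whose |z| exceeds the two-sided
point threshold (default p < .001) are grouped into connected components
over the sensor adjacency graph.  Components are tracked through time by
electrode-set overlap, tracks must persist beyond a minimum duration
(default 20 ms), and component sizes must exceed a Monte-Carlo threshold
calibrated on smoothness-matched Gaussian noise topographies.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import norm

from .preprocess import CategoryERP
from .synthetic import SensorLayout

__all__ = [
    "ScalpCluster",
    "z_topography",
    "find_clusters",
    "cluster_erp",
    "noise_cluster_size_threshold",
]


@dataclass
class ScalpCluster:
    """A spatially contiguous electrode set with its temporal extent."""

    electrodes: frozenset
    onset_ms: float
    offset_ms: float
    peak_z: float

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("cluster offset must exceed its onset")
        self.electrodes = frozenset(self.electrodes)

    def jaccard(self, other) -> float:
        other = frozenset(other.electrodes if isinstance(other, ScalpCluster) else other)
        union = self.electrodes | other
        return len(self.electrodes & other) / len(union) if union else 0.0


def z_topography(voltages: np.ndarray, times: np.ndarray, baseline_ms=(-100.0, 0.0),
                 electrode_ids=None) -> np.ndarray:
    """Z-score per-electrode voltages against their baseline distribution.

    ``voltages`` is (electrodes, samples), typically the grand-average ERP
    (averaged over categories and participants).  z(e, t) = (V(e, t) -
    baseline mean at e) / baseline sd at e.  The baseline interval must be
    pre-stimulus and span at least 10 samples.
    """
    voltages = np.asarray(voltages, dtype=float)
    times = np.asarray(times, dtype=float)
    if voltages.ndim != 2 or voltages.shape[1] != len(times):
        raise ValueError("voltages must be electrodes x samples matching times")
    if baseline_ms[1] > 0:
        raise ValueError("baseline interval must be pre-stimulus")
    idx = np.flatnonzero((times >= baseline_ms[0]) & (times < baseline_ms[1]))
    if len(idx) < 10:
        raise ValueError("baseline interval must contain at least 10 samples")
    mu = voltages[:, idx].mean(axis=1, keepdims=True)
    sd = voltages[:, idx].std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        e = int(np.argmax(sd[:, 0] == 0))
        name = electrode_ids[e] if electrode_ids is not None else f"index {e}"
        raise ValueError(f"zero baseline standard deviation at electrode {name}")
    return (voltages - mu) / sd


def _neighbor_correlation(zmap_baseline: np.ndarray, adjacency: np.ndarray) -> float:
    """Mean Pearson correlation over adjacent electrode pairs (baseline samples)."""
    if zmap_baseline.shape[1] < 3:
        return 0.0
    z = zmap_baseline - zmap_baseline.mean(axis=1, keepdims=True)
    sd = z.std(axis=1)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    corr = (z @ z.T) / zmap_baseline.shape[1]
    i, j = np.where(np.triu(adjacency, 1))
    if len(i) == 0:
        return 0.0
    return float(corr[i, j].mean())


def noise_cluster_size_threshold(
    layout: SensorLayout,
    zcrit: float,
    target_neighbor_corr: float = 0.0,
    n_null: int = 200,
    size_alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Monte-Carlo cluster-size threshold under smoothness-matched noise.

    Gaussian noise fields are spatially smoothed on the adjacency graph
    until their mean neighbor correlation matches the target, thresholded
    at ``zcrit``, and the (1 - size_alpha) quantile of the maximum
    connected-component size is returned.
    """
    rng = np.random.default_rng(int(seed) % 2**31)
    A = layout.adjacency.astype(float)
    deg = np.maximum(A.sum(axis=1), 1.0)
    Anorm = A / deg[:, None]

    w = 0.0
    if target_neighbor_corr > 0.02:
        base = rng.standard_normal((layout.n_electrodes, 400))
        lo, hi = 0.0, 4.0
        for _ in range(25):
            w = 0.5 * (lo + hi)
            y = base + w * (Anorm @ base)
            if _neighbor_correlation(y, layout.adjacency) < target_neighbor_corr:
                lo = w
            else:
                hi = w
        w = 0.5 * (lo + hi)

    draws = rng.standard_normal((n_null, layout.n_electrodes))
    if w > 0:
        draws = draws + (draws @ Anorm.T) * w
    draws = (draws - draws.mean(axis=0)) / draws.std(axis=0)
    graph = csr_matrix(layout.adjacency)
    sizes = np.zeros(n_null, dtype=int)
    for k in range(n_null):
        supra = np.abs(draws[k]) > zcrit
        if not np.any(supra):
            continue
        sizes[k] = _max_component_size(graph, supra)
    return float(np.quantile(sizes, 1.0 - size_alpha))


def _max_component_size(graph: csr_matrix, supra: np.ndarray) -> int:
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return 0
    sub = graph[np.ix_(idx, idx)]
    _, labels = connected_components(sub, directed=False)
    return int(np.bincount(labels).max())


def _components(graph: csr_matrix, supra: np.ndarray):
    idx = np.flatnonzero(supra)
    if len(idx) == 0:
        return []
    sub = graph[np.ix_(idx, idx)]
    n, labels = connected_components(sub, directed=False)
    return [frozenset(idx[labels == k].tolist()) for k in range(n)]


def find_clusters(
    zmap: np.ndarray,
    times: np.ndarray,
    layout: SensorLayout,
    point_alpha: float = 0.001,
    min_duration_ms: float = 20.0,
    size_alpha: float = 0.05,
    n_null: int = 200,
    seed: int = 0,
) -> list[ScalpCluster]:
    """Spatially contiguous, temporally persistent suprathreshold clusters.

    Per time point, electrodes with |z| above the two-sided ``point_alpha``
    normal quantile form connected components over the layout adjacency;
    components smaller than the Monte-Carlo noise size threshold are
    dropped.  Components are tracked across consecutive time points by
    Jaccard overlap > 0.5 and tracks persisting longer than
    ``min_duration_ms`` are returned, with electrodes the union over the
    track's lifetime.
    """
    zmap = np.asarray(zmap, dtype=float)
    if layout.n_electrodes == 0:
        raise ValueError("empty layout")
    if zmap.shape[0] != layout.n_electrodes:
        raise ValueError("zmap and layout must share electrodes")
    zcrit = float(norm.ppf(1.0 - point_alpha / 2.0))
    baseline_idx = np.flatnonzero(times < 0)
    target = _neighbor_correlation(zmap[:, baseline_idx], layout.adjacency) if len(baseline_idx) >= 3 else 0.0
    size_thr = noise_cluster_size_threshold(
        layout, zcrit, target_neighbor_corr=max(0.0, target),
        n_null=n_null, size_alpha=size_alpha, seed=seed,
    )
    graph = csr_matrix(layout.adjacency)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0

    active: list[dict] = []
    finished: list[dict] = []
    for ti, t in enumerate(times):
        supra = np.abs(zmap[:, ti]) > zcrit
        comps = [c for c in _components(graph, supra) if len(c) > size_thr]
        matched = [False] * len(comps)
        new_active = []
        for track in active:
            best, best_j = None, 0.5
            for k, comp in enumerate(comps):
                if matched[k]:
                    continue
                inter = len(track["current"] & comp)
                union = len(track["current"] | comp)
                j = inter / union if union else 0.0
                if j > best_j:
                    best, best_j = k, j
            if best is not None:
                comp = comps[best]
                matched[best] = True
                track["current"] = comp
                for e in comp:
                    track["counts"][e] = track["counts"].get(e, 0) + 1
                track["n_slices"] += 1
                track["last"] = t
                track["peak"] = max(track["peak"], float(np.abs(zmap[list(comp), ti]).max()))
                new_active.append(track)
            else:
                finished.append(track)
        for k, comp in enumerate(comps):
            if not matched[k]:
                new_active.append(
                    {
                        "counts": {e: 1 for e in comp},
                        "n_slices": 1,
                        "current": comp,
                        "start": float(t),
                        "last": float(t),
                        "peak": float(np.abs(zmap[list(comp), ti]).max()),
                    }
                )
        active = new_active
    finished.extend(active)

    clusters = []
    for track in finished:
        duration = track["last"] - track["start"] + dt
        if duration <= min_duration_ms:
            continue
        # core membership: electrodes present in at least half the track's
        # time slices (one-off noise joiners are not part of the cluster),
        # restricted to the largest connected component
        half = 0.5 * track["n_slices"]
        core = {e for e, c in track["counts"].items() if c >= half}
        if not core:
            core = set(track["counts"])
        best = max(
            (c for c in _components(graph, np.isin(np.arange(layout.n_electrodes), list(core)))),
            key=len,
        )
        cluster = ScalpCluster(
            electrodes=frozenset(layout.electrode_ids[i] for i in best),
            onset_ms=track["start"],
            offset_ms=track["last"] + dt,
            peak_z=track["peak"],
        )
        _assert_connected(cluster, layout)
        clusters.append(cluster)
    clusters.sort(key=lambda c: (c.onset_ms, -len(c.electrodes)))
    return clusters


def _assert_connected(cluster: ScalpCluster, layout: SensorLayout) -> None:
    idx = {e: i for i, e in enumerate(layout.electrode_ids)}
    g = nx.Graph()
    members = [idx[e] for e in cluster.electrodes]
    g.add_nodes_from(members)
    for a in members:
        for b in members:
            if a < b and layout.adjacency[a, b]:
                g.add_edge(a, b)
    if not nx.is_connected(g):
        raise AssertionError("cluster electrode set is not connected under the layout adjacency")


def cluster_erp(erp: CategoryERP, cluster: ScalpCluster, unit_id: str | None = None) -> CategoryERP:
    """Average a category ERP over a cluster's member electrodes."""
    missing = [e for e in cluster.electrodes if e not in erp.electrodes]
    if missing:
        raise ValueError(f"cluster electrodes absent from the ERP: {missing}")
    idx = [erp.electrodes.index(e) for e in sorted(cluster.electrodes)]
    mean = erp.voltages[idx].mean(axis=0, keepdims=True)
    return CategoryERP(
        voltages=mean,
        times=erp.times,
        sampling_hz=erp.sampling_hz,
        categories=erp.categories,
        electrodes=(unit_id or f"cluster[{len(idx)}e@{cluster.onset_ms:g}ms]",),
        n_trials_used=erp.n_trials_used,
        participant_id=erp.participant_id,
    )
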