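"""Permutation statistics and noise ceilings for encoding traces.

The null hypothesis is built by fully exchanging the row and column labels
of each participant's neural RDMs (independently per participant and
permutation), recomputing the encoding statistic, and storing the group
mean per time point.  Multiple comparisons are controlled by cluster
extent: time points exceed a Bonferroni-adjusted pointwise threshold from
the null, and contiguous suprathreshold runs survive only if longer than
the null's maximum-run-length quantile.  Tests are one-sided (explained
variance only meaningfully exceeds chance).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .encoding import _layer_design, batched_rank_r2
from .rdm import RDM, lower_triangle, n_pairs

__all__ = [
    "PermutationNull",
    "NoiseCeiling",
    "permute_rdm_labels",
    "pair_permutation_indices",
    "build_null",
    "group_null_stats",
    "cluster_extent_correct",
    "noise_ceiling",
    "noise_ceiling_series",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Group-level statistic per (permutation, time); row 0 is the identity
    permutation, i.e. the observed statistic."""

    stats: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if self.stats.ndim != 2:
            raise ValueError("stats must be (permutations, time)")

    @property
    def n_permutations(self) -> int:
        return self.stats.shape[0]

    @property
    def observed(self) -> np.ndarray:
        return self.stats[0]


@dataclass
class NoiseCeiling:
    """Bounds on the group-average RDM correlation any true model could reach."""

    lower: np.ndarray
    upper: np.ndarray
    scale: str = "correlation"

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        ok = ~(np.isnan(self.lower) | np.isnan(self.upper))
        if np.any(self.lower[ok] > self.upper[ok] + 1e-9):
            raise ValueError("noise-ceiling lower bound exceeds upper bound")


def _check_permutation(perm, n: int) -> np.ndarray:
    perm = np.asarray(perm, dtype=int)
    if sorted(perm.tolist()) != list(range(n)):
        raise ValueError("permutation must be a bijection over the categories")
    return perm


def permute_rdm_labels(rdm: RDM, permutation) -> RDM:
    """Jointly reindex an RDM's rows and columns by a category permutation."""
    perm = _check_permutation(permutation, rdm.n_categories)
    values = rdm.values[np.ix_(perm, perm)]
    return RDM(values, rdm.categories, source=rdm.source + "|permuted")


def pair_permutation_indices(n_categories: int, permutation) -> np.ndarray:
    """Index map carrying a category relabeling onto lower-triangle vectors.

    ``vec_permuted = vec[pair_permutation_indices(n, perm)]`` equals the
    lower triangle of the relabeled RDM.
    """
    perm = _check_permutation(permutation, n_categories)
    m = np.zeros((n_categories, n_categories), dtype=int)
    tri = np.tril_indices(n_categories, -1)
    m[tri] = np.arange(n_pairs(n_categories))
    m = m + m.T
    return m[np.ix_(perm, perm)][tri]


def group_null_stats(
    neural_per_participant,
    layers,
    n_categories: int,
    n_permutations: int = 1000,
    seed: int = 0,
    chunk: int = 100,
):
    """Permutation distributions of the group-mean encoding statistics.

    ``neural_per_participant``: per participant, an array (time, pairs) of
    lower-triangle dissimilarity vectors (NaN rows = skipped windows).
    Returns a dict with 'all' -> (B, T) joint-model R^2 and 'layer' ->
    (L, B, T) single-layer rho^2, where permutation 0 is the identity.
    Each participant receives an independent relabeling per permutation.
    """
    if n_permutations < 100:
        warnings.warn("n_permutations < 100 gives an unstable null tail", stacklevel=2)
    rng = np.random.default_rng(int(seed) % 2**31)
    design, pinv = _layer_design(layers)
    Xr = design[:, 1:]
    xc = Xr - Xr.mean(axis=0, keepdims=True)
    xn = xc / np.linalg.norm(xc, axis=0, keepdims=True)
    L = Xr.shape[1]

    n_sub = len(neural_per_participant)
    T = neural_per_participant[0].shape[0]
    B = int(n_permutations)
    sum_all = np.zeros((B, T))
    cnt_all = np.zeros((B, T))
    sum_layer = np.zeros((L, B, T))

    # one independent relabeling per participant per permutation (perm 0 = identity)
    perms = np.empty((n_sub, B, n_pairs(n_categories)), dtype=np.int32)
    identity = np.arange(n_pairs(n_categories), dtype=np.int32)
    for s in range(n_sub):
        perms[s, 0] = identity
        for b in range(1, B):
            perms[s, b] = pair_permutation_indices(
                n_categories, rng.permutation(n_categories)
            )

    for s, neural in enumerate(neural_per_participant):
        neural = np.asarray(neural, dtype=float)
        if neural.shape[0] != T:
            raise ValueError("participants must share the time grid")
        ranks = np.full_like(neural, np.nan)
        valid = ~np.any(np.isnan(neural), axis=1)
        if np.any(valid):
            ranks[valid] = rankdata(neural[valid], axis=1)
        for b0 in range(0, B, chunk):
            b1 = min(b0 + chunk, B)
            block = ranks[:, perms[s, b0:b1]].transpose(1, 0, 2)  # (chunk, T, P)
            flat = block.reshape(-1, block.shape[-1])
            r2, _ = batched_rank_r2(flat, design, pinv)
            r2 = r2.reshape(b1 - b0, T)
            ok = ~np.isnan(r2)
            sum_all[b0:b1][ok] += r2[ok]
            cnt_all[b0:b1][ok] += 1.0
            # single-layer rho^2 from the same permuted ranks
            yc = flat - np.nanmean(flat, axis=1, keepdims=True)
            norms = np.sqrt(np.nansum(yc**2, axis=1, keepdims=True))
            with np.errstate(invalid="ignore", divide="ignore"):
                yn = yc / norms
            rho = np.clip(yn @ xn, -1.0, 1.0).reshape(b1 - b0, T, L)
            r2l = np.transpose(rho**2, (2, 0, 1))  # (L, chunk, T)
            okl = ~np.isnan(r2l)
            sum_layer[:, b0:b1][okl] += r2l[okl]

    with np.errstate(invalid="ignore", divide="ignore"):
        stats_all = np.where(cnt_all > 0, sum_all / cnt_all, np.nan)
        stats_layer = np.where(cnt_all[None] > 0, sum_layer / cnt_all[None], np.nan)
    return {"all": stats_all, "layer": stats_layer}


def build_null(
    neural_per_participant,
    layers,
    n_categories: int,
    n_permutations: int = 1000,
    seed: int = 0,
    stat: str = "all",
    layer: int | None = None,
) -> PermutationNull:
    """Permutation null of one group-level statistic per time point.

    ``stat='all'`` uses the joint-model R^2; ``stat='layer'`` with a layer
    index uses that layer's rho^2.  Deterministic per seed; permutation 0
    reproduces the observed statistic.
    """
    out = group_null_stats(
        neural_per_participant, layers, n_categories, n_permutations, seed
    )
    if stat == "all":
        return PermutationNull(out["all"], seed=int(seed))
    if stat == "layer":
        if layer is None:
            raise ValueError("stat='layer' requires a layer index")
        return PermutationNull(out["layer"][layer], seed=int(seed))
    raise ValueError("stat must be 'all' or 'layer'")


def _run_lengths(mask: np.ndarray):
    """(start, length) of each maximal run of True in a boolean vector."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def _max_run_lengths(masks: np.ndarray) -> np.ndarray:
    """Maximum run length of True per row of a boolean matrix."""
    B, T = masks.shape
    padded = np.zeros((B, T + 2), dtype=bool)
    padded[:, 1:-1] = masks
    d = np.diff(padded.astype(np.int8), axis=1)
    out = np.zeros(B, dtype=int)
    for b in range(B):
        starts = np.flatnonzero(d[b] == 1)
        ends = np.flatnonzero(d[b] == -1)
        if len(starts):
            out[b] = int((ends - starts).max())
    return out


def cluster_extent_correct(
    observed: np.ndarray,
    null: PermutationNull,
    alpha: float = 0.05,
    n_comparisons: int = 1,
) -> np.ndarray:
    """Cluster-extent corrected significance mask over time.

    Time points exceed the pointwise (1 - alpha/n_comparisons) null
    quantile (one-sided); contiguous suprathreshold runs form clusters and
    survive only if their length strictly exceeds the (1 - alpha) quantile
    of the null's maximum-run-length distribution.
    """
    observed = np.asarray(observed, dtype=float)
    stats = null.stats
    if stats.size == 0:
        raise ValueError("empty null")
    if stats.shape[1] != len(observed):
        raise ValueError("null not built on the observed time grid")
    q = 1.0 - alpha / max(1, n_comparisons)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        thresholds = np.nanquantile(stats, q, axis=0)
    supra_obs = np.where(np.isnan(observed) | np.isnan(thresholds), False, observed > thresholds)
    supra_null = np.where(np.isnan(stats) | np.isnan(thresholds)[None], False, stats > thresholds[None])
    max_runs = _max_run_lengths(supra_null)
    lstar = float(np.quantile(max_runs, 1.0 - alpha))
    mask = np.zeros(len(observed), dtype=bool)
    for start, length in _run_lengths(supra_obs):
        if length > lstar:
            mask[start : start + length] = True
    return mask


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ar, br = rankdata(a), rankdata(b)
    ac, bc = ar - ar.mean(), br - br.mean()
    na, nb = np.linalg.norm(ac), np.linalg.norm(bc)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def noise_ceiling(subject_vectors, scale: str = "correlation") -> NoiseCeiling:
    """Noise-ceiling bounds from per-participant RDM vectors at one point.

    Upper bound: mean Spearman correlation of each participant with the
    group mean (including themselves; overfit, hence an overestimate).
    Lower bound: leave-one-participant-out correlation with the mean of
    the others.  Degenerate (constant) participant vectors are excluded
    with a logged notice.  Requires >= 3 participants.
    """
    V = np.asarray(subject_vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 3:
        raise ValueError("noise ceiling requires >= 3 participants")
    keep = (V.max(axis=1) - V.min(axis=1)) > 0
    keep &= ~np.any(np.isnan(V), axis=1)
    if not np.all(keep):
        logger.info("noise ceiling: excluding %d degenerate participant(s)", int((~keep).sum()))
    V = V[keep]
    if V.shape[0] < 2:
        return NoiseCeiling(np.nan, np.nan, scale=scale)
    group = V.mean(axis=0)
    n = V.shape[0]
    upper = np.mean([_spearman(V[i], group) for i in range(n)])
    lower = np.mean(
        [_spearman(V[i], (group * n - V[i]) / (n - 1)) for i in range(n)]
    )
    if scale == "squared":
        lower, upper = np.sign(lower) * lower**2, np.sign(upper) * upper**2
    elif scale != "correlation":
        raise ValueError("scale must be 'correlation' or 'squared'")
    return NoiseCeiling(lower, upper, scale=scale)


def noise_ceiling_series(neural_per_participant, scale: str = "correlation") -> NoiseCeiling:
    """Noise ceiling at every time point of a set of (time, pairs) arrays."""
    arrs = [np.asarray(a, dtype=float) for a in neural_per_participant]
    T = arrs[0].shape[0]
    lower = np.full(T, np.nan)
    upper = np.full(T, np.nan)
    stack = np.stack(arrs)  # (S, T, P)
    for t in range(T):
        V = stack[:, t, :]
        keep = ~np.any(np.isnan(V), axis=1) & ((np.nanmax(V, axis=1) - np.nanmin(V, axis=1)) > 0)
        if keep.sum() < 3:
            continue
        nc = noise_ceiling(V[keep], scale=scale)
        lower[t], upper[t] = nc.lower[0], nc.upper[0]
    return NoiseCeiling(lower, upper, scale=scale)
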