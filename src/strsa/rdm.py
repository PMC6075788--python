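"""Representational dissimilarity matrices (RDMs).

An RDM summarises the category geometry of a response space: entry (i, j)
is ``1 - Spearman rho`` between the response vectors of categories *i* and
*j*, so values live in [0, 2] with 0 on the (unused) diagonal.  RDMs are
built both from feature banks (one per model layer) and from per-electrode
sliding windows of category-averaged ERPs; all downstream analyses consume
only the lower triangle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import rankdata

__all__ = [
    "DegenerateInputError",
    "WindowTooShortError",
    "FeatureBank",
    "RDM",
    "RDMSeries",
    "feature_rdm",
    "erp_window_rdm",
    "sliding_rdms",
    "lower_triangle",
    "vector_to_matrix",
    "n_pairs",
]


class DegenerateInputError(ValueError):
    """A response vector has zero rank variance (constant input)."""


class WindowTooShortError(ValueError):
    """A truncated window retains fewer than the minimum 3 samples."""


MIN_WINDOW_SAMPLES = 3


def n_pairs(n_categories: int) -> int:
    """Number of lower-triangle entries, n(n-1)/2."""
    return n_categories * (n_categories - 1) // 2


@dataclass
class FeatureBank:
    """One layer's exemplar-by-feature activation matrix.

    ``category_means`` (category x feature) is derived from ``activations``
    on construction and is the input to :func:`feature_rdm`.
    """

    layer_id: str
    activations: np.ndarray
    labels: np.ndarray
    categories: tuple
    category_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activations = np.asarray(self.activations, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.activations.ndim != 2:
            raise ValueError("activations must be exemplar x feature")
        if self.activations.shape[1] < 2:
            raise ValueError("feature count must be >= 2")
        if len(self.labels) != self.activations.shape[0]:
            raise ValueError("labels must match exemplar count")
        declared = set(self.categories)
        if not set(self.labels.tolist()) <= declared:
            raise ValueError("labels contain categories outside the declared set")
        means = np.stack(
            [self.activations[self.labels == c].mean(axis=0) for c in self.categories]
        )
        if self.category_means is None:
            self.category_means = means
        elif not np.allclose(self.category_means, means, atol=1e-10):
            raise ValueError("category_means inconsistent with activations")

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass
class RDM:
    """Symmetric category x category dissimilarity matrix.

    The diagonal is conceptually undefined; it is stored as 0 and never
    enters any analysis (only :func:`lower_triangle` is consumed).
    """

    values: np.ndarray
    categories: tuple
    source: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.categories)
        if v.shape != (n, n):
            raise ValueError("values must be square over the category list")
        if not np.all(np.isfinite(v)):
            raise ValueError("RDM contains non-finite entries")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("RDM must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-9):
            raise ValueError("RDM diagonal must be stored as 0")
        if v.min() < -1e-9 or v.max() > 2 + 1e-9:
            raise ValueError("RDM entries must lie in [0, 2]")
        self.values = v

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass
class RDMSeries:
    """Sliding-window RDMs for every electrode of a category ERP.

    ``vectors`` holds lower-triangle dissimilarity vectors with shape
    (electrodes, windows, pairs); windows skipped as degenerate or too
    short are NaN rows, with a notice recorded per skip.
    """

    vectors: np.ndarray
    window_starts: np.ndarray
    window_ms: float
    step_ms: float
    categories: tuple
    electrodes: tuple
    notices: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[1]

    def rdm_at(self, electrode_index: int, window_index: int) -> RDM:
        vec = self.vectors[electrode_index, window_index]
        if np.any(np.isnan(vec)):
            raise DegenerateInputError(
                f"window {window_index} at electrode {self.electrodes[electrode_index]} "
                "was skipped"
            )
        return RDM(
            vector_to_matrix(vec, len(self.categories)),
            self.categories,
            source=(
                f"electrode={self.electrodes[electrode_index]},"
                f"window_start={self.window_starts[window_index]:g}ms"
            ),
        )


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average-rank transform along the last axis (standard Spearman ties)."""
    return rankdata(x, axis=-1, method="average")


def _one_minus_spearman(vectors: np.ndarray) -> np.ndarray:
    """1 - Spearman correlation matrix of the rows of ``vectors``.

    Raises :class:`DegenerateInputError` if any row has zero rank variance.
    """
    ranks = _rank_rows(vectors)
    centered = ranks - ranks.mean(axis=-1, keepdims=True)
    norms = np.linalg.norm(centered, axis=-1)
    if np.any(norms == 0):
        raise DegenerateInputError("constant response vector")
    z = centered / norms[..., None]
    corr = np.clip(z @ z.T, -1.0, 1.0)
    values = 1.0 - corr
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return values


def feature_rdm(bank: FeatureBank) -> RDM:
    """RDM over a feature bank's category-mean activation rows."""
    if bank.n_categories < 3:
        raise ValueError("feature_rdm requires >= 3 categories")
    means = bank.category_means
    ptp = means.max(axis=1) - means.min(axis=1)
    if np.any(ptp == 0):
        bad = bank.categories[int(np.argmax(ptp == 0))]
        raise DegenerateInputError(
            f"category {bad!r} has a constant category-mean row in layer {bank.layer_id}"
        )
    return RDM(_one_minus_spearman(means), tuple(bank.categories), source=f"layer={bank.layer_id}")


def _window_sample_slice(times: np.ndarray, start_ms: float, window_ms: float) -> np.ndarray:
    mask = (times >= start_ms) & (times < start_ms + window_ms)
    return np.flatnonzero(mask)


def erp_window_rdm(erp, electrode, window_start_ms: float, window_ms: float = 40.0) -> RDM:
    """RDM of one electrode's voltages within [start, start + window) ms.

    Windows are half-open and onset-anchored; a window running off the end
    of the epoch is truncated and must retain at least 3 samples.
    ``electrode`` may be an id from ``erp.electrodes`` or an integer index.
    """
    if isinstance(electrode, (int, np.integer)):
        e = int(electrode)
    else:
        e = erp.electrodes.index(electrode)
    idx = _window_sample_slice(erp.times, window_start_ms, window_ms)
    if len(idx) < MIN_WINDOW_SAMPLES:
        raise WindowTooShortError(
            f"window at {window_start_ms:g} ms retains {len(idx)} samples (< {MIN_WINDOW_SAMPLES})"
        )
    vectors = erp.voltages[e, idx, :].T  # category x samples
    ptp = vectors.max(axis=1) - vectors.min(axis=1)
    if np.any(ptp == 0):
        bad = erp.categories[int(np.argmax(ptp == 0))]
        raise DegenerateInputError(
            f"category {bad!r} constant in window at {window_start_ms:g} ms, "
            f"electrode {erp.electrodes[e]}"
        )
    return RDM(
        _one_minus_spearman(vectors),
        tuple(erp.categories),
        source=f"electrode={erp.electrodes[e]},window_start={window_start_ms:g}ms",
    )


def sliding_rdms(erp, window_ms: float = 40.0, step_ms: float | None = None) -> RDMSeries:
    """Sliding-window RDM series over every electrode of a category ERP.

    The window slides from the first sample (the start of the baseline) to
    the end of the epoch; the default step is one sample.  Tail windows are
    truncated, and windows with < 3 samples or a zero-variance category
    vector are skipped (NaN) with a notice.
    """
    dt = 1000.0 / erp.sampling_hz
    if step_ms is None:
        step_ms = dt
    if step_ms < dt - 1e-9:
        raise ValueError("step_ms must be at least one sample")
    step = max(1, int(round(step_ms / dt)))
    w = max(1, int(round(window_ms / dt)))
    n_samples = len(erp.times)
    n_cat = len(erp.categories)
    start_idx = np.arange(0, n_samples, step)
    # drop starts whose truncated window falls below the minimum
    start_idx = start_idx[np.minimum(w, n_samples - start_idx) >= MIN_WINDOW_SAMPLES]
    starts_ms = erp.times[start_idx]
    p = n_pairs(n_cat)
    tri = np.tril_indices(n_cat, -1)
    out = np.full((erp.voltages.shape[0], len(start_idx), p), np.nan)
    notices: list = []

    full = start_idx[start_idx + w <= n_samples]
    for e in range(erp.voltages.shape[0]):
        data = erp.voltages[e].T  # category x samples
        if len(full):
            views = sliding_window_view(data, w, axis=1)[:, full, :]  # cat x win x w
            views = np.ascontiguousarray(np.swapaxes(views, 0, 1))  # win x cat x w
            ptp = views.max(axis=2) - views.min(axis=2)
            ok = ~np.any(ptp == 0, axis=1)
            if np.any(ok):
                ranks = _rank_rows(views[ok])
                centered = ranks - ranks.mean(axis=-1, keepdims=True)
                z = centered / np.linalg.norm(centered, axis=-1, keepdims=True)
                corr = np.clip(np.einsum("wck,wdk->wcd", z, z), -1.0, 1.0)
                vals = 1.0 - corr
                out[e, np.flatnonzero(ok), :] = vals[:, tri[0], tri[1]]
            for wi in np.flatnonzero(~ok):
                notices.append(
                    f"degenerate window at electrode {erp.electrodes[e]} "
                    f"start {starts_ms[wi]:g} ms"
                )
        # truncated tail windows
        for k in range(len(full), len(start_idx)):
            i0 = start_idx[k]
            vecs = data[:, i0:]
            ptp = vecs.max(axis=1) - vecs.min(axis=1)
            if np.any(ptp == 0):
                notices.append(
                    f"degenerate window at electrode {erp.electrodes[e]} "
                    f"start {starts_ms[k]:g} ms"
                )
                continue
            vals = _one_minus_spearman(vecs)
            out[e, k, :] = vals[tri]

    return RDMSeries(
        vectors=out,
        window_starts=np.asarray(starts_ms, dtype=float),
        window_ms=float(window_ms),
        step_ms=float(step * dt),
        categories=tuple(erp.categories),
        electrodes=tuple(erp.electrodes),
        notices=notices,
    )


def lower_triangle(rdm: RDM | np.ndarray) -> np.ndarray:
    """Below-diagonal entries in row-major order (row i, columns j < i)."""
    values = rdm.values if isinstance(rdm, RDM) else np.asarray(rdm)
    n = values.shape[0]
    return values[np.tril_indices(n, -1)].copy()


def vector_to_matrix(vec: np.ndarray, n_categories: int) -> np.ndarray:
    """Inverse of :func:`lower_triangle`: symmetrize with a zero diagonal."""
    vec = np.asarray(vec, dtype=float)
    if len(vec) != n_pairs(n_categories):
        raise ValueError("vector length does not match n(n-1)/2")
    m = np.zeros((n_categories, n_categories))
    tri = np.tril_indices(n_categories, -1)
    m[tri] = vec
    return m + m.T
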