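"""Time-resolved encoding of neural RDMs by layered feature RDMs.

The joint model regresses the rank-transformed neural lower-triangle
vector on the rank-transformed layer vectors (ordinary least squares with
an intercept); "variance explained" is the OLS R^2 on that rank scale,
consistent with the Spearman-based single-layer comparisons.  Residuals
are reported as observed minus fitted, mapped back to dissimilarity units
by the ratio of raw to rank standard deviations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .rdm import RDM, RDMSeries, DegenerateInputError, lower_triangle, n_pairs, vector_to_matrix

__all__ = [
    "EncodingFit",
    "SingleLayerFit",
    "EncodingTrace",
    "EncodingSummary",
    "ResidualSummary",
    "encode_all_layers",
    "encode_single_layer",
    "trace_over_time",
    "summarize_trace",
    "residual_analysis",
]

logger = logging.getLogger(__name__)

DEFAULT_BINS = ((0.0, 100.0), (101.0, 200.0), (200.0, 300.0))


@dataclass
class EncodingFit:
    """Joint-model fit: R^2, coefficients, and per-pair residuals."""

    r2: float
    residuals: np.ndarray
    coefficients: np.ndarray
    collinear: bool = False


@dataclass
class SingleLayerFit:
    """Single-layer comparison: Spearman rho and signed rho^2."""

    rho: float
    r2: float

    @property
    def negative(self) -> bool:
        return self.rho < 0


def _as_vector(x) -> np.ndarray:
    if isinstance(x, RDM):
        return lower_triangle(x)
    return np.asarray(x, dtype=float)


def _check_nondegenerate(vec: np.ndarray, name: str) -> None:
    if vec.max() == vec.min():
        raise DegenerateInputError(f"{name} vector has zero variance")


def encode_all_layers(neural, layers, rank_transform: bool = True) -> EncodingFit:
    """OLS of the neural dissimilarity vector on all layer vectors jointly.

    All vectors are rank-transformed first (set ``rank_transform=False`` to
    fit on the raw scale).  A rank-deficient layer set is fitted through
    the pseudoinverse with a logged collinearity warning.
    """
    y_raw = _as_vector(neural)
    X_raw = np.column_stack([_as_vector(l) for l in layers])
    m, p = X_raw.shape
    if len(y_raw) != m:
        raise ValueError("neural and layer vectors must share length")
    if m < p + 3:
        raise ValueError("need at least 2 more observations than predictors")
    _check_nondegenerate(y_raw, "neural")
    if rank_transform:
        y = rankdata(y_raw)
        X = rankdata(X_raw, axis=0)
    else:
        y, X = y_raw, X_raw
    design = np.column_stack([np.ones(m), X])
    rank = np.linalg.matrix_rank(design)
    collinear = rank < design.shape[1]
    if collinear:
        logger.warning("collinear layer set (rank %d < %d); using pseudoinverse", rank, p + 1)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    # map rank-scale residuals back to dissimilarity units
    rank_sd = y.std()
    scale = y_raw.std() / rank_sd if rank_transform and rank_sd > 0 else 1.0
    return EncodingFit(
        r2=float(np.clip(r2, 0.0, 1.0)),
        residuals=resid * scale,
        coefficients=beta,
        collinear=collinear,
    )


def encode_single_layer(neural, layer) -> SingleLayerFit:
    """Spearman correlation of neural and layer vectors; r^2 = rho^2."""
    y = _as_vector(neural)
    x = _as_vector(layer)
    if len(y) != len(x):
        raise ValueError("vectors must share length")
    _check_nondegenerate(y, "neural")
    _check_nondegenerate(x, "layer")
    yr, xr = rankdata(y), rankdata(x)
    yc, xc = yr - yr.mean(), xr - xr.mean()
    rho = float(np.clip(yc @ xc / (np.linalg.norm(yc) * np.linalg.norm(xc)), -1.0, 1.0))
    return SingleLayerFit(rho=rho, r2=rho**2)


@dataclass
class EncodingTrace:
    """Per-unit time course of explained variance.

    ``r2_all`` is the joint-model R^2 per window; ``r2_layer`` (layers x
    windows) the single-layer rho^2 with ``rho_layer`` carrying the signs.
    Skipped windows are NaN.  ``sig_mask`` stays None until the stats stage
    populates it.
    """

    unit: str
    times: np.ndarray
    r2_all: np.ndarray | None = None
    r2_layer: np.ndarray | None = None
    rho_layer: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    layer_sig_mask: np.ndarray | None = None
    residuals: np.ndarray | None = None


def _layer_design(layers) -> tuple[np.ndarray, np.ndarray]:
    X = np.column_stack([_as_vector(l) for l in layers])
    Xr = rankdata(X, axis=0)
    design = np.column_stack([np.ones(X.shape[0]), Xr])
    return design, np.linalg.pinv(design)


def batched_rank_r2(Y: np.ndarray, design: np.ndarray, pinv: np.ndarray,
                    residual_scale: np.ndarray | None = None):
    """Joint-model R^2 for many already-ranked response rows at once.

    Y : (n, pairs) ranked responses (rows may be NaN -> NaN output).
    Returns (r2, residuals) where residuals is None unless
    ``residual_scale`` (per-row factors) is given.
    """
    valid = ~np.any(np.isnan(Y), axis=1)
    r2 = np.full(Y.shape[0], np.nan)
    resid_out = None
    if residual_scale is not None:
        resid_out = np.full(Y.shape, np.nan)
    if np.any(valid):
        Yv = Y[valid]
        coef = Yv @ pinv.T
        fitted = coef @ design.T
        resid = Yv - fitted
        sse = np.sum(resid**2, axis=1)
        centered = Yv - Yv.mean(axis=1, keepdims=True)
        sst = np.sum(centered**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2[valid] = np.clip(1.0 - sse / sst, 0.0, 1.0)
        if residual_scale is not None:
            resid_out[valid] = resid * residual_scale[valid, None]
    return r2, resid_out


def trace_over_time(
    series: RDMSeries,
    layers,
    mode: str = "all",
    store_residuals: bool = False,
) -> list[EncodingTrace]:
    """Apply the chosen encoder at every (electrode, window start).

    ``mode='all'`` fits the joint model per window; ``mode='single'``
    computes each layer's Spearman rho.  ``mode='both'`` does both.
    Skipped windows propagate as NaN and are excluded from summaries.
    """
    if mode not in ("all", "single", "both"):
        raise ValueError("mode must be 'all', 'single' or 'both'")
    for l in layers:
        if isinstance(l, RDM) and tuple(l.categories) != tuple(series.categories):
            raise ValueError("layer RDMs must share the series' category order")
    design, pinv = _layer_design(layers)
    L = len(layers)
    traces = []
    for e, unit in enumerate(series.electrodes):
        Yraw = series.vectors[e]  # (W, P)
        Y = np.full_like(Yraw, np.nan)
        valid = ~np.any(np.isnan(Yraw), axis=1)
        if np.any(valid):
            Y[valid] = rankdata(Yraw[valid], axis=1)
        trace = EncodingTrace(unit=str(unit), times=series.window_starts.copy())
        if mode in ("all", "both"):
            scale = None
            if store_residuals:
                with np.errstate(invalid="ignore"):
                    raw_sd = np.nanstd(Yraw, axis=1)
                    rank_sd = np.nanstd(Y, axis=1)
                scale = np.where(rank_sd > 0, raw_sd / np.where(rank_sd > 0, rank_sd, 1.0), 0.0)
            r2, resid = batched_rank_r2(Y, design, pinv, residual_scale=scale)
            trace.r2_all = r2
            trace.residuals = resid
        if mode in ("single", "both"):
            Xr = design[:, 1:]
            xc = Xr - Xr.mean(axis=0, keepdims=True)
            xn = xc / np.linalg.norm(xc, axis=0, keepdims=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                yc = Y - np.nanmean(Y, axis=1, keepdims=True)
            norms = np.sqrt(np.nansum(yc**2, axis=1, keepdims=True))
            with np.errstate(invalid="ignore", divide="ignore"):
                yn = yc / norms
            rho = np.clip(yn @ xn, -1.0, 1.0).T  # (L, W)
            trace.rho_layer = rho
            trace.r2_layer = rho**2
        traces.append(trace)
    return traces


@dataclass
class BinSummary:
    """Maximum explained variance and its latency within one time bin."""

    bin_ms: tuple
    max_r2: float | None
    latency_ms: float | None


@dataclass
class EncodingSummary:
    """Onset of significant encoding plus per-bin maxima for one trace."""

    unit: str
    onset_ms: float | None
    bins: list


def summarize_trace(trace: EncodingTrace, bins=DEFAULT_BINS, layer: int | None = None) -> EncodingSummary:
    """Onset (first time of the first surviving cluster) and per-bin maxima.

    ``layer=None`` summarises the joint-model trace against ``sig_mask``;
    an integer selects that layer's single-layer trace and mask row.
    """
    if layer is None:
        values = trace.r2_all
        mask = trace.sig_mask
    else:
        values = trace.r2_layer[layer]
        mask = None if trace.layer_sig_mask is None else trace.layer_sig_mask[layer]
    if values is None:
        raise ValueError("trace does not carry the requested statistic")
    if mask is None:
        raise ValueError("sig_mask must be populated before summarising")
    onset = float(trace.times[np.argmax(mask)]) if np.any(mask) else None
    out_bins = []
    for lo, hi in bins:
        in_bin = (trace.times >= lo) & (trace.times <= hi) & ~np.isnan(values)
        if np.any(in_bin):
            idx = np.flatnonzero(in_bin)
            best = idx[np.argmax(values[idx])]
            out_bins.append(BinSummary((lo, hi), float(values[best]), float(trace.times[best])))
        else:
            out_bins.append(BinSummary((lo, hi), None, None))
    return EncodingSummary(unit=trace.unit, onset_ms=onset, bins=out_bins)


@dataclass
class ResidualSummary:
    """Mean residual geometry over a time window, at category and
    superordinate resolution."""

    residual_matrix: np.ndarray
    superordinate_matrix: np.ndarray
    superordinates: tuple
    grouping: dict
    categories: tuple


def residual_analysis(
    residuals_per_participant,
    times: np.ndarray,
    categories,
    grouping: dict,
    window=(50.0, 250.0),
) -> ResidualSummary:
    """Average joint-model residuals over a window and over participants.

    ``residuals_per_participant`` is a sequence of (windows, pairs) arrays
    (NaN rows for skipped windows).  The averaged vector is reshaped to the
    symmetric category matrix, then block-averaged into the superordinate
    matrix; within-block cells average only that block's off-diagonal
    pairs.  Residual sign convention: observed minus fitted dissimilarity,
    so negative values mean the model predicted too much dissimilarity
    (over-predicted distinctness).
    """
    categories = tuple(categories)
    missing = [c for c in categories if c not in grouping]
    if missing:
        raise ValueError(f"grouping is missing categories: {missing}")
    sel = (times >= window[0]) & (times <= window[1])
    if not np.any(sel):
        raise ValueError("window contains no time points")
    stacked = np.stack([np.nanmean(r[sel], axis=0) for r in residuals_per_participant])
    mean_vec = np.nanmean(stacked, axis=0)
    mat = vector_to_matrix(mean_vec, len(categories))

    supers = tuple(dict.fromkeys(grouping[c] for c in categories))
    k = len(supers)
    out = np.zeros((k, k))
    group_idx = {s: [i for i, c in enumerate(categories) if grouping[c] == s] for s in supers}
    for a, sa in enumerate(supers):
        for b, sb in enumerate(supers):
            ia, ib = group_idx[sa], group_idx[sb]
            if a == b:
                vals = [mat[i, j] for i in ia for j in ib if i > j]
            else:
                vals = [mat[i, j] for i in ia for j in ib]
            out[a, b] = float(np.mean(vals))
    out = 0.5 * (out + out.T)
    return ResidualSummary(
        residual_matrix=mat,
        superordinate_matrix=out,
        superordinates=supers,
        grouping=dict(grouping),
        categories=categories,
    )
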