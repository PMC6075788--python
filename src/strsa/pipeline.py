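"""End-to-end pipeline: simulate -> preprocess -> RDM -> encode -> stats ->
clusters -> decode, with all scientific outputs written deterministically.

Units analysed are the all-electrode scalp average (always) plus each
data-driven scalp cluster.  Group-level traces are participant means; the
significance masks come from label-permutation nulls with cluster-extent
correction.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .config import RunConfig
from .encoding import (
    EncodingTrace,
    residual_analysis,
    summarize_trace,
    trace_over_time,
)
from .layer_decoding import decode_all_layers
from .preprocess import (
    CategoryERP,
    bandpass,
    baseline_correct,
    category_means,
    rereference_average,
    subaverage_bootstrap,
    reject_artifacts,
)
from .rdm import feature_rdm, lower_triangle, sliding_rdms
from .scalp_clustering import ScalpCluster, cluster_erp, find_clusters, z_topography
from .stats import cluster_extent_correct, group_null_stats, noise_ceiling_series, PermutationNull
from .synthetic import default_study_preset, simulate_participants, superordinate_grouping

__all__ = ["run_pipeline", "preprocess_participant", "unit_erp", "PipelineResult"]

logger = logging.getLogger(__name__)


def preprocess_participant(epochs, config: RunConfig, seed: int):
    """Full per-participant preprocessing chain -> (CategoryERP, report)."""
    if config.apply_bandpass:
        epochs = bandpass(epochs, *config.band_hz)
    epochs, report = reject_artifacts(epochs, config.reject_uv)
    epochs = baseline_correct(epochs, (-config.baseline_ms, 0.0))
    if config.rereference:
        epochs = rereference_average(epochs)
    epochs = subaverage_bootstrap(epochs, config.subavg_fraction, seed=seed)
    return category_means(epochs), report


def unit_erp(erp: CategoryERP, unit_id: str = "scalp-average") -> CategoryERP:
    """Collapse a multi-electrode ERP to a single virtual unit (mean)."""
    return CategoryERP(
        voltages=erp.voltages.mean(axis=0, keepdims=True),
        times=erp.times,
        sampling_hz=erp.sampling_hz,
        categories=erp.categories,
        electrodes=(unit_id,),
        n_trials_used=erp.n_trials_used,
        participant_id=erp.participant_id,
    )


@dataclass
class PipelineResult:
    """In-memory handle on everything the pipeline computed."""

    config: RunConfig
    layout: object
    truth: object
    clusters: list
    traces: dict
    null_stats: dict
    noise_ceiling: object
    residuals: object
    decoding: list
    summaries: pd.DataFrame
    report: dict


def scalp_average_vectors(erps, config: RunConfig):
    """Per-participant electrode-mean RDM vectors (time, pairs).

    The whole-scalp unit averages each participant's per-electrode
    dissimilarity vectors, the tractable stand-in for averaging
    per-electrode encoding traces over the full array.
    """
    out = []
    starts = None
    for erp in erps:
        series = sliding_rdms(erp, window_ms=config.window_ms, step_ms=config.step_ms)
        out.append(np.nanmean(series.vectors, axis=0))
        starts = series.window_starts
    return out, starts


def _unit_neural_vectors(erps, unit_builder, config: RunConfig):
    """Per-participant (time, pairs) dissimilarity vectors for one unit."""
    out = []
    starts = None
    for erp in erps:
        series = sliding_rdms(unit_builder(erp), window_ms=config.window_ms, step_ms=config.step_ms)
        out.append(series.vectors[0])
        starts = series.window_starts
    return out, starts


def _group_trace(unit, starts, neural, layer_rdms, config, store_residuals=False):
    """Group-mean encoding trace plus per-participant residual stacks."""
    per_sub = []
    residuals = []
    for vec in neural:
        series_like = _FakeSeries(vec, starts, layer_rdms[0].categories, unit)
        tr = trace_over_time(series_like, layer_rdms, mode="both", store_residuals=store_residuals)[0]
        per_sub.append(tr)
        if store_residuals:
            residuals.append(tr.residuals)
    trace = EncodingTrace(
        unit=unit,
        times=starts,
        r2_all=np.nanmean(np.stack([t.r2_all for t in per_sub]), axis=0),
        r2_layer=np.nanmean(np.stack([t.r2_layer for t in per_sub]), axis=0),
        rho_layer=np.nanmean(np.stack([t.rho_layer for t in per_sub]), axis=0),
    )
    return trace, residuals


class _FakeSeries:
    """Adapter presenting one unit's vectors with the RDMSeries interface."""

    def __init__(self, vectors, starts, categories, unit):
        self.vectors = vectors[None, :, :]
        self.window_starts = np.asarray(starts)
        self.categories = tuple(categories)
        self.electrodes = (unit,)


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    """Execute the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash
    timings: dict = {}
    report: dict = {"config_hash": chash, "seed": config.seed, "preset": config.preset}

    def stage(name):
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 3)

    stage("simulate")
    preset = default_study_preset()[config.preset]
    study = simulate_participants(preset, seed=config.seed, artifact_rate=config.artifact_rate)
    sio.write_layout_csv(out / "layout.csv", study.layout)
    sio.write_ground_truth_json(out / "ground_truth.json", study.truth)
    done("simulate")

    stage("preprocess")
    erps = []
    rejection = {}
    for ep in study.epochs:
        erp, rep = preprocess_participant(ep, config, seed=config.seed)
        erps.append(erp)
        rejection[ep.participant_id] = {
            "fraction_rejected": rep.fraction_rejected,
            "rejected_trials": rep.rejected_trials.tolist(),
        }
    (out / "rejection_log.json").write_text(json.dumps(rejection, indent=1, sort_keys=True))
    done("preprocess")

    stage("layer_rdms")
    layer_rdms = [feature_rdm(b) for b in study.banks]
    for rdm in layer_rdms:
        sio.write_rdm_csv(out / f"rdm_{rdm.source.split('=')[1]}.csv", rdm, config_hash=chash)
    done("layer_rdms")

    stage("clusters")
    grand = np.mean([e.voltages.mean(axis=2) for e in erps], axis=0)  # (E, S)
    zmap = z_topography(grand, erps[0].times, (-config.baseline_ms, 0.0),
                        electrode_ids=study.layout.electrode_ids)
    clusters = find_clusters(
        zmap,
        erps[0].times,
        study.layout,
        point_alpha=config.point_alpha,
        min_duration_ms=config.min_cluster_ms,
        seed=config.seed,
    )
    sio.write_clusters_json(out / "clusters.json", clusters, config_hash=chash)
    done("clusters")

    units: dict = {"scalp-average": None}  # electrode-mean RDM vectors
    for k, cl in enumerate(clusters):
        units[f"cluster-{k:02d}"] = (
            lambda erp, cl=cl, k=k: cluster_erp(erp, cl, unit_id=f"cluster-{k:02d}")
        )
    n_comparisons = config.n_comparisons or len(units)

    stage("encode_stats")
    n_cat = len(layer_rdms[0].categories)
    traces: dict = {}
    null_stats: dict = {}
    residuals_scalp = None
    starts_all = None
    for name, builder in units.items():
        if builder is None:
            neural, starts = scalp_average_vectors(erps, config)
        else:
            neural, starts = _unit_neural_vectors(erps, builder, config)
        starts_all = starts
        store_res = name == "scalp-average"
        trace, residuals = _group_trace(name, starts, neural, layer_rdms, config,
                                        store_residuals=store_res)
        nulls = group_null_stats(
            neural, layer_rdms, n_cat,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        null_all = PermutationNull(nulls["all"], seed=config.seed)
        trace.sig_mask = cluster_extent_correct(
            trace.r2_all, null_all, alpha=config.alpha, n_comparisons=n_comparisons
        )
        layer_masks = []
        for l in range(len(layer_rdms)):
            null_l = PermutationNull(nulls["layer"][l], seed=config.seed)
            layer_masks.append(
                cluster_extent_correct(
                    trace.r2_layer[l], null_l, alpha=config.alpha,
                    n_comparisons=n_comparisons * len(layer_rdms),
                )
            )
        trace.layer_sig_mask = np.stack(layer_masks)
        traces[name] = trace
        null_stats[name] = nulls["all"]
        if store_res:
            residuals_scalp = residuals
            ceiling = noise_ceiling_series(neural)
    done("encode_stats")

    stage("summaries")
    rows = []
    for name, trace in traces.items():
        s = summarize_trace(trace, bins=config.bins)
        for b in s.bins:
            rows.append(
                dict(unit=name, layer="all", onset_ms=s.onset_ms, bin_lo=b.bin_ms[0],
                     bin_hi=b.bin_ms[1], max_r2=b.max_r2, latency_ms=b.latency_ms)
            )
        for l in range(len(layer_rdms)):
            sl = summarize_trace(trace, bins=config.bins, layer=l)
            for b in sl.bins:
                rows.append(
                    dict(unit=name, layer=f"layer{l + 1}", onset_ms=sl.onset_ms,
                         bin_lo=b.bin_ms[0], bin_hi=b.bin_ms[1], max_r2=b.max_r2,
                         latency_ms=b.latency_ms)
                )
    summaries = pd.DataFrame(rows)
    with open(out / "summaries.csv", "w") as f:
        f.write(f"# config_hash={chash}\n")
        summaries.to_csv(f, index=False, float_format="%.17g")

    grouping = superordinate_grouping(layer_rdms[0].categories)
    resid = residual_analysis(
        residuals_scalp, starts_all, layer_rdms[0].categories, grouping,
        window=config.residual_window,
    )
    pd.DataFrame(
        resid.superordinate_matrix, index=list(resid.superordinates),
        columns=list(resid.superordinates),
    ).to_csv(out / "residual_superordinate.csv", float_format="%.17g")
    pd.DataFrame(
        resid.residual_matrix, index=list(resid.categories), columns=list(resid.categories)
    ).to_csv(out / "residual_matrix.csv", float_format="%.17g")

    pd.DataFrame(
        {"time_ms": starts_all, "lower": ceiling.lower, "upper": ceiling.upper}
    ).to_csv(out / "noise_ceiling.csv", index=False, float_format="%.17g")
    done("summaries")

    stage("decode")
    decoding = decode_all_layers(study.banks, n_folds=config.n_folds, seed=config.seed)
    pd.DataFrame(
        [
            dict(layer=d.layer_id, fold=i, accuracy=a)
            for d in decoding
            for i, a in enumerate(d.fold_accuracies)
        ]
    ).to_csv(out / "decoding.csv", index=False, float_format="%.17g")
    done("decode")

    # traces to HDF5
    import h5py

    with h5py.File(out / "traces.h5", "w") as f:
        for name, trace in traces.items():
            g = f.create_group(name)
            g.create_dataset("times", data=trace.times, track_times=False)
            g.create_dataset("r2_all", data=trace.r2_all, track_times=False)
            g.create_dataset("r2_layer", data=trace.r2_layer, track_times=False)
            g.create_dataset("sig_mask", data=trace.sig_mask, track_times=False)
            g.create_dataset("layer_sig_mask", data=trace.layer_sig_mask, track_times=False)
        f.attrs["config_hash"] = chash

    config.to_json(out / "config.json")
    report["n_clusters"] = len(clusters)
    report["units"] = list(traces.keys())
    scalp = traces["scalp-average"]
    s_all = summarize_trace(scalp, bins=config.bins)
    report["scalp_onset_ms"] = s_all.onset_ms
    finite = ~np.isnan(scalp.r2_all)
    report["scalp_max_r2"] = float(np.nanmax(scalp.r2_all)) if np.any(finite) else None
    report["scalp_peak_latency_ms"] = (
        float(scalp.times[np.nanargmax(scalp.r2_all)]) if np.any(finite) else None
    )
    report["decoding_accuracy"] = {d.layer_id: d.accuracy for d in decoding}
    layer_onsets = []
    for l in range(len(layer_rdms)):
        sl = summarize_trace(scalp, bins=config.bins, layer=l)
        layer_onsets.append(sl.onset_ms)
    report["layer_onsets_ms"] = layer_onsets
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    # timings are diagnostics, not scientific output; kept apart from report.json
    (out / "run_log.json").write_text(json.dumps({"stage_seconds": timings}, indent=1))

    return PipelineResult(
        config=config,
        layout=study.layout,
        truth=study.truth,
        clusters=clusters,
        traces=traces,
        null_stats=null_stats,
        noise_ceiling=ceiling,
        residuals=resid,
        decoding=decoding,
        summaries=summaries,
        report=report,
    )
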