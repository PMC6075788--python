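"""On-disk formats: HDF5 epoch bundles, layout/bank/RDM CSV, result tables.

The epoch bundle schema: HDF5 groups ``/voltages`` (electrodes x samples x
trials, float, microvolts), ``/labels`` (per-trial category id),
``/times`` (ms), ``/valid`` (boolean), with attributes ``sampling_hz``,
``participant_id`` and ``categories``.  All datasets are written with
``track_times=False`` so identical runs produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .preprocess import CategoryERP, EpochSet
from .rdm import FeatureBank, RDM, RDMSeries
from .synthetic import GroundTruth, SensorLayout

__all__ = [
    "BundleSchemaError",
    "write_bundle",
    "read_bundle",
    "write_erp",
    "read_erp",
    "write_layout_csv",
    "read_layout_csv",
    "write_feature_bank_csv",
    "read_feature_bank_csv",
    "write_ground_truth_json",
    "write_rdm_csv",
    "read_rdm_csv",
    "write_rdm_long_csv",
    "write_rdm_series",
    "read_rdm_series",
    "write_clusters_json",
    "read_clusters_json",
]

_H5 = dict(track_times=False)


class BundleSchemaError(ValueError):
    """An epoch bundle violates the on-disk schema."""


def _require(f: h5py.File, name: str):
    if name not in f:
        raise BundleSchemaError(f"bundle is missing dataset {name}")
    return f[name]


def write_bundle(path, epochs: EpochSet, config_hash: str = "") -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=epochs.voltages, **_H5)
        f.create_dataset(
            "labels", data=np.asarray([str(l) for l in epochs.labels], dtype="S32"), **_H5
        )
        f.create_dataset("times", data=epochs.times, **_H5)
        f.create_dataset("valid", data=epochs.valid_mask, **_H5)
        f.attrs["sampling_hz"] = float(epochs.sampling_hz)
        f.attrs["participant_id"] = str(epochs.participant_id)
        f.attrs["categories"] = np.asarray([str(c) for c in epochs.categories], dtype="S32")
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_bundle(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        voltages = _require(f, "voltages")[()]
        labels = np.asarray([s.decode() for s in _require(f, "labels")[()]], dtype=object)
        times = _require(f, "times")[()]
        valid = _require(f, "valid")[()].astype(bool)
        if "sampling_hz" not in f.attrs:
            raise BundleSchemaError("bundle is missing attribute sampling_hz")
        categories = tuple(s.decode() for s in f.attrs["categories"])
        if voltages.ndim != 3:
            raise BundleSchemaError("/voltages must be electrodes x samples x trials")
        if len(labels) != voltages.shape[2]:
            raise BundleSchemaError("/labels length does not match the /voltages trial axis")
        if len(times) != voltages.shape[1]:
            raise BundleSchemaError("/times length does not match the /voltages sample axis")
        if len(valid) != voltages.shape[2]:
            raise BundleSchemaError("/valid length does not match the /voltages trial axis")
        unknown = set(labels.tolist()) - set(categories)
        if unknown:
            raise BundleSchemaError(f"/labels contains unknown categories: {sorted(unknown)}")
        return EpochSet(
            voltages=voltages,
            labels=labels,
            times=times,
            sampling_hz=float(f.attrs["sampling_hz"]),
            participant_id=str(f.attrs["participant_id"]),
            categories=categories,
            valid_mask=valid,
        )


def write_erp(path, erp: CategoryERP, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltages", data=erp.voltages, **_H5)
        f.create_dataset("times", data=erp.times, **_H5)
        f.create_dataset("n_trials_used", data=erp.n_trials_used, **_H5)
        f.attrs["sampling_hz"] = float(erp.sampling_hz)
        f.attrs["participant_id"] = str(erp.participant_id)
        f.attrs["categories"] = np.asarray([str(c) for c in erp.categories], dtype="S32")
        f.attrs["electrodes"] = np.asarray([str(e) for e in erp.electrodes], dtype="S48")
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_erp(path) -> CategoryERP:
    with h5py.File(path, "r") as f:
        return CategoryERP(
            voltages=f["voltages"][()],
            times=f["times"][()],
            sampling_hz=float(f.attrs["sampling_hz"]),
            categories=tuple(s.decode() for s in f.attrs["categories"]),
            electrodes=tuple(s.decode() for s in f.attrs["electrodes"]),
            n_trials_used=f["n_trials_used"][()],
            participant_id=str(f.attrs["participant_id"]),
        )


def write_layout_csv(path, layout: SensorLayout) -> None:
    with open(path, "w") as f:
        f.write(f"# adjacency_radius={layout.adjacency_radius!r}\n")
        f.write("electrode_id,x,y\n")
        for eid, (x, y) in zip(layout.electrode_ids, layout.positions):
            f.write(f"{eid},{float(x)!r},{float(y)!r}\n")


def read_layout_csv(path) -> SensorLayout:
    radius = None
    with open(path) as f:
        first = f.readline()
        if first.startswith("# adjacency_radius="):
            radius = float(first.split("=", 1)[1])
    if radius is None:
        raise ValueError("layout CSV is missing the adjacency_radius header comment")
    df = pd.read_csv(path, comment="#")
    positions = df[["x", "y"]].to_numpy(dtype=float)
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    adjacency = dist < radius
    np.fill_diagonal(adjacency, False)
    return SensorLayout(tuple(df["electrode_id"]), positions, adjacency, radius)


def write_feature_bank_csv(path, bank: FeatureBank) -> None:
    df = pd.DataFrame(bank.activations, columns=[f"f{i}" for i in range(bank.activations.shape[1])])
    df.insert(0, "label", bank.labels)
    with open(path, "w") as f:
        f.write(f"# layer_id={bank.layer_id}\n")
        df.to_csv(f, index=False)


def read_feature_bank_csv(path) -> FeatureBank:
    layer_id = Path(path).stem
    with open(path) as f:
        first = f.readline()
        if first.startswith("# layer_id="):
            layer_id = first.split("=", 1)[1].strip()
    df = pd.read_csv(path, comment="#")
    labels = df["label"].to_numpy()
    categories = tuple(dict.fromkeys(labels.tolist()))
    return FeatureBank(
        layer_id=layer_id,
        activations=df.drop(columns="label").to_numpy(dtype=float),
        labels=labels,
        categories=categories,
    )


def write_ground_truth_json(path, truth: GroundTruth) -> None:
    payload = {
        "layer_latencies": truth.layer_latencies.tolist(),
        "layer_embeddings": truth.layer_embeddings.tolist(),
        "category_signals": None
        if truth.category_signals is None
        else truth.category_signals.tolist(),
        "layer_loadings": None if truth.layer_loadings is None else truth.layer_loadings.tolist(),
        "layer_regions": None
        if truth.layer_regions is None
        else [sorted(r) for r in truth.layer_regions],
        "noise_sd": truth.noise_sd,
        "seed": truth.seed,
        "amplitude": truth.amplitude,
        "evoked_offset": truth.evoked_offset,
        "artifact_log": {k: np.asarray(v).tolist() for k, v in truth.artifact_log.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def write_rdm_csv(path, rdm: RDM, config_hash: str = "") -> None:
    df = pd.DataFrame(rdm.values, index=list(rdm.categories), columns=list(rdm.categories))
    with open(path, "w") as f:
        if config_hash:
            f.write(f"# config_hash={config_hash}\n")
        if rdm.source:
            f.write(f"# source={rdm.source}\n")
        df.to_csv(f, float_format="%.17g")


def read_rdm_csv(path) -> RDM:
    df = pd.read_csv(path, comment="#", index_col=0)
    return RDM(df.to_numpy(dtype=float), tuple(df.columns))


def write_rdm_long_csv(path, rdm: RDM) -> None:
    rows = []
    for i, ci in enumerate(rdm.categories):
        for j, cj in enumerate(rdm.categories):
            if j < i:
                rows.append((ci, cj, rdm.values[i, j]))
    pd.DataFrame(rows, columns=["cat_i", "cat_j", "dissimilarity"]).to_csv(path, index=False)


def write_rdm_series(path, series: RDMSeries, config_hash: str = "") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=series.vectors, **_H5)
        f.create_dataset("window_starts", data=series.window_starts, **_H5)
        f.attrs["window_ms"] = series.window_ms
        f.attrs["step_ms"] = series.step_ms
        f.attrs["categories"] = np.asarray([str(c) for c in series.categories], dtype="S32")
        f.attrs["electrodes"] = np.asarray([str(e) for e in series.electrodes], dtype="S48")
        if config_hash:
            f.attrs["config_hash"] = config_hash


def read_rdm_series(path) -> RDMSeries:
    with h5py.File(path, "r") as f:
        return RDMSeries(
            vectors=f["vectors"][()],
            window_starts=f["window_starts"][()],
            window_ms=float(f.attrs["window_ms"]),
            step_ms=float(f.attrs["step_ms"]),
            categories=tuple(s.decode() for s in f.attrs["categories"]),
            electrodes=tuple(s.decode() for s in f.attrs["electrodes"]),
        )


def write_clusters_json(path, clusters, config_hash: str = "") -> None:
    payload = {
        "config_hash": config_hash,
        "clusters": [
            {
                "electrodes": sorted(c.electrodes),
                "onset_ms": c.onset_ms,
                "offset_ms": c.offset_ms,
                "peak_z": c.peak_z,
            }
            for c in clusters
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_clusters_json(path):
    from .scalp_clustering import ScalpCluster

    payload = json.loads(Path(path).read_text())
    return [
        ScalpCluster(
            electrodes=frozenset(c["electrodes"]),
            onset_ms=c["onset_ms"],
            offset_ms=c["offset_ms"],
            peak_z=c["peak_z"],
        )
        for c in payload["clusters"]
    ]
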