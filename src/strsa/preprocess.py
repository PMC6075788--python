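"""Preprocessing of epoched EEG voltages.

Raw epochs (electrodes x samples x trials, in microvolts) are band-pass
filtered, screened for amplitude artifacts, baseline corrected to the
pre-stimulus interval, optionally re-referenced to the net average, and
sub-average bootstrapped before category-mean ERPs are formed.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "EpochSet",
    "CategoryERP",
    "RejectionReport",
    "ParticipantExcludedError",
    "bandpass",
    "reject_artifacts",
    "baseline_correct",
    "rereference_average",
    "subaverage_bootstrap",
    "category_means",
]


class ParticipantExcludedError(RuntimeError):
    """Raised when a participant retains fewer than half of their trials."""


@dataclass
class EpochSet:
    """One participant's epoched voltages with per-trial category labels.

    voltages : (electrodes, samples, trials) array, microvolts
    labels   : per-trial category identifiers drawn from ``categories``
    times    : per-sample latency relative to stimulus onset, milliseconds
    valid_mask : trials that survive screening so far
    """

    voltages: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    sampling_hz: float
    participant_id: str
    categories: tuple
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.labels = np.asarray(self.labels)
        self.times = np.asarray(self.times, dtype=float)
        if self.voltages.ndim != 3:
            raise ValueError("voltages must be electrodes x samples x trials")
        if len(self.times) != self.voltages.shape[1]:
            raise ValueError("times length must equal the sample count")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, 1000.0 / self.sampling_hz, atol=1e-6)):
            raise ValueError("times must increase uniformly at 1/sampling_hz")
        if len(self.labels) != self.voltages.shape[2]:
            raise ValueError("labels length must equal the trial count")
        if not set(self.labels.tolist()) <= set(self.categories):
            raise ValueError("labels contain categories outside the declared set")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.voltages.shape[2], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if len(self.valid_mask) != self.voltages.shape[2]:
            raise ValueError("valid_mask length must equal the trial count")

    @property
    def n_electrodes(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def n_trials(self) -> int:
        return self.voltages.shape[2]


@dataclass
class CategoryERP:
    """Category-mean ERPs: (electrodes, samples, categories) in microvolts."""

    voltages: np.ndarray
    times: np.ndarray
    sampling_hz: float
    categories: tuple
    electrodes: tuple
    n_trials_used: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if not np.all(np.isfinite(self.voltages)):
            raise ValueError("CategoryERP voltages must be finite")
        if self.voltages.shape != (
            len(self.electrodes),
            len(self.times),
            len(self.categories),
        ):
            raise ValueError("CategoryERP axes inconsistent with metadata")


def design_bandpass(low_hz: float, high_hz: float, sampling_hz: float) -> np.ndarray:
    """Second-order sections of the 4th-order Butterworth band-pass used here."""
    nyq = sampling_hz / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError("band edges must satisfy 0 < low < high < Nyquist")
    return signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=sampling_hz, output="sos")


def bandpass(epochs: EpochSet, low_hz: float = 0.1, high_hz: float = 45.0) -> EpochSet:
    """Zero-phase band-pass per electrode and trial.

    The per-trial mean (DC) is removed explicitly before forward-backward
    filtering: epoch segments are far shorter than the low-edge period, so
    the recursive filter alone cannot settle on the DC component within an
    epoch.  Forward-backward application squares the magnitude response,
    so stop-band attenuation doubles in dB relative to a single pass.
    """
    sos = design_bandpass(low_hz, high_hz, epochs.sampling_hz)
    v = epochs.voltages - epochs.voltages.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, v, axis=1)
    return replace(epochs, voltages=filtered)


@dataclass
class RejectionReport:
    """Outcome of amplitude screening for one participant."""

    participant_id: str
    threshold_uv: float
    rejected_trials: np.ndarray
    n_trials: int

    @property
    def fraction_rejected(self) -> float:
        return len(self.rejected_trials) / self.n_trials if self.n_trials else 0.0


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = 100.0
) -> tuple[EpochSet, RejectionReport]:
    """Invalidate trials with any sample strictly exceeding +-threshold_uv.

    The test is strict (|V| > threshold): a sample exactly at the threshold
    survives.  If fewer than half of all trials remain valid afterwards the
    participant is excluded via :class:`ParticipantExcludedError`.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    exceeds = np.any(np.abs(epochs.voltages) > threshold_uv, axis=(0, 1))
    rejected = np.flatnonzero(exceeds & epochs.valid_mask)
    mask = epochs.valid_mask & ~exceeds
    report = RejectionReport(
        participant_id=epochs.participant_id,
        threshold_uv=float(threshold_uv),
        rejected_trials=rejected,
        n_trials=epochs.n_trials,
    )
    if mask.sum() < 0.5 * epochs.n_trials:
        raise ParticipantExcludedError(
            f"participant {epochs.participant_id}: only {int(mask.sum())} of "
            f"{epochs.n_trials} trials valid after +-{threshold_uv:g} uV screening"
        )
    return replace(epochs, valid_mask=mask), report


def _baseline_sample_index(epochs: EpochSet, baseline_ms) -> np.ndarray:
    lo, hi = baseline_ms
    idx = np.flatnonzero((epochs.times >= lo) & (epochs.times < hi))
    if len(idx) == 0:
        raise ValueError(f"baseline interval [{lo:g}, {hi:g}) ms contains no samples")
    return idx


def baseline_correct(epochs: EpochSet, baseline_ms=( -100.0, 0.0)) -> EpochSet:
    """Subtract each trial's mean voltage over the pre-stimulus baseline.

    The default interval is the final 100 ms before stimulus onset.
    """
    if baseline_ms[1] > 0:
        raise ValueError("baseline interval must lie in the pre-stimulus period")
    idx = _baseline_sample_index(epochs, baseline_ms)
    means = epochs.voltages[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, voltages=epochs.voltages - means)


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-reference to the net average: subtract the mean over electrodes."""
    return replace(epochs, voltages=epochs.voltages - epochs.voltages.mean(axis=0, keepdims=True))


def _trial_rng(master_seed: int, participant_id: str, cat_index: int, ordinal: int):
    pid_key = zlib.crc32(str(participant_id).encode())
    return np.random.default_rng([int(master_seed) % 2**31, pid_key, cat_index, ordinal])


def subaverage_bootstrap(epochs: EpochSet, fraction: float = 0.2, seed: int = 0) -> EpochSet:
    """Replace each valid trial by a sub-average of same-category trials.

    For each valid trial of a category with n_c valid trials, the surrogate
    is the mean of ceil(fraction * n_c) distinct valid trials of that
    category, always including the anchor trial itself, with the remainder
    drawn uniformly without replacement.  Output trials are the surrogates
    of the valid input trials, in input order.

    Sampling is keyed to (participant, category, within-category ordinal)
    derived from the master seed, so each surrogate depends only on the
    anchor's position among its category's valid trials.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    valid = np.flatnonzero(epochs.valid_mask)
    out = np.empty((epochs.n_electrodes, epochs.n_samples, len(valid)))
    out_labels = epochs.labels[valid]
    for ci, cat in enumerate(epochs.categories):
        members = valid[epochs.labels[valid] == cat]
        if len(members) == 0:
            continue
        if len(members) < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 valid trials")
        n_c = len(members)
        k = math.ceil(fraction * n_c)
        cat_data = epochs.voltages[:, :, members]
        out_pos = np.flatnonzero(out_labels == cat)
        for j in range(n_c):
            if k == 1:
                chosen = np.array([j])
            else:
                rng = _trial_rng(seed, epochs.participant_id, ci, j)
                others = np.delete(np.arange(n_c), j)
                chosen = np.concatenate([[j], rng.choice(others, size=k - 1, replace=False)])
            out[:, :, out_pos[j]] = cat_data[:, :, chosen].mean(axis=2)
    return replace(
        epochs,
        voltages=out,
        labels=out_labels,
        valid_mask=np.ones(len(valid), dtype=bool),
    )


def category_means(epochs: EpochSet) -> CategoryERP:
    """Per-category mean ERP over valid trials."""
    n_cat = len(epochs.categories)
    out = np.empty((epochs.n_electrodes, epochs.n_samples, n_cat))
    counts = np.zeros(n_cat, dtype=int)
    for ci, cat in enumerate(epochs.categories):
        members = np.flatnonzero((epochs.labels == cat) & epochs.valid_mask)
        if len(members) == 0:
            raise ValueError(f"category {cat!r} has no valid trials")
        counts[ci] = len(members)
        out[:, :, ci] = epochs.voltages[:, :, members].mean(axis=2)
    return CategoryERP(
        voltages=out,
        times=epochs.times,
        sampling_hz=epochs.sampling_hz,
        categories=tuple(epochs.categories),
        electrodes=tuple(f"E{i:03d}" for i in range(epochs.n_electrodes)),
        n_trials_used=counts,
        participant_id=epochs.participant_id,
    )
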