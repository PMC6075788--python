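"""Filtering, artifact screening, baseline correction, sub-averaging."""

import numpy as np
import pytest
from scipy import signal as sps

from strsa.preprocess import (
    EpochSet,
    ParticipantExcludedError,
    bandpass,
    baseline_correct,
    category_means,
    design_bandpass,
    reject_artifacts,
    subaverage_bootstrap,
)


def _tone_epochs(freq_hz, fs=250.0, dur_s=4.0, amp=5.0):
    times = np.arange(-1000.0, dur_s * 1000.0 - 1000.0, 1000.0 / fs)
    v = amp * np.sin(2 * np.pi * freq_hz * times / 1000.0)
    return EpochSet(
        voltages=np.tile(v, (2, 1))[:, :, None],
        labels=np.array(["a"], dtype=object),
        times=times,
        sampling_hz=fs,
        participant_id="p",
        categories=("a",),
    )


class TestBandpass:
    def test_dc_removed(self, small_epochs):
        const = small_epochs
        const.voltages[:] = 5.0
        out = bandpass(const, 0.1, 45.0)
        assert np.abs(out.voltages).mean() < 0.5

    def test_in_band_tone_preserved(self):
        out = bandpass(_tone_epochs(10.0), 0.1, 45.0)
        mid = slice(200, 800)
        ratio = out.voltages[0, mid, 0].std() / _tone_epochs(10.0).voltages[0, mid, 0].std()
        assert abs(20 * np.log10(ratio)) < 1.0

    def test_stopband_tone_matches_frequency_response_oracle(self):
        """60 Hz attenuation agrees with |H(f)|^2 of the designed filter.

        The tone amplitude is measured by quadrature demodulation so the
        slow transient of the 0.1 Hz pole does not contaminate the ratio.
        """

        def tone_amp(v, times, f):
            ref_s = np.sin(2 * np.pi * f * times / 1000.0)
            ref_c = np.cos(2 * np.pi * f * times / 1000.0)
            return 2 * np.hypot(v @ ref_s, v @ ref_c) / len(times)

        ep = _tone_epochs(60.0)
        out = bandpass(ep, 0.1, 45.0)
        mid = slice(200, 800)
        t = ep.times[mid]
        ratio = tone_amp(out.voltages[0, mid, 0], t, 60.0) / tone_amp(
            ep.voltages[0, mid, 0], t, 60.0
        )
        atten_db = -20 * np.log10(ratio)
        assert atten_db >= 20.0
        sos = design_bandpass(0.1, 45.0, 250.0)
        _, h = sps.sosfreqz(sos, worN=[60.0], fs=250.0)
        predicted_db = -20 * np.log10(np.abs(h[0]) ** 2)  # forward-backward squares |H|
        assert atten_db == pytest.approx(predicted_db, abs=1.5)

    def test_nyquist_violation_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            bandpass(small_epochs, 0.1, 200.0)


class TestRejectArtifacts:
    def test_clean_data_untouched(self, small_epochs):
        small_epochs.voltages[:] = 0.0
        out, report = reject_artifacts(small_epochs, 100.0)
        assert report.fraction_rejected == 0.0
        assert out.valid_mask.all()

    def test_strict_threshold_boundary(self, small_epochs):
        small_epochs.voltages[:] = 0.0
        small_epochs.voltages[0, 3, 2] = 100.0  # exactly at threshold: kept
        small_epochs.voltages[1, 5, 7] = 100.5  # strictly above: rejected
        out, report = reject_artifacts(small_epochs, 100.0)
        assert out.valid_mask[2]
        assert not out.valid_mask[7]
        assert list(report.rejected_trials) == [7]

    def test_injected_spikes_rejected_exactly(self, desk_layout):
        from strsa.synthetic import EpochTiming, gen_epochs, gen_feature_banks

        banks, truth = gen_feature_banks(30, 10, (20,) * 8, np.linspace(0.2, 3, 8), seed=6,
                                         noise_sd=10.0)
        ep = gen_epochs(desk_layout, banks, truth, 10, epoch=EpochTiming(100, 750, 250.0),
                        artifact_rate=0.1, seed=31)
        out, report = reject_artifacts(ep, 100.0)
        assert set(report.rejected_trials.tolist()) == set(
            truth.artifact_log[ep.participant_id].tolist()
        )

    def test_majority_rejection_excludes_participant(self, small_epochs):
        small_epochs.voltages[:] = 500.0
        with pytest.raises(ParticipantExcludedError):
            reject_artifacts(small_epochs, 100.0)

    def test_idempotent(self, small_epochs):
        small_epochs.voltages[0, 0, 0] = 150.0
        once, _ = reject_artifacts(small_epochs, 100.0)
        twice, rep = reject_artifacts(once, 100.0)
        assert np.array_equal(once.valid_mask, twice.valid_mask)
        assert rep.fraction_rejected == 0.0


class TestBaselineCorrect:
    def test_constant_trial_zeroed(self, small_epochs):
        small_epochs.voltages[:] = 3.0
        out = baseline_correct(small_epochs, (-40.0, 0.0))
        assert np.allclose(out.voltages, 0.0)

    def test_baseline_mean_zero_and_idempotent(self, small_epochs):
        out = baseline_correct(small_epochs, (-40.0, 0.0))
        idx = (out.times >= -40) & (out.times < 0)
        assert np.all(np.abs(out.voltages[:, idx, :].mean(axis=1)) < 1e-9)
        again = baseline_correct(out, (-40.0, 0.0))
        assert np.allclose(out.voltages, again.voltages)

    def test_ramp_matches_direct_subtraction(self, small_epochs):
        ramp = np.linspace(0, 10, small_epochs.n_samples)
        small_epochs.voltages[:] = ramp[None, :, None]
        out = baseline_correct(small_epochs, (-40.0, 0.0))
        idx = (small_epochs.times >= -40) & (small_epochs.times < 0)
        expected = ramp - ramp[idx].mean()
        assert np.allclose(out.voltages[0, :, 0], expected, atol=1e-12)

    def test_empty_baseline_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            baseline_correct(small_epochs, (-0.5, -0.4))


class TestSubaverage:
    def test_full_fraction_gives_category_mean(self, small_epochs):
        out = subaverage_bootstrap(small_epochs, fraction=1.0, seed=0)
        for cat in small_epochs.categories:
            members = small_epochs.labels == cat
            mean = small_epochs.voltages[:, :, members].mean(axis=2)
            for t in np.flatnonzero(out.labels == cat):
                assert np.allclose(out.voltages[:, :, t], mean)

    def test_each_surrogate_averages_exactly_k_trials(self):
        # constant-per-trial voltages make the averaged subset identifiable
        times = np.arange(-40.0, 160.0, 4.0)
        vals = np.arange(10, dtype=float) * 7 + 1
        v = np.ones((2, len(times), 10)) * vals[None, None, :]
        ep = EpochSet(v, np.array(["a"] * 10, dtype=object), times, 250.0, "p", ("a",))
        out = subaverage_bootstrap(ep, fraction=0.2, seed=3)  # ceil(0.2*10) = 2
        for j in range(10):
            s = out.voltages[0, 0, j]
            other = 2 * s - vals[j]  # anchor always included
            assert np.any(np.isclose(other, np.delete(vals, j)))

    def test_fraction_one_over_n_is_identity(self):
        times = np.arange(-40.0, 160.0, 4.0)
        v = np.random.default_rng(0).normal(size=(2, len(times), 10))
        ep = EpochSet(v, np.array(["a"] * 10, dtype=object), times, 250.0, "p", ("a",))
        out = subaverage_bootstrap(ep, fraction=0.1, seed=3)  # ceil(1) = 1 trial
        assert np.allclose(out.voltages, v)

    def test_deterministic_per_seed(self, small_epochs):
        a = subaverage_bootstrap(small_epochs, 0.5, seed=9)
        b = subaverage_bootstrap(small_epochs, 0.5, seed=9)
        c = subaverage_bootstrap(small_epochs, 0.5, seed=10)
        assert np.array_equal(a.voltages, b.voltages)
        assert not np.array_equal(a.voltages, c.voltages)

    def test_variance_reduced_on_noisy_data(self):
        times = np.arange(-40.0, 160.0, 4.0)
        reduced = 0
        for seed in range(20):
            v = np.random.default_rng(seed).normal(size=(1, len(times), 20))
            ep = EpochSet(v, np.array(["a"] * 20, dtype=object), times, 250.0, "p", ("a",))
            out = subaverage_bootstrap(ep, 0.2, seed=seed)
            if out.voltages.var(axis=2).mean() < v.var(axis=2).mean():
                reduced += 1
        assert reduced == 20

    def test_too_few_trials_rejected(self):
        times = np.arange(-40.0, 160.0, 4.0)
        ep = EpochSet(
            np.zeros((1, len(times), 1)), np.array(["a"], dtype=object), times, 250.0, "p", ("a",)
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            subaverage_bootstrap(ep, 0.5, seed=0)


class TestCategoryMeans:
    def test_single_trial_categories_pass_through(self, rng):
        times = np.arange(-40.0, 160.0, 4.0)
        v = rng.normal(size=(3, len(times), 2))
        ep = EpochSet(v, np.array(["a", "b"], dtype=object), times, 250.0, "p", ("a", "b"))
        erp = category_means(ep)
        assert np.allclose(erp.voltages[:, :, 0], v[:, :, 0])
        assert np.allclose(erp.voltages[:, :, 1], v[:, :, 1])

    def test_matches_naive_summation(self, small_epochs):
        erp = category_means(small_epochs)
        for ci, cat in enumerate(small_epochs.categories):
            total = np.zeros_like(small_epochs.voltages[:, :, 0])
            n = 0
            for t in range(small_epochs.n_trials):
                if small_epochs.labels[t] == cat and small_epochs.valid_mask[t]:
                    total += small_epochs.voltages[:, :, t]
                    n += 1
            assert np.all(np.abs(erp.voltages[:, :, ci] - total / n) < 1e-12)
        assert np.array_equal(erp.n_trials_used, [4, 4, 4])

    def test_empty_category_rejected(self, small_epochs):
        small_epochs.valid_mask[small_epochs.labels == "b"] = False
        with pytest.raises(ValueError, match="'b'"):
            category_means(small_epochs)
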