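"""Joint and single-layer encoding, trace summaries, residual geometry."""

import numpy as np
import pytest

from strsa.encoding import (
    EncodingTrace,
    encode_all_layers,
    encode_single_layer,
    residual_analysis,
    summarize_trace,
    trace_over_time,
)
from strsa.rdm import RDMSeries, n_pairs, vector_to_matrix


@pytest.fixture
def layer_vectors(rng):
    return [rng.normal(size=435) + 1.0 for _ in range(8)]


class TestEncodeAllLayers:
    def test_neural_equal_to_one_layer_is_perfect(self, layer_vectors):
        fit = encode_all_layers(layer_vectors[0], layer_vectors)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_monotone_transform_of_layer_is_perfect(self, layer_vectors):
        # rank regression: any monotone transform of a predictor is fitted exactly
        fit = encode_all_layers(np.exp(layer_vectors[2]), layer_vectors)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_independent_neural_matches_analytic_mean_r2(self, rng):
        """For a random response, E[R^2] = p / (m - 1) under OLS."""
        layers = [rng.normal(size=435) for _ in range(8)]
        r2s = [
            encode_all_layers(rng.normal(size=435), layers).r2 for _ in range(400)
        ]
        assert np.mean(r2s) == pytest.approx(8 / 434, abs=0.005)

    def test_orthogonal_planted_shares_recovered_exactly(self, rng):
        # raw-scale fit on orthogonalized predictors with known contributions
        X = rng.normal(size=(435, 8))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        w = np.arange(1.0, 9.0)
        y = Q @ w
        fit = encode_all_layers(y, list(Q.T), rank_transform=False)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        planted = 0.64
        noise = rng.normal(size=435)
        noise -= Q @ (Q.T @ noise)  # orthogonal to predictors
        noise -= noise.mean()
        noise *= np.linalg.norm(y - y.mean()) * np.sqrt(1 / planted - 1) / np.linalg.norm(noise)
        fit2 = encode_all_layers(y + noise, list(Q.T), rank_transform=False)
        assert fit2.r2 == pytest.approx(planted, abs=1e-6)

    def test_collinear_layers_warn_but_fit(self, rng, caplog):
        x = rng.normal(size=435)
        layers = [x, 2 * x + 1, rng.normal(size=435)]
        with caplog.at_level("WARNING"):
            fit = encode_all_layers(rng.normal(size=435), layers)
        assert "collinear" in caplog.text
        assert 0.0 <= fit.r2 <= 1.0

    def test_nesting_beats_single_layers(self, rng):
        for _ in range(10):
            layers = [rng.normal(size=120) for _ in range(5)]
            y = rng.normal(size=120)
            joint = encode_all_layers(y, layers).r2
            best = max(encode_single_layer(y, l).r2 for l in layers)
            assert joint >= best - 1e-10

    def test_consistent_relabeling_invariance(self, rng):
        n = 12
        perm = rng.permutation(n)
        idx = np.zeros((n, n), dtype=int)
        tri = np.tril_indices(n, -1)
        idx[tri] = np.arange(n_pairs(n))
        idx += idx.T
        pair_perm = idx[np.ix_(perm, perm)][tri]
        layers = [rng.normal(size=n_pairs(n)) for _ in range(3)]
        y = rng.normal(size=n_pairs(n))
        a = encode_all_layers(y, layers).r2
        b = encode_all_layers(y[pair_perm], [l[pair_perm] for l in layers]).r2
        assert a == pytest.approx(b, abs=1e-12)


class TestEncodeSingleLayer:
    def test_identity_and_reversal(self, rng):
        x = rng.normal(size=50)
        up = encode_single_layer(x, x)
        assert up.rho == pytest.approx(1.0) and up.r2 == pytest.approx(1.0)
        down = encode_single_layer(x, -x)
        assert down.rho == pytest.approx(-1.0) and down.r2 == pytest.approx(1.0)
        assert down.negative

    def test_matches_explicit_rank_oracle(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(11)
        a, b = rng.normal(size=435), rng.normal(size=435)
        ra, rb = rankdata(a), rankdata(b)
        expected = np.corrcoef(ra, rb)[0, 1]
        assert encode_single_layer(a, b).rho == pytest.approx(expected, abs=1e-12)


def _series_from_vectors(vectors, starts):
    n_cat = int(round((1 + np.sqrt(1 + 8 * vectors.shape[-1])) / 2))
    return RDMSeries(
        vectors=vectors[None, :, :],
        window_starts=np.asarray(starts, dtype=float),
        window_ms=40.0,
        step_ms=float(starts[1] - starts[0]),
        categories=tuple(f"c{i}" for i in range(n_cat)),
        electrodes=("unit",),
    )


class TestTraceOverTime:
    def test_planted_layer_peaks_at_planted_time(self, rng):
        layers = [np.abs(rng.normal(size=45)) for _ in range(3)]
        starts = np.arange(-100.0, 300.0, 10.0)
        peak = 15  # index of the planted peak (50 ms)
        weight = np.exp(-0.5 * ((np.arange(len(starts)) - peak) / 3.0) ** 2)
        vectors = np.stack(
            [1.0 + w * layers[1] + 0.05 * rng.normal(size=45) for w in weight]
        )
        traces = trace_over_time(_series_from_vectors(vectors, starts), layers, mode="both")
        t = traces[0]
        assert abs(starts[np.nanargmax(t.r2_layer[1])] - starts[peak]) <= 30.0
        assert np.nanmax(t.r2_layer[1]) > np.nanmax(t.r2_layer[0])

    def test_skipped_windows_propagate_as_nan(self, rng):
        layers = [rng.normal(size=45) for _ in range(2)]
        vectors = rng.normal(size=(5, 45)) + 1.0
        vectors[2] = np.nan
        traces = trace_over_time(
            _series_from_vectors(vectors, np.arange(5) * 10.0), layers, mode="both"
        )
        assert np.isnan(traces[0].r2_all[2])
        assert np.isnan(traces[0].r2_layer[:, 2]).all()
        assert np.isfinite(traces[0].r2_all[[0, 1, 3, 4]]).all()


class TestSummarizeTrace:
    def _trace(self, times, r2, mask):
        return EncodingTrace(
            unit="u", times=np.asarray(times, float), r2_all=np.asarray(r2, float),
            sig_mask=np.asarray(mask, bool),
        )

    def test_all_false_mask_gives_absent_onset(self):
        t = self._trace([0, 10, 20], [0.1, 0.2, 0.3], [False] * 3)
        s = summarize_trace(t, bins=((0, 20),))
        assert s.onset_ms is None
        assert s.bins[0].max_r2 == pytest.approx(0.3)

    def test_contiguous_run_onset(self):
        times = np.arange(0, 200, 10.0)
        mask = (times >= 80) & (times <= 120)
        t = self._trace(times, np.linspace(0, 0.5, len(times)), mask)
        assert summarize_trace(t, bins=((0, 100),)).onset_ms == 80.0

    def test_bin_maxima_and_latency(self):
        times = np.arange(0, 300, 10.0)
        r2 = np.zeros(len(times))
        r2[times == 50] = 0.4
        r2[times == 250] = 0.6
        t = self._trace(times, r2, np.ones(len(times), bool))
        s = summarize_trace(t, bins=((0, 100), (200, 300)))
        assert s.bins[0].max_r2 == pytest.approx(0.4) and s.bins[0].latency_ms == 50.0
        assert s.bins[1].max_r2 == pytest.approx(0.6) and s.bins[1].latency_ms == 250.0

    def test_nan_windows_excluded_from_bins(self):
        times = np.arange(0, 100, 10.0)
        r2 = np.full(len(times), np.nan)
        r2[3] = 0.2
        t = self._trace(times, r2, np.zeros(len(times), bool))
        s = summarize_trace(t, bins=((0, 100),))
        assert s.bins[0].max_r2 == pytest.approx(0.2)


class TestResidualAnalysis:
    def _grouping(self, n=6):
        cats = tuple(f"c{i}" for i in range(n))
        groups = {c: ["ga", "gb", "gc"][i // 2] for i, c in enumerate(cats)}
        return cats, groups

    def test_zero_residuals_give_zero_matrices(self):
        cats, groups = self._grouping()
        res = residual_analysis(
            [np.zeros((5, 15))], np.arange(5) * 50.0, cats, groups, window=(50, 250)
        )
        assert np.allclose(res.residual_matrix, 0.0)
        assert np.allclose(res.superordinate_matrix, 0.0)

    def test_planted_block_sign_isolates(self):
        cats, groups = self._grouping()
        mat = np.zeros((6, 6))
        for i in range(4, 6):
            for j in range(4, 6):
                if i != j:
                    mat[i, j] = -1.0  # model over-predicts gc distinctness
        vec = mat[np.tril_indices(6, -1)]
        res = residual_analysis(
            [np.tile(vec, (3, 1))], np.array([50.0, 100.0, 150.0]), cats, groups
        )
        s = res.superordinate_matrix
        gc = res.superordinates.index("gc")
        assert s[gc, gc] == pytest.approx(-1.0)
        mask = np.ones_like(s, dtype=bool)
        mask[gc, gc] = False
        assert np.allclose(s[mask], 0.0)

    def test_block_means_match_enumeration(self, rng):
        cats, groups = self._grouping()
        vec = rng.normal(size=15)
        res = residual_analysis([vec[None, :]], np.array([100.0]), cats, groups)
        mat = vector_to_matrix(vec, 6)
        for a, sa in enumerate(res.superordinates):
            for b, sb in enumerate(res.superordinates):
                ia = [i for i, c in enumerate(cats) if groups[c] == sa]
                ib = [i for i, c in enumerate(cats) if groups[c] == sb]
                if a == b:
                    vals = [mat[i, j] for i in ia for j in ib if i > j]
                else:
                    vals = [mat[i, j] for i in ia for j in ib]
                assert res.superordinate_matrix[a, b] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_missing_category_in_grouping_raises(self):
        cats, groups = self._grouping()
        del groups["c3"]
        with pytest.raises(ValueError, match="c3"):
            residual_analysis([np.zeros((2, 15))], np.array([60.0, 70.0]), cats, groups)
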