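import itertools

import numpy as np
import pytest

from speechtrf.components import (
    COMPONENT_WINDOWS,
    ComponentError,
    assemble_feature_table,
    default_manifest,
    dtw_path,
    find_grand_peak,
    grand_average,
    map_peak_latency,
    position_contrasts,
    window_amplitude,
)
from speechtrf.trf import LagAxis, TRFSet


def _trfset(kernels_by_feature, lag_axis, channels=("Cz",)):
    feats = list(kernels_by_feature)
    weights = np.stack([[kernels_by_feature[f] for f in feats]
                        for _ in channels])
    return TRFSet("word_class", feats, lag_axis, weights,
                  np.zeros(len(channels)), channel_names=tuple(channels))


def exhaustive_dtw(a, b):
    """Brute-force oracle: enumerate every monotone path, return min cost."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, cost):
        cost += abs(a[i] - b[j])
        if cost >= best[0]:
            return
        if (i, j) == (n - 1, m - 1):
            best[0] = cost
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            if i + di < n and j + dj < m:
                walk(i + di, j + dj, cost)

    walk(0, 0, 0.0)
    return best[0]


class TestGrandAverage:
    def test_single_participant_identity(self, lag_axis):
        k = np.sin(np.linspace(0, 3, lag_axis.n_lags))
        t = _trfset({"open": k}, lag_axis)
        np.testing.assert_array_equal(grand_average([t], "open", "Cz"), k)

    def test_opposite_kernels_cancel(self, lag_axis):
        k = np.sin(np.linspace(0, 3, lag_axis.n_lags))
        ts = [_trfset({"open": k}, lag_axis), _trfset({"open": -k}, lag_axis)]
        np.testing.assert_allclose(grand_average(ts, "open", "Cz"), 0.0,
                                   atol=1e-15)

    def test_average_peak_between_extremes(self, lag_axis):
        lags = lag_axis.lags_ms
        ts = [_trfset({"open": -np.exp(-0.5 * ((lags - c) / 50) ** 2)},
                      lag_axis) for c in (400.0, 500.0)]
        g = grand_average(ts, "open", "Cz")
        peak = find_grand_peak(g, lag_axis, COMPONENT_WINDOWS["late_open"])
        assert 400.0 < peak < 500.0

    def test_empty_input_rejected(self):
        with pytest.raises(ComponentError):
            grand_average([], "open", "Cz")


class TestWindowAmplitude:
    def test_constant_series(self, lag_axis):
        assert window_amplitude(np.ones(lag_axis.n_lags), lag_axis,
                                COMPONENT_WINDOWS["N1"]) == 1.0

    def test_linear_ramp_gives_midpoint(self, lag_axis):
        series = lag_axis.lags_ms.copy()  # value == lag in ms
        amp = window_amplitude(series, lag_axis, (300.0, 600.0))
        assert amp == pytest.approx(450.0)

    def test_sign_flip_linearity(self, lag_axis):
        rng = np.random.default_rng(0)
        s = rng.standard_normal(lag_axis.n_lags)
        a = window_amplitude(s, lag_axis, COMPONENT_WINDOWS["P2"])
        assert window_amplitude(-s, lag_axis,
                                COMPONENT_WINDOWS["P2"]) == pytest.approx(-a)


class TestFindGrandPeak:
    def test_constructed_late_bump_at_455(self, lag_axis):
        lags = lag_axis.lags_ms
        series = -np.exp(-0.5 * ((lags - 455.0) / 70.0) ** 2)
        assert find_grand_peak(series, lag_axis,
                               COMPONENT_WINDOWS["late_open"]) == 455.0

    def test_monotone_series_boundary_or_no_peak(self, lag_axis):
        falling = -np.linspace(0, 1, lag_axis.n_lags)  # minimum at the end
        assert find_grand_peak(falling, lag_axis,
                               COMPONENT_WINDOWS["late_open"]) == 600.0
        rising = np.linspace(0.1, 1, lag_axis.n_lags)  # never negative
        assert find_grand_peak(rising, lag_axis,
                               COMPONENT_WINDOWS["late_open"]) is None

    def test_tie_takes_earlier(self, lag_axis):
        series = np.zeros(lag_axis.n_lags)
        series[lag_axis.index_of_ms(400.0)] = -1.0
        series[lag_axis.index_of_ms(500.0)] = -1.0
        assert find_grand_peak(series, lag_axis,
                               COMPONENT_WINDOWS["late_open"]) == 400.0


class TestDtw:
    def test_identical_series_diagonal_zero_cost(self):
        a = np.array([0.0, 1.0, 3.0, 2.0, 0.5])
        path, cost = dtw_path(a, a)
        assert cost == 0.0
        assert path == [(i, i) for i in range(a.size)]

    def test_total_cost_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.standard_normal(rng.integers(2, 10))
            b = rng.standard_normal(rng.integers(2, 10))
            assert dtw_path(a, b)[1] == pytest.approx(dtw_path(b, a)[1])

    def test_matches_exhaustive_oracle_short_series(self):
        rng = np.random.default_rng(2)
        for _ in range(60):
            a = rng.integers(-3, 4, rng.integers(2, 9)).astype(float)
            b = rng.integers(-3, 4, rng.integers(2, 9)).astype(float)
            assert dtw_path(a, b)[1] == pytest.approx(exhaustive_dtw(a, b))


class TestMapPeakLatency:
    def _wave(self, lag_axis, shift=0.0):
        lags = lag_axis.lags_ms
        return (-1.0 * np.exp(-0.5 * ((lags - 120 - shift) / 15) ** 2)
                + 1.1 * np.exp(-0.5 * ((lags - 215 - shift) / 25) ** 2)
                - 0.9 * np.exp(-0.5 * ((lags - 455 - shift) / 70) ** 2))

    def test_identity_returns_grand_peak(self, lag_axis):
        g = self._wave(lag_axis)
        peak = find_grand_peak(g, lag_axis, COMPONENT_WINDOWS["late_open"])
        assert map_peak_latency(g, g, peak, lag_axis) == peak

    def test_pure_shift_recovered(self, lag_axis):
        g = self._wave(lag_axis)
        peak = find_grand_peak(g, lag_axis, COMPONENT_WINDOWS["late_open"])
        step = 1000.0 / lag_axis.fs
        for shift in (-25.0, 25.0, 50.0):
            lat = map_peak_latency(self._wave(lag_axis, shift), g, peak,
                                   lag_axis)
            assert abs(lat - (peak + shift)) <= step + 1e-9

    def test_amplitude_scaling_invariance(self, lag_axis):
        g = self._wave(lag_axis)
        peak = find_grand_peak(g, lag_axis, COMPONENT_WINDOWS["late_open"])
        assert map_peak_latency(2.0 * g, g, peak, lag_axis) == peak


class TestPositionContrasts:
    def test_equal_values_zero(self):
        out = position_contrasts({"beginning": -1.5, "middle": -1.5,
                                  "end": -1.5})
        assert all(v == 0.0 for v in out.values())

    def test_arithmetic_and_antisymmetry(self):
        out = position_contrasts({"beginning": -2.0, "middle": -1.2,
                                  "end": -1.0})
        assert out["beginning-end"] == pytest.approx(-1.0)
        assert out["beginning-middle"] == pytest.approx(-0.8)
        assert out["middle-end"] == pytest.approx(
            -(out["beginning-middle"] - out["beginning-end"]))

    def test_missing_side_gives_nan(self):
        out = position_contrasts({"beginning": -2.0, "end": -1.0})
        assert np.isnan(out["beginning-middle"])
        assert out["beginning-end"] == pytest.approx(-1.0)


class TestManifest:
    def test_default_manifest_counts_117(self):
        manifest = default_manifest()
        assert len(manifest) == 117
        # 39 distinct feature x measure combinations, 3 channels each
        combos = {(e.scheme, e.feature, e.component, e.measure)
                  for e in manifest}
        assert len(combos) == 39
        assert {e.channel for e in manifest} == {"Fz", "Cz", "Pz"}

    def test_no_clear_peak_exclusions(self):
        manifest = default_manifest()
        # latency dropped for pronouns / BE / auxiliary verbs
        for pos in ("pronoun", "be_verb", "auxiliary_verb"):
            assert not any(e.feature == pos and e.measure == "latency"
                           for e in manifest)
            assert any(e.feature == pos and e.measure == "amplitude"
                       for e in manifest)
        # numbers, interrogatives, relative pronouns, conjunctions absent
        for pos in ("number", "interrogative_word", "relative_pronoun",
                    "conjunction"):
            assert not any(e.feature == pos for e in manifest)

    def test_names_unique(self):
        names = [e.name for e in default_manifest()]
        assert len(names) == len(set(names))


class TestAssembleFeatureTable:
    def _toy_cohort(self, lag_axis, n=3):
        lags = lag_axis.lags_ms
        trfsets = []
        for p in range(n):
            shift = 10.0 * p
            k_open = (-np.exp(-0.5 * ((lags - 120 - shift) / 15) ** 2)
                      - 0.9 * np.exp(-0.5 * ((lags - 455 - shift) / 70) ** 2))
            k_closed = -np.exp(-0.5 * ((lags - 700 - shift) / 90) ** 2)
            trfsets.append(_trfset({"open": k_open, "closed": k_closed},
                                   lag_axis, channels=("Fz", "Cz", "Pz")))
        return {"word_class": trfsets}

    def _toy_manifest(self):
        from speechtrf.components import ManifestEntry
        return [
            ManifestEntry("word_class", "open", "N1", "amplitude", "Cz"),
            ManifestEntry("word_class", "open", "N1", "latency", "Cz"),
            ManifestEntry("word_class", "open", "late_open", "latency", "Cz"),
            ManifestEntry("word_class", "closed", "late_closed", "amplitude",
                          "Pz"),
        ]

    def test_shape_contract(self, lag_axis):
        trfsets = self._toy_cohort(lag_axis, n=2)
        ft = assemble_feature_table(trfsets, np.array([500.0, 600.0]),
                                    self._toy_manifest())
        assert ft.table.shape == (2, 5)  # 4 features + score

    def test_deterministic(self, lag_axis):
        trfsets = self._toy_cohort(lag_axis)
        scores = np.array([450.0, 550.0, 650.0])
        a = assemble_feature_table(trfsets, scores, self._toy_manifest())
        b = assemble_feature_table(trfsets, scores, self._toy_manifest())
        assert a.table.equals(b.table)

    def test_latencies_track_planted_shifts(self, lag_axis):
        trfsets = self._toy_cohort(lag_axis)
        ft = assemble_feature_table(trfsets, np.array([1.0, 2.0, 3.0]),
                                    self._toy_manifest())
        lats = ft.table["word_class.open.late_open.latency.Cz"].to_numpy()
        assert lats[0] < lats[1] < lats[2]

    def test_amplitude_sign_matches_polarity(self, lag_axis):
        """Window holding a negative bump yields a negative mean amplitude."""
        trfsets = self._toy_cohort(lag_axis)
        ft = assemble_feature_table(trfsets, np.zeros(3),
                                    self._toy_manifest())
        assert (ft.table["word_class.open.N1.amplitude.Cz"] < 0).all()

    def test_score_mismatch_rejected(self, lag_axis):
        with pytest.raises(ComponentError):
            assemble_feature_table(self._toy_cohort(lag_axis), np.zeros(2),
                                   self._toy_manifest())


class TestDtwProperties:
    """Hypothesis property tests for the warping-path contract."""

    from hypothesis import given, settings, strategies as st

    series = st.lists(st.floats(-5, 5, allow_nan=False, width=32),
                      min_size=2, max_size=12)

    @given(a=series, b=series)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_cost_nonnegative_symmetric_and_optimal(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        path, cost = dtw_path(a, b)
        assert cost >= 0.0
        assert cost == pytest.approx(dtw_path(b, a)[1])
        assert cost == pytest.approx(exhaustive_dtw(a, b))
        # path is monotone, continuous, and spans both series
        assert path[0] == (0, 0) and path[-1] == (a.size - 1, b.size - 1)
        for (i0, j0), (i1, j1) in zip(path, path[1:]):
            assert (i1 - i0, j1 - j0) in ((1, 0), (0, 1), (1, 1))

    @given(a=series)
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_self_alignment_is_free(self, a):
        a = np.asarray(a)
        path, cost = dtw_path(a, a)
        assert cost == 0.0
        assert path == [(i, i) for i in range(a.size)]
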