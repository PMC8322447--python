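"""Component features extracted from estimated TRFs.

Three components are measured on every relevant TRF: the N1 (negative,
90-140 ms), the P2 (positive, 190-250 ms) and a late component — the
N400-like negativity of open-class words (300-600 ms) or the slower
negativity of closed-class words (500-800 ms).

Amplitudes are window means.  Latencies are found on the cohort
grand-average waveform first and then transferred to each participant by
dynamic time warping (DTW): the indices of the individual series that the
optimal warping path matches to the grand-average peak index are collected
and their (lower) median, converted to ms, is the individual latency.  DTW
runs on z-normalised series restricted to non-negative lags so amplitude
scale cannot dominate the temporal alignment.

The default feature manifest enumerates 117 participant-level features:
39 feature x measure combinations at each of the three midline electrodes
(Fz, Cz, Pz) — word class (12), speech rate (4), word-position pairwise
contrasts (6) and parts of speech (17, honouring the exclusions of
components without clear peaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage

from .trf import LagAxis, TRFSet

__all__ = [
    "COMPONENT_WINDOWS",
    "MANIFEST_CHANNELS",
    "ComponentWindow",
    "ManifestEntry",
    "FeatureTable",
    "default_manifest",
    "grand_average",
    "window_amplitude",
    "find_grand_peak",
    "dtw_path",
    "map_peak_latency",
    "position_contrasts",
    "assemble_feature_table",
]


class ComponentError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentWindow:
    component: str
    window_ms: tuple[float, float]
    polarity: int  # -1 negative, +1 positive

    def __post_init__(self) -> None:
        if self.window_ms[0] >= self.window_ms[1]:
            raise ComponentError("window lower bound must be < upper bound")


COMPONENT_WINDOWS = {
    "N1": ComponentWindow("N1", (90.0, 140.0), -1),
    "P2": ComponentWindow("P2", (190.0, 250.0), +1),
    "late_open": ComponentWindow("late_open", (300.0, 600.0), -1),
    "late_closed": ComponentWindow("late_closed", (500.0, 800.0), -1),
}

#: Electrodes entering the default manifest (the montage's midline sites).
MANIFEST_CHANNELS = ("Fz", "Cz", "Pz")

_POSITION_PAIRS = (("beginning", "middle"), ("beginning", "end"),
                   ("middle", "end"))


# ---------------------------------------------------------------------------
# Elementary measures
# ---------------------------------------------------------------------------

def grand_average(trfsets: list[TRFSet], feature: str, channel) -> np.ndarray:
    """Pointwise mean lag series across participants."""
    if not trfsets:
        raise ComponentError("grand average of an empty cohort")
    return np.mean([t.kernel(feature, channel) for t in trfsets], axis=0)


def _window_indices(lag_axis: LagAxis, window_ms: tuple[float, float]
                    ) -> np.ndarray:
    lags = lag_axis.lags_ms
    idx = np.flatnonzero((lags >= window_ms[0] - 1e-9)
                         & (lags <= window_ms[1] + 1e-9))
    if idx.size == 0:
        raise ComponentError(f"window {window_ms} outside the lag axis")
    return idx


def window_amplitude(series: np.ndarray, lag_axis: LagAxis,
                     window: ComponentWindow | tuple[float, float]) -> float:
    """Mean of the samples whose lag falls in the window (inclusive)."""
    wms = window.window_ms if isinstance(window, ComponentWindow) else window
    return float(np.mean(series[_window_indices(lag_axis, wms)]))


def find_grand_peak(series: np.ndarray, lag_axis: LagAxis,
                    window: ComponentWindow) -> float | None:
    """Latency (ms) of the polarity-matching extremum inside the window.

    Ties take the earliest latency.  If the extremum does not have the
    required sign there is no peak of that component: ``None`` is returned
    and the feature is treated as missing downstream.
    """
    idx = _window_indices(lag_axis, window.window_ms)
    vals = series[idx]
    k = int(np.argmin(vals)) if window.polarity < 0 else int(np.argmax(vals))
    if window.polarity * vals[k] <= 0:
        return None
    return float(lag_axis.lags_ms[idx[k]])


# ---------------------------------------------------------------------------
# Dynamic time warping
# ---------------------------------------------------------------------------

def dtw_path(a: np.ndarray, b: np.ndarray
             ) -> tuple[list[tuple[int, int]], float]:
    """Optimal monotone warping path between two series.

    Local cost |a_i - b_j|; steps (1,0), (0,1), (1,1); the path runs from
    (0, 0) to (len(a)-1, len(b)-1) and minimises the summed local cost.
    Backtracking breaks ties preferring the diagonal step, then (1,0).
    Returns ``(path, total_cost)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ComponentError("DTW inputs must be non-empty")
    n, m = a.size, b.size
    cost = np.abs(a[:, None] - b[None, :])
    D = np.full((n, m), np.inf)
    D[0, 0] = cost[0, 0]
    D[1:, 0] = np.cumsum(cost[1:, 0]) + cost[0, 0]
    D[0, 1:] = np.cumsum(cost[0, 1:]) + cost[0, 0]
    for i in range(1, n):
        Di, Dp = D[i], D[i - 1]
        for j in range(1, m):
            Di[j] = cost[i, j] + min(Dp[j - 1], Dp[j], Di[j - 1])

    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            candidates = ((D[i - 1, j - 1], (i - 1, j - 1)),
                          (D[i - 1, j], (i - 1, j)),
                          (D[i, j - 1], (i, j - 1)))
            _, (i, j) = min(candidates, key=lambda t: t[0])
        path.append((i, j))
    path.reverse()
    return path, float(D[n - 1, m - 1])


def _znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def map_peak_latency(individual: np.ndarray, grand: np.ndarray,
                     grand_peak_ms: float, lag_axis: LagAxis, *,
                     z_normalize: bool = True,
                     restrict_nonnegative: bool = True,
                     smooth_ms: float = 50.0,
                     pool_halfwidth_ms: float = 150.0) -> float:
    """Transfer a grand-average peak latency onto an individual TRF.

    Both series are smoothed with a Gaussian kernel of SD ``smooth_ms``
    (symmetric smoothing moves no peak), z-normalised and restricted to
    lags >= 0, then aligned by DTW.  The warp around the grand peak is read
    off the path: for every path pair (i, j) with j within
    ``pool_halfwidth_ms`` of the grand-peak index, the shift-corrected
    individual index ``i - (j - j_peak)`` is collected, and the lower
    median of those indices, converted back to ms, is the individual peak
    latency.  Pooling over the component's temporal support (rather than
    the single peak column) keeps the estimate stable when the waveform is
    flat near its extremum.
    """
    lags_ms = lag_axis.lags_ms
    sel = np.flatnonzero(lags_ms >= 0) if restrict_nonnegative else \
        np.arange(lags_ms.size)
    ind = individual[sel].astype(float)
    gra = grand[sel].astype(float)
    if smooth_ms > 0:
        sigma = smooth_ms / 1000.0 * lag_axis.fs
        ind = scipy.ndimage.gaussian_filter1d(ind, sigma)
        gra = scipy.ndimage.gaussian_filter1d(gra, sigma)
    if z_normalize:
        ind, gra = _znorm(ind), _znorm(gra)
    peak_j = int(np.argmin(np.abs(lags_ms[sel] - grand_peak_ms)))
    pool = max(0, int(round(pool_halfwidth_ms / 1000.0 * lag_axis.fs)))
    path, _ = dtw_path(ind, gra)
    matched = sorted(i - (j - peak_j) for i, j in path
                     if abs(j - peak_j) <= pool)
    med = matched[(len(matched) - 1) // 2]  # lower median -> earlier tie
    return float(lags_ms[sel][int(np.clip(med, 0, sel.size - 1))])


def position_contrasts(values: dict[str, float]) -> dict[str, float]:
    """Pairwise beginning/middle/end differences (NaN where a side is missing)."""
    out = {}
    for a, b in _POSITION_PAIRS:
        va, vb = values.get(a), values.get(b)
        out[f"{a}-{b}"] = (float(va - vb)
                          if va is not None and vb is not None
                          and not (np.isnan(va) or np.isnan(vb)) else np.nan)
    return out


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestEntry:
    scheme: str        # which TRF estimation run the entry reads from
    feature: str       # stimulus feature row, or "a-b" position contrast
    component: str     # key into COMPONENT_WINDOWS
    measure: str       # amplitude | latency
    channel: str

    @property
    def name(self) -> str:
        return f"{self.scheme}.{self.feature}.{self.component}.{self.measure}.{self.channel}"

    @property
    def is_contrast(self) -> bool:
        return "-" in self.feature


def default_manifest(channels=MANIFEST_CHANNELS) -> list[ManifestEntry]:
    """The 117-entry participant-feature manifest (39 measures x 3 sites).

    Exclusions baked in: latency is dropped for pronouns, BE verbs and
    auxiliary verbs (no clear grand-average peaks) and numbers,
    interrogative words, relative pronouns and conjunctions are absent
    entirely (no clear slow negativity).
    """
    spec: list[tuple[str, str, str, tuple[str, ...]]] = []
    for wc, late in (("open", "late_open"), ("closed", "late_closed")):
        for comp in ("N1", "P2", late):
            spec.append(("word_class", wc, comp, ("amplitude", "latency")))
    for rate in ("fast", "slow"):
        spec.append(("speech_rate", rate, "late_open", ("amplitude", "latency")))
    for a, b in _POSITION_PAIRS:
        spec.append(("word_position", f"{a}-{b}", "late_open",
                     ("amplitude", "latency")))
    for pos in ("general_noun", "proper_noun", "verb", "adjective", "adverb"):
        spec.append(("parts_of_speech", pos, "late_open",
                     ("amplitude", "latency")))
    for pos in ("article_determiner", "preposition"):
        spec.append(("parts_of_speech", pos, "late_closed",
                     ("amplitude", "latency")))
    for pos in ("pronoun", "be_verb", "auxiliary_verb"):
        spec.append(("parts_of_speech", pos, "late_closed", ("amplitude",)))

    return [ManifestEntry(scheme, feat, comp, measure, ch)
            for scheme, feat, comp, measures in spec
            for measure in measures
            for ch in channels]


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Participants x features with the score column and assembly notes."""

    table: pd.DataFrame                  # one row per participant
    manifest: list[ManifestEntry]
    missing: dict[str, int]              # column -> imputed count
    no_peak_features: list[str]          # columns dropped to all-missing

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.table.columns if c != "score"]


def _measure_column(trfsets: list[TRFSet], feature: str, channel: str,
                    window: ComponentWindow, measure: str,
                    lag_axis: LagAxis) -> np.ndarray:
    if measure == "amplitude":
        return np.array([window_amplitude(t.kernel(feature, channel),
                                          lag_axis, window)
                         for t in trfsets])
    grand = grand_average(trfsets, feature, channel)
    peak = find_grand_peak(grand, lag_axis, window)
    if peak is None:
        return np.full(len(trfsets), np.nan)
    halfwidth = (window.window_ms[1] - window.window_ms[0]) / 2.0
    return np.array([map_peak_latency(t.kernel(feature, channel), grand,
                                      peak, lag_axis,
                                      pool_halfwidth_ms=halfwidth)
                     for t in trfsets])


def assemble_feature_table(trfsets_by_scheme: dict[str, list[TRFSet]],
                           scores: np.ndarray,
                           manifest: list[ManifestEntry] | None = None, *,
                           impute: bool = True) -> FeatureTable:
    """Build the participant x feature table from per-scheme TRF sets.

    Amplitudes are window means; latencies are grand-average peaks
    transferred by DTW; position-contrast entries are built from the three
    per-position values of the same component and measure.  Features whose
    grand average has no polarity-matching peak become missing, as do
    contrasts with a missing side; missing values are imputed with the
    cohort median (columns missing everywhere are filled with 0 and listed
    in ``no_peak_features``).
    """
    manifest = manifest if manifest is not None else default_manifest()
    n = {len(v) for v in trfsets_by_scheme.values()}
    if len(n) != 1:
        raise ComponentError("schemes disagree on participant count")
    n = n.pop()
    if len(scores) != n:
        raise ComponentError("scores/participant count mismatch")

    cache: dict[tuple, np.ndarray] = {}

    def column(scheme: str, feature: str, comp: str, measure: str,
               channel: str) -> np.ndarray:
        key = (scheme, feature, comp, measure, channel)
        if key not in cache:
            if scheme not in trfsets_by_scheme:
                raise ComponentError(f"no TRFs supplied for scheme {scheme!r}")
            trfsets = trfsets_by_scheme[scheme]
            if feature not in trfsets[0].feature_names:
                raise ComponentError(
                    f"feature {feature!r} absent from scheme {scheme!r}")
            cache[key] = _measure_column(trfsets, feature, channel,
                                         COMPONENT_WINDOWS[comp], measure,
                                         trfsets[0].lag_axis)
        return cache[key]

    data: dict[str, np.ndarray] = {}
    for e in manifest:
        if e.is_contrast:
            a, b = e.feature.split("-")
            data[e.name] = (column(e.scheme, a, e.component, e.measure, e.channel)
                            - column(e.scheme, b, e.component, e.measure,
                                     e.channel))
        else:
            data[e.name] = column(e.scheme, e.feature, e.component, e.measure,
                                  e.channel)

    table = pd.DataFrame(data)
    missing = {c: int(table[c].isna().sum())
               for c in table.columns if table[c].isna().any()}
    no_peak = [c for c in table.columns if table[c].isna().all()]
    if impute:
        for c in missing:
            if table[c].isna().all():
                table[c] = 0.0
            else:
                table[c] = table[c].fillna(table[c].median())
    table["score"] = np.asarray(scores, dtype=float)
    return FeatureTable(table=table, manifest=manifest, missing=missing,
                        no_peak_features=no_peak)
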