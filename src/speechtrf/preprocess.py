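"""Deterministic EEG signal conditioning.

Fixed pipeline order: re-reference to the earlobe average -> 0.5-50 Hz
bandpass FIR (order 3300, designed at the 500 Hz acquisition rate) ->
resample to 200 Hz -> (external artifact removal happens here in a real
study) -> 7 Hz low-pass FIR (order 1320).  Filters are windowed-sinc
(Hamming) linear-phase designs and are applied zero-phase by default so
component latencies are not shifted; a causal mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

__all__ = ["EEGRecording", "rereference", "fir_filter", "resample",
           "preprocess_pipeline"]


class PreprocessError(ValueError):
    pass


@dataclass
class EEGRecording:
    """Multichannel EEG with sampling rate, labels and trial boundaries."""

    values: np.ndarray                 # (n_channels, n_samples)
    fs: float
    channel_names: tuple[str, ...]
    trials: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise PreprocessError("fs must be positive")
        if len(self.channel_names) != self.values.shape[0]:
            raise PreprocessError("channel_names/values mismatch")
        n = self.values.shape[1]
        for on, off in self.trials:
            if not (0 <= on < off <= n):
                raise PreprocessError(f"trial boundary ({on}, {off}) outside record")


def rereference(rec: EEGRecording, reference_channels) -> EEGRecording:
    """Subtract the mean of the reference channels; drop them from output."""
    refs = list(reference_channels)
    for r in refs:
        if r not in rec.channel_names:
            raise PreprocessError(f"reference channel {r!r} not in recording")
    ref_idx = [rec.channel_names.index(r) for r in refs]
    keep = [i for i, name in enumerate(rec.channel_names) if name not in refs]
    ref_mean = rec.values[ref_idx].mean(axis=0)
    return replace(rec, values=rec.values[keep] - ref_mean,
                   channel_names=tuple(rec.channel_names[i] for i in keep))


_FILTERS = {
    # kind: (order, band, pass_zero)
    "bandpass": (3300, (0.5, 50.0), False),
    "lowpass": (1320, 7.0, True),
}


def design_fir(kind: str, fs: float) -> np.ndarray:
    """Hamming windowed-sinc taps for the named filter at rate ``fs``."""
    if kind not in _FILTERS:
        raise PreprocessError(f"unknown filter kind {kind!r}")
    order, band, pass_zero = _FILTERS[kind]
    hi = band[1] if isinstance(band, tuple) else band
    if hi >= fs / 2:
        raise PreprocessError(f"cutoff {hi} Hz >= Nyquist at fs {fs}")
    return scipy.signal.firwin(order + 1, band, pass_zero=pass_zero,
                               window="hamming", fs=fs)


def fir_filter(rec: EEGRecording, kind: str, *,
               zero_phase: bool = True) -> EEGRecording:
    """Apply the 0.5-50 Hz bandpass or 7 Hz low-pass FIR filter.

    ``zero_phase`` compensates the linear-phase group delay (odd-length
    symmetric taps, convolution mode "same"), leaving latencies untouched;
    ``zero_phase=False`` applies the filter causally.
    """
    taps = design_fir(kind, rec.fs)
    if zero_phase:
        out = np.stack([scipy.signal.fftconvolve(ch, taps, mode="same")
                        for ch in rec.values])
    else:
        out = scipy.signal.lfilter(taps, 1.0, rec.values, axis=-1)
    return replace(rec, values=out)


def resample(rec: EEGRecording, target_fs: float = 200.0) -> EEGRecording:
    """Polyphase resampling; duration and sub-Nyquist content preserved."""
    if target_fs <= 0:
        raise PreprocessError("target_fs must be positive")
    if abs(target_fs - rec.fs) < 1e-12:
        return replace(rec)
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10000)
    out = scipy.signal.resample_poly(rec.values, frac.numerator,
                                     frac.denominator, axis=-1)
    ratio = target_fs / rec.fs
    trials = [(int(round(on * ratio)), int(round(off * ratio)))
              for on, off in rec.trials]
    return replace(rec, values=out, fs=target_fs, trials=trials)


def preprocess_pipeline(rec: EEGRecording, *, reference_channels=(),
                        target_fs: float = 200.0, zero_phase: bool = True,
                        skip_filters: bool = False) -> EEGRecording:
    """Re-reference -> bandpass -> resample -> low-pass, in that order.

    ``skip_filters`` bypasses both FIR stages for inputs that are already
    band-limited (e.g. synthetic recordings rendered at the analysis rate).
    """
    if reference_channels:
        rec = rereference(rec, reference_channels)
    if not skip_filters:
        rec = fir_filter(rec, "bandpass", zero_phase=zero_phase)
    rec = resample(rec, target_fs)
    if not skip_filters:
        rec = fir_filter(rec, "lowpass", zero_phase=zero_phase)
    return rec
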