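"""Sensor-level preprocessing: filtering, resampling, re-referencing and
analytic-signal extraction.

The preprocessing chain mirrors a standard resting/task EEG pipeline:
a zero-phase Butterworth band-pass (the filter is designed at the stated
order and applied forward-backward, so the net phase response is zero and
the effective magnitude response is the squared one-pass response),
polyphase downsampling with an anti-alias filter, common-average
re-referencing, and per-segment Hilbert analytic signals from which
instantaneous phase and amplitude are read off.

Artifact handling is segment-based: marked intervals are cut out of each
trial, the analytic transform is computed on every remaining continuous
stretch (never across a splice), filter/Hilbert edge transients are
trimmed, and the surviving phase/amplitude samples are concatenated into
one pooled series per channel.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


@dataclass
class BandSignal:
    """A band-limited multichannel time series.

    ``data`` is (n_samples, n_channels); ``band`` is the (low, high) edge
    pair in Hz and must sit strictly inside the Nyquist interval.
    """

    data: np.ndarray
    fs: float
    band: tuple[float, float]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("BandSignal data must be 2-D (time x channel)")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.fs / 2.0):
            raise ValueError(f"band {self.band} not inside (0, fs/2)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BandSignal data must be finite")


@dataclass
class AnalyticSeries:
    """Instantaneous phase and amplitude of a band-limited signal.

    ``phase`` is wrapped to (-pi, pi]; ``amplitude`` is non-negative. Both
    are (n_samples,) or (n_samples, n_channels) and share their shape.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    fs: float
    band: tuple[float, float]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.phase = np.asarray(self.phase, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase and amplitude must share a shape")
        if np.any(self.amplitude < 0):
            raise ValueError("amplitude must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.phase.shape[0]


def bandpass(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 4,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    The filter is designed at ``order`` and run forward-backward
    (``sosfiltfilt``), so the magnitude response is the squared Butterworth
    response and the phase response is identically zero.
    """
    lo, hi = band
    if not (0.0 < lo < hi < fs / 2.0):
        raise ValueError(f"band edges {band} must satisfy 0 < lo < hi < fs/2")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=axis)


def bandpass_gain(
    freq: float, fs: float, band: tuple[float, float], order: int = 4
) -> float:
    """Effective gain of :func:`bandpass` at ``freq`` (squared magnitude
    of the one-pass Butterworth response, because of the forward-backward
    application)."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    _, h = signal.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


def resample(
    data: np.ndarray, fs: float, target_fs: float, axis: int = 0
) -> np.ndarray:
    """Anti-alias filtered polyphase downsampling to ``target_fs``.

    Only downsampling is supported; the output length scales by
    ``target_fs / fs``.
    """
    if target_fs >= fs:
        raise ValueError("resample only downsamples: target_fs must be < fs")
    ratio = Fraction(target_fs / fs).limit_denominator(10_000)
    return signal.resample_poly(
        np.asarray(data, dtype=float), ratio.numerator, ratio.denominator, axis=axis
    )


def rereference_common_average(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every channel.

    After the operation the per-sample mean across channels is zero.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("common-average reference needs >= 2 channels")
    return data - data.mean(axis=1, keepdims=True)


def analytic(
    data: np.ndarray,
    fs: float,
    band: tuple[float, float],
    trim_samples: int | None = None,
    trim_cycles: float = 1.0,
) -> AnalyticSeries:
    """Hilbert analytic signal of a band-limited segment.

    Amplitude is the modulus and phase the argument of the analytic
    signal.  ``trim_samples`` samples (default: one cycle of the band's
    low edge) are dropped from each end to discard filter/Hilbert edge
    transients.  Segments shorter than 3 cycles of the low band edge are
    rejected: the analytic transform is meaningless on shorter stretches.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    lo = band[0]
    min_len = int(np.ceil(3.0 * fs / lo))
    if n < min_len:
        raise ValueError(
            f"segment of {n} samples is shorter than 3 cycles of {lo} Hz "
            f"({min_len} samples at fs={fs})"
        )
    if trim_samples is None:
        trim_samples = int(round(trim_cycles * fs / lo))
    z = signal.hilbert(data, axis=0)
    if trim_samples > 0:
        z = z[trim_samples : n - trim_samples]
    return AnalyticSeries(
        phase=np.angle(z), amplitude=np.abs(z), fs=fs, band=tuple(band)
    )


def split_clean(
    data: np.ndarray,
    fs: float,
    artifacts: Sequence[tuple[float, float]],
    t0: float = 0.0,
) -> list[np.ndarray]:
    """Cut marked artifact intervals (seconds, relative to ``t0``) out of a
    continuous segment and return the remaining clean stretches in order.

    A fully artifactual segment yields an empty list.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    bad = np.zeros(n, dtype=bool)
    for start, stop in artifacts:
        i0 = max(0, int(np.floor((start - t0) * fs)))
        i1 = min(n, int(np.ceil((stop - t0) * fs)))
        if i1 > i0:
            bad[i0:i1] = True
    segments: list[np.ndarray] = []
    i = 0
    while i < n:
        if bad[i]:
            i += 1
            continue
        j = i
        while j < n and not bad[j]:
            j += 1
        segments.append(data[i:j])
        i = j
    return segments


def concatenate_clean(series: Sequence[AnalyticSeries]) -> AnalyticSeries:
    """Pool phase/amplitude samples of retained clean segments.

    All segments must share band and sampling rate; the result's sample
    count is the sum of the segments'.  Zero retained samples is an error.
    """
    series = [s for s in series if s.n_samples > 0]
    if not series:
        raise ValueError("no clean samples to concatenate")
    band, fs = series[0].band, series[0].fs
    for s in series[1:]:
        if tuple(s.band) != tuple(band) or s.fs != fs:
            raise ValueError("all segments must share band and sampling rate")
    return AnalyticSeries(
        phase=np.concatenate([s.phase for s in series], axis=0),
        amplitude=np.concatenate([s.amplitude for s in series], axis=0),
        fs=fs,
        band=tuple(band),
        labels=series[0].labels,
    )


def preprocess_trials(
    trials: Sequence[np.ndarray],
    fs: float,
    band: tuple[float, float],
    artifacts_per_trial: Sequence[Sequence[tuple[float, float]]] | None = None,
    order: int = 4,
    trim_samples: int | None = None,
    min_samples: int | None = None,
) -> AnalyticSeries:
    """Band-pass each trial, excise artifact intervals, compute the
    analytic signal per continuous clean stretch, and concatenate.

    Stretches too short for the analytic transform (< 3 cycles of the low
    band edge after excision, or < ``min_samples`` when given) are
    dropped rather than failing the run.  Pass the same ``min_samples``
    and ``trim_samples`` for two bands to keep their pooled sample sets
    aligned (required for phase-amplitude coupling across bands).
    """
    if artifacts_per_trial is None:
        artifacts_per_trial = [[] for _ in trials]
    pieces: list[AnalyticSeries] = []
    for trial, arts in zip(trials, artifacts_per_trial):
        filtered = bandpass(trial, fs, band, order=order)
        for seg in split_clean(filtered, fs, arts):
            if min_samples is not None and seg.shape[0] < min_samples:
                continue
            try:
                pieces.append(
                    analytic(seg, fs, band, trim_samples=trim_samples)
                )
            except ValueError:
                continue  # too short after excision
    return concatenate_clean(pieces)


def read_brainvision(vhdr_path: str):
    """Read a BrainVision triplet (.vhdr/.vmrk/.eeg) via MNE.

    Returns ``(data, fs, labels)`` with data shaped (n_samples,
    n_channels) in volts.  MNE is only imported here; the rest of the
    package has no dependency on it.
    """
    import mne  # local import: optional reader only

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return raw.get_data().T, float(raw.info["sfreq"]), list(raw.ch_names)
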