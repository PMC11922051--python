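"""Filtering, energy normalization and spectral reduction of raw traces."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import PATimeSeries


@dataclass(eq=False)
class PASpectrum:
    """Peak-to-peak photoacoustic amplitude per wavelength (energy-normalized)."""

    wavelengths: np.ndarray
    amplitude: np.ndarray
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.size == 0:
            raise ValueError("wavelengths must be a non-empty 1-D sequence")
        if self.wavelengths.size != self.amplitude.size:
            raise ValueError("wavelengths and amplitude must have equal length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("amplitude contains non-finite values")


def design_bandpass(
    sampling_rate: float,
    low: float = 1e6,
    high: float = 9e6,
    order: int = 4,
    ripple_db: float = 0.5,
) -> np.ndarray:
    """Chebyshev type I band-pass design in second-order sections."""
    nyquist = sampling_rate / 2.0
    if not (0.0 < low < high < nyquist):
        raise ValueError(
            f"band [{low:g}, {high:g}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyquist:g} Hz)"
        )
    if order < 1:
        raise ValueError("order must be >= 1")
    if ripple_db <= 0:
        raise ValueError("ripple_db must be positive")
    return sps.cheby1(
        order, ripple_db, [low, high], btype="bandpass", fs=sampling_rate, output="sos"
    )


def bandpass_filter(
    signal: PATimeSeries,
    low: float = 1e6,
    high: float = 9e6,
    order: int = 4,
    ripple_db: float = 0.5,
    zero_phase: bool = True,
) -> PATimeSeries:
    """Chebyshev type I band-pass filter (1-9 MHz by default).

    With ``zero_phase`` the filter is applied forward-backward
    (``sosfiltfilt``) so peak positions, and hence time-of-flight depth
    mapping, are not shifted; the effective magnitude response is then the
    squared single-pass response.
    """
    sos = design_bandpass(signal.sampling_rate, low, high, order, ripple_db)
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, signal.samples)
    else:
        filtered = sps.sosfilt(sos, signal.samples)
    return signal.with_samples(filtered)


def energy_normalize(signal: PATimeSeries) -> PATimeSeries:
    """Divide samples by the per-shot pulse energy.

    The original energy is preserved in ``meta['original_pulse_energy']``
    and ``pulse_energy`` is reset to 1, making the operation idempotent.
    """
    energy = signal.pulse_energy
    if not np.isfinite(energy) or energy <= 0:
        raise ValueError("pulse_energy must be positive and finite")
    out = signal.with_samples(signal.samples / energy)
    out.meta.setdefault("original_pulse_energy", energy)
    out.pulse_energy = 1.0
    return out


def peak_to_peak(signal: PATimeSeries, window: tuple | None = None) -> float:
    """Max minus min of the samples, optionally within a time window (s)."""
    samples = signal.samples
    if window is not None:
        t0, t1 = (float(v) for v in window)
        if t1 < t0:
            raise ValueError("window must satisfy t0 <= t1")
        t = signal.times()
        mask = (t >= t0) & (t <= t1)
        if not np.any(mask):
            raise ValueError("window contains no samples")
        samples = samples[mask]
    return float(np.max(samples) - np.min(samples))


def build_spectrum(signals, blank: PASpectrum | None = None) -> PASpectrum:
    """Per-wavelength peak-to-peak spectrum, optionally blank-corrected.

    All traces must already be energy-normalized (``pulse_energy == 1``)
    and carry unique wavelengths.  When a blank spectrum (e.g. water or
    BSA) is given on the same wavelength grid, its amplitude is subtracted
    and the result is flagged as baseline-corrected.
    """
    signals = list(signals)
    if not signals:
        raise ValueError("need at least one signal")
    for s in signals:
        if abs(s.pulse_energy - 1.0) > 1e-12:
            raise ValueError(
                "signals must be energy-normalized before building a spectrum"
            )
    wavelengths = np.array([s.wavelength for s in signals], dtype=float)
    if np.unique(wavelengths).size != wavelengths.size:
        raise ValueError("wavelengths must be unique (one trace per wavelength)")
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    amplitude = np.array([peak_to_peak(signals[i]) for i in order], dtype=float)
    corrected = False
    if blank is not None:
        if blank.wavelengths.size != wavelengths.size or not np.allclose(
            blank.wavelengths, wavelengths, rtol=0.0, atol=1e-9
        ):
            raise ValueError("blank spectrum wavelength grid does not match")
        amplitude = amplitude - blank.amplitude
        corrected = True
    return PASpectrum(
        wavelengths=wavelengths, amplitude=amplitude, baseline_corrected=corrected
    )
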