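"""Transducer deconvolution, envelope extraction and time-to-depth mapping.

The stages in this module turn a filtered, energy-normalized trace into a
:class:`~papeors.types.FluenceDepthProfile`: Wiener deconvolution removes
the band-limited transducer response, the analytic-signal envelope makes
the bipolar result nonnegative, a sweep over candidate speeds of sound
anchors the time axis to the known source-detector distance, and the time
axis is converted to depth.
"""
from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq
from scipy.signal import hilbert

from .types import AcquisitionGeometry, FluenceDepthProfile, PATimeSeries, TransducerIR

#: Relative spectral floor added to the Wiener regularizer so that bins
#: where the kernel magnitude underflows never amplify rounding noise,
#: even at nsr=0.
_WIENER_FLOOR = 1e-12


def deconvolve(
    signal: PATimeSeries,
    ir: TransducerIR,
    nsr: float = 1e-3,
    prior: str = "smooth",
) -> PATimeSeries:
    """Frequency-domain Wiener deconvolution of the transducer response.

    ``nsr`` is the scalar noise-to-signal power ratio referenced to the
    peak of the kernel's power spectrum.  The ``prior`` selects the
    spectral shape of the regularizer:

    ``"smooth"`` (default)
        penalty grows as ``(f / f_c)**2`` with ``f_c`` the transducer
        center frequency — the Wiener solution for a signal whose power
        falls off as ``1/f**2`` (a fluence profile with step boundaries)
        in white noise; reconstructs the full profile including its
        slowly varying interior.

    ``"flat"``
        frequency-independent penalty; keeps only spectral bins where the
        kernel is strong, which is appropriate after band-pass
        prefiltering when the subsequent analysis reads band-limited
        boundary responses rather than the profile interior.

    ``nsr=0`` gives the regularized inverse limited only by a tiny
    numerical floor.  The kernel's group delay (envelope peak position)
    is compensated so the output stays aligned with the input, and the
    output length equals the input length.
    """
    if nsr < 0:
        raise ValueError("nsr must be nonnegative")
    if prior not in {"smooth", "flat"}:
        raise ValueError("prior must be 'smooth' or 'flat'")
    if abs(signal.sampling_rate - ir.sampling_rate) > 1e-6 * signal.sampling_rate:
        raise ValueError("signal and impulse response sampling rates differ")
    h = ir.samples
    if float(np.max(np.abs(h))) == 0.0:
        raise ValueError("impulse response is all zero")
    n = signal.samples.size
    m = h.size
    nfft = next_fast_len(n + m - 1)
    H = rfft(h, nfft)
    X = rfft(signal.samples, nfft)
    power = np.abs(H) ** 2
    peak_power = float(np.max(power))
    if prior == "smooth":
        shape = (rfftfreq(nfft, 1.0 / signal.sampling_rate) / ir.center_frequency) ** 2
    else:
        shape = 1.0
    lam = peak_power * (nsr * shape + _WIENER_FLOOR)
    estimate = irfft(X * np.conj(H) / (power + lam), nfft)
    # compensate the kernel delay (position of its envelope peak)
    delay = int(np.argmax(np.abs(hilbert(h))))
    estimate = np.roll(estimate, delay)[:n]
    return signal.with_samples(estimate)


def envelope(signal: PATimeSeries) -> PATimeSeries:
    """Magnitude of the analytic signal; nonnegative everywhere."""
    return signal.with_samples(np.abs(hilbert(signal.samples)))


def calibrate_sos(
    signal: PATimeSeries,
    geometry: AcquisitionGeometry,
    landmark: str = "peak",
    min_amplitude: float = 0.0,
    onset_fraction: float = 0.1,
) -> float:
    """Speed of sound from the sweep best matching the known path length.

    The arrival time of a landmark (envelope peak, or first onset crossing
    of ``onset_fraction`` of the peak) is swept against candidate speeds;
    the candidate ``v`` minimizing ``|v * t_landmark - known_path_length|``
    is returned, with ties broken toward the lower speed.
    """
    if landmark not in {"peak", "onset"}:
        raise ValueError("landmark must be 'peak' or 'onset'")
    env = np.abs(hilbert(signal.samples))
    peak = float(np.max(env))
    if peak <= min_amplitude or peak <= 0.0:
        raise ValueError("no signal: landmark amplitude is below the noise floor")
    if landmark == "peak":
        index = int(np.argmax(env))
    else:
        above = np.nonzero(env >= onset_fraction * peak)[0]
        index = int(above[0])
    t_landmark = signal.time_offset + index / signal.sampling_rate
    lo, hi = geometry.sos_sweep
    candidates = np.arange(lo, hi + geometry.sos_step / 2, geometry.sos_step)
    errors = np.abs(candidates * t_landmark - geometry.known_path_length)
    return float(candidates[int(np.argmin(errors))])


def to_depth_profile(
    signal: PATimeSeries,
    sos: float,
    reference_time: float = 0.0,
) -> FluenceDepthProfile:
    """Map the time axis to depth: ``depth = sos * (t - reference_time)``.

    The signal must already be an envelope (nonnegative samples).
    ``reference_time`` positions depth zero at a chosen instant (e.g. the
    arrival of the illumination-point signal); resulting depths must be
    nonnegative.
    """
    if sos <= 0:
        raise ValueError("sos must be positive")
    t = signal.times()
    depth = sos * (t - float(reference_time))
    if depth[0] < 0:
        raise ValueError(
            "negative depths: increase time_offset or adjust reference_time "
            "so the window starts at or after the depth-zero instant"
        )
    amplitude = signal.samples
    if np.any(amplitude < -1e-9 * max(1.0, float(np.max(np.abs(amplitude))))):
        raise ValueError("signal must be an envelope (nonnegative samples)")
    return FluenceDepthProfile(
        depth=depth, amplitude=np.clip(amplitude, 0.0, None), sos_used=float(sos)
    )
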