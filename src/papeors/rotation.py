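"""Optical-rotation estimation from fluence-depth profiles.

The Malus-law analogue links the photoacoustic amplitudes at the reference
point (``P0``, just inside the illumination face) and at the path length of
interest (``P``) through ``P = P0 * cos(theta)**2``, so the rotation is
``theta = arccos(sqrt(P / P0))``.
"""
from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .types import FluenceDepthProfile


class ClampWarning(UserWarning):
    """Raised when a noisy amplitude ratio had to be clamped into [0, 1]."""


def extract_amplitudes(
    profile: FluenceDepthProfile,
    target_depth: float,
    p0_depth: float = 1.8e-5,
    window: int = 5,
    reference_depth: float = 0.0,
    noise_floor: float = 0.0,
) -> tuple[float, float]:
    """Read (P0, P) off a depth profile.

    Each amplitude is the mean of ``window`` samples centered on the sample
    nearest the requested depth.  ``reference_depth`` shifts both requests,
    which lets a caller anchor them to a detected illumination-face
    landmark on an absolute depth axis.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd sample count")
    depth = profile.depth
    amplitude = profile.amplitude

    def _mean_at(requested: float, label: str) -> float:
        if requested < depth[0] or requested > depth[-1]:
            raise ValueError(
                f"{label} depth {requested * 1e3:.3f} mm is outside the profile "
                f"range [{depth[0] * 1e3:.3f}, {depth[-1] * 1e3:.3f}] mm"
            )
        center = int(np.argmin(np.abs(depth - requested)))
        half = window // 2
        lo, hi = center - half, center + half + 1
        if lo < 0 or hi > depth.size:
            raise ValueError(
                f"{label} extraction window extends outside the profile"
            )
        return float(np.mean(amplitude[lo:hi]))

    p0 = _mean_at(reference_depth + p0_depth, "P0")
    p = _mean_at(reference_depth + target_depth, "target")
    if p0 <= noise_floor or p0 <= 0.0:
        raise ValueError("unusable reference: P0 is at or below the noise floor")
    return p0, p


def estimate_rotation(p: float, p0: float, clamp: bool = True) -> float:
    """Rotation ``theta = arccos(sqrt(P/P0))`` in radians, in [0, pi/2].

    With ``clamp`` (the default) a noisy ratio outside [0, 1] is clipped
    and a :class:`ClampWarning` is emitted; with ``clamp=False`` a ratio
    above 1 raises instead.
    """
    if p0 <= 0:
        raise ValueError("P0 must be positive")
    if p < 0:
        raise ValueError("P must be nonnegative")
    ratio = p / p0
    if ratio > 1.0:
        if not clamp:
            raise ValueError(f"P/P0 = {ratio:.6g} exceeds 1 and clamping is disabled")
        warnings.warn(
            f"P/P0 = {ratio:.6g} clamped to 1 (noisy amplitudes)", ClampWarning
        )
        ratio = 1.0
    return math.acos(math.sqrt(ratio))


def rotation_curve(measurements) -> pd.DataFrame:
    """Per-concentration mean rotation, sample SD and replicate count.

    Accepts an iterable of :class:`~papeors.types.RotationMeasurement`.
    The SD column is reported as missing (NaN) for single replicates
    rather than zero.
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements given")
    frame = pd.DataFrame(
        {
            "concentration": [m.concentration_ref for m in measurements],
            "theta": [m.theta for m in measurements],
        }
    )
    grouped = frame.groupby("concentration", sort=True)["theta"]
    summary = grouped.agg(theta_mean="mean", theta_sd="std", n="count").reset_index()
    # pandas already yields NaN sample SD for n == 1, which is the contract
    summary["n"] = summary["n"].astype(int)
    return summary
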