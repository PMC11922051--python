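"""Domain types for photoacoustic optical-rotation sensing.

All quantities use SI units internally (seconds, meters, joules, hertz,
radians); wavelengths are kept in nanometers as is conventional for
spectroscopy metadata.  Each type validates its invariants on construction
and raises ``ValueError`` on structurally invalid input rather than
coercing silently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

#: Incident polarization states: vertical, +45 deg linear, right circular,
#: horizontal, -45 deg linear, left circular.
POLARIZATION_STATES = frozenset({"V", "P", "R", "H", "M", "L"})

CONCENTRATION_UNITS = frozenset({"mg/dl", "mg/ml"})


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(eq=False)
class PATimeSeries:
    """One sampled photoacoustic pressure trace with acquisition metadata.

    Sample ``i`` occurs at time ``time_offset + i / sampling_rate`` relative
    to the laser trigger.
    """

    samples: np.ndarray
    sampling_rate: float
    time_offset: float = 0.0
    pulse_energy: float = 1.0
    wavelength: float = 1560.0
    polarization: str = "V"
    replicate_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = _as_1d_float(self.samples, "samples")
        self.sampling_rate = float(self.sampling_rate)
        self.time_offset = float(self.time_offset)
        self.pulse_energy = float(self.pulse_energy)
        self.wavelength = float(self.wavelength)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.time_offset < 0:
            raise ValueError("time_offset must be nonnegative")
        if self.pulse_energy <= 0:
            raise ValueError("pulse_energy must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.polarization not in POLARIZATION_STATES:
            raise ValueError(
                f"polarization must be one of {sorted(POLARIZATION_STATES)}, "
                f"got {self.polarization!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        """Sample times in seconds relative to the laser trigger."""
        return self.time_offset + np.arange(self.samples.size) / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "PATimeSeries":
        """Copy of this trace with new samples and identical metadata."""
        return PATimeSeries(
            samples=np.asarray(samples, dtype=float),
            sampling_rate=self.sampling_rate,
            time_offset=self.time_offset,
            pulse_energy=self.pulse_energy,
            wavelength=self.wavelength,
            polarization=self.polarization,
            replicate_id=self.replicate_id,
            meta=dict(self.meta),
        )


@dataclass(eq=False)
class TransducerIR:
    """Band-limited impulse response of an ultrasound transducer."""

    samples: np.ndarray
    sampling_rate: float
    center_frequency: float
    fractional_bandwidth: float

    def __post_init__(self) -> None:
        self.samples = _as_1d_float(self.samples, "samples")
        self.sampling_rate = float(self.sampling_rate)
        self.center_frequency = float(self.center_frequency)
        self.fractional_bandwidth = float(self.fractional_bandwidth)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if float(np.linalg.norm(self.samples)) <= 0.0:
            raise ValueError("impulse response has zero L2 norm")
        if self.center_frequency <= 0:
            raise ValueError("center_frequency must be positive")
        if self.center_frequency >= self.sampling_rate / 2:
            raise ValueError(
                "center_frequency must be below the Nyquist frequency "
                f"({self.sampling_rate / 2:g} Hz)"
            )
        if not (0.0 < self.fractional_bandwidth < 2.0):
            raise ValueError("fractional_bandwidth must lie in (0, 2)")


@dataclass
class AcquisitionGeometry:
    """Acoustic geometry of the trans-illumination measurement.

    ``known_path_length`` is the physical distance from the illumination
    point on the sample holder to the transducer face and anchors the
    speed-of-sound calibration.
    """

    sos: float = 1500.0
    known_path_length: float = 0.04
    p0_depth: float = 1.8e-5
    sos_sweep: tuple = (1400.0, 1550.0)
    sos_step: float = 5.0

    def __post_init__(self) -> None:
        self.sos = float(self.sos)
        self.known_path_length = float(self.known_path_length)
        self.p0_depth = float(self.p0_depth)
        lo, hi = (float(v) for v in self.sos_sweep)
        self.sos_sweep = (lo, hi)
        self.sos_step = float(self.sos_step)
        if self.sos <= 0:
            raise ValueError("sos must be positive")
        if self.known_path_length <= 0:
            raise ValueError("known_path_length must be positive")
        if not (0.0 <= self.p0_depth < self.known_path_length):
            raise ValueError("p0_depth must satisfy 0 <= p0_depth < known_path_length")
        if not (0 < lo < hi):
            raise ValueError("sos_sweep must be a positive increasing interval")
        if self.sos_step <= 0:
            raise ValueError("sos_step must be positive")


@dataclass(eq=False)
class FluenceDepthProfile:
    """Energy-normalized envelope amplitude against physical depth.

    This is the object the Malus-law amplitude ratio is read from: the
    envelope contract guarantees ``amplitude >= 0`` everywhere so the
    ratio P/P0 is nonnegative.
    """

    depth: np.ndarray
    amplitude: np.ndarray
    sos_used: float

    def __post_init__(self) -> None:
        self.depth = _as_1d_float(self.depth, "depth")
        self.amplitude = _as_1d_float(self.amplitude, "amplitude")
        self.sos_used = float(self.sos_used)
        if self.depth.size != self.amplitude.size:
            raise ValueError("depth and amplitude must have equal length")
        if np.any(np.diff(self.depth) <= 0):
            raise ValueError("depth must be strictly increasing")
        if np.any(self.depth < 0):
            raise ValueError("depth must be nonnegative")
        if np.any(self.amplitude < -1e-9 * max(1.0, float(np.max(np.abs(self.amplitude))))):
            raise ValueError("amplitude must be nonnegative (envelope contract)")
        # tolerate tiny numerical undershoot from the Hilbert transform
        self.amplitude = np.clip(self.amplitude, 0.0, None)
        if self.sos_used <= 0:
            raise ValueError("sos_used must be positive")


@dataclass
class RotationMeasurement:
    """Estimated optical rotation at one path length for one trace."""

    theta: float
    path_length: float
    concentration_ref: float
    polarization: str = "V"
    p_amplitude: float = 0.0
    p0_amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.theta = float(self.theta)
        self.path_length = float(self.path_length)
        self.concentration_ref = float(self.concentration_ref)
        self.p_amplitude = float(self.p_amplitude)
        self.p0_amplitude = float(self.p0_amplitude)
        if not (0.0 <= self.theta <= math.pi / 2 + 1e-12):
            raise ValueError("theta must lie in [0, pi/2] radians")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.concentration_ref < 0:
            raise ValueError("concentration_ref must be nonnegative")
        if self.polarization not in POLARIZATION_STATES:
            raise ValueError(f"invalid polarization {self.polarization!r}")
        if self.p_amplitude < 0:
            raise ValueError("p_amplitude must be nonnegative")
        if self.p0_amplitude <= 0:
            raise ValueError("p0_amplitude must be positive")
        ratio = min(max(self.p_amplitude / self.p0_amplitude, 0.0), 1.0)
        expected = math.acos(math.sqrt(ratio))
        if abs(expected - self.theta) > 1e-6:
            raise ValueError(
                "theta inconsistent with arccos(sqrt(P/P0)): "
                f"got {self.theta:.8f}, expected {expected:.8f}"
            )


@dataclass
class SpecificRotationParams:
    """Specific rotation of a chiral substance at wavelength/temperature."""

    specific_rotation: float
    wavelength: float = 1560.0
    temperature: float = 25.0

    def __post_init__(self) -> None:
        self.specific_rotation = float(self.specific_rotation)
        self.wavelength = float(self.wavelength)
        self.temperature = float(self.temperature)
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")


@dataclass
class PiecewiseQuadModel:
    """Two free quadratics in theta joined at the threshold ``theta_t``.

    Predicted concentration is ``a1*theta**2 + b1*theta + k1`` for
    ``theta <= theta_t`` and ``a2*theta**2 + b2*theta + k2`` above it.
    No continuity constraint is imposed at the threshold.
    """

    a1: float
    b1: float
    k1: float
    a2: float
    b2: float
    k2: float
    theta_t: float
    units_out: str = "mg/dl"

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "k1", "a2", "b2", "k2", "theta_t"):
            value = float(getattr(self, name))
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, value)
        if self.theta_t <= 0:
            raise ValueError("theta_t must be positive")
        if self.units_out not in CONCENTRATION_UNITS:
            raise ValueError(f"units_out must be one of {sorted(CONCENTRATION_UNITS)}")


@dataclass
class LinearModel:
    """Ordinary least-squares line with its coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        self.slope = float(self.slope)
        self.intercept = float(self.intercept)
        self.r_squared = float(self.r_squared)
        if not all(map(math.isfinite, (self.slope, self.intercept, self.r_squared))):
            raise ValueError("model coefficients must be finite")
        if not (-1e-12 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        self.r_squared = min(max(self.r_squared, 0.0), 1.0)


@dataclass
class SimulatorConfig:
    """Parameters of the 1-D ballistic forward model.

    The source amplitude follows the photoacoustic proportionality
    ``p = grueneisen * mu_a * surface_fluence`` with Beer-Lambert decay at
    rate ``mu_eff`` (defaults to ``mu_a``) and a Malus-type ``cos**2``
    modulation accruing at ``rotation_per_depth`` radians per meter.
    Setting ``mu_eff = 0`` with ``mu_a > 0`` models an optically thin
    absorber: photoacoustic emission without measurable attenuation.
    """

    grueneisen: float = 0.2
    mu_a: float = 100.0
    surface_fluence: float = 1.0
    rotation_per_depth: float = 0.0
    noise_sd: float = 0.0
    energy_jitter_cv: float = 0.0
    seed: int = 0
    mu_eff: float | None = None
    slab_thickness: float | None = 2e-3
    snr_db: float | None = None
    base_pulse_energy: float = 2.5e-3

    def __post_init__(self) -> None:
        if self.grueneisen <= 0:
            raise ValueError("grueneisen must be positive")
        if self.mu_a < 0:
            raise ValueError("mu_a must be nonnegative")
        if self.surface_fluence <= 0:
            raise ValueError("surface_fluence must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.energy_jitter_cv < 0:
            raise ValueError("energy_jitter_cv must be nonnegative")
        if self.mu_eff is not None and self.mu_eff < 0:
            raise ValueError("mu_eff must be nonnegative")
        if self.slab_thickness is not None and self.slab_thickness <= 0:
            raise ValueError("slab_thickness must be positive")
        if self.base_pulse_energy <= 0:
            raise ValueError("base_pulse_energy must be positive")
        self.seed = int(self.seed)

    @property
    def attenuation(self) -> float:
        """Fluence attenuation coefficient actually applied (1/m)."""
        return self.mu_a if self.mu_eff is None else self.mu_eff


@dataclass(eq=False)
class GroundTruth:
    """Analytic ground truth attached to a simulated trace."""

    concentration: float
    config: SimulatorConfig

    def __post_init__(self) -> None:
        self.concentration = float(self.concentration)
        if self.concentration < 0:
            raise ValueError("concentration must be nonnegative")

    def theta_at(self, path_length: float) -> float:
        """True cumulative optical rotation (radians) at a path length."""
        if path_length < 0:
            raise ValueError("path_length must be nonnegative")
        return self.config.rotation_per_depth * path_length

    def fluence_at(self, path_length: float) -> float:
        """True relative fluence at a path length (a.u.)."""
        if path_length < 0:
            raise ValueError("path_length must be nonnegative")
        return self.config.surface_fluence * math.exp(
            -self.config.attenuation * path_length
        )


@dataclass(eq=False)
class CEGAResult:
    """Per-point Clarke error-grid zones with zone percentages."""

    zones: list
    zone_percentages: dict
    n_points: int

    def __post_init__(self) -> None:
        self.zones = list(self.zones)
        self.n_points = int(self.n_points)
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if len(self.zones) != self.n_points:
            raise ValueError("length of zones must equal n_points")
        bad = [z for z in self.zones if z not in {"A", "B", "C", "D", "E"}]
        if bad:
            raise ValueError(f"invalid zone labels: {bad[:5]}")
        self.zone_percentages = {
            z: float(self.zone_percentages.get(z, 0.0)) for z in "ABCDE"
        }
        total = sum(self.zone_percentages.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"zone percentages must sum to 100, got {total!r}")
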