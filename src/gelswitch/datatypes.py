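"""Data containers shared across the pipeline stages.

All containers are lightweight dataclasses around numpy arrays.  Validation
happens in ``__post_init__`` so that an instance, once constructed, satisfies
its documented invariants.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "TemperatureProfile",
    "SyntheticTruth",
    "FrameSeries",
    "AreaTrace",
    "CalibrationResult",
    "AlignedSeries",
    "CircleFit",
    "Pore",
    "PoreSizeDistribution",
    "TransitionResult",
    "CycleMetrics",
    "DoseResponse",
    "CDSpectrum",
    "BandFeatures",
    "SuperpositionFit",
]


def _as1d(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass
class TemperatureProfile:
    """Timestamped heating-stage temperature trajectory (ramp or cyclic)."""

    times: np.ndarray  # s, strictly increasing
    temps: np.ndarray  # degC
    protocol_label: str = ""

    def __post_init__(self):
        self.times = _as1d(self.times)
        self.temps = _as1d(self.temps)
        if self.times.shape != self.temps.shape:
            raise InvalidParameterError("times and temps must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if np.any(self.temps < 0) or np.any(self.temps > 100):
            raise InvalidParameterError("temperatures must lie within [0, 100] degC")

    def temperature_at(self, t) -> np.ndarray:
        """Linear interpolation of stage temperature at time(s) ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.temps)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.temps.min()), float(self.temps.max())


@dataclass
class SyntheticTruth:
    """Ground-truth parameters behind a synthetic contraction trace."""

    T_t: float  # degC, transition midpoint
    stroke_area: float  # fraction of projected area lost across the transition
    width_w: float  # degC, logistic transition width
    loss_per_cycle: float = 0.0  # irreversible fraction lost per heating cycle
    A0: float = 3.0  # cm^2, initial projected area
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.stroke_area < 1.0:
            raise InvalidParameterError("stroke_area must lie strictly in (0, 1)")
        if self.width_w <= 0:
            raise InvalidParameterError("width_w must be positive")
        if not 0.0 <= self.loss_per_cycle < 0.05:
            raise InvalidParameterError("loss_per_cycle must lie in [0, 0.05)")
        if self.A0 <= 0:
            raise InvalidParameterError("A0 must be positive")


@dataclass
class FrameSeries:
    """Calibrated grayscale image sequence with per-frame timestamps."""

    frames: np.ndarray  # (n, h, w) uint8
    times: np.ndarray  # s
    pixel_size: float  # physical length per pixel (cm/px or um/px)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a (n, h, w) stack")
        self.times = _as1d(self.times)
        if len(self.frames) != len(self.times):
            raise InvalidParameterError("one timestamp per frame required")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class AreaTrace:
    """Projected gel area vs time — the central observable of the switching
    experiments.  ``area_raw`` is in cm^2 when a calibration was applied,
    otherwise px^2."""

    times: np.ndarray
    area_raw: np.ndarray
    temps: Optional[np.ndarray] = None
    area_smooth: Optional[np.ndarray] = None
    sigma_used: Optional[float] = None
    method_label: str = ""
    flags: Optional[np.ndarray] = None  # True where a frame failed and was interpolated

    def __post_init__(self):
        self.times = _as1d(self.times)
        self.area_raw = _as1d(self.area_raw)
        if self.times.shape != self.area_raw.shape:
            raise InvalidParameterError("times and area_raw must have equal length")
        if self.temps is not None:
            self.temps = _as1d(self.temps)
            if self.temps.shape != self.times.shape:
                raise InvalidParameterError("temps must match times in length")
        if self.area_smooth is not None:
            self.area_smooth = _as1d(self.area_smooth)
            if self.area_smooth.shape != self.times.shape:
                raise InvalidParameterError("area_smooth must match times in length")
            if self.sigma_used is None:
                raise InvalidParameterError("sigma_used must be recorded with area_smooth")
        if np.any(self.area_raw < 0):
            raise InvalidParameterError("areas must be non-negative")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def best(self) -> np.ndarray:
        """Smoothed signal when available, raw otherwise."""
        return self.area_smooth if self.area_smooth is not None else self.area_raw


@dataclass
class CalibrationResult:
    """Pixel-to-physical calibration from a reference object of known size."""

    pixel_size: float
    reference_object_px: float
    reference_object_physical: float

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be positive")

    @property
    def area_factor(self) -> float:
        """Physical area per pixel (pixel_size squared)."""
        return self.pixel_size ** 2


@dataclass
class AlignedSeries:
    """A frame series with one interpolated stage temperature per frame."""

    frames: FrameSeries
    frame_temps: np.ndarray

    def __post_init__(self):
        self.frame_temps = _as1d(self.frame_temps)
        if len(self.frame_temps) != len(self.frames):
            raise InvalidParameterError("one temperature per frame required")


@dataclass
class CircleFit:
    """Gradient-based circle fit to the gel's top-view outline."""

    center_x: float  # px (column)
    center_y: float  # px (row)
    radius: float  # px
    residual: float  # 1 - (perimeter-mean gradient / max gradient), dimensionless

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("radius must be positive")

    @property
    def area(self) -> float:
        return float(np.pi * self.radius ** 2)


@dataclass
class Pore:
    """A maximal inscribed circle in the interstitial (non-fibril) space."""

    center_x: float  # um
    center_y: float  # um
    radius: float  # um

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError("pore radius must be positive")


@dataclass
class PoreSizeDistribution:
    """Pore radii with a kernel density estimate and modal size P_max."""

    radii: np.ndarray  # um
    density_x: Optional[np.ndarray] = None  # um grid
    density_y: Optional[np.ndarray] = None  # probability density (integrates to 1 on grid)
    P_max: Optional[float] = None  # um, argmax of density
    bandwidth: Optional[float] = None  # um, KDE bandwidth used
    hist_counts: Optional[np.ndarray] = None
    hist_edges: Optional[np.ndarray] = None
    temperature: float = float("nan")
    flagged: bool = False  # True when too few pores for a density estimate

    def __post_init__(self):
        self.radii = _as1d(self.radii) if np.size(self.radii) else np.empty(0)

    @property
    def n_pores(self) -> int:
        return int(self.radii.size)

    @property
    def iqr(self) -> float:
        if self.radii.size == 0:
            return float("nan")
        q1, q3 = np.percentile(self.radii, [25, 75])
        return float(q3 - q1)


@dataclass
class TransitionResult:
    """Transition temperature and stroke extracted from one heating trace."""

    T_t: float  # degC
    derivative_peak: float  # most negative dA/dT (area units per degC)
    heating_rate: float  # degC/s
    stroke_area: float  # fraction
    stroke_volume_est: float  # fraction, isotropic-shrinkage estimate
    dose: float = float("nan")  # kGy label

    def __post_init__(self):
        if not 0.0 <= self.stroke_area <= 1.0:
            raise InvalidParameterError("stroke_area must lie in [0, 1]")


@dataclass
class CycleMetrics:
    """Per-cycle actuation metrics from a cyclic heating protocol."""

    n_cycles: int
    inflection_times: np.ndarray  # s
    inflection_temps: np.ndarray  # degC
    amplitude_per_cycle: np.ndarray  # fraction, one per cycle
    loss_per_cycle: float  # mean fraction lost per cycle
    loss_per_cycle_sd: float
    losses: Optional[np.ndarray] = None  # individual per-cycle losses

    def __post_init__(self):
        self.inflection_times = _as1d(self.inflection_times)
        self.inflection_temps = _as1d(self.inflection_temps)
        self.amplitude_per_cycle = _as1d(self.amplitude_per_cycle)
        if np.any(self.amplitude_per_cycle < -1e-9) or np.any(self.amplitude_per_cycle > 1 + 1e-9):
            raise InvalidParameterError("amplitudes must lie in [0, 1]")


@dataclass
class DoseResponse:
    """Linear dose dependence of the transition temperature."""

    doses: np.ndarray  # kGy
    T_ts: np.ndarray  # degC
    slope: float  # degC/kGy
    intercept: float  # degC
    residual_sd: float  # degC

    def __post_init__(self):
        self.doses = _as1d(self.doses)
        self.T_ts = _as1d(self.T_ts)


@dataclass
class CDSpectrum:
    """Wavelength-resolved ellipticity with optional photomultiplier HT channel.

    ``valid`` marks samples usable for norms, features and fits; ``qc_pass``
    is False when the HT criterion fails in the protected wavelength range.
    """

    wavelengths: np.ndarray  # nm, strictly monotone (conventionally 250 -> 190)
    ellipticity: np.ndarray  # mdeg
    ht: Optional[np.ndarray] = None  # V
    temperature: float = float("nan")  # degC
    dose: float = float("nan")  # kGy
    n_replicates: int = 1
    valid: Optional[np.ndarray] = None
    qc_pass: bool = True
    label: str = ""

    def __post_init__(self):
        self.wavelengths = _as1d(self.wavelengths)
        self.ellipticity = _as1d(self.ellipticity)
        if self.wavelengths.shape != self.ellipticity.shape:
            raise InvalidParameterError("wavelengths and ellipticity must match")
        d = np.diff(self.wavelengths)
        if self.wavelengths.size >= 2 and not (np.all(d > 0) or np.all(d < 0)):
            raise InvalidParameterError("wavelengths must be strictly monotone")
        if not np.all(np.isfinite(self.ellipticity)):
            raise InvalidParameterError("ellipticity must be finite")
        if self.ht is not None:
            self.ht = _as1d(self.ht)
            if self.ht.shape != self.wavelengths.shape:
                raise InvalidParameterError("ht channel must match wavelengths")
            if np.any(self.ht < 0):
                raise InvalidParameterError("ht must be non-negative")
        if self.valid is None:
            self.valid = np.ones(self.wavelengths.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def copy(self, **updates) -> "CDSpectrum":
        from dataclasses import replace

        return replace(self, **updates)


@dataclass
class BandFeatures:
    """Local extrema and canonical band values of a preprocessed spectrum."""

    minima: list  # of (wavelength nm, ellipticity)
    maxima: list
    value_at: dict  # canonical wavelength (nm) -> ellipticity


@dataclass
class SuperpositionFit:
    """Least-squares weights expressing a target spectrum as a component sum."""

    weights: np.ndarray
    residual_rms: float
    components: list

    def __post_init__(self):
        self.weights = _as1d(self.weights)
        if self.residual_rms < 0 or not np.all(np.isfinite(self.weights)):
            raise InvalidParameterError("fit results must be finite, residual >= 0")
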