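"""Core value objects shared across the package.

A :class:`Spectrum` carries the complex signal of one single-voxel
acquisition (muscle or external-reference phantom) together with the
acquisition metadata needed for absolute quantification.  The remaining
dataclasses hold the results of the downstream stages: lineshape fits,
the carnosine / fiber-type calibration, cohort records and the logistic
discipline model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "VoxelGeometry",
    "SubjectRecord",
    "PeakSpec",
    "PeakFit",
    "QuantificationInputs",
    "CalibrationModel",
    "ReferenceStats",
    "SigmoidModel",
    "WATER_PPM",
    "SEX_TOKENS",
    "GROUP_TOKENS",
    "CATEGORY_TOKENS",
]

#: Chemical shift conventionally assigned to the water resonance.
WATER_PPM = 4.70

SEX_TOKENS = ("male", "female")
GROUP_TOKENS = ("control", "talent", "elite", "ex_athlete")
CATEGORY_TOKENS = ("explosive", "endurance", "mixed", "control")


@dataclass
class Spectrum:
    """One single-voxel MRS acquisition (time- or frequency-domain).

    Parameters
    ----------
    samples
        Complex signal.  In the time domain this is the FID sampled at
        ``1 / bandwidth_hz`` intervals; in the frequency domain it is the
        complex spectrum on the ppm axis returned by :meth:`ppm_axis`.
    bandwidth_hz
        Spectral (receiver) bandwidth in Hz.
    transmitter_mhz
        Transmitter frequency in MHz; converts Hz offsets to ppm.
    reference_ppm
        Chemical shift assigned to the center of the spectral window.
    echo_time_ms, repetition_time_ms
        PRESS sequence timing (TE, TR) in milliseconds.
    n_averages
        Number of excitations averaged into the stored signal.
    role
        ``"muscle"`` or ``"phantom"``.
    domain
        ``"time"`` or ``"frequency"``.
    """

    samples: np.ndarray
    bandwidth_hz: float
    transmitter_mhz: float
    reference_ppm: float = WATER_PPM
    echo_time_ms: float = 30.0
    repetition_time_ms: float = 2000.0
    n_averages: int = 128
    role: str = "muscle"
    domain: str = "time"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("empty spectrum: samples must be a non-empty 1-D array")
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth_hz must be > 0")
        if self.transmitter_mhz <= 0:
            raise ValueError("transmitter_mhz must be > 0")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.role not in ("muscle", "phantom"):
            raise ValueError(f"role must be 'muscle' or 'phantom', got {self.role!r}")
        if self.domain not in ("time", "frequency"):
            raise ValueError(f"domain must be 'time' or 'frequency', got {self.domain!r}")

    @property
    def n_points(self) -> int:
        return int(self.samples.size)

    @property
    def dwell_time_s(self) -> float:
        """Sampling interval of the FID in seconds."""
        return 1.0 / self.bandwidth_hz

    def time_axis_s(self) -> np.ndarray:
        if self.domain != "time":
            raise ValueError("time axis only defined for time-domain spectra")
        return np.arange(self.n_points) * self.dwell_time_s

    def freq_axis_hz(self) -> np.ndarray:
        """Frequency offsets from the carrier, ascending, in Hz."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell_time_s))

    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis, ascending in ppm (display reverses it)."""
        return self.reference_ppm + self.freq_axis_hz() / self.transmitter_mhz

    def with_(self, **changes) -> "Spectrum":
        return replace(self, **changes)


@dataclass(frozen=True)
class VoxelGeometry:
    """Cuboid voxel dimensions in mm; the study's average was 40x12x28 mm."""

    dim_x_mm: float = 40.0
    dim_y_mm: float = 12.0
    dim_z_mm: float = 28.0

    def __post_init__(self) -> None:
        if min(self.dim_x_mm, self.dim_y_mm, self.dim_z_mm) <= 0:
            raise ValueError("voxel dimensions must be > 0")

    @property
    def volume_mm3(self) -> float:
        return self.dim_x_mm * self.dim_y_mm * self.dim_z_mm

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass
class SubjectRecord:
    """One individual of the cohort.

    At least one leg's carnosine value is required; ``carnosine_mean_mm``
    is the bilateral mean (or the single available value).
    """

    subject_id: str
    sex: str
    group: str
    category: str
    discipline: str = ""
    best_distance_m: Optional[float] = None
    carnosine_left_mm: Optional[float] = None
    carnosine_right_mm: Optional[float] = None
    carnosine_mean_mm: Optional[float] = None
    z_score: Optional[float] = None
    # ground truth carried by the simulator; never serialized
    true_carnosine_mm: Optional[float] = None
    true_ft_area_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sex not in SEX_TOKENS:
            raise ValueError(f"unknown sex {self.sex!r}; valid: {SEX_TOKENS}")
        if self.group not in GROUP_TOKENS:
            raise ValueError(f"unknown group {self.group!r}; valid: {GROUP_TOKENS}")
        if self.category not in CATEGORY_TOKENS:
            raise ValueError(
                f"unknown category {self.category!r}; valid: {CATEGORY_TOKENS}"
            )
        if self.carnosine_left_mm is None and self.carnosine_right_mm is None:
            raise ValueError(f"subject {self.subject_id}: no carnosine measurement")
        for v, name in (
            (self.carnosine_left_mm, "carnosine_left_mm"),
            (self.carnosine_right_mm, "carnosine_right_mm"),
        ):
            if v is not None and v <= 0:
                raise ValueError(f"subject {self.subject_id}: {name} must be > 0")
        if self.best_distance_m is not None and self.best_distance_m <= 0:
            raise ValueError(f"subject {self.subject_id}: best_distance_m must be > 0")
        if self.carnosine_mean_mm is None:
            present = [
                v
                for v in (self.carnosine_left_mm, self.carnosine_right_mm)
                if v is not None
            ]
            self.carnosine_mean_mm = float(np.mean(present))


@dataclass(frozen=True)
class PeakSpec:
    """One resonance of the synthetic signal model."""

    center_ppm: float
    amplitude: float  # signal units per mM per mm^3 (before relaxation scaling)
    linewidth_fwhm_hz: float
    lineshape: str = "lorentzian"
    label: str = ""

    def __post_init__(self) -> None:
        if self.linewidth_fwhm_hz <= 0:
            raise ValueError(f"peak {self.label or self.center_ppm}: linewidth must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"peak {self.label or self.center_ppm}: amplitude must be >= 0")
        if self.lineshape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown lineshape {self.lineshape!r}")


@dataclass
class PeakFit:
    """Result of a windowed single-lineshape fit (areas are S_m or S_r)."""

    center_ppm: float
    linewidth_fwhm_hz: float
    area: float
    lineshape: str
    baseline_coefficients: np.ndarray
    rmse: float
    converged: bool
    message: str = ""

    def __post_init__(self) -> None:
        if self.converged and self.linewidth_fwhm_hz <= 0:
            raise ValueError("converged fit must have positive linewidth")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass(frozen=True)
class QuantificationInputs:
    """Every quantity entering the absolute-concentration formula.

    Units: concentrations mM, areas in (consistent) signal units,
    volumes mm^3, times ms, temperatures K.
    """

    c_r_mm: float
    s_m: float
    s_r: float
    v_m_mm3: float
    v_r_mm3: float
    t1_m_ms: float
    t2_m_ms: float
    t1_r_ms: float
    t2_r_ms: float
    tr_ms: float
    te_ms: float
    temp_m_k: float
    temp_r_k: float

    def __post_init__(self) -> None:
        positive = {
            "c_r_mm": self.c_r_mm,
            "s_r": self.s_r,
            "v_m_mm3": self.v_m_mm3,
            "v_r_mm3": self.v_r_mm3,
            "t1_m_ms": self.t1_m_ms,
            "t2_m_ms": self.t2_m_ms,
            "t1_r_ms": self.t1_r_ms,
            "t2_r_ms": self.t2_r_ms,
            "tr_ms": self.tr_ms,
            "temp_m_k": self.temp_m_k,
            "temp_r_k": self.temp_r_k,
        }
        for name, v in positive.items():
            if v <= 0:
                if name == "s_r":
                    raise ValueError("phantom signal absent (s_r must be > 0)")
                raise ValueError(f"{name} must be > 0")
        if self.s_m < 0:
            raise ValueError("s_m must be >= 0")
        if self.te_ms < 0:
            raise ValueError("te_ms must be >= 0")
        if self.te_ms >= self.tr_ms:
            raise ValueError("TE must be smaller than TR")


@dataclass
class CalibrationModel:
    """Linear calibration of carnosine (mM, y) on % type-II fiber area (x)."""

    slope: float  # mM per % type-II area
    intercept: float  # mM
    r: float
    p_value: float
    n: int
    residual_sd: float  # mM, n-2 denominator
    x_mean: float  # %
    y_mean: float  # mM
    sxx: float  # sum of squared x deviations; needed for intervals

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("calibration needs n >= 3")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")


@dataclass(frozen=True)
class ReferenceStats:
    """Sex-specific reference mean/SD used for Z-scoring."""

    sex: str
    mean_mm: float
    sd_mm: float
    n: int

    def __post_init__(self) -> None:
        if self.sex not in SEX_TOKENS:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.sd_mm <= 0:
            raise ValueError("reference sd must be > 0")
        if self.n < 2:
            raise ValueError("reference n must be >= 2")


@dataclass
class SigmoidModel:
    """Four-parameter logistic of Z-score against log10 running distance.

    ``z(d) = bottom + (top - bottom) / (1 + (d / d50_m) ** hill)``

    With ``top > bottom`` and ``hill > 0`` the curve decreases with
    distance; ``d50_m`` is the distance at the transition midpoint.
    """

    top: float
    bottom: float
    d50_m: float
    hill: float
    r_squared: float = float("nan")
    converged: bool = True

    def __post_init__(self) -> None:
        if self.d50_m <= 0:
            raise ValueError("d50_m must be > 0")

    def __call__(self, distance_m) -> np.ndarray:
        d = np.asarray(distance_m, dtype=float)
        if np.any(d <= 0):
            raise ValueError("distance must be > 0")
        return self.bottom + (self.top - self.bottom) / (1.0 + (d / self.d50_m) ** self.hill)
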