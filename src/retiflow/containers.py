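"""Core in-memory containers shared across pipeline stages.

The pipeline's central intermediates are plain dataclasses wrapping
numpy arrays: a raw interferogram-like :class:`FrameStack`, the
per-window spectral-moment maps of a :class:`MomentVideo`, the
segmentation products in :class:`ArterialMap`, and the waveform /
biomarker results. Arrays are stored as given (no copies) and validated
on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidSpecError

#: Optical wavelength of the instrument's laser, nm.
DEFAULT_WAVELENGTH_NM = 852.0
#: Analysis band for Doppler spectral moments, Hz.
DEFAULT_BAND_HZ = (6000.0, 33000.0)
#: Short-time Fourier window length, frames.
DEFAULT_WINDOW = 512
#: Camera frame rate, Hz.
DEFAULT_FRAME_RATE_HZ = 67000.0


@dataclass
class FrameStack:
    """Raw (H, W, T) real or complex frame sequence with acquisition metadata."""

    frames: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidSpecError("frames must be a (H, W, T) array")
        h, w, t = self.frames.shape
        if h < 8 or w < 8 or t < 1:
            raise InvalidSpecError(f"stack too small: {self.frames.shape}")
        if not self.frame_rate_hz > 0:
            raise InvalidSpecError("frame_rate_hz must be positive")

    @property
    def shape(self):
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]


@dataclass
class MomentVideo:
    """Per-window in-band power (m0) and normalized second moment (m2, Hz^2).

    ``m2`` is the power-weighted mean of f^2 over the analysis band; it is
    NaN wherever the in-band power is zero (undefined, not zero). K windows
    of ``window_length`` frames are placed every ``hop`` frames.
    """

    m0: np.ndarray
    m2: np.ndarray
    frame_rate_hz: float
    pixel_size_um: float
    window_length: int = DEFAULT_WINDOW
    hop: int = DEFAULT_WINDOW
    band_lo_hz: float = DEFAULT_BAND_HZ[0]
    band_hi_hz: float = DEFAULT_BAND_HZ[1]
    window_times_s: np.ndarray | None = None

    def __post_init__(self):
        self.m0 = np.asarray(self.m0, dtype=float)
        self.m2 = np.asarray(self.m2, dtype=float)
        if self.m0.shape != self.m2.shape or self.m0.ndim != 3:
            raise InvalidSpecError("m0 and m2 must share a (H, W, K) shape")
        if np.any(self.m0 < 0):
            raise InvalidSpecError("m0 must be nonnegative")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise InvalidSpecError("band edges must satisfy 0 < lo < hi")
        if self.window_times_s is None:
            k = self.m0.shape[2]
            centers = (np.arange(k) * self.hop + self.window_length / 2.0)
            self.window_times_s = centers / self.frame_rate_hz
        self.window_times_s = np.asarray(self.window_times_s, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.m0.shape[2]

    @property
    def sampling_rate_hz(self) -> float:
        """Rate of the window time series (frame rate / hop)."""
        return self.frame_rate_hz / self.hop


@dataclass
class PoiseuilleFit:
    """Result of fitting v(x) = v_max * max(0, 1 - ((x - x0)/R)^2)."""

    v_max: float
    center_px: float
    radius_px: float
    diameter_um: float
    residual: float  # relative RMS residual
    ok: bool


@dataclass
class CrossSection:
    """A sampling line across one vessel branch.

    ``center`` and ``direction`` are in (row, col) pixel coordinates;
    the profile is sampled at unit-pixel spacing over +-half_length and
    has odd length (centered sample).
    """

    branch_id: int
    center: tuple[float, float]
    direction: tuple[float, float]  # unit normal to the local centerline
    half_length: int
    profile: np.ndarray | None = None  # time-mean velocity, mm/s
    fit: PoiseuilleFit | None = None

    @property
    def fitted_diameter_um(self) -> float | None:
        return None if self.fit is None else self.fit.diameter_um

    def sample_offsets(self) -> np.ndarray:
        return np.arange(-self.half_length, self.half_length + 1, dtype=float)

    def sample_coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) sample positions along the section."""
        s = self.sample_offsets()
        r = self.center[0] + s * self.direction[0]
        c = self.center[1] + s * self.direction[1]
        return np.stack([r, c], axis=1)


@dataclass
class ArterialMap:
    """Segmentation products: masks, branch labels, and cross-sections."""

    artery_mask: np.ndarray
    background_mask: np.ndarray
    branch_labels: np.ndarray
    disc_center: tuple[float, float]
    disc_diameter_px: float
    sections: list[CrossSection] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None  # all tubular pixels, incl. rejected
    centerlines: dict[int, np.ndarray] = field(default_factory=dict)
    intensity: np.ndarray | None = None  # image used to orient sections

    def __post_init__(self):
        self.artery_mask = np.asarray(self.artery_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        self.branch_labels = np.asarray(self.branch_labels, dtype=int)
        if np.any(self.artery_mask & self.background_mask):
            raise InvalidSpecError("artery and background masks overlap")
        if np.any((self.branch_labels > 0) & ~self.artery_mask):
            raise InvalidSpecError("branch labels outside the artery mask")

    @property
    def branch_ids(self) -> list[int]:
        ids = np.unique(self.branch_labels)
        return [int(i) for i in ids if i > 0]


@dataclass
class Waveform:
    """A sampled hemodynamic time series with cardiac-cycle annotations."""

    t: np.ndarray
    value: np.ndarray
    kind: str  # "velocity" (mm/s) or "volume_rate" (uL/min)
    heart_rate_bpm: float | None = None
    systole_idx: np.ndarray | None = None
    diastole_idx: np.ndarray | None = None
    maxslope_idx: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.shape != self.value.shape:
            raise InvalidSpecError("t and value must have equal length")
        if self.kind not in ("velocity", "volume_rate"):
            raise InvalidSpecError(f"unknown waveform kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else np.nan


BIOMARKER_NAMES = (
    "qs_ul_min", "qd_ul_min", "qm_ul_min", "vas_nl",
    "ri_v", "pi_v", "ri_q", "pi_q", "heart_rate_bpm", "mean_diameter_um",
)


@dataclass
class BiomarkerSet:
    """The ten scalar biomarkers of one measurement.

    Systolic/diastolic/mean total volume rates (QS, QD, QM, uL/min),
    arterial stroke volume (VAS, nL), resistivity and pulsatility indices
    from the velocity and the volume-rate waveform, heart rate (bpm) and
    mean arterial diameter (um).
    """

    qs_ul_min: float
    qd_ul_min: float
    qm_ul_min: float
    vas_nl: float
    ri_v: float
    pi_v: float
    ri_q: float
    pi_q: float
    heart_rate_bpm: float
    mean_diameter_um: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in BIOMARKER_NAMES}


@dataclass
class Calibration:
    """Scaling constants that map Doppler broadening to velocity.

    v = alpha * lambda * delta_f / NA, with the empirical scaling alpha,
    optical wavelength lambda and eye numerical aperture NA. Pixel size
    is calibrated from the optic-disc diameter (assumed anatomical size
    over measured size in pixels).
    """

    alpha: float = 5.0
    wavelength_nm: float = DEFAULT_WAVELENGTH_NM
    numerical_aperture: float = 0.25
    disc_diameter_mm: float = 1.79
    pixel_size_um: float | None = None

    def __post_init__(self):
        for name in ("alpha", "wavelength_nm", "numerical_aperture",
                     "disc_diameter_mm"):
            if not getattr(self, name) > 0:
                raise InvalidSpecError(f"{name} must be strictly positive")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise InvalidSpecError("pixel_size_um must be strictly positive")

    @classmethod
    def from_disc(cls, disc_diameter_px: float, disc_diameter_mm: float = 1.79,
                  **kwargs) -> "Calibration":
        """Calibrate pixel pitch from the measured disc diameter in pixels."""
        if not disc_diameter_px > 0:
            raise InvalidSpecError("disc_diameter_px must be positive")
        px = 1000.0 * disc_diameter_mm / disc_diameter_px
        return cls(disc_diameter_mm=disc_diameter_mm, pixel_size_um=px, **kwargs)

    def velocity_mm_s_per_hz(self) -> float:
        """Linear coefficient of the broadening-to-velocity model, (mm/s)/Hz."""
        lam_mm = self.wavelength_nm * 1e-6
        return self.alpha * lam_mm / self.numerical_aperture

    def broadening_hz_per_mm_s(self) -> float:
        """Inverse coefficient used by the scene generator, Hz/(mm/s)."""
        return 1.0 / self.velocity_mm_s_per_hz()
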