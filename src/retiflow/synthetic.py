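"""Synthetic retinal Doppler scenes with full ground-truth annotation.

The generator emulates what the analysis assumes about the data: an
arterial tree radiating from the optic-nerve-head disc, Poiseuille
(parabolic) velocity profiles across each vessel, a periodic cardiac
waveform with a systolic peak and a dicrotic notch, diffuse tissue
broadening outside vessels, static clutter, and sensor noise. Scenes can
be emitted either directly as spectral-moment videos (the reconstruction
module's output, bypassing frame synthesis) or as interferogram-like
frame stacks whose short-time spectra carry the same moments.

All randomness flows from the config seed; identical configs produce
byte-identical output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (DEFAULT_BAND_HZ, DEFAULT_FRAME_RATE_HZ,
                         DEFAULT_WINDOW, Calibration, FrameStack, MomentVideo)
from .errors import AliasingError, InvalidSpecError, SceneError
from .units import circular_area_um2, flow_ul_min, ul_min_s_to_nl

__all__ = [
    "CardiacWaveformSpec", "BranchSpec", "SceneConfig", "GroundTruth",
    "RepeatStudyConfig", "make_cardiac_waveform", "evaluate_waveform",
    "render_moment_video", "render_frame_stack", "scene_truth",
    "simulate_repeat_study", "default_scene", "tone_stack",
    "bandlimited_noise_stack",
]


# ---------------------------------------------------------------------------
# cardiac waveform
# ---------------------------------------------------------------------------

@dataclass
class CardiacWaveformSpec:
    """Parameters of the periodic arterial pulse shape.

    The waveform is peak-normalized (systolic maximum 1) and its
    resistivity index (max - min)/max equals ``target_ri`` by
    construction.
    """

    heart_rate_bpm: float = 75.0
    systolic_fraction: float = 0.33
    dicrotic_notch_depth: float = 0.25
    target_ri: float = 0.8
    duration_s: float = 5.0

    def __post_init__(self):
        if not 0 < self.target_ri <= 1:
            raise InvalidSpecError("target_ri must lie in (0, 1]")
        if not 0 < self.systolic_fraction < 1:
            raise InvalidSpecError("systolic_fraction must lie in (0, 1)")
        if not 0 <= self.dicrotic_notch_depth < 1:
            raise InvalidSpecError("dicrotic_notch_depth must lie in [0, 1)")
        if self.heart_rate_bpm <= 0 or self.duration_s <= 0:
            raise InvalidSpecError("heart_rate_bpm and duration_s must be > 0")

    @property
    def period_s(self) -> float:
        return 60.0 / self.heart_rate_bpm


def _pulse_shape(phase, systolic_fraction, notch_depth):
    """Un-normalized periodic pulse shape on cycle phase in [0, 1).

    A Gaussian systolic bump early in the cycle plus a smaller bump just
    after end-systole (the dicrotic notch); neighboring-cycle copies are
    summed so the shape is smooth across the wrap.
    """
    peak = 0.45 * systolic_fraction
    width = 0.32 * systolic_fraction
    notch_center = systolic_fraction + 0.08
    notch_width = 0.035
    out = np.zeros_like(np.asarray(phase, dtype=float))
    for k in (-1.0, 0.0, 1.0):
        p = phase + k
        out = out + np.exp(-0.5 * ((p - peak) / width) ** 2)
        if notch_depth > 0:
            out = out + notch_depth * np.exp(
                -0.5 * ((p - notch_center) / notch_width) ** 2)
    return out


_EXTREMA_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def _shape_extrema(spec: CardiacWaveformSpec, n_dense: int = 100_000):
    """Continuous extrema of the pulse shape from a dense one-period grid."""
    key = (spec.systolic_fraction, spec.dicrotic_notch_depth)
    if key not in _EXTREMA_CACHE:
        phase = np.arange(n_dense) / n_dense
        s = _pulse_shape(phase, spec.systolic_fraction,
                         spec.dicrotic_notch_depth)
        _EXTREMA_CACHE[key] = (float(s.min()), float(s.max()))
    return _EXTREMA_CACHE[key]


def evaluate_waveform(spec: CardiacWaveformSpec, t) -> np.ndarray:
    """Noiseless peak-normalized waveform at arbitrary times (seconds)."""
    t = np.asarray(t, dtype=float)
    phase = (t / spec.period_s) % 1.0
    s = _pulse_shape(phase, spec.systolic_fraction, spec.dicrotic_notch_depth)
    lo, hi = _shape_extrema(spec)
    unit = (s - lo) / (hi - lo)  # in [0, 1]
    return (1.0 - spec.target_ri) + spec.target_ri * unit


def make_cardiac_waveform(spec: CardiacWaveformSpec,
                          frame_rate_hz: float) -> np.ndarray:
    """Sample the waveform at ``frame_rate_hz`` over ``spec.duration_s``.

    Requires the duration to cover at least two cardiac periods so that
    downstream cycle detection is well-posed.
    """
    if spec.duration_s < 2 * spec.period_s:
        raise InvalidSpecError("duration must cover at least two cardiac periods")
    n = int(round(spec.duration_s * frame_rate_hz))
    t = np.arange(n) / frame_rate_hz
    return evaluate_waveform(spec, t)


# ---------------------------------------------------------------------------
# scene configuration
# ---------------------------------------------------------------------------

@dataclass
class BranchSpec:
    """One arterial branch: a centerline polyline with constant caliber.

    Diameter is constant along the branch (diameter pulsatility in large
    retinal arteries is ~±2% over the cycle and is deliberately
    neglected). ``peak_centerline_velocity_mm_s`` is the centerline
    velocity at the systolic peak; the cross-vessel profile is parabolic
    (Poiseuille), so the section-mean velocity is half the centerline
    value.
    """

    centerline: np.ndarray  # (n, 2) (row, col) pixel coordinates, disc rim first
    diameter_um: float = 100.0
    peak_centerline_velocity_mm_s: float = 40.0
    waveform: CardiacWaveformSpec = field(default_factory=CardiacWaveformSpec)

    def __post_init__(self):
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 2 \
                or self.centerline.shape[0] < 2:
            raise InvalidSpecError("centerline must be an (n>=2, 2) polyline")
        if self.diameter_um <= 0 or self.peak_centerline_velocity_mm_s <= 0:
            raise InvalidSpecError("diameter and peak velocity must be > 0")


@dataclass
class SceneConfig:
    """Full description of a synthetic acquisition."""

    image_size: int = 64
    pixel_size_um: float = 12.0
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    n_frames: int = 2048
    disc_center: tuple[float, float] = (32.0, 32.0)
    disc_diameter_um: float = 288.0
    branches: list[BranchSpec] = field(default_factory=list)
    background_m2_hz2: float = 5.0e7
    clutter_amplitude: float = 0.0
    signal_amplitude: float = 1.0
    noise_sd: float = 0.0
    band_lo_hz: float = DEFAULT_BAND_HZ[0]
    band_hi_hz: float = DEFAULT_BAND_HZ[1]
    calibration: Calibration = field(default_factory=Calibration)
    seed: int = 0

    def __post_init__(self):
        if self.frame_rate_hz < 2 * self.band_hi_hz:
            raise InvalidSpecError(
                "frame rate must be at least twice the upper band edge")
        if self.background_m2_hz2 < 0:
            raise InvalidSpecError("background_m2_hz2 must be >= 0")
        for b in self.branches:
            if b.diameter_um <= 2 * self.pixel_size_um:
                raise InvalidSpecError(
                    f"branch caliber {b.diameter_um} um must exceed two pixels")

    @property
    def disc_diameter_px(self) -> float:
        return self.disc_diameter_um / self.pixel_size_um

    @property
    def shape(self):
        return (self.image_size, self.image_size)


@dataclass
class GroundTruth:
    """Ground-truth bookkeeping for a rendered scene.

    Scalars follow the biomarker conventions: per-cycle systolic maximum
    (QS), diastolic minimum (QD), time mean (QM) of the total volume-rate
    waveform; stroke volume (VAS) integrated from the maximum-derivative
    point of the upstroke to the systolic peak; RI and PI from the same
    extrema. Periodicity makes every cycle identical, so single-period
    dense evaluation suffices.
    """

    total_qs_ul_min: float
    total_qd_ul_min: float
    total_qm_ul_min: float
    vas_nl: float
    true_ri: float
    true_pi: float
    true_h_bpm: float
    true_diameters_um: dict[int, float]
    per_branch_qm_ul_min: dict[int, float]
    artery_mask: np.ndarray | None = None
    branch_masks: dict[int, np.ndarray] = field(default_factory=dict)
    centerlines: dict[int, np.ndarray] = field(default_factory=dict)
    velocity_field_mm_s: np.ndarray | None = None
    per_branch_flow_ul_min: dict[int, np.ndarray] = field(default_factory=dict)
    total_flow_ul_min: np.ndarray | None = None
    window_times_s: np.ndarray | None = None


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _distance_to_polyline(shape, polyline):
    """Per-pixel Euclidean distance (in px) from pixel centers to a polyline."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    dist = np.full(pts.shape[0], np.inf)
    for p0, p1 in zip(polyline[:-1], polyline[1:]):
        v = p1 - p0
        denom = float(v @ v)
        if denom == 0:
            proj = np.broadcast_to(p0, pts.shape)
        else:
            tt = np.clip((pts - p0) @ v / denom, 0.0, 1.0)
            proj = p0 + tt[:, None] * v
        dist = np.minimum(dist, np.linalg.norm(pts - proj, axis=1))
    return dist.reshape(shape)


def _branch_fields(config: SceneConfig):
    """Per-branch boolean mask and normalized parabolic profile factor."""
    masks, profiles = [], []
    for b in config.branches:
        radius_px = b.diameter_um / (2.0 * config.pixel_size_um)
        dist = _distance_to_polyline(config.shape, b.centerline)
        mask = dist < radius_px
        prof = np.where(mask, 1.0 - (dist / radius_px) ** 2, 0.0)
        masks.append(mask)
        profiles.append(prof)
    if masks and np.any(np.sum(masks, axis=0) > 1):
        raise SceneError("branches overlap; scene violates segmentation "
                         "assumptions")
    return masks, profiles


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _upstroke_markers(t, q):
    """(t_diastole, t_maxslope, t_peak) of the last full cycle of a dense
    periodic waveform: systolic peak, preceding minimum, and the maximum
    derivative between them."""
    i_peak = int(np.argmax(q[len(q) // 2:]) + len(q) // 2)
    i = i_peak
    while i > 1 and q[i - 1] <= q[i]:
        i -= 1
    i_dia = i
    grad = np.gradient(q, t)
    seg = slice(i_dia, i_peak + 1)
    i_slope = i_dia + int(np.argmax(grad[seg]))
    return i_dia, i_slope, i_peak


def scene_truth(config: SceneConfig, window_times_s=None,
                n_dense: int = 8192) -> GroundTruth:
    """Ground-truth biomarkers of a scene, from the analytic waveforms.

    Dense two-period evaluation of the total volume-rate waveform gives
    QS/QD/QM, RI/PI and the stroke volume; optional ``window_times_s``
    additionally tabulates per-branch flow at the analysis time base.
    """
    if not config.branches:
        raise SceneError("scene has no branches; ground truth is undefined")
    period = config.branches[0].waveform.period_s
    t = np.linspace(0.0, 2 * period, n_dense, endpoint=False)
    total = np.zeros_like(t)
    per_branch_qm, diameters = {}, {}
    for i, b in enumerate(config.branches, start=1):
        area = circular_area_um2(b.diameter_um)
        w = evaluate_waveform(b.waveform, t)
        qb = flow_ul_min(0.5 * b.peak_centerline_velocity_mm_s * w, area)
        total += qb
        per_branch_qm[i] = float(qb.mean())
        diameters[i] = b.diameter_um
    qs, qd, qm = float(total.max()), float(total.min()), float(total.mean())
    i_dia, i_slope, i_peak = _upstroke_markers(t, total)
    vas = ul_min_s_to_nl(np.trapezoid(total[i_slope:i_peak + 1],
                                      t[i_slope:i_peak + 1]))
    gt = GroundTruth(
        total_qs_ul_min=qs, total_qd_ul_min=qd, total_qm_ul_min=qm,
        vas_nl=float(vas),
        true_ri=(qs - qd) / qs, true_pi=(qs - qd) / qm,
        true_h_bpm=config.branches[0].waveform.heart_rate_bpm,
        true_diameters_um=diameters, per_branch_qm_ul_min=per_branch_qm)
    if window_times_s is not None:
        window_times_s = np.asarray(window_times_s, dtype=float)
        total_k = np.zeros_like(window_times_s)
        for i, b in enumerate(config.branches, start=1):
            area = circular_area_um2(b.diameter_um)
            w = evaluate_waveform(b.waveform, window_times_s)
            qb = flow_ul_min(0.5 * b.peak_centerline_velocity_mm_s * w, area)
            gt.per_branch_flow_ul_min[i] = qb
            total_k = total_k + qb
        gt.total_flow_ul_min = total_k
        gt.window_times_s = window_times_s
    return gt


# ---------------------------------------------------------------------------
# renderers
# ---------------------------------------------------------------------------

def render_moment_video(config: SceneConfig,
                        window_length: int = DEFAULT_WINDOW,
                        hop: int | None = None):
    """Synthesize the spectral-moment video a reconstruction would yield.

    Inside vessels, ``m2 = background + (NA * v / (alpha * lambda))^2``
    — the inversion of the broadening-to-velocity model — with v a
    Poiseuille profile across the lumen modulated by the cardiac
    waveform; outside vessels m2 is the tissue background. ``noise_sd``
    applies multiplicative Gaussian perturbation to the moment maps
    (relative estimator noise).

    Returns ``(MomentVideo, GroundTruth)``.
    """
    hop = window_length if hop is None else int(hop)
    if config.n_frames < window_length:
        raise InvalidSpecError("n_frames shorter than one analysis window")
    k = (config.n_frames - window_length) // hop + 1
    times = (np.arange(k) * hop + window_length / 2.0) / config.frame_rate_hz
    masks, profiles = _branch_fields(config)
    h = w = config.image_size

    coef = config.calibration.broadening_hz_per_mm_s()  # Hz per mm/s
    v_field = np.zeros((h, w, k))
    for b, prof in zip(config.branches, profiles):
        wave = evaluate_waveform(b.waveform, times)
        v_field += prof[:, :, None] * (b.peak_centerline_velocity_mm_s
                                       * wave[None, None, :])
    m2 = config.background_m2_hz2 + (coef * v_field) ** 2
    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        m2 = m2 * (1.0 + config.noise_sd * rng.standard_normal(m2.shape))
        m2 = np.clip(m2, 1e-9 * config.background_m2_hz2, None)
    m0 = np.ones((h, w, k))

    video = MomentVideo(m0=m0, m2=m2, frame_rate_hz=config.frame_rate_hz,
                        pixel_size_um=config.pixel_size_um,
                        window_length=window_length, hop=hop,
                        band_lo_hz=config.band_lo_hz,
                        band_hi_hz=config.band_hi_hz, window_times_s=times)
    if config.branches:
        gt = scene_truth(config, window_times_s=times)
    else:
        gt = GroundTruth(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, {}, {},
                         window_times_s=times)
    gt.velocity_field_mm_s = v_field
    gt.artery_mask = (np.sum(masks, axis=0) > 0 if masks
                      else np.zeros((h, w), dtype=bool))
    gt.branch_masks = {i + 1: m for i, m in enumerate(masks)}
    gt.centerlines = {i + 1: b.centerline.copy()
                      for i, b in enumerate(config.branches)}
    return video, gt


def _inband_moment_table(window_length, frame_rate_hz, band, n_sigma=3000):
    """Monotone table sigma -> in-band second moment of a centered Gaussian
    PSD sampled on the discrete STFT frequency grid."""
    f = np.fft.fftfreq(window_length, d=1.0 / frame_rate_hz)
    mask = (np.abs(f) >= band[0]) & (np.abs(f) <= band[1])
    fb = f[mask]
    sig = np.geomspace(band[0] / 50.0, band[1] * 50.0, n_sigma)
    log_s = -0.5 * (fb[None, :] / sig[:, None]) ** 2
    s = np.exp(log_s - log_s.max(axis=1, keepdims=True))
    m2 = (s * fb[None, :] ** 2).sum(axis=1) / s.sum(axis=1)
    return sig, m2


def render_frame_stack(config: SceneConfig,
                       window_length: int = DEFAULT_WINDOW) -> FrameStack:
    """Synthesize a complex interferogram-like stack matching the scene.

    Per non-overlapping ``window_length`` block, each pixel carries a
    stationary circular-Gaussian process whose power spectral density is
    a centered Gaussian shaped so that its in-band second moment on the
    STFT frequency grid equals the scene's local m2 (band-aware shaping;
    see the methods note). A rank-1 static clutter component and white
    sensor noise are added on top.
    """
    if config.n_frames < window_length:
        raise InvalidSpecError("n_frames must cover at least one STFT window")
    n_blocks = int(np.ceil(config.n_frames / window_length))
    masks, profiles = _branch_fields(config)
    h = w = config.image_size
    coef = config.calibration.broadening_hz_per_mm_s()
    sig_grid, m2_grid = _inband_moment_table(
        window_length, config.frame_rate_hz, (config.band_lo_hz,
                                              config.band_hi_hz))
    rng = np.random.default_rng(config.seed)
    frames = np.zeros((h, w, n_blocks * window_length), dtype=complex)
    block_times = (np.arange(n_blocks) + 0.5) * window_length / config.frame_rate_hz
    for j in range(n_blocks):
        v = np.zeros((h, w))
        for b, prof in zip(config.branches, profiles):
            wave = float(evaluate_waveform(b.waveform, block_times[j]))
            v += prof * (b.peak_centerline_velocity_mm_s * wave)
        m2_target = config.background_m2_hz2 + (coef * v) ** 2
        if np.any(m2_target > m2_grid[-1]):
            raise AliasingError(
                "requested m2 exceeds what the band/frame rate can carry")
        if np.any(m2_target < m2_grid[0]):
            raise AliasingError("requested m2 below the reachable in-band range")
        if config.signal_amplitude > 0:
            sigma = np.interp(m2_target, m2_grid, sig_grid)
            f = np.fft.fftfreq(window_length, d=1.0 / config.frame_rate_hz)
            psd = np.exp(-0.5 * (f[None, None, :] / sigma[:, :, None]) ** 2)
            psd *= window_length ** 2 / psd.sum(axis=-1, keepdims=True)
            spec = np.sqrt(psd / 2.0) * (
                rng.standard_normal((h, w, window_length))
                + 1j * rng.standard_normal((h, w, window_length)))
            block = np.fft.ifft(spec, axis=-1) * config.signal_amplitude
        else:
            block = np.zeros((h, w, window_length), dtype=complex)
        frames[:, :, j * window_length:(j + 1) * window_length] = block
    if config.clutter_amplitude > 0:
        phase = rng.uniform(0.0, 2 * np.pi, size=(h, w))
        clutter = config.clutter_amplitude * np.exp(1j * phase)
        frames += clutter[:, :, None]
    if config.noise_sd > 0:
        t_total = frames.shape[2]
        frames += config.noise_sd / np.sqrt(2.0) * (
            rng.standard_normal((h, w, t_total))
            + 1j * rng.standard_normal((h, w, t_total)))
    frames = frames[:, :, :config.n_frames]
    return FrameStack(frames, config.frame_rate_hz, config.pixel_size_um,
                      config.calibration.wavelength_nm)


def tone_stack(shape, f0_hz, frame_rate_hz, n_frames, pixel_size_um=12.0,
               at=None, amplitude=1.0) -> FrameStack:
    """A zero stack with a pure complex tone at one pixel (test fixture)."""
    h, w = shape
    at = (h // 2, w // 2) if at is None else at
    t = np.arange(n_frames) / frame_rate_hz
    frames = np.zeros((h, w, n_frames), dtype=complex)
    frames[at[0], at[1], :] = amplitude * np.exp(2j * np.pi * f0_hz * t)
    return FrameStack(frames, frame_rate_hz, pixel_size_um)


def bandlimited_noise_stack(shape, band, frame_rate_hz, n_frames,
                            pixel_size_um=12.0, seed=0) -> FrameStack:
    """Complex noise whose spectrum is flat over ``band`` and zero outside."""
    h, w = shape
    rng = np.random.default_rng(seed)
    f = np.fft.fftfreq(n_frames, d=1.0 / frame_rate_hz)
    mask = (np.abs(f) >= band[0]) & (np.abs(f) <= band[1])
    spec = np.where(mask[None, None, :], 1.0, 0.0) / np.sqrt(2.0) * (
        rng.standard_normal((h, w, n_frames))
        + 1j * rng.standard_normal((h, w, n_frames)))
    frames = np.fft.ifft(spec, axis=-1) * n_frames
    return FrameStack(frames, frame_rate_hz, pixel_size_um)


# ---------------------------------------------------------------------------
# default desk-scale scene
# ---------------------------------------------------------------------------

def default_scene(seed: int = 0, n_cycles: float = 6.5,
                  heart_rate_bpm: float = 75.0, target_ri: float = 0.8,
                  noise_sd: float = 0.0, image_size: int = 64,
                  pixel_size_um: float = 12.0) -> SceneConfig:
    """A four-branch desk-scale scene with realistic retinal calibers.

    Branches of 96-120 um caliber radiate from a synthetic disc at the
    image center; peak centerline velocities of 30-45 mm/s give per-branch
    mean volume rates of a few uL/min, comparable to large retinal
    arteries.
    """
    duration = n_cycles * 60.0 / heart_rate_bpm
    frame_rate = DEFAULT_FRAME_RATE_HZ
    n_frames = int(np.ceil(duration * frame_rate / DEFAULT_WINDOW)) * DEFAULT_WINDOW
    wf = CardiacWaveformSpec(heart_rate_bpm=heart_rate_bpm,
                             target_ri=target_ri, duration_s=duration)
    center = np.array([image_size / 2.0, image_size / 2.0])
    disc_diameter_um = 24 * pixel_size_um
    r0 = disc_diameter_um / (2.0 * pixel_size_um)
    r1 = image_size / 2.0 - 3.0
    angles_deg = (10.0, 100.0, 190.0, 280.0)
    diameters = (96.0, 108.0, 120.0, 96.0)
    peaks = (30.0, 40.0, 45.0, 35.0)
    branches = []
    for ang, d_um, vpk in zip(angles_deg, diameters, peaks):
        u = np.array([np.sin(np.deg2rad(ang)), np.cos(np.deg2rad(ang))])
        line = np.stack([center + r0 * u, center + r1 * u])
        branches.append(BranchSpec(centerline=line, diameter_um=d_um,
                                   peak_centerline_velocity_mm_s=vpk,
                                   waveform=wf))
    return SceneConfig(image_size=image_size, pixel_size_um=pixel_size_um,
                       frame_rate_hz=frame_rate, n_frames=n_frames,
                       disc_center=tuple(center),
                       disc_diameter_um=disc_diameter_um,
                       branches=branches, noise_sd=noise_sd, seed=seed)


# ---------------------------------------------------------------------------
# repeat studies
# ---------------------------------------------------------------------------

@dataclass
class RepeatStudyConfig:
    """Layout and variability of a simulated repeat study.

    Between-subject and within-subject coefficients of variation (in %)
    scale each measurement's true flow multiplicatively; design-specific
    perturbation schedules only alter nuisance parameters (noise,
    illumination, disc position), never the ground-truth flow.
    """

    n_subjects: int = 7
    n_repeats_per_session: int = 2
    n_sessions: int = 3
    between_subject_cv: float = 30.0
    within_subject_cv: float = 10.0
    design_label: str = "intra_day"
    axial_snr_profile: list[float] | None = None
    lateral_positions: list[tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.design_label not in ("intra_day", "inter_day", "axial",
                                     "lateral"):
            raise InvalidSpecError(f"unknown design {self.design_label!r}")
        if self.between_subject_cv < 0 or self.within_subject_cv < 0:
            raise InvalidSpecError("CVs must be nonnegative")
        if min(self.n_subjects, self.n_repeats_per_session,
               self.n_sessions) < 1:
            raise InvalidSpecError("counts must be >= 1")


@dataclass
class RepeatMeasurement:
    """One simulated measurement: its scene config and scalar ground truth."""

    subject_id: int
    session_id: int
    repeat_id: int
    design_label: str
    scene: SceneConfig
    flow_scale: float
    truth: GroundTruth


def _scaled_scene(base: SceneConfig, scale: float, seed: int) -> SceneConfig:
    branches = [replace(b, peak_centerline_velocity_mm_s=
                        b.peak_centerline_velocity_mm_s * scale)
                for b in base.branches]
    return replace(base, branches=branches, seed=seed)


def simulate_repeat_study(config: RepeatStudyConfig,
                          base: SceneConfig) -> list[RepeatMeasurement]:
    """Draw a grouped repeat study around a base scene.

    Subject-level mean flow factors are drawn with ``between_subject_cv``
    and repeat-level factors with ``within_subject_cv`` (both relative,
    truncated to stay positive). Axial designs additionally scale
    noise/illumination per position, and lateral designs shift the disc
    center and the arterial tree; neither perturbs the true flow.
    Scenes are returned as configs (render on demand).
    """
    rng = np.random.default_rng(config.seed)
    base_truth = scene_truth(base)
    out = []
    n_positions = (config.n_sessions * config.n_repeats_per_session)
    for s in range(config.n_subjects):
        g = max(1.0 + config.between_subject_cv / 100.0 * rng.standard_normal(),
                0.05)
        pos = 0
        for sess in range(config.n_sessions):
            for rep in range(config.n_repeats_per_session):
                m = max(1.0 + config.within_subject_cv / 100.0
                        * rng.standard_normal(), 0.05)
                scale = g * m
                seed = int(rng.integers(0, 2**31 - 1))
                scene = _scaled_scene(base, scale, seed)
                if config.design_label == "axial":
                    profile = (config.axial_snr_profile
                               or _default_axial_profile(n_positions))
                    snr = profile[pos % len(profile)]
                    scene = replace(scene,
                                    signal_amplitude=base.signal_amplitude * snr,
                                    noise_sd=base.noise_sd / max(snr, 1e-3))
                elif config.design_label == "lateral":
                    offsets = (config.lateral_positions
                               or _default_lateral_positions())
                    dr, dc = offsets[pos % len(offsets)]
                    shifted = [replace(b, centerline=b.centerline
                                       + np.array([dr, dc]))
                               for b in scene.branches]
                    scene = replace(
                        scene, branches=shifted,
                        disc_center=(scene.disc_center[0] + dr,
                                     scene.disc_center[1] + dc))
                truth = copy.deepcopy(base_truth)
                for name in ("total_qs_ul_min", "total_qd_ul_min",
                             "total_qm_ul_min", "vas_nl"):
                    setattr(truth, name, getattr(truth, name) * scale)
                truth.per_branch_qm_ul_min = {
                    k: v * scale for k, v in truth.per_branch_qm_ul_min.items()}
                out.append(RepeatMeasurement(
                    subject_id=s, session_id=sess, repeat_id=rep,
                    design_label=config.design_label, scene=scene,
                    flow_scale=scale, truth=truth))
                pos += 1
    return out


def _default_axial_profile(n: int) -> list[float]:
    """Optical throughput vs axial position: best at mid-range, tapering."""
    center = (n - 1) / 2.0
    return [float(1.0 - 0.06 * abs(i - center)) for i in range(n)]


def _default_lateral_positions() -> list[tuple[float, float]]:
    return [(0.0, 0.0), (0.0, 4.0), (0.0, -4.0), (4.0, 0.0), (-4.0, 0.0)]


def truth_table(measurements: list[RepeatMeasurement]):
    """Tabulate per-measurement ground-truth biomarkers as a DataFrame."""
    import pandas as pd

    rows = []
    for m in measurements:
        rows.append({
            "subject_id": m.subject_id, "session_id": m.session_id,
            "repeat_id": m.repeat_id, "design_label": m.design_label,
            "qm_ul_min": m.truth.total_qm_ul_min,
            "qs_ul_min": m.truth.total_qs_ul_min,
            "qd_ul_min": m.truth.total_qd_ul_min,
            "vas_nl": m.truth.vas_nl,
            "ri_q": m.truth.true_ri, "pi_q": m.truth.true_pi,
            "heart_rate_bpm": m.truth.true_h_bpm,
            "flow_scale": m.flow_scale,
        })
    return pd.DataFrame(rows)
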