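"""Stage 2: broadening to velocity, diameters, volume rates, biomarkers.

Velocity follows the forward-scattering broadening model
``v = alpha * lambda * delta_f / NA``; vessel diameter comes from a
least-squares Poiseuille (clipped-parabola) fit to the cycle-averaged
velocity profile of each cross-section; volume rate multiplies the
section-mean velocity (half the fitted centerline velocity, the
area-mean of a parabolic profile in a circular lumen) by the circular
lumen area, averaged over sections within a branch and summed over
branches. The waveform layer detects cardiac cycles, low-pass filters
over an integer cycle count, and extracts the ten scalar biomarkers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

from .containers import (ArterialMap, BiomarkerSet, Calibration, CrossSection,
                         MomentVideo, PoiseuilleFit, Waveform)
from .errors import InvalidSpecError, NoCyclesError
from .reconstruction import differential_broadening
from .units import circular_area_um2, flow_ul_min, ul_min_s_to_nl

__all__ = [
    "velocity_from_broadening", "velocity_video", "region_velocity_waveform",
    "fit_poiseuille", "mean_time_profile", "branch_volume_rate",
    "total_volume_rate", "detect_cycles", "cycle_filter", "biomarkers",
    "quantify",
]


# ---------------------------------------------------------------------------
# velocity
# ---------------------------------------------------------------------------

def velocity_from_broadening(delta_f, calib: Calibration | None = None):
    """RMS blood velocity (mm/s) from differential broadening (Hz).

    Linear model ``v = alpha * lambda * delta_f / NA``; negative
    broadening (artery apparently narrower-spectrum than background)
    carries no flow signal and is clipped to zero.
    """
    calib = calib or Calibration()
    v = calib.velocity_mm_s_per_hz() * np.asarray(delta_f, dtype=float)
    v = np.clip(v, 0.0, None)
    return float(v) if v.ndim == 0 else v


@dataclass
class VelocityVideo:
    """Per-window velocity maps (mm/s) on the moment-video time base."""

    v: np.ndarray  # (H, W, K)
    window_times_s: np.ndarray
    pixel_size_um: float


def _background_series(moments: MomentVideo, amap: ArterialMap) -> np.ndarray:
    """Spatially averaged background m2 per window (tissue baseline)."""
    bg = amap.background_mask
    if not bg.any():
        raise InvalidSpecError("background annulus is empty")
    m2 = np.nan_to_num(moments.m2, nan=0.0)
    return m2[bg].mean(axis=0)


def velocity_video(moments: MomentVideo, amap: ArterialMap,
                   calib: Calibration | None = None) -> VelocityVideo:
    """Per-pixel velocity maps from differential broadening vs the annulus."""
    calib = calib or Calibration()
    bg = _background_series(moments, amap)  # (K,)
    m2 = np.nan_to_num(moments.m2, nan=0.0)
    delta = differential_broadening(m2, bg[None, None, :])
    v = velocity_from_broadening(delta, calib)
    return VelocityVideo(v=v, window_times_s=moments.window_times_s,
                         pixel_size_um=moments.pixel_size_um)


def region_velocity_waveform(moments: MomentVideo, amap: ArterialMap,
                             calib: Calibration | None = None) -> Waveform:
    """Spatially averaged arterial velocity waveform.

    Differential broadening between the artery-region mean m2 and the
    annulus mean m2 per window (region-level sign correction), mapped to
    velocity.
    """
    calib = calib or Calibration()
    m2 = np.nan_to_num(moments.m2, nan=0.0)
    art = m2[amap.artery_mask].mean(axis=0)
    bg = _background_series(moments, amap)
    delta = differential_broadening(art, bg)
    v = velocity_from_broadening(delta, calib)
    return Waveform(t=moments.window_times_s, value=v, kind="velocity")


# ---------------------------------------------------------------------------
# Poiseuille profile fitting
# ---------------------------------------------------------------------------

def _parabola(x, v_max, x0, radius):
    return v_max * np.clip(1.0 - ((x - x0) / radius) ** 2, 0.0, None)


def fit_poiseuille(profile, pixel_size_um, x=None,
                   max_rel_residual: float = 0.35,
                   interior_fraction: float = 0.12) -> PoiseuilleFit:
    """Least-squares clipped-parabola fit of a cross-vessel velocity profile.

    Fits ``v(x) = v_max * max(0, 1 - ((x - x0)/R)^2)`` and reports the
    lumen diameter 2R in micrometers. Samples below ``interior_fraction``
    of the peak are excluded from the least squares: near the lumen wall
    the image-sampled profile is smeared over about a pixel, so the
    radius is extrapolated from the interior curvature rather than read
    off the smeared wall position. The profile is normalized by its
    maximum before fitting so the solution is exactly scale-equivariant
    (calibration changes rescale ``v_max`` and leave the geometry
    bit-identical). Fits with relative RMS residual above
    ``max_rel_residual``, non-positive profiles, or maxima at the profile
    edge (monotone profiles) are flagged as failed.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.size < 5:
        raise InvalidSpecError("profile needs at least 5 samples")
    x = np.arange(profile.size, dtype=float) if x is None else np.asarray(x)
    peak = profile.max()
    i_peak = int(np.argmax(profile))
    if peak <= 0 or i_peak in (0, profile.size - 1):
        return PoiseuilleFit(0.0, np.nan, np.nan, np.nan, np.inf, False)
    p = profile / peak
    use = p >= interior_fraction
    if np.count_nonzero(use) < 5:
        use = np.ones_like(p, dtype=bool)
    xu, pu = x[use], p[use]
    width = max(np.count_nonzero(p > 0.05) / 2.0, 1.5)
    x0_init = float(x[i_peak])
    try:
        res = optimize.least_squares(
            lambda th: _parabola(xu, th[0], th[1], th[2]) - pu,
            x0=np.array([1.0, x0_init, width]),
            bounds=([1e-6, x.min() - 1, 0.5],
                    [10.0, x.max() + 1, float(np.ptp(x))]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except Exception:
        return PoiseuilleFit(0.0, np.nan, np.nan, np.nan, np.inf, False)
    v_max_n, x0, radius = res.x
    rel = float(np.sqrt(2 * res.cost) / np.linalg.norm(pu))
    ok = bool(np.isfinite(rel) and rel <= max_rel_residual and radius > 0.5)
    return PoiseuilleFit(v_max=float(v_max_n * peak), center_px=float(x0),
                         radius_px=float(radius),
                         diameter_um=float(2.0 * radius * pixel_size_um),
                         residual=rel, ok=ok)


def _fit_parabola_squared(delta_m2, pixel_size_um, coef_mm_s_per_hz,
                          max_rel_residual: float = 0.35) -> PoiseuilleFit:
    """Poiseuille geometry fitted directly to an m2-difference profile.

    Since ``m2 - background = (v / coef)^2``, a parabolic velocity
    profile appears as ``A * max(0, 1 - ((x - x0)/R)^2)^2`` in the moment
    domain. Fitting there keeps the estimator noise zero-mean (no square
    root of a noisy difference), which matters at low SNR; for noiseless
    input the solution coincides with the velocity-domain fit.
    """
    y = np.asarray(delta_m2, dtype=float)
    if y.size < 5:
        raise InvalidSpecError("profile needs at least 5 samples")
    x = np.arange(y.size, dtype=float)
    peak = y.max()
    i_peak = int(np.argmax(y))
    if peak <= 0 or i_peak in (0, y.size - 1):
        return PoiseuilleFit(0.0, np.nan, np.nan, np.nan, np.inf, False)
    p = y / peak
    width = max(np.count_nonzero(p > 0.02) / 2.0, 1.5)
    try:
        res = optimize.least_squares(
            lambda th: th[0] * np.clip(
                1.0 - ((x - th[1]) / th[2]) ** 2, 0.0, None) ** 2 - p,
            x0=np.array([1.0, float(x[i_peak]), width]),
            bounds=([1e-6, x.min() - 1, 0.5],
                    [10.0, x.max() + 1, float(np.ptp(x))]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15)
    except Exception:
        return PoiseuilleFit(0.0, np.nan, np.nan, np.nan, np.inf, False)
    a_n, x0, radius = res.x
    rel = float(np.sqrt(2 * res.cost) / np.linalg.norm(p))
    ok = bool(np.isfinite(rel) and rel <= max_rel_residual and radius > 0.5)
    v_max = coef_mm_s_per_hz * np.sqrt(max(a_n, 0.0) * peak)
    return PoiseuilleFit(v_max=float(v_max), center_px=float(x0),
                         radius_px=float(radius),
                         diameter_um=float(2.0 * radius * pixel_size_um),
                         residual=rel, ok=ok)


def _bilinear_sample(field, coords):
    """Sample a (H, W, K) field at (n, 2) fractional (row, col) positions.

    Returns an (n, K) array; bilinear interpolation, edge-clamped.
    """
    h, w = field.shape[:2]
    r = np.clip(coords[:, 0], 0, h - 1)
    c = np.clip(coords[:, 1], 0, w - 1)
    r0 = np.clip(np.floor(r).astype(int), 0, h - 2) if h > 1 else np.zeros_like(r, int)
    c0 = np.clip(np.floor(c).astype(int), 0, w - 2) if w > 1 else np.zeros_like(c, int)
    fr = (r - r0)[:, None]
    fc = (c - c0)[:, None]
    f00 = field[r0, c0]
    f01 = field[r0, c0 + 1]
    f10 = field[r0 + 1, c0]
    f11 = field[r0 + 1, c0 + 1]
    return ((1 - fr) * (1 - fc) * f00 + (1 - fr) * fc * f01
            + fr * (1 - fc) * f10 + fr * fc * f11)


def section_profiles(velocity: VelocityVideo,
                     section: CrossSection) -> np.ndarray:
    """Per-window velocity profiles along a section, (n_samples, K)."""
    coords = section.sample_coords()
    h, w = velocity.v.shape[:2]
    if (coords[:, 0].min() < 0 or coords[:, 0].max() > h - 1
            or coords[:, 1].min() < 0 or coords[:, 1].max() > w - 1):
        raise InvalidSpecError("section extends outside the image")
    return _bilinear_sample(velocity.v, coords)


def mean_time_profile(velocity: VelocityVideo, section: CrossSection,
                      window_slice: slice | None = None) -> np.ndarray:
    """Cycle-averaged velocity profile of one section.

    Arithmetic mean over the averaging span (an integer number of
    detected cycles when ``window_slice`` is given, otherwise all
    windows).
    """
    prof = section_profiles(velocity, section)
    if window_slice is not None:
        prof = prof[:, window_slice]
    return prof.mean(axis=1)


# ---------------------------------------------------------------------------
# volume rates
# ---------------------------------------------------------------------------

def branch_volume_rate(moments: MomentVideo, sections: list[CrossSection],
                       background_m2,
                       calib: Calibration | None = None,
                       window_slice: slice | None = None,
                       max_rel_residual: float = 0.35):
    """Per-branch volume-rate waveform (uL/min), averaged over sections.

    Each accepted section contributes ``0.5 * v_max(t) * pi (d/2)^2``.
    The diameter and parabola template come from a Poiseuille fit to the
    cycle-averaged differential-broadening velocity profile; the
    per-window centerline amplitude ``v_max(t)`` is recovered by linear
    projection of the background-subtracted m2 profile onto the squared
    template. Working in the m2 domain keeps the estimator noise
    zero-mean (the square root of a noisy moment difference has a
    positive pedestal that would bias flow upward). Sections whose fit
    fails are excluded; returns None if no section survives.
    """
    calib = calib or Calibration()
    bg = np.asarray(background_m2, dtype=float)  # (K,)
    m2 = np.nan_to_num(moments.m2, nan=0.0)
    coef = calib.velocity_mm_s_per_hz()
    flows = []
    for sec in sections:
        prof_m2 = _bilinear_sample(m2, sec.sample_coords())  # (n, K)
        span = prof_m2[:, window_slice] if window_slice is not None else prof_m2
        bg_span = bg[window_slice] if window_slice is not None else bg
        delta_m2 = span.mean(axis=1) - float(bg_span.mean())
        fit = _fit_parabola_squared(delta_m2, moments.pixel_size_um, coef,
                                    max_rel_residual=max_rel_residual)
        sec.profile = coef * np.sqrt(np.clip(delta_m2, 0.0, None))
        sec.fit = fit
        if not fit.ok:
            continue
        x = np.arange(delta_m2.size, dtype=float)
        template = _parabola(x, 1.0, fit.center_px, fit.radius_px)
        template = np.where(template >= 0.12, template, 0.0)  # interior only
        t2 = template**2
        denom = float(t2 @ t2)
        if denom == 0:
            continue
        # m2 - bg = (coef^-1 v_max)^2 template^2 along the section
        amp = (t2 @ (prof_m2 - bg[None, :])) / denom  # (K,), Hz^2
        v_max_t = coef * np.sqrt(np.clip(amp, 0.0, None))  # mm/s
        flows.append(flow_ul_min(0.5 * v_max_t,
                                 circular_area_um2(fit.diameter_um)))
    if not flows:
        return None
    return np.mean(flows, axis=0)


def total_volume_rate(branch_waveforms: dict[int, np.ndarray],
                      window_times_s) -> Waveform:
    """Pointwise sum of per-branch volume-rate waveforms."""
    window_times_s = np.asarray(window_times_s, dtype=float)
    arrays = [np.asarray(q, dtype=float) for q in branch_waveforms.values()]
    if not arrays:
        raise InvalidSpecError("no branch waveforms to sum")
    for q in arrays:
        if q.shape != window_times_s.shape:
            raise InvalidSpecError("branch waveforms on mismatched time bases")
    return Waveform(t=window_times_s, value=np.sum(arrays, axis=0),
                    kind="volume_rate")


# ---------------------------------------------------------------------------
# cardiac cycle analysis
# ---------------------------------------------------------------------------

def _dominant_frequency(t, y):
    dt = t[1] - t[0]
    y = y - y.mean()
    if np.allclose(y, 0):
        raise NoCyclesError("flat waveform: no cardiac periodicity")
    freqs, power = signal.periodogram(y, fs=1.0 / dt)
    power[0] = 0.0
    i = int(np.argmax(power))
    if power[i] <= 0:
        raise NoCyclesError("no dominant spectral peak")
    return float(freqs[i])


def _refine_peak_time(t, y, i):
    """Parabolic sub-sample refinement of a local maximum."""
    if i <= 0 or i >= len(y) - 1:
        return float(t[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(t[i] + np.clip(delta, -1, 1) * (t[1] - t[0]))


def detect_cycles(waveform: Waveform) -> Waveform:
    """Annotate a waveform with systole/diastole/max-derivative markers.

    The dominant cardiac frequency from the periodogram seeds a per-cycle
    peak search (minimum peak separation of 60% of the period, so the
    dicrotic notch is not counted as a systole); heart rate is the median
    refined peak-to-peak interval. Flat or single-peak waveforms raise
    :class:`NoCyclesError`, propagating the acquisition exclusion rule.
    """
    t, y = waveform.t, waveform.value
    f0 = _dominant_frequency(t, y)
    duration = t[-1] - t[0]
    if duration < 2.0 / f0:
        raise NoCyclesError("waveform shorter than two cardiac periods")
    dt = t[1] - t[0]
    min_dist = max(int(round(0.6 / f0 / dt)), 1)
    # systoles live in the upper half of the pulse; a height gate keeps
    # boundary peaks detectable (prominence is ill-defined at the edges)
    peaks, _ = signal.find_peaks(y, distance=min_dist,
                                 height=y.min() + 0.5 * np.ptp(y))
    if len(peaks) < 2:
        raise NoCyclesError("fewer than two systolic peaks detected")
    peak_times = np.array([_refine_peak_time(t, y, i) for i in peaks])
    heart_rate = 60.0 / float(np.median(np.diff(peak_times)))

    # diastole/upstroke markers only between consecutive systoles; a
    # minimum at the array boundary is not a true end-diastole
    diastole, slopes = [], []
    grad = np.gradient(y, t)
    for lo, p in zip(peaks[:-1], peaks[1:]):
        d = lo + int(np.argmin(y[lo:p + 1]))
        diastole.append(d)
        up = grad[d:p + 1]
        slopes.append(d + int(np.argmax(up)) if up.size else d)
    return Waveform(t=t, value=y, kind=waveform.kind,
                    heart_rate_bpm=heart_rate, systole_idx=np.asarray(peaks),
                    diastole_idx=np.asarray(diastole, dtype=int),
                    maxslope_idx=np.asarray(slopes, dtype=int))


def cycle_filter(waveform: Waveform, cutoff_multiple: float = 10.0) -> Waveform:
    """Crop to an integer number of cycles and low-pass the waveform.

    The span between the first and last detected systole covers an exact
    integer cycle count; a zero-phase Butterworth low-pass with cutoff
    ``cutoff_multiple`` times the heart rate suppresses window noise
    while preserving the systolic peak and dicrotic notch. Cycle markers
    are re-detected on the filtered series.
    """
    if waveform.systole_idx is None:
        waveform = detect_cycles(waveform)
    peaks = waveform.systole_idx
    if len(peaks) < 2:
        raise NoCyclesError("need at least one full cycle")
    # small margin keeps the boundary systoles detectable after filtering
    lo = max(int(peaks[0]) - 3, 0)
    hi = min(int(peaks[-1]) + 4, waveform.value.size)
    t, y = waveform.t[lo:hi], waveform.value[lo:hi]
    fs = 1.0 / (t[1] - t[0])
    cutoff = cutoff_multiple * waveform.heart_rate_bpm / 60.0
    if cutoff < 0.49 * fs:
        b, a = signal.butter(4, cutoff / (fs / 2.0))
        pad = min(3 * max(len(a), len(b)), y.size - 1)
        y = signal.filtfilt(b, a, y, padlen=pad)
    out = Waveform(t=t, value=y, kind=waveform.kind)
    return detect_cycles(out)


# ---------------------------------------------------------------------------
# biomarkers
# ---------------------------------------------------------------------------

def _cycle_stats(w: Waveform):
    """Per-cycle systolic maxima, diastolic minima and the time mean."""
    y = w.value
    sys_vals = y[w.systole_idx]
    dia_vals = y[w.diastole_idx] if len(w.diastole_idx) else np.array([y.min()])
    return float(sys_vals.mean()), float(dia_vals.mean()), float(y.mean())


def _indices(systolic, diastolic, mean):
    ri = (systolic - diastolic) / systolic if systolic != 0 else np.nan
    pi = (systolic - diastolic) / mean if mean != 0 else np.nan
    return ri, pi


def _stroke_volume(w: Waveform) -> float:
    """Mean over cycles of the BVR integral from max-derivative to systole, nL."""
    vols = []
    # markers sit between consecutive systoles: pair with the later peak
    for d, s, p in zip(w.diastole_idx, w.maxslope_idx, w.systole_idx[1:]):
        if p <= s:
            continue
        vols.append(ul_min_s_to_nl(
            np.trapezoid(w.value[s:p + 1], w.t[s:p + 1])))
    return float(np.mean(vols)) if vols else np.nan


def biomarkers(q_waveform: Waveform, v_waveform: Waveform,
               diameters_um) -> BiomarkerSet:
    """The ten scalar biomarkers from annotated waveforms and diameters.

    QS/QD are the means over cycles of the per-cycle systolic maximum and
    diastolic minimum of the volume-rate waveform, QM its time mean; RI
    and PI follow the Pourcelot/Gosling definitions computed separately
    on the velocity and volume-rate waveforms; VAS integrates the
    volume-rate upstroke; mean diameter averages the accepted section
    fits.
    """
    for w in (q_waveform, v_waveform):
        if w.systole_idx is None:
            raise NoCyclesError("waveforms must be cycle-annotated")
    qs, qd, qm = _cycle_stats(q_waveform)
    vs, vd, vm = _cycle_stats(v_waveform)
    ri_q, pi_q = _indices(qs, qd, qm)
    ri_v, pi_v = _indices(vs, vd, vm)
    diameters_um = np.asarray(list(diameters_um), dtype=float)
    return BiomarkerSet(
        qs_ul_min=qs, qd_ul_min=qd, qm_ul_min=qm,
        vas_nl=_stroke_volume(q_waveform),
        ri_v=ri_v, pi_v=pi_v, ri_q=ri_q, pi_q=pi_q,
        heart_rate_bpm=float(q_waveform.heart_rate_bpm),
        mean_diameter_um=float(diameters_um.mean()) if diameters_um.size
        else np.nan)


# ---------------------------------------------------------------------------
# end-to-end quantification
# ---------------------------------------------------------------------------

def quantify(moments: MomentVideo, amap: ArterialMap,
             calib: Calibration | None = None,
             cutoff_multiple: float = 10.0):
    """Moments + arterial map -> (BiomarkerSet, total Waveform, velocity Waveform).

    Runs the full stage-2 chain: velocity maps, per-branch volume rates
    from Poiseuille-fitted sections, total waveform, cycle detection and
    integer-cycle low-pass filtering, then the biomarker extraction.
    """
    calib = calib or Calibration()
    if calib.pixel_size_um is None:
        calib = Calibration(alpha=calib.alpha,
                            wavelength_nm=calib.wavelength_nm,
                            numerical_aperture=calib.numerical_aperture,
                            disc_diameter_mm=calib.disc_diameter_mm,
                            pixel_size_um=moments.pixel_size_um)
    v_wave = region_velocity_waveform(moments, amap, calib)
    v_cycles = detect_cycles(v_wave)
    # integer-cycle span for diameter averaging
    span = slice(int(v_cycles.systole_idx[0]), int(v_cycles.systole_idx[-1]) + 1)
    bg = _background_series(moments, amap)

    branch_flows: dict[int, np.ndarray] = {}
    diameters = []
    for bid in amap.branch_ids:
        secs = [s for s in amap.sections if s.branch_id == bid]
        if not secs:
            continue
        q = branch_volume_rate(moments, secs, bg, calib, window_slice=span)
        if q is None:
            continue
        branch_flows[bid] = q
        diameters.extend(s.fit.diameter_um for s in secs if s.fit and s.fit.ok)
    if not branch_flows:
        raise NoCyclesError("no branch produced a valid volume-rate waveform")
    q_total = total_volume_rate(branch_flows, moments.window_times_s)
    q_filt = cycle_filter(detect_cycles(q_total), cutoff_multiple)
    v_filt = cycle_filter(v_cycles, cutoff_multiple)
    markers = biomarkers(q_filt, v_filt, diameters)
    return markers, q_filt, v_filt
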