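"""Offline reconstruction streamline: propagation, clutter rejection, moments.

The chain mirrors the instrument's offline processing: an angular-spectrum
propagation of the hologram to the retinal plane, singular-value-decomposition
rejection of static clutter on the Casorati (pixels x time) matrix, and
short-time Fourier analysis in fixed-length windows yielding the in-band
power ``m0`` and the normalized second-order Doppler spectrum moment ``m2``
used downstream as the velocity proxy.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse.linalg

from .containers import (DEFAULT_BAND_HZ, DEFAULT_WINDOW, FrameStack,
                         MomentVideo)
from .errors import InvalidSpecError

__all__ = [
    "angular_spectrum_propagate",
    "svd_clutter_filter",
    "stft_moments",
    "differential_broadening",
    "band_moments",
]


def angular_spectrum_propagate(field, distance, wavelength, pixel_pitch):
    """Propagate a 2-D complex field by the angular-spectrum method.

    The field's spatial spectrum is multiplied by the transfer function
    ``exp(i 2 pi z sqrt(1/lambda^2 - fx^2 - fy^2))``; evanescent components
    (negative root argument) are suppressed. Energy in propagating
    components is conserved (pure phase transfer).

    Parameters
    ----------
    field : (H, W) complex array
    distance : float
        Propagation distance in meters (signed).
    wavelength : float
        Optical wavelength in meters.
    pixel_pitch : float
        Sample pitch in meters.
    """
    if wavelength <= 0 or pixel_pitch <= 0:
        raise InvalidSpecError("wavelength and pixel_pitch must be positive")
    field = np.asarray(field, dtype=complex)
    if field.ndim != 2:
        raise InvalidSpecError("field must be 2-D")
    h, w = field.shape
    fy = np.fft.fftfreq(h, d=pixel_pitch)[:, None]
    fx = np.fft.fftfreq(w, d=pixel_pitch)[None, :]
    arg = 1.0 / wavelength**2 - fx**2 - fy**2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    transfer = np.where(propagating,
                        np.exp(2j * np.pi * distance * kz), 0.0)
    return np.fft.ifft2(np.fft.fft2(field) * transfer)


def svd_clutter_filter(stack: FrameStack, n_remove: int) -> FrameStack:
    """Remove the ``n_remove`` leading singular components along time.

    The stack is reshaped to its Casorati form (pixels x time); the
    projection onto the leading left-singular subspace — dominated by
    temporally static clutter — is subtracted. ``n_remove = 0`` is the
    identity (on a copy).
    """
    h, w, t = stack.frames.shape
    npix = h * w
    if not 0 <= n_remove < min(npix, t):
        raise InvalidSpecError(
            f"n_remove must lie in [0, {min(npix, t)}), got {n_remove}")
    casorati = stack.frames.reshape(npix, t)
    if n_remove == 0:
        filtered = casorati.copy()
    elif n_remove >= min(npix, t) - 1:
        # svds cannot return the full spectrum; fall back to dense SVD
        u, s, vh = np.linalg.svd(casorati, full_matrices=False)
        uk = u[:, :n_remove]
        filtered = casorati - uk @ (uk.conj().T @ casorati)
    else:
        u, _, _ = scipy.sparse.linalg.svds(
            casorati.astype(complex if np.iscomplexobj(casorati) else float),
            k=n_remove, which="LM")
        filtered = casorati - u @ (u.conj().T @ casorati)
    return FrameStack(filtered.reshape(h, w, t), stack.frame_rate_hz,
                      stack.pixel_size_um, stack.wavelength_nm)


def _band_freqs(window_length, frame_rate_hz, band, complex_input):
    """Frequency grid and in-band mask for a window of given length."""
    lo, hi = band
    if not 0 < lo < hi <= frame_rate_hz / 2:
        raise InvalidSpecError(
            f"band {band} must lie within (0, {frame_rate_hz / 2}]")
    if complex_input:
        f = np.fft.fftfreq(window_length, d=1.0 / frame_rate_hz)
        mask = (np.abs(f) >= lo) & (np.abs(f) <= hi)
    else:
        f = np.fft.rfftfreq(window_length, d=1.0 / frame_rate_hz)
        mask = (f >= lo) & (f <= hi)
    return f, mask


def band_moments(psd, freqs, mask):
    """In-band m0 and normalized second moment of a sampled PSD.

    ``psd`` may have any leading shape with frequency on the last axis.
    Returns (m0, m2) with m2 NaN where the in-band power is zero.
    """
    f2 = freqs[mask] ** 2
    s = psd[..., mask]
    m0 = s.sum(axis=-1)
    total = psd.sum(axis=-1)
    # in-band power that is pure numerical leakage counts as zero
    valid = m0 > 1e-12 * total
    with np.errstate(invalid="ignore", divide="ignore"):
        m2 = (s * f2).sum(axis=-1) / m0
    m2 = np.where(valid, m2, np.nan)
    return m0, m2


def stft_moments(stack: FrameStack, window_length: int = DEFAULT_WINDOW,
                 hop: int | None = None, band=DEFAULT_BAND_HZ,
                 window: str = "rect") -> MomentVideo:
    """Short-time Fourier spectral moments of a frame stack.

    Per pixel and window the power spectral density is formed from the
    (optionally Hann-tapered) discrete Fourier transform; ``m0`` is the
    in-band power and ``m2`` the raw (non-centered) power-weighted mean
    of f^2 over the band. Windows with zero in-band power carry NaN in
    ``m2`` (undefined, propagated as missing).
    """
    frames = stack.frames
    h, w, t = frames.shape
    if t < window_length:
        raise InvalidSpecError(
            f"stack has {t} frames, shorter than the {window_length}-frame window")
    hop = window_length if hop is None else int(hop)
    if hop < 1:
        raise InvalidSpecError("hop must be >= 1")
    is_complex = np.iscomplexobj(frames)
    freqs, mask = _band_freqs(window_length, stack.frame_rate_hz, band,
                              is_complex)
    if window == "rect":
        taper = None
    elif window == "hann":
        taper = np.hanning(window_length)
    else:
        raise InvalidSpecError(f"unknown window {window!r}")

    k = (t - window_length) // hop + 1
    m0 = np.empty((h, w, k))
    m2 = np.empty((h, w, k))
    fft = np.fft.fft if is_complex else np.fft.rfft
    for j in range(k):
        seg = frames[:, :, j * hop:j * hop + window_length]
        if taper is not None:
            seg = seg * taper
        psd = np.abs(fft(seg, axis=-1)) ** 2
        m0[:, :, j], m2[:, :, j] = band_moments(psd, freqs, mask)
    times = (np.arange(k) * hop + window_length / 2.0) / stack.frame_rate_hz
    return MomentVideo(m0=m0, m2=m2, frame_rate_hz=stack.frame_rate_hz,
                       pixel_size_um=stack.pixel_size_um,
                       window_length=window_length, hop=hop,
                       band_lo_hz=band[0], band_hi_hz=band[1],
                       window_times_s=times)


def differential_broadening(m2_region, m2_background):
    """Signed differential Doppler broadening, Hz.

    ``sign(m2_region - m2_background) * sqrt(|m2_region - m2_background|)``;
    the sign corrects windows where the background annulus overestimates
    the arterial baseline. Works elementwise on arrays.
    """
    a = np.asarray(m2_region, dtype=float)
    b = np.asarray(m2_background, dtype=float)
    if np.any(a[np.isfinite(a)] < 0) or np.any(b[np.isfinite(b)] < 0):
        raise InvalidSpecError("spectral moments must be nonnegative")
    diff = a - b
    out = np.sign(diff) * np.sqrt(np.abs(diff))
    if out.ndim == 0:
        return float(out)
    return out
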