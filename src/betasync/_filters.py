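"""Zero-phase frequency-domain filters shared across the package.

All band-limiting in this package is done by multiplying the real-signal
spectrum with a real, non-negative raised-cosine mask.  This is an exact
zero-phase linear filter (a long symmetric FIR applied circularly), so
spike/LFP timing relations are never skewed by group delay, and a sinusoid
inside the passband is returned with unchanged amplitude and phase.
"""

from __future__ import annotations

import numpy as np


def raised_cosine_band_mask(
    freqs: np.ndarray,
    f_lo: float,
    f_hi: float,
    transition_hz: float = 2.0,
) -> np.ndarray:
    """Band-pass magnitude response: 1 on [f_lo, f_hi], cosine roll-off
    over `transition_hz` on each side, 0 outside [f_lo - tw, f_hi + tw]."""
    f = np.abs(np.asarray(freqs, dtype=float))
    h = np.zeros_like(f)
    inside = (f >= f_lo) & (f <= f_hi)
    h[inside] = 1.0
    tw = float(transition_hz)
    if tw > 0:
        lo_edge = (f >= f_lo - tw) & (f < f_lo)
        h[lo_edge] = 0.5 * (1 + np.cos(np.pi * (f_lo - f[lo_edge]) / tw))
        hi_edge = (f > f_hi) & (f <= f_hi + tw)
        h[hi_edge] = 0.5 * (1 + np.cos(np.pi * (f[hi_edge] - f_hi) / tw))
    return h


def raised_cosine_lowpass_mask(
    freqs: np.ndarray, cutoff_hz: float, transition_hz: float = 50.0
) -> np.ndarray:
    """Low-pass response: 1 up to cutoff, cosine roll-off, 0 above
    cutoff + transition."""
    f = np.abs(np.asarray(freqs, dtype=float))
    h = np.zeros_like(f)
    h[f <= cutoff_hz] = 1.0
    tw = float(transition_hz)
    if tw > 0:
        edge = (f > cutoff_hz) & (f <= cutoff_hz + tw)
        h[edge] = 0.5 * (1 + np.cos(np.pi * (f[edge] - cutoff_hz) / tw))
    return h


def apply_mask(x: np.ndarray, fs: float, mask_fn, **mask_kwargs) -> np.ndarray:
    """Filter a real signal by spectral multiplication with ``mask_fn``."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    h = mask_fn(freqs, **mask_kwargs)
    return np.fft.irfft(np.fft.rfft(x, axis=-1) * h, n=n, axis=-1)


def bandpass_zero_phase(
    x: np.ndarray, fs: float, band: tuple[float, float], transition_hz: float = 2.0
) -> np.ndarray:
    """Zero-phase band-pass of ``x`` onto [f_lo, f_hi] Hz.

    Raises ValueError for a degenerate band or one outside (0, fs/2).
    """
    f_lo, f_hi = band
    if not (0 < f_lo < f_hi <= fs / 2):
        raise ValueError(f"band {band} must satisfy 0 < f_lo < f_hi <= fs/2 = {fs / 2}")
    return apply_mask(
        x, fs, raised_cosine_band_mask, f_lo=f_lo, f_hi=f_hi, transition_hz=transition_hz
    )
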