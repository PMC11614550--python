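"""Magnitude-squared coherence between cortical and striatal LFPs.

Coherence is estimated from Welch-averaged auto- and cross-spectra that
share the spectral module's estimator settings:

    Cxy(f) = |Pxy(f)|^2 / (Pxx(f) * Pyy(f))

With K averaged windows the estimator has a positive bias of about 1/K
under independence; no bias correction is applied, but the independence
expectation is exposed via :func:`expected_null_coherence`.

The region-pair summary computes the band-mean coherence for every
(cortex electrode, striatum electrode) pair and then averages the pairs,
keeping the per-pair table for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .bands import HIGH_BETA
from .io import MOTOR_CORTEX, STRIATUM, Segment
from .spectral import DEFAULT_WELCH, WelchSettings


@dataclass
class CoherenceSpectrum:
    """Per-frequency magnitude-squared coherence plus the spectra behind it.

    Invariants: 0 <= Cxy <= 1 everywhere; |Pxy|^2 <= Pxx*Pyy
    (Cauchy-Schwarz); K >= 2.
    """

    frequencies: np.ndarray
    cxy: np.ndarray
    pxy: np.ndarray
    pxx: np.ndarray
    pyy: np.ndarray
    n_windows: int
    settings: WelchSettings

    def __post_init__(self) -> None:
        if self.n_windows < 2:
            raise ValueError("coherence needs K >= 2 averaged windows")
        if np.any(self.cxy < -1e-9) or np.any(self.cxy > 1 + 1e-9):
            raise ValueError("Cxy must lie in [0, 1]")


def expected_null_coherence(n_windows: int) -> float:
    """Expected band coherence of two independent signals (~1/K bias)."""
    return 1.0 / n_windows


def window_ffts(
    x: np.ndarray, fs: float, settings: WelchSettings = DEFAULT_WELCH
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-window rFFTs of overlapping, detrended, tapered segments.

    Returns (frequencies, X[k, f], density_scale) with the scale chosen so
    that ``mean_k |X|^2 * scale`` equals the scipy Welch one-sided density.
    Used so that many channel pairs reuse one FFT pass per channel.
    """
    x = np.asarray(x, dtype=float)
    nper = settings.nperseg(fs)
    step = nper - settings.noverlap(fs)
    n = x.shape[-1]
    if nper > n:
        raise ValueError("window longer than data")
    k = (n - nper) // step + 1
    idx = np.arange(nper)[None, :] + step * np.arange(k)[:, None]
    segs = x[idx]
    if settings.detrend == "constant":
        segs = segs - segs.mean(axis=1, keepdims=True)
    win = signal.get_window(settings.window, nper)
    ffts = np.fft.rfft(segs * win, axis=1)
    scale = 1.0 / (fs * (win * win).sum())
    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    return freqs, ffts, scale


def _one_sided(p: np.ndarray, nper: int) -> np.ndarray:
    p = p.copy()
    if nper % 2 == 0:
        p[..., 1:-1] *= 2.0
    else:
        p[..., 1:] *= 2.0
    return p


def coherence_from_ffts(
    freqs: np.ndarray,
    fx: np.ndarray,
    fy: np.ndarray,
    scale: float,
    settings: WelchSettings,
) -> CoherenceSpectrum:
    nper = 2 * (freqs.size - 1)
    pxx = _one_sided((np.abs(fx) ** 2).mean(axis=0) * scale, nper)
    pyy = _one_sided((np.abs(fy) ** 2).mean(axis=0) * scale, nper)
    pxy = _one_sided((fx * np.conj(fy)).mean(axis=0) * scale, nper)
    denom = pxx * pyy
    with np.errstate(divide="ignore", invalid="ignore"):
        cxy = np.where(denom > 0, np.abs(pxy) ** 2 / denom, 0.0)
    return CoherenceSpectrum(
        frequencies=freqs,
        cxy=np.clip(cxy, 0.0, 1.0),
        pxy=pxy,
        pxx=pxx,
        pyy=pyy,
        n_windows=fx.shape[0],
        settings=settings,
    )


def coherence_spectrum(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    settings: WelchSettings = DEFAULT_WELCH,
) -> CoherenceSpectrum:
    """Magnitude-squared coherence of two equal-length channels.

    Refuses single-window estimation (K < 2), which is identically 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if settings.n_windows(x.shape[-1], fs) < 2:
        raise ValueError("coherence needs at least 2 averaged windows")
    freqs, fx, scale = window_ffts(x, fs, settings)
    _, fy, _ = window_ffts(y, fs, settings)
    return coherence_from_ffts(freqs, fx, fy, scale, settings)


def mean_band_coherence(
    coh: CoherenceSpectrum, band: tuple[float, float] = HIGH_BETA
) -> float:
    """Unweighted mean of Cxy over bins inside the closed band."""
    f_lo, f_hi = band
    mask = (coh.frequencies >= f_lo) & (coh.frequencies <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no coherence bins inside band {band}")
    return float(coh.cxy[mask].mean())


def region_pair_coherence(
    segment: Segment,
    band: tuple[float, float] = HIGH_BETA,
    settings: WelchSettings = DEFAULT_WELCH,
) -> tuple[float, pd.DataFrame]:
    """Band-mean coherence for every cortex-striatum electrode pair.

    Returns the arithmetic mean over pairs and the per-pair table.  One FFT
    pass per channel feeds all pairs so the three spectra of each pair are
    co-estimated with identical settings.
    """
    rec = segment.recording
    ctx = rec.region_indices(MOTOR_CORTEX)
    str_ = rec.region_indices(STRIATUM)
    if not ctx or not str_:
        raise ValueError("segment must contain both regions")
    cache: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    for i in set(ctx) | set(str_):
        cache[i] = window_ffts(rec.samples[i], rec.fs, settings)
    rows = []
    for i in ctx:
        for j in str_:
            freqs, fx, scale = cache[i]
            _, fy, _ = cache[j]
            coh = coherence_from_ffts(freqs, fx, fy, scale, settings)
            rows.append(
                {
                    "cortex_channel": rec.channels[i][0],
                    "striatum_channel": rec.channels[j][0],
                    "pair_id": f"{rec.channels[i][0]}-{rec.channels[j][0]}",
                    "band_mean": mean_band_coherence(coh, band),
                    "n_windows": coh.n_windows,
                }
            )
    table = pd.DataFrame(rows)
    return float(table["band_mean"].mean()), table
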