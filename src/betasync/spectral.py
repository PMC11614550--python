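"""Welch power spectra, spectrograms, named-band power and peak frequency.

Estimator convention: 1-s Hann windows with 50 % overlap (1 Hz resolution,
K = 119 averages on a 60-s segment).  Densities are one-sided and normalised
so that the trapezoidal integral over [0, fs/2] recovers the signal variance
(window-corrected), which makes band powers directly comparable across
channels and segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class WelchSettings:
    """Shared Welch estimator settings (also used by the coherence stage)."""

    window_s: float = 1.0
    overlap_frac: float = 0.5
    window: str = "hann"
    detrend: str = "constant"

    def nperseg(self, fs: float) -> int:
        return int(round(self.window_s * fs))

    def noverlap(self, fs: float) -> int:
        return int(round(self.overlap_frac * self.nperseg(fs)))

    def n_windows(self, n_samples: int, fs: float) -> int:
        nper = self.nperseg(fs)
        step = nper - self.noverlap(fs)
        if n_samples < nper:
            return 0
        return (n_samples - nper) // step + 1


DEFAULT_WELCH = WelchSettings()


@dataclass
class PowerSpectrum:
    """One-sided PSD with estimator metadata.

    Invariants: power >= 0 everywhere; frequency grid strictly increasing,
    spanning [0, fs/2].
    """

    frequencies: np.ndarray
    power: np.ndarray  # signal-units^2 / Hz
    fs: float
    settings: WelchSettings = field(default_factory=WelchSettings)
    n_windows: int = 0

    def __post_init__(self) -> None:
        if np.any(self.power < -1e-12):
            raise ValueError("PSD must be non-negative")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def welch_psd(
    x: np.ndarray,
    fs: float,
    settings: WelchSettings = DEFAULT_WELCH,
) -> PowerSpectrum:
    """Welch-averaged one-sided PSD of a single channel.

    Raises ValueError if the window is longer than the data.
    """
    x = np.asarray(x, dtype=float)
    nper = settings.nperseg(fs)
    if nper > x.shape[-1]:
        raise ValueError(
            f"window of {nper} samples exceeds data length {x.shape[-1]}"
        )
    f, p = signal.welch(
        x,
        fs=fs,
        window=settings.window,
        nperseg=nper,
        noverlap=settings.noverlap(fs),
        detrend=settings.detrend,
        scaling="density",
    )
    return PowerSpectrum(
        frequencies=f,
        power=p,
        fs=fs,
        settings=settings,
        n_windows=settings.n_windows(x.shape[-1], fs),
    )


def spectrogram(
    x: np.ndarray,
    fs: float,
    window_s: float = 1.0,
    step_s: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window periodogram matrix (freq x time).

    Column t is the modified periodogram of the window starting at
    ``t * step_s``; averaging all columns reproduces the Welch estimate with
    the same window.  Returns (frequencies, window_start_times, power).
    """
    if window_s <= 0 or step_s <= 0:
        raise ValueError("window_s and step_s must be positive")
    x = np.asarray(x, dtype=float)
    nper = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if nper > x.shape[-1]:
        raise ValueError("window longer than data")
    f, t, s = signal.spectrogram(
        x,
        fs=fs,
        window=window,
        nperseg=nper,
        noverlap=nper - step,
        detrend="constant",
        scaling="density",
        mode="psd",
    )
    # report window *start* times rather than scipy's window centres
    t_start = t - (nper / 2) / fs
    return f, t_start, s


def band_power(psd: PowerSpectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the density over [f_lo, f_hi] (closed band).

    Disjoint bands are additive: powers of adjoining bands sum to the
    integral over their union.
    """
    f_lo, f_hi = band
    f = psd.frequencies
    if f_lo < f[0] or f_hi > f[-1] or f_lo >= f_hi:
        raise ValueError(f"band {band} outside PSD grid [{f[0]}, {f[-1]}]")
    # integrate on the band's exact support, interpolating at the edges
    grid = f[(f > f_lo) & (f < f_hi)]
    grid = np.concatenate(([f_lo], grid, [f_hi]))
    dens = np.interp(grid, f, psd.power)
    return float(np.trapezoid(dens, grid))


def total_power(psd: PowerSpectrum) -> float:
    """Integral of the density over the full grid (approximates variance)."""
    return float(np.trapezoid(psd.power, psd.frequencies))


def peak_frequency(psd: PowerSpectrum, search_band: tuple[float, float]) -> float:
    """Frequency of maximum density inside ``search_band``; ties break to the
    lowest frequency."""
    f_lo, f_hi = search_band
    mask = (psd.frequencies >= f_lo) & (psd.frequencies <= f_hi)
    if not np.any(mask):
        raise ValueError(f"no PSD bins inside search band {search_band}")
    f_band = psd.frequencies[mask]
    p_band = psd.power[mask]
    return float(f_band[int(np.argmax(p_band))])
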