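"""Time-frequency feature extraction and per-band accumulation.

Two interchangeable extractors produce a nonnegative spectrum per channel and
window: Welch's averaged modified periodogram (segment length 256 samples,
90% overlap, Hann taper) and a complex-Morlet continuous wavelet transform on
a 16-point logarithmic frequency grid over 8-30 Hz.  Band powers are summed
over the bins of each rhythm of interest (mu and the three beta sub-bands),
yielding, per trial / window / band, a length-C electrode contribution
vector rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pywt
from scipy import signal as sps

from .montage import Montage
from .preprocess import TrialEpoch, sliding_windows

__all__ = [
    "WelchConfig", "CWTConfig", "SpectralVector", "Band", "ContributionTensor",
    "welch_psd", "morlet_cwt", "cwt_power", "band_power", "contribution_tensor",
    "MU", "BETA", "BETA_LOW", "BETA_MED", "BETA_HIGH", "SCENARIO_BANDS",
]


@dataclass(frozen=True)
class Band:
    name: str
    fmin: float
    fmax: float

    def __post_init__(self) -> None:
        if not self.fmin < self.fmax:
            raise ValueError("band requires fmin < fmax")


MU = Band("mu", 8.0, 12.0)
BETA_LOW = Band("beta_low", 16.0, 20.0)
BETA_MED = Band("beta_med", 20.0, 24.0)
BETA_HIGH = Band("beta_high", 24.0, 28.0)
BETA = Band("beta", 16.0, 28.0)  # union of the three beta sub-bands

#: Band combinations evaluated as scenarios A-D (one CNN branch per band).
SCENARIO_BANDS: dict[str, tuple[Band, ...]] = {
    "A": (MU,),
    "B": (BETA,),
    "C": (MU, BETA),
    "D": (MU, BETA_LOW, BETA_MED, BETA_HIGH),
}


@dataclass(frozen=True)
class WelchConfig:
    fs: float = 250.0
    nperseg: int = 256
    overlap_fraction: float = 0.9
    taper: str = "hann"

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    @property
    def noverlap(self) -> int:
        return int(round(self.overlap_fraction * self.nperseg))


@dataclass(frozen=True)
class CWTConfig:
    fs: float = 250.0
    wavelet: str = "cmor1.5-1.0"
    n_freqs: int = 16          # number of wavelet scales
    fmin: float = 8.0
    fmax: float = 30.0

    def __post_init__(self) -> None:
        if self.n_freqs < 1:
            raise ValueError("n_freqs must be >= 1")
        if not (0.0 < self.fmin < self.fmax < self.fs / 2.0):
            raise ValueError("frequency grid must lie in (0, fs/2)")

    @property
    def freqs(self) -> np.ndarray:
        """Logarithmically spaced analysis frequencies (Hz, ascending)."""
        return np.geomspace(self.fmin, self.fmax, self.n_freqs)


@dataclass
class SpectralVector:
    freqs: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.values < -1e-12):
            raise ValueError("spectral values must be nonnegative")


@dataclass
class ContributionTensor:
    """Electrode band powers per (trial, window, band)."""

    values: np.ndarray            # n_trials x n_windows x n_bands x C
    window_starts: np.ndarray     # seconds
    bands: tuple[Band, ...]
    montage: Montage
    labels: np.ndarray            # trial class labels


def welch_psd(window_signal: np.ndarray, cfg: WelchConfig) -> SpectralVector:
    """Averaged modified periodogram of a single window (one channel)."""
    x = np.asarray(window_signal, dtype=float)
    if x.shape[-1] < cfg.nperseg:
        raise ValueError(
            f"signal length {x.shape[-1]} shorter than nperseg={cfg.nperseg}")
    freqs, pxx = sps.welch(x, fs=cfg.fs, window=cfg.taper, nperseg=cfg.nperseg,
                           noverlap=cfg.noverlap, detrend="constant",
                           scaling="density", axis=-1)
    return SpectralVector(freqs, np.maximum(pxx, 0.0))


@lru_cache(maxsize=8)
def _wavelet_table(name: str, precision: int = 12):
    w = pywt.ContinuousWavelet(name)
    psi, x = w.wavefun(precision)
    return np.asarray(x, dtype=float), np.asarray(psi, dtype=complex), w.center_frequency


def _morlet_kernels(cfg: CWTConfig) -> list[np.ndarray]:
    """Conjugate Morlet kernels (sample units) for each analysis frequency."""
    x, psi, fc = _wavelet_table(cfg.wavelet)
    dt = 1.0 / cfg.fs
    kernels = []
    for f in cfg.freqs:
        scale = fc / (f * dt)          # scale in samples
        half = int(np.ceil(scale * x[-1]))
        k = np.arange(-half, half + 1) / scale
        ker = np.interp(k, x, psi.real) + 1j * np.interp(k, x, psi.imag)
        kernels.append(np.conj(ker) / np.sqrt(scale))
    return kernels


def morlet_cwt(window_signal: np.ndarray, cfg: CWTConfig) -> np.ndarray:
    """Complex Morlet CWT, shape (..., n_freqs, n_times).

    Correlates the signal with the scaled, conjugated wavelet at each grid
    frequency; coefficients are aligned with the input time axis.  Accepts
    batched input over leading axes.
    """
    x = np.asarray(window_signal, dtype=float)
    if x.shape[-1] == 0:
        raise ValueError("empty signal")
    out = np.empty(x.shape[:-1] + (cfg.n_freqs, x.shape[-1]), dtype=complex)
    for i, ker in enumerate(_morlet_kernels(cfg)):
        shape = (1,) * (x.ndim - 1) + (len(ker),)
        out[..., i, :] = sps.fftconvolve(x, ker[::-1].reshape(shape),
                                         mode="same", axes=-1)
    return out


def cwt_power(coeffs: np.ndarray, cfg: CWTConfig) -> SpectralVector:
    """Time-averaged squared magnitude per frequency (wavelet power)."""
    c = np.asarray(coeffs)
    return SpectralVector(cfg.freqs, np.mean(np.abs(c) ** 2, axis=-1))


def band_power(spec: SpectralVector, band: Band) -> float:
    """Sum of spectral values over bins with fmin <= f <= fmax (inclusive)."""
    mask = (spec.freqs >= band.fmin) & (spec.freqs <= band.fmax)
    if not mask.any():
        raise ValueError(f"no spectral bins inside band {band.name} "
                         f"[{band.fmin}, {band.fmax}] Hz")
    return float(np.sum(spec.values[..., mask], axis=-1))


def _band_sums(freqs: np.ndarray, values: np.ndarray,
               bands: tuple[Band, ...]) -> np.ndarray:
    """Stack band sums along a new axis -2; values shaped (..., n_bins)."""
    out = []
    for band in bands:
        mask = (freqs >= band.fmin) & (freqs <= band.fmax)
        if not mask.any():
            raise ValueError(f"no spectral bins inside band {band.name}")
        out.append(values[..., mask].sum(axis=-1))
    return np.stack(out, axis=-1)


def contribution_tensor(trials: list[TrialEpoch], extractor: str = "cwt",
                        bands: tuple[Band, ...] = SCENARIO_BANDS["D"],
                        tau: float = 2.0, step: float = 1.0,
                        window_starts: list[float] | None = None,
                        welch_cfg: WelchConfig | None = None,
                        cwt_cfg: CWTConfig | None = None,
                        montage: Montage | None = None) -> ContributionTensor:
    """Per-(trial, window, band) electrode contribution vectors.

    ``window_starts`` restricts the analysis to the sliding windows whose
    start times (s) match; by default all windows are kept.
    """
    if not trials:
        raise ValueError("no trials")
    fs = trials[0].fs
    n_ch = trials[0].data.shape[0]
    for t in trials:
        if t.fs != fs or t.data.shape[0] != n_ch:
            raise ValueError("trials must share sampling rate and channel count")
    extractor = extractor.lower()
    if extractor not in ("psd", "cwt"):
        raise ValueError("extractor must be 'psd' or 'cwt'")
    wcfg = welch_cfg or WelchConfig(fs=fs)
    ccfg = cwt_cfg or CWTConfig(fs=fs)

    # windows: (n_trials, n_win, C, tau*fs)
    wsets = [sliding_windows(t, tau=tau, step=step) for t in trials]
    starts = wsets[0].starts
    win = np.stack([w.windows for w in wsets])
    if window_starts is not None:
        keep = [int(np.argmin(np.abs(starts - s))) for s in window_starts]
        for j, s in zip(keep, window_starts):
            if abs(starts[j] - s) > 1e-9:
                raise ValueError(f"no window starting at {s} s (starts: {starts})")
        win = win[:, keep]
        starts = starts[keep]

    try:
        if extractor == "psd":
            freqs, pxx = sps.welch(win, fs=fs, window=wcfg.taper,
                                   nperseg=wcfg.nperseg, noverlap=wcfg.noverlap,
                                   detrend="constant", scaling="density", axis=-1)
            spectra = np.maximum(pxx, 0.0)          # (n_trials, n_win, C, n_bins)
        else:
            coeffs = morlet_cwt(win, ccfg)          # (..., n_freqs, n_times)
            spectra = np.mean(np.abs(coeffs) ** 2, axis=-1)
            freqs = ccfg.freqs
    except ValueError as err:
        raise ValueError(f"feature extraction failed ({extractor}, "
                         f"{len(trials)} trials, {n_ch} channels): {err}") from err

    if montage is not None and len(montage) != n_ch:
        raise ValueError(f"montage size {len(montage)} != channel count {n_ch}")
    sums = _band_sums(freqs, spectra, bands)        # (n_trials, n_win, C, n_bands)
    values = np.moveaxis(sums, -1, 2)               # (n_trials, n_win, n_bands, C)
    labels = np.array([t.label for t in trials], dtype=object)
    return ContributionTensor(values=values, window_starts=starts,
                              bands=tuple(bands), montage=montage, labels=labels)
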