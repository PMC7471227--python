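"""Synthetic motor-imagery EEG with the statistical structure the pipeline
assumes, for testing the whole chain without external recordings.

Each 7 s trial contains, at every electrode, 1/f background noise (power
exponent 1) plus mu (10 Hz) and beta (22 Hz) oscillators sourced at C3, C4
and Cz.  During the imagery interval (3-6 s) the source mapped to the trial's
class — right hand -> C3, left hand -> C4, foot -> Cz, i.e. the contralateral
sensorimotor site — is attenuated by ``erd_depth`` (event-related
desynchronization); the other sources keep full amplitude, so the
discriminative signal is exactly the lateralized power drop.  Source activity
spreads to neighbouring electrodes with Gaussian weight exp(-d^2 / 2 sigma^2)
in unit-sphere chord distance, and the noise is mixed with the same
(variance-preserving) kernel so channels are spatially correlated.
Oscillator amplitudes are calibrated so that ``snr`` is the ratio of rhythm
band power to background band power at the source electrode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BETA, MU, WelchConfig, band_power, welch_psd
from .montage import Montage, standard_montage_22
from .preprocess import RawRecording

__all__ = ["SimConfig", "generate_dataset", "planted_truth", "CLASS_SOURCES"]

#: class -> discriminative (attenuated) source electrode
CLASS_SOURCES = {"right": "C3", "left": "C4", "foot": "Cz"}

_RHYTHMS = ((MU, 10.0), (BETA, 22.0))   # (calibration band, oscillator Hz)
_MI_INTERVAL = (3.0, 6.0)


@dataclass
class SimConfig:
    n_trials_per_class: int = 72
    classes: tuple[str, ...] = ("left", "right")
    fs: float = 250.0
    T: float = 7.0
    erd_depth: float = 0.8         # fractional mu-amplitude reduction during MI
    beta_erd_depth: float | None = None   # defaults to erd_depth
    snr: float = 2.0               # rhythm-to-background band-power ratio
    smear_sigma: float = 0.15      # Gaussian width, unit-sphere chord distance
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must be in [0, 1]")
        if self.beta_erd_depth is not None and not 0.0 <= self.beta_erd_depth <= 1.0:
            raise ValueError("beta_erd_depth must be in [0, 1]")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        unknown = set(self.classes) - set(CLASS_SOURCES)
        if unknown:
            raise ValueError(f"unknown class(es): {sorted(unknown)}")


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...],
                n_samples: int, fs: float) -> np.ndarray:
    """1/f-power noise, unit variance, independent along leading axes."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** -0.5
    spec = (rng.standard_normal(shape + (len(freqs),))
            + 1j * rng.standard_normal(shape + (len(freqs),))) * amp
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def _mixing(montage: Montage, sigma: float) -> np.ndarray:
    """Channel x channel Gaussian smearing weights in chord distance."""
    p = montage.positions3d
    d2 = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _tone_band_sum(freq: float, band, fs: float, n: int) -> float:
    """Welch band sum of a unit-amplitude tone; calibration reference."""
    t = np.arange(n) / fs
    return band_power(welch_psd(np.sin(2 * np.pi * freq * t),
                                WelchConfig(fs=fs)), band)


def generate_dataset(cfg: SimConfig) -> RawRecording:
    """A continuous seeded recording of concatenated, labelled 7 s trials."""
    rng = np.random.default_rng(cfg.seed)
    montage = standard_montage_22()
    c = len(montage)
    n_samp = int(round(cfg.T * cfg.fs))
    labels = np.repeat(list(cfg.classes), cfg.n_trials_per_class)
    rng.shuffle(labels)
    n_trials = len(labels)

    noise = _pink_noise(rng, (n_trials, c), n_samp, cfg.fs)
    mix = _mixing(montage, cfg.smear_sigma)
    mix_noise = mix / np.sqrt((mix ** 2).sum(axis=1, keepdims=True))
    noise = np.einsum("ij,njt->nit", mix_noise, noise)

    # amplitude calibration against the realized background at each source
    wcfg = WelchConfig(fs=cfg.fs)
    n_cal = min(20, n_trials)
    amps: dict[tuple[str, float], dict[str, float]] = {}
    for band, f0 in _RHYTHMS:
        tone_sum = _tone_band_sum(f0, band, cfg.fs, n_samp)
        amps[(band.name, f0)] = {}
        for src in CLASS_SOURCES.values():
            ci = montage.index(src)
            bg = np.mean([band_power(welch_psd(noise[k, ci], wcfg), band)
                          for k in range(n_cal)])
            amps[(band.name, f0)][src] = np.sqrt(cfg.snr * bg / tone_sum)

    t = np.arange(n_samp) / cfg.fs
    mi = (t >= _MI_INTERVAL[0]) & (t < _MI_INTERVAL[1])
    depths = {MU.name: cfg.erd_depth,
              BETA.name: cfg.beta_erd_depth if cfg.beta_erd_depth is not None
              else cfg.erd_depth}

    data = noise
    src_idx = {s: montage.index(s) for s in CLASS_SOURCES.values()}
    spread = {s: mix[:, src_idx[s]] for s in CLASS_SOURCES.values()}
    for n_i, label in enumerate(labels):
        attenuated = CLASS_SOURCES[label]
        for (bname, f0), per_src in amps.items():
            for src, amp in per_src.items():
                phase = rng.uniform(0, 2 * np.pi)
                osc = amp * np.sin(2 * np.pi * f0 * t + phase)
                if src == attenuated:
                    env = np.where(mi, 1.0 - depths[bname], 1.0)
                    osc = osc * env
                data[n_i] += spread[src][:, None] * osc[None, :]

    events = [(k * n_samp, str(labels[k])) for k in range(n_trials)]
    rec = RawRecording(data=np.concatenate(data, axis=-1).reshape(c, -1),
                       fs=cfg.fs, montage=montage, events=events)
    return rec


def planted_truth(cfg: SimConfig) -> dict[str, str]:
    """Ground-truth discriminative source electrode per class."""
    return {cls: CLASS_SOURCES[cls] for cls in cfg.classes}
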