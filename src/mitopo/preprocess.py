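"""Band-pass filtering, epoching into trials, and sliding-window segmentation.

Motor-imagery trials last ``T = 7`` s (cue at 0 s, imagery between 3 and 6 s)
sampled at 250 Hz.  Filtering is zero-phase (forward-backward Butterworth,
so the effective order doubles) and is applied to the continuous record
*before* cutting epochs so that filter transients fall outside the trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .montage import Montage

__all__ = [
    "RawRecording",
    "TrialEpoch",
    "WindowSet",
    "bandpass",
    "epoch",
    "sliding_windows",
    "select_channels",
]

TRIAL_SECONDS = 7.0
MI_WINDOW = (3.0, 6.0)  # imagery interval within a trial


@dataclass
class RawRecording:
    """Continuous multichannel EEG with montage, sampling rate and events."""

    data: np.ndarray          # channels x samples, microvolts
    fs: float                 # Hz
    montage: Montage
    events: list              # (onset_sample, class_label)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.montage):
            raise ValueError(
                f"channel count {self.data.shape[0]} != montage size {len(self.montage)}"
            )
        for onset, _ in self.events:
            if not (0 <= onset < self.data.shape[1]):
                raise ValueError(f"event onset {onset} outside record")


@dataclass
class TrialEpoch:
    """One 7 s trial, time-locked to the trial start (cue at 0 s)."""

    data: np.ndarray          # channels x samples
    label: object             # class id
    fs: float

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class WindowSet:
    """Sliding windows cut from one trial."""

    windows: np.ndarray       # n_windows x channels x window_samples
    starts: np.ndarray        # seconds
    tau: float
    step: float


def bandpass(rec: RawRecording, low: float = 8.0, high: float = 30.0,
             order: int = 5) -> RawRecording:
    """Zero-phase Butterworth band-pass, channel-wise; shape preserved."""
    if not (0.0 < low < high < rec.fs / 2.0):
        raise ValueError(f"invalid band edges ({low}, {high}) for fs={rec.fs}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=-1)
    return replace(rec, data=filtered)


def epoch(rec: RawRecording, duration: float = TRIAL_SECONDS) -> list[TrialEpoch]:
    """Cut one fixed-length epoch per event; out-of-bounds epochs are skipped."""
    if not rec.events:
        raise ValueError("recording has no events")
    n = int(round(duration * rec.fs))
    epochs, skipped = [], 0
    for onset, label in rec.events:
        if onset + n > rec.data.shape[1]:
            skipped += 1
            continue
        epochs.append(TrialEpoch(rec.data[:, onset:onset + n].copy(), label, rec.fs))
    if skipped:
        warnings.warn(f"skipped {skipped} event(s) whose epoch exceeded the record",
                      stacklevel=2)
    return epochs


def sliding_windows(trial: TrialEpoch, tau: float = 2.0, step: float = 1.0,
                    t_max: float = 6.0) -> WindowSet:
    """Segment a trial into overlapping windows.

    Windows start at 0 and advance by ``step`` while fitting inside
    ``max(t_max, tau)`` seconds; with the defaults (7 s trial, tau=2, step=1,
    t_max=6) this yields the 5 segments covering 0-6 s, the last second of
    the trial being discarded.
    """
    n_total = trial.data.shape[1]
    tau_s = int(round(tau * trial.fs))
    step_s = int(round(step * trial.fs))
    if tau_s > n_total:
        raise ValueError(f"window length {tau} s exceeds trial duration")
    if step_s <= 0:
        raise ValueError("step must be positive")
    used = min(n_total, max(int(round(t_max * trial.fs)), tau_s))
    n_win = (used - tau_s) // step_s + 1
    starts_s = np.arange(n_win) * step_s
    windows = np.stack([trial.data[:, s:s + tau_s] for s in starts_s])
    return WindowSet(windows=windows, starts=starts_s / trial.fs, tau=tau, step=step)


def select_channels(trial: TrialEpoch, indices: list[int]) -> TrialEpoch:
    """A copy of the trial restricted to the given channel indices."""
    return TrialEpoch(trial.data[np.asarray(indices, dtype=int)].copy(),
                      trial.label, trial.fs)
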