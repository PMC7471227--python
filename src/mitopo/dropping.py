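"""Spatial dropping of electrodes.

Two strategies sharpen the spatial interpretation of the classifier:

* ``sensorimotor_prior`` — restrict the montage to the 10 motor-cortex
  electrodes *before* any training (subject independent);
* ``relevance_threshold`` — after an initial fit, keep only electrodes whose
  relevance score (max over bands) reaches a quantile threshold, then retrain
  the full pipeline on the retained subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import Montage, sensorimotor_subset
from .preprocess import TrialEpoch, select_channels

__all__ = ["DroppingSpec", "apply_prior_dropping", "threshold_electrodes",
           "rerun_with_subset"]


@dataclass(frozen=True)
class DroppingSpec:
    strategy: str = "none"        # none | sensorimotor_prior | relevance_threshold
    quantile: float = 0.75
    min_electrodes: int = 4

    def __post_init__(self) -> None:
        if self.strategy not in ("none", "sensorimotor_prior", "relevance_threshold"):
            raise ValueError(f"unknown dropping strategy {self.strategy!r}")
        if not 0.0 <= self.quantile < 1.0:
            raise ValueError("quantile must be in [0, 1)")
        if self.min_electrodes < 2:
            raise ValueError("must keep at least 2 electrodes")


def apply_prior_dropping(trials: list[TrialEpoch], montage: Montage
                         ) -> tuple[list[TrialEpoch], Montage]:
    """Restrict trials and montage to the sensorimotor subset (idempotent)."""
    sub = sensorimotor_subset(montage)
    idx = [montage.index(lb) for lb in sub.labels]
    return [select_channels(t, idx) for t in trials], sub


def threshold_electrodes(scores: np.ndarray, labels: list[str],
                         spec: DroppingSpec) -> list[str]:
    """Electrodes whose max-over-bands score reaches the quantile threshold.

    ``scores`` is (n_bands, C) or (C,).  Ties at the threshold are kept;
    if fewer than ``spec.min_electrodes`` survive, the rank order fills the
    set back up to the minimum.
    """
    s = np.asarray(scores, dtype=float)
    if np.any(s < 0):
        raise ValueError("relevance scores must be nonnegative")
    agg = s.max(axis=0) if s.ndim == 2 else s
    if agg.shape != (len(labels),):
        raise ValueError("scores and labels disagree in electrode count")
    thr = np.quantile(agg, spec.quantile)
    retained = [lb for lb, v in zip(labels, agg) if v >= thr]
    if len(retained) < spec.min_electrodes:
        order = np.argsort(agg)[::-1][:spec.min_electrodes]
        retained = [labels[i] for i in sorted(order)]
    return retained


def rerun_with_subset(trials: list[TrialEpoch], montage: Montage,
                      retained: list[str], run_cfg):
    """Re-execute features -> topomaps -> CV on the retained electrodes.

    ``run_cfg`` is a :class:`mitopo.pipeline.RunConfig`; returns the
    per-window CV results of the reduced pipeline.
    """
    from .pipeline import evaluate_trials  # deferred: pipeline imports us

    if len(retained) < 2:
        raise ValueError("need at least 2 retained electrodes")
    sub = montage.subset(retained)
    idx = [montage.index(lb) for lb in sub.labels]
    sub_trials = [select_channels(t, idx) for t in trials]
    return evaluate_trials(sub_trials, sub, run_cfg)
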