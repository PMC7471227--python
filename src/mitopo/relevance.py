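"""Back-projection of learned dense-layer weights into scalp relevance maps.

After training, each row of the first dense-layer weight matrix W
(flatten_dim x h_u) describes how strongly one pooled-map feature drives the
hidden representation.  The feature's relevance is the l_p norm of its row
(p=2 by default).  The relevance vector is unflattened back into the
per-(band, kernel) 21x28 pooled maps, averaged over kernels, bilinearly
upsampled to the 42x56 image grid, and masked to the head disk.  Averaging
the map over a small pixel neighbourhood of each electrode's projected
position gives a per-electrode contribution score, the quantity thresholded
by the data-driven dropping strategy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .features import Band
from .model import TrainedModel
from .montage import Montage
from .topomap import IMAGE_SHAPE, electrode_pixels

__all__ = ["RelevanceMap", "ElectrodeContribution", "relevance_vector",
           "unflatten", "reconstruct_map", "electrode_contribution",
           "unmix_electrode_contribution", "relevance_from_model"]


@dataclass
class RelevanceMap:
    """An upsampled, kernel-averaged relevance image for one band."""

    theta: np.ndarray             # rows x cols, nonnegative
    mask: np.ndarray
    band: Band | None = None

    def __post_init__(self) -> None:
        if np.any(self.theta < -1e-12):
            raise ValueError("relevance map must be nonnegative")
        if np.any(self.theta[~self.mask] != 0.0):
            raise ValueError("off-mask relevance must be 0")


@dataclass
class ElectrodeContribution:
    scores: np.ndarray            # per electrode, montage order
    labels: list
    band: Band | None = None

    def top(self, k: int) -> list:
        order = np.argsort(self.scores)[::-1]
        return [self.labels[i] for i in order[:k]]


def relevance_vector(w: np.ndarray, p: float = 2.0) -> np.ndarray:
    """Per-row l_p norm of the dense weight matrix (generalized mean)."""
    if p <= 0:
        raise ValueError("norm order p must be positive")
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("weight matrix contains non-finite entries")
    return (np.abs(w) ** p).sum(axis=1) ** (1.0 / p)


def unflatten(rho: np.ndarray, n_kernels: int, n_bands: int,
              g: int = 21, g2: int = 28) -> np.ndarray:
    """Inverse of the model's flatten: (D,) -> (n_bands, n_kernels, g, g2).

    The model flattens band-major, then kernel, then row-major pixels; this
    is its exact round-trip inverse.
    """
    rho = np.asarray(rho)
    d = n_bands * n_kernels * g * g2
    if rho.shape != (d,):
        raise ValueError(f"relevance length {rho.shape} != "
                         f"{n_bands}*{n_kernels}*{g}*{g2} = {d}")
    return rho.reshape(n_bands, n_kernels, g, g2)


def _upsample_bilinear(m: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    g, g2 = m.shape
    interp = RegularGridInterpolator(
        (np.arange(g), np.arange(g2)), m, method="linear")
    rr = np.linspace(0, g - 1, shape[0])
    cc = np.linspace(0, g2 - 1, shape[1])
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(grid)


def reconstruct_map(kernel_maps: np.ndarray, mask: np.ndarray,
                    band: Band | None = None) -> RelevanceMap:
    """Average pooled maps over kernels, upsample to the image grid, mask."""
    km = np.asarray(kernel_maps, dtype=float)
    if km.ndim == 2:
        km = km[None]
    if km.shape[0] < 1:
        raise ValueError("need at least one kernel map")
    mean_map = km.mean(axis=0)
    up = _upsample_bilinear(mean_map, mask.shape)
    up[~mask] = 0.0
    return RelevanceMap(theta=np.maximum(up, 0.0), mask=mask, band=band)


def electrode_contribution(rmap: RelevanceMap, montage: Montage,
                           radius: float = 2.0) -> ElectrodeContribution:
    """Mean relevance in a fixed-radius pixel disk around each electrode."""
    shape = rmap.theta.shape
    pix = electrode_pixels(montage, shape)
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    scores = np.empty(len(montage))
    for i, (r, c) in enumerate(pix):
        if not (0 <= r <= shape[0] - 1 and 0 <= c <= shape[1] - 1):
            raise ValueError(
                f"electrode {montage.labels[i]!r} projects off the grid")
        near = (rows - r) ** 2 + (cols - c) ** 2 <= radius ** 2
        scores[i] = rmap.theta[near].mean()
    return ElectrodeContribution(scores=scores, labels=montage.labels,
                                 band=rmap.band)


def unmix_electrode_contribution(rmap: RelevanceMap, montage: Montage,
                                 radius: float = 2.0) -> ElectrodeContribution:
    """Electrode scores by deconvolving the spline point-spread.

    The rendered bump of a single electrode is the spherical-spline kernel
    centred at it, so neighbouring electrodes always sit on each other's
    shoulders and raw neighbourhood means cannot separate a source from its
    immediate neighbour.  This scorer solves a small nonnegative
    least-squares problem: find electrode weights (plus a constant
    background) whose unit-bump responses, measured with the same
    neighbourhood-mean operator, best reproduce the observed per-electrode
    means.  The result attributes each bump to the electrode that generated
    it.
    """
    from scipy.optimize import nnls

    from .topomap import TopomapRenderer

    observed = electrode_contribution(rmap, montage, radius=radius).scores
    renderer = TopomapRenderer(montage, shape=rmap.theta.shape)
    response = np.empty((len(montage), len(montage)))
    for j in range(len(montage)):
        unit = np.zeros(len(montage))
        unit[j] = 1.0
        bump = np.maximum(renderer.render_batch(unit)[0], 0.0) * rmap.mask
        response[:, j] = electrode_contribution(
            RelevanceMap(theta=bump, mask=rmap.mask, band=rmap.band),
            montage, radius=radius).scores
    design = np.concatenate([response, np.ones((len(montage), 1))], axis=1)
    weights, _ = nnls(design, observed)
    return ElectrodeContribution(scores=weights[:-1], labels=montage.labels,
                                 band=rmap.band)


def relevance_from_model(model: TrainedModel, montage: Montage,
                         mask: np.ndarray, bands: tuple[Band, ...] | None = None,
                         p: float = 2.0, radius: float = 2.0):
    """Relevance maps and electrode scores per band from a trained model.

    Returns (maps, scores_df): one RelevanceMap per input branch and a tidy
    table (electrode, band, score).
    """
    cfg = model.cfg
    rho = relevance_vector(model.dense_weights, p=p)
    g, g2 = cfg.pooled_shape
    groups = cfg.map_groups   # one map per band branch; one shared map in
    per_band = unflatten(rho, cfg.n_kernels, groups, g, g2)  # channels mode
    if bands is not None and cfg.band_mode == "branches" \
            and len(bands) != cfg.n_bands:
        raise ValueError("band list must match the model's branch count")
    maps, rows = [], []
    for b in range(groups):
        band = bands[b] if bands is not None and cfg.band_mode == "branches" \
            else None
        rmap = reconstruct_map(per_band[b], mask, band=band)
        maps.append(rmap)
        contrib = electrode_contribution(rmap, montage, radius=radius)
        for lbl, sc in zip(contrib.labels, contrib.scores):
            rows.append({"electrode": lbl,
                         "band": band.name if band else str(b),
                         "score": sc})
    return maps, pd.DataFrame(rows)
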