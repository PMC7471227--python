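"""Spherical-spline interpolation of electrode values onto a 42x56 scalp image.

Electrode contribution vectors are interpolated on the sphere with
Perrin-style spherical splines (order m=4, Legendre series truncated at 50
terms, tiny Tikhonov ridge 1e-10 to guard against coincident electrodes) and rendered on a fixed 42-row by
56-column pixel grid.  The head disk is inscribed and centred (radius 20.5
pixels); each pixel inside the disk is mapped back to the sphere by the
inverse azimuthal equidistant projection and evaluated there.  Pixels outside
the disk are meaningless for the scalp field and are set to exactly 0, so the
CNN always receives a fixed-size rectangular input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre
from scipy.linalg import lu_factor, lu_solve

from .features import Band, ContributionTensor
from .montage import Montage

__all__ = [
    "SplineModel", "TopoImage", "TopomapRenderer",
    "fit_spherical_spline", "render_topomap", "image_stack", "topomap_arrays",
    "head_grid", "electrode_pixels", "IMAGE_SHAPE",
]

IMAGE_SHAPE = (42, 56)  # rows x columns
#: Polar angle (as a fraction of 90 deg) at the head-disk rim.  The montage
#: only reaches 54 deg from the vertex; drawing the disk out to 72 deg
#: (0.8) spreads the electrodes across ~80% of the image radius instead of
#: crowding them in the middle, so neighbouring electrodes stay separable
#: at the 42x56 resolution.  1.0 would put the equator (ear line) on the rim.
EXTENT = 0.8
_N_TERMS = 50


@lru_cache(maxsize=8)
def _legendre_coeffs(order: int, n_terms: int = _N_TERMS) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    c = (2.0 * n + 1.0) / ((n * (n + 1.0)) ** order * 4.0 * np.pi)
    return np.concatenate([[0.0], c])


def _g(cosang: np.ndarray, order: int) -> np.ndarray:
    """Spline kernel g_m(cos angle) as a truncated Legendre series."""
    return legendre.legval(np.clip(cosang, -1.0, 1.0), _legendre_coeffs(order))


@dataclass
class SplineModel:
    """A fitted spherical spline: per-electrode weights plus a constant term."""

    coefficients: np.ndarray      # length C
    constant: float
    montage: Montage
    order: int = 4
    regularization: float = 1e-10

    def evaluate(self, points3d: np.ndarray) -> np.ndarray:
        """Spline values at unit-sphere points, shape (n, 3) -> (n,)."""
        p = np.asarray(points3d, dtype=float)
        cosang = p @ self.montage.positions3d.T
        return _g(cosang, self.order) @ self.coefficients + self.constant


@dataclass
class TopoImage:
    """A rendered scalp image with its head-disk validity mask."""

    grid: np.ndarray              # rows x cols
    mask: np.ndarray              # boolean, same shape
    band: Band | None = None
    window: int | None = None
    trial: int | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.grid[self.mask])):
            raise ValueError("topomap contains non-finite values on the head disk")
        if np.any(self.grid[~self.mask] != 0.0):
            raise ValueError("off-disk pixels must be exactly 0")


def _spline_system(montage: Montage, order: int, reg: float):
    e = montage.positions3d
    c = len(montage)
    g = _g(e @ e.T, order) + reg * np.eye(c)
    a = np.zeros((c + 1, c + 1))
    a[:c, :c] = g
    a[:c, c] = 1.0
    a[c, :c] = 1.0
    return a


def fit_spherical_spline(montage: Montage, values: np.ndarray, order: int = 4,
                         regularization: float = 1e-10) -> SplineModel:
    """Solve the spline system for one electrode-value vector.

    Interpolation is exact at the electrode sites up to the regularization
    tolerance; a constant input is reproduced exactly everywhere.
    """
    v = np.asarray(values, dtype=float)
    if v.shape != (len(montage),):
        raise ValueError(f"values length {v.shape} != electrode count {len(montage)}")
    a = _spline_system(montage, order, regularization)
    rhs = np.concatenate([v, [0.0]])
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular spline system (coincident electrodes?); "
            "try increasing the regularization") from err
    return SplineModel(coefficients=sol[:-1], constant=float(sol[-1]),
                       montage=montage, order=order, regularization=regularization)


def head_grid(shape: tuple[int, int] = IMAGE_SHAPE):
    """Pixel-centre disk coordinates and head mask for the rendering grid.

    Row 0 is the top of the image (nose, +y); the column axis increases to
    the right (+x).  Coordinates are in disk units (rim = 1); the rim sits
    at polar angle ``EXTENT`` * 90 deg on the scalp.  Returns (x, y, mask)
    arrays of the given shape.
    """
    rows, cols = shape
    radius = (min(rows, cols) - 1) / 2.0
    i = np.arange(rows)[:, None]
    j = np.arange(cols)[None, :]
    x = (j - (cols - 1) / 2.0) / radius
    y = ((rows - 1) / 2.0 - i) / radius
    mask = x**2 + y**2 <= 1.0 + 1e-12
    return np.broadcast_to(x, shape).copy(), np.broadcast_to(y, shape).copy(), mask


def _sphere_points(x: np.ndarray, y: np.ndarray,
                   extent: float | None = None) -> np.ndarray:
    """Inverse azimuthal equidistant projection of disk points to the sphere."""
    if extent is None:
        extent = EXTENT
    r = np.hypot(x, y)
    theta = r * extent * np.pi / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(r > 0, x / r, 0.0)
        uy = np.where(r > 0, y / r, 0.0)
    return np.stack([np.sin(theta) * ux, np.sin(theta) * uy, np.cos(theta)], axis=-1)


def electrode_pixels(montage: Montage, shape: tuple[int, int] = IMAGE_SHAPE) -> np.ndarray:
    """Fractional (row, col) pixel positions of the electrodes on the grid."""
    rows, cols = shape
    radius = (min(rows, cols) - 1) / 2.0
    p2 = montage.positions2d / EXTENT   # disk units: rim = EXTENT * 90 deg
    if np.any(np.hypot(p2[:, 0], p2[:, 1]) > 1.0):
        raise ValueError("electrode outside the rendering disk; reduce EXTENT")
    row = (rows - 1) / 2.0 - p2[:, 1] * radius
    col = (cols - 1) / 2.0 + p2[:, 0] * radius
    return np.stack([row, col], axis=1)


class TopomapRenderer:
    """Batch renderer: caches the spline system and pixel kernel matrix."""

    def __init__(self, montage: Montage, shape: tuple[int, int] = IMAGE_SHAPE,
                 order: int = 4, regularization: float = 1e-10):
        self.montage = montage
        self.shape = shape
        self.order = order
        self.regularization = regularization
        self._lu = lu_factor(_spline_system(montage, order, regularization))
        x, y, self.mask = head_grid(shape)
        pts = _sphere_points(x[self.mask], y[self.mask])
        self._gpix = _g(pts @ montage.positions3d.T, order)

    def render_batch(self, values: np.ndarray) -> np.ndarray:
        """Render many electrode-value vectors; (n, C) -> (n, rows, cols)."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        rhs = np.concatenate([v, np.zeros((v.shape[0], 1))], axis=1).T
        sol = lu_solve(self._lu, rhs)                       # (C+1, n)
        coef, const = sol[:-1], sol[-1]
        pix = self._gpix @ coef + const                     # (n_maskpix, n)
        out = np.zeros((v.shape[0],) + self.shape)
        out[:, self.mask] = pix.T
        return out


def render_topomap(spline: SplineModel, s: int = IMAGE_SHAPE[0],
                   s2: int = IMAGE_SHAPE[1]) -> TopoImage:
    """Evaluate a fitted spline on the head-disk grid; off-disk pixels are 0."""
    x, y, mask = head_grid((s, s2))
    grid = np.zeros((s, s2))
    grid[mask] = spline.evaluate(_sphere_points(x[mask], y[mask]))
    return TopoImage(grid=grid, mask=mask)


def _minmax_on_mask(grid: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = grid[mask]
    lo, hi = vals.min(), vals.max()
    out = np.zeros_like(grid)
    out[mask] = (vals - lo) / (hi - lo) if hi > lo else 0.0
    return out


def image_stack(contributions: ContributionTensor, montage: Montage,
                normalize: bool = True,
                shape: tuple[int, int] = IMAGE_SHAPE) -> list[TopoImage]:
    """One TopoImage per (trial, window, band) contribution vector."""
    arr, mask = topomap_arrays(contributions, montage, normalize=normalize,
                               shape=shape)
    images = []
    n_tr, n_win, n_bands = arr.shape[:3]
    for r in range(n_tr):
        for m in range(n_win):
            for b in range(n_bands):
                images.append(TopoImage(grid=arr[r, m, b], mask=mask,
                                        band=contributions.bands[b],
                                        window=m, trial=r))
    return images


def topomap_arrays(contributions: ContributionTensor, montage: Montage,
                   normalize: bool | str = "minmax",
                   shape: tuple[int, int] = IMAGE_SHAPE):
    """Render all contribution vectors; returns (array, mask).

    The array has shape (n_trials, n_windows, n_bands, rows, cols).
    ``normalize`` selects the intensity scaling:

    * ``"minmax"`` (or True) — each image min-max scaled to [0, 1] on the
      head disk.  Comparable across subjects, but the per-image normalizer
      couples every pixel to the image extremes, which blurs *where* class
      information lives;
    * ``"global"`` — one scale per band (division by the dataset-wide max
      absolute value), preserving the spatial localization of between-trial
      differences; preferred when relevance maps are the goal;
    * ``False``/``None`` — raw band-power units.
    """
    vals = contributions.values
    if vals.shape[-1] != len(montage):
        raise ValueError("contribution length does not match montage size")
    if normalize is True:
        normalize = "minmax"
    if normalize not in ("minmax", "global", False, None):
        raise ValueError("normalize must be 'minmax', 'global', or falsy")
    renderer = TopomapRenderer(montage, shape=shape)
    flat = vals.reshape(-1, vals.shape[-1])
    imgs = renderer.render_batch(flat)
    if normalize == "minmax":
        on = imgs[:, renderer.mask]
        lo = on.min(axis=1, keepdims=True)
        hi = on.max(axis=1, keepdims=True)
        rng = np.where(hi > lo, hi - lo, 1.0)
        imgs[:, renderer.mask] = np.where(hi > lo, (on - lo) / rng, 0.0)
    imgs = imgs.reshape(vals.shape[:-1] + shape)
    if normalize == "global":
        scale = np.abs(imgs).max(axis=(0, 1, 3, 4), keepdims=True)
        imgs = imgs / np.where(scale > 0, scale, 1.0)
    return imgs, renderer.mask
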