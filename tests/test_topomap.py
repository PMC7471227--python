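"""Spherical-spline fitting and topographic rendering."""

import numpy as np
import pytest

from mitopo.features import MU, SCENARIO_BANDS, contribution_tensor
from mitopo.montage import Electrode, Montage, project_azimuthal
from mitopo.preprocess import TrialEpoch
from mitopo.topomap import (IMAGE_SHAPE, TopomapRenderer, electrode_pixels,
                            fit_spherical_spline, head_grid, image_stack,
                            render_topomap, topomap_arrays, _g)


@pytest.fixture(scope="module")
def toy_montage():
    pts = [("A", [0, 0, 1]), ("B", [0.8, 0, 0.6]),
           ("C", [-0.8, 0, 0.6]), ("D", [0, 0.8, 0.6])]
    return project_azimuthal(
        Montage(tuple(Electrode(l, np.array(p, float)) for l, p in pts)))


class TestSplineFit:
    def test_constant_values_reproduced_everywhere(self, montage22):
        sp = fit_spherical_spline(montage22, np.full(22, 3.7))
        rng = np.random.default_rng(0)
        pts = rng.standard_normal((100, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        np.testing.assert_allclose(sp.evaluate(pts), 3.7, atol=1e-6)

    def test_interpolation_exact_at_electrodes(self, montage22):
        rng = np.random.default_rng(1)
        v = 1.0 + rng.random(22)  # bounded away from 0 for relative error
        sp = fit_spherical_spline(montage22, v)
        at = sp.evaluate(montage22.positions3d)
        assert np.max(np.abs((at - v) / v)) < 1e-3

    def test_matches_dense_linear_algebra_oracle(self, toy_montage):
        # independent oracle: assemble and solve the full system directly
        v = np.array([1.0, 0.0, 0.0, 0.0])
        order, reg = 4, 1e-10
        e = toy_montage.positions3d
        g = _g(e @ e.T, order) + reg * np.eye(4)
        a = np.block([[g, np.ones((4, 1))], [np.ones((1, 4)), np.zeros((1, 1))]])
        expected = np.linalg.lstsq(a, np.concatenate([v, [0.0]]), rcond=None)[0]
        sp = fit_spherical_spline(toy_montage, v, order=order, regularization=reg)
        np.testing.assert_allclose(sp.coefficients, expected[:-1], atol=1e-8)
        np.testing.assert_allclose(sp.constant, expected[-1], atol=1e-8)

    def test_wrong_length_rejected(self, montage22):
        with pytest.raises(ValueError):
            fit_spherical_spline(montage22, np.ones(5))


class TestRendering:
    def test_constant_spline_renders_constant_on_mask(self, montage22):
        img = render_topomap(fit_spherical_spline(montage22, np.full(22, 2.0)))
        assert img.grid.shape == IMAGE_SHAPE
        np.testing.assert_allclose(img.grid[img.mask], 2.0, atol=1e-6)
        assert np.all(img.grid[~img.mask] == 0.0)

    def test_mask_depends_only_on_geometry(self, montage22):
        _, _, mask = head_grid(IMAGE_SHAPE)
        img = render_topomap(fit_spherical_spline(montage22, np.arange(22.0)))
        np.testing.assert_array_equal(img.mask, mask)

    def test_planted_peak_lands_near_electrode(self, montage22):
        v = np.zeros(22)
        v[montage22.index("C3")] = 1.0
        img = render_topomap(fit_spherical_spline(montage22, v))
        peak = np.unravel_index(np.argmax(img.grid), img.grid.shape)
        target = electrode_pixels(montage22)[montage22.index("C3")]
        assert np.hypot(peak[0] - target[0], peak[1] - target[1]) <= 3.0

    def test_mirror_symmetry_of_homologue_swap(self, montage22):
        rng = np.random.default_rng(2)
        v = rng.random(22)
        swapped = v.copy()
        for a, b in [("C3", "C4"), ("C5", "C6"), ("C1", "C2"), ("FC3", "FC4"),
                     ("FC1", "FC2"), ("CP3", "CP4"), ("CP1", "CP2"),
                     ("P1", "P2")]:
            ia, ib = montage22.index(a), montage22.index(b)
            swapped[ia], swapped[ib] = v[ib], v[ia]
        img = render_topomap(fit_spherical_spline(montage22, v)).grid
        mirror = render_topomap(fit_spherical_spline(montage22, swapped)).grid
        np.testing.assert_allclose(img, mirror[:, ::-1], atol=1e-6)

    def test_raising_electrode_value_raises_its_pixel(self, montage22):
        rng = np.random.default_rng(3)
        v = rng.random(22)
        i = montage22.index("Cz")
        r, c = np.round(electrode_pixels(montage22)[i]).astype(int)
        lo = render_topomap(fit_spherical_spline(montage22, v)).grid[r, c]
        v[i] += 1.0
        hi = render_topomap(fit_spherical_spline(montage22, v)).grid[r, c]
        assert hi > lo

    def test_batch_renderer_matches_single_renders(self, montage22):
        rng = np.random.default_rng(4)
        v = rng.random((3, 22))
        batch = TopomapRenderer(montage22).render_batch(v)
        for k in range(3):
            single = render_topomap(fit_spherical_spline(montage22, v[k]))
            np.testing.assert_allclose(batch[k], single.grid, atol=1e-8)


class TestImageStack:
    def _tensor(self, n_trials=2):
        rng = np.random.default_rng(5)
        trials = [TrialEpoch(rng.standard_normal((22, 1750)), "left", 250.0)
                  for _ in range(n_trials)]
        return contribution_tensor(trials, "psd", SCENARIO_BANDS["D"])

    def test_one_image_per_vector(self, montage22):
        tensor = self._tensor()
        images = image_stack(tensor, montage22)
        assert len(images) == 2 * 5 * 4
        assert all(im.grid.shape == IMAGE_SHAPE for im in images)

    def test_minmax_normalization_bounds(self, montage22):
        arr, mask = topomap_arrays(self._tensor(), montage22,
                                   normalize="minmax")
        on = arr[..., mask]
        assert on.min() >= 0.0 and on.max() <= 1.0

    def test_identical_vectors_identical_images(self, montage22):
        tensor = self._tensor(1)
        tensor.values[0, 1] = tensor.values[0, 0]
        arr, _ = topomap_arrays(tensor, montage22, normalize=False)
        np.testing.assert_array_equal(arr[0, 0], arr[0, 1])

    def test_global_normalization_preserves_relative_scale(self, montage22):
        tensor = self._tensor(1)
        raw, _ = topomap_arrays(tensor, montage22, normalize=False)
        glob, mask = topomap_arrays(tensor, montage22, normalize="global")
        assert np.abs(glob).max() <= 1.0 + 1e-12
        k = np.abs(glob[0, 0, 0][mask]).sum() / np.abs(raw[0, 0, 0][mask]).sum()
        np.testing.assert_allclose(glob[0, 1, 0][mask],
                                   k * raw[0, 1, 0][mask], atol=1e-9)
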