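import numpy as np
import pytest

from bbbq import core_io, synthetic, tfm
from conftest import bead_pair_with_uniform_shift

GEL = tfm.GelProperties(5000.0, 0.45)
PS = 0.645


def disp_field(u, v, spacing=1.0):
    ny, nx = u.shape
    return tfm.DisplacementField(np.arange(nx) * spacing,
                                 np.arange(ny) * spacing, u, v)


class TestPiv:
    def test_ref_vs_ref_zero_field(self):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(8, 119, 350),
                               rng.uniform(8, 119, 350)])
        img = synthetic._render_beads((128, 128), pos, 1.5)
        f = tfm.piv(img, img, window_px=32, pixel_size=1.0)
        assert np.abs(f.u).max() < 1e-9
        assert np.abs(f.v).max() < 1e-9

    def test_integer_shift_recovered_exactly(self):
        rng = np.random.default_rng(0)
        pos = np.column_stack([rng.uniform(8, 119, 350),
                               rng.uniform(8, 119, 350)])
        img = synthetic._render_beads((128, 128), pos, 1.5)
        f = tfm.piv(img, np.roll(img, 3, axis=1), window_px=32,
                    pixel_size=1.0)
        # interior nodes: boundary windows straddle the wrap seam
        err = np.hypot(f.u - 3.0, f.v)[1:-1, 1:-1]
        assert err.max() < 0.05

    def test_physical_units_scale_with_pixel_size(self):
        rng = np.random.default_rng(1)
        pos = np.column_stack([rng.uniform(8, 119, 350),
                               rng.uniform(8, 119, 350)])
        img = synthetic._render_beads((128, 128), pos, 1.5)
        f = tfm.piv(img, np.roll(img, 3, axis=1), window_px=32,
                    pixel_size=PS)
        assert np.median(f.u) == pytest.approx(3 * PS, abs=0.05 * PS)

    def test_vertical_shift_sign_convention(self):
        # beads moved down-screen (rows +2) mean v = -2 (v is up-positive)
        rng = np.random.default_rng(2)
        pos = np.column_stack([rng.uniform(8, 119, 350),
                               rng.uniform(8, 119, 350)])
        img = synthetic._render_beads((128, 128), pos, 1.5)
        f = tfm.piv(img, np.roll(img, 2, axis=0), window_px=32,
                    pixel_size=1.0)
        assert np.median(f.v) == pytest.approx(-2.0, abs=0.05)

    def test_subpixel_shift_rmse_bound(self):
        sq = []
        for s in range(50):
            ref, moved = bead_pair_with_uniform_shift((0.5, 0.0), seed=s)
            f = tfm.piv(ref, moved, window_px=32, pixel_size=1.0)
            sq.append(np.mean((f.u[1:-1, 1:-1] - 0.5) ** 2
                              + f.v[1:-1, 1:-1] ** 2))
        assert np.sqrt(np.mean(sq)) < 0.2

    def test_featureless_image_rejected(self):
        flat = np.zeros((128, 128))
        with pytest.raises(ValueError):
            tfm.piv(flat, flat, window_px=32)

    def test_window_must_be_power_of_two(self):
        img = np.random.default_rng(0).normal(size=(64, 64))
        with pytest.raises(ValueError):
            tfm.piv(img, img, window_px=24)

    def test_recovery_degrades_as_density_decreases(self):
        rmse = []
        for dens in (0.02, 0.01, 0.005, 0.002):
            sq = []
            for s in range(6):
                ref, moved = bead_pair_with_uniform_shift(
                    (0.5, 0.3), seed=100 + s, density=dens)
                f = tfm.piv(ref, moved, window_px=32, pixel_size=1.0)
                sq.append(np.mean((f.u[1:-1, 1:-1] - 0.5) ** 2
                                  + (f.v[1:-1, 1:-1] + 0.3) ** 2))
            rmse.append(np.sqrt(np.mean(sq)))
        assert all(lo < hi for lo, hi in zip(rmse, rmse[1:]))


class TestReconstruction:
    def test_zero_displacement_zero_traction(self):
        f = disp_field(np.zeros((16, 16)), np.zeros((16, 16)))
        t = tfm.reconstruct_traction(f, GEL)
        assert np.all(t.tx == 0) and np.all(t.ty == 0)

    def test_forward_inverse_consistency_on_periodic_grid(self):
        tx, ty = synthetic.make_dipole_traction((64, 64), 2.0,
                                                separation_um=40.0,
                                                magnitude_pa=150.0,
                                                sigma_um=10.0)
        u, v = tfm.forward_displacement(tx, ty, GEL, 2.0, pad_factor=1)
        rec = tfm.reconstruct_traction(disp_field(u, v, 2.0), GEL,
                                       lambda_reg=0.0)
        np.testing.assert_allclose(rec.tx, tx, atol=1e-6 * np.abs(tx).max())
        np.testing.assert_allclose(rec.ty, ty, atol=1e-6 * np.abs(tx).max())

    def test_doubling_modulus_doubles_traction_exactly(self):
        tx, ty = synthetic.make_dipole_traction((32, 32), 4.0,
                                                separation_um=40.0,
                                                magnitude_pa=150.0,
                                                sigma_um=12.0)
        u, v = tfm.forward_displacement(tx, ty, GEL, 4.0)
        f = disp_field(u, v, 4.0)
        t1 = tfm.reconstruct_traction(f, tfm.GelProperties(5000.0, 0.45),
                                      lambda_reg=0.0)
        t2 = tfm.reconstruct_traction(f, tfm.GelProperties(10000.0, 0.45),
                                      lambda_reg=0.0)
        np.testing.assert_allclose(t2.tx, 2 * t1.tx, rtol=1e-10)
        np.testing.assert_allclose(t2.ty, 2 * t1.ty, rtol=1e-10)

    def test_grid_too_small_rejected(self):
        f = disp_field(np.zeros((4, 4)), np.zeros((4, 4)))
        with pytest.raises(ValueError):
            tfm.reconstruct_traction(f, GEL)

    def test_rotating_pair_rotates_recovered_vectors(self):
        tx, ty = synthetic.make_dipole_traction((192, 192), PS,
                                                separation_um=40.0,
                                                magnitude_pa=200.0,
                                                sigma_um=8.0)
        ref, dfm, _ = synthetic.gen_bead_pair(tx, ty, GEL, n_beads=2500,
                                              image_shape=(192, 192),
                                              seed=3, pixel_size=PS)
        f1 = tfm.piv(ref.frame(0), dfm.frame(0), window_px=32,
                     pixel_size=PS)
        f2 = tfm.piv(np.rot90(ref.frame(0)).copy(),
                     np.rot90(dfm.frame(0)).copy(), window_px=32,
                     pixel_size=PS)
        # np.rot90 is a +90 deg screen-CCW rotation: (u, v) -> (-v, u),
        # and the node grid maps (i, j) -> (n-1-j, i)
        n = f1.u.shape[0]
        for (i, j) in [(2, 3), (5, 5), (7, 2), (4, 8)]:
            assert f2.u[n - 1 - j, i] == pytest.approx(-f1.v[i, j],
                                                       abs=0.1 * PS)
            assert f2.v[n - 1 - j, i] == pytest.approx(f1.u[i, j],
                                                       abs=0.1 * PS)


class TestRingDecomposition:
    @staticmethod
    def _ring(n=128, ps=1.0):
        half = n * ps / 2
        return core_io.PatternGeometry("ring", center=(half, half),
                                       diameter=0.6 * n * ps,
                                       band_width=0.25 * n * ps)

    def test_pure_inward_field(self):
        geo = self._ring()
        tx, ty = synthetic.make_ring_traction(geo, (128, 128), 1.0,
                                              magnitude_pa=100.0)
        summary = tfm.ring_decomposition(
            tfm.TractionField(np.arange(128.), np.arange(128.), tx, ty), geo)
        assert summary.mean_radial_pa < 0
        assert summary.mean_tangential_pa == pytest.approx(0.0, abs=1e-9)
        assert summary.net_moment_pa_um == pytest.approx(0.0, abs=1e-6)
        assert summary.contractile_moment_pa_um2 > 0
        assert summary.balance_residual < 1e-9

    def test_pure_ccw_tangential_field(self):
        geo = self._ring()
        rows, cols = np.mgrid[0:128, 0:128].astype(float)
        cx, cy = geo.center
        rx, ry_up = cols - cx, cy - rows
        r = np.hypot(rx, ry_up)
        with np.errstate(invalid="ignore"):
            tx = np.where(r > 0, -ry_up / r, 0.0) * 50.0
            ty = np.where(r > 0, rx / r, 0.0) * 50.0
        summary = tfm.ring_decomposition(
            tfm.TractionField(np.arange(128.), np.arange(128.), tx, ty), geo)
        assert summary.net_moment_pa_um > 0
        assert summary.mean_radial_pa == pytest.approx(0.0, abs=1e-9)
        assert summary.mean_tangential_pa > 0

    def test_cw_tangential_bias_flips_moment_sign(self):
        geo = self._ring()
        tx, ty = synthetic.make_ring_traction(geo, (128, 128), 1.0,
                                              magnitude_pa=100.0,
                                              tangential_frac=-0.1)
        summary = tfm.ring_decomposition(
            tfm.TractionField(np.arange(128.), np.arange(128.), tx, ty), geo)
        assert summary.net_moment_pa_um < 0
        assert summary.mean_radial_pa < 0

    def test_no_nodes_in_annulus_rejected(self):
        geo = core_io.PatternGeometry("ring", center=(1000.0, 1000.0),
                                      diameter=50.0, band_width=10.0)
        t = tfm.TractionField(np.arange(16.), np.arange(16.),
                              np.zeros((16, 16)), np.zeros((16, 16)))
        with pytest.raises(ValueError):
            tfm.ring_decomposition(t, geo)


def test_coculture_amplitude_contrast_recovered():
    """Doubling the generator traction amplitude roughly doubles the
    recovered mean traction through the full PIV + FTTC chain."""
    n = 192
    half = n * PS / 2
    geo = core_io.PatternGeometry("ring", center=(half, half),
                                  diameter=0.6 * n * PS,
                                  band_width=0.25 * n * PS)
    mean_t = {}
    for mag in (100.0, 200.0):
        tx, ty = synthetic.make_ring_traction(
            geo, (n, n), PS, magnitude_pa=mag, tangential_frac=-0.1,
            profile_sigma_um=geo.band_width / 2.5)
        ref, dfm, _ = synthetic.gen_bead_pair(tx, ty, GEL, n_beads=3000,
                                              image_shape=(n, n), seed=1,
                                              pixel_size=PS)
        f = tfm.piv(ref.frame(0), dfm.frame(0), window_px=32,
                    overlap_frac=0.75, pixel_size=PS)
        trac = tfm.reconstruct_traction(f, GEL, lambda_reg="lcurve")
        xx, yy = np.meshgrid(trac.x_um, trac.y_um)
        r = np.hypot(xx - half, yy - half)
        sel = (r >= geo.inner_radius) & (r <= geo.outer_radius)
        mean_t[mag] = trac.magnitude[sel].mean()
    assert mean_t[200.0] / mean_t[100.0] == pytest.approx(2.0, abs=0.2)
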