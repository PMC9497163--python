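"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from bbbq import core_io, synthetic, tfm


@pytest.fixture
def ring_geometry():
    """A ring comfortably inside a 280x280 frame at 0.645 µm/px."""
    return core_io.PatternGeometry("ring", center=(90.0, 90.0),
                                   diameter=160.0, band_width=45.0)


def rasterize_truth_curves(truths, shape):
    """Dense raster of the generator's junction polylines (oracle side)."""
    img = np.zeros(shape, bool)
    for t in truths:
        pts = t["points_px"]
        for a, b in zip(pts[:-1], pts[1:]):
            n = max(int(np.hypot(*(b - a)) * 3), 2)
            seg = a[None] + np.linspace(0, 1, n)[:, None] * (b - a)[None]
            rr = np.clip(np.round(seg[:, 1]).astype(int), 0, shape[0] - 1)
            cc = np.clip(np.round(seg[:, 0]).astype(int), 0, shape[1] - 1)
            img[rr, cc] = True
    return img


def direct_boussinesq_displacement(traction_fn, gel, spacing_um, shape,
                                   refine=10):
    """Independent direct-space oracle for the elastic forward model.

    Point-force quadrature of the Boussinesq surface Green function
    G_ij(r) = (1+nu)/(pi E) [ (1-nu)/r delta_ij + nu r_i r_j / r^3 ]
    over a fine grid offset by half a fine cell (so the singularity is
    never hit).  ``traction_fn(x, y)`` returns (tx, ty) analytically in the
    y-down plane frame; the returned v is flipped to the package's y-up
    convention.
    """
    ny, nx = shape
    e, nu = gel.youngs_modulus_pa, gel.poisson_ratio
    hf = spacing_um / refine
    fy, fx = np.mgrid[0:ny * refine, 0:nx * refine].astype(float)
    fx = (fx + 0.5) * hf - spacing_um / 2
    fy = (fy + 0.5) * hf - spacing_um / 2
    txf, tyf = traction_fn(fx, fy)
    txf, tyf = txf.ravel(), tyf.ravel()
    fx, fy = fx.ravel(), fy.ravel()
    pref = (1 + nu) / (np.pi * e)
    da = hf * hf
    u = np.zeros(shape)
    v_dn = np.zeros(shape)
    for i in range(ny):
        for j in range(nx):
            rx = j * spacing_um - fx
            ry = i * spacing_um - fy
            r = np.hypot(rx, ry)
            dot = rx * txf + ry * tyf
            u[i, j] = np.sum(pref * ((1 - nu) / r * txf + nu * rx * dot / r ** 3)) * da
            v_dn[i, j] = np.sum(pref * ((1 - nu) / r * tyf + nu * ry * dot / r ** 3)) * da
    return u, -v_dn


def bead_pair_with_uniform_shift(shift_xy, seed, density=0.02,
                                 canvas=160, crop=16):
    """Reference/shifted bead images whose texture translates rigidly,
    with content flowing in from outside the cropped frame."""
    rng = np.random.default_rng(seed)
    n = int(density * canvas * canvas)
    pos = np.column_stack([rng.uniform(0, canvas - 1, n),
                           rng.uniform(0, canvas - 1, n)])
    ref = synthetic._render_beads((canvas, canvas), pos, 1.5)
    moved = synthetic._render_beads((canvas, canvas),
                                    pos + np.asarray(shift_xy, float), 1.5)
    sl = np.s_[crop:canvas - crop, crop:canvas - crop]
    return ref[sl], moved[sl]
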