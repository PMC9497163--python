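"""Traction force microscopy: PIV displacement estimation and Fourier-space
traction reconstruction on an elastic half-space.

Bead displacements between a reference and a deformed image are measured by
windowed FFT normalized cross-correlation with subpixel (3-point Gaussian)
peak fitting and multi-pass window offsetting.  Displacements are inverted
to traction stress with regularized Fourier-transform traction cytometry
(FTTC): per-wavenumber inversion of the Boussinesq half-space Green tensor
with zeroth-order Tikhonov regularization.

Conventions: node *positions* (x, y) are in micrometres with y increasing
down rows (array order); *vector components* (u, v) and (tx, ty) are in the
screen-CCW frame, i.e. v and ty positive point up-screen (toward smaller
row index).  See :mod:`bbbq.angles`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import PatternGeometry

__all__ = [
    "GelProperties",
    "DisplacementField",
    "TractionField",
    "RingForceSummary",
    "piv",
    "forward_displacement",
    "reconstruct_traction",
    "lcurve_lambda",
    "ring_decomposition",
]


@dataclass
class GelProperties:
    """Linear-elastic substrate: Young's modulus (Pa) and Poisson ratio."""

    youngs_modulus_pa: float
    poisson_ratio: float = 0.45

    def __post_init__(self):
        if self.youngs_modulus_pa <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not (0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


@dataclass
class DisplacementField:
    """Gridded displacement vectors (µm) with per-node correlation SNR."""

    x_um: np.ndarray  # 1D node x coordinates (columns)
    y_um: np.ndarray  # 1D node y coordinates (rows, y down)
    u: np.ndarray  # 2D, µm, +x
    v: np.ndarray  # 2D, µm, up-screen positive
    snr: np.ndarray = None
    valid: np.ndarray = None

    def __post_init__(self):
        self.u = np.asarray(self.u, float)
        self.v = np.asarray(self.v, float)
        if self.snr is None:
            self.snr = np.full_like(self.u, np.inf)
        if self.valid is None:
            self.valid = np.ones(self.u.shape, bool)
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("displacement field must be finite")

    @property
    def spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])


@dataclass
class TractionField:
    """Gridded traction stress vectors (Pa)."""

    x_um: np.ndarray
    y_um: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    regularization_lambda: float = 0.0

    @property
    def spacing_um(self) -> float:
        return float(self.x_um[1] - self.x_um[0])

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)


@dataclass
class RingForceSummary:
    """Radial/tangential decomposition of traction on a ring pattern.

    mean_radial_pa < 0 means inward (contractile); mean_tangential_pa > 0
    means counterclockwise on screen.
    """

    mean_radial_pa: float
    mean_tangential_pa: float
    net_moment_pa_um: float
    contractile_moment_pa_um2: float
    balance_residual: float
    n_nodes: int


# ---------------------------------------------------------------------------
# Boussinesq Green tensor in Fourier space (Fourier-transform traction
# cytometry). For wavevector k on the surface of an elastic half-space:
#   G(k) = 2 (1+nu) / (E k^3) * [[(1-nu) k^2 + nu ky^2,  -nu kx ky],
#                                [-nu kx ky,  (1-nu) k^2 + nu kx^2]]
# ---------------------------------------------------------------------------

def _greens_fourier(kx, ky, gel: GelProperties):
    e, nu = gel.youngs_modulus_pa, gel.poisson_ratio
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (e * k ** 3)
        g11 = pref * ((1.0 - nu) * k ** 2 + nu * ky ** 2)
        g22 = pref * ((1.0 - nu) * k ** 2 + nu * kx ** 2)
        g12 = pref * (-nu * kx * ky)
    zero = k == 0
    for g in (g11, g12, g22):
        g[zero] = 0.0
    return g11, g12, g22


def forward_displacement(tx: np.ndarray, ty: np.ndarray, gel: GelProperties,
                         spacing_um: float, pad_factor: int = 4):
    """Surface displacement (µm) produced by a gridded traction field (Pa).

    Convolution with the Boussinesq half-space Green tensor, evaluated in
    Fourier space with zero padding (pad_factor x grid size) to suppress the
    periodic images of the FFT.  Vector components follow the screen-CCW
    convention (y up); the solve internally runs in array (y-down)
    coordinates, which only flips the sign of the y components.
    """
    tx = np.asarray(tx, float)
    ty_dn = -np.asarray(ty, float)  # to array-frame y (down rows)
    if tx.shape != ty_dn.shape:
        raise ValueError("tx and ty must have the same shape")
    ny, nx = tx.shape
    py, px = pad_factor * ny, pad_factor * nx
    kx = 2 * np.pi * np.fft.fftfreq(px, d=spacing_um)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(py, d=spacing_um)[:, None]
    g11, g12, g22 = _greens_fourier(kx, ky, gel)
    ftx = np.fft.fft2(tx, s=(py, px))
    fty = np.fft.fft2(ty_dn, s=(py, px))
    fu = g11 * ftx + g12 * fty
    fv = g12 * ftx + g22 * fty
    u = np.fft.ifft2(fu).real[:ny, :nx]
    v_dn = np.fft.ifft2(fv).real[:ny, :nx]
    return u, -v_dn


def _tikhonov_invert(fu, fv, g11, g12, g22, lam):
    # per-wavenumber solve of (G^T G + lam^2 I) T = G^T U for symmetric G
    a11 = g11 * g11 + g12 * g12 + lam ** 2
    a12 = g12 * (g11 + g22)
    a22 = g22 * g22 + g12 * g12 + lam ** 2
    det = a11 * a22 - a12 * a12
    b1 = g11 * fu + g12 * fv
    b2 = g12 * fu + g22 * fv
    with np.errstate(divide="ignore", invalid="ignore"):
        ftx = (a22 * b1 - a12 * b2) / det
        fty = (-a12 * b1 + a11 * b2) / det
    ftx[det == 0] = 0.0
    fty[det == 0] = 0.0
    return ftx, fty


def lcurve_lambda(disp: DisplacementField, gel: GelProperties,
                  n_lambdas: int = 25) -> float:
    """Pick a Tikhonov parameter at the L-curve corner (max curvature of
    log residual-norm vs log solution-norm)."""
    u, v_dn = disp.u, -disp.v
    ny, nx = u.shape
    d = disp.spacing_um
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=d)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=d)[:, None]
    g11, g12, g22 = _greens_fourier(kx, ky, gel)
    fu, fv = np.fft.fft2(u), np.fft.fft2(v_dn)
    gscale = 2.0 * (1.0 + gel.poisson_ratio) / gel.youngs_modulus_pa
    lams = gscale * np.logspace(-4, 1, n_lambdas) * d
    rho, eta = [], []
    for lam in lams:
        ftx, fty = _tikhonov_invert(fu, fv, g11, g12, g22, lam)
        ru = g11 * ftx + g12 * fty - fu
        rv = g12 * ftx + g22 * fty - fv
        rho.append(np.sqrt(np.sum(np.abs(ru) ** 2 + np.abs(rv) ** 2)))
        eta.append(np.sqrt(np.sum(np.abs(ftx) ** 2 + np.abs(fty) ** 2)))
    lr = np.log10(np.maximum(rho, 1e-300))
    le = np.log10(np.maximum(eta, 1e-300))
    # discrete curvature of the (lr, le) curve
    d1r, d1e = np.gradient(lr), np.gradient(le)
    d2r, d2e = np.gradient(d1r), np.gradient(d1e)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (d1r * d2e - d2r * d1e) / (d1r ** 2 + d1e ** 2) ** 1.5
    kappa[~np.isfinite(kappa)] = -np.inf
    return float(lams[int(np.argmax(kappa))])


def reconstruct_traction(disp: DisplacementField, gel: GelProperties,
                         lambda_reg: float | str = 0.0) -> TractionField:
    """Invert a displacement field to traction stress (FTTC).

    lambda_reg: Tikhonov parameter in the Green-function units (µm/Pa);
    0 for an unregularized inversion, or "lcurve" to pick it automatically.
    The zero-frequency (rigid drift) component is removed.
    """
    u, v_dn = np.asarray(disp.u, float), -np.asarray(disp.v, float)
    ny, nx = u.shape
    if min(ny, nx) < 8:
        raise ValueError("displacement grid too small for reconstruction (< 8 nodes)")
    if lambda_reg == "lcurve":
        lambda_reg = lcurve_lambda(disp, gel)
    lam = float(lambda_reg)
    if lam < 0:
        raise ValueError("regularization must be >= 0")
    d = disp.spacing_um
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=d)[None, :]
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=d)[:, None]
    g11, g12, g22 = _greens_fourier(kx, ky, gel)
    fu, fv = np.fft.fft2(u), np.fft.fft2(v_dn)
    ftx, fty = _tikhonov_invert(fu, fv, g11, g12, g22, lam)
    ftx[0, 0] = 0.0
    fty[0, 0] = 0.0
    tx = np.fft.ifft2(ftx).real
    ty_dn = np.fft.ifft2(fty).real
    return TractionField(disp.x_um, disp.y_um, tx, -ty_dn,
                         regularization_lambda=lam)


# ---------------------------------------------------------------------------
# PIV
# ---------------------------------------------------------------------------

def _xcorr_peak(a: np.ndarray, b: np.ndarray, max_shift: int):
    """Normalized FFT cross-correlation peak of two equal windows.

    Returns (d_col, d_row, snr) with subpixel 3-point Gaussian fit, or None
    for a featureless window.  Positive d means b is a shifted b(x) =
    a(x - d).
    """
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    n = a.shape[0]
    size = 2 * n
    fa = np.fft.rfft2(a, s=(size, size))
    fb = np.fft.rfft2(b, s=(size, size))
    c = np.fft.irfft2(np.conj(fa) * fb, s=(size, size)) / (na * nb)
    c = np.fft.fftshift(c)
    center = size // 2
    # divide out the triangular zero-padding overlap envelope: the raw
    # linear correlation sits on a tilted pedestal that biases the subpixel
    # fit toward zero lag (peak locking).  The search stays within
    # max_shift, where the envelope is still well conditioned.
    lag = np.abs(np.arange(size) - center)
    env = np.maximum(1.0 - lag / n, 1e-6)
    c = c / np.outer(env, env)
    # restrict the search to physically plausible shifts
    lo, hi = center - max_shift, center + max_shift + 1
    roi = c[lo:hi, lo:hi]
    ij = np.unravel_index(np.argmax(roi), roi.shape)
    pr, pc = ij[0] + lo, ij[1] + lo
    peak = c[pr, pc]
    if peak <= 0:
        return None
    # SNR: primary peak over the largest peak outside its 3x3 neighborhood
    roi2 = roi.copy()
    roi2[max(ij[0] - 1, 0):ij[0] + 2, max(ij[1] - 1, 0):ij[1] + 2] = -np.inf
    second = roi2.max()
    snr = peak / second if second > 0 else np.inf
    # 3-point Gaussian subpixel fit per axis
    def subpix(cm, c0, cp):
        cm = max(cm, c0 * 1e-6)
        cp = max(cp, c0 * 1e-6)
        denom = np.log(cm) - 2 * np.log(c0) + np.log(cp)
        if denom >= 0:
            return 0.0
        return 0.5 * (np.log(cm) - np.log(cp)) / denom
    dr = pr - center
    dc = pc - center
    if 0 < pr < size - 1:
        dr += subpix(c[pr - 1, pc], peak, c[pr + 1, pc])
    if 0 < pc < size - 1:
        dc += subpix(c[pr, pc - 1], peak, c[pr, pc + 1])
    return dc, dr, snr


def piv(ref, deformed, window_px: int = 32, overlap_frac: float = 0.5,
        passes: int = 2, snr_threshold: float = 1.3,
        pixel_size: float = 1.0) -> DisplacementField:
    """Estimate the displacement field from a reference/deformed image pair.

    Windowed, mean-subtracted FFT normalized cross-correlation with 3-point
    Gaussian subpixel peak fitting; later passes re-extract the deformed
    window at the integer-rounded displacement from the previous pass.
    Nodes whose correlation peak ratio falls below ``snr_threshold`` (or
    featureless windows) are replaced by the local median and flagged.
    """
    ref = np.asarray(ref, float)
    deformed = np.asarray(deformed, float)
    if ref.shape != deformed.shape:
        raise ValueError("frames must have the same shape")
    if window_px < 16 or window_px & (window_px - 1):
        raise ValueError("window must be a power of two >= 16")
    w2 = window_px // 2
    step = max(int(round(window_px * (1 - overlap_frac))), 1)
    rows = np.arange(w2, ref.shape[0] - w2 + 1, step)
    cols = np.arange(w2, ref.shape[1] - w2 + 1, step)
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("image smaller than one PIV window")
    du = np.zeros((len(rows), len(cols)))
    dv = np.zeros_like(du)
    snr = np.zeros_like(du)
    ok = np.zeros(du.shape, bool)
    max_shift = w2 - 1
    for _pass in range(passes):
        for i, r in enumerate(rows):
            for j, c in enumerate(cols):
                offc = int(round(du[i, j]))
                offr = int(round(dv[i, j]))
                r2, c2 = r + offr, c + offc
                if not (w2 <= r2 <= ref.shape[0] - w2 and
                        w2 <= c2 <= ref.shape[1] - w2):
                    r2, c2, offr, offc = r, c, 0, 0
                a = ref[r - w2:r + w2, c - w2:c + w2]
                b = deformed[r2 - w2:r2 + w2, c2 - w2:c2 + w2]
                res = _xcorr_peak(a, b, max_shift)
                if res is None:
                    ok[i, j] = False
                    snr[i, j] = 0.0
                    continue
                dc, dr, s = res
                du[i, j] = offc + dc
                dv[i, j] = offr + dr
                snr[i, j] = s
                ok[i, j] = True
    valid = ok & (snr >= snr_threshold)
    if not valid.any():
        raise ValueError("no valid PIV nodes (featureless images?)")
    du = _median_fill(du, valid)
    dv = _median_fill(dv, valid)
    return DisplacementField(
        x_um=cols * pixel_size,
        y_um=rows * pixel_size,
        u=du * pixel_size,
        v=-dv * pixel_size,  # rows increase down-screen; v is up-positive
        snr=snr,
        valid=valid,
    )


def _median_fill(a: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Replace invalid nodes by the median of valid 3x3 neighbours."""
    if valid.all():
        return a
    out = a.copy()
    bad = ~valid
    tmp = np.where(valid, a, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN patches
        med = ndimage.generic_filter(tmp, np.nanmedian, size=3,
                                     mode="constant", cval=np.nan)
    out[bad] = np.where(np.isfinite(med[bad]), med[bad], 0.0)
    return out


def ring_decomposition(traction: TractionField,
                       ring: PatternGeometry) -> RingForceSummary:
    """Radial/tangential traction decomposition over a ring pattern."""
    if ring.kind != "ring":
        raise ValueError("ring_decomposition needs a ring geometry")
    xx, yy = np.meshgrid(traction.x_um, traction.y_um)
    cx, cy = ring.center
    rx = xx - cx
    ry_up = cy - yy  # positions are y-down; vectors live in the y-up frame
    r = np.hypot(rx, ry_up)
    sel = (r >= ring.inner_radius) & (r <= ring.outer_radius) & (r > 0)
    if not sel.any():
        raise ValueError("no grid nodes inside the ring annulus")
    rhx, rhy = rx[sel] / r[sel], ry_up[sel] / r[sel]
    thx, thy = -rhy, rhx  # CCW tangent
    tx, ty = traction.tx[sel], traction.ty[sel]
    t_rad = tx * rhx + ty * rhy
    t_tan = tx * thx + ty * thy
    da = traction.spacing_um ** 2
    mag = np.hypot(tx, ty)
    net_fx, net_fy = tx.sum() * da, ty.sum() * da
    denom = mag.sum() * da
    balance = float(np.hypot(net_fx, net_fy) / denom) if denom > 0 else 0.0
    return RingForceSummary(
        mean_radial_pa=float(t_rad.mean()),
        mean_tangential_pa=float(t_tan.mean()),
        net_moment_pa_um=float(np.sum(rx[sel] * ty - ry_up[sel] * tx) * da),
        contractile_moment_pa_um2=float(-np.sum(t_rad * r[sel]) * da),
        balance_residual=balance,
        n_nodes=int(sel.sum()),
    )
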