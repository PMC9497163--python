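"""Synthetic inputs with known ground truth for every analysis stage.

The study's raw microscopy cannot be downloaded, so each analysis stage is
exercised on generated data that emulates the relevant image structure:

* oriented stripe texture on ring/line micropatterns with a controllable
  chiral bias and von Mises angular dispersion (sampled on doubled angles,
  so concentration applies to the axial orientation),
* Voronoi polygonal junction networks with sinusoidal edge wiggle and an
  analytically integrated true arc length,
* fluorescent-bead image pairs deformed by the elastic forward model
  (Boussinesq half-space) of a known traction field,
* fluorescence traces containing sparks of known amplitude and kinetics,
* grouped TEER resistance records and permeability time series.

Every generator is a pure function of its parameters and a seed, and emits
its ground truth alongside the data; analysis stages never see the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import Voronoi, QhullError

from . import angles, tfm
from .barrier import TeerRecord
from .calcium import CalciumTrace
from .core_io import ImageStack, PatternGeometry, RoiMask, pattern_mask

__all__ = [
    "ChiralityTruth",
    "TractionTruth",
    "SparkTruth",
    "gen_ring_texture",
    "gen_junction_network",
    "gen_bead_pair",
    "gen_calcium_trace",
    "gen_barrier_records",
    "make_ring_traction",
    "make_dipole_traction",
    "make_permeability_series",
    "render_calcium_movie",
]


# ---------------------------------------------------------------------------
# chirality texture
# ---------------------------------------------------------------------------

@dataclass
class ChiralityTruth:
    """Ground truth for a chiral texture: bias angle (deg, CCW-positive,
    in (-90, 90]), von Mises concentration kappa (np.inf = no dispersion,
    0 = isotropic), and the pattern geometry."""

    bias_deg: float
    kappa: float
    geometry: PatternGeometry
    sampled_angles_deg: np.ndarray | None = None
    block_centers_px: np.ndarray | None = None

    def __post_init__(self):
        if not (-90.0 < self.bias_deg <= 90.0):
            raise ValueError("bias must be in (-90, 90]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


def _sample_axial_noise(rng, kappa, size):
    """Axial von Mises noise (deg): sampled on doubled angles and halved,
    so kappa concentrates the *orientation* on [0, 180)."""
    if np.isinf(kappa):
        return 0.0 if size is None else np.zeros(size)
    return np.degrees(rng.vonmises(0.0, kappa, size=size)) / 2.0


def gen_ring_texture(truth: ChiralityTruth, image_shape=(384, 384),
                     stripe_period_px: int = 8, noise_sd: float = 0.05,
                     seed: int = 0, pixel_size: float = 0.645,
                     block_px: int = 16):
    """Render a striped texture whose local orientation is the pattern
    reference direction plus the chiral bias plus von Mises noise.

    The pattern mask is tiled into ``block_px`` blocks; each block gets one
    orientation sample (reference at the block centre + bias + noise) and is
    filled with sinusoidal stripes of that orientation.  The sampled angles
    and block centres are stored on the returned truth.
    """
    if stripe_period_px < 3:
        raise ValueError("stripe period must be >= 3 px")
    rng = np.random.default_rng(seed)
    geo = truth.geometry
    roi = pattern_mask(geo, image_shape, pixel_size)
    img = 0.5 + rng.normal(0.0, noise_sd, image_shape) if noise_sd > 0 \
        else np.full(image_shape, 0.5)
    rows, cols = np.mgrid[0:image_shape[0], 0:image_shape[1]].astype(float)
    sampled, centers = [], []
    for r0 in range(0, image_shape[0], block_px):
        for c0 in range(0, image_shape[1], block_px):
            sub = np.s_[r0:min(r0 + block_px, image_shape[0]),
                        c0:min(c0 + block_px, image_shape[1])]
            m = roi.mask[sub]
            if not m.any():
                continue
            rc = (r0 + (sub[0].stop - r0) / 2.0, c0 + (sub[1].stop - c0) / 2.0)
            if geo.kind == "ring":
                x_um, y_um = rc[1] * pixel_size, rc[0] * pixel_size
                if np.hypot(x_um - geo.center[0], y_um - geo.center[1]) == 0:
                    continue
                ref = angles.ring_tangent_deg(x_um, y_um, geo.center)
            else:
                ref = geo.axis_angle
            theta = ref + truth.bias_deg + _sample_axial_noise(rng, truth.kappa, None)
            th = np.radians(theta)
            # stripe phase coordinate runs perpendicular to the orientation
            s = -cols[sub] * np.sin(th) - rows[sub] * np.cos(th)
            stripes = 0.5 + 0.4 * np.sin(2 * np.pi * s / stripe_period_px)
            img[sub] = np.where(m, stripes + (rng.normal(0, noise_sd, m.shape)
                                              if noise_sd > 0 else 0.0), img[sub])
            sampled.append(angles.wrap_axial_deg(theta))
            centers.append((rc[1], rc[0]))  # (col, row) = (x, y) px
    out_truth = replace(truth,
                        sampled_angles_deg=np.asarray(sampled, float),
                        block_centers_px=np.asarray(centers, float))
    return ImageStack(img, pixel_size=pixel_size), out_truth


# ---------------------------------------------------------------------------
# junction networks
# ---------------------------------------------------------------------------

def _wiggle_edge(p0, p1, amp, freq, n=512):
    """Sinusoidally perturbed edge from p0 to p1 with ``freq`` full periods
    of amplitude ``amp`` along the normal; densely sampled polyline."""
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    length = np.hypot(*d)
    u = d / length
    nrm = np.array([-u[1], u[0]])
    s = np.linspace(0.0, 1.0, n)
    pts = p0[None] + s[:, None] * d[None] \
        + (amp * np.sin(2 * np.pi * freq * s))[:, None] * nrm[None]
    return pts


def _polyline_length(pts):
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def gen_junction_network(n_cells: int, wiggle_amp: float = 2.0,
                         wiggle_freq: float = 3.0,
                         image_shape=(256, 256), seed: int = 0,
                         pixel_size: float = 1.0, shear: float = 0.0):
    """Voronoi-style polygonal cell boundaries with sinusoidal edge wiggle,
    rendered as bright ~2-px-wide curves.

    Returns (ImageStack, truths): one truth dict per rendered edge with the
    dense generating polyline (px), true arc and chord lengths (µm, from
    dense numeric integration) and the arc-chord ratio.  ``shear`` applies
    the map x -> x + shear * y_up to the Voronoi vertices before wiggling
    (y_up measured from the image centre), giving a net with a known
    chirality sign.
    """
    if n_cells < 2:
        raise ValueError("need n_cells >= 2")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    margin = 0.08 * min(h, w)
    for attempt in range(10):
        pts = np.column_stack([rng.uniform(0, w, n_cells),
                               rng.uniform(0, h, n_cells)])
        try:
            vor = Voronoi(pts)
            break
        except QhullError:
            continue  # degenerate layout: redraw with a fresh jitter
    else:
        raise RuntimeError("could not build a Voronoi layout")

    def shear_xy(p):
        x, y = p
        return np.array([x + shear * (h / 2.0 - y), y])

    img = np.zeros(image_shape, bool)
    truths = []
    center = vor.points.mean(axis=0)
    far = 2.0 * max(h, w)
    for (p0, p1), (i0, i1) in zip(vor.ridge_points, vor.ridge_vertices):
        if i0 < 0 and i1 < 0:
            continue
        if i0 < 0 or i1 < 0:
            # semi-infinite ridge: extend from the finite vertex outward
            # (perpendicular to the segment between the two input points)
            vfin = vor.vertices[i1 if i0 < 0 else i0]
            t = vor.points[p1] - vor.points[p0]
            t = t / np.hypot(*t)
            nvec = np.array([-t[1], t[0]])
            mid = vor.points[[p0, p1]].mean(axis=0)
            if np.dot(mid - center, nvec) < 0:
                nvec = -nvec
            v0 = shear_xy(vfin)
            v1 = shear_xy(vfin + nvec * far)
        else:
            v0 = shear_xy(vor.vertices[i0])
            v1 = shear_xy(vor.vertices[i1])
        if np.hypot(*(v1 - v0)) < 4:
            continue
        dense = _wiggle_edge(v0, v1, wiggle_amp, wiggle_freq, n=4096)
        # clip to the frame (with margin); each contiguous in-frame run is
        # one rendered edge piece with its own ground truth
        inside = ((dense[:, 0] >= margin) & (dense[:, 0] <= w - 1 - margin)
                  & (dense[:, 1] >= margin) & (dense[:, 1] <= h - 1 - margin))
        # brief excursions out of the frame margin are bridged by the 2-px
        # rendering anyway: keep them part of one piece
        arc_step = _polyline_length(dense) / len(dense)
        min_gap = max(int(8.0 / max(arc_step, 1e-9)), 1)
        runs = np.nonzero(np.diff(inside.astype(int)))[0] + 1
        bounds = np.concatenate([[0], runs, [len(dense)]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if not inside[b0] and b1 - b0 < min_gap and b0 > 0 and b1 < len(dense):
                inside[b0:b1] = True
        splits = np.nonzero(np.diff(inside.astype(int)))[0] + 1
        for piece in np.split(np.arange(len(dense)), splits):
            if not inside[piece[0]] or len(piece) < 2:
                continue
            seg = dense[piece]
            chord_px = float(np.hypot(*(seg[-1] - seg[0])))
            if chord_px < 8:
                continue
            rr = np.round(seg[:, 1]).astype(int)
            cc = np.round(seg[:, 0]).astype(int)
            img[rr, cc] = True
            truths.append({
                "points_px": seg[::32].copy(),
                "endpoints_px": (tuple(seg[0]), tuple(seg[-1])),
                "arc_um": _polyline_length(seg) * pixel_size,
                "chord_um": chord_px * pixel_size,
                "ratio": _polyline_length(seg) / chord_px,
            })
    img = ndimage.binary_dilation(img, structure=np.ones((2, 2)))
    frame = img.astype(float)
    return ImageStack(frame, pixel_size=pixel_size), truths


# ---------------------------------------------------------------------------
# bead pairs / traction
# ---------------------------------------------------------------------------

@dataclass
class TractionTruth:
    """Known traction field (Pa) and the displacement field (µm) it produces
    through the half-space forward model, on the image pixel grid."""

    tx: np.ndarray
    ty: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gel: tfm.GelProperties
    pixel_size: float

    @property
    def net_force(self):
        da = self.pixel_size ** 2
        return float(self.tx.sum() * da), float(self.ty.sum() * da)


def make_dipole_traction(image_shape, pixel_size: float,
                         center_um=None, separation_um: float = 40.0,
                         magnitude_pa: float = 200.0, sigma_um: float = 8.0):
    """Contractile dipole: two Gaussian traction patches pulling toward each
    other along x.  Net force is zero by construction."""
    h, w = image_shape
    if center_um is None:
        center_um = (w * pixel_size / 2.0, h * pixel_size / 2.0)
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    x, y = cols * pixel_size, rows * pixel_size
    cx, cy = center_um
    half = separation_um / 2.0
    gl = np.exp(-((x - (cx - half)) ** 2 + (y - cy) ** 2) / (2 * sigma_um ** 2))
    gr = np.exp(-((x - (cx + half)) ** 2 + (y - cy) ** 2) / (2 * sigma_um ** 2))
    tx = magnitude_pa * (gl - gr)  # left patch pulls +x, right pulls -x
    ty = np.zeros_like(tx)
    return tx, ty


def make_ring_traction(geometry: PatternGeometry, image_shape,
                       pixel_size: float, magnitude_pa: float = 100.0,
                       tangential_frac: float = 0.0,
                       profile_sigma_um: float | None = None):
    """Contractile ring: inward radial traction with a Gaussian radial
    profile centred mid-band, plus an optional tangential component
    (positive fraction = CCW)."""
    h, w = image_shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    x, y = cols * pixel_size, rows * pixel_size
    cx, cy = geometry.center
    rx, ry_up = x - cx, cy - y
    r = np.hypot(rx, ry_up)
    r_mid = (geometry.inner_radius + geometry.outer_radius) / 2.0
    sig = profile_sigma_um or geometry.band_width / 4.0
    wgt = np.exp(-((r - r_mid) ** 2) / (2 * sig ** 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhx, rhy = np.where(r > 0, rx / r, 0.0), np.where(r > 0, ry_up / r, 0.0)
    tx = magnitude_pa * wgt * (-rhx + tangential_frac * (-rhy))
    ty = magnitude_pa * wgt * (-rhy + tangential_frac * rhx)
    return tx, ty


def _render_beads(shape, positions, sigma_px, amplitude=1.0):
    """Sum of Gaussian spots at float (col, row) positions."""
    img = np.zeros(shape)
    rad = int(np.ceil(4 * sigma_px))
    for cx, cy in positions:
        r0, r1 = int(np.floor(cy)) - rad, int(np.floor(cy)) + rad + 1
        c0, c1 = int(np.floor(cx)) - rad, int(np.floor(cx)) + rad + 1
        r0c, r1c = max(r0, 0), min(r1, shape[0])
        c0c, c1c = max(c0, 0), min(c1, shape[1])
        if r0c >= r1c or c0c >= c1c:
            continue
        rr, cc = np.mgrid[r0c:r1c, c0c:c1c].astype(float)
        img[r0c:r1c, c0c:c1c] += amplitude * np.exp(
            -((cc - cx) ** 2 + (rr - cy) ** 2) / (2 * sigma_px ** 2))
    return img


def _bilinear(a, rr, cc):
    r0 = np.clip(np.floor(rr).astype(int), 0, a.shape[0] - 2)
    c0 = np.clip(np.floor(cc).astype(int), 0, a.shape[1] - 2)
    fr, fc = rr - r0, cc - c0
    return (a[r0, c0] * (1 - fr) * (1 - fc) + a[r0 + 1, c0] * fr * (1 - fc)
            + a[r0, c0 + 1] * (1 - fr) * fc + a[r0 + 1, c0 + 1] * fr * fc)


def gen_bead_pair(tx: np.ndarray, ty: np.ndarray, gel: tfm.GelProperties,
                  n_beads: int = 2000, bead_sigma_px: float = 1.5,
                  image_shape=(256, 256), seed: int = 0,
                  pixel_size: float = 0.645, noise_sd: float = 0.0):
    """Reference/deformed fluorescent-bead images for a known traction field.

    The displacement field is computed from the traction by the Fourier
    half-space forward model; beads are Gaussian spots in the reference
    image and are shifted by the bilinearly interpolated local displacement
    in the deformed image.  The truth carries the gridded displacement.
    """
    tx = np.asarray(tx, float)
    ty = np.asarray(ty, float)
    if tx.shape != tuple(image_shape):
        raise ValueError("traction grid must match the image shape")
    u, v = tfm.forward_displacement(tx, ty, gel, spacing_um=pixel_size)
    rng = np.random.default_rng(seed)
    marg = 4 * bead_sigma_px
    pos = np.column_stack([
        rng.uniform(marg, image_shape[1] - 1 - marg, n_beads),
        rng.uniform(marg, image_shape[0] - 1 - marg, n_beads)])
    du_px = _bilinear(u, pos[:, 1], pos[:, 0]) / pixel_size
    dv_px = -_bilinear(v, pos[:, 1], pos[:, 0]) / pixel_size  # v is y-up
    ref = _render_beads(image_shape, pos, bead_sigma_px)
    moved = pos + np.column_stack([du_px, dv_px])
    deformed = _render_beads(image_shape, moved, bead_sigma_px)
    if noise_sd > 0:
        ref = ref + rng.normal(0, noise_sd, ref.shape)
        deformed = deformed + rng.normal(0, noise_sd, deformed.shape)
    truth = TractionTruth(tx=tx, ty=ty, u=u, v=v, gel=gel,
                          pixel_size=pixel_size)
    return (ImageStack(ref, pixel_size=pixel_size),
            ImageStack(deformed, pixel_size=pixel_size), truth)


# ---------------------------------------------------------------------------
# calcium
# ---------------------------------------------------------------------------

@dataclass
class SparkTruth:
    """One synthetic spark: linear rise over ``time_to_peak_s`` then
    exponential decay with ``decay_tau_s``; amplitude is peak dF/F0."""

    onset_s: float
    amplitude_dFF0: float
    time_to_peak_s: float
    decay_tau_s: float
    baseline_F: float = 100.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.amplitude_dFF0 <= 0:
            raise ValueError("amplitude must be > 0")
        if self.decay_tau_s <= 0:
            raise ValueError("tau must be > 0")
        if self.onset_s < 0:
            raise ValueError("onset must be >= 0")


def gen_calcium_trace(truths: list[SparkTruth], n_frames: int = 400,
                      frame_interval: float = 3.0, seed: int = 0,
                      roi_label: str = "synthetic"):
    """Fluorescence trace F(t) = baseline + sum of spark events + noise.

    Events must be separated by at least 3 decay time constants (after the
    previous peak); overlap raises.  Deterministic per seed.
    """
    if not truths:
        base, noise = 100.0, 0.0
    else:
        base = truths[0].baseline_F
        noise = truths[0].noise_sd
        if any(t.baseline_F != base or t.noise_sd != noise for t in truths):
            raise ValueError("all events on one trace share baseline and noise")
    t = np.arange(n_frames) * frame_interval
    if truths:
        ordered = sorted(truths, key=lambda s: s.onset_s)
        for a, b in zip(ordered[:-1], ordered[1:]):
            if b.onset_s < a.onset_s + a.time_to_peak_s + 3 * a.decay_tau_s:
                raise ValueError("events overlap (need >= 3 tau separation)")
        if ordered[-1].onset_s + ordered[-1].time_to_peak_s >= t[-1]:
            raise ValueError("event onset/peak beyond the trace end")
    f = np.full(n_frames, base)
    for s in truths:
        peak_t = s.onset_s + s.time_to_peak_s
        dfpk = s.amplitude_dFF0 * base
        rise = (t >= s.onset_s) & (t <= peak_t)
        if s.time_to_peak_s > 0:
            f = f + np.where(rise, dfpk * (t - s.onset_s) / s.time_to_peak_s, 0.0)
        decay = t > peak_t
        f = f + np.where(decay, dfpk * np.exp(-(t - peak_t) / s.decay_tau_s), 0.0)
    if noise > 0:
        f = f + np.random.default_rng(seed).normal(0, noise, n_frames)
    trace = CalciumTrace(f, frame_interval_s=frame_interval,
                         roi_label=roi_label)
    return trace, list(truths)


def render_calcium_movie(trace: CalciumTrace, frame_shape=(64, 64),
                         roi_frac: float = 0.25, pixel_size: float = 0.645):
    """Render a trace into a movie: pixels inside a central disc ROI carry
    F(t), the background a dim constant.  Returns (ImageStack, RoiMask)."""
    h, w = frame_shape
    rows, cols = np.mgrid[0:h, 0:w]
    r = np.hypot(rows - h / 2.0, cols - w / 2.0)
    mask = r <= roi_frac * min(h, w)
    bg = 0.1 * float(np.min(trace.F))
    movie = np.full((trace.n_frames, h, w), bg)
    movie[:, mask] = trace.F[:, None]
    stack = ImageStack(movie, pixel_size=pixel_size,
                       frame_interval=trace.frame_interval_s)
    return stack, RoiMask(mask, label="synthetic_cell")


# ---------------------------------------------------------------------------
# barrier
# ---------------------------------------------------------------------------

def gen_barrier_records(group_means: dict[str, float],
                        group_sds: dict[str, float], n_per_group: int,
                        area_cm2: float = 4.5, seed: int = 0,
                        r_m_ohm: float = 120.0,
                        day: int = 1) -> list[TeerRecord]:
    """TEER records with resistances drawn normal(mean, sd) per group and a
    fixed blank membrane resistance."""
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    rng = np.random.default_rng(seed)
    records = []
    for name in group_means:
        sd = group_sds.get(name, 0.0)
        draws = rng.normal(group_means[name], sd, n_per_group) if sd > 0 \
            else np.full(n_per_group, group_means[name])
        for r in draws:
            records.append(TeerRecord(r_ohm=float(r), r_m_ohm=r_m_ohm,
                                      area_cm2=area_cm2, group=name, day=day))
    return records


def make_permeability_series(papp_cm_s: float, donor_c0: float = 100.0,
                             area_cm2: float = 4.5,
                             receiver_volume_ml: float = 1.0,
                             times_s=None, noise_frac: float = 0.0,
                             seed: int = 0):
    """Receiver concentration time series with a known apparent permeability
    (sink condition: linear accumulation)."""
    if times_s is None:
        times_s = np.arange(0.0, 3600.0 + 1, 600.0)
    t = np.asarray(times_s, float)
    conc = papp_cm_s * area_cm2 * donor_c0 * t / receiver_volume_ml
    if noise_frac > 0:
        # proportional (constant-CV) assay noise, as for a plate-reader read
        rng = np.random.default_rng(seed)
        conc = conc * (1.0 + rng.normal(0, noise_frac, conc.shape))
    return np.column_stack([t, conc])
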