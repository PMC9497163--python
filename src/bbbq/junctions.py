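"""Tight-junction and cell-shape morphometry.

From a ZO-1 immunofluorescence frame: segment the junction network to a
1-px skeleton, trace node-to-node paths, and score each path's arc-chord
tortuosity (>= 1; a proxy for junctional interdigitation).  Cell shape is
summarized by the moment-equivalent ellipse (polarization = major/minor,
orientation relative to the pattern axis), and left-right boundary
asymmetry by the signed chord angles of junction paths relative to the
anteroposterior (AP) axis with an exact binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage import filters, morphology

from . import angles
from .core_io import RoiMask

__all__ = [
    "JunctionPath",
    "TortuosityResult",
    "EllipseFit",
    "BoundaryAngleDistribution",
    "segment_skeleton",
    "trace_paths",
    "split_closed",
    "tortuosity",
    "fit_ellipse",
    "boundary_angle_chirality",
]


@dataclass
class JunctionPath:
    """Ordered polyline (µm) along one junction segment."""

    points: np.ndarray  # (n, 2) as (x, y) µm
    endpoints_are_nodes: bool = True

    def __post_init__(self):
        pts = np.asarray(self.points, float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise ValueError("path needs >= 2 (x, y) points")
        if np.any(np.all(np.diff(pts, axis=0) == 0, axis=1)):
            raise ValueError("consecutive path points must be distinct")
        self.points = pts

    @property
    def is_closed(self) -> bool:
        return bool(np.all(self.points[0] == self.points[-1]))

    @property
    def chord_vector(self) -> np.ndarray:
        return self.points[-1] - self.points[0]


@dataclass
class TortuosityResult:
    arc_um: float
    chord_um: float
    ratio: float


@dataclass
class EllipseFit:
    """Moment-equivalent ellipse of a cell mask."""

    centroid_um: tuple[float, float]
    major_um: float
    minor_um: float
    polarization: float
    theta_deg: float  # relative to the pattern axis, in (-90, 90]
    degenerate: bool = False


@dataclass
class BoundaryAngleDistribution:
    """Signed chord angles relative to the AP axis and their L-R split."""

    angles_deg: np.ndarray
    frac_positive: float
    binom_p: float
    n_nonzero: int


def segment_skeleton(zo1_frame: np.ndarray, smooth_sigma: float = 1.0,
                     min_branch_um: float = 2.0, pixel_size: float = 1.0,
                     threshold: float | None = None) -> np.ndarray:
    """Binary 1-px skeleton of a junction fluorescence image.

    Gaussian smooth, global threshold (Otsu unless a fixed value is given),
    morphological skeletonization, then pruning of terminal branches
    shorter than ``min_branch_um``.
    """
    frame = np.asarray(zo1_frame, float)
    sm = filters.gaussian(frame, smooth_sigma, preserve_range=True)
    thr = filters.threshold_otsu(sm) if threshold is None else threshold
    fg = sm > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    skel = morphology.skeletonize(fg)
    min_branch_px = min_branch_um / pixel_size
    for _ in range(3):  # pruning can expose new spurs; a few rounds suffice
        pruned = _prune_spurs(skel, min_branch_px)
        if pruned.sum() == skel.sum():
            break
        skel = morphology.skeletonize(pruned)
    return skel


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    cnt = np.zeros(skel.shape, int)
    for dr, dc in _NEIGHBORS:
        cnt += np.roll(np.roll(skel, dr, axis=0), dc, axis=1)
    return np.where(skel, cnt, 0)


def _prune_spurs(skel: np.ndarray, min_px: float) -> np.ndarray:
    """Remove terminal (endpoint-to-node) branches shorter than min_px."""
    paths = _trace_pixel_paths(skel)
    out = skel.copy()
    deg = _neighbor_counts(skel)
    for pix in paths:
        arr = np.array(pix)
        length = np.sum(np.hypot(*np.diff(arr, axis=0).T))
        ends_deg = deg[pix[0][0], pix[0][1]], deg[pix[-1][0], pix[-1][1]]
        if length < min_px and min(ends_deg) <= 1:
            interior = pix if max(ends_deg) <= 1 else pix[:-1] if ends_deg[1] > 2 else pix[1:]
            for r, c in interior:
                # keep branch points themselves
                if deg[r, c] <= 2:
                    out[r, c] = False
    return out


def _trace_pixel_paths(skel: np.ndarray) -> list[list[tuple[int, int]]]:
    """Node-to-node pixel runs of a 1-px skeleton.

    Node pixels (degree != 2) that touch each other are collapsed into one
    node cluster — skeletonization leaves small clumps at branch points —
    and each run of degree-2 pixels connecting two clusters is emitted as
    one path.  Pure cycles (every pixel degree 2) are emitted closed,
    starting at their lexicographically smallest pixel: an arbitrary but
    deterministic split point.
    """
    skel = np.asarray(skel, bool)
    deg = _neighbor_counts(skel)
    pixels = set(zip(*np.nonzero(skel)))
    if not pixels:
        return []

    def nbrs(p):
        return [(p[0] + dr, p[1] + dc) for dr, dc in _NEIGHBORS
                if (p[0] + dr, p[1] + dc) in pixels]

    node_px = {p for p in pixels if deg[p] != 2}
    # cluster adjacent node pixels
    cluster_of = {}
    for start in sorted(node_px):
        if start in cluster_of:
            continue
        cid = len(set(cluster_of.values()))
        stack = [start]
        while stack:
            p = stack.pop()
            if p in cluster_of:
                continue
            cluster_of[p] = cid
            stack.extend(q for q in nbrs(p) if q in node_px and q not in cluster_of)

    visited = set()  # interior (degree-2) pixels already assigned to a path
    paths = []
    for node in sorted(node_px):
        for first in sorted(nbrs(node)):
            if first in node_px or first in visited:
                continue
            path = [node, first]
            prev, cur = node, first
            while cur not in node_px:
                visited.add(cur)
                options = [q for q in nbrs(cur) if q != prev and q not in visited]
                if not options:
                    break
                # a reachable node pixel terminates the run
                node_opts = [q for q in options if q in node_px]
                step = sorted(node_opts)[0] if node_opts else sorted(options)[0]
                prev, cur = cur, step
                path.append(cur)
            if len(path) >= 2:
                paths.append(path)
    # pure cycles: leftover degree-2 pixels not reached from any node
    remaining = sorted(pixels - visited - node_px)
    seen = set()
    for start in remaining:
        if start in seen:
            continue
        cyc = [start]
        prev, cur = None, start
        while True:
            options = [q for q in nbrs(cur) if q != prev]
            if not options:
                break
            prev, cur = cur, sorted(options)[0]
            if cur == start:
                cyc.append(start)
                break
            cyc.append(cur)
        seen.update(cyc)
        if len(cyc) >= 4:
            paths.append(cyc)
    return paths


def trace_paths(skeleton: np.ndarray, pixel_size: float = 1.0) -> list[JunctionPath]:
    """Trace a 1-px skeleton into node-to-node :class:`JunctionPath`s.

    Nodes are endpoints and branch points (>= 3 neighbours); cycles are
    emitted as closed paths (first == last point) split at a deterministic
    pixel.  An empty skeleton yields an empty list.
    """
    out = []
    for pix in _trace_pixel_paths(np.asarray(skeleton, bool)):
        pts = np.array([(c * pixel_size, r * pixel_size) for r, c in pix])
        keep = np.ones(len(pts), bool)
        keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
        pts = pts[keep]
        if len(pts) >= 2:
            out.append(JunctionPath(pts))
    return out


def split_closed(path: JunctionPath) -> list[JunctionPath]:
    """Split a closed path at its two farthest-apart points into two open
    halves (how loops are scored for tortuosity)."""
    if not path.is_closed:
        return [path]
    pts = path.points[:-1]
    d = np.hypot(*(pts - pts[0]).T)
    k = int(np.argmax(d))
    if k == 0:
        raise ValueError("degenerate closed path")
    half1 = pts[:k + 1]
    half2 = np.vstack([pts[k:], pts[:1]])
    return [JunctionPath(half1), JunctionPath(half2)]


def tortuosity(path: JunctionPath) -> TortuosityResult:
    """Arc-chord ratio of a path: total length / endpoint distance (>= 1)."""
    arc = float(np.sum(np.hypot(*np.diff(path.points, axis=0).T)))
    chord = float(np.hypot(*(path.points[-1] - path.points[0])))
    if chord == 0:
        raise ValueError("closed path has zero chord; split it first "
                         "(see split_closed)")
    return TortuosityResult(arc_um=arc, chord_um=chord, ratio=arc / chord)


def fit_ellipse(cell_mask: RoiMask, pattern_axis_deg: float = 0.0,
                pixel_size: float = 1.0) -> EllipseFit:
    """Moment-equivalent ellipse of a cell mask.

    Second central moments give the principal axes; polarization is the
    major/minor axis ratio and theta the signed axial angle between the
    major axis and the pattern axis, in (-90, 90].  Near-isotropic masks
    (polarization ~ 1) have an ill-defined orientation and are flagged
    degenerate with theta reported as 0.
    """
    rows, cols = np.nonzero(cell_mask.mask)
    if rows.size < 10:
        raise ValueError("mask too small to fit an ellipse (< 10 px)")
    x = cols.astype(float)
    y = rows.astype(float)
    mx, my = x.mean(), y.mean()
    cxx = np.mean((x - mx) ** 2)
    cyy = np.mean((y - my) ** 2)
    cxy = np.mean((x - mx) * (y - my))
    cov = np.array([[cxx, cxy], [cxy, cyy]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    if evals[1] <= 0:
        raise ValueError("degenerate mask: zero variance")
    lam_minor = max(evals[0], 0.0)
    lam_major = evals[1]
    major = 4.0 * np.sqrt(lam_major) * pixel_size
    minor = 4.0 * np.sqrt(lam_minor) * pixel_size
    if lam_minor == 0:
        polarization = np.inf
    else:
        polarization = float(np.sqrt(lam_major / lam_minor))
    vx, vy = evecs[:, 1]  # (d_col, d_row) of the major axis
    axis_angle = angles.wrap_axial_deg(angles.vector_angle_deg(vx, vy))
    degenerate = polarization < 1.02
    theta = 0.0 if degenerate else float(
        angles.signed_axial_diff_deg(axis_angle, pattern_axis_deg))
    return EllipseFit(
        centroid_um=(float(mx * pixel_size), float(my * pixel_size)),
        major_um=float(major), minor_um=float(minor),
        polarization=polarization, theta_deg=theta, degenerate=degenerate)


def boundary_angle_chirality(paths: list[JunctionPath],
                             ap_axis_deg: float = 0.0) -> BoundaryAngleDistribution:
    """Signed chord angles of junction paths relative to the AP axis.

    Each path contributes the axial angle of its chord minus the AP axis,
    in (-90, 90].  frac_positive counts angles > 0 among nonzero angles;
    binom_p is the exact two-sided binomial test against an even L-R split.
    """
    if not paths:
        raise ValueError("no paths")
    ang = []
    for p in paths:
        dx, dy = p.chord_vector
        if dx == 0 and dy == 0:
            continue
        chord_angle = angles.wrap_axial_deg(angles.vector_angle_deg(dx, dy))
        ang.append(angles.signed_axial_diff_deg(chord_angle, ap_axis_deg))
    ang = np.asarray(ang, float)
    nonzero = ang[ang != 0]
    if nonzero.size == 0:
        raise ValueError("all chord angles are exactly zero")
    npos = int(np.sum(nonzero > 0))
    res = stats.binomtest(npos, nonzero.size, 0.5, alternative="two-sided")
    return BoundaryAngleDistribution(
        angles_deg=ang, frac_positive=npos / nonzero.size,
        binom_p=float(res.pvalue), n_nonzero=int(nonzero.size))
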