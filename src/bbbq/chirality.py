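"""Left-right asymmetric alignment (chirality) of cells on micropatterns.

The method quantifies how cellular texture deviates from the reference
direction of the underlying pattern.  Per-pixel axial orientations are
obtained from Gaussian-derivative intensity gradients; each grid subregion
deposits its pixels into a von Mises accumulator (on doubled angles) to find
the dominant local direction; the signed axial deviation of that direction
from the circumferential tangent (ring) or pattern axis (line) is the
subregion's bias angle.  Biases are summarized with circular statistics and
a Rayleigh test.  Positive bias = counterclockwise on screen; negative =
clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pingouin
from scipy import ndimage

from . import angles
from .core_io import PatternGeometry, RoiMask

__all__ = [
    "OrientationField",
    "SubregionResult",
    "BiasSummary",
    "orientation_field",
    "dominant_directions",
    "bias_from_geometry",
    "summarize_bias",
    "analyze_pattern",
]


@dataclass
class OrientationField:
    """Per-pixel axial texture orientation in [0, 180) deg plus gradient
    magnitude (0 where the image is locally constant)."""

    orientation: np.ndarray
    magnitude: np.ndarray

    def __post_init__(self):
        if self.orientation.shape != self.magnitude.shape:
            raise ValueError("orientation/magnitude shapes differ")


@dataclass
class SubregionResult:
    """Dominant direction and bias for one grid subregion."""

    centroid_um: tuple[float, float]
    dominant_deg: float
    resultant_length: float
    n_pixels: int
    bias_deg: float = np.nan
    reliable: bool = True


@dataclass
class BiasSummary:
    """Circular summary of subregion biases.

    classification is CCW iff mean_bias > 0 and rayleigh_p < alpha, CW iff
    mean_bias < 0 and rayleigh_p < alpha, otherwise none.
    """

    mean_bias_deg: float
    circ_sd_deg: float
    n_subregions: int
    rayleigh_p: float
    classification: str
    alpha: float = 0.05


def orientation_field(frame: np.ndarray, sigma_px: float = 2.0) -> OrientationField:
    """Axial texture orientation from Gaussian first-derivative gradients.

    The texture runs perpendicular to the intensity gradient, so the
    orientation is the gradient direction rotated by 90 deg, reduced mod
    180.  A constant image yields zero magnitude everywhere (valid; callers
    should treat zero-magnitude pixels as uninformative).
    """
    frame = np.asarray(frame, float)
    if sigma_px <= 0:
        raise ValueError("sigma_px must be > 0")
    if min(frame.shape) < 3 * sigma_px:
        raise ValueError("frame smaller than 3 sigma in some dimension")
    gy = ndimage.gaussian_filter(frame, sigma_px, order=(1, 0))  # d/d(row)
    gx = ndimage.gaussian_filter(frame, sigma_px, order=(0, 1))  # d/d(col)
    grad_angle = angles.vector_angle_deg(gx, gy)
    orientation = angles.wrap_axial_deg(grad_angle + 90.0)
    magnitude = np.hypot(gx, gy)
    return OrientationField(orientation=orientation, magnitude=magnitude)


def _vm_accumulator_peak(theta_deg, weights, kappa):
    """Dominant axial direction by a von Mises accumulator.

    Doubled angles are binned at 1 degree; each pixel deposits a von Mises
    kernel of concentration kappa weighted by gradient magnitude.  The peak
    bin is refined by quadratic (parabolic) sub-bin interpolation.
    """
    nbins = 360  # 1 deg bins on doubled angles
    doubled = np.mod(2.0 * np.asarray(theta_deg, float), 360.0)
    hist, _ = np.histogram(doubled, bins=nbins, range=(0, 360), weights=weights)
    centers = np.arange(nbins) + 0.5
    kernel = np.exp(kappa * np.cos(np.radians(centers - centers[nbins // 2])))
    kernel /= kernel.sum()
    acc = np.real(np.fft.ifft(np.fft.fft(hist) * np.fft.fft(np.fft.ifftshift(kernel))))
    b = int(np.argmax(acc))
    c0, cm, cp = acc[b], acc[(b - 1) % nbins], acc[(b + 1) % nbins]
    denom = cm - 2 * c0 + cp
    shift = 0.5 * (cm - cp) / denom if denom < 0 else 0.0
    peak_doubled = np.mod(centers[b] + shift, 360.0)
    return angles.wrap_axial_deg(peak_doubled / 2.0)


def dominant_directions(fieldmap: OrientationField, roi: RoiMask,
                        grid_px: int = 32, kappa: float = 8.0,
                        mag_quantile: float = 0.25, min_pixels: int = 30,
                        min_mask_frac: float = 0.5,
                        pixel_size: float = 1.0) -> list[SubregionResult]:
    """Partition the ROI into grid subregions and find each one's dominant
    axial direction via the von Mises accumulator.

    Pixels below the ``mag_quantile`` gradient-magnitude quantile (computed
    within the ROI) are discarded; subregions with fewer than ``min_pixels``
    survivors or less than ``min_mask_frac`` of their pixels inside the ROI
    are dropped.  Subregions with near-zero circular resultant (two equal
    crossed populations) are flagged unreliable.
    """
    if grid_px < 8:
        raise ValueError("grid_px must be >= 8")
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    mask = roi.mask
    if mask.shape != fieldmap.orientation.shape:
        raise ValueError("ROI shape does not match the orientation field")
    if not mask.any():
        raise ValueError("empty ROI")
    thresh = np.quantile(fieldmap.magnitude[mask], mag_quantile)
    results = []
    nrows, ncols = mask.shape
    for r0 in range(0, nrows, grid_px):
        for c0 in range(0, ncols, grid_px):
            sub = np.s_[r0:min(r0 + grid_px, nrows), c0:min(c0 + grid_px, ncols)]
            m = mask[sub]
            if m.mean() < min_mask_frac:
                continue
            ori = fieldmap.orientation[sub][m]
            mag = fieldmap.magnitude[sub][m]
            keep = (mag >= thresh) & (mag > 0)
            if keep.sum() < min_pixels:
                continue
            ori, mag = ori[keep], mag[keep]
            dominant = _vm_accumulator_peak(ori, mag, kappa)
            _, rlen = angles.axial_resultant(ori, mag)
            rows_idx, cols_idx = np.nonzero(m)
            cy = (rows_idx + r0).mean() * pixel_size
            cx = (cols_idx + c0).mean() * pixel_size
            results.append(SubregionResult(
                centroid_um=(float(cx), float(cy)),
                dominant_deg=float(dominant),
                resultant_length=float(rlen),
                n_pixels=int(keep.sum()),
                reliable=bool(rlen > 0.1),
            ))
    return results


def bias_from_geometry(results: list[SubregionResult],
                       geometry: PatternGeometry) -> list[SubregionResult]:
    """Fill each subregion's signed bias relative to the pattern reference.

    Ring: reference = tangent to the circle through the subregion centroid.
    Line: reference = the pattern axis.  Bias is the signed axial difference
    (dominant - reference) in (-90, 90], positive = counterclockwise.
    """
    out = []
    for res in results:
        if geometry.kind == "ring":
            x, y = res.centroid_um
            if np.hypot(x - geometry.center[0], y - geometry.center[1]) == 0:
                raise ValueError("subregion centroid at the ring center: "
                                 "tangent undefined")
            ref = angles.ring_tangent_deg(x, y, geometry.center)
        else:
            ref = geometry.axis_angle
        bias = angles.signed_axial_diff_deg(res.dominant_deg, ref)
        out.append(SubregionResult(
            centroid_um=res.centroid_um, dominant_deg=res.dominant_deg,
            resultant_length=res.resultant_length, n_pixels=res.n_pixels,
            bias_deg=float(bias), reliable=res.reliable))
    return out


def summarize_bias(results: list[SubregionResult],
                   alpha: float = 0.05) -> BiasSummary:
    """Circular mean/SD of subregion biases (on doubled angles, halved
    back), Rayleigh non-uniformity test, and CW/CCW/none classification."""
    biases = np.asarray([r.bias_deg for r in results if np.isfinite(r.bias_deg)])
    if biases.size < 3:
        raise ValueError("need >= 3 subregions with bias values")
    doubled = np.radians(2.0 * biases)
    z = np.mean(np.exp(1j * doubled))
    rlen = np.abs(z)
    mean_bias = np.degrees(np.angle(z)) / 2.0  # in (-90, 90]
    if np.isclose(mean_bias, -90.0):
        mean_bias = 90.0
    circ_sd = (np.degrees(np.sqrt(-2.0 * np.log(rlen))) / 2.0
               if rlen > 0 else np.inf)
    _, p = pingouin.circ_rayleigh(doubled)
    if p < alpha and mean_bias > 0:
        cls = "CCW"
    elif p < alpha and mean_bias < 0:
        cls = "CW"
    else:
        cls = "none"
    return BiasSummary(mean_bias_deg=float(mean_bias),
                       circ_sd_deg=float(circ_sd),
                       n_subregions=int(biases.size),
                       rayleigh_p=float(p),
                       classification=cls, alpha=alpha)


def analyze_pattern(frame: np.ndarray, geometry: PatternGeometry,
                    pixel_size: float, sigma_px: float = 2.0,
                    grid_px: int = 32, kappa: float = 8.0,
                    mag_quantile: float = 0.25, alpha: float = 0.05,
                    roi: RoiMask | None = None):
    """End-to-end chirality analysis of one frame on one pattern.

    Returns (per-subregion results with bias filled, BiasSummary).
    """
    from .core_io import pattern_mask

    if roi is None:
        roi = pattern_mask(geometry, frame.shape, pixel_size)
    fieldmap = orientation_field(frame, sigma_px=sigma_px)
    subs = dominant_directions(fieldmap, roi, grid_px=grid_px, kappa=kappa,
                               mag_quantile=mag_quantile,
                               pixel_size=pixel_size)
    subs = bias_from_geometry(subs, geometry)
    return subs, summarize_bias(subs, alpha=alpha)
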