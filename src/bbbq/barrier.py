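"""Transwell barrier metrics: TEER area normalization, sodium-fluorescein
permeability coefficient, and group significance testing.

TEER follows the blank-subtracted area normalization
``TEER = (R - Rm) * A`` (ohm * cm^2).  The permeability coefficient uses the
standard two-compartment transwell sink-condition analysis: the apparent
coefficient is the slope of receiver tracer *amount* vs time divided by
(membrane area x donor concentration), and the endothelial contribution is
obtained by series subtraction of the blank (coated, cell-free) insert:
``1/Pe = 1/Papp - 1/Pe_blank``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TeerRecord",
    "PermeabilityRecord",
    "GroupComparison",
    "teer",
    "permeability",
    "compare_groups",
    "DEFAULT_INSERT_AREA_CM2",
]

#: Growth area of a 6-well transwell insert (cm^2).
DEFAULT_INSERT_AREA_CM2 = 4.5


@dataclass
class TeerRecord:
    """One TEER measurement, normalized to the barrier area."""

    r_ohm: float
    r_m_ohm: float
    area_cm2: float
    group: str = ""
    day: int = 0
    teer_ohm_cm2: float = field(init=False)
    negative: bool = field(init=False)

    def __post_init__(self):
        self.teer_ohm_cm2 = teer(self.r_ohm, self.r_m_ohm, self.area_cm2)
        self.negative = self.teer_ohm_cm2 < 0


@dataclass
class PermeabilityRecord:
    """Transwell permeability analysis result (coefficients in cm/s)."""

    pe_apparent: float
    pe_blank: float
    pe_endothelial: float
    slope_per_s: float
    r_squared: float
    area_cm2: float
    group: str = ""


@dataclass
class GroupComparison:
    """Two-sample contrast: Student's two-tailed t-test and fold change."""

    group_a: list
    group_b: list
    t_stat: float
    p_two_tailed: float
    fold_change: float
    welch: bool = False


def teer(r_ohm: float, r_m_ohm: float, area_cm2: float) -> float:
    """Area-normalized TEER: (R - Rm) * A in ohm * cm^2.

    A negative result (measured resistance below the blank) is returned
    as-is; callers flag it via :class:`TeerRecord`.
    """
    if area_cm2 <= 0:
        raise ValueError("area must be > 0")
    return (r_ohm - r_m_ohm) * area_cm2


def patterned_area_fraction_teer(teer_ohm_cm2: float, mask_area_cm2: float,
                                 insert_area_cm2: float) -> float:
    """Optional normalization of TEER by the micropatterned area fraction
    (patterned mask area / insert growth area)."""
    if not (0 < mask_area_cm2 <= insert_area_cm2):
        raise ValueError("mask area must be in (0, insert area]")
    return teer_ohm_cm2 * (mask_area_cm2 / insert_area_cm2)


def permeability(samples, donor_c0: float, area_cm2: float,
                 blank_pe: float | None = None,
                 receiver_volume_ml: float = 1.0,
                 group: str = "") -> PermeabilityRecord:
    """Permeability coefficient from a receiver concentration time series.

    Parameters
    ----------
    samples
        Sequence of (time_s, receiver_concentration) pairs; >= 3 points on
        the linear (sink-condition) phase.
    donor_c0
        Donor compartment concentration, same units as the samples.
    area_cm2
        Membrane area.
    blank_pe
        Apparent permeability of the blank (cell-free, coated) insert in
        cm/s, for series subtraction; None skips the correction.
    receiver_volume_ml
        Receiver compartment volume (mL = cm^3), needed to convert receiver
        concentration to amount.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise ValueError("need >= 3 (time, concentration) samples")
    if donor_c0 <= 0 or area_cm2 <= 0 or receiver_volume_ml <= 0:
        raise ValueError("donor_c0, area and receiver volume must be > 0")
    t, c = samples[:, 0], samples[:, 1]
    res = stats.linregress(t, c)
    slope = res.slope  # concentration / s
    papp = slope * receiver_volume_ml / (area_cm2 * donor_c0)  # cm/s
    if papp < 0:
        raise ValueError("negative flux slope; not a sink-condition series")
    if blank_pe is None:
        pe = papp
        blank = np.inf
    else:
        if blank_pe <= papp:
            raise ValueError("blank permeability must exceed the apparent "
                             "permeability (series subtraction)")
        pe = 0.0 if papp == 0 else 1.0 / (1.0 / papp - 1.0 / blank_pe)
        blank = blank_pe
    return PermeabilityRecord(
        pe_apparent=float(papp), pe_blank=float(blank),
        pe_endothelial=float(pe), slope_per_s=float(slope),
        r_squared=float(res.rvalue ** 2), area_cm2=area_cm2, group=group)


def compare_groups(a, b, welch: bool = False) -> GroupComparison:
    """Two-sample two-tailed t-test (classical Student's by default,
    Welch optional) plus the fold change of group means (mean_b/mean_a)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_ind(b, a, equal_var=not welch)
    fold = b.mean() / a.mean() if a.mean() != 0 else np.inf
    return GroupComparison(group_a=list(a), group_b=list(b),
                           t_stat=float(t_stat), p_two_tailed=float(p),
                           fold_change=float(fold), welch=welch)
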