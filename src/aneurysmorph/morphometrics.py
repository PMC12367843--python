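"""Geometric morphometry of near-spherical intracranial aneurysms.

Every quantity here is derived from five 2D angiographic measurements, all in
millimetres: dome height ``h``, dome width ``w``, two perpendicular neck
diameters ``d1 >= d2``, and parent-vessel radius ``r``.

The central construct is the wall-thickness-to-radius ratio

    WTR = t_A / R_dome,

where the dome radius ``R_dome = sqrt(h*w) / 2`` is half the geometric-mean
dome diameter and the dome wall thickness ``t_A`` is obtained by conserving
the wall material of the elliptical neck disc over the spherical dome surface:

    t_A = (d1 * d2) / (4 * h * w) * t_V.

The parent-vessel wall thickness ``t_V`` comes from a linear correlation of
the wall-thickness-to-lumen-diameter ratio against vessel radius, fitted to
intra-operative measurements of cerebral vessels:

    t_V = (slope * r + intercept) * (2 * r),

with default ``slope = -0.0297`` per mm and ``intercept = 0.1187``.  The
linear ratio crosses zero near ``r = 3.997`` mm; beyond that the model is
meaningless and we raise rather than clamp (a clamped thickness of zero would
silently zero WTR downstream).

Comparator indices: aspect ratio ``AR = h / sqrt(d1*d2)``, bottleneck factor
``BF = w / sqrt(d1*d2)``, size ratio ``SR = max(h, w) / (2*r)``.

Measured heights of ruptured aneurysms are inflated on average by 14.9%
relative to the pre-rupture state; dividing by 1.149 removes this, giving the
corrected (primed) indices WTR', AR', SR'.  BF depends only on width and neck
and is never corrected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .cohort_io import AneurysmRecord

__all__ = [
    "VesselWallModel",
    "MorphometricIndices",
    "DEFAULT_WALL_MODEL",
    "HEIGHT_INFLATION_FACTOR",
    "sphericity_index",
    "vessel_wall_thickness",
    "aneurysm_wall_thickness",
    "dome_radius",
    "apply_height_correction",
    "compute_indices",
    "screen_spherical",
    "SPHERICITY_THRESHOLD",
]

#: Inclusion bound of the sphericity screen (strict "<").
SPHERICITY_THRESHOLD = 0.2

#: Average post-rupture height inflation: measured h of a ruptured aneurysm
#: overestimates the pre-rupture h by 14.9%, so h' = h / 1.149.
HEIGHT_INFLATION_FACTOR = 1.149


class MorphometryDomainError(ValueError):
    """A measurement is outside the domain of a morphometric formula."""


@dataclass(frozen=True)
class VesselWallModel:
    """Linear model for the vessel wall-thickness-to-diameter ratio.

    ``ratio(r) = slope * r + intercept`` (dimensionless), so the predicted
    wall thickness is ``ratio(r) * 2r`` mm.  Coefficients are configurable to
    admit refitted wall-thickness data; the defaults are the published fit to
    intra-operative cerebrovascular measurements.
    """

    slope: float = -0.0297  # per mm
    intercept: float = 0.1187  # dimensionless

    @property
    def max_radius(self) -> float:
        """Radius at which the predicted ratio reaches zero (validity bound)."""
        if self.slope >= 0:
            return math.inf
        return -self.intercept / self.slope

    def ratio(self, r: float) -> float:
        return self.slope * r + self.intercept


DEFAULT_WALL_MODEL = VesselWallModel()


@dataclass(frozen=True)
class MorphometricIndices:
    """Derived quantities for one aneurysm (lengths in mm).

    ``corrected`` is True when the height used was h' = h / 1.149, i.e. the
    post-rupture inflation was removed before computing WTR, AR and SR.
    """

    t_V: float
    t_A: float
    R_dome: float
    WTR: float
    AR: float
    BF: float
    SR: float
    sphericity: float
    corrected: bool = False


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if not value > 0 or not math.isfinite(value):
            raise MorphometryDomainError(
                f"{name} must be a positive finite length, got {value!r}"
            )


def sphericity_index(h: float, w: float) -> float:
    """Shape statistic |h - w| / (h + w), in [0, 1).

    Zero for a perfectly spherical dome (h == w); the study inclusion rule
    keeps aneurysms with index strictly below 0.2.
    """
    _require_positive(h=h, w=w)
    return abs(h - w) / (h + w)


def vessel_wall_thickness(r: float, model: VesselWallModel = DEFAULT_WALL_MODEL) -> float:
    """Parent-vessel wall thickness t_V in mm, from the linear ratio model.

    Raises
    ------
    MorphometryDomainError
        If ``r`` is non-positive, or at/beyond the zero-crossing of the linear
        ratio (r >= 3.997 mm at default coefficients), where the model would
        predict a non-positive wall.
    """
    _require_positive(r=r)
    ratio = model.ratio(r)
    if ratio <= 0:
        raise MorphometryDomainError(
            f"vessel radius outside wall-model validity: r={r:g} mm predicts "
            f"ratio {ratio:g} (validity bound r < {model.max_radius:.4g} mm)"
        )
    return ratio * (2.0 * r)


def aneurysm_wall_thickness(h: float, w: float, d1: float, d2: float, t_V: float) -> float:
    """Dome wall thickness t_A = d1*d2*t_V / (4*h*w), in mm.

    Conserves the elliptical neck disc's wall material (area pi*d1*d2/4,
    thickness t_V) over the spherical dome surface 4*pi*R_dome^2.
    """
    _require_positive(h=h, w=w, d1=d1, d2=d2, t_V=t_V)
    return (d1 * d2) / (4.0 * h * w) * t_V


def dome_radius(h: float, w: float) -> float:
    """Dome radius: geometric mean of height and width, halved (mm)."""
    _require_positive(h=h, w=w)
    return math.sqrt(h * w) / 2.0


def apply_height_correction(h: float) -> float:
    """Remove average post-rupture inflation: h' = h / 1.149 (mm)."""
    _require_positive(h=h)
    return h / HEIGHT_INFLATION_FACTOR


def compute_indices(
    record: "AneurysmRecord",
    correct_for_rupture: bool = False,
    model: VesselWallModel = DEFAULT_WALL_MODEL,
) -> MorphometricIndices:
    """All morphometric indices for one measured aneurysm.

    With ``correct_for_rupture`` the measured height is replaced by
    h' = h / 1.149 in t_A, R_dome, WTR, AR and SR (giving the primed
    variants); width, neck and hence BF are unchanged.  Correction is only
    meaningful for ruptured records and raises otherwise.
    """
    if correct_for_rupture and not record.ruptured:
        raise ValueError(
            f"record {record.id!r}: height correction applies only to ruptured "
            "aneurysms (the inflation being removed is a post-rupture change)"
        )
    h = apply_height_correction(record.h) if correct_for_rupture else record.h
    w, d1, d2, r = record.w, record.d1, record.d2, record.r

    t_V = vessel_wall_thickness(r, model)
    t_A = aneurysm_wall_thickness(h, w, d1, d2, t_V)
    R_dome = dome_radius(h, w)
    neck = math.sqrt(d1 * d2)
    return MorphometricIndices(
        t_V=t_V,
        t_A=t_A,
        R_dome=R_dome,
        WTR=t_A / R_dome,
        AR=h / neck,
        BF=w / neck,
        SR=max(h, w) / (2.0 * r),
        sphericity=sphericity_index(h, w),
        corrected=correct_for_rupture,
    )


def screen_spherical(cohort, threshold: float = SPHERICITY_THRESHOLD):
    """Partition a cohort into near-spherical (kept) and excluded records.

    A record is kept iff ``sphericity_index(h, w) < threshold`` strictly;
    boundary cases are excluded.  Returns ``(kept, excluded)`` cohort tables
    whose records partition the input exhaustively and disjointly.
    """
    from .cohort_io import CohortTable

    kept, excluded = [], []
    for rec in cohort.records:
        if sphericity_index(rec.h, rec.w) < threshold:
            kept.append(rec)
        else:
            excluded.append(rec)
    note = cohort.provenance or "unspecified source"
    return (
        CohortTable(records=kept, provenance=f"{note} [sphericity < {threshold:g}]"),
        CohortTable(records=excluded, provenance=f"{note} [sphericity >= {threshold:g}]"),
    )
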