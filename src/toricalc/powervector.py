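"""Astigmatism power-vector arithmetic.

A spherocylindrical power (sphere S, cylinder C at axis alpha) is represented
as the power vector (EQ, C0, C45):

    EQ  = S + C/2
    C0  = C * cos(2 * alpha)
    C45 = C * sin(2 * alpha)

with the axis taken as the cylinder axis, i.e. the *flat* corneal meridian
when keratometry is written in plus-cylinder form.  Under this convention a
steep vertical cornea (with-the-rule astigmatism) has positive C0 and a steep
horizontal cornea (against-the-rule) has negative C0.

.. warning::
   C0 and C45 here are *full-cylinder* projections — exactly twice the
   Jackson-cross-cylinder components J0/J45 used by some authors.  The factor
   shows up in the defocus equivalent, which carries 1/4 (not 1) on the
   squared astigmatism terms.

Angles are degrees at every public interface and are normalized to [0, 180)
by mod-180 arithmetic; radians appear only inside the trigonometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpheroCylinder",
    "MeridionalPower",
    "PowerVector",
    "normalize_axis",
    "spherocyl_to_powervector",
    "meridional_to_powervector",
    "powervector_to_spherocyl",
    "mirror_for_left_eye",
    "mirror_axis",
    "defocus_equivalent",
    "classify_orientation",
]


def normalize_axis(axis_deg: float) -> float:
    """Map an axis in degrees onto the canonical [0, 180) range."""
    a = float(axis_deg) % 180.0
    # guard against -1e-16 % 180 == 180.0-ish artefacts
    return 0.0 if a >= 180.0 or a <= 0.0 else a


def _require_finite(**values: float) -> None:
    for name, v in values.items():
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class SpheroCylinder:
    """Sphere/cylinder/axis notation for refractions, keratometry and IOLs.

    The cylinder may be written in plus or minus form; the transposed form
    (sphere+cylinder, −cylinder, axis+90°) denotes the same physical power.
    """

    sphere: float
    cylinder: float
    axis: float  # degrees, cylinder axis, normalized to [0, 180)

    def __post_init__(self) -> None:
        _require_finite(sphere=self.sphere, cylinder=self.cylinder, axis=self.axis)
        object.__setattr__(self, "axis", normalize_axis(self.axis))

    def transposed(self) -> "SpheroCylinder":
        return SpheroCylinder(
            self.sphere + self.cylinder, -self.cylinder, self.axis + 90.0
        )

    def to_plus_cylinder(self) -> "SpheroCylinder":
        return self if self.cylinder >= 0 else self.transposed()

    def to_minus_cylinder(self) -> "SpheroCylinder":
        return self if self.cylinder <= 0 else self.transposed()


@dataclass(frozen=True)
class MeridionalPower:
    """Principal-meridian notation: flat/steep powers with the flat axis.

    Regular astigmatism is assumed, so the steep meridian sits at
    ``axis_flat + 90`` and only the flat axis is stored.
    """

    power_flat: float
    power_steep: float
    axis_flat: float  # degrees, normalized to [0, 180)

    def __post_init__(self) -> None:
        _require_finite(
            power_flat=self.power_flat,
            power_steep=self.power_steep,
            axis_flat=self.axis_flat,
        )
        if self.power_steep < self.power_flat:
            raise ValueError(
                "malformed meridional record: steep power "
                f"{self.power_steep} < flat power {self.power_flat}"
            )
        object.__setattr__(self, "axis_flat", normalize_axis(self.axis_flat))

    def to_spherocylinder(self) -> SpheroCylinder:
        """Plus-cylinder form with the cylinder axis on the flat meridian."""
        return SpheroCylinder(
            self.power_flat, self.power_steep - self.power_flat, self.axis_flat
        )


@dataclass(frozen=True)
class PowerVector:
    """The (EQ, C0, C45) triple in dioptres."""

    EQ: float
    C0: float
    C45: float

    def __post_init__(self) -> None:
        _require_finite(EQ=self.EQ, C0=self.C0, C45=self.C45)

    # -- small vector algebra used throughout the pipeline -------------
    def as_array(self) -> np.ndarray:
        return np.array([self.EQ, self.C0, self.C45], dtype=float)

    @classmethod
    def from_array(cls, a) -> "PowerVector":
        a = np.asarray(a, dtype=float).reshape(3)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __add__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.EQ + other.EQ, self.C0 + other.C0, self.C45 + other.C45)

    def __sub__(self, other: "PowerVector") -> "PowerVector":
        return PowerVector(self.EQ - other.EQ, self.C0 - other.C0, self.C45 - other.C45)

    @property
    def cylinder_magnitude(self) -> float:
        """sqrt(C0² + C45²), the full astigmatism magnitude in dioptres."""
        return math.hypot(self.C0, self.C45)


def spherocyl_to_powervector(sc: SpheroCylinder) -> PowerVector:
    """Decompose sphere/cylinder/axis into (EQ, C0, C45)."""
    two_alpha = math.radians(2.0 * sc.axis)
    return PowerVector(
        sc.sphere + sc.cylinder / 2.0,
        sc.cylinder * math.cos(two_alpha),
        sc.cylinder * math.sin(two_alpha),
    )


def meridional_to_powervector(mp: MeridionalPower) -> PowerVector:
    """Decompose flat/steep meridional powers into (EQ, C0, C45)."""
    return spherocyl_to_powervector(mp.to_spherocylinder())


def powervector_to_spherocyl(
    pv: PowerVector, cylinder_sign: str = "plus"
) -> SpheroCylinder:
    """Invert the power-vector decomposition.

    Parameters
    ----------
    cylinder_sign:
        ``"plus"`` returns the plus-cylinder form (axis on the flat
        meridian); ``"minus"`` its transposition.
    """
    cyl = pv.cylinder_magnitude
    if cyl == 0.0:
        sc = SpheroCylinder(pv.EQ, 0.0, 0.0)
    else:
        axis = math.degrees(0.5 * math.atan2(pv.C45, pv.C0))
        sc = SpheroCylinder(pv.EQ - cyl / 2.0, cyl, axis)
    if cylinder_sign == "plus":
        return sc
    if cylinder_sign == "minus":
        return sc.to_minus_cylinder()
    raise ValueError(f"cylinder_sign must be 'plus' or 'minus', got {cylinder_sign!r}")


def mirror_axis(axis_deg: float) -> float:
    """Mirror an axis across the vertical, θ → 180 − θ (mod 180).

    This is the angular equivalent of flipping the sign of C45 and converts
    left-eye axes into the right-eye convention (and back — it is an
    involution).
    """
    return normalize_axis(180.0 - float(axis_deg))


def mirror_for_left_eye(pv: PowerVector) -> PowerVector:
    """Flip the oblique component sign: (EQ, C0, C45) → (EQ, C0, −C45).

    Left and right eyes are mirror-symmetric about the vertical meridian, so
    left-eye power vectors are mirrored to treat all eyes in the right-eye
    convention.  Applying the map twice is the identity.
    """
    return PowerVector(pv.EQ, pv.C0, -pv.C45)


def defocus_equivalent(ref: PowerVector) -> float:
    """Defocus equivalent DEQ = sqrt(EQ² + ¼ C0² + ¼ C45²) in dioptres.

    A scalar summary of a spherocylindrical refractive error; reduces to
    |EQ| for a pure sphere and to |cylinder|/2 for a pure cylinder.  The 1/4
    factors arise because C0/C45 are full-cylinder (not half-cylinder)
    projections.
    """
    return math.sqrt(ref.EQ**2 + 0.25 * ref.C0**2 + 0.25 * ref.C45**2)


def classify_orientation(pv: PowerVector, tol: float = 1e-12) -> str:
    """Classify astigmatism orientation from the steep-meridian angle.

    Returns ``"WTR"`` (steep meridian 60–120°), ``"ATR"`` (0–30° or
    150–180°), ``"OBL"`` (30–60° or 120–150°) or ``"none"`` when the
    astigmatism magnitude is below ``tol``.
    """
    if pv.cylinder_magnitude <= tol:
        return "none"
    flat_axis = math.degrees(0.5 * math.atan2(pv.C45, pv.C0)) % 180.0
    steep = (flat_axis + 90.0) % 180.0
    if 60.0 <= steep <= 120.0:
        return "WTR"
    if steep <= 30.0 or steep >= 150.0:
        return "ATR"
    return "OBL"
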