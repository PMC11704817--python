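"""Paraxial astigmatic optics of the pseudophakic eye.

Spherocylindrical powers and vergences are handled as symmetric 2x2 dioptric
matrices so that surfaces with arbitrary (non-aligned) astigmatic axes can be
added and propagated.  The bijection with power vectors is

    m11 = EQ - C0/2,   m22 = EQ + C0/2,   m12 = m21 = -C45/2

whose eigenvalues are the two principal powers and whose half-trace is EQ.

The eye model has three thin refracting elements: the spectacle correction at
a vertex distance in front of the cornea (air, n = 1.0), the cornea, and the
toric IOL at the effective lens position (ELP) behind it, with aqueous
(n_A = 1.336) between cornea and IOL and vitreous (n_V = 1.336) between IOL
and the focal plane at the axial length.  The ELP follows the Haigis linear
regression on ACD and AL.

Two directions through this model are implemented:

* ``simulate_refraction`` — given the corneal power, the IOL and the
  geometry, compute the spectacle refraction (the forward model);
* ``reconstruct_rcp`` — given the refraction and the IOL, back-calculate the
  corneal power (RCP, "reconstructed corneal power").  It is the exact
  algebraic inverse of the forward model.

Lengths are millimetres at the public interface (as reported by biometers)
and metres internally; all powers and vergences are dioptres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .powervector import (
    PowerVector,
    SpheroCylinder,
    powervector_to_spherocyl,
    spherocyl_to_powervector,
)

__all__ = [
    "DegenerateVergenceError",
    "EyeModelConstants",
    "HaigisConstants",
    "TORBI709",
    "LISA939",
    "PseudophakicGeometry",
    "powervector_to_matrix",
    "matrix_to_powervector",
    "translate_vergence",
    "haigis_elp",
    "iol_to_spherocylinder",
    "reconstruct_rcp",
    "simulate_refraction",
]

_I2 = np.eye(2)


class DegenerateVergenceError(ValueError):
    """A vergence focuses exactly at (or pathologically near) the next plane."""


@dataclass(frozen=True)
class EyeModelConstants:
    """Fixed constants of the paraxial pseudophakic eye model.

    vertex_distance : metres between spectacle plane and cornea (0.012).
    object_distance : metres from object to spectacle plane (6.0, the
        refraction lane), giving an object vergence of -1/6 D.
    n_spectacle_to_cornea : refractive index of the spectacle-cornea gap.
    n_aqueous, n_vitreous : indices between cornea/IOL and IOL/retina.
    """

    vertex_distance: float = 0.012
    object_distance: float = 6.0
    n_spectacle_to_cornea: float = 1.0
    n_aqueous: float = 1.336
    n_vitreous: float = 1.336

    def __post_init__(self) -> None:
        if self.vertex_distance <= 0 or self.object_distance <= 0:
            raise ValueError("distances must be positive")
        if min(self.n_spectacle_to_cornea, self.n_aqueous, self.n_vitreous) < 1.0:
            raise ValueError("refractive indices must be >= 1")

    @property
    def object_vergence(self) -> float:
        """Vergence of the far object at the spectacle plane, in dioptres."""
        return -1.0 / self.object_distance


@dataclass(frozen=True)
class HaigisConstants:
    """Haigis ELP regression constants: ELP = a0 + a1*ACD + a2*AL (mm)."""

    a0: float
    a1: float
    a2: float
    lens_model: str = "custom"


#: IOLCon constants for the Zeiss AT TORBI 709 monofocal toric lens.
TORBI709 = HaigisConstants(0.912, 0.4, 0.1, "TORBI709")
#: IOLCon constants for the Zeiss AT LISA 939 trifocal toric lens.
LISA939 = HaigisConstants(0.96, 0.4, 0.1, "LISA939")

HAIGIS_BY_MODEL = {"TORBI709": TORBI709, "LISA939": LISA939}


@dataclass(frozen=True)
class PseudophakicGeometry:
    """Axial geometry of one pseudophakic eye, in millimetres."""

    axial_length: float
    elp: float

    def __post_init__(self) -> None:
        if not (0.0 < self.elp < self.axial_length):
            raise ValueError(
                f"need 0 < ELP < AL, got ELP={self.elp}, AL={self.axial_length}"
            )


def powervector_to_matrix(pv: PowerVector) -> np.ndarray:
    """Symmetric 2x2 dioptric matrix of a power vector."""
    return np.array(
        [
            [pv.EQ - pv.C0 / 2.0, -pv.C45 / 2.0],
            [-pv.C45 / 2.0, pv.EQ + pv.C0 / 2.0],
        ]
    )


def matrix_to_powervector(m: np.ndarray) -> PowerVector:
    """Inverse of :func:`powervector_to_matrix` (symmetrizes its input)."""
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2):
        raise ValueError(f"expected a 2x2 matrix, got shape {m.shape}")
    m12 = 0.5 * (m[0, 1] + m[1, 0])
    return PowerVector(
        0.5 * (m[0, 0] + m[1, 1]), m[1, 1] - m[0, 0], -2.0 * m12
    )


def _spherocyl_matrix(sc: SpheroCylinder) -> np.ndarray:
    return powervector_to_matrix(spherocyl_to_powervector(sc))


def translate_vergence(
    V: np.ndarray, distance: float, n: float, direction: str = "forward"
) -> np.ndarray:
    """Propagate a vergence matrix through a homogeneous gap.

    Forward (along the light, over reduced distance d/n):
    ``V' = V (I - (d/n) V)^(-1)``; backward is the exact inverse,
    ``V = V' (I + (d/n) V')^(-1)``.  Zero distance is the identity.

    Raises
    ------
    DegenerateVergenceError
        if the beam focuses exactly within the gap, which would send the
        transformed vergence to infinity.
    """
    V = np.asarray(V, dtype=float)
    tau = distance / n
    if direction == "forward":
        A = _I2 - tau * V
    elif direction == "backward":
        A = _I2 + tau * V
    else:
        raise ValueError(f"direction must be 'forward' or 'backward', got {direction!r}")
    det = np.linalg.det(A)
    if abs(det) < 1e-9:
        raise DegenerateVergenceError(
            f"vergence focuses at the translation interval (|det| = {abs(det):.2e})"
        )
    out = V @ np.linalg.inv(A)
    return 0.5 * (out + out.T)  # kill float asymmetry


def haigis_elp(acd: float, al: float, constants: HaigisConstants) -> float:
    """Effective lens position ELP = a0 + a1*ACD + a2*AL, all in mm."""
    if not (math.isfinite(acd) and math.isfinite(al)):
        raise ValueError("ACD and AL must be finite")
    if not (1.0 < acd < 6.0) or not (15.0 < al < 40.0):
        warnings.warn(
            f"biometry outside the plausible range (ACD={acd} mm, AL={al} mm)",
            stacklevel=2,
        )
    return constants.a0 + constants.a1 * acd + constants.a2 * al


def iol_to_spherocylinder(iolseq: float, iolc: float, iolma: float) -> SpheroCylinder:
    """Labelled toric IOL power as a spherocylinder.

    IOLSEQ is the labelled equivalent power and IOLC the full cylinder; the
    marked axis IOLMA denotes the *flat* axis of the lens, so the principal
    powers are IOLSEQ -/+ IOLC/2 at IOLMA / IOLMA+90.
    """
    if iolc < 0:
        raise ValueError("labelled IOL cylinder must be non-negative")
    return SpheroCylinder(iolseq - iolc / 2.0, iolc, iolma)


def _vergence_behind_cornea(
    iol: SpheroCylinder, geometry: PseudophakicGeometry, constants: EyeModelConstants
) -> np.ndarray:
    """Path B: from the focal plane backwards to just behind the cornea."""
    al_m = geometry.axial_length / 1000.0
    elp_m = geometry.elp / 1000.0
    # spherical vergence behind the IOL: reciprocal of the reduced distance
    # (AL - ELP)/n_V to the focal plane
    v_behind_iol = constants.n_vitreous / (al_m - elp_m) * _I2
    v_front_iol = v_behind_iol - _spherocyl_matrix(iol)
    return translate_vergence(v_front_iol, elp_m, constants.n_aqueous, "backward")


def reconstruct_rcp(
    refraction: SpheroCylinder,
    iol: SpheroCylinder,
    geometry: PseudophakicGeometry,
    constants: EyeModelConstants = EyeModelConstants(),
) -> PowerVector:
    """Back-calculate the corneal power from refraction and toric IOL data.

    Path A runs forward from object space: the object vergence at the
    spectacle plane (-1/6 D for a 6 m lane) plus the spectacle refraction is
    translated through the vertex distance, giving the vergence in front of
    the cornea.  Path B runs backward from the focal plane: the spherical
    vergence n_V/(AL-ELP) behind the IOL, minus the labelled IOL power,
    back-translated through the ELP, gives the vergence behind the cornea.
    The reconstructed corneal power (RCP) is their difference, returned as a
    power vector.

    The IOL spherocylinder must carry the marked flat axis (IOLMA); use
    :func:`iol_to_spherocylinder` to build it from labelled powers.
    """
    v_spectacle = _spherocyl_matrix(refraction) + constants.object_vergence * _I2
    v_front_cornea = translate_vergence(
        v_spectacle,
        constants.vertex_distance,
        constants.n_spectacle_to_cornea,
        "forward",
    )
    v_behind_cornea = _vergence_behind_cornea(iol, geometry, constants)
    return matrix_to_powervector(v_behind_cornea - v_front_cornea)


def simulate_refraction(
    cornea: PowerVector,
    iol: SpheroCylinder,
    geometry: PseudophakicGeometry,
    constants: EyeModelConstants = EyeModelConstants(),
    cylinder_sign: str = "minus",
) -> SpheroCylinder:
    """Spectacle refraction of an eye with known corneal power and toric IOL.

    Exact inverse of :func:`reconstruct_rcp`: for every valid configuration
    ``reconstruct_rcp(simulate_refraction(K, ...), ...) == K`` to float
    tolerance.  Returned in minus-cylinder form by default (clinical
    convention), without any step quantization.
    """
    v_behind_cornea = _vergence_behind_cornea(iol, geometry, constants)
    v_front_cornea = v_behind_cornea - powervector_to_matrix(cornea)
    v_spectacle = translate_vergence(
        v_front_cornea,
        constants.vertex_distance,
        constants.n_spectacle_to_cornea,
        "backward",
    )
    ref_matrix = v_spectacle - constants.object_vergence * _I2
    return powervector_to_spherocyl(matrix_to_powervector(ref_matrix), cylinder_sign)
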