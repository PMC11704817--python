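"""Synthetic toric-IOL cohorts with the statistical structure of the source data.

The generator emulates, eye by eye, the measurement set of a retrospective
toric-IOL series: biometry (AL, ACD), preoperative keratometry and total
corneal power, the implanted toric lens (equivalent power targeted at
emmetropia through the paraxial eye model, cylinder matched to the corneal
astigmatism, marked axis aligned with the steep corneal meridian plus
misalignment noise), postoperative corneal powers, a manifest refraction
simulated through the same vergence optics and quantized to trial-lens
steps, and visual acuities.  Default distribution parameters are the
published cohort's marginal means and SDs (see :mod:`toricalc.published`).

A ground-truth mode replaces the physical postoperative cornea by
``map(preoperative keratometry vector) + noise`` for a configurable linear
map, so that reconstructing RCP from the generated refractions recovers the
map exactly up to the configured noise — the harness for parameter-recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import published
from .nomogram import LinearMapModel
from .powervector import (
    MeridionalPower,
    PowerVector,
    SpheroCylinder,
    meridional_to_powervector,
    mirror_axis,
    mirror_for_left_eye,
    powervector_to_spherocyl,
    defocus_equivalent,
    spherocyl_to_powervector,
)
from .vergence import (
    HAIGIS_BY_MODEL,
    EyeModelConstants,
    HaigisConstants,
    PseudophakicGeometry,
    haigis_elp,
    iol_to_spherocylinder,
    reconstruct_rcp,
    simulate_refraction,
)

__all__ = [
    "CohortConfig",
    "EyeRecord",
    "generate_cohort",
    "cohort_to_modelling_table",
    "reconstruct_rcp_for_record",
]

_CS = published.COHORT_SUMMARY
_PV = published.POWER_VECTOR_SUMMARY


@dataclass(frozen=True)
class CohortConfig:
    """Distributional parameters of the synthetic cohort.

    Defaults reproduce the marginal means/SDs of the published N = 442
    cohort (right-eye convention for C45).  All SDs in the units of the
    quantity; powers dioptres, lengths mm, acuities LogMAR, axes degrees.
    """

    n_eyes: int = 442
    seed: int = 0
    p_right: float = _CS["fraction_right_eyes"]
    # biometry
    al_mean: float = _CS["AL_mm"]["mean"]
    al_sd: float = _CS["AL_mm"]["sd"]
    acd_mean: float = _CS["ACD_mm"]["mean"]
    acd_sd: float = _CS["ACD_mm"]["sd"]
    al_acd_corr: float = 0.4  # assumed; not reported for the source cohort
    # preoperative keratometry power vector (right-eye convention)
    k_eq_mean: float = _PV["preop_keratometry"]["EQ"]["mean"]
    k_eq_sd: float = _PV["preop_keratometry"]["EQ"]["sd"]
    k_c0_mean: float = _PV["preop_keratometry"]["C0"]["mean"]
    k_c0_sd: float = _PV["preop_keratometry"]["C0"]["sd"]
    k_c45_mean: float = _PV["preop_keratometry"]["C45"]["mean"]
    k_c45_sd: float = _PV["preop_keratometry"]["C45"]["sd"]
    # total corneal power = keratometry + posterior-cornea offset + noise
    tk_eq_offset: float = 0.0631
    tk_c0_offset: float = -0.1648  # against-the-rule shift of the posterior cornea
    tk_c45_offset: float = -0.0439
    tk_noise_sd: float = 0.05
    # surgery
    surgical_change_sd: float = 0.10  # per power-vector component
    axis_misalignment_sd: float = 3.0  # degrees, IOL mark vs target axis
    iol_power_step: float = 0.5
    iol_cyl_min: float = 1.0
    iol_cyl_max: float = 12.0
    p_torbi: float = _CS["n_torbi"] / _CS["n_eyes"]
    # refraction measurement
    refraction_noise_sd: float = 0.25  # per power-vector component
    refraction_step: float = 0.25
    quantize_refraction: bool = True
    # acuities
    acuity_slope: float = 0.22  # LogMAR per dioptre of DEQ
    acuity_intercept: float = 0.015
    acuity_noise_sd: float = 0.10
    acuity_floor: float = -0.2
    cdva_mean: float = 0.03
    cdva_sd: float = 0.10
    # ground-truth mode
    ground_truth_map: Optional[LinearMapModel] = None
    ground_truth_noise_sd: float = 0.27
    max_retries: int = 100


@dataclass(frozen=True)
class EyeRecord:
    """One eye's full measurement set, in device (un-mirrored) convention."""

    eye_id: str
    laterality: str  # "OD" | "OS"
    al_mm: float
    acd_mm: float
    k_pre: MeridionalPower
    tk_pre: MeridionalPower
    k_post: MeridionalPower
    tk_post: MeridionalPower
    iolseq: float
    iolc: float
    iolta: float  # target axis, degrees
    iolma: float  # postoperatively measured marked (flat) axis, degrees
    refraction: SpheroCylinder
    udva_logmar: float
    cdva_logmar: float
    lens_model: str  # "TORBI709" | "LISA939"


def _truncated_biometry(rng: np.random.Generator, cfg: CohortConfig) -> tuple:
    cov = np.array(
        [
            [cfg.al_sd**2, cfg.al_acd_corr * cfg.al_sd * cfg.acd_sd],
            [cfg.al_acd_corr * cfg.al_sd * cfg.acd_sd, cfg.acd_sd**2],
        ]
    )
    mean = np.array([cfg.al_mean, cfg.acd_mean])
    for _ in range(cfg.max_retries):
        al, acd = rng.multivariate_normal(mean, cov)
        if 20.0 < al < 30.0 and 2.0 < acd < 4.5:
            return float(al), float(acd)
    raise RuntimeError("could not sample plausible biometry (check config)")


def _pv_to_meridional(pv: PowerVector) -> MeridionalPower:
    sc = powervector_to_spherocyl(pv, "plus")
    return MeridionalPower(sc.sphere, sc.sphere + sc.cylinder, sc.axis)


def _round_step(x: float, step: float) -> float:
    return round(x / step) * step


def _scalar_meridian_iol_power(
    k_power: float, geometry: PseudophakicGeometry, constants: EyeModelConstants
) -> float:
    """IOL power focusing a plano eye for one corneal principal meridian."""
    v_sp = constants.object_vergence  # plano refraction target
    tau = constants.vertex_distance / constants.n_spectacle_to_cornea
    v_fc = v_sp / (1.0 - tau * v_sp)
    v_bc = v_fc + k_power
    elp_m = geometry.elp / 1000.0
    al_m = geometry.axial_length / 1000.0
    v_front_iol = v_bc / (1.0 - (elp_m / constants.n_aqueous) * v_bc)
    return constants.n_vitreous / (al_m - elp_m) - v_front_iol


def _choose_iol(
    tk_pre: PowerVector,
    geometry: PseudophakicGeometry,
    constants: EyeModelConstants,
    cfg: CohortConfig,
) -> tuple:
    """Labelled (IOLSEQ, IOLC, target axis) for emmetropia on total corneal power."""
    sc = powervector_to_spherocyl(tk_pre, "plus")
    k_flat, k_steep = sc.sphere, sc.sphere + sc.cylinder
    steep_axis = (sc.axis + 90.0) % 180.0
    # the IOL meridian at the corneal flat axis must carry the higher power
    p_at_flat = _scalar_meridian_iol_power(k_flat, geometry, constants)
    p_at_steep = _scalar_meridian_iol_power(k_steep, geometry, constants)
    seq = _round_step(0.5 * (p_at_flat + p_at_steep), cfg.iol_power_step)
    cyl = _round_step(abs(p_at_flat - p_at_steep), cfg.iol_power_step)
    cyl = min(max(cyl, cfg.iol_cyl_min), cfg.iol_cyl_max)
    return seq, cyl, steep_axis


def generate_cohort(config: CohortConfig = CohortConfig()) -> list:
    """Generate a deterministic synthetic cohort of :class:`EyeRecord`.

    All sampling is internal to the right-eye convention; angles of left
    eyes are mirrored (θ → 180−θ) when the record is written, exactly
    undoing the C45 sign-flip used in analysis.
    """
    cfg = config
    if cfg.n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    constants = EyeModelConstants()
    records = []
    for i in range(cfg.n_eyes):
        laterality = "OD" if rng.random() < cfg.p_right else "OS"
        lens_model = "TORBI709" if rng.random() < cfg.p_torbi else "LISA939"
        haigis = HAIGIS_BY_MODEL[lens_model]

        for _ in range(cfg.max_retries):
            al, acd = _truncated_biometry(rng, cfg)
            elp = haigis_elp(acd, al, haigis)
            if 0.5 < elp < al - 2.0:
                break
        else:  # pragma: no cover - pathological configs only
            raise RuntimeError("could not sample a feasible ELP < AL")
        geometry = PseudophakicGeometry(al, elp)

        k_pre = PowerVector(
            rng.normal(cfg.k_eq_mean, cfg.k_eq_sd),
            rng.normal(cfg.k_c0_mean, cfg.k_c0_sd),
            rng.normal(cfg.k_c45_mean, cfg.k_c45_sd),
        )
        tk_noise = rng.normal(0.0, cfg.tk_noise_sd, size=3)
        tk_pre = PowerVector(
            k_pre.EQ + cfg.tk_eq_offset + tk_noise[0],
            k_pre.C0 + cfg.tk_c0_offset + tk_noise[1],
            k_pre.C45 + cfg.tk_c45_offset + tk_noise[2],
        )

        iolseq, iolc, target_axis = _choose_iol(tk_pre, geometry, constants, cfg)
        iolma = (target_axis + rng.normal(0.0, cfg.axis_misalignment_sd)) % 180.0

        # one physical surgical change, shared by keratometry and TK
        delta = rng.normal(0.0, cfg.surgical_change_sd, size=3)
        k_post = PowerVector(k_pre.EQ + delta[0], k_pre.C0 + delta[1], k_pre.C45 + delta[2])
        tk_post = PowerVector(
            tk_pre.EQ + delta[0], tk_pre.C0 + delta[1], tk_pre.C45 + delta[2]
        )

        if cfg.ground_truth_map is not None:
            # the "true" postoperative cornea IS the mapped keratometry vector
            noise = rng.normal(0.0, cfg.ground_truth_noise_sd, size=3)
            tk_post = PowerVector.from_array(
                cfg.ground_truth_map.predict(k_pre).as_array() + noise
            )

        iol_sc = iol_to_spherocylinder(iolseq, iolc, iolma)
        ref = simulate_refraction(tk_post, iol_sc, geometry, constants)
        ref_pv = spherocyl_to_powervector(ref)
        if cfg.ground_truth_map is None and cfg.refraction_noise_sd > 0:
            ref_pv = PowerVector.from_array(
                ref_pv.as_array() + rng.normal(0.0, cfg.refraction_noise_sd, size=3)
            )
        ref_sc = powervector_to_spherocyl(ref_pv, "minus")
        if cfg.quantize_refraction and cfg.ground_truth_map is None:
            ref_sc = SpheroCylinder(
                _round_step(ref_sc.sphere, cfg.refraction_step),
                _round_step(ref_sc.cylinder, cfg.refraction_step),
                round(ref_sc.axis) % 180.0,
            )

        deq = defocus_equivalent(spherocyl_to_powervector(ref_sc))
        udva = max(
            cfg.acuity_floor,
            cfg.acuity_intercept
            + cfg.acuity_slope * deq
            + rng.normal(0.0, cfg.acuity_noise_sd),
        )
        cdva = max(cfg.acuity_floor, rng.normal(cfg.cdva_mean, cfg.cdva_sd))

        mirror = laterality == "OS"

        def dev_pv(pv: PowerVector) -> MeridionalPower:
            return _pv_to_meridional(mirror_for_left_eye(pv) if mirror else pv)

        dev_axis = mirror_axis if mirror else (lambda a: a % 180.0)
        records.append(
            EyeRecord(
                eye_id=f"eye{i:05d}",
                laterality=laterality,
                al_mm=al,
                acd_mm=acd,
                k_pre=dev_pv(k_pre),
                tk_pre=dev_pv(tk_pre),
                k_post=dev_pv(k_post),
                tk_post=dev_pv(tk_post),
                iolseq=iolseq,
                iolc=iolc,
                iolta=dev_axis(target_axis),
                iolma=dev_axis(iolma),
                refraction=SpheroCylinder(
                    ref_sc.sphere, ref_sc.cylinder, dev_axis(ref_sc.axis)
                ),
                udva_logmar=udva,
                cdva_logmar=cdva,
                lens_model=lens_model,
            )
        )
    return records


def _record_complete(rec: EyeRecord) -> bool:
    scalars = [
        rec.al_mm,
        rec.acd_mm,
        rec.iolseq,
        rec.iolc,
        rec.iolta,
        rec.iolma,
        rec.udva_logmar,
        rec.cdva_logmar,
    ]
    return all(v is not None and math.isfinite(v) for v in scalars)


def reconstruct_rcp_for_record(
    rec: EyeRecord,
    haigis: Optional[HaigisConstants] = None,
    constants: EyeModelConstants = EyeModelConstants(),
    right_eye_convention: bool = True,
) -> PowerVector:
    """Back-calculate RCP for one eye record.

    For left eyes all angular inputs (refraction axis, IOL marked axis) are
    mirrored to the right-eye convention before the vergence calculation;
    with ``right_eye_convention=False`` the result is mirrored back to the
    eye's own (device) orientation on output.
    """
    if haigis is None:
        haigis = HAIGIS_BY_MODEL[rec.lens_model]
    elp = haigis_elp(rec.acd_mm, rec.al_mm, haigis)
    geometry = PseudophakicGeometry(rec.al_mm, elp)
    mirror = rec.laterality == "OS"
    ref = rec.refraction
    iolma = rec.iolma
    if mirror:
        ref = SpheroCylinder(ref.sphere, ref.cylinder, mirror_axis(ref.axis))
        iolma = mirror_axis(iolma)
    iol_sc = iol_to_spherocylinder(rec.iolseq, rec.iolc, iolma)
    rcp = reconstruct_rcp(ref, iol_sc, geometry, constants)
    if mirror and not right_eye_convention:
        rcp = mirror_for_left_eye(rcp)
    return rcp


def cohort_to_modelling_table(
    records: Sequence[EyeRecord],
    source: str = "keratometry",
    constants: EyeModelConstants = EyeModelConstants(),
):
    """Paired (X, Y) power-vector arrays for nomogram fitting.

    X holds the preoperative keratometry (or total corneal power) vectors
    and Y the reconstructed corneal power, both in right-eye convention.
    Incomplete records are skipped and counted.

    Returns
    -------
    (X, Y, n_skipped) with X, Y of shape (n, 3).
    """
    if source not in ("keratometry", "total_corneal_power"):
        raise ValueError(f"unknown source {source!r}")
    xs, ys = [], []
    n_skipped = 0
    for rec in records:
        if not _record_complete(rec):
            n_skipped += 1
            continue
        mp = rec.k_pre if source == "keratometry" else rec.tk_pre
        x = meridional_to_powervector(mp)
        if rec.laterality == "OS":
            x = mirror_for_left_eye(x)
        y = reconstruct_rcp_for_record(rec, constants=constants)
        xs.append(x.as_array())
        ys.append(y.as_array())
    if not xs:
        raise ValueError("no complete records")
    return np.vstack(xs), np.vstack(ys), n_skipped
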