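"""Cohort CSV reading/writing with validation.

One wide CSV per cohort, one row per eye, decimal points, empty cells for
missing values, units embedded in the column names (mm, D, deg, LogMAR).
Rows violating the record invariants (axes outside [0, 180), steep power
below flat power, non-finite required fields) are excluded on read and
counted, mirroring the exclusion of incomplete clinical records at source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EyeRecord
from .powervector import MeridionalPower, SpheroCylinder

__all__ = ["COLUMNS", "CohortReadResult", "read_cohort", "write_cohort"]

logger = logging.getLogger("toricalc")

COLUMNS = [
    "eye_id",
    "laterality",
    "AL_mm",
    "ACD_mm",
    "KF_D",
    "KS_D",
    "KA_deg",
    "TKF_D",
    "TKS_D",
    "TKA_deg",
    "KF_post_D",
    "KS_post_D",
    "KA_post_deg",
    "TKF_post_D",
    "TKS_post_D",
    "TKA_post_deg",
    "IOLSEQ_D",
    "IOLC_D",
    "IOLTA_deg",
    "IOLMA_deg",
    "REFS_D",
    "REFC_D",
    "REFA_deg",
    "UDVA_logmar",
    "CDVA_logmar",
    "lens_model",
]

_NUMERIC = [c for c in COLUMNS if c not in ("eye_id", "laterality", "lens_model")]


@dataclass
class CohortReadResult:
    records: list
    n_excluded: int
    exclusion_reasons: list  # (eye_id, reason) pairs


def write_cohort(records, path) -> None:
    """Write eye records to the cohort CSV schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "eye_id": r.eye_id,
                "laterality": r.laterality,
                "AL_mm": r.al_mm,
                "ACD_mm": r.acd_mm,
                "KF_D": r.k_pre.power_flat,
                "KS_D": r.k_pre.power_steep,
                "KA_deg": r.k_pre.axis_flat,
                "TKF_D": r.tk_pre.power_flat,
                "TKS_D": r.tk_pre.power_steep,
                "TKA_deg": r.tk_pre.axis_flat,
                "KF_post_D": r.k_post.power_flat,
                "KS_post_D": r.k_post.power_steep,
                "KA_post_deg": r.k_post.axis_flat,
                "TKF_post_D": r.tk_post.power_flat,
                "TKS_post_D": r.tk_post.power_steep,
                "TKA_post_deg": r.tk_post.axis_flat,
                "IOLSEQ_D": r.iolseq,
                "IOLC_D": r.iolc,
                "IOLTA_deg": r.iolta,
                "IOLMA_deg": r.iolma,
                "REFS_D": r.refraction.sphere,
                "REFC_D": r.refraction.cylinder,
                "REFA_deg": r.refraction.axis,
                "UDVA_logmar": r.udva_logmar,
                "CDVA_logmar": r.cdva_logmar,
                "lens_model": r.lens_model,
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False, float_format="%.10g")


def _row_to_record(row) -> EyeRecord:
    lat = str(row["laterality"])
    if lat not in ("OD", "OS"):
        raise ValueError(f"laterality must be OD or OS, got {lat!r}")
    lens = str(row["lens_model"])
    if not np.all(np.isfinite([row[c] for c in _NUMERIC])):
        raise ValueError("non-finite or missing numeric field")

    def mer(f, s, a):
        return MeridionalPower(float(row[f]), float(row[s]), float(row[a]))

    for a in ("KA_deg", "TKA_deg", "KA_post_deg", "TKA_post_deg", "IOLTA_deg", "IOLMA_deg", "REFA_deg"):
        if not (0.0 <= float(row[a]) < 180.0):
            raise ValueError(f"axis {a} = {row[a]} outside [0, 180)")
    return EyeRecord(
        eye_id=str(row["eye_id"]),
        laterality=lat,
        al_mm=float(row["AL_mm"]),
        acd_mm=float(row["ACD_mm"]),
        k_pre=mer("KF_D", "KS_D", "KA_deg"),
        tk_pre=mer("TKF_D", "TKS_D", "TKA_deg"),
        k_post=mer("KF_post_D", "KS_post_D", "KA_post_deg"),
        tk_post=mer("TKF_post_D", "TKS_post_D", "TKA_post_deg"),
        iolseq=float(row["IOLSEQ_D"]),
        iolc=float(row["IOLC_D"]),
        iolta=float(row["IOLTA_deg"]),
        iolma=float(row["IOLMA_deg"]),
        refraction=SpheroCylinder(
            float(row["REFS_D"]), float(row["REFC_D"]), float(row["REFA_deg"])
        ),
        udva_logmar=float(row["UDVA_logmar"]),
        cdva_logmar=float(row["CDVA_logmar"]),
        lens_model=lens,
    )


def read_cohort(path, strict_header: bool = True) -> CohortReadResult:
    """Read and validate a cohort CSV.

    Unknown or missing columns abort with a column-level message; invalid
    rows are excluded (not fixed up) and returned as (eye_id, reason) pairs.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    unknown = [c for c in df.columns if c not in COLUMNS]
    if unknown and strict_header:
        raise ValueError(f"cohort CSV has unknown columns: {unknown}")
    records, reasons = [], []
    for _, row in df.iterrows():
        try:
            records.append(_row_to_record(row))
        except (ValueError, TypeError) as exc:
            reasons.append((str(row.get("eye_id", "?")), str(exc)))
    if reasons:
        logger.info("excluded %d invalid rows from %s", len(reasons), path)
    return CohortReadResult(records=records, n_excluded=len(reasons), exclusion_reasons=reasons)
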