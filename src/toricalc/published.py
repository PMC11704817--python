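"""Published reference values of the Homburg-Adelaide toric IOL nomogram.

These constants were derived from a clinical cohort of N = 442 eyes
implanted with Zeiss toric lenses (AT TORBI 709, n = 282; AT LISA 939,
n = 160) and biometered with the IOLMaster 700.  They serve three purposes
in this package:

* the published multilinear nomogram coefficients (keratometry -> RCP and
  total corneal power -> RCP) used by :func:`toricalc.nomogram.published_nomogram`;
* marginal summary statistics of the cohort, used as the default calibration
  of the synthetic-cohort generator;
* internally consistent cross-checks (the against-the-rule offset of total
  corneal power vs keratometry, and the 95% error-ellipse area implied by
  the published residual SDs).

All powers are dioptres, lengths millimetres, acuities LogMAR.
"""

from __future__ import annotations

import numpy as np

# ---------------------------------------------------------------------------
# Multilinear nomogram coefficients: predicted RCP = W @ (EQ, C0, C45) + b
# ---------------------------------------------------------------------------

KERATOMETRY_MATRIX = np.array(
    [
        [0.9458, 0.0332, -0.0104],
        [0.0009, 0.9135, -0.0711],
        [0.0129, 0.0315, 0.8557],
    ]
)
KERATOMETRY_INTERCEPT = np.array([2.5173, -0.1031, -0.5451])

TOTAL_CORNEAL_POWER_MATRIX = np.array(
    [
        [0.9523, 0.0360, 0.0011],
        [-0.0196, 0.8931, -0.0342],
        [0.0125, -0.0424, 0.8148],
    ]
)
TOTAL_CORNEAL_POWER_INTERCEPT = np.array([2.1739, 0.9693, -0.4971])

# ---------------------------------------------------------------------------
# Cohort marginal statistics (means and SDs), right-eye convention for C45
# ---------------------------------------------------------------------------

#: Biometry, IOL, refraction and acuity summary of the source cohort.
COHORT_SUMMARY = {
    "n_eyes": 442,
    "fraction_right_eyes": 0.51,
    "n_torbi": 282,
    "n_lisa": 160,
    "AL_mm": {"mean": 23.6688, "sd": 1.2167},
    "ACD_mm": {"mean": 3.1219, "sd": 0.4232},
    "IOLEQ_D": {"mean": 20.1804, "sd": 3.6260},
    "IOLC_D": {"mean": 1.8179, "sd": 0.9590},
    "REFEQ_D": {"mean": -0.0716, "sd": 0.6331},
    "REFC_D": {"mean": 0.3935, "sd": 0.3840},
    "DEQ_D": {"mean": 0.4774, "sd": 0.5036},
    "UDVA_logmar": {"mean": 0.1195, "sd": 0.1886},
    "CDVA_logmar": {"mean": 0.0284, "sd": 0.1412},
}

#: Power-vector summaries (mean, sd) per component, dioptres.
POWER_VECTOR_SUMMARY = {
    "preop_keratometry": {
        "EQ": {"mean": 43.7843, "sd": 1.5160},
        "C0": {"mean": -0.1401, "sd": 1.2984},
        "C45": {"mean": -0.1152, "sd": 0.6970},
    },
    "preop_total_corneal_power": {
        "EQ": {"mean": 43.8474, "sd": 1.5107},
        "C0": {"mean": -0.3049, "sd": 1.3294},
        "C45": {"mean": -0.1591, "sd": 0.7083},
    },
    "postop_keratometry": {
        "EQ": {"mean": 43.8466, "sd": 1.5417},
        "C0": {"mean": -0.0772, "sd": 1.3361},
        "C45": {"mean": -0.1582, "sd": 0.7149},
    },
    "postop_total_corneal_power": {
        "EQ": {"mean": 43.9077, "sd": 1.5398},
        "C0": {"mean": -0.2369, "sd": 1.3497},
        "C45": {"mean": -0.2004, "sd": 0.7438},
    },
}

#: SDs of RCP minus measured corneal power differences (EQ, C0, C45), dioptres.
RCP_DIFFERENCE_SD = {
    "preop_keratometry": (0.4927, 0.5138, 0.5061),
    "preop_total_corneal_power": (0.48853, 0.5169, 0.5193),
    "postop_keratometry": (0.3626, 0.5412, 0.4949),
    "postop_total_corneal_power": (0.3156, 0.2639, 0.2384),
}

#: Published crossvalidation metrics (MDV in D, MSE in D^2) of the nomograms.
PUBLISHED_FIT_METRICS = {
    "REG_keratometry": {
        "train": {"mdv": 0.4014, "mse": 0.2176},
        "test": {"mdv": 0.3834, "mse": 0.2158},
    },
    "REG_total_corneal_power": {
        "train": {"mdv": 0.4017, "mse": 0.2163},
        "test": {"mdv": 0.3767, "mse": 0.2152},
    },
    "NET_keratometry": {
        "train": {"mdv": 0.2886, "mse": 0.1100},
        "test": {"mdv": 0.3679, "mse": 0.2010},
    },
    "NET_total_corneal_power": {
        "train": {"mdv": 0.3029, "mse": 0.1198},
        "test": {"mdv": 0.3443, "mse": 0.1757},
    },
}


def preop_atr_offset() -> float:
    """Mean preoperative C0 of keratometry minus total corneal power, D.

    Total corneal power carries the against-the-rule contribution of the
    posterior corneal surface, shifting its C0 towards negative values; the
    difference (about +0.16 D) is the systematic posterior-cornea offset the
    nomogram absorbs.
    """
    k = POWER_VECTOR_SUMMARY["preop_keratometry"]["C0"]["mean"]
    tk = POWER_VECTOR_SUMMARY["preop_total_corneal_power"]["C0"]["mean"]
    return k - tk
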