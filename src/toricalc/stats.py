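"""Outcome statistics for toric IOL astigmatism analyses.

Residual-based summaries (mean difference vector, generalized mean squared
error), bivariate 95% error ellipses on the (C0, C45) plane, double-angle
plot coordinates, acuity-vs-refraction regressions and axis-binned residual
cylinder summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "mean_difference_vector",
    "mean_squared_error",
    "ErrorEllipse",
    "error_ellipse",
    "chi2_scale",
    "double_angle_coordinates",
    "AcuityRegression",
    "acuity_regression",
    "AxisBinSummary",
    "axis_binned_cylinder_summary",
]


def _residual_matrix(residuals) -> np.ndarray:
    rows = []
    for r in residuals:
        rows.append(r.as_array() if hasattr(r, "as_array") else np.asarray(r, float))
    if not rows:
        raise ValueError("empty residual set")
    mat = np.vstack([np.atleast_1d(r) for r in rows])
    if not np.all(np.isfinite(mat)):
        raise ValueError("residuals must be finite")
    return mat


def mean_difference_vector(residuals) -> float:
    """Mean Euclidean norm of the residual vectors (MDV), dioptres.

    Norms are averaged, not signed components — a symmetric residual cloud
    has MDV > 0 even though its centroid is at the origin.
    """
    mat = _residual_matrix(residuals)
    return float(np.mean(np.linalg.norm(mat, axis=1)))


def mean_squared_error(residuals) -> float:
    """Mean squared Euclidean norm of the residual vectors, dioptres².

    The generalized (vector-valued) MSE; by Jensen's inequality
    ``mean_difference_vector(r) <= sqrt(mean_squared_error(r))``.
    """
    mat = _residual_matrix(residuals)
    return float(np.mean(np.sum(mat**2, axis=1)))


def chi2_scale(coverage: float = 0.95) -> float:
    """Chi-square (2 df) quantile scaling covariance to a coverage ellipse."""
    return float(sps.chi2.ppf(coverage, df=2))


@dataclass(frozen=True)
class ErrorEllipse:
    """A bivariate coverage ellipse on the (C0, C45) plane.

    semi_axes are sqrt(chi2 * eigenvalues of the covariance), dioptres;
    orientation is the angle of the major axis in degrees; area is
    ``pi * chi2 * sqrt(det(cov))`` in dioptres².  ``degenerate`` flags a
    (numerically) singular covariance whose ellipse collapses to a segment.
    """

    centroid: tuple
    semi_axes: tuple
    orientation_deg: float
    area: float
    coverage: float
    degenerate: bool
    covariance: np.ndarray

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points falling inside the ellipse."""
        pts = np.atleast_2d(np.asarray(points, float)) - np.asarray(self.centroid)
        sol = np.linalg.solve(self.covariance, pts.T)
        d2 = np.sum(pts.T * sol, axis=0)
        return d2 <= chi2_scale(self.coverage)

    def boundary(self, n_points: int = 180) -> np.ndarray:
        """(n, 2) polygon of the ellipse boundary, for plotting exports."""
        t = np.linspace(0.0, 2.0 * np.pi, n_points)
        circ = np.stack([np.cos(t), np.sin(t)])
        ang = np.radians(self.orientation_deg)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        pts = rot @ (np.diag(self.semi_axes) @ circ)
        return pts.T + np.asarray(self.centroid)


def error_ellipse(astig_residuals, coverage: float = 0.95) -> ErrorEllipse:
    """95% (by default) error ellipse of 2-component astigmatism residuals.

    The sample covariance is eigen-decomposed; semi-axes and area follow the
    large-sample chi-square(2) scaling (5.9915 at 95%), which is the
    convention under which independent SDs (s1, s2) give an area of
    ``pi * 5.9915 * s1 * s2``.
    """
    mat = _residual_matrix(astig_residuals)
    if mat.shape[1] != 2:
        raise ValueError(f"expected 2-component residuals, got {mat.shape[1]}")
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 residuals for an ellipse")
    centroid = mat.mean(axis=0)
    cov = np.cov(mat, rowvar=False)
    k = chi2_scale(coverage)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    degenerate = bool(evals[0] <= 1e-12 * max(evals[1], 1.0))
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = tuple(float(np.sqrt(k * ev)) for ev in evals)
    orientation = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])) % 180.0)
    area = float(np.pi * k * np.sqrt(max(np.linalg.det(cov), 0.0)))
    return ErrorEllipse(
        centroid=(float(centroid[0]), float(centroid[1])),
        semi_axes=semi,
        orientation_deg=orientation,
        area=area,
        coverage=coverage,
        degenerate=degenerate,
        covariance=cov,
    )


def double_angle_coordinates(cylinder, axis_deg):
    """Double-angle plot coordinates (C cos 2a, C sin 2a).

    Identical to the astigmatism part of the power-vector decomposition;
    vectorized over arrays.  Periodic with period 180° in the axis.
    """
    cylinder = np.asarray(cylinder, dtype=float)
    if np.any(cylinder < 0):
        raise ValueError("cylinder magnitudes must be non-negative")
    two_a = np.radians(2.0 * np.asarray(axis_deg, dtype=float))
    return cylinder * np.cos(two_a), cylinder * np.sin(two_a)


@dataclass(frozen=True)
class AcuityRegression:
    """OLS line of LogMAR acuity on a dioptric predictor."""

    slope_logmar_per_d: float
    slope_lines_per_d: float  # decimal lines per dioptre = 10 x LogMAR slope
    intercept: float
    pearson_r: float
    p_value: float
    n: int


def acuity_regression(acuity, predictor) -> AcuityRegression:
    """Regress LogMAR acuity on a refraction summary (DEQ, |REFEQ| or REFC).

    Returns the slope both in LogMAR/D and in decimal lines per dioptre
    (0.1 LogMAR = 1 line), with Pearson R and its exact two-sided t-test
    p-value.
    """
    a = np.asarray(acuity, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if a.shape != x.shape or a.ndim != 1:
        raise ValueError("acuity and predictor must be paired 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    res = sps.linregress(x, a)
    return AcuityRegression(
        slope_logmar_per_d=float(res.slope),
        slope_lines_per_d=float(10.0 * res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(a.size),
    )


@dataclass(frozen=True)
class AxisBinSummary:
    """Residual-cylinder summary over 8 equidistant axis bins of 22.5°.

    ``cumulative_density`` holds, per bin, the within-bin empirical CDF of
    cylinder magnitude evaluated on ``cyl_grid``; rows of empty bins are NaN
    (flagged via ``counts == 0``), never silently zero.
    """

    bin_edges: np.ndarray  # 9 edges over [0, 180]
    counts: np.ndarray  # (8,)
    means: np.ndarray  # (8,) NaN where empty
    medians: np.ndarray  # (8,) NaN where empty
    cyl_grid: np.ndarray  # (G,)
    cumulative_density: np.ndarray  # (8, G)
    n_total: int
    n_below_min: int


def axis_binned_cylinder_summary(
    cylinders, axes, min_cyl: float = 0.25, grid_step: float = 0.25
) -> AxisBinSummary:
    """Summarize residual refractive cylinder by axis in 8 bins of 22.5°.

    Eyes with cylinder below ``min_cyl`` are excluded (counted in
    ``n_below_min``); an axis of exactly 180° wraps to 0°.
    """
    cyl = np.asarray(cylinders, dtype=float)
    ax = np.asarray(axes, dtype=float)
    if cyl.shape != ax.shape or cyl.ndim != 1:
        raise ValueError("cylinders and axes must be paired 1-D arrays")
    if min_cyl < 0:
        raise ValueError("min_cyl must be non-negative")
    keep = cyl >= min_cyl
    n_below = int(np.sum(~keep))
    cyl, ax = cyl[keep], ax[keep] % 180.0
    edges = np.linspace(0.0, 180.0, 9)
    idx = np.minimum((ax // 22.5).astype(int), 7)
    counts = np.bincount(idx, minlength=8) if cyl.size else np.zeros(8, int)
    cmax = float(cyl.max()) if cyl.size else min_cyl
    grid = np.arange(0.0, cmax + grid_step, grid_step)
    means = np.full(8, np.nan)
    medians = np.full(8, np.nan)
    cdf = np.full((8, grid.size), np.nan)
    for b in range(8):
        vals = cyl[idx == b]
        if vals.size == 0:
            continue
        means[b] = float(np.mean(vals))
        medians[b] = float(np.median(vals))
        cdf[b] = np.searchsorted(np.sort(vals), grid, side="right") / vals.size
    return AxisBinSummary(
        bin_edges=edges,
        counts=counts,
        means=means,
        medians=medians,
        cyl_grid=grid,
        cumulative_density=cdf,
        n_total=int(cyl.size),
        n_below_min=n_below,
    )
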