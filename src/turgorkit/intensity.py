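"""Turgor estimation from cytoplasmic-fluorophore intensity (method 2).

A constitutively expressed cytoplasmic fluorophore reports cytoplasmic
concentration: as a protoplast shrinks under hyperosmotic sorbitol, the
marker concentrates and its background-corrected mean ROI intensity rises
(and vice versa when it swells).  Intensities are normalized against an
intact-cell calibration population imaged on the same slide under identical
settings, so a normalized value of 1.0 means "same cytoplasmic concentration
as intact cells".  A linear regression of normalized intensity against
sorbitol concentration, inverted at 1.0, locates the isotonic point without
requiring volume measurements -- an intensive property that does not depend
on how many cells are sampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .core import IsotonicEstimate, OsmoticCondition, combine_errors_delta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityRecord:
    """One cell's mean ROI fluorescence with its slide-local background."""

    condition: OsmoticCondition
    slide_id: str
    cell_id: str
    roi_mean: float
    background_mean: float

    @property
    def corrected(self) -> float:
        return self.roi_mean - self.background_mean


@dataclass(frozen=True)
class IntensityCalibration:
    """Per-slide intact-cell calibration used to normalize protoplast data."""

    slide_id: str
    intact_mean: float
    intact_var_between_replicates: float = 0.0

    def __post_init__(self) -> None:
        if self.intact_mean <= 0:
            raise ValueError("calibration intact mean must be > 0")
        if self.intact_var_between_replicates < 0:
            raise ValueError("calibration variance must be >= 0")


@dataclass(frozen=True)
class IntensityLinearFit:
    """OLS line of normalized intensity vs. sorbitol concentration.

    ``param_covariance`` is ordered ``(slope, intercept)``; ``fit_window`` is
    the concentration interval actually used.
    """

    slope: float
    intercept: float
    param_covariance: np.ndarray
    fit_window: tuple[float, float]
    n_points: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.param_covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("param_covariance must be 2x2")


def correct_and_normalize(
    records: Sequence[IntensityRecord],
    calibrations: Mapping[str, IntensityCalibration] | Sequence[IntensityCalibration],
) -> np.ndarray:
    """Background-correct and slide-normalize per-cell intensities.

    Returns ``(roi_mean - background_mean) / intact_mean`` per record, NaN
    for flagged records whose corrected intensity is non-positive (their
    count is logged).  Every slide appearing in ``records`` must have a
    calibration.  Because each slide is divided by its own intact-cell mean,
    the result is invariant under any multiplicative gain common to a slide.
    """
    if not isinstance(calibrations, Mapping):
        calibrations = {c.slide_id: c for c in calibrations}
    missing = {r.slide_id for r in records} - set(calibrations)
    if missing:
        raise ValueError(f"no intact-cell calibration for slide(s): {sorted(missing)}")
    out = np.empty(len(records), dtype=float)
    n_flagged = 0
    for i, rec in enumerate(records):
        corrected = rec.corrected
        if corrected <= 0:
            out[i] = np.nan
            n_flagged += 1
            continue
        out[i] = corrected / calibrations[rec.slide_id].intact_mean
    if n_flagged:
        logger.warning(
            "excluded %d/%d cells with non-positive background-corrected intensity",
            n_flagged,
            len(records),
        )
    return out


def fit_intensity_vs_concentration(
    concentrations: Sequence[float],
    normalized: Sequence[float],
    window: tuple[float, float] | None = None,
) -> IntensityLinearFit:
    """OLS line through per-condition mean normalized intensities.

    ``concentrations`` and ``normalized`` are paired per-cell (or
    per-condition) values; cells sharing a sorbitol concentration are
    averaged into one point first.  ``window`` restricts the fit to
    concentrations inside a closed interval -- the regression is meant to be
    local around the intact-cell intensity, and a window excludes conditions
    far from it where the inverse-volume response is visibly curved.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(normalized, dtype=float)
    keep = ~np.isnan(y)
    c, y = c[keep], y[keep]
    if window is not None:
        lo, hi = float(window[0]), float(window[1])
        if hi <= lo:
            raise ValueError("window must be an increasing interval")
        sel = (c >= lo) & (c <= hi)
        c, y = c[sel], y[sel]
    uniq = np.unique(c)
    if uniq.size < 2:
        raise ValueError(
            "need >= 2 distinct sorbitol concentrations inside the window"
        )
    means = np.array([y[c == u].mean() for u in uniq])

    design = sm.add_constant(uniq)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(means, design).fit()
        cov = np.asarray(res.cov_params())
    intercept, slope = float(res.params[0]), float(res.params[1])
    # a two-point fit has no residual degrees of freedom: no covariance info
    cov = np.where(np.isfinite(cov), cov, 0.0)
    param_covariance = np.array(
        [[cov[1, 1], cov[1, 0]], [cov[0, 1], cov[0, 0]]], dtype=float
    )
    if slope <= 0:
        logger.warning(
            "intensity slope %.3g <= 0: normalized intensity should rise with "
            "sorbitol concentration",
            slope,
        )
    return IntensityLinearFit(
        slope=slope,
        intercept=intercept,
        param_covariance=param_covariance,
        fit_window=(float(uniq.min()), float(uniq.max())),
        n_points=int(uniq.size),
    )


def predict_intensity(fit: IntensityLinearFit, c_sorbitol: float) -> float:
    """Model normalized intensity at sorbitol concentration ``c_sorbitol``."""
    return fit.intercept + fit.slope * c_sorbitol


def invert_intensity(
    fit: IntensityLinearFit,
    intact_normalized_target: float = 1.0,
    intact_var: float = 0.0,
    n: int = 0,
) -> IsotonicEstimate:
    """Sorbitol concentration at which the fitted line reaches the intact level.

    ``c_iso = (target - intercept) / slope``; the error combines the fit
    covariance (delta method) with the between-replicate variance of the
    normalized intact-cell intensity.  An inversion landing outside the
    fitted window is flagged in the result's ``note``.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a zero-slope intensity fit")
    if intact_var < 0:
        raise ValueError("intact variance must be >= 0")
    c_iso = (intact_normalized_target - fit.intercept) / fit.slope
    if c_iso < 0:
        raise ValueError(
            f"inverted concentration {c_iso:.4g} mol/L is negative: protoplasts "
            "reach the intact intensity without added sorbitol"
        )
    # gradient w.r.t. (slope, intercept)
    grad = np.array([-c_iso / fit.slope, -1.0 / fit.slope])
    var_fit = float(grad @ fit.param_covariance @ grad)
    var_target = intact_var / fit.slope**2
    err = combine_errors_delta(max(var_fit, 0.0), var_target)
    note = None
    lo, hi = fit.fit_window
    if not (lo <= c_iso <= hi):
        note = (
            f"c_iso = {c_iso:.3g} mol/L lies outside the fitted window "
            f"[{lo:.3g}, {hi:.3g}]; the inversion extrapolates"
        )
        logger.warning(note)
    return IsotonicEstimate(
        method="intensity", c_iso=c_iso, c_iso_err=err, n=n, note=note
    )
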