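"""Turgor estimation from 3D cell-volume measurements (method 1).

Protoplasts behave as ideal osmometers: their equilibrium volume obeys the
Boyle-Van't Hoff relation

    V = m0 / C_total + b0

where ``C_total`` is the total external osmolyte concentration (added
sorbitol plus growth-medium baseline), ``m0`` is proportional to the
apparent number of osmotically active particles inside the cell, and ``b0``
is the non-osmotic volume (macromolecules and organelles that do not
exchange water).  Fitting this line to protoplast population summaries at
several osmolarities and inverting it at the intact-cell volume yields the
isotonic concentration, hence turgor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core import IsotonicEstimate, OsmoticCondition, combine_errors_delta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumePopulation:
    """One measured population: condition plus per-cell volumes and summary."""

    condition: OsmoticCondition
    volumes: tuple[float, ...]
    summary_stat: float
    summary_spread: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        if v.size == 0:
            raise ValueError("population must contain at least one volume")
        if np.any(v <= 0):
            raise ValueError("all volumes must be > 0 um^3")
        if not (v.min() <= self.summary_stat <= v.max()):
            raise ValueError("summary statistic must lie within the volume range")

    @classmethod
    def from_volumes(
        cls,
        condition: OsmoticCondition,
        volumes: Sequence[float],
        statistic: str = "median",
        replicate_labels: Sequence | None = None,
    ) -> "VolumePopulation":
        summary, spread = summarize_population(volumes, statistic, replicate_labels)
        return cls(
            condition=condition,
            volumes=tuple(float(v) for v in volumes),
            summary_stat=summary,
            summary_spread=spread,
        )


@dataclass(frozen=True)
class BVHFit:
    """Fitted Boyle-Van't Hoff parameters.

    ``param_covariance`` is the 2x2 covariance of ``(m0, b0)`` from the
    ordinary-least-squares formula; it drives the delta-method error on the
    inverted isotonic concentration.
    """

    m0: float
    b0: float
    param_covariance: np.ndarray
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        cov = np.asarray(self.param_covariance, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("param_covariance must be 2x2")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("param_covariance must be symmetric")


def summarize_population(
    volumes: Sequence[float],
    statistic: str = "median",
    replicate_labels: Sequence | None = None,
) -> tuple[float, float]:
    """Central statistic of a volume population and its between-replicate spread.

    With ``replicate_labels``, the statistic is computed per replicate; the
    summary is the mean of per-replicate statistics and the spread their
    sample SD (0.0 with a single replicate).  Without labels the statistic
    is computed on the pooled volumes and the spread is 0.0.
    """
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty population")
    if statistic == "median":
        stat = np.median
    elif statistic == "mean":
        stat = np.mean
    else:
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")

    if replicate_labels is None:
        return float(stat(v)), 0.0

    labels = np.asarray(replicate_labels)
    if labels.shape[0] != v.shape[0]:
        raise ValueError("replicate_labels must match volumes in length")
    per_rep = np.array([stat(v[labels == lab]) for lab in np.unique(labels)])
    spread = float(np.std(per_rep, ddof=1)) if per_rep.size > 1 else 0.0
    return float(np.mean(per_rep)), spread


def fit_boyle_vant_hoff(populations: Sequence[VolumePopulation]) -> BVHFit:
    """OLS fit of population summary volumes against 1 / C_total.

    Each population contributes one point (replicates of the same condition
    enter as distinct points).  Requires at least three distinct total
    concentrations, all strictly positive, and protoplast populations only.
    """
    if any(not p.condition.is_protoplast for p in populations):
        raise ValueError("Boyle-Van't Hoff fit expects protoplast populations only")
    c_total = np.array([p.condition.total_conc for p in populations], dtype=float)
    if np.any(c_total <= 0):
        raise ValueError("total concentration must be > 0 for every fit point")
    if np.unique(c_total).size < 3:
        raise ValueError(
            "need >= 3 distinct total concentrations to constrain (m0, b0)"
        )
    y = np.array([p.summary_stat for p in populations], dtype=float)
    x = 1.0 / c_total

    design = sm.add_constant(x)
    res = sm.OLS(y, design).fit()
    b0, m0 = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params())
    # reorder from (const, slope) to the (m0, b0) convention
    param_covariance = np.array(
        [[cov[1, 1], cov[1, 0]], [cov[0, 1], cov[0, 0]]], dtype=float
    )
    if m0 <= 0:
        warnings.warn(
            "fitted m0 <= 0: volumes do not decrease with osmolarity", stacklevel=2
        )
    if b0 < 0:
        warnings.warn(
            f"fitted non-osmotic volume b0 = {b0:.3g} um^3 is negative", stacklevel=2
        )
    return BVHFit(
        m0=m0,
        b0=b0,
        param_covariance=param_covariance,
        n_points=int(x.size),
        r_squared=float(res.rsquared),
    )


def predict_volume(fit: BVHFit, c_total: float) -> float:
    """Model volume (um^3) at total external concentration ``c_total`` (mol/L)."""
    if c_total <= 0:
        raise ValueError("total concentration must be > 0 mol/L")
    return fit.m0 / c_total + fit.b0


def invert_bvh(
    fit: BVHFit,
    target_volume: float,
    medium_baseline: float,
    target_volume_spread: float = 0.0,
    n: int = 0,
) -> IsotonicEstimate:
    """Isotonic sorbitol concentration at which the model volume equals the target.

    Solves ``C_total = m0 / (V - b0)`` at the intact-cell summary volume and
    subtracts the medium baseline.  The error combines, by the first-order
    delta method, the fit covariance of ``(m0, b0)`` with the SD of the
    intact-cell summary volume (``target_volume_spread``).
    """
    if medium_baseline < 0:
        raise ValueError("medium baseline must be >= 0 mol/L")
    if target_volume_spread < 0:
        raise ValueError("target volume spread must be >= 0")
    denom = target_volume - fit.b0
    if denom <= 0:
        raise ValueError(
            f"target volume {target_volume:.4g} um^3 is at or below the "
            f"non-osmotic volume b0 = {fit.b0:.4g} um^3; no positive solution"
        )
    c_total = fit.m0 / denom
    c_iso = c_total - medium_baseline
    if c_iso < 0:
        raise ValueError(
            f"isotonic total concentration {c_total:.4g} mol/L is below the medium "
            f"baseline {medium_baseline:.4g} mol/L: intact cells appear hypotonic "
            "to their own medium (check units and baseline)"
        )
    # gradient of c_iso w.r.t. (m0, b0): d/dm0 = 1/denom, d/db0 = m0/denom^2
    grad = np.array([1.0 / denom, fit.m0 / denom**2])
    var_fit = float(grad @ fit.param_covariance @ grad)
    # target volume enters as d/dV = -m0/denom^2
    var_target = (fit.m0 / denom**2) ** 2 * target_volume_spread**2
    err = combine_errors_delta(max(var_fit, 0.0), var_target)
    return IsotonicEstimate(method="volume", c_iso=c_iso, c_iso_err=err, n=n)
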