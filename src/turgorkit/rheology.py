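"""Turgor estimation from cytGEMs nanorheology (method 3).

40-nm genetically encoded multimeric nanoparticles (cytGEMs) are passive
tracers of cytoplasmic crowding.  Their 2D trajectories, imaged at 100 fps,
yield a time-averaged mean-squared displacement; fitting the first lags of
the MSD curve to the Brownian law ``MSD(tau) = 4 D_eff tau`` gives an
effective diffusion coefficient per condition.  Across sorbitol
concentrations, ``D_eff`` follows the Phillies law for self-diffusion in a
crowded polymer solution,

    D_eff(C) = D0 * exp(-beta * (C + C0)),

with ``D0`` the Stokes-Einstein diffusivity of a 40-nm sphere in water,
``C`` the added sorbitol and ``C0`` the osmolarity of the growth medium.
Inverting the fitted curve at the intact-cell ``D_eff`` locates the isotonic
concentration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import IsotonicEstimate, combine_errors_delta

logger = logging.getLogger(__name__)

#: Stokes-Einstein diffusion of a 40-nm sphere in water, um^2/s.  Treated as
#: an opaque named constant of the Phillies model, not recomputed.
D0_WATER_40NM = 13.56

#: Default number of leading MSD lags entering the Brownian fit.
DEFAULT_MSD_POINTS = 10

#: Tracks shorter than this cannot contribute all default lags.
DEFAULT_MIN_TRACK_LENGTH = DEFAULT_MSD_POINTS + 1


@dataclass(frozen=True)
class Track:
    """One 2D particle trajectory sampled on a uniform time grid."""

    track_id: str
    times: tuple[float, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size < 2:
            raise ValueError("a track needs at least two frames")
        if len(self.x) != t.size or len(self.y) != t.size:
            raise ValueError("times, x and y must have equal length")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("track times must be strictly increasing")
        if np.any(np.abs(dt / dt[0] - 1.0) > 1e-3):
            raise ValueError("track times must be uniformly spaced")

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class MSDCurve:
    """Time-averaged MSD of one track on the lag grid k*dt, k = 1..max_lag."""

    lags: tuple[float, ...]
    msd: tuple[float, ...]
    n_pairs_per_lag: tuple[int, ...]
    sem_per_lag: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.lags) == len(self.msd) == len(self.n_pairs_per_lag)):
            raise ValueError("lag grid fields must have equal length")
        if any(m < 0 for m in self.msd):
            raise ValueError("MSD values must be >= 0")


@dataclass(frozen=True)
class DeffEstimate:
    """Effective diffusion for one condition: ensemble fit with its SEM."""

    d_eff: float
    sem: float
    n_tracks: int

    def __post_init__(self) -> None:
        if self.d_eff < 0:
            raise ValueError("effective diffusion must be >= 0")


@dataclass(frozen=True)
class PhilliesFit:
    """Exponential concentration model for tracer diffusion.

    ``d0`` and ``c0_medium`` are fixed inputs (not fitted); only the
    crowding sensitivity ``beta`` (L/mol) is estimated.
    """

    d0: float
    beta: float
    c0_medium: float
    beta_variance: float

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0 (diffusion slows with crowding)")
        if self.beta_variance < 0:
            raise ValueError("beta variance must be >= 0")


def compute_msd(track: Track, max_lag: int = DEFAULT_MSD_POINTS) -> MSDCurve:
    """Time-averaged MSD of one track over lags 1..max_lag frames.

    Uses all overlapping pairs per lag:
    ``MSD(k dt) = mean_i [(x_{i+k}-x_i)^2 + (y_{i+k}-y_i)^2]``.
    """
    if len(track) < max_lag + 1:
        raise ValueError(
            f"track {track.track_id} has {len(track)} frames; "
            f"needs >= {max_lag + 1} for {max_lag} lags"
        )
    x = np.asarray(track.x, dtype=float)
    y = np.asarray(track.y, dtype=float)
    dt = track.frame_interval
    lags, msd, n_pairs, sems = [], [], [], []
    for k in range(1, max_lag + 1):
        sq = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
        lags.append(k * dt)
        msd.append(float(sq.mean()))
        n_pairs.append(int(sq.size))
        sems.append(float(sq.std(ddof=1) / math.sqrt(sq.size)) if sq.size > 1 else 0.0)
    return MSDCurve(tuple(lags), tuple(msd), tuple(n_pairs), tuple(sems))


def msd_curves_from_arrays(
    times: np.ndarray, xs: np.ndarray, ys: np.ndarray, max_lag: int = DEFAULT_MSD_POINTS
) -> list[MSDCurve]:
    """Vectorized per-track MSD for an ensemble of equal-length tracks.

    ``xs``/``ys`` have shape (n_tracks, n_frames) on the shared time grid
    ``times``.  Equivalent to mapping :func:`compute_msd` over tracks, but
    computed for all tracks per lag in one pass.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    t = np.asarray(times, dtype=float)
    n_frames = xs.shape[1]
    if n_frames < max_lag + 1:
        raise ValueError(f"tracks of {n_frames} frames support < {max_lag} lags")
    dt = float(t[1] - t[0])
    msd = np.empty((xs.shape[0], max_lag))
    sem = np.empty_like(msd)
    n_pairs = np.empty(max_lag, dtype=int)
    for k in range(1, max_lag + 1):
        sq = (xs[:, k:] - xs[:, :-k]) ** 2 + (ys[:, k:] - ys[:, :-k]) ** 2
        msd[:, k - 1] = sq.mean(axis=1)
        n = sq.shape[1]
        n_pairs[k - 1] = n
        sem[:, k - 1] = sq.std(axis=1, ddof=1) / math.sqrt(n) if n > 1 else 0.0
    lags = tuple(k * dt for k in range(1, max_lag + 1))
    return [
        MSDCurve(lags, tuple(msd[i]), tuple(n_pairs), tuple(sem[i]))
        for i in range(xs.shape[0])
    ]


def fit_deff(
    curves: Sequence[MSDCurve],
    n_points: int = DEFAULT_MSD_POINTS,
    intercept: bool = False,
) -> DeffEstimate:
    """Ensemble effective diffusion from truncated MSD curves.

    Fits the ensemble-mean MSD over the first ``n_points`` lags to
    ``MSD = 4 D tau`` by least squares through the origin; the SEM comes
    from the spread of per-track ``D`` values.  With ``intercept=True`` a
    free offset absorbs the static localization-noise plateau (2D: 4 sigma^2)
    instead of letting it inflate the slope.
    """
    usable = [c for c in curves if len(c.lags) >= n_points]
    dropped = len(curves) - len(usable)
    if dropped:
        logger.warning("excluded %d curves with fewer than %d lags", dropped, n_points)
    if not usable:
        raise ValueError("no MSD curve has enough lags to fit")
    taus = np.asarray(usable[0].lags[:n_points], dtype=float)
    for c in usable[1:]:
        if not np.allclose(c.lags[:n_points], taus, rtol=1e-6):
            raise ValueError("all curves must share one lag grid")
    msd = np.asarray([c.msd[:n_points] for c in usable], dtype=float)

    def slope_through_origin(y: np.ndarray) -> np.ndarray:
        return (y @ taus) / (4.0 * taus @ taus)

    if intercept:
        design = np.column_stack([np.ones_like(taus), 4.0 * taus])
        coef, *_ = np.linalg.lstsq(design, msd.mean(axis=0), rcond=None)
        d_ens = float(coef[1])
        per_track = np.linalg.lstsq(design, msd.T, rcond=None)[0][1]
    else:
        d_ens = float(slope_through_origin(msd.mean(axis=0)))
        per_track = slope_through_origin(msd)
    sem = (
        float(np.std(per_track, ddof=1) / math.sqrt(per_track.size))
        if per_track.size > 1
        else 0.0
    )
    return DeffEstimate(d_eff=max(d_ens, 0.0), sem=sem, n_tracks=len(usable))


def fit_phillies(
    concentrations: Sequence[float],
    d_effs: Sequence[DeffEstimate | float],
    c0_medium: float,
    d0: float = D0_WATER_40NM,
    space: str = "log",
) -> PhilliesFit:
    """Fit the crowding sensitivity ``beta`` of the Phillies model.

    ``space="log"`` (default) linearizes ``ln(D/D0) = -beta (C + C0)`` into a
    one-parameter regression through the origin; ``space="linear"`` performs
    nonlinear least squares on the untransformed model.  The two agree
    exactly on noiseless data.
    """
    c = np.asarray(concentrations, dtype=float)
    d = np.asarray(
        [e.d_eff if isinstance(e, DeffEstimate) else float(e) for e in d_effs]
    )
    if c.size != d.size:
        raise ValueError("concentrations and d_effs must pair up")
    if np.unique(c).size < 2:
        raise ValueError("need >= 2 distinct sorbitol concentrations")
    if np.any(d <= 0):
        raise ValueError("all d_eff must be > 0")
    if np.any(d >= d0):
        raise ValueError(
            "d_eff >= D0 is unphysical for the Phillies model "
            f"(max d_eff {d.max():.4g} vs D0 {d0:.4g} um^2/s)"
        )
    if c0_medium < 0:
        raise ValueError("medium concentration must be >= 0 mol/L")

    x = c + c0_medium
    y = np.log(d / d0)
    beta = float(-(x @ y) / (x @ x))
    resid = y + beta * x
    dof = x.size - 1
    beta_var = float((resid @ resid) / dof / (x @ x)) if dof > 0 else 0.0

    if space == "linear":
        popt, pcov = curve_fit(
            lambda cc, b: d0 * np.exp(-b * (cc + c0_medium)), c, d, p0=[beta]
        )
        beta = float(popt[0])
        beta_var = float(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else 0.0
    elif space != "log":
        raise ValueError("space must be 'log' or 'linear'")
    return PhilliesFit(d0=float(d0), beta=beta, c0_medium=float(c0_medium),
                       beta_variance=beta_var)


def predict_deff(fit: PhilliesFit, c_sorbitol: float) -> float:
    """Model ``D_eff`` (um^2/s) at sorbitol concentration ``c_sorbitol``."""
    return fit.d0 * math.exp(-fit.beta * (c_sorbitol + fit.c0_medium))


def invert_phillies(fit: PhilliesFit, d_eff_intact: DeffEstimate) -> IsotonicEstimate:
    """Sorbitol concentration matching protoplast mobility to intact cells.

    ``c_iso = ln(D0 / D_eff) / beta - C0``; the error combines the variance
    of ``beta`` and the intact-cell SEM through the first-order delta method.
    """
    d = d_eff_intact.d_eff
    if not (0.0 < d < fit.d0):
        raise ValueError(
            f"intact d_eff must lie in (0, D0) = (0, {fit.d0:.4g}), got {d:.4g}"
        )
    log_ratio = math.log(fit.d0 / d)
    c_iso = log_ratio / fit.beta - fit.c0_medium
    if c_iso < 0:
        raise ValueError(
            f"inverted concentration {c_iso:.4g} mol/L is negative: intact "
            "mobility is matched below the medium's own osmolarity"
        )
    var_beta = (log_ratio / fit.beta**2) ** 2 * fit.beta_variance
    var_intact = (1.0 / (fit.beta * d)) ** 2 * d_eff_intact.sem**2
    err = combine_errors_delta(var_beta, var_intact)
    return IsotonicEstimate(
        method="rheology", c_iso=c_iso, c_iso_err=err, n=d_eff_intact.n_tracks
    )
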