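"""Shared osmotic-physics primitives for turgor estimation.

A walled cell holds an internal hydrostatic (turgor) pressure ``P`` equal to
the difference between its internal osmotic potential and that of the growth
medium, ``P = Pi_C - Pi_buffer``.  A protoplast (the same cell with its wall
removed) carries no turgor and behaves as an ideal osmometer, so the sorbitol
concentration at which a protoplast matches the intact cell -- in volume,
cytoplasmic concentration, or tracer mobility -- measures the intact cell's
osmotic excess over the medium.  That isotonic sorbitol concentration
``c_iso`` converts to pressure through the Van't Hoff relation ``P = C R T``.

This module holds the physical constants, the pressure/concentration
conversion, and the cross-method aggregation used by the three estimation
pipelines.  Concentrations are mol/L, temperatures K, pressures MPa
throughout the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Ideal gas constant, J / (mol K).
GAS_CONSTANT_R = 8.314

#: Default study temperature: 30 degrees C cultures, in kelvin.
DEFAULT_TEMPERATURE_K = 303.15

#: Method labels used by the three estimation pipelines.
METHOD_LABELS = ("volume", "intensity", "rheology")


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant and study temperature bundle.

    The temperature is configurable per study (it enters the Van't Hoff
    conversion linearly) but defaults to the 30 degree C culture temperature.
    """

    gas_constant_R: float = GAS_CONSTANT_R
    default_temperature_K: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.gas_constant_R <= 0:
            raise ValueError("gas constant must be positive")
        if self.default_temperature_K <= 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class OsmoticCondition:
    """A media composition under which one cell population was measured.

    ``sorbitol_conc`` is the sorbitol added on top of the growth medium,
    whose own osmolarity is ``medium_baseline_conc``; the fit abscissa for
    osmometer analyses is their sum ``total_conc``.
    """

    strain_label: str
    sorbitol_conc: float
    medium_baseline_conc: float
    is_protoplast: bool = True

    def __post_init__(self) -> None:
        if self.sorbitol_conc < 0:
            raise ValueError("sorbitol concentration must be >= 0 mol/L")
        if self.medium_baseline_conc < 0:
            raise ValueError("medium baseline concentration must be >= 0 mol/L")

    @property
    def total_conc(self) -> float:
        """Total external osmolyte concentration, mol/L."""
        return self.sorbitol_conc + self.medium_baseline_conc


@dataclass(frozen=True)
class IsotonicEstimate:
    """Isotonic sorbitol concentration produced by one method.

    This is the common currency of the three pipelines: the sorbitol
    concentration (mol/L) at which protoplasts match intact cells, with a
    combined standard error and the number of cells or tracks that entered
    the estimate.  ``note`` carries non-fatal diagnostics (e.g. an inversion
    that extrapolates outside the fitted window).
    """

    method: str
    c_iso: float
    c_iso_err: float
    n: int = 0
    note: str | None = None

    def __post_init__(self) -> None:
        if self.c_iso < 0:
            raise ValueError("isotonic concentration must be >= 0 mol/L")
        if self.c_iso_err < 0:
            raise ValueError("isotonic concentration error must be >= 0 mol/L")


@dataclass(frozen=True)
class TurgorResult:
    """Turgor pressure in MPa with its error and provenance.

    ``provenance`` is a method label (``volume``/``intensity``/``rheology``)
    or ``"average"`` for the cross-method mean.
    """

    pressure_MPa: float
    pressure_err_MPa: float
    provenance: str

    def __post_init__(self) -> None:
        if self.pressure_MPa < 0:
            raise ValueError("turgor pressure must be >= 0 MPa")
        if self.pressure_err_MPa < 0:
            raise ValueError("pressure error must be >= 0 MPa")


def vant_hoff_pressure(
    c_sorbitol: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Osmotic pressure (MPa) of an ideal solute at concentration ``c_sorbitol``.

    Applies ``P = C R T`` with unit bookkeeping: mol/L -> mol/m^3 (x1000),
    pressure in Pa -> MPa (/1e6).  At 303.15 K, 0.40 mol/L maps to 1.008 MPa.

    Parameters
    ----------
    c_sorbitol:
        Solute concentration, mol/L. Must be non-negative.
    temperature:
        Absolute temperature, K. Must be positive.
    """
    c = float(c_sorbitol)
    t = float(temperature)
    if c < 0:
        raise ValueError(f"concentration must be >= 0 mol/L, got {c}")
    if t <= 0:
        raise ValueError(f"temperature must be > 0 K, got {t}")
    return c * 1000.0 * GAS_CONSTANT_R * t / 1.0e6


def pressure_to_concentration(
    pressure_MPa: float, temperature: float = DEFAULT_TEMPERATURE_K
) -> float:
    """Inverse of :func:`vant_hoff_pressure`: MPa -> mol/L at ``temperature``."""
    p = float(pressure_MPa)
    t = float(temperature)
    if p < 0:
        raise ValueError(f"pressure must be >= 0 MPa, got {p}")
    if t <= 0:
        raise ValueError(f"temperature must be > 0 K, got {t}")
    return p * 1.0e6 / (1000.0 * GAS_CONSTANT_R * t)


def turgor_from_isotonic(
    estimate: IsotonicEstimate, temperature: float = DEFAULT_TEMPERATURE_K
) -> TurgorResult:
    """Convert an isotonic sorbitol estimate to turgor pressure via Van't Hoff.

    The error converts with the same linear factor ``R T``.  The medium
    baseline is common to intact cells and protoplasts and cancels in
    ``P = Pi_C - Pi_buffer``, so only the sorbitol concentration enters.
    """
    return TurgorResult(
        pressure_MPa=vant_hoff_pressure(estimate.c_iso, temperature),
        pressure_err_MPa=vant_hoff_pressure(estimate.c_iso_err, temperature),
        provenance=estimate.method,
    )


def combine_methods(estimates: Sequence[TurgorResult]) -> TurgorResult:
    """Cross-method average: arithmetic mean with the between-method SD as error.

    Requires at least two method results (the sample SD, with its n-1
    denominator, is undefined for one).
    """
    if len(estimates) < 2:
        raise ValueError("cross-method average needs >= 2 method results")
    pressures = np.asarray([e.pressure_MPa for e in estimates], dtype=float)
    return TurgorResult(
        pressure_MPa=float(np.mean(pressures)),
        pressure_err_MPa=float(np.std(pressures, ddof=1)),
        provenance="average",
    )


def combine_isotonic(estimates: Sequence[IsotonicEstimate]) -> IsotonicEstimate:
    """Cross-method average of isotonic concentrations (mean, between-method SD)."""
    if len(estimates) < 2:
        raise ValueError("cross-method average needs >= 2 method estimates")
    c = np.asarray([e.c_iso for e in estimates], dtype=float)
    return IsotonicEstimate(
        method="average",
        c_iso=float(np.mean(c)),
        c_iso_err=float(np.std(c, ddof=1)),
        n=int(sum(e.n for e in estimates)),
    )


def combine_errors_delta(
    fit_variance_on_c: float, intact_variance_on_c: float
) -> float:
    """Combine two independent variance contributions on the concentration scale.

    Each input must already be propagated (first-order delta method) through
    the relevant inversion into (mol/L)^2; the combined standard error is the
    square root of their sum.
    """
    a = float(fit_variance_on_c)
    b = float(intact_variance_on_c)
    if a < 0 or b < 0:
        raise ValueError("variances must be >= 0")
    return math.sqrt(a + b)


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (used for table-style reporting)."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - int(math.floor(math.log10(abs(x))))
    return round(x, ndigits)
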