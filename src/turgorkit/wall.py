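"""Thin-shell cell-wall mechanics: Young's modulus and wall tension.

For a rod-shaped walled cell with a homogeneous, isotropic wall of thickness
``h`` and radius ``R`` under turgor ``dP``, the lateral wall carries an
elastic strain set by the force balance

    dP * R / (Y * h) = epsilon,

so ``Y = dP * R / (h * epsilon)``, and the in-plane wall tension is
``T = dP * R``.  Units compose cleanly: MPa * um = N/m exactly, and
(MPa * um) / nm = 1000 MPa.  Cross-species comparisons need only the
*ratios* of turgor, radius, thickness and strain.
"""

from __future__ import annotations

from dataclasses import dataclass


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class WallGeometry:
    """Per-strain wall geometry consumed by the report generator."""

    radius_um: float
    thickness_nm: float
    elastic_strain: float

    def __post_init__(self) -> None:
        _require_positive(
            radius_um=self.radius_um,
            thickness_nm=self.thickness_nm,
            elastic_strain=self.elastic_strain,
        )


def young_modulus(
    turgor_MPa: float, radius_um: float, thickness_nm: float, strain: float
) -> float:
    """Lateral-wall Young's modulus (MPa) from the thin-shell force balance.

    ``Y = dP * R / (h * epsilon)`` with inputs in (MPa, um, nm): the um/nm
    ratio contributes a factor 1000.
    """
    _require_positive(
        turgor_MPa=turgor_MPa,
        radius_um=radius_um,
        thickness_nm=thickness_nm,
        strain=strain,
    )
    return turgor_MPa * (radius_um * 1000.0) / (thickness_nm * strain)


def scale_young(
    y_ref_MPa: float,
    turgor_ratio: float,
    radius_ratio: float,
    thickness_ratio: float,
    strain_ratio: float,
) -> float:
    """Scale a reference modulus across species using geometry/turgor ratios.

    ``Y = Y_ref * turgor_ratio * radius_ratio / (thickness_ratio *
    strain_ratio)``.  E.g. a species with double the radius, double the wall
    thickness, half the turgor and equal strain has half the reference
    modulus.
    """
    _require_positive(
        y_ref_MPa=y_ref_MPa,
        turgor_ratio=turgor_ratio,
        radius_ratio=radius_ratio,
        thickness_ratio=thickness_ratio,
        strain_ratio=strain_ratio,
    )
    return y_ref_MPa * turgor_ratio * radius_ratio / (thickness_ratio * strain_ratio)


def wall_tension(turgor_MPa: float, radius_um: float) -> float:
    """In-plane wall tension (N/m) of the lateral wall: ``T = dP * R``.

    MPa * um = N/m with no numeric factor, so half the turgor at double the
    radius leaves the tension unchanged.
    """
    _require_positive(turgor_MPa=turgor_MPa, radius_um=radius_um)
    return turgor_MPa * radius_um
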