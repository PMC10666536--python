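"""Interfacial energetics of a droplet interface bilayer (DIB).

Two lipid-monolayer-coated aqueous droplets adhering in oil form a bilayer
over their contact zone. The geometry of the two contacting spherical caps
gives the contact angle θ; together with the monolayer tension γ_m of the
oil–lipid–water interface it yields, by a force balance at the contact
line and the Young–Dupré relation,

    γ_B = 2 γ_m cos θ              (bilayer tension)
    ΔF  = 2 γ_m (cos θ − 1) ≤ 0    (free energy of bilayer formation per area)
    π   = γ_m (1 − cos θ) = |ΔF|/2 (relative membrane lateral pressure)

Angles are handled in degrees throughout (the reporting unit); trigonometry
converts internally. Tensions are in mN/m, ΔF in mJ/m² (numerically equal
scales: 1 mN/m = 1 mJ/m²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, InvalidGeometryError

__all__ = [
    "ContactGeometry",
    "InterfacialParams",
    "contact_angle",
    "bilayer_tension",
    "formation_free_energy",
    "lateral_pressure",
    "derive_params",
    "tension_table",
]


@dataclass(frozen=True)
class ContactGeometry:
    """Radii of two adherent droplets and of their contact zone, in μm.

    Invariants: ``R1 > 0``, ``R2 > 0``, ``0 <= r <= min(R1, R2)``.
    """

    R1: float
    R2: float
    r: float

    def __post_init__(self) -> None:
        if self.R1 <= 0 or self.R2 <= 0:
            raise InvalidGeometryError(
                f"droplet radii must be positive, got R1={self.R1}, R2={self.R2}")
        if not 0.0 <= self.r <= min(self.R1, self.R2):
            raise InvalidGeometryError(
                f"contact radius r={self.r} must lie in [0, min(R1, R2)="
                f"{min(self.R1, self.R2)}]")


@dataclass(frozen=True)
class InterfacialParams:
    """Derived interfacial parameters for one membrane condition."""

    gamma_m: float          # monolayer tension, mN/m
    theta: float            # contact angle, degrees
    gamma_B: float          # bilayer tension, mN/m
    delta_F: float          # formation free energy, signed, mJ/m² (<= 0)
    lateral_pressure: float  # π, mN/m (>= 0)

    @property
    def abs_delta_F(self) -> float:
        return abs(self.delta_F)


def contact_angle(geom: ContactGeometry) -> float:
    """Contact angle (degrees) between two adherent spherical droplets.

    Mean half-angle of the two contacting spherical caps:
    θ = ½ [arcsin(r/R1) + arcsin(r/R2)]. Symmetric in (R1, R2) and
    monotonically increasing in r at fixed radii.
    """
    half = 0.5 * (math.asin(geom.r / geom.R1) + math.asin(geom.r / geom.R2))
    return math.degrees(half)


def _check_tension_angle(gamma_m: float, theta: float) -> float:
    if gamma_m <= 0:
        raise DomainError(f"monolayer tension must be positive, got {gamma_m}")
    if not 0.0 <= theta < 90.0:
        raise DomainError(f"contact angle must lie in [0, 90) degrees, got {theta}")
    return math.cos(math.radians(theta))


def bilayer_tension(gamma_m: float, theta: float) -> float:
    """Bilayer tension γ_B = 2 γ_m cos θ (mN/m); θ in degrees."""
    return 2.0 * gamma_m * _check_tension_angle(gamma_m, theta)


def formation_free_energy(gamma_m: float, theta: float) -> float:
    """Signed free energy of bilayer formation ΔF = 2 γ_m (cos θ − 1) (mJ/m²).

    Always ≤ 0: adhesion of the two monolayers is spontaneous. Reports
    conventionally quote |ΔF|.
    """
    return 2.0 * gamma_m * (_check_tension_angle(gamma_m, theta) - 1.0)


def lateral_pressure(gamma_m: float, theta: float) -> float:
    """Relative membrane lateral pressure π = γ_m (1 − cos θ) = |ΔF|/2 (mN/m)."""
    return gamma_m * (1.0 - _check_tension_angle(gamma_m, theta))


def derive_params(gamma_m: float, theta: float) -> InterfacialParams:
    """Bundle γ_B, ΔF and π for one (γ_m, θ) pair."""
    return InterfacialParams(
        gamma_m=gamma_m,
        theta=theta,
        gamma_B=bilayer_tension(gamma_m, theta),
        delta_F=formation_free_energy(gamma_m, theta),
        lateral_pressure=lateral_pressure(gamma_m, theta),
    )


def tension_table(table: pd.DataFrame, mode: str = "angle") -> pd.DataFrame:
    """Derive interfacial parameters for a table of measurements.

    Parameters
    ----------
    table:
        ``mode="angle"``: columns ``label, gamma_m_mN_m, theta_deg``.
        ``mode="geometry"``: columns ``label, R1_um, R2_um, r_um,
        gamma_m_mN_m`` — the contact angle is computed from the geometry.
    mode:
        ``"angle"`` or ``"geometry"``.

    Returns
    -------
    DataFrame with columns ``label, gamma_m_mN_m, theta_deg, gamma_B_mN_m,
    abs_delta_F_mJ_m2, lateral_pressure_mN_m``; γ_B rounded to 2 decimals
    and |ΔF| to 3 (report precision), π unrounded.
    """
    if mode not in ("angle", "geometry"):
        raise ValueError(f"mode must be 'angle' or 'geometry', got {mode!r}")
    rows = []
    for rec in table.to_dict("records"):
        if mode == "geometry":
            theta = contact_angle(
                ContactGeometry(rec["R1_um"], rec["R2_um"], rec["r_um"]))
        else:
            theta = float(rec["theta_deg"])
        p = derive_params(float(rec["gamma_m_mN_m"]), theta)
        rows.append({
            "label": rec.get("label", ""),
            "gamma_m_mN_m": p.gamma_m,
            "theta_deg": round(p.theta, 2),
            "gamma_B_mN_m": round(p.gamma_B, 2),
            "abs_delta_F_mJ_m2": round(p.abs_delta_F, 3),
            "lateral_pressure_mN_m": p.lateral_pressure,
        })
    return pd.DataFrame(rows)
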