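"""Lippert-Mataga solvatochromic analysis.

The Stokes shift in wavenumbers, Δν̄ = ν̄_abs − ν̄_em, of a
charge-transfer dye grows linearly with the solvent orientation
polarizability

    Δf = (ε − 1)/(2ε + 1) − (n² − 1)/(2n² + 1),

with slope 2(μ_E − μ_G)²/(h c a³): a positive slope means the excited
state is more polar than the ground state.  The slope→dipole conversion
is done in CGS units (h in erg·s, c in cm/s, a in cm, μ in esu·cm;
1 D = 1e-18 esu·cm) so that the slope stays in cm⁻¹ per unit Δf.
A companion trend of absorption energy against the empirical E_T(30)
polarity scale is fitted the same way.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SolventRecord",
    "SolvatochromicPoint",
    "LippertFit",
    "SOLVENTS",
    "to_wavenumber",
    "to_wavelength",
    "orientation_polarizability",
    "lippert_fit",
    "dipole_change_from_slope",
    "slope_from_dipole_change",
    "et30_trend",
]

PLANCK_ERG_S = 6.62607015e-27  # h, CGS
LIGHT_SPEED_CM_S = 2.99792458e10  # c, CGS
ESU_CM_PER_DEBYE = 1e-18


@dataclass(frozen=True)
class SolventRecord:
    """Static dielectric constant, refractive index and E_T(30) of a solvent."""

    name: str
    dielectric: float
    refractive_index: float
    et30: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.dielectric <= 1 or self.refractive_index <= 1:
            raise ValueError("dielectric and refractive_index must exceed 1")
        if self.dielectric < self.refractive_index**2 - 0.05:
            raise ValueError(
                f"{self.name}: static dielectric {self.dielectric} below n^2 "
                f"{self.refractive_index ** 2:.3f}"
            )

    @property
    def delta_f(self) -> float:
        return orientation_polarizability(self.dielectric, self.refractive_index)


# Handbook constants (CRC / Reichardt) for the solvents used in the
# solvatochromic series; implementation data, not fitted quantities.
SOLVENTS: dict[str, SolventRecord] = {
    r.name: r
    for r in [
        SolventRecord("water", 78.36, 1.3325, 63.1),
        SolventRecord("acetonitrile", 35.94, 1.3442, 45.6),
        SolventRecord("acetone", 20.56, 1.3588, 42.2),
        SolventRecord("ethyl_acetate", 6.02, 1.3723, 38.1),
        SolventRecord("dmso", 46.45, 1.4793, 45.1),
        SolventRecord("methanol", 32.66, 1.3284, 55.4),
        SolventRecord("glycerol", 42.50, 1.4746, 57.0),
        SolventRecord("ethanol", 24.55, 1.3614, 51.9),
        SolventRecord("dichloromethane", 8.93, 1.4242, 40.7),
    ]
}


@dataclass(frozen=True)
class SolvatochromicPoint:
    solvent: SolventRecord
    nu_abs: float  # cm^-1
    nu_em: float  # cm^-1

    @property
    def delta_f(self) -> float:
        return self.solvent.delta_f

    @property
    def stokes_shift(self) -> float:
        return self.nu_abs - self.nu_em


@dataclass(frozen=True)
class LippertFit:
    slope: float  # cm^-1 per unit delta_f
    intercept: float  # cm^-1; the vacuum Stokes shift k
    r_squared: float


def to_wavenumber(lambda_nm: float) -> float:
    """nm → cm⁻¹ (10⁷/λ)."""
    lam = np.asarray(lambda_nm, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be > 0")
    out = 1e7 / lam
    return float(out) if out.ndim == 0 else out


def to_wavelength(nu_cm: float) -> float:
    """cm⁻¹ → nm; inverse of :func:`to_wavenumber`."""
    nu = np.asarray(nu_cm, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be > 0")
    out = 1e7 / nu
    return float(out) if out.ndim == 0 else out


def orientation_polarizability(dielectric: float, refractive_index: float) -> float:
    """Δf = (ε−1)/(2ε+1) − (n²−1)/(2n²+1)."""
    eps = float(dielectric)
    n = float(refractive_index)
    if 2 * eps + 1 <= 0 or 2 * n**2 + 1 <= 0:
        raise ValueError("denominator not positive; unphysical constants")
    if n < 1:
        raise ValueError("refractive_index must be >= 1")
    return (eps - 1) / (2 * eps + 1) - (n**2 - 1) / (2 * n**2 + 1)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), float(intercept), float(min(max(r2, 0.0), 1.0))


def lippert_fit(points: Sequence[SolvatochromicPoint]) -> LippertFit:
    """OLS of Stokes shift on orientation polarizability."""
    if len(points) < 3:
        raise ValueError("need >= 3 solvatochromic points")
    df = np.array([p.delta_f for p in points])
    shift = np.array([p.stokes_shift for p in points])
    if np.ptp(df) == 0:
        raise ValueError("all orientation polarizabilities equal; slope undefined")
    slope, intercept, r2 = _ols(df, shift)
    return LippertFit(slope=slope, intercept=intercept, r_squared=r2)


def slope_from_dipole_change(dipole_debye: float, cavity_radius_angstrom: float) -> float:
    """Forward Lippert slope (cm⁻¹ per Δf) from a dipole change and cavity radius."""
    if dipole_debye < 0 or cavity_radius_angstrom <= 0:
        raise ValueError("dipole must be >= 0 and radius > 0")
    mu_esu = dipole_debye * ESU_CM_PER_DEBYE
    a_cm = cavity_radius_angstrom * 1e-8
    return 2.0 * mu_esu**2 / (PLANCK_ERG_S * LIGHT_SPEED_CM_S * a_cm**3)


def dipole_change_from_slope(slope: float, cavity_radius_angstrom: float) -> float:
    """|μ_E − μ_G| in Debye from a fitted Lippert slope.

    A negative slope (anomalous solvatochromism) is an error here, not a
    silent square root of a negative number.
    """
    if slope < 0:
        raise ValueError("negative Lippert slope: anomalous solvatochromism")
    if cavity_radius_angstrom <= 0:
        raise ValueError("cavity radius must be > 0")
    a_cm = cavity_radius_angstrom * 1e-8
    mu_esu = np.sqrt(slope * PLANCK_ERG_S * LIGHT_SPEED_CM_S * a_cm**3 / 2.0)
    return float(mu_esu / ESU_CM_PER_DEBYE)


def et30_trend(
    points: Sequence[tuple[float, float]],
) -> tuple[float, float]:
    """OLS slope and R² of absorption energy (cm⁻¹) on E_T(30) (kcal/mol)."""
    if len(points) < 3:
        raise ValueError("need >= 3 (et30, energy) points")
    et = np.array([p[0] for p in points], dtype=float)
    e = np.array([p[1] for p in points], dtype=float)
    if np.ptp(et) == 0:
        raise ValueError("degenerate design: all E_T(30) equal")
    slope, _, r2 = _ols(et, e)
    return slope, r2
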