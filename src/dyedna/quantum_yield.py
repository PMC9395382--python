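"""Relative fluorescence quantum yield by the slope-ratio method.

Φ_sample = Φ_ref · (grad_sample/grad_ref) · (η_sample² / η_ref²),
where each grad is the slope of integrated emission intensity versus
absorbance at the excitation wavelength, measured for a dilution series
kept optically thin (A ≲ 0.1) to avoid inner-filter effects.
Brightness = ε × Φ is the practical stain figure of merit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "GradFit",
    "QYResult",
    "REFERENCE_DYES",
    "grad_fit",
    "relative_quantum_yield",
    "brightness",
]

#: Packaged reference standards: name -> (Φ_F, excitation window nm).
REFERENCE_DYES: dict[str, tuple[float, tuple[float, float]]] = {
    "fluorescein": (0.95, (470.0, 490.0)),
    "rhodamine_6g": (0.95, (470.0, 510.0)),
    "cresyl_violet": (0.54, (540.0, 590.0)),
}

#: Absorbance above which the inner-filter effect starts to bias grad.
INNER_FILTER_WARN_ABS = 0.15


@dataclass(frozen=True)
class GradFit:
    grad: float  # integrated intensity per absorbance unit
    r_squared: float  # of the free-intercept diagnostic fit
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


@dataclass(frozen=True)
class QYResult:
    phi: float
    phi_ref: float
    eta_sample: float
    eta_ref: float
    reference_name: str = ""

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("phi must be >= 0")


def grad_fit(
    absorbances: Sequence[float], integrated_intensities: Sequence[float]
) -> GradFit:
    """Slope of integrated emission vs absorbance, constrained through the origin.

    Zero absorbance physically implies zero emission, so the slope is the
    origin-constrained least-squares estimate Σ(A·I)/Σ(A²); the R² of a
    free-intercept line is reported as a diagnostic. A single point
    reduces to the ratio I/A.
    """
    a = np.asarray(absorbances, dtype=float)
    y = np.asarray(integrated_intensities, dtype=float)
    if a.size != y.size or a.size < 1:
        raise ValueError("need matched, non-empty absorbance/intensity arrays")
    if np.all(a == 0):
        raise ValueError("all absorbances are zero; slope undefined")
    if np.any(a > INNER_FILTER_WARN_ABS):
        warnings.warn(
            f"absorbance above {INNER_FILTER_WARN_ABS} risks inner-filter bias "
            "in the slope",
            stacklevel=2,
        )
    grad = float(np.sum(a * y) / np.sum(a * a))

    if a.size >= 3 and np.ptp(a) > 0:
        slope, intercept = np.polyfit(a, y, 1)
        resid = y - (slope * a + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    else:
        r2 = 1.0
    return GradFit(grad=grad, r_squared=float(min(max(r2, 0.0), 1.0)), n_points=int(a.size))


def relative_quantum_yield(
    grad_sample: float,
    grad_ref: float,
    eta_sample: float,
    eta_ref: float,
    phi_ref: float | None = None,
    reference_name: str | None = None,
) -> QYResult:
    """Relative quantum yield from slope and refractive-index ratios.

    Either ``phi_ref`` is given directly or ``reference_name`` selects one
    of the packaged standards (fluorescein, rhodamine_6g, cresyl_violet).
    Values above 1 are physically impossible and warned about (slope or
    reference misuse), not rejected.
    """
    if reference_name is not None:
        if reference_name not in REFERENCE_DYES:
            raise KeyError(
                f"unknown reference {reference_name!r}; "
                f"packaged: {sorted(REFERENCE_DYES)}"
            )
        phi_ref = REFERENCE_DYES[reference_name][0]
    elif phi_ref is None:
        raise ValueError("give phi_ref or reference_name")
    if grad_ref <= 0:
        raise ValueError("grad_ref must be > 0")
    if eta_sample <= 0 or eta_ref <= 0:
        raise ValueError("refractive indices must be > 0")
    if not 0 < phi_ref <= 1:
        raise ValueError("phi_ref must lie in (0, 1]")
    if grad_sample < 0:
        raise ValueError("grad_sample must be >= 0")

    phi = phi_ref * (grad_sample / grad_ref) * (eta_sample**2 / eta_ref**2)
    if phi > 1.0:
        warnings.warn(
            f"quantum yield {phi:.3g} > 1 is unphysical; check slopes and reference",
            stacklevel=2,
        )
    return QYResult(
        phi=float(phi),
        phi_ref=float(phi_ref),
        eta_sample=float(eta_sample),
        eta_ref=float(eta_ref),
        reference_name=reference_name or "",
    )


def brightness(epsilon: float, phi: float) -> float:
    """Brightness = ε × Φ in M⁻¹cm⁻¹."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    return epsilon * phi
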