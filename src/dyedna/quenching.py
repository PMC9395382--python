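"""Stern-Volmer analysis of salt-dependent fluorescence quenching.

F0/F = 1 + K_SV [Q]: for a cationic dye bound to DNA, added NaCl screens
the electrostatic contribution to binding and displaces the dye, so a
large K_SV marks an exposed (groove-bound) dye and a small one a
protected (intercalated) dye.  The fit is constrained through the fixed
unit intercept of the equation — (F0/F − 1) is regressed on [Q] through
the origin — with a free-intercept line reported as a diagnostic for
baseline or static-quenching artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

__all__ = ["QuenchSeries", "QuenchFit", "stern_volmer_fit"]


@dataclass(frozen=True)
class QuenchSeries:
    """Fluorescence versus quencher concentration, plus the quencher-free F0."""

    f0: float
    quencher_M: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_M, dtype=float)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "quencher_M", q)
        object.__setattr__(self, "fluorescence", f)
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")
        if q.shape != f.shape or q.ndim != 1:
            raise ValueError("quencher_M and fluorescence must be matched 1-D arrays")
        if np.any(q < 0):
            raise ValueError("quencher concentrations must be >= 0")
        if np.any(f <= 0):
            raise ValueError("fluorescence must be > 0")

    def __len__(self) -> int:
        return int(self.quencher_M.size)


@dataclass(frozen=True)
class QuenchFit:
    k_sv: float  # M^-1
    r_squared: float
    intercept_free: float  # intercept of the unconstrained F0/F line (diagnostic)


def stern_volmer_fit(q: QuenchSeries) -> QuenchFit:
    """Origin-constrained OLS of (F0/F − 1) on [Q]; K_SV in M⁻¹."""
    if len(q) < 3:
        raise ValueError("need >= 3 quench points")
    if np.unique(q.quencher_M).size < 2:
        raise ValueError("need at least 2 distinct quencher concentrations")

    conc = q.quencher_M
    y = q.f0 / q.fluorescence - 1.0
    k_sv = float(np.sum(conc * y) / np.sum(conc * conc))
    if k_sv < 0:
        warnings.warn(
            f"negative K_SV {k_sv:.3g} M^-1: intensity rises with quencher",
            stacklevel=2,
        )

    resid = y - k_sv * conc
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot

    slope_free, intercept_free = np.polyfit(conc, q.f0 / q.fluorescence, 1)
    return QuenchFit(
        k_sv=k_sv,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        intercept_free=float(intercept_free),
    )
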