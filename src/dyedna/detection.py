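"""Calibration curves, 3×SD/slope detection limits, and DNA quantitation helpers.

A detection limit is computed as LOD = 3·SD/slope of a linear
calibration of instrument response (fluorescence intensity, or the
A_f/A_i absorbance ratio between the bound-band and free-band
wavelengths) against DNA mass concentration.  SD is read as the
residual standard deviation of the calibration fit; a blank-replicate
SD may be supplied instead.  Mass LODs (ng/mL) are converted to molar
LODs through the duplex molecular weight computed from the base
sequence, and the molar extinction coefficient at 260 nm is computed
from the sequence by the standard nearest-neighbor sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .spectra import Spectrum

__all__ = [
    "CalibrationFit",
    "DuplexInfo",
    "fit_calibration",
    "lod_from_calibration",
    "absorbance_ratio_response",
    "duplex_mw",
    "mass_to_molar",
    "molar_to_mass",
    "epsilon260_nearest_neighbor",
    "reverse_complement",
    "make_duplex_info",
]

MIN_CALIBRATION_POINTS = 5

# Residue masses of the 2'-deoxynucleoside 5'-monophosphates (g/mol) and the
# per-strand correction for the 5'-OH free-acid convention
# (remove one HPO3, 79.98, add one H2O, 18.02).
RESIDUE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}
STRAND_END_CORRECTION = 61.96

# Nearest-neighbor extinction coefficients at 260 nm (M^-1 cm^-1),
# Cantor-Warshaw-Shapiro doublet and monomer values as tabulated for
# single-stranded DNA.
EPS260_DOUBLET = {
    "AA": 27400, "AC": 21200, "AG": 25000, "AT": 22800,
    "CA": 21200, "CC": 14600, "CG": 18000, "CT": 15200,
    "GA": 25200, "GC": 17600, "GG": 21600, "GT": 20000,
    "TA": 23400, "TC": 16200, "TG": 19000, "TT": 16800,
}
EPS260_MONOMER = {"A": 15400, "C": 7400, "G": 11500, "T": 8700}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CalibrationFit:
    """Linear calibration with the pieces a 3×SD/slope LOD needs."""

    slope: float  # response per concentration unit
    intercept: float  # response units
    sd: float  # residual standard deviation, response units
    r_squared: float
    n_points: int
    mode: str  # "fluorescence" or "absorbance_ratio"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.mode not in ("fluorescence", "absorbance_ratio"):
            raise ValueError(f"unknown calibration mode {self.mode!r}")


@dataclass(frozen=True)
class DuplexInfo:
    strand1: str
    strand2: str
    length_bp: int
    mw: float  # g/mol, duplex
    epsilon260: float  # M^-1 cm^-1, sum of the two strands' ss values


def _check_sequence(strand: str, label: str = "strand") -> str:
    seq = strand.upper()
    if not seq:
        raise ValueError(f"{label} is empty")
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(f"{label}: non-ACGT character {base!r} at position {i + 1}")
    return seq


def reverse_complement(strand: str) -> str:
    return _check_sequence(strand)[::-1].translate(_COMPLEMENT)


def fit_calibration(
    conc: Sequence[float], response: Sequence[float], mode: str = "fluorescence"
) -> CalibrationFit:
    """OLS calibration line; SD is the residual standard deviation.

    At least five concentration points are required — the stated minimum
    for constructing these calibration curves.
    """
    c = np.asarray(conc, dtype=float)
    r = np.asarray(response, dtype=float)
    if c.size != r.size:
        raise ValueError("conc and response must have equal length")
    if c.size < MIN_CALIBRATION_POINTS:
        raise ValueError(
            f"calibration needs at least {MIN_CALIBRATION_POINTS} points, got {c.size}"
        )
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all concentrations equal")

    slope, intercept = np.polyfit(c, r, 1)
    resid = r - (slope * c + intercept)
    sd = float(np.sqrt(np.sum(resid**2) / (c.size - 2)))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        sd=sd,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=int(c.size),
        mode=mode,
    )


def lod_from_calibration(fit: CalibrationFit, sd_blank: float | None = None) -> float:
    """LOD = 3·SD/slope, in the concentration units of the calibration.

    ``sd_blank`` substitutes a blank-replicate SD for the residual SD.
    """
    sd = fit.sd if sd_blank is None else float(sd_blank)
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if fit.slope <= 0:
        raise ValueError(f"LOD undefined for non-positive slope {fit.slope:.3g}")
    return 3.0 * sd / fit.slope


def absorbance_ratio_response(
    s: Spectrum, lambda_f_nm: float, lambda_i_nm: float
) -> float:
    """A(λ_f)/A(λ_i): bound-band over free-band absorbance.

    Wavelengths are matched to the nearest grid point within 1 nm.
    """
    def _value_at(lam: float) -> float:
        idx = int(np.argmin(np.abs(s.wavelengths_nm - lam)))
        if abs(s.wavelengths_nm[idx] - lam) > 1.0:
            raise ValueError(f"wavelength {lam:g} nm more than 1 nm off the grid")
        return float(s.values[idx])

    a_f = _value_at(lambda_f_nm)
    a_i = _value_at(lambda_i_nm)
    if a_i <= 0:
        raise ValueError(f"reference absorbance A({lambda_i_nm:g} nm) = {a_i:.4g} <= 0")
    return a_f / a_i


def duplex_mw(strand1: str, strand2: str) -> float:
    """Molecular weight (g/mol) of a DNA duplex from its two strands.

    Residue-mass sum under the 5'-OH free-acid convention (61.96 g/mol
    subtracted per strand).  Strands that are not reverse complements
    get a warning, not an error, so mismatched or overhung duplexes can
    still be weighed.
    """
    s1 = _check_sequence(strand1, "strand1")
    s2 = _check_sequence(strand2, "strand2")
    if reverse_complement(s1) != s2:
        warnings.warn("strands are not exact reverse complements", stacklevel=2)
    mw = sum(RESIDUE_MASS[b] for b in s1 + s2) - 2 * STRAND_END_CORRECTION
    return float(mw)


def mass_to_molar(conc_ng_per_mL: float, mw: float) -> float:
    """ng/mL → mol/L given a molecular weight in g/mol."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return conc_ng_per_mL * 1e-6 / mw  # ng/mL = 1e-6 g/L


def molar_to_mass(conc_M: float, mw: float) -> float:
    """mol/L → ng/mL; inverse of :func:`mass_to_molar`."""
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return conc_M * mw * 1e6


def epsilon260_nearest_neighbor(strand: str) -> float:
    """Single-strand ε260 (M⁻¹cm⁻¹) by the nearest-neighbor method.

    ε = Σ ε(doublets) − Σ ε(internal monomers): every overlapping
    dinucleotide contributes its tabulated value and each base except
    the two termini is subtracted once to undo the double counting.
    """
    seq = _check_sequence(strand)
    if len(seq) < 2:
        raise ValueError("nearest-neighbor ε260 needs length >= 2")
    eps = sum(EPS260_DOUBLET[seq[i : i + 2]] for i in range(len(seq) - 1))
    eps -= sum(EPS260_MONOMER[b] for b in seq[1:-1])
    return float(eps)


def make_duplex_info(
    strand1: str, strand2: str, hypochromicity_factor: float = 1.0
) -> DuplexInfo:
    """Assemble duplex MW and ε260 for quantitation.

    The duplex ε260 is the sum of the two single-strand nearest-neighbor
    values scaled by an optional two-state hypochromicity factor
    (default 1.0, i.e. no hypochromic correction).
    """
    if not 0 < hypochromicity_factor <= 1.0:
        raise ValueError("hypochromicity_factor must lie in (0, 1]")
    s1 = _check_sequence(strand1, "strand1")
    s2 = _check_sequence(strand2, "strand2")
    eps = hypochromicity_factor * (
        epsilon260_nearest_neighbor(s1) + epsilon260_nearest_neighbor(s2)
    )
    return DuplexInfo(
        strand1=s1,
        strand2=s2,
        length_bp=min(len(s1), len(s2)),
        mw=duplex_mw(s1, s2),
        epsilon260=float(eps),
    )
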