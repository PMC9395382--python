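"""Spectrum container, CSV I/O, and descriptive spectral quantities.

The quantities here are the ones a dye-characterization table is built
from: the absorption/emission maximum ``lambda_max``, the bathochromic
(red) shift of the DNA-bound band relative to the free dye, the molar
extinction coefficient from a Beer-Lambert dilution series, the
fluorescence enhancement ratio F/F0, and integrated band areas used by
the relative quantum-yield method.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "BeerLambertFit",
    "SpectrumParseError",
    "read_spectrum",
    "lambda_max",
    "bathochromic_shift",
    "fit_beer_lambert",
    "enhancement_ratio",
    "integrate_band",
]

SPECTRUM_KINDS = ("absorption", "emission")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file violates the two-column contract."""


@dataclass(frozen=True)
class Spectrum:
    """A sampled optical spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nm, at least 3 points.
    values : array-like
        Absorbance (AU) or fluorescence (counts), same length as the grid.
    kind : {"absorption", "emission"}
    meta : mapping
        Free-form tags (dye id, solvent, DNA state, temperature).
    baseline_tolerance : float
        Most-negative absorbance accepted as baseline noise (AU).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str
    meta: Mapping[str, object] = field(default_factory=dict)
    baseline_tolerance: float = 0.01

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if self.kind not in SPECTRUM_KINDS:
            raise ValueError(f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if wl.ndim != 1 or vals.ndim != 1 or wl.size != vals.size:
            raise ValueError("wavelengths and values must be 1-D and the same length")
        if wl.size < 3:
            raise ValueError(f"a spectrum needs >= 3 points, got {wl.size}")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise ValueError("non-finite wavelength or value")
        if self.kind == "absorption" and vals.min() < -self.baseline_tolerance:
            raise ValueError(
                f"absorbance {vals.min():.4g} below baseline tolerance "
                f"-{self.baseline_tolerance:g}"
            )

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)


@dataclass(frozen=True)
class BeerLambertFit:
    """Result of an absorbance-vs-concentration line: ε from the slope."""

    epsilon: float  # M^-1 cm^-1
    intercept: float  # AU, baseline diagnostic
    r_squared: float
    path_length_cm: float

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")
        if self.path_length_cm <= 0:
            raise ValueError("path_length_cm must be > 0")


def read_spectrum(path, kind: str, meta: Mapping[str, object] | None = None) -> Spectrum:
    """Read a two-column (wavelength, value) delimited text file.

    Comma- or tab-delimited; a single non-numeric header row is allowed.
    Rows are sorted by wavelength; duplicate wavelengths are an error.
    """
    if hasattr(path, "read"):
        lines = path.read().splitlines()
        name = getattr(path, "name", "<stream>")
    else:
        name = str(path)
        with open(path, "r", encoding="utf-8") as fh:
            lines = fh.read().splitlines()

    rows: list[tuple[float, float]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = [p for p in line.replace("\t", ",").split(",") if p.strip() != ""]
        if len(parts) != 2:
            raise SpectrumParseError(f"{name}:{lineno}: expected 2 columns, got {len(parts)}")
        try:
            wl, val = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not rows:  # header row
                continue
            raise SpectrumParseError(f"{name}:{lineno}: non-numeric row {line!r}") from None
        rows.append((wl, val))

    if len(rows) < 3:
        raise SpectrumParseError(f"{name}: need >= 3 data rows, got {len(rows)}")
    rows.sort(key=lambda r: r[0])
    wl = np.array([r[0] for r in rows])
    if np.any(np.diff(wl) == 0):
        dup = wl[np.flatnonzero(np.diff(wl) == 0)[0]]
        raise SpectrumParseError(f"{name}: duplicate wavelength {dup:g} nm")
    vals = np.array([r[1] for r in rows])
    return Spectrum(wl, vals, kind=kind, meta=dict(meta or {}))


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Write the (wavelength_nm, value) CSV dialect ``read_spectrum`` reads."""
    buf = io.StringIO()
    buf.write("wavelength_nm,value\n")
    for wl, v in zip(s.wavelengths_nm, s.values):
        buf.write(f"{wl:.6g},{v:.10g}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(buf.getvalue())


def _window_mask(s: Spectrum, window_nm: tuple[float, float] | None) -> np.ndarray:
    if window_nm is None:
        return np.ones(len(s), dtype=bool)
    lo, hi = window_nm
    if hi < lo:
        lo, hi = hi, lo
    mask = (s.wavelengths_nm >= lo) & (s.wavelengths_nm <= hi)
    return mask


def lambda_max(s: Spectrum, window_nm: tuple[float, float] | None = None) -> float:
    """Wavelength (nm) of the global maximum, ties broken to the red.

    The red-most maximum is returned on exact ties because the
    longest-wavelength band is the analytically useful one for these
    charge-transfer dyes.
    """
    mask = _window_mask(s, window_nm)
    if not mask.any():
        raise ValueError(f"window {window_nm} does not overlap the wavelength grid")
    wl = s.wavelengths_nm[mask]
    vals = s.values[mask]
    best = vals.max()
    return float(wl[vals == best][-1])


def bathochromic_shift(free: Spectrum, bound: Spectrum) -> float:
    """λmax(bound) − λmax(free) in nm; positive means a red shift."""
    if free.kind != bound.kind:
        raise ValueError(f"kind mismatch: {free.kind!r} vs {bound.kind!r}")
    return lambda_max(bound) - lambda_max(free)


def fit_beer_lambert(
    conc_M: Sequence[float],
    absorbance: Sequence[float],
    path_length_cm: float = 1.0,
) -> BeerLambertFit:
    """Least-squares line A = ε·l·c + b; ε from the slope only.

    The intercept is fitted freely and reported as a baseline diagnostic.
    """
    c = np.asarray(conc_M, dtype=float)
    a = np.asarray(absorbance, dtype=float)
    if c.size != a.size or c.size < 3:
        raise ValueError("need >= 3 matched (concentration, absorbance) points")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")
    if np.ptp(c) == 0:
        raise ValueError("degenerate design: all concentrations equal")
    if path_length_cm <= 0:
        raise ValueError("path_length_cm must be > 0")

    slope, intercept = np.polyfit(c, a, 1)
    resid = a - (slope * c + intercept)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return BeerLambertFit(
        epsilon=max(float(slope) / path_length_cm, 0.0),
        intercept=float(intercept),
        r_squared=float(min(max(r2, 0.0), 1.0)),
        path_length_cm=path_length_cm,
    )


def enhancement_ratio(F: float, F0: float) -> float:
    """Fluorescence enhancement F/F0 (with vs without DNA)."""
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    return F / F0


def integrate_band(s: Spectrum, window_nm: tuple[float, float] | None = None) -> float:
    """Trapezoidal integral of the spectrum over a window (value·nm).

    Integration is on the native grid without resampling; the spectra
    this package handles are smooth, densely sampled bands.
    """
    mask = _window_mask(s, window_nm)
    if mask.sum() < 2:
        raise ValueError(f"window {window_nm} contains fewer than 2 grid points")
    return float(np.trapezoid(s.values[mask], s.wavelengths_nm[mask]))
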