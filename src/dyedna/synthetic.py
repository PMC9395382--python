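"""Synthetic-data generators for every stage of the analysis pipeline.

Each generator produces data with exactly the statistical structure its
downstream fitter assumes — titrations obeying the neighbor-exclusion
isotherm, quench series obeying Stern-Volmer, Gaussian absorption and
emission bands, solvatochromic Stokes-shift series on the packaged
solvent table, and linear calibration series — so parameter-recovery
round trips exercise the whole pipeline without any measured spectra.

Defaults mirror the study conditions: dye at 2 µM titrated with DNA at
0.3–3 µM (per bp), NaCl quenching over 50–200 mM, and proportional
Gaussian noise at 1% (typical plate-reader reproducibility) when noise
is requested.

Reproducibility: a single integer seed is split into fixed per-generator
substreams, so adding a call to one generator never shifts the noise
another generator draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import solvatochromism as solv
from .binding import TitrationSeries, forward_fluorescence
from .quenching import QuenchSeries
from .spectra import Spectrum

__all__ = [
    "GeneratorConfig",
    "DEFAULT_C_DYE_M",
    "DEFAULT_C_DNA_GRID_M",
    "DEFAULT_NACL_GRID_M",
    "gen_titration",
    "gen_quench_series",
    "gen_spectrum",
    "gen_solvatochromic_series",
    "gen_calibration",
]

NOISE_MODELS = ("none", "gaussian_additive", "gaussian_proportional")

# Study conditions: [Dye] = 2 uM; [DNA (bp)] = 0.3-3 uM; NaCl 50-200 mM.
DEFAULT_C_DYE_M = 2e-6
DEFAULT_C_DNA_GRID_M = np.linspace(0.3e-6, 3e-6, 10)
DEFAULT_NACL_GRID_M = np.array([0.05, 0.10, 0.15, 0.20])

# Fixed substream ids; order is part of the reproducibility contract.
_STREAMS = {
    "titration": 1,
    "quench": 2,
    "spectrum": 3,
    "solvatochromic": 4,
    "calibration": 5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded noise configuration shared by all generators."""

    seed: int = 0
    noise_model: str = "none"
    noise_scale: float = 0.01  # 1% proportional, or additive in data units

    def __post_init__(self) -> None:
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(_STREAMS[stream],))
        )

    def apply_noise(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.noise_model == "none" or self.noise_scale == 0:
            return values
        draws = rng.standard_normal(values.shape)
        if self.noise_model == "gaussian_additive":
            return values + self.noise_scale * draws
        return values * (1.0 + self.noise_scale * draws)


def gen_titration(
    k_b: float,
    site_size: float,
    f_max: float,
    c_dye: float = DEFAULT_C_DYE_M,
    c_dna_grid: Sequence[float] | None = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> TitrationSeries:
    """Simulate a fluorescence titration by solving the isotherm per point."""
    grid = np.asarray(
        DEFAULT_C_DNA_GRID_M if c_dna_grid is None else c_dna_grid, dtype=float
    )
    f = np.array(
        [forward_fluorescence(c, c_dye, k_b, site_size, f_max) for c in grid]
    )
    f = cfg.apply_noise(f, cfg.rng("titration"))
    return TitrationSeries(c_dye=c_dye, c_dna_bp=grid, fluorescence=f)


def gen_quench_series(
    k_sv: float,
    f0: float = 1000.0,
    q_grid: Sequence[float] | None = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> QuenchSeries:
    """Stern-Volmer series F = F0/(1 + K_SV [Q]) plus configured noise."""
    if k_sv < 0:
        raise ValueError("k_sv must be >= 0")
    q = np.asarray(DEFAULT_NACL_GRID_M if q_grid is None else q_grid, dtype=float)
    f = f0 / (1.0 + k_sv * q)
    f = cfg.apply_noise(f, cfg.rng("quench"))
    return QuenchSeries(f0=f0, quencher_M=q, fluorescence=f)


def gen_spectrum(
    center_nm: float,
    fwhm_nm: float,
    amplitude: float,
    grid: Sequence[float] | None = None,
    kind: str = "absorption",
    cfg: GeneratorConfig = GeneratorConfig(),
    meta: dict | None = None,
) -> Spectrum:
    """Gaussian band on a wavelength grid (default 350-800 nm, 0.5-nm step)."""
    if fwhm_nm <= 0:
        raise ValueError("fwhm must be > 0")
    wl = np.arange(350.0, 800.5, 0.5) if grid is None else np.asarray(grid, dtype=float)
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    vals = amplitude * np.exp(-0.5 * ((wl - center_nm) / sigma) ** 2)
    vals = cfg.apply_noise(vals, cfg.rng("spectrum"))
    return Spectrum(wl, vals, kind=kind, meta=dict(meta or {}))


def gen_solvatochromic_series(
    dipole_debye: float,
    cavity_radius_angstrom: float,
    nu0_abs: float,
    nu0_em: float,
    solvent_names: Sequence[str] | None = None,
    et30_sensitivity: float = 0.0,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> list[solv.SolvatochromicPoint]:
    """Stokes-shift series obeying the Lippert relation on packaged solvents.

    The emission wavenumber absorbs the Δf-dependent Stokes shift on top
    of the vacuum gap ``nu0_abs - nu0_em``; the absorption energy can
    additionally be tied linearly to E_T(30) (cm⁻¹ per kcal/mol) to
    emulate polarity-sensitive absorption.
    """
    names = list(solvent_names or solv.SOLVENTS)
    unknown = [n for n in names if n not in solv.SOLVENTS]
    if unknown:
        raise KeyError(f"unknown solvents {unknown}; packaged: {sorted(solv.SOLVENTS)}")
    slope = solv.slope_from_dipole_change(dipole_debye, cavity_radius_angstrom)
    rng = cfg.rng("solvatochromic")
    points = []
    for name in names:
        rec = solv.SOLVENTS[name]
        nu_abs = nu0_abs + et30_sensitivity * rec.et30
        shift = slope * rec.delta_f + (nu0_abs - nu0_em)
        nu_abs, nu_em = cfg.apply_noise(
            np.array([nu_abs, nu_abs - shift]), rng
        )
        points.append(solv.SolvatochromicPoint(solvent=rec, nu_abs=nu_abs, nu_em=nu_em))
    return points


def gen_calibration(
    slope: float,
    intercept: float,
    sd: float,
    conc_grid: Sequence[float] | None = None,
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Linear calibration responses with additive Gaussian noise of scale sd."""
    conc = (
        np.linspace(10.0, 200.0, 6)
        if conc_grid is None
        else np.asarray(conc_grid, dtype=float)
    )
    if conc.size < 5:
        raise ValueError("need >= 5 calibration concentrations")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    resp = slope * conc + intercept
    if sd > 0:
        resp = resp + sd * cfg.rng("calibration").standard_normal(conc.shape)
    return conc, resp
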