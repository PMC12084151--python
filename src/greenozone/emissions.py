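"""Biogenic isoprene emissions in the MEGAN form.

Per cell and hour the flux of species *i* is

    F_i = γ_i · Σ_j ε_{i,j} χ_j

with χ_j the PFT fractional coverages, ε_{i,j} the standard emission
factor (µg m⁻² h⁻¹ at standard conditions) and the emission activity
factor

    γ_i = C_CE · LAI · γ_L · γ_T · γ_LA · γ_SM · γ_CI .

The light and temperature responses use the published MEGAN2.1 closed
forms for isoprene-like (light-dependent) emissions:

* γ_T = E_opt · CT2 · exp(CT1·x) / (CT2 − CT1·(1 − exp(CT2·x))) with
  x = (1/T_opt − 1/T)/0.00831; single-peaked with maximum E_opt at T_opt.
* γ_L = C_P · α·PAR / sqrt(1 + α²·PAR²); zero in the dark, saturating.

Leaf temperature is approximated by 2 m air temperature. Leaf-age,
soil-moisture and CO₂-inhibition activities default to 1 (no driver data)
and are overridable. The canopy-environment coefficient C_CE is chosen so
that γ = 1 at standard conditions (LAI = 5, T = 303.15 K,
PAR = 1500 µmol m⁻² s⁻¹), following the MEGAN normalization convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .grid import Grid
from .landcover import LAIMap, N_PFT, PFTMap

STANDARD_LAI = 5.0
STANDARD_T_K = 303.15
STANDARD_PAR = 1500.0


@dataclass(frozen=True)
class ActivityParams:
    """Isoprene activity-response parameters (MEGAN2.1 closed forms)."""

    ct1: float = 95.0
    ct2: float = 230.0
    t_opt_k: float = 313.0
    e_opt: float = 2.034
    alpha: float = 0.0027
    cp: float = 1.066
    gamma_leaf_age: float = 1.0
    gamma_soil_moisture: float = 1.0
    gamma_co2: float = 1.0

    def c_ce(self) -> float:
        """Canopy coefficient normalizing γ to 1 at standard conditions."""
        g = (STANDARD_LAI * gamma_temperature(STANDARD_T_K, self)
             * gamma_light(STANDARD_PAR, self)
             * self.gamma_leaf_age * self.gamma_soil_moisture * self.gamma_co2)
        return 1.0 / g


@dataclass
class EmissionField:
    """Hourly per-cell emission flux (µg m⁻² h⁻¹) for one species."""

    grid: Grid
    species: str
    flux: np.ndarray                       # (n_hours, ny, nx), >= 0
    epsilon: np.ndarray                    # (16,) standard emission factors
    params: ActivityParams = field(default_factory=ActivityParams)

    def __post_init__(self) -> None:
        if self.flux.shape[1:] != self.grid.shape:
            raise ValueError("flux raster shape mismatch")
        if np.nanmin(self.flux) < 0:
            raise ValueError("emission flux must be nonnegative")


def load_emission_factors(path: str | None = None,
                          species: str = "isoprene") -> np.ndarray:
    """(16,) standard emission factors ε_j, µg m⁻² h⁻¹, by PFT index."""
    if path:
        df = pd.read_csv(path)
    else:
        with resources.files("greenozone.data").joinpath(
                "isoprene_emission_factors.csv").open() as fh:
            df = pd.read_csv(fh)
    if species not in df.columns:
        raise ValueError(f"no emission-factor column for species {species!r}")
    s = df.set_index("pft_index")[species]
    missing = set(range(1, N_PFT + 1)) - set(s.index)
    if missing:
        raise ValueError(f"ε table missing PFT entries: {sorted(missing)}")
    return s.reindex(range(1, N_PFT + 1)).to_numpy(dtype=float)


def gamma_temperature(t_leaf_k: np.ndarray | float,
                      params: ActivityParams = ActivityParams()) -> np.ndarray | float:
    """Temperature activity γ_T; single-peaked, equal to E_opt at T_opt."""
    t = np.asarray(t_leaf_k, dtype=float)
    if np.any(t < 240.0) or np.any(t > 330.0):
        raise ValueError("leaf temperature outside the physical range [240, 330] K")
    x = (1.0 / params.t_opt_k - 1.0 / t) / 0.00831
    num = params.ct2 * np.exp(params.ct1 * x)
    den = params.ct2 - params.ct1 * (1.0 - np.exp(params.ct2 * x))
    out = params.e_opt * num / den
    return out if out.ndim else float(out)


def gamma_light(par: np.ndarray | float,
                params: ActivityParams = ActivityParams()) -> np.ndarray | float:
    """Light activity γ_L; zero at PAR = 0, saturating with PAR."""
    p = np.asarray(par, dtype=float)
    if np.any(p < 0):
        raise ValueError("PAR must be nonnegative")
    out = params.cp * params.alpha * p / np.sqrt(1.0 + (params.alpha * p) ** 2)
    return out if out.ndim else float(out)


def activity_factor(lai: np.ndarray, t_leaf_k: np.ndarray, par: np.ndarray,
                    params: ActivityParams = ActivityParams()) -> np.ndarray:
    """γ = C_CE · LAI · γ_L · γ_T · γ_LA · γ_SM · γ_CI (broadcasting)."""
    return (params.c_ce() * lai * gamma_light(par, params)
            * gamma_temperature(t_leaf_k, params)
            * params.gamma_leaf_age * params.gamma_soil_moisture
            * params.gamma_co2)


def emission_flux(pft_map: PFTMap, lai_map: LAIMap, t2m_k: np.ndarray,
                  par: np.ndarray, params: ActivityParams = ActivityParams(),
                  epsilon: np.ndarray | None = None,
                  species: str = "isoprene") -> EmissionField:
    """Hourly flux F = γ(cell, hour) · Σ_j ε_j χ_j on the analysis grid."""
    if pft_map.grid != lai_map.grid:
        raise ValueError("PFT and LAI grids differ")
    if t2m_k.shape != par.shape or t2m_k.shape[1:] != pft_map.grid.shape:
        raise ValueError("meteorology misaligned with the analysis grid")
    eps = load_emission_factors(species=species) if epsilon is None \
        else np.asarray(epsilon, dtype=float)
    if eps.shape != (N_PFT,):
        raise ValueError("ε table must cover all 16 PFTs")
    source = np.tensordot(eps, pft_map.chi, axes=(0, 0))      # Σ_j ε_j χ_j
    gamma = activity_factor(lai_map.lai[None, :, :], t2m_k, par, params)
    return EmissionField(pft_map.grid, species, gamma * source[None, :, :],
                         eps, params)


def seasonal_budget(em: EmissionField, mask: np.ndarray,
                    cell_area_m2: float | np.ndarray | None = None,
                    dt_hours: float = 1.0) -> dict[str, float]:
    """Season totals in Gg and the urban share of the domain total.

    total = Σ_cells Σ_hours F · area · Δt, with F in µg m⁻² h⁻¹; exact
    decomposition total = urban + non-urban by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != em.grid.shape:
        raise ValueError("mask must live on the emission grid")
    area = em.grid.cell_area_m2 if cell_area_m2 is None else cell_area_m2
    if np.any(np.asarray(area) < 0):
        raise ValueError("cell areas must be nonnegative")
    per_cell_ug = em.flux.sum(axis=0) * area * dt_hours       # µg per cell
    to_gg = 1e-15                                             # µg -> Gg
    urban = float(per_cell_ug[mask].sum() * to_gg)
    nonurban = float(per_cell_ug[~mask].sum() * to_gg)
    total = urban + nonurban
    return {"species": em.species, "total_Gg": total, "urban_Gg": urban,
            "nonurban_Gg": nonurban,
            "urban_fraction": urban / total if total > 0 else float("nan")}
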