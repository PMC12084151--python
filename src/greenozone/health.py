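"""Ozone-attributable mortality and urban-greening attribution.

The burden framework follows the attributable-fraction formulation used in
grid-level ambient-pollution assessments:

    M      = Σ_g P_g · Î · (RR(C_g) − 1)          attributable deaths
    Î      = I / RR̄                               underlying incidence
    RR̄    = Σ_g P_g·RR(C_g) / Σ_g P_g            population-weighted RR
    RR(C)  = rr^((C − C0)/10)  if C > C0, else 1

where C_g is the cell's exposure (seasonal mean of daily MDA8 O₃, ppb),
P_g population, I the reported annual cause-specific mortality incidence,
C0 the theoretical minimum-risk concentration (32.4 ppb) and rr the
relative risk per 10 ppb. A seasonal burden scales the annual incidence by
season_days/365.

Urban-greening attribution computes the burden independently for the Base
(no urban BVOC) and UG exposure surfaces; the attributed deaths are
M_UG − M_Base and the attribution fraction (M_UG − M_Base)/M_UG.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_C0_PPB = 32.4
DEFAULT_RR_PER_10PPB = 1.06   # editable; per-10-ppb COPD risk from cohort literature


@dataclass(frozen=True)
class RRModel:
    """Log-linear concentration-response above a minimum-risk threshold."""

    rr_per_10ppb: float = DEFAULT_RR_PER_10PPB
    c0: float = DEFAULT_C0_PPB
    cause: str = "copd"
    age_groups: tuple[str, ...] = ("all",)

    def __post_init__(self) -> None:
        if self.rr_per_10ppb <= 0:
            raise ValueError("rr_per_10ppb must be positive")
        if self.c0 < 0:
            raise ValueError("minimum-risk concentration must be nonnegative")


@dataclass
class HealthBurden:
    """Gridded and aggregated attributable deaths for one exposure surface."""

    m_grid: np.ndarray                # (ny, nx) deaths, summed over age groups
    total: float
    by_group: pd.DataFrame            # age_group, incidence, i_hat, deaths
    i_hat: dict[str, float]           # underlying incidence per group
    rr_bar: float
    season_days: float
    attribution_fraction: float | None = None


def relative_risk(c: np.ndarray | float, model: RRModel) -> np.ndarray | float:
    """RR(C) = rr^((C − C0)/10) where C > C0, exactly 1 elsewhere."""
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be nonnegative")
    rr = np.where(c_arr > model.c0,
                  model.rr_per_10ppb ** ((c_arr - model.c0) / 10.0), 1.0)
    return rr if rr.ndim else float(rr)


def population_weighted_rr(c: np.ndarray, p: np.ndarray,
                           model: RRModel) -> float:
    """RR̄ = Σ_g P_g·RR(C_g) / Σ_g P_g."""
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    if c.shape != p.shape:
        raise ValueError("concentration and population rasters misaligned")
    if np.any(p < 0):
        raise ValueError("population must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("total population is zero")
    return float(np.sum(p * relative_risk(c, model)) / total)


def _incidence_frame(incidence: pd.DataFrame | dict | float) -> pd.DataFrame:
    if isinstance(incidence, pd.DataFrame):
        df = incidence[["age_group", "annual_rate"]].copy()
    elif isinstance(incidence, dict):
        df = pd.DataFrame({"age_group": list(incidence),
                           "annual_rate": list(incidence.values())})
    else:
        df = pd.DataFrame({"age_group": ["all"],
                           "annual_rate": [float(incidence)]})
    if (df["annual_rate"] < 0).any():
        raise ValueError("incidence rates must be nonnegative")
    return df


def attributable_mortality(c: np.ndarray, p: np.ndarray,
                           incidence: pd.DataFrame | dict | float,
                           model: RRModel = RRModel(),
                           season_days: float = 365.0) -> HealthBurden:
    """Attributable deaths M = Σ_g P_g · Î · (RR(C_g) − 1) per age group.

    ``incidence`` holds annual rates; a seasonal burden (e.g. JJA,
    season_days=92) scales them by season_days/365. Population is shared
    across age groups unless the incidence table carries a
    ``pop_fraction`` column splitting it.
    """
    c = np.asarray(c, dtype=float)
    p = np.asarray(p, dtype=float)
    inc = _incidence_frame(incidence)
    rr = relative_risk(c, model)
    rr_bar = population_weighted_rr(c, p, model)
    scale = season_days / 365.0

    frac = (incidence["pop_fraction"].to_numpy(dtype=float)
            if isinstance(incidence, pd.DataFrame)
            and "pop_fraction" in incidence.columns
            else np.ones(len(inc)))
    m_grid = np.zeros_like(p)
    rows, i_hat = [], {}
    excess = rr - 1.0
    for (_, row), pf in zip(inc.iterrows(), frac):
        ih = row["annual_rate"] / rr_bar
        grid = (p * pf) * ih * excess * scale
        deaths = float(grid.sum())
        m_grid += grid
        i_hat[row["age_group"]] = float(ih)
        rows.append({"age_group": row["age_group"],
                     "annual_rate": row["annual_rate"],
                     "i_hat": float(ih), "deaths": deaths})
    return HealthBurden(m_grid=m_grid, total=float(m_grid.sum()),
                        by_group=pd.DataFrame(rows), i_hat=i_hat,
                        rr_bar=rr_bar, season_days=season_days)


def attribute_to_urban_greening(c_base: np.ndarray, c_ug: np.ndarray,
                                p: np.ndarray,
                                incidence: pd.DataFrame | dict | float,
                                model: RRModel = RRModel(),
                                season_days: float = 92.0) -> dict:
    """Split the O₃ burden into Base and urban-greening components.

    Both scenario burdens are computed independently (each with its own
    population-weighted RR̄ and underlying incidence); attributed deaths
    are M_UG − M_Base and the fraction (M_UG − M_Base)/M_UG, which lies in
    [0, 1] whenever the UG exposure dominates cellwise. Reported as None
    when M_UG = 0.
    """
    if np.asarray(c_base).shape != np.asarray(c_ug).shape:
        raise ValueError("scenario exposure rasters misaligned")
    burden_base = attributable_mortality(c_base, p, incidence, model, season_days)
    burden_ug = attributable_mortality(c_ug, p, incidence, model, season_days)
    attributed = burden_ug.total - burden_base.total
    fraction = attributed / burden_ug.total if burden_ug.total > 0 else None
    burden_ug.attribution_fraction = fraction
    return {"m_base": burden_base.total, "m_ug": burden_ug.total,
            "attributed": attributed, "fraction": fraction,
            "burden_base": burden_base, "burden_ug": burden_ug}
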