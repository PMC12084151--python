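"""Independent brute-force oracles used by the unit and acceptance tests.

Each function here is a separate, deliberately naive transcription of the
quantity it checks — loops and closed forms, no shared code with the
package implementation.
"""
from __future__ import annotations

import math

import numpy as np


def mda8_brute_force(hourly: np.ndarray) -> np.ndarray:
    """Exhaustive O(n·8) scan over every 8-hour window of a 1-D series.

    Windows start at each hour; a window assigned to its start day needs
    >= 6 valid (non-NaN) hours; a day needs >= 18 valid windows, else NaN.
    """
    n_days = len(hourly) // 24
    out = np.full(n_days, np.nan)
    for d in range(n_days):
        window_means = []
        for s in range(24):
            hours = [hourly[d * 24 + s + k]
                     for k in range(8) if d * 24 + s + k < len(hourly)]
            valid = [h for h in hours if not math.isnan(h)]
            if len(valid) >= 6:
                window_means.append(sum(valid) / len(valid))
        if len(window_means) >= 18:
            out[d] = max(window_means)
    return out


def health_brute_force(c, p, incidence_rates, rr, c0, season_days=365.0):
    """Loop transcription of the attributable-mortality chain.

    Returns (m_total, m_grid, rr_bar, i_hat_per_group) computed cell by
    cell: RR(C)=rr^((C-c0)/10) above c0 else 1; RR̄ population-weighted;
    Î = I/RR̄; M = Σ_g Σ_groups P_g·Î·(RR_g − 1)·season/365.
    """
    c = np.asarray(c, dtype=float).ravel()
    p = np.asarray(p, dtype=float).ravel()
    rr_cells = []
    for cg in c:
        rr_cells.append(rr ** ((cg - c0) / 10.0) if cg > c0 else 1.0)
    num = sum(pg * r for pg, r in zip(p, rr_cells))
    rr_bar = num / p.sum()
    i_hat = [rate / rr_bar for rate in incidence_rates]
    m_grid = np.zeros_like(p)
    for g, (pg, r) in enumerate(zip(p, rr_cells)):
        for ih in i_hat:
            m_grid[g] += pg * ih * (r - 1.0) * season_days / 365.0
    return m_grid.sum(), m_grid, rr_bar, i_hat


def gamma_t_closed_form(t_k, ct1=95.0, ct2=230.0, t_opt=313.0, e_opt=2.034):
    """Independent transcription of the single-peaked temperature response."""
    x = (1.0 / t_opt - 1.0 / t_k) / 0.00831
    return e_opt * ct2 * math.exp(ct1 * x) / (
        ct2 - ct1 * (1.0 - math.exp(ct2 * x)))


def gamma_l_closed_form(par, alpha=0.0027, cp=1.066):
    """Independent transcription of the saturating light response."""
    return cp * alpha * par / math.sqrt(1.0 + (alpha * par) ** 2)


def ar1_daily_anomalies(rng: np.random.Generator, n: int, sd: float,
                        rho: float) -> np.ndarray:
    """Re-simulation of the meteorology generator's daily-anomaly recipe."""
    z = rng.standard_normal(n)
    a = np.empty(n)
    a[0] = sd * z[0]
    for d in range(1, n):
        a[d] = rho * a[d - 1] + sd * math.sqrt(1.0 - rho ** 2) * z[d]
    return a
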