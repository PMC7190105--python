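"""Stylized multi-region partial-equilibrium crop market.

Constant-elasticity (log-linear) supply and demand per region and crop,
cleared each year against a single world price per commodity (net-trade
closure: regional surpluses and deficits sum to zero). Supply is harvested
area — responding to the current world price — times an exogenously
growing, shifter-adjusted yield; demand scales with population and
per-capita income and responds to its own price. Crops do not interact
through cross-price terms, so each commodity clears independently.

The year-by-year projection turns FPU yield shifters into 2010-2050
trajectories of prices, areas, production and consumption, plus a
livestock-feed feedback: cheaper feed grain supports a larger cattle herd
and hence more enteric emissions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp

from .config import LivestockLink
from .tailoring import shift_supply

#: solver tolerance on relative excess demand
CLEARING_TOL = 1e-10
_MAX_FP_ITER = 200


class ConvergenceError(RuntimeError):
    """Market failed to clear; carries the last residual."""


@dataclass
class YearSolution:
    price: float
    area: np.ndarray
    yield_: np.ndarray
    supply: np.ndarray
    demand: np.ndarray


def _clear_crop(a_coef, eps_s, b_coef, eps_d, p0=1.0):
    """World price where sum_i a_i P^eps_s_i = sum_j b_j P^eps_d_j.

    Damped fixed point on log price (Newton-like step using the mean
    elasticity spread), falling back to bisection bracketing if it fails
    to converge. Excess demand is strictly decreasing in P (supply
    elasticities >= 0, demand elasticities <= 0), so the root is unique.
    """
    a_coef = np.asarray(a_coef, float)
    b_coef = np.asarray(b_coef, float)
    eps_s = np.asarray(eps_s, float)
    eps_d = np.asarray(eps_d, float)
    log_a, log_b = np.log(a_coef), np.log(b_coef)

    def excess_log(lp):
        # log demand minus log supply, computed in log space for stability
        s = logsumexp(log_a + eps_s * lp)
        d = logsumexp(log_b + eps_d * lp)
        return float(d - s)

    spread = max(float(np.mean(eps_s) - np.mean(eps_d)), 1e-6)
    lp = np.log(p0)
    for _ in range(_MAX_FP_ITER):
        f = excess_log(lp)
        if abs(np.expm1(f)) < CLEARING_TOL:
            return float(np.exp(lp))
        lp += 0.9 * f / spread

    lo, hi = -4.0, 4.0
    for _ in range(60):
        if excess_log(lo) > 0 >= excess_log(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise ConvergenceError(
            f"cannot bracket clearing price; residual {excess_log(lp):.3e}")
    lp = brentq(excess_log, lo, hi, xtol=1e-14, rtol=8.9e-16)
    if abs(np.expm1(excess_log(lp))) > 1e-8:
        raise ConvergenceError(
            f"bisection residual {excess_log(lp):.3e} above tolerance")
    return float(np.exp(lp))


def _region_shifters(shifters, regions, crop):
    """(region, crop) -> shifter fraction lookup; missing pairs are 0."""
    if shifters is None:
        return np.zeros(len(regions))
    return np.array([shifters.get((r, crop), 0.0) for r in regions])


def solve_year(params: pd.DataFrame, macro: pd.DataFrame, year_index: int,
               shifters=None, climate_trend=None, shifter_mode="growth",
               p_start=None) -> pd.DataFrame:
    """Clear every crop market for one year; returns the state table.

    ``params`` is the per-region x crop parameter table
    (see :mod:`csasim.world`); ``year_index`` counts years since the base
    year. ``shifters`` maps (region_id, crop) to a total fractional yield
    shifter; ``climate_trend`` maps (region_id, crop) to an annual yield
    trend modifier (fraction/yr). ``p_start`` optionally maps crop to a
    warm-start price.

    Output rows: region_id, crop, price, area, yield, production, demand,
    net_trade. Net trade sums to ~0 per crop (world clearing).
    """
    m = macro.set_index("region_id")
    t = year_index
    rows = []
    for crop, grp in params.groupby("crop", sort=True):
        regions = grp["region_id"].to_numpy()
        pop_ratio = ((1.0 + m.loc[regions, "pop_growth"].to_numpy()) ** t)
        inc_ratio = ((1.0 + m.loc[regions, "income_growth"].to_numpy()) ** t)

        trend = (np.array([climate_trend.get((r, crop), 0.0) for r in regions])
                 if climate_trend is not None else np.zeros(len(regions)))
        shift = _region_shifters(shifters, regions, crop)
        g = grp["yield_growth"].to_numpy() + trend
        if shifter_mode == "growth":
            g_eff = np.array([shift_supply(gi, si, "growth")
                              for gi, si in zip(g, shift)])
            yld = grp["base_yield"].to_numpy() * (1.0 + g_eff) ** t
        else:  # level entry: first-year bump, BAU growth afterwards
            yld = (grp["base_yield"].to_numpy() * (1.0 + shift)
                   * (1.0 + g) ** t)

        a_coef = grp["base_area"].to_numpy() * yld          # supply at P=1
        eps_s = grp["area_price_elast"].to_numpy()
        b_coef = (grp["demand_base"].to_numpy() * pop_ratio
                  * inc_ratio ** grp["income_elast"].to_numpy())
        eps_d = grp["demand_price_elast"].to_numpy()

        p0 = 1.0 if p_start is None else p_start.get(crop, 1.0)
        price = _clear_crop(a_coef, eps_s, b_coef, eps_d, p0)
        area = grp["base_area"].to_numpy() * price ** eps_s
        supply = area * yld
        demand = b_coef * price ** eps_d
        rows.append(pd.DataFrame({
            "region_id": regions, "crop": crop, "price": price,
            "area": area, "yield": yld, "production": supply,
            "demand": demand, "net_trade": supply - demand,
        }))
    return pd.concat(rows, ignore_index=True)


def project(params: pd.DataFrame, macro: pd.DataFrame, years,
            shifters=None, climate_trend=None,
            shifter_mode="growth") -> pd.DataFrame:
    """Annual market states for a run of years (inclusive range or list).

    Recursive annual solution with warm-started prices; years are calendar
    years, internally indexed from the first. Solver failures propagate
    with the year attached.
    """
    years = list(years)
    base = years[0]
    states = []
    p_start = None
    for y in years:
        try:
            st = solve_year(params, macro, y - base, shifters,
                            climate_trend, shifter_mode, p_start)
        except ConvergenceError as e:
            raise ConvergenceError(f"year {y}: {e}") from e
        st.insert(0, "year", y)
        p_start = st.groupby("crop")["price"].first().to_dict()
        states.append(st)
    return pd.concat(states, ignore_index=True)


def feed_price_index(state: pd.DataFrame, params: pd.DataFrame) -> float:
    """Feed-grain price index: feed-quantity-weighted mean of world prices."""
    fs = params.groupby("crop")["feed_share"].first()
    crop_state = state.groupby("crop").agg(price=("price", "first"),
                                           demand=("demand", "sum"))
    w = crop_state["demand"] * fs.reindex(crop_state.index)
    if w.sum() == 0:
        return 1.0
    return float(np.average(crop_state["price"], weights=w))


def livestock_feedback(price_ratio: float, link: LivestockLink):
    """Herd and cattle-emission response to a feed-price change vs BAU.

    herd delta = base*(ratio**elasticity - 1) head; emission delta in
    t CO2e/yr. Ratio 1 (no price change) gives (0, 0); cheaper feed
    (ratio < 1, elasticity <= 0) grows the herd and its emissions.
    """
    if price_ratio <= 0:
        raise ValueError("price ratio must be > 0")
    herd = link.base_herd * price_ratio ** link.feed_price_elast
    delta = herd - link.base_herd
    return delta, delta * link.ef_per_head


def production_and_area_report(states_scen: pd.DataFrame,
                               states_bau: pd.DataFrame) -> pd.DataFrame:
    """Per-crop world report: % changes first->last year, and vs-BAU deltas.

    Both runs must cover the same regions, crops and years (mismatched
    worlds are a hard error). Columns: crop, production_pct_change,
    price_pct_change, bau_production_pct_change, bau_price_pct_change,
    production_delta_vs_bau_pct, price_growth_delta_vs_bau_pp,
    area_delta_vs_bau_ha.
    """
    for col in ("region_id", "crop", "year"):
        if set(states_scen[col].unique()) != set(states_bau[col].unique()):
            raise ValueError(f"scenario and BAU runs disagree on {col}")

    def world(states):
        return (states.groupby(["year", "crop"])
                .agg(production=("production", "sum"), area=("area", "sum"),
                     price=("price", "first")).reset_index())

    ws, wb = world(states_scen), world(states_bau)
    y0, y1 = ws["year"].min(), ws["year"].max()
    rows = []
    for crop in sorted(ws["crop"].unique()):
        s0 = ws.query("year == @y0 and crop == @crop").iloc[0]
        s1 = ws.query("year == @y1 and crop == @crop").iloc[0]
        b0 = wb.query("year == @y0 and crop == @crop").iloc[0]
        b1 = wb.query("year == @y1 and crop == @crop").iloc[0]
        prod_pct = 100.0 * (s1["production"] / s0["production"] - 1.0)
        price_pct = 100.0 * (s1["price"] / s0["price"] - 1.0)
        bau_prod_pct = 100.0 * (b1["production"] / b0["production"] - 1.0)
        bau_price_pct = 100.0 * (b1["price"] / b0["price"] - 1.0)
        rows.append({
            "crop": crop,
            "production_pct_change": prod_pct,
            "price_pct_change": price_pct,
            "bau_production_pct_change": bau_prod_pct,
            "bau_price_pct_change": bau_price_pct,
            "production_delta_vs_bau_pct":
                100.0 * (s1["production"] / b1["production"] - 1.0),
            "price_growth_delta_vs_bau_pp": price_pct - bau_price_pct,
            "area_delta_vs_bau_ha": s1["area"] - b1["area"],
        })
    return pd.DataFrame(rows)
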