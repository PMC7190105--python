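"""Food-security indicators from market outcomes.

Regional food consumption is converted to kilocalories per capita per
day; the share of the population at risk of hunger follows a monotone
empirical-style mapping of kilocalorie availability relative to a
base-year reference; the share of undernourished children under five is
a linear index in calorie availability and three socio-economic
covariates (women's secondary-education access, the female-to-male
life-expectancy ratio, and a health-and-sanitation index), clipped to
[0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import KCAL_PER_T, ChildParams, HungerParams


def kcal_per_capita(consumption_t, kcal_per_t, population):
    """kcal per person per day from annual consumption by crop.

    ``consumption_t`` and ``kcal_per_t`` are mappings keyed by crop
    (tonnes/yr and kcal/tonne). Linear in consumption.
    """
    if population <= 0:
        raise ValueError("population must be > 0")
    total = sum(consumption_t[c] * kcal_per_t[c] for c in consumption_t)
    return total / population / 365.0


def share_at_risk(rel_availability, params: HungerParams):
    """Population share at risk of hunger given relative kcal availability.

    share = clip(s0 * availability**(-eta), 0, 1): anchored at s0 for
    availability 1, strictly decreasing where unclipped, tending to 0 as
    availability grows.
    """
    rel = np.asarray(rel_availability, dtype=float)
    if np.any(rel <= 0):
        raise ValueError("relative availability must be > 0")
    out = np.clip(params.s0 * rel ** (-params.eta), 0.0, 1.0)
    return out if out.ndim else float(out)


def undernourished_children(kcal, edu, life_ratio, sanitation,
                            params: ChildParams, child_population):
    """Millions of undernourished children under five.

    Linear index in calorie availability and the three covariates, clipped
    to [0, 1], times the under-five population. Decreasing in kcal.
    """
    share = (params.base_share
             + params.c_kcal * (np.asarray(kcal, float) - params.kcal_ref) / 1000.0
             + params.c_edu * (np.asarray(edu, float) - params.edu_ref)
             + params.c_life * (np.asarray(life_ratio, float) - params.life_ref)
             + params.c_san * (np.asarray(sanitation, float) - params.san_ref))
    share = np.clip(share, 0.0, 1.0)
    out = share * np.asarray(child_population, float) / 1e6
    return out if np.ndim(out) else float(out)


def indicator_table(states: pd.DataFrame, macro: pd.DataFrame,
                    kcal_ref_world: float | None = None,
                    eta: float = 2.0,
                    child_params: ChildParams = ChildParams(),
                    kcal_per_t=KCAL_PER_T) -> pd.DataFrame:
    """Region x year food-security indicators from a market projection.

    Consumption is the market demand of the three crops. The reference
    availability is the base-year world-average kcal/capita/day of the
    same measure (computed from the first year unless ``kcal_ref_world``
    is given). Non-food covariates follow the linear improvement paths in
    ``macro``.

    Columns: year, region_id, kcal_pc_day, share_at_risk,
    millions_at_risk, undernourished_children_millions.
    """
    m = macro.set_index("region_id")
    base = states["year"].min()
    cons = (states.pivot_table(index=["year", "region_id"], columns="crop",
                               values="demand", aggfunc="sum")
            .reset_index())
    crops = [c for c in kcal_per_t if c in cons.columns]

    rows = []
    for _, rec in cons.iterrows():
        t = int(rec["year"] - base)
        r = rec["region_id"]
        pop = m.loc[r, "base_population"] * (1 + m.loc[r, "pop_growth"]) ** t
        kcal = kcal_per_capita({c: rec[c] for c in crops}, kcal_per_t, pop)
        rows.append({"year": int(rec["year"]), "region_id": r,
                     "population": pop, "kcal_pc_day": kcal})
    out = pd.DataFrame(rows)

    if kcal_ref_world is None:
        b = out[out["year"] == base]
        kcal_ref_world = float(np.average(b["kcal_pc_day"],
                                          weights=b["population"]))
    shares, kids = [], []
    for _, rec in out.iterrows():
        r = rec["region_id"]
        t = int(rec["year"] - base)
        hp = HungerParams(s0=float(m.loc[r, "s0_hunger"]), eta=eta)
        shares.append(share_at_risk(rec["kcal_pc_day"] / kcal_ref_world, hp))
        edu = min(1.0, m.loc[r, "edu_index"] + m.loc[r, "edu_rate"] * t)
        life = m.loc[r, "life_ratio"] + m.loc[r, "life_rate"] * t
        san = min(1.0, m.loc[r, "san_index"] + m.loc[r, "san_rate"] * t)
        kids.append(undernourished_children(
            rec["kcal_pc_day"], edu, life, san, child_params,
            rec["population"] * m.loc[r, "child_share"]))
    out["share_at_risk"] = shares
    out["millions_at_risk"] = out["share_at_risk"] * out["population"] / 1e6
    out["undernourished_children_millions"] = kids
    out.attrs["kcal_ref_world"] = kcal_ref_world
    return out
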