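"""IPCC Tier-1 greenhouse-gas accounting for cropland.

Direct N2O from nitrogen inputs (emission-factor arithmetic, with a
reduced factor for flooded rice soils), seasonal rice CH4 from the Tier-1
baseline-times-scaling-factors product, soil-organic-carbon change as
negative CO2, and GWP100 conversion to CO2-equivalents. Everything is
vectorized: scalar and array inputs both work.

Unit conventions: N inputs kg N/ha; CH4 and N2O masses kg/ha per season
(annualized one season per year); SOC change t C/ha/yr; CO2e t/ha/yr.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import EmissionFactors

N2O_N_TO_N2O = 44.0 / 28.0   # molecular/atomic mass ratio
C_TO_CO2 = 44.0 / 12.0


def _check_nonneg(name, x):
    if np.any(np.asarray(x) < 0):
        raise ValueError(f"{name} must be >= 0")


def n2o_direct(n_mineral, n_manure, n_residue, n_mineralized, flooded,
               ef: EmissionFactors = EmissionFactors()):
    """Direct N2O-N emitted (kg N2O-N/ha) from nitrogen inputs.

    Non-flooded soils: 1% of mineral-fertilizer and organic-amendment N,
    1% of N mineralized from soil organic matter, and ~0.7% of crop-residue
    N (factors from ``ef``). Flooded rice soils instead emit
    ``ef_n_flooded`` (0.3%) of applied N (mineral + manure). Linear in
    every N channel.
    """
    for name, x in (("n_mineral", n_mineral), ("n_manure", n_manure),
                    ("n_residue", n_residue), ("n_mineralized", n_mineralized)):
        _check_nonneg(name, x)
    n_mineral, n_manure, n_residue, n_mineralized = (
        np.asarray(x, dtype=float) for x in
        (n_mineral, n_manure, n_residue, n_mineralized))
    flooded = np.asarray(flooded, dtype=bool)

    dry = (ef.ef_n_mineral * n_mineral + ef.ef_n_organic * n_manure
           + ef.ef_n_residue * n_residue + ef.ef_n_mineralized * n_mineralized)
    applied = n_mineral + n_manure
    if ef.flooded_includes_mineralized:
        applied = applied + n_mineralized
    wet = ef.ef_n_flooded * applied
    out = np.where(flooded, wet, dry)
    return out if out.ndim else float(out)


def sf_organic(straw_rate, fym_rate, ef: EmissionFactors = EmissionFactors()):
    """Organic-amendment scaling factor for rice CH4.

    ``(1 + straw + cfoa_fym * fym)**straw_param`` — straw enters with
    conversion factor 1, farmyard manure with ``cfoa_fym`` (0.14); the
    exponent is the Tier-1 straw parameter (0.59). Equals 1 with no
    amendments.
    """
    _check_nonneg("straw_rate", straw_rate)
    _check_nonneg("fym_rate", fym_rate)
    base = 1.0 + np.asarray(straw_rate, dtype=float) \
        + ef.cfoa_fym * np.asarray(fym_rate, dtype=float)
    out = base ** ef.straw_param
    return out if np.ndim(out) else float(out)


def ch4_season(season_days, regime, straw_rate=0.0, fym_rate=0.0,
               ef: EmissionFactors = EmissionFactors()):
    """Seasonal rice CH4 (kg CH4/ha).

    Tier-1 product: baseline daily factor (1.3 kg CH4/ha/day) x water-regime
    scaling (continuous flooding 1, multiple drainage 0.52) x organic-
    amendment scaling x days in the growing season. Non-rice regimes
    (``"none"``) emit nothing.
    """
    _check_nonneg("season_days", season_days)
    season_days = np.asarray(season_days, dtype=float)
    regime = np.asarray(regime)
    sf_w = np.select(
        [regime == "continuous_flooding", regime == "multiple_drainage"],
        [ef.sf_continuous, ef.sf_multiple_drainage],
        default=0.0)
    out = ef.ch4_ef_base * sf_w * sf_organic(straw_rate, fym_rate, ef) * season_days
    return out if out.ndim else float(out)


def to_co2e(n2o_mass, ch4_mass, soc_delta, ef: EmissionFactors = EmissionFactors()):
    """Net emissions in t CO2e/ha/yr.

    GWP100-weighted N2O and CH4 masses (kg -> t via /1000) minus the CO2
    drawn down by SOC accrual (t C x 44/12). SOC gains therefore reduce
    the net total and can make it negative.
    """
    if ef.gwp_ch4 <= 0 or ef.gwp_n2o <= 0:
        raise ValueError("GWP values must be > 0")
    out = ((ef.gwp_n2o * np.asarray(n2o_mass, dtype=float)
            + ef.gwp_ch4 * np.asarray(ch4_mass, dtype=float)) / 1000.0
           - np.asarray(soc_delta, dtype=float) * C_TO_CO2)
    return out if np.ndim(out) else float(out)


def ledger_for_cells(cells: pd.DataFrame, responses: pd.DataFrame | None = None,
                     ef: EmissionFactors = EmissionFactors()) -> pd.DataFrame:
    """Per-hectare emission ledger for a cell table, BAU or under a practice.

    With ``responses=None`` the business-as-usual ledger is computed from
    the cells' own inputs and water regimes. Otherwise ``responses`` must
    carry one row per cell (columns ``cell_id, practice, yield_delta,
    soc_delta, water_regime_out, n_mineral_override, n_manure_override``)
    and the ledger reflects the practice's input and regime changes.

    Output columns: ``cell_id, practice, n2o_n, n2o_mass, ch4_mass,
    soc_delta, co2e_total, output, intensity, intensity_defined``.
    Intensity is t CO2e per t fresh output; it is NaN (flagged) where the
    realized output is not positive.
    """
    df = cells
    if responses is None:
        practice = "bau"
        yield_delta = np.zeros(len(df))
        soc_delta = np.zeros(len(df))
        regime = df["water_regime"].to_numpy()
        n_mineral = df["n_mineral"].to_numpy(dtype=float)
        n_manure = df["n_manure"].to_numpy(dtype=float)
    else:
        r = responses.set_index("cell_id")
        missing = set(df["cell_id"]) - set(r.index)
        if missing:
            raise ValueError(f"responses missing for cells {sorted(missing)[:5]}")
        r = r.loc[df["cell_id"]]
        practice = r["practice"].to_numpy()
        yield_delta = r["yield_delta"].to_numpy(dtype=float)
        soc_delta = r["soc_delta"].to_numpy(dtype=float)
        out_regime = r["water_regime_out"].to_numpy()
        base_regime = df["water_regime"].to_numpy()
        # upland practices report "none"; keep the cell's baseline regime then
        is_rice = (df["crop"] == "rice").to_numpy()
        regime = np.where(is_rice, out_regime, base_regime)
        n_mineral = np.where(np.isnan(r["n_mineral_override"].to_numpy(dtype=float)),
                             df["n_mineral"].to_numpy(dtype=float),
                             r["n_mineral_override"].to_numpy(dtype=float))
        n_manure = np.where(np.isnan(r["n_manure_override"].to_numpy(dtype=float)),
                            df["n_manure"].to_numpy(dtype=float),
                            r["n_manure_override"].to_numpy(dtype=float))

    flooded = (df["crop"].to_numpy() == "rice") & (np.asarray(regime) != "none")
    n2o_n = n2o_direct(n_mineral, n_manure,
                       df["n_residue"].to_numpy(dtype=float),
                       df["n_mineralized"].to_numpy(dtype=float),
                       flooded, ef)
    n2o_mass = np.asarray(n2o_n) * N2O_N_TO_N2O
    ch4 = ch4_season(df["season_days"].to_numpy(dtype=float), regime,
                     df["straw_rate"].to_numpy(dtype=float),
                     df["fym_rate"].to_numpy(dtype=float), ef)
    co2e = to_co2e(n2o_mass, ch4, soc_delta, ef)
    output = df["yield_base"].to_numpy(dtype=float) * (1.0 + yield_delta)
    defined = output > 0
    intensity = np.full(len(df), np.nan)
    intensity[defined] = np.asarray(co2e)[defined] / output[defined]
    return pd.DataFrame({
        "cell_id": df["cell_id"].to_numpy(),
        "practice": practice,
        "n2o_n": np.asarray(n2o_n),
        "n2o_mass": n2o_mass,
        "ch4_mass": np.asarray(ch4),
        "soc_delta": soc_delta,
        "co2e_total": np.asarray(co2e),
        "output": output,
        "intensity": intensity,
        "intensity_defined": defined,
    })


def candidate_ledgers(cells: pd.DataFrame, responses: pd.DataFrame,
                      ef: EmissionFactors = EmissionFactors()) -> pd.DataFrame:
    """Ledger rows for every (cell, practice) candidate in ``responses``."""
    parts = []
    for practice, sub in responses.groupby("practice", sort=True):
        sub_cells = cells[cells["cell_id"].isin(sub["cell_id"])]
        parts.append(ledger_for_cells(sub_cells, sub, ef))
    if not parts:
        return ledger_for_cells(cells.iloc[:0], None, ef)
    return pd.concat(parts, ignore_index=True)


def aggregate_emissions(ledger: pd.DataFrame, cells: pd.DataFrame,
                        level: str = "world") -> pd.Series:
    """Total emissions (t CO2e/yr) grouped at cell/fpu/country/world level.

    Per-hectare ledger totals are multiplied by cell areas; group totals
    partition the world total exactly. A ledger row without a matching cell
    is a hard error.
    """
    key = {"cell": "cell_id", "fpu": "fpu_id", "country": "country_id",
           "world": None}
    if level not in key:
        raise ValueError(f"unknown aggregation level {level!r}")
    meta = cells.set_index("cell_id")[["fpu_id", "country_id", "area"]]
    missing = set(ledger["cell_id"]) - set(meta.index)
    if missing:
        raise ValueError(f"no area for cells {sorted(missing)[:5]}")
    m = meta.loc[ledger["cell_id"]]
    total = ledger["co2e_total"].to_numpy() * m["area"].to_numpy()
    if level == "world":
        return pd.Series({"world": float(total.sum())})
    if level == "cell":
        return pd.Series(total, index=ledger["cell_id"].to_numpy()).groupby(level=0).sum()
    return pd.Series(total, index=m[key[level]].to_numpy()).groupby(level=0).sum()
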