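"""Seeded synthetic world: grid cells, practice responses, climates, macro.

Stands in for the gridded crop-production data layer (crop locations,
inputs, simulated practice responses, climate-model yield trends) so the
whole scenario pipeline runs from a (config, seed) pair. All tables are
plain pandas DataFrames; column units are recorded in ``UNITS`` and written
as comment headers by :func:`save_world`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    CLIMATES,
    CROPS,
    PRACTICE_CROPS,
    ConfigError,
    AwdWaterSpec,
    GeneratorConfig,
)

UNITS = {
    "cells": {
        "cell_id": "-", "country_id": "-", "fpu_id": "-", "crop": "-",
        "water_system": "-", "water_regime": "-", "area": "ha",
        "yield_base": "t fresh matter/ha", "n_mineral": "kg N/ha",
        "n_manure": "kg N/ha", "n_residue": "kg N/ha",
        "n_mineralized": "kg N/ha", "season_days": "days",
        "straw_rate": "t/ha", "fym_rate": "t/ha",
    },
    "responses": {
        "cell_id": "-", "practice": "-", "climate_id": "-",
        "yield_delta": "fraction", "soc_delta": "t C/ha/yr",
        "water_regime_out": "-", "n_mineral_override": "kg N/ha",
        "n_manure_override": "kg N/ha",
    },
    "climate": {"climate_id": "-", "fpu_id": "-", "crop": "-",
                "trend": "fraction/yr"},
    "macro": {"region_id": "-", "base_population": "persons",
              "pop_growth": "fraction/yr", "base_income": "USD/cap",
              "income_growth": "fraction/yr", "s0_hunger": "fraction",
              "edu_index": "index 0-1", "edu_rate": "index/yr",
              "life_ratio": "ratio", "life_rate": "ratio/yr",
              "san_index": "index 0-1", "san_rate": "index/yr",
              "child_share": "fraction"},
    "market_params": {"region_id": "-", "crop": "-", "base_area": "ha",
                      "base_yield": "t/ha", "area_price_elast": "-",
                      "yield_growth": "fraction/yr", "demand_base": "t/yr",
                      "demand_price_elast": "-", "income_elast": "-",
                      "feed_share": "fraction"},
}


@dataclass
class World:
    """A complete synthetic study world.

    cells: one row per grid-cell x crop x water-system production unit.
    responses: per-cell practice effects under each pseudo-climate path.
    climate: per-FPU x crop baseline yield trend modifiers per climate.
    macro: per-country population/income paths and food-security covariates.
    market_params: per-country x crop supply/demand parameters.
    excluded_countries: country ids where no-till is not simulated.
    """

    cells: pd.DataFrame
    responses: pd.DataFrame
    climate: pd.DataFrame
    macro: pd.DataFrame
    market_params: pd.DataFrame
    excluded_countries: tuple
    config: GeneratorConfig


def awd_cycle(spec: AwdWaterSpec):
    """Length of one AWD wet-dry cycle and drainage-event counter.

    Returns ``(drydown_days, cycle_days, events)`` where ``events`` maps a
    season length in days to the number of complete drainage cycles it fits
    (``floor(season_days / cycle_days)``).

    >>> d, c, ev = awd_cycle(AwdWaterSpec())
    >>> d, c, ev(120)
    (30.0, 60.0, 2)
    """
    depth = spec.flood_depth - spec.min_level
    drydown = depth / spec.drawdown_rate
    cycle = drydown + depth / spec.reflood_rate

    def events(season_days: float) -> int:
        if season_days < 0:
            raise ValueError("season_days must be >= 0")
        if cycle == 0:
            return 0
        return int(math.floor(season_days / cycle))

    return drydown, cycle, events


def _lognormal(rng, median, log_sd, size):
    return np.exp(rng.normal(np.log(median), log_sd, size))


def generate_world(config: GeneratorConfig, seed: int) -> World:
    """Generate a world deterministically from ``(config, seed)``.

    Structure: ``n_countries`` countries partition ``n_fpus`` FPUs, which
    partition ``n_cells`` cells (every FPU gets at least one cell). Each
    cell grows one crop under one water system; rice cells carry a flooded
    baseline water regime. Practice responses are drawn per eligible cell
    and climate from the configured distributions; market demand intercepts
    are calibrated so the base-year world price of every crop is 1.
    """
    if not isinstance(config, GeneratorConfig):
        raise ConfigError("config must be a GeneratorConfig")
    rng = np.random.default_rng(seed)
    n = config.n_cells

    # --- structure: country <- fpu <- cell -------------------------------
    fpu_country = np.empty(config.n_fpus, dtype=int)
    fpu_country[: config.n_countries] = np.arange(config.n_countries)
    fpu_country[config.n_countries:] = rng.integers(
        0, config.n_countries, config.n_fpus - config.n_countries)

    cell_fpu = np.empty(n, dtype=int)
    cell_fpu[: config.n_fpus] = np.arange(config.n_fpus)
    cell_fpu[config.n_fpus:] = rng.integers(0, config.n_fpus, n - config.n_fpus)
    cell_country = fpu_country[cell_fpu]

    crops = rng.choice(
        CROPS, size=n, p=[config.crop_shares[c] for c in CROPS])
    irr_p = np.array([config.irrigated_share[c] for c in crops])
    water_system = np.where(rng.random(n) < irr_p, "irrigated", "rainfed")
    water_regime = np.where(crops == "rice", "continuous_flooding", "none")

    yield_base = _lognormal(
        rng, np.array([config.yield_median[c] for c in crops]),
        config.yield_log_sd, n)
    area = _lognormal(rng, config.area_median_ha, config.area_log_sd, n)
    n_mineral = _lognormal(
        rng, np.array([config.n_mineral_median[c] for c in crops]),
        config.n_mineral_log_sd, n)
    n_manure = _lognormal(rng, config.n_manure_median, config.n_manure_log_sd, n)
    n_residue = _lognormal(rng, config.n_residue_median, config.n_residue_log_sd, n)
    n_mineralized = np.clip(
        rng.normal(config.n_mineralized_mean, config.n_mineralized_sd, n), 0, None)
    lo = np.array([config.season_days_range[c][0] for c in crops])
    hi = np.array([config.season_days_range[c][1] for c in crops])
    season_days = rng.uniform(lo, hi)
    is_rice = crops == "rice"
    straw_rate = np.where(is_rice, _lognormal(rng, config.straw_median, config.straw_log_sd, n), 0.0)
    fym_rate = np.where(is_rice, _lognormal(rng, config.fym_median, config.fym_log_sd, n), 0.0)

    cells = pd.DataFrame({
        "cell_id": np.arange(n),
        "country_id": cell_country,
        "fpu_id": cell_fpu,
        "crop": crops,
        "water_system": water_system,
        "water_regime": water_regime,
        "area": area,
        "yield_base": yield_base,
        "n_mineral": n_mineral,
        "n_manure": n_manure,
        "n_residue": n_residue,
        "n_mineralized": n_mineralized,
        "season_days": season_days,
        "straw_rate": straw_rate,
        "fym_rate": fym_rate,
    })

    # --- practice responses ----------------------------------------------
    rows = []
    for practice, eligible_crops in PRACTICE_CROPS.items():
        mask = cells["crop"].isin(eligible_crops).to_numpy()
        if practice == "awd":
            mask &= (cells["water_system"] == "irrigated").to_numpy()
        idx = cells.index[mask]
        pp = config.practice_params[practice]
        for climate in CLIMATES:
            m = len(idx)
            ydelta = np.clip(
                rng.normal(pp.yield_mean + config.climate_delta_offset[climate],
                           pp.yield_sd, m),
                *config.yield_delta_bounds)
            soc = rng.normal(pp.soc_mean, pp.soc_sd, m)
            sub = pd.DataFrame({
                "cell_id": cells.loc[idx, "cell_id"].to_numpy(),
                "practice": practice,
                "climate_id": climate,
                "yield_delta": ydelta,
                "soc_delta": soc,
            })
            if practice == "awd":
                sub["water_regime_out"] = "multiple_drainage"
            elif practice == "nue":
                sub["water_regime_out"] = "continuous_flooding"
            else:
                sub["water_regime_out"] = "none"
            sub["n_mineral_override"] = np.nan
            sub["n_manure_override"] = np.nan
            if practice == "nue":
                sub["n_mineral_override"] = (
                    config.nue_mineral_factor
                    * cells.loc[idx, "n_mineral"].to_numpy())
            if practice == "isfm":
                sub["n_manure_override"] = (
                    cells.loc[idx, "n_manure"].to_numpy()
                    + _lognormal(rng, config.isfm_manure_add_median,
                                 config.isfm_manure_add_log_sd, m))
            rows.append(sub)
    responses = pd.concat(rows, ignore_index=True)

    # --- climate trend modifiers -----------------------------------------
    crows = []
    for climate in CLIMATES:
        for crop in CROPS:
            crows.append(pd.DataFrame({
                "climate_id": climate,
                "fpu_id": np.arange(config.n_fpus),
                "crop": crop,
                "trend": rng.normal(config.climate_trend_mean[climate],
                                    config.climate_trend_sd, config.n_fpus),
            }))
    climate = pd.concat(crows, ignore_index=True)

    # --- macro paths -------------------------------------------------------
    pop_w = rng.dirichlet(np.full(config.n_countries, 2.0))
    inc = _lognormal(rng, config.base_income_pc, 0.6, config.n_countries)
    macro = pd.DataFrame({
        "region_id": np.arange(config.n_countries),
        "base_population": pop_w * config.base_population_total,
        "pop_growth": config.population_growth,
        "base_income": inc,
        "income_growth": config.gdp_pc_growth,
        "s0_hunger": rng.uniform(0.04, 0.25, config.n_countries),
        "edu_index": rng.uniform(0.3, 0.9, config.n_countries),
        "edu_rate": 0.004,
        "life_ratio": rng.uniform(1.02, 1.10, config.n_countries),
        "life_rate": 0.0002,
        "san_index": rng.uniform(0.3, 0.9, config.n_countries),
        "san_rate": 0.005,
        "child_share": config.child_share,
    })

    # --- market parameters: calibrated so base-year world price = 1 --------
    prod = cells.assign(production=cells["area"] * cells["yield_base"])
    by_rc = (prod.groupby(["country_id", "crop"], sort=True)
             .agg(base_area=("area", "sum"), production=("production", "sum"))
             .reset_index())
    by_rc["base_yield"] = by_rc["production"] / by_rc["base_area"]
    world_q = by_rc.groupby("crop")["production"].transform("sum")
    pop = macro.set_index("region_id")["base_population"]
    popw = by_rc["country_id"].map(pop)
    # demand intercept: population-proportional with a random diet factor,
    # renormalized per crop so world supply = world demand at P = 1
    taste = rng.lognormal(0.0, 0.3, len(by_rc))
    w = popw.to_numpy() * taste
    w = w / by_rc.assign(w=w).groupby("crop")["w"].transform("sum").to_numpy()
    by_rc["demand_base"] = w * world_q.to_numpy()
    market_params = pd.DataFrame({
        "region_id": by_rc["country_id"],
        "crop": by_rc["crop"],
        "base_area": by_rc["base_area"],
        "base_yield": by_rc["base_yield"],
        "area_price_elast": config.area_price_elast,
        "yield_growth": config.exog_yield_growth,
        "demand_base": by_rc["demand_base"],
        "demand_price_elast": config.demand_price_elast,
        "income_elast": by_rc["crop"].map(config.income_elast),
        "feed_share": by_rc["crop"].map(config.feed_share),
    })

    excluded = tuple(
        sorted(rng.choice(config.n_countries, config.n_excluded_countries,
                          replace=False).tolist()))

    return World(cells=cells, responses=responses, climate=climate,
                 macro=macro, market_params=market_params,
                 excluded_countries=excluded, config=config)


# --------------------------------------------------------------------------
# serialization: a directory of CSV tables with '# column = unit' headers
# --------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path, units: dict) -> None:
    with open(path, "w") as fh:
        for col in df.columns:
            fh.write(f"# {col} = {units.get(col, '-')}\n")
        df.to_csv(fh, index=False)


def save_world(world: World, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("cells", "responses", "climate", "macro", "market_params"):
        _write_csv(getattr(world, name), out / f"{name}.csv", UNITS[name])
    meta = {"excluded_countries": list(world.excluded_countries),
            "config": world.config.to_dict()}
    import yaml
    with open(out / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_world(indir) -> World:
    import yaml
    ind = Path(indir)
    tables = {name: pd.read_csv(ind / f"{name}.csv", comment="#")
              for name in ("cells", "responses", "climate", "macro", "market_params")}
    with open(ind / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    return World(
        **tables,
        excluded_countries=tuple(meta["excluded_countries"]),
        config=GeneratorConfig.from_dict(meta["config"]),
    )
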