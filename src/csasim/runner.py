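"""Scenario matrix orchestration and mean-plus-range reporting.

A scenario is (adoption scheme, pseudo-climate path, tailoring level,
climate-change flag). The default matrix is the full cross of four
adoption schemes x two climates x three tailoring levels plus one
business-as-usual run per climate: 26 runs. Each run executes the
pipeline adoption -> tailoring -> market -> emissions -> food security
against its climate's BAU counterfactual, and the summary reports every
metric as the across-climate mean at average tailoring with the min-max
range over all climate x tailoring combinations.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import adoption, foodsec, ghg, market, tailoring
from .config import (
    CLIMATES,
    PRACTICES,
    RULES,
    TAILORINGS,
    AwdEconomics,
    ChildParams,
    ConfigError,
    EmissionFactors,
    LivestockLink,
)
from .world import World

log = logging.getLogger("csasim")

SCHEMES = ("bau",) + RULES


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the scenario matrix."""

    scheme: str
    climate_id: str
    tailoring: str | None = None
    climate_change_on: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "bau" and self.tailoring is not None:
            raise ConfigError("bau carries no tailoring level")
        if self.scheme != "bau" and self.tailoring not in TAILORINGS:
            raise ConfigError(f"invalid tailoring {self.tailoring!r}")

    @property
    def name(self) -> str:
        parts = [self.scheme, self.climate_id]
        if self.tailoring:
            parts.append(self.tailoring)
        if not self.climate_change_on:
            parts.append("nocc")
        return "_".join(parts)


def build_matrix(climates=CLIMATES, schemes=RULES, tailorings=TAILORINGS,
                 climate_change_on=True, seed=0) -> list:
    """Enumerate the scenario matrix in deterministic order.

    One BAU per climate, then each adoption scheme x climate x tailoring.
    The default configuration yields 2 + 4*2*3 = 26 specs.
    """
    for s in schemes:
        if s not in RULES:
            raise ConfigError(f"unknown adoption scheme {s!r}")
    specs = [ScenarioSpec("bau", c, None, climate_change_on, seed)
             for c in climates]
    for scheme in schemes:
        for climate in climates:
            for level in tailorings:
                specs.append(ScenarioSpec(scheme, climate, level,
                                          climate_change_on, seed))
    return specs


def default_rate_table(world: World) -> pd.DataFrame:
    """Synthetic placeholder adoption-rate caps (country x practice).

    The survey-based rates the capped scenario calls for are not published
    at this granularity; these stand-in values are uniform per practice and
    deliberately below 1 so the capped scenario is a strict interpolation
    between BAU and full adoption.
    """
    rates = {"no_till": 0.40, "isfm": 0.30, "nue": 0.35, "awd": 0.25}
    rows = [{"country_id": c, "practice": p, "rate": r}
            for c in world.macro["region_id"]
            for p, r in rates.items()]
    return pd.DataFrame(rows)


@dataclass
class ScenarioResult:
    """Everything one run produced."""

    spec: ScenarioSpec
    decisions: pd.DataFrame | None
    shifters: pd.DataFrame | None
    states: pd.DataFrame
    bau_states: pd.DataFrame
    indicators: pd.DataFrame
    bau_indicators: pd.DataFrame
    emissions_by_year: pd.DataFrame
    report: pd.DataFrame
    metrics: dict = field(default_factory=dict)


def _climate_trend_map(world: World, climate_id: str) -> dict:
    """(region, crop) -> production-weighted FPU trend modifier."""
    cl = world.climate[world.climate["climate_id"] == climate_id]
    prod = world.cells.assign(
        production=world.cells["area"] * world.cells["yield_base"])
    fpu_prod = (prod.groupby(["country_id", "fpu_id", "crop"])["production"]
                .sum().reset_index())
    merged = fpu_prod.merge(cl, on=["fpu_id", "crop"], how="left")
    merged["trend"] = merged["trend"].fillna(0.0)
    out = {}
    for (r, c), grp in merged.groupby(["country_id", "crop"]):
        out[(r, c)] = float(np.average(grp["trend"], weights=grp["production"]))
    return out


def _region_shifters(world: World, decisions: pd.DataFrame,
                     shifter_tab: pd.DataFrame, level: str) -> dict:
    """(region, crop) -> effective shifter.

    The FPU shifter at the requested tailoring level is scaled by the
    FPU's adopted production share and production-weighted up to the
    country, so regions where little area adopts see little shift.
    """
    cells = world.cells.set_index("cell_id")
    d = decisions.join(cells[["fpu_id", "country_id", "crop", "area",
                              "yield_base"]], on="cell_id")
    d["production"] = d["area"] * d["yield_base"]
    d["adopted_production"] = d["production"] * d["adopted_fraction"]

    s = shifter_tab[shifter_tab["tailoring"] == level].set_index(
        ["fpu_id", "crop"])["shifter"]
    out = {}
    for (r, c), grp in d.groupby(["country_id", "crop"]):
        total = grp["production"].sum()
        if total == 0:
            continue
        fpu = grp.groupby("fpu_id").agg(
            adopted=("adopted_production", "sum"))
        keys = pd.MultiIndex.from_product([fpu.index, [c]])
        fpu["shifter"] = np.nan_to_num(
            s.reindex(keys).to_numpy(dtype=float), nan=0.0)
        eff = float((fpu["adopted"] * fpu["shifter"]).sum() / total)
        if eff != 0.0:
            out[(r, c)] = eff
    return out


def _emission_paths(world: World, blend_perha: pd.Series,
                    states: pd.DataFrame) -> pd.DataFrame:
    """World emission totals per year, t CO2e, scaling cell areas with the
    market's country x crop harvested-area path."""
    cells = world.cells
    base = cells.assign(em=blend_perha.reindex(cells["cell_id"]).to_numpy()
                        * cells["area"])
    grp = base.groupby(["country_id", "crop"])["em"].sum()

    areas = states.pivot_table(index="year", columns=["region_id", "crop"],
                               values="area", aggfunc="sum")
    base_year = areas.index.min()
    ratio = areas / areas.loc[base_year]
    em = grp.reindex(ratio.columns).fillna(0.0)
    totals = ratio.mul(em, axis=1).sum(axis=1)
    return pd.DataFrame({"year": totals.index, "total_t_co2e": totals.to_numpy()})


def run_scenario(spec: ScenarioSpec, world: World,
                 ef: EmissionFactors = EmissionFactors(),
                 rate_table: pd.DataFrame | None = None,
                 awd_econ: AwdEconomics = AwdEconomics(),
                 livestock: LivestockLink | None = None,
                 shifter_mode: str = "growth",
                 bau_cache: dict | None = None) -> ScenarioResult:
    """Run one scenario end to end.

    Stages: adoption decisions (skipped for BAU) -> FPU tailoring shifters
    -> market projection -> GHG ledger with market areas -> food-security
    indicators; each against the matching-climate BAU counterfactual.
    ``bau_cache`` (keyed by (climate_id, climate_change_on)) avoids
    re-solving the BAU trajectory across the matrix.
    """
    cfg = world.config
    years = range(cfg.start_year, cfg.end_year + 1)
    trend = (_climate_trend_map(world, spec.climate_id)
             if spec.climate_change_on else None)
    if livestock is None:
        livestock = LivestockLink(cfg.livestock_base_herd,
                                  cfg.livestock_feed_price_elast,
                                  cfg.livestock_ef_per_head)

    # --- BAU counterfactual ------------------------------------------------
    key = (spec.climate_id, spec.climate_change_on)
    if bau_cache is not None and key in bau_cache:
        bau_states, bau_em, bau_ind = bau_cache[key]
    else:
        log.info("solving BAU trajectory for %s", key)
        bau_states = market.project(world.market_params, world.macro, years,
                                    shifters=None, climate_trend=trend,
                                    shifter_mode=shifter_mode)
        ledger_bau = ghg.ledger_for_cells(world.cells, None, ef)
        perha_bau = ledger_bau.set_index("cell_id")["co2e_total"]
        bau_em = _emission_paths(world, perha_bau, bau_states)
        bau_ind = foodsec.indicator_table(bau_states, world.macro,
                                          eta=cfg.hunger_eta)
        if bau_cache is not None:
            bau_cache[key] = (bau_states, bau_em, bau_ind)

    ledger_bau = ghg.ledger_for_cells(world.cells, None, ef)

    if spec.scheme == "bau":
        states, em, ind = bau_states, bau_em, bau_ind
        decisions = shifter_tab = None
        rep = market.production_and_area_report(states, bau_states)
        metrics = _metrics(spec, world, None, states, bau_states, em, bau_em,
                           ind, bau_ind, rep, livestock, ledger_bau, None)
        return ScenarioResult(spec, None, None, states, bau_states, ind,
                              bau_ind, em, rep, metrics)

    # --- adoption ----------------------------------------------------------
    responses = world.responses[
        world.responses["climate_id"] == spec.climate_id]
    ledger_alt = ghg.candidate_ledgers(world.cells, responses, ef)
    if spec.scheme == "rule1_rates" and rate_table is None:
        rate_table = default_rate_table(world)
    rule = adoption.AdoptionRule(
        spec.scheme,
        rate_table if spec.scheme == "rule1_rates" else None,
        awd_econ if spec.scheme == "rule2_awdcost" else None)
    decisions = adoption.decide_cells(world.cells, responses, ledger_bau,
                                      ledger_alt, rule,
                                      world.excluded_countries)
    log.info("%s: %d of %d cells adopt", spec.name,
             int((decisions["adopted_fraction"] > 0).sum()), len(decisions))

    # --- tailoring ---------------------------------------------------------
    shifter_tab = tailoring.shifter_table(decisions, world.cells)
    region_shift = _region_shifters(world, decisions, shifter_tab,
                                    spec.tailoring)

    # --- market ------------------------------------------------------------
    states = market.project(world.market_params, world.macro, years,
                            shifters=region_shift, climate_trend=trend,
                            shifter_mode=shifter_mode)
    rep = market.production_and_area_report(states, bau_states)

    # --- emissions ---------------------------------------------------------
    chosen = decisions[decisions["adopted_fraction"] > 0]
    alt = ledger_alt.set_index(["cell_id", "practice"])["co2e_total"]
    perha = ledger_bau.set_index("cell_id")["co2e_total"].copy()
    if len(chosen):
        keys = pd.MultiIndex.from_arrays(
            [chosen["cell_id"], chosen["chosen"]])
        alt_vals = alt.reindex(keys).to_numpy()
        f = chosen["adopted_fraction"].to_numpy()
        blended = ((1 - f) * perha.reindex(chosen["cell_id"]).to_numpy()
                   + f * alt_vals)
        perha.loc[chosen["cell_id"].to_numpy()] = blended
    em = _emission_paths(world, perha, states)

    # --- food security -----------------------------------------------------
    ref = bau_ind.attrs.get("kcal_ref_world")
    ind = foodsec.indicator_table(states, world.macro, kcal_ref_world=ref,
                                  eta=cfg.hunger_eta)

    metrics = _metrics(spec, world, decisions, states, bau_states, em,
                       bau_em, ind, bau_ind, rep, livestock, ledger_bau,
                       chosen)
    return ScenarioResult(spec, decisions, shifter_tab, states, bau_states,
                          ind, bau_ind, em, rep, metrics)


def _metrics(spec, world, decisions, states, bau_states, em, bau_em,
             ind, bau_ind, rep, livestock, ledger_bau, chosen) -> dict:
    y1 = states["year"].max()
    metrics = {"scheme": spec.scheme, "climate_id": spec.climate_id,
               "tailoring": spec.tailoring or "none"}

    if decisions is not None:
        metrics["adopted_area_mha"] = float(
            adoption.adopted_area(decisions, world.cells)["world"] / 1e6)
        if len(chosen):
            w = (world.cells.set_index("cell_id")["area"]
                 .reindex(chosen["cell_id"]).to_numpy()
                 * chosen["adopted_fraction"].to_numpy())
            metrics["soc_gain_t_ha_yr"] = float(
                np.average(chosen["soc_delta"], weights=w)) if w.sum() else 0.0
        else:
            metrics["soc_gain_t_ha_yr"] = 0.0
    else:
        metrics["adopted_area_mha"] = 0.0
        metrics["soc_gain_t_ha_yr"] = 0.0

    merged = em.merge(bau_em, on="year", suffixes=("", "_bau"))
    metrics["abatement_mt_co2e_yr"] = float(
        (merged["total_t_co2e_bau"] - merged["total_t_co2e"]).mean() / 1e6)
    metrics["emissions_2050_mt"] = float(
        em.loc[em["year"] == y1, "total_t_co2e"].iloc[0] / 1e6)

    for _, row in rep.iterrows():
        c = row["crop"]
        metrics[f"production_pct_change_{c}"] = row["production_pct_change"]
        metrics[f"price_pct_change_{c}"] = row["price_pct_change"]
        metrics[f"production_delta_vs_bau_pct_{c}"] = \
            row["production_delta_vs_bau_pct"]
        metrics[f"price_growth_delta_pp_{c}"] = \
            row["price_growth_delta_vs_bau_pp"]

    last = ind[ind["year"] == y1]
    blast = bau_ind[bau_ind["year"] == y1]
    metrics["millions_at_risk_2050"] = float(last["millions_at_risk"].sum())
    metrics["millions_at_risk_delta_2050"] = float(
        last["millions_at_risk"].sum() - blast["millions_at_risk"].sum())
    metrics["undernourished_children_delta_2050"] = float(
        last["undernourished_children_millions"].sum()
        - blast["undernourished_children_millions"].sum())

    fp_s = market.feed_price_index(states[states["year"] == y1],
                                   world.market_params)
    fp_b = market.feed_price_index(bau_states[bau_states["year"] == y1],
                                   world.market_params)
    _, cattle = market.livestock_feedback(fp_s / fp_b, livestock)
    metrics["cattle_emission_delta_mt_yr"] = float(cattle / 1e6)
    return metrics


def run_matrix(world: World, specs=None, **kwargs) -> list:
    """Run a list of scenario specs (default: the full 26-run matrix)."""
    if specs is None:
        specs = build_matrix()
    cache: dict = {}
    return [run_scenario(s, world, bau_cache=cache, **kwargs) for s in specs]


def summarize(results) -> pd.DataFrame:
    """Mean-plus-range summary table across the matrix.

    For each scheme and metric: the mean over climates at average
    tailoring, and the min/max over every climate x tailoring run of that
    scheme. min <= mean <= max holds whenever the average-tailoring runs
    are present; missing combinations are flagged in the ``complete``
    column rather than fatal.
    """
    rows = []
    frame = pd.DataFrame([r.metrics for r in results])
    skip = {"scheme", "climate_id", "tailoring"}
    for scheme, grp in frame.groupby("scheme", sort=True):
        at_avg = grp[grp["tailoring"].isin(["average", "none"])]
        for metric in grp.columns:
            if metric in skip:
                continue
            vals = grp[metric].dropna()
            if vals.empty:
                continue
            mean = float(at_avg[metric].mean()) if len(at_avg) else float("nan")
            rows.append({
                "scheme": scheme, "metric": metric, "mean": mean,
                "min": float(vals.min()), "max": float(vals.max()),
                "complete": len(at_avg) > 0,
            })
    return pd.DataFrame(rows)


def share_of_benchmark(value: float, benchmark: float) -> float:
    """Percentage a quantity represents of a benchmark (e.g. an abatement
    total against an economic mitigation potential)."""
    if benchmark == 0:
        raise ValueError("benchmark must be non-zero")
    return 100.0 * value / benchmark


def write_run(result: ScenarioResult, outdir) -> None:
    """Persist one run: CSV tables plus a reproducibility manifest."""
    from pathlib import Path

    out = Path(outdir) / result.spec.name
    out.mkdir(parents=True, exist_ok=True)
    if result.decisions is not None:
        result.decisions.to_csv(out / "decisions.csv", index=False)
        result.shifters.to_csv(out / "shifters.csv", index=False)
    result.states.to_csv(out / "market_states.csv", index=False)
    result.indicators.to_csv(out / "indicators.csv", index=False)
    result.emissions_by_year.to_csv(out / "emissions.csv", index=False)
    result.report.to_csv(out / "report.csv", index=False)
    pd.DataFrame([result.metrics]).to_csv(out / "metrics.csv", index=False)
    cfg_yaml = yaml.safe_dump(result.spec.__dict__, sort_keys=True)
    manifest = {
        "scenario": result.spec.name,
        "seed": result.spec.seed,
        "spec": result.spec.__dict__,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
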