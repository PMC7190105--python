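"""Grid-cell adoption rules for climate-smart practices.

Rule 1 adopts the candidate practice with the largest yield gain provided
the gain is strictly positive; Rule 2 additionally requires the candidate
to lower the cell's emission intensity (CO2e per tonne of output) relative
to business as usual. Two variants relax the extremes: Rule 1 with
exogenous country x practice adoption-rate caps, and Rule 2 with an AWD
cost break-even that lets alternate wetting and drying in despite a modest
yield loss. Farmers whose candidates all fail retain their current
practice. No-till is never offered in the configured exclusion countries
(places where it is already widespread).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PRACTICE_ORDER, RULES, AwdEconomics, ConfigError


@dataclass(frozen=True)
class AdoptionRule:
    """One of the four adoption schemes.

    rule1_rates requires ``rate_table`` (country x practice fractions);
    rule2_awdcost requires ``awd_econ``.
    """

    rule_id: str
    rate_table: pd.DataFrame | None = None
    awd_econ: AwdEconomics | None = None

    def __post_init__(self) -> None:
        if self.rule_id not in RULES:
            raise ConfigError(f"unknown rule {self.rule_id!r}")
        if self.rule_id == "rule1_rates" and self.rate_table is None:
            raise ConfigError("rule1_rates needs an adoption-rate table")
        if self.rule_id == "rule2_awdcost" and self.awd_econ is None:
            raise ConfigError("rule2_awdcost needs AwdEconomics")


def awd_breakeven(econ: AwdEconomics) -> float:
    """Largest fractional yield decline at which AWD stays profitable.

    From the break-even condition revenue*(1-d) - cost*(1 - share*saving) =
    revenue - cost with cost = ratio * revenue:
    d* = irrigation_cost_share * irrigation_cost_reduction * cost_revenue_ratio.
    With the default 0.30 share, 0.30 saving and cost equal to revenue this
    is a 9% tolerable decline.
    """
    return (econ.irrigation_cost_share * econ.irrigation_cost_reduction
            * econ.cost_revenue_ratio)


def decide_cells(cells: pd.DataFrame, responses: pd.DataFrame,
                 ledger_bau: pd.DataFrame, ledger_alt: pd.DataFrame,
                 rule: AdoptionRule,
                 excluded_countries=()) -> pd.DataFrame:
    """Apply an adoption rule to every cell; returns the decision table.

    ``responses`` holds all candidate practices for one climate path;
    ``ledger_alt`` must carry one row per (cell_id, practice) candidate and
    ``ledger_bau`` one row per cell (a missing ledger is a hard error).
    Ties on yield gain break on the fixed practice order, so the decision
    is deterministic and independent of candidate row order.

    Output: one row per cell with ``cell_id, rule_id, chosen,
    adopted_fraction, yield_delta, soc_delta``; non-adopting cells carry
    ``chosen="retain_current"`` and fraction 0.
    """
    cand = responses.merge(
        ledger_alt[["cell_id", "practice", "intensity", "intensity_defined"]],
        on=["cell_id", "practice"], how="left", validate="one_to_one")
    if cand["intensity_defined"].isna().any():
        bad = cand.loc[cand["intensity_defined"].isna(),
                       ["cell_id", "practice"]].head()
        raise ValueError(f"missing alternative ledger for candidates:\n{bad}")
    bau = ledger_bau.set_index("cell_id")
    missing = set(cand["cell_id"]) - set(bau.index)
    if missing:
        raise ValueError(f"missing BAU ledger for cells {sorted(missing)[:5]}")
    cand["intensity_bau"] = bau["intensity"].reindex(cand["cell_id"]).to_numpy()
    cand["bau_defined"] = bau["intensity_defined"].reindex(cand["cell_id"]).to_numpy()

    country = cells.set_index("cell_id")["country_id"]
    cand["country_id"] = country.reindex(cand["cell_id"]).to_numpy()

    # eligibility -----------------------------------------------------------
    excluded = set(excluded_countries)
    not_excluded = ~((cand["practice"] == "no_till")
                     & cand["country_id"].isin(excluded))
    gains = cand["yield_delta"] > 0
    lowers_intensity = (cand["intensity_defined"].astype(bool)
                        & cand["bau_defined"].astype(bool)
                        & (cand["intensity"] < cand["intensity_bau"]))

    if rule.rule_id in ("rule1", "rule1_rates"):
        eligible = gains
    elif rule.rule_id == "rule2":
        eligible = gains & lowers_intensity
    else:  # rule2_awdcost
        tol = awd_breakeven(rule.awd_econ)
        awd_ok = ((cand["practice"] == "awd")
                  & (cand["yield_delta"] > -tol) & lowers_intensity)
        eligible = (gains & lowers_intensity) | awd_ok
    eligible &= not_excluded

    cand = cand[eligible].copy()
    cand["practice_rank"] = cand["practice"].map(PRACTICE_ORDER)
    cand = cand.sort_values(
        ["cell_id", "yield_delta", "practice_rank"],
        ascending=[True, False, True], kind="mergesort")
    best = cand.drop_duplicates("cell_id", keep="first")

    decisions = pd.DataFrame({"cell_id": cells["cell_id"].to_numpy()})
    decisions["rule_id"] = rule.rule_id
    b = best.set_index("cell_id")
    decisions["chosen"] = (b["practice"].reindex(decisions["cell_id"])
                           .fillna("retain_current").to_numpy())
    adopted = decisions["chosen"] != "retain_current"
    decisions["adopted_fraction"] = np.where(adopted, 1.0, 0.0)
    decisions["yield_delta"] = (b["yield_delta"].reindex(decisions["cell_id"])
                                .fillna(0.0).to_numpy())
    decisions["soc_delta"] = (b["soc_delta"].reindex(decisions["cell_id"])
                              .fillna(0.0).to_numpy())

    if rule.rule_id == "rule1_rates":
        decisions = apply_adoption_rates(decisions, cells, rule.rate_table)
    return decisions


def apply_adoption_rates(decisions: pd.DataFrame, cells: pd.DataFrame,
                         rate_table: pd.DataFrame) -> pd.DataFrame:
    """Scale adopted fractions by country x practice adoption-rate caps.

    ``rate_table`` columns: country_id, practice, rate (in [0, 1]); pairs
    absent from the table keep full adoption. Retaining cells are untouched.
    """
    if ((rate_table["rate"] < 0) | (rate_table["rate"] > 1)).any():
        raise ConfigError("adoption rates must be in [0, 1]")
    out = decisions.copy()
    country = cells.set_index("cell_id")["country_id"]
    key = pd.MultiIndex.from_arrays(
        [country.reindex(out["cell_id"]).to_numpy(), out["chosen"].to_numpy()])
    rates = rate_table.set_index(["country_id", "practice"])["rate"]
    r = rates.reindex(key).fillna(1.0).to_numpy()
    adopted = out["chosen"] != "retain_current"
    out.loc[adopted, "adopted_fraction"] = (
        out.loc[adopted, "adopted_fraction"].to_numpy() * r[adopted.to_numpy()])
    return out


def adopted_area(decisions: pd.DataFrame, cells: pd.DataFrame,
                 by: str = "world") -> pd.Series:
    """Adopted hectares, grouped by practice, country, or the world.

    Sum of cell area x adopted fraction. ``by`` in {"world", "practice",
    "country"}.
    """
    area = cells.set_index("cell_id")["area"].reindex(decisions["cell_id"])
    ha = area.to_numpy() * decisions["adopted_fraction"].to_numpy()
    if by == "world":
        return pd.Series({"world": float(ha.sum())})
    if by == "practice":
        s = pd.Series(ha, index=decisions["chosen"].to_numpy()).groupby(level=0).sum()
        return s.drop("retain_current", errors="ignore")
    if by == "country":
        country = cells.set_index("cell_id")["country_id"].reindex(decisions["cell_id"])
        return pd.Series(ha, index=country.to_numpy()).groupby(level=0).sum()
    raise ValueError(f"unknown grouping {by!r}")
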