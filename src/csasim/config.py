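"""Parameter containers and configuration I/O.

Every tunable quantity in the simulator lives in one of the frozen
dataclasses below, so a scenario is fully described by (config, seed).
Configs round-trip through YAML for the command-line interface.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

CROPS = ("maize", "wheat", "rice")
PRACTICES = ("no_till", "isfm", "nue", "awd")

#: crops each practice can attach to (no-till and integrated soil fertility
#: management are upland practices; nitrogen-use efficiency and alternate
#: wetting and drying are rice practices)
PRACTICE_CROPS = {
    "no_till": ("maize", "wheat"),
    "isfm": ("maize", "wheat"),
    "nue": ("rice",),
    "awd": ("rice",),
}

#: deterministic practice precedence used for tie-breaking in the adoption
#: engine (fixed order, then cell id)
PRACTICE_ORDER = {p: i for i, p in enumerate(PRACTICES)}

CLIMATES = ("pseudo_dry_cool", "pseudo_hot")
TAILORINGS = ("poor", "average", "optimal")
WATER_REGIMES = ("continuous_flooding", "multiple_drainage", "none")
RULES = ("rule1", "rule2", "rule1_rates", "rule2_awdcost")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass(frozen=True)
class AwdWaterSpec:
    """Water-management cycle for alternate wetting and drying (AWD).

    The paddy starts flooded to ``flood_depth`` (cm), the water table falls
    at ``drawdown_rate`` (cm/day) to ``min_level`` (cm, below the surface,
    hence negative), then is re-flooded at ``reflood_rate`` (cm/day) back to
    ``flood_depth``.
    """

    flood_depth: float = 10.0
    drawdown_rate: float = 0.5
    min_level: float = -5.0
    reflood_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.drawdown_rate <= 0 or self.reflood_rate <= 0:
            raise ConfigError("AWD drawdown/reflood rates must be > 0")
        if self.flood_depth < self.min_level:
            raise ConfigError("flood_depth must be >= min_level")


@dataclass(frozen=True)
class EmissionFactors:
    """IPCC Tier-1 emission coefficients and GWP conversions.

    N2O channels are fractions of applied/mineralized N emitted as N2O-N.
    The rice CH4 model is ``base x water-regime scaling x organic-amendment
    scaling x season days`` with the organic scaling
    ``(1 + straw + cfoa_fym * fym)**straw_param``.

    GWP100 defaults are AR5 (CH4 = 28, N2O = 265); both are plain fields so
    other inventories' values drop in via config.
    """

    ef_n_mineral: float = 0.01
    ef_n_organic: float = 0.01
    ef_n_mineralized: float = 0.01
    ef_n_residue: float = 0.007
    ef_n_flooded: float = 0.003
    ch4_ef_base: float = 1.3          # kg CH4 / ha / day
    sf_continuous: float = 1.0
    sf_multiple_drainage: float = 0.52
    straw_param: float = 0.59
    cfoa_fym: float = 0.14
    gwp_ch4: float = 28.0
    gwp_n2o: float = 265.0
    # whether the flooded-rice N2O factor also covers mineralized N
    # (default: applied N only, i.e. mineral + manure)
    flooded_includes_mineralized: bool = False

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if v < 0:
                raise ConfigError(f"emission factor {f.name} must be >= 0")
        if self.sf_multiple_drainage > self.sf_continuous:
            raise ConfigError("sf_multiple_drainage must be <= sf_continuous")


@dataclass(frozen=True)
class AwdEconomics:
    """Cost parameters behind the AWD profitability break-even.

    irrigation_cost_share: irrigation's share of total production cost
    (literature range 0.03-0.36). irrigation_cost_reduction: fraction of
    irrigation cost saved by AWD (up to 0.30). cost_revenue_ratio: total
    production cost relative to gross revenue (1.0 = break-even farm).
    """

    irrigation_cost_share: float = 0.30
    irrigation_cost_reduction: float = 0.30
    cost_revenue_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.irrigation_cost_share <= 1.0:
            raise ConfigError("irrigation_cost_share must be in [0, 1]")
        if not 0.0 <= self.irrigation_cost_reduction <= 1.0:
            raise ConfigError("irrigation_cost_reduction must be in [0, 1]")
        if not 0.0 < self.cost_revenue_ratio <= 2.0:
            raise ConfigError("cost_revenue_ratio must be in (0, 2]")


@dataclass(frozen=True)
class PracticeResponseParams:
    """Sampling distribution of one practice's cell-level response.

    yield_delta ~ Normal(mean, sd) truncated to [-0.5, 0.5];
    soc_delta ~ Normal(soc_mean, soc_sd), t C/ha/yr.
    """

    yield_mean: float
    yield_sd: float
    soc_mean: float
    soc_sd: float


@dataclass(frozen=True)
class HungerParams:
    """Mapping from relative kilocalorie availability to hunger risk.

    share = clip(s0 * availability**(-eta), 0, 1): anchored at s0 when
    availability equals the base-year world reference, strictly decreasing
    where unclipped.
    """

    s0: float = 0.12
    eta: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.s0 <= 1.0:
            raise ConfigError("s0 must be in [0, 1]")
        if self.eta <= 0:
            raise ConfigError("eta must be > 0")


@dataclass(frozen=True)
class ChildParams:
    """Linear index for the share of undernourished children under five.

    The share is ``clip(base + c_kcal*(kcal-kcal_ref)/1000 + c_edu*(edu-edu_ref)
    + c_life*(life-life_ref) + c_san*(san-san_ref), 0, 1)``; c_kcal <= 0 so
    more food means fewer undernourished children.
    """

    base_share: float = 0.22
    c_kcal: float = -0.06      # per 1000 kcal/cap/day above reference
    c_edu: float = -0.15
    c_life: float = -0.30
    c_san: float = -0.12
    kcal_ref: float = 1200.0
    edu_ref: float = 0.5
    life_ref: float = 1.05
    san_ref: float = 0.5

    def __post_init__(self) -> None:
        if self.c_kcal > 0:
            raise ConfigError("c_kcal must be <= 0 (more food, less undernourishment)")


#: kilocalories per tonne of fresh harvest, config constants with
#: literature-typical cereal energy densities
KCAL_PER_T = {"maize": 3.58e6, "wheat": 3.34e6, "rice": 3.60e6}


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic-world generator settings.

    The defaults define the study conditions: a 2000-cell grid in 40 food
    production units (FPUs) across 15 countries, three crops, two contrasting
    pseudo-climate paths, SSP2-style macro growth (population 0.6 %/yr,
    per-capita income 2 %/yr), and per-practice response distributions that
    allow both yield gains and losses.
    """

    n_cells: int = 2000
    n_fpus: int = 40
    n_countries: int = 15
    crop_shares: dict = field(default_factory=lambda: {"maize": 0.38, "wheat": 0.34, "rice": 0.28})
    irrigated_share: dict = field(default_factory=lambda: {"maize": 0.25, "wheat": 0.35, "rice": 0.60})

    # baseline agronomy (lognormal medians / sd of log where noted)
    yield_median: dict = field(default_factory=lambda: {"maize": 4.5, "wheat": 3.1, "rice": 4.2})
    yield_log_sd: float = 0.35
    area_median_ha: float = 1.0e5
    area_log_sd: float = 0.8
    n_mineral_median: dict = field(default_factory=lambda: {"maize": 95.0, "wheat": 85.0, "rice": 100.0})
    n_mineral_log_sd: float = 0.45
    n_manure_median: float = 18.0     # kg N/ha, lognormal
    n_manure_log_sd: float = 0.7
    n_residue_median: float = 15.0
    n_residue_log_sd: float = 0.5
    n_mineralized_mean: float = 30.0
    n_mineralized_sd: float = 8.0
    season_days_range: dict = field(default_factory=lambda: {
        "maize": (100, 160), "wheat": (120, 220), "rice": (100, 150)})
    straw_median: float = 1.5         # t/ha incorporated rice straw
    straw_log_sd: float = 0.5
    fym_median: float = 0.8           # t/ha farmyard manure on rice
    fym_log_sd: float = 0.7

    # practice responses (per-cell draws; both signs possible)
    practice_params: dict = field(default_factory=lambda: {
        "no_till": PracticeResponseParams(0.02, 0.06, 0.15, 0.10),
        "isfm": PracticeResponseParams(0.08, 0.08, 0.20, 0.15),
        "nue": PracticeResponseParams(0.06, 0.05, 0.02, 0.02),
        "awd": PracticeResponseParams(-0.02, 0.04, 0.00, 0.02),
    })
    yield_delta_bounds: tuple = (-0.5, 0.5)
    #: additive shift of practice yield-delta means under each pseudo-climate
    climate_delta_offset: dict = field(default_factory=lambda: {
        "pseudo_dry_cool": 0.0, "pseudo_hot": -0.005})
    #: per-FPU x crop baseline yield trend modifiers (fraction/yr), Normal
    climate_trend_mean: dict = field(default_factory=lambda: {
        "pseudo_dry_cool": -0.001, "pseudo_hot": -0.003})
    climate_trend_sd: float = 0.002

    # practice input changes applied by the generator
    isfm_manure_add_median: float = 15.0   # extra organic N, kg N/ha
    isfm_manure_add_log_sd: float = 0.4
    nue_mineral_factor: float = 0.80       # deep placement: same uptake, less N applied

    # macro paths (SSP2-style)
    population_growth: float = 0.006
    gdp_pc_growth: float = 0.02
    base_population_total: float = 6.9e9
    base_income_pc: float = 9000.0

    # market behaviour
    area_price_elast: float = 0.25
    demand_price_elast: float = -0.35
    income_elast: dict = field(default_factory=lambda: {"maize": 0.15, "wheat": 0.20, "rice": 0.25})
    exog_yield_growth: float = 0.008
    feed_share: dict = field(default_factory=lambda: {"maize": 0.50, "wheat": 0.20, "rice": 0.02})

    # food security
    hunger_eta: float = 2.0
    child_share: float = 0.10

    # livestock link
    livestock_base_herd: float = 1.5e9
    livestock_feed_price_elast: float = -0.3
    livestock_ef_per_head: float = 1.8     # t CO2e/head/yr

    n_excluded_countries: int = 6          # no-till exclusion set size
    start_year: int = 2010
    end_year: int = 2050

    def __post_init__(self) -> None:
        if self.n_fpus > self.n_cells:
            raise ConfigError("n_fpus must not exceed n_cells")
        if self.n_countries > self.n_fpus:
            raise ConfigError("n_countries must not exceed n_fpus")
        for crop, y in self.yield_median.items():
            if y <= 0:
                raise ConfigError(f"non-positive baseline yield for {crop}")
        if abs(sum(self.crop_shares.values()) - 1.0) > 1e-9:
            raise ConfigError("crop_shares must sum to 1")
        if self.n_excluded_countries > self.n_countries:
            raise ConfigError("cannot exclude more countries than exist")

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["practice_params"] = {
            k: dataclasses.asdict(v) for k, v in self.practice_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "practice_params" in d:
            d["practice_params"] = {
                k: PracticeResponseParams(**v) if isinstance(v, dict) else v
                for k, v in d["practice_params"].items()}
        if "yield_delta_bounds" in d:
            d["yield_delta_bounds"] = tuple(d["yield_delta_bounds"])
        if "season_days_range" in d:
            d["season_days_range"] = {
                k: tuple(v) for k, v in d["season_days_range"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass(frozen=True)
class LivestockLink:
    """Global cattle herd responding to feed prices.

    herd = base_herd * feed_price_ratio**elasticity; the emission delta is
    (herd - base_herd) * ef_per_head, in t CO2e/yr.
    """

    base_herd: float = 1.5e9
    feed_price_elast: float = -0.3
    ef_per_head: float = 1.8

    def __post_init__(self) -> None:
        if self.ef_per_head < 0:
            raise ConfigError("per-head emissions must be >= 0")
        if self.feed_price_elast > 0:
            raise ConfigError("feed-price elasticity of the herd must be <= 0")
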