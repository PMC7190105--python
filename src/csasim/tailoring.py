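"""FPU-level yield shifters at three tailoring proficiency levels.

Farmers differ in how well they adapt a practice to local conditions.
That heterogeneity is summarized from the distribution of adopted yield
gains inside each food production unit (FPU): "poor" tailoring realizes
the mean of the lower quartile, "average" the mean of the whole
distribution, "optimal" the mean of the upper quartile. The resulting
shifter enters the market model either as a first-year yield level bump
or spread over the projection horizon as an annualized growth increment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import TAILORINGS

#: projection horizon (years) over which a growth-mode shifter compounds
HORIZON_YEARS = 40


def fpu_shifters(gains, weights=None) -> dict:
    """Poor/average/optimal shifters from one FPU x crop gain distribution.

    ``gains`` are the adopted cells' fractional yield deltas, ``weights``
    their adopted areas (equal weights when omitted). Quartiles are taken
    on the weighted empirical CDF F: the lower-quartile set is
    {x <= Q1} with Q1 = inf{x : F(x) >= 0.25}; the upper-quartile set is
    {x >= Q3} with Q3 = inf{x : F(x) > 0.75}. Both sets are non-empty for
    any non-empty input and the ordering poor <= average <= optimal always
    holds. An empty gain list (no adoption in the FPU) gives zero shifters.
    """
    gains = np.asarray(gains, dtype=float)
    if gains.size == 0:
        return {"poor": 0.0, "average": 0.0, "optimal": 0.0}
    if weights is None:
        weights = np.ones_like(gains)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    if weights.sum() == 0:
        weights = np.ones_like(gains)

    order = np.argsort(gains, kind="mergesort")
    g, w = gains[order], weights[order]
    cdf = np.cumsum(w) / w.sum()

    q1 = g[np.searchsorted(cdf, 0.25, side="left")]
    # smallest value whose CDF strictly exceeds 0.75
    idx = np.searchsorted(cdf, 0.75, side="right")
    q3 = g[min(idx, len(g) - 1)]

    lower = g <= q1
    upper = g >= q3
    avg = float(np.average(g, weights=w))
    return {
        "poor": float(np.average(g[lower], weights=w[lower])),
        "average": avg,
        "optimal": float(np.average(g[upper], weights=w[upper])),
    }


def shifter_table(decisions: pd.DataFrame, cells: pd.DataFrame,
                  weighting: str = "area") -> pd.DataFrame:
    """All-FPU shifter table from an adoption decision table.

    One row per (fpu_id, crop, tailoring) that has at least one adopting
    cell; weights are adopted areas (``weighting="area"``, default) or
    cell counts (``weighting="count"``).
    """
    meta = cells.set_index("cell_id")[["fpu_id", "crop", "area"]]
    d = decisions[decisions["adopted_fraction"] > 0].copy()
    d = d.join(meta, on="cell_id")
    rows = []
    for (fpu, crop), grp in d.groupby(["fpu_id", "crop"], sort=True):
        w = (grp["area"] * grp["adopted_fraction"]).to_numpy() \
            if weighting == "area" else None
        s = fpu_shifters(grp["yield_delta"].to_numpy(), w)
        for level in TAILORINGS:
            rows.append({"fpu_id": fpu, "crop": crop,
                         "tailoring": level, "shifter": s[level]})
    return pd.DataFrame(rows, columns=["fpu_id", "crop", "tailoring", "shifter"])


def shift_supply(bau_growth: float, shifter: float, mode: str = "growth"):
    """Fold a yield shifter into a supply trajectory parameter.

    ``mode="level"``: returns the first-year yield multiplier (1+shifter),
    growth untouched. ``mode="growth"`` (default): returns the adjusted
    annual growth rate — the annualized increment (1+shifter)**(1/H) - 1 is
    compounded onto the BAU rate, g' = (1+g)(1+shifter)**(1/H) - 1, so the
    horizon-end yield ratio versus BAU is exactly (1+shifter).
    """
    if mode == "level":
        return 1.0 + shifter
    if mode == "growth":
        return (1.0 + bau_growth) * (1.0 + shifter) ** (1.0 / HORIZON_YEARS) - 1.0
    raise ValueError(f"unknown shifter mode {mode!r}")
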