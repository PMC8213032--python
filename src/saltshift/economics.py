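"""Healthcare cost offsets from averted incident strokes.

Costs attach only to first-ever incident events — the cost source is
first-time hospitalisation for acute stroke — so savings are averted incident
counts times the unit cost, discounted to the base year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .errors import InvalidConfigError
from .lifetable import discount_stream


@dataclass(frozen=True)
class CostModel:
    """Unit cost (US$) per first-ever incident case, keyed (disease, sex)."""

    cost_per_case: Mapping[tuple[str, str], float]
    currency_year: int = 2019

    def __post_init__(self) -> None:
        for key, v in self.cost_per_case.items():
            if v < 0:
                raise InvalidConfigError(f"negative unit cost for {key}: {v}")

    @classmethod
    def from_table(cls, costs: pd.DataFrame) -> "CostModel":
        """Build from a costs table with columns disease, sex, cost_per_case."""
        required = {"disease", "sex", "cost_per_case"}
        missing = required - set(costs.columns)
        if missing:
            raise InvalidConfigError(f"costs table missing columns {sorted(missing)}")
        mapping = {(r.disease, r.sex): float(r.cost_per_case)
                   for r in costs.itertuples()}
        year = int(costs["currency_year"].iloc[0]) if "currency_year" in costs else 2019
        return cls(cost_per_case=mapping, currency_year=year)


def cost_savings(baseline_incident: pd.DataFrame,
                 intervention_incident: pd.DataFrame,
                 costs: CostModel, rate: float,
                 base_year: int = 2019) -> pd.DataFrame:
    """Discounted savings per disease, sex and year from averted incidence.

    Both inputs need columns (disease, sex, year, incident) on identical
    indices; mismatched indices raise.  Negative averted counts (intervention
    above baseline) are tolerated and appear as negative savings.
    """
    key = ["disease", "sex", "year"]
    base = baseline_incident.set_index(key).sort_index()
    intv = intervention_incident.set_index(key).sort_index()
    if not base.index.equals(intv.index):
        raise ValueError("baseline and intervention arms are not aligned on "
                         "(disease, sex, year)")
    out = base[["incident"]].rename(columns={"incident": "baseline_incident"})
    out["intervention_incident"] = intv["incident"]
    out["averted"] = out["baseline_incident"] - out["intervention_incident"]
    out = out.reset_index()
    unit = out.apply(lambda r: costs.cost_per_case[(r["disease"], r["sex"])], axis=1)
    out["savings"] = out["averted"] * unit
    out["savings_discounted"] = discount_stream(
        out["savings"].to_numpy(), rate, base_year, out["year"].to_numpy())
    return out


def summarise_costs(savings: pd.DataFrame) -> pd.DataFrame:
    """Cumulative savings per disease x sex, in millions US$."""
    g = savings.groupby(["disease", "sex"], sort=True)[
        ["averted", "savings", "savings_discounted"]].sum().reset_index()
    g["savings_musd"] = g["savings_discounted"] / 1e6
    g["savings_undiscounted_musd"] = g["savings"] / 1e6
    return g.drop(columns=["savings", "savings_discounted"])
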