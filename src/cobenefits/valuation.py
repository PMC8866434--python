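"""Monetization of avoided mortality with value-of-statistical-life models.

Two VSL variants are supported:

* ``local_linear`` — benefit transfer over time within one country:
  VSL_target = VSL_baseline + (INC_target - INC_baseline) * MVSL, where
  MVSL is the marginal VSL per unit of per-capita disposable income.  The
  default slope follows a contingent-valuation study in Chongqing in which
  VSL rose by 14,550 USD per 145.8 USD of annual income.
* ``international_transfer`` — a foreign reference VSL scaled by an income
  ratio with elasticity beta: VSL = VSL_ref * (INC_target/INC_ref)**beta.

Monetized benefits are avoided deaths times VSL, reported in billion USD
(2017 USD throughout; no inflation adjustment inside the pipeline), and
net benefits are benefits minus scenario mitigation costs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, InputError

__all__ = [
    "VSLModel",
    "ScenarioCost",
    "vsl_local_linear",
    "vsl_international_transfer",
    "monetize",
    "net_benefit",
    "build_valuation_table",
    "validate_valuation",
    "CHONGQING_MVSL",
    "VALUATION_COLUMNS",
]

#: Marginal VSL (USD of VSL per USD of annual per-capita income) from the
#: Chongqing contingent-valuation relationship: 14,550 USD of VSL per
#: 145.8 USD of income.
CHONGQING_MVSL = 14550.0 / 145.8

VALUATION_COLUMNS = [
    "scenario_pair",
    "year",
    "health_benefit",
    "benefit_low",
    "benefit_high",
    "cost",
    "net_benefit",
    "benefit_cost_ratio",
]


@dataclass(frozen=True)
class VSLModel:
    """Configuration of a VSL benefit-transfer model (all values in USD).

    ``variant`` selects which fields are used: ``local_linear`` needs
    ``vsl_baseline``, ``income_baseline`` and ``mvsl_slope``;
    ``international_transfer`` needs ``vsl_reference``, ``income_reference``
    and the income elasticity ``beta`` (conventionally in [0, 2]).
    """

    variant: str
    vsl_baseline: float = 0.0
    income_baseline: float = 0.0
    mvsl_slope: float = CHONGQING_MVSL
    vsl_reference: float = 0.0
    income_reference: float = 0.0
    beta: float = 0.8

    def __post_init__(self) -> None:
        if self.variant not in ("local_linear", "international_transfer"):
            raise ConfigurationError(f"unknown VSL variant {self.variant!r}")
        for name in ("vsl_baseline", "income_baseline", "vsl_reference", "income_reference"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not (0.0 <= self.beta <= 2.0):
            raise InputError(f"beta must be in [0, 2], got {self.beta}")

    def vsl_at(self, income_target: float) -> float:
        if self.variant == "local_linear":
            return vsl_local_linear(self, income_target)
        return vsl_international_transfer(self, income_target)


def vsl_local_linear(m: VSLModel, income_target: float, floor: bool = True) -> float:
    """Local linear VSL: baseline plus marginal VSL times the income change.

    With ``floor`` the result is clipped at zero (with a warning) when a
    large income decline would drive it negative; otherwise that raises.
    """
    if m.variant != "local_linear":
        raise ConfigurationError("vsl_local_linear requires a local_linear model")
    vsl = m.vsl_baseline + (float(income_target) - m.income_baseline) * m.mvsl_slope
    if vsl < 0:
        if not floor:
            raise InputError(f"local-linear VSL is negative ({vsl:.2f} USD)")
        warnings.warn("local-linear VSL fell below zero; floored at 0", stacklevel=2)
        return 0.0
    return vsl


def vsl_international_transfer(m: VSLModel, income_target: float) -> float:
    """Reference VSL scaled by the income ratio raised to elasticity beta."""
    if m.variant != "international_transfer":
        raise ConfigurationError("vsl_international_transfer requires an international_transfer model")
    if m.income_reference <= 0 or income_target <= 0:
        raise InputError("incomes must be positive for the international transfer")
    return m.vsl_reference * (float(income_target) / m.income_reference) ** m.beta


@dataclass(frozen=True)
class ScenarioCost:
    """Mitigation cost of one scenario pair (billion USD); an input, not computed."""

    label: str
    mitigation_cost: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mitigation_cost) or self.mitigation_cost < 0:
            raise InputError(f"mitigation cost must be finite and >= 0, got {self.mitigation_cost}")


def monetize(avoided: pd.DataFrame, vsl: float) -> tuple[float, float, float]:
    """Total avoided deaths times VSL, in billion USD: (mean, low, high).

    ``avoided`` is a burden-shaped difference table; signs propagate, so a
    scenario pair in which the policy run carries the larger burden yields
    a negative benefit.
    """
    if vsl < 0:
        raise InputError("VSL must be >= 0")
    scale = float(vsl) / 1e9
    return (
        float(avoided["deaths_mean"].sum()) * scale,
        float(avoided["deaths_low"].sum()) * scale,
        float(avoided["deaths_high"].sum()) * scale,
    )


def net_benefit(benefit: float, cost: "ScenarioCost | float") -> float:
    """Net benefit in billion USD: health benefit minus mitigation cost."""
    c = cost.mitigation_cost if isinstance(cost, ScenarioCost) else float(cost)
    return float(benefit) - c


def build_valuation_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Assemble a valuation table from per-scenario-pair entries.

    Each row dict provides ``scenario_pair``, ``year``, the monetized
    ``(health_benefit, benefit_low, benefit_high)`` and ``cost`` (billion
    USD).  ``net_benefit`` and ``benefit_cost_ratio`` are derived here;
    the ratio is NaN when cost is zero (flagged undefined rather than
    infinite).
    """
    out = []
    for r in rows:
        benefit = float(r["health_benefit"])
        cost = float(r["cost"])
        out.append(
            {
                "scenario_pair": r["scenario_pair"],
                "year": r["year"],
                "health_benefit": benefit,
                "benefit_low": float(r.get("benefit_low", benefit)),
                "benefit_high": float(r.get("benefit_high", benefit)),
                "cost": cost,
                "net_benefit": benefit - cost,
                "benefit_cost_ratio": benefit / cost if cost > 0 else float("nan"),
            }
        )
    df = pd.DataFrame(out, columns=VALUATION_COLUMNS)
    return df.sort_values(["scenario_pair", "year"], kind="mergesort").reset_index(drop=True)


def validate_valuation(df: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check the net-benefit identity (net = benefit - cost) row by row."""
    missing = [c for c in VALUATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"valuation table missing columns: {missing}")
    resid = df["net_benefit"] - (df["health_benefit"] - df["cost"])
    if np.any(np.abs(resid.to_numpy(dtype=float)) > tol):
        raise InputError("valuation table violates net_benefit = health_benefit - cost")
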