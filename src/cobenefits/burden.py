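"""Attributable mortality, its confidence envelope, and scenario co-benefits.

The attributable-fraction bookkeeping runs in three steps per (disease i,
age group j).  First the population-weighted mean relative risk over the
grid, RRbar.  Second the "underlying incidence" Ihat = I / RRbar — the
hypothetical cause-specific mortality rate that would remain were the
whole population at the minimum-risk concentration (the reported national
rate I already embeds the prevailing exposure).  Third the grid sum

    M_{i,j} = sum_g P_{g,j} * Ihat_{i,j} * (RR(C_g) - 1),

deaths per year attributable to PM2.5.  For a spatially uniform field
this collapses to the familiar attributable-fraction identity
M = P * I * (RR - 1)/RR.

Confidence bounds rerun the whole chain (RR, RRbar, Ihat) with theta
shifted by -/+ 1.96 SE(theta): a single global parameter shift, so bounds
summed across strata are a perfect-dependence bound, not an independent
propagation — flagged as such in table metadata.

Scenario co-benefits are plain differences, dM = M_REF - M_policy, per
matching (year, disease, age group, region) key; the sign is preserved
(negative means the policy scenario is worse).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, FormatError, InputError
from .exposure_grid import ConcentrationField, PopulationField, check_registration
from .gemm_risk import GEMMParamSet, relative_risk

__all__ = [
    "IncidenceTable",
    "underlying_incidence",
    "attributable_mortality",
    "avoided_mortality",
    "aggregate_burden",
    "validate_burden",
    "read_burden",
    "write_burden",
    "BURDEN_KEYS",
    "BURDEN_COLUMNS",
    "CI_NOTE",
]

BURDEN_KEYS = ["scenario", "year", "disease", "age_group", "region"]
BURDEN_COLUMNS = BURDEN_KEYS + ["deaths_mean", "deaths_low", "deaths_high"]

#: Metadata note attached to every burden table: CI bounds across strata
#: are summed under a perfect-dependence assumption (one global theta
#: shift), i.e. they are a bound, not an independently propagated interval.
CI_NOTE = (
    "deaths_low/deaths_high derive from a single global theta -/+ 1.96*SE shift; "
    "sums across strata are perfect-dependence bounds, not propagated intervals"
)


class IncidenceTable:
    """National cause-specific mortality rates I_{i,j}, deaths per person-year.

    Keys are (disease, age_group); rates must be finite and non-negative
    and each key unique.  Held fixed across projection years (no baseline-
    mortality projection).
    """

    def __init__(self, rates: Mapping[tuple[str, str], float]):
        self._rates: dict[tuple[str, str], float] = {}
        for key, value in rates.items():
            disease, age = key
            v = float(value)
            if not np.isfinite(v) or v < 0:
                raise InputError(f"incidence for {key} must be finite and >= 0, got {value}")
            k = (str(disease), str(age))
            if k in self._rates:
                raise FormatError(f"duplicate incidence key {k}")
            self._rates[k] = v

    def __len__(self) -> int:
        return len(self._rates)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self._rates

    def get(self, disease: str, age_group: str) -> float:
        key = (disease, age_group)
        if key not in self._rates:
            raise ConfigurationError(f"no incidence entry for (disease, age_group) {key}")
        return self._rates[key]

    def items(self):
        return self._rates.items()

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"disease": d, "age_group": a, "incidence": v}
            for (d, a), v in sorted(self._rates.items())
        ]
        return pd.DataFrame(rows, columns=["disease", "age_group", "incidence"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceTable":
        missing = [c for c in ("disease", "age_group", "incidence") if c not in df.columns]
        if missing:
            raise FormatError(f"incidence table missing columns: {missing}")
        rates: dict[tuple[str, str], float] = {}
        for idx, row in df.iterrows():
            key = (str(row["disease"]), str(row["age_group"]))
            if key in rates:
                raise FormatError(f"duplicate incidence key {key} at row {idx}")
            rates[key] = float(row["incidence"])
        return cls(rates)

    @classmethod
    def read_csv(cls, path) -> "IncidenceTable":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def underlying_incidence(i_rate: float, rr_bar: float) -> float:
    """Underlying incidence Ihat = I / RRbar (deaths per person-year).

    The rate that would remain at the minimum-risk concentration; never
    exceeds the reported rate since RRbar >= 1.
    """
    if rr_bar < 1:
        raise InputError(f"mean population-weighted RR must be >= 1, got {rr_bar}")
    if i_rate < 0:
        raise InputError(f"incidence must be >= 0, got {i_rate}")
    return i_rate / rr_bar


def attributable_mortality(
    conc: ConcentrationField,
    pop: PopulationField,
    inc: IncidenceTable,
    params: Sequence[GEMMParamSet],
    scenario: str | None = None,
    year: int | None = None,
    region: str = "national",
    z_crit: float = 1.96,
    national_pop: PopulationField | None = None,
) -> pd.DataFrame:
    """Attributable deaths per (disease, age group) as a burden table.

    The mean RR entering the underlying incidence is weighted by the
    national (whole-grid) population; pass ``national_pop`` when ``pop``
    has been masked to a region so that the national underlying incidence
    is reused.  Age groups without a parameter set (children under 25)
    contribute no attributable deaths and no rows.
    """
    if not check_registration(conc, pop):
        raise AlignmentError("concentration and population grids are not co-registered")
    ref_pop = national_pop if national_pop is not None else pop
    if national_pop is not None and not check_registration(conc, national_pop):
        raise AlignmentError("national population grid is not co-registered")

    rows = []
    for p in params:
        i_rate = inc.get(p.disease, p.age_group)  # ConfigurationError if absent
        weights = pop.age_slice(p.age_group)
        nat_weights = ref_pop.age_slice(p.age_group)
        nat_total = nat_weights.sum()
        deaths = {}
        for label, theta in (
            ("deaths_mean", p.theta),
            ("deaths_low", p.theta - z_crit * p.theta_se),
            ("deaths_high", p.theta + z_crit * p.theta_se),
        ):
            if nat_total <= 0:
                deaths[label] = 0.0
                continue
            rr = relative_risk(conc.values, p.with_theta(theta))
            rr_bar = float((rr * nat_weights).sum() / nat_total)
            # plain division, no >=1 gate: the lower-bound rerun may push
            # theta (and hence RRbar) below the null
            i_hat = i_rate / rr_bar
            deaths[label] = float((weights * i_hat * (rr - 1.0)).sum())
        lo, hi = sorted((deaths["deaths_low"], deaths["deaths_high"]))
        rows.append(
            {
                "scenario": scenario if scenario is not None else conc.scenario_label,
                "year": year if year is not None else (conc.year if conc.year is not None else -1),
                "disease": p.disease,
                "age_group": p.age_group,
                "region": region,
                "deaths_mean": deaths["deaths_mean"],
                "deaths_low": lo,
                "deaths_high": hi,
            }
        )
    df = pd.DataFrame(rows, columns=BURDEN_COLUMNS)
    df = df.sort_values(BURDEN_KEYS, kind="mergesort").reset_index(drop=True)
    df.attrs["ci_note"] = CI_NOTE
    return df


def avoided_mortality(ref: pd.DataFrame, policy: pd.DataFrame) -> pd.DataFrame:
    """Avoided deaths dM = M_REF - M_policy per matching key.

    Keys are (year, disease, age_group, region); the scenario column of
    the result is "<ref>-<policy>".  Sign is preserved: negative avoided
    deaths mean the policy scenario carries the larger burden.
    """
    keys = [k for k in BURDEN_KEYS if k != "scenario"]
    left = ref.set_index(keys)
    right = policy.set_index(keys)
    unmatched = left.index.symmetric_difference(right.index)
    if len(unmatched) > 0:
        raise AlignmentError(f"burden tables do not align; unmatched keys: {list(unmatched)}")
    right = right.reindex(left.index)
    out = pd.DataFrame(index=left.index)
    for col in ("deaths_mean", "deaths_low", "deaths_high"):
        out[col] = left[col] - right[col]
    ref_label = ref["scenario"].iloc[0] if len(ref) else "ref"
    pol_label = policy["scenario"].iloc[0] if len(policy) else "policy"
    out = out.reset_index()
    out.insert(0, "scenario", f"{ref_label}-{pol_label}")
    out = out[BURDEN_COLUMNS].sort_values(BURDEN_KEYS, kind="mergesort").reset_index(drop=True)
    out.attrs["ci_note"] = CI_NOTE
    return out


def aggregate_burden(b: pd.DataFrame, by: Iterable[str] = ()) -> pd.DataFrame:
    """Sum deaths within groups, keeping only the keys named in ``by``.

    ``by`` is a subset of {disease, age_group, region}; scenario and year
    always remain grouping keys.  Collapsed keys are reported as "all".
    The grand total is invariant under any choice of grouping.
    """
    by = list(by)
    allowed = {"disease", "age_group", "region"}
    unknown = set(by) - allowed
    if unknown:
        raise ConfigurationError(f"unknown grouping keys: {sorted(unknown)}; allowed: {sorted(allowed)}")
    group_keys = ["scenario", "year"] + [k for k in ("disease", "age_group", "region") if k in by]
    value_cols = ["deaths_mean", "deaths_low", "deaths_high"]
    grouped = b.groupby(group_keys, as_index=False, sort=True)[value_cols].sum()
    for k in ("disease", "age_group", "region"):
        if k not in by:
            grouped[k] = "all"
    grouped = grouped[BURDEN_COLUMNS].sort_values(BURDEN_KEYS, kind="mergesort").reset_index(drop=True)
    grouped.attrs["ci_note"] = CI_NOTE
    return grouped


def validate_burden(df: pd.DataFrame, allow_negative: bool = False) -> None:
    """Raise unless the table has the burden schema and ordered CI bounds."""
    missing = [c for c in BURDEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"burden table missing columns: {missing}")
    vals = df[["deaths_mean", "deaths_low", "deaths_high"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise InputError("burden table contains non-finite entries")
    if not allow_negative and np.any(vals < 0):
        raise InputError("burden table contains negative deaths")
    if np.any(df["deaths_low"].to_numpy() > df["deaths_mean"].to_numpy() + 1e-9) or np.any(
        df["deaths_mean"].to_numpy() > df["deaths_high"].to_numpy() + 1e-9
    ):
        raise InputError("burden table violates deaths_low <= deaths_mean <= deaths_high")


def write_burden(df: pd.DataFrame, path, allow_negative: bool = False) -> None:
    """Write a burden table with deterministic row and column order."""
    validate_burden(df, allow_negative=allow_negative)
    out = df[BURDEN_COLUMNS].sort_values(BURDEN_KEYS, kind="mergesort")
    out.to_csv(path, index=False, float_format="%.17g")


def read_burden(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in BURDEN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"burden table missing columns: {missing}")
    df.attrs["ci_note"] = CI_NOTE
    return df
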