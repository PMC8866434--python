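"""End-to-end scenario runs: config, staging, and deterministic reports.

A run is a pure function of (config, input files): per scenario it
computes the population-weighted concentration, the population above an
air-quality threshold, and the attributable-mortality table; per
(policy, reference) pair it computes avoided deaths and the monetized
cost–benefit comparison.  Outputs are delimited tables with fixed column
order plus a plain-text summary and a run log (package and library
versions, seed, config hash), so repeated runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .burden import (
    IncidenceTable,
    aggregate_burden,
    attributable_mortality,
    avoided_mortality,
    validate_burden,
    write_burden,
    BURDEN_COLUMNS,
)
from .errors import ConfigurationError
from .exposure_grid import (
    ConcentrationField,
    PopulationField,
    population_above,
    population_weighted_concentration,
)
from .gemm_risk import read_gemm_params
from .valuation import (
    VSLModel,
    build_valuation_table,
    validate_valuation,
    monetize,
)

__all__ = ["ScenarioSpec", "RunConfig", "load_config", "run_pipeline", "write_report"]

#: Air-quality threshold for the population-above metric, ug/m3 (the
#: "at most 35" annual-mean goal; non-attainment is strictly above).
DEFAULT_THRESHOLD = 35.0

EXPOSURE_COLUMNS = ["scenario", "year", "pwc", "population_above_threshold", "threshold"]


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    year: int
    concentration: str
    cost: float | None = None  # billion USD; required for policy scenarios


@dataclass
class RunConfig:
    """Validated run configuration.

    ``reference_map`` sends each policy scenario label to its reference
    (no-climate-policy) scenario; both must be listed under ``scenarios``
    with the same year and, when labels follow the ``SSPx_...`` pattern,
    the same socio-economic pathway.
    """

    scenarios: list[ScenarioSpec]
    reference_map: dict[str, str]
    population: str
    incidence: str
    gemm_params: str
    vsl: dict[str, Any]
    output_dir: str = "out"
    seed: int = 0
    threshold: float = DEFAULT_THRESHOLD
    gdp_by_year: dict[int, float] = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        labels = {s.label: s for s in self.scenarios}
        if len(labels) != len(self.scenarios):
            raise ConfigurationError("scenario labels must be unique")
        for policy, ref in self.reference_map.items():
            if policy not in labels:
                raise ConfigurationError(f"policy scenario {policy!r} not in scenario list")
            if ref not in labels:
                raise ConfigurationError(f"reference scenario {ref!r} not in scenario list")
            if labels[policy].year != labels[ref].year:
                raise ConfigurationError(
                    f"policy {policy!r} (year {labels[policy].year}) and reference "
                    f"{ref!r} (year {labels[ref].year}) must share a year"
                )
            p_ssp, _, _ = policy.partition("_")
            r_ssp, _, _ = ref.partition("_")
            if p_ssp.startswith("SSP") and r_ssp.startswith("SSP") and p_ssp != r_ssp:
                raise ConfigurationError(
                    f"policy {policy!r} and reference {ref!r} belong to different pathways"
                )
            if labels[policy].cost is None:
                raise ConfigurationError(f"policy scenario {policy!r} needs a mitigation cost")

    def resolve(self, p: str) -> Path:
        path = Path(p)
        return path if path.is_absolute() else self.base_dir / path

    def vsl_model(self) -> VSLModel:
        kwargs = {k: v for k, v in self.vsl.items() if k in VSLModel.__dataclass_fields__}
        return VSLModel(**kwargs)

    def vsl_for_year(self, year: int) -> float:
        model = self.vsl_model()
        income_by_year = self.vsl.get("income_by_year", {})
        if year in income_by_year:
            income = float(income_by_year[year])
        elif "income_target" in self.vsl:
            income = float(self.vsl["income_target"])
        elif model.variant == "local_linear":
            income = model.income_baseline
        else:
            raise ConfigurationError(
                f"no target income for year {year}; set vsl.income_by_year or vsl.income_target"
            )
        return model.vsl_at(income)


def load_config(path) -> RunConfig:
    """Read a YAML run configuration; relative paths resolve next to it."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config {path} is not a mapping")
    try:
        scenarios = [
            ScenarioSpec(
                label=str(s["label"]),
                year=int(s["year"]),
                concentration=str(s["concentration"]),
                cost=None if s.get("cost") is None else float(s["cost"]),
            )
            for s in raw["scenarios"]
        ]
        cfg = RunConfig(
            scenarios=scenarios,
            reference_map={str(k): str(v) for k, v in raw.get("reference_map", {}).items()},
            population=str(raw["population"]),
            incidence=str(raw["incidence"]),
            gemm_params=str(raw["gemm_params"]),
            vsl=dict(raw.get("vsl", {"variant": "local_linear"})),
            output_dir=str(raw.get("output_dir", "out")),
            seed=int(raw.get("seed", 0)),
            threshold=float(raw.get("threshold", DEFAULT_THRESHOLD)),
            gdp_by_year={int(k): float(v) for k, v in raw.get("gdp_by_year", {}).items()},
            base_dir=path.parent,
        )
    except KeyError as exc:
        raise ConfigurationError(f"config missing required key: {exc}") from exc
    cfg.raw = raw  # retained for hashing into the run log
    return cfg


def _load_concentration(cfg: RunConfig, spec: ScenarioSpec) -> ConcentrationField:
    path = cfg.resolve(spec.concentration)
    if not path.exists():
        raise ConfigurationError(f"concentration file for {spec.label!r} not found: {path}")
    return ConcentrationField.from_long_table(
        pd.read_csv(path), scenario_label=spec.label, year=spec.year
    )


def _load_population(cfg: RunConfig) -> PopulationField:
    path = cfg.resolve(cfg.population)
    if not path.exists():
        raise ConfigurationError(f"population file not found: {path}")
    return PopulationField.from_long_table(pd.read_csv(path))


def run_pipeline(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute every stage and return the result tables.

    Returns ``exposure`` (PWC and population above the threshold, one row
    per scenario), ``burden`` (attributable deaths by scenario, disease
    and age), ``avoided`` (reference minus policy deaths per pair) and
    ``valuation`` (monetized benefits versus mitigation costs).
    """
    pop = _load_population(cfg)
    inc = IncidenceTable.read_csv(cfg.resolve(cfg.incidence))
    params = read_gemm_params(cfg.resolve(cfg.gemm_params))

    fields = {s.label: _load_concentration(cfg, s) for s in cfg.scenarios}
    by_label = {s.label: s for s in cfg.scenarios}

    exposure_rows = []
    burden_tables = {}
    for s in cfg.scenarios:
        conc = fields[s.label]
        exposure_rows.append(
            {
                "scenario": s.label,
                "year": s.year,
                "pwc": population_weighted_concentration(conc, pop),
                "population_above_threshold": population_above(conc, pop, cfg.threshold),
                "threshold": cfg.threshold,
            }
        )
        burden_tables[s.label] = attributable_mortality(
            conc, pop, inc, params, scenario=s.label, year=s.year
        )
    exposure = pd.DataFrame(exposure_rows, columns=EXPOSURE_COLUMNS)
    burden = pd.concat(burden_tables.values(), ignore_index=True)[BURDEN_COLUMNS]

    avoided_tables = []
    valuation_rows = []
    for policy_label in sorted(cfg.reference_map):
        ref_label = cfg.reference_map[policy_label]
        diff = avoided_mortality(burden_tables[ref_label], burden_tables[policy_label])
        avoided_tables.append(diff)
        year = by_label[policy_label].year
        vsl = cfg.vsl_for_year(year)
        benefit, lo, hi = monetize(diff, vsl)
        valuation_rows.append(
            {
                "scenario_pair": f"{ref_label}-{policy_label}",
                "year": year,
                "health_benefit": benefit,
                "benefit_low": lo,
                "benefit_high": hi,
                "cost": by_label[policy_label].cost,
            }
        )
    avoided = (
        pd.concat(avoided_tables, ignore_index=True)[BURDEN_COLUMNS]
        if avoided_tables
        else pd.DataFrame(columns=BURDEN_COLUMNS)
    )
    valuation = build_valuation_table(valuation_rows)
    if cfg.gdp_by_year:
        valuation["gdp_share_percent"] = [
            100.0 * nb / cfg.gdp_by_year[y] if y in cfg.gdp_by_year else float("nan")
            for nb, y in zip(valuation["net_benefit"], valuation["year"])
        ]
    return {"exposure": exposure, "burden": burden, "avoided": avoided, "valuation": valuation}


def _config_hash(cfg: RunConfig) -> str:
    raw = getattr(cfg, "raw", None)
    payload = json.dumps(raw, sort_keys=True, default=str) if raw is not None else repr(cfg)
    return hashlib.sha256(payload.encode()).hexdigest()


def _summary_text(tables: Mapping[str, pd.DataFrame], threshold: float) -> str:
    lines = ["Co-benefit run summary", "======================", ""]
    lines.append("Exposure by scenario:")
    for _, r in tables["exposure"].iterrows():
        lines.append(
            f"  {r['scenario']} ({int(r['year'])}): PWC = {r['pwc']:.2f} ug/m3, "
            f"population above {threshold:g} ug/m3 = {r['population_above_threshold']:,.0f}"
        )
    lines.append("")
    lines.append("Attributable deaths (all diseases and ages):")
    totals = aggregate_burden(tables["burden"])
    for _, r in totals.iterrows():
        lines.append(
            f"  {r['scenario']} ({int(r['year'])}): {r['deaths_mean']:,.0f} "
            f"(95% CI {r['deaths_low']:,.0f}-{r['deaths_high']:,.0f})"
        )
    if len(tables["avoided"]):
        lines.append("")
        lines.append("Avoided deaths and monetized net benefit per scenario pair:")
        avoided_totals = aggregate_burden(tables["avoided"])
        val = tables["valuation"].set_index("scenario_pair")
        for _, r in avoided_totals.iterrows():
            pair = r["scenario"]
            v = val.loc[pair]
            ratio = v["benefit_cost_ratio"]
            ratio_txt = f"{ratio:.2f}" if pd.notna(ratio) else "undefined (zero cost)"
            lines.append(
                f"  {pair} ({int(r['year'])}): {r['deaths_mean']:,.0f} avoided deaths "
                f"(95% CI {r['deaths_low']:,.0f}-{r['deaths_high']:,.0f}); "
                f"benefit {v['health_benefit']:.2f} B USD, cost {v['cost']:.2f} B USD, "
                f"net {v['net_benefit']:.2f} B USD, benefit/cost {ratio_txt}"
            )
    lines.append("")
    return "\n".join(lines)


def write_report(tables: Mapping[str, pd.DataFrame], outdir, cfg: RunConfig | None = None) -> dict[str, Path]:
    """Write result tables, a plain-text summary, and the run log.

    Tables are re-validated before writing (burden CI ordering, the
    net-benefit identity); an invariant violation refuses to write.
    Column order is fixed; rows are already deterministically sorted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    validate_burden(tables["burden"])
    validate_burden(tables["avoided"], allow_negative=True)
    validate_valuation(tables["valuation"])

    paths = {
        "exposure": outdir / "exposure_summary.csv",
        "burden": outdir / "burden.csv",
        "avoided": outdir / "avoided_deaths.csv",
        "valuation": outdir / "valuation.csv",
        "summary": outdir / "summary.txt",
        "run_log": outdir / "run_log.json",
    }
    tables["exposure"].to_csv(paths["exposure"], index=False, float_format="%.17g")
    write_burden(tables["burden"], paths["burden"])
    write_burden(tables["avoided"], paths["avoided"], allow_negative=True)
    tables["valuation"].to_csv(paths["valuation"], index=False, float_format="%.17g")

    threshold = cfg.threshold if cfg is not None else DEFAULT_THRESHOLD
    paths["summary"].write_text(_summary_text(tables, threshold))

    import numpy, scipy  # versions recorded for the run log

    log = {
        "package_version": __version__,
        "numpy_version": numpy.__version__,
        "pandas_version": pd.__version__,
        "scipy_version": scipy.__version__,
        "seed": cfg.seed if cfg is not None else None,
        "config_sha256": _config_hash(cfg) if cfg is not None else None,
    }
    paths["run_log"].write_text(json.dumps(log, indent=2, sort_keys=True) + "\n")
    return paths
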