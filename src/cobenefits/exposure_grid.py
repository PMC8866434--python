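"""Co-registered gridded PM2.5 and population fields with exposure summaries.

Concentration and population live on the same regular lat/lon grid (cell
edges, strictly monotone).  The pipeline performs no regridding: inputs
must already be co-registered, and every exposure summary first checks
registration.  Summaries include the population-weighted concentration
(PWC), the population living above a concentration threshold, and the
population-weighted mean relative risk that feeds the attributable-
mortality calculation.

Grid I/O comes in two flavours: an xarray Dataset (NetCDF-style, with
``lat_edge``/``lon_edge`` coordinates and named variables) and a plain
delimited "long" table (``lat_index, lon_index, value``) convenient for
small text fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .errors import InputError, RegistrationError, WeightingError
from .gemm_risk import GEMMParamSet, relative_risk

__all__ = [
    "ConcentrationField",
    "PopulationField",
    "check_registration",
    "population_weighted_concentration",
    "population_above",
    "mean_population_weighted_rr",
    "pearson_station_eval",
    "apply_region_mask",
]

#: Registration tolerance on grid edges, degrees.
EDGE_TOL = 1e-9


def _check_edges(edges: np.ndarray, name: str) -> np.ndarray:
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2:
        raise InputError(f"{name} must be a 1-D array of at least 2 edges")
    if not np.all(np.isfinite(edges)):
        raise InputError(f"{name} must be finite")
    if not (np.all(np.diff(edges) > 0) or np.all(np.diff(edges) < 0)):
        raise InputError(f"{name} must be strictly monotone")
    return edges


def unit_edges(n: int, start: float = 0.0) -> np.ndarray:
    """Convenience 1-degree cell edges for index-based fixtures."""
    return start + np.arange(n + 1, dtype=float)


@dataclass
class ConcentrationField:
    """Annual-mean PM2.5 concentration on a regular lat/lon grid.

    ``values`` has shape ``(n_lat, n_lon)`` in ug/m3; ``lat_edges`` and
    ``lon_edges`` are the cell-edge coordinates (length n+1).
    """

    values: np.ndarray
    lat_edges: np.ndarray
    lon_edges: np.ndarray
    scenario_label: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lat_edges = _check_edges(self.lat_edges, "lat_edges")
        self.lon_edges = _check_edges(self.lon_edges, "lon_edges")
        if self.values.ndim != 2:
            raise InputError("concentration values must be 2-D (lat, lon)")
        if self.values.shape != (self.lat_edges.size - 1, self.lon_edges.size - 1):
            raise InputError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.lat_edges.size - 1}, {self.lon_edges.size - 1})"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("concentration values must be finite")
        if np.any(self.values < 0):
            raise InputError("concentration values must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def scaled(self, factor: float, scenario_label: str | None = None) -> "ConcentrationField":
        """A copy with all cells multiplied by ``factor``."""
        return ConcentrationField(
            self.values * float(factor),
            self.lat_edges,
            self.lon_edges,
            scenario_label if scenario_label is not None else self.scenario_label,
            self.year,
        )

    # ---- I/O -------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {"pm25": (("lat", "lon"), self.values)},
            coords={"lat_edge": ("lat_edge", self.lat_edges), "lon_edge": ("lon_edge", self.lon_edges)},
            attrs={"scenario_label": self.scenario_label, "year": -1 if self.year is None else self.year},
        )
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ConcentrationField":
        year = int(ds.attrs.get("year", -1))
        return cls(
            np.asarray(ds["pm25"].values),
            np.asarray(ds["lat_edge"].values),
            np.asarray(ds["lon_edge"].values),
            str(ds.attrs.get("scenario_label", "")),
            None if year < 0 else year,
        )

    def to_long_table(self) -> pd.DataFrame:
        n_lat, n_lon = self.shape
        ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
        return pd.DataFrame(
            {"lat_index": ii.ravel(), "lon_index": jj.ravel(), "value": self.values.ravel()}
        )

    @classmethod
    def from_long_table(
        cls,
        df: pd.DataFrame,
        lat_edges: np.ndarray | None = None,
        lon_edges: np.ndarray | None = None,
        scenario_label: str = "",
        year: int | None = None,
    ) -> "ConcentrationField":
        n_lat = int(df["lat_index"].max()) + 1
        n_lon = int(df["lon_index"].max()) + 1
        values = np.zeros((n_lat, n_lon))
        values[df["lat_index"].to_numpy(), df["lon_index"].to_numpy()] = df["value"].to_numpy()
        if lat_edges is None:
            lat_edges = unit_edges(n_lat)
        if lon_edges is None:
            lon_edges = unit_edges(n_lon)
        return cls(values, lat_edges, lon_edges, scenario_label, year)


@dataclass
class PopulationField:
    """Age-structured population counts on the same grid convention.

    ``counts`` has shape ``(n_age, n_lat, n_lon)`` in persons;
    ``age_groups`` are the ordered, unique band labels.
    """

    counts: np.ndarray
    age_groups: Sequence[str]
    lat_edges: np.ndarray
    lon_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.age_groups = list(self.age_groups)
        self.lat_edges = _check_edges(self.lat_edges, "lat_edges")
        self.lon_edges = _check_edges(self.lon_edges, "lon_edges")
        if self.counts.ndim != 3:
            raise InputError("population counts must be 3-D (age, lat, lon)")
        if len(self.age_groups) != self.counts.shape[0]:
            raise InputError("age_groups length does not match counts")
        if len(set(self.age_groups)) != len(self.age_groups):
            raise InputError("age_groups must be unique")
        if self.counts.shape[1:] != (self.lat_edges.size - 1, self.lon_edges.size - 1):
            raise InputError("counts shape does not match grid")
        if not np.all(np.isfinite(self.counts)):
            raise InputError("population counts must be finite")
        if np.any(self.counts < 0):
            raise InputError("population counts must be >= 0")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def age_slice(self, age_group: str) -> np.ndarray:
        if age_group not in self.age_groups:
            raise InputError(f"age group {age_group!r} not in population field")
        return self.counts[self.age_groups.index(age_group)]

    def all_ages(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def scaled(self, factor: float) -> "PopulationField":
        return PopulationField(self.counts * float(factor), self.age_groups, self.lat_edges, self.lon_edges)

    # ---- I/O -------------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {"population": (("age_group", "lat", "lon"), self.counts)},
            coords={
                "age_group": ("age_group", list(self.age_groups)),
                "lat_edge": ("lat_edge", self.lat_edges),
                "lon_edge": ("lon_edge", self.lon_edges),
            },
        )

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "PopulationField":
        return cls(
            np.asarray(ds["population"].values),
            [str(a) for a in ds["age_group"].values],
            np.asarray(ds["lat_edge"].values),
            np.asarray(ds["lon_edge"].values),
        )

    def to_long_table(self) -> pd.DataFrame:
        n_age, n_lat, n_lon = self.counts.shape
        aa, ii, jj = np.meshgrid(np.arange(n_age), np.arange(n_lat), np.arange(n_lon), indexing="ij")
        return pd.DataFrame(
            {
                "age_group": [self.age_groups[a] for a in aa.ravel()],
                "lat_index": ii.ravel(),
                "lon_index": jj.ravel(),
                "value": self.counts.ravel(),
            }
        )

    @classmethod
    def from_long_table(
        cls,
        df: pd.DataFrame,
        lat_edges: np.ndarray | None = None,
        lon_edges: np.ndarray | None = None,
        age_order: Sequence[str] | None = None,
    ) -> "PopulationField":
        ages = list(age_order) if age_order is not None else list(pd.unique(df["age_group"]))
        n_lat = int(df["lat_index"].max()) + 1
        n_lon = int(df["lon_index"].max()) + 1
        counts = np.zeros((len(ages), n_lat, n_lon))
        aidx = pd.Categorical(df["age_group"], categories=ages).codes
        counts[aidx, df["lat_index"].to_numpy(), df["lon_index"].to_numpy()] = df["value"].to_numpy()
        if lat_edges is None:
            lat_edges = unit_edges(n_lat)
        if lon_edges is None:
            lon_edges = unit_edges(n_lon)
        return cls(counts, ages, lat_edges, lon_edges)


def check_registration(conc: ConcentrationField, pop: PopulationField) -> bool:
    """True iff the two grids share identical edges (within 1e-9 degrees).

    Ordering is part of the contract: the same edges stored reversed do
    not register.
    """
    if conc.lat_edges.shape != pop.lat_edges.shape or conc.lon_edges.shape != pop.lon_edges.shape:
        return False
    return bool(
        np.all(np.abs(conc.lat_edges - pop.lat_edges) <= EDGE_TOL)
        and np.all(np.abs(conc.lon_edges - pop.lon_edges) <= EDGE_TOL)
    )


def _require_registered(conc: ConcentrationField, pop: PopulationField) -> None:
    if not check_registration(conc, pop):
        raise RegistrationError(
            "concentration and population grids are not co-registered; "
            "regrid inputs before running the pipeline"
        )


def population_weighted_concentration(conc: ConcentrationField, pop: PopulationField) -> float:
    """Population-weighted mean PM2.5, sum_g C_g P_g / sum_g P_g (ug/m3)."""
    _require_registered(conc, pop)
    weights = pop.all_ages()
    total = weights.sum()
    if total <= 0:
        raise WeightingError("total population is zero; weighted concentration undefined")
    return float((conc.values * weights).sum() / total)


def population_above(conc: ConcentrationField, pop: PopulationField, threshold: float) -> float:
    """Population in cells with concentration strictly above ``threshold``.

    Strict inequality: an air-quality goal of "at most T" is failed only
    by cells with C > T.
    """
    _require_registered(conc, pop)
    mask = conc.values > float(threshold)
    return float(pop.all_ages()[mask].sum())


def mean_population_weighted_rr(
    conc: ConcentrationField, pop: PopulationField, p: GEMMParamSet
) -> float:
    """Population-weighted mean relative risk for ``p``'s age group.

    Weighted over grid cells by that age group's population; always >= 1
    for non-negative theta, and exactly 1 when the whole field is at or
    below the minimum-risk concentration.
    """
    _require_registered(conc, pop)
    weights = pop.age_slice(p.age_group)
    total = weights.sum()
    if total <= 0:
        raise WeightingError(
            f"age group {p.age_group!r} has zero population; weighted RR undefined"
        )
    rr = relative_risk(conc.values, p)
    return float((rr * weights).sum() / total)


def pearson_station_eval(simulated, observed) -> float:
    """Pearson r between paired simulated and observed station values."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape or sim.ndim != 1:
        raise InputError("simulated and observed must be 1-D arrays of equal length")
    if sim.size < 3:
        raise InputError("need at least 3 station pairs")
    if np.ptp(sim) == 0 or np.ptp(obs) == 0:
        raise InputError("correlation undefined for a constant series")
    return float(stats.pearsonr(sim, obs).statistic)


def apply_region_mask(pop: PopulationField, mask: np.ndarray) -> PopulationField:
    """Restrict a population field to a region by zeroing cells outside ``mask``.

    ``mask`` is a boolean (n_lat, n_lon) grid; this reproduces regional
    reporting without a GIS dependency.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pop.counts.shape[1:]:
        raise InputError("mask shape does not match population grid")
    return PopulationField(pop.counts * mask[None, :, :], pop.age_groups, pop.lat_edges, pop.lon_edges)
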