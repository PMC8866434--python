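"""Synthetic inputs with the statistical structure the analysis assumes.

Real inputs to the pipeline are chemistry-transport concentration fields,
a gridded age-structured population, burden-of-disease incidence rates
and exposure–response fit parameters.  None of these can be bundled, so
this module generates stand-ins that preserve what the analysis actually
relies on:

* concentration — positive, spatially correlated, log-normal in level,
  with scenario pairs that differ by a controlled fractional reduction
  (the policy field is the reference field scaled down cell-wise);
* population — non-negative counts clustered around a few urban centers,
  summing exactly to the requested national total, with an age structure
  resembling a mid-2010s Chinese profile;
* incidence — cause-specific mortality rates rising steeply with age;
* exposure–response parameters — per-age fits with positive theta and
  scales in the range of the published fits.

Everything is deterministic under the spec's single seed.  Defaults mimic
the study conditions: an unweighted mean concentration of 53 ug/m3 (the
2015 population-weighted PM2.5 level in China), a ~10% policy reduction
(the scale of the strictest mid-century scenario), and a 1.37-billion
population on a China-sized domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError
from .exposure_grid import ConcentrationField, PopulationField
from .gemm_risk import GEMMParamSet, write_gemm_params
from .burden import IncidenceTable

__all__ = [
    "SyntheticSpec",
    "make_concentration_pair",
    "make_population",
    "make_incidence_and_params",
    "write_synthetic_inputs",
    "regrid_nearest",
    "DEFAULT_AGE_GROUPS",
    "DEFAULT_AGE_PROFILE",
    "ADULT_AGE_GROUPS",
]

#: Age bands: one child band (no attributed risk below 25) plus 5-year
#: adult bands up to 85+.
DEFAULT_AGE_GROUPS = (
    "0-24",
    "25-29",
    "30-34",
    "35-39",
    "40-44",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    "75-79",
    "80-84",
    "85+",
)
ADULT_AGE_GROUPS = DEFAULT_AGE_GROUPS[1:]

#: Share of population per band, approximating China's mid-2010s age
#: pyramid; sums to 1 exactly.
DEFAULT_AGE_PROFILE = (
    0.332,
    0.082,
    0.071,
    0.068,
    0.080,
    0.086,
    0.065,
    0.055,
    0.055,
    0.040,
    0.027,
    0.020,
    0.012,
    0.007,
)

# Domain roughly spanning mainland China.
_LAT_SPAN = (18.0, 54.0)
_LON_SPAN = (73.0, 135.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions.

    ``conc_mean`` is the target unweighted mean of the reference field
    (ug/m3); ``conc_spatial_corr_length`` the smoothing half-width in
    cells; ``conc_lognormal_sigma`` the log-scale spread (0 gives a
    spatially uniform field); ``reduction_fraction`` the cell-wise
    fractional cut the policy scenario applies to the reference field.
    """

    grid_shape: tuple[int, int] = (64, 64)
    conc_mean: float = 53.0
    conc_spatial_corr_length: int = 4
    conc_lognormal_sigma: float = 0.5
    pop_total: int = 1_370_000_000
    pop_cluster_count: int = 12
    age_groups: tuple[str, ...] = DEFAULT_AGE_GROUPS
    age_profile: tuple[float, ...] = DEFAULT_AGE_PROFILE
    reduction_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        n_lat, n_lon = self.grid_shape
        if n_lat < 1 or n_lon < 1:
            raise ConfigurationError("grid_shape must be at least 1x1")
        if self.conc_mean <= 0:
            raise ConfigurationError("conc_mean must be positive")
        if self.conc_spatial_corr_length < 0:
            raise ConfigurationError("conc_spatial_corr_length must be >= 0")
        if self.conc_lognormal_sigma < 0:
            raise ConfigurationError("conc_lognormal_sigma must be >= 0")
        if self.pop_total < 0:
            raise ConfigurationError("pop_total must be >= 0")
        if self.pop_cluster_count < 1:
            raise ConfigurationError("pop_cluster_count must be >= 1")
        if not (0.0 <= self.reduction_fraction < 1.0):
            raise ConfigurationError("reduction_fraction must be in [0, 1)")
        if len(self.age_groups) != len(self.age_profile):
            raise ConfigurationError("age_groups and age_profile lengths differ")
        if abs(sum(self.age_profile) - 1.0) > 1e-9:
            raise ConfigurationError("age_profile must sum to 1")
        if any(p < 0 for p in self.age_profile):
            raise ConfigurationError("age_profile proportions must be >= 0")

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        n_lat, n_lon = self.grid_shape
        return (
            np.linspace(*_LAT_SPAN, n_lat + 1),
            np.linspace(*_LON_SPAN, n_lon + 1),
        )


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    # independent streams per product, all keyed to the one spec seed
    return np.random.default_rng([spec.seed, stream])


def make_concentration_pair(
    spec: SyntheticSpec,
    ref_label: str = "REF",
    policy_label: str = "RCP",
    year: int | None = None,
) -> tuple[ConcentrationField, ConcentrationField]:
    """A (reference, policy) pair of spatially correlated positive fields.

    White noise is smoothed with a separable moving average of half-width
    ``conc_spatial_corr_length``, standardized, exponentiated with
    log-scale ``conc_lognormal_sigma`` and rescaled so the unweighted mean
    is exactly ``conc_mean``.  The policy field is the reference scaled by
    ``1 - reduction_fraction`` in every cell.
    """
    rng = _rng(spec, 1)
    n_lat, n_lon = spec.grid_shape
    if spec.conc_lognormal_sigma == 0 or n_lat * n_lon == 1:
        values = np.full((n_lat, n_lon), spec.conc_mean)
    else:
        noise = rng.standard_normal((n_lat, n_lon))
        size = 2 * spec.conc_spatial_corr_length + 1
        smooth = ndimage.uniform_filter(noise, size=size, mode="wrap")
        sd = smooth.std()
        z = (smooth - smooth.mean()) / sd if sd > 0 else np.zeros_like(smooth)
        values = np.exp(spec.conc_lognormal_sigma * z)
        values *= spec.conc_mean / values.mean()
    lat_edges, lon_edges = spec.edges()
    ref = ConcentrationField(values, lat_edges, lon_edges, ref_label, year)
    policy = ref.scaled(1.0 - spec.reduction_fraction, policy_label)
    return ref, policy


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``targets``."""
    if total == 0 or targets.sum() <= 0:
        return np.zeros(targets.shape, dtype=np.int64)
    quota = targets / targets.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = quota - base
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def make_population(spec: SyntheticSpec) -> PopulationField:
    """Clustered integer population counts summing exactly to ``pop_total``.

    Cell weights mix Gaussian bumps at seeded cluster centers with a thin
    rural background; counts are apportioned by largest remainder, first
    across age bands and then across cells within each band, so both the
    national total and the age split are exact.
    """
    rng = _rng(spec, 2)
    n_lat, n_lon = spec.grid_shape
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    weights = np.full((n_lat, n_lon), 0.05)
    scale = max(min(n_lat, n_lon) / 10.0, 1.0)
    for _ in range(spec.pop_cluster_count):
        ci = rng.uniform(0, n_lat)
        cj = rng.uniform(0, n_lon)
        sd = scale * rng.uniform(0.5, 1.5)
        amp = rng.uniform(0.5, 2.0)
        weights += amp * np.exp(-(((ii - ci) ** 2) + ((jj - cj) ** 2)) / (2 * sd**2))
    age_totals = _largest_remainder(np.asarray(spec.age_profile, dtype=float), int(spec.pop_total))
    counts = np.zeros((len(spec.age_groups), n_lat, n_lon), dtype=float)
    flat = weights.ravel()
    for a, n_a in enumerate(age_totals):
        counts[a] = _largest_remainder(flat, int(n_a)).reshape(n_lat, n_lon)
    lat_edges, lon_edges = spec.edges()
    return PopulationField(counts, list(spec.age_groups), lat_edges, lon_edges)


def _age_midpoint(label: str) -> float:
    if label.endswith("+"):
        return float(label[:-1]) + 2.5
    lo, hi = label.split("-")
    return (float(lo) + float(hi)) / 2.0


def make_incidence_and_params(
    spec: SyntheticSpec,
    diseases: Sequence[str] = ("NCD+LRI",),
    theta_zero: bool = False,
) -> tuple[IncidenceTable, list[GEMMParamSet]]:
    """Cause-specific incidence and exposure–response fits per adult band.

    Incidence rises roughly exponentially with age, spanning about
    7e-4 deaths per person-year at 25-29 to ~0.2 at 85+, the shape of a
    combined noncommunicable-disease + lower-respiratory-infection
    endpoint.  Fit parameters draw theta near the published magnitude
    (~0.1, standard error a tenth of that) and scales alpha in [1, 20],
    mu in [5, 30], nu in [1, 50].  ``theta_zero`` produces a null model
    (theta = 0, SE = 0) under which the downstream burden is exactly zero.
    """
    rng = _rng(spec, 3)
    rates: dict[tuple[str, str], float] = {}
    params: list[GEMMParamSet] = []
    adult_groups = [g for g in spec.age_groups if _age_midpoint(g) >= 25.0]
    for disease in diseases:
        for group in adult_groups:
            mid = _age_midpoint(group)
            rate = 6e-4 * np.exp(0.095 * (mid - 27.0)) * rng.uniform(0.9, 1.1)
            rates[(disease, group)] = float(rate)
            theta = 0.0 if theta_zero else float(np.clip(rng.normal(0.12, 0.02), 0.02, 0.3))
            params.append(
                GEMMParamSet(
                    disease=disease,
                    age_group=group,
                    theta=theta,
                    theta_se=0.0 if theta_zero else 0.1 * theta,
                    alpha=float(rng.uniform(1.0, 20.0)),
                    mu=float(rng.uniform(5.0, 30.0)),
                    nu=float(rng.uniform(1.0, 50.0)),
                )
            )
    return IncidenceTable(rates), params


def regrid_nearest(
    field: ConcentrationField, lat_edges: np.ndarray, lon_edges: np.ndarray
) -> ConcentrationField:
    """Nearest-neighbor regrid, for fixture construction only.

    The analysis core never regrids; use this to co-register a synthetic
    field onto a target grid before feeding the pipeline.
    """
    lat_edges = np.asarray(lat_edges, dtype=float)
    lon_edges = np.asarray(lon_edges, dtype=float)
    src_lat = 0.5 * (field.lat_edges[:-1] + field.lat_edges[1:])
    src_lon = 0.5 * (field.lon_edges[:-1] + field.lon_edges[1:])
    dst_lat = 0.5 * (lat_edges[:-1] + lat_edges[1:])
    dst_lon = 0.5 * (lon_edges[:-1] + lon_edges[1:])
    li = np.abs(dst_lat[:, None] - src_lat[None, :]).argmin(axis=1)
    lj = np.abs(dst_lon[:, None] - src_lon[None, :]).argmin(axis=1)
    values = field.values[np.ix_(li, lj)]
    return ConcentrationField(values, lat_edges, lon_edges, field.scenario_label, field.year)


def write_synthetic_inputs(spec: SyntheticSpec, outdir, year: int = 2050) -> dict[str, Path]:
    """Generate and write every input file the pipeline reads.

    Writes long-table CSVs for the reference and policy concentration
    fields and the population, plus incidence and exposure–response
    parameter tables.  Returns the paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, policy = make_concentration_pair(spec, year=year)
    pop = make_population(spec)
    inc, params = make_incidence_and_params(spec)
    paths = {
        "concentration_ref": outdir / "concentration_ref.csv",
        "concentration_policy": outdir / "concentration_policy.csv",
        "population": outdir / "population.csv",
        "incidence": outdir / "incidence.csv",
        "gemm_params": outdir / "gemm_params.csv",
    }
    ref.to_long_table().to_csv(paths["concentration_ref"], index=False, float_format="%.17g")
    policy.to_long_table().to_csv(paths["concentration_policy"], index=False, float_format="%.17g")
    pop.to_long_table().to_csv(paths["population"], index=False, float_format="%.17g")
    inc.write_csv(paths["incidence"])
    write_gemm_params(params, paths["gemm_params"])
    return paths
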