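"""GEMM exposure–response function and its parameter tables.

The Global Exposure Mortality Model (GEMM) expresses the relative risk
of cause-specific mortality from long-term ambient PM2.5 exposure as a
log-linear term damped by a logistic weight,

    RR(c) = exp{ theta * ln(z/alpha + 1) / (1 + exp(-(z - mu)/nu)) },
    z = c - cmin,

for concentrations ``c`` above the theoretical minimum-risk concentration
``cmin`` (default 2.4 ug/m3), and RR = 1 otherwise.  ``theta`` sets the
log-RR scale, ``alpha`` the curvature of the log term, and ``mu``/``nu``
the center and width of the logistic damping.  Parameters are fitted per
disease endpoint and 5-year adult age band; the public fit tables report
a standard error for ``theta`` only, which is what the confidence
envelope here propagates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, ParameterLookupError

__all__ = [
    "GEMMParamSet",
    "relative_risk",
    "relative_risk_ci",
    "read_gemm_params",
    "write_gemm_params",
    "params_by_key",
    "lookup_params",
    "DEFAULT_CMIN",
]

#: Theoretical minimum-risk concentration, ug/m3.
DEFAULT_CMIN = 2.4

#: Columns a parameter table must provide.
REQUIRED_COLUMNS = ("disease", "age_group", "theta", "theta_se", "alpha", "mu", "nu")


@dataclass(frozen=True)
class GEMMParamSet:
    """Fitted exposure–response parameters for one (disease, age group).

    Parameters
    ----------
    disease
        Endpoint label, e.g. ``"NCD+LRI"`` (noncommunicable diseases plus
        lower respiratory infections).
    age_group
        Age-band label; 5-year adult bands (``"25-29"`` ... ``"85+"``) or
        an all-adult aggregate.
    theta, theta_se
        Log-RR scale coefficient and its standard error (dimensionless).
    alpha
        Scale of the logarithmic term, ug/m3.
    mu, nu
        Center and width of the logistic damping term, ug/m3.
    cmin
        Theoretical minimum-risk concentration, ug/m3; no excess risk is
        attributed below it.
    """

    disease: str
    age_group: str
    theta: float
    theta_se: float
    alpha: float
    mu: float
    nu: float
    cmin: float = DEFAULT_CMIN

    def __post_init__(self) -> None:
        for name in ("theta", "theta_se", "alpha", "mu", "nu", "cmin"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise InputError(f"{name} must be a finite number, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.alpha <= 0:
            raise InputError(f"alpha must be > 0, got {self.alpha}")
        if self.nu <= 0:
            raise InputError(f"nu must be > 0, got {self.nu}")
        if self.cmin < 0:
            raise InputError(f"cmin must be >= 0, got {self.cmin}")
        if self.theta_se < 0:
            raise InputError(f"theta_se must be >= 0, got {self.theta_se}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.disease, self.age_group)

    def with_theta(self, theta: float) -> "GEMMParamSet":
        """A copy with ``theta`` replaced (used for CI perturbations)."""
        return replace(self, theta=float(theta))


def _validate_concentration(c) -> np.ndarray:
    arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("concentration must be finite")
    if np.any(arr < 0):
        raise InputError("concentration must be >= 0")
    return arr


def relative_risk(c, p: GEMMParamSet):
    """Relative risk at concentration ``c`` (ug/m3) under parameters ``p``.

    Vectorizes elementwise over array input; returns exactly 1 at or
    below the minimum-risk concentration.  Scalar input yields a float.
    """
    arr = _validate_concentration(c)
    z = arr - p.cmin
    # Evaluate the log term on clipped z so the masked-out branch never
    # sees a negative argument.
    zpos = np.maximum(z, 0.0)
    log_term = np.log(zpos / p.alpha + 1.0)
    logistic = 1.0 / (1.0 + np.exp(-(zpos - p.mu) / p.nu))
    rr = np.where(z > 0, np.exp(p.theta * log_term * logistic), 1.0)
    if np.isscalar(c) or np.ndim(c) == 0:
        return float(rr)
    return rr


def relative_risk_ci(c, p: GEMMParamSet, z_crit: float = 1.96):
    """(rr_low, rr_mean, rr_high) with ``theta`` shifted by ``-/+ z_crit*SE``.

    Only ``theta`` carries uncertainty; the public GEMM fit tables report
    a standard error for it alone.  With ``z_crit = 1.96`` the bounds are
    an approximate 95% envelope.  All three equal 1 below ``cmin``.
    """
    if not math.isfinite(z_crit):
        raise InputError("z_crit must be finite")
    lo = relative_risk(c, p.with_theta(p.theta - z_crit * p.theta_se))
    mid = relative_risk(c, p)
    hi = relative_risk(c, p.with_theta(p.theta + z_crit * p.theta_se))
    return lo, mid, hi


def read_gemm_params(source, cmin: float = DEFAULT_CMIN, sep: str = ",") -> list[GEMMParamSet]:
    """Read a delimited parameter table into validated parameter sets.

    The table must carry the columns ``disease, age_group, theta,
    theta_se, alpha, mu, nu`` (the layout of the public GEMM fit tables);
    unknown columns are ignored.  An optional ``cmin`` column overrides
    the default threshold row-wise.
    """
    # round_trip parsing so write-then-read reproduces values bit-exactly
    df = pd.read_csv(source, sep=sep, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing required columns: {missing}")
    out: list[GEMMParamSet] = []
    seen: set[tuple[str, str]] = set()
    for idx, row in df.iterrows():
        key = (str(row["disease"]), str(row["age_group"]))
        if key in seen:
            raise FormatError(f"duplicate (disease, age_group) {key} at row {idx}")
        seen.add(key)
        kwargs = {}
        for col in ("theta", "theta_se", "alpha", "mu", "nu"):
            try:
                kwargs[col] = float(row[col])
            except (TypeError, ValueError) as exc:
                raise FormatError(f"non-numeric {col}={row[col]!r} at row {idx}") from exc
        row_cmin = cmin
        if "cmin" in df.columns and pd.notna(row["cmin"]):
            row_cmin = float(row["cmin"])
        try:
            out.append(GEMMParamSet(disease=key[0], age_group=key[1], cmin=row_cmin, **kwargs))
        except InputError as exc:
            raise FormatError(f"invalid parameters at row {idx}: {exc}") from exc
    return out


def write_gemm_params(params: Iterable[GEMMParamSet], path, sep: str = ",") -> None:
    """Write parameter sets as a delimited table (round-trips bit-exactly)."""
    rows = [
        {
            "disease": p.disease,
            "age_group": p.age_group,
            "theta": p.theta,
            "theta_se": p.theta_se,
            "alpha": p.alpha,
            "mu": p.mu,
            "nu": p.nu,
            "cmin": p.cmin,
        }
        for p in params
    ]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False, float_format="%.17g")


def params_by_key(params: Iterable[GEMMParamSet]) -> dict[tuple[str, str], GEMMParamSet]:
    """Index parameter sets by (disease, age_group); duplicates rejected."""
    out: dict[tuple[str, str], GEMMParamSet] = {}
    for p in params:
        if p.key in out:
            raise FormatError(f"duplicate (disease, age_group) {p.key}")
        out[p.key] = p
    return out


def lookup_params(params: Sequence[GEMMParamSet], disease: str, age_group: str) -> GEMMParamSet:
    for p in params:
        if p.disease == disease and p.age_group == age_group:
            return p
    raise ParameterLookupError(f"no GEMM parameters for ({disease!r}, {age_group!r})")
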