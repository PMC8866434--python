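import numpy as np
import pytest

from cobenefits import ConcentrationField, GEMMParamSet, PopulationField
from cobenefits.exposure_grid import unit_edges


@pytest.fixture
def params():
    """A hand-checkable parameter set: at c = 12.4 the logistic term is
    exactly 1/2, so RR = exp(theta * ln(6) / 2)."""
    return GEMMParamSet(
        disease="NCD+LRI", age_group="25-29", theta=0.1, theta_se=0.01, alpha=2.0, mu=10.0, nu=5.0
    )


def make_fields(conc_values, pop_counts, age_groups=("25-29",)):
    """Co-registered fields on unit-degree edges from plain nested lists."""
    conc_values = np.asarray(conc_values, dtype=float)
    pop_counts = np.asarray(pop_counts, dtype=float)
    if pop_counts.ndim == 2:
        pop_counts = pop_counts[None, :, :]
    n_lat, n_lon = conc_values.shape
    lat, lon = unit_edges(n_lat), unit_edges(n_lon)
    conc = ConcentrationField(conc_values, lat, lon, scenario_label="test", year=2050)
    pop = PopulationField(pop_counts, list(age_groups), lat, lon)
    return conc, pop


@pytest.fixture
def two_cell_fields():
    """Two cells at 2.4 and 12.4 ug/m3 with equal single-age population."""
    return make_fields([[2.4, 12.4]], [[1.0, 1.0]])
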