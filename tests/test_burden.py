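import math

import numpy as np
import pandas as pd
import pytest

from cobenefits import (
    GEMMParamSet,
    IncidenceTable,
    aggregate_burden,
    attributable_mortality,
    avoided_mortality,
    relative_risk,
    underlying_incidence,
)
from cobenefits.burden import CI_NOTE, read_burden, validate_burden, write_burden
from cobenefits.errors import AlignmentError, ConfigurationError, FormatError, InputError

from _oracles import brute_force_burden, gemm_rr_oracle
from conftest import make_fields


def single_age_inputs(conc_values, pop_values, i_rate=0.01, **param_overrides):
    conc, pop = make_fields(conc_values, pop_values)
    kwargs = dict(
        disease="NCD+LRI", age_group="25-29", theta=0.1, theta_se=0.01, alpha=2.0, mu=10.0, nu=5.0
    )
    kwargs.update(param_overrides)
    p = GEMMParamSet(**kwargs)
    inc = IncidenceTable({("NCD+LRI", "25-29"): i_rate})
    return conc, pop, inc, [p]


class TestUnderlyingIncidence:
    def test_no_risk_leaves_rate_unchanged(self):
        assert underlying_incidence(0.01, 1.0) == 0.01

    def test_zero_rate(self):
        assert underlying_incidence(0.0, 1.7) == 0.0

    def test_division(self):
        assert underlying_incidence(0.01, 1.5) == pytest.approx(0.0066667, abs=5e-8)

    def test_mean_rr_below_one_rejected(self):
        with pytest.raises(InputError):
            underlying_incidence(0.01, 0.9)


class TestAttributableMortality:
    def test_uniform_field_paf_identity(self):
        # spatially uniform exposure collapses the grid sum to the
        # attributable-fraction identity M = P * I * (RR - 1) / RR
        c, p_total, i_rate = 40.0, 123456.0, 0.008
        conc, pop, inc, params = single_age_inputs(
            np.full((3, 4), c), np.full((3, 4), p_total / 12.0), i_rate=i_rate
        )
        rr = relative_risk(c, params[0])
        expected = p_total * i_rate * (rr - 1.0) / rr
        got = attributable_mortality(conc, pop, inc, params)["deaths_mean"].iloc[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_single_cell_hand_arithmetic(self):
        # choose theta so that RR = 1.5 exactly at 12.4 ug/m3, then
        # M = 1000 * 0.01 * 0.5 / 1.5 = 10/3 deaths
        theta = math.log(1.5) / (math.log(6.0) * 0.5)
        conc, pop, inc, params = single_age_inputs([[12.4]], [[1000.0]], i_rate=0.01, theta=theta)
        got = attributable_mortality(conc, pop, inc, params)["deaths_mean"].iloc[0]
        assert got == pytest.approx(10.0 / 3.0, rel=1e-12)
        assert got == pytest.approx(3.3333, abs=5e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_unvectorized_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        c = rng.lognormal(math.log(40), 0.6, (20, 20))
        p = rng.uniform(0, 1e5, (20, 20))
        theta, alpha, mu, nu = rng.uniform(0.05, 0.3), rng.uniform(1, 20), rng.uniform(5, 30), rng.uniform(1, 50)
        conc, pop, inc, params = single_age_inputs(
            c, p, i_rate=0.012, theta=theta, theta_se=0.1 * theta, alpha=alpha, mu=mu, nu=nu
        )
        table = attributable_mortality(conc, pop, inc, params)
        for col, th in (
            ("deaths_mean", theta),
            ("deaths_low", theta - 1.96 * 0.1 * theta),
            ("deaths_high", theta + 1.96 * 0.1 * theta),
        ):
            expected = brute_force_burden(c.ravel(), p.ravel(), 0.012, th, alpha, mu, nu)
            assert table[col].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_zero_burden_below_threshold(self):
        conc, pop, inc, params = single_age_inputs([[1.0, 2.4]], [[10.0, 20.0]])
        table = attributable_mortality(conc, pop, inc, params)
        assert (table[["deaths_mean", "deaths_low", "deaths_high"]] == 0).all().all()

    def test_ci_brackets_mean_and_collapses_at_zero_se(self):
        conc, pop, inc, params = single_age_inputs([[30.0, 60.0]], [[1e4, 2e4]])
        row = attributable_mortality(conc, pop, inc, params).iloc[0]
        assert row["deaths_low"] < row["deaths_mean"] < row["deaths_high"]
        conc, pop, inc, params = single_age_inputs([[30.0, 60.0]], [[1e4, 2e4]], theta_se=0.0)
        row = attributable_mortality(conc, pop, inc, params).iloc[0]
        assert row["deaths_low"] == row["deaths_mean"] == row["deaths_high"]

    def test_monotone_in_uniform_concentration_scaling(self):
        rng = np.random.default_rng(9)
        c = rng.uniform(10, 60, (5, 5))  # everywhere above threshold
        p = rng.uniform(0, 1e4, (5, 5))
        totals = []
        for k in (1.0, 1.2, 1.5, 2.0):
            conc, pop, inc, params = single_age_inputs(c * k, p)
            totals.append(attributable_mortality(conc, pop, inc, params)["deaths_mean"].iloc[0])
        assert all(a <= b + 1e-12 for a, b in zip(totals, totals[1:]))

    def test_population_scaling_is_linear(self):
        rng = np.random.default_rng(11)
        c = rng.uniform(5, 80, (4, 4))
        p = rng.uniform(0, 1e4, (4, 4))
        conc, pop, inc, params = single_age_inputs(c, p)
        base = attributable_mortality(conc, pop, inc, params)["deaths_mean"].iloc[0]
        conc3, pop3, _, _ = single_age_inputs(c, 3.0 * p)
        tripled = attributable_mortality(conc3, pop3, inc, params)["deaths_mean"].iloc[0]
        assert tripled == pytest.approx(3.0 * base, rel=1e-12)

    def test_missing_incidence_is_configuration_error(self):
        conc, pop, inc, params = single_age_inputs([[30.0]], [[10.0]])
        empty = IncidenceTable({("NCD+LRI", "85+"): 0.1})
        with pytest.raises(ConfigurationError):
            attributable_mortality(conc, pop, empty, params)

    def test_ci_note_metadata_attached(self):
        conc, pop, inc, params = single_age_inputs([[30.0]], [[10.0]])
        table = attributable_mortality(conc, pop, inc, params)
        assert table.attrs["ci_note"] == CI_NOTE


class TestAvoidedMortality:
    def _burden(self, c_values, scenario):
        conc, pop, inc, params = single_age_inputs(c_values, [[1e4, 1e4]])
        return attributable_mortality(conc, pop, inc, params, scenario=scenario, year=2050)

    def test_identical_tables_give_zero(self):
        ref = self._burden([[30.0, 60.0]], "REF")
        diff = avoided_mortality(ref, self._burden([[30.0, 60.0]], "RCP"))
        assert (diff[["deaths_mean", "deaths_low", "deaths_high"]] == 0).all().all()

    def test_sign_and_antisymmetry(self):
        ref = self._burden([[30.0, 60.0]], "REF")
        pol = self._burden([[27.0, 54.0]], "RCP")
        fwd = avoided_mortality(ref, pol)
        bwd = avoided_mortality(pol, ref)
        assert fwd["deaths_mean"].iloc[0] > 0
        assert fwd["deaths_mean"].iloc[0] == pytest.approx(-bwd["deaths_mean"].iloc[0], rel=1e-14)

    def test_key_mismatch_lists_unmatched(self):
        ref = self._burden([[30.0, 60.0]], "REF")
        pol = self._burden([[27.0, 54.0]], "RCP").assign(age_group="85+")
        with pytest.raises(AlignmentError, match="85\\+"):
            avoided_mortality(ref, pol)


class TestAggregation:
    @pytest.fixture
    def table(self):
        rows = []
        for disease in ("NCD", "LRI"):
            for age in ("25-29", "65-69"):
                for region, d in (("east", 10.0), ("west", 20.0)):
                    rows.append(
                        {
                            "scenario": "REF",
                            "year": 2030,
                            "disease": disease,
                            "age_group": age,
                            "region": region,
                            "deaths_mean": d,
                            "deaths_low": d / 2,
                            "deaths_high": 2 * d,
                        }
                    )
        return pd.DataFrame(rows)

    def test_grand_total_invariant_under_grouping(self, table):
        total = aggregate_burden(table)["deaths_mean"].sum()
        for by in ([], ["disease"], ["age_group"], ["region"], ["disease", "age_group", "region"]):
            assert aggregate_burden(table, by)["deaths_mean"].sum() == pytest.approx(total)

    def test_group_by_nothing_yields_single_total_row(self, table):
        out = aggregate_burden(table)
        assert len(out) == 1
        assert out["deaths_mean"].iloc[0] == pytest.approx(120.0)
        assert out["age_group"].iloc[0] == "all"

    def test_two_age_groups_sum(self):
        df = pd.DataFrame(
            {
                "scenario": ["REF", "REF"],
                "year": [2030, 2030],
                "disease": ["NCD", "NCD"],
                "age_group": ["25-29", "30-34"],
                "region": ["national", "national"],
                "deaths_mean": [10.0, 20.0],
                "deaths_low": [8.0, 16.0],
                "deaths_high": [12.0, 24.0],
            }
        )
        out = aggregate_burden(df, ["disease"])
        assert out["deaths_mean"].iloc[0] == 30.0

    def test_unknown_grouping_key_rejected(self, table):
        with pytest.raises(ConfigurationError):
            aggregate_burden(table, ["province"])


class TestBurdenIO:
    def test_round_trip_and_validation(self, tmp_path):
        conc, pop, inc, params = single_age_inputs([[30.0, 60.0]], [[1e4, 2e4]])
        table = attributable_mortality(conc, pop, inc, params, scenario="REF", year=2050)
        path = tmp_path / "burden.csv"
        write_burden(table, path)
        back = read_burden(path)
        pd.testing.assert_frame_equal(back, table, check_dtype=False)
        assert back.attrs["ci_note"] == CI_NOTE

    def test_write_refuses_invalid_table(self, tmp_path):
        bad = pd.DataFrame(
            {
                "scenario": ["REF"],
                "year": [2050],
                "disease": ["NCD"],
                "age_group": ["25-29"],
                "region": ["national"],
                "deaths_mean": [10.0],
                "deaths_low": [11.0],  # low above mean
                "deaths_high": [12.0],
            }
        )
        with pytest.raises(InputError):
            write_burden(bad, tmp_path / "bad.csv")
        with pytest.raises(FormatError):
            validate_burden(bad.drop(columns=["region"]))
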