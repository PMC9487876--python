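import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thetagrow import (
    CensusSeries,
    ThetaLogisticParams,
    UndefinedRateError,
    build_default_design,
    growth_table,
    interval_growth_rate,
    intrinsic_rate,
    intrinsic_rate_table,
    simulate_study,
    theta_logistic_growth,
)
from thetagrow.design import SimulationParams


def _series(days, counts, **kw):
    kw.setdefault("clone_id", "c1")
    kw.setdefault("group", "post")
    kw.setdefault("population_id", "p1")
    return CensusSeries(days=days, counts=counts,
                        biomass=tuple(c * 0.05 for c in counts), **kw)


class TestIntervalGrowthRate:
    @pytest.mark.parametrize(
        "n0, n1, d, expected",
        [
            (10, 10, 8, 0.0),
            (20, 10, 8, -0.0866433976),   # ln(1/2)/8
            (1, 18, 18, 0.1605762088),    # ln(18)/18
        ],
    )
    def test_examples(self, n0, n1, d, expected):
        assert interval_growth_rate(n0, n1, d) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("args", [(0, 5, 8), (5, 0, 8), (5, 5, 0), (-1, 5, 8)])
    def test_undefined_rate(self, args):
        with pytest.raises(UndefinedRateError):
            interval_growth_rate(*args)

    @given(
        ns=st.lists(st.floats(0.1, 1e4), min_size=3, max_size=8),
        d=st.floats(0.5, 30.0),
        c=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_properties(self, ns, d, c):
        """Telescoping over intervals, antisymmetry under swapping the
        endpoints, and invariance to rescaling both abundances."""
        total = sum(interval_growth_rate(a, b, d) * d for a, b in zip(ns, ns[1:]))
        assert total == pytest.approx(math.log(ns[-1] / ns[0]), abs=1e-7)
        g = interval_growth_rate(ns[0], ns[1], d)
        assert interval_growth_rate(ns[1], ns[0], d) == pytest.approx(-g, abs=1e-12)
        assert interval_growth_rate(c * ns[0], c * ns[1], d) == pytest.approx(
            g, abs=max(1e-9, 1e-7 * abs(g)))


class TestIntrinsicRate:
    def test_formula(self):
        series = _series((0.0, 9.0, 18.0), (1.0, 5.0, 18.0))
        est = intrinsic_rate(series, "numerical")
        assert est.r == pytest.approx(math.log(18.0) / 18.0, abs=1e-12)
        assert est.d == 18.0

    def test_no_change_gives_zero(self):
        est = intrinsic_rate(_series((0.0, 11.0, 19.0), (1.0, 2.0, 1.0)))
        assert est.r == 0.0

    def test_extinct_population_marked_missing(self):
        est = intrinsic_rate(_series((0.0, 11.0, 19.0), (1.0, 2.0, 0.0)))
        assert est.r is None and est.d is None

    def test_uses_actual_elapsed_days(self):
        # irregular schedule (e.g. a delayed census): d follows the dates
        est = intrinsic_rate(_series((0.0, 11.0, 25.0), (1.0, 3.0, 10.0)))
        assert est.d == 25.0
        assert est.r == pytest.approx(math.log(10.0) / 25.0)


@pytest.fixture(scope="module")
def noise_free_study():
    design = build_default_design().with_(
        clones_per_group={"pre": 2, "post": 2}, populations_per_clone=2
    )
    params = SimulationParams(
        group_params={
            "post": ThetaLogisticParams(r=0.16, K=50.88, theta=0.38),
            "pre": ThetaLogisticParams(r=0.13, K=39.99, theta=0.38),
        },
        demographic_stochasticity=False,
    )
    return design, params, simulate_study(design, params, seed=0)


class TestGrowthTable:
    def test_observation_count_after_skip(self, noise_free_study):
        """10 censuses minus the 2-census r window leave 7 consecutive
        pairs per surviving population."""
        _, _, census = noise_free_study
        growth = growth_table(census, "numerical", skip_through_census=2)
        per_pop = growth.groupby(["clone_id", "population_id"]).size()
        assert (per_pop == 7).all()

    def test_noise_free_growth_matches_model(self, noise_free_study):
        """Without noise every G must equal r(1-(N/K)^theta) evaluated at
        the interval-start density — the generator and the fitted model
        are the same curve."""
        design, params, census = noise_free_study
        growth = growth_table(census, "numerical", skip_through_census=0)
        for _, row in growth.iterrows():
            gp = params.group_params[row["group"]]
            assert row["G"] == pytest.approx(
                theta_logistic_growth(gp, row["N_start"]), abs=1e-10)

    def test_zero_intervals_dropped(self):
        days = [0.0, 11.0, 19.0, 27.0, 35.0, 43.0]
        counts = [1.0, 4.0, 9.0, 12.0, 0.0, 0.0]
        census = _series(tuple(days), tuple(counts)).to_frame()
        growth = growth_table(census, "numerical", skip_through_census=0)
        # pairs (11,19) and (19,27) usable; anything touching 0 is gone
        assert (growth["N_start"] > 0).all()
        assert growth["day_start"].tolist() == [11.0, 19.0]

    def test_irregular_interval_duration(self):
        census = _series((0.0, 11.0, 19.0, 41.0), (1.0, 3.0, 9.0, 30.0)).to_frame()
        growth = growth_table(census, "numerical", skip_through_census=0)
        assert growth["d"].tolist() == [8.0, 22.0]

    def test_biomass_measure(self, small_study):
        census, _ = small_study
        growth = growth_table(census, "biomass", skip_through_census=2)
        assert (growth["measure"] == "biomass").all()
        assert (growth["N_start"] > 0).all()


def test_intrinsic_rate_table_matches_per_series(small_study):
    census, _ = small_study
    table = intrinsic_rate_table(census, "numerical")
    assert len(table) == census.groupby(["clone_id", "population_id"]).ngroups
    row = table.iloc[0]
    sub = census[(census["clone_id"] == row["clone_id"])
                 & (census["population_id"] == row["population_id"])]
    sub = sub.sort_values("day")
    expected = math.log(sub["count"].iloc[2] / sub["count"].iloc[0]) / sub["day"].iloc[2]
    assert row["r"] == pytest.approx(expected)
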