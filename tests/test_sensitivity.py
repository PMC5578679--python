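"""One-way analysis, triangular sampling, and the probabilistic analysis."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

import depscreen_cea as d
from depscreen_cea.cea import DOMINANT
from depscreen_cea.sensitivity import ONE_WAY_PARAMETERS, Incremental, _incremental


def test_triangular_degenerate_distribution():
    tri = d.TriangularParam(2.0, 2.0, 2.0)
    for u in (0.0, 0.3, 1.0):
        assert d.sample_triangular(tri, u) == 2.0


def test_triangular_mode_at_its_cdf_value():
    tri = d.TriangularParam(1.0, 3.0, 7.0)
    u_mode = (tri.base - tri.low) / (tri.high - tri.low)
    assert d.sample_triangular(tri, u_mode) == pytest.approx(tri.base)
    assert d.sample_triangular(tri, 0.0) == tri.low
    assert d.sample_triangular(tri, 1.0) == pytest.approx(tri.high)


def test_triangular_sample_mean_matches_closed_form():
    tri = d.TriangularParam(0.0, 2584.0, 2584.0)
    rng = np.random.default_rng(0)
    draws = [d.sample_triangular(tri, u) for u in rng.random(40_000)]
    expected = (tri.low + tri.base + tri.high) / 3.0
    assert np.mean(draws) == pytest.approx(expected, rel=0.01)


@pytest.mark.parametrize("u", [0.05, 0.25, 0.5, 0.75, 0.95])
def test_triangular_matches_scipy_inverse_cdf(u):
    low, base, high = 0.42, 0.52, 0.62
    ref = stats.triang.ppf(u, c=(base - low) / (high - low), loc=low, scale=high - low)
    assert d.sample_triangular(d.TriangularParam(low, base, high), u) == pytest.approx(ref)


def test_triangular_rejects_bad_quantile():
    with pytest.raises(ValueError):
        d.sample_triangular(d.TriangularParam(0.0, 1.0, 2.0), 1.5)


@pytest.mark.parametrize("name", ONE_WAY_PARAMETERS)
def test_one_way_at_base_reproduces_base_case(params, schedule, name, base_results):
    """Re-running the model with a parameter overridden to its current value
    must reproduce the base-case increments exactly."""
    if name == "productivity_age_cap":
        value = params.productivity_age_cap
    elif name in ("phq2_cutoff", "phq9_cutoff"):
        value = (params.phq2 if name == "phq2_cutoff" else params.phq9).cutoff
    else:
        value = params.triangulars[name].base
    by_key = {r.strategy.key: r for r in base_results}
    base_dc = by_key[4].discounted_cost - by_key[1].discounted_cost
    base_de = by_key[4].discounted_qalys - by_key[1].discounted_qalys
    at_base = _incremental(d.with_override(params, name, value), schedule)
    assert at_base.delta_cost == base_dc
    assert at_base.delta_qalys == base_de


def test_one_way_removing_productivity_raises_icer(params, schedule):
    res = d.one_way(params, schedule, "c_productivity_total")
    assert res.at_low.icer > res.base.icer  # productivity = 0 at the low bound
    assert res.at_high.delta_cost == pytest.approx(res.base.delta_cost)


def test_one_way_cheap_collaborative_care_is_cost_saving(params, schedule):
    res = d.one_way(params, schedule, "c_treatment_cc")
    assert res.at_low.delta_cost < 0
    assert res.at_low.icer == DOMINANT
    assert res.at_high.icer > res.base.icer


def test_one_way_unknown_parameter(params, schedule):
    with pytest.raises(KeyError):
        d.one_way(params, schedule, "not_a_parameter")


def test_one_way_table_shape(params, schedule):
    table = d.one_way_table(params, schedule, names=("c_treatment_cc", "phq2_cutoff"))
    assert list(table["parameter"]) == ["c_treatment_cc", "phq2_cutoff"]
    assert {"inc_cost_high", "icer_low"} <= set(table.columns)


def _degenerate(params):
    tris = {
        name: d.TriangularParam(tri.base, tri.base, tri.base)
        for name, tri in params.triangulars.items()
    }
    return dataclasses.replace(params, triangulars=tris)


def test_degenerate_psa_equals_base_case(params, schedule, base_results):
    """With every distribution collapsed to its mode, each draw reproduces
    the base case: the interval collapses, the CEAC is a step at the base
    ICER, and the EVPI is identically zero."""
    psa = d.run_psa(_degenerate(params), schedule, n_draws=20, seed=5)
    by_key = {r.strategy.key: r for r in base_results}
    base_dc = by_key[4].discounted_cost - by_key[1].discounted_cost
    base_de = by_key[4].discounted_qalys - by_key[1].discounted_qalys
    assert np.allclose(psa.draws["delta_cost"], base_dc, atol=1e-9)
    assert np.allclose(psa.draws["delta_qalys"], base_de, atol=1e-12)
    lower, upper = psa.plausible_interval
    assert lower.icer == pytest.approx(upper.icer)
    assert lower.icer == pytest.approx(base_dc / base_de)
    base_icer = base_dc / base_de
    ceac = psa.ceac
    assert (ceac.loc[ceac["wtp"] > base_icer, "p_cost_effective"] == 1.0).all()
    assert (ceac.loc[ceac["wtp"] < base_icer, "p_cost_effective"] == 0.0).all()
    assert np.allclose(psa.evpi["evpi"], 0.0, atol=1e-8)


def test_psa_reproducible_under_seed(params, flat_schedule):
    a = d.run_psa(params, flat_schedule, n_draws=40, seed=123)
    b = d.run_psa(params, flat_schedule, n_draws=40, seed=123)
    assert a.draws.equals(b.draws)
    assert a.ceac.equals(b.ceac) and a.evpi.equals(b.evpi)


def test_psa_draw_bookkeeping(params, flat_schedule, tmp_path):
    psa = d.run_psa(params, flat_schedule, n_draws=30, seed=9)
    assert psa.n_draws == 30
    assert {"cost_1", "qalys_5", "delta_cost"} <= set(psa.draws.columns)
    # probability draws stay in [0, 1]
    for col in ("p_adequate_cc", "se_phq2", "u_depressed"):
        assert psa.draws[col].between(0, 1).all()
    table = d.export_scatter(psa, tmp_path / "scatter.csv")
    assert len(table) == 30
    assert (tmp_path / "scatter.csv").exists()


def test_psa_rejects_bad_arguments(params, flat_schedule):
    with pytest.raises(ValueError):
        d.run_psa(params, flat_schedule, n_draws=0, seed=1)
    with pytest.raises(d.UnknownParameterError):
        d.run_psa(params, flat_schedule, n_draws=2, seed=1, sampled=["nope"])


def test_ceac_is_one_when_every_draw_is_cost_saving():
    """Construct increments that always save money and gain QALYs."""
    dc = np.array([-10.0, -5.0, -1.0])
    de = np.array([0.1, 0.2, 0.3])
    for wtp in (0.0, 10_000.0):
        assert np.mean(wtp * de - dc > 0) == 1.0


def test_evpi_nonnegative(params, flat_schedule):
    psa = d.run_psa(params, flat_schedule, n_draws=60, seed=2)
    assert (psa.evpi["evpi"] >= 0).all()
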