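"""PD units: algebraic identities, graph rules, link dynamics, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsim.assembly import assemble
from popsim.engine import integrate
from popsim.errors import GraphError, ValidationError
from popsim.pdmodels import (
    direct_response,
    evaluate_long,
    operational_response,
    time_summary,
    validate_graph,
)
from popsim.population import representative_individual
from popsim.workspace import (
    CompoundModel,
    DoseEvent,
    ModelSelection,
    PDGraph,
    PDUnit,
    SolverSettings,
)

from conftest import degenerate_population, linear_compound

IND = representative_individual(degenerate_population())
TIGHT = SolverSettings(method="rk5", rtol=1e-10, atol=1e-13)


# -- direct responses --------------------------------------------------------

def test_emax_half_maximal_at_ec50():
    p = {"e0": 2.0, "emax": 8.0, "ec50": 3.0}
    assert direct_response("emax", 3.0, p) == pytest.approx(2.0 + 4.0)


def test_baseline_at_zero_concentration():
    for model, params in [
        ("linear", {"e0": 1.5, "slope": 2.0}),
        ("emax", {"e0": 1.5, "emax": 5.0, "ec50": 2.0}),
        ("sigmoid_emax", {"e0": 1.5, "emax": 5.0, "ec50": 2.0, "n": 3.0}),
    ]:
        assert direct_response(model, 0.0, params) == pytest.approx(1.5)


def test_steep_hill_saturates_above_ec50():
    p = {"e0": 0.0, "emax": 10.0, "ec50": 1.0, "n": 20.0}
    response = direct_response("sigmoid_emax", 2.0, p)
    assert response == pytest.approx(10.0, rel=1e-3)  # within 0.1% of E0+Emax


def test_nonpositive_ec50_rejected():
    with pytest.raises(ValidationError):
        direct_response("emax", 1.0, {"emax": 1.0, "ec50": 0.0})


@given(st.floats(0.0, 1e3), st.floats(0.0, 1e3))
@settings(max_examples=100, deadline=None)
def test_direct_response_monotone_in_concentration(c1, c2):
    """Positive-Emax responses are nondecreasing in concentration."""
    lo, hi = sorted((c1, c2))
    p = {"e0": 0.5, "emax": 4.0, "ec50": 2.5, "n": 2.0}
    assert direct_response("sigmoid_emax", lo, p) <= direct_response("sigmoid_emax", hi, p) + 1e-12


# -- operational agonism -----------------------------------------------------

def test_operational_full_agonist_limit():
    p = {"em": 7.0, "ka": 2.0, "tau": 1e9, "n": 1.0}
    assert operational_response(5.0, p) == pytest.approx(7.0, rel=1e-6)


def test_operational_zero_concentration():
    assert operational_response(0.0, {"em": 7.0, "ka": 2.0, "tau": 3.0}) == 0.0


def test_operational_half_maximal_condition_n1():
    """For n = 1, E = Em/2 exactly where τC = KA + C."""
    ka, tau = 2.0, 3.0
    c_half = ka / (tau - 1.0)
    assert operational_response(c_half, {"em": 6.0, "ka": ka, "tau": tau}) == pytest.approx(3.0)


def test_operational_reduces_to_emax_for_n1():
    """Algebraic identity: n=1 operational ≡ Emax with Emax = Em·τ/(1+τ),
    EC50 = KA/(1+τ), checked over a wide concentration grid."""
    em, ka, tau = 5.0, 1.7, 2.4
    C = np.linspace(0.0, 50.0, 100)
    operational = operational_response(C, {"em": em, "ka": ka, "tau": tau, "n": 1.0})
    emax_form = direct_response(
        "emax", C, {"emax": em * tau / (1 + tau), "ec50": ka / (1 + tau)}
    )
    assert np.max(np.abs(operational - emax_form)) < 1e-10


# -- graph validation --------------------------------------------------------

def _unit(uid, input_, kind="basic", model="emax", **params):
    defaults = {"emax": 1.0, "ec50": 1.0}
    defaults.update(params)
    return PDUnit(uid, kind, model, input_, defaults)


def test_chain_orders_topologically():
    g = PDGraph(units=(
        _unit("b", "pk:drug"),
        PDUnit("l", "link", "effect_compartment", "unit:b", {"ke0": 1.0}),
    ))
    assert validate_graph(g) == ["b", "l"]


def test_cycle_rejected_with_unit_ids():
    g = PDGraph(units=(_unit("a", "unit:b"), _unit("b", "unit:a")))
    with pytest.raises(GraphError, match="cycle"):
        validate_graph(g)


def test_fan_out_rejected_as_unsupported_motif():
    g = PDGraph(units=(
        _unit("src", "pk:drug"),
        _unit("d1", "unit:src"),
        _unit("d2", "unit:src"),
    ))
    with pytest.raises(GraphError, match="splitting is unsupported"):
        validate_graph(g)


def test_long_timescale_requires_summary_input():
    g = PDGraph(units=(
        _unit("b", "pk:drug"),
        PDUnit("s", "link", "survival", "unit:b", {"h0": 0.1}, timescale="long"),
    ))
    with pytest.raises(GraphError, match="time-independent"):
        validate_graph(g)


# -- link dynamics in the assembled system -----------------------------------

def _simulate_pd(units, doses, horizon=100.0, n=201):
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="iv", distribution="one_compartment",
                              elimination=frozenset({"linear_cl"}))})
    system = assemble(sel, [linear_compound()], PDGraph(units=tuple(units)))
    obs = np.linspace(0.0, horizon, n)
    return integrate(system, doses, IND, TIGHT, obs), obs


def test_indirect_response_baseline_stability():
    """Without drug the turnover state holds kin/kout to 1e-8 for 100 h."""
    unit = PDUnit("r", "link", "indirect_1", "pk:drug",
                  {"kin": 4.0, "kout": 0.5, "imax": 0.9, "ic50": 1.0})
    ps, _ = _simulate_pd([unit], doses=[])
    response = ps.observable("PD_r")
    assert np.max(np.abs(response - 8.0)) < 1e-8


def test_effect_compartment_equilibrates_to_constant_concentration():
    """Under a maintained infusion Ce approaches the plateau C."""
    unit = PDUnit("ce", "link", "effect_compartment", "pk:drug", {"ke0": 2.0})
    dose = DoseEvent(0.0, "drug", "iv_infusion", 2000.0, infusion_duration=200.0)
    ps, obs = _simulate_pd([unit], [dose], horizon=100.0)
    c = ps.observable("C_drug")
    ce = ps.observable("PD_ce")
    assert ce[-1] == pytest.approx(c[-1], rel=1e-4)


def test_survival_constant_hazard_closed_form():
    """β = 0, h0 = 0.1/h → S(10 h) = e^(−1)."""
    unit = PDUnit("s", "link", "survival", "pk:drug", {"h0": 0.1, "beta": 0.0})
    ps, obs = _simulate_pd([unit], doses=[], horizon=10.0, n=101)
    s = ps.observable("PD_s")
    assert s[-1] == pytest.approx(np.exp(-1.0), rel=1e-6)
    assert np.all((s > 0) & (s <= 1.0))
    assert np.all(np.diff(s) <= 1e-15)  # nonincreasing


def test_indirect_inhibition_of_loss_raises_response():
    unit = PDUnit("r", "link", "indirect_2", "pk:drug",
                  {"kin": 4.0, "kout": 0.5, "imax": 0.5, "ic50": 0.5})
    dose = DoseEvent(0.0, "drug", "iv_infusion", 4000.0, infusion_duration=400.0)
    ps, _ = _simulate_pd([unit], [dose], horizon=200.0)
    r = ps.observable("PD_r")
    assert r[-1] > 8.0  # above the drug-free baseline kin/kout


def test_transduction_chain_occupancy_then_operational():
    """Two connected basic units in operational mode reproduce the one-step
    operational response of the driving concentration."""
    em, ka, tau = 4.0, 1.5, 2.0
    upstream = PDUnit("occ", "basic", "occupancy", "pk:drug", {"ka": ka},
                      transduction="operational")
    downstream = PDUnit("resp", "basic", "operational", "unit:occ",
                        {"em": em, "tau": tau, "n": 1.0}, transduction="operational")
    ps, obs = _simulate_pd([upstream, downstream],
                           [DoseEvent(0.0, "drug", "iv_bolus", 100.0)], horizon=24.0)
    c = ps.observable("C_drug")
    expected = operational_response(c, {"em": em, "ka": ka, "tau": tau, "n": 1.0})
    np.testing.assert_allclose(ps.observable("PD_resp"), expected, rtol=1e-9)


# -- time summaries ----------------------------------------------------------

def test_summary_constant_profile():
    t = np.linspace(0.0, 10.0, 21)
    profile = np.full_like(t, 3.0)
    assert time_summary(t, profile, "auc") == pytest.approx(30.0)
    assert time_summary(t, profile, "cmax") == pytest.approx(3.0)
    assert time_summary(t, profile, "mean") == pytest.approx(3.0)


def test_summary_triangular_profile():
    t = np.linspace(0.0, 10.0, 1001)
    profile = np.where(t <= 5.0, 0.8 * t, 4.0 - 0.8 * (t - 5.0))
    assert time_summary(t, profile, "auc") == pytest.approx(20.0, rel=1e-6)
    assert time_summary(t, profile, "value_at(5)") == pytest.approx(4.0)


def test_summary_exponential_auc_closed_form():
    t = np.linspace(0.0, 24.0, 4001)
    profile = 10.0 * np.exp(-0.2 * t)
    expected = 50.0 * (1.0 - np.exp(-4.8))
    assert time_summary(t, profile, "auc") == pytest.approx(expected, rel=1e-3)


def test_value_at_outside_grid_is_range_error():
    t = np.linspace(0.0, 10.0, 11)
    with pytest.raises(ValidationError):
        time_summary(t, t, "value_at(11)")


# -- long timescale ----------------------------------------------------------

def test_long_survival_on_summarised_drive():
    unit = PDUnit("s", "link", "survival", "unit:x", {"h0": 0.01, "beta": 0.5},
                  timescale="long")
    horizon = np.linspace(0.0, 500.0, 11)
    drive = 2.0
    series = evaluate_long(unit, drive, horizon)
    hazard = 0.01 * np.exp(0.5 * drive)
    np.testing.assert_allclose(series, np.exp(-hazard * horizon), rtol=1e-12)
    assert np.all(np.diff(series) < 0)
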