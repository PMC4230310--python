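"""ODE engine: analytic agreement, events, solver consistency, stiffness."""

import numpy as np
import pytest

from popsim.assembly import assemble, register_custom_block
from popsim.engine import expand_regimen, integrate, superposition_check
from popsim.errors import StepBudgetError
from popsim.population import representative_individual
from popsim.workspace import (
    CompoundModel,
    DoseEvent,
    ModelSelection,
    SolverSettings,
    TmddParams,
)

from conftest import bateman, degenerate_population, linear_compound

IND = representative_individual(degenerate_population())
TIGHT = SolverSettings(method="rk5", rtol=1e-8, atol=1e-12)


def iv_system(cl=2.0, v=10.0):
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="iv", distribution="one_compartment",
                              elimination=frozenset({"linear_cl"}))})
    return assemble(sel, [linear_compound(cl=cl, v=v)])


def oral_system(cl=2.0, v=10.0, ka=1.0):
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="first_order", distribution="one_compartment",
                              elimination=frozenset({"linear_cl"}))})
    return assemble(sel, [linear_compound(cl=cl, v=v, ka=ka)])


def test_iv_bolus_matches_mono_exponential():
    obs = np.linspace(0.0, 24.0, 49)
    ps = integrate(iv_system(), [DoseEvent(0.0, "drug", "iv_bolus", 100.0)], IND, TIGHT, obs)
    expected = 10.0 * np.exp(-0.2 * obs)
    np.testing.assert_allclose(ps.observable("C_drug"), expected, rtol=1e-6)
    assert ps.observable("C_drug")[2] == pytest.approx(10.0 * np.exp(-0.2), rel=1e-6)


def test_oral_matches_bateman():
    obs = np.linspace(0.0, 24.0, 49)
    ps = integrate(oral_system(), [DoseEvent(0.0, "drug", "oral", 100.0)], IND, TIGHT, obs)
    np.testing.assert_allclose(
        ps.observable("C_drug")[1:], bateman(obs)[1:], rtol=1e-6
    )


def test_constant_infusion_reaches_steady_state():
    """C_ss = R/CL for a maintained infusion."""
    rate = 10.0  # mg/h over 100 h → amount 1000 mg
    obs = np.linspace(0.0, 100.0, 51)
    ps = integrate(
        iv_system(),
        [DoseEvent(0.0, "drug", "iv_infusion", 1000.0, infusion_duration=100.0)],
        IND, TIGHT, obs,
    )
    c = ps.observable("C_drug")
    assert c[-1] == pytest.approx(rate / 2.0 * (1 - np.exp(-0.2 * 100.0)), rel=1e-6)
    assert c[-1] == pytest.approx(5.0, rel=1e-6)  # R/CL


def test_empty_schedule_zero_profile():
    obs = np.linspace(0.0, 10.0, 11)
    ps = integrate(iv_system(), [], IND, TIGHT, obs)
    assert np.all(ps.subjects[0].states == 0.0)


def test_event_exactness_bolus_jump():
    """States immediately before and after a bolus differ exactly by the
    dosed amount in the target state (dose-before-observation)."""
    obs = np.array([0.0, 5.999999, 6.0, 12.0])
    ps = integrate(iv_system(), [DoseEvent(0.0, "drug", "iv_bolus", 100.0),
                                 DoseEvent(6.0, "drug", "iv_bolus", 100.0)], IND, TIGHT, obs)
    a = ps.subjects[0].states[:, 0]
    pre = 100.0 * np.exp(-0.2 * 6.0)
    assert a[1] == pytest.approx(pre, rel=1e-5)
    assert a[2] == pytest.approx(pre + 100.0, rel=1e-6)  # post-dose convention


def test_rk5_and_lsoda_agree_on_non_stiff_problem():
    obs = np.linspace(0.0, 24.0, 25)
    doses = [DoseEvent(0.0, "drug", "oral", 100.0)]
    rtol = 1e-8
    a = integrate(oral_system(), doses, IND,
                  SolverSettings(method="rk5", rtol=rtol, atol=1e-12), obs)
    b = integrate(oral_system(), doses, IND,
                  SolverSettings(method="lsoda", rtol=rtol, atol=1e-12), obs)
    ref = np.abs(a.observable("C_drug")).max()
    assert np.max(np.abs(a.observable("C_drug") - b.observable("C_drug"))) <= 10 * rtol * ref


def test_grid_invariance_under_max_step():
    obs = np.linspace(0.0, 24.0, 25)
    doses = [DoseEvent(0.0, "drug", "oral", 100.0)]
    a = integrate(oral_system(), doses, IND, TIGHT, obs)
    halved = SolverSettings(method="rk5", rtol=TIGHT.rtol, atol=TIGHT.atol, max_step=0.25)
    b = integrate(oral_system(), doses, IND, halved, obs)
    ref = np.abs(a.observable("C_drug")).max()
    assert np.max(np.abs(a.observable("C_drug") - b.observable("C_drug"))) <= 10 * TIGHT.rtol * ref


def test_step_budget_error_names_time():
    tiny_budget = SolverSettings(method="rk5", rtol=1e-10, atol=1e-14, max_internal_steps=5)
    obs = np.linspace(0.0, 24.0, 5)
    with pytest.raises(StepBudgetError):
        integrate(oral_system(), [DoseEvent(0.0, "drug", "oral", 100.0)], IND, tiny_budget, obs)


def test_multidose_superposition_holds():
    report = superposition_check(
        iv_system(),
        expand_regimen("drug", "iv_bolus", 100.0, 12.0, 3),
        IND, TIGHT, np.linspace(0.0, 48.0, 97),
    )
    assert report["linear"] and report["pass"], report


def test_single_dose_superposition_trivial():
    report = superposition_check(
        iv_system(), [DoseEvent(0.0, "drug", "iv_bolus", 100.0)],
        IND, TIGHT, np.linspace(0.0, 24.0, 25),
    )
    assert report["pass"]


def test_superposition_guard_on_tmdd():
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="iv", distribution="one_compartment",
                              elimination=frozenset({"linear_cl"}), tmdd=True)})
    system = assemble(sel, [linear_compound(tmdd=TmddParams(1.0, 0.1, 0.05, 0.2, 0.1))])
    report = superposition_check(system, [DoseEvent(0.0, "drug", "iv_bolus", 100.0)],
                                 IND, TIGHT, np.linspace(0.0, 24.0, 25))
    assert not report["pass"] and "precondition" in report["reason"]


def test_stiffness_prone_selection_promoted_to_auto():
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="iv", distribution="one_compartment",
                              elimination=frozenset({"linear_cl"}), tmdd=True)})
    system = assemble(sel, [linear_compound(tmdd=TmddParams(1.0, 0.1, 0.05, 0.2, 0.1))])
    with pytest.warns(UserWarning, match="stiff"):
        ps = integrate(system, [DoseEvent(0.0, "drug", "iv_bolus", 100.0)], IND,
                       SolverSettings(method="rk5", rtol=1e-6, atol=1e-9),
                       np.linspace(0.0, 24.0, 13))
    assert ps.solver_log["method"] == "auto"


# stiff three-species benchmark ---------------------------------------------

def _robertson_system():
    """Three coupled species with rate constants spanning nine orders of
    magnitude (0.04, 1e4, 3e7) appended as a custom block to an inert
    carrier system."""
    sel = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="iv", distribution="one_compartment",
                              elimination=frozenset())})
    base = assemble(sel, [linear_compound(cl=0.0)])

    def step(t, full, u, ctx):
        a, b, c = u
        return [
            -0.04 * a + 1.0e4 * b * c,
            0.04 * a - 1.0e4 * b * c - 3.0e7 * b * b,
            3.0e7 * b * b,
        ]

    return register_custom_block(base, 3, step, lambda ctx: [1.0, 0.0, 0.0])


def test_stiff_three_species_auto_within_budget_matches_tight_reference():
    system = _robertson_system()
    obs = np.geomspace(1e-4, 1e3, 25)
    # atol sits well below the smallest species concentration of interest
    # (~1e-8), otherwise the absolute floor dominates the comparison
    run = integrate(system, [], IND,
                    SolverSettings(method="auto", rtol=1e-8, atol=1e-14,
                                   max_internal_steps=20_000), obs)
    ref = integrate(system, [], IND,
                    SolverSettings(method="auto", rtol=1e-12, atol=1e-16,
                                   max_internal_steps=200_000), obs)
    for k in (1, 2, 3):  # the three species states
        a = run.subjects[0].states[:, k]
        b = ref.subjects[0].states[:, k]
        scale = np.maximum(np.abs(b), 1e-10)
        assert np.max(np.abs(a - b) / scale) < 1e-4
    assert run.solver_log["internal_steps"] <= 20_000
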