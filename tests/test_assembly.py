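"""Model assembly: state counting, mechanism composition, mass balance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsim.assembly import assemble, count_states, evaluate_rhs, register_custom_block
from popsim.engine import integrate
from popsim.errors import AssemblyError, ContractError, ValidationError
from popsim.population import representative_individual
from popsim.workspace import (
    CompoundModel,
    DoseEvent,
    MetaboliteSpec,
    ModelSelection,
    PDGraph,
    PDUnit,
    SolverSettings,
    TmddParams,
)

from conftest import degenerate_population, linear_compound

IND = representative_individual(degenerate_population())


def one_compound_selection(**kw) -> ModelSelection:
    defaults = dict(absorption="first_order", distribution="one_compartment",
                    elimination=frozenset({"linear_cl"}))
    defaults.update(kw)
    return ModelSelection(compound_models={"drug": CompoundModel(**defaults)})


# -- state counting ----------------------------------------------------------

def test_minimal_composition_two_states():
    system = assemble(one_compound_selection(), [linear_compound()])
    assert system.n_states == 2
    assert {(e.moiety, e.compartment) for e in system.index_map.entries} == {
        ("drug", "gut"), ("drug", "central")
    }


def test_cat7_minimal_pbpk_is_ten_states():
    """7 transit segments + central/portal/liver."""
    sel = one_compound_selection(absorption="cat", n_transit=7, distribution="minimal_pbpk")
    assert count_states(sel) == 10
    assert assemble(sel, [linear_compound()]).n_states == 10


def test_iv_one_compartment_single_state():
    assert count_states(one_compound_selection(absorption="iv")) == 1


def test_metabolite_adds_one_state():
    base = one_compound_selection(absorption="iv")
    met = one_compound_selection(
        absorption="iv", metabolites=(MetaboliteSpec("m1"),)
    )
    assert count_states(met) == count_states(base) + 1


def test_four_metabolites_rejected():
    mets = tuple(MetaboliteSpec(f"m{i}") for i in range(4))
    with pytest.raises(ValidationError):
        count_states(one_compound_selection(metabolites=mets))


def test_five_compounds_rejected():
    models = {f"c{i}": CompoundModel() for i in range(5)}
    with pytest.raises(ValidationError):
        count_states(ModelSelection(compound_models=models))


def test_missing_mechanism_parameter_names_compound_and_parameter():
    c = linear_compound(clint_per_enzyme={})
    sel = one_compound_selection(elimination=frozenset({"well_stirred_hepatic"}))
    with pytest.raises(AssemblyError, match="drug.*well_stirred_hepatic.*clint"):
        assemble(sel, [c])


def test_tmdd_without_parameters_rejected():
    with pytest.raises(AssemblyError, match="tmdd"):
        assemble(one_compound_selection(tmdd=True), [linear_compound()])


# strictly increasing compositionality ---------------------------------------

def test_compositionality_increments():
    base = one_compound_selection(absorption="cat", n_transit=3)
    n0 = count_states(base)
    more_transit = one_compound_selection(absorption="cat", n_transit=4)
    assert count_states(more_transit) == n0 + 1
    with_met = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="cat", n_transit=3,
                              metabolites=(MetaboliteSpec("m1"),))})
    assert count_states(with_met) == n0 + 1
    with_tmdd = ModelSelection(compound_models={
        "drug": CompoundModel(absorption="cat", n_transit=3, tmdd=True)})
    assert count_states(with_tmdd) == n0 + 2  # free target + complex
    pd_graph = PDGraph(units=(
        PDUnit("ce", "link", "effect_compartment", "pk:drug", {"ke0": 1.0}),
    ))
    assert count_states(base, pd_graph) == n0 + 1


# randomized oracle equivalence ----------------------------------------------

@st.composite
def selections(draw):
    n = draw(st.integers(1, 4))
    models = {}
    for i in range(n):
        absorption = draw(st.sampled_from(["iv", "first_order", "cat"]))
        distribution = draw(st.sampled_from(["one_compartment", "minimal_pbpk", "full_pbpk"]))
        organs = tuple(draw(st.sets(st.sampled_from(["liver", "kidney", "muscle", "brain"]),
                                    min_size=1, max_size=4)))
        mets = tuple(
            MetaboliteSpec(f"c{i}m{j}",
                           disposition=draw(st.sampled_from(["one_compartment", "minimal_pbpk"])))
            for j in range(draw(st.integers(0, 3)))
        )
        models[f"c{i}"] = CompoundModel(
            absorption=absorption,
            n_transit=draw(st.integers(1, 12)),
            distribution=distribution,
            organs=organs if distribution == "full_pbpk" else (),
            elimination=frozenset({"linear_cl"}),
            metabolites=mets,
            tmdd=draw(st.booleans()),
        )
    return ModelSelection(
        compound_models=models,
        track_balance=draw(st.booleans()),
    )


@given(selections())
@settings(max_examples=200, deadline=None)
def test_count_states_matches_assembled_size(sel):
    compounds = [
        linear_compound(name, role="substrate" if i == 0 else f"inhibitor{min(i, 3)}",
                        tmdd=TmddParams(1.0, 0.1, 0.05, 0.2, 0.1))
        for i, name in enumerate(sel.compound_models)
    ]
    system = assemble(sel, compounds)
    assert system.n_states == count_states(sel)


# -- right-hand side ---------------------------------------------------------

def test_zero_state_zero_gradient():
    system = assemble(one_compound_selection(), [linear_compound()])
    dy = evaluate_rhs(system, 0.0, np.zeros(system.n_states), IND)
    assert np.allclose(dy, 0.0)


def test_one_compartment_iv_closed_form_gradient():
    """A = 100 mg, CL = 2 L/h, V = 10 L → dA/dt = −20 mg/h."""
    system = assemble(one_compound_selection(absorption="iv"), [linear_compound(cl=2.0, v=10.0)])
    dy = evaluate_rhs(system, 0.0, np.array([100.0]), IND)
    assert dy[0] == pytest.approx(-20.0)


def test_infusion_term_added():
    system = assemble(one_compound_selection(absorption="iv"), [linear_compound()])
    dy = evaluate_rhs(system, 0.0, np.zeros(1), IND, infusions=[(0, 5.0)])
    assert dy[0] == pytest.approx(5.0)


def test_competitive_inhibition_halves_clint_at_ki():
    """With the inhibitor's unbound site concentration equal to Ki, the
    enzyme's intrinsic-clearance contribution is halved."""
    sub = linear_compound("sub", linear_cl=0.0, clint_per_enzyme={"CYP3A4": 2.0})
    inh = linear_compound("inh", role="inhibitor1", linear_cl=0.0, fu_plasma=1.0,
                          molecular_weight=400.0)
    models = {
        "sub": CompoundModel(absorption="iv", distribution="one_compartment",
                             elimination=frozenset({"well_stirred_hepatic"})),
        "inh": CompoundModel(absorption="iv", distribution="one_compartment",
                             elimination=frozenset()),
    }
    ki = 1.0  # µM
    sel_inh = ModelSelection(compound_models=models,
                             inhibition={"inh": {"CYP3A4": ki}})
    sel_free = ModelSelection(compound_models=models)
    sys_inh = assemble(sel_inh, [sub, inh])
    sys_free = assemble(sel_free, [sub, inh])
    ctx = sys_inh.build_context(IND)
    # inhibitor amount giving exactly Cu = Ki at its site (fu=1):
    # Cu_uM = C_mgL/MW·1000 = Ki → C_mgL = Ki·MW/1000; A = C·V
    v_inh = ctx["compounds"]["inh"]["V_c"]
    a_inh = ki * 400.0 / 1000.0 * v_inh
    i_sub = sys_inh.index_map.index("sub", "central")
    i_inh = sys_inh.index_map.index("inh", "central")
    y = np.zeros(sys_inh.n_states)
    y[i_sub], y[i_inh] = 50.0, a_inh

    clint = ctx["compounds"]["sub"]["clint"]["CYP3A4"]
    fub = ctx["compounds"]["sub"]["fuB"]
    qh = ctx["compounds"]["sub"]["Q_H"]
    c_sub = 50.0 / ctx["compounds"]["sub"]["V_c"]

    def clh(ci):
        return qh * fub * ci / (qh + fub * ci)

    dy_free = evaluate_rhs(sys_free, 0.0, y, IND)
    dy_inh = evaluate_rhs(sys_inh, 0.0, y, IND)
    assert dy_free[i_sub] == pytest.approx(-clh(clint) * c_sub, rel=1e-12)
    assert dy_inh[i_sub] == pytest.approx(-clh(clint / 2.0) * c_sub, rel=1e-12)


def test_infinite_ki_reproduces_uninhibited_trajectory():
    sub = linear_compound("sub", linear_cl=0.0, clint_per_enzyme={"CYP3A4": 2.0})
    inh = linear_compound("inh", role="inhibitor1", linear_cl=1.0)
    models = {
        "sub": CompoundModel(absorption="iv", distribution="one_compartment",
                             elimination=frozenset({"well_stirred_hepatic"})),
        "inh": CompoundModel(absorption="iv", distribution="one_compartment",
                             elimination=frozenset({"linear_cl"})),
    }
    doses = [DoseEvent(0.0, "sub", "iv_bolus", 100.0), DoseEvent(0.0, "inh", "iv_bolus", 500.0)]
    obs = np.linspace(0, 24, 25)
    settings_ = SolverSettings(method="rk5", rtol=1e-8, atol=1e-12)

    def run(sel):
        system = assemble(sel, [sub, inh])
        return integrate(system, doses, IND, settings_, obs).observable("C_sub")

    free = run(ModelSelection(compound_models=models))
    huge_ki = run(ModelSelection(compound_models=models, inhibition={"inh": {"CYP3A4": 1e12}}))
    assert np.allclose(free, huge_ki, rtol=1e-7)


# -- custom block ------------------------------------------------------------

def test_custom_block_duplicating_central_matches_builtin():
    """A user block restating the central-compartment ODE reproduces the
    built-in state's trajectory."""
    c = linear_compound(cl=2.0, v=10.0)
    system = assemble(one_compound_selection(absorption="iv"), [c])
    i_central = system.index_map.index("drug", "central")

    def step(t, full_state, user, ctx):
        cc = ctx["compounds"]["drug"]
        return [-cc["CL_lin"] / cc["V_c"] * user[0]]

    def init(ctx):
        return [100.0]

    extended = register_custom_block(system, 1, step, init)
    assert extended.n_states == system.n_states + 1
    obs = np.linspace(0, 24, 49)
    ps = integrate(extended, [DoseEvent(0.0, "drug", "iv_bolus", 100.0)], IND,
                   SolverSettings(method="rk5", rtol=1e-10, atol=1e-12), obs)
    sp = ps.subjects[0]
    builtin = sp.states[:, i_central]
    user = sp.states[:, -1]
    assert np.allclose(builtin, user, rtol=1e-8, atol=1e-10)


def test_zero_user_states_identity():
    system = assemble(one_compound_selection(), [linear_compound()])
    assert register_custom_block(system, 0, lambda *a: []) is system


def test_wrong_gradient_length_is_contract_error():
    system = assemble(one_compound_selection(absorption="iv"), [linear_compound()])
    bad = register_custom_block(system, 1, lambda t, y, u, ctx: [0.0, 0.0])
    with pytest.raises(ContractError):
        evaluate_rhs(bad, 0.0, np.zeros(bad.n_states), IND)


# -- mass balance ------------------------------------------------------------

BALANCE_CASES = [
    dict(absorption="iv", distribution="one_compartment",
         elimination=frozenset({"linear_cl"})),
    dict(absorption="first_order", distribution="one_compartment",
         elimination=frozenset({"linear_cl", "renal"})),
    dict(absorption="cat", n_transit=5, distribution="one_compartment",
         elimination=frozenset({"linear_cl"})),
    dict(absorption="first_order", distribution="minimal_pbpk",
         elimination=frozenset({"well_stirred_hepatic", "renal"})),
    dict(absorption="iv", distribution="full_pbpk", organs=("liver", "kidney", "muscle"),
         elimination=frozenset({"well_stirred_hepatic"})),
    dict(absorption="first_order", distribution="one_compartment",
         elimination=frozenset({"well_stirred_hepatic"}),
         metabolites=(MetaboliteSpec("m1", fraction_formed=0.6),
                      MetaboliteSpec("m2", fraction_formed=0.5))),
]


@pytest.mark.parametrize("case", BALANCE_CASES, ids=lambda c: f"{c['absorption']}-{c['distribution']}")
def test_mass_balance_closes(case):
    """Compartments + eliminated + unabsorbed account for the full dose to
    1e-8 relative at every output time (linear systems, tracked balance)."""
    c = linear_compound(cl=2.0, v=10.0, fa=0.8, renal_cl=1.0,
                        clint_per_enzyme={"CYP3A4": 2.0})
    sel = ModelSelection(compound_models={"drug": CompoundModel(**case)}, track_balance=True)
    system = assemble(sel, [c])
    route = "iv_bolus" if case["absorption"] == "iv" else "oral"
    dose = 100.0
    obs = np.linspace(0, 48, 97)
    ps = integrate(system, [DoseEvent(0.0, "drug", route, dose)], IND,
                   SolverSettings(method="rk5", rtol=1e-10, atol=1e-13), obs)
    total = ps.subjects[0].states.sum(axis=1)
    assert np.allclose(total, dose, rtol=1e-8)
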