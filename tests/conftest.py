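"""Shared fixtures: deterministic workspaces with closed-form PK."""

from __future__ import annotations

import numpy as np
import pytest

from popsim.workspace import (
    CompoundModel,
    CompoundRecord,
    DoseEvent,
    DoseRegimen,
    ModelSelection,
    ObservationGrid,
    PopulationRecord,
    SolverSettings,
    TrialDesign,
    Workspace,
)

REF_TIMESTAMP = "2026-01-15T12:00:00+00:00"


def degenerate_population(**overrides) -> PopulationRecord:
    """A population with no variability at all: every sampled individual
    equals the representative subject (70 kg male)."""
    base = dict(
        name="fixed_adult",
        age_range=(35.0, 35.0),
        proportion_female=0.0,
        body_weight={"male": (70.0, 0.0), "female": (60.0, 0.0)},
        enzyme_abundances={"CYP3A4": (137.0, 0.0)},
        organ_volumes={
            "liver": (1.69, 0.0),
            "portal_vein": (0.07, 0.0),
            "kidney": (0.31, 0.0),
            "muscle": (29.0, 0.0),
            "brain": (1.45, 0.0),
        },
        organ_flows={
            "hepatic_artery": (21.6, 0.0),
            "portal_vein": (68.4, 0.0),
            "kidney": (74.0, 0.0),
            "muscle": (45.0, 0.0),
            "brain": (46.0, 0.0),
        },
    )
    base.update(overrides)
    return PopulationRecord(**base)


def linear_compound(name="drug", cl=2.0, v=10.0, ka=1.0, fa=1.0, **overrides) -> CompoundRecord:
    """One-compartment compound with purely linear clearance: V given in L
    for a 70 kg subject, CL in L/h."""
    base = dict(
        name=name,
        role="substrate",
        molecular_weight=400.0,
        fu_plasma=0.5,
        blood_plasma_ratio=1.0,
        ka=ka,
        fa=fa,
        vss=v / 70.0,
        clint_per_enzyme={},
        renal_cl=0.0,
        linear_cl=cl,
        dose_defaults=DoseRegimen(route="iv_bolus", amount=100.0),
    )
    base.update(overrides)
    return CompoundRecord(**base)


def make_workspace(
    compound: CompoundRecord,
    model: CompoundModel,
    doses: tuple[DoseEvent, ...],
    obs: ObservationGrid = ObservationGrid(0.0, 24.0, 97),
    solver: SolverSettings = SolverSettings(method="rk5", rtol=1e-8, atol=1e-12),
    population: PopulationRecord | None = None,
    **kw,
) -> Workspace:
    return Workspace(
        compounds=(compound,),
        population=population or degenerate_population(),
        trial=TrialDesign(
            n_trials=1, n_subjects_per_trial=1, regimens=doses, observations=obs, seed=7
        ),
        model_selection=ModelSelection(compound_models={compound.name: model}, **kw),
        solver_settings=solver,
        created_timestamp=REF_TIMESTAMP,
    )


@pytest.fixture
def iv_workspace() -> Workspace:
    """100 mg iv bolus, V = 10 L, CL = 2 L/h: C(t) = 10·e^(−0.2 t)."""
    c = linear_compound()
    model = CompoundModel(absorption="iv", distribution="one_compartment",
                          elimination=frozenset({"linear_cl"}))
    return make_workspace(c, model, (DoseEvent(0.0, c.name, "iv_bolus", 100.0),))


@pytest.fixture
def oral_workspace() -> Workspace:
    """100 mg oral, ka = 1/h, V = 10 L, CL = 2 L/h: Bateman profile."""
    c = linear_compound(ka=1.0)
    model = CompoundModel(absorption="first_order", distribution="one_compartment",
                          elimination=frozenset({"linear_cl"}))
    return make_workspace(c, model, (DoseEvent(0.0, c.name, "oral", 100.0),))


def bateman(t, dose=100.0, f=1.0, ka=1.0, cl=2.0, v=10.0):
    ke = cl / v
    t = np.asarray(t, dtype=float)
    return f * dose * ka / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))


# ---------------------------------------------------------------------------
# synthetic observed-data problems for the estimation suite


def oral_fit_problem():
    """Noise-free single-subject oral data at known (CL, V, ka) with fit
    parameters displaced 2× from the truth.  Returns
    (workspace, dataset, fit_parameters, truth-dict)."""
    import pandas as pd

    from popsim.estimation import FitParameter
    from popsim.observed import parse_observed
    from popsim.population import representative_individual
    from popsim.simulate import simulate_subject

    c = linear_compound(cl=2.0, v=10.0, ka=1.2)
    model = CompoundModel(absorption="first_order", distribution="one_compartment",
                          elimination=frozenset({"linear_cl"}))
    w = make_workspace(
        c, model, (DoseEvent(0.0, c.name, "oral", 100.0),),
        obs=ObservationGrid(0.0, 24.0, 13),
        solver=SolverSettings(method="lsoda", rtol=1e-8, atol=1e-12),
    )
    ps = simulate_subject(w, representative_individual(w.population))
    rows = [{"ID": 1, "TIME": 0.0, "DV": "", "AMT": 100.0, "EVID": 1, "MDV": 1}]
    for t, cv in zip(ps.times[1:], ps.observable("C_drug")[1:]):
        rows.append({"ID": 1, "TIME": t, "DV": cv, "AMT": 0, "EVID": 0, "MDV": 0})
    data, issues = parse_observed(pd.DataFrame(rows).to_csv(index=False))
    assert not issues
    params = (
        FitParameter("compounds[0].linear_cl", 4.0, 0.5, 8.0),
        FitParameter("compounds[0].vss", 2 * 10 / 70, 10 / 700, 10 / 7),
        FitParameter("compounds[0].ka", 2.4, 0.6, 6.0),
    )
    truth = {"compounds[0].linear_cl": 2.0, "compounds[0].vss": 10 / 70,
             "compounds[0].ka": 1.2}
    return w, data, params, truth


def population_em_problem(n_subjects=100, omega=0.30, sigma_prop=0.10, seed=20130603):
    """Synthetic population with lognormal IIV on clearance and
    proportional residual error; iv bolus, rich sampling.  Returns
    (workspace, dataset)."""
    import math

    import pandas as pd

    from popsim.assembly import assemble
    from popsim.engine import integrate
    from popsim.observed import parse_observed
    from popsim.paths import set_path
    from popsim.population import representative_individual

    rng = np.random.default_rng(seed)
    c = linear_compound(cl=2.0, v=10.0)
    model = CompoundModel(absorption="iv", distribution="one_compartment",
                          elimination=frozenset({"linear_cl"}))
    w = make_workspace(
        c, model, (DoseEvent(0.0, c.name, "iv_bolus", 100.0),),
        obs=ObservationGrid(0.0, 24.0, 9),
        solver=SolverSettings(method="lsoda", rtol=1e-6, atol=1e-9),
    )
    ind = representative_individual(w.population)
    obs_times = np.array([0.5, 1, 2, 4, 6, 8, 12, 16, 24], float)
    rows = []
    for sid in range(1, n_subjects + 1):
        eta = rng.normal(0.0, omega)
        wi = set_path(w, "compounds[0].linear_cl", 2.0 * math.exp(eta))
        system = assemble(wi.model_selection, wi.compounds)
        ps = integrate(system, wi.trial.regimens, ind, wi.solver_settings, obs_times)
        conc = ps.observable("C_drug")
        rows.append({"ID": sid, "TIME": 0.0, "DV": "", "AMT": 100.0, "EVID": 1, "MDV": 1})
        for t, cv in zip(obs_times, conc):
            dv = cv * (1.0 + sigma_prop * rng.normal())
            rows.append({"ID": sid, "TIME": t, "DV": max(dv, 1e-6),
                         "AMT": 0, "EVID": 0, "MDV": 0})
    data, issues = parse_observed(pd.DataFrame(rows).to_csv(index=False))
    assert not any(i.fatal for i in issues)
    return w, data
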