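"""Workspace XML: round trips, validation, forward compatibility."""

import re
import xml.etree.ElementTree as ET

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsim.errors import ParseError, UnsupportedVersionError, ValidationError
from popsim.workspace import (
    CompoundModel,
    CompoundRecord,
    DoseEvent,
    DoseRegimen,
    ModelSelection,
    ObservationGrid,
    SolverSettings,
    TmddParams,
    TrialDesign,
    Workspace,
    default_population,
    default_workspace,
)
from popsim.xmlio import (
    FIELD_DEFAULTS,
    load_workspace,
    load_workspace_bytes,
    save_workspace,
    workspace_to_bytes,
)

from conftest import REF_TIMESTAMP, degenerate_population, linear_compound


def _save_load(w, tmp_path):
    path = tmp_path / "ws.xml"
    save_workspace(w, str(path))
    return load_workspace(str(path))


def test_minimal_round_trip(tmp_path, iv_workspace):
    w2, warnings = _save_load(iv_workspace, tmp_path)
    assert warnings == []
    assert w2 == iv_workspace


# randomized workspaces ------------------------------------------------------

_names = st.sampled_from(["alpha", "beta", "gamma", "delta"])


@st.composite
def workspaces(draw):
    n_compounds = draw(st.integers(1, 4))
    names = [f"cmp{i}" for i in range(n_compounds)]
    compounds = []
    models = {}
    for i, name in enumerate(names):
        absorption = draw(st.sampled_from(["iv", "first_order", "cat"]))
        distribution = draw(st.sampled_from(["one_compartment", "minimal_pbpk", "full_pbpk"]))
        organs = ("liver", "kidney") if distribution == "full_pbpk" else ()
        tmdd_on = draw(st.booleans())
        compounds.append(
            CompoundRecord(
                name=name,
                role="substrate" if i == 0 else f"inhibitor{i}",
                molecular_weight=draw(st.floats(100, 900)),
                fu_plasma=draw(st.floats(0.01, 1.0)),
                ka=draw(st.floats(0.1, 5.0)),
                fa=draw(st.floats(0.1, 1.0)),
                transit_segments=draw(st.integers(1, 9)),
                vss=draw(st.floats(0.1, 5.0)),
                clint_per_enzyme={"CYP3A4": draw(st.floats(0.1, 10.0))},
                renal_cl=draw(st.floats(0.0, 10.0)),
                tmdd=TmddParams(1.0, 0.1, 0.05, 0.2, 0.1) if tmdd_on else None,
                dose_defaults=DoseRegimen(route="oral", amount=draw(st.floats(1, 500))),
            )
        )
        models[name] = CompoundModel(
            absorption=absorption,
            n_transit=draw(st.integers(1, 9)),
            distribution=distribution,
            organs=organs,
            elimination=frozenset({"well_stirred_hepatic", "renal"}),
            tmdd=tmdd_on,
        )
    trial = TrialDesign(
        n_trials=draw(st.integers(1, 3)),
        n_subjects_per_trial=draw(st.integers(1, 20)),
        regimens=(DoseEvent(0.0, names[0], "oral", 100.0),),
        observations=ObservationGrid(0.0, draw(st.floats(12.0, 96.0)), draw(st.integers(2, 60))),
        seed=draw(st.integers(0, 2**31 - 1)),
    )
    return Workspace(
        compounds=tuple(compounds),
        population=default_population(),
        trial=trial,
        model_selection=ModelSelection(compound_models=models),
        solver_settings=SolverSettings(
            method=draw(st.sampled_from(["rk5", "lsoda", "auto"])),
            rtol=draw(st.floats(1e-10, 1e-3)),
        ),
        created_timestamp=REF_TIMESTAMP,
    )


@given(workspaces())
@settings(max_examples=30, deadline=None)
def test_property_round_trip(w):
    """Any generated valid workspace survives save→load unchanged with no
    default-fill warnings."""
    w2, warnings = load_workspace_bytes(workspace_to_bytes(w))
    assert warnings == []
    assert w2 == w


# validation errors ----------------------------------------------------------

def test_five_compounds_rejected(tmp_path):
    comps = tuple(
        linear_compound(f"c{i}", **{"role": "substrate" if i == 0 else f"inhibitor{min(i, 3)}"})
        for i in range(5)
    )
    model = CompoundModel(absorption="iv", distribution="one_compartment",
                          elimination=frozenset({"linear_cl"}))
    w = Workspace(
        compounds=comps,
        population=degenerate_population(),
        trial=TrialDesign(regimens=(DoseEvent(0.0, "c0", "iv_bolus", 1.0),)),
        model_selection=ModelSelection(compound_models={c.name: model for c in comps}),
    )
    with pytest.raises(ValidationError) as err:
        save_workspace(w, str(tmp_path / "bad.xml"))
    assert err.value.field == "compounds"


def test_missing_substrate_role_rejected(tmp_path, iv_workspace):
    c = iv_workspace.compounds[0]
    w = iv_workspace.replace(compounds=(
        CompoundRecord(**{**c.__dict__, "role": "inhibitor1"}),
    ))
    with pytest.raises(ValidationError) as err:
        save_workspace(w, str(tmp_path / "bad.xml"))
    assert err.value.field == "role"


def test_truncated_file_is_a_parse_error(tmp_path, iv_workspace):
    path = tmp_path / "ws.xml"
    save_workspace(iv_workspace, str(path))
    data = path.read_bytes()[: len(path.read_bytes()) // 2]
    with pytest.raises(ParseError):
        load_workspace_bytes(data)


def test_newer_schema_rejected(iv_workspace):
    data = workspace_to_bytes(iv_workspace).replace(
        b'schema_version="2"', b'schema_version="99"', 1
    )
    with pytest.raises(UnsupportedVersionError):
        load_workspace_bytes(data)


# forward compatibility ------------------------------------------------------

OPTIONAL_COMPOUND_TAGS = [
    "role", "molecular_weight", "fu_plasma", "blood_plasma_ratio", "ka", "fa",
    "transit_segments", "mtt", "vss", "renal_cl", "linear_cl", "dose_defaults",
]


@pytest.mark.parametrize("tag", OPTIONAL_COMPOUND_TAGS)
def test_deleting_one_optional_field_fills_documented_default(tag, iv_workspace):
    """An older-schema file lacking one optional element loads with exactly
    one warning naming the field, and the documented default value."""
    root = ET.fromstring(workspace_to_bytes(iv_workspace))
    compound_el = root.find("compounds/compound")
    victim = compound_el.find(tag)
    compound_el.remove(victim)
    w2, warnings = load_workspace_bytes(ET.tostring(root))
    assert len(warnings) == 1
    assert f"compound.{tag}" in warnings[0]
    loaded = getattr(w2.compounds[0], tag if tag != "dose_defaults" else "dose_defaults")
    assert loaded == FIELD_DEFAULTS[f"compound.{tag}"]


def test_older_schema_version_accepted_with_fill(iv_workspace):
    data = workspace_to_bytes(iv_workspace).replace(
        b'schema_version="2"', b'schema_version="1"', 1
    )
    root = ET.fromstring(data)
    compound_el = root.find("compounds/compound")
    compound_el.remove(compound_el.find("mtt"))  # field appended in schema 2
    w2, warnings = load_workspace_bytes(ET.tostring(root))
    assert len(warnings) == 1 and "compound.mtt" in warnings[0]
    assert w2.compounds[0].mtt == FIELD_DEFAULTS["compound.mtt"]
    assert w2.schema_version == 2  # upgraded on load
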