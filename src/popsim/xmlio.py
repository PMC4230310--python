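"""Workspace / compound / population XML serialization.

The element vocabulary is original to this package (no public schema
exists for the file family it emulates).  Files carry an integer
``schema_version`` in the root element; the schema is fixed per release
and later releases only append elements.  On load, any missing optional
field is filled from the documented default table (`FIELD_DEFAULTS`)
and one warning per fill is returned, so files written by an older
release keep loading unchanged — forward compatibility by default
filling.

Numbers are serialized with ``repr``, which round-trips IEEE doubles
exactly; the CSV/XML layer never applies locale-dependent formatting.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from datetime import datetime, timezone
from typing import Any

from .errors import ParseError, UnsupportedVersionError, ValidationError
from .workspace import (
    CURRENT_SCHEMA_VERSION,
    CompoundModel,
    CompoundRecord,
    DoseEvent,
    DoseRegimen,
    MetaboliteSpec,
    ModelSelection,
    ObservationGrid,
    ParameterDistribution,
    PDGraph,
    PDUnit,
    PopulationRecord,
    SolverSettings,
    TmddParams,
    TrialDesign,
    Workspace,
)

__all__ = [
    "save_workspace",
    "load_workspace",
    "save_compound",
    "load_compound",
    "save_population",
    "load_population",
    "FIELD_DEFAULTS",
]

# Documented defaults for every optional field, applied when a file
# (typically written by an older schema) lacks the element.  Keys are
# dotted field paths as they appear in load warnings.
FIELD_DEFAULTS: dict[str, Any] = {
    "compound.role": "substrate",
    "compound.molecular_weight": 400.0,
    "compound.fu_plasma": 1.0,
    "compound.blood_plasma_ratio": 1.0,
    "compound.ka": 1.0,
    "compound.fa": 1.0,
    "compound.transit_segments": 7,
    "compound.mtt": 3.5,
    "compound.vss": 0.7,
    "compound.renal_cl": 0.0,
    "compound.linear_cl": 0.0,
    "compound.dose_defaults": DoseRegimen(),
    "population.name": "healthy_adult",
    "population.proportion_female": 0.5,
    "population.age_range": (20.0, 50.0),
    "population.mppgl": 40.0,
    "population.liver_density": 1.08,
    "trial.n_trials": 1,
    "trial.n_subjects_per_trial": 10,
    "trial.seed": 20130603,
    "trial.observations": ObservationGrid(),
    "model_selection.track_balance": False,
    "solver.method": "rk5",
    "solver.rtol": 1e-6,
    "solver.atol": 1e-9,
    "solver.max_step": math.inf,
    "solver.max_internal_steps": 500_000,
    "workspace.output_selection": ("plasma_concentration",),
}


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def _sub(parent: ET.Element, tag: str, text=None, **attrs) -> ET.Element:
    el = ET.SubElement(parent, tag, {k: _fmt(v) for k, v in attrs.items()})
    if text is not None:
        el.text = _fmt(text)
    return el


# ---------------------------------------------------------------------------
# writing


def _compound_element(c: CompoundRecord) -> ET.Element:
    el = ET.Element("compound")
    _sub(el, "name", c.name)
    _sub(el, "role", c.role)
    _sub(el, "molecular_weight", c.molecular_weight)
    _sub(el, "fu_plasma", c.fu_plasma)
    _sub(el, "blood_plasma_ratio", c.blood_plasma_ratio)
    _sub(el, "ka", c.ka)
    _sub(el, "fa", c.fa)
    _sub(el, "transit_segments", c.transit_segments)
    _sub(el, "mtt", c.mtt)
    _sub(el, "vss", c.vss)
    kp = _sub(el, "kp")
    for tissue, v in sorted(c.kp.items()):
        _sub(kp, "tissue", v, name=tissue)
    clint = _sub(el, "clint")
    for enz, v in sorted(c.clint_per_enzyme.items()):
        _sub(clint, "enzyme", v, name=enz)
    _sub(el, "renal_cl", c.renal_cl)
    _sub(el, "linear_cl", c.linear_cl)
    ki = _sub(el, "ki")
    for enz, v in sorted(c.ki_per_enzyme.items()):
        _sub(ki, "enzyme", v, name=enz)
    if c.tmdd is not None:
        _sub(el, "tmdd", kon=c.tmdd.kon, koff=c.tmdd.koff, kint=c.tmdd.kint,
             ksyn=c.tmdd.ksyn, kdeg=c.tmdd.kdeg)
    d = c.dose_defaults
    _sub(el, "dose_defaults", route=d.route, amount=d.amount, interval=d.interval,
         n_doses=d.n_doses, infusion_duration=d.infusion_duration)
    return el


def _population_element(p: PopulationRecord) -> ET.Element:
    el = ET.Element("population")
    _sub(el, "name", p.name)
    _sub(el, "age_range", min=p.age_range[0], max=p.age_range[1])
    _sub(el, "proportion_female", p.proportion_female)
    for sex, (m, cv) in sorted(p.body_weight.items()):
        _sub(el, "body_weight", sex=sex, median=m, cv=cv)
    for d in p.parameter_distributions:
        _sub(el, "distribution", parameter=d.parameter, mean=d.mean, cv=d.cv,
             type=d.distribution, lower=d.lower, upper=d.upper)
    for enz, (m, cv) in sorted(p.enzyme_abundances.items()):
        _sub(el, "enzyme", name=enz, abundance=m, cv=cv)
    for organ, (m, cv) in sorted(p.organ_volumes.items()):
        _sub(el, "organ_volume", name=organ, value=m, cv=cv)
    for organ, (m, cv) in sorted(p.organ_flows.items()):
        _sub(el, "organ_flow", name=organ, value=m, cv=cv)
    _sub(el, "mppgl", p.mppgl)
    _sub(el, "liver_density", p.liver_density)
    return el


def _selection_element(sel: ModelSelection) -> ET.Element:
    el = ET.Element("model_selection", {"track_balance": _fmt(sel.track_balance)})
    for name, cm in sel.compound_models.items():
        cme = _sub(el, "compound_model", compound=name, absorption=cm.absorption,
                   n_transit=cm.n_transit, distribution=cm.distribution, tmdd=cm.tmdd)
        _sub(cme, "organs", " ".join(cm.organs))
        _sub(cme, "elimination", " ".join(sorted(cm.elimination)))
        for m in cm.metabolites:
            _sub(cme, "metabolite", name=m.name, disposition=m.disposition,
                 fraction_formed=m.fraction_formed, cl=m.cl, vss=m.vss,
                 molecular_weight=m.molecular_weight)
    for inhibitor, table in sorted(sel.inhibition.items()):
        for enz, ki in sorted(table.items()):
            _sub(el, "inhibition", inhibitor=inhibitor, enzyme=enz, ki=ki)
    return el


def _pd_graph_element(g: PDGraph) -> ET.Element:
    el = ET.Element("pd_graph")
    for u in g.units:
        ue = _sub(el, "unit", id=u.unit_id, kind=u.kind, model=u.model, input=u.input,
                  transduction=u.transduction, timescale=u.timescale)
        for k, v in sorted(u.params.items()):
            _sub(ue, "param", name=k, value=v)
    return el


def workspace_to_element(w: Workspace, stamp: bool = True) -> ET.Element:
    root = ET.Element("workspace", {"schema_version": str(w.schema_version)})
    ts = w.created_timestamp
    if stamp and not ts:
        ts = datetime.now(timezone.utc).isoformat(timespec="seconds")
    _sub(root, "meta", creator_version=w.creator_version, created_timestamp=ts)
    comps = _sub(root, "compounds")
    for c in w.compounds:
        comps.append(_compound_element(c))
    root.append(_population_element(w.population))
    trial = _sub(root, "trial", n_trials=w.trial.n_trials,
                 n_subjects_per_trial=w.trial.n_subjects_per_trial, seed=w.trial.seed)
    for ev in w.trial.regimens:
        _sub(trial, "dose", time=ev.time, compound=ev.compound, route=ev.route,
             amount=ev.amount, infusion_duration=ev.infusion_duration)
    obs = w.trial.observations
    _sub(trial, "observations", start=obs.start, end=obs.end, n=obs.n, spacing=obs.spacing)
    root.append(_selection_element(w.model_selection))
    s = w.solver_settings
    _sub(root, "solver", method=s.method, rtol=s.rtol, atol=s.atol,
         max_step=s.max_step, max_internal_steps=s.max_internal_steps)
    if w.pd_graph is not None:
        root.append(_pd_graph_element(w.pd_graph))
    out = _sub(root, "output_selection")
    for name in w.output_selection:
        _sub(out, "table", name)
    return root


def save_workspace(w: Workspace, destination) -> None:
    """Validate and write ``w`` as XML to ``destination`` (path or file)."""
    w.validate()
    root = workspace_to_element(w)
    ET.indent(root)
    ET.ElementTree(root).write(destination, encoding="utf-8", xml_declaration=True)


def workspace_to_bytes(w: Workspace) -> bytes:
    w.validate()
    root = workspace_to_element(w)
    ET.indent(root)
    return ET.tostring(root, encoding="utf-8", xml_declaration=True)


# ---------------------------------------------------------------------------
# reading


def _opt_text(elem: ET.Element, tag: str, path: str, warnings: list[str], conv=float):
    child = elem.find(tag)
    if child is None or child.text is None:
        default = FIELD_DEFAULTS[path]
        warnings.append(f"{path} missing; default {default!r} applied")
        return default
    text = child.text.strip()
    return conv(text)


def _req_text(elem: ET.Element, tag: str, context: str, conv=str):
    child = elem.find(tag)
    if child is None or child.text is None:
        raise ParseError(f"required element <{tag}> missing in <{context}>")
    return conv(child.text.strip())


def _named_table(elem: ET.Element, tag: str, value_attr: str) -> dict[str, tuple[float, float]]:
    out = {}
    for child in elem.findall(tag):
        out[child.get("name")] = (float(child.get(value_attr)), float(child.get("cv", "0")))
    return out


def _compound_from_element(el: ET.Element, warnings: list[str]) -> CompoundRecord:
    name = _req_text(el, "name", "compound")

    def opt(tag, conv=float):
        return _opt_text(el, tag, f"compound.{tag}", warnings, conv)

    kp = {}
    kpe = el.find("kp")
    if kpe is not None:
        for t in kpe.findall("tissue"):
            kp[t.get("name")] = float(t.text)
    clint = {}
    ce = el.find("clint")
    if ce is not None:
        for e in ce.findall("enzyme"):
            clint[e.get("name")] = float(e.text)
    ki = {}
    kie = el.find("ki")
    if kie is not None:
        for e in kie.findall("enzyme"):
            ki[e.get("name")] = float(e.text)
    tmdd = None
    te = el.find("tmdd")
    if te is not None:
        tmdd = TmddParams(**{k: float(te.get(k)) for k in ("kon", "koff", "kint", "ksyn", "kdeg")})
    de = el.find("dose_defaults")
    if de is None:
        dose = FIELD_DEFAULTS["compound.dose_defaults"]
        warnings.append(f"compound.dose_defaults missing; default {dose!r} applied")
    else:
        dose = DoseRegimen(
            route=de.get("route", "oral"),
            amount=float(de.get("amount", "100")),
            interval=float(de.get("interval", "24")),
            n_doses=int(de.get("n_doses", "1")),
            infusion_duration=float(de.get("infusion_duration", "1")),
        )
    return CompoundRecord(
        name=name,
        role=opt("role", str),
        molecular_weight=opt("molecular_weight"),
        fu_plasma=opt("fu_plasma"),
        blood_plasma_ratio=opt("blood_plasma_ratio"),
        ka=opt("ka"),
        fa=opt("fa"),
        transit_segments=opt("transit_segments", int),
        mtt=opt("mtt"),
        vss=opt("vss"),
        kp=kp,
        clint_per_enzyme=clint,
        renal_cl=opt("renal_cl"),
        linear_cl=opt("linear_cl"),
        ki_per_enzyme=ki,
        tmdd=tmdd,
        dose_defaults=dose,
    )


def _population_from_element(el: ET.Element, warnings: list[str]) -> PopulationRecord:
    def opt(tag, conv=float):
        return _opt_text(el, tag, f"population.{tag}", warnings, conv)

    age = el.find("age_range")
    if age is None:
        age_range = FIELD_DEFAULTS["population.age_range"]
        warnings.append(f"population.age_range missing; default {age_range!r} applied")
    else:
        age_range = (float(age.get("min")), float(age.get("max")))
    body_weight = {}
    for bw in el.findall("body_weight"):
        body_weight[bw.get("sex")] = (float(bw.get("median")), float(bw.get("cv", "0")))
    if not body_weight:
        body_weight = {"male": (78.0, 0.2), "female": (65.0, 0.2)}
        warnings.append("population.body_weight missing; reference adult weights applied")
    dists = tuple(
        ParameterDistribution(
            parameter=d.get("parameter"),
            mean=float(d.get("mean")),
            cv=float(d.get("cv", "0")),
            distribution=d.get("type", "lognormal"),
            lower=float(d.get("lower", "0")),
            upper=float(d.get("upper", "inf")),
        )
        for d in el.findall("distribution")
    )
    return PopulationRecord(
        name=opt("name", str),
        age_range=age_range,
        proportion_female=opt("proportion_female"),
        body_weight=body_weight,
        parameter_distributions=dists,
        enzyme_abundances=_named_table(el, "enzyme", "abundance"),
        organ_volumes=_named_table(el, "organ_volume", "value"),
        organ_flows=_named_table(el, "organ_flow", "value"),
        mppgl=opt("mppgl"),
        liver_density=opt("liver_density"),
    )


def _selection_from_element(el: ET.Element, warnings: list[str]) -> ModelSelection:
    if el.get("track_balance") is None:
        track = FIELD_DEFAULTS["model_selection.track_balance"]
        warnings.append(f"model_selection.track_balance missing; default {track!r} applied")
    else:
        track = _parse_bool(el.get("track_balance"))
    models = {}
    for cme in el.findall("compound_model"):
        organs_el = cme.find("organs")
        organs = tuple((organs_el.text or "").split()) if organs_el is not None else ()
        elim_el = cme.find("elimination")
        elim = frozenset((elim_el.text or "").split()) if elim_el is not None else frozenset()
        mets = tuple(
            MetaboliteSpec(
                name=m.get("name"),
                disposition=m.get("disposition", "one_compartment"),
                fraction_formed=float(m.get("fraction_formed", "1")),
                cl=float(m.get("cl", "5")),
                vss=float(m.get("vss", "0.5")),
                molecular_weight=float(m.get("molecular_weight", "380")),
            )
            for m in cme.findall("metabolite")
        )
        models[cme.get("compound")] = CompoundModel(
            absorption=cme.get("absorption", "first_order"),
            n_transit=int(cme.get("n_transit", "7")),
            distribution=cme.get("distribution", "one_compartment"),
            organs=organs,
            elimination=elim,
            metabolites=mets,
            tmdd=_parse_bool(cme.get("tmdd", "false")),
        )
    inhibition: dict[str, dict[str, float]] = {}
    for ie in el.findall("inhibition"):
        inhibition.setdefault(ie.get("inhibitor"), {})[ie.get("enzyme")] = float(ie.get("ki"))
    return ModelSelection(compound_models=models, inhibition=inhibition, track_balance=track)


def _pd_graph_from_element(el: ET.Element) -> PDGraph:
    units = []
    for ue in el.findall("unit"):
        params = {p.get("name"): float(p.get("value")) for p in ue.findall("param")}
        units.append(
            PDUnit(
                unit_id=ue.get("id"),
                kind=ue.get("kind"),
                model=ue.get("model"),
                input=ue.get("input"),
                params=params,
                transduction=ue.get("transduction", "empirical"),
                timescale=ue.get("timescale", "profile"),
            )
        )
    return PDGraph(units=tuple(units))


def workspace_from_element(root: ET.Element) -> tuple[Workspace, list[str]]:
    if root.tag != "workspace":
        raise ParseError(f"expected <workspace> root element, found <{root.tag}>")
    version_text = root.get("schema_version")
    if version_text is None:
        raise ParseError("root element lacks schema_version")
    try:
        version = int(version_text)
    except ValueError as exc:
        raise ParseError(f"unrecognised schema_version {version_text!r}") from exc
    if version > CURRENT_SCHEMA_VERSION:
        raise UnsupportedVersionError(
            f"file schema_version {version} is newer than supported version "
            f"{CURRENT_SCHEMA_VERSION}"
        )

    warnings: list[str] = []
    meta = root.find("meta")
    creator = meta.get("creator_version", "") if meta is not None else ""
    timestamp = meta.get("created_timestamp", "") if meta is not None else ""

    comps_el = root.find("compounds")
    if comps_el is None:
        raise ParseError("missing <compounds> element")
    compounds = tuple(_compound_from_element(c, warnings) for c in comps_el.findall("compound"))

    pop_el = root.find("population")
    if pop_el is None:
        raise ParseError("missing <population> element")
    population = _population_from_element(pop_el, warnings)

    trial_el = root.find("trial")
    if trial_el is None:
        raise ParseError("missing <trial> element")

    def trial_attr(attr, conv):
        value = trial_el.get(attr)
        if value is None:
            default = FIELD_DEFAULTS[f"trial.{attr}"]
            warnings.append(f"trial.{attr} missing; default {default!r} applied")
            return default
        return conv(value)

    regimens = tuple(
        DoseEvent(
            time=float(d.get("time")),
            compound=d.get("compound"),
            route=d.get("route", "oral"),
            amount=float(d.get("amount")),
            infusion_duration=float(d.get("infusion_duration", "0")),
        )
        for d in trial_el.findall("dose")
    )
    obs_el = trial_el.find("observations")
    if obs_el is None:
        observations = FIELD_DEFAULTS["trial.observations"]
        warnings.append(f"trial.observations missing; default {observations!r} applied")
    else:
        observations = ObservationGrid(
            start=float(obs_el.get("start")),
            end=float(obs_el.get("end")),
            n=int(obs_el.get("n")),
            spacing=obs_el.get("spacing", "linear"),
        )
    trial = TrialDesign(
        n_trials=trial_attr("n_trials", int),
        n_subjects_per_trial=trial_attr("n_subjects_per_trial", int),
        regimens=regimens,
        observations=observations,
        seed=trial_attr("seed", int),
    )

    sel_el = root.find("model_selection")
    if sel_el is None:
        raise ParseError("missing <model_selection> element")
    selection = _selection_from_element(sel_el, warnings)

    solver_el = root.find("solver")
    if solver_el is None:
        warnings.append("solver settings missing; defaults applied")
        solver = SolverSettings()
    else:
        def solver_attr(attr, conv):
            value = solver_el.get(attr)
            if value is None:
                default = FIELD_DEFAULTS[f"solver.{attr}"]
                warnings.append(f"solver.{attr} missing; default {default!r} applied")
                return default
            return conv(value)

        solver = SolverSettings(
            method=solver_attr("method", str),
            rtol=solver_attr("rtol", float),
            atol=solver_attr("atol", float),
            max_step=solver_attr("max_step", float),
            max_internal_steps=solver_attr("max_internal_steps", int),
        )

    pd_el = root.find("pd_graph")
    pd_graph = _pd_graph_from_element(pd_el) if pd_el is not None else None

    out_el = root.find("output_selection")
    if out_el is None:
        output = FIELD_DEFAULTS["workspace.output_selection"]
        warnings.append(f"workspace.output_selection missing; default {output!r} applied")
    else:
        output = tuple(t.text.strip() for t in out_el.findall("table"))

    w = Workspace(
        compounds=compounds,
        population=population,
        trial=trial,
        model_selection=selection,
        solver_settings=solver,
        pd_graph=pd_graph,
        output_selection=output,
        schema_version=CURRENT_SCHEMA_VERSION,
        creator_version=creator,
        created_timestamp=timestamp,
    )
    w.validate()
    return w, warnings


def load_workspace(source) -> tuple[Workspace, list[str]]:
    """Load a workspace XML file; returns ``(workspace, warnings)``.

    Warnings list one entry per default-filled field.  Raises
    :class:`~popsim.errors.ParseError` for malformed XML (with the line
    number) and :class:`~popsim.errors.UnsupportedVersionError` for
    files from a newer schema.
    """
    try:
        tree = ET.parse(source)
    except ET.ParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise ParseError(f"malformed workspace XML: {exc.msg if hasattr(exc, 'msg') else exc}", line) from exc
    return workspace_from_element(tree.getroot())


def load_workspace_bytes(data: bytes) -> tuple[Workspace, list[str]]:
    try:
        root = ET.fromstring(data)
    except ET.ParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise ParseError("malformed workspace XML", line) from exc
    return workspace_from_element(root)


# standalone compound / population files ------------------------------------


def save_compound(c: CompoundRecord, destination) -> None:
    c.validate()
    el = _compound_element(c)
    el.set("schema_version", str(CURRENT_SCHEMA_VERSION))
    ET.indent(el)
    ET.ElementTree(el).write(destination, encoding="utf-8", xml_declaration=True)


def load_compound(source) -> tuple[CompoundRecord, list[str]]:
    try:
        root = ET.parse(source).getroot()
    except ET.ParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise ParseError("malformed compound XML", line) from exc
    if root.tag != "compound":
        raise ParseError(f"expected <compound> root element, found <{root.tag}>")
    warnings: list[str] = []
    c = _compound_from_element(root, warnings)
    c.validate()
    return c, warnings


def save_population(p: PopulationRecord, destination) -> None:
    p.validate()
    el = _population_element(p)
    el.set("schema_version", str(CURRENT_SCHEMA_VERSION))
    ET.indent(el)
    ET.ElementTree(el).write(destination, encoding="utf-8", xml_declaration=True)


def load_population(source) -> tuple[PopulationRecord, list[str]]:
    try:
        root = ET.parse(source).getroot()
    except ET.ParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise ParseError("malformed population XML", line) from exc
    if root.tag != "population":
        raise ParseError(f"expected <population> root element, found <{root.tag}>")
    warnings: list[str] = []
    p = _population_from_element(root, warnings)
    p.validate()
    return p, warnings
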