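"""Domain types making up a simulation workspace.

A workspace is the unit of reproducibility: it bundles the compounds
(drug-dependent parameters), the population (system parameters with
inter-individual variability), the trial design, the model selection,
solver settings, an optional pharmacodynamic graph and the output
selection.  Everything needed to re-run a simulation is in this one
object; :mod:`popsim.xmlio` round-trips it to XML.

Units are fixed repository-wide: amounts in mg, volumes in L, times in
h, concentrations in mg/L, binding constants in µM, clearances in L/h.
Molar conversions happen only at model boundaries via the molecular
weight (g/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ValidationError

__all__ = [
    "TmddParams",
    "DoseRegimen",
    "CompoundRecord",
    "ParameterDistribution",
    "PopulationRecord",
    "DoseEvent",
    "ObservationGrid",
    "TrialDesign",
    "MetaboliteSpec",
    "CompoundModel",
    "ModelSelection",
    "SolverSettings",
    "PDUnit",
    "PDGraph",
    "Workspace",
    "default_compound",
    "default_population",
    "default_workspace",
]

ROLES = ("substrate", "inhibitor1", "inhibitor2", "inhibitor3")
ROUTES = ("oral", "iv_bolus", "iv_infusion")
SUPPORTED_ORGANS = (
    "liver",
    "kidney",
    "muscle",
    "adipose",
    "brain",
    "heart",
    "skin",
    "bone",
    "gut",
)
MAX_COMPOUNDS = 4
MAX_METABOLITES = 3


def _require(cond: bool, fld: str, msg: str) -> None:
    if not cond:
        raise ValidationError(fld, msg)


@dataclass(frozen=True)
class TmddParams:
    """Full target-mediated drug disposition parameters (Mager–Jusko).

    kon in 1/(µM·h), koff/kint/kdeg in 1/h, ksyn in µM/h.
    """

    kon: float
    koff: float
    kint: float
    ksyn: float
    kdeg: float

    def validate(self) -> None:
        for name in ("kon", "koff", "kint", "ksyn", "kdeg"):
            _require(getattr(self, name) >= 0, f"tmdd.{name}", "must be >= 0")


@dataclass(frozen=True)
class DoseRegimen:
    route: str = "oral"
    amount: float = 100.0  # mg
    interval: float = 24.0  # h
    n_doses: int = 1
    infusion_duration: float = 1.0  # h, iv_infusion only

    def validate(self) -> None:
        _require(self.route in ROUTES, "dose_defaults.route", f"must be one of {ROUTES}")
        _require(self.amount >= 0, "dose_defaults.amount", "must be >= 0")
        _require(self.interval > 0, "dose_defaults.interval", "must be > 0")
        _require(self.n_doses >= 1, "dose_defaults.n_doses", "must be >= 1")
        if self.route == "iv_infusion":
            _require(self.infusion_duration > 0, "dose_defaults.infusion_duration", "must be > 0")


@dataclass(frozen=True)
class CompoundRecord:
    """Drug-dependent parameters for one chemical moiety."""

    name: str
    role: str = "substrate"
    molecular_weight: float = 400.0  # g/mol
    fu_plasma: float = 1.0  # fraction unbound in plasma
    blood_plasma_ratio: float = 1.0
    ka: float = 1.0  # 1/h first-order absorption
    fa: float = 1.0  # fraction absorbed
    transit_segments: int = 7
    mtt: float = 3.5  # h, mean small-intestinal transit time (CAT)
    vss: float = 0.7  # L/kg
    kp: dict[str, float] = field(default_factory=dict)  # tissue:plasma partition
    clint_per_enzyme: dict[str, float] = field(default_factory=dict)  # µL/min/pmol
    renal_cl: float = 0.0  # L/h
    linear_cl: float = 0.0  # L/h, model-independent systemic clearance
    ki_per_enzyme: dict[str, float] = field(default_factory=dict)  # µM, competitive
    tmdd: Optional[TmddParams] = None
    dose_defaults: DoseRegimen = field(default_factory=DoseRegimen)

    def validate(self) -> None:
        _require(bool(self.name), "name", "must be non-empty")
        _require(self.role in ROLES, "role", f"must be one of {ROLES}")
        _require(self.molecular_weight > 0, "molecular_weight", "must be > 0")
        _require(0 < self.fu_plasma <= 1, "fu_plasma", "must be in (0, 1]")
        _require(self.blood_plasma_ratio > 0, "blood_plasma_ratio", "must be > 0")
        _require(0 <= self.fa <= 1, "fa", "must be in [0, 1]")
        _require(self.ka >= 0, "ka", "must be >= 0")
        _require(self.transit_segments >= 0, "transit_segments", "must be >= 0")
        _require(self.mtt > 0, "mtt", "must be > 0")
        _require(self.vss > 0, "vss", "must be > 0")
        _require(self.renal_cl >= 0, "renal_cl", "must be >= 0")
        _require(self.linear_cl >= 0, "linear_cl", "must be >= 0")
        for enz, v in self.clint_per_enzyme.items():
            _require(v >= 0, f"clint_per_enzyme[{enz}]", "must be >= 0")
        for enz, v in self.ki_per_enzyme.items():
            _require(v > 0, f"ki_per_enzyme[{enz}]", "must be > 0")
        for organ, v in self.kp.items():
            _require(v > 0, f"kp[{organ}]", "must be > 0")
        if self.tmdd is not None:
            self.tmdd.validate()
        self.dose_defaults.validate()


@dataclass(frozen=True)
class ParameterDistribution:
    """One inter-individual variability entry of a population.

    For ``lognormal`` the mean is interpreted as the median (geometric
    mean); sampling uses ``exp(N(ln mean, ln(1+cv²)))``.
    """

    parameter: str
    mean: float
    cv: float = 0.0
    distribution: str = "lognormal"
    lower: float = 0.0
    upper: float = math.inf

    def validate(self) -> None:
        _require(self.cv >= 0, f"{self.parameter}.cv", "must be >= 0")
        _require(
            self.distribution in ("lognormal", "normal"),
            f"{self.parameter}.distribution",
            "must be lognormal or normal",
        )
        _require(
            self.lower <= self.mean <= self.upper,
            f"{self.parameter}.bounds",
            "bounds must contain the mean",
        )


@dataclass(frozen=True)
class PopulationRecord:
    """System parameters of a population with variability distributions.

    Organ volumes and flows are stated for a 70 kg reference adult and
    scaled allometrically per individual; ``cv`` entries give residual
    lognormal variability after weight scaling.
    """

    name: str = "healthy_adult"
    age_range: tuple[float, float] = (20.0, 50.0)
    proportion_female: float = 0.5
    # sex -> (median kg, cv)
    body_weight: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"male": (78.0, 0.2), "female": (65.0, 0.2)}
    )
    parameter_distributions: tuple[ParameterDistribution, ...] = ()
    enzyme_abundances: dict[str, tuple[float, float]] = field(  # pmol/mg, cv
        default_factory=lambda: {"CYP3A4": (137.0, 0.41), "CYP2D6": (8.0, 0.6)}
    )
    organ_volumes: dict[str, tuple[float, float]] = field(  # L at 70 kg, cv
        default_factory=lambda: {
            "liver": (1.69, 0.23),
            "portal_vein": (0.07, 0.1),
            "kidney": (0.31, 0.2),
            "muscle": (29.0, 0.15),
            "adipose": (18.2, 0.4),
            "brain": (1.45, 0.1),
            "heart": (0.33, 0.15),
            "skin": (3.3, 0.15),
            "bone": (10.5, 0.1),
            "gut": (1.2, 0.15),
        }
    )
    organ_flows: dict[str, tuple[float, float]] = field(  # L/h at 70 kg, cv
        default_factory=lambda: {
            "hepatic_artery": (21.6, 0.2),
            "portal_vein": (68.4, 0.2),
            "kidney": (74.0, 0.2),
            "muscle": (45.0, 0.2),
            "adipose": (18.6, 0.3),
            "brain": (46.0, 0.1),
            "heart": (14.4, 0.2),
            "skin": (18.0, 0.2),
            "bone": (12.0, 0.2),
            "gut": (65.0, 0.2),
        }
    )
    mppgl: float = 40.0  # mg microsomal protein per g liver
    liver_density: float = 1.08  # g/mL

    def validate(self) -> None:
        _require(bool(self.name), "population.name", "must be non-empty")
        _require(
            0 <= self.proportion_female <= 1, "proportion_female", "must be in [0, 1]"
        )
        _require(
            self.age_range[0] <= self.age_range[1], "age_range", "min must be <= max"
        )
        for sex, (m, cv) in self.body_weight.items():
            _require(m > 0, f"body_weight[{sex}]", "median must be > 0")
            _require(cv >= 0, f"body_weight[{sex}]", "cv must be >= 0")
        for d in self.parameter_distributions:
            d.validate()
        for label, table in (
            ("enzyme_abundances", self.enzyme_abundances),
            ("organ_volumes", self.organ_volumes),
            ("organ_flows", self.organ_flows),
        ):
            for key, (m, cv) in table.items():
                _require(m > 0, f"{label}[{key}]", "mean must be > 0")
                _require(cv >= 0, f"{label}[{key}]", "cv must be >= 0")
        _require(self.mppgl > 0, "mppgl", "must be > 0")
        _require(self.liver_density > 0, "liver_density", "must be > 0")


@dataclass(frozen=True)
class DoseEvent:
    time: float  # h
    compound: str
    route: str = "oral"
    amount: float = 0.0  # mg
    infusion_duration: float = 0.0  # h, > 0 for iv_infusion

    def validate(self) -> None:
        _require(self.time >= 0, "dose.time", "must be >= 0")
        _require(self.amount >= 0, "dose.amount", "must be >= 0")
        _require(self.route in ROUTES, "dose.route", f"must be one of {ROUTES}")
        if self.route == "iv_infusion":
            _require(self.infusion_duration > 0, "dose.infusion_duration", "must be > 0")


@dataclass(frozen=True)
class ObservationGrid:
    start: float = 0.0
    end: float = 24.0
    n: int = 97
    spacing: str = "linear"

    def times(self):
        import numpy as np

        if self.spacing == "linear":
            return np.linspace(self.start, self.end, self.n)
        if self.spacing == "log":
            _require(self.start > 0, "observations", "log spacing requires start > 0")
            return np.geomspace(self.start, self.end, self.n)
        raise ValidationError("observations.spacing", "must be linear or log")

    def validate(self) -> None:
        _require(self.end > self.start, "observations", "end must exceed start")
        _require(self.n >= 2, "observations.n", "must be >= 2")


@dataclass(frozen=True)
class TrialDesign:
    n_trials: int = 1
    n_subjects_per_trial: int = 10
    regimens: tuple[DoseEvent, ...] = ()
    observations: ObservationGrid = field(default_factory=ObservationGrid)
    seed: int = 20130603

    def validate(self) -> None:
        _require(self.n_trials >= 1, "n_trials", "must be >= 1")
        _require(self.n_subjects_per_trial >= 1, "n_subjects_per_trial", "must be >= 1")
        for ev in self.regimens:
            ev.validate()
        self.observations.validate()
        t = self.observations.times()
        _require(bool((t[1:] > t[:-1]).all()), "observation_times", "must be strictly increasing")


@dataclass(frozen=True)
class MetaboliteSpec:
    """One metabolite in the (up to 3 deep) chain formed from a parent.

    ``fraction_formed`` is the fraction of the predecessor's hepatic
    elimination flux converted into this metabolite; its own disposition
    is one-compartment or minimal PBPK with a linear clearance.
    """

    name: str
    disposition: str = "one_compartment"  # or minimal_pbpk
    fraction_formed: float = 1.0
    cl: float = 5.0  # L/h
    vss: float = 0.5  # L/kg
    molecular_weight: float = 380.0

    def validate(self) -> None:
        _require(bool(self.name), "metabolite.name", "must be non-empty")
        _require(
            self.disposition in ("one_compartment", "minimal_pbpk"),
            "metabolite.disposition",
            "must be one_compartment or minimal_pbpk",
        )
        _require(0 <= self.fraction_formed <= 1, "metabolite.fraction_formed", "must be in [0, 1]")
        _require(self.cl >= 0, "metabolite.cl", "must be >= 0")
        _require(self.vss > 0, "metabolite.vss", "must be > 0")


ABSORPTIONS = ("iv", "first_order", "cat")
DISTRIBUTIONS = ("one_compartment", "minimal_pbpk", "full_pbpk")
ELIMINATIONS = ("well_stirred_hepatic", "renal", "linear_cl")


@dataclass(frozen=True)
class CompoundModel:
    """Model choices for one compound: which mechanisms to compose."""

    absorption: str = "first_order"
    n_transit: int = 7
    distribution: str = "one_compartment"
    organs: tuple[str, ...] = ()
    elimination: frozenset[str] = frozenset({"linear_cl"})
    metabolites: tuple[MetaboliteSpec, ...] = ()
    tmdd: bool = False

    def validate(self) -> None:
        _require(self.absorption in ABSORPTIONS, "absorption", f"must be one of {ABSORPTIONS}")
        if self.absorption == "cat":
            _require(self.n_transit >= 1, "n_transit", "must be >= 1 for cat absorption")
        _require(
            self.distribution in DISTRIBUTIONS, "distribution", f"must be one of {DISTRIBUTIONS}"
        )
        if self.distribution == "full_pbpk":
            for organ in self.organs:
                _require(
                    organ in SUPPORTED_ORGANS,
                    "organs",
                    f"{organ!r} not in supported set {SUPPORTED_ORGANS}",
                )
        for mech in self.elimination:
            _require(mech in ELIMINATIONS, "elimination", f"must be drawn from {ELIMINATIONS}")
        _require(
            len(self.metabolites) <= MAX_METABOLITES,
            "metabolites",
            f"at most {MAX_METABOLITES} metabolites per compound",
        )
        for m in self.metabolites:
            m.validate()


@dataclass(frozen=True)
class ModelSelection:
    """Per-compound model choices plus the cross-compound inhibition map.

    ``inhibition`` maps inhibitor compound name -> enzyme -> competitive
    Ki (µM); it scales the target enzyme's intrinsic clearance by
    ``1/(1 + Σ Cu_i/Ki_i)``.
    """

    compound_models: dict[str, CompoundModel] = field(default_factory=dict)
    inhibition: dict[str, dict[str, float]] = field(default_factory=dict)
    track_balance: bool = False

    def validate(self) -> None:
        _require(
            len(self.compound_models) <= MAX_COMPOUNDS,
            "compound_models",
            f"at most {MAX_COMPOUNDS} compounds",
        )
        for cm in self.compound_models.values():
            cm.validate()
        for inhibitor, table in self.inhibition.items():
            for enz, ki in table.items():
                _require(ki > 0, f"inhibition[{inhibitor}][{enz}]", "Ki must be > 0")

    def for_compound(self, name: str) -> CompoundModel:
        return self.compound_models[name]


@dataclass(frozen=True)
class SolverSettings:
    method: str = "rk5"  # rk5 | lsoda | auto
    rtol: float = 1e-6
    atol: float = 1e-9
    max_step: float = math.inf  # h
    max_internal_steps: int = 500_000

    def validate(self) -> None:
        _require(self.method in ("rk5", "lsoda", "auto"), "solver.method", "must be rk5, lsoda or auto")
        _require(self.rtol > 0, "solver.rtol", "must be > 0")
        _require(self.atol > 0, "solver.atol", "must be > 0")
        _require(self.max_step > 0, "solver.max_step", "must be > 0")
        _require(self.max_internal_steps >= 1, "solver.max_internal_steps", "must be >= 1")


@dataclass(frozen=True)
class PDUnit:
    """One pharmacodynamic response unit (node of the PD graph).

    Basic units are direct concentration-response transforms; link units
    carry dynamics (effect compartment, turnover, progression, survival)
    and contribute states to the assembled ODE system.
    """

    unit_id: str
    kind: str  # basic | link
    model: str
    input: str  # "pk:<compound>[:<compartment>]" or "unit:<unit_id>"
    params: dict[str, float] = field(default_factory=dict)
    transduction: str = "empirical"  # empirical | operational | intrinsic_efficacy
    timescale: str = "profile"  # profile | summary:<metric> | long

    BASIC_MODELS = ("linear", "emax", "sigmoid_emax", "operational", "occupancy")
    LINK_MODELS = (
        "effect_compartment",
        "indirect_1",
        "indirect_2",
        "indirect_3",
        "indirect_4",
        "progression_linear",
        "progression_asymptotic",
        "survival",
        "custom",
    )

    def validate(self) -> None:
        _require(self.kind in ("basic", "link"), f"unit[{self.unit_id}].kind", "must be basic or link")
        menu = self.BASIC_MODELS if self.kind == "basic" else self.LINK_MODELS
        _require(self.model in menu, f"unit[{self.unit_id}].model", f"must be one of {menu}")
        _require(
            self.input.startswith("pk:") or self.input.startswith("unit:"),
            f"unit[{self.unit_id}].input",
            "must be 'pk:<compound>' or 'unit:<unit_id>'",
        )
        ts = self.timescale
        _require(
            ts in ("profile", "long") or ts.startswith("summary:"),
            f"unit[{self.unit_id}].timescale",
            "must be profile, long or summary:<metric>",
        )
        if ts == "long":
            _require(self.kind == "link", f"unit[{self.unit_id}].timescale", "long timescale only on link units")
        _require(
            self.transduction in ("empirical", "operational", "intrinsic_efficacy"),
            f"unit[{self.unit_id}].transduction",
            "unknown transduction mode",
        )


@dataclass(frozen=True)
class PDGraph:
    units: tuple[PDUnit, ...] = ()

    def validate(self) -> None:
        from .pdmodels import validate_graph  # deferred; structural checks live there

        for u in self.units:
            u.validate()
        validate_graph(self)

    def unit(self, unit_id: str) -> PDUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)


CURRENT_SCHEMA_VERSION = 2


@dataclass(frozen=True)
class Workspace:
    """Snapshot of the running condition of one simulation."""

    compounds: tuple[CompoundRecord, ...]
    population: PopulationRecord
    trial: TrialDesign
    model_selection: ModelSelection
    solver_settings: SolverSettings = field(default_factory=SolverSettings)
    pd_graph: Optional[PDGraph] = None
    output_selection: tuple[str, ...] = ("plasma_concentration",)
    schema_version: int = CURRENT_SCHEMA_VERSION
    creator_version: str = "popsim 0.1.0"
    created_timestamp: str = ""

    def validate(self) -> None:
        _require(
            1 <= len(self.compounds) <= MAX_COMPOUNDS,
            "compounds",
            f"workspace must contain 1 to {MAX_COMPOUNDS} compounds",
        )
        names = [c.name for c in self.compounds]
        _require(len(set(names)) == len(names), "compounds", "compound names must be unique")
        substrates = [c for c in self.compounds if c.role == "substrate"]
        _require(len(substrates) == 1, "role", "exactly one compound must have role 'substrate'")
        for c in self.compounds:
            c.validate()
        self.population.validate()
        self.trial.validate()
        self.model_selection.validate()
        for name in self.model_selection.compound_models:
            _require(name in names, "model_selection", f"model for unknown compound {name!r}")
        for c in self.compounds:
            _require(
                c.name in self.model_selection.compound_models,
                "model_selection",
                f"no model selected for compound {c.name!r}",
            )
        self.solver_settings.validate()
        if self.pd_graph is not None:
            self.pd_graph.validate()

    def compound(self, name: str) -> CompoundRecord:
        for c in self.compounds:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def substrate(self) -> CompoundRecord:
        return next(c for c in self.compounds if c.role == "substrate")

    def replace(self, **kw) -> "Workspace":
        return replace(self, **kw)


def default_compound(name: str = "drugA", **overrides) -> CompoundRecord:
    """A mid-size lipophilic small molecule with CYP3A4 clearance."""
    base = dict(
        name=name,
        role="substrate",
        molecular_weight=400.0,
        fu_plasma=0.1,
        blood_plasma_ratio=0.85,
        ka=1.0,
        fa=0.9,
        vss=0.8,
        clint_per_enzyme={"CYP3A4": 2.0},
        renal_cl=1.0,
        dose_defaults=DoseRegimen(route="oral", amount=100.0, interval=24.0, n_doses=1),
    )
    base.update(overrides)
    return CompoundRecord(**base)


def default_population(**overrides) -> PopulationRecord:
    return PopulationRecord(**overrides)


def default_workspace() -> Workspace:
    """A single-compound oral one-compartment workspace used in examples."""
    cmp = default_compound()
    trial = TrialDesign(
        n_trials=1,
        n_subjects_per_trial=10,
        regimens=(DoseEvent(time=0.0, compound=cmp.name, route="oral", amount=100.0),),
        observations=ObservationGrid(0.0, 24.0, 97),
    )
    selection = ModelSelection(
        compound_models={
            cmp.name: CompoundModel(
                absorption="first_order",
                distribution="one_compartment",
                elimination=frozenset({"well_stirred_hepatic", "renal"}),
            )
        }
    )
    return Workspace(
        compounds=(cmp,),
        population=default_population(),
        trial=trial,
        model_selection=selection,
    )
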