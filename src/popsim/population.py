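"""Virtual individuals and populations.

Each individual carries demographic covariates and physiological
parameters (organ volumes/flows, enzyme abundances) sampled from the
population record's variability distributions.  Body weight is sampled
lognormally by sex; organ volumes scale with (weight/70)^1 and flows
with (weight/70)^0.75 before residual lognormal variability is applied,
so weight mediates the correlation between organ sizes and perfusion.

Reproducibility: every subject gets a counter-based random substream
derived from ``(seed, trial_id, subject_id)``, so subject k's
parameters do not depend on how many other subjects are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .workspace import ParameterDistribution, PopulationRecord, TrialDesign

__all__ = [
    "Individual",
    "Population",
    "representative_individual",
    "sample_individual",
    "generate_population",
]

REFERENCE_WEIGHT = 70.0  # kg; population tables are stated at this weight
_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class Individual:
    subject_id: int
    trial_id: int
    age: float
    sex: str
    body_weight: float
    organ_volumes: dict[str, float] = field(default_factory=dict)  # L
    organ_flows: dict[str, float] = field(default_factory=dict)  # L/h
    enzyme_abundances: dict[str, float] = field(default_factory=dict)  # pmol/mg
    parameters: dict[str, float] = field(default_factory=dict)
    mppgl: float = 40.0
    liver_density: float = 1.08

    @property
    def liver_weight_g(self) -> float:
        return self.organ_volumes.get("liver", 1.69) * self.liver_density * 1000.0


@dataclass(frozen=True)
class Population:
    individuals: tuple[Individual, ...]
    generation_seed: int
    spec_reference: str

    def __post_init__(self):
        ids = [(i.trial_id, i.subject_id) for i in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValidationError("individuals", "subject ids must be unique")

    def by_trial(self, trial_id: int) -> tuple[Individual, ...]:
        return tuple(i for i in self.individuals if i.trial_id == trial_id)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log1p(cv * cv))


def _sample_scalar(
    mean: float,
    cv: float,
    rng: np.random.Generator,
    distribution: str = "lognormal",
    lower: float = 0.0,
    upper: float = math.inf,
    label: str = "parameter",
) -> float:
    """Draw one value; bounds are enforced by rejection resampling."""
    if cv == 0.0:
        return mean
    for _ in range(_MAX_REJECTIONS):
        if distribution == "lognormal":
            value = mean * math.exp(rng.normal(0.0, _lognormal_sigma(cv)))
        else:
            value = rng.normal(mean, cv * abs(mean))
        if lower <= value <= upper:
            return value
    raise ValidationError(label, f"bounds [{lower}, {upper}] infeasible after {_MAX_REJECTIONS} resamples")


def _central_sex(spec: PopulationRecord) -> str:
    return "female" if spec.proportion_female >= 0.5 else "male"


def representative_individual(spec: PopulationRecord) -> Individual:
    """The population-representative subject: every parameter at its
    central value (lognormal median / normal mean), deterministically.

    Used by the sensitivity-analysis tool, which scans parameters for a
    single representative subject rather than a sampled population.
    """
    spec.validate()
    sex = _central_sex(spec)
    weight = spec.body_weight[sex][0]
    return _build_individual(
        spec,
        subject_id=0,
        trial_id=0,
        age=0.5 * (spec.age_range[0] + spec.age_range[1]),
        sex=sex,
        weight=weight,
        rng=None,
    )


def _build_individual(spec, subject_id, trial_id, age, sex, weight, rng) -> Individual:
    """Scale organ tables to the subject's weight, then apply residual
    variability (skipped when ``rng`` is None → central values)."""
    size_scale = weight / REFERENCE_WEIGHT
    flow_scale = size_scale**0.75

    def draw(mean, cv, label):
        if rng is None:
            return mean
        return _sample_scalar(mean, cv, rng, "lognormal", label=label)

    volumes = {
        organ: draw(mean * size_scale, cv, f"organ_volumes[{organ}]")
        for organ, (mean, cv) in spec.organ_volumes.items()
    }
    flows = {
        organ: draw(mean * flow_scale, cv, f"organ_flows[{organ}]")
        for organ, (mean, cv) in spec.organ_flows.items()
    }
    enzymes = {
        enz: draw(mean, cv, f"enzyme_abundances[{enz}]")
        for enz, (mean, cv) in spec.enzyme_abundances.items()
    }
    params = {}
    for d in spec.parameter_distributions:
        if rng is None or d.cv == 0.0:
            params[d.parameter] = d.mean
        else:
            params[d.parameter] = _sample_scalar(
                d.mean, d.cv, rng, d.distribution, d.lower, d.upper, d.parameter
            )
    return Individual(
        subject_id=subject_id,
        trial_id=trial_id,
        age=age,
        sex=sex,
        body_weight=weight,
        organ_volumes=volumes,
        organ_flows=flows,
        enzyme_abundances=enzymes,
        parameters=params,
        mppgl=spec.mppgl,
        liver_density=spec.liver_density,
    )


def sample_individual(
    spec: PopulationRecord,
    rng: np.random.Generator,
    subject_id: int = 0,
    trial_id: int = 0,
) -> Individual:
    """Sample one virtual individual from ``spec`` using ``rng``.

    Draw order is fixed (sex, age, weight, volumes, flows, enzymes,
    extra parameters) so a given substream always produces the same
    subject.
    """
    spec.validate()
    if spec.proportion_female in (0.0, 1.0):
        sex = "female" if spec.proportion_female == 1.0 else "male"
        rng.random()  # keep the stream layout identical either way
    else:
        sex = "female" if rng.random() < spec.proportion_female else "male"
    lo, hi = spec.age_range
    age = lo if lo == hi else rng.uniform(lo, hi)
    w_mean, w_cv = spec.body_weight[sex]
    weight = _sample_scalar(w_mean, w_cv, rng, "lognormal", label="body_weight")
    return _build_individual(spec, subject_id, trial_id, age, sex, weight, rng)


def subject_rng(seed: int, trial_id: int, subject_id: int) -> np.random.Generator:
    """Counter-based substream for one subject; independent of cohort size."""
    return np.random.default_rng(np.random.SeedSequence([seed, trial_id, subject_id]))


def generate_population(spec: PopulationRecord, trial: TrialDesign) -> Population:
    """Generate ``n_trials × n_subjects_per_trial`` virtual individuals.

    Subject k of trial j is drawn from the substream seeded by
    ``(trial.seed, j, k)``; enlarging the cohort never changes already
    generated subjects.
    """
    spec.validate()
    trial.validate()
    individuals = []
    for trial_id in range(1, trial.n_trials + 1):
        for subject_id in range(1, trial.n_subjects_per_trial + 1):
            rng = subject_rng(trial.seed, trial_id, subject_id)
            individuals.append(sample_individual(spec, rng, subject_id, trial_id))
    return Population(
        individuals=tuple(individuals),
        generation_seed=trial.seed,
        spec_reference=spec.name,
    )
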