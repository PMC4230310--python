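"""Parameter estimation against observed data.

Up to 10 workspace parameters (addressed by dotted paths) are fitted to
NONMEM-style observations, either by weighted least squares / maximum
likelihood with derivative-free optimizers — Nelder–Mead simplex,
Hooke–Jeeves pattern search, or a real-coded genetic algorithm — or by
an EM scheme for mixed-effects (population) estimation with lognormal
inter-individual variability, in maximum-likelihood or (with priors)
maximum-a-posteriori flavour.

Parameters whose bounds are strictly positive are log-transformed
internally so optimizer steps are scale-free; a simulation failure at a
candidate θ yields a large finite penalty (1e12) rather than a crash.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .assembly import assemble
from .engine import integrate
from .errors import FitError
from .observed import ObservedDataset
from .paths import set_path
from .population import representative_individual
from .workspace import DoseEvent, Workspace

__all__ = [
    "FitParameter",
    "FitSpec",
    "FitResult",
    "objective_value",
    "fit",
    "fit_population_em",
]

MAX_PARAMETERS = 10
PENALTY = 1.0e12

WEIGHTINGS = ("uniform", "1/obs", "1/obs2")
ERROR_MODELS = ("additive", "proportional", "combined")
METHODS = ("nelder_mead", "hooke_jeeves", "genetic")


@dataclass(frozen=True)
class FitParameter:
    path: str
    initial: float
    lower: float
    upper: float

    def validate(self) -> None:
        if not self.lower <= self.initial <= self.upper:
            raise FitError(f"{self.path}: bounds [{self.lower}, {self.upper}] "
                           f"must contain the initial value {self.initial}")
        if self.lower >= self.upper:
            raise FitError(f"{self.path}: lower bound must be < upper bound")


@dataclass(frozen=True)
class FitSpec:
    parameters: tuple[FitParameter, ...]
    method: str = "nelder_mead"
    objective: str = "wls"  # wls | ml
    weighting: str = "uniform"
    error_model: str = "proportional"
    sigma_add: float = 0.1  # additive sd, observation units
    sigma_prop: float = 0.1  # proportional sd, fraction
    max_evaluations: int = 2000
    objective_tolerance: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        if not 1 <= len(self.parameters) <= MAX_PARAMETERS:
            raise FitError(
                f"{len(self.parameters)} parameters requested; the estimator fits "
                f"between 1 and {MAX_PARAMETERS} parameters simultaneously"
            )
        for p in self.parameters:
            p.validate()
        if self.method not in METHODS:
            raise FitError(f"method must be one of {METHODS}")
        if self.objective not in ("wls", "ml"):
            raise FitError("objective must be wls or ml")
        if self.weighting not in WEIGHTINGS:
            raise FitError(f"weighting must be one of {WEIGHTINGS}")
        if self.error_model not in ERROR_MODELS:
            raise FitError(f"error_model must be one of {ERROR_MODELS}")


@dataclass(frozen=True)
class FitResult:
    estimates: dict[str, float]
    objective: float
    evaluations: int
    converged: bool
    predictions: pd.DataFrame
    omega: dict[str, float] = field(default_factory=dict)
    individual_modes: dict = field(default_factory=dict)
    monitor: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# prediction


def _subject_schedule(w: Workspace, data: ObservedDataset, sid) -> list[DoseEvent]:
    doses = data.doses(sid)
    if doses.empty:
        return list(w.trial.regimens)
    # route follows the selected absorption model: NONMEM-style records
    # carry no route column
    absorption = w.model_selection.for_compound(w.substrate.name).absorption
    if absorption == "iv":
        route = w.substrate.dose_defaults.route
        if route == "oral":
            route = "iv_bolus"
    else:
        route = "oral"
    return [
        DoseEvent(time=float(r["time"]), compound=w.substrate.name, route=route,
                  amount=float(r["amt"]),
                  infusion_duration=w.substrate.dose_defaults.infusion_duration
                  if route == "iv_infusion" else 0.0)
        for _, r in doses.iterrows()
    ]


def _series_for_dvid(w: Workspace, dvid) -> str:
    key = str(dvid)
    if key in ("pk", "1", "1.0"):
        return f"C_{w.substrate.name}"
    if key.startswith("pd:"):
        return f"PD_{key[3:]}"
    return f"PD_{key}"


def predict_subject(w: Workspace, data: ObservedDataset, sid,
                    individual=None) -> pd.DataFrame:
    """Model predictions at one subject's observation records."""
    obs = data.observations(sid)
    if obs.empty:
        return pd.DataFrame(columns=["subject_id", "time", "dvid", "obs", "pred"])
    system = assemble(w.model_selection, w.compounds, w.pd_graph)
    if individual is None:
        individual = representative_individual(w.population)
    times = np.unique(obs["time"].to_numpy(dtype=float))
    if times.size == 1:  # the integrator wants a grid of at least 2 points
        times = np.array([0.0, times[0]]) if times[0] > 0 else np.array([0.0, 1e-6])
    schedule = _subject_schedule(w, data, sid)
    ps = integrate(system, schedule, individual, w.solver_settings, times)
    rows = []
    for _, r in obs.iterrows():
        series = ps.observable(_series_for_dvid(w, r["dvid"]))
        pred = float(np.interp(float(r["time"]), ps.times, series))
        rows.append({"subject_id": sid, "time": float(r["time"]),
                     "dvid": r["dvid"], "obs": float(r["dv"]), "pred": pred})
    return pd.DataFrame(rows)


def _apply_theta(w: Workspace, spec: FitSpec, theta: Sequence[float]) -> Workspace:
    for p, value in zip(spec.parameters, theta):
        w = set_path(w, p.path, float(value))
    return w


def _residual_sd(spec: FitSpec, pred: np.ndarray) -> np.ndarray:
    if spec.error_model == "additive":
        return np.full_like(pred, spec.sigma_add)
    if spec.error_model == "proportional":
        return spec.sigma_prop * np.maximum(np.abs(pred), 1e-12)
    return spec.sigma_add + spec.sigma_prop * np.abs(pred)


def _objective_from_predictions(spec: FitSpec, obs: np.ndarray, pred: np.ndarray) -> float:
    if spec.objective == "wls":
        if spec.weighting == "uniform":
            wgt = np.ones_like(obs)
        elif spec.weighting == "1/obs":
            wgt = 1.0 / np.maximum(np.abs(obs), 1e-12)
        else:
            wgt = 1.0 / np.maximum(obs * obs, 1e-24)
        return float(np.sum(wgt * (obs - pred) ** 2))
    sd = _residual_sd(spec, pred)
    z = (obs - pred) / sd
    return float(np.sum(z * z + np.log(2.0 * math.pi * sd * sd)))


def objective_value(w: Workspace, data: ObservedDataset, spec: FitSpec,
                    theta: Sequence[float], individuals: Optional[dict] = None) -> float:
    """Objective at θ: weighted least squares or −2·log-likelihood.

    Simulation failures return the documented finite penalty so
    optimizers can step away instead of crashing.
    """
    spec.validate()
    for p, value in zip(spec.parameters, theta):
        if not p.lower <= value <= p.upper:
            return PENALTY
    try:
        # candidate θ may be degenerate (zero volumes etc.); the penalty
        # path handles it, so numpy warnings are noise here
        with np.errstate(all="ignore"):
            wt = _apply_theta(w, spec, theta)
            frames = []
            for sid in data.subject_ids:
                ind = individuals.get(sid) if individuals else None
                frames.append(predict_subject(wt, data, sid, ind))
            preds = pd.concat(frames, ignore_index=True)
    except Exception:
        return PENALTY
    if preds.empty:
        raise FitError("no observation records to fit")
    return _objective_from_predictions(
        spec, preds["obs"].to_numpy(float), preds["pred"].to_numpy(float)
    )


# ---------------------------------------------------------------------------
# transforms


def _to_internal(spec: FitSpec, theta: np.ndarray) -> np.ndarray:
    out = np.empty(len(spec.parameters))
    for i, p in enumerate(spec.parameters):
        out[i] = math.log(theta[i]) if p.lower > 0 else theta[i]
    return out


def _from_internal(spec: FitSpec, x: np.ndarray) -> np.ndarray:
    out = np.empty(len(spec.parameters))
    for i, p in enumerate(spec.parameters):
        out[i] = math.exp(x[i]) if p.lower > 0 else x[i]
    return out


def _internal_bounds(spec: FitSpec) -> list[tuple[float, float]]:
    bounds = []
    for p in spec.parameters:
        if p.lower > 0:
            bounds.append((math.log(p.lower), math.log(p.upper)))
        else:
            bounds.append((p.lower, p.upper))
    return bounds


# ---------------------------------------------------------------------------
# optimizers


class _Counter:
    def __init__(self, fn, budget):
        self.fn = fn
        self.budget = budget
        self.calls = 0
        self.best = math.inf
        self.best_x = None

    def __call__(self, x):
        if self.calls >= self.budget:
            return self.best  # freeze once the budget is spent
        self.calls += 1
        value = self.fn(x)
        if value < self.best:
            self.best = value
            self.best_x = np.array(x, dtype=float)
        return value


def _run_nelder_mead(obj, x0, bounds, spec) -> tuple[np.ndarray, float, int, bool]:
    counter = _Counter(obj, spec.max_evaluations)
    res = minimize(
        counter, x0, method="Nelder-Mead", bounds=bounds,
        options={"maxfev": spec.max_evaluations, "fatol": spec.objective_tolerance,
                 "xatol": 1e-8},
    )
    return counter.best_x, counter.best, counter.calls, bool(res.success)


def _run_hooke_jeeves(obj, x0, bounds, spec) -> tuple[np.ndarray, float, int, bool]:
    """Classic pattern search: exploratory ± step moves per coordinate
    around the trial point, pattern moves doubling successful directions,
    step halved on failure; initial step 10% of each range, stop at 1e-5
    of the range or on the evaluation budget.  (The finer stop is needed
    for sub-0.1% recovery in correlated clearance–volume valleys.)"""
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    ranges = hi - lo
    step = 0.1 * ranges
    stop = 1e-5 * ranges
    counter = _Counter(obj, spec.max_evaluations)

    def explore(point, f_point):
        x = point.copy()
        fx = f_point
        for i in range(x.size):
            for direction in (+1.0, -1.0):
                trial = x.copy()
                trial[i] = np.clip(trial[i] + direction * step[i], lo[i], hi[i])
                f_trial = counter(trial)
                if f_trial < fx:
                    x, fx = trial, f_trial
                    break
        return x, fx

    base = np.array(x0, dtype=float)
    f_base = counter(base)
    trial, f_trial = base, f_base
    while counter.calls < spec.max_evaluations and (step > stop).any():
        new, f_new = explore(trial, f_trial)
        if f_new < f_base:
            # pattern move: continue along base → new
            trial = np.clip(new + (new - base), lo, hi)
            base, f_base = new, f_new
            f_trial = counter(trial)
        else:
            if np.array_equal(trial, base):
                step *= 0.5
            trial, f_trial = base, f_base
    converged = bool((step <= stop).all())
    return counter.best_x, counter.best, counter.calls, converged


def _run_genetic(obj, x0, bounds, spec) -> tuple[np.ndarray, float, int, bool]:
    """Real-coded GA: population 40, tournament selection (k=3), blend
    crossover (BLX-0.5), Gaussian mutation, 2 elites; deterministic for
    a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    span = hi - lo
    pop_size, n_elite = 40, 2
    counter = _Counter(obj, spec.max_evaluations)

    pop = rng.uniform(lo, hi, size=(pop_size, lo.size))
    pop[0] = np.clip(np.array(x0, dtype=float), lo, hi)
    fitness = np.array([counter(ind) for ind in pop])

    while counter.calls + pop_size <= spec.max_evaluations:
        order = np.argsort(fitness)
        new_pop = [pop[i].copy() for i in order[:n_elite]]
        while len(new_pop) < pop_size:
            contenders = rng.integers(0, pop_size, size=3)
            a = pop[contenders[np.argmin(fitness[contenders])]]
            contenders = rng.integers(0, pop_size, size=3)
            b = pop[contenders[np.argmin(fitness[contenders])]]
            low = np.minimum(a, b) - 0.5 * np.abs(a - b)
            high = np.maximum(a, b) + 0.5 * np.abs(a - b)
            child = rng.uniform(low, high)
            mutate = rng.random(child.size) < 0.2
            child = np.where(mutate, child + rng.normal(0.0, 0.1 * span), child)
            new_pop.append(np.clip(child, lo, hi))
        pop = np.array(new_pop)
        fitness = np.array([counter(ind) for ind in pop])
        if fitness.min() <= spec.objective_tolerance:
            break
    return counter.best_x, counter.best, counter.calls, True


_OPTIMIZERS = {
    "nelder_mead": _run_nelder_mead,
    "hooke_jeeves": _run_hooke_jeeves,
    "genetic": _run_genetic,
}


def fit(w: Workspace, data: ObservedDataset, spec: FitSpec) -> FitResult:
    """Bounded fit of the spec'd parameters by the chosen optimizer."""
    spec.validate()
    w.validate()

    def obj(x):
        return objective_value(w, data, spec, _from_internal(spec, np.asarray(x)))

    x0 = _to_internal(spec, np.array([p.initial for p in spec.parameters]))
    bounds = _internal_bounds(spec)
    best_x, best_f, calls, converged = _OPTIMIZERS[spec.method](obj, x0, bounds, spec)
    theta = _from_internal(spec, best_x)
    estimates = {p.path: float(v) for p, v in zip(spec.parameters, theta)}
    wt = _apply_theta(w, spec, theta)
    preds = pd.concat(
        [predict_subject(wt, data, sid) for sid in data.subject_ids], ignore_index=True
    )
    return FitResult(
        estimates=estimates,
        objective=float(best_f),
        evaluations=calls,
        converged=converged,
        predictions=preds,
    )


# ---------------------------------------------------------------------------
# EM mixed-effects estimation


OMEGA_FLOOR = 0.05  # effective minimum ω during the E-step (keeps it mobile)


def fit_population_em(
    w: Workspace,
    data: ObservedDataset,
    spec: FitSpec,
    iiv_spec: dict[str, float],
    priors: Optional[dict[str, tuple[float, float]]] = None,
    max_iterations: int = 20,
    rel_tolerance: float = 1e-3,
    monitor_patience: int = 3,
) -> FitResult:
    """EM estimation of population parameters with lognormal IIV.

    ``iiv_spec`` maps a subset of the fitted parameter paths to initial
    ω values (sd of the log random effect).  E-step: per-subject MAP
    mode of η given the current population values; M-step: population
    update by the geometric mean of the individual modes and a moment
    update of ω² with a Laplace shrinkage correction (mean of
    η̂² + posterior variance).  Passing ``priors`` (path → (mean, sd of
    ln θ)) turns the M-step into its MAP variant.  The convergence
    monitor is the penalised −2·log-likelihood; more than
    ``monitor_patience`` consecutive increases flag non-convergence but
    a result is still returned.
    """
    spec.validate()
    if data.n_subjects < 2:
        raise FitError("population EM estimation requires at least 2 subjects")
    for path in iiv_spec:
        if path not in [p.path for p in spec.parameters]:
            raise FitError(f"iiv_spec path {path!r} is not among the fitted parameters")

    params = {p.path: p for p in spec.parameters}
    theta = {p.path: p.initial for p in spec.parameters}
    omega2 = {path: max(om, 0.0) ** 2 for path, om in iiv_spec.items()}
    rng_paths = list(iiv_spec)
    subject_ids = data.subject_ids
    n = len(subject_ids)

    def subject_objective(sid, eta_vec) -> float:
        wt = w
        for path in theta:
            value = theta[path]
            if path in omega2:
                value *= math.exp(eta_vec[rng_paths.index(path)])
            value = min(max(value, params[path].lower), params[path].upper)
            wt = set_path(wt, path, value)
        try:
            preds = predict_subject(wt, data, sid)
        except Exception:
            return PENALTY
        return _objective_from_predictions(
            spec, preds["obs"].to_numpy(float), preds["pred"].to_numpy(float)
        )

    monitor: list[float] = []
    increases = 0
    eta_modes = {sid: np.zeros(len(rng_paths)) for sid in subject_ids}
    eta_vars = {sid: np.zeros(len(rng_paths)) for sid in subject_ids}

    for iteration in range(max_iterations):
        om_eff = {path: max(math.sqrt(omega2[path]), OMEGA_FLOOR) for path in rng_paths}

        # E-step: per-subject posterior modes of η ------------------------
        total_obj = 0.0
        for sid in subject_ids:
            if len(rng_paths) == 1:
                om = om_eff[rng_paths[0]]

                def g(e):
                    return subject_objective(sid, np.array([e])) + (e / om) ** 2

                res = minimize_scalar(g, bounds=(-4.0 * om, 4.0 * om), method="bounded",
                                      options={"xatol": 1e-6})
                eta_hat = np.array([res.x])
                g_hat = res.fun
                h = 1e-3
                second = (g(res.x + h) - 2.0 * g_hat + g(res.x - h)) / (h * h)
            else:
                oms = np.array([om_eff[p] for p in rng_paths])

                def g(e):
                    return subject_objective(sid, e) + float(np.sum((e / oms) ** 2))

                res = minimize(g, eta_modes[sid], method="Nelder-Mead",
                               options={"xatol": 1e-4, "fatol": 1e-6})
                eta_hat = res.x
                g_hat = res.fun
                h = 1e-3
                second = np.mean([
                    (g(eta_hat + h * ev) - 2.0 * g_hat + g(eta_hat - h * ev)) / (h * h)
                    for ev in np.eye(len(rng_paths))
                ])
            eta_modes[sid] = eta_hat
            # g is −2·log posterior: curvature/2 is the precision
            var = 2.0 / second if second > 0 else om_eff[rng_paths[0]] ** 2
            eta_vars[sid] = np.full(len(rng_paths), max(var, 0.0))
            total_obj += g_hat
        total_obj += n * sum(math.log(max(omega2[p], OMEGA_FLOOR**2)) for p in rng_paths)

        # M-step ----------------------------------------------------------
        etas = np.array([eta_modes[sid] for sid in subject_ids])  # n × k
        variances = np.array([eta_vars[sid] for sid in subject_ids])
        mean_eta = etas.mean(axis=0)
        for k, path in enumerate(rng_paths):
            new_log = math.log(theta[path]) + mean_eta[k]
            if priors and path in priors:
                pm, ps = priors[path]
                w_data = n / max(omega2[path], OMEGA_FLOOR**2)
                w_prior = 1.0 / (ps * ps)
                new_log = (w_data * new_log + w_prior * math.log(pm)) / (w_data + w_prior)
            theta[path] = min(max(math.exp(new_log), params[path].lower), params[path].upper)
            centred = etas[:, k] - mean_eta[k]
            omega2[path] = float(np.mean(centred**2 + variances[:, k]))
        for sid in subject_ids:  # recentre the modes around the updated mean
            eta_modes[sid] = eta_modes[sid] - mean_eta

        monitor.append(total_obj)
        if len(monitor) >= 2:
            prev, cur = monitor[-2], monitor[-1]
            if cur > prev + 1e-8 * max(1.0, abs(prev)):
                increases += 1
            else:
                increases = 0
            if abs(cur - prev) <= rel_tolerance * max(1.0, abs(prev)):
                break

    converged = increases <= monitor_patience
    estimates = dict(theta)
    omega = {path: math.sqrt(max(om2, 0.0)) for path, om2 in omega2.items()}
    wt = w
    for path, value in estimates.items():
        wt = set_path(wt, path, value)
    preds = pd.concat(
        [predict_subject(wt, data, sid) for sid in subject_ids], ignore_index=True
    )
    return FitResult(
        estimates=estimates,
        objective=float(monitor[-1]) if monitor else math.inf,
        evaluations=0,
        converged=converged,
        predictions=preds,
        omega=omega,
        individual_modes={sid: eta_modes[sid].copy() for sid in subject_ids},
        monitor=tuple(monitor),
    )
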