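"""Pharmacodynamic response units and their graph.

Responses are composed from two unit kinds wired into a directed
acyclic graph: *basic* units transform a driving concentration into a
response algebraically (linear, Emax, sigmoid Emax, receptor occupancy,
operational agonism), while *link* units carry dynamics — effect
compartment, the four turnover (indirect-response) types, disease
progression trends and a proportional-hazards survival state — and
contribute states to the assembled ODE system.

Fan-out (one unit feeding several downstream units) is deliberately
rejected: response splitting is not part of the supported motif set.
"""

from __future__ import annotations

import math
from typing import Iterable

import networkx as nx
import numpy as np

from .errors import GraphError, ValidationError
from .workspace import PDGraph, PDUnit

__all__ = [
    "validate_graph",
    "direct_response",
    "operational_response",
    "drug_stimulation",
    "drug_inhibition",
    "time_summary",
    "evaluate_basic",
    "link_state_count",
    "link_initial",
    "link_gradient",
    "link_output",
    "evaluate_long",
]


# ---------------------------------------------------------------------------
# graph structure


def validate_graph(g: PDGraph) -> list[str]:
    """Check acyclicity and the single-consumer rule; return a topological
    evaluation order of unit ids."""
    ids = [u.unit_id for u in g.units]
    if len(set(ids)) != len(ids):
        raise GraphError("duplicate unit ids in PD graph")
    dg = nx.DiGraph()
    dg.add_nodes_from(ids)
    for u in g.units:
        if u.input.startswith("unit:"):
            upstream = u.input.split(":", 1)[1]
            if upstream not in dg:
                raise GraphError(f"unit {u.unit_id!r} references unknown upstream unit {upstream!r}")
            dg.add_edge(upstream, u.unit_id)
    try:
        order = list(nx.topological_sort(dg))
    except nx.NetworkXUnfeasible:
        cycle = [a for a, _ in nx.find_cycle(dg)]
        raise GraphError(f"PD graph contains a cycle through units {cycle}") from None
    for node in dg:
        if dg.out_degree(node) > 1:
            sinks = sorted(dg.successors(node))
            raise GraphError(
                f"unit {node!r} feeds {len(sinks)} downstream units {sinks}; "
                "response splitting is unsupported"
            )
    for u in g.units:
        if u.timescale == "long":
            if not u.input.startswith("unit:"):
                raise GraphError(f"long-timescale unit {u.unit_id!r} must be fed by a summary unit")
            upstream = g.unit(u.input.split(":", 1)[1])
            if not upstream.timescale.startswith("summary:"):
                raise GraphError(
                    f"long-timescale unit {u.unit_id!r} requires a time-independent "
                    f"(summary) input, got timescale {upstream.timescale!r}"
                )
    return order


# ---------------------------------------------------------------------------
# direct (basic) responses


def direct_response(model: str, C, params: dict) -> np.ndarray | float:
    """Algebraic concentration-response transforms.

    linear: E0 + S·C; emax: E0 + Emax·C/(EC50+C);
    sigmoid_emax: E0 + Emax·Cⁿ/(EC50ⁿ+Cⁿ); occupancy: C/(KA+C).
    """
    C = np.asarray(C, dtype=float)
    if model == "linear":
        return params.get("e0", 0.0) + params.get("slope", 1.0) * C
    if model in ("emax", "sigmoid_emax"):
        ec50 = params.get("ec50", 1.0)
        if ec50 <= 0:
            raise ValidationError("ec50", "must be > 0")
        n = params.get("n", 1.0) if model == "sigmoid_emax" else 1.0
        cn = np.power(C, n)
        return params.get("e0", 0.0) + params.get("emax", 1.0) * cn / (ec50**n + cn)
    if model == "occupancy":
        ka = params.get("ka", 1.0)
        if ka <= 0:
            raise ValidationError("ka", "binding constant must be > 0")
        return C / (ka + C)
    if model == "operational":
        return operational_response(C, params)
    raise ValidationError("model", f"unknown basic model {model!r}")


def operational_response(C, params: dict) -> np.ndarray | float:
    """Operational model of agonism (transducer-ratio parameterisation):

        E = Em·τⁿCⁿ / ((KA + C)ⁿ + τⁿCⁿ)

    τ is the transducer ratio; τ→∞ recovers a full agonist (E→Em), and
    for n = 1 the model collapses to an Emax form with
    Emax = Em·τ/(1+τ) and EC50 = KA/(1+τ).
    """
    ka = params.get("ka", 1.0)
    tau = params.get("tau", 1.0)
    if ka <= 0:
        raise ValidationError("ka", "must be > 0")
    if tau < 0:
        raise ValidationError("tau", "must be >= 0")
    em = params.get("em", 1.0)
    n = params.get("n", 1.0)
    C = np.asarray(C, dtype=float)
    tc = np.power(tau * C, n)
    return em * tc / (np.power(ka + C, n) + tc)


def _stimulus_response(stimulus, em: float):
    """Hyperbolic stimulus-response used by the transduction modes."""
    s = np.asarray(stimulus, dtype=float)
    return em * s / (1.0 + s)


def evaluate_basic(unit: PDUnit, drive, receptor_abundance: float = 1.0):
    """Evaluate a basic unit under its transduction mode.

    empirical: plain model transform of the drive.
    operational: a pk-driven unit produces receptor occupancy; a
      unit-driven one applies the operational transform to the upstream
      occupancy (E = Em·(τ·occ)ⁿ/(1+(τ·occ)ⁿ), algebraically identical
      to the concentration form).
    intrinsic_efficacy: stimulus = ε·R0·occupancy with the receptor
      abundance R0 drawn from the population, then a hyperbolic
      stimulus-response.
    """
    p = unit.params
    if unit.transduction == "empirical":
        return direct_response(unit.model, drive, p)
    occ_input = unit.input.startswith("pk:")
    if occ_input:
        occ = direct_response("occupancy", drive, p)
    else:
        occ = np.asarray(drive, dtype=float)
    if unit.transduction == "operational":
        if occ_input and unit.model == "occupancy":
            return occ
        tau = p.get("tau", 1.0)
        n = p.get("n", 1.0)
        return _stimulus_response(np.power(tau * occ, n), p.get("em", 1.0))
    # intrinsic_efficacy
    eps = p.get("efficacy", 1.0)
    stimulus = eps * receptor_abundance * occ
    return _stimulus_response(stimulus, p.get("em", 1.0))


# drug functions for turnover models ----------------------------------------


def drug_stimulation(C, params: dict):
    smax = params.get("smax", 1.0)
    sc50 = params.get("sc50", 1.0)
    if sc50 <= 0:
        raise ValidationError("sc50", "must be > 0")
    C = np.asarray(C, dtype=float)
    return smax * C / (sc50 + C)


def drug_inhibition(C, params: dict):
    imax = params.get("imax", 1.0)
    ic50 = params.get("ic50", 1.0)
    if not 0 <= imax <= 1:
        raise ValidationError("imax", "must be in [0, 1]")
    if ic50 <= 0:
        raise ValidationError("ic50", "must be > 0")
    C = np.asarray(C, dtype=float)
    return imax * C / (ic50 + C)


# ---------------------------------------------------------------------------
# link units: states, gradients, outputs

_LINK_STATES = {
    "effect_compartment": 1,
    "indirect_1": 1,
    "indirect_2": 1,
    "indirect_3": 1,
    "indirect_4": 1,
    "progression_linear": 1,
    "progression_asymptotic": 1,
    "survival": 1,
}


def link_state_count(unit: PDUnit) -> int:
    if unit.model == "custom":
        return int(unit.params.get("n_states", 1))
    return _LINK_STATES[unit.model]


def _check_positive(params: dict, names: Iterable[str]) -> None:
    for name in names:
        if params.get(name, 1.0) <= 0:
            raise ValidationError(name, "must be > 0")


def link_initial(unit: PDUnit) -> list[float]:
    p = unit.params
    if unit.model == "effect_compartment":
        _check_positive(p, ["ke0"])
        return [p.get("ce0", 0.0)]
    if unit.model.startswith("indirect"):
        _check_positive(p, ["kin", "kout"])
        return [p.get("kin", 1.0) / p.get("kout", 1.0)]
    if unit.model in ("progression_linear", "progression_asymptotic"):
        return [p.get("p0", 0.0)]
    if unit.model == "survival":
        return [0.0]  # cumulative hazard Λ
    raise ValidationError("model", f"link model {unit.model!r} has no built-in states")


def link_gradient(unit: PDUnit, drive: float, states: np.ndarray) -> list[float]:
    """Time gradient of a link unit's states given its driving input."""
    p = unit.params
    if unit.model == "effect_compartment":
        ke0 = p.get("ke0", 1.0)
        return [ke0 * (drive - states[0])]
    if unit.model.startswith("indirect"):
        kin = p.get("kin", 1.0)
        kout = p.get("kout", 1.0)
        R = states[0]
        if unit.model == "indirect_1":
            return [kin * (1.0 - drug_inhibition(drive, p)) - kout * R]
        if unit.model == "indirect_2":
            return [kin - kout * (1.0 - drug_inhibition(drive, p)) * R]
        if unit.model == "indirect_3":
            return [kin * (1.0 + drug_stimulation(drive, p)) - kout * R]
        return [kin - kout * (1.0 + drug_stimulation(drive, p)) * R]
    if unit.model == "progression_linear":
        return [p.get("alpha", 0.0) + p.get("beta", 0.0) * drive]
    if unit.model == "progression_asymptotic":
        kprog = p.get("kprog", 0.1)
        return [kprog * (p.get("pss", 1.0) - states[0]) + p.get("beta", 0.0) * drive]
    if unit.model == "survival":
        h0 = p.get("h0", 0.0)
        if h0 < 0:
            raise ValidationError("h0", "baseline hazard must be >= 0")
        return [h0 * math.exp(p.get("beta", 0.0) * drive)]
    raise ValidationError("model", f"link model {unit.model!r} has no built-in gradient")


def link_output(unit: PDUnit, states: np.ndarray):
    """Map a link unit's states to its scalar output (S(t) for survival)."""
    if unit.model == "survival":
        return np.exp(-np.asarray(states[0], dtype=float))
    return states[0]


# ---------------------------------------------------------------------------
# time summaries and the long timescale


def time_summary(times, profile, metric: str) -> float:
    """Collapse a response profile to a scalar: cmax, auc (trapezoid),
    value_at(t), or mean (time-averaged)."""
    times = np.asarray(times, dtype=float)
    profile = np.asarray(profile, dtype=float)
    if times.size == 0:
        raise ValidationError("profile", "must be nonempty")
    if metric == "cmax":
        return float(profile.max())
    if metric == "auc":
        return float(np.trapezoid(profile, times))
    if metric == "mean":
        span = times[-1] - times[0]
        if span == 0:
            return float(profile[0])
        return float(np.trapezoid(profile, times) / span)
    if metric.startswith("value_at("):
        t = float(metric[len("value_at("):-1])
        if not (times[0] <= t <= times[-1]):
            raise ValidationError("value_at", f"t={t} outside the observation grid")
        return float(np.interp(t, times, profile))
    raise ValidationError("metric", f"unknown summary metric {metric!r}")


def evaluate_long(unit: PDUnit, scalar_drive: float, horizon_times) -> np.ndarray:
    """Evaluate a long-timescale link unit on a constant (summarised) drive.

    With the drive time-independent the link ODEs have closed forms;
    e.g. survival gives S(t) = exp(−h0·e^{β·drv}·t).
    """
    t = np.asarray(horizon_times, dtype=float)
    p = unit.params
    if unit.model == "survival":
        hazard = p.get("h0", 0.0) * math.exp(p.get("beta", 0.0) * scalar_drive)
        return np.exp(-hazard * t)
    if unit.model == "progression_linear":
        return p.get("p0", 0.0) + (p.get("alpha", 0.0) + p.get("beta", 0.0) * scalar_drive) * t
    if unit.model == "progression_asymptotic":
        kprog = p.get("kprog", 0.1)
        pss = p.get("pss", 1.0) + p.get("beta", 0.0) * scalar_drive / max(kprog, 1e-300)
        p0 = p.get("p0", 0.0)
        return pss + (p0 - pss) * np.exp(-kprog * t)
    if unit.model == "effect_compartment":
        ke0 = p.get("ke0", 1.0)
        ce0 = p.get("ce0", 0.0)
        return scalar_drive + (ce0 - scalar_drive) * np.exp(-ke0 * t)
    if unit.model.startswith("indirect"):
        # constant drive: R relaxes mono-exponentially to its driven steady state
        kin = p.get("kin", 1.0)
        kout = p.get("kout", 1.0)
        if unit.model == "indirect_1":
            kin = kin * (1.0 - drug_inhibition(scalar_drive, p))
        elif unit.model == "indirect_2":
            kout = kout * (1.0 - drug_inhibition(scalar_drive, p))
        elif unit.model == "indirect_3":
            kin = kin * (1.0 + drug_stimulation(scalar_drive, p))
        else:
            kout = kout * (1.0 + drug_stimulation(scalar_drive, p))
        r0 = p.get("kin", 1.0) / p.get("kout", 1.0)
        rss = kin / kout
        return rss + (r0 - rss) * np.exp(-kout * t)
    raise ValidationError("model", f"model {unit.model!r} has no long-timescale form")
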