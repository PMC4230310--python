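"""Run a workspace end to end: population → assembly → integration → tables.

This is the layer the CLI, the sensitivity tool, the estimator and the
autotest harness all build on.  Output tables are plain DataFrames
rendered to RFC-4180 CSV with '.' decimal separators and no locale
formatting, so re-running a workspace at the same seed reproduces the
files byte for byte.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import AssembledODESystem, assemble
from .codec import encode_profile
from .engine import ProfileSet, SubjectProfile, integrate
from .pdmodels import evaluate_long, time_summary
from .population import Individual, generate_population, representative_individual
from .workspace import Workspace

__all__ = ["RunMetrics", "SimulationResult", "run_workspace", "simulate_subject", "pk_endpoints"]

CSV_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class RunMetrics:
    """Per-simulation metrics tracked by the regression harness."""

    n_states: int
    internal_steps: int
    wall_time_s: float
    stored_profile_bytes: int
    solver_switches: int = 0
    n_subjects: int = 1

    def to_dict(self) -> dict:
        return {
            "n_states": self.n_states,
            "internal_steps": self.internal_steps,
            "wall_time_s": self.wall_time_s,
            "stored_profile_bytes": self.stored_profile_bytes,
            "solver_switches": self.solver_switches,
            "n_subjects": self.n_subjects,
        }


@dataclass(frozen=True)
class SimulationResult:
    workspace: Workspace
    tables: dict[str, pd.DataFrame]
    metrics: RunMetrics
    profiles: ProfileSet = None


def pk_endpoints(times: np.ndarray, conc: np.ndarray) -> dict[str, float]:
    """Standard non-compartmental endpoints of one concentration profile."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    i_max = int(np.argmax(conc))
    return {
        "auc": float(np.trapezoid(conc, times)),
        "cmax": float(conc[i_max]),
        "tmax": float(times[i_max]),
        "css": float(conc[-1]),
    }


def simulate_subject(w: Workspace, individual: Individual,
                     system: AssembledODESystem | None = None) -> ProfileSet:
    """Integrate one individual under the workspace's trial design."""
    if system is None:
        system = assemble(w.model_selection, w.compounds, w.pd_graph)
    return integrate(
        system,
        w.trial.regimens,
        individual,
        w.solver_settings,
        w.trial.observations.times(),
    )


def _subject_label(p: SubjectProfile) -> str:
    return f"t{p.trial_id}s{p.subject_id}"


def run_workspace(w: Workspace, subjects: str = "population") -> SimulationResult:
    """Run the workspace and build its selected output tables.

    ``subjects='representative'`` runs the single population-representative
    individual (used by the sensitivity tool); the default simulates the
    full virtual population of the trial design.
    """
    w.validate()
    t0 = _time.perf_counter()
    system = assemble(w.model_selection, w.compounds, w.pd_graph)
    if subjects == "representative":
        individuals = [representative_individual(w.population)]
    else:
        individuals = list(generate_population(w.population, w.trial).individuals)

    times = w.trial.observations.times()
    profiles: list[SubjectProfile] = []
    total_steps = 0
    stored_bytes = 0
    for ind in individuals:
        ps = integrate(system, w.trial.regimens, ind, w.solver_settings, times,
                       ctx=system.build_context(ind))
        sp = ps.subjects[0]
        profiles.append(sp)
        total_steps += ps.solver_log["internal_steps"]
        for series in sp.observables.values():
            stored_bytes += encode_profile(series).nbytes
    profile_set = ProfileSet(times=times, subjects=tuple(profiles))

    tables = _build_tables(w, system, profile_set, individuals)
    metrics = RunMetrics(
        n_states=system.n_states,
        internal_steps=total_steps,
        wall_time_s=_time.perf_counter() - t0,
        stored_profile_bytes=stored_bytes,
        n_subjects=len(individuals),
    )
    return SimulationResult(workspace=w, tables=tables, metrics=metrics, profiles=profile_set)


def _build_tables(w: Workspace, system: AssembledODESystem,
                  profiles: ProfileSet,
                  individuals: list[Individual] | None = None) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    times = profiles.times
    selection = set(w.output_selection)

    if "plasma_concentration" in selection:
        data = {"time_h": times}
        for name in w.model_selection.compound_models:
            for p in profiles.subjects:
                data[f"{name}_{_subject_label(p)}"] = p.observables[f"C_{name}"]
        tables["plasma_concentration"] = pd.DataFrame(data)

    if "summary" in selection:
        rows = []
        for name in w.model_selection.compound_models:
            for p in profiles.subjects:
                ep = pk_endpoints(times, p.observables[f"C_{name}"])
                rows.append({"compound": name, "trial": p.trial_id,
                             "subject": p.subject_id, **ep})
        tables["summary"] = pd.DataFrame(rows)

    if w.pd_graph is not None and "pd_response" in selection:
        data = {"time_h": times}
        for u in w.pd_graph.units:
            if u.timescale == "long":
                continue
            for p in profiles.subjects:
                data[f"{u.unit_id}_{_subject_label(p)}"] = p.observables[f"PD_{u.unit_id}"]
        tables["pd_response"] = pd.DataFrame(data)

    if w.pd_graph is not None and any(
        u.timescale.startswith("summary:") or u.timescale == "long" for u in w.pd_graph.units
    ):
        rows = []
        scalars: dict[tuple[str, str], float] = {}  # (unit, subject label) -> value
        for u in w.pd_graph.units:
            if not u.timescale.startswith("summary:"):
                continue
            metric = u.timescale.split(":", 1)[1]
            for p in profiles.subjects:
                value = time_summary(times, p.observables[f"PD_{u.unit_id}"], metric)
                scalars[(u.unit_id, _subject_label(p))] = value
                rows.append({"unit": u.unit_id, "trial": p.trial_id,
                             "subject": p.subject_id, "metric": metric, "value": value})
        for u in w.pd_graph.units:
            if u.timescale != "long":
                continue
            upstream = u.input.split(":", 1)[1]
            horizon = u.params.get("horizon", 1000.0)
            grid = np.linspace(0.0, horizon, 101)
            for p in profiles.subjects:
                drive = scalars[(upstream, _subject_label(p))]
                series = evaluate_long(u, drive, grid)
                rows.append({"unit": u.unit_id, "trial": p.trial_id,
                             "subject": p.subject_id, "metric": f"long_end@{horizon:g}h",
                             "value": float(series[-1])})
        if rows:
            tables["pd_summary"] = pd.DataFrame(rows)

    if "individuals" in selection and individuals:
        rows = []
        for ind in individuals:
            row = {"trial": ind.trial_id, "subject": ind.subject_id,
                   "age_y": ind.age, "sex": ind.sex, "body_weight_kg": ind.body_weight}
            row.update({f"V_{o}_L": v for o, v in sorted(ind.organ_volumes.items())})
            row.update({f"Q_{o}_Lh": v for o, v in sorted(ind.organ_flows.items())})
            row.update({f"{e}_pmol_mg": v for e, v in sorted(ind.enzyme_abundances.items())})
            row.update(ind.parameters)
            rows.append(row)
        tables["individuals"] = pd.DataFrame(rows)

    return tables


def write_tables(tables: dict[str, pd.DataFrame], directory) -> list[str]:
    """Write each table as ``<name>.csv`` (RFC 4180, UTF-8); returns paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for name, df in tables.items():
        path = os.path.join(directory, f"{name}.csv")
        df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")
        paths.append(path)
    return paths
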