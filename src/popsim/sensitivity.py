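"""Automated local sensitivity analysis.

One or two workspace parameters are scanned over a grid (linear or
geometric step distribution) for the population-representative subject;
each grid point re-runs the simulation and reports the selected
endpoints together with a sensitivity index

    SI = (E − E_base) / (p − p_base)

and an elasticity index

    EI = SI · p_base / E_base

both taken as secant differences against the workspace's current
(baseline) parameter value.  EI is dimensionless: for an endpoint that
is a pure power law a·p^k, EI → k as the grid point approaches the
baseline.  At most two parameters are scanned at a time; whole-
population or higher-dimensional scans belong to batch processing, not
to this tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import assemble
from .engine import integrate
from .errors import ScanError, ValidationError
from .paths import get_path, set_path
from .pdmodels import time_summary
from .population import representative_individual
from .simulate import pk_endpoints
from .workspace import Workspace

__all__ = ["ParameterScan", "ASAResult", "build_grid", "run_scan", "SUPPORTED_ENDPOINTS"]

SUPPORTED_ENDPOINTS = ("auc", "cmax", "tmax", "css")
MAX_SCANS = 2


@dataclass(frozen=True)
class ParameterScan:
    parameter_path: str
    min: float
    max: float
    steps: int
    spacing: str = "linear"

    def validate(self) -> None:
        if self.min >= self.max:
            raise ScanError(f"{self.parameter_path}: min must be < max")
        if self.steps < 2:
            raise ScanError(f"{self.parameter_path}: steps must be >= 2")
        if self.spacing not in ("linear", "log"):
            raise ScanError(f"{self.parameter_path}: spacing must be linear or log")
        if self.spacing == "log" and self.min <= 0:
            raise ScanError(f"{self.parameter_path}: log spacing requires min > 0")


@dataclass(frozen=True)
class ASAResult:
    scans: tuple[ParameterScan, ...]
    grids: tuple[np.ndarray, ...]
    baseline_values: tuple[float, ...]
    baseline_endpoints: dict[str, float]
    table: pd.DataFrame  # grid values, endpoints, SI/EI per endpoint


def build_grid(scan: ParameterScan) -> np.ndarray:
    """Inclusive grid from min to max: arithmetic or geometric progression."""
    scan.validate()
    if scan.spacing == "linear":
        return np.linspace(scan.min, scan.max, scan.steps)
    return np.geomspace(scan.min, scan.max, scan.steps)


def _endpoint_names(endpoints, w: Workspace) -> list[str]:
    names = []
    pd_units = {u.unit_id for u in (w.pd_graph.units if w.pd_graph else ())}
    for name in endpoints:
        key = name.lower()
        if key in SUPPORTED_ENDPOINTS:
            names.append(key)
        elif key.startswith("pd_"):
            uid = name[3:].split(":")[0]
            if uid not in pd_units:
                raise ValidationError("endpoints", f"unknown PD unit in endpoint {name!r}")
            names.append(name)
        else:
            raise ValidationError(
                "endpoints",
                f"unknown endpoint {name!r}; supported: {SUPPORTED_ENDPOINTS} and pd_<unit>[:metric]",
            )
    return names


def _evaluate_endpoints(w: Workspace, names: list[str]) -> dict[str, float]:
    system = assemble(w.model_selection, w.compounds, w.pd_graph)
    individual = representative_individual(w.population)
    times = w.trial.observations.times()
    ps = integrate(system, w.trial.regimens, individual, w.solver_settings, times)
    conc = ps.observable(f"C_{w.substrate.name}")
    base = pk_endpoints(times, conc)
    out = {}
    for name in names:
        if name in SUPPORTED_ENDPOINTS:
            out[name] = base[name]
        else:
            uid, _, metric = name[3:].partition(":")
            out[name] = time_summary(times, ps.observable(f"PD_{uid}"), metric or "auc")
    return out


def run_scan(w: Workspace, scans, endpoints) -> ASAResult:
    """Scan one or two parameters and report endpoints with SI/EI.

    The baseline run (the workspace's current parameter values) is
    included in the outputs; where the baseline endpoint is zero the
    elasticity is reported as missing rather than infinite.
    """
    scans = tuple(scans)
    if not 1 <= len(scans) <= MAX_SCANS:
        raise ScanError(
            f"{len(scans)} scans requested; the tool accepts a maximum of {MAX_SCANS} at a time"
        )
    names = _endpoint_names(endpoints, w)
    w.validate()
    grids = tuple(build_grid(s) for s in scans)
    base_values = tuple(float(get_path(w, s.parameter_path)) for s in scans)
    base_endpoints = _evaluate_endpoints(w, names)

    mesh = np.meshgrid(*grids, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=-1)

    rows = []
    for point in points:
        wp = w
        for scan, value in zip(scans, point):
            wp = set_path(wp, scan.parameter_path, float(value))
        values = _evaluate_endpoints(wp, names)
        row: dict = {
            scan.parameter_path: float(v) for scan, v in zip(scans, point)
        }
        at_baseline = all(
            math.isclose(v, b, rel_tol=1e-12) for v, b in zip(point, base_values)
        )
        for name in names:
            e, e0 = values[name], base_endpoints[name]
            row[name] = e
            if at_baseline:
                si = ei = float("nan")
            else:
                # secant against the baseline along the first moved axis
                dp = next(
                    (float(v) - b for v, b in zip(point, base_values)
                     if not math.isclose(float(v), b, rel_tol=1e-12)),
                    float("nan"),
                )
                p0 = next(
                    (b for v, b in zip(point, base_values)
                     if not math.isclose(float(v), b, rel_tol=1e-12)),
                    float("nan"),
                )
                si = (e - e0) / dp
                ei = si * p0 / e0 if e0 != 0.0 else float("nan")
            row[f"SI_{name}"] = si
            row[f"EI_{name}"] = ei
        rows.append(row)

    baseline_row: dict = {scan.parameter_path: b for scan, b in zip(scans, base_values)}
    for name in names:
        baseline_row[name] = base_endpoints[name]
        baseline_row[f"SI_{name}"] = float("nan")
        baseline_row[f"EI_{name}"] = float("nan")
    table = pd.DataFrame([baseline_row] + rows)
    return ASAResult(
        scans=scans,
        grids=grids,
        baseline_values=base_values,
        baseline_endpoints=base_endpoints,
        table=table,
    )
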