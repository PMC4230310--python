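"""Regression autotesting of workspace repositories.

A directory of workspaces is run end to end, each producing a results
bundle and run metrics; a comparison pass then checks the current CSV
outputs against committed benchmarks cell by cell with a relative
threshold (1% by default) and an absolute floor below which differences
are noise.  Failures are isolated per workspace: one corrupt file never
suppresses the results of the others.  Benchmarks are regenerated only
by an explicit bless.
"""

from __future__ import annotations

import os
import traceback
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundle import write_results_bundle
from .errors import ValidationError
from .simulate import RunMetrics, run_workspace, write_tables
from .xmlio import load_workspace

__all__ = [
    "ComparisonSettings",
    "Discrepancy",
    "DiscrepancyReport",
    "RepositoryRun",
    "run_repository",
    "compare_tables",
    "compare_table_dirs",
    "compare_metrics",
]


@dataclass(frozen=True)
class ComparisonSettings:
    relative_threshold: float = 0.01
    absolute_floor: float = 1e-12
    table_filter: tuple[str, ...] = ()  # empty = compare all tables

    def validate(self) -> None:
        if self.relative_threshold <= 0:
            raise ValidationError("relative_threshold", "must be > 0")
        if self.absolute_floor < 0:
            raise ValidationError("absolute_floor", "must be >= 0")


@dataclass(frozen=True)
class Discrepancy:
    table: str
    row: object
    column: str
    benchmark: float | str
    current: float | str
    relative_difference: float

    def __str__(self) -> str:
        return (f"{self.table}[{self.row}, {self.column}]: benchmark {self.benchmark} "
                f"vs current {self.current} (rel {self.relative_difference:.3g})")


@dataclass(frozen=True)
class DiscrepancyReport:
    discrepancies: tuple[Discrepancy, ...]
    n_cells_compared: int

    @property
    def passed(self) -> bool:
        return len(self.discrepancies) == 0

    def summary(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (f"{status}: {len(self.discrepancies)} discrepancies in "
                f"{self.n_cells_compared} compared cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"table": d.table, "row": d.row, "column": d.column,
             "benchmark": d.benchmark, "current": d.current,
             "relative_difference": d.relative_difference}
            for d in self.discrepancies
        ])


@dataclass(frozen=True)
class RepositoryRun:
    results: dict[str, RunMetrics]
    errors: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.errors


def run_repository(workspace_dir, out_dir) -> RepositoryRun:
    """Run every ``*.xml`` workspace in a directory.

    Each workspace writes ``<out>/<name>/tables/*.csv`` plus a results
    bundle ``<name>.zip``; an unreadable or failing workspace is
    recorded under ``errors`` and the run continues.
    """
    os.makedirs(out_dir, exist_ok=True)
    results: dict[str, RunMetrics] = {}
    errors: dict[str, str] = {}
    for fname in sorted(os.listdir(workspace_dir)):
        if not fname.endswith(".xml"):
            continue
        name = fname[:-4]
        try:
            w, _ = load_workspace(os.path.join(workspace_dir, fname))
            result = run_workspace(w)
            ws_out = os.path.join(out_dir, name)
            write_tables(result.tables, os.path.join(ws_out, "tables"))
            write_results_bundle(w, result.tables, result.metrics,
                                 os.path.join(out_dir, f"{name}.zip"))
            results[name] = result.metrics
        except Exception as exc:  # isolation: record and continue
            errors[name] = f"{type(exc).__name__}: {exc}"
    return RepositoryRun(results=results, errors=errors)


def _flag(bench: float, cur: float, settings: ComparisonSettings) -> tuple[bool, float]:
    diff = abs(cur - bench)
    denom = max(abs(bench), settings.absolute_floor)
    rel = diff / denom if denom > 0 else (0.0 if diff == 0 else np.inf)
    flagged = diff > settings.absolute_floor and rel > settings.relative_threshold
    return flagged, rel


def compare_tables(
    current: dict[str, pd.DataFrame],
    benchmark: dict[str, pd.DataFrame],
    settings: ComparisonSettings | None = None,
) -> DiscrepancyReport:
    """Cell-by-cell comparison of two table sets.

    A numeric cell is flagged iff it differs by more than the absolute
    floor and by more than the relative threshold of the benchmark
    value; structural mismatches (missing tables, different shapes,
    unequal text cells) are reported as discrepancies rather than
    raised.
    """
    settings = settings or ComparisonSettings()
    settings.validate()
    names = set(current) | set(benchmark)
    if settings.table_filter:
        names &= set(settings.table_filter)
    discrepancies: list[Discrepancy] = []
    n_cells = 0
    for name in sorted(names):
        cur = current.get(name)
        ref = benchmark.get(name)
        if cur is None or ref is None:
            discrepancies.append(Discrepancy(
                name, "-", "-", "present" if ref is not None else "absent",
                "present" if cur is not None else "absent", np.inf))
            continue
        if list(cur.columns) != list(ref.columns) or len(cur) != len(ref):
            discrepancies.append(Discrepancy(
                name, "-", "-", f"shape {ref.shape}", f"shape {cur.shape}", np.inf))
            continue
        for col in ref.columns:
            ref_col = ref[col]
            cur_col = cur[col]
            if pd.api.types.is_numeric_dtype(ref_col) and pd.api.types.is_numeric_dtype(cur_col):
                for i, (b, c) in enumerate(zip(ref_col.to_numpy(), cur_col.to_numpy())):
                    n_cells += 1
                    flagged, rel = _flag(float(b), float(c), settings)
                    if flagged:
                        discrepancies.append(Discrepancy(name, i, str(col), float(b), float(c), rel))
            else:
                for i, (b, c) in enumerate(zip(ref_col, cur_col)):
                    n_cells += 1
                    if str(b) != str(c):
                        discrepancies.append(Discrepancy(name, i, str(col), str(b), str(c), np.inf))
    return DiscrepancyReport(tuple(discrepancies), n_cells)


def _read_table_dir(path) -> dict[str, pd.DataFrame]:
    tables = {}
    for fname in sorted(os.listdir(path)):
        if fname.endswith(".csv"):
            tables[fname[:-4]] = pd.read_csv(os.path.join(path, fname))
    return tables


def compare_table_dirs(current_dir, benchmark_dir,
                       settings: ComparisonSettings | None = None) -> DiscrepancyReport:
    return compare_tables(_read_table_dir(current_dir), _read_table_dir(benchmark_dir), settings)


# exact structural metrics; wall time and memory are hardware-dependent and
# therefore advisory only
_EXACT_METRICS = ("n_states", "internal_steps", "stored_profile_bytes", "n_subjects")
_ADVISORY_METRICS = ("wall_time_s",)


def compare_metrics(
    current: dict[str, RunMetrics | dict],
    benchmark: dict[str, RunMetrics | dict],
    tolerances: dict[str, float] | None = None,
) -> dict:
    """Flag metric regressions; returns {'pass', 'flags', 'advisories'}.

    Structural metrics (state count, step count, stored bytes) must
    match within their tolerance (default exact); wall-time changes are
    advisory notes, never failures.
    """
    tolerances = tolerances or {}
    flags: list[str] = []
    advisories: list[str] = []
    for name in sorted(set(current) & set(benchmark)):
        cur = current[name].to_dict() if isinstance(current[name], RunMetrics) else current[name]
        ref = benchmark[name].to_dict() if isinstance(benchmark[name], RunMetrics) else benchmark[name]
        for metric in _EXACT_METRICS:
            if metric not in cur or metric not in ref:
                continue
            tol = tolerances.get(metric, 0.0)
            b, c = float(ref[metric]), float(cur[metric])
            if abs(c - b) > tol * max(abs(b), 1.0):
                flags.append(f"{name}: {metric} changed {b:g} → {c:g}")
        for metric in _ADVISORY_METRICS:
            if metric not in cur or metric not in ref:
                continue
            b, c = float(ref[metric]), float(cur[metric])
            if b > 0 and c > 1.25 * b:
                advisories.append(f"{name}: {metric} increased {b:.3g}s → {c:.3g}s (advisory)")
    return {"pass": not flags, "flags": flags, "advisories": advisories}
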