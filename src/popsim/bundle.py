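"""Results bundles: CSV tables + verbatim workspace copy + checksum.

A bundle is a zip archive holding every output table, the exact bytes
of the workspace that produced them (``workspace.xml``), a SHA-256
digest of those bytes (``checksum.txt``) and run metrics
(``metrics.json``).  The embedded copy makes any simulation exactly
reproducible from its own results; the digest makes tampering with the
embedded workspace evident on verification.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass

import pandas as pd

from .errors import IntegrityError, ValidationError
from .simulate import CSV_FLOAT_FORMAT, RunMetrics
from .workspace import Workspace
from .xmlio import load_workspace_bytes, workspace_to_bytes

__all__ = ["ResultsBundle", "write_results_bundle", "read_results_bundle", "verify_bundle"]


@dataclass(frozen=True)
class ResultsBundle:
    tables: dict[str, pd.DataFrame]
    embedded_workspace: bytes
    checksum: str
    metrics: RunMetrics | dict

    def workspace(self) -> Workspace:
        """Reconstruct the workspace from the embedded verbatim copy."""
        verify_bundle(self)
        w, _ = load_workspace_bytes(self.embedded_workspace)
        return w


def _digest(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def write_results_bundle(
    w: Workspace,
    tables: dict[str, pd.DataFrame],
    metrics: RunMetrics | dict,
    destination,
) -> ResultsBundle:
    """Write a zip bundle to ``destination`` (path or binary file)."""
    if not tables:
        raise ValidationError("tables", "bundle requires at least one table")
    ws_bytes = workspace_to_bytes(w)
    checksum = _digest(ws_bytes)
    metrics_dict = metrics.to_dict() if isinstance(metrics, RunMetrics) else dict(metrics)
    with zipfile.ZipFile(destination, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, df in tables.items():
            buf = io.StringIO()
            df.to_csv(buf, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")
            zf.writestr(f"tables/{name}.csv", buf.getvalue())
        zf.writestr("workspace.xml", ws_bytes)
        zf.writestr("checksum.txt", checksum + "\n")
        zf.writestr("metrics.json", json.dumps(metrics_dict, indent=2, sort_keys=True))
    return ResultsBundle(
        tables=dict(tables),
        embedded_workspace=ws_bytes,
        checksum=checksum,
        metrics=metrics,
    )


def read_results_bundle(source) -> ResultsBundle:
    with zipfile.ZipFile(source, "r") as zf:
        tables = {}
        for info in zf.infolist():
            if info.filename.startswith("tables/") and info.filename.endswith(".csv"):
                name = info.filename[len("tables/"):-len(".csv")]
                with zf.open(info) as fh:
                    tables[name] = pd.read_csv(fh)
        ws_bytes = zf.read("workspace.xml")
        checksum = zf.read("checksum.txt").decode().strip()
        metrics = json.loads(zf.read("metrics.json"))
    bundle = ResultsBundle(
        tables=tables, embedded_workspace=ws_bytes, checksum=checksum, metrics=metrics
    )
    verify_bundle(bundle)
    return bundle


def verify_bundle(bundle: ResultsBundle) -> None:
    """Raise :class:`~popsim.errors.IntegrityError` if the embedded
    workspace bytes do not hash to the recorded checksum."""
    actual = _digest(bundle.embedded_workspace)
    if actual != bundle.checksum:
        raise IntegrityError(
            f"embedded workspace digest {actual[:12]}… does not match recorded "
            f"checksum {bundle.checksum[:12]}…"
        )
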