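"""NONMEM-style observed datasets for parameter estimation.

Clinical observations arrive as comma- or tab-delimited tables with the
usual column vocabulary — ID, TIME, DV, DVID, AMT, EVID, MDV plus free
covariate columns — or as the XML dialect written by
:func:`write_observed_xml`.  Two validation passes run on load: a
per-record pass (types and ranges) and a whole-dataset pass (subject
consistency, presence of dosing); every problem is reported with its
row, column and reason.  Fatal problems suppress the dataset but the
issue list is always complete.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError

__all__ = ["Issue", "ObservedDataset", "parse_observed", "write_observed_xml"]

_CANONICAL = {
    "id": "subject_id",
    "subject": "subject_id",
    "subject_id": "subject_id",
    "time": "time",
    "dv": "dv",
    "dvid": "dvid",
    "amt": "amt",
    "evid": "evid",
    "mdv": "mdv",
}

OBSERVATION, DOSE = 0, 1


@dataclass(frozen=True)
class Issue:
    row: int  # 1-based data row (header excluded)
    column: str
    reason: str
    fatal: bool = True

    def __str__(self) -> str:
        kind = "error" if self.fatal else "warning"
        where = f"row {self.row}" if self.row > 0 else "dataset"
        return f"{kind} at {where}, column {self.column}: {self.reason}"


@dataclass(frozen=True)
class ObservedDataset:
    records: pd.DataFrame  # canonical columns + covariates

    @property
    def subject_ids(self) -> list:
        return sorted(self.records["subject_id"].unique().tolist())

    def observations(self, subject_id) -> pd.DataFrame:
        r = self.records
        return r[(r["subject_id"] == subject_id) & (r["evid"] == OBSERVATION) & (r["mdv"] == 0)]

    def doses(self, subject_id) -> pd.DataFrame:
        r = self.records
        return r[(r["subject_id"] == subject_id) & (r["evid"] == DOSE)]

    @property
    def n_subjects(self) -> int:
        return self.records["subject_id"].nunique()


def _read_table(source) -> pd.DataFrame:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and not text.lstrip().startswith("<"):
            # a path rather than inline content
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
    if text.lstrip().startswith("<"):
        return _records_from_xml(text)
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    return pd.read_csv(io.StringIO(text), sep=sep, skipinitialspace=True)


def _records_from_xml(text: str) -> pd.DataFrame:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        line = exc.position[0] if getattr(exc, "position", None) else None
        raise ParseError("malformed observed-data XML", line) from exc
    if root.tag != "observed_data":
        raise ParseError(f"expected <observed_data> root, found <{root.tag}>")
    rows = [dict(rec.attrib) for rec in root.findall("record")]
    return pd.DataFrame(rows)


def write_observed_xml(records: pd.DataFrame, destination) -> None:
    """Write the XML dialect of an observed dataset (template output)."""
    root = ET.Element("observed_data")
    for _, row in records.iterrows():
        ET.SubElement(root, "record", {k: str(v) for k, v in row.items() if pd.notna(v)})
    ET.indent(root)
    ET.ElementTree(root).write(destination, encoding="utf-8", xml_declaration=True)


def parse_observed(source) -> tuple[ObservedDataset | None, list[Issue]]:
    """Parse and doubly validate an observed dataset.

    Returns ``(dataset, issues)``; when any fatal issue is present the
    dataset is None and the issue list is complete.  A subject carrying
    observations but no dose anywhere is a non-fatal, whole-dataset
    issue: such subjects may still be dosed from the workspace regimen.
    """
    raw = _read_table(source)
    issues: list[Issue] = []
    rename = {}
    for col in raw.columns:
        key = str(col).strip().lower()
        rename[col] = _CANONICAL.get(key, str(col).strip().lower())
    df = raw.rename(columns=rename)
    for required in ("subject_id", "time", "dv"):
        if required not in df.columns:
            issues.append(Issue(0, required, "required column missing"))
    if any(i.fatal for i in issues):
        return None, issues
    if "evid" not in df.columns:
        df["evid"] = np.where(df.get("amt", pd.Series(0, index=df.index)).fillna(0) > 0, DOSE, OBSERVATION)
    if "mdv" not in df.columns:
        df["mdv"] = np.where(df["evid"] == DOSE, 1, 0)
    if "amt" not in df.columns:
        df["amt"] = 0.0
    if "dvid" not in df.columns:
        df["dvid"] = "pk"
    # XML sources deliver strings: coerce the numeric vocabulary up front
    for col in ("evid", "mdv"):
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    for col in ("time", "amt", "dv"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    subject_numeric = pd.to_numeric(df["subject_id"], errors="coerce")
    if not subject_numeric.isna().any():
        df["subject_id"] = subject_numeric

    # pass 1: per-record checks -------------------------------------------
    for i, row in df.iterrows():
        rownum = int(i) + 1
        t = row["time"]
        if pd.isna(t):
            issues.append(Issue(rownum, "time", "not a number"))
            continue
        if t < 0:
            issues.append(Issue(rownum, "time", f"negative time {t}"))
        evid = int(float(row["evid"]))
        if evid not in (OBSERVATION, DOSE):
            issues.append(Issue(rownum, "evid", f"must be {OBSERVATION} or {DOSE}, got {evid}"))
        mdv = int(float(row["mdv"]))
        dv_missing = pd.isna(row["dv"])
        if evid == OBSERVATION:
            if mdv == 0 and dv_missing:
                issues.append(Issue(rownum, "dv", "observation record without a DV value"))
            if mdv == 1 and not dv_missing:
                issues.append(Issue(rownum, "dv", "DV present although MDV flags it missing"))
        if evid == DOSE:
            amt = float(row["amt"]) if not pd.isna(row["amt"]) else 0.0
            if amt <= 0:
                issues.append(Issue(rownum, "amt", "dose record requires a positive amount"))

    # pass 2: whole-dataset consistency -----------------------------------
    for sid, group in df.groupby("subject_id"):
        has_obs = ((group["evid"] == OBSERVATION) & (group["mdv"] == 0)).any()
        has_dose = (group["evid"] == DOSE).any()
        if has_obs and not has_dose:
            issues.append(
                Issue(0, "subject_id",
                      f"subject {sid!r} has observations but no dose record "
                      "(workspace regimen will be used)", fatal=False)
            )

    if any(i.fatal for i in issues):
        return None, issues
    df = df.copy()
    df["amt"] = df["amt"].fillna(0.0)
    return ObservedDataset(records=df), issues
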