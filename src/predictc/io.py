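"""Tabular I/O for qPCR Cq tables and clinical outcome tables.

Two plain-text formats are supported, both CSV (comma default, tab
accepted), UTF-8:

* Cq long format, header ``patient_id,timepoint,gene,replicate,cq``; one row
  per replicate well.  A Cq of ``undetermined`` (or an empty field) means the
  well never crossed the fluorescence threshold within ``max_cycles``.
* Clinical format, header
  ``patient_id,pfs_months,pfs_event,os_months,os_event,ct_response,<covariates...>``;
  extra columns are carried through untouched as covariates.

``assemble_cohort`` merges both sources into a :class:`Cohort`, recording
per-patient timepoint availability and flagging (never dropping) patients who
cannot be run through the response classifier.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .panel import TIMEPOINTS, MarkerPanel, Timepoint

CQ_COLUMNS = ("patient_id", "timepoint", "gene", "replicate", "cq")
CLINICAL_BASE_COLUMNS = (
    "patient_id",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "ct_response",
)

#: spelled-out sentinel for a well that never amplified
UNDETERMINED = "undetermined"

CT_RESPONSE_VALUES = ("responder", "non_responder", "unevaluated")

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _sniff_sep(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def _parse_cq(raw: object, max_cycles: int, row: int) -> float:
    """Parse one Cq field; NaN encodes the undetermined sentinel."""
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return math.nan
    text = str(raw).strip().lower()
    if text in ("", UNDETERMINED, "nan", "na", "n/a"):
        return math.nan
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"row {row}: unparseable cq value {raw!r}") from exc
    if not 0.0 <= value <= max_cycles:
        raise ValidationError(
            f"row {row}: cq value {value} outside [0, {max_cycles}]"
        )
    return value


def read_cq_table(
    path: str | Path, panel: MarkerPanel | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read a long-format Cq table and validate it against the panel vocabulary.

    Returns a DataFrame with columns ``patient_id, timepoint, gene, replicate,
    cq`` where undetermined wells carry ``NaN`` in ``cq``.
    """
    panel = panel or MarkerPanel()
    sep = _sniff_sep(path, sep)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in CQ_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"Cq table missing required column(s): {', '.join(missing)}")

    allowed = set(panel.genes)
    records: list[tuple] = []
    for i, row in enumerate(raw.itertuples(index=False), start=2):  # 1 = header
        tp = str(row.timepoint).strip()
        if tp not in TIMEPOINTS:
            raise ValidationError(
                f"row {i}: unknown timepoint {tp!r}; allowed: {', '.join(TIMEPOINTS)}"
            )
        gene = str(row.gene).strip()
        if gene not in allowed:
            raise ValidationError(
                f"row {i}: gene {gene!r} not in panel; allowed: "
                + ", ".join(sorted(allowed))
            )
        try:
            replicate = int(str(row.replicate))
        except ValueError as exc:
            raise ValidationError(
                f"row {i}: replicate must be an integer, got {row.replicate!r}"
            ) from exc
        if replicate < 1:
            raise ValidationError(f"row {i}: replicate must be positive")
        cq = _parse_cq(row.cq, panel.max_cycles, i)
        records.append((str(row.patient_id).strip(), tp, gene, replicate, cq))

    df = pd.DataFrame.from_records(records, columns=CQ_COLUMNS)
    dup = df.duplicated(subset=["patient_id", "timepoint", "gene", "replicate"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            "duplicate Cq record for "
            f"({first.patient_id}, {first.timepoint}, {first.gene}, "
            f"replicate {first.replicate})"
        )
    return df


def _format_cq(value: float) -> str:
    return UNDETERMINED if (value is None or math.isnan(value)) else repr(float(value))


def write_cq_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a Cq table in canonical form (sorted, ``undetermined`` sentinel)."""
    out = df.loc[:, list(CQ_COLUMNS)].copy()
    out = out.sort_values(["patient_id", "timepoint", "gene", "replicate"]).reset_index(
        drop=True
    )
    out["cq"] = out["cq"].map(_format_cq)
    out.to_csv(path, sep=sep, index=False)


def _parse_bool(raw: object, column: str, row: int) -> bool:
    text = str(raw).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"row {row}: {column} must be boolean-like, got {raw!r}")


def read_clinical_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the clinical outcome table.

    Survival times are months (floats), events booleans; unknown columns are
    preserved untouched as covariates.  A missing ``ct_response`` column makes
    every patient CT-unevaluated (with a warning).
    """
    sep = _sniff_sep(path, sep)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = [c for c in CLINICAL_BASE_COLUMNS if c != "ct_response"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"clinical table missing required column(s): {', '.join(missing)}"
        )
    has_ct = "ct_response" in raw.columns
    if not has_ct:
        warnings.warn(
            "clinical table has no ct_response column; all patients treated "
            "as CT-unevaluated",
            stacklevel=2,
        )

    df = raw.copy()
    df["patient_id"] = df["patient_id"].astype(str).str.strip()
    if df["patient_id"].duplicated().any():
        dups = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id(s) in clinical table: {dups}")

    for col in ("pfs_months", "os_months"):
        values = []
        for i, raw_val in enumerate(df[col], start=2):
            try:
                v = float(raw_val)
            except ValueError as exc:
                raise ValidationError(
                    f"row {i}: {col} must be numeric, got {raw_val!r}"
                ) from exc
            if v < 0:
                raise ValidationError(f"row {i}: {col} must be nonnegative, got {v}")
            values.append(v)
        df[col] = values
    for col in ("pfs_event", "os_event"):
        df[col] = [
            _parse_bool(v, col, i) for i, v in enumerate(df[col], start=2)
        ]

    if has_ct:
        ct = df["ct_response"].astype(str).str.strip()
        ct = ct.where(ct != "", "unevaluated")
        bad = sorted(set(ct) - set(CT_RESPONSE_VALUES))
        if bad:
            raise ValidationError(
                f"unknown ct_response value(s) {bad}; allowed: "
                + ", ".join(CT_RESPONSE_VALUES)
            )
        df["ct_response"] = ct
    else:
        df["ct_response"] = "unevaluated"

    # real registries can violate pfs <= os; warn, do not reject
    both = df["pfs_event"] & df["os_event"]
    offending = df.loc[both & (df["pfs_months"] > df["os_months"]), "patient_id"]
    if len(offending):
        warnings.warn(
            "pfs_months exceeds os_months for patient(s) with both events "
            f"observed: {offending.tolist()}",
            stacklevel=2,
        )
    ordered = [c for c in CLINICAL_BASE_COLUMNS] + [
        c for c in df.columns if c not in CLINICAL_BASE_COLUMNS
    ]
    return df.loc[:, ordered]


def write_clinical_table(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    out = df.copy().sort_values("patient_id").reset_index(drop=True)
    for col in ("pfs_event", "os_event"):
        out[col] = out[col].map(lambda b: "true" if b else "false")
    out.to_csv(path, sep=sep, index=False)


@dataclass
class Cohort:
    """Merged Cq + clinical view of one study cohort.

    ``availability`` is a boolean patient x timepoint table; ``unclassifiable``
    lists patients lacking a baseline or week-4 Cq sample, who are excluded
    from response classification but retained for baseline-only analyses.
    """

    cq: pd.DataFrame
    clinical: pd.DataFrame
    panel: MarkerPanel = field(default_factory=MarkerPanel)
    availability: pd.DataFrame = field(init=False)
    unclassifiable: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.cq = (
            self.cq.sort_values(["patient_id", "timepoint", "gene", "replicate"])
            .reset_index(drop=True)
        )
        self.clinical = self.clinical.sort_values("patient_id").reset_index(drop=True)
        patients = sorted(
            set(self.cq["patient_id"]) | set(self.clinical["patient_id"])
        )
        avail = pd.DataFrame(False, index=patients, columns=list(TIMEPOINTS))
        if len(self.cq):
            present = self.cq.groupby(["patient_id", "timepoint"]).size()
            for (pid, tp) in present.index:
                avail.loc[pid, tp] = True
        self.availability = avail
        self.unclassifiable = [
            pid
            for pid in patients
            if not (avail.loc[pid, Timepoint.BASELINE.value]
                    and avail.loc[pid, Timepoint.WEEK4.value])
        ]

    @property
    def patients(self) -> list[str]:
        return list(self.availability.index)

    @property
    def classifiable(self) -> list[str]:
        excluded = set(self.unclassifiable)
        return [p for p in self.patients if p not in excluded]


def assemble_cohort(
    cq: pd.DataFrame,
    clinical: pd.DataFrame,
    panel: MarkerPanel | None = None,
) -> Cohort:
    """Merge Cq and clinical tables into a :class:`Cohort`.

    Patients present in either source are kept; patients with Cq data but no
    clinical record are retained with missing survival (warned), and patients
    lacking baseline or week-4 samples are flagged unclassifiable, not
    dropped.
    """
    panel = panel or MarkerPanel()
    cq_only = sorted(set(cq["patient_id"]) - set(clinical["patient_id"]))
    if cq_only:
        warnings.warn(
            f"patient(s) with Cq data but no clinical record: {cq_only}",
            stacklevel=2,
        )
    return Cohort(cq=cq.copy(), clinical=clinical.copy(), panel=panel)
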