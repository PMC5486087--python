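"""Reference-gene normalization of replicate Cq values.

Expression is reported on the delta-Cq scale

    delta_cq = (max_cycles - Cq_target) - (max_cycles - Cq_reference)

with ``max_cycles`` = 40 by default.  Higher values mean more target
transcript relative to the reference (PTPRC/CD45, which controls for the
leukocyte background of the immunoisolated fraction).  A target that never
amplified is imputed at Cq = ``max_cycles``, mapping absent transcript to the
floor of the scale; a reference that never amplified makes the whole sample
unusable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ReferenceNotDetectedError, ValidationError
from .io import Cohort
from .panel import MarkerPanel

#: |Cq1 - Cq2| beyond which duplicate wells are considered discordant
DEFAULT_QC_SPREAD_CYCLES = 1.5


def collapse_replicates(
    cqs: Sequence[float],
    method: Literal["mean", "geometric"] = "mean",
    qc_spread_cycles: float | None = DEFAULT_QC_SPREAD_CYCLES,
) -> float:
    """Collapse replicate Cq wells into a single Cq.

    NaN encodes the undetermined sentinel.  Undetermined replicates are
    excluded when at least one numeric replicate exists; if every replicate is
    undetermined the sentinel propagates.  ``method="geometric"`` averages on
    the linear 2**(-Cq) scale instead of the Cq scale.  Replicate spreads
    larger than ``qc_spread_cycles`` trigger a QC warning.
    """
    if len(cqs) == 0:
        raise ValidationError("cannot collapse an empty replicate list")
    numeric = [c for c in cqs if not math.isnan(c)]
    if not numeric:
        return math.nan
    if (
        qc_spread_cycles is not None
        and len(numeric) > 1
        and max(numeric) - min(numeric) > qc_spread_cycles
    ):
        warnings.warn(
            f"replicate Cq spread {max(numeric) - min(numeric):.2f} cycles exceeds "
            f"QC threshold {qc_spread_cycles}",
            stacklevel=2,
        )
    if method == "mean":
        return float(np.mean(numeric))
    if method == "geometric":
        return float(-np.log2(np.mean([2.0 ** (-c) for c in numeric])))
    raise ValueError(f"unknown replicate collapse method {method!r}")


def normalize_cq(
    cq_target: float, cq_reference: float, max_cycles: int = 40
) -> float:
    """Reference-normalized expression for a single marker measurement.

    Returns ``(max_cycles - cq_target) - (max_cycles - cq_reference)``.
    An undetermined target (NaN) is imputed at ``max_cycles``; an undetermined
    reference raises :class:`ReferenceNotDetectedError`.
    """
    if math.isnan(cq_reference):
        raise ReferenceNotDetectedError(
            "reference gene not detected; sample cannot be normalized"
        )
    if math.isnan(cq_target):
        cq_target = float(max_cycles)
    return (max_cycles - cq_target) - (max_cycles - cq_reference)


@dataclass
class ExpressionMatrix:
    """Reference-normalized expression for a cohort.

    ``long`` has one row per (patient_id, timepoint, marker) with a numeric
    ``delta_cq``; ``failed_samples`` lists (patient_id, timepoint) pairs whose
    reference gene did not amplify (excluded from ``long``); ``missing`` lists
    (patient_id, timepoint, marker) triples that were simply not measured.
    """

    long: pd.DataFrame
    failed_samples: list[tuple[str, str]] = field(default_factory=list)
    missing: list[tuple[str, str, str]] = field(default_factory=list)

    def wide(self) -> pd.DataFrame:
        """Pivot to rows = (patient_id, timepoint), columns = markers."""
        return self.long.pivot_table(
            index=["patient_id", "timepoint"],
            columns="marker",
            values="delta_cq",
            aggfunc="first",
        )

    def to_csv(self, path: str | Path) -> None:
        self.wide().reset_index().to_csv(path, index=False)


def build_expression_matrix(
    cohort: Cohort,
    panel: MarkerPanel | None = None,
    collapse: Literal["mean", "geometric"] = "mean",
    qc_spread_cycles: float | None = DEFAULT_QC_SPREAD_CYCLES,
) -> ExpressionMatrix:
    """Collapse replicates and normalize every marker to the reference gene.

    One expression value is produced per (patient, timepoint, marker) where
    both the marker and the reference were measured; samples whose reference
    failed to amplify are excluded and flagged.
    """
    panel = panel or cohort.panel
    rows: list[dict] = []
    failed: list[tuple[str, str]] = []
    missing: list[tuple[str, str, str]] = []

    grouped = cohort.cq.groupby(["patient_id", "timepoint"], sort=True)
    for (pid, tp), sample in grouped:
        by_gene = {
            gene: collapse_replicates(
                sub["cq"].tolist(), method=collapse, qc_spread_cycles=qc_spread_cycles
            )
            for gene, sub in sample.groupby("gene")
        }
        ref = by_gene.get(panel.reference_gene, math.nan)
        if math.isnan(ref):
            failed.append((pid, tp))
            continue
        for marker in panel.markers:
            if marker not in by_gene:
                missing.append((pid, tp, marker))
                continue
            rows.append(
                {
                    "patient_id": pid,
                    "timepoint": tp,
                    "marker": marker,
                    "delta_cq": normalize_cq(by_gene[marker], ref, panel.max_cycles),
                }
            )
    long = pd.DataFrame(
        rows, columns=["patient_id", "timepoint", "marker", "delta_cq"]
    )
    return ExpressionMatrix(long=long, failed_samples=failed, missing=missing)
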