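"""Percentile cutoffs and the majority-vote high/low-CTC panel call.

Each marker gets a cutoff at a percentile (default 75th) of its cohort
delta-Cq distribution, computed separately per timepoint.  A marker call is
"high" when expression is strictly above the cutoff (ties score low, so at
most 25% of a cohort can be high per marker at the 75th percentile).  The
panel call is a majority vote: high-CTC when at least ``call_threshold``
(default 4 of 7) markers are high, low-CTC when at least that many are low,
unevaluable when missingness starves both counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .normalization import ExpressionMatrix
from .panel import MarkerPanel

MarkerCall = Literal["low", "high", "missing"]
Group = Literal["low_ctc", "high_ctc", "unevaluable"]

LOW, HIGH, MISSING = "low", "high", "missing"
LOW_CTC, HIGH_CTC, UNEVALUABLE = "low_ctc", "high_ctc", "unevaluable"


def compute_cutoff(
    values: Iterable[float], percentile: float, method: str = "linear"
) -> float:
    """Empirical percentile of a marker's delta-Cq values.

    Uses linear interpolation between closest order statistics (position
    ``1 + (n-1) * p / 100``; Hyndman-Fan type 7) by default; any quantile
    ``method`` accepted by :func:`numpy.percentile` may be substituted.
    """
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size == 0:
        raise ValidationError("cannot compute a cutoff from an empty sample")
    return float(np.percentile(arr, percentile, method=method))


@dataclass
class CutoffSet:
    """Per-(marker, timepoint) cutoffs on the delta-Cq scale.

    ``provenance`` records whether cutoffs were computed from the analyzed
    cohort or supplied externally (e.g. frozen from a prior study).
    """

    table: pd.DataFrame  # columns: marker, timepoint, cutoff
    percentile: float
    provenance: Literal["computed_from_cohort", "supplied"]

    def get(self, marker: str, timepoint: str) -> float:
        hit = self.table[
            (self.table["marker"] == marker) & (self.table["timepoint"] == timepoint)
        ]
        if hit.empty:
            raise ConfigurationError(
                f"no cutoff available for marker {marker!r} at timepoint {timepoint!r}"
            )
        return float(hit["cutoff"].iloc[0])

    @classmethod
    def from_expression(
        cls,
        expression: ExpressionMatrix,
        panel: MarkerPanel,
        method: str = "linear",
    ) -> "CutoffSet":
        """Compute cohort cutoffs at the panel percentile, per marker and timepoint."""
        rows = []
        for (marker, tp), sub in expression.long.groupby(["marker", "timepoint"]):
            rows.append(
                {
                    "marker": marker,
                    "timepoint": tp,
                    "cutoff": compute_cutoff(
                        sub["delta_cq"], panel.cutoff_percentile, method=method
                    ),
                }
            )
        table = pd.DataFrame(rows).sort_values(["timepoint", "marker"]).reset_index(
            drop=True
        )
        return cls(
            table=table,
            percentile=panel.cutoff_percentile,
            provenance="computed_from_cohort",
        )

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, percentile: float = 75.0) -> "CutoffSet":
        table = pd.read_csv(path)
        return cls(table=table, percentile=percentile, provenance="supplied")

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "percentile": float(self.percentile),
            "provenance": self.provenance,
            "cutoffs": [
                {
                    "marker": r.marker,
                    "timepoint": r.timepoint,
                    "cutoff": float(r.cutoff),
                }
                for r in self.table.itertuples(index=False)
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CutoffSet":
        payload = yaml.safe_load(Path(path).read_text())
        table = pd.DataFrame(payload["cutoffs"])
        return cls(
            table=table,
            percentile=float(payload.get("percentile", 75.0)),
            provenance="supplied",
        )


def call_marker(value: float, cutoff: float) -> str:
    """High iff strictly above the cutoff; equality scores low."""
    return HIGH if value > cutoff else LOW


def call_panel(marker_calls: Mapping[str, str], threshold: int) -> str:
    """Majority vote over marker calls.

    high-CTC when at least ``threshold`` markers are high; low-CTC when at
    least ``threshold`` are low; unevaluable when missing calls leave both
    counts short.  With a full 7-marker vector and threshold 4 exactly one
    side always wins.
    """
    n_high = sum(1 for c in marker_calls.values() if c == HIGH)
    n_low = sum(1 for c in marker_calls.values() if c == LOW)
    if n_high >= threshold:
        return HIGH_CTC
    if n_low >= threshold:
        return LOW_CTC
    return UNEVALUABLE


def score_cohort(
    expression: ExpressionMatrix,
    cutoffs: CutoffSet,
    panel: MarkerPanel | None = None,
) -> pd.DataFrame:
    """Produce one panel call per (patient, timepoint) with any expression.

    Returns a DataFrame with one column per marker (low/high/missing), the
    high/low tallies and the panel ``group``.  A missing cutoff for a scored
    (marker, timepoint) raises :class:`ConfigurationError`.
    """
    panel = panel or MarkerPanel()
    rows = []
    for (pid, tp), sub in expression.long.groupby(["patient_id", "timepoint"]):
        values = dict(zip(sub["marker"], sub["delta_cq"]))
        calls = {
            marker: (
                call_marker(values[marker], cutoffs.get(marker, tp))
                if marker in values
                else MISSING
            )
            for marker in panel.markers
        }
        n_high = sum(1 for c in calls.values() if c == HIGH)
        n_low = sum(1 for c in calls.values() if c == LOW)
        rows.append(
            {
                "patient_id": pid,
                "timepoint": tp,
                **calls,
                "n_high": n_high,
                "n_low": n_low,
                "n_missing": panel.n_markers - n_high - n_low,
                "group": call_panel(calls, panel.call_threshold),
            }
        )
    columns = (
        ["patient_id", "timepoint"]
        + list(panel.markers)
        + ["n_high", "n_low", "n_missing", "group"]
    )
    return pd.DataFrame(rows, columns=columns).sort_values(
        ["patient_id", "timepoint"]
    ).reset_index(drop=True)
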