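"""Responder / non-responder classification from longitudinal panel calls.

The decision scheme reads the high/low-CTC group at baseline and week 4,
and — only for patients dropping from high to low — a confirmatory week-16
sample:

* low → low  (LL): responder
* high → high (HH): non-responder
* low → high (LH): non-responder (CTC burden rose under therapy)
* high → low (HL): provisional responder, confirmed at week 16
  (low: responder; high: reclassified non-responder; absent: unresolved)

Patients without an evaluable baseline or week-4 call are unclassifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .panel import Timepoint
from .scoring import HIGH_CTC, LOW_CTC, UNEVALUABLE

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
NEEDS_CONFIRMATION = "needs_confirmation"
UNCLASSIFIABLE = "unclassifiable"

PATH_LL = "LL"
PATH_HH = "HH"
PATH_LH = "LH"
PATH_HL_CONFIRMED_LOW = "HL_confirmed_low"
PATH_HL_RECLASSIFIED_HIGH = "HL_reclassified_high"
PATH_HL_UNCONFIRMED = "HL_unconfirmed"


@dataclass(frozen=True)
class ResponseCall:
    """Final label plus the decision-path branch that produced it."""

    patient_id: str
    label: str
    path: str | None


def classify_response(
    baseline: str | None,
    week4: str | None,
    week16: str | None = None,
    patient_id: str = "",
) -> ResponseCall:
    """Classify one patient from panel groups at the three timepoints.

    ``baseline``/``week4``/``week16`` are panel groups (``low_ctc``,
    ``high_ctc``, ``unevaluable``) or None when no sample exists.  Week-16
    data is read only on the high→low branch.
    """
    evaluable = (LOW_CTC, HIGH_CTC)
    if baseline not in evaluable or week4 not in evaluable:
        return ResponseCall(patient_id, UNCLASSIFIABLE, None)
    if baseline == LOW_CTC and week4 == LOW_CTC:
        return ResponseCall(patient_id, RESPONDER, PATH_LL)
    if baseline == HIGH_CTC and week4 == HIGH_CTC:
        return ResponseCall(patient_id, NON_RESPONDER, PATH_HH)
    if baseline == LOW_CTC and week4 == HIGH_CTC:
        return ResponseCall(patient_id, NON_RESPONDER, PATH_LH)
    # high -> low: provisional responder pending week-16 confirmation
    if week16 == LOW_CTC:
        return ResponseCall(patient_id, RESPONDER, PATH_HL_CONFIRMED_LOW)
    if week16 == HIGH_CTC:
        return ResponseCall(patient_id, NON_RESPONDER, PATH_HL_RECLASSIFIED_HIGH)
    return ResponseCall(patient_id, NEEDS_CONFIRMATION, PATH_HL_UNCONFIRMED)


def classify_cohort(
    panel_calls: pd.DataFrame, all_patients: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Classify every patient in a panel-call table.

    Parameters
    ----------
    panel_calls
        Output of :func:`predictc.scoring.score_cohort` (needs ``patient_id``,
        ``timepoint`` and ``group`` columns).
    all_patients
        Optional full roster; patients with no panel call at all are reported
        unclassifiable rather than silently absent.

    Returns the per-patient label table (columns ``patient_id, label, path``)
    and a summary dict with counts per path, provisional and final tallies,
    and the fraction of classified patients resolved after week 4 alone.
    """
    groups: dict[str, dict[str, str]] = {}
    for row in panel_calls.itertuples(index=False):
        groups.setdefault(row.patient_id, {})[row.timepoint] = row.group

    patients = list(all_patients) if all_patients is not None else sorted(groups)
    calls = [
        classify_response(
            groups.get(pid, {}).get(Timepoint.BASELINE.value),
            groups.get(pid, {}).get(Timepoint.WEEK4.value),
            groups.get(pid, {}).get(Timepoint.WEEK16.value),
            patient_id=pid,
        )
        for pid in patients
    ]
    df = pd.DataFrame(
        [(c.patient_id, c.label, c.path) for c in calls],
        columns=["patient_id", "label", "path"],
    )

    pending = df[df["label"] == NEEDS_CONFIRMATION]
    if len(pending):
        warnings.warn(
            "patient(s) with a high→low transition but no week-16 sample remain "
            f"unconfirmed: {pending['patient_id'].tolist()}",
            stacklevel=2,
        )

    path_counts = df["path"].value_counts().to_dict()
    n_unclassifiable = int((df["label"] == UNCLASSIFIABLE).sum())
    n_classified = len(df) - n_unclassifiable - len(pending)
    n_hl = sum(
        path_counts.get(p, 0)
        for p in (PATH_HL_CONFIRMED_LOW, PATH_HL_RECLASSIFIED_HIGH, PATH_HL_UNCONFIRMED)
    )
    # provisional view: HL patients counted as responders pending confirmation
    n_provisional_responder = path_counts.get(PATH_LL, 0) + n_hl
    n_provisional_non_responder = path_counts.get(PATH_HH, 0) + path_counts.get(
        PATH_LH, 0
    )
    summary = {
        "n_patients": len(df),
        "n_responder": int((df["label"] == RESPONDER).sum()),
        "n_non_responder": int((df["label"] == NON_RESPONDER).sum()),
        "n_needs_confirmation": len(pending),
        "n_unclassifiable": n_unclassifiable,
        "n_classified": n_classified,
        "paths": path_counts,
        "n_needing_week16": n_hl,
        "provisional": {
            "responder": n_provisional_responder,
            "non_responder": n_provisional_non_responder,
        },
        "fraction_classified_after_week4": (
            1.0 - n_hl / (n_classified + len(pending))
            if (n_classified + len(pending)) > 0
            else float("nan")
        ),
    }
    return df, summary
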