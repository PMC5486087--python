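"""Diagnostic concordance between the panel classifier and CT-scan response.

The positive class throughout is *non-responder* (the clinically actionable
call: detecting a patient who is not benefiting from therapy).  Besides the
usual cross-tabulation and sensitivity/specificity/PPV/NPV/accuracy
("global efficiency") metrics, this module can reconstruct the integer 2x2
table underlying a published report from its prediction margins and rounded
per-class rates, by exhaustive search over all consistent tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import pandas as pd

from .errors import PrediCTCError, ValidationError
from .response import NON_RESPONDER, RESPONDER

POSITIVE = NON_RESPONDER
NEGATIVE = RESPONDER


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the convention of most published percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 table; positive class = non-responder.

    tp: true non-responders called non-responder; fp: responders called
    non-responder; fn: non-responders called responder; tn: responders called
    responder.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion-table cells must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def predicted_positive(self) -> int:
        return self.tp + self.fp

    @property
    def predicted_negative(self) -> int:
        return self.fn + self.tn

    @property
    def true_positive_margin(self) -> int:
        return self.tp + self.fn

    @property
    def true_negative_margin(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages rounded half-up; None marks an undefined (0/0) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    fnr: float | None
    accuracy: float | None
    decimals: int = 1


def _ratio_pct(num: int, den: int, decimals: int) -> float | None:
    if den == 0:
        return None
    return round_half_up(100.0 * num / den, decimals)


def compute_metrics(t: ConfusionTable, decimals: int = 1) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV, false-negative rate and accuracy.

    All values are percentages rounded half-up to ``decimals``.  A metric
    whose denominator is zero is returned as None, never as 0.
    """
    if t.total == 0:
        raise ValidationError("cannot compute metrics on an empty table")
    return DiagnosticMetrics(
        sensitivity=_ratio_pct(t.tp, t.tp + t.fn, decimals),
        specificity=_ratio_pct(t.tn, t.tn + t.fp, decimals),
        ppv=_ratio_pct(t.tp, t.tp + t.fp, decimals),
        npv=_ratio_pct(t.tn, t.tn + t.fn, decimals),
        fnr=_ratio_pct(t.fn, t.tp + t.fn, decimals),
        accuracy=_ratio_pct(t.tp + t.tn, t.total, decimals),
        decimals=decimals,
    )


class NoConsistentTableError(PrediCTCError):
    """No integer table matches the stated margins and rounded rates."""


class AmbiguousTableError(PrediCTCError):
    """Multiple integer tables match; candidates are attached."""

    def __init__(self, candidates: list[ConfusionTable]):
        self.candidates = candidates
        super().__init__(
            f"{len(candidates)} tables consistent with the stated rates: "
            + ", ".join(
                f"(tp={c.tp}, fp={c.fp}, fn={c.fn}, tn={c.tn})" for c in candidates
            )
        )


def reconstruct_confusion(
    pos_margin: int,
    neg_margin: int,
    sensitivity_pct: float,
    specificity_pct: float,
    decimals: int = 1,
) -> ConfusionTable:
    """Recover the unique 2x2 table behind published margins and rates.

    ``pos_margin`` is the number of predicted positives (tp + fp) and
    ``neg_margin`` the predicted negatives (fn + tn).  All tables with those
    margins whose sensitivity and specificity round (half-up, ``decimals``)
    to the stated percentages are enumerated; exactly one must remain.
    """
    if pos_margin <= 0 or neg_margin <= 0:
        raise ValidationError("margins must be positive")
    candidates: list[ConfusionTable] = []
    for tp in range(pos_margin + 1):
        fp = pos_margin - tp
        for tn in range(neg_margin + 1):
            fn = neg_margin - tn
            if tp + fn == 0 or tn + fp == 0:
                continue
            sens = round_half_up(100.0 * tp / (tp + fn), decimals)
            spec = round_half_up(100.0 * tn / (tn + fp), decimals)
            if sens == round_half_up(sensitivity_pct, decimals) and spec == round_half_up(
                specificity_pct, decimals
            ):
                candidates.append(ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn))
    if not candidates:
        raise NoConsistentTableError(
            f"no table with margins ({pos_margin}, {neg_margin}) yields "
            f"sensitivity {sensitivity_pct}% and specificity {specificity_pct}%"
        )
    if len(candidates) > 1:
        raise AmbiguousTableError(candidates)
    return candidates[0]


@dataclass
class ConcordanceResult:
    """Cross-classification of two binary response calls on shared patients."""

    both_responder: int
    both_non_responder: int
    panel_nr_ct_r: int
    panel_r_ct_nr: int
    uncompared: int
    disagreement_panel_nr: list[str]
    disagreement_panel_r: list[str]
    uncompared_patients: list[str]

    @property
    def n_compared(self) -> int:
        return (
            self.both_responder
            + self.both_non_responder
            + self.panel_nr_ct_r
            + self.panel_r_ct_nr
        )

    @property
    def n_agreeing(self) -> int:
        return self.both_responder + self.both_non_responder

    def agreement_fraction(self, denominator: int | None = None) -> float:
        """Fraction equally classified; denominator defaults to all patients."""
        den = denominator if denominator is not None else (
            self.n_compared + self.uncompared
        )
        return self.n_agreeing / den


def concordance_table(
    panel_labels: pd.DataFrame, ct_calls: pd.DataFrame
) -> ConcordanceResult:
    """Cross-classify panel vs CT calls patient by patient.

    ``panel_labels`` needs ``patient_id`` and ``label`` (responder /
    non_responder; anything else is uncompared), ``ct_calls`` needs
    ``patient_id`` and ``ct_response`` (unevaluated is uncompared).  Patients
    present in only one table are uncompared as well.
    """
    panel = dict(zip(panel_labels["patient_id"], panel_labels["label"]))
    ct = dict(zip(ct_calls["patient_id"], ct_calls["ct_response"]))
    patients = sorted(set(panel) | set(ct))
    rr = nn = nr_r = r_nr = 0
    dis_nr: list[str] = []
    dis_r: list[str] = []
    uncompared: list[str] = []
    for pid in patients:
        p = panel.get(pid)
        c = ct.get(pid)
        if p not in (RESPONDER, NON_RESPONDER) or c not in (
            RESPONDER,
            NON_RESPONDER,
        ):
            uncompared.append(pid)
            continue
        if p == RESPONDER and c == RESPONDER:
            rr += 1
        elif p == NON_RESPONDER and c == NON_RESPONDER:
            nn += 1
        elif p == NON_RESPONDER and c == RESPONDER:
            nr_r += 1
            dis_nr.append(pid)
        else:
            r_nr += 1
            dis_r.append(pid)
    return ConcordanceResult(
        both_responder=rr,
        both_non_responder=nn,
        panel_nr_ct_r=nr_r,
        panel_r_ct_nr=r_nr,
        uncompared=len(uncompared),
        disagreement_panel_nr=dis_nr,
        disagreement_panel_r=dis_r,
        uncompared_patients=uncompared,
    )


def confusion_from_calls(
    calls: pd.DataFrame, truth: pd.DataFrame, call_col: str = "label"
) -> ConfusionTable:
    """Build a 2x2 table of a classifier's calls against adjudicated truth.

    ``truth`` needs ``patient_id`` and ``true_response``.  Only patients with
    a definite call (responder / non_responder) on both sides are counted.
    """
    merged = calls.merge(truth, on="patient_id", how="inner")
    merged = merged[
        merged[call_col].isin([RESPONDER, NON_RESPONDER])
        & merged["true_response"].isin([RESPONDER, NON_RESPONDER])
    ]
    pred_pos = merged[call_col] == POSITIVE
    true_pos = merged["true_response"] == POSITIVE
    return ConfusionTable(
        tp=int((pred_pos & true_pos).sum()),
        fp=int((pred_pos & ~true_pos).sum()),
        fn=int((~pred_pos & true_pos).sum()),
        tn=int((~pred_pos & ~true_pos).sum()),
    )
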