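"""Model/Results front end tying the pipeline stages together.

``PrediCTCModel`` holds a cohort (Cq + clinical tables) and a panel
configuration; ``fit()`` runs normalization, cutoff estimation, panel
scoring, response classification and the response-model survival fits, and
returns a ``PrediCTCResults`` object carrying estimates, uncertainties and a
``summary()`` table, in the style of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .concordance import (
    ConcordanceResult,
    ConfusionTable,
    DiagnosticMetrics,
    compute_metrics,
    concordance_table,
    confusion_from_calls,
)
from .io import Cohort, assemble_cohort, read_clinical_table, read_cq_table
from .normalization import ExpressionMatrix, build_expression_matrix
from .panel import MarkerPanel
from .response import NON_RESPONDER, RESPONDER, classify_cohort
from .scoring import CutoffSet, score_cohort
from .survival import (
    CoxResult,
    cox_fit,
    marker_survival_report,
    plot_km,
    survival_report,
)


class PrediCTCModel:
    """CTC-panel response model for one cohort.

    Parameters
    ----------
    cohort
        Assembled cohort (see :func:`predictc.io.assemble_cohort`).
    panel
        Marker panel and calling rule; defaults to the 7-gene panel with a
        4-of-7 vote at the 75th percentile.
    """

    def __init__(self, cohort: Cohort, panel: MarkerPanel | None = None):
        self.cohort = cohort
        self.panel = panel or cohort.panel

    @classmethod
    def from_files(
        cls,
        cq_path: str | Path,
        clinical_path: str | Path,
        panel: MarkerPanel | None = None,
    ) -> "PrediCTCModel":
        panel = panel or MarkerPanel()
        cq = read_cq_table(cq_path, panel)
        clinical = read_clinical_table(clinical_path)
        return cls(assemble_cohort(cq, clinical, panel), panel)

    @classmethod
    def from_dataframes(
        cls,
        cq: pd.DataFrame,
        clinical: pd.DataFrame,
        panel: MarkerPanel | None = None,
    ) -> "PrediCTCModel":
        panel = panel or MarkerPanel()
        return cls(assemble_cohort(cq, clinical, panel), panel)

    def fit(
        self,
        cutoffs: CutoffSet | None = None,
        ties: str = "breslow",
    ) -> "PrediCTCResults":
        """Run the full pipeline and fit the response survival models.

        ``cutoffs`` may be supplied (e.g. frozen from a prior study);
        otherwise per-(marker, timepoint) percentile cutoffs are computed
        from this cohort.  ``ties`` selects the Cox tie-handling method.
        """
        expression = build_expression_matrix(self.cohort, self.panel)
        if cutoffs is None:
            cutoffs = CutoffSet.from_expression(expression, self.panel)
        panel_calls = score_cohort(expression, cutoffs, self.panel)
        labels, summary = classify_cohort(panel_calls, self.cohort.patients)

        cox_results: dict[str, CoxResult | None] = {}
        merged = labels.merge(self.cohort.clinical, on="patient_id", how="inner")
        definite = merged[merged["label"].isin([RESPONDER, NON_RESPONDER])]
        for endpoint in ("pfs", "os"):
            sub = definite[definite[f"{endpoint}_months"] > 0]
            if len(sub) and sub[f"{endpoint}_event"].any() and sub["label"].nunique() == 2:
                x = (sub["label"] == NON_RESPONDER).astype(float)
                cox_results[endpoint] = cox_fit(
                    sub[f"{endpoint}_months"],
                    sub[f"{endpoint}_event"],
                    x.to_frame("non_responder"),
                    ties=ties,
                )
            else:
                cox_results[endpoint] = None
        return PrediCTCResults(
            model=self,
            expression=expression,
            cutoffs=cutoffs,
            panel_calls=panel_calls,
            response_calls=labels,
            response_summary=summary,
            cox=cox_results,
        )


@dataclass
class PrediCTCResults:
    """Fitted pipeline state: calls, cutoffs and response survival models."""

    model: PrediCTCModel
    expression: ExpressionMatrix
    cutoffs: CutoffSet
    panel_calls: pd.DataFrame
    response_calls: pd.DataFrame
    response_summary: dict
    cox: dict[str, CoxResult | None]

    # -- survival -----------------------------------------------------------

    def survival_report(
        self, endpoint: str = "pfs", by: str = "response"
    ) -> tuple[pd.DataFrame, float]:
        """Restricted-mean table + log-rank p, stratified by response label
        (``by="response"``) or by the panel group at a timepoint
        (``by="baseline"``/``"week4"``)."""
        clinical = self.model.cohort.clinical
        if by == "response":
            labels = self.response_calls[
                self.response_calls["label"].isin([RESPONDER, NON_RESPONDER])
            ]
            return survival_report(labels, clinical, endpoint, group_col="label")
        calls = self.panel_calls[self.panel_calls["timepoint"] == by]
        labels = calls[["patient_id", "group"]][
            calls["group"].isin(["low_ctc", "high_ctc"])
        ]
        return survival_report(labels, clinical, endpoint, group_col="group")

    def marker_report(self, timepoint: str, endpoint: str = "pfs") -> pd.DataFrame:
        return marker_survival_report(
            self.panel_calls,
            self.model.cohort.clinical,
            self.model.panel.markers,
            timepoint,
            endpoint,
        )

    def plot_km(self, endpoint: str = "pfs", ax=None):
        labels = self.response_calls[
            self.response_calls["label"].isin([RESPONDER, NON_RESPONDER])
        ]
        return plot_km(labels, self.model.cohort.clinical, endpoint, "label", ax=ax)

    # -- concordance --------------------------------------------------------

    def concordance(self) -> ConcordanceResult:
        """Cross-classification of panel vs CT-scan response calls."""
        return concordance_table(
            self.response_calls,
            self.model.cohort.clinical[["patient_id", "ct_response"]],
        )

    def diagnostics(
        self, truth: pd.DataFrame, decimals: int = 1
    ) -> dict[str, dict]:
        """Panel and CT diagnostic metrics against adjudicated truth.

        ``truth`` needs ``patient_id`` and ``true_response`` columns.
        """
        out = {}
        panel_t = confusion_from_calls(self.response_calls, truth, "label")
        out["panel"] = {
            "table": panel_t,
            "metrics": compute_metrics(panel_t, decimals),
        }
        ct_calls = self.model.cohort.clinical[["patient_id", "ct_response"]].rename(
            columns={"ct_response": "label"}
        )
        ct_t = confusion_from_calls(ct_calls, truth, "label")
        out["ct"] = {"table": ct_t, "metrics": compute_metrics(ct_t, decimals)}
        return out

    # -- summary ------------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (counts, paths, hazard ratios)."""
        s = self.response_summary
        lines = [
            "PrediCTC cohort fit",
            "=" * 55,
            f"patients: {s['n_patients']}   classifiable: {s['n_classified']}   "
            f"unclassifiable: {s['n_unclassifiable']}",
            f"responders: {s['n_responder']}   non-responders: {s['n_non_responder']}"
            f"   pending week-16: {s['n_needs_confirmation']}",
            "decision paths: "
            + ", ".join(f"{k}={v}" for k, v in sorted(s["paths"].items())),
            f"classified after one cycle: "
            f"{100 * s['fraction_classified_after_week4']:.1f}%",
            f"cutoffs: {self.cutoffs.provenance} "
            f"(percentile {self.cutoffs.percentile:g})",
            "-" * 55,
        ]
        for endpoint in ("pfs", "os"):
            fit = self.cox.get(endpoint)
            if fit is None:
                lines.append(f"{endpoint.upper()}: no Cox fit (degenerate grouping)")
                continue
            hr = fit.hazard_ratios[0]
            lo, hi = fit.ci[0]
            p = fit.wald_p[0]
            lines.append(
                f"{endpoint.upper()} non-responder vs responder: "
                f"HR {hr:.2f} (95% CI {lo:.2f}-{hi:.2f}), p={p:.4g}"
                + ("  [non-convergent]" if not fit.converged else "")
            )
        return "\n".join(lines)
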