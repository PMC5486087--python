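"""Synthetic cohort generation.

Two generators live here:

* :func:`generate_cohort` — a stochastic simulator producing Cq, clinical and
  truth tables with the statistical structure the analysis assumes: a latent
  non-responder subpopulation shifting correlated marker delta-Cq
  distributions (upward, i.e. more CTC transcript), opposite week-4 drifts
  for the two subpopulations, exponential survival with configurable group
  hazard ratios, administrative uniform censoring, and an imperfect CT
  classifier with configurable sensitivity/specificity.
* :func:`fixed_count_fixture` — a deterministic, hand-constructed 94-patient
  bundle reproducing a fixed count structure (70 responders / 22
  non-responders / 2 unclassifiable, 7 confirmatory week-16 samples with one
  reclassification, a 66/2/17/1 panel-vs-CT cross-tab with 8 uncompared),
  used as a stable end-to-end test input.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ValidationError
from .io import write_clinical_table, write_cq_table
from .panel import DEFAULT_MARKERS, MarkerPanel, Timepoint


@dataclass
class GeneratorConfig:
    """Knobs of the stochastic cohort simulator.

    Marker expression is multivariate normal on the delta-Cq scale (units:
    PCR cycles).  Survival is exponential per latent response group; hazard
    ratios are non-responder vs responder.  CT sensitivity/specificity are
    per-patient mislabeling rates of the latent truth.
    """

    n_patients: int = 94
    prevalence: float = 25 / 92  # latent non-responder fraction
    marker_mean: float = -10.0  # delta-Cq cycles
    marker_sd: float = 3.0
    marker_corr: float = 0.4
    nr_shift: float = 2.0  # non-responder baseline shift, cycles
    week4_shift_responder: float = -1.5
    week4_shift_non_responder: float = 1.5
    week4_noise_sd: float = 1.0
    median_pfs_responder: float = 14.4  # months
    median_os_responder: float = 24.7
    hr_pfs: float = 1.88
    hr_os: float = 3.83
    follow_up_months: float = 30.0  # administrative censoring window
    ct_sensitivity: float = 0.174
    ct_specificity: float = 0.985
    ct_unevaluated_rate: float = 0.0
    missing_sample_rate: float = 0.02
    replicate_jitter_sd: float = 0.15
    reference_cq_mean: float = 26.0
    reference_cq_sd: float = 1.5
    markers: tuple[str, ...] = DEFAULT_MARKERS

    def validate(self) -> None:
        for name in ("prevalence", "ct_sensitivity", "ct_specificity",
                     "ct_unevaluated_rate", "missing_sample_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.marker_sd <= 0 or self.replicate_jitter_sd < 0:
            raise ValidationError("standard deviations must be positive")
        if self.hr_pfs <= 0 or self.hr_os <= 0:
            raise ValidationError("hazard ratios must be positive")
        k = len(self.markers)
        corr = np.full((k, k), self.marker_corr)
        np.fill_diagonal(corr, 1.0)
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValidationError("marker correlation matrix is not PSD")


@dataclass
class SyntheticCohort:
    """Generator output: the three tables plus provenance."""

    cq: pd.DataFrame
    clinical: pd.DataFrame
    truth: pd.DataFrame
    config: dict
    seed: int | None

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "cq": outdir / "cq.csv",
            "clinical": outdir / "clinical.csv",
            "truth": outdir / "truth.csv",
            "provenance": outdir / "provenance.json",
        }
        write_cq_table(self.cq, paths["cq"])
        write_clinical_table(self.clinical, paths["clinical"])
        self.truth.sort_values("patient_id").to_csv(paths["truth"], index=False)
        paths["provenance"].write_text(
            json.dumps({"config": self.config, "seed": self.seed}, indent=2) + "\n"
        )
        return paths


def _exponential_rate(median: float) -> float:
    return math.log(2.0) / median


def censoring_window_for_rate(
    target_rate: float, rates: list[float], weights: list[float]
) -> float:
    """Width W of U(0, W) censoring giving an expected censored fraction.

    For exponential event times with rate lambda and C ~ U(0, W),
    P(censored) = (1 - exp(-lambda W)) / (lambda W); the mixture over groups
    is monotone decreasing in W, so the root is found by bisection.
    """
    if not 0.0 < target_rate < 1.0:
        raise ValidationError("target censoring rate must be in (0, 1)")

    def p_cens(w: float) -> float:
        return sum(
            wt * (1.0 - math.exp(-lam * w)) / (lam * w)
            for lam, wt in zip(rates, weights)
        )

    return float(brentq(lambda w: p_cens(w) - target_rate, 1e-9, 1e9))


def simulate_survival_cohort(
    n_responder: int,
    n_non_responder: int,
    hazard_ratio: float,
    median_responder: float,
    censoring_rate: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One two-group exponential survival cohort with uniform censoring.

    The censoring window is calibrated so the expected censored fraction
    equals ``censoring_rate``; censoring is independent of group and time.
    Returns columns ``group`` (1 = non-responder), ``time``, ``event``.
    """
    lam_r = _exponential_rate(median_responder)
    lam_nr = lam_r * hazard_ratio
    n = n_responder + n_non_responder
    group = np.concatenate(
        [np.zeros(n_responder, dtype=int), np.ones(n_non_responder, dtype=int)]
    )
    rates = np.where(group == 1, lam_nr, lam_r)
    t_event = rng.exponential(1.0 / rates)
    window = censoring_window_for_rate(
        censoring_rate,
        [lam_r, lam_nr],
        [n_responder / n, n_non_responder / n],
    )
    c = rng.uniform(0.0, window, size=n)
    time = np.minimum(t_event, c)
    event = t_event <= c
    # guard against zero times downstream
    time = np.maximum(time, 1e-6)
    return pd.DataFrame({"group": group, "time": time, "event": event})


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int | None = None
) -> SyntheticCohort:
    """Sample one synthetic cohort (deterministic for a fixed seed).

    The latent non-responder label drives the marker shift at baseline, the
    direction of the week-4 drift, the survival hazards and the imperfect CT
    call; the panel classifier therefore sees a noisy signature of the truth,
    so classifier errors attenuate observed hazard ratios, as in real data.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    k = len(config.markers)
    corr = np.full((k, k), config.marker_corr)
    np.fill_diagonal(corr, 1.0)
    cov = corr * config.marker_sd**2

    n = config.n_patients
    width = len(str(n))
    pids = [f"P{i + 1:0{width}d}" for i in range(n)]
    latent_nr = rng.random(n) < config.prevalence

    base = rng.multivariate_normal(
        np.full(k, config.marker_mean), cov, size=n, method="cholesky"
    )
    base[latent_nr] += config.nr_shift
    drift = np.where(
        latent_nr, config.week4_shift_non_responder, config.week4_shift_responder
    )
    wk4 = base + drift[:, None] + rng.normal(0, config.week4_noise_sd, size=(n, k))
    wk16 = wk4 + drift[:, None] + rng.normal(0, config.week4_noise_sd, size=(n, k))
    per_tp = {
        Timepoint.BASELINE.value: base,
        Timepoint.WEEK4.value: wk4,
        Timepoint.WEEK16.value: wk16,
    }

    max_cycles = MarkerPanel(markers=config.markers).max_cycles
    cq_rows: list[tuple] = []
    for j, tp in enumerate(per_tp):
        expr = per_tp[tp]
        missing = rng.random(n) < config.missing_sample_rate
        ref_cq = rng.normal(config.reference_cq_mean, config.reference_cq_sd, size=n)
        jitter = rng.normal(0, config.replicate_jitter_sd, size=(n, k + 1, 2))
        for i in range(n):
            if missing[i]:
                continue
            for rep in (1, 2):
                ref_val = ref_cq[i] + jitter[i, k, rep - 1]
                cq_rows.append(
                    (pids[i], tp, "PTPRC", rep, round(min(ref_val, max_cycles), 3))
                )
            for m, marker in enumerate(config.markers):
                target = ref_cq[i] - expr[i, m]
                for rep in (1, 2):
                    val = target + jitter[i, m, rep - 1]
                    cq_rows.append(
                        (
                            pids[i],
                            tp,
                            marker,
                            rep,
                            math.nan if val >= max_cycles else round(max(val, 0.0), 3),
                        )
                    )
    cq = pd.DataFrame(
        cq_rows, columns=["patient_id", "timepoint", "gene", "replicate", "cq"]
    )

    lam_pfs_r = _exponential_rate(config.median_pfs_responder)
    lam_death_r = _exponential_rate(config.median_os_responder)
    lam_pfs = np.where(latent_nr, lam_pfs_r * config.hr_pfs, lam_pfs_r)
    lam_death = np.where(latent_nr, lam_death_r * config.hr_os, lam_death_r)
    t_prog = rng.exponential(1.0 / lam_pfs)
    t_death = rng.exponential(1.0 / lam_death)
    t_pfs = np.minimum(t_prog, t_death)  # progression or death, whichever first
    censor = rng.uniform(0.0, config.follow_up_months, size=n)
    pfs_months = np.maximum(np.minimum(t_pfs, censor), 1e-3)
    pfs_event = t_pfs <= censor
    os_months = np.maximum(np.minimum(t_death, censor), 1e-3)
    os_event = t_death <= censor

    u = rng.random(n)
    ct = np.where(
        latent_nr,
        np.where(u < config.ct_sensitivity, "non_responder", "responder"),
        np.where(u < config.ct_specificity, "responder", "non_responder"),
    )
    ct = np.where(
        rng.random(n) < config.ct_unevaluated_rate, "unevaluated", ct
    )

    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "pfs_months": np.round(pfs_months, 3),
            "pfs_event": pfs_event,
            "os_months": np.round(os_months, 3),
            "os_event": os_event,
            "ct_response": ct,
            "age_years": rng.integers(35, 85, size=n),
            "sex": rng.choice(["male", "female"], size=n, p=[0.63, 0.37]),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": pids,
            "true_response": np.where(latent_nr, "non_responder", "responder"),
        }
    )
    cfg_dict = asdict(config)
    cfg_dict["markers"] = list(config.markers)
    return SyntheticCohort(
        cq=cq, clinical=clinical, truth=truth, config=cfg_dict, seed=seed
    )


# ---------------------------------------------------------------------------
# Deterministic fixture
# ---------------------------------------------------------------------------

_LOW_DCQ = -10.0  # low-CTC expression level, cycles
_HIGH_DCQ = -4.0  # high-CTC expression level
_REF_CQ = 26.0


def fixed_count_fixture() -> SyntheticCohort:
    """Deterministic 94-patient bundle with a fixed count structure.

    Hand-constructed, not sampled.  Patient blocks (baseline -> week-4 panel
    transitions): 64 low->low, 8 high->high, 13 low->high, 7 high->low (6
    confirmed low at week 16, 1 reclassified high), 2 without a week-4 sample
    (unclassifiable).  Final tallies: 70 responders, 22 non-responders,
    15 high-CTC at baseline; CT cross-tab 66/2/17/1 with 8 uncompared; 71 of
    94 patients progress during follow-up.

    Expression uses two delta-Cq levels only (-10 low, -4 high, reference Cq
    26), so the 75th-percentile cutoff of every marker is -10 at every
    timepoint and "high" is exactly the strictly-greater set; duplicates are
    identical.  The adjudicated ``true_response`` column is laid out so the
    panel's 2x2 table against truth is tp=15, fp=7, fn=10, tn=60.
    """
    n = 94
    pids = [f"P{i + 1:03d}" for i in range(n)]
    blocks = (
        ["LL"] * 64 + ["HH"] * 8 + ["LH"] * 13 + ["HL_low"] * 6 + ["HL_high"] * 1
        + ["missing_week4"] * 2
    )
    assert len(blocks) == n
    panel = MarkerPanel()

    def level(block: str, tp: str) -> float | None:
        if block == "missing_week4":
            return _LOW_DCQ if tp == "baseline" else None
        base_high = block in ("HH", "HL_low", "HL_high")
        wk4_high = block in ("HH", "LH")
        if tp == "baseline":
            return _HIGH_DCQ if base_high else _LOW_DCQ
        if tp == "week4":
            return _HIGH_DCQ if wk4_high else _LOW_DCQ
        # week 16 sampled only for the HL confirmation branch
        if block == "HL_low":
            return _LOW_DCQ
        if block == "HL_high":
            return _HIGH_DCQ
        return None

    cq_rows = []
    for pid, block in zip(pids, blocks):
        for tp in ("baseline", "week4", "week16"):
            dcq = level(block, tp)
            if dcq is None:
                continue
            for rep in (1, 2):
                cq_rows.append((pid, tp, panel.reference_gene, rep, _REF_CQ))
            for marker in panel.markers:
                for rep in (1, 2):
                    cq_rows.append((pid, tp, marker, rep, _REF_CQ - dcq))
    cq = pd.DataFrame(
        cq_rows, columns=["patient_id", "timepoint", "gene", "replicate", "cq"]
    )

    # final labels implied by the blocks
    label = {
        "LL": "responder",
        "HH": "non_responder",
        "LH": "non_responder",
        "HL_low": "responder",
        "HL_high": "non_responder",
        "missing_week4": "unclassifiable",
    }
    labels = [label[b] for b in blocks]
    responders = [p for p, l in zip(pids, labels) if l == "responder"]
    non_responders = [p for p, l in zip(pids, labels) if l == "non_responder"]
    assert len(responders) == 70 and len(non_responders) == 22

    # CT calls: 66 R/R + 1 R/NR + 3 R-unevaluated; 17 NR/R + 2 NR/NR +
    # 3 NR-unevaluated; the 2 unclassifiable are uncompared regardless.
    ct_call = {}
    for i, pid in enumerate(responders):
        ct_call[pid] = (
            "responder" if i < 66 else "non_responder" if i < 67 else "unevaluated"
        )
    for i, pid in enumerate(non_responders):
        ct_call[pid] = (
            "responder" if i < 17 else "non_responder" if i < 19 else "unevaluated"
        )
    for pid, block in zip(pids, blocks):
        if block == "missing_week4":
            ct_call[pid] = "responder"

    # adjudicated truth giving the panel table tp=15, fp=7, fn=10, tn=60
    truth_call = {}
    for i, pid in enumerate(non_responders):  # panel-positive margin (22)
        truth_call[pid] = "non_responder" if i < 15 else "responder"
    for i, pid in enumerate(responders):  # panel-negative margin (70)
        truth_call[pid] = "non_responder" if i < 10 else "responder"
    for pid, block in zip(pids, blocks):
        if block == "missing_week4":
            truth_call[pid] = "responder"

    # survival: every non-responder progresses (22) plus 49 responders -> 71
    rows = []
    resp_rank = {p: i for i, p in enumerate(responders)}
    nr_rank = {p: i for i, p in enumerate(non_responders)}
    for pid, block, lab in zip(pids, blocks, labels):
        if lab == "non_responder":
            i = nr_rank[pid]
            pfs, pfs_ev = 4.0 + 0.4 * i, True
            os_m, os_ev = 8.0 + 0.5 * i, i < 18
        elif lab == "responder":
            i = resp_rank[pid]
            pfs_ev = i < 49
            pfs = 9.0 + 0.2 * i if pfs_ev else 18.0 + 0.3 * (i - 49)
            os_ev = i < 30
            os_m = 16.0 + 0.4 * i if os_ev else 26.0 + 0.2 * (i - 30)
        else:  # unclassifiable: baseline-only patients still have follow-up
            pfs, pfs_ev = 10.0, False
            os_m, os_ev = 20.0, False
        os_m = max(os_m, pfs)
        rows.append(
            (pid, round(pfs, 3), pfs_ev, round(os_m, 3), os_ev, ct_call[pid])
        )
    clinical = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "pfs_months",
            "pfs_event",
            "os_months",
            "os_event",
            "ct_response",
        ],
    )
    assert int(clinical["pfs_event"].sum()) == 71

    truth = pd.DataFrame(
        {"patient_id": pids, "true_response": [truth_call[p] for p in pids]}
    )
    return SyntheticCohort(
        cq=cq,
        clinical=clinical,
        truth=truth,
        config={"kind": "fixed_count_fixture"},
        seed=None,
    )
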