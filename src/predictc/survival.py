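"""Kaplan-Meier curves, restricted-mean survival, log-rank and Cox models.

The "mean survival" reported for each stratum is the restricted mean
survival time (RMST): the area under the Kaplan-Meier curve up to a
truncation time, by default the largest observed time in the stratum.  Its
standard error uses the standard area-based variance

    Var(RMST) = sum over event times t_i <= tau of
                A_i^2 * d_i / (n_i * (n_i - d_i)),   A_i = integral of S on [t_i, tau]

and 95% confidence intervals are normal-approximation throughout.

Kaplan-Meier estimation and the log-rank test are delegated to lifelines;
the Cox proportional-hazards fitter is implemented here (Newton-Raphson on
the partial likelihood) with Breslow tie handling as the default and Efron
selectable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test as _ll_mv_logrank
from scipy import stats

from .errors import ValidationError


# ---------------------------------------------------------------------------
# Kaplan-Meier and restricted mean
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit estimate plus its restricted-mean summary.

    ``event_times`` are the distinct observed-event times (ascending);
    ``survival`` is S(t) just after each event time; ``at_risk`` and
    ``n_events`` the corresponding risk-set sizes and event counts.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    tau: float
    restricted_mean: float
    rm_se: float
    rm_ci: tuple[float, float]
    max_observed_time: float
    all_censored: bool = False

    def survival_at(self, t: float) -> float:
        """S(t) as a right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def _rmst_with_se(
    event_times: np.ndarray,
    survival: np.ndarray,
    at_risk: np.ndarray,
    n_events: np.ndarray,
    tau: float,
) -> tuple[float, float]:
    """Area under the KM step function on [0, tau] and its SE."""
    # grid of step starts within [0, tau]: 0 (S=1) then each event time
    starts = [0.0]
    values = [1.0]
    for t, s in zip(event_times, survival):
        if t >= tau:
            break
        starts.append(float(t))
        values.append(float(s))
    starts.append(tau)
    area = 0.0
    tail_areas = []  # integral of S from each event time to tau
    for k in range(len(values)):
        area += values[k] * (starts[k + 1] - starts[k])
    for i, t in enumerate(event_times):
        if t >= tau:
            tail_areas.append(0.0)
            continue
        a = 0.0
        for k in range(len(values)):
            lo, hi = max(starts[k], t), starts[k + 1]
            if hi > lo:
                a += values[k] * (hi - lo)
        tail_areas.append(a)
    var = 0.0
    for a, d, n in zip(tail_areas, n_events, at_risk):
        if n - d > 0:
            var += a * a * d / (n * (n - d))
    return area, math.sqrt(var)


def km_estimate(
    times: Sequence[float], events: Sequence[bool], tau: float | None = None
) -> KMCurve:
    """Kaplan-Meier product-limit estimate with restricted-mean summary.

    Censored observations tied with events at the same time are handled in
    the standard way (censoring after events).  ``tau`` defaults to the
    largest observed time; an all-censored input yields the degenerate curve
    S = 1 with the restricted mean flagged truncation-limited.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=bool)
    if times.size == 0:
        raise ValidationError("km_estimate requires at least one record")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValidationError("survival times must be finite and positive")

    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    observed = table[table["observed"] > 0]
    event_times = observed.index.to_numpy(dtype=float)
    n_events = observed["observed"].to_numpy(dtype=float)
    at_risk = observed["at_risk"].to_numpy(dtype=float)
    surv = np.asarray(
        [float(kmf.survival_function_at_times(t).iloc[0]) for t in event_times]
    )

    max_observed = float(times.max())
    all_censored = event_times.size == 0
    if all_censored:
        warnings.warn(
            "all observations censored: survival curve is flat and the "
            "restricted mean is truncation-limited",
            stacklevel=2,
        )
    if tau is None:
        tau = max_observed
    if tau > max_observed:
        raise ValidationError(
            f"truncation time {tau} exceeds the largest observed time {max_observed}"
        )
    area, se = _rmst_with_se(event_times, surv, at_risk, n_events, tau)
    z = stats.norm.ppf(0.975)
    return KMCurve(
        event_times=event_times,
        survival=surv,
        at_risk=at_risk,
        n_events=n_events,
        tau=float(tau),
        restricted_mean=area,
        rm_se=se,
        rm_ci=(area - z * se, area + z * se),
        max_observed_time=max_observed,
        all_censored=all_censored,
    )


def restricted_mean(curve: KMCurve, tau: float) -> tuple[float, tuple[float, float]]:
    """RMST of an existing curve at a new truncation time, with its 95% CI."""
    if tau > curve.max_observed_time:
        raise ValidationError(
            f"truncation time {tau} exceeds follow-up ({curve.max_observed_time})"
        )
    area, se = _rmst_with_se(
        curve.event_times, curve.survival, curve.at_risk, curve.n_events, tau
    )
    z = stats.norm.ppf(0.975)
    return area, (area - z * se, area + z * se)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p_value: float


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> LogrankResult:
    """Two-group log-rank test (hypergeometric expectations per event time)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a = np.asarray(events_a, bool)
    events_b = np.asarray(events_b, bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise ValidationError("log-rank statistic undefined with zero events")
    res = _ll_logrank(times_a, times_b, events_a, events_b)
    return LogrankResult(chi2=float(res.test_statistic), p_value=float(res.p_value))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Partial-likelihood fit of a Cox proportional-hazards model."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    converged: bool
    monotone_likelihood: bool = False

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> np.ndarray:
        """95% CI bounds for the hazard ratios, shape (p, 2)."""
        z = stats.norm.ppf(0.975)
        return np.exp(
            np.column_stack([self.coef - z * self.se, self.coef + z * self.se])
        )

    @property
    def wald_p(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    @property
    def model_chi2(self) -> float:
        """Likelihood-ratio chi-square against the null model."""
        return 2.0 * (self.loglik - self.loglik_null)

    @property
    def model_p(self) -> float:
        return float(stats.chi2.sf(self.model_chi2, df=len(self.covariates)))

    def summary(self) -> pd.DataFrame:
        ci = self.ci
        return pd.DataFrame(
            {
                "coef": self.coef,
                "HR": self.hazard_ratios,
                "HR 95% low": ci[:, 0],
                "HR 95% high": ci[:, 1],
                "se(coef)": self.se,
                "p": self.wald_p,
            },
            index=self.covariates,
        )


def _cox_loglik_grad_hess(
    beta: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    ties: str,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow or Efron partial log-likelihood with analytic derivatives."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for t in np.unique(times[events]):
        risk = times >= t
        dead = events & (times == t)
        d = int(dead.sum())
        sw = w[risk].sum()
        swx = (w[risk, None] * X[risk]).sum(axis=0)
        swxx = np.einsum("i,ij,ik->jk", w[risk], X[risk], X[risk])
        s_dead = X[dead].sum(axis=0)
        ll += eta[dead].sum()
        if ties == "breslow" or d == 1:
            ll -= d * math.log(sw)
            xbar = swx / sw
            grad += s_dead - d * xbar
            hess += d * (swxx / sw - np.outer(xbar, xbar))
        elif ties == "efron":
            dw = w[dead].sum()
            dwx = (w[dead, None] * X[dead]).sum(axis=0)
            dwxx = np.einsum("i,ij,ik->jk", w[dead], X[dead], X[dead])
            grad += s_dead
            for l in range(d):
                f = l / d
                phi = sw - f * dw
                phix = swx - f * dwx
                phixx = swxx - f * dwxx
                ll -= math.log(phi)
                grad -= phix / phi
                hess += phixx / phi - np.outer(phix, phix) / phi**2
        else:
            raise ValueError(f"unknown tie method {ties!r}")
    return ll, grad, hess


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    X: pd.DataFrame | np.ndarray,
    covariates: list[str] | None = None,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    ``ties`` selects Breslow (default) or Efron handling of tied event times.
    A monotone partial likelihood (perfect separation of event order by a
    covariate) is detected and flagged rather than silently reported as a
    finite estimate.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    if isinstance(X, pd.DataFrame):
        covariates = covariates or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        covariates = covariates or [f"x{i}" for i in range(X.shape[1])]
    if events.sum() == 0:
        raise ValidationError("Cox fit requires at least one event")

    center = X.mean(axis=0)
    Xc = X - center  # centering stabilizes exp() without changing beta

    beta = np.zeros(X.shape[1])
    ll0, _, _ = _cox_loglik_grad_hess(beta, times, events, Xc, ties)
    ll = ll0
    converged = False
    monotone = False
    for _ in range(max_iter):
        ll, grad, hess = _cox_loglik_grad_hess(beta, times, events, Xc, ties)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            monotone = True
            break
        # step-halving to keep the likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            ll_new, _, _ = _cox_loglik_grad_hess(candidate, times, events, Xc, ties)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        if np.max(np.abs(beta)) > 15.0:
            monotone = True  # estimate running away: monotone likelihood
            break
        if np.max(np.abs(scale * step)) < tol:
            converged = True
            break

    ll, grad, hess = _cox_loglik_grad_hess(beta, times, events, Xc, ties)
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.nan)
    if monotone:
        warnings.warn(
            "monotone partial likelihood detected; coefficient estimates do "
            "not converge (perfect separation of event order)",
            stacklevel=2,
        )
    return CoxResult(
        covariates=covariates,
        coef=beta,
        se=se,
        loglik=ll,
        loglik_null=ll0,
        n=len(times),
        n_events=int(events.sum()),
        ties=ties,
        converged=converged and not monotone,
        monotone_likelihood=monotone,
    )


def cox_score_test(
    times: Sequence[float], events: Sequence[bool], x: Sequence[float]
) -> tuple[float, float]:
    """Score test of beta = 0 for a single covariate.

    With Breslow tie handling this equals the two-group log-rank chi-square
    when the covariate is a group indicator.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.asarray(x, float)[:, None]
    _, grad, hess = _cox_loglik_grad_hess(
        np.zeros(1), times, events, X - X.mean(axis=0), "breslow"
    )
    chi2 = float(grad[0] ** 2 / hess[0, 0])
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# Stratified reports
# ---------------------------------------------------------------------------


def survival_report(
    labels: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "pfs",
    group_col: str = "label",
    include_groups: Iterable[str] | None = None,
    tau: float | None = None,
) -> tuple[pd.DataFrame, float]:
    """Restricted-mean survival per stratum plus an across-strata log-rank p.

    ``labels`` must carry ``patient_id`` and ``group_col``; survival columns
    ``{endpoint}_months`` / ``{endpoint}_event`` are pulled from ``clinical``.
    Strata with no subjects are omitted with a warning; the log-rank p is NaN
    for a single stratum.
    """
    if endpoint not in ("pfs", "os"):
        raise ValidationError("endpoint must be 'pfs' or 'os'")
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    merged = labels.merge(
        clinical[["patient_id", time_col, event_col]], on="patient_id", how="inner"
    )
    merged = merged[merged[time_col] > 0]
    if include_groups is not None:
        include = list(include_groups)
        missing = [g for g in include if g not in set(merged[group_col])]
        for g in missing:
            warnings.warn(f"stratum {g!r} has no subjects; omitted", stacklevel=2)
        merged = merged[merged[group_col].isin(include)]

    rows = []
    by_group: dict[str, pd.DataFrame] = {}
    for g, sub in merged.groupby(group_col, sort=True):
        by_group[str(g)] = sub
        curve = km_estimate(sub[time_col], sub[event_col], tau=tau)
        rows.append(
            {
                group_col: g,
                "n": len(sub),
                "events": int(sub[event_col].sum()),
                "mean_months": curve.restricted_mean,
                "ci_low": curve.rm_ci[0],
                "ci_high": curve.rm_ci[1],
                "tau": curve.tau,
            }
        )
    table = pd.DataFrame(rows)

    p = float("nan")
    if len(by_group) == 2:
        (ga, sa), (gb, sb) = sorted(by_group.items())
        p = logrank_test(
            sa[time_col], sa[event_col], sb[time_col], sb[event_col]
        ).p_value
    elif len(by_group) > 2:
        res = _ll_mv_logrank(
            merged[time_col], merged[group_col], merged[event_col]
        )
        p = float(res.p_value)
    return table, p


def marker_survival_report(
    panel_calls: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: Iterable[str],
    timepoint: str,
    endpoint: str = "pfs",
) -> pd.DataFrame:
    """Per-marker low/high restricted-mean table (one row per marker level)."""
    calls_tp = panel_calls[panel_calls["timepoint"] == timepoint]
    frames = []
    for marker in markers:
        labels = calls_tp[["patient_id", marker]].rename(columns={marker: "level"})
        labels = labels[labels["level"].isin(["low", "high"])]
        if labels.empty:
            warnings.warn(f"no calls for marker {marker!r}; omitted", stacklevel=2)
            continue
        table, p = survival_report(
            labels, clinical, endpoint=endpoint, group_col="level"
        )
        table.insert(0, "marker", marker)
        table["logrank_p"] = p
        frames.append(table)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def plot_km(
    labels: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "pfs",
    group_col: str = "label",
    ax=None,
):
    """Step plot of the Kaplan-Meier curves per stratum (matplotlib axes)."""
    import matplotlib.pyplot as plt

    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    merged = labels.merge(
        clinical[["patient_id", time_col, event_col]], on="patient_id", how="inner"
    )
    if ax is None:
        _, ax = plt.subplots()
    for g, sub in merged.groupby(group_col, sort=True):
        kmf = KaplanMeierFitter().fit(sub[time_col], sub[event_col], label=str(g))
        kmf.plot_survival_function(ax=ax, ci_show=False)
    ax.set_xlabel("months")
    ax.set_ylabel(f"{endpoint.upper()} probability")
    return ax
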