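"""Censored time-to-event analysis for biomarker stratification.

Product-limit (Kaplan-Meier) estimation, the two-group log-rank test,
optimal dichotomization by the Youden index of the marker's ROC against
the observed-event indicator, median splits, and univariate Cox
proportional-hazards fits with Efron tie handling — the three-way
(continuous / median / Youden) evaluation used for genes and cell-score
ratios against recurrence and metastasis endpoints.

Under censoring the ROC's positive class is "event observed during
follow-up"; censored subjects count as non-events. This is a pragmatic
convention, not a time-dependent ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ConvergenceError(RuntimeError):
    """Raised when the Cox partial likelihood is monotone/divergent."""


def _validate_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan-Meier table: one row per distinct time.

    Columns ``time``, ``n_at_risk``, ``n_events``, ``survival`` (the
    estimate just after ``time``). Subjects censored at t are still at
    risk at t.
    """
    times, events = _validate_surv(times, events)
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    uniq = np.unique(times)
    rows, surv, n = [], 1.0, times.size
    for t in uniq:
        at = times == t
        n_at_risk = int((times >= t).sum())
        d = int(events[at].sum())
        if d:
            surv *= 1.0 - d / n_at_risk
        rows.append((float(t), n_at_risk, d, surv))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and p-value.

    At each distinct event time the observed-minus-expected events in
    group 1 accumulate with the hypergeometric variance.
    """
    times, events = _validate_surv(times, events)
    group = np.asarray(group)
    levels = np.unique(group)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {list(levels)}")
    g1 = group == levels[1]
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank p = 1")
        return 0.0, 1.0
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = int(events[times == t].sum())
        d1 = int(events[(times == t) & g1].sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n - d) * n1 * (n - n1) / (n ** 2 * (n - 1))
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e ** 2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CutpointResult:
    marker: str
    method: str                # youden | median
    cutoff: float
    direction: str             # side enriched for events: "high" or "low"
    j_statistic: float         # sensitivity + specificity - 1, oriented
    groups: pd.Series          # per-sample "high"/"low"


def youden_cutpoint(marker, event, name: str = "marker") -> CutpointResult:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Candidate cutoffs are midpoints between consecutive sorted distinct
    marker values; both orientations (events enriched above or below
    the cutoff) are evaluated and ties resolve to the lowest cutoff.
    Samples with value > cutoff are labelled "high".
    """
    marker = pd.Series(np.asarray(marker, dtype=float)) if not isinstance(marker, pd.Series) \
        else marker.astype(float)
    event = np.asarray(event).astype(int)
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    if event.sum() == 0 or event.sum() == event.size:
        raise ValueError("both classes must be present for ROC analysis")
    vals = marker.to_numpy()
    distinct = np.unique(vals)
    if distinct.size < 2:
        raise ValueError("marker must take at least 2 distinct values")
    cuts = (distinct[:-1] + distinct[1:]) / 2.0

    n_pos, n_neg = event.sum(), (1 - event).sum()
    best = None
    for cut in cuts:
        high = vals > cut
        sens_high = (high & (event == 1)).sum() / n_pos
        spec_high = (~high & (event == 0)).sum() / n_neg
        j_high = sens_high + spec_high - 1.0
        j, direction = (j_high, "high") if j_high >= -j_high else (-j_high, "low")
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cut), direction)
    j, cutoff, direction = best
    groups = pd.Series(np.where(vals > cutoff, "high", "low"), index=marker.index)
    return CutpointResult(marker=name, method="youden", cutoff=cutoff,
                          direction=direction, j_statistic=float(j), groups=groups)


def dichotomize(marker, method: str, event=None, name: str = "marker") -> CutpointResult:
    """Split samples into high/low by Youden cutpoint or sample median.

    Median splits send values equal to the median to "low". Degenerate
    splits (an empty group) raise.
    """
    marker = pd.Series(np.asarray(marker, dtype=float)) if not isinstance(marker, pd.Series) \
        else marker.astype(float)
    if method == "youden":
        if event is None:
            raise ValueError("youden dichotomization needs the event indicator")
        res = youden_cutpoint(marker, event, name=name)
    elif method == "median":
        if marker.size < 2:
            raise ValueError("median split needs n >= 2")
        cutoff = float(marker.median())
        groups = pd.Series(np.where(marker.to_numpy() > cutoff, "high", "low"),
                           index=marker.index)
        res = CutpointResult(marker=name, method="median", cutoff=cutoff,
                             direction="high", j_statistic=float("nan"), groups=groups)
    else:
        raise ValueError(f"unknown method {method!r}")
    counts = res.groups.value_counts()
    if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
        raise ValueError(f"degenerate split for {name!r}: one group is empty")
    return res


def _efron_quantities(beta: float, times, events, x):
    """Log partial likelihood, score, and information at beta (Efron ties)."""
    order = np.argsort(-times, kind="stable")  # decreasing time
    t_s, e_s, x_s = times[order], events[order], x[order]
    eta = beta * x_s
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_s)
    s2 = np.cumsum(w * x_s ** 2)
    ll = u = info = 0.0
    i = 0
    n = t_s.size
    while i < n:
        j = i
        while j < n and t_s[j] == t_s[i]:
            j += 1
        # indices i..j-1 share this time; risk set = everything up to j-1
        ev = np.arange(i, j)[e_s[i:j] == 1]
        d = ev.size
        if d:
            S0, S1, S2 = s0[j - 1], s1[j - 1], s2[j - 1]
            wd = w[ev]
            d0, d1, d2 = wd.sum(), (wd * x_s[ev]).sum(), (wd * x_s[ev] ** 2).sum()
            ll += eta[ev].sum()
            u += x_s[ev].sum()
            for l in range(d):
                f = l / d
                phi0 = S0 - f * d0
                phi1 = S1 - f * d1
                phi2 = S2 - f * d2
                ll -= np.log(phi0)
                u -= phi1 / phi0
                info += phi2 / phi0 - (phi1 / phi0) ** 2
        i = j
    return ll, u, info


def cox_univariate(times, events, covariate, tol: float = 1e-8,
                   max_iter: int = 50) -> tuple[float, float, float, float]:
    """Univariate Cox fit: returns (beta, hazard ratio, se, Wald p).

    Safeguarded Newton iterations (step halving on likelihood decrease)
    on the Efron-tie partial likelihood; convergence at |step| < 1e-8.
    A constant covariate or a monotone likelihood (perfect separation)
    raises.
    """
    times, events = _validate_surv(times, events)
    x = np.asarray(covariate, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    if events.sum() == 0:
        raise ValueError("no events observed")

    beta = 0.0
    ll, u, info = _efron_quantities(beta, times, events, x)
    for _ in range(max_iter):
        if info <= 0:
            raise ConvergenceError("non-positive information; cannot fit")
        step = u / info
        new_beta = beta + step
        new_ll, new_u, new_info = _efron_quantities(new_beta, times, events, x)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_u, new_info = _efron_quantities(new_beta, times, events, x)
            halvings += 1
        beta, ll, u, info = new_beta, new_ll, new_u, new_info
        if abs(beta) > 25:
            raise ConvergenceError(
                "partial likelihood appears monotone (perfect separation)")
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError("Newton iterations did not converge")
    se = 1.0 / np.sqrt(info)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return float(beta), float(np.exp(beta)), float(se), p


@dataclass
class SurvivalResult:
    """Three-way evaluation of one marker against one endpoint."""

    marker: str
    endpoint: str
    cox_beta: float
    cox_hr: float
    cox_se: float
    cox_p: float
    cutpoints: dict[str, CutpointResult]
    logrank: dict[str, tuple[float, float]]     # method -> (chi2, p)
    km_curves: dict[tuple[str, str], pd.DataFrame]  # (method, group) -> table


def evaluate_marker(marker: pd.Series, times, events, name: str,
                    endpoint: str, methods=("youden", "median")) -> SurvivalResult:
    """Continuous Cox plus dichotomized log-rank analyses of one marker."""
    times, ev = _validate_surv(times, events)
    beta, hr, se, p = cox_univariate(times, ev, marker.to_numpy())
    cutpoints, logrank, curves = {}, {}, {}
    for method in methods:
        cp = dichotomize(marker, method, event=ev, name=name)
        cutpoints[method] = cp
        chi2, lr_p = logrank_test(times, ev, cp.groups.to_numpy())
        logrank[method] = (chi2, lr_p)
        for level in ("low", "high"):
            mask = (cp.groups == level).to_numpy()
            curves[(method, level)] = km_estimate(times[mask], ev[mask])
    return SurvivalResult(marker=name, endpoint=endpoint, cox_beta=beta,
                          cox_hr=hr, cox_se=se, cox_p=p, cutpoints=cutpoints,
                          logrank=logrank, km_curves=curves)
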