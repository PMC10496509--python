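"""Survival analysis primitives: Kaplan-Meier curves, the two-group log-rank
test with its O-E hazard-ratio estimator, and the maximally-selected
("optimal") expression cutoff used to dichotomize patients.

The hazard ratio is the Pike estimator ``HR = exp((O1-E1)/V)`` derived from
the log-rank observed-minus-expected statistic, with
``CI = exp((O1-E1)/V +/- 1.96/sqrt(V))``.  Group 1 is always the
high-covariate group when a cutoff is involved, so HR > 1 means high
expression is associated with worse outcome.

The cutoff scan maximizes the log-rank chi-square over every admissible
split; the reported p-value is the naive log-rank p at the selected cutoff
and is therefore anti-conservative — every result carries a
``selection_bias`` flag recording that no multiple-testing correction for
the scan is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _dist

__all__ = [
    "SurvivalComparison",
    "km_curve",
    "logrank_test",
    "logrank_counts",
    "optimal_cutoff",
    "stratified_survival",
    "load_survival_table",
    "write_km_curve",
]


@dataclass(frozen=True)
class SurvivalComparison:
    """Two-group log-rank comparison summary.

    ``observed_minus_expected`` and ``variance`` refer to group 1 (the
    high-expression group when produced by a cutoff scan).
    """

    chi2: float
    p: float
    hr: float
    hr_ci: tuple[float, float]
    n_high: int
    n_low: int
    observed_minus_expected: float
    variance: float
    cutoff: float = math.nan
    selection_bias: bool = False
    note: str = ""


def _check_times(time: np.ndarray) -> None:
    if time.size == 0:
        raise ValueError("empty survival input")
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and positive")


def km_curve(time, event) -> pd.DataFrame:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns a step-function table with columns ``time``, ``n_at_risk``,
    ``n_events``, ``survival``; the first row is (0, n, 0, 1).  At tied
    times events are handled before censorings (both leave the risk set
    after the time point, so the product-limit factor uses everyone still
    at risk at that time).
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(int)
    _check_times(time)
    if time.size != event.size:
        raise ValueError("time/event length mismatch")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    n = time.size
    rows = [(0.0, n, 0, 1.0)]
    s = 1.0
    i = 0
    while i < n:
        t = time[i]
        j = i
        d = 0
        while j < n and time[j] == t:
            d += int(event[j])
            j += 1
        at_risk = n - i
        if d > 0:
            s *= 1.0 - d / at_risk
            rows.append((t, at_risk, d, s))
        i = j
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events",
                                       "survival"])


def logrank_counts(time1, event1, time2, event2):
    """Log-rank O1, E1, V summed over the distinct event times of the
    pooled sample, using the hypergeometric variance at each time."""
    t1 = np.asarray(time1, dtype=float).ravel()
    e1 = np.asarray(event1).ravel().astype(int)
    t2 = np.asarray(time2, dtype=float).ravel()
    e2 = np.asarray(event2).ravel().astype(int)
    _check_times(t1)
    _check_times(t2)
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group1 = np.concatenate([np.ones(t1.size, bool), np.zeros(t2.size, bool)])
    event_times = np.unique(times[events == 1])
    O1 = E1 = V = 0.0
    for t in event_times:
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group1).sum())
        dmask = (times == t) & (events == 1)
        d = int(dmask.sum())
        d1 = int((dmask & group1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O1, E1, V


def _comparison_from_counts(O1, E1, V, n1, n2, cutoff=math.nan,
                            selection_bias=False, note="") -> SurvivalComparison:
    ome = O1 - E1
    if V <= 0:
        # no information (e.g. all events in one pattern): null comparison
        return SurvivalComparison(0.0, 1.0, 1.0, (math.nan, math.nan),
                                  n1, n2, ome, V, cutoff, selection_bias, note)
    chi2 = ome * ome / V
    p = float(_dist.chi2.sf(chi2, 1))
    loghr = ome / V
    half = 1.96 / math.sqrt(V)
    return SurvivalComparison(chi2, p, math.exp(loghr),
                              (math.exp(loghr - half), math.exp(loghr + half)),
                              n1, n2, ome, V, cutoff, selection_bias, note)


def logrank_test(time1, event1, time2, event2) -> SurvivalComparison:
    """Two-group log-rank test; group 1 plays the 'high' role in the HR."""
    e1 = np.asarray(event1).ravel().astype(int)
    e2 = np.asarray(event2).ravel().astype(int)
    if e1.sum() == 0:
        raise ValueError("group 1 has zero events")
    if e2.sum() == 0:
        raise ValueError("group 2 has zero events")
    O1, E1, V = logrank_counts(time1, event1, time2, event2)
    return _comparison_from_counts(O1, E1, V, e1.size, e2.size)


def _scan_chi2(time, event, covariate, cutoffs):
    """Vectorized log-rank scan: chi2, O1-E1 and V of the high group
    (covariate > cutoff) for every candidate cutoff at once."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    covariate = np.asarray(covariate, dtype=float)
    event_times = np.unique(time[event == 1])
    # risk/death indicator matrices: patients x event-times
    R = time[:, None] >= event_times[None, :]
    D = (time[:, None] == event_times[None, :]) & (event[:, None] == 1)
    n_t = R.sum(axis=0).astype(float)
    d_t = D.sum(axis=0).astype(float)
    M = covariate[None, :] > np.asarray(cutoffs, dtype=float)[:, None]
    n1_t = M.astype(float) @ R
    d1_t = M.astype(float) @ D
    frac = n1_t / n_t
    E1 = (d_t * frac).sum(axis=1)
    O1 = d1_t.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vterm = np.where(n_t > 1, d_t * frac * (1 - frac) * (n_t - d_t) /
                         np.maximum(n_t - 1, 1), 0.0)
    V = vterm.sum(axis=1)
    ome = O1 - E1
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, ome * ome / V, 0.0)
    return chi2, ome, V


def optimal_cutoff(time, event, covariate, minprop: float = 0.1):
    """Maximally-selected log-rank cutoff for a continuous covariate.

    Every distinct covariate value ``c`` is a candidate split
    (low: covariate <= c; high: covariate > c) provided both groups contain
    at least ``minprop * n`` patients and at least one event.  The cutoff
    maximizing the log-rank chi-square wins; ties break toward the smaller
    covariate value.  Returns ``(cutoff, SurvivalComparison)`` where the
    comparison's group 1 is the high-expression group.
    """
    time = np.asarray(time, dtype=float).ravel()
    event = np.asarray(event).ravel().astype(int)
    covariate = np.asarray(covariate, dtype=float).ravel()
    _check_times(time)
    if not (0.0 < minprop < 0.5):
        raise ValueError("minprop must lie in (0, 0.5)")
    if np.unique(covariate[np.isfinite(covariate)]).size < 2:
        raise ValueError("covariate is constant; no cutoff exists")
    keep = np.isfinite(covariate)
    time, event, covariate = time[keep], event[keep], covariate[keep]
    n = time.size
    if n < 10:
        raise ValueError(f"need n >= 10 for a cutoff scan, got {n}")
    values = np.unique(covariate)
    lowsize = np.searchsorted(np.sort(covariate), values, side="right")
    min_n = minprop * n
    admissible = (lowsize >= min_n) & ((n - lowsize) >= min_n)
    cand = values[admissible]
    # both sides must contain at least one event
    ev_cov = np.sort(covariate[event == 1])
    if ev_cov.size:
        low_ev = np.searchsorted(ev_cov, cand, side="right")
        cand = cand[(low_ev >= 1) & (ev_cov.size - low_ev >= 1)]
    else:
        cand = cand[:0]
    if cand.size == 0:
        raise ValueError("no admissible cutoff under the constraints")
    chi2, _, _ = _scan_chi2(time, event, covariate, cand)
    best = int(np.argmax(chi2))  # argmax takes the first (smallest) on ties
    c = float(cand[best])
    high = covariate > c
    comp = logrank_test(time[high], event[high], time[~high], event[~high])
    return c, SurvivalComparison(
        comp.chi2, comp.p, comp.hr, comp.hr_ci, comp.n_high, comp.n_low,
        comp.observed_minus_expected, comp.variance, cutoff=c,
        selection_bias=True,
        note="naive log-rank p at a maximally selected cutoff; "
             "no correction for the scan applied")


@dataclass(frozen=True)
class StratumResult:
    """Per-stratum outcome of a stratified cutoff analysis."""

    stratum: str
    evaluable: bool
    cutoff: float = math.nan
    comparison: SurvivalComparison | None = None
    reason: str = ""


def stratified_survival(frame: pd.DataFrame, minprop: float = 0.1,
                        covariate: str = "expression",
                        stratum: str = "stratum") -> dict[str, StratumResult]:
    """Run :func:`optimal_cutoff` independently within each stratum (e.g.
    p53 wt vs mut).  A stratum that cannot be evaluated (too small,
    constant covariate, no admissible split) is reported as such; the
    others are still returned.
    """
    out: dict[str, StratumResult] = {}
    for label, sub in frame.groupby(stratum, sort=True):
        try:
            c, comp = optimal_cutoff(sub["time"].to_numpy(),
                                     sub["event"].to_numpy(),
                                     sub[covariate].to_numpy(), minprop)
            out[str(label)] = StratumResult(str(label), True, c, comp)
        except ValueError as exc:
            out[str(label)] = StratumResult(str(label), False, reason=str(exc))
    return out


def load_survival_table(path) -> pd.DataFrame:
    """Read a survival TSV with columns sample_id, time, event, expression
    and optional stratum."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_km_curve(curve: pd.DataFrame, path) -> None:
    curve.to_csv(path, sep="\t", index=False, float_format="%.10g")
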