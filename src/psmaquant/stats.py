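"""Concordance, rank correlation, cohort summaries and survival analysis.

The survival machinery treats death as the event and both "switched to a
different treatment" and "last study visit" as right-censoring. Kaplan-Meier
fitting and the log-rank test are delegated to lifelines; the median
confidence interval is Brookmeyer-Crowley on log S(t) with the Greenwood
variance, computed here because lifelines exposes a different construction.

Spearman correlation uses average ranks (tie-corrected). Two-sided
p-values come from exhaustive permutation of one ranking for n <= 10 and
from the t-approximation for larger n. No multiplicity adjustment is
applied anywhere in the correlation screen: each cell reports its raw p.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .response import PatientRecord, Response

RESPONSE_LEVELS = (Response.PR.value, Response.SD.value, Response.PD.value)

EXACT_PERMUTATION_MAX_N = 10


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceResult:
    n_total: int
    n_agree: int
    fraction: float
    cross_table: pd.DataFrame  # 3x3 PR/SD/PD x PR/SD/PD counts


def concordance(calls_a: Sequence, calls_b: Sequence) -> ConcordanceResult:
    """Elementwise agreement fraction of two response-call lists plus the
    full PR/SD/PD cross-table (rows: method A, columns: method B)."""
    a = [getattr(c, "value", c) for c in calls_a]
    b = [getattr(c, "value", c) for c in calls_b]
    if len(a) != len(b):
        raise ValueError(f"call lists differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("call lists must be non-empty")
    table = pd.DataFrame(0, index=pd.Index(RESPONSE_LEVELS, name="method_a"),
                         columns=pd.Index(RESPONSE_LEVELS, name="method_b"))
    for ra, rb in zip(a, b):
        table.loc[ra, rb] += 1
    n_agree = int(np.trace(table.values))
    return ConcordanceResult(n_total=len(a), n_agree=n_agree,
                             fraction=n_agree / len(a), cross_table=table)


# ---------------------------------------------------------------------------
# Spearman correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float  # nan when undefined (constant input)
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return math.isfinite(self.r)


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    # Pearson on average ranks == tie-corrected Spearman
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    return float(rx @ ry) / denom


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided p by enumerating all n! pairings of the two rankings."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    hits = total = 0
    threshold = abs(r_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(rxc @ ryc[list(perm)]) / denom
        if abs(r) >= threshold:
            hits += 1
        total += 1
    return hits / total


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Tie-corrected (average-rank) Spearman correlation with two-sided p.

    A constant input vector leaves the coefficient undefined; the result
    then carries ``r = p = nan`` rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, p=math.nan, n=n)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = _rank_correlation(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        p = float(sps.spearmanr(x, y).pvalue)  # t-approximation
    return CorrelationResult(r=r, p=min(p, 1.0), n=n)


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Plain Pearson correlation, reported alongside Spearman where the
    coefficient flavour of a literature value is ambiguous."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=math.nan, p=math.nan, n=len(x))
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


def correlation_screen(covariates: Mapping[str, Sequence[float]],
                       deltas: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Rank-correlation screen of baseline covariates against the response deltas.

    Missing values (NaN) are handled pairwise-complete per cell; a cell
    with fewer than 3 complete pairs is reported undefined. Returns a long
    table with columns covariate, delta, r, p, n.
    """
    rows = []
    for cov_name, cov in covariates.items():
        cov = np.asarray(cov, dtype=np.float64)
        for d_name, d in deltas.items():
            d = np.asarray(d, dtype=np.float64)
            if len(cov) != len(d):
                raise ValueError(f"covariate '{cov_name}' and delta '{d_name}' differ in length")
            keep = np.isfinite(cov) & np.isfinite(d)
            if keep.sum() < 3:
                res = CorrelationResult(r=math.nan, p=math.nan, n=int(keep.sum()))
            else:
                res = spearman(cov[keep], d[keep])
            rows.append({"covariate": cov_name, "delta": d_name,
                         "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["covariate", "delta", "r", "p", "n"])


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored follow-up interval in months."""

    time: float
    event: bool  # True = death observed
    group: str = "all"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival estimate.

    ``median`` is the earliest time with S(t) <= 0.5 and None when the
    curve never reaches 0.5 ("not reached"); CI bounds may likewise be
    None when undefined on a side.
    """

    times: np.ndarray  # event/censor time grid, ascending, starts at 0
    survival: np.ndarray  # S(t), right-continuous step values at `times`
    at_risk: np.ndarray
    median: float | None
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return self.median is not None

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.times, "S": self.survival, "n_at_risk": self.at_risk})


def _median_ci_brookmeyer_crowley(times: np.ndarray, survival: np.ndarray,
                                  var_log_s: np.ndarray, z: float = 1.959964) -> tuple[float | None, float | None]:
    """CI for the median: event times t where |log S(t) - log 0.5| <= z * se(log S)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        ok = survival > 0
        stat = np.full_like(survival, np.inf)
        stat[ok] = np.abs(np.log(survival[ok]) - math.log(0.5)) / np.sqrt(np.maximum(var_log_s[ok], 1e-300))
        # S == 0.5 exactly with zero variance is inside the region
        stat[ok & np.isclose(survival, 0.5)] = 0.0
    inside = stat <= z
    if not inside.any():
        return (None, None)
    idx = np.flatnonzero(inside)
    lower = float(times[idx[0]])
    # upper bound undefined when the region extends to the end of follow-up
    upper = float(times[idx[-1] + 1]) if idx[-1] + 1 < len(times) else None
    return (lower, upper)


def km_fit(records: Iterable[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with Brookmeyer-Crowley median CI.

    Without censoring the estimate equals the empirical survival function
    exactly. The median is the earliest time with S(t) <= 0.5, "not
    reached" (None) if the curve stays above 0.5.
    """
    records = list(records)
    if not records:
        raise ValueError("need at least one survival record")
    durations = np.array([r.time for r in records], dtype=np.float64)
    events = np.array([r.event for r in records], dtype=bool)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    times = kmf.survival_function_.index.to_numpy(dtype=np.float64)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=np.float64)
    at_risk = np.array([int((durations >= t).sum()) for t in times])

    # Greenwood variance of log S(t): sum over event times <= t of d/(n(n-d))
    event_times = np.unique(durations[events])
    var_terms = []
    for t in event_times:
        n_t = int((durations >= t).sum())
        d_t = int(((durations == t) & events).sum())
        var_terms.append((t, d_t / (n_t * (n_t - d_t)) if n_t > d_t else np.inf))
    var_log_s = np.zeros_like(times)
    for i, t in enumerate(times):
        var_log_s[i] = sum(v for tt, v in var_terms if tt <= t)

    below = np.flatnonzero(survival <= 0.5)
    median = float(times[below[0]]) if below.size else None
    ci = _median_ci_brookmeyer_crowley(times, survival, var_log_s) if events.any() else (None, None)

    return KMEstimate(times=times, survival=survival, at_risk=at_risk,
                      median=median, median_ci=ci,
                      n=len(records), n_events=int(events.sum()))


@dataclass(frozen=True)
class LogrankResult:
    statistic: float  # chi-square(1), nan when undefined (no events)
    p: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.statistic)


def logrank(group_a: Iterable[SurvivalRecord], group_b: Iterable[SurvivalRecord]) -> LogrankResult:
    """Two-group log-rank test: (O-E)^2/V with hypergeometric variance,
    two-sided p from chi-square(1). Undefined (nan) with zero total events."""
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if not any(r.event for r in a + b):
        return LogrankResult(statistic=math.nan, p=math.nan)
    res = logrank_test(
        np.array([r.time for r in a]), np.array([r.time for r in b]),
        event_observed_A=np.array([r.event for r in a], dtype=int),
        event_observed_B=np.array([r.event for r in b], dtype=int),
    )
    return LogrankResult(statistic=float(res.test_statistic), p=float(res.p_value))


def read_survival_csv(path) -> list[SurvivalRecord]:
    """Survival CSV contract: patient_id, time_months, event (0/1), group."""
    frame = pd.read_csv(path)
    missing = {"time_months", "event", "group"} - set(frame.columns)
    if missing:
        raise ValueError(f"survival CSV is missing columns: {sorted(missing)}")
    return [SurvivalRecord(time=float(r.time_months), event=bool(int(r.event)), group=str(r.group))
            for r in frame.itertuples()]


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

def summarize_cohort(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Median and min-max range of TLP/MTV/PSA, pre and post therapy.

    Standard sample median (mean of the central pair at even n). Returns a
    table with rows (variable, timepoint) and columns median/min/max.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort must contain at least one record")
    rows = []
    for var in ("tlp", "mtv", "psa"):
        for tp in ("pre", "post"):
            values = np.array([getattr(r, f"{var}_{tp}") for r in records], dtype=np.float64)
            rows.append({"variable": var, "timepoint": tp,
                         "median": float(np.median(values)),
                         "min": float(values.min()), "max": float(values.max())})
    return pd.DataFrame(rows, columns=["variable", "timepoint", "median", "min", "max"])
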