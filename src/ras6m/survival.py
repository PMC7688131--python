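"""Survival stratification by expression cutoffs.

Implements the log-rank test with O/E-based hazard ratio, the
log-rank-with-multiple-cutoffs (LRMC) scan that evaluates every
sample-defined expression cutoff and selects the one with the minimal
log-rank p, Kaplan-Meier product-limit estimation, a single
binary-covariate Cox proportional-hazards fit, and the combined
three-gene Good/Bad prognostic classifier.

A scan over all cutoffs and selection of the minimal p inflates type-I
error; the scan result therefore always carries a selection annotation
(no multiplicity correction is applied by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalError",
    "AllCensoredError",
    "LogRankResult",
    "CutoffScan",
    "KaplanMeierEstimate",
    "CoxResult",
    "PrognosticCall",
    "logrank_test",
    "lrmc_scan",
    "km_estimate",
    "cox_hr_binary",
    "classify_prognosis",
    "classify_cohort",
    "read_survival_table",
]


class SurvivalError(ValueError):
    pass


class AllCensoredError(SurvivalError):
    pass


@dataclass(frozen=True)
class LogRankResult:
    """Mantel-Haenszel log-rank (1 df) with O/E hazard ratio (b vs a)."""

    statistic: float
    p_value: float
    hazard_ratio: float
    observed_a: float
    expected_a: float
    observed_b: float
    expected_b: float


@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Product-limit survival curve over the observed event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S(0) = 1.
    ``median`` is the smallest time with S(t) <= 0.5 (None if never
    reached).
    """

    event_times: np.ndarray
    survival: np.ndarray
    n: int
    median: float | None

    def survival_at(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        s = np.concatenate([[1.0], self.survival])
        out = s[idx]
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CoxResult:
    """Univariate Cox fit for a binary group indicator (Breslow ties)."""

    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    beta: float
    se: float
    converged: bool


@dataclass
class CutoffScan:
    """Per-cutoff log-rank results plus the selected (minimal-p) cutoff."""

    table: pd.DataFrame  # cutoff, n_low, n_high, statistic, p, neg_log10_p, hr
    selected_cutoff: float
    selected_p: float
    n_cutoffs_tested: int
    selection_note: str


@dataclass(frozen=True)
class PrognosticCall:
    """Combined three-gene call: Good iff the favorable pattern holds."""

    label: str  # "Good" | "Bad"
    calls: dict[str, str]  # gene -> "High" | "Low"


def _check_arrays(time, event) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise SurvivalError("time and event must be 1-d and equal length")
    if len(t) == 0:
        raise SurvivalError("empty group")
    if np.any(~np.isfinite(t)) or np.any(t <= 0):
        raise SurvivalError("times must be finite and > 0")
    if not np.isin(e, (0.0, 1.0)).all():
        raise SurvivalError("event must be 0 (censored) or 1 (death)")
    return t, e.astype(int)


def _counts_at(times_sorted: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    """Number at risk (time >= t) for each event time."""
    return len(times_sorted) - np.searchsorted(times_sorted, event_times, side="left")


def _deaths_at(death_times_sorted: np.ndarray, event_times: np.ndarray) -> np.ndarray:
    hi = np.searchsorted(death_times_sorted, event_times, side="right")
    lo = np.searchsorted(death_times_sorted, event_times, side="left")
    return hi - lo


def logrank_test(time_a, event_a, time_b, event_b) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test with O/E hazard ratio.

    The statistic is (O_b - E_b)^2 / V with the hypergeometric variance V
    summed over distinct event times; p from chi-square with 1 df.  The
    hazard ratio (O_b/E_b)/(O_a/E_a) is NaN when a group has zero expected
    events (p is still returned).
    """
    ta, ea = _check_arrays(time_a, event_a)
    tb, eb = _check_arrays(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise AllCensoredError("no events in either group")

    sa, sb = np.sort(ta), np.sort(tb)
    da, db = np.sort(ta[ea == 1]), np.sort(tb[eb == 1])
    event_times = np.unique(np.concatenate([da, db]))

    n_a = _counts_at(sa, event_times).astype(float)
    n_b = _counts_at(sb, event_times).astype(float)
    d_a = _deaths_at(da, event_times).astype(float)
    d_b = _deaths_at(db, event_times).astype(float)
    n = n_a + n_b
    d = d_a + d_b

    e_b = d * n_b / n
    e_a = d * n_a / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * (n - d) / (n - 1) * n_a * n_b / n**2
    v = np.where(n > 1, v, 0.0)

    O_a, O_b = float(d_a.sum()), float(d_b.sum())
    E_a, E_b = float(e_a.sum()), float(e_b.sum())
    V = float(v.sum())
    if V > 0:
        statistic = (O_b - E_b) ** 2 / V
        p = float(stats.chi2.sf(statistic, df=1))
    else:
        statistic, p = 0.0, 1.0

    if E_a > 0 and E_b > 0:
        rate_a, rate_b = O_a / E_a, O_b / E_b
        if rate_a > 0:
            hr = rate_b / rate_a
        elif rate_b > 0:
            hr = math.inf
        else:
            hr = 1.0
    else:
        hr = math.nan
    return LogRankResult(
        statistic=float(statistic),
        p_value=p,
        hazard_ratio=float(hr),
        observed_a=O_a,
        expected_a=E_a,
        observed_b=O_b,
        expected_b=E_b,
    )


def lrmc_scan(
    time,
    event,
    expression,
    min_group_size: int = 3,
) -> CutoffScan:
    """Scan every sample-defined expression cutoff for survival separation.

    Each distinct expression value is a candidate cutoff splitting the
    cohort into Low (expression strictly below the cutoff) and High (at or
    above it); a cutoff is admissible when both sides have at least
    ``min_group_size`` patients (use 1 for the literal "all cutoffs"
    reading).  For each admissible cutoff the log-rank p and the High-vs-Low
    hazard ratio are recorded; the selected cutoff attains the minimal p,
    ties going to the cutoff nearest the median expression.
    """
    t, e = _check_arrays(time, event)
    expr = np.asarray(expression, dtype=float)
    if expr.shape != t.shape:
        raise SurvivalError("expression must align with time/event")
    if e.sum() == 0:
        raise AllCensoredError("all patients censored; log-rank undefined")
    if min_group_size < 1:
        raise SurvivalError("min_group_size must be >= 1")

    rows = []
    for cutoff in np.unique(expr):
        high = expr >= cutoff
        n_low, n_high = int((~high).sum()), int(high.sum())
        if n_low < min_group_size or n_high < min_group_size:
            continue
        res = logrank_test(t[~high], e[~high], t[high], e[high])
        rows.append(
            {
                "cutoff": float(cutoff),
                "n_low": n_low,
                "n_high": n_high,
                "statistic": res.statistic,
                "p": res.p_value,
                "neg_log10_p": -math.log10(res.p_value) if res.p_value > 0 else math.inf,
                "hr": res.hazard_ratio,
            }
        )
    if not rows:
        raise SurvivalError(
            f"no admissible cutoff with min_group_size={min_group_size}"
        )
    table = pd.DataFrame(rows)
    p_min = table["p"].min()
    tied = table[table["p"] == p_min]
    med = float(np.median(expr))
    sel = tied.iloc[int(np.argmin(np.abs(tied["cutoff"].to_numpy() - med)))]
    return CutoffScan(
        table=table,
        selected_cutoff=float(sel["cutoff"]),
        selected_p=float(sel["p"]),
        n_cutoffs_tested=len(table),
        selection_note=(
            f"selected by minimum p over {len(table)} cutoffs; "
            "no multiplicity correction applied"
        ),
    )


def km_estimate(time, event) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate of the survival function."""
    t, e = _check_arrays(time, event)
    ts = np.sort(t)
    deaths = np.sort(t[e == 1])
    event_times = np.unique(deaths)
    if event_times.size == 0:
        return KaplanMeierEstimate(
            event_times=np.empty(0), survival=np.empty(0), n=len(t), median=None
        )
    n_risk = _counts_at(ts, event_times).astype(float)
    d = _deaths_at(deaths, event_times).astype(float)
    surv = np.cumprod(1.0 - d / n_risk)
    below = surv <= 0.5
    median = float(event_times[np.argmax(below)]) if below.any() else None
    return KaplanMeierEstimate(
        event_times=event_times, survival=surv, n=len(t), median=median
    )


_MAX_ABS_BETA = 15.0


def cox_hr_binary(time, event, group) -> CoxResult:
    """Univariate Cox PH fit for a binary group indicator.

    Maximizes the Breslow partial likelihood by Newton iteration on the
    single log-hazard-ratio coefficient.  Both groups must contain at
    least one event.  A monotone likelihood (one group's events all
    precede the other's risk) is flagged via ``converged=False``.
    """
    t, e = _check_arrays(time, event)
    g = np.asarray(group)
    if g.shape != t.shape:
        raise SurvivalError("group indicator must align with time/event")
    g = g.astype(bool)
    if e[g].sum() == 0 or e[~g].sum() == 0:
        raise SurvivalError("both groups need at least one event")

    deaths = np.sort(t[e == 1])
    event_times = np.unique(deaths)
    s0, s1 = np.sort(t[~g]), np.sort(t[g])
    d0s, d1s = np.sort(t[(e == 1) & ~g]), np.sort(t[(e == 1) & g])
    n0 = _counts_at(s0, event_times).astype(float)
    n1 = _counts_at(s1, event_times).astype(float)
    d1 = _deaths_at(d1s, event_times).astype(float)
    d = _deaths_at(deaths, event_times).astype(float)
    s1_total = float(d1.sum())

    beta = 0.0
    converged = False
    for _ in range(100):
        eb = math.exp(beta)
        denom = n0 + n1 * eb
        mu = d * n1 * eb / denom
        score = s1_total - float(mu.sum())
        info = float((d * n0 * n1 * eb / denom**2).sum())
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(beta) > _MAX_ABS_BETA:  # monotone likelihood
            beta = math.copysign(_MAX_ABS_BETA, beta)
            break
        if abs(step) < 1e-12:
            converged = True
            break
    eb = math.exp(beta)
    denom = n0 + n1 * eb
    info = float((d * n0 * n1 * eb / denom**2).sum())
    se = math.sqrt(1.0 / info) if info > 0 else math.inf
    z = beta / se if se > 0 and math.isfinite(se) else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    zcrit = stats.norm.ppf(0.975)

    def safe_exp(x: float) -> float:
        return math.exp(x) if x < 700 else math.inf

    return CoxResult(
        hazard_ratio=safe_exp(beta),
        ci_lower=safe_exp(beta - zcrit * se) if math.isfinite(se) else 0.0,
        ci_upper=safe_exp(beta + zcrit * se) if math.isfinite(se) else math.inf,
        p_value=p,
        beta=beta,
        se=se,
        converged=converged,
    )


def classify_prognosis(
    expression: Mapping[str, float],
    cutoffs: Mapping[str, float],
    good_high: Sequence[str] = ("IGF2R", "CTSA"),
    good_low: Sequence[str] = ("ATP6AP2",),
) -> PrognosticCall:
    """Combined multi-gene Good/Bad call from per-gene expression cutoffs.

    Each gene is called High when expression is at or above its cutoff and
    Low when strictly below (ties land in High).  The patient is "Good"
    when every ``good_high`` gene is High and every ``good_low`` gene is
    Low; anything else is "Bad".  Defaults encode the favorable AML
    pattern: IGF2R High, CTSA High, ATP6AP2 Low.
    """
    calls: dict[str, str] = {}
    for gene in tuple(good_high) + tuple(good_low):
        if gene not in expression:
            raise SurvivalError(f"missing expression for gene {gene!r}")
        if gene not in cutoffs:
            raise SurvivalError(f"missing cutoff for gene {gene!r}")
        calls[gene] = "High" if expression[gene] >= cutoffs[gene] else "Low"
    good = all(calls[gn] == "High" for gn in good_high) and all(
        calls[gn] == "Low" for gn in good_low
    )
    return PrognosticCall(label="Good" if good else "Bad", calls=calls)


def classify_cohort(
    expression: pd.DataFrame,
    cutoffs: Mapping[str, float],
    good_high: Sequence[str] = ("IGF2R", "CTSA"),
    good_low: Sequence[str] = ("ATP6AP2",),
) -> pd.Series:
    """Vector version of :func:`classify_prognosis` (genes x samples)."""
    labels = {}
    for sample in expression.columns:
        call = classify_prognosis(
            expression[sample].to_dict(), cutoffs, good_high, good_low
        )
        labels[sample] = call.label
    return pd.Series(labels, name="prognosis")


def read_survival_table(path) -> pd.DataFrame:
    """Read a survival TSV with columns sample_id, time_days, event."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time_days", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SurvivalError(f"survival table missing columns: {sorted(missing)}")
    _check_arrays(df["time_days"], df["event"])
    return df
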