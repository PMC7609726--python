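"""Validation-phase statistics for qPCR-measured candidates.

Efficiency-corrected relative quantification (the Pfaffl ratio),
overall-survival bin comparisons by Mann-Whitney U (exact by
enumeration for small samples) with a Kruskal-Wallis omnibus,
expression dichotomization, the Kaplan-Meier product-limit estimator
and the two-group log-rank test with an O/E hazard ratio.

The hazard ratio here is the classic log-rank estimate
HR = (O1/E1)/(O2/E2) with CI exp(log HR +/- 1.96 sqrt(1/E1 + 1/E2)) —
a risk-set summary, not a fitted proportional-hazards model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, NumericalError
from .io import QpcrTable, SurvivalData

__all__ = [
    "pfaffl_ratio",
    "relative_expression",
    "mann_whitney",
    "split_by_os",
    "compare_os_groups",
    "dichotomize",
    "KmCurve",
    "kaplan_meier",
    "LogRankResult",
    "log_rank",
]


def pfaffl_ratio(
    e_target: float,
    dcq_target: float,
    e_reference: float = 2.0,
    dcq_reference: float = 0.0,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_target ** dCq_target / E_reference ** dCq_reference, with
    dCq = Cq(calibrator) - Cq(sample).  With both efficiencies at 2
    (perfect doubling) this is exactly the classic 2^-ddCq form.
    """
    for e in (e_target, e_reference):
        if not (1.0 <= e <= 2.0):
            raise InputError(f"efficiency must lie in [1, 2], got {e}")
    return float(e_target ** dcq_target / e_reference ** dcq_reference)


def relative_expression(
    table: QpcrTable, calibrator: str | None = None
) -> pd.Series:
    """Per-sample Pfaffl ratios from a replicate-level Cq table.

    Replicates are averaged (arithmetic mean) first.  ``calibrator``
    names the reference sample; by default the sample-mean Cq serves as
    calibrator, which rescales every ratio by a common factor and
    leaves between-sample comparisons untouched.
    """
    avg = table.averaged()
    if calibrator is not None:
        row = avg[avg["sample_id"] == calibrator]
        if row.empty:
            raise InputError(f"calibrator sample {calibrator!r} not found")
        cal_t = float(row["target_cq"].iloc[0])
        cal_r = float(row["reference_cq"].iloc[0])
    else:
        cal_t = float(avg["target_cq"].mean())
        cal_r = float(avg["reference_cq"].mean())
    out = {}
    for _, row in avg.iterrows():
        out[row["sample_id"]] = pfaffl_ratio(
            row["target_efficiency"],
            cal_t - row["target_cq"],
            row["reference_efficiency"],
            cal_r - row["reference_cq"],
        )
    return pd.Series(out, name="relative_expression")


def _rank_with_ties(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled)


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    ``exact`` enumerates all C(n_a + n_b, n_a) assignments of the
    pooled (tie-averaged) ranks, so it remains valid under ties;
    ``asymptotic`` uses the normal approximation with tie and
    continuity corrections.  ``auto`` picks exact when the pooled size
    is at most 12.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return n_a * n_b / 2.0, 1.0
    ranks = _rank_with_ties(pooled)
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    if mode not in ("exact", "asymptotic", "auto"):
        raise InputError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if n_a + n_b <= 12 else "asymptotic"
    if mode == "exact":
        mu = n_a * n_b / 2.0
        dev_obs = abs(u_obs - mu)
        total = math.comb(n_a + n_b, n_a)
        extreme = 0
        csum = ranks.sum()
        for idx in combinations(range(n_a + n_b), n_a):
            u = float(ranks[list(idx)].sum() - n_a * (n_a + 1) / 2.0)
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    # asymptotic with tie correction and continuity correction
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u_obs, 1.0
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return u_obs, float(2.0 * stats.norm.sf(z))


def split_by_os(
    surv: SurvivalData, bins: tuple[float, float] = (12.0, 24.0)
) -> dict[str, pd.DataFrame]:
    """Split patients into OS bins: [0, 12), [12, 24], (24, inf).

    The middle bin is closed on both ends (ties at the boundaries fall
    inside it); an empty bin draws a warning so downstream comparisons
    can skip pairs involving it.
    """
    lo, hi = bins
    t = surv.time
    masks = {
        f"OS<{lo:g}": t < lo,
        f"OS{lo:g}-{hi:g}": (t >= lo) & (t <= hi),
        f"OS>{hi:g}": t > hi,
    }
    out = {}
    for name, mask in masks.items():
        out[name] = surv.data[mask].reset_index(drop=True)
        if not mask.any():
            warnings.warn(f"empty OS group {name}")
    return out


def compare_os_groups(
    values: pd.Series, surv: SurvivalData, bins=(12.0, 24.0)
) -> pd.DataFrame:
    """Pairwise Mann-Whitney tests of expression between OS bins, plus a
    Kruskal-Wallis omnibus row and fold changes between group means."""
    groups = split_by_os(surv, bins)
    per_group = {
        name: values.reindex(df["sample_id"]).dropna().to_numpy()
        for name, df in groups.items()
    }
    rows = []
    names = list(per_group)
    for ga, gb in combinations(names, 2):
        va, vb = per_group[ga], per_group[gb]
        if va.size == 0 or vb.size == 0:
            continue
        u, p = mann_whitney(va, vb)
        fold = float(vb.mean() / va.mean()) if va.mean() != 0 else float("nan")
        rows.append({"test": "mann-whitney", "group_a": ga, "group_b": gb,
                     "statistic": u, "p": p, "fold_change_b_vs_a": fold})
    nonempty = [v for v in per_group.values() if v.size > 0]
    if len(nonempty) >= 2:
        h, p = stats.kruskal(*nonempty)
        rows.append({"test": "kruskal-wallis", "group_a": "all",
                     "group_b": "all", "statistic": float(h), "p": float(p),
                     "fold_change_b_vs_a": float("nan")})
    return pd.DataFrame(rows)


def dichotomize(values) -> tuple[np.ndarray, np.ndarray, float]:
    """Split expression into high/low by the mean of the provisional low half.

    The overall median defines a provisional low half; the cut-off is
    that half's mean; the final split is high = value > cut-off,
    low = value <= cut-off.  Returns (high mask, low mask, cut-off).
    This makes the published "mean of the low expression group" rule —
    circular as printed — well defined.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise InputError("dichotomize needs at least 4 patients")
    if np.all(v == v[0]):
        raise NumericalError("all expression values identical")
    provisional_low = v[v <= np.median(v)]
    cutoff = float(provisional_low.mean())
    high = v > cutoff
    return high, ~high, cutoff


@dataclass
class KmCurve:
    """Product-limit estimate: event-time grid with at-risk/event counts."""

    table: pd.DataFrame  # time, at_risk, events, censored, survival

    def survival_at(self, t: float) -> float:
        mask = self.table["time"] <= t
        if not mask.any():
            return 1.0
        return float(self.table.loc[mask, "survival"].iloc[-1])

    def step_function(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.table["time"].to_numpy(dtype=float),
            self.table["survival"].to_numpy(dtype=float),
        )


def kaplan_meier(time, event) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Events precede censorings at tied times (the censored patient is
    still at risk for the tied event).  The returned table has one row
    per distinct observed time with the at-risk count, events,
    censorings and the running survival estimate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise InputError("no records")
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n_at_risk = time.size
    for t in np.unique(time):
        here = time == t
        d = int(event[here].sum())
        c = int((~event[here]).sum())
        if d > 0:
            s *= 1.0 - d / n_at_risk
        rows.append({"time": float(t), "at_risk": n_at_risk, "events": d,
                     "censored": c, "survival": s})
        n_at_risk -= d + c
    return KmCurve(pd.DataFrame(rows))


@dataclass
class LogRankResult:
    chi_square: float
    p: float
    hazard_ratio: float | None  # None when an expected count is zero
    ci95: tuple[float, float] | None
    observed: tuple[float, float]
    expected: tuple[float, float]


def log_rank(time1, event1, time2, event2) -> LogRankResult:
    """Two-group log-rank test with the O/E hazard ratio.

    Walks the pooled risk sets: at each event time, O and E accumulate
    per group; chi-square = (O1 - E1)^2 / V with the hypergeometric
    variance; HR = (O1/E1)/(O2/E2) and
    CI = exp(log HR +/- 1.96 sqrt(1/E1 + 1/E2)).
    """
    t1 = np.asarray(time1, dtype=float)
    e1 = np.asarray(event1, dtype=bool)
    t2 = np.asarray(time2, dtype=float)
    e2 = np.asarray(event2, dtype=bool)
    if e1.sum() + e2.sum() == 0:
        raise NumericalError("no events in either group")
    event_times = np.unique(np.concatenate([t1[e1], t2[e2]]))
    o1 = e1.sum()
    o2 = e2.sum()
    exp1 = exp2 = 0.0
    var = 0.0
    for t in event_times:
        n1 = int((t1 >= t).sum())
        n2 = int((t2 >= t).sum())
        d1 = int(((t1 == t) & e1).sum())
        d2 = int(((t2 == t) & e2).sum())
        n = n1 + n2
        d = d1 + d2
        if n == 0:
            continue
        exp1 += d * n1 / n
        exp2 += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0:
        raise NumericalError("log-rank variance is zero")
    chi2 = float((o1 - exp1) ** 2 / var)
    p = float(stats.chi2.sf(chi2, df=1))
    if exp1 <= 0 or exp2 <= 0 or o1 == 0 or o2 == 0:
        warnings.warn("zero observed or expected events; hazard ratio undefined")
        hr, ci = None, None
    else:
        hr = float((o1 / exp1) / (o2 / exp2))
        se = np.sqrt(1.0 / exp1 + 1.0 / exp2)
        ci = (float(hr * np.exp(-1.96 * se)), float(hr * np.exp(1.96 * se)))
    return LogRankResult(chi2, p, hr, ci, (float(o1), float(o2)),
                         (float(exp1), float(exp2)))
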