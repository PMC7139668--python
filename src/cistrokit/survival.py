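"""Expression-stratified survival: median split, Kaplan-Meier, logrank.

Cohorts are plain tables with follow-up time (months), an event indicator
(1 = relapse/death, 0 = censored) and an expression z-score used to split
patients into high/low groups.  The split is at the median with ties
assigned to "low" (the cutoff quantile is configurable).  Survival curves
use the product-limit estimator and groups are compared with the logrank
(Mantel-Cox) test: the observed-minus-expected statistic summed over
distinct event times, referred to a chi-square with 1 df.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

COHORT_COLUMNS = ("patient", "time", "event", "expression_z")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival curve evaluated at event times (plus t=0)."""

    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray

    def __post_init__(self) -> None:
        s = self.survival
        if s.size and (s[0] > 1 + 1e-12 or np.any(np.diff(s) > 1e-12)):
            raise ValueError("survival must start at <=1 and be non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "at_risk": self.at_risk, "survival": self.survival}
        )


def median_split(values: Sequence[float], quantile: float = 0.5) -> np.ndarray:
    """Label each value "high" (> cutoff) or "low" (<= cutoff).

    The cutoff is the given quantile (default median); values equal to the
    cutoff go to "low".  All-identical values cannot be split.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("median_split needs >=2 records")
    if np.all(v == v[0]):
        raise ValueError("degenerate split: all values identical")
    cutoff = np.quantile(v, quantile)
    return np.where(v > cutoff, "high", "low")


def km_curve(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only times do not drop the curve; the returned grid is t=0
    followed by the distinct event times.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("km_curve needs >=1 record")
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise ValueError("events must be 0/1")
    event_times = np.unique(t[e == 1])
    grid = [0.0]
    at_risk = [t.size]
    surv = [1.0]
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & (e == 1)))
        s *= 1.0 - d / n_risk
        grid.append(float(et))
        at_risk.append(n_risk)
        surv.append(s)
    return KMCurve(np.array(grid), np.array(at_risk), np.array(surv))


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Logrank (Mantel-Cox) test between two groups: (chi2, p), 1 df.

    Sums observed minus expected events in group A over distinct event
    times with the hypergeometric variance.  Symmetric in group labels.
    """
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=int)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("logrank test requires >=1 event")
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        n1 = int(np.sum(ta >= et))
        n2 = int(np.sum(tb >= et))
        d1 = int(np.sum((ta == et) & (ea == 1)))
        d2 = int(np.sum((tb == et) & (eb == 1)))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or n1 == 0 or n2 == 0:
            continue
        o_minus_e += d1 - d * n1 / n
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort TSV with patient/time/event/expression_z columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if (df["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not set(df["event"].unique()) <= {0, 1}:
        raise ValueError("event indicator must be 0/1")
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def cohort_logrank(cohort: pd.DataFrame, quantile: float = 0.5) -> dict:
    """Median-split a cohort on expression_z and compare survival.

    Returns the group sizes, KM curves and the logrank chi2/p.
    """
    labels = median_split(cohort["expression_z"].to_numpy(), quantile=quantile)
    high = cohort[labels == "high"]
    low = cohort[labels == "low"]
    chi2, p = logrank_test(
        high["time"], high["event"], low["time"], low["event"]
    )
    return {
        "n_high": len(high),
        "n_low": len(low),
        "km_high": km_curve(high["time"], high["event"]),
        "km_low": km_curve(low["time"], low["event"]),
        "chi2": chi2,
        "p": p,
    }
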