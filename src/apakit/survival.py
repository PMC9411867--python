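"""APA-index survival analysis: median split, Kaplan-Meier, log-rank.

For one gene, samples are split at the median of its usage index (ties at
the median go to the low group), survival in the two groups is estimated
with the Kaplan-Meier product-limit estimator, and the groups are compared
with the two-group log-rank test. The hazard ratio is the O/E (Pike)
estimate (O_high/E_high)/(O_low/E_low) from the log-rank table — no
regression model is fitted, since no covariates enter the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .model import APAError, ClinicalTable, GroupAssignment


@dataclass
class KMEstimate:
    """Product-limit survival curve plus the median survival time."""

    curve: pd.DataFrame  # columns: time, survival
    median: float  # NaN when the curve never reaches 0.5
    n: int
    events: int

    def survival_at(self, t: float) -> float:
        below = self.curve[self.curve["time"] <= t]
        return float(below["survival"].iloc[-1]) if not below.empty else 1.0


@dataclass
class SurvivalResult:
    """Two-group log-rank comparison with O/E hazard ratio."""

    feature_id: str
    n_low: int
    n_high: int
    events_low: int
    events_high: int
    median_low: float
    median_high: float
    chi_square: float
    p: float
    hr: float  # hazard of the high group relative to the low group
    hr_unstable: bool = False
    dropped_samples: list[str] = field(default_factory=list)
    curves: dict[str, KMEstimate] | None = field(default=None, repr=False)


def median_split(row: pd.Series) -> GroupAssignment:
    """Split samples at the median usage: value <= median -> low, else high."""
    clean = row.dropna()
    if clean.size < 4:
        raise APAError(f"median split needs >= 4 non-missing values, got {clean.size}")
    med = float(np.median(clean.to_numpy(dtype=float)))
    if np.ptp(clean.to_numpy(dtype=float)) == 0:
        raise APAError("constant usage values: median split undefined")
    mapping = {s: ("low" if v <= med else "high") for s, v in clean.items()}
    if not any(g == "high" for g in mapping.values()):
        raise APAError("median split produced an empty high group")
    return GroupAssignment(mapping=mapping, order=("high", "low"))


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with median survival time.

    Censored samples (event = 0) reduce the risk set without contributing
    a step. The median is the earliest time with S(t) <= 0.5; it is NaN
    when the curve never drops that far (heavy censoring).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.size == 0:
        raise APAError("empty survival input")
    if np.any(t < 0):
        raise APAError("survival times must be >= 0")
    if not np.all(np.isin(e, (0.0, 1.0))):
        raise APAError("event indicators must be 0 or 1")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    curve = pd.DataFrame({"time": sf.index.to_numpy(dtype=float),
                          "survival": sf.iloc[:, 0].to_numpy(dtype=float)})
    median = float(kmf.median_survival_time_)
    if np.isinf(median):
        median = float("nan")
    return KMEstimate(curve=curve, median=median, n=int(t.size),
                      events=int(e.sum()))


def _logrank_table(t_low, e_low, t_high, e_high):
    """Pooled risk-set tabulation for the two-group log-rank test.

    Returns observed/expected events for the high group, the hypergeometric
    variance sum, and per-group observed/expected totals.
    """
    t = np.concatenate([t_low, t_high])
    e = np.concatenate([e_low, e_high])
    grp = np.concatenate([np.zeros(len(t_low)), np.ones(len(t_high))])
    o_high = e_high_sum = v_sum = 0.0
    o_low = e_low_sum = 0.0
    for tj in np.unique(t[e == 1]):
        at_risk = t >= tj
        n_j = at_risk.sum()
        n_hj = (at_risk & (grp == 1)).sum()
        n_lj = n_j - n_hj
        died = (t == tj) & (e == 1)
        d_j = died.sum()
        d_hj = (died & (grp == 1)).sum()
        o_high += d_hj
        o_low += d_j - d_hj
        e_hj = d_j * n_hj / n_j
        e_high_sum += e_hj
        e_low_sum += d_j - e_hj
        if n_j > 1:
            v_sum += d_j * (n_hj / n_j) * (n_lj / n_j) * (n_j - d_j) / (n_j - 1)
    return o_high, e_high_sum, o_low, e_low_sum, v_sum


def logrank(times_low, events_low, times_high, events_high,
            feature_id: str = "feature") -> SurvivalResult:
    """Two-group log-rank test with the O/E hazard-ratio estimate.

    The chi-square statistic is (O_high - E_high)^2 / V with 1 degree of
    freedom; it is invariant under swapping the group labels. The hazard
    ratio (high vs low) is (O_high/E_high)/(O_low/E_low) and is flagged
    unstable when either group has zero observed events.
    """
    t_low = np.asarray(times_low, dtype=float)
    e_low = np.asarray(events_low, dtype=float)
    t_high = np.asarray(times_high, dtype=float)
    e_high = np.asarray(events_high, dtype=float)
    if t_low.size == 0 or t_high.size == 0:
        raise APAError("both groups need >= 1 sample")
    o_h, exp_h, o_l, exp_l, v = _logrank_table(t_low, e_low, t_high, e_high)
    if v > 0:
        chi2 = (o_h - exp_h) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    unstable = o_h == 0 or o_l == 0
    if o_h > 0 and o_l > 0 and exp_h > 0 and exp_l > 0:
        hr = (o_h / exp_h) / (o_l / exp_l)
    else:
        hr = float("nan")
    km_low = km_estimate(t_low, e_low)
    km_high = km_estimate(t_high, e_high)
    return SurvivalResult(
        feature_id=feature_id,
        n_low=int(t_low.size), n_high=int(t_high.size),
        events_low=int(e_low.sum()), events_high=int(e_high.sum()),
        median_low=km_low.median, median_high=km_high.median,
        chi_square=float(chi2), p=p, hr=float(hr), hr_unstable=bool(unstable),
        curves={"low": km_low, "high": km_high},
    )


def survival_by_apa(row: pd.Series, clinical: ClinicalTable,
                    feature_id: str | None = None) -> SurvivalResult:
    """Median-split a usage row and log-rank compare the two groups.

    Only samples with both a usage value and survival data enter; the
    result records which samples were dropped for missingness.
    """
    usable = row.dropna().index.intersection(clinical.table.index)
    times = clinical.times.loc[usable]
    events = clinical.events.loc[usable]
    keep = usable[~times.isna()]
    dropped = sorted(set(row.index) - set(keep))
    if len(keep) < 4:
        raise APAError(
            f"usage and clinical tables share {len(keep)} usable samples; need >= 4"
        )
    groups = median_split(row.loc[keep])
    low = groups.samples("low")
    high = groups.samples("high")
    res = logrank(times.loc[low], events.loc[low],
                  times.loc[high], events.loc[high],
                  feature_id=feature_id or str(row.name or "feature"))
    res.dropped_samples = dropped
    return res


def survival_table(results: list[SurvivalResult]) -> pd.DataFrame:
    """Flatten survival results into the exportable TSV layout."""
    return pd.DataFrame([
        {"feature_id": r.feature_id, "n_low": r.n_low, "n_high": r.n_high,
         "events_low": r.events_low, "events_high": r.events_high,
         "median_low": r.median_low, "median_high": r.median_high,
         "chi_square": r.chi_square, "p": r.p, "hr": r.hr}
        for r in results
    ])


def km_points_table(result: SurvivalResult) -> pd.DataFrame:
    """KM curve points (time, survival, group) for external plotting."""
    frames = []
    for label, km in (result.curves or {}).items():
        f = km.curve.copy()
        f["group"] = label
        frames.append(f)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["time", "survival", "group"])
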