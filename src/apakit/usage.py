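"""Usage indices and differential 3'UTR usage statistics.

PAU (polyA site usage) is the fraction of a gene's expression carried by
one APA isoform; PDUI is the fraction of transcripts using the distal
site. Both live in [0, 1] with the higher-is-longer polarity, so the
group mean difference (``delta``) reads directly as 3'UTR lengthening
(positive) or shortening (negative).

Group comparisons are nonparametric: Mann-Whitney U for two groups
(exact enumeration when both groups have <= 8 observations and no ties,
normal approximation with tie correction otherwise) and Kruskal-Wallis
for more. p-values are Benjamini-Hochberg adjusted across an analysis
run; the raw p is always reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import APAError, GroupAssignment, UsageMatrix

EXACT_MAX_N = 8  # exact Mann-Whitney enumeration bound per group


def compute_pau(tpm: np.ndarray | list[float]) -> np.ndarray:
    """PAU of each isoform of one gene in one sample: TPM_i / sum_j TPM_j.

    A zero-expression gene yields all-missing PAU (no usage evidence is
    not zero usage); otherwise the non-missing PAUs sum to 1.
    """
    arr = np.asarray(tpm, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise APAError("negative TPM values are not allowed")
    total = np.nansum(arr)
    if total <= 0 or np.all(np.isnan(arr)):
        return np.full(arr.shape, np.nan)
    return arr / total


def _group_values(row: pd.Series, groups: GroupAssignment) -> dict[str, np.ndarray]:
    out = {}
    for label in groups.labels:
        ids = [s for s in groups.samples(label) if s in row.index]
        vals = row.loc[ids].to_numpy(dtype=float)
        out[label] = vals[~np.isnan(vals)]
    return out


def delta_usage(row: pd.Series, groups: GroupAssignment) -> float:
    """Mean usage difference mean(first group) - mean(second group).

    Group order is the assignment's declared order; swapping it flips the
    sign. Missing values are dropped per group.
    """
    if len(groups.labels) != 2:
        raise APAError("delta_usage requires exactly 2 groups")
    vals = _group_values(row, groups)
    g1, g2 = (vals[l] for l in groups.labels)
    if g1.size == 0 or g2.size == 0:
        raise APAError("each group needs >= 1 non-missing value")
    return float(np.mean(g1) - np.mean(g2))


def test_diff(row: pd.Series, groups: GroupAssignment) -> tuple[float, float]:
    """Two-sided nonparametric group comparison of one usage row.

    Returns ``(statistic, p)``: Mann-Whitney U for 2 groups, Kruskal-Wallis
    H for more. Requires >= 2 non-missing values per group.
    """
    vals = _group_values(row, groups)
    arrays = [vals[l] for l in groups.labels]
    if any(a.size < 2 for a in arrays):
        raise APAError("each group needs >= 2 non-missing values for testing")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        # every observation identical: no evidence of any difference
        if len(arrays) == 2:
            return float(arrays[0].size * arrays[1].size / 2), 1.0
        return 0.0, 1.0
    if len(arrays) == 2:
        a, b = arrays
        no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
        method = "exact" if (no_ties and a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def adjust_bh(pvalues: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise APAError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_trend(delta: float, q: float, min_delta: float = 0.1,
                   alpha: float = 0.05) -> str:
    """Call a 3'UTR trend from effect size and adjusted significance.

    ``lengthened`` if delta >= min_delta and q < alpha; ``shortened`` if
    delta <= -min_delta and q < alpha; ``unchanged`` otherwise. Assumes
    higher-is-longer usage polarity.
    """
    if q < alpha and delta >= min_delta:
        return "lengthened"
    if q < alpha and delta <= -min_delta:
        return "shortened"
    return "unchanged"


def top_bottom_split(row: pd.Series, n: int = 30) -> GroupAssignment:
    """Split samples into the ``n`` highest-usage vs ``n`` lowest-usage.

    Boundary ties are broken by lexicographic sample-id order so the split
    is deterministic across runs.
    """
    clean = row.dropna()
    if clean.size < 2 * n:
        raise APAError(
            f"top/bottom split needs >= {2 * n} non-missing samples, got {clean.size}"
        )
    ordered = sorted(clean.items(), key=lambda kv: (kv[1], kv[0]))
    low = [s for s, _ in ordered[:n]]
    high = [s for s, _ in ordered[-n:]]
    mapping = {s: "low" for s in low}
    mapping.update({s: "high" for s in high})
    return GroupAssignment(mapping=mapping, order=("high", "low"))


@dataclass
class DiffResult:
    """Per-feature differential usage result (one row of the result table)."""

    feature_id: str
    group1: str
    group2: str
    mean1: float
    mean2: float
    delta: float
    statistic: float
    p: float
    q: float
    trend: str
    n1: int
    n2: int


def differential_usage(usage: UsageMatrix, groups: GroupAssignment,
                       min_delta: float = 0.1, alpha: float = 0.05,
                       gene_symbols: dict[str, str] | None = None) -> pd.DataFrame:
    """Differential usage over all features of a matrix, with trend calls.

    Features whose groups lack enough non-missing values are skipped and
    listed in the table attribute ``skipped``. For > 2 groups only the
    omnibus Kruskal-Wallis statistic is reported (delta and trend are NA).

    Returns a table with columns: feature_id, gene_symbol, mean_<g1>,
    mean_<g2>, delta, statistic, p, q, trend, n1, n2.
    """
    two_groups = len(groups.labels) == 2
    rows = []
    skipped: list[tuple[str, str]] = []
    for fid in usage.feature_ids:
        row = usage.values.loc[fid]
        vals = _group_values(row, groups)
        sizes = [vals[l].size for l in groups.labels]
        if any(sz < 2 for sz in sizes):
            skipped.append((fid, f"group sizes {sizes} below 2 usable values"))
            continue
        stat, p = test_diff(row, groups)
        rec = {"feature_id": fid,
               "gene_symbol": (gene_symbols or {}).get(fid, fid)}
        if two_groups:
            g1, g2 = groups.labels
            rec[f"mean_{g1}"] = float(np.mean(vals[g1]))
            rec[f"mean_{g2}"] = float(np.mean(vals[g2]))
            rec["delta"] = rec[f"mean_{g1}"] - rec[f"mean_{g2}"]
        else:
            rec["delta"] = np.nan
        rec.update(statistic=stat, p=p, n1=sizes[0],
                   n2=sizes[1] if len(sizes) > 1 else np.nan)
        rows.append(rec)
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = adjust_bh(table["p"].to_numpy())
        if two_groups:
            table["trend"] = [
                classify_trend(d, q, min_delta=min_delta, alpha=alpha)
                for d, q in zip(table["delta"], table["q"])
            ]
        else:
            table["trend"] = "NA"
        lead = ["feature_id", "gene_symbol"]
        means = [c for c in table.columns if c.startswith("mean_")]
        table = table[lead + means + ["delta", "statistic", "p", "q", "trend", "n1", "n2"]]
    table.attrs["skipped"] = skipped
    return table
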