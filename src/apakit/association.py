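"""Usage-expression and expression-expression correlation with OLS band.

The linear association between an APA usage index (PAU/PDUI) and gene
expression is summarised by a Pearson correlation (Spearman optional), an
ordinary least-squares fit, and the 95% confidence band for the mean
response, computed from the t distribution with n - 2 degrees of freedom.
A screen over a whole dataset keeps features passing |r| > r_min and
p < alpha, the usual gate for calling usage-coupled genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .model import APAError, ExpressionMatrix, GroupAssignment, UsageMatrix


@dataclass
class CorrResult:
    """Correlation between two variables plus the OLS mean-response band."""

    feature_x: str
    feature_y: str
    n: int
    r: float
    p: float
    slope: float
    intercept: float
    band: pd.DataFrame = field(repr=False)  # columns: x, fit, lower, upper
    method: str = "pearson"
    group: str = "all"


def _complete_pairs(x: pd.Series | np.ndarray, y: pd.Series | np.ndarray):
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape:
        raise APAError(f"length mismatch: {xv.size} vs {yv.size}")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    return xv[keep], yv[keep]


def correlate(x, y, method: str = "pearson", feature_x: str = "x",
              feature_y: str = "y", conf_level: float = 0.95,
              log2_expression: bool = False) -> CorrResult:
    """Correlate two paired variables and fit the regression line.

    Pairs with a missing value on either side are dropped. Requires >= 3
    complete pairs and non-constant inputs (correlation is undefined for
    a constant variable, so that is an error rather than NaN).

    ``log2_expression`` applies log2(y + 1) before analysis, for TPM
    responses with heavy tails.
    """
    xv, yv = _complete_pairs(x, y)
    if log2_expression:
        yv = np.log2(yv + 1.0)
    if xv.size < 3:
        raise APAError(f"need >= 3 complete pairs, got {xv.size}")
    if np.ptp(xv) == 0:
        raise APAError(f"{feature_x!r} is constant; correlation undefined")
    if np.ptp(yv) == 0:
        raise APAError(f"{feature_y!r} is constant; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise APAError(f"unknown correlation method {method!r}")

    X = sm.add_constant(xv)
    fit = sm.OLS(yv, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=1 - conf_level)
    order = np.argsort(xv, kind="stable")
    band = pd.DataFrame({
        "x": xv[order],
        "fit": pred["mean"].to_numpy()[order],
        "lower": pred["mean_ci_lower"].to_numpy()[order],
        "upper": pred["mean_ci_upper"].to_numpy()[order],
    })
    return CorrResult(feature_x=feature_x, feature_y=feature_y, n=int(xv.size),
                      r=float(r), p=float(p), slope=float(fit.params[1]),
                      intercept=float(fit.params[0]), band=band, method=method)


def correlate_genes(expr_a: pd.Series, expr_b: pd.Series,
                    method: str = "pearson", **kwargs) -> CorrResult:
    """Correlation between the expressions of two genes over shared samples."""
    shared = expr_a.index.intersection(expr_b.index)
    return correlate(expr_a.loc[shared], expr_b.loc[shared], method=method,
                     feature_x=str(expr_a.name or "gene_a"),
                     feature_y=str(expr_b.name or "gene_b"), **kwargs)


def correlate_grouped(x: pd.Series, y: pd.Series, groups: GroupAssignment,
                      **kwargs) -> dict[str, CorrResult]:
    """Apply :func:`correlate` within each group of a sample assignment."""
    out = {}
    for label in groups.labels:
        ids = [s for s in groups.samples(label) if s in x.index and s in y.index]
        res = correlate(x.loc[ids], y.loc[ids], **kwargs)
        res.group = label
        out[label] = res
    return out


def screen_correlated(usage: UsageMatrix, expression: ExpressionMatrix,
                      r_min: float = 0.3, alpha: float = 0.05,
                      method: str = "pearson",
                      feature_map: dict[str, str] | None = None,
                      log2_expression: bool = False) -> list[CorrResult]:
    """Screen all usage features for expression-correlated genes.

    Each usage feature is matched to the expression row named by
    ``feature_map`` (or its own id) over the shared samples; features
    passing ``|r| > r_min and p < alpha`` are returned sorted by |r|
    descending. Features that are constant or too sparse are skipped.
    """
    shared = [s for s in usage.sample_ids if s in expression.values.columns]
    if len(shared) < 3:
        raise APAError(
            f"usage and expression share {len(shared)} samples; need >= 3"
        )
    hits: list[CorrResult] = []
    for fid in usage.feature_ids:
        target = (feature_map or {}).get(fid, fid)
        if target not in expression.values.index:
            continue
        try:
            res = correlate(
                usage.values.loc[fid, shared], expression.values.loc[target, shared],
                method=method, feature_x=fid, feature_y=target,
                log2_expression=log2_expression,
            )
        except APAError:
            continue
        if abs(res.r) > r_min and res.p < alpha:
            hits.append(res)
    hits.sort(key=lambda h: (-abs(h.r), h.feature_x))
    return hits


def corr_table(results: list[CorrResult]) -> pd.DataFrame:
    """Flatten correlation results into the exportable TSV layout."""
    return pd.DataFrame([
        {"feature_x": r.feature_x, "feature_y": r.feature_y, "group": r.group,
         "n": r.n, "r": r.r, "p": r.p, "slope": r.slope, "intercept": r.intercept}
        for r in results
    ], columns=["feature_x", "feature_y", "group", "n", "r", "p", "slope",
                "intercept"])
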