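"""Trait correlations and classical path-coefficient analysis.

Pearson correlations are computed pairwise-complete over genotype-entry
means, with two-sided t-tests on n - 2 degrees of freedom.

Path analysis decomposes each predictor's correlation with a dependent
trait into a direct effect (its standardized partial-regression
coefficient) and indirect effects routed through the other, correlated
predictors.  Writing ``R_xx`` for the predictor correlation matrix and
``r_xy`` for the predictor-dependent correlations, the direct effects solve
``R_xx P = r_xy``; the indirect effect of predictor i via predictor k is
``r_ik P_k``, so that ``r_iy = P_i + sum_{k != i} r_ik P_k`` exactly; the
residual path is ``U = sqrt(1 - sum_k P_k r_ky)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "PathResult",
    "correlation_matrix",
    "path_analysis",
    "gd_trait_correlations",
    "significance_stars",
]


def significance_stars(p: float) -> str:
    """Star annotation at the 0.05 / 0.01 / 0.001 thresholds."""
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationResult:
    """Symmetric correlation matrix with per-pair p-values and sample sizes."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        return self.p.map(significance_stars)


@dataclass
class PathResult:
    """Direct effects, indirect-effect matrix and residual path coefficient.

    ``indirect.loc[i, k]`` (i != k) is the indirect effect of predictor i
    transmitted through predictor k, i.e. ``r_ik P_k``; the diagonal holds
    the direct effects so each row sums to the total correlation r_iy.
    """

    dependent: str
    direct: pd.Series
    indirect: pd.DataFrame
    r_xy: pd.Series
    residual: float


def correlation_matrix(table: pd.DataFrame, min_n: int = 3) -> CorrelationResult:
    """Pairwise-complete Pearson correlations over a genotype x trait table.

    Zero-variance columns yield NaN correlations; pairs with fewer than
    ``min_n`` complete rows raise.  P-values come from the exact t transform
    ``t = r sqrt((n-2)/(1-r^2))`` with n - 2 degrees of freedom.
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            xy = table[[cols[i], cols[j]]].dropna()
            m = len(xy)
            n[i, j] = n[j, i] = m
            if i == j:
                r[i, i] = 1.0
                p[i, i] = 0.0
                continue
            if m < min_n:
                raise ValueError(
                    f"pair ({cols[i]}, {cols[j]}) has only {m} complete rows")
            x, y = xy.iloc[:, 0].to_numpy(), xy.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue  # r stays NaN for a zero-variance column
            rij = float(np.corrcoef(x, y)[0, 1])
            rij = max(-1.0, min(1.0, rij))
            r[i, j] = r[j, i] = rij
            if abs(rij) == 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((m - 2) / (1.0 - rij ** 2))
                pij = float(2.0 * stats.t.sf(abs(t), m - 2))
            p[i, j] = p[j, i] = pij
    mk = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return CorrelationResult(r=mk(r), p=mk(p), n=mk(n))


def path_analysis(corr: CorrelationResult | pd.DataFrame, dependent: str,
                  predictors: list[str] | None = None,
                  max_condition: float = 1e6) -> PathResult:
    """Classical path-coefficient analysis from a correlation matrix.

    Solves ``R_xx P = r_xy`` for the direct effects.  A predictor
    correlation matrix with condition number above ``max_condition`` is
    rejected (naming the most collinear pair) rather than pseudo-inverted.
    The residual path is ``sqrt(max(0, 1 - sum_k P_k r_ky))``.
    """
    r = corr.r if isinstance(corr, CorrelationResult) else corr
    if dependent not in r.index:
        raise KeyError(f"dependent trait {dependent!r} not in correlation matrix")
    if predictors is None:
        predictors = [c for c in r.columns if c != dependent]
    rxx = r.loc[predictors, predictors].to_numpy()
    rxy = r.loc[predictors, dependent].to_numpy()
    if np.isnan(rxx).any() or np.isnan(rxy).any():
        raise ValueError("correlation matrix has NaN entries among predictors")
    cond = np.linalg.cond(rxx)
    if cond > max_condition:
        off = np.abs(rxx - np.eye(len(predictors)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ValueError(
            f"predictor correlation matrix is near-singular "
            f"(condition number {cond:.3g}); most collinear pair: "
            f"{predictors[i]!r} / {predictors[j]!r}")
    direct = np.linalg.solve(rxx, rxy)
    indirect = rxx * direct[None, :]  # entry (i, k) = r_ik * P_k
    residual = float(np.sqrt(max(0.0, 1.0 - float(direct @ rxy))))
    return PathResult(
        dependent=dependent,
        direct=pd.Series(direct, index=predictors, name="direct"),
        indirect=pd.DataFrame(indirect, index=predictors, columns=predictors),
        r_xy=pd.Series(rxy, index=predictors, name="r_xy"),
        residual=residual,
    )


def gd_trait_correlations(gd: pd.DataFrame, hybrid_table: pd.DataFrame,
                          value_cols: list[str] | None = None,
                          exclude_parent: str | None = None) -> pd.DataFrame:
    """Correlate parental genetic distance with per-hybrid quantities.

    ``gd`` is the symmetric parent distance matrix; ``hybrid_table`` has one
    row per hybrid with ``parent_a, parent_b, trait`` and one column per
    quantity (e.g. hybrid mean, heterosis, SCA effect).  When
    ``exclude_parent`` is set, hybrids involving that parent (e.g. the wild
    relative) are dropped before correlating.  Returns one row per
    (trait, quantity) with r, p and n.
    """
    if value_cols is None:
        value_cols = [c for c in hybrid_table.columns
                      if c not in ("parent_a", "parent_b", "trait")]
    sub = hybrid_table
    if exclude_parent is not None:
        keep = (sub["parent_a"] != exclude_parent) & (sub["parent_b"] != exclude_parent)
        sub = sub[keep]
    d = sub.apply(lambda row: gd.loc[row["parent_a"], row["parent_b"]], axis=1)
    rows = []
    for trait, grp in sub.assign(_gd=d).groupby("trait", sort=True):
        for col in value_cols:
            xy = grp[["_gd", col]].dropna()
            if len(xy) < 3:
                raise ValueError(
                    f"fewer than 3 hybrids for trait {trait!r}, column {col!r}")
            g, v = xy["_gd"].to_numpy(), xy[col].to_numpy()
            if g.std() == 0 or v.std() == 0:
                r_val, p_val = np.nan, np.nan
            else:
                res = stats.pearsonr(g, v)
                r_val, p_val = float(res.statistic), float(res.pvalue)
            rows.append((trait, col, r_val, p_val, len(xy)))
    return pd.DataFrame(rows, columns=["trait", "quantity", "r", "p", "n"])
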