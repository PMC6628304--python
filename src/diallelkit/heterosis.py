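"""Mid-parent heterosis for half-diallel hybrids.

For hybrid i x j with entry mean F1 = x_ij and mid-parent value
MP = (x_ii + x_jj)/2, heterosis is the percentage deviation::

    Het = 100 (F1 - MP) / MP

Heterosis is invariant to rescaling a trait by a positive constant but not
to shifting it — traits with means near zero give unstable percentages, and
MP = 0 leaves Het undefined (reported as NaN with a warning).

Significance of F1 - MP uses the plot-level error variance: an entry mean
has variance sigma2_e/b, so Var(F1 - MP) = (3/2) sigma2_e / b, and the
t-test uses the ANOVA error degrees of freedom.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .griffing import EntryMeanTable

__all__ = ["mid_parent_heterosis", "heterosis_summary", "heterosis_range"]


def mid_parent_heterosis(x: EntryMeanTable, ms_error: float | None = None,
                         error_df: int | None = None) -> pd.DataFrame:
    """Per-hybrid mid-parent heterosis, optionally with a t-test.

    Returns one row per hybrid (i < j) with columns ``parent_a, parent_b,
    f1, mp, het_pct`` plus ``t, p`` when ``ms_error`` (the per-plot error
    mean square) is supplied.
    """
    p, b = x.p, x.b
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            f1 = x.x[i, j]
            mp = 0.5 * (x.x[i, i] + x.x[j, j])
            if mp == 0:
                warnings.warn(
                    f"mid-parent value is 0 for {x.parents[i]} x {x.parents[j]}; "
                    "heterosis undefined")
                het = np.nan
            else:
                het = 100.0 * (f1 - mp) / mp
            rows.append((x.parents[i], x.parents[j], f1, mp, het))
    out = pd.DataFrame(rows, columns=["parent_a", "parent_b", "f1", "mp", "het_pct"])
    if ms_error is not None:
        if error_df is None:
            error_df = (b - 1) * (p * (p + 1) // 2 - 1)
        se = np.sqrt(1.5 * ms_error / b)
        diff = out["f1"] - out["mp"]
        if se > 0:
            t = diff / se
            out["t"] = t
            out["p"] = 2.0 * stats.t.sf(np.abs(t), error_df)
        else:
            out["t"] = np.nan
            out["p"] = np.nan
    return out


def heterosis_summary(het: pd.DataFrame) -> pd.Series:
    """Boxplot-style summary of per-hybrid heterosis for one trait.

    Median, quartiles, extremes and the max - min range over hybrids.
    """
    v = het["het_pct"].dropna().to_numpy()
    if v.size == 0:
        raise ValueError("no finite heterosis values")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return pd.Series({
        "median": med, "q1": q1, "q3": q3,
        "min": v.min(), "max": v.max(), "range": v.max() - v.min(),
        "n": v.size,
    })


def heterosis_range(het: pd.DataFrame) -> float:
    """Spread (max - min) of heterosis across hybrids; 0 for a single hybrid."""
    v = het["het_pct"].dropna().to_numpy()
    if v.size == 0:
        raise ValueError("no finite heterosis values")
    return float(v.max() - v.min())
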