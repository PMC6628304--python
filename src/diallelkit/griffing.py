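"""Griffing Method 2 / Model 1 combining-ability analysis.

Method 2 analyses a half diallel containing the ``p`` parents and their
``p(p-1)/2`` F1 hybrids (no reciprocals); Model 1 treats genotype effects as
fixed.  Writing ``x_ij`` for the entry mean of cross i x j over blocks (with
``x_ii`` the parent means on the diagonal), ``x_i.`` for the i-th array sum
and ``x..`` for the grand sum of the distinct entries, the closed-form
estimators are::

    mu_hat = 2 x.. / (p (p + 1))
    g_i    = [x_i. + x_ii - (2/p) x..] / (p + 2)
    s_ij   = x_ij - (x_i. + x_ii + x_j. + x_jj)/(p + 2) + 2 x../((p+1)(p+2))

The decomposition is saturated: ``mu_hat + g_i + g_j + s_ij`` reproduces
every entry mean exactly (selfs carry ``2 g_i``), and the GCA estimates sum
to zero.  The genotype sum of squares from the block x genotype ANOVA is
partitioned into GCA and SCA strata using Griffing's sums computed on entry
means and rescaled by the number of blocks, so GCA/SCA mean squares sit on
the per-plot scale of the error mean square; this makes the genotype MS the
df-weighted combination of the two component mean squares.

The Baker ratio ``2 MS_GCA / (2 MS_GCA + MS_SCA)`` summarises the
predominance of additive over non-additive variation (values near 1 favour
selection over hybrid breeding).  It is computed from mean squares by
default; a variance-component form is available via ``mode="varcomp"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import DiallelDesign

__all__ = [
    "EntryMeanTable",
    "CombiningAbilityResult",
    "entry_means",
    "griffing_anova",
    "combining_abilities",
    "combining_ability_analysis",
    "baker_ratio",
    "heritabilities",
    "variance_components_mom",
    "relative_sca",
    "group_summary",
]


@dataclass
class EntryMeanTable:
    """Symmetric p x p table of genotype-entry means averaged over blocks.

    ``x[i, i]`` is the mean of parent i, ``x[i, j]`` the mean of hybrid
    i x j.  ``b`` records how many blocks were averaged (needed to put the
    combining-ability sums of squares on the per-plot scale).
    """

    parents: tuple[str, ...]
    x: np.ndarray
    b: int

    def __post_init__(self):
        self.parents = tuple(self.parents)
        self.x = np.asarray(self.x, dtype=float)
        p = len(self.parents)
        if self.x.shape != (p, p):
            raise ValueError("entry-mean matrix shape does not match parents")
        if not np.allclose(self.x, self.x.T, equal_nan=True):
            raise ValueError("entry-mean matrix must be symmetric")
        if np.isnan(self.x).any():
            raise ValueError("entry-mean matrix has missing cells")

    @property
    def p(self) -> int:
        return len(self.parents)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.x, index=self.parents, columns=self.parents)


@dataclass
class CombiningAbilityResult:
    """GCA/SCA estimates with standard errors and fixed-effect t-tests."""

    parents: tuple[str, ...]
    mu_hat: float
    gca: pd.Series
    gca_se: pd.Series
    gca_p: pd.Series
    sca: pd.DataFrame
    sca_se: pd.DataFrame
    sca_p: pd.DataFrame

    @property
    def p(self) -> int:
        return len(self.parents)

    def fitted(self) -> pd.DataFrame:
        """Entry means reconstructed as mu + g_i + g_j + s_ij (exact)."""
        g = self.gca.to_numpy()
        fit = self.mu_hat + g[:, None] + g[None, :] + self.sca.to_numpy()
        return pd.DataFrame(fit, index=self.parents, columns=self.parents)


def _check_complete(plots: pd.DataFrame, trait: str, parents, blocks) -> pd.DataFrame:
    sub = plots[plots["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no rows for trait {trait!r}")
    idx = {p: i for i, p in enumerate(parents)}
    missing = []
    seen = {}
    for rec in sub.itertuples(index=False):
        i, j = sorted((idx[rec.parent_a], idx[rec.parent_b]))
        key = (rec.block, i, j)
        if key in seen:
            raise ValueError(f"duplicate plot for block {rec.block}, entry {key[1:]}")
        seen[key] = rec.value
    for k in blocks:
        for i in range(len(parents)):
            for j in range(i, len(parents)):
                if (k, i, j) not in seen:
                    missing.append((k, parents[i], parents[j]))
    if missing:
        raise ValueError(f"incomplete RCBD: missing plots {missing[:10]}"
                         + (" ..." if len(missing) > 10 else ""))
    return sub


def _infer_parents(plots: pd.DataFrame, trait: str, design: DiallelDesign | None):
    if design is not None:
        return design.parent_ids
    sub = plots[plots["trait"] == trait]
    labels = sorted(set(sub["parent_a"]) | set(sub["parent_b"]))
    return tuple(labels)


def entry_means(plots: pd.DataFrame, trait: str,
                design: DiallelDesign | None = None) -> EntryMeanTable:
    """Average a tidy plot table over blocks into a symmetric entry-mean matrix.

    Raises if any (block, entry) cell is missing or duplicated: the RCBD must
    be complete, no missing-value augmentation is attempted.
    """
    parents = _infer_parents(plots, trait, design)
    sub = plots[plots["trait"] == trait]
    blocks = sorted(sub["block"].unique())
    _check_complete(plots, trait, parents, blocks)
    idx = {p: i for i, p in enumerate(parents)}
    p = len(parents)
    acc = np.zeros((p, p))
    cnt = np.zeros((p, p))
    for rec in sub.itertuples(index=False):
        i, j = idx[rec.parent_a], idx[rec.parent_b]
        acc[i, j] += rec.value
        cnt[i, j] += 1
        if i != j:
            acc[j, i] += rec.value
            cnt[j, i] += 1
    return EntryMeanTable(parents=parents, x=acc / cnt, b=len(blocks))


def _griffing_ss_from_means(x: np.ndarray) -> tuple[float, float]:
    """Griffing Method 2 GCA/SCA sums of squares on the entry-mean scale."""
    p = x.shape[0]
    xi = x.sum(axis=1)                      # array sums, diagonal counted once
    iu = np.triu_indices(p)
    xdd = float(x[iu].sum())                # grand sum over distinct entries
    t = xi + np.diag(x)
    ss_gca = (1.0 / (p + 2)) * (float((t ** 2).sum()) - (4.0 / p) * xdd ** 2)
    ss_sca = (float((x[iu] ** 2).sum())
              - (1.0 / (p + 2)) * float((t ** 2).sum())
              + (2.0 / ((p + 1) * (p + 2))) * xdd ** 2)
    return ss_gca, ss_sca


def griffing_anova(plots: pd.DataFrame, trait: str,
                   design: DiallelDesign | None = None) -> pd.DataFrame:
    """Block x genotype ANOVA with Griffing's GCA/SCA partition of genotypes.

    Returns a table indexed by stratum (block, genotype, gca, sca, error)
    with columns ``df, ss, ms, F, p``.  GCA and SCA mean squares are tested
    against the RCBD error mean square (fixed-effects Model 1).  With
    zero-variance data the F statistics are reported as NaN.
    """
    x = entry_means(plots, trait, design)
    p, b = x.p, x.b
    if p < 3:
        raise ValueError("p < 3: the SCA stratum is degenerate")
    if b < 2:
        raise ValueError("b < 2: the RCBD error stratum is undefined")
    sub = plots[plots["trait"] == trait]
    g = p * (p + 1) // 2

    y = sub["value"].to_numpy(dtype=float)
    grand = y.mean()
    block_means = sub.groupby("block")["value"].mean()
    ss_block = g * float(((block_means - grand) ** 2).sum())
    iu = np.triu_indices(p)
    ss_geno = b * float(((x.x[iu] - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_error = ss_total - ss_block - ss_geno

    ss_gca_m, ss_sca_m = _griffing_ss_from_means(x.x)
    ss_gca, ss_sca = b * ss_gca_m, b * ss_sca_m

    df = {"block": b - 1, "genotype": g - 1, "gca": p - 1,
          "sca": p * (p - 1) // 2, "error": (b - 1) * (g - 1)}
    ss = {"block": ss_block, "genotype": ss_geno, "gca": ss_gca,
          "sca": ss_sca, "error": max(ss_error, 0.0)}
    rows = {}
    ms_error = ss["error"] / df["error"]
    for stratum in ("block", "genotype", "gca", "sca", "error"):
        ms = ss[stratum] / df[stratum]
        if stratum == "error" or ms_error <= 0:
            f = pval = np.nan
        else:
            f = ms / ms_error
            pval = float(stats.f.sf(f, df[stratum], df["error"]))
        rows[stratum] = (df[stratum], ss[stratum], ms, f, pval)
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "ss", "ms", "F", "p"])
    table.attrs.update({"p": p, "b": b, "trait": trait})
    return table


def _sca_coeff_vector(p: int, i: int, j: int) -> np.ndarray:
    """Coefficients of s_ij over the p(p+1)/2 distinct entry means."""
    cl = [(a, c) for a in range(p) for c in range(a, p)]
    coef = np.zeros(len(cl))
    for k, (a, c) in enumerate(cl):
        v = 0.0
        if (a, c) == (min(i, j), max(i, j)):
            v += 1.0
        for target in ((i,) if i == j else (i, j)):
            w = 2.0 if i == j else 1.0
            arr = (1.0 if (a == target or c == target) else 0.0)
            arr += 1.0 if (a == target and c == target) else 0.0
            v -= w * arr / (p + 2)
        v += 2.0 / ((p + 1) * (p + 2))
        coef[k] = v
    return coef


def _gca_coeff_vector(p: int, i: int) -> np.ndarray:
    cl = [(a, c) for a in range(p) for c in range(a, p)]
    coef = np.zeros(len(cl))
    for k, (a, c) in enumerate(cl):
        v = 1.0 if (a == i or c == i) else 0.0
        v += 1.0 if (a == i and c == i) else 0.0
        v -= 2.0 / p
        coef[k] = v / (p + 2)
    return coef


def combining_abilities(x: EntryMeanTable, ms_error: float,
                        error_df: int | None = None) -> CombiningAbilityResult:
    """Closed-form GCA/SCA estimates with Model 1 standard errors.

    ``ms_error`` is the per-plot error mean square from the RCBD ANOVA; the
    variance of an entry mean is then ``ms_error / b``.  Standard errors
    follow from the effects being fixed linear combinations of the
    independent entry means (e.g. ``Var(g_i) = (p-1)/(p(p+2)) ms_error/b``),
    and two-sided t-tests use the error degrees of freedom.
    """
    if ms_error < 0:
        raise ValueError("ms_error must be non-negative")
    p, b = x.p, x.b
    xm = x.x
    if error_df is None:
        error_df = (b - 1) * (p * (p + 1) // 2 - 1)
    sigma2_m = ms_error / b

    xi = xm.sum(axis=1)
    iu = np.triu_indices(p)
    xdd = float(xm[iu].sum())
    mu_hat = 2.0 * xdd / (p * (p + 1))
    g = (xi + np.diag(xm) - (2.0 / p) * xdd) / (p + 2)

    s = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            s[i, j] = (xm[i, j]
                       - (xi[i] + xm[i, i] + xi[j] + xm[j, j]) / (p + 2)
                       + 2.0 * xdd / ((p + 1) * (p + 2)))
            s[j, i] = s[i, j]

    g_se = np.empty(p)
    for i in range(p):
        g_se[i] = np.sqrt(sigma2_m * (_gca_coeff_vector(p, i) ** 2).sum())
    s_se = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            se = np.sqrt(sigma2_m * (_sca_coeff_vector(p, i, j) ** 2).sum())
            s_se[i, j] = s_se[j, i] = se

    def _pvals(est, se):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, est / se, np.nan)
        return 2.0 * stats.t.sf(np.abs(t), error_df)

    parents = x.parents
    return CombiningAbilityResult(
        parents=parents,
        mu_hat=float(mu_hat),
        gca=pd.Series(g, index=parents, name="gca"),
        gca_se=pd.Series(g_se, index=parents, name="se"),
        gca_p=pd.Series(_pvals(g, g_se), index=parents, name="p"),
        sca=pd.DataFrame(s, index=parents, columns=parents),
        sca_se=pd.DataFrame(s_se, index=parents, columns=parents),
        sca_p=pd.DataFrame(_pvals(s, s_se), index=parents, columns=parents),
    )


def baker_ratio(ms_gca: float, ms_sca: float, mode: str = "ms",
                p: int | None = None, b: int = 1) -> float:
    """Baker's predictability ratio ``2 MS_GCA / (2 MS_GCA + MS_SCA)``.

    ``mode="ms"`` (default) works directly on the mean squares.
    ``mode="varcomp"`` substitutes method-of-moments variance components
    (requires ``p`` and ``b``; the error MS is taken as 0 here so the caller
    should prefer :func:`variance_components_mom` for full control).
    Returns NaN when both inputs are zero.
    """
    if ms_gca < 0 or ms_sca < 0:
        raise ValueError("mean squares must be non-negative")
    if mode == "varcomp":
        if p is None:
            raise ValueError("mode='varcomp' requires p")
        var_g = max((ms_gca - ms_sca) / (b * (p + 2)), 0.0)
        var_s = max(ms_sca / b, 0.0)
        ms_gca, ms_sca = var_g, var_s
    elif mode != "ms":
        raise ValueError(f"unknown mode {mode!r}")
    denom = 2.0 * ms_gca + ms_sca
    if denom == 0:
        return float("nan")
    return 2.0 * ms_gca / denom


def heritabilities(ms_gca: float, ms_sca: float, ms_error: float,
                   p: int) -> tuple[float, float]:
    """Narrow- and broad-sense heritability from diallel mean squares.

    Convention: ``var_g = (MS_GCA - MS_SCA)/(p + 2)``,
    ``var_s = MS_SCA - MS_error``, ``var_e = MS_error``; then
    ``h2_narrow = 2 var_g / (2 var_g + var_s + var_e)`` and
    ``h2_broad = (2 var_g + var_s) / (2 var_g + var_s + var_e)``.
    Negative component estimates are truncated at zero with a warning.
    Heritability conventions for diallels vary between software packages;
    this one is documented in the methods note.
    """
    var_g = (ms_gca - ms_sca) / (p + 2)
    var_s = ms_sca - ms_error
    var_e = ms_error
    if var_g < 0 or var_s < 0:
        warnings.warn("negative variance-component estimate truncated at 0")
        var_g, var_s = max(var_g, 0.0), max(var_s, 0.0)
    denom = 2 * var_g + var_s + var_e
    if denom == 0:
        return 0.0, 0.0
    return 2 * var_g / denom, (2 * var_g + var_s) / denom


def variance_components_mom(ms_gca: float, ms_sca: float, ms_error: float,
                            p: int, b: int) -> dict[str, float]:
    """Method-of-moments GCA/SCA/error variance components.

    With per-plot-scale mean squares the expected values under random
    centred GCA draws and i.i.d. SCA draws are::

        E[MS_error] = var_e
        E[MS_SCA]   = var_e + b var_s
        E[MS_GCA]   = var_e + b var_s + b (p + 2) var_g

    so the estimators are unbiased inversions of this triangular system.
    Estimates are not truncated; callers decide how to treat negatives.
    """
    var_e = ms_error
    var_s = (ms_sca - ms_error) / b
    var_g = (ms_gca - ms_sca) / (b * (p + 2))
    return {"sigma2_g": var_g, "sigma2_s": var_s, "sigma2_e": var_e}


def relative_sca(sca: pd.DataFrame, trait_mean: float) -> pd.DataFrame:
    """SCA effects as a percentage of the trait mean (sign preserved)."""
    if trait_mean == 0:
        raise ValueError("trait mean is zero: relative SCA undefined")
    return 100.0 * sca / trait_mean


def group_summary(plots: pd.DataFrame, trait: str,
                  design: DiallelDesign | None = None) -> pd.DataFrame:
    """Parent vs hybrid group summary over genotype-entry means.

    Returns rows ``parents`` / ``hybrids`` with mean, min, max, CV% (the
    standard deviation over the mean x 100) and group size; the Welch
    two-sided t-test p-value for the difference between the group means is
    stored in ``result.attrs['t_p']``.
    """
    x = entry_means(plots, trait, design)
    diag = np.diag(x.x)
    iu = np.triu_indices(x.p, 1)
    off = x.x[iu]
    out = {}
    for name, vals in (("parents", diag), ("hybrids", off)):
        if len(vals) < 2:
            raise ValueError(f"group {name!r} too small for a CV")
        out[name] = (vals.mean(), vals.min(), vals.max(),
                     100.0 * vals.std(ddof=1) / vals.mean(), len(vals))
    table = pd.DataFrame.from_dict(
        out, orient="index", columns=["mean", "min", "max", "cv_pct", "n"])
    t_p = float(stats.ttest_ind(diag, off, equal_var=False).pvalue)
    table.attrs["t_p"] = t_p
    return table


def combining_ability_analysis(plots: pd.DataFrame, trait: str,
                               design: DiallelDesign | None = None):
    """Full per-trait analysis: ANOVA, effects, Baker ratio, heritabilities.

    Convenience wrapper returning ``(anova, result, extras)`` where
    ``extras`` holds the Baker ratio, heritabilities, variance components
    and the relative-SCA matrix.
    """
    anova = griffing_anova(plots, trait, design)
    x = entry_means(plots, trait, design)
    res = combining_abilities(x, anova.loc["error", "ms"],
                              int(anova.loc["error", "df"]))
    ms_gca, ms_sca, ms_err = (anova.loc[s, "ms"] for s in ("gca", "sca", "error"))
    h2n, h2b = heritabilities(ms_gca, ms_sca, ms_err, x.p)
    trait_mean = float(res.mu_hat)
    extras = {
        "baker": baker_ratio(ms_gca, ms_sca),
        "h2_narrow": h2n,
        "h2_broad": h2b,
        "varcomp": variance_components_mom(ms_gca, ms_sca, ms_err, x.p, x.b),
        "relative_sca": relative_sca(res.sca, trait_mean) if trait_mean != 0 else None,
    }
    return anova, res, extras
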