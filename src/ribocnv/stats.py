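"""Cohort-level copy-number-variation statistics.

Summaries (lineage means, fold variation, foreign-ribotype fractions)
follow the reporting conventions of the source survey tables: means to
integers, fold ratios and percentages to one decimal, missing ("n.d.")
observations excluded rather than zero-filled.  Inference uses ordinary
least squares, one-/two-way ANOVA, and Tukey-type pairwise comparisons
whose family-wise adjustment is Monte-Carlo sampled from the studentized
range null rather than read from special-function tables.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

CLADE_VOCABULARY = ("H", "I-American", "I-Eurasian", "Xa", "Xu")


def _round_half_up(x: float, ndigits: int = 0) -> float:
    factor = 10.0**ndigits
    return math.floor(x * factor + 0.5) / factor


def fold_variation(values: Sequence[float]) -> float:
    """max/min ratio of strictly positive values (1.0 for identical values)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("empty value set")
    if (arr <= 0).any() or not np.isfinite(arr).all():
        raise ValueError("fold variation requires strictly positive finite values")
    return float(arr.max() / arr.min())


def lineage_summary(
    table: pd.DataFrame,
    group_col: str = "clade",
    value_col: str = "native_cn",
    level: str = "taxon-means",
    taxon_col: str = "taxon",
) -> pd.DataFrame:
    """Per-lineage mean, s.d. and fold variation of copy number.

    ``level='taxon-means'`` first averages replicate rows per taxon and then
    summarizes taxon means; ``level='individuals'`` summarizes rows directly.
    Means are reported rounded to integer and fold variation to one decimal
    (unrounded values are carried in ``*_raw`` columns); single-member
    groups report fold 1.0 and undefined s.d.
    """
    if level not in {"taxon-means", "individuals"}:
        raise ValueError("level must be 'taxon-means' or 'individuals'")
    data = table[[group_col, taxon_col, value_col]].dropna(subset=[value_col])
    if level == "taxon-means":
        data = (
            data.groupby([group_col, taxon_col], sort=False)[value_col]
            .mean()
            .reset_index()
        )
    rows = []
    for lineage, grp in data.groupby(group_col, sort=True):
        values = grp[value_col].to_numpy(float)
        if values.size == 0:
            warnings.warn(f"group {lineage!r} empty after exclusions; skipped", stacklevel=2)
            continue
        mean = float(values.mean())
        sd = float(values.std(ddof=1)) if values.size > 1 else np.nan
        fold = fold_variation(values) if values.size > 1 else 1.0
        rows.append(
            {
                "lineage": lineage,
                "n": values.size,
                "mean_cn": int(_round_half_up(mean)),
                "sd_cn": sd,
                "fold_variation": _round_half_up(fold, 1),
                "mean_cn_raw": mean,
                "fold_variation_raw": fold,
            }
        )
    return pd.DataFrame(rows)


def foreign_fraction_summary(
    table: pd.DataFrame,
    ribotypes: Sequence[str] = ("panicum", "paspalum", "setaria", "euclasta"),
    denominator: str = "native",
    native_col: str = "native_cn",
) -> pd.DataFrame:
    """Mean percent of each foreign ribotype across taxa where detected.

    Rows with a missing (not-detected) value for a ribotype are excluded
    from that ribotype's mean, never zero-filled.  ``denominator='native'``
    divides by the native copy number (the convention that reproduces the
    published 0.1-1.9% range); ``'native_plus_foreign'`` divides by native
    plus all detected foreign copies in the same row.
    """
    if denominator not in {"native", "native_plus_foreign"}:
        raise ValueError("denominator must be 'native' or 'native_plus_foreign'")
    cols = [f"{r}_cn" for r in ribotypes]
    rows = []
    for ribotype, col in zip(ribotypes, cols):
        detected = table.dropna(subset=[col, native_col])
        if detected.empty:
            warnings.warn(f"ribotype {ribotype!r} never detected; omitted", stacklevel=2)
            continue
        if denominator == "native":
            denom = detected[native_col]
        else:
            denom = detected[native_col] + detected[cols].fillna(0.0).sum(axis=1)
        pct = 100.0 * detected[col] / denom
        mean = float(pct.mean())
        rows.append(
            {
                "ribotype": ribotype,
                "n_detected": int(detected.shape[0]),
                "mean_fraction_pct": _round_half_up(mean, 1),
                "mean_fraction_pct_raw": mean,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inference


@dataclasses.dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    adjusted_r_squared: float
    p_value: float
    n: int


def ols_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple least-squares regression with adjusted R^2 and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: x is constant")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        adjusted_r_squared=float(res.rsquared_adj),
        p_value=float(res.pvalues[1]),
        n=int(res.nobs),
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Standard one-way ANOVA F statistic and p-value across groups."""
    cleaned = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(cleaned) < len(list(groups)):
        warnings.warn("empty group(s) excluded from ANOVA", stacklevel=2)
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    if sum(g.size for g in cleaned) <= len(cleaned):
        raise ValueError("need total n greater than the number of groups")
    pooled = np.concatenate(cleaned)
    if np.ptp(pooled) == 0:  # no variation at all: zero between-group signal
        return 0.0, 1.0
    f, p = scipy.stats.f_oneway(*cleaned)
    return float(f), float(p)


def two_way_anova(
    data: pd.DataFrame, value: str, factor_a: str, factor_b: str
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, Type-II sums of squares.

    Type II handles the unbalanced cells that arise when not every
    ribotype is detected in every subclade or region.
    """
    df = data[[value, factor_a, factor_b]].dropna()
    model = smf.ols(f"{value} ~ C({factor_a}) * C({factor_b})", data=df).fit()
    return anova_lm(model, typ=2)


# ---------------------------------------------------------------------------
# Monte-Carlo Tukey-type pairwise comparisons


def simulate_studentized_range(
    k: int, df: int, n_draws: int, seed: int | None = None
) -> np.ndarray:
    """Draws from the studentized range null for k groups and df error d.f."""
    if k < 2 or df < 1 or n_draws < 1:
        raise ValueError("need k >= 2, df >= 1, n_draws >= 1")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_draws, k))
    s = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    return (z.max(axis=1) - z.min(axis=1)) / s


def studentized_range_critical(
    k: int, df: int, alpha: float = 0.05, n_draws: int = 200_000, seed: int | None = 0
) -> float:
    """Monte-Carlo upper-alpha critical value q(alpha; k, df)."""
    draws = simulate_studentized_range(k, df, n_draws, seed)
    return float(np.quantile(draws, 1.0 - alpha))


def pairwise_comparisons_mc(
    groups: Sequence[Sequence[float]],
    n_draws: int = 100_000,
    seed: int | None = None,
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tukey-Kramer family-wise adjusted p-values by Monte-Carlo.

    Each pair's studentized statistic |mean_i - mean_j| /
    sqrt(MSE/2 (1/n_i + 1/n_j)) is referred to the simulated distribution
    of the studentized range of k groups at the pooled error d.f.  The
    returned matrix is symmetric with unit diagonal.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be >= 10^4")
    cleaned = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(cleaned)
    if k < 2:
        raise ValueError("need at least 2 non-empty groups")
    n = np.array([g.size for g in cleaned])
    total = int(n.sum())
    df = total - k
    if df < 1:
        raise ValueError("no error degrees of freedom")
    means = np.array([g.mean() for g in cleaned])
    sse = float(sum(((g - g.mean()) ** 2).sum() for g in cleaned))
    mse = sse / df
    draws = simulate_studentized_range(k, df, n_draws, seed)
    if labels is None:
        labels = [f"group{i + 1}" for i in range(k)]
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if mse == 0:
                q_obs = 0.0 if means[i] == means[j] else np.inf
            else:
                se = math.sqrt(mse / 2.0 * (1.0 / n[i] + 1.0 / n[j]))
                q_obs = abs(means[i] - means[j]) / se
            p[i, j] = p[j, i] = float((draws >= q_obs).mean())
    return pd.DataFrame(p, index=list(labels), columns=list(labels))
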