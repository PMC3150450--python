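"""The inferential battery used around serial-passage experiments.

One-way ANOVA with Tukey (equal n) / Tukey–Kramer (unequal n) post hoc
comparisons, ANCOVA-style slope homogeneity tests on log-scale series with
studentized-range-adjusted pairwise slope contrasts, Welch's unequal
variance t, a two-sample t on fitted slopes, and the exact two-tailed
binomial test (minimum-likelihood definition of the second tail).

Standard distributions and linear-model machinery come from scipy and
statsmodels; the contracts here add the degenerate-input conventions the
surrounding analyses rely on (e.g. zero within-group variance with equal
means yields F = 0, p = 1 rather than NaN).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .data_model import DataError, FitError
from .kinetics import RateFit


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: list[float]
    group_sizes: list[int]


@dataclass
class PairwiseResult:
    """One post hoc pair: the studentized-range statistic q and adjusted p."""

    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    mean_difference: float
    variant: str  # "tukey" | "tukey-kramer"


@dataclass
class SlopeComparisonResult:
    labels: list[str]
    slopes: dict[str, float]
    slope_stderrs: dict[str, float]
    interaction_f: float
    df_num: int
    df_den: int
    p_value: float
    pairwise: list[PairwiseResult]


# ---------------------------------------------------------------------------
# One-way ANOVA and Tukey / Tukey–Kramer
# ---------------------------------------------------------------------------

def _as_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise DataError("need >= 2 groups")
    if any(len(g) == 0 for g in gs):
        raise DataError("every group needs >= 1 value")
    return gs


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way between/within decomposition.

    Zero within-group variance with equal group means yields F = 0, p = 1.
    """
    gs = _as_groups(groups)
    n_total = sum(len(g) for g in gs)
    k = len(gs)
    if n_total <= k:
        raise DataError("total N must exceed the number of groups")
    grand = float(np.concatenate(gs).mean())
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs)
    dfb, dfw = k - 1, n_total - k
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else math.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(sps.f.sf(f, dfb, dfw))
    return AnovaResult(float(f), dfb, dfw, p,
                       [float(g.mean()) for g in gs], [len(g) for g in gs])


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence[str]] = None) -> list[PairwiseResult]:
    """All-pairs studentized-range comparisons after a one-way layout.

    With unequal group sizes the Tukey–Kramer form (per-pair harmonic
    standard error) is applied automatically; the variant used is reported
    on every pair.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"g{i + 1}" for i in range(len(gs))]
    k = len(gs)
    n_total = sum(len(g) for g in gs)
    dfw = n_total - k
    if dfw <= 0:
        raise DataError("no residual degrees of freedom for Tukey's test")
    msw = sum(float(((g - g.mean()) ** 2).sum()) for g in gs) / dfw
    equal_n = len({len(g) for g in gs}) == 1
    variant = "tukey" if equal_n else "tukey-kramer"
    out = []
    for (i, a), (j, b) in itertools.combinations(enumerate(gs), 2):
        diff = float(a.mean() - b.mean())
        se = math.sqrt(msw / 2 * (1 / len(a) + 1 / len(b)))
        if se == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            p = 1.0 if diff == 0.0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, dfw))
        out.append(PairwiseResult((labels[i], labels[j]), q, p, diff, variant))
    return out


# ---------------------------------------------------------------------------
# ANCOVA on slopes
# ---------------------------------------------------------------------------

def ancova_slopes(series: dict[str, tuple[Sequence[float], Sequence[float]]]
                  ) -> SlopeComparisonResult:
    """Slope-homogeneity test for per-group (x, y) data on the log scale.

    Fits the general linear model y ~ group * x; the interaction F (df
    k−1, N−2k) tests whether the semi-log slopes differ among groups.
    Pairwise slope contrasts use the pooled residual variance with a
    studentized-range adjustment, mirroring a Tukey post hoc on slopes.
    """
    if len(series) < 2:
        raise DataError("need >= 2 groups for a slope comparison")
    frames = []
    for label, (x, y) in series.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) < 3:
            raise DataError(f"group {label!r}: need >= 3 points")
        if np.ptp(x) == 0:
            raise FitError(f"group {label!r}: x values are collinear (constant)")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": label}))
    df = pd.concat(frames, ignore_index=True)
    labels = list(series.keys())
    k = len(labels)

    full = smf.ols("y ~ C(g) * x", data=df).fit()
    reduced = smf.ols("y ~ C(g) + x", data=df).fit()
    df_num = k - 1
    df_den = int(full.df_resid)
    tss = float(((df["y"] - df["y"].mean()) ** 2).sum())
    tol = 1e-12 * max(tss, 1.0)
    extra = reduced.ssr - full.ssr
    if full.ssr <= tol:
        # both models (near-)interpolate: no evidence of slope heterogeneity
        # unless the common-slope model leaves real residual variance
        f = 0.0 if extra <= tol else math.inf
        p = 1.0 if f == 0.0 else 0.0
    else:
        f = max(extra, 0.0) / df_num / (full.ssr / df_den)
        p = float(sps.f.sf(f, df_num, df_den))

    # per-group slopes and their standard errors from separate OLS lines,
    # contrast variance from the pooled (full-model) residual variance
    slopes: dict[str, float] = {}
    stderrs: dict[str, float] = {}
    sxx: dict[str, float] = {}
    mse = full.ssr / df_den if df_den > 0 else 0.0
    for label, (x, y) in series.items():
        x = np.asarray(x, dtype=float)
        res = sps.linregress(x, np.asarray(y, dtype=float))
        slopes[label] = float(res.slope)
        stderrs[label] = 0.0 if math.isnan(res.stderr) else float(res.stderr)
        sxx[label] = float(((x - x.mean()) ** 2).sum())

    pairwise = []
    for la, lb in itertools.combinations(labels, 2):
        diff = slopes[la] - slopes[lb]
        var = mse * (1 / sxx[la] + 1 / sxx[lb])
        if var == 0.0:
            q = 0.0 if diff == 0.0 else math.inf
            padj = 1.0 if q == 0.0 else 0.0
        else:
            q = abs(diff) / math.sqrt(var / 2)  # studentized-range scaling
            padj = float(sps.studentized_range.sf(q, k, df_den))
        pairwise.append(PairwiseResult((la, lb), q, padj, diff, "tukey"))
    return SlopeComparisonResult(labels, slopes, stderrs, float(f),
                                 df_num, df_den, p, pairwise)


# ---------------------------------------------------------------------------
# t tests
# ---------------------------------------------------------------------------

def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t with Satterthwaite df; two-tailed p.

    Both groups degenerate (zero variance) with equal means returns
    (0, n_a + n_b − 2, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataError("need >= 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(na + nb - 2), 0.0
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * float(sps.t.sf(abs(t), df))
    return float(t), float(df), p


def slope_t_test(fit_a: RateFit, fit_b: RateFit) -> tuple[float, float, float]:
    """Two-tailed t comparing two fitted slopes.

    t = (b_a − b_b)/√(SE_a² + SE_b²) with df = n_a + n_b − 4 (two slopes and
    two intercepts estimated).
    """
    for name, fit in (("a", fit_a), ("b", fit_b)):
        if fit.stderr is None or math.isnan(fit.stderr):
            raise DataError(f"fit {name} carries no slope standard error")
    df = float(fit_a.n_points + fit_b.n_points - 4)
    if df <= 0:
        raise DataError("not enough points for a slope comparison")
    diff = fit_a.slope - fit_b.slope
    se = math.sqrt(fit_a.stderr ** 2 + fit_b.stderr ** 2)
    if se == 0.0:
        if diff == 0.0:
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff), df, 0.0
    t = diff / se
    return float(t), df, 2 * float(sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# Exact binomial
# ---------------------------------------------------------------------------

def binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Exact two-tailed binomial p (minimum-likelihood second tail).

    Sums P(X = x) over every outcome x whose point probability does not
    exceed that of the observed k (the convention of scipy's ``binomtest``).
    """
    if not (0 <= k <= n):
        raise DataError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < p0 < 1):
        raise DataError(f"p0 must lie in (0, 1), got {p0!r}")
    return float(sps.binomtest(int(k), int(n), p0).pvalue)
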