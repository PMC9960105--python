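"""Per-peak class statistics and the cohort power calculation.

For every picked peak the cohort table reports:

* ``Dave`` — the difference between the maximal and minimal class-average
  peak quantity, a simple univariate separation score;
* ``PTTA`` — the p-value of a two-sample Student t-test (2 classes) or a
  one-way ANOVA (>= 3 classes);
* ``PWKW`` — the p-value of the Wilcoxon rank-sum test (2 classes) or its
  k-sample generalization, the Kruskal-Wallis test (>= 3 classes);
* ``PAD`` — the Anderson-Darling normality p-value of the pooled
  within-class residuals, which flags peaks whose quantities are not
  normally distributed;

plus the per-class mean +- SD.  The module also provides the balanced
one-way ANOVA power calculation (noncentral F) used to size the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import PeakMatrix


@dataclass
class PeakStatsRow:
    index: int
    centroid_mz: float
    dave: float
    ptta: float
    pwkw: float
    pad: float
    class_means: dict   # label -> mean
    class_sds: dict     # label -> SD
    constant: bool = False


def dave(class_means) -> float:
    """Max minus min of the class-average peak quantities."""
    means = list(dict(class_means).values())
    if len(means) < 2:
        raise ValueError("dave needs at least 2 classes")
    return float(max(means) - min(means))


def anderson_darling_p(x) -> float:
    """Anderson-Darling test p-value for composite normality.

    Uses the A^2 statistic with estimated mean and variance and the
    small-sample correction A* = A^2 (1 + 0.75/n + 2.25/n^2), with the
    Stephens / D'Agostino piecewise exponential approximation of the null
    distribution (the same formulas R's ``nortest::ad.test`` applies).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("Anderson-Darling needs n >= 8")
    z = np.sort((x - x.mean()) / x.std(ddof=1))
    cdf = sps.norm.cdf(z)
    eps = np.finfo(float).tiny
    cdf = np.clip(cdf, eps, 1 - 1e-16)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(cdf) + np.log1p(-cdf[::-1])))
    a = a2 * (1.0 + 0.75 / n + 2.25 / n ** 2)
    if a >= 0.6:
        p = np.exp(1.2937 - 5.709 * a + 0.0186 * a * a)
    elif a > 0.34:
        p = np.exp(0.9177 - 4.279 * a - 1.38 * a * a)
    elif a > 0.2:
        p = 1.0 - np.exp(-8.318 + 42.796 * a - 59.938 * a * a)
    else:
        p = 1.0 - np.exp(-13.436 + 101.14 * a - 223.73 * a * a)
    return float(min(max(p, 0.0), 1.0))


def class_tests(matrix: PeakMatrix) -> list:
    """Compute the per-peak class statistics for a labeled peak matrix.

    A constant column gets all p-values reported as 1 with ``constant=True``
    rather than NaN.
    """
    labels = np.asarray(matrix.labels)
    classes = matrix.class_names
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    masks = {c: labels == c for c in classes}
    for c, m in masks.items():
        if m.sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    rows = []
    for j, peak in enumerate(matrix.peaks):
        col = matrix.values[:, j]
        groups = [col[masks[c]] for c in classes]
        means = {c: float(g.mean()) for c, g in zip(classes, groups)}
        sds = {c: float(g.std(ddof=1)) for c, g in zip(classes, groups)}
        d = dave(means)
        constant = np.ptp(col) == 0
        if constant:
            ptta = pwkw = pad = 1.0
        else:
            if len(classes) == 2:
                ptta = float(sps.ttest_ind(*groups).pvalue)
                pwkw = float(sps.ranksums(*groups).pvalue)
            else:
                ptta = float(sps.f_oneway(*groups).pvalue)
                try:
                    pwkw = float(sps.kruskal(*groups).pvalue)
                except ValueError:  # all values identical within groups
                    pwkw = 1.0
            residuals = np.concatenate([g - g.mean() for g in groups])
            if np.ptp(residuals) == 0 or len(residuals) < 8:
                pad = 1.0  # too little data to assess normality
            else:
                pad = anderson_darling_p(residuals)
            if not np.isfinite(ptta):
                ptta = 1.0
            if not np.isfinite(pwkw):
                pwkw = 1.0
        rows.append(PeakStatsRow(index=peak.index, centroid_mz=peak.centroid_mz,
                                 dave=d, ptta=ptta, pwkw=pwkw, pad=pad,
                                 class_means=means, class_sds=sds,
                                 constant=constant))
    return rows


def stats_table(matrix: PeakMatrix, bh_adjust: bool = False) -> pd.DataFrame:
    """The per-peak statistics as a DataFrame (one row per peak).

    With ``bh_adjust=True``, Benjamini-Hochberg adjusted columns
    ``ptta_bh`` / ``pwkw_bh`` are appended (off by default; the reference
    analysis applied no multiplicity correction).
    """
    rows = class_tests(matrix)
    classes = matrix.class_names
    recs = []
    for r in rows:
        rec = {"index": r.index, "mass": r.centroid_mz, "dave": r.dave,
               "ptta": r.ptta, "pwkw": r.pwkw, "pad": r.pad,
               "constant": r.constant}
        for c in classes:
            rec[f"{c}_avg"] = r.class_means[c]
            rec[f"{c}_sd"] = r.class_sds[c]
        recs.append(rec)
    df = pd.DataFrame(recs)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests
        for col in ("ptta", "pwkw"):
            df[f"{col}_bh"] = multipletests(df[col], method="fdr_bh")[1]
    return df


def anova_power(f: float, k: int, alpha: float, n_total: int) -> float:
    """Power of a balanced one-way fixed-effects ANOVA.

    ``f`` is Cohen's effect size (between-group SD of means over within-group
    SD); the test statistic follows a noncentral F distribution with
    ``k-1`` and ``n_total-k`` degrees of freedom and noncentrality
    ``lambda = f^2 * n_total``.
    """
    if f < 0:
        raise ValueError("effect size must be >= 0")
    if k < 2:
        raise ValueError("need k >= 2 groups")
    if n_total < k + 1:
        raise ValueError("infeasible degrees of freedom")
    df1, df2 = k - 1, n_total - k
    fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
    if f == 0:
        return float(alpha)  # central case: rejection rate is the level
    lam = f * f * n_total
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def required_n(f: float, k: int, alpha: float, target_power: float,
               n_cap: int = 100000) -> int:
    """Smallest balanced total sample size reaching the target power."""
    if not (alpha < target_power < 1):
        raise ValueError("target power must lie in (alpha, 1)")
    m = 2  # need n_total - k >= 1 within-group df, with >= 2 per group
    while k * m <= n_cap:
        n = k * m
        if anova_power(f, k, alpha, n) >= target_power:
            return n
        m += 1
    raise ValueError(f"target power unreachable below n_total={n_cap}")
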