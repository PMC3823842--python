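"""Between-condition statistics on integrated network parameters.

The study design is within-subject: every subject contributes one
integrated-metric set per condition, so differences are tested with a
paired t-test (df = M - 1) by default; an unpaired variant is available
for sensitivity.  Normality of the paired differences is screened with a
Lilliefors test (Kolmogorov-Smirnov with estimated mean and SD) whose
p-value comes from Monte Carlo simulation under the normal null, making
it reproducible at any sample size given a seed.

Multiple testing is corrected per family with Benjamini-Hochberg FDR:
the six global parameters form one family and the N nodal betweenness
tests another, mirroring how global and regional results are reported
separately.  Raw p-values are always reported alongside q-values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .integration import IntegratedMetrics

GLOBAL_PARAMS = ("aCp", "aLp", "aGamma", "aLambda", "aEglob", "aEloc")


def lilliefors_statistic(values: np.ndarray) -> float:
    """Sup-norm distance between the empirical CDF and the fitted normal CDF."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sps.norm.cdf(z)
    up = np.arange(1, n + 1) / n - cdf
    down = cdf - np.arange(0, n) / n
    return float(max(up.max(), down.max()))


def lilliefors(values, n_mc: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Lilliefors normality test with a Monte Carlo p-value.

    The null distribution of D is simulated with ``n_mc`` standard-normal
    samples of the same length; p = (1 + #{D_mc >= D}) / (n_mc + 1).
    Deterministic given ``seed``.  Constant input raises.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 5:
        raise ValueError("Lilliefors test needs at least 5 observations")
    if x.std(ddof=1) == 0:
        raise ValueError("constant sample: normality test undefined")
    d_obs = lilliefors_statistic(x)
    n = len(x)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_mc, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    z.sort(axis=1)
    cdf = sps.norm.cdf(z)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_mc = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    p = (1 + int((d_mc >= d_obs).sum())) / (n_mc + 1)
    return d_obs, float(p)


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject differences x - y.

    All-zero differences return (0.0, 1.0); constant non-zero
    differences (zero variance, non-zero mean) raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors with M >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, 1.0
        raise ValueError("zero-variance non-zero differences: t undefined")
    m = len(d)
    t = d.mean() / (sd / np.sqrt(m))
    p = 2.0 * sps.t.sf(abs(t), df=m - 1)
    return float(t), float(p)


def unpaired_ttest(x, y) -> tuple[float, float]:
    """Two-sided two-sample t-test (equal variances), sensitivity variant."""
    t, p = sps.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(t), float(p)


def fdr_bh(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: adjusted q-values and rejection flags."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, q <= alpha


def compare_conditions(
    results: list[IntegratedMetrics],
    alpha: float = 0.05,
    paired: bool = True,
    lilliefors_n_mc: int = 10_000,
    lilliefors_seed: int = 0,
    conditions: tuple[str, str] = ("implicit", "explicit"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Global and nodal between-condition comparison tables.

    Returns ``(global_table, nodal_table)``; the global table has one row
    per integrated parameter, the nodal table one row per region (aBC).
    Each row carries the per-condition mean and SD, the t statistic on
    (first condition - second condition), raw p, FDR q within its family,
    a ``significant`` flag (q <= alpha) and the Lilliefors normality flag
    of the paired differences.  Every subject must appear in both
    conditions.
    """
    ca, cb = conditions
    by_cond: dict[str, dict[str, IntegratedMetrics]] = {ca: {}, cb: {}}
    for r in results:
        if r.condition in by_cond:
            by_cond[r.condition][r.subject_id] = r
    subjects = sorted(by_cond[ca])
    for s in set(subjects) ^ set(by_cond[cb]):
        raise ValueError(f"subject {s} is missing one condition")
    if len(subjects) < 2:
        raise ValueError("need at least 2 complete subjects")
    test = paired_ttest if paired else unpaired_ttest

    def one_family(names, getter):
        rows = []
        for i, name in enumerate(names):
            x = np.array([getter(by_cond[ca][s], i) for s in subjects])
            y = np.array([getter(by_cond[cb][s], i) for s in subjects])
            if np.isnan(x).all() and np.isnan(y).all():
                continue  # parameter not computed (e.g. no null ensemble)
            t, p = test(x, y)
            d = x - y
            if d.std(ddof=1) > 0 and len(d) >= 5:
                _, lp = lilliefors(
                    d, n_mc=lilliefors_n_mc, seed=lilliefors_seed + i
                )
                normal = lp > alpha
            else:
                normal = True
            rows.append(
                {
                    "name": name,
                    f"mean_{ca}": x.mean(),
                    f"sd_{ca}": x.std(ddof=1),
                    f"mean_{cb}": y.mean(),
                    f"sd_{cb}": y.std(ddof=1),
                    "t": t,
                    "p": p,
                    "normal": normal,
                }
            )
        df = pd.DataFrame(rows)
        df["q"], df["significant"] = fdr_bh(df["p"].to_numpy(), alpha=alpha)
        df["direction"] = np.where(
            df["t"] > 0, f"{ca}>{cb}", np.where(df["t"] < 0, f"{ca}<{cb}", "none")
        )
        return df

    any_r = next(iter(by_cond[ca].values()))
    glob = one_family(
        GLOBAL_PARAMS, lambda r, i: r.global_values()[GLOBAL_PARAMS[i]]
    )
    nodal = one_family(list(any_r.labels), lambda r, i: r.a_bc[i])
    return glob, nodal
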