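"""Statistics battery for the cohort analyses.

Kruskal-Wallis with Dunn's pairwise post hoc comparisons, Kendall tau-b and
partial Kendall correlation, Pearson chi-square for categorical
associations, chance-corrected inter-rater agreement (Cohen's kappa for two
raters, Fleiss' kappa for more) with the interpretation bands used in the
study, and the bias-corrected and accelerated (BCa) bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.stats as ss
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

from .errors import InvalidInputError, UndefinedValueWarning


@dataclass
class StatTestResult:
    """Outcome of one statistical test."""

    method: str
    statistic: float
    df: object  # int, pair of ints, or None
    p: float
    n: int
    ci: Optional[tuple[float, float]] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise InvalidInputError("ci.low must be <= ci.high")


#: Agreement bands, lower-inclusive: kappa of exactly 0.2 is "fair",
#: 0.8 is "very good".
KAPPA_BANDS = (
    (0.2, "poor"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "good"),
    (np.inf, "very good"),
)


def kappa_band(kappa: float) -> str:
    """Interpretation band for a kappa coefficient."""
    for upper, name in KAPPA_BANDS:
        if kappa < upper:
            return name
    return "very good"


@dataclass
class KappaResult:
    kappa: float
    band: str
    n_cases: int
    n_raters: int
    degenerate: bool = False


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2):
    if len(groups) < min_groups:
        raise InvalidInputError(f"need at least {min_groups} groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise InvalidInputError("all groups must be non-empty")
    return arrs


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatTestResult:
    """Kruskal-Wallis H test on mid-ranks with tie correction.

    H is defined as 0 (p = 1) when every observation is identical, where
    the tie-correction denominator vanishes.
    """
    arrs = _check_groups(groups)
    n = sum(a.size for a in arrs)
    df = len(arrs) - 1
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return StatTestResult("kruskal-wallis", 0.0, df, 1.0, n)
    stat, p = ss.kruskal(*arrs)
    return StatTestResult("kruskal-wallis", float(stat), df, float(p), n)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    names: Optional[Sequence[str]] = None,
) -> list[StatTestResult]:
    """Dunn's z tests on the joint ranking for every pair of groups.

    Each result carries the unadjusted two-sided normal p; the Bonferroni
    adjusted value (times the number of pairs, capped at 1) is in
    ``extra["p_bonferroni"]``.
    """
    arrs = _check_groups(groups)
    if names is None:
        names = [str(i) for i in range(len(arrs))]
    pooled = np.concatenate(arrs)
    n = pooled.size
    ranks = ss.rankdata(pooled)
    # tie correction term for the variance of mean rank differences
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    base_var = n * (n + 1) / 12.0 - tie_term
    mean_ranks, sizes, idx = [], [], 0
    for a in arrs:
        mean_ranks.append(ranks[idx : idx + a.size].mean())
        sizes.append(a.size)
        idx += a.size
    n_pairs = len(arrs) * (len(arrs) - 1) // 2
    results = []
    for i, j in combinations(range(len(arrs)), 2):
        diff = mean_ranks[i] - mean_ranks[j]
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0.0:
            z = 0.0 if diff == 0.0 else np.inf
        else:
            z = diff / se
        p = float(2.0 * ss.norm.sf(abs(z)))
        results.append(
            StatTestResult(
                "dunn",
                float(z),
                None,
                p,
                sizes[i] + sizes[j],
                extra={
                    "pair": (names[i], names[j]),
                    "p_bonferroni": min(1.0, p * n_pairs),
                },
            )
        )
    return results


def _check_xy(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InvalidInputError("x and y must have equal length")
    if x.size < min_n:
        raise InvalidInputError(f"need at least {min_n} observations")
    return x, y


def kendall_tau(x, y) -> StatTestResult:
    """Kendall tau-b rank correlation with tie handling; asymptotic
    (normal-approximation) p-value.

    A constant input vector leaves the correlation undefined: the result
    carries NaN and an :class:`UndefinedValueWarning` is issued.
    """
    x, y = _check_xy(x, y)
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("kendall tau undefined for a constant vector",
                      UndefinedValueWarning)
        return StatTestResult("kendall-tau-b", float("nan"), None, float("nan"),
                              x.size)
    tau, p = ss.kendalltau(x, y, variant="b", method="asymptotic")
    return StatTestResult("kendall-tau-b", float(tau), None, float(p), x.size)


def kendall_partial(x, y, z) -> StatTestResult:
    """Partial Kendall correlation of x and y controlling for z.

    tau_xy.z = (tau_xy - tau_xz * tau_zy) / sqrt((1 - tau_xz^2)(1 - tau_zy^2)),
    each tau being tau-b. The p-value applies the plain-tau normal
    approximation to the partial coefficient (an approximation; there is no
    standard exact null distribution for the partial tau).
    """
    x, y = _check_xy(x, y)
    z = np.asarray(z, dtype=float)
    if z.size != x.size:
        raise InvalidInputError("z must match x and y in length")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedValueWarning)
        t_xy = kendall_tau(x, y).statistic
        t_xz = kendall_tau(x, z).statistic
        t_zy = kendall_tau(z, y).statistic
    denom_sq = (1.0 - t_xz**2) * (1.0 - t_zy**2)
    if not np.isfinite(denom_sq) or denom_sq <= 0.0:
        warnings.warn("partial kendall tau undefined (degenerate control)",
                      UndefinedValueWarning)
        return StatTestResult("kendall-partial", float("nan"), None,
                              float("nan"), x.size)
    tau_p = (t_xy - t_xz * t_zy) / np.sqrt(denom_sq)
    n = x.size
    var = 2.0 * (2.0 * n + 5.0) / (9.0 * n * (n - 1.0))
    zstat = tau_p / np.sqrt(var)
    p = float(2.0 * ss.norm.sf(abs(zstat)))
    return StatTestResult("kendall-partial", float(tau_p), None, p, n,
                          extra={"tau_xy": t_xy, "tau_xz": t_xz, "tau_zy": t_zy})


def chi_square(table) -> StatTestResult:
    """Pearson chi-square on an r x c contingency table, no continuity
    correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise InvalidInputError("table must be a 2-D array of non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidInputError("table has a zero row or column marginal")
    stat, p, df, _ = ss.chi2_contingency(t, correction=False)
    return StatTestResult("chi-square", float(stat), int(df), float(p),
                          int(t.sum()))


def interrater_kappa(ratings) -> KappaResult:
    """Chance-corrected agreement for an n-cases x m-raters label matrix.

    Two raters: Cohen's kappa. More: Fleiss' kappa on per-case category
    proportions. When every rater assigns one identical category to every
    case, expected agreement is 1 and kappa is undefined; observed
    agreement is perfect, so 1.0 is reported with ``degenerate=True``.
    """
    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[1] < 2:
        raise InvalidInputError("ratings must be n_cases x m_raters with m >= 2")
    n_cases, m = r.shape
    categories = np.unique(r)
    if categories.size == 1:
        warnings.warn("kappa undefined: a single category used throughout; "
                      "agreement is trivially perfect", UndefinedValueWarning)
        return KappaResult(1.0, kappa_band(1.0), n_cases, m, degenerate=True)
    if m == 2:
        k = float(cohen_kappa_score(r[:, 0], r[:, 1]))
    else:
        counts, _ = aggregate_raters(r)
        k = float(fleiss_kappa(counts, method="fleiss"))
    if np.isnan(k):  # expected agreement 1 with >1 category cannot occur,
        # but guard the library's 0/0 edge
        return KappaResult(1.0, kappa_band(1.0), n_cases, m, degenerate=True)
    return KappaResult(k, kappa_band(k), n_cases, m)


def bca_bootstrap(
    data,
    statistic: Callable[[np.ndarray], float],
    B: int = 1000,
    level: float = 0.95,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    ``B`` resamples with replacement; the bias correction z0 comes from the
    fraction of resample statistics below the observed value, the
    acceleration from the jackknife skewness of the statistic. A degenerate
    resample distribution (all values equal) collapses to a point interval
    with a warning.
    """
    data = np.asarray(data, dtype=float)
    n = data.size
    if n < 8:
        raise InvalidInputError("need at least 8 observations for BCa")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    theta = float(statistic(data))
    idx = rng.integers(0, n, size=(B, n))
    boots = np.array([float(statistic(data[row])) for row in idx])
    if np.all(boots == boots[0]):
        warnings.warn("degenerate bootstrap distribution: point interval",
                      UndefinedValueWarning)
        return theta, theta
    # bias correction
    prop = (np.count_nonzero(boots < theta)
            + 0.5 * np.count_nonzero(boots == theta)) / B
    prop = min(max(prop, 1.0 / (B + 1)), B / (B + 1.0))
    z0 = ss.norm.ppf(prop)
    # acceleration from jackknife skewness
    jack = np.array(
        [float(statistic(np.delete(data, i))) for i in range(n)]
    )
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    a = float(np.sum(dev**3) / (6.0 * denom)) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    lo_hi = []
    for q in (alpha, 1.0 - alpha):
        zq = ss.norm.ppf(q)
        adj = ss.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        lo_hi.append(float(np.quantile(boots, adj)))
    return min(lo_hi), max(lo_hi)
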