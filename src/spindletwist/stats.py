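"""Statistical procedures and derived descriptors for spindle twist data.

Twist classification thresholds follow the visual-scoring scale used for
end-on spindles: |twist| < 1 deg/um is scored as no visible twist,
1 <= |twist| < 2 as weak, and |twist| >= 2 as strong (over a typical
5-um bundle, 2 deg/um corresponds to a total rotation of more than 10
degrees, which is visually unambiguous). Negative twist is left-handed.

The hypothesis tests are thin, explicit wrappers over scipy/statsmodels:
two-proportion z (pooled, no continuity correction), one-sample t from
summary statistics (mean, SEM, n), Welch's t, paired t, one-way ANOVA
with Tukey HSD. Wrapping them fixes the exact conventions used for the
twist analyses and returns a uniform result record.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "TwistClass",
    "StatResult",
    "classify_twist",
    "two_prop_z",
    "prop_se",
    "strong_twist_fraction",
    "one_sample_t_summary",
    "welch_t",
    "paired_t",
    "anova_tukey",
    "fold_change",
    "linear_fit",
    "quantify_intensity",
    "strong_twist_cutoff",
    "DEFAULT_STRONG_TWIST_CUTOFF",
]

#: Strong left-handed twist cutoff (deg/um): one standard deviation below
#: the mean bundle twist of uncompressed metaphase spindles.
DEFAULT_STRONG_TWIST_CUTOFF = -2.8

WEAK_THRESHOLD = 1.0
STRONG_THRESHOLD = 2.0


class TwistClass(enum.Enum):
    left = "left"
    weak_left = "weak_left"
    none = "none"
    weak_right = "weak_right"
    right = "right"


@dataclass(frozen=True)
class StatResult:
    """Uniform record of a hypothesis-test outcome (two-sided p)."""

    test: str
    statistic: float
    df: float | tuple[float, float] | None
    p: float
    estimate: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p value out of [0, 1]: {self.p}")


def classify_twist(
    twist: float,
    weak: float = WEAK_THRESHOLD,
    strong: float = STRONG_THRESHOLD,
) -> TwistClass:
    """Map a twist value (deg/um) onto the five-level visual scale.

    Boundary values belong to the stronger category: exactly 1 deg/um is
    weak, exactly 2 deg/um is strong.
    """
    if not np.isfinite(twist):
        raise ValueError("twist must be finite")
    mag = abs(twist)
    if mag < weak:
        return TwistClass.none
    if mag < strong:
        return TwistClass.weak_left if twist < 0 else TwistClass.weak_right
    return TwistClass.left if twist < 0 else TwistClass.right


def two_prop_z(k1: int, n1: int, k2: int, n2: int) -> StatResult:
    """Two-proportion z test (pooled variance, no continuity correction).

    Used to compare the fraction of strongly twisted bundles between
    conditions, e.g. 9/80 before vs 21/73 after axial compression, which
    gives p = 0.0064.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0:
            raise ValueError("sample size must be positive")
        if not 0 <= k <= n:
            raise ValueError("count must satisfy 0 <= k <= n")
    z, p = proportions_ztest(
        count=np.array([k1, k2]), nobs=np.array([n1, n2]),
        alternative="two-sided",
    )
    return StatResult(
        test="two_prop_z",
        statistic=float(z),
        df=None,
        p=float(p),
        estimate=k1 / n1 - k2 / n2,
    )


def prop_se(k: int, n: int) -> float:
    """Binomial (Wald) standard error of a proportion, in percent."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    p = k / n
    return 100.0 * math.sqrt(p * (1.0 - p) / n)


def strong_twist_fraction(
    bundle_twists: np.ndarray,
    cutoff: float = DEFAULT_STRONG_TWIST_CUTOFF,
) -> tuple[int, int, float]:
    """Count bundles with twist strictly below the cutoff.

    Returns (k, n, percentage). With the default cutoff of -2.8 deg/um
    this is the fraction of strongly left-handed bundles.
    """
    t = np.asarray(bundle_twists, dtype=float)
    if t.size == 0:
        raise ValueError("need at least one bundle twist")
    k = int(np.sum(t < cutoff))
    return k, int(t.size), 100.0 * k / t.size


def strong_twist_cutoff(reference_twists: np.ndarray) -> float:
    """Cutoff rule: mean minus one SD of the reference condition."""
    t = np.asarray(reference_twists, dtype=float)
    return float(t.mean() - t.std(ddof=1))


def one_sample_t_summary(mean: float, sem: float, n: int) -> StatResult:
    """One-sample t test against 0 from summary statistics.

    t = mean / SEM with n - 1 degrees of freedom; this is how published
    mean +- SEM twist values are tested for a nonzero population twist.
    """
    if not sem > 0:
        raise ValueError("SEM must be positive")
    if n < 2:
        raise ValueError("need n >= 2")
    t = mean / sem
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(
        test="one_sample_t", statistic=float(t), df=df, p=float(p),
        estimate=mean,
    )


def welch_t(a: np.ndarray, b: np.ndarray) -> StatResult:
    """Two-sample unequal-variance (Welch) t test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=False)
    return StatResult(
        test="welch_t",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        estimate=float(a.mean() - b.mean()),
    )


def paired_t(before: np.ndarray, after: np.ndarray) -> StatResult:
    """Paired t test (one-sample t on within-pair differences)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("paired samples must have equal length")
    if before.size < 2:
        raise ValueError("need n >= 2 pairs")
    diff = after - before
    if np.allclose(diff.std(ddof=1), 0.0):
        raise ValueError("zero variance of differences; t undefined")
    res = sps.ttest_rel(after, before)
    return StatResult(
        test="paired_t",
        statistic=float(res.statistic),
        df=float(before.size - 1),
        p=float(res.pvalue),
        estimate=float(diff.mean()),
    )


def anova_tukey(
    groups: dict[str, np.ndarray],
) -> tuple[StatResult, "pd.DataFrame"]:
    """One-way ANOVA plus Tukey HSD post hoc pairwise comparisons.

    Returns the ANOVA result and a tidy DataFrame of Tukey-adjusted
    pairwise p values.
    """
    import pandas as pd

    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    F, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    anova = StatResult(
        test="one_way_anova",
        statistic=float(F),
        df=(float(k - 1), float(n_total - k)),
        p=float(p),
    )
    values = np.concatenate(arrays)
    labels = np.concatenate(
        [np.repeat(g, a.size) for g, a in zip(names, arrays)]
    )
    tk = pairwise_tukeyhsd(values, labels)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return anova, table


def fold_change(before_mean: float, after_mean: float) -> float:
    """Ratio of twist magnitudes |after| / |before|."""
    if before_mean == 0:
        raise ValueError("before mean must be nonzero")
    return abs(after_mean) / abs(before_mean)


def linear_fit(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Ordinary least-squares line: returns (slope, intercept, R^2).

    Used for twist versus width/length-ratio regressions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 points")
    if np.allclose(x, x[0]):
        raise ValueError("x must not be constant")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def quantify_intensity(
    spindle_polygon_mean: float, background_mean: float, n_slices: int
) -> float:
    """Background-corrected mean spindle fluorescence per z slice (a.u.).

    Negative results are possible (background above signal) and left to
    the caller to flag.
    """
    if n_slices < 1:
        raise ValueError("need >= 1 z slice")
    return (spindle_polygon_mean - background_mean) / n_slices
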