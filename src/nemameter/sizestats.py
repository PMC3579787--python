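"""Statistics for comparing worm size and shape between populations.

Implements the descriptive and inferential procedures used alongside the
measurement pipeline: moment-based sample skewness and excess kurtosis
(to justify normality assumptions on volume), a balanced-subsampling
Bonferroni-corrected two-sample Student's t-test for unequal group sizes,
a test for the difference between two regression slopes (worm shape as
width-on-length slope), and a two-sample two-sided power analysis based on
the non-central t distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SampleStats",
    "SlopeComparison",
    "PowerSpec",
    "PowerResult",
    "sample_skewness",
    "excess_kurtosis",
    "describe_sample",
    "balanced_subsample_ttest",
    "compare_slopes",
    "power_sample_size",
    "achieved_power",
]


def _central_moments(xs):
    xs = np.asarray(xs, dtype=float)
    d = xs - xs.mean()
    return len(xs), d.var(), (d**3).mean(), (d**4).mean()


def sample_skewness(xs) -> float:
    """Moment skewness g1 = m3 / m2^{3/2}, with m_k = (1/n)Σ(x−x̄)^k."""
    xs = np.asarray(xs, dtype=float)
    if len(xs) < 3:
        raise ValueError("skewness needs n >= 3")
    n, m2, m3, _ = _central_moments(xs)
    if m2 == 0:
        raise ValueError("skewness undefined for zero variance")
    return float(m3 / m2**1.5)


def excess_kurtosis(xs) -> float:
    """Excess kurtosis g2 = m4 / m2² − 3 (0 for a normal population)."""
    xs = np.asarray(xs, dtype=float)
    if len(xs) < 3:
        raise ValueError("kurtosis needs n >= 3")
    _, m2, _, m4 = _central_moments(xs)
    if m2 == 0:
        raise ValueError("kurtosis undefined for zero variance")
    return float(m4 / m2**2 - 3.0)


@dataclass
class SampleStats:
    n: int
    mean: float
    m2: float
    m3: float
    m4: float
    g1: float
    g2: float


def describe_sample(xs) -> SampleStats:
    xs = np.asarray(xs, dtype=float)
    n, m2, m3, m4 = _central_moments(xs)
    return SampleStats(n=n, mean=float(xs.mean()), m2=float(m2), m3=float(m3),
                       m4=float(m4), g1=sample_skewness(xs),
                       g2=excess_kurtosis(xs))


def balanced_subsample_ttest(control_values_by_replicate,
                             strain_values_by_replicate,
                             n_iter: int = 1000, n_comparisons: int = 1,
                             seed: int | None = None) -> float:
    """Median subsampled two-sample t-test p value, Bonferroni corrected.

    The two groups (values pooled over replicates) usually differ in size;
    each iteration subsamples the larger group without replacement down to
    the smaller group's size and runs a two-sided equal-variance Student's
    t-test.  The median of the ``n_iter`` p values is multiplied by
    ``n_comparisons`` and capped at 1.

    ``seed`` drives the single generator used for all subsampling and is
    required for reproducibility (pass an int).
    """
    control = np.concatenate([np.asarray(v, dtype=float).ravel()
                              for v in control_values_by_replicate])
    strain = np.concatenate([np.asarray(v, dtype=float).ravel()
                             for v in strain_values_by_replicate])
    if len(control) < 2 or len(strain) < 2:
        raise ValueError("each group needs at least 2 values")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n = min(len(control), len(strain))
    ps = np.empty(n_iter)
    for i in range(n_iter):
        a = control if len(control) == n else rng.choice(control, n, replace=False)
        b = strain if len(strain) == n else rng.choice(strain, n, replace=False)
        ps[i] = stats.ttest_ind(a, b, equal_var=True).pvalue
    return float(min(np.median(ps) * n_comparisons, 1.0))


@dataclass
class SlopeComparison:
    b1: float
    b2: float
    se_diff: float
    t_stat: float
    df: int
    p: float


def compare_slopes(x1, y1, x2, y2) -> SlopeComparison:
    """Student's t-test on the difference between two OLS regression slopes.

    The slope difference is weighted by its standard error, pooling the
    residual mean squares of the two regressions:
    se = sqrt(s²_p/Sxx₁ + s²_p/Sxx₂), df = n₁ + n₂ − 4 (Zar's procedure).
    """
    x1, y1, x2, y2 = (np.asarray(a, dtype=float) for a in (x1, y1, x2, y2))
    for x in (x1, x2):
        if len(x) < 3:
            raise ValueError("each dataset needs n >= 3")
        if np.ptp(x) == 0:
            raise ValueError("constant x: slope undefined")
    b1, sse1, sxx1 = _ols(x1, y1)
    b2, sse2, sxx2 = _ols(x2, y2)
    df = len(x1) + len(x2) - 4
    s2 = (sse1 + sse2) / df
    se = float(np.sqrt(s2 / sxx1 + s2 / sxx2))
    diff = b1 - b2
    if se == 0:
        t = np.inf if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
    else:
        t = diff / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return SlopeComparison(b1=b1, b2=b2, se_diff=se, t_stat=float(t), df=df, p=p)


def _ols(x, y):
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    a = ym - b * xm
    sse = float(np.sum((y - a - b * x) ** 2))
    return b, sse, sxx


@dataclass
class PowerSpec:
    """Two-sample, two-sided design.  ``delta`` and ``sigma`` share units
    (conveniently: fractions of the control mean, so sigma is the CV)."""

    alpha: float = 0.01
    beta: float = 0.2
    delta: float = 0.15
    sigma: float = 0.21

    def __post_init__(self):
        if not 0 < self.alpha < 1 or not 0 < self.beta < 1:
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.delta <= 0 or self.sigma <= 0:
            raise ValueError("delta and sigma must be > 0")


@dataclass
class PowerResult:
    n_real: float
    n: int  # ceiling, per group
    df: float
    ncp: float


def achieved_power(n: float, spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test at per-group size n."""
    df = 2.0 * (n - 1.0)
    ncp = spec.delta / spec.sigma * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(tcrit, df, ncp))


def power_sample_size(spec: PowerSpec) -> PowerResult:
    """Per-group sample size n solving power(n) = 1 − β.

    Solves 1 − β = 1 − F_nct(t_{1−α/2, 2(n−1)}; 2(n−1), (δ/σ)√(n/2)) for
    real n by bracketed root-finding on n ∈ [2, 10⁷], then reports the
    ceiling (achieved power at the ceiling is ≥ 1 − β).
    """
    target = 1.0 - spec.beta

    def gap(n):
        return achieved_power(n, spec) - target

    lo, hi = 2.0, 1e7
    if gap(lo) >= 0:
        n_real = lo
    else:
        if gap(hi) < 0:
            raise ValueError("no feasible sample size in [2, 1e7] for this spec")
        n_real = float(optimize.brentq(gap, lo, hi, xtol=1e-6))
    n_ceil = int(np.ceil(n_real - 1e-9))
    return PowerResult(n_real=n_real, n=n_ceil, df=2.0 * (n_real - 1.0),
                       ncp=spec.delta / spec.sigma * np.sqrt(n_real / 2.0))


def size_table(df, control: str, value_columns=("length_um", "mid_width_um",
                                                "volume_pl"),
               strain_col="strain", time_col="time", rep_col="replicate",
               n_iter: int = 1000, seed: int = 0):
    """Per-strain, per-time subsampled t-test table against a control.

    One row per (strain, time): Bonferroni-adjusted median-subsample p
    values for each measurement column plus skewness and excess kurtosis
    of the strain's volume distribution.  The Bonferroni factor is the
    total number of tests in the table.
    """
    import pandas as pd

    strains = [s for s in df[strain_col].unique() if s != control]
    times = sorted(df[time_col].unique())
    n_comp = max(len(strains) * len(times) * len(value_columns), 1)
    vol_col = value_columns[-1]
    rows = []
    for si, strain in enumerate(strains):
        for ti, time in enumerate(times):
            ctrl = df[(df[strain_col] == control) & (df[time_col] == time)]
            mut = df[(df[strain_col] == strain) & (df[time_col] == time)]
            row = {strain_col: strain, time_col: time}
            for vi, col in enumerate(value_columns):
                if len(ctrl) < 2 or len(mut) < 2:
                    row[f"{col}_p"] = np.nan
                    continue
                row[f"{col}_p"] = balanced_subsample_ttest(
                    [g[col].to_numpy() for _, g in ctrl.groupby(rep_col)],
                    [g[col].to_numpy() for _, g in mut.groupby(rep_col)],
                    n_iter=n_iter, n_comparisons=n_comp,
                    seed=seed + 1000 * si + 10 * ti + vi)
            vols = mut[vol_col].to_numpy()
            row["volume_skewness"] = (sample_skewness(vols)
                                      if len(vols) >= 3 else np.nan)
            row["volume_kurtosis"] = (excess_kurtosis(vols)
                                      if len(vols) >= 4 else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def shape_table(df, control: str, length_col="length_um",
                width_col="mid_width_um", strain_col="strain"):
    """Width-on-length regression slope per strain, tested against control.

    Pools all time points per strain (shape is conserved through larval
    development); p values are Bonferroni adjusted by the number of
    non-control strains and capped at 1.
    """
    import pandas as pd

    ctrl = df[df[strain_col] == control]
    strains = [s for s in df[strain_col].unique() if s != control]
    rows = []
    for strain in strains:
        mut = df[df[strain_col] == strain]
        cmp = compare_slopes(ctrl[length_col], ctrl[width_col],
                             mut[length_col], mut[width_col])
        rows.append({strain_col: strain, "slope": cmp.b2,
                     "p": min(cmp.p * max(len(strains), 1), 1.0)})
    c = compare_slopes(ctrl[length_col], ctrl[width_col],
                       ctrl[length_col], ctrl[width_col])
    rows.append({strain_col: control, "slope": c.b1, "p": np.nan})
    return pd.DataFrame(rows)
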