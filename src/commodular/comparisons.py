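"""Statistical comparison of two ordinations as bivariate distributions.

An ordination's taxon loadings on the two latent axes are treated as a sample
from a bivariate distribution.  Two ordinations (e.g. the observed community
versus a randomized null) are compared marginally — per axis, the means by a
pooled-variance t test and the variances by a two-sided variance-ratio F test
— after checking approximate normality with the Shapiro-Wilk test.  The four
resulting p-values (2 axes x {mean, variance}) are combined by Fisher's
method into a single chi-square on 8 degrees of freedom.  The correlation
between the two axes within each ordination is tested and cross-compared on
Fisher's z scale.  An eigenvalue profile of the taxa correlation matrix
summarizes how concentrated the community's covariation is on a few axes.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CommunityMatrix

__all__ = [
    "MarginalSummary",
    "ComparisonReport",
    "shapiro_wilk",
    "pooled_t_test",
    "variance_ratio_test",
    "fisher_combine",
    "fisher_z_test",
    "fisher_z_compare",
    "eigen_profile",
    "compare_ordinations",
]


@dataclass
class MarginalSummary:
    """Mean/variance of one axis's loadings plus its Shapiro-Wilk normality check."""

    mean: float
    variance: float
    n: int
    shapiro_W: float
    shapiro_p: float


def shapiro_wilk(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value for a univariate sample."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pooled_t_test(mean1: float, var1: float, n1: int, mean2: float, var2: float,
                  n2: int, df_mode: str = "per-sample") -> tuple[float, float]:
    """Two-sample t test on summary statistics with pooled variance.

    Returns the magnitude |t| with the two-sided p-value (the direction of
    the difference carries no meaning for the bivariate-distribution
    comparison, and reports conventionally print the magnitude).

    df_mode 'per-sample' uses n1 - 1 degrees of freedom (the convention under
    which published t_35 values for two groups of 36 back-calculate);
    'standard' uses the textbook n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if var1 < 0 or var2 < 0:
        raise ValueError("variances must be non-negative")
    if df_mode == "per-sample":
        df = n1 - 1
    elif df_mode == "standard":
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown df_mode {df_mode!r}")
    s2p = ((n1 - 1) * var1 + (n2 - 1) * var2) / (n1 + n2 - 2)
    se = math.sqrt(s2p * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = abs(mean1 - mean2) / se
    p = 2.0 * stats.t.sf(t, df)
    return float(t), float(min(p, 1.0))


def variance_ratio_test(var1: float, n1: int, var2: float, n2: int) -> tuple[float, float]:
    """Variance-ratio F = var1/var2 with a two-sided p-value.

    Degrees of freedom (n1 - 1, n2 - 1); the two-sided p doubles the smaller
    tail and is invariant to swapping the two variances.
    """
    if var2 <= 0:
        raise ValueError("var2 must be positive")
    if var1 < 0:
        raise ValueError("var1 must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    F = var1 / var2
    dist = stats.f(n1 - 1, n2 - 1)
    p = 2.0 * min(dist.sf(F), dist.cdf(F))
    return float(F), float(min(p, 1.0))


def fisher_combine(pvalues) -> tuple[float, int, float]:
    """Fisher's method: chi2 = -2 sum(ln p) on 2m degrees of freedom."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return chi2, df, float(stats.chi2.sf(chi2, df))


def fisher_z_test(r: float, n: int) -> tuple[float, float]:
    """Test H0: rho = 0 via Fisher's z-transformation, z = atanh(r) * sqrt(n-3)."""
    if abs(r) >= 1:
        raise ValueError("|r| must be < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    z = math.atanh(r) * math.sqrt(n - 3)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Test H0: rho1 = rho2 for two independent correlations on the z scale."""
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1:
            raise ValueError("|r| must be < 1")
        if n < 4:
            raise ValueError("need n >= 4")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def eigen_profile(cm: CommunityMatrix | np.ndarray) -> np.ndarray:
    """Descending eigenvalues of the taxa x taxa Pearson correlation matrix.

    The trace equals the number of taxa; a community whose covariation is
    concentrated on few axes shows a steep leading drop, a random assemblage
    stays near 1 throughout.
    """
    counts = cm.counts if isinstance(cm, CommunityMatrix) else np.asarray(cm, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 taxa")
    sd = counts.std(axis=0)
    if (sd == 0).any():
        j = int(np.flatnonzero(sd == 0)[0])
        name = cm.taxon_ids[j] if isinstance(cm, CommunityMatrix) else str(j)
        raise ValueError(f"constant column, correlation undefined: {name!r}")
    R = np.corrcoef(counts, rowvar=False)
    vals = np.linalg.eigvalsh(R)
    return vals[::-1].copy()


@dataclass
class ComparisonReport:
    """The full marginal + correlation battery comparing two loading sets."""

    marginals_a: list[MarginalSummary]
    marginals_b: list[MarginalSummary]
    t_stats: list[float]
    t_pvalues: list[float]
    f_stats: list[float]
    f_pvalues: list[float]
    combined_chi2: float
    combined_df: int
    combined_p: float
    r_a: float
    r_a_z: float
    r_a_p: float
    r_b: float
    r_b_z: float
    r_b_p: float
    compare_z: float
    compare_p: float
    normality_warning: bool

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = asdict(self)
        path.write_text(json.dumps(d, indent=1))
        return path

    def to_table(self) -> pd.DataFrame:
        """Table-1-shaped layout: one row per (set, axis)."""
        rows = []
        for name, margs in (("A", self.marginals_a), ("B", self.marginals_b)):
            for lv, m in enumerate(margs, start=1):
                row = {"set": name, "axis": f"LV{lv}", "mean": m.mean,
                       "variance": m.variance, "W": m.shapiro_W, "W_p": m.shapiro_p}
                if name == "B":
                    row.update({"t": self.t_stats[lv - 1], "t_p": self.t_pvalues[lv - 1],
                                "F": self.f_stats[lv - 1], "F_p": self.f_pvalues[lv - 1]})
                    if lv == 1:
                        row.update({"chi2": self.combined_chi2, "chi2_p": self.combined_p})
                rows.append(row)
        return pd.DataFrame(rows)


def compare_ordinations(loadings_a: np.ndarray, loadings_b: np.ndarray,
                        df_mode: str = "per-sample") -> ComparisonReport:
    """Compare two 2-axis loading sets as bivariate normal distributions.

    Per axis: Shapiro-Wilk on each marginal, pooled-variance t test on the
    means, variance-ratio F test on the variances; the four mean/variance
    p-values combine by Fisher's method (chi-square, df 8).  Within-set
    axis correlations are tested against 0 and against each other on
    Fisher's z scale.  Normality is reported, not enforced: a warning is
    issued if any marginal rejects at 0.05 but the battery still runs.
    """
    A = np.asarray(loadings_a, dtype=float)
    B = np.asarray(loadings_b, dtype=float)
    for name, X in (("loadings_a", A), ("loadings_b", B)):
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError(f"{name} must have exactly 2 columns, got shape {X.shape}")

    def summarize(X):
        out = []
        for col in X.T:
            W, p = shapiro_wilk(col)
            out.append(MarginalSummary(mean=float(col.mean()),
                                       variance=float(col.var(ddof=1)),
                                       n=len(col), shapiro_W=W, shapiro_p=p))
        return out

    ma, mb = summarize(A), summarize(B)
    norm_warn = any(m.shapiro_p < 0.05 for m in ma + mb)
    if norm_warn:
        warnings.warn("a marginal distribution rejects normality at 0.05; "
                      "the bivariate-normal comparison may be approximate", stacklevel=2)

    t_stats, t_ps, f_stats, f_ps = [], [], [], []
    for a, b in zip(ma, mb):
        t, tp = pooled_t_test(a.mean, a.variance, a.n, b.mean, b.variance, b.n, df_mode=df_mode)
        F, fp = variance_ratio_test(a.variance, a.n, b.variance, b.n)
        t_stats.append(t); t_ps.append(tp); f_stats.append(F); f_ps.append(fp)

    chi2, df, comb_p = fisher_combine([max(p, 1e-300) for p in t_ps + f_ps])

    def corr_block(X):
        r = float(np.corrcoef(X[:, 0], X[:, 1])[0, 1])
        r = float(np.clip(r, -0.999999, 0.999999))
        z, p = fisher_z_test(r, X.shape[0])
        return r, z, p

    ra, za, pa = corr_block(A)
    rb, zb, pb = corr_block(B)
    cz, cp = fisher_z_compare(ra, A.shape[0], rb, B.shape[0])

    return ComparisonReport(
        marginals_a=ma, marginals_b=mb,
        t_stats=t_stats, t_pvalues=t_ps, f_stats=f_stats, f_pvalues=f_ps,
        combined_chi2=chi2, combined_df=df, combined_p=comb_p,
        r_a=ra, r_a_z=za, r_a_p=pa, r_b=rb, r_b_z=zb, r_b_p=pb,
        compare_z=cz, compare_p=cp, normality_warning=norm_warn,
    )
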