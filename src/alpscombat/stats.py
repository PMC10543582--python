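"""Effect sizes, group tests, ANOVA and power for harmonization evaluation.

Cohen's d here uses the pooled scale S_c = sqrt((n1·s1² + n2·s2²)/(n1 + n2))
with per-group s the usual 1/(n−1) sample SD — i.e. the group variances are
weighted by group size and the sum divided by the total n, not n1+n2−2.  This
convention, used throughout the study design this package supports, differs
slightly from Hedges' pooled SD for small samples; the difference vanishes as
n grows.  d is reported as an absolute (non-negative) standardized difference.

Power for the two-group comparison uses the exact noncentral-t formulation:
for a two-sided level-alpha test with df = n1+n2−2 and noncentrality
ncp = d·sqrt(n1·n2/(n1+n2)),

    power = 1 − F_nct(t_crit; df, ncp) + F_nct(−t_crit; df, ncp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison: Welch's t and the pooled-scale Cohen's d."""

    label_1: str
    label_2: str
    n_1: int
    n_2: int
    mean_1: float
    mean_2: float
    sd_1: float
    sd_2: float
    cohen_d: float
    welch_t: float
    welch_dof: float
    p_value: float


@dataclass(frozen=True)
class AnovaResult:
    """Per-factor F, p and partial eta² from a Type-II GLM ANOVA."""

    table: pd.DataFrame  # index: factor; columns: F, p_value, partial_eta_sq, df
    residual_dof: float


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    p_value: float


@dataclass(frozen=True)
class PowerResult:
    d: float
    n_1: int
    n_2: int
    alpha: float
    power: float
    target_power: float | None = None


def _as_sample(x, name: str, min_n: int = 2) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {x.size}")
    if not np.isfinite(x).all():
        raise ValueError(f"{name} contains non-finite values")
    return x


def cohens_d(values_1, values_2) -> float:
    """Absolute standardized mean difference with the n-weighted pooled scale.

    S_c = sqrt((n1·s1² + n2·s2²)/(n1+n2)) with s the 1/(n−1) sample SD;
    d = |x̄1 − x̄2| / S_c.
    """
    x1 = _as_sample(values_1, "values_1")
    x2 = _as_sample(values_2, "values_2")
    n1, n2 = x1.size, x2.size
    s1, s2 = x1.std(ddof=1), x2.std(ddof=1)
    sc = np.sqrt((n1 * s1**2 + n2 * s2**2) / (n1 + n2))
    diff = abs(x1.mean() - x2.mean())
    if sc == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: d is infinite")
    return float(diff / sc)


def welch_t(values_1, values_2, label_1: str = "1", label_2: str = "2") -> GroupComparison:
    """Welch's unequal-variance t test with Welch–Satterthwaite dof."""
    x1 = _as_sample(values_1, "values_1")
    x2 = _as_sample(values_2, "values_2")
    n1, n2 = x1.size, x2.size
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        if x1.mean() == x2.mean():
            t, dof, p = 0.0, float(n1 + n2 - 2), 1.0
        else:
            raise ValueError("zero variance in both groups with unequal means")
    else:
        res = sps.ttest_ind(x1, x2, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        se1, se2 = v1 / n1, v2 / n2
        dof = float(
            (se1 + se2) ** 2 / (se1**2 / (n1 - 1) + se2**2 / (n2 - 1))
        )
    return GroupComparison(
        label_1=label_1,
        label_2=label_2,
        n_1=n1,
        n_2=n2,
        mean_1=float(x1.mean()),
        mean_2=float(x2.mean()),
        sd_1=float(np.sqrt(v1)),
        sd_2=float(np.sqrt(v2)),
        cohen_d=cohens_d(x1, x2),
        welch_t=t,
        welch_dof=dof,
        p_value=p,
    )


def pearson_r(x, y, var_x: str = "x", var_y: str = "y") -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p value."""
    xa = _as_sample(x, var_x, min_n=3)
    ya = _as_sample(y, var_y, min_n=3)
    if xa.size != ya.size:
        raise ValueError(f"{var_x} and {var_y} differ in length")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    res = sps.pearsonr(xa, ya)
    return CorrelationResult(
        var_x=var_x, var_y=var_y, n=xa.size, r=float(res.statistic), p_value=float(res.pvalue)
    )


def glm_anova(table: pd.DataFrame, outcome: str, factors=("scanner", "age", "group")) -> AnovaResult:
    """GLM ANOVA of an outcome on scanner, age and group (Type II SS).

    Categorical factors (non-numeric columns) are treated as such; partial
    eta² = SS_factor / (SS_factor + SS_residual).  Every categorical level
    must have at least two observations.
    """
    df = table[[outcome, *factors]].copy()
    terms = []
    for f in factors:
        if pd.api.types.is_numeric_dtype(df[f]):
            terms.append(f)
        else:
            counts = df[f].value_counts()
            small = counts[counts < 2]
            if len(small):
                raise ValueError(
                    f"factor {f!r} has levels with < 2 observations: {dict(small)}"
                )
            terms.append(f"C({f})")
    model = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(aov.loc["Residual", "sum_sq"])
    rows = {}
    for f, term in zip(factors, terms):
        ss = float(aov.loc[term, "sum_sq"])
        rows[f] = {
            "F": float(aov.loc[term, "F"]),
            "p_value": float(aov.loc[term, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_resid),
            "df": float(aov.loc[term, "df"]),
        }
    return AnovaResult(
        table=pd.DataFrame(rows).T, residual_dof=float(aov.loc["Residual", "df"])
    )


def power_two_sample(d: float, n_1: int, n_2: int, alpha: float = 0.05) -> PowerResult:
    """Exact two-sided power of the two-group t test via the noncentral t."""
    if d < 0:
        raise ValueError("effect size d must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_1 < 2 or n_2 < 2:
        raise ValueError("need n >= 2 per group")
    dof = n_1 + n_2 - 2
    ncp = d * np.sqrt(n_1 * n_2 / (n_1 + n_2))
    t_crit = sps.t.ppf(1 - alpha / 2, dof)
    power = float(1 - sps.nct.cdf(t_crit, dof, ncp) + sps.nct.cdf(-t_crit, dof, ncp))
    return PowerResult(d=d, n_1=n_1, n_2=n_2, alpha=alpha, power=power)


def sample_size_for_power(
    d: float,
    target_power: float = 0.80,
    alpha: float = 0.05,
    allocation_ratio: float = 1.0,
) -> PowerResult:
    """Smallest group sizes reaching the target power at a given allocation.

    ``allocation_ratio`` = n2/n1.  n1 is increased from 2 until the exact
    noncentral-t power with n2 = ceil(ratio·n1) (at least 2) reaches the
    target; power is monotone in both sizes so the first hit is minimal.
    """
    if d <= 0:
        raise ValueError("effect size d must be > 0 to size a study")
    if not alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")
    if allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be > 0")
    n1 = 2
    while True:
        n2 = max(2, int(np.ceil(allocation_ratio * n1)))
        res = power_two_sample(d, n1, n2, alpha)
        if res.power >= target_power:
            return PowerResult(
                d=d, n_1=n1, n_2=n2, alpha=alpha, power=res.power,
                target_power=target_power,
            )
        n1 += 1
        if n1 > 10_000_000:  # pragma: no cover - d>0 guarantees termination
            raise RuntimeError("sample-size search failed to terminate")


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p values (optional extra for correlation tables)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
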