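"""Screening statistics: two-group tests, ANOVA + Dunnett, chi-squared,
and 4PL dose-response fitting.

Conventions: alpha = 0.05, two-sided tests, 95% confidence intervals.
"Student's t-test" uses the classical pooled-variance form (Welch available
by flag); Pearson's chi-squared is computed without Yates continuity
correction; Dunnett's many-to-one comparisons use the equal-correlation
multivariate-t distribution.  The dose-response model is the four-parameter
logistic ``y = bottom + (top - bottom) / (1 + (x / IC50)^h)`` fitted by
least squares in log-dose space, with parameter standard errors from the
Jacobian at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = ["StatTestResult", "DunnettComparison", "AnovaDunnettResult",
           "DoseResponseFit", "t_test", "anova_dunnett", "chi_squared",
           "fit_4pl", "four_pl"]

from .synthplate import four_pl  # re-exported: the model the simulator uses


@dataclass(frozen=True)
class StatTestResult:
    """Outcome of one hypothesis test on the reported scale."""

    test: str
    statistic: float
    df: float
    p: float
    mean_difference: Optional[float] = None
    ci95_low: Optional[float] = None
    ci95_high: Optional[float] = None
    n: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if (self.mean_difference is not None and self.ci95_low is not None
                and not (self.ci95_low <= self.mean_difference
                         <= self.ci95_high)):
            raise ValueError("CI must bracket the mean difference")


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

def t_test(group_a: Sequence[float], group_b: Sequence[float],
           paired: bool = False, equal_var: bool = True) -> StatTestResult:
    """Two-sided t-test of ``group_a`` vs ``group_b``.

    Unpaired tests default to the classical pooled-variance Student form;
    ``equal_var=False`` selects Welch.  The mean difference is
    ``mean(a) - mean(b)`` with its 95% CI.  Degenerate inputs are resolved
    explicitly: identical constant groups give t = 0, p = 1; a constant
    nonzero paired shift gives p -> 0 with a degenerate CI at the shift.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired and a.size != b.size:
        raise ValueError("paired test requires equal group sizes")
    name = ("paired t-test" if paired
            else "student t-test" if equal_var else "welch t-test")

    if paired:
        d = a - b
        diff = float(d.mean())
        if d.std(ddof=1) == 0:
            p, stat = (1.0, 0.0) if diff == 0 else (0.0, np.inf * np.sign(diff))
            return StatTestResult(name, float(stat), float(a.size - 1), p,
                                  diff, diff, diff, (a.size, b.size))
        res = stats.ttest_rel(a, b)
        ci = res.confidence_interval(0.95)
        return StatTestResult(name, float(res.statistic), float(res.df),
                              float(res.pvalue), diff,
                              float(ci.low), float(ci.high),
                              (a.size, b.size))

    diff = float(a.mean() - b.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if diff == 0:
            df = float(a.size + b.size - 2)
            return StatTestResult(name, 0.0, df, 1.0, 0.0, 0.0, 0.0,
                                  (a.size, b.size))
        return StatTestResult(name, np.inf * np.sign(diff),
                              float(a.size + b.size - 2), 0.0,
                              diff, diff, diff, (a.size, b.size))
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    ci = res.confidence_interval(0.95)
    return StatTestResult(name, float(res.statistic), float(res.df),
                          float(res.pvalue), diff,
                          float(ci.low), float(ci.high), (a.size, b.size))


# ---------------------------------------------------------------------------
# one-way ANOVA + Dunnett
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DunnettComparison:
    """One treatment-vs-control comparison with Dunnett-adjusted p."""

    label: str
    mean_difference: float
    statistic: float
    p_adjusted: float
    ci95_low: float
    ci95_high: float


@dataclass(frozen=True)
class AnovaDunnettResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_anova: float
    comparisons: Tuple[DunnettComparison, ...]


def anova_dunnett(groups: Mapping[str, Sequence[float]], control: str,
                  rng: Optional[np.random.Generator] = None
                  ) -> AnovaDunnettResult:
    """One-way ANOVA followed by Dunnett's many-to-one comparisons.

    Every non-control group is compared against ``control``; adjusted
    p-values and simultaneous 95% CIs come from the max-|t| equal-correlation
    multivariate-t distribution.  ``rng`` seeds the numerical evaluation of
    that distribution, making results reproducible to its integration
    tolerance.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    labels = [k for k in arrays if k != control]
    ctrl = arrays[control]
    n_total = sum(v.size for v in arrays.values())
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0:  # all observations identical
        comps = tuple(DunnettComparison(lab, 0.0, 0.0, 1.0, 0.0, 0.0)
                      for lab in labels)
        return AnovaDunnettResult(0.0, df_between, df_within, 1.0, comps)

    f_stat, p_anova = stats.f_oneway(*arrays.values())
    res = stats.dunnett(*(arrays[lab] for lab in labels), control=ctrl,
                        rng=rng)
    ci = res.confidence_interval(0.95)
    comps = tuple(
        DunnettComparison(
            label=lab,
            mean_difference=float(arrays[lab].mean() - ctrl.mean()),
            statistic=float(res.statistic[i]),
            p_adjusted=float(min(1.0, res.pvalue[i])),
            ci95_low=float(ci.low[i]), ci95_high=float(ci.high[i]))
        for i, lab in enumerate(labels))
    return AnovaDunnettResult(float(f_stat), df_between, df_within,
                              float(p_anova), comps)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi_squared(table: Sequence[Sequence[int]]) -> StatTestResult:
    """Pearson chi-squared on a contingency table, no continuity correction.

    Counts must be non-negative integers with every row and column margin
    positive (df = 1 for a 2x2 table).
    """
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("table must be 2-D")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("every row and column margin must be > 0")
    res = stats.chi2_contingency(arr, correction=False)
    return StatTestResult("pearson chi-squared", float(res.statistic),
                          float(res.dof), float(res.pvalue),
                          n=tuple(int(x) for x in arr.sum(axis=1)))


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters with standard errors (reported as value +/- SE)."""

    ic50_nM: float
    ic50_se_nM: float
    hill_slope: float
    hill_se: float
    top: float
    top_se: float
    bottom: float
    bottom_se: float
    rss: float
    converged: bool
    notes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not self.ic50_nM > 0:
            raise ValueError("converged fit must have IC50 > 0")


def fit_4pl(doses_nM: Sequence[float], responses: Sequence[float],
            expected_direction: str = "decreasing") -> DoseResponseFit:
    """Least-squares 4PL fit of response (e.g. % of control) vs dose (nM).

    The curve is fitted in log10-dose space with parameters
    (top, bottom, log10 IC50, Hill slope); the IC50 standard error follows
    from the log-IC50 error by the delta method.  At least 4 distinct
    positive doses are required (one observation per replicate; pass
    replicates as repeated dose entries).  Non-convergence is reported via
    ``converged=False`` and ``notes`` — never silently.  A fitted Hill slope
    whose sign contradicts ``expected_direction`` ('decreasing' responses
    have h > 0 in this parameterization) is flagged in ``notes``.
    """
    x = np.asarray(doses_nM, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.shape != y.shape:
        raise ValueError("doses and responses differ in length")
    if np.any(x <= 0):
        raise ValueError("doses must be > 0")
    if np.unique(x).size < 4:
        raise ValueError("need >= 4 distinct doses")
    logx = np.log10(x)

    def model(lx, top, bottom, log_ic50, hill):
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (lx - log_ic50)))

    slope_sign = 1.0 if np.corrcoef(logx, y)[0, 1] < 0 else -1.0
    p0 = (float(y.max()), float(y.min()), float(np.median(logx)), slope_sign)
    notes: List[str] = []
    try:
        with warnings.catch_warnings():
            # an inestimable covariance is reported via `notes` below
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(model, logx, y, p0=p0,
                                            maxfev=20000)
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError as exc:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan,
                               np.nan, np.nan, np.nan, np.nan, False,
                               (f"optimizer failed: {exc}",))
    top, bottom, log_ic50, hill = popt
    with np.errstate(invalid="ignore"):
        perr = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(perr)):
        notes.append("singular Jacobian: standard errors unreliable")
    ic50 = 10.0 ** log_ic50
    ic50_se = np.log(10.0) * ic50 * perr[2]
    rss = float(np.sum((y - model(logx, *popt)) ** 2))
    expected_sign = 1.0 if expected_direction == "decreasing" else -1.0
    if np.sign(hill) != expected_sign:
        notes.append(
            f"fitted Hill slope {hill:.3g} contradicts the expected "
            f"{expected_direction} dose-response direction")
    return DoseResponseFit(
        ic50_nM=float(ic50), ic50_se_nM=float(ic50_se),
        hill_slope=float(hill), hill_se=float(perr[3]),
        top=float(top), top_se=float(perr[0]),
        bottom=float(bottom), bottom_se=float(perr[1]),
        rss=rss, converged=converged, notes=tuple(notes))
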