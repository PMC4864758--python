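"""Inferential battery: paired t, pooled two-sample t, 2x2 mixed ANOVA.

All p-values are two-sided.  Effect sizes follow the conventions of the
adolescent slant-integration study this pipeline models: Cohen's d for a
paired test is |t| / sqrt(n), the two-sample tests are pooled-variance
Student (df = n1 + n2 - 2), and ANOVA effects are reported as partial eta
squared F * df1 / (F * df1 + df2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateDataError, InvalidSpecificationError

__all__ = [
    "PairedTestResult",
    "TwoSampleResult",
    "AnovaResult",
    "paired_t",
    "cohens_d_from_t",
    "two_sample_pooled_t",
    "two_sample_pooled_t_from_data",
    "mixed_anova_2x2",
    "anova_ss_decomposition",
    "partial_eta_sq",
    "dual_test_alpha",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    cohens_d: float


@dataclass(frozen=True)
class TwoSampleResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired t-test on x - y with Cohen's d = |t| / sqrt(n).

    A difference vector that is identically zero yields t = 0, p = 1 (the
    samples are equal); a nonzero constant difference has zero variance and
    an undefined (infinite) statistic, flagged as degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise InvalidSpecificationError("x and y must be equal-length vectors, n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, cohens_d=0.0)
        raise DegenerateDataError("constant nonzero difference vector (infinite t)")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return PairedTestResult(t=float(t), df=n - 1, p=float(p),
                            cohens_d=cohens_d_from_t(t, n))


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-test effect size |t| / sqrt(n)."""
    if n < 2:
        raise InvalidSpecificationError("n must be >= 2")
    return abs(t) / math.sqrt(n)


def two_sample_pooled_t(m1: float, sd1: float, n1: int,
                        m2: float, sd2: float, n2: int) -> TwoSampleResult:
    """Pooled-variance Student t from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise InvalidSpecificationError("both groups need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidSpecificationError("standard deviations must be > 0")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(pooled_var * (1 / n1 + 1 / n2))
    t = (m1 - m2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TwoSampleResult(t=float(t), df=df, p=float(p))


def two_sample_pooled_t_from_data(x, y) -> TwoSampleResult:
    """Same test computed from raw vectors (exactly equals the summary form)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return two_sample_pooled_t(x.mean(), x.std(ddof=1), x.size,
                               y.mean(), y.std(ddof=1), y.size)


def partial_eta_sq(F: float, df1: int, df2: int) -> float:
    """Partial eta squared F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise InvalidSpecificationError("F must be >= 0")
    return F * df1 / (F * df1 + df2)


def dual_test_alpha(alpha: float) -> float:
    """Joint type-I bound for requiring both planned comparisons significant."""
    if not 0 < alpha <= 1:
        raise InvalidSpecificationError("alpha must be in (0, 1]")
    return alpha**2


def mixed_anova_2x2(congruent_scores, incongruent_scores, group_labels):
    """2x2 mixed ANOVA: condition (within, 2 levels) x group (between).

    Computed from the explicit subject-level decomposition rather than an
    opaque model fit: subject means carry the between-subject factor and
    per-subject condition differences carry the within-subject effects.  With
    unequal group sizes the condition contrast is the unweighted mean of the
    group mean differences (the convention of standard factorial ANOVA
    software).  Returns a dict of AnovaResult keyed ``condition``, ``group``,
    ``interaction``; all effects use df1 = 1, df2 = N - 2.
    """
    y1 = np.asarray(congruent_scores, dtype=float)
    y2 = np.asarray(incongruent_scores, dtype=float)
    g = np.asarray(group_labels)
    if not (y1.shape == y2.shape == g.shape) or y1.ndim != 1:
        raise InvalidSpecificationError("inputs must be equal-length vectors")
    levels = np.unique(g)
    if len(levels) != 2:
        raise InvalidSpecificationError("exactly two groups are required")
    n1, n2 = int(np.sum(g == levels[0])), int(np.sum(g == levels[1]))
    if n1 < 2 or n2 < 2:
        raise InvalidSpecificationError("need >= 2 subjects per group")
    N = n1 + n2
    df2 = N - 2

    m = (y1 + y2) / 2.0  # subject means (between-subject part)
    d = y1 - y2          # condition differences (within-subject part)

    # between-subjects: one-way ANOVA on subject means, scaled by 2 conditions
    grand_m = m.mean()
    ss_group = 2 * sum(np.sum(g == lv) * (m[g == lv].mean() - grand_m) ** 2
                       for lv in levels)
    ss_err_between = 2 * sum(np.sum((m[g == lv] - m[g == lv].mean()) ** 2)
                             for lv in levels)
    if ss_err_between == 0 and ss_group != 0:
        raise DegenerateDataError("zero between-subject error variance")
    f_group = 0.0 if ss_group == 0 else (ss_group / 1) / (ss_err_between / df2)

    # within-subjects: pooled variance of the condition differences
    var_d = sum(np.sum((d[g == lv] - d[g == lv].mean()) ** 2)
                for lv in levels) / df2
    d1, d2 = d[g == levels[0]].mean(), d[g == levels[1]].mean()
    # condition: unweighted grand mean of the group differences
    est_c = (d1 + d2) / 2
    # interaction: difference of the group differences
    est_i = d1 - d2
    if var_d == 0 and (est_c != 0 or est_i != 0):
        raise DegenerateDataError("zero within-subject error variance")
    f_cond = 0.0 if est_c == 0 else est_c**2 / (var_d * (1 / n1 + 1 / n2) / 4)
    f_int = 0.0 if est_i == 0 else est_i**2 / (var_d * (1 / n1 + 1 / n2))

    def pack(F):
        F = float(F)
        return AnovaResult(F=F, df1=1, df2=df2, p=float(sps.f.sf(F, 1, df2)),
                           partial_eta_sq=partial_eta_sq(F, 1, df2))

    return {"condition": pack(f_cond), "group": pack(f_group),
            "interaction": pack(f_int)}


def anova_ss_decomposition(congruent_scores, incongruent_scores, group_labels):
    """Sum-of-squares bookkeeping for the mixed design.

    Returns (ss_total, ss_between_subjects, ss_within); the first always
    equals the sum of the other two, which the test-suite asserts as a
    conservation property.
    """
    y1 = np.asarray(congruent_scores, dtype=float)
    y2 = np.asarray(incongruent_scores, dtype=float)
    y = np.concatenate([y1, y2])
    m = (y1 + y2) / 2.0
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    ss_between_subj = 2 * np.sum((m - grand) ** 2)
    ss_within = np.sum((y1 - m) ** 2) + np.sum((y2 - m) ** 2)
    return float(ss_total), float(ss_between_subj), float(ss_within)
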