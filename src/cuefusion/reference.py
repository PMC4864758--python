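"""Published group-level statistics of the adolescent slant-integration study.

The study this package models deposited no participant-level data; what is
recoverable are its printed group statistics.  Each entry here pins a value
that the package's formulas can recompute exactly from other printed numbers,
and serves as a regression fixture (`cuefusion reference-checks`).

Two printed quantities are deliberately absent because they are internally
inconsistent and cannot be reproduced from the printed inputs under any
standard formula: the effect size reported for the ASD congruent
texture comparison (0.39, against |t|/sqrt(n) = 0.69 from its own t and n),
and the two single-cue difference-score t statistics (whose printed t, p and
SDs disagree with each other).  They are excluded rather than chased.
"""

from __future__ import annotations

from . import stats as _stats

__all__ = ["PAIRED_EFFECT_SIZES", "ANOVA_EFFECTS", "GROUP_COMPARISONS",
           "DUAL_TEST_ALPHA", "run_reference_checks"]

#: paired-comparison effect sizes: (label, printed t, n, printed Cohen's d)
PAIRED_EFFECT_SIZES = [
    ("typical T+D+ vs T+", 2.91, 14, 0.78),
    ("typical T+D+ vs D+", 2.96, 14, 0.79),
    ("ASD T+D+ vs D+", 4.84, 16, 1.21),
    ("typical T+D- vs T+", -4.06, 14, 1.09),
    ("typical T+D- vs D-", -2.31, 14, 0.62),
    ("ASD T+D- vs T+", -2.78, 16, 0.70),
]

#: ANOVA effects on integration scores: (label, printed F, df1, df2,
#: printed partial eta squared)
ANOVA_EFFECTS = [
    ("condition", 4.12, 1, 28, 0.13),
    ("group", 1.16, 1, 28, 0.04),
    ("interaction", 0.35, 1, 28, 0.012),
]

#: between-group IQ comparisons from the descriptives table:
#: (label, m1, sd1, n1, m2, sd2, n2, printed |t|, tolerance)
GROUP_COMPARISONS = [
    ("performance IQ", 108.8, 11.9, 16, 113.5, 8.8, 14, 1.21, 0.02),
    ("full-scale IQ", 104.5, 10.7, 16, 116.7, 8.3, 14, 3.44, 0.02),
]

#: the study's dual-test argument: alpha -> joint type-I bound
DUAL_TEST_ALPHA = (0.05, 0.0025)

#: group-mean worked example for the congruent integration score:
#: d'(T+D+), d'(T+), d'(D+) -> score (best single cue is D+)
CONGRUENT_SCORE_EXAMPLE = (2.23, 1.37, 1.43, 0.80)


def run_reference_checks() -> list[dict]:
    """Recompute every pinned statistic; returns one record per check."""
    records = []

    def add(name, computed, expected, tol):
        records.append({"name": name, "computed": float(computed),
                        "expected": float(expected), "tolerance": float(tol),
                        "passed": bool(abs(computed - expected) <= tol + 1e-9)})

    for label, t, n, d in PAIRED_EFFECT_SIZES:
        add(f"cohens_d {label}", _stats.cohens_d_from_t(t, n), d, 0.005)
    for label, F, df1, df2, eta in ANOVA_EFFECTS:
        ndec = 3 if eta < 0.1 else 2
        add(f"partial_eta_sq {label}", _stats.partial_eta_sq(F, df1, df2),
            eta, 0.5 * 10**-ndec)
    for label, m1, s1, n1, m2, s2, n2, t_abs, tol in GROUP_COMPARISONS:
        res = _stats.two_sample_pooled_t(m1, s1, n1, m2, s2, n2)
        add(f"pooled_t {label}", abs(res.t), t_abs, tol)
    add("dual_test_alpha", _stats.dual_test_alpha(DUAL_TEST_ALPHA[0]),
        DUAL_TEST_ALPHA[1], 1e-12)
    tdp, tp, dp, score = CONGRUENT_SCORE_EXAMPLE
    add("congruent integration score (group means)", tdp - max(tp, dp),
        score, 0.005)
    return records
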