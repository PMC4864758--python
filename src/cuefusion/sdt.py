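"""Signal-detection scoring of same-different trial tables.

"Different" is treated as the signal response: a hit is responding
"different" on a truly different trial, a false alarm is responding
"different" on a truly same trial, and d' = z(H) - z(FA).  The task design
yields 15 signal and 15 noise trials per condition, so extreme proportions
are common; the log-linear correction (add 0.5 to each count, 1 to each
denominator) is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import stats as _stats
from .exceptions import (DataError, DegenerateDataError, IncompleteDataError,
                         InvalidSpecificationError)
from .observer import ANALYZED_CONDITIONS, CONDITIONS, TrialRecord

__all__ = [
    "ConditionScores",
    "IntegrationScores",
    "CueDifferenceScores",
    "compute_dprime",
    "score_subject",
    "score_table",
    "apply_exclusions",
    "integration_scores",
    "cue_difference_scores",
    "classify_fusion_pattern",
    "trials_to_dataframe",
]

#: single-cue conditions to which the at-or-below-chance exclusion applies
EXCLUSION_CONDITIONS = ("T+", "D-", "D+")

TRIAL_COLUMNS = ["subject_id", "group", "condition", "trial", "truth", "response"]


@dataclass
class ConditionScores:
    """Per-subject d' by condition, with the underlying trial counts."""

    subject_id: str
    group: str
    dprime: dict  # condition -> d'
    n_signal: dict = field(default_factory=dict)
    n_noise: dict = field(default_factory=dict)

    #: conditions carried but excluded from every analysis
    OUT_OF_ANALYSIS = ("T-",)


@dataclass(frozen=True)
class IntegrationScores:
    """Benefit/cost of cue combination relative to the relevant single cue.

    congruent_score  = d'(T+D+) - max(d'(T+), d'(D+))   (gain if positive)
    incongruent_score = d'(T+D-) - min(d'(T+), d'(D-))  (fusion cost if negative)
    """

    subject_id: str
    congruent_score: float
    incongruent_score: float


@dataclass(frozen=True)
class CueDifferenceScores:
    """Single-cue reliability mismatch: T+ minus the paired D condition."""

    subject_id: str
    congruent_diff: float
    incongruent_diff: float


def compute_dprime(n_hits: int, n_fas: int, n_signal: int, n_noise: int,
                   correction: str = "loglinear") -> float:
    """d' = z(hit rate) - z(false-alarm rate).

    correction="loglinear" adds 0.5 to each count and 1 to each denominator,
    keeping d' finite at perfect or zero rates; "none" applies the raw rates
    (infinite at the extremes).
    """
    if n_signal <= 0 or n_noise <= 0:
        raise InvalidSpecificationError("n_signal and n_noise must be > 0")
    if not (0 <= n_hits <= n_signal and 0 <= n_fas <= n_noise):
        raise InvalidSpecificationError("counts out of range")
    if correction == "loglinear":
        h = (n_hits + 0.5) / (n_signal + 1)
        f = (n_fas + 0.5) / (n_noise + 1)
    elif correction == "none":
        h = n_hits / n_signal
        f = n_fas / n_noise
    else:
        raise InvalidSpecificationError(f"unknown correction {correction!r}")
    return float(norm.ppf(h) - norm.ppf(f))


def trials_to_dataframe(trials) -> pd.DataFrame:
    """Normalise a list of TrialRecord or a DataFrame to the canonical table."""
    if isinstance(trials, pd.DataFrame):
        missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
        if missing:
            raise DataError(f"trial table missing columns: {missing}")
        return trials
    rows = [(t.subject_id, t.group, t.condition, t.trial_index, t.truth, t.response)
            for t in trials]
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _validate_rows(df: pd.DataFrame):
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        i = int(np.flatnonzero(bad_cond.to_numpy())[0])
        raise DataError(f"row {i}: unknown condition {df['condition'].iloc[i]!r}")
    for col in ("truth", "response"):
        bad = ~df[col].isin(("same", "different"))
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"row {i}: invalid {col} {df[col].iloc[i]!r}")


def score_subject(trials, correction: str = "loglinear") -> ConditionScores:
    """Aggregate one subject's trials into per-condition d' scores.

    Order of trials is irrelevant.  Raises IncompleteDataError naming any
    analysed condition with no trials.
    """
    df = trials_to_dataframe(trials)
    _validate_rows(df)
    subjects = df["subject_id"].unique()
    if len(subjects) != 1:
        raise DataError(f"expected one subject, got {list(subjects)}")
    present = set(df["condition"])
    gaps = [c for c in ANALYZED_CONDITIONS if c not in present]
    if gaps:
        raise IncompleteDataError(
            f"subject {subjects[0]!r} missing condition(s): {gaps}")
    dprime, n_sig, n_noise = {}, {}, {}
    for cond, sub in df.groupby("condition"):
        signal = sub["truth"] == "different"
        said_diff = sub["response"] == "different"
        ns, nn = int(signal.sum()), int((~signal).sum())
        if ns == 0 or nn == 0:
            raise IncompleteDataError(
                f"condition {cond}: needs both same and different trials")
        dprime[cond] = compute_dprime(int((signal & said_diff).sum()),
                                      int((~signal & said_diff).sum()),
                                      ns, nn, correction)
        n_sig[cond], n_noise[cond] = ns, nn
    return ConditionScores(subject_id=str(subjects[0]),
                           group=str(df["group"].iloc[0]),
                           dprime=dprime, n_signal=n_sig, n_noise=n_noise)


def score_table(trials, correction: str = "loglinear") -> list[ConditionScores]:
    """Score every subject in a trial table."""
    df = trials_to_dataframe(trials)
    return [score_subject(sub, correction)
            for _, sub in df.groupby("subject_id", sort=True)]


def apply_exclusions(scores: list[ConditionScores]):
    """Drop subjects at or below chance (d' <= 0) on any single-cue condition.

    The rule applies to T+, D- and D+ only; combined-cue performance never
    excludes.  Returns (retained, excluded) where each exclusion is a
    (ConditionScores, reason) pair.
    """
    retained, excluded = [], []
    for s in scores:
        reasons = [f"{c} <= 0" for c in EXCLUSION_CONDITIONS
                   if s.dprime.get(c, np.nan) <= 0]
        if reasons:
            excluded.append((s, "; ".join(reasons)))
        else:
            retained.append(s)
    return retained, excluded


def integration_scores(scores: ConditionScores) -> IntegrationScores:
    """Congruent and incongruent integration scores for one subject."""
    d = scores.dprime
    missing = [c for c in ANALYZED_CONDITIONS if c not in d]
    if missing:
        raise IncompleteDataError(f"missing condition(s): {missing}")
    return IntegrationScores(
        subject_id=scores.subject_id,
        congruent_score=d["T+D+"] - max(d["T+"], d["D+"]),
        incongruent_score=d["T+D-"] - min(d["T+"], d["D-"]))


def cue_difference_scores(scores: ConditionScores) -> CueDifferenceScores:
    """Single-cue difference scores (reliability-mismatch check)."""
    d = scores.dprime
    return CueDifferenceScores(subject_id=scores.subject_id,
                               congruent_diff=d["T+"] - d["D+"],
                               incongruent_diff=d["T+"] - d["D-"])


#: the four planned comparisons: (combined, single, expected direction)
PLANNED_COMPARISONS = (
    ("T+D+", "T+", +1),
    ("T+D+", "D+", +1),
    ("T+D-", "T+", -1),
    ("T+D-", "D-", -1),
)


def planned_comparisons(group_scores: list[ConditionScores], alpha: float = 0.05):
    """Run the four paired comparisons; returns {name: (result, significant)}.

    A comparison counts toward integration only if it is significant at
    ``alpha`` *and* in the predicted direction (combined above singles for
    congruent, below for incongruent).
    """
    out = {}
    for combined, single, sign in PLANNED_COMPARISONS:
        x = np.array([s.dprime[combined] for s in group_scores], dtype=float)
        y = np.array([s.dprime[single] for s in group_scores], dtype=float)
        try:
            res = _stats.paired_t(x, y)
        except DegenerateDataError:
            # constant nonzero difference: direction is certain
            mean_sign = float(np.sign(np.mean(x - y)))
            res = _stats.PairedTestResult(t=mean_sign * np.inf, df=len(x) - 1,
                                          p=0.0, cohens_d=np.inf)
        hit = res.p < alpha and np.sign(np.mean(x - y)) == sign
        out[f"{combined} vs {single}"] = (res, bool(hit))
    return out


def classify_fusion_pattern(group_scores: list[ConditionScores],
                            alpha: float = 0.05) -> str:
    """Map the dual planned-comparison outcomes onto a fusion regime.

    Congruent integration requires *both* T+D+ vs T+ and T+D+ vs D+
    significant with the combined condition higher; incongruent fusion
    requires *both* T+D- vs T+ and T+D- vs D- significant with the combined
    condition lower.  (congruent, incongruent) maps to:
    (yes, yes) mandatory_fusion, (yes, no) selective_fusion,
    (no, no) no_fusion, (no, yes) indeterminate.
    """
    if len(group_scores) < 2:
        raise DegenerateDataError("need at least 2 subjects to classify")
    comps = planned_comparisons(group_scores, alpha)
    congruent = comps["T+D+ vs T+"][1] and comps["T+D+ vs D+"][1]
    incongruent = comps["T+D- vs T+"][1] and comps["T+D- vs D-"][1]
    return {(True, True): "mandatory_fusion",
            (True, False): "selective_fusion",
            (False, False): "no_fusion",
            (False, True): "indeterminate"}[(congruent, incongruent)]
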