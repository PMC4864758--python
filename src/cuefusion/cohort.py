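"""Synthetic study generator: subjects, block schedules, trial tables.

Emulates the study design this package models: two groups of adolescents
(16 and 14 subjects), six conditions of 30 trials each (180 per subject),
comparisons at +/-12.5 deg around a 45 deg standard, half same / half
different, presented in 18 blocks of 10 trials mixing a condition pair
5 + 5.  Subjects draw their single-cue noise levels from a lognormal
population distribution and respond via the coupling-prior observer model,
with the fusion regime fixed per group, so every generated study carries
full ground truth for parameter- and regime-recovery scoring.

Every subject owns an independent RNG stream keyed by (seed, subject index),
so enlarging a cohort never perturbs existing subjects.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InvalidSpecificationError
from .observer import (ANALYZED_CONDITIONS, CONDITIONS, REGIMES, ObserverParams,
                       analytic_dprime, simulate_responses)
from . import sdt

__all__ = [
    "LognormalSpec",
    "CohortSpec",
    "DesignSchedule",
    "Subject",
    "build_schedule",
    "generate_cohort",
    "run_study",
    "simulate_study",
    "ground_truth_record",
    "recovery_report",
]

#: condition pairs mixed within a block (5 trials each)
BLOCK_PAIRS = (("D+", "D-"), ("T+", "T-"), ("T+D+", "T+D-"))
BLOCK_SIZE = 10


@dataclass(frozen=True)
class LognormalSpec:
    """Lognormal population distribution given median and geometric SD."""

    median: float = 4.0
    gsd: float = 1.3

    def __post_init__(self):
        if self.median <= 0 or self.gsd < 1:
            raise InvalidSpecificationError("median must be > 0 and gsd >= 1")

    def sample(self, rng: np.random.Generator, size=None):
        return self.median * np.exp(math.log(self.gsd) * rng.standard_normal(size))


@dataclass(frozen=True)
class CohortSpec:
    """Population and design parameters of one synthetic study."""

    n_per_group: dict = field(default_factory=lambda: {"ASD": 16, "TD": 14})
    regime_by_group: dict = field(default_factory=lambda: {
        "ASD": "selective_fusion", "TD": "mandatory_fusion"})
    sigma_T_dist: LognormalSpec = LognormalSpec()
    sigma_D_dist: LognormalSpec = LognormalSpec()
    trials_per_condition: int = 30
    criterion: float = 6.25
    gate_k: float = 2.0
    lapse_rate: float = 0.0
    no_fusion_rule: str = "switch"
    seed: int = 0

    def __post_init__(self):
        for g, n in self.n_per_group.items():
            if n < 1:
                raise InvalidSpecificationError(f"group {g}: n must be >= 1")
            if self.regime_by_group.get(g) not in REGIMES:
                raise InvalidSpecificationError(f"group {g}: missing/unknown regime")
        if self.trials_per_condition % 2 or self.trials_per_condition <= 0:
            raise InvalidSpecificationError("trials_per_condition must be positive and even")

    def observer_params(self, sigma_T: float, sigma_D: float, regime: str
                        ) -> ObserverParams:
        sigma_c = math.inf if regime == "no_fusion" else 0.0
        return ObserverParams(sigma_T=sigma_T, sigma_D=sigma_D, sigma_c=sigma_c,
                              criterion_c=self.criterion, regime=regime,
                              gate_k=self.gate_k, lapse_rate=self.lapse_rate,
                              no_fusion_rule=self.no_fusion_rule)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    group: str
    regime: str
    params: ObserverParams
    stream_key: tuple  # SeedSequence entropy for this subject


@dataclass(frozen=True)
class DesignSchedule:
    """Ordered blocks of (condition, truth) trials."""

    blocks: tuple  # tuple of tuples of (condition, truth)

    @property
    def trials(self) -> list:
        return [t for b in self.blocks for t in b]

    def counts(self) -> pd.DataFrame:
        df = pd.DataFrame(self.trials, columns=["condition", "truth"])
        return df.value_counts(["condition", "truth"]).unstack()


def build_schedule(spec: CohortSpec, rng: np.random.Generator) -> DesignSchedule:
    """Randomised block schedule honouring the 5+5 pair structure.

    Each condition contributes trials_per_condition trials, half same and
    half different, dealt 5 per block into blocks that mix the condition with
    its designated pair; block order and within-block order are randomised
    while the per-condition same/different balance is preserved exactly.
    """
    tpc = spec.trials_per_condition
    if tpc % 5 or (tpc // 5) % 2:
        raise InvalidSpecificationError(
            "trials_per_condition must be divisible by 5 with an even block count")
    per_cond = {}
    for cond in CONDITIONS:
        labels = ["same"] * (tpc // 2) + ["different"] * (tpc // 2)
        rng.shuffle(labels)
        per_cond[cond] = labels
    blocks = []
    for a, b in BLOCK_PAIRS:
        for i in range(tpc // 5):
            chunk = ([(a, t) for t in per_cond[a][i * 5:(i + 1) * 5]]
                     + [(b, t) for t in per_cond[b][i * 5:(i + 1) * 5]])
            rng.shuffle(chunk)
            blocks.append(tuple(chunk))
    order = rng.permutation(len(blocks))
    return DesignSchedule(blocks=tuple(blocks[i] for i in order))


def _subject_key(subject_id: str) -> int:
    """Stable 63-bit stream key from the subject id (not list position), so
    growing a cohort never reseeds existing subjects."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int.from_bytes(digest[:8], "little") >> 1


def _subject_rng(spec_seed: int, key: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, key, purpose)))


def generate_cohort(spec: CohortSpec, rng=None) -> list[Subject]:
    """Draw subjects with per-group regimes and lognormal cue noise.

    ``rng`` may override the per-subject seeding for exploratory use; by
    default each subject's parameters come from their own (seed, index)
    stream.
    """
    cohort = []
    for group in sorted(spec.n_per_group):
        regime = spec.regime_by_group[group]
        for k in range(spec.n_per_group[group]):
            subject_id = f"{group}{k + 1:02d}"
            key = _subject_key(subject_id)
            r = rng if rng is not None else _subject_rng(spec.seed, key, 0)
            sigma_t = float(spec.sigma_T_dist.sample(r))
            sigma_d = float(spec.sigma_D_dist.sample(r))
            cohort.append(Subject(
                subject_id=subject_id, group=group, regime=regime,
                params=spec.observer_params(sigma_t, sigma_d, regime),
                stream_key=(spec.seed, key)))
    return cohort


def run_study(cohort: list[Subject], spec: CohortSpec,
              schedule: DesignSchedule | None = None) -> pd.DataFrame:
    """Simulate every subject through the block design.

    Each subject runs their own randomised schedule (pass ``schedule`` to
    share one).  Responses are simulated per condition from the subject's
    response stream; the returned table has one row per subject x trial in
    session order.
    """
    rows = []
    for subj in cohort:
        sched_rng = _subject_rng(*subj.stream_key, 1)
        resp_rng = _subject_rng(*subj.stream_key, 2)
        sched = schedule if schedule is not None else build_schedule(spec, sched_rng)
        trials = sched.trials
        # simulate condition-wise (vectorised), then scatter back to session order
        responses = [None] * len(trials)
        for cond in CONDITIONS:
            idx = [i for i, (c, _) in enumerate(trials) if c == cond]
            truth = np.array([trials[i][1] == "different" for i in idx])
            resp = simulate_responses(subj.params, cond, truth, resp_rng)
            for i, r in zip(idx, resp):
                responses[i] = "different" if r else "same"
        for i, (cond, truth) in enumerate(trials):
            rows.append((subj.subject_id, subj.group, cond, i + 1, truth,
                         responses[i]))
    return pd.DataFrame(rows, columns=sdt.TRIAL_COLUMNS)


def ground_truth_record(cohort: list[Subject]) -> dict:
    """Sidecar ground truth (per-subject parameters and regime) for recovery."""
    return {s.subject_id: {
        "group": s.group, "regime": s.regime,
        "sigma_T": s.params.sigma_T, "sigma_D": s.params.sigma_D,
        "sigma_c": s.params.sigma_c if math.isfinite(s.params.sigma_c) else "inf",
        "criterion": s.params.criterion_c, "gate_k": s.params.gate_k,
        "lapse_rate": s.params.lapse_rate,
    } for s in cohort}


def simulate_study(spec: CohortSpec):
    """Full study: cohort, trial table, ground truth.  Deterministic in seed."""
    cohort = generate_cohort(spec)
    table = run_study(cohort, spec)
    return cohort, table, ground_truth_record(cohort)


# --------------------------------------------------------------------------
# regime recovery
# --------------------------------------------------------------------------

def _simulate_group_scores(subjects: list[Subject], tpc: int, rep: int
                           ) -> list[sdt.ConditionScores]:
    """Condition-wise simulation and scoring, bypassing the block schedule.

    Responses are trial-wise independent, so for scoring purposes the block
    structure is irrelevant; this keeps large recovery grids cheap.
    """
    scores = []
    for subj in subjects:
        rng = _subject_rng(*subj.stream_key, 100 + rep)
        dprime, n_sig, n_noise = {}, {}, {}
        for cond in ANALYZED_CONDITIONS:
            truth = np.zeros(tpc, dtype=bool)
            truth[tpc // 2:] = True
            resp = simulate_responses(subj.params, cond, truth, rng)
            hits = int(np.sum(resp[truth]))
            fas = int(np.sum(resp[~truth]))
            dprime[cond] = sdt.compute_dprime(hits, fas, tpc // 2, tpc // 2)
            n_sig[cond] = n_noise[cond] = tpc // 2
        scores.append(sdt.ConditionScores(subject_id=subj.subject_id,
                                          group=subj.group, dprime=dprime,
                                          n_signal=n_sig, n_noise=n_noise))
    return scores


def _analytic_group_scores(subjects: list[Subject]) -> list[sdt.ConditionScores]:
    return [sdt.ConditionScores(
        subject_id=s.subject_id, group=s.group,
        dprime={c: analytic_dprime(s.params, c) for c in ANALYZED_CONDITIONS})
        for s in subjects]


def recovery_report(n_replicates: int, *, regimes=REGIMES,
                    trials_grid=(30, 100, 300), n_subjects: int = 16,
                    alpha: float = 0.05, base_spec: CohortSpec | None = None,
                    seed: int = 0, use_incongruent: bool = True) -> pd.DataFrame:
    """Classification accuracy of the planned-comparison battery by regime.

    For every (regime, trials_per_condition) cell, ``n_replicates`` cohorts
    of ``n_subjects`` are generated under that regime, scored, passed through
    the exclusion rule and classified; accuracy is the fraction classified as
    the generating regime.  ``trials_per_condition = None`` denotes the
    infinite-trials limit (analytic d' instead of sampled responses).
    ``use_incongruent=False`` withholds the incongruent comparisons from the
    classifier (congruent evidence cannot separate mandatory from selective
    fusion; the classifier then labels any integrator ``mandatory_fusion``),
    an ablation that drops mandatory/selective discrimination to chance.
    """
    if n_replicates < 2:
        raise InvalidSpecificationError("n_replicates must be >= 2")
    base = base_spec if base_spec is not None else CohortSpec()
    rows = []
    for regime in regimes:
        for tpc in trials_grid:
            correct = 0
            for rep in range(n_replicates):
                spec = replace(base, n_per_group={"G": n_subjects},
                               regime_by_group={"G": regime},
                               seed=seed * 100003 + rep)
                subjects = generate_cohort(spec)
                if tpc is None:
                    scores = _analytic_group_scores(subjects)
                else:
                    scores = _simulate_group_scores(subjects, tpc, rep)
                retained, _ = sdt.apply_exclusions(scores)
                try:
                    if use_incongruent:
                        label = sdt.classify_fusion_pattern(retained, alpha=alpha)
                    else:
                        comps = sdt.planned_comparisons(retained, alpha=alpha)
                        congruent = (comps["T+D+ vs T+"][1]
                                     and comps["T+D+ vs D+"][1])
                        label = "mandatory_fusion" if congruent else "no_fusion"
                except Exception:
                    label = "error"
                correct += label == regime
            rows.append({"regime": regime,
                         "trials_per_condition": math.inf if tpc is None else tpc,
                         "n_replicates": n_replicates,
                         "accuracy": correct / n_replicates})
    return pd.DataFrame(rows)
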