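"""Coupling-prior observers for the same-different slant task.

An observer receives a noisy texture-based and a noisy disparity-based slant
estimate for each disc.  How the two estimates are combined is governed by a
Gaussian coupling prior on the cue discrepancy: its width sigma_c expresses
how strongly the observer believes the two cues signal the same surface.
A peaked prior (sigma_c -> 0) forces mandatory fusion into a single
reliability-weighted slant; a flat prior (sigma_c -> inf) leaves the cues
independent; intermediate widths pull the two percepts partway toward each
other.  Three discrete regimes wrap this continuum:

``mandatory_fusion``
    always couple the cues (sigma_c, default 0);
``no_fusion``
    never couple; on combined-cue trials attend to a single cue - by default
    one chosen at random each trial (cue switching), optionally always the
    more reliable one;
``selective_fusion``
    couple only when the within-disc cue discrepancy is small enough to be
    credibly a single surface (gate at k * sqrt(sigma_T^2 + sigma_D^2));
    on detected conflicts keep the cues separate and respond "different"
    if either cue's between-disc difference exceeds the criterion.

Decisions use a differencing rule: respond "different" when the absolute
between-disc difference of the percept exceeds a fixed criterion (default
6.25 deg, half the slant increment used in the task).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .exceptions import InvalidSpecificationError
from .geometry import CONDITION_DELTAS

__all__ = [
    "ObserverParams",
    "TrialStimulus",
    "TrialRecord",
    "REGIMES",
    "CONDITIONS",
    "ANALYZED_CONDITIONS",
    "sample_cue_estimates",
    "coupling_map",
    "fuse_estimates",
    "decide_same_different",
    "simulate_condition",
    "simulate_responses",
    "predicted_dprime_fused",
    "analytic_rates",
    "analytic_dprime",
]

REGIMES = ("no_fusion", "mandatory_fusion", "selective_fusion")
CONDITIONS = ("T+", "T-", "D+", "D-", "T+D+", "T+D-")
#: conditions entering the analysis (the descending texture-only condition is
#: run to balance the design but scored out-of-analysis).
ANALYZED_CONDITIONS = ("T+", "D+", "D-", "T+D+", "T+D-")


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one simulated observer.

    sigma_T, sigma_D : single-cue slant noise SDs, degrees.
    sigma_c : coupling-prior SD on the cue discrepancy, degrees
        (0 = mandatory averaging, ``inf`` = fully uncoupled).
    criterion_c : same/different criterion on |percept difference|, degrees.
    regime : one of ``no_fusion``, ``mandatory_fusion``, ``selective_fusion``.
    gate_k : conflict-gate multiplier for selective fusion.
    lapse_rate : probability of a uniformly random response.
    no_fusion_rule : ``"switch"`` (attend one cue per trial at random) or
        ``"best"`` (always the more reliable cue, ties to texture).
    """

    sigma_T: float
    sigma_D: float
    sigma_c: float = 0.0
    criterion_c: float = 6.25
    regime: str = "mandatory_fusion"
    gate_k: float = 2.0
    lapse_rate: float = 0.0
    no_fusion_rule: str = "switch"

    def __post_init__(self):
        if not (self.sigma_T > 0 and self.sigma_D > 0):
            raise InvalidSpecificationError("sigma_T and sigma_D must be > 0")
        if not (self.sigma_c >= 0 or math.isinf(self.sigma_c)):
            raise InvalidSpecificationError("sigma_c must be >= 0 or inf")
        if not self.criterion_c > 0:
            raise InvalidSpecificationError("criterion_c must be > 0")
        if self.regime not in REGIMES:
            raise InvalidSpecificationError(f"unknown regime {self.regime!r}")
        if not 0 <= self.lapse_rate <= 0.1:
            raise InvalidSpecificationError("lapse_rate must be in [0, 0.1]")
        if self.no_fusion_rule not in ("switch", "best"):
            raise InvalidSpecificationError("no_fusion_rule must be 'switch' or 'best'")


@dataclass(frozen=True)
class TrialStimulus:
    """Slant offsets of the comparison disc relative to the 45 deg standard."""

    condition: str
    truth: str
    standard_slant: float = 45.0
    delta_texture: float = 0.0
    delta_disparity: float = 0.0

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise InvalidSpecificationError(f"unknown condition {self.condition!r}")
        if self.truth not in ("same", "different"):
            raise InvalidSpecificationError("truth must be 'same' or 'different'")
        nonzero = self.delta_texture != 0 or self.delta_disparity != 0
        if (self.truth == "different") != nonzero:
            raise InvalidSpecificationError(
                "truth must be 'different' iff at least one delta is nonzero")

    @classmethod
    def for_trial(cls, condition: str, truth: str) -> "TrialStimulus":
        d_tex, d_disp = CONDITION_DELTAS[condition]
        if truth == "same":
            return cls(condition=condition, truth=truth)
        return cls(condition=condition, truth=truth,
                   delta_texture=d_tex or 0.0, delta_disparity=d_disp or 0.0)


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    group: str
    condition: str
    trial_index: int
    truth: str
    response: str

    def __post_init__(self):
        if self.response not in ("same", "different"):
            raise InvalidSpecificationError("response must be 'same' or 'different'")


# --------------------------------------------------------------------------
# estimation and fusion
# --------------------------------------------------------------------------

def sample_cue_estimates(true_texture_slant, true_disparity_slant,
                         params: ObserverParams, rng: np.random.Generator):
    """Independent Gaussian slant estimates from each cue."""
    shape = np.shape(true_texture_slant)
    est_t = np.asarray(true_texture_slant) + params.sigma_T * rng.standard_normal(shape)
    est_d = np.asarray(true_disparity_slant) + params.sigma_D * rng.standard_normal(shape)
    return est_t, est_d


def coupling_map(est_T, est_D, sigma_T: float, sigma_D: float, sigma_c: float):
    """MAP percept pair (S_T*, S_D*) under the Gaussian coupling prior.

    Maximises N(est_T; S_T, sigma_T^2) * N(est_D; S_D, sigma_D^2)
    * N(S_T - S_D; 0, sigma_c^2).  Closed form of the quadratic optimum:
    with precisions a, b, c the determinant is ab + ac + bc and

        S_T* = (a (b + c) est_T + b c est_D) / det
        S_D* = (a c est_T + b (a + c) est_D) / det

    sigma_c = 0 collapses both onto the reliability-weighted average;
    sigma_c = inf returns the raw estimates.
    """
    if not (sigma_T > 0 and sigma_D > 0):
        raise InvalidSpecificationError("cue sigmas must be positive and finite")
    est_T = np.asarray(est_T, dtype=float)
    est_D = np.asarray(est_D, dtype=float)
    a, b = 1.0 / sigma_T**2, 1.0 / sigma_D**2
    if sigma_c == 0:
        fused = (a * est_T + b * est_D) / (a + b)
        return fused, fused.copy() if isinstance(fused, np.ndarray) else fused
    if math.isinf(sigma_c):
        return est_T, est_D
    c = 1.0 / sigma_c**2
    det = a * b + a * c + b * c
    s_t = (a * (b + c) * est_T + b * c * est_D) / det
    s_d = (a * c * est_T + b * (a + c) * est_D) / det
    return s_t, s_d


def fuse_estimates(est_T, est_D, params: ObserverParams):
    """Single fused slant percept: the reliability-weighted cue average.

    This is the coupled MAP readout w_T est_T + w_D est_D with
    w_T = sigma_D^2 / (sigma_T^2 + sigma_D^2); reading the coupled percept
    pair out with the same reliability weights gives the identical value for
    every finite coupling width, so the fused scalar does not depend on
    sigma_c.  An infinite sigma_c leaves no fused percept (the regime logic
    in :func:`decide_same_different` then keeps the cues separate).
    """
    if math.isinf(params.sigma_c):
        raise InvalidSpecificationError(
            "no fused percept under an infinitely wide coupling prior")
    a, b = 1.0 / params.sigma_T**2, 1.0 / params.sigma_D**2
    return (a * np.asarray(est_T, dtype=float) + b * np.asarray(est_D, dtype=float)) / (a + b)


def predicted_dprime_fused(dprime_T: float, dprime_D: float) -> float:
    """Quadratic-summation benchmark for optimal integration."""
    if dprime_T < 0 or dprime_D < 0:
        raise InvalidSpecificationError("single-cue d' inputs must be >= 0")
    return math.hypot(dprime_T, dprime_D)


# --------------------------------------------------------------------------
# trial simulation
# --------------------------------------------------------------------------

def _cues_of(condition: str):
    d_tex, d_disp = CONDITION_DELTAS[condition]
    return d_tex is not None, d_disp is not None


def simulate_responses(params: ObserverParams, condition: str,
                       truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised responses for a block of trials of one condition.

    ``truth`` is a boolean array (True = "different").  Returns a boolean
    array of "different" responses.
    """
    if condition not in CONDITIONS:
        raise InvalidSpecificationError(f"unknown condition {condition!r}")
    truth = np.asarray(truth, dtype=bool)
    n = truth.size
    has_t, has_d = _cues_of(condition)
    d_tex, d_disp = CONDITION_DELTAS[condition]
    std = 45.0

    # per-disc true slants; absent cue mirrors the physical (disparity) slant
    # but is never read out
    tex_std, disp_std = std, std
    tex_cmp = std + (d_tex or 0.0) * truth
    disp_cmp = std + (d_disp or 0.0) * truth

    et_s, ed_s = sample_cue_estimates(np.full(n, tex_std), np.full(n, disp_std),
                                      params, rng)
    et_c, ed_c = sample_cue_estimates(tex_cmp, disp_cmp, params, rng)
    c = params.criterion_c

    if has_t and not has_d:
        respond_diff = np.abs(et_c - et_s) > c
    elif has_d and not has_t:
        respond_diff = np.abs(ed_c - ed_s) > c
    else:
        respond_diff = _decide_combined(params, et_s, ed_s, et_c, ed_c, rng)

    if params.lapse_rate > 0:
        lapse = rng.random(n) < params.lapse_rate
        respond_diff = np.where(lapse, rng.random(n) < 0.5, respond_diff)
    return respond_diff


def _decide_combined(params, et_s, ed_s, et_c, ed_c, rng):
    c = params.criterion_c
    n = et_s.size
    if params.regime == "mandatory_fusion":
        st_s, sd_s = coupling_map(et_s, ed_s, params.sigma_T, params.sigma_D,
                                  params.sigma_c)
        st_c, sd_c = coupling_map(et_c, ed_c, params.sigma_T, params.sigma_D,
                                  params.sigma_c)
        return np.maximum(np.abs(st_c - st_s), np.abs(sd_c - sd_s)) > c
    if params.regime == "no_fusion":
        if params.no_fusion_rule == "best":
            use_t = params.sigma_T <= params.sigma_D
            use_tex = np.full(n, use_t)
        else:  # trial-wise cue switching
            use_tex = rng.random(n) < 0.5
        diff = np.where(use_tex, np.abs(et_c - et_s), np.abs(ed_c - ed_s))
        return diff > c
    # selective fusion: gate on the within-disc discrepancy of either disc
    gate = params.gate_k * math.hypot(params.sigma_T, params.sigma_D)
    conflict = (np.abs(et_s - ed_s) > gate) | (np.abs(et_c - ed_c) > gate)
    fused_s = fuse_estimates(et_s, ed_s, params) if not math.isinf(params.sigma_c) \
        else (et_s + ed_s) / 2
    fused_c = fuse_estimates(et_c, ed_c, params) if not math.isinf(params.sigma_c) \
        else (et_c + ed_c) / 2
    fused_resp = np.abs(fused_c - fused_s) > c
    separate_resp = np.maximum(np.abs(et_c - et_s), np.abs(ed_c - ed_s)) > c
    return np.where(conflict, separate_resp, fused_resp)


def decide_same_different(stim: TrialStimulus, params: ObserverParams,
                          rng: np.random.Generator) -> str:
    """Simulate one trial's response for a stimulus pair."""
    truth = np.array([stim.truth == "different"])
    resp = simulate_responses(params, stim.condition, truth, rng)[0]
    return "different" if resp else "same"


def simulate_condition(observer: ObserverParams, condition: str, n_trials: int,
                       rng: np.random.Generator, *, subject_id: str = "S1",
                       group: str = "SIM") -> list[TrialRecord]:
    """Simulate a balanced block of trials (half same, half different).

    Trial order is randomised; each record carries the ground truth and the
    simulated response.
    """
    if n_trials % 2 != 0:
        raise InvalidSpecificationError("n_trials must be even (half same/different)")
    truth = np.zeros(n_trials, dtype=bool)
    truth[n_trials // 2:] = True
    rng.shuffle(truth)
    resp = simulate_responses(observer, condition, truth, rng)
    return [
        TrialRecord(subject_id=subject_id, group=group, condition=condition,
                    trial_index=i + 1,
                    truth="different" if t else "same",
                    response="different" if r else "same")
        for i, (t, r) in enumerate(zip(truth, resp))
    ]


# --------------------------------------------------------------------------
# analytic performance (closed-form Gaussian tail rates)
# --------------------------------------------------------------------------

def _p_exceed(mu: float, sd: float, c: float) -> float:
    """P(|N(mu, sd^2)| > c)."""
    return float(norm.sf((c - mu) / sd) + norm.cdf((-c - mu) / sd))


def analytic_rates(params: ObserverParams, condition: str) -> tuple[float, float]:
    """Closed-form (hit, false-alarm) probabilities for one condition.

    Exact for single-cue conditions and every regime with sigma_c = 0; for
    selective fusion the conflict gate is treated as deterministic per trial
    type (a good approximation when the stimulus discrepancy is far from the
    gate threshold, as with the task's 25 deg incongruent conflict).
    """
    d_tex, d_disp = CONDITION_DELTAS[condition]
    has_t, has_d = _cues_of(condition)
    c = params.criterion_c
    st, sd_ = params.sigma_T, params.sigma_D
    sd_t, sd_d = math.sqrt(2) * st, math.sqrt(2) * sd_

    if has_t and not has_d:
        return _p_exceed(abs(d_tex), sd_t, c), _p_exceed(0.0, sd_t, c)
    if has_d and not has_t:
        return _p_exceed(abs(d_disp), sd_d, c), _p_exceed(0.0, sd_d, c)

    if params.regime == "mandatory_fusion":
        if params.sigma_c != 0:
            raise NotImplementedError(
                "analytic rates for partial coupling are not available")
        a, b = 1 / st**2, 1 / sd_**2
        w_t = a / (a + b)
        mu = w_t * d_tex + (1 - w_t) * d_disp
        sd_f = math.sqrt(2 * (w_t**2 * st**2 + (1 - w_t)**2 * sd_**2))
        return _p_exceed(abs(mu), sd_f, c), _p_exceed(0.0, sd_f, c)

    if params.regime == "no_fusion":
        h_t, f_t = _p_exceed(abs(d_tex), sd_t, c), _p_exceed(0.0, sd_t, c)
        h_d, f_d = _p_exceed(abs(d_disp), sd_d, c), _p_exceed(0.0, sd_d, c)
        if params.no_fusion_rule == "best":
            return (h_t, f_t) if st <= sd_ else (h_d, f_d)
        return 0.5 * (h_t + h_d), 0.5 * (f_t + f_d)

    # selective fusion, deterministic gate: congruent-looking stimuli are
    # fused, detected conflicts fall back to the separate-cue max rule
    a, b = 1 / st**2, 1 / sd_**2
    w_t = a / (a + b)
    sd_f = math.sqrt(2 * (w_t**2 * st**2 + (1 - w_t)**2 * sd_**2))
    fa = _p_exceed(0.0, sd_f, c)  # "same" stimuli never conflict within-disc
    if d_tex == d_disp:
        hit = _p_exceed(abs(w_t * d_tex + (1 - w_t) * d_disp), sd_f, c)
    else:  # 25 deg within-disc conflict on the comparison: cues kept separate
        miss = ((1 - _p_exceed(abs(d_tex), sd_t, c))
                * (1 - _p_exceed(abs(d_disp), sd_d, c)))
        hit = 1 - miss
    return hit, fa


def analytic_dprime(params: ObserverParams, condition: str) -> float:
    """d' = z(hit) - z(false alarm) from the closed-form rates."""
    hit, fa = analytic_rates(params, condition)
    return float(norm.ppf(hit) - norm.ppf(fa))
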