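"""Comfort-target personalization by maximum-likelihood IRL.

The state and the action are both comfort-target (CT) profiles over the five
training bands.  The candidate space is built by scaling each band's standard
CT by a per-band factor from a small scale set ({0.5, 0.75, 1.0} by default)
and enumerating all combinations:

    CT_new(i) = CT_standard(i) * scale(i)

A training session presents paired comparisons: the same noisy utterance is
rendered under the current state's CTs and under a proposed action's CTs, and
the listener answers "audio 1", "audio 2", or "same".  Choosing the action is
positive feedback (and the state moves there), choosing the state is negative,
"same" is neutral.  All feedback feeds a smoothed preference model H(s, a).

The reward is linear, R_W(s, a) = W^T phi(s, a), with phi a one-hot encoding
of the action's per-band scale, and the policy is Boltzmann in the reward.
The demonstration likelihood factorizes over records as pi_W(s, a) * H(s, a).
Because H carries no W-dependence, the weights are fit to the listener's
*demonstrated selections*: a positive record contributes the probability of
picking the action out of the presented pair, a negative record the
probability of keeping the state, and neutral records shape only H.  This is
a Luce-choice (conditional-logit) likelihood in the linear reward; gradient
ascent on its log is globally convergent (the objective is concave).

The personalized profile is the reward-maximizing profile under the fitted
weights, expanded back to the ten amplifier bands (each training band's scale
applies to both of its amplifier bands).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .audio import Calibration, mix_at_snr, synthesize_babble, synthesize_utterance
from .engine import (
    ListenerProfile,
    equilibrium_start,
    run_adaptive_gains,
)
from .filterbank import ADRO_LAYOUT, decompose
from .levels import frame_spl

DEFAULT_SCALES = (0.5, 0.75, 1.0)
POSITIVE, NEGATIVE, NEUTRAL = "positive", "negative", "neutral"


class MlirlError(ValueError):
    pass


def _round_half_up(x) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def expand_to_adro_bands(scales, standard_ct_10) -> np.ndarray:
    """Apply per-training-band scales to the ten-band standard CTs.

    Training band i covers amplifier bands 2i and 2i+1; both get the same
    scale.  Results are rounded to integer dB (half up).
    """
    scales = np.asarray(scales, dtype=np.float64)
    ct10 = np.asarray(standard_ct_10, dtype=np.float64)
    if ct10.size != 2 * scales.size:
        raise MlirlError(
            f"{scales.size} training bands cannot map onto {ct10.size} amplifier bands"
        )
    return _round_half_up(ct10 * np.repeat(scales, 2))


@dataclass(frozen=True)
class CTProfile:
    """A comfort-target vector over the training bands (state = action)."""

    ct_db: tuple
    scales: tuple

    def __post_init__(self) -> None:
        if len(self.ct_db) != len(self.scales):
            raise MlirlError("ct_db and scales lengths differ")
        object.__setattr__(self, "ct_db", tuple(float(c) for c in self.ct_db))
        object.__setattr__(self, "scales", tuple(float(s) for s in self.scales))


@dataclass(frozen=True)
class StateActionSpace:
    """Factorial enumeration of scaled CT profiles (S = A)."""

    profiles: tuple  # tuple[CTProfile]
    scales: tuple  # the per-band scale set
    standard_index: int
    scale_indices: np.ndarray  # (P, n_bands) int: which scale each band uses
    features_matrix: np.ndarray  # (P, n_bands * n_scales) one-hot blocks

    @property
    def n_profiles(self) -> int:
        return len(self.profiles)

    @property
    def n_bands(self) -> int:
        return len(self.profiles[0].ct_db)

    @property
    def n_features(self) -> int:
        return self.features_matrix.shape[1]


def build_action_space(
    ct_standard,
    scales=DEFAULT_SCALES,
    at_db=None,
    ldl_db=None,
) -> StateActionSpace:
    """Enumerate all per-band scale combinations of the standard CTs.

    Entries are rounded to 1 dB and clamped into [AT, LDL] of the mapped band
    when bounds are given.  The scale set must include 1.0 so the standard
    profile is a member of the space.
    """
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise MlirlError("scale set must be non-empty")
    if any(not 0 < s <= 1.5 for s in scales):
        raise MlirlError("scales must lie in (0, 1.5]")
    if 1.0 not in scales:
        raise MlirlError("scale set must include 1.0 (the standard profile)")
    ct_standard = np.asarray(ct_standard, dtype=np.float64)
    n_bands = ct_standard.size
    n_scales = len(scales)

    combos = list(itertools.product(range(n_scales), repeat=n_bands))
    profiles = []
    for combo in combos:
        s = np.array([scales[i] for i in combo])
        ct = _round_half_up(ct_standard * s)
        if at_db is not None:
            ct = np.maximum(ct, np.asarray(at_db, dtype=np.float64))
        if ldl_db is not None:
            ct = np.minimum(ct, np.asarray(ldl_db, dtype=np.float64))
        profiles.append(CTProfile(tuple(ct), tuple(s)))

    scale_indices = np.asarray(combos, dtype=np.intp)
    feats = np.zeros((len(combos), n_bands * n_scales))
    cols = np.arange(n_bands) * n_scales + scale_indices
    feats[np.arange(len(combos))[:, None], cols] = 1.0
    standard_index = combos.index(tuple([scales.index(1.0)] * n_bands))
    return StateActionSpace(
        profiles=tuple(profiles),
        scales=scales,
        standard_index=standard_index,
        scale_indices=scale_indices,
        features_matrix=feats,
    )


def features(space: StateActionSpace, s: int, a: int) -> np.ndarray:
    """phi(s, a): one-hot per-band scale indicators of the *action*.

    The encoding depends on the action only; with five bands the vector has
    exactly five ones.
    """
    if not (0 <= s < space.n_profiles and 0 <= a < space.n_profiles):
        raise MlirlError("state or action index out of range")
    return space.features_matrix[a].copy()


@dataclass(frozen=True)
class RewardWeights:
    """The weight vector W of the linear reward R_W(s,a) = W^T phi(s,a)."""

    w: np.ndarray
    converged: bool = True
    n_iterations: int = 0
    final_grad_norm: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=np.float64)
        if not np.all(np.isfinite(w)):
            raise MlirlError("reward weights must be finite")
        object.__setattr__(self, "w", w)

    def reward(self, space: StateActionSpace, a: int) -> float:
        return float(space.features_matrix[a] @ self.w)


def policy(
    space: StateActionSpace,
    w: RewardWeights,
    s: int,
    candidates=None,
    temperature: float = 1.0,
) -> np.ndarray:
    """Boltzmann policy over the candidate actions (all profiles by default)."""
    if candidates is None:
        candidates = np.arange(space.n_profiles)
    candidates = np.asarray(candidates, dtype=np.intp)
    logits = (space.features_matrix[candidates] @ w.w) / temperature
    logits -= logits.max()  # overflow-safe log-sum-exp
    p = np.exp(logits)
    return p / p.sum()


# ---------------------------------------------------------------------------
# Feedback, preference model, demonstration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeedbackRecord:
    """One paired comparison: (state, action) plus the listener's feedback."""

    state_index: int
    action_index: int
    feedback: str  # positive / negative / neutral
    trajectory: int = 0
    step: int = 0
    utterance_seed: int = 0

    def __post_init__(self) -> None:
        if self.feedback not in (POSITIVE, NEGATIVE, NEUTRAL):
            raise MlirlError(f"unknown feedback {self.feedback!r}")


@dataclass(frozen=True)
class Demonstration:
    """Ordered trajectories of feedback records (the demonstration D)."""

    trajectories: tuple  # tuple[tuple[FeedbackRecord, ...], ...]

    def records(self):
        for traj in self.trajectories:
            yield from traj

    @property
    def n_records(self) -> int:
        return sum(len(t) for t in self.trajectories)


@dataclass(frozen=True)
class PreferenceModel:
    """Smoothed preference probabilities H(s, a) from feedback counts.

    ``H = (n_pos + 0.5*n_neutral + alpha) / (n_pos + n_neg + n_neutral +
    2*alpha)`` with Laplace ``alpha = 1``; unvisited pairs sit at the 0.5
    prior, so H never touches 0 or 1.
    """

    alpha: float = 1.0
    counts: dict = field(default_factory=dict)  # (s, a) -> (pos, neg, neut)

    def prob(self, s: int, a: int) -> float:
        pos, neg, neut = self.counts.get((s, a), (0, 0, 0))
        return (pos + 0.5 * neut + self.alpha) / (pos + neg + neut + 2 * self.alpha)


def update_preference_model(h: PreferenceModel, rec: FeedbackRecord) -> PreferenceModel:
    """Return a new model with the record's feedback tallied in."""
    key = (rec.state_index, rec.action_index)
    pos, neg, neut = h.counts.get(key, (0, 0, 0))
    if rec.feedback == POSITIVE:
        pos += 1
    elif rec.feedback == NEGATIVE:
        neg += 1
    else:
        neut += 1
    counts = dict(h.counts)
    counts[key] = (pos, neg, neut)
    return replace(h, counts=counts)


def build_preference_model(d: Demonstration, alpha: float = 1.0) -> PreferenceModel:
    h = PreferenceModel(alpha=alpha)
    for rec in d.records():
        h = update_preference_model(h, rec)
    return h


# ---------------------------------------------------------------------------
# Likelihood and its maximization
# ---------------------------------------------------------------------------


def _choice_terms(d: Demonstration):
    """Demonstrated selections: (state, chosen, candidate pair) per record.

    Positive feedback demonstrates choosing the action out of {state, action};
    negative demonstrates keeping the state; neutral records carry no choice.
    """
    for rec in d.records():
        if rec.feedback == NEUTRAL:
            continue
        chosen = rec.action_index if rec.feedback == POSITIVE else rec.state_index
        yield rec.state_index, chosen, (rec.state_index, rec.action_index)


def log_likelihood(
    d: Demonstration,
    w: RewardWeights,
    h: PreferenceModel,
    space: StateActionSpace,
    temperature: float = 1.0,
) -> float:
    """Log of the demonstration likelihood: sum of log pi_W + log H.

    Each non-neutral record contributes the log-probability of the listener's
    demonstrated selection within the presented pair, plus the log preference
    probability of that selection.  An empty demonstration has likelihood 1.
    """
    total = 0.0
    for s, chosen, cand in _choice_terms(d):
        p = policy(space, w, s, candidates=np.asarray(cand), temperature=temperature)
        total += math.log(p[cand.index(chosen)]) + math.log(h.prob(s, chosen))
    return total


def maximize_likelihood(
    d: Demonstration,
    h: PreferenceModel,
    space: StateActionSpace,
    temperature: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> RewardWeights:
    """Gradient ascent on the demonstration log-likelihood from W = 0.

    Backtracking (Armijo) line search guarantees the log-likelihood sequence
    is non-decreasing; the objective is concave, so the result is the global
    maximizer when the gradient tolerance is reached.
    """
    if d.n_records == 0:
        raise MlirlError("cannot maximize over an empty demonstration")
    terms = list(_choice_terms(d))
    if not terms:  # all-neutral demonstration: likelihood is flat in W
        return RewardWeights(np.zeros(space.n_features), converged=True)

    F = space.features_matrix
    chosen_f = np.stack([F[c] for _, c, _ in terms])
    cand_f = np.stack([F[list(cand)] for _, _, cand in terms])  # (m, k, n)

    def objective_and_grad(w):
        logits = cand_f @ w / temperature  # (m, k)
        mx = logits.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(logits - mx).sum(axis=1))
        chosen_logit = chosen_f @ w / temperature
        obj = float((chosen_logit - lse).sum())
        soft = np.exp(logits - lse[:, None])  # (m, k)
        grad = (chosen_f - (soft[:, :, None] * cand_f).sum(axis=1)).sum(axis=0) / temperature
        return obj, grad

    w = np.zeros(space.n_features)
    obj, grad = objective_and_grad(w)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(grad))
        if not np.all(np.isfinite(grad)):
            raise MlirlError("non-finite gradient")
        if gnorm <= tol:
            break
        step = 1.0
        for _ in range(50):
            w_new = w + step * grad
            obj_new, grad_new = objective_and_grad(w_new)
            if obj_new >= obj + 1e-4 * step * gnorm**2:
                break
            step *= 0.5
        else:  # no ascent step found: at numerical optimum
            break
        w, obj, grad = w_new, obj_new, grad_new
    gnorm = float(np.linalg.norm(grad))
    return RewardWeights(
        w, converged=gnorm <= tol, n_iterations=n_iter, final_grad_norm=gnorm
    )


def personalized_profile_index(space: StateActionSpace, w: RewardWeights) -> int:
    """Reward-maximizing profile; ties break toward the standard profile."""
    rewards = space.features_matrix @ w.w
    best = rewards.max()
    tied = np.flatnonzero(rewards >= best - 1e-12)
    std_ct = np.asarray(space.profiles[space.standard_index].ct_db)
    dists = [np.abs(np.asarray(space.profiles[i].ct_db) - std_ct).sum() for i in tied]
    return int(tied[int(np.argmin(dists))])


# ---------------------------------------------------------------------------
# Online training session
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SessionResult:
    demonstration: Demonstration
    weights: RewardWeights
    personalized: CTProfile
    personalized_ct_adro_db: np.ndarray
    space: StateActionSpace
    preference_model: PreferenceModel


def _training_band_ct(ct10: np.ndarray) -> np.ndarray:
    """Standard CTs mapped to the five training bands (mean of each pair)."""
    ct10 = np.asarray(ct10, dtype=np.float64)
    return _round_half_up((ct10[0::2] + ct10[1::2]) / 2.0)


def run_training_session(
    listener,
    profile: ListenerProfile,
    *,
    n_trajectories: int = 7,
    n_pairs: int = 31,
    seed: int = 0,
    scales=DEFAULT_SCALES,
    n_candidates: int = 16,
    epsilon: float = 0.5,
    snr_db: float = 5.0,
    duration_s: float = 2.5,
    n_babble_talkers: int = 8,
    cal: Calibration = Calibration(),
    temperature: float = 1.0,
    choose_fn=None,
) -> SessionResult:
    """Full online personalization session against a listener.

    Every trajectory restarts at the standard profile.  Each step proposes an
    action epsilon-greedily (random candidate with probability ``epsilon``,
    otherwise the reward-maximizing candidate under the weights refit after
    each completed trajectory), renders the same babble-corrupted utterance
    under the state's and the action's comfort targets, and records the
    listener's judgement.  Positive feedback moves the state to the action.
    After all trajectories the reward weights are fit to the complete
    demonstration and the personalized profile is the reward maximizer.

    Deterministic for a fixed seed and listener.
    """
    if choose_fn is None:
        from .listeners import choose as choose_fn  # avoid a circular import

    rng = np.random.default_rng(seed)
    m10 = profile.map
    ct5_standard = _training_band_ct(m10.ct_db)
    space = build_action_space(ct5_standard, scales)
    n_profiles = space.n_profiles

    babble = synthesize_babble(
        n_babble_talkers, duration_s, seed=int(rng.integers(2**31))
    )

    def render_pair(state_idx: int, action_idx: int, utt_seed: int):
        utt = synthesize_utterance(duration_s, utt_seed)
        mixture = mix_at_snr(utt, babble, snr_db)
        bf = decompose(mixture, ADRO_LAYOUT)
        levels = frame_spl(bf, cal)
        diags = []
        for idx in (state_idx, action_idx):
            ct10 = expand_to_adro_bands(space.profiles[idx].scales, m10.ct_db)
            m = m10.with_ct(ct10)
            g0, p0 = equilibrium_start(levels, m)
            diags.append(
                run_adaptive_gains(
                    levels, m, bf.frame_hop_s, init_gain_db=g0, init_percentiles=p0
                )
            )
        return diags

    h = PreferenceModel()
    w_curr = RewardWeights(np.zeros(space.n_features))
    trajectories = []
    for traj in range(n_trajectories):
        state = space.standard_index
        records = []
        for step in range(n_pairs):
            pool = np.delete(np.arange(n_profiles), state)
            cand = rng.choice(pool, size=min(n_candidates, pool.size), replace=False)
            if rng.random() < epsilon or not np.any(w_curr.w):
                action = int(rng.choice(cand))
            else:
                action = int(cand[np.argmax(space.features_matrix[cand] @ w_curr.w)])
            utt_seed = int(rng.integers(2**31))
            diag_state, diag_action = render_pair(state, action, utt_seed)
            answer = choose_fn(diag_state, diag_action, listener, rng)
            feedback = {"first": NEGATIVE, "second": POSITIVE, "same": NEUTRAL}[answer]
            rec = FeedbackRecord(
                state_index=state,
                action_index=action,
                feedback=feedback,
                trajectory=traj,
                step=step,
                utterance_seed=utt_seed,
            )
            records.append(rec)
            h = update_preference_model(h, rec)
            if feedback == POSITIVE:
                state = action
        trajectories.append(tuple(records))
        demo_so_far = Demonstration(tuple(trajectories))
        if any(r.feedback != NEUTRAL for r in demo_so_far.records()):
            w_curr = maximize_likelihood(demo_so_far, h, space, temperature=temperature)

    demonstration = Demonstration(tuple(trajectories))
    if any(r.feedback != NEUTRAL for r in demonstration.records()):
        weights = maximize_likelihood(demonstration, h, space, temperature=temperature)
    else:
        weights = RewardWeights(np.zeros(space.n_features))
    best = personalized_profile_index(space, weights)
    personalized = space.profiles[best]
    ct10 = expand_to_adro_bands(personalized.scales, m10.ct_db)
    return SessionResult(
        demonstration=demonstration,
        weights=weights,
        personalized=personalized,
        personalized_ct_adro_db=ct10,
        space=space,
        preference_model=h,
    )


# ---------------------------------------------------------------------------
# Standard-CT staircase measurement
# ---------------------------------------------------------------------------


def measure_standard_ct(
    listener,
    band: int,
    start_db: float = 40.0,
    step_db: float = 5.0,
    max_db: float = 120.0,
    too_loud_fn=None,
) -> float:
    """Ascending staircase: raise a band tone in 5 dB steps until "too loud",
    then step back 5 dB and return that level as the comfort target."""
    if too_loud_fn is None:
        from .listeners import too_loud as too_loud_fn

    level = start_db
    while level < max_db:
        if too_loud_fn(level, band, listener):
            return level - step_db
        level += step_db
    raise MlirlError(
        f"listener never reported 'too loud' below {max_db} dB SPL in band {band}"
    )
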