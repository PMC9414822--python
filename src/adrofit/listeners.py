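"""Simulated listeners for paired-comparison and staircase procedures.

A simulated listener stands in for a human subject.  Its ground truth is a
preferred comfort-target vector: a rendering is scored by how close the
engine's final mid-percentile levels land to those preferred levels, with a
penalty for frames that exceed the discomfort level.  Scoring on engine
diagnostics (rather than raw audio) makes the preferred profile exactly the
quantity the amplifier controls, so parameter recovery is well-posed.

Choices between two renderings follow a logistic (Bradley-Terry style) rule
on the score difference, with a "same" response when the difference is below
a just-noticeable threshold and a temperature parameter for choice noise
(temperature 0 is the deterministic listener).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .engine import Diagnostics, ListenerProfile
from .mlirl import expand_to_adro_bands

#: Default choice-noise temperature (score units).  With the 1.0-unit "same"
#: threshold, the smallest non-"same" score difference gives a choice
#: probability of sigmoid(1/0.25) = 0.982, so repeated presentations of any
#: discriminable pair agree at least 96.4 % of the time.
DEFAULT_TEMPERATURE = 0.25
DEFAULT_SAME_THRESHOLD = 1.0
DEFAULT_LDL_PENALTY = 20.0

FIRST, SECOND, SAME = "first", "second", "same"


class ListenerError(ValueError):
    pass


@dataclass(frozen=True)
class SimulatedListener:
    """Ground-truth preference over comfort-target profiles.

    ``true_ct_train_db`` is the preferred 5-band (training-band) profile;
    ``true_ct_adro_db`` its 10-band expansion used for scoring diagnostics.
    """

    true_ct_train_db: np.ndarray  # (5,)
    true_ct_adro_db: np.ndarray  # (10,)
    at_db: np.ndarray  # (10,)
    ldl_db: np.ndarray  # (10,)
    choice_noise_temperature: float = DEFAULT_TEMPERATURE
    same_threshold: float = DEFAULT_SAME_THRESHOLD
    ldl_penalty: float = DEFAULT_LDL_PENALTY
    true_scales: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("true_ct_train_db", "true_ct_adro_db", "at_db", "ldl_db"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.choice_noise_temperature < 0:
            raise ListenerError("temperature must be non-negative")
        if np.any(self.true_ct_adro_db <= self.at_db) or np.any(
            self.true_ct_adro_db >= self.ldl_db
        ):
            raise ListenerError("preferred CT must lie strictly inside (AT, LDL)")


def listener_from_scales(
    profile: ListenerProfile,
    scales,
    **kwargs,
) -> SimulatedListener:
    """Listener whose preferred profile is the standard CT scaled per band."""
    scales = tuple(float(s) for s in scales)
    ct10 = expand_to_adro_bands(scales, profile.map.ct_db)
    ct5 = np.asarray(
        [round((profile.map.ct_db[2 * i] + profile.map.ct_db[2 * i + 1]) / 2 * scales[i])
         for i in range(len(scales))],
        dtype=np.float64,
    )
    return SimulatedListener(
        true_ct_train_db=ct5,
        true_ct_adro_db=ct10,
        at_db=profile.map.at_db,
        ldl_db=profile.map.ldl_db,
        true_scales=scales,
        **kwargs,
    )


def random_listener(
    profile: ListenerProfile,
    seed: int,
    scale_choices=(0.5, 0.75, 1.0),
    n_training_bands: int = 5,
    **kwargs,
) -> SimulatedListener:
    """Listener with per-training-band preferred scales drawn at random."""
    rng = np.random.default_rng(seed)
    scales = tuple(rng.choice(scale_choices) for _ in range(n_training_bands))
    return listener_from_scales(profile, scales, **kwargs)


def comfort_score(diagnostics: Diagnostics, listener: SimulatedListener) -> float:
    """Score of a rendering: 0 is perfect, more negative is worse.

    ``-sum_b |final mid percentile - preferred CT| - penalty * LDL fraction``.
    """
    if diagnostics is None:
        raise ListenerError("diagnostics required to score a rendering")
    dev = np.abs(diagnostics.final_mid_db - listener.true_ct_adro_db).sum()
    return float(-dev - listener.ldl_penalty * diagnostics.ldl_exceed_fraction)


def choose(
    audio_a_diag: Diagnostics,
    audio_b_diag: Diagnostics,
    listener: SimulatedListener,
    seed_or_rng=0,
) -> str:
    """Judge a pair: "first", "second", or "same".

    Score difference below the "same" threshold gives "same"; otherwise the
    first rendering is chosen with probability sigmoid(delta/temperature)
    (argmax at temperature 0).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    delta = comfort_score(audio_a_diag, listener) - comfort_score(audio_b_diag, listener)
    if abs(delta) < listener.same_threshold:
        return SAME
    if listener.choice_noise_temperature == 0:
        return FIRST if delta > 0 else SECOND
    p_first = expit(delta / listener.choice_noise_temperature)
    return FIRST if rng.random() < p_first else SECOND


def too_loud(level_db: float, band: int, listener: SimulatedListener) -> bool:
    """True when a tone at this band level reaches the discomfort boundary."""
    if not 0 <= band < listener.ldl_db.size:
        raise ListenerError(f"band {band} out of range")
    return bool(level_db >= listener.ldl_db[band])
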