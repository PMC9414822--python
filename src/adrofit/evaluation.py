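"""Held-out preference testing and the cohort statistic.

After personalization, fresh babble-corrupted utterances are rendered under
the standard and the personalized comfort targets, presented in randomized
order, and tallied.  The cohort comparison uses a classical one-way ANOVA
with two groups (per-listener counts of standard-preferred vs
personalized-preferred utterances), giving 1 and ``n_a + n_b - 2`` degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .audio import Calibration, mix_at_snr, synthesize_babble, synthesize_utterance
from .engine import ListenerProfile, equilibrium_start, run_adaptive_gains
from .filterbank import ADRO_LAYOUT, decompose
from .levels import frame_spl
from .listeners import FIRST, SAME, SimulatedListener, choose


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class PreferenceTally:
    """Counts from a preference test; they always sum to the pairs presented."""

    n_personalized: int
    n_standard: int
    n_same: int

    @property
    def n_pairs(self) -> int:
        return self.n_personalized + self.n_standard + self.n_same


def preference_test(
    listener: SimulatedListener,
    standard_profile: ListenerProfile,
    personalized_ct_db,
    n_pairs: int = 30,
    seed: int = 0,
    *,
    snr_db: float = 5.0,
    duration_s: float = 2.5,
    n_babble_talkers: int = 8,
    cal: Calibration = Calibration(),
) -> PreferenceTally:
    """Randomized standard-vs-personalized paired-comparison test.

    Each pair uses a fresh utterance mixed with babble at the session SNR;
    presentation order is randomized per pair.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    m_std = standard_profile.map
    m_pers = m_std.with_ct(np.asarray(personalized_ct_db, dtype=np.float64))
    babble = synthesize_babble(n_babble_talkers, duration_s, seed=int(rng.integers(2**31)))

    n_personalized = n_standard = n_same = 0
    for _ in range(n_pairs):
        utt = synthesize_utterance(duration_s, int(rng.integers(2**31)))
        mixture = mix_at_snr(utt, babble, snr_db)
        bf = decompose(mixture, ADRO_LAYOUT)
        levels = frame_spl(bf, cal)
        diags = {}
        for name, m in (("standard", m_std), ("personalized", m_pers)):
            g0, p0 = equilibrium_start(levels, m)
            diags[name] = run_adaptive_gains(
                levels, m, bf.frame_hop_s, init_gain_db=g0, init_percentiles=p0
            )
        order = ("standard", "personalized") if rng.random() < 0.5 else ("personalized", "standard")
        answer = choose(diags[order[0]], diags[order[1]], listener, rng)
        if answer == SAME:
            n_same += 1
        else:
            picked = order[0] if answer == FIRST else order[1]
            if picked == "personalized":
                n_personalized += 1
            else:
                n_standard += 1
    return PreferenceTally(n_personalized, n_standard, n_same)


def one_way_anova_f(group_a, group_b) -> tuple:
    """Classical two-group one-way ANOVA.

    Returns ``(F, df1, df2)`` with df1 = 1 and df2 = n_a + n_b - 2.  When the
    within-group variance is zero with unequal means, F is reported as the
    +infinity sentinel.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EvaluationError("both groups must be non-empty")
    grand = np.concatenate([a, b]).mean()
    ss_between = a.size * (a.mean() - grand) ** 2 + b.size * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df1 = 1
    df2 = a.size + b.size - 2
    if ss_within == 0.0:
        f = 0.0 if ss_between == 0.0 else float("inf")
    else:
        f = (ss_between / df1) / (ss_within / df2)
    return float(f), df1, df2


def tallies_to_frame(tallies) -> pd.DataFrame:
    """One row per listener: preference counts from the testing session."""
    return pd.DataFrame(
        [
            {
                "listener": i,
                "n_personalized": t.n_personalized,
                "n_standard": t.n_standard,
                "n_same": t.n_same,
            }
            for i, t in enumerate(tallies)
        ]
    )


def cohort_summary(tallies) -> dict:
    """Totals, preference ratio, and the two-group ANOVA over the cohort.

    The ratio denominator is floored at one preference so the statistic stays
    finite when no listener ever picks the standard fitting.
    """
    total_p = sum(t.n_personalized for t in tallies)
    total_s = sum(t.n_standard for t in tallies)
    total_same = sum(t.n_same for t in tallies)
    f, df1, df2 = one_way_anova_f(
        [t.n_personalized for t in tallies], [t.n_standard for t in tallies]
    )
    return {
        "total_personalized": total_p,
        "total_standard": total_s,
        "total_same": total_same,
        "preference_ratio": total_p / max(1, total_s),
        "anova_f": f,
        "anova_df": (df1, df2),
    }
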