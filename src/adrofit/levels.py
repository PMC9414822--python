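"""Band SPL conversion and streaming percentile tracking.

The gain rules compare running estimates of the 98th, 70th and 30th
percentiles of each band's SPL against the listener's map.  The estimates use
constant-step stochastic-approximation quantile tracking: for target quantile
p, the estimate moves up by ``step*p`` when the new level exceeds it and down
by ``step*(1-p)`` otherwise, so at equilibrium the probability of an
up-move balances the down-move exactly at the p-th quantile.  The tracker is
streaming and O(1) per band; the exact order-statistic quantile is kept only
as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio import Calibration
from .filterbank import BandFrames

DEFAULT_PERCENTILES = (0.98, 0.70, 0.30)
DEFAULT_STEP_DB = 0.2
SPL_FLOOR_DB = 0.0


class LevelError(ValueError):
    pass


def frame_spl(b: BandFrames, cal: Calibration) -> np.ndarray:
    """Per-frame per-band level in dB SPL, floored at 0 dB for silence."""
    with np.errstate(divide="ignore"):
        level = 10.0 * np.log10(b.band_power) + cal.spl_at_full_scale
    return np.maximum(level, SPL_FLOOR_DB)


@dataclass(frozen=True)
class PercentileState:
    """Running high/mid/low band-SPL percentile estimates.

    Each field is a vector over bands.  ``percentiles`` gives the tracked
    quantiles for (high, mid, low); ``step_db`` is the adaptation increment.
    """

    high_db: np.ndarray
    mid_db: np.ndarray
    low_db: np.ndarray
    step_db: float = DEFAULT_STEP_DB
    percentiles: tuple = DEFAULT_PERCENTILES

    def __post_init__(self) -> None:
        for name in ("high_db", "mid_db", "low_db"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if not (self.percentiles[0] > self.percentiles[1] > self.percentiles[2]):
            raise LevelError("percentiles must be ordered high > mid > low")
        if not 0 < self.step_db:
            raise LevelError("step_db must be positive")

    @classmethod
    def initialized_at(cls, level_db, n_bands: int | None = None, **kw) -> "PercentileState":
        """All three estimates start at a common level (per band or scalar)."""
        level = np.asarray(level_db, dtype=np.float64)
        if level.ndim == 0:
            level = np.full(n_bands, float(level))
        return cls(level.copy(), level.copy(), level.copy(), **kw)


def _track(est: np.ndarray, level: np.ndarray, p: float, step: float) -> np.ndarray:
    return np.where(level > est, est + step * p, est - step * (1.0 - p))


def update_percentiles(state: PercentileState, level_db) -> PercentileState:
    """One tracking step given the current per-band level (dB SPL)."""
    level = np.asarray(level_db, dtype=np.float64)
    p_hi, p_mid, p_lo = state.percentiles
    return replace(
        state,
        high_db=_track(state.high_db, level, p_hi, state.step_db),
        mid_db=_track(state.mid_db, level, p_mid, state.step_db),
        low_db=_track(state.low_db, level, p_lo, state.step_db),
    )


def empirical_percentiles(levels, p) -> float:
    """Exact interpolated order-statistic quantile (test oracle only)."""
    levels = np.asarray(levels, dtype=np.float64)
    if levels.size == 0:
        raise LevelError("empty level sequence")
    return float(np.quantile(levels, p))
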