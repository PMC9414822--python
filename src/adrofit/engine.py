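"""The ADRO amplifier: map parameters, comparator gain rules, processing.

Per band the map holds an audibility target (AT), comfort target (CT),
loudness discomfort level (LDL), maximum power output (MPO, an output-level
cap) and maximum gain (MG).  Every frame, running percentile estimates of the
amplified band level are compared against the map and exactly one rule fires
per band, with safety-first precedence:

1. if the high (98th) percentile exceeds LDL, reduce the gain;
2. else if the mid (70th) percentile is below CT, increase the gain —
   unless the gain has reached MG or the high percentile has reached LDL;
3. else if the low (30th) percentile is above AT, reduce the gain.

Gain moves at the slew rate (3 dB/s by default, i.e. 0.012 dB per 4 ms hop)
and is clamped to [-MG, +MG].  MPO is applied as an instantaneous extra
attenuation at synthesis, after the rule gain.

Percentile estimates track the *amplified* (pre-MPO) band level, so rule 2's
equilibrium is "mid percentile of the output = CT", which is the quantity the
fitting controls and the quantity listeners judge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .audio import Calibration, Waveform
from .filterbank import ADRO_LAYOUT, BandLayout, decompose, reconstruct
from .levels import (
    DEFAULT_PERCENTILES,
    DEFAULT_STEP_DB,
    PercentileState,
    frame_spl,
)

DEFAULT_SLEW_DB_PER_S = 3.0
DEFAULT_BURN_IN_S = 1.0
DEFAULT_MAX_GAIN_DB = 30.0
DEFAULT_AT_DB = 20.0
DEFAULT_LDL_OFFSET_DB = 25.0


class EngineError(ValueError):
    pass


@dataclass(frozen=True)
class MapParameters:
    """Per-band AT/CT/LDL/MPO (dB SPL) and MG (dB)."""

    at_db: np.ndarray
    ct_db: np.ndarray
    ldl_db: np.ndarray
    mpo_db: np.ndarray
    mg_db: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("at_db", "ct_db", "ldl_db", "mpo_db", "mg_db"):
            a = np.asarray(getattr(self, name), dtype=np.float64)
            if n is None:
                n = a.size
            elif a.size != n:
                raise EngineError("map parameter vectors differ in length")
            arrays[name] = a
            object.__setattr__(self, name, a)
        if np.any(arrays["at_db"] >= arrays["ct_db"]):
            raise EngineError("AT must be below CT in every band")
        if np.any(arrays["ct_db"] >= arrays["ldl_db"]):
            raise EngineError("CT must be below LDL in every band")
        if np.any(arrays["mpo_db"] > arrays["ldl_db"]):
            raise EngineError("MPO must not exceed LDL")
        if np.any(arrays["mg_db"] < 0):
            raise EngineError("MG must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.ct_db.size

    @classmethod
    def from_standard_ct(
        cls,
        ct_db,
        at_db: float = DEFAULT_AT_DB,
        ldl_offset_db: float = DEFAULT_LDL_OFFSET_DB,
        mg_db: float = DEFAULT_MAX_GAIN_DB,
    ) -> "MapParameters":
        """Build a map from measured comfort targets with default bounds.

        AT defaults to a flat 20 dB SPL, LDL to CT + 25 dB, MPO to LDL.
        """
        ct = np.asarray(ct_db, dtype=np.float64)
        ldl = ct + ldl_offset_db
        return cls(
            at_db=np.full_like(ct, at_db),
            ct_db=ct,
            ldl_db=ldl,
            mpo_db=ldl.copy(),
            mg_db=np.full_like(ct, mg_db),
        )

    def with_ct(self, ct_db) -> "MapParameters":
        """Same bounds with a different comfort-target vector."""
        return replace(self, ct_db=np.asarray(ct_db, dtype=np.float64))


@dataclass(frozen=True)
class GainState:
    """Current per-band gain with its slew-rate limit."""

    gain_db: np.ndarray
    slew_rate_db_per_s: float = DEFAULT_SLEW_DB_PER_S

    def __post_init__(self) -> None:
        object.__setattr__(self, "gain_db", np.asarray(self.gain_db, dtype=np.float64))
        if self.slew_rate_db_per_s <= 0:
            raise EngineError("slew rate must be positive")


@dataclass(frozen=True)
class ListenerProfile:
    """Audiogram plus map parameters over the ten amplifier bands."""

    audiogram_db_hl: np.ndarray
    map: MapParameters
    reference_personalized_ct: np.ndarray | None = None
    subject: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.audiogram_db_hl, dtype=np.float64)
        if a.size != self.map.n_bands:
            raise EngineError("audiogram length does not match the band layout")
        object.__setattr__(self, "audiogram_db_hl", a)
        if self.reference_personalized_ct is not None:
            object.__setattr__(
                self,
                "reference_personalized_ct",
                np.asarray(self.reference_personalized_ct, dtype=np.float64),
            )


# ---------------------------------------------------------------------------
# Comparator rules
# ---------------------------------------------------------------------------


def gain_rule_step(
    p: PercentileState, m: MapParameters, g: GainState, dt_s: float
) -> GainState:
    """One comparator update: exactly one rule fires per band (1 > 2 > 3)."""
    if not dt_s > 0:
        raise EngineError("dt_s must be positive")
    step = g.slew_rate_db_per_s * dt_s
    gain = g.gain_db
    rule1 = p.high_db > m.ldl_db
    rule2 = ~rule1 & (p.mid_db < m.ct_db)
    rule2_inc = rule2 & (gain < m.mg_db) & (p.high_db < m.ldl_db)
    rule3 = ~rule1 & ~rule2 & (p.low_db > m.at_db)
    new = gain - step * rule1 + step * rule2_inc - step * rule3
    new = np.clip(new, -m.mg_db, m.mg_db)
    return replace(g, gain_db=new)


def apply_mpo(band_output_levels_db, m: MapParameters) -> np.ndarray:
    """Clamp per-band output levels at MPO (idempotent)."""
    return np.minimum(np.asarray(band_output_levels_db, dtype=np.float64), m.mpo_db)


# ---------------------------------------------------------------------------
# Frame loop (numba-accelerated when available)
# ---------------------------------------------------------------------------


def _adaptive_loop_py(
    levels_in,
    at,
    ct,
    ldl,
    mg,
    step_db,
    p_hi,
    p_mid,
    p_lo,
    slew_step,
    burn_frames,
    init_gain,
    init_hi,
    init_mid,
    init_lo,
):
    T, B = levels_in.shape
    gains = np.empty((T, B))
    hi = np.empty((T, B))
    mid = np.empty((T, B))
    lo = np.empty((T, B))
    level_out = np.empty((T, B))
    g = init_gain.copy()
    ehi = init_hi.copy()
    emid = init_mid.copy()
    elo = init_lo.copy()
    for t in range(T):
        for b in range(B):
            out = levels_in[t, b] + g[b]
            level_out[t, b] = out
            if out > ehi[b]:
                ehi[b] += step_db * p_hi
            else:
                ehi[b] -= step_db * (1.0 - p_hi)
            if out > emid[b]:
                emid[b] += step_db * p_mid
            else:
                emid[b] -= step_db * (1.0 - p_mid)
            if out > elo[b]:
                elo[b] += step_db * p_lo
            else:
                elo[b] -= step_db * (1.0 - p_lo)
            gains[t, b] = g[b]
            hi[t, b] = ehi[b]
            mid[t, b] = emid[b]
            lo[t, b] = elo[b]
        if t >= burn_frames:
            for b in range(B):
                if ehi[b] > ldl[b]:
                    g[b] -= slew_step
                elif emid[b] < ct[b]:
                    if g[b] < mg[b] and ehi[b] < ldl[b]:
                        g[b] += slew_step
                elif elo[b] > at[b]:
                    g[b] -= slew_step
                if g[b] > mg[b]:
                    g[b] = mg[b]
                elif g[b] < -mg[b]:
                    g[b] = -mg[b]
    return gains, hi, mid, lo, level_out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _adaptive_loop = njit(cache=True)(_adaptive_loop_py)
except ImportError:  # pragma: no cover
    _adaptive_loop = _adaptive_loop_py


# ---------------------------------------------------------------------------
# Diagnostics and whole-utterance processing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Diagnostics:
    """Per-frame trajectories recorded while processing an utterance."""

    level_in_db: np.ndarray  # (T, B) band SPL before amplification
    level_out_db: np.ndarray  # (T, B) band SPL after rule gain, before MPO
    gain_db: np.ndarray  # (T, B) rule gain applied to each frame
    high_db: np.ndarray
    mid_db: np.ndarray
    low_db: np.ndarray
    frame_hop_s: float
    map: MapParameters
    #: rule gain minus the MPO limiter's attenuation; filled in when the
    #: output is rendered
    applied_gain_db: np.ndarray | None = None

    @property
    def level_applied_db(self) -> np.ndarray:
        """Band level actually synthesized into each band channel."""
        if self.applied_gain_db is None:
            raise EngineError("no rendered output: applied gains unavailable")
        return self.level_in_db + self.applied_gain_db

    @property
    def final_mid_db(self) -> np.ndarray:
        return self.mid_db[-1]

    @property
    def final_gain_db(self) -> np.ndarray:
        return self.gain_db[-1]

    def steady_gain_db(self, window_s: float = 5.0) -> np.ndarray:
        """Per-band gain averaged over the trailing window.

        The instantaneous gain oscillates in a limit cycle around its
        equilibrium; the trailing mean is the proper steady-state estimate
        to compare against :func:`steady_state_gain`.
        """
        n = max(1, int(round(window_s / self.frame_hop_s)))
        return self.gain_db[-n:].mean(axis=0)

    @property
    def ldl_exceed_fraction(self) -> float:
        """Fraction of (frame, band) cells whose pre-MPO level exceeds LDL."""
        return float(np.mean(self.level_out_db > self.map.ldl_db))

    def to_frame(self) -> pd.DataFrame:
        T, B = self.gain_db.shape
        frames, bands = np.meshgrid(np.arange(T), np.arange(B), indexing="ij")
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "band": bands.ravel(),
                "level_db": self.level_in_db.ravel(),
                "high_db": self.high_db.ravel(),
                "mid_db": self.mid_db.ravel(),
                "low_db": self.low_db.ravel(),
                "gain_db": self.gain_db.ravel(),
            }
        )


def run_adaptive_gains(
    levels_in: np.ndarray,
    m: MapParameters,
    frame_hop_s: float,
    *,
    slew_rate_db_per_s: float = DEFAULT_SLEW_DB_PER_S,
    step_db: float = DEFAULT_STEP_DB,
    percentiles: tuple = DEFAULT_PERCENTILES,
    burn_in_s: float = DEFAULT_BURN_IN_S,
    init_gain_db: np.ndarray | None = None,
    init_percentiles: PercentileState | None = None,
) -> Diagnostics:
    """Run the comparator over a precomputed band-level sequence.

    By default gains start at 0 dB, percentile estimates start at CT, and the
    rules are held for a 1 s burn-in while the estimators settle.
    """
    levels_in = np.asarray(levels_in, dtype=np.float64)
    T, B = levels_in.shape
    if B != m.n_bands:
        raise EngineError("level sequence does not match the map's band count")
    init_gain = (
        np.zeros(B) if init_gain_db is None else np.asarray(init_gain_db, dtype=np.float64)
    )
    if init_percentiles is None:
        init_hi = m.ct_db.copy()
        init_mid = m.ct_db.copy()
        init_lo = m.ct_db.copy()
    else:
        init_hi = init_percentiles.high_db.copy()
        init_mid = init_percentiles.mid_db.copy()
        init_lo = init_percentiles.low_db.copy()
    burn_frames = int(round(burn_in_s / frame_hop_s))
    p_hi, p_mid, p_lo = percentiles
    gains, hi, mid, lo, level_out = _adaptive_loop(
        levels_in,
        m.at_db,
        m.ct_db,
        m.ldl_db,
        m.mg_db,
        float(step_db),
        float(p_hi),
        float(p_mid),
        float(p_lo),
        slew_rate_db_per_s * frame_hop_s,
        burn_frames,
        init_gain,
        init_hi,
        init_mid,
        init_lo,
    )
    return Diagnostics(
        level_in_db=levels_in,
        level_out_db=level_out,
        gain_db=gains,
        high_db=hi,
        mid_db=mid,
        low_db=lo,
        frame_hop_s=frame_hop_s,
        map=m,
    )


def process(
    x: Waveform,
    profile: ListenerProfile,
    cal: Calibration = Calibration(),
    *,
    layout: BandLayout = ADRO_LAYOUT,
    slew_rate_db_per_s: float = DEFAULT_SLEW_DB_PER_S,
    step_db: float = DEFAULT_STEP_DB,
    percentiles: tuple = DEFAULT_PERCENTILES,
    burn_in_s: float = DEFAULT_BURN_IN_S,
    init_gain_db: np.ndarray | None = None,
    init_percentiles: PercentileState | None = None,
    render: bool = True,
):
    """Process an utterance end to end.

    Returns ``(output_waveform, diagnostics)``; the waveform is None when
    ``render=False`` (diagnostics-only runs skip synthesis).  Deterministic:
    identical inputs give bit-identical diagnostics.
    """
    bf = decompose(x, layout)
    levels_in = frame_spl(bf, cal)
    diag = run_adaptive_gains(
        levels_in,
        profile.map,
        bf.frame_hop_s,
        slew_rate_db_per_s=slew_rate_db_per_s,
        step_db=step_db,
        percentiles=percentiles,
        burn_in_s=burn_in_s,
        init_gain_db=init_gain_db,
        init_percentiles=init_percentiles,
    )
    if not render:
        return None, diag
    # MPO: instantaneous extra attenuation where the amplified level
    # overshoots.  The overshoot is taken over a 3-frame neighborhood because
    # 50%-overlapped synthesis smears each frame into its neighbors; clamping
    # against the local maximum keeps the re-analyzed output below MPO.
    level = diag.level_out_db
    local_max = level.copy()
    local_max[1:] = np.maximum(local_max[1:], level[:-1])
    local_max[:-1] = np.maximum(local_max[:-1], level[1:])
    overshoot = np.maximum(0.0, local_max - profile.map.mpo_db)
    applied = diag.gain_db - overshoot
    y = reconstruct(bf, applied)
    return y, replace(diag, applied_gain_db=applied)


def equilibrium_start(
    levels_in: np.ndarray,
    m: MapParameters,
    *,
    percentiles: tuple = DEFAULT_PERCENTILES,
    step_db: float = DEFAULT_STEP_DB,
) -> tuple[np.ndarray, PercentileState]:
    """Closed-form warm start: rule-equilibrium gains for a known stimulus.

    Paired-comparison renders model a listener who has worn each fitting long
    enough for the 3 dB/s adaptation to settle, so sessions initialize each
    render at the gain the rules converge to on that stimulus:
    ``clip(CT - q70, -MG, MG)`` further capped so the 98th output percentile
    stays at or below LDL.  Percentile estimates start at the corresponding
    output percentiles.
    """
    levels_in = np.asarray(levels_in, dtype=np.float64)
    p_hi, p_mid, p_lo = percentiles
    q_hi = np.quantile(levels_in, p_hi, axis=0)
    q_mid = np.quantile(levels_in, p_mid, axis=0)
    q_lo = np.quantile(levels_in, p_lo, axis=0)
    g0 = np.clip(m.ct_db - q_mid, -m.mg_db, m.mg_db)
    g0 = np.minimum(g0, np.maximum(m.ldl_db - q_hi, -m.mg_db))
    state = PercentileState(
        high_db=q_hi + g0,
        mid_db=q_mid + g0,
        low_db=q_lo + g0,
        step_db=step_db,
        percentiles=percentiles,
    )
    return g0, state


# ---------------------------------------------------------------------------
# Steady-state oracle
# ---------------------------------------------------------------------------


def steady_state_gain(
    level_samples: np.ndarray,
    m: MapParameters,
    *,
    frame_hop_s: float = 64 / 16000,
    slew_rate_db_per_s: float = DEFAULT_SLEW_DB_PER_S,
    step_db: float = DEFAULT_STEP_DB,
    percentiles: tuple = DEFAULT_PERCENTILES,
    tol_db: float = 0.1,
    max_passes: int = 400,
) -> np.ndarray:
    """Fixed point of the full rule system on a stationary level distribution.

    Brute force by direct iteration: the complete dynamics (percentile
    trackers plus comparator rules, identical step sizes) are replayed over
    the sample stream pass after pass, carrying state across passes, until
    the per-pass mean gain stops moving; the limit-cycle mean of the last
    pass is returned per band.  Serves as the independent equilibrium oracle
    for :func:`process` in tests: a single 30 s run must land where the
    iterated system settles.
    """
    samples = np.asarray(level_samples, dtype=np.float64)
    if samples.ndim == 1:
        samples = samples[:, None]
    B = samples.shape[1]
    if B != m.n_bands:
        raise EngineError("sample columns must match the map's band count")
    p_hi, p_mid, p_lo = percentiles
    slew_step = slew_rate_db_per_s * frame_hop_s

    gain = np.zeros(B)
    est_hi = m.ct_db.copy()
    est_mid = m.ct_db.copy()
    est_lo = m.ct_db.copy()
    prev_mean = np.full(B, np.inf)
    for _ in range(max_passes):
        gains, hi, mid, lo, _ = _adaptive_loop(
            samples,
            m.at_db,
            m.ct_db,
            m.ldl_db,
            m.mg_db,
            float(step_db),
            float(p_hi),
            float(p_mid),
            float(p_lo),
            slew_step,
            0,
            gain,
            est_hi,
            est_mid,
            est_lo,
        )
        gain = gains[-1].copy()
        est_hi, est_mid, est_lo = hi[-1].copy(), mid[-1].copy(), lo[-1].copy()
        mean = gains.mean(axis=0)
        if np.all(np.abs(mean - prev_mean) < tol_db):
            return mean
        prev_mean = mean
    raise RuntimeError("rule iteration did not settle: oscillation exceeds bound")
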