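"""STFT band decomposition and weighted overlap-add reconstruction.

The amplifier operates on ten contiguous frequency bands; personalization
groups them into five training bands (two amplifier bands each).  Analysis
uses 8 ms periodic-Hann frames with 50 % overlap, which satisfies the
constant-overlap-add condition exactly, so decompose -> reconstruct at unity
gain is an identity up to float rounding.  Each FFT bin belongs to exactly
one band (half-open intervals by bin center frequency; the Nyquist bin joins
the last band), so per-frame band powers partition the frame power exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .audio import Waveform

#: Ten amplifier bands.  The published list starts at 125 Hz and ends with an
#: open "6000 Hz and higher" band; the first band is widened to 0 Hz and the
#: last closed at the 8 kHz Nyquist so the partition covers the spectrum.
ADRO_BAND_EDGES_HZ = (0, 250, 500, 750, 1000, 1500, 2000, 3000, 4000, 6000, 8000)

#: Five training bands; training band i covers amplifier bands 2i and 2i+1.
TRAINING_BAND_EDGES_HZ = (0, 500, 1000, 2000, 4000, 8000)

FRAME_LEN = 128  # 8 ms at 16 kHz
FRAME_HOP = 64  # 50 % overlap


class FilterbankError(ValueError):
    """Invalid layout or mismatched dimensions."""


@dataclass(frozen=True)
class BandLayout:
    """Contiguous band partition defined by an ordered edge list in Hz."""

    edges_hz: tuple

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges_hz)
        if len(edges) < 2:
            raise FilterbankError("a layout needs at least two edges")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise FilterbankError("band edges must be strictly increasing")
        if edges[0] != 0.0:
            raise FilterbankError("layout must start at 0 Hz to cover the spectrum")
        object.__setattr__(self, "edges_hz", edges)

    @property
    def n_bands(self) -> int:
        return len(self.edges_hz) - 1

    def bin_bands(self, n_fft: int, sample_rate_hz: int) -> np.ndarray:
        """Band index of each rfft bin (bin center frequency, [low, high))."""
        if self.edges_hz[-1] > sample_rate_hz / 2:
            raise FilterbankError("last edge exceeds Nyquist")
        freqs = np.fft.rfftfreq(n_fft, 1.0 / sample_rate_hz)
        idx = np.searchsorted(self.edges_hz, freqs, side="right") - 1
        return np.clip(idx, 0, self.n_bands - 1)  # Nyquist bin joins the last band


ADRO_LAYOUT = BandLayout(ADRO_BAND_EDGES_HZ)
TRAINING_LAYOUT = BandLayout(TRAINING_BAND_EDGES_HZ)


@dataclass(frozen=True)
class BandFrames:
    """STFT frames with per-frame per-band power.

    ``band_power`` is normalized so a full-scale sine concentrated in one
    band reports the sine's mean-square amplitude (0.5 for unit amplitude),
    and band powers sum exactly to the total frame power.
    """

    stft: np.ndarray  # (n_frames, n_bins) complex
    band_power: np.ndarray  # (n_frames, n_bands)
    layout: BandLayout
    bin_band: np.ndarray  # (n_bins,) int
    sample_rate_hz: int
    frame_len: int
    hop: int
    n_samples: int  # original length, for trimming after synthesis

    @property
    def n_frames(self) -> int:
        return self.stft.shape[0]

    @property
    def frame_hop_s(self) -> float:
        return self.hop / self.sample_rate_hz


def _hann_periodic(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def decompose(
    x: Waveform,
    layout: BandLayout = ADRO_LAYOUT,
    frame_len: int = FRAME_LEN,
    hop: int = FRAME_HOP,
) -> BandFrames:
    """Split a waveform into per-frame band components.

    Requires ``hop = frame_len / 2`` (the overlap-add identity relies on it).
    """
    if len(x) < frame_len:
        raise FilterbankError("waveform shorter than one analysis frame")
    if hop * 2 != frame_len:
        raise FilterbankError("hop must be half the frame length")

    padded = np.concatenate([np.zeros(frame_len), x.samples, np.zeros(frame_len)])
    n_frames = (padded.size - frame_len) // hop + 1
    usable = (n_frames - 1) * hop + frame_len
    frames = sliding_window_view(padded[:usable], frame_len)[::hop]
    window = _hann_periodic(frame_len)
    stft = np.fft.rfft(frames * window, axis=1)

    bin_band = layout.bin_bands(frame_len, x.sample_rate_hz)
    coef = np.full(stft.shape[1], 2.0)
    coef[0] = 1.0
    if frame_len % 2 == 0:
        coef[-1] = 1.0
    wsum = window.sum()
    bin_power = coef * np.abs(stft) ** 2 / wsum**2
    band_power = np.zeros((stft.shape[0], layout.n_bands))
    np.add.at(band_power.T, bin_band, bin_power.T)

    return BandFrames(
        stft=stft,
        band_power=band_power,
        layout=layout,
        bin_band=bin_band,
        sample_rate_hz=x.sample_rate_hz,
        frame_len=frame_len,
        hop=hop,
        n_samples=len(x),
    )


def reconstruct(b: BandFrames, gains_db: np.ndarray) -> Waveform:
    """Overlap-add synthesis with a per-frame per-band gain trajectory.

    ``gains_db`` has shape (n_frames, n_bands).  With all gains at 0 dB the
    output reproduces the input to float precision.
    """
    gains_db = np.asarray(gains_db, dtype=np.float64)
    if gains_db.shape != (b.n_frames, b.layout.n_bands):
        raise FilterbankError(
            f"gain trajectory shape {gains_db.shape} does not match "
            f"({b.n_frames}, {b.layout.n_bands})"
        )
    lin = 10.0 ** (gains_db / 20.0)
    spec = b.stft * lin[:, b.bin_band]
    frames = np.fft.irfft(spec, n=b.frame_len, axis=1)

    total = (b.n_frames - 1) * b.hop + 2 * b.frame_len
    out = np.zeros(total)
    # at 50 % overlap, frames of a common parity tile the axis without
    # overlapping each other, so each parity adds in one contiguous write
    for phase in range(2):
        rows = np.arange(phase, b.n_frames, 2)
        if rows.size:
            start = phase * b.hop
            out[start : start + rows.size * b.frame_len] += frames[rows].ravel()

    y = out[b.frame_len : b.frame_len + b.n_samples]
    return Waveform(y, b.sample_rate_hz)
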