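"""Audio I/O, SPL calibration, and synthetic stimulus generation.

All processing runs on mono waveforms at 16 kHz (speech content up to about
4 kHz, so the band decomposition has a comfortable Nyquist margin).  A fixed
affine calibration maps digital RMS to dB SPL so that every level quantity in
the fitting pipeline is well defined: by default an RMS of 1.0 corresponds to
100 dB SPL.

Training stimuli are short (~2.5 s) speech-like utterances produced by a
harmonic-source-plus-formant synthesizer, with multi-talker babble built by
summing independent utterance streams.  Babble is added to speech at a
requested SNR (5 dB in the standard protocol).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.io import wavfile
from scipy.signal import lfilter, resample_poly

TARGET_RATE_HZ = 16000


class AudioError(ValueError):
    """Invalid audio input (empty file, silent signal, bad parameter)."""


@dataclass(frozen=True)
class Waveform:
    """Mono audio buffer with its sample rate.

    Samples are float64 amplitudes nominally in [-1, 1]; the constructor
    rejects non-finite values.
    """

    samples: np.ndarray
    sample_rate_hz: int = TARGET_RATE_HZ

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioError(f"expected mono 1-D samples, got shape {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise AudioError("waveform contains non-finite samples")
        if self.sample_rate_hz <= 0:
            raise AudioError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(self.samples**2)))


@dataclass(frozen=True)
class Calibration:
    """Affine map between digital amplitude and sound pressure level.

    ``spl_at_full_scale`` is the dB SPL assigned to a signal with RMS 1.0;
    a signal of RMS r is at ``20*log10(r) + spl_at_full_scale`` dB SPL.
    """

    spl_at_full_scale: float = 100.0

    def __post_init__(self) -> None:
        if not self.spl_at_full_scale > 0:
            raise AudioError("spl_at_full_scale must be strictly positive")


# ---------------------------------------------------------------------------
# WAV ingest / export
# ---------------------------------------------------------------------------

_PCM_SCALES = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
}


def read_wav(path) -> Waveform:
    """Read a WAV file as a mono 16 kHz :class:`Waveform`.

    Stereo files are averaged across channels; other sample rates are
    polyphase-resampled to 16 kHz.  PCM data are scaled to [-1, 1].
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises plain ValueError on bad files
        raise AudioError(f"cannot read WAV file {path!r}: {exc}") from exc
    if data.size == 0:
        raise AudioError(f"WAV file {path!r} contains no samples")
    data = np.asarray(data)
    if data.dtype in _PCM_SCALES:
        x = data.astype(np.float64) / _PCM_SCALES[data.dtype]
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim == 2:
        x = x.mean(axis=1)
    if rate != TARGET_RATE_HZ:
        frac = Fraction(TARGET_RATE_HZ, int(rate)).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
    return Waveform(np.clip(x, -1.0, 1.0), TARGET_RATE_HZ)


def write_wav(path, x: Waveform) -> None:
    """Write a waveform as 16-bit PCM."""
    pcm = np.clip(x.samples, -1.0, 1.0)
    wavfile.write(path, x.sample_rate_hz, (pcm * 32767.0).astype(np.int16))


# ---------------------------------------------------------------------------
# Synthetic stimuli
# ---------------------------------------------------------------------------


def _formant_filter(x: np.ndarray, fc: float, bw: float, fs: float) -> np.ndarray:
    # two-pole resonator, unity gain at resonance
    r = np.exp(-np.pi * bw / fs)
    theta = 2.0 * np.pi * fc / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    b = [(1.0 - r) * np.sqrt(1.0 - 2.0 * r * np.cos(2.0 * theta) + r * r)]
    return lfilter(b, a, x)


def synthesize_utterance(
    duration_s: float = 2.5,
    seed: int = 0,
    sample_rate_hz: int = TARGET_RATE_HZ,
    target_rms: float = 0.1,
) -> Waveform:
    """Generate a deterministic speech-like utterance.

    The signal is a sawtooth-like glottal source with a drifting fundamental
    in 90-220 Hz, shaped by three random formant resonances, modulated at a
    syllabic 3-5 Hz rate, with one or two brief silent gaps.  Most of its
    power lies below 4 kHz, like natural speech.
    """
    if not duration_s > 0:
        raise AudioError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    fs = float(sample_rate_hz)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    f0 = rng.uniform(90.0, 220.0)
    drift = 1.0 + 0.08 * np.sin(2.0 * np.pi * rng.uniform(0.3, 1.2) * t + rng.uniform(0, 2 * np.pi))
    phase = np.cumsum(f0 * drift) / fs
    source = 2.0 * (phase % 1.0) - 1.0  # sawtooth: harmonics fall off as 1/k
    source += 0.03 * rng.standard_normal(n)  # aspiration noise

    voiced = np.zeros(n)
    f1 = rng.uniform(300.0, 800.0)
    f2 = rng.uniform(900.0, 2200.0)
    f3 = rng.uniform(2300.0, 3200.0)
    for fc, bw in ((f1, 80.0), (f2, 120.0), (f3, 160.0)):
        voiced += _formant_filter(source, fc, bw, fs)

    syllable_hz = rng.uniform(3.0, 5.0)
    env = 0.5 * (1.0 - np.cos(2.0 * np.pi * syllable_hz * t + rng.uniform(0, 2 * np.pi)))
    env = env**0.7

    # one or two word gaps of 100-200 ms, smoothed to avoid clicks
    gate = np.ones(n)
    for _ in range(int(rng.integers(1, 3))):
        gap = int(rng.uniform(0.10, 0.20) * fs)
        if gap < n:
            start = int(rng.integers(0, n - gap))
            gate[start : start + gap] = 0.0
    smooth = int(0.010 * fs)
    if smooth > 1:
        gate = np.convolve(gate, np.ones(smooth) / smooth, mode="same")

    x = voiced * env * gate
    rms = np.sqrt(np.mean(x**2))
    if rms <= 0:
        raise AudioError("synthesized utterance is silent")
    x *= target_rms / rms
    return Waveform(np.clip(x, -1.0, 1.0), sample_rate_hz)


def synthesize_babble(
    n_talkers: int = 8,
    duration_s: float = 2.5,
    seed: int = 0,
    sample_rate_hz: int = TARGET_RATE_HZ,
) -> Waveform:
    """Multi-talker babble: the sum of independent utterance streams.

    The sum is RMS-normalized to 1/sqrt(2) of full scale; the mixer rescales
    it anyway when a target SNR is imposed.
    """
    if n_talkers < 2:
        raise AudioError("babble requires at least 2 talkers")
    if not duration_s > 0:
        raise AudioError("duration_s must be positive")
    seeds = np.random.SeedSequence(seed).spawn(n_talkers)
    n = int(round(duration_s * sample_rate_hz))
    total = np.zeros(n)
    for child in seeds:
        talker_seed = int(child.generate_state(1)[0] % (2**31))
        total += synthesize_utterance(duration_s, talker_seed, sample_rate_hz).samples[:n]
    rms = np.sqrt(np.mean(total**2))
    total *= (1.0 / np.sqrt(2.0)) / rms
    # not clipped: the mixer rescales the babble far below full scale anyway,
    # and hard clipping would distort its amplitude statistics
    return Waveform(total, sample_rate_hz)


# ---------------------------------------------------------------------------
# Mixing and normalization
# ---------------------------------------------------------------------------


def mix_at_snr(speech: Waveform, noise: Waveform, snr_db: float) -> Waveform:
    """Add noise to speech at an exact long-term SNR.

    The noise is trimmed to the speech length and rescaled so that
    ``20*log10(rms(speech)/rms(noise))`` equals ``snr_db``.
    """
    if speech.sample_rate_hz != noise.sample_rate_hz:
        raise AudioError("sample rates differ")
    if len(noise) < len(speech):
        raise AudioError("noise must be at least as long as speech")
    noise_cut = noise.samples[: len(speech)]
    rms_s = speech.rms
    rms_n = float(np.sqrt(np.mean(noise_cut**2)))
    if rms_s <= 0:
        raise AudioError("speech has zero RMS")
    if rms_n <= 0:
        raise AudioError("noise has zero RMS")
    gain = (rms_s / rms_n) * 10.0 ** (-snr_db / 20.0)
    return Waveform(speech.samples + gain * noise_cut, speech.sample_rate_hz)


def rms_normalize(x: Waveform, target_rms: float) -> Waveform:
    """Scale a waveform to an exact RMS, preserving its shape."""
    if not target_rms > 0:
        raise AudioError("target_rms must be positive")
    rms = x.rms
    if rms <= 0:
        raise AudioError("cannot normalize a silent waveform")
    return Waveform(x.samples * (target_rms / rms), x.sample_rate_hz)


def measured_snr_db(mixture: Waveform, speech: Waveform) -> float:
    """Post-hoc SNR of ``mixture = speech + noise`` given the clean speech."""
    noise = mixture.samples - speech.samples[: len(mixture)]
    rms_n = float(np.sqrt(np.mean(noise**2)))
    return 20.0 * np.log10(speech.rms / rms_n)
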