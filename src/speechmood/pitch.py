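"""Fundamental-frequency and pitch-strength estimation by sawtooth-spectrum matching.

The estimator follows the SWIPE' family of algorithms: for each analysis
frame the square-root-compressed magnitude spectrum, resampled on an
ERB-spaced frequency grid, is compared against a bank of sawtooth-harmonic
kernels, one per log-spaced pitch candidate.  The kernel places positive
cosine lobes on the first and prime-numbered harmonics of the candidate
(skipping non-prime multiples suppresses sub-harmonic confusion), negative
valleys between them, and a 1/sqrt(f) amplitude envelope matching the
compressed spectrum of an ideal sawtooth.  Pitch strength is the cosine
similarity between kernel and spectrum, so it is bounded in [-1, 1] and
invariant to amplitude scaling of the input; the per-frame F0 is the
candidate maximizing strength, refined by parabolic interpolation on the
log2-frequency candidate grid.

Each candidate is analysed with a window of roughly eight pitch periods.
Only power-of-two window sizes are computed; a candidate's strength is the
log-distance-weighted blend of the two window sizes bracketing its optimal
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import rfft

__all__ = [
    "AudioSignal",
    "PitchConfig",
    "PitchTrack",
    "hz_to_erb",
    "erb_to_hz",
    "build_kernel",
    "estimate_pitch",
]

# Window size in pitch periods: the Hann-windowed frame spans ~8 periods of
# the candidate at its optimal window size.
_PERIODS_PER_WINDOW = 8.0


@dataclass(frozen=True)
class AudioSignal:
    """A single-channel audio signal.

    Parameters
    ----------
    samples
        Amplitude sequence, dimensionless, nominally in [-1, 1].
    rate
        Sampling frequency in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("AudioSignal requires a single channel (1-D samples)")
        if not np.all(np.isfinite(samples)):
            raise ValueError("AudioSignal samples must be finite")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class PitchConfig:
    """Settings of the pitch estimator.

    Attributes
    ----------
    f_min, f_max
        Pitch search range in Hz.  Defaults 75-500 Hz cover adult male and
        female conversational speech.
    hop
        Frame step in seconds (frames are centred at ``t = i * hop``).
    candidate_step
        Spacing of the log2 pitch-candidate grid, in octaves.
    erb_step
        Spacing of the spectral sampling grid, in ERB units.
    """

    f_min: float = 75.0
    f_max: float = 500.0
    hop: float = 0.010
    candidate_step: float = 1.0 / 96.0
    erb_step: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.hop <= 0:
            raise ValueError("hop must be positive")
        if self.candidate_step <= 0 or self.erb_step <= 0:
            raise ValueError("grid steps must be positive")


@dataclass
class PitchTrack:
    """Per-frame pitch estimates for one recording.

    ``f0`` is NaN on frames with no admissible candidate (e.g. an all-zero
    window); such frames carry strength 0 rather than being dropped, so the
    time axis stays uniform.
    """

    times: np.ndarray
    f0: np.ndarray
    strength: np.ndarray
    rate: float
    hop: float
    config: PitchConfig = field(default_factory=PitchConfig)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.f0 = np.asarray(self.f0, dtype=np.float64)
        self.strength = np.asarray(self.strength, dtype=np.float64)
        n = len(self.times)
        if not (len(self.f0) == len(self.strength) == n):
            raise ValueError("times, f0 and strength must share length")
        if n > 1 and not np.allclose(np.diff(self.times), self.hop, atol=1e-9):
            raise ValueError("times must be uniformly spaced by hop")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def voiced_mask(self) -> np.ndarray:
        """Boolean mask of frames carrying an F0 estimate."""
        return np.isfinite(self.f0)

    @property
    def duration(self) -> float:
        """Nominal track duration: one frame interval per frame."""
        return len(self.times) * self.hop


def hz_to_erb(f):
    """Map frequency in Hz to ERB-number (Cam) scale.

    ERBs(f) = 21.4 * log10(1 + 0.00437 f).
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    out = 21.4 * np.log10(1.0 + 0.00437 * f)
    return float(out) if out.ndim == 0 else out


def erb_to_hz(e):
    """Inverse of :func:`hz_to_erb`."""
    e = np.asarray(e, dtype=np.float64)
    if np.any(e < 0):
        raise ValueError("ERB-number must be non-negative")
    out = (np.power(10.0, e / 21.4) - 1.0) / 0.00437
    return float(out) if out.ndim == 0 else out


def _primes_up_to(n: int) -> np.ndarray:
    if n < 2:
        return np.array([], dtype=int)
    sieve = np.ones(n + 1, dtype=bool)
    sieve[:2] = False
    for p in range(2, int(n**0.5) + 1):
        if sieve[p]:
            sieve[p * p :: p] = False
    return np.nonzero(sieve)[0]


def build_kernel(f_candidate: float, freq_grid: np.ndarray) -> np.ndarray:
    """Sawtooth-spectrum matching kernel for one pitch candidate.

    Positive cosine lobes sit on the candidate's first and prime-numbered
    harmonics, negative half-lobes fill the inter-harmonic valleys, and
    each lobe carries a 1/sqrt(i) weight so the template mirrors the
    square-root-compressed spectrum of an ideal sawtooth.  The returned
    kernel has unit Euclidean norm, so an inner product with a unit-norm
    spectrum is a cosine similarity.
    """
    if f_candidate <= 0:
        raise ValueError("candidate frequency must be positive")
    freq_grid = np.asarray(freq_grid, dtype=np.float64)
    q = freq_grid / f_candidate
    k = np.zeros_like(q)
    n_harm = int(freq_grid[-1] / f_candidate - 0.75)
    for i in np.concatenate(([1], _primes_up_to(n_harm))):
        a = np.abs(q - i)
        w = 1.0 / np.sqrt(i)  # lobe weight decays with harmonic frequency
        peak = a < 0.25
        k[peak] = w * np.cos(2.0 * np.pi * q[peak])
        valley = (0.25 < a) & (a < 0.75)
        k[valley] += w * np.cos(2.0 * np.pi * q[valley]) / 2.0
    # the support starts at the first lobe: no valley below the fundamental
    k[q < 0.75] = 0.0
    norm = np.linalg.norm(k)
    if norm > 0:
        k /= norm
    return k


def _frame_signal(x: np.ndarray, centers: np.ndarray, size: int) -> np.ndarray:
    """Extract zero-padded frames of ``size`` samples centred on ``centers``."""
    n = len(x)
    half = size // 2
    frames = np.zeros((len(centers), size))
    for j, c in enumerate(centers):
        lo = c - half
        hi = lo + size
        src_lo, src_hi = max(lo, 0), min(hi, n)
        if src_lo < src_hi:
            frames[j, src_lo - lo : src_hi - lo] = x[src_lo:src_hi]
    return frames


def estimate_pitch(audio: AudioSignal, config: PitchConfig | None = None) -> PitchTrack:
    """Estimate per-frame F0 and pitch strength.

    Frames are centred at ``t = i * hop`` starting at 0; windows are
    zero-padded at the signal edges.  The output is invariant to positive
    amplitude scaling of the input (each frame's spectrum is normalised
    before matching).
    """
    if config is None:
        config = PitchConfig()
    x = audio.samples
    rate = audio.rate
    if len(x) == 0:
        raise ValueError("empty audio")
    if config.f_max >= rate / 2:
        raise ValueError("f_max must be below the Nyquist frequency")
    if audio.duration < _PERIODS_PER_WINDOW / config.f_min / 2:
        raise ValueError("audio shorter than one analysis window at f_min")

    # Log2-spaced pitch candidates covering [f_min, f_max].
    n_steps = int(np.floor(np.log2(config.f_max / config.f_min) / config.candidate_step + 1e-12))
    log2pc = np.log2(config.f_min) + np.arange(n_steps + 1) * config.candidate_step
    pc = np.power(2.0, log2pc)

    # ERB-spaced spectral grid from a quarter of the lowest candidate to Nyquist.
    f_erb = erb_to_hz(
        np.arange(hz_to_erb(config.f_min / 4.0), hz_to_erb(rate / 2.0), config.erb_step)
    )
    f_erb = np.asarray(f_erb)

    # One kernel per candidate; the grid is shared by all window sizes.
    kernels = np.vstack([build_kernel(p, f_erb) for p in pc])

    # Power-of-two window sizes bracketing ~8 periods of every candidate.
    exp_hi = int(round(np.log2(_PERIODS_PER_WINDOW * rate / config.f_min)))
    exp_lo = int(round(np.log2(_PERIODS_PER_WINDOW * rate / config.f_max)))
    sizes = [2**e for e in range(exp_hi, exp_lo - 1, -1)]
    p_opt = np.array([_PERIODS_PER_WINDOW * rate / w for w in sizes])
    # Candidate position on the window-size axis: d = i exactly at the
    # optimal pitch of the i-th (1-based) window size.
    d = 1.0 + log2pc - np.log2(p_opt[0])

    n_frames = int(np.floor(audio.duration / config.hop)) + 1
    times = np.arange(n_frames) * config.hop
    centers = np.round(times * rate).astype(int)

    strength = np.zeros((len(pc), n_frames))
    any_energy = np.zeros(n_frames, dtype=bool)

    chunk = 256
    for i, size in enumerate(sizes, start=1):
        window = np.hanning(size)
        bin_step = rate / size
        # Linear-interpolation gather from uniform FFT bins onto the ERB grid.
        pos = f_erb / bin_step
        i0 = np.minimum(pos.astype(int), size // 2 - 1)
        w1 = pos - i0

        if len(sizes) == 1:
            sel = np.arange(len(pc))
        elif i == len(sizes):
            sel = np.nonzero(d - i > -1)[0]
        elif i == 1:
            sel = np.nonzero(d - i < 1)[0]
        else:
            sel = np.nonzero(np.abs(d - i) < 1)[0]
        mu = 1.0 - np.abs(d[sel] - i)
        if i == 1:
            mu[d[sel] < i] = 1.0
        if i == len(sizes):
            mu[d[sel] > i] = 1.0

        for lo in range(0, n_frames, chunk):
            hi = min(lo + chunk, n_frames)
            frames = _frame_signal(x, centers[lo:hi], size) * window
            mag = np.abs(rfft(frames, axis=1))
            loud = np.sqrt(mag[:, i0] * (1.0 - w1) + mag[:, i0 + 1] * w1)
            norms = np.linalg.norm(loud, axis=1)
            ok = norms > 0
            any_energy[lo:hi] |= ok
            loud[ok] /= norms[ok, None]
            loud[~ok] = 0.0
            strength[np.ix_(sel, np.arange(lo, hi))] += mu[:, None] * (
                kernels[sel] @ loud.T
            )

    f0 = np.full(n_frames, np.nan)
    out_strength = np.zeros(n_frames)
    best = np.argmax(strength, axis=0)
    for j in range(n_frames):
        if not any_energy[j]:
            continue
        b = best[j]
        s = strength[b, j]
        log2f = log2pc[b]
        if 0 < b < len(pc) - 1:
            s_m, s_p = strength[b - 1, j], strength[b + 1, j]
            denom = s_m - 2.0 * s + s_p
            if denom < 0:
                shift = min(max(0.5 * (s_m - s_p) / denom, -0.5), 0.5)
                log2f += shift * config.candidate_step
                s -= 0.25 * (s_m - s_p) * shift
        f0[j] = min(max(2.0**log2f, config.f_min), config.f_max)
        out_strength[j] = min(max(s, -1.0), 1.0)

    return PitchTrack(
        times=times, f0=f0, strength=out_strength, rate=rate, hop=config.hop, config=config
    )
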