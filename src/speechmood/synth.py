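"""Synthetic running-speech generator with exact ground truth.

A script is a list of events — voiced, unvoiced or silence — rendered back
to back.  Voiced events are sums of harmonics with 1/k amplitudes (a
sawtooth-like spectrum, the positive control for a sawtooth-matching pitch
estimator) whose fundamental follows a linear contour from ``f0_start`` to
``f0_end``.  Cycle-to-cycle jitter is injected at the period level: each
pitch period's instantaneous F0 is multiplied by (1 + eps) with eps drawn
from a zero-mean normal of standard deviation ``jitter_level``, which is
exactly the perturbation that local relative jitter measures downstream.
Unvoiced events are white Gaussian noise; silence is zeros.  The result
carries the true segment boundaries, F0 contour and expected per-event
features, so every downstream module can be tested without a recording.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .pitch import AudioSignal
from .segmentation import VoicedSegment

__all__ = [
    "SynthEvent",
    "SynthResult",
    "render",
    "truth_features",
    "standard_script",
    "load_script",
    "save_script",
]

# RMS of unvoiced noise relative to the event amplitude; keeps fricative-like
# noise at an intensity comparable to the voiced events.
_NOISE_RMS = 0.25


@dataclass(frozen=True)
class SynthEvent:
    """One scripted event.

    ``f0_start``/``f0_end`` (Hz), ``n_harmonics`` and ``jitter_level`` only
    matter for voiced events.  ``jitter_level`` is the relative standard
    deviation of the period-level F0 perturbation.
    """

    kind: str
    duration: float
    f0_start: float = 0.0
    f0_end: float = 0.0
    n_harmonics: int = 10
    jitter_level: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("voiced", "unvoiced", "silence"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.kind == "voiced" and (self.f0_start <= 0 or self.f0_end <= 0):
            raise ValueError("voiced events need positive F0")
        if self.jitter_level < 0:
            raise ValueError("jitter_level must be >= 0")


@dataclass
class SynthResult:
    """Rendered audio plus its ground truth."""

    audio: AudioSignal
    truth_segments: list[VoicedSegment]
    truth_f0: list[tuple[float, float, float, float]]  # (t0, t1, f0_start, f0_end)
    truth_features: list[tuple[float, float]]  # per voiced event (mean_f0, jitter)

    def true_f0_at(self, t: np.ndarray) -> np.ndarray:
        """True F0 contour sampled at times ``t`` (NaN outside voiced events)."""
        t = np.asarray(t, dtype=np.float64)
        out = np.full(t.shape, np.nan)
        for t0, t1, fa, fb in self.truth_f0:
            m = (t >= t0) & (t < t1)
            out[m] = fa + (fb - fa) * (t[m] - t0) / (t1 - t0)
        return out


def _render_voiced(event: SynthEvent, rate: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(event.duration * rate))
    f_lo = min(event.f0_start, event.f0_end)
    f_hi = max(event.f0_start, event.f0_end)
    if f_hi >= rate / 4:
        raise ValueError("fundamental too high for the sampling rate (aliasing)")
    # Cap harmonics below Nyquist (with a small guard band).
    k_max = max(1, min(event.n_harmonics, int(0.95 * (rate / 2) / f_hi)))

    # Walk period by period: each period gets one jittered instantaneous F0.
    inst_f0 = np.empty(n)
    t = 0.0
    i = 0
    while i < n:
        frac = t / event.duration
        f_contour = event.f0_start + (event.f0_end - event.f0_start) * frac
        f = f_contour
        if event.jitter_level > 0:
            f = f_contour * (1.0 + rng.normal(0.0, event.jitter_level))
            f = max(f, 0.2 * f_lo)
        period = 1.0 / f
        j = min(n, i + max(1, int(round(period * rate))))
        inst_f0[i:j] = f
        t += period
        i = j

    phase = 2.0 * np.pi * np.cumsum(inst_f0) / rate
    amps = 1.0 / np.arange(1, k_max + 1)
    x = np.zeros(n)
    for k, a in enumerate(amps, start=1):
        x += a * np.sin(k * phase)
    x *= event.amplitude / np.sum(amps)
    return x


def render(script: Sequence[SynthEvent], rate: float = 48000.0, seed: int = 0) -> SynthResult:
    """Render a script into audio with ground truth.

    Identical (script, rate, seed) triples produce bit-identical output.
    """
    if len(script) == 0:
        raise ValueError("script must contain at least one event")
    rng = np.random.default_rng(seed)
    chunks: list[np.ndarray] = []
    segments: list[VoicedSegment] = []
    contours: list[tuple[float, float, float, float]] = []
    expected: list[tuple[float, float]] = []
    t = 0.0
    for event in script:
        n = int(round(event.duration * rate))
        if event.kind == "voiced":
            chunks.append(_render_voiced(event, rate, rng))
            segments.append(VoicedSegment(start=t, end=t + event.duration))
            contours.append((t, t + event.duration, event.f0_start, event.f0_end))
            expected.append(((event.f0_start + event.f0_end) / 2.0, event.jitter_level))
        elif event.kind == "unvoiced":
            chunks.append(event.amplitude * _NOISE_RMS * rng.standard_normal(n))
        else:
            chunks.append(np.zeros(n))
        t += event.duration
    samples = np.concatenate(chunks)
    peak = np.max(np.abs(samples))
    if peak > 1.0:
        samples = samples / peak
    return SynthResult(
        audio=AudioSignal(samples=samples, rate=rate),
        truth_segments=segments,
        truth_f0=contours,
        truth_features=expected,
    )


def truth_features(script: Sequence[SynthEvent]) -> list[tuple[float, float]]:
    """Expected (mean_f0, jitter) per voiced event.

    mean_f0 is the time average of the linear contour.  The injected
    jitter_level is returned as the expected jitter; the downstream
    measurement sits in a band around it (roughly a factor of two either
    way) because frame-based tracking smooths period-level perturbations.
    """
    return [
        ((e.f0_start + e.f0_end) / 2.0, e.jitter_level)
        for e in script
        if e.kind == "voiced"
    ]


def standard_script(total: float = 30.0, jitter_level: float = 0.0) -> list[SynthEvent]:
    """The standard running-speech fixture: alternating voiced/noise/silence.

    A repeating pattern of voiced events at varied F0 (120-320 Hz, level
    and gliding contours), fricative-like noise bursts and pauses, tiled
    until ``total`` seconds are covered.  Roughly half the timeline is
    voiced, emulating the voiced fraction of read speech.
    """
    pattern = [
        SynthEvent("voiced", 0.60, 180.0, 220.0, jitter_level=jitter_level),
        SynthEvent("unvoiced", 0.25),
        SynthEvent("voiced", 0.40, 120.0, 120.0, jitter_level=jitter_level),
        SynthEvent("silence", 0.30),
        SynthEvent("voiced", 0.50, 260.0, 300.0, jitter_level=jitter_level),
        SynthEvent("unvoiced", 0.20),
        SynthEvent("silence", 0.25),
        SynthEvent("voiced", 0.35, 320.0, 280.0, jitter_level=jitter_level),
        SynthEvent("silence", 0.15),
    ]
    script: list[SynthEvent] = []
    t = 0.0
    i = 0
    while t < total:
        e = pattern[i % len(pattern)]
        if t + e.duration > total:
            break
        script.append(e)
        t += e.duration
        i += 1
    return script


def save_script(script: Sequence[SynthEvent], path: str | Path) -> None:
    """Write a script file: one whitespace-separated event per line."""
    lines = ["# kind duration f0_start f0_end n_harmonics jitter_level amplitude"]
    for e in script:
        lines.append(
            f"{e.kind} {e.duration:g} {e.f0_start:g} {e.f0_end:g} "
            f"{e.n_harmonics:d} {e.jitter_level:g} {e.amplitude:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_script(path: str | Path) -> list[SynthEvent]:
    """Read a script file written by :func:`save_script`."""
    script = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: need at least 'kind duration'")
        kind, duration = parts[0], float(parts[1])
        extra = [float(p) for p in parts[2:]]
        defaults = [0.0, 0.0, 10, 0.0, 1.0]
        vals = extra + defaults[len(extra):]
        script.append(
            SynthEvent(
                kind=kind,
                duration=duration,
                f0_start=vals[0],
                f0_end=vals[1],
                n_harmonics=int(vals[2]),
                jitter_level=vals[3],
                amplitude=vals[4],
            )
        )
    return script
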