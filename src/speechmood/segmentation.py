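"""Voiced-segment detection and operating-threshold selection.

Two detectors are provided.  The device-style method thresholds the pitch
strength of an existing track: a frame is voiced when its strength strictly
exceeds the threshold, and maximal runs of voiced frames become segments.
The reference method works on the waveform directly, labelling frames
voiced when their RMS energy is high (above a quantile of all frame
energies) and their zero-crossing rate is low — the classic
intensity + ZCR rule used by ground-truth segmenters.

The operating threshold is chosen from a specificity/sensitivity sweep:
among thresholds achieving specificity > 0.9 and sensitivity > 0.6 against
a reference segmentation, the most sensitive one is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pitch import AudioSignal, PitchTrack

__all__ = [
    "VoicedSegment",
    "SegmentationParams",
    "ThresholdCurve",
    "NoAdmissibleThresholdError",
    "segment_by_strength",
    "segment_by_intensity_zcr",
    "sweep_threshold",
    "choose_threshold",
]


class NoAdmissibleThresholdError(ValueError):
    """No threshold meets the specificity/sensitivity requirements."""


@dataclass(frozen=True)
class VoicedSegment:
    """A contiguous voiced time interval.

    ``first_frame``/``last_frame`` are the inclusive indices of the frames
    forming the segment (meaningful when derived from a track; -1 when the
    segment came from an external source such as a TSV file).
    """

    start: float
    end: float
    first_frame: int = -1
    last_frame: int = -1

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("need 0 <= start < end")

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of both segmentation methods.

    strength_threshold : pitch-strength cut for the device-style method.
    min_segment       : minimum segment duration kept, seconds.
    frame             : energy/ZCR analysis frame length, seconds.
    energy_quantile   : voiced frames must exceed this quantile of frame
                        RMS energies.  The default 0.3 makes the energy
                        gate a silence rejector (silence rarely exceeds a
                        third of a running-speech timeline); separating
                        voiced speech from fricative noise is the ZCR
                        gate's job.
    zcr_threshold     : voiced frames must stay below this zero-crossing
                        rate, in crossings per second.
    """

    strength_threshold: float = 0.30
    min_segment: float = 0.02
    frame: float = 0.030
    energy_quantile: float = 0.3
    zcr_threshold: float = 3000.0

    def __post_init__(self) -> None:
        if not (-1.0 <= self.strength_threshold <= 1.0):
            raise ValueError("strength_threshold must lie in [-1, 1]")
        if self.min_segment < 0:
            raise ValueError("min_segment must be >= 0")
        if not (0 < self.energy_quantile < 1):
            raise ValueError("energy_quantile must lie in (0, 1)")


@dataclass(frozen=True)
class ThresholdCurve:
    """Specificity/sensitivity as functions of the strength threshold."""

    thresholds: np.ndarray
    specificity: np.ndarray
    sensitivity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=np.float64)
        sp = np.asarray(self.specificity, dtype=np.float64)
        se = np.asarray(self.sensitivity, dtype=np.float64)
        if not (len(t) == len(sp) == len(se)):
            raise ValueError("curve arrays must share length")
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "specificity", sp)
        object.__setattr__(self, "sensitivity", se)


def _runs_to_segments(
    mask: np.ndarray, times: np.ndarray, hop: float, min_segment: float
) -> list[VoicedSegment]:
    """Turn maximal True-runs of a frame mask into segments.

    A frame centred at t covers [t - hop/2, t + hop/2]; segment starts are
    clipped at 0 so segments stay inside the recording.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(int)
    edges = np.diff(padded)
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0] - 1
    out = []
    for a, b in zip(starts, ends):
        seg = VoicedSegment(
            start=max(times[a] - hop / 2.0, 0.0),
            end=times[b] + hop / 2.0,
            first_frame=int(a),
            last_frame=int(b),
        )
        if seg.length >= min_segment and seg.length > 0:
            out.append(seg)
    return out


def segment_by_strength(
    track: PitchTrack, params: SegmentationParams | None = None
) -> list[VoicedSegment]:
    """Voiced segments as maximal runs of frames with strength > threshold."""
    if params is None:
        params = SegmentationParams()
    if len(track) == 0:
        raise ValueError("empty track")
    mask = track.strength > params.strength_threshold
    return _runs_to_segments(mask, track.times, track.hop, params.min_segment)


def segment_by_intensity_zcr(
    audio: AudioSignal,
    params: SegmentationParams | None = None,
    hop: float = 0.010,
) -> list[VoicedSegment]:
    """Reference voiced detection from RMS energy and zero-crossing rate.

    Frames of ``params.frame`` seconds, stepped by ``hop`` and centred at
    ``t = i * hop``, are voiced when their RMS energy strictly exceeds the
    ``energy_quantile`` quantile of all frame energies and their
    zero-crossing rate is below ``zcr_threshold`` crossings/s.
    """
    if params is None:
        params = SegmentationParams()
    x = audio.samples
    frame_len = int(round(params.frame * audio.rate))
    if len(x) <= frame_len:
        raise ValueError("audio shorter than one analysis frame")
    n_frames = int(np.floor(audio.duration / hop)) + 1
    times = np.arange(n_frames) * hop
    centers = np.round(times * audio.rate).astype(int)
    half = frame_len // 2

    energy = np.zeros(n_frames)
    zcr = np.zeros(n_frames)
    for j, c in enumerate(centers):
        lo, hi = max(c - half, 0), min(c - half + frame_len, len(x))
        w = x[lo:hi]
        if len(w) == 0:
            continue
        energy[j] = np.sqrt(np.mean(w * w))
        if len(w) > 1:
            crossings = np.count_nonzero(np.diff(np.signbit(w)))
            zcr[j] = crossings * audio.rate / (len(w) - 1)
    cut = np.quantile(energy, params.energy_quantile)
    mask = (energy > cut) & (zcr < params.zcr_threshold)
    return _runs_to_segments(mask, times, hop, params.min_segment)


def sweep_threshold(
    track: PitchTrack,
    reference: Sequence[VoicedSegment],
    thresholds: Sequence[float],
    grid_step: float = 0.001,
) -> ThresholdCurve:
    """Frame-level specificity/sensitivity of strength segmentation vs a reference.

    ``min_segment`` is held at 0 during the sweep so the curve reflects the
    thresholding rule alone.
    """
    from .evaluation import frame_confusion

    thresholds = np.asarray(list(thresholds), dtype=np.float64)
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    if len(reference) == 0:
        raise ValueError("reference segmentation is empty")
    duration = max(track.duration, max(s.end for s in reference))
    spec = np.zeros_like(thresholds)
    sens = np.zeros_like(thresholds)
    for i, th in enumerate(thresholds):
        params = SegmentationParams(strength_threshold=float(np.clip(th, -1, 1)),
                                    min_segment=0.0)
        segs = segment_by_strength(track, params)
        conf = frame_confusion(segs, list(reference), duration, grid_step)
        spec[i] = conf.specificity
        sens[i] = conf.sensitivity
    return ThresholdCurve(thresholds=thresholds, specificity=spec, sensitivity=sens)


def choose_threshold(
    curve: ThresholdCurve, min_spec: float = 0.9, min_sens: float = 0.6
) -> float:
    """Most sensitive threshold with specificity > min_spec and sensitivity > min_sens.

    Ties on sensitivity resolve to the smallest threshold.  Raises
    :class:`NoAdmissibleThresholdError` when no threshold qualifies.
    """
    if len(curve.thresholds) == 0:
        raise ValueError("empty threshold curve")
    ok = (curve.specificity > min_spec) & (curve.sensitivity > min_sens)
    if not ok.any():
        raise NoAdmissibleThresholdError(
            f"no threshold reaches specificity > {min_spec} and sensitivity > {min_sens}"
        )
    idx = np.nonzero(ok)[0]
    best_sens = curve.sensitivity[idx].max()
    winners = idx[curve.sensitivity[idx] == best_sens]
    return float(curve.thresholds[winners].min())
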