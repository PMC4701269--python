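"""Per-segment prosodic features and their cross-segment summaries.

Each voiced segment yields three F0-based features: the mean F0, the
sample standard deviation of F0 (stdF0), and jitter.  Jitter is the local
relative kind: the mean absolute difference between consecutive pitch
periods divided by the mean period, computed from the frame-wise periods
T(i) = 1/F0(i).  Across the segments of one recording each feature is
summarised by its median, median absolute deviation (MAD, unscaled) and
moment skewness — robust statistics suited to the strongly non-Gaussian
feature distributions of running speech.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .pitch import PitchTrack
from .segmentation import VoicedSegment

__all__ = [
    "SegmentFeatures",
    "FeatureSummary",
    "FEATURE_NAMES",
    "SUMMARY_STATS",
    "segment_features",
    "summarize",
    "features_from_f0",
]

FEATURE_NAMES = ("mean_f0", "std_f0", "jitter")
SUMMARY_STATS = ("median", "mad", "skewness")


@dataclass(frozen=True)
class SegmentFeatures:
    """Prosodic features of a single voiced segment.

    ``std_f0`` and ``jitter`` are NaN when the segment holds a single
    frame (variability undefined).
    """

    segment_id: int
    mean_f0: float
    std_f0: float
    jitter: float
    n_frames: int
    start: float = float("nan")
    end: float = float("nan")


@dataclass(frozen=True)
class FeatureSummary:
    """Median / MAD / skewness of each feature across segments.

    ``values[stat][feature]`` holds the summary, e.g.
    ``values["mad"]["mean_f0"]`` is the MAD of the per-segment mean F0 —
    the longitudinal marker MAD_meanF0.  Skewness is NaN below three
    segments.
    """

    values: dict
    n_segments: int

    def as_dict(self) -> dict[str, float]:
        """Flatten to ``{"<stat>_<feature>": value}`` (e.g. ``mad_mean_f0``)."""
        return {
            f"{stat}_{feat}": self.values[stat][feat]
            for stat in SUMMARY_STATS
            for feat in FEATURE_NAMES
        }


def features_from_f0(f0: np.ndarray) -> tuple[float, float, float]:
    """(mean_f0, std_f0, jitter) from a segment's frame-wise F0 values."""
    f0 = np.asarray(f0, dtype=np.float64)
    if len(f0) < 1:
        raise ValueError("a segment needs at least one frame")
    if not np.all(np.isfinite(f0)) or np.any(f0 <= 0):
        raise ValueError("segment frames must carry positive, non-missing F0")
    mean_f0 = float(np.mean(f0))
    if len(f0) < 2:
        return mean_f0, math.nan, math.nan
    std_f0 = float(np.std(f0, ddof=1))
    periods = 1.0 / f0
    jitter = float(np.mean(np.abs(np.diff(periods))) / np.mean(periods))
    return mean_f0, std_f0, jitter


def segment_features(track: PitchTrack, segment: VoicedSegment) -> SegmentFeatures:
    """Compute the features of one voiced segment from its track frames."""
    if segment.first_frame >= 0:
        f0 = track.f0[segment.first_frame : segment.last_frame + 1]
    else:
        mask = (track.times >= segment.start) & (track.times <= segment.end)
        f0 = track.f0[mask]
    mean_f0, std_f0, jitter = features_from_f0(f0)
    return SegmentFeatures(
        segment_id=segment.first_frame,
        mean_f0=mean_f0,
        std_f0=std_f0,
        jitter=jitter,
        n_frames=len(f0),
        start=segment.start,
        end=segment.end,
    )


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def summarize(features: Sequence[SegmentFeatures]) -> FeatureSummary:
    """Median, MAD and skewness of each feature across segments.

    Segments where a feature is undefined (single-frame segments have no
    stdF0/jitter) are dropped for that feature only.
    """
    if len(features) == 0:
        raise ValueError("cannot summarise an empty feature list")
    values: dict[str, dict[str, float]] = {stat: {} for stat in SUMMARY_STATS}
    for feat in FEATURE_NAMES:
        x = np.array([getattr(f, feat) for f in features], dtype=np.float64)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            for stat in SUMMARY_STATS:
                values[stat][feat] = math.nan
            continue
        values["median"][feat] = float(np.median(x))
        values["mad"][feat] = _mad(x)
        if len(x) < 3 or np.ptp(x) == 0:  # skewness of constant data is 0/0
            values["skewness"][feat] = math.nan
        else:
            values["skewness"][feat] = float(stats.skew(x))
    return FeatureSummary(values=values, n_segments=len(features))
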