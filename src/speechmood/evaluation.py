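"""Agreement statistics between two voiced-segmentation / feature chains.

Agreement is quantified three ways, mirroring how a phone-based analysis
chain is validated against a high-quality reference chain:

* frame-level sensitivity/specificity of voiced detection, computed on a
  fine common time grid so that chains with different internal hops can be
  compared;
* Pearson correlation of features recomputed on the *overlapping portions*
  of matched segments (overlap-restricted features remove the influence of
  boundary disagreements);
* two-sample Kolmogorov–Smirnov comparison of feature distributions, with
  an exact permutation p-value for small samples and the asymptotic
  Kolmogorov distribution otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import special, stats

from .features import features_from_f0
from .pitch import PitchTrack
from .segmentation import VoicedSegment

__all__ = [
    "FrameConfusion",
    "MatchedPair",
    "CorrelationResult",
    "UndefinedCorrelationError",
    "frame_confusion",
    "match_segments",
    "correlate_matched",
    "ks_compare",
]

# Exact KS enumeration is used up to this pooled sample size.
_KS_EXACT_MAX = 12


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (zero variance or too few observations)."""


@dataclass(frozen=True)
class FrameConfusion:
    """Frame-level confusion counts with the reference chain as truth."""

    tp: int
    fp: int
    tn: int
    fn: int
    grid_step: float

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) > 0 else math.nan


@dataclass(frozen=True)
class MatchedPair:
    """A reference segment paired with its best-overlapping test segment."""

    ref_segment: VoicedSegment
    test_segment: VoicedSegment
    overlap_start: float
    overlap_end: float

    def __post_init__(self) -> None:
        if not self.overlap_start < self.overlap_end:
            raise ValueError("overlap interval must be non-empty")

    @property
    def overlap(self) -> float:
        return self.overlap_end - self.overlap_start


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def _voiced_mask(segments: Sequence[VoicedSegment], centers: np.ndarray) -> np.ndarray:
    """True where a grid-cell centre lies inside a segment (half-open)."""
    mask = np.zeros(len(centers), dtype=bool)
    for seg in segments:
        mask |= (centers >= seg.start) & (centers < seg.end)
    return mask


def frame_confusion(
    test: Sequence[VoicedSegment],
    reference: Sequence[VoicedSegment],
    duration: float,
    grid_step: float = 0.001,
) -> FrameConfusion:
    """Rasterize both segment lists to a common grid and count agreement.

    A cell is voiced when its centre falls inside a segment; the reference
    is taken as the truth.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    n = int(np.ceil(duration / grid_step))
    centers = (np.arange(n) + 0.5) * grid_step
    ref = _voiced_mask(reference, centers)
    tst = _voiced_mask(test, centers)
    tp = int(np.count_nonzero(ref & tst))
    fn = int(np.count_nonzero(ref & ~tst))
    fp = int(np.count_nonzero(~ref & tst))
    tn = int(np.count_nonzero(~ref & ~tst))
    return FrameConfusion(tp=tp, fp=fp, tn=tn, fn=fn, grid_step=grid_step)


def match_segments(
    test: Sequence[VoicedSegment],
    reference: Sequence[VoicedSegment],
    min_overlap: float = 0.02,
) -> list[MatchedPair]:
    """Greedily pair each reference segment with its best-overlapping test segment.

    Candidate (reference, test) pairs are ranked by descending temporal
    overlap; each segment on either side is used at most once, and pairs
    with overlap below ``min_overlap`` seconds are discarded.
    """
    cands = []
    for ri, r in enumerate(reference):
        for ti, t in enumerate(test):
            lo, hi = max(r.start, t.start), min(r.end, t.end)
            if hi - lo >= min_overlap and hi > lo:
                cands.append((hi - lo, ri, ti, lo, hi))
    cands.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs = []
    for _, ri, ti, lo, hi in cands:
        if ri in used_ref or ti in used_test:
            continue
        used_ref.add(ri)
        used_test.add(ti)
        pairs.append(
            MatchedPair(
                ref_segment=reference[ri],
                test_segment=test[ti],
                overlap_start=lo,
                overlap_end=hi,
            )
        )
    pairs.sort(key=lambda p: p.overlap_start)
    return pairs


def _overlap_feature(track: PitchTrack, lo: float, hi: float, feature: str) -> float:
    mask = (track.times >= lo) & (track.times <= hi) & np.isfinite(track.f0)
    f0 = track.f0[mask]
    if len(f0) == 0:
        return math.nan
    mean_f0, std_f0, jitter = features_from_f0(f0)
    return {"mean_f0": mean_f0, "std_f0": std_f0, "jitter": jitter}[feature]


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value (n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 3 or len(y) != n:
        raise UndefinedCorrelationError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r = float(np.corrcoef(x, y)[0, 1])
    r = min(max(r, -1.0), 1.0)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=r, p_value=p, n=n)


def correlate_matched(
    pairs: Sequence[MatchedPair],
    track_ref: PitchTrack,
    track_test: PitchTrack,
    feature: str,
) -> CorrelationResult:
    """Correlate a feature recomputed on the overlap interval of each pair.

    The feature (``mean_f0`` | ``std_f0`` | ``jitter``) is evaluated on the
    frames of each track whose centres fall inside the pair's intersection
    interval; pairs where the feature is undefined in either track are
    dropped.
    """
    if feature not in ("mean_f0", "std_f0", "jitter"):
        raise ValueError(f"unknown feature {feature!r}")
    if len(pairs) < 3:
        raise UndefinedCorrelationError("need at least 3 matched pairs")
    xs, ys = [], []
    for p in pairs:
        a = _overlap_feature(track_ref, p.overlap_start, p.overlap_end, feature)
        b = _overlap_feature(track_test, p.overlap_start, p.overlap_end, feature)
        if math.isfinite(a) and math.isfinite(b):
            xs.append(a)
            ys.append(b)
    if len(xs) < 3:
        raise UndefinedCorrelationError("fewer than 3 pairs with defined features")
    return pearson(np.array(xs), np.array(ys))


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """sup_x |ECDF_a(x) - ECDF_b(x)|."""
    all_vals = np.concatenate([a, b])
    cdf_a = np.searchsorted(np.sort(a), all_vals, side="right") / len(a)
    cdf_b = np.searchsorted(np.sort(b), all_vals, side="right") / len(b)
    return float(np.max(np.abs(cdf_a - cdf_b)))


def ks_compare(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    Returns (D, p).  For pooled sizes n_a + n_b <= 12 the p-value is exact,
    by enumerating every assignment of the pooled values to the two
    samples; otherwise it uses the asymptotic Kolmogorov distribution with
    effective size n = n_a n_b / (n_a + n_b).
    """
    a = np.asarray(list(a), dtype=np.float64)
    b = np.asarray(list(b), dtype=np.float64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    d_obs = _ks_statistic(a, b)
    na, nb = len(a), len(b)
    if na + nb <= _KS_EXACT_MAX:
        pooled = np.concatenate([a, b])
        idx = np.arange(na + nb)
        hits = total = 0
        for comb in combinations(idx, na):
            comb = np.array(comb)
            rest = np.setdiff1d(idx, comb, assume_unique=True)
            d = _ks_statistic(pooled[comb], pooled[rest])
            total += 1
            if d >= d_obs - 1e-12:
                hits += 1
        p = hits / total
    else:
        en = na * nb / (na + nb)
        p = float(special.kolmogorov(math.sqrt(en) * d_obs))
    return d_obs, min(max(p, 0.0), 1.0)
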