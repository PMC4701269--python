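"""Evaluation tests: frame confusion, segment matching, correlations, KS test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from speechmood.evaluation import (
    UndefinedCorrelationError,
    correlate_matched,
    frame_confusion,
    ks_compare,
    match_segments,
    pearson,
)
from speechmood.pitch import PitchTrack
from speechmood.segmentation import VoicedSegment


def seg(a, b):
    return VoicedSegment(start=a, end=b)


class TestFrameConfusion:
    def test_identity(self):
        ref = [seg(0.1, 0.4), seg(0.6, 0.9)]
        c = frame_confusion(ref, ref, 1.0)
        assert c.sensitivity == pytest.approx(1.0)
        assert c.specificity == pytest.approx(1.0)

    def test_hand_counted_grid(self):
        # 10 cells of 0.1 s; reference voiced cells {2..5}, test {3..6}
        ref = [seg(0.2, 0.6)]
        tst = [seg(0.3, 0.7)]
        c = frame_confusion(tst, ref, 1.0, grid_step=0.1)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 5)
        assert c.sensitivity == pytest.approx(0.75)
        assert c.specificity == pytest.approx(5.0 / 6.0, abs=1e-4)

    def test_empty_test_list(self):
        c = frame_confusion([], [seg(0.2, 0.5)], 1.0)
        assert c.sensitivity == 0.0
        assert c.specificity == 1.0

    def test_counts_partition_grid(self, rng):
        for _ in range(20):
            edges = np.sort(rng.uniform(0, 1, size=8))
            ref = [seg(edges[0], edges[1]), seg(edges[2], edges[3])]
            tst = [seg(edges[4], edges[5]), seg(edges[6], edges[7])]
            c = frame_confusion(tst, ref, 1.0, grid_step=0.01)
            assert c.tp + c.fp + c.tn + c.fn == 100

    def test_swapping_roles_swaps_errors(self):
        ref, tst = [seg(0.1, 0.5)], [seg(0.3, 0.8)]
        a = frame_confusion(tst, ref, 1.0)
        b = frame_confusion(ref, tst, 1.0)
        assert (a.fp, a.fn) == (b.fn, b.fp)
        assert a.tp == b.tp


class TestMatchSegments:
    def test_identity_pairs_everything(self):
        segs = [seg(0.0, 0.1), seg(0.2, 0.35)]
        pairs = match_segments(segs, segs, min_overlap=0.02)
        assert len(pairs) == 2
        for p in pairs:
            assert p.overlap == pytest.approx(p.ref_segment.length)

    def test_partial_overlap(self):
        pairs = match_segments([seg(0.05, 0.2)], [seg(0.0, 0.1)], min_overlap=0.02)
        assert len(pairs) == 1
        assert pairs[0].overlap_start == pytest.approx(0.05)
        assert pairs[0].overlap_end == pytest.approx(0.1)

    def test_disjoint_gives_empty(self):
        assert match_segments([seg(0.2, 0.3)], [seg(0.0, 0.1)], 0.02) == []

    def test_each_test_segment_used_once(self):
        ref = [seg(0.0, 0.1), seg(0.1, 0.2)]
        tst = [seg(0.0, 0.2)]
        pairs = match_segments(tst, ref, min_overlap=0.02)
        assert len(pairs) == 1
        assert pairs[0].overlap == pytest.approx(0.1)

    def test_reference_indices_unique(self, rng):
        ref = [seg(0.2 + i * 0.2, 0.3 + i * 0.2) for i in range(5)]
        tst = [seg(0.2 + i * 0.2 + rng.uniform(-0.05, 0.05), 0.32 + i * 0.2) for i in range(5)]
        pairs = match_segments(tst, ref, min_overlap=0.02)
        starts = [p.ref_segment.start for p in pairs]
        assert len(starts) == len(set(starts))


def two_tone_track(f0_per_segment, frames_per_segment=10, hop=0.01):
    f0 = np.concatenate([np.full(frames_per_segment, f) for f in f0_per_segment])
    return PitchTrack(
        times=np.arange(len(f0)) * hop,
        f0=f0,
        strength=np.full(len(f0), 0.6),
        rate=48000.0,
        hop=hop,
    )


class TestCorrelateMatched:
    def make_pairs(self, n=4, frames=10, hop=0.01):
        segs = [
            seg(i * frames * hop + 1e-9, (i + 1) * frames * hop - hop / 2)
            for i in range(n)
        ]
        return [
            match_segments([s], [s], min_overlap=0.02)[0] for s in segs
        ]

    def test_identical_tracks_rho_one(self):
        track = two_tone_track([150.0, 200.0, 250.0, 300.0])
        pairs = self.make_pairs()
        res = correlate_matched(pairs, track, track, "mean_f0")
        assert res.rho == pytest.approx(1.0)

    def test_pearson_exact_linear(self):
        res = pearson(np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8]))
        assert res.rho == pytest.approx(1.0)

    def test_pearson_small_sample_p(self):
        res = pearson(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
        assert res.rho == pytest.approx(0.5)
        assert res.p_value == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_affine_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        y = np.array([2.0, 3.0, 1.0, 9.0, 4.0])
        a = pearson(x, y)
        b = pearson(3.0 * x - 7.0, 0.5 * y + 2.0)
        assert b.rho == pytest.approx(a.rho, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        track = two_tone_track([150.0, 200.0])
        with pytest.raises(UndefinedCorrelationError):
            correlate_matched(self.make_pairs(2), track, track, "mean_f0")

    def test_zero_variance_rejected(self):
        track = two_tone_track([200.0, 200.0, 200.0, 200.0])
        with pytest.raises(UndefinedCorrelationError):
            correlate_matched(self.make_pairs(), track, track, "mean_f0")


def ks_oracle(a, b):
    """Brute-force two-sample KS p by enumerating all label assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def d_stat(x, y):
        allv = np.concatenate([x, y])
        return np.max(
            np.abs(
                np.searchsorted(np.sort(x), allv, side="right") / len(x)
                - np.searchsorted(np.sort(y), allv, side="right") / len(y)
            )
        )

    d_obs = d_stat(a, b)
    pooled = np.concatenate([a, b])
    idx = range(len(pooled))
    hits = total = 0
    for comb in itertools.combinations(idx, len(a)):
        rest = [i for i in idx if i not in comb]
        total += 1
        if d_stat(pooled[list(comb)], pooled[rest]) >= d_obs - 1e-12:
            hits += 1
    return d_obs, hits / total


class TestKsCompare:
    def test_identical_samples(self):
        d, p = ks_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert p == 1.0

    def test_fully_separated(self):
        d, p = ks_compare([1, 2, 3], [4, 5, 6])
        assert d == pytest.approx(1.0)
        assert p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments attain D=1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_compare([], [1.0])

    def test_exact_matches_enumeration_all_small_splits(self, rng):
        """Exact p agrees with brute-force enumeration for every (na, nb), na+nb <= 10."""
        for na in range(1, 6):
            for nb in range(1, 6):
                a = rng.normal(size=na)
                b = rng.normal(loc=0.5, size=nb)
                d, p = ks_compare(a, b)
                d_ref, p_ref = ks_oracle(a, b)
                assert d == pytest.approx(d_ref, abs=1e-12)
                assert p == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_scipy(self, rng):
        for _ in range(30):
            a = rng.normal(size=int(rng.integers(2, 6)))
            b = rng.normal(size=int(rng.integers(2, 6)))
            d, p = ks_compare(a, b)
            ref = stats.ks_2samp(a, b, method="exact")
            assert d == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_asymptotic_kolmogorov_branch(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.7, size=40)
        d, p = ks_compare(a, b)
        en = 30 * 40 / 70
        from scipy.special import kolmogorov

        assert p == pytest.approx(float(kolmogorov(math.sqrt(en) * d)), abs=1e-12)
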