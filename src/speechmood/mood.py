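"""Mood-state classification and longitudinal feature–mood correlation.

Clinician assessments carry two scores: the Quick Depression Inventory
(QID; cutoff 8) and the Young Mania Rating Scale (YMRS; cutoff 6).
Crossing the QID cutoff alone marks a depressive state, the YMRS cutoff
alone a hypomanic state, both a mixed state, neither euthymia.  For
longitudinal analysis the non-mixed states are placed on an ordinal axis
running hypomania (1) → euthymia (2) → depression (3); the mixed state
does not fit a one-dimensional mood model and is excluded.

Per-session feature summaries (median/MAD/skewness of mean F0, stdF0 and
jitter across voiced segments) are correlated with the ordinal mood rank
by Spearman rank correlation, with an exact permutation p-value for small
session counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from itertools import islice, permutations

import numpy as np
import pandas as pd
from scipy import stats

from .evaluation import CorrelationResult, UndefinedCorrelationError
from .features import FEATURE_NAMES, SUMMARY_STATS, FeatureSummary

__all__ = [
    "MoodState",
    "MoodAssessment",
    "SessionRecord",
    "MixedStateError",
    "classify_mood",
    "mood_ordinal",
    "spearman",
    "longitudinal_report",
    "synthetic_cohort",
]

logger = logging.getLogger(__name__)

QID_CUTOFF = 8
YMRS_CUTOFF = 6

# Exact permutation enumeration for the Spearman p-value up to this n.
_SPEARMAN_EXACT_MAX = 9


class MoodState(str, Enum):
    HYPOMANIC = "hypomanic"
    EUTHYMIC = "euthymic"
    DEPRESSIVE = "depressive"
    MIXED = "mixed"


class MixedStateError(ValueError):
    """The mixed state has no place on the linear hypomania–depression scale."""


@dataclass(frozen=True)
class MoodAssessment:
    """One clinician assessment with its derived state and ordinal rank."""

    session_id: int
    qid: int
    ymrs: int

    @property
    def state(self) -> MoodState:
        return classify_mood(self.qid, self.ymrs)

    @property
    def ordinal(self) -> float:
        try:
            return mood_ordinal(self.state)
        except MixedStateError:
            return math.nan


@dataclass(frozen=True)
class SessionRecord:
    """One recording session: its assessment and its feature summary."""

    session_id: int
    assessment: MoodAssessment
    summary: FeatureSummary


def classify_mood(
    qid: float, ymrs: float, qid_cut: float = QID_CUTOFF, ymrs_cut: float = YMRS_CUTOFF
) -> MoodState:
    """Classify a (QID, YMRS) score pair into a mood state.

    Scores at or above their cutoff count as symptomatic.
    """
    if qid < 0 or ymrs < 0:
        raise ValueError("scores must be non-negative")
    dep = qid >= qid_cut
    hyp = ymrs >= ymrs_cut
    if dep and hyp:
        return MoodState.MIXED
    if dep:
        return MoodState.DEPRESSIVE
    if hyp:
        return MoodState.HYPOMANIC
    return MoodState.EUTHYMIC


def mood_ordinal(state: MoodState) -> int:
    """Rank the state on the hypomania(1) → euthymia(2) → depression(3) axis."""
    ranks = {MoodState.HYPOMANIC: 1, MoodState.EUTHYMIC: 2, MoodState.DEPRESSIVE: 3}
    if state == MoodState.MIXED:
        raise MixedStateError("mixed state is not on the linear mood scale")
    return ranks[state]


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho: float) -> float:
    """Two-sided permutation p: share of permutations with |rho| >= |observed|."""
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    total = math.factorial(n)
    hits = 0
    perm_iter = permutations(yc)
    chunk = 40320
    while True:
        block = np.array(list(islice(perm_iter, chunk)))
        if block.size == 0:
            break
        rhos = block @ xc / denom
        hits += int(np.count_nonzero(np.abs(rhos) >= abs(rho) - 1e-12))
    return hits / total


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of mid-ranks (ties get average ranks).
    The p-value is exact — a full permutation enumeration — for n <= 9,
    and the t-approximation with n-2 degrees of freedom above that.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = len(x)
    if n < 3 or len(y) != n:
        raise UndefinedCorrelationError("need >= 3 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("constant input sequence")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    rho = min(max(rho, -1.0), 1.0)
    if n <= _SPEARMAN_EXACT_MAX:
        p = _exact_spearman_p(xr, yr, rho)
    elif abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n)


def longitudinal_report(sessions: list[SessionRecord]) -> pd.DataFrame:
    """Correlate each summary statistic with the ordinal mood rank.

    Mixed-state sessions are excluded (with a logged warning).  Returns a
    table with one row per (statistic, feature) combination: columns
    ``statistic``, ``rho``, ``p_value``, ``n``.  Rows whose statistic is
    constant across sessions get NaN correlation.
    """
    usable = [s for s in sessions if s.assessment.state != MoodState.MIXED]
    n_mixed = len(sessions) - len(usable)
    if n_mixed:
        logger.warning("excluding %d mixed-state session(s) from the ordinal analysis", n_mixed)
    if len(usable) < 3:
        raise ValueError("need at least 3 non-mixed sessions")
    ordinals = np.array([s.assessment.ordinal for s in usable], dtype=np.float64)
    if np.all(ordinals == ordinals[0]):
        raise UndefinedCorrelationError(
            "mood ordinal is constant across sessions (single observed state)"
        )
    rows = []
    for stat in SUMMARY_STATS:
        for feat in FEATURE_NAMES:
            name = f"{stat}_{feat}"
            vals = np.array([s.summary.values[stat][feat] for s in usable])
            ok = np.isfinite(vals)
            try:
                res = spearman(vals[ok], ordinals[ok])
                rows.append((name, res.rho, res.p_value, res.n))
            except UndefinedCorrelationError:
                rows.append((name, math.nan, math.nan, int(ok.sum())))
    return pd.DataFrame(rows, columns=["statistic", "rho", "p_value", "n"])


def synthetic_cohort(
    n_depressive: int = 2,
    n_hypomanic: int = 4,
    n_euthymic: int = 9,
    mad_base: float = 4.0,
    mad_slope: float = 4.0,
    mad_noise: float = 2.0,
    seed: int = 0,
) -> list[SessionRecord]:
    """Generate a longitudinal cohort with a known mood→MAD_meanF0 link.

    Emulates a monitoring case study: one session per assessment, with the
    MAD of the per-segment mean F0 increasing linearly with the ordinal
    mood rank (slope ``mad_slope`` Hz per rank step) plus Gaussian noise.
    The default composition — 2 depressive, 4 hypomanic, 9 euthymic
    sessions — matches a 15-session monitoring period of a rapid-cycling
    patient.  The remaining summary statistics are drawn without any mood
    link, as plausible adult-speech values.
    """
    rng = np.random.default_rng(seed)
    states = (
        [MoodState.DEPRESSIVE] * n_depressive
        + [MoodState.HYPOMANIC] * n_hypomanic
        + [MoodState.EUTHYMIC] * n_euthymic
    )
    order = rng.permutation(len(states))
    score_for = {
        MoodState.DEPRESSIVE: (lambda: (int(rng.integers(8, 15)), int(rng.integers(0, 6)))),
        MoodState.HYPOMANIC: (lambda: (int(rng.integers(0, 8)), int(rng.integers(6, 13)))),
        MoodState.EUTHYMIC: (lambda: (int(rng.integers(0, 8)), int(rng.integers(0, 6)))),
    }
    sessions = []
    for sid, k in enumerate(order):
        state = states[k]
        qid, ymrs = score_for[state]()
        assessment = MoodAssessment(session_id=sid, qid=qid, ymrs=ymrs)
        rank = mood_ordinal(state)
        mad_mean_f0 = max(mad_base + mad_slope * rank + rng.normal(0.0, mad_noise), 0.1)
        values = {
            "median": {
                "mean_f0": 200.0 + rng.normal(0.0, 10.0),
                "std_f0": 8.0 + rng.normal(0.0, 2.0),
                "jitter": 0.01 + rng.normal(0.0, 0.002),
            },
            "mad": {
                "mean_f0": mad_mean_f0,
                "std_f0": abs(3.0 + rng.normal(0.0, 1.0)),
                "jitter": abs(0.004 + rng.normal(0.0, 0.001)),
            },
            "skewness": {
                "mean_f0": rng.normal(0.0, 0.5),
                "std_f0": rng.normal(0.5, 0.5),
                "jitter": rng.normal(0.5, 0.5),
            },
        }
        summary = FeatureSummary(values=values, n_segments=int(rng.integers(20, 60)))
        sessions.append(SessionRecord(session_id=sid, assessment=assessment, summary=summary))
    return sessions
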