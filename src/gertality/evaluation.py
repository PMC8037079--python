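"""Discrimination and calibration-style evaluation of mortality scores.

The AUC is computed in its Mann-Whitney form: the probability that a
randomly chosen death outranks a randomly chosen survivor, with ties
counted one half.  Midrank tie handling matters here because an additive
0-5 point score takes only six distinct values.  The ROC polygon is built
from thresholds at each distinct score value and the trapezoidal area under
it equals the Mann-Whitney statistic exactly; the equality doubles as an
internal consistency check in the test suite.

Confidence intervals use DeLong's asymptotic variance of the AUC by
default, with a seeded stratified bootstrap as a small-sample fallback.
Higher score is taken to mean higher predicted mortality; a score that
discriminates in the wrong direction is reported with AUC < 0.5, never
auto-flipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .scores import MissingPolicy, gertality_score, gtos, iss, ScoredRecord
from .types import Cohort, DomainError

Z_95 = 1.959963984540054


@dataclass(frozen=True)
class RocResult:
    score_name: str
    auc: float
    ci_low: float
    ci_high: float
    roc_points: np.ndarray  # (k, 2) array of (FPR, TPR), from (0,0) to (1,1)
    n_pos: int
    n_neg: int


def _midrank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    m = len(pos)
    return (ranks[:m].sum() - m * (m + 1) / 2) / (m * len(neg))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong's variance of the AUC via placement values."""
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n        # per-death placements
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m  # per-survivor
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def _roc_points(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """ROC polygon with one vertex per distinct score threshold."""
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
    return np.column_stack([fpr, tpr])


def auc(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    score_name: str = "score",
    ci_method: str = "delong",
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> RocResult:
    """AUC of a score against a binary outcome, with a 95% CI.

    Raises :class:`DomainError` unless both outcome classes are present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape:
        raise DomainError("scores and outcomes lengths differ")
    if np.any(np.isnan(s)):
        raise DomainError("scores contain missing values; filter upstream")
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("both outcome classes must be present")

    estimate = _midrank_auc(pos, neg)
    if ci_method == "delong":
        se = math.sqrt(_delong_variance(pos, neg))
        lo, hi = estimate - Z_95 * se, estimate + Z_95 * se
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            bp = pos[rng.integers(0, len(pos), len(pos))]
            bn = neg[rng.integers(0, len(neg), len(neg))]
            reps[b] = _midrank_auc(bp, bn)
        lo, hi = np.quantile(reps, [0.025, 0.975])
    else:
        raise DomainError(f"unknown ci_method {ci_method!r}")

    return RocResult(
        score_name=score_name,
        auc=float(estimate),
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        roc_points=_roc_points(pos, neg),
        n_pos=len(pos),
        n_neg=len(neg),
    )


@dataclass(frozen=True)
class ScoreLevelRow:
    level: int
    n: int
    deaths: int
    mortality: float  # NaN when n = 0
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class ScoreMortalityTable:
    rows: tuple[ScoreLevelRow, ...]
    n_missing: int

    @property
    def n_total(self) -> int:
        return sum(r.n for r in self.rows)

    def mortality_by_level(self) -> dict[int, float]:
        return {r.level: r.mortality for r in self.rows}


def mortality_by_score(
    scored: Sequence[ScoredRecord],
    outcomes: Sequence[bool],
    max_level: int = 5,
) -> ScoreMortalityTable:
    """Observed mortality per score level with exact binomial 95% CIs.

    One row per level 0..max_level (empty levels get n = 0); records with a
    missing score are excluded and counted in ``n_missing``.
    """
    if len(scored) != len(outcomes):
        raise DomainError("scored records and outcomes lengths differ")
    counts = {lvl: [0, 0] for lvl in range(max_level + 1)}  # level -> [n, deaths]
    missing = 0
    for rec, died in zip(scored, outcomes):
        pts = rec.gertality_points
        if pts is None:
            missing += 1
            continue
        if pts not in counts:
            raise DomainError(f"score {pts} outside 0..{max_level}")
        counts[pts][0] += 1
        counts[pts][1] += int(bool(died))
    rows = []
    for level in range(max_level + 1):
        n, deaths = counts[level]
        if n == 0:
            rows.append(ScoreLevelRow(level, 0, 0, math.nan, math.nan, math.nan))
            continue
        ci = stats.binomtest(deaths, n).proportion_ci(0.95, method="exact")
        rows.append(
            ScoreLevelRow(
                level=level,
                n=n,
                deaths=deaths,
                mortality=deaths / n,
                ci_low=float(ci.low),
                ci_high=float(ci.high),
            )
        )
    return ScoreMortalityTable(rows=tuple(rows), n_missing=missing)


#: Score extractors available to compare_scores; each returns a float or
#: None when the record lacks the inputs.
SCORE_EXTRACTORS = {
    "gertality": lambda r, policy: gertality_score(r, policy),
    "gtos": lambda r, policy: gtos(r),
    "max_ais": lambda r, policy: float(r.max_ais),
    "iss": lambda r, policy: float(iss(r)),
    "age": lambda r, policy: float(r.age),
}


def compare_scores(
    cohort: Cohort,
    score_names: Sequence[str] = ("gertality", "gtos", "max_ais", "iss", "age"),
    missing_policy: MissingPolicy = MissingPolicy.ZERO_POINTS,
    ci_method: str = "delong",
    seed: Optional[int] = None,
) -> list[RocResult]:
    """ROC comparison of several mortality scores on one cohort.

    All AUCs are computed on the intersection of records where every
    requested score is evaluable, so the comparison is on identical
    subsets.  Results are ordered by AUC descending.
    """
    if len(score_names) < 2:
        raise DomainError("need at least two scores to compare")
    unknown = set(score_names) - set(SCORE_EXTRACTORS)
    if unknown:
        raise DomainError(f"unknown score names: {sorted(unknown)}")

    values: dict[str, list[float]] = {name: [] for name in score_names}
    outcomes: list[bool] = []
    for record in cohort.records:
        row = {
            name: SCORE_EXTRACTORS[name](record, missing_policy)
            for name in score_names
        }
        if any(v is None for v in row.values()):
            continue
        for name in score_names:
            values[name].append(float(row[name]))
        outcomes.append(record.died_in_hospital)
    if not outcomes:
        raise DomainError("no records evaluable for all requested scores")

    results = [
        auc(values[name], outcomes, score_name=name, ci_method=ci_method, seed=seed)
        for name in score_names
    ]
    return sorted(results, key=lambda r: r.auc, reverse=True)
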