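"""Similarity scoring between a query peak list and a consensus MSP.

The identification score realizes the way commercial biotypers describe
their scores — counting matching peaks in both directions and weighing the
concordance of peak heights — as a three-factor log-scaled composite in
[0, 3]:

    score = clamp( log10(1000 · a · b · c), 0, 3 )

where ``a`` is the fraction of MSP peaks matched by the query, ``b`` the
fraction of query peaks matched by the MSP, and ``c`` an intensity
rank-concordance term in [0, 1].  A perfect self-match gives exactly 3.0
(log10 1000); the conventional reading of the scale is preserved: > 2.00
high relatedness (factor product above 0.1), < 1.70 low relatedness.  The
exact vendor formula is proprietary and is NOT reproduced numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import spearmanr

from .types import (
    DEFAULT_TOLERANCE,
    Library,
    MainSpectrum,
    MassTolerance,
    PeakList,
)


@dataclass(frozen=True)
class MatchedPair:
    query_mz: float
    query_intensity: float
    ref_mz: float
    ref_intensity: float

    @property
    def dmz(self) -> float:
        return self.query_mz - self.ref_mz


@dataclass(frozen=True)
class ScoreBreakdown:
    frac_ref_matched: float
    frac_query_matched: float
    intensity_concordance: float
    composite: float
    flatline: bool = False


@dataclass(frozen=True)
class Hit:
    label: str
    species: str
    score: float
    breakdown: Optional[ScoreBreakdown] = None


@dataclass
class MatchResult:
    """Ranked hits of one query reading against a library.

    Hits are sorted by score descending; exact ties break by label so the
    ranking is a total (deterministic) order.
    """

    query_id: str
    hits: list[Hit] = field(default_factory=list)
    tolerance: MassTolerance = DEFAULT_TOLERANCE
    flatline: bool = False

    @property
    def top(self) -> Optional[Hit]:
        return self.hits[0] if self.hits else None


def _arrays(obj: Union[PeakList, MainSpectrum]) -> tuple[np.ndarray, np.ndarray]:
    return obj.mz, obj.intensities


def match_peaks(
    query: Union[PeakList, MainSpectrum],
    ref: Union[PeakList, MainSpectrum],
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    method: str = "greedy",
) -> list[MatchedPair]:
    """One-to-one peak matching in m/z within the tolerance window.

    ``greedy`` pairs candidates by ascending |Δm/z| (nearest neighbour,
    each peak used once); ``assignment`` solves the optimal one-to-one
    assignment and exists as an oracle for testing the greedy default.
    """
    qmz, qint = _arrays(query)
    rmz, rint = _arrays(ref)
    if len(qmz) == 0 or len(rmz) == 0:
        return []
    delta = np.abs(qmz[:, None] - rmz[None, :])
    mid = 0.5 * (qmz[:, None] + rmz[None, :])
    window = np.maximum(tolerance.ppm * 1e-6 * mid, tolerance.min_da)
    ok = delta <= window

    pairs: list[tuple[int, int]] = []
    if method == "greedy":
        qi, ri = np.nonzero(ok)
        order = np.lexsort((ri, qi, delta[qi, ri]))
        used_q: set[int] = set()
        used_r: set[int] = set()
        for k in order:
            i, j = int(qi[k]), int(ri[k])
            if i in used_q or j in used_r:
                continue
            used_q.add(i)
            used_r.add(j)
            pairs.append((i, j))
    elif method == "assignment":
        big = 1e9
        cost = np.where(ok, delta, big)
        rows, cols = linear_sum_assignment(cost)
        pairs = [(int(i), int(j)) for i, j in zip(rows, cols) if ok[i, j]]
    else:
        raise ValueError(f"unknown matching method {method!r}")

    pairs.sort()
    return [
        MatchedPair(float(qmz[i]), float(qint[i]), float(rmz[j]), float(rint[j]))
        for i, j in pairs
    ]


def _concordance(pairs: Sequence[MatchedPair], min_pairs: int = 3) -> float:
    """Spearman rank correlation of matched intensities, clipped to [0, 1].

    Fewer than ``min_pairs`` pairs give 0 (insufficient evidence must not
    inflate a score).  Degenerate (constant-rank) inputs count as perfectly
    concordant so that a self-match of a flat-intensity MSP still scores 3.
    """
    if len(pairs) < min_pairs:
        return 0.0
    q = np.array([p.query_intensity for p in pairs])
    r = np.array([p.ref_intensity for p in pairs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(q, r).statistic
    if np.isnan(rho):
        return 1.0
    if rho >= 1.0 - 1e-9:  # identical rankings up to floating error
        return 1.0
    return float(np.clip(rho, 0.0, 1.0))


def composite_score(a: float, b: float, c: float) -> float:
    """``clamp(log10(1000·a·b·c), 0, 3)``; exactly 0 when any factor is 0."""
    product = a * b * c
    if product <= 0.0:
        return 0.0
    return float(np.clip(np.log10(1000.0 * product), 0.0, 3.0))


def score(
    query: PeakList,
    msp: Union[MainSpectrum, PeakList],
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    method: str = "greedy",
) -> ScoreBreakdown:
    """Score one query reading against one MSP."""
    if isinstance(query, PeakList) and (query.flatline or len(query) == 0):
        return ScoreBreakdown(0.0, 0.0, 0.0, 0.0, flatline=True)
    n_ref = len(msp.mz)
    n_query = len(query.mz)
    if n_ref == 0:
        return ScoreBreakdown(0.0, 0.0, 0.0, 0.0)
    pairs = match_peaks(query, msp, tolerance, method=method)
    a = len(pairs) / n_ref
    b = len(pairs) / n_query
    c = _concordance(pairs)
    return ScoreBreakdown(a, b, c, composite_score(a, b, c))


def rank_against_library(
    query: PeakList,
    library: Library,
    tolerance: MassTolerance = DEFAULT_TOLERANCE,
    query_id: Optional[str] = None,
    method: str = "greedy",
) -> MatchResult:
    """Rank a query reading against every MSP in the library.

    The top hit defines the replicate-level call regardless of its score
    magnitude; a flatline query yields an empty hit list with the flatline
    flag set.
    """
    if query_id is None:
        query_id = query.meta.reading_id if query.meta is not None else "query"
    if query.flatline or len(query) == 0:
        return MatchResult(query_id=query_id, tolerance=tolerance, flatline=True)
    hits = [
        Hit(m.label, m.taxonomy.species, (b := score(query, m, tolerance, method)).composite, b)
        for m in library.msps
    ]
    hits.sort(key=lambda h: (-h.score, h.label))
    return MatchResult(query_id=query_id, hits=hits, tolerance=tolerance)
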