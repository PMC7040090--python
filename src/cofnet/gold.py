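"""Gold standards and Bayesian log-likelihood scoring of evidence.

The confidence that a gene pair is co-functional, given a data-intrinsic
score S (a correlation, a mutual information, ...), is expressed as a log
likelihood score

    LLS = ln[ (P(L|S) / P(not L|S)) / (P(L) / P(not L)) ]

i.e. the log of the posterior odds of the pair being a gold-standard positive
over the prior odds.  The conditional odds are estimated empirically: pairs
are sorted by raw score, cut into bins of 1,000, and each bin's
positive/negative counts against the gold standard give one (mean score, LLS)
point.  A monotone four-parameter logistic fitted to those points then maps
*every* pair's raw score — gold-standard member or not — to an LLS.

A source is only admitted into network integration if at least 2,000 of its
calibrated links are better than random (LLS > 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model import EvidenceTable, Pair, canonical_pair

logger = logging.getLogger(__name__)


@dataclass
class GoldStandard:
    """A gene universe plus a set of positive (co-functional) pairs.

    Every other pair over the universe is implicitly a negative; the negative
    set is never materialized, only counted.
    """

    universe: Set[str]
    positives: Set[Pair]

    def __post_init__(self) -> None:
        for a, b in self.positives:
            if a >= b:
                raise ValueError(f"positive pair {(a, b)} is not canonical")
            if a not in self.universe or b not in self.universe:
                raise ValueError(
                    f"positive pair {(a, b)} has a gene outside the universe"
                )

    def n_possible_pairs(self) -> int:
        n = len(self.universe)
        return n * (n - 1) // 2

    def negative_count(self) -> int:
        """C(|universe|, 2) minus the number of positives."""
        return self.n_possible_pairs() - len(self.positives)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.positives


def build_gold_standard(
    positive_pairs: Iterable[Tuple[str, str]],
    universe: Optional[Iterable[str]] = None,
) -> GoldStandard:
    """Build a gold standard from positive pairs and an optional universe.

    If ``universe`` is omitted it defaults to the genes appearing in the
    positives.  An explicit universe must cover every positive pair.
    """
    positives = {canonical_pair(a, b) for a, b in positive_pairs}
    if universe is None:
        uni: Set[str] = set()
        for a, b in positives:
            uni.add(a)
            uni.add(b)
    else:
        uni = set(universe)
    return GoldStandard(uni, positives)


def union_gold_standards(gs_list: Sequence[GoldStandard]) -> GoldStandard:
    """Union of universes and positive sets (how multi-species transfers of
    curated pairs are combined into one training standard)."""
    if not gs_list:
        raise ValueError("need at least one gold standard")
    universe: Set[str] = set()
    positives: Set[Pair] = set()
    for gs in gs_list:
        universe |= gs.universe
        positives |= gs.positives
    return GoldStandard(universe, positives)


@dataclass(frozen=True)
class BinStats:
    mean_score: float
    positives: int
    negatives: int
    lls: float

    @property
    def size(self) -> int:
        return self.positives + self.negatives


@dataclass
class BinnedLLS:
    """Per-bin log-likelihood scores, ordered by descending raw score."""

    bins: List[BinStats]
    bin_size: int
    n_positive_total: int
    n_negative_total: int

    def __len__(self) -> int:
        return len(self.bins)

    def mean_scores(self) -> np.ndarray:
        return np.array([b.mean_score for b in self.bins])

    def lls_values(self) -> np.ndarray:
        return np.array([b.lls for b in self.bins])


def lls_from_counts(p: int, n: int, P: int, N: int) -> float:
    """LLS of a bin with ``p`` positives / ``n`` negatives against prior
    totals ``P`` / ``N``; +0.5 continuity correction when either cell is 0."""
    if P <= 0 or N <= 0:
        raise ValueError("gold standard must contain positives and negatives")
    pf, nf = float(p), float(n)
    if p == 0 or n == 0:
        pf += 0.5
        nf += 0.5
    return math.log((pf / nf) / (P / N))


def bin_and_score(
    evidence: EvidenceTable,
    gs: GoldStandard,
    bin_size: int = 1000,
    min_tail: int = 100,
) -> BinnedLLS:
    """Sort pairs by raw score, bin, and compute per-bin LLS.

    Only pairs with both genes in the gold-standard universe enter the bins.
    Sorting is stable on (score descending, canonical pair ascending) so the
    result does not depend on input order.  A partial final bin with fewer
    than ``min_tail`` pairs is merged into the previous bin to avoid a
    high-variance tail estimate.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    P = len(gs.positives)
    N = gs.negative_count()
    if P <= 0 or N <= 0:
        raise ValueError("gold standard must have both positives and negatives")

    items = [
        (s, pair) for pair, s in evidence.scores.items()
        if pair[0] in gs.universe and pair[1] in gs.universe
    ]
    if not items:
        raise ValueError(
            f"no pair of source {evidence.source_code!r} overlaps the "
            "gold-standard universe"
        )
    items.sort(key=lambda t: (-t[0], t[1]))

    scores = np.array([t[0] for t in items])
    labels = np.array([t[1] in gs.positives for t in items], dtype=bool)

    edges = list(range(0, len(items), bin_size)) + [len(items)]
    starts, stops = edges[:-1], edges[1:]
    if len(starts) > 1 and (stops[-1] - starts[-1]) < min_tail:
        starts.pop()
        stops.pop(-2)

    bins: List[BinStats] = []
    for lo, hi in zip(starts, stops):
        p = int(labels[lo:hi].sum())
        n = (hi - lo) - p
        bins.append(
            BinStats(float(scores[lo:hi].mean()), p, n, lls_from_counts(p, n, P, N))
        )
    return BinnedLLS(bins, bin_size, P, N)


def _logistic(x: np.ndarray, lower: float, upper: float, slope: float, mid: float) -> np.ndarray:
    # overflow-safe logistic; scipy.special.expit on the signed argument
    z = np.clip(slope * (np.asarray(x, dtype=float) - mid), -700, 700)
    return lower + (upper - lower) / (1.0 + np.exp(-z))


@dataclass
class CalibrationCurve:
    """Monotone 4-parameter logistic mapping raw score -> LLS.

    ``y = lower + (upper - lower) / (1 + exp(-slope * (x - mid)))`` with
    ``upper >= lower`` and ``slope`` signed by the empirical score-vs-LLS
    trend, so the curve is monotone and every prediction lies inside
    ``[lower, upper]`` — extrapolation beyond the fitted score range tends to
    the asymptotes instead of diverging.
    """

    lower: float
    upper: float
    slope: float
    mid: float
    fit_residual: float
    score_range: Tuple[float, float] = (-np.inf, np.inf)

    def predict(self, x) -> np.ndarray:
        y = _logistic(np.asarray(x, dtype=float), self.lower, self.upper, self.slope, self.mid)
        return np.clip(y, min(self.lower, self.upper), max(self.lower, self.upper))

    def predict_one(self, x: float) -> float:
        return float(self.predict(np.array([x]))[0])


def fit_calibration(binned: BinnedLLS) -> CalibrationCurve:
    """Least-squares fit of the monotone logistic to (mean score, LLS) points.

    The monotone direction follows the empirical correlation between bin mean
    scores and bin LLS values; a flat (degenerate) relationship is accepted
    and yields ``upper ~= lower``.
    """
    if len(binned) < 4:
        raise ValueError(
            f"need >= 4 bins to fit 4 parameters, got {len(binned)}"
        )
    x = binned.mean_scores()
    y = binned.lls_values()

    y_span = float(y.max() - y.min())
    x_span = float(x.max() - x.min())
    if x_span == 0:
        raise ValueError("all bins share one mean score; cannot calibrate")
    trend = np.corrcoef(x, y)[0, 1] if y_span > 0 else 0.0
    sign = -1.0 if trend < 0 else 1.0

    # parameters: lower, span (>= 0), |slope| (>= 0), mid
    def resid(theta: np.ndarray) -> np.ndarray:
        lo, span, k, m = theta
        return _logistic(x, lo, lo + span, sign * k, m) - y

    # a bounded box keeps the trust-region solver out of the degenerate
    # plateau where slope and midpoint are unidentifiable (flat data)
    span_cap = 10.0 * (y_span + 1.0)
    lb = [float(y.min()) - span_cap, 0.0, 0.0, float(x.min()) - 2 * x_span]
    ub = [float(y.max()) + span_cap, span_cap, 1e4 / x_span, float(x.max()) + 2 * x_span]
    inits = [
        np.array([float(y.min()), max(min(y_span, span_cap), 1e-8), 4.0 / x_span, m0])
        for m0 in np.percentile(x, [50, 25, 75])
    ]
    sol = None
    for theta0 in inits:
        cand = least_squares(
            resid, theta0, bounds=(lb, ub), method="dogbox", x_scale="jac",
            max_nfev=5000,
        )
        if cand.success:
            sol = cand
            break
        if sol is None or cand.cost < sol.cost:
            sol = cand
    if not sol.success:
        raise RuntimeError(f"calibration fit did not converge: {sol.message}")
    lo, span, k, m = sol.x
    residual = float(np.sqrt(np.mean(sol.fun ** 2)))
    return CalibrationCurve(
        lower=float(lo),
        upper=float(lo + span),
        slope=float(sign * k),
        mid=float(m),
        fit_residual=residual,
        score_range=(float(x.min()), float(x.max())),
    )


def calibrate_evidence(
    evidence: EvidenceTable, curve: CalibrationCurve
) -> EvidenceTable:
    """Map every pair's raw score through the calibration curve to an LLS."""
    pairs = list(evidence.scores.keys())
    raw = np.fromiter(evidence.scores.values(), dtype=float, count=len(pairs))
    lls = curve.predict(raw)
    return EvidenceTable(evidence.source_code, dict(zip(pairs, lls.tolist())))


@dataclass
class AdmissionResult:
    """Outcome of the better-than-random link filter for one source."""

    source_code: str
    admitted: bool
    n_positive_lls: int
    table: EvidenceTable  # filtered to LLS > 0 (empty when nothing passes)


def filter_admissible(
    evidence_lls: EvidenceTable, min_links: int = 2000
) -> AdmissionResult:
    """Keep LLS > 0 links; reject the whole source if fewer than ``min_links``
    remain (a source must supply at least that many links more likely than
    random chance to be integrated)."""
    kept = {p: s for p, s in evidence_lls.scores.items() if s > 0}
    admitted = len(kept) >= min_links
    if not admitted:
        logger.warning(
            "source %s rejected: only %d links with LLS > 0 (< %d required)",
            evidence_lls.source_code, len(kept), min_links,
        )
    return AdmissionResult(
        evidence_lls.source_code,
        admitted,
        len(kept),
        EvidenceTable(evidence_lls.source_code, kept),
    )
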