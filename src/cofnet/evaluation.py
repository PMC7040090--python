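"""Network evaluation: precision–coverage, leave-one-out AUROC, connectivity
tests and topology-preserving randomization.

The central question is always the same — does ranking genes (or edges) by
network weight recover held-out functional truth?  Edge-level quality is
summarized as precision over ranked edges vs. genome coverage; gene-level
prediction power as leave-one-out ROC analysis of guilt-by-association
scores, including partial AUROC at small false-positive-rate cutoffs (only
the earliest retrieved candidates matter in practice); trait-level signal as
the within-group edge connectivity of a gene set against random sets and a
binomial null; robustness via degree-preserving partial edge randomization.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .gold import GoldStandard
from .model import AnnotationSet, Pair, WeightedNetwork, canonical_pair

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# precision–coverage
# ---------------------------------------------------------------------------

def precision_coverage_curve(
    net: WeightedNetwork,
    truth_pairs: Set[Pair],
    genome_size: int,
    annotated_genes: Optional[Set[str]] = None,
) -> List[Tuple[float, float]]:
    """Precision of ranked edges vs. coverage of the genome.

    Edges are sorted by weight descending (ties: canonical pair ascending).
    At each prefix, precision is the fraction of prefix edges that are truth
    pairs, counted only among edges whose both endpoints are annotated
    (``annotated_genes`` defaults to the genes appearing in ``truth_pairs``);
    coverage is the number of distinct genes in the prefix divided by
    ``genome_size``.
    """
    if not truth_pairs:
        raise ValueError("truth pair set is empty")
    truth = {canonical_pair(*p) for p in truth_pairs}
    if annotated_genes is None:
        annotated_genes = set()
        for a, b in truth:
            annotated_genes.add(a)
            annotated_genes.add(b)
    if genome_size < len(net.genes()):
        raise ValueError("genome_size smaller than the network gene count")

    ordered = sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    seen: Set[str] = set()
    n_eval = 0
    n_true = 0
    out: List[Tuple[float, float]] = []
    for (a, b), _w in ordered:
        seen.add(a)
        seen.add(b)
        if a in annotated_genes and b in annotated_genes:
            n_eval += 1
            if (a, b) in truth:
                n_true += 1
        precision = n_true / n_eval if n_eval else 0.0
        out.append((len(seen) / genome_size, precision))
    return out


# ---------------------------------------------------------------------------
# leave-one-out ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Full and partial AUROC of one guilt-by-association ranking."""

    auroc_full: float
    auroc_at: Dict[float, float]  # FPR cutoff -> normalized partial AUROC
    ranks: List[str]              # genes, best-scored first

    def __post_init__(self) -> None:
        vals = [self.auroc_full, *self.auroc_at.values()]
        if any(not (0.0 <= v <= 1.0 + 1e-12) for v in vals):
            raise ValueError(f"AUROC values outside [0, 1]: {vals}")


def _partial_auroc(fpr: np.ndarray, tpr: np.ndarray, cutoff: float) -> float:
    """Area under the ROC curve up to ``cutoff`` FPR, divided by ``cutoff``
    (so a perfect ranking scores 1.0 at every cutoff)."""
    if cutoff <= 0 or cutoff > 1:
        raise ValueError(f"FPR cutoff must be in (0, 1], got {cutoff}")
    tpr_at = float(np.interp(cutoff, fpr, tpr))
    mask = fpr < cutoff
    xs = np.concatenate([fpr[mask], [cutoff]])
    ys = np.concatenate([tpr[mask], [tpr_at]])
    return float(np.trapezoid(ys, xs) / cutoff)


def guilt_by_association_scores(
    net: WeightedNetwork, positives: Set[str]
) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Score every network gene by its summed edge weight to the positive set.

    Positive genes are scored leave-one-out: a gene never contributes to its
    own score (there are no self-edges, so simply summing over the positive
    set minus the gene itself achieves this).
    """
    genes = sorted(net.genes())
    idx = {g: i for i, g in enumerate(genes)}
    pos_mask = np.array([g in positives for g in genes], dtype=bool)
    scores = np.zeros(len(genes))
    for (a, b), w in net.edges.items():
        ia, ib = idx[a], idx[b]
        if pos_mask[ib]:
            scores[ia] += w
        if pos_mask[ia]:
            scores[ib] += w
    return genes, scores, pos_mask


def loo_auroc(
    net: WeightedNetwork,
    positives: Iterable[str],
    fpr_cutoffs: Sequence[float] = (0.01, 0.1, 1.0),
) -> RocResult:
    """Leave-one-out ROC analysis of network-based gene prioritization.

    Every network gene is scored by its summed edge weight to the known
    positive genes (each positive excluded from its own score); the ROC curve
    contrasts positives against all other network genes.  Partial AUROCs are
    reported up to each FPR cutoff, normalized by the cutoff.
    """
    pos = set(positives)
    genes, scores, labels = guilt_by_association_scores(net, pos)
    if labels.sum() < 2:
        raise ValueError("need at least 2 positive genes in the network")
    if (~labels).sum() < 1:
        raise ValueError("no negative gene in the network")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auroc_at = {float(c): _partial_auroc(fpr, tpr, float(c)) for c in fpr_cutoffs}
    full = _partial_auroc(fpr, tpr, 1.0)
    order = sorted(zip(genes, scores), key=lambda t: (-t[1], t[0]))
    return RocResult(full, auroc_at, [g for g, _ in order])


@dataclass
class BatchAurocResult:
    per_term: Dict[str, RocResult]
    fpr_cutoffs: Tuple[float, ...]

    def auroc_vector(self, cutoff: Optional[float] = None) -> Dict[str, float]:
        if cutoff is None:
            return {t: r.auroc_full for t, r in self.per_term.items()}
        return {t: r.auroc_at[cutoff] for t, r in self.per_term.items()}

    def summary(self, cutoff: Optional[float] = None) -> Dict[str, float]:
        """Distribution summary (10/25/50/75/90 percentiles) of per-term AUROC."""
        vals = np.array(list(self.auroc_vector(cutoff).values()))
        q = np.percentile(vals, [10, 25, 50, 75, 90])
        return {
            "n_terms": float(len(vals)),
            "p10": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "p90": float(q[4]),
        }


def batch_auroc(
    net: WeightedNetwork,
    annos: AnnotationSet,
    min_set: int = 10,
    fpr_cutoffs: Sequence[float] = (0.01, 0.1, 1.0),
) -> BatchAurocResult:
    """Leave-one-out AUROC for every annotation term with at least ``min_set``
    genes in the network."""
    net_genes = net.genes()
    per_term: Dict[str, RocResult] = {}
    for term_id in sorted(annos.terms):
        members = annos.terms[term_id].genes & net_genes
        if len(members) < min_set:
            continue
        per_term[term_id] = loo_auroc(net, members, fpr_cutoffs)
    if not per_term:
        raise ValueError(f"no term has >= {min_set} genes in the network")
    return BatchAurocResult(per_term, tuple(float(c) for c in fpr_cutoffs))


def paired_auroc_test(
    a: Mapping[str, float], b: Mapping[str, float]
) -> Tuple[float, int]:
    """Paired Wilcoxon signed-rank test between two per-term AUROC vectors.

    Returns (two-sided p, number of common terms).  Identical vectors (all
    zero differences) give p = 1.0.
    """
    common = sorted(set(a) & set(b))
    if not common:
        raise ValueError("no common terms between the two AUROC vectors")
    diffs = np.array([a[t] - b[t] for t in common])
    if np.all(diffs == 0):
        return 1.0, len(common)
    stat = stats.wilcoxon(diffs)
    return float(stat.pvalue), len(common)


# ---------------------------------------------------------------------------
# within-group connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityTest:
    observed_edges: int
    null_counts: List[int]
    p_binomial: float
    p_empirical: float

    def __post_init__(self) -> None:
        if not (0 < self.p_binomial <= 1 and 0 < self.p_empirical <= 1):
            raise ValueError("p-values must lie in (0, 1]")


def _dense_adjacency(net: WeightedNetwork) -> Tuple[List[str], np.ndarray]:
    genes = sorted(net.genes())
    idx = {g: i for i, g in enumerate(genes)}
    A = np.zeros((len(genes), len(genes)), dtype=bool)
    for a, b in net.edges:
        A[idx[a], idx[b]] = True
        A[idx[b], idx[a]] = True
    return genes, A


def within_group_connectivity(
    net: WeightedNetwork,
    gene_set: Iterable[str],
    n_random: int = 1000,
    seed: Optional[int] = None,
) -> ConnectivityTest:
    """Edge count inside a gene set vs. random same-size network gene sets.

    ``p_empirical`` is the permutation tail ``(1 + #{null >= observed}) /
    (n_random + 1)``; ``p_binomial`` is ``P[X >= observed]`` for ``X ~
    Binomial(C(k, 2), density)`` with the network's global edge density —
    the parametric companion when a trait gene set is asked to be more
    interconnected than chance.
    """
    genes, A = _dense_adjacency(net)
    idx = {g: i for i, g in enumerate(genes)}
    members = sorted(set(gene_set) & set(genes))
    k = len(members)
    if k < 2:
        raise ValueError(f"need >= 2 set genes in the network, got {k}")
    sel = np.array([idx[g] for g in members])
    observed = int(A[np.ix_(sel, sel)].sum() // 2)

    n = len(genes)
    m = len(net.edges)
    trials = k * (k - 1) // 2
    density = m / (n * (n - 1) / 2)
    p_binomial = float(stats.binom.sf(observed - 1, trials, density))
    # sf can underflow to 0 for extreme enrichment; keep p in (0, 1]
    p_binomial = max(p_binomial, 5e-324)

    rng = np.random.default_rng(seed)
    # batched sampling of n_random uniform k-subsets of the network genes
    R = rng.random((n_random, n))
    draws = np.argpartition(R, k - 1, axis=1)[:, :k]
    sub = A[draws[:, :, None], draws[:, None, :]]
    null_counts = (sub.sum(axis=(1, 2)) // 2).astype(int)
    p_empirical = float((1 + int((null_counts >= observed).sum())) / (n_random + 1))
    return ConnectivityTest(
        observed, null_counts.tolist(), min(p_binomial, 1.0), p_empirical
    )


# ---------------------------------------------------------------------------
# topology-preserving randomization
# ---------------------------------------------------------------------------

def randomize_network(
    net: WeightedNetwork,
    fraction: float = 0.2,
    seed: Optional[int] = None,
    max_tries_per_edge: int = 200,
) -> WeightedNetwork:
    """Rewire a fraction of edges with degree-preserving double-edge swaps.

    Each accepted swap replaces two edges (a,b), (c,d) with (a,d), (c,b) —
    or (a,c), (b,d) — provided no self-loop or duplicate edge arises, so the
    degree of every gene and the edge count are exactly conserved.  Weights
    stay attached to their original edge slots (the *label* of the slot
    changes, not its weight), which is what makes the result a noise model:
    same topology statistics, scrambled biology.  Swapping continues until at
    least ``fraction`` of edges differ from the input network.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    edges = list(net.edges.items())
    m = len(edges)
    target = int(round(fraction * m))
    if target == 0:
        return WeightedNetwork(dict(net.edges))
    if m < 2:
        raise ValueError("network too small to rewire")

    slots: List[Tuple[str, str]] = [p for p, _w in edges]
    weights: List[float] = [w for _p, w in edges]
    original = set(slots)
    current = set(slots)
    rng = np.random.default_rng(seed)
    diff = 0
    budget = max_tries_per_edge * m
    tries = 0
    while diff < target and tries < budget:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = slots[i]
        c, d = slots[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposal: (a, d), (c, b)
        if a == d or c == b:
            continue
        e1 = (a, d) if a < d else (d, a)
        e2 = (c, b) if c < b else (b, c)
        if e1 in current or e2 in current or e1 == e2:
            continue
        old1, old2 = slots[i], slots[j]
        current.discard(old1)
        current.discard(old2)
        current.add(e1)
        current.add(e2)
        slots[i], slots[j] = e1, e2
        diff += (e1 not in original) + (e2 not in original)
        diff -= (old1 not in original) + (old2 not in original)
    if diff < target:
        achieved = diff / m
        raise RuntimeError(
            f"could not reach rewiring fraction {fraction:.3f}; achieved "
            f"{achieved:.3f} after {tries} attempts"
        )
    return WeightedNetwork({p: w for p, w in zip(slots, weights)})


def rewired_fraction(original: WeightedNetwork, randomized: WeightedNetwork) -> float:
    """Fraction of edges of ``randomized`` absent from ``original``."""
    if len(randomized) == 0:
        return 0.0
    return sum(p not in original.edges for p in randomized.edges) / len(randomized)


# ---------------------------------------------------------------------------
# train/eval independence guard
# ---------------------------------------------------------------------------

class EvaluationOverlapError(RuntimeError):
    """Evaluation truth overlaps the training gold standard too much."""


def evaluation_overlap(truth_pairs: Iterable[Pair], gs: GoldStandard) -> float:
    """Fraction of training gold-standard pairs also present in the truth set."""
    truth = {canonical_pair(*p) for p in truth_pairs}
    if not gs.positives:
        raise ValueError("gold standard has no positives")
    return len(truth & gs.positives) / len(gs.positives)


def assert_evaluation_independent(
    truth_pairs: Iterable[Pair],
    gs: GoldStandard,
    max_fraction: float = 0.05,
    override: bool = False,
) -> float:
    """Refuse to evaluate on a truth set entangled with the training data.

    Computes the pair overlap between the evaluation truth and the training
    gold standard, as a fraction of the training positives; raises
    :class:`EvaluationOverlapError` when it exceeds ``max_fraction`` unless
    ``override`` is set.  Returns the overlap fraction either way it is
    allowed through.
    """
    frac = evaluation_overlap(truth_pairs, gs)
    if frac > max_fraction and not override:
        raise EvaluationOverlapError(
            f"evaluation truth shares {100 * frac:.2f}% of training positives "
            f"(> {100 * max_fraction:.2f}%); pass override=True to proceed"
        )
    if frac > max_fraction:
        logger.warning(
            "evaluating despite %.2f%% training overlap (override)", 100 * frac
        )
    return frac
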