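"""Core data model for co-functional gene networks.

A co-functional link asserts that two genes take part in the same biological
process, with a confidence weight (a log-likelihood score, LLS).  Everything
in this package works on *unordered* gene pairs: a pair is stored once, in
canonical (lexicographic) order, and self-pairs are rejected at construction.

The containers here are deliberately plain: evidence tables and networks are
dictionaries keyed by canonical pairs, which keeps symmetry and deduplication
trivial to enforce and makes every downstream algorithm order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import numpy as np

#: An unordered gene pair in canonical order (lexicographically smaller id first).
Pair = Tuple[str, str]


class PairError(ValueError):
    """Raised for invalid gene identifiers or self-pairs."""


def validate_gene_id(gene: str) -> str:
    """Check that *gene* is a usable identifier (non-empty, no whitespace)."""
    if not isinstance(gene, str) or not gene:
        raise PairError(f"gene id must be a non-empty string, got {gene!r}")
    if any(ch.isspace() for ch in gene):
        raise PairError(f"gene id may not contain whitespace: {gene!r}")
    return gene


def canonical_pair(a: str, b: str) -> Pair:
    """Return the canonical representation of the unordered pair {a, b}.

    Gene identifiers are case-sensitive strings; the smaller one (string
    order) comes first so that ``canonical_pair(a, b) == canonical_pair(b, a)``.

    Raises
    ------
    PairError
        If either id is invalid or ``a == b`` (self-pairs carry no
        co-functional information and are banned throughout).
    """
    validate_gene_id(a)
    validate_gene_id(b)
    if a == b:
        raise PairError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def _check_scores_finite(scores: Mapping[Pair, float], what: str) -> None:
    for pair, s in scores.items():
        if pair[0] >= pair[1]:
            raise PairError(f"{what}: pair {pair} is not canonical")
        if not math.isfinite(s):
            raise ValueError(f"{what}: non-finite score {s!r} for pair {pair}")


@dataclass
class EvidenceTable:
    """Raw (or calibrated) pairwise scores from one data source.

    ``source_code`` is a short tag naming the source, e.g. ``"CX"`` for
    co-expression, ``"DP"`` for domain profiles, ``"PG"`` for phylogenetic
    profiles, or ``"SC-CC"`` for a transferred yeast co-citation layer.
    """

    source_code: str
    scores: Dict[Pair, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.scores:
            if a >= b:
                raise PairError(f"pair {(a, b)} is not canonical (or a self-pair)")

    @classmethod
    def from_records(
        cls, source_code: str, records: Iterable[Tuple[str, str, float]]
    ) -> "EvidenceTable":
        """Build a table from (gene_a, gene_b, score) records.

        Pairs are canonicalized; a duplicate pair with the same score is
        silently deduplicated, a duplicate with a conflicting score is an
        error (silently averaging or taking the max would hide upstream bugs).
        """
        scores: Dict[Pair, float] = {}
        for a, b, s in records:
            pair = canonical_pair(a, b)
            s = float(s)
            if not math.isfinite(s):
                raise ValueError(f"non-finite score {s!r} for pair {pair}")
            if pair in scores and not math.isclose(scores[pair], s, rel_tol=1e-9, abs_tol=0.0):
                raise ValueError(
                    f"conflicting scores for pair {pair}: {scores[pair]!r} vs {s!r}"
                )
            scores[pair] = s
        return cls(source_code, scores)

    def validate(self) -> None:
        _check_scores_finite(self.scores, f"EvidenceTable[{self.source_code}]")

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.scores:
            out.add(a)
            out.add(b)
        return out

    def get(self, a: str, b: str, default: Optional[float] = None) -> Optional[float]:
        return self.scores.get(canonical_pair(a, b), default)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.scores

    def __iter__(self) -> Iterator[Pair]:
        return iter(self.scores)


@dataclass
class WeightedNetwork:
    """Undirected gene network with real edge weights (LLS / WS scores).

    ``components`` optionally retains, per edge, the per-source LLS values
    that went into the integrated weight — the raw material for evidence
    breakdowns in candidate-gene reports.
    """

    edges: Dict[Pair, float] = field(default_factory=dict)
    components: Optional[Dict[Pair, Dict[str, float]]] = None

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a >= b:
                raise PairError(f"edge {(a, b)} is not canonical (or a self-pair)")
        if self.components is not None:
            for pair, comp in self.components.items():
                if pair not in self.edges:
                    raise ValueError(f"component for unknown edge {pair}")
                if not comp:
                    raise ValueError(f"edge {pair} has an empty component map")

    @classmethod
    def from_records(
        cls, records: Iterable[Tuple[str, str, float]]
    ) -> "WeightedNetwork":
        table = EvidenceTable.from_records("net", records)
        return cls(table.scores)

    def validate(self) -> None:
        _check_scores_finite(self.edges, "WeightedNetwork")

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    def get(self, a: str, b: str, default: Optional[float] = None) -> Optional[float]:
        return self.edges.get(canonical_pair(a, b), default)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: Pair) -> bool:
        return canonical_pair(*pair) in self.edges

    def adjacency(self) -> Dict[str, Dict[str, float]]:
        """Gene -> {neighbor -> weight} view (built fresh on each call)."""
        adj: Dict[str, Dict[str, float]] = {}
        for (a, b), w in self.edges.items():
            adj.setdefault(a, {})[b] = w
            adj.setdefault(b, {})[a] = w
        return adj

    def degree_map(self) -> Dict[str, int]:
        deg: Dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def subnetwork(self, pairs: Iterable[Pair]) -> "WeightedNetwork":
        """Restrict to the given edges (which must all exist)."""
        keep = {canonical_pair(*p) for p in pairs}
        edges = {p: w for p, w in self.edges.items() if p in keep}
        comps = None
        if self.components is not None:
            comps = {p: dict(self.components[p]) for p in edges if p in self.components}
        return WeightedNetwork(edges, comps)


def confidence_threshold(fold: float) -> float:
    """LLS threshold above which an edge is *fold* times more likely than random.

    An LLS is the natural log of an odds ratio, so a fold-change cutoff on the
    likelihood translates to a cutoff of ``ln(fold)`` on the score.
    """
    if not fold > 1:
        raise ValueError(f"fold must be > 1, got {fold!r}")
    return math.log(fold)


def classify_confidence(net: WeightedNetwork, fold: float = 20.0) -> WeightedNetwork:
    """Return the high-confidence subnetwork: edges with weight >= ln(fold).

    With the default ``fold=20`` this selects links at least 20-fold more
    likely to be co-functional than a random gene pair.
    """
    thr = confidence_threshold(fold)
    return net.subnetwork(p for p, w in net.edges.items() if w >= thr)


@dataclass(frozen=True)
class Term:
    """One annotation term: an identifier, a human-readable name, a gene set."""

    term_id: str
    name: str
    genes: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"term {self.term_id!r} has an empty gene set")


@dataclass
class AnnotationSet:
    """A namespaced collection of gene sets (e.g. GO biological process terms
    of one species), used both for search and for network evaluation."""

    namespace: str
    terms: Dict[str, Term] = field(default_factory=dict)

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for t in self.terms.values():
            out |= t.genes
        return out

    def __len__(self) -> int:
        return len(self.terms)


class ExpressionMatrix:
    """Genes x samples matrix of expression values."""

    def __init__(self, genes: List[str], samples: List[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(samples)):
            raise ValueError(
                f"shape {values.shape} does not match {len(genes)} genes x "
                f"{len(samples)} samples"
            )
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids in expression matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite")
        self.genes = list(genes)
        self.samples = list(samples)
        self.values = values

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


class ProfileMatrix:
    """Genes x features matrix of profile values.

    ``binary=True`` marks presence/absence profiles (protein domain
    composition); continuous non-negative profiles hold ``-log(E-value)``
    homology-hit strengths across genomes (phylogenetic profiles).
    """

    def __init__(
        self,
        genes: List[str],
        features: List[str],
        values: np.ndarray,
        binary: bool = False,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(features)):
            raise ValueError(
                f"shape {values.shape} does not match {len(genes)} genes x "
                f"{len(features)} features"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("profile values must be finite")
        if binary and not np.all(np.isin(values, (0.0, 1.0))):
            raise ValueError("binary profile matrix may contain only {0, 1}")
        self.genes = list(genes)
        self.features = list(features)
        self.values = values
        self.binary = binary

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape
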