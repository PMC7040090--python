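"""Network-based prioritization: pathway-, gene- and context-centric searches.

All three algorithms are guilt-by-association on a weighted co-functional
network:

* pathway-centric — rank candidate genes for a pathway/trait by the summed
  edge weight to user-supplied guide genes;
* gene-centric — rank functional terms for one gene by the summed edge
  weight to its direct neighbors annotated with each term;
* context-centric — rank hub genes (degree >= 100) by the one-sided Fisher
  significance of the overlap between their neighborhoods and a context gene
  set such as differentially expressed genes (DEGs).

Rankings are deterministic: ties break on score descending, then identifier
ascending; hub tables order by ascending p-value, then identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import AnnotationSet, WeightedNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedEntry:
    """One ranked candidate (a gene or a term)."""

    identifier: str
    score: float
    rank: int
    breakdown: Optional[Dict[str, float]] = None  # source_code -> % of score


@dataclass
class RankedCandidates:
    """An ordered candidate list with dense ranks 1..k."""

    entries: List[RankedEntry] = field(default_factory=list)
    missing_guides: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def identifiers(self) -> List[str]:
        return [e.identifier for e in self.entries]

    def __iter__(self):
        return iter(self.entries)


def _rank(scored: Dict[str, float], top_k: Optional[int]) -> List[Tuple[str, float]]:
    ordered = sorted(scored.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_k is not None:
        ordered = ordered[:top_k]
    return ordered


def pathway_centric_search(
    net: WeightedNetwork,
    guides: Iterable[str],
    top_k: Optional[int] = 100,
    min_weight: Optional[float] = None,
) -> RankedCandidates:
    """Rank non-guide genes by summed edge weight to the guide set.

    ``min_weight`` optionally ignores edges below a score threshold (the
    knob that controls how many close neighbors are considered).  Guides
    absent from the network are reported, not fatal; having *no* guide in
    the network is an error.  Candidates with zero score are omitted, and
    guides never appear as candidates.

    When the network carries per-source components, each candidate's entry
    includes an evidence breakdown: every source's share of the summed
    component LLS over its guide edges, as a percentage of the total.
    """
    guide_set = set(guides)
    net_genes = net.genes()
    present = guide_set & net_genes
    missing = sorted(guide_set - net_genes)
    if not present:
        raise ValueError(f"no guide gene found in the network; unmapped: {missing}")
    if missing:
        logger.warning("%d guide genes not in the network: %s", len(missing), missing)

    adj = net.adjacency()
    scores: Dict[str, float] = {}
    contribs: Dict[str, Dict[str, float]] = {}
    for g in present:
        for nb, w in adj[g].items():
            if nb in guide_set:
                continue
            if min_weight is not None and w < min_weight:
                continue
            scores[nb] = scores.get(nb, 0.0) + w
            if net.components is not None:
                comp = net.components.get((min(g, nb), max(g, nb)), {})
                dest = contribs.setdefault(nb, {})
                for src, lls in comp.items():
                    dest[src] = dest.get(src, 0.0) + lls

    entries: List[RankedEntry] = []
    for rank, (gene, score) in enumerate(_rank(scores, top_k), start=1):
        breakdown = None
        comp = contribs.get(gene)
        if comp:
            total = sum(comp.values())
            if total > 0:
                breakdown = {src: 100.0 * v / total for src, v in comp.items()}
        entries.append(RankedEntry(gene, score, rank, breakdown))
    return RankedCandidates(entries, missing)


def gene_centric_search(
    net: WeightedNetwork,
    gene: str,
    annos: Sequence[AnnotationSet],
    top_k: Optional[int] = None,
    max_term_size: int = 1000,
) -> Dict[str, RankedCandidates]:
    """Rank functional terms for one gene, per annotation namespace.

    Information propagates to *direct* neighbors only: a term's score is the
    summed edge weight from the query gene to its neighbors annotated with
    the term.  Terms annotating more than ``max_term_size`` genes are
    excluded — such broad terms would dominate any neighborhood without
    saying anything specific.
    """
    adj = net.adjacency()
    if gene not in adj:
        raise ValueError(f"gene {gene!r} is not in the network")
    neighbors = adj[gene]
    out: Dict[str, RankedCandidates] = {}
    for anno in annos:
        scores: Dict[str, float] = {}
        for term_id, term in anno.terms.items():
            if len(term.genes) > max_term_size:
                continue
            s = sum(w for nb, w in neighbors.items() if nb in term.genes)
            if s > 0:
                scores[term_id] = s
        entries = [
            RankedEntry(t, s, rank)
            for rank, (t, s) in enumerate(_rank(scores, top_k), start=1)
        ]
        if not entries:
            logger.warning(
                "gene %s has no annotated neighbor in namespace %s", gene, anno.namespace
            )
        out[anno.namespace] = RankedCandidates(entries)
    return out


@dataclass(frozen=True)
class HubEntry:
    hub: str
    degree: int
    overlap: int
    p_value: float
    fdr: float
    is_deg: bool


@dataclass
class ContextHubResult:
    """Hubs ordered by ascending overlap p-value."""

    entries: List[HubEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def hubs(self) -> List[str]:
        return [e.hub for e in self.entries]

    def __iter__(self):
        return iter(self.entries)


def fisher_overlap_p(overlap: int, set_a: int, set_b: int, universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for the overlap of two sets.

    Equals the hypergeometric tail ``P[X >= overlap]`` with ``X ~
    Hypergeom(universe, set_a, set_b)``.
    """
    p = float(hypergeom.sf(overlap - 1, universe, set_a, set_b))
    # sf underflows to 0 for extreme overlaps; keep p in (0, 1]
    return min(max(p, 5e-324), 1.0)


def context_centric_search(
    net: WeightedNetwork,
    degs: Iterable[str],
    min_hub_degree: int = 100,
    fdr_method: str = "fdr_bh",
) -> ContextHubResult:
    """Rank hub genes by the significance of the DEG overlap of their
    neighborhoods.

    Each gene with at least ``min_hub_degree`` neighbors defines a subnetwork
    (itself plus direct neighbors) standing in for a pathway.  A one-sided
    Fisher exact test asks whether the hub's neighbors are enriched for the
    context gene set; the background is the network gene universe minus the
    hub itself (the hub never counts toward its own contingency table).  The
    hub may or may not itself be a DEG — the ``is_deg`` flag records it.
    Benjamini–Hochberg FDR is attached across all tested hubs.
    """
    net_genes = net.genes()
    deg_set = set(degs) & net_genes
    if not deg_set:
        raise ValueError("no context (DEG) gene overlaps the network")
    adj = net.adjacency()
    hubs = sorted(g for g, nb in adj.items() if len(nb) >= min_hub_degree)
    if not hubs:
        logger.warning("no gene reaches hub degree %d", min_hub_degree)
        return ContextHubResult([])

    records = []
    for hub in hubs:
        neighbors = set(adj[hub])
        context = deg_set - {hub}
        universe = len(net_genes) - 1
        overlap = len(neighbors & context)
        p = fisher_overlap_p(overlap, len(neighbors), len(context), universe)
        records.append((hub, len(neighbors), overlap, min(p, 1.0)))

    pvals = [r[3] for r in records]
    fdrs = multipletests(pvals, method=fdr_method)[1]
    entries = [
        HubEntry(hub, degree, overlap, p, float(fdr), hub in deg_set)
        for (hub, degree, overlap, p), fdr in zip(records, fdrs)
    ]
    entries.sort(key=lambda e: (e.p_value, e.hub))
    return ContextHubResult(entries)


@dataclass(frozen=True)
class TermEnrichment:
    term_id: str
    name: str
    overlap: int
    term_size: int
    p_value: float
    fdr: float


def enrich_candidates(
    candidates: Iterable[str],
    annos: Sequence[AnnotationSet],
    background: Iterable[str],
) -> Dict[str, List[TermEnrichment]]:
    """Gene-set enrichment of a candidate list, per annotation namespace.

    One-sided Fisher exact test of candidate/term overlap against the given
    background universe, with Benjamini–Hochberg FDR within each namespace.
    Terms are returned sorted by ascending p-value (then term id), so the
    head of each list is the "top enriched annotations" report.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene set is empty")
    cand = set(candidates)
    if not cand <= bg:
        raise ValueError("candidates must be a subset of the background")

    out: Dict[str, List[TermEnrichment]] = {}
    for anno in annos:
        records = []
        for term_id in sorted(anno.terms):
            term = anno.terms[term_id]
            term_genes = term.genes & bg
            if not term_genes:
                continue
            overlap = len(cand & term_genes)
            p = fisher_overlap_p(overlap, len(term_genes), len(cand), len(bg))
            records.append((term_id, term.name, overlap, len(term_genes), min(p, 1.0)))
        if not records:
            out[anno.namespace] = []
            continue
        fdrs = multipletests([r[4] for r in records], method="fdr_bh")[1]
        enriched = [
            TermEnrichment(tid, name, ov, size, p, float(fdr))
            for (tid, name, ov, size, p), fdr in zip(records, fdrs)
        ]
        enriched.sort(key=lambda e: (e.p_value, e.term_id))
        out[anno.namespace] = enriched
    return out
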