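"""Per-source evidence inference from raw omics inputs.

Each function turns one kind of raw input into an :class:`EvidenceTable`
of data-intrinsic pairwise scores, later calibrated to log-likelihood
scores against a gold standard:

* ``coexpression_scores`` — Pearson correlation of expression profiles (CX)
* ``domain_profile_scores`` — rarity-weighted shared information between
  binary protein-domain composition profiles (DP)
* ``phylo_profile_scores`` — mutual information between phylogenetic
  profiles, computed separately per domain of life (PG)
* ``transfer_associalogs`` — transfer of co-functional links from another
  species' network through orthology (both endpoints mapped)
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .model import (
    EvidenceTable,
    ExpressionMatrix,
    Pair,
    ProfileMatrix,
    WeightedNetwork,
    canonical_pair,
)

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Many-to-many orthology: source-species gene -> set of target genes
    (co-orthologs allowed)."""

    pairs: Dict[str, Set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for src, targets in self.pairs.items():
            if not targets:
                raise ValueError(f"ortholog map has empty target set for {src!r}")

    def __len__(self) -> int:
        return len(self.pairs)


def coexpression_scores(
    expr: ExpressionMatrix, min_samples: int = 3
) -> EvidenceTable:
    """Pearson correlation (PCC) between all gene pairs of an expression set.

    Genes with zero variance across samples carry no correlation signal and
    are excluded with a warning.
    """
    if len(expr.samples) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples, got {len(expr.samples)}"
        )
    values = expr.values
    sd = values.std(axis=1)
    keep = sd > 0
    dropped = [g for g, k in zip(expr.genes, keep) if not k]
    if dropped:
        logger.warning(
            "excluding %d zero-variance genes from co-expression", len(dropped)
        )
    genes = [g for g, k in zip(expr.genes, keep) if k]
    if len(genes) < 2:
        return EvidenceTable("CX", {})
    pcc = np.corrcoef(values[keep])
    np.clip(pcc, -1.0, 1.0, out=pcc)
    scores: Dict[Pair, float] = {}
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    vals = pcc[iu, ju]
    for i, j, v in zip(iu.tolist(), ju.tolist(), vals.tolist()):
        scores[canonical_pair(genes[i], genes[j])] = v
    return EvidenceTable("CX", scores)


def domain_weights(profiles: ProfileMatrix) -> np.ndarray:
    """Rarity weight per domain: ``w(f) = -ln(freq(f))`` with ``freq(f)`` the
    fraction of genes carrying ``f``.  A domain carried by every gene gets
    weight 0 (it is uninformative about co-function)."""
    freq = profiles.values.mean(axis=0)
    with np.errstate(divide="ignore"):
        w = -np.log(freq)
    w[~np.isfinite(w)] = 0.0  # absent domains (freq 0) carry no weight either
    return w


def domain_profile_scores(profiles: ProfileMatrix) -> EvidenceTable:
    """Weighted mutual information between binary domain-composition profiles.

    Rarer domains are more informative about shared function, so each domain
    contributes its self-information ``w(f) = -ln(freq(f))``; a gene pair's
    score is the summed weight of the domains they share:

        WMI(a, b) = sum over shared domains f of -ln(freq(f))

    Domains present in no gene or in every gene are dropped as uninformative,
    and pairs sharing no informative domain score 0.  The weighting strategy
    is isolated in :func:`domain_weights` and can be swapped out.
    """
    if not profiles.binary:
        raise ValueError("domain profiles must be binary")
    counts = profiles.values.sum(axis=0)
    informative = (counts >= 1) & (counts < len(profiles.genes))
    X = profiles.values[:, informative]
    w = domain_weights(
        ProfileMatrix(profiles.genes, list(np.array(profiles.features)[informative]),
                      X, binary=True)
    )
    # pairwise sum of weights over shared (1,1) domains: (X * w) @ X.T
    shared = (X * w) @ X.T
    scores: Dict[Pair, float] = {}
    genes = profiles.genes
    iu, ju = np.triu_indices(len(genes), k=1)
    vals = shared[iu, ju]
    for i, j, v in zip(iu.tolist(), ju.tolist(), vals.tolist()):
        scores[canonical_pair(genes[i], genes[j])] = float(v)
    return EvidenceTable("DP", scores)


def _equal_frequency_digitize(row: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize one profile into at most ``n_bins`` equal-frequency bins.

    Quantile edges are deduplicated, so heavily tied profiles (lots of zero
    hit scores) collapse into fewer, well-populated states.
    """
    qs = np.quantile(row, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, row, side="left")


def mutual_information(a: np.ndarray, b: np.ndarray, n_states: int) -> float:
    """Plug-in mutual information (natural log) of two discrete sequences."""
    joint = np.bincount(a * n_states + b, minlength=n_states * n_states).astype(float)
    joint = joint.reshape(n_states, n_states) / len(a)
    pa = joint.sum(axis=1)
    pb = joint.sum(axis=0)
    mask = joint > 0
    outer = np.outer(pa, pb)
    return float(np.sum(joint[mask] * np.log(joint[mask] / outer[mask])))


def phylo_profile_scores(
    profiles: ProfileMatrix,
    domain_groups: Mapping[str, str],
    n_bins: int = 8,
) -> Dict[str, EvidenceTable]:
    """Pairwise mutual information of phylogenetic profiles, per domain of life.

    ``profiles`` holds continuous ``-log(E-value)`` homology-hit strengths of
    each gene across reference genomes; ``domain_groups`` assigns every
    genome to one group (bacteria / eukaryota / archaea).  Per group, each
    gene's sub-profile is discretized into equal-frequency bins and plug-in
    MI (natural log) is computed for every gene pair.  One evidence table per
    group is returned, to be calibrated and integrated separately.
    """
    missing = [f for f in profiles.features if f not in domain_groups]
    if missing:
        raise ValueError(f"features without a group assignment: {missing[:5]}")
    groups: Dict[str, List[int]] = {}
    for idx, f in enumerate(profiles.features):
        groups.setdefault(domain_groups[f], []).append(idx)

    out: Dict[str, EvidenceTable] = {}
    genes = profiles.genes
    n = len(genes)
    for group in sorted(groups):
        cols = groups[group]
        if len(cols) < 2:
            logger.warning(
                "group %r has %d features (<2); skipped", group, len(cols)
            )
            continue
        sub = profiles.values[:, cols]
        disc = np.vstack(
            [_equal_frequency_digitize(sub[i], n_bins) for i in range(n)]
        ).astype(np.int64)
        scores: Dict[Pair, float] = {}
        for i in range(n):
            for j in range(i + 1, n):
                scores[canonical_pair(genes[i], genes[j])] = mutual_information(
                    disc[i], disc[j], n_bins
                )
        out[group] = EvidenceTable(f"PG-{group}", scores)
    return out


def transfer_associalogs(
    source_net: WeightedNetwork, ortho: OrthologMap
) -> EvidenceTable:
    """Transfer co-functional links between species through orthology.

    Every source edge (x, y) is projected onto all target pairs (a, b) with
    ``a in map(x)``, ``b in map(y)`` and ``a != b``, carrying the edge's LLS.
    When several source edges land on the same target pair the maximum is
    kept (redundant orthology paths are not double-counted).  The result is a
    *raw-score* table: transferred scores are re-benchmarked against the
    target species' own gold standard before integration.
    """
    scores: Dict[Pair, float] = {}
    for (x, y), w in source_net.edges.items():
        targets_x = ortho.pairs.get(x)
        targets_y = ortho.pairs.get(y)
        if not targets_x or not targets_y:
            continue
        for a in targets_x:
            for b in targets_y:
                if a == b:
                    continue
                pair = canonical_pair(a, b)
                prev = scores.get(pair)
                if prev is None or w > prev:
                    scores[pair] = w
    if not scores:
        logger.warning("no source edge mapped onto the target species")
    return EvidenceTable("associalog", scores)
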