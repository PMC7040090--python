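"""Planted-module synthetic data: ground truth for every pipeline stage.

The generator partitions a gene universe into disjoint functional modules
plus background genes, then fabricates every raw input the toolkit consumes
— per-source pairwise evidence, an expression matrix, domain and
phylogenetic profile matrices, an ortholog map with a foreign source
network, annotations, a DEG list — such that within-module gene pairs carry
elevated signal and everything else is noise.

Training/evaluation separation is by module: the gold standard contains only
the pairs of a *training* subset of modules, while annotations cover all
modules, so held-out modules provide evaluation truth disjoint from training
by construction.

The pair-score model is deliberately Gaussian rather than mechanistic: the
calibration and integration machinery only ever sees score-versus-label
structure, so a location-shifted normal per source is the minimal model that
exercises it.  Evidence layers cover all module pairs plus a sampled subset
of background pairs, mirroring the sparsity of real evidence sources.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .evidence import OrthologMap
from .gold import GoldStandard, build_gold_standard
from .model import (
    AnnotationSet,
    EvidenceTable,
    ExpressionMatrix,
    Pair,
    ProfileMatrix,
    Term,
    WeightedNetwork,
    canonical_pair,
)
from . import evaluation, integration


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the planted-module benchmark.

    Defaults are desk-scale with clearly recoverable signal: 2,000 genes, 20
    modules of 25 genes, five evidence sources of which one is pure noise,
    within-module scores N(2, 1) against a N(0, 1) background, and half the
    modules used for training.
    """

    n_genes: int = 2000
    n_modules: int = 20
    module_size: int = 25
    n_sources: int = 5
    noise_source_count: int = 1
    within_mean: float = 2.0
    within_sd: float = 1.0
    background_mean: float = 0.0
    background_sd: float = 1.0
    background_pairs_per_source: int = 50000
    train_fraction_of_modules: float = 0.5
    n_samples: int = 40
    n_features: int = 250
    deg_overlap: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules do not fit into the gene universe")
        for name in ("train_fraction_of_modules", "deg_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_source_count > self.n_sources:
            raise ValueError("more noise sources than sources")
        if min(self.n_genes, self.n_modules, self.module_size, self.n_sources,
               self.n_samples, self.n_features) < 1:
            raise ValueError("all sizes must be >= 1")


@dataclass
class World:
    """One synthetic dataset bundle with its ground truth."""

    config: SynthConfig
    genes: List[str]
    modules: List[List[str]]
    train_modules: List[int]
    heldout_modules: List[int]
    evidence_tables: List[EvidenceTable]
    noise_sources: List[str]
    gold_standard: GoldStandard
    expression: ExpressionMatrix
    domain_profiles: ProfileMatrix
    phylo_profiles: ProfileMatrix
    phylo_groups: Dict[str, str]
    ortholog_map: OrthologMap
    source_network: WeightedNetwork
    annotations: AnnotationSet
    deg_genes: List[str]
    truth_pairs: Set[Pair]

    def module_pairs(self, module_index: int) -> Set[Pair]:
        genes = self.modules[module_index]
        return {canonical_pair(a, b) for a, b in itertools.combinations(genes, 2)}


def _sample_background_pairs(
    rng: np.random.Generator,
    n_genes: int,
    count: int,
    forbidden: Set[Tuple[int, int]],
) -> List[Tuple[int, int]]:
    """Sample distinct random index pairs avoiding within-module pairs."""
    total = n_genes * (n_genes - 1) // 2
    count = min(count, total - len(forbidden))
    chosen: Set[Tuple[int, int]] = set()
    while len(chosen) < count:
        need = int((count - len(chosen)) * 1.3) + 16
        i = rng.integers(0, n_genes, size=need)
        j = rng.integers(0, n_genes, size=need)
        for a, b in zip(i.tolist(), j.tolist()):
            if a == b:
                continue
            p = (a, b) if a < b else (b, a)
            if p in forbidden or p in chosen:
                continue
            chosen.add(p)
            if len(chosen) == count:
                break
    return sorted(chosen)


def generate_world(cfg: SynthConfig) -> World:
    """Generate the full synthetic bundle; deterministic for a given config."""
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_genes - 1))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]

    perm = rng.permutation(cfg.n_genes)
    modules: List[List[str]] = []
    module_of = np.full(cfg.n_genes, -1, dtype=int)
    for m in range(cfg.n_modules):
        idx = perm[m * cfg.module_size:(m + 1) * cfg.module_size]
        module_of[idx] = m
        modules.append(sorted(genes[i] for i in idx))

    n_train = int(round(cfg.train_fraction_of_modules * cfg.n_modules))
    train_modules = list(range(n_train))
    heldout_modules = list(range(n_train, cfg.n_modules))

    within_idx: List[Tuple[int, int]] = []
    for m in range(cfg.n_modules):
        idx = sorted(int(i) for i in np.flatnonzero(module_of == m))
        within_idx.extend(itertools.combinations(idx, 2))
    within_set = set(within_idx)

    # --- evidence sources -------------------------------------------------
    n_noise = cfg.noise_source_count
    n_info = cfg.n_sources - n_noise
    source_codes = [f"S{k + 1}" for k in range(n_info)] + [
        f"NS{k + 1}" for k in range(n_noise)
    ]
    noise_sources = source_codes[n_info:]
    tables: List[EvidenceTable] = []
    for code in source_codes:
        bg_idx = _sample_background_pairs(
            rng, cfg.n_genes, cfg.background_pairs_per_source, within_set
        )
        is_noise = code in noise_sources
        w_mean = cfg.background_mean if is_noise else cfg.within_mean
        w_sd = cfg.background_sd if is_noise else cfg.within_sd
        within_scores = rng.normal(w_mean, w_sd, size=len(within_idx))
        bg_scores = rng.normal(cfg.background_mean, cfg.background_sd, size=len(bg_idx))
        scores: Dict[Pair, float] = {}
        for (i, j), s in zip(within_idx, within_scores.tolist()):
            scores[canonical_pair(genes[i], genes[j])] = s
        for (i, j), s in zip(bg_idx, bg_scores.tolist()):
            scores[canonical_pair(genes[i], genes[j])] = s
        tables.append(EvidenceTable(code, scores))

    # --- gold standard: training-module pairs only ------------------------
    positives = [
        (genes[i], genes[j]) for (i, j) in within_idx
        if module_of[i] in set(train_modules)
    ]
    gold = build_gold_standard(positives, universe=genes)

    # --- expression: shared latent factor per module ----------------------
    loading = 0.8
    factors = rng.normal(size=(cfg.n_modules, cfg.n_samples))
    noise = rng.normal(size=(cfg.n_genes, cfg.n_samples))
    expr = np.empty((cfg.n_genes, cfg.n_samples))
    for g in range(cfg.n_genes):
        m = module_of[g]
        if m >= 0:
            expr[g] = loading * factors[m] + _noise_scale(loading) * noise[g]
        else:
            expr[g] = noise[g]
    samples = [f"sample{s:02d}" for s in range(cfg.n_samples)]
    expression = ExpressionMatrix(genes, samples, expr)

    # --- domain profiles: modules carry private rare domains --------------
    n_feat = cfg.n_features
    feat_width = len(str(n_feat - 1))
    domains = [f"IPR{i:0{feat_width}d}" for i in range(n_feat)]
    base_rate = rng.uniform(0.01, 0.15, size=n_feat)
    dp = (rng.random((cfg.n_genes, n_feat)) < base_rate).astype(float)
    private_per_module = max(1, n_feat // (4 * cfg.n_modules))
    feat_perm = rng.permutation(n_feat)
    for m in range(cfg.n_modules):
        feats = feat_perm[m * private_per_module:(m + 1) * private_per_module]
        rows = np.flatnonzero(module_of == m)
        carry = rng.random((len(rows), len(feats))) < 0.8
        dp[np.ix_(rows, feats)] = np.maximum(dp[np.ix_(rows, feats)], carry.astype(float))
    domain_profiles = ProfileMatrix(genes, domains, dp, binary=True)

    # --- phylogenetic profiles: shared module base profile + noise --------
    genomes = [f"genome{i:0{feat_width}d}" for i in range(n_feat)]
    group_names = ("bacteria", "eukaryota", "archaea")
    group_draw = rng.choice(3, size=n_feat, p=(0.6, 0.3, 0.1))
    phylo_groups = {g: group_names[k] for g, k in zip(genomes, group_draw.tolist())}
    module_base = rng.gamma(2.0, 2.0, size=(cfg.n_modules, n_feat))
    pg = rng.gamma(2.0, 2.0, size=(cfg.n_genes, n_feat))
    for m in range(cfg.n_modules):
        rows = np.flatnonzero(module_of == m)
        pg[rows] = np.clip(
            module_base[m] + rng.normal(0.0, 1.0, size=(len(rows), n_feat)), 0.0, None
        )
    phylo_profiles = ProfileMatrix(genes, genomes, pg, binary=False)

    # --- ortholog map + foreign network over half of the modules ----------
    mapped_modules = list(range(0, cfg.n_modules, 2))
    ortho_pairs: Dict[str, Set[str]] = {}
    src_edges: Dict[Pair, float] = {}
    for m in mapped_modules:
        for g in modules[m]:
            ortho_pairs[f"X_{g}"] = {g}
        for a, b in itertools.combinations(modules[m], 2):
            if rng.random() < 0.5:
                sa, sb = f"X_{a}", f"X_{b}"
                src_edges[canonical_pair(sa, sb)] = float(rng.uniform(1.0, 3.0))
    ortholog_map = OrthologMap(ortho_pairs)
    source_network = WeightedNetwork(src_edges)

    # --- annotations over all modules (train + held-out) ------------------
    terms = {
        f"MOD{m:02d}": Term(f"MOD{m:02d}", f"planted module {m}", frozenset(modules[m]))
        for m in range(cfg.n_modules)
    }
    annotations = AnnotationSet("synthetic", terms)

    # --- DEG list: one held-out module, corrupted to the target overlap ----
    deg_module = heldout_modules[0] if heldout_modules else 0
    k_true = int(round(cfg.deg_overlap * cfg.module_size))
    module_genes = modules[deg_module]
    take = rng.permutation(len(module_genes))[:k_true]
    degs = [module_genes[i] for i in sorted(take.tolist())]
    non_module = np.flatnonzero(module_of != deg_module)
    fill = rng.choice(non_module, size=cfg.module_size - k_true, replace=False)
    degs += [genes[i] for i in sorted(fill.tolist())]

    truth_pairs = {canonical_pair(genes[i], genes[j]) for (i, j) in within_idx}

    return World(
        config=cfg,
        genes=genes,
        modules=modules,
        train_modules=train_modules,
        heldout_modules=heldout_modules,
        evidence_tables=tables,
        noise_sources=noise_sources,
        gold_standard=gold,
        expression=expression,
        domain_profiles=domain_profiles,
        phylo_profiles=phylo_profiles,
        phylo_groups=phylo_groups,
        ortholog_map=ortholog_map,
        source_network=source_network,
        annotations=annotations,
        deg_genes=degs,
        truth_pairs=truth_pairs,
    )


def _noise_scale(loading: float) -> float:
    """sqrt(1 - loading^2): noise scale giving unit-variance expression."""
    return float(np.sqrt(1.0 - loading * loading))


@dataclass
class RecoveryReport:
    """How well a built network recovers the planted modules."""

    heldout_auroc_median: float
    heldout_aurocs: Dict[int, float]
    auprc: float
    precision_at_truth: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "heldout_auroc_median": self.heldout_auroc_median,
            "auprc": self.auprc,
            "precision_at_truth": self.precision_at_truth,
        }


def score_recovery(world: World, net: WeightedNetwork) -> RecoveryReport:
    """Recovery metrics of a built network against the planted ground truth.

    * median leave-one-out AUROC across held-out modules (evaluation truth
      disjoint from the training gold standard);
    * trapezoidal AUPRC of ranked edges against all within-module pairs;
    * fraction of truth pairs among the top-``|truth|`` ranked edges.
    """
    net_genes = net.genes()
    aurocs: Dict[int, float] = {}
    for m in world.heldout_modules:
        members = set(world.modules[m]) & net_genes
        if len(members) < 2:
            continue
        aurocs[m] = evaluation.loo_auroc(net, members, fpr_cutoffs=(1.0,)).auroc_full
    median = float(np.median(list(aurocs.values()))) if aurocs else float("nan")

    pairs = list(net.edges.keys())
    ws = np.fromiter(net.edges.values(), dtype=float, count=len(pairs))
    labels = np.array([p in world.truth_pairs for p in pairs], dtype=bool)
    pr_auc = integration.auprc(ws, labels) if labels.any() else 0.0

    k = min(len(world.truth_pairs), len(pairs))
    if k > 0:
        top = np.argsort(-ws, kind="stable")[:k]
        prec_at = float(labels[top].mean())
    else:
        prec_at = 0.0
    return RecoveryReport(median, aurocs, pr_auc, prec_at)
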