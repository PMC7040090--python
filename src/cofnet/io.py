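"""Readers and writers for the plain-text formats the toolkit consumes.

All files are TSV, UTF-8, with ``#``-prefixed comment/header lines:

* edge lists — ``gene_a<TAB>gene_b[<TAB>score]``
* GMT gene sets — ``term_id<TAB>description<TAB>gene...``
* annotation tables — ``gene<TAB>term_id<TAB>namespace``
* expression / profile matrices — gene rows, labelled sample/feature columns

Weights are serialized with 6 significant digits, enough for a bit-stable
round trip at the precision actually carried by the scores.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple, Union

import pandas as pd

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

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


def _rows(path: Union[str, Path]) -> Iterable[Tuple[int, List[str]]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_edge_list(
    path: Union[str, Path], has_weight: bool = True
) -> Union[WeightedNetwork, Set[Pair]]:
    """Read a TSV edge list.

    With ``has_weight=True`` rows are ``gene_a, gene_b, score`` and a
    :class:`WeightedNetwork` is returned; otherwise rows are bare pairs and a
    set of canonical pairs is returned (e.g. gold-standard positives).

    Duplicate pairs with identical scores are deduplicated; conflicting
    scores, self-pairs and malformed rows raise :class:`ParseError` naming
    the line number.
    """
    ncol = 3 if has_weight else 2
    scores: Dict[Pair, float] = {}
    pairs: Set[Pair] = set()
    for lineno, fields in _rows(path):
        if len(fields) != ncol:
            raise ParseError(
                f"{path}:{lineno}: expected {ncol} tab-separated columns, "
                f"got {len(fields)}"
            )
        try:
            pair = canonical_pair(fields[0], fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if not has_weight:
            pairs.add(pair)
            continue
        try:
            score = float(fields[2])
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: non-numeric score {fields[2]!r}"
            ) from exc
        if not math.isfinite(score):
            raise ParseError(f"{path}:{lineno}: non-finite score {fields[2]!r}")
        if pair in scores and not math.isclose(
            scores[pair], score, rel_tol=1e-9, abs_tol=0.0
        ):
            raise ParseError(
                f"{path}:{lineno}: conflicting score for pair {pair}: "
                f"{scores[pair]!r} vs {score!r}"
            )
        scores[pair] = score
    if not has_weight:
        return pairs
    return WeightedNetwork(scores)


def read_evidence_table(path: Union[str, Path], source_code: str) -> EvidenceTable:
    """Read a weighted edge list as one data source's evidence table."""
    net = read_edge_list(path, has_weight=True)
    assert isinstance(net, WeightedNetwork)
    return EvidenceTable(source_code, net.edges)


def write_edge_list(
    obj: Union[WeightedNetwork, EvidenceTable, Iterable[Pair]],
    path: Union[str, Path],
) -> None:
    """Write an edge list TSV with deterministic (canonical pair sort) order.

    ``read_edge_list(write_edge_list(x))`` reproduces the exact edge map.
    """
    if isinstance(obj, WeightedNetwork):
        scores: Dict[Pair, float] = obj.edges
        weighted = True
    elif isinstance(obj, EvidenceTable):
        scores = obj.scores
        weighted = True
    else:
        scores = {canonical_pair(*p): 0.0 for p in obj}
        weighted = False
    with open(path, "w", encoding="utf-8") as fh:
        if weighted:
            fh.write("#gene_a\tgene_b\tscore\n")
            for (a, b) in sorted(scores):
                fh.write(f"{a}\t{b}\t{scores[(a, b)]:.6g}\n")
        else:
            fh.write("#gene_a\tgene_b\n")
            for (a, b) in sorted(scores):
                fh.write(f"{a}\t{b}\n")


def read_gene_list(path: Union[str, Path]) -> List[str]:
    """Read a one-gene-per-line list (e.g. differentially expressed genes)."""
    genes: List[str] = []
    seen: Set[str] = set()
    for _lineno, fields in _rows(path):
        g = fields[0].strip()
        if g and g not in seen:
            seen.add(g)
            genes.append(g)
    return genes


def write_gene_list(genes: Iterable[str], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path: Union[str, Path], namespace: str = "") -> AnnotationSet:
    """Read a GMT gene-set file: ``term_id<TAB>description<TAB>gene...``.

    Terms with no genes are dropped with a logged warning; duplicate genes
    within a row are deduplicated.  ``namespace`` defaults to the file stem.
    """
    path = Path(path)
    namespace = namespace or path.stem
    terms: Dict[str, Term] = {}
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: GMT rows need >= 2 columns")
        term_id, name = fields[0], fields[1]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            logger.warning("%s:%d: term %s has no genes; dropped", path, lineno, term_id)
            continue
        terms[term_id] = Term(term_id, name or term_id, genes)
    return AnnotationSet(namespace, terms)


def write_gmt(annos: AnnotationSet, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(annos.terms):
            t = annos.terms[term_id]
            genes = "\t".join(sorted(t.genes))
            fh.write(f"{t.term_id}\t{t.name}\t{genes}\n")


def read_annotation_tsv(path: Union[str, Path]) -> List[AnnotationSet]:
    """Read a flat ``gene, term_id, namespace`` table into AnnotationSets."""
    by_ns: Dict[str, Dict[str, Set[str]]] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 3:
            raise ParseError(f"{path}:{lineno}: expected gene, term_id, namespace")
        gene, term_id, ns = fields
        by_ns.setdefault(ns, {}).setdefault(term_id, set()).add(gene)
    out = []
    for ns in sorted(by_ns):
        terms = {
            tid: Term(tid, tid, frozenset(genes)) for tid, genes in by_ns[ns].items()
        }
        out.append(AnnotationSet(ns, terms))
    return out


def _read_matrix(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    # a '#'-prefixed header cell is tolerated ("#gene")
    df.index.name = str(df.index.name or "gene").lstrip("#")
    return df


def read_expression_matrix(path: Union[str, Path]) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column = gene id, header = samples)."""
    df = _read_matrix(path)
    return ExpressionMatrix(
        [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy(float)
    )


def write_expression_matrix(expr: ExpressionMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(expr.values, index=expr.genes, columns=expr.samples)
    df.index.name = "#gene"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_profile_matrix(path: Union[str, Path], binary: bool = False) -> ProfileMatrix:
    """Read a genes x features TSV profile matrix."""
    df = _read_matrix(path)
    return ProfileMatrix(
        [str(g) for g in df.index],
        [str(c) for c in df.columns],
        df.to_numpy(float),
        binary=binary,
    )


def write_profile_matrix(prof: ProfileMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(prof.values, index=prof.genes, columns=prof.features)
    df.index.name = "#gene"
    fmt = "%g" if prof.binary else "%.6g"
    df.to_csv(path, sep="\t", float_format=fmt)


def read_feature_groups(path: Union[str, Path]) -> Dict[str, str]:
    """Read a ``feature<TAB>group`` map (e.g. genome -> domain of life)."""
    groups: Dict[str, str] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected feature, group")
        groups[fields[0]] = fields[1]
    return groups


def read_ortholog_map(path: Union[str, Path]) -> Dict[str, Set[str]]:
    """Read a ``source_gene<TAB>target_gene`` many-to-many ortholog table."""
    out: Dict[str, Set[str]] = {}
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected source_gene, target_gene")
        out.setdefault(fields[0], set()).add(fields[1])
    return out
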