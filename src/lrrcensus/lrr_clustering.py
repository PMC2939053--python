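"""LRR-domain subsequence extraction and Markov clustering of a similarity graph.

Repeat domains evolve fast and align poorly over full-length proteins, so
relatedness is assessed on the extracted LRR subsequences alone: an
all-vs-all similarity search yields e-values, edges at or below a cutoff
(default 1e-15) form a graph weighted by -log10(e), and Markov clustering
(MCL) partitions the graph into clusters and singletons.

MCL here is the standard flow simulation on the column-stochastic matrix:
alternate matrix expansion (power ``expansion``) with elementwise inflation
(power ``inflation`` followed by column re-normalisation), pruning tiny
entries between iterations, until the matrix stops changing. Clusters are
read off as connected components of the non-zero pattern of the limit
matrix. The full OrthoMCL protocol additionally normalises reciprocal best
hits across species before clustering; only the MCL core with the stated
cutoff and inflation is implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .annotation_io import (
    DomainHit,
    ParseError,
    ProteinRecord,
    Source,
    ValidationError,
    _iter_lines,
    atomic_write_text,
)
from .architecture import LRR_ACCESSIONS

__all__ = [
    "DomainSubsequence",
    "SimilarityEdge",
    "ClusterSet",
    "extract_subsequences",
    "build_graph",
    "mcl",
    "cluster_stats",
    "read_edges",
    "write_edges",
    "write_clusters",
    "write_subsequences_fasta",
    "pairwise_edges",
]


@dataclass(frozen=True)
class DomainSubsequence:
    """One extracted domain region, identified as ``proteinid/start-end``."""

    id: str
    parent_protein: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValidationError(f"{self.id}: empty subsequence")


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected similarity edge with a search e-value; stored as a < b."""

    a: str
    b: str
    e_value: float

    def __post_init__(self):
        if self.a == self.b:
            raise ValidationError(f"self-edge on {self.a!r}")
        if self.e_value < 0:
            raise ValidationError(f"negative e-value on edge {self.a}-{self.b}")
        if self.b < self.a:
            a, b = self.b, self.a
            object.__setattr__(self, "a", a)
            object.__setattr__(self, "b", b)


@dataclass(frozen=True)
class ClusterSet:
    """An MCL result: clusters of size >= 2 plus singletons, partitioning the ids."""

    clusters: tuple[tuple[str, ...], ...]
    singletons: frozenset
    converged: bool = True
    n_iterations: int = 0
    max_colsum_deviation: float = 0.0

    def __post_init__(self):
        clusters = tuple(tuple(sorted(c)) for c in self.clusters)
        clusters = tuple(sorted(clusters, key=lambda c: (-len(c), c)))
        object.__setattr__(self, "clusters", clusters)
        object.__setattr__(self, "singletons", frozenset(self.singletons))
        seen: set[str] = set()
        for cluster in clusters:
            if len(cluster) < 2:
                raise ValidationError("clusters must have size >= 2 (smaller sets are singletons)")
            for node in cluster:
                if node in seen:
                    raise ValidationError(f"node {node!r} appears in two clusters")
                seen.add(node)
        overlap = seen & self.singletons
        if overlap:
            raise ValidationError(f"nodes both clustered and singleton: {sorted(overlap)[:5]}")

    @property
    def all_ids(self) -> frozenset:
        ids = set(self.singletons)
        for cluster in self.clusters:
            ids.update(cluster)
        return frozenset(ids)


def extract_subsequences(
    proteins: Iterable[ProteinRecord],
    hits: Iterable[DomainHit],
    lrr_accessions: frozenset = LRR_ACCESSIONS,
) -> list[DomainSubsequence]:
    """Slice one subsequence per LRR hit from the parent protein sequence."""
    by_id = {p.protein_id: p for p in proteins}
    out = []
    for hit in hits:
        if hit.accession not in lrr_accessions:
            continue
        prot = by_id.get(hit.protein_id)
        if prot is None:
            raise ValidationError(f"hit references unknown protein {hit.protein_id!r}")
        if prot.sequence is None:
            raise ValidationError(f"{prot.protein_id}: protein record carries no sequence")
        if hit.end > prot.length:
            raise ValidationError(
                f"{prot.protein_id}: hit {hit.start}-{hit.end} outside sequence of length {prot.length}"
            )
        out.append(
            DomainSubsequence(
                id=f"{hit.protein_id}/{hit.start}-{hit.end}",
                parent_protein=hit.protein_id,
                residues=prot.sequence[hit.start - 1 : hit.end],
            )
        )
    return out


def build_graph(
    edges: Iterable[SimilarityEdge],
    e_cutoff: float = 1e-15,
    zero_cap: float = 200.0,
    nodes: Iterable[str] = (),
) -> nx.Graph:
    """Threshold edges at ``e_cutoff`` and weight survivors by -log10(e).

    An e-value of exactly zero maps to ``zero_cap`` (and every weight is
    capped there). ``nodes`` may pre-register ids with no passing edges so
    they surface later as singletons.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for edge in edges:
        graph.add_node(edge.a)
        graph.add_node(edge.b)
        if edge.e_value > e_cutoff:
            continue
        weight = zero_cap if edge.e_value == 0 else min(-math.log10(edge.e_value), zero_cap)
        # parallel entries keep the best (largest) weight
        if graph.has_edge(edge.a, edge.b):
            weight = max(weight, graph[edge.a][edge.b]["weight"])
        graph.add_edge(edge.a, edge.b, weight=weight)
    return graph


def _normalize_columns(matrix: sp.csc_matrix) -> sp.csc_matrix:
    colsums = np.asarray(matrix.sum(axis=0)).ravel()
    colsums[colsums == 0] = 1.0
    scale = sp.diags(1.0 / colsums)
    return (matrix @ scale).tocsc()


def mcl(
    graph: nx.Graph,
    inflation: float = 1.5,
    expansion: int = 2,
    max_iter: int = 100,
    prune_below: float = 1e-5,
    converge_tol: float = 1e-6,
) -> ClusterSet:
    """Markov clustering of a weighted undirected graph.

    Self-loops are added with the node's maximum incident edge weight (1
    for isolated nodes) before column normalisation — the usual
    regularisation that keeps the process aperiodic. Iteration alternates
    expansion and inflation with pruning of entries below ``prune_below``,
    stopping when the maximum absolute change drops under ``converge_tol``.
    Non-convergence within ``max_iter`` produces a warning and the current
    interpretation, flagged via ``converged=False``.

    Deterministic for a fixed graph: nodes are processed in sorted order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes())
    isolated = [n for n in nodes if graph.degree(n) == 0]
    active = [n for n in nodes if graph.degree(n) > 0]
    if not active:
        return ClusterSet(clusters=(), singletons=frozenset(isolated))

    adjacency = nx.to_scipy_sparse_array(graph, nodelist=active, weight="weight", format="csc")
    max_incident = np.asarray(adjacency.max(axis=0).todense()).ravel()
    max_incident[max_incident <= 0] = 1.0
    matrix = _normalize_columns((adjacency + sp.diags(max_incident)).tocsc())

    converged = False
    iteration = 0
    max_dev = 0.0
    for iteration in range(1, max_iter + 1):
        previous = matrix.copy()
        expanded = matrix
        for _ in range(expansion - 1):
            expanded = (expanded @ matrix).tocsc()
        matrix = expanded
        matrix.data = np.power(matrix.data, inflation)
        matrix = _normalize_columns(matrix)
        if prune_below > 0:
            matrix.data[matrix.data < prune_below] = 0.0
            matrix.eliminate_zeros()
            matrix = _normalize_columns(matrix)
        dev = float(np.max(np.abs(np.asarray(matrix.sum(axis=0)).ravel() - 1.0)))
        max_dev = max(max_dev, dev)
        delta = sp.csc_matrix(matrix - previous)
        change = float(np.max(np.abs(delta.data))) if delta.nnz else 0.0
        if change < converge_tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {max_iter} iterations (last change above tolerance)",
            RuntimeWarning,
            stacklevel=2,
        )

    # clusters: connected components of the limit matrix's non-zero pattern
    pattern = matrix + matrix.T
    n_comp, labels = sp.csgraph.connected_components(pattern, directed=False)
    groups: dict[int, list[str]] = {}
    for node, label in zip(active, labels):
        groups.setdefault(int(label), []).append(node)
    clusters = [tuple(g) for g in groups.values() if len(g) >= 2]
    singles = set(isolated)
    singles.update(g[0] for g in groups.values() if len(g) == 1)
    return ClusterSet(
        clusters=tuple(clusters),
        singletons=frozenset(singles),
        converged=converged,
        n_iterations=iteration,
        max_colsum_deviation=max_dev,
    )


def cluster_stats(cs: ClusterSet) -> dict:
    """Counts over a cluster set: clusters, singletons, total sequences."""
    n_clustered = sum(len(c) for c in cs.clusters)
    return {
        "n_clusters": len(cs.clusters),
        "n_singletons": len(cs.singletons),
        "n_sequences": n_clustered + len(cs.singletons),
    }


# ---------------------------------------------------------------------------
# formats: ABC edge list, MCL-style cluster lines, subsequence FASTA

def read_edges(source: Source) -> list[SimilarityEdge]:
    """Read a 3-column TSV edge list (id_a, id_b, e_value) — the ABC dialect."""
    edges = []
    for lineno, line in _iter_lines(source):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ParseError(f"expected 3 tab-separated fields, got {len(parts)}", lineno)
        try:
            edges.append(SimilarityEdge(a=parts[0], b=parts[1], e_value=float(parts[2])))
        except (ValueError, ValidationError) as exc:
            raise ParseError(str(exc), lineno) from exc
    return edges


def write_edges(edges: Sequence[SimilarityEdge], sink) -> None:
    import os

    lines = [f"{e.a}\t{e.b}\t{e.e_value:g}" for e in edges]
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, (str, os.PathLike)):
        atomic_write_text(sink, text)
    else:
        sink.write(text)


def write_clusters(cs: ClusterSet, sink) -> None:
    """One cluster per line, tab-separated ids; singletons follow, one per line."""
    import os

    lines = ["\t".join(cluster) for cluster in cs.clusters]
    lines.extend(sorted(cs.singletons))
    text = "\n".join(lines) + ("\n" if lines else "")
    if isinstance(sink, (str, os.PathLike)):
        atomic_write_text(sink, text)
    else:
        sink.write(text)


def write_subsequences_fasta(subseqs: Sequence[DomainSubsequence], sink) -> None:
    """Export extracted domain subsequences for external tree building."""
    import os

    chunks = [f">{s.id}\n{s.residues}" for s in subseqs]
    text = "\n".join(chunks) + ("\n" if chunks else "")
    if isinstance(sink, (str, os.PathLike)):
        atomic_write_text(sink, text)
    else:
        sink.write(text)


def pairwise_edges(
    subseqs: Sequence[DomainSubsequence],
    max_e_value: float = 10.0,
) -> list[SimilarityEdge]:
    """All-vs-all local-alignment similarity for small, self-contained runs.

    Scores Smith-Waterman alignments (BLOSUM62, affine gaps) with Biopython
    and converts bit scores to Karlin-Altschul e-values for the searched
    residue space. Quadratic in the number of subsequences — intended for
    demo datasets; use a real search tool for anything large.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    # gapped BLOSUM62 statistics
    lam, kparam = 0.267, 0.041
    total = sum(len(s.residues) for s in subseqs)
    edges = []
    for i, sub_a in enumerate(subseqs):
        for sub_b in subseqs[i + 1 :]:
            score = aligner.score(sub_a.residues, sub_b.residues)
            e_val = kparam * len(sub_a.residues) * (total - len(sub_a.residues)) * math.exp(
                -lam * score
            )
            if e_val <= max_e_value:
                edges.append(SimilarityEdge(a=sub_a.id, b=sub_b.id, e_value=e_val))
    return edges
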