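"""Independent reference implementations used only to cross-check the package.

These are deliberately written against different libraries/idioms than the
implementations they check: dense numpy matrix powers instead of sparse
algebra for MCL, and a clause-by-clause rule evaluator instead of the
ClassRule.matches method.
"""

from __future__ import annotations

import numpy as np


def dense_mcl_partition(
    nodes,
    weighted_edges,
    inflation,
    expansion=2,
    max_iter=200,
    prune_below=1e-5,
    converge_tol=1e-6,
):
    """Dense-matrix MCL; returns (frozenset of clusters >=2, frozenset singletons).

    Mirrors the canonical algorithm: max-incident self-loops, column
    normalisation, expansion/inflation/prune loop, components of the limit
    pattern. Isolated nodes are singletons.
    """
    nodes = sorted(nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b, w in weighted_edges:
        i, j = index[a], index[b]
        adj[i, j] = max(adj[i, j], w)
        adj[j, i] = max(adj[j, i], w)
    degree = adj.sum(axis=0)
    active = [i for i in range(n) if degree[i] > 0]
    isolated = [nodes[i] for i in range(n) if degree[i] == 0]
    if not active:
        return frozenset(), frozenset(isolated)
    mat = adj[np.ix_(active, active)]
    loops = mat.max(axis=0)
    loops[loops <= 0] = 1.0
    mat = mat + np.diag(loops)
    mat = mat / mat.sum(axis=0)
    for _ in range(max_iter):
        prev = mat.copy()
        mat = np.linalg.matrix_power(mat, expansion)
        mat = mat ** inflation
        mat = mat / mat.sum(axis=0)
        mat[mat < prune_below] = 0.0
        colsum = mat.sum(axis=0)
        colsum[colsum == 0] = 1.0
        mat = mat / colsum
        if np.abs(mat - prev).max() < converge_tol:
            break
    pattern = (mat + mat.T) > 0
    labels = _components(pattern)
    groups = {}
    for local_idx, label in enumerate(labels):
        groups.setdefault(label, []).append(nodes[active[local_idx]])
    clusters = frozenset(
        tuple(sorted(g)) for g in groups.values() if len(g) >= 2
    )
    singles = set(isolated)
    singles.update(g[0] for g in groups.values() if len(g) == 1)
    return clusters, frozenset(singles)


def _components(pattern):
    """Connected-component labels of a boolean adjacency matrix (BFS)."""
    n = pattern.shape[0]
    labels = [-1] * n
    current = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            node = stack.pop()
            for nbr in np.nonzero(pattern[node])[0]:
                if labels[nbr] == -1:
                    labels[nbr] = current
                    stack.append(nbr)
        current += 1
    return labels


def brute_force_labels(arch, rules) -> frozenset:
    """Evaluate each rule clause independently against an architecture."""
    accessions = {hit.accession for hit in arch.domains}
    n_tm = len(arch.tm_corrected)
    has_sp = arch.signal_peptide is not None
    labels = set()
    for name, rule in rules.items():
        ok = True
        for group in rule.required_groups:
            if not any(acc in accessions for acc in group):
                ok = False
        for acc in rule.forbidden:
            if acc in accessions:
                ok = False
        kind, k = rule.tm.kind, rule.tm.k
        if kind == "exact" and n_tm != k:
            ok = False
        if kind == "at_least" and n_tm < k:
            ok = False
        if rule.signal_peptide == "required" and not has_sp:
            ok = False
        if rule.signal_peptide == "forbidden" and has_sp:
            ok = False
        if ok:
            labels.add(name)
    return frozenset(labels)
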