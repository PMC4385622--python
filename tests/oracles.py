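"""Independent brute-force oracles.

Everything here is deliberately naive: exhaustive enumeration of simple
paths, direct recounting, and a from-scratch permutation loop.  None of
it shares code with the package's Dijkstra/reconstruction machinery, so
agreement is meaningful.
"""

from itertools import combinations

import numpy as np


def enumerate_simple_paths(edges, source, target):
    """All simple paths in an undirected weighted edge dict
    {frozenset({u, v}): weight}; yields (node_tuple, total_weight)."""
    adjacency = {}
    for key, w in edges.items():
        u, v = tuple(key)
        adjacency.setdefault(u, []).append((v, w))
        adjacency.setdefault(v, []).append((u, w))

    def _walk(path, weight):
        last = path[-1]
        if last == target:
            yield tuple(path), weight
            return
        for nxt, w in adjacency.get(last, ()):
            if nxt not in path:
                path.append(nxt)
                yield from _walk(path, weight + w)
                path.pop()

    if source in adjacency:
        yield from _walk([source], 0)


def min_weight_paths(edges, source, target):
    """(min_total_weight, sorted list of minimum-weight node tuples); (None, []) if disconnected."""
    best = None
    paths = []
    for nodes, weight in enumerate_simple_paths(edges, source, target):
        if best is None or weight < best:
            best, paths = weight, [nodes]
        elif weight == best:
            paths.append(nodes)
    return best, sorted(paths)


def lex_min_shortest_path(edges, source, target):
    """The lexicographically smallest minimum-weight path, or None."""
    _, paths = min_weight_paths(edges, source, target)
    return paths[0] if paths else None


def seed_betweenness_counts(edges, seeds, mode="single_path"):
    """Inner-node counts over all unordered seed pairs.

    Returns (counts dict node -> int, pairs_evaluated, pairs_disconnected).
    """
    counts = {}
    evaluated = disconnected = 0
    for s, t in combinations(sorted(seeds), 2):
        _, paths = min_weight_paths(edges, s, t)
        if not paths:
            disconnected += 1
            continue
        evaluated += 1
        chosen = paths[:1] if mode == "single_path" else paths
        for p in chosen:
            for node in p[1:-1]:
                counts[node] = counts.get(node, 0) + 1
    return counts, evaluated, disconnected


def permutation_fdrs(edges, protein_ids, chemical_ids, seed_ids, candidate_ids,
                     n_genes, n_chems, n_permutations, rng_seed,
                     comparator="strictly_greater", mode="single_path"):
    """From-scratch replay of the permutation test.

    Mirrors the package's documented sampling protocol -- one generator
    seeded from ``rng_seed``; per permutation, one ``choice`` over the
    ascending-sorted protein ids then one over the chemical ids -- but
    computes every betweenness table by exhaustive enumeration.
    """
    observed, _, _ = seed_betweenness_counts(edges, seed_ids, mode)
    obs = {c: observed.get(c, 0) for c in candidate_ids}
    exceed = {c: 0 for c in candidate_ids}
    rng = np.random.default_rng(rng_seed)
    proteins = sorted(protein_ids)
    chemicals = sorted(chemical_ids)
    for _ in range(n_permutations):
        null_seeds = []
        if n_genes:
            null_seeds.extend(rng.choice(proteins, size=n_genes, replace=False))
        if n_chems:
            null_seeds.extend(rng.choice(chemicals, size=n_chems, replace=False))
        null, _, _ = seed_betweenness_counts(edges, [str(s) for s in null_seeds], mode)
        for c in candidate_ids:
            nv, ov = null.get(c, 0), obs[c]
            if (nv > ov) if comparator == "strictly_greater" else (nv >= ov):
                exceed[c] += 1
    return {c: exceed[c] / n_permutations for c in candidate_ids}


def random_graph_edges(rng, n_nodes, edge_prob=0.45, score_lo=1, score_hi=999):
    """Random undirected scored graph over nodes n0..n{k-1} as an edge dict
    {frozenset: weight} plus the score map {frozenset: score}."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    scores = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                scores[frozenset((nodes[i], nodes[j]))] = int(rng.integers(score_lo, score_hi + 1))
    weights = {k: 1000 - s for k, s in scores.items()}
    return nodes, scores, weights
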