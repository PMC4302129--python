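"""Independent first-principles oracles used to validate the statistics.

Everything here is deliberately naive — plain loops, direct transcription
of textbook definitions, exhaustive enumeration — and shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


# ----------------------------------------------------------- diversity
def naive_ho(genotypes: list[str]) -> float:
    het = [g.split("/")[0] != g.split("/")[1] for g in genotypes]
    return sum(het) / len(het)


def naive_unbiased_he(genotypes: list[str]) -> float:
    alleles = [a for g in genotypes for a in g.split("/")]
    n = len(genotypes)
    freqs = {a: alleles.count(a) / len(alleles) for a in set(alleles)}
    return (2 * n) / (2 * n - 1) * (1 - sum(p * p for p in freqs.values()))


def naive_fw(genotypes: list[str]) -> float:
    he = naive_unbiased_he(genotypes)
    return 1 - naive_ho(genotypes) / he if he > 0 else float("nan")


def naive_gst(focal: list[str], rest: list[str]) -> float:
    def freqs(gens):
        alleles = [a for g in gens for a in g.split("/")]
        return {a: alleles.count(a) / len(alleles) for a in set(alleles)}

    nf, nr = len(focal), len(rest)
    pf, pr = freqs(focal), freqs(rest)
    hs_f = 1 - sum(p * p for p in pf.values())
    hs_r = 1 - sum(p * p for p in pr.values())
    hs = (nf * hs_f + nr * hs_r) / (nf + nr)
    pooled = {
        a: (nf * pf.get(a, 0) + nr * pr.get(a, 0)) / (nf + nr)
        for a in set(pf) | set(pr)
    }
    ht = 1 - sum(p * p for p in pooled.values())
    return (ht - hs) / ht if ht > 0 else float("nan")


# ----------------------------------------------------------- WC theta
def naive_theta(loci: list[tuple[list[str], list[str]]]) -> float:
    """Multi-locus Weir-Cockerham theta for two populations by the
    ratio-of-sums rule; ``loci`` holds per-locus (pop-A, pop-B) non-missing
    genotype lists."""
    num = den = 0.0
    for pops in loci:
        comp = _naive_wc_locus(pops)
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den


def _naive_wc_locus(pops):
    r = 2
    alleles = sorted({al for gens in pops for g in gens for al in g.split("/")})
    if len(alleles) < 2:
        return None
    n = [len(g) for g in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    a_s = b_s = c_s = 0.0
    for al in alleles:
        p = []
        h = []
        for gens in pops:
            cnt = sum(g.split("/").count(al) for g in gens)
            het = sum(
                1 for g in gens if al in g.split("/") and g.split("/")[0] != g.split("/")[1]
            )
            p.append(cnt / (2 * len(gens)))
            h.append(het / len(gens))
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_s += a
        b_s += b
        c_s += c
    return a_s, b_s, c_s


# --------------------------------------------------- simple matching
def naive_simple_matching(row_a, row_b, mode: str) -> float:
    sims = []
    for a, b in zip(row_a, row_b):
        if not isinstance(a, str) or not isinstance(b, str):
            continue
        if mode == "haplotypic":
            sims.append(1.0 if a == b else 0.0)
        else:
            xa, xb = sorted(a.split("/")), sorted(b.split("/"))
            shared = 0
            pool = list(xb)
            for al in xa:
                if al in pool:
                    pool.remove(al)
                    shared += 1
            sims.append(shared / 2)
    return 1 - sum(sims) / len(sims)


# --------------------------------------------------------------- trees
def enumerate_unrooted_topologies(leaves: list[str]):
    """All unrooted binary leaf-labeled topologies as edge lists."""
    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    base = [(leaves[0], "i0"), (leaves[1], "i0"), (leaves[2], "i0")]
    stack = [(base, 3)]
    while stack:
        tree, k = stack.pop()
        if k == len(leaves):
            yield tree
            continue
        internals = {n for e in tree for n in e if str(n).startswith("i")}
        new_int = f"i{len(internals)}"
        for idx, (u, v) in enumerate(tree):
            t2 = tree[:idx] + tree[idx + 1 :] + [
                (u, new_int),
                (v, new_int),
                (leaves[k], new_int),
            ]
            stack.append((t2, k + 1))


def _leaf_paths(edges, leaves):
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    paths = {}
    for a, b in itertools.combinations(leaves, 2):
        # BFS path from a to b
        prev = {a: None}
        queue = [a]
        while queue:
            x = queue.pop(0)
            if x == b:
                break
            for y in adj[x]:
                if y not in prev:
                    prev[y] = x
                    queue.append(y)
        path_edges = []
        node = b
        while prev[node] is not None:
            path_edges.append(frozenset((node, prev[node])))
            node = prev[node]
        paths[(a, b)] = path_edges
    return paths


def fit_tree_lengths(edges, leaves, dist):
    """Least-squares non-negative edge lengths for a fixed topology;
    returns (lengths per edge, residual, fitted patristic dict)."""
    from scipy.optimize import nnls

    edge_keys = [frozenset(e) for e in edges]
    pairs = list(itertools.combinations(leaves, 2))
    paths = _leaf_paths(edges, leaves)
    A = np.zeros((len(pairs), len(edge_keys)))
    d = np.zeros(len(pairs))
    for row, (a, b) in enumerate(pairs):
        for e in paths[(a, b)]:
            A[row, edge_keys.index(e)] = 1.0
        d[row] = dist[(a, b)] if (a, b) in dist else dist[(b, a)]
    x, rnorm = nnls(A, d)
    fitted = {pair: float(A[row] @ x) for row, pair in enumerate(pairs)}
    return x, rnorm, fitted


def exhaustive_best_tree(leaves, dist):
    """Search all topologies; return the (splits, patristic) of the best
    least-squares fit (zero residual when the distances are additive)."""
    best = None
    for edges in enumerate_unrooted_topologies(list(leaves)):
        _x, rnorm, fitted = fit_tree_lengths(edges, leaves, dist)
        if best is None or rnorm < best[0]:
            best = (rnorm, edges, fitted)
    rnorm, edges, fitted = best
    return rnorm, tree_splits(edges, set(leaves)), fitted


def tree_splits(edges, leaf_set):
    """Non-trivial bipartitions of the leaf set induced by internal edges."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    for u, v in edges:
        # collect leaves on u's side when edge (u, v) removed
        seen = {u}
        queue = [u]
        while queue:
            x = queue.pop()
            for y in adj[x]:
                if y == v and x == u:
                    continue
                if y not in seen and not (x == u and y == v):
                    seen.add(y)
                    queue.append(y)
        side = frozenset(w for w in seen if w in leaf_set)
        other = frozenset(leaf_set - side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits


def newick_splits_and_patristic(newick: str, leaf_set):
    """Splits and leaf-pair path lengths of a newick tree (via dendropy)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    patristic = {
        (a, b): pdm.patristic_distance(taxa[a], taxa[b])
        for a, b in itertools.combinations(sorted(leaf_set), 2)
    }
    splits = set()
    for edge in tree.preorder_edge_iter():
        if edge.head_node is None or edge.tail_node is None:
            continue
        side = frozenset(
            leaf.taxon.label for leaf in edge.head_node.leaf_iter()
        )
        other = frozenset(leaf_set - side)
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset((side, other)))
    return splits, patristic
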