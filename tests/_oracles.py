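"""Independent oracles used by the test suite.

These deliberately avoid the library's alignment code paths: the local
aligner oracle is a plain-Python affine-gap dynamic program, itself validated
on tiny inputs against a brute-force recursion that enumerates every gapped
alignment explicitly.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def blosum62(x: str, y: str) -> float:
    return _B62[x, y]


def sw_score_oracle(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Smith-Waterman score, affine gaps costing open + k*extend."""
    first = gap_open + gap_extend
    m, n = len(a), len(b)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    Ix = [[NEG] * (n + 1) for _ in range(m + 1)]
    Iy = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            diag = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1], 0.0)
            M[i][j] = _B62[ai, b[j - 1]] + diag
            Ix[i][j] = max(M[i - 1][j] - first, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - first, Iy[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best = M[i][j]
    return int(best)


def _global_enum(a: str, b: str, gap_open: int, gap_extend: int) -> float:
    """Best global alignment score by explicit recursion over every gapped
    alignment (exponential; only for tiny sequences)."""
    first = gap_open + gap_extend

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            best = max(best, _B62[a[i], b[j]] + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else first
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else first
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "")


def sw_score_enumeration(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Local score as the max over all substring pairs of the enumerated
    global score (tiny inputs only)."""
    best = 0.0
    for i0 in range(len(a) + 1):
        for i1 in range(i0 + 1, len(a) + 1):
            for j0 in range(len(b) + 1):
                for j1 in range(j0 + 1, len(b) + 1):
                    s = _global_enum(a[i0:i1], b[j0:j1], gap_open, gap_extend)
                    if s > best:
                        best = s
    return int(best)


def random_additive_tree(rng, n_taxa: int):
    """Random binary tree with positive branch lengths, built by random
    sequential joins; the distance matrix is exact path-length summation.

    Returns (labels, D, splits) where splits are the tree's non-trivial
    bipartitions, each encoded as the side not containing the smallest label.
    """
    import numpy as np

    labels = [f"t{i}" for i in range(n_taxa)]
    index = {lab: k for k, lab in enumerate(labels)}
    D = np.zeros((n_taxa, n_taxa))
    # each active subtree: dict leaf -> distance to subtree root
    active = [{lab: 0.0} for lab in labels]
    splits: set[frozenset] = set()
    all_set = frozenset(labels)
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        left, right = active[j], active[i]  # pop larger index first
        e1 = 0.1 + 0.9 * rng.random()
        e2 = 0.1 + 0.9 * rng.random()
        for u, du in left.items():
            for v, dv in right.items():
                d = du + e1 + dv + e2
                D[index[u], index[v]] = D[index[v], index[u]] = d
        merged = {u: du + e1 for u, du in left.items()}
        merged.update({v: dv + e2 for v, dv in right.items()})
        del active[j], active[i]
        active.append(merged)
        side = frozenset(merged)
        if 2 <= len(side) <= n_taxa - 2:
            if labels[0] in side:
                side = all_set - side
            if len(side) >= 2:
                splits.add(side)
    left, right = active
    bridge = 0.1 + 0.9 * rng.random()
    for u, du in left.items():
        for v, dv in right.items():
            d = du + dv + bridge
            D[index[u], index[v]] = D[index[v], index[u]] = d
    for side in (frozenset(left), frozenset(right)):
        if 2 <= len(side) <= n_taxa - 2:
            norm = all_set - side if labels[0] in side else side
            if len(norm) >= 2:
                splits.add(norm)
    return labels, D, splits


def tree_path_lengths(tree, labels):
    """Leaf-to-leaf path-length matrix of a grasfam Tree, by recursion over
    the node structure (independent of any library distance code)."""
    import numpy as np

    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    D = np.zeros((n, n))

    def depths(node, acc):
        if node.is_leaf():
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(depths(c, acc + c.length))
        return out

    def walk(node):
        subs = []
        for c in node.children:
            subs.append(depths(c, c.length))
            walk(c)
        for a in range(len(subs)):
            for b in range(a + 1, len(subs)):
                for u, du in subs[a].items():
                    for v, dv in subs[b].items():
                        D[index[u], index[v]] = D[index[v], index[u]] = du + dv

    walk(tree.root)
    return D
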