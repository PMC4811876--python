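"""Distance phylogenetics: column masking, NJ, bootstrap consensus and
reference-anchored subfamily assignment.

Trees are built by neighbor joining on p-distances or on JTT-calibrated
corrected distances (Kimura's empirical protein correction
``d = -ln(1 - p - 0.2 p^2)``, the standard closed-form approximation to the
JTT expected-substitution curve).  Clade support comes from seeded bootstrap
resampling of alignment columns; partitions reproduced in fewer than the
retention fraction of replicates are collapsed to polytomies.  Support at
exactly the retention floor is kept (collapse applies to "less than").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .alignment import MultipleAlignment

#: distance assigned when the correction saturates (p too large to invert)
_SATURATED = 10.0


@dataclass
class PhyloParams:
    min_site_coverage: float = 0.95
    bootstrap_replicates: int = 100
    collapse_below: float = 0.30
    distance_model: str = "jtt_corrected"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_site_coverage <= 1.0:
            raise ValueError("min_site_coverage must be in (0, 1]")
        if not 0.0 <= self.collapse_below <= 1.0:
            raise ValueError("collapse_below must be in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.distance_model not in {"p_distance", "jtt_corrected"}:
            raise ValueError(f"unknown distance model {self.distance_model!r}")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary root (trifurcating for NJ
    output); internal-edge ``support`` is a percentage when the tree is a
    bootstrap consensus."""

    root: TreeNode

    def __post_init__(self) -> None:
        self._set_parents(self.root)
        names = [l.name for l in self.root.leaves()]
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")

    def _set_parents(self, node: TreeNode) -> None:
        for c in node.children:
            c.parent = node
            self._set_parents(c)

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(name)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each encoded as the side not containing the
        lexicographically smallest leaf."""
        all_names = self.leaf_names()
        ref = min(all_names)
        out: set[frozenset[str]] = set()
        def walk(node: TreeNode) -> None:
            for c in node.children:
                clade = c.leaf_names()
                side = all_names - clade if ref in clade else clade
                if 2 <= len(side) <= len(all_names) - 2:
                    out.add(side)
                walk(c)
        walk(self.root)
        return out

    def newick(self, lengths: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                s = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                s = f"({inner}){label}"
            if lengths and node.parent is not None:
                s += f":{node.length:.6g}"
            return s
        return fmt(self.root) + ";"


# ---------------------------------------------------------------------------
# column masking and distances
# ---------------------------------------------------------------------------

def mask_columns(
    msa: MultipleAlignment, min_site_coverage: float = 0.95
) -> MultipleAlignment:
    """Drop columns whose non-gap fraction is strictly below the threshold."""
    n = len(msa.rows)
    keep = [
        j
        for j in range(msa.length)
        if sum(1 for c in msa.column(j) if c != "-") / n >= min_site_coverage
    ]
    if not keep:
        raise ValueError("masking removed every column; alignment unusable")
    rows = [
        (rid, "".join(seq[j] for j in keep)) for rid, seq in msa.rows
    ]
    return MultipleAlignment(rows=rows)


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), -1
    )


def jtt_correct(p: float) -> float:
    """Kimura-style correction calibrated to the JTT substitution curve."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0:
        return _SATURATED
    return min(-math.log(arg), _SATURATED)


def distance_matrix(
    msa: MultipleAlignment, model: str = "jtt_corrected"
) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise distances over mutually ungapped columns."""
    if len(msa.rows) < 2:
        raise ValueError("need at least 2 rows")
    labels = msa.ids
    enc = _encode([seq for _, seq in msa.rows])
    valid = enc != ord("-")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        compared = both.sum(axis=1)
        mismatch = ((enc[i] != enc[i + 1 :]) & both).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            if compared[k] == 0:
                raise ValueError(
                    f"no mutually ungapped columns for pair "
                    f"({labels[i]!r}, {labels[j]!r})"
                )
            p = mismatch[k] / compared[k]
            d = jtt_correct(p) if model == "jtt_corrected" else p
            D[i, j] = D[j, i] = d
    return labels, D


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(labels: list[str], D: np.ndarray) -> Tree:
    """Saitou–Nei neighbor joining.

    Negative branch lengths are clamped to zero with the deficit moved onto
    the sibling edge, preserving the joined pair's path length.  Ties in the
    Q criterion break on the lexicographically smallest joined label pair, so
    the topology is independent of input row order.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    D = D.astype(float).copy()
    nodes = [TreeNode(name=lab) for lab in labels]
    keys = [(lab,) for lab in labels]  # sorted label tuples for tie-breaks
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = [
            (tuple(sorted((keys[i][0], keys[j][0]))), i, j)
            for i, j in np.argwhere(Q <= qmin + 1e-12)
            if i < j
        ]
        _, i, j = min(ties)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length, nodes[j].length = li, lj
        parent.children = [nodes[i], nodes[j]]
        dnew = 0.5 * (D[:, i] + D[:, j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        new_key = (min(keys[i][0], keys[j][0]),)
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]
    # final trifurcation: closed-form edge lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = TreeNode()
    for node, ln in zip(nodes, (l0, l1, l2)):
        node.length = max(ln, 0.0)
        root.children.append(node)
    return Tree(root=root)


# ---------------------------------------------------------------------------
# bootstrap consensus
# ---------------------------------------------------------------------------

def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return a.isdisjoint(b) or a <= b or b <= a


def _tree_from_clades(
    all_names: frozenset[str], clades: dict[frozenset[str], float]
) -> Tree:
    """Build a rooted clade tree (root = all leaves) from nested clade sets."""
    nodes: dict[frozenset[str], TreeNode] = {
        all_names: TreeNode()
    }
    for clade, support in sorted(
        clades.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
    ):
        nodes[clade] = TreeNode(support=support)
    leaf_sets = {frozenset([n]): TreeNode(name=n) for n in all_names}
    nodes.update(leaf_sets)
    ordered = sorted(nodes, key=len)
    for cl in ordered:
        if cl == all_names:
            continue
        parent = min(
            (other for other in nodes if len(other) > len(cl) and cl < other),
            key=len,
        )
        nodes[parent].children.append(nodes[cl])
    for node in nodes.values():
        node.children.sort(key=lambda c: sorted(c.leaf_names())[0])
    return Tree(root=nodes[all_names])


def bootstrap_consensus(
    msa: MultipleAlignment, params: PhyloParams | None = None
) -> Tree:
    """Majority-style bootstrap consensus of NJ trees on resampled columns.

    Splits supported by at least ``collapse_below`` of usable replicates are
    retained (added greedily by descending support, keeping compatibility);
    everything else is collapsed to polytomies.  Supports are percentages.
    """
    params = params or PhyloParams()
    rng = np.random.default_rng(params.seed)
    ncols = msa.length
    all_names = msa.leaf_names() if hasattr(msa, "leaf_names") else frozenset(msa.ids)
    ref = min(all_names)
    counts: dict[frozenset[str], int] = {}
    used = 0
    for _ in range(params.bootstrap_replicates):
        idx = rng.integers(0, ncols, size=ncols)
        rows = [(rid, "".join(seq[j] for j in idx)) for rid, seq in msa.rows]
        rep = MultipleAlignment(rows=rows)
        try:
            labels, D = distance_matrix(rep, params.distance_model)
            tree = nj_tree(labels, D)
        except ValueError as exc:
            warnings.warn(f"bootstrap replicate skipped: {exc}")
            continue
        used += 1
        for side in tree.bipartitions():
            counts[side] = counts.get(side, 0) + 1
    if used == 0:
        raise ValueError("every bootstrap replicate was degenerate")
    threshold = params.collapse_below * used
    kept: dict[frozenset[str], float] = {}
    candidates = sorted(
        (
            (clade, cnt)
            for clade, cnt in counts.items()
            if cnt >= threshold - 1e-9
        ),
        key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0])),
    )
    for clade, cnt in candidates:
        if all(_compatible(clade, other) for other in kept):
            kept[clade] = 100.0 * cnt / used
    return _tree_from_clades(frozenset(all_names), kept)


# ---------------------------------------------------------------------------
# subfamily assignment
# ---------------------------------------------------------------------------

@dataclass
class SubfamilyAssignment:
    labels: dict[str, str]
    unassigned: list[str]

    def label(self, protein_id: str) -> str:
        return self.labels.get(protein_id, "unassigned")


def assign_subfamilies(tree: Tree, anchors: dict[str, str]) -> SubfamilyAssignment:
    """Label each unlabeled leaf by the anchors of its smallest enclosing
    retained group.

    Groups are the sides of the tree's retained (post-collapse) unrooted
    splits, so a subfamily that happens to contain the rooting leaf still
    forms a usable group.  For each leaf, the smallest side containing it
    that holds any anchor decides: a single anchor label is inherited; mixed
    labels leave the leaf unassigned, and a fully collapsed star assigns
    nothing.
    """
    all_names = tree.leaf_names()
    for anchor in anchors:
        if anchor not in all_names:
            raise ValueError(f"anchor {anchor!r} missing from tree")
    # retained clades viewed as unrooted splits: both sides are candidates,
    # so a subfamily that happens to contain the rooting leaf still forms a
    # usable side
    sides: set[frozenset[str]] = set()
    def walk(node: TreeNode) -> None:
        for c in node.children:
            clade = c.leaf_names()
            if 2 <= len(clade) <= len(all_names) - 1:
                sides.add(clade)
                complement = all_names - clade
                if len(complement) >= 2:
                    sides.add(frozenset(complement))
            walk(c)
    walk(tree.root)
    labels: dict[str, str] = dict(anchors)
    unassigned: list[str] = []
    for leaf in tree.leaves():
        if leaf.name in anchors:
            continue
        containing = sorted(
            (s for s in sides if leaf.name in s and len(s) < len(all_names)),
            key=lambda s: (len(s), sorted(s)),
        )
        assigned = None
        for side in containing:
            side_labels = {anchors[n] for n in side if n in anchors}
            if side_labels:
                if len(side_labels) == 1:
                    assigned = side_labels.pop()
                break
        if assigned is None:
            unassigned.append(leaf.name)
        else:
            labels[leaf.name] = assigned
    return SubfamilyAssignment(labels=labels, unassigned=sorted(unassigned))


def write_phylip(labels: list[str], D: np.ndarray, path) -> None:
    """Square PHYLIP distance matrix."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{len(labels)}\n")
        for lab, row in zip(labels, D):
            fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")
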