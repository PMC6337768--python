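"""RT-domain phylogeny: redundancy removal, distances, neighbor joining.

The classification narrative is backed by a tree of representative
reverse-transcriptase peptides: redundant sequences are removed by
greedy identity clustering, pairwise p-distances are computed from
global alignments, and an unrooted tree is built by neighbor joining
with deterministic tie-breaking (smallest leaf index) and negative
branch lengths clamped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import global_prot_identity


def dedup_representatives(peptides: list[tuple[str, str]],
                          identity_threshold: float = 0.90) -> list[tuple[str, str]]:
    """Greedy redundancy removal on (id, peptide) pairs.

    Sequences are visited by decreasing length (ties by id); each joins
    the first existing representative at >= threshold identity, else
    founds a new one.  Representatives are returned in founding order.
    """
    ordered = sorted(peptides, key=lambda p: (-len(p[1]), p[0]))
    reps: list[tuple[str, str]] = []
    for name, pep in ordered:
        for _, rep in reps:
            if global_prot_identity(pep, rep) >= identity_threshold:
                break
        else:
            reps.append((name, pep))
    return reps


def rt_distance_matrix(representatives: list[tuple[str, str]]) -> np.ndarray:
    """Symmetric matrix of pairwise global-alignment p-distances.

    p-distance = mismatched columns / aligned columns, gap columns
    excluded; the diagonal is zero.
    """
    n = len(representatives)
    if n < 3:
        raise ValueError("need at least 3 representatives")
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - global_prot_identity(representatives[i][1], representatives[j][1])
            dist[i, j] = dist[j, i] = d
    return dist


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._newick()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    root: TreeNode
    labels: list[str]

    @property
    def newick(self) -> str:
        return self.root.newick()

    def splits(self) -> list[frozenset[str]]:
        """Leaf sets of every edge (one side of each bipartition)."""
        out: list[frozenset[str]] = []

        def walk(node: TreeNode):
            for child, _ in node.children:
                out.append(frozenset(child.leaves()))
                walk(child)

        walk(self.root)
        return out

    def is_monophyletic(self, group: set[str]) -> bool:
        """True if some edge separates ``group`` from all other leaves."""
        all_leaves = set(self.root.leaves())
        group = set(group)
        if not group <= all_leaves:
            raise ValueError("group contains unknown leaves")
        if len(group) <= 1 or group == all_leaves:
            return True
        complement = frozenset(all_leaves - group)
        target = frozenset(group)
        return any(s in (target, complement) for s in self.splits())


def build_nj_tree(matrix: np.ndarray, labels: list[str]) -> PhyloTree:
    """Standard neighbor joining with deterministic tie-breaks.

    The Q-criterion minimum is chosen; ties go to the smallest pair of
    current node indices.  Negative branch lengths are clamped to 0.
    The final three nodes are joined at a trifurcating root with the
    three-point formula, giving the usual unrooted representation.
    """
    d = np.asarray(matrix, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distances")
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("matrix/label size mismatch")
    nodes: list[TreeNode] = [TreeNode(name=str(l)) for l in labels]
    d = d.copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_row = np.array([
            max(0.0, 0.5 * (d[i, k] + d[j, k] - d[i, j]))
            for k in range(m) if k not in (i, j)
        ])
        keep = [k for k in range(m) if k not in (i, j)]
        d = d[np.ix_(keep, keep)]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes = [nodes[k] for k in keep] + [parent]

    if len(nodes) == 3:
        la = max(0.0, 0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
        lb = max(0.0, 0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
        lc = max(0.0, 0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
        root = TreeNode(children=[(nodes[0], la), (nodes[1], lb), (nodes[2], lc)])
    elif len(nodes) == 2:
        root = TreeNode(children=[(nodes[0], d[0, 1] / 2), (nodes[1], d[0, 1] / 2)])
    else:
        root = nodes[0]
    return PhyloTree(root=root, labels=[str(l) for l in labels])
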