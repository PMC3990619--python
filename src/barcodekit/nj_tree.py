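"""Neighbour-joining trees and deep-divergence case reports.

Implements the Saitou–Nei agglomeration: repeatedly join the pair (i, j)
minimising Q(i, j) = (n-2) d(i,j) - R(i) - R(j), attach the pair to a new
node with the rate-corrected branch lengths, and reduce the matrix.
Negative branch lengths are clamped to zero with the difference moved to
the sister branch, and Q-ties break deterministically to the
lexicographically smallest id pair so trees are reproducible.

Species whose maximum intraspecific divergence exceeds a threshold
(default 2%) are flagged as potential cryptic complexes; their subtrees
are partitioned into within-species clades annotated with localities and
a divergence-time estimate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, SpeciesSummary, divergence_time
from .io_qc import SpecimenMetadata


@dataclass
class TreeNode:
    name: Optional[str] = None  # leaf seq_id; None for internal nodes
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [lf.name for lf in self.leaves()]


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary internal root of degree 3."""

    root: TreeNode

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self, labels: Optional[dict[str, str]] = None) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                name = labels.get(node.name, node.name) if labels else node.name
                return _quote(name)
            inner = ",".join(f"{rec(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return rec(self.root) + ";"

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distance matrix."""
        leaves = self.root.leaves()
        names = [lf.name for lf in leaves]
        index = {id(lf): i for i, lf in enumerate(leaves)}
        n = len(leaves)
        d = np.zeros((n, n))

        def below(node: TreeNode) -> dict[int, float]:
            """Map leaf-index -> distance from node, filling d for pairs meeting at node."""
            if node.is_leaf:
                return {index[id(node)]: 0.0}
            groups = []
            for child, bl in node.children:
                sub = below(child)
                groups.append({k: v + bl for k, v in sub.items()})
            for ga, gb in itertools.combinations(groups, 2):
                for i, di in ga.items():
                    for j, dj in gb.items():
                        d[i, j] = d[j, i] = di + dj
            merged: dict[int, float] = {}
            for g in groups:
                merged.update(g)
            return merged

        below(self.root)
        return names, d


def _quote(name: str) -> str:
    if any(c in name for c in " ()[]:;,'"):
        return "'" + name.replace("'", "''") + "'"
    return name


class MaskedCellsError(ValueError):
    """Raised in strict mode when the input matrix has undefined cells."""


def _drop_for_complete(m: DistanceMatrix) -> DistanceMatrix:
    """Greedily drop the taxa with the most masked cells until complete."""
    keep = list(range(m.n))
    defined = m.defined.copy()
    while True:
        sub = defined[np.ix_(keep, keep)]
        bad = (~sub).sum(axis=1)
        if bad.sum() == 0:
            break
        worst = keep[int(np.argmax(bad))]
        keep = [k for k in keep if k != worst]
        if len(keep) < 3:
            raise MaskedCellsError("cannot obtain a complete submatrix of >=3 taxa")
    return m.submatrix([m.ids[k] for k in keep])


def neighbor_joining(m: DistanceMatrix, masked_policy: str = "drop") -> Tree:
    """Build an unrooted NJ tree from a K2P distance matrix.

    ``masked_policy`` is ``"drop"`` (remove the fewest taxa needed to get a
    complete matrix) or ``"strict"`` (raise listing offending pairs).
    """
    if not m.defined.all():
        if masked_policy == "strict":
            bad = [
                (m.ids[i], m.ids[j])
                for i in range(m.n)
                for j in range(i + 1, m.n)
                if not m.defined[i, j]
            ]
            raise MaskedCellsError(f"masked cells present: {bad[:10]}")
        m = _drop_for_complete(m)
    if m.n < 3:
        raise ValueError("neighbor_joining requires at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=s) for s in m.ids]
    # sort keys: lexicographically smallest id reachable in each cluster
    keys: list[str] = list(m.ids)
    n0 = m.n
    d = np.zeros((2 * n0 - 1, 2 * n0 - 1))
    d[:n0, :n0] = m.d
    active = list(range(len(nodes)))

    while len(active) > 2:
        n_act = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (n_act - 2) * sub - r[:, None] - r[None, :]
        iu = np.triu_indices(n_act, k=1)
        qvals = q[iu]
        hit = np.nonzero(qvals == qvals.min())[0]
        ties = [(int(iu[0][h]), int(iu[1][h])) for h in hit]
        ai, aj = min(
            ties, key=lambda t: tuple(sorted((keys[active[t[0]]], keys[active[t[1]]])))
        )
        i, j = active[ai], active[aj]
        dij = d[i, j]
        if n_act > 2:
            li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (n_act - 2))
        else:
            li = 0.5 * dij
        lj = dij - li
        # clamp negatives, moving the deficit to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        lj = max(lj, 0.0)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        keys.append(min(keys[i], keys[j]))
        k = len(nodes) - 1
        rest = np.array([a for a in active if a not in (i, j)], dtype=int)
        if rest.size:
            d[k, rest] = d[rest, k] = 0.5 * (d[i, rest] + d[j, rest] - dij)
        active = [a for a in active if a not in (i, j)] + [k]

    # join the last two clusters with a single edge; distribute it so the
    # root is the junction (degree-3 root when the last node is internal)
    i, j = active
    bl = max(d[i, j], 0.0)
    a, b = nodes[i], nodes[j]
    if not b.is_leaf:
        a, b = b, a  # make 'a' the internal node if possible
    if a.is_leaf:
        root = TreeNode(children=[(a, bl / 2), (b, bl / 2)])
    else:
        root = a
        root.children.append((b, bl))
    return Tree(root=root)


def flag_deep_divergence(
    summaries: Sequence[SpeciesSummary], threshold_pct: float = 2.0
) -> list[str]:
    """Species whose max intraspecific divergence strictly exceeds the
    threshold (singletons are not assessable and never flagged)."""
    return [
        s.species_label
        for s in summaries
        if s.max_intra is not None and s.max_intra > threshold_pct
    ]


@dataclass
class DeepDivergenceCase:
    """A potential cryptic complex: within-species lineages + localities."""

    species_label: str
    max_intra: float  # %
    lineages: list[tuple[list[str], list[str]]]  # (member seq_ids, localities)
    estimated_time_my: float


def _species_clades(
    tree: Tree, member_ids: set[str], split_depth: float = 0.0
) -> list[list[str]]:
    """Maximal clades whose leaves all belong to ``member_ids``.

    When ``split_depth`` > 0 (a branch-length proportion), a conspecific
    clade is further split at its root while the branches joining its
    child groups sum to more than the given depth, so a deep two-lineage
    species yields its two lineages even though the species itself is
    monophyletic.
    """

    clades: list[TreeNode] = []

    def walk(node: TreeNode) -> bool:
        """True if every leaf below node is a member (clade not yet emitted)."""
        if node.is_leaf:
            return node.name in member_ids
        flags = [(child, walk(child)) for child, _ in node.children]
        if all(f for _, f in flags):
            return True
        for child, f in flags:
            if f:
                clades.append(child)
        return False

    if walk(tree.root):  # whole tree conspecific
        clades.append(tree.root)

    def deep_split(node: TreeNode) -> list[TreeNode]:
        if node.is_leaf or split_depth <= 0:
            return [node]
        joining = sum(sorted((bl for _, bl in node.children), reverse=True)[:2])
        if joining > split_depth:
            out = []
            for child, _ in node.children:
                out.extend(deep_split(child))
            return out
        return [node]

    final: list[TreeNode] = []
    for clade in clades:
        final.extend(deep_split(clade))
    return [c.leaf_names() for c in final]


def subtree_report(
    tree: Tree,
    species_label: str,
    meta: Sequence[SpecimenMetadata],
    rate_pct_per_my: float = 2.0,
    max_intra_pct: Optional[float] = None,
    split_threshold_pct: float = 2.0,
) -> DeepDivergenceCase:
    """Partition a species' leaves into within-species clades.

    Each lineage lists its member sequences and their (unique, sorted)
    localities; the case carries a divergence-time estimate from the
    species' maximum intraspecific divergence. ``split_threshold_pct``
    controls when a monophyletic species is split into deep lineages.
    """
    by_id = {mm.seq_id: mm for mm in meta}
    member_ids = {mm.seq_id for mm in meta if mm.species_label == species_label}
    present = member_ids & set(tree.leaf_names())
    if not present:
        raise ValueError(f"species {species_label!r} absent from tree")
    if len(present) < 2:
        raise ValueError(f"species {species_label!r} has <2 members in the tree")
    clades = _species_clades(tree, present, split_depth=split_threshold_pct / 100.0)
    lineages = []
    for members in sorted(clades, key=lambda c: (-len(c), c)):
        locs = sorted({by_id[s].locality for s in members if by_id[s].locality})
        lineages.append((sorted(members), locs))
    if max_intra_pct is None:
        max_intra_pct = 0.0
    return DeepDivergenceCase(
        species_label=species_label,
        max_intra=max_intra_pct,
        lineages=lineages,
        estimated_time_my=divergence_time(max_intra_pct, rate_pct_per_my),
    )
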