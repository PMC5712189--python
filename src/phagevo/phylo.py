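"""Tree building and Dollo polarization of gap blocks.

A neighbor-joining tree is built from Jukes-Cantor distances over the gap-free
alignment columns, rooted with an explicit outgroup, and each gap block's
presence/absence pattern is polarized under Dollo parsimony: the character
(the sequence) is gained at most once, and may be lost any number of times.
With that constraint the minimum-loss reconstruction places the single gain at
the most recent common ancestor of the genomes carrying the sequence; the
block is a deletion (ancestral presence) when that ancestor is the root, and
an insertion on the gain clade's stem branch otherwise.

Branch ids are stable strings derived from the sorted set of leaves below the
branch, so reports are reproducible across runs and topologically equal trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import dendropy
import numpy as np
import pandas as pd

from .align import CollinearAlignment
from .variants import GapBlock

logger = logging.getLogger(__name__)


class PhyloError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0,
                 children: Optional[list["Node"]] = None):
        self.name = name
        self.length = length
        self.children: list[Node] = children or []
        for c in self.children:
            c.parent = self
        self.parent: Optional[Node] = None

    def add(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted (binary or multifurcating) tree with named leaves."""

    def __init__(self, root: Node):
        self.root = root
        names = [n.name for n in self.leaves()]
        if len(set(names)) != len(names):
            raise PhyloError("duplicate leaf names")
        if any(n is None for n in names):
            raise PhyloError("unnamed leaf")

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterable[Node]:
        stack, out = [self.root], []
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def leafset(self, node: Node) -> frozenset[str]:
        return frozenset(n.name for n in self._subtree_leaves(node))

    @staticmethod
    def _subtree_leaves(node: Node) -> list[Node]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(n.children)
        return out

    def branch_id(self, node: Node) -> str:
        return ",".join(sorted(self.leafset(node)))

    def branches(self) -> list[str]:
        """Branch ids of every non-root node (the branch above it)."""
        return [self.branch_id(n) for n in self.postorder() if n is not self.root]

    def mrca(self, names: Iterable[str]) -> Node:
        want = frozenset(names)
        if not want:
            raise PhyloError("empty leaf set")
        best: Optional[Node] = None
        for n in self.postorder():
            if want <= self.leafset(n):
                best = n
                break  # postorder: first superset is the smallest
        if best is None:
            raise PhyloError(f"leaves {sorted(want)} not all in tree")
        return best

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                body = n.name
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")"
            if n is self.root:
                return body
            return f"{body}:{n.length:g}"
        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True)

        def conv(dn) -> Node:
            node = Node(name=dn.taxon.label if dn.taxon else None,
                        length=float(dn.edge.length or 0.0))
            for c in dn.child_nodes():
                node.add(conv(c))
            return node

        return cls(conv(dt.seed_node))

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


# ---------------------------------------------------------------------------
# distances and NJ


def jc_distance_matrix(aln: CollinearAlignment) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Jukes-Cantor distances over gap-free columns (N excluded pairwise).

    Returns ``(jc, p)``: corrected distances and raw p-distances.  JC is
    undefined at p >= 0.75 and raises.
    """
    mat = aln.matrix
    gap_free = (mat != ord("-")).all(axis=0)
    sub = mat[:, gap_free]
    informative = sub != ord("N")
    n = len(aln.ids)
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = informative[i] & informative[j]
            total = int(both.sum())
            if total == 0:
                raise PhyloError(f"no comparable columns between {aln.ids[i]} "
                                 f"and {aln.ids[j]}")
            p[i, j] = p[j, i] = ((sub[i] != sub[j]) & both).sum() / total
    if (p >= 0.75).any():
        raise PhyloError("p-distance >= 0.75: Jukes-Cantor correction undefined")
    jc = -0.75 * np.log1p(-4.0 * p / 3.0)
    np.fill_diagonal(jc, 0.0)
    return (pd.DataFrame(jc, index=aln.ids, columns=aln.ids),
            pd.DataFrame(p, index=aln.ids, columns=aln.ids))


def neighbor_joining(dist: pd.DataFrame) -> Tree:
    """Standard neighbor joining.

    Returns an unrooted tree represented with a trifurcating root.  Negative
    branch lengths are clamped to zero and the deficit logged.  Ties in the
    Q matrix are broken toward the lexicographically smallest index pair for
    determinism.
    """
    taxa = list(dist.index)
    if len(taxa) < 3:
        raise PhyloError("neighbor joining needs at least 3 taxa")
    D = dist.to_numpy(dtype=float).copy()
    if not np.allclose(D, D.T):
        raise PhyloError("distance matrix not symmetric")
    if (D < 0).any():
        raise PhyloError("negative distances")
    nodes: list[Node] = [Node(name=t) for t in taxa]

    def clamp(x: float, what: str) -> float:
        if x < 0:
            logger.info("NJ: clamping negative branch length %.6g on %s", x, what)
            return 0.0
        return x

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # row-major: first min
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        a, b = nodes[i], nodes[j]
        a.length = clamp(li, a.name or "internal")
        b.length = clamp(lj, b.name or "internal")
        u = Node(children=[a, b])
        duk = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        newD = np.zeros((n - 1, n - 1))
        newD[: n - 2, : n - 2] = D[np.ix_(keep, keep)]
        newD[n - 2, : n - 2] = newD[: n - 2, n - 2] = duk[keep]
        D = newD
        nodes = [nodes[x] for x in keep] + [u]
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = clamp((dab + dac - dbc) / 2.0, a.name or "internal")
    b.length = clamp((dab + dbc - dac) / 2.0, b.name or "internal")
    c.length = clamp((dac + dbc - dab) / 2.0, c.name or "internal")
    return Tree(Node(children=[a, b, c]))


def root_by_outgroup(tree: Tree, outgroup_leaves: Union[str, Sequence[str]]) -> Tree:
    """Root on the branch separating the outgroup from the ingroup, at its
    midpoint.  The outgroup must be a single leaf or form a clade in the
    unrooted tree."""
    if isinstance(outgroup_leaves, str):
        outgroup_leaves = [outgroup_leaves]
    og = frozenset(outgroup_leaves)
    leaves = frozenset(tree.leaf_names())
    if not og or not og <= leaves:
        raise PhyloError(f"outgroup {sorted(og)} not a subset of the leaves")
    if og == leaves:
        raise PhyloError("outgroup cannot be the entire leaf set")
    target: Optional[Node] = None
    for n in tree.postorder():
        if n is tree.root:
            continue
        ls = tree.leafset(n)
        if ls == og or ls == leaves - og:
            target = n
            break
    if target is None:
        raise PhyloError(
            f"outgroup {sorted(og)} is not monophyletic in the unrooted tree")

    # reroot at the midpoint of the edge above `target`
    parent = target.parent
    half = (target.length or 0.0) / 2.0

    def rebuild(node: Node, came_from: Optional[Node], length: float) -> Node:
        nbrs: list[tuple[Node, float]] = []
        for c in node.children:
            if c is not came_from:
                nbrs.append((c, c.length))
        if node.parent is not None and node.parent is not came_from:
            nbrs.append((node.parent, node.length))
        new = Node(name=node.name if node.is_leaf else None, length=length)
        for nbr, l in nbrs:
            new.add(rebuild(nbr, node, l))
        return new

    side_a = rebuild(target, parent, half)
    side_b = rebuild(parent, target, half)

    def suppress_unary(n: Node) -> Node:
        while len(n.children) == 1 and not n.is_leaf:
            child = n.children[0]
            child.length += n.length
            child.parent = n.parent
            n = child
        n.children = [suppress_unary(c) for c in n.children]
        for c in n.children:
            c.parent = n
        return n

    root = Node(children=[suppress_unary(side_a), suppress_unary(side_b)])
    rooted = Tree(root)
    # put the outgroup side second, mirroring the convention of listing the
    # outgroup last
    if rooted.leafset(root.children[0]) == og:
        root.children.reverse()
    return rooted


# ---------------------------------------------------------------------------
# Dollo polarization


@dataclass
class EventCall:
    block_id: Optional[int]
    event_type: str                    # "insertion" | "deletion" | "ancestral-no-event"
    gain_branch: Optional[str] = None  # branch id of the gain (insertions)
    loss_branches: list[str] = field(default_factory=list)
    present_leaves: frozenset[str] = frozenset()


def dollo_polarize(tree: Tree, block: Union[GapBlock, dict[str, bool]]) -> EventCall:
    """Polarize a presence/absence pattern under Dollo parsimony (<=1 gain,
    minimum losses) on a rooted tree.

    Present in every leaf -> ancestral, no event.  Otherwise the gain sits at
    the MRCA of the present leaves: at the root this is ancestral presence and
    the pattern is one or more deletions (one loss per maximal absent subtree);
    below the root it is an insertion on the MRCA's stem branch, with losses
    for any absent subtrees inside the gain clade.
    """
    if isinstance(block, GapBlock):
        presence = block.presence
        block_id = block.block_id
    else:
        presence = block
        block_id = None
    leaves = set(tree.leaf_names())
    if set(presence) != leaves:
        raise PhyloError("presence vector does not cover the tree's leaves")
    present = frozenset(g for g, p in presence.items() if p)
    if not present:
        raise PhyloError("presence vector is empty: nothing to polarize")
    if present == leaves:
        return EventCall(block_id, "ancestral-no-event", present_leaves=present)
    gain = tree.mrca(present)
    # inside the gain clade, a node is "on" when it has a present descendant;
    # each edge on -> off is one loss
    losses: list[str] = []
    def walk(n: Node) -> bool:
        if n.is_leaf:
            return n.name in present
        child_states = [(c, walk(c)) for c in n.children]
        on = any(s for _, s in child_states)
        if on:
            for c, s in child_states:
                if not s:
                    losses.append(tree.branch_id(c))
        return on
    walk(gain)
    losses.sort()
    if gain is tree.root:
        return EventCall(block_id, "deletion", gain_branch=None,
                         loss_branches=losses, present_leaves=present)
    return EventCall(block_id, "insertion", gain_branch=tree.branch_id(gain),
                     loss_branches=losses, present_leaves=present)


def summarize_branch_events(tree: Tree, calls: Sequence[EventCall]) -> pd.DataFrame:
    """Per-branch insertion/deletion tallies over all branches of the tree.

    An insertion counts on its gain branch; every loss branch of a deletion
    call counts one deletion, as do losses inside an insertion clade (a
    secondary deletion of inserted sequence).
    """
    branches = tree.branches()
    ins = {b: 0 for b in branches}
    dels = {b: 0 for b in branches}
    for call in calls:
        if call.event_type == "ancestral-no-event":
            continue
        if call.event_type == "insertion":
            ins[call.gain_branch] += 1
        for b in call.loss_branches:
            dels[b] += 1
    df = pd.DataFrame({
        "branch": branches,
        "insertions": [ins[b] for b in branches],
        "deletions": [dels[b] for b in branches],
    })
    return df.set_index("branch")


def write_event_table(calls: Sequence[EventCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("# block_id\ttype\tgain_branch\tloss_branches\tpresent_in\n")
        for c in calls:
            fh.write(f"{c.block_id if c.block_id is not None else '.'}\t"
                     f"{c.event_type}\t{c.gain_branch or '.'}\t"
                     f"{';'.join(c.loss_branches) or '.'}\t"
                     f"{','.join(sorted(c.present_leaves))}\n")
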