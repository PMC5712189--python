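"""Independent brute-force oracle for Dollo polarization.

Enumerates every internal ancestral-state assignment (present/absent), keeps
those with at most one gain (an edge 0->1, or presence at the root), and takes
the assignment with the fewest losses (edges 1->0), preferring ancestral
presence on ties.  Completely independent of the production reconstruction,
which never enumerates.
"""

from itertools import product

import numpy as np

from phagevo.phylo import Node, Tree


def all_rooted_binary_trees(leaves: list[str]):
    """Every rooted binary topology on the labeled leaves, as nested tuples."""
    def insert(tree, leaf):
        yield (leaf, tree)
        if isinstance(tree, tuple):
            l, r = tree
            for t in insert(l, leaf):
                yield (t, r)
            for t in insert(r, leaf):
                yield (l, t)

    trees = [leaves[0]]
    for leaf in leaves[1:]:
        trees = [t for base in trees for t in insert(base, leaf)]
    return trees


def tuple_to_tree(t) -> Tree:
    def conv(x) -> Node:
        if isinstance(x, str):
            return Node(name=x, length=1.0)
        n = Node(length=1.0)
        for c in x:
            n.add(conv(c))
        return n
    return Tree(conv(t))


def collapse_random_edges(tup, rng):
    """Random multifurcating variant of a binary tuple-tree (as a Tree)."""
    t = tuple_to_tree(tup)
    internal = [n for n in t.postorder()
                if not n.is_leaf and n.parent is not None]
    for n in internal:
        if rng.random() < 0.4:
            p = n.parent
            p.children = [c for c in p.children if c is not n] + n.children
            for c in n.children:
                c.parent = p
    return Tree(t.root)


def oracle_all_vectors(tree: Tree):
    """Exhaustive oracle, vectorized over all assignments x presence vectors.

    Returns {presence_mask: (event_type, gain_branch, loss_branch_tuple)}
    where the mask's bit i corresponds to sorted leaf name i.
    """
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    leaf_names = sorted(n.name for n in nodes if n.is_leaf)
    leaf_pos = {n.name: idx[id(n)] for n in nodes if n.is_leaf}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf]
    edges = [(idx[id(n.parent)], idx[id(n)]) for n in nodes
             if n.parent is not None]
    child_branch = [tree.branch_id(n) for n in nodes if n.parent is not None]
    root_i = idx[id(tree.root)]

    k, m, nn = len(internal), len(leaf_names), len(nodes)
    na = 2 ** k
    nv = 2 ** m - 1
    A = (np.arange(na)[:, None] >> np.arange(k)) & 1          # (na, k)
    V = ((np.arange(1, nv + 1)[:, None] >> np.arange(m)) & 1)  # (nv, m)
    S = np.zeros((na, nv, nn), dtype=np.int8)
    for j, i in enumerate(internal):
        S[:, :, i] = A[:, None, j]
    for j, name in enumerate(leaf_names):
        S[:, :, leaf_pos[name]] = V[None, :, j]

    gains = S[:, :, root_i].astype(np.int32)
    losses = np.zeros((na, nv), dtype=np.int32)
    loss_flags = np.zeros((na, nv, len(edges)), dtype=bool)
    for e, (p, c) in enumerate(edges):
        up = (S[:, :, p] == 0) & (S[:, :, c] == 1)
        dn = (S[:, :, p] == 1) & (S[:, :, c] == 0)
        gains += up
        losses += dn
        loss_flags[:, :, e] = dn
    cost = np.where(gains <= 1, losses * 2 + (1 - S[:, :, root_i]),
                    np.iinfo(np.int32).max)
    best = np.argmin(cost, axis=0)                            # (nv,)

    out = {}
    for v in range(nv):
        a = best[v]
        root_state = S[a, v, root_i]
        loss_b = tuple(sorted(child_branch[e]
                              for e in np.nonzero(loss_flags[a, v])[0]))
        mask = v + 1
        if all((mask >> i) & 1 for i in range(m)):
            out[mask] = ("ancestral-no-event", None, ())
        elif root_state == 1:
            out[mask] = ("deletion", None, loss_b)
        else:
            gain_edges = [e for e, (p, c) in enumerate(edges)
                          if S[a, v, p] == 0 and S[a, v, c] == 1]
            assert len(gain_edges) == 1
            out[mask] = ("insertion", child_branch[gain_edges[0]], loss_b)
    return leaf_names, out


def oracle_polarize(tree: Tree, presence: dict[str, bool]):
    """(event_type, gain_branch, sorted loss branches) by exhaustive search."""
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf]
    leaf_state = {i: presence[n.name] for i, n in enumerate(nodes) if n.is_leaf}
    edges = [(idx[id(n.parent)], idx[id(n)]) for n in nodes if n.parent is not None]
    root_i = idx[id(tree.root)]

    if all(presence.values()):
        pass  # oracle still runs; caller compares against ancestral-no-event

    best = None  # (losses, prefer_root_absent, states)
    for bits in product((0, 1), repeat=len(internal)):
        states = np.zeros(len(nodes), dtype=int)
        for i, s in leaf_state.items():
            states[i] = int(s)
        for i, b in zip(internal, bits):
            states[i] = b
        gains = states[root_i] + sum(
            1 for p, c in edges if states[p] == 0 and states[c] == 1)
        if gains > 1:
            continue
        losses = sum(1 for p, c in edges if states[p] == 1 and states[c] == 0)
        key = (losses, 1 - states[root_i])  # fewest losses, then prefer root=1
        if best is None or key < best[0]:
            best = (key, states)
    assert best is not None
    states = best[1]
    loss_branches = sorted(
        tree.branch_id(nodes[c]) for p, c in edges
        if states[p] == 1 and states[c] == 0)
    if all(presence.values()):
        return ("ancestral-no-event", None, [])
    if states[root_i] == 1:
        return ("deletion", None, loss_branches)
    gain_edges = [c for p, c in edges if states[p] == 0 and states[c] == 1]
    assert len(gain_edges) == 1
    return ("insertion", tree.branch_id(nodes[gain_edges[0]]), loss_branches)
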