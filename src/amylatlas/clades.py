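"""Tree rooting, clade extraction and consensus-based representatives.

The amylase phylogeny is rooted at the midpoint of its longest
leaf-to-leaf path, partitioned into k clades (default 3: pullulanases,
alpha-1,4-amylases and cyclomaltodextrin-like amylases) and each clade is
summarized by the member most similar to the clade consensus sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from amylatlas.io import Alignment


@dataclass
class CladePartition:
    """Assignment of every leaf to one of k clades (1-based indices)."""

    k: int
    assignments: dict[str, int]

    def members(self, clade: int) -> list[str]:
        return [leaf for leaf, c in self.assignments.items() if c == clade]


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------


def _leaf_distances(tree: dendropy.Tree) -> tuple[list, dict]:
    """Distance from every node to its farthest descendant-or-other leaf.

    Returns leaves list and a dict node -> {leaf: distance} computed by a
    simple pairwise Dijkstra over the (small) tree graph; adequate for the
    tree sizes this pipeline handles.
    """
    # build adjacency over nodes
    adj: dict[dendropy.Node, list[tuple[dendropy.Node, float]]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            if child.edge.length is None:
                raise ValueError("midpoint rooting requires branch lengths on every edge")
            adj.setdefault(node, []).append((child, child.edge.length))
            adj.setdefault(child, []).append((node, child.edge.length))
    leaves = [lf for lf in tree.leaf_node_iter()]
    return leaves, adj


def _farthest_from(start, adj) -> dict:
    """Single-source distances over the tree (BFS; unique paths)."""
    dist = {start: 0.0}
    stack = [start]
    while stack:
        node = stack.pop()
        for nbr, w in adj.get(node, []):
            if nbr not in dist:
                dist[nbr] = dist[node] + w
                stack.append(nbr)
    return dist


def tree_diameter_path(tree: dendropy.Tree) -> tuple[float, dendropy.Node, dendropy.Node]:
    """Length and endpoint leaves of the longest leaf-to-leaf path.

    Uses the double-sweep property of trees: the farthest leaf from an
    arbitrary leaf is one endpoint of a diameter.
    """
    leaves, adj = _leaf_distances(tree)
    if len(leaves) < 2:
        raise ValueError("tree must have at least two leaves")
    d0 = _farthest_from(leaves[0], adj)
    end_a = max(leaves, key=lambda lf: d0[lf])
    da = _farthest_from(end_a, adj)
    end_b = max(leaves, key=lambda lf: da[lf])
    return da[end_b], end_a, end_b


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest leaf-to-leaf path.

    Returns a new rooted tree; after rooting, the two largest root-to-leaf
    distances are equal (each is half the tree diameter).  Requires branch
    lengths on every edge and at least two leaves.
    """
    tree = tree.clone(depth=1)
    diameter, end_a, end_b = tree_diameter_path(tree)
    _, adj = _leaf_distances(tree)
    half = diameter / 2.0

    # walk from end_a toward end_b until the cumulative distance reaches half
    dist_a = _farthest_from(end_a, adj)
    # reconstruct the a->b path
    path = [end_b]
    while path[-1] is not end_a:
        node = path[-1]
        nxt = min(
            (nbr for nbr, w in adj[node] if abs(dist_a[nbr] + w - dist_a[node]) < 1e-12),
            key=lambda n: dist_a[n],
        )
        path.append(nxt)
    path.reverse()  # end_a ... end_b

    # find the edge (u, v) on the path containing the midpoint
    for u, v in zip(path, path[1:]):
        if dist_a[u] <= half <= dist_a[v] + 1e-15:
            break
    offset = half - dist_a[u]  # distance from u toward v

    # (u, v) is a parent/child pair in some orientation
    if v.parent_node is u:
        child, from_child_end = v, dist_a[v] - half  # distance from v up to midpoint
    else:
        child, from_child_end = u, offset
    edge_len = child.edge.length
    from_parent_end = edge_len - from_child_end
    tree.reroot_at_edge(
        child.edge,
        length1=from_parent_end,
        length2=from_child_end,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    # rerooting can leave the old root as a degree-2 node; collapse it
    tree.suppress_unifurcations()
    return tree


def root_to_leaf_distances(tree: dendropy.Tree) -> dict[str, float]:
    out = {}
    for lf in tree.leaf_node_iter():
        out[lf.taxon.label] = lf.distance_from_root()
    return out


# ---------------------------------------------------------------------------
# clade extraction
# ---------------------------------------------------------------------------


def _subtree_span(node, depths: dict) -> float:
    """Max depth of a leaf under ``node`` measured from ``node``."""
    return max(depths[lf] for lf in node.leaf_iter()) - depths[node]


def extract_clades(rooted_tree: dendropy.Tree, k: int) -> CladePartition:
    """Partition the leaves into k connected clades by greedy deepest splits.

    Starting from the whole tree, k-1 internal edges are cut; at each step
    the cut chosen is the one minimizing the maximum within-clade
    root-to-leaf span over the resulting partition (ties broken by edge
    preorder position, which is deterministic).  Each resulting clade is a
    connected subtree.
    """
    leaves = [lf.taxon.label for lf in rooted_tree.leaf_node_iter()]
    if not 1 <= k <= len(leaves):
        raise ValueError(f"k={k} out of range 1..{len(leaves)}")

    # node depths from root
    depths: dict = {}
    for node in rooted_tree.preorder_node_iter():
        parent = node.parent_node
        step = node.edge.length or 0.0
        depths[node] = 0.0 if parent is None else depths[parent] + step

    root = rooted_tree.seed_node
    cut_roots: list = [root]  # topmost node of each current clade

    def span_of(clade_root, cuts_below) -> float | None:
        """Max root-to-leaf span within the clade; None when the clade
        would be left without leaves (an inadmissible cut)."""
        best = None
        for lf in clade_root.leaf_iter():
            # leaf belongs to this clade only if no cut root lies strictly
            # between clade_root and the leaf
            node, blocked = lf, False
            while node is not clade_root:
                if node in cuts_below:
                    blocked = True
                    break
                node = node.parent_node
            if not blocked:
                span = depths[lf] - depths[clade_root]
                best = span if best is None else max(best, span)
        return best

    # any non-root node may head a new clade (a cut above a leaf makes a
    # singleton clade, needed when k approaches the leaf count)
    candidates = [n for n in rooted_tree.preorder_node_iter() if n.parent_node is not None]

    for _ in range(k - 1):
        best_node, best_score = None, None
        for cand in candidates:  # preorder => deterministic tie-break
            if cand in cut_roots:
                continue
            trial = cut_roots + [cand]
            spans = [span_of(cr, set(trial) - {cr}) for cr in trial]
            if any(s is None for s in spans):
                continue  # cut would empty a clade
            score = max(spans)
            if best_score is None or score < best_score - 1e-15:
                best_node, best_score = cand, score
        if best_node is None:
            raise ValueError("cannot split tree into the requested number of clades")
        cut_roots.append(best_node)

    # assign leaves to the nearest enclosing cut root
    cut_set = set(cut_roots)
    order = {node: i for i, node in enumerate(cut_roots)}
    assignments: dict[str, int] = {}
    for lf in rooted_tree.leaf_node_iter():
        node = lf
        while node not in cut_set:
            node = node.parent_node
        assignments[lf.taxon.label] = order[node] + 1
    # renumber clades 1..k in order of first appearance among leaves
    seen: dict[int, int] = {}
    for leaf in leaves:
        c = assignments[leaf]
        if c not in seen:
            seen[c] = len(seen) + 1
    return CladePartition(k=k, assignments={leaf: seen[assignments[leaf]] for leaf in leaves})


# ---------------------------------------------------------------------------
# consensus and representatives
# ---------------------------------------------------------------------------


def consensus_sequence(alignment: Alignment, member_ids, gap_policy: str = "ignore_gaps") -> str:
    """Per-column majority residue over the given alignment members.

    Gaps are excluded from the counts under ``ignore_gaps`` (default);
    under ``count_gaps`` the gap character competes like a residue.  An
    all-gap column emits '-'.  Ties go to the lexicographically smallest
    residue.
    """
    members = [alignment[m] for m in member_ids]
    if not members:
        raise ValueError("member set must be non-empty")
    out = []
    for col in range(alignment.length):
        column = [seq[col] for seq in members]
        if gap_policy == "ignore_gaps":
            column = [c for c in column if c != "-"]
        counts: dict[str, int] = {}
        for c in column:
            counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append("-")
            continue
        # highest count wins; ties go to the lexicographically smallest residue
        top = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == top))
    return "".join(out)


def identity_to(seq: str, reference: str) -> float:
    """Fraction of identical columns, ignoring columns gapped in either."""
    pairs = [(a, b) for a, b in zip(seq, reference) if a != "-" and b != "-"]
    if not pairs:
        return 0.0
    return sum(a == b for a, b in pairs) / len(pairs)


def select_representative(alignment: Alignment, member_ids) -> str:
    """The member most similar to the clade consensus.

    Similarity is the fraction of identical columns over positions where
    neither the member nor the consensus is gapped; ties are broken by
    member input order.
    """
    member_ids = list(member_ids)
    if not member_ids:
        raise ValueError("member set must be non-empty")
    consensus = consensus_sequence(alignment, member_ids)
    best_id, best_score = member_ids[0], -1.0
    for mid in member_ids:
        score = identity_to(alignment[mid], consensus)
        if score > best_score:
            best_id, best_score = mid, score
    return best_id
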