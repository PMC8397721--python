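"""Maximum-parsimony trees from binary presence/absence of somatic variants.

Each patient's tumor samples (plus the matched normal as an all-zero
outgroup) are encoded as a binary character matrix: one row per variant, one
column per sample, entry 1 when the variant was called in that sample. All
unrooted leaf-labelled topologies are enumerated (patients here contribute
2-3 tumor samples, so exhaustive search is exact and instant) and scored
with Fitch's small-parsimony algorithm; the minimum-score topology wins,
ties broken by lexicographically smallest Newick string. Branch lengths are
integer mutation counts assigned by Fitch traceback with the germline state
(all zero) forced at the normal leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAX_LEAVES = 8

Edge = frozenset


@dataclass
class PhyloTree:
    """Unrooted tree over sample leaves with per-edge mutation counts.

    ``adjacency`` maps node -> sorted neighbours; leaves are sample-name
    strings, internal nodes negative ints.
    """

    leaves: list[str]
    adjacency: dict
    score: int = 0
    edge_counts: dict = field(default_factory=dict)
    homoplastic_variants: list = field(default_factory=list)
    outgroup: str = "normal"

    def edges(self) -> list[Edge]:
        seen = set()
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                seen.add(Edge((a, b)))
        return sorted(seen, key=lambda e: str(sorted(e, key=str)))


def build_matrix(
    sample_variants: dict[str, set[str]], normal: str = "normal",
    normal_variants: set[str] | None = None,
) -> pd.DataFrame:
    """Binary character matrix (variants x samples) with an all-zero normal column.

    ``sample_variants`` maps tumor sample name -> set of variant keys.
    Variants also seen in the matched normal are non-somatic and dropped, as
    are variants absent from every tumor sample.
    """
    if len(sample_variants) < 2:
        raise ValueError("need at least 2 tumor samples")
    if normal in sample_variants:
        raise ValueError(f"'{normal}' is reserved for the outgroup column")
    germline = normal_variants or set()
    all_variants = sorted(set().union(*sample_variants.values()) - germline)
    mat = pd.DataFrame(
        {s: [int(v in vs) for v in all_variants] for s, vs in sorted(sample_variants.items())},
        index=all_variants,
        dtype=np.int8,
    )
    mat[normal] = 0
    mat = mat[mat.drop(columns=normal).sum(axis=1) > 0]
    return mat


def enumerate_topologies(leaves: list[str]):
    """Yield adjacency dicts of every unrooted binary topology over ``leaves``.

    Standard stepwise-addition enumeration: (2n-5)!! trees for n leaves.
    Internal nodes are negative ints.
    """
    leaves = sorted(leaves)
    n = len(leaves)
    if n < 3:
        adj: dict = {leaf: [other for other in leaves if other != leaf] for leaf in leaves}
        yield adj
        return

    def copy_adj(adj):
        return {k: list(v) for k, v in adj.items()}

    base = {-1: leaves[:3]}
    for leaf in leaves[:3]:
        base[leaf] = [-1]
    stack = [(base, 3, -2)]
    while stack:
        adj, k, next_internal = stack.pop()
        if k == n:
            yield adj
            continue
        leaf = leaves[k]
        edges = set()
        for a, nbrs in adj.items():
            for b in nbrs:
                edges.add(Edge((a, b)))
        for edge in sorted(edges, key=lambda e: str(sorted(e, key=str))):
            a, b = sorted(edge, key=str)
            new = copy_adj(adj)
            v = next_internal
            new[a].remove(b)
            new[b].remove(a)
            new[a].append(v)
            new[b].append(v)
            new[v] = [a, b, leaf]
            new[leaf] = [v]
            stack.append((new, k + 1, next_internal - 1))


def _postorder(adjacency: dict, root) -> list[tuple]:
    """(node, parent) pairs, children before parents, rooted at ``root``."""
    order, stack, seen = [], [(root, None)], set()
    while stack:
        node, parent = stack.pop()
        seen.add(node)
        order.append((node, parent))
        for nbr in adjacency[node]:
            if nbr not in seen:
                stack.append((nbr, node))
    return list(reversed(order))


def fitch_score(adjacency: dict, matrix: pd.DataFrame) -> int:
    """Total Fitch small-parsimony count of ``matrix`` on one topology."""
    leaves = [n for n, nbrs in adjacency.items() if isinstance(n, str)]
    if set(leaves) != set(matrix.columns):
        raise ValueError("topology leaves do not match matrix columns")
    root = sorted(leaves)[0]
    order = _postorder(adjacency, root)
    data = matrix.to_numpy(dtype=np.int8)
    col = {s: i for i, s in enumerate(matrix.columns)}
    n_var = data.shape[0]
    # state sets encoded as bitmasks: 1 -> {0}, 2 -> {1}, 3 -> {0,1}
    sets: dict = {}
    total = np.zeros(n_var, dtype=np.int64)
    for node, parent in order:
        if isinstance(node, str):
            sets[node] = np.where(data[:, col[node]] == 1, 2, 1).astype(np.int8)
        else:
            children = [n for n in adjacency[node] if n != parent]
            acc = None
            for child in children:
                cs = sets[child]
                if acc is None:
                    acc = cs.copy()
                else:
                    inter = acc & cs
                    union = acc | cs
                    empty = inter == 0
                    total += empty
                    acc = np.where(empty, union, inter).astype(np.int8)
            sets[node] = acc
    # the root leaf itself: one more change if its state is not in the root-adjacent set
    root_child = [n for n in adjacency[root]][0]
    total += (sets[root_child] & sets[root]) == 0
    return int(total.sum())


def infer_parsimony_tree(matrix: pd.DataFrame, outgroup: str = "normal") -> PhyloTree:
    """Exhaustive maximum-parsimony tree for one patient's character matrix.

    Ties among equally parsimonious topologies are broken by the
    lexicographically smallest Newick string (without branch lengths).
    """
    leaves = sorted(matrix.columns)
    if len(leaves) > MAX_LEAVES:
        raise ValueError(
            f"{len(leaves)} leaves exceeds the exhaustive-search cap of {MAX_LEAVES}; "
            "reduce the sample set or raise MAX_LEAVES deliberately"
        )
    best = None
    for adj in enumerate_topologies(leaves):
        score = fitch_score(adj, matrix) if len(leaves) >= 3 else int(matrix.to_numpy().sum())
        key = _topology_newick(adj, outgroup if outgroup in leaves else leaves[0])
        if best is None or (score, key) < (best[0], best[1]):
            best = (score, key, adj)
    score, _, adj = best
    tree = PhyloTree(leaves=leaves, adjacency=adj, score=score, outgroup=outgroup)
    assign_edge_mutations(tree, matrix)
    return tree


def assign_edge_mutations(tree: PhyloTree, matrix: pd.DataFrame) -> dict:
    """Per-edge mutation counts by Fitch traceback with germline state at the outgroup.

    Top-down pass keeps the parent state when ambiguous, so a variant shared
    by all tumor samples maps to the trunk edge below the normal. Variants
    needing more than one change (homoplasy) are counted once per change and
    flagged in ``tree.homoplastic_variants``.
    """
    adjacency = tree.adjacency
    root = tree.outgroup if tree.outgroup in tree.leaves else sorted(tree.leaves)[0]
    order = _postorder(adjacency, root)
    col = {s: i for i, s in enumerate(matrix.columns)}
    data = matrix.to_numpy(dtype=np.int8)
    n_var = data.shape[0]

    sets: dict = {}
    for node, parent in order:
        if isinstance(node, str):
            sets[node] = np.where(data[:, col[node]] == 1, 2, 1).astype(np.int8)
        else:
            children = [n for n in adjacency[node] if n != parent]
            acc = None
            for child in children:
                cs = sets[child]
                if acc is None:
                    acc = cs.copy()
                else:
                    inter = acc & cs
                    acc = np.where(inter == 0, acc | cs, inter).astype(np.int8)
            sets[node] = acc

    # top-down state assignment; root (normal leaf) is germline 0 -> mask 1
    states = {root: np.full(n_var, 1, dtype=np.int8)}
    edge_changes: dict = {}
    changes_per_variant = np.zeros(n_var, dtype=np.int64)
    for node, parent in reversed(order):
        if parent is None:
            continue
        pstate = states[parent]
        nset = sets[node]
        keep = (nset & pstate) != 0
        state = np.where(keep, pstate, np.where(nset == 3, pstate, nset)).astype(np.int8)
        # nset==3 with parent not in set cannot occur; nset is 1 or 2 when keep is False
        states[node] = state
        changed = state != pstate
        edge_changes[Edge((parent, node))] = changed
        changes_per_variant += changed

    tree.edge_counts = {e: int(ch.sum()) for e, ch in edge_changes.items()}
    tree.homoplastic_variants = list(matrix.index[changes_per_variant > 1])
    return tree.edge_counts


def _topology_newick(adjacency: dict, root) -> str:
    """Canonical Newick (no lengths) for tie-breaking, rooted at ``root``."""

    def rec(node, parent):
        children = [n for n in adjacency[node] if n != parent]
        if not children:
            return node
        parts = sorted(rec(c, node) for c in children)
        return "(" + ",".join(parts) + ")"

    inner = adjacency[root][0]
    return f"({rec(inner, root)},{root});"


def write_newick(tree: PhyloTree) -> str:
    """Newick string rooted at the outgroup, branch lengths = edge mutation counts."""
    adjacency = tree.adjacency
    root = tree.outgroup if tree.outgroup in tree.leaves else sorted(tree.leaves)[0]
    counts = tree.edge_counts

    def rec(node, parent):
        children = [n for n in adjacency[node] if n != parent]
        length = counts.get(Edge((parent, node)), 0) if parent is not None else 0
        if not children:
            return f"{node}:{length}"
        parts = sorted(rec(c, node) for c in children)
        return "(" + ",".join(parts) + f"):{length}"

    inner = adjacency[root][0]
    root_len = counts.get(Edge((root, inner)), 0)
    if isinstance(inner, str):  # degenerate two-leaf tree
        return f"({inner}:{root_len},{root}:0);"
    children = [n for n in adjacency[inner] if n != root]
    parts = sorted(rec(c, inner) for c in children)
    return "(" + "(" + ",".join(parts) + f"):{root_len}," + f"{root}:0);"


def read_newick(text: str):
    """Parse a Newick string into (leaf -> branch length, total length) via dendropy."""
    import dendropy

    t = dendropy.Tree.get(data=text, schema="newick")
    lengths = {
        leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()
    }
    total = sum(e.length or 0 for e in t.edges())
    return lengths, total


def patient_tree(
    tables: dict[str, pd.DataFrame], normal: str = "normal"
) -> tuple[PhyloTree, pd.DataFrame]:
    """Convenience: matrix + tree from per-sample mutation tables of one patient."""
    sample_variants = {}
    for sample, table in tables.items():
        keys = (
            table["chrom"].astype(str)
            + ":"
            + table["pos"].astype(str)
            + ":"
            + table["ref"].astype(str)
            + ":"
            + table["alt"].astype(str)
        )
        sample_variants[sample] = set(keys)
    matrix = build_matrix(sample_variants, normal=normal)
    return infer_parsimony_tree(matrix, outgroup=normal), matrix
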