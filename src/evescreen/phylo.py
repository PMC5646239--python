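"""Distance phylogenetics: pairwise identity, center-star MSA, neighbor
joining, midpoint rooting and column bootstrap.

Neighbor joining on p-distances is the implemented stand-in for ML tree
inference: it is exact on additive distance matrices (the module's primary
correctness oracle) and, with column-bootstrap support, reproduces the
clade-level structure questions the screen needs answered (do novel loci
group with a known genus, and do host-class clades hold up).

Trees are rooted node structures; unrooted NJ results are stored with a
trifurcating root.  Newick output carries bootstrap supports as internal
node labels and tip annotations as NHX-style comments; parsing goes through
dendropy.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import matrices
from ._align import GlobalAlignment, nw_align


# ---------------------------------------------------------------------------
# pairwise alignment and distance matrices


def global_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: int = matrices.DEFAULT_GAP_OPEN,
    gap_extend: int = matrices.DEFAULT_GAP_EXTEND,
) -> GlobalAlignment:
    """Optimal affine-gap Needleman–Wunsch alignment of two peptides.

    Percent identity is matches / aligned columns after trimming
    terminal-gap overhangs.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    if matrix is None:
        matrix = matrices.DEFAULT_MATRIX
    return nw_align(
        a, b, matrices.encode(a), matrices.encode(b), matrix, gap_open, gap_extend
    )


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.isfinite(self.d)) or np.any(np.diag(self.d) != 0):
            raise ValueError("distances must be finite with zero diagonal")

    def to_tsv(self, path) -> None:
        """PHYLIP-compatible square format with a tab-separated body."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.taxa)}\n")
            for label, row in zip(self.taxa, self.d):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def identity_matrix(seqs: Mapping[str, str], **align_kwargs) -> DistanceMatrix:
    """All-pairs global-alignment distance matrix of (1 - percent identity)."""
    taxa = list(seqs)
    if len(taxa) != len(set(taxa)):
        raise ValueError("duplicate sequence labels")
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[taxa[i]], seqs[taxa[j]], **align_kwargs)
            d[i, j] = d[j, i] = 1.0 - aln.identity
    return DistanceMatrix(taxa, d)


# ---------------------------------------------------------------------------
# multiple sequence alignment (center-star)


@dataclass
class Msa:
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows differ in length")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace("-", "")


def build_msa_center_star(seqs: Mapping[str, str], **align_kwargs) -> Msa:
    """Center-star progressive alignment.

    The center is the sequence maximizing summed pairwise identity; every
    other sequence is aligned to it pairwise and the pairwise alignments are
    merged under the once-a-gap-always-a-gap rule.
    """
    taxa = list(seqs)
    if len(taxa) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(taxa)
    ident = np.zeros((n, n))
    alns: dict[tuple[int, int], GlobalAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[taxa[i]], seqs[taxa[j]], **align_kwargs)
            alns[(i, j)] = aln
            ident[i, j] = ident[j, i] = aln.identity
    center = int(np.argmax(ident.sum(axis=1)))

    master = seqs[taxa[center]]  # center row, accumulating gaps
    rows: dict[int, str] = {center: master}
    for k in range(n):
        if k == center:
            continue
        if (min(center, k), max(center, k)) in alns:
            aln = alns[(min(center, k), max(center, k))]
            if center < k:
                ca, sa = aln.aligned_a, aln.aligned_b
            else:
                ca, sa = aln.aligned_b, aln.aligned_a
        master, rows, new_row = _merge_into_master(master, rows, ca, sa)
        rows[k] = new_row
    width = len(master)
    ordered = [rows[i].ljust(width, "-") for i in range(n)]
    return Msa(taxa, ordered)


def _merge_into_master(master, rows, center_aln, seq_aln):
    """Merge one (center, sequence) pairwise alignment into the master MSA."""
    out_master = []
    out_rows = {k: [] for k in rows}
    out_new = []
    i = 0  # position in master
    j = 0  # position in center_aln / seq_aln
    while i < len(master) or j < len(center_aln):
        mc = master[i] if i < len(master) else None
        cc = center_aln[j] if j < len(center_aln) else None
        if mc == "-" and (cc != "-" or cc is None):
            # master has a gap the new pairwise alignment lacks
            out_master.append("-")
            for k in rows:
                out_rows[k].append(rows[k][i])
            out_new.append("-")
            i += 1
        elif cc == "-" and (mc != "-" or mc is None):
            # new alignment inserts a gap into the center
            out_master.append("-")
            for k in rows:
                out_rows[k].append("-")
            out_new.append(seq_aln[j])
            j += 1
        else:
            # both aligned the same center residue (or both gap)
            out_master.append(mc if mc is not None else "-")
            for k in rows:
                out_rows[k].append(rows[k][i] if i < len(master) else "-")
            out_new.append(seq_aln[j] if j < len(center_aln) else "-")
            i += 1
            j += 1
    new_master = "".join(out_master)
    new_rows = {k: "".join(v) for k, v in out_rows.items()}
    return new_master, new_rows, "".join(out_new)


def p_distance_matrix(msa: Msa) -> DistanceMatrix:
    """d[i][j] = mismatches / columns where both rows are non-gap."""
    n = len(msa.taxa)
    if n < 2:
        raise ValueError("need at least 2 rows")
    arr = np.array([list(r) for r in msa.rows])
    gaps = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~gaps[i] & ~gaps[j]
            total = int(both.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {msa.taxa[i]} and {msa.taxa[j]}"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(msa.taxa, d)


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_labels(self) -> list[str]:
        return [l.label for l in self.leaves()]

    def to_newick(self, annotations: bool = False) -> str:
        return _newick(self.root, annotations, is_root=True) + ";"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """All pairwise leaf-to-leaf path lengths."""
        adj = _adjacency(self.root)
        labels = {id(l): l.label for l in self.leaves()}
        dists: dict[tuple[str, str], float] = {}
        for leaf in self.leaves():
            seen = {id(leaf): 0.0}
            stack = [leaf]
            while stack:
                node = stack.pop()
                for nbr, w in adj[id(node)]:
                    if id(nbr) not in seen:
                        seen[id(nbr)] = seen[id(node)] + w
                        stack.append(nbr)
            for nid, dist in seen.items():
                if nid in labels and nid != id(leaf):
                    key = tuple(sorted((leaf.label, labels[nid])))
                    dists[key] = dist
        return dists

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions as frozensets of the side not containing
        the lexicographically first taxon (rooting-independent)."""
        all_taxa = frozenset(self.leaf_labels())
        anchor = min(all_taxa)
        bips = set()
        for node, _parent in _walk(self.root, None):
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.label for l in node.leaves())
            if anchor in side:
                side = all_taxa - side
            if 1 < len(side) < len(all_taxa) - 1:
                bips.add(side)
        return bips


def _walk(node, parent):
    yield node, parent
    for c in node.children:
        yield from _walk(c, node)


def _adjacency(root):
    adj: dict[int, list] = {}
    for node, parent in _walk(root, None):
        adj.setdefault(id(node), [])
        if parent is not None:
            adj[id(node)].append((parent, node.length))
            adj.setdefault(id(parent), []).append((node, node.length))
    return adj


def _newick(node: TreeNode, annotations: bool, is_root: bool = False) -> str:
    if node.is_leaf:
        txt = _quote_label(node.label or "")
        if annotations and node.annotations:
            nhx = ":".join(f"{k}={v}" for k, v in sorted(node.annotations.items()))
            txt += f"[&&NHX:{nhx}]"
    else:
        inner = ",".join(_newick(c, annotations) for c in node.children)
        label = ""
        if node.support is not None:
            label = f"{node.support:g}"
        txt = f"({inner}){label}"
    if is_root:
        return txt
    return f"{txt}:{node.length:g}"


_LABEL_UNSAFE = re.compile(r"[\s()\[\]:;,']")


def _quote_label(label: str) -> str:
    if _LABEL_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def from_newick(text: str) -> PhyloTree:
    """Parse newick (via dendropy), recovering supports and NHX annotations."""
    import dendropy

    # dendropy strips NHX comments into node.comments
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )

    def convert(dnode) -> TreeNode:
        node = TreeNode(length=dnode.edge.length or 0.0)
        if dnode.is_leaf():
            node.label = dnode.taxon.label if dnode.taxon else dnode.label
        else:
            if dnode.label is not None:
                try:
                    node.support = float(dnode.label)
                except ValueError:
                    node.label = dnode.label
            node.children = [convert(c) for c in dnode.child_nodes()]
        if dnode.annotations:
            node.annotations.update(
                {k: str(v) for k, v in dnode.annotations.values_as_dict().items()}
            )
        return node

    return PhyloTree(convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Canonical neighbor joining (Q-criterion), deterministic tie-breaks.

    Negative branch lengths are clamped to zero with the deficit transferred
    to the sister edge.  The result is unrooted, stored with a trifurcating
    root (bifurcating for 2 taxa).
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes = [TreeNode(label=t) for t in dm.taxa]
    if n == 2:
        half = dm.d[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return PhyloTree(TreeNode(children=nodes))
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(int(np.argmin(q)), q.shape)  # first min: lowest pair
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sister edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li = max(li, 0.0)
        lj = max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d[None, :]])
        d = np.hstack([d, np.append(new_d, 0.0)[:, None]])
        nodes.append(parent)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # join the final three around the root
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
    return PhyloTree(TreeNode(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# midpoint rooting


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Pairwise leaf path lengths are preserved.  With all-zero branch lengths
    the tree is returned rooted at the first internal node, with a warning.
    """
    leaves = tree.leaves()
    if len(leaves) < 2:
        raise ValueError("need at least 2 leaves")
    dists = tree.leaf_distances()
    best = max(dists.values())
    if best == 0:
        warnings.warn("all-zero branch lengths; rooting at first internal node")
        return PhyloTree(_detach_copy(tree.root))
    # deterministic tie-break: lexicographically first diameter pair
    u, v = min(sorted(k) for k, val in dists.items() if val == best)
    path = _leaf_path(tree.root, u, v)
    half = best / 2.0
    walked = 0.0
    for (node_a, node_b, edge_len, child) in path:
        if walked + edge_len >= half - 1e-12:
            offset = half - walked  # distance from node_a along this edge
            return _reroot_on_edge(tree, child, edge_len, offset_from_child_side=None,
                                   offset_from_a=offset, a_is_parent=(child is node_b))
        walked += edge_len
    # numerical fallthrough: root at far end
    return PhyloTree(_detach_copy(tree.root))


def _detach_copy(node: TreeNode) -> TreeNode:
    new = TreeNode(node.label, node.length, node.support, annotations=dict(node.annotations))
    new.children = [_detach_copy(c) for c in node.children]
    return new


def _leaf_path(root, u_label, v_label):
    """Edges along the path from leaf u to leaf v as
    (from_node, to_node, length, child_node) tuples, where child_node is the
    rooted-tree child endpoint of the edge."""
    parent_of = {id(root): None}
    node_by_id = {id(root): root}
    for node, parent in _walk(root, None):
        node_by_id[id(node)] = node
        if parent is not None:
            parent_of[id(node)] = parent
    leaf_nodes = {l.label: l for l in root.leaves()}
    u, v = leaf_nodes[u_label], leaf_nodes[v_label]
    anc_u = []
    x = u
    while x is not None:
        anc_u.append(x)
        x = parent_of[id(x)]
    anc_set = {id(x) for x in anc_u}
    x = v
    anc_v = []
    while id(x) not in anc_set:
        anc_v.append(x)
        x = parent_of[id(x)]
    lca = x
    path = []
    x = u
    while x is not lca:
        p = parent_of[id(x)]
        path.append((x, p, x.length, x))
        x = p
    down = []
    for node in reversed(anc_v):
        down.append((parent_of[id(node)], node, node.length, node))
    return path + down


def _reroot_on_edge(tree, child, edge_len, offset_from_child_side, offset_from_a, a_is_parent):
    """Insert a root on the edge above ``child`` (which has length edge_len),
    at ``offset_from_a`` from the path's from-node, and rebuild rooted."""
    # distance from the child end of the edge:
    if a_is_parent:
        dist_from_child = edge_len - offset_from_a
    else:
        dist_from_child = offset_from_a
    adj = _adjacency(tree.root)
    node_by_id = {id(n): n for n, _ in _walk(tree.root, None)}
    parent_of = {}
    for node, parent in _walk(tree.root, None):
        parent_of[id(node)] = parent
    parent = parent_of[id(child)]

    def build(node, came_from, incoming_len):
        new = TreeNode(
            node.label,
            incoming_len,
            node.support,
            annotations=dict(node.annotations),
        )
        for nbr, w in adj[id(node)]:
            if nbr is came_from:
                continue
            new.children.append(build(nbr, node, w))
        return new

    root = TreeNode()
    side_child = build(child, parent, dist_from_child)
    side_parent = build(parent, child, edge_len - dist_from_child)
    root.children = [side_child, side_parent]
    for i, c in enumerate(root.children):
        root.children[i] = _suppress_unifurcations(c)
    return PhyloTree(root)


def _suppress_unifurcations(node: TreeNode) -> TreeNode:
    """Collapse degree-2 internal nodes left over from rerooting."""
    node.children = [_suppress_unifurcations(c) for c in node.children]
    if len(node.children) == 1:
        child = node.children[0]
        child.length += node.length
        return child
    return node


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    msa: Msa, n_reps: int, seed: int
) -> tuple[PhyloTree, dict[frozenset, float]]:
    """Column bootstrap of the NJ tree.

    Columns are resampled with replacement per replicate; support for each
    original-tree bipartition is the percentage of replicate trees containing
    it.  Fully reproducible given the seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(p_distance_matrix(msa))
    orig_bips = tree.bipartitions()
    counts = {b: 0 for b in orig_bips}
    rng = np.random.default_rng(seed)
    arr = np.array([list(r) for r in msa.rows])
    n_cols = arr.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep_msa = Msa(list(msa.taxa), rep_rows)
        try:
            rep_tree = nj_tree(p_distance_matrix(rep_msa))
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        rep_bips = rep_tree.bipartitions()
        for b in orig_bips:
            if b in rep_bips:
                counts[b] += 1
    support = {b: 100.0 * c / n_reps for b, c in counts.items()}
    annotate_supports(tree, support)
    return tree, support


def annotate_supports(tree: PhyloTree, support: dict[frozenset, float]) -> None:
    """Attach bipartition support percentages to internal nodes (any rooting)."""
    all_taxa = frozenset(tree.leaf_labels())
    anchor = min(all_taxa)
    for node, _parent in _walk(tree.root, None):
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(l.label for l in node.leaves())
        if anchor in side:
            side = all_taxa - side
        if side in support:
            node.support = support[side]


# ---------------------------------------------------------------------------
# tip metadata


def tag_tips(
    tree: PhyloTree, metadata: Mapping[str, tuple[str, str]]
) -> PhyloTree:
    """Attach (host_class, geography) annotations to tree tips.

    Tips without a metadata row are tagged "missing"; metadata labels absent
    from the tree raise a warning, not an error.
    """
    tips = {l.label: l for l in tree.leaves()}
    for label, (host, geo) in metadata.items():
        if label not in tips:
            warnings.warn(f"metadata label {label!r} not present in tree")
            continue
        tips[label].annotations["host_class"] = host
        tips[label].annotations["geography"] = geo
    for label, tip in tips.items():
        tip.annotations.setdefault("host_class", "missing")
        tip.annotations.setdefault("geography", "missing")
    return tree


def read_metadata_tsv(path) -> dict[str, tuple[str, str]]:
    """label -> (host_class, geography) from a 3-column TSV with header."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("missing")
    cols = list(df.columns)
    if len(cols) < 3:
        raise ValueError("metadata TSV needs label, host_class, geography columns")
    out = {}
    for _, row in df.iterrows():
        label = row[cols[0]]
        if label in out:
            raise ValueError(f"duplicate metadata label {label!r}")
        out[label] = (row[cols[1]], row[cols[2]])
    return out
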