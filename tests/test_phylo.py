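"""Distance matrices, center-star MSA, NJ exactness, rooting and bootstrap."""

import numpy as np
import pytest

from evescreen.phylo import (
    DistanceMatrix,
    Msa,
    PhyloTree,
    TreeNode,
    bootstrap_support,
    build_msa_center_star,
    from_newick,
    identity_matrix,
    midpoint_root,
    nj_tree,
    p_distance_matrix,
    tag_tips,
)


# ---------------------------------------------------------------------------
# distances


def test_identity_matrix_symmetric_zero_diagonal():
    dm = identity_matrix({"a": "MKVHW", "b": "MKVHW", "c": "MKVHY"})
    assert dm.d[0, 1] == 0.0
    assert np.allclose(dm.d, dm.d.T)
    assert dm.d[0, 2] == pytest.approx(0.2)


def test_identity_matrix_duplicate_labels_error():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "a"], np.zeros((2, 2)) + np.array([[0, 1], [2, 0]]))


def test_identity_matrix_tracks_simulated_divergence(rng):
    from evescreen.synthetic import evolve_protein

    base = "M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=599))
    seqs = {f"t{i}": evolve_protein(base, 0.3, rng) for i in range(4)}
    dm = identity_matrix(seqs)
    off = dm.d[np.triu_indices(4, 1)]
    # two seqs at 0.3 divergence from a common base differ at ~1-0.7^2-ish
    assert 0.2 <= off.mean() <= 0.55


def test_p_distance_examples():
    msa = Msa(["a", "b"], ["AAAA", "AAAT"])
    assert p_distance_matrix(msa).d[0, 1] == pytest.approx(0.25)
    msa = Msa(["a", "b"], ["AAAA", "AAAA"])
    assert p_distance_matrix(msa).d[0, 1] == 0.0
    with pytest.raises(ValueError, match="comparable"):
        p_distance_matrix(Msa(["a", "b"], ["AA--", "--AA"]))


def test_p_distance_matches_naive_per_pair(rng):
    rows = []
    for _ in range(5):
        rows.append(
            "".join(
                rng.choice(list("ACDE-"), size=60, p=[0.22, 0.22, 0.22, 0.22, 0.12])
            )
        )
    msa = Msa([f"t{i}" for i in range(5)], rows)
    dm = p_distance_matrix(msa)
    for i in range(5):
        for j in range(i + 1, 5):
            comp = [
                (x, y)
                for x, y in zip(rows[i], rows[j])
                if x != "-" and y != "-"
            ]
            expect = sum(1 for x, y in comp if x != y) / len(comp)
            assert dm.d[i, j] == pytest.approx(expect)


# ---------------------------------------------------------------------------
# center-star MSA


def test_center_star_identical_sequences_gapless():
    msa = build_msa_center_star({"a": "MKVHW", "b": "MKVHW", "c": "MKVHW"})
    assert msa.rows == ["MKVHW", "MKVHW", "MKVHW"]


def test_center_star_single_deletion_gap():
    seqs = {"a": "MKVHWDE", "b": "MKVHWDE", "c": "MKVWDE"}  # c lacks the H
    msa = build_msa_center_star(seqs)
    assert msa.n_columns == 7
    for i, label in enumerate(msa.taxa):
        assert msa.ungapped(i) == seqs[label]
    c_row = msa.rows[msa.taxa.index("c")]
    assert c_row.count("-") == 1


def test_center_star_ungap_recovers_inputs(rng):
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aas, size=80))
    seqs = {}
    for i in range(5):
        s = list(base)
        # random point changes and a short deletion
        for _ in range(8):
            s[int(rng.integers(len(s)))] = aas[int(rng.integers(20))]
        if i % 2:
            start = int(rng.integers(10, 60))
            del s[start : start + 3]
        seqs[f"t{i}"] = "".join(s)
    msa = build_msa_center_star(seqs)
    for i, label in enumerate(msa.taxa):
        assert msa.ungapped(i) == seqs[label]


def _sum_of_pairs(msa: Msa) -> int:
    score = 0
    for i in range(len(msa.rows)):
        for j in range(i + 1, len(msa.rows)):
            score += sum(
                1
                for x, y in zip(msa.rows[i], msa.rows[j])
                if x == y and x != "-"
            )
    return score


def test_center_star_beats_first_sequence_anchor(rng):
    """Sum-of-pairs matches under the chosen center >= anchoring on an
    arbitrary (first) sequence."""
    from evescreen.phylo import _merge_into_master, global_align

    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base = "".join(rng.choice(aas, size=60))
    seqs = {}
    for i in range(5):
        s = list(base)
        for _ in range(12):
            s[int(rng.integers(len(s)))] = aas[int(rng.integers(20))]
        seqs[f"t{i}"] = "".join(s)
    star = build_msa_center_star(seqs)

    labels = list(seqs)
    master = seqs[labels[0]]
    rows = {0: master}
    for k in range(1, len(labels)):
        aln = global_align(seqs[labels[0]], seqs[labels[k]])
        master, rows, new_row = _merge_into_master(
            master, rows, aln.aligned_a, aln.aligned_b
        )
        rows[k] = new_row
    width = len(master)
    naive = Msa(labels, [rows[i].ljust(width, "-") for i in range(len(labels))])
    assert _sum_of_pairs(star) >= _sum_of_pairs(naive)


# ---------------------------------------------------------------------------
# neighbor joining


def test_nj_two_taxa_splits_edge():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
    tree = nj_tree(dm)
    lengths = {l.label: l.length for l in tree.leaves()}
    assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}


def test_nj_three_taxa_closed_form():
    d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
    tree = nj_tree(DistanceMatrix(["A", "B", "C"], d))
    lengths = {l.label: l.length for l in tree.leaves()}
    assert lengths["A"] == pytest.approx(1.0)
    assert lengths["B"] == pytest.approx(1.0)
    assert lengths["C"] == pytest.approx(3.0)


def test_nj_requires_symmetric_matrix():
    with pytest.raises(ValueError):
        DistanceMatrix(["a", "b"], np.array([[0, 1], [2, 0]]))


def _random_additive_tree(n_leaves, rng):
    """A random binary tree with positive branch lengths; returns
    (DistanceMatrix from path lengths, PhyloTree)."""
    nodes = [TreeNode(label=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)), children=[a, b])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    tree = PhyloTree(TreeNode(children=nodes))
    dists = tree.leaf_distances()
    labels = sorted(l.label for l in tree.leaves())
    n = len(labels)
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            d[x, y] = d[y, x] = dists[(labels[x], labels[y])]
    return DistanceMatrix(labels, d), tree


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_nj_exact_on_additive_matrices(seed):
    """NJ recovers topology and branch lengths exactly from additive
    distances (tolerance 1e-9)."""
    rng = np.random.default_rng(seed)
    for _ in range(10):
        n = int(rng.integers(5, 9))
        dm, true_tree = _random_additive_tree(n, rng)
        est = nj_tree(dm)
        assert est.bipartitions() == true_tree.bipartitions()
        est_d = est.leaf_distances()
        true_d = true_tree.leaf_distances()
        for key, val in true_d.items():
            assert est_d[key] == pytest.approx(val, abs=1e-9)


def test_nj_topology_agrees_with_dendropy():
    """Independent-library cross-check on a non-additive noisy matrix."""
    import dendropy

    rng = np.random.default_rng(11)
    dm, _tree = _random_additive_tree(7, rng)
    noisy = dm.d + rng.uniform(0, 0.01, size=dm.d.shape)
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0)
    dm2 = DistanceMatrix(dm.taxa, noisy)
    mine = nj_tree(dm2)

    csv = "," + ",".join(dm2.taxa) + "\n"
    for t, row in zip(dm2.taxa, dm2.d):
        csv += t + "," + ",".join(str(v) for v in row) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(csv), is_first_row_column_names=True, is_first_column_row_names=True
    )
    dtree = pdm.nj_tree()
    dnewick = dtree.as_string(schema="newick").replace("[&U]", "").strip()
    theirs = from_newick(dnewick)
    assert mine.bipartitions() == theirs.bipartitions()


# ---------------------------------------------------------------------------
# midpoint rooting


def test_midpoint_two_taxa():
    dm = DistanceMatrix(["a", "b"], np.array([[0, 0.4], [0.4, 0]]))
    rooted = midpoint_root(nj_tree(dm))
    assert len(rooted.root.children) == 2
    for child in rooted.root.children:
        assert child.length == pytest.approx(0.2)


def test_midpoint_bisects_caterpillar_diameter():
    # caterpillar: ((((a,b),c),d),e) with known lengths
    a = TreeNode("a", 1.0)
    b = TreeNode("b", 0.1)
    ab = TreeNode(None, 0.5, children=[a, b])
    c = TreeNode("c", 0.1)
    abc = TreeNode(None, 0.5, children=[ab, c])
    d = TreeNode("d", 0.1)
    abcd = TreeNode(None, 0.5, children=[abc, d])
    e = TreeNode("e", 2.0)
    tree = PhyloTree(TreeNode(children=[abcd, e]))
    dists = tree.leaf_distances()
    diameter = max(dists.values())
    assert dists[("a", "e")] == pytest.approx(diameter)
    rooted = midpoint_root(tree)
    # the two root-to-extreme-leaf distances are equal (= diameter / 2)
    rd = {}
    def depth(node, acc):
        if node.is_leaf:
            rd[node.label] = acc + node.length
        for ch in node.children:
            depth(ch, acc + (node.length if node is not rooted.root else 0))
    depth(rooted.root, 0.0)
    assert rd["a"] == pytest.approx(diameter / 2)
    assert rd["e"] == pytest.approx(diameter / 2)


def test_midpoint_preserves_leaf_distances(rng):
    dm, tree = _random_additive_tree(8, rng)
    rooted = midpoint_root(tree)
    before = tree.leaf_distances()
    after = rooted.leaf_distances()
    for key, val in before.items():
        assert after[key] == pytest.approx(val, abs=1e-9)


def test_midpoint_all_zero_lengths_warns():
    a = TreeNode("a", 0.0)
    b = TreeNode("b", 0.0)
    tree = PhyloTree(TreeNode(children=[a, b]))
    with pytest.warns(UserWarning):
        midpoint_root(tree)


# ---------------------------------------------------------------------------
# bootstrap


def _structured_msa(rng):
    """Two 4-taxon clades with 50 diagnostic columns each plus noise."""
    n_noise = 60
    rows = []
    noise = rng.choice(list("ACDEFGHIKL"), size=(8, n_noise))
    for i in range(8):
        clade = i // 4
        diag1 = ("K" if clade == 0 else "E") * 50
        diag2 = ("R" if clade == 0 else "D") * 50
        rows.append(diag1 + diag2 + "".join(noise[i]))
    return Msa([f"t{i}" for i in range(8)], rows)


def test_bootstrap_structured_clades_high_support(rng):
    msa = _structured_msa(rng)
    tree, support = bootstrap_support(msa, n_reps=100, seed=5)
    clade_a = frozenset(["t4", "t5", "t6", "t7"])  # side without first taxon
    assert clade_a in support
    assert support[clade_a] >= 95.0


def test_bootstrap_reproducible_given_seed(rng):
    msa = _structured_msa(rng)
    _, s1 = bootstrap_support(msa, n_reps=25, seed=9)
    _, s2 = bootstrap_support(msa, n_reps=25, seed=9)
    assert s1 == s2
    assert all(0.0 <= v <= 100.0 for v in s1.values())


def test_bootstrap_degenerate_identical_rows_no_crash():
    msa = Msa(["a", "b", "c", "d"], ["AAAA"] * 4)
    tree, support = bootstrap_support(msa, n_reps=10, seed=1)
    assert set(tree.leaf_labels()) == {"a", "b", "c", "d"}


# ---------------------------------------------------------------------------
# tip tagging and newick round-trip


def test_tag_tips_and_missing():
    dm = DistanceMatrix(
        ["DrPV-1", "x", "y"],
        np.array([[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]]),
    )
    tree = nj_tree(dm)
    with pytest.warns(UserWarning, match="notatip"):
        tag_tips(tree, {"DrPV-1": ("Mammalia", "Brazil"), "notatip": ("x", "y")})
    tips = {l.label: l for l in tree.leaves()}
    assert tips["DrPV-1"].annotations == {
        "host_class": "Mammalia",
        "geography": "Brazil",
    }
    assert tips["x"].annotations["host_class"] == "missing"


def test_newick_round_trip_preserves_structure_and_tags():
    dm = DistanceMatrix(
        ["a", "b", "c", "d"],
        np.array(
            [
                [0, 0.2, 0.8, 0.9],
                [0.2, 0, 0.7, 0.8],
                [0.8, 0.7, 0, 0.3],
                [0.9, 0.8, 0.3, 0],
            ]
        ),
    )
    tree = nj_tree(dm)
    tag_tips(tree, {"a": ("Aves", "Madagascar")})
    text = tree.to_newick(annotations=True)
    back = from_newick(text)
    assert back.bipartitions() == tree.bipartitions()
    d1, d2 = tree.leaf_distances(), back.leaf_distances()
    for key, val in d1.items():
        assert d2[key] == pytest.approx(val, abs=1e-6)
    tips = {l.label: l for l in back.leaves()}
    assert tips["a"].annotations["host_class"] == "Aves"
    assert tips["a"].annotations["geography"] == "Madagascar"
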