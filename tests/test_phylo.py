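import itertools

import dendropy
import numpy as np
import pytest

from wrkyscan.phylo import (
    DistanceMatrix,
    bootstrap,
    neighbor_joining,
    p_distance,
    progressive_msa,
    read_newick,
    tree_distance_matrix,
    write_newick,
    _bipartitions,
)


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def test_p_distance_simple_mismatch():
    dm = p_distance(["ACGT", "ACGA"])
    assert dm.d[0, 1] == pytest.approx(0.25)


def test_p_distance_pairwise_gap_deletion():
    dm = p_distance(["AC-T", "ACGT"])
    assert dm.d[0, 1] == 0.0  # 3 compared columns, 0 mismatches


def test_p_distance_identical_rows():
    assert p_distance(["MKV", "MKV"]).d[0, 1] == 0.0


def test_p_distance_all_gap_pair_is_an_error():
    with pytest.raises(ValueError):
        p_distance(["A--", "-AA", "AAA"])


def test_p_distance_range_and_monotonicity():
    base_a, base_b = "ACGTACGT", "ACGTACGA"
    d0 = p_distance([base_a, base_b]).d[0, 1]
    d1 = p_distance([base_a + "A", base_b + "C"]).d[0, 1]  # add a mismatch column
    assert 0.0 <= d0 <= d1 <= 1.0


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form():
    dm = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    tree = neighbor_joining(dm)
    lengths = {
        nd.taxon.label: nd.edge.length for nd in tree.leaf_node_iter()
    }
    assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}


def _additive_matrix():
    # unrooted tree ((A:1,B:2):1.5,(C:3,D:0.5)) -> pairwise path lengths
    labels = ["A", "B", "C", "D"]
    d = {
        ("A", "B"): 3.0,
        ("A", "C"): 5.5, ("A", "D"): 3.0,
        ("B", "C"): 6.5, ("B", "D"): 4.0,
        ("C", "D"): 3.5,
    }
    m = np.zeros((4, 4))
    for (x, y), v in d.items():
        i, j = labels.index(x), labels.index(y)
        m[i, j] = m[j, i] = v
    return DistanceMatrix(labels, m)


def _ls_residual(dm, split):
    """Least-squares branch-length fit of a 4-taxon topology; returns the
    residual (0 for the generating topology of an additive matrix)."""
    labels = dm.labels
    (p, q), (r, s) = split
    # branch params: 4 leaf branches + 1 internal
    idx = {lab: k for k, lab in enumerate(labels)}
    rows, y = [], []
    for i, j in itertools.combinations(labels, 2):
        row = np.zeros(5)
        row[idx[i]] = 1
        row[idx[j]] = 1
        same_side = {i, j} in ({p, q}, {r, s})
        if not same_side:
            row[4] = 1
        rows.append(row)
        y.append(dm.d[labels.index(i), labels.index(j)])
    sol, res, *_ = np.linalg.lstsq(np.array(rows), np.array(y), rcond=None)
    pred = np.array(rows) @ sol
    return float(np.sum((pred - np.array(y)) ** 2))


def test_four_taxon_additive_recovery_vs_exhaustive_search():
    dm = _additive_matrix()
    tree = neighbor_joining(dm)
    # brute force over the 3 unrooted topologies: the generating split AB|CD
    # is the unique zero-residual fit
    splits = [
        (("A", "B"), ("C", "D")),
        (("A", "C"), ("B", "D")),
        (("A", "D"), ("B", "C")),
    ]
    residuals = {s: _ls_residual(dm, s) for s in splits}
    best = min(residuals, key=residuals.get)
    assert best == (("A", "B"), ("C", "D"))
    assert residuals[best] == pytest.approx(0.0, abs=1e-18)
    got = _bipartitions(tree)
    assert frozenset({"A", "B"}) in got or frozenset({"C", "D"}) in got


def test_additive_matrix_path_lengths_reproduced_exactly():
    dm = _additive_matrix()
    tree = neighbor_joining(dm)
    out = tree_distance_matrix(tree)
    want = {lab: i for i, lab in enumerate(dm.labels)}
    for i, a in enumerate(out.labels):
        for j, b in enumerate(out.labels):
            assert out.d[i, j] == pytest.approx(dm.d[want[a], want[b]], abs=1e-9)


def test_all_equal_distances_deterministic():
    d = np.ones((5, 5)) - np.eye(5)
    t1 = neighbor_joining(DistanceMatrix(list("ABCDE"), d))
    t2 = neighbor_joining(DistanceMatrix(list("ABCDE"), d))
    assert t1.as_string(schema="newick") == t2.as_string(schema="newick")


def test_asymmetric_matrix_is_an_error():
    d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], float)
    with pytest.raises(ValueError):
        DistanceMatrix(["A", "B", "C"], d)


def test_negative_branch_lengths_clamped():
    # a strongly non-additive matrix can produce negative NJ branch estimates
    d = np.array(
        [[0, 1, 10, 10], [1, 0, 1, 10], [10, 1, 0, 1], [10, 10, 1, 0]], float
    )
    tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            assert edge.length >= 0.0


# ---------------------------------------------------------------------------
# progressive MSA
# ---------------------------------------------------------------------------

def test_msa_identical_sequences_no_gaps():
    aln = progressive_msa(["MKVAC", "MKVAC", "MKVAC"])
    assert aln == ["MKVAC", "MKVAC", "MKVAC"]


def test_msa_two_sequences_reduces_to_pairwise():
    aln = progressive_msa(["MKVACDE", "MKACDE"])
    assert [r.replace("-", "") for r in aln] == ["MKVACDE", "MKACDE"]
    assert len(aln[0]) == len(aln[1])


def test_msa_rows_degap_to_inputs():
    seqs = ["MKVACDEFG", "MKVACD", "MKVYYDEFG", "KVACDEFG"]
    aln = progressive_msa(seqs)
    assert [r.replace("-", "") for r in aln] == seqs


def _sp_score(aln):
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load("BLOSUM62")
    total = 0.0
    for i in range(len(aln)):
        for j in range(i + 1, len(aln)):
            for x, y in zip(aln[i], aln[j]):
                if x == "-" and y == "-":
                    continue
                total += -8.0 if "-" in (x, y) else float(sub[x, y])
    return total


def test_msa_sum_of_pairs_beats_column_shuffles():
    seqs = ["MKVACDEFGKLMNPQRSTVW", "MKVACDEFGKLMNPQRSTW", "MKVACEFGKLMNPQRSTVW"]
    aln = progressive_msa(seqs)
    base = _sp_score(aln)
    rng = np.random.default_rng(1)
    ncol = len(aln[0])
    for _ in range(50):
        perm = rng.permutation(ncol)
        shuffled = ["".join(r[k] for k in perm) for r in aln]
        # keep only shuffles whose rows still degap to the inputs
        if [r.replace("-", "") for r in shuffled] != seqs:
            continue
        assert _sp_score(shuffled) <= base + 1e-9


def test_msa_single_sequence_is_an_error():
    with pytest.raises(ValueError):
        progressive_msa(["MKV"])


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _two_clade_alignment(rng):
    # two well-separated clades of 3: within-clade distance tiny,
    # between-clade distance large
    base1 = "".join(rng.choice(list("ACDEFGHIKL"), 60))
    base2 = "".join(rng.choice(list("MNPQRSTVWY"), 60))

    def noisy(base, n):
        s = list(base)
        for i in rng.choice(60, size=n, replace=False):
            s[i] = "G" if s[i] != "G" else "A"
        return "".join(s)

    return [noisy(base1, 2), noisy(base1, 2), noisy(base1, 2),
            noisy(base2, 2), noisy(base2, 2), noisy(base2, 2)]


def test_separated_clades_get_high_support():
    rng = np.random.default_rng(23)
    aln = _two_clade_alignment(rng)
    labels = [f"t{i}" for i in range(6)]
    tree = bootstrap(aln, labels, n_reps=100, seed=5)
    clade = frozenset(labels[:3])
    supports = {}
    all_labels = frozenset(labels)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node or node.label is None:
            continue
        side = frozenset(nd.taxon.label for nd in node.leaf_iter())
        key = min(side, all_labels - side, key=lambda s: (len(s), sorted(s)))
        supports[key] = int(node.label)
    assert supports.get(clade, supports.get(all_labels - clade, 0)) >= 95


def test_single_replicate_supports_binary():
    rng = np.random.default_rng(2)
    aln = _two_clade_alignment(rng)
    tree = bootstrap(aln, [f"t{i}" for i in range(6)], n_reps=1, seed=3)
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            assert int(node.label) in (0, 100)


def test_row_permutation_leaves_clade_support_unchanged():
    # per-replicate column draws are independent of row order, so the support
    # of the well-separated clade is invariant under permuting input rows
    # (within-clade edges can differ where distances tie exactly)
    rng = np.random.default_rng(31)
    aln = _two_clade_alignment(rng)
    labels = [f"t{i}" for i in range(6)]
    clade = frozenset(labels[:3])

    def clade_support(a, l):
        tree = bootstrap(a, l, n_reps=50, seed=9)
        all_l = frozenset(l)
        for node in tree.preorder_internal_node_iter():
            if node is tree.seed_node or node.label is None:
                continue
            side = frozenset(nd.taxon.label for nd in node.leaf_iter())
            if side in (clade, all_l - clade):
                return int(node.label)
        return None

    perm = [3, 0, 5, 1, 4, 2]
    s1 = clade_support(aln, labels)
    s2 = clade_support([aln[i] for i in perm], [labels[i] for i in perm])
    assert s1 is not None
    assert s1 == s2


# ---------------------------------------------------------------------------
# Newick round trip
# ---------------------------------------------------------------------------

def test_newick_round_trip(tmp_path):
    dm = _additive_matrix()
    tree = neighbor_joining(dm)
    p = tmp_path / "t.nwk"
    write_newick(tree, p)
    back = read_newick(p)
    assert {t.label for t in back.taxon_namespace} == set(dm.labels)
    d1 = tree_distance_matrix(tree)
    d2 = tree_distance_matrix(back)
    assert np.allclose(d1.d, d2.d, atol=1e-9)
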