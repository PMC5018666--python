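"""Distance-based phylogenies of WRKY domains.

Implements the classic distance pipeline: progressive multiple alignment over
an NJ guide tree, p-distance with pairwise gap deletion, Saitou–Nei
neighbor joining, and nonparametric bootstrap of alignment columns.  Trees
are dendropy objects; Newick round-trips go through dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
#: linear per-residue gap penalty used by the progressive profile aligner
PROFILE_GAP = -8.0

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------

def p_distance(
    alignment: list[str],
    labels: list[str] | None = None,
    mode: str = "pairwise-gap-deletion",
) -> DistanceMatrix:
    """Proportion of mismatched sites per pair, excluding columns gapped in
    either row of the pair (pairwise gap deletion).

    Raises ValueError if a pair shares no ungapped column.
    """
    if mode != "pairwise-gap-deletion":
        raise ValueError(f"unknown mode {mode!r}")
    n = len(alignment)
    if n < 2:
        raise ValueError("need at least 2 rows")
    if len({len(r) for r in alignment}) != 1:
        raise ValueError("ragged alignment")
    if labels is None:
        labels = [f"seq{i}" for i in range(n)]
    arr = np.array([list(r) for r in alignment])
    gaps = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = ~(gaps[i] | gaps[j])
            m = int(keep.sum())
            if m == 0:
                raise ValueError(
                    f"rows {labels[i]!r}/{labels[j]!r} share no ungapped columns"
                )
            d[i, j] = d[j, i] = float((arr[i, keep] != arr[j, keep]).sum()) / m
    return DistanceMatrix(labels=list(labels), d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining.

    Ties in the Q-criterion break on the lowest (i, j) index pair; negative
    branch lengths are clamped to zero and flagged via the tree annotation
    ``clamped_branches``.  On an additive matrix the output path lengths
    reproduce the input exactly.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
    D = dm.d.copy()
    clamped = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        totals = D.sum(axis=1)
        Q = (m - 2) * D - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ii, jj = min(
            (int(i), int(j))
            for i, j in np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-9))
            if i < j
        )
        dij = D[ii, jj]
        li = 0.5 * dij + (totals[ii] - totals[jj]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[ii])
        nodes[ii].edge.length = _clamp(li)
        parent.add_child(nodes[jj])
        nodes[jj].edge.length = _clamp(lj)
        dnew = 0.5 * (D[ii] + D[jj] - dij)
        keep = [k for k in range(m) if k not in (ii, jj)]
        D2 = np.zeros((m - 1, m - 1))
        D2[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D2[m - 2, : m - 2] = dnew[keep]
        D2[: m - 2, m - 2] = dnew[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-point join at an unrooted (degree-3) root
    (a, b, c) = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    for nd, ln in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        root.add_child(nd)
        nd.edge.length = _clamp(ln)
    tree.seed_node = root
    tree.is_rooted = False
    tree.annotations.add_new("clamped_branches", clamped)
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path lengths of a tree, as a DistanceMatrix."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

_ALPHA = "ACDEFGHIKLMNPQRSTVWYX"
_ALPHA_IDX = {c: i for i, c in enumerate(_ALPHA)}
_SUBMAT = np.array(
    [[_BLOSUM62[a, b] for b in _ALPHA] for a in _ALPHA], dtype=float
)


def _profile_counts(profile: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column residue-count matrix (cols x alphabet) and gap counts."""
    ncol = len(profile[0])
    counts = np.zeros((ncol, len(_ALPHA)))
    gaps = np.zeros(ncol)
    for row in profile:
        for j, ch in enumerate(row):
            if ch == GAP:
                gaps[j] += 1
            else:
                counts[j, _ALPHA_IDX.get(ch, len(_ALPHA) - 1)] += 1
    return counts, gaps


def _align_profiles(pa: list[str], pb: list[str]) -> list[str]:
    """Global DP alignment of two profiles with sum-of-pairs column scoring."""
    la, lb = len(pa[0]), len(pb[0])
    ca, gaps_a = _profile_counts(pa)
    cb, gaps_b = _profile_counts(pb)
    nres_a = ca.sum(axis=1)
    nres_b = cb.sum(axis=1)
    ga = PROFILE_GAP * nres_a  # cost of a gap column against profile a
    gb = PROFILE_GAP * nres_b
    # sum-of-pairs column-vs-column scores, residue-residue + residue-gap terms
    pair = ca @ _SUBMAT @ cb.T
    pair += PROFILE_GAP * (gaps_a[:, None] * nres_b[None, :] + nres_a[:, None] * gaps_b[None, :])

    S = np.zeros((la + 1, lb + 1))
    back = np.zeros((la + 1, lb + 1), dtype=np.int8)  # 0 diag, 1 up(gap b), 2 left(gap a)
    for i in range(1, la + 1):
        S[i, 0] = S[i - 1, 0] + ga[i - 1]
        back[i, 0] = 1
    for j in range(1, lb + 1):
        S[0, j] = S[0, j - 1] + gb[j - 1]
        back[0, j] = 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = S[i - 1, j - 1] + pair[i - 1, j - 1]
            up = S[i - 1, j] + ga[i - 1]
            left = S[i, j - 1] + gb[j - 1]
            best = max(diag, up, left)
            S[i, j] = best
            back[i, j] = 0 if best == diag else (1 if best == up else 2)

    rows_a = ["" for _ in pa]
    rows_b = ["" for _ in pb]
    i, j = la, lb
    while i > 0 or j > 0:
        move = back[i, j]
        if move == 0:
            for k in range(len(pa)):
                rows_a[k] = pa[k][i - 1] + rows_a[k]
            for k in range(len(pb)):
                rows_b[k] = pb[k][j - 1] + rows_b[k]
            i, j = i - 1, j - 1
        elif move == 1:
            for k in range(len(pa)):
                rows_a[k] = pa[k][i - 1] + rows_a[k]
            for k in range(len(pb)):
                rows_b[k] = GAP + rows_b[k]
            i -= 1
        else:
            for k in range(len(pa)):
                rows_a[k] = GAP + rows_a[k]
            for k in range(len(pb)):
                rows_b[k] = pb[k][j - 1] + rows_b[k]
            j -= 1
    return rows_a + rows_b


def progressive_msa(sequences: list[str]) -> list[str]:
    """Progressive multiple alignment over an NJ guide tree.

    Pairwise guide distances are p-distances of global pairwise profile
    alignments.  Rows of the result, degapped, equal the inputs, in input
    order.
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if n == 2:
        a, b = _align_profiles([sequences[0]], [sequences[1]])
        return [a, b]

    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = _align_profiles([sequences[i]], [sequences[j]])
            cols = [(x, y) for x, y in zip(ra, rb) if x != GAP and y != GAP]
            d[i, j] = d[j, i] = (
                sum(x != y for x, y in cols) / len(cols) if cols else 1.0
            )
    guide = neighbor_joining(DistanceMatrix([str(i) for i in range(n)], d))

    def _profile(node) -> list[tuple[int, str]]:
        if node.is_leaf():
            idx = int(node.taxon.label)
            return [(idx, sequences[idx])]
        merged: list[tuple[int, str]] | None = None
        for child in node.child_nodes():
            sub = _profile(child)
            if merged is None:
                merged = sub
            else:
                rows = _align_profiles(
                    [s for _, s in merged], [s for _, s in sub]
                )
                idxs = [i for i, _ in merged] + [i for i, _ in sub]
                merged = list(zip(idxs, rows))
        return merged

    prof = _profile(guide.seed_node)
    out = [""] * n
    for idx, row in prof:
        out[idx] = row
    return out


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as frozensets of the smaller/canonical side."""
    all_labels = frozenset(t.label for t in tree.taxon_namespace)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(nd.taxon.label for nd in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_labels) - 2:
            continue
        other = all_labels - side
        out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return out


def bootstrap(
    alignment: list[str],
    labels: list[str],
    n_reps: int = 100,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports (% of replicates containing each
    internal bipartition) on internal node labels.

    Column indices for each replicate are drawn once, independently of row
    order, so permuting input rows leaves supports unchanged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ncol = len(alignment[0])
    tree = neighbor_joining(p_distance(alignment, labels))
    counts: dict[frozenset[str], int] = {}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rep = ["".join(row[k] for k in idx) for row in alignment]
        try:
            rep_tree = neighbor_joining(p_distance(rep, labels))
        except ValueError:  # a pair with no shared ungapped resampled columns
            continue
        for bp in _bipartitions(rep_tree):
            counts[bp] = counts.get(bp, 0) + 1
    all_labels = frozenset(labels)
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(nd.taxon.label for nd in node.leaf_iter())
        if len(side) < 2 or len(side) > len(all_labels) - 2:
            continue
        key = min(side, all_labels - side, key=lambda s: (len(s), sorted(s)))
        node.label = str(round(100.0 * counts.get(key, 0) / n_reps))
    return tree


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
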