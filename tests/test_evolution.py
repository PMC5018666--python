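import numpy as np
import pytest

from wrkyscan.evolution import (
    align_pair,
    all_pairs_kaks,
    classify_duplication,
    find_homolog_pairs,
    kaks_nei_gojobori,
    reciprocal_best_hits,
    _codon_sites,
    HomologPair,
)
from wrkyscan.io_formats import GeneModel

AAS = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def test_identical_sequences():
    aln = align_pair("MKVACDEF", "MKVACDEF")
    assert aln.identity_pct == 100.0
    assert aln.coverage_pct == 100.0


def test_single_substitution_identity():
    aln = align_pair("ACDEFG", "ACDEFH")
    assert aln.identity_pct == pytest.approx(100 * 5 / 6, abs=0.1)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        align_pair("", "ACD")


def _gotoh_score(a, b, sub, open_=-10.0, ext=-0.5):
    """Independent affine-gap global DP (Gotoh) computing the optimal score."""
    NEG = -1e9
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = open_ + (i - 1) * ext
    for j in range(1, m + 1):
        Y[0, j] = open_ + (j - 1) * ext
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + open_, X[i - 1, j] + ext, Y[i - 1, j] + open_)
            Y[i, j] = max(M[i, j - 1] + open_, Y[i, j - 1] + ext, X[i, j - 1] + open_)
    return max(M[n, m], X[n, m], Y[n, m])


def test_aligner_score_matches_brute_force_dp():
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(11)
    for _ in range(25):
        a = "".join(rng.choice(list(AAS), 12))
        b = "".join(rng.choice(list(AAS), 12))
        got = align_pair(a, b, mode="global-affine").score
        assert got == pytest.approx(_gotoh_score(a, b, sub), abs=1e-6)


# ---------------------------------------------------------------------------
# homolog pairs and duplication classes
# ---------------------------------------------------------------------------

def _mutate(seq, n, rng):
    s = list(seq)
    for i in rng.choice(len(s), size=n, replace=False):
        s[i] = "W" if s[i] != "W" else "Y"
    return "".join(s)


def test_homolog_pair_thresholds():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list(AAS), 200))
    near = _mutate(base, 20, rng)      # ~90% identity, full coverage -> kept
    far = _mutate(base, 80, rng)       # ~60% identity -> dropped
    short = base[:100]                 # 100% identity, 50% coverage -> dropped
    pairs = find_homolog_pairs({"a": base, "b": near, "c": far, "d": short})
    kept = {frozenset((p.gene_a, p.gene_b)) for p in pairs}
    assert frozenset(("a", "b")) in kept
    assert all(frozenset(("a", "c")) != k for k in kept)
    assert all("d" not in k for k in kept)


def _pair(a="a", b="b"):
    return HomologPair(gene_a=a, gene_b=b, identity_pct=90, coverage_pct=95)


def _models(spec):
    return {
        gid: GeneModel(gid, chrom, "+", start, start + 1000)
        for gid, (chrom, start) in spec.items()
    }


def test_adjacent_same_chromosome_is_tandem():
    models = _models({"a": ("chr1", 0), "b": ("chr1", 50_000)})
    assert classify_duplication(_pair(), models, {"a", "b"}) == "tandem"


def test_different_chromosomes_is_segmental():
    models = _models({"a": ("chr1", 0), "b": ("chr5", 0)})
    assert classify_duplication(_pair(), models, {"a", "b"}) == "segmental"


def test_intervening_family_gene_blocks_tandem():
    models = _models({"a": ("chr1", 0), "b": ("chr1", 5_000_000), "c": ("chr1", 100_000)})
    assert classify_duplication(_pair(), models, {"a", "b", "c"}) == "unclassified"


def test_unplaced_gene_unclassified():
    models = _models({"a": ("N/A", 0), "b": ("chr1", 0)})
    assert classify_duplication(_pair(), models, {"a", "b"}) == "unclassified"


def test_tandem_never_returned_across_chromosomes():
    rng = np.random.default_rng(5)
    for _ in range(20):
        ca, cb = rng.choice([f"chr{i}" for i in range(1, 6)], 2, replace=False)
        models = _models({"a": (ca, int(rng.integers(1e6))), "b": (cb, int(rng.integers(1e6)))})
        assert classify_duplication(_pair(), models, {"a", "b"}) != "tandem"


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def test_identical_proteomes_pair_every_gene():
    rng = np.random.default_rng(9)
    prots = {f"g{i}": "".join(rng.choice(list(AAS), 120)) for i in range(5)}
    other = {f"h{i}": prots[f"g{i}"] for i in range(5)}
    pairs = reciprocal_best_hits(prots, other)
    assert {(p.gene_a, p.gene_b) for p in pairs} == {(f"g{i}", f"h{i}") for i in range(5)}


def test_non_reciprocal_hit_dropped():
    rng = np.random.default_rng(13)
    base = "".join(rng.choice(list(AAS), 150))
    # a1 is closest to b, but b is closer to a2: no pair involving a1
    a2 = _mutate(base, 3, np.random.default_rng(1))
    a1 = _mutate(a2, 8, np.random.default_rng(2))
    pairs = reciprocal_best_hits({"a1": a1, "a2": a2}, {"b": base})
    assert {(p.gene_a, p.gene_b) for p in pairs} == {("a2", "b")}


def test_random_unrelated_proteins_score_below_threshold():
    """The default score floor rejects unrelated random 300-mers."""
    from wrkyscan.evolution import DEFAULT_MIN_SCORE

    rng = np.random.default_rng(17)
    for _ in range(30):
        a = "".join(rng.choice(list(AAS), 300))
        b = "".join(rng.choice(list(AAS), 300))
        assert align_pair(a, b).score < DEFAULT_MIN_SCORE


def test_empty_proteome_is_an_error():
    with pytest.raises(ValueError):
        reciprocal_best_hits({}, {"b": "ACD"})


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

def test_identical_cds_zero_rates():
    cds = "ATGGCTGGT"
    ka, ks, ratio = kaks_nei_gojobori(cds, cds, ("MAG", "MAG"))
    assert ka == 0.0 and ks == 0.0
    assert ratio is None


def test_synonymous_third_position_change():
    # Phe TTT -> TTC: the single difference is synonymous
    ka, ks, _ = kaks_nei_gojobori("TTT", "TTC", ("F", "F"))
    assert ka == 0.0
    assert ks > 0.0


def test_site_counts_sum_to_three_per_codon():
    from Bio.Data.CodonTable import standard_dna_table

    for codon in standard_dna_table.forward_table:
        s, n = _codon_sites(codon)
        assert s + n == pytest.approx(3.0)
        assert 0.0 <= s <= 3.0


def test_kaks_symmetric_in_arguments():
    a = "ATGGCTAAAGGTTTC"
    b = "ATGGCAAAAGGATTT"
    pa = ("MAKGF", "MAKGF")
    ka1, ks1, _ = kaks_nei_gojobori(a, b, pa)
    ka2, ks2, _ = kaks_nei_gojobori(b, a, pa)
    assert ka1 == pytest.approx(ka2)
    assert ks1 == pytest.approx(ks2)
    assert ka1 >= 0 and ks1 >= 0


def test_internal_stop_is_an_error():
    with pytest.raises(ValueError, match="stop"):
        kaks_nei_gojobori("ATGTAAGGT", "ATGGCTGGT", ("M*G", "MAG"))


def test_length_mismatch_is_an_error():
    with pytest.raises(ValueError):
        kaks_nei_gojobori("ATGG", "ATGGCT", ("MA", "MA"))


def test_ambiguous_codon_skipped():
    ka, ks, _ = kaks_nei_gojobori("ATGNNNTTT", "ATGGCTTTC", ("MXF", "MAF"))
    # only codons 1 and 3 compared; the single synonymous change registers
    assert ka == 0.0
    assert ks > 0.0


def test_all_pairs_count(default_genome):
    g3 = [g.gene_id for g in default_genome.genes if g.group == "III"]
    res = all_pairs_kaks(
        {g: default_genome.cds[g] for g in g3},
        {g: default_genome.proteins[g] for g in g3},
    )
    k = len(g3)
    assert len(res) == k * (k - 1) // 2
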