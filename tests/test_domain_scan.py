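import pytest
from hypothesis import given, settings, strategies as st

from wrkyscan.domain_scan import (
    ScanConfig,
    find_heptapeptides,
    find_zinc_finger,
    scan_protein,
    search_accessory_motifs,
)
from wrkyscan.io_formats import ProteinRecord

BG = "AGSTPLMNQDE"  # no C/H/W: cannot fake fingers or heptapeptides


def prot(seq: str, pid: str = "p") -> ProteinRecord:
    return ProteinRecord(pid, seq)


def c2h2(x1: int = 4, x2: int = 22) -> str:
    return "C" + "A" * x1 + "C" + "A" * x2 + "H" + "A" + "H"


def c2hc() -> str:
    return "C" + "A" * 7 + "C" + "A" * 23 + "H" + "A" + "C"


# ---------------------------------------------------------------------------
# heptapeptides
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mer,expected",
    [
        ("WRKYGQK", "canonical"),
        ("WRKYGRK", "WRKYGRK"),
        ("WKKYGQK", "WKKYGQK"),
        ("WRKYGKK", "WRKYGKK"),
    ],
)
def test_heptapeptide_variants(mer, expected):
    hits = find_heptapeptides(prot("AAAA" + mer + "AAAA"))
    assert hits == [(4, mer, expected)]


def test_heptapeptide_three_mismatches_not_found():
    assert find_heptapeptides(prot("AAAWRKYAAAAAA"), max_mismatch=1) == []


def test_heptapeptide_one_off_variant_labelled():
    # WRKYGQE is one substitution from canonical but not in the variant set
    hits = find_heptapeptides(prot("AAWRKYGQEAA"))
    assert hits == [(2, "WRKYGQE", "other-1-mismatch")]


def test_heptapeptide_zero_mismatch_mode():
    assert find_heptapeptides(prot("AAWRKYGQEAA"), max_mismatch=0) == []


# ---------------------------------------------------------------------------
# zinc fingers
# ---------------------------------------------------------------------------

def test_c2h2_finger_found():
    seq = "A" * 10 + c2h2()
    ftype, pos = find_zinc_finger(prot(seq), 0)
    assert ftype == "C2H2"
    assert seq[pos[0]] == "C" and seq[pos[1]] == "C"
    assert seq[pos[2]] == "H" and seq[pos[3]] == "H"


def test_c2hc_finger_found():
    seq = "A" * 5 + c2hc()
    ftype, pos = find_zinc_finger(prot(seq), 0)
    assert ftype == "C2HC"
    assert seq[pos[3]] == "C"


@pytest.mark.parametrize("x1,x2", [(4, 21), (5, 19)])
def test_variant_c2h2_fingers(x1, x2):
    seq = c2h2(x1, x2)
    ftype, _ = find_zinc_finger(prot(seq), 0)
    assert ftype == "variant-C2H2"


def test_no_finger_in_polyalanine():
    assert find_zinc_finger(prot("A" * 120), 0) is None


def test_search_start_out_of_range():
    with pytest.raises(IndexError):
        find_zinc_finger(prot("AAAA"), 99)


def test_reported_finger_positions_hold_stated_residues(default_genome):
    # invariant checked across every planted protein of the default genome
    for gene in default_genome.genes[:30]:
        for dom in scan_protein(prot(gene.protein, gene.gene_id)):
            if not dom.complete:
                continue
            c1, c2, h3, h4 = dom.finger_positions
            assert gene.protein[c1] == "C" and gene.protein[c2] == "C"
            assert gene.protein[h3] == "H"
            assert gene.protein[h4] in "HC"


# ---------------------------------------------------------------------------
# scan_protein
# ---------------------------------------------------------------------------

def test_two_domain_protein_yields_two_domains():
    unit = "WRKYGQK" + "A" * 13 + c2h2()
    seq = "G" * 20 + unit + "G" * 90 + unit + "G" * 30
    doms = scan_protein(prot(seq))
    assert len(doms) == 2
    assert all(d.complete for d in doms)


def test_scrambled_finger_gives_incomplete_domain():
    seq = "G" * 20 + "WRKYGQK" + "G" * 60
    doms = scan_protein(prot(seq))
    assert len(doms) == 1
    assert not doms[0].complete
    assert doms[0].finger_type == "none"
    assert doms[0].domain_end == doms[0].hepta_start + 6


def test_one_heptapeptide_two_tandem_fingers_flagged():
    # a single-domain gene descended from a two-domain ancestor: one
    # heptapeptide followed by two consecutive finger motifs
    seq = "G" * 10 + "WRKYGRK" + "A" * 5 + c2h2() + "A" * 10 + c2h2() + "G" * 10
    doms = scan_protein(prot(seq))
    assert len(doms) == 1
    assert doms[0].n_fingers == 2


def test_scan_positions_shift_with_prefix():
    unit = "WRKYGQK" + "A" * 13 + c2h2()
    seq = "G" * 15 + unit + "G" * 20
    base = scan_protein(prot(seq))
    shifted = scan_protein(prot("T" * 11 + seq))
    assert len(base) == len(shifted) == 1
    assert shifted[0].hepta_start == base[0].hepta_start + 11
    assert shifted[0].finger_positions == tuple(p + 11 for p in base[0].finger_positions)


def test_planted_domains_recovered_exactly(default_genome):
    """The scanner recovers 100% of planted domains with exact variant labels."""
    cfg = ScanConfig()
    for gene in default_genome.genes:
        doms = scan_protein(prot(gene.protein, gene.gene_id), cfg)
        assert [d.hepta_start for d in doms] == gene.domain_starts
        if gene.variant != "canonical":
            assert doms[0].hepta_variant == gene.variant
        else:
            assert all(d.hepta_variant == "canonical" for d in doms)


# ---------------------------------------------------------------------------
# accessory motifs
# ---------------------------------------------------------------------------

def test_harf_motif():
    hits = search_accessory_motifs(prot("GGG" + "RTGHARFRRAP" + "GGG"))
    assert any(h.motif_name == "HARF" and h.start == 3 for h in hits)
    hits_g = search_accessory_motifs(prot("RTGHARFRRGP"))
    assert any(h.motif_name == "HARF" for h in hits_g)


def test_lxxll_motif():
    hits = search_accessory_motifs(prot("AAALKDLLAAA"))
    assert any(h.motif_name == "LXXLL" and h.matched_seq == "LKDLL" for h in hits)


def test_leucine_zipper_heptad():
    seq = "LAAAAAALAAAAAALAAAAAAL"  # leucines at 0,7,14,21
    hits = [h for h in search_accessory_motifs(prot(seq)) if h.motif_name == "LeuZipper"]
    assert hits and hits[0].start == 0


def test_leucine_zipper_brute_force_agreement():
    # brute force: check all start positions for 4 leucines spaced exactly 7
    seqs = [
        "LAAAAAALAAAAAALAAAAAAL",
        "ALAAAAAALAAAAAALAAAAAALA",
        "LAAAAAALAAAAAALAAAAAA",  # only 3 heptad leucines
        "L" * 22,
    ]
    for seq in seqs:
        expected = {
            i
            for i in range(len(seq) - 21)
            if all(seq[i + 7 * k] == "L" for k in range(4))
        }
        got = {
            h.start
            for h in search_accessory_motifs(ProteinRecord("p", seq))
            if h.motif_name == "LeuZipper"
        }
        assert got == expected


def test_motif_hit_matches_protein_substring():
    seq = "AAALKDLLAAARTGHARFRRAPGG"
    p = prot(seq)
    for h in search_accessory_motifs(p):
        assert seq[h.start : h.start + len(h.matched_seq)] == h.matched_seq


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.text(alphabet=BG, min_size=7, max_size=40))
def test_no_hits_in_background_alphabet(body):
    # sequences without W cannot contain a heptapeptide within one mismatch
    assert find_heptapeptides(ProteinRecord("p", body)) == []
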