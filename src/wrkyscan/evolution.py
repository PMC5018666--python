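"""Homology, duplication classes, orthology, and Ka/Ks.

Pairwise protein alignment is dynamic programming (BLOSUM62, affine gaps) via
Bio.Align.PairwiseAligner.  Duplicate pairs follow the family-survey rules:
alignment coverage >= 80% of the longer protein and identity >= 65%; tandem
duplicates are adjacent homologs on one chromosome, segmental duplicates sit
on different chromosomes.  Orthologs are reciprocal best hits above a score
threshold, with an extra N/C-domain concordance requirement for two-domain
(group I) genes.  Ka and Ks use the Nei–Gojobori (1986) counting method with
Jukes–Cantor correction; Ka/Ks < 0.5 flags purifying selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from math import log

from .io_formats import GeneModel

MIN_COVERAGE_PCT = 80.0
MIN_IDENTITY_PCT = 65.0
PURIFYING_THRESHOLD = 0.5
#: default reciprocal-best-hit score floor; unrelated random 300-mers score
#: far below this under global BLOSUM62/affine scoring (verified by simulation),
#: while genuine homologs (>=65% identity over >=100 residues) score several-fold higher
DEFAULT_MIN_SCORE = 150.0

_CODON_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)
_NTS = "ACGT"


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    coverage_pct: float
    mode: str


@dataclass
class HomologPair:
    gene_a: str
    gene_b: str
    identity_pct: float
    coverage_pct: float
    dup_class: str = "unclassified"
    ka: float | None = None
    ks: float | None = None
    ka_ks: float | None = None

    @property
    def purifying(self) -> bool:
        return self.ka_ks is not None and self.ka_ks < PURIFYING_THRESHOLD


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float
    concordant_domains: bool | None = None  # set for group-I pairs only


def _make_aligner(mode: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    if mode == "global-affine":
        aligner.mode = "global"
    elif mode == "local-affine":
        aligner.mode = "local"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return aligner


def align_pair(
    seq_a: str,
    seq_b: str,
    mode: str = "global-affine",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> PairwiseAlignment:
    """Optimal pairwise alignment.

    Identity counts exact matches over all alignment columns (gap columns
    included in the denominator); coverage is the number of columns where both
    sequences hold a residue, as a percentage of the longer sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = _make_aligner(mode, gap_open, gap_extend)
    aln = aligner.align(seq_a, seq_b)[0]
    ra, rb = str(aln[0]), str(aln[1])
    cols = len(ra)
    matches = sum(x == y and x != "-" for x, y in zip(ra, rb))
    both = sum(x != "-" and y != "-" for x, y in zip(ra, rb))
    return PairwiseAlignment(
        aligned_a=ra,
        aligned_b=rb,
        score=float(aln.score),
        identity_pct=100.0 * matches / cols if cols else 0.0,
        coverage_pct=100.0 * both / max(len(seq_a), len(seq_b)),
        mode=mode,
    )


def find_homolog_pairs(
    proteins: dict[str, str],
    min_coverage: float = MIN_COVERAGE_PCT,
    min_identity: float = MIN_IDENTITY_PCT,
) -> list[HomologPair]:
    """All unordered pairs meeting the coverage and identity thresholds."""
    ids = list(proteins)
    out: list[HomologPair] = []
    for a, b in combinations(ids, 2):
        aln = align_pair(proteins[a], proteins[b])
        if aln.coverage_pct >= min_coverage and aln.identity_pct >= min_identity:
            out.append(
                HomologPair(
                    gene_a=a, gene_b=b,
                    identity_pct=aln.identity_pct,
                    coverage_pct=aln.coverage_pct,
                )
            )
    return out


def classify_duplication(
    pair: HomologPair,
    gene_models: dict[str, GeneModel],
    family_gene_ids: set[str],
    tandem_window_bp: int = 200_000,
    nonadjacent_same_chrom: str = "unclassified",
) -> str:
    """Tandem vs segmental duplication.

    Tandem: same chromosome, no other family gene between the two, and
    start-to-start gap <= the tandem window.  Segmental: different
    chromosomes.  Same-chromosome non-adjacent pairs default to unclassified
    (configurable to "segmental").  Pairs with an unplaced gene are
    unclassified.
    """
    ga, gb = gene_models[pair.gene_a], gene_models[pair.gene_b]
    if not (ga.placed and gb.placed):
        return "unclassified"
    if ga.chromosome != gb.chromosome:
        return "segmental"
    lo, hi = sorted((ga.start, gb.start))
    between = any(
        gid not in (pair.gene_a, pair.gene_b)
        and gene_models[gid].chromosome == ga.chromosome
        and lo < gene_models[gid].start < hi
        for gid in family_gene_ids
        if gid in gene_models
    )
    if not between and hi - lo <= tandem_window_bp:
        return "tandem"
    return nonadjacent_same_chrom


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def _best_hits(
    queries: dict[str, str], targets: dict[str, str], mode: str
) -> dict[str, tuple[str, float]]:
    out: dict[str, tuple[str, float]] = {}
    for q, qseq in queries.items():
        best, best_score = None, None
        for t, tseq in targets.items():
            s = align_pair(qseq, tseq, mode=mode).score
            if best_score is None or s > best_score:
                best, best_score = t, s
        out[q] = (best, best_score)
    return out


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    min_score: float = DEFAULT_MIN_SCORE,
    mode: str = "global-affine",
    group1_domains_a: dict[str, dict[str, str]] | None = None,
    group1_domains_b: dict[str, dict[str, str]] | None = None,
) -> list[OrthologPair]:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    A pair (a, b) is kept iff b is a's best-scoring hit, a is b's, and the
    score reaches ``min_score``.  When both genes carry two WRKY domains
    (group I) and domain sequences are supplied as ``{gene: {"N": .., "C": ..}}``,
    the N- and C-terminal domains must each independently pick the same
    partner gene; discordant pairs are dropped.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    ab = _best_hits(proteome_a, proteome_b, mode)
    ba = _best_hits(proteome_b, proteome_a, mode)
    pairs: list[OrthologPair] = []
    for a, (b, score) in ab.items():
        if b is None or score < min_score:
            continue
        back, _ = ba[b]
        if back != a:
            continue
        concordant: bool | None = None
        if (
            group1_domains_a
            and group1_domains_b
            and a in group1_domains_a
            and b in group1_domains_b
        ):
            concordant = _domains_concordant(
                a, b, group1_domains_a, group1_domains_b, mode
            )
            if not concordant:
                continue
        pairs.append(OrthologPair(gene_a=a, gene_b=b, score=score, concordant_domains=concordant))
    return pairs


def _domains_concordant(
    a: str,
    b: str,
    doms_a: dict[str, dict[str, str]],
    doms_b: dict[str, dict[str, str]],
    mode: str,
) -> bool:
    for label in ("N", "C"):
        if label not in doms_a[a]:
            return False
        best, best_score = None, None
        for gb, d in doms_b.items():
            if label not in d:
                continue
            s = align_pair(doms_a[a][label], d[label], mode=mode).score
            if best_score is None or s > best_score:
                best, best_score = gb, s
        if best != b:
            return False
    return True


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks
# ---------------------------------------------------------------------------

def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; they sum to 3 exactly.

    Each position contributes 1/3 per possible nucleotide change that is
    synonymous; changes creating a stop codon count as nonsynonymous.
    """
    aa = _CODON_AA[codon]
    syn = 0.0
    for pos in range(3):
        for nt in _NTS:
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in _STOPS and _CODON_AA[mut] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _path_steps(c1: str, c2: str, allow_stops: bool) -> list[tuple[float, float]]:
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results: list[tuple[float, float]] = []
    for order in permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS and not allow_stops:
                ok = False
                break
            if (
                cur not in _STOPS
                and nxt not in _STOPS
                and _CODON_AA[cur] == _CODON_AA[nxt]
            ):
                sd += 1
            else:  # amino-acid change, or a step into/out of a stop codon
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    return results


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts."""
    if c1 == c2:
        return 0.0, 0.0
    paths = _path_steps(c1, c2, allow_stops=False)
    if not paths:  # every pathway passes through a stop codon
        paths = _path_steps(c1, c2, allow_stops=True)
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    """Jukes–Cantor multiple-hit correction of a difference proportion.

    At or beyond saturation (p >= 3/4, reachable only on degenerate inputs of
    a few codons) the correction is undefined and the raw proportion is
    returned instead.
    """
    if p == 0.0:
        return 0.0
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0:
        return p
    return -0.75 * log(x)


def _validate_cds(cds: str, name: str) -> None:
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length not divisible by 3")
    for i in range(0, len(cds) - 3, 3):
        if cds[i : i + 3] in _STOPS:
            raise ValueError(f"{name}: internal stop codon at nt {i}")


def kaks_nei_gojobori(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str],
) -> tuple[float, float, float | None]:
    """Nei–Gojobori Ka and Ks from two CDS and their protein alignment.

    The protein alignment is back-translated to a codon alignment; codon
    pairs with a gap or an ambiguous base are skipped.  Returns
    (ka, ks, ka_ks); ka_ks is None when ks = 0.
    """
    cds_a, cds_b = cds_a.upper(), cds_b.upper()
    _validate_cds(cds_a, "cds_a")
    _validate_cds(cds_b, "cds_b")
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("protein alignment rows differ in length")
    # trailing stop codons, if present, are ignored
    na = len(row_a.replace("-", ""))
    nb = len(row_b.replace("-", ""))
    if len(cds_a) not in (3 * na, 3 * na + 3) or len(cds_b) not in (3 * nb, 3 * nb + 3):
        raise ValueError("CDS length does not match protein alignment row")

    ia = ib = 0
    S = N = Sd = Nd = 0.0
    for aa_a, aa_b in zip(row_a, row_b):
        ca = cds_a[3 * ia : 3 * ia + 3] if aa_a != "-" else None
        cb = cds_b[3 * ib : 3 * ib + 3] if aa_b != "-" else None
        if aa_a != "-":
            ia += 1
        if aa_b != "-":
            ib += 1
        if ca is None or cb is None:
            continue
        if set(ca) - set(_NTS) or set(cb) - set(_NTS):
            continue  # ambiguous codon: skip the pair's codon
        sa, nna = _codon_sites(ca)
        sb, nnb = _codon_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (nna + nnb)
        sd, nd = _codon_differences(ca, cb)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    ks = _jukes_cantor(Sd / S)
    ka = _jukes_cantor(Nd / N)
    ka_ks = (ka / ks) if ks > 0 else None
    return ka, ks, ka_ks


def all_pairs_kaks(
    cds: dict[str, str], proteins: dict[str, str]
) -> list[HomologPair]:
    """Ka/Ks over every unordered pair of the given genes (k genes ->
    k(k-1)/2 pairs), aligning proteins globally and back-translating."""
    out: list[HomologPair] = []
    for a, b in combinations(sorted(cds), 2):
        aln = align_pair(proteins[a], proteins[b])
        ka, ks, ratio = kaks_nei_gojobori(cds[a], cds[b], (aln.aligned_a, aln.aligned_b))
        out.append(
            HomologPair(
                gene_a=a, gene_b=b,
                identity_pct=aln.identity_pct,
                coverage_pct=aln.coverage_pct,
                ka=ka, ks=ks, ka_ks=ratio,
            )
        )
    return out
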