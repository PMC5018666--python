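"""Pattern-based detection of WRKY domains and accessory motifs.

A WRKY domain is a ~60-residue DNA-binding unit: the heptapeptide WRKYGQK
(or a near variant) at its N side followed, within a configurable window, by
a spacing-constrained zinc finger.  Finger patterns, in search priority:

* C2H2          C-X(4,5)-C-X(22,23)-H-X-H
* C2HC          C-X(7)-C-X(23)-H-X-C          (the group III signature)
* variant C2H2  C-X(4)-C-X(21)-H-X-H  or  C-X(5)-C-X(19)-H-X-H

Domains whose finger cannot be located are retained as incomplete: family
surveys keep such proteins in all downstream analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .io_formats import ProteinRecord

CANONICAL_HEPTAPEPTIDE = "WRKYGQK"
DEFAULT_VARIANTS = frozenset(
    {"WRKYGQK", "WRKYGRK", "WKKYGQK", "WRKYGKK", "WRKYGEK"}
)
DEFAULT_FINGER_WINDOW = 80

# (finger_type, compiled regex with lazy spacers -> leftmost-then-shortest match;
#  the second C is captured so spacer cysteines cannot confuse position reporting)
_FINGER_PATTERNS: list[tuple[str, re.Pattern]] = [
    ("C2H2", re.compile(r"C.{4,5}?(C).{22,23}?H.H")),
    ("C2HC", re.compile(r"C.{7}(C).{23}H.C")),
    ("variant-C2H2", re.compile(r"C.{4}(C).{21}H.H")),
    ("variant-C2H2", re.compile(r"C.{5}(C).{19}H.H")),
]


@dataclass
class WRKYDomain:
    protein_id: str
    hepta_start: int
    hepta_seq: str
    hepta_variant: str
    finger_type: str = "none"
    finger_positions: tuple[int, int, int, int] | None = None
    domain_start: int = 0
    domain_end: int = 0
    complete: bool = False
    n_fingers: int = 0


@dataclass
class MotifHit:
    protein_id: str
    motif_name: str
    start: int
    matched_seq: str


@dataclass
class ScanConfig:
    allowed_variants: frozenset[str] = DEFAULT_VARIANTS
    max_mismatch: int = 1
    finger_window: int = DEFAULT_FINGER_WINDOW


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_heptapeptides(
    protein: ProteinRecord,
    allowed_variants: frozenset[str] = DEFAULT_VARIANTS,
    max_mismatch: int = 1,
) -> list[tuple[int, str, str]]:
    """Locate heptapeptide cores, left to right, non-overlapping.

    Returns (position, 7-mer, variant) triples.  A 7-mer in
    ``allowed_variants`` is labelled by its own string ("canonical" for
    WRKYGQK); otherwise, with ``max_mismatch=1``, any 7-mer one substitution
    away from WRKYGQK is labelled ``other-1-mismatch``.
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    seq = protein.sequence
    hits: list[tuple[int, str, str]] = []
    i = 0
    while i <= len(seq) - 7:
        mer = seq[i : i + 7]
        variant = None
        if mer in allowed_variants:
            variant = "canonical" if mer == CANONICAL_HEPTAPEPTIDE else mer
        elif max_mismatch >= 1 and _hamming(mer, CANONICAL_HEPTAPEPTIDE) <= 1:
            variant = "other-1-mismatch"
        if variant is not None:
            hits.append((i, mer, variant))
            i += 7
        else:
            i += 1
    return hits


def find_zinc_finger(
    protein: ProteinRecord, search_start: int, window: int = DEFAULT_FINGER_WINDOW
) -> tuple[str, tuple[int, int, int, int]] | None:
    """Find the first zinc finger within ``window`` residues of ``search_start``.

    Patterns are tried in priority order (C2H2, C2HC, variant C2H2); within a
    pattern the leftmost and then shortest-spacer match wins.  Returns the
    finger type and the absolute indices of (C1, C2, H/C3, H/C4), or None.
    """
    seq = protein.sequence
    if not 0 <= search_start <= len(seq):
        raise IndexError(f"search_start {search_start} out of range")
    region = seq[search_start : search_start + window]
    for ftype, pat in _FINGER_PATTERNS:
        m = pat.search(region)
        if m:
            s = search_start + m.start()
            e = search_start + m.end()
            positions = (s, search_start + m.start(1), e - 3, e - 1)
            return ftype, positions
    return None


def scan_protein(protein: ProteinRecord, config: ScanConfig | None = None) -> list[WRKYDomain]:
    """Detect all WRKY domains in a protein.

    One domain per heptapeptide hit; incomplete domains (no locatable finger)
    are retained.  When a second finger pattern follows the first within the
    window (single-domain proteins descended from two-domain ancestors carry
    one heptapeptide but two fingers), ``n_fingers`` counts both.
    """
    cfg = config or ScanConfig()
    domains: list[WRKYDomain] = []
    for pos, mer, variant in find_heptapeptides(
        protein, cfg.allowed_variants, cfg.max_mismatch
    ):
        dom = WRKYDomain(
            protein_id=protein.id,
            hepta_start=pos,
            hepta_seq=mer,
            hepta_variant=variant,
            domain_start=pos,
            domain_end=pos + 6,
        )
        hit = find_zinc_finger(protein, pos + 7, cfg.finger_window)
        if hit is not None:
            ftype, fpos = hit
            dom.finger_type = ftype
            dom.finger_positions = fpos
            dom.domain_end = fpos[3]
            dom.complete = True
            dom.n_fingers = 1
            # look for a tandem second finger right after the first
            nxt = fpos[3] + 1
            if nxt < len(protein.sequence):
                second = find_zinc_finger(protein, nxt, cfg.finger_window)
                if second is not None:
                    dom.n_fingers = 2
                    dom.domain_end = second[1][3]
        domains.append(dom)
    return domains


# ---------------------------------------------------------------------------
# hand-curated accessory motifs
# ---------------------------------------------------------------------------

_HARF = re.compile(r"RTGHARFRR[AG]P")
_LXXLL = re.compile(r"L..LL")
_LXLXLX = re.compile(r"L.L.L.")


def _overlapping(pattern: re.Pattern, seq: str):
    i = 0
    while True:
        m = pattern.search(seq, i)
        if m is None:
            return
        yield m
        i = m.start() + 1


def search_accessory_motifs(
    protein: ProteinRecord, leucine_heptads: int = 4
) -> list[MotifHit]:
    """Scan for HARF, LXXLL, LXLXLX and heptad-repeat leucine zippers.

    The leucine zipper rule: at least ``leucine_heptads`` leucines spaced
    exactly 7 residues apart.
    """
    seq = protein.sequence
    hits: list[MotifHit] = []
    for name, pat in (("HARF", _HARF), ("LXXLL", _LXXLL), ("LXLXLX", _LXLXLX)):
        for m in _overlapping(pat, seq):
            hits.append(MotifHit(protein.id, name, m.start(), m.group(0)))
    span = 7 * (leucine_heptads - 1)
    for i in range(len(seq) - span):
        if all(seq[i + 7 * k] == "L" for k in range(leucine_heptads)):
            hits.append(MotifHit(protein.id, "LeuZipper", i, seq[i : i + span + 1]))
    return hits
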