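"""Physicochemical and gene-structure characteristics.

Molecular weight uses average residue masses (sum of residue masses plus one
water); the isoelectric point is the root of the Henderson–Hasselbalch net
charge over the termini and the ionizable side chains (D, E, C, Y, H, K, R),
found by bisection with the Bjellqvist pKa set.  Introns are mapped from CDS
coordinates to the residue they interrupt and typed R or V when they fall at
the conserved positions flanking the zinc finger of a complete WRKY domain.
"""

from __future__ import annotations

from dataclasses import dataclass

from .domain_scan import WRKYDomain
from .io_formats import GeneModel, ProteinRecord

WATER = 18.01524

#: average (isotope-weighted) residue masses, Da
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
#: unknown residue X contributes the unweighted mean of the 20 standard masses
RESIDUE_MASS["X"] = sum(v for k, v in RESIDUE_MASS.items()) / 20

#: Bjellqvist pKa values (ExPASy "compute pI" lineage): generic termini +
#: ionizable side chains.  Positive groups: N-terminus, H, K, R.
PKA = {
    "Nterm": 7.5, "Cterm": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    "H": 5.98, "K": 10.0, "R": 12.0,
}


@dataclass
class ProteinProperties:
    length_aa: int
    mw_da: float
    pi: float

    @property
    def mw_kda(self) -> float:
        """MW in kDa at the 0.1 precision family tables print."""
        return round(self.mw_da / 1000.0, 1)


@dataclass
class IntronAnnotation:
    gene_id: str
    intron_index: int
    phase: int
    protein_position: int
    splice_type: str  # R-type | V-type | untyped


def molecular_weight(sequence: str) -> float:
    """Average molecular weight of a peptide, in daltons."""
    if not sequence:
        raise ValueError("empty sequence")
    try:
        return sum(RESIDUE_MASS[aa] for aa in sequence) + WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc


def net_charge(sequence: str, ph: float) -> float:
    """Net charge at a given pH (Henderson–Hasselbalch, Bjellqvist pKa)."""
    pos = 1.0 / (1.0 + 10 ** (ph - PKA["Nterm"]))
    for aa in "HKR":
        pos += sequence.count(aa) / (1.0 + 10 ** (ph - PKA[aa]))
    neg = 1.0 / (1.0 + 10 ** (PKA["Cterm"] - ph))
    for aa in "DECY":
        neg += sequence.count(aa) / (1.0 + 10 ** (PKA[aa] - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-3) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14].

    The charge curve is strictly decreasing in pH, so the root is unique.
    Reported at 2-decimal precision by callers; the bisection itself stops at
    ``tol``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def protein_properties(protein: ProteinRecord) -> ProteinProperties:
    seq = protein.sequence
    return ProteinProperties(
        length_aa=len(seq),
        mw_da=molecular_weight(seq),
        pi=round(isoelectric_point(seq), 2),
    )


# ---------------------------------------------------------------------------
# introns
# ---------------------------------------------------------------------------

#: residues of tolerance around the canonical R / V splice offsets
RV_TOLERANCE = 2


def annotate_introns(
    gene: GeneModel,
    protein: ProteinRecord,
    domains: list[WRKYDomain],
    tolerance: int = RV_TOLERANCE,
) -> list[IntronAnnotation]:
    """Map each intron to the residue it interrupts and type it.

    R-type: the splice point sits at an R residue about five residues before
    the first finger cysteine (window C1-5 +/- tolerance).  V-type: the splice
    point immediately precedes a V residue six residues after the second
    finger cysteine (window C2+6 +/- tolerance).  Anything else is untyped;
    typing requires a complete domain.
    """
    cds_len = gene.cds_length
    plen = len(protein.sequence)
    if cds_len not in (3 * plen, 3 * plen + 3):
        raise ValueError(
            f"gene {gene.gene_id!r}: CDS length {cds_len} does not match "
            f"protein length {plen} (stop codon excluded)"
        )
    fingers = [d.finger_positions for d in domains if d.complete and d.finger_positions]
    out: list[IntronAnnotation] = []
    offset = 0
    for idx, (s, e, _ph) in enumerate(gene.cds_segments[:-1]):
        offset += e - s
        phase = offset % 3
        residue = offset // 3
        stype = "untyped"
        aa = protein.sequence[residue] if residue < plen else ""
        for c1, c2, _h3, _h4 in fingers:
            if aa == "R" and abs(residue - (c1 - 5)) <= tolerance:
                stype = "R-type"
                break
            if aa == "V" and abs(residue - (c2 + 6)) <= tolerance:
                stype = "V-type"
                break
        out.append(
            IntronAnnotation(
                gene_id=gene.gene_id,
                intron_index=idx,
                phase=phase,
                protein_position=residue,
                splice_type=stype,
            )
        )
    return out
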