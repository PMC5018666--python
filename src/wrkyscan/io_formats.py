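"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every genomic interval is 0-based, half-open.  GFF3 is 1-based,
inclusive; the conversion happens here and only here.  ``GeneModel.cds_segments``
are kept in *transcription* order (reversed file order for minus-strand genes),
so downstream intron/phase arithmetic never needs to look at the strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
#: permissive load alphabet: the 20 standard residues plus X (unknown) and * (stop)
PROTEIN_ALPHABET = AMINO_ACIDS | {"X"}

#: sentinel chromosome for genes that could not be placed on any chromosome
UNPLACED = "N/A"

GROUP_LABELS = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ProteinRecord:
    id: str
    sequence: str
    source_gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ParseError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)!r}"
            )
        if not self.source_gene_id:
            self.source_gene_id = self.id

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.sequence)


@dataclass
class GeneModel:
    """A single gene model (one mRNA) with CDS segments in transcription order."""

    gene_id: str
    chromosome: str
    strand: str
    start: int  # 0-based
    end: int    # half-open
    cds_segments: list[tuple[int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ParseError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if self.end < self.start:
            raise ParseError(f"gene {self.gene_id!r}: end < start")
        genomic = sorted((s, e) for s, e, _ in self.cds_segments)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ParseError(f"gene {self.gene_id!r}: overlapping CDS segments")
        for s, e, phase in self.cds_segments:
            if phase not in (0, 1, 2):
                raise ParseError(f"gene {self.gene_id!r}: phase {phase!r} not in 0/1/2")

    @property
    def exon_count(self) -> int:
        return len(self.cds_segments)

    @property
    def intron_count(self) -> int:
        return max(0, len(self.cds_segments) - 1)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e, _ in self.cds_segments)

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass
class FamilyTableRow:
    gene_name: str
    sequence_id: str
    chromosome: str
    group: str
    at_orthologs: list[str]
    pt_orthologs: list[str]
    length_aa: int
    pi: float
    mw_kda: float
    introns: int

    def __post_init__(self) -> None:
        # "II" is tolerated for pipeline runs without a subgroup reference
        # panel; curated tables always carry the full seven-value label set
        if self.group not in GROUP_LABELS and self.group != "II":
            raise ParseError(
                f"row {self.gene_name!r}: group {self.group!r} not one of {GROUP_LABELS}"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects, in file order.

    Sequences are uppercased and a single terminal stop (``*``) is stripped.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except ParseError as exc:
            raise ParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide CDS FASTA as an id -> sequence mapping (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    return out


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r"(\w+)=([^;]+)")


def _parse_attrs(col: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(col))


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from a GFF3 file into :class:`GeneModel`.

    One model per gene: if a gene carries several mRNAs, the one with the
    longest total CDS is kept.  CDS coordinates are converted to 0-based
    half-open and re-ordered into transcription order for minus-strand genes.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_cds: dict[str, list[tuple[int, int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start, end, _score, strand, phase, attrs = cols
            a = _parse_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = dict(
                    chromosome=seqid, strand=strand, start=int(start) - 1, end=int(end)
                )
            elif ftype == "mRNA":
                mid, parent = a.get("ID"), a.get("Parent")
                if mid is None or parent is None:
                    raise ParseError(f"{path}:{lineno}: mRNA needs ID and Parent")
                mrna_parent[mid] = parent
                mrna_cds.setdefault(mid, [])
            elif ftype == "CDS":
                parent = a.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}:{lineno}: CDS without Parent")
                ph = 0 if phase == "." else int(phase)
                mrna_cds.setdefault(parent, []).append((int(start) - 1, int(end), ph))

    # CDS may be attached directly to a gene (no mRNA level)
    models: list[GeneModel] = []
    for mid in mrna_cds:
        if mid not in mrna_parent and mid not in genes:
            raise ParseError(f"{path}: CDS parent {mid!r} matches no gene or mRNA")

    by_gene: dict[str, list[list[tuple[int, int, int]]]] = {}
    for mid, segs in mrna_cds.items():
        gid = mrna_parent.get(mid, mid)
        if gid not in genes:
            raise ParseError(f"{path}: mRNA {mid!r} has unknown parent gene {gid!r}")
        if segs:
            by_gene.setdefault(gid, []).append(segs)

    for gid, info in genes.items():
        variants = by_gene.get(gid, [])
        if not variants:
            continue
        segs = max(variants, key=lambda v: sum(e - s for s, e, _ in v))
        segs = sorted(segs)
        if info["strand"] == "-":
            segs = segs[::-1]  # transcription order
        models.append(
            GeneModel(
                gene_id=gid,
                chromosome=info["chromosome"],
                strand=info["strand"],
                start=info["start"],
                end=info["end"],
                cds_segments=segs,
            )
        )
    return models


# ---------------------------------------------------------------------------
# Family characterization table (fixture format)
# ---------------------------------------------------------------------------

_EMPTY_CELL = {"–", "-", ""}

_TABLE_COLUMNS = [
    "gene", "sequence_id", "chromosome", "group",
    "at_orthologs", "pt_orthologs", "length_aa", "pi", "mw_kda", "introns",
]


def _split_orthologs(cell: str) -> list[str]:
    cell = cell.strip()
    if cell in _EMPTY_CELL:
        return []
    return [tok.strip() for tok in re.split(r"[,/]", cell) if tok.strip()]


def load_family_table(path: str | Path | None = None) -> list[FamilyTableRow]:
    """Load a family characterization table (TSV).

    With no argument, loads the packaged 85-gene willow WRKY table.  Empty
    ortholog cells ("–") parse to empty lists; multi-ortholog cells split on
    both "," and "/".
    """
    if path is None:
        ref = resources.files("wrkyscan.data") / "family_table.tsv"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header != _TABLE_COLUMNS:
        raise ParseError(f"family table: unexpected header {header!r}")
    rows: list[FamilyTableRow] = []
    for lineno, line in enumerate(lines[1:], 2):
        cols = line.split("\t")
        if len(cols) != len(_TABLE_COLUMNS):
            raise ParseError(
                f"family table line {lineno}: expected {len(_TABLE_COLUMNS)} columns, "
                f"got {len(cols)}"
            )
        rows.append(
            FamilyTableRow(
                gene_name=cols[0],
                sequence_id=cols[1],
                chromosome=cols[2],
                group=cols[3],
                at_orthologs=_split_orthologs(cols[4]),
                pt_orthologs=_split_orthologs(cols[5]),
                length_aa=int(cols[6].replace(",", "")),
                pi=float(cols[7]),
                mw_kda=float(cols[8]),
                introns=int(cols[9]),
            )
        )
    return rows
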