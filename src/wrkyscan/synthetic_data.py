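"""Synthetic genomes with planted WRKY-family structure.

The generator emits a complete, internally consistent mini-genome — protein
FASTA, CDS FASTA, GFF3 gene models, a per-tissue count table — plus a ground
truth manifest, so every pipeline stage can be scored against known answers
without downloading anything.

Defaults mirror the architecture of a sequenced willow-sized WRKY family:
85 genes over 19 chromosomes (group I 19, IIa 4, IIb 8, IIc 23, IId 13,
IIe 11, III 7, one gene unplaced), four heptapeptide-variant genes, 11 gene
clusters totalling 23 genes, 33 segmental duplicate pairs, group III genes
with exactly two introns, V-type domain introns only in IIa/IIb and R-type
in the other intron-bearing classes.

Background (non-domain) residues are drawn from an alphabet without C, H or
W, so planted zinc fingers and heptapeptides are the only ones the scanner
can find; mutations applied when building duplicates and ortholog genomes
avoid the structural residues (heptapeptide, finger, splice-site R/V).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .domain_scan import CANONICAL_HEPTAPEPTIDE
from .io_formats import ProteinRecord, write_fasta

#: background alphabet: no C/H (would fake zinc fingers), no W (heptapeptides)
BG_ALPHABET = "ADEFGIKLMNPQRSTVY"

GROUP_LABELS_ORDER = ("I", "IIa", "IIb", "IIc", "IId", "IIe", "III")

#: synonymous codon lists for reverse translation
_CODONS: dict[str, list[str]] = {}
from Bio.Data.CodonTable import standard_dna_table as _tbl

for _codon, _aa in _tbl.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


# ---------------------------------------------------------------------------
# domain templates
# ---------------------------------------------------------------------------

# layout of a planted domain, relative to the heptapeptide start:
#   hepta [0:7], linker [7:20] with R at 15 (= C1 - 5), finger from 20.
# C2H2:  C(20) x4 C(25) x22 H(48) x H(50)  -> length 51, V planted at 31 (= C2 + 6)
# C2HC:  C(20) x7 C(28) x23 H(52) x C(54)  -> length 55
_R_OFFSET = 15
_C1_OFFSET = 20
_V_OFFSET = 31
C2H2_LEN = 51
C2HC_LEN = 55

#: template classes -> finger type; group I genes use I-N + I-C
TEMPLATE_CLASSES = ("I-N", "I-C", "IIa", "IIb", "IIc", "IId", "IIe", "III")


def _make_template(rng: np.random.Generator, finger: str) -> str:
    length = C2HC_LEN if finger == "C2HC" else C2H2_LEN
    chars = list(rng.choice(list(BG_ALPHABET), size=length))
    chars[0:7] = list(CANONICAL_HEPTAPEPTIDE)
    chars[_R_OFFSET] = "R"
    if finger == "C2HC":
        chars[20], chars[28], chars[52], chars[54] = "C", "C", "H", "C"
    else:
        chars[20], chars[25], chars[48], chars[50] = "C", "C", "H", "H"
        chars[_V_OFFSET] = "V"
    return "".join(chars)


def _template_divergence(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x != y for x, y in zip(a[:n], b[:n])) / n


def make_templates(
    template_seed: int = 424242, min_divergence: float = 0.2
) -> dict[str, str]:
    """Fixed per-class domain templates with a pairwise-divergence guard."""
    rng = np.random.default_rng(template_seed)
    out: dict[str, str] = {}
    for cls in TEMPLATE_CLASSES:
        out[cls] = _make_template(rng, "C2HC" if cls == "III" else "C2H2")
    labels = list(out)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if _template_divergence(out[a], out[b]) < min_divergence:
                raise ValueError(
                    f"templates {a}/{b} diverge by less than {min_divergence:.0%}: "
                    "panel would be unlearnable"
                )
    return out


TEMPLATES = make_templates()

#: structural (mutation-protected) offsets within a template
def _protected_offsets(cls: str) -> set[int]:
    out = set(range(7)) | {_R_OFFSET}
    if cls == "III":
        out |= {20, 28, 52, 53, 54}
    else:
        out |= {20, 25, 48, 49, 50, _V_OFFSET}
    return out


# ---------------------------------------------------------------------------
# configuration and manifest
# ---------------------------------------------------------------------------

def _default_group_counts() -> dict[str, int]:
    return {"I": 19, "IIa": 4, "IIb": 8, "IIc": 23, "IId": 13, "IIe": 11, "III": 7}


def _default_variant_plan() -> dict[str, int]:
    # four variant genes out of 85: two WRKYGKK, one WKKYGQK, one WRKYGRK
    return {"WRKYGKK": 2, "WKKYGQK": 1, "WRKYGRK": 1}


def _default_cluster_plan() -> list[tuple[str, int]]:
    # 11 clusters, 23 genes: 3 on chr2, 2 each on chr6 and chr14, 1 each on
    # chr3, chr8, chr10, chr18
    return [
        ("chr2", 3), ("chr2", 2), ("chr2", 2),
        ("chr6", 2), ("chr6", 2),
        ("chr14", 2), ("chr14", 2),
        ("chr3", 2), ("chr8", 2), ("chr10", 2), ("chr18", 2),
    ]


def _default_segmental_plan() -> dict[str, int]:
    # 33 disjoint duplicate pairs (66 genes): I 7, IIa 2, IIb 4, IIc 9,
    # IId 6, IIe 2, III 3
    return {"I": 7, "IIa": 2, "IIb": 4, "IIc": 9, "IId": 6, "IIe": 2, "III": 3}


def _default_expression_means() -> dict[str, float]:
    return {"root": 40.0, "stem": 25.0, "bark": 45.0, "bud": 35.0, "leaf": 15.0}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_chromosomes: int = 19
    chromosome_length_bp: int = 12_000_000
    group_counts: dict[str, int] = field(default_factory=_default_group_counts)
    variant_plan: dict[str, int] = field(default_factory=_default_variant_plan)
    n_unplaced: int = 1
    cluster_plan: list[tuple[str, int]] = field(default_factory=_default_cluster_plan)
    cluster_gap_bp: int = 60_000          # start-to-start gap inside planted clusters
    intercluster_gap_bp: int = 400_000    # minimum gap between placement units
    segmental_pairs: dict[str, int] = field(default_factory=_default_segmental_plan)
    tandem_pairs: dict[str, int] = field(default_factory=dict)
    tandem_gap_bp: int = 50_000
    duplicate_identity_pct: float = 80.0
    ortholog_mutation_rate: float = 0.05
    tissues: tuple[str, ...] = ("root", "stem", "bark", "bud", "leaf")
    expression_means: dict[str, float] = field(default_factory=_default_expression_means)
    expression_dispersion: float = 0.8
    min_template_divergence: float = 0.2
    #: per-gene mutation rate away from the class template at non-structural
    #: domain positions, giving every gene an individually recognizable domain
    domain_individuality_rate: float = 0.10
    panel_exemplars: int = 3
    panel_noise_rate: float = 0.04


@dataclass
class PlantedGene:
    gene_id: str
    group: str                       # I / IIa..IIe / III
    variant: str                     # heptapeptide variant string or "canonical"
    protein: str
    cds: str                         # includes the stop codon
    domain_starts: list[int]         # protein offsets of each planted domain
    domain_classes: list[str]        # template class of each domain
    intron_offsets: list[int]        # CDS-coordinate intron positions
    intron_types: list[str]          # R-type / V-type / untyped
    chromosome: str = ""
    strand: str = "+"
    start: int = 0                   # 0-based genomic
    end: int = 0
    cluster_id: str = ""
    duplicate_of: str = ""
    dup_class: str = ""


@dataclass
class GroundTruthManifest:
    genes: pd.DataFrame              # one row per gene with all planted truth
    duplicate_pairs: pd.DataFrame    # gene_a, gene_b, dup_class, target identity
    clusters: dict[str, list[str]]   # cluster_id -> member gene ids
    ortholog_map: dict[str, str]     # genome A id -> genome B id
    counts: pd.DataFrame             # genes x tissues


class SyntheticGenome:
    """In-memory result of :func:`generate_genome`, with file export."""

    def __init__(
        self,
        config: GeneratorConfig,
        genes: list[PlantedGene],
        manifest: GroundTruthManifest,
        ortholog_proteins: dict[str, str],
        ortholog_cds: dict[str, str],
    ):
        self.config = config
        self.genes = genes
        self.manifest = manifest
        self.ortholog_proteins = ortholog_proteins
        self.ortholog_cds = ortholog_cds

    @property
    def proteins(self) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes}

    @property
    def cds(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes}

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "proteins": outdir / "proteins.fasta",
            "cds": outdir / "cds.fasta",
            "gff3": outdir / "genes.gff3",
            "counts": outdir / "counts.tsv",
            "manifest": outdir / "manifest_genes.tsv",
            "ortholog_proteins": outdir / "ortholog_proteins.fasta",
        }
        write_fasta(
            [ProteinRecord(g.gene_id, g.protein) for g in self.genes],
            paths["proteins"],
        )
        with open(paths["cds"], "w") as fh:
            for g in self.genes:
                fh.write(f">{g.gene_id}\n{g.cds}\n")
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write(_gene_gff3(g))
        self.manifest.counts.to_csv(paths["counts"], sep="\t")
        self.manifest.genes.to_csv(paths["manifest"], sep="\t", index=False)
        write_fasta(
            [ProteinRecord(k, v) for k, v in self.ortholog_proteins.items()],
            paths["ortholog_proteins"],
        )
        return paths


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons) + "TAA"


def _bg(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BG_ALPHABET), size=n))


def _individualize(
    template: str, cls: str, rate: float, rng: np.random.Generator
) -> str:
    """Mutate non-structural template positions so each gene's domain is its
    own recognizable variant of the class template."""
    protected = _protected_offsets(cls)
    seq = list(template)
    for i in range(len(seq)):
        if i in protected:
            continue
        if rng.random() < rate:
            alt = [c for c in BG_ALPHABET if c != seq[i]]
            seq[i] = alt[int(rng.integers(len(alt)))]
    return "".join(seq)


def _build_protein(
    group: str, variant: str, rng: np.random.Generator, individuality: float
) -> tuple[str, list[int], list[str]]:
    """Assemble a planted protein; returns (sequence, domain starts, classes)."""
    nflank = _bg(rng, int(rng.integers(40, 110)))
    cflank = _bg(rng, int(rng.integers(60, 160)))
    if group == "I":
        mid = _bg(rng, int(rng.integers(60, 120)))
        dn = _individualize(TEMPLATES["I-N"], "I-N", individuality, rng)
        dc = _individualize(TEMPLATES["I-C"], "I-C", individuality, rng)
        if variant != "canonical":  # variant goes on the N-terminal domain
            dn = variant + dn[7:]
        seq = nflank + dn + mid + dc + cflank
        starts = [len(nflank), len(nflank) + len(dn) + len(mid)]
        return seq, starts, ["I-N", "I-C"]
    dom = _individualize(TEMPLATES[group], group, individuality, rng)
    if variant != "canonical":
        dom = variant + dom[7:]
    seq = nflank + dom + cflank
    return seq, [len(nflank)], [group]


def _plan_introns(
    gene: PlantedGene, rng: np.random.Generator
) -> tuple[list[int], list[str]]:
    """CDS-coordinate intron offsets and their planted types."""
    plen = len(gene.protein)
    offsets: list[int] = []
    types: list[str] = []

    def _domain_splice(dom_start: int, kind: str) -> None:
        if kind == "R":
            pos = dom_start + _R_OFFSET
            offsets.append(3 * pos + 1)  # phase 1, inside the R codon
            types.append("R-type")
        else:
            pos = dom_start + _V_OFFSET
            offsets.append(3 * pos)      # phase 0, immediately before the V
            types.append("V-type")

    group = gene.group
    if group == "I":
        _domain_splice(gene.domain_starts[1], "R")  # C-terminal domain only
        n_background = 2
    elif group in ("IIa", "IIb"):
        _domain_splice(gene.domain_starts[0], "V")
        n_background = 2
    elif group == "III":
        _domain_splice(gene.domain_starts[0], "R")
        n_background = 1  # group III genes carry exactly two introns
    else:
        _domain_splice(gene.domain_starts[0], "R")
        n_background = 1

    # background introns at codon boundaries in the flanks, away from domains
    domain_spans = [
        (s, s + (C2HC_LEN if c == "III" else C2H2_LEN))
        for s, c in zip(gene.domain_starts, gene.domain_classes)
    ]
    candidates = [
        r
        for r in range(10, plen - 10)
        if all(not (s - 5 <= r <= e + 5) for s, e in domain_spans)
    ]
    taken = {o // 3 for o in offsets}
    picks: list[int] = []
    while len(picks) < n_background and candidates:
        r = int(rng.choice(candidates))
        if all(abs(r - t) >= 10 for t in taken):
            picks.append(r)
            taken.add(r)
        candidates.remove(r)
    for r in picks:
        offsets.append(3 * r)
        types.append("untyped")
    order = np.argsort(offsets)
    return [offsets[i] for i in order], [types[i] for i in order]


def _mutate_protein(
    gene: PlantedGene, n_mutations: int, rng: np.random.Generator
) -> str:
    protected: set[int] = set()
    for s, cls in zip(gene.domain_starts, gene.domain_classes):
        protected |= {s + off for off in _protected_offsets(cls)}
    protected |= {o // 3 for o in gene.intron_offsets}
    sites = [i for i in range(len(gene.protein)) if i not in protected]
    if n_mutations > len(sites):
        n_mutations = len(sites)
    chosen = rng.choice(len(sites), size=n_mutations, replace=False)
    seq = list(gene.protein)
    for k in chosen:
        i = sites[int(k)]
        alt = [c for c in BG_ALPHABET if c != seq[i]]
        seq[i] = alt[int(rng.integers(len(alt)))]
    return "".join(seq)


def _gene_gff3(g: PlantedGene) -> str:
    """gene/mRNA/CDS features, 1-based inclusive, CDS split at introns."""
    lines = []
    span = g.end - g.start
    # exon pieces in transcript coordinates
    bounds = [0] + list(g.intron_offsets) + [len(g.cds)]
    intron_lens = _intron_lengths(g)
    tpieces = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    genomic: list[tuple[int, int]] = []
    cursor = 0
    for k, (a, b) in enumerate(tpieces):
        glen = b - a
        genomic.append((cursor, cursor + glen))
        cursor += glen
        if k < len(intron_lens):
            cursor += intron_lens[k]
    assert cursor == span
    segs = []
    cum = 0
    for (a, b), (ga, gb) in zip(tpieces, genomic):
        phase = (3 - cum % 3) % 3
        cum += b - a
        if g.strand == "+":
            s, e = g.start + ga, g.start + gb
        else:
            s, e = g.end - gb, g.end - ga
        segs.append((s, e, phase))
    chrom = g.chromosome
    lines.append(
        f"{chrom}\twrkysim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
    )
    lines.append(
        f"{chrom}\twrkysim\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
        f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
    )
    for s, e, phase in sorted(segs):
        lines.append(
            f"{chrom}\twrkysim\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t{phase}\t"
            f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
        )
    return "".join(lines)


def _intron_lengths(g: PlantedGene) -> list[int]:
    # deterministic per gene: derived from the gene id so layout is stable
    base = sum(ord(c) for c in g.gene_id)
    return [120 + 37 * ((base + 13 * k) % 9) for k in range(len(g.intron_offsets))]


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def generate_genome(config: GeneratorConfig | None = None) -> SyntheticGenome:
    """Build a deterministic synthetic genome per the configuration.

    Raises ValueError on infeasible plans (more cluster/pair genes than a
    group provides, or genes that do not fit on the chromosomes).
    """
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    templates = make_templates(min_divergence=cfg.min_template_divergence)
    globals()["TEMPLATES"] = templates  # honor a custom divergence guard

    # --- roster: gene ids per group, variants assigned to the first genes
    roster: list[tuple[str, str]] = []  # (gene_id, group)
    counter = 1
    for group in GROUP_LABELS_ORDER:
        for _ in range(int(cfg.group_counts.get(group, 0))):
            roster.append((f"g{counter:03d}", group))
            counter += 1
    if not roster:
        raise ValueError("empty gene plan")

    # --- duplicate pairs (disjoint, within group)
    by_group: dict[str, list[str]] = {}
    for gid, group in roster:
        by_group.setdefault(group, []).append(gid)
    dup_pairs: list[tuple[str, str, str]] = []  # (src, copy, class)
    used: set[str] = set()
    for plan, dclass in ((cfg.tandem_pairs, "tandem"), (cfg.segmental_pairs, "segmental")):
        for group, npairs in plan.items():
            avail = [g for g in by_group.get(group, []) if g not in used]
            if 2 * npairs > len(avail):
                raise ValueError(
                    f"group {group}: {npairs} {dclass} pairs need {2 * npairs} genes, "
                    f"only {len(avail)} available"
                )
            for k in range(npairs):
                a, b = avail[2 * k], avail[2 * k + 1]
                dup_pairs.append((a, b, dclass))
                used |= {a, b}

    # --- heptapeptide variants: planted on genes outside duplicate pairs so
    # the realized variant census equals the plan exactly
    variant_of: dict[str, str] = {}
    vlist = [v for v, k in cfg.variant_plan.items() for _ in range(k)]
    candidates = [gid for gid, _ in roster if gid not in used]
    if len(vlist) > len(candidates):
        raise ValueError("more planted variants than unpaired genes")
    vstep = max(1, len(candidates) // (len(vlist) + 1))
    for i, v in enumerate(vlist):
        variant_of[candidates[min((i + 1) * vstep, len(candidates) - 1)]] = v

    # --- build proteins, CDS, introns
    genes: dict[str, PlantedGene] = {}
    copy_of = {b: a for a, b, _ in dup_pairs}
    dup_class_of: dict[str, str] = {}
    for a, b, c in dup_pairs:
        dup_class_of[a] = dup_class_of[b] = c
    for gid, group in roster:
        if gid in copy_of:
            continue  # built from its source below
        variant = variant_of.get(gid, "canonical")
        seq, starts, classes = _build_protein(
            group, variant, rng, cfg.domain_individuality_rate
        )
        g = PlantedGene(
            gene_id=gid, group=group, variant=variant, protein=seq, cds="",
            domain_starts=starts, domain_classes=classes,
            intron_offsets=[], intron_types=[],
        )
        g.intron_offsets, g.intron_types = _plan_introns(g, rng)
        g.cds = _reverse_translate(seq, rng)
        genes[gid] = g
    for a, b, dclass in dup_pairs:
        src = genes[a]
        n_mut = int(round((1.0 - cfg.duplicate_identity_pct / 100.0) * len(src.protein)))
        mutated = _mutate_protein(src, n_mut, rng)
        g = PlantedGene(
            gene_id=b, group=src.group, variant=src.variant, protein=mutated,
            cds=_reverse_translate(mutated, rng),
            domain_starts=list(src.domain_starts),
            domain_classes=list(src.domain_classes),
            intron_offsets=list(src.intron_offsets),
            intron_types=list(src.intron_types),
            duplicate_of=a, dup_class=dclass,
        )
        genes[b] = g
        genes[a].dup_class = dclass

    # --- placement
    chroms = [f"chr{i}" for i in range(1, cfg.n_chromosomes + 1)]
    forced: dict[str, str] = {}
    partner: dict[str, str] = {}
    for a, b, dclass in dup_pairs:
        if dclass == "segmental":
            partner[a] = b
            partner[b] = a

    cluster_members: dict[str, list[str]] = {}
    order = [gid for gid, _ in roster]
    unassigned = list(order)

    # tandem pairs are atomic units on one chromosome
    tandem_units: list[tuple[str, str]] = [
        (a, b) for a, b, c in dup_pairs if c == "tandem"
    ]
    for a, b in tandem_units:
        unassigned.remove(a)
        unassigned.remove(b)

    # unplaced genes come off the back of the roster (never clustered/tandem)
    unplaced: list[str] = []
    for gid in reversed(order):
        if len(unplaced) >= cfg.n_unplaced:
            break
        if gid in unassigned and gid not in partner:
            unplaced.append(gid)
            unassigned.remove(gid)

    for ci, (chrom, size) in enumerate(cfg.cluster_plan):
        cid = f"cluster{ci + 1}"
        members: list[str] = []
        for gid in list(unassigned):
            if len(members) == size:
                break
            p = partner.get(gid)
            if p is not None and forced.get(p) == chrom:
                continue  # keep segmental pairs on different chromosomes
            members.append(gid)
            forced[gid] = chrom
            unassigned.remove(gid)
        if len(members) < size:
            raise ValueError(f"cluster plan infeasible at {cid} on {chrom}")
        cluster_members[cid] = members

    # remaining singletons round-robin, avoiding the partner's chromosome
    units: dict[str, list[list[str]]] = {c: [] for c in chroms}
    for cid, members in cluster_members.items():
        units[forced[members[0]]].append(members)
    for a, b in tandem_units:
        chrom = chroms[int(rng.integers(len(chroms)))]
        forced[a] = forced[b] = chrom
        units[chrom].append([a, b])
    ci = 0
    for gid in unassigned:
        for _ in range(len(chroms)):
            chrom = chroms[ci % len(chroms)]
            ci += 1
            p = partner.get(gid)
            if p is None or forced.get(p) != chrom:
                forced[gid] = chrom
                units[chrom].append([gid])
                break
        else:
            raise ValueError(f"cannot place {gid}: partner blocks every chromosome")

    cid_of: dict[str, str] = {}
    for cid, members in cluster_members.items():
        for gid in members:
            cid_of[gid] = cid

    for chrom in chroms:
        cursor = 100_000
        for unit in units[chrom]:
            for k, gid in enumerate(unit):
                g = genes[gid]
                span = len(g.cds) + sum(_intron_lengths(g))
                g.chromosome = chrom
                g.strand = "+" if rng.random() < 0.5 else "-"
                g.start = cursor
                g.end = cursor + span
                g.cluster_id = cid_of.get(gid, "")
                if k < len(unit) - 1:
                    gap = (
                        cfg.tandem_gap_bp
                        if (gid, unit[k + 1]) in tandem_units or (unit[k + 1], gid) in tandem_units
                        else cfg.cluster_gap_bp
                    )
                    cursor += gap
                else:
                    cursor += span + cfg.intercluster_gap_bp + int(rng.integers(0, 200_000))
            if cursor > cfg.chromosome_length_bp:
                raise ValueError(
                    f"{chrom}: placement exceeds chromosome length "
                    f"({cursor} > {cfg.chromosome_length_bp})"
                )
    for gid in unplaced:
        g = genes[gid]
        g.chromosome = "chrUn"
        g.strand = "+"
        g.start = 10_000
        g.end = g.start + len(g.cds) + sum(_intron_lengths(g))

    # --- consistency: every CDS translates back to its protein
    for g in genes.values():
        aa = str(Seq(g.cds).translate())
        if not aa.endswith("*") or aa[:-1] != g.protein:
            raise AssertionError(f"{g.gene_id}: CDS/protein inconsistent")
        for s, cls in zip(g.domain_starts, g.domain_classes):
            hepta = g.protein[s : s + 7]
            expect = g.variant if (g.variant != "canonical" and cls != "I-C") else CANONICAL_HEPTAPEPTIDE
            if hepta != expect:
                raise AssertionError(f"{g.gene_id}: heptapeptide mismatch at {s}")

    # --- ortholog genome (genome B)
    ortho_prot: dict[str, str] = {}
    ortho_cds: dict[str, str] = {}
    ortho_map: dict[str, str] = {}
    for gid, _ in roster:
        g = genes[gid]
        n_mut = int(round(cfg.ortholog_mutation_rate * len(g.protein)))
        mutated = _mutate_protein(g, n_mut, rng)
        bid = f"{gid}_b"
        ortho_prot[bid] = mutated
        ortho_cds[bid] = _reverse_translate(mutated, rng)
        ortho_map[gid] = bid

    # --- expression counts (negative binomial per tissue)
    r = cfg.expression_dispersion
    rows = []
    for gid, _ in roster:
        row = {}
        for t in cfg.tissues:
            mu = cfg.expression_means[t]
            p = r / (r + mu)
            row[t] = int(rng.negative_binomial(r, p))
        rows.append(row)
    counts = pd.DataFrame(rows, index=[gid for gid, _ in roster])
    counts.index.name = "gene"

    gene_rows = []
    ordered_genes = [genes[gid] for gid, _ in roster]
    for g in ordered_genes:
        gene_rows.append(
            dict(
                gene_id=g.gene_id, group=g.group, variant=g.variant,
                chromosome=g.chromosome, strand=g.strand, start=g.start, end=g.end,
                length_aa=len(g.protein),
                domain_starts=",".join(map(str, g.domain_starts)),
                domain_classes=",".join(g.domain_classes),
                intron_offsets=",".join(map(str, g.intron_offsets)),
                intron_types=",".join(g.intron_types),
                cluster_id=g.cluster_id, duplicate_of=g.duplicate_of,
                dup_class=g.dup_class,
            )
        )
    manifest = GroundTruthManifest(
        genes=pd.DataFrame(gene_rows),
        duplicate_pairs=pd.DataFrame(
            [
                dict(gene_a=a, gene_b=b, dup_class=c,
                     target_identity_pct=cfg.duplicate_identity_pct)
                for a, b, c in dup_pairs
            ]
        ),
        clusters=cluster_members,
        ortholog_map=ortho_map,
        counts=counts,
    )
    return SyntheticGenome(cfg, ordered_genes, manifest, ortho_prot, ortho_cds)


def generate_reference_panel(
    config: GeneratorConfig | None = None,
) -> list[tuple[str, str]]:
    """Labelled domain exemplars for subgroup assignment.

    Returns (label, sequence) pairs covering IIa-IIe plus group I N/C and
    group III templates, ``panel_exemplars`` noisy copies per class.
    """
    cfg = config or GeneratorConfig()
    templates = make_templates(min_divergence=cfg.min_template_divergence)
    rng = np.random.default_rng(cfg.seed + 7919)
    panel: list[tuple[str, str]] = []
    for cls in TEMPLATE_CLASSES:
        protected = _protected_offsets(cls)
        for _ in range(cfg.panel_exemplars):
            seq = list(templates[cls])
            for i in range(len(seq)):
                if i in protected:
                    continue
                if rng.random() < cfg.panel_noise_rate:
                    alt = [c for c in BG_ALPHABET if c != seq[i]]
                    seq[i] = alt[int(rng.integers(len(alt)))]
            panel.append((cls, "".join(seq)))
    return panel
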