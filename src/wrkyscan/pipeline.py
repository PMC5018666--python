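"""End-to-end orchestration and family-table summarization.

``run_pipeline`` wires the stages in order — domain scan, group/subgroup
classification, physicochemical features, chromosomal organization,
duplication/orthology/Ka-Ks, domain phylogeny, expression — and writes each
stage's table.  ``summarize_family`` computes the aggregate statistics a
family survey reports (counts per group, intron histogram, length/pI/MW
ranges, chromosome census, ortholog tallies) from a characterization table
alone; it is pure and order-insensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import classify, domain_scan, evolution, expression, gene_features, genome_org, phylo
from .io_formats import (
    FamilyTableRow,
    GeneModel,
    ProteinRecord,
    UNPLACED,
    read_cds_fasta,
    read_fasta,
    read_gff3,
)


@dataclass
class FamilySummary:
    n_genes: int
    group_counts: dict[str, int]          # I / II / III
    subgroup_counts: dict[str, int]       # I, IIa..IIe, III
    intron_histogram: dict[int, int]
    mean_length_aa: int                   # round-half-even
    min_length_aa: int
    max_length_aa: int
    min_pi: float
    max_pi: float
    min_mw_kda: float
    max_mw_kda: float
    per_chromosome: dict[str, int]
    n_unplaced: int
    genes_with_at_ortholog: int
    genes_with_pt_ortholog: int
    group3_allpairs: int                  # k(k-1)/2 for the group III genes
    n_clusters: int | None = None
    clustered_genes: int | None = None
    homolog_pairs: int | None = None
    tandem_pairs: int | None = None
    segmental_pairs: int | None = None
    ortholog_pairs: int | None = None
    expressed_per_tissue: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_family(rows: list[FamilyTableRow]) -> FamilySummary:
    """Aggregate a family characterization table."""
    if not rows:
        raise ValueError("empty family table")
    main = {"I": 0, "II": 0, "III": 0}
    sub: dict[str, int] = {}
    hist: dict[int, int] = {}
    per_chrom: dict[str, int] = {}
    for r in rows:
        key = "II" if r.group.startswith("II") and r.group != "III" else r.group
        main[key] += 1
        sub[r.group] = sub.get(r.group, 0) + 1
        hist[r.introns] = hist.get(r.introns, 0) + 1
        if r.chromosome != UNPLACED:
            per_chrom[r.chromosome] = per_chrom.get(r.chromosome, 0) + 1
    lengths = [r.length_aa for r in rows]
    pis = [r.pi for r in rows]
    mws = [r.mw_kda for r in rows]
    k3 = main["III"]
    return FamilySummary(
        n_genes=len(rows),
        group_counts=main,
        subgroup_counts=dict(sorted(sub.items())),
        intron_histogram=dict(sorted(hist.items())),
        mean_length_aa=round(sum(lengths) / len(lengths)),
        min_length_aa=min(lengths),
        max_length_aa=max(lengths),
        min_pi=min(pis),
        max_pi=max(pis),
        min_mw_kda=min(mws),
        max_mw_kda=max(mws),
        per_chromosome=dict(sorted(per_chrom.items(), key=lambda kv: kv[0])),
        n_unplaced=sum(r.chromosome == UNPLACED for r in rows),
        genes_with_at_ortholog=sum(bool(r.at_orthologs) for r in rows),
        genes_with_pt_ortholog=sum(bool(r.pt_orthologs) for r in rows),
        group3_allpairs=k3 * (k3 - 1) // 2,
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    protein_fasta: str
    cds_fasta: str | None = None
    gff3: str | None = None
    counts_tsv: str | None = None
    reference_panel_fasta: str | None = None   # headers ">label|n"
    second_proteome_fasta: str | None = None
    outdir: str | None = None
    gene_prefix: str = "WRKY"
    subgroup_method: str = "tree"
    cluster_window_bp: int = 200_000
    min_coverage_pct: float = 80.0
    min_identity_pct: float = 65.0
    min_ortholog_score: float = 50.0
    bootstrap_reps: int = 100
    bootstrap_seed: int = 0
    run_expression: bool = True
    run_phylogeny: bool = True
    unplaced_seqids: tuple[str, ...] = ("chrUn", "N/A", "scaffold_un")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: FamilySummary
    domains: dict[str, list[domain_scan.WRKYDomain]]
    assignments: dict[str, classify.GroupAssignment]
    subgroups: dict[str, str]
    properties: dict[str, gene_features.ProteinProperties]
    introns: dict[str, list[gene_features.IntronAnnotation]]
    rename_map: dict[str, str]
    clusters: list[genome_org.GeneCluster]
    homolog_pairs: list[evolution.HomologPair]
    group3_kaks: list[evolution.HomologPair]
    orthologs: list[evolution.OrthologPair]
    tree_newick: str | None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r}: {detail}")
        self.stage = stage


def _read_panel(path: str) -> list[tuple[str, str]]:
    return [(r.id.split("|")[0], r.sequence) for r in read_fasta(path)]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; any stage error aborts with the stage
    name and the offending record."""
    proteins = {r.id: r for r in read_fasta(config.protein_fasta)}
    cds = read_cds_fasta(config.cds_fasta) if config.cds_fasta else {}
    models: dict[str, GeneModel] = {}
    if config.gff3:
        for m in read_gff3(config.gff3):
            if m.chromosome in config.unplaced_seqids:
                m.chromosome = UNPLACED
            models[m.gene_id] = m

    # --- scan
    domains: dict[str, list[domain_scan.WRKYDomain]] = {}
    for pid, rec in proteins.items():
        found = domain_scan.scan_protein(rec)
        if found:
            domains[pid] = found
    if not domains:
        raise StageError("scan", "no WRKY domains found in any protein")

    # --- classify
    assignments: dict[str, classify.GroupAssignment] = {}
    subgroups: dict[str, str] = {}
    panel = _read_panel(config.reference_panel_fasta) if config.reference_panel_fasta else []
    sub_panel = [(lab, seq) for lab, seq in panel if lab in classify.SUBGROUPS]
    for pid, doms in domains.items():
        try:
            assignments[pid] = classify.assign_group(doms)
        except ValueError as exc:
            raise StageError("classify", f"{pid}: {exc}") from exc
        if assignments[pid].group == "II":
            if sub_panel:
                seq = proteins[pid].sequence[
                    doms[0].domain_start : doms[0].domain_end + 1
                ]
                label, _tie = classify.assign_subgroup(
                    seq, sub_panel, method=config.subgroup_method
                )
                subgroups[pid] = label
            else:
                subgroups[pid] = "II"
        else:
            subgroups[pid] = assignments[pid].group

    family_ids = list(domains)

    # --- features
    properties: dict[str, gene_features.ProteinProperties] = {}
    introns: dict[str, list[gene_features.IntronAnnotation]] = {}
    for pid in family_ids:
        properties[pid] = gene_features.protein_properties(proteins[pid])
        if pid in models:
            try:
                introns[pid] = gene_features.annotate_introns(
                    models[pid], proteins[pid], domains[pid]
                )
            except ValueError as exc:
                raise StageError("features", str(exc)) from exc

    # --- genome organization
    family_models = [models[p] for p in family_ids if p in models]
    rename_map = genome_org.rename_by_position(family_models, config.gene_prefix)
    clusters = genome_org.find_clusters(family_models, config.cluster_window_bp)

    # --- evolution
    seqs = {p: proteins[p].sequence for p in family_ids}
    homologs = evolution.find_homolog_pairs(
        seqs, config.min_coverage_pct, config.min_identity_pct
    )
    family_set = set(family_ids)
    for pair in homologs:
        if pair.gene_a in models and pair.gene_b in models:
            pair.dup_class = evolution.classify_duplication(pair, models, family_set)
    group3 = [p for p in family_ids if subgroups.get(p) == "III"]
    group3_kaks: list[evolution.HomologPair] = []
    if cds and len(group3) >= 2:
        try:
            group3_kaks = evolution.all_pairs_kaks(
                {g: cds[g] for g in group3 if g in cds},
                {g: seqs[g] for g in group3},
            )
        except ValueError as exc:
            raise StageError("evolution", str(exc)) from exc

    orthologs: list[evolution.OrthologPair] = []
    if config.second_proteome_fasta:
        proteome_b = {
            r.id: r.sequence for r in read_fasta(config.second_proteome_fasta)
        }
        dom_a = _group1_domains(proteins, domains, assignments)
        scans_b = {
            pid: domain_scan.scan_protein(ProteinRecord(pid, seq))
            for pid, seq in proteome_b.items()
        }
        assign_b = {
            pid: classify.assign_group(d) for pid, d in scans_b.items() if d
        }
        dom_b = _group1_domains(
            {pid: ProteinRecord(pid, s) for pid, s in proteome_b.items()},
            scans_b,
            assign_b,
        )
        orthologs = evolution.reciprocal_best_hits(
            seqs,
            proteome_b,
            min_score=config.min_ortholog_score,
            group1_domains_a=dom_a,
            group1_domains_b=dom_b,
        )

    # --- phylogeny of domains
    tree_newick: str | None = None
    if config.run_phylogeny and len(family_ids) >= 3:
        labels, dseqs = [], []
        for pid in family_ids:
            for i, d in enumerate(domains[pid]):
                suffix = ("-N", "-C")[i] if len(domains[pid]) == 2 else ""
                labels.append(f"{pid}{suffix}")
                dseqs.append(
                    proteins[pid].sequence[d.domain_start : d.domain_end + 1]
                )
        aln = phylo.progressive_msa(dseqs)
        tree = phylo.bootstrap(
            aln, labels, n_reps=config.bootstrap_reps, seed=config.bootstrap_seed
        )
        tree_newick = tree.as_string(schema="newick", suppress_rooting=True)

    # --- expression
    expressed: dict[str, int] | None = None
    em: expression.ExpressionMatrix | None = None
    if config.run_expression and config.counts_tsv:
        counts = pd.read_csv(config.counts_tsv, sep="\t", index_col=0)
        counts = counts.loc[[g for g in counts.index if g in family_set]]
        lengths = pd.Series(
            {g: models[g].cds_length if g in models else 3 * len(seqs[g]) for g in counts.index}
        )
        em = expression.ExpressionMatrix(counts=counts, gene_lengths_bp=lengths)
        expressed = em.expressed_per_tissue().to_dict()

    # --- summary (via the same table path the fixture uses)
    rows = []
    for pid in family_ids:
        model = models.get(pid)
        chrom = model.chromosome if model else UNPLACED
        n_introns = model.intron_count if model else 0
        rows.append(
            FamilyTableRow(
                gene_name=rename_map.get(pid, pid),
                sequence_id=pid,
                chromosome=chrom,
                group=subgroups[pid],
                at_orthologs=[],
                pt_orthologs=[],
                length_aa=properties[pid].length_aa,
                pi=properties[pid].pi,
                mw_kda=properties[pid].mw_kda,
                introns=n_introns,
            )
        )
    summary = summarize_family(rows)
    summary.n_clusters = len(clusters)
    summary.clustered_genes = sum(len(c.member_gene_ids) for c in clusters)
    summary.homolog_pairs = len(homologs)
    summary.tandem_pairs = sum(p.dup_class == "tandem" for p in homologs)
    summary.segmental_pairs = sum(p.dup_class == "segmental" for p in homologs)
    summary.ortholog_pairs = len(orthologs) if config.second_proteome_fasta else None
    summary.expressed_per_tissue = expressed

    result = PipelineResult(
        summary=summary,
        domains=domains,
        assignments=assignments,
        subgroups=subgroups,
        properties=properties,
        introns=introns,
        rename_map=rename_map,
        clusters=clusters,
        homolog_pairs=homologs,
        group3_kaks=group3_kaks,
        orthologs=orthologs,
        tree_newick=tree_newick,
    )
    result.tables = _stage_tables(result)
    if config.outdir:
        _write_outputs(result, em, Path(config.outdir))
    return result


def _group1_domains(proteins, domains, assignments) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for pid, asg in assignments.items():
        if asg.group != "I" or len(domains[pid]) != 2:
            continue
        seq = proteins[pid].sequence
        dn, dc = domains[pid]
        out[pid] = {
            "N": seq[dn.domain_start : dn.domain_end + 1],
            "C": seq[dc.domain_start : dc.domain_end + 1],
        }
    return out


def _stage_tables(res: PipelineResult) -> dict[str, pd.DataFrame]:
    dom_rows = [
        dict(
            protein_id=d.protein_id, hepta_start=d.hepta_start, hepta_seq=d.hepta_seq,
            variant=d.hepta_variant, finger_type=d.finger_type,
            complete=d.complete, n_fingers=d.n_fingers,
        )
        for doms in res.domains.values()
        for d in doms
    ]
    grp_rows = [
        dict(
            protein_id=pid, group=res.assignments[pid].group,
            subgroup=res.subgroups[pid], evidence=res.assignments[pid].evidence,
        )
        for pid in res.assignments
    ]
    feat_rows = [
        dict(
            protein_id=pid, name=res.rename_map.get(pid, pid),
            length_aa=p.length_aa, mw_kda=p.mw_kda, pi=p.pi,
            introns=len(res.introns.get(pid, [])),
            splice_types=",".join(i.splice_type for i in res.introns.get(pid, [])),
        )
        for pid, p in res.properties.items()
    ]
    pair_rows = [
        dict(
            gene_a=p.gene_a, gene_b=p.gene_b,
            identity_pct=round(p.identity_pct, 1), coverage_pct=round(p.coverage_pct, 1),
            dup_class=p.dup_class,
        )
        for p in res.homolog_pairs
    ]
    kaks_rows = [
        dict(pair=f"{p.gene_a}-{p.gene_b}", ka=p.ka, ks=p.ks, ka_ks=p.ka_ks)
        for p in res.group3_kaks
    ]
    cluster_rows = [
        dict(
            cluster_id=c.cluster_id, chromosome=c.chromosome,
            members=",".join(c.member_gene_ids), span_bp=c.span_bp,
        )
        for c in res.clusters
    ]
    orth_rows = [
        dict(gene_a=p.gene_a, gene_b=p.gene_b, score=p.score,
             concordant=p.concordant_domains)
        for p in res.orthologs
    ]
    return {
        "domains": pd.DataFrame(dom_rows),
        "groups": pd.DataFrame(grp_rows),
        "features": pd.DataFrame(feat_rows),
        "homolog_pairs": pd.DataFrame(pair_rows),
        "kaks_group3": pd.DataFrame(kaks_rows),
        "clusters": pd.DataFrame(cluster_rows),
        "orthologs": pd.DataFrame(orth_rows),
    }


def _write_outputs(res: PipelineResult, em, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in res.tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
    if res.tree_newick:
        (outdir / "domain_tree.nwk").write_text(res.tree_newick)
    if em is not None:
        em.rpkm_matrix().to_csv(outdir / "rpkm.tsv", sep="\t")
        em.heatmap_matrix().to_csv(outdir / "log2_rpkm.tsv", sep="\t", na_rep="NA")
        (outdir / "tissue_dendrogram.nwk").write_text(expression.cluster_tissues(em))
    with open(outdir / "summary.json", "w") as fh:
        json.dump(res.summary.to_dict(), fh, indent=2, default=str)
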