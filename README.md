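# wrkyscan

Genome-wide identification and characterization of **WRKY transcription-factor
gene families**, as a reusable, fully tested pipeline.

WRKY proteins are plant transcription factors defined by a ~60-residue
DNA-binding domain: the heptapeptide **WRKYGQK** (or a near variant such as
WRKYGRK, WKKYGQK, WRKYGKK) followed by a spacing-constrained zinc finger,
either C-X<sub>4–5</sub>-C-X<sub>22–23</sub>-H-X-H (C2H2) or
C-X<sub>7</sub>-C-X<sub>23</sub>-H-X-C (C2HC). They bind the W-box promoter
element ([C/T]TGAC[T/C]) and regulate stress and developmental programs.
Family surveys classify members by domain count and finger type:

* **group I** — two WRKY domains (N- and C-terminal) with C2H2 fingers;
* **group II** — one domain with a C2H2 finger, split phylogenetically into
  subgroups IIa–IIe;
* **group III** — one domain with the diagnostic C2HC finger.

`wrkyscan` implements every stage such a survey runs:

| stage | module | method |
|---|---|---|
| domain detection | `domain_scan` | heptapeptide + zinc-finger pattern scan, accessory motifs (HARF, LXXLL, LXLXLX, heptad Leu zipper) |
| classification | `classify` | structural group rules; subgroup by nearest reference domain or NJ-tree placement against a labelled panel |
| characterization | `gene_features` | length, average MW, Bjellqvist-pKa bisection pI; intron phases and conserved **R-type / V-type** domain-intron typing |
| chromosomal organization | `genome_org` | ordinal renaming along chromosomes; 200-kb gene clusters (chained, start-to-start) |
| evolution | `evolution` | BLOSUM62 affine pairwise alignment; duplicate screen (coverage ≥ 80% of the longer protein, identity ≥ 65%); tandem vs segmental labels; reciprocal-best-hit orthology with the group-I N/C-domain concordance rule; **Nei–Gojobori Ka/Ks** with Jukes–Cantor correction (Ka/Ks < 0.5 ⇒ purifying selection) |
| phylogeny | `phylo` | progressive MSA over an NJ guide tree, p-distance with pairwise gap deletion, Saitou–Nei neighbor joining, column bootstrap |
| expression | `expression` | RPKM = count / (length<sub>kb</sub> × mapped<sub>millions</sub>), log2 heat-map export (NA for unexpressed), average-linkage tissue clustering |
| synthetic data | `synthetic_data` | deterministic genomes with planted domains, variants, clusters, duplicate pairs, orthologs and NB counts, plus a ground-truth manifest |

The package also ships a curated characterization table of the 85-member
willow (*Salix suchowensis*) WRKY family (gene, chromosome, group, orthologs
in *Arabidopsis* and poplar, length, pI, MW, introns), which
`summarize_family` aggregates exactly.

## Worked example

```python
from wrkyscan import load_family_table, summarize_family

s = summarize_family(load_family_table())
print(s.n_genes, s.group_counts)      # 85 {'I': 19, 'II': 59, 'III': 7}
print(s.subgroup_counts)              # {'I': 19, 'III': 7, 'IIa': 4, 'IIb': 8,
                                      #  'IIc': 23, 'IId': 13, 'IIe': 11}
print(s.mean_length_aa)               # 407
print(s.min_pi, s.max_pi)             # 5.03 10.27
print(s.group3_allpairs)              # 21
```

85 genes split 19/59/7 across the three groups; proteins average 407
residues; isoelectric points span 5.03–10.27; and the 7 group III genes give
7·6/2 = 21 pairs for the all-pairs Ka/Ks screen.

End-to-end on synthetic data:

```bash
wrkyscan synth --seed 1 --out demo/          # genome + ground truth + panel
wrkyscan fixture-summary                     # aggregates of the packaged table
wrkyscan run --config cfg.yaml               # full pipeline, summary JSON
```

where `cfg.yaml` names the inputs:

```yaml
protein_fasta: demo/proteins.fasta
cds_fasta: demo/cds.fasta
gff3: demo/genes.gff3
counts_tsv: demo/counts.tsv
reference_panel_fasta: demo/reference_panel.fasta
outdir: demo/out
```

`demo/out/` then holds per-stage TSVs (domains, groups, features, clusters,
homolog pairs, group III Ka/Ks), the domain NJ tree and tissue dendrogram in
Newick, RPKM/log2 matrices, and `summary.json`.

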