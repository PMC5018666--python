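# Methods

This note documents the models, parameter choices and numerical decisions
behind `wrkyscan`, and what the synthetic-data tests do and do not establish
about real genomes.

## Domain model and scanning

A WRKY domain is detected as a heptapeptide core followed by a zinc finger
within a window. The heptapeptide matcher accepts an explicit variant set
(WRKYGQK, WRKYGRK, WKKYGQK, WRKYGKK, WRKYGEK by default) and, with
`max_mismatch=1`, any 7-mer a single substitution from WRKYGQK (labelled
`other-1-mismatch`). Finger patterns are tried in priority order — C2H2
(C-X(4,5)-C-X(22,23)-H-X-H), C2HC (C-X7-C-X23-H-X-C), then the two observed
variant C2H2 spacings (C-X4-C-X21 and C-X5-C-X19) — with leftmost, then
shortest-spacer matches winning (lazy regex quantifiers). Domains without a
locatable finger are kept as *incomplete*: family surveys retain such genes
in all downstream analyses. A second finger immediately following the first
is counted (`n_fingers = 2`); this is the signature of a single-heptapeptide
gene descended from a two-domain ancestor and is classified into group I.

The heptapeptide–finger distance is not standardized in the literature; the
window defaults to 80 residues and is a config key. This pattern scanner
replaces profile-HMM identification deliberately: on sequences with intact
cores it is exact and fully deterministic, at the cost of missing heavily
degenerate cores a profile might still score.

## Classification

Structural rules fix the main group (two domains → I; C2HC → III; C2H2 →
II). Subgroups IIa–IIe have no structural definition, so placement is
reference-guided: either the label of the reference domain at the smallest
p-distance (after pairwise global alignment, gap-excluded columns), or —
the default — the majority label of the smallest NJ-tree clade containing
the query and at least one reference, with ties falling back to
nearest-distance and first-in-file order (flagged). Equidistant references
are a real possibility on short domains; the tie flag surfaces them.

## Physicochemical features

Molecular weight is the sum of average residue masses plus one water;
unknown `X` contributes the unweighted mean of the 20 standard residues.
Isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14] to
|ΔpH| < 0.001, with a fixed Bjellqvist-style pKa table (N-terminus 7.5,
C-terminus 3.55; D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0).
The charge curve is strictly decreasing, so the root is unique; a dense
grid scan (step 0.0005) is the test oracle and agrees within 0.01 pH.
Implementations differing in terminal-pKa detail (e.g. residue-specific
N-terminal values) can differ by a few tenths of a pH unit; the packaged
characterization table is therefore the reference for table-level
aggregates, not recomputation.

## Introns

Intron phase and the interrupted residue follow from cumulative CDS length
(stop codon excluded from the CDS↔protein accounting; a trailing stop is
tolerated). Within a complete domain, an intron is **R-type** when the
splice point sits at an arginine about five residues before the first finger
cysteine, and **V-type** when it immediately precedes a valine six residues
after the second cysteine; "about" is implemented as ±2 residues. Whether a
published diagram's arrowheads mark codon boundaries or within-codon breaks
is ambiguous; the mapping here is phase-aware, so both phase-0 (before the
residue) and phase-1/2 (inside the residue's codon) splice points type
correctly.

## Chromosomal organization

Ordinal family names sort by (natural chromosome order, gene start);
unplaced genes take the final ordinals. Clusters chain consecutive family
genes whose start-to-start distance is ≤ 200 kb and keep maximal chains of
≥ 2. Start-to-start distance and transitive chaining were genuinely open
choices; chaining is used because surveys report multi-cluster
high-density regions as single spans.

## Homology, duplication, orthology

Pairwise alignment is dynamic programming (BLOSUM62; gap open −10, extend
−0.5) through Biopython's `PairwiseAligner`; an independent Gotoh DP in the
test suite checks optimal scores. Identity is exact matches over **all**
alignment columns (gaps included in the denominator); coverage is columns
where both sequences hold a residue, over the longer sequence length.
Duplicate pairs require coverage ≥ 80% and identity ≥ 65%. Tandem
duplicates are same-chromosome, adjacent (no intervening family gene),
within 200 kb; different chromosomes ⇒ segmental; same-chromosome
non-adjacent pairs are unclassified by default (configurable).

Orthology is reciprocal best hit by alignment score with a floor of 150 —
chosen so unrelated random 300-mers (observed maximum ≈ 56) can never pass
while genuine homologs at ≥ 65% identity over ≥ 100 residues score several
hundred; the rejection property is asserted by simulation in the tests.
An E-value threshold is not meaningful without a database model, hence the
raw-score floor. For two-domain (group I) genes the N- and C-terminal
domains must each independently pick the same partner gene; discordant
pairs are dropped, mirroring how surveys treat group-I orthology.

## Ka/Ks

Nei–Gojobori (1986) counting: the protein alignment is back-translated to a
codon alignment; per codon, each position contributes 1/3 per synonymous
single-nucleotide change (changes to stops count as nonsynonymous, so
synonymous + nonsynonymous sites sum to exactly 3); differences are averaged
over mutational pathways, excluding pathways through stop codons whenever a
stop-free pathway exists; proportions are Jukes–Cantor corrected. At
saturation (p ≥ 3/4, reachable only on degenerate inputs of a few codons)
the uncorrected proportion is returned. Ka/Ks is undefined (None) when
Ks = 0; Ka/Ks < 0.5 flags purifying selection. Codons containing ambiguous
bases are skipped. The counting method is used instead of maximum-likelihood
estimation; at the effect sizes the purifying screen targets (< 0.5 vs ≈ 1)
the two agree in sign and order of magnitude.

## Phylogeny

p-distance with pairwise gap deletion (columns gapped in either row are
excluded per pair; an all-gap pair is an error). Neighbor joining is the
standard Saitou–Nei agglomeration; Q-matrix ties break on the lowest index
pair, and negative branch-length estimates are clamped to 0 and counted in
the tree's `clamped_branches` annotation. On additive matrices the output
reproduces every pairwise path length to machine precision (tested on random
4- and 5-taxon trees, and against brute-force topology enumeration for 4
taxa). The progressive aligner builds single-sequence pairwise alignments
for guide distances, an NJ guide tree, and profile–profile global DP with
sum-of-pairs scoring (BLOSUM62, linear gap −8 per residue–gap pair); its
fidelity target is planted-clade recovery on ~60-residue domains, not
reproduction of any particular aligner's output. Bootstrap resamples
columns with replacement (100 replicates by default, configurable to 1000);
supports are the percentage of replicate trees containing each internal
bipartition. Column draws are independent of row order, so the support of a
well-separated clade is invariant under row permutation; individual
within-clade edges can differ where distances tie exactly, because NJ
tie-breaking is index-based.

## Expression

RPKM uses per-tissue library sizes defaulting to the column sums of the
supplied count table (configurable override). The heat-map export is
log2(RPKM) with NA wherever the raw count is zero — an unexpressed gene, not
a zero value. Tissue clustering is average-linkage hierarchical
agglomeration on Euclidean distances of the log2 matrix with NA zero-filled
for the distance computation only; the dendrogram is exported as Newick.

## Synthetic genomes

The generator's defaults emulate a willow-scale family: 85 genes on 19
chromosomes (group I 19, IIa 4, IIb 8, IIc 23, IId 13, IIe 11, III 7), four
heptapeptide-variant genes, one unplaced gene, 11 clusters holding 23 genes,
and 33 disjoint segmental duplicate pairs (66 genes) at 80% target protein
identity. Group III genes carry exactly two introns; V-type domain introns
are planted only in IIa/IIb, R-type in IC/IIc/IId/IIe/III, and none in the
group-I N-terminal domain.

Construction details that matter:

* background residues are drawn from an alphabet without C, H or W, so the
  planted fingers and heptapeptides are the only ones a scanner can find;
* each class has a fixed ~51/55-residue domain template (pairwise divergence
  guard ≥ 20%), and every gene's domain is *individualized* by mutating 10%
  of its non-structural positions — without this, the group-I N/C ortholog
  concordance rule would be undecidable (all N domains identical);
* duplicates and ortholog-genome copies mutate only non-structural
  positions (heptapeptide, finger residues and planted splice-site R/V are
  protected); CDSs are re-reverse-translated with random synonymous codon
  choice, so duplicate pairs carry substantial synonymous divergence;
* expression counts are negative binomial per tissue (means 40/25/45/35/15
  for root/stem/bark/bud/leaf, dispersion 0.8) — chosen as typical RNA-seq
  overdispersion for a moderately expressed TF family;
* all randomness flows from one seed; identical seeds give byte-identical
  output files, and every emitted CDS translates exactly to its protein
  (checked at generation time).

What passing these tests shows — and does not. The generator plants intact,
canonical-architecture genes with clean intron placements and no
pseudogenes, fragmented models, alternative isoform conflicts or
assembly-induced coordinate errors. Perfect recovery on synthetic genomes
therefore validates the *logic* of each stage and its thresholds, not
robustness to annotation noise in real genomes.

## Problem sizes

The test suite and the reproduction script run at the default family scale
(85 genes; ~3.6k pairwise protein alignments for the duplicate screen,
2 × 85² alignments for reciprocal best hits, 59 tree-guided subgroup
placements, 200 Ka/Ks Monte-Carlo replicates of 100 codons). Bootstrap
defaults to 100 replicates with a config path to 1000. These sizes keep a
full run around a minute on one CPU while exercising every stage at the
scale a real single-genome survey would.

## Known limitations

* Pattern scanning misses domains whose heptapeptide degenerates beyond one
  substitution; a profile method would not.
* Subgroup assignment quality is bounded by the reference panel; with
  under-diverged references the tie flag fires rather than failing loudly.
* The Nei–Gojobori estimator is biased at high divergence relative to ML
  codon models; it is used here as a screen, not an estimator of absolute
  rates.
* The MSA is a simple sum-of-pairs progressive aligner without iterative
  refinement; long, gappy alignments of full-length proteins are out of its
  design envelope (domains are its target).
* RPKM totals use within-family column sums unless a genome-wide total is
  supplied, so absolute RPKM values are comparable within a run, not across
  studies.
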