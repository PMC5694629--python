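# Methods

This note records the models, conventions and design choices behind
`cyanotax`, in enough detail to reproduce or audit any number the package
emits.

## Genomic signatures

**AAI.**  Orthologs between two proteomes are reciprocal best hits under
local alignment with BLOSUM62 and affine gaps (open 11, extend 1; a gap of
length L costs 11 + (L−1)).  Percent identity is matches over aligned
columns, with internal gap columns counted as mismatches.  A hit is kept
when identity ≥ 30% and the aligned span covers ≥ 70% of the shorter
sequence; best-hit ties break by score, then alignment length, then
lexicographic identifier.  AAI is the unweighted mean of RBH identities —
a two-way, length-unweighted definition.  With zero RBH pairs AAI is
recorded as missing, never as 0: a missing value and maximal divergence
are different statements.

**GGD.**  The genome-to-genome distance is expressed as a percent
similarity in the digital DNA–DNA hybridisation family: fragment genome A
into non-overlapping 1 kb windows; align each window locally to genome B
(match +2, mismatch −3, gap open 5, extend 2); discard HSPs shorter than
100 bp or below 50% identity; GGD(A→B) = 100 · Σ identities / Σ HSP
columns, and the reported value is the mean of both directions.  For
tractability each window is first anchored: the window's 13-mers vote for
a diagonal of B (bucket width 64), and the local alignment runs against
that diagonal's region ± 100 bp rather than all of B.  For genuinely
homologous windows the best local alignment lies on the dominant shared
diagonal, so the anchored alignment is the same one a full scan would
find; windows with no shared 13-mer (expected identity far below 50%)
produce no HSP either way.  A pair with no surviving HSP in either
direction gets GGD 0 with an explicit `no_homology` flag.

**16S identity.**  Ends-free global alignment under the same nucleotide
scoring; identity excludes terminal-gap columns and counts internal gaps
as mismatches.  Fragments shorter than 500 bp are rejected as too short to
be meaningful.  Strains without a 16S gene carry missing values through
the whole pipeline; the species criterion then rests on AAI and GGD, and
the genome is flagged.

**Tajima–Nei distances.**  For tree-side sanity checks the package
computes the equal-input distance d = −b·ln(1 − p/b) with
b = ½(1 − Σgᵢ² + p²/h) and h = Σ_{i<j} x²ᵢⱼ/(2gᵢgⱼ), over columns where
both rows are unambiguous bases.  Pairs at or beyond the correction's
validity limit (log argument ≤ 0) are flagged non-finite rather than
clamped.

**Marker concatenation.**  Per-gene aligned protein sets are concatenated
into a supermatrix; only genomes present in *every* marker are retained,
the rest are listed in an exclusion report, and per-gene column
coordinates are emitted.

## Taxon delimitation

Cut-offs (inclusive): same species when AAI ≥ 95 ∧ GGD ≥ 70 ∧ (16S missing
∨ 16S ≥ 98.8); same genus when AAI ≥ 70.  Missing GGD blocks a species
call and is flagged.

Clusters are single-linkage connected components of the pairwise verdict
graph.  The within-cluster consistency rule is deliberately permissive:
a component is never broken by an internal failing pair, but every such
triple (two qualifying edges, one failing chord) is emitted as a
non-transitivity warning — conflicts are surfaced, not hidden.

Genus components are refined against a rooted reference tree: a component
that is not monophyletic is split into its maximal monophyletic subclades
(largest tree nodes whose leaves all belong to the component).  Species
rank is defined by genomic signatures and genus rank by topology, and
species are nested inside genera, so a species cluster is never divided by
this refinement: if a split would divide one, the whole species cluster
follows its majority subclade (ties to the subclade with the
lexicographically smallest member) and the event is logged.  Genomes
absent from the tree stay with their AAI component and are flagged.
Cluster names are synthetic (`species_NN`, `genus_NN`, numbered by
smallest member identifier); Latin names are display metadata only.

The AAI heatmap ordering uses Manhattan distances between AAI row vectors
and complete linkage (configurable), mirroring the ecogroup stage.

A genome enters the analysis when its user-supplied completeness is
≥ 90% and it is assembled in fewer than 500 contigs (strict bound).
Completeness is an input column, not computed: completeness estimation is
a separate concern with its own tooling.

## Read recruitment and abundance

Reads are recruited by exact canonical k-mer matching, k = 31 (odd, so no
k-mer is its own reverse complement; both strands are represented through
strand-minimum canonicalisation).  A read's score against a genome is the
fraction of its k-mer positions whose canonical k-mer occurs in the
genome; the read is assigned to the top-scoring genome(s) when the score
is ≥ 0.5, with ties split fractionally and equally — a read from a region
shared verbatim by two genomes contributes half a count to each.  Base
qualities are ignored; recruitment is exact-match by construction.

Per sample, abundance is Σ fractional weights per genome, divided by
genome length (reads per base), closed to sum to 1.  Samples with zero
assigned reads yield an all-zero column and an explicit flag instead of a
silent NaN.

## Correlation profiles and ecogroups

Spearman ρ is computed per genome × parameter over pairwise-complete
samples with average ranks for ties; a parameter needs ≥ 3 paired
observations, and constant vectors yield missing cells.  Two-sided
p-values use the t approximation (adequate for the n ≥ 10 surveys the
package targets); an exact full-permutation p is available for n < 10.
Benjamini–Hochberg q-values are computed across all cells jointly and
capped at 1.  Significance only annotates the output: *all* correlations
enter the clustering, since weak associations still carry ecological
signal.

Profiles are clustered by complete linkage on Manhattan distances between
ρ vectors; missing cells are imputed as 0 (no association) and flagged.
The dendrogram is cut into k groups (default 3, a parameter) rather than
by visual inspection, making the grouping reproducible.  Genomes are
processed in identifier order so the partition is input-order invariant.

Group naming is rule-based, from mean correlations per group (T̄ =
temperature; N̄ = mean over nitrate, nitrite, phosphate): T̄ > 0 ∧ N̄ < 0
→ High Temperature Oligotroph (if several groups qualify, the one with the
largest T̄ − N̄; a survey has one warm-oligotrophic extreme); T̄ < 0 ∧
N̄ > 0 → ranked by |N̄|, strongest = Low Temperature Copiotroph, next =
Low Temperature.  A single qualifying cold group takes the base Low
Temperature name, since "copiotroph" is a comparative label.  Groups
failing all rules stay unnamed.  Names derive only from the sign rules,
never from input labels.

**NMDS.**  Samples are ordinated from Bray–Curtis dissimilarities
(Σ|a−b| / Σ(a+b)) by non-metric SMACOF: iterative majorisation with
isotonic regression on dissimilarity ranks, minimising Kruskal stress-1,
tolerance 1e-6, 300 iterations.  One restart starts from the classical
(Torgerson) scaling solution and is deterministic; 7 further restarts are
random, seeded; the lowest-stress configuration wins.  The deterministic
first restart makes single-init runs permutation-equivariant and usually
already optimal; the random restarts guard against isotonic local minima.

## Synthetic data: what it emulates and what it does not

The generator exists so that recovery claims are checked against known
truth, at desk scale.

**Clade scenes.**  Sequences evolve down a generated tree by per-site
substitution (uniform over alternative residues).  Per-edge rates are set
so pairwise identities land on nested bands — defaults 97 / 85 / 55%
protein identity within species / within genus between species / between
genera, with nucleotide bands 97 / 80 / 55 — using the multiplicative
approximation identity(path) ≈ Π(1 − r_edge).  Within the clade simulator
substitution counts are fixed to round(rate × length) rather than
binomially sampled: the planted identities must respect their partition
bands on every run (this is asserted after generation), and exact counts
remove the sampling tail that would occasionally push a within-species
16S pair below the 98.8% cut-off.  The 16S gene evolves at 1/5 of the
genomic substitution rate, mirroring its relative conservation, so the
98.8% species band co-occurs with the AAI bands.  Proteins and genome
evolve independently at consistent band levels — the tests need controlled
identity, not a codon model.  Default scene: 3 genera × 2 species × 2
genomes; genomes 8 kb, proteomes 16 × 150 aa, 16S 1.2 kb.  These sizes are
chosen so a full 12-genome signature matrix builds in ~20 s while binomial
noise on any realized identity stays far inside its band.

**Community scenes.**  Genomes are independent random sequences (k-mer
recruitment is then unambiguous).  Abundance follows
log a_gs = Σₚ β_gp·z(env_ps) + ε, ε ~ N(0, σ = 0.2), closed per sample;
reads are drawn multinomially ∝ a·length from uniform positions on either
strand.  β follows three sign templates with strong effects at |β| = 1:
the Low Temperature group is cold-water and nutrient-associated, the Low
Temperature Copiotroph repeats that sign pattern with uniformly stronger
magnitudes (the two groups differ by effect size, as "copiotroph" is
comparative), and the High Temperature Oligotroph inverts the nutrient
signs and favours warm, autotroph-dense water.  The environmental table
has a temperature gradient with nutrients (nitrate, nitrite, phosphate,
silicate) anti-correlated with temperature — the oceanic pattern — and
independent noise on the remaining parameters.  Default survey: 30
genomes (3 × 10), 40 samples, 4,000 reads per sample, error-free reads.

**What passing means.**  Recovery at ARI 1.0 on these scenes shows the
pipeline's inference is correct when its assumptions hold: clean
assemblies, divergence inside the bands, reads without error, niches that
really are log-linear in measured parameters.  Real surveys add read
error, conserved regions shared across distant genomes, abundance
compositionality, and environmental collinearity beyond the planted
temperature–nutrient axis; the synthetic results bound none of those
effects.

## Numerical conventions and degenerate inputs

- Identity computations: internal gaps are mismatches; terminal gaps are
  excluded (ends-free 16S mode only).  Diagonals of signature matrices
  are exactly 100; symmetry is validated to 0.1 absolute.
- Ambiguity codes other than N are collapsed to N on input with a logged
  warning; k-mers and GGD seeds containing N never match; N is excluded
  from GC content on both sides of the ratio.
- Tie-breaks are deterministic everywhere (lexicographic identifiers), so
  equal inputs give byte-identical outputs.
- All-N genomes, empty FASTA files, duplicated identifiers, k even or out
  of [15, 63], p-values outside [0, 1], all-zero abundance vector pairs,
  and asymmetric dissimilarity matrices raise named errors instead of
  propagating NaN.

## Known limitations

- The k-mer recruiter is exact-match: reads with errors in every k-mer
  window of a region recruit weakly; at 31-mers a 1% error rate loses
  roughly a quarter of k-mers per read.  For abundance at survey scale
  this biases all genomes similarly, but it is not an aligner.
- GGD here is one member of the dDDH formula family (identities over HSP
  columns); absolute values can differ from other members by a few
  percent near the 70% bound, though the self = 100 / unrelated ≈ 0
  anchors hold.
- Monophyly refinement trusts the input tree; a wrong tree produces
  confidently wrong genus splits.
- The ecogroup count k is a parameter, not inferred; the default 3 encodes
  the expected warm/cold × nutrient structure of marine surveys.
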