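# Methods

This note documents the statistical procedures, the synthetic-study model
behind the test suite, and the numerical choices made where the design was
genuinely open. Problem sizes quoted here are the ones the shipped tests
and `scripts/acceptance.py` actually run.

## Differential-expression classification

A gene's DE category is a function of its log2 fold change (LFC) and
BH-adjusted p-value. Significance gate: padj ≤ 0.01; a missing padj (as
produced by independent filtering in count-based DE tools) is treated as
non-significant. Interval boundaries are taken literally from the category
definitions: `strongly activated` requires LFC > 2.0 strictly, so LFC
exactly 2.0 with significance falls in `weakly activated` (1 < LFC ≤ 2);
repression is symmetric. Boundaries are measure-zero for real data; the
convention only matters for constructed inputs and is pinned by tests.

Pair sorting: with exactly one significant member, the non-significant
member's LFC is replaced by 0 for ordering — equivalently, a significant
activated gene is always the high member and a significant repressed gene
the low member, regardless of the partner's raw LFC. The recorded
`sort_basis` distinguishes whether this override changed the raw-LFC order
(`fdr_override`) or not (`zero_replacement`). Exact key ties are broken
lexicographically by gene id so results are independent of member input
order.

DE_PKA membership: high member `strongly_activated` AND low member in
{no change, weakly repressed, strongly repressed}. "Repressed" includes
both repression grades.

## Stress surrogates and DE_Stress

Per-species stress LFC matrices are z-normalized with the **pooled** mean
and standard deviation over all conditions jointly (population
denominator, which makes renormalization exactly idempotent) — not per
column, so relative condition strengths survive. PKA-like conditions are
those whose Pearson correlation with the measured PKA-inhibition LFC
exceeds 0.75 in the focal species and 0.65 in the non-WGH reference,
computed over pairwise-complete observations (microarray matrices carry
missing values; conditions sharing < 10 genes with a PKA vector are
skipped with a warning). Whether correlations are computed before or
after z-normalization is immaterial — Pearson r is affine-invariant — so
the implementation normalizes first.

`LFC_est` is the per-gene mean of the normalized LFC over however many
selected conditions are observed (minimum-conditions knob, default 1).
DE_Stress selects pairs with higher member > 1.5, lower member < 0.9 and
difference > 0.9 on LFC_est; `cutoff_overlap_curve` tabulates |DE_Stress|
and its overlap with a reference set over a cutoff grid, the device used
to choose the low-member cutoff (the overlap plateaus once the cutoff
clears the noise ceiling of true low members).

## Promoters and motifs

Promoters are the 700 bp upstream of the gene feature's 5' end (gene-level
annotations; no CDS sub-features needed), clipped at the scaffold edge and
flagged; minus-strand promoters are reverse-complemented so every promoter
reads toward the start codon. Neighboring genes are ignored — promoters may
overlap adjacent gene bodies. The 3'-extension utility adds 400 bp past
each gene's stop (strand-aware, clipped); it is additive, not idempotent,
unless clipped.

Motif scanning is exact matching of degenerate patterns (STRE = CCCCT;
TATA = TATAWAWR in IUPAC codes), implemented with a lookahead regular
expression so overlapping matches are all counted; `N` matches nothing.
Scanning is single-stranded on the stored promoter orientation — the
promoter set already fixes an orientation per gene, and no strand rule is
part of the published procedure — with a `both_strands` option (offsets
deduplicated) for sensitivity analyses. Offsets are 0-based from the
promoter's 5' end; distance to the start codon is
`promoter length − offset − pattern length`.

## Enrichment statistics

Every enrichment question is a 2×2 table (set membership × property);
one-sided p-values are exact hypergeometric tail sums (scipy's
distribution machinery; the suite checks them against full enumeration to
1e-12). By default the background **includes** the test set — the test
compares the property rate within the set to the rate in the whole
background — with an exclusive mode behind a flag. Mid-p corrections are
off. BH adjustment is the step-up rule
`q_i = min_{j ≥ rank(i)} m·p_(j)/j`, applied within one family per
(analysis × direction); enrichment and de-enrichment are separate
families. GO terms are transferred to the second species as the union of
its orthologs' term sets (a gene with two orthologs gets both); genes with
no ortholog leave the GO universe.

## Orthology, name mapping, synteny, filters

Pillar tables carry two slot columns for the focal post-WGH species and
one (possibly comma-separated) slot per other species; two focal entries
make an ohnolog pair, one makes a singleton, more than two is a format
error. Name mapping scores global protein alignments at match +1,
mismatch −1, gap open −0.5, gap extend −0.1 (a length-L gap costs
open + (L−1)·extend; terminal gaps are penalized). Candidates are the top
5 targets at or above a species-specific threshold — thresholds are
config values, not constants, because they are dataset-specific. The
retention rule keeps the top candidate and each next candidate while the
score drop is **< 10 points from the previously retained candidate**; the
"drop from the top candidate" reading is available as `drop_from="top"`.
Score ties order lexicographically by target id for determinism.

Synteny assignment automates what was originally manual curation: a
post-WGH gene is assigned to the lineage of whichever pair member shares
more orthogroups among the ±8 flanking genes (windows truncated at
scaffold edges), requiring strictly greater support of at least 2 — a
floor chosen to suppress single-gene coincidences; ties are undetermined.

The promoter-subset filters remove DE pairs with (1) zero STREs in the
high member's promoter, (2) duplicate orthologs in more than 8 non-WGH
species, (3) no non-WGH ortholog at all. The predicates are independent
and applied in one pass, so any order gives the same retained set; the
report names every filter each removed pair failed, and pairs whose high
member lacks a promoter scan are counted separately.

## Clustering

STRE-count profiles (rows = pairs, columns = the designated non-WGH +
outgroup species; duplicated orthologs contribute their mean count) are
compared by correlation distance over pairwise-complete columns; rows
sharing fewer than 3 observed columns, or constant on them, get the
neutral distance 1 (zero correlation). Trees are average-linkage (UPGMA);
flat clusters come from the inconsistency criterion at t = 1.1 with
depth-2 windows (a merge plus its child merges). The inconsistency sd
uses the **sample (n−1) denominator**, matching the hierarchical-
clustering dialect of the standard scientific-Python stack this procedure
comes from; the population denominator is a config switch. GO clustering
builds one 0/1 coordinate per (curated term × pair member) plus a
metabolic-map indicator valued 4 — large enough to dominate Euclidean
distances and force map pairs together — and applies Ward linkage.

A property of the inconsistency criterion worth knowing: a merge whose two
child merges sit at near-equal heights has a coefficient ≈ 1.155 (its
maximum for a 3-height window) regardless of scale, so at t = 1.1 noisy
but homogeneous blobs fragment into many flat clusters. This is inherent
to the criterion, not a defect; consequently the class-recovery experiment
below cuts the same UPGMA tree at the known number of planted classes,
while the inconsistency cut remains the default flat-cluster op and is
tested on constructed fixtures where its behavior is unambiguous.

## The synthetic study

The generator emulates the study's input universe from one seeded config.
`n_pillars` ancestral loci pass through the WGH; a fixed fraction
(`round(frac·n)`, exact so planted counts are deterministic) retains both
focal copies. Non-retained pillars keep the ancestrally surviving copy,
chosen once and shared by all post-WGH species, which is what makes
flanking-gene content informative for synteny. Gene order follows pillar
order within two homeologous subgenomes, genes are placed left-to-right
with exponential intergenic gaps (mean 300 bp above a 210 bp floor, so
same-strand promoter windows never collide), and strands are random.

Promoter base composition is yeast-like (A/T 0.31, C/G 0.19), giving
~0.28 chance CCCCT occurrences per 700 bp. Planted Poisson rates —
background 0.35, induced high members 1.1 — were set so total means are
~0.63 and ~1.35 STREs/promoter (~45% and ~75% of promoters with ≥ 1),
the regime reported for real yeast promoter sets. Planted motifs occupy
non-overlapping genomic slots (rejection sampling, ≤ 50 tries) so no
planted occurrence destroys another; truth labels record actual planted
offsets, and detection is checked as a superset (chance matches are
legitimate extras). Setting the induced rate to 0 makes induced promoters
indistinguishable from background, the documented degenerate case.

Expression: planted high members draw LFC ~ N(5, 0.3) with padj
10^−U(4,10) and basal rlog ~ N(4.4, 0.5); their partners and all
background genes draw LFC around 0 (sd 0.3) with rlog ~ N(6.4, 0.5). A
shared environmental-stress-response component (15% of non-DE pillars,
effects ~ N(0, 2.5), conserved across species) provides the cross-species
correlation structure. Adjusted p-values are simulated directly and track
the **true** planted effect — genes with a real effect get small padj,
pure nulls get Uniform(0,1) — because only threshold behavior matters
downstream and a count model would re-derive machinery that is
deliberately out of scope. Stress matrices contain 5 PKA-like conditions
built as r·z(PKA vector) + √(1−r²)·noise (r = 0.8 focal, 0.7 non-WGH),
2 decoys at r = 0.5, and pure-noise conditions, with 5% missing cells.
Microarray replicate matrices add replicate-specific location/scale
distortions and 5% duplicate probes — exactly what quantile normalization
and median collapse undo.

For cross-species STRE profiles, each non-WGH species gets a lognormal
(σ = 1.0) multiplier on a base rate of 0.8 — species genuinely differ
widely in promoter STRE abundance — and each planted DE pair carries a
mechanism label: `post_wgh_gain` (STREs only in the focal high member;
non-WGH orthologs at species background) or `pre_wgh_gain` (ZT-branch
orthologs at rate 4.0; KLE and outgroup orthologs depleted to 5% of
background, the signature of a gene that was not ancestrally
stress-regulated outside the ZT lineage). These settings were fixed from
a pre-registered parameter sweep before the tests were written.

What the generator does **not** emulate: read-level noise and count
overdispersion, probe-level microarray artifacts, real promoter sequence
composition beyond mononucleotide frequencies, gene loss biased by
function, phylogenetic correlation between species, or motif turnover
within a lineage. Passing tests therefore demonstrate that the procedures
recover the structure they are defined on — not that the biological
conclusions of any particular dataset are correct.

## Problem sizes and calibration experiments

* DE_PKA recovery: 2000 focal genes (1800 pillars, 200 pairs, 50 planted
  DE), 200 seeds in the test suite (60 in the acceptance script):
  sensitivity 100%, ≤ 1 false pair in ≥ 95% of seeds.
* STRE contrast: ~200 induced vs ~4000 background promoters, Fisher
  p < 1e-6 per seed; measured fractions ≈ 75% vs ≈ 48%.
* Profile clustering: 41 profiled species, ~40 DE pairs per seed, mean
  two-class adjusted Rand ≥ 0.8 over 20 seeds.
* Oracle equivalence: scanner vs sliding window on 10,000 random
  sequences; Fisher vs exact enumeration over strided tables with margins
  ≤ 30 at 1e-12; alignment vs Gotoh DP on 500 pairs ≤ 50 aa; UPGMA/Ward
  vs brute agglomeration on 500 matrices n ≤ 8.
* BH calibration: m = 1000, 1000 uniform-null repetitions, mean
  false-rejection proportion within Monte-Carlo error of ≤ 0.05. The
  exact-test uniformity check uses randomized p-values, the standard
  construction for discrete tests (raw exact p-values are super-uniform
  between atoms and fail any continuous-uniform test by design).

## Known limitations

* The synteny scorer approximates curated judgment; at small genome sizes
  (< ~500 loci) chance flank overlap inflates support, so its null
  behavior is only meaningful for realistically sized genomes.
* Name mapping scores all query-target pairs (quadratic); fine for the
  intended thousands-of-proteins scale, not for metagenome-scale inputs.
* The inconsistency flat-cluster criterion fragments homogeneous noisy
  data (see above); treat its cluster count as descriptive.
* Quantile normalization requires complete replicate rows; rows with
  missing replicate values should be dropped or imputed upstream.
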