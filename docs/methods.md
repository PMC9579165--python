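# Methods

This note records the models, parameter choices and numerical conventions
behind `proteoscan`, and what the synthetic-data generator does and does
not emulate.

## The screen and its data model

A multiplexed knockout screen quantifies proteins across thousands of
strains with TMT 10plex labeling: each MS run holds up to eight knockout
samples, a technical spike-in reference on the 127C channel (one frozen
wild-type lysate shared by all runs) and a biological wild-type control on
130N (grown alongside the knockouts on the same plate). Intensities are
processed throughout on the log2 scale; a raw reporter intensity of zero
is a non-quantification and is stored as missing, never as zero. TSV/CSV
formats use "NA" or empty cells for missing values; the channel vocabulary
is fixed to the ten TMT10 label names.

## Normalization

Three stages, all operating on observed values only (no imputation):

1. **Spike-reference**: per run, subtract the spike-in channel's log2
   value per protein. Because the spike-in is the same material in every
   run, this cancels per-(protein, run) measurement effects; proteins
   without a spike-in value in a run are removed for that run, since no
   reference exists for them there.
2. **Sample median centering**: each sample's median over observed
   proteins becomes 0. The screen's design assumes equal total protein
   load per channel.
3. **Protein-median adjustment**: each protein's per-run median is shifted
   to its global median (computed over non-technical samples). This is an
   exact identity after the shift — the per-run medians of every protein
   are equal — and removes batch structure the spike-in cannot carry, such
   as effects of the plate the cultures grew on (the spike-in was never
   grown on those plates). Technical channels are identically zero after
   stage 1 and are dropped after stage 3.

"Average intensity" in the stage descriptions is implemented as the
median; the median is what makes stage 3 an exact identity and is robust
to the missingness structure.

**Diagnostics.** The bias coefficient is the mean over proteins of the
fraction of the protein's variance explained by run membership (one-way
between/total sum of squares over observed, non-technical values). There
is no canonical closed form for such a coefficient; this definition was
chosen because it is simple, lies in [0, 1], and is monotone in batch
severity. Fidelity is the median over samples of the Pearson correlation
between pre- and post-normalization columns. Alternative normalizers
(ComBat/SVA-family) are deliberately not re-implemented; any externally
normalized matrix can be scored with the same `batch_bias_metrics`.

A note on idempotence: stage 2 and stage 3 are each exactly idempotent,
and stage 3 re-applied after the full pipeline is a no-op. The full
three-stage pipeline applied a second time is not *exactly* the identity
(stage 3's protein-specific per-run shifts can move sample medians by a
small amount), but the second application changes values only negligibly;
the test suite bounds the RMS change.

## Differential expression

The screen has one sample per knockout, so the null distribution per
protein is estimated from the pooled wild-type biological replicates:
mean μ_p and sample SD σ_p (n−1 denominator) over observed WT values.
Proteins observed in fewer than `min_n = 10` WT samples are untestable;
zero-variance proteins are excluded rather than assigned infinite
z-scores. Each knockout value gives z = (x − μ_p)/σ_p and a two-sided
normal p-value; Benjamini–Hochberg correction is applied **per strain**
across that strain's tested proteins (the per-strain convention matches
how altered-protein counts are reported per knockout), and q < 0.05 calls
a protein altered. With ~24–460 WT replicates the normal approximation to
the estimated-σ null is adequate; the null simulations in the acceptance
suite confirm the altered fraction stays well below the nominal level.

Replicate mode uses the standard two-sided Student t-test with the
thresholds |log2FC| > 0.2 and p < 0.03. When exactly one of a strain's
four replicates is missing for a protein, the missing value is
reconstructed by an EM iteration over a low-rank (probabilistic-PCA)
model of the replicate matrix: missing cells start at column means, the
matrix is repeatedly SVD-reconstructed at a rank chosen automatically
from the complete rows (singular values above the optimal hard threshold
for white noise), and observed cells are never modified. Rows with two or
more missing replicates are left missing. Imputation is used only in
replicate mode, never in the screen.

Labeling QC reports the percentage of evidence records with no TMT label
(under-labeling) and with a label on H/S/T/Y side chains (over-labeling),
contaminants excluded.

## Clustering

**Input.** `coexpression_input` restricts to knockout samples, drops
proteins with fewer than 3 observed values or zero variance, z-scores each
protein (population SD, n denominator — so a 3-vector maps to ±1.2247)
and winsorizes at |z| ≤ 3. Winsorizing bounds the leverage of strains
with extreme proteome remodeling, which otherwise dominate Euclidean
distances; it is a standard robust-clustering step and markedly
stabilizes module recovery on heavy-tailed screens.

**SOM.** The self-organizing map is implemented in-package: rectangular
grid, Gaussian neighborhood, learning rate and radius decaying linearly
over epochs (defaults 0.5→0.01 and half the larger grid dimension→0.5,
500 epochs), online updates in a seeded random order, codebook initialized
from randomly drawn items. Distances are masked Euclidean normalized by
the number of observed dimensions, and updates touch observed dimensions
only, so missing values need no imputation. Best-matching-unit ties break
to the lowest unit index; training is deterministic given the seed. Grid
defaults are 12×12 for proteins and 11×11 for strains (at desk scale the
examples use smaller grids sized to the number of planted modules).

**Cluster filter.** A cluster's quality is its mean member distance to
the unit codebook; clusters strictly below the 75th percentile of all
item distances are kept. Strain-axis clustering works on the columns of
the same per-protein z-score matrix (so unperturbed wild-type samples sit
near the origin and group together); clusters containing any wild-type
sample are removed before the percentile filter, which is then computed
over the surviving items' distances.

**Benchmarks.** The connectivity score of a cluster is its number of
within-cluster network associations (combined score strictly greater than
150) divided by the mean count over size-matched random protein sets
(default 1000 draws); the empirical p is (1 + #{null ≥ observed})/(n+1).
Genetic-interaction benchmarking compares within- versus between-cluster
profile correlations with a two-sided Mann–Whitney test. Gene-set
enrichment of cluster members is an upper-tail hypergeometric test with
BH correction across sets. The preranked enrichment statistic along a
strain ranking is the unweighted Kolmogorov–Smirnov-style running sum;
permutation p-values place the hit set at random, and small instances can
be enumerated exhaustively for exact p-values.

## Paired transcriptome–proteome analysis

Transcript matrices are CPM-based; CPM values below the global lowest
quantile are removed before log2 transformation. Fold changes versus the
wild-type replicate mean are computed per layer with Student t-tests;
significance flags are |log2FC| ≥ 0.6 and p ≤ 0.005 (transcript) and
|log2FC| > 0.2 and p < 0.03 (protein). Correlation measures use
pairwise-complete observations with at least 3 shared points; per-gene
p-values come from t = R√(n−2)/√(1−R²). Strain pairs are counted as
ordered pairs (i ≠ j), so 94 strains give 8742 pairs.

Protein-only regulation: per gene, the number of strains where the
protein flag is set, the transcript flag is not, and both layers are
measured ("stable mRNA" means measured and unflagged, not unmeasured).
Genes with a nonzero count are ranked (ties broken by gene id) and the
top half (ceiling) kept. PAM clustering is the classic deterministic
BUILD + SWAP k-medoids (swap gains evaluated by the nearest/second-nearest
decomposition), Euclidean distance, restricted to strains with complete
fold changes over the selected genes; k ∈ [2, 10] is chosen by maximal
average silhouette width, ties toward the smaller k.

## Codon optimality

Per-gene codon usage is the percentage of each of the 64 codons (stop
codons included) among the gene's codons; profiles sum to 100 exactly.
Group usage is the **mean of per-gene percentages** (each gene weighted
equally, regardless of length), and the group comparison is the log2
ratio of up-group over down-group means; codons with zero mean usage in
either group are reported missing rather than infinite. Per-strain codon
matrices apply the same comparison to each strain's own up/down
protein-only gene groups. The reporter comparison square-root-transforms
fluorescence intensities (variance stabilization toward normality) before
a two-sided Student t-test, reporting the fold change of arm means on the
original scale.

The packaged `default_codon_table` is a synthetic stand-in: one optimal
codon per synonymous family with at least two members (lexicographically
first), single-codon families and stops non-optimal. Real analyses should
load an empirically measured optimality table.

## Growth fitness

OD600 is z-scored within each 96-well plate (n−1 SD; zero-variance plates
yield missing z with a warning). Strains are ranked by altered-protein
count (ties by strain id) and divided into consecutive bins of 100, the
remainder merged into the last bin — 3308 strains give 33 bins with the
last holding 108. The growth comparison is a tie-corrected Kruskal–Wallis
test of the most-remodeled bin versus all other strains (a joint
all-bins variant is available behind a flag). Desk-scale analyses use a
proportionally smaller bin size (30 for 120 strains).

## The synthetic-data generator

The generator defines the study conditions for every test: a screen of
800 proteins, 120 knockouts and 24 wild-type biological replicates over
24 runs on 2 plates — small enough for continuous testing, large enough
for stable error-rate estimates. Protein log2 intensity is additive:
base abundance (N(20, 2²)) + module loading (0.5) × a per-sample latent
factor for the protein's module (10 modules) + the knockout effect +
per-(protein, run) and per-(protein, plate) batch shifts (SD 0.5 and 0.3;
no quantitative magnitudes are published for such shifts, so these are
free parameters of the config) + noise (SD 0.25). The technical spike-in
carries the run shift but no plate shift or module factor, which is
exactly why stage 1 of normalization removes run structure and stage 3
the rest. Missingness is MNAR through a logistic link on standardized
base abundance (slope −1.5, intercept −2.2, ≈17% missing overall) so
abundant proteins are quantified more often.

Knockout effects are sparse and heavy-tailed: each strain alters a
fraction of the proteome equal to 0.05 × a mean-one lognormal factor
(σ = 1), with effect sizes N(0, (6 σ_WT)²) where σ_WT is the wild-type
biological SD. The lognormal dispersion reproduces the empirical shape of
remodeling distributions — most strains perturb few proteins, a tail
remodels hundreds — and is what makes ranking strains by measured altered
counts meaningful. Growth couples to remodeling: OD600 = 1.2 + N(0,
0.05²) − 0.02 × max(0, altered − 30), floored at 0.05.

The paired-omics generator (1706 genes × 94 strains × 4 replicates)
assigns genes to classes: 600 up-translational and 600 down-translational
(transcript fold change identically zero; protein fold change ± gene
amplitude N(1, 0.2²) × strain multiplier N(1, 0.3²)), 306 transcriptional
(per-(gene, strain) transcript fold changes, active with probability
0.15, N(0, 1.2²), propagated to the protein layer) and 200 null;
replicate noise SD 0.25 on both layers. These defaults make the
protein-only selection keep ~790 genes across 94 strains, mirroring the
scale at which the regulation-archetype clustering operates. The ORF
generator draws amino acids uniformly and synonymous codons with weights
tilted by exp(±bias) toward/away from optimal codons for the up/down
classes (uniform elsewhere), lengths 100–300 codons, ATG start and a stop
codon end. The annotation-network generator connects within-module pairs
at one rate and all other pairs at a background rate, associated edges
scored uniformly in 151–1000 plus a small sub-threshold decoy fraction.

**What the generator does not emulate**, hence what passing tests do not
show about real data: peptide-level quantitation and roll-up, reporter
ion ratio compression, isotope impurity, correlated effect signatures
(knockout effects are independent across proteins, so co-expression
modules and differential responses are decoupled), shared transcriptional
programs across strains (the strain-pair transcriptome/proteome
meta-correlation therefore centers near zero rather than at the positive
values seen in real paired data), and real codon-optimality tables.

## Numerical conventions and degenerate inputs

Missing values are NaN end to end; medians, means, SDs and correlations
use observed values only. Z-scoring of expression rows uses the
population SD; growth and WT-reference SDs use n−1. Pairwise correlations
require a configurable minimum overlap (default 10 for expression rows, 3
for fold-change vectors). BH correction is the standard step-up
(delegated to statsmodels and cross-checked against a brute-force oracle
in the tests). Zero-variance rows, empty groups, missing controls,
sub-minimum replicate counts and malformed codon tables raise typed
errors (`ValidationError`/`FormatError`) naming the offender; partially
malformed FASTA inputs load the valid records and report the rest.

## Problem sizes used in tests

The default test and acceptance runs use the generator defaults above
(800×120×24 screens; 20 null screens for the error-rate check; 1000
random draws for connectivity nulls; SOM at 12 units × 100 epochs for
module recovery). These sizes give stable Monte-Carlo estimates while
keeping the whole suite around a minute.
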