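# Methods

This note records the models, parameter choices, numerical policies and
known limitations behind `homoevol`.  It is written for a reader who wants
to know exactly what each number the package prints means, and what passing
the test suite does and does not demonstrate about real data.

## The analysis model

The package treats a recent allotetraploid as two interleaved diploid
subgenomes whose chromosomes come in declared homoeologous pairs.  All
downstream biology is phrased as contrasts *within* homoeolog pairs, which
removes most between-sample nuisance variation by construction.

### Homoeolog identification

Anchors (putative homologous gene pairs between one chromosome pair) are
chained by dynamic programming over gene-order ranks.  A chain may extend
when both rank gaps are ≤ `max_rank_gap` (default 25, the conventional
MCScanX-style gap bound) and both ranks move strictly monotonically; the
chain score is `anchors − 0.1 × total gap`.  Chains are extracted greedily
(best chain first, each anchor used once) and chains shorter than 5 anchors
are discarded.  Only blocks between declared homoeologous chromosomes yield
homoeolog calls; homoeology between chromosomes is an assembly-level fact
the caller supplies, never inferred.  Anchor generation itself (homology
search) is out of scope: anchors come from the simulator truth table or a
user-provided table.  When several chains tie, the chain whose first anchor
has the smallest rank on the first chromosome wins, making output
deterministic; equal-score optima may differ from other implementations in
membership but never in score.

### Ka/Ks

The estimator is Nei–Gojobori (1986).  Per sense codon, each position
contributes a synonymous-site fraction computed over its non-stop single-
nucleotide neighbours, so every codon carries exactly 3 sites.  Differences
between two codons are averaged over all minimal substitution pathways;
pathways through a stop codon are excluded (when no stop-free pathway
exists — which cannot happen for the pairs the test grid covers — all
pathways are used with stop steps counted nonsynonymous).  Distances are
Jukes–Cantor corrected; p ≥ 3/4 is reported as saturated (`None`), never as
a sentinel number, and undefined ratios (Ks = 0) are likewise `None`.
NG86 was chosen over codon-model estimators because it is exactly checkable
by enumeration and adequate in the low-divergence regime of recent
homoeologs (Ks ≈ 0.1); the estimator is a plain function, so a codon-model
variant can be swapped in.  Codon alignment is protein-guided: global
Needleman–Wunsch on the translations (BLOSUM62, gap open 10 / extend 1)
back-translated to codons, so gaps always occupy whole codons.  Ambiguous
bases make a codon column ignored; only the standard genetic code is
supported.

Ks distributions use a Gaussian KDE with Silverman bandwidth on Ks in
(0, 5]; values above 5 are saturated and excluded, zeros are excluded as
uninformative for dating.  Peaks are KDE local maxima with prominence at
least 5% of the maximum density.  A point-mass sample (zero variance) would
make the KDE singular; it is reported as a single narrow Gaussian at the
common value.

### Expression bias

TPM is the expression unit (rate = count/length scaled to 10⁶ per sample);
a gene is *expressed* if it exceeds 0.5 TPM in any sample, and a pair is
*high-confidence* when both members are expressed.  The differential test
is a self-contained negative-binomial Wald test of homoeolog A vs B over the
same samples: median-of-ratios size factors from the full count matrix,
per-pair dispersion α̂ by method of moments ((s² − m)/m², clipped at zero,
averaged over the two genes, floored at 10⁻⁸), log2 fold change from
normalized means with pseudocount 0.5, and a delta-method standard error
under Var(X) = μ + αμ².  No multiple-testing correction is applied by
default, mirroring raw-p thresholds throughout; a Benjamini–Hochberg helper
exists.  Boundary policy: p = 0.05 is significant for category assignment
(the no-difference category is p > 0.05); the grouping χ² uses p < 0.05.
FC is the linear max/min fold change (≥ 1), so "FC ≤ 2" means
|log2FC| ≤ 1.

The pooled analysis treats all 30 samples as replicates rather than summing
them; with tissue structure present the moment dispersion absorbs the
between-tissue variance, making the pooled test conservative for genes with
strong tissue patterns — a deliberate trade-off that mirrors running a
two-group NB test without covariates.

Chromosome grouping counts, per declared pair, the significant ≥ 2-fold
pairs by the side hosting the higher-expressed copy and tests 50/50 by
Pearson χ² (df = 1).  Significant pairs are SA (majority side) / SB;
non-significant are SC/SD; an exact tie puts SC on the lexicographically
smaller chromosome; a pair with zero significant genes is flagged
unclassifiable.  The TE stratification assigns each such pair to one of four
strata by whether each member has a TE strictly within 2 kb (a distance of
exactly 2000 bp counts as "no").

### Dynamics

Per-tissue scopes are tissue × variety (10 scopes), not tissue collapsed
over varieties.  A scope's signed log2FC is zeroed when p ≥ 0.05 (the
boundary is zeroed — "no difference means FC = 0").  The change score is the
maximum absolute difference between any scope fold change and the pooled
fold change; a max statistic was preferred over a mean because "most
variable anywhere" is the notion of interest.  Dynamic and stable sets are
the top and bottom ⌊0.10 n⌋ by change score over all high-confidence pairs,
ties broken by pair ID.  Mann–Whitney tests are exact for combined n ≤ 20
without ties, otherwise normal with tie and continuity corrections.

### LTR retrotransposons

Classification is by translated homology of the candidate's flanks against
a reference Gag-Pol protein (six reading frames, local alignment): coverage
≥ 95% at ≥ 30% identity on a flank → intact ("complete" internal domain);
≥ 50% coverage on one side → truncated; neither → solo.  Insertion age is
T = K/(2μ) with K the Jukes–Cantor distance between the globally aligned
5′ and 3′ LTRs (p-distance over non-gap columns) and μ = 1.3 × 10⁻⁸
substitutions · site⁻¹ · year⁻¹; p ≥ 3/4 is saturated (age undefined).
Clustering is single-linkage transitive closure over pairs whose LTRs
mutually cover ≥ 70% at ≥ 60% identity (identity over terminal-gap-trimmed
columns); solo/truncated elements join an intact element's cluster only by
meeting those same thresholds — a similarity floor the "most similar intact
element" attachment rule otherwise lacks.  Removal statistics report
genome-wide S:I, T:I and (S+T):I; the "S:I > 3" cluster share uses a strict
inequality and only clusters with ≥ 1 intact member in the denominator.
Gene-to-TE distances use interval arithmetic on 0-based half-open
coordinates (overlap = 0), computed through pyranges with the gap convention
normalized; genes on TE-free chromosomes get a missing value.

### SV breakpoints

Flanks are ±2 kb windows around both reference breakpoints of each SV,
edge-truncated and deduplicated; the null is 1000 uniformly placed 4-kb
regions per chromosome (overlaps permitted, seeded).  Two statistics are
reported per TE class: a 2 × 2 presence/absence Pearson χ² (primary,
uncorrected) and a Mann–Whitney on per-region TE counts.  The χ² assumes
regions are independent Bernoulli trials; when TEs are few or windows
overlap heavily, both fractions are driven by the same TE placements and the
test becomes conservative — the calibration experiments therefore use many
small TEs and well-separated breakpoints, matching the assumption the
statistic makes.  Translocation breakpoints use reference coordinates only.

### Coexpression divergence

Input is log2(TPM + 1) over expressed genes, one network per variety.  The
soft power β is the first integer in 1..20 whose scale-free fit (signed R²
of log10 p(k) vs log10 k over 10 connectivity bins) reaches 0.9, falling
back to the best-fit power with a warning — planted block-structured
modules are *not* scale-free, so on simulated data the fallback is the
expected path.  Adjacency is signed-hybrid (negative correlations zeroed)
raised to β with zero diagonal; TOM is the unsigned form
(Σ aᵢᵤaᵤⱼ + aᵢⱼ)/(min(kᵢ,kⱼ) + 1 − aᵢⱼ) with unit diagonal.  Module
detection replaces dynamic tree cut with a static cut of the average-linkage
tree at height 0.99 plus iterative eigengene merging at dissimilarity
< 0.25; module recovery on planted two-block data is the correctness surface
for that simplification.  Eigengenes are first principal components of the
gene-standardized module submatrix, unit-norm, sign-oriented to correlate
positively with members.  The divergence threshold is 0.5 × the median over
all distinct module-pair eigengene distances (strictly greater than the
threshold → divergent); pairs with a grey member are excluded with a count.

## The synthetic tetraploid generator

The generator's defaults are the study conditions for every test.  They
emulate: 4 homoeologous chromosome pairs of 1 Mb (chr01/chr02, ...), 200
genes per chromosome with 1–8 exons, 80% homoeolog retention in collinear
order with one planted ~15-gene inversion per pair; a 5-tissue × 2-variety ×
3-replicate design (30 samples); bias categories planted at 55/20/15/10%
(no-difference/lower/medium/higher) with |log2FC| of 0 / 0.8 / 2.0 / 3.5 —
inside the <2-fold, (2,8)-fold and ≥8-fold category bands; 10% of planted
effects restricted to one tissue; half the chromosome pairs biased with the
higher copy on the dominant side with probability 0.85; NB dispersion 0.05
(typical for bulk RNA-seq replicates) with lognormal(0, 0.1) library size
factors and lognormal base means (median 150 counts); coding divergence at
Ks ≈ 0.08 with Ka/Ks ≈ 0.3 (the scale of the most recent WGD); TE densities
of 3 / 1.5 / 0.8 per 100 kb (Gypsy/Copia/LINE1) with a 5× LINE1 boost in the
central 20% of each chromosome (pericentromere); TE suppression: 30% of
genes get a TE planted within 2 kb upstream and their expression halved; 75
LTR candidates (20 intact / 40 solo / 15 truncated) with exponential ages of
mean 2 Myr and flanks of 2 kb around a 200-aa Gag-Pol (scaled from the 15-kb
flank / full-length protein of real annotation pipelines); 82 SVs across the
five types in roughly the proportions seen in real tetraploid comparisons,
with breakpoint odds tilted 3× toward TE neighbourhoods by rejection
sampling.  All streams derive from `default_rng([seed, tag])`, so bundles
are byte-identical per config and each component is independently
deterministic.

What the generator does **not** emulate: realistic base composition or
isochores, read-level noise (counts are drawn directly), genuine dynamic-
tree-cut module shapes, gene conversion between homoeologs, indels in LTRs
(substitutions only, keeping the dating oracle exact), or assembly error.
Passing the suite therefore demonstrates algorithmic correctness and
parameter recovery under the stated model, not robustness to real-data
artifacts.

## Recovery definitions used by the tests

Chromosome-group recovery is defined as agreement between the grouping
computed from *estimated* DE and the grouping computed from the *planted*
truth table (planted categories and directions run through the same χ²
rule).  This isolates the pipeline's estimation error, which is the thing a
recovery test can bound: a truly balanced chromosome pair is mis-grouped at
the χ² type-I rate (~5%) no matter how good the estimates are, so recovery
against the planted direction *probability* cannot exceed ~0.95 per balanced
pair and is not a meaningful target.

Calibration experiments (DE type-I, SV-enrichment type-I) simulate pairs or
regions directly under the null that the statistic assumes — constant means
within scope, independent windows — because that is the regime in which
"rejection rate ≈ α" is the correct expectation.

## Problem sizes and runtime

Default problem sizes were chosen so a full pipeline run (1600 genes, ~650
pairs, 30 samples, 75 LTR elements, 82 SVs, two networks) completes in
about half a minute and the entire test suite in a few minutes on one CPU.
Ka/Ks in the pipeline samples up to 300–400 pairs deterministically; the
NG86 oracle tests run all 61 × 61 codon pairs and 1000 random 300-codon
pairs.

## Known limitations

- The NB Wald test has no shrinkage; with 2–3 replicates per scope its
  dispersion estimate is noisy and per-tissue calls are conservative.  An
  external DE table (e.g. from a shrinkage-based tool) can be imported.
- The static-cut module detector needs well-separated modules; on weakly
  separated real data dynamic tree cut would recover more structure.
- Gag-Pol detection uses one reference protein, not a profile database, so
  highly diverged internal domains (identity < 30%) would be missed.
- The chainer is O(n²) per chromosome pair — fine for tens of thousands of
  anchors, not for all-vs-all genome comparisons.
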