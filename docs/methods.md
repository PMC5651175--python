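# Methods

This note documents the models and procedures esomix implements, the
defaults and why, what the synthetic cohort does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Coordinates and formats

All genomic intervals are 0-based, half-open internally. SEG files are
read and written in the common 1-based inclusive dialect (configurable);
the conversion happens at exactly one site so it can be tested as a
self-inverse. Chromosome labels are normalized by stripping any `chr`
prefix. The MAF dialect is a minimal contract — chromosome, 1-based
position, ref/alt alleles, tumour and normal ref/alt read counts, caller
label, optional trinucleotide context and read-orientation counts —
because consortium MAFs vary; extra columns pass through untouched.
A built-in autosomal arm table at megabase resolution (GRCh37-like
centromere splits) is provided; acrocentric p-arms (13p, 14p, 15p, 21p,
22p) default to non-callable because arrays carry no reliable probes
there.

## Arm-level CIN calling

For each arm, `fraction_loss` is the summed intersection of segments
with log2 ≤ −0.15 with the arm interval divided by the *full* arm
length; `fraction_gain` analogously with log2 ≥ +0.15. Uncovered arm
bases therefore count toward neither state — the strict reading of
"fraction of the arm". Both the magnitude threshold (0.15) and the
altered-fraction threshold (0.80) are inclusive (≥), following the
"at least" wording of the rule. Fractions are base-pair weighted by
default; probe weighting is available where probe counts are more
trustworthy than physical extent.

A sample is SCNA-high iff it has ≥ 1 arm-level **loss** whose arm is
not in the exclusion set {18p, 18q, 21p, 21q}; gains never qualify.
The exclusion of chromosome 21 is applied to both arms — the
conservative, chromosome-level reading — and is configurable.

## Ensemble mutation filtering

Call sets are unioned on (sample, chromosome, position, ref, alt); read
counts for a shared variant come from the reporting caller with the
greatest total depth. Filters accumulate reasons rather than
short-circuiting, so the rejects table is a complete audit trail and
the evaluation order provably cannot matter. The normal-sample
conditions (alt reads > 1, VAF > 1%) combine with OR by default — the
stricter of the two grammatical readings — with an AND mode available.
Tumour requirements are inclusive minima (alt ≥ 2 AND VAF ≥ 5%). VAF
denominators use ref + alt counts only, since those are the counts the
records carry. The oxoG filter applies only to C>A / G>T variants with
orientation counts: flagged when the artifact-consistent orientation
(F2R1 for C>A, F1R2 for G>T) holds ≥ 90% of ≥ 3 oriented alt reads.
The upstream per-centre caller pipelines are consumed, not
re-implemented.

## Pathway scoring

Gene-level testing uses Kruskal–Wallis by ranks (mid-rank ties,
chi-square approximation with groups − 1 df), vectorized over genes;
an all-tied gene carries no information and returns p = 1. The unit
tests document the approximation: for n = 3 + 3 the chi-square p is
0.0495 while exhaustive permutation gives 0.1.

The pathway score is classic Fisher, S = −2 Σ ln pᵢ. (A −Σ ln pᵢ
variant only rescales S and cancels in the permutation null, so the
classic form is used.) P_s is the add-one estimator
(1 + #{S_rand ≥ S}) / (1 + n_perm) over n_perm = 10,000 random gene
sets of matched size drawn without replacement from all genes present
in the expression matrix (the natural pool; a pathway-union pool is
available). Per-pathway random streams derive from the master seed and
a CRC of the pathway name, making results independent of pathway order
in the GMT. With independent uniform gene p-values, S is χ²(2k) and the
empirical P_s matches the closed-form tail within Monte-Carlo error —
an identity the acceptance tests exercise.

## Silencing calls and the exact Fisher test

The original silencing calls were made by reading a
methylation-versus-expression scatterplot; as a reproducible surrogate,
a gene is silenced in a sample iff promoter beta ≥ 0.3 **and**
expression (log2(RPKM+1)) ≤ the 25th percentile of expression among
samples with beta < 0.1. The low-methylation samples supply the gene's
own expression reference; a gene with fewer than 5 such samples is
uncallable. All three constants are configuration. When several probes
map to one promoter, the probe most negatively correlated with
expression is used.

The two-sided Fisher exact test enumerates every table with the
observed margins (hypergeometric pmf via log-gamma) and sums point
probabilities ≤ that of the observed table, with a 1e-7 relative
tolerance so floating-point rounding cannot drop equal-probability
tables from the opposite tail — the minimum-likelihood convention of
mainstream statistical software.

## Clustering and integration

Expression feature selection keeps the top 25% most-variable genes
with mean > 10 RPKM. "Top 25%" is counted against all features in the
matrix, capped at the number passing the mean filter (both readings of
the ambiguous composition coincide whenever more than a quarter pass);
a flag switches the basis, and `top_n` reproduces count-based
conventions such as the 303 most-variable miRNA strands. Rows are
transformed log10(x+1) and z-scored (constant rows map to zeros, not
NaN). Samples are agglomerated by Ward's minimum-variance criterion in
the ward.D2 convention — dissimilarities squared inside the
Lance–Williams update — on 1 − Pearson correlation. scipy's `ward`
linkage on a condensed dissimilarity matrix implements exactly this
convention; a brute-force O(n³) agglomeration oracle confirms the merge
heights in tests. The number of clusters k is a required input (a
silhouette scan over k = 2..10 is provided as a diagnostic, since no
selection rule is prescribed).

Centroid classification restricts to genes shared with the centroid
set, transforms log2(x+1), median-centres each gene across samples, and
assigns each sample the centroid of maximal Pearson correlation, with
lexicographic tie-breaking (flagged) and a low-confidence flag below a
configurable correlation floor.

Integration clusters samples on the one-hot encoding of their
per-platform labels. SuperCluster scales each platform's indicator
block by 1/√(total column variance of the block) so each platform
contributes equal total variance; COCA scales each block by 1/√K_p,
equalizing the expected contribution of a random label against platform
granularity. Both formulas are this package's operationalization of
methods whose exact published adjustments are not available in detail,
and are documented as such. The weighted indicator matrix is clustered
with ward.D2 on Euclidean distance and cut at k; samples missing a
platform get zero rows there and an explicit missingness flag.

Two properties deserve note. First, with clean, coherent platform
labelings the integrated partition is exactly invariant to duplicating
a platform (within-group indicator distances stay zero); with noisy
labelings, duplication doubles a platform's vote weight and can move
genuinely tied samples, so exact invariance cannot hold there for any
per-block scaling. Second, recovery under label noise improves sharply
with platform count: with three platforms, samples corrupted in a
single platform form tied patterns that cap mean adjusted Rand index
near 0.82, while five platforms — the number of molecular data types a
full multi-omic study contributes — recover the planted 3-subtype
structure at ARI ≈ 0.99 under 10% per-platform noise. The recovery
tests therefore use five platforms.

## Mutational signatures

Catalogs use the standard 96 channels: six pyrimidine-strand
substitution classes × 16 flanking-base pairs; purine-strand records
are reverse-complemented (G>T at TGT → A[C>A]A). Records lacking a
valid context are tallied as rejects, and per-sample channel sums equal
the counted SNVs by construction.

Signatures are extracted by KL-divergence NMF with automatic relevance
determination: each candidate signature k has a relevance scale λ_k
shared by its profile column and exposure row under exponential priors.
MAP multiplicative updates run until the relative objective change
drops below 1e-7 (cap 3000 iterations); the prior shape is a = 10 and
the prior scale b is matched to the data mean, following the standard
L1-ARD construction. Components whose share of the reconstruction falls
below 1e-3 are pruned; the surviving count is the selected rank. Ten
random restarts are run and the best final objective kept. The
objective is verified non-increasing across updates in every test run.
Signature-to-truth matching in tests uses maximum-weight bipartite
matching on cosine similarity. Exposure fractions are per-sample row
normalizations of H; simple channel-mass summaries (APOBEC-context
fraction, C>A fraction, the T>G-with-3′T channel group that captures
A>C transversions at AA dinucleotides on the original strand) support
group comparisons via Wilcoxon rank-sum or Kruskal–Wallis tests.

## Synthetic cohort: what it emulates, and what it does not

The generator plants, under one master seed with independent
per-platform substreams (adding a platform never perturbs another):

* **Copy number** — subtype-structured arm events covering 95% of the
  arm at log2 ±0.3 with per-segment Gaussian noise (sd 0.03), neutral
  arms tiled around log2 0. Defaults sit well away from the 0.80/0.15
  decision boundaries, so recovery failures indicate logic errors, not
  unlucky draws; boundary behaviour is tested with deterministic
  fixtures instead.
* **Methylation/expression coupling** — non-silenced promoter betas
  from Beta(2, 40) (concentrated below 0.15), silenced from
  Beta(12, 4) (concentrated above 0.5) with expression multiplied by
  0.05. One gene is differentially silenced between subtypes
  (40% vs 5%); 50 extra marker probes, hypermethylated in one subtype
  and mapped to no gene, give the methylation platform subtype
  structure without touching silencing truth.
* **Mutations** — true VAFs from Beta(2, 5); tumour depth Poisson(200)
  and normal depth Poisson(130) (deep-exome scale, and deep enough that
  a single stray normal read is not mistaken for > 1% contamination);
  normal error rate 0.001; four callers with 5% dropout each; three
  planted false-positive classes (low-evidence, blacklist-site,
  oxoG-oriented), each removable by the matching filter. Contexts are
  drawn from the sample's signature mixture over three synthetic
  signatures (APOBEC-like, C>A-heavy, CpG C>T).
* **Expression** — log-normal baselines with three planted 30-gene
  pathways shifted 1.0 on the log10 scale between subtypes, plus null
  pathways.

It does **not** emulate: realistic genome coordinates or linkage,
indels, focal copy-number peaks, tumour purity or subclonality,
batch effects, or correlated noise between platforms. Passing recovery
tests therefore demonstrates correctness of the implemented decision
rules and estimators under their stated models — not robustness to the
full messiness of real tumour data.

## Problem sizes

Recovery experiments run at the sizes their properties reference:
200 samples for CIN recovery, 50 samples × ~100 true variants for the
ensemble, 40 + 40 samples for pathway power and silencing, 1,000 null
pathways × 1,000 permutations for type-I calibration, 20 replicates of
90 samples × 5 platforms for integration, and 50 samples × ~500
mutations for signature extraction. The full suite and the acceptance
script each complete in about a minute or two on one core.

## Known limitations

* The silencing thresholds operationalize a visual call; they were
  chosen on the synthetic model, not calibrated on array data.
* The COCA/SuperCluster weightings are surrogates (see above), and
  k must be supplied by the user.
* ARD-NMF rank selection depends on the pruning threshold and prior
  scale; heavily correlated signatures or very low mutation counts can
  merge components, as with any NMF-based extraction.
* Headline cohort statistics that depend on the original patient data
  (e.g. cohort-level alteration frequencies) are inherently outside
  what a synthetic cohort can reproduce; the acceptance script instead
  recomputes the statistics implied by printed contingency counts and
  the recovery metrics above.
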