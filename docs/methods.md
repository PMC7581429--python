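# Methods

This note documents the models and procedures implemented in `chdprio`, the
assumptions behind them, the parameters that matter, and what the synthetic
data do and do not emulate.

## Scientific setting

Hypoplastic left heart syndrome (HLHS) and related congenital heart disease
are genetically heterogeneous and likely oligogenic: no single locus explains
most cases, so gene discovery proceeds by aggressive filtering of a family's
genome against rarity, predicted function, and inheritance logic, followed by
orthogonal evidence such as transcriptome differences in patient-derived
iPSCs. `chdprio` implements two such workflows as reusable, tested code:

1. a **family-quintet prioritization cascade** (two unrelated parents, an
   affected proband, and unaffected siblings), and
2. a **case-control rare-variant burden framework** for candidate genes.

## Family cascade

### Quality rules

Variants enter the cascade only if, in order:

* **read depth** ≥ `min_depth` (default 10) in the proband and both parents;
  for recessive candidates, all genotyped family members must also pass
  (removing a real de novo candidate because a sibling was under-covered
  would be wrong, so the sibling depth requirement applies only to the
  recessive path);
* **no adjacent homopolymer**: the maximal single-base run anchored at the
  base immediately left or right of the variant's reference span may not
  exceed `homopolymer_max_run` (default 5) bases.  The run may not include
  the variant bases themselves; for insertions/deletions the rule is applied
  to the full reference span.  Homopolymer-adjacent calls are a classic
  short-read artifact mode;
* **internal recurrence**: present in fewer than 5 of 147 internal exome
  datasets (a local blacklist against platform artifacts and local common
  variation);
* **rarity**: maximum frequency across the configured population databases
  strictly below 1% for dominant-acting candidates (de novo, inherited
  loss-of-function) and 3% for recessive candidates.  An absent frequency
  means the variant is novel and is treated as 0;
* **function**: the consequence class must impact protein sequence, a
  canonical splice site, a microRNA coding sequence or binding site, an
  enhancer, or an ENCODE-validated transcription-factor binding site within
  a promoter.

Missing DP/GQ fields fail their threshold in `strict` mode (default) and pass
in `permissive` mode; the upstream pipelines these inputs come from normally
populate both fields.

### Inheritance classification

Per gene, qualifying variants are classified as:

* **de novo** — proband carries the allele; both parents explicitly
  homozygous reference at adequate depth (guarding against allele dropout);
* **homozygous recessive** — proband homozygous alternate, both parents
  heterozygous;
* **compound heterozygous** — at least one maternally and one paternally
  transmitted heterozygous variant.  Phase is inferred by transmission, not
  read-backed phasing.  A variant heterozygous in both parents is
  origin-ambiguous: it may fill either side of the pair but never both, and
  two distinct variants are always required.  If phased proband genotypes
  are present they are checked for consistency (all maternal alternates on
  one haplotype, paternal on the other) and a contradiction is an error;
* **X-linked recessive** — gene on X; male proband hemizygous alternate with
  a carrier mother and non-carrier father (female probands: homozygous with
  carrier parents).  Hemizygous male calls are accepted as single-allele
  genotypes; a diploid-coded male X heterozygote is flagged inconsistent and
  dropped;
* **inherited loss of function** — inherited frameshift/stop variants are
  retained only in genes intolerant of loss of function (pLI strictly
  above 0.75).

**Sibling exclusion** operates on the full causal configuration, not on
single variants: an unaffected sibling voids a call only by reproducing the
proband's complete genotype state (both alleles of a homozygous call; at
least one maternal *and* one paternal variant of a compound set, as two
distinct variants; the hemizygous state for X-linked calls).  This matters in
practice — unaffected siblings are frequently heterozygous carriers of single
variants of a compound pair.

Every input variant is recorded in an audit table with the stage at which it
was removed (or `candidate`), so filter behaviour is fully traceable and the
conservation invariant (each variant appears exactly once) is testable.

### Expression intersection

A gene is concordantly differentially expressed at a timepoint when it is
significant versus *both* parents (`adjusted_p < 0.05`) with the same
fold-change sign and `|log2FC| >= 1`.  Final candidates carry an inheritance
call and concordant expression at both the undifferentiated (d0) and
differentiated (d25) timepoints.  The fold-change threshold is configurable
because reasonable pipelines differ here; the packaged worked example is
insensitive to it by construction.  A first-neighbor subnetwork (induced
subgraph on seed genes plus their direct interactors, self-loops dropped,
duplicate edges merged with type union) supports downstream interpretation.

## Burden framework

### Site QC

Cohort sites must PASS the upstream variant-quality filter; genotypes with
GQ < 20 are masked; sites with call rate < 0.95 or exact Hardy-Weinberg
p < 1e-8 are excluded.  The Hardy-Weinberg test is the conditional exact test
(two-sided, probability-ordering definition), computed in log space from the
distribution of heterozygote counts given the allele counts; a chi-square
variant exists for comparison only.  The 1e-8 threshold is conventionally
applied to exact tests, which motivated implementing the exact form.  By
default the test uses all samples (cases + controls) after GQ masking; a
controls-only mode is available.

### Statistics

For a gene with dosage matrix `G` (n samples × m variants, missing dosages
mean-imputed per variant), weights `w_j = Beta(MAF_j; 1, 25)` evaluated at the
observed minor-allele frequency of the analyzed cohort, and residuals
`r = y - mu` from a logistic null model (intercept-only unless covariates are
supplied):

* SKAT: `Q_skat = sum_j w_j^2 (g_j' r)^2`
* burden: `Q_burden = (sum_j w_j g_j' r)^2`
* SKAT-O: `Q_rho = (1 - rho) Q_skat + rho Q_burden` over the grid
  `{0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}`.

Under the null each `Q_rho` is asymptotically a mixture of 1-df chi-squares
with eigenvalues from `R_rho^{1/2} B R_rho^{1/2}`, where
`B = W G' P G W` is the projected score covariance and
`R_rho = (1-rho) I + rho 11'`.  Tail probabilities of the mixture are
computed by numerical inversion of the characteristic function (Imhof's
method), which is exact to quadrature tolerance at every p; the
single-eigenvalue and equal-eigenvalue chi-square reductions are
special-cased, and a seeded Monte-Carlo estimate backs the inversion up if
the quadrature misbehaves.  A moment-matched noncentral chi-square
approximation is used only where speed matters and accuracy is second-order:
inside the vectorized SKAT-O integrand and for quantile inversion.

The SKAT-O p-value is `P(min_rho p_rho <= T)` with `T` the smallest per-rho
p.  For large samples this is evaluated by the standard one-dimensional
integration over the common-burden chi-square component, with the remaining
mixture's conditional survival variance-adjusted.  Rho = 1 is capped at 0.999
inside the integration to avoid a zero denominator.  The final p is clamped
to `[T, K*T]` (K = grid size), the bounds implied by the minimum-p
construction.

### Small samples

Binary traits at small n break two asymptotic conveniences: the score vector
is visibly non-Gaussian, and the test statistic is lattice-valued (integer
dosages against ±(1-mu) residuals), so a continuous approximation can sit a
few percent away from an exact permutation tail.  Below n = 200 `skat_o`
therefore (a) uses the unbiased (n-1) denominator for the residual variance
and (b) evaluates the min-p combination by seeded Monte Carlo over the exact
Gaussian null of the score vector (400,000 draws, fixed internal seed, so the
p-value is deterministic given the data) instead of the one-dimensional
approximation.  The phenotype-label permutation path — available via
`n_permutations` and used as the test oracle, never as the production
path — counts ties with the observed statistic at half weight (mid-p), the
unbiased discrete estimate of a continuous tail probability.

### Reporting

Alongside the SKAT-O p, each gene reports carrier frequencies per phenotype
group (a carrier holds ≥ 1 alternate allele across the masked variants),
their fold ratio, and a two-sided Fisher exact p on the 2×2 carrier table —
clearly labelled as supplementary and distinct from the SKAT-O p.  Ancestry
subsetting retains samples whose ancestry fraction strictly exceeds the
threshold (default 0.80).  Multiple testing uses a Bonferroni threshold
`alpha / n_tests` (0.05 / 2 = 0.025 for a two-gene screen).

Variant inclusion follows the default strict-impact policy (frameshift,
missense, stop-gain/loss, essential splice; missense additionally requires
CADD strictly above 24; MAF strictly below 0.01 across all populations), or a
per-category mode (missense, intronic, splice region, synonymous, UTRs,
1 kb upstream, or BED-defined regulatory regions) with the rarity rule only;
a relaxed mode drops the CADD restriction.

## Synthetic data

The quintet fixture transcribes the 22 published worked-example variant rows
(ten genes: seven compound heterozygous, one homozygous recessive, two
X-linked) onto synthetic contigs, one contig per autosomal gene and a shared
X contig, with the printed proband/parent/sibling genotypes, consequence
classes, population frequencies, and dbSNP identifiers in the VCF ID column.
Reference contigs are random sequence constrained to runs of at most three
bases except where a seven-base run is planted next to a homopolymer decoy.
In `study_initiation` mode, frequencies above the 3% recessive threshold are
clamped to 2.9%, emulating the sparser databases available when the study
began (this is an emulation, not historical data); `current` mode keeps the
printed frequencies, which removes the two genes whose qualifying variant is
now known to be common.  Decoy genes each violate exactly one rule (depth 9,
homopolymer adjacency, internal recurrence, common frequency, non-functional
consequence, sibling carrying the full compound configuration, a one-sided
pair with no inheritance mode, discordant expression, expression at one
timepoint only); everything else about a decoy is valid, so each is removed
at exactly its intended stage.

The cohort simulator draws variant frequencies uniformly, genotypes at
Hardy-Weinberg proportions (no linkage disequilibrium), and — when a per-gene
carrier log-odds is planted — case labels from a logistic model on carrier
state with the intercept solved by bisection for the requested expected case
count; the all-null case assigns exactly the requested group sizes by
permutation.  The default dimensions mirror a 130-case / 861-control design.
The DET simulator plants concordant, discordant and null genes with
configurable effect (default |log2FC| = 2, noise SD 0.2).

None of the generators model sequencing error (beyond an optional genotype
error rate for the quintet), population structure, relatedness, linkage
disequilibrium, or annotation error.  Passing tests therefore demonstrate
correctness of the *logic and statistics* under clean inputs, not robustness
to real-data pathologies.

## Numerical and design choices

* Multi-allelic records are split per alternate allele before any filtering
  (all thresholds are per-allele); genotypes carrying a different alternate
  are non-carriers of the analyzed allele and flagged.  Unphased genotype
  allele order is normalized on read.
* Coordinates are 1-based closed (VCF convention) throughout.
* Monomorphic sites have exact Hardy-Weinberg p = 1 (single attainable
  configuration); probability-ordering comparisons use a 1e-10 relative
  margin against floating-point ties.
* The observed MAF for weights is computed from the full analyzed cohort
  (cases + controls), minor-allele oriented.
* Genome build is never assumed; contig names are taken verbatim and no
  liftover is performed.
* Problem sizes in the test suite (for example 2,000 null replicates at
  1,000 samples × 20 variants for type-I calibration, 10^5 permutations for
  the small-instance agreement check, and the exhaustive Hardy-Weinberg sweep
  to n = 50) were chosen to make the statistical assertions decisive at
  desk scale.

## Known limitations

* The cascade does not scan for inherited, incompletely penetrant
  autosomal-dominant variants; mosaicism and imprinting are out of scope.
* Compound-het phase is transmission-inferred; a both-parent-het variant
  cannot anchor a pair alone.  Read-backed phasing would resolve the
  ambiguous cases.
* The burden framework assumes unrelated samples (no kinship or mixed-model
  adjustment) and consumes ancestry fractions as input rather than
  estimating them.
* The published cohort's gene-level p-values depend on unpublished
  individual-level genotypes and are not reproduced; the statistics are
  validated by oracle agreement, calibration and power ordering on
  simulated data instead.
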