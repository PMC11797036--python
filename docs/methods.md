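# Methods

## Scientific setting

Clonally propagated crops such as cassava rarely pass through meiosis, so
recombination cannot purge deleterious alleles and purifying selection on
sexual-reproduction functions (flowering, pollen development) can relax.
This package implements the statistical machinery for detecting that
relaxation at two timescales:

* **between species** — a branch-model dN/dS contrast asking whether a
  focal lineage's protein-coding genes evolve with a higher
  nonsynonymous/synonymous rate ratio than the rest of the tree;
* **within species** — intolerance scores (RVIS/DRVIS) asking which genes
  carry an excess of functional polymorphism in a large clone panel, and a
  McDonald–Kreitman α combining both timescales;

followed by GO-term enrichment of the flagged gene sets.

## Codon substitution model

The interspecific core is a GY94-style codon model over the 61 sense codons
of the standard code. The instantaneous rate from codon *i* to *j* is

```
q_ij = pi_j * kappa^[transition] * omega^[nonsynonymous]
```

for single-nucleotide exchanges and 0 otherwise, with rows normalized so one
unit of branch length is one expected substitution per codon site at
stationarity. Exchangeabilities are symmetric, so the chain is reversible
(`pi_i q_ij = pi_j q_ji`), and the likelihood is invariant to root placement.

Likelihoods use Felsenstein pruning with site-pattern compression. P(t)
matrices come from a single symmetric eigendecomposition of Q per
parameter vector (Q is similar to `D^1/2 Q D^-1/2`, D = diag(pi)), so each
branch costs one elementwise exponential and two matrix products. Codons
containing gaps or N are marginalized as missing data (partial likelihood
of ones); a stop codon in the data is an error. Per-node rescaling guards
against underflow.

**One-ratio vs two-ratio fits.** The one-ratio model shares a single omega
across the tree; the two-ratio model gives one flagged ("foreground")
branch — the focal species' terminal branch, marked `#1` in Newick — its
own omega. Both maximize over (kappa, omega(s), tree_scale) with L-BFGS-B
in log-parameters, three starts from dispersed omega values (0.1, 1, 2);
omega is bounded to [1e-4, 10], and estimates at a bound or non-converged
optimizations are flagged, never silent. Codon frequencies are fixed at the
F3x4 empirical estimate (position-specific nucleotide frequencies,
renormalized over sense codons with a 1e-6 floor) rather than jointly
optimized, matching common codeml practice.

Two deliberate simplifications relative to codeml:

* input branch lengths are kept proportional and only a global
  `tree_scale` is re-estimated, keeping the optimization low-dimensional;
* the reported dN/dS cap at 2 is presentational only — applied when
  computing the reported `delta_dnds`, never during fitting.

**The branch test.** `delta_dnds = capped(omega_tree) -
capped(omega_foreground)`; negative values mean the focal branch evolves
with the higher ratio (relaxed or positive selection). The LRT statistic
`2(lnL_two - lnL_one)` is clamped at zero (1e-6 numerical slack; a larger
negative value is an optimizer failure and raises) and referred to
chi-square with 1 df — no 50:50 boundary mixture, since the alternative is
two-sided in omega. Significance across genes uses a Bonferroni threshold
alpha/m with m the number of tests performed.

## Per-site rates

The baseml-analogue: an HKY model with a discrete-gamma rate mixture
(4 equal-probability categories, mean discretization). Kappa, the gamma
shape and a tree scale are fit by ML; each column's rate is the
posterior-mean category rate, normalized to mean 1 over non-missing
columns (all-gap columns are NaN). These rates feed the deleterious-site
rule (rate < 0.5 marks a conserved position).

## Alignment conditioning

* best homolog per target genome: aligned fraction >= 0.90 of the
  reference transcript (inclusive), then maximal alignment score, ties by
  smallest candidate id;
* columns gapped in the reference are removed so the reference frame
  defines codon coordinates (idempotent);
* 4-fold-degenerate site extraction is strict: a codon column contributes
  its third position only when every sequence is ungapped and unambiguous,
  all share the same two-base prefix, and that prefix starts a 4-fold
  family — this guarantees third-position changes are synonymous
  alignment-wide. Columns mixing two 4-fold families (e.g. GCx/GGx) are
  excluded, a documented choice where the source procedure is silent;
* genes need >= 4 aligned non-reference genomes (the reference does not
  count);
* transcript selection: drop transcripts without annotated UTRs, drop the
  gene if no surviving transcript has a cross-species ortholog, then pick
  minimal dN/dS, then maximal CDS length, then smallest transcript id.

## Intraspecific scores

Variant filters: biallelic single-nucleotide sites, missingness strictly
below 20%, minor-allele count >= 3. MAF and MAC are computed over observed
(non-missing) allele copies only — the only defensible convention with
missing genotypes. Multiallelic sites are dropped, not decomposed.

RVIS regresses each gene's common (MAF >= 1%) nonsynonymous SNP count on
its total SNP count (OLS with intercept) and scores the gene's *externally*
(leave-one-out) studentized residual; DRVIS repeats this with putatively
deleterious counts (rate < 0.5 strict, SIFT-type score <= 0.05 inclusive,
MAF < 20% strict). External studentization follows original RVIS practice;
the source text does not distinguish internal vs external. On an exactly
collinear panel the scores are defined as zero. Top/bottom 5% membership
takes ceil(0.05 n) genes and includes boundary ties.

MK alpha is computed literally from the printed formula
`alpha = 1 - (pN/pS)/(dN/dS)`: pN and pS are site counts at MAF >= 10%
(the cutoff direction is ambiguous in the source; >= excludes segregating
slightly-deleterious variants, consistent with the known MK sensitivity),
while dN/dS is the model-based rate ratio. The units mismatch between a
count ratio and a rate ratio is inherited from the formula and preserved.
alpha is undefined (flagged, never NaN-propagated) when pS = 0 or the
divergence ratio is 0.

## Gene-set statistics

Annotations are propagated to all ancestor terms over an acyclic parent
graph. Enrichment is the classic one-sided Fisher exact (hypergeometric
upper tail) per term, after removing terms annotating fewer than two
universe genes. This intentionally does not reproduce topGO's
DAG-decorrelated algorithms, so published table p-values are matched in
shape, not value. The universe is the caller's choice; the pipeline uses
genes with >= 1 propagated term. Orthogroup consolidation records the
least extreme member values (smallest |delta dN/dS|, largest p — possibly
from different members); the duplication-confound filter keeps significant
genes only in single-copy orthogroups or when every copy is significant,
so ongoing fractionation after whole-genome duplication is not mistaken
for relaxed selection. Distribution contrasts use Pearson chi-square on
pooled-decile bins, merging adjacent bins until all expected counts reach
5 (df = k - 1); the binning rule is ours, as none is stated in the source.

## Synthetic data: what it does and does not emulate

* **Codon alignments** evolve by exact stochastic simulation (Gillespie)
  along each branch — chosen over matrix-exponential endpoint sampling so
  true per-branch substitution counts are available as counting oracles.
  Root codons are stationary draws; frequencies default to uniform 1/61.
  Defaults: 8 taxa, kappa 2, background omega 0.2 (strong purifying
  selection typical of conserved plant genes), foreground 1.5 for relaxed
  genes, exponential branch lengths with mean 0.1 substitutions/site.
  No indels, no rate heterogeneity across sites, no selection on codon
  usage — passing recovery tests shows the estimator is correct under its
  own model, not that real alignments satisfy that model.
* **SNP panels** draw totals Poisson(50) per gene and nonsynonymous counts
  `round(0.3 * total + N(0, 2))`, clipped to [0, total]; planted outliers
  get a fixed extra nonsynonymous count. Deleterious counts are a binomial
  thinning (15%). This reproduces the regression structure the intolerance
  score assumes — linear mean, homoskedastic noise — but not LD, allele
  frequency spectra or gene-length confounds of a real panel.
* **GO universes** assign background terms uniformly (Poisson sizes, mean
  10) and plant one over-represented term whose study-set overlap is drawn
  from Fisher's noncentral hypergeometric with odds equal to the enrichment
  factor — exactly the hypergeometric null at factor 1, which is what makes
  the null calibration check exact.

All generators are pure functions of (config, seed) via one
`numpy.random.default_rng` per call.

## Numerical choices and problem sizes

* Optimizer: L-BFGS-B, log-parameter space, maxiter 500; bounds kappa
  [0.01, 100], omega [1e-4, 10], tree_scale [1e-3, 100]; two-ratio fits
  may warm-start from the one-ratio optimum (the pipeline does).
* Validation sizes (the `validation` module defaults): 50 replicates at
  1,000 codons for recovery, 200 replicates at 500 codons for null LRT
  calibration, 50 replicates at 2,000 codons for power, 1,000-gene SNP
  panels, 100 synthetic GO universes. These sizes give binomial standard
  errors small enough for the stated pass bands while keeping a full
  validation run in the minutes range on one core.
* Ties: best-homolog and best-transcript ties break on lexicographic ids;
  top-fraction sets include boundary ties.

## Known limitations

* Branch lengths are not re-optimized per branch during fitting; strongly
  misspecified input trees will bias omega estimates.
* The Fisher test treats genes as exchangeable; gene length and annotation
  bias are not modeled (the published analyses share this property).
* The two-ratio model flags exactly one terminal branch; internal
  foreground branches are not supported.
* SIFT-like deleteriousness scores are consumed, never computed.
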