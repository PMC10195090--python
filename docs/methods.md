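# Methods

## Design and data model

The unit of observation is a transcript × sample matrix of reads that
overlap fixed inter-specific SNPs, so hybrid reads can be assigned to a
parental allele.  Parental samples contribute one total-expression column
each; every hybrid biological replicate contributes two allele columns
(A1 = fraterculus-derived, A2 = obliqua-derived).  The cross design has a
structural hole: the FO direction (♀ fraterculus × ♂ obliqua) produces
only female progeny, so FO-male samples are rejected at validation and
every downstream model is built for the incomplete sex × cross layout.
Hybrid total expression is always derived on demand as A1 + A2 per
replicate, never stored.

## Preprocessing

1. Counts are rounded to the nearest integer on input.
2. Low-expression filter: a transcript is kept only if it reaches
   `min_cpm` (default 3 counts-per-million) in at least `min_replicates`
   (default 2) replicates within *every* comparable group.  Comparable
   groups are each parental line × sex and each hybrid cross × sex, the
   latter evaluated on per-replicate allele totals.  Filtering hybrids at
   the total rather than per-allele level is deliberate: hemizygous
   transcripts (X-linked loci in males) legitimately have one all-zero
   allele column, and the X-linkage scan depends on their surviving the
   filter.  It is also the only reading under which the subsequent
   zero-adjustment step has anything left to adjust.
3. Zero adjustment: remaining zeros become ones, so the binomial ratio
   tests see strictly positive integers.  cpm is computed on raw column
   totals before TMM.

## Normalization

Between-library scaling uses trimmed-mean-of-M-values factors (30% trim
on M, 5% on A, inverse-variance weights, reference column chosen by the
upper-quartile rule, factors renormalized to geometric mean 1).  The
implementation was cross-checked against Bioconductor edgeR
`calcNormFactors` on a fixed fixture; agreement is within ~0.01, the
residual coming from reference-selection details.  Effective library
size = column total × factor; a hybrid replicate's total-expression
library is the sum of its two allele columns' effective sizes.

## Statistical contrasts

Five contrasts per transcript, each BH-adjusted within its own family
(contrast × sex × cross):

* **ED** — fraterculus vs obliqua parents (per sex).
* **AI** — A1 vs A2 within a hybrid cross × sex.
* **H_vs_P1 / H_vs_P2** — hybrid totals vs each parent.
* **RATIO** — hybrid allele ratio vs parental ratio (trans evidence).

The NB tests are likelihood-ratio deviance tests with a plug-in common
dispersion: group means are fitted by Fisher scoring on log λ with
effective-library-size offsets, and 2·Δloglik is referred to χ²₁.  The
estimator ln λ converges in a handful of iterations and the whole test is
vectorized across transcripts, which is what keeps 6,000-transcript runs
in seconds.  log2FC is log2(λ₁/λ₂).  In the Poisson limit the p-value
tracks the mid-p exact conditional binomial test within ~10%;
against statsmodels' NB GLM deviance it agrees to 6 decimals.

The common dispersion φ (variance = μ + φμ²) maximizes the *conditional*
profile likelihood given each group's total count (Robinson–Smyth qCML
style, with counts pre-scaled to the geometric-mean depth).  The plain
profile MLE is biased low with 3 replicates (≈0.13 at a true 0.2); the
conditional version recovers 0.197 on the same data.  φ is clamped to
[1e-6, 10] and can be fixed by the user instead.

The RATIO test is a logit GLM of allele-1 counts out of totals with a
hybrid-vs-parent indicator.  With one binary covariate the MLE is the
pair of pooled proportions, so the Wald statistic has closed form; the
reported effect is T = Rp − Rh in log2 units.  Two refinements:

* inputs are library-normalized pseudo-counts (each column scaled to the
  geometric-mean effective depth) — on raw counts, depth imbalance
  between the parental libraries masquerades as a trans effect;
* the default standard error carries a quasi-binomial scale estimated
  from the Pearson statistic of per-replicate proportions (floored at 1),
  because biological replicates are overdispersed relative to binomial
  sampling.  The plain Wald version (`dispersion_adjust=False`) leaks
  ~1.3% of strong pure-cis transcripts into cis + trans; the scaled
  version brings that to ~0.3% while trans-detection power at |t| = 3
  stays above 0.95.  Degenerate (separated) tables fall back to the
  two-proportion likelihood-ratio p.

Significance everywhere is the dual rule q < α (default 0.05) **and**
|log2FC| > `fc_threshold` (default 1.25); for the RATIO contrast the
fold-change clause applies to |T| and can be switched off
(`fc_threshold_on_ratio`).

## Classifiers

**Inheritance** (from ED, H_vs_P1, H_vs_P2 and normalized means):
conserved = nothing significant; dominant for a parent = ED significant,
hybrid indistinguishable from that parent, distinguishable from the
other; additive = all three significant and the hybrid mean strictly
between the parents; over-/underdominant = hybrid differs from both
parents and sits above/below the range; anything else ambiguous.  Exact
ties with a parental mean are ambiguous.  Transgressive calls do not by
default require parental ED (`require_ed_for_transgressive` restores the
stricter reading).  Note a structural consequence of the dual rule: a
hybrid at the *arithmetic* midpoint of the parents can never clear the
1.25 fold-change bar against the higher parent (the ratio is bounded by
2), so detectable additivity lives near the *geometric* midpoint — which
is also what the synthetic generator produces (below).

**Regulatory** (from ED, AI, RATIO plus the signs of Rh and Rp):
conserved (ns, ns, ns); cis-only (sig, sig, ns); trans-only
(sig, ns, sig); compensatory (ns, sig, sig); cis + trans / cis × trans
(all significant, same / opposite signs of Rh and Rp, with |·| < 1e-9
treated as sign-less → ambiguous); every other pattern ambiguous.  Both
classifiers are total functions, verified in the tests by exhaustive
enumeration against independently written truth tables, and both are
invariant under relabeling the species (dominant categories swap, all
others fixed).

Rh and Rp are computed from TMM-normalized means pooled across replicates
within a cross × sex; I_cis = |Rh|/(|Rh| + |T|) is undefined (and dropped
from averages) when Rh = T = 0.

**X linkage**: a transcript is flagged when AI is significant in hybrid
males and every raw (pre-zero-adjust) fraterculus-allele count in hybrid
males is zero — in this design a male's X comes from the obliqua mother.
Flagged transcripts are kept by default (`remove_x_linked` drops them).

## Molecular divergence

Per SNP, d = |freq_frat − freq_obliq|; d = 1 is a fixed difference.
Per transcript, d_xy = fixed SNPs / total SNPs, after dropping SNPs that
are near-monomorphic for the *same* allele in both species (minor allele
frequency < 2% in both) as likely sequencing noise — fixed differences
are deliberately untouched by this filter.

Ka/Ks uses Nei–Gojobori (1986) counting: per codon, fractional synonymous
site counts from the 9 possible point mutations (mutations to stops count
as nonsynonymous), so S + N = 3 per codon exactly; codon pairs with
multiple differences average the synonymous/nonsynonymous tallies over
all orderings of the minimal mutational path, excluding orderings through
stop codons; site counts are averaged between the two sequences;
K = −(3/4)·ln(1 − 4p/3).  Ka/Ks is undefined when Ks = 0 or p ≥ 3/4, and
such cases carry an explanatory note rather than a number.  The tests
check 50 random pairs against an independent recursive enumeration oracle
(Biopython translation) to 1e-9, and neutral simulation drives the mean
ratio to 1.00 ± 0.07.  Other estimator families (e.g. maximum-likelihood
codon models) can differ from NG86 by a method-dependent factor; this
package deliberately trades estimator variety for an oracle-checkable
reference method.

## Category associations

The association table has one row per transcript × sex × cross.  Category
effects on a response (normalized transcript counts, |log2FC| ED, I_cis,
Ka, Ks, Ka/Ks) are ordinary least squares on square-root-transformed
values — the responses are proportions/rates, and the family of the
original analysis is otherwise unspecified — with factors category, sex,
cross and category × sex, *no* sex × cross or three-way terms (that cell
of the design is empty), and Treatment contrasts against the conserved
category.  Consequently sex contrasts are informed by the OF cross only
and cross contrasts by females only.  Transcript-count responses are
aggregated per category × sex × cross and normalized by the profile's
transcript total.  Undefined I_cis / Ka/Ks values are dropped listwise
per response; categories with fewer than 2 observations are excluded;
rank deficiency beyond the expected aliasing raises with the aliased
term names.

## Synthetic data

The generator reproduces the full 21-library design (plus male/female
hybrid allele columns) from per-transcript architectures (c, t, μ):

    obliqua parent        μ
    fraterculus parent    μ · 2^(c+t)
    hybrid obliqua allele (μ/2) · 2^(t/2)
    hybrid frat allele    (μ/2) · 2^(c + t/2)

so that E[Rh] = c, E[Rp] = c + t, E[T] = t: the hybrid trans environment
is the parental midpoint on the log scale, the simplest model preserving
the Rh-is-cis identity, and allele means are halved so hybrid totals
match the parental scale under the null.  Counts are gamma-Poisson
(NB) with common dispersion φ (default 0.05; per-transcript gamma option),
scaled by log-normal library-size factors (σ = 0.15 by default).
Defaults follow the study conditions: 3 replicates, ~strong effects at
|c|, |t| = 3 log2, baseline mean 500.

Inheritance overrides rescale the hybrid total (preserving the allele
ratio) to: the parent itself (dominant), the *geometric* parental
midpoint (additive — the arithmetic midpoint is undetectable under the
dual rule, see above), or 2^±1.5 beyond the parental range
(over-/underdominant).  X-linked transcripts draw zero
fraterculus-allele counts in hybrid males.

What the generator does **not** emulate: read-level effects (mapping
bias, positional coverage, SNP density variation), correlated transcripts,
isoform structure, or sex-specific expression baselines.  Passing the
recovery tests therefore demonstrates that the statistical pipeline
inverts its own generative model at realistic noise levels — not that
upstream read processing is unbiased; the mapping-bias diagnostic exists
to check that assumption on real data.

The power module simulates two-group NB datasets over a grid of true
effects and reports, per fold-change threshold, the fraction of truly-DE
transcripts called at FDR 0.05 plus the realized false-discovery
proportion.  The mapping-bias diagnostic reports each hybrid library's
mean log2(A1/A2) across transcripts with a t-interval and flags libraries
whose interval excludes 0.

## Numerical and reproducibility choices

Fisher scoring runs ≤ 60 iterations with step clamping at ±4 on the log
scale; dispersions are bounded in [1e-6, 10]; sign comparisons treat
|x| < 1e-9 as zero; TSV output uses a fixed %.6g float format so reruns
are byte-identical; all randomness flows through
`numpy.random.default_rng(seed)`.  Problem sizes in the acceptance script
(2,000-transcript null, 6,000-transcript recovery, 20 neutral CDS pairs
of 800 codons) were chosen to give stable Monte-Carlo estimates while
running in seconds.

## Known limitations

* A single common dispersion across transcripts; no tagwise shrinkage or
  quasi-likelihood F-tests, so very heterogeneous real datasets may be
  mildly anti-conservative in the NB contrasts.
* The RATIO test conditions on pooled counts; replicate weighting enters
  only through the quasi-binomial scale.
* NG86 assumes equal base frequencies and no transition/transversion
  bias; Ka/Ks values are comparable within this package, not across
  estimator families.
* FDR families are per contrast × sex × cross; a global family would give
  systematically different q-values.
* The classifiers inherit every pathology of their inputs: with weak
  effects most truly-divergent transcripts land in conserved/ambiguous,
  which is the expected behaviour of the dual significance rule, not a
  bug.
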