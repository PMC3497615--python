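# Methods

## Model

The unit of inference is a single biallelic SNP observed in *n*
independent tissue samples.  Imprinting status is a binary latent state
with prior π = Pr(imprinted); per sample the genotype δ ∈ {XX, XY, YY}
is latent with Hardy–Weinberg weights (p², 2pq, q²) taken from a
user-supplied population frequency p of allele X (treated as a known
constant).  Conditional on genotype and status, the allelic counts
(x, y) with n = x + y fixed follow binomials:

* homozygote (either status): the off-allele count is
  Binomial(n, p_e) — reads of the absent allele are sequencing errors;
* heterozygote, imprinted: an equal-weight mixture of the two
  monoallelic binomials, because the expressed allele is inherited at
  random (phase prior ½);
* heterozygote, biallelic: x ~ Binomial(n, ½), from the assumptions
  that both alleles are transcribed at the same level and sequenced with
  the same efficiency.

The posterior follows from Bayes' rule with sample-wise products.  Key
structural consequences, which the tests exercise: homozygote terms
cancel between the hypotheses, so monoallelic counts at a possibly
homozygous site barely move the prior (a single (20, 0) sample at
p = 0.5 yields posterior ≈ 0.0198); one decisively balanced sample
produces likelihood ratios of order 2⁻ⁿ and overwhelms any number of
monoallelic samples at realistic depths (posterior < prior against 30
monoallelic depth-30 samples); and the whole model is symmetric under
swapping the allele labels together with p ↔ 1 − p.

The depth n carries no information about status (it is conditioned on),
and the third-nucleotide count e enters only the QS filter, never the
likelihood.

### Numerics

All likelihoods are computed in natural-log space; the three genotype
components are combined by log-sum-exp per sample and summed over
samples.  Direct products underflow double precision at depths the model
routinely sees (a balanced SNP in 20 samples of depth 30 has posterior
~10⁻¹⁵⁰), and downstream geometric-mean summaries need those magnitudes
exactly, so the log posterior is the primitive quantity and is
exponentiated last.  The test suite pins the implementation against an
exact-rational (fractions.Fraction) evaluation of the same formulas to a
relative error of 1e-10 over all single-sample counts with x + y ≤ 30 at
p ∈ {0.1, 0.5}, p_e ∈ {0.01, 0.05}.  Degenerate frequencies p ∈ {0, 1}
are permitted (one genotype takes all the weight) with a warning, since
such SNPs cannot distinguish the hypotheses.

## Parameters

| parameter | default | meaning |
|---|---|---|
| prior_imprinted (π) | 0.01 | prior probability a gene is imprinted; matches the commonly cited ~1% prevalence of imprinted genes |
| seq_error_rate (p_e) | 0.02 | average per-read probability that a read of the expressed allele reports the other allele; a single global constant per run |
| qs_cutoff | 0.9 (strict >) | minimum fraction of reads at the SNP showing one of its two annotated alleles |
| min_total | 3 (inclusive ≥) | minimum allelic count for a (SNP, sample) observation to be *valid*; "sample size" is the number of valid observations |
| call_cutoff | 0.2 | posterior threshold for a supporting SNP |
| contradiction_cutoff | 0.002 | minimum posterior every SNP of a called gene must exceed; calibrated as roughly the 5th percentile of simulated imprinted posteriors |
| exclude_chroms | {chrX, X} | X-inactivation produces imprinting-like monoallelic expression |

The QS filter is applied per (SNP, sample) observation — the
conservative reading of discarding low-quality evidence — rather than
dropping a SNP outright when any one sample fails.  The thresholds'
strictness (QS strictly greater, total inclusive) follows the filter
definitions exactly.

## Synthetic-data generator

The simulator emulates allelic counts at a SNP across independent
samples: genotype from HWE at the configured minor allele frequency,
depth from a negative binomial (mean 30, dispersion 5, truncated at
≥ 3), allele-of-origin per read from the generating hypothesis, then
sequencing error.  Moderate depth with substantial overdispersion is a
realistic stand-in for exonic SNP coverage in bulk mRNA-Seq; all
printed-performance checks in the test suite are bounds, and this depth
model satisfies them with margin.

Two error channels are provided.  The default, `nucleotide`, misreads a
base to each of the other three nucleotides with probability p_e/3, so
only a third of errors land on the opposite allele and the rest fall
into the third-nucleotide count e that feeds QS — this is the mechanism
stated in the simulation design the model was originally assessed with.
The `allele` mode flips a read straight to the opposite allele with
probability p_e, which is the likelihood model's own abstraction; it is
the harsher condition (three times the allele-to-allele contamination)
and is kept as an option for sensitivity analysis.  Under the default
channel a sample can be drawn whose counts fail the validity filters
(e.g. depth 3 with one third-nucleotide read); such samples are redrawn,
so `n_valid_samples` is exactly the number of valid samples, matching
the sample-size definition used throughout.

Biallelic heterozygotes support a fixed imbalance coefficient
FIC ∈ (0, 1]: the weaker allele contributes a fraction FIC of the
stronger allele's transcripts, i.e. an origin weight FIC/(1+FIC)
(FIC = 1 recovers balance).  `fixed` mode always down-weights the same
allele; `random` re-draws the down-weighted allele per sample.  The
`one_biallelic` truth models a gene that is imprinted-looking in all
samples but clearly biallelic in one: sample 0 is a balanced
heterozygote, the rest follow the imprinted generator.

What the generator does **not** emulate: mapping bias toward the
reference allele, correlated errors within a library, overdispersed
(beta-binomial) allelic ratios from RT-PCR stochasticity, finite-genome
linkage between SNPs, or population stratification in allele
frequencies.  Passing simulation-based tests therefore demonstrates the
statistical machinery under the model's own assumptions plus the stated
error mechanism — not robustness to the full messiness of real
libraries, where reference bias in particular can mimic allelic
imbalance.

## Performance estimation

Sensitivity at a grid cell is the fraction of imprinted replicates with
posterior > 0.2; specificity the fraction of balanced biallelic
replicates at or below it; both use 20,000 replicates per condition.
The FDR combines the class-conditional rates with the prior prevalence:

FDR = (1 − spec)(1 − prev) / [(1 − spec)(1 − prev) + sens · prev],
prev = 0.01.

When no positives occur in either class the FDR is undefined and
reported as NA, as is a minor allele frequency outside the simulated
grid range; sample-size lookups snap to the nearest simulated size.
Geometric means of posteriors (used for the curves-vs-sample-size
summaries) are computed on the log scale so that astronomically small
biallelic posteriors contribute exactly.

Problem sizes used by the shipped checks: 20,000 replicates per
condition for the operating characteristics and the contradiction-cutoff
calibration (sample sizes 1–30 pooled, 600,000 posteriors), 4,000
replicates for the directional imbalance curves, and 10,000 simulated
SNPs for the preference test's type-I error; the whole suite runs in
well under a minute of simulation time.

## Allele-preference test

Samples qualify when x > 10, y > 10, x + y > 50, x/y < 10 and
y/x < 10 (all strict), which makes a monoallelic or error-driven origin
of the observed counts implausible.  A SNP with at least 8 qualified
samples is tested: z = #{samples with x > y} against Binomial(n, ½).
Ties (x = y) carry no direction and are removed from both z and n;
qualification is judged on the pre-tie count.  The p-value is the exact
two-sided tail-doubled probability, 2·min(P(Z ≤ z), P(Z ≥ z)) capped at
1 — a conventional choice adopted because the test's sidedness is
otherwise underdetermined; for p = ½ it coincides with the
minimum-likelihood two-sided definition (the pmf is symmetric), which
the suite verifies against an independent implementation.  A
Benjamini–Hochberg column is emitted for convenience; headline
significance is the raw p < 0.05.

## Sample clustering

Each sample is scored on its own (single-observation posteriors per
SNP), transformed by v = max(0, ln(100 · posterior)) so that posteriors
at or below the prior become exactly 0, and SNPs that are 0 in every
sample are dropped — only imprinting-inclined SNPs drive the clustering.
Sample distance is 1 − ρ (Spearman, average ranks for ties;
(1 − ρ)/2 available as an option), clustered agglomeratively with
average linkage and exported as Newick.  Missing (SNP, sample)
observations are filled with the prior, i.e. transformed 0 — the
no-information value — rather than intersecting SNP sets across samples.
Samples with zero variance across retained SNPs have undefined rank
correlations; they are reported as NA and excluded with a warning.

## Design choices and limitations

* The model is single-SNP: a gene with several exonic SNPs gets one
  posterior per SNP, reconciled only through the call/contradiction
  rule.  A joint multi-SNP likelihood would need phasing assumptions and
  is out of scope.
* The method cannot determine the parent of origin, and with samples
  from diverse tissues it is blind to tissue-specific imprinting (one
  biallelic tissue vetoes the call — by design).
* Strong fixed allelic imbalance of a biallelic gene (FIC ≲ 0.13,
  i.e. the minor allele below ~13% of the major) is indistinguishable
  from imprinting; the simulator reproduces this failure mode and the
  suite asserts it directionally.
* p_e is global; a per-SNP override can be supplied via configuration
  but no attempt is made to estimate it from data.
* SAM/BAM counting streams the whole file once (no index required); it
  trades random access for simplicity and is ample at the scale of
  per-sample SNP panels.
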