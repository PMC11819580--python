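# Methods

`pedmut` implements the pedigree (trio) approach to germline mutation
analysis: de novo mutations (DNMs) are identified as Mendelian violations
in mother–father–child trios from a jointly called multi-sample VCF,
filtered with a stringent candidate battery, assigned a parent of origin
by read tracing, and converted into per-generation rates and sex-specific
parental-age models. A synthetic-cohort simulator provides ground truth
for every stage. This note documents the models, the parameter choices,
and what the tests do and do not establish.

## DNM calling

Candidates are sites where both parents are called homozygous reference
and the child heterozygous — the most error-robust Mendelian-violation
configuration. Sites first pass a cohort-level allelic-balance screen:
the mean ABHet = ref/(ref+alt) across heterozygous carriers must lie in
[0.2, 0.8] (sites with no heterozygous carrier are retained and marked
not-evaluable). Seven per-candidate filters follow; each is recorded as
pass / fail / not-evaluable, a candidate passes only if all seven pass,
and a filter that cannot be evaluated fails the candidate (fail closed):

1. depth between 15 and a per-sample maximum in all trio members;
2. genotype quality strictly above 60 in all members;
3. the child call heterozygous under two independent callers
   (consumed as an annotation, not recomputed);
4. alternate allele on both strands in the child;
5. zero alternate reads in either parent;
6. alternate allele absent from every other cohort sample, excluding
   siblings and the focal child's descendants;
7. child allelic balance strictly above 0.35.

The maximum-depth bound defaults to mean + 4·√mean (a four-sigma Poisson
bound; printed renderings of this rule are ambiguous, and a 5×mean
alternative is exposed as `max_depth_mode="fivex"` — at 40× coverage
5×mean excludes almost nothing, so the sigma bound is the default).
Filter 6 operates at read level by default (any alternate read fails the
candidate), with a genotype-level switch. Descendants of the focal child
are exempted alongside siblings because roughly half of a carrier's true
DNMs are transmitted to each of its offspring; without the exemption no
transmitted DNM could ever be called, contradicting the downstream
transmission check. Inequalities for GQ and allelic balance are strict.

Multi-nucleotide mutations (constituent SNVs within 10 bp in the same
child) remain separate rows sharing an `mnm_cluster_id`; sibling-shared
DNMs stay in each sibling's list, flagged. X-linked contigs are excluded
before calling; they are recognised from per-contig, per-individual depth
and heterozygosity: a contig is X-linked when either metric differs
between the sexes (Welch two-sided t-test, P < 0.05) and male depth is
below 25×; significant contigs with high male depth are only labelled,
not removed.

## Rate estimation and callability

The per-generation rate for trio *i* is μᵢ = N_mut,i / (2·ΣₓCᵢˣ), where
the denominator counts callable haploid sites: depth-passing sites (from
the per-trio mask) times the probability that a true DNM configuration
survives the filters in all three members, C = c_child·c_father·c_mother
(independence assumed). c_child is the fraction of high-confidence child
heterozygotes — sites with opposite-homozygote parents — passing the
child-specific filters (depth, GQ, concordance, strand, allelic
balance). The parent-side terms are the analogous pass fractions of
high-confidence homozygous-reference parental genotypes under the
parent-specific filters (depth, GQ, zero alternate reads); the
high-confidence set for a parent is taken where the *other* parent is
homozygous alternate and the child heterozygous, which pins the focal
parent's genotype. This parent-side construction is an interpretation:
the source method states only that parental callability is estimated "in
a similar manner" to the child's.

Cohort rates are unweighted means of per-trio rates, not pooled counts
over pooled sites: on the 12-trio table only the unweighted mean
reproduces the published 1.49×10⁻⁸ (pooling gives 1.47×10⁻⁸), and
likewise 0.74×10⁻⁸ for the 21 baboon trios. The published "callable
genome size" column is the haploid ΣₓCᵢˣ; the diploid factor 2 lives in
the rate denominator. The correction assumes no false positives, which
holds exactly in the simulator's default regime (noise produces false
negatives only) and is supported for the real data by transmission and
resequencing evidence.

## Read-tracing phasing

A DNM is assigned to a parent through heterozygous child SNPs within
±1,000 bp whose allele origin is logically forced by the parental
genotypes: opposite homozygotes pin both alleles; one heterozygous
parent still pins both (the homozygous parent contributes its own
allele, forcing the other allele to the heterozygous parent); two
heterozygous parents are ambiguous and skipped. Reads or read pairs
carrying the DNM alternate allele vote for the parent implied by the
informative allele they also carry; the DNM is assigned only on a
unanimous vote with at least one supporting read (`min_votes`
configurable), otherwise it stays unphased. Conflict handling by
unanimity is this package's policy — the read-tracing tools it mirrors
do not document their tie-breaking. No DNM is ever assigned from
genotypes alone. A generic two-phaser diff (`compare_phasers`) reports
concordant/discordant/one-sided counts for comparing alternative
phasings; extended haplotype-bridged tracing is out of scope.

## Parental-age models

Counts are modelled with Poisson regressions under an **identity** link,
so coefficients are additive mutation counts.

*Total model*: N ~ Poisson(β₀ + β_P·L·X_P + β_M·L·X_M) with L the
diploid callable genome size (2× the haploid callable sites) and X the
parental ages. *Phased models*: for each parent separately,
(N_phased + 1) ~ Poisson(β₀ + β·ζ), ζ = L·S·X, with a pseudocount of 1
keeping identity-link means positive. The scale factor S defaults to the
trio's **total mutation count** (`phased_scale="total"`); the fraction of
mutations phased is available as `phased_scale="fraction"`. The total
reading follows the source definition of the symbol and reproduces its
downstream numbers (the paternal Wald P of 0.19 and the equal-age
solution near 9 years); the fraction reading is dimensionally tidier —
it makes the covariate scale with the expected phased count — but yields
a different equal-age solution (~4 years), so it is kept as an option
rather than the default.

Fitting is maximum likelihood with every fitted mean constrained
positive (SLSQP with linear constraints plus damped Newton polishing);
the link is never switched to log. Standard errors use expected (Fisher)
information; Wald tests are two-sided (the source does not state
sidedness; two-sided is the default convention). Note that default IRLS
implementations can stall short of the optimum on these small
identity-link problems — the constrained+Newton fit is verified in the
tests against derivative-free likelihood maximisation to four
significant digits, and its log-likelihood dominates the IRLS fit.

`effect_per_year` converts a slope to mutations/year as β·L_ref, with
L_ref defaulting to the cohort-mean diploid callable size; the
confidence interval scales exactly. On the 12-trio table the maternal
effect is 4.49 mutations/year (95% CI 3.58–5.39, z ≈ 9.7). The published
value for this quantity is 7.2 (CI 5.8–8.6) with the *same* z-statistic,
i.e. it equals the same fitted coefficient multiplied by a ≈5.9×10⁹ bp
diploid length rather than the ≈3.7×10⁹ bp cohort-mean callable size.
A length of that magnitude would correspond to the depth-passing (not
callability-discounted) genome at a callability product near 0.62, or to
a ≈2.9 Gbp assembly, but no such length is derivable from the published
per-trio table, so this package reports the coefficient at the callable
size it was fitted on and flags the discrepancy rather than rescaling
toward the published number.

*Equal-age solver*: assuming both parents conceive at the same age *a*,
the solver finds where predicted paternal/maternal phased counts equal a
target ratio (e.g. the phylogenetic α). Under the default
`phased_scale="total"`, the trio total entering ζ(a) is itself predicted
from the total model at equal ages, keeping the construction
self-consistent; fitting pseudocounts are subtracted before the ratio is
taken, and roots are searched where both predicted counts are positive
(the ratio has a pole where the maternal prediction crosses zero;
spurious sign changes there are rejected). On the 12-trio table the
solution for a target of 3.1 is 9.06 years. Fig-2-style regression lines
are the fitted means minus the pseudocount, with pointwise delta-method
95% bands.

## Spectrum and cohort statistics

Substitutions collapse to the six pyrimidine-strand types; CpG status is
a C followed by G and the APOBEC-associated TpC context a C preceded by
T, both read from the reference-strand trinucleotide context and
strand-collapsed. Enrichment tests use Fisher's exact test with the
**unconditional sample odds ratio** ad/bc — the convention that
reproduces the published 1.91 and 1.43 — with the conditional MLE also
reported; the published comparisons use overlapping categories (the
signature subset against the full C>T class, CpG excluded), implemented
as printed with a non-overlapping variant behind a flag. Transmission to
the third generation is tested with the exact two-sided binomial test
against 0.5 (minimum-likelihood summation, matching the published 0.74
and 0.36). Spectrum homogeneity uses the chi-square test, switching to a
Monte-Carlo p-value (group spectra resampled from the pooled
distribution with totals fixed, add-one corrected) when any expected
cell is below 5. Relatedness between two genomes is
(shared het − 2·IBS0)/min(het_a, het_b) over non-missing shared sites —
≈0 for unrelated pairs, ≈0.5 for parent–child.

## Comparative sex bias (X vs autosomes)

Because the X spends 2/3 of its history in females, α (male-to-female
substitution rate ratio) follows from the X/autosome branch-length
ratio: α = (4 − 3·X/A)/(3·X/A − 2), valid on X/A ∈ (2/3, 4/3) with the
boundaries mapping to all-male (+∞) and all-female (0) limits. The point
estimate uses the mean autosomal length; the 95% CI is Student-t over
per-autosome α values (n−1 df; a z option exists — the source does not
state which was used). Autosomes whose X/A ratio leaves the valid
interval are excluded and logged. Branch lengths arrive as a TSV;
substitution-model fitting and alignment processing are out of scope.

## Synthetic cohorts

The simulator emulates the data model of a trio sequencing study on a
desk-scale genome (default: four 2.5 Mb autosomes plus a 1.25 Mb X).
Founder genotypes are drawn under Hardy–Weinberg at segregating sites
whose density matches the configured per-bp heterozygosity (allele
frequencies uniform on 0.05–0.5, giving mean heterozygosity ≈0.32 per
site, hence density = het_rate/0.32); children inherit one parental
haplotype per contig per meiosis, which makes read-scale phase exact
without modelling recombination. DNM counts per trio are Poisson with
the identity-link linear mean β₀ + β_P·L·X_P + β_M·L·X_M (negative means
are a configuration error); the parent of origin follows the two age
terms with the intercept split evenly, clamped to [0, 1]. Transmission
of a DNM to a sampled grandchild is an independent Bernoulli(1/2) per
DNM — at contig scale the no-recombination rule would make transmission
all-or-none per chromosome, which is unrealistic (real DNMs are
separated by many recombination events) and would break the 50%
binomial transmission property.

Noise: per-call depths are Poisson at the configured mean (halved for
male X), heterozygous allele balance is Beta(k/2, k/2) with
concentration k = 60, GQ drops below the threshold with probability
0.03 per call, alternate reads split binomially between strands,
homozygous-reference samples show spurious high-quality alternate reads
at 10⁻⁴ per read, and 1% of heterozygous calls are marked
caller-discordant. These defaults produce per-member callabilities near
0.85–0.95 (products 0.65–0.85), in the range reported for ~40×
short-read trio studies. Read evidence for phasing is emitted as a flat
(read_id, contig, pos, allele) table: paired 150 bp reads with 500 bp
fragments drawn at half the site depth, each pair sampled from one child
haplotype and reporting that haplotype's alleles at the DNM and any
child-het site it covers — haplotype-consistent by construction, so
unanimous-vote phasing can be exactly checked against truth.

Default study conditions follow the aye-aye cohort where stated: 12
trios, ages uniform on 6.7–30.5 years, 39.1× coverage, low polymorphism
(5×10⁻⁴). The default age-model coefficients are the least-squares
calibration of the even-split family against the cohort's per-parent
inferred counts (β₀ = −9.15 mutations, +1.87/year paternal, +2.28/year
maternal, divided by the simulated L): the published total-count fit has
a negative intercept and a ≈zero paternal slope, which under an even
intercept split would clamp the paternal share to zero and produce
all-maternal cohorts — inconsistent with the observed 113 paternal
phased mutations. The calibrated defaults reproduce the published count
scale (≈19 DNMs at the youngest ages to ≈117 at the oldest) with both
parents contributing and the maternal age effect exceeding the paternal.

What passing simulator-based tests show: the calling, callability
correction, phasing and regression machinery are internally consistent
and unbiased *under the generative model* — Mendelian inheritance,
independent per-call noise, haplotype-consistent reads. What they do not
show: robustness to mapping artefacts, systematic (non-independent)
genotyping error, somatic mosaicism, reference bias, or index swaps —
none of which the generator emulates.

## Numerical choices and degenerate inputs

- Optimiser: covariates internally scaled to unit magnitude (L carried
  in 10⁹ bp units); fitted-mean floor 10⁻⁹; SLSQP then trust-constr
  fallback, then damped Newton to gradient < 10⁻¹⁰.
- A phased design with zero covariate variance returns the
  intercept-only ML with slope exactly 0 (flagged), rather than an
  arbitrary point on the unidentified ridge.
- Collinear parental ages in the total model fit proceed but are
  flagged.
- Zero maternal phased count makes the pedigree α infinite, with a
  warning; empty mutation tables propagate as zero counts, not errors.
- Identity-link means below zero at any observed covariate are treated
  as non-convergence and flagged; the link is never silently switched.
- Branch-length noise is applied to autosomes only: a jitter on the
  single X entry would shift all per-chromosome α values jointly and
  invalidate the per-chromosome CI construction.

## Problem sizes used in the tests

Simulated cohorts in the test suite use 3–6 trios on 0.4–1 Mb genomes
(hundreds of true DNMs, thousands of variant sites); regression
calibration uses 60–200 replicate cohorts of 30–100 trios at the
count level (no genotype simulation); the spectrum Monte-Carlo test uses
2,000 resamples. These sizes give Monte-Carlo errors comfortably inside
the asserted tolerances while keeping the whole suite under a minute of
simulation time.

## Known limitations

- The two-caller concordance filter consumes an annotation; the package
  never re-runs a second caller.
- Parent-side callability is an interpretation of an underspecified
  construction (see above) and is validated only against the simulator.
- The equal-age solver and the phased models inherit the ambiguity of
  the scale factor S; both readings are implemented, and the default is
  the one that reproduces the published downstream numbers.
- The maternal effect_per_year at the cohort-mean callable size is 4.49,
  not the published 7.2; see the regression section for the analysis.
- Read evidence is synthetic-format (flat TSV); BAM/CRAM pileup
  extraction is out of scope.
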