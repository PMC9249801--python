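# Methods

`mitofam` implements an end-to-end analysis of mitochondrial DNA (mtDNA)
heteroplasmy and content in family-based disease studies: calling
low-fraction variants from ultradeep pileups, estimating mtDNA copy number,
classifying predicted-pathogenic (PP) variants, tracing maternal
transmission and germline selection, and fitting the matched case-control
association layer. A synthetic-data generator reproduces the statistical
structure these analyses assume and provides truth tables for validation.
This note records the models, the defaults, and the choices made where the
design was genuinely open.

## Genome model

Coordinates are 1-based inclusive rCRS positions ("m." notation) over the
circular 16,569-bp molecule; any half-open representation is converted at
the boundary. The packaged reference sequence is synthetic (seeded,
deterministic, with three anchor bases pinned to their true rCRS alleles so
canonical examples such as m.3243A>G annotate correctly); the gene map is
the standard human one (13 OXPHOS genes with complex labels, 22 tRNAs,
2 rRNAs, D-loop). No downstream statistic depends on the packaged
sequence's bases; a true rCRS FASTA can be supplied. Low-complexity masking
uses the three homopolymeric intervals m.302–316, m.512–526, m.16184–16193
and is idempotent. Overlapping genes (ATP8/ATP6, ND4L/ND4) report *all*
memberships with a per-gene consequence; consumers deduplicate. Coding
effects use the vertebrate mitochondrial codon table, with light-strand
genes (ND6 and eight tRNAs) handled by reverse complement. The D-loop wrap
length (150 bp) is carried as metadata for circular-alignment provenance;
alignment itself is out of scope and pileups are assumed to carry the
upstream read-level filters (proper pair except D-loop, MAPQ ≥ 20,
BAQ ≥ 30, < 5% mismatches).

Change universes enumerate exactly 3 alternative alleles per position of a
gene category; transitions are A↔G / C↔T.

## Heteroplasmy calling

A site pileup carries strand-split allele counts, per-allele mean BAQ, and
the fraction of bases with BAQ ≥ 30. The minor allele is the second most
frequent allele (so homoplasmic substitutions never masquerade as
heteroplasmies), and the filter cascade is:

1. depth of unique/consensus reads > 500 with > 70% of bases at BAQ ≥ 30;
2. outside the low-complexity mask;
3. minor count ≥ 5 and minor fraction ≥ 1.5% (the NUMT defense);
4. BAQ-based log-likelihood quality score > 5;
5. strand concordance: non-zero minor allele on both strands and two-sided
   Fisher exact P ≥ 1e-4 (the two-sided convention sums all tables with
   point probability ≤ observed, the standard definition).

The quality score is the log10 likelihood ratio between "heteroplasmy at
the plug-in fraction p = k/n" and "errors only", with per-base mixture
terms p(1−e) + (1−p)e/3 for minor-allele bases and (1−p)(1−e) + p·e/3 for
major bases, e = 10^(−BAQ/10). The score is floored at 0: when k/n falls
below the error expectation the error-only model is itself the maximum-
likelihood fit. Error alleles under the null are spread uniformly over the
three non-reference bases (e/3 each), a maximum-entropy default absent a
substitution-specific error profile. The exact likelihood form behind the
published ">5" convention is not standardized; this mixture form is pinned
here and borderline calls may shift relative to other implementations.

**Sharing test.** A variant is shared with a second sample when its
fraction there is ≥ 0.2% among > 500 unique reads and the upper-tail
binomial probability P(X ≥ k | n, e) is < 1e-3; depth ≤ 500 yields
*indeterminate*, distinct from not-shared. The default error rate 1e-3 is
the BAQ-30 bound; site-specific rates from mean BAQ are supported. The test
rescues "secondary" heteroplasmies in relatives below the primary VAF
floor.

**Detection power** is exact binomial: the critical count k* is the
smallest k whose null tail is ≤ α, power is the alternative's tail at k*.
No normal approximation; at VAF ≤ error rate the value returned is the
achieved size.

**Consensus mode.** Barcode-grouped read families are merged with a
uniform-prior Bayesian posterior over the four bases (per-read likelihood
1−e correct, e/3 otherwise); ties emit N and are excluded from counts
(conservative). Filter vi requires the VAF among multi-read consensus
reads to be comparable to the single-read class (Fisher P ≥ 1e-4 and
VAF decrease < 5-fold); filter vii removes all calls at sites where more
than half of the batch's variants fail vi. Whether "the batch" means a
sequencing batch or a whole study is not standardized; per-batch is pinned
here.

**Sample QC** (report-only): children with > 15 de novo heteroplasmies,
mother-child major-allele sequences differing at ≥ 5 sites (a mislabeling
proxy replacing haplogroup nomenclature), and samples with median mtDNA
coverage < 500×.

## mtDNA content and mtCNz

The WGS estimator is 2 × mean over the 22 autosomes of (mt depth /
autosome coverage), where autosome coverage averages 100-kb windows (50-kb
step) with > 80% of sites covered; it is invariant to global depth
scaling. The capture estimator is 2 × (mean consensus reads per usable mt
probe / mean per nuclear target), with probes disqualified when a
polymorphism in their arm region has its minor allele in > 0.2% of batch
samples. The published "residual method" internals are under-documented;
the ratio estimator with probe masking is implemented and named as such.

mtCNz is the standardized residual of child content regressed on age (or
gestational age) and the parental mean (or maternal) content; missing ages
are imputed with the cohort mean, constant covariates dropped with a
warning, and residuals are divided by their population (ddof = 0) standard
deviation so the fitted set has mean 0 / sd 1 exactly. Standardization is
fit once on the full child set — never refit per subgroup — so stratified
analyses share one scale. Tertiles are cut at the 1/3 and 2/3 empirical
quantiles of the pooled children (cases + controls), ties broken by stable
order; the pooling set is a pinned choice.

## Pathogenicity

PP classification: nonsynonymous OXPHOS variants need *all* of CADD-Phred
> 15, PolyPhen-2 possibly/probably damaging, and MutPred > 0.6; tRNA
variants need MitoTIP raw > 12.66. The per-applicability reading (i–iii
for protein changes, iv for tRNA) is deliberate: tRNA variants have no
PolyPhen/MutPred scores and protein variants no MitoTIP, so an any-of
reading would be vacuous. A confirmed mitochondrial-disorder mutation not
marked benign in ClinVar qualifies regardless of predictors. Either route
additionally requires maximum population frequency ≤ 0.05%; the *maximum*
across panels is used (the stricter reading of a multi-panel bound).
Missing required predictors give an indeterminate flag, distinct from
False. rRNA and D-loop variants have no predictor route and no z-score.

Pathogenicity z is the rank-based inverse-normal transform over the
complete change universe of the category: z = Φ⁻¹((r − 0.5)/m), mean rank
for ties. The (r − 0.5)/m offset is a pinned convention. z is invariant to
monotone transforms of the raw score and approximately standard normal
over large universes.

## Transmission and selection

Origin: a child call shared with any maternal-lineage member (the mother,
plus the other child in quartets — a variant present in the sibling blocks
de novo status) is inherited; an unshared call at VAF ≥ 1.5% is de novo;
insufficient lineage depth leaves it unknown. Every child call is exactly
one of inherited / de novo / unknown, every maternal call transmitted /
untransmitted / indeterminate.

Selection tests: (1) a two-sided one-sample t test of mean pathogenicity z
against 0; (2) a resampling test drawing, from the universe, 10⁵ sets that
match the observed composition exactly within each (gene category ×
transition/transversion) stratum — joint strata are pinned over marginal
matching. The lower tail is the default "P for selection" (the hypothesis
is purifying selection); a two-sided variant doubles the smaller tail. The
+1 smoothing, p = (1 + hits)/(B + 1), guarantees validity at finite B, and
the resampler is deterministic under its seed. The transmission readout
fits logit(transmitted) ~ z + RNA-or-OXPHOS + maternal VAF + sex and
reports the per-SD OR; constant covariates are dropped, separation is
flagged with an unbounded CI.

Maternal-age effects: ordinary least squares of de novo count on maternal
age at childbirth, with a group × age interaction for slope heterogeneity
and an optional paternal-age covariate. The mutation-rate estimator is
`rate = Σ counts / (n_children × callable sites) / detectable_fraction`,
with the detectability correction an explicit input defaulting to 1 (off),
because detectability depends on study-specific depth and VAF floors; it
is validated by simulation round-trip only.

## Association layer

Exposure: a child carries a PP heteroplasmy only if its fraction exceeds
the comparator's (sibling in quartets, mother in dyads). Matched quartets
are fitted by conditional logistic regression stratified on family
(statsmodels' conditional ML; for one binary exposure in 1:1 pairs this is
the discordant-pair ratio). Dyads use ordinary logistic regression with
sex and an mtDNA-lineage ancestry label (a categorical sample-sheet
column; haplogroup nomenclature is out of scope). Nested models are
compared by likelihood-ratio test. Nominal two-sided P values are
reported; no hidden multiplicity correction.

Fixed-effect meta-analysis back-calculates each stratum's log-OR SE from
its 95% CI assuming symmetric Wald intervals on the log scale — the only
reading that reproduces published combined ORs from printed per-cohort
intervals — then combines by inverse variance; heterogeneity is Cochran's
Q (χ², k−1 df) and I² = max(0, (Q−(k−1))/Q). PAR = p₀(OR−1)/(1+p₀(OR−1))
with p₀ the family-adjusted prevalence among controls, defined here as the
comparator-rule exposure proportion over matched units, with a
family-bootstrap SEM/CI (1,000 resamples). "Family-adjusted prevalence" is
not defined precisely in the literature this mirrors; this definition is
pinned and may differ in detail from other implementations. The severity
score is the sum of four cohort-referenced indicators: NV-IQ < 70,
V-IQ < 70, adaptive-behavior composite in the bottom quartile, negated
ADOS calibrated severity in the bottom quartile.

## Synthetic data generator

The generator's defaults are the study conditions; they are fixed, not
tuning knobs.

* **Designs**: quartets (mother, father, proband, sibling) or mother-child
  dyads (cord blood, age 0). Child ages uniform 4–18 y; maternal age at
  childbirth normal(30, 5) clipped to 16–50.
* **Heteroplasmy load**: maternal (and paternal) heteroplasmy counts
  Poisson(1.2) at VAF log-uniform on [2%, 50%], drawn from the unmasked
  OXPHOS+tRNA change universe (≈ 78% of the molecule, the categories that
  carry pathogenicity scores). Fathers never transmit, by construction.
  Each lineage also carries ~Poisson(10) private homoplasmies, which give
  the QC layer a realistic major-allele signal.
* **Bottleneck and selection**: the child allele count is a binomial draw
  of 32 segregating units at the maternal VAF (a single-generation
  bottleneck, the minimal mechanism producing VAF drift and loss; the
  choice of 32 units is in the range inferred for the human germline).
  With selection off, transmission is exactly bottleneck survival. With
  selection on, the transmitted indicator follows
  logit P = 0.6 + 2.5·VAF + log(0.64)·z, so the per-SD transmission OR
  equals the configured 0.64 *by construction* and a correctly specified
  logistic refit recovers it; the bottleneck then supplies the child VAF
  conditional on transmission. Stacking a thinning step on top of
  bottleneck survival instead would attenuate the refitted slope
  (non-collapsibility of the logistic), which is why the indicator is
  modeled directly.
* **De novo mutation**: count Poisson with mean 2e-5 × (unmasked sites)
  + 0.015 × (maternal age − 30) ≈ 0.33 per child at age 30 — the scale of
  *detectable* de novo heteroplasmies per child, not the molecular per-
  genome rate. Entries are drawn from the universe with an exponential
  tilt exp(θz), θ = 0.02 × (age − 30), giving an approximately linear
  location shift of pathogenicity with maternal age; VAF log-uniform on
  [1.5%, 30%].
* **Pileups**: depth negative-binomial (mean 2,000, sd 300), ~50/50
  strand split, error floor 0.0002 per base spread equally over the three
  non-reference alleles (strand-symmetric by default, with a strand-bias
  knob for testing the concordance filter), per-allele mean BAQ
  normal(33, 2), site-level fraction of BAQ ≥ 30 bases ~0.92.
* **Content**: additive-genetic decomposition on the standardized scale —
  parental additive values N(0, h²), child = midparent + segregation
  N(0, h²/2), residual environment topping variance to one — so
  midparent-offspring regression recovers h² = 0.65 and the parent-child
  correlation is h²/2 ≈ 0.325 (an extra shared-environment term is added
  only if a larger correlation is requested). Raw content is
  150 + 35·latent − 1.0·(age − mean age), floored at 5 copies.
* **Phenotype**: in quartets the case child is drawn within family with
  softmax probability of the linear predictor log(1.5)·carryPP +
  log(1.4)·carryPP·lowT1 + log(0.85)·mtCNz — the exact conditional-
  logistic generating process, so matched refits are correctly specified.
  Probands are male with probability 0.8. Dyads use a logistic model with
  baseline prevalence 0.2 and a sex term.
* **Determinism**: every family has its own spawned random stream, so the
  first k families are bit-identical whatever `n_families` is; pileups
  have per-sample streams. The phenotype layer is cohort-level (tertiles
  are cohort quantiles), so it is deterministic under the seed but not
  family-separable.
* **Synthetic scores**: a latent pathogenicity variable drives correlated
  CADD-like, PolyPhen-like, MutPred-like and MitoTIP-like marginals
  (≈ 7% of universe entries end up PP after the frequency screen, giving
  a ≈ 5% comparator-rule carrier prevalence among children — the scale of
  the motivating studies); population frequency is concentrated on benign
  changes.

What the generator does *not* emulate: NUMT contamination, alignment
artifacts, capture-efficiency variation and replicate VAF overdispersion
(a single error-floor knob stands in for the conflated sources), somatic
accumulation with age, and real linkage between sites. Passing tests
therefore demonstrate statistical correctness of the estimators under the
assumed mechanisms, not robustness to those real-data pathologies.

## Problem sizes in the test suite

The suite exercises parameter recovery at the sizes the designs call for —
2,000 families for the matched disease OR, 2,000 maternal heteroplasmies
for the transmission OR, 2,000 children for the maternal-age slope, 5,000
trios for heritability — and calibration at 250–5,000 Monte-Carlo
replicates with a ±2 MC-SE band. Caller error control uses 100 error-only
whole-molecule samples; sensitivity uses 360 planted variants at VAF
5–45%. These sizes make every check sharp enough to detect the relevant
failure modes while keeping the whole suite in the minutes range on one
CPU.

## Known limitations

* The caller operates on pileup summaries; read-level artifacts that
  survive the upstream filters are invisible to it.
* Conditional logistic fitting supports 1:1 family strata (the quartet
  design); general m:n strata are out of scope.
* The mutation-rate estimator's detectability correction must be supplied
  by the user; no attempt is made to infer it from depth profiles.
* The meta-analysis assumes symmetric log-scale Wald CIs when
  back-calculating SEs; profile-likelihood CIs would be mildly
  misweighted.
* Indels, NUMT database lookups, haplogroup nomenclature, and nuclear
  variant calling are out of scope.
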