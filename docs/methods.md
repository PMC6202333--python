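# Methods

`cgdseek` reimplements, as a tested library, the computational chain by which
a rare homozygous loss-of-function genotype can be discovered and
characterized in a founder population: family-based rare-genotype filtering,
single-site genealogical imputation with an informativeness score,
recessive-model association testing, Hardy-Weinberg founder arithmetic, and
dihydrorhodamine (DHR) oxidative-burst classification.  Every analysis runs
on synthetic cohorts with retained ground truth, so each statistical claim in
the test suite is checked against an oracle rather than asserted.

## Rare-genotype prioritization

Genotypes are alternate-allele counts 0/1/2 per individual (0/1 for males on
the X chromosome; pseudo-autosomal regions are not modelled).  All
frequencies are minor allele frequencies (MAF): alternate-allele fractions
folded at 0.5, with the alternate allele treated as minor on an exact tie —
the tie-break only matters at MAF exactly 0.5, far above every filter
threshold.

Two inheritance-model filters operate on a family plus two reference
frequency columns (an internal population panel and an external database):

* **Dominant** (default threshold MAF < 0.05%): the variant must be
  heterozygous in every affected individual, below threshold in both
  references, and absent from both unaffected parents.
* **Recessive** (default threshold MAF < 2%): the genotype must be
  homozygous — hemizygous for males on X — in every affected individual, or
  a gene-level pair of heterozygous variants in trans; every contributing
  variant must individually pass the threshold in both references.  The
  per-variant (rather than per-genotype) threshold is the interpretation
  adopted here.

Decisions where the procedure was genuinely open:

* An **absent external frequency passes** the external clause: absence from
  a database of >100k individuals is evidence of rarity, not missingness to
  be penalized.  An absent internal frequency is treated as 0 (never
  observed in the reference panel).
* A **missing genotype in any affected excludes** the candidate
  (conservative: an unverifiable genotype is not a discovery).
* Compound-heterozygous pairs whose phase cannot be resolved are **retained
  and flagged `ambiguous`** rather than silently kept or dropped; pairs
  forced in cis in any affected are dropped.  Intergenic variants (no gene
  symbol) never pair.
* The dominant filter requires the variant in **all** affecteds, not any.

Compound-het phasing enumerates the four possible parental origins of the
two alternate alleles and keeps those compatible with each parent's
genotype; the verdict is `in_trans`/`in_cis` only when every compatible
configuration agrees.  A property test checks this against brute-force
enumeration of explicit parental haplotype pairs on every constructible trio.

A segregation check then rejects recessive candidates carried as the full
genotype by any unaffected relative, and dominant candidates carried at all.
For compound hets the conservative rule is used: an unaffected relative
carrying *both* variants (in any phase) fails the candidate.

Impact classes map consequence terms to `high` (stop-gained, frameshift,
splice acceptor/donor, ...), `moderate` (missense, splice-region, in-frame
indels, ...), `low` (synonymous, UTR), `dhs` (annotated regulatory/DNase-I
hypersensitivity terms), and `remaining` (everything else, including
unknown).  The exact membership of `low` and `dhs` beyond the headline terms
is this package's documented choice.

## Genealogical imputation

Imputation is single-site and genealogy-only: a deliberate simplification of
population-scale long-range-haplotype imputation, which needs genotyping
-array haplotypes unavailable at this scale.  The algorithm assigns an
allele to a haplotype only when Mendelian logic forces it:

1. a homozygous parent fixes the allele it transmits;
2. a proven heterozygote with one resolved haplotype has the other forced;
3. a child's resolved transmitted allele proves its parent carries that
   allele — on an identified haplotype side when the parent's other side is
   already fixed to the complement, otherwise as an origin-unlabelled
   "floating" allele; two distinct floating alleles prove heterozygosity.

These rules run to a fixed point; any contradiction is a Mendelian
inconsistency and the site is rejected.  There is no probabilistic peeling,
which keeps every assignment checkable against the gene-dropping ground
truth.

Each unresolved haplotype then contributes its conditional expectation,
computed founders-first: the mean of the transmitting parent's two haplotype
values when the parent is in the pedigree, the population allele frequency
`p` otherwise.  Using the parent-conditional mean (e.g. 0.5 for the child of
a typed heterozygote) rather than a flat `p` is what makes the dosage
`theta_hat = E(theta | typed data)` calibrated, with population mean 2p; the
flat prior applies exactly where no relative carries information.  Typed
individuals always keep their observed counts.

Because only forced chains propagate, evidence that is informative but not
deterministic (e.g. a heterozygous child raising the posterior allele count
of an untyped parent) is ignored.  At common allele frequencies this leaves
a small downward bias in the population mean dosage; at the rare-allele
frequencies this package targets (MAF < 1%) the effect is negligible, and
the calibration test runs at those conditions.

**Information score.** Imputation informativeness is the variance ratio

    info = Var(per-haplotype imputed expectations) / p(1 - p)

— 0 when the same value is always imputed, 1 when fully informative, and
asymptotically the squared correlation between imputed and true allele
counts.  The numerator uses haplotype-level values: a typed unphased
heterozygote contributes {0, 1} (its allele multiset is known even when
origins are not), not two copies of 0.5.  Halving the diploid dosage instead
would halve the score of a fully typed panel and break the fully-informative
= 1 anchor; the haplotype-level form reproduces both anchors exactly and
tracks the direct r² within 0.005–0.015 in the packaged simulations.  The
score can exceed 1 marginally through sampling noise; it is clipped only for
reporting.

X-linked sites are handled by the filters but not by the imputation module,
which assumes autosomal diploid transmission.

## Association testing

Binary outcomes use maximum-likelihood logistic regression with the
homozygosity indicator plus covariates (sex, age, region in the synthetic
cohorts); the p-value is the 1-df likelihood-ratio test, the effect the
exponentiated coefficient, and the 95% CI Wald on the log-odds scale (the CI
construction is this package's choice).  Under quasi-complete separation —
routine when every homozygote is a case — the fit switches to Firth's
penalized likelihood (Jeffreys-prior penalty `0.5 log|X'WX|`, Newton
iterations with leverage-adjusted scores, penalized LRT), implemented here
because no installed library provides it; the fallback is flagged in the
model label.

Quantitative traits are first adjusted for covariates by ordinary least
squares, then rank-inverse-normal standardized with Blom plotting positions
`(rank - 3/8)/(n + 1/4)` (ties share averaged ranks), and tested with an
ordinary fixed-effect linear model.  **No mixed-model relatedness correction
is applied.**  This is an explicit deviation from biobank-scale practice
(which uses a linear mixed model): with strong cryptic relatedness the
fixed-effect test is anticonservative, and the synthetic generator can
inject family structure precisely so that this inflation can be
demonstrated.  Effects are reported in SD units; a caller-supplied reference
SD converts to natural units.

Dosages become homozygosity indicators by hard-calling at `theta_hat > 1.5`
(configurable); no hard-call rule is claimed to be the original one.

Genome-wide significance uses weighted-Bonferroni class thresholds:
high 2.5e-7, moderate 5.0e-8, low 4.5e-9, DHS 2.3e-9, remaining 7.5e-10.

## Founder-population arithmetic

Under Hardy-Weinberg equilibrium (no inbreeding coefficient), carrier
fraction `2p(1-p)`, homozygote fraction `p²`, and genotype-count prevalence
`positives/n`.  Unrounded values are always returned; the report forms are
this package's conventions: carrier reciprocals rounded to one significant
figure, prevalence reciprocals to the nearest 1,000 / 100 / 10 above
10,000 / 1,000 / below.  At MAF 0.76% the carrier fraction is 0.01508
("1 in 70"; unrounded 1 in 66.3); the expected homozygote count in 338,000
people is 19.52 and is reported as the unrounded value with an integer
rounding of 20 alongside — it is not forced to any previously printed
figure.

## Burst assay

The stimulation index is the ratio of geometric-mean fluorescence of
PMA-stimulated over unstimulated events — the standard DHR convention; the
formula behind published SI values is often unstated, so printed indices are
treated as classification inputs, not computation targets.  Zero intensities
trigger a logged +1 offset applied to both conditions.  The positivity gate
is the 0.99 quantile of the unstimulated distribution (configurable; the
gate is usually drawn, not parameterized, in published figures).  An SI
strictly below 3 classifies the burst as impaired, the regime of severe
(X-linked-like) disease.  SI is scale-equivariant: rescaling both conditions
by any constant leaves it unchanged (exactly, when no offset is triggered).

## Synthetic cohorts

The generator emulates the study conditions and nothing more:

* **Genealogy**: `n_generations` (default 4) of monogamous random matings,
  ~`n_individuals/n_generations` per generation, multinomial sibship sizes
  with mean 3; founders and marry-ins have no recorded parents.
* **Gene drop**: founder haplotypes carry the focal allele at
  `founder_maf = 0.0076`; fair Mendelian segregation; independent decoy
  variants with a log-uniform MAF spectrum.  Single-site model: no linkage
  disequilibrium, recombination, or sequence context — every analysis under
  test is single-variant.
* **Phenotypes**: binary outcome from a logistic model with baseline risk
  0.007 and homozygote odds ratio 67.6; quantitative trait standard normal
  with a homozygote shift of −1.24 SD; mild sex/age/region covariate effects
  (region drawn from 8 categories) so covariate adjustment is exercised.
* **Typing**: a `chip_typed_fraction` (default 0.5) of individuals is
  genotyped in the emitted VCF; the rest are missing calls for the
  imputation stage.  Ground truth retains complete genotypes and haplotype
  origins.
* **Flow events**: lognormal intensities (σ = 0.3) whose true geometric-mean
  ratio equals the requested stimulation index.
* **Seeding**: one master seed; child generators derived per operation via
  spawn keys, so every output is reproducible and independent per stage.

The seven-member discovery-family fixture is deterministic (byte-identical
across builds) and synthetic: it is constructed from published summary
descriptions (genotype pattern, frequencies, consequences), not from any
individual-level data.  It carries the high-impact founder site (MAF 0.76%,
absent externally), the moderate-impact homozygous missense site (0.33%), a
known oxidase-gene site absent from the affecteds (0.58%), and decoys that
each exercise one rejection path: a homozygous site above 2%, a common
heterozygous gene pair, and a rare in-cis pair.

**What passing tests do and do not show.**  The synthetic cohorts have fair
segregation, perfectly known pedigrees, no genotyping error, no missingness
beyond the typing mask, and covariates with known effects.  Passing tests
therefore demonstrate the correctness of the algorithms under their stated
models, not robustness to pedigree errors, genotype error, population
structure, or ascertainment bias — none of which the generator emulates.

## Problem sizes and numerical choices

The packaged test suite and acceptance script use: 1,000 random trios for
the phasing oracle; 10,000 haplotypes for the information-vs-r² check;
10,000 individuals (50% typed) for dosage calibration; 1,000 null replicates
for LRT calibration; 100 replicates of n = 50,000 with 8 homozygotes for
quantitative-effect recovery; and a 150,000-individual gene-dropped cohort
for odds-ratio recovery — chosen as the sizes at which each statistical
check is informative.  With roughly ten homozygotes, the recovered odds
ratio is intrinsically noisy (a wide CI is the honest output, as in the
original regime).  Logistic fits cap at 200 Newton iterations; a
non-converged or infinite-SE fit falls through to Firth.  LRT statistics are
floored at 0 and p-values clamped to (0, 1].

## Known limitations

* Imputation ignores non-forced probabilistic evidence (by design) and does
  not handle X-linked transmission.
* No mixed-model correction for relatedness in association tests.
* The compound-het segregation rule is conservative and can reject true
  candidates when an unaffected relative carries both variants in cis.
* The VCF writer emits minimal headers (GT only); BCF, indexing, structural
  variants, and phased input genotypes are out of scope.
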