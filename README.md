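# cgdseek

Rare recessive genotype discovery in founder populations: pedigree-aware
rare-variant prioritization, genealogical genotype imputation with an
informativeness score, recessive-model association testing, Hardy-Weinberg
founder arithmetic, and oxidative-burst (DHR assay) classification.

## Who this is for

Statistical geneticists and rare-disease analysts who want the full
discovery chain behind a founder-population recessive finding — from a
sequenced nuclear family to a population-level prevalence statement — as a
tested, scriptable library rather than a one-off analysis.  The motivating
setting is chronic granulomatous disease (CGD): two affected brothers
homozygous for a stop-gained founder allele in an NADPH-oxidase chaperone
gene, with the allele segregating at minor allele frequency (MAF) ~0.76% in
the population.

## The models at the core

**Prioritization.** For a family with affected individuals, retain
heterozygous genotypes with MAF < 0.05% absent from both unaffected parents
(dominant model), and homozygous or trans compound-heterozygous genotypes
whose variants each have MAF < 2% in an internal reference panel and an
external database (recessive model), then reject candidates carried as the
full genotype by unaffected relatives.

**Imputation.** At a single site, untyped individuals receive
θ̂ = E(θ | typed relatives) via forced haplotype transmission through the
pedigree; unresolved haplotypes contribute their conditional expectation.
Informativeness is the variance ratio

    info = Var(E(θ | data)) / p(1 − p),   θ = haplotype allele count,

which is 0 when imputation is uninformative, 1 when fully informative, and
asymptotically the r² between imputed and true allele counts.

**Association.** Recessive logistic regression with a 1-df likelihood-ratio
test (Firth-penalized fallback under separation) for binary outcomes;
rank-inverse-normal standardization (Blom offsets) plus a fixed-effect
linear model for quantitative traits; weighted-Bonferroni significance
thresholds per functional impact class (2.5×10⁻⁷ for high-impact down to
7.5×10⁻¹⁰ for remaining variants).

**Founder arithmetic.** Under Hardy-Weinberg equilibrium, carrier fraction
2p(1−p), expected homozygote count p²N, and genotype-based prevalence
positives/n with "1 in N" reporting.

**Burst assay.** Stimulation index SI = geometric-mean fluorescence of
PMA-stimulated over unstimulated neutrophils; SI < 3 classifies the burst
as impaired.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

Build the packaged seven-member discovery family (two affected brothers,
heterozygous parents, two heterozygous and one non-carrier sibling), add two
simulated burst samples, and run the pipeline:

```python
import tempfile
from cgdseek import RunConfig, run_pipeline
from cgdseek.synthetic_population import (
    build_proband_family_fixture, simulate_flow_events, write_flow_events,
)

d = tempfile.mkdtemp()
build_proband_family_fixture(d)
write_flow_events(
    [simulate_flow_events(1.5, 2000, seed=1, sample_id="probandA"),
     simulate_flow_events(8.0, 2000, seed=2, sample_id="control")],
    f"{d}/events.tsv",
)
summary = run_pipeline(RunConfig(
    vcf=f"{d}/family.vcf", ped=f"{d}/family.ped", freq=f"{d}/freqs.tsv",
    events=f"{d}/events.tsv", out_dir=f"{d}/out",
))
```

The summary (also written to `out/summary.json`) contains:

```
"n_candidates": 2
"high_impact_recessive": [{"gene": "CYBC1", "variants": ["chr17:82449249:C>G"]}]
"imputation": {"variant": "chr17:82449249:C>G", "information": 1.0}
"burst": [
  {"sample_id": "control",  "si": 7.9651, "classification": "normal"},
  {"sample_id": "probandA", "si": 1.4843, "classification": "impaired"}
]
```

Reading: the recessive MAF < 2% filter leaves exactly two candidate
genotypes (a homozygous stop-gained variant in *CYBC1* at MAF 0.76% and a
homozygous missense variant in *GCGR* at 0.33%); requiring high functional
impact isolates the *CYBC1* knockout.  The family is fully genotyped, so
imputation information is 1.0.  The burst sample simulated at a true
stimulation index of 1.5 is classified impaired (SI < 3); the control at 8.0
is normal.

Founder arithmetic from the command line:

```bash
cgdseek founder-stats --maf 0.0076 --pop-size 338000 \
    --positives 13 --n-genotyped 155250
```

prints carrier fraction 0.01508 ("1 in 70", unrounded 1 in 66.3), an
expected 19.52 homozygotes among 338,000 people, and a genotype-based
prevalence of "1 in 12,000" (unrounded 1 in 11,942).

Other subcommands: `cgdseek simulate | prioritize | impute | associate |
burst | run --config config.yaml`.

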