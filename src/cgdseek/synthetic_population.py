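"""Synthetic founder-population cohorts with known ground truth.

Generates every input the pipeline consumes, with the statistical structure
the analysis assumes: a multi-generation genealogy, gene-dropped genotypes
for a rare founder allele (default minor allele frequency 0.76%) plus decoy
variants, phenotypes with a recessive disease effect (default homozygote
odds ratio 67.6 on a binary outcome and a -1.24 SD homozygote shift on a
quantitative trait), and lognormal flow-cytometry event lists for burst
assays.  The model is single-site: no linkage disequilibrium, recombination,
or sequence-level realism — the analyses under test are single-variant.

Ground truth (true genotypes, haplotype origins, liabilities) is retained so
simulations can serve as oracles for the imputation, association, and burst
modules.  All randomness flows from one master seed; child generators are
derived deterministically per operation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    Individual,
    Pedigree,
    VariantRecord,
    write_frequency_table,
    write_pedigree,
    write_vcf,
)
from .variant_prioritization import FrequencyRecord

#: spawn keys for per-operation child generators (one master seed in config)
_RNG_TAGS = {"genealogy": 0, "gene_drop": 1, "phenotypes": 2, "flow": 3, "typing": 4}


def child_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-operation generator derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_RNG_TAGS[tag],)))


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the discovery setting: a founder stop-gained allele at
    MAF 0.76%, a rare recessive binary outcome with homozygote odds ratio
    67.6 over a ~0.7% baseline risk, and a -1.24 SD homozygote shift in a
    standardized quantitative trait.
    """

    n_individuals: int = 5000
    n_generations: int = 4
    founder_maf: float = 0.0076
    chip_typed_fraction: float = 0.5
    baseline_risk: float = 0.007
    homozygote_or: float = 67.6
    quant_effect_sd: float = -1.24
    n_decoy_variants: int = 10
    decoy_maf_range: tuple[float, float] = (0.005, 0.4)
    mean_sibship: float = 3.0
    n_regions: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("founder_maf", "chip_typed_fraction", "baseline_risk"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_individuals < 1 or self.n_generations < 1:
            raise ValueError("need at least one individual and one generation")


@dataclass
class GroundTruth:
    """Simulator-internal truth, the oracle store for downstream tests."""

    focal_variant: VariantRecord
    focal_haplotypes: dict[str, tuple[int, int]]  # id -> (paternal, maternal)
    genotypes: dict[str, dict[str, int]]  # variant str key -> id -> count
    realized_maf: float
    liabilities: dict[str, float] = field(default_factory=dict)

    def focal_counts(self) -> dict[str, int]:
        return {iid: a + b for iid, (a, b) in self.focal_haplotypes.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "focal_variant": str(self.focal_variant),
            "realized_maf": self.realized_maf,
            "focal_haplotypes": {k: list(v) for k, v in self.focal_haplotypes.items()},
            "genotypes": self.genotypes,
            "liabilities": self.liabilities,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# Genealogy
# ---------------------------------------------------------------------------


def simulate_genealogy(config: SimulationConfig) -> Pedigree:
    """Multi-generation pedigree with monogamous matings.

    Generation sizes are approximately ``n_individuals / n_generations``;
    couples are formed by random pairing within the previous generation and
    children are assigned to couples at random, giving multinomial sibship
    sizes with the configured mean.  Reproducible from the config seed.
    """
    rng = child_rng(config.seed, "genealogy")
    per_gen = max(2, config.n_individuals // config.n_generations)
    individuals: list[Individual] = []
    prev_gen: list[Individual] = []
    counter = 0
    for gen in range(config.n_generations):
        birth_year = 1900 + 25 * gen
        size = per_gen if gen < config.n_generations - 1 else max(
            2, config.n_individuals - per_gen * (config.n_generations - 1)
        )
        this_gen: list[Individual] = []
        males = [i for i in prev_gen if i.sex == "male"]
        females = [i for i in prev_gen if i.sex == "female"]
        rng.shuffle(males)
        rng.shuffle(females)
        n_couples_possible = min(len(males), len(females))
        n_couples = (
            0
            if gen == 0 or n_couples_possible == 0
            else max(1, min(n_couples_possible, int(round(size / config.mean_sibship))))
        )
        couples = list(zip(males[:n_couples], females[:n_couples]))
        for _ in range(size):
            counter += 1
            sex = "male" if rng.random() < 0.5 else "female"
            if couples:
                f, m = couples[rng.integers(len(couples))]
                father_id, mother_id = f.id, m.id
            else:
                father_id = mother_id = None  # founder (or marry-in)
            this_gen.append(
                Individual(
                    id=f"I{counter:06d}",
                    sex=sex,
                    father_id=father_id,
                    mother_id=mother_id,
                    birth_year=int(birth_year + rng.integers(0, 10)),
                )
            )
        individuals.extend(this_gen)
        prev_gen = this_gen
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

FOCAL_VARIANT = VariantRecord(
    chrom="chr17",
    pos=82_449_249,
    ref="C",
    alt="G",
    gene="CYBC1",
    consequence="stop_gained",
    hgvs_p="p.Tyr2Ter",
)

_DECOY_CONSEQUENCES = (
    "missense_variant",
    "synonymous_variant",
    "intron_variant",
    "splice_region_variant",
    "stop_gained",
)


def gene_drop(
    pedigree: Pedigree, config: SimulationConfig
) -> tuple[list[tuple[VariantRecord, dict[str, int | None]]], GroundTruth]:
    """Drop founder alleles through the pedigree under fair segregation.

    Founder haplotypes carry the focal allele with probability
    ``founder_maf``; every child inherits one uniformly chosen haplotype
    from each parent.  Decoy variants are dropped independently with
    frequencies spanning ``decoy_maf_range``.  Returns the per-variant call
    tables and the ground truth (haplotype origins, realized frequency).
    """
    rng = child_rng(config.seed, "gene_drop")
    order = pedigree.topological_order()
    n = len(order)

    def drop_one(maf: float) -> dict[str, tuple[int, int]]:
        founder_alleles = rng.random((n, 2)) < maf  # consumed for founder slots
        picks = rng.integers(0, 2, size=(n, 2))  # which parental haplotype drops
        haps: dict[str, tuple[int, int]] = {}
        for idx, iid in enumerate(order):
            ind = pedigree[iid]
            alleles = []
            for j, pid in enumerate((ind.father_id, ind.mother_id)):
                if pid is None or pid not in pedigree.individuals:
                    alleles.append(int(founder_alleles[idx, j]))
                else:
                    alleles.append(haps[pid][picks[idx, j]])
            haps[iid] = (alleles[0], alleles[1])
        return haps

    focal_haps = drop_one(config.founder_maf)
    focal_counts: dict[str, int | None] = {i: a + b for i, (a, b) in focal_haps.items()}
    n_haps = 2 * len(pedigree)
    realized = sum(sum(h) for h in focal_haps.values()) / n_haps if n_haps else 0.0

    calls: list[tuple[VariantRecord, dict[str, int | None]]] = [
        (FOCAL_VARIANT, focal_counts)
    ]
    genotypes = {str(FOCAL_VARIANT): {k: v for k, v in focal_counts.items()}}
    lo, hi = config.decoy_maf_range
    for k in range(config.n_decoy_variants):
        maf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rec = VariantRecord(
            chrom="chr1",
            pos=1_000_000 + 1_000 * k,
            ref="A",
            alt="T",
            gene=f"DECOY{k + 1}",
            consequence=_DECOY_CONSEQUENCES[k % len(_DECOY_CONSEQUENCES)],
        )
        haps = drop_one(maf)
        counts = {i: a + b for i, (a, b) in haps.items()}
        calls.append((rec, counts))
        genotypes[str(rec)] = counts
    truth = GroundTruth(
        focal_variant=FOCAL_VARIANT,
        focal_haplotypes=focal_haps,
        genotypes=genotypes,
        realized_maf=realized,
    )
    return calls, truth


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    pedigree: Pedigree, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Binary and quantitative phenotypes with a recessive genotype effect.

    The binary outcome follows a logistic model: baseline log-odds plus
    ``ln(homozygote_or)`` for focal homozygotes plus mild sex/age/region
    effects.  The quantitative trait is standard normal plus
    ``quant_effect_sd`` for homozygotes plus the same covariates.  Columns:
    id, case_status, trait, sex, age, region.
    """
    rng = child_rng(config.seed, "phenotypes")
    counts = truth.focal_counts()
    inds = list(pedigree)
    n = len(inds)
    base_logit = float(np.log(config.baseline_risk / (1 - config.baseline_risk)))
    log_or = float(np.log(config.homozygote_or))
    region_effect = rng.normal(0.0, 0.1, size=config.n_regions)

    hom = np.array([1 if counts.get(i.id, 0) == 2 else 0 for i in inds])
    sex = np.array([1.0 if i.sex == "male" else 0.0 for i in inds])
    age = np.array([float(2018 - (i.birth_year or 1950)) for i in inds])
    region = rng.integers(config.n_regions, size=n)
    eta = base_logit + log_or * hom + 0.05 * sex + 0.002 * (age - 50) + region_effect[region]
    liability = eta + rng.logistic(size=n)
    case = (liability > 0).astype(int)
    trait = (
        rng.normal(size=n)
        + config.quant_effect_sd * hom
        + 0.1 * sex
        - 0.005 * (age - 50)
        + 0.05 * region_effect[region]
    )
    truth.liabilities.update({i.id: float(l) for i, l in zip(inds, liability)})
    return pd.DataFrame(
        {
            "id": [i.id for i in inds],
            "case_status": case,
            "trait": trait,
            "sex": [i.sex for i in inds],
            "age": age,
            "region": [f"R{r + 1}" for r in region],
        }
    )


# ---------------------------------------------------------------------------
# Flow-cytometry events
# ---------------------------------------------------------------------------


def simulate_flow_events(
    si_true: float,
    n_events: int = 10_000,
    seed: int = 0,
    sample_id: str = "S1",
    mu_unstim: float = np.log(50.0),
    sigma: float = 0.3,
):
    """Paired lognormal event sets whose true geometric-mean ratio is ``si_true``."""
    from .burst_assay import FlowEventSet

    if si_true <= 0:
        raise ValueError("si_true must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_RNG_TAGS["flow"],)))
    unstim = rng.lognormal(mean=mu_unstim, sigma=sigma, size=n_events)
    stim = rng.lognormal(mean=mu_unstim + np.log(si_true), sigma=sigma, size=n_events)
    return (
        FlowEventSet(sample_id, "PMA", stim),
        FlowEventSet(sample_id, "unstimulated", unstim),
    )


def write_flow_events(pairs, path: str | Path) -> None:
    """Write (stim, unstim) FlowEventSet pairs as a long event TSV."""
    rows = []
    for stim, unstim in pairs:
        for cond_set in (unstim, stim):
            for v in cond_set.fluorescences:
                rows.append((cond_set.sample_id, cond_set.condition, f"{v:.6g}"))
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\tintensity\n")
        for r in rows:
            fh.write("\t".join(r) + "\n")


# ---------------------------------------------------------------------------
# The packaged proband-family fixture
# ---------------------------------------------------------------------------

_FAMILY_IDS = ["A", "B", "father", "mother", "sib1", "sib2", "sib3"]


def build_proband_family_fixture(outdir: str | Path | None = None):
    """The seven-member discovery family with its candidate and decoy sites.

    Two affected brothers homozygous for a high-impact stop-gained founder
    allele (internal MAF 0.76%, absent from the external database) and for a
    moderate-impact missense allele (MAF 0.33%); both parents and two
    unaffected siblings are heterozygous carriers of each, the third sibling
    a non-carrier.  A known recessive site in another oxidase gene (MAF
    0.58%) is present in the family but absent from the affecteds, plus
    decoys: a homozygous site above the 2% recessive threshold, a common
    heterozygous pair in one gene, and a rare in-cis pair.  Deterministic:
    identical bytes on every build.

    Returns ``(pedigree, calls, freqs)``; when ``outdir`` is given, also
    writes family.vcf, family.ped and freqs.tsv there.
    """
    inds = [
        Individual("A", "male", "father", "mother", affected="yes", genotyped=True),
        Individual("B", "male", "father", "mother", affected="yes", genotyped=True),
        Individual("father", "male", affected="no", genotyped=True),
        Individual("mother", "female", affected="no", genotyped=True),
        Individual("sib1", "male", "father", "mother", affected="no", genotyped=True),
        Individual("sib2", "female", "father", "mother", affected="no", genotyped=True),
        Individual("sib3", "female", "father", "mother", affected="no", genotyped=True),
    ]
    pedigree = Pedigree(inds)

    def counts(a, b, fa, mo, s1, s2, s3):
        return dict(zip(_FAMILY_IDS, [a, b, fa, mo, s1, s2, s3]))

    sites: list[tuple[VariantRecord, dict[str, int | None], FrequencyRecord]] = [
        # the high-impact founder knockout analogue
        (
            FOCAL_VARIANT,
            counts(2, 2, 1, 1, 1, 1, 0),
            FrequencyRecord(maf_internal=0.0076, maf_external=None),
        ),
        # the moderate-impact homozygous missense analogue
        (
            VariantRecord("chr17", 81_811_277, "G", "A", "GCGR", "missense_variant",
                          "p.Ser150Asn"),
            counts(2, 2, 1, 1, 1, 0, 1),
            FrequencyRecord(maf_internal=0.0033, maf_external=0.002),
        ),
        # known recessive oxidase site, absent from the affecteds
        (
            VariantRecord("chr16", 88_643_289, "C", "T", "CYBA", "missense_variant",
                          "p.Arg90Trp"),
            counts(0, 0, 0, 1, 1, 0, 0),
            FrequencyRecord(maf_internal=0.0058, maf_external=0.003),
        ),
        # homozygous decoy above the recessive MAF threshold
        (
            VariantRecord("chr2", 5_000_000, "G", "C", "DECOYHOM", "missense_variant"),
            counts(2, 2, 1, 1, 1, 1, 1),
            FrequencyRecord(maf_internal=0.025, maf_external=0.03),
        ),
        # common heterozygous pair in one gene (fails the MAF clause)
        (
            VariantRecord("chr3", 7_000_000, "A", "G", "DECOYCOMMON", "missense_variant"),
            counts(1, 1, 1, 1, 0, 1, 1),
            FrequencyRecord(maf_internal=0.30, maf_external=0.28),
        ),
        (
            VariantRecord("chr3", 7_002_000, "T", "C", "DECOYCOMMON", "synonymous_variant"),
            counts(1, 1, 0, 1, 1, 0, 0),
            FrequencyRecord(maf_internal=0.25, maf_external=0.26),
        ),
        # rare pair forced in cis (father carries both, mother neither)
        (
            VariantRecord("chr4", 9_000_000, "C", "A", "DECOYCIS", "missense_variant"),
            counts(1, 1, 1, 0, 0, 0, 0),
            FrequencyRecord(maf_internal=0.005, maf_external=0.004),
        ),
        (
            VariantRecord("chr4", 9_001_000, "G", "T", "DECOYCIS", "missense_variant"),
            counts(1, 1, 1, 0, 1, 0, 0),
            FrequencyRecord(maf_internal=0.006, maf_external=0.005),
        ),
    ]
    calls = [(rec, cts) for rec, cts, _ in sites]
    freqs = {rec.key: fr for rec, _, fr in sites}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sexes = {i.id: i.sex for i in pedigree}
        write_vcf(calls, _FAMILY_IDS, outdir / "family.vcf", sexes=sexes)
        write_pedigree(pedigree, outdir / "family.ped")
        write_frequency_table(freqs, outdir / "freqs.tsv")
    return pedigree, calls, freqs


# ---------------------------------------------------------------------------
# Whole-cohort emission
# ---------------------------------------------------------------------------


def emit_cohort(config: SimulationConfig, outdir: str | Path) -> dict[str, str]:
    """Simulate a full cohort and write every pipeline input to ``outdir``.

    Files: cohort.vcf, cohort.ped, freqs.tsv, phenotypes.tsv, truth.json,
    events.tsv (one impaired and one normal burst sample).  A
    ``chip_typed_fraction`` of individuals is genotyped in the emitted VCF;
    the rest are written as missing calls (imputation's job downstream).
    Ground truth always holds the complete genotypes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pedigree = simulate_genealogy(config)
    calls, truth = gene_drop(pedigree, config)
    pheno = simulate_phenotypes(pedigree, truth, config)

    sample_ids = [i.id for i in pedigree]
    sexes = {i.id: i.sex for i in pedigree}
    rng = child_rng(config.seed, "typing")
    typed = {i for i in sample_ids if rng.random() < config.chip_typed_fraction}
    for ind in pedigree:
        ind.genotyped = ind.id in typed
    masked = [
        (rec, {i: (c if i in typed else None) for i, c in cts.items()})
        for rec, cts in calls
    ]
    write_vcf(masked, sample_ids, outdir / "cohort.vcf", sexes=sexes)
    write_pedigree(pedigree, outdir / "cohort.ped")
    freqs = {}
    from .variant_prioritization import UndefinedFrequencyError, compute_maf

    for rec, cts in masked:
        try:
            maf = compute_maf(cts, chrom=rec.chrom, sexes=sexes)
        except UndefinedFrequencyError:
            maf = 0.0
        freqs[rec.key] = FrequencyRecord(maf_internal=min(maf, 0.5), maf_external=None)
    write_frequency_table(freqs, outdir / "freqs.tsv")
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    pairs = [
        simulate_flow_events(1.5, n_events=2000, seed=config.seed, sample_id="impaired_case"),
        simulate_flow_events(8.0, n_events=2000, seed=config.seed + 1, sample_id="normal_control"),
    ]
    write_flow_events(pairs, outdir / "events.tsv")
    return {
        "vcf": str(outdir / "cohort.vcf"),
        "ped": str(outdir / "cohort.ped"),
        "freqs": str(outdir / "freqs.tsv"),
        "phenotypes": str(outdir / "phenotypes.tsv"),
        "truth": str(outdir / "truth.json"),
        "events": str(outdir / "events.tsv"),
    }
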