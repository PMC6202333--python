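"""Pedigree-aware rare-genotype prioritization.

Implements the discovery filters used to find a causal recessive genotype in
a sequenced nuclear family within a founder population:

* *dominant model* — variants heterozygous in every affected individual, with
  minor allele frequency (MAF) below 0.05% in both the internal reference
  panel and the external database, and absent from both unaffected parents;
* *recessive model* — genotypes homozygous (hemizygous for males on X) in
  every affected individual, or gene-level compound-heterozygous pairs in
  trans, where every contributing variant has MAF below 2% in both
  references;
* trio-based phasing of compound-heterozygote pairs by transmission logic;
* a family segregation check rejecting candidates carried (as the full
  genotype) by unaffected relatives.

Frequencies are *minor* allele frequencies: alternate-allele fractions are
folded at 0.5, treating the alternate allele as minor on an exact tie.
An absent external frequency is treated as passing the external clause —
absence from a large external database is itself evidence of rarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .io_formats import Pedigree, VariantRecord, X_CHROM_LABEL

DOMINANT_MAF_THRESHOLD = 0.0005
RECESSIVE_MAF_THRESHOLD = 0.02


class UndefinedFrequencyError(ValueError):
    """No called alleles at a site: frequency is undefined."""


class NoAffectedError(ValueError):
    """Filter invoked on a pedigree with no affected individuals."""


@dataclass(frozen=True)
class FrequencyRecord:
    """Minor-allele frequencies of one variant in the two reference sets."""

    maf_internal: float | None
    maf_external: float | None = None

    def __post_init__(self) -> None:
        for v in (self.maf_internal, self.maf_external):
            if v is not None and not (0.0 <= v <= 0.5):
                raise ValueError(f"MAF must lie in [0, 0.5], got {v}")


@dataclass(frozen=True)
class CandidateGenotype:
    """A genotype surviving an inheritance-model filter."""

    model: str  # dominant / recessive_hom / recessive_comphet / x_linked
    variants: tuple[VariantRecord, ...]
    carrier_ids: tuple[str, ...]
    phase: str  # in_trans / in_cis / ambiguous / not_applicable
    maf_summary: tuple[FrequencyRecord, ...]

    def __post_init__(self) -> None:
        if self.model == "recessive_comphet":
            if len(self.variants) != 2 or self.phase == "not_applicable":
                raise ValueError("compound het candidates need 2 variants and a phase")
        elif len(self.variants) != 1:
            raise ValueError(f"{self.model} candidates carry exactly 1 variant")


# ---------------------------------------------------------------------------
# Impact classification
# ---------------------------------------------------------------------------

#: Consequence-term -> impact-class mapping (every known term maps to exactly
#: one of high / moderate / low / dhs / remaining; anything else falls through
#: to "remaining").
IMPACT_CLASSES: dict[str, str] = {
    # protein-truncating / splice-disrupting
    "stop_gained": "high",
    "stop_lost": "high",
    "start_lost": "high",
    "frameshift_variant": "high",
    "splice_acceptor_variant": "high",
    "splice_donor_variant": "high",
    "transcript_ablation": "high",
    # protein-altering
    "missense_variant": "moderate",
    "splice_region_variant": "moderate",
    "inframe_insertion": "moderate",
    "inframe_deletion": "moderate",
    "protein_altering_variant": "moderate",
    # coding but (mostly) silent, UTRs
    "synonymous_variant": "low",
    "stop_retained_variant": "low",
    "start_retained_variant": "low",
    "5_prime_UTR_variant": "low",
    "3_prime_UTR_variant": "low",
    # annotated regulatory / DNase I hypersensitivity regions
    "regulatory_region_variant": "dhs",
    "TF_binding_site_variant": "dhs",
}

IMPACT_LABELS = ("high", "moderate", "low", "dhs", "remaining")


def classify_impact(consequence: str) -> str:
    """Map a consequence term to its impact class (total function)."""
    return IMPACT_CLASSES.get(consequence, "remaining")


# ---------------------------------------------------------------------------
# Frequency
# ---------------------------------------------------------------------------


def compute_maf(
    counts: Mapping[str, int | None],
    chrom: str | None = None,
    sexes: Mapping[str, str] | None = None,
    x_label: str = X_CHROM_LABEL,
) -> float:
    """Minor allele frequency from per-individual alternate-allele counts.

    Alternate-allele fraction folded to <= 0.5; exact ties keep the alternate
    allele as minor.  Missing calls are excluded from the denominator; males
    contribute a single allele on the X chromosome.
    """
    sexes = sexes or {}
    on_x = chrom == x_label
    alt = 0
    total = 0
    for iid, c in counts.items():
        if c is None:
            continue
        ploidy = 1 if (on_x and sexes.get(iid) == "male") else 2
        if c > ploidy:
            raise ValueError(f"allele count {c} exceeds ploidy {ploidy} for {iid}")
        alt += c
        total += ploidy
    if total == 0:
        raise UndefinedFrequencyError("no called alleles at site")
    f = alt / total
    return f if f <= 0.5 else 1.0 - f


def _passes_maf(freq: FrequencyRecord | None, threshold: float) -> bool:
    """Threshold clause on both references.

    Internal frequency absent is treated as 0 (the variant was never seen in
    the reference panel); external absent passes the external clause.
    """
    internal = 0.0 if freq is None or freq.maf_internal is None else freq.maf_internal
    if internal >= threshold:
        return False
    external = None if freq is None else freq.maf_external
    return external is None or external < threshold


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------


def _can_transmit_alt(count: int | None) -> bool:
    return count is None or count >= 1


def _can_transmit_ref(count: int | None) -> bool:
    return count is None or count <= 1


def phase_compound_het(
    child_counts: tuple[int, int],
    father_counts: tuple[int | None, int | None],
    mother_counts: tuple[int | None, int | None],
) -> str:
    """Phase a heterozygous variant pair in a child from parental genotypes.

    Enumerates the four possible parental origins of the two alternate
    alleles and keeps those compatible with each parent's genotype (a parent
    can transmit an alternate allele iff it carries one, and a reference
    allele iff it is not homozygous alternate; missing parental genotypes
    constrain nothing).  Returns ``in_trans`` when every compatible
    configuration places the alternates on opposite parental haplotypes,
    ``in_cis`` when all place them on the same, and ``ambiguous`` otherwise.
    """
    if child_counts != (1, 1):
        raise ValueError("child must be heterozygous at both sites")
    feasible: list[tuple[str, str]] = []
    parents = {"F": father_counts, "M": mother_counts}
    for o1 in ("F", "M"):
        for o2 in ("F", "M"):
            ok = True
            for site, origin in enumerate((o1, o2)):
                other = "M" if origin == "F" else "F"
                if not _can_transmit_alt(parents[origin][site]):
                    ok = False
                elif not _can_transmit_ref(parents[other][site]):
                    ok = False
            if ok:
                feasible.append((o1, o2))
    if not feasible:
        return "ambiguous"  # Mendelian-inconsistent input: undecidable
    kinds = {"trans" if a != b else "cis" for a, b in feasible}
    if kinds == {"trans"}:
        return "in_trans"
    if kinds == {"cis"}:
        return "in_cis"
    return "ambiguous"


# ---------------------------------------------------------------------------
# Segregation
# ---------------------------------------------------------------------------


def _is_hom(count: int | None, variant: VariantRecord, sex: str, x_label: str) -> bool:
    """Homozygous alternate, counting male-X hemizygotes as homozygous."""
    if count is None:
        return False
    if variant.chrom == x_label and sex == "male":
        return count == 1
    return count == 2


def check_segregation(
    candidate: CandidateGenotype,
    family: Pedigree,
    calls: Mapping[tuple[str, int, str, str], Mapping[str, int | None]],
    x_label: str = X_CHROM_LABEL,
) -> tuple[bool, str]:
    """Does the candidate genotype segregate with affection status?

    Recessive candidates fail when any unaffected relative carries the full
    genotype (homozygous, or carrying both variants of a compound-het pair);
    dominant candidates fail when any unaffected relative carries the variant
    at all.  Returns ``(passed, reason)``.
    """
    for iid in family.unaffected_ids:
        sex = family[iid].sex
        if candidate.model == "dominant":
            c = calls[candidate.variants[0].key].get(iid)
            if c is not None and c >= 1:
                return False, f"unaffected carrier {iid} of dominant variant"
        elif candidate.model in ("recessive_hom", "x_linked"):
            v = candidate.variants[0]
            if _is_hom(calls[v.key].get(iid), v, sex, x_label):
                return False, f"unaffected carrier {iid} of full genotype"
        else:  # recessive_comphet: conservative — both variants carried at all
            cs = [calls[v.key].get(iid) for v in candidate.variants]
            if all(c is not None and c >= 1 for c in cs):
                return False, f"unaffected carrier {iid} of full genotype"
    return True, "segregates with affection status"


# ---------------------------------------------------------------------------
# Model filters
# ---------------------------------------------------------------------------

CallTable = Sequence[tuple[VariantRecord, Mapping[str, int | None]]]


def calls_by_key(calls: CallTable) -> dict[tuple[str, int, str, str], Mapping[str, int | None]]:
    return {rec.key: counts for rec, counts in calls}


def filter_dominant(
    family: Pedigree,
    calls: CallTable,
    freqs: Mapping[tuple[str, int, str, str], FrequencyRecord],
    threshold: float = DOMINANT_MAF_THRESHOLD,
) -> list[CandidateGenotype]:
    """Dominant-model candidates: rare hets shared by all affecteds, absent
    from both unaffected parents and from every other unaffected relative."""
    affected = family.affected_ids
    if not affected:
        raise NoAffectedError("pedigree has no affected individuals")
    by_key = calls_by_key(calls)
    parent_ids = {
        pid
        for aid in affected
        for pid in (family[aid].father_id, family[aid].mother_id)
        if pid is not None and pid in family and family[pid].affected == "no"
    }
    out: list[CandidateGenotype] = []
    for rec, counts in calls:
        if not all(counts.get(a) == 1 for a in affected):
            continue
        if not _passes_maf(freqs.get(rec.key), threshold):
            continue
        if any((counts.get(pid) or 0) >= 1 or counts.get(pid) is None for pid in parent_ids):
            continue
        cand = CandidateGenotype(
            model="dominant",
            variants=(rec,),
            carrier_ids=tuple(affected),
            phase="not_applicable",
            maf_summary=(freqs.get(rec.key) or FrequencyRecord(None, None),),
        )
        if check_segregation(cand, family, by_key)[0]:
            out.append(cand)
    return out


def filter_recessive(
    family: Pedigree,
    calls: CallTable,
    freqs: Mapping[tuple[str, int, str, str], FrequencyRecord],
    threshold: float = RECESSIVE_MAF_THRESHOLD,
    x_label: str = X_CHROM_LABEL,
) -> list[CandidateGenotype]:
    """Recessive-model candidates: rare homozygotes (hemizygotes on male X)
    and gene-level compound-heterozygous pairs shared by all affecteds.

    Each contributing variant must pass the MAF threshold in both reference
    sets.  Compound-het pairs phased ``in_cis`` in any affected are dropped;
    unphaseable pairs are retained with phase ``ambiguous``.  Candidates in
    which any affected has a missing genotype are excluded, and candidates
    failing the family segregation check are dropped.
    """
    affected = family.affected_ids
    if not affected:
        raise NoAffectedError("pedigree has no affected individuals")
    by_key = calls_by_key(calls)
    out: list[CandidateGenotype] = []

    # (a) homozygous / hemizygous candidates
    for rec, counts in calls:
        if any(counts.get(a) is None for a in affected):
            continue
        if not all(_is_hom(counts[a], rec, family[a].sex, x_label) for a in affected):
            continue
        if not _passes_maf(freqs.get(rec.key), threshold):
            continue
        model = "x_linked" if rec.chrom == x_label else "recessive_hom"
        cand = CandidateGenotype(
            model=model,
            variants=(rec,),
            carrier_ids=tuple(affected),
            phase="not_applicable",
            maf_summary=(freqs.get(rec.key) or FrequencyRecord(None, None),),
        )
        if check_segregation(cand, family, by_key, x_label)[0]:
            out.append(cand)

    # (b) compound-heterozygous pairs, per gene (intergenic variants never pair)
    by_gene: dict[str, list[tuple[VariantRecord, Mapping[str, int | None]]]] = {}
    for rec, counts in calls:
        if not rec.gene:
            continue
        if any(counts.get(a) != 1 for a in affected):
            continue
        if not _passes_maf(freqs.get(rec.key), threshold):
            continue
        by_gene.setdefault(rec.gene, []).append((rec, counts))
    for gene, members in by_gene.items():
        members.sort(key=lambda rc: (rc[0].chrom, rc[0].pos, rc[0].alt))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                (v1, c1), (v2, c2) = members[i], members[j]
                phases = set()
                for aid in affected:
                    f, m = family[aid].father_id, family[aid].mother_id
                    fc = (
                        by_key[v1.key].get(f) if f in family.individuals else None,
                        by_key[v2.key].get(f) if f in family.individuals else None,
                    )
                    mc = (
                        by_key[v1.key].get(m) if m in family.individuals else None,
                        by_key[v2.key].get(m) if m in family.individuals else None,
                    )
                    phases.add(phase_compound_het((1, 1), fc, mc))
                if "in_cis" in phases:
                    continue
                phase = "in_trans" if phases == {"in_trans"} else "ambiguous"
                cand = CandidateGenotype(
                    model="recessive_comphet",
                    variants=(v1, v2),
                    carrier_ids=tuple(affected),
                    phase=phase,
                    maf_summary=(
                        freqs.get(v1.key) or FrequencyRecord(None, None),
                        freqs.get(v2.key) or FrequencyRecord(None, None),
                    ),
                )
                if check_segregation(cand, family, by_key, x_label)[0]:
                    out.append(cand)
    out.sort(key=lambda c: (c.variants[0].chrom, c.variants[0].pos, c.model))
    return out
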