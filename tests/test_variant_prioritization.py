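"""Rare-genotype filters: MAF folding, impact classes, dominant/recessive
selection, compound-het phasing against exhaustive enumeration, segregation."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cgdseek.io_formats import Individual, Pedigree, VariantRecord
from cgdseek.variant_prioritization import (
    CandidateGenotype,
    FrequencyRecord,
    NoAffectedError,
    UndefinedFrequencyError,
    calls_by_key,
    check_segregation,
    classify_impact,
    compute_maf,
    filter_dominant,
    filter_recessive,
    phase_compound_het,
)


# ---------------------------------------------------------------------------
# compute_maf
# ---------------------------------------------------------------------------


class TestComputeMAF:
    def test_direct_count(self):
        assert compute_maf({"a": 0, "b": 1, "c": 1, "d": 2}) == pytest.approx(0.5)

    def test_all_reference(self):
        assert compute_maf({"a": 0, "b": 0}) == 0.0

    def test_folding_matches_bruteforce_minor_count(self):
        counts = {f"i{k}": 2 for k in range(9)} | {"j": 0}
        # brute force: count both alleles, take the rarer
        alt = sum(counts.values())
        total = 2 * len(counts)
        expected = min(alt, total - alt) / total
        assert compute_maf(counts) == pytest.approx(expected) == pytest.approx(0.1)

    def test_missing_excluded_from_denominator(self):
        assert compute_maf({"a": 1, "b": None}) == pytest.approx(0.5)

    def test_zero_called_alleles_raises(self):
        with pytest.raises(UndefinedFrequencyError):
            compute_maf({"a": None})


def test_male_x_fold_value():
    # 2 alt alleles out of 3 called -> folded MAF 1/3
    maf = compute_maf({"m": 1, "f": 1}, chrom="chrX", sexes={"m": "male", "f": "female"})
    assert maf == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# classify_impact
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "term,label",
    [
        ("stop_gained", "high"),
        ("frameshift_variant", "high"),
        ("splice_acceptor_variant", "high"),
        ("splice_donor_variant", "high"),
        ("missense_variant", "moderate"),
        ("splice_region_variant", "moderate"),
        ("inframe_deletion", "moderate"),
        ("synonymous_variant", "low"),
        ("regulatory_region_variant", "dhs"),
        ("intergenic_variant", "remaining"),
        ("unknown", "remaining"),
        ("never_heard_of_it", "remaining"),
    ],
)
def test_classify_impact(term, label):
    assert classify_impact(term) == label


# ---------------------------------------------------------------------------
# phasing: implementation vs exhaustive transmission enumeration
# ---------------------------------------------------------------------------


def enumerate_phase(father, mother):
    """Independent oracle: enumerate explicit parental haplotype pairs over
    two sites, keep configurations producing a double-het child, and classify
    the child's phase across all of them."""
    def haplotype_pairs(counts):
        out = []
        for g1 in ([0, 1, 2] if counts[0] is None else [counts[0]]):
            for g2 in ([0, 1, 2] if counts[1] is None else [counts[1]]):
                site1 = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[g1]
                site2 = {0: [(0, 0)], 1: [(0, 1), (1, 0)], 2: [(1, 1)]}[g2]
                for a in site1:
                    for b in site2:
                        # haplotype h is (allele at site1, allele at site2)
                        out.append(((a[0], b[0]), (a[1], b[1])))
        return out

    kinds = set()
    for fh in haplotype_pairs(father):
        for mh in haplotype_pairs(mother):
            for ft in fh:  # transmitted paternal haplotype
                for mt in mh:  # transmitted maternal haplotype
                    child = (ft[0] + mt[0], ft[1] + mt[1])
                    if child != (1, 1):
                        continue
                    if ft == (1, 1) or mt == (1, 1):
                        kinds.add("cis")
                    else:
                        kinds.add("trans")
    if not kinds:
        return "ambiguous"
    if kinds == {"trans"}:
        return "in_trans"
    if kinds == {"cis"}:
        return "in_cis"
    return "ambiguous"


class TestPhaseCompoundHet:
    def test_opposite_carriers_force_trans(self):
        assert phase_compound_het((1, 1), (1, 0), (0, 1)) == "in_trans"

    def test_single_parent_carrying_both_forces_cis(self):
        assert phase_compound_het((1, 1), (1, 1), (0, 0)) == "in_cis"

    def test_double_het_parents_ambiguous(self):
        assert phase_compound_het((1, 1), (1, 1), (1, 1)) == "ambiguous"

    def test_missing_parents_ambiguous(self):
        assert phase_compound_het((1, 1), (None, None), (None, None)) == "ambiguous"

    def test_child_not_double_het_raises(self):
        with pytest.raises(ValueError):
            phase_compound_het((2, 1), (1, 0), (0, 1))

    def test_agrees_with_enumeration_on_all_parent_genotype_pairs(self):
        vals = [0, 1, 2, None]
        for father in itertools.product(vals, vals):
            for mother in itertools.product(vals, vals):
                expected = enumerate_phase(father, mother)
                got = phase_compound_het((1, 1), father, mother)
                assert got == expected, (father, mother, got, expected)

    @settings(max_examples=300, deadline=None)
    @given(
        st.tuples(st.sampled_from([0, 1, 2, None]), st.sampled_from([0, 1, 2, None])),
        st.tuples(st.sampled_from([0, 1, 2, None]), st.sampled_from([0, 1, 2, None])),
    )
    def test_property_matches_oracle(self, father, mother):
        assert phase_compound_het((1, 1), father, mother) == enumerate_phase(father, mother)


# ---------------------------------------------------------------------------
# dominant / recessive filters on constructed families
# ---------------------------------------------------------------------------


def nuclear_family():
    return Pedigree(
        [
            Individual("p1", "male", "dad", "mom", affected="yes"),
            Individual("p2", "male", "dad", "mom", affected="yes"),
            Individual("dad", "male", affected="no"),
            Individual("mom", "female", affected="no"),
            Individual("sib", "female", "dad", "mom", affected="no"),
        ]
    )


def make_call(gene, consequence, counts, pos=1000, chrom="chr5"):
    rec = VariantRecord(chrom, pos, "A", "T", gene, consequence)
    return rec, dict(counts)


class TestFilterDominant:
    def test_rare_het_absent_from_parents_retained(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 1, "p2": 1, "dad": 0, "mom": 0, "sib": 0})]
        freqs = {calls[0][0].key: FrequencyRecord(0.0004, 0.0003)}
        out = filter_dominant(fam, calls, freqs)
        assert len(out) == 1 and out[0].model == "dominant"

    def test_carried_by_unaffected_parent_removed(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 1, "p2": 1, "dad": 1, "mom": 0, "sib": 0})]
        freqs = {calls[0][0].key: FrequencyRecord(0.0004, None)}
        assert filter_dominant(fam, calls, freqs) == []

    def test_maf_above_threshold_removed(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 1, "p2": 1, "dad": 0, "mom": 0, "sib": 0})]
        freqs = {calls[0][0].key: FrequencyRecord(0.0006, None)}
        assert filter_dominant(fam, calls, freqs) == []

    def test_no_affecteds_raises(self):
        fam = Pedigree([Individual("x", "male", affected="no")])
        with pytest.raises(NoAffectedError):
            filter_dominant(fam, [], {})


class TestFilterRecessive:
    def test_rare_homozygote_retained(self):
        fam = nuclear_family()
        calls = [make_call("CYBC1", "stop_gained",
                           {"p1": 2, "p2": 2, "dad": 1, "mom": 1, "sib": 1})]
        freqs = {calls[0][0].key: FrequencyRecord(0.0076, None)}
        out = filter_recessive(fam, calls, freqs)
        assert [c.model for c in out] == ["recessive_hom"]

    def test_maf_above_two_percent_removed(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 2, "p2": 2, "dad": 1, "mom": 1, "sib": 1})]
        freqs = {calls[0][0].key: FrequencyRecord(0.025, None)}
        assert filter_recessive(fam, calls, freqs) == []

    def test_external_frequency_above_threshold_removed(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 2, "p2": 2, "dad": 1, "mom": 1, "sib": 1})]
        freqs = {calls[0][0].key: FrequencyRecord(0.01, 0.03)}
        assert filter_recessive(fam, calls, freqs) == []

    def test_missing_genotype_in_affected_excluded(self):
        fam = nuclear_family()
        calls = [make_call("G1", "missense_variant",
                           {"p1": 2, "p2": None, "dad": 1, "mom": 1, "sib": 1})]
        freqs = {calls[0][0].key: FrequencyRecord(0.01, None)}
        assert filter_recessive(fam, calls, freqs) == []

    def test_trans_compound_het_retained_cis_dropped(self):
        fam = nuclear_family()
        trans = [
            make_call("GT", "missense_variant",
                      {"p1": 1, "p2": 1, "dad": 1, "mom": 0, "sib": 0}, pos=100),
            make_call("GT", "missense_variant",
                      {"p1": 1, "p2": 1, "dad": 0, "mom": 1, "sib": 0}, pos=200),
        ]
        cis = [
            make_call("GC", "missense_variant",
                      {"p1": 1, "p2": 1, "dad": 1, "mom": 0, "sib": 0}, pos=300),
            make_call("GC", "missense_variant",
                      {"p1": 1, "p2": 1, "dad": 1, "mom": 0, "sib": 0}, pos=400),
        ]
        calls = trans + cis
        freqs = {r.key: FrequencyRecord(0.005, None) for r, _ in calls}
        out = filter_recessive(fam, calls, freqs)
        assert len(out) == 1
        assert out[0].model == "recessive_comphet" and out[0].phase == "in_trans"
        assert out[0].variants[0].gene == "GT"

    def test_male_x_hemizygotes_count_as_homozygous(self):
        fam = nuclear_family()
        rec = VariantRecord("chrX", 500, "A", "T", "GX", "missense_variant")
        calls = [(rec, {"p1": 1, "p2": 1, "dad": 0, "mom": 1, "sib": 1})]
        freqs = {rec.key: FrequencyRecord(0.005, None)}
        out = filter_recessive(fam, calls, freqs)
        assert [c.model for c in out] == ["x_linked"]

    def test_fixture_yields_exactly_two_candidates(self, family_bundle):
        out = filter_recessive(
            family_bundle["pedigree"], family_bundle["calls"], family_bundle["freqs"]
        )
        assert len(out) == 2
        assert sorted(c.variants[0].gene for c in out) == ["CYBC1", "GCGR"]

    def test_fixture_single_high_impact_candidate(self, family_bundle):
        from cgdseek.variant_prioritization import classify_impact

        out = filter_recessive(
            family_bundle["pedigree"], family_bundle["calls"], family_bundle["freqs"]
        )
        high = [c for c in out
                if all(classify_impact(v.consequence) == "high" for v in c.variants)]
        assert len(high) == 1 and high[0].variants[0].gene == "CYBC1"

    @pytest.mark.parametrize("loose,tight", [(0.02, 0.01), (0.02, 0.001), (0.01, 0.005)])
    def test_monotonicity_lower_threshold_never_adds(self, family_bundle, loose, tight):
        fam, calls, freqs = (
            family_bundle["pedigree"], family_bundle["calls"], family_bundle["freqs"],
        )
        at_loose = {tuple(v.key for v in c.variants)
                    for c in filter_recessive(fam, calls, freqs, loose)}
        at_tight = {tuple(v.key for v in c.variants)
                    for c in filter_recessive(fam, calls, freqs, tight)}
        assert at_tight <= at_loose


class TestCheckSegregation:
    def _candidate(self, rec, model="recessive_hom", phase="not_applicable"):
        return CandidateGenotype(model, (rec,), ("p1", "p2"), phase,
                                 (FrequencyRecord(0.005, None),))

    def test_fig_configuration_passes(self, family_bundle):
        fam, calls = family_bundle["pedigree"], family_bundle["calls"]
        focal = next(r for r, _ in calls if r.gene == "CYBC1")
        cand = CandidateGenotype("recessive_hom", (focal,), ("A", "B"),
                                 "not_applicable", (FrequencyRecord(0.0076, None),))
        ok, reason = check_segregation(cand, fam, calls_by_key(calls))
        assert ok

    def test_unaffected_homozygote_fails(self):
        fam = nuclear_family()
        rec, counts = make_call("G1", "missense_variant",
                                {"p1": 2, "p2": 2, "dad": 1, "mom": 1, "sib": 2})
        ok, reason = check_segregation(self._candidate(rec), fam, {rec.key: counts})
        assert not ok and "full genotype" in reason

    def test_dominant_het_in_unaffected_sib_fails(self):
        fam = nuclear_family()
        rec, counts = make_call("G1", "missense_variant",
                                {"p1": 1, "p2": 1, "dad": 0, "mom": 0, "sib": 1})
        cand = self._candidate(rec, model="dominant")
        ok, _ = check_segregation(cand, fam, {rec.key: counts})
        assert not ok
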