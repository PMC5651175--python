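import numpy as np
import pytest

from esomix.mutation_ensemble import (
    FilterDecision,
    FilterParams,
    apply_site_blacklists,
    filter_variant,
    merge_call_sets,
    oxog_filter,
    run_ensemble,
)
from .conftest import make_variant, random_variant


def brute_force_decision(v, germline, pon, params=FilterParams()):
    """Independent single-pass oracle testing every rule separately."""
    reasons = set()
    if (v.chromosome, v.position, v.alt) in germline or \
            (v.chromosome, v.position, "*") in germline:
        reasons.add("germline_1000G")
    if (v.chromosome, v.position, v.alt) in pon or \
            (v.chromosome, v.position, "*") in pon:
        reasons.add("panel_of_normals")
    if v.n_ref_count < 8:
        reasons.add("normal_low_ref_coverage")
    if v.n_alt_count > 1:
        reasons.add("normal_alt_reads")
    nd = v.n_ref_count + v.n_alt_count
    if nd > 0 and v.n_alt_count / nd > 0.01:
        reasons.add("normal_vaf")
    if v.t_alt_count < 2:
        reasons.add("tumor_alt_reads")
    td = v.t_ref_count + v.t_alt_count
    if td == 0 or v.t_alt_count / td < 0.05:
        reasons.add("tumor_vaf")
    if (v.ref, v.alt) in (("C", "A"), ("G", "T")) and v.alt_f1r2 is not None \
            and v.alt_f2r1 is not None:
        artifact = v.alt_f2r1 if v.ref == "C" else v.alt_f1r2
        total = v.alt_f1r2 + v.alt_f2r1
        if total >= 3 and artifact / total >= 0.9:
            reasons.add("oxog_orientation")
    return reasons


class TestMerge:
    def test_two_callers_one_record(self):
        a = make_variant(caller="A")
        b = make_variant(caller="B")
        (m,) = merge_call_sets([[a], [b]])
        assert m.callers == ("A", "B")

    def test_min_callers_drops_singletons(self):
        a = make_variant(caller="A")
        assert merge_call_sets([[a], []], min_callers=2) == []

    def test_highest_depth_record_wins(self):
        shallow = make_variant(caller="A", t_ref_count=10, t_alt_count=2)
        deep = make_variant(caller="B", t_ref_count=190, t_alt_count=30)
        (m,) = merge_call_sets([[shallow], [deep]])
        assert m.variant.t_ref_count == 190

    def test_union_of_planned_overlaps(self):
        # 12 records across 3 callers covering 7 distinct variants
        positions = {"A": [1, 2, 3, 4], "B": [2, 3, 5, 6], "C": [3, 4, 6, 7]}
        sets = [[make_variant(position=p, caller=c) for p in ps]
                for c, ps in positions.items()]
        assert sum(len(s) for s in sets) == 12
        merged = merge_call_sets(sets)
        assert len(merged) == 7

    def test_conflicting_ref_alleles_rejected(self):
        a = make_variant(ref="C", alt="T")
        b = make_variant(ref="G", alt="T")
        with pytest.raises(ValueError, match="conflicting"):
            merge_call_sets([[a], [b]])


class TestFilterVariant:
    def test_clean_variant_kept(self):
        d = filter_variant(make_variant(n_ref_count=50, n_alt_count=0,
                                        t_alt_count=5, t_ref_count=55))
        assert d.kept and d.reasons == []

    @pytest.mark.parametrize("overrides,expected_reason", [
        (dict(n_ref_count=7), "normal_low_ref_coverage"),
        (dict(n_alt_count=2, n_ref_count=500), "normal_alt_reads"),
        (dict(n_alt_count=1, n_ref_count=50), "normal_vaf"),
        (dict(t_alt_count=1, t_ref_count=9), "tumor_alt_reads"),
        (dict(t_alt_count=2, t_ref_count=48), "tumor_vaf"),
    ])
    def test_each_rule_fires(self, overrides, expected_reason):
        d = filter_variant(make_variant(**overrides))
        assert not d.kept
        assert expected_reason in d.reasons

    def test_reasons_accumulate_without_short_circuit(self):
        d = filter_variant(make_variant(n_ref_count=0, n_alt_count=5,
                                        t_alt_count=0, t_ref_count=0))
        assert set(d.reasons) == {"normal_low_ref_coverage", "normal_alt_reads",
                                  "normal_vaf", "tumor_alt_reads", "tumor_vaf"}

    def test_zero_normal_depth_fails_coverage(self):
        d = filter_variant(make_variant(n_ref_count=0, n_alt_count=0))
        assert "normal_low_ref_coverage" in d.reasons

    def test_and_mode_requires_both_normal_conditions(self):
        v = make_variant(n_alt_count=1, n_ref_count=50)  # vaf 1.96%, alt == 1
        d = filter_variant(v, FilterParams(normal_alt_or_vaf="and"))
        assert "normal_vaf" not in d.reasons and "normal_alt_reads" not in d.reasons


class TestBlacklists:
    def test_listed_site_flagged(self):
        v = make_variant()
        (d,) = apply_site_blacklists([v], germline_sites={("1", 100, "*")})
        assert d.reasons == ["germline_1000G"]

    def test_empty_blacklists_change_nothing(self):
        decisions = apply_site_blacklists([make_variant()], set(), set())
        assert all(d.kept for d in decisions)

    def test_exactly_five_of_twenty_flagged(self):
        variants = [make_variant(position=i) for i in range(20)]
        germ = {("1", i, "*") for i in (0, 3, 7, 11, 19)}
        decisions = apply_site_blacklists(variants, germ)
        assert sum(not d.kept for d in decisions) == 5

    def test_alt_specific_site_requires_matching_alt(self):
        v = make_variant(alt="T")
        (d,) = apply_site_blacklists([v], germline_sites={("1", 100, "G")})
        assert d.kept


class TestOxog:
    def test_biased_c_to_a_flagged(self):
        v = make_variant(ref="C", alt="A", alt_f2r1=9, alt_f1r2=1)
        assert oxog_filter(v).reasons == ["oxog_orientation"]

    def test_wrong_substitution_class_never_flagged(self):
        v = make_variant(ref="T", alt="G", alt_f2r1=10, alt_f1r2=0)
        assert oxog_filter(v).kept

    def test_balanced_orientation_kept(self):
        v = make_variant(ref="C", alt="A", alt_f2r1=5, alt_f1r2=5)
        assert oxog_filter(v).kept

    def test_g_to_t_uses_f1r2(self):
        v = make_variant(ref="G", alt="T", alt_f1r2=9, alt_f2r1=1)
        assert not oxog_filter(v).kept

    def test_missing_orientation_counts_skip(self):
        v = make_variant(ref="C", alt="A")
        assert oxog_filter(v).kept


class TestPipelineEquivalence:
    def test_matches_brute_force_oracle_on_random_variants(self):
        rng = np.random.default_rng(17)
        variants = [random_variant(rng, sample=f"T{i % 5}", caller="A", position=i)
                    for i in range(300)]
        germ = {(v.chromosome, v.position, "*")
                for v in rng.choice(variants, 30, replace=False)}
        pon = {(v.chromosome, v.position, "*")
               for v in rng.choice(variants, 15, replace=False)}
        survivors, decisions = run_ensemble([variants], germ, pon)
        for key, d in decisions.items():
            v = next(v for v in variants if v.key == key)
            assert set(d.reasons) == brute_force_decision(v, germ, pon), key

    def test_survivors_monotone_in_threshold_strictness(self):
        rng = np.random.default_rng(5)
        variants = [random_variant(rng) for _ in range(200)]
        # distinct keys only
        seen, unique = set(), []
        for v in variants:
            if v.key not in seen:
                seen.add(v.key)
                unique.append(v)
        lax = sum(filter_variant(v, FilterParams(min_tumor_vaf=0.02)).kept
                  for v in unique)
        strict = sum(filter_variant(v, FilterParams(min_tumor_vaf=0.10)).kept
                     for v in unique)
        assert strict <= lax

    def test_reason_sets_are_order_independent(self):
        rng = np.random.default_rng(8)
        variants = [random_variant(rng, sample="X") for _ in range(100)]
        seen, unique = set(), []
        for v in variants:
            if v.key not in seen:
                seen.add(v.key)
                unique.append(v)
        germ = {(v.chromosome, v.position, "*") for v in unique[:10]}
        _, d1 = run_ensemble([unique], germ, set())
        _, d2 = run_ensemble([list(reversed(unique))], germ, set())
        assert {k: tuple(d.reasons) for k, d in d1.items()} == \
            {k: tuple(d.reasons) for k, d in d2.items()}
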