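import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hlassp import typing_engine as te
from hlassp.panel_model import ReactivityMatrix

A = "HLA-A "
B = "HLA-B "
C = "HLA-C "


def rx(prefix, *nums):
    return frozenset(f"{prefix}{n:03d}" for n in nums)


@pytest.fixture(scope="module")
def toy_matrix():
    # one allele, one reaction: the smallest decodable code book
    return ReactivityMatrix("TOY", ["x"], ["TOY 001"], np.array([[True]]))


class TestPatterns:
    def test_allele_pattern_a0205(self, matrix_a):
        assert te.allele_pattern(matrix_a, "A*0205").reactions == rx(A, 2, 3, 11, 17, 18)

    def test_allele_pattern_a0101(self, matrix_a):
        assert te.allele_pattern(matrix_a, "A*0101").reactions == rx(A, 7, 12, 18)

    def test_unknown_allele(self, matrix_a):
        with pytest.raises(KeyError):
            te.allele_pattern(matrix_a, "A*9999")

    def test_all_false_row_gives_empty_pattern(self):
        m = ReactivityMatrix("TOY", ["x", "y"], ["TOY 001"],
                             np.array([[True], [False]]))
        assert te.allele_pattern(m, "y").reactions == frozenset()

    def test_genotype_union(self, matrix_a):
        p = te.genotype_pattern(matrix_a, "A*0101", "A*0205")
        assert p.reactions == rx(A, 2, 3, 7, 11, 12, 17, 18)

    def test_homozygote_identity(self, matrix_a):
        p = te.genotype_pattern(matrix_a, "A*2902", "A*2902")
        assert p.reactions == rx(A, 1, 13)
        assert p == te.allele_pattern(matrix_a, "A*2902")

    def test_published_b_collision(self, matrix_b):
        assert te.genotype_pattern(matrix_b, "B*4201", "B*4202") == \
            te.genotype_pattern(matrix_b, "B*4201", "B*4201")

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_symmetry_and_union_bound(self, matrix_b, data):
        a1 = data.draw(st.sampled_from(matrix_b.alleles))
        a2 = data.draw(st.sampled_from(matrix_b.alleles))
        p12 = te.genotype_pattern(matrix_b, a1, a2)
        p21 = te.genotype_pattern(matrix_b, a2, a1)
        assert p12 == p21
        assert len(p12) <= len(te.allele_pattern(matrix_b, a1)) + \
            len(te.allele_pattern(matrix_b, a2))


class TestEnumerationAndUniqueness:
    @pytest.mark.parametrize("locus,n_genotypes", [
        ("HLA-A", 105), ("HLA-B", 276), ("HLA-C", 78),
    ])
    def test_genotype_counts(self, matrices, locus, n_genotypes):
        genos = te.enumerate_genotypes(matrices[locus])
        n = len(matrices[locus].alleles)
        assert len(genos) == n * (n + 1) // 2 == n_genotypes

    def test_single_allele_matrix(self, toy_matrix):
        assert len(te.enumerate_genotypes(toy_matrix)) == 1

    def test_hla_a_all_unique(self, matrix_a):
        ua = te.uniqueness_audit(matrix_a)
        assert ua.distinct_pattern_count == 105
        assert ua.collision_groups == []

    def test_hla_c_all_unique(self, matrix_c):
        ua = te.uniqueness_audit(matrix_c)
        assert ua.distinct_pattern_count == 78
        assert ua.collision_groups == []

    def test_hla_b_three_collisions(self, matrix_b):
        ua = te.uniqueness_audit(matrix_b)
        assert ua.total_genotypes == 276
        assert ua.distinct_pattern_count == 273
        assert ua.collision_groups == [
            [("B*0702", "B*4201"), ("B*0702", "B*4202")],
            [("B*4201", "B*4201"), ("B*4201", "B*4202")],
            [("B*4201", "B*8101"), ("B*4202", "B*8101")],
        ]

    def test_conservation(self, matrices):
        for m in matrices.values():
            ua = te.uniqueness_audit(m)
            excess = sum(len(g) - 1 for g in ua.collision_groups)
            assert ua.distinct_pattern_count + excess == ua.total_genotypes

    def test_carrier_discriminability(self, matrices):
        # only B*4201/B*4202 can be eclipsed: for every other addressed allele,
        # carrier genotypes never share a pattern with non-carrier genotypes
        for m in matrices.values():
            genos = te.enumerate_genotypes(m)
            by_pattern = {}
            for g, p in genos.items():
                by_pattern.setdefault(p.reactions, []).append(g)
            ambiguous = set()
            for group in by_pattern.values():
                if len(group) < 2:
                    continue
                for allele in m.alleles:
                    carriage = {allele in g for g in group}
                    if len(carriage) == 2:
                        ambiguous.add(allele)
            if m.locus == "HLA-B":
                assert ambiguous == {"B*4201", "B*4202"}
            else:
                assert ambiguous == set()


class TestCallReactivity:
    def test_positive(self):
        rec = te.CtRecord("s1", "HLA-A 001", 25.1, 24.6)
        (call,) = te.call_reactivity([rec], cutoffs=7.0)
        assert call.status == "positive"
        assert call.delta_ct == pytest.approx(0.5)

    def test_negative_undetermined_specific(self):
        rec = te.CtRecord("s1", "HLA-A 001", 60.0, 24.0)
        (call,) = te.call_reactivity([rec], cutoffs=7.0)
        assert call.status == "negative"
        assert call.delta_ct == pytest.approx(36.0)

    def test_internal_failure_is_invalid(self):
        rec = te.CtRecord("s1", "HLA-A 001", 10.0, 60.0)
        (call,) = te.call_reactivity([rec])
        assert call.status == "invalid"

    def test_internal_fail_threshold(self):
        rec = te.CtRecord("s1", "HLA-A 001", 41.0, 40.0)
        (call,) = te.call_reactivity([rec], internal_fail_ct=40.0)
        assert call.status == "invalid"

    def test_per_reaction_cutoffs(self):
        recs = [te.CtRecord("s1", "R1", 30.0, 24.0), te.CtRecord("s1", "R2", 30.0, 24.0)]
        calls = te.call_reactivity(recs, cutoffs={"R1": 10.0, "R2": 3.0})
        assert [c.status for c in calls] == ["positive", "negative"]

    def test_unknown_reaction(self):
        rec = te.CtRecord("s1", "NOPE", 25.0, 24.0)
        with pytest.raises(KeyError, match="NOPE"):
            te.call_reactivity([rec], known_reactions={"HLA-A 001"})

    def test_ct_out_of_range(self):
        with pytest.raises(ValueError):
            te.CtRecord("s1", "HLA-A 001", 61.0, 24.0)
        with pytest.raises(ValueError):
            te.CtRecord("s1", "HLA-A 001", 25.0, -1.0)


class TestCalibrateCutoffs:
    def _records(self, deltas, reaction="R1"):
        return [te.CtRecord(f"s{i}", reaction, 24.0 + d, 24.0)
                for i, d in enumerate(deltas)]

    def test_midpoint(self):
        deltas = [0.4, 1.1, 12.0, 36.0]
        labels = {("s0", "R1"): True, ("s1", "R1"): True,
                  ("s2", "R1"): False, ("s3", "R1"): False}
        cal = te.calibrate_cutoffs(self._records(deltas), labels)
        assert cal["R1"].cutoff == pytest.approx(6.55)
        assert cal["R1"].flags == frozenset()

    def test_non_separable(self):
        deltas = [8.0, 5.0]
        labels = {("s0", "R1"): True, ("s1", "R1"): False}
        cal = te.calibrate_cutoffs(self._records(deltas), labels)
        assert "non_separable" in cal["R1"].flags

    def test_fallback_on_single_class(self):
        deltas = [12.0, 13.0]
        labels = {("s0", "R1"): False, ("s1", "R1"): False}
        cal = te.calibrate_cutoffs(self._records(deltas), labels)
        assert cal["R1"].flags == frozenset({"fallback"})
        assert cal["R1"].cutoff == te.DEFAULT_CUTOFF


class TestDecode:
    def test_exact_homozygote_with_flag(self, matrix_a):
        call = te.decode(rx(A, 1, 13), matrix_a.reactions, matrix_a)
        assert call.status == "exact"
        assert call.candidates == frozenset({("A*2902", "A*2902")})
        assert "homozygote_overcall_risk" in call.flags

    def test_ambiguous_collision(self, matrix_b):
        observed = rx(B, 4, 15, 16, 18, 25, 27, 37)
        call = te.decode(observed, matrix_b.reactions, matrix_b)
        assert call.status == "ambiguous_collision"
        assert call.candidates == frozenset({
            ("B*4201", "B*4201"), ("B*4201", "B*4202")})

    def test_empty_pattern_no_call(self, matrix_a):
        call = te.decode(frozenset(), matrix_a.reactions, matrix_a)
        assert call.status == "no_call"
        assert call.candidates == frozenset()
        assert call.flags == frozenset({"all_negative"})

    def test_observed_outside_valid_rejected(self, matrix_a):
        with pytest.raises(ValueError):
            te.decode(rx(A, 1), rx(A, 2, 3), matrix_a)

    def test_nearest_match_one_mismatch(self, matrix_a):
        # drop one reaction from a unique heterozygote pattern
        true_pattern = te.genotype_pattern(matrix_a, "A*0101", "A*0205").reactions
        observed = true_pattern - {f"{A}002"}
        call = te.decode(observed, matrix_a.reactions, matrix_a, max_mismatch=1)
        assert call.status == "nearest_match"
        assert call.mismatch_count == 1
        assert ("A*0101", "A*0205") in call.candidates
        assert "possible_nonaddressed" in call.flags

    def test_no_call_beyond_max_mismatch(self, matrix_a):
        true_pattern = te.genotype_pattern(matrix_a, "A*0101", "A*0205").reactions
        observed = frozenset(list(true_pattern)[:2])
        call = te.decode(observed, matrix_a.reactions, matrix_a, max_mismatch=1)
        assert call.status == "no_call"
        assert call.candidates == frozenset()

    def test_decode_inverts_genotype_pattern(self, matrices):
        # brute force: every genotype outside a collision group decodes to itself
        for m in matrices.values():
            genos = te.enumerate_genotypes(m)
            collided = {g for grp in te.uniqueness_audit(m).collision_groups
                        for g in grp}
            for g, p in genos.items():
                call = te.decode(p.reactions, m.reactions, m)
                if g in collided:
                    assert call.status == "ambiguous_collision"
                    assert g in call.candidates
                else:
                    assert call.status == "exact"
                    assert call.candidates == frozenset({g})

    def test_restriction_grows_exact_candidates(self, matrix_b):
        # with reaction 004 invalid, B*4201 and B*4202 homo/heterozygotes merge
        p = te.genotype_pattern(matrix_b, "B*4202", "B*4202").reactions
        full = te.decode(p, matrix_b.reactions, matrix_b)
        valid = frozenset(matrix_b.reactions) - {f"{B}004"}
        restricted = te.decode(p & valid, valid, matrix_b)
        assert full.candidates <= restricted.candidates
        assert len(restricted.candidates) > len(full.candidates)

    def test_decode_plate_groups_by_sample(self, matrix_a):
        p = te.genotype_pattern(matrix_a, "A*0101", "A*0301").reactions
        calls = [
            te.ReactivityCall("s1", r, 0.5 if r in p else 36.0,
                              "positive" if r in p else "negative")
            for r in matrix_a.reactions
        ]
        out = te.decode_plate(calls, matrix_a)
        assert out["s1"].candidates == frozenset({("A*0101", "A*0301")})

    def test_decode_plate_unknown_reaction(self, matrix_a):
        calls = [te.ReactivityCall("s1", "NOPE", 0.5, "positive")]
        with pytest.raises(KeyError, match="NOPE"):
            te.decode_plate(calls, matrix_a)


class TestCarrierConfusion:
    def _perfect_calls(self, matrix, truth):
        return {
            s: te.decode(te.genotype_pattern(matrix, *g).reactions,
                         matrix.reactions, matrix, sample_id=s)
            for s, g in truth.items()
        }

    def test_perfect_concordance(self, matrix_a):
        # mirrors the validation design: all calls identical to truth
        alleles = matrix_a.alleles
        truth = {}
        i = 0
        for a in alleles:
            for b in alleles:
                truth[f"s{i}"] = tuple(sorted((a, b)))
                i += 1
                if i >= 125:
                    break
            if i >= 125:
                break
        calls = self._perfect_calls(matrix_a, truth)
        res = te.carrier_confusion(calls, truth, "A*0201")
        n_carriers = sum("A*0201" in g for g in truth.values())
        assert res.tp == n_carriers and res.fn == 0 and res.fp == 0
        assert res.sensitivity == res.specificity == res.ppv == res.npv == 1.0

    def test_one_miss_gives_90pct_sensitivity(self, matrix_a):
        truth = {f"s{i}": ("A*0101", "A*0301") for i in range(10)}
        truth.update({f"t{i}": ("A*0205", "A*2301") for i in range(5)})
        calls = self._perfect_calls(matrix_a, truth)
        calls["s0"] = te.GenotypeCall("s0", "HLA-A",
                                      frozenset({("A*0205", "A*0301")}),
                                      "exact", 0, frozenset(), frozenset())
        res = te.carrier_confusion(calls, truth, "A*0101")
        assert res.sensitivity == pytest.approx(0.9)

    def test_zero_carriers_sensitivity_absent(self, matrix_a):
        truth = {"s0": ("A*0101", "A*0301")}
        calls = self._perfect_calls(matrix_a, truth)
        res = te.carrier_confusion(calls, truth, "A*2902")
        assert res.sensitivity is None and res.ppv is None
        assert res.specificity == 1.0

    def test_missing_sample_raises(self, matrix_a):
        truth = {"s0": ("A*0101", "A*0301"), "s1": ("A*0101", "A*0101")}
        with pytest.raises(KeyError, match="s1"):
            te.carrier_confusion({"s0": te.GenotypeCall(
                "s0", "HLA-A", frozenset(), "no_call", 0, frozenset(),
                frozenset())}, truth, "A*0101")

    def test_ambiguous_counts_conservatively(self, matrix_b):
        truth = {"s0": ("B*4201", "B*4202")}
        p = te.genotype_pattern(matrix_b, "B*4201", "B*4202").reactions
        calls = {"s0": te.decode(p, matrix_b.reactions, matrix_b, sample_id="s0")}
        assert te.is_carrier(calls["s0"], "B*4201")  # in every candidate
        assert not te.is_carrier(calls["s0"], "B*4202")  # only in one
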