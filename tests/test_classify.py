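import random

import numpy as np
import pytest

from capsid.classify import (
    Classification,
    ClassifierParams,
    aggregate_report,
    candidate_set,
    classify_contig,
    lca_classify,
    pass1,
    pass2,
    viral_filter,
)

from .conftest import make_record, random_instance
from .oracles import brute_pass1, brute_pass2

PARAMS = ClassifierParams()


def two_taxon_profile():
    """L=10; taxon A (101): 20 bits over 1–10; taxon B (102): 15 bits over 1–5."""
    records = [
        make_record(101, 1, 10, 20.0, subject_id="eA"),
        make_record(102, 1, 5, 15.0, subject_id="eB"),
    ]
    return records, pass1(records, 10)


class TestPass1:
    def test_worked_example_scores_and_global_top(self):
        _, profile = two_taxon_profile()
        assert profile.pass1_score[101] == pytest.approx(20.0)
        assert profile.pass1_score[102] == pytest.approx(15.0)
        assert list(profile.global_top) == [3.0] * 5 + [2.0] * 5

    def test_single_record_score_conservation(self):
        profile = pass1([make_record(7, 1, 25, 50.0)], 30)
        assert profile.pass1_score[7] == pytest.approx(50.0)

    def test_same_taxon_overlap_takes_max_not_sum(self):
        records = [
            make_record(7, 1, 10, 10.0, subject_id="e1"),  # s=1.0
            make_record(7, 6, 10, 10.0, subject_id="e2"),  # s=2.0 on 6–10
        ]
        profile = pass1(records, 10)
        assert list(profile.top_per_taxon[7]) == [1.0] * 5 + [2.0] * 5
        assert profile.pass1_score[7] == pytest.approx(15.0)

    def test_out_of_bounds_record_is_error(self):
        with pytest.raises(ValueError, match="outside contig"):
            pass1([make_record(7, 1, 20, 10.0)], 10)


class TestPass2:
    def test_worked_example_volumes(self):
        records, profile = two_taxon_profile()
        vol = pass2(records, profile.global_top, PARAMS).volume
        # A: 5 positions at s=2, r=2/3 → 5·2·(2/3)³ ; 5 positions at r=1 → 10
        assert vol[101] == pytest.approx(5 * 2.0 * (2 / 3) ** 3 + 10.0)
        assert vol[101] == pytest.approx(12.963, abs=1e-3)
        assert vol[102] == pytest.approx(15.0)

    def test_global_top_holder_volume_equals_pass1_score(self):
        records = [make_record(7, 1, 40, 60.0)]
        profile = pass1(records, 40)
        vol = pass2(records, profile.global_top, PARAMS).volume
        assert vol[7] == pytest.approx(profile.pass1_score[7])

    def test_duplicate_entries_double_volume_not_pass1(self):
        records = [
            make_record(7, 1, 20, 30.0, subject_id="e1"),
            make_record(7, 1, 20, 30.0, subject_id="e2"),
        ]
        profile = pass1(records, 20)
        vol = pass2(records, profile.global_top, PARAMS).volume
        assert profile.pass1_score[7] == pytest.approx(30.0)
        assert vol[7] == pytest.approx(60.0)

    def test_uncovered_global_top_is_internal_error(self):
        records, profile = two_taxon_profile()
        stray = make_record(103, 1, 10, 20.0)
        with pytest.raises(ValueError, match="global top is zero"):
            pass2([stray], np.zeros(10), PARAMS)

    def test_aa_weights_are_harsher_than_nt(self):
        for r in (0.2, 0.5, 0.9, 0.99):
            assert PARAMS.weight(r, "aa") < PARAMS.weight(r, "nt")
        assert PARAMS.weight(1.0, "aa") == PARAMS.weight(1.0, "nt") == 1.0
        grid = np.linspace(0.01, 1.0, 50)
        assert np.all(np.diff(PARAMS.weight(grid, "nt")) > 0)
        assert np.all(np.diff(PARAMS.weight(grid, "aa")) > 0)


class TestOracleEquivalence:
    def test_pass1_pass2_match_bruteforce_on_random_instances(self):
        rng = random.Random(123)
        for _ in range(200):
            records, length = random_instance(rng)
            profile = pass1(records, length)
            _, brute_top, brute_scores = brute_pass1(records, length)
            assert profile.global_top == pytest.approx(brute_top, rel=1e-9)
            for t, s in brute_scores.items():
                assert profile.pass1_score[t] == pytest.approx(s, rel=1e-9)
            vol = pass2(records, profile.global_top, PARAMS).volume
            brute_vol = brute_pass2(
                records, brute_top, PARAMS.w_nt_exponent, PARAMS.aa_exponent
            )
            for t, v in brute_vol.items():
                assert vol[t] == pytest.approx(v, rel=1e-9)

    def test_raising_bits_never_decreases_scores(self):
        rng = random.Random(321)
        for _ in range(30):
            records, length = random_instance(rng)
            i = rng.randrange(len(records))
            bumped = records.copy()
            r = records[i]
            bumped[i] = make_record(
                r.subject_taxid, r.q_start, r.q_end, r.bits * 1.5,
                kind=r.kind, subject_id=r.subject_id,
            )
            p_before, p_after = pass1(records, length), pass1(bumped, length)
            t = r.subject_taxid
            assert p_after.pass1_score[t] >= p_before.pass1_score[t] - 1e-12
            v_after = pass2(bumped, p_after.global_top, PARAMS).volume
            # adding/raising a record never deletes the taxon's support
            assert v_after[t] > 0


class TestScoringInvariants:
    """Structural invariants of the two-pass profile on arbitrary records."""

    from hypothesis import given, settings, strategies as st

    @given(
        st.lists(
            st.tuples(
                st.integers(100, 104),  # taxid
                st.integers(1, 30),  # q_start
                st.integers(0, 20),  # span - 1
                st.floats(0.5, 100.0),  # bits
                st.sampled_from(["nt", "aa"]),
            ),
            min_size=1,
            max_size=15,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_profile_invariants(self, raw):
        length = 50
        records = [
            make_record(t, qs, min(qs + span, length), round(bits, 3), kind=kind,
                        subject_id=f"e{i}")
            for i, (t, qs, span, bits, kind) in enumerate(raw)
        ]
        profile = pass1(records, length)
        for t, arr in profile.top_per_taxon.items():
            assert np.all(arr <= profile.global_top + 1e-12)
            assert profile.pass1_score[t] == pytest.approx(float(arr.sum()))
        stacked = np.max(list(profile.top_per_taxon.values()), axis=0)
        assert stacked == pytest.approx(list(profile.global_top))
        vol = pass2(records, profile.global_top, PARAMS)
        assert all(v >= 0 for v in vol.volume.values())
        # per-entry contributions sum to the taxon volume
        for t in vol.volume:
            assert vol.volume[t] == pytest.approx(
                sum(v for (tt, _), v in vol.per_entry.items() if tt == t)
            )


class TestViralFilter:
    def test_bacterial_top_taxon_filtered(self, mini_tree):
        records = [
            make_record(2001, 1, 100, 200.0),  # host, stronger
            make_record(13001, 1, 100, 150.0),
        ]
        verdict, reason = viral_filter(pass1(records, 100), mini_tree, PARAMS)
        assert verdict == "filtered_nonviral"
        assert "2001" in reason

    def test_majority_host_topped_bases_filtered(self, mini_tree):
        """Viral top taxon but 60% of aligned bases topped by the host."""
        records = [
            make_record(13001, 1, 100, 300.0),  # viral, s=3.0 everywhere
            make_record(2001, 1, 60, 240.0),  # host, s=4.0 on 60% of bases
        ]
        verdict, _ = viral_filter(pass1(records, 100), mini_tree, PARAMS)
        assert verdict == "filtered_nonviral"

    def test_all_viral_passes(self, mini_tree):
        records = [make_record(13001, 1, 100, 200.0)]
        verdict, _ = viral_filter(pass1(records, 100), mini_tree, PARAMS)
        assert verdict == "classified"

    def test_position_ties_count_as_viral(self, mini_tree):
        records = [
            make_record(13001, 1, 100, 200.0),  # viral, s=2.0, top overall
            make_record(2001, 1, 99, 198.0),  # host, s=2.0: ties on 99% of bases
        ]
        verdict, _ = viral_filter(pass1(records, 100), mini_tree, PARAMS)
        assert verdict == "classified"


class TestCandidateSet:
    def test_perfect_hit_gets_minimum_radius(self):
        # L=100, b_max=2 → self_max=200; best=200 → q=1 → ρ=radius_min=0.02
        records = [
            make_record(1, 1, 100, 200.0),
            make_record(2, 1, 100, 197.0),  # within 2%
            make_record(3, 1, 100, 195.0),  # outside 2%
        ]
        assert candidate_set(pass1(records, 100), PARAMS) == {1, 2}

    def test_weak_hit_widens_radius(self):
        # best=40 bits on L=100 → q=0.2 → ρ=0.02+0.8·0.23=0.204
        records = [
            make_record(1, 1, 100, 40.0),
            make_record(2, 1, 100, 32.0),  # 80% of best → admitted
            make_record(3, 1, 100, 31.0),  # 77.5% → excluded
        ]
        assert candidate_set(pass1(records, 100), PARAMS) == {1, 2}

    def test_single_taxon_is_sole_candidate(self):
        assert candidate_set(pass1([make_record(9, 1, 50, 70.0)], 50), PARAMS) == {9}


class TestLcaClassify:
    def test_single_candidate_species(self, mini_tree):
        taxid, rank = lca_classify({13001}, {13001: 500.0}, mini_tree, PARAMS)
        assert (taxid, rank) == (13001, "species")

    def test_dominant_sibling_at_large_volume(self, mini_tree):
        """90/10 volume split with V ≫ V0: the 0.9 share beats m(V) → species."""
        volumes = {13001: 9000.0, 13002: 1000.0}
        m = PARAMS.majority_threshold(10000.0)
        assert 0.9 > m
        taxid, rank = lca_classify(set(volumes), volumes, mini_tree, PARAMS)
        assert (taxid, rank) == (13001, "species")

    def test_balanced_siblings_at_small_volume_back_off_to_genus(self, mini_tree):
        """55/45 at V=100: m ≈ 0.93, neither species passes; genus holds 100%."""
        volumes = {13001: 55.0, 13002: 45.0}
        m = PARAMS.majority_threshold(100.0)
        assert 0.55 < m
        taxid, rank = lca_classify(set(volumes), volumes, mini_tree, PARAMS)
        assert (taxid, rank) == (12001, "genus")

    def test_cross_genus_balance_backs_off_to_family(self, mini_tree):
        volumes = {13001: 55.0, 13003: 45.0}  # different genera
        taxid, rank = lca_classify(set(volumes), volumes, mini_tree, PARAMS)
        assert (taxid, rank) == (11000, "family")

    def test_fallback_to_max_volume_below_superkingdom(self, mini_tree):
        # candidates spread so far that no rank below superkingdom reaches a
        # majority: a strain, plus both genera's species on the other side
        volumes = {13001: 40.0, 13003: 35.0, 13004: 25.0}
        params = ClassifierParams(majority_cap=0.95, lca_excess=0.45)
        # family holds 100% → to force the fallback, exclude family rank
        import capsid.taxonomy as taxmod

        tree = mini_tree
        old_ranks = tree.ranks
        tree.ranks = ("species", "genus")
        try:
            taxid, rank = lca_classify(set(volumes), volumes, tree, params)
        finally:
            tree.ranks = old_ranks
        assert taxid == 13001  # argmax volume below Viruses

    def test_strain_projects_to_species(self, mini_tree):
        taxid, rank = lca_classify({14001}, {14001: 800.0}, mini_tree, PARAMS)
        assert (taxid, rank) == (13001, "species")

    def test_empty_candidates_is_error(self, mini_tree):
        with pytest.raises(ValueError, match="empty candidate"):
            lca_classify(set(), {}, mini_tree, PARAMS)

    def test_majority_threshold_strictly_decreasing_and_bounded(self):
        grid = [10.0, 100.0, 1000.0, 10000.0, 1e6]
        values = [PARAMS.majority_threshold(v) for v in grid]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert all(PARAMS.lca_base_majority < m <= 0.95 for m in values)


class TestClassifyContig:
    def test_low_information_contig_filtered(self, mini_tree):
        cls = classify_contig(
            "c1", 200, [make_record(13001, 1, 200, 250.0)], mini_tree, PARAMS
        )
        assert cls.verdict == "filtered_lowinfo"
        assert "250" in cls.reason

    def test_exact_database_contig_classified_to_species(self, mini_tree):
        records = [
            make_record(13001, 1, 300, 600.0, subject_id="own"),
            make_record(13002, 1, 300, 420.0, subject_id="sibling"),
        ]
        cls = classify_contig("c1", 300, records, mini_tree, PARAMS)
        assert cls.verdict == "classified"
        assert (cls.taxid, cls.rank) == (13001, "species")

    def test_equidistant_between_genera_backs_off_to_family(self, mini_tree):
        records = [
            make_record(13001, 1, 300, 330.0, subject_id="g1hit"),
            make_record(13003, 1, 300, 330.0, subject_id="g2hit"),
        ]
        cls = classify_contig("c1", 300, records, mini_tree, PARAMS)
        assert cls.verdict == "classified"
        assert (cls.taxid, cls.rank) == (11000, "family")

    def test_no_alignments_is_lowinfo(self, mini_tree):
        cls = classify_contig("c1", 600, [], mini_tree, PARAMS)
        assert cls.verdict == "filtered_lowinfo"


class TestAggregateReport:
    def _cls(self, cid, taxid, bits, length=1000, verdict="classified", reason=""):
        return Classification(
            cid, taxid, "species" if verdict == "classified" else None,
            bits, bits, verdict, reason, length,
        )

    def test_taxon_above_threshold_reported(self, mini_tree):
        rows, _ = aggregate_report(
            [self._cls("c1", 13001, 600.0), self._cls("c2", 13001, 500.0)],
            {"c1": 40, "c2": 30},
            mini_tree,
            PARAMS,
        )
        (row,) = rows
        assert row.total_bits == pytest.approx(1100.0)
        assert row.reads == 70
        assert row.n_contigs == 2

    def test_taxon_below_thousand_bits_suppressed(self, mini_tree):
        rows, _ = aggregate_report(
            [self._cls("c1", 13001, 999.0)], {}, mini_tree, PARAMS
        )
        assert rows == []

    def test_long_unclassifiable_contig_listed(self, mini_tree):
        _, unclassified = aggregate_report(
            [self._cls("c1", None, 0.0, length=520, verdict="filtered_lowinfo",
                       reason="no alignments")],
            {"c1": 12},
            mini_tree,
            PARAMS,
        )
        (row,) = unclassified
        assert row.contig_id == "c1" and row.length == 520 and row.reads == 12

    def test_short_filtered_contig_not_listed(self, mini_tree):
        _, unclassified = aggregate_report(
            [self._cls("c1", None, 0.0, length=480, verdict="filtered_lowinfo")],
            {},
            mini_tree,
            PARAMS,
        )
        assert unclassified == []
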