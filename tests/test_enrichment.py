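"""Enrichment battery: ECDF-difference scores, permutation p-values, KSEA,
motif enrichment, BH adjustment, pathway ranking."""

import math
import statistics
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptmnav import fixtures as fx
from ptmnav.enrichment import (
    EnrichmentResult,
    RankedProfile,
    Signature,
    bh_adjust,
    enrichment_score,
    ksea,
    load_signatures,
    motif_enrichment,
    permutation_pvalues,
    rank_pathways,
    score_percentile,
    site_key,
)
from ptmnav.projection import KinaseSubstrateRow, KinaseSubstrateTable

from conftest import ecdf_score_oracle


def profile_of(values, policy="collapse_max_abs", keys=None):
    keys = keys or [chr(ord("a") + i) for i in range(len(values))]
    return RankedProfile(list(zip(keys, values)), policy)


class TestEnrichmentScore:
    def test_top_vs_bottom_symmetry(self):
        prof = profile_of([4.0, 3.0, 2.0, 1.0])
        top, _ = enrichment_score(prof, Signature.from_keys("s", ["a", "b"]))
        bottom, _ = enrichment_score(prof, Signature.from_keys("s", ["c", "d"]))
        assert top > 0 > bottom
        assert top == pytest.approx(-bottom)
        assert top == pytest.approx(0.5)  # hand ECDF computation on 4 items

    def test_matches_brute_force_oracle_on_six_items(self):
        rng = random.Random(7)
        values = [rng.uniform(-3, 3) for _ in range(6)]
        prof = profile_of(values)
        sig = Signature.from_keys("s", ["b", "e"])
        score, overlap = enrichment_score(prof, sig)
        assert overlap == 2
        assert score == pytest.approx(ecdf_score_oracle(prof.items, {"b", "e"}), abs=1e-12)

    def test_zero_overlap_gives_nan_not_exception(self):
        score, overlap = enrichment_score(profile_of([1.0, 2.0]), Signature.from_keys("s", ["zz"]))
        assert overlap == 0 and math.isnan(score)

    def test_signature_covering_whole_profile_is_na(self):
        score, overlap = enrichment_score(profile_of([1.0, 2.0]), Signature.from_keys("s", ["a", "b"]))
        assert overlap == 2 and math.isnan(score)

    def test_keep_all_counts_duplicate_keys_multiple_times(self):
        # one gene measured 3 times: redundant counting strengthens the score
        items = [("g1", 5.0), ("g1", 4.0), ("g1", 3.0), ("x", -1.0), ("y", -2.0), ("z", 0.0)]
        redundant = RankedProfile(list(items), "keep_all")
        score_r, _ = enrichment_score(redundant, Signature.from_keys("s", ["g1"]))
        assert score_r == pytest.approx(ecdf_score_oracle(redundant.items, {"g1"}), abs=1e-12)
        collapsed = RankedProfile(list(items), "collapse_max_abs")
        score_c, _ = enrichment_score(collapsed, Signature.from_keys("s", ["g1"]))
        assert score_r > score_c > 0

    def test_collapse_max_abs_keeps_strongest_entry(self):
        prof = RankedProfile([("g", 1.0), ("g", -4.0), ("h", 2.0)], "collapse_max_abs")
        assert dict(prof.items)["g"] == -4.0

    def test_gc_and_gcr_coincide_without_duplicates(self):
        rng = random.Random(1)
        values = [rng.uniform(-2, 2) for _ in range(9)]
        sig = Signature.from_keys("s", ["c", "f", "h"])
        gc, _ = enrichment_score(profile_of(values, "collapse_max_abs"), sig)
        gcr, _ = enrichment_score(profile_of(values, "keep_all"), sig)
        assert gc == gcr

    def test_negative_signed_member_contributes_negated(self):
        items = [("a", 3.0), ("b", 2.0), ("down_site", -5.0), ("c", 1.0)]
        signed = Signature("s", (("down_site", -1),))
        score, _ = enrichment_score(RankedProfile(list(items), "keep_all"), signed)
        # negated value +5 ranks first -> strong positive enrichment
        unsigned_score, _ = enrichment_score(
            RankedProfile(list(items), "keep_all"), Signature.from_keys("s", ["down_site"])
        )
        assert score > 0 > unsigned_score

    @pytest.mark.parametrize("n", range(3, 9))
    def test_exhaustive_small_signature_sweep(self, n):
        import itertools

        rng = random.Random(n)
        values = [rng.uniform(-4, 4) for _ in range(n)]
        prof = profile_of(values)
        keys = [k for k, _ in prof.items]
        for size in (1, 2, 3):
            for members in itertools.combinations(keys, size):
                sig = Signature.from_keys("s", members)
                score, _ = enrichment_score(prof, sig)
                oracle = ecdf_score_oracle(prof.items, set(members))
                if math.isnan(oracle):
                    assert math.isnan(score)
                else:
                    assert score == pytest.approx(oracle, abs=1e-12)


class TestPermutation:
    def test_deterministic_under_seed(self):
        prof = profile_of([float(v) for v in range(20, 0, -1)])
        sigs = [Signature.from_keys(f"s{i}", ["a", "e", "k"]) for i in range(3)]
        r1 = permutation_pvalues(prof, sigs, n_perm=300, seed=5)
        r2 = permutation_pvalues(prof, sigs, n_perm=300, seed=5)
        assert [r.p for r in r1] == [r.p for r in r2]

    def test_extreme_signature_attains_minimum_p(self):
        keys = [f"k{i}" for i in range(60)]
        prof = RankedProfile([(k, 60.0 - i) for i, k in enumerate(keys)], "collapse_max_abs")
        sig = Signature.from_keys("top", keys[:3])
        (res,) = permutation_pvalues(prof, [sig], n_perm=500, seed=2)
        assert res.p == pytest.approx(1.0 / 501.0)

    def test_na_scores_excluded_from_bh_family(self):
        prof = profile_of([3.0, 2.0, 1.0])
        sigs = [Signature.from_keys("hit", ["a"]), Signature.from_keys("miss", ["zz"])]
        res = {r.signature_id: r for r in permutation_pvalues(prof, sigs, n_perm=100, seed=0)}
        assert math.isnan(res["miss"].score) and math.isnan(res["miss"].p_adj)
        assert not math.isnan(res["hit"].p_adj)


class TestKsea:
    def _table(self, sites):
        rows = [KinaseSubstrateRow("KIN", g, r, p) for g, r, p in sites]
        return KinaseSubstrateTable(rows)

    def test_closed_form_against_hand_computation(self):
        rng = random.Random(3)
        for _ in range(20):
            n = rng.randint(20, 60)
            values = [rng.gauss(0, 1) for _ in range(n)]
            profile = [(f"G{i}_S{i + 10}", values[i]) for i in range(n)]
            sub_idx = rng.sample(range(n), rng.randint(3, 6))
            table = self._table([(f"G{i}", "S", i + 10) for i in sub_idx])
            (act,) = ksea(profile, table, min_substrates=3)
            mean_all = statistics.fmean(values)
            sd_all = statistics.stdev(values)
            mean_s = statistics.fmean(values[i] for i in sub_idx)
            expected = (mean_s - mean_all) * math.sqrt(len(sub_idx)) / sd_all
            assert act.z_score == pytest.approx(expected, abs=1e-12)

    def test_background_substrates_score_near_zero(self):
        rng = random.Random(9)
        values = [rng.gauss(0, 1) for _ in range(400)]
        profile = [(f"G{i}_S{i + 10}", values[i]) for i in range(400)]
        table = self._table([(f"G{i}", "S", i + 10) for i in rng.sample(range(400), 30)])
        (act,) = ksea(profile, table)
        assert abs(act.z_score) < 3.0

    def test_whole_background_as_substrates_is_exactly_zero(self):
        rng = random.Random(4)
        values = [rng.gauss(0, 1) for _ in range(50)]
        profile = [(f"G{i}_S{i + 10}", values[i]) for i in range(50)]
        table = self._table([(f"G{i}", "S", i + 10) for i in range(50)])
        (act,) = ksea(profile, table)
        assert act.z_score == pytest.approx(0.0, abs=1e-12)

    def test_min_substrates_filters_kinases(self):
        profile = [("A_S10", 1.0), ("B_S11", -1.0), ("C_S12", 0.5)]
        table = self._table([("A", "S", 10), ("B", "S", 11)])
        assert ksea(profile, table, min_substrates=3) == []

    def test_zero_sd_background_raises(self):
        profile = [("A_S10", 1.0), ("B_S11", 1.0), ("C_S12", 1.0), ("D_S13", 1.0)]
        table = self._table([("A", "S", 10), ("B", "S", 11), ("C", "S", 12)])
        with pytest.raises(ValueError, match="standard deviation"):
            ksea(profile, table)

    def test_planted_kinase_recovered_first(self, ks_table):
        spec = fx.SyntheticSpec(seed=42)
        records, _ = fx.make_synthetic_dataset(spec, ks_table=ks_table)
        activities = ksea(fx.dataset_profile(records), ks_table)
        ranked = sorted(activities, key=lambda a: abs(a.z_score), reverse=True)
        assert ranked[0].kinase == spec.planted_kinase
        assert ranked[0].p_adj < 0.1 and ranked[0].z_score < 0


class TestMotif:
    def test_argmax_peptide_scores_maximal_with_percentile_one(self):
        pssms = fx.make_pssms(seed=1, n_kinases=3)
        bg = fx.make_background(pssms, n=200, seed=1)
        pssm = pssms[0]
        best = pssm.argmax_sequence()
        score = pssm.score(best)
        assert score >= max(pssm.score(fx.random_peptide(pssm.window, random.Random(i))) for i in range(50))
        assert score_percentile(score, bg[pssm.kinase]) == 1.0

    def test_wrong_width_sequence_rejected_with_index(self):
        pssms = fx.make_pssms(seed=1, n_kinases=2)
        bg = fx.make_background(pssms, n=50, seed=1)
        with pytest.raises(ValueError, match="#1"):
            motif_enrichment([("A" * 10, "up"), ("AAA", "up")], pssms, bg)

    def test_padding_skipped_in_scoring(self):
        pssms = fx.make_pssms(seed=1, n_kinases=1)
        pssm = pssms[0]
        seq = pssm.argmax_sequence()
        padded = "__" + seq[2:]
        expected = sum(
            math.log2(pssm.weights[pos][res])
            for pos, res in zip(pssm.positions, seq)
            if res in pssm.weights[pos]
        ) - sum(math.log2(pssm.weights[pos][res]) for pos, res in list(zip(pssm.positions, seq))[:2])
        assert pssm.score(padded) == pytest.approx(expected)

    def test_planted_motif_recovered_with_smallest_p_adj(self):
        pssms = fx.make_pssms(seed=2)
        bg = fx.make_background(pssms, seed=2)
        peptides = fx.make_motif_dataset(8, pssms, "KIN4")
        results = [r for r in motif_enrichment(peptides, pssms, bg, top_k=2) if r.direction == "up"]
        best = min(results, key=lambda r: r.p_adj)
        assert best.kinase == "KIN4"


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == [pytest.approx(0.2)]

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_never_decreases_any_p(self, ps):
        adjusted = bh_adjust(ps)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, ps))

    @pytest.mark.parametrize("p,m", [(0.05, 1), (0.2, 4), (1.0, 3)])
    def test_all_equal_p_is_fixed_point(self, p, m):
        # p * m/m = p at every rank: constant vectors adjust to themselves
        assert bh_adjust([p] * m) == pytest.approx([p] * m)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=15), st.randoms())
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_equivariant_under_permutation(self, ps, rnd):
        order = list(range(len(ps)))
        rnd.shuffle(order)
        shuffled = [ps[i] for i in order]
        adj = bh_adjust(ps)
        adj_shuffled = bh_adjust(shuffled)
        assert adj_shuffled == pytest.approx([adj[i] for i in order])


class TestRankPathways:
    def test_na_last_and_by_absolute_score(self):
        results = [
            EnrichmentResult("A", 3, 2.1, 0.01, 0.02),
            EnrichmentResult("B", 4, -3.0, 0.01, 0.02),
            EnrichmentResult("C", 0, math.nan),
        ]
        assert [r.signature_id for r in rank_pathways(results)] == ["B", "A", "C"]

    def test_all_na_preserves_input_order(self):
        results = [EnrichmentResult(s, 0, math.nan) for s in "XYZ"]
        assert [r.signature_id for r in rank_pathways(results)] == ["X", "Y", "Z"]

    def test_ties_are_stable(self):
        results = [EnrichmentResult(s, 1, 1.0, 0.5, 0.5) for s in "PQR"]
        assert [r.signature_id for r in rank_pathways(results)] == ["P", "Q", "R"]


class TestSignatureIo:
    def test_gmt_round_trip_with_signs(self):
        text = "SIG1\tdesc\tAKT1_S473;+1\tMTOR_S2448;-1\nSIG2\tdesc\tGENE1\tGENE2\n"
        sigs = load_signatures(text)
        assert sigs[0].sign_map() == {"AKT1_S473": 1, "MTOR_S2448": -1}
        assert sigs[1].sign_map() == {"GENE1": 1, "GENE2": 1}

    def test_site_key_normalization(self):
        assert site_key("sos1", "s", 1134) == "SOS1_S1134"
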