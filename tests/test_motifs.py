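"""Motif enumeration, window counting and the randomized draw test."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifhotspot.context import ContextWindow, ReferenceSequence, StrandMode, WindowSpec
from motifhotspot.motifs import (
    Correction,
    MotifSpec,
    NullModel,
    PermutationConfig,
    Statistic,
    count_in_window,
    count_table,
    dinucleotide_shuffle,
    enumerate_motifs,
    observed_statistic,
    reverse_complement,
    run_randomized_test,
    scan_all_motifs,
)

dna = st.text(alphabet="ACGT", min_size=3, max_size=15)


def _win(seq, id="w", start=1):
    return ContextWindow(id, start, start + len(seq) - 1, seq)


def naive_count(seq: str, motif: str) -> int:
    return sum(seq[i : i + len(motif)] == motif for i in range(len(seq) - len(motif) + 1))


class TestEnumerate:
    def test_small_alphabets(self):
        assert enumerate_motifs(1) == ["A", "C", "G", "T"]
        m3 = enumerate_motifs(MotifSpec(3))
        assert len(m3) == 64 and m3[0] == "AAA" and m3[-1] == "TTT"
        assert len(set(m3)) == 64

    def test_matches_cartesian_product_oracle(self):
        assert enumerate_motifs(2) == ["".join(p) for p in itertools.product("ACGT", repeat=2)]


class TestCountInWindow:
    def test_single_and_overlapping_hits(self):
        assert count_in_window(_win("AAAAGTAAAAA"), "GTA") == 1
        assert count_in_window(_win("GTAGTAGTAGT"), "GTA") == 3

    def test_n_blocks_matches(self):
        assert count_in_window(_win("GTNGTAGG"), "GTA") == 1
        assert count_in_window(_win("GTNNNNN"), "GTA") == 0

    def test_motif_longer_than_window_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert count_in_window(_win("ACG"), "ACGT") == 0

    def test_both_strands_adds_reverse_complement(self):
        # TAC is the reverse complement of GTA: counted only under BOTH_STRANDS
        assert count_in_window(_win("TACAAAA"), "GTA") == 0
        assert count_in_window(_win("TACAAAA"), "GTA", StrandMode.BOTH_STRANDS) == 1
        assert count_in_window(_win("GTATTTTAC"), "GTA", StrandMode.BOTH_STRANDS) == 2

    def test_palindromic_motif_not_double_counted(self):
        # AT is its own reverse complement: each site counts once
        assert count_in_window(_win("ATAT"), "AT", StrandMode.BOTH_STRANDS) == 2

    @given(st.text(alphabet="ACGTN", min_size=3, max_size=20), st.integers(0, 63))
    def test_counts_match_naive_scan_oracle(self, seq, motif_idx):
        motif = enumerate_motifs(3)[motif_idx]
        assert count_in_window(_win(seq), motif) == naive_count(seq, motif)
        both = count_in_window(_win(seq), motif, StrandMode.BOTH_STRANDS)
        rc = reverse_complement(motif)
        expected = naive_count(seq, motif) + (naive_count(seq, rc) if rc != motif else 0)
        assert both == expected


class TestObservedStatistic:
    def test_windows_with_hit_vs_total_occurrences(self):
        ws = [_win("AAGTAAAAAAA", "a"), _win("CCCCCCCCCCC", "b"), _win("AAAAAAGTAAA", "c")]
        stat, flagged = observed_statistic(ws, "GTA", MotifSpec(3, Statistic.WINDOWS_WITH_HIT))
        assert stat == 2 and flagged == {"a", "c"}
        total, _ = observed_statistic(ws, "GTA", MotifSpec(3, Statistic.TOTAL_OCCURRENCES))
        assert total == 2

    def test_multi_hit_window(self):
        ws = [_win("GTAGTAGTAGT")]
        assert observed_statistic(ws, "GTA", MotifSpec(3, Statistic.WINDOWS_WITH_HIT))[0] == 1
        assert observed_statistic(ws, "GTA", MotifSpec(3, Statistic.TOTAL_OCCURRENCES))[0] == 3

    def test_empty_window_list(self):
        assert observed_statistic([], "GTA")[0] == 0

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_sum_over_all_motifs(self, seed):
        """Every untruncated 11-bp window contributes exactly 9 total 3-mer
        occurrences across the 64 motifs."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=11))
        table = count_table([_win(seq)], MotifSpec(3, Statistic.TOTAL_OCCURRENCES))
        assert sum(table.per_motif.values()) == 9


class TestRandomizedTest:
    def _tiny(self, seed=1, n_bases=30):
        rng = np.random.default_rng(seed)
        bases = "".join(rng.choice(list("ACGT"), size=n_bases))
        return ReferenceSequence("t", 1, bases)

    def test_observed_zero_gives_p_one(self):
        ref = self._tiny(2)
        ws = [_win("CCCCCCCCCCC")]  # no GTA anywhere in the window
        res = run_randomized_test(ref, ws, "GTA", WindowSpec(5), PermutationConfig(50, seed=3))
        assert res.observed == 0 and res.p_empirical == 1.0

    def test_p_equals_tail_count_over_iterations(self):
        ref = self._tiny(4)
        ws = [_win("AAGTAAAAAAA"), _win("TTTTTTTTTTT")]
        res = run_randomized_test(ref, ws, "GTA", WindowSpec(5), PermutationConfig(40, seed=5))
        expected = np.count_nonzero(res.null_draws >= res.observed) / 40
        assert res.p_empirical == expected
        assert res.p_corrected >= res.p_empirical - 1e-12

    def test_p_monotone_in_observed_for_fixed_draws(self):
        ref = self._tiny(6)
        ws = [_win("AAGTAAAAAAA")]
        res = run_randomized_test(ref, ws, "GTA", WindowSpec(5), PermutationConfig(60, seed=7))
        draws = res.null_draws
        ps = [np.count_nonzero(draws >= o) / len(draws) for o in range(0, 4)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_zero_p_displayed_as_less_than_resolution(self):
        ref = ReferenceSequence("t", 1, "ATATATATATATATATATATATAT")
        ws = [_win("GTAGTAGTAGT")] * 4  # unreachable under this reference's null
        res = run_randomized_test(ref, ws, "GTA", WindowSpec(5), PermutationConfig(100, seed=1))
        assert res.p_empirical == 0.0
        assert res.p_display == "< 0.01"
        assert 0 < res.p_add_one <= 1 / 100

    def test_draw_exceeding_eligible_positions_errors(self):
        ref = self._tiny(8, n_bases=15)
        ws = [_win("AAAAAAAAAAA")] * 10
        with pytest.raises(ValueError, match="eligible"):
            run_randomized_test(ref, ws, "GTA", WindowSpec(5), PermutationConfig(10, seed=2))

    def test_brute_force_recount_of_every_draw(self):
        """On a tiny reference the fast vectorized null must agree with a
        naive per-draw recount (independent string-scanning oracle)."""
        ref = self._tiny(9, n_bases=30)
        ws = [_win("AAGTAAAAAAA"), _win("GGGTAGGGGGG"), _win("TTTTTTTTTTT")]
        sink = []
        res = run_randomized_test(
            ref, ws, "GTA", WindowSpec(5), PermutationConfig(100, seed=10), position_sink=sink
        )
        assert len(sink) == 100
        for draws, positions in zip(res.null_draws, sink):
            recount = 0
            for pos in positions:
                seq = ref.bases[pos - 1 - 5 : pos + 5]  # naive slice, untruncated by construction
                assert len(seq) == 11
                recount += naive_count(seq, "GTA") > 0
            assert recount == draws

    def test_reproducibility_bit_identical(self):
        ref = self._tiny(12, n_bases=200)
        ws = [_win("AAGTAAAAAAA"), _win("CCCCCCCCCCC")]
        cfg = PermutationConfig(200, seed=42)
        r1 = run_randomized_test(ref, ws, "GTA", WindowSpec(5), cfg)
        r2 = run_randomized_test(ref, ws, "GTA", WindowSpec(5), cfg)
        assert np.array_equal(r1.null_draws, r2.null_draws)
        assert r1.p_empirical == r2.p_empirical


class TestScanAllMotifs:
    def test_degenerate_all_a_reference(self):
        ref = ReferenceSequence("t", 1, "A" * 50)
        ws = [_win("AAAAAAAAAAA", id=f"w{i}") for i in range(3)]
        results = scan_all_motifs(ref, ws, PermutationConfig(50, seed=1), MotifSpec(1), WindowSpec(5))
        by_motif = {r.motif: r for r in results}
        assert by_motif["A"].observed == 3
        for m in "CGT":
            assert by_motif[m].observed == 0 and by_motif[m].p_empirical == 1.0

    def test_bonferroni_is_capped_multiplication(self):
        rng = np.random.default_rng(3)
        bases = "".join(rng.choice(list("ACGT"), size=400))
        ref = ReferenceSequence("t", 1, bases)
        ws = [_win(bases[i : i + 11], id=f"w{i}") for i in (10, 50, 90, 130)]
        results = scan_all_motifs(ref, ws, PermutationConfig(80, seed=2, correction=Correction.BONFERRONI))
        for r in results:
            assert r.p_corrected == pytest.approx(min(1.0, 64 * r.p_empirical))

    def test_shared_null_and_sort_order(self):
        rng = np.random.default_rng(4)
        bases = "".join(rng.choice(list("ACGT"), size=300))
        ref = ReferenceSequence("t", 1, bases)
        ws = [_win(bases[i : i + 11], id=f"w{i}") for i in range(20, 200, 20)]
        results = scan_all_motifs(ref, ws, PermutationConfig(100, seed=9))
        keys = [(r.p_corrected, -r.observed, r.motif) for r in results]
        assert keys == sorted(keys)
        assert len(results) == 64
        # conservation across the shared null: TOTAL_OCCURRENCES sums to 9/window
        res_tot = scan_all_motifs(
            ref,
            ws,
            PermutationConfig(30, seed=9),
            MotifSpec(3, Statistic.TOTAL_OCCURRENCES),
        )
        null_sum = np.stack([r.null_draws for r in res_tot]).sum(axis=0)
        assert np.all(null_sum == 9 * len(ws))

    def test_planted_enrichment_ranks_first(self, small_dataset):
        from motifhotspot.context import extract_windows

        _, ref, _, records, _ = small_dataset
        ws = extract_windows(ref, records)
        results = scan_all_motifs(ref, ws, PermutationConfig(500, seed=6))
        assert results[0].motif == "GTA" and results[0].significant

    def test_position_mask_restricts_null_draws(self, tmp_path):
        """With a BED mask the null only resamples masked positions."""
        from motifhotspot.context import bed_mask_positions

        rng = np.random.default_rng(14)
        bases = "".join(rng.choice(list("ACGT"), size=120))
        ref = ReferenceSequence("t", 1, bases)
        bed = tmp_path / "mask.bed"
        bed.write_text("t\t20\t60\nother\t0\t100\n")  # 0-based half-open -> 21..60
        mask = bed_mask_positions(bed, "t")
        assert mask == set(range(21, 61))
        ws = [_win(bases[i : i + 11], id=f"w{i}") for i in (30, 40)]
        sink = []
        run_randomized_test(
            ref, ws, "GTA", WindowSpec(5), PermutationConfig(50, seed=3),
            position_sink=sink, position_mask=mask,
        )
        for positions in sink:
            assert set(positions) <= mask

    def test_dinucleotide_shuffle_null_runs_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        bases = "".join(rng.choice(list("ACGT"), size=100))
        ref = ReferenceSequence("t", 1, bases)
        ws = [_win(bases[i : i + 11], id=f"w{i}") for i in (5, 30, 60)]
        cfg = PermutationConfig(50, null_model=NullModel.DINUCLEOTIDE_SHUFFLE, seed=8)
        r1 = scan_all_motifs(ref, ws, cfg)
        r2 = scan_all_motifs(ref, ws, cfg)
        assert all(np.array_equal(a.null_draws, b.null_draws) for a, b in zip(r1, r2))


class TestDinucleotideShuffle:
    @given(dna, st.integers(0, 2**31 - 1))
    def test_preserves_dinucleotide_composition_and_endpoints(self, seq, seed):
        from collections import Counter

        rng = np.random.default_rng(seed)
        out = dinucleotide_shuffle(seq, rng)
        assert len(out) == len(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]
        assert Counter(zip(out, out[1:])) == Counter(zip(seq, seq[1:]))
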