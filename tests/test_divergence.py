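"""BLOSUM62-based column similarity: mapping, gaps, EC/IC halves."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protosym.divergence import (
    BLOSUM62,
    DivergenceError,
    MSA,
    TMRegion,
    custom_pair_score,
    msa_similarity,
    score_tm_halves,
    split_ec_ic,
)
from protosym.synthetic import AA20, make_synthetic_msa


class TestBlosumTable:
    def test_matches_published_matrix(self):
        """The embedded table equals Biopython's published BLOSUM62 copy."""
        from Bio.Align import substitution_matrices

        ref = substitution_matrices.load("BLOSUM62")
        for a in AA20:
            for b in AA20:
                assert BLOSUM62[(a, b)] == int(ref[a][b])

    def test_checksum(self):
        total = sum(BLOSUM62[(a, b)] for a in AA20 for b in AA20)
        diag = sum(BLOSUM62[(a, a)] for a in AA20)
        assert (total, diag) == (-426, 116)


class TestCustomPairScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("A", "A", 1.0),     # BLOSUM62 4 -> 1
            ("W", "W", 1.0),     # 11 -> 1 (>= 4 mapped to 1)
            ("Y", "F", 0.75),    # 3
            ("E", "D", 0.50),    # 2
            ("S", "A", 0.25),    # 1
            ("A", "V", 0.125),   # 0
            ("W", "G", 0.0),     # negative
            ("X", "A", 0.0),     # nonstandard residue scores 0
        ],
    )
    def test_mapping(self, a, b, expected):
        assert custom_pair_score(a, b) == expected

    def test_symmetric(self):
        for a in AA20:
            for b in AA20:
                assert custom_pair_score(a, b) == custom_pair_score(b, a)

    def test_non_letter_rejected(self):
        with pytest.raises(DivergenceError):
            custom_pair_score("A", "-")


def _brute_force_similarity(rows, cols):
    """Independent O(rows² x cols) recount straight from the definition."""
    total, n = 0.0, 0
    for c in cols:
        letters = [r[c] for r in rows if r[c] != "-"]
        for i in range(len(letters)):
            for j in range(i + 1, len(letters)):
                a, b = letters[i], letters[j]
                if a == "X" or b == "X":
                    s = 0.0
                else:
                    v = BLOSUM62[(a, b)]
                    s = 1.0 if v >= 4 else {3: 0.75, 2: 0.5, 1: 0.25, 0: 0.125}.get(v, 0.0)
                total += s
                n += 1
    return (math.nan if n == 0 else 100.0 * total / n), n


class TestMsaSimilarity:
    def test_identical_sequences_score_100(self):
        msa = MSA(["a", "b", "c"], ["LVIFA", "LVIFA", "LVIFA"])
        assert msa_similarity(msa).percentage == pytest.approx(100.0)

    def test_hand_enumerated_column(self):
        # column {A, A, V}: pairs (A,A)=1, (A,V)=0.125 twice -> 125/3
        msa = MSA(["1", "2", "3"], ["A", "A", "V"])
        result = msa_similarity(msa)
        assert result.n_comparisons == 3
        assert result.percentage == pytest.approx(100.0 * 1.25 / 3, abs=1e-9)

    def test_gap_excluded_from_comparisons(self):
        msa = MSA(["1", "2", "3"], ["A", "-", "V"])
        result = msa_similarity(msa)
        assert result.n_comparisons == 1
        assert result.percentage == pytest.approx(12.5)

    def test_all_gap_range_flagged_undefined(self):
        msa = MSA(["1", "2"], ["A-", "A-"])
        result = msa_similarity(msa, [1])
        assert not result.defined
        assert math.isnan(result.percentage)

    def test_row_permutation_invariance_and_bounds(self):
        rows, _ = make_synthetic_msa("LVIFAGWSTYCMEQ", 6, 0.4, seed=8)
        msa = MSA.from_pairs(rows)
        perm = MSA.from_pairs([rows[i] for i in (3, 0, 5, 1, 4, 2)])
        r1, r2 = msa_similarity(msa), msa_similarity(perm)
        assert r1.percentage == pytest.approx(r2.percentage, abs=1e-12)
        assert 0.0 <= r1.percentage <= 100.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_on_random_msas(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(6):
            letters = [
                "-" if rng.random() < 0.1 else AA20[rng.integers(20)]
                for _ in range(40)
            ]
            rows.append((f"s{i}", "".join(letters)))
        msa = MSA.from_pairs(rows)
        expected, n = _brute_force_similarity(msa.rows, range(40))
        got = msa_similarity(msa)
        assert got.n_comparisons == n
        if n:
            assert got.percentage == pytest.approx(expected, abs=1e-9)

    def test_monotone_one_more_mismatch_never_increases(self):
        base = ["LVIFA", "LVIFA", "LVIFA"]
        msa = MSA(["1", "2", "3"], base)
        worse = MSA(["1", "2", "3"], ["LVIFA", "LVIFA", "LVIFR"])  # A->R at col 4
        assert msa_similarity(worse).percentage <= msa_similarity(msa).percentage


class TestSplitEcIc:
    def test_n_term_ec(self):
        region = TMRegion(1, 10, 30, 20, "EC")
        ec, ic = split_ec_ic(region)
        assert ec == list(range(10, 20))
        assert ic == list(range(21, 31))

    def test_n_term_ic_swaps(self):
        region = TMRegion(1, 10, 30, 20, "IC")
        ec, ic = split_ec_ic(region)
        assert ec == list(range(21, 31))
        assert ic == list(range(10, 20))

    def test_center_at_region_start_leaves_half_empty(self):
        region = TMRegion(1, 10, 30, 10, "EC")
        ec, ic = split_ec_ic(region)
        assert ec == []
        assert ic == list(range(11, 31))

    def test_center_column_in_neither_half(self):
        region = TMRegion(1, 0, 10, 5, "EC")
        ec, ic = split_ec_ic(region)
        assert 5 not in ec and 5 not in ic


class TestScoreTmHalves:
    def _make_map(self, ids, regions):
        return {i: list(regions) for i in ids}

    def test_identical_sequences_all_scopes_100(self):
        rows = [("a", "LVIFAGWLVIFAGWLVIFAGW"), ("b", "LVIFAGWLVIFAGWLVIFAGW")]
        msa = MSA.from_pairs(rows)
        regions = [TMRegion(1, 0, 8, 4, "EC"), TMRegion(2, 12, 20, 16, "IC")]
        results = score_tm_halves(msa, self._make_map(["a", "b"], regions))
        for r in results:
            if r.defined:
                assert r.percentage == pytest.approx(100.0)

    def test_one_tm_full_equals_msa_similarity(self):
        rows, _ = make_synthetic_msa("LVIFAGWSTYCM", 4, 0.3, seed=5)
        msa = MSA.from_pairs(rows)
        region = TMRegion(1, 0, 11, 6, "EC")
        results = score_tm_halves(
            msa, self._make_map([i for i, _ in rows], [region]),
            protodomains={},
        )
        full = next(r for r in results if r.scope == "TM1")
        direct = msa_similarity(msa, range(0, 12))
        assert full.percentage == pytest.approx(direct.percentage, abs=1e-12)

    def test_asymmetric_rates_give_ec_below_ic(self):
        """EC halves mutated harder than IC halves are scored as more diverged."""
        n_sites = 42
        regions = [TMRegion(1, 0, 20, 10, "EC"), TMRegion(2, 21, 41, 31, "IC")]
        wins = 0
        for seed in range(20):
            rates = np.zeros(n_sites)
            for region in regions:
                ec, ic = split_ec_ic(region)
                rates[ec] = 0.55
                rates[ic] = 0.1
            rows, _ = make_synthetic_msa("L" * n_sites, 8, 0.0, seed=seed,
                                         site_rates=rates)
            msa = MSA.from_pairs(rows)
            results = {
                r.scope: r for r in score_tm_halves(
                    msa, self._make_map([i for i, _ in rows], regions),
                    protodomains={},
                )
            }
            if all(results[f"TM{k}_EC"].percentage < results[f"TM{k}_IC"].percentage
                   for k in (1, 2)):
                wins += 1
        assert wins == 20

    def test_inconsistent_tm_sets_error_names_sequence(self):
        rows = [("a", "LVIFA"), ("b", "LVIFA")]
        msa = MSA.from_pairs(rows)
        mapping = {
            "a": [TMRegion(1, 0, 4, 2, "EC")],
            "b": [TMRegion(2, 0, 4, 2, "EC")],
        }
        with pytest.raises(DivergenceError, match="'b'"):
            score_tm_halves(msa, mapping)

    def test_protodomain_aggregates_average_constituents(self):
        rows, _ = make_synthetic_msa("LVIFAGWSTYCMEQHKNDRP" * 2, 5, 0.25, seed=9)
        msa = MSA.from_pairs(rows)
        regions = [
            TMRegion(1, 0, 8, 4, "EC"),
            TMRegion(2, 10, 18, 14, "IC"),
            TMRegion(3, 20, 28, 24, "EC"),
            TMRegion(4, 30, 38, 34, "IC"),
        ]
        results = {r.scope: r for r in score_tm_halves(
            msa, self._make_map([i for i, _ in rows], regions))}
        expected_pd1 = np.mean([results["TM1"].percentage, results["TM2"].percentage])
        assert results["protodomain_1"].percentage == pytest.approx(expected_pd1)
        expected_pd2 = np.mean([results["TM3"].percentage, results["TM4"].percentage])
        assert results["protodomain_2"].percentage == pytest.approx(expected_pd2)
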