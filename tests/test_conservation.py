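"""Alignment, species filtering, star MSA, refinement and masking."""

import itertools

import numpy as np
import pytest

from comotif.conservation import (
    AlignmentParams,
    MultipleAlignment,
    filter_species,
    mask_nonconserved,
    progressive_msa,
    refine_msa,
    sum_of_pairs,
    sw_gotoh,
)
from comotif.promoter_io import OrthologueGroup, PromoterRecord

from conftest import random_dna


def brute_force_affine(a: str, b: str, p: AlignmentParams) -> float:
    """Independent three-matrix affine-gap local DP (score only)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = p.match if (a[i - 1] == b[j - 1] and a[i - 1] in "ACGT") else p.mismatch
            M[i][j] = s + max(0.0, M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + p.gap_open, X[i - 1][j] + p.gap_extend)
            Y[i][j] = max(M[i][j - 1] + p.gap_open, Y[i][j - 1] + p.gap_extend)
            best = max(best, M[i][j])
    return best


def sp3_optimum(s1: str, s2: str, s3: str, p: AlignmentParams) -> float:
    """Exact 3-sequence sum-of-pairs optimum under linear gap costs."""

    def pair(x: str | None, y: str | None) -> float:
        if x is None and y is None:
            return 0.0
        if x is None or y is None:
            return p.gap_open
        return p.match if (x == y and x in "ACGT") else p.mismatch

    seqs = (s1, s2, s3)
    dims = tuple(len(s) + 1 for s in seqs)
    NEG = -1e18
    D = np.full(dims, NEG)
    D[0, 0, 0] = 0.0
    moves = [m for m in itertools.product((0, 1), repeat=3) if any(m)]
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                cur = D[i, j, k]
                if cur <= NEG / 2:
                    continue
                for di, dj, dk in moves:
                    ni, nj, nk = i + di, j + dj, k + dk
                    if ni >= dims[0] or nj >= dims[1] or nk >= dims[2]:
                        continue
                    cs = [
                        seqs[0][i] if di else None,
                        seqs[1][j] if dj else None,
                        seqs[2][k] if dk else None,
                    ]
                    cost = pair(cs[0], cs[1]) + pair(cs[0], cs[2]) + pair(cs[1], cs[2])
                    val = cur + cost
                    if val > D[ni, nj, nk]:
                        D[ni, nj, nk] = val
    return float(D[dims[0] - 1, dims[1] - 1, dims[2] - 1])


class TestSwGotoh:
    def test_identity_alignment(self, params):
        seq = "ACGTACGTAC"
        aln = sw_gotoh(seq, seq, params)
        assert aln.score == params.match * len(seq)
        assert aln.aligned_a == aln.aligned_b == seq

    def test_no_positive_alignment_returns_empty(self, params):
        aln = sw_gotoh("AAAA", "TTTT", params)
        assert aln.score == 0.0
        assert aln.aligned_a == aln.aligned_b == ""

    def test_matches_brute_force_oracle_on_random_pairs(self, params, rng):
        for _ in range(200):
            a = random_dna(rng, int(rng.integers(1, 31)))
            b = random_dna(rng, int(rng.integers(1, 31)))
            assert sw_gotoh(a, b, params).score == pytest.approx(
                brute_force_affine(a, b, params), abs=1e-9
            )

    def test_matches_biopython_local_aligner(self, params, rng):
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = params.match
        aligner.mismatch_score = params.mismatch
        aligner.open_gap_score = params.gap_open
        aligner.extend_gap_score = params.gap_extend
        for _ in range(50):
            a = random_dna(rng, int(rng.integers(5, 40)))
            b = random_dna(rng, int(rng.integers(5, 40)))
            ours = sw_gotoh(a, b, params).score
            assert ours == pytest.approx(max(aligner.score(a, b), 0.0), abs=1e-9)

    def test_score_symmetric(self, params, rng):
        for _ in range(30):
            a = random_dna(rng, 20)
            b = random_dna(rng, 25)
            assert sw_gotoh(a, b, params).score == sw_gotoh(b, a, params).score

    def test_ungapping_recovers_input_substrings(self, params, rng):
        for _ in range(30):
            a = random_dna(rng, 30)
            b = random_dna(rng, 30)
            aln = sw_gotoh(a, b, params)
            assert aln.aligned_a.replace("-", "") == a[aln.a_start : aln.a_end]
            assert aln.aligned_b.replace("-", "") == b[aln.b_start : aln.b_end]

    def test_n_never_matches(self, params):
        aln = sw_gotoh("NNNN", "NNNN", params)
        assert aln.score == 0.0


class TestFilterSpecies:
    def _group(self, others: dict[str, str], ref_seq: str) -> OrthologueGroup:
        members = {"mouse": PromoterRecord("g", "mouse", ref_seq, 0)}
        for sp, seq in others.items():
            members[sp] = PromoterRecord("g", sp, seq, 0)
        return OrthologueGroup("g", members)

    def test_thresholds(self, params):
        ref = random_dna(np.random.default_rng(0), 700)
        # identical 700-mer: score 3500 > 200, consensus length 700 in bounds
        group = self._group({"human": ref}, ref)
        assert filter_species(group, params) == ["mouse", "human"]

    def test_score_boundary_is_strict(self, params):
        # 40 matching bases => score exactly 200, must be dropped
        ref = random_dna(np.random.default_rng(1), 40)
        group = self._group({"human": ref}, ref)
        assert filter_species(group, params, min_len=1, max_len=1000) == ["mouse"]
        # 41 matches -> 205 > 200: retained
        ref41 = random_dna(np.random.default_rng(2), 41)
        group41 = self._group({"human": ref41}, ref41)
        assert filter_species(group41, params, min_len=1, max_len=1000) == ["mouse", "human"]

    def test_consensus_length_bounds_inclusive(self, params):
        ref = random_dna(np.random.default_rng(3), 1001)
        group = self._group({"human": ref}, ref)
        # identical sequences align over 1001 columns > max_len
        assert filter_species(group, params) == ["mouse"]
        assert filter_species(group, params, max_len=1001) == ["mouse", "human"]

    def test_missing_reference_errors(self, params):
        group = OrthologueGroup("g", {"human": PromoterRecord("g", "human", "ACGT", 0)})
        with pytest.raises(KeyError):
            filter_species(group, params)


class TestProgressiveMsa:
    def _group(self, seqs: dict[str, str]) -> OrthologueGroup:
        return OrthologueGroup(
            "g", {sp: PromoterRecord("g", sp, s, 0) for sp, s in seqs.items()}
        )

    def test_identical_pair_gapless(self, params):
        seq = "ACGTACGTACGT"
        msa = progressive_msa(self._group({"mouse": seq, "human": seq}), ["mouse", "human"], params)
        assert msa.rows == [seq, seq]
        assert msa.sp_score() == params.match * len(seq)

    def test_single_species_degenerate(self, params):
        seq = "ACGTACGT"
        msa = progressive_msa(self._group({"mouse": seq}), ["mouse"], params)
        assert msa.rows == [seq]

    def test_three_sequences_bounded_by_exact_optimum(self, params, rng):
        for _ in range(10):
            seqs = {sp: random_dna(rng, int(rng.integers(4, 9))) for sp in ("mouse", "human", "rat")}
            msa = progressive_msa(self._group(seqs), list(seqs), params)
            contents = [r.replace("-", "") for r in msa.rows]
            if any(not c for c in contents):
                continue  # species with no local alignment to the reference
            optimum = sp3_optimum(*contents, params)
            assert msa.sp_score() <= optimum + 1e-9


class TestRefineMsa:
    def test_fixed_point_on_identical_rows(self, params):
        msa = MultipleAlignment(["mouse", "human"], ["ACGTAC", "ACGTAC"], params)
        refined = refine_msa(msa, params)
        assert refined.rows == msa.rows

    def test_sp_score_never_decreases(self, params, rng):
        for _ in range(5):
            n = int(rng.integers(6, 10))
            base = random_dna(rng, n)
            rows = []
            for _ in range(3):
                row = list(base)
                pos = int(rng.integers(0, n))
                row[pos] = "-"
                rows.append("".join(row) + random_dna(rng, 1))
            msa = MultipleAlignment(["a", "b", "c"], rows, params)
            refined = refine_msa(msa, params)
            assert refined.sp_score() >= msa.sp_score() - 1e-9

    def test_recovers_optimum_after_misplaced_gap(self, params):
        # all rows hold ACGTAC; row b carries a shifted gap
        rows = ["ACGTAC-", "-ACGTAC", "ACGTAC-"]
        msa = MultipleAlignment(["a", "b", "c"], rows, params)
        refined = refine_msa(msa, params)
        contents = [r.replace("-", "") for r in refined.rows]
        assert refined.sp_score() == pytest.approx(sp3_optimum(*contents, params))
        assert refined.rows == ["ACGTAC", "ACGTAC", "ACGTAC"]


class TestMaskNonconserved:
    def test_full_conservation_masks_nothing(self, params):
        rows = ["ACGTACGTACGT"] * 3
        msa = MultipleAlignment(["mouse", "human", "rat"], rows, params)
        masked = mask_nonconserved(msa)
        assert masked.sequence == rows[0]
        assert masked.fraction_masked == 0.0

    def test_total_disagreement_masks_everything(self, params):
        msa = MultipleAlignment(["mouse", "human"], ["AAAAAAAA", "TTTTTTTT"], params)
        masked = mask_nonconserved(msa)
        assert masked.sequence == "N" * 8
        assert masked.fraction_masked == 1.0

    def test_conserved_core_survives_divergent_flanks(self, params):
        core = "ACGTACGTAC"  # 10 columns, longer than min_run
        ref = "TTTTT" + core + "TTTTT"
        other1 = "GGGGG" + core + "GGGGG"
        other2 = "CCCCC" + core + "CCCCC"
        msa = MultipleAlignment(["mouse", "human", "rat"], [ref, other1, other2], params)
        masked = mask_nonconserved(msa)
        assert masked.sequence == "N" * 5 + core + "N" * 5

    def test_short_conserved_runs_are_masked(self, params):
        core = "ACGT"  # below the min_run=6 cutoff
        ref = "TTTTT" + core + "TTTTT"
        other = "GGGGG" + core + "GGGGG"
        msa = MultipleAlignment(["mouse", "human"], [ref, other], params)
        masked = mask_nonconserved(msa)
        assert masked.sequence == "N" * len(ref)

    def test_single_row_warns_and_keeps_sequence(self, params, caplog):
        msa = MultipleAlignment(["mouse"], ["ACGTACGT"], params)
        with caplog.at_level("WARNING"):
            masked = mask_nonconserved(msa)
        assert masked.sequence == "ACGTACGT"
        assert "nothing masked" in caplog.text

    def test_masking_monotone_in_agreement_fraction(self, params, rng):
        for _ in range(10):
            ref = random_dna(rng, 40)
            rows = [ref]
            for _ in range(3):
                row = list(ref)
                for pos in rng.choice(40, size=12, replace=False):
                    row[pos] = "ACGT"[int(rng.integers(0, 4))]
                rows.append("".join(row))
            msa = MultipleAlignment(["mouse", "a", "b", "c"], rows, params)
            masked_lo = mask_nonconserved(msa, min_agree_frac=0.3)
            masked_hi = mask_nonconserved(msa, min_agree_frac=0.8)
            lo_n = {i for i, ch in enumerate(masked_lo.sequence) if ch == "N"}
            hi_n = {i for i, ch in enumerate(masked_hi.sequence) if ch == "N"}
            assert lo_n <= hi_n

    def test_output_length_equals_reference_length(self, params):
        # reference row with gaps: output must match ungapped reference length
        msa = MultipleAlignment(["mouse", "human"], ["AC-GTACG", "ACCGTACG"], params)
        masked = mask_nonconserved(msa)
        assert len(masked.sequence) == 7
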