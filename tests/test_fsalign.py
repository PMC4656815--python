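import random

import pytest

from fsdenovo.fsalign import AlignParams, best_reference, fs_align
from fsdenovo.seqio import translate
from oracle import brute_force_score

AA20 = "ARNDCQEGHILKMFPSTWYV"


@pytest.fixture(scope="module")
def params():
    return AlignParams()


def _random_coding(rng, n_codons):
    """Random STOP-free coding sequence."""
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice("ACGT") for _ in range(3))
        if translate(c) != "*":
            codons.append(c)
    return "".join(codons)


class TestKnownInstances:
    def test_perfect_in_frame_query(self, params):
        a = fs_align("ATGAAACTG", "MKL", params)
        # BLOSUM62 diagonal: S(M,M)+S(K,K)+S(L,L) = 5+5+4
        assert a.score == 14
        assert a.identity == 1.0
        assert a.events == []
        assert a.corrected_aa == "MKL"
        assert a.aligned_ref_span == (0, 3)

    def test_single_interior_deletion_costs_one_fs_penalty(self, params):
        rng = random.Random(42)
        coding = _random_coding(rng, 20)
        ref = translate(coding)
        mutated = coding[:30] + coding[31:]  # delete one nt mid-codon 11
        a = fs_align(mutated, ref, params)
        assert len(a.events) == 1 and a.events[0][1] == 2
        assert a.corrected_aa == ref
        S = params.subst_matrix
        assert a.score == sum(S[aa, aa] for aa in ref) + params.fs_penalty
        assert brute_force_score(mutated, ref) == a.score

    def test_single_interior_insertion_costs_one_fs_penalty(self, params):
        rng = random.Random(43)
        coding = _random_coding(rng, 20)
        ref = translate(coding)
        mutated = coding[:30] + "A" + coding[30:]
        a = fs_align(mutated, ref, params)
        assert len(a.events) == 1 and a.events[0][1] == 4
        assert a.corrected_aa == ref
        S = params.subst_matrix
        assert a.score == sum(S[aa, aa] for aa in ref) + params.fs_penalty

    def test_terminal_incomplete_codon_is_not_an_event(self, params):
        # a 400-nt in-frame read is 133 codons plus one dangling base;
        # the dangling base must not be charged as a frameshift
        rng = random.Random(44)
        coding = _random_coding(rng, 134)
        a = fs_align(coding[:400], translate(coding[:400]), params)
        assert a.events == []
        assert a.identity == 1.0
        assert len(a.corrected_aa) == 133

    def test_reverse_complement_is_out_of_contract(self, params):
        rng = random.Random(0)
        coding = _random_coding(rng, 40)
        ref = translate(coding)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(coding))
        a = fs_align(rc, ref, params)
        assert a.identity < 0.5  # orientation must be handled upstream

    def test_errors(self, params):
        with pytest.raises(ValueError, match="STOP"):
            fs_align("ATGATG", "M*K", params)
        with pytest.raises(ValueError, match="3 nt"):
            fs_align("AT", "M", params)
        with pytest.raises(ValueError):
            AlignParams(fs_penalty=1.0)


class TestOracleEquivalence:
    def test_dp_equals_exhaustive_enumeration(self, params):
        """DP score must equal brute-force path enumeration on >= 1000
        random small instances."""
        rng = random.Random(20240917)
        for _ in range(1000):
            n = rng.randint(3, 15)
            m = rng.randint(1, 5)
            q = "".join(rng.choice("ACGT") for _ in range(n))
            r = "".join(rng.choice(AA20) for _ in range(m))
            expected = brute_force_score(q, r)
            got = fs_align(q, r, params).score
            assert got == pytest.approx(expected), (q, r)

    def test_oracle_equivalence_with_ambiguous_bases(self, params):
        rng = random.Random(5)
        for _ in range(100):
            n = rng.randint(3, 12)
            q = "".join(rng.choice("ACGTN") for _ in range(n))
            r = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 4)))
            assert fs_align(q, r, params).score == pytest.approx(brute_force_score(q, r))


class TestInvariants:
    def test_error_free_sequence_scores_diagonal_sum(self, params):
        rng = random.Random(11)
        coding = _random_coding(rng, 50)
        ref = translate(coding)
        a = fs_align(coding, ref, params)
        S = params.subst_matrix
        assert a.score == sum(S[aa, aa] for aa in ref)
        assert a.identity == 1.0 and a.events == []

    @pytest.mark.parametrize("positions", [(60,), (60, 120), (30, 90)])
    def test_event_count_matches_introduced_indels(self, params, positions):
        rng = random.Random(13)
        coding = _random_coding(rng, 60)
        ref = translate(coding)
        mutated = coding
        for off, pos in enumerate(sorted(positions, reverse=True)):
            if off % 2:
                mutated = mutated[:pos] + rng.choice("ACGT") + mutated[pos:]
            else:
                mutated = mutated[:pos] + mutated[pos + 1 :]
        a = fs_align(mutated, ref, params)
        assert len(a.events) == len(positions)
        diffs = sum(x != y for x, y in zip(a.corrected_aa, ref))
        assert diffs <= len(positions)  # <= 1 residue damaged per site

    def test_translation_invariant(self, params):
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randint(6, 40)
            q = "".join(rng.choice("ACGT") for _ in range(n))
            r = "".join(rng.choice(AA20) for _ in range(rng.randint(2, 8)))
            a = fs_align(q, r, params)
            assert translate(a.corrected_nt, 0) == a.corrected_aa
            assert len(a.corrected_nt) % 3 == 0

    def test_score_monotone_in_fs_penalty(self):
        rng = random.Random(19)
        coding = _random_coding(rng, 30)
        mutated = coding[:40] + coding[41:]  # one deletion
        ref = translate(coding)
        scores = [
            fs_align(mutated, ref, AlignParams(fs_penalty=p)).score
            for p in (-5.0, -10.0, -15.0, -25.0)
        ]
        assert scores == sorted(scores, reverse=True)

    def test_determinism(self, params):
        rng = random.Random(23)
        q = "".join(rng.choice("ACGT") for _ in range(50))
        r = "".join(rng.choice(AA20) for _ in range(15))
        a1, a2 = fs_align(q, r, params), fs_align(q, r, params)
        assert a1 == a2


class TestMatrixLoading:
    def test_matrix_file_round_trip(self, tmp_path):
        import numpy as np

        from fsdenovo.fsalign import load_matrix

        m = load_matrix("BLOSUM62")
        path = tmp_path / "custom.mat"
        path.write_text(str(m))
        m2 = load_matrix(str(path))
        assert np.allclose(np.asarray(m), np.asarray(m2))
        assert str(m2.alphabet) == str(m.alphabet)

    def test_unknown_name_rejected(self):
        from fsdenovo.fsalign import load_matrix

        with pytest.raises(Exception):
            load_matrix("NOSUCHMATRIX")


class TestBestReference:
    def test_exact_match_beats_distant_homolog(self, params):
        rng = random.Random(29)
        coding = _random_coding(rng, 40)
        ref = translate(coding)
        distant = "".join(rng.choice(AA20) for _ in range(40))
        rid, aln = best_reference(coding, [("far", distant), ("self", ref)], params)
        assert rid == "self" and aln.identity == 1.0

    def test_single_ref(self, params):
        rid, _ = best_reference("ATGAAA", [("only", "MK")], params)
        assert rid == "only"

    def test_tie_goes_to_first(self, params):
        rid, _ = best_reference("ATGAAA", [("first", "MK"), ("second", "MK")], params)
        assert rid == "first"

    def test_empty_refs_rejected(self, params):
        with pytest.raises(ValueError):
            best_reference("ATGAAA", [], params)
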