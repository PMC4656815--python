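import random

import pytest

from fsdenovo.preprocess import (
    FilterParams,
    SampleSheet,
    SLPParams,
    demultiplex,
    dereplicate,
    expected_errors,
    mee_filter,
    pairwise_distance,
    reextract_identical,
    remove_singletons,
    slp,
    trim_to_length,
)
from fsdenovo.seqio import Read, UniqueSeq

BENA_649F = "GARAAYGGHGCNGAYGGYTAYCA"
PRIMER_SITE = "GAGAATGGTGCAGATGGTTATCA"  # one concrete realisation


def _mk(seq, q=30):
    return Read("r", seq, [q] * len(seq))


class TestDemultiplex:
    def sheet(self):
        return SampleSheet({"s1": ("AACC", BENA_649F), "s2": ("GGTT", BENA_649F)})

    def test_exact_barcode_then_degenerate_primer(self):
        payload = "ACGT" * 10
        read = _mk("AACC" + PRIMER_SITE + payload)
        assigned, unassigned = demultiplex([read], self.sheet())
        assert not unassigned
        (out,) = assigned["s1"]
        assert out.seq == payload
        assert len(out.qual) == len(payload)

    def test_barcode_mismatch_unassigned(self):
        read = _mk("TACC" + PRIMER_SITE + "ACGT")
        assigned, unassigned = demultiplex([read], self.sheet())
        assert [r.id for r, _ in unassigned] == ["r"]

    def test_primer_mismatch_reason(self):
        bad_site = "C" + PRIMER_SITE[1:]  # first primer base R={A,G}
        read = _mk("AACC" + bad_site + "ACGT")
        _, unassigned = demultiplex([read], self.sheet())
        assert unassigned[0][1] == "primer mismatch after barcode"

    def test_empty_sheet_everything_unassigned(self):
        reads = [_mk("ACGTACGT")]
        assigned, unassigned = demultiplex(reads, SampleSheet({}))
        assert not any(assigned.values()) and len(unassigned) == 1

    def test_partition_conserved(self):
        reads = [_mk("AACC" + PRIMER_SITE + "AAAA"), _mk("TTTT" * 12)]
        assigned, unassigned = demultiplex(reads, self.sheet())
        assert sum(map(len, assigned.values())) + len(unassigned) == len(reads)

    def test_ambiguous_barcodes_rejected(self):
        with pytest.raises(ValueError, match="prefix"):
            SampleSheet({"a": ("AAC", "N"), "b": ("AACC", "N")})


class TestTrim:
    @pytest.mark.parametrize("length,kept", [(420, True), (400, True), (399, False)])
    def test_boundaries(self, length, kept):
        reads = [_mk("A" * length)]
        k, d = trim_to_length(reads, 400)
        assert (len(k) == 1) is kept
        if kept:
            assert len(k[0].seq) == 400 and len(k[0].qual) == 400
        assert len(k) + len(d) == 1


class TestMee:
    def test_closed_form_uniform_q20(self):
        assert expected_errors([20] * 400) == pytest.approx(4.0)

    def test_single_base_q30(self):
        assert expected_errors([30]) == pytest.approx(0.001)

    def test_empty_qualities(self):
        assert expected_errors([]) == 0.0

    def test_q20_read_removed_at_every_study_threshold(self):
        read = _mk("A" * 400, q=20)  # E = 4.0
        for mee_max in (0.5, 1.0, 1.5, 2.0):
            kept, discarded = mee_filter([read], mee_max)
            assert not kept and len(discarded) == 1

    def test_kept_iff_under_threshold(self):
        good = Read("g", "A" * 100, [35] * 100)  # E ~ 0.03
        kept, _ = mee_filter([good], 0.5)
        assert kept

    def test_nested_kept_sets_across_sweep(self):
        rng = random.Random(0)
        reads = [
            Read(f"r{i}", "A" * 50, [rng.randint(5, 40) for _ in range(50)])
            for i in range(200)
        ]
        previous = set()
        for mee_max in (0.5, 1.0, 1.5, 2.0):
            kept = {r.id for r in mee_filter(reads, mee_max)[0]}
            assert previous <= kept
            previous = kept

    def test_fasta_input_rejected(self):
        with pytest.raises(ValueError, match="FASTA"):
            mee_filter([Read("r", "ACGT")], 1.0)


class TestReextract:
    def test_identical_discard_rescued(self):
        kept = [Read("k1", "ACGT" * 100, [35] * 400)]
        disc = [Read("d1", "ACGT" * 100, [10] * 400)]
        all_kept, rescued, still = reextract_identical(kept, disc)
        assert [r.id for r in rescued] == ["d1"]
        assert len(all_kept) == 2 and not still
        # abundance of the rescued sequence grows on dereplication
        assert dereplicate(all_kept)[0].abundance == 2

    def test_near_identical_stays_discarded(self):
        kept = [Read("k1", "AAAA", [35] * 4)]
        disc = [Read("d1", "AAAT", [10] * 4)]
        _, rescued, still = reextract_identical(kept, disc)
        assert not rescued and len(still) == 1

    def test_empty_discarded_is_identity(self):
        kept = [Read("k1", "AAAA", [35] * 4)]
        all_kept, rescued, still = reextract_identical(kept, [])
        assert all_kept == kept and not rescued and not still


class TestDereplicate:
    def test_abundance_counts(self):
        reads = [Read("a1", "AAAA"), Read("a2", "AAAA"), Read("b1", "CCCC")]
        u = dereplicate(reads)
        assert [(x.seq, x.abundance) for x in u] == [("AAAA", 2), ("CCCC", 1)]
        assert u[0].members == ["a1", "a2"]

    def test_all_distinct(self):
        reads = [Read(f"r{i}", "ACGT"[i % 4] * 4) for i in range(4)]
        u = dereplicate(reads)
        assert len(u) == 4 and all(x.abundance == 1 for x in u)

    def test_empty(self):
        assert dereplicate([]) == []

    def test_tie_break_lexicographic(self):
        reads = [Read("r1", "TTTT"), Read("r2", "AAAA")]
        u = dereplicate(reads)
        assert [x.seq for x in u] == ["AAAA", "TTTT"]

    def test_back_replication_recovers_read_count(self):
        rng = random.Random(2)
        reads = [Read(f"r{i}", rng.choice(["AAAA", "CCCC", "GGGG"])) for i in range(50)]
        u = dereplicate(reads)
        names = {x.id: x.members for x in u}
        assert sum(len(v) for v in names.values()) == 50


class TestPairwiseDistance:
    def test_identical(self):
        s = "ACGT" * 100
        assert pairwise_distance(s, s) == 0.0

    def test_four_substitutions_in_400(self):
        rng = random.Random(9)
        a = "".join(rng.choice("ACGT") for _ in range(400))
        b = list(a)
        for pos in (10, 110, 210, 310):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        assert pairwise_distance(a, "".join(b)) == pytest.approx(0.01)

    def test_totally_different(self):
        assert pairwise_distance("A", "T") == 1.0

    def test_symmetric(self):
        a, b = "ACGTACGTAA", "ACGTTCGTA"
        assert pairwise_distance(a, b) == pytest.approx(pairwise_distance(b, a))


class TestSlp:
    def _uniq(self, seq, n, tag):
        return UniqueSeq(seq, n, [f"{tag}{i}" for i in range(n)])

    def test_merge_within_threshold(self):
        rng = random.Random(4)
        x = "".join(rng.choice("ACGT") for _ in range(400))
        xp = list(x)
        xp[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[xp[50]]
        xp[250] = {"A": "C", "C": "G", "G": "T", "T": "A"}[xp[250]]
        xp = "".join(xp)  # 2 substitutions in 400 nt: d = 0.005
        assert pairwise_distance(x, xp) == pytest.approx(0.005)
        merged = slp([self._uniq(x, 10, "a"), self._uniq(xp, 3, "b")], SLPParams(0.01))
        assert len(merged) == 1
        assert merged[0].seq == x and merged[0].abundance == 13

    def test_no_merge_beyond_threshold(self):
        rng = random.Random(4)
        x = "".join(rng.choice("ACGT") for _ in range(400))
        y = list(x)
        for pos in range(0, 400, 20):  # 20 substitutions: d = 0.05
            y[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[y[pos]]
        uniques = [self._uniq(x, 10, "a"), self._uniq("".join(y), 3, "b")]
        assert slp(uniques, SLPParams(0.01)) == uniques

    def test_w_zero_merges_only_identical(self):
        uniques = [self._uniq("AAAA", 3, "a"), self._uniq("AAAT", 2, "b")]
        assert len(slp(uniques, SLPParams(0.0))) == 2

    def test_conserves_reads_and_is_fixpoint(self):
        rng = random.Random(6)
        base = "".join(rng.choice("ACGT") for _ in range(400))
        uniques = [self._uniq(base, 20, "s")]
        for k in range(5):
            v = list(base)
            v[k * 37] = {"A": "C", "C": "G", "G": "T", "T": "A"}[v[k * 37]]
            uniques.append(self._uniq("".join(v), 5 - k, f"v{k}"))
        total = sum(u.abundance for u in uniques)
        once = slp(uniques, SLPParams(0.01))
        assert sum(u.abundance for u in once) == total
        assert len(once) <= len(uniques)
        twice = slp(once, SLPParams(0.01))
        assert [(u.seq, u.abundance) for u in twice] == [(u.seq, u.abundance) for u in once]


class TestSingletons:
    def test_partition(self):
        u = [UniqueSeq("AAAA", 5, list("abcde")), UniqueSeq("CCCC", 1, ["f"])]
        kept, removed = remove_singletons(u)
        assert [x.seq for x in kept] == ["AAAA"]
        assert [x.seq for x in removed] == ["CCCC"]

    def test_all_singletons(self):
        u = [UniqueSeq("AAAA", 1, ["a"])]
        kept, removed = remove_singletons(u)
        assert not kept and len(removed) == 1

    def test_no_singletons_identity(self):
        u = [UniqueSeq("AAAA", 2, ["a", "b"])]
        assert remove_singletons(u) == (u, [])


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            FilterParams(mee_max=-1)
        with pytest.raises(ValueError):
            FilterParams(trim_len=0)
        with pytest.raises(ValueError):
            SLPParams(1.0)
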