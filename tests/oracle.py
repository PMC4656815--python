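"""Independent brute-force oracle for the frameshift-aware glocal DP.

Enumerates every legal transition path by memoised recursion, scoring each
transition from first principles (explicit completion enumeration, no reuse
of the implementation's lookup tables).  Tractable only for tiny instances.
"""
from functools import lru_cache

from Bio.Align import substitution_matrices

from fsdenovo.seqio import translate

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def _s(aa, r):
    a = aa if aa in _B62.alphabet else "X"
    b = r if r in _B62.alphabet else "X"
    return float(_B62[a, b])


def _best_completion_score(partial, r):
    """Max substitution score over non-STOP codon completions of a 1/2-mer.

    A 2-mer takes one wildcard at any of the 3 codon positions; a single
    base takes two wildcards (the base may sit at codon position 0, 1 or 2).
    """
    codons = set()
    if len(partial) == 2:
        for pos in range(3):
            for b in "ACGT":
                codons.add(partial[:pos] + b + partial[pos:])
    else:
        for pos in range(3):
            for b1 in "ACGT":
                for b2 in "ACGT":
                    rest = [b1, b2]
                    parts = rest[:pos] + [partial] + rest[pos:]
                    codons.add("".join(parts[:3]))
    best = None
    for codon in codons:
        aa = translate(codon)
        if aa == "*":
            continue
        sc = _s(aa, r)
        if best is None or sc > best:
            best = sc
    return best if best is not None else float(min(_B62.flatten()))


def brute_force_score(query, ref, fs=-15.0, gap=-11.0, lengths=(1, 2, 4, 5)):
    n, m = len(query), len(ref)

    @lru_cache(maxsize=None)
    def M(i, j):
        if i == 0:
            return 0.0
        if j < 0 or (j == 0 and i > 0):
            return NEG
        best = NEG
        r = ref[j - 1]
        if i >= 3:
            best = max(best, M(i - 3, j - 1) + _s(translate(query[i - 3:i]), r))
            best = max(best, M(i - 3, j) + gap)          # query codon insertion
        if 2 in lengths and i >= 2:
            best = max(best, M(i - 2, j - 1) + fs + _best_completion_score(query[i - 2:i], r))
        if 1 in lengths and i >= 1:
            best = max(best, M(i - 1, j - 1) + fs + _best_completion_score(query[i - 1], r))
        if 4 in lengths and i >= 4:
            inner = max(_s(translate(query[i - 4:i - 1]), r), _s(translate(query[i - 3:i]), r))
            best = max(best, M(i - 4, j - 1) + fs + inner)
        if 5 in lengths and i >= 5:
            inner = max(_s(translate(query[i - 5 + k:i - 2 + k]), r) for k in range(3))
            best = max(best, M(i - 5, j - 1) + fs + inner)
        best = max(best, M(i, j - 1) + gap)              # reference residue skip
        return best

    # up to 2 trailing query nucleotides may dangle unaligned for free
    # (terminal incomplete codon)
    return max(
        M(n - tail, j)
        for tail in (0, 1, 2)
        if n - tail >= 1
        for j in range(1, m + 1)
    )
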