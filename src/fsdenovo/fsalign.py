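"""Frameshift-aware glocal alignment of a nucleotide query to a protein.

The dynamic program aligns every nucleotide of the query (global in the
read) against a contiguous region of the reference protein (local in the
reference: leading and trailing reference overhangs are free).  Each
reference residue is matched by a query "codon" of 3 nucleotides (regular),
of 1 or 2 nucleotides (a deletion slipped the frame; the missing bases are
treated as wildcards and the best non-STOP completion is scored), or of 4
or 5 nucleotides (an insertion; the best in-register 3-mer inside the
window is scored).  Every non-triplet codon pays a single frameshift
penalty regardless of its length.  Reference residues may also be skipped
(query gap) and whole query codons inserted (reference gap), each at a
linear per-residue gap cost.

Recurrence, with ``M(i, j)`` the best score aligning query nucleotides
``1..i`` to reference residues ``1..j``::

    (a) M(i-3, j-1) + S(aa(x[i-2..i]), r_j)          regular codon
    (b) M(i-2, j-1) + P_fs + best2(x[i-1..i], r_j)   2 nt codon
    (c) M(i-1, j-1) + P_fs + best1(x[i], r_j)        1 nt codon
    (d) M(i-4, j-1) + P_fs + best of 2 inner 3-mers  4 nt codon
    (e) M(i-5, j-1) + P_fs + best of 3 inner 3-mers  5 nt codon
    (f) M(i,   j-1) + g                              reference residue skipped
    (g) M(i-3, j)   + g                              query codon inserted

with ``M(0, j) = 0`` for all j, ``M(i, 0) = -inf`` for i > 0, and final
score ``max_j max(M(n, j), M(n-1, j), M(n-2, j))``: up to two trailing
query nucleotides may remain unaligned for free, because a terminal
incomplete codon is an artefact of the fixed trim length (400 nt is 133
codons plus one base), not a frameshift.

The matrix fill is vectorised over the reference axis; the linear gap in
(f) is folded in with a running-maximum scan, which is exact for linear
(non-affine) gap costs.  Traceback re-tests transitions cell by cell with a
fixed priority order, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import translate

__all__ = [
    "AlignParams",
    "FSAlignment",
    "fs_align",
    "best_reference",
    "load_matrix",
]

_NT = {"A": 0, "C": 1, "G": 2, "T": 3}
_NT_INV = "ACGT"

NEG_INF = -1e30


def load_matrix(name_or_path: str) -> "substitution_matrices.Array":
    """Load a scoring matrix by registered name (e.g. BLOSUM62) or from an
    NCBI-format matrix file."""
    p = Path(name_or_path)
    if p.exists():
        return substitution_matrices.read(str(p))
    return substitution_matrices.load(name_or_path)


@dataclass
class AlignParams:
    """Scoring parameters for the frameshift-aware aligner.

    fs_penalty: one penalty per non-triplet codon, whatever its length.
    gap_penalty: linear cost per skipped reference residue or inserted
    query codon.  subst_matrix: amino-acid scoring table including 'X'
    and '*' rows (BLOSUM62 by default).
    """

    fs_penalty: float = -15.0
    gap_penalty: float = -11.0
    matrix_name: str = "BLOSUM62"
    allowed_lengths: frozenset = frozenset({1, 2, 4, 5})
    subst_matrix: Optional["substitution_matrices.Array"] = None

    def __post_init__(self) -> None:
        if self.fs_penalty >= 0:
            raise ValueError("fs_penalty must be negative")
        if self.gap_penalty >= 0:
            raise ValueError("gap_penalty must be negative")
        if not self.allowed_lengths <= {1, 2, 4, 5}:
            raise ValueError("allowed frameshift codon lengths must be within {1,2,4,5}")
        if self.subst_matrix is None:
            self.subst_matrix = load_matrix(self.matrix_name)
        self._tables = _ScoreTables(self.subst_matrix)


class _ScoreTables:
    """Static lookup tables derived from one substitution matrix."""

    def __init__(self, matrix) -> None:
        alphabet = str(matrix.alphabet)
        self.alphabet = alphabet
        self.index = {aa: k for k, aa in enumerate(alphabet)}
        self.x_idx = self.index["X"]
        self.S = np.asarray(matrix, dtype=np.float64)
        self.min_score = float(self.S.min())
        A = len(alphabet)

        # codon (base-4 index) -> matrix row index of its residue
        self.codon_aa = np.empty(64, dtype=np.intp)
        self.codons = []
        for idx in range(64):
            codon = _NT_INV[idx >> 4] + _NT_INV[(idx >> 2) & 3] + _NT_INV[idx & 3]
            self.codons.append(codon)
            aa = translate(codon)
            self.codon_aa[idx] = self.index.get(aa, self.x_idx)

        # best-completion score rows for 2-mers (wildcard at any of the 3
        # codon positions) and single bases (two wildcards).  STOP
        # completions are excluded; if every completion is a STOP the matrix
        # minimum is used.
        self.best2 = np.full((17, A), self.min_score)
        self.comp2: List[List[str]] = []
        for t in range(16):
            two = _NT_INV[t >> 2] + _NT_INV[t & 3]
            comps = sorted(
                {c for c in _completions(two) if translate(c) != "*"}
            )
            self.comp2.append(comps)
            rows = [self.index.get(translate(c), self.x_idx) for c in comps]
            if rows:
                self.best2[t] = self.S[rows].max(axis=0)
        self.best2[16] = self.S[self.x_idx]  # 2-mer containing N
        self.comp2.append([])

        self.best1 = np.full((5, A), self.min_score)
        self.comp1: List[List[str]] = []
        for b in range(4):
            base = _NT_INV[b]
            comps = sorted(
                {c for c in _completions1(base) if translate(c) != "*"}
            )
            self.comp1.append(comps)
            rows = [self.index.get(translate(c), self.x_idx) for c in comps]
            if rows:
                self.best1[b] = self.S[rows].max(axis=0)
        self.best1[4] = self.S[self.x_idx]
        self.comp1.append([])


def _completions(two: str) -> List[str]:
    """All codons obtained by inserting one base at any position of a 2-mer."""
    out = []
    for pos in range(3):
        for b in _NT_INV:
            out.append(two[:pos] + b + two[pos:])
    return out


def _completions1(base: str) -> List[str]:
    """All codons containing the base at one position, wildcards elsewhere."""
    out = []
    for pos in range(3):
        for b1 in _NT_INV:
            for b2 in _NT_INV:
                pad = [b1, b2]
                codon = pad[:pos] + [base] + pad[pos:]
                out.append("".join(codon[:3]))
    return out


@dataclass
class FSAlignment:
    """Result of a frameshift-aware alignment.

    events: (query offset, codon length consumed) for every non-triplet
    codon.  columns: (codon-or-gap, residue-or-gap) pairs in reference
    order.  aligned_ref_span is 0-based half-open in reference residues.
    identity counts columns whose corrected residue equals the reference
    residue over all columns spanned by the query, gap columns included.
    """

    score: float
    identity: float
    events: List[Tuple[int, int]]
    aligned_ref_span: Tuple[int, int]
    corrected_nt: str
    corrected_aa: str
    columns: List[Tuple[str, str]]


def _encode(query: str) -> np.ndarray:
    enc = np.full(len(query), 4, dtype=np.intp)
    for k, ch in enumerate(query):
        enc[k] = _NT.get(ch, 4)
    return enc


def fs_align(query: str, ref: str, params: Optional[AlignParams] = None) -> FSAlignment:
    """Align nucleotide ``query`` (global) to protein ``ref`` (local)."""
    if params is None:
        params = AlignParams()
    query = query.upper()
    ref = ref.upper()
    if len(query) < 3:
        raise ValueError("query must be at least 3 nt")
    if not ref:
        raise ValueError("reference protein must be nonempty")
    if "*" in ref:
        raise ValueError("reference protein contains a STOP symbol '*'")

    T = params._tables
    fs = params.fs_penalty
    g = params.gap_penalty
    allowed = params.allowed_lengths
    n, m = len(query), len(ref)

    enc = _encode(query)
    ref_idx = np.array([T.index.get(aa, T.x_idx) for aa in ref], dtype=np.intp)

    # per-position score rows (index i = last nucleotide, 1-based),
    # built by fancy indexing: aa row per codon ending at i, then per-ref
    # columns
    codon_row = np.full((n + 1, m), NEG_INF)
    if n >= 3:
        b0, b1, b2 = enc[:-2], enc[1:-1], enc[2:]
        ambig = (b0 > 3) | (b1 > 3) | (b2 > 3)
        cidx = np.where(ambig, 0, (b0 << 4) | (b1 << 2) | b2)
        aa_rows = np.where(ambig, T.x_idx, T.codon_aa[cidx])
        codon_row[3:] = T.S[aa_rows][:, ref_idx]

    if 2 in allowed:
        two_row = np.empty((n + 1, m))
        t0, t1 = enc[:-1], enc[1:]
        tidx = np.where((t0 > 3) | (t1 > 3), 16, (t0 << 2) | t1)
        two_row[2:] = T.best2[tidx][:, ref_idx]
    if 1 in allowed:
        one_row = np.empty((n + 1, m))
        one_row[1:] = T.best1[np.minimum(enc, 4)][:, ref_idx]

    jarr = np.arange(1, m + 1, dtype=np.float64)
    M = np.full((n + 1, m + 1), NEG_INF)
    M[0, :] = 0.0

    for i in range(1, n + 1):
        V = np.full(m, NEG_INF)
        if i >= 3:
            np.maximum(V, M[i - 3, :m] + codon_row[i], out=V)
            np.maximum(V, M[i - 3, 1:] + g, out=V)  # (g) query codon insertion
        if 2 in allowed and i >= 2:
            np.maximum(V, M[i - 2, :m] + fs + two_row[i], out=V)
        if 1 in allowed:
            np.maximum(V, M[i - 1, :m] + fs + one_row[i], out=V)
        if 4 in allowed and i >= 4:
            np.maximum(V, M[i - 4, :m] + fs + np.maximum(codon_row[i - 1], codon_row[i]), out=V)
        if 5 in allowed and i >= 5:
            s5 = np.maximum(np.maximum(codon_row[i - 2], codon_row[i - 1]), codon_row[i])
            np.maximum(V, M[i - 5, :m] + fs + s5, out=V)
        # (f) reference-residue skip: linear gap folded in by a running max
        M[i, 1:] = np.maximum.accumulate(V - g * jarr) + g * jarr

    # free terminal incomplete codon: up to 2 trailing query nt may dangle;
    # prefer consuming more query, then the smaller reference end on ties
    i_end, j_end, score = n, 1, NEG_INF
    for i_cand in (n, n - 1, n - 2):
        if i_cand < 1:
            break
        j_cand = int(np.argmax(M[i_cand, 1:])) + 1
        if M[i_cand, j_cand] > score:
            i_end, j_end, score = i_cand, j_cand, float(M[i_cand, j_cand])
    columns, events, j_start = _traceback(
        query, ref, enc, M, codon_row, params, i_end, j_end
    )

    corrected_nt = "".join(c for c, _ in columns if c != "-")
    corrected_aa = translate(corrected_nt, 0)
    matches = 0
    aa_iter = iter(corrected_aa)
    for codon, res in columns:
        if codon == "-":
            continue
        if next(aa_iter) == res:
            matches += 1
    identity = matches / len(columns) if columns else 0.0

    return FSAlignment(
        score=score,
        identity=identity,
        events=events,
        aligned_ref_span=(j_start, j_end),
        corrected_nt=corrected_nt,
        corrected_aa=corrected_aa,
        columns=columns,
    )


def _best_completion(comps: Sequence[str], tables: _ScoreTables, r_idx: int) -> str:
    """Lexicographically smallest completion codon with the maximal score."""
    if not comps:
        return ""
    best, best_score = None, -np.inf
    for c in comps:  # comps sorted lexicographically
        s = tables.S[tables.index.get(translate(c), tables.x_idx), r_idx]
        if s > best_score:
            best, best_score = c, s
    return best


def _traceback(query, ref, enc, M, codon_row, params, i_end, j_end):
    T = params._tables
    fs, g = params.fs_penalty, params.gap_penalty
    allowed = params.allowed_lengths
    atol = 1e-9
    cols_rev: List[Tuple[str, str]] = []
    events_rev: List[Tuple[int, int]] = []
    i, j = i_end, j_end
    while i > 0:
        here = M[i, j]
        r_idx = T.index.get(ref[j - 1], T.x_idx) if j >= 1 else None
        # priority: (a) > (f) > (g) > (b) > (d) > (c) > (e)
        if i >= 3 and j >= 1 and abs(M[i - 3, j - 1] + codon_row[i, j - 1] - here) <= atol:
            codon = query[i - 3 : i]
            cols_rev.append((codon, ref[j - 1]))
            i, j = i - 3, j - 1
            continue
        if j >= 1 and abs(M[i, j - 1] + g - here) <= atol:
            cols_rev.append(("-", ref[j - 1]))
            j -= 1
            continue
        if i >= 3 and abs(M[i - 3, j] + g - here) <= atol:
            cols_rev.append((query[i - 3 : i], "-"))
            i -= 3
            continue
        if 2 in allowed and i >= 2 and j >= 1:
            b = enc[i - 2 : i]
            t = 16 if (b == 4).any() else int((b[0] << 2) | b[1])
            if abs(M[i - 2, j - 1] + fs + T.best2[t, r_idx] - here) <= atol:
                comps = T.comp2[t] or sorted(_completions(query[i - 2 : i]))
                codon = _best_completion(comps, T, r_idx) or query[i - 2 : i] + "A"
                cols_rev.append((codon, ref[j - 1]))
                events_rev.append((i - 2, 2))
                i, j = i - 2, j - 1
                continue
        if 4 in allowed and i >= 4 and j >= 1:
            s4 = max(codon_row[i - 1, j - 1], codon_row[i, j - 1])
            if abs(M[i - 4, j - 1] + fs + s4 - here) <= atol:
                # leftmost maximal in-register 3-mer of the 4-nt window
                codon = query[i - 4 : i - 1] if codon_row[i - 1, j - 1] >= codon_row[i, j - 1] else query[i - 3 : i]
                cols_rev.append((codon, ref[j - 1]))
                events_rev.append((i - 4, 4))
                i, j = i - 4, j - 1
                continue
        if 1 in allowed and i >= 1 and j >= 1:
            t = int(min(enc[i - 1], 4))
            if abs(M[i - 1, j - 1] + fs + T.best1[t, r_idx] - here) <= atol:
                comps = T.comp1[t] or sorted(_completions1(query[i - 1]))
                codon = _best_completion(comps, T, r_idx) or query[i - 1] + "AA"
                cols_rev.append((codon, ref[j - 1]))
                events_rev.append((i - 1, 1))
                i, j = i - 1, j - 1
                continue
        if 5 in allowed and i >= 5 and j >= 1:
            vals = [codon_row[i - 2, j - 1], codon_row[i - 1, j - 1], codon_row[i, j - 1]]
            if abs(M[i - 5, j - 1] + fs + max(vals) - here) <= atol:
                k = int(np.argmax(vals))  # leftmost on ties via argmax order
                codon = query[i - 5 + k : i - 2 + k]
                cols_rev.append((codon, ref[j - 1]))
                events_rev.append((i - 5, 5))
                i, j = i - 5, j - 1
                continue
        raise RuntimeError(
            f"traceback stuck at ({i}, {j}); no transition reproduces the score"
        )
    cols_rev.reverse()
    events_rev.reverse()
    return cols_rev, events_rev, j


def best_reference(
    query: str,
    refs: Sequence[Tuple[str, str]],
    params: Optional[AlignParams] = None,
) -> Tuple[str, FSAlignment]:
    """Align ``query`` to every (id, protein) in ``refs`` and return the
    highest-scoring one; ties go to the first in input order."""
    if not refs:
        raise ValueError("refs must be nonempty")
    if params is None:
        params = AlignParams()
    best_id, best_aln = None, None
    for rid, rseq in refs:
        aln = fs_align(query, rseq, params)
        if best_aln is None or aln.score > best_aln.score:
            best_id, best_aln = rid, aln
    return best_id, best_aln
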