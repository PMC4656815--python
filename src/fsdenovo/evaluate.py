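"""Frameshift detection against known references and treatment metrics.

On a mock community the true proteins are known, so frameshifts can be
detected directly: a sequence has a frameshift iff its best frameshift-
aware alignment against the known reference set contains at least one
non-triplet codon event.  The same alignment yields the per-read amino-acid
accuracy: identical residues to the assigned reference divided by the
expected full-length residue count of the amplicon (133 for a 400-nt
primer-anchored read), capped at 1.

Treatment summaries collect the read-processing comparison metrics: total
reads, unique sequences, singletons, and the percentage of frameshifted
sequences with and without singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .fsalign import AlignParams, best_reference
from .seqio import UniqueSeq

__all__ = [
    "EvalParams",
    "TreatmentSummary",
    "detect_fs",
    "accuracy",
    "treatment_summary",
    "summaries_table",
]


@dataclass
class EvalParams:
    """Expected full amplicon length in residues and the known protein set."""

    known_refs: List[Tuple[str, str]]
    expected_full_length: int = 133
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if self.expected_full_length < 1:
            raise ValueError("expected_full_length must be >= 1")
        if not self.known_refs:
            raise ValueError("known reference set must be nonempty")


@dataclass
class TreatmentSummary:
    label: str
    total_reads: int
    unique_count: int
    singleton_count: int
    fs_pct_with_singletons: float
    fs_pct_without_singletons: Optional[float]
    fs_pct_with_singletons_uniques: float
    fs_pct_without_singletons_uniques: Optional[float]
    accuracy: Optional[float] = None


def detect_fs(
    seqs: Sequence[Tuple[str, str]], params: EvalParams
) -> Dict[str, Tuple[bool, int]]:
    """Per-sequence frameshift call against the known references.

    ``seqs`` is (id, nucleotide sequence).  Returns id -> (has_fs, events),
    where has_fs is True iff the best-scoring alignment contains >= 1
    frameshift event.  Deterministic: ties in reference score go to the
    first reference in input order.
    """
    out: Dict[str, Tuple[bool, int]] = {}
    for sid, seq in seqs:
        _, aln = best_reference(seq, params.known_refs, params.align)
        out[sid] = (len(aln.events) > 0, len(aln.events))
    return out


def accuracy(
    corrected: Sequence[Tuple[str, int]], params: EvalParams
) -> float:
    """Abundance-weighted mean amino-acid accuracy of corrected proteins.

    ``corrected`` is (protein sequence, abundance).  Each protein is
    assigned its best-scoring known reference; per-read accuracy is the
    number of alignment columns with identical residues divided by the
    expected full length, capped at 1.
    """
    if not corrected:
        raise ValueError("no sequences to score")
    L = params.expected_full_length
    aligner = _ProteinIdentityScorer(params)
    num = 0.0
    den = 0
    for aa, ab in corrected:
        ident = aligner.identical_residues(aa)
        num += ab * min(1.0, ident / L)
        den += ab
    return num / den


class _ProteinIdentityScorer:
    """Counts identical residues between a protein and its best reference
    using a standard global protein alignment with free end gaps."""

    def __init__(self, params: EvalParams) -> None:
        from Bio.Align import PairwiseAligner, substitution_matrices

        self._aligner = PairwiseAligner(
            mode="global",
            substitution_matrix=params.align.subst_matrix,
            open_gap_score=params.align.gap_penalty,
            extend_gap_score=params.align.gap_penalty,
            end_gap_score=0.0,
        )
        self._refs = params.known_refs

    def identical_residues(self, aa: str) -> int:
        clean = aa.replace("*", "X")
        best = None
        for _, ref in self._refs:
            aln = self._aligner.align(clean, ref)[0]
            if best is None or aln.score > best.score:
                best = aln
        return int(best.counts().identities)


def treatment_summary(
    label: str,
    uniques: Sequence[UniqueSeq],
    fs_flags: Dict[str, bool],
    acc: Optional[float] = None,
) -> TreatmentSummary:
    """Figure-style comparison metrics for one processing treatment.

    ``fs_flags`` maps the representative sequence (by nucleotide string) to
    its frameshift call.  The without-singletons percentages restrict both
    numerator and denominator to abundance >= 2 uniques; if every unique is
    a singleton they are reported as missing, not zero.
    """
    total = sum(u.abundance for u in uniques)
    n_uniq = len(uniques)
    singles = [u for u in uniques if u.abundance == 1]
    non_singles = [u for u in uniques if u.abundance >= 2]

    def pct(subset: Sequence[UniqueSeq], by_reads: bool) -> Optional[float]:
        den = sum(u.abundance for u in subset) if by_reads else len(subset)
        if den == 0:
            return None
        if by_reads:
            num = sum(u.abundance for u in subset if fs_flags[u.seq])
        else:
            num = sum(1 for u in subset if fs_flags[u.seq])
        return 100.0 * num / den

    return TreatmentSummary(
        label=label,
        total_reads=total,
        unique_count=n_uniq,
        singleton_count=len(singles),
        fs_pct_with_singletons=pct(uniques, True) if uniques else 0.0,
        fs_pct_without_singletons=pct(non_singles, True),
        fs_pct_with_singletons_uniques=pct(uniques, False) if uniques else 0.0,
        fs_pct_without_singletons_uniques=pct(non_singles, False),
        accuracy=acc,
    )


def summaries_table(summaries: Sequence[TreatmentSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
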