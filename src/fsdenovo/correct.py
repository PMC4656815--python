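"""Frameshift correction of dereplicated amplicon sequences.

Two modes share the same aligner and acceptance rule (identity >= t_id and
corrected protein length >= L_min):

* reference-based — every unique sequence is aligned against an external
  protein reference set and corrected against its best-scoring hit.

* de novo — references are bootstrapped from the data itself, on the
  premise that errors derive from true sequences during amplification and
  sequencing, so abundant sequences are more likely correct.  The most
  abundant unprocessed sequence whose translation is STOP-free is promoted
  to reference; all unprocessed sequences above the cut-offs are corrected
  against it; the loop repeats on whatever remains.  Candidates rejected
  for an in-frame STOP stay eligible for correction by later references
  and are discarded only if never corrected.

A reference processes itself: it is counted with status ``reference``,
excluded from the corrected-% numerator but included in the denominator.
Corrected sequences are never re-used as references within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .fsalign import AlignParams, FSAlignment, best_reference, fs_align
from .seqio import UniqueSeq, translate

__all__ = [
    "DenovoParams",
    "CorrectionOutcome",
    "DenovoResult",
    "correct_with_refs",
    "denovo",
    "correction_report",
    "auto_frame",
]

STATUS_REFERENCE = "reference"
STATUS_CORRECTED = "corrected"
STATUS_DISCARDED = "discarded"


@dataclass
class DenovoParams:
    """Correction cut-offs: identity_min and length_min follow the de novo
    defaults (0.4 and 100 residues); frame is the shared reading frame of
    the primer-anchored amplicon."""

    identity_min: float = 0.4
    length_min: int = 100
    frame: int = 0
    align: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not (0 < self.identity_min <= 1):
            raise ValueError("identity_min must be in (0, 1]")
        if self.length_min < 1:
            raise ValueError("length_min must be >= 1")
        if self.frame not in (0, 1, 2):
            raise ValueError("frame must be 0, 1 or 2")


@dataclass
class CorrectionOutcome:
    seq_id: str
    status: str
    abundance: int
    reference_id: Optional[str] = None
    events: int = 0
    identity: float = 0.0
    corrected_nt: str = ""
    corrected_aa: str = ""


@dataclass
class DenovoResult:
    reference_ids: List[str]
    outcomes: List[CorrectionOutcome]
    rounds: int


def _accept(aln: FSAlignment, p: DenovoParams) -> bool:
    return aln.identity >= p.identity_min and len(aln.corrected_aa) >= p.length_min


def correct_with_refs(
    uniques: Sequence[UniqueSeq],
    refs: Sequence[Tuple[str, str]],
    p: Optional[DenovoParams] = None,
) -> List[CorrectionOutcome]:
    """Reference-based mode: align each unique to its best external
    reference protein; accept iff identity and corrected length clear the
    cut-offs, else discard."""
    if not refs:
        raise ValueError("reference set must be nonempty")
    if p is None:
        p = DenovoParams()
    outcomes: List[CorrectionOutcome] = []
    for u in uniques:
        rid, aln = best_reference(u.seq, refs, p.align)
        if _accept(aln, p):
            outcomes.append(
                CorrectionOutcome(
                    u.id, STATUS_CORRECTED, u.abundance, rid,
                    len(aln.events), aln.identity, aln.corrected_nt, aln.corrected_aa,
                )
            )
        else:
            outcomes.append(
                CorrectionOutcome(u.id, STATUS_DISCARDED, u.abundance,
                                  None, len(aln.events), aln.identity)
            )
    return outcomes


def denovo(uniques: Sequence[UniqueSeq], p: Optional[DenovoParams] = None) -> DenovoResult:
    """De novo mode: iteratively promote the most abundant STOP-free
    unprocessed sequence to reference and correct the rest against it.

    ``uniques`` must be sorted by abundance descending (ties pre-broken by
    dereplication), which makes the run fully deterministic.
    """
    if not uniques:
        raise ValueError("de novo correction needs at least one sequence")
    if p is None:
        p = DenovoParams()

    n = len(uniques)
    processed: List[Optional[CorrectionOutcome]] = [None] * n
    reference_ids: List[str] = []
    rounds = 0
    while True:
        ref_pos = None
        for k in range(n):
            if processed[k] is None and "*" not in translate(uniques[k].seq, p.frame):
                ref_pos = k
                break
        if ref_pos is None:
            for k in range(n):
                if processed[k] is None:
                    processed[k] = CorrectionOutcome(
                        uniques[k].id, STATUS_DISCARDED, uniques[k].abundance
                    )
            break
        rounds += 1
        ref_u = uniques[ref_pos]
        ref_aa = translate(ref_u.seq, p.frame)
        reference_ids.append(ref_u.id)
        processed[ref_pos] = CorrectionOutcome(
            ref_u.id, STATUS_REFERENCE, ref_u.abundance, ref_u.id,
            0, 1.0, ref_u.seq[p.frame : p.frame + 3 * len(ref_aa)], ref_aa,
        )
        for k in range(n):
            if processed[k] is not None:
                continue
            aln = fs_align(uniques[k].seq, ref_aa, p.align)
            if _accept(aln, p):
                processed[k] = CorrectionOutcome(
                    uniques[k].id, STATUS_CORRECTED, uniques[k].abundance, ref_u.id,
                    len(aln.events), aln.identity, aln.corrected_nt, aln.corrected_aa,
                )
        if all(o is not None for o in processed):
            break

    outcomes = [o for o in processed if o is not None]
    assert len(outcomes) == n
    return DenovoResult(reference_ids, outcomes, rounds)


def auto_frame(uniques: Sequence[UniqueSeq], top: int = 20) -> int:
    """Pick the reading frame minimising in-frame STOPs over the ``top``
    most abundant uniques (amplicons share one frame; this recovers it)."""
    counts = [0, 0, 0]
    for u in uniques[:top]:
        for f in range(3):
            counts[f] += translate(u.seq, f).count("*")
    return min(range(3), key=lambda f: counts[f])


def correction_report(outcomes: Sequence[CorrectionOutcome]) -> pd.DataFrame:
    """Summary of a correction run, abundance-weighted and by uniques.

    One row with: totals, % corrected with >= 1 frameshift event, %
    discarded (both read-weighted and unique-weighted), and per-reference
    usage is available via the outcome list itself.
    """
    if not outcomes:
        raise ValueError("no outcomes to report")
    total_reads = sum(o.abundance for o in outcomes)
    total_uniques = len(outcomes)
    corr_ev_reads = sum(o.abundance for o in outcomes
                        if o.status == STATUS_CORRECTED and o.events > 0)
    disc_reads = sum(o.abundance for o in outcomes if o.status == STATUS_DISCARDED)
    corr_ev_uniq = sum(1 for o in outcomes
                       if o.status == STATUS_CORRECTED and o.events > 0)
    disc_uniq = sum(1 for o in outcomes if o.status == STATUS_DISCARDED)
    n_refs = sum(1 for o in outcomes if o.status == STATUS_REFERENCE)
    return pd.DataFrame(
        [
            {
                "total_reads": total_reads,
                "total_uniques": total_uniques,
                "n_references": n_refs,
                "corrected_with_fs_pct_reads": 100.0 * corr_ev_reads / total_reads,
                "discarded_pct_reads": 100.0 * disc_reads / total_reads,
                "corrected_with_fs_pct_uniques": 100.0 * corr_ev_uniq / total_uniques,
                "discarded_pct_uniques": 100.0 * disc_uniq / total_uniques,
            }
        ]
    )
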