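"""Read-processing workflow for primer-anchored pyrosequencing amplicons.

Stages, in the order the pipeline applies them:

1. demultiplex — assign reads to samples by exact barcode match followed by
   IUPAC-degenerate forward-primer match; strip the matched prefix.
2. trim_to_length — truncate reads to a fixed amplicon length, discarding
   shorter ones, so that downstream dereplication compares like with like.
3. mee_filter — maximum-expected-error filtering: a read is kept iff
   E = sum_i 10^(-Q_i/10) is at most the chosen ceiling.
4. reextract_identical — discarded reads whose sequence is string-identical
   to a kept read are rescued, so abundance counts are not deflated by
   quality strings alone.
5. dereplicate — collapse identical reads to unique sequences with
   abundances.
6. slp — abundance-seeded single-linkage pre-clustering: each unique, in
   descending abundance order, absorbs all less-abundant unmerged uniques
   within distance w of it.
7. remove_singletons — drop uniques observed exactly once.

Every stage partitions its input: kept + removed == in, always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence, Tuple

import edlib
from Bio.Align import PairwiseAligner

from .seqio import Read, UniqueSeq, iupac_match

__all__ = [
    "SampleSheet",
    "FilterParams",
    "SLPParams",
    "demultiplex",
    "trim_to_length",
    "expected_errors",
    "mee_filter",
    "reextract_identical",
    "dereplicate",
    "pairwise_distance",
    "slp",
    "remove_singletons",
    "drop_ids",
]

MEE_SWEEP = (0.5, 1.0, 1.5, 2.0)


@dataclass
class SampleSheet:
    """sample name -> (barcode, IUPAC forward primer).

    Barcodes must be unique and barcode+primer prefixes unambiguous: no
    sample's literal barcode may IUPAC-match the start of another sample's
    barcode+primer region (a read prefix could then belong to both).
    """

    samples: Dict[str, Tuple[str, str]]

    def __post_init__(self) -> None:
        barcodes = [bc for bc, _ in self.samples.values()]
        if len(barcodes) != len(set(barcodes)):
            raise ValueError("barcodes are not unique")
        items = list(self.samples.items())
        for i, (ni, (bi, _)) in enumerate(items):
            for nj, (bj, _) in items[i + 1 :]:
                if bi.startswith(bj) or bj.startswith(bi):
                    raise ValueError(
                        f"barcodes of {ni!r} and {nj!r} are prefix-ambiguous"
                    )

    @classmethod
    def from_tsv(cls, path: str) -> "SampleSheet":
        samples: Dict[str, Tuple[str, str]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"sample sheet line {lineno}: expected 3 columns")
                name, bc, primer = parts
                samples[name] = (bc.upper(), primer.upper())
        return cls(samples)


@dataclass
class FilterParams:
    """MEE ceiling and fixed trim length; defaults follow the standard sweep (0.5-2.0 by 0.5, trim 400)."""

    mee_max: float = 1.0
    trim_len: int = 400

    def __post_init__(self) -> None:
        if self.mee_max < 0:
            raise ValueError("mee_max must be >= 0")
        if self.trim_len <= 0:
            raise ValueError("trim_len must be > 0")


@dataclass
class SLPParams:
    w: float = 0.01

    def __post_init__(self) -> None:
        if not (0 <= self.w < 1):
            raise ValueError("w must be in [0, 1)")


# --- demultiplex ---------------------------------------------------------


def demultiplex(
    reads: Sequence[Read], sheet: SampleSheet
) -> Tuple[Dict[str, List[Read]], List[Tuple[Read, str]]]:
    """Assign reads to samples and strip barcode+primer.

    A read is assigned iff its prefix exactly matches a sample's barcode and
    the following bases IUPAC-match that sample's primer.  Barcodes are
    matched literally; primers degenerately (printed primers contain
    degeneracy codes, so a literal primer match is impossible).  Qualities
    are trimmed in lockstep.  Unassigned reads are returned with a reason.
    """
    assigned: Dict[str, List[Read]] = {name: [] for name in sheet.samples}
    unassigned: List[Tuple[Read, str]] = []
    for read in reads:
        hit = None
        reason = "no barcode match"
        for name, (bc, primer) in sheet.samples.items():
            if not read.seq.startswith(bc):
                continue
            window = read.seq[len(bc) : len(bc) + len(primer)]
            if len(window) < len(primer):
                reason = "read shorter than barcode+primer"
                continue
            if iupac_match(primer, window):
                hit = (name, len(bc) + len(primer))
                break
            reason = "primer mismatch after barcode"
        if hit is None:
            unassigned.append((read, reason))
        else:
            name, cut = hit
            assigned[name].append(
                Read(read.id, read.seq[cut:], read.qual[cut:] if read.qual else [])
            )
    return assigned, unassigned


def trim_to_length(reads: Sequence[Read], trim_len: int) -> Tuple[List[Read], List[Read]]:
    """Truncate reads to ``trim_len``; discard reads shorter than that."""
    kept: List[Read] = []
    discarded: List[Read] = []
    for r in reads:
        if len(r.seq) >= trim_len:
            kept.append(Read(r.id, r.seq[:trim_len], r.qual[:trim_len] if r.qual else []))
        else:
            discarded.append(r)
    return kept, discarded


# --- MEE filtering -------------------------------------------------------


def expected_errors(qual: Sequence[int]) -> float:
    """E = sum_i 10^(-Q_i/10): the expected number of errors in the read."""
    return float(sum(10.0 ** (-q / 10.0) for q in qual))


def mee_filter(reads: Sequence[Read], mee_max: float) -> Tuple[List[Read], List[Read]]:
    """Keep reads with expected errors E <= ``mee_max``.

    Reads without qualities cannot be scored; raise so the caller either
    supplies FASTQ or skips this stage explicitly.
    """
    kept: List[Read] = []
    discarded: List[Read] = []
    for r in reads:
        if not r.qual:
            raise ValueError(
                f"read {r.id!r} has no qualities; MEE filtering needs FASTQ "
                "input — skip this stage for FASTA data"
            )
        (kept if expected_errors(r.qual) <= mee_max else discarded).append(r)
    return kept, discarded


def reextract_identical(
    kept: Sequence[Read], discarded: Sequence[Read]
) -> Tuple[List[Read], List[Read], List[Read]]:
    """Rescue discarded reads that are sequence-identical to a kept read.

    Returns (all kept reads incl. rescued, rescued subset, still discarded).
    Rescue happens before dereplication, so the abundance of the identical
    sequence simply grows by the rescued copies; no new sequences appear.
    """
    kept_seqs = {r.seq for r in kept}
    rescued: List[Read] = []
    still: List[Read] = []
    for r in discarded:
        (rescued if r.seq in kept_seqs else still).append(r)
    return list(kept) + rescued, rescued, still


# --- dereplication -------------------------------------------------------


def dereplicate(reads: Sequence[Read]) -> List[UniqueSeq]:
    """Collapse identical reads into uniques, sorted by abundance descending.

    Ties at equal abundance break lexicographically by sequence, then by
    first-seen read id — determinism matters because the de novo mode
    selects references by this ordering.
    """
    groups: Dict[str, List[str]] = {}
    for r in reads:
        groups.setdefault(r.seq, []).append(r.id)
    uniques = [UniqueSeq(seq, len(ids), ids) for seq, ids in groups.items()]
    uniques.sort(key=lambda u: (-u.abundance, u.seq, u.members[0]))
    return uniques


# --- pairwise distance & SLP --------------------------------------------

_NT_ALIGNER = PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=-1,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def pairwise_distance(a: str, b: str) -> float:
    """Global-alignment distance d = 1 - matches / aligned columns.

    Scoring: match +1, mismatch -1, linear gap -2.  Every gap column counts
    as a non-match.  Symmetric; d(a, a) == 0.
    """
    if not a or not b:
        raise ValueError("pairwise_distance requires nonempty sequences")
    aln = _NT_ALIGNER.align(a, b)[0]
    counts = aln.counts()
    columns = aln.length
    return 1.0 - counts.identities / columns


def _edit_distance_bound(w: float, length: int) -> int:
    # d <= w forces edit distance <= 2wL/(1-2w): each edit op removes at
    # most... conservatively, a substitution costs 1 non-match column and an
    # indel costs 1 non-match column while adding <= 1 column, so
    # nonmatch >= ed/2 and columns <= L + ed; d >= (ed/2)/(L+ed).
    if w >= 0.5:
        return length * 2
    return int(2 * w * length / (1 - 2 * w)) + 1


def slp(
    uniques: Sequence[UniqueSeq],
    params: SLPParams,
    distance_fn: Callable[[str, str], float] = pairwise_distance,
) -> List[UniqueSeq]:
    """Abundance-seeded single-linkage pre-clustering.

    One greedy pass in descending abundance order: each not-yet-merged
    unique becomes a seed and absorbs every remaining less-abundant
    unmerged unique at distance <= w.  The representative sequence is the
    seed's; abundances and member lists are summed.  Total read count is
    conserved and the number of uniques never increases.

    A conservative edit-distance prefilter (via edlib) skips pairs that
    provably exceed w under the declared alignment dialect; the exact
    distance for candidate pairs always comes from ``distance_fn``.
    """
    w = params.w
    n = len(uniques)
    merged = [False] * n
    out: List[UniqueSeq] = []
    use_prefilter = distance_fn is pairwise_distance and n > 0
    for i in range(n):
        if merged[i]:
            continue
        seed = uniques[i]
        merged[i] = True
        members = list(seed.members)
        abundance = seed.abundance
        bound = _edit_distance_bound(w, max(len(seed.seq), 1))
        for j in range(i + 1, n):
            if merged[j]:
                continue
            cand = uniques[j]
            if use_prefilter:
                res = edlib.align(seed.seq, cand.seq, mode="NW", task="distance", k=bound)
                if res["editDistance"] == -1:
                    continue
            if distance_fn(seed.seq, cand.seq) <= w:
                merged[j] = True
                abundance += cand.abundance
                members.extend(cand.members)
        out.append(UniqueSeq(seed.seq, abundance, members))
    out.sort(key=lambda u: (-u.abundance, u.seq, u.members[0]))
    return out


def remove_singletons(
    uniques: Sequence[UniqueSeq],
) -> Tuple[List[UniqueSeq], List[UniqueSeq]]:
    """Partition uniques into abundance >= 2 (kept) and singletons (removed)."""
    kept = [u for u in uniques if u.abundance >= 2]
    removed = [u for u in uniques if u.abundance == 1]
    return kept, removed


def drop_ids(
    uniques: Sequence[UniqueSeq], ids: Sequence[str]
) -> Tuple[List[UniqueSeq], List[UniqueSeq]]:
    """Pass-through hook for an external chimera screen: drop uniques whose
    representative id is listed."""
    drop = set(ids)
    kept = [u for u in uniques if u.id not in drop]
    removed = [u for u in uniques if u.id in drop]
    return kept, removed
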