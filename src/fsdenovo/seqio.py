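"""Sequence I/O and small alphabet utilities.

Readers/writers for the formats the pipeline touches — Sanger FASTQ
(Phred+33), FASTA, and mothur-style names files — plus translation under
the standard genetic code and IUPAC-degenerate primer matching.

Quality encoding is fixed to Phred+33.  Phred+64 files are refused with an
explicit error rather than converted: qualities decoded from a Phred+64
file would all land at Q >= 31 with characters outside the Sanger range,
which we detect heuristically (any character below '!' is impossible; a
file whose every quality character is above 'J' is almost certainly +64).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "Read",
    "UniqueSeq",
    "read_fastq",
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "read_names",
    "write_names",
    "translate",
    "iupac_match",
    "IUPAC_NT",
]


@dataclass
class Read:
    """A single sequencing read: id, nucleotides, per-base Phred qualities.

    ``qual`` is empty for FASTA-derived records; otherwise it has one
    integer per base.
    """

    id: str
    seq: str
    qual: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.qual and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class UniqueSeq:
    """A dereplicated sequence with its abundance and member read ids."""

    seq: str
    abundance: int
    members: List[str]

    def __post_init__(self) -> None:
        if self.abundance != len(self.members):
            raise ValueError(
                f"abundance {self.abundance} != number of members "
                f"{len(self.members)}"
            )
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")

    @property
    def id(self) -> str:
        """Representative id: the first member read id."""
        return self.members[0]


# --- FASTQ ---------------------------------------------------------------

_PHRED_OFFSET = 33


def read_fastq(path: str | Path) -> List[Read]:
    """Parse a Sanger (Phred+33) FASTQ file into a list of :class:`Read`.

    Record order is preserved.  Malformed records (missing ``+`` separator,
    seq/qual length mismatch, truncated file) raise ``ValueError`` naming
    the offending line.  Files that look Phred+64-encoded are refused.
    """
    reads: List[Read] = []
    seen: set[str] = set()
    min_char = 126
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ValueError(f"line {lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not seq:
                raise ValueError(f"line {lineno}: truncated FASTQ record")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"line {lineno - 1}: expected '+' separator, got {plus[:20]!r}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"line {lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            rid = header[1:].split()[0] if len(header) > 1 else ""
            if rid in seen:
                raise ValueError(f"line {lineno - 3}: duplicate read id {rid!r}")
            seen.add(rid)
            if qual:
                min_char = min(min_char, min(ord(c) for c in qual))
            quals = [ord(c) - _PHRED_OFFSET for c in qual]
            if any(q < 0 for q in quals):
                raise ValueError(f"line {lineno}: quality character below '!'; not Phred+33")
            reads.append(Read(rid, seq.upper(), quals))
    if reads and min_char >= ord("J") + 1 and min_char != 126:
        raise ValueError(
            "all quality characters are above 'J': this looks like Phred+64 "
            "encoding, which is not supported (re-encode to Sanger Phred+33)"
        )
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if len(r.qual) != len(r.seq):
                raise ValueError(f"read {r.id!r} has no per-base qualities")
            qstr = "".join(chr(q + _PHRED_OFFSET) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


# --- FASTA ---------------------------------------------------------------


def read_fasta(path: str | Path) -> List[Read]:
    """Parse FASTA; header is split at the first whitespace, ids must be unique."""
    reads: List[Read] = []
    seen: Dict[str, int] = {}
    rid = None
    chunks: List[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if rid is not None:
                    reads.append(Read(rid, "".join(chunks).upper()))
                rid = line[1:].split()[0] if len(line) > 1 else ""
                seen[rid] = seen.get(rid, 0) + 1
                chunks = []
            elif line:
                if rid is None:
                    raise ValueError("FASTA file does not start with '>'")
                chunks.append(line.strip())
        if rid is not None:
            reads.append(Read(rid, "".join(chunks).upper()))
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise ValueError(f"duplicate FASTA ids: {', '.join(dups)}")
    return reads


def write_fasta(records: Iterable[Read], path: str | Path, wrap: int = 80) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(r.seq), wrap):
                    fh.write(r.seq[i : i + wrap] + "\n")
            else:
                fh.write(r.seq + "\n")


# --- names files ---------------------------------------------------------


def read_names(path: str | Path) -> Dict[str, List[str]]:
    """Read a mothur-style names file: representative id -> member read ids."""
    names: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            rep, members = parts
            if rep in names:
                raise ValueError(f"line {lineno}: duplicate representative {rep!r}")
            names[rep] = members.split(",")
    all_members = list(itertools.chain.from_iterable(names.values()))
    if len(all_members) != len(set(all_members)):
        raise ValueError("names file member lists are not disjoint")
    return names


def write_names(names: Mapping[str, List[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rep, members in names.items():
            fh.write(f"{rep}\t{','.join(members)}\n")


# --- translation ---------------------------------------------------------

_CODON_TABLE: Dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def translate(seq: str, frame: int = 0) -> str:
    """Translate ``seq`` in ``frame`` (0-2) under the standard genetic code.

    Trailing 1-2 nt are dropped; STOP codons become ``*``; any codon
    containing a non-ACGT symbol becomes ``X``.  Output length is
    ``(len(seq) - frame) // 3``.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = seq[frame:].upper()
    n = len(s) - len(s) % 3
    return "".join(_CODON_TABLE.get(s[i : i + 3], "X") for i in range(0, n, 3))


# --- IUPAC ---------------------------------------------------------------

IUPAC_NT: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def iupac_match(pattern: str, window: str) -> bool:
    """True iff every ``window`` base is in the degeneracy set of the
    corresponding ``pattern`` symbol.

    An ``N`` in the window matches only a pattern ``N`` (an uncalled base
    cannot be claimed by a specific degenerate symbol).  Pattern and window
    must be the same length; unknown symbols raise ``ValueError``.
    """
    if len(pattern) != len(window):
        raise ValueError("pattern and window must have equal length")
    for p, w in zip(pattern.upper(), window.upper()):
        if p not in IUPAC_NT:
            raise ValueError(f"unknown IUPAC symbol in pattern: {p!r}")
        if w == "N":
            if p != "N":
                return False
            continue
        if w not in "ACGT":
            raise ValueError(f"unknown nucleotide in window: {w!r}")
        if w not in IUPAC_NT[p]:
            return False
    return True
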