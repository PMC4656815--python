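"""Synthetic 454-style amplicon reads with an exact ground-truth manifest.

The generator emulates the dominant features of unidirectional
pyrosequencing of primer-anchored protein-coding amplicons:

* abundance-skewed sampling of coding templates (frame 0, STOP-free);
* substitution errors at a per-base rate, modulated by a per-read quality
  factor (bad reads carry more errors, as on a real picotiter plate);
* homopolymer-biased 1-2 nt indels: each homopolymer run of length l
  suffers a slippage indel with probability indel_rate * (l - 1), i.e.
  proportional to the number of identical adjacent pairs, so positions
  outside homopolymers never slip;
* per-base Phred qualities from a position-dependent mean with per-read
  and per-base Gaussian noise, floored at Q2, and reduced by a fixed
  offset at realized error sites so expected-error filtering has signal;
* optional two-parent chimeras with a uniform breakpoint, labeled in the
  manifest but never flagged by the pipeline itself (chimera screening is
  an external step; the manifest feeds its pass-through hook).

Every read's edits are recorded in template coordinates; replaying them
reproduces the read byte for byte, which the test suite asserts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .seqio import Read, translate

__all__ = [
    "SimConfig",
    "Edit",
    "ReadTruth",
    "TruthManifest",
    "simulate",
    "replay",
    "packaged_toy_community",
    "write_manifest",
    "read_manifest",
]

_LN10_OVER_10 = math.log(10) / 10.0


@dataclass
class Edit:
    pos: int  # position in the (possibly chimeric) source sequence
    kind: str  # 'sub' | 'ins' | 'del'
    payload: str  # sub: new base; ins: inserted bases; del: deleted bases


@dataclass
class ReadTruth:
    read_id: str
    template_id: str
    edits: List[Edit]
    is_chimera: bool = False
    parents: Optional[Tuple[str, str]] = None
    breakpoint: Optional[int] = None


TruthManifest = Dict[str, ReadTruth]


@dataclass
class SimConfig:
    """Study-condition defaults: 400-nt amplicons, 0.5% substitutions,
    0.2% homopolymer slippage per adjacent identical pair, skewed template
    abundances, no chimeras unless asked for."""

    templates: List[Tuple[str, str]]
    n_reads: int = 5000
    weights: Optional[Sequence[float]] = None
    sub_rate: float = 0.005
    indel_rate: float = 0.002
    indel_two_nt_fraction: float = 0.1
    chimera_fraction: float = 0.0
    read_length: int = 400
    q_start: float = 37.0
    q_end: float = 28.0
    read_q_sd: float = 4.0
    base_q_sd: float = 3.0
    error_q_offset: float = 15.0
    prefix: str = ""  # optional barcode+primer to prepend
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("at least one template is required")
        for rate in (self.sub_rate, self.indel_rate, self.chimera_fraction):
            if not (0 <= rate <= 1):
                raise ValueError("rates must be in [0, 1]")
        for tid, seq in self.templates:
            if len(seq) < self.read_length:
                raise ValueError(f"template {tid!r} shorter than read length")
            if "*" in translate(seq, 0):
                raise ValueError(
                    f"template {tid!r} contains an in-frame STOP codon; "
                    "coding templates must be STOP-free in frame 0"
                )
        if self.weights is None:
            # abundance skew: geometric halving across templates
            raw = [0.5**k for k in range(len(self.templates))]
            self.weights = [x / sum(raw) for x in raw]
        w = list(self.weights)
        if len(w) != len(self.templates) or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("weights must match templates and sum to 1")


def _homopolymer_runs(seq: str) -> List[Tuple[int, int]]:
    """(start, length) of every maximal single-base run."""
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j - i))
        i = j
    return runs


_BASES = "ACGT"


def simulate(config: SimConfig) -> Tuple[List[Read], TruthManifest]:
    """Draw reads under the error model; return reads and exact manifest."""
    rng = np.random.default_rng(config.seed)
    reads: List[Read] = []
    manifest: TruthManifest = {}
    tmpl = config.templates
    weights = np.asarray(config.weights)
    # per-read multiplier 10^(-delta/10), normalised to mean 1 so the
    # realised mean substitution rate equals sub_rate
    mult_norm = math.exp((config.read_q_sd * _LN10_OVER_10) ** 2 / 2.0)

    for r in range(config.n_reads):
        rid = f"read_{r:06d}"
        delta = rng.normal(0.0, config.read_q_sd)
        mult = min(10.0 ** (-delta / 10.0) / mult_norm, 20.0)

        k = int(rng.choice(len(tmpl), p=weights))
        tid, source = tmpl[k][0], tmpl[k][1]
        is_chimera = False
        parents = None
        breakpoint = None
        if config.chimera_fraction > 0 and rng.random() < config.chimera_fraction:
            k2 = int(rng.choice(len(tmpl), p=weights))
            if k2 != k:
                is_chimera = True
                t2id, t2 = tmpl[k2][0], tmpl[k2][1]
                lo, hi = 50, min(len(source), len(t2)) - 50
                breakpoint = int(rng.integers(lo, hi))
                source = source[:breakpoint] + t2[breakpoint:]
                parents = (tid, t2id)
                tid = f"{tid}|{t2id}"

        edits: List[Edit] = []
        # substitutions
        p_sub = min(config.sub_rate * mult, 0.75)
        hits = np.nonzero(rng.random(len(source)) < p_sub)[0]
        for pos in hits:
            old = source[pos]
            alts = [b for b in _BASES if b != old]
            edits.append(Edit(int(pos), "sub", alts[int(rng.integers(3))]))
        # homopolymer slippage indels
        for start, length in _homopolymer_runs(source):
            if length < 2:
                continue
            p_run = min(config.indel_rate * (length - 1) * mult, 0.5)
            if rng.random() >= p_run:
                continue
            size = 2 if rng.random() < config.indel_two_nt_fraction else 1
            base = source[start]
            if rng.random() < 0.5:
                edits.append(Edit(start, "ins", base * size))
            else:
                size = min(size, length)
                edits.append(Edit(start, "del", base * size))

        seq, err_positions = _apply_edits(source, edits)
        prefix = config.prefix
        seq = prefix + seq
        err_read_pos = [p + len(prefix) for p in err_positions]

        qual = _qualities(rng, len(seq), len(prefix), delta, err_read_pos, config)
        # sequencer length limit: a little past the amplicon span
        cut = min(len(seq), len(prefix) + config.read_length + 20)
        reads.append(Read(rid, seq[:cut], qual[:cut]))
        manifest[rid] = ReadTruth(rid, tid, edits, is_chimera, parents, breakpoint)

    return reads, manifest


def _apply_edits(source: str, edits: List[Edit]) -> Tuple[str, List[int]]:
    """Apply edits (template coordinates) right to left; also return the
    positions of error sites in read coordinates."""
    s = list(source)
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        if e.kind == "sub":
            s[e.pos] = e.payload
        elif e.kind == "ins":
            s[e.pos:e.pos] = list(e.payload)
        elif e.kind == "del":
            del s[e.pos : e.pos + len(e.payload)]
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    seq = "".join(s)
    # recompute read-coordinate error positions by replaying offsets
    err: List[int] = []
    shift = 0
    for e in sorted(edits, key=lambda e: e.pos):
        if e.kind == "sub":
            err.append(e.pos + shift)
        elif e.kind == "ins":
            err.extend(range(e.pos + shift, e.pos + shift + len(e.payload)))
            shift += len(e.payload)
        else:
            err.append(max(e.pos + shift - 1, 0))
            shift -= len(e.payload)
    return seq, [p for p in err if 0 <= p < len(seq)]


def _qualities(rng, total_len, prefix_len, delta, err_positions, config) -> List[int]:
    body = total_len - prefix_len
    pos = np.arange(body)
    span = max(config.read_length, 1)
    mean = config.q_start + (config.q_end - config.q_start) * np.minimum(pos / span, 1.0)
    q = mean + delta + rng.normal(0.0, config.base_q_sd, size=body)
    q = np.concatenate([np.full(prefix_len, 40.0), q])
    for p in err_positions:
        if p < total_len:
            q[p] -= config.error_q_offset
    q = np.clip(np.rint(q), 2, 40).astype(int)
    return q.tolist()


def replay(truth: ReadTruth, templates: Dict[str, str], read: Read, prefix: str = "") -> str:
    """Reconstruct a read's sequence from its manifest entry."""
    if truth.is_chimera:
        p1, p2 = truth.parents
        source = templates[p1][: truth.breakpoint] + templates[p2][truth.breakpoint :]
    else:
        source = templates[truth.template_id]
    seq, _ = _apply_edits(source, truth.edits)
    return (prefix + seq)[: len(read.seq)]


# --- packaged toy community ---------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if translate(a + b + c) != "*"
]

_TOY_SEED = 20150612
_TOY_LEN_CODONS = 140  # 420 nt: covers the 400-nt amplicon with margin


def packaged_toy_community() -> List[Tuple[str, str]]:
    """Four synthetic coding templates standing in for a 4-strain mock
    community carrying two dioxygenase-like marker genes.

    Deterministically generated (fixed internal seed): each template is 420
    nt of random non-STOP codons, so all four are mutually unrelated
    (<40% amino-acid identity), frame 0 and STOP-free, and a 400-nt read
    translates to 133 complete codons.
    """
    rng = np.random.default_rng(_TOY_SEED)
    names = ["strain1_bphA", "strain2_bphA", "strain3_benA", "strain4_benA"]
    out = []
    for name in names:
        codons = rng.choice(len(_NONSTOP_CODONS), size=_TOY_LEN_CODONS)
        out.append((name, "".join(_NONSTOP_CODONS[i] for i in codons)))
    return out


# --- manifest TSV ---------------------------------------------------------


def write_manifest(manifest: TruthManifest, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttemplate\tis_chimera\tparents\tbreakpoint\tedits\n")
        for rid, t in manifest.items():
            edits = ";".join(f"{e.pos}:{e.kind}:{e.payload}" for e in t.edits)
            parents = ",".join(t.parents) if t.parents else ""
            bp = "" if t.breakpoint is None else str(t.breakpoint)
            fh.write(f"{rid}\t{t.template_id}\t{int(t.is_chimera)}\t{parents}\t{bp}\t{edits}\n")


def read_manifest(path: str) -> TruthManifest:
    manifest: TruthManifest = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, tid, chim, parents, bp, edits = line.rstrip("\n").split("\t")
            elist = []
            if edits:
                for tok in edits.split(";"):
                    pos, kind, payload = tok.split(":")
                    elist.append(Edit(int(pos), kind, payload))
            manifest[rid] = ReadTruth(
                rid,
                tid,
                elist,
                bool(int(chim)),
                tuple(parents.split(",")) if parents else None,
                int(bp) if bp else None,
            )
    return manifest
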