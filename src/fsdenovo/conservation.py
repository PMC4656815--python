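"""Per-column conservancy of a protein multiple sequence alignment.

For every alignment column the residue frequency vector is computed over
the 20 amino acids plus the gap character, and the Shannon entropy
H' = -sum_a p_a ln p_a is reported.  The gap is treated as a 21st symbol:
a column where many sequences carry an inserted gap is thereby highly
entropic, which is exactly the signal sought (alignment regions dominated
by indels are not conserved).  'X' (unknown residue) is excluded from both
numerator and denominator.  Natural log by default; log2 available.

Conserved sites are columns whose consensus frequency strictly exceeds a
threshold, reported in the numbering of a user-chosen anchor sequence so
positions can be quoted against a reference protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["ConservationProfile", "conservancy", "conserved_sites", "profile_table"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AA20 + "-"  # gap as 21st symbol


@dataclass
class ConservationProfile:
    """Columns x 21 frequency matrix with consensus and entropy per column."""

    freqs: np.ndarray  # (n_columns, 21), rows sum to 1 (or 0 for all-X columns)
    consensus: List[str]
    consensus_freq: np.ndarray
    entropy: np.ndarray
    alphabet: str = ALPHABET
    row_ids: Optional[List[str]] = None
    msa: Optional[List[Tuple[str, str]]] = None

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]


def conservancy(
    msa: Sequence[Tuple[str, str]],
    weights: Optional[Sequence[float]] = None,
    log_base: str = "ln",
) -> ConservationProfile:
    """Column-wise residue frequencies and gap-treated Shannon entropy.

    ``msa`` is (id, aligned protein) with equal aligned lengths; ``weights``
    are optional per-row abundances (defaults to 1 per row).
    """
    if not msa:
        raise ValueError("empty alignment")
    length = len(msa[0][1])
    for rid, row in msa:
        if len(row) != length:
            raise ValueError(f"ragged alignment: row {rid!r} has length {len(row)}")
    if weights is None:
        w = np.ones(len(msa))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(msa):
            raise ValueError("one weight per alignment row required")

    idx = {aa: k for k, aa in enumerate(ALPHABET)}
    counts = np.zeros((length, len(ALPHABET)))
    for (rid, row), wt in zip(msa, w):
        for col, ch in enumerate(row.upper()):
            if ch == "X":
                continue  # unknown residues carry no information
            if ch == ".":
                ch = "-"
            k = idx.get(ch)
            if k is None:
                raise ValueError(f"unexpected symbol {ch!r} in row {rid!r}")
            counts[col, k] += wt

    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    logf = np.where(freqs > 0, np.log(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logf).sum(axis=1) + 0.0  # +0.0 normalises -0.0
    if log_base == "log2":
        entropy = entropy / math.log(2)
    elif log_base != "ln":
        raise ValueError("log_base must be 'ln' or 'log2'")

    cons_idx = freqs.argmax(axis=1)
    consensus = [ALPHABET[k] for k in cons_idx]
    cons_freq = freqs[np.arange(length), cons_idx]
    return ConservationProfile(
        freqs=freqs,
        consensus=consensus,
        consensus_freq=cons_freq,
        entropy=entropy,
        row_ids=[rid for rid, _ in msa],
        msa=list(msa),
    )


def conserved_sites(
    profile: ConservationProfile,
    anchor_id: str,
    thresholds: Sequence[float] = (0.999, 0.95),
) -> Dict[float, List[Tuple[int, str, float]]]:
    """Columns whose consensus frequency strictly exceeds each threshold.

    Positions are reported in anchor-sequence numbering (1-based residue
    index in the ungapped anchor); columns where the anchor has a gap get
    no number and are omitted.
    """
    if profile.msa is None or profile.row_ids is None:
        raise ValueError("profile was built without row information")
    try:
        anchor_row = profile.msa[profile.row_ids.index(anchor_id)][1]
    except ValueError:
        raise ValueError(f"anchor {anchor_id!r} not found in the alignment") from None

    anchor_pos: List[Optional[int]] = []
    pos = 0
    for ch in anchor_row:
        if ch in ("-", "."):
            anchor_pos.append(None)
        else:
            pos += 1
            anchor_pos.append(pos)

    out: Dict[float, List[Tuple[int, str, float]]] = {}
    for th in thresholds:
        sites: List[Tuple[int, str, float]] = []
        for col in range(profile.n_columns):
            if anchor_pos[col] is None:
                continue
            if profile.consensus_freq[col] > th:
                sites.append(
                    (anchor_pos[col], profile.consensus[col], float(profile.consensus_freq[col]))
                )
        out[th] = sites
    return out


def profile_table(profile: ConservationProfile, anchor_id: Optional[str] = None) -> pd.DataFrame:
    """Long-format per-column table: column, anchor position, consensus,
    consensus frequency, entropy."""
    anchor_pos: List[Optional[int]] = [None] * profile.n_columns
    if anchor_id is not None and profile.msa is not None:
        row = profile.msa[profile.row_ids.index(anchor_id)][1]
        pos = 0
        for col, ch in enumerate(row):
            if ch not in ("-", "."):
                pos += 1
                anchor_pos[col] = pos
    return pd.DataFrame(
        {
            "column": np.arange(profile.n_columns),
            "anchor_position": anchor_pos,
            "consensus": profile.consensus,
            "consensus_freq": profile.consensus_freq,
            "entropy": profile.entropy,
        }
    )
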