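"""End-to-end workflow: demultiplex, trim, filter, cluster, correct, evaluate.

Stage order follows the amplicon-processing recipe the package implements:

    demux -> trim -> MEE filter (+ re-extraction of identical discards)
          -> dereplicate -> SLP -> [external chimera drop-list hook]
          -> singleton removal -> frameshift correction -> evaluation

Each stage partitions its input (kept + removed == in) and the run log
records the partition, so read-count conservation is checkable after every
run.  Intermediates are materialized as FASTA + names files so external
tools (e.g. a real chimera screen) can be spliced in between stages.
The pipeline itself has no randomness: identical config and input give
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml

from . import preprocess
from .correct import CorrectionOutcome, DenovoParams, DenovoResult, correct_with_refs, denovo
from .evaluate import EvalParams, detect_fs
from .preprocess import FilterParams, SLPParams, SampleSheet
from .seqio import Read, UniqueSeq, write_fasta, write_names

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    mode: str = "denovo"  # 'denovo' or 'ref'
    filter_params: FilterParams = field(default_factory=FilterParams)
    slp_params: Optional[SLPParams] = field(default_factory=SLPParams)
    denovo_params: DenovoParams = field(default_factory=DenovoParams)
    sample_sheet: Optional[SampleSheet] = None
    sample: Optional[str] = None  # which demultiplexed sample to process
    refs: Optional[List[Tuple[str, str]]] = None  # protein refs for 'ref' mode
    known_refs: Optional[List[Tuple[str, str]]] = None  # for evaluation
    skip_mee: bool = False
    keep_singletons: bool = False
    chimera_ids: Sequence[str] = ()
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in ("denovo", "ref"):
            raise ValueError(f"mode must be 'denovo' or 'ref', got {self.mode!r}")
        if self.mode == "ref" and not self.refs:
            raise ValueError("reference-based mode requires a protein reference set")


@dataclass
class PipelineResult:
    stage_log: pd.DataFrame
    uniques: List[UniqueSeq]  # the uniques handed to correction
    result: object  # DenovoResult or list of CorrectionOutcome
    outcomes: List[CorrectionOutcome]
    fs_after: Optional[Dict[str, Tuple[bool, int]]] = None


def _log(rows: List[dict], stage: str, n_in: int, kept: int, removed: int) -> None:
    assert kept + removed == n_in, f"{stage}: {kept}+{removed} != {n_in}"
    rows.append({"stage": stage, "in": n_in, "kept": kept, "removed": removed})


def run_pipeline(reads: Sequence[Read], config: PipelineConfig) -> PipelineResult:
    rows: List[dict] = []
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    work = list(reads)
    if config.sample_sheet is not None:
        assigned, unassigned = preprocess.demultiplex(work, config.sample_sheet)
        if config.sample is not None:
            picked = assigned.get(config.sample, [])
        else:
            picked = [r for sample in assigned.values() for r in sample]
        _log(rows, "demux", len(work), len(picked),
             len(work) - len(picked))
        work = picked

    kept, short = preprocess.trim_to_length(work, config.filter_params.trim_len)
    _log(rows, "trim", len(work), len(kept), len(short))
    work = kept

    if not config.skip_mee:
        kept, discarded = preprocess.mee_filter(work, config.filter_params.mee_max)
        kept, rescued, discarded = preprocess.reextract_identical(kept, discarded)
        _log(rows, f"mee_{config.filter_params.mee_max}", len(work), len(kept), len(discarded))
        work = kept

    uniques = preprocess.dereplicate(work)
    _log(rows, "dereplicate", len(work), len(work), 0)

    if config.slp_params is not None:
        before = sum(u.abundance for u in uniques)
        uniques = preprocess.slp(uniques, config.slp_params)
        assert sum(u.abundance for u in uniques) == before
        _log(rows, "slp", before, before, 0)

    if config.chimera_ids:
        uniques, chim = preprocess.drop_ids(uniques, config.chimera_ids)
        _log(rows, "chimera_drop",
             sum(u.abundance for u in uniques) + sum(u.abundance for u in chim),
             sum(u.abundance for u in uniques), sum(u.abundance for u in chim))

    if not config.keep_singletons:
        uniques, singles = preprocess.remove_singletons(uniques)
        total = sum(u.abundance for u in uniques) + len(singles)
        _log(rows, "singletons", total, sum(u.abundance for u in uniques), len(singles))

    if out_dir:
        write_fasta([Read(u.id, u.seq) for u in uniques], out_dir / "precorrect.fasta")
        write_names({u.id: u.members for u in uniques}, out_dir / "precorrect.names")

    if not uniques:
        raise ValueError("no sequences left before correction; relax the filters")

    if config.mode == "denovo":
        result: object = denovo(uniques, config.denovo_params)
        outcomes = result.outcomes
    else:
        outcomes = correct_with_refs(uniques, config.refs, config.denovo_params)
        result = outcomes

    corrected = [(o.seq_id, o.corrected_nt) for o in outcomes if o.corrected_nt]
    fs_after = None
    if config.known_refs:
        fs_after = detect_fs(corrected, EvalParams(known_refs=list(config.known_refs),
                                                   align=config.denovo_params.align))

    if out_dir:
        _write_outputs(out_dir, rows, outcomes, config)

    return PipelineResult(pd.DataFrame(rows), uniques, result, list(outcomes), fs_after)


def _write_outputs(out_dir: Path, rows, outcomes, config) -> None:
    pd.DataFrame(rows).to_csv(out_dir / "stage_log.tsv", sep="\t", index=False)
    corr_nt = [Read(o.seq_id, o.corrected_nt) for o in outcomes if o.corrected_nt]
    corr_aa = [Read(o.seq_id, o.corrected_aa) for o in outcomes if o.corrected_aa]
    write_fasta(corr_nt, out_dir / "corrected_nt.fasta")
    write_fasta(corr_aa, out_dir / "corrected_aa.fasta")
    pd.DataFrame(
        [
            {
                "id": o.seq_id,
                "status": o.status,
                "abundance": o.abundance,
                "reference": o.reference_id or "",
                "events": o.events,
                "identity": round(o.identity, 6),
            }
            for o in outcomes
        ]
    ).to_csv(out_dir / "outcomes.tsv", sep="\t", index=False)
    cfg = {
        "mode": config.mode,
        "mee_max": config.filter_params.mee_max,
        "trim_len": config.filter_params.trim_len,
        "slp_w": config.slp_params.w if config.slp_params else None,
        "identity_min": config.denovo_params.identity_min,
        "length_min": config.denovo_params.length_min,
        "frame": config.denovo_params.frame,
        "fs_penalty": config.denovo_params.align.fs_penalty,
        "gap_penalty": config.denovo_params.align.gap_penalty,
        "keep_singletons": config.keep_singletons,
        "skip_mee": config.skip_mee,
    }
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
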