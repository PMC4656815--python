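import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from fsdenovo.evaluate import EvalParams, detect_fs
from fsdenovo.pipeline import PipelineConfig, run_pipeline
from fsdenovo.preprocess import FilterParams, SLPParams
from fsdenovo.seqio import translate
from fsdenovo.simulate import SimConfig, packaged_toy_community, simulate

# Standard conditions for the simulated mock community: 4 templates, 0.5%
# substitutions, 0.2% homopolymer slippage, 5000 reads, fixed seed.
SIM_SEED = 17
SIM_N = 5000


@pytest.fixture(scope="session")
def toy_templates():
    return packaged_toy_community()


@pytest.fixture(scope="session")
def known_refs(toy_templates):
    return [(tid, translate(seq[:400])) for tid, seq in toy_templates]


@pytest.fixture(scope="session")
def study_sim(toy_templates):
    cfg = SimConfig(
        templates=toy_templates,
        n_reads=SIM_N,
        sub_rate=0.005,
        indel_rate=0.002,
        seed=SIM_SEED,
    )
    reads, manifest = simulate(cfg)
    return cfg, reads, manifest


@pytest.fixture(scope="session")
def study_pipeline(study_sim, known_refs):
    """Full workflow at standard conditions: trim 400, MEE 1.0, SLP 0.01,
    singleton removal, de novo correction."""
    _, reads, _ = study_sim
    cfg = PipelineConfig(
        mode="denovo",
        filter_params=FilterParams(mee_max=1.0, trim_len=400),
        slp_params=SLPParams(0.01),
        known_refs=known_refs,
    )
    return run_pipeline(reads, cfg)


@pytest.fixture(scope="session")
def study_pipeline_no_slp(study_sim, known_refs):
    """Same run without pre-clustering or singleton removal, so the de novo
    corrector actually has erroneous satellites to fix."""
    _, reads, _ = study_sim
    cfg = PipelineConfig(
        mode="denovo",
        filter_params=FilterParams(mee_max=1.0, trim_len=400),
        slp_params=None,
        keep_singletons=True,
        known_refs=known_refs,
    )
    return run_pipeline(reads, cfg)


@pytest.fixture(scope="session")
def raw_fs_flags(study_sim, known_refs):
    """Frameshift calls for every unique raw (trimmed) sequence; computed
    once and reused across treatments, mirroring the
    dereplicate-once-then-back-replicate evaluation strategy."""
    from fsdenovo.preprocess import dereplicate, trim_to_length

    _, reads, _ = study_sim
    trimmed, _ = trim_to_length(reads, 400)
    uniques = dereplicate(trimmed)
    params = EvalParams(known_refs=list(known_refs))
    flags = detect_fs([(u.id, u.seq) for u in uniques], params)
    return {u.seq: flags[u.id] for u in uniques}, trimmed
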