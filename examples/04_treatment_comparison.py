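"""Compare read-processing treatments by residual frameshift rate.

Frameshifts are detected once on the dereplicated raw reads against the
known mock-community proteins, then each treatment's surviving sequences
are summarised: raw data, expected-error filtering (MEE 1.0), and MEE
followed by abundance-seeded single-linkage pre-clustering.
"""

from fsdenovo.evaluate import EvalParams, detect_fs, summaries_table, treatment_summary
from fsdenovo.preprocess import (
    SLPParams,
    dereplicate,
    mee_filter,
    reextract_identical,
    slp,
    trim_to_length,
)
from fsdenovo.seqio import translate
from fsdenovo.simulate import SimConfig, packaged_toy_community, simulate

templates = packaged_toy_community()
reads, _ = simulate(SimConfig(templates=templates, n_reads=800, seed=5))
known = [(tid, translate(seq[:400])) for tid, seq in templates]

trimmed, _ = trim_to_length(reads, 400)
raw_u = dereplicate(trimmed)
flags = detect_fs([(u.id, u.seq) for u in raw_u], EvalParams(known_refs=known))
by_seq = {u.seq: flags[u.id][0] for u in raw_u}

kept, discarded = mee_filter(trimmed, 1.0)
kept, _, _ = reextract_identical(kept, discarded)
mee_u = dereplicate(kept)
slp_u = slp(mee_u, SLPParams(0.01))

rows = [
    treatment_summary("raw", raw_u, by_seq),
    treatment_summary("MEE 1.0", mee_u, by_seq),
    treatment_summary("MEE 1.0 + SLP", slp_u, by_seq),
]
print(summaries_table(rows).to_string(index=False))
# The %FS column drops with each treatment: quality filtering removes
# error-rich reads, and pre-clustering reabsorbs erroneous satellites into
# their abundant parent sequences.
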