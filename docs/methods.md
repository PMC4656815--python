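# Methods

## Scope and model

The package corrects frameshifts in protein-coding amplicon reads from
unidirectional pyrosequencing. The underlying model: reads are
primer-anchored copies of coding templates sharing one reading frame
(default frame 0); sequencing introduces substitutions and, predominantly
within homopolymer runs, short (1–2 nt) insertions/deletions; indels whose
lengths do not sum to a multiple of 3 shift the frame. Correction is cast
as alignment of the nucleotide read (global) against a protein reference
(local), in which a reference residue may be paid for by a codon of 1, 2,
3, 4 or 5 nucleotides; any non-triplet codon is a frameshift event.

## The frameshift-aware aligner

Recurrence (`M(i, j)` = best score, query nt `1..i` vs reference residues
`1..j`):

* regular codon: `M(i−3, j−1) + S(aa(x[i−2..i]), r_j)`;
* 2-nt codon: `M(i−2, j−1) + P_fs + max_c S(aa(c), r_j)` over the 12
  single-wildcard completions `c`, STOP completions excluded;
* 1-nt codon: same with two wildcards (base at any of the 3 codon
  positions); if every completion is a STOP the matrix minimum is used;
* 4-/5-nt codon: `P_fs +` the best of the 2 (resp. 3) contiguous
  in-register 3-mers in the window;
* reference-residue skip and query-codon insertion at a linear gap cost
  `g` per residue.

Boundary conditions: `M(0, j) = 0` (free leading reference overhang),
`M(i, 0) = −∞` for `i > 0`; the final score maximises over the reference
end *and* over up to two unaligned trailing query nucleotides. The
trailing allowance is deliberate: a 400-nt trimmed read is 133 codons plus
one dangling base, and charging that terminal incomplete codon as a
frameshift would mark every error-free read as frameshifted. A terminal
partial codon is a trim artefact, not a frame break. The consequence —an
indel within the last two bases of a read can be absorbed silently — is
accepted and shared by the brute-force oracle in the test suite.

Defaults: BLOSUM62 (with its standard `X`/`*` rows), `P_fs = −15`,
`g = −11`, identity cut-off 0.4, minimum corrected protein length 100
residues. One `P_fs` is charged per non-triplet codon regardless of its
length, so a 2-nt slip is one event. The gap model is linear, not affine:
the frameshift penalty is the only indel-related price the method
specifies, and a linear gap keeps the DP single-state and exactly
checkable by path enumeration.

Numerics: the matrix fill is vectorised over the reference axis; the
linear reference-skip is folded in with a running-maximum scan
(`M(i,j) = g·j + cummax_j(V_j − g·j)`), which is exact for linear gaps.
Traceback re-tests transitions cell by cell with fixed priority (regular
codon > reference skip > codon insertion > 2-nt > 4-nt > 1-nt > 5-nt,
then the smaller reference index; at the end, more consumed query first),
making output byte-deterministic. Score comparisons use an absolute
tolerance of 1e-9; all default scores are integer-valued, so this is
slack, not a tuning knob.

Corrected output: each short codon is replaced by its best-scoring
non-STOP completion (lexicographically smallest codon on ties), each long
codon by its best in-register 3-mer (leftmost on ties); the corrected
protein is the translation of the corrected nucleotides, so
`translate(corrected_nt) == corrected_aa` holds by construction. Writing
concrete bases rather than `N` placeholders at completed positions keeps
that invariant; the cost is that a completed base is a best guess
informed by the reference, which is exactly what a corrector is for.
Identity is matching columns over all aligned columns (gap columns
included) within the query-consuming span.

## Correction modes

Reference-based mode aligns every unique sequence to its best external
reference (ties to first input order) and accepts iff identity ≥ 0.4 and
corrected length ≥ 100 residues.

De novo mode iterates: promote the most abundant unprocessed sequence
whose translation is STOP-free to reference; correct all unprocessed
sequences that clear the cut-offs against it; repeat. STOP-rejected
candidates remain eligible for correction by later references and are
discarded only at termination. A reference counts as status `reference`
(in the denominator of percentages, not in the corrected-% numerator);
corrected sequences are never recycled as references. The reference
length cut-off applies to the corrected protein length — the more
conservative of the two readings (aligned span vs corrected length) — and
is configurable. Percentages are reported both abundance-weighted (reads)
and per unique; reads is the default.

Determinism: dereplication breaks abundance ties lexicographically by
sequence then by first-seen read id, so reference selection and therefore
whole runs are reproducible byte for byte.

## Preprocessing

* Demultiplexing: barcode matched literally, forward primer
  IUPAC-degenerately (printed primers contain degeneracy codes, so literal
  matching is impossible); an uncalled `N` in the read matches only a
  pattern `N`. Reverse-complement orientation is never searched
  (unidirectional sequencing).
* Trimming to 400 nt; shorter reads discarded.
* MEE filtering: `E = Σ 10^(−Q_i/10)` ≤ threshold (sweep 0.5–2.0 by 0.5;
  default 1.0); discarded reads string-identical to a kept read are
  re-extracted before dereplication, in input order.
* SLP: one greedy pass in descending abundance order; each unmerged
  sequence seeds a cluster absorbing all less-abundant unmerged sequences
  at distance ≤ w = 0.01. This is abundance-seeded pre-clustering, not
  full single-linkage over the distance matrix: the former is what the
  "exploit abundance information" idea describes and is quadratic only in
  the worst case.
* Distance dialect: global nucleotide alignment, match +1 / mismatch −1 /
  linear gap −2; `d = 1 − matches/columns`, every gap column a non-match.
  The external command this mirrors does not document its exact gap
  handling, so one dialect is fixed and declared rather than guessed.
  Inside SLP an edit-distance prefilter (edlib) skips pairs that provably
  exceed w: a substitution contributes one non-match column and an indel
  one non-match column plus at most one extra column, so
  `d ≥ (ed/2)/(L + ed)`; `d ≤ w` therefore forces
  `ed ≤ 2wL/(1 − 2w)`. Candidate pairs inside the bound are always
  scored by the exact aligner.
* Singleton removal: uniques of abundance 1 dropped (treated as likely
  erroneous). Chimera screening is external by design; the pipeline
  accepts a drop-list of representative ids between pre-clustering and
  correction.

## Evaluation

Frameshift detection against known proteins uses the in-house aligner
(has_fs := best alignment contains ≥ 1 event) rather than an external
translated-BLAST search: it removes a database-version-dependent
external and makes "zero frameshifts after correction" assertable
hermetically. Amino-acid accuracy is identical residues to the assigned
best reference divided by the expected full length (133 residues for a
400-nt amplicon), capped at 1 per read (insertions can otherwise push
the count past the denominator), abundance-weighted. Treatment summaries
report totals, uniques, singletons and %FS with/without singletons; when
every unique is a singleton the without-singletons figure is a missing
value, not 0.

## Conservancy

Per-column residue frequencies over the 20 amino acids plus gap, and
Shannon entropy `H′ = −Σ p ln p` (`0·ln 0 = 0`; natural log, log2
optional). The gap is a 21st symbol: columns dominated by inserted gaps
should score as highly entropic, which would be impossible if gaps were
excluded. `X` carries no information and is excluded from numerator and
denominator. Conserved sites are columns whose consensus frequency
strictly exceeds a threshold (0.999, 0.95), numbered along a user-chosen
anchor sequence; columns where the anchor has a gap get no number.

## Simulator

What it emulates: abundance-skewed template sampling (geometric halving
by default), substitutions at a per-base rate, homopolymer slippage, a
position-dependent quality falloff (Q37 → Q28 over 400 nt) with per-read
(sd 4) and per-base (sd 3) Gaussian variation floored at Q2, a 15-point
quality drop at realized error sites, and optional two-parent chimeras at
a uniform breakpoint, labeled in the manifest only. The per-read quality
shift also multiplies the error rates (normalised so the mean substitution
rate equals the nominal rate): bad reads are bad in both senses, which is
what gives expected-error filtering its discriminating signal.

Homopolymer model: each maximal run of length ℓ suffers a slippage indel
with probability `indel_rate × (ℓ − 1)` (capped at 0.5), i.e. one
opportunity per identical adjacent pair; insertions duplicate the run
base, deletions remove 1–2 bases. Single bases never slip. At the default
rates (substitution 0.005/base, slippage 0.002/pair) roughly 15% of reads
carry a net frameshift — the regime this class of data shows.

What it does not emulate: flowgram-level signal, PCR-cycle chimera
kinetics, position-specific motifs, reverse reads, or length-dependent
quality cliffs. Passing tests on these simulations therefore demonstrate
the algorithmic contracts (recovery of true templates, zero residual
frameshifts, monotone treatment effects) — not performance on any
particular instrument run.

The manifest records every edit in template coordinates; replaying the
edits reproduces each read exactly, and the suite asserts this.

## Problem sizes and test design

The standard simulated dataset is 5000 reads from the four packaged
templates (420 nt each, mutually <40% amino-acid identity, STOP-free in
frame 0). Four mutually unrelated templates are required for the de novo
recovery property to be well-posed: templates above the 0.4 identity
cut-off of an earlier reference would be absorbed as corrected rather
than promoted. Oracle equivalence is asserted on 1000 random instances
with queries ≤ 15 nt and references ≤ 5 aa, where exhaustive path
enumeration is tractable. Examples use 600–2000 reads.

## Known limitations

* Indels within the last two bases of a read are absorbed by the free
  terminal codon rather than reported as events.
* The aligner is exact but unbanded: ~7 ms per 400 nt × 133 aa alignment;
  very large unique sets against many references cost minutes.
* De novo mode inherits the abundance premise: a true low-abundance
  variant closer than the identity cut-off to an abundant reference is
  corrected toward that reference, and a systematically erroneous but
  abundant STOP-free sequence could be promoted.
* The distance dialect and gap model are declared defaults, not recovered
  from any external tool's internals.
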