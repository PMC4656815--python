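"""Column conservancy of a protein alignment with gap-treated entropy.

Builds a toy gapped alignment and reports, per column, the consensus
residue, its frequency, and the Shannon entropy with the gap counted as a
21st symbol, then lists conserved sites in anchor numbering.
"""

from fsdenovo.conservation import conservancy, conserved_sites, profile_table

msa = [
    ("anchor", "MKLVDAHG"),
    ("seq2",   "MKLVDAHG"),
    ("seq3",   "MKIVDSHG"),
    ("seq4",   "MK-VDAHG"),
    ("seq5",   "MKLVDAHG"),
]

profile = conservancy(msa)
print(profile_table(profile, anchor_id="anchor").to_string(index=False))

sites = conserved_sites(profile, anchor_id="anchor", thresholds=(0.999, 0.95))
for th, hits in sites.items():
    pretty = ", ".join(f"{aa}{pos} ({freq:.3f})" for pos, aa, freq in hits)
    print(f"consensus > {th:.1%}: {pretty or '(none)'}")
# Columns where every sequence agrees have entropy 0; the column with the
# inserted gap scores non-zero entropy even though all residues agree,
# because the gap is a symbol of its own.
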