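"""Scan an MCR-alpha alignment for the Tyr444-Gly445-Tyr446 motif.

A synthetic gapped alignment anchored on a reference sequence carries
known Y/F substitutions at positions 444 and 446.  The scanner maps
reference residue numbers through the gaps and classifies every sequence.
"""

from methanokinetics.motif import classify_motifs
from methanokinetics.synthetic import make_alignment

aln, truth = make_alignment(
    label_counts={"YGY": 6, "FGY": 3, "YGF": 2, "FGF": 1, "other/gapped": 2},
    seed=1,
)
report = classify_motifs(aln)

print(f"sequences: {len(report.records)}  (alignment width {aln.width})")
for label, n in sorted(report.counts().items()):
    print(f"  {label:<14} {n}")
agree = sum(r.label == truth[r.seq_id] for r in report.records)
print(f"agreement with generator ground truth: {agree}/{len(report.records)}")

# YGY is the motif shared by the high-performance strains; F substitutions
# at 444 or 446 mark other lineages, and gapped motifs are reported as such.
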