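"""Build sequence-logo data from anchored mature peptides.

Aligns a small set of 13-mers on the D-Y anchor (no gaps needed),
computes per-column Shannon information in bits (log2 20 = 4.32 bits
maximum) and prints the consensus with ambiguity classes.
"""

from rgfmine.peptide import MaturePeptide
from rgfmine.profile import anchor_align, consensus, logo

peptides = [MaturePeptide(s, 0) for s in (
    "DYNSPKGHPPSNN", "DYSRPAGHPPSHN", "DYWGPGEHPPENN",
    "DYTSPIQHPPGNN", "DYSIPGAHPPGNN", "DYEWPLVHPPTNN",
)]

aln = anchor_align(peptides, partition="demo")
lm = logo(aln)

print("col  information(bits)  top residues")
for col in lm.columns:
    top = sorted(col.frequencies.items(), key=lambda kv: -kv[1])[:3]
    shown = " ".join(f"{a}:{f:.2f}" for a, f in top if f > 0)
    print(f"{col.index:3d}  {col.information:17.3f}  {shown}")

print(f"\nconsensus (majority 0.5): {consensus(lm)}")
print("Invariant anchor columns (D, Y) carry the full 4.32 bits; variable "
      "columns carry little information, mirroring the family's conserved "
      "scaffold around a variable core.")
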