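"""Classify mature peptides into the family's groups and subgroups.

Builds a handful of 13/14-residue D-Y-anchored peptides and prints the
group call (H: histidine at position 8; R: consecutive R/K at 7-8 with
NN at 12-13), the Group H terminal subgroup and the conservation score
(0-7 diagnostic positions matched).
"""

from rgfmine.peptide import MaturePeptide, classify

peptides = [
    ("liverwort-style", MaturePeptide("DYNSPKPHPPSSN", 0)),
    ("canonical H-N", MaturePeptide("DYSRPAGHPPSHN", 0)),
    ("R-type", MaturePeptide("DYVSPTRRPPLNN", 0)),
    ("terminal-PP", MaturePeptide("DYEGPLGHPPLPP", 0)),
    ("triple-proline 14-mer", MaturePeptide("DYNSPKPHPPPLSN", 0, variant="triple_P_14")),
]

for label, m in peptides:
    r = classify(m)
    flags = [f for f, on in (("liverwort-SSN", r.liverwort_ssn),
                             ("moss-terminus", r.moss_terminus),
                             ("lycophyte-terminal-H", r.lycophyte_terminal_h)) if on]
    print(f"{label:24s} {m.residues:15s} group={r.group:10s} subgroup={r.subgroup:5s} "
          f"conservation={r.conservation_score}/7 {' '.join(flags)}")

print("\nThe conservation score counts matches at the seven family-diagnostic "
      "positions (1 D, 2 Y, 5 P, 8 basic/H, 9 P, 10 P, terminal N/P/H).")
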