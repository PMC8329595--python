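# rgfmine

Mining, classification and phylogenetic profiling of RGF/GLV/CLEL-like
short-peptide precursors in plant transcriptomes and proteomes.

## The problem

ROOT GROWTH FACTOR (RGF, also GOLVEN/CLEL) peptides are ~13-residue
tyrosine-sulfated signaling peptides cut from short precursor proteins.
Outside the peptide-encoding region the precursors are so variable that
ordinary homology search and phylogenetics struggle: the only reliably
conserved signal is the mature peptide itself, which begins at the first
aspartate followed by tyrosine (the **D-Y anchor**) and carries a small
set of diagnostic residues. `rgfmine` implements, as a tested and
reusable library, the complete procedure for finding such sequences in
assembled transcriptomes (searched in all six reading frames) and
predicted proteomes, classifying the presumptive mature peptides, and
mapping presence/absence onto a species tree — together with a
ground-truthed synthetic-data generator, so the whole pipeline can be
exercised and validated without any external downloads.

## The method

1. **Short-query seeded search** (`rgfmine.search`): a from-scratch
   protein BLAST-style engine tuned for very short queries —
   word size 2, PAM30, word-neighborhood threshold 16, two-hit window 15,
   affine gaps (open 9, extend 1), no composition-based statistics, at
   most 30 subjects per query; transcripts are translated in all six
   frames first (`rgfmine.seqio`). Queries are 16-mers: a known mature
   peptide plus its three preceding residues. An exhaustive affine-gap
   Smith–Waterman (`sw_oracle`) serves as an independent reference in
   tests.
2. **Curation and classification** (`rgfmine.peptide`): hits are merged
   per locus; the mature peptide is cut at the first D-Y anchor in the
   hit-supported window — 13 residues, or 14 when three consecutive
   prolines span the canonical 9–10 proline positions; candidates are
   kept when they match at least 5 of 7 diagnostic positions
   (1 D, 2 Y, 5 P, 8 H/R/K, 9 P, 10 P, 13 N/P/H). A signal peptide is
   never required. Classification: **Group R** = consecutive R/K at
   positions 7–8 with N at 12–13; otherwise **Group H** = H at position 8,
   split by the terminus into **H-N**, **H-P** and **H-PP**. Cleavage
   motifs (dibasic R/K pairs), C-terminal extensions (0 for H, 9–18 for
   R, >20 "long") and paired H/R precursors sharing an N-terminal region
   are annotated.
3. **Profiles** (`rgfmine.profile`): gap-free anchored alignment of
   matures, per-column frequencies, Shannon information in bits
   (WebLogo convention, optional small-sample correction), consensus
   calls with ambiguity classes.
4. **Gain/loss mapping** (`rgfmine.phylo`): taxon × group presence
   matrices ("present" vs "not detected" — never "absent"), Dollo
   parsimony (single gain at the MRCA of present tips, minimal
   independent losses), a brute-force enumeration oracle, and a
   sensitivity report flagging transcriptome-only absences as possible
   false negatives.
5. **Synthetic data** (`rgfmine.synthetic`): precursor ORFs (hydrophobic
   N-terminus, variable linker with planted cleavage motifs, PWM-drawn
   mature, group-dependent extension) embedded on random strands/frames
   among vetted decoys; presence/absence evolved by irreversible losses
   on a tree; every emission ships a machine-checkable ground truth.

## Worked example

`python examples/mine_synthetic_transcriptome.py` hides 10 precursor
ORFs among 90 decoy transcripts and mines them back:

```
100 transcripts searched, 108 raw hits, 10 curated candidates (17 dropped)

demo_pre000    frame -1  DYSAPTRKPPWNN  R/none score= 64  [true]
demo_pre001    frame -1  DYQLPIQHPPVHN  H/H-N  score= 57  [true]
...
demo_pre009    frame +1  DYVSPLSHPPSPP  H/H-PP score= 57  [true]

recall 10/10, decoy false positives 0
```

Each line is one recovered candidate: the transcript and reading frame
it was found in, the extracted 13-residue mature peptide, its group and
subgroup call, and the raw PAM30 alignment score. All ten embedded
precursors are recovered, none of the 90 decoys survives curation.

`python examples/infer_losses.py` maps detections on a toy land-plant
cladogram where the moss crown and hornworts lack the family:

```
gain placed at: node0
independent losses: 2
  loss on the edge to {mossA, mossB}
  loss on the edge to {horn1, horn2}
brute-force minimal loss count: 2
```

See also `examples/classify_peptides.py` (group rules on hand-built
peptides) and `examples/sequence_logo.py` (information content and
consensus). A thin CLI wraps the same library calls:
`rgfmine generate | mine | classify | logo | phylo | all`.

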