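# Methods

## Scope and model

`rgfmine` re-implements a mining procedure for a family of short
secreted plant signaling peptides whose precursors conserve almost
nothing outside the ~13-residue mature peptide. The package treats the
mature peptide as the unit of homology: detection, curation,
classification and cross-species comparison all operate on the
D-Y-anchored peptide window, not on whole-precursor alignments. Species
relationships are an *input* (a rooted cladogram); the package never
infers trees.

## Search engine

The engine reproduces the seeded-alignment strategy of protein BLAST at
the parameterization used for short peptide queries:

| parameter | default | meaning |
|---|---|---|
| word_size | 2 | length of indexed words |
| neighborhood_threshold | 16 | minimum word score (PAM30) to index |
| gap_open / gap_extend | 9 / 1 | affine gap costs; a gap of length g costs 9 + g |
| two_hit_window | 15 | max diagonal distance between the two triggering word hits |
| max_target_seqs | 30 | subjects reported per query |
| x_drop | 20 | ungapped extension drop-off |
| band_width | 24 | subject-window radius for the gapped stage; `None` = whole subject |

Scores come from the published PAM30 matrix (loaded from Biopython),
with two conventions enforced: the stop character `*` scores −4 against
everything, which terminates extensions at stop codons without
ORF-splitting, and `X` never scores positive. No Karlin–Altschul
E-values are computed: the procedure this package implements ranked hits
by raw score and filtered by peptide conservation, so gapped-PAM30
statistical parameters are unnecessary; an empirical shuffled-null
significance could be layered on top but is not part of curation.

The per-query report threshold defaults to the query's self-score minus
a configurable slack. The engine-level default slack is 0.4; **the
mining pipeline passes 0.8** (i.e. reports from 20% of self-score). This
is deliberate: a true homolog shares mainly the 7–8 anchored positions
with a motif query (roughly half the self-score under PAM30's steep
mismatch penalties), so a tight raw-score gate would discard genuine
family members. Specificity is instead provided by curation — the D-Y
anchor plus the conservation filter: a permissive search feeding a
strict curation step.

`sw_oracle` is a deliberately plain, unbanded Gotoh Smith–Waterman used
as an independent reference. Tests verify (a) soundness — no reported
score ever exceeds the oracle — and (b) completeness at exhaustive
settings (single-hit seeding, neighborhood threshold at the minimum word
self-score, unbounded band), where the engine returns exactly the oracle
score for every subject above threshold.

## Curation and classification rules

* Mature peptide: first D immediately followed by Y, searched downstream
  from the hit-supported window (margin 5 upstream to cover the query's
  three context residues) — never from the protein start, which avoids
  spurious upstream D-Y dipeptides. Length 13; when positions 9–11 are
  PPP the peptide is the atypical 14-mer (`triple_P_14`), and positional
  rules are applied after collapsing the extra proline out.
* Conservation score (0–7): one point each for 1 D, 2 Y, 5 P,
  8 ∈ {H,R,K}, 9 P, 10 P, 13 ∈ {N,P,H}. The terminal set is widened to
  {N,P,H} so that the terminal-P and terminal-H lineage variants are not
  penalized; the set is configurable. Curation default: ≥ 5 of 7, which
  admits every described lineage variant while rejecting vetted decoys.
* Group R before Group H: a peptide matching the full R signature
  (7–8 ∈ {R,K}, 12 N — or H in seed-plant lineages — and 13 N) is R even
  though position 8 also matches the basic set; the H call requires only
  H at position 8. Subgroups for H: 12–13 PP → H-PP, else 13 N → H-N,
  else 13 P → H-P. Lineage-profile flags (liverwort 11–13 SSN; moss
  11 R/K, 12 G/S, 13 N; terminal H) are reported independently of the
  group call.
* Gymnosperm-style H subgroup profiles (H1–H5 and similar) are supported
  as a user-supplied position→residue-set table; no default residues are
  shipped because the package defines the mechanism, not a canonical
  set.
* Cleavage annotation scans between precursor position 20 and the mature
  start for dibasic motifs (RR/KR/RK/KK) or an isolated R/K followed
  within three residues by a small residue (A/G/S/T) — a stated
  approximation to subtilase target sites, since exact site tables are
  not part of the package.
* Isoform collapsing: within a taxon, candidates with an identical
  mature peptide and ≥ 95% global precursor identity reduce to the
  best-scoring representative (transcriptome assemblies carry redundant
  isoforms; counts are intended per gene).
* Paired H/R detection: global identity ≥ 80% over ≥ 30 aligned residues
  of the pre-peptide regions.

## Logos

Anchored 13/14-mers need no alignment step: column 1 is the anchor D.
The extra proline of 14-mers goes to a flagged insertion column placed
between canonical columns 10 and 11 (configurable). Information content
follows the WebLogo convention: R = log2(20) − H, optionally minus the
small-sample correction e_n = 19/(2·ln 2·n); letter height = frequency ×
R; gaps/X/stop are excluded from counts with the column n adjusted.
Pseudocount defaults: 0 for display, 0.5 recommended for consensus
calls.

## Dollo mapping

Each character (family, or one group) is assumed to have arisen once:
the gain sits at the MRCA of the tips where it was detected and each
loss is a maximal clade below the gain whose scored tips are all
"not detected". This placement is minimal; `enumerate_loss_oracle`
verifies it by brute force on small trees. "Not detected" is never
reported as confirmed absence — transcriptome datasets can simply lack
low-abundance transcripts — and the sensitivity report flags such cells
unless a genome-derived proteome was searched. Polytomies are allowed; a
loss on a polytomy edge counts once. Multi-gain scenarios are not
reconstructed automatically, but per-group maps make two-origin
comparisons straightforward.

## Synthetic data: what it emulates and what it does not

The generator's defaults describe the study conditions used throughout
the tests: per taxon, 20 precursor transcripts (benchmark runs: 100)
against 180 decoys (benchmark: 900); group mix 50% H, 30% R, 20% H-PP;
N-terminal hydrophobic stretch 15–30 aa; linker 30–80 aa with exactly 2
planted dibasic motifs; R-type extensions uniform on 9–18 aa, H-type 0,
terminal-PP optionally 21–35; UTRs 20–100 nt; uniform synonymous codon
choice; random strand. Mature peptides are drawn from group PWMs whose
diagnostic positions carry the group residues and whose free positions
are near-uniform over a neutral pool (no D/Y, no R/K, no P/H/N), so that
spurious anchors, cleavage motifs and conservation points cannot arise
by construction. Decoys (length-matched random ORFs and
shuffled-precursor negatives) are resampled until no reading frame
contains a D-Y window reaching the curation threshold.

Substitution noise (`mutation_rate`, per site) applies to mature
positions 3–13 only: the D-Y anchor defines family membership under the
mining rule, so an anchor-mutated sequence would not be a divergent
family member but a non-member, and including such draws would change
the benchmark's positive set rather than its difficulty.

Tree scenarios evolve the character by irreversible per-edge loss from a
present root. The recorded "true" gain/loss map is the *identifiable*
form — maximal fully-lost clades below the MRCA of surviving tips —
because sibling losses, stacked losses, or losses that eliminate one
side of the root entirely are indistinguishable from tip data; the raw
event edges are kept alongside for inspection.

What passing tests on this generator do **not** show: performance on
real assemblies with sequencing error, fragmented ORFs, codon bias,
indels inside the mature peptide, or realistic transcript-abundance
variation — none of which are modeled. Detection dropout (transcriptome
taxa only) is a coarse stand-in for expression-level false negatives.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally, 1-based inclusive in all
  written reports.
* Standard genetic code only; codons with ambiguity codes translate to a
  residue only when every expansion agrees, else X.
* Deterministic tie-breaks everywhere: subjects by (score desc, id asc,
  start asc); candidate tables sorted by (id, frame, start); identical
  config + seed reproduce reports byte-identically, and every report
  carries the seed and a config hash in its header.
* The dense recovery benchmark lifts `max_target_seqs`, since a single
  synthetic dataset holds 100 family members — denser than any real
  species' dataset — and the cap would otherwise censor recall
  measurement.
* Problem sizes in the shipped tests (500 oracle pairs at 16×200
  residues; 100 random trees ≤ 10 tips; one 100+900-transcript benchmark
  per noise level) were chosen as the smallest sets that exercise every
  code path with stable statistics.

## Known limitations

* Signal peptides are flagged-only by design (never a prerequisite), and
  no external predictor is integrated.
* E-value statistics, PSI-BLAST-style iteration and translated-query
  modes are out of scope.
* The two-hit trigger requires two words scoring ≥ 16; queries composed
  entirely of low-self-score residues (e.g. poly-A) cannot seed at
  default settings — irrelevant for anchored peptide queries, which
  always contain the DY (18) and PP (16) words.
* Sulfation chemistry and peptide bioactivity are not modeled.
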