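"""Curation of search hits into precursor candidates and mature-peptide
extraction, scoring, classification and annotation.

The presumptive mature peptide is defined positionally: it begins at the
first aspartate immediately followed by tyrosine (the D-Y anchor) within
the hit-supported region and runs 13 residues, or 14 when three
consecutive prolines span the canonical two-proline positions (9-10).
Classification into the two major groups follows the family's diagnostic
residues: Group H carries histidine at position 8; Group R carries
consecutive R/K at positions 7-8 together with asparagines at 12-13.
Group H splits by its terminal residue(s) into H-N, H-P and H-PP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .search import Hsp

BASIC = set("RK")
SMALL = set("AGST")
DIBASIC_MOTIFS = ("RR", "KR", "RK", "KK")

#: Built-in consensus 13-mers used to seed searches when no user query
#: set is given. Anchored positions carry the group-diagnostic residues;
#: remaining positions are filled with unremarkable residues.
GROUP_CONSENSUS = {
    "H": "DYSNPKGHPPSNN",
    "R": "DYSNPGRKPPSNN",
    "H-PP": "DYSNPKGHPPSPP",
}


class ExtractionError(ValueError):
    """Raised when no D-Y anchor can be located in a candidate."""


@dataclass(frozen=True)
class MaturePeptide:
    """The extracted presumptive mature peptide.

    ``start`` is the 0-based position of the anchor D within the source
    protein (translated frame or protein record). ``partial`` marks
    C-truncated peptides shorter than the canonical length.
    """

    residues: str
    start: int
    variant: str = "canonical_13"  # or "triple_P_14"
    partial: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) < 2 or self.residues[0] != "D" or self.residues[1] != "Y":
            raise ValueError(f"mature peptide {self.residues!r} lacks the D-Y anchor")
        if not self.partial:
            want = 14 if self.variant == "triple_P_14" else 13
            if len(self.residues) != want:
                raise ValueError(
                    f"{self.variant} peptide must have {want} residues, got {len(self.residues)}")
            if self.variant == "triple_P_14" and self.residues[8:11] != "PPP":
                raise ValueError("triple_P_14 requires P at positions 9-11")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def collapsed(self) -> str:
        """The peptide in the canonical 13-position frame (the extra P of a
        triple-proline 14-mer, position 11, is collapsed out)."""
        if self.variant == "triple_P_14":
            return self.residues[:10] + self.residues[11:]
        return self.residues


@dataclass
class PrecursorCandidate:
    """A curated candidate precursor: one locus on one subject frame."""

    taxon: str | None
    source_id: str
    frame: int
    protein: str  # full translated frame or protein record
    hit_start: int  # merged hit-supported window, 0-based half-open
    hit_end: int
    provenance: tuple[Hsp, ...]
    mature: MaturePeptide | None = None
    orf_start: int = 0
    orf_end: int = 0
    completeness: str = "full_length"  # | N_truncated | C_truncated
    best_score: int = 0

    @property
    def precursor(self) -> str:
        """The candidate's open-reading-frame protein region."""
        return self.protein[self.orf_start:self.orf_end]

    @property
    def mature_start_in_precursor(self) -> int | None:
        if self.mature is None:
            return None
        return self.mature.start - self.orf_start


@dataclass(frozen=True)
class ClassificationResult:
    group: str  # H | R | unassigned
    subgroup: str  # H-N | H-P | H-PP | none
    conservation_score: int
    twelfth_residue: str
    liverwort_ssn: bool = False
    moss_terminus: bool = False
    lycophyte_terminal_h: bool = False


@dataclass(frozen=True)
class CleavageAnnotation:
    positions: tuple[tuple[int, str], ...]  # (0-based precursor position, motif)
    count: int
    note: str = ""


# --- extraction ------------------------------------------------------------

def _window_bounds(candidate: PrecursorCandidate, upstream_margin: int = 5,
                   downstream_margin: int = 14) -> tuple[int, int]:
    lo = max(0, candidate.hit_start - upstream_margin)
    hi = min(len(candidate.protein), candidate.hit_end + downstream_margin)
    return lo, hi


def extract_mature(candidate: PrecursorCandidate, upstream_margin: int = 5) -> MaturePeptide:
    """Locate the first D-Y anchor downstream of the hit-supported region
    and cut the 13-residue (or triple-proline 14-residue) mature peptide.

    The anchor search starts at the hit window rather than the protein
    start so that spurious upstream D-Y dipeptides are ignored. A stop
    codon inside the would-be peptide disqualifies that anchor. An anchor
    closer than 13 residues to the sequence end yields a partial,
    C-truncated peptide.
    """
    seq = candidate.protein
    lo, hi = _window_bounds(candidate, upstream_margin)
    pos = lo
    fallback: MaturePeptide | None = None
    while True:
        pos = seq.find("DY", pos, hi)
        if pos == -1:
            break
        window = seq[pos:pos + 14]
        body13 = window[:13]
        if "*" not in body13:
            if len(body13) == 13:
                if window[8:11] == "PPP" and len(window) == 14 and "*" not in window:
                    return MaturePeptide(window, pos, variant="triple_P_14")
                return MaturePeptide(body13, pos)
            if fallback is None:  # runs off the end: C-truncated partial
                fallback = MaturePeptide(body13, pos, partial=True)
        pos += 1
    if fallback is not None:
        return fallback
    raise ExtractionError(
        f"{candidate.source_id} frame {candidate.frame}: no usable D-Y anchor "
        f"in window [{lo}, {hi})")


def conservation_score(mature: MaturePeptide) -> int:
    """Count of conserved family-diagnostic positions present (0-7):
    1 D, 2 Y, 5 P, 8 in {H,R,K}, 9 P, 10 P and terminal 13 in {N,P,H},
    evaluated in the collapsed 13-position frame."""
    c = mature.collapsed
    checks = (
        (0, {"D"}), (1, {"Y"}), (4, {"P"}), (7, {"H", "R", "K"}),
        (8, {"P"}), (9, {"P"}), (12, {"N", "P", "H"}),
    )
    return sum(1 for i, allowed in checks if i < len(c) and c[i] in allowed)


def max_anchor_conservation(protein: str) -> int:
    """Best conservation score over every D-Y anchored window in a protein
    (used to vet decoys and to pre-screen frames)."""
    best = 0
    pos = protein.find("DY")
    while pos != -1:
        window = protein[pos:pos + 14]
        if "*" not in window[:13]:
            variant = "triple_P_14" if window[8:11] == "PPP" and len(window) == 14 else "canonical_13"
            residues = window if variant == "triple_P_14" else window[:13]
            if len(residues) >= 2:
                m = MaturePeptide(residues, pos, variant=variant,
                                  partial=len(residues) < (14 if variant == "triple_P_14" else 13))
                best = max(best, conservation_score(m))
        pos = protein.find("DY", pos + 1)
    return best


SEED_PLANT_LINEAGES = {"seed_plant", "gymnosperm", "angiosperm"}


def classify(mature: MaturePeptide, lineage: str | None = None) -> ClassificationResult:
    """Assign the peptide to Group R or H (R rule first), pick the Group H
    terminal subgroup, and set the lineage-profile flags.

    Group R requires consecutive R/K at positions 7-8 plus N at 12-13;
    for seed-plant lineages H is tolerated at position 12. Group H only
    requires the diagnostic H at position 8. Subgroups: terminal PP ->
    H-PP, else terminal N -> H-N, else terminal P -> H-P.
    """
    c = mature.collapsed
    score = conservation_score(mature)
    if len(c) < 13:
        return ClassificationResult("unassigned", "none", score,
                                    c[11] if len(c) > 11 else "")
    twelfth, thirteenth = c[11], c[12]
    twelfth_ok = twelfth == "N" or (lineage in SEED_PLANT_LINEAGES and twelfth == "H")
    group, subgroup = "unassigned", "none"
    if c[6] in BASIC and c[7] in BASIC and twelfth_ok and thirteenth == "N":
        group = "R"
    elif c[7] == "H":
        group = "H"
        if c[11:13] == "PP":
            subgroup = "H-PP"
        elif thirteenth == "N":
            subgroup = "H-N"
        elif thirteenth == "P":
            subgroup = "H-P"
    return ClassificationResult(
        group=group, subgroup=subgroup, conservation_score=score,
        twelfth_residue=twelfth,
        liverwort_ssn=c[10:13] == "SSN",
        moss_terminus=c[10] in BASIC and c[11] in {"G", "S"} and thirteenth == "N",
        lycophyte_terminal_h=thirteenth == "H",
    )


# --- curation --------------------------------------------------------------

def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _locate_orf(candidate: PrecursorCandidate) -> None:
    """Fill orf bounds and the completeness flag from stop codons flanking
    the mature peptide. Protein-record subjects (frame 0) are taken as
    complete proteins."""
    seq, m = candidate.protein, candidate.mature
    anchor = m.start
    prev_stop = seq.rfind("*", 0, anchor)
    next_stop = seq.find("*", anchor + len(m.residues))
    candidate.orf_start = prev_stop + 1
    candidate.orf_end = next_stop if next_stop != -1 else len(seq)
    if candidate.frame == 0:
        candidate.completeness = "full_length"
        return
    if m.partial or next_stop == -1:
        candidate.completeness = "C_truncated"
    elif prev_stop == -1:
        candidate.completeness = "N_truncated"
    else:
        candidate.completeness = "full_length"


_identity_aligner = Align.PairwiseAligner(
    mode="global", match_score=2, mismatch_score=-1,
    open_gap_score=-4, extend_gap_score=-1)


def global_identity(a: str, b: str) -> tuple[float, int]:
    """Fraction of identical aligned residue pairs over the longer
    sequence, plus the number of aligned (residue-residue) columns."""
    if not a or not b:
        return 0.0, 0
    aln = _identity_aligner.align(a, b)[0]
    matches = aligned = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        aligned += a1 - a0
        matches += sum(1 for x, y in zip(a[a0:a1], b[b0:b1]) if x == y)
    return matches / max(len(a), len(b)), aligned


def curate_hits(hsps: Iterable[Hsp],
                proteins: Mapping[tuple[str, int], str],
                taxon: str | None = None,
                min_conservation: int = 5,
                collapse: bool = True,
                collapse_identity: float = 0.95,
                ) -> tuple[list[PrecursorCandidate], list[dict]]:
    """Fold raw Hsps into curated precursor candidates.

    Hsps from different queries landing on the same (subject, frame)
    locus are merged into one candidate; candidates without a D-Y anchor
    or whose extracted mature peptide scores below ``min_conservation``
    are dropped (with a reason row). Signal-peptide presence is never
    required. With ``collapse``, near-identical isoforms within a taxon
    (same mature peptide, >=collapse_identity precursor identity) are
    reduced to their best-scoring representative.

    ``proteins`` maps (subject_id, frame) to the subject protein string
    (the translated frame for tblastn-mode hits, frame 0 for proteins).
    """
    groups: dict[tuple[str, int], list[Hsp]] = {}
    for h in hsps:
        groups.setdefault((h.subject_id, h.frame), []).append(h)

    candidates: list[PrecursorCandidate] = []
    dropped: list[dict] = []
    for (sid, frame), hs in sorted(groups.items()):
        seq = proteins[(sid, frame)]
        loci = _merge_intervals([(h.subject_start, h.subject_end) for h in hs])
        for lo, hi in loci:
            members = tuple(h for h in hs if h.subject_start < hi and lo < h.subject_end)
            cand = PrecursorCandidate(
                taxon=taxon, source_id=sid, frame=frame, protein=seq,
                hit_start=lo, hit_end=hi, provenance=members,
                best_score=max(h.raw_score for h in members))
            try:
                cand.mature = extract_mature(cand)
            except ExtractionError:
                dropped.append({"source_id": sid, "frame": frame, "reason": "no_anchor"})
                continue
            score = conservation_score(cand.mature)
            if score < min_conservation:
                dropped.append({"source_id": sid, "frame": frame,
                                "reason": "low_conservation", "score": score})
                continue
            _locate_orf(cand)
            candidates.append(cand)

    if collapse:
        candidates = _collapse_isoforms(candidates, collapse_identity, dropped)
    return candidates, dropped


def _collapse_isoforms(candidates: list[PrecursorCandidate], threshold: float,
                       dropped: list[dict]) -> list[PrecursorCandidate]:
    kept: list[PrecursorCandidate] = []
    order = sorted(candidates, key=lambda c: (-c.best_score, c.source_id, c.frame))
    for cand in order:
        redundant = False
        for rep in kept:
            if (cand.taxon == rep.taxon
                    and cand.mature.residues == rep.mature.residues
                    and global_identity(cand.precursor, rep.precursor)[0] >= threshold):
                redundant = True
                dropped.append({"source_id": cand.source_id, "frame": cand.frame,
                                "reason": "isoform_of:" + rep.source_id})
                break
        if not redundant:
            kept.append(cand)
    kept.sort(key=lambda c: (c.source_id, c.frame, c.hit_start))
    return kept


# --- annotation ------------------------------------------------------------

def annotate_cleavage(candidate: PrecursorCandidate,
                      mature: MaturePeptide | None = None,
                      region_start: int = 19) -> CleavageAnnotation:
    """Scan the variable region between precursor position 20 (1-based)
    and the mature start for basic-residue cleavage motifs: the dibasic
    pairs RR/KR/RK/KK, or an isolated R/K followed within three residues
    by a small residue (A/G/S/T) — the signature targeted by
    subtilisin-like serine proteases."""
    mature = mature or candidate.mature
    if mature is None:
        raise ValueError("candidate has no mature peptide")
    m_start = mature.start - candidate.orf_start
    if m_start <= 0 or candidate.completeness == "N_truncated" and m_start <= region_start:
        return CleavageAnnotation((), 0, note="mature_at_precursor_start"
                                  if m_start <= 0 else "region_truncated")
    region = candidate.precursor[region_start:m_start]
    if len(region) < 1:
        return CleavageAnnotation((), 0, note="region_too_short")
    hits: list[tuple[int, str]] = []
    i = 0
    while i < len(region):
        pair = region[i:i + 2]
        if pair in DIBASIC_MOTIFS:
            hits.append((region_start + i, pair))
            i += 2
            continue
        if region[i] in BASIC and (set(region[i + 1:i + 4]) & SMALL):
            hits.append((region_start + i, region[i] + "-small"))
        i += 1
    return CleavageAnnotation(tuple(hits), len(hits))


def c_terminal_extension(candidate: PrecursorCandidate,
                         mature: MaturePeptide | None = None) -> tuple[int | None, str]:
    """Length of the tail following the mature peptide, to the stop codon
    or protein end, with a flag: 'none' (0, the Group H norm),
    'R_typical' (9-18, the Group R norm), 'long' (>20, seen for some
    terminal-PP peptides) or 'other'. C-truncated candidates: unknown."""
    mature = mature or candidate.mature
    if mature is None:
        raise ValueError("candidate has no mature peptide")
    if candidate.completeness == "C_truncated":
        return None, "unknown"
    ext = candidate.orf_end - (mature.start + len(mature.residues))
    if ext == 0:
        return 0, "none"
    if 9 <= ext <= 18:
        return ext, "R_typical"
    if ext > 20:
        return ext, "long"
    return ext, "other"


def detect_paired(candidates: Sequence[PrecursorCandidate],
                  classifications: Sequence[ClassificationResult] | None = None,
                  identity_threshold: float = 0.8,
                  min_aligned: int = 30) -> list[tuple[PrecursorCandidate, PrecursorCandidate]]:
    """Find H/R precursor pairs within a taxon that share their N-terminal
    (pre-peptide) region — the signature of a common origin such as
    alternative splicing. A pair is reported when the global identity of
    the upstream regions reaches ``identity_threshold`` over at least
    ``min_aligned`` aligned residues."""
    if classifications is None:
        classifications = [classify(c.mature) for c in candidates]
    pairs = []
    for i, ci in enumerate(candidates):
        for j, cj in enumerate(candidates):
            if classifications[i].group != "H" or classifications[j].group != "R":
                continue
            if ci.taxon != cj.taxon:
                continue
            up_i = ci.precursor[:ci.mature_start_in_precursor]
            up_j = cj.precursor[:cj.mature_start_in_precursor]
            ident, aligned = global_identity(up_i, up_j)
            if aligned >= min_aligned and ident >= identity_threshold:
                pairs.append((ci, cj))
    return pairs


# --- query construction ----------------------------------------------------

def build_query_set(entries: Sequence[tuple[str, int, MaturePeptide]],
                    context: int = 3) -> list[str]:
    """Build search queries from known matures with precursor context:
    the mature peptide plus its three preceding residues (16 residues for
    canonical 13-mers; triple-proline 14-mers yield 17 with a warning).
    Duplicates are removed, order preserved.

    ``entries`` are (precursor_protein, mature_start, mature) triples.
    """
    queries: list[str] = []
    seen: set[str] = set()
    for protein, start, mature in entries:
        if start < context:
            raise ValueError(
                f"insufficient context: mature at position {start + 1} has fewer "
                f"than {context} preceding residues")
        q = protein[start - context:start] + mature.residues
        if mature.variant == "triple_P_14":
            warnings.warn(f"triple-proline mature yields a {len(q)}-residue query")
        if q not in seen:
            seen.add(q)
            queries.append(q)
    return queries
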