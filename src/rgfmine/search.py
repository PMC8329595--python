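"""Short-query seeded local-alignment search (tblastn / blastp-short style).

Implements the word-neighborhood + two-hit + extension strategy of
protein BLAST for very short queries, with the parameterization used for
mining ~13-residue signaling-peptide motifs: word size 2, PAM30,
neighborhood threshold 16, affine gaps 9/1, two-hit window 15, at most
30 subjects reported per query. No Karlin-Altschul statistics are
computed — ranking is by raw score, and downstream curation is
conservation-based, so E-values are deliberately absent.

`sw_oracle` is an exhaustive affine-gap Smith-Waterman used as an
independent reference in tests; the seeded engine never calls it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import STANDARD_AA, SequenceRecord, TranslatedFrame, six_frame_translate

_MATRIX_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
_CHAR_INDEX = {c: i for i, c in enumerate(_MATRIX_ALPHABET)}
_X_IDX = _CHAR_INDEX["X"]
STOP_SCORE = -4  # '*' vs anything: blocks extension across stop codons


@dataclass(frozen=True)
class ScoringMatrix:
    """24-letter substitution matrix (20 aa + B, Z, X, *)."""

    name: str
    scores: np.ndarray  # (24, 24) int

    def __post_init__(self) -> None:
        s = self.scores
        assert s.shape == (24, 24) and np.array_equal(s, s.T), "matrix must be symmetric 24x24"
        assert (s[_X_IDX, :] <= 0).all(), "X must score <= 0 against everything"
        stop = _CHAR_INDEX["*"]
        assert (s[stop, :] < 0).all(), "'*' must score strictly negative"

    def index(self, residue: str) -> int:
        return _CHAR_INDEX.get(residue, _X_IDX)

    def encode(self, seq: str) -> np.ndarray:
        return np.fromiter((self.index(c) for c in seq), dtype=np.int16, count=len(seq))

    def score(self, a: str, b: str) -> int:
        return int(self.scores[self.index(a), self.index(b)])

    def self_score(self, seq: str) -> int:
        idx = self.encode(seq)
        return int(self.scores[idx, idx].sum())


def load_matrix(name: str = "PAM30") -> ScoringMatrix:
    """Load a published substitution matrix and enforce the engine's
    conventions: '*' scores ``STOP_SCORE`` against everything (including
    itself) and X never scores positive."""
    m = substitution_matrices.load(name)
    scores = np.zeros((24, 24), dtype=np.int32)
    for i, a in enumerate(_MATRIX_ALPHABET):
        for j, b in enumerate(_MATRIX_ALPHABET):
            scores[i, j] = int(m[a, b])
    scores[_CHAR_INDEX["*"], :] = STOP_SCORE
    scores[:, _CHAR_INDEX["*"]] = STOP_SCORE
    scores[_X_IDX, :] = np.minimum(scores[_X_IDX, :], 0)
    scores[:, _X_IDX] = np.minimum(scores[:, _X_IDX], 0)
    return ScoringMatrix(name=name, scores=scores)


@dataclass(frozen=True)
class SearchParams:
    """Engine parameters; defaults mirror the short-peptide tblastn set
    (-word_size 2 -gapopen 9 -gapextend 1 -matrix PAM30 -threshold 16
    -comp_based_stats 0 -window_size 15 -max_target_seqs 30)."""

    word_size: int = 2
    neighborhood_threshold: int = 16
    gap_open: int = 9
    gap_extend: int = 1
    two_hit_window: int = 15
    max_target_seqs: int = 30
    min_report_score: int | None = None  # None -> self-score * (1 - score_slack)
    score_slack: float = 0.4
    x_drop: int = 20
    band_width: int | None = 24  # subject-window radius around the seed; None = whole subject
    single_hit: bool = False

    def __post_init__(self) -> None:
        if self.word_size < 1 or self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("word_size must be >=1 and gap costs non-negative")
        if not 0.0 <= self.score_slack < 1.0:
            raise ValueError("score_slack must be in [0, 1)")

    def report_threshold(self, query: str, matrix: ScoringMatrix) -> int:
        if self.min_report_score is not None:
            return self.min_report_score
        return int(np.ceil(matrix.self_score(query) * (1.0 - self.score_slack)))


@dataclass(frozen=True)
class Hsp:
    """A high-scoring local alignment between a query and a subject
    (a protein record, or one translated frame of a transcript)."""

    query_id: str
    subject_id: str
    frame: int  # 0 for protein subjects
    query_start: int  # 0-based half-open, protein coords
    query_end: int
    subject_start: int  # protein coords within the frame / record
    subject_end: int
    raw_score: int
    aligned_query: str
    aligned_subject: str
    subject_nt_start: int | None = None  # plus-strand nt coords when framed
    subject_nt_end: int | None = None

    def rescore(self, matrix: ScoringMatrix, gap_open: int, gap_extend: int) -> int:
        """Re-score the reported alignment strings (invariant check)."""
        total, gap_side = 0, None
        for qa, sa in zip(self.aligned_query, self.aligned_subject):
            if qa == "-" or sa == "-":
                side = "q" if qa == "-" else "s"
                total -= gap_extend if gap_side == side else gap_open + gap_extend
                gap_side = side
            else:
                total += matrix.score(qa, sa)
                gap_side = None
        return total


# --- word neighborhood -----------------------------------------------------

def build_neighborhood(query: str, params: SearchParams,
                       matrix: ScoringMatrix) -> dict[str, list[int]]:
    """Map every length-w word over the 20 standard residues to the query
    positions whose word scores >= neighborhood_threshold against it."""
    w = params.word_size
    if len(query) < w:
        raise ValueError(f"query {query!r} shorter than word size {w}")
    if set(query) <= {"X"}:
        warnings.warn(f"query {query!r} contains only X; empty neighborhood")
        return {}
    index: dict[str, list[int]] = {}
    aa_idx = np.array([_CHAR_INDEX[c] for c in STANDARD_AA])
    for qpos in range(len(query) - w + 1):
        qword_idx = [matrix.index(c) for c in query[qpos:qpos + w]]
        # score of every candidate word, position by position
        per_pos = [matrix.scores[qi, aa_idx] for qi in qword_idx]
        totals = per_pos[0]
        for col in per_pos[1:]:
            totals = totals[:, None] + col[None, :]
        hits = np.argwhere(totals.reshape((len(STANDARD_AA),) * w) >= params.neighborhood_threshold)
        for combo in hits:
            word = "".join(STANDARD_AA[k] for k in combo)
            index.setdefault(word, []).append(qpos)
    return index


@dataclass(frozen=True)
class Seed:
    qpos: int
    spos: int

    @property
    def diagonal(self) -> int:
        return self.spos - self.qpos


def find_seeds(index: dict[str, list[int]], subject: str,
               params: SearchParams) -> list[Seed]:
    """Word hits grouped by diagonal; in two-hit mode a seed triggers when
    two non-overlapping hits share a diagonal within two_hit_window."""
    w = params.word_size
    hits_by_diag: dict[int, list[tuple[int, int]]] = {}
    for spos in range(len(subject) - w + 1):
        word = subject[spos:spos + w]
        for qpos in index.get(word, ()):
            hits_by_diag.setdefault(spos - qpos, []).append((spos, qpos))
    seeds: list[Seed] = []
    for diag, hits in sorted(hits_by_diag.items()):
        hits.sort()
        if params.single_hit:
            seeds.extend(Seed(q, s) for s, q in hits)
            continue
        last = None
        for s, q in hits:
            if last is not None and last + w <= s <= last + params.two_hit_window:
                seeds.append(Seed(q, s))
            last = s
    return seeds


# --- extension -------------------------------------------------------------

def _ungapped_extend(q: np.ndarray, s: np.ndarray, seed: Seed, w: int,
                     matrix: ScoringMatrix, x_drop: int) -> tuple[int, int, int]:
    """X-drop ungapped extension; returns (q_start, q_end, score)."""
    sc = matrix.scores
    score = int(sc[q[seed.qpos:seed.qpos + w], s[seed.spos:seed.spos + w]].sum())
    best = score
    # right
    qi, si = seed.qpos + w, seed.spos + w
    best_q_end = qi
    while qi < len(q) and si < len(s):
        score += int(sc[q[qi], s[si]])
        if score > best:
            best, best_q_end = score, qi + 1
        if best - score > x_drop:
            break
        qi += 1
        si += 1
    # left
    score = best
    qi, si = seed.qpos - 1, seed.spos - 1
    best_q_start = seed.qpos
    while qi >= 0 and si >= 0:
        score += int(sc[q[qi], s[si]])
        if score > best:
            best, best_q_start = score, qi
        if best - score > x_drop:
            break
        qi -= 1
        si -= 1
    return best_q_start, best_q_end, best


def _local_dp(q: np.ndarray, s: np.ndarray, matrix: ScoringMatrix,
              gap_open: int, gap_extend: int) -> tuple[int, int, int, int, int, list[str], list[str]]:
    """Affine-gap local DP (Gotoh) with traceback over the full q x s
    rectangle. Returns (score, q_start, q_end, s_start, s_end, aq, as)."""
    n, m = len(q), len(s)
    NEG = -10 ** 9
    oc = gap_open + gap_extend
    sc = matrix.scores
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query (consumes subject)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in subject (consumes query)
    for i in range(1, n + 1):
        qi = int(q[i - 1])
        Hi, Hi1, Ei, Fi, Fi1 = H[i], H[i - 1], E[i], F[i], F[i - 1]
        row = sc[qi]
        for j in range(1, m + 1):
            e = Ei[j - 1] - gap_extend
            ho = Hi[j - 1] - oc
            if ho > e:
                e = ho
            f = Fi1[j] - gap_extend
            fo = Hi1[j] - oc
            if fo > f:
                f = fo
            h = Hi1[j - 1] + int(row[int(s[j - 1])])
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j], Fi[j], Hi[j] = e, f, h
    score = int(H.max())
    if score == 0:
        return 0, 0, 0, 0, 0, [], []
    i, j = (int(v) for v in np.unravel_index(int(H.argmax()), H.shape))
    q_end, s_end = i, j
    aq: list[str] = []
    asub: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if H[i, j] == 0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sc[int(q[i - 1]), int(s[j - 1])]:
                aq.append(_MATRIX_ALPHABET[q[i - 1]])
                asub.append(_MATRIX_ALPHABET[s[j - 1]])
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aq.append("-")
            asub.append(_MATRIX_ALPHABET[s[j - 1]])
            if E[i, j] == H[i, j - 1] - oc:
                state = "H"
            j -= 1
        else:
            aq.append(_MATRIX_ALPHABET[q[i - 1]])
            asub.append("-")
            if F[i, j] == H[i - 1, j] - oc:
                state = "H"
            i -= 1
    return score, i, q_end, j, s_end, aq[::-1], asub[::-1]


def extend_seed(query: str, subject: str, seed: Seed, matrix: ScoringMatrix,
                params: SearchParams, query_id: str = "query",
                subject_id: str = "subject", frame: int = 0) -> Hsp | None:
    """Ungapped X-drop extension followed by gapped DP in a subject window
    around the ungapped HSP; returns the best local alignment there if its
    score reaches the report threshold."""
    q = matrix.encode(query)
    s = matrix.encode(subject)
    q_start, q_end, _ = _ungapped_extend(q, s, seed, params.word_size, matrix, params.x_drop)
    diag = seed.diagonal
    if params.band_width is None:
        w_lo, w_hi = 0, len(s)
    else:
        w_lo = max(0, q_start + diag - params.band_width)
        w_hi = min(len(s), q_end + diag + params.band_width)
    score, qi, qe, si, se, aq, asub = _local_dp(q, s[w_lo:w_hi], matrix,
                                               params.gap_open, params.gap_extend)
    if score < params.report_threshold(query, matrix):
        return None
    return Hsp(query_id=query_id, subject_id=subject_id, frame=frame,
               query_start=qi, query_end=qe,
               subject_start=w_lo + si, subject_end=w_lo + se,
               raw_score=score, aligned_query="".join(aq),
               aligned_subject="".join(asub))


# --- full search -----------------------------------------------------------

def _overlaps(h: Hsp, others: Iterable[Hsp]) -> bool:
    for o in others:
        if (h.subject_start < o.subject_end and o.subject_start < h.subject_end
                and h.query_start < o.query_end and o.query_start < h.query_end):
            return True
    return False


def _search_one(query: str, query_id: str, index: dict[str, list[int]],
                subject: str, subject_id: str, frame: int,
                matrix: ScoringMatrix, params: SearchParams) -> list[Hsp]:
    seeds = find_seeds(index, subject, params)
    if params.band_width is None and seeds:
        # unbounded band: the gapped stage covers the whole subject, so the
        # result is seed-independent; one extension suffices
        seeds = seeds[:1]
    hsps: list[Hsp] = []
    for seed in seeds:
        if any(h.subject_start <= seed.spos < h.subject_end
               and h.query_start <= seed.qpos < h.query_end for h in hsps):
            continue  # seed already covered by a reported alignment
        h = extend_seed(query, subject, seed, matrix, params, query_id, subject_id, frame)
        if h is not None and not _overlaps(h, hsps):
            hsps.append(h)
    return hsps


def search(queries: Sequence[SequenceRecord] | Sequence[str],
           subjects: Sequence[SequenceRecord],
           params: SearchParams | None = None,
           matrix: ScoringMatrix | None = None) -> dict[str, list[Hsp]]:
    """Search every query against every subject.

    Nucleotide subjects are searched in all six translated frames
    (tblastn mode); protein subjects directly (blastp-short mode).
    Mixing alphabets in one subject set is an error. Per query, subjects
    are ranked by their best Hsp score (ties: subject id, then start) and
    truncated to max_target_seqs subjects.
    """
    params = params or SearchParams()
    matrix = matrix or load_matrix()
    qrecs = [q if isinstance(q, SequenceRecord) else SequenceRecord(f"q{i}", q)
             for i, q in enumerate(queries)]
    alphabets = {s.alphabet for s in subjects}
    if len(alphabets) > 1:
        raise ValueError(f"mixed subject alphabets: {sorted(alphabets)}")
    translated: list[tuple[str, int, str, TranslatedFrame | None]] = []
    if alphabets == {"nucleotide"}:
        for rec in subjects:
            for fr in six_frame_translate(rec):
                if fr.residues:
                    translated.append((rec.id, fr.frame, fr.residues, fr))
    else:
        translated = [(rec.id, 0, rec.residues, None) for rec in subjects]

    results: dict[str, list[Hsp]] = {}
    for qrec in qrecs:
        index = build_neighborhood(qrec.residues, params, matrix)
        all_hsps: list[Hsp] = []
        for subject_id, frame, seq, fr in translated:
            for h in _search_one(qrec.residues, qrec.id, index, seq, subject_id,
                                 frame, matrix, params):
                if fr is not None:
                    lo, hi = fr.subject_nt_interval(h.subject_start, h.subject_end)
                    h = replace(h, subject_nt_start=lo, subject_nt_end=hi)
                all_hsps.append(h)
        # rank subjects by best score, truncate, keep deterministic order
        best: dict[str, int] = {}
        for h in all_hsps:
            best[h.subject_id] = max(best.get(h.subject_id, -10 ** 9), h.raw_score)
        kept = sorted(best, key=lambda sid: (-best[sid], sid))[:params.max_target_seqs]
        kept_set = set(kept)
        hsps = [h for h in all_hsps if h.subject_id in kept_set]
        hsps.sort(key=lambda h: (-h.raw_score, h.subject_id, h.subject_start))
        results[qrec.id] = hsps
    return results


# --- exhaustive oracle -----------------------------------------------------

def sw_oracle(query: str, subject: str, matrix: ScoringMatrix | None = None,
              gap_open: int = 9, gap_extend: int = 1) -> int:
    """Unbanded affine-gap Smith-Waterman optimum (score only).

    Written as an independent reference: straightforward row-recurrence
    Gotoh with no seeding, windowing or drop-off heuristics.
    """
    matrix = matrix or load_matrix()
    q = matrix.encode(query)
    s = matrix.encode(subject)
    n, m = len(q), len(s)
    NEG = -10 ** 9
    open_cost = gap_open + gap_extend
    prev_h = [0] * (m + 1)
    prev_f = [NEG] * (m + 1)
    best = 0
    sc = matrix.scores
    for i in range(1, n + 1):
        cur_h = [0] * (m + 1)
        cur_f = [NEG] * (m + 1)
        e = NEG
        row = sc[q[i - 1]]
        for j in range(1, m + 1):
            e = max(cur_h[j - 1] - open_cost, e - gap_extend)
            f = max(prev_h[j] - open_cost, prev_f[j] - gap_extend)
            h = max(0, prev_h[j - 1] + int(row[s[j - 1]]), e, f)
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, prev_f = cur_h, cur_f
    return best


def hit_report_rows(results: dict[str, list[Hsp]]) -> list[dict]:
    """Flatten search results to report rows (1-based inclusive coords)."""
    rows = []
    for qid in sorted(results):
        for h in results[qid]:
            rows.append({
                "query_id": h.query_id, "subject_id": h.subject_id, "frame": h.frame,
                "subject_start": h.subject_start + 1, "subject_end": h.subject_end,
                "subject_nt_start": "" if h.subject_nt_start is None else h.subject_nt_start + 1,
                "subject_nt_end": "" if h.subject_nt_end is None else h.subject_nt_end,
                "raw_score": h.raw_score,
                "aligned_query": h.aligned_query, "aligned_subject": h.aligned_subject,
            })
    return rows
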