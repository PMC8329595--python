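"""Mature-peptide extraction, conservation scoring and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rgfmine import peptide as pep
from rgfmine.peptide import (ClassificationResult, ExtractionError, MaturePeptide,
                             PrecursorCandidate, annotate_cleavage, build_query_set,
                             c_terminal_extension, classify, conservation_score,
                             curate_hits, detect_paired, extract_mature)
from rgfmine.search import Hsp
from rgfmine.seqio import STANDARD_AA

CANONICAL = "DYNSPKGHPPSNN"  # 13-mer matching all seven conserved positions


def make_candidate(protein, hit_start=0, hit_end=None, frame=1, taxon="tax"):
    return PrecursorCandidate(
        taxon=taxon, source_id="s1", frame=frame, protein=protein,
        hit_start=hit_start, hit_end=hit_end if hit_end is not None else len(protein),
        provenance=())


class TestExtractMature:
    def test_canonical_13mer(self):
        protein = "MLLKRAAAA" + "DYNSPKPHNPPSN" + "GGG"
        cand = make_candidate(protein, hit_start=9, hit_end=9 + 13)
        m = extract_mature(cand)
        assert m.residues == "DYNSPKPHNPPSN" and len(m) == 13
        assert m.variant == "canonical_13" and m.start == 9

    def test_triple_proline_14mer(self):
        pep14 = "DYNSPKPHPPPSN"  # P at 9,10,11 after extending to 14
        protein = "MAAAA" + "DYNSPKPH" + "PPP" + "LSN" + "AAA"
        cand = make_candidate(protein, hit_start=5, hit_end=5 + 14)
        m = extract_mature(cand)
        assert len(m) == 14 and m.variant == "triple_P_14"
        assert m.residues[8:11] == "PPP"

    def test_no_aspartate_fails(self):
        cand = make_candidate("MGGGGYYYGGGGGGGG")
        with pytest.raises(ExtractionError):
            extract_mature(cand)

    def test_anchor_near_end_is_partial(self):
        cand = make_candidate("MAAAADYNSPK")
        m = extract_mature(cand)
        assert m.partial and m.residues == "DYNSPK"

    def test_upstream_dy_outside_window_ignored(self):
        protein = "MDYAAAAAAAAAAAAAAAA" + CANONICAL
        cand = make_candidate(protein, hit_start=19, hit_end=19 + 13)
        assert extract_mature(cand).start == 19

    def test_stop_inside_window_skips_anchor(self):
        protein = "MAADYN*PKAAA" + CANONICAL
        cand = make_candidate(protein, hit_start=3, hit_end=len(protein))
        assert extract_mature(cand).residues == CANONICAL


class TestConservation:
    def test_full_match_scores_seven(self):
        assert conservation_score(MaturePeptide(CANONICAL, 0)) == 7

    def test_anchor_only_scores_two(self):
        assert conservation_score(MaturePeptide("DY" + "G" * 11, 0)) == 2

    def test_atrgf_like_pattern(self):
        # H at 8, N at 13, all P positions present
        assert conservation_score(MaturePeptide("DYSRPAGHPPSHN", 0)) == 7

    def test_collapsed_14mer_scored_in_13_frame(self):
        m = MaturePeptide("DYNSPKPH" + "PPP" + "LSN", 0, variant="triple_P_14")
        assert conservation_score(m) == 7

    def test_monotone_under_substitution(self, rng):
        """Substituting any canonical-set residue for a non-member never
        increases the score."""
        base = MaturePeptide(CANONICAL, 0)
        s0 = conservation_score(base)
        for i in range(13):
            for aa in "GQW":  # residues outside every diagnostic set
                mutated = CANONICAL[:i] + aa + CANONICAL[i + 1:]
                if mutated[:2] != "DY":
                    continue
                assert conservation_score(MaturePeptide(mutated, 0)) <= s0


def pep13(s):
    return MaturePeptide(s, 0)


class TestClassify:
    def test_group_h_terminal_n(self):
        r = classify(pep13("DYNSPKPHNPPSN"))
        assert (r.group, r.subgroup) == ("H", "H-N")

    def test_group_r(self):
        r = classify(pep13("DYNSPKKRPPSNN"))
        assert (r.group, r.subgroup) == ("R", "none")

    def test_group_h_pp(self):
        r = classify(pep13("DYNSPKPHPPSPP"))
        assert (r.group, r.subgroup) == ("H", "H-PP")

    def test_group_h_terminal_p(self):
        r = classify(pep13("DYNSPKPHPPSNP"))
        assert (r.group, r.subgroup) == ("H", "H-P")

    def test_unassigned(self):
        assert classify(pep13("DYNSPKPQNPPSN")).group == "unassigned"

    def test_seed_plant_twelfth_h_override(self):
        p = pep13("DYNSPKKRPPSHN")
        assert classify(p).group == "unassigned"
        assert classify(p, lineage="gymnosperm").group == "R"

    def test_lineage_flags(self):
        assert classify(pep13("DYNSPKPHPPSSN")).liverwort_ssn
        assert classify(pep13("DYNSPKPHPPRGN")).moss_terminus
        assert classify(pep13("DYNSPKPHPPSNH")).lycophyte_terminal_h

    @given(st.text(alphabet=STANDARD_AA, min_size=11, max_size=11))
    @settings(max_examples=500, deadline=None)
    def test_h_and_r_mutually_exclusive(self, body):
        """No peptide is both H and R; classification is a pure function."""
        p = pep13("DY" + body)
        r1, r2 = classify(p), classify(p)
        assert r1 == r2
        assert r1.group in {"H", "R", "unassigned"}
        if r1.group == "R":
            assert not (r1.subgroup != "none")

    def test_exclusivity_bulk(self, rng):
        letters = np.array(list(STANDARD_AA))
        bodies = rng.integers(0, 20, size=(100_000, 11))
        for row in bodies[:: max(1, len(bodies) // 100000)]:
            p = pep13("DY" + "".join(letters[row]))
            r = classify(p)
            if r.group == "R":  # the full R signature takes precedence over 8==H
                c = p.collapsed
                assert c[6] in "RK" and c[7] in "RK" and c[11] == "N" and c[12] == "N"


class TestCurate:
    def _hsp(self, sid, start, end, score=60, frame=1):
        return Hsp("q0", sid, frame, 0, end - start, start, end, score,
                   "A" * (end - start), "A" * (end - start))

    def test_overlapping_hits_merge_to_one_candidate(self):
        protein = "M" + "A" * 30 + CANONICAL + "A" * 5
        hsps = [self._hsp("s1", 28, 42), self._hsp("s1", 30, 44)]
        cands, _ = curate_hits(hsps, {("s1", 1): protein})
        assert len(cands) == 1

    def test_no_anchor_dropped_with_reason(self):
        hsps = [self._hsp("s1", 0, 10)]
        cands, dropped = curate_hits(hsps, {("s1", 1): "MGGGGGGGGGGGGGGG"})
        assert cands == [] and dropped[0]["reason"] == "no_anchor"

    def test_low_conservation_dropped(self):
        protein = "MAAA" + "DY" + "G" * 20
        cands, dropped = curate_hits([self._hsp("s1", 4, 17)], {("s1", 1): protein})
        assert cands == [] and dropped[0]["reason"] == "low_conservation"

    def test_isoform_collapse(self):
        protein = "M" + "A" * 30 + CANONICAL
        hsps = [self._hsp("s1", 30, 44), self._hsp("s2", 30, 44)]
        proteins = {("s1", 1): protein, ("s2", 1): protein}
        cands, dropped = curate_hits(hsps, proteins, taxon="t")
        assert len(cands) == 1
        assert any(d["reason"].startswith("isoform_of") for d in dropped)


class TestAnnotations:
    def _full_candidate(self, linker="A" * 30, extension=""):
        protein = "M" + "L" * 19 + linker + CANONICAL + extension
        cand = make_candidate(protein, hit_start=20 + len(linker),
                              hit_end=20 + len(linker) + 13, frame=0)
        cand.mature = extract_mature(cand)
        cand.orf_start, cand.orf_end = 0, len(protein)
        return cand

    def test_two_dibasic_motifs_counted(self):
        linker = "A" * 10 + "KR" + "A" * 10 + "RR" + "A" * 6
        ann = annotate_cleavage(self._full_candidate(linker))
        assert ann.count == 2
        assert [m for _, m in ann.positions] == ["KR", "RR"]

    def test_no_basic_residues_zero(self):
        assert annotate_cleavage(self._full_candidate("Q" * 30)).count == 0

    def test_mature_at_start_empty_with_flag(self):
        cand = make_candidate(CANONICAL + "AAA", frame=0)
        cand.mature = extract_mature(cand)
        cand.orf_start, cand.orf_end = 0, len(cand.protein)
        ann = annotate_cleavage(cand)
        assert ann.count == 0 and ann.note == "mature_at_precursor_start"

    def test_extension_flags(self):
        assert c_terminal_extension(self._full_candidate()) == (0, "none")
        assert c_terminal_extension(self._full_candidate(extension="Q" * 12)) == (12, "R_typical")
        assert c_terminal_extension(self._full_candidate(extension="Q" * 25)) == (25, "long")
        trunc = self._full_candidate()
        trunc.completeness = "C_truncated"
        assert c_terminal_extension(trunc) == (None, "unknown")


class TestPaired:
    def _candidate(self, mature13, upstream, taxon="t", sid="c"):
        protein = upstream + mature13
        cand = make_candidate(protein, hit_start=len(upstream),
                              hit_end=len(protein), frame=0, taxon=taxon)
        cand.source_id = sid
        cand.mature = extract_mature(cand)
        cand.orf_start, cand.orf_end = 0, len(protein)
        return cand

    def test_identical_nterminus_paired(self):
        up = "M" + "LAVST" * 12  # 61 shared residues
        h = self._candidate("DYNSPKPHNPPSN", up, sid="h1")
        r = self._candidate("DYNSPKKRPPSNN", up, sid="r1")
        assert detect_paired([h, r]) == [(h, r)]

    def test_half_identity_not_paired(self):
        up1 = "M" + "LAVST" * 12
        up2 = "M" + ("LA" + "GQ" + "ST") * 10  # ~50% identical
        h = self._candidate("DYNSPKPHNPPSN", up1, sid="h1")
        r = self._candidate("DYNSPKKRPPSNN", up2, sid="r1")
        assert detect_paired([h, r]) == []


class TestQuerySet:
    def test_sixteen_residues(self):
        protein = "MAAASKR" + CANONICAL
        m = extract_mature(make_candidate(protein, hit_start=7, frame=0))
        qs = build_query_set([(protein, m.start, m)])
        assert qs == ["SKR" + CANONICAL] and len(qs[0]) == 16

    def test_insufficient_context_errors(self):
        protein = "MA" + CANONICAL
        m = extract_mature(make_candidate(protein, hit_start=2, frame=0))
        with pytest.raises(ValueError, match="insufficient context"):
            build_query_set([(protein, m.start, m)])

    def test_duplicates_removed(self):
        protein = "MAAASKR" + CANONICAL
        m = extract_mature(make_candidate(protein, hit_start=7, frame=0))
        assert len(build_query_set([(protein, m.start, m)] * 2)) == 1

    def test_triple_proline_query_is_17_with_warning(self):
        protein = "MAAASKR" + "DYNSPKPH" + "PPP" + "LSN"
        m = extract_mature(make_candidate(protein, hit_start=7, frame=0))
        assert m.variant == "triple_P_14"
        with pytest.warns(UserWarning, match="17"):
            qs = build_query_set([(protein, m.start, m)])
        assert len(qs[0]) == 17
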