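"""Seeded short-query local alignment: words, seeds, extension, soundness."""

from itertools import product

import numpy as np
import pytest

from rgfmine import search as se
from rgfmine.search import Seed, SearchParams, build_neighborhood, extend_seed, find_seeds, sw_oracle
from rgfmine.seqio import STANDARD_AA, SequenceRecord


def random_protein(rng, n):
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, n))


class TestScoringMatrix:
    def test_invariants(self, pam30):
        s = pam30.scores
        assert np.array_equal(s, s.T)
        x = pam30.index("X")
        stop = pam30.index("*")
        assert (s[x, :] <= 0).all()
        assert (s[stop, :] < 0).all()

    def test_known_entries(self, pam30):
        # spot checks against the published PAM30 values
        assert pam30.score("D", "D") == 8
        assert pam30.score("Y", "Y") == 10
        assert pam30.score("W", "W") == 13
        assert pam30.score("D", "Y") == -11

    def test_unknown_residue_maps_to_x(self, pam30):
        assert pam30.score("U", "A") == pam30.score("X", "A")


class TestNeighborhood:
    def test_self_word_membership_matches_diagonal_sum(self, pam30):
        """A word is in its own neighborhood exactly when its diagonal
        pair-sum reaches the threshold."""
        params = SearchParams()
        for a, b in [("D", "Y"), ("P", "P"), ("A", "A"), ("W", "W"), ("N", "N")]:
            query = a + b
            index = build_neighborhood(query, params, pam30)
            self_score = pam30.score(a, a) + pam30.score(b, b)
            assert (query in index) == (self_score >= params.neighborhood_threshold)

    def test_dy_neighborhood_equals_bruteforce(self, pam30):
        """Neighborhood of 'DY' == all dipeptides w with
        PAM30(D,w1)+PAM30(Y,w2) >= 16, enumerated exhaustively."""
        params = SearchParams()
        index = build_neighborhood("DY", params, pam30)
        expected = {w1 + w2 for w1, w2 in product(STANDARD_AA, repeat=2)
                    if pam30.score("D", w1) + pam30.score("Y", w2) >= 16}
        assert set(index) == expected
        assert all(positions == [0] for positions in index.values())

    def test_infinite_threshold_empty(self, pam30):
        params = SearchParams(neighborhood_threshold=10 ** 6)
        assert build_neighborhood("DYNSPKPHNPPSN", params, pam30) == {}

    def test_all_x_query_warns_empty(self, pam30):
        with pytest.warns(UserWarning):
            assert build_neighborhood("XXX", SearchParams(), pam30) == {}


QUERY = "SKRDYSNPKGHPPSNN"  # motif-style 16-mer with several high-scoring words


class TestSeeds:
    def test_exact_copy_triggers(self, pam30):
        params = SearchParams()
        index = build_neighborhood(QUERY, params, pam30)
        subject = "AAAAA" + QUERY + "AAAAA"
        seeds = find_seeds(index, subject, params)
        assert any(s.diagonal == 5 for s in seeds)

    def test_distant_hits_do_not_trigger(self, pam30):
        """Two word hits on one diagonal separated by more than the two-hit
        window do not trigger."""
        params = SearchParams()
        index = build_neighborhood("DYAAAAAAAAAAAAAAAAAAAADY", params, pam30)
        # subject shares the two DY words on one diagonal, 22 apart (> 15)
        subject = "DYGGGGGGGGGGGGGGGGGGGGDY"
        assert find_seeds(index, subject, params) == []

    def test_single_hit_mode(self, pam30):
        params = SearchParams(single_hit=True)
        index = build_neighborhood("DY", params, pam30)
        assert find_seeds(index, "GGDYGG", params) == [Seed(0, 2)]


class TestExtension:
    def test_exact_copy_scores_self_score(self, pam30):
        params = SearchParams()
        subject = "AAAA" + QUERY + "AAAA"
        h = extend_seed(QUERY, subject, Seed(3, 7), pam30, params)
        assert h is not None
        assert h.raw_score == pam30.self_score(QUERY)
        assert h.aligned_query == h.aligned_subject == QUERY

    def test_single_deletion_costs_open_plus_extend(self, pam30):
        """Subject missing one internal residue: gapped score equals the
        ungapped self-score minus (gap_open + 1*gap_extend) = 10."""
        subject = "AAAA" + QUERY[:8] + QUERY[9:] + "AAAA"
        h = extend_seed(QUERY, subject, Seed(3, 7), pam30,
                        SearchParams(min_report_score=20))
        expected = pam30.self_score(QUERY) - pam30.score(QUERY[8], QUERY[8]) - (9 + 1)
        assert h is not None and h.raw_score == expected
        assert "-" in h.aligned_subject

    def test_all_x_region_yields_nothing(self, pam30):
        h = extend_seed(QUERY, "X" * 40, Seed(0, 10), pam30, SearchParams())
        assert h is None

    def test_reported_alignment_rescores_to_raw_score(self, pam30, rng):
        """Invariant: the aligned strings re-score to raw_score under the
        matrix + affine gap model."""
        params = SearchParams(min_report_score=25, single_hit=True)
        for _ in range(50):
            q = random_protein(rng, 16)
            sub = list(random_protein(rng, 80))
            pos = int(rng.integers(0, 60))
            sub[pos:pos + 16] = list(q)
            if rng.random() < 0.5:  # introduce an indel
                del sub[pos + 8]
            subject = "".join(sub)
            index = build_neighborhood(q, params, pam30)
            for seed in find_seeds(index, subject, params)[:3]:
                h = extend_seed(q, subject, seed, pam30, params)
                if h is not None:
                    assert h.rescore(pam30, params.gap_open, params.gap_extend) == h.raw_score


class TestSearch:
    def _transcript_with(self, query_protein, frame_offset=1):
        """Nucleotide record carrying the reverse-translated query in +2."""
        from rgfmine.synthetic import reverse_translate
        rng = np.random.default_rng(5)
        cds = reverse_translate(query_protein, rng)
        return SequenceRecord("tx", "G" * frame_offset + cds + "GG", "nucleotide")

    def test_embedded_query_found_in_frame(self, pam30):
        rec = self._transcript_with(QUERY, frame_offset=1)
        res = se.search([QUERY], [rec], SearchParams(), pam30)
        top = res["q0"][0]
        assert top.subject_id == "tx" and top.frame == 2
        assert top.raw_score == pam30.self_score(QUERY)
        assert top.subject_nt_start is not None

    def test_max_target_seqs_truncates(self, pam30):
        subjects = [SequenceRecord(f"s{i:02d}", "AAAA" + QUERY + "AAAA")
                    for i in range(40)]
        res = se.search([QUERY], subjects, SearchParams(), pam30)
        assert len({h.subject_id for h in res["q0"]}) == 30

    def test_no_hits_below_threshold(self, pam30):
        res = se.search([QUERY], [SequenceRecord("s", "GGGGGGGGGGGG")],
                        SearchParams(), pam30)
        assert res["q0"] == []

    def test_mixed_alphabets_rejected(self, pam30):
        subs = [SequenceRecord("a", "ACGT", "nucleotide"), SequenceRecord("b", "MD")]
        with pytest.raises(ValueError, match="mixed"):
            se.search([QUERY], subs, SearchParams(), pam30)

    def test_determinism(self, pam30, rng):
        subjects = [SequenceRecord(f"s{i}", random_protein(rng, 60) + QUERY)
                    for i in range(5)]
        r1 = se.search([QUERY], subjects, SearchParams(), pam30)
        r2 = se.search([QUERY], subjects, SearchParams(), pam30)
        assert se.hit_report_rows(r1) == se.hit_report_rows(r2)


class TestOracle:
    def test_self_alignment(self, pam30):
        assert sw_oracle(QUERY, QUERY, pam30) == pam30.self_score(QUERY)

    def test_all_negative_is_zero(self, pam30):
        assert sw_oracle("DDDD", "GGGG", pam30) == 0

    def test_engine_never_beats_oracle(self, pam30, rng):
        """Soundness at default (banded, two-hit) settings: every reported
        score <= the exhaustive Smith-Waterman optimum."""
        params = SearchParams(min_report_score=20)
        for _ in range(100):
            q = random_protein(rng, 16)
            sub = list(random_protein(rng, 120))
            pos = int(rng.integers(0, 100))
            copy = list(q)
            for i in range(16):
                if rng.random() < 0.2:
                    copy[i] = STANDARD_AA[int(rng.integers(20))]
            sub[pos:pos + 16] = copy
            subject = "".join(sub)
            res = se.search([q], [SequenceRecord("s", subject)], params, pam30)
            oracle = sw_oracle(q, subject, pam30)
            for h in res["q0"]:
                assert h.raw_score <= oracle
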