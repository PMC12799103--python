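import numpy as np
import pytest

import jdpevo as J
from jdpevo import hmm
from jdpevo.io import AMINO_ACIDS

from _oracles import enumerate_profile_paths, path_posteriors
from conftest import random_small_model


def encode(seq):
    return np.array([AMINO_ACIDS.index(a) for a in seq], dtype=np.int64)


def random_sequence(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


class TestBuildProfile:
    def test_consensus_dominates_identical_seed(self, toy_profile):
        assert toy_profile.length == 3
        assert AMINO_ACIDS[toy_profile.match_emissions[1].argmax()] == "P"

    def test_occupancy_threshold_defines_match_columns(self):
        block = J.AlignmentBlock(["a", "b", "c"], ["AC-D", "AC-E", "ACFD"])
        model = J.build_profile(block, match_occupancy_threshold=0.5, weighting="none")
        assert model.length == 3
        assert list(model.match_column_map) == [0, 1, 3]

    def test_all_gap_seed_rejected(self):
        block = J.AlignmentBlock(["a", "b"], ["--", "--"])
        with pytest.raises(ValueError, match="no match columns"):
            J.build_profile(block)

    def test_single_row_seed_rejected(self):
        block = J.AlignmentBlock(["a"], ["ACD"])
        with pytest.raises(ValueError, match="single-row"):
            J.build_profile(block)

    def test_row_order_invariance_without_weighting(self):
        rows = ["ACDE", "AC-E", "GCDE", "ACDF"]
        b1 = J.AlignmentBlock(list("abcd"), rows)
        b2 = J.AlignmentBlock(list("dcba"), rows[::-1])
        m1 = J.build_profile(b1, weighting="none")
        m2 = J.build_profile(b2, weighting="none")
        assert np.allclose(m1.match_emissions, m2.match_emissions)
        for key in m1.transitions:
            assert np.allclose(m1.transitions[key], m2.transitions[key])

    def test_emission_and_transition_rows_normalised(self, toy_profile):
        # exercised by the ProfileHMM validator; also check directly
        assert np.allclose(toy_profile.match_emissions.sum(axis=1), 1.0, atol=1e-12)


class TestForward:
    def test_consensus_scores_above_null(self, toy_profile):
        assert J.forward_score(toy_profile, J.ProteinRecord("q", "HPD")) > 0

    def test_order_sensitivity(self, toy_profile):
        fwd = J.forward_score(toy_profile, J.ProteinRecord("q", "HPD"))
        rev = J.forward_score(toy_profile, J.ProteinRecord("q", "DPH"))
        assert fwd > rev

    def test_empty_sequence_is_error(self, toy_profile):
        with pytest.raises(ValueError):
            J.forward_score(toy_profile, J.ProteinRecord("q", ""))

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 25:
            try:
                model = random_small_model(rng, max_cols=4)
            except ValueError:
                continue
            if model.length > 4:
                continue
            seq = random_sequence(rng, int(rng.integers(1, 6)))
            rec = J.ProteinRecord("q", seq)
            paths = enumerate_profile_paths(model, encode(seq))
            total = sum(p for p, _ in paths)
            ll = hmm.forward_log_likelihood(model, rec)
            assert ll == pytest.approx(np.log(total), abs=1e-10)
            checked += 1

    def test_forward_equals_backward_on_random_pairs(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 100:
            try:
                model = random_small_model(rng, max_cols=6)
            except ValueError:
                continue
            rec = J.ProteinRecord("q", random_sequence(rng, int(rng.integers(1, 9))))
            f = hmm.forward_log_likelihood(model, rec)
            b = hmm.backward_log_likelihood(model, rec)
            assert b == pytest.approx(f, rel=1e-8)
            checked += 1


class TestViterbi:
    def test_consensus_gives_all_match_path(self, toy_profile):
        hit = J.viterbi_align(toy_profile, J.ProteinRecord("q", "HPD"))
        assert [s for s, _ in hit.viterbi_path] == ["M", "M", "M"]
        assert list(hit.match_assignment) == [0, 1, 2]
        assert hit.aligned_span == (0, 3)

    def test_deleted_residue_yields_single_delete_state(self):
        block = J.AlignmentBlock(["a", "b", "c"], ["HPDW"] * 3)
        model = J.build_profile(
            block, pseudocount_weight=0.1, weighting="none", flank_expected_len=None
        )
        hit = J.viterbi_align(model, J.ProteinRecord("q", "HPW"))
        states = [s for s, _ in hit.viterbi_path]
        assert states.count("D") == 1 and states.count("M") == 3

    def test_tie_break_prefers_match_over_delete(self):
        # uniform emissions and symmetric transitions make M and D+I paths tie
        block = J.AlignmentBlock(["a", "b"], ["AC", "AC"])
        model = J.build_profile(
            block, pseudocount_weight=1e6, weighting="none", flank_expected_len=None
        )
        t = model.transitions
        for key in t:
            t[key][:] = 1.0 / 3.0
        t["md"][-1] = 0.0
        t["id"][-1] = 0.0
        t["mm"][-1] = t["mi"][-1] = 0.5
        t["im"][-1] = t["ii"][-1] = 0.5
        t["dm"][-1] = t["di"][-1] = 0.5
        t["dd"][-1] = 0.0
        model.__dict__.pop("_log_cache", None)
        hit = J.viterbi_align(model, J.ProteinRecord("q", "GG"))
        assert [s for s, _ in hit.viterbi_path] == ["M", "M"]

    def test_viterbi_never_exceeds_forward(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 30:
            try:
                model = random_small_model(rng)
            except ValueError:
                continue
            rec = J.ProteinRecord("q", random_sequence(rng, int(rng.integers(1, 8))))
            hit = J.viterbi_align(model, rec)
            assert hit.viterbi_bits <= hit.bit_score + 1e-9
            checked += 1

    def test_viterbi_matches_enumeration_maximum(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 20:
            try:
                model = random_small_model(rng, max_cols=4)
            except ValueError:
                continue
            if model.length > 4:
                continue
            seq = random_sequence(rng, int(rng.integers(1, 6)))
            rec = J.ProteinRecord("q", seq)
            paths = enumerate_profile_paths(model, encode(seq))
            best = max(p for p, _ in paths)
            null = sum(np.log(model.background[a]) for a in encode(seq))
            hit = J.viterbi_align(model, rec)
            assert hit.viterbi_bits * np.log(2) + null == pytest.approx(
                np.log(best), abs=1e-10
            )
            checked += 1


class TestPosteriorDecode:
    def test_forced_path_has_confident_match_posteriors(self):
        # a deep identical seed makes both emissions and transitions sharp
        block = J.AlignmentBlock([f"s{i}" for i in range(20)], ["HPDWK"] * 20)
        model = J.build_profile(
            block, pseudocount_weight=0.01, weighting="none", flank_expected_len=None
        )
        post = J.posterior_decode(model, J.ProteinRecord("q", "HPDWK"))
        assert all(post.p_match[i, i] >= 0.99 for i in range(5))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 20:
            try:
                model = random_small_model(rng)
            except ValueError:
                continue
            rec = J.ProteinRecord("q", random_sequence(rng, int(rng.integers(1, 8))))
            post = J.posterior_decode(model, rec)
            assert np.allclose(post.p_match.sum(axis=1) + post.p_insert, 1.0, atol=1e-8)
            checked += 1

    def test_matches_enumeration_posteriors(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 20:
            try:
                model = random_small_model(rng, max_cols=4)
            except ValueError:
                continue
            if model.length > 4:
                continue
            seq = random_sequence(rng, int(rng.integers(1, 6)))
            rec = J.ProteinRecord("q", seq)
            paths = enumerate_profile_paths(model, encode(seq))
            pm, pi, pd, _ = path_posteriors(paths, len(seq), model.length)
            post = J.posterior_decode(model, rec)
            assert np.allclose(pm, post.p_match, atol=1e-10)
            assert np.allclose(pi, post.p_insert, atol=1e-10)
            assert np.allclose(pd, post.p_delete, atol=1e-10)
            checked += 1


class TestSearch:
    @pytest.fixture()
    def family(self, toy_profile):
        rng = np.random.default_rng(0)
        block = J.AlignmentBlock(["a", "b", "c"], ["HPDWKELF"] * 3)
        model = J.build_profile(block, pseudocount_weight=0.1, weighting="none")
        consensus = J.ProteinRecord("cons", "HPDWKELF")
        shuffles = []
        for i in range(3):
            letters = list("HPDWKELF")
            rng.shuffle(letters)
            shuffles.append(J.ProteinRecord(f"shuf{i}", "".join(letters)))
        return model, [consensus] + shuffles

    def test_threshold_retrieves_only_consensus(self, family):
        model, records = family
        hits = J.search_profile(model, records, bit_threshold=10.0)
        assert [h.record_id for h in hits] == ["cons"]

    def test_minus_infinity_returns_all_sorted(self, family):
        model, records = family
        hits = J.search_profile(model, records, bit_threshold=-np.inf)
        assert len(hits) == len(records)
        scores = [h.bit_score for h in hits]
        assert scores == sorted(scores, reverse=True)

    def test_plus_infinity_returns_none(self, family):
        model, records = family
        assert J.search_profile(model, records, bit_threshold=np.inf) == []

    def test_empty_record_list(self, family):
        model, _ = family
        assert J.search_profile(model, [], bit_threshold=0.0) == []


class TestSerialization:
    def test_round_trip(self, tmp_path, toy_profile):
        p = tmp_path / "toy.hmm"
        J.write_profile(toy_profile, p)
        back = J.read_profile(p)
        assert back.length == toy_profile.length
        assert np.allclose(back.match_emissions, toy_profile.match_emissions, atol=1e-5)
        rec = J.ProteinRecord("q", "HPD")
        assert J.forward_score(back, rec) == pytest.approx(
            J.forward_score(toy_profile, rec), abs=1e-3
        )
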