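import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpcrminer import hmm
from gpcrminer.seqio import AMINO_ACIDS, SequenceRecord

from oracle import consensus_oracle, enumerate_scores


class TestBuildProfile:
    def test_single_ungapped_sequence(self):
        p = hmm.build_profile(["ACD"])
        assert p.n_match == 3
        for k, aa in enumerate("ACD"):
            assert np.argmax(p.match_emissions[k]) == AMINO_ACIDS.index(aa)

    def test_gap_fraction_boundary_is_match(self):
        # column 2 gap fraction exactly 0.5 <= 0.5 -> match state
        p = hmm.build_profile(["A-", "AC"])
        assert p.n_match == 2

    def test_laplace_smoothing(self):
        # column counts {A:3, G:1}, pseudocount 1 -> P(A) = 4/24
        p = hmm.build_profile(["A", "A", "A", "G"])
        assert p.match_emissions[0, AMINO_ACIDS.index("A")] == \
            pytest.approx(4 / 24)
        assert p.match_emissions[0, AMINO_ACIDS.index("G")] == \
            pytest.approx(2 / 24)
        assert p.match_emissions[0, AMINO_ACIDS.index("C")] == \
            pytest.approx(1 / 24)

    def test_zero_match_columns_is_error(self):
        with pytest.raises(hmm.ProfileError, match="match"):
            hmm.build_profile(["--A", "-A-", "A--"])

    def test_normalisation_invariants(self, toy_profiles):
        for p in toy_profiles:
            assert np.allclose(p.match_emissions.sum(axis=1), 1.0)
            for j in range(1, p.n_match):
                assert p.t_mm[j] + p.t_mi[j] + p.t_md[j] == \
                    pytest.approx(1.0)


class TestViterbiOracle:
    """DP scores must equal exhaustive path enumeration on toy HMMs."""

    def test_viterbi_and_forward_match_enumeration(self, toy_profiles):
        rng = np.random.default_rng(7)
        for p in toy_profiles:
            targets = ["".join(AMINO_ACIDS[i] for i in
                               rng.integers(0, 20, size=n))
                       for n in (1, 2, 3, 4, 5, 6) for _ in range(2)]
            targets.append(hmm.emit_consensus(p))
            for t in targets:
                if len(t) > 6:
                    continue
                vit_o, fwd_o = enumerate_scores(p, t)
                vit = hmm.viterbi_bits(p, t)
                fwd = hmm.forward_score(p, t)
                assert vit == pytest.approx(vit_o, abs=1e-9)
                assert fwd == pytest.approx(fwd_o, abs=1e-9)
                assert fwd >= vit - 1e-12

    def test_align_agrees_with_score(self, toy_profiles):
        for p in toy_profiles:
            hit = hmm.viterbi_align(p, "ACDEFG")
            assert hit.bit_score == pytest.approx(
                hmm.viterbi_bits(p, "ACDEFG"), abs=1e-9)
            assert 1 <= hit.env_start <= hit.env_end <= 6

    def test_single_forced_path_forward_equals_viterbi(self):
        # one match state: entry is the only path per start position,
        # but multiple starts exist; a 1-residue target forces one path
        p = hmm.build_profile(["A"] * 5)
        assert hmm.forward_score(p, "A") == \
            pytest.approx(hmm.viterbi_bits(p, "A"), abs=1e-12)

    def test_consensus_beats_shuffles(self):
        rng = np.random.default_rng(11)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 40))
                for _ in range(1)] * 6
        p = hmm.build_profile(rows, name="fam")
        cons = hmm.emit_consensus(p)
        ref = hmm.viterbi_bits(p, cons)
        wins = 0
        for k in range(40):
            shuf = "".join(rng.permutation(list(cons)))
            wins += ref > hmm.viterbi_bits(p, shuf)
        assert wins >= 38  # 95%+ of shuffles score lower


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_forward_ge_viterbi_property(seed):
    """log-sum over paths is never below the best single path."""
    rng = np.random.default_rng(seed)
    ncol = int(rng.integers(2, 8))
    rows = ["".join(AMINO_ACIDS[i] if rng.random() > 0.2 else "-"
                    for i in rng.integers(0, 20, size=ncol))
            for _ in range(4)]
    rows = ["A" + r[1:] for r in rows]
    try:
        p = hmm.build_profile(rows)
    except hmm.ProfileError:
        return
    target = "".join(AMINO_ACIDS[i]
                     for i in rng.integers(0, 20, size=rng.integers(1, 15)))
    assert hmm.forward_score(p, target) >= \
        hmm.viterbi_bits(p, target) - 1e-9


@pytest.fixture(scope="module")
def calibrated():
    rng = np.random.default_rng(3)
    rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))]
    p = hmm.build_profile(rows * 5, name="cal")
    return hmm.calibrate_evalue(p, n_random=200, length=80, seed=42)


class TestCalibration:

    def test_same_seed_same_parameters(self, calibrated):
        rng = np.random.default_rng(3)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))]
        p = hmm.build_profile(rows * 5, name="cal")
        again = hmm.calibrate_evalue(p, n_random=200, length=80, seed=42)
        assert again.gumbel_lambda == calibrated.gumbel_lambda
        assert again.gumbel_mu == calibrated.gumbel_mu

    def test_calibration_does_not_mutate_emissions(self, calibrated):
        rng = np.random.default_rng(3)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))]
        p = hmm.build_profile(rows * 5, name="cal")
        assert np.array_equal(p.match_emissions,
                              calibrated.match_emissions)
        assert np.array_equal(p.t_mm, calibrated.t_mm)

    def test_evalue_monotone_and_linear_in_db_size(self, calibrated):
        scores = [5.0, 10.0, 20.0, 40.0]
        es = [hmm.evalue(calibrated, s, 100) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert hmm.evalue(calibrated, 10.0, 200) == \
            pytest.approx(2 * hmm.evalue(calibrated, 10.0, 100))

    def test_evalue_at_mu(self, calibrated):
        assert hmm.evalue(calibrated, calibrated.gumbel_mu, 1) == \
            pytest.approx(1 - math.exp(-1))

    def test_evalue_vanishes_at_high_score(self, calibrated):
        assert hmm.evalue(calibrated, 1e4, 100) < 1e-12

    def test_log10_evalue_matches_direct_log(self, calibrated):
        for s in (5.0, 15.0):
            e = hmm.evalue(calibrated, s, 50)
            assert hmm.log10_evalue(calibrated, s, 50) == \
                pytest.approx(math.log10(e), abs=1e-9)

    def test_max_null_score_has_evalue_near_one(self):
        # by construction of the fitted null, the best of n random
        # scores has E (at db = n) within an order of magnitude of 1
        rng = np.random.default_rng(5)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 40))]
        p = hmm.build_profile(rows * 5, name="null")
        pc = hmm.calibrate_evalue(p, n_random=500, length=100, seed=9)
        obs = rng.choice(20, size=(500, 100), p=pc.background)
        best = max(hmm.viterbi_bits(
            pc, "".join(AMINO_ACIDS[i] for i in row)) for row in obs)
        e = hmm.evalue(pc, best, 500)
        assert 0.1 <= e <= 10.0

    def test_uncalibrated_profile_is_error(self):
        p = hmm.build_profile(["ACD"] * 3)
        with pytest.raises(hmm.ProfileError, match="calibrated"):
            hmm.evalue(p, 1.0, 10)

    def test_gumbel_fit_recovery(self):
        from scipy import stats
        draws = stats.gumbel_r.rvs(loc=-5.0, scale=1 / 0.7, size=1000,
                                   random_state=1)
        lam, mu = hmm.fit_gumbel(draws)
        assert abs(lam - 0.7) / 0.7 < 0.10
        assert abs(mu - (-5.0)) < 0.5


class TestConsensus:
    def test_identical_inputs_reproduced(self):
        for n in (1, 2, 5):
            p = hmm.build_profile(["MKTW"] * n)
            assert hmm.emit_consensus(p) == "MKTW"

    def test_matches_column_argmax_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            ncol = int(rng.integers(3, 12))
            rows = ["".join(AMINO_ACIDS[i] if rng.random() > 0.25 else "-"
                            for i in rng.integers(0, 20, size=ncol))
                    for _ in range(6)]
            rows = ["C" + r[1:] for r in rows]
            try:
                p = hmm.build_profile(rows)
            except hmm.ProfileError:
                continue
            assert hmm.emit_consensus(p) == consensus_oracle(rows)


class TestSampling:
    def test_reproducible(self):
        p = hmm.build_profile(["ACDEFGHIKL"] * 8)
        assert hmm.sample_sequence(p, seed=5).sequence == \
            hmm.sample_sequence(p, seed=5).sequence

    def test_samples_score_above_shuffles(self):
        rng = np.random.default_rng(17)
        rows = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 50))]
        p = hmm.build_profile(rows * 10, name="fam")
        scores, shuf_scores = [], []
        for k in range(50):
            s = hmm.sample_sequence(p, seed=k).sequence
            scores.append(hmm.viterbi_bits(p, s))
            shuf_scores.append(hmm.viterbi_bits(
                p, "".join(rng.permutation(list(s)))))
        assert np.mean(scores) > np.mean(shuf_scores)

    def test_length_near_n_match(self):
        p = hmm.build_profile(["ACDEFGHIKLMNPQRSTVWY"] * 10)
        lens = [len(hmm.sample_sequence(p, seed=k).sequence)
                for k in range(50)]
        assert abs(np.mean(lens) - p.n_match) < 3


@pytest.fixture(scope="module")
def two_profiles():
    rng = np.random.default_rng(23)
    a = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))
    b = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 30))
    pa = hmm.calibrate_evalue(hmm.build_profile([a] * 6, name="domA"),
                              n_random=150, length=80, seed=1)
    pb = hmm.calibrate_evalue(hmm.build_profile([b] * 6, name="domB"),
                              n_random=150, length=80, seed=2)
    return pa, pb, a, b


class TestScan:

    def test_non_overlapping_hits_both_kept(self, two_profiles):
        pa, pb, a, b = two_profiles
        seq = a + "GSGSGSGSGS" + b
        hits = hmm.scan_best_domains([pa, pb], seq, report_cutoff=1e-3,
                                     db_size=1)
        assert [h.model_name for h in hits] == ["domA", "domB"]
        assert hits[0].env_end < hits[1].env_start

    def test_overlapping_region_keeps_best_only(self, two_profiles):
        pa, pb, a, b = two_profiles
        # target IS profile A's consensus: both models align over the
        # same region, only the lower-E hit survives
        hits = hmm.scan_best_domains([pa, pb], a, report_cutoff=10.0,
                                     db_size=1)
        strong = [h for h in hits if h.model_name == "domA"]
        assert strong and strong[0].evalue < 1e-6
        for h in hits:
            if h.model_name == "domB":
                ov = (min(h.env_end, strong[0].env_end)
                      - max(h.env_start, strong[0].env_start) + 1)
                assert ov <= 0.5 * min(h.length, strong[0].length)

    def test_random_background_yields_nothing_strict(self, two_profiles):
        pa, pb, *_ = two_profiles
        rng = np.random.default_rng(31)
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 200))
        assert hmm.scan_best_domains([pa, pb], seq, report_cutoff=1e-3,
                                     db_size=1) == []


class TestSerialization:
    def test_round_trip(self, tmp_path, toy_profiles):
        p = hmm.calibrate_evalue(toy_profiles[-1], n_random=120,
                                 length=50, seed=3)
        path = tmp_path / "p.hmmtxt"
        hmm.write_profile(p, path)
        back = hmm.read_profile(path)
        assert back.name == p.name
        assert np.array_equal(back.match_emissions, p.match_emissions)
        assert np.array_equal(back.t_mm, p.t_mm)
        assert back.gumbel_lambda == p.gumbel_lambda
        seq = "ACDEFGHIKL"
        assert hmm.viterbi_bits(back, seq) == \
            pytest.approx(hmm.viterbi_bits(p, seq), abs=1e-12)


def test_pyhmmer_cross_check_discrimination():
    """Our engine and pyhmmer agree on who is family and who is noise.

    Conventions differ (null models, priors), so the cross-check is on
    discrimination: both engines must score every family sample above
    every length-matched random sequence.
    """
    pyhmmer = pytest.importorskip("pyhmmer")
    rng = np.random.default_rng(41)
    consensus = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 60))
    rows = []
    for _ in range(12):
        rows.append("".join(
            c if rng.random() > 0.15 else AMINO_ACIDS[rng.integers(20)]
            for c in consensus))
    ours = hmm.build_profile(rows, name="fam")

    alphabet = pyhmmer.easel.Alphabet.amino()
    seqs = [pyhmmer.easel.TextSequence(name=f"s{i}".encode(), sequence=r)
            for i, r in enumerate(rows)]
    msa = pyhmmer.easel.TextMSA(name=b"fam", sequences=seqs).digitize(
        alphabet)
    builder = pyhmmer.plan7.Builder(alphabet)
    hmm_p, _, _ = builder.build_msa(msa, pyhmmer.plan7.Background(alphabet))

    members = ["".join(
        c if rng.random() > 0.15 else AMINO_ACIDS[rng.integers(20)]
        for c in consensus) for _ in range(10)]
    noise = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 60))
             for _ in range(10)]

    def pyhmmer_score(seq):
        dsq = pyhmmer.easel.TextSequence(
            name=b"q", sequence=seq).digitize(alphabet)
        pipeline = pyhmmer.plan7.Pipeline(alphabet, bias_filter=False,
                                          F1=1.0, F2=1.0, F3=1.0)
        hits = pipeline.search_hmm(hmm_p, pyhmmer.easel.DigitalSequenceBlock(
            alphabet, [dsq]))
        return hits[0].score if len(hits) else -100.0

    ours_members = [hmm.viterbi_bits(ours, s) for s in members]
    ours_noise = [hmm.viterbi_bits(ours, s) for s in noise]
    py_members = [pyhmmer_score(s) for s in members]
    py_noise = [pyhmmer_score(s) for s in noise]
    assert min(ours_members) > max(ours_noise)
    assert min(py_members) > max(py_noise)
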