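"""Profile construction, forward-algorithm exactness, E-value calibration,
and dual-model classification."""

import math

import numpy as np
import pytest

from bshscan import hmmclass, simulate
from bshscan.errors import CalibrationError, ConstructionError
from bshscan.hmmclass import _AA_INDEX
from bshscan.seqio import AA20, Msa, ProteinRecord


def brute_force_logprob(hmm: hmmclass.ProfileHmm, seq: str) -> float:
    """Exhaustive sum over every state path (tiny models only)."""
    M = hmm.n_match
    T = hmm.transitions.copy()
    T[0, 2, :] = 0.0
    em, ei = hmm.match_emissions, hmm.insert_emissions
    x = [_AA_INDEX[c] for c in seq]
    total = 0.0

    def rec(state, node, i, p):
        nonlocal total
        if p == 0.0:
            return
        s = {"M": 0, "I": 1, "D": 2}[state]
        p_next_m = T[node, s, 0]
        if node == M:
            if i == len(x):
                total += p * p_next_m
        elif i < len(x):
            rec("M", node + 1, i + 1, p * p_next_m * em[node, x[i]])
        if i < len(x):
            rec("I", node, i + 1, p * T[node, s, 1] * ei[node, x[i]])
        if node < M:
            rec("D", node + 1, i, p * T[node, s, 2])

    rec("M", 0, 0, 1.0)
    return math.log(total)


def random_toy_hmm(n_match: int, seed: int) -> hmmclass.ProfileHmm:
    rng = np.random.default_rng(seed)

    def simplex(shape):
        a = rng.random(shape) + 0.05
        return a / a.sum(axis=-1, keepdims=True)

    trans = np.zeros((n_match + 1, 3, 3))
    for node in range(n_match + 1):
        targets = (0, 1) if node == n_match else (0, 1, 2)
        sources = (0, 1) if node == 0 else (0, 1, 2)
        for s in sources:
            row = simplex(len(targets))
            for t_idx, t in enumerate(targets):
                trans[node, s, t] = row[t_idx]
    return hmmclass.ProfileHmm(
        name="toy",
        match_emissions=simplex((n_match, 20)),
        insert_emissions=simplex((n_match + 1, 20)),
        transitions=trans,
        background=simplex(20),
    )


class TestMatchColumnSelection:
    def test_gapless_alignment_all_match(self):
        msa = Msa(rows=(("a", "MCD"), ("b", "MCE")))
        assert hmmclass.select_match_columns(msa) == [0, 1, 2]

    def test_half_gapped_column_is_insert(self):
        # 2 gaps of 4 rows: gap fraction 0.5 is not < 0.5.
        msa = Msa(rows=(("a", "MC"), ("b", "M-"), ("c", "MD"), ("d", "M-")))
        assert hmmclass.select_match_columns(msa, 0.5) == [0]

    def test_matches_gap_counting_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n_rows, n_cols = int(rng.integers(2, 8)), int(rng.integers(1, 15))
            rows = tuple(
                (
                    f"r{i}",
                    "".join(
                        "-" if rng.random() < 0.35 else AA20[rng.integers(20)]
                        for _ in range(n_cols)
                    ),
                )
                for i in range(n_rows)
            )
            msa = Msa(rows=rows)
            expected = [
                j
                for j in range(n_cols)
                if sum(r[1][j] == "-" for r in rows) / n_rows < 0.5
            ]
            if not expected:
                with pytest.raises(ConstructionError):
                    hmmclass.select_match_columns(msa)
            else:
                assert hmmclass.select_match_columns(msa) == expected

    def test_all_gap_alignment_rejected(self):
        msa = Msa(rows=(("a", "--"), ("b", "--")))
        with pytest.raises(ConstructionError):
            hmmclass.select_match_columns(msa)


class TestEstimateParameters:
    def test_laplace_emission_formula(self):
        """Three identical sequences, a column of C: P(C) = (3+1)/(3+20)."""
        msa = Msa(rows=(("a", "C"), ("b", "C"), ("c", "C")))
        hmm = hmmclass.estimate_parameters(msa, [0])
        assert hmm.match_emissions[0, _AA_INDEX["C"]] == pytest.approx(4 / 23)

    def test_hand_tallied_toy_alignment(self):
        #       col: 0 (match), 1 (match), 2 (insert: 2/3 gaps)
        msa = Msa(rows=(("a", "MCA"), ("b", "MD-"), ("c", "-C-")))
        hmm = hmmclass.estimate_parameters(msa, [0, 1])
        # Match 1 emissions: two M of 2 residues -> (2+1)/(2+20).
        assert hmm.match_emissions[0, _AA_INDEX["M"]] == pytest.approx(3 / 22)
        # Match 2: C twice, D once -> P(C) = (2+1)/(3+20).
        assert hmm.match_emissions[1, _AA_INDEX["C"]] == pytest.approx(3 / 23)
        assert hmm.match_emissions[1, _AA_INDEX["D"]] == pytest.approx(2 / 23)
        # Insert state at node 2 saw one A: (1+1)/(1+20).
        assert hmm.insert_emissions[2, _AA_INDEX["A"]] == pytest.approx(2 / 21)
        # Transitions out of Begin: paths start M,M,D -> counts M:2, D:1,
        # I:0; +1 smoothing over 3 targets -> (3/6, 1/6, 2/6).
        assert hmm.transitions[0, 0] == pytest.approx([3 / 6, 1 / 6, 2 / 6])
        # Node 2 (last): M2 is visited in all three rows; a continues to
        # the insert (M->I), b and c go straight to End (M->End).
        # Counts End:2, I:1; +1 smoothing over the two legal targets.
        assert hmm.transitions[2, 0, 0] == pytest.approx(3 / 5)
        assert hmm.transitions[2, 0, 1] == pytest.approx(2 / 5)

    def test_emission_rows_normalized(self, reference_profiles):
        hmm = reference_profiles["hmm_bsh"]
        assert np.allclose(hmm.match_emissions.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(hmm.insert_emissions.sum(axis=1), 1.0, atol=1e-9)


class TestForward:
    @pytest.mark.parametrize("n_match", [1, 2, 3])
    def test_matches_path_enumeration(self, n_match):
        """Forward log-probability equals the exhaustive path sum (<= 1e-9)."""
        for seed in range(3):
            hmm = random_toy_hmm(n_match, seed)
            for seq in ["A", "AC", "MCD", "WYYV", "C"]:
                got = hmmclass.forward_logprob(hmm, seq)
                want = brute_force_logprob(hmm, seq)
                assert abs(got - want) <= 1e-9

    def test_estimated_model_matches_enumeration(self):
        msa = Msa(rows=(("a", "MCA"), ("b", "MD-"), ("c", "-C-")))
        hmm = hmmclass.estimate_parameters(msa, [0, 1])
        for seq in ["MC", "MCA", "MDCA", "A"]:
            assert abs(
                hmmclass.forward_logprob(hmm, seq) - brute_force_logprob(hmm, seq)
            ) <= 1e-9

    def test_consensus_outscores_shuffles(self, small_profile):
        hmm, consensus = small_profile
        rng = np.random.default_rng(7)
        cons_score = hmmclass.forward_score(hmm, consensus)
        shuffle_scores = []
        for _ in range(100):
            letters = list(consensus)
            rng.shuffle(letters)
            shuffle_scores.append(hmmclass.forward_score(hmm, "".join(letters)))
        assert cons_score > np.median(shuffle_scores)

    def test_unknown_residue_scores_via_background(self, small_profile):
        hmm, consensus = small_profile
        with_x = "X" + consensus[1:]
        assert np.isfinite(hmmclass.forward_score(hmm, with_x))

    def test_no_underflow_on_long_sequence(self, small_profile):
        hmm, consensus = small_profile
        long_seq = (consensus * 20)[:1200]
        assert np.isfinite(hmmclass.forward_logprob(hmm, long_seq))


class TestCalibration:
    def test_location_quantile_property(self, small_profile):
        """One-sample location check: P(score > mu) ~ 1 - 1/e ~ 0.632 on
        the decoy population (Gumbel CDF value at its location)."""
        hmm, _ = small_profile
        calib = hmmclass.calibrate_evalues(hmm, n_decoys=200, decoy_len=80, seed=1)
        # Regenerate the decoy sample through the same seeded draw.
        rng = np.random.default_rng(1)
        decoys = [
            hmmclass.forward_score(
                hmm, "".join(rng.choice(hmmclass._AA, p=hmm.background, size=80))
            )
            for _ in range(200)
        ]
        frac = np.mean([s > calib.mu for s in decoys])
        assert 0.55 <= frac <= 0.70

    def test_stability_under_doubling(self, small_profile):
        hmm, _ = small_profile
        c1 = hmmclass.calibrate_evalues(hmm, n_decoys=150, decoy_len=80, seed=2)
        c2 = hmmclass.calibrate_evalues(hmm, n_decoys=300, decoy_len=80, seed=2)
        assert abs(c2.mu - c1.mu) <= 0.10 * abs(c1.mu)
        assert abs(c2.lam - c1.lam) <= 0.10 * c1.lam

    def test_deterministic_under_seed(self, small_profile):
        hmm, _ = small_profile
        c1 = hmmclass.calibrate_evalues(hmm, n_decoys=120, decoy_len=60, seed=5)
        c2 = hmmclass.calibrate_evalues(hmm, n_decoys=120, decoy_len=60, seed=5)
        assert (c1.mu, c1.lam) == (c2.mu, c2.lam)

    def test_too_few_decoys_rejected(self, small_profile):
        hmm, _ = small_profile
        with pytest.raises(CalibrationError):
            hmmclass.calibrate_evalues(hmm, n_decoys=50)

    def test_mle_method_fits_bulk(self, small_profile):
        hmm, _ = small_profile
        calib = hmmclass.calibrate_evalues(
            hmm, n_decoys=150, decoy_len=80, seed=3, method="mle"
        )
        assert calib.lam > 0 and calib.method == "mle"


class TestEvalue:
    calib = hmmclass.EvalueCalibration(
        mu=10.0, lam=math.log(2), n_decoys=200, decoy_len=320, db_size=1000
    )

    def test_evalue_at_location(self):
        e = hmmclass.evalue(10.0, self.calib)
        assert e == pytest.approx(1000 * (1 - math.exp(-1)), rel=1e-9)

    def test_monotone_decreasing_and_vanishing(self):
        scores = [0.0, 10.0, 50.0, 200.0, 2000.0]
        es = [hmmclass.evalue(s, self.calib) for s in scores]
        assert all(a > b for a, b in zip(es, es[1:]))
        assert es[-1] == 0.0  # far tail underflows to exactly zero

    def test_linear_in_db_size(self):
        e1 = hmmclass.evalue(42.0, self.calib, db_size=100)
        e2 = hmmclass.evalue(42.0, self.calib, db_size=200)
        assert e2 == pytest.approx(2 * e1, rel=1e-12)


class TestClassify:
    def test_smaller_evalue_wins(self, reference_profiles):
        rp = reference_profiles
        member = rp["refs_bsh"][0]
        res = hmmclass.classify(
            member, rp["hmm_bsh"], rp["hmm_pva"], rp["calib_bsh"], rp["calib_pva"]
        )
        assert res.label == "BSH"
        assert res.evalue_bsh < 1e-99
        assert res.evalue_bsh < res.evalue_pva

    def test_weak_hits_removed_under_retention_rule(self, reference_profiles):
        rp = reference_profiles
        decoy = ProteinRecord(
            "d", "M" + simulate._random_protein(319, np.random.default_rng(1))
        )
        res = hmmclass.classify(
            decoy, rp["hmm_bsh"], rp["hmm_pva"], rp["calib_bsh"], rp["calib_pva"]
        )
        assert res.label == "removed"
        assert min(res.evalue_bsh, res.evalue_pva) > 1e-99

    def test_inverted_retention_flag(self, reference_profiles):
        """The literal reading (remove strong hits) is exposed behind a flag."""
        rp = reference_profiles
        member = rp["refs_bsh"][0]
        res = hmmclass.classify(
            member, rp["hmm_bsh"], rp["hmm_pva"], rp["calib_bsh"], rp["calib_pva"],
            retain_strong=False,
        )
        assert res.label == "removed"

    def test_deterministic(self, reference_profiles):
        rp = reference_profiles
        member = rp["refs_pva"][0]
        r1 = hmmclass.classify(
            member, rp["hmm_bsh"], rp["hmm_pva"], rp["calib_bsh"], rp["calib_pva"]
        )
        r2 = hmmclass.classify(
            member, rp["hmm_bsh"], rp["hmm_pva"], rp["calib_bsh"], rp["calib_pva"]
        )
        assert r1 == r2 and r1.label == "PVA"

    def test_score_margin_dichotomy(self, family_pair, reference_profiles):
        """Correctly labelled members score higher under their own model
        (the two-clade separation seen on real data)."""
        spec_b, spec_p, cons_b, cons_p = family_pair
        rp = reference_profiles
        margins = []
        for i in range(20):
            b = simulate.evolve_member(cons_b, 0.3, spec_b.motif_blocks, 3000 + i)
            p = simulate.evolve_member(cons_p, 0.3, spec_p.motif_blocks, 4000 + i)
            for seq, own, other in (
                (b, rp["hmm_bsh"], rp["hmm_pva"]),
                (p, rp["hmm_pva"], rp["hmm_bsh"]),
            ):
                margins.append(
                    hmmclass.forward_score(own, seq) - hmmclass.forward_score(other, seq)
                )
        assert np.mean([m > 0 for m in margins]) >= 0.95


class TestProfileSerialization:
    def test_round_trip(self, tmp_path, small_profile):
        hmm, consensus = small_profile
        path = tmp_path / "model.txt"
        hmmclass.write_profile(hmm, path)
        back = hmmclass.read_profile(path)
        assert back.n_match == hmm.n_match
        assert np.allclose(back.match_emissions, hmm.match_emissions, atol=1e-9)
        assert np.allclose(back.transitions, hmm.transitions, atol=1e-9)
        # Scores agree through the round trip.
        assert hmmclass.forward_score(back, consensus) == pytest.approx(
            hmmclass.forward_score(hmm, consensus), abs=1e-6
        )
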