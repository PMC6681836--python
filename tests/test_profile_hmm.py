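import math

import numpy as np
import pytest

from tps_survey._jtt import AA_INDEX
from tps_survey.align_core import MultipleAlignment
from tps_survey.io_formats import SequenceRecord
from tps_survey.profile_hmm import (
    DomainHit, ProfileError, ProfileHMM, build_profile, calibrate,
    calibrate_for_database, evalue, forward, scan_proteome, viterbi,
)
from tps_survey.synthetic_data import ProteomeConfig, generate_proteome


def toy_profile(L: int = 3, seed: int = 1, p_exit: float = 0.05) -> ProfileHMM:
    rng = np.random.default_rng(seed)

    def probs(n):
        v = rng.random(n) + 0.05
        return v / v.sum()

    return ProfileHMM(
        label="toy",
        match_emissions=np.array([probs(20) for _ in range(L)]),
        insert_emissions=np.array([probs(20) for _ in range(L + 1)]),
        t_mm=np.full(L - 1, 0.7), t_mi=np.full(L - 1, 0.2), t_md=np.full(L - 1, 0.1),
        t_im=np.full(L - 1, 0.5), t_ii=np.full(L - 1, 0.5),
        t_dm=np.full(L - 1, 0.8), t_dd=np.full(L - 1, 0.2),
        background=probs(20), p_exit=p_exit,
    )


def enumeration_bits(prof: ProfileHMM, seq: str) -> float:
    """Independent oracle: sum P(path) over every state path of the
    documented generative model, in raw probability space."""
    xs = [AA_INDEX[c] for c in seq]
    n, L, pe = len(xs), prof.L, prof.p_exit
    p_loop = n / (n + 2.0)
    bg, me, ie = prof.background, prof.match_emissions, prof.insert_emissions
    total = 0.0

    def rec(state, k, i, p):
        nonlocal total
        if p == 0.0:
            return
        if state == "E":
            rem = n - i
            tail = (p_loop ** rem) * (1 - p_loop)
            total += p * tail * math.prod(bg[xs[j]] for j in range(i, n))
            return
        if state == "M":
            if k < L:
                rec("E", None, i, p * pe)
                if i < n:
                    rec("M", k + 1, i + 1, p * (1 - pe) * prof.t_mm[k - 1] * me[k, xs[i]])
                    rec("I", k, i + 1, p * (1 - pe) * prof.t_mi[k - 1] * ie[k, xs[i]])
                rec("D", k + 1, i, p * (1 - pe) * prof.t_md[k - 1])
            else:
                rec("E", None, i, p)
        elif state == "I":
            if i < n:
                rec("M", k + 1, i + 1, p * prof.t_im[k - 1] * me[k, xs[i]])
                rec("I", k, i + 1, p * prof.t_ii[k - 1] * ie[k, xs[i]])
        elif state == "D":
            if k < L:
                if i < n:
                    rec("M", k + 1, i + 1, p * prof.t_dm[k - 1] * me[k, xs[i]])
                rec("D", k + 1, i, p * prof.t_dd[k - 1])
            else:
                rec("E", None, i, p)

    for j in range(n):  # flank length before entry; the entry match emits x_j
        pn = (p_loop ** j) * (1 - p_loop) * math.prod(bg[xs[t]] for t in range(j))
        for k0 in range(1, L + 1):
            rec("M", k0, j + 1, pn * (1.0 / L) * me[k0 - 1, xs[j]])
    null = math.prod(bg[x] for x in xs) * (n / (n + 1.0)) ** n / (n + 1.0)
    return math.log2(total / null)


class TestForwardViterbi:
    @pytest.mark.parametrize("L,seed,seq", [
        (2, 1, "AC"), (2, 2, "WACD"), (3, 1, "ACD"), (3, 3, "MKTAY"),
        (4, 5, "QWERTY"[:5].replace("Q", "A").replace("W", "C")),
    ])
    def test_forward_equals_path_enumeration(self, L, seed, seq):
        prof = toy_profile(L, seed)
        assert abs(forward(prof, seq) - enumeration_bits(prof, seq)) < 1e-9

    @pytest.mark.parametrize("seq", ["AC", "ACDEF", "MKTAYIAKQRQISF"])
    def test_forward_dominates_viterbi(self, seq):
        prof = toy_profile(3, 7)
        bits, _, _ = viterbi(prof, seq)
        assert forward(prof, seq) >= bits - 1e-12

    def test_consensus_scores_above_its_shuffle(self, profiles):
        prof = profiles["NTD"]
        cons = prof.consensus()
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(10):
            shuf = "".join(rng.permutation(list(cons)))
            wins += forward(prof, cons) > forward(prof, shuf)
        assert wins >= 9

    def test_long_sequence_no_underflow(self):
        prof = toy_profile(5, 2)
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=5000))
        assert math.isfinite(forward(prof, seq))

    def test_invalid_residue_rejected(self):
        with pytest.raises(ProfileError):
            forward(toy_profile(), "MK1T")


class TestBuildProfile:
    def test_identical_gapless_rows(self):
        msa = MultipleAlignment({"a": "MKTAY", "b": "MKTAY"})
        prof = build_profile(msa)
        assert prof.L == 5
        for k, ch in enumerate("MKTAY"):
            assert prof.match_emissions[k].argmax() == AA_INDEX[ch]

    def test_low_occupancy_column_becomes_insert(self):
        rows = {f"r{i}": ("MK-TAY" if i < 3 else "MKCTAY") for i in range(5)}
        prof = build_profile(MultipleAlignment(rows), match_fraction=0.5)
        assert prof.L == 5  # the 40%-occupied column is modeled as an insert

    def test_probability_conservation(self, profiles):
        for prof in profiles.values():
            assert np.allclose(prof.match_emissions.sum(axis=1), 1.0)
            assert np.allclose(prof.insert_emissions.sum(axis=1), 1.0)
            assert np.allclose(prof.t_mm + prof.t_mi + prof.t_md, 1.0)
            assert np.allclose(prof.t_im + prof.t_ii, 1.0)
            assert np.allclose(prof.t_dm + prof.t_dd, 1.0)

    def test_all_gap_columns_rejected(self):
        with pytest.raises(ProfileError):
            build_profile(MultipleAlignment({"a": "--", "b": "--"}))

    def test_single_row_rejected(self):
        with pytest.raises(ProfileError):
            build_profile(MultipleAlignment({"a": "MKT"}))

    def test_serialization_round_trip(self, profiles):
        prof = profiles["NTD"]
        text = prof.to_text()
        back = ProfileHMM.from_text(text)
        assert back.L == prof.L and back.label == prof.label
        assert np.allclose(back.match_emissions, prof.match_emissions)
        assert np.allclose(back.t_mm, prof.t_mm)


class TestCalibration:
    def test_evalue_at_null_median_is_half_database(self, profiles):
        prof = profiles["IDS"]
        rng = np.random.default_rng(8)
        lengths = rng.integers(80, 300, size=200)
        calibrate(prof, lengths, n_samples=1000, seed=2)
        # draw fresh null scores; the E-value at their median ~ db/2
        from tps_survey._jtt import AA_ORDER
        aas = np.array(list(AA_ORDER))
        scores = []
        for _ in range(400):
            m = int(rng.choice(lengths))
            scores.append(forward(prof, "".join(rng.choice(aas, size=m, p=prof.background))))
        med = float(np.median(scores))
        db = 1000
        assert evalue(prof, med, db) == pytest.approx(db / 2, rel=0.10)

    def test_evalue_vanishes_for_large_scores(self, profiles):
        prof = profiles["IDS"]
        assert evalue(prof, 1e6, 1000) == 0.0

    def test_determinism(self):
        prof_a, prof_b = toy_profile(4, 3), toy_profile(4, 3)
        ca = calibrate(prof_a, [100, 200], n_samples=1000, seed=5)
        cb = calibrate(prof_b, [100, 200], n_samples=1000, seed=5)
        assert ca == cb

    def test_too_few_samples_rejected(self):
        with pytest.raises(ProfileError):
            calibrate(toy_profile(), [100], n_samples=10)

    def test_uncalibrated_scan_rejected(self):
        prof = toy_profile()
        with pytest.raises(ProfileError):
            scan_proteome(prof, [SequenceRecord("x", "MKTAY")])


class TestScan:
    def test_hits_at_strict_cutoff_subset_of_relaxed(self, bench_proteome):
        records, _, profs = bench_proteome
        sub = records[:120]
        strict = {(h.seq_id, h.env_start) for h in
                  scan_proteome(profs["NTD"], sub, e_cutoff=1.0)}
        relaxed = {(h.seq_id, h.env_start) for h in
                   scan_proteome(profs["NTD"], sub, e_cutoff=100.0)}
        assert strict <= relaxed

    def test_envelope_overlap_with_planted_truth(self, bench_proteome):
        records, truth, profs = bench_proteome
        sub = [r for r in records if r.id.startswith("full")][:30]
        hits = scan_proteome(profs["CTD"], sub, e_cutoff=1.0)
        jac = []
        for h in hits:
            envs = [d for d in truth.planted_domains[h.seq_id] if d[0] == "CTD"]
            env = envs[0]
            a = set(range(h.env_start, h.env_end + 1))
            b = set(range(env[1], env[2] + 1))
            jac.append(len(a & b) / len(a | b))
        assert jac and min(jac) >= 0.8

    def test_decoy_only_expected_false_positive_scale(self):
        from tps_survey.synthetic_data import default_profiles
        prof = default_profiles(("NTD",))["NTD"]
        records, _ = generate_proteome(
            ProteomeConfig(n_full=0, n_ntd_only=0, n_ctd_only=0, n_decoy=300), 17,
            profiles={"NTD": prof, "CTD": prof},
        )
        calibrate_for_database(prof, records, seed=3)
        hits = scan_proteome(prof, records, e_cutoff=1.0)
        # E-value semantics: ~cutoff false hits expected, order of magnitude
        assert len({h.seq_id for h in hits}) <= 10

    def test_hit_envelope_invariants(self, bench_proteome):
        records, _, profs = bench_proteome
        hits = scan_proteome(profs["NTD"], records[:60], e_cutoff=1.0)
        by_id = {r.id: r for r in records}
        for h in hits:
            assert 1 <= h.env_start <= h.env_end <= len(by_id[h.seq_id].residues)
            assert h.evalue >= 0


class TestDomainHit:
    def test_invalid_envelope_rejected(self):
        with pytest.raises(ProfileError):
            DomainHit("s", "NTD", 5, 3, 10.0, 0.1, False)
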