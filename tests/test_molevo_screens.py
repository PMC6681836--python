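import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tps_survey.align_core import MultipleAlignment
from tps_survey.io_formats import SequenceRecord
from tps_survey.molevo_screens import (
    MolEvoError, build_ppd_profile, conserved_columns, discover_ppd,
    hgt_verdict, ng86_kaks, percent_half_up, ppd_scan_report, screen_hgt,
)
from tps_survey.profile_hmm import calibrate_for_database
from tps_survey.synthetic_data import (
    default_profiles, evolve_codon_pair, generate_ids_panel,
)

def _translate(codon):
    from Bio.Seq import Seq
    return str(Seq(codon).translate())


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_kaks("ATGGCTGCA", "ATGGCTGCA")
        assert r.ka == 0 and r.ks == 0 and r.undefined_ratio

    def test_single_synonymous_third_position_change(self):
        # GGA vs GGG among 99 identical GGA codons: both codons have exactly
        # one synonymous site (third position fourfold degenerate; first two
        # positions nonsynonymous), so S = 100, N = 200, Sd = 1, Nd = 0
        a = "GGA" * 100
        b = "GGA" * 99 + "GGG"
        r = ng86_kaks(a, b)
        assert r.s_sites == pytest.approx(100.0)
        assert r.n_sites == pytest.approx(200.0)
        assert (r.nd, r.sd) == (0.0, 1.0)
        assert r.ka == 0.0
        p = 1 / 100
        assert r.ks == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))

    def test_single_nonsynonymous_change(self):
        a = "ATGGCT" * 50
        b = "ATGGCT" * 49 + "ATGTCT"  # Ala -> Ser at second position
        r = ng86_kaks(a, b)
        assert r.sd == 0.0 and r.nd == 1.0 and r.ks == 0.0 and r.ka > 0

    @pytest.mark.parametrize("ca,cb", [
        ("TTT", "GTA"), ("ATG", "AAA"), ("GGA", "GTG"), ("CCT", "CAG"),
    ])
    def test_two_difference_codons_match_pathway_enumeration(self, ca, cb):
        background = "ATGGCT" * 30
        r = ng86_kaks(background + ca, background + cb)
        # independent enumeration over substitution orders
        positions = [i for i in range(3) if ca[i] != cb[i]]
        stops = {"TAA", "TAG", "TGA"}
        paths = []
        for order in itertools.permutations(positions):
            cur, nd, sd, ok = ca, 0, 0, True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
                if nxt in stops:
                    ok = False
                if _translate(cur) == _translate(nxt) and nxt not in stops \
                        and cur not in stops:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                paths.append((nd, sd))
        exp_nd = sum(p[0] for p in paths) / len(paths)
        exp_sd = sum(p[1] for p in paths) / len(paths)
        assert r.nd == pytest.approx(exp_nd)
        assert r.sd == pytest.approx(exp_sd)

    def test_site_counts_always_sum_to_three_per_codon(self):
        a, b = evolve_codon_pair(150, 0.4, 2)
        r = ng86_kaks(a, b)
        assert r.n_sites + r.s_sites == pytest.approx(3 * r.n_codons)

    def test_gapped_codons_dropped_pairwise(self):
        r = ng86_kaks("ATG---GCT", "ATGGCAGCT")
        assert r.n_codons == 2

    def test_cross_check_against_independent_implementation(self):
        # Biopython's experimental NG86 differs slightly in its stop-codon
        # site convention; agreement is expected within a few percent
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        a, b = evolve_codon_pair(400, 0.3, 5)
        mine = ng86_kaks(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert mine.ka == pytest.approx(dn, rel=0.08)
        assert mine.ks == pytest.approx(ds, rel=0.08)

    def test_omega_recovery_at_1000_codons(self):
        a, b = evolve_codon_pair(1000, 0.2, 13)
        r = ng86_kaks(a, b)
        assert r.ratio == pytest.approx(0.2, rel=0.15)

    @pytest.mark.parametrize("a,b,err", [
        ("ATGGC", "ATGGC", "divisible"),
        ("ATGGCT", "ATG", "length"),
        ("ATGTAAGCT", "ATGGCAGCT", "stop"),
    ])
    def test_input_validation(self, a, b, err):
        with pytest.raises(MolEvoError):
            ng86_kaks(a, b)


class TestPercentages:
    @pytest.mark.parametrize("num,den,expected", [
        (948, 1054, 89.9),
        (20113, 22375, 89.9),
        (9, 30, 30.0),
        (0, 103, 0.0),
        (46, 1054, 4.4),
    ])
    def test_published_fraction_convention(self, num, den, expected):
        assert percent_half_up(num, den) == expected

    @given(st.integers(0, 10_000), st.integers(1, 10_000))
    def test_half_up_matches_integer_arithmetic_oracle(self, num, den):
        q, r = divmod(num * 1000, den)
        oracle = (q + (1 if 2 * r >= den else 0)) / 10
        assert percent_half_up(num, den) == pytest.approx(oracle)

    def test_zero_denominator_rejected(self):
        with pytest.raises(MolEvoError):
            percent_half_up(1, 0)


@pytest.fixture(scope="module")
def ids_screen():
    """IDS panel with planted degenerate PPD windows, scanned by the
    calibrated C-terminal-domain profile."""
    profs = default_profiles(("CTD", "IDS"))
    panel = generate_ids_panel(n_ids=80, n_decoy=220, seed=3,
                               profiles={"IDS": profs["IDS"]})
    calibrate_for_database(profs["CTD"], panel, seed=4)
    return panel, profs["CTD"]


class TestPpdPipeline:
    def test_relaxed_threshold_recovers_fragments_strict_misses(self, ids_screen):
        panel, ctd = ids_screen
        relaxed = discover_ppd(panel, ctd, relaxed_e=100.0)
        strict = discover_ppd(panel, ctd, relaxed_e=1.0)
        relaxed_ids = {h.seq_id for h in relaxed.hits if h.seq_id.startswith("ids")}
        strict_ids = {h.seq_id for h in strict.hits if h.seq_id.startswith("ids")}
        assert strict_ids <= relaxed_ids
        assert relaxed_ids - strict_ids        # some PPDs need the relaxed cutoff
        assert len(relaxed_ids) > len(panel) * 0.1

    def test_duplicate_fragments_deduplicate(self, ids_screen):
        panel, ctd = ids_screen
        # clone one planted protein under a new id: same envelope string
        clone = SequenceRecord("clone0001", panel[0].residues)
        d = discover_ppd(panel + [clone], ctd)
        assert d.n_raw >= d.n_unique
        strings = [panel[0].residues[h.env_start - 1:h.env_end]
                   for h in d.hits if h.seq_id in (panel[0].id, "clone0001")]
        if len(strings) == 2:
            assert strings[0] == strings[1]   # identical fragments, one seed

    def test_seed_lengths_near_expected_motif_length(self, ids_screen):
        panel, ctd = ids_screen
        d = discover_ppd(panel, ctd, expected_len=33)
        lo, hi = d.seed_length_range
        assert lo >= 0.6 * 33 and hi <= 1.5 * 33

    def test_scan_report_fractions(self, ids_screen):
        panel, ctd = ids_screen
        ids_only = [r for r in panel if r.id.startswith("ids")]
        decoys = [r for r in panel if r.id.startswith("bg")]
        # discovery runs on the IDS set itself (every scanned protein is a
        # genuine IDS, as in the original survey)
        d = discover_ppd(ids_only, ctd)
        ppd = build_ppd_profile(d.seeds)
        calibrate_for_database(ppd, panel, seed=9)
        reports = ppd_scan_report(ppd, {"ids": ids_only, "decoys": decoys},
                                  e_cutoff=1.0)
        assert reports["ids"].percentage >= 80.0
        assert reports["decoys"].percentage <= 10.0
        for rep in reports.values():
            assert rep.percentage == percent_half_up(rep.n_hits, rep.set_size)

    def test_empty_target_set_rejected(self, ids_screen):
        _, ctd = ids_screen
        with pytest.raises(MolEvoError):
            ppd_scan_report(ctd, {"empty": []})


class TestConservedColumns:
    def test_fully_identical_alignment_returns_all_columns(self):
        msa = MultipleAlignment({"a": "MKT", "b": "MKT"})
        assert conserved_columns(msa) == [0, 1, 2]

    def test_single_divergent_residue_excludes_column(self):
        msa = MultipleAlignment({"a": "MKT", "b": "MAT"})
        assert conserved_columns(msa) == [0, 2]

    def test_subset_conserved_column(self):
        # column 1 is invariant within the IDS-like subset only
        msa = MultipleAlignment({"ids1": "MKT", "ids2": "MKT",
                                 "tps1": "MAT", "tps2": "MCT"})
        assert 1 in conserved_columns(msa, subset={"ids1", "ids2"})
        assert 1 not in conserved_columns(msa)

    def test_gaps_ignored_in_agreement(self):
        msa = MultipleAlignment({"a": "M-T", "b": "MKT"})
        assert conserved_columns(msa) == [0, 1, 2]

    def test_threshold_validation(self):
        msa = MultipleAlignment({"a": "MKT", "b": "MKT"})
        with pytest.raises(MolEvoError):
            conserved_columns(msa, identity_threshold=0.0)


class TestHgt:
    @given(st.floats(0, 1), st.floats(0, 1), st.integers(0, 5), st.integers(0, 3))
    def test_verdict_equals_bruteforce_predicates(self, cov, ident, n_sp, n_other):
        verdict, failed = hgt_verdict(cov, ident, n_sp, n_other)
        expected = (cov > 0.70 and ident > 0.80 and n_sp >= 2 and n_other == 0)
        assert (verdict == "HGT_candidate") == expected
        assert bool(failed) != expected

    def _mutate(self, seq, rate, seed):
        rng = np.random.default_rng(seed)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        return "".join(aas[rng.integers(20)] if rng.random() < rate else c
                       for c in seq)

    def test_screen_scenarios(self):
        rng = np.random.default_rng(8)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        tps = "".join(rng.choice(aas, size=120))
        plant_panels = {
            "cotton": [SequenceRecord("cotton_tps", tps)],
            "grape": [SequenceRecord("grape_tps", self._mutate(tps, 0.08, 1))],
            "rice": [SequenceRecord("rice_tps", self._mutate(tps, 0.08, 2))],
        }
        unrelated = SequenceRecord("unrelated", "".join(rng.choice(aas, size=120)))

        # scenario 1: bacterial protein identical to the cotton gene,
        # high-similarity hits in 3 species, nothing elsewhere
        bact = SequenceRecord("bact1", tps)
        out = screen_hgt([bact], plant_panels, {"nitro": [unrelated]})
        assert out[0].verdict == "HGT_candidate"
        assert out[0].n_plant_species_high_similarity >= 2

    def test_low_identity_rejected(self):
        rng = np.random.default_rng(9)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        tps = "".join(rng.choice(aas, size=120))
        weak = self._mutate(tps, 0.35, 3)
        panels = {"cotton": [SequenceRecord("c", tps)],
                  "grape": [SequenceRecord("g", tps)]}
        out = screen_hgt([SequenceRecord("bact", weak)], panels, {})
        cand = out[0]
        assert cand.best_plant_hit[1] < 0.8          # measured identity precondition
        assert cand.verdict == "rejected" and "identity" in cand.failed_rules

    def test_bacterial_homolog_vetoes(self):
        rng = np.random.default_rng(10)
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        tps = "".join(rng.choice(aas, size=120))
        panels = {"cotton": [SequenceRecord("c", tps)],
                  "grape": [SequenceRecord("g", tps)]}
        other = {"nitro": [SequenceRecord("n", self._mutate(tps, 0.3, 4))]}
        out = screen_hgt([SequenceRecord("bact", tps)], panels, other)
        assert out[0].verdict == "rejected"
        assert "bacterial_homolog" in out[0].failed_rules

    def test_empty_panels_rejected(self):
        with pytest.raises(MolEvoError):
            screen_hgt([], {}, {})
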