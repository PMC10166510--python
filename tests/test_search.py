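"""Digestion, decoys, tolerance windows, fragment matching and open search."""

import math

import numpy as np
import pandas as pd
import pytest

from diadem.demultiplex import PseudoSpectrum
from diadem.search import (PROTON, PeptideIndex, SearchConfig, build_index,
                           digest_fasta, fragment_ladders, generate_decoys,
                           hyperscore, match_fragments, mass_from_mz,
                           mz_from_mass, open_search, peptide_mass,
                           read_pepxml_psms, score_spectrum, tolerance_window)

# Independent monoisotopic residue masses (IUPAC/expasy values, typed by hand,
# not taken from the implementation's source table).
ORACLE_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
ORACLE_WATER = 18.01056


class TestDigestion:
    def test_hand_digestion_no_missed_cleavage(self):
        peps = digest_fasta([("P1", "MKAAAAAAARCCCC")], max_missed=0,
                            min_length=4, max_length=50)
        assert {p.sequence for p in peps} == {"AAAAAAAR", "CCCC"}

    def test_hand_digestion_one_missed_cleavage(self):
        peps = digest_fasta([("P1", "MKAAAAAAARCCCC")], max_missed=1,
                            min_length=4, max_length=50)
        assert {p.sequence for p in peps} == \
            {"AAAAAAAR", "CCCC", "MKAAAAAAAR", "AAAAAAARCCCC"}

    def test_no_cleavage_before_proline(self):
        peps = digest_fasta([("P1", "AAAKPGGGGRCCCC")], max_missed=0,
                            min_length=4, max_length=50)
        assert {p.sequence for p in peps} == {"AAAKPGGGGR", "CCCC"}

    def test_mass_against_independent_residue_table(self):
        for seq in ("PEPTIDEK", "GWSTYLNQR", "AAAAAAAR"):
            want = sum(ORACLE_RESIDUE[a] for a in seq) + ORACLE_WATER
            assert peptide_mass(seq) == pytest.approx(want, abs=1e-3)

    def test_nonstandard_residues_skipped(self):
        peps = digest_fasta([("P1", "AAAXAAAK" + "GGGGGGGR")], max_missed=0)
        assert {p.sequence for p in peps} == {"GGGGGGGR"}

    def test_duplicate_sequences_merge_proteins(self):
        peps = digest_fasta([("P1", "AAAAAAAK"), ("P2", "AAAAAAAK")],
                            max_missed=0)
        assert len(peps) == 1
        assert set(peps[0].protein_ids) == {"P1", "P2"}


class TestDecoys:
    def test_deterministic_under_seed(self):
        prots = [("P1", "MKAAAAAAARCCCCDDDDK"), ("P2", "WWYYFFHHKR")]
        assert generate_decoys(prots, 42) == generate_decoys(prots, 42)
        assert generate_decoys(prots, 42) != generate_decoys(prots, 43)

    def test_composition_preserved_and_prefixed(self):
        prots = [("P1", "MKAAAAAAARCCCCDDDDK")]
        (acc, seq), = generate_decoys(prots, 1)
        assert acc == "DECOY_P1"
        assert sorted(seq) == sorted(prots[0][1])


class TestToleranceWindow:
    def test_charge_independent_constants(self):
        tw = tolerance_window(24.0, 2, "charge_independent")
        assert (tw.lower, tw.upper) == (-100.0, 400.0)

    @pytest.mark.parametrize("w,z,half", [(24.0, 2, 27.0), (4.0, 3, 9.0),
                                          (24.0, 1, 15.0), (24.0, 5, 63.0)])
    def test_charge_dependent_formula(self, w, z, half):
        tw = tolerance_window(w, z, "charge_dependent")
        assert (tw.lower, tw.upper) == (-half, half)

    def test_invalid_charge_rejected(self):
        with pytest.raises(ValueError):
            tolerance_window(24.0, 6, "charge_dependent")

    def test_symmetry_and_linear_growth_property(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            w = float(rng.uniform(1, 50))
            z = int(rng.integers(1, 6))
            tw = tolerance_window(w, z, "charge_dependent")
            assert tw.lower == -tw.upper
            assert tw.upper == pytest.approx(w * z / 2 + 3)
        # slope in z is w/2
        for w in (4.0, 24.0):
            uppers = [tolerance_window(w, z, "charge_dependent").upper
                      for z in range(1, 6)]
            diffs = np.diff(uppers)
            np.testing.assert_allclose(diffs, w / 2)


def _ladder_spectrum(seq, charge=2, drop=(), mod_delta=0.0, mod_site=None):
    b, y = fragment_ladders(seq, mod_delta, mod_site)
    mz = np.concatenate([b, y])
    keep = np.ones(mz.size, bool)
    for name in drop:
        series, i = name[0], int(name[1:])
        keep[(i - 1) + (0 if series == "b" else b.size)] = False
    mz = np.sort(mz[keep])
    return mz, np.full(mz.size, 100.0)


class TestFragmentMatching:
    def test_full_ladder_all_matched(self):
        mz, inten = _ladder_spectrum("PEPTIDEK")
        m = match_fragments(mz, inten, "PEPTIDEK", 2)
        assert m.matched_b == 7 and m.matched_y == 7
        assert m.longest_consecutive_by == 7

    def test_empty_spectrum_matches_nothing(self):
        m = match_fragments(np.zeros(0), np.zeros(0), "PEPTIDEK", 2)
        assert m.matched_b == m.matched_y == 0
        assert hyperscore(m) == float("-inf")

    def test_missing_y4_leaves_run_of_three(self):
        b, y = fragment_ladders("PEPTIDEK")
        mz = np.sort(np.delete(y, 3))  # y ions only, y4 removed
        m = match_fragments(mz, np.full(mz.size, 1.0), "PEPTIDEK", 2)
        assert m.matched_y == 6 and m.matched_b == 0
        assert m.longest_consecutive_by == 3

    def test_two_plus_ions_matched_for_high_charge(self):
        b, y = fragment_ladders("PEPTIDEK")
        mz = np.sort((y + PROTON) / 2.0)
        m3 = match_fragments(mz, np.full(mz.size, 1.0), "PEPTIDEK", 3)
        m2 = match_fragments(mz, np.full(mz.size, 1.0), "PEPTIDEK", 2)
        assert m3.matched_y == 7
        assert m2.matched_y <= 1  # 2+ ions not generated at charge 2


class TestScoring:
    def test_doubling_intensities_shifts_score_by_ln2(self):
        mz, inten = _ladder_spectrum("PEPTIDEK")
        m1 = match_fragments(mz, inten, "PEPTIDEK", 2)
        m2 = match_fragments(mz, 2 * inten, "PEPTIDEK", 2)
        assert hyperscore(m2) - hyperscore(m1) == pytest.approx(math.log(2))

    def test_true_peptide_ranks_first_in_clean_cases(self):
        proteins = [("P1", _random_proteome_seq(7))]
        index = build_index(proteins, decoy_seed=3)
        targets = [e for e in index.entries if not e.is_decoy
                   and 7 <= len(e.sequence) <= 25]
        cfg = SearchConfig(tolerance_mode="charge_independent")
        n_ok = 0
        cases = targets[:40]
        for e in cases:
            mz, inten = _ladder_spectrum(e.sequence)
            z = 2
            ps = PseudoSpectrum(mz, inten,
                                pseudo_precursor_mz=mz_from_mass(
                                    e.monoisotopic_mass, z),
                                source_scan=1, rt=0.0, window_index=0,
                                iteration=1)
            rows = score_spectrum(ps, index, z, 24.0, cfg)
            if rows and rows[0]["peptide"] == e.sequence:
                n_ok += 1
        assert n_ok >= 0.95 * len(cases)

    def test_candidate_masses_lie_inside_window(self, benchmark_demux):
        run, truth, pseudo, _ = benchmark_demux
        index = build_index(truth.proteome[:10], decoy_seed=1)
        widths = {w.index: w.width for w in run.windows}
        cfg = SearchConfig()
        psms = open_search(pseudo[:40], index, widths, cfg)
        for _, r in psms.iterrows():
            tw = tolerance_window(widths[r["window_index"]], r["charge"],
                                  cfg.tolerance_mode)
            assert tw.lower - 1e-9 <= r["mass_delta"] <= tw.upper + 1e-9

    def test_expect_antimonotone_in_score(self, benchmark_demux):
        run, truth, pseudo, _ = benchmark_demux
        index = build_index(truth.proteome[:10], decoy_seed=1)
        widths = {w.index: w.width for w in run.windows}
        psms = open_search(pseudo[:30], index, widths, SearchConfig())
        for _, grp in psms.groupby("spec_id"):
            g = grp.sort_values("score", ascending=False)
            assert (np.diff(g["expect"].to_numpy()) >= -1e-12).all()
            assert (g["expect"] > 0).all()

    def test_search_deterministic(self, small_run):
        run, truth = small_run
        from diadem.demultiplex import DemuxConfig, demultiplex_run
        pseudo, _ = demultiplex_run(run, DemuxConfig(cycle_window_s=5))
        index = build_index(truth.proteome, decoy_seed=1)
        widths = {w.index: w.width for w in run.windows}
        a = open_search(pseudo, index, widths, SearchConfig())
        b = open_search(pseudo, index, widths, SearchConfig())
        pd.testing.assert_frame_equal(a, b)

    def test_each_spectrum_searched_at_five_charges(self, small_run):
        run, truth = small_run
        from diadem.demultiplex import DemuxConfig, demultiplex_run
        pseudo, _ = demultiplex_run(run, DemuxConfig(cycle_window_s=5))
        index = build_index(truth.proteome, decoy_seed=1)
        widths = {w.index: w.width for w in run.windows}
        psms = open_search(pseudo[:5], index, widths,
                           SearchConfig(tolerance_mode="charge_independent"))
        by_spec = psms.groupby(["scan", "iteration"])["charge"].nunique()
        assert by_spec.max() == 5


def _random_proteome_seq(seed, length=400):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHILMNPQSTVWY")
    out = []
    while len(out) < length:
        out.extend(rng.choice(aas, size=int(rng.integers(6, 16))))
        out.append(str(rng.choice(["K", "R"])))
    return "".join(out[:length])


class TestBatchScorerAgainstReference:
    def test_batch_stats_match_per_candidate_matching(self):
        rng = np.random.default_rng(12)
        proteins = [("P1", _random_proteome_seq(5))]
        index = build_index(proteins, decoy_seed=2)
        mz = np.sort(rng.uniform(150, 1500, 120))
        inten = rng.uniform(1, 100, 120)
        ps = PseudoSpectrum(mz, inten, pseudo_precursor_mz=650.0,
                            source_scan=1, rt=0.0, window_index=0, iteration=1)
        cfg = SearchConfig(tolerance_mode="charge_independent")
        rows = score_spectrum(ps, index, 2, 24.0, cfg)
        for r in rows:
            ref = match_fragments(ps.mz, ps.intensity, r["peptide"], 2,
                                  cfg.frag_tol_ppm)
            assert r["matched_b"] == ref.matched_b
            assert r["matched_y"] == ref.matched_y
            assert r["matched_intensity"] == pytest.approx(
                ref.matched_intensity)
            assert r["score"] == pytest.approx(hyperscore(ref), abs=1e-9)


PEPXML = """<?xml version="1.0" encoding="UTF-8"?>
<msms_pipeline_analysis xmlns="http://regis-web.systemsbiology.net/pepXML">
 <msms_run_summary>
  <spectrum_query spectrum="run.101.101.2" start_scan="101" end_scan="101"
                  assumed_charge="2">
   <search_result>
    <search_hit hit_rank="1" peptide="PEPTIDEK" protein="P1" massdiff="0.002">
     <search_score name="hyperscore" value="31.5"/>
     <search_score name="expect" value="0.0004"/>
    </search_hit>
    <search_hit hit_rank="2" peptide="PEPTIDER" protein="DECOY_P2"
                massdiff="-0.5">
     <search_score name="hyperscore" value="12.0"/>
     <search_score name="expect" value="0.9"/>
    </search_hit>
   </search_result>
  </spectrum_query>
 </msms_run_summary>
</msms_pipeline_analysis>
"""


class TestPepxmlAdapter:
    def test_import_maps_to_native_schema(self, tmp_path):
        path = tmp_path / "r.pep.xml"
        path.write_text(PEPXML)
        df = read_pepxml_psms(path)
        assert len(df) == 2
        top = df[df["rank"] == 1].iloc[0]
        assert top["peptide"] == "PEPTIDEK"
        assert top["scan"] == 101 and top["charge"] == 2
        assert top["expect"] == pytest.approx(0.0004)
        assert not top["is_decoy"]
        assert df[df["rank"] == 2].iloc[0]["is_decoy"]
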