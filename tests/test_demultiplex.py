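"""Fragment-correlation demultiplexing: matrix construction, base-peak rules,
Pearson/KDE machinery and the iterative pseudo-spectrum assembly."""

import math

import numpy as np
import pytest

from diadem.demultiplex import (DemuxConfig, FragmentMatrix,
                                assemble_pseudo_spectrum,
                                build_fragment_matrix, demultiplex_scan,
                                estimate_cycle_window, find_base_peak,
                                kde_density, kde_threshold, pearson_profiles,
                                profile_pcc)
from diadem.spectra_io import IsolationWindow, Ms1Scan, Ms2Scan, MSRun

WINDOW = IsolationWindow(500.0, 24.0, 0)
CFG = DemuxConfig(cycle_window_s=5)


def _scan(cycle, mz, inten, wi=0):
    return Ms2Scan(cycle + 1, float(cycle), wi, cycle,
                   np.array(mz, float), np.array(inten, float))


def _ms1_run(base_mzs):
    ms1 = [Ms1Scan(i + 1, float(i), [m, m + 100.0], [10.0, 1.0])
           for i, m in enumerate(base_mzs)]
    return MSRun(ms1, [WINDOW], {0: []})


class TestCycleWindowEstimate:
    def test_constant_runs_of_five(self):
        run = _ms1_run([400.0] * 5 + [500.0] * 5 + [600.0] * 5)
        assert estimate_cycle_window(run) == 5

    def test_mean_of_four_and_six(self):
        run = _ms1_run([400.0] * 4 + [500.0] * 6)
        assert estimate_cycle_window(run) == 5

    def test_even_mean_forced_odd_upward(self):
        run = _ms1_run([400.0] * 3 + [500.0] * 5)
        # mean run length 4 -> rounded 4 -> forced odd -> 5
        assert estimate_cycle_window(run) == 5

    def test_too_few_ms1_scans_returns_default(self):
        run = _ms1_run([400.0, 500.0])
        assert estimate_cycle_window(run) == 5

    def test_clamped_to_three(self):
        run = _ms1_run([400.0, 500.0, 600.0, 700.0])
        assert estimate_cycle_window(run) == 3


class TestFragmentMatrix:
    def test_ppm_tolerance_matching(self):
        # 700.0042 is 6 ppm from 700.000 -> inside a 10 ppm tolerance;
        # 700.014 is 20 ppm away -> no match
        scans = [_scan(0, [700.0042], [7.0]),
                 _scan(1, [700.000], [5.0]),
                 _scan(2, [700.014], [9.0])]
        m = build_fragment_matrix(scans, 1, WINDOW, CFG, 3)
        assert m.n_fragments == 1
        np.testing.assert_allclose(m.intensities[:, 0], [7.0, 5.0, 0.0])

    def test_low_mz_and_in_window_fragments_excluded(self):
        scans = [_scan(0, [139.9, 200.0, 495.0, 600.0], [1.0] * 4)]
        m = build_fragment_matrix(scans, 0, WINDOW, CFG, 3)
        # 139.9 < 140 excluded; 495 inside [488, 512] excluded
        np.testing.assert_allclose(m.fragment_mzs, [200.0, 600.0])

    def test_run_boundary_rows_are_zero(self):
        scans = [_scan(i, [600.0], [float(i + 1)]) for i in range(3)]
        m = build_fragment_matrix(scans, 0, WINDOW, CFG, 5)
        assert m.S == 5 and m.center_row == 2
        np.testing.assert_allclose(m.intensities[:, 0],
                                   [0.0, 0.0, 1.0, 2.0, 3.0])


def _matrix(cols, mzs=None):
    """Matrix from explicit per-column 5-cycle profiles."""
    cols = np.asarray(cols, float)
    if mzs is None:
        mzs = 600.0 + 10.0 * np.arange(cols.shape[0])
    return FragmentMatrix(np.asarray(mzs, float), cols.T.copy(),
                          center_row=2, window=WINDOW, source_scan=1)


class TestBasePeak:
    def test_single_eligible_column_wins(self):
        m = _matrix([[1, 2, 9, 2, 1], [0, 0, 1, 0, 0]], mzs=[600.0, 650.0])
        assert find_base_peak(m, 9.0, CFG) == 0

    def test_non_consecutive_profile_ineligible(self):
        m = _matrix([[0, 0, 9, 0, 0]], mzs=[600.0])
        assert find_base_peak(m, 9.0, CFG) is None

    def test_tie_breaks_to_lowest_mz(self):
        m = _matrix([[1, 2, 9, 2, 1], [1, 2, 9, 2, 1]], mzs=[600.0, 400.0])
        assert find_base_peak(m, 9.0, CFG) == 1

    def test_low_mz_and_weak_columns_ineligible(self):
        m = _matrix([[1, 2, 9, 2, 1],      # below 300 Th
                     [1, 1, 0.009, 1, 1]],  # < 1% of raw base intensity
                    mzs=[299.0, 600.0])
        assert find_base_peak(m, 1.0, CFG) is None


def _pearson_oracle(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)
                    * sum((b - my) ** 2 for b in y))
    return num / den


class TestPearson:
    def test_identity_and_scaling(self):
        base = np.array([1.0, 4.0, 9.0, 4.0, 1.0])
        m = _matrix([base, 2 * base])
        assert profile_pcc(m, 0)[0] == pytest.approx(1.0)

    def test_anticorrelated(self):
        base = np.array([1.0, 4.0, 9.0, 4.0, 1.0])
        m = _matrix([base, base.max() - base])
        assert profile_pcc(m, 0)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        base = [1.0, 4.0, 9.0, 4.0, 1.0]
        other = [1.0, 4.0, 9.0, 4.0, 2.0]
        m = _matrix([base, other])
        assert profile_pcc(m, 0)[0] == pytest.approx(
            _pearson_oracle(base, other), abs=1e-12)

    def test_zero_variance_profile_defined_as_zero(self):
        m = _matrix([[1.0, 4.0, 9.0, 4.0, 1.0], [3.0] * 5])
        assert profile_pcc(m, 0)[0] == 0.0

    def test_random_profiles_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b = rng.uniform(0, 10, (2, 7))
            got = pearson_profiles(b[None, :], a)[0]
            assert got == pytest.approx(_pearson_oracle(a, b), abs=1e-10)


def _kde_oracle(values, grid, h):
    out = []
    for g in grid:
        s = sum(math.exp(-0.5 * ((g - v) / h) ** 2) for v in values)
        out.append(s / (len(values) * h * math.sqrt(2 * math.pi)))
    return np.array(out)


class TestKde:
    def test_density_equals_brute_force_kernel_sum(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(-1, 1, 40)
        grid = np.arange(-1.0, 1.0025, 0.005)
        got = kde_density(values, grid, 0.05)
        want = _kde_oracle(values, grid, 0.05)
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_low_valley_floored_at_08(self):
        rng = np.random.default_rng(2)
        values = np.concatenate([rng.normal(0.3, 0.03, 25),
                                 rng.normal(0.95, 0.02, 25)])
        p0 = kde_threshold(values, CFG)
        assert p0 == pytest.approx(0.8)

    def test_unimodal_returns_floor(self):
        assert kde_threshold(np.full(30, 0.95), CFG) == pytest.approx(0.8)

    def test_high_valley_located_by_grid_scan_oracle(self):
        rng = np.random.default_rng(3)
        values = np.concatenate([rng.normal(0.85, 0.01, 30),
                                 rng.normal(0.99, 0.005, 30)])
        p0 = kde_threshold(values, CFG)
        assert 0.8 < p0 < 0.99
        # oracle: exhaustive scan for the minimum between the two peaks
        grid = np.arange(-1.0, 1.0025, 0.005)
        dens = _kde_oracle(values, grid, 0.05)
        sel = (grid > 0.85) & (grid < 0.99)
        want = grid[sel][np.argmin(dens[sel])]
        assert p0 == pytest.approx(want, abs=0.0051)

    def test_p0_always_within_floor_and_one(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            n = rng.integers(1, 60)
            values = rng.uniform(-1, 1, n)
            p0 = kde_threshold(values, CFG)
            assert 0.8 <= p0 <= 1.0


class TestAssembly:
    def test_all_correlating_columns_in_one_pseudo_spectrum(self):
        base = np.array([1.0, 4.0, 9.0, 4.0, 1.0])
        m = _matrix([base, 2 * base, 0.5 * base, 3 * base])
        ps, rest = assemble_pseudo_spectrum(m, 0, 0.8, CFG, rt=0.0, iteration=1)
        assert ps.fragment_indices == frozenset({0, 1, 2, 3})
        assert rest.size == 0
        assert ps.pseudo_precursor_mz == WINDOW.center_mz

    def test_second_collection_via_f1st_member(self):
        # col 2 fails the base correlation but matches col 1 (an F-1st member)
        base = np.array([0.0, 2.0, 9.0, 2.0, 0.0])
        member = np.array([0.5, 3.5, 9.0, 5.0, 1.5])
        friend_of_member = np.array([1.0, 4.5, 8.5, 6.5, 2.5])
        m = _matrix([base, member, friend_of_member])
        p0 = 0.92
        assert pearson_profiles(member[None, :], base)[0] > p0
        assert pearson_profiles(friend_of_member[None, :], base)[0] < p0
        assert pearson_profiles(friend_of_member[None, :], member)[0] > p0
        ps, rest = assemble_pseudo_spectrum(m, 0, p0, CFG, rt=0.0, iteration=1)
        assert 1 in ps.first_collection
        assert 2 in ps.second_collection
        assert rest.size == 0

    def test_lowering_floor_never_shrinks_first_collection(self):
        rng = np.random.default_rng(5)
        profiles = rng.uniform(0, 10, (20, 5))
        m = _matrix(profiles)
        sizes = []
        for p0 in (0.95, 0.9, 0.8, 0.5):
            ps, _ = assemble_pseudo_spectrum(m, 0, p0, CFG, rt=0.0, iteration=1)
            sizes.append(len(ps.first_collection))
        assert sizes == sorted(sizes)


def _planted_window_scans(rng, apexes, n_frag=18, n_cycles=15, noise=6):
    """Scans of one window with co-eluting synthetic peptides at given apexes."""
    frag_sets = []
    lo = 600.0
    for _ in apexes:
        frag_sets.append(lo + rng.uniform(0, 80, n_frag))
        lo += 100.0
    scans = []
    for c in range(n_cycles):
        mzs, ints = [], []
        for mz_set, apex in zip(frag_sets, apexes):
            w = math.exp(-(c - apex) ** 2 / (2 * 1.5 ** 2))
            if w < 0.01:
                continue
            mzs.append(mz_set)
            ints.append(w * np.linspace(100.0, 40.0, n_frag))
        mzs.append(rng.uniform(140, 1000, noise))
        ints.append(rng.uniform(0.1, 1.0, noise))
        mz = np.concatenate(mzs)
        it = np.concatenate(ints)
        scans.append(_scan(c, mz, it))
    return scans, frag_sets


class TestDemultiplexScan:
    def test_pure_noise_yields_single_fallback(self):
        rng = np.random.default_rng(6)
        scans = [_scan(c, np.sort(rng.uniform(140, 1000, 30)),
                       rng.uniform(1, 10, 30)) for c in range(7)]
        out = demultiplex_scan(scans, 3, WINDOW, CFG, 5)
        assert len(out) == 1
        assert out[0].is_fallback
        np.testing.assert_allclose(out[0].mz, scans[3].mz)
        np.testing.assert_allclose(out[0].intensity, scans[3].intensity)

    def test_three_coeluting_peptides_pop_disjoint_pseudo_spectra(self):
        rng = np.random.default_rng(7)
        scans, frag_sets = _planted_window_scans(rng, apexes=[4.0, 7.0, 10.0])
        out = demultiplex_scan(scans, 7, WINDOW, CFG, 5)
        real = [ps for ps in out if not ps.is_fallback]
        assert len(real) >= 2
        seen = set()
        for ps in real:
            assert not (ps.fragment_indices & seen)
            seen |= ps.fragment_indices
        # the apex-7 peptide's fragments should come out as one clean group
        target = frag_sets[1]
        best = max(real, key=lambda ps: np.isin(
            np.round(ps.mz, 4), np.round(target, 4)).sum())
        hits = np.isin(np.round(best.mz, 4), np.round(target, 4)).sum()
        assert hits >= 0.9 * len(target)
        purity = hits / best.mz.size
        assert purity >= 0.9

    def test_iteration_indices_sequential(self):
        rng = np.random.default_rng(8)
        scans, _ = _planted_window_scans(rng, apexes=[4.0, 7.0, 10.0])
        out = demultiplex_scan(scans, 7, WINDOW, CFG, 5)
        assert [ps.iteration for ps in out] == list(
            range(1, len(out) + 1))

    def test_disjointness_and_conservation_over_random_scans(self):
        rng = np.random.default_rng(9)
        for trial in range(30):
            apexes = sorted(rng.uniform(3, 11, rng.integers(1, 4)))
            scans, _ = _planted_window_scans(rng, apexes)
            c0 = int(rng.integers(2, 13))
            out = demultiplex_scan(scans, c0, WINDOW, CFG, 5)
            post_exclusion = ((scans[c0].mz >= CFG.min_fragment_mz)
                              & ~((scans[c0].mz >= WINDOW.lower)
                                  & (scans[c0].mz <= WINDOW.upper)))
            allowed = set(np.flatnonzero(post_exclusion))
            seen = set()
            for ps in out:
                if ps.is_fallback:
                    continue
                assert not (ps.fragment_indices & seen)
                seen |= ps.fragment_indices
            assert seen <= set(range(int(post_exclusion.sum())))


class TestDemuxRunLevel:
    def test_every_scan_yields_at_least_one_block(self, benchmark_demux):
        run, _, pseudo, stats = benchmark_demux
        assert stats.n_scans == run.n_ms2
        assert stats.n_pseudo >= stats.n_scans

    def test_pseudo_precursor_equals_window_center(self, benchmark_demux):
        run, _, pseudo, _ = benchmark_demux
        for ps in pseudo[::37]:
            assert ps.pseudo_precursor_mz == \
                run.window(ps.window_index).center_mz

    def test_deterministic(self):
        from diadem.synthetic import SimConfig, simulate_run
        from diadem.demultiplex import demultiplex_run
        cfg = SimConfig(seed=11, n_peptides_sampled=30, n_windows=4,
                        n_cycles=12, protein_length=200)
        run, _ = simulate_run(cfg)
        a, _ = demultiplex_run(run, CFG)
        b, _ = demultiplex_run(run, CFG)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.mz, y.mz)
            np.testing.assert_array_equal(x.intensity, y.intensity)
            assert x.iteration == y.iteration
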