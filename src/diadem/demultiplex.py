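"""Fragment-correlation self-demultiplexing of DIA MS2 scans.

Each DIA MS2 scan is a superposition of the fragment spectra of every peptide
co-isolated in its window.  Co-fragmented peptides differ in their elution
profiles, so the intensity traces of their fragments across neighbouring cycles
are correlated within a peptide and (usually) uncorrelated between peptides.
The demultiplexer builds an S x n matrix of fragment traces centred on the scan
to be demultiplexed, seeds each group with the scan's base peak, thresholds the
Pearson correlations of all other traces against it with a KDE-derived cutoff,
and iteratively pops pseudo-spectra until too few fragments remain.  The whole
procedure uses only MS2 information; no precursor signal is required, which is
what lets suppressed-precursor peptides be identified at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectra_io import IsolationWindow, Ms2Scan, MSRun

log = logging.getLogger(__name__)


@dataclass
class DemuxConfig:
    """Tunable parameters of the demultiplexer.

    Defaults are the method's printed constants: fragments below 140 Th or
    inside the isolation window are excluded; the base peak must sit above
    300 Th, persist in >= 3 consecutive cycles and exceed 1% of the raw scan's
    base peak; iteration continues only while more than ``min_high_pcc_fragments``
    fragments correlate with the base peak at PCC > 0.9; the PCC threshold is
    the KDE valley floored at 0.8; iteration stops when fewer than 10 fragments
    remain.
    """

    cycle_window_s: int | None = None  # odd S; auto-estimated from MS1 if None
    trace_mz_tol_ppm: float = 10.0
    min_fragment_mz: float = 140.0
    base_peak_min_mz: float = 300.0
    base_peak_min_rel_intensity: float = 0.01
    min_high_pcc_fragments: int = 10  # gate: count at PCC > 0.9 must exceed this
    high_pcc: float = 0.9
    kde_bandwidth: float = 0.05
    kde_grid_step: float = 0.005
    pcc_floor: float = 0.8
    min_rest_fragments: int = 10
    max_iterations: int = 10

    def __post_init__(self):
        if not (0 < self.pcc_floor <= 1):
            raise ValueError("pcc_floor must be in (0, 1]")
        if self.kde_bandwidth <= 0 or self.kde_grid_step <= 0:
            raise ValueError("KDE bandwidth and grid step must be positive")
        if self.cycle_window_s is not None:
            s = self.cycle_window_s
            if s < 3 or s % 2 == 0:
                raise ValueError("cycle window S must be odd and >= 3")


@dataclass
class FragmentMatrix:
    """S x n matrix of fragment intensity traces centred on scan C_0.

    Rows are cycles C_{-k}..C_{+k} (k = (S-1)/2); columns are the fragments of
    the centre scan that survive the m/z exclusions.  Cycles beyond the run
    boundary contribute all-zero rows.
    """

    fragment_mzs: np.ndarray
    intensities: np.ndarray  # shape (S, n)
    center_row: int
    window: IsolationWindow
    source_scan: int

    @property
    def n_fragments(self) -> int:
        return self.fragment_mzs.size

    @property
    def S(self) -> int:
        return self.intensities.shape[0]


@dataclass
class PseudoSpectrum:
    """A demultiplexed fragment group presented as a DDA-like spectrum.

    ``pseudo_precursor_mz`` is always the isolation-window center.  Peak
    intensities are those of the centre scan (C_0).  ``first_collection`` and
    ``second_collection`` hold the column indices (into the source matrix) of
    the two collection steps; they are disjoint.  A fallback pseudo-spectrum
    reproduces the raw scan unchanged.
    """

    mz: np.ndarray
    intensity: np.ndarray
    pseudo_precursor_mz: float
    source_scan: int
    rt: float
    window_index: int
    iteration: int
    first_collection: frozenset = frozenset()
    second_collection: frozenset = frozenset()
    is_fallback: bool = False

    def __post_init__(self):
        if self.first_collection & self.second_collection:
            raise ValueError("F-1st and F-2nd must be disjoint")

    @property
    def fragment_indices(self) -> frozenset:
        return self.first_collection | self.second_collection


# ---------------------------------------------------------------------------
# S estimation
# ---------------------------------------------------------------------------

def estimate_cycle_window(run: MSRun, trace_mz_tol_ppm: float = 10.0,
                          default: int = 5) -> int:
    """Estimate S: the average number of consecutive MS1 scans over which a
    base peak persists, rounded, forced odd (rounding up) and clamped to >= 3.
    """
    if len(run.ms1_scans) < 3:
        log.warning("fewer than 3 MS1 scans; using default S=%d", default)
        return default
    base_mzs = np.array([s.base_peak_mz for s in run.ms1_scans])
    runs = []
    length = 1
    for prev, cur in zip(base_mzs[:-1], base_mzs[1:]):
        if np.isfinite(prev) and np.isfinite(cur) and \
                abs(cur - prev) <= prev * trace_mz_tol_ppm * 1e-6:
            length += 1
        else:
            runs.append(length)
            length = 1
    runs.append(length)
    s = int(round(float(np.mean(runs))))
    if s % 2 == 0:
        s += 1
    return max(s, 3)


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _nearest_intensity(scan: Ms2Scan, query_mz: np.ndarray, ppm: float) -> np.ndarray:
    """Intensity of the closest peak within ppm tolerance for each query m/z."""
    out = np.zeros(query_mz.size)
    if scan.mz.size == 0 or query_mz.size == 0:
        return out
    idx = np.searchsorted(scan.mz, query_mz)
    left = np.clip(idx - 1, 0, scan.mz.size - 1)
    right = np.clip(idx, 0, scan.mz.size - 1)
    d_left = np.abs(scan.mz[left] - query_mz)
    d_right = np.abs(scan.mz[right] - query_mz)
    use_left = d_left <= d_right
    best = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    ok = dist <= query_mz * ppm * 1e-6
    out[ok] = scan.intensity[best[ok]]
    return out


def build_fragment_matrix(scans: list[Ms2Scan], c0: int, window: IsolationWindow,
                          config: DemuxConfig, S: int) -> FragmentMatrix:
    """Build the S x n trace matrix for the scan at cycle index ``c0``.

    Columns are the centre scan's peaks with m/z >= ``min_fragment_mz`` and
    outside the isolation window's m/z range.  Each entry is the intensity of
    the closest peak within ``trace_mz_tol_ppm`` in the corresponding cycle's
    scan, or 0; cycles beyond the run boundary give all-zero rows.
    """
    if not (0 <= c0 < len(scans)):
        raise IndexError("c0 out of range")
    center = scans[c0]
    keep = (center.mz >= config.min_fragment_mz) & \
           ~((center.mz >= window.lower) & (center.mz <= window.upper))
    frag_mzs = center.mz[keep]
    k = (S - 1) // 2
    mat = np.zeros((S, frag_mzs.size))
    for row, cyc in enumerate(range(c0 - k, c0 + k + 1)):
        if cyc < 0 or cyc >= len(scans):
            continue
        if cyc == c0:
            mat[row] = center.intensity[keep]
        else:
            mat[row] = _nearest_intensity(scans[cyc], frag_mzs, config.trace_mz_tol_ppm)
    return FragmentMatrix(frag_mzs, mat, center_row=k, window=window,
                          source_scan=center.scan_id)


# ---------------------------------------------------------------------------
# Base peak
# ---------------------------------------------------------------------------

def _has_three_consecutive_through_center(col: np.ndarray, center: int) -> bool:
    """True if a run of >= 3 consecutive non-zero entries includes ``center``."""
    if col[center] == 0:
        return False
    lo = center
    while lo - 1 >= 0 and col[lo - 1] > 0:
        lo -= 1
    hi = center
    while hi + 1 < col.size and col[hi + 1] > 0:
        hi += 1
    return hi - lo + 1 >= 3


def find_base_peak(matrix: FragmentMatrix, raw_base_intensity: float,
                   config: DemuxConfig,
                   active: np.ndarray | None = None) -> int | None:
    """Pick the seed fragment for one demultiplexing round.

    Eligible columns have m/z > 300 Th, a non-zero trace in at least three
    consecutive cycles including C_0, and a centre intensity above 1% of the
    raw scan's base peak.  Among eligible (active) columns the one with the
    highest centre intensity wins; ties break to the lowest m/z.  Returns the
    column index, or None when nothing is eligible.
    """
    cols = np.arange(matrix.n_fragments) if active is None else np.asarray(active)
    best = None
    best_int = -1.0
    best_mz = np.inf
    for c in cols:
        mz = matrix.fragment_mzs[c]
        ci = matrix.intensities[matrix.center_row, c]
        if mz <= config.base_peak_min_mz:
            continue
        if ci <= config.base_peak_min_rel_intensity * raw_base_intensity:
            continue
        if not _has_three_consecutive_through_center(matrix.intensities[:, c],
                                                     matrix.center_row):
            continue
        if ci > best_int or (ci == best_int and mz < best_mz):
            best, best_int, best_mz = int(c), ci, mz
    return best


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def pearson_profiles(profiles: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``profiles`` against ``reference``.

    A profile (or reference) with zero variance yields r = 0, a deliberately
    defined value that can never pass any positive threshold.
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    ref = np.asarray(reference, dtype=float)
    ref_c = ref - ref.mean()
    ref_ss = float(ref_c @ ref_c)
    prof_c = profiles - profiles.mean(axis=1, keepdims=True)
    prof_ss = np.einsum("ij,ij->i", prof_c, prof_c)
    out = np.zeros(profiles.shape[0])
    if ref_ss <= 0:
        return out
    ok = prof_ss > 0
    out[ok] = (prof_c[ok] @ ref_c) / np.sqrt(prof_ss[ok] * ref_ss)
    return np.clip(out, -1.0, 1.0)


def profile_pcc(matrix: FragmentMatrix, base_col: int,
                cols: np.ndarray | None = None) -> np.ndarray:
    """PCC of every other column's trace against the base column's trace."""
    if cols is None:
        cols = np.array([c for c in range(matrix.n_fragments) if c != base_col])
    cols = np.asarray(cols, dtype=int)
    if cols.size == 0:
        return np.zeros(0)
    return pearson_profiles(matrix.intensities[:, cols].T,
                            matrix.intensities[:, base_col])


# ---------------------------------------------------------------------------
# KDE threshold
# ---------------------------------------------------------------------------

def kde_density(values: np.ndarray, grid: np.ndarray, bandwidth: float) -> np.ndarray:
    """Gaussian kernel density estimate evaluated on ``grid``."""
    values = np.asarray(values, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    k = np.exp(-0.5 * z * z)
    return k.sum(axis=1) / (values.size * bandwidth * np.sqrt(2.0 * np.pi))


def _local_maxima(d: np.ndarray) -> list[int]:
    idx = []
    for i in range(d.size):
        left = d[i - 1] if i > 0 else -np.inf
        right = d[i + 1] if i < d.size - 1 else -np.inf
        if d[i] > left and d[i] >= right:
            idx.append(i)
    return idx


def kde_threshold(pcc_values: np.ndarray, config: DemuxConfig) -> float:
    """Derive the PCC cutoff p0 separating within- from between-peptide
    correlations.

    A Gaussian KDE (bandwidth 0.05 by default) is evaluated on a fixed grid
    over [-1, 1].  The base peak's own fragments form the rightmost density
    mode (their PCC is ~1 by construction); the boundary p is the deepest
    valley between that mode and the nearest competing mode to its left, and
    p0 = max(p, pcc_floor).  A unimodal density yields the floor.  Always
    pcc_floor <= p0 <= 1.
    """
    values = np.asarray(pcc_values, dtype=float)
    if values.size == 0:
        return config.pcc_floor
    grid = np.arange(-1.0, 1.0 + config.kde_grid_step / 2, config.kde_grid_step)
    dens = kde_density(values, grid, config.kde_bandwidth)
    maxima = _local_maxima(dens)
    if len(maxima) < 2:
        return config.pcc_floor
    lo, hi = maxima[-2], maxima[-1]
    valley = lo + int(np.argmin(dens[lo:hi + 1]))
    p = float(grid[valley])
    return float(min(max(p, config.pcc_floor), 1.0))


# ---------------------------------------------------------------------------
# Assembly and iteration
# ---------------------------------------------------------------------------

def assemble_pseudo_spectrum(matrix: FragmentMatrix, base_col: int, p0: float,
                             config: DemuxConfig, rt: float, iteration: int,
                             active: np.ndarray | None = None,
                             ) -> tuple[PseudoSpectrum, np.ndarray]:
    """Two-step fragment collection around the base peak.

    F-1st = base peak plus every active fragment whose trace correlates with
    the base trace above p0.  F-2nd = remaining fragments whose best PCC
    against any F-1st member exceeds p0.  The pseudo-spectrum reports the
    centre-scan peaks of F-1st + F-2nd; everything else is F-rest, returned for
    the next iteration.
    """
    if active is None:
        active = np.arange(matrix.n_fragments)
    active = np.asarray(active, dtype=int)
    others = active[active != base_col]
    pcc = profile_pcc(matrix, base_col, others)
    first = set(others[pcc > p0].tolist()) | {int(base_col)}
    rest0 = [c for c in others.tolist() if c not in first]
    second: set[int] = set()
    if rest0 and first:
        first_profiles = matrix.intensities[:, sorted(first)].T
        for c in rest0:
            r = pearson_profiles(first_profiles, matrix.intensities[:, c])
            if r.max() > p0:
                second.add(c)
    rest = np.array([c for c in rest0 if c not in second], dtype=int)
    members = np.array(sorted(first | second), dtype=int)
    ps = PseudoSpectrum(
        mz=matrix.fragment_mzs[members],
        intensity=matrix.intensities[matrix.center_row, members],
        pseudo_precursor_mz=matrix.window.center_mz,
        source_scan=matrix.source_scan,
        rt=rt,
        window_index=matrix.window.index,
        iteration=iteration,
        first_collection=frozenset(int(c) for c in first),
        second_collection=frozenset(int(c) for c in second),
    )
    return ps, rest


def demultiplex_scan(scans: list[Ms2Scan], c0: int, window: IsolationWindow,
                     config: DemuxConfig, S: int) -> list[PseudoSpectrum]:
    """Demultiplex one MS2 scan into pseudo-spectra.

    Iterates base-peak detection, the >10-fragments-at-PCC>0.9 gate, KDE
    thresholding and two-step collection on the shrinking fragment set; stops
    when no base peak is eligible, the gate fails, fewer than 10 fragments
    remain, or ``max_iterations`` is hit.  If no pseudo-spectrum was produced,
    the raw scan itself is reported as a single fallback pseudo-spectrum.
    """
    raw = scans[c0]
    matrix = build_fragment_matrix(scans, c0, window, config, S)
    active = np.arange(matrix.n_fragments)
    out: list[PseudoSpectrum] = []
    for _ in range(config.max_iterations):
        base = find_base_peak(matrix, raw.base_peak_intensity, config, active)
        if base is None:
            break
        others = active[active != base]
        pcc = profile_pcc(matrix, base, others)
        if int(np.sum(pcc > config.high_pcc)) <= config.min_high_pcc_fragments:
            break
        p0 = kde_threshold(pcc, config)
        ps, active = assemble_pseudo_spectrum(
            matrix, base, p0, config, rt=raw.rt, iteration=len(out) + 1,
            active=active)
        out.append(ps)
        if active.size < config.min_rest_fragments:
            break
    if not out:
        out.append(PseudoSpectrum(
            mz=raw.mz.copy(), intensity=raw.intensity.copy(),
            pseudo_precursor_mz=window.center_mz, source_scan=raw.scan_id,
            rt=raw.rt, window_index=window.index, iteration=1, is_fallback=True))
    return out


@dataclass
class DemuxStats:
    n_scans: int = 0
    n_pseudo: int = 0
    n_fallback: int = 0
    iterations_hist: dict = field(default_factory=dict)


def demultiplex_run(run: MSRun, config: DemuxConfig | None = None,
                    ) -> tuple[list[PseudoSpectrum], DemuxStats]:
    """Demultiplex every MS2 scan of a run. Deterministic: no randomness."""
    config = config or DemuxConfig()
    S = config.cycle_window_s or estimate_cycle_window(run, config.trace_mz_tol_ppm)
    stats = DemuxStats()
    out: list[PseudoSpectrum] = []
    for wi in sorted(run.ms2_by_window):
        scans = run.ms2_by_window[wi]
        window = run.window(wi)
        for c0 in range(len(scans)):
            pss = demultiplex_scan(scans, c0, window, config, S)
            stats.n_scans += 1
            stats.n_pseudo += len(pss)
            stats.n_fallback += sum(p.is_fallback for p in pss)
            k = len([p for p in pss if not p.is_fallback])
            stats.iterations_hist[k] = stats.iterations_hist.get(k, 0) + 1
            out.extend(pss)
    log.info("demultiplexed %d scans -> %d pseudo-spectra (%d fallbacks), S=%d",
             stats.n_scans, stats.n_pseudo, stats.n_fallback, S)
    return out, stats
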