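"""Putative-modification annotation of unexplained PSMs.

A peptide hit without precursor evidence at its unmodified mass may still be
real: its precursor may carry a modification, shifting the MS1 signal by the
modification's delta mass.  This module detects candidate precursor signals
inside the isolation window (S/N > 10, >= 2 consecutive MS1 scans, > 3 isotope
peaks, isotope-envelope shape correlating > 0.8 with the theoretical pattern),
matches the observed mass difference against a Unimod-style delta-mass table,
localizes the modification site with a binomial fragment-matching score
(ptmRS-like; acceptance at site probability > 0.75), requires the precursor and
fragment chromatograms to co-elute (median PCC > 0.9 over >= 4 matched
fragments), and ranks surviving candidates by consecutive b/y coverage, isotope
intensity, and PCC.  One modification per peptide is assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy import stats as _stats

from .demultiplex import PseudoSpectrum, pearson_profiles
from .refine import MassCalibration
from .search import (ISOTOPE_SPACING, PROTON, fragment_ladders, mz_from_mass,
                     peptide_mass)
from .spectra_io import MSRun

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Modification table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModificationRecord:
    """A named mass shift with residue/terminus specificity."""

    id: str
    name: str
    delta_mass: float
    sites: frozenset[str]  # residue letters plus optional 'nterm'/'cterm'

    def __post_init__(self):
        if not np.isfinite(self.delta_mass) or abs(self.delta_mass) >= 2000:
            raise ValueError("modification delta mass out of range")


def load_modification_table(path=None) -> list[ModificationRecord]:
    """Load the modification table (TSV: id, name, delta_mass, sites).

    Without ``path`` the packaged snapshot of common Unimod entries is used;
    users can pass their own table with the same columns.
    """
    if path is None:
        src = resources.files("diadem").joinpath("data/modifications.tsv")
        df = pd.read_csv(src.open(), sep="\t", dtype={"id": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
    out = []
    for _, r in df.iterrows():
        sites = frozenset(s.strip() for s in str(r["sites"]).split(",") if s.strip())
        out.append(ModificationRecord(str(r["id"]), r["name"],
                                      float(r["delta_mass"]), sites))
    return out


def admissible_sites(record: ModificationRecord, sequence: str) -> list[int]:
    """0-based residue indices where ``record`` may sit on ``sequence``."""
    sites = [i for i, aa in enumerate(sequence) if aa in record.sites]
    if "nterm" in record.sites and 0 not in sites:
        sites.insert(0, 0)
    if "cterm" in record.sites and len(sequence) - 1 not in sites:
        sites.append(len(sequence) - 1)
    return sorted(set(sites))


# ---------------------------------------------------------------------------
# Theoretical isotope patterns
# ---------------------------------------------------------------------------

_ELEMENT_DIST: dict[str, np.ndarray] = {}


def _element_distribution(element: str) -> np.ndarray:
    """Isotope abundance vector of one element, indexed by neutron surplus."""
    if element in _ELEMENT_DIST:
        return _ELEMENT_DIST[element]
    iso = _pmass.nist_mass[element]
    natural = [k for k in iso if k != 0 and iso[k][1] > 0]
    mono = min(natural)
    pairs = sorted((k - mono, iso[k][1]) for k in natural)
    size = max(d for d, _ in pairs) + 1
    v = np.zeros(size)
    for d, ab in pairs:
        v[d] = ab
    _ELEMENT_DIST[element] = v
    return v


def _convolve_power(dist: np.ndarray, n: int, k: int) -> np.ndarray:
    """``dist`` convolved with itself ``n`` times, truncated to ``k`` terms."""
    result = np.zeros(k)
    result[0] = 1.0
    base = dist[:k].copy()
    while n:
        if n & 1:
            result = np.convolve(result, base)[:k]
        base = np.convolve(base, base)[:k]
        n >>= 1
    return result


def theoretical_isotope_pattern(sequence: str, k: int = 6) -> np.ndarray:
    """Theoretical isotope envelope of a stripped peptide sequence.

    The elemental composition (residue formulas plus water) is convolved
    element-wise from per-element natural isotope distributions; the first
    ``k`` isotopes are returned normalized so the most intense equals 1.
    """
    comp = _pmass.Composition(sequence=sequence)
    pattern = np.zeros(k)
    pattern[0] = 1.0
    for element, count in comp.items():
        pattern = np.convolve(pattern, _convolve_power(
            _element_distribution(element), count, k))[:k]
    return pattern / pattern.max()


# ---------------------------------------------------------------------------
# Precursor candidate detection
# ---------------------------------------------------------------------------

@dataclass
class PtmConfig:
    ms1_ppm_tol: float = 10.0
    min_snr: float = 10.0
    min_consecutive_ms1: int = 2
    min_isotope_peaks: int = 4  # "greater than 3"
    min_isotope_pcc: float = 0.8
    charges: tuple[int, ...] = (1, 2, 3, 4, 5)
    rt_halfwidth_cycles: int = 5
    peak_depth: int = 8  # top-d peaks per 100 Th for localization
    frag_tol_da: float = 0.02
    min_site_probability: float = 0.75
    min_median_pcc: float = 0.9
    min_corr_fragments: int = 4
    top_fragments: int = 5
    delta_ppm_tol: float = 10.0


@dataclass
class PrecursorCandidate:
    """An MS1 isotope-envelope feature inside an isolation window."""

    mono_mz: float
    charge: int
    snr: float
    consecutive_ms1: int
    isotope_mzs: np.ndarray
    isotope_intensities: np.ndarray
    isotope_pcc: float
    apex_rt: float
    apex_scan_index: int

    @property
    def neutral_mass(self) -> float:
        return (self.mono_mz - PROTON) * self.charge

    @property
    def envelope_intensity(self) -> float:
        return float(self.isotope_intensities.sum())


def _peak_at(scan, mz: float, ppm: float) -> int | None:
    if scan.mz.size == 0:
        return None
    i = int(np.searchsorted(scan.mz, mz))
    best, dist = None, np.inf
    for j in (i - 1, i):
        if 0 <= j < scan.mz.size:
            d = abs(scan.mz[j] - mz)
            if d < dist:
                best, dist = j, d
    return best if best is not None and dist <= mz * ppm * 1e-6 else None


def detect_precursor_candidates(run: MSRun, window, rt: float,
                                stripped_sequence: str,
                                config: PtmConfig | None = None,
                                ) -> list[PrecursorCandidate]:
    """Find MS1 features in the isolation window that could be the (modified)
    precursor of the PSM's peptide.

    All four filter criteria are enforced: S/N > 10 against the median local
    intensity, presence in >= 2 consecutive MS1 scans, more than 3 isotope
    peaks at spacing 1.00335/z, and a Pearson correlation > 0.8 between the
    observed envelope and the theoretical pattern of the stripped sequence.
    """
    config = config or PtmConfig()
    if not run.ms1_scans:
        return []
    rts = run.ms1_rts()
    center = int(np.clip(np.searchsorted(rts, rt), 0, rts.size - 1))
    lo = max(0, center - config.rt_halfwidth_cycles)
    hi = min(len(run.ms1_scans) - 1, center + config.rt_halfwidth_cycles)
    theo = theoretical_isotope_pattern(stripped_sequence)
    out: list[PrecursorCandidate] = []
    seen: list[tuple[float, int]] = []
    for si in range(lo, hi + 1):
        scan = run.ms1_scans[si]
        sel = (scan.mz >= window.lower) & (scan.mz <= window.upper)
        local_mz, local_int = scan.mz[sel], scan.intensity[sel]
        if local_mz.size == 0:
            continue
        for pi in np.flatnonzero(sel):
            mono = float(scan.mz[pi])
            inten = float(scan.intensity[pi])
            for z in config.charges:
                if any(abs(mono - m) <= m * config.ms1_ppm_tol * 1e-6
                       and z == zz for m, zz in seen):
                    continue
                spacing = ISOTOPE_SPACING / z
                # reject if this peak is itself an isotope of a lower peak
                if _peak_at(scan, mono - spacing, config.ms1_ppm_tol) is not None:
                    continue
                env_mz = [mono]
                env_int = [inten]
                while True:
                    j = _peak_at(scan, mono + len(env_mz) * spacing,
                                 config.ms1_ppm_tol)
                    if j is None or scan.intensity[j] <= 0:
                        break
                    env_mz.append(float(scan.mz[j]))
                    env_int.append(float(scan.intensity[j]))
                if len(env_mz) < config.min_isotope_peaks:
                    continue
                # noise = median window-local intensity, excluding the
                # candidate's own envelope (in a sparse window the envelope
                # would otherwise dominate its own noise estimate)
                env_arr = np.array(env_mz)
                is_env = np.min(np.abs(local_mz[:, None] - env_arr[None, :]),
                                axis=1) <= local_mz * config.ms1_ppm_tol * 1e-6
                noise_pool = local_int[~is_env]
                if noise_pool.size >= 3:
                    noise = float(np.median(noise_pool))
                else:
                    noise = float(np.percentile(scan.intensity, 25)) \
                        if scan.intensity.size else 0.0
                if noise > 0 and inten / noise <= config.min_snr:
                    continue
                # consecutive MS1 presence of the monoisotope
                consec = 1
                i2 = si - 1
                while i2 >= 0 and _peak_at(run.ms1_scans[i2], mono,
                                           config.ms1_ppm_tol) is not None:
                    consec += 1
                    i2 -= 1
                i2 = si + 1
                while i2 < len(run.ms1_scans) and \
                        _peak_at(run.ms1_scans[i2], mono,
                                 config.ms1_ppm_tol) is not None:
                    consec += 1
                    i2 += 1
                if consec < config.min_consecutive_ms1:
                    continue
                obs = np.array(env_int)
                kk = min(obs.size, theo.size)
                pcc = float(pearson_profiles(obs[None, :kk], theo[:kk])[0])
                if pcc <= config.min_isotope_pcc:
                    continue
                out.append(PrecursorCandidate(
                    mono_mz=mono, charge=z,
                    snr=inten / noise if noise > 0 else np.inf,
                    consecutive_ms1=consec,
                    isotope_mzs=np.array(env_mz),
                    isotope_intensities=obs,
                    isotope_pcc=pcc,
                    apex_rt=float(scan.rt), apex_scan_index=si))
                seen.append((mono, z))
    return out


# ---------------------------------------------------------------------------
# Unimod delta matching
# ---------------------------------------------------------------------------

def match_unimod(peptide: str, peptide_mass_da: float,
                 candidate: PrecursorCandidate,
                 mod_table: Sequence[ModificationRecord],
                 ppm_tol: float = 10.0,
                 ) -> list[tuple[ModificationRecord, list[int]]]:
    """Match the observed mass delta against the modification table.

    The delta is candidate neutral mass minus theoretical peptide mass; a
    record matches when its delta mass agrees within ``ppm_tol`` (on the
    neutral mass) and its site specificity intersects the peptide.  One
    modification per peptide is assumed.
    """
    delta = candidate.neutral_mass - peptide_mass_da
    tol = candidate.neutral_mass * ppm_tol * 1e-6
    out = []
    for rec in mod_table:
        if abs(delta - rec.delta_mass) <= tol:
            sites = admissible_sites(rec, peptide)
            if sites:
                out.append((rec, sites))
    return out


# ---------------------------------------------------------------------------
# Site localization (binomial / ptmRS-like)
# ---------------------------------------------------------------------------

def _top_peaks_per_window(mz: np.ndarray, intensity: np.ndarray,
                          depth: int, window_th: float = 100.0,
                          ) -> tuple[np.ndarray, np.ndarray]:
    keep = np.zeros(mz.size, dtype=bool)
    if mz.size == 0:
        return mz, intensity
    start = np.floor(mz / window_th)
    for w in np.unique(start):
        idx = np.flatnonzero(start == w)
        if idx.size > depth:
            idx = idx[np.argsort(intensity[idx])[-depth:]]
        keep[idx] = True
    return mz[keep], intensity[keep]


def localize_sites(mz: np.ndarray, intensity: np.ndarray, peptide: str,
                   modification: ModificationRecord, sites: Sequence[int],
                   config: PtmConfig | None = None,
                   ) -> dict[int, float]:
    """Site localization probabilities from site-determining fragment ions.

    For each admissible single-site isoform, the mass-shifted b/y ladder is
    matched against the top-``peak_depth`` peaks per 100 Th; the isoform score
    is -10*log10 of the binomial survival probability of observing at least
    that many matches by chance (match probability p = depth * 2*tol / 100).
    Site probabilities are the normalized isoform likelihoods and sum to 1.
    """
    config = config or PtmConfig()
    sites = list(sites)
    if not sites:
        raise ValueError("modification has no admissible site on this peptide")
    if len(sites) == 1:
        return {sites[0]: 1.0}
    fmz, fint = _top_peaks_per_window(mz, intensity, config.peak_depth)
    p = config.peak_depth * 2.0 * config.frag_tol_da / 100.0
    log_sf = np.empty(len(sites))
    for i, site in enumerate(sites):
        b, y = fragment_ladders(peptide, modification.delta_mass, site)
        theo = np.concatenate([b, y])
        n_match = 0
        for t in theo:
            j = int(np.searchsorted(fmz, t))
            for jj in (j - 1, j):
                if 0 <= jj < fmz.size and abs(fmz[jj] - t) <= config.frag_tol_da:
                    n_match += 1
                    break
        log_sf[i] = _stats.binom.logsf(n_match - 1, theo.size, p)
    # likelihood_i = 1 / sf_i; normalize in log space
    x = -log_sf
    if np.any(np.isinf(x)):
        probs = np.where(np.isinf(x), 1.0, 0.0)
        probs /= probs.sum()
    else:
        x = x - x.max()
        probs = np.exp(x)
        probs /= probs.sum()
    return {site: float(pr) for site, pr in zip(sites, probs)}


# ---------------------------------------------------------------------------
# Precursor-fragment correlation
# ---------------------------------------------------------------------------

def precursor_fragment_pcc(candidate: PrecursorCandidate, psm_row,
                           run: MSRun, matched_fragment_mzs: np.ndarray,
                           matched_fragment_intensities: np.ndarray,
                           config: PtmConfig | None = None,
                           ) -> tuple[float | None, str]:
    """Median PCC between the precursor's MS1 trace and the MS2 traces of the
    top-5 (by intensity) matched fragments.

    The MS1 profile is linearly interpolated onto the MS2 cycle times.  At
    least four fragments with a computable PCC are required; otherwise the
    annotation is rejected with reason ``"insufficient fragments"``.
    """
    config = config or PtmConfig()
    scans = run.ms2_by_window[int(psm_row["window_index"])]
    rts = np.array([s.rt for s in scans])
    c0 = int(np.clip(np.searchsorted(rts, float(psm_row["rt"])), 0,
                     len(scans) - 1))
    lo = max(0, c0 - config.rt_halfwidth_cycles)
    hi = min(len(scans) - 1, c0 + config.rt_halfwidth_cycles)
    cycle_rts = rts[lo:hi + 1]

    ms1_rts = run.ms1_rts()
    ms1_trace = np.zeros(ms1_rts.size)
    for i, scan in enumerate(run.ms1_scans):
        j = _peak_at(scan, candidate.mono_mz, config.ms1_ppm_tol)
        if j is not None:
            ms1_trace[i] = scan.intensity[j]
    prec_profile = np.interp(cycle_rts, ms1_rts, ms1_trace)

    order = np.argsort(matched_fragment_intensities)[::-1][:config.top_fragments]
    pccs = []
    for fi in order:
        fmz = matched_fragment_mzs[fi]
        prof = np.empty(cycle_rts.size)
        for k, ci in enumerate(range(lo, hi + 1)):
            j = _peak_at(scans[ci], fmz, config.ms1_ppm_tol)
            prof[k] = scans[ci].intensity[j] if j is not None else 0.0
        if np.ptp(prof) > 0 and np.ptp(prec_profile) > 0:
            pccs.append(float(pearson_profiles(prof[None, :], prec_profile)[0]))
    if len(pccs) < config.min_corr_fragments:
        return None, "insufficient fragments"
    return float(np.median(pccs)), "ok"


# ---------------------------------------------------------------------------
# Candidate ranking and orchestration
# ---------------------------------------------------------------------------

@dataclass
class ModificationAnnotation:
    """A putative modification explaining an unexplained PSM."""

    candidate: PrecursorCandidate
    modification: ModificationRecord
    site: int
    site_probability: float
    median_pcc: float
    consecutive_by_length: int
    ppm_error: float
    rank: int = 0


def rank_modification_candidates(annotations: list[ModificationAnnotation],
                                 ) -> ModificationAnnotation | None:
    """Rank annotations by (1) consecutive b/y coverage, (2) precursor isotope
    intensity, (3) median precursor-fragment PCC; return the top one."""
    if not annotations:
        return None
    ordered = sorted(annotations, key=lambda a: (
        -a.consecutive_by_length, -a.candidate.envelope_intensity,
        -a.median_pcc))
    for i, a in enumerate(ordered, start=1):
        a.rank = i
    return ordered[0]


def annotate_unexplained(unexplained: pd.DataFrame, run: MSRun,
                         pseudo_by_key: dict[tuple[int, int], PseudoSpectrum],
                         mod_table: Sequence[ModificationRecord],
                         calibration: MassCalibration | None = None,
                         config: PtmConfig | None = None) -> pd.DataFrame:
    """Annotate unexplained PSMs with putative modifications.

    For each PSM: detect filtered precursor candidates in its window, match
    their mass deltas against the modification table, localize the site
    (accept > 0.75), require precursor-fragment co-elution (median PCC > 0.9),
    apply the mass-calibration band to the candidate's ppm error, and report
    the top-ranked annotation.  Returns the annotated subset with modification
    columns added.
    """
    from .search import match_fragments  # local import to avoid cycle at load

    config = config or PtmConfig()
    rows = []
    for _, psm in unexplained.iterrows():
        key = (int(psm["scan"]), int(psm["iteration"]))
        ps = pseudo_by_key.get(key)
        if ps is None:
            continue
        window = run.window(int(psm["window_index"]))
        peptide = psm["peptide"]
        pmass = peptide_mass(peptide)
        cands = detect_precursor_candidates(run, window, float(psm["rt"]),
                                            peptide, config)
        annotations: list[ModificationAnnotation] = []
        for cand in cands:
            if cand.charge != int(psm["charge"]):
                continue
            for rec, sites in match_unimod(peptide, pmass, cand, mod_table,
                                           config.delta_ppm_tol):
                site_probs = localize_sites(ps.mz, ps.intensity, peptide,
                                            rec, sites, config)
                best_site = max(site_probs, key=site_probs.get)
                if site_probs[best_site] <= config.min_site_probability:
                    continue
                fm = match_fragments(ps.mz, ps.intensity, peptide,
                                     int(psm["charge"]),
                                     mod_delta=rec.delta_mass,
                                     mod_site=best_site)
                matched_mzs, matched_ints = _matched_peaks(
                    ps, peptide, rec.delta_mass, best_site, config)
                pcc, reason = precursor_fragment_pcc(
                    cand, psm, run, matched_mzs, matched_ints, config)
                if pcc is None or pcc <= config.min_median_pcc:
                    continue
                theo_mz = mz_from_mass(pmass + rec.delta_mass, cand.charge)
                ppm = (cand.mono_mz - theo_mz) / theo_mz * 1e6
                if calibration is not None and calibration.n_anchors >= 20 \
                        and not calibration.contains(ppm):
                    continue
                annotations.append(ModificationAnnotation(
                    cand, rec, best_site, site_probs[best_site], pcc,
                    fm.longest_consecutive_by, ppm))
        best = rank_modification_candidates(annotations)
        if best is None:
            continue
        row = psm.to_dict()
        row.update({
            "mod_name": best.modification.name,
            "mod_delta": best.modification.delta_mass,
            "mod_site": best.site,
            "site_probability": best.site_probability,
            "median_pcc": best.median_pcc,
            "isotope_peak_count": best.candidate.isotope_mzs.size,
            "observed_mz": best.candidate.mono_mz,
            "ppm_error": best.ppm_error,
            "precursor_snr": best.candidate.snr,
            "consecutive_ms1_count": best.candidate.consecutive_ms1,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def _matched_peaks(ps: PseudoSpectrum, peptide: str, mod_delta: float,
                   site: int, config: PtmConfig,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-spectrum peaks matching the modified peptide's b/y ladder."""
    b, y = fragment_ladders(peptide, mod_delta, site)
    theo = np.concatenate([b, y])
    mzs, ints = [], []
    for t in theo:
        j = int(np.searchsorted(ps.mz, t))
        for jj in (j - 1, j):
            if 0 <= jj < ps.mz.size and abs(ps.mz[jj] - t) <= config.frag_tol_da:
                mzs.append(float(ps.mz[jj]))
                ints.append(float(ps.intensity[jj]))
                break
    return np.array(mzs), np.array(ints)
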