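"""Synthetic DIA runs with complete ground truth.

The generator emulates the acquisition structure the demultiplexer exploits:
random proteins are digested into tryptic peptides, each peptide is assigned an
isolation window by precursor m/z, a charge state, and a Gaussian elution
profile over cycles; MS2 scans superpose the b/y fragment ladders of all
co-eluting peptides in the window plus uncorrelated noise peaks; MS1 scans
carry isotope envelopes (from the theoretical pattern of the stripped
sequence) unless the peptide is flagged precursor-suppressed; an optional
fraction of peptides carries a phosphogroup on S/T/Y with mass-shifted
fragments.  Every non-noise peak is traceable to exactly one peptide record,
and generation is deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ptm import theoretical_isotope_pattern
from .search import (PROTON, ISOTOPE_SPACING, digest_fasta, fragment_ladders,
                     mz_from_mass, peptide_mass)
from .spectra_io import IsolationWindow, Ms1Scan, Ms2Scan, MSRun

log = logging.getLogger(__name__)

PHOSPHO_DELTA = 79.966331

_AA = "ACDEFGHILMNPQSTVWY"  # K/R added separately to control peptide length


@dataclass
class SimConfig:
    """Study conditions for a simulated DIA run.

    The defaults realize a window scheme of 25 x 24 Da windows over
    400-1000 Th, 40 cycles, sigma = 1.5 cycles and 200 sampled peptides, which
    yields a mean co-elution density of about 2 distinct peptides per MS2
    scan.
    """

    seed: int = 0
    n_proteins: int = 40
    protein_length: int = 360
    n_peptides_sampled: int = 200
    window_low: float = 400.0
    window_width: float = 24.0
    n_windows: int = 25
    n_cycles: int = 40
    cycle_time: float = 3.0  # seconds per full MS1+MS2 cycle
    elution_sigma_cycles: float = 1.5
    contribution_floor: float = 0.01  # min elution weight that emits peaks
    noise_peaks_per_scan: int = 30
    noise_intensity_bounds: tuple[float, float] = (1e2, 1e4)
    ms1_noise_peaks: int = 30
    ms1_noise_intensity_bounds: tuple[float, float] = (50.0, 500.0)
    base_intensity_bounds: tuple[float, float] = (1e5, 1e7)
    fragment_decay: float = 0.93
    precursor_intensity_scale: float = 3.0
    n_isotopes: int = 5
    suppressed_precursor_fraction: float = 0.0
    modified_fraction: float = 0.0
    charge_states: tuple[int, ...] = (2, 3)
    charge_probs: tuple[float, ...] = (0.7, 0.3)
    min_peptide_length: int = 7
    max_peptide_length: int = 30

    def __post_init__(self):
        for frac in (self.suppressed_precursor_fraction, self.modified_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if self.window_width <= 0:
            raise ValueError("window width must be positive")
        if self.n_cycles < 7:
            raise ValueError("need at least 7 cycles")

    @property
    def window_high(self) -> float:
        return self.window_low + self.n_windows * self.window_width


@dataclass
class PlantedPeptide:
    """Ground-truth record for one simulated peptide."""

    peptide_id: int
    sequence: str
    charge: int
    mass: float
    precursor_mz: float
    window_index: int
    apex_cycle: float
    base_intensity: float
    suppressed: bool
    mod_site: int | None  # phospho site, 0-based, or None
    fragment_mzs: np.ndarray
    fragment_intensities: np.ndarray  # at elution weight 1

    @property
    def mod_delta(self) -> float | None:
        return PHOSPHO_DELTA if self.mod_site is not None else None


@dataclass
class GroundTruth:
    peptides: list[PlantedPeptide]
    #: (window_index, cycle) -> list of (peptide_id, weight)
    contributions: dict[tuple[int, int], list[tuple[int, float]]]
    #: (window_index, cycle) -> set of noise peak m/z values
    noise_mzs: dict[tuple[int, int], np.ndarray]
    #: the simulated proteome the peptides were digested from
    proteome: list[tuple[str, str]] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        rows = []
        for p in self.peptides:
            rows.append({
                "peptide_id": p.peptide_id, "sequence": p.sequence,
                "charge": p.charge, "mass": p.mass,
                "precursor_mz": p.precursor_mz,
                "window_index": p.window_index, "apex_cycle": p.apex_cycle,
                "suppressed": p.suppressed,
                "mod_site": -1 if p.mod_site is None else p.mod_site,
                "mod_delta": 0.0 if p.mod_site is None else PHOSPHO_DELTA,
                "n_fragments": p.fragment_mzs.size,
            })
        return pd.DataFrame(rows)


def _random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein with K/R placed to give tryptic peptides of 7-18 residues."""
    out = []
    while len(out) < length:
        seg = rng.integers(6, 18)
        out.extend(rng.choice(list(_AA), size=seg))
        out.append(rng.choice(["K", "R"]))
    return "".join(out[:length])


def make_proteome(config: SimConfig, rng: np.random.Generator,
                  ) -> list[tuple[str, str]]:
    return [(f"SYN{i:04d}", _random_protein(rng, config.protein_length))
            for i in range(config.n_proteins)]


def _fragment_set(seq: str, base_intensity: float, decay: float,
                  rng: np.random.Generator, mod_site: int | None,
                  window: IsolationWindow, min_mz: float = 140.0,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """b/y 1+ ladder with geometric rank-decayed intensities in random order.

    Fragments below ``min_mz`` or inside the isolation window would be excluded
    by the demultiplexer anyway but are still emitted — the exclusion is the
    demultiplexer's job, not the instrument's.
    """
    delta = PHOSPHO_DELTA if mod_site is not None else 0.0
    b, y = fragment_ladders(seq, delta, mod_site)
    mzs = np.concatenate([b, y])
    order = rng.permutation(mzs.size)
    ranks = np.empty(mzs.size, dtype=int)
    ranks[order] = np.arange(mzs.size)
    ints = base_intensity * decay ** ranks
    # large fragments of multiply-charged precursors also appear doubly charged
    big = mzs > 700.0
    if np.any(big):
        mzs = np.concatenate([mzs, (mzs[big] + PROTON) / 2.0])
        ints = np.concatenate([ints, 0.3 * ints[big]])
    keep = mzs > 0
    srt = np.argsort(mzs[keep])
    return mzs[keep][srt], ints[keep][srt]


def plant_peptides(config: SimConfig, rng: np.random.Generator,
                   proteome: list[tuple[str, str]]) -> list[PlantedPeptide]:
    entries = digest_fasta(proteome, max_missed=0,
                           min_length=config.min_peptide_length,
                           max_length=config.max_peptide_length)
    windows = [IsolationWindow(config.window_low + (i + 0.5) * config.window_width,
                               config.window_width, i)
               for i in range(config.n_windows)]
    by_window: dict[int, list] = {i: [] for i in range(config.n_windows)}
    charges = np.array(config.charge_states)
    for e in entries:
        z = int(rng.choice(charges, p=np.array(config.charge_probs)))
        mz = mz_from_mass(e.monoisotopic_mass, z)
        if not (config.window_low <= mz < config.window_high):
            continue
        wi = int((mz - config.window_low) // config.window_width)
        by_window[wi].append((e, z, mz))
    per_window = int(np.ceil(config.n_peptides_sampled / config.n_windows))
    chosen: list[tuple] = []
    for wi in range(config.n_windows):
        pool = by_window[wi]
        take = min(per_window, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False) if pool else []
        chosen.extend((wi, *pool[i]) for i in idx)
    if len(chosen) < config.n_peptides_sampled:
        raise ValueError(
            f"proteome yields only {len(chosen)} in-range peptides; "
            f"requested {config.n_peptides_sampled}")
    sel = rng.choice(len(chosen), size=config.n_peptides_sampled, replace=False)
    chosen = [chosen[i] for i in sorted(sel)]

    n_mod = int(round(config.modified_fraction * len(chosen)))
    sty = [k for k, (_, e, _, _) in enumerate(chosen)
           if any(a in "STY" for a in e.sequence)]
    mod_idx = set(rng.choice(sty, size=min(n_mod, len(sty)),
                             replace=False).tolist()) if n_mod else set()
    n_sup = int(round(config.suppressed_precursor_fraction * len(chosen)))
    sup_idx = set(rng.choice(len(chosen), size=n_sup, replace=False).tolist())

    margin = min(max(4.0, 3.0 * config.elution_sigma_cycles),
                 (config.n_cycles - 1) / 2.0)
    peptides: list[PlantedPeptide] = []
    for k, (wi, e, z, mz) in enumerate(chosen):
        seq, mass = e.sequence, e.monoisotopic_mass
        mod_site = None
        if k in mod_idx:
            sites = [i for i, a in enumerate(seq) if a in "STY"]
            mod_site = int(rng.choice(sites))
            mass = mass + PHOSPHO_DELTA
            mz = mz_from_mass(mass, z)
            if not (config.window_low <= mz < config.window_high):
                mod_site, mass = None, e.monoisotopic_mass
                mz = mz_from_mass(mass, z)
            else:
                wi = int((mz - config.window_low) // config.window_width)
        base = float(np.exp(rng.uniform(*np.log(config.base_intensity_bounds))))
        apex = float(rng.uniform(margin, config.n_cycles - 1 - margin))
        fmz, fint = _fragment_set(seq, base, config.fragment_decay, rng,
                                  mod_site, IsolationWindow(
                                      config.window_low + (wi + 0.5) * config.window_width,
                                      config.window_width, wi))
        peptides.append(PlantedPeptide(
            peptide_id=k, sequence=seq, charge=z, mass=mass, precursor_mz=mz,
            window_index=wi, apex_cycle=apex, base_intensity=base,
            suppressed=k in sup_idx, mod_site=mod_site,
            fragment_mzs=fmz, fragment_intensities=fint))
    return peptides


def _merge_peaks(mz_list: list[np.ndarray], int_list: list[np.ndarray],
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate peak sets, summing intensities of exactly coincident m/z."""
    if not mz_list:
        return np.zeros(0), np.zeros(0)
    mz = np.concatenate(mz_list)
    inten = np.concatenate(int_list)
    order = np.argsort(mz, kind="stable")
    mz, inten = mz[order], inten[order]
    uniq, inverse = np.unique(np.round(mz, 6), return_inverse=True)
    summed = np.zeros(uniq.size)
    np.add.at(summed, inverse, inten)
    return uniq, summed


def simulate_run(config: SimConfig) -> tuple[MSRun, GroundTruth]:
    """Generate a DIA run and its ground truth. Deterministic under seed."""
    rng = np.random.default_rng(config.seed)
    proteome = make_proteome(config, rng)
    peptides = plant_peptides(config, rng, proteome)

    windows = [IsolationWindow(config.window_low + (i + 0.5) * config.window_width,
                               config.window_width, i)
               for i in range(config.n_windows)]
    by_window_pep: dict[int, list[PlantedPeptide]] = {
        w.index: [] for w in windows}
    for p in peptides:
        by_window_pep[p.window_index].append(p)

    iso_patterns = {p.peptide_id: theoretical_isotope_pattern(p.sequence,
                                                              config.n_isotopes)
                    for p in peptides if not p.suppressed}

    sigma = config.elution_sigma_cycles
    contributions: dict[tuple[int, int], list[tuple[int, float]]] = {}
    noise_mzs: dict[tuple[int, int], np.ndarray] = {}
    ms1_scans: list[Ms1Scan] = []
    ms2_by_window: dict[int, list[Ms2Scan]] = {w.index: [] for w in windows}
    scan_id = 0
    for cycle in range(config.n_cycles):
        rt0 = cycle * config.cycle_time
        # MS1 scan at the start of the cycle
        scan_id += 1
        mzs, ints = [], []
        for p in peptides:
            if p.suppressed:
                continue
            w = float(np.exp(-(cycle - p.apex_cycle) ** 2 / (2 * sigma ** 2)))
            if w < config.contribution_floor:
                continue
            pattern = iso_patterns[p.peptide_id]
            iso_mz = p.precursor_mz + np.arange(config.n_isotopes) * \
                ISOTOPE_SPACING / p.charge
            mzs.append(iso_mz)
            ints.append(pattern * p.base_intensity
                        * config.precursor_intensity_scale * w)
        n_noise = config.ms1_noise_peaks
        noise_mz = rng.uniform(config.window_low, config.window_high, n_noise)
        lo, hi = config.ms1_noise_intensity_bounds
        noise_int = np.exp(rng.uniform(np.log(lo), np.log(hi), n_noise))
        mzs.append(noise_mz)
        ints.append(noise_int)
        mz_arr, int_arr = _merge_peaks(mzs, ints)
        ms1_scans.append(Ms1Scan(scan_id, rt0, mz_arr, int_arr))

        for w in windows:
            scan_id += 1
            rt = rt0 + (w.index + 1) * config.cycle_time / (config.n_windows + 1)
            mzs, ints = [], []
            contrib: list[tuple[int, float]] = []
            for p in by_window_pep[w.index]:
                wt = float(np.exp(-(cycle - p.apex_cycle) ** 2 / (2 * sigma ** 2)))
                if wt < config.contribution_floor:
                    continue
                mzs.append(p.fragment_mzs)
                ints.append(p.fragment_intensities * wt)
                contrib.append((p.peptide_id, wt))
            noise_mz = rng.uniform(140.0, 1800.0, config.noise_peaks_per_scan)
            lo, hi = config.noise_intensity_bounds
            noise_int = np.exp(rng.uniform(np.log(lo), np.log(hi),
                                           config.noise_peaks_per_scan))
            mzs.append(noise_mz)
            ints.append(noise_int)
            mz_arr, int_arr = _merge_peaks(mzs, ints)
            ms2_by_window[w.index].append(
                Ms2Scan(scan_id, rt, w.index, cycle, mz_arr, int_arr))
            contributions[(w.index, cycle)] = contrib
            noise_mzs[(w.index, cycle)] = np.round(noise_mz, 6)

    run = MSRun(ms1_scans, windows, ms2_by_window, name=f"sim{config.seed}")
    truth = GroundTruth(peptides, contributions, noise_mzs, proteome)
    dens = np.mean([len(v) for v in contributions.values()])
    log.info("simulated %d peptides over %d windows x %d cycles; "
             "mean co-elution density %.2f",
             len(peptides), config.n_windows, config.n_cycles, dens)
    return run, truth


def mean_coelution_density(truth: GroundTruth) -> float:
    """Mean number of distinct contributing peptides per MS2 scan."""
    return float(np.mean([len(v) for v in truth.contributions.values()]))
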