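"""Shared fixtures: simulated runs at the standard study conditions."""

import numpy as np
import pytest

from diadem.demultiplex import DemuxConfig, demultiplex_run
from diadem.synthetic import SimConfig, simulate_run


def jaccard(planted_mz: np.ndarray, pseudo, ppm: float = 10.0) -> float:
    """Jaccard overlap between a planted fragment set and a pseudo-spectrum."""
    matched = 0
    for m in planted_mz:
        j = int(np.searchsorted(pseudo.mz, m))
        if any(0 <= jj < pseudo.mz.size
               and abs(pseudo.mz[jj] - m) <= m * ppm * 1e-6
               for jj in (j - 1, j)):
            matched += 1
    union = planted_mz.size + pseudo.mz.size - matched
    return matched / union if union else 0.0


def planted_ladder(peptide, window) -> np.ndarray:
    """A planted peptide's fragments after the demultiplexer's exclusions."""
    keep = (peptide.fragment_mzs >= 140.0) & ~(
        (peptide.fragment_mzs >= window.lower)
        & (peptide.fragment_mzs <= window.upper))
    return peptide.fragment_mzs[keep]


def recovery_fraction(run, truth, pseudo_spectra, min_jaccard=0.6):
    """Fraction of planted peptides with a pseudo-spectrum at Jaccard >= 0.6."""
    by_window = {}
    for ps in pseudo_spectra:
        by_window.setdefault(ps.window_index, []).append(ps)
    recovered = []
    for p in truth.peptides:
        ladder = planted_ladder(p, run.window(p.window_index))
        best = max((jaccard(ladder, ps)
                    for ps in by_window.get(p.window_index, [])), default=0.0)
        recovered.append(best >= min_jaccard)
    return np.array(recovered)


@pytest.fixture(scope="session")
def small_run():
    """A small run for I/O and refinement tests: 4 windows x 12 cycles."""
    cfg = SimConfig(seed=11, n_peptides_sampled=40, n_windows=4, n_cycles=12,
                    protein_length=200)
    run, truth = simulate_run(cfg)
    return run, truth


@pytest.fixture(scope="session")
def benchmark_run():
    """The standard benchmark conditions: 200 peptides, 24 Da windows,
    sigma = 1.5 cycles, ~2 co-eluting peptides per scan, seed 7, with 30%
    of precursors suppressed in MS1."""
    cfg = SimConfig(seed=7, suppressed_precursor_fraction=0.3)
    run, truth = simulate_run(cfg)
    return run, truth


@pytest.fixture(scope="session")
def benchmark_demux(benchmark_run):
    run, truth = benchmark_run
    pseudo, stats = demultiplex_run(run, DemuxConfig(cycle_window_s=5))
    return run, truth, pseudo, stats
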