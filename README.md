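# diadem

Library-free peptide identification from data-independent acquisition (DIA)
mass spectrometry.

DIA instruments co-fragment every precursor inside wide isolation windows, so
each MS2 scan is a multiplexed mixture of fragments from several peptides —
and some of those peptides never show a usable precursor signal in MS1 at all
(ion suppression, low abundance). Library-based DIA tools cannot see such
peptides; precursor-based demultiplexers (DIA-Umpire-style) cannot either.
`diadem` takes the fragment-only route:

1. **Self-demultiplexing.** For the scan to be demultiplexed (cycle C₀), an
   S×n matrix of fragment intensity traces I_{f,c} is built over the S
   surrounding cycles of the same window. The scan's base peak (m/z > 300,
   ≥ 3 consecutive non-zero cycles, > 1% of the raw base peak) seeds a group;
   Pearson correlations r of every other trace against it are thresholded at
   p₀ = max(p, 0.8), where p is the valley of a Gaussian kernel density
   estimate (bandwidth 0.05) of the r values. A second collection round picks
   up fragments correlating with any first-round member. The group is emitted
   as a DDA-like *pseudo-spectrum* whose precursor m/z is the window center,
   and the procedure iterates on the remaining fragments.
2. **Open search.** Each pseudo-spectrum is searched at assumed charges 1–5
   against a tryptic digest of a FASTA database (plus shuffled decoys) with a
   wide precursor tolerance — ±(w·z/2 + 3) Da (charge-dependent; w = window
   width) or (−100, +400) Da (charge-independent) — scored with a
   hyperscore ln(b!·y!·ΣI) and an expect value from a survival-function tail
   fit.
3. **Refinement.** Hits are verified against MS1 (precursor at the
   theoretical m/z, inside the source window, near the elution time), a ppm
   mass calibration m ± 3s removes outliers, and missed-cleavage and
   homolog artifacts of the open search are collapsed.
4. **Putative modifications.** Unverified hits are tested for a modified
   precursor: MS1 features passing S/N > 10, ≥ 2 consecutive scans, > 3
   isotope peaks and isotope-envelope correlation > 0.8 are matched against a
   Unimod-style delta-mass table; sites are localized with a binomial
   (ptmRS-like) score (accept > 0.75) and the precursor must co-elute with
   the matched fragments (median PCC > 0.9).
5. **FDR.** Target-decoy competition with q-values, estimated separately for
   modified and unmodified peptides; auxiliary features are exportable as a
   Percolator PIN file.

A synthetic-data module generates DIA runs with complete ground truth
(Gaussian elution profiles, co-eluting peptides, isotope envelopes,
suppressed precursors, phosphopeptides), so the whole pipeline is testable
without any external data.

## Worked example

```python
from diadem.synthetic import SimConfig, simulate_run
from diadem.pipeline import PipelineConfig, run_pipeline
from diadem.demultiplex import DemuxConfig

# 200 tryptic peptides over 25 x 24 Da windows, 40 cycles, sigma = 1.5
# cycles, ~2 co-eluting peptides per scan; 30% of precursors suppressed
run, truth = simulate_run(SimConfig(seed=7, suppressed_precursor_fraction=0.3))
res = run_pipeline(run, truth.proteome, "out",
                   PipelineConfig(demux=DemuxConfig(cycle_window_s=5)))
print(res["manifest"]["n_pseudo_spectra"], "pseudo-spectra")
print(res["manifest"]["n_peptides_passing"], "peptides at q <= 0.01")
```

prints

```
1510 pseudo-spectra
203 peptides at q <= 0.01
```

i.e. the 1000 multiplexed MS2 scans yield 1510 demultiplexed pseudo-spectra,
and 203 peptides pass the 1% peptide-level FDR — 197 of the 200 planted
peptides (including 58 of the 60 whose precursor never appears in MS1),
which is the point of fragment-only demultiplexing: losing the precursor
does not lose the identification.

The same stages are available from the shell:

```
diadem simulate --seed 7 --n-peptides 200 --out sim/
diadem demux    --mzml sim/sim7.mzML --out sim/sim7.pseudo.mgf
diadem pipeline --mzml sim/sim7.mzML --fasta sim/targets.fasta --out sim/results
```

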