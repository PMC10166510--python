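# Methods

## Model of the data

A DIA run is a sequence of cycles; each cycle records one MS1 survey scan and
one MS2 scan per isolation window. Every peptide precursor inside a window is
co-fragmented, so an MS2 scan is a superposition of b/y fragment ladders of
all peptides currently eluting in that window, plus chemical noise. A
peptide's fragment intensities across cycles follow its elution profile;
fragments of one peptide are therefore strongly correlated across cycles,
fragments of different peptides generally are not. That correlation structure
— not any precursor signal — is what the demultiplexer consumes, and it is why
peptides whose precursor is invisible in MS1 remain identifiable.

## Demultiplexing

For the scan at cycle C₀ of one window, an S×n matrix holds the traces of its
n fragments over the S cycles centred on C₀ (boundary cycles are zero-padded
so the matrix stays rectangular). Fragments below 140 Th or inside the
window's own m/z range are excluded; trace extraction matches the nearest
peak within 10 ppm (configurable; Orbitrap-class data).

The seed ("base peak") must satisfy m/z > 300 Th, non-zero intensity in ≥ 3
consecutive cycles including C₀, and intensity > 1% of the raw scan's base
peak; ties break to the lowest m/z for determinism. Demultiplexing of a scan
continues only while more than ten fragments correlate with the seed at
r > 0.9. A trace with zero variance is assigned r = 0 — a defined value that
can never pass a positive threshold.

The correlation cutoff p₀ = max(p, 0.8) uses a Gaussian KDE (bandwidth 0.05,
grid step 0.005 over [−1, 1]) of the r values. The boundary p is taken as the
deepest valley between the *rightmost* density mode and the nearest mode to
its left. The rightmost mode is the seed peptide's own fragment cluster
(its traces correlate at r ≈ 1 with the seed by construction); the
next-lower mode is the nearest competing cluster, typically a peptide
co-eluting a fraction of a cycle away. An alternative rule — the valley
between the two *tallest* modes — fails exactly in the three-or-more-peptide
case, where the two tallest modes can both sit below the seed's cluster and
the threshold then swallows a neighbour; this was observed directly on
simulated scans and motivated the rule used here. A unimodal density yields
the floor.

Collection is two-step: F-1st is the seed plus every fragment above p₀
against the seed; F-2nd is every remaining fragment whose best correlation
against an F-1st member exceeds p₀. Their union is reported as a
pseudo-spectrum with the window centre as pseudo-precursor m/z and C₀
intensities as peak intensities. The remainder seeds the next iteration;
iteration stops below ten remaining fragments or after 10 rounds (a safety
valve; the gate terminates earlier in practice). A scan that produces no
pseudo-spectrum is passed through unmodified as a fallback, so no scan is
ever silently dropped.

S, the trace length, is estimated as the mean number of consecutive MS1
scans over which the MS1 base peak persists, rounded, forced odd (upward)
and clamped to ≥ 3. On synthetic data with densely alternating base peaks
this estimator is deliberately conservative; the tests and the acceptance
script fix S = 5, the canonical value for ~2–3 s cycles and ~10 s
chromatographic peaks.

### What demultiplexing cannot do

Two peptides whose elution apexes coincide to within about half a cycle have
(sampled) profiles correlating above any usable threshold; their fragments
merge into one pseudo-spectrum. This is a physical identifiability limit of
correlation-based demultiplexing, not an implementation artifact. At a
co-elution density of ~2 peptides per scan and sigma = 1.5 cycles, roughly
10–15% of peptides have such a twin; the search stage still identifies both
from the merged spectrum (both rank among the top hits), which is why
refinement considers all retained ranks rather than rank 1 only.

## Open search

Tryptic digestion (cleave after K/R except before P, ≤ 2 missed cleavages,
length 7–50); decoys are whole-protein shuffles (seeded, composition-
preserving, `DECOY_` accessions); a shuffled peptide that collides with a
target sequence stays a target. Each pseudo-spectrum is searched at charges
1–5. The precursor tolerance is ±(w·z/2 + 3) Da in charge-dependent mode
(w = window width; the 3 Da margin covers isotope envelopes split between
windows) or (−100, +400) Da in charge-independent mode, which also admits
large modification shifts. Theoretical b/y ions at 1+ (and 2+ for assumed
charge ≥ 3) are matched within 20 ppm, one peak per ion, greedily by ppm
error. The score is the hyperscore ln(b!·y!·ΣI); zero matched intensity is
scored −∞ and can never out-rank a matched candidate.

The expect value (expected number of random candidates at or above a score)
comes from a linear fit to the log survival function of the spectrum's own
candidate scores, over the decline region (above the median, survival ≥ 3,
excluding the extreme tail, which contains the possibly-correct top hits and
would flatten the slope). Zero-match candidates enter the fit at score 0 —
they are observations of the null, and discarding them destroys the fit on
clean spectra where almost nothing matches by chance. When the per-spectrum
fit is degenerate, a run-level fit pooled over *decoy* candidates only is
used; pooling target scores would contaminate the upper tail with true
hits. When both fits fail the candidate count is used as a flat,
deliberately pessimistic expect.

## Refinement

All retained hits (top 5 per spectrum × charge) are checked for MS1
precursor evidence: theoretical m/z inside the source window, a peak within
10 ppm in the MS1 scans within ± S cycles of the pseudo-spectrum's retention
time; the isotope envelope (spacing 1.00335/z) and the run of consecutive
MS1 appearances are recorded as auxiliary features, and the ppm error is
taken at the apex.

Hits sharing one precursor *feature* — same window, same charge, m/z within
tolerance, elution apex within about one cycle — keep only the lowest
expect. The apex-time condition matters: two distinct features 10 ppm apart
in m/z but minutes apart in elution are different precursors.

Verified hits with expect < 0.01 anchor a ppm calibration; hits outside
mean ± 3·sd are removed. The band half-width has a numeric floor of 0.5 ppm:
on near-perfect data the anchor spread collapses below rounding noise and a
literal 3-sigma band would reject true hits. The filter is skipped below 20
anchors.

Open-search artifacts are collapsed at two levels. Per spectrum: a peptide
that is a missed-cleavage extension of another hit on the same spectrum
(substring at tryptic boundaries) is the same species when the mass-delta
difference equals the extension mass (same assumed charge) or whenever the
charges differ (the two pseudo-masses are then incommensurable and the
sequence relation alone marks the artifact); equal-length homologs with ≤ 2
substitutions collapse as connected components, keeping the best expect.
Across spectra: the same relations are applied over each window's pooled
hits when the two readings co-elute, with the winner chosen by precursor
evidence, then matched-ion fraction, then score — an extension artifact can
out-hyperscore its parent at a higher assumed charge, but it never explains
a larger share of its own ion ladder.

## Putative modifications

Unverified rank-1 hits are tested against precursor candidates detected
inside their isolation window: S/N > 10 (noise = median window-local MS1
intensity, excluding the candidate's own envelope, which would otherwise
dominate the estimate in a sparse window), ≥ 2 consecutive MS1 scans, > 3
isotope peaks at spacing 1.00335/z, and Pearson correlation > 0.8 between
the observed envelope and the theoretical isotope pattern of the stripped
sequence. Theoretical patterns come from element-wise convolution of natural
isotope distributions (residue formulas + water, first 6 isotopes,
normalised to the maximum).

The observed mass delta (candidate neutral mass − peptide mass) is matched
within 10 ppm against a packaged snapshot of common Unimod entries
(`diadem/data/modifications.tsv`; users may supply their own table with the
same columns). One modification per peptide is assumed. Site localization
enumerates single-site isoforms, matches each shifted ladder against the
top-8 peaks per 100 Th (±0.02 Da), scores each isoform by the binomial
survival probability of its match count (match probability
p = 8 × 0.04/100), and normalises the isoform likelihoods into site
probabilities (accept > 0.75; a perfectly ambiguous two-site spectrum yields
exactly 0.5/0.5). Finally the candidate's MS1 trace must co-elute with the
top-5 matched fragments' MS2 traces (MS1 linearly interpolated onto MS2
cycle times; ≥ 4 computable correlations; median > 0.9). Competing
annotations rank by consecutive b/y coverage, then envelope intensity, then
median correlation.

## FDR

Target-decoy competition: PSMs sorted by the discriminant,
FDR(s) = (decoys ≥ s + 1)/targets ≥ s with tied scores sharing one
threshold, q = running minimum from the worst score up. Peptide level keeps
the best PSM per (sequence, modification); protein level the best peptide
per accession. Modified and unmodified peptides are estimated in separate
strata, since modified-peptide scores run systematically lower.

The discriminant is the hyperscore. The expect value would be the natural
choice, but it rests on a per-spectrum extrapolation that degenerates
exactly where it matters (sparse candidate sets, clean spectra), and a
degenerate expect once promoted an artifact with three matched ions past
well-supported hits; the hyperscore is directly comparable across spectra
and needs no fit. Expect still governs within-spectrum ranking,
shared-precursor resolution and calibration anchors. PSMs without precursor
evidence that no modification explains still compete in the FDR with their
evidence flag at 0 — removing them would amount to requiring a precursor,
which is exactly what this method exists to avoid. The full feature vector
(expect, hyperscore, score gap, matched counts and fractions, consecutive
coverage, ppm error, isotope count, evidence flag, length, missed
cleavages, charge indicators) is exportable as a Percolator PIN file for
external rescoring.

## Synthetic data

The generator emulates the acquisition geometry the demultiplexer relies
on. Defaults: 25 isolation windows of 24 Da over 400–1000 Th, 40 cycles of
3 s, 200 tryptic peptides (length 7–30, from random proteins with K/R
spacing giving realistic peptide lengths), charges 70% 2+ / 30% 3+,
Gaussian elution with sigma = 1.5 cycles and uniformly random apexes,
fragment intensities geometrically decaying (ratio 0.93) over a random rank
permutation, base intensities log-uniform over 10⁵–10⁷, 30 uncorrelated
noise peaks per MS2 scan (10²–10⁴), MS1 isotope envelopes from the
theoretical pattern unless the peptide is flagged precursor-suppressed.
Fragments above 700 Th also appear doubly charged at 30% intensity, as they
do in HCD spectra of multiply charged precursors; without them, 7-residue
peptides present too few usable fragments to ever pass the
ten-fragment demultiplexing gate, an artifact of over-simplified spectra
rather than of the method. These defaults realize a mean co-elution density
of ~2 distinct peptides per MS2 scan.

What the generator does not model: chromatographic tailing, profile-mode
peaks, isotope envelopes of fragments, neutral losses, detector saturation,
dynamic range compression, and retention-time drift. Passing tests
therefore demonstrate the correctness of the algorithms under the stated
correlation structure, not instrument-level robustness.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at 200 peptides ×
25 windows × 40 cycles and the clean-run check at 150 peptides × 60 cycles;
these sizes exercise every code path while keeping a full run in tens of
seconds. Determinism: all randomness flows from explicit seeds
(`numpy.random.default_rng` in the generator, `random.Random` for decoy
shuffles); demultiplexing and search are deterministic given their inputs,
and ties break lexicographically or to the lower m/z throughout. The
q ≤ 0.01 threshold is only meaningful once a stratum holds on the order of
a hundred targets — with the +1 decoy correction, q cannot fall below
1/#targets — so small demonstration runs should be read at q ≤ 0.05.

## Known limitations

- Exactly co-eluting peptides (apex separation ≲ 0.5 cycle) cannot be
  demultiplexed by correlation; they are identified from merged spectra
  instead, which slightly inflates pseudo-spectrum sizes.
- Peptides shorter than 8 residues clear the ten-fragment gate only when
  doubly charged fragment ions are present.
- One modification per peptide; no neutral-loss-aware localization.
- The native FDR has no learned feature re-weighting; the PIN export exists
  so Percolator can do that externally.
- The S estimator assumes precursors dominate the MS1 base peak for several
  consecutive cycles; on data where that fails, set `cycle_window_s`
  explicitly.
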