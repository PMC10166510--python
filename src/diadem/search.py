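"""Large-precursor-tolerance open search of pseudo-spectra.

A pseudo-spectrum carries no measured precursor mass: only the isolation-window
center.  Each pseudo-spectrum is therefore searched repeatedly, once per assumed
charge state (1-5 by default), against every database peptide whose mass falls
in a wide tolerance window around the pseudo-precursor neutral mass.  The window
is either charge-dependent, +/-(w*z/2 + 3) Da, where w is the isolation-window
width, z the assumed charge and the 3 Da margin covers isotope envelopes that
split between windows; or charge-independent, (-100, +400) Da, which also admits
large modification mass shifts.  Candidates are scored with a hyperscore-style
statistic and an expect value from a survival-function tail fit.
"""

from __future__ import annotations

import logging
import math
import random
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy.special import gammaln

log = logging.getLogger(__name__)

PROTON = 1.00727646688
WATER = 18.0105646863
ISOTOPE_SPACING = 1.00335  # average C13-C12 spacing used for envelopes, Da

#: Monoisotopic residue masses (from the pyteomics reference tables).
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa]
                                  for aa in "ACDEFGHIKLMNPQRSTVWY"}

_NONSTANDARD = set("BZXUOJ")


def peptide_mass(sequence: str) -> float:
    """Neutral monoisotopic peptide mass (Da)."""
    try:
        return sum(RESIDUE_MASS[a] for a in sequence) + WATER
    except KeyError as e:
        raise ValueError(f"non-standard residue {e.args[0]!r} in {sequence!r}") from None


def mz_from_mass(neutral_mass: float, z: int) -> float:
    return (neutral_mass + z * PROTON) / z


def mass_from_mz(mz: float, z: int) -> float:
    return (mz - PROTON) * z


@dataclass
class PeptideEntry:
    sequence: str
    monoisotopic_mass: float
    protein_ids: list[str]
    missed_cleavages: int
    is_decoy: bool = False


_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def _tryptic_fragments(sequence: str) -> list[str]:
    return [p for p in _TRYPSIN.split(sequence) if p]


def digest_fasta(proteins: list[tuple[str, str]], max_missed: int = 2,
                 min_length: int = 7, max_length: int = 50,
                 is_decoy: bool = False) -> list[PeptideEntry]:
    """Tryptic in-silico digestion (cleave after K/R, not before P).

    Peptides with 0..``max_missed`` missed cleavages in the given length range
    are enumerated; duplicate sequences are merged with their protein lists
    union'ed.  Peptides containing non-standard residues (B, Z, X, U, O, J)
    are skipped and counted in the log.
    """
    by_seq: dict[str, PeptideEntry] = {}
    n_skipped = 0
    for acc, seq in proteins:
        pieces = _tryptic_fragments(seq)
        for i in range(len(pieces)):
            for mc in range(max_missed + 1):
                if i + mc >= len(pieces):
                    break
                pep = "".join(pieces[i:i + mc + 1])
                if not (min_length <= len(pep) <= max_length):
                    continue
                if set(pep) & _NONSTANDARD:
                    n_skipped += 1
                    continue
                entry = by_seq.get(pep)
                if entry is None:
                    by_seq[pep] = PeptideEntry(pep, peptide_mass(pep), [acc],
                                               mc, is_decoy)
                else:
                    if acc not in entry.protein_ids:
                        entry.protein_ids.append(acc)
                    entry.missed_cleavages = min(entry.missed_cleavages, mc)
    if n_skipped:
        log.info("skipped %d peptides with non-standard residues", n_skipped)
    return list(by_seq.values())


def generate_decoys(proteins: list[tuple[str, str]], seed: int,
                    ) -> list[tuple[str, str]]:
    """Shuffle-strategy decoy proteins: each sequence is randomly permuted with
    a seeded generator, preserving amino-acid composition; accessions get a
    ``DECOY_`` prefix.  Deterministic for a fixed seed."""
    rng = random.Random(seed)
    out = []
    for acc, seq in proteins:
        chars = list(seq)
        rng.shuffle(chars)
        out.append(("DECOY_" + acc, "".join(chars)))
    return out


# ---------------------------------------------------------------------------
# Tolerance windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToleranceWindow:
    lower: float
    upper: float
    mode: str

    def __post_init__(self):
        if self.lower >= self.upper:
            raise ValueError("tolerance window must have lower < upper")


def tolerance_window(w: float, z: int, mode: str) -> ToleranceWindow:
    """Precursor mass tolerance window in Da on the neutral-mass scale.

    charge_dependent: +/-(w*z/2 + 3), symmetric, growing linearly with the
    assumed charge; charge_independent: (-100, +400) regardless of w and z.
    """
    if mode == "charge_independent":
        return ToleranceWindow(-100.0, 400.0, mode)
    if mode == "charge_dependent":
        if not (1 <= z <= 5):
            raise ValueError(f"charge {z} outside 1..5 for charge-dependent mode")
        if w <= 0:
            raise ValueError("window width must be positive")
        half = w * z / 2.0 + 3.0
        return ToleranceWindow(-half, half, mode)
    raise ValueError(f"unknown tolerance mode {mode!r}")


# ---------------------------------------------------------------------------
# Fragment matching
# ---------------------------------------------------------------------------

def fragment_ladders(sequence: str, mod_delta: float = 0.0,
                     mod_site: int | None = None,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Singly-charged b- and y-ion m/z ladders (b_1..b_{L-1}, y_1..y_{L-1}).

    A single modification of ``mod_delta`` Da at 0-based residue ``mod_site``
    shifts every fragment that contains the site.
    """
    res = np.array([RESIDUE_MASS[a] for a in sequence])
    if mod_site is not None:
        res = res.copy()
        res[mod_site] += mod_delta
    prefix = np.cumsum(res)[:-1]
    total = res.sum()
    b = prefix + PROTON
    y = (total - prefix)[::-1] + WATER + PROTON
    return b, y


@dataclass
class FragmentMatch:
    matched_b: int
    matched_y: int
    longest_consecutive_by: int
    matched_intensity: float
    n_theoretical: int
    matched_b_mask: np.ndarray  # per position 1..L-1, any charge
    matched_y_mask: np.ndarray


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best


def match_fragments(mz: np.ndarray, intensity: np.ndarray, sequence: str,
                    charge: int, frag_tol_ppm: float = 20.0,
                    mod_delta: float = 0.0, mod_site: int | None = None,
                    ) -> FragmentMatch:
    """Match theoretical b/y ions against a sorted peak list.

    Ions are generated at 1+ (and 2+ when the assumed precursor charge is
    >= 3).  Each theoretical ion is paired with its nearest peak within the
    ppm tolerance; a peak may satisfy only one ion, resolved greedily by
    ascending ppm error.
    """
    b1, y1 = fragment_ladders(sequence, mod_delta, mod_site)
    L1 = b1.size
    theo_mz = [b1, y1]
    theo_series = [np.zeros(L1, dtype=int), np.ones(L1, dtype=int)]
    theo_pos = [np.arange(L1), np.arange(L1)]
    if charge >= 3:
        theo_mz += [(b1 + PROTON) / 2.0, (y1 + PROTON) / 2.0]
        theo_series += [np.zeros(L1, dtype=int), np.ones(L1, dtype=int)]
        theo_pos += [np.arange(L1), np.arange(L1)]
    tmz = np.concatenate(theo_mz)
    tseries = np.concatenate(theo_series)
    tpos = np.concatenate(theo_pos)

    b_mask = np.zeros(L1, dtype=bool)
    y_mask = np.zeros(L1, dtype=bool)
    matched_int = 0.0
    nb = ny = 0
    if mz.size:
        idx = np.searchsorted(mz, tmz)
        left = np.clip(idx - 1, 0, mz.size - 1)
        right = np.clip(idx, 0, mz.size - 1)
        d_left = np.abs(mz[left] - tmz)
        d_right = np.abs(mz[right] - tmz)
        use_left = d_left <= d_right
        peak = np.where(use_left, left, right)
        dist = np.where(use_left, d_left, d_right)
        tol = tmz * frag_tol_ppm * 1e-6
        cand = np.flatnonzero(dist <= tol)
        order = cand[np.argsort(dist[cand] / tmz[cand])]
        used_peaks: set[int] = set()
        used_ions: set[int] = set()
        for j in order:
            pj = int(peak[j])
            if pj in used_peaks or j in used_ions:
                continue
            used_peaks.add(pj)
            used_ions.add(int(j))
            matched_int += float(intensity[pj])
            if tseries[j] == 0:
                nb += 1
                b_mask[tpos[j]] = True
            else:
                ny += 1
                y_mask[tpos[j]] = True
    longest = max(_longest_run(b_mask), _longest_run(y_mask))
    return FragmentMatch(nb, ny, longest, matched_int, tmz.size, b_mask, y_mask)


NEG_INF_SCORE = float("-inf")


def hyperscore(match: FragmentMatch) -> float:
    """ln(b! * y! * sum of matched intensities); -inf when nothing matched."""
    if match.matched_intensity <= 0.0:
        return NEG_INF_SCORE
    return (math.lgamma(match.matched_b + 1) + math.lgamma(match.matched_y + 1)
            + math.log(match.matched_intensity))


# ---------------------------------------------------------------------------
# Expect values
# ---------------------------------------------------------------------------

def _survival_fit(scores: np.ndarray) -> tuple[float, float] | None:
    """Fit ln(#candidates >= s) = a + b*s over the decline region of the score
    distribution: scores above the median but excluding the extreme tail
    (survival count < 3), which is dominated by the (possibly correct) top
    hits and would flatten the slope.  Candidates that matched nothing are
    part of the null distribution and enter the fit at score 0.  Returns
    (a, b) with b < 0, or None when the fit is degenerate."""
    s = np.sort(np.where(np.isfinite(scores), scores, 0.0))
    if s.size < 4:
        return None
    # survival count at each distinct score
    uniq = np.unique(s)
    surv = s.size - np.searchsorted(s, uniq, side="left")
    med = np.median(s)
    sel = (uniq >= med) & (surv >= 3)
    x, y = uniq[sel], np.log(surv[sel])
    if x.size < 3 or np.ptp(x) == 0:
        return None
    b, a = np.polyfit(x, y, 1)
    if b >= 0:
        return None
    return float(a), float(b)


def expect_from_fit(score: float, fit: tuple[float, float] | None,
                    n_candidates: int) -> float:
    """Expected number of random candidates scoring >= ``score``."""
    if not np.isfinite(score):
        return float(max(n_candidates, 1))
    if fit is None:
        return float(max(n_candidates, 1))  # uninformative
    a, b = fit
    return float(max(math.exp(a + b * score), 1e-30))


# ---------------------------------------------------------------------------
# Search driver
# ---------------------------------------------------------------------------

def _batch_score(ps, index, cand: list[int], charge: int,
                 config) -> tuple[np.ndarray, np.ndarray]:
    """Hyperscores plus (matched_b, matched_y, n_theoretical, matched_intensity)
    for every candidate, with one vectorized peak lookup for the whole set.

    Peak-sharing conflicts within one candidate are resolved greedily by ppm
    error, matching :func:`match_fragments`; the per-position masks (needed
    only for the reported top hits) are not built here.
    """
    with_2plus = charge >= 3
    ladders = [index.ladder(ci, with_2plus) for ci in cand]
    sizes = np.array([lad.size for lad in ladders])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    tmz = np.concatenate(ladders)
    cand_of_ion = np.repeat(np.arange(len(cand)), sizes)
    # series: first half of each ladder (per charge block) is b, second is y
    is_b = np.zeros(tmz.size, dtype=bool)
    for k, lad in enumerate(ladders):
        half = lad.size // (4 if with_2plus else 2)
        o = offsets[k]
        is_b[o:o + half] = True
        if with_2plus:
            is_b[o + 2 * half:o + 3 * half] = True

    mz, intensity = ps.mz, ps.intensity
    scores = np.full(len(cand), NEG_INF_SCORE)
    stats = np.zeros((len(cand), 4))
    stats[:, 2] = sizes
    if mz.size == 0:
        return scores, stats
    idx = np.searchsorted(mz, tmz)
    left = np.clip(idx - 1, 0, mz.size - 1)
    right = np.clip(idx, 0, mz.size - 1)
    d_left = np.abs(mz[left] - tmz)
    d_right = np.abs(mz[right] - tmz)
    use_left = d_left <= d_right
    peak = np.where(use_left, left, right)
    dist = np.where(use_left, d_left, d_right)
    hit = dist <= tmz * config.frag_tol_ppm * 1e-6
    hit_ions = np.flatnonzero(hit)
    if hit_ions.size == 0:
        return scores, stats
    order = hit_ions[np.argsort(dist[hit_ions] / tmz[hit_ions], kind="stable")]
    # greedy uniqueness per candidate: (candidate, peak) may be used once
    used: set[tuple[int, int]] = set()
    nb = np.zeros(len(cand), dtype=np.int64)
    ny = np.zeros(len(cand), dtype=np.int64)
    m_int = np.zeros(len(cand))
    for j in order:
        c = int(cand_of_ion[j])
        key = (c, int(peak[j]))
        if key in used:
            continue
        used.add(key)
        if is_b[j]:
            nb[c] += 1
        else:
            ny[c] += 1
        m_int[c] += float(intensity[peak[j]])
    stats[:, 0], stats[:, 1], stats[:, 3] = nb, ny, m_int
    matched = m_int > 0
    scores[matched] = (gammaln(nb[matched] + 1) + gammaln(ny[matched] + 1)
                       + np.log(m_int[matched]))
    return scores, stats


@dataclass
class SearchConfig:
    tolerance_mode: str = "charge_dependent"
    charges: tuple[int, ...] = (1, 2, 3, 4, 5)
    frag_tol_ppm: float = 20.0
    top_n: int = 5
    min_candidates_for_fit: int = 10


class PeptideIndex:
    """Mass-sorted peptide index over target + decoy entries.

    Caches each peptide's theoretical fragment ladder so repeated scoring
    across spectra reuses the arrays.
    """

    def __init__(self, entries: list[PeptideEntry]):
        self.entries = sorted(entries, key=lambda e: e.monoisotopic_mass)
        self.masses = np.array([e.monoisotopic_mass for e in self.entries])
        self._ladders: dict[tuple[int, bool], np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.entries)

    def candidates(self, lo_mass: float, hi_mass: float) -> list[int]:
        i = int(np.searchsorted(self.masses, lo_mass, side="left"))
        j = int(np.searchsorted(self.masses, hi_mass, side="right"))
        return list(range(i, j))

    def ladder(self, entry_idx: int, with_2plus: bool) -> np.ndarray:
        """Concatenated theoretical ion m/z array (b then y, 1+ then 2+)."""
        key = (entry_idx, with_2plus)
        got = self._ladders.get(key)
        if got is None:
            b1, y1 = fragment_ladders(self.entries[entry_idx].sequence)
            parts = [b1, y1]
            if with_2plus:
                parts += [(b1 + PROTON) / 2.0, (y1 + PROTON) / 2.0]
            got = np.concatenate(parts)
            self._ladders[key] = got
        return got


def build_index(target_proteins: list[tuple[str, str]], decoy_seed: int = 0,
                max_missed: int = 2, min_length: int = 7, max_length: int = 50,
                ) -> PeptideIndex:
    decoys = generate_decoys(target_proteins, decoy_seed)
    entries = digest_fasta(target_proteins, max_missed, min_length, max_length)
    entries += digest_fasta(decoys, max_missed, min_length, max_length,
                            is_decoy=True)
    # a shuffled peptide colliding with a target sequence stays a target
    target_seqs = {e.sequence for e in entries if not e.is_decoy}
    entries = [e for e in entries
               if not (e.is_decoy and e.sequence in target_seqs)]
    return PeptideIndex(entries)


def score_spectrum(ps, index: PeptideIndex, charge: int, window_width: float,
                   config: SearchConfig,
                   global_fit: tuple[float, float] | None = None,
                   score_sink: list | None = None) -> list[dict]:
    """Score one pseudo-spectrum at one assumed charge; returns top-N PSM rows.

    The expect value comes from a linear tail fit to the log survival function
    of this spectrum's candidate score distribution; with fewer than
    ``min_candidates_for_fit`` candidates a run-level (global) calibration is
    used instead.
    """
    tw = tolerance_window(window_width, charge, config.tolerance_mode)
    pmass = mass_from_mz(ps.pseudo_precursor_mz, charge)
    cand = index.candidates(pmass + tw.lower, pmass + tw.upper)
    if not cand:
        return []
    scores, stats = _batch_score(ps, index, cand, charge, config)
    if score_sink is not None:
        score_sink.extend(scores[np.isfinite(scores)].tolist())
    return _emit_rows(ps, index, charge, pmass, cand, scores, stats,
                      config, global_fit)


def _emit_rows(ps, index, charge, pmass, cand, scores, stats, config,
               global_fit):
    if len(cand) >= config.min_candidates_for_fit:
        fit = _survival_fit(scores) or global_fit
    else:
        fit = global_fit
    rows = []
    for k, ci in enumerate(cand):
        if not np.isfinite(scores[k]):
            continue
        e = index.entries[ci]
        nb, ny, n_theo, m_int = stats[k]
        rows.append({
            "spec_id": f"{ps.source_scan}.{ps.iteration}.{charge}",
            "scan": ps.source_scan,
            "iteration": ps.iteration,
            "window_index": ps.window_index,
            "rt": ps.rt,
            "pseudo_mz": ps.pseudo_precursor_mz,
            "charge": charge,
            "peptide": e.sequence,
            "proteins": ";".join(e.protein_ids),
            "is_decoy": e.is_decoy,
            "score": float(scores[k]),
            "expect": expect_from_fit(scores[k], fit, len(cand)),
            "matched_b": int(nb),
            "matched_y": int(ny),
            "matched_intensity": float(m_int),
            "n_theoretical": int(n_theo),
            "mass_delta": pmass - e.monoisotopic_mass,
            "peptide_length": len(e.sequence),
            "missed_cleavages": e.missed_cleavages,
            "n_candidates": len(cand),
        })
    rows.sort(key=lambda r: (r["expect"], -r["score"], r["peptide_length"],
                             r["peptide"]))
    for rank, r in enumerate(rows, start=1):
        r["rank"] = rank
    rows = rows[:config.top_n]
    # exact per-position matching (for consecutive b/y coverage) only on the
    # retained rows; the batch pass skips it for speed
    for r in rows:
        fm = match_fragments(ps.mz, ps.intensity, r["peptide"], charge,
                             config.frag_tol_ppm)
        r["longest_consecutive_by"] = fm.longest_consecutive_by
        r["matched_b"], r["matched_y"] = fm.matched_b, fm.matched_y
        r["matched_intensity"] = fm.matched_intensity
    return rows


def open_search(pseudo_spectra, index: PeptideIndex,
                window_widths: dict[int, float],
                config: SearchConfig | None = None) -> pd.DataFrame:
    """Search every pseudo-spectrum at every configured charge state.

    ``window_widths`` maps window index -> isolation window width (Da), needed
    for the charge-dependent tolerance.  Returns the merged PSM table (top-N
    per spectrum x charge), deterministic for fixed inputs.
    """
    config = config or SearchConfig()
    # pass 1: score everything.  The run-level expect calibration pools only
    # decoy-candidate scores: decoys are null by construction, whereas a pool
    # with target scores is contaminated by the true hits in its upper tail.
    pool: list[float] = []
    stash: list[tuple] = []
    for ps in pseudo_spectra:
        w = window_widths[ps.window_index]
        for z in config.charges:
            tw = tolerance_window(w, z, config.tolerance_mode)
            pmass = mass_from_mz(ps.pseudo_precursor_mz, z)
            cand = index.candidates(pmass + tw.lower, pmass + tw.upper)
            if not cand:
                continue
            scores, stats = _batch_score(ps, index, cand, z, config)
            decoy_scores = [0.0 if not np.isfinite(scores[k]) else scores[k]
                            for k, ci in enumerate(cand)
                            if index.entries[ci].is_decoy]
            pool.extend(decoy_scores)
            stash.append((ps, z, pmass, cand, scores, stats))
    global_fit = _survival_fit(np.array(pool)) if len(pool) >= 4 else None
    if global_fit is None:
        log.warning("global expect calibration unavailable; "
                    "using candidate counts as expect fallback")
    # pass 2: expect values and top-N rows
    rows: list[dict] = []
    for ps, z, pmass, cand, scores, stats in stash:
        rows.extend(_emit_rows(ps, index, z, pmass, cand, scores, stats,
                               config, global_fit))
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(["scan", "iteration", "charge", "rank"],
                            kind="stable").reset_index(drop=True)
    return df


def read_pepxml_psms(path) -> pd.DataFrame:
    """Adapter: import PSMs from an external engine's pepXML output.

    Maps the minimal column set (scan, charge, peptide, expect, hyperscore,
    massdiff, protein, decoy flag by DECOY_ prefix) onto the native PSM schema.
    """
    from lxml import etree
    ns = "{http://regis-web.systemsbiology.net/pepXML}"
    rows = []
    for _, sq in etree.iterparse(str(path), events=("end",),
                                 tag=(ns + "spectrum_query", "spectrum_query")):
        tag_ns = ns if sq.tag.startswith(ns) else ""
        for hit in sq.iter(tag_ns + "search_hit"):
            proteins = [hit.get("protein", "")]
            proteins += [alt.get("protein", "") for alt in
                         hit.iter(tag_ns + "alternative_protein")]
            proteins = [p for p in proteins if p]
            scores = {sc.get("name"): sc.get("value")
                      for sc in hit.iter(tag_ns + "search_score")}
            rows.append({
                "spec_id": sq.get("spectrum", ""),
                "scan": int(sq.get("start_scan", 0)),
                "iteration": 1,
                "charge": int(sq.get("assumed_charge", 0)),
                "peptide": hit.get("peptide", ""),
                "proteins": ";".join(proteins),
                "is_decoy": bool(proteins) and
                all(p.startswith("DECOY_") for p in proteins),
                "score": float(scores.get("hyperscore", 0.0)),
                "expect": float(scores.get("expect", 1.0)),
                "mass_delta": float(hit.get("massdiff", 0.0)),
                "rank": int(hit.get("hit_rank", 1)),
            })
        sq.clear()
    return pd.DataFrame(rows)
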