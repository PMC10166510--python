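"""Post-search verification and filtering of PSMs.

A pseudo-spectrum's precursor is only a window center, so every peptide hit is
checked against the MS1 data: a verified hit has a real precursor signal at its
theoretical m/z, inside its source isolation window, near the pseudo-spectrum's
retention time.  Verified hits anchor a ppm mass calibration whose m +/- 3s band
removes outliers; hits sharing one precursor keep only the best expect; open-
search artifacts from missed cleavages and near-identical (homologous) sequences
are collapsed.  Hits with no precursor evidence are not discarded — they are
forwarded to the putative-modification stage, which is the point of the whole
framework: fragment evidence alone can carry an identification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .search import ISOTOPE_SPACING, PROTON, RESIDUE_MASS, mz_from_mass
from .spectra_io import Ms1Scan, MSRun

log = logging.getLogger(__name__)


@dataclass
class RefineConfig:
    ms1_ppm_tol: float = 10.0
    rt_halfwidth_cycles: int | None = None  # defaults to demux S
    anchor_expect: float = 0.01
    min_anchors: int = 20
    calibration_sigmas: float = 3.0
    #: numeric floor on the band half-width: on near-perfect data the anchor
    #: spread can collapse below rounding noise, which would reject true hits
    min_band_halfwidth_ppm: float = 0.5
    #: verify all retained ranks (a merged pseudo-spectrum can legitimately
    #: report several co-fragmented peptides); modification search still only
    #: sees the best unexplained hit per spectrum x charge
    max_rank: int = 5


@dataclass
class PrecursorEvidence:
    observed_mz: float
    charge: int
    ppm_error: float
    isotope_peak_count: int
    consecutive_ms1_count: int
    apex_rt: float
    apex_intensity: float


@dataclass
class MassCalibration:
    mean_ppm: float
    sd_ppm: float
    n_anchors: int
    min_halfwidth_ppm: float = 0.5

    @property
    def band(self) -> tuple[float, float]:
        half = max(3.0 * self.sd_ppm, self.min_halfwidth_ppm)
        return (self.mean_ppm - half, self.mean_ppm + half)

    def contains(self, ppm: float, sigmas: float = 3.0) -> bool:
        half = max(sigmas * self.sd_ppm, self.min_halfwidth_ppm)
        return abs(ppm - self.mean_ppm) <= half


def _nearest_peak(scan: Ms1Scan, mz: float, ppm: float) -> int | None:
    if scan.mz.size == 0:
        return None
    i = int(np.searchsorted(scan.mz, mz))
    best, dist = None, np.inf
    for j in (i - 1, i):
        if 0 <= j < scan.mz.size:
            d = abs(scan.mz[j] - mz)
            if d < dist:
                best, dist = j, d
    if best is not None and dist <= mz * ppm * 1e-6:
        return best
    return None


def _ms1_index_near(ms1_rts: np.ndarray, rt: float) -> int:
    return int(np.clip(np.searchsorted(ms1_rts, rt), 0, ms1_rts.size - 1))


def verify_precursor(theoretical_mass: float, charge: int, rt: float,
                     window, run: MSRun, config: RefineConfig,
                     s_cycles: int = 5) -> PrecursorEvidence | None:
    """Look for an MS1 precursor signal matching a peptide hit.

    The theoretical m/z must fall inside the source isolation window; the MS1
    scans within +/- ``s_cycles`` cycles of the pseudo-spectrum rt are searched
    for a matching peak; when found, the isotope envelope (spacing 1.00335/z)
    is extended, the run of consecutive MS1 scans containing the monoisotope is
    counted, and the ppm error is taken at the apex scan.
    """
    halfwidth = config.rt_halfwidth_cycles or s_cycles
    mz = mz_from_mass(theoretical_mass, charge)
    if not window.contains(mz):
        return None
    if not run.ms1_scans:
        return None
    rts = run.ms1_rts()
    center = _ms1_index_near(rts, rt)
    lo = max(0, center - halfwidth)
    hi = min(len(run.ms1_scans) - 1, center + halfwidth)
    hits: list[tuple[int, int]] = []  # (ms1 index, peak index)
    for i in range(lo, hi + 1):
        j = _nearest_peak(run.ms1_scans[i], mz, config.ms1_ppm_tol)
        if j is not None:
            hits.append((i, j))
    if not hits:
        return None
    apex_i, apex_j = max(hits, key=lambda t: run.ms1_scans[t[0]].intensity[t[1]])
    apex = run.ms1_scans[apex_i]
    observed = float(apex.mz[apex_j])
    # isotope envelope at the apex scan
    iso_count = 1
    while True:
        nxt = observed + iso_count * ISOTOPE_SPACING / charge
        j = _nearest_peak(apex, nxt, config.ms1_ppm_tol)
        if j is None or apex.intensity[j] <= 0:
            break
        iso_count += 1
    # consecutive MS1 scans containing the monoisotope, through the apex
    hit_set = {i for i, _ in hits}
    run_lo = apex_i
    while run_lo - 1 in hit_set:
        run_lo -= 1
    run_hi = apex_i
    while run_hi + 1 in hit_set:
        run_hi += 1
    return PrecursorEvidence(
        observed_mz=observed,
        charge=charge,
        ppm_error=(observed - mz) / mz * 1e6,
        isotope_peak_count=iso_count,
        consecutive_ms1_count=run_hi - run_lo + 1,
        apex_rt=float(apex.rt),
        apex_intensity=float(apex.intensity[apex_j]),
    )


def resolve_shared_precursor(df: pd.DataFrame, ppm_tol: float = 10.0,
                             rt_tol: float = 5.0) -> pd.DataFrame:
    """When several PSMs match the same MS1 precursor signal (same window,
    same charge, observed m/z within tolerance, apex rt within ``rt_tol``
    seconds), keep only the most confident (lowest expect; ties to higher
    score, then lexicographic peptide).  Two features at the same m/z but
    different elution apexes are different precursors and both survive."""
    if df.empty:
        return df
    keep = np.ones(len(df), dtype=bool)
    work = df.reset_index(drop=True)
    has_rt = "apex_rt" in work.columns
    for (_, _), grp in work.groupby(["window_index", "charge"], sort=False):
        grp = grp.sort_values("observed_mz", kind="stable")
        cluster: list[int] = []
        prev_mz = None
        clusters: list[list[int]] = []
        for idx, row in grp.iterrows():
            mz = row["observed_mz"]
            same_mz = prev_mz is not None and \
                mz - prev_mz <= prev_mz * ppm_tol * 1e-6
            same_rt = True
            if same_mz and has_rt and cluster:
                rts = work.loc[cluster, "apex_rt"]
                same_rt = bool(np.nanmin(np.abs(rts - row["apex_rt"]))
                               <= rt_tol)
            if same_mz and same_rt:
                cluster.append(idx)
            else:
                if cluster:
                    clusters.append(cluster)
                cluster = [idx]
            prev_mz = mz
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            if len(cl) < 2:
                continue
            sub = work.loc[cl].sort_values(
                ["expect", "score", "peptide"],
                ascending=[True, False, True], kind="stable")
            for idx in sub.index[1:]:
                keep[idx] = False
    return work[keep].reset_index(drop=True)


def calibrate_and_filter(df: pd.DataFrame, config: RefineConfig,
                         ) -> tuple[MassCalibration | None, pd.DataFrame]:
    """Estimate precursor mass accuracy from confident hits and remove
    outliers.

    Anchors are verified hits with expect < 0.01; the ppm-error mean m and
    standard deviation s define the m +/- 3s acceptance band.  With fewer
    than ``min_anchors`` anchors the filter is skipped (calibration still
    reported).
    """
    if df.empty:
        return None, df
    anchors = df[(df["expect"] < config.anchor_expect)
                 & np.isfinite(df["ppm_error"])]
    if anchors.empty:
        return None, df
    cal = MassCalibration(float(anchors["ppm_error"].mean()),
                          float(anchors["ppm_error"].std(ddof=0)),
                          len(anchors), config.min_band_halfwidth_ppm)
    if cal.n_anchors < config.min_anchors:
        log.warning("only %d calibration anchors (< %d); mass filter skipped",
                    cal.n_anchors, config.min_anchors)
        return cal, df
    lo, hi = cal.band
    ok = (df["ppm_error"] >= lo) & (df["ppm_error"] <= hi)
    return cal, df[ok].reset_index(drop=True)


def _is_extension(short: str, long_: str) -> str | None:
    """Return the extension sequence if ``short`` occurs inside ``long_``
    aligned at tryptic boundaries (so ``long_`` is a missed-cleavage extension
    of ``short``); None otherwise."""
    if len(short) >= len(long_):
        return None
    start = 0
    while True:
        start = long_.find(short, start)
        if start < 0:
            return None
        end = start + len(short)
        left_ok = start == 0 or long_[start - 1] in "KR"
        right_ok = end == len(long_) or short[-1] in "KR"
        if left_ok and right_ok:
            return long_[:start] + long_[end:]
        start += 1


def collapse_missed_cleavage(df: pd.DataFrame, ppm_tol: float = 10.0,
                             ) -> pd.DataFrame:
    """Collapse open-search artifacts caused by missed cleavages.

    A peptide contained in a missed-cleavage extension shares its fragment
    ladder with it, so both routinely match the same pseudo-spectrum.  At the
    same assumed charge the pair is an artifact when the mass-delta difference
    equals the extension mass; across different assumed charges the two
    pseudo-masses are incommensurable and the sequence relation alone marks
    the artifact.  Only the better expect survives.
    """
    if df.empty:
        return df
    drop: set[int] = set()
    work = df.reset_index(drop=True)
    for _, grp in work.groupby(["scan", "iteration"], sort=False):
        idxs = list(grp.index)
        for i in range(len(idxs)):
            for j in range(len(idxs)):
                if i == j:
                    continue
                a, b = work.loc[idxs[i]], work.loc[idxs[j]]
                ext = _is_extension(a["peptide"], b["peptide"])
                if ext is None:
                    continue
                cross_charge = "charge" in work.columns \
                    and a["charge"] != b["charge"]
                if cross_charge:
                    same_species = True
                else:
                    ext_mass = sum(RESIDUE_MASS[r] for r in ext)
                    diff = abs(abs(a["mass_delta"] - b["mass_delta"])
                               - ext_mass)
                    tol = max(ext_mass * ppm_tol * 1e-6, 0.01)
                    same_species = diff <= tol
                if not same_species:
                    continue
                if cross_charge and "n_theoretical" in work.columns:
                    # across charges the expect scales differ; the reading
                    # explaining more of its own ion ladder is the real one
                    frac_a = (a["matched_b"] + a["matched_y"]) \
                        / max(a["n_theoretical"], 1)
                    frac_b = (b["matched_b"] + b["matched_y"]) \
                        / max(b["n_theoretical"], 1)
                    a_worse = (frac_a, a["score"]) < (frac_b, b["score"])
                else:
                    a_worse = a["expect"] > b["expect"]
                drop.add(idxs[i] if a_worse else idxs[j])
    return work[~work.index.isin(drop)].reset_index(drop=True)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def collapse_homologs(df: pd.DataFrame, max_distance: int = 2) -> pd.DataFrame:
    """Collapse homologous hits on one pseudo-spectrum.

    Equal-length peptides differing in at most two residues are linked; each
    connected component (the transitive closure, so chains A~B~C collapse even
    when A and C differ at more positions) keeps only its best-expect member.
    """
    if df.empty:
        return df
    work = df.reset_index(drop=True)
    drop: set[int] = set()
    for _, grp in work.groupby(["scan", "iteration"], sort=False):
        idxs = list(grp.index)
        parent = {i: i for i in idxs}

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(idxs)):
            for j in range(i + 1, len(idxs)):
                a, b = work.loc[idxs[i], "peptide"], work.loc[idxs[j], "peptide"]
                if len(a) == len(b) and _hamming(a, b) <= max_distance:
                    parent[find(idxs[i])] = find(idxs[j])
        comps: dict[int, list[int]] = {}
        for i in idxs:
            comps.setdefault(find(i), []).append(i)
        for members in comps.values():
            if len(members) < 2:
                continue
            best = min(members, key=lambda i: (work.loc[i, "expect"],
                                               -work.loc[i, "score"]
                                               if "score" in work else 0.0))
            drop.update(m for m in members if m != best)
    return work[~work.index.isin(drop)].reset_index(drop=True)


def collapse_artifact_features(df: pd.DataFrame, rt_tol: float,
                               ppm_tol: float = 10.0) -> pd.DataFrame:
    """Collapse sequence-related interpretations of one chromatographic
    feature across the whole PSM pool.

    Two PSMs in the same isolation window, eluting within ``rt_tol`` seconds,
    whose peptides are missed-cleavage extensions of one another (at any
    assumed charge) or equal-length homologs with at most two substitutions,
    are interpretations of the same species; the better-scoring sequence
    keeps all its rows, the other loses the overlapping ones.  This catches
    artifacts that the per-spectrum collapses miss when the competing
    interpretations surface on different scans of the same elution peak.
    """
    if df.empty:
        return df
    work = df.reset_index(drop=True)
    drop: set[int] = set()

    def strength(rows: list[int]) -> tuple:
        sub = work.loc[rows]
        evidence = bool(sub.get("has_precursor_evidence",
                                pd.Series(False)).any())
        if "matched_b" in sub and "n_theoretical" in sub:
            frac = float(((sub["matched_b"] + sub["matched_y"])
                          / sub["n_theoretical"].clip(lower=1)).max())
        else:
            frac = 0.0
        score = float(sub["score"].max()) if "score" in sub else 0.0
        return (evidence, frac, score)

    for _, grp in work.groupby("window_index", sort=False):
        by_pep: dict[str, list[int]] = {}
        for i in grp.index:
            by_pep.setdefault(work.loc[i, "peptide"], []).append(i)
        peps = list(by_pep)
        for i in range(len(peps)):
            for j in range(i + 1, len(peps)):
                a, b = peps[i], peps[j]
                related = (_is_extension(a, b) is not None
                           or _is_extension(b, a) is not None
                           or (len(a) == len(b) and _hamming(a, b) <= 2))
                if not related:
                    continue
                rows_a = [r for r in by_pep[a] if r not in drop]
                rows_b = [r for r in by_pep[b] if r not in drop]
                if not rows_a or not rows_b:
                    continue
                rts_a = work.loc[rows_a, "rt"].to_numpy()
                rts_b = work.loc[rows_b, "rt"].to_numpy()
                if np.min(np.abs(rts_a[:, None] - rts_b[None, :])) > rt_tol:
                    continue
                # the interpretation with real precursor evidence, then the
                # one explaining the larger share of its own ion ladder, wins
                a_wins = strength(rows_a) >= strength(rows_b)
                drop.update(rows_b if a_wins else rows_a)
    return work[~work.index.isin(drop)].reset_index(drop=True)


def refine_psms(psms: pd.DataFrame, run: MSRun, peptide_masses: dict[str, float],
                config: RefineConfig | None = None, s_cycles: int = 5,
                ) -> tuple[pd.DataFrame, pd.DataFrame, MassCalibration | None]:
    """Run the full refinement pipeline on rank-1 PSMs.

    Returns ``(verified, unexplained, calibration)``: verified PSMs carry
    precursor-evidence columns; unexplained PSMs (no MS1 signal at the
    theoretical mass) are forwarded to the putative-modification stage.  The
    two outputs partition the post-collapse PSM set.
    """
    config = config or RefineConfig()
    if psms.empty:
        empty = psms.copy()
        return empty, empty.copy(), None
    work = psms[psms["rank"] <= config.max_rank].copy() \
        if "rank" in psms else psms.copy()
    ev_cols = {"observed_mz": np.nan, "ppm_error": np.nan,
               "isotope_peak_count": 0, "consecutive_ms1_count": 0,
               "apex_rt": np.nan, "apex_intensity": np.nan,
               "has_precursor_evidence": False}
    for c, v in ev_cols.items():
        work[c] = v
    for idx, row in work.iterrows():
        ev = verify_precursor(
            peptide_masses[row["peptide"]] + row.get("mod_delta", 0.0),
            int(row["charge"]), float(row["rt"]),
            run.window(int(row["window_index"])), run, config, s_cycles)
        if ev is not None:
            work.loc[idx, ["observed_mz", "ppm_error", "isotope_peak_count",
                           "consecutive_ms1_count", "apex_rt",
                           "apex_intensity", "has_precursor_evidence"]] = [
                ev.observed_mz, ev.ppm_error, ev.isotope_peak_count,
                ev.consecutive_ms1_count, ev.apex_rt, ev.apex_intensity, True]
    verified = work[work["has_precursor_evidence"]].reset_index(drop=True)
    unexplained = work[~work["has_precursor_evidence"]]
    if "rank" in unexplained.columns:
        # only the top hit per spectrum x charge proceeds to the
        # putative-modification search
        unexplained = unexplained[unexplained["rank"] == 1]
    unexplained = unexplained.reset_index(drop=True)

    rts = run.ms1_rts()
    rt_tol = 1.5 * float(np.median(np.diff(rts))) if rts.size > 1 else 5.0
    verified = resolve_shared_precursor(verified, config.ms1_ppm_tol, rt_tol)
    cal, verified = calibrate_and_filter(verified, config)
    verified = collapse_missed_cleavage(verified, config.ms1_ppm_tol)
    verified = collapse_homologs(verified)
    unexplained = collapse_missed_cleavage(unexplained, config.ms1_ppm_tol)
    unexplained = collapse_homologs(unexplained)
    return verified, unexplained, cal
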