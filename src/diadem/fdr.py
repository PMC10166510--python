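"""Target-decoy FDR estimation with auxiliary features.

Native q-values come from target-decoy competition: PSMs are ranked by a
discriminant (by default -log10 expect), the FDR at each threshold is
(decoys + 1) / targets above it, and q-values are the running minimum from the
worst score upward.  Modified and unmodified peptides are estimated in separate
strata because modified-peptide scores run systematically lower and would
otherwise be swamped.  The auxiliary feature vector is also exportable as a
Percolator PIN file for external rescoring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Auxiliary features exported to PIN and usable as rescoring inputs.
FEATURE_NAMES = [
    "neg_log_expect", "hyperscore", "delta_score_next_best",
    "matched_fragment_count", "matched_fragment_fraction",
    "longest_consecutive_by", "precursor_ppm_error", "isotope_peak_count",
    "precursor_evidence_flag", "peptide_length", "missed_cleavages",
    "charge_2", "charge_3", "charge_other",
]


def compute_features(df: pd.DataFrame) -> pd.DataFrame:
    """Add the auxiliary feature columns to a PSM table.

    Deterministic row-wise mapping; PSMs without precursor evidence get
    ppm_error imputed to 0 with the evidence flag at 0.
    """
    out = df.copy()
    out["neg_log_expect"] = -np.log10(np.clip(out["expect"], 1e-30, None))
    out["hyperscore"] = out["score"]
    if "delta_score_next_best" not in out:
        out["delta_score_next_best"] = 0.0
    out["matched_fragment_count"] = out["matched_b"] + out["matched_y"]
    out["matched_fragment_fraction"] = (
        out["matched_fragment_count"] / out["n_theoretical"].clip(lower=1))
    flag = out.get("has_precursor_evidence")
    if flag is None:
        flag = pd.Series(False, index=out.index)
    out["precursor_evidence_flag"] = flag.fillna(False).astype(int)
    ppm = out.get("ppm_error")
    if ppm is None:
        ppm = pd.Series(np.nan, index=out.index)
    out["precursor_ppm_error"] = ppm.fillna(0.0)
    if "isotope_peak_count" not in out:
        out["isotope_peak_count"] = 0
    out["isotope_peak_count"] = out["isotope_peak_count"].fillna(0).astype(int)
    out["charge_2"] = (out["charge"] == 2).astype(int)
    out["charge_3"] = (out["charge"] == 3).astype(int)
    out["charge_other"] = (~out["charge"].isin([2, 3])).astype(int)
    return out


def estimate_qvalues(df: pd.DataFrame, key: str = "neg_log_expect",
                     ) -> pd.DataFrame:
    """Assign target-decoy q-values by competition on the ``key`` column.

    PSMs are sorted by descending discriminant; FDR(s) = (#decoys >= s + 1) /
    max(1, #targets >= s); q is the cumulative minimum taken from the worst
    score upward, so q-values are monotone along the ranking.  With zero
    decoys every target gets q = 1 / #targets, with a warning.
    """
    if df.empty:
        out = df.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    out = df.copy()
    scores = out[key].to_numpy()
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    is_decoy = out["is_decoy"].to_numpy()[order].astype(bool)
    n_decoy_cum = np.cumsum(is_decoy)
    n_target_cum = np.cumsum(~is_decoy)
    if n_decoy_cum[-1] == 0:
        log.warning("no decoys present; q-values set to 1/#targets")
        q_sorted = np.full(len(out), 1.0 / max(int(n_target_cum[-1]), 1))
    else:
        # tied scores share one threshold: use counts at the tie block's end
        last_of_tie = np.flatnonzero(
            np.r_[sorted_scores[1:] != sorted_scores[:-1], True])
        block_end = last_of_tie[
            np.searchsorted(last_of_tie, np.arange(len(out)))]
        fdr = (n_decoy_cum[block_end] + 1) / np.maximum(
            n_target_cum[block_end], 1)
        q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(len(out))
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    out["q_value"] = q
    return out


def peptide_rollup(df: pd.DataFrame, key: str = "neg_log_expect",
                   ) -> pd.DataFrame:
    """Best PSM per (peptide sequence, modification), then peptide-level
    q-values by the same competition.

    If a ``stratum`` column is present (from :func:`split_fdr`), the
    peptide-level competition runs within each stratum as well.
    """
    if df.empty:
        out = df.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    mod = df.get("mod_name")
    work = df.copy()
    work["_pep_key"] = work["peptide"] + "|" + (
        mod.fillna("").astype(str) if mod is not None else "")
    best = (work.sort_values(key, ascending=False, kind="stable")
            .drop_duplicates("_pep_key").drop(columns="_pep_key"))
    best = best.reset_index(drop=True)
    if "stratum" in best.columns:
        parts = [estimate_qvalues(grp.reset_index(drop=True), key)
                 for _, grp in best.groupby("stratum", sort=False)]
        return pd.concat(parts, ignore_index=True)
    return estimate_qvalues(best, key)


def protein_rollup(peptides: pd.DataFrame, key: str = "neg_log_expect",
                   ) -> pd.DataFrame:
    """Best peptide per protein accession, then protein-level q-values."""
    if peptides.empty:
        out = peptides.copy()
        out["q_value"] = pd.Series(dtype=float)
        return out
    rows = []
    for _, r in peptides.iterrows():
        for acc in str(r["proteins"]).split(";"):
            d = r.to_dict()
            d["protein"] = acc
            rows.append(d)
    flat = pd.DataFrame(rows)
    best = (flat.sort_values(key, ascending=False, kind="stable")
            .drop_duplicates("protein"))
    return estimate_qvalues(best.reset_index(drop=True), key)


def split_fdr(df: pd.DataFrame, key: str = "neg_log_expect",
              min_stratum: int = 2) -> pd.DataFrame:
    """Estimate q-values separately for modified and unmodified PSMs.

    Modified-peptide scores are systematically lower than unmodified ones, so
    pooling them would let unmodified decoys set the bar for modified targets
    (and vice versa).  A stratum smaller than ``min_stratum`` is skipped with
    a warning (its q-values are NaN).  Adds a ``stratum`` column.
    """
    if df.empty:
        out = df.copy()
        out["q_value"] = pd.Series(dtype=float)
        out["stratum"] = pd.Series(dtype=str)
        return out
    mod = df.get("mod_name")
    is_mod = (mod.notna() & (mod != "")) if mod is not None \
        else pd.Series(False, index=df.index)
    parts = []
    for name, sel in (("unmodified", ~is_mod), ("modified", is_mod)):
        sub = df[sel]
        if sub.empty:
            continue
        if len(sub) < min_stratum:
            log.warning("stratum %r has %d PSM(s); skipped", name, len(sub))
            sub = sub.copy()
            sub["q_value"] = np.nan
        else:
            sub = estimate_qvalues(sub.reset_index(drop=True), key)
        sub["stratum"] = name
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)
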