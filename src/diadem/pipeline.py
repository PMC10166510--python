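"""End-to-end orchestration: demux -> search -> refine -> ptm -> fdr -> export.

Each stage is a pure function of its inputs plus the configuration; the driver
writes per-stage TSV artifacts, final peptide/protein tables at q <= 0.01, an
SSL spectral-library export and a PIN export, and a manifest recording the
configuration hash, package version and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, fdr as _fdr, ptm as _ptm, refine as _refine
from .demultiplex import DemuxConfig, demultiplex_run
from .refine import RefineConfig
from .ptm import PtmConfig, load_modification_table
from .search import SearchConfig, build_index, open_search
from .spectra_io import (MSRun, format_modified_sequence, read_fasta,
                         read_mzml_run, write_mgf, write_pin, write_ssl)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str | None = None
    decoy_seed: int = 1
    q_threshold: float = 0.01
    #: discriminant for target-decoy competition.  The hyperscore is robust
    #: across spectra; the expect value depends on a per-spectrum survival
    #: fit that can degenerate on sparse candidate sets, so it serves for
    #: within-spectrum ranking and anchor selection instead
    discriminant: str = "hyperscore"
    demux: DemuxConfig = field(default_factory=DemuxConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    ptm: PtmConfig = field(default_factory=PtmConfig)
    mod_table_path: str | None = None

    def digest(self) -> str:
        blob = json.dumps({
            "fasta": self.fasta, "decoy_seed": self.decoy_seed,
            "q": self.q_threshold, "demux": asdict(self.demux),
            "search": asdict(self.search), "refine": asdict(self.refine),
            "ptm": asdict(self.ptm)}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _mark_best_deltas(psms: pd.DataFrame) -> pd.DataFrame:
    """delta_score_next_best = rank-1 score minus rank-2 score per spectrum x charge."""
    if psms.empty:
        return psms
    out = psms.copy()
    out["delta_score_next_best"] = 0.0
    for _, grp in out.groupby("spec_id", sort=False):
        if len(grp) >= 2:
            s = grp.sort_values("rank")["score"].to_numpy()
            out.loc[grp.index[grp["rank"] == 1], "delta_score_next_best"] = \
                float(s[0] - s[1])
    return out


def run_pipeline(run: MSRun, proteins: list[tuple[str, str]],
                 out_dir, config: PipelineConfig | None = None) -> dict:
    """Execute the full identification pipeline on a loaded run.

    Returns a dict of the principal DataFrames and writes all artifacts under
    ``out_dir``.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pseudo, demux_stats = demultiplex_run(run, config.demux)
    write_mgf(pseudo, out / f"{run.name}.pseudo.mgf", run_name=run.name)

    index = build_index(proteins, decoy_seed=config.decoy_seed)
    widths = {w.index: w.width for w in run.windows}
    psms = open_search(pseudo, index, widths, config.search)
    psms = _mark_best_deltas(psms)
    psms.to_csv(out / "psms.tsv", sep="\t", index=False)

    masses = {e.sequence: e.monoisotopic_mass for e in index.entries}
    s_cycles = config.demux.cycle_window_s or 5
    verified, unexplained, calibration = _refine.refine_psms(
        psms, run, masses, config.refine, s_cycles)
    verified.to_csv(out / "psms_verified.tsv", sep="\t", index=False)
    unexplained.to_csv(out / "psms_unexplained.tsv", sep="\t", index=False)

    pseudo_by_key = {(p.source_scan, p.iteration): p for p in pseudo}
    mod_table = load_modification_table(config.mod_table_path)
    annotated = _ptm.annotate_unexplained(
        unexplained, run, pseudo_by_key, mod_table, calibration, config.ptm)
    if not annotated.empty:
        annotated.to_csv(out / "psms_modified.tsv", sep="\t", index=False)

    # precursor evidence is a feature, not a filter: unexplained PSMs that no
    # modification could account for still compete in the FDR with their
    # evidence flag at 0 — fragment evidence alone can carry a suppressed-
    # precursor identification
    if not annotated.empty:
        ann_keys = set(zip(annotated["scan"], annotated["iteration"],
                           annotated["charge"], annotated["peptide"]))
        rest = unexplained[[
            (k not in ann_keys) for k in zip(
                unexplained["scan"], unexplained["iteration"],
                unexplained["charge"], unexplained["peptide"])]]
        pool = pd.concat([verified, annotated, rest], ignore_index=True)
    else:
        pool = pd.concat([verified, unexplained], ignore_index=True)
    # collapse artifacts across streams and scans: a missed-cleavage
    # extension or near-homolog of a peptide that elutes at the same place in
    # the same window is an alternative reading of the same species
    rts = run.ms1_rts()
    rt_tol = float(np.median(np.diff(rts))) * (
        (config.demux.cycle_window_s or 5)) if rts.size > 1 else 15.0
    pool = _refine.collapse_artifact_features(pool, rt_tol,
                                              config.refine.ms1_ppm_tol)
    pool = _fdr.compute_features(pool)
    scored = _fdr.split_fdr(pool, key=config.discriminant)
    scored.to_csv(out / "psms_scored.tsv", sep="\t", index=False)

    peptides = _fdr.peptide_rollup(
        scored[scored["q_value"].notna()], key=config.discriminant)
    peptides_pass = peptides[(peptides["q_value"] <= config.q_threshold)
                             & ~peptides["is_decoy"]]
    peptides_pass.to_csv(out / "peptides.tsv", sep="\t", index=False)
    prots = _fdr.protein_rollup(peptides_pass, key=config.discriminant)
    prots[~prots["is_decoy"]].to_csv(out / "proteins.tsv", sep="\t", index=False)

    ssl_rows = []
    for _, r in peptides_pass.iterrows():
        ssl_rows.append({
            "file": f"{run.name}.pseudo.mgf", "scan": int(r["scan"]),
            "charge": int(r["charge"]),
            "sequence": format_modified_sequence(
                r["peptide"],
                None if pd.isna(r.get("mod_site", np.nan)) else int(r["mod_site"]),
                None if pd.isna(r.get("mod_delta", np.nan)) else float(r["mod_delta"]))})
    write_ssl(ssl_rows, out / "library.ssl")

    pin = _fdr.compute_features(pool)
    pin["peptide"] = "-." + pin["peptide"] + ".-"
    write_pin(pin.to_dict("records"), _fdr.FEATURE_NAMES, out / "psms.pin")

    manifest = {
        "version": __version__, "config_hash": config.digest(),
        "decoy_seed": config.decoy_seed, "run": run.name,
        "n_ms2_scans": run.n_ms2, "n_pseudo_spectra": demux_stats.n_pseudo,
        "n_fallback": demux_stats.n_fallback,
        "n_psms": int(len(psms)), "n_verified": int(len(verified)),
        "n_unexplained": int(len(unexplained)),
        "n_modified_annotated": int(len(annotated)),
        "n_peptides_passing": int(len(peptides_pass)),
        "calibration": None if calibration is None else asdict(calibration),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"pseudo": pseudo, "psms": psms, "verified": verified,
            "unexplained": unexplained, "annotated": annotated,
            "scored": scored, "peptides": peptides_pass, "manifest": manifest}


def run_pipeline_from_files(mzml_path, fasta_path, out_dir,
                            config: PipelineConfig | None = None) -> dict:
    mzml_path, fasta_path = Path(mzml_path), Path(fasta_path)
    for p in (mzml_path, fasta_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    run = read_mzml_run(mzml_path)
    proteins = read_fasta(fasta_path)
    return run_pipeline(run, proteins, out_dir, config)
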