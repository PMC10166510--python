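"""Reading and writing of on-disk spectral formats.

Handles mzML (read/write), MGF (read/write in the pseudo-spectrum dialect used by
the demultiplexer), MS1 text (read/write), FASTA (read/write), BiblioSpec SSL
(write) and Percolator PIN (write), and organises scans into the per-isolation-
window, cycle-ordered structure the demultiplexer consumes.

All retention times are normalised to seconds at read time; all peak lists are
kept as parallel numpy arrays sorted ascending in m/z.
"""

from __future__ import annotations

import base64
import logging
import re
import struct
import zlib
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from lxml import etree
from pyteomics import fasta as _fasta
from pyteomics import mgf as _mgf
from pyteomics import ms1 as _ms1

log = logging.getLogger(__name__)


class Peak(NamedTuple):
    """A centroided peak: m/z in Thomson, intensity in arbitrary counts."""

    mz: float
    intensity: float


def _as_sorted_arrays(mz, intensity):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have equal length")
    if np.any(np.isnan(mz)) or np.any(np.isnan(intensity)):
        raise ValueError("NaN in peak list")
    if np.any(intensity < 0) or np.any(mz <= 0):
        raise ValueError("negative intensity or non-positive m/z")
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


@dataclass
class Ms1Scan:
    """A survey scan over the precursor m/z range."""

    scan_id: int
    rt: float  # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    @property
    def base_peak_mz(self) -> float:
        if not self.intensity.size:
            return float("nan")
        return float(self.mz[int(np.argmax(self.intensity))])


@dataclass
class Ms2Scan:
    """A fragment scan acquired for one isolation window.

    ``cycle`` is the rank of this scan among the scans of the same window,
    ordered by retention time, starting at 0.
    """

    scan_id: int
    rt: float  # seconds
    window_index: int
    cycle: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass(frozen=True)
class IsolationWindow:
    """A precursor isolation window with center m/z (Th) and width (Da)."""

    center_mz: float
    width: float
    index: int

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("isolation window width must be positive")

    @property
    def lower(self) -> float:
        return self.center_mz - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.center_mz + self.width / 2.0

    def contains(self, mz: float) -> bool:
        return self.lower <= mz <= self.upper


@dataclass
class MSRun:
    """A DIA run: rt-ordered MS1 scans plus per-window cycle-ordered MS2 scans."""

    ms1_scans: list[Ms1Scan]
    windows: list[IsolationWindow]
    ms2_by_window: dict[int, list[Ms2Scan]]
    name: str = "run"

    def window(self, index: int) -> IsolationWindow:
        return self.windows[index]

    @property
    def n_ms2(self) -> int:
        return sum(len(v) for v in self.ms2_by_window.values())

    def ms1_rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.ms1_scans])


# ---------------------------------------------------------------------------
# mzML
# ---------------------------------------------------------------------------

_SCAN_RE = re.compile(r"scan=(\d+)")

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary_array(ba_elem) -> np.ndarray:
    """Decode one <binaryDataArray>: 32/64-bit float, zlib or no compression."""
    dtype = "<f8"
    compressed = False
    for cv in ba_elem.iter(_MZML_NS + "cvParam"):
        name = cv.get("name", "")
        if name == "32-bit float":
            dtype = "<f4"
        elif name == "64-bit float":
            dtype = "<f8"
        elif name == "zlib compression":
            compressed = True
    node = ba_elem.find(_MZML_NS + "binary")
    if node is None or not (node.text or "").strip():
        return np.zeros(0)
    raw = base64.b64decode(node.text)
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _spectrum_arrays(spec_elem) -> tuple[np.ndarray, np.ndarray]:
    mz = inten = None
    for ba in spec_elem.iter(_MZML_NS + "binaryDataArray"):
        names = {cv.get("name") for cv in ba.iter(_MZML_NS + "cvParam")}
        if "m/z array" in names:
            mz = _decode_binary_array(ba)
        elif "intensity array" in names:
            inten = _decode_binary_array(ba)
    if mz is None or inten is None:
        raise ValueError("spectrum lacks m/z or intensity array")
    return mz, inten


def read_mzml_run(path, windows: Sequence[tuple[float, float]] | None = None,
                  name: str | None = None) -> MSRun:
    """Read a centroided DIA mzML file into an :class:`MSRun`.

    Parameters
    ----------
    path : str
        mzML file with centroided MS1 and MS2 spectra.  MS2 spectra must carry
        isolation-window target m/z and offsets unless ``windows`` is given.
    windows : sequence of (center_mz, width), optional
        Explicit isolation-window scheme.  When supplied it overrides any
        metadata in the file; MS2 scans are assigned to the window containing
        their isolation target.

    Raises a :class:`ValueError` naming the first offending scan if isolation
    metadata is missing and no ``windows`` override is supplied, or if a
    profile-mode spectrum is encountered.
    """
    ms1: list[Ms1Scan] = []
    ms2_raw: list[tuple[int, float, float, float, float, np.ndarray, np.ndarray]] = []
    for i, (_, spec) in enumerate(etree.iterparse(
            str(path), events=("end",), tag=_MZML_NS + "spectrum")):
        m = _SCAN_RE.search(spec.get("id", ""))
        sid = int(m.group(1)) if m else i + 1
        level = None
        profile = False
        rt = None
        target = lo_off = hi_off = None
        for cv in spec.iter(_MZML_NS + "cvParam"):
            nm = cv.get("name", "")
            if nm == "ms level":
                level = int(cv.get("value"))
            elif nm == "profile spectrum":
                profile = True
            elif nm == "scan start time":
                rt = float(cv.get("value"))
                unit = cv.get("unitName", "minute")
                if unit in ("minute", "min"):
                    rt *= 60.0
                elif unit in ("millisecond", "ms"):
                    rt /= 1000.0
            elif nm == "isolation window target m/z":
                target = float(cv.get("value"))
            elif nm == "isolation window lower offset":
                lo_off = float(cv.get("value"))
            elif nm == "isolation window upper offset":
                hi_off = float(cv.get("value"))
        if profile:
            raise ValueError(
                f"scan {sid} is profile mode; centroid the data before reading")
        if level is None:
            raise ValueError(f"scan {sid} lacks an 'ms level' cvParam")
        if rt is None:
            raise ValueError(f"scan {sid} lacks 'scan start time'")
        mz, inten = _spectrum_arrays(spec)
        if level == 1:
            ms1.append(Ms1Scan(sid, rt, mz, inten))
        else:
            if target is None:
                if windows is None:
                    raise ValueError(
                        f"scan {sid} lacks isolation-window metadata and no "
                        "window list was supplied")
                lo_off = hi_off = 0.0
                # fall back to selected ion m/z for window assignment
                for cv in spec.iter(_MZML_NS + "cvParam"):
                    if cv.get("name") == "selected ion m/z":
                        target = float(cv.get("value"))
                if target is None:
                    raise ValueError(f"scan {sid} has no precursor m/z at all")
            ms2_raw.append((sid, rt, target, lo_off or 0.0, hi_off or 0.0,
                            mz, inten))
        spec.clear()

    ms1.sort(key=lambda s: s.rt)

    if windows is not None:
        win_objs = [IsolationWindow(c, w, i) for i, (c, w) in enumerate(windows)]

        def assign(target, lo, hi):
            for w in win_objs:
                if w.contains(target):
                    return w.index
            raise ValueError(f"isolation target {target} falls in no configured window")
    else:
        keys = sorted({(round(t, 4), round(lo, 4), round(hi, 4))
                       for _, _, t, lo, hi, _, _ in ms2_raw})
        win_objs = [IsolationWindow(t, lo + hi, i) for i, (t, lo, hi) in enumerate(keys)]
        key_to_index = {k: i for i, k in enumerate(keys)}

        def assign(target, lo, hi):
            return key_to_index[(round(target, 4), round(lo, 4), round(hi, 4))]

    by_window: dict[int, list[Ms2Scan]] = {w.index: [] for w in win_objs}
    for sid, rt, target, lo, hi, mz, inten in sorted(ms2_raw, key=lambda r: r[1]):
        wi = assign(target, lo, hi)
        cycle = len(by_window[wi])
        by_window[wi].append(Ms2Scan(sid, rt, wi, cycle, mz, inten))

    run_name = name or re.sub(r"\.mzML$", "", str(path).split("/")[-1], flags=re.I)
    return MSRun(ms1, win_objs, by_window, name=run_name)


def _b64(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _cv(parent, accession, name, value="", **extra):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    attrs.update(extra)
    etree.SubElement(parent, "cvParam", attrs)


def write_mzml(run: MSRun, path) -> None:
    """Write an :class:`MSRun` as a minimal centroided mzML file.

    Emits only the subset of mzML needed to round-trip through standard readers:
    ms level, centroiding flag, scan start time (seconds), isolation-window
    target/offsets for MS2 scans, and zlib-compressed 64-bit peak arrays.
    """
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element("mzML", xmlns=NS, version="1.1.0")
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(cv_list, "cv", id="MS", fullName="PSI-MS",
                     URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000580", "MSn spectrum")

    scans: list[tuple[float, int, Ms1Scan | Ms2Scan]] = []
    for s in run.ms1_scans:
        scans.append((s.rt, 1, s))
    for lst in run.ms2_by_window.values():
        for s in lst:
            scans.append((s.rt, 2, s))
    scans.sort(key=lambda t: (t[0], t[1]))

    srun = etree.SubElement(root, "run", id=run.name)
    slist = etree.SubElement(srun, "spectrumList", count=str(len(scans)),
                             defaultDataProcessingRef="dp")
    for idx, (rt, level, scan) in enumerate(scans):
        sp = etree.SubElement(
            slist, "spectrum", index=str(idx),
            id=f"scan={scan.scan_id}", defaultArrayLength=str(len(scan.mz)))
        _cv(sp, "MS:1000511", "ms level", level)
        _cv(sp, "MS:1000127", "centroid spectrum")
        sl = etree.SubElement(sp, "scanList", count="1")
        sc = etree.SubElement(sl, "scan")
        _cv(sc, "MS:1000016", "scan start time", repr(rt),
            unitCvRef="UO", unitAccession="UO:0000010", unitName="second")
        if level == 2:
            win = run.window(scan.window_index)
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            iso = etree.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z", repr(win.center_mz),
                unitCvRef="MS", unitAccession="MS:1000040", unitName="m/z")
            _cv(iso, "MS:1000828", "isolation window lower offset", repr(win.width / 2.0))
            _cv(iso, "MS:1000829", "isolation window upper offset", repr(win.width / 2.0))
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, aname, values in (
                ("MS:1000514", "m/z array", scan.mz),
                ("MS:1000515", "intensity array", scan.intensity)):
            payload = _b64(values)
            ba = etree.SubElement(balist, "binaryDataArray",
                                  encodedLength=str(len(payload)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000574", "zlib compression")
            _cv(ba, accession, aname)
            etree.SubElement(ba, "binary").text = payload

    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# MGF (pseudo-spectrum dialect)
# ---------------------------------------------------------------------------

@dataclass
class MgfSpectrum:
    """One BEGIN IONS/END IONS block; ``charge`` is absent for pseudo-spectra."""

    title: str
    pepmass: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None

    def __post_init__(self):
        self.mz, self.intensity = _as_sorted_arrays(self.mz, self.intensity)


def read_mgf(path) -> list[MgfSpectrum]:
    """Read an MGF file; CHARGE lines are optional."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for block in reader:
            p = block["params"]
            charge = p.get("charge")
            if charge:
                charge = int(charge[0])
            else:
                charge = None
            rt = p.get("rtinseconds", 0.0)
            out.append(MgfSpectrum(
                title=p.get("title", ""),
                pepmass=float(p["pepmass"][0]),
                rt=float(rt),
                mz=np.asarray(block["m/z array"], dtype=float),
                intensity=np.asarray(block["intensity array"], dtype=float),
                charge=charge,
            ))
    return out


def write_mgf(pseudo_spectra: Iterable, path, run_name: str = "run") -> int:
    """Write pseudo-spectra as MGF blocks.

    PEPMASS is the isolation-window center (the pseudo-precursor m/z); TITLE is
    ``<run>.<scan_id>.<scan_id>.<iteration>``; no CHARGE line is written because
    charge is assigned at search time.  Empty peak lists are skipped with a
    warning.  Returns the number of blocks written.
    """
    n = 0
    with open(path, "w") as fh:
        for ps in pseudo_spectra:
            if len(ps.mz) == 0:
                log.warning("skipping empty pseudo-spectrum from scan %s", ps.source_scan)
                continue
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={run_name}.{ps.source_scan}.{ps.source_scan}.{ps.iteration}\n")
            fh.write(f"PEPMASS={ps.pseudo_precursor_mz:.6f}\n")
            fh.write(f"RTINSECONDS={ps.rt:.4f}\n")
            for m, i in zip(ps.mz, ps.intensity):
                fh.write(f"{m:.6f} {i:.6f}\n")
            fh.write("END IONS\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# MS1 text
# ---------------------------------------------------------------------------

def read_ms1(path) -> list[Ms1Scan]:
    """Read an MS1 text file (S/I/Z header lines + peak rows); rt in seconds."""
    out = []
    with _ms1.MS1(str(path)) as reader:
        for spec in reader:
            p = spec["params"]
            sid = int(p["scan"][0]) if isinstance(p.get("scan"), (list, tuple)) \
                else int(p.get("scan", len(out) + 1))
            rt_min = float(p.get("RTime", 0.0))
            out.append(Ms1Scan(
                sid, rt_min * 60.0,
                np.asarray(spec["m/z array"], dtype=float),
                np.asarray(spec["intensity array"], dtype=float)))
    out.sort(key=lambda s: s.rt)
    return out


def write_ms1(ms1_scans: Sequence[Ms1Scan], path) -> None:
    """Write MS1 scans in the standard MS1 text format (RTime in minutes)."""
    with open(path, "w") as fh:
        fh.write("H\tCreationDate\t-\nH\tExtractor\tdiadem\n")
        for s in ms1_scans:
            fh.write(f"S\t{s.scan_id:06d}\t{s.scan_id:06d}\n")
            fh.write(f"I\tRTime\t{s.rt / 60.0:.6f}\n")
            for m, i in zip(s.mz, s.intensity):
                fh.write(f"{m:.6f} {i:.2f}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a protein FASTA as (accession, sequence) pairs."""
    out = []
    with _fasta.FASTA(str(path)) as reader:
        for header, seq in reader:
            out.append((header.split()[0], seq))
    return out


def write_fasta(entries: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for acc, seq in entries:
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# SSL / PIN
# ---------------------------------------------------------------------------

def format_modified_sequence(sequence: str, mod_site: int | None,
                             mod_delta: float | None) -> str:
    """Bracketed-delta notation, e.g. ``VGS[+79.96633]EK`` for one modification."""
    if mod_site is None or mod_delta is None:
        return sequence
    i = int(mod_site)
    return f"{sequence[:i + 1]}[{mod_delta:+.5f}]{sequence[i + 1:]}"


def write_ssl(psms, path) -> None:
    """Write FDR-filtered PSMs as a BiblioSpec SSL table.

    ``psms`` is an iterable of mappings/namespaces with fields ``file``,
    ``scan``, ``charge`` and ``sequence`` (already in bracketed-mass notation).
    A PSM without a charge is an error: SSL requires one.
    """
    with open(path, "w") as fh:
        fh.write("file\tscan\tcharge\tsequence\n")
        for p in psms:
            get = p.get if hasattr(p, "get") else lambda k: getattr(p, k)
            charge = get("charge")
            if charge is None or (isinstance(charge, float) and np.isnan(charge)):
                raise ValueError(f"PSM for scan {get('scan')} lacks a charge")
            fh.write(f"{get('file')}\t{get('scan')}\t{int(charge)}\t{get('sequence')}\n")


def write_pin(psms, feature_names: Sequence[str], path) -> None:
    """Write PSMs in Percolator PIN format.

    Columns: SpecId, Label (+1 target / -1 decoy), ScanNr, the features in
    ``feature_names`` order, Peptide, Proteins.  A missing feature raises a
    :class:`ValueError` naming the PSM and the feature.
    """
    with open(path, "w") as fh:
        fh.write("SpecId\tLabel\tScanNr\t" + "\t".join(feature_names)
                 + "\tPeptide\tProteins\n")
        for p in psms:
            get = p.get if hasattr(p, "get") else lambda k, d=None: getattr(p, k, d)
            feats = []
            for fn in feature_names:
                v = get(fn)
                if v is None or (isinstance(v, float) and np.isnan(v)):
                    raise ValueError(f"PSM {get('spec_id')} lacks feature {fn!r}")
                feats.append(f"{float(v):.6g}")
            label = -1 if get("is_decoy") else 1
            fh.write(f"{get('spec_id')}\t{label}\t{get('scan')}\t"
                     + "\t".join(feats)
                     + f"\t{get('peptide')}\t{get('proteins')}\n")
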