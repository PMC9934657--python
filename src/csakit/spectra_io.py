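"""MSP/MGF spectral file I/O and the fragmentation-spectra database (FSDB).

MSP parsing is deliberately tolerant: community libraries (GNPS, MoNA,
NIST exports) vary in field naming, peak-line separators and record
spacing.  Field names are matched case-insensitively with a synonym map;
a declared ``Num Peaks`` that disagrees with the actual number of peak
lines is trusted to the actual lines (with a warning).

The FSDB is this project's own versioned JSON container (schema
``csakit-fsdb-1``): flat arrays of m/z and intensity with per-entry
offsets, the pre-computed spectral entropy and characteristic markers of
each conditioned spectrum, and a snapshot of the build parameters.  It is
plain text and deterministic: building twice from the same inputs yields
byte-identical files.
"""

from __future__ import annotations

import json
import logging
import os
import re
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .errors import FormatError, InputError
from .fsa import SearchParams, characteristic_markers, condition_spectrum, spectral_entropy
from .spectra import FragmentSpectrum

__all__ = [
    "FragmentSpectrum",
    "FSDBEntry",
    "FSDB",
    "read_msp",
    "write_msp",
    "read_mgf",
    "read_spectra",
    "build_fsdb",
    "save_fsdb",
    "load_fsdb",
]

logger = logging.getLogger(__name__)

FSDB_SCHEMA = "csakit-fsdb-1"

# canonical names of precursor/retention metadata (case-insensitive lookup)
_PRECURSOR_KEYS = {"precursormz", "precursor_mz", "precursor_m/z", "precursor m/z", "pepmass"}
_RT_KEYS = {"retention_time", "retentiontime", "rt", "rtinseconds", "retention time"}

_PEAK_LINE = re.compile(r"^\s*([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)[\s;:,]+"
                        r"([0-9]*\.?[0-9]+(?:[eE][-+]?[0-9]+)?)")


@dataclass
class FSDBEntry:
    """One library entry: conditioned spectrum plus cached entropy and markers."""

    spectrum: FragmentSpectrum
    entropy: float
    markers: np.ndarray
    source_id: str = ""


@dataclass
class FSDB:
    """Fragmentation-spectra database with pre-computed entropy and markers."""

    entries: list[FSDBEntry] = field(default_factory=list)
    ionization_mode: str = "positive"
    build_params: SearchParams = field(default_factory=SearchParams)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# MSP
# ---------------------------------------------------------------------------

def _finalize_record(meta: dict, peaks: list, declared: Optional[int],
                     path: str) -> Optional[FragmentSpectrum]:
    if not peaks:
        if meta:
            logger.warning("skipping record %r in %s: no peaks", meta.get("Name"), path)
        return None
    if declared is not None and declared != len(peaks):
        logger.warning(
            "record %r in %s declares %d peaks but has %d; keeping actual",
            meta.get("Name"), path, declared, len(peaks))
    precursor_mz = None
    precursor_rt = None
    clean_meta = {}
    for key, value in meta.items():
        low = key.lower()
        if low in _PRECURSOR_KEYS:
            try:
                precursor_mz = float(str(value).split()[0])
                continue
            except (ValueError, IndexError):
                pass
        if low in _RT_KEYS:
            try:
                rt = float(str(value).split()[0])
                precursor_rt = rt / 60.0 if low == "rtinseconds" else rt
                continue
            except (ValueError, IndexError):
                pass
        clean_meta[key] = str(value)
    mz = [p[0] for p in peaks]
    inten = [p[1] for p in peaks]
    try:
        return FragmentSpectrum(np.asarray(mz), np.asarray(inten),
                                precursor_mz=precursor_mz, precursor_rt=precursor_rt,
                                metadata=clean_meta)
    except ValueError as exc:
        logger.warning("skipping record %r in %s: %s", meta.get("Name"), path, exc)
        return None


def read_msp(path: str) -> list[FragmentSpectrum]:
    """Parse a NIST-style MSP file into spectra.

    Records start at a ``Name:`` line; peak lines follow ``Num Peaks:``
    until a blank line or the next record.  Unparseable records are
    skipped with a warning.
    """
    if not os.path.exists(path):
        raise InputError(f"MSP file not found: {path}")
    spectra: list[FragmentSpectrum] = []
    meta: dict = {}
    peaks: list = []
    declared: Optional[int] = None
    in_record = False

    def flush():
        nonlocal meta, peaks, declared, in_record
        if in_record:
            spec = _finalize_record(meta, peaks, declared, path)
            if spec is not None:
                spectra.append(spec)
        meta, peaks, declared, in_record = {}, [], None, False

    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                continue
            low = line.lower()
            if low.startswith("name:"):
                flush()
                in_record = True
                meta["Name"] = line.split(":", 1)[1].strip()
                continue
            if not in_record:
                continue
            if low.replace(" ", "").startswith("numpeaks:"):
                try:
                    declared = int(line.split(":", 1)[1].strip())
                except ValueError:
                    declared = None
                continue
            m = _PEAK_LINE.match(line)
            if m and ":" not in line.split()[0]:
                peaks.append((float(m.group(1)), float(m.group(2))))
                continue
            if ":" in line:
                key, value = line.split(":", 1)
                meta[key.strip()] = value.strip()
    flush()
    if not spectra:
        raise FormatError(f"no parseable MSP records in {path}")
    return spectra


def write_msp(spectra: list[FragmentSpectrum], path: str) -> None:
    """Write spectra as NIST-style MSP text.

    m/z values carry 5+ decimal places; a precursor line is emitted only
    when the spectrum has one (composite spectra typically do not).
    """
    if not spectra:
        raise InputError("refusing to write an empty MSP file")
    with open(path, "w", encoding="utf-8") as fh:
        for spec in spectra:
            name = spec.metadata.get("Name", "")
            fh.write(f"Name: {name}\n")
            if spec.precursor_mz is not None:
                fh.write(f"PrecursorMZ: {spec.precursor_mz:.6f}\n")
            if spec.precursor_rt is not None:
                fh.write(f"Retention_time: {spec.precursor_rt:.6f}\n")
            for key, value in spec.metadata.items():
                if key == "Name":
                    continue
                fh.write(f"{key}: {value}\n")
            fh.write(f"Num Peaks: {len(spec)}\n")
            for mz, inten in zip(spec.mz, spec.intensity):
                fh.write(f"{mz:.6f} {inten:.10g}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def read_mgf(path: str) -> list[FragmentSpectrum]:
    """Parse a Mascot generic format file (BEGIN IONS/END IONS blocks).

    PEPMASS maps to the precursor m/z (a trailing intensity column is
    ignored), TITLE to Name, RTINSECONDS to the retention time in minutes;
    charge columns on peak lines are ignored.
    """
    if not os.path.exists(path):
        raise InputError(f"MGF file not found: {path}")
    spectra: list[FragmentSpectrum] = []
    meta: dict = {}
    peaks: list = []
    in_block = False
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            upper = line.upper()
            if upper == "BEGIN IONS":
                in_block = True
                meta, peaks = {}, []
                continue
            if upper == "END IONS":
                if in_block:
                    if "TITLE" in meta:
                        meta["Name"] = meta.pop("TITLE")
                    spec = _finalize_record(meta, peaks, None, path)
                    if spec is not None:
                        spectra.append(spec)
                in_block = False
                continue
            if not in_block:
                continue
            if "=" in line and not line[0].isdigit():
                key, value = line.split("=", 1)
                meta[key.strip()] = value.strip()
                continue
            m = _PEAK_LINE.match(line)
            if m:
                peaks.append((float(m.group(1)), float(m.group(2))))
    if not spectra:
        raise FormatError(f"no parseable MGF blocks in {path}")
    return spectra


def read_spectra(path: str) -> list[FragmentSpectrum]:
    """Dispatch on file extension: .msp or .mgf."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".msp":
        return read_msp(path)
    if ext == ".mgf":
        return read_mgf(path)
    raise InputError(f"unsupported spectral file extension: {path}")


# ---------------------------------------------------------------------------
# FSDB
# ---------------------------------------------------------------------------

def build_fsdb(
    spectra: list[FragmentSpectrum],
    params: Optional[SearchParams] = None,
    ionization_mode: str = "positive",
) -> FSDB:
    """Condition each spectrum and cache its entropy and characteristic markers.

    Spectra left empty by denoising are dropped with a warning; entry
    order follows input order.
    """
    params = params if params is not None else SearchParams()
    params.validate()
    entries: list[FSDBEntry] = []
    for i, raw in enumerate(spectra):
        if not raw.is_usable():
            logger.warning("dropping unusable spectrum %d (%r)", i, raw.name)
            continue
        spec = condition_spectrum(raw, params)
        if not spec.is_usable():
            logger.warning("dropping spectrum %d (%r): empty after denoising", i, raw.name)
            continue
        entries.append(
            FSDBEntry(
                spectrum=spec,
                entropy=spectral_entropy(spec),
                markers=characteristic_markers(spec, params.marker_baseline_pct),
                source_id=raw.name or f"spectrum_{i}",
            )
        )
    return FSDB(entries=entries, ionization_mode=ionization_mode, build_params=params)


def save_fsdb(fsdb: FSDB, path: str) -> None:
    """Serialize to the versioned JSON container (deterministic byte layout)."""
    mz: list[float] = []
    intensity: list[float] = []
    offsets = [0]
    marker_mz: list[float] = []
    marker_offsets = [0]
    entropy = []
    precursor_mz = []
    precursor_rt = []
    metadata = []
    source_ids = []
    for entry in fsdb.entries:
        mz.extend(entry.spectrum.mz.tolist())
        intensity.extend(entry.spectrum.intensity.tolist())
        offsets.append(len(mz))
        marker_mz.extend(np.asarray(entry.markers).tolist())
        marker_offsets.append(len(marker_mz))
        entropy.append(entry.entropy)
        precursor_mz.append(entry.spectrum.precursor_mz)
        precursor_rt.append(entry.spectrum.precursor_rt)
        metadata.append(entry.spectrum.metadata)
        source_ids.append(entry.source_id)
    doc = {
        "schema": FSDB_SCHEMA,
        "ionization_mode": fsdb.ionization_mode,
        "build_params": asdict(fsdb.build_params),
        "n_entries": len(fsdb.entries),
        "offsets": offsets,
        "mz": mz,
        "intensity": intensity,
        "entropy": entropy,
        "marker_offsets": marker_offsets,
        "marker_mz": marker_mz,
        "precursor_mz": precursor_mz,
        "precursor_rt": precursor_rt,
        "metadata": metadata,
        "source_ids": source_ids,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))


def load_fsdb(path: str) -> FSDB:
    if not os.path.exists(path):
        raise InputError(f"FSDB file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema") != FSDB_SCHEMA:
        raise FormatError(f"unrecognized FSDB schema in {path}: {doc.get('schema')}")
    params = SearchParams.from_dict(doc["build_params"])
    mz = np.asarray(doc["mz"])
    intensity = np.asarray(doc["intensity"])
    marker_mz = np.asarray(doc["marker_mz"])
    entries = []
    for k in range(doc["n_entries"]):
        a, b = doc["offsets"][k], doc["offsets"][k + 1]
        ma, mb = doc["marker_offsets"][k], doc["marker_offsets"][k + 1]
        spec = FragmentSpectrum(
            mz[a:b], intensity[a:b],
            precursor_mz=doc["precursor_mz"][k],
            precursor_rt=doc["precursor_rt"][k],
            metadata=dict(doc["metadata"][k]),
        )
        entries.append(FSDBEntry(spectrum=spec, entropy=doc["entropy"][k],
                                 markers=marker_mz[ma:mb], source_id=doc["source_ids"][k]))
    return FSDB(entries=entries, ionization_mode=doc["ionization_mode"], build_params=params)
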