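"""Minimal mzML reader/writer (centroid MS1/MS2, no external dependencies).

Supports the subset of mzML needed for this pipeline: 32/64-bit float
m/z and intensity binary arrays, optional zlib compression, scan start
times in seconds or minutes, MS level, selected precursor m/z and
isolation windows.  Profile-mode spectra are rejected with a format error
advising centroiding.  The writer emits uncompressed 64-bit arrays, so
the output is plain base64-in-XML text.
"""

from __future__ import annotations

import base64
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FormatError, InputError

__all__ = ["RawSpectrum", "read_mzml", "write_mzml"]

NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS controlled-vocabulary accessions used here
ACC_MS_LEVEL = "MS:1000511"
ACC_CENTROID = "MS:1000127"
ACC_PROFILE = "MS:1000128"
ACC_SCAN_START = "MS:1000016"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INT_ARRAY = "MS:1000515"
ACC_F64 = "MS:1000523"
ACC_F32 = "MS:1000521"
ACC_ZLIB = "MS:1000574"
ACC_NO_COMPRESSION = "MS:1000576"
ACC_SELECTED_MZ = "MS:1000744"
ACC_ISO_TARGET = "MS:1000827"
ACC_ISO_LOWER = "MS:1000828"
ACC_ISO_UPPER = "MS:1000829"


@dataclass
class RawSpectrum:
    """One decoded mzML spectrum."""

    rt_minutes: float
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_window: Optional[tuple[float, float]] = None


def _cv_params(elem) -> dict[str, dict]:
    return {cv.get("accession"): cv.attrib for cv in elem.findall(f"{NS}cvParam")}


def _decode_binary(bda) -> tuple[Optional[str], np.ndarray]:
    cvs = _cv_params(bda)
    kind = "mz" if ACC_MZ_ARRAY in cvs else ("intensity" if ACC_INT_ARRAY in cvs else None)
    dtype = "<f8" if ACC_F64 in cvs else ("<f4" if ACC_F32 in cvs else "<f8")
    text_elem = bda.find(f"{NS}binary")
    text = (text_elem.text or "") if text_elem is not None else ""
    raw = base64.b64decode(text.strip()) if text.strip() else b""
    if ACC_ZLIB in cvs and raw:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(np.float64)


def _parse_spectrum(elem) -> RawSpectrum:
    cvs = _cv_params(elem)
    if ACC_PROFILE in cvs:
        raise FormatError(
            "profile-mode spectra detected; centroid the data first "
            "(e.g. msconvert --filter 'peakPicking')")
    ms_level = int(cvs.get(ACC_MS_LEVEL, {}).get("value", 1))
    rt = 0.0
    scan_list = elem.find(f"{NS}scanList")
    if scan_list is not None:
        for scan in scan_list.findall(f"{NS}scan"):
            scan_cvs = _cv_params(scan)
            if ACC_SCAN_START in scan_cvs:
                attrs = scan_cvs[ACC_SCAN_START]
                rt = float(attrs.get("value", 0.0))
                unit = (attrs.get("unitName") or "").lower()
                if unit in ("second", "seconds", ""):
                    rt /= 60.0
    precursor_mz = None
    isolation = None
    plist = elem.find(f"{NS}precursorList")
    if plist is not None:
        for prec in plist.findall(f"{NS}precursor"):
            iso = prec.find(f"{NS}isolationWindow")
            if iso is not None:
                iso_cvs = _cv_params(iso)
                if ACC_ISO_TARGET in iso_cvs:
                    target = float(iso_cvs[ACC_ISO_TARGET]["value"])
                    lo = float(iso_cvs.get(ACC_ISO_LOWER, {}).get("value", 0.0))
                    hi = float(iso_cvs.get(ACC_ISO_UPPER, {}).get("value", 0.0))
                    isolation = (target - lo, target + hi)
            ion_list = prec.find(f"{NS}selectedIonList")
            if ion_list is not None:
                for ion in ion_list.findall(f"{NS}selectedIon"):
                    ion_cvs = _cv_params(ion)
                    if ACC_SELECTED_MZ in ion_cvs:
                        precursor_mz = float(ion_cvs[ACC_SELECTED_MZ]["value"])
    mz = np.empty(0)
    intensity = np.empty(0)
    bdal = elem.find(f"{NS}binaryDataArrayList")
    if bdal is not None:
        for bda in bdal.findall(f"{NS}binaryDataArray"):
            kind, arr = _decode_binary(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                intensity = arr
    if mz.size != intensity.size:
        raise FormatError("m/z and intensity arrays differ in length")
    return RawSpectrum(rt_minutes=rt, ms_level=ms_level, mz=mz, intensity=intensity,
                       precursor_mz=precursor_mz, isolation_window=isolation)


def read_mzml(path: str) -> list[RawSpectrum]:
    """Stream-parse an mzML file into decoded spectra (in file order)."""
    spectra: list[RawSpectrum] = []
    try:
        context = ET.iterparse(path, events=("end",))
    except (OSError, FileNotFoundError) as exc:
        raise InputError(f"cannot open mzML file {path}: {exc}") from exc
    try:
        for _, elem in context:
            if elem.tag == f"{NS}spectrum":
                spectra.append(_parse_spectrum(elem))
                elem.clear()
    except ET.ParseError as exc:
        raise FormatError(f"malformed mzML in {path}: {exc}") from exc
    return spectra


def _encode_binary(arr: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{arr.size}d", *arr.astype(np.float64))).decode()


def _cv(accession: str, name: str, value: str = "", unit: Optional[tuple[str, str]] = None) -> str:
    attrs = f'cvRef="MS" accession="{accession}" name="{name}" value="{value}"'
    if unit is not None:
        attrs += f' unitCvRef="UO" unitAccession="{unit[0]}" unitName="{unit[1]}"'
    return f"<cvParam {attrs}/>"


def write_mzml(spectra: list[RawSpectrum], path: str) -> None:
    """Write centroid spectra as uncompressed 64-bit mzML."""
    lines = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        '<run id="run1">',
        f'<spectrumList count="{len(spectra)}">',
    ]
    for i, spec in enumerate(spectra):
        n = spec.mz.size
        lines.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">')
        lines.append(_cv(ACC_MS_LEVEL, "ms level", str(spec.ms_level)))
        lines.append(_cv(ACC_CENTROID, "centroid spectrum"))
        lines.append('<scanList count="1"><scan>')
        lines.append(_cv(ACC_SCAN_START, "scan start time", f"{spec.rt_minutes:.8f}",
                         unit=("UO:0000031", "minute")))
        lines.append("</scan></scanList>")
        if spec.ms_level >= 2 and (spec.precursor_mz is not None or spec.isolation_window):
            lines.append('<precursorList count="1"><precursor>')
            if spec.isolation_window is not None:
                lo, hi = spec.isolation_window
                target = 0.5 * (lo + hi)
                lines.append("<isolationWindow>")
                lines.append(_cv(ACC_ISO_TARGET, "isolation window target m/z", f"{target:.6f}"))
                lines.append(_cv(ACC_ISO_LOWER, "isolation window lower offset",
                                 f"{target - lo:.6f}"))
                lines.append(_cv(ACC_ISO_UPPER, "isolation window upper offset",
                                 f"{hi - target:.6f}"))
                lines.append("</isolationWindow>")
            if spec.precursor_mz is not None:
                lines.append('<selectedIonList count="1"><selectedIon>')
                lines.append(_cv(ACC_SELECTED_MZ, "selected ion m/z", f"{spec.precursor_mz:.6f}"))
                lines.append("</selectedIon></selectedIonList>")
            lines.append("</precursor></precursorList>")
        lines.append('<binaryDataArrayList count="2">')
        for arr, acc, name in ((spec.mz, ACC_MZ_ARRAY, "m/z array"),
                               (spec.intensity, ACC_INT_ARRAY, "intensity array")):
            payload = _encode_binary(np.asarray(arr))
            lines.append(f'<binaryDataArray encodedLength="{len(payload)}">')
            lines.append(_cv(ACC_F64, "64-bit float"))
            lines.append(_cv(ACC_NO_COMPRESSION, "no compression"))
            lines.append(_cv(acc, name))
            lines.append(f"<binary>{payload}</binary>")
            lines.append("</binaryDataArray>")
        lines.append("</binaryDataArrayList>")
        lines.append("</spectrum>")
    lines.extend(["</spectrumList>", "</run>", "</mzML>", ""])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))
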