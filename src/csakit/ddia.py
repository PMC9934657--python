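"""DDA and DIA fragment-spectrum extraction.

DDA: MS2 scans whose selected precursor matches an MS1 peak's 12C m/z
within tolerance and whose RT lies inside the peak boundaries are
collected and, when several exist, consolidated by one of three options:
integrate all scans, keep the most abundant scan verbatim, or denoise
(drop RT-flat fragments by relative standard deviation, then keep
fragments whose across-scan profile correlates with the precursor's MS1
EIC).

DIA: candidate fragment m/z values come from the MS2 scan nearest in RT
to the MS1 peak apex (honouring isolation windows); each candidate's MS2
EIC over the peak boundaries is correlated against the precursor's MS1
EIC and retained at ``r >= pearson_min``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from typing import Optional, Sequence

import numpy as np

from .deconv import profile_correlation
from .errors import InputError, TooShortError, ValidationError
from .ms1 import EIC, MS1Peak, Scan, ScanTable, extract_eic, smooth_eic
from .spectra import FragmentSpectrum

__all__ = ["DDAParams", "DIAParams", "extract_dda", "extract_dia"]

logger = logging.getLogger(__name__)

CONSOLIDATION_OPTIONS = ("integrate_all", "most_abundant", "denoise")


@dataclass
class DDAParams:
    consolidation: str = "integrate_all"
    rsd_flat_max: float = 25.0           # %; fragments at or below are "flat"
    pearson_min: float = 0.8
    precursor_mz_tol: float = 0.01       # Da
    fragment_bin_tol: float = 0.005      # Da; same-fragment binning width

    def validate(self) -> None:
        if self.consolidation not in CONSOLIDATION_OPTIONS:
            raise ValidationError(
                f"consolidation must be one of {CONSOLIDATION_OPTIONS}: "
                f"{self.consolidation}")
        if self.rsd_flat_max < 0:
            raise ValidationError(f"rsd_flat_max must be >= 0: {self.rsd_flat_max}")
        if not (-1.0 <= self.pearson_min <= 1.0):
            raise ValidationError(f"pearson_min must be in [-1, 1]: {self.pearson_min}")

    @classmethod
    def from_dict(cls, d: dict) -> "DDAParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown DDA parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class DIAParams:
    pearson_min: float = 0.8
    height_fraction: float = 0.5
    fragment_mz_tol: float = 0.01        # Da; MS2 EIC extraction tolerance
    min_fragment_intensity: float = 0.0
    # EIC smoothing (shared with the deconvolution defaults)
    loess_span: float = 0.2
    loess_degree: int = 2
    grid_n: int = 100
    eic_mz_tol: float = 10.0
    eic_tol_is_ppm: bool = True

    def validate(self) -> None:
        if not (-1.0 <= self.pearson_min <= 1.0):
            raise ValidationError(f"pearson_min must be in [-1, 1]: {self.pearson_min}")
        if not (0.0 <= self.height_fraction < 1.0):
            raise ValidationError(
                f"height_fraction must be in [0, 1): {self.height_fraction}")

    @classmethod
    def from_dict(cls, d: dict) -> "DIAParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown DIA parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


# ---------------------------------------------------------------------------
# DDA
# ---------------------------------------------------------------------------

def _bin_fragments(mz_lists: list[np.ndarray], tol: float) -> np.ndarray:
    """Cluster fragment m/z values across scans into bin centres."""
    allmz = np.sort(np.concatenate(mz_lists))
    if allmz.size == 0:
        return allmz
    run_id = np.concatenate(([0], np.cumsum(np.diff(allmz) > tol)))
    centres = np.zeros(int(run_id[-1]) + 1)
    counts = np.zeros_like(centres)
    np.add.at(centres, run_id, allmz)
    np.add.at(counts, run_id, 1.0)
    return centres / counts


def _scan_bin_matrix(ms2: list[Scan], bins: np.ndarray, tol: float) -> np.ndarray:
    """Intensity of each fragment bin in each scan (summed within tol)."""
    matrix = np.zeros((len(ms2), bins.size))
    for si, scan in enumerate(ms2):
        a = np.searchsorted(scan.mz, bins - tol, side="left")
        b = np.searchsorted(scan.mz, bins + tol, side="right")
        for bi in range(bins.size):
            if b[bi] > a[bi]:
                matrix[si, bi] = scan.intensity[a[bi]:b[bi]].sum()
    return matrix


def _spectrum_from_scan(scan: Scan, peak: MS1Peak, extra: dict) -> FragmentSpectrum:
    meta = {"Name": f"DDA_{peak.peak_id}", **extra}
    return FragmentSpectrum(scan.mz.copy(), scan.intensity.copy(),
                            precursor_mz=peak.mz_12C, precursor_rt=peak.rt_apex,
                            metadata=meta)


def extract_dda(
    scans: ScanTable,
    peaks: Sequence[MS1Peak],
    params: Optional[DDAParams] = None,
) -> list[FragmentSpectrum]:
    """One consolidated DDA spectrum per MS1 peak with matching MS2 scans."""
    params = params if params is not None else DDAParams()
    params.validate()
    out: list[FragmentSpectrum] = []
    ms2_all = scans.level(2)
    if not ms2_all:
        logger.warning("no MS2 scans present; DDA extraction yields nothing")
        return out
    for peak in peaks:
        matching = [
            s for s in ms2_all
            if s.precursor_mz is not None
            and abs(s.precursor_mz - peak.mz_12C) <= params.precursor_mz_tol
            and peak.rt_start <= s.rt <= peak.rt_end
        ]
        if not matching:
            logger.info("peak %d: no matching DDA scans", peak.peak_id)
            continue
        meta = {"Consolidation": params.consolidation, "Scans": str(len(matching))}
        if len(matching) == 1:
            out.append(_spectrum_from_scan(matching[0], peak, meta))
            continue
        if params.consolidation == "most_abundant":
            best = max(matching, key=lambda s: float(s.intensity.sum()))
            out.append(_spectrum_from_scan(best, peak, meta))
            continue
        bins = _bin_fragments([s.mz for s in matching], params.fragment_bin_tol)
        matrix = _scan_bin_matrix(matching, bins, params.fragment_bin_tol)
        if params.consolidation == "integrate_all":
            keep = matrix.sum(axis=0) > 0
            spec = FragmentSpectrum(bins[keep], matrix.sum(axis=0)[keep],
                                    precursor_mz=peak.mz_12C, precursor_rt=peak.rt_apex,
                                    metadata={"Name": f"DDA_{peak.peak_id}", **meta})
            out.append(spec)
            continue
        # denoise: drop flat fragments, then require co-variation with the
        # precursor's MS1 elution profile at the MS2 scan RTs
        means = matrix.mean(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rsd = np.where(means > 0, matrix.std(axis=0, ddof=0) / means * 100.0, 0.0)
        keep = (means > 0) & (rsd > params.rsd_flat_max)
        try:
            ms1_eic = extract_eic(scans, peak.mz_12C, rt_window=(peak.rt_start, peak.rt_end))
        except InputError:
            continue
        scan_rts = np.asarray([s.rt for s in matching])
        ref = np.interp(scan_rts, ms1_eic.rt_grid, ms1_eic.intensities)
        if np.ptp(ref) == 0:
            logger.warning("peak %d: constant MS1 reference; skipping denoise", peak.peak_id)
            continue
        retained = []
        for bi in np.where(keep)[0]:
            prof = matrix[:, bi]
            if np.ptp(prof) == 0:
                continue
            r = float(np.corrcoef(prof, ref)[0, 1])
            if np.isfinite(r) and r >= params.pearson_min:
                retained.append(bi)
        if not retained:
            logger.info("peak %d: denoise removed every fragment", peak.peak_id)
            continue
        retained = np.asarray(retained)
        spec = FragmentSpectrum(bins[retained], matrix.sum(axis=0)[retained],
                                precursor_mz=peak.mz_12C, precursor_rt=peak.rt_apex,
                                metadata={"Name": f"DDA_{peak.peak_id}", **meta})
        out.append(spec)
    return out


# ---------------------------------------------------------------------------
# DIA
# ---------------------------------------------------------------------------

def _smooth_or_none(eic: EIC, params: DIAParams) -> Optional[EIC]:
    try:
        sm = smooth_eic(eic, loess_span=params.loess_span,
                        loess_degree=params.loess_degree, grid_n=params.grid_n)
    except TooShortError:
        return None
    return sm if sm.apex_intensity > 0 else None


def extract_dia(
    scans: ScanTable,
    peaks: Sequence[MS1Peak],
    params: Optional[DIAParams] = None,
) -> list[FragmentSpectrum]:
    """One DIA spectrum per MS1 peak whose MS2 channel co-varies with it.

    Fragments are seeded from the single MS2 scan nearest the MS1 apex
    (restricted to scans whose isolation window covers the precursor when
    windows are present); a fragment survives when its smoothed MS2 EIC
    correlates with the precursor's smoothed MS1 EIC at
    ``>= pearson_min``.  Intensities are the fragments' own apex EIC
    heights; the MS1 peak is the precursor.
    """
    params = params if params is not None else DIAParams()
    params.validate()
    out: list[FragmentSpectrum] = []
    ms2_all = scans.level(2)
    if not ms2_all:
        logger.warning("no MS2 scans present; DIA extraction yields nothing")
        return out
    for peak in peaks:
        window = (peak.rt_start, peak.rt_end)
        channel = [
            s for s in ms2_all
            if s.isolation_window is None
            or (s.isolation_window[0] <= peak.mz_12C <= s.isolation_window[1])
        ]
        in_window = [s for s in channel if window[0] <= s.rt <= window[1]]
        if not in_window:
            continue
        apex_scan = min(in_window, key=lambda s: abs(s.rt - peak.rt_apex))
        candidates = apex_scan.mz[apex_scan.intensity > params.min_fragment_intensity]
        if candidates.size == 0:
            continue
        try:
            ms1_raw = extract_eic(scans, peak.mz_12C, mz_tol=params.eic_mz_tol,
                                  rt_window=window, tol_is_ppm=params.eic_tol_is_ppm)
        except InputError:
            continue
        ms1_eic = _smooth_or_none(ms1_raw, params)
        if ms1_eic is None:
            continue
        frag_mz: list[float] = []
        frag_int: list[float] = []
        for fmz in candidates:
            try:
                frag_raw = extract_eic(scans, float(fmz), mz_tol=params.fragment_mz_tol,
                                       rt_window=window, ms_level=2, tol_is_ppm=False,
                                       isolation_contains=peak.mz_12C)
            except InputError:
                continue
            frag_eic = _smooth_or_none(frag_raw, params)
            if frag_eic is None or len(frag_eic) != len(ms1_eic):
                continue
            # MS2 scans sample different RTs than MS1; re-grid the MS1
            # reference onto the fragment grid before correlating
            ref = EIC(peak_id=peak.peak_id, rt_grid=frag_eic.rt_grid,
                      intensities=np.interp(frag_eic.rt_grid, ms1_eic.rt_grid,
                                            ms1_eic.intensities),
                      smoothed=True)
            r = profile_correlation(ref, frag_eic, params.height_fraction)
            if r >= params.pearson_min:
                frag_mz.append(float(fmz))
                frag_int.append(frag_eic.apex_intensity)
        if not frag_mz:
            continue
        out.append(
            FragmentSpectrum(
                np.asarray(frag_mz), np.asarray(frag_int),
                precursor_mz=peak.mz_12C, precursor_rt=peak.rt_apex,
                metadata={"Name": f"DIA_{peak.peak_id}",
                          "Retention_time": f"{peak.rt_apex:.4f}"},
            )
        )
    return out
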