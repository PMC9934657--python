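"""MS1 scan model: scan ingestion, peak lists, EIC extraction and smoothing.

Unit conventions used project-wide: retention time in minutes, m/z in Da,
EIC m/z tolerance in ppm by default (absolute Da optional).  RT windows
are half-open ``[start, end)`` so adjacent windows never double-count a
scan.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from . import mzml
from .errors import FormatError, InputError, TooShortError

__all__ = [
    "Scan",
    "ScanTable",
    "MS1Peak",
    "EIC",
    "read_scans",
    "write_scans",
    "read_peaklist",
    "write_peaklist",
    "read_aligned_table",
    "extract_eic",
    "loess",
    "smooth_eic",
    "C13_C12_MIN",
    "C13_C12_MAX",
]

logger = logging.getLogger(__name__)

# permitted 13C-12C spacing for a singly charged isotopologue pair (Da)
C13_C12_MIN = 1.0000
C13_C12_MAX = 1.0070

PEAKLIST_COLUMNS = ["peak_id", "mz", "mz_13C", "rt_apex", "rt_start", "rt_end", "height", "snr"]
_REQUIRED_COLUMNS = ["mz", "rt_apex", "rt_start", "rt_end", "height", "snr"]


@dataclass
class Scan:
    rt: float                   # minutes
    ms_level: int
    mz: np.ndarray              # ascending
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    isolation_window: Optional[tuple[float, float]] = None


@dataclass
class ScanTable:
    """Ordered centroided scans (MS1 and optionally MS2)."""

    scans: list[Scan] = field(default_factory=list)

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise FormatError("scan retention times must be non-decreasing")
        for s in self.scans:
            if s.mz.size != s.intensity.size:
                raise FormatError("scan m/z and intensity arrays differ in length")

    def __len__(self) -> int:
        return len(self.scans)

    def level(self, ms_level: int) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == ms_level]

    @property
    def rt_range(self) -> tuple[float, float]:
        if not self.scans:
            return (0.0, 0.0)
        return (self.scans[0].rt, self.scans[-1].rt)


@dataclass
class MS1Peak:
    """One chromatographic peak from an upstream peak list."""

    peak_id: int
    mz_12C: float
    rt_apex: float
    rt_start: float
    rt_end: float
    height: float
    snr: float
    mz_13C: Optional[float] = None

    def validate(self) -> None:
        if not (self.rt_start < self.rt_apex < self.rt_end):
            raise FormatError(
                f"peak {self.peak_id}: need rt_start < rt_apex < rt_end "
                f"({self.rt_start}, {self.rt_apex}, {self.rt_end})")
        if self.height <= 0 or self.snr <= 0:
            raise FormatError(f"peak {self.peak_id}: height and snr must be > 0")
        if self.mz_13C is not None:
            spacing = self.mz_13C - self.mz_12C
            if not (C13_C12_MIN <= spacing <= C13_C12_MAX):
                raise FormatError(
                    f"peak {self.peak_id}: 13C-12C spacing {spacing:.5f} outside "
                    f"[{C13_C12_MIN}, {C13_C12_MAX}]")


@dataclass
class EIC:
    """Extracted-ion chromatogram on a retention-time grid."""

    peak_id: Optional[int]
    rt_grid: np.ndarray
    intensities: np.ndarray
    smoothed: bool = False

    def __len__(self) -> int:
        return int(self.rt_grid.size)

    @property
    def apex_intensity(self) -> float:
        return float(self.intensities.max()) if len(self) else 0.0

    @property
    def apex_rt(self) -> float:
        return float(self.rt_grid[int(np.argmax(self.intensities))])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_scans(path: str) -> ScanTable:
    """Read centroided scan data (mzML) into a ScanTable, RT in minutes."""
    raw = mzml.read_mzml(path)
    scans = [
        Scan(rt=r.rt_minutes, ms_level=r.ms_level, mz=r.mz, intensity=r.intensity,
             precursor_mz=r.precursor_mz, isolation_window=r.isolation_window)
        for r in raw
    ]
    return ScanTable(scans=scans)


def write_scans(table: ScanTable, path: str) -> None:
    """Write a ScanTable as plain-text (uncompressed base64) mzML."""
    raw = [
        mzml.RawSpectrum(rt_minutes=s.rt, ms_level=s.ms_level, mz=s.mz,
                         intensity=s.intensity, precursor_mz=s.precursor_mz,
                         isolation_window=s.isolation_window)
        for s in table.scans
    ]
    mzml.write_mzml(raw, path)


def _detect_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_peaklist(path) -> list[MS1Peak]:
    """Read a chromatographic peak list (TSV/CSV with documented headers).

    Required columns: ``mz, rt_apex, rt_start, rt_end, height, snr``;
    optional: ``peak_id`` (defaults to row order) and ``mz_13C`` (blank =
    absent).  Rows violating the peak invariants are dropped with a
    warning; a missing required column is a format error.
    """
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise InputError(f"peak list not found: {path}")
    table = pd.read_csv(path, sep=_detect_sep(path))
    for col in _REQUIRED_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"peak list {path} is missing required column '{col}'")
    peaks: list[MS1Peak] = []
    for i, row in table.iterrows():
        mz_13c = row.get("mz_13C")
        if mz_13c is not None and pd.isna(mz_13c):
            mz_13c = None
        peak = MS1Peak(
            peak_id=int(row["peak_id"]) if "peak_id" in table.columns else int(i),
            mz_12C=float(row["mz"]),
            mz_13C=float(mz_13c) if mz_13c is not None else None,
            rt_apex=float(row["rt_apex"]),
            rt_start=float(row["rt_start"]),
            rt_end=float(row["rt_end"]),
            height=float(row["height"]),
            snr=float(row["snr"]),
        )
        try:
            peak.validate()
        except FormatError as exc:
            logger.warning("dropping invalid peak-list row %d: %s", i, exc)
            continue
        peaks.append(peak)
    return peaks


def write_peaklist(peaks: Sequence[MS1Peak], path: str) -> None:
    rows = [
        {
            "peak_id": p.peak_id,
            "mz": p.mz_12C,
            "mz_13C": p.mz_13C if p.mz_13C is not None else "",
            "rt_apex": p.rt_apex,
            "rt_start": p.rt_start,
            "rt_end": p.rt_end,
            "height": p.height,
            "snr": p.snr,
        }
        for p in peaks
    ]
    pd.DataFrame(rows, columns=PEAKLIST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_aligned_table(path) -> pd.DataFrame:
    """Read an aligned peak-height table (rows = peaks, columns = samples).

    Requires ``mz`` and ``rt`` columns; every remaining column is a sample
    of peak heights (0 or blank = not detected).  The row index is the
    aligned-row id used throughout the pipeline.
    """
    if isinstance(path, (str, os.PathLike)) and not os.path.exists(path):
        raise InputError(f"aligned table not found: {path}")
    table = pd.read_csv(path, sep=_detect_sep(path))
    for col in ("mz", "rt"):
        if col not in table.columns:
            raise FormatError(f"aligned table {path} is missing required column '{col}'")
    return table


# ---------------------------------------------------------------------------
# EIC extraction and smoothing
# ---------------------------------------------------------------------------

def extract_eic(
    scans: ScanTable,
    mz: float,
    mz_tol: float = 10.0,
    rt_window: Optional[tuple[float, float]] = None,
    ms_level: int = 1,
    tol_is_ppm: bool = True,
    peak_id: Optional[int] = None,
    isolation_contains: Optional[float] = None,
) -> EIC:
    """Extract one intensity per in-window scan of the requested MS level.

    The intensity is the sum of centroids within ``±tol`` of ``mz`` (0
    when none); the RT window is half-open ``[start, end)``.  For MS2
    channels, ``isolation_contains`` restricts to scans whose isolation
    window covers that m/z.
    """
    tol = mz * mz_tol * 1e-6 if tol_is_ppm else mz_tol
    rts: list[float] = []
    values: list[float] = []
    for scan in scans.scans:
        if scan.ms_level != ms_level:
            continue
        if rt_window is not None and not (rt_window[0] <= scan.rt < rt_window[1]):
            continue
        if isolation_contains is not None and scan.isolation_window is not None:
            lo, hi = scan.isolation_window
            if not (lo <= isolation_contains <= hi):
                continue
        a = np.searchsorted(scan.mz, mz - tol, side="left")
        b = np.searchsorted(scan.mz, mz + tol, side="right")
        rts.append(scan.rt)
        values.append(float(scan.intensity[a:b].sum()))
    if not rts:
        raise InputError(
            f"no MS{ms_level} scans inside RT window {rt_window} for m/z {mz:.4f}")
    rt_grid = np.asarray(rts)
    if rt_grid.size > 1 and np.any(np.diff(rt_grid) <= 0):
        keep = np.concatenate(([True], np.diff(rt_grid) > 0))
        logger.warning("dropping %d non-increasing RT points from EIC", int((~keep).sum()))
        rt_grid = rt_grid[keep]
        values = list(np.asarray(values)[keep])
    return EIC(peak_id=peak_id, rt_grid=rt_grid, intensities=np.asarray(values))


def loess(x: np.ndarray, y: np.ndarray, span: float = 0.2, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at the input points.

    Tricube weights over the ``ceil(span * n)`` nearest neighbours of each
    point (never fewer than ``degree + 2``); the local fit is centred on
    the evaluation point so the fitted intercept is the smoothed value.
    Fully vectorized via batched normal-equation solves.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n < degree + 2:
        return y.copy()
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)
    delta = x[None, :] - x[:, None]                    # delta[i, j] = x_j - x_i
    dist = np.abs(delta)
    bandwidth = np.partition(dist, k - 1, axis=1)[:, k - 1]
    bandwidth = np.maximum(bandwidth, 1e-12)
    u = dist / bandwidth[:, None]
    w = np.clip(1.0 - u**3, 0.0, None) ** 3
    # points exactly at the bandwidth edge get weight 0; guarantee >= degree+1
    # usable points by flooring the self weight
    w[np.arange(n), np.arange(n)] = np.maximum(w[np.arange(n), np.arange(n)], 1e-6)
    # batched weighted polynomial fit: moments of (x_j - x_i)
    powers = [np.ones_like(delta)]
    for _ in range(2 * degree):
        powers.append(powers[-1] * delta)
    moments = np.stack([(w * p).sum(axis=1) for p in powers], axis=1)   # (n, 2d+1)
    rhs = np.stack([(w * p * y[None, :]).sum(axis=1) for p in powers[: degree + 1]], axis=1)
    m = degree + 1
    a = np.empty((n, m, m))
    for r in range(m):
        for c in range(m):
            a[:, r, c] = moments[:, r + c]
    # tiny ridge keeps near-singular local systems solvable
    ridge = 1e-10 * np.maximum(np.trace(a, axis1=1, axis2=2), 1e-30)
    a += ridge[:, None, None] * np.eye(m)[None, :, :]
    try:
        beta = np.linalg.solve(a, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        beta = np.stack([np.linalg.lstsq(a[i], rhs[i], rcond=None)[0] for i in range(n)])
    return beta[:, 0]


def smooth_eic(
    eic: EIC,
    loess_span: float = 0.2,
    loess_degree: int = 2,
    grid_n: int = 100,
) -> EIC:
    """LOESS fit followed by cubic-spline interpolation onto a uniform grid.

    The smoothed EIC covers exactly the input RT interval on ``grid_n``
    points; negative interpolated values are clipped to 0.
    """
    if len(eic) < 5:
        raise TooShortError(
            f"EIC for peak {eic.peak_id} has {len(eic)} points; >= 5 required")
    fitted = loess(eic.rt_grid, eic.intensities, span=loess_span, degree=loess_degree)
    grid = np.linspace(eic.rt_grid[0], eic.rt_grid[-1], grid_n)
    spline = CubicSpline(eic.rt_grid, fitted)
    values = np.clip(spline(grid), 0.0, None)
    return EIC(peak_id=eic.peak_id, rt_grid=grid, intensities=values, smoothed=True)
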