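"""Composite-spectra deconvolution.

Groups co-eluting MS1 peaks into clusters anchored on intensity-ordered
seed peaks: the most intense unassigned peak above the S/N threshold
seeds a cluster, peaks within the RT grouping window are recruited when
their smoothed EIC correlates with the seed's at or above ``pearson_min``
(computed only on grid points above a height fraction of each profile's
own apex), and clusters survive only with at least ``min_ions`` members
spanning more than ``min_mz_span`` Da of 12C m/z — suppressing bare
isotopic envelopes.  13C partners are appended to the exported spectrum
only when their 12C counterpart is a member; every peak is assigned to at
most one cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError, TooShortError, ValidationError
from .ms1 import EIC, MS1Peak, ScanTable, extract_eic, smooth_eic
from .spectra import FragmentSpectrum

__all__ = [
    "CSAParams",
    "CSACluster",
    "select_seed",
    "group_candidates",
    "profile_correlation",
    "intersample_filter",
    "build_cluster",
    "deconvolute_file",
    "link_true_positive",
    "map_peaks_to_aligned",
    "clusters_to_spectra",
]

logger = logging.getLogger(__name__)


@dataclass
class CSAParams:
    """Deconvolution thresholds plus EIC extraction/smoothing settings."""

    seed_snr_min: float = 5.0
    rt_group_window: float = 0.01        # minutes, closed on both ends
    pearson_min: float = 0.98
    height_fraction: float = 0.5         # fraction of apex used for correlation
    min_ions: int = 2
    min_mz_span: float = 8.0             # Da, strict lower bound on 12C span
    intersample_r_min: Optional[float] = 0.5   # None disables the filter
    # EIC extraction / smoothing
    eic_mz_tol: float = 10.0
    eic_tol_is_ppm: bool = True
    loess_span: float = 0.2
    loess_degree: int = 2
    grid_n: int = 100

    def validate(self) -> None:
        if not (0.0 < self.pearson_min <= 1.0):
            raise ValidationError(f"pearson_min must be in (0, 1]: {self.pearson_min}")
        if not (0.0 <= self.height_fraction < 1.0):
            raise ValidationError(
                f"height_fraction must be in [0, 1): {self.height_fraction}")
        if self.min_ions < 2:
            raise ValidationError(f"min_ions must be >= 2: {self.min_ions}")
        if self.min_mz_span <= 0:
            raise ValidationError(f"min_mz_span must be > 0: {self.min_mz_span}")
        if self.rt_group_window <= 0:
            raise ValidationError(f"rt_group_window must be > 0: {self.rt_group_window}")

    @classmethod
    def from_dict(cls, d: dict) -> "CSAParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown CSA parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class CSACluster:
    """A set of co-eluting peaks assigned to one seed."""

    seed_peak_id: int
    member_peak_ids: list[int]
    member_r: dict[int, float]
    rt_apex: float
    spectrum: FragmentSpectrum
    file_id: str = ""


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def select_seed(
    peaks: Sequence[MS1Peak], assigned: set[int], params: CSAParams
) -> Optional[MS1Peak]:
    """Most intense unassigned peak with snr >= seed_snr_min (ties: lower id)."""
    best: Optional[MS1Peak] = None
    for peak in peaks:
        if peak.peak_id in assigned or peak.snr < params.seed_snr_min:
            continue
        if best is None or peak.height > best.height or (
            peak.height == best.height and peak.peak_id < best.peak_id
        ):
            best = peak
    return best


def group_candidates(
    peaks: Sequence[MS1Peak], seed: MS1Peak, assigned: set[int], params: CSAParams
) -> list[MS1Peak]:
    """Unassigned peaks within the RT window of the seed apex (closed window)."""
    out = [
        p for p in peaks
        if p.peak_id not in assigned
        and p.peak_id != seed.peak_id
        # closed window; epsilon keeps decimal boundaries inside despite fp error
        and abs(p.rt_apex - seed.rt_apex) <= params.rt_group_window + 1e-9
    ]
    out.sort(key=lambda p: p.peak_id)
    return out


def profile_correlation(eic_a: EIC, eic_b: EIC, height_fraction: float = 0.5) -> float:
    """Pearson r of two smoothed EICs on their shared grid.

    Only grid points where both profiles exceed ``height_fraction`` of
    their own apex enter the correlation (trimming tailing/fronting);
    fewer than 5 such points, or a constant profile, yields -1
    (non-correlatable).
    """
    if not (eic_a.smoothed and eic_b.smoothed):
        raise ContractError("profile_correlation requires smoothed EICs")
    if len(eic_a) != len(eic_b) or not np.allclose(eic_a.rt_grid, eic_b.rt_grid):
        raise ContractError("EICs must share one RT grid")
    a, b = eic_a.intensities, eic_b.intensities
    if a.max() <= 0 or b.max() <= 0:
        return -1.0
    mask = (a > height_fraction * a.max()) & (b > height_fraction * b.max())
    if int(mask.sum()) < 5:
        return -1.0
    av, bv = a[mask], b[mask]
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return -1.0
    r = np.corrcoef(av, bv)[0, 1]
    return float(r) if np.isfinite(r) else -1.0


def intersample_filter(
    aligned: pd.DataFrame,
    seed_row: int,
    candidate_rows: dict[int, int],
    r_min: float,
) -> set[int]:
    """Keep candidates whose across-sample heights track the seed's.

    ``candidate_rows`` maps candidate peak id to its aligned-table row.
    Correlation is computed on samples where both peaks are detected
    (height > 0); with fewer than 5 shared samples the candidate is
    retained by default (no evidence against it).
    """
    sample_cols = [c for c in aligned.columns if c not in ("mz", "rt")]
    seed_vec = aligned.loc[seed_row, sample_cols].to_numpy(dtype=float)
    retained: set[int] = set()
    for peak_id, row in candidate_rows.items():
        cand_vec = aligned.loc[row, sample_cols].to_numpy(dtype=float)
        both = (
            np.isfinite(seed_vec) & np.isfinite(cand_vec)
            & (seed_vec > 0) & (cand_vec > 0)
        )
        if int(both.sum()) < 5:
            retained.add(peak_id)
            continue
        sv, cv = seed_vec[both], cand_vec[both]
        if np.ptp(sv) == 0 or np.ptp(cv) == 0:
            retained.add(peak_id)
            continue
        r = float(np.corrcoef(sv, cv)[0, 1])
        if np.isfinite(r) and r >= r_min:
            retained.add(peak_id)
    return retained


def _member_eic(scans: ScanTable, mz: float, window: tuple[float, float],
                params: CSAParams, peak_id: Optional[int] = None) -> Optional[EIC]:
    try:
        raw = extract_eic(scans, mz, mz_tol=params.eic_mz_tol, rt_window=window,
                          tol_is_ppm=params.eic_tol_is_ppm, peak_id=peak_id)
        smoothed = smooth_eic(raw, loess_span=params.loess_span,
                              loess_degree=params.loess_degree, grid_n=params.grid_n)
    except (InputError, TooShortError):
        return None
    return smoothed if smoothed.apex_intensity > 0 else None


def build_cluster(
    seed: MS1Peak,
    candidates: Sequence[MS1Peak],
    scans: ScanTable,
    params: CSAParams,
    file_id: str = "",
) -> Optional[CSACluster]:
    """Correlate candidates against the seed and apply the cluster filters.

    Members are the seed (r = 1) plus candidates whose smoothed EIC
    correlates at ``>= pearson_min`` over the seed's RT window; ``None``
    unless at least ``min_ions`` members span more than ``min_mz_span``
    Da.  The exported spectrum holds each member's 12C m/z at the apex
    height of its own EIC, plus the 13C partner of any member that
    carries one (at its own apex EIC height).
    """
    window = (seed.rt_start, seed.rt_end)
    seed_eic = _member_eic(scans, seed.mz_12C, window, params, seed.peak_id)
    if seed_eic is None:
        return None
    members: list[tuple[MS1Peak, float, float]] = [   # (peak, r, apex height)
        (seed, 1.0, seed_eic.apex_intensity)
    ]
    for cand in candidates:
        cand_eic = _member_eic(scans, cand.mz_12C, window, params, cand.peak_id)
        if cand_eic is None:
            continue
        r = profile_correlation(seed_eic, cand_eic, params.height_fraction)
        if r >= params.pearson_min:
            members.append((cand, r, cand_eic.apex_intensity))
    if len(members) < params.min_ions:
        return None
    mzs = [m[0].mz_12C for m in members]
    if max(mzs) - min(mzs) <= params.min_mz_span:
        return None
    spec_mz: list[float] = []
    spec_int: list[float] = []
    comments: list[str] = []
    for peak, r, apex in members:
        spec_mz.append(peak.mz_12C)
        spec_int.append(apex)
        comments.append(f"{peak.mz_12C:.5f}:r={r:.4f}")
        if peak.mz_13C is not None:
            iso = _member_eic(scans, peak.mz_13C, window, params)
            if iso is not None:
                spec_mz.append(peak.mz_13C)
                spec_int.append(iso.apex_intensity)
    spectrum = FragmentSpectrum(
        np.asarray(spec_mz), np.asarray(spec_int),
        precursor_rt=seed.rt_apex,
        metadata={
            "Name": f"CSA_{file_id or 'file'}_{seed.peak_id}",
            "Retention_time": f"{seed.rt_apex:.4f}",
            "Correlations": "; ".join(comments),
            "Num_12C_ions": str(len(members)),
        },
    )
    return CSACluster(
        seed_peak_id=seed.peak_id,
        member_peak_ids=[m[0].peak_id for m in members],
        member_r={m[0].peak_id: m[1] for m in members},
        rt_apex=seed.rt_apex,
        spectrum=spectrum,
        file_id=file_id,
    )


def map_peaks_to_aligned(
    peaks: Sequence[MS1Peak],
    aligned: pd.DataFrame,
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
) -> dict[int, int]:
    """Map peak ids to aligned-table rows by nearest m/z within tolerances."""
    mapping: dict[int, int] = {}
    amz = aligned["mz"].to_numpy(dtype=float)
    art = aligned["rt"].to_numpy(dtype=float)
    index = aligned.index.to_numpy()
    for peak in peaks:
        ok = (np.abs(amz - peak.mz_12C) <= mz_tol) & (np.abs(art - peak.rt_apex) <= rt_tol)
        if not ok.any():
            continue
        cand = np.where(ok)[0]
        best = cand[np.argmin(np.abs(amz[cand] - peak.mz_12C))]
        mapping[peak.peak_id] = int(index[best])
    return mapping


def deconvolute_file(
    scans: ScanTable,
    peaks: Sequence[MS1Peak],
    params: Optional[CSAParams] = None,
    aligned: Optional[pd.DataFrame] = None,
    file_id: str = "",
) -> list[CSACluster]:
    """Run the full seed-group-correlate-filter loop over one file.

    Deterministic and order-invariant: seeding depends only on
    (height, S/N, peak id).  Every peak ends in at most one cluster; a
    seed that fails to form a cluster stays assigned and yields nothing.
    """
    params = params if params is not None else CSAParams()
    params.validate()
    peak_rows = aligned is not None and len(aligned) > 0
    aligned_map = (
        map_peaks_to_aligned(peaks, aligned) if peak_rows else {}
    )
    assigned: set[int] = set()
    clusters: list[CSACluster] = []
    while True:
        seed = select_seed(peaks, assigned, params)
        if seed is None:
            break
        assigned.add(seed.peak_id)
        candidates = group_candidates(peaks, seed, assigned, params)
        if (
            peak_rows
            and params.intersample_r_min is not None
            and seed.peak_id in aligned_map
        ):
            candidate_rows = {
                c.peak_id: aligned_map[c.peak_id]
                for c in candidates if c.peak_id in aligned_map
            }
            kept = intersample_filter(
                aligned, aligned_map[seed.peak_id], candidate_rows,
                params.intersample_r_min,
            )
            candidates = [
                c for c in candidates
                if c.peak_id not in candidate_rows or c.peak_id in kept
            ]
        cluster = build_cluster(seed, candidates, scans, params, file_id=file_id)
        if cluster is not None:
            assigned.update(cluster.member_peak_ids)
            clusters.append(cluster)
    return clusters


def link_true_positive(
    clusters: Sequence[CSACluster],
    targets: Sequence[dict],
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
) -> list[CSACluster]:
    """Attach target names to clusters matching (m/z, RT) within tolerance.

    Each target is a mapping with ``mz``, ``rt`` and ``name``.  A target
    matching several clusters annotates all of them (with a warning).
    """
    for target in targets:
        matched = []
        for cluster in clusters:
            if abs(cluster.rt_apex - target["rt"]) > rt_tol:
                continue
            if np.any(np.abs(cluster.spectrum.mz - target["mz"]) <= mz_tol):
                matched.append(cluster)
        if len(matched) > 1:
            logger.warning(
                "target %r matches %d clusters", target.get("name"), len(matched))
        for cluster in matched:
            existing = cluster.spectrum.metadata.get("Target")
            name = str(target.get("name", ""))
            cluster.spectrum.metadata["Target"] = (
                f"{existing}; {name}" if existing else name
            )
    return list(clusters)


def clusters_to_spectra(clusters: Sequence[CSACluster]) -> list[FragmentSpectrum]:
    return [c.spectrum for c in clusters]
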