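"""Spectral similarity search engine.

Implements spectrum conditioning (adjacent-fragment resolving, noise
removal), characteristic-marker prefiltering, and the similarity scores
used to rank library hits: cosine similarity over matched fragment pairs,
Shannon spectral entropy with the low-entropy weight transformation,
entropy similarity of the 1:1 merged spectrum, normalized Euclidean mass
error (NEME), and the final score ``cosine * entropy_similarity**2``.

All scores are invariant under positive rescaling of either spectrum's
intensities; normalization happens here, never at parse time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError
from .spectra import FragmentSpectrum

__all__ = [
    "SearchParams",
    "MatchResult",
    "resolve_adjacent",
    "remove_noise",
    "characteristic_markers",
    "prefilter",
    "match_fragments",
    "cosine_similarity",
    "spectral_entropy",
    "weight_transform",
    "entropy_similarity",
    "neme",
    "condition_spectrum",
    "search",
    "summarize_study",
]

logger = logging.getLogger(__name__)

LN4 = math.log(4.0)


@dataclass
class SearchParams:
    """Parameters of spectrum conditioning, prefiltering and scoring.

    ``lib_norm`` selects the denominator convention of the cosine score:
    ``"all"`` (default) lets every library peak contribute to the library
    norm while the experimental norm runs over matched peaks only;
    ``"matched"`` restricts both norms to matched pairs.
    """

    resolution_tol: float = 0.005          # Da; adjacent-fragment merge width
    noise_pct: float = 1.0                 # % of base peak removed as noise
    marker_baseline_pct: float = 10.0      # % of base peak defining markers
    marker_min_match_pct: float = 50.0     # % of markers that must be matched
    fragment_mz_tol: float = 0.01          # Da; fragment pairing tolerance
    precursor_mz_tol: Optional[float] = None  # Da; None disables the gate
    entsim_cutoff: float = 0.75            # minimum entropy similarity of a hit
    neme_max: Optional[float] = None       # Da; None disables the gate
    lib_norm: str = "all"

    def validate(self) -> None:
        if not (0.0 <= self.noise_pct < 100.0):
            raise ValidationError(f"noise_pct must be in [0, 100): {self.noise_pct}")
        if not (0.0 < self.entsim_cutoff <= 1.0):
            raise ValidationError(
                f"entsim_cutoff must be in (0, 1]: {self.entsim_cutoff}")
        if self.resolution_tol < 0 or self.fragment_mz_tol <= 0:
            raise ValidationError("tolerances must be positive")
        if not (0.0 <= self.marker_baseline_pct <= 100.0):
            raise ValidationError(
                f"marker_baseline_pct must be in [0, 100]: {self.marker_baseline_pct}")
        if not (0.0 <= self.marker_min_match_pct <= 100.0):
            raise ValidationError(
                f"marker_min_match_pct must be in [0, 100]: {self.marker_min_match_pct}")
        if self.lib_norm not in ("all", "matched"):
            raise ValidationError(f"lib_norm must be 'all' or 'matched': {self.lib_norm}")

    @classmethod
    def from_dict(cls, d: dict) -> "SearchParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown search parameter(s): {sorted(unknown)}")
        params = cls(**d)
        params.validate()
        return params


@dataclass
class MatchResult:
    """One library hit of a similarity search."""

    library_entry_id: int
    np_matched: int
    cosine: float
    entropy_sim: float
    neme: float
    score: float
    rank: int = 0
    name: str = ""


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

def resolve_adjacent(spectrum: FragmentSpectrum, resolution_tol: float) -> FragmentSpectrum:
    """Merge fragments closer than the instrument resolution.

    Maximal runs of peaks whose consecutive m/z gaps are all
    ``<= resolution_tol`` collapse into one peak with the summed intensity
    and the intensity-weighted mean m/z (plain mean if the run carries no
    intensity).
    """
    if len(spectrum) < 2 or resolution_tol <= 0:
        return spectrum.replace()
    gaps = np.diff(spectrum.mz)
    # run id increments wherever a gap exceeds the tolerance
    run_id = np.concatenate(([0], np.cumsum(gaps > resolution_tol)))
    n_runs = int(run_id[-1]) + 1
    if n_runs == len(spectrum):
        return spectrum.replace()
    inten = np.zeros(n_runs)
    np.add.at(inten, run_id, spectrum.intensity)
    wmz = np.zeros(n_runs)
    np.add.at(wmz, run_id, spectrum.mz * spectrum.intensity)
    counts = np.zeros(n_runs)
    np.add.at(counts, run_id, 1.0)
    smz = np.zeros(n_runs)
    np.add.at(smz, run_id, spectrum.mz)
    with np.errstate(invalid="ignore", divide="ignore"):
        mz = np.where(inten > 0, wmz / inten, smz / counts)
    return spectrum.replace(mz=mz, intensity=inten)


def remove_noise(spectrum: FragmentSpectrum, noise_pct: float) -> FragmentSpectrum:
    """Drop peaks below ``noise_pct`` percent of the base peak."""
    if len(spectrum) == 0:
        raise InputError("cannot denoise an empty spectrum")
    threshold = spectrum.base_peak_intensity * noise_pct / 100.0
    keep = spectrum.intensity >= threshold
    return spectrum.replace(mz=spectrum.mz[keep], intensity=spectrum.intensity[keep])


def condition_spectrum(spectrum: FragmentSpectrum, params: SearchParams) -> FragmentSpectrum:
    """resolve_adjacent followed by remove_noise (the standard pipeline order)."""
    return remove_noise(resolve_adjacent(spectrum, params.resolution_tol), params.noise_pct)


def characteristic_markers(spectrum: FragmentSpectrum, marker_baseline_pct: float) -> np.ndarray:
    """m/z of peaks at or above ``marker_baseline_pct`` % of the base peak."""
    if len(spectrum) == 0:
        return np.empty(0)
    baseline = spectrum.base_peak_intensity * marker_baseline_pct / 100.0
    return spectrum.mz[spectrum.intensity >= baseline].copy()


# ---------------------------------------------------------------------------
# prefilter
# ---------------------------------------------------------------------------

def prefilter(query: FragmentSpectrum, entry, params: SearchParams) -> bool:
    """Cheap gate run before scoring a library entry.

    Passes iff the precursor gate (skipped when either precursor is absent
    or the gate is disabled) and the marker gate (at least
    ``marker_min_match_pct`` % of the entry's characteristic markers have a
    query peak within ``fragment_mz_tol``) both pass.
    """
    if (
        params.precursor_mz_tol is not None
        and query.precursor_mz is not None
        and entry.spectrum.precursor_mz is not None
    ):
        if abs(query.precursor_mz - entry.spectrum.precursor_mz) > params.precursor_mz_tol:
            return False
    markers = np.asarray(entry.markers, dtype=np.float64)
    if markers.size == 0 or params.marker_min_match_pct <= 0:
        return True
    if len(query) == 0:
        return False
    idx = np.searchsorted(query.mz, markers)
    idx_lo = np.clip(idx - 1, 0, len(query) - 1)
    idx_hi = np.clip(idx, 0, len(query) - 1)
    dist = np.minimum(np.abs(query.mz[idx_lo] - markers), np.abs(query.mz[idx_hi] - markers))
    matched = int(np.count_nonzero(dist <= params.fragment_mz_tol))
    return matched * 100.0 >= params.marker_min_match_pct * markers.size


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def match_fragments(
    lib: FragmentSpectrum, exptl: FragmentSpectrum, fragment_mz_tol: float
) -> list[tuple[int, int]]:
    """Greedy nearest-m/z one-to-one pairing of library and experimental peaks.

    Candidate (lib, exptl) index pairs within ``fragment_mz_tol`` are
    accepted in order of ascending mass difference, each peak claimed at
    most once; the result is independent of input peak order. Returns
    pairs sorted by library index; its length is NP.
    """
    if len(lib) == 0 or len(exptl) == 0:
        return []
    lo = np.searchsorted(exptl.mz, lib.mz - fragment_mz_tol, side="left")
    hi = np.searchsorted(exptl.mz, lib.mz + fragment_mz_tol, side="right")
    cand_i, cand_j, cand_d = [], [], []
    for i in range(len(lib)):
        for j in range(int(lo[i]), int(hi[i])):
            cand_i.append(i)
            cand_j.append(j)
            cand_d.append(abs(lib.mz[i] - exptl.mz[j]))
    if not cand_i:
        return []
    order = sorted(range(len(cand_i)), key=lambda k: (cand_d[k], cand_i[k], cand_j[k]))
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = cand_i[k], cand_j[k]
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def cosine_similarity(
    lib: FragmentSpectrum,
    exptl: FragmentSpectrum,
    pairs: Sequence[tuple[int, int]],
    lib_norm: str = "all",
) -> float:
    """Cosine score over matched fragment pairs.

    The numerator runs over matched pairs.  With ``lib_norm="all"`` the
    library norm includes every library peak (unmatched library fragments
    penalize the score) while the experimental norm runs over matched
    peaks only; ``lib_norm="matched"`` restricts both norms to the pairs.
    Returns 0 when there are no pairs.
    """
    if not pairs:
        return 0.0
    li = np.fromiter((p[0] for p in pairs), dtype=np.intp, count=len(pairs))
    ej = np.fromiter((p[1] for p in pairs), dtype=np.intp, count=len(pairs))
    num = float(np.dot(lib.intensity[li], exptl.intensity[ej]))
    if lib_norm == "all":
        lib_sq = float(np.dot(lib.intensity, lib.intensity))
    else:
        lib_sq = float(np.dot(lib.intensity[li], lib.intensity[li]))
    exp_sq = float(np.dot(exptl.intensity[ej], exptl.intensity[ej]))
    denom = math.sqrt(lib_sq * exp_sq)
    if denom == 0.0:
        return 0.0
    return min(num / denom, 1.0)


def spectral_entropy(spectrum: FragmentSpectrum) -> float:
    """Shannon entropy (nats) of the intensity distribution normalized to sum 1."""
    total = spectrum.total_intensity
    if total <= 0:
        raise InputError("spectral entropy is undefined for all-zero intensities")
    p = spectrum.intensity / total
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def weight_transform(spectrum: FragmentSpectrum) -> FragmentSpectrum:
    """Low-entropy intensity re-weighting.

    For a normalized spectrum with entropy ``S``: identity when ``S >= 3``,
    otherwise each intensity is raised to ``w = 0.25 * (1 + S)`` and the
    result re-normalized to sum 1.
    """
    s = spectral_entropy(spectrum)
    norm = spectrum.normalized()
    if s >= 3.0:
        return norm
    w = 0.25 * (1.0 + s)
    weighted = np.power(norm.intensity, w, where=norm.intensity > 0,
                        out=np.zeros_like(norm.intensity))
    return norm.replace(intensity=weighted / weighted.sum())


def entropy_similarity(
    lib: FragmentSpectrum, exptl: FragmentSpectrum, fragment_mz_tol: float
) -> float:
    """Entropy similarity of the 1:1 merged spectrum, clipped to [0, 1].

    Both operands are normalized and weight-transformed; the merged
    spectrum is their union with intensities halved, peaks of the two
    operands within ``fragment_mz_tol`` combined into one merged peak.
    Similarity = ``1 - (2*S_merged - S_lib - S_exptl) / ln 4``.
    """
    if len(lib) == 0 or len(exptl) == 0:
        return 0.0
    if not (lib.is_usable() and exptl.is_usable()):
        return 0.0
    a = weight_transform(lib)
    b = weight_transform(exptl)
    s_a = spectral_entropy(a)
    s_b = spectral_entropy(b)
    pairs = match_fragments(a, b, fragment_mz_tol)
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    merged = [0.5 * a.intensity[i] + 0.5 * b.intensity[j] for i, j in pairs]
    merged.extend(0.5 * a.intensity[i] for i in range(len(a)) if i not in matched_a)
    merged.extend(0.5 * b.intensity[j] for j in range(len(b)) if j not in matched_b)
    p = np.asarray(merged)
    p = p[p > 0]
    s_merged = float(-np.sum(p * np.log(p)))
    sim = 1.0 - (2.0 * s_merged - s_a - s_b) / LN4
    return float(min(max(sim, 0.0), 1.0))


def neme(
    lib: FragmentSpectrum, exptl: FragmentSpectrum, pairs: Sequence[tuple[int, int]]
) -> float:
    """Normalized Euclidean mass error: RMS of matched-pair mass differences (Da)."""
    if not pairs:
        raise InputError("NEME is undefined without matched fragment pairs")
    li = np.fromiter((p[0] for p in pairs), dtype=np.intp, count=len(pairs))
    ej = np.fromiter((p[1] for p in pairs), dtype=np.intp, count=len(pairs))
    diff = lib.mz[li] - exptl.mz[ej]
    return float(math.sqrt(float(np.dot(diff, diff)) / len(pairs)))


# ---------------------------------------------------------------------------
# search and study summary
# ---------------------------------------------------------------------------

def search(
    query: FragmentSpectrum,
    fsdb,
    params: Optional[SearchParams] = None,
    use_prefilter: bool = True,
    condition_query: bool = True,
) -> list[MatchResult]:
    """Rank library entries against one query spectrum.

    The query is conditioned (resolve_adjacent then remove_noise) unless
    ``condition_query`` is False; entries failing the prefilter, the
    entropy-similarity cutoff or the NEME gate are dropped; survivors are
    scored ``cosine * entropy_similarity**2`` and sorted descending by
    score, ties broken by lower NEME then library order.
    """
    params = params if params is not None else fsdb.build_params
    if len(fsdb.entries) == 0:
        raise InputError("cannot search an empty library")
    q = condition_spectrum(query, params) if condition_query else query
    if not q.is_usable():
        return []
    hits: list[MatchResult] = []
    for entry_id, entry in enumerate(fsdb.entries):
        if use_prefilter and not prefilter(q, entry, params):
            continue
        lib = entry.spectrum
        pairs = match_fragments(lib, q, params.fragment_mz_tol)
        if not pairs:
            continue
        ent_sim = entropy_similarity(lib, q, params.fragment_mz_tol)
        if ent_sim < params.entsim_cutoff:
            continue
        mass_err = neme(lib, q, pairs)
        if params.neme_max is not None and mass_err > params.neme_max:
            continue
        cos = cosine_similarity(lib, q, pairs, lib_norm=params.lib_norm)
        hits.append(
            MatchResult(
                library_entry_id=entry_id,
                np_matched=len(pairs),
                cosine=cos,
                entropy_sim=ent_sim,
                neme=mass_err,
                score=cos * ent_sim * ent_sim,
                name=lib.name or entry.source_id,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.neme, h.library_entry_id))
    for rank, hit in enumerate(hits, start=1):
        hit.rank = rank
    return hits


def summarize_study(
    per_sample_results: dict[str, pd.DataFrame],
    aligned: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Annotation frequency and overall median rank across a study.

    ``per_sample_results`` maps sample id to a hit table with columns
    ``row_id`` (aligned-table row), ``compound`` and ``rank``.  The result
    has one row per (row_id, compound) with ``frequency`` = number of
    samples reporting the hit and ``median_rank`` = median of its ranks,
    sorted by frequency descending then median_rank ascending.
    """
    frames = []
    for sample_id, table in per_sample_results.items():
        if table is None or len(table) == 0:
            continue
        sub = table[["row_id", "compound", "rank"]].copy()
        sub["sample"] = sample_id
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["row_id", "compound", "frequency", "median_rank"])
    allhits = pd.concat(frames, ignore_index=True)
    grouped = (
        allhits.groupby(["row_id", "compound"], sort=False)
        .agg(frequency=("sample", "nunique"), median_rank=("rank", "median"))
        .reset_index()
    )
    if aligned is not None and "mz" in aligned.columns:
        grouped = grouped.merge(
            aligned[["mz", "rt"]], left_on="row_id", right_index=True, how="left"
        )
    grouped = grouped.sort_values(
        ["frequency", "median_rank", "row_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return grouped
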