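"""Cross-file spectrum aggregation.

``aggregate_variants`` collapses spectra recurring across many files into
unique variants by greedy single-linkage over the stream ordered by
descending total intensity: a spectrum joins the first variant whose RT
centre is within the window and whose representative is entropy-similar
enough, else it founds a new variant.  ``consensus_from_aligned`` merges
clusters that share aligned-table rows (Tanimoto coefficient) into
batch-consensus spectra of the most common ions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .deconv import CSACluster
from .fsa import entropy_similarity
from .spectra import FragmentSpectrum

__all__ = ["SpectrumVariant", "aggregate_variants", "consensus_from_aligned", "tanimoto"]

logger = logging.getLogger(__name__)


@dataclass
class SpectrumVariant:
    """A recurring spectrum with its detection frequency across files."""

    representative: FragmentSpectrum
    member_refs: list[tuple[str, str]] = field(default_factory=list)
    members: list[FragmentSpectrum] = field(default_factory=list)
    rt_center: float = 0.0

    @property
    def detection_frequency(self) -> int:
        return len({file_id for file_id, _ in self.member_refs})

    @property
    def n_members(self) -> int:
        return len(self.member_refs)


def _spectrum_rt(spec: FragmentSpectrum) -> Optional[float]:
    if spec.precursor_rt is not None:
        return spec.precursor_rt
    rt = spec.metadata.get("Retention_time")
    return float(rt) if rt is not None else None


def aggregate_variants(
    spectra: Sequence[tuple[str, str, FragmentSpectrum]],
    rt_window: float = 0.1,
    entsim_min: float = 0.75,
    fragment_mz_tol: float = 0.01,
) -> list[SpectrumVariant]:
    """Collapse per-file spectra into unique variants.

    ``spectra`` is a sequence of ``(file_id, spectrum_id, spectrum)``;
    every spectrum must carry a retention time (``precursor_rt`` or a
    ``Retention_time`` metadata field).  Spectra are processed in
    descending total-intensity order (ties by file then spectrum id), so
    each variant's representative is its most intense member and the
    result is a partition of the input.
    """
    entries = []
    for file_id, spec_id, spec in spectra:
        rt = _spectrum_rt(spec)
        if rt is None:
            raise ValueError(f"spectrum {file_id}/{spec_id} carries no retention time")
        entries.append((file_id, str(spec_id), spec, rt))
    entries.sort(key=lambda e: (-e[2].total_intensity, e[0], e[1]))
    variants: list[SpectrumVariant] = []
    for file_id, spec_id, spec, rt in entries:
        joined = False
        for variant in variants:
            if abs(rt - variant.rt_center) > rt_window:
                continue
            if entropy_similarity(variant.representative, spec, fragment_mz_tol) >= entsim_min:
                variant.member_refs.append((file_id, spec_id))
                variant.members.append(spec)
                joined = True
                break
        if not joined:
            variants.append(
                SpectrumVariant(representative=spec, member_refs=[(file_id, spec_id)],
                                members=[spec], rt_center=rt)
            )
    return variants


def tanimoto(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B| (0 for two empty sets)."""
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def _connected_groups(sets: list[set], threshold: float) -> list[list[int]]:
    """Transitive closure of the pairwise-Tanimoto-above-threshold relation."""
    n = len(sets)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if tanimoto(sets[i], sets[j]) >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [groups[r] for r in sorted(groups)]


def consensus_from_aligned(
    clusters: Sequence[CSACluster],
    aligned: pd.DataFrame,
    tanimoto_min: float = 0.5,
    quorum: float = 0.5,
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
) -> list[FragmentSpectrum]:
    """Batch-consensus spectra from clusters sharing aligned-table rows.

    Each cluster becomes the set of aligned rows matched by its 12C
    member peaks; cluster pairs with Tanimoto >= ``tanimoto_min`` merge
    transitively; each merged group emits one spectrum holding the rows
    present in at least ``quorum`` of the group's clusters, with the
    median apex height as intensity.  Clusters with no aligned-row
    mapping are excluded with a warning.
    """
    row_sets: list[set] = []
    kept: list[CSACluster] = []
    ion_heights: list[dict[int, float]] = []
    amz = aligned["mz"].to_numpy(dtype=float)
    art = aligned["rt"].to_numpy(dtype=float)
    index = aligned.index.to_numpy()
    for cluster in clusters:
        rows: set[int] = set()
        heights: dict[int, float] = {}
        for mz, inten in zip(cluster.spectrum.mz, cluster.spectrum.intensity):
            ok = (np.abs(amz - mz) <= mz_tol) & (np.abs(art - cluster.rt_apex) <= rt_tol)
            if not ok.any():
                continue
            cand = np.where(ok)[0]
            row = int(index[cand[np.argmin(np.abs(amz[cand] - mz))]])
            rows.add(row)
            heights[row] = float(inten)
        if not rows:
            logger.warning(
                "cluster %s/%d maps to no aligned rows; excluded",
                cluster.file_id, cluster.seed_peak_id)
            continue
        row_sets.append(rows)
        kept.append(cluster)
        ion_heights.append(heights)
    if not kept:
        return []
    consensus: list[FragmentSpectrum] = []
    for group in _connected_groups(row_sets, tanimoto_min):
        counts: dict[int, int] = {}
        for gi in group:
            for row in row_sets[gi]:
                counts[row] = counts.get(row, 0) + 1
        need = quorum * len(group)
        rows = sorted(r for r, c in counts.items() if c >= need)
        if not rows:
            continue
        mzs = [float(aligned.loc[r, "mz"]) for r in rows]
        intens = [
            float(np.median([ion_heights[gi][r] for gi in group if r in ion_heights[gi]]))
            for r in rows
        ]
        rts = [kept[gi].rt_apex for gi in group]
        consensus.append(
            FragmentSpectrum(
                np.asarray(mzs), np.asarray(intens),
                precursor_rt=float(np.median(rts)),
                metadata={
                    "Name": f"Consensus_{kept[group[0]].file_id}_{kept[group[0]].seed_peak_id}",
                    "Clusters": str(len(group)),
                },
            )
        )
    return consensus
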