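"""Core fragmentation-spectrum type.

A :class:`FragmentSpectrum` is an ordered (m/z, intensity) peak list with
optional precursor metadata.  It is the unit of MSP/MGF/FSDB I/O and the
operand of all similarity math.  Intensities are stored raw; normalization
happens inside scoring, never at construction or parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["FragmentSpectrum"]


@dataclass
class FragmentSpectrum:
    """An (m/z, intensity) peak list with optional precursor metadata.

    Invariants enforced at construction:

    * peaks sorted ascending by m/z;
    * exact duplicate m/z values merged (intensities summed);
    * all intensities >= 0 and all m/z > 0.
    """

    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: Optional[float] = None
    precursor_rt: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (np.any(mz <= 0) or np.any(~np.isfinite(mz))):
            raise ValueError("all m/z values must be finite and > 0")
        if inten.size and (np.any(inten < 0) or np.any(~np.isfinite(inten))):
            raise ValueError("all intensities must be finite and >= 0")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        if mz.size > 1 and np.any(np.diff(mz) == 0.0):
            # merge exact duplicates: unique m/z with summed intensity
            umz, inverse = np.unique(mz, return_inverse=True)
            uint = np.zeros_like(umz)
            np.add.at(uint, inverse, inten)
            mz, inten = umz, uint
        self.mz = mz
        self.intensity = inten

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def n_peaks(self) -> int:
        return len(self)

    @property
    def total_intensity(self) -> float:
        return float(self.intensity.sum())

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if len(self) else 0.0

    def is_usable(self) -> bool:
        """At least one strictly positive intensity."""
        return len(self) > 0 and bool(np.any(self.intensity > 0))

    # -- derived spectra ---------------------------------------------------

    def normalized(self) -> "FragmentSpectrum":
        """Intensities rescaled to sum to 1 (peaks with zero total rejected)."""
        total = self.total_intensity
        if total <= 0:
            raise ValueError("cannot normalize a spectrum with zero total intensity")
        return self.replace(intensity=self.intensity / total)

    def scaled(self, factor: float) -> "FragmentSpectrum":
        return self.replace(intensity=self.intensity * float(factor))

    def replace(self, **kwargs) -> "FragmentSpectrum":
        """Copy with selected fields replaced (arrays copied)."""
        out = dict(
            mz=self.mz.copy(),
            intensity=self.intensity.copy(),
            precursor_mz=self.precursor_mz,
            precursor_rt=self.precursor_rt,
            metadata=dict(self.metadata),
        )
        out.update(kwargs)
        return FragmentSpectrum(**out)

    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))

    @property
    def name(self) -> str:
        return str(self.metadata.get("Name", ""))
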