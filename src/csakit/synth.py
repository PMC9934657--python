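"""Ground-truthed synthetic fixtures for every pipeline stage.

Generates centroided MS1/MS2 scan tables, matching peak lists, aligned
peak-height tables and reference spectral libraries from declared
compounds, fully reproducible from a seed.  Elution profiles are Gaussian
with an optional exponential tailing factor; noise is log-normal
multiplicative on intensities plus random singleton chromatographic
peaks.  Every emitted signal is attributed to exactly one compound or to
noise in the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ms1 import MS1Peak, Scan, ScanTable
from .spectra import FragmentSpectrum

__all__ = [
    "SyntheticCompound",
    "GroundTruth",
    "gen_scan_table",
    "gen_msms_fixture",
    "gen_library",
    "random_compounds",
    "C13_OFFSET",
]

logger = logging.getLogger(__name__)

C13_OFFSET = 1.00336   # Da, singly-charged 13C isotopologue spacing


@dataclass
class SyntheticCompound:
    """A compound emitting several co-eluting ions."""

    name: str
    ions: list[tuple[float, float, bool]]   # (mz, relative_abundance, has_13C)
    rt_apex: float                          # minutes
    peak_sigma: float = 0.04                # minutes
    max_height: float = 1e6
    tailing: float = 0.0                    # 0 = symmetric Gaussian
    fragments: list[tuple[float, float]] = field(default_factory=list)  # MS2 (mz, rel)
    noise_fragments: list[tuple[float, float]] = field(default_factory=list)  # RT-flat

    def __post_init__(self) -> None:
        mzs = [ion[0] for ion in self.ions]
        if len(set(mzs)) != len(mzs):
            raise ValueError(f"compound {self.name}: ion m/z values must be distinct")
        for _, rel, _ in self.ions:
            if not (0.0 < rel <= 1.0):
                raise ValueError(f"compound {self.name}: abundances must be in (0, 1]")

    @property
    def precursor_mz(self) -> float:
        return max(self.ions, key=lambda ion: ion[1])[0]


@dataclass
class GroundTruth:
    """Attribution of every synthetic signal."""

    compound_peaks: dict[str, list[int]] = field(default_factory=dict)
    noise_peak_ids: list[int] = field(default_factory=list)
    compound_fragments: dict[str, list[float]] = field(default_factory=dict)
    noise_fragment_mz: dict[str, list[float]] = field(default_factory=dict)

    def peak_to_compound(self) -> dict[int, str]:
        return {
            pid: name for name, pids in self.compound_peaks.items() for pid in pids
        }


def _profile(rt: np.ndarray, apex_rt: float, sigma: float, tailing: float) -> np.ndarray:
    """Gaussian elution profile, optionally convolved tail (EMG-like)."""
    z = (rt - apex_rt) / sigma
    base = np.exp(-0.5 * z * z)
    if tailing > 0:
        tail = np.where(rt > apex_rt, np.exp(-(rt - apex_rt) / (tailing * sigma)), 1.0)
        base = np.maximum(base, 0.6 * np.exp(-0.5 * np.clip(z, None, 0) ** 2) * tail)
    return base


def gen_scan_table(
    compounds: Sequence[SyntheticCompound],
    rt_range: tuple[float, float] = (0.0, 10.0),
    scan_interval: float = 0.005,
    noise_peaks: int = 0,
    intensity_noise: float = 0.0,         # sigma of log-normal multiplicative noise
    c13_fraction: float = 0.05,
    peak_snr: float = 100.0,
    noise_snr: float = 20.0,
    noise_rt_min_sep: float = 0.0,
    seed: int = 0,
    min_signal: float = 1.0,
) -> tuple[ScanTable, list[MS1Peak], GroundTruth]:
    """MS1 scans + peak list + ground truth for the declared compounds.

    Every 12C ion (and injected noise singleton) yields a peak-list row
    with apex/boundaries/height/S/N derived from the injected truth; 13C
    partner signals are emitted at ``c13_fraction`` of the 12C profile for
    ions flagged ``has_13C``.
    """
    rng = np.random.default_rng(seed)
    for compound in compounds:
        if not (rt_range[0] < compound.rt_apex < rt_range[1]):
            raise ValueError(
                f"compound {compound.name}: rt_apex outside rt_range {rt_range}")
    rts = np.arange(rt_range[0], rt_range[1] + 0.5 * scan_interval, scan_interval)
    truth = GroundTruth()
    # signal registry: (mz, apex_height, rt_apex, sigma, tailing, has_13C, owner)
    signals: list[tuple] = []
    for compound in compounds:
        truth.compound_peaks[compound.name] = []
        for mz, rel, has_13c in compound.ions:
            signals.append((mz, compound.max_height * rel, compound.rt_apex,
                            compound.peak_sigma, compound.tailing, has_13c,
                            compound.name))
    margin = 0.3
    noise_apices: list[float] = []
    for _ in range(noise_peaks):
        mz = float(rng.uniform(70.0, 900.0))
        # optional minimum spacing between noise apices: exactly co-eluting
        # noise singletons are indistinguishable from real ion clusters
        for _attempt in range(1000):
            apex = float(rng.uniform(rt_range[0] + margin, rt_range[1] - margin))
            if noise_rt_min_sep <= 0 or all(
                abs(apex - other) >= noise_rt_min_sep for other in noise_apices
            ):
                break
        noise_apices.append(apex)
        sigma = float(rng.uniform(0.02, 0.06))
        height = float(rng.lognormal(mean=np.log(2e5), sigma=0.8))
        signals.append((mz, height, apex, sigma, 0.0, False, None))

    profiles = []
    for mz, height, apex, sigma, tailing, has_13c, owner in signals:
        prof = height * _profile(rts, apex, sigma, tailing)
        if intensity_noise > 0:
            prof = prof * rng.lognormal(mean=0.0, sigma=intensity_noise, size=prof.size)
        profiles.append(prof)

    scans: list[Scan] = []
    for si, rt in enumerate(rts):
        mz_list: list[float] = []
        int_list: list[float] = []
        for (mz, _h, _a, _s, _t, has_13c, _o), prof in zip(signals, profiles):
            value = prof[si]
            if value >= min_signal:
                mz_list.append(mz)
                int_list.append(float(value))
                if has_13c:
                    iso = value * c13_fraction
                    if iso >= min_signal:
                        mz_list.append(mz + C13_OFFSET)
                        int_list.append(float(iso))
        order = np.argsort(mz_list)
        scans.append(Scan(rt=float(rt), ms_level=1,
                          mz=np.asarray(mz_list)[order],
                          intensity=np.asarray(int_list)[order]))

    peaks: list[MS1Peak] = []
    for pid, ((mz, height, apex, sigma, _t, has_13c, owner), prof) in enumerate(
        zip(signals, profiles)
    ):
        start = max(rt_range[0], apex - 3.0 * sigma)
        end = min(rt_range[1], apex + 3.0 * sigma)
        peak = MS1Peak(
            peak_id=pid, mz_12C=mz, mz_13C=mz + C13_OFFSET if has_13c else None,
            rt_apex=apex, rt_start=start, rt_end=end,
            height=float(prof.max()), snr=peak_snr if owner else noise_snr,
        )
        peaks.append(peak)
        if owner is None:
            truth.noise_peak_ids.append(pid)
        else:
            truth.compound_peaks[owner].append(pid)
    return ScanTable(scans=scans), peaks, truth


def gen_msms_fixture(
    compounds: Sequence[SyntheticCompound],
    acquisition: str = "DDA",
    rt_range: tuple[float, float] = (0.0, 10.0),
    scan_interval: float = 0.01,
    ms2_per_cycle: int = 1,
    isolation_width: float = 25.0,
    seed: int = 0,
    min_signal: float = 1.0,
) -> tuple[ScanTable, list[MS1Peak], GroundTruth]:
    """Interleaved MS1/MS2 fixture for DDA or DIA extraction.

    Fragment elution co-varies with the precursor; fragments listed in
    ``noise_fragments`` are RT-flat at a constant intensity.  DDA MS2
    scans carry the precursor m/z; DIA MS2 scans carry an isolation
    window covering the precursor.
    """
    if acquisition not in ("DDA", "DIA"):
        raise ValueError("acquisition must be 'DDA' or 'DIA'")
    rng = np.random.default_rng(seed)
    table, peaks, truth = gen_scan_table(
        compounds, rt_range=rt_range, scan_interval=scan_interval,
        seed=seed, min_signal=min_signal,
    )
    for compound in compounds:
        truth.compound_fragments[compound.name] = [f[0] for f in compound.fragments]
        truth.noise_fragment_mz[compound.name] = [f[0] for f in compound.noise_fragments]
    all_scans: list[Scan] = []
    ms2_offset = scan_interval / (2.0 * max(ms2_per_cycle * max(len(compounds), 1), 1))
    for scan in table.scans:
        all_scans.append(scan)
        slot = 0
        for compound in compounds:
            prof = _profile(np.asarray([scan.rt]), compound.rt_apex,
                            compound.peak_sigma, compound.tailing)[0]
            precursor_height = compound.max_height * prof
            if acquisition == "DDA" and precursor_height < 100.0 * min_signal:
                continue   # DDA only triggers on sufficiently intense precursors
            mz_list: list[float] = []
            int_list: list[float] = []
            for fmz, rel in compound.fragments:
                value = precursor_height * rel
                if value >= min_signal:
                    mz_list.append(fmz)
                    int_list.append(float(value))
            for fmz, rel in compound.noise_fragments:
                mz_list.append(fmz)
                int_list.append(float(compound.max_height * rel))   # RT-flat
            if not mz_list:
                continue
            for rep in range(ms2_per_cycle):
                slot += 1
                order = np.argsort(mz_list)
                rt2 = scan.rt + slot * ms2_offset
                if acquisition == "DDA":
                    all_scans.append(Scan(
                        rt=rt2, ms_level=2,
                        mz=np.asarray(mz_list)[order],
                        intensity=np.asarray(int_list)[order] * (1.0 + 0.05 * rep),
                        precursor_mz=compound.precursor_mz))
                else:
                    target = compound.precursor_mz
                    window = (target - isolation_width / 2, target + isolation_width / 2)
                    all_scans.append(Scan(
                        rt=rt2, ms_level=2,
                        mz=np.asarray(mz_list)[order],
                        intensity=np.asarray(int_list)[order],
                        isolation_window=window))
    all_scans.sort(key=lambda s: s.rt)
    return ScanTable(scans=all_scans), peaks, truth


def gen_library(
    compounds: Sequence[SyntheticCompound],
    mass_jitter: float = 0.0,
    intensity_jitter: float = 0.0,
    seed: int = 0,
    use_fragments: bool = False,
) -> list[FragmentSpectrum]:
    """Reference spectra per compound, optionally mass/intensity perturbed.

    By default the spectrum holds the compound's MS1 ions (matching what
    deconvolution exports); ``use_fragments`` switches to the MS2
    fragment list.
    """
    rng = np.random.default_rng(seed)
    out: list[FragmentSpectrum] = []
    for compound in compounds:
        if use_fragments:
            source = [(mz, rel) for mz, rel in compound.fragments]
        else:
            source = [(mz, rel) for mz, rel, _ in compound.ions]
        mz = np.asarray([s[0] for s in source], dtype=float)
        inten = np.asarray([s[1] for s in source], dtype=float) * 1000.0
        if mass_jitter > 0:
            mz = mz + rng.normal(0.0, mass_jitter, size=mz.size)
        if intensity_jitter > 0:
            inten = inten * rng.lognormal(0.0, intensity_jitter, size=inten.size)
        out.append(
            FragmentSpectrum(
                mz, inten,
                precursor_mz=compound.precursor_mz,
                precursor_rt=compound.rt_apex,
                metadata={"Name": compound.name},
            )
        )
    return out


def random_compounds(
    n: int,
    seed: int = 0,
    rt_range: tuple[float, float] = (0.5, 9.5),
    min_ions: int = 3,
    max_ions: int = 8,
    min_rt_separation: float = 0.1,
    min_span: float = 10.0,
) -> list[SyntheticCompound]:
    """Well-separated random compounds with guaranteed m/z span > min_span."""
    rng = np.random.default_rng(seed)
    lo, hi = rt_range
    usable = hi - lo
    if n * min_rt_separation > usable:
        raise ValueError("rt_range too narrow for the requested separation")
    # evenly spaced apices with random offsets keep pairwise separation
    base = np.linspace(lo, hi, n, endpoint=False)
    jitter = rng.uniform(0.0, max((usable / n - min_rt_separation) * 0.9, 0.0), size=n)
    apices = base + jitter
    out: list[SyntheticCompound] = []
    for i in range(n):
        n_ions = int(rng.integers(min_ions, max_ions + 1))
        first = float(rng.uniform(80.0, 500.0))
        mzs = {first, first + min_span + float(rng.uniform(0.5, 200.0))}
        while len(mzs) < n_ions:
            mzs.add(first + float(rng.uniform(-40.0, 300.0)))
        ions = [
            (float(mz), float(rng.uniform(0.2, 1.0)), bool(rng.random() < 0.5))
            for mz in sorted(mzs) if mz > 50.0
        ]
        # one ion at full abundance so the peak list has a clear seed
        k = int(rng.integers(0, len(ions)))
        ions[k] = (ions[k][0], 1.0, ions[k][2])
        out.append(
            SyntheticCompound(
                name=f"compound_{i:03d}", ions=ions, rt_apex=float(apices[i]),
                peak_sigma=float(rng.uniform(0.03, 0.05)),
                max_height=float(rng.uniform(5e5, 5e6)),
            )
        )
    return out
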