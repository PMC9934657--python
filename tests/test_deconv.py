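"""Composite-spectra deconvolution: stages, filters and recovery."""

import numpy as np
import pandas as pd
import pytest

from csakit.deconv import (
    CSAParams,
    build_cluster,
    deconvolute_file,
    group_candidates,
    intersample_filter,
    link_true_positive,
    profile_correlation,
    select_seed,
)
from csakit.errors import ContractError
from csakit.ms1 import EIC, MS1Peak
from csakit.synth import SyntheticCompound, gen_scan_table, random_compounds


def peak(pid, height, snr=10.0, rt=1.0, mz=300.0):
    return MS1Peak(peak_id=pid, mz_12C=mz, rt_apex=rt, rt_start=rt - 0.1,
                   rt_end=rt + 0.1, height=height, snr=snr)


def smoothed_gaussian(apex_rt, sigma=0.05, n=100, window=(0.8, 1.2), scale=1.0):
    grid = np.linspace(*window, n)
    return EIC(None, grid, scale * np.exp(-0.5 * ((grid - apex_rt) / sigma) ** 2),
               smoothed=True)


class TestSelectSeed:
    def test_most_intense_wins(self):
        peaks = [peak(0, 10), peak(1, 5), peak(2, 3)]
        assert select_seed(peaks, set(), CSAParams()).peak_id == 0

    def test_assigned_skipped(self):
        peaks = [peak(0, 10), peak(1, 5)]
        assert select_seed(peaks, {0}, CSAParams()).peak_id == 1

    def test_snr_gate_exhausts(self):
        peaks = [peak(0, 10, snr=1.0)]
        assert select_seed(peaks, set(), CSAParams(seed_snr_min=5.0)) is None

    def test_tie_broken_by_lower_id(self):
        peaks = [peak(1, 10), peak(0, 10)]
        assert select_seed(peaks, set(), CSAParams()).peak_id == 0


class TestGroupCandidates:
    def test_window_grouping(self):
        seed = peak(0, 10, rt=1.0)
        peaks = [seed, peak(1, 5, rt=1.005), peak(2, 5, rt=0.995), peak(3, 5, rt=1.009),
                 peak(4, 5, rt=1.02), peak(5, 5, rt=0.9)]
        got = group_candidates(peaks, seed, set(), CSAParams(rt_group_window=0.01))
        assert [p.peak_id for p in got] == [1, 2, 3]

    def test_empty_neighborhood(self):
        seed = peak(0, 10, rt=1.0)
        assert group_candidates([seed, peak(1, 5, rt=2.0)], seed, set(), CSAParams()) == []

    def test_boundary_included(self):
        seed = peak(0, 10, rt=1.0)
        exactly = peak(1, 5, rt=1.01)
        got = group_candidates([seed, exactly], seed, set(), CSAParams(rt_group_window=0.01))
        assert [p.peak_id for p in got] == [1]


class TestProfileCorrelation:
    def test_identical_is_one(self):
        a = smoothed_gaussian(1.0)
        assert profile_correlation(a, a) == pytest.approx(1.0)

    def test_scaled_copy_is_one(self):
        a = smoothed_gaussian(1.0)
        b = smoothed_gaussian(1.0, scale=3.0)
        assert profile_correlation(a, b) == pytest.approx(1.0)

    def test_four_sigma_offset_below_threshold(self):
        a = smoothed_gaussian(0.95, sigma=0.05)
        b = smoothed_gaussian(1.15, sigma=0.05)   # 4 sigma apart
        assert profile_correlation(a, b) < 0.98

    def test_grid_mismatch_raises(self):
        a = smoothed_gaussian(1.0, window=(0.8, 1.2))
        b = smoothed_gaussian(1.0, window=(0.7, 1.2))
        with pytest.raises(ContractError):
            profile_correlation(a, b)

    def test_unsmoothed_raises(self):
        a = smoothed_gaussian(1.0)
        raw = EIC(None, a.rt_grid, a.intensities, smoothed=False)
        with pytest.raises(ContractError):
            profile_correlation(raw, a)

    def test_too_few_overlap_points(self):
        a = smoothed_gaussian(0.85, sigma=0.01)
        b = smoothed_gaussian(1.15, sigma=0.01)
        assert profile_correlation(a, b) == -1.0


class TestIntersampleFilter:
    def _aligned(self, rows):
        table = pd.DataFrame(rows)
        table.insert(0, "mz", np.arange(len(rows)) + 100.0)
        table.insert(1, "rt", 1.0)
        return table

    def test_identical_vector_retained(self):
        v = {f"s{i}": float(i + 1) for i in range(10)}
        aligned = self._aligned([v, dict(v)])
        assert intersample_filter(aligned, 0, {1: 1}, 0.5) == {1}

    def test_permuted_vector_rejected(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 100, size=200)
        shuffled = rng.permutation(base)
        aligned = self._aligned([
            {f"s{i}": float(v) for i, v in enumerate(base)},
            {f"s{i}": float(v) for i, v in enumerate(shuffled)},
        ])
        assert intersample_filter(aligned, 0, {1: 1}, 0.5) == set()

    def test_few_shared_samples_retained_by_default(self):
        aligned = self._aligned([
            {"s0": 1.0, "s1": 2.0, "s2": 3.0, "s3": 0.0, "s4": 0.0},
            {"s0": 3.0, "s1": 2.0, "s2": 1.0, "s3": 0.0, "s4": 0.0},
        ])
        assert intersample_filter(aligned, 0, {1: 1}, 0.99) == {1}


class TestBuildCluster:
    def _compound(self, mzs, rt=2.0, name="c"):
        return SyntheticCompound(name=name, ions=[(mz, 1.0 - 0.1 * i, False)
                                                  for i, mz in enumerate(mzs)],
                                 rt_apex=rt, peak_sigma=0.05, max_height=1e6)

    def test_five_coeluting_ions(self):
        comp = self._compound([150.0, 210.0, 260.0, 310.0, 380.0])
        table, peaks, _ = gen_scan_table([comp], rt_range=(0.0, 4.0))
        seed = max(peaks, key=lambda p: p.height)
        others = [p for p in peaks if p.peak_id != seed.peak_id]
        cluster = build_cluster(seed, others, table, CSAParams())
        assert cluster is not None
        assert sorted(cluster.member_peak_ids) == sorted(p.peak_id for p in peaks)
        assert cluster.member_r[seed.peak_id] == 1.0

    def test_small_span_rejected(self):
        comp = self._compound([300.0, 305.0])   # span 5 < 8
        table, peaks, _ = gen_scan_table([comp], rt_range=(0.0, 4.0))
        seed = max(peaks, key=lambda p: p.height)
        others = [p for p in peaks if p.peak_id != seed.peak_id]
        assert build_cluster(seed, others, table, CSAParams()) is None

    def test_isotopologue_only_partner_rejected(self):
        # a seed whose only companion signal is its own 13C partner
        comp = SyntheticCompound(name="iso", ions=[(300.0, 1.0, True)], rt_apex=2.0,
                                 peak_sigma=0.05, max_height=1e6)
        table, peaks, _ = gen_scan_table([comp], rt_range=(0.0, 4.0))
        assert build_cluster(peaks[0], [], table, CSAParams()) is None

    def test_13c_streamlined_into_spectrum(self):
        comp = SyntheticCompound(
            name="c13", ions=[(150.0, 1.0, True), (250.0, 0.8, False)],
            rt_apex=2.0, peak_sigma=0.05, max_height=1e6)
        table, peaks, _ = gen_scan_table([comp], rt_range=(0.0, 4.0), c13_fraction=0.1)
        seed = max(peaks, key=lambda p: p.height)
        others = [p for p in peaks if p.peak_id != seed.peak_id]
        cluster = build_cluster(seed, others, table, CSAParams())
        assert cluster is not None
        # spectrum holds both 12C ions plus the 13C partner of the first
        assert len(cluster.spectrum) == 3
        assert np.any(np.abs(cluster.spectrum.mz - 151.00336) < 1e-6)
        # but the 13C ion does not count as a member
        assert len(cluster.member_peak_ids) == 2


class TestDeconvoluteFile:
    def test_three_disjoint_compounds_recovered(self):
        compounds = random_compounds(3, seed=5)
        table, peaks, truth = gen_scan_table(compounds, seed=5)
        clusters = deconvolute_file(table, peaks)
        assert len(clusters) == 3
        got = sorted(sorted(c.member_peak_ids) for c in clusters)
        want = sorted(sorted(v) for v in truth.compound_peaks.values())
        assert got == want

    def test_singletons_yield_nothing(self):
        compounds = [
            SyntheticCompound(name=f"s{i}", ions=[(200.0 + 50 * i, 1.0, False)],
                              rt_apex=1.0 + i, peak_sigma=0.04, max_height=1e6)
            for i in range(4)
        ]
        table, peaks, _ = gen_scan_table(compounds, rt_range=(0.0, 6.0))
        assert deconvolute_file(table, peaks) == []

    def test_deterministic_and_idempotent(self):
        compounds = random_compounds(4, seed=9)
        table, peaks, _ = gen_scan_table(compounds, seed=9)
        a = deconvolute_file(table, peaks)
        b = deconvolute_file(table, peaks)
        assert [c.member_peak_ids for c in a] == [c.member_peak_ids for c in b]
        assert [c.seed_peak_id for c in a] == [c.seed_peak_id for c in b]

    def test_order_invariance(self, rng):
        compounds = random_compounds(4, seed=11)
        table, peaks, _ = gen_scan_table(compounds, seed=11)
        shuffled = list(peaks)
        rng.shuffle(shuffled)
        a = deconvolute_file(table, peaks)
        b = deconvolute_file(table, shuffled)
        assert sorted(map(sorted, (c.member_peak_ids for c in a))) == \
            sorted(map(sorted, (c.member_peak_ids for c in b)))

    def test_disjoint_membership(self):
        compounds = random_compounds(6, seed=13)
        table, peaks, _ = gen_scan_table(compounds, noise_peaks=30, seed=13)
        clusters = deconvolute_file(table, peaks)
        seen: set[int] = set()
        for cluster in clusters:
            members = set(cluster.member_peak_ids)
            assert not (members & seen)
            seen |= members

    def test_threshold_monotonicity(self):
        compounds = random_compounds(4, seed=17)
        table, peaks, _ = gen_scan_table(compounds, intensity_noise=0.05, seed=17)
        loose = deconvolute_file(table, peaks, params=CSAParams(pearson_min=0.90))
        strict = deconvolute_file(table, peaks, params=CSAParams(pearson_min=0.995))
        loose_members = {pid for c in loose for pid in c.member_peak_ids}
        strict_members = {pid for c in strict for pid in c.member_peak_ids}
        assert strict_members <= loose_members


class TestLinkTruePositive:
    def _clusters(self):
        compounds = random_compounds(2, seed=21)
        table, peaks, truth = gen_scan_table(compounds, seed=21)
        return deconvolute_file(table, peaks), compounds

    def test_matching_target_annotated(self):
        clusters, compounds = self._clusters()
        target_mz = compounds[0].ions[0][0]
        targets = [{"mz": target_mz, "rt": compounds[0].rt_apex, "name": "TargetA"}]
        link_true_positive(clusters, targets)
        annotated = [c for c in clusters if "Target" in c.spectrum.metadata]
        assert len(annotated) == 1
        assert annotated[0].spectrum.metadata["Target"] == "TargetA"

    def test_rt_mismatch_not_annotated(self):
        clusters, compounds = self._clusters()
        targets = [{"mz": compounds[0].ions[0][0],
                    "rt": compounds[0].rt_apex + 0.5, "name": "WrongRT"}]
        link_true_positive(clusters, targets, rt_tol=0.1)
        assert all("Target" not in c.spectrum.metadata for c in clusters)
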