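"""Scoring-engine unit and property tests against the naive oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csakit.errors import InputError
from csakit.fsa import (
    SearchParams,
    characteristic_markers,
    condition_spectrum,
    cosine_similarity,
    entropy_similarity,
    match_fragments,
    neme,
    prefilter,
    remove_noise,
    resolve_adjacent,
    search,
    spectral_entropy,
    summarize_study,
    weight_transform,
)
from csakit.spectra import FragmentSpectrum
from csakit.spectra_io import build_fsdb

from conftest import make_random_spectrum
from oracles import (
    naive_cosine,
    naive_entropy,
    naive_entropy_similarity,
    naive_neme,
    naive_pairs,
)


def spec(mz, intensity, **kw):
    return FragmentSpectrum(np.asarray(mz, float), np.asarray(intensity, float), **kw)


# ---------------------------------------------------------------------------
# conditioning
# ---------------------------------------------------------------------------

class TestResolveAdjacent:
    def test_weighted_mean_merge(self):
        s = resolve_adjacent(spec([100.000, 100.005], [2.0, 1.0]), 0.01)
        assert len(s) == 1
        assert s.mz[0] == pytest.approx((2 * 100.000 + 1 * 100.005) / 3, abs=1e-9)
        assert s.intensity[0] == pytest.approx(3.0)

    def test_gaps_above_tol_unchanged(self):
        s0 = spec([100.0, 100.05, 100.2], [1, 2, 3])
        s = resolve_adjacent(s0, 0.01)
        np.testing.assert_allclose(s.mz, s0.mz)
        np.testing.assert_allclose(s.intensity, s0.intensity)

    def test_chained_run_merges_fully(self):
        s = resolve_adjacent(spec([100.0, 100.008, 100.016], [1, 1, 1]), 0.01)
        assert len(s) == 1
        assert s.intensity[0] == pytest.approx(3.0)

    def test_total_intensity_conserved(self, rng):
        s0 = make_random_spectrum(rng, n_peaks=30, mz_range=(100.0, 101.0))
        s = resolve_adjacent(s0, 0.05)
        assert s.total_intensity == pytest.approx(s0.total_intensity)


class TestRemoveNoise:
    def test_one_percent_default(self):
        s = remove_noise(spec([100, 200], [1000.0, 5.0]), 1.0)
        assert len(s) == 1 and s.mz[0] == 100

    def test_all_above_threshold_identity(self):
        s0 = spec([100, 200], [1000.0, 500.0])
        assert len(remove_noise(s0, 1.0)) == 2

    def test_single_peak_survives(self):
        assert len(remove_noise(spec([100], [3.0]), 99.0)) == 1

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            remove_noise(spec([], []), 1.0)


class TestMarkers:
    def test_baseline_zero_keeps_all(self):
        s = spec([1, 2, 3], [100, 40, 5])
        assert len(characteristic_markers(s, 0.0)) == 3

    def test_baseline_100_keeps_base_peak(self):
        s = spec([1, 2, 3], [100, 40, 5])
        assert list(characteristic_markers(s, 100.0)) == [1.0]

    def test_baseline_10(self):
        s = spec([1, 2, 3], [100, 40, 5])
        assert len(characteristic_markers(s, 10.0)) == 2


# ---------------------------------------------------------------------------
# matching and scores
# ---------------------------------------------------------------------------

class TestMatchFragments:
    def test_identical_spectra_full_match(self, random_spectrum):
        pairs = match_fragments(random_spectrum, random_spectrum, 0.01)
        assert len(pairs) == len(random_spectrum)
        assert pairs == [(i, i) for i in range(len(random_spectrum))]

    def test_disjoint_no_match(self):
        assert match_fragments(spec([100], [1]), spec([200], [1]), 0.01) == []

    def test_nearest_wins_other_available(self):
        lib = spec([100.000, 100.009], [1, 1])
        exptl = spec([100.001, 100.006], [1, 1])
        pairs = match_fragments(lib, exptl, 0.01)
        # 100.000<->100.001 is the globally closest; 100.009 then claims 100.006
        assert pairs == [(0, 0), (1, 1)]

    def test_matches_oracle(self, rng):
        for _ in range(50):
            a = make_random_spectrum(rng, mz_range=(100.0, 100.5))
            b = make_random_spectrum(rng, mz_range=(100.0, 100.5))
            assert match_fragments(a, b, 0.05) == naive_pairs(
                a.mz.tolist(), b.mz.tolist(), 0.05)


class TestCosine:
    def test_identical_is_one(self, random_spectrum):
        pairs = match_fragments(random_spectrum, random_spectrum, 0.01)
        assert cosine_similarity(random_spectrum, random_spectrum, pairs) == pytest.approx(1.0)

    def test_direct_arithmetic(self):
        lib = spec([100, 200], [1.0, 1.0])
        exptl = spec([100, 200], [1.0, 0.5])
        pairs = match_fragments(lib, exptl, 0.01)
        assert cosine_similarity(lib, exptl, pairs) == pytest.approx(
            1.5 / math.sqrt(2 * 1.25), abs=1e-12)

    def test_scale_invariance(self, random_spectrum):
        pairs = match_fragments(random_spectrum, random_spectrum, 0.01)
        scaled = random_spectrum.scaled(37.0)
        assert cosine_similarity(random_spectrum, scaled, pairs) == pytest.approx(1.0)


class TestEntropy:
    def test_single_peak_zero(self):
        assert spectral_entropy(spec([100], [123.0])) == 0.0

    @pytest.mark.parametrize("n", [2, 5, 17])
    def test_equal_peaks_ln_n(self, n):
        s = spec(np.arange(n) + 100.0, np.ones(n))
        assert spectral_entropy(s) == pytest.approx(math.log(n), abs=1e-12)

    def test_three_one(self):
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert spectral_entropy(spec([1, 2], [3.0, 1.0])) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_raises(self):
        with pytest.raises(InputError):
            spectral_entropy(spec([1, 2], [0.0, 0.0]))


class TestWeightTransform:
    def test_high_entropy_identity(self):
        n = 30
        s = spec(np.arange(n) + 100.0, np.ones(n))   # entropy ln 30 > 3
        t = weight_transform(s)
        np.testing.assert_allclose(t.intensity, np.full(n, 1.0 / n), atol=1e-12)

    def test_single_peak(self):
        t = weight_transform(spec([100], [5.0]))
        assert t.intensity[0] == pytest.approx(1.0)

    def test_two_peak_arithmetic(self):
        s = spec([100, 200], [0.75, 0.25])
        entropy = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        w = 0.25 * (1 + entropy)
        expected = np.array([0.75**w, 0.25**w])
        expected /= expected.sum()
        np.testing.assert_allclose(weight_transform(s).intensity, expected, atol=1e-12)


class TestEntropySimilarity:
    def test_identical_is_one(self, random_spectrum):
        assert entropy_similarity(random_spectrum, random_spectrum, 0.01) == pytest.approx(1.0)

    def test_disjoint_single_peaks_zero(self):
        assert entropy_similarity(spec([100], [1]), spec([500], [1]), 0.01) == pytest.approx(0.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            a = make_random_spectrum(rng, n_peaks=10)
            b = make_random_spectrum(rng, n_peaks=10)
            expected = naive_entropy_similarity(
                (a.mz.tolist(), a.intensity.tolist()),
                (b.mz.tolist(), b.intensity.tolist()), 0.01)
            assert entropy_similarity(a, b, 0.01) == pytest.approx(expected, abs=1e-10)


class TestNeme:
    def test_exact_match_zero(self, random_spectrum):
        pairs = match_fragments(random_spectrum, random_spectrum, 0.01)
        assert neme(random_spectrum, random_spectrum, pairs) == 0.0

    def test_single_pair(self):
        lib, exptl = spec([100.002], [1]), spec([100.000], [1])
        assert neme(lib, exptl, [(0, 0)]) == pytest.approx(0.002, abs=1e-12)

    def test_two_errors(self):
        lib = spec([100.003, 200.004], [1, 1])
        exptl = spec([100.000, 200.000], [1, 1])
        pairs = match_fragments(lib, exptl, 0.01)
        assert neme(lib, exptl, pairs) == pytest.approx(math.sqrt(12.5e-6), abs=1e-12)

    def test_no_pairs_raises(self):
        with pytest.raises(InputError):
            neme(spec([100], [1]), spec([200], [1]), [])


# ---------------------------------------------------------------------------
# hypothesis properties
# ---------------------------------------------------------------------------

peak_lists = st.integers(min_value=1, max_value=20).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(60.0, 900.0), min_size=n, max_size=n, unique=True),
        st.lists(st.floats(0.01, 1e6), min_size=n, max_size=n),
    )
)


@settings(max_examples=60, deadline=None)
@given(peak_lists, st.floats(0.1, 1000.0))
def test_scores_scale_invariant(data, factor):
    mz, intensity = data
    a = spec(sorted(mz), intensity)
    b = a.scaled(factor)
    pairs = match_fragments(a, b, 0.01)
    assert cosine_similarity(a, b, pairs) == pytest.approx(
        cosine_similarity(a, a, pairs), abs=1e-10)
    assert entropy_similarity(a, b, 0.01) == pytest.approx(
        entropy_similarity(a, a, 0.01), abs=1e-10)


@settings(max_examples=60, deadline=None)
@given(peak_lists, peak_lists)
def test_entropy_similarity_symmetric_and_bounded(d1, d2):
    a = spec(sorted(d1[0]), d1[1])
    b = spec(sorted(d2[0]), d2[1])
    sab = entropy_similarity(a, b, 0.01)
    sba = entropy_similarity(b, a, 0.01)
    assert sab == pytest.approx(sba, abs=1e-9)
    assert 0.0 <= sab <= 1.0


@settings(max_examples=60, deadline=None)
@given(peak_lists)
def test_entropy_bounds(data):
    s = spec(sorted(data[0]), data[1])
    value = spectral_entropy(s)
    assert -1e-12 <= value <= math.log(len(s)) + 1e-9


@settings(max_examples=40, deadline=None)
@given(peak_lists)
def test_neme_bounded_by_tolerance(data):
    s = spec(sorted(data[0]), data[1])
    rng = np.random.default_rng(0)
    jittered = spec(np.asarray(sorted(data[0])) + rng.uniform(-0.004, 0.004, len(s)),
                    data[1])
    pairs = match_fragments(s, jittered, 0.01)
    if pairs:
        assert 0.0 <= neme(s, jittered, pairs) <= 0.01 + 1e-12


# ---------------------------------------------------------------------------
# prefilter and search
# ---------------------------------------------------------------------------

class TestPrefilter:
    def test_self_spectrum_passes(self, rng):
        lib = [make_random_spectrum(rng, precursor=True) for _ in range(5)]
        fsdb = build_fsdb(lib, SearchParams())
        for entry in fsdb.entries:
            assert prefilter(entry.spectrum, entry, fsdb.build_params)

    def test_precursor_gate(self):
        params = SearchParams(precursor_mz_tol=0.01, marker_min_match_pct=0.0)
        lib = spec([100], [1], precursor_mz=300.0)
        fsdb = build_fsdb([lib], params)
        query = spec([100], [1], precursor_mz=100.0)
        assert not prefilter(query, fsdb.entries[0], params)

    def test_marker_percentage_gate(self):
        lib = spec([100, 200, 300, 400], [100, 100, 100, 100])
        query = spec([100, 200], [1, 1])
        entry = build_fsdb([lib], SearchParams()).entries[0]
        assert not prefilter(query, entry, SearchParams(marker_min_match_pct=75.0))
        assert prefilter(query, entry, SearchParams(marker_min_match_pct=50.0))


class TestSearch:
    def test_self_hit_rank_one_score_one(self, rng):
        lib = [make_random_spectrum(rng, n_peaks=8) for _ in range(20)]
        fsdb = build_fsdb(lib, SearchParams())
        hits = search(fsdb.entries[3].spectrum, fsdb)
        assert hits and hits[0].rank == 1
        assert hits[0].library_entry_id == 3
        assert hits[0].score == pytest.approx(1.0, abs=1e-10)
        assert hits[0].neme == 0.0

    def test_disjoint_library_no_hits(self):
        lib = [spec([100 + 10 * i], [1.0]) for i in range(5)]
        fsdb = build_fsdb(lib, SearchParams())
        assert search(spec([700.0], [1.0]), fsdb) == []

    def test_score_identity(self, rng):
        lib = [make_random_spectrum(rng, n_peaks=8) for _ in range(10)]
        fsdb = build_fsdb(lib, SearchParams(entsim_cutoff=0.01))
        rs = make_random_spectrum(rng, n_peaks=8)
        for hit in search(rs, fsdb):
            assert hit.score == pytest.approx(hit.cosine * hit.entropy_sim**2, abs=1e-12)
            assert hit.np_matched >= 1

    def test_empty_library_raises(self, random_spectrum):
        from csakit.spectra_io import FSDB

        with pytest.raises(InputError):
            search(random_spectrum, FSDB(entries=[]))


class TestSummarizeStudy:
    def test_full_frequency(self):
        import pandas as pd

        results = {
            f"s{i}": pd.DataFrame(
                {"row_id": [7], "compound": ["X"], "rank": [1]}) for i in range(10)
        }
        out = summarize_study(results)
        assert len(out) == 1
        assert out.loc[0, "frequency"] == 10
        assert out.loc[0, "median_rank"] == 1

    def test_median_rank(self):
        import pandas as pd

        results = {
            "a": pd.DataFrame({"row_id": [1], "compound": ["X"], "rank": [1]}),
            "b": pd.DataFrame({"row_id": [1], "compound": ["X"], "rank": [2]}),
            "c": pd.DataFrame({"row_id": [1], "compound": ["X"], "rank": [4]}),
        }
        out = summarize_study(results)
        assert out.loc[0, "median_rank"] == 2

    def test_no_hits_empty(self):
        out = summarize_study({})
        assert len(out) == 0


def test_conditioning_pipeline_order(rng):
    # resolve first, denoise second: merged adjacent peaks can rise above
    # the noise threshold only if merging precedes thresholding
    s = spec([100.000, 100.004, 200.0], [6.0, 6.0, 1000.0])
    out = condition_spectrum(s, SearchParams(resolution_tol=0.01, noise_pct=1.0))
    assert len(out) == 2   # the merged 12.0 survives the 10.0 threshold
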