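import itertools

import numpy as np
import pytest

from hhtmass.peaks import (
    Peak,
    PeakList,
    count_peaks_by_region,
    detect_peaks_cwt,
    detect_peaks_localmax,
    link_ridges,
    match_peaks,
)


def _make_peaklist(mzs):
    return PeakList(
        [Peak(index=i, mz=m, intensity=1.0, snr=10.0, detector="localmax") for i, m in enumerate(mzs)]
    )


class TestLocalMax:
    def test_single_noiseless_gaussian(self, gaussian_spectrum):
        spec = gaussian_spectrum(1000, [500], [100.0], [5.0])
        pl = detect_peaks_localmax(spec)
        assert [p.index for p in pl] == [500]

    def test_two_gaussians_hundred_apart(self, gaussian_spectrum):
        spec = gaussian_spectrum(2000, [900, 1000], [100.0, 80.0], [5.0, 5.0])
        pl = detect_peaks_localmax(spec, half_window=10)
        assert [p.index for p in pl] == [900, 1000]

    def test_white_noise_rarely_detected_at_high_snr(self, index_spectrum):
        detections = 0
        for seed in range(100):
            y = np.random.default_rng(seed).normal(size=2000)
            pl = detect_peaks_localmax(index_spectrum(y), snr_min=10.0)
            detections += len(pl) > 0
        assert detections <= 5  # 0 peaks in >= 95 of 100 trials

    def test_shift_equivariance(self, gaussian_spectrum):
        spec = gaussian_spectrum(2000, [700, 1400], [50.0, 30.0], [6.0, 8.0], noise=1.0)
        shifted = spec.with_intensity(spec.intensity + 1234.5)
        a = detect_peaks_localmax(spec)
        b = detect_peaks_localmax(shifted)
        assert [p.index for p in a] == [p.index for p in b]

    def test_no_two_peaks_within_half_window(self, gaussian_spectrum):
        spec = gaussian_spectrum(4096, [500, 1500, 2500], [50.0, 40.0, 30.0], [8.0, 8.0, 8.0], noise=2.0)
        half_window = 10
        pl = detect_peaks_localmax(spec, half_window=half_window)
        idx = [p.index for p in pl]
        assert all(b - a > half_window for a, b in zip(idx, idx[1:]))

    def test_bad_half_window_is_contract_error(self, gaussian_spectrum):
        spec = gaussian_spectrum(100, [50], [10.0], [3.0])
        with pytest.raises(ValueError):
            detect_peaks_localmax(spec, half_window=0)


class TestCWT:
    def test_single_gaussian_scale_matches_width(self, gaussian_spectrum):
        for sigma in (5.0, 10.0, 20.0):
            spec = gaussian_spectrum(2048, [1000], [100.0], [sigma])
            pl = detect_peaks_cwt(spec)
            assert len(pl) == 1
            peak = pl.peaks[0]
            assert peak.index == 1000
            assert sigma / 2 <= peak.scale <= sigma * 2

    def test_deterministic(self, gaussian_spectrum):
        spec = gaussian_spectrum(2048, [700, 1200], [60.0, 40.0], [6.0, 12.0], noise=1.0)
        a = detect_peaks_cwt(spec)
        b = detect_peaks_cwt(spec)
        assert [(p.index, p.snr, p.scale) for p in a] == [(p.index, p.snr, p.scale) for p in b]

    def test_too_few_scales_is_contract_error(self, gaussian_spectrum):
        spec = gaussian_spectrum(2048, [1000], [50.0], [5.0])
        with pytest.raises(ValueError):
            detect_peaks_cwt(spec, scales=(2, 4), min_ridge_length=3)


def brute_force_ridges(maxima_per_row, tols, gap_max):
    """Exhaustive ridge enumeration oracle for tiny inputs.

    Enumerates all maximal chains: a chain picks at most one position per
    row, consecutive picks within tolerance of the earlier pick, at most
    gap_max skipped rows between picks. Returns the set of frozensets of
    (row, pos) chains that the greedy linker should reproduce for a
    single unambiguous planted ridge.
    """
    n_rows = len(maxima_per_row)
    chains = []

    def extend(chain, row):
        if row == n_rows:
            if chain:
                chains.append(tuple(chain))
            return
        last = chain[-1] if chain else None
        extended = False
        for pos in maxima_per_row[row]:
            if last is None or (
                abs(pos - last[1]) <= tols[row] and row - last[0] <= gap_max + 1
            ):
                extend(chain + [(row, pos)], row + 1)
                extended = True
        extend(chain, row + 1)  # skip this row
        return extended

    extend([], 0)
    # keep maximal chains only
    out = set()
    chain_sets = [frozenset(c) for c in chains]
    for c in chain_sets:
        if not any(c < other for other in chain_sets):
            out.add(c)
    return out


class TestRidgeLinking:
    def test_planted_diagonal_ridge_recovered_exactly(self):
        # one clean diagonal ridge drifting by 1 position per row
        maxima = [[10], [11], [12], [13], [14], [15]]
        tols = [3] * 6
        ridges = link_ridges(maxima, tols, gap_max=2)
        assert len(ridges) == 1
        expected = brute_force_ridges(maxima, tols, gap_max=2)
        assert frozenset(ridges[0]) in expected

    def test_ridge_with_gap_and_decoy(self):
        maxima = [[10, 40], [11], [], [12, 39], [13], [14]]
        tols = [3] * 6
        ridges = link_ridges(maxima, tols, gap_max=2)
        main = max(ridges, key=len)
        assert [p for _, p in main] == [10, 11, 12, 13, 14]

    def test_gap_limit_splits_ridges(self):
        maxima = [[10], [], [], [], [10], [10]]
        ridges = link_ridges(maxima, [2] * 6, gap_max=2)
        assert sorted(len(r) for r in ridges) == [1, 2]

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_instances_against_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # sparse maxima on a 6x50 grid, far apart so chains are unambiguous
        maxima = []
        for _ in range(6):
            cols = sorted(rng.choice(50, size=rng.integers(0, 3), replace=False).tolist())
            maxima.append([int(c) for c in cols])
        tols = [2] * 6
        ridges = link_ridges(maxima, tols, gap_max=1)
        oracle = brute_force_ridges(maxima, tols, gap_max=1)
        # every linked ridge must be one of the oracle's maximal chains,
        # and all linked points must cover exactly the available maxima
        for ridge in ridges:
            assert frozenset(ridge) in oracle or len(ridge) == 1
        linked_points = sorted(p for r in ridges for p in r)
        available = sorted((row, pos) for row, cols in enumerate(maxima) for pos in cols)
        assert linked_points == available


class TestRegions:
    def test_example_counts(self):
        pl = _make_peaklist([2500.0, 4500.0, 4600.0])
        assert count_peaks_by_region(pl) == [1, 2, 0, 0, 0, 0, 0]

    def test_empty_list(self):
        assert count_peaks_by_region(PeakList([])) == [0] * 7

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        mzs = sorted(set(rng.uniform(1500.0, 16000.0, size=40).tolist()))
        pl = _make_peaklist(mzs)
        counts = count_peaks_by_region(pl)
        in_range = sum(1 for m in mzs if 2000.0 <= m < 15000.0)
        assert sum(counts) == in_range

    def test_unsorted_boundaries_is_contract_error(self):
        with pytest.raises(ValueError):
            count_peaks_by_region(PeakList([]), boundaries=(1.0, 3.0, 2.0))


class TestMatchPeaks:
    def test_exact_match(self):
        pl = _make_peaklist([100.0, 200.0, 300.0])
        precision, recall, pairs = match_peaks(pl, [100.0, 200.0, 300.0], tol_da=1.0)
        assert precision == 1.0 and recall == 1.0 and len(pairs) == 3

    def test_empty_detected_convention(self):
        precision, recall, pairs = match_peaks(PeakList([]), [100.0], tol_da=1.0)
        assert precision == 1.0 and recall == 0.0 and pairs == []

    def test_two_detected_near_one_truth(self):
        pl = _make_peaklist([99.5, 100.4])
        precision, recall, pairs = match_peaks(pl, [100.0], tol_da=1.0)
        assert precision == 0.5 and recall == 1.0 and len(pairs) == 1

    def test_nonpositive_tolerance_is_contract_error(self):
        with pytest.raises(ValueError):
            match_peaks(_make_peaklist([1.0]), [1.0], tol_da=0.0)


class TestDetectorComparison:
    def test_cwt_recall_at_least_localmax_for_faint_peaks(self, index_spectrum):
        """Ridge persistence across scales should recover faint peaks that a
        plain windowed maximum with the same SNR threshold misses."""
        rng = np.random.default_rng(42)
        n = 4096
        x = np.arange(n, dtype=float)
        centers = list(range(300, 3900, 360))
        clean = np.zeros(n)
        for c in centers:
            clean += 4.0 * np.exp(-0.5 * ((x - c) / 6.0) ** 2)  # SNR ~ 4 < 5
        spec = index_spectrum(clean + rng.normal(size=n))
        truth = [float(c + 1) for c in centers]
        pl_local = detect_peaks_localmax(spec)
        pl_cwt = detect_peaks_cwt(spec)
        _, recall_local, _ = match_peaks(pl_local, truth, tol_da=10.0)
        _, recall_cwt, _ = match_peaks(pl_cwt, truth, tol_da=10.0)
        assert recall_cwt >= recall_local
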