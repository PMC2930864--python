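"""Peak detection on (preprocessed) spectra.

Two detectors are provided, mirroring the two peak-picking styles the
HHTMass pipeline is typically paired with:

* a windowed local-maximum detector with a robust local SNR gate
  (``localmax``): a sample is a peak iff it is the strict maximum of its
  +-``half_window`` neighbourhood and its prominence above the local
  median, divided by the robust local scale (1.4826 x MAD about the local
  median, both over a +-``noise_half_window`` sample window), reaches
  ``snr_min``. The SNR is fully shift-invariant, so adding a constant to
  the intensities changes nothing.

* a continuous-wavelet-transform ridge detector (``cwt``): Mexican-hat
  CWT coefficients are computed at a ladder of scales, per-scale
  coefficient maxima are linked into ridge lines across scales (allowing
  short gaps), and ridges that persist over enough scales with a
  sufficient coefficient SNR are reported. Ridge persistence makes the
  detector sensitive to low-SNR peaks while rejecting single-scale noise.

Truth matching (:func:`match_peaks`) provides precision/recall evaluation
against a synthetic spectrum's planted peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d
from scipy.signal import fftconvolve
from sklearn.base import BaseEstimator

from .spectra_io import Spectrum

__all__ = [
    "Peak",
    "PeakList",
    "detect_peaks_localmax",
    "detect_peaks_cwt",
    "link_ridges",
    "count_peaks_by_region",
    "match_peaks",
    "LocalMaxPeakDetector",
    "CWTPeakDetector",
    "DEFAULT_REGION_BOUNDARIES",
]

#: Table-style m/z region boundaries (Da): regions A..G between 2000 and 15000.
DEFAULT_REGION_BOUNDARIES = (2000.0, 4000.0, 6000.0, 8000.0, 10000.0, 12000.0, 14000.0, 15000.0)


@dataclass(frozen=True)
class Peak:
    """One detected peak."""

    index: int
    mz: float
    intensity: float
    snr: float
    detector: str
    scale: float | None = None


@dataclass
class PeakList:
    """Detected peaks sorted by m/z, plus the detector's parameters."""

    peaks: list[Peak]
    source_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        mzs = [p.mz for p in self.peaks]
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("peak m/z values must be strictly increasing")
        idx = [p.index for p in self.peaks]
        if len(set(idx)) != len(idx):
            raise ValueError("no two peaks may share a sample index")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "index": p.index,
                    "mz": p.mz,
                    "intensity": p.intensity,
                    "snr": p.snr,
                    "detector": p.detector,
                    "scale": p.scale,
                }
                for p in self.peaks
            ],
            columns=["index", "mz", "intensity", "snr", "detector", "scale"],
        )

    def in_range(self, lo: float, hi: float) -> "PeakList":
        """Peaks with lo <= mz < hi (analysis-window restriction)."""
        return PeakList(
            [p for p in self.peaks if lo <= p.mz < hi], dict(self.source_config)
        )


def _snr_localmax(x: np.ndarray, i: int, half: int, exclude: int) -> float:
    """Robust local SNR: prominence of x[i] above the local median, divided
    by 1.4826 x MAD about that median. Both statistics are taken over the
    +-``half`` sample window with the central +-``exclude`` samples removed,
    so the candidate peak's own body does not inflate its noise estimate."""
    lo = max(0, i - half)
    hi = min(x.size, i + half + 1)
    idx = np.r_[lo : max(lo, i - exclude), min(hi, i + exclude + 1) : hi]
    window = x[idx] if idx.size else x[lo:hi]
    med = float(np.median(window))
    noise = 1.4826 * float(np.median(np.abs(window - med)))
    prominence = x[i] - med
    if noise == 0.0:
        return float("inf") if prominence > 0 else 0.0
    return max(0.0, prominence / noise)


def detect_peaks_localmax(
    spec: Spectrum,
    half_window: int = 10,
    snr_min: float = 3.0,
    noise_half_window: int = 200,
) -> PeakList:
    """Windowed local-maximum peak detection with a robust SNR gate.

    A sample qualifies iff it is the strict maximum of its
    +-``half_window`` neighbourhood (ties broken to the lowest index) and
    its local SNR reaches ``snr_min``. No two reported peaks lie within
    ``half_window`` samples of each other.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    x = spec.intensity
    n = x.size
    if n <= 2 * half_window:
        raise ValueError("spectrum shorter than the detection window")
    size = 2 * half_window + 1
    local_max = maximum_filter1d(x, size=size, mode="constant", cval=-np.inf)
    candidates = np.flatnonzero(x == local_max)
    kept: list[int] = []
    for i in candidates:
        if kept and i - kept[-1] <= half_window:
            continue  # tie or redundant neighbour; lowest index wins
        kept.append(int(i))
    exclude = min(4 * half_window, noise_half_window // 4)
    peaks = []
    for i in kept:
        snr = _snr_localmax(x, i, noise_half_window, exclude)
        if snr >= snr_min:
            peaks.append(
                Peak(
                    index=i,
                    mz=float(spec.axis[i]),
                    intensity=float(x[i]),
                    snr=snr,
                    detector="localmax",
                )
            )
    config = {
        "detector": "localmax",
        "half_window": half_window,
        "snr_min": snr_min,
        "noise_half_window": noise_half_window,
    }
    return PeakList(peaks, config)


def _ricker(points: int, a: float) -> np.ndarray:
    """L2-normalised Mexican-hat (Ricker) wavelet of width ``a`` samples."""
    amp = 2.0 / (np.sqrt(3.0 * a) * np.pi**0.25)
    t = np.arange(points) - (points - 1) / 2.0
    u = (t / a) ** 2
    return amp * (1.0 - u) * np.exp(-u / 2.0)


def _cwt_mexh(x: np.ndarray, scales: Sequence[int]) -> np.ndarray:
    """Mexican-hat CWT, one row per scale.

    L2 kernel normalisation keeps the white-noise coefficient level flat
    across scales, so a single smallest-scale noise estimate is a valid
    floor for every scale, and a Gaussian peak of width sigma attains its
    ridge maximum at scale ~ sigma.
    """
    rows = np.empty((len(scales), x.size))
    for k, a in enumerate(scales):
        points = min(int(10 * a) | 1, x.size)
        rows[k] = fftconvolve(x, _ricker(points, a), mode="same")
    return rows


def link_ridges(
    maxima_per_row: Sequence[Sequence[int]],
    tols: Sequence[int],
    gap_max: int = 2,
) -> list[list[tuple[int, int]]]:
    """Link per-row maxima positions into ridge lines.

    Rows are processed in the given order (for the CWT detector: from the
    largest scale down to the smallest). Each maximum in a row is matched
    greedily (nearest first, lower position on ties) to an active ridge
    whose current position lies within ``tols[row]`` samples; unmatched
    maxima start new ridges, and a ridge is closed after it has missed
    more than ``gap_max`` consecutive rows.

    Returns, for each ridge, the list of ``(row, position)`` pairs it
    matched, in processing order. Deterministic.
    """
    active: list[dict] = []
    closed: list[list[tuple[int, int]]] = []
    for row, positions in enumerate(maxima_per_row):
        tol = int(tols[row])
        pairs = []
        for pos in sorted(positions):
            for ridge_id, ridge in enumerate(active):
                dist = abs(pos - ridge["pos"])
                if dist <= tol:
                    pairs.append((dist, pos, ridge_id))
        pairs.sort()
        used_pos: set[int] = set()
        used_ridge: set[int] = set()
        for dist, pos, ridge_id in pairs:
            if pos in used_pos or ridge_id in used_ridge:
                continue
            used_pos.add(pos)
            used_ridge.add(ridge_id)
            ridge = active[ridge_id]
            ridge["points"].append((row, pos))
            ridge["pos"] = pos
            ridge["gap"] = 0
        for pos in sorted(positions):
            if pos not in used_pos:
                active.append({"points": [(row, pos)], "pos": pos, "gap": 0})
        survivors = []
        for ridge_id, ridge in enumerate(active):
            if ridge_id not in used_ridge and ridge["points"][-1][0] != row:
                ridge["gap"] += 1
                if ridge["gap"] > gap_max:
                    closed.append(ridge["points"])
                    continue
            survivors.append(ridge)
        active = survivors
    closed.extend(r["points"] for r in active)
    return closed


def detect_peaks_cwt(
    spec: Spectrum,
    scales: Sequence[int] = (2, 4, 8, 16, 32, 64),
    snr_min: float = 3.0,
    min_ridge_length: int = 3,
    gap_max: int = 2,
    noise_half_window: int = 200,
) -> PeakList:
    """Mexican-hat CWT ridge-line peak detection.

    Coefficients are computed at each scale; per-scale coefficient maxima
    are linked into ridges from the largest scale downwards; ridges
    spanning at least ``min_ridge_length`` scales whose best-scale
    coefficient SNR reaches ``snr_min`` are reported. The noise floor is
    1.4826 x MAD of the smallest-scale coefficients in a
    +-``noise_half_window`` sample window around the ridge. The apex is
    the raw-signal local maximum nearest the ridge position within
    +-best-scale samples.
    """
    scales = sorted(int(s) for s in scales)
    if len(scales) < min_ridge_length:
        raise ValueError("need at least min_ridge_length scales")
    if min(scales) < 1:
        raise ValueError("scales must be >= 1")
    x = spec.intensity
    n = x.size
    if n <= 4 * max(scales):
        raise ValueError("spectrum shorter than 4x the largest scale")
    coefs = _cwt_mexh(x, scales)
    # width-matched rows (coef / a) peak at scale ~ the Gaussian sigma and
    # drive ridge linking and best-scale selection; the L2 rows, whose
    # white-noise level is flat across scales, drive the SNR.
    matched = coefs / np.asarray(scales, dtype=np.float64)[:, None]
    # rows from largest scale down to smallest for ridge linking
    order = np.argsort(scales)[::-1]
    maxima_rows: list[np.ndarray] = []
    tols: list[int] = []
    for k in order:
        row = matched[k]
        size = 2 * max(1, scales[k] // 2) + 1
        is_max = (row == maximum_filter1d(row, size=size, mode="constant", cval=-np.inf))
        maxima_rows.append(np.flatnonzero(is_max & (row > 0)))
        tols.append(max(2, scales[k]))
    ridges = link_ridges(maxima_rows, tols, gap_max=gap_max)
    smallest = coefs[0]
    # numerical floor: convolution dust must not pass as infinite-SNR ridges
    noise_floor = 1e-10 * float(np.max(np.abs(coefs)))
    best: dict[int, Peak] = {}
    for points in ridges:
        if len(points) < min_ridge_length:
            continue
        # ridge strength = largest L2 coefficient along the ridge (robust
        # across scales); reported scale/position = width-matched argmax
        l2_vals = [coefs[order[row]][pos] for row, pos in points]
        matched_vals = [matched[order[row]][pos] for row, pos in points]
        coef_best = float(max(l2_vals))
        j = int(np.argmax(matched_vals))
        row, pos = points[j]
        scale = scales[order[row]]
        lo = max(0, pos - noise_half_window)
        hi = min(n, pos + noise_half_window + 1)
        window = smallest[lo:hi]
        mad = float(np.median(np.abs(window - np.median(window))))
        noise = max(1.4826 * mad, noise_floor)
        snr = float("inf") if noise == 0.0 else coef_best / noise
        if snr < snr_min:
            continue
        a = max(0, pos - scale)
        b = min(n, pos + scale + 1)
        apex = a + int(np.argmax(x[a:b]))
        peak = Peak(
            index=apex,
            mz=float(spec.axis[apex]),
            intensity=float(x[apex]),
            snr=max(0.0, snr),
            detector="cwt",
            scale=float(scale),
        )
        if apex not in best or best[apex].snr < peak.snr:
            best[apex] = peak
    config = {
        "detector": "cwt",
        "scales": list(scales),
        "snr_min": snr_min,
        "min_ridge_length": min_ridge_length,
        "gap_max": gap_max,
        "noise_half_window": noise_half_window,
    }
    return PeakList(list(best.values()), config)


def count_peaks_by_region(
    pl: PeakList,
    boundaries: Sequence[float] = DEFAULT_REGION_BOUNDARIES,
) -> list[int]:
    """Count peaks with mz in [b_i, b_{i+1}) for each consecutive pair.

    The counts sum to the number of peaks within [b_0, b_last).
    """
    boundaries = np.asarray(boundaries, dtype=np.float64)
    if boundaries.ndim != 1 or boundaries.size < 2:
        raise ValueError("need at least two boundaries")
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("boundaries must be strictly increasing")
    mz = pl.mz
    counts, _ = np.histogram(mz, bins=boundaries)
    # np.histogram closes the last bin on the right; match [b_i, b_{i+1})
    if mz.size and np.any(mz == boundaries[-1]):
        counts[-1] -= int(np.count_nonzero(mz == boundaries[-1]))
    return [int(c) for c in counts]


def match_peaks(
    detected: PeakList,
    truth,
    tol_da: float | None = None,
    tol_rel: float = 0.003,
) -> tuple[float, float, list[tuple[int, int]]]:
    """Greedy nearest-match of detected peaks against planted truth.

    ``truth`` is a SyntheticTruth (its ``peak_mz`` is used) or any
    sequence of m/z values. A detected/truth pair is matchable when their
    m/z distance is within ``tol_da`` (absolute), or within ``tol_rel``
    of the truth m/z when ``tol_da`` is None (default 0.3%, a typical
    SELDI mass accuracy). Pairs are matched nearest-first; each peak on
    either side matches at most once.

    Returns ``(precision, recall, matched_pairs)`` with the convention
    that an empty denominator yields 1.0. ``matched_pairs`` holds
    ``(detected_index, truth_index)`` positions into the two lists.
    """
    if tol_da is not None and tol_da <= 0:
        raise ValueError("tol_da must be positive")
    truth_mz = np.asarray(getattr(truth, "peak_mz", truth), dtype=np.float64)
    det_mz = detected.mz
    pairs = []
    for ti, t in enumerate(truth_mz):
        tol = tol_da if tol_da is not None else tol_rel * t
        for di, d in enumerate(det_mz):
            dist = abs(d - t)
            if dist <= tol:
                pairs.append((dist, di, ti))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, di, ti in pairs:
        if di in used_d or ti in used_t:
            continue
        used_d.add(di)
        used_t.add(ti)
        matched.append((di, ti))
    precision = len(matched) / len(det_mz) if det_mz.size else 1.0
    recall = len(matched) / truth_mz.size if truth_mz.size else 1.0
    return precision, recall, matched


class LocalMaxPeakDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_peaks_localmax`."""

    def __init__(self, half_window: int = 10, snr_min: float = 3.0, noise_half_window: int = 200):
        self.half_window = half_window
        self.snr_min = snr_min
        self.noise_half_window = noise_half_window

    def detect(self, spec: Spectrum) -> PeakList:
        return detect_peaks_localmax(
            spec,
            half_window=self.half_window,
            snr_min=self.snr_min,
            noise_half_window=self.noise_half_window,
        )


class CWTPeakDetector(BaseEstimator):
    """Estimator wrapper around :func:`detect_peaks_cwt`."""

    def __init__(
        self,
        scales: Sequence[int] = (2, 4, 8, 16, 32, 64),
        snr_min: float = 3.0,
        min_ridge_length: int = 3,
        gap_max: int = 2,
        noise_half_window: int = 200,
    ):
        self.scales = scales
        self.snr_min = snr_min
        self.min_ridge_length = min_ridge_length
        self.gap_max = gap_max
        self.noise_half_window = noise_half_window

    def detect(self, spec: Spectrum) -> PeakList:
        return detect_peaks_cwt(
            spec,
            scales=self.scales,
            snr_min=self.snr_min,
            min_ridge_length=self.min_ridge_length,
            gap_max=self.gap_max,
            noise_half_window=self.noise_half_window,
        )
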