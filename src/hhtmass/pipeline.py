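"""The HHTMass preprocessing pipeline.

Denoising by IMF-band removal, windowed baseline subtraction, and a shift
to a non-negative intensity floor. The pipeline order is

    decompose -> select_components -> estimate_baseline
              -> subtract_baseline -> rescale to positive

The high-frequency IMFs (C1..C6 by default) carry electrical noise and
the dense low-mass chemical noise; the lowest-frequency components (the
last two IMFs plus the residue by default) carry the slowly varying trend
of the spectrum. Summing the retained middle band gives a denoised,
detrended spectrum; a windowed-minimum baseline (window 20 samples) is
then subtracted and the spectrum is shifted so its minimum sits at zero.

:class:`HHTMassPreprocessor` exposes the same computation as a
scikit-learn transformer operating on rows of an ``(n_spectra, n_points)``
matrix, so the method composes with sklearn pipelines; the module-level
functions remain the primary single-spectrum API.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .emd import IMFSet, decompose
from .spectra_io import Spectrum

__all__ = [
    "HHTMassConfig",
    "PreprocessedSpectrum",
    "select_components",
    "estimate_baseline",
    "subtract_baseline",
    "rescale_positive",
    "preprocess",
    "HHTMassPreprocessor",
]


@dataclass(frozen=True)
class HHTMassConfig:
    """Tunable parameters of the preprocessing pipeline.

    drop_low : number of highest-frequency IMFs removed for denoising
        (default 6, i.e. C1..C6).
    drop_high : number of lowest-frequency components removed for
        detrending, counting the residue as the last trend component
        (default 3: residue plus the two slowest IMFs).
    baseline_window : window size in samples for the windowed-minimum
        baseline, or ``None`` (default) to partition the spectrum into 20
        windows (window length ``n_points // 20``). A baseline must vary
        slowly relative to the peaks, and after EMD denoising nothing
        faster than ~100 samples survives, so a literal 20-sample minimum
        window would subtract the peaks themselves; dividing the spectrum
        into 20 windows is the reading under which baseline subtraction
        leaves the peak profile intact (see docs/methods.md).
    """

    drop_low: int = 6
    drop_high: int = 3
    baseline_window: int | None = None
    do_baseline: bool = True
    do_rescale: bool = True

    #: Number of baseline partitions used when ``baseline_window`` is None.
    BASELINE_N_WINDOWS = 20

    def __post_init__(self) -> None:
        if self.drop_low < 0 or self.drop_high < 0:
            raise ValueError("drop counts must be non-negative")
        if self.baseline_window is not None and self.baseline_window < 2:
            raise ValueError("baseline_window must be >= 2")

    def resolve_baseline_window(self, n_points: int) -> int:
        if self.baseline_window is not None:
            return self.baseline_window
        return max(2, n_points // self.BASELINE_N_WINDOWS)


@dataclass
class PreprocessedSpectrum:
    """Result of :func:`preprocess`: the cleaned spectrum plus provenance."""

    spectrum: Spectrum
    baseline: np.ndarray
    removed_low: list[int]
    removed_high: list[int]
    provenance: dict
    imfset: IMFSet | None = None


def select_components(imfset: IMFSet, drop_low: int, drop_high: int) -> np.ndarray:
    """Sum of the retained middle-band components.

    Components are ordered C1..Cn, residue; ``drop_low`` removes from the
    fast end, ``drop_high`` removes from the trend end with the residue
    removed first. Dropping everything yields an all-zero series.
    """
    if drop_low < 0 or drop_high < 0:
        raise ValueError("drop counts must be non-negative")
    components = list(imfset.imfs) + [imfset.residue]
    total = len(components)
    if drop_low + drop_high > total:
        raise ValueError(
            f"drop_low + drop_high = {drop_low + drop_high} exceeds the "
            f"{total} available components (n_imfs + residue)"
        )
    kept = components[drop_low : total - drop_high]
    if not kept:
        return np.zeros_like(imfset.residue)
    out = kept[0].copy()
    for comp in kept[1:]:
        out += comp
    return out


def estimate_baseline(signal: np.ndarray, window: int = 20) -> np.ndarray:
    """Windowed-minimum baseline.

    The index range is partitioned into consecutive windows of ``window``
    samples; each window's minimum becomes a baseline knot at the window
    centre. Knots are linearly interpolated across the full range (edge
    knots extended flat) and the result is smoothed with a moving average
    of width ``window``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > x.size:
        raise ValueError(f"window {window} exceeds signal length {x.size}")
    centers = []
    mins = []
    for start in range(0, x.size, window):
        stop = min(start + window, x.size)
        centers.append((start + stop - 1) // 2)
        mins.append(x[start:stop].min())
    knots = np.interp(np.arange(x.size), centers, mins)  # flat beyond edge knots
    return uniform_filter1d(knots, size=window, mode="nearest")


def subtract_baseline(signal: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Elementwise ``signal - baseline`` (lengths must match)."""
    signal = np.asarray(signal, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if signal.shape != baseline.shape:
        raise ValueError("signal and baseline must have the same length")
    return signal - baseline


def rescale_positive(signal: np.ndarray) -> np.ndarray:
    """Shift the whole series up so its minimum is zero, if it dips below.

    A pure shift: all pairwise differences are preserved exactly. Signals
    already non-negative are returned unchanged.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("rescale_positive needs a nonempty signal")
    lo = x.min()
    return x - lo if lo < 0 else x


def _preprocess_intensity(
    intensity: np.ndarray,
    config: HHTMassConfig,
    max_iter: int = 50,
    sd_threshold: float = 0.2,
) -> tuple[np.ndarray, np.ndarray, IMFSet]:
    """Shared pipeline core; returns (output, baseline, imfset)."""
    imfset = decompose(intensity, max_iter=max_iter, sd_threshold=sd_threshold)
    available = imfset.n_imfs + 1
    if config.drop_low + config.drop_high > available:
        raise ValueError(
            f"decomposition produced {available} components; reduce drop_low "
            f"({config.drop_low}) and/or drop_high ({config.drop_high})"
        )
    denoised = select_components(imfset, config.drop_low, config.drop_high)
    if config.do_baseline:
        window = config.resolve_baseline_window(denoised.size)
        baseline = estimate_baseline(denoised, window)
        out = subtract_baseline(denoised, baseline)
    else:
        baseline = np.zeros_like(denoised)
        out = denoised
    if config.do_rescale:
        # anchor the floor at exactly zero (pure shift; see docs/methods.md)
        out = out - out.min()
    return out, baseline, imfset


def preprocess(
    spec: Spectrum,
    config: HHTMassConfig | None = None,
    max_iter: int = 50,
    sd_threshold: float = 0.2,
    keep_imfs: bool = True,
) -> PreprocessedSpectrum:
    """Run the full HHTMass pipeline on one spectrum.

    Deterministic; never alters the axis or the number of points. Raises
    ``ValueError`` if the decomposition yields fewer components than the
    configured drop counts demand.
    """
    config = config or HHTMassConfig()
    out, baseline, imfset = _preprocess_intensity(
        spec.intensity, config, max_iter=max_iter, sd_threshold=sd_threshold
    )
    n = imfset.n_imfs
    removed_low = list(range(1, config.drop_low + 1))
    # components indexed 1..n+1 with the residue as n+1
    removed_high = list(range(n + 2 - config.drop_high, n + 2))
    return PreprocessedSpectrum(
        spectrum=spec.with_intensity(out),
        baseline=baseline,
        removed_low=removed_low,
        removed_high=removed_high,
        provenance=asdict(config),
        imfset=imfset if keep_imfs else None,
    )


class HHTMassPreprocessor(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer form of the HHTMass pipeline.

    Operates row-wise on an ``(n_spectra, n_points)`` intensity matrix;
    the axis is not needed because every pipeline stage works in index
    space. Stateless (``fit`` only records the input width), so it can be
    cloned and placed inside sklearn pipelines.

    Parameters mirror :class:`HHTMassConfig` plus the EMD stopping knobs.
    """

    def __init__(
        self,
        drop_low: int = 6,
        drop_high: int = 3,
        baseline_window: int | None = None,
        do_baseline: bool = True,
        do_rescale: bool = True,
        max_iter: int = 50,
        sd_threshold: float = 0.2,
    ):
        self.drop_low = drop_low
        self.drop_high = drop_high
        self.baseline_window = baseline_window
        self.do_baseline = do_baseline
        self.do_rescale = do_rescale
        self.max_iter = max_iter
        self.sd_threshold = sd_threshold

    def _config(self) -> HHTMassConfig:
        return HHTMassConfig(
            drop_low=self.drop_low,
            drop_high=self.drop_high,
            baseline_window=self.baseline_window,
            do_baseline=self.do_baseline,
            do_rescale=self.do_rescale,
        )

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=8)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_min_features=8)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        config = self._config()
        out = np.empty_like(X, dtype=np.float64)
        for i, row in enumerate(X):
            out[i], _, _ = _preprocess_intensity(
                row, config, max_iter=self.max_iter, sd_threshold=self.sd_threshold
            )
        return out

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X).transform(X)
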