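"""Synthetic SELDI/MALDI-like spectra with known ground truth.

The generator emulates the structure of serum protein-profiling spectra:

* a quadratically spaced m/z axis (a uniform time-of-flight grid mapped
  through the TOF -> m/z calibration);
* a handful of Gaussian protein peaks between 2 and 15 kDa;
* a slowly decaying exponential baseline;
* dense "chemical noise" in the low-mass band (< 1000 Da): many narrow
  peaklets standing in for matrix organic-acid ions — true peaks, not
  white noise;
* additive zero-mean Gaussian broadband noise.

The noise model is a stand-in: the distributions are conventional
choices, not fits to any real instrument (real SELDI noise is not known
to follow any simple model). Everything is a pure function of the
:class:`SyntheticTruth` record, so identical seeds give bitwise-identical
spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .spectra_io import (
    DEFAULT_CALIBRATION,
    CalibrationParams,
    Spectrum,
    mz_to_tof,
    tof_to_mz,
)

__all__ = [
    "SyntheticTruth",
    "generate",
    "clean_signal",
    "default_ovarian_like",
    "doubly_charged_mz",
]

#: Nominal proton mass (Da) used in the charge-state arithmetic.
PROTON_DA = 1.0


def doubly_charged_mz(mass_da: float) -> float:
    """m/z of the doubly charged protonated species, ``(M + 1) / 2``.

    Uses the nominal 1 Da proton: a protein of mass 5119 Da appears at
    (5119 + 1)/2 = 2560 Da when carrying two charges.
    """
    return (mass_da + PROTON_DA) / 2.0


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted peaks and noise/baseline parameters of a generated spectrum.

    baseline_params : (amplitude, decay constant in Da) of the
        exponential baseline ``A * exp(-mz / lam)``.
    chem_band : (low, high) m/z band (Da) carrying the dense
        chemical-noise peaklets.
    """

    peak_mz: tuple[float, ...]
    peak_height: tuple[float, ...]
    peak_sigma: tuple[float, ...]
    baseline_params: tuple[float, float] = (0.0, 1.0)
    noise_sigma: float = 0.0
    chem_band: tuple[float, float] = (58.75, 1000.0)
    seed: int = 0
    n_chem_peaks: int = 0
    chem_height_mean: float = 15.0

    def __post_init__(self) -> None:
        mz = tuple(float(v) for v in self.peak_mz)
        h = tuple(float(v) for v in self.peak_height)
        s = tuple(float(v) for v in self.peak_sigma)
        object.__setattr__(self, "peak_mz", mz)
        object.__setattr__(self, "peak_height", h)
        object.__setattr__(self, "peak_sigma", s)
        if not (len(mz) == len(h) == len(s)):
            raise ValueError("peak_mz, peak_height and peak_sigma must align")
        if any(v <= 0 for v in h) or any(v <= 0 for v in s):
            raise ValueError("peak heights and sigmas must be positive")
        if self.chem_band[0] >= self.chem_band[1]:
            raise ValueError("chem_band low must be below high")
        if self.noise_sigma < 0 or self.n_chem_peaks < 0:
            raise ValueError("noise_sigma and n_chem_peaks must be non-negative")


def _axis(n_points: int, mz_range: tuple[float, float], calib: CalibrationParams) -> np.ndarray:
    floor = calib.U * calib.b
    lo = max(mz_range[0], floor)  # the calibration cannot reach below U*b
    hi = mz_range[1]
    if hi <= lo:
        raise ValueError("mz_range high must exceed the calibration floor")
    t = np.linspace(mz_to_tof(lo, calib), mz_to_tof(hi, calib), n_points)
    return tof_to_mz(t, calib)


def clean_signal(truth: SyntheticTruth, axis: np.ndarray) -> np.ndarray:
    """The planted peak-only signal (no baseline, chemical band or noise)."""
    axis = np.asarray(axis, dtype=np.float64)
    out = np.zeros_like(axis)
    for mu, h, s in zip(truth.peak_mz, truth.peak_height, truth.peak_sigma):
        out += h * np.exp(-0.5 * ((axis - mu) / s) ** 2)
    return out


def generate(
    truth: SyntheticTruth,
    n_points: int = 21551,
    mz_range: tuple[float, float] = (58.75, 101453.0),
    calib: CalibrationParams = DEFAULT_CALIBRATION,
) -> tuple[Spectrum, SyntheticTruth]:
    """Generate one synthetic spectrum from a truth record.

    Fully reproducible: the realisation is a pure function of
    ``(truth, n_points, mz_range)``. Raises ``ValueError`` when a planted
    peak lies outside the generated axis.
    """
    if n_points < 64:
        raise ValueError("n_points must be >= 64")
    axis = _axis(n_points, mz_range, calib)
    if truth.peak_mz and (
        min(truth.peak_mz) < axis[0] or max(truth.peak_mz) > axis[-1]
    ):
        raise ValueError("planted peaks must lie inside mz_range")
    intensity = clean_signal(truth, axis)
    amp, lam = truth.baseline_params
    if amp:
        intensity = intensity + amp * np.exp(-axis / lam)
    rng = np.random.default_rng(truth.seed)
    if truth.n_chem_peaks:
        lo, hi = truth.chem_band
        pos = rng.uniform(lo, hi, size=truth.n_chem_peaks)
        height = rng.exponential(truth.chem_height_mean, size=truth.n_chem_peaks)
        sigma = rng.uniform(1.0, 3.0, size=truth.n_chem_peaks)
        band = (axis >= lo - 15.0) & (axis <= hi + 15.0)
        sub = axis[band]
        chem = np.zeros_like(sub)
        for p, h, s in zip(pos, height, sigma):
            chem += h * np.exp(-0.5 * ((sub - p) / s) ** 2)
        intensity = intensity.copy()
        intensity[band] += chem
    if truth.noise_sigma:
        intensity = intensity + rng.normal(0.0, truth.noise_sigma, size=n_points)
    return Spectrum(axis, intensity, "mz"), truth


#: Planted protein peaks of the serum-like preset: (m/z in Da, height in
#: noise-sigma units). Includes the 5119 Da model protein and its doubly
#: charged partner at (5119 + 1)/2 = 2560 Da.
_OVARIAN_PEAKS = (
    (2560.0, 60.0),
    (3100.0, 35.0),
    (4200.0, 45.0),
    (5119.0, 120.0),
    (6300.0, 80.0),
    (7800.0, 50.0),
    (9200.0, 40.0),
    (10800.0, 30.0),
    (12600.0, 25.0),
    (14300.0, 20.0),
)

#: Relative peak width: sigma = 0.5% of m/z, i.e. FWHM ~ 1.2% of m/z
#: (resolving power ~ 85, typical of linear-mode SELDI protein profiling).
_SIGMA_REL = 0.005


def default_ovarian_like(seed: int) -> SyntheticTruth:
    """Preset emulating a serum SELDI profile: ~10 protein peaks between
    2 and 15 kDa over a decaying baseline, with a dense chemical-noise
    band below 1000 Da and unit white noise.

    Peak heights span 20-120x the white-noise sigma; the doubly charged
    partner of the 5119 Da protein is planted at 2560 Da.
    """
    mz = tuple(m for m, _ in _OVARIAN_PEAKS)
    heights = tuple(h for _, h in _OVARIAN_PEAKS)
    sigmas = tuple(_SIGMA_REL * m for m in mz)
    return SyntheticTruth(
        peak_mz=mz,
        peak_height=heights,
        peak_sigma=sigmas,
        baseline_params=(50.0, 3000.0),
        noise_sigma=1.0,
        chem_band=(58.75, 1000.0),
        seed=int(seed),
        n_chem_peaks=150,
        chem_height_mean=15.0,
    )
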