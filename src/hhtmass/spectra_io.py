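"""Spectrum container, delimited-text I/O and TOF -> m/z calibration.

A SELDI/MALDI-TOF profile spectrum is a pair of equal-length arrays: an
axis (time of flight in seconds, or mass-to-charge in Da) and detector
intensities. Everything downstream (decomposition, baseline removal, peak
picking) consumes the :class:`Spectrum` produced here, so the loader
normalises the axis once: rows are sorted, exact duplicate axis values are
merged by mean intensity, and non-finite intensities are rejected.

The time-of-flight axis of a linear TOF instrument maps to m/z through a
quadratic calibration

    m/z = U * (a * (t - t0)**2 + b)

where ``t`` is the flight time, ``t0`` an electronic delay, and ``U``,
``a``, ``b`` instrument constants. The default constants reproduce an
axis floor of ``U * b = 58.75`` Da at ``t = t0``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

__all__ = [
    "Spectrum",
    "CalibrationParams",
    "DEFAULT_CALIBRATION",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_arrays",
    "tof_to_mz",
    "mz_to_tof",
    "calibrate_axis",
]

logger = logging.getLogger(__name__)


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed into two numeric columns."""


@dataclass(frozen=True)
class CalibrationParams:
    """Constants of the quadratic TOF -> m/z calibration.

    Parameters
    ----------
    U : float
        Accelerating-potential constant (dimensionless as printed).
    a : float
        Quadratic coefficient (Da / s**2 after multiplication by U).
    b : float
        Offset coefficient; ``U * b`` is the m/z value at ``t = t0``.
    t0 : float
        Time offset in seconds.
    """

    U: float = 25000.0
    a: float = 3.36e8
    b: float = 0.00235
    t0: float = 3.7071e-7

    def __post_init__(self) -> None:
        vals = (self.U, self.a, self.b, self.t0)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("calibration constants must be finite")
        if self.U <= 0 or self.a <= 0:
            raise ValueError("calibration requires U > 0 and a > 0")


#: Calibration of the SELDI instrument the default synthetic axis emulates.
DEFAULT_CALIBRATION = CalibrationParams()


@dataclass(frozen=True)
class Spectrum:
    """One mass spectrum: a strictly increasing axis plus intensities.

    ``axis_kind`` is ``"tof"`` (seconds) or ``"mz"`` (Da).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = "mz"

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=np.float64)
        intensity = np.asarray(self.intensity, dtype=np.float64)
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensity", intensity)
        if self.axis_kind not in ("tof", "mz"):
            raise ValueError(f"axis_kind must be 'tof' or 'mz', got {self.axis_kind!r}")
        if axis.ndim != 1 or intensity.ndim != 1:
            raise ValueError("axis and intensity must be one-dimensional")
        if axis.size != intensity.size:
            raise ValueError("axis and intensity must have equal length")
        if axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(axis)) or not np.all(np.isfinite(intensity)):
            raise ValueError("axis and intensity must be finite")
        if np.any(np.diff(axis) <= 0):
            raise ValueError("axis must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        """Return a copy of this spectrum carrying new intensities."""
        return Spectrum(self.axis, intensity, self.axis_kind)


def _sniff_delimiter(line: str) -> str | None:
    if "," in line:
        return ","
    if "\t" in line:
        return "\t"
    return None  # any whitespace


def _parse_rows(lines: Iterable[str], delimiter: str | None) -> tuple[np.ndarray, np.ndarray]:
    axis: list[float] = []
    intensity: list[float] = []
    delim = delimiter
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None:
            delim = _sniff_delimiter(line)
        fields = line.split(delim) if delim else line.split()
        fields = [f for f in (s.strip() for s in fields) if f]
        if len(fields) != 2:
            raise SpectrumFormatError(
                f"line {lineno}: expected 2 fields, got {len(fields)}"
            )
        try:
            a, b = float(fields[0]), float(fields[1])
        except ValueError as exc:
            raise SpectrumFormatError(f"line {lineno}: non-numeric field") from exc
        axis.append(a)
        intensity.append(b)
    return np.asarray(axis), np.asarray(intensity)


def read_spectrum(
    path: str | Path,
    delimiter: str | None = None,
    axis_kind: str = "mz",
) -> Spectrum:
    """Read a two-column delimited spectrum file.

    The delimiter is auto-sniffed (comma, tab, then whitespace) unless
    given. Lines starting with ``#`` and blank lines are skipped. Rows are
    sorted by axis value; exact duplicate axis values are merged by mean
    intensity with a logged warning.

    Raises
    ------
    OSError
        If the file cannot be read.
    SpectrumFormatError
        On a non-numeric field (naming the line number) or if fewer than
        two valid rows remain.
    """
    path = Path(path)
    with open(path, "r") as fh:
        axis, intensity = _parse_rows(fh, delimiter)
    if axis.size < 2:
        raise SpectrumFormatError(f"{path}: need at least 2 data rows, got {axis.size}")
    order = np.argsort(axis, kind="stable")
    axis, intensity = axis[order], intensity[order]
    uniq, inverse, counts = np.unique(axis, return_inverse=True, return_counts=True)
    if uniq.size != axis.size:
        merged = np.zeros_like(uniq)
        np.add.at(merged, inverse, intensity)
        merged /= counts
        logger.warning(
            "%s: merged %d duplicate axis value(s) by mean intensity",
            path,
            axis.size - uniq.size,
        )
        axis, intensity = uniq, merged
    if axis.size < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 distinct axis values")
    return Spectrum(axis, intensity, axis_kind)


def write_spectrum(spec: Spectrum, path: str | Path, delimiter: str = ",") -> None:
    """Write a spectrum as two delimited columns.

    Floats are printed with shortest round-trip representation, so
    ``read_spectrum(write_spectrum(s))`` reproduces the arrays exactly.
    Intensities are written as-is (negative values are preserved).
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# axis({spec.axis_kind}){delimiter}intensity\n")
        for a, y in zip(spec.axis, spec.intensity):
            fh.write(f"{float(a)!r}{delimiter}{float(y)!r}\n")


def read_arrays(mz: np.ndarray, intensity: np.ndarray) -> Spectrum:
    """Build an m/z Spectrum from raw arrays, applying the loader contract
    (sorting, duplicate merging). This is the adapter point for readers of
    other formats (e.g. an mzML reader's m/z and intensity arrays)."""
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse, counts = np.unique(mz, return_inverse=True, return_counts=True)
    if uniq.size != mz.size:
        merged = np.zeros_like(uniq)
        np.add.at(merged, inverse, intensity)
        merged /= counts
        mz, intensity = uniq, merged
    return Spectrum(mz, intensity, "mz")


def tof_to_mz(t, calib: CalibrationParams = DEFAULT_CALIBRATION):
    """Convert time of flight (seconds) to m/z (Da).

    Implements ``m/z = U * (a * (t - t0)**2 + b)``; vectorised over array
    input and strictly increasing for ``t > t0``.
    """
    t = np.asarray(t, dtype=np.float64)
    out = calib.U * (calib.a * (t - calib.t0) ** 2 + calib.b)
    return out if out.ndim else float(out)


def mz_to_tof(mz, calib: CalibrationParams = DEFAULT_CALIBRATION):
    """Invert :func:`tof_to_mz` on the physical branch ``t >= t0``.

    Requires ``mz >= U * b`` (the calibration's axis floor).
    """
    mz = np.asarray(mz, dtype=np.float64)
    arg = (mz / calib.U - calib.b) / calib.a
    if np.any(arg < 0):
        raise ValueError(f"m/z below calibration floor {calib.U * calib.b!r} Da")
    out = calib.t0 + np.sqrt(arg)
    return out if out.ndim else float(out)


def calibrate_axis(spec: Spectrum, calib: CalibrationParams = DEFAULT_CALIBRATION) -> Spectrum:
    """Map a TOF spectrum onto the m/z axis, leaving intensities untouched."""
    if spec.axis_kind != "tof":
        raise ValueError("calibrate_axis expects a TOF spectrum")
    return Spectrum(tof_to_mz(spec.axis, calib), spec.intensity, "mz")
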