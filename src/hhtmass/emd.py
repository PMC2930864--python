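"""Empirical mode decomposition (EMD) by the sifting process.

EMD adaptively splits a signal into intrinsic mode functions (IMFs): fast
oscillations come out first, slower ones later, and a final low-order
residue carries the trend. An IMF is a component whose number of extrema
and number of zero crossings agree to within one, and whose local mean --
the average of the cubic-spline envelopes through the maxima and through
the minima -- is (approximately) zero everywhere.

Sifting repeatedly subtracts the envelope mean from the running component
until it qualifies as an IMF; the accepted IMF is subtracted from the
running residue, and the process repeats until the residue is monotone or
has too few extrema to envelope. Because each IMF is subtracted exactly,
the decomposition is complete: the IMFs plus the residue sum back to the
input to floating-point accuracy.

For broadband noise EMD behaves like a dyadic filter bank, so the number
of IMFs grows like log2(N) in the signal length N.

Numerical conventions (documented in docs/methods.md):

* envelopes are natural cubic splines through the extrema, with the two
  edge extrema mirrored across each boundary to suppress end swings;
  fewer than 4 extrema on a side degrades to linear interpolation;
* sifting stops when the Cauchy criterion SD < ``sd_threshold`` *and* the
  candidate passes the IMF count test, or when the count test has held
  for 2 consecutive sifts (S-number rule), or at ``max_iter``;
* the IMF count test is evaluated on the interior 95% of samples, since
  mirrored ends can create spurious boundary extrema.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "IMFSet",
    "find_extrema",
    "count_zero_crossings",
    "envelope_mean",
    "is_imf",
    "sift",
    "decompose",
]


def find_extrema(signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima.

    A plateau of equal values bounded by lower (higher) neighbours yields
    a single maximum (minimum) at the plateau midpoint, rounded down.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        raise ValueError("find_extrema needs at least 3 samples")
    # run-length encode so plateaus collapse to single run values
    change = np.flatnonzero(np.diff(x) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [x.size - 1]))  # inclusive
    vals = x[starts]
    if vals.size < 3:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    rising = np.diff(vals) > 0  # between consecutive runs, values strictly differ
    up_then_down = rising[:-1] & ~rising[1:]
    down_then_up = ~rising[:-1] & rising[1:]
    mid = (starts + ends) // 2
    maxima = mid[np.flatnonzero(up_then_down) + 1]
    minima = mid[np.flatnonzero(down_then_up) + 1]
    return maxima.astype(np.intp), minima.astype(np.intp)


def count_zero_crossings(signal: np.ndarray) -> int:
    """Sign changes between consecutive nonzero samples.

    A run of exact zeros counts as a single crossing iff the flanking
    signs differ; an all-zero signal has zero crossings.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 2:
        raise ValueError("count_zero_crossings needs at least 2 samples")
    nz = x[x != 0]
    if nz.size < 2:
        return 0
    s = np.sign(nz)
    return int(np.count_nonzero(s[:-1] != s[1:]))


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Spline (or linear, when extrema are sparse) envelope through x[idx],
    with the two edge extrema mirrored across each boundary."""
    n = x.size
    left_idx = -idx[:2][::-1]
    right_idx = 2 * (n - 1) - idx[-2:][::-1]
    knots_x = np.concatenate((left_idx, idx, right_idx))
    knots_y = np.concatenate((x[idx[:2][::-1]], x[idx], x[idx[-2:][::-1]]))
    grid = np.arange(n)
    if idx.size < 4:
        return np.interp(grid, knots_x, knots_y)
    return CubicSpline(knots_x, knots_y, bc_type="natural")(grid)


def envelope_mean(signal: np.ndarray) -> np.ndarray | None:
    """Pointwise mean of the upper (maxima) and lower (minima) envelopes.

    Returns ``None`` when the signal has fewer than 2 maxima or 2 minima,
    signalling to the caller that the residue stage has been reached.
    """
    x = np.asarray(signal, dtype=np.float64)
    maxima, minima = find_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    upper = _envelope(x, maxima)
    lower = _envelope(x, minima)
    return 0.5 * (upper + lower)


def is_imf(signal: np.ndarray, slack: int = 1) -> bool:
    """IMF count test: |#extrema - #zero crossings| <= ``slack``.

    Evaluated on the interior 95% of samples so that boundary artefacts
    of envelope mirroring do not fail an otherwise valid component.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 3:
        raise ValueError("is_imf needs at least 3 samples")
    trim = int(round(0.025 * x.size))
    core = x[trim : x.size - trim] if x.size - 2 * trim >= 3 else x
    maxima, minima = find_extrema(core)
    n_extrema = maxima.size + minima.size
    n_crossings = count_zero_crossings(core)
    return abs(n_extrema - n_crossings) <= slack


def sift(
    signal: np.ndarray,
    max_iter: int = 50,
    sd_threshold: float = 0.2,
) -> tuple[np.ndarray, int]:
    """Extract one IMF candidate by iterated envelope-mean subtraction.

    Iterates ``h <- h - envelope_mean(h)`` until the Cauchy criterion
    ``SD = sum((h_prev - h)**2) / sum(h_prev**2) < sd_threshold`` is met
    by a candidate that also passes :func:`is_imf`, or the count test has
    held for 2 consecutive sifts, or ``max_iter`` is reached.

    Returns ``(imf, iterations)``. Raises ``ValueError`` if the input has
    too few extrema to envelope at entry (callers normally guard this).
    """
    h = np.asarray(signal, dtype=np.float64).copy()
    streak = 0
    iterations = 0
    for iterations in range(1, max_iter + 1):
        m = envelope_mean(h)
        if m is None:
            if iterations == 1:
                raise ValueError("sift requires at least 2 maxima and 2 minima")
            break
        denom = float(np.dot(h, h))
        sd = float(np.dot(m, m)) / denom if denom > 0 else 0.0
        h -= m
        ok = is_imf(h)
        streak = streak + 1 if ok else 0
        if (sd < sd_threshold and ok) or streak >= 2:
            break
    return h, iterations


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d >= 0) or np.all(d <= 0))


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the final residue.

    ``imfs[0]`` (C1) is the fastest component. ``sift_counts`` records the
    number of sifting iterations each IMF took (diagnostics).
    """

    imfs: list[np.ndarray]
    residue: np.ndarray
    sift_counts: list[int] = field(default_factory=list)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """Sum of all IMFs plus the residue (equals the input signal)."""
        out = self.residue.copy()
        for imf in self.imfs:
            out += imf
        return out

    def to_dataframe(self, axis: np.ndarray | None = None) -> pd.DataFrame:
        """Tabulate as columns axis, C1..Cn, residue (for CSV export)."""
        data: dict[str, np.ndarray] = {}
        data["axis"] = np.asarray(axis) if axis is not None else np.arange(self.residue.size)
        for i, imf in enumerate(self.imfs, start=1):
            data[f"C{i}"] = imf
        data["residue"] = self.residue
        return pd.DataFrame(data)


def decompose(
    signal: np.ndarray,
    max_imfs: int | None = None,
    max_iter: int = 50,
    sd_threshold: float = 0.2,
) -> IMFSet:
    """Full empirical mode decomposition of a 1-D signal.

    IMFs are extracted from the running residue until it is monotone or
    has fewer than 2 maxima or 2 minima (or ``max_imfs`` is reached). The
    decomposition is deterministic and complete: ``imfs`` plus ``residue``
    sum back to ``signal`` to floating-point accuracy.

    A constant signal yields zero IMFs with the input as residue.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("decompose expects a 1-D signal")
    if x.size < 8:
        raise ValueError("decompose needs at least 8 samples")
    residue = x.copy()
    imfs: list[np.ndarray] = []
    counts: list[int] = []
    scale = float(np.max(np.abs(x))) or 1.0
    prev_n_extrema: int | None = None
    stall = 0
    while True:
        if max_imfs is not None and len(imfs) >= max_imfs:
            break
        maxima, minima = find_extrema(residue)
        n_extrema = maxima.size + minima.size
        if maxima.size < 2 or minima.size < 2 or _is_monotone(residue):
            break
        # EMD coarsens: each extraction should reduce the residue's extrema
        # count. An exploding or persistently non-decreasing count means the
        # decomposition has stalled on numerical micro-ripples of the spline
        # envelopes (tiny residues can carry hundreds of float-level extrema).
        if prev_n_extrema is not None and n_extrema >= prev_n_extrema:
            stall += 1
            if n_extrema >= 2 * prev_n_extrema or stall >= 3:
                break
        else:
            stall = 0
        prev_n_extrema = n_extrema
        imf, iters = sift(residue, max_iter=max_iter, sd_threshold=sd_threshold)
        if np.max(np.abs(imf)) < 1e-12 * scale:
            break  # numerically zero component
        imfs.append(imf)
        counts.append(iters)
        residue = residue - imf
    return IMFSet(imfs=imfs, residue=residue, sift_counts=counts)
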