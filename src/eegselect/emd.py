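"""Empirical mode decomposition by cubic-spline sifting.

EMD decomposes a signal into intrinsic mode functions (IMFs) by repeatedly
subtracting the mean of the upper and lower extrema envelopes until the
proto-mode satisfies a Cauchy-type stopping criterion, then peeling the mode
off and sifting the remainder.  The implementation uses:

* cubic-spline envelopes through local maxima / minima,
* mirrored extension of the boundary extrema (two at each end) to tame
  end effects,
* the standard deviation criterion ``sum((h_prev - h)^2) / sum(h_prev^2)``
  with a configurable threshold (default 0.2),
* termination when the residual has fewer than two maxima or two minima
  (i.e. is monotone up to noise) or a maximum IMF count is reached.

Degenerate inputs (constant or too-short signals) yield an empty IMF list
with the residual equal to the input — no exception, so downstream feature
extraction can apply its fixed-dimension fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = ["IMFSet", "emd_decompose"]

_MIN_LENGTH = 16


@dataclass
class IMFSet:
    """Result of one decomposition: original signal, IMFs (fast to slow), residual."""

    original: np.ndarray
    imfs: list[np.ndarray]
    residual: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.original)
        for i, imf in enumerate(self.imfs):
            if len(imf) != n:
                raise ValueError(f"IMF {i} length {len(imf)} != signal length {n}")
        if len(self.residual) != n:
            raise ValueError("residual length mismatch")

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruction_error(self) -> float:
        """Relative error of sum(IMFs) + residual against the original."""
        recon = self.residual + (np.sum(self.imfs, axis=0) if self.imfs else 0.0)
        denom = max(float(np.max(np.abs(self.original))), 1e-300)
        return float(np.max(np.abs(recon - self.original))) / denom


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima; plateau extrema use their midpoint."""
    d = np.diff(x)
    # collapse zero slopes onto the preceding non-zero slope so plateaus
    # register a single sign change at their far edge
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    change = np.diff(s)
    maxima = np.flatnonzero(change < 0) + 1
    minima = np.flatnonzero(change > 0) + 1
    return maxima, minima


def _mirrored_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema ``idx``, mirrored at both ends."""
    n = len(x)
    t = idx.astype(np.float64)
    v = x[idx]
    n_mirror = min(2, len(idx))
    left_t = -t[:n_mirror][::-1]
    left_v = v[:n_mirror][::-1]
    right_t = 2.0 * (n - 1) - t[-n_mirror:][::-1]
    right_v = v[-n_mirror:][::-1]
    # guard against coincident knots when an extremum sits on the boundary
    tt = np.concatenate([left_t, t, right_t])
    vv = np.concatenate([left_v, v, right_v])
    keep = np.concatenate([[True], np.diff(tt) > 0])
    spline = CubicSpline(tt[keep], vv[keep])
    return spline(np.arange(n, dtype=np.float64))


def _sift(signal: np.ndarray, sd_threshold: float, max_iterations: int) -> np.ndarray | None:
    """Extract one IMF from ``signal``; None if it has too few extrema."""
    h = signal
    for _ in range(max_iterations):
        maxima, minima = _local_extrema(h)
        if len(maxima) < 2 or len(minima) < 2:
            return None if h is signal else h
        upper = _mirrored_envelope(h, maxima)
        lower = _mirrored_envelope(h, minima)
        mean_env = 0.5 * (upper + lower)
        h_new = h - mean_env
        sd = float(np.sum((h - h_new) ** 2) / (np.sum(h ** 2) + 1e-300))
        h = h_new
        if sd < sd_threshold:
            break
    return h


def emd_decompose(signal: np.ndarray, sd_threshold: float = 0.2,
                  max_sift_iterations: int = 50, max_imfs: int = 10) -> IMFSet:
    """Decompose ``signal`` into IMFs ordered fast to slow.

    The sum of the IMFs plus the residual reconstructs the input to floating
    point accuracy (each IMF is literally subtracted from the running
    residual).  Constant or too-short signals return zero IMFs.
    """
    signal = np.asarray(signal, dtype=np.float64)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite values")
    if len(signal) < _MIN_LENGTH or np.ptp(signal) == 0.0:
        return IMFSet(original=signal, imfs=[], residual=signal.copy())

    imfs: list[np.ndarray] = []
    residual = signal.copy()
    while len(imfs) < max_imfs:
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        imf = _sift(residual, sd_threshold, max_sift_iterations)
        if imf is None:
            break
        imfs.append(imf)
        residual = residual - imf
    return IMFSet(original=signal, imfs=imfs, residual=residual)
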