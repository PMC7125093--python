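"""IMF selection and the four per-IMF features; per-channel 8-feature blocks.

Each EEG channel of an epoch is decomposed by EMD, the two IMFs closest to
the original signal in Minkowski distance are kept (redundant sifting modes
sit far from the signal), and each kept IMF is summarized by four features:

1. instantaneous energy — ``log10(mean(x^2))``, the overall energy level;
2. Teager energy — ``log10(mean |x[n]^2 - x[n-1] x[n+1]|)``, sensitive to
   joint amplitude/frequency modulation (Teager-Kaiser operator);
3. Higuchi fractal dimension — curve-length scaling across lags k=1..k_max;
4. Petrosian fractal dimension — sign changes of the first difference.

Two IMFs x four features give the fixed 8-feature block per channel; masked
channel blocks concatenated in montage order form the instance vector.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.distance import minkowski

from .dataset import EpochSet, FeatureCache
from .emd import IMFSet, emd_decompose

__all__ = [
    "FeatureConfig",
    "select_imfs_minkowski",
    "instantaneous_energy",
    "teager_energy",
    "higuchi_fd",
    "petrosian_fd",
    "extract_channel_features",
    "build_instance_vector",
    "compute_feature_cache",
]

FEATURE_NAMES = (
    "imf1_instantaneous_energy", "imf1_teager_energy",
    "imf1_higuchi_fd", "imf1_petrosian_fd",
    "imf2_instantaneous_energy", "imf2_teager_energy",
    "imf2_higuchi_fd", "imf2_petrosian_fd",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for decomposition, IMF selection and the four features.

    minkowski_p
        Order of the Minkowski distance ranking IMFs against the original
        signal (2 = Euclidean).
    higuchi_kmax
        Largest lag in the Higuchi curve-length regression.
    log_floor
        Lower bound inside the log10 of the two energies, guarding
        zero-energy modes.
    sift_sd_threshold, max_sift_iterations, max_imfs
        EMD sifting controls (Cauchy SD stop, per-IMF iteration cap, mode cap).
    """

    minkowski_p: float = 2.0
    higuchi_kmax: int = 10
    log_floor: float = 1e-12
    sift_sd_threshold: float = 0.2
    max_sift_iterations: int = 50
    max_imfs: int = 10

    def __post_init__(self) -> None:
        if self.minkowski_p <= 0:
            raise ValueError("minkowski_p must be > 0")
        if self.higuchi_kmax < 2:
            raise ValueError("higuchi_kmax must be >= 2")
        if self.log_floor <= 0:
            raise ValueError("log_floor must be > 0")

    def provenance(self) -> dict:
        return {"feature_order": list(FEATURE_NAMES), **asdict(self)}


def decompose(signal: np.ndarray, cfg: FeatureConfig = FeatureConfig()) -> IMFSet:
    """EMD decomposition with this configuration's sifting settings."""
    return emd_decompose(signal, sd_threshold=cfg.sift_sd_threshold,
                         max_sift_iterations=cfg.max_sift_iterations,
                         max_imfs=cfg.max_imfs)


def select_imfs_minkowski(imfset: IMFSet, p: float = 2.0) -> tuple[int, ...]:
    """Indices of the two IMFs closest to the original signal, nearest first.

    Ties break toward the lower IMF index.  With fewer than two IMFs, the
    available indices are returned (possibly an empty tuple); the fixed-width
    fallback lives in :func:`extract_channel_features`.
    """
    if imfset.n_imfs <= 2:
        return tuple(range(imfset.n_imfs))
    distances = np.array([
        minkowski(imfset.original, imf, p=p) for imf in imfset.imfs
    ])
    order = np.argsort(distances, kind="stable")
    return tuple(int(i) for i in order[:2])


def instantaneous_energy(x: np.ndarray, log_floor: float = 1e-12) -> float:
    """log10 of the mean squared amplitude (floored to avoid log of zero)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.log10(max(float(np.mean(x ** 2)), log_floor)))


def teager_energy(x: np.ndarray, log_floor: float = 1e-12) -> float:
    """log10 of the mean absolute Teager-Kaiser operator ``x[n]^2 - x[n-1]x[n+1]``."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("Teager energy needs at least 3 samples")
    op = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.log10(max(float(np.mean(np.abs(op))), log_floor)))


def higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension via curve-length scaling.

    For each lag k and offset m, the normalized curve length is

        L_m(k) = (N-1) / (floor((N-m-1)/k) * k^2) * sum_i |x[m+ik] - x[m+(i-1)k]|

    and the dimension is the negated least-squares slope of log L(k) against
    log k, with L(k) the mean over offsets.  Values land near 1 for smooth
    curves and near 2 for white noise.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max}")
    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            n_steps = (n - m - 1) // k
            if n_steps < 1:
                continue
            idx = m + np.arange(n_steps + 1) * k
            curve = np.sum(np.abs(np.diff(x[idx])))
            lengths.append(curve * (n - 1) / (n_steps * k * k))
        lk[k - 1] = np.mean(lengths)
    log_k = np.log(np.arange(1, k_max + 1))
    log_l = np.log(np.maximum(lk, 1e-300))
    slope = np.polyfit(log_k, log_l, 1)[0]
    return float(-slope)


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference.

    ``PFD = log10(N) / (log10(N) + log10(N / (N + 0.4 * N_delta)))`` where
    ``N_delta`` counts sign changes in diff(x); zero differences carry the
    previous sign, so plateaus do not register spurious changes.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError("Petrosian dimension needs at least 3 samples")
    d = np.diff(x)
    s = np.sign(d)
    for i in range(1, len(s)):
        if s[i] == 0:
            s[i] = s[i - 1]
    nz = s != 0
    s_nz = s[nz]
    n_delta = int(np.sum(s_nz[1:] != s_nz[:-1])) if s_nz.size > 1 else 0
    log_n = np.log10(n)
    return float(log_n / (log_n + np.log10(n / (n + 0.4 * n_delta))))


def _four_features(x: np.ndarray, cfg: FeatureConfig) -> list[float]:
    return [
        instantaneous_energy(x, cfg.log_floor),
        teager_energy(x, cfg.log_floor),
        higuchi_fd(x, cfg.higuchi_kmax),
        petrosian_fd(x),
    ]


def extract_channel_features(signal: np.ndarray,
                             cfg: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """Fixed 8-feature block for one channel of one epoch.

    EMD, then the two closest IMFs by Minkowski distance, then the four
    features per IMF in ascending-distance order.  If the decomposition
    yields fewer than two IMFs the closest available mode (or, for zero IMFs,
    the residual itself) is duplicated so the block keeps its fixed width —
    classifiers downstream require constant dimensionality.
    """
    imfset = decompose(np.asarray(signal, dtype=np.float64), cfg)
    if imfset.n_imfs == 0:
        modes = [imfset.residual, imfset.residual]
    elif imfset.n_imfs == 1:
        modes = [imfset.imfs[0], imfset.imfs[0]]
    else:
        first, second = select_imfs_minkowski(imfset, cfg.minkowski_p)
        modes = [imfset.imfs[first], imfset.imfs[second]]
    block = np.array(_four_features(modes[0], cfg) + _four_features(modes[1], cfg))
    return block


def build_instance_vector(epoch: np.ndarray, mask, cfg: FeatureConfig = FeatureConfig(),
                          cached_blocks: np.ndarray | None = None) -> np.ndarray:
    """Instance feature vector for one epoch restricted to a channel mask.

    ``mask`` is a set/sequence of 0-based channel indices; blocks are
    concatenated in montage (ascending index) order, giving ``8 * |mask|``
    values.  When ``cached_blocks`` (an ``(n_channels, 8)`` array for this
    epoch) is supplied the blocks are served from it instead of recomputed.
    """
    idx = sorted(int(i) for i in mask)
    if not idx:
        raise ValueError("empty channel mask")
    epoch = np.asarray(epoch, dtype=np.float64)
    if idx[0] < 0 or idx[-1] >= epoch.shape[0]:
        raise ValueError(f"mask indices out of range for {epoch.shape[0]} channels")
    if cached_blocks is not None:
        return np.concatenate([np.asarray(cached_blocks)[i] for i in idx])
    return np.concatenate([extract_channel_features(epoch[i], cfg) for i in idx])


def compute_feature_cache(epochset: EpochSet,
                          cfg: FeatureConfig = FeatureConfig()) -> FeatureCache:
    """Extract the 8-feature block for every (subject, session, epoch, channel).

    The cache is complete over all channels, so any later channel mask is
    served by slicing; extraction settings are recorded as provenance.
    """
    blocks: dict[tuple[str, str], np.ndarray] = {}
    for key, arr in epochset.epochs.items():
        n_epochs, n_channels, _ = arr.shape
        out = np.empty((n_epochs, n_channels, 8))
        for e in range(n_epochs):
            for c in range(n_channels):
                out[e, c] = extract_channel_features(arr[e, c], cfg)
        blocks[key] = out
    return FeatureCache(montage=epochset.montage, blocks=blocks,
                        provenance=cfg.provenance())
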