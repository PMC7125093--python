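"""Common average reference (CAR) re-referencing.

CAR subtracts, at every sample, the mean over all recorded electrodes from
each channel: ``V_i^CAR[t] = V_i[t] - (1/n) * sum_j V_j[t]``.  It removes the
information common to all electrodes and improves signal-to-noise before
feature extraction.

CAR is always computed over the full montage, before any channel selection,
so per-channel feature caches stay valid for every candidate channel mask.
It is applied per epoch, matching the epoch-wise processing of the rest of
the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import EpochSet


@dataclass(frozen=True)
class CARConfig:
    """Whether to apply common average referencing (disable for ablation)."""

    apply: bool = True


def common_average_reference(epoch: np.ndarray) -> np.ndarray:
    """Re-reference one epoch (channels x samples) to the common average.

    Raises
    ------
    ValueError
        If the epoch has fewer than 2 channel rows (the common average of a
        single channel would simply zero it) or non-finite values.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError(f"expected channels x samples matrix, got shape {epoch.shape}")
    if epoch.shape[0] < 2:
        raise ValueError("CAR needs at least 2 channels")
    if not np.all(np.isfinite(epoch)):
        raise ValueError("epoch contains non-finite values")
    return epoch - epoch.mean(axis=0, keepdims=True)


def apply_car(epochset: EpochSet, config: CARConfig = CARConfig()) -> EpochSet:
    """Return a copy of ``epochset`` with every epoch re-referenced.

    With ``config.apply`` false the input is returned unchanged (same object).
    """
    if not config.apply:
        return epochset
    referenced = {
        key: arr - arr.mean(axis=1, keepdims=True)
        for key, arr in epochset.epochs.items()
    }
    return EpochSet(montage=epochset.montage, sampling_rate=epochset.sampling_rate,
                    epochs=referenced)
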