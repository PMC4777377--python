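"""Epoch reintegration: collapse fine-epoch counts into coarser epochs.

Consecutive blocks of ``k = target / source`` epochs are summed per axis,
emulating how count exports are reintegrated after collection. Blocks are
aligned to the series start (the reader and simulator pin starts to epoch 0
of a calendar day, so 60-s blocks align with clock minutes — the wear-time
algorithms are minute-defined). A trailing partial block is dropped rather
than padded. The vector magnitude is recomputed from the summed axes, not
summed: the norm of a sum is not the sum of norms.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io_actigraph import VALID_EPOCHS, CountSeries, compute_vm

__all__ = ["EpochIncompatibleError", "reintegrate"]


class EpochIncompatibleError(ValueError):
    """Target epoch is finer than, or not a multiple of, the source epoch."""


def _block_sum(arr: np.ndarray, k: int) -> np.ndarray:
    n = (len(arr) // k) * k
    if n == 0:
        return arr[:0].copy()
    return arr[:n].reshape(-1, k).sum(axis=1)


def reintegrate(series: CountSeries, target_epoch: int) -> CountSeries:
    """Collapse ``series`` to ``target_epoch`` seconds per epoch.

    ``target_epoch`` must be one of {1, 5, 10, 15, 30, 60} and an integer
    multiple of the source epoch. Returns the series unchanged (as a copy)
    when the target equals the source epoch.
    """
    if target_epoch not in VALID_EPOCHS:
        raise EpochIncompatibleError(
            f"target epoch must be one of {VALID_EPOCHS}, got {target_epoch}"
        )
    src = series.epoch_length
    if target_epoch < src:
        raise EpochIncompatibleError(
            f"cannot reintegrate {src}-s epochs to finer {target_epoch}-s epochs"
        )
    if target_epoch % src != 0:
        raise EpochIncompatibleError(
            f"{target_epoch}-s target is not a multiple of the {src}-s source epoch"
        )
    k = target_epoch // src
    if k == 1:
        return replace(series)
    a1 = _block_sum(series.axis1, k)
    a2 = _block_sum(series.axis2, k)
    a3 = _block_sum(series.axis3, k)
    return CountSeries(
        start_time=series.start_time,
        epoch_length=target_epoch,
        axis1=a1,
        axis2=a2,
        axis3=a3,
        vm=compute_vm(a1, a2, a3),
        subject_id=series.subject_id,
    )
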