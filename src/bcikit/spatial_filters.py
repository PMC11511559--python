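"""Spatial re-referencing of epochs: common average reference and surface
Laplacian.

Both filters are per-sample linear maps across channels.  CAR subtracts the
instantaneous mean of all electrodes from every electrode; the surface
Laplacian subtracts the mean of each electrode's small (immediate) or large
(next-nearest) neighbor set, sharpening spatial focus over sensorimotor
cortex.  Neighbor sets come from a :class:`~bcikit.eeg_core.Montage`.

The neighbor average is unweighted by default; inverse-distance weighting
is available behind a flag.  Edge electrodes with fewer than the nominal
neighbor count use whatever neighbors they have, so the channel count is
preserved for downstream fixed-length feature vectors.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .eeg_core import Epoch, Montage

__all__ = ["car", "laplacian", "apply_spatial"]


def car(epoch: Epoch) -> Epoch:
    """Common average reference: subtract the per-sample channel mean."""
    if epoch.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    out = epoch.data - epoch.data.mean(axis=0, keepdims=True)
    return replace(epoch, data=out)


def laplacian(
    epoch: Epoch,
    montage: Montage,
    size: str = "small",
    weighted: bool = False,
) -> Epoch:
    """Surface Laplacian: subtract the (small or large) neighbor mean.

    ``weighted=True`` uses inverse-distance weights instead of a plain mean.
    Channels must all be present in the montage; each needs at least one
    neighbor of the requested size.
    """
    if size not in ("small", "large"):
        raise ValueError("size must be 'small' or 'large'")
    if epoch.channel_labels is None:
        raise ValueError("epoch carries no channel labels; montage lookup impossible")
    labels = epoch.channel_labels
    missing = [lab for lab in labels if lab not in montage.positions]
    if missing:
        raise KeyError(f"channels absent from montage: {missing}")
    index = {lab: i for i, lab in enumerate(labels)}
    out = np.empty_like(epoch.data)
    for i, lab in enumerate(labels):
        nbrs = [n for n in montage.neighbors(lab, size) if n in index]
        if not nbrs:
            raise ValueError(f"channel {lab} has no {size} neighbors in this epoch")
        rows = epoch.data[[index[n] for n in nbrs]]
        if weighted:
            p0 = np.asarray(montage.positions[lab])
            d = np.array(
                [np.hypot(*(np.asarray(montage.positions[n]) - p0)) for n in nbrs]
            )
            w = 1.0 / np.maximum(d, 1e-12)
            w /= w.sum()
            ref = w @ rows
        else:
            ref = rows.mean(axis=0)
        out[i] = epoch.data[i] - ref
    return replace(epoch, data=out)


def apply_spatial(
    epoch: Epoch,
    montage: Montage | None = None,
    use_car: bool = True,
    laplacian_size: str | None = "small",
    weighted: bool = False,
) -> Epoch:
    """Apply the configured spatial chain: CAR first, then Laplacian.

    Either stage can be switched off (``use_car=False`` /
    ``laplacian_size=None``).
    """
    out = epoch
    if use_car:
        out = car(out)
    if laplacian_size is not None:
        if montage is None:
            raise ValueError("laplacian requested but no montage given")
        out = laplacian(out, montage, size=laplacian_size, weighted=weighted)
    return out
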