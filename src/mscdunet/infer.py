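"""Full-volume prediction: overlapping patches + majority voting.

The volume is swept by a 3-D lattice of patch windows with a fixed
stride (clipped so the final window touches the far edge of each
axis). Every window is segmented independently and each voxel's final
label is the most frequent label among the windows that cover it,
ties broken toward the smallest class index. Volumes smaller than the
patch along any axis are edge-padded and the padding cropped from the
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_prep import LabelMap, Volume
from .network import MSCDUNet, predict_labels
from .nn import functional as F

__all__ = ["VotingGrid", "window_starts", "predict_volume"]


@dataclass
class VotingGrid:
    """Per-class vote counts and per-voxel window coverage."""

    counts: np.ndarray  # (n_classes, D, H, W)
    coverage: np.ndarray  # (D, H, W)


def window_starts(extent: int, patch: int, stride: int):
    """Start offsets of the sliding windows along one axis.

    The regular lattice 0, stride, 2*stride, ... is clipped at
    extent - patch, which is appended when it does not already lie on
    the lattice, so every voxel is covered.
    """
    if extent < patch:
        raise ValueError(
            f"extent {extent} smaller than patch {patch}; pad the volume first"
        )
    if not 1 <= stride <= patch:
        raise ValueError(
            f"stride must lie in [1, patch]; stride {stride} > patch {patch} "
            "would leave voxels uncovered"
        )
    last = extent - patch
    starts = list(range(0, last + 1, stride))
    if starts[-1] != last:
        starts.append(last)
    return starts


def predict_volume(
    model: MSCDUNet,
    volumes,
    patch: int = None,
    stride: int = 8,
    batch_windows: int = 8,
    mode: str = "vote",
):
    """Segment a full multi-modality volume; returns (LabelMap, VotingGrid).

    ``mode='vote'`` tallies hard per-window labels (majority voting);
    ``mode='prob'`` accumulates softmax probabilities instead.
    """
    if patch is None:
        patch = model.cfg.patch_size
    if len(volumes) != model.cfg.n_modalities:
        raise ValueError(
            f"model expects {model.cfg.n_modalities} modalities, got {len(volumes)}"
        )
    if mode not in ("vote", "prob"):
        raise ValueError(f"unknown voting mode {mode!r}")
    shape = volumes[0].data.shape
    for v in volumes:
        if v.data.shape != shape:
            raise ValueError("all modalities must share a voxel grid")
    pad = [max(0, patch - e) for e in shape]
    padded = [
        np.pad(v.data, [(0, p) for p in pad], mode="edge") if any(pad) else v.data
        for v in volumes
    ]
    pshape = padded[0].shape
    n_classes = model.cfg.n_classes
    dtype = model.fusion_weights.value.dtype
    counts = np.zeros((n_classes,) + pshape, dtype=np.float64)
    coverage = np.zeros(pshape, dtype=np.int64)

    model.eval()
    windows = list(
        product(*(window_starts(e, patch, stride) for e in pshape))
    )
    for i in range(0, len(windows), batch_windows):
        chunk = windows[i : i + batch_windows]
        crops = np.stack(
            [
                np.stack(
                    [
                        v[d : d + patch, h : h + patch, w : w + patch]
                        for v in padded
                    ]
                )
                for (d, h, w) in chunk
            ]
        )
        outputs = model.forward(crops.astype(dtype))
        if mode == "vote":
            labels = predict_labels(outputs)
            for j, (d, h, w) in enumerate(chunk):
                onehot = labels[j][None] == np.arange(n_classes)[:, None, None, None]
                counts[
                    :, d : d + patch, h : h + patch, w : w + patch
                ] += onehot
                coverage[d : d + patch, h : h + patch, w : w + patch] += 1
        else:
            probs = F.softmax(outputs.fused_logits.value)
            for j, (d, h, w) in enumerate(chunk):
                counts[
                    :, d : d + patch, h : h + patch, w : w + patch
                ] += probs[j]
                coverage[d : d + patch, h : h + patch, w : w + patch] += 1

    final = np.argmax(counts, axis=0).astype(np.int16)
    crop = tuple(slice(0, e) for e in shape)
    grid = VotingGrid(
        counts=counts[(slice(None),) + crop]
        if mode == "prob"
        else counts[(slice(None),) + crop].astype(np.int64),
        coverage=coverage[crop],
    )
    return (
        LabelMap(data=final[crop], spacing=volumes[0].spacing, n_classes=n_classes),
        grid,
    )
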