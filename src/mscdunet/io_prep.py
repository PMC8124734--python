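"""Volume containers, NIfTI I/O, intensity normalization, patch
sampling and training-time augmentation.

Normalization follows the three-step scheme used for multi-center MR
data: subtract a heavily Gaussian-smoothed copy (removes smooth
background/inhomogeneity), apply contrast-limited adaptive histogram
equalization (CLAHE) to boost local contrast, then z-score the result
to zero mean / unit standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "Volume",
    "LabelMap",
    "Patch",
    "PatchBatch",
    "DegenerateVolumeError",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "normalize_volume",
    "sample_patch",
    "AugmentParams",
    "augment",
]


class DegenerateVolumeError(ValueError):
    """Raised when an operation is undefined on a constant volume."""


class AlignmentError(ValueError):
    """Raised when volumes/labels do not share a voxel grid."""


@dataclass
class Volume:
    """One modality's 3-D intensity grid with voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    modality: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume data must be finite everywhere")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive on all axes")


@dataclass
class LabelMap:
    """Integer tissue labels aligned with its volumes.

    Convention used package-wide: 0 = background/other, 1 = gray
    matter, 2 = white matter, 3 = cerebrospinal fluid.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    n_classes: int = 4

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer")
        if self.data.size and (self.data.min() < 0 or self.data.max() >= self.n_classes):
            raise ValueError(
                f"labels must lie in [0, {self.n_classes - 1}]"
            )


@dataclass
class Patch:
    """Same-center multi-modal crop: inputs (M, p, p, p), target (p, p, p)."""

    inputs: np.ndarray
    target: np.ndarray
    center: np.ndarray


@dataclass
class PatchBatch:
    inputs: np.ndarray  # (B, M, p, p, p)
    targets: np.ndarray  # (B, p, p, p)
    centers: np.ndarray  # (B, 3)

    @classmethod
    def stack(cls, patches):
        return cls(
            inputs=np.stack([p.inputs for p in patches]),
            targets=np.stack([p.target for p in patches]),
            centers=np.stack([p.center for p in patches]),
        )


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path, modality="") -> Volume:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data=data, spacing=spacing, modality=modality)


def write_volume(path, v: Volume):
    affine = np.diag(list(v.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(v.data, dtype=np.float32), affine), str(path))


def read_labelmap(path, n_classes=4) -> LabelMap:
    img = nib.load(str(path))
    data = np.rint(np.asarray(img.get_fdata())).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(data=data, spacing=spacing, n_classes=n_classes)


def write_labelmap(path, lm: LabelMap):
    affine = np.diag(list(lm.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(lm.data, dtype=np.int16), affine), str(path))


# ---------------------------------------------------------------------------
# normalization

def normalize_volume(
    v: Volume,
    smooth_sigma: float = 8.0,
    clahe_clip: float = 0.01,
    clahe_tiles=(8, 8, 8),
    clahe_mode: str = "3d",
) -> Volume:
    """Smooth-subtract, CLAHE, then z-score one volume.

    ``smooth_sigma`` is in voxels; ``clahe_tiles`` is the number of
    tiles per axis; ``clahe_mode`` selects volumetric CLAHE ("3d") or
    per-axial-slice CLAHE ("2d").
    """
    if smooth_sigma <= 0:
        raise ValueError("smooth_sigma must be positive")
    a = np.asarray(v.data, dtype=np.float64)
    res = a - ndimage.gaussian_filter(a, smooth_sigma)
    lo, hi = res.min(), res.max()
    if hi == lo:
        raise DegenerateVolumeError(
            "volume is constant after background subtraction"
        )
    res01 = (res - lo) / (hi - lo)
    if clahe_mode == "3d":
        kernel = tuple(max(1, s // t) for s, t in zip(res01.shape, clahe_tiles))
        eq = exposure.equalize_adapthist(res01, kernel_size=kernel, clip_limit=clahe_clip)
    elif clahe_mode == "2d":
        kernel = tuple(max(1, s // t) for s, t in zip(res01.shape[:2], clahe_tiles[:2]))
        eq = np.empty_like(res01)
        for z in range(res01.shape[2]):
            eq[:, :, z] = exposure.equalize_adapthist(
                res01[:, :, z], kernel_size=kernel, clip_limit=clahe_clip
            )
    else:
        raise ValueError(f"unknown clahe_mode {clahe_mode!r}")
    std = eq.std()
    if std == 0:
        raise DegenerateVolumeError("volume has zero variance after enhancement")
    out = (eq - eq.mean()) / std
    return Volume(data=out, spacing=v.spacing, modality=v.modality)


# ---------------------------------------------------------------------------
# patch sampling

def sample_patch(volumes, labels: LabelMap, patch_size: int, rng) -> Patch:
    """Crop one same-center sub-volume per modality plus the label crop.

    The crop start is drawn uniformly over all fully-inside positions.
    """
    shape = labels.data.shape
    for v in volumes:
        if v.data.shape != shape:
            raise AlignmentError(
                f"volume grid {v.data.shape} does not match labels {shape}"
            )
    if any(e < patch_size for e in shape):
        raise ValueError(
            f"grid {shape} is smaller than patch size {patch_size}"
        )
    start = np.array(
        [rng.integers(0, e - patch_size + 1) for e in shape], dtype=np.intp
    )
    sl = tuple(slice(s, s + patch_size) for s in start)
    inputs = np.stack([v.data[sl] for v in volumes])
    return Patch(
        inputs=inputs,
        target=np.ascontiguousarray(labels.data[sl]),
        center=start + patch_size // 2,
    )


# ---------------------------------------------------------------------------
# augmentation

@dataclass
class AugmentParams:
    """Probabilities and magnitudes of the geometric augmentations.

    Angles in degrees, shifts in voxels; the same transform is applied
    to every modality and (with nearest-neighbor sampling) to the
    label crop.
    """

    p_flip: float = 0.5
    p_rotate: float = 0.5
    rotate_max_deg: float = 10.0
    p_zoom: float = 0.5
    zoom_range: tuple = (0.9, 1.1)
    p_shift: float = 0.5
    shift_max: float = 4.0
    p_elastic: float = 0.5
    elastic_alpha: float = 1.5
    elastic_sigma: float = 3.0


def _rotation_matrix(axis_pair, angle_rad):
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    m = np.eye(3)
    i, j = axis_pair
    m[i, i] = c
    m[i, j] = -s
    m[j, i] = s
    m[j, j] = c
    return m


def augment(patch: Patch, rng, params: AugmentParams = None) -> Patch:
    """Randomly flip / rotate / zoom / shift / elastically deform a patch.

    All random draws happen unconditionally so the rng consumption (and
    hence determinism) does not depend on which transforms fire.
    """
    if params is None:
        params = AugmentParams()
    shape = patch.target.shape

    flips = rng.random(3) < params.p_flip
    do_rot = rng.random() < params.p_rotate
    rot_pair = tuple(rng.choice(3, size=2, replace=False))
    rot_angle = np.deg2rad(rng.uniform(-params.rotate_max_deg, params.rotate_max_deg))
    do_zoom = rng.random() < params.p_zoom
    zoom = rng.uniform(*params.zoom_range)
    do_shift = rng.random() < params.p_shift
    shift = rng.uniform(-params.shift_max, params.shift_max, size=3)
    do_elastic = rng.random() < params.p_elastic
    noise = rng.standard_normal((3,) + shape)

    inputs = patch.inputs
    target = patch.target
    if flips.any():
        axes = tuple(int(a) for a in np.nonzero(flips)[0])
        inputs = np.flip(inputs, axis=tuple(a + 1 for a in axes))
        target = np.flip(target, axis=axes)

    if not (do_rot or do_zoom or do_shift or do_elastic):
        return Patch(inputs=inputs.copy(), target=target.copy(), center=patch.center)

    mat = np.eye(3)
    if do_rot:
        mat = _rotation_matrix(rot_pair, rot_angle) @ mat
    if do_zoom:
        # sampling grid scaled by 1/zoom magnifies the content by `zoom`
        mat = mat / zoom
    center = (np.array(shape) - 1) / 2.0
    grid = np.indices(shape, dtype=np.float64)
    coords = np.tensordot(mat, grid - center.reshape(3, 1, 1, 1), axes=(1, 0))
    coords += center.reshape(3, 1, 1, 1)
    if do_shift:
        coords -= shift.reshape(3, 1, 1, 1)
    if do_elastic:
        disp = np.stack(
            [
                ndimage.gaussian_filter(noise[i], params.elastic_sigma)
                for i in range(3)
            ]
        )
        disp *= params.elastic_alpha / max(np.abs(disp).max(), 1e-12)
        coords += disp

    out_inputs = np.stack(
        [
            ndimage.map_coordinates(ch, coords, order=1, mode="nearest")
            for ch in inputs
        ]
    )
    out_target = ndimage.map_coordinates(target, coords, order=0, mode="nearest")
    return Patch(inputs=out_inputs, target=out_target, center=patch.center)
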