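"""Synthetic multi-modality brain phantoms with ground-truth labels.

The phantom is a set of nested, radially perturbed shells: white
matter innermost, wrapped by gray matter, wrapped by cerebrospinal
fluid, embedded in background. Each modality draws voxel intensities
class-conditionally from a configurable (mean, std) table, multiplies
by a smooth multiplicative bias field (MR-style inhomogeneity) and
adds Gaussian noise. Adjacent-class intensity distributions overlap
(about 1.5 pooled standard deviations apart by default) so that the
segmentation task is non-trivial at tissue boundaries, mimicking the
GM/WM ambiguity at rugged cortical edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_prep import LabelMap, Volume

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "phantom_dataset",
    "DEFAULT_CLASS_INTENSITY",
    "MODALITY_NAMES",
]

MODALITY_NAMES = ("T1", "T1_IR", "FLAIR")

# (mean, std) per class per modality; class order: background, GM, WM, CSF.
# Contrast orderings differ between modalities so multi-modal input is
# genuinely informative; adjacent tissue classes sit ~1.5 pooled std apart
# once the default additive noise is included.
DEFAULT_CLASS_INTENSITY = np.array(
    [
        # T1-like       T1_IR-like    FLAIR-like
        [(10.0, 10.0), (10.0, 10.0), (10.0, 10.0)],  # background/other
        [(70.0, 10.0), (62.0, 10.0), (65.0, 10.0)],  # gray matter
        [(87.0, 10.0), (45.0, 10.0), (48.0, 10.0)],  # white matter
        [(53.0, 10.0), (79.0, 10.0), (25.0, 10.0)],  # CSF
    ]
)


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    n_modalities: int = 3
    class_intensity: np.ndarray = None
    shell_radii: tuple = (28.0, 22.0, 14.0)  # CSF, GM, WM outer radii (voxels)
    surface_irregularity: float = 2.0
    bias_amplitude: float = 0.2
    noise_std: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.class_intensity is None:
            self.class_intensity = DEFAULT_CLASS_INTENSITY[:, : self.n_modalities]
        self.class_intensity = np.asarray(self.class_intensity, dtype=np.float64)
        if not 1 <= self.n_modalities <= 3:
            raise ValueError("n_modalities must be in [1, 3]")
        if self.class_intensity.shape[:2] != (4, self.n_modalities):
            raise ValueError(
                "class_intensity must have 4 rows (background/GM/WM/CSF) "
                f"per modality; got shape {self.class_intensity.shape}"
            )
        if not np.all(np.isfinite(self.class_intensity)):
            raise ValueError("class_intensity parameters must be finite")
        if any(e < 32 for e in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} too small: every axis must be "
                ">= 32 so that training patches fit"
            )
        r = self.shell_radii
        if not (r[0] > r[1] > r[2] > 0):
            raise ValueError("shell_radii must be strictly decreasing and positive")
        if r[0] >= min(self.grid_shape) / 2:
            raise ValueError("all shell radii must be < min(grid_shape)/2")
        if min(self.surface_irregularity, self.bias_amplitude, self.noise_std) < 0:
            raise ValueError("irregularity/bias/noise amplitudes must be >= 0")


def _smooth_field(shape, sigma, rng):
    """Zero-mean, unit-std low-frequency random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    f -= f.mean()
    std = f.std()
    return f / std if std > 0 else f


def _label_field(spec: PhantomSpec, rng) -> np.ndarray:
    shape = spec.grid_shape
    center = (np.array(shape) - 1) / 2.0
    grid = np.indices(shape, dtype=np.float64)
    r = np.sqrt(((grid - center.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
    if spec.surface_irregularity > 0:
        r = r + spec.surface_irregularity * _smooth_field(
            shape, min(shape) / 8.0, rng
        )
    else:
        # keep rng consumption identical either way
        _smooth_field(shape, min(shape) / 8.0, rng)
    csf_r, gm_r, wm_r = spec.shell_radii
    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= csf_r] = 3  # CSF shell (outermost brain layer)
    labels[r <= gm_r] = 1  # gray matter
    labels[r <= wm_r] = 2  # white matter core
    return labels


def generate_phantom(spec: PhantomSpec):
    """Generate ``spec.n_modalities`` volumes and the label map.

    Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _label_field(spec, rng)
    shape = spec.grid_shape
    volumes = []
    for m in range(spec.n_modalities):
        means = spec.class_intensity[:, m, 0][labels]
        stds = spec.class_intensity[:, m, 1][labels]
        img = means + stds * rng.standard_normal(shape)
        if spec.bias_amplitude > 0:
            bias = np.exp(
                spec.bias_amplitude * _smooth_field(shape, min(shape) / 4.0, rng)
            )
            img = img * bias
        else:
            _smooth_field(shape, min(shape) / 4.0, rng)
        if spec.noise_std > 0:
            img = img + spec.noise_std * rng.standard_normal(shape)
        else:
            rng.standard_normal(shape)
        volumes.append(
            Volume(data=img, spacing=spec.spacing, modality=MODALITY_NAMES[m])
        )
    return volumes, LabelMap(data=labels, spacing=spec.spacing, n_classes=4)


def phantom_dataset(spec: PhantomSpec, n_subjects: int, seed: int):
    """n_subjects phantoms with per-subject seeds and jittered radii.

    Subject i uses seed ``seed + i``; its shell radii are scaled by a
    common factor in [0.92, 1.0] plus a small per-shell jitter, so
    subjects differ in anatomy while shell ordering is preserved.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = []
    for i in range(n_subjects):
        sub_seed = seed + i
        jrng = np.random.default_rng(sub_seed)
        scale = jrng.uniform(0.92, 1.0)
        jitter = jrng.uniform(0.98, 1.02, size=3)
        radii = tuple(r * scale * j for r, j in zip(spec.shell_radii, jitter))
        if not radii[0] > radii[1] > radii[2]:
            radii = tuple(sorted(radii, reverse=True))
        sub_spec = replace(spec, shell_radii=radii, seed=sub_seed)
        out.append(generate_phantom(sub_spec))
    return out
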