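"""CT volume -> normalized 5-slice model input.

Deterministic pipeline: resample the scan to a consistent spatial resolution
of 0.75 x 0.75 mm in-plane and 2.5 mm between slices (trilinear), window the
Hounsfield intensities to [-150, 150] HU to highlight soft-tissue contrast
and rescale to [0, 1], then extract five consecutive axial slices centered
on the largest tumor cross-section with a 160 x 160 in-plane crop centered
on that section's mask centroid. A configurable augmentation policy
(reflections, translation, blur, sharpening, Laplacian enhancement) is
applied on the fly to training batches only.

Volumes are indexed (z, y, x), 0-based; NIfTI I/O goes through nibabel with
the voxel spacing carried on the affine diagonal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "SliceStack",
    "AugmentPolicy",
    "HU_WINDOW",
    "TARGET_SPACING",
    "resample",
    "window_normalize",
    "select_slices",
    "augment",
    "preprocess_volume",
]

HU_WINDOW = (-150.0, 150.0)
TARGET_SPACING = (2.5, 0.75, 0.75)  # (z, y, x) mm
N_SLICES = 5
CROP_SIZE = 160


@dataclass
class ImageVolume:
    """A scalar 3-D image on a regular grid.

    ``voxels`` is (z, y, x); ``spacing``/``origin`` are mm triples in the
    same axis order.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (z, y, x)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxels must be finite")

    def to_nifti(self, path) -> None:
        # nibabel expects (x, y, z); spacing rides on the affine diagonal
        data = np.ascontiguousarray(self.voxels.transpose(2, 1, 0))
        sz, sy, sx = self.spacing
        oz, oy, ox = self.origin
        affine = np.diag([sx, sy, sz, 1.0])
        affine[:3, 3] = [ox, oy, oz]
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path) -> "ImageVolume":
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=np.float64).transpose(2, 1, 0)
        zooms = img.header.get_zooms()[:3]  # (x, y, z)
        offset = img.affine[:3, 3]
        return cls(data, spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
                   origin=(float(offset[2]), float(offset[1]), float(offset[0])))


@dataclass
class SliceStack:
    """Model input: 5 axial planes, 160 x 160, values in [0, 1]."""

    planes: np.ndarray
    source_slice_indices: tuple[int, ...]
    crop_center: tuple[int, int]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ValueError("planes must be (k, crop, crop)")
        if self.planes.min() < -1e-9 or self.planes.max() > 1 + 1e-9:
            raise ValueError("plane values must lie in [0, 1]")

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, planes=self.planes)
        sidecar = {"source_slice_indices": list(self.source_slice_indices),
                   "crop_center": list(self.crop_center)}
        with open(path.with_suffix(".json"), "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, path) -> "SliceStack":
        path = Path(path)
        with np.load(path) as data:
            planes = data["planes"]
        with open(path.with_suffix(".json")) as fh:
            meta = json.load(fh)
        return cls(planes, tuple(meta["source_slice_indices"]),
                   tuple(meta["crop_center"]))


def resample(volume: ImageVolume,
             target_spacing: tuple[float, float, float] = TARGET_SPACING,
             is_mask: bool = False) -> ImageVolume:
    """Resample onto ``target_spacing`` (trilinear; masks nearest-neighbor).

    Output index j on each axis maps to input coordinate j * target / source,
    so the output grid covers the input physical extent (edge-clamped).
    Masks are re-binarized at 0.5 after interpolation.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target_spacing must be positive, got {target_spacing}")
    src = np.asarray(volume.spacing, dtype=float)
    tgt = np.asarray(target_spacing, dtype=float)
    if np.allclose(src, tgt):
        return ImageVolume(volume.voxels.copy(), tuple(tgt), volume.origin)
    out_shape = tuple(int(np.ceil(n * s / t)) for n, s, t in
                      zip(volume.voxels.shape, src, tgt))
    grids = np.meshgrid(*[np.arange(n) * t / s for n, s, t in
                          zip(out_shape, src, tgt)], indexing="ij")
    order = 0 if is_mask else 1
    out = ndimage.map_coordinates(volume.voxels, np.array(grids), order=order,
                                  mode="nearest")
    if is_mask:
        out = (out > 0.5).astype(np.float64)
    return ImageVolume(out, tuple(tgt), volume.origin)


def window_normalize(volume: ImageVolume,
                     window: tuple[float, float] = HU_WINDOW) -> ImageVolume:
    """Clip HU to ``window`` and map affinely onto [0, 1]."""
    lo, hi = window
    out = (np.clip(volume.voxels, lo, hi) - lo) / (hi - lo)
    return ImageVolume(out, volume.spacing, volume.origin)


def select_slices(volume: ImageVolume, mask: ImageVolume,
                  k: int = N_SLICES, crop: int = CROP_SIZE) -> SliceStack:
    """Crop ``k`` consecutive slices around the largest tumor cross-section.

    The anchor is the axial slice with maximal in-plane mask area; the crop
    is centered on the anchor-slice mask centroid (rounded to whole voxels).
    Slices beyond the volume are replaced by the nearest edge slice;
    out-of-plane crop regions are zero-padded (the post-normalization floor).
    """
    m = mask.voxels > 0.5
    if not m.any():
        raise ValueError("tumor not identified: mask is empty")
    if volume.voxels.shape != m.shape:
        raise ValueError("volume and mask shapes differ")
    areas = m.sum(axis=(1, 2))
    anchor = int(np.argmax(areas))
    nz = volume.voxels.shape[0]
    indices = tuple(int(np.clip(anchor + off, 0, nz - 1))
                    for off in range(-(k // 2), k - k // 2))
    ys, xs = np.nonzero(m[anchor])
    cy, cx = int(round(ys.mean())), int(round(xs.mean()))
    half = crop // 2
    planes = np.zeros((k, crop, crop))
    ny, nx = volume.voxels.shape[1:]
    y0, y1 = cy - half, cy - half + crop
    x0, x1 = cx - half, cx - half + crop
    sy0, sy1 = max(y0, 0), min(y1, ny)
    sx0, sx1 = max(x0, 0), min(x1, nx)
    for i, z in enumerate(indices):
        planes[i, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = \
            volume.voxels[z, sy0:sy1, sx0:sx1]
    return SliceStack(np.clip(planes, 0.0, 1.0), indices, (cy, cx))


@dataclass
class AugmentPolicy:
    """Per-transform application probabilities and parameter ranges.

    Geometric transforms (reflections, translation) are drawn once and
    applied identically to all planes to preserve cross-slice coherence.
    """

    p_flip_lr: float = 0.5
    p_flip_ap: float = 0.5
    p_translate: float = 0.5
    max_translate: float = 8.0        # voxels, each in-plane axis
    p_blur: float = 0.25
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    p_sharpen: float = 0.25
    sharpen_strength_range: tuple[float, float] = (0.3, 1.0)
    p_laplacian: float = 0.25
    laplacian_strength_range: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        for name in ("p_flip_lr", "p_flip_ap", "p_translate", "p_blur",
                     "p_sharpen", "p_laplacian"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentPolicy":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, (0.5, 1.5), 0.0, (0.3, 1.0),
                   0.0, (0.2, 0.8))

    @classmethod
    def flips_only(cls) -> "AugmentPolicy":
        """Reflections only: the safe subset for texture-amplitude phantoms,
        where blur/sharpening would alter the class-defining signal."""
        return cls(0.5, 0.5, 0.0, 0.0, 0.0, (0.5, 1.5), 0.0, (0.3, 1.0),
                   0.0, (0.2, 0.8))


def augment(stack: SliceStack | np.ndarray, policy: AugmentPolicy,
            rng: np.random.Generator) -> SliceStack | np.ndarray:
    """Apply the augmentation policy; returns the same type as the input."""
    planes = stack.planes if isinstance(stack, SliceStack) else np.asarray(stack)
    out = planes.copy()
    if rng.random() < policy.p_flip_lr:
        out = out[:, :, ::-1]
    if rng.random() < policy.p_flip_ap:
        out = out[:, ::-1, :]
    if rng.random() < policy.p_translate:
        dy, dx = rng.uniform(-policy.max_translate, policy.max_translate, size=2)
        out = np.stack([ndimage.shift(p, (dy, dx), order=1, cval=0.0) for p in out])
    if rng.random() < policy.p_blur:
        sigma = rng.uniform(*policy.blur_sigma_range)
        out = np.stack([ndimage.gaussian_filter(p, sigma) for p in out])
    if rng.random() < policy.p_sharpen:
        s = rng.uniform(*policy.sharpen_strength_range)
        blurred = np.stack([ndimage.gaussian_filter(p, 1.0) for p in out])
        out = out + s * (out - blurred)
    if rng.random() < policy.p_laplacian:
        s = rng.uniform(*policy.laplacian_strength_range)
        out = out - s * np.stack([ndimage.laplace(p) for p in out])
    out = np.clip(np.ascontiguousarray(out), 0.0, 1.0)
    if isinstance(stack, SliceStack):
        return SliceStack(out, stack.source_slice_indices, stack.crop_center)
    return out


def preprocess_volume(volume: ImageVolume, mask: ImageVolume,
                      target_spacing: tuple[float, float, float] = TARGET_SPACING,
                      window: tuple[float, float] = HU_WINDOW,
                      k: int = N_SLICES, crop: int = CROP_SIZE) -> SliceStack:
    """Full deterministic pipeline: resample -> window -> slice selection."""
    vol = window_normalize(resample(volume, target_spacing), window)
    msk = resample(mask, target_spacing, is_mask=True)
    return select_slices(vol, msk, k=k, crop=crop)
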