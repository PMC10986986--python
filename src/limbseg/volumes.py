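"""Image and label volume containers and limb preprocessing.

Volumes are 3D voxel grids with physical spacing in mm.  The package-wide
axis convention is ``(axial, row, column)``: axis 0 runs along the limb with
slice 0 the most proximal (hip) slice, and axis 2 is the left-right
in-plane direction.  NIfTI files are read and written through nibabel; on
disk the axes follow NIfTI's ``(x, y, z)`` order and are transposed on load.

Preprocessing mirrors how multi-sequence lower-limb MRI is prepared for
2D slice-wise networks: each acquisition sequence (hip / thigh / knee /
shank) is resampled to isotropic 1 mm spacing, the sequences are stacked
into one continuous hip-to-ankle volume by padding the in-plane fields of
view with zeros, and left limbs are mirrored so that all limbs share one
anatomical orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .schema import MuscleSchema, N_MUSCLE_CLASSES

Triple = tuple[float, float, float]


def _check_geometry(spacing: Sequence[float], voxels: np.ndarray) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={voxels.ndim}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")


@dataclass
class ImageVolume:
    """Greyscale 3D image: voxels (axial, row, column) + spacing in mm."""

    voxels: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    axial_axis: int = 0
    origin_offset: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_geometry(self.spacing, self.voxels)
        if self.axial_axis != 0:
            raise ValueError("axis order is fixed (axial, row, column); axial_axis must be 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin_offset = tuple(float(o) for o in self.origin_offset)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def same_geometry(self, other: "ImageVolume | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and self.axial_axis == other.axial_axis
        )


@dataclass
class LabelVolume:
    """Integer class map: 0 = background, 1..37 = muscle class ids."""

    labels: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    axial_axis: int = 0
    origin_offset: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.min(initial=0) < 0 or labels.max(initial=0) > N_MUSCLE_CLASSES:
            raise ValueError("label values must lie in 0..37")
        self.labels = labels.astype(np.uint8)
        _check_geometry(self.spacing, self.labels)
        if self.axial_axis != 0:
            raise ValueError("axis order is fixed (axial, row, column); axial_axis must be 0")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin_offset = tuple(float(o) for o in self.origin_offset)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def same_geometry(self, other: "ImageVolume | LabelVolume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and self.axial_axis == other.axial_axis
        )


# ---------------------------------------------------------------------------
# NIfTI I/O.  Our (axial, row, column) axis 0 maps to the last on-disk axis.


def save_nifti(volume: ImageVolume | LabelVolume, path: str) -> None:
    data = volume.voxels if isinstance(volume, ImageVolume) else volume.labels
    arr = np.transpose(data, (2, 1, 0))
    affine = np.diag([*volume.spacing[::-1], 1.0])
    affine[:3, 3] = volume.origin_offset[::-1]
    nib.save(nib.Nifti1Image(arr, affine), path)


def _load(path: str) -> tuple[np.ndarray, Triple, Triple]:
    img = nib.load(path)
    arr = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    offset = tuple(float(x) for x in img.affine[:3, 3][::-1])
    return arr, tuple(float(z) for z in zooms[::-1]), offset


def load_image(path: str) -> ImageVolume:
    arr, spacing, offset = _load(path)
    return ImageVolume(arr.astype(np.float32), spacing, origin_offset=offset)


def load_labels(path: str) -> LabelVolume:
    arr, spacing, offset = _load(path)
    return LabelVolume(np.rint(arr).astype(np.uint8), spacing, origin_offset=offset)


# ---------------------------------------------------------------------------
# Resampling


def _resample_array(
    data: np.ndarray, spacing: Triple, target: Triple, order: int
) -> np.ndarray:
    new_shape = tuple(
        max(1, int(round(n * s / t))) for n, s, t in zip(data.shape, spacing, target)
    )
    # output voxel i on axis a sits at input index i * target/spacing,
    # anchored at the first voxel centre; edges clamp.
    grids = np.meshgrid(
        *[np.arange(n) * (t / s) for n, s, t in zip(new_shape, spacing, target)],
        indexing="ij",
    )
    return ndimage.map_coordinates(data, grids, order=order, mode="nearest")


def resample_isotropic(
    volume: ImageVolume | LabelVolume, target_spacing: Triple = (1.0, 1.0, 1.0)
):
    """Resample to a new spacing: trilinear for images, nearest for labels.

    The output grid spans the same physical extent to within one voxel.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be positive")
    target = tuple(float(t) for t in target_spacing)
    if isinstance(volume, ImageVolume):
        out = _resample_array(volume.voxels, volume.spacing, target, order=1)
        return ImageVolume(out, target, origin_offset=volume.origin_offset)
    out = _resample_array(volume.labels, volume.spacing, target, order=0)
    return LabelVolume(out, target, origin_offset=volume.origin_offset)


# ---------------------------------------------------------------------------
# Stacking sequences into one hip-to-ankle volume


def stack_sequences(sequences: Sequence[ImageVolume]) -> ImageVolume:
    """Stack resampled sequences into one volume using their mm offsets.

    The output field of view is the union of all inputs; uncovered voxels
    are 0 (blank padding).  Where sequences overlap, the later sequence in
    list order wins; callers should order sequences proximal to distal
    (hip, thigh, knee, shank).
    """
    if not sequences:
        raise ValueError("no sequences to stack")
    spacing = sequences[0].spacing
    for seq in sequences[1:]:
        if not np.allclose(seq.spacing, spacing):
            raise ValueError(
                f"mismatched spacing: {seq.spacing} vs {spacing}; resample first"
            )
    starts = np.array(
        [
            [int(round(o / s)) for o, s in zip(seq.origin_offset, spacing)]
            for seq in sequences
        ]
    )
    ends = starts + np.array([seq.shape for seq in sequences])
    lo = starts.min(axis=0)
    hi = ends.max(axis=0)
    out = np.zeros(tuple(hi - lo), dtype=np.float32)
    for seq, start in zip(sequences, starts):
        idx = tuple(slice(a, a + n) for a, n in zip(start - lo, seq.shape))
        out[idx] = seq.voxels
    origin = tuple(float(a * s) for a, s in zip(lo, spacing))
    return ImageVolume(out, spacing, origin_offset=origin)


# ---------------------------------------------------------------------------
# Left/right homogenisation


def reflect_limb(
    image: ImageVolume, labels: LabelVolume, side: str
) -> tuple[ImageVolume, LabelVolume]:
    """Mirror a left limb along the left-right axis; right limbs pass through.

    Reflection homogenises the two limbs into one orientation so a single
    network sees consistent anatomy.  Class ids are untouched.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not image.same_geometry(labels):
        raise ValueError("image and labels must share geometry")
    if side == "right":
        return image, labels
    return (
        replace(image, voxels=image.voxels[:, :, ::-1].copy()),
        replace(labels, labels=labels.labels[:, :, ::-1].copy()),
    )


# ---------------------------------------------------------------------------
# Mask <-> label map conversion


def masks_to_labelmap(
    masks: Mapping[int, np.ndarray],
    schema: MuscleSchema,
    spacing: Triple = (1.0, 1.0, 1.0),
    resolve_overlaps: bool = False,
) -> LabelVolume:
    """Combine per-muscle binary masks into one integer label map.

    Voxels in mask ``k`` get value ``k``; uncovered voxels stay 0.  By
    default overlapping masks are an error naming the colliding classes;
    with ``resolve_overlaps`` the lowest class id wins.
    """
    if not masks:
        raise ValueError("no masks given")
    ids = sorted(masks)
    valid = set(schema.class_ids)
    bad = [k for k in ids if k not in valid]
    if bad:
        raise ValueError(f"class ids {bad} not in schema")
    shape = np.asarray(masks[ids[0]]).shape
    out = np.zeros(shape, dtype=np.uint8)
    # iterate high id -> low id so that with resolution enabled the lowest wins
    for k in sorted(ids, reverse=True):
        m = np.asarray(masks[k]).astype(bool)
        if m.shape != shape:
            raise ValueError(f"mask {k} shape {m.shape} != {shape}")
        if not resolve_overlaps:
            clash = m & (out > 0)
            if clash.any():
                others = sorted(int(v) for v in np.unique(out[clash]))
                raise ValueError(f"masks overlap: class {k} collides with {others}")
        out[m] = k
    return LabelVolume(out, spacing)


def labelmap_to_mask(labels: LabelVolume, class_id: int) -> np.ndarray:
    """Binary mask of one class (0 gives the background complement)."""
    if not 0 <= class_id <= N_MUSCLE_CLASSES:
        raise ValueError(f"class id {class_id} outside 0..37")
    return labels.labels == class_id
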