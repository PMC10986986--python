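"""Synthetic limb phantoms with paired labels and deformation augmentation.

The phantom emulates, at desk scale, what stacked T1-weighted lower-limb
volumes look like to a slice-wise segmentation network: a roughly circular
limb cross-section of soft tissue, containing several muscle-like
elliptical tubes, each with a distinct mean intensity, a characteristic
axial extent (hip muscles proximal, calf muscles distal), smoothly varying
centrelines and radii, per-subject shape jitter, and additive Gaussian
noise.  Augmented ("virtual") subjects are created by warping an existing
subject's image and labels with one random smooth displacement field, the
same statistical role that deformable registration between subject pairs
plays when a real cohort is augmented; each augmented subject records a
(fixed, moving) provenance pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volumes import ImageVolume, LabelVolume

DEFAULT_GRID = (96, 48, 48)  # (axial, row, column)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom cohort generator.

    axial_extents are per-class ``(start, end)`` fractions of the axial
    axis; intensity_means has one value per class preceded by the
    soft-tissue background mean.  Intensities are on an arbitrary [0, 1]
    scale so no further normalisation is needed before training.
    """

    n_classes: int = 6
    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axial_extents: tuple[tuple[float, float], ...] = ()
    intensity_means: tuple[float, ...] = ()
    noise_sd: float = 0.03
    shape_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_classes <= 37:
            raise ValueError("n_classes must be in 1..37")
        if not self.axial_extents:
            object.__setattr__(self, "axial_extents", _default_extents(self.n_classes))
        if not self.intensity_means:
            means = (0.15, *np.linspace(0.35, 0.9, self.n_classes).round(4))
            object.__setattr__(self, "intensity_means", tuple(float(m) for m in means))
        if len(self.axial_extents) != self.n_classes:
            raise ValueError("one axial extent per class required")
        for lo, hi in self.axial_extents:
            if not 0.0 <= lo < hi <= 1.0:
                raise ValueError(f"bad axial extent ({lo}, {hi})")
        if len(self.intensity_means) != self.n_classes + 1:
            raise ValueError("intensity_means must have background + one value per class")
        if self.shape_jitter < 0 or self.noise_sd < 0:
            raise ValueError("noise_sd and shape_jitter must be >= 0")


def _default_extents(n_classes: int) -> tuple[tuple[float, float], ...]:
    """Staggered axial bands: class 1 most proximal, the last most distal."""
    if n_classes == 1:
        return ((0.0, 1.0),)
    span = 0.45
    starts = np.linspace(0.0, 1.0 - span, n_classes)
    return tuple((float(s), float(s + span)) for s in starts)


@dataclass
class PhantomSubject:
    """A synthetic subject: paired image/label volumes plus provenance."""

    subject_id: str
    image: ImageVolume
    labels: LabelVolume
    provenance: tuple[str, str] | None = None  # (fixed_id, moving_id)

    @property
    def is_augmented(self) -> bool:
        return self.provenance is not None


def generate_phantom(spec: PhantomSpec, subject_seed: int, subject_id: str | None = None) -> PhantomSubject:
    """Generate one phantom subject, deterministic in (spec.seed, subject_seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, subject_seed]))
    nz, ny, nx = spec.grid_shape
    z = np.arange(nz)
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")

    cy0, cx0 = (ny - 1) / 2.0, (nx - 1) / 2.0
    limb_r = 0.46 * min(ny, nx)
    limb = ((yy - cy0) ** 2 + (xx - cx0) ** 2) <= limb_r**2

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    base_r = 0.14 * min(ny, nx)
    ring = 0.26 * min(ny, nx)
    for k in range(1, spec.n_classes + 1):
        angle = 2.0 * np.pi * (k - 1) / spec.n_classes + rng.normal(0, spec.shape_jitter)
        # smoothly wandering centreline and radii along z
        phase = rng.uniform(0, 2 * np.pi, size=2)
        wobble = 0.12 * ring * (1 + spec.shape_jitter * rng.normal())
        cy = cy0 + ring * np.sin(angle) + wobble * np.sin(2 * np.pi * z / nz + phase[0])
        cx = cx0 + ring * np.cos(angle) + wobble * np.cos(2 * np.pi * z / nz + phase[1])
        r_y = base_r * (1 + spec.shape_jitter * rng.normal()) * (
            1 + 0.15 * np.sin(2 * np.pi * z / nz + phase[0])
        )
        r_x = base_r * (1 + spec.shape_jitter * rng.normal()) * (
            1 + 0.15 * np.cos(2 * np.pi * z / nz + phase[1])
        )
        lo, hi = spec.axial_extents[k - 1]
        z_on = (z >= lo * nz) & (z < np.ceil(hi * nz))
        d2 = (
            (yy[None] - cy[:, None, None]) ** 2 / np.maximum(r_y, 1.0)[:, None, None] ** 2
            + (xx[None] - cx[:, None, None]) ** 2 / np.maximum(r_x, 1.0)[:, None, None] ** 2
        )
        tube = (d2 <= 1.0) & z_on[:, None, None] & limb[None]
        labels[tube & (labels == 0)] = k  # lowest id wins on overlap

    means = np.asarray(spec.intensity_means, dtype=np.float32)
    image = np.where(
        np.broadcast_to(limb, spec.grid_shape), means[0], 0.0
    ).astype(np.float32)
    for k in range(1, spec.n_classes + 1):
        image[labels == k] = means[k]
    image += rng.normal(0.0, spec.noise_sd, size=image.shape).astype(np.float32)

    sid = subject_id if subject_id is not None else f"S{subject_seed:03d}"
    return PhantomSubject(
        subject_id=sid,
        image=ImageVolume(image, spec.spacing),
        labels=LabelVolume(labels, spec.spacing),
        provenance=None,
    )


# ---------------------------------------------------------------------------
# Deformation augmentation


def random_displacement_field(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    amplitude: float,
    smoothness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One random smooth displacement field in mm, shape (3, nz, ny, nx).

    White noise is Gaussian-smoothed with kernel width ``smoothness`` (mm)
    and rescaled so the largest displacement vector has norm ``amplitude``.
    """
    if amplitude == 0:
        return np.zeros((3, *shape), dtype=np.float32)
    field_ = rng.normal(size=(3, *shape))
    sigmas = [smoothness / s for s in spacing]
    for a in range(3):
        field_[a] = ndimage.gaussian_filter(field_[a], sigma=sigmas)
    norms = np.sqrt((field_**2).sum(axis=0))
    peak = norms.max()
    if peak > 0:
        field_ *= amplitude / peak
    return field_.astype(np.float32)


def _jacobian_determinant(field_mm: np.ndarray, spacing: Sequence[float]) -> np.ndarray:
    """Determinant of d(phi)/dx for phi = identity + displacement, per voxel."""
    grads = np.empty((3, 3, *field_mm.shape[1:]), dtype=np.float32)
    for i in range(3):
        for j in range(3):
            grads[i, j] = np.gradient(field_mm[i], spacing[j], axis=j)
            if i == j:
                grads[i, j] += 1.0
    a = np.moveaxis(grads, (0, 1), (-2, -1))
    return np.linalg.det(a)


def _warp(data: np.ndarray, field_vox: np.ndarray, order: int) -> np.ndarray:
    coords = [np.arange(n) for n in data.shape]
    grid = np.meshgrid(*coords, indexing="ij")
    sample = [g + f for g, f in zip(grid, field_vox)]
    return ndimage.map_coordinates(data, sample, order=order, mode="nearest")


def deform_subject(
    subject: PhantomSubject,
    amplitude: float,
    smoothness: float,
    field_seed: int,
    fixed_id: str,
    subject_id: str | None = None,
    max_retries: int = 5,
) -> PhantomSubject:
    """Warp image and labels with one random smooth field; tag provenance.

    Image values are linearly interpolated, labels nearest-neighbour, so
    no new class ids can appear.  Fields whose Jacobian determinant is not
    everywhere positive (folding) are regenerated with damped amplitude.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    spacing = subject.image.spacing
    shape = subject.image.shape
    amp = amplitude
    rng = np.random.default_rng(np.random.SeedSequence([field_seed]))
    field_mm = random_displacement_field(shape, spacing, amp, smoothness, rng)
    for _ in range(max_retries):
        if amp == 0 or _jacobian_determinant(field_mm, spacing).min() > 0:
            break
        amp *= 0.5
        warnings.warn(
            f"displacement field folds at amplitude {amp * 2:.2f} mm; damped to {amp:.2f} mm"
        )
        field_mm *= 0.5
    field_vox = field_mm / np.asarray(spacing, dtype=np.float32)[:, None, None, None]
    image = _warp(subject.image.voxels, field_vox, order=1)
    labels = _warp(subject.labels.labels, field_vox, order=0)
    sid = subject_id if subject_id is not None else f"aug_{fixed_id}_{subject.subject_id}"
    return PhantomSubject(
        subject_id=sid,
        image=ImageVolume(image, spacing),
        labels=LabelVolume(labels, spacing),
        provenance=(fixed_id, subject.subject_id),
    )


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    n_augmented_per_pair: int = 0,
    amplitude: float = 3.0,
    smoothness: float = 8.0,
) -> list[PhantomSubject]:
    """Originals plus augmented subjects for every ordered subject pair.

    ``n`` originals and ``n * (n-1) * n_augmented_per_pair`` augmented
    subjects (11 originals with one copy per ordered pair give 110).  The
    augmented subject for pair (fixed, moving) is a warped copy of the
    moving subject.  Fully deterministic under ``spec.seed``.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    originals = [generate_phantom(spec, i, subject_id=f"S{i:02d}") for i in range(1, n_subjects + 1)]
    cohort = list(originals)
    for i, fixed in enumerate(originals):
        for j, moving in enumerate(originals):
            if i == j:
                continue
            for k in range(n_augmented_per_pair):
                seed = ((spec.seed * 1009 + i) * 1013 + j) * 7 + k + 1
                sid = f"aug_{fixed.subject_id}_{moving.subject_id}" + (
                    f"_{k}" if n_augmented_per_pair > 1 else ""
                )
                cohort.append(
                    deform_subject(
                        moving,
                        amplitude=amplitude,
                        smoothness=smoothness,
                        field_seed=seed % (2**31 - 1),
                        fixed_id=fixed.subject_id,
                        subject_id=sid,
                    )
                )
    return cohort


def cohort_manifest(cohort: Sequence[PhantomSubject]) -> list[dict]:
    """Provenance manifest rows: subject_id, kind, fixed_id, moving_id."""
    rows = []
    for s in cohort:
        rows.append(
            {
                "subject_id": s.subject_id,
                "kind": "augmented" if s.is_augmented else "original",
                "fixed_id": s.provenance[0] if s.provenance else "",
                "moving_id": s.provenance[1] if s.provenance else "",
            }
        )
    return rows
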