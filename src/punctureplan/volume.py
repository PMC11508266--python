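"""Volume data model, medical-image readers, and the synthetic CT phantom.

The in-memory container is :class:`CTVolume`: a 3-D array of Hounsfield-unit
(HU) values indexed ``(i, j, k)`` for ``(x, y, z)``, with per-axis voxel
spacing in millimetres.  Geometry convention used throughout the package:

* 0-based voxel indices;
* voxel ``(i, j, k)`` occupies the axis-aligned cell
  ``[i*sx, (i+1)*sx) x [j*sy, (j+1)*sy) x [k*sz, (k+1)*sz)`` in
  volume-local mm;
* the voxel *center* sits at ``(index + 0.5) * spacing``;
* ``origin_mm`` is the world position of the center of voxel ``(0, 0, 0)``.

Readers cover a DICOM series (one axial slice per file), NRRD and NIfTI-1;
phantoms are written as NIfTI-1.  HU values are clamped to [-2000, 4000] on
load (scanners can emit padding values such as -3024 outside the calibrated
range).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence, Union

import numpy as np

logger = logging.getLogger("punctureplan")

HU_MIN = -2000.0
HU_MAX = 4000.0


class VolumeFormatError(ValueError):
    """Input file/series is malformed or missing required metadata."""


class EmptyInputError(FileNotFoundError):
    """No usable input found (e.g. empty DICOM directory)."""


class PhantomSpecError(ValueError):
    """Phantom specification violates its invariants."""


class VoxelIndex(NamedTuple):
    i: int
    j: int
    k: int


class PointMM(NamedTuple):
    """A point in volume-local millimetre coordinates."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class CTVolume:
    """3-D grid of HU values with voxel spacing in mm.

    ``values`` is indexed ``(i, j, k)`` = ``(x, y, z)``.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3-D, got ndim={self.values.ndim}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the volume along each axis (mm)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))  # type: ignore[return-value]

    @property
    def diagonal_mm(self) -> float:
        return float(math.sqrt(sum(e * e for e in self.extent_mm)))

    def voxel_center_mm(self, index: Sequence[int]) -> PointMM:
        """Volume-local mm coordinates of a voxel center."""
        sp = self.spacing_mm
        return PointMM(*((float(index[a]) + 0.5) * sp[a] for a in range(3)))

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= int(index[a]) < self.shape[a] for a in range(3))


def clamp_hu(values: np.ndarray) -> np.ndarray:
    """Clamp HU values into [-2000, 4000]; warn if anything was clipped."""
    n_out = int(np.count_nonzero((values < HU_MIN) | (values > HU_MAX)))
    if n_out:
        logger.warning("clamped %d voxel(s) outside HU range [%g, %g]", n_out, HU_MIN, HU_MAX)
    return np.clip(values, HU_MIN, HU_MAX)


# ---------------------------------------------------------------------------
# Readers / writer
# ---------------------------------------------------------------------------

def load_dicom_series(directory: Union[str, Path]) -> CTVolume:
    """Load a single-frame CT DICOM series (one axial slice per file).

    Slices are ordered by ImagePositionPatient projected onto the slice
    normal (never by filename); HU values are computed from the rescale
    slope/intercept.  Missing pixel spacing or slice-position metadata is an
    error — no silent defaults.
    """
    import pydicom

    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file()) if directory.is_dir() else []
    datasets = []
    for path in files:
        try:
            ds = pydicom.dcmread(str(path))
        except Exception:
            continue
        if getattr(ds, "Rows", None) is None:
            continue
        datasets.append(ds)
    if not datasets:
        raise EmptyInputError(f"no readable single-frame DICOM slices in {directory}")

    rows = int(datasets[0].Rows)
    cols = int(datasets[0].Columns)
    for ds in datasets:
        if int(ds.Rows) != rows or int(ds.Columns) != cols:
            raise VolumeFormatError(
                f"inconsistent slice dimensions: expected {rows}x{cols}, "
                f"got {int(ds.Rows)}x{int(ds.Columns)}"
            )
    pixel_spacing = getattr(datasets[0], "PixelSpacing", None)
    if pixel_spacing is None:
        raise VolumeFormatError("PixelSpacing tag missing; refusing to guess in-plane spacing")
    # DICOM PixelSpacing is (row spacing, column spacing) = (dy, dx).
    dy, dx = float(pixel_spacing[0]), float(pixel_spacing[1])

    def _slice_position(ds) -> float:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise VolumeFormatError("ImagePositionPatient tag missing; cannot order slices")
        iop = getattr(ds, "ImageOrientationPatient", None)
        if iop is not None:
            r = np.asarray(iop[:3], dtype=float)
            c = np.asarray(iop[3:], dtype=float)
            normal = np.cross(r, c)
        else:
            normal = np.array([0.0, 0.0, 1.0])
        return float(np.dot(np.asarray(ipp, dtype=float), normal))

    if len(datasets) > 1:
        datasets.sort(key=_slice_position)
        positions = np.array([_slice_position(ds) for ds in datasets])
        dz = float(np.median(np.diff(positions)))
        if dz <= 0:
            raise VolumeFormatError("non-increasing slice positions")
    else:
        thickness = getattr(datasets[0], "SliceThickness", None)
        if thickness is None:
            raise VolumeFormatError(
                "single-slice series without SliceThickness; cannot derive z spacing"
            )
        dz = float(thickness)

    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float64) * slope + intercept
        # pixel_array is (rows, cols) = (y, x); transpose to (x, y)
        slices.append(hu.T)
    values = clamp_hu(np.stack(slices, axis=-1))

    ipp0 = getattr(datasets[0], "ImagePositionPatient", None)
    origin = tuple(float(v) for v in ipp0) if ipp0 is not None else (0.0, 0.0, 0.0)
    return CTVolume(values=values, spacing_mm=(dx, dy, dz), origin_mm=origin)


def load_volume(path: Union[str, Path]) -> CTVolume:
    """Load an NRRD or NIfTI-1 volume; axis order normalized to (x, y, z)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(str(path))
            data = np.asanyarray(img.dataobj)
        except Exception as exc:
            raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
        affine = img.affine
        spacing = tuple(float(np.linalg.norm(affine[:3, a])) for a in range(3))
        origin = tuple(float(v) for v in affine[:3, 3])
        if any(s <= 0 for s in spacing):
            raise VolumeFormatError(f"non-positive spacing in NIfTI affine of {path}")
        return CTVolume(values=clamp_hu(np.asarray(data, dtype=np.float64)),
                        spacing_mm=spacing, origin_mm=origin)
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except Exception as exc:
            raise VolumeFormatError(f"cannot read NRRD volume {path}: {exc}") from exc
        arr = sitk.GetArrayFromImage(img)  # (z, y, x)
        if arr.ndim != 3:
            raise VolumeFormatError(f"expected a 3-D NRRD volume, got ndim={arr.ndim}")
        values = clamp_hu(np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float64))
        return CTVolume(values=values,
                        spacing_mm=tuple(float(s) for s in img.GetSpacing()),
                        origin_mm=tuple(float(o) for o in img.GetOrigin()))
    raise VolumeFormatError(f"unsupported volume format: {path.name}")


def save_volume(volume: CTVolume, path: Union[str, Path]) -> Path:
    """Write a volume as NIfTI-1 (int16 HU) so a reload round-trips exactly."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    affine[:3, 3] = volume.origin_mm
    data = np.asarray(np.rint(volume.values), dtype=np.int16)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


# ---------------------------------------------------------------------------
# Synthetic phantom
# ---------------------------------------------------------------------------
#
# No patient volumes ship with the package, so tests and demos run on a
# parametric phantom: exterior-air background, a soft-tissue body ellipsoid,
# optional fat skin shell, organ blobs (HU 30-60, not puncturable), enclosed
# airways (HU < -900), and bone shells/rods (HU > 100).  Voxels are painted
# in the order background -> body -> skin -> organs -> airways -> bone, so a
# later shape overwrites an earlier one.

@dataclass(frozen=True)
class Ellipsoid:
    center_mm: tuple[float, float, float]
    semiaxes_mm: tuple[float, float, float]
    hu: float

    def mask(self, centers: list[np.ndarray]) -> np.ndarray:
        q = sum(((centers[a] - self.center_mm[a]) / self.semiaxes_mm[a]) ** 2 for a in range(3))
        return q <= 1.0

    def contains(self, point: Sequence[float], margin: float = 0.0) -> bool:
        q = sum(((float(point[a]) - self.center_mm[a]) / self.semiaxes_mm[a]) ** 2
                for a in range(3))
        return q < (1.0 - margin) ** 2


@dataclass(frozen=True)
class Sphere:
    center_mm: tuple[float, float, float]
    radius_mm: float
    hu: float

    def mask(self, centers: list[np.ndarray]) -> np.ndarray:
        d2 = sum((centers[a] - self.center_mm[a]) ** 2 for a in range(3))
        return d2 <= self.radius_mm ** 2


@dataclass(frozen=True)
class SphericalShell:
    """Hollow sphere, optionally pierced by conical holes.

    A hole is ``(axis_unit_vector, half_angle_deg)``: shell voxels whose
    direction from the shell center lies within the cone are left unpainted.
    """

    center_mm: tuple[float, float, float]
    inner_radius_mm: float
    outer_radius_mm: float
    hu: float
    holes: tuple[tuple[tuple[float, float, float], float], ...] = ()

    def mask(self, centers: list[np.ndarray]) -> np.ndarray:
        d = [centers[a] - self.center_mm[a] for a in range(3)]
        r = np.sqrt(sum(x * x for x in d))
        m = (r >= self.inner_radius_mm) & (r <= self.outer_radius_mm)
        for axis, half_angle_deg in self.holes:
            u = np.asarray(axis, dtype=float)
            u = u / np.linalg.norm(u)
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = sum(d[a] * u[a] for a in range(3)) / np.where(r > 0, r, np.inf)
            m &= ~(cosang >= math.cos(math.radians(half_angle_deg)))
        return m


@dataclass(frozen=True)
class Cylinder:
    """Finite rod between two endpoints (bone rods, vessels)."""

    start_mm: tuple[float, float, float]
    end_mm: tuple[float, float, float]
    radius_mm: float
    hu: float

    def mask(self, centers: list[np.ndarray]) -> np.ndarray:
        p0 = np.asarray(self.start_mm, dtype=float)
        p1 = np.asarray(self.end_mm, dtype=float)
        axis = p1 - p0
        length2 = float(np.dot(axis, axis))
        d = [centers[a] - p0[a] for a in range(3)]
        t = sum(d[a] * axis[a] for a in range(3)) / max(length2, 1e-30)
        t = np.clip(t, 0.0, 1.0)
        dist2 = sum((d[a] - t * axis[a]) ** 2 for a in range(3))
        return dist2 <= self.radius_mm ** 2


Shape3D = Union[Ellipsoid, Sphere, SphericalShell, Cylinder]

# HU bands the phantom shapes must respect (matching the classifier's bands)
_PUNCTURABLE_BANDS = ((-900.0, 30.0), (60.0, 100.0))


def _is_puncturable_hu(hu: float) -> bool:
    lo1, hi1 = _PUNCTURABLE_BANDS[0]
    lo2, hi2 = _PUNCTURABLE_BANDS[1]
    return (lo1 <= hu < hi1) or (lo2 < hu <= hi2)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic CT phantom."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    body: Ellipsoid = None  # type: ignore[assignment]
    bone_shapes: tuple[Shape3D, ...] = ()
    organ_blobs: tuple[Sphere, ...] = ()
    airway_blobs: tuple[Sphere, ...] = ()
    skin_shell_mm: float = 0.0
    skin_hu: float = -75.0
    target: VoxelIndex = VoxelIndex(0, 0, 0)
    background_hu: float = -1000.0
    seed: int = 0

    def validate(self) -> None:
        if self.body is None:
            raise PhantomSpecError("phantom requires a body ellipsoid")
        if self.background_hu >= -900.0:
            raise PhantomSpecError("background HU must be below -900 (exterior air)")
        if not _is_puncturable_hu(self.body.hu):
            raise PhantomSpecError(f"body HU {self.body.hu} is not in a puncturable band")
        if self.skin_shell_mm > 0 and not _is_puncturable_hu(self.skin_hu):
            raise PhantomSpecError(f"skin HU {self.skin_hu} is not in a puncturable band")
        for s in self.bone_shapes:
            if not s.hu > 100.0:
                raise PhantomSpecError(f"bone shape HU {s.hu} must exceed 100")
        for s in self.organ_blobs:
            if not (30.0 <= s.hu <= 60.0):
                raise PhantomSpecError(f"organ blob HU {s.hu} must lie in [30, 60]")
        for s in self.airway_blobs:
            if not s.hu < -900.0:
                raise PhantomSpecError(f"airway blob HU {s.hu} must be below -900")
        if not all(0 <= self.target[a] < self.shape[a] for a in range(3)):
            raise PhantomSpecError(f"target {self.target} outside volume shape {self.shape}")
        center = tuple((self.target[a] + 0.5) * self.spacing_mm[a] for a in range(3))
        if not self.body.contains(center, margin=1e-9):
            raise PhantomSpecError(f"target {self.target} lies outside the body ellipsoid")

    @property
    def target_center_mm(self) -> PointMM:
        return PointMM(*((self.target[a] + 0.5) * self.spacing_mm[a] for a in range(3)))


def make_phantom(spec: PhantomSpec) -> CTVolume:
    """Render a phantom spec to a CTVolume (deterministic; no randomness)."""
    spec.validate()
    nx, ny, nz = spec.shape
    sp = spec.spacing_mm
    ax = [(np.arange(n) + 0.5) * s for n, s in zip(spec.shape, sp)]
    centers = list(np.meshgrid(*ax, indexing="ij"))

    values = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    body_mask = spec.body.mask(centers)
    values[body_mask] = spec.body.hu
    if spec.skin_shell_mm > 0:
        inner = Ellipsoid(
            spec.body.center_mm,
            tuple(max(a - spec.skin_shell_mm, 1e-6) for a in spec.body.semiaxes_mm),
            spec.body.hu,
        )
        values[body_mask & ~inner.mask(centers)] = spec.skin_hu
    for blob in spec.organ_blobs:
        values[blob.mask(centers)] = blob.hu
    for blob in spec.airway_blobs:
        values[blob.mask(centers)] = blob.hu
    for bone in spec.bone_shapes:
        values[bone.mask(centers)] = bone.hu
    return CTVolume(values=clamp_hu(values), spacing_mm=sp)


def default_phantom_spec(shape: tuple[int, int, int] = (64, 64, 64),
                         spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
                         seed: int = 0) -> PhantomSpec:
    """A torso-like demo phantom: body, skin, one organ, one airway, one rib rod."""
    ext = tuple(n * s for n, s in zip(shape, spacing_mm))
    c = tuple(e / 2 for e in ext)
    semi = tuple(0.42 * e for e in ext)
    body = Ellipsoid(center_mm=c, semiaxes_mm=semi, hu=20.0)
    organ = Sphere(center_mm=(c[0] + 0.55 * semi[0], c[1], c[2]), radius_mm=0.12 * min(ext), hu=45.0)
    airway = Sphere(center_mm=(c[0] - 0.4 * semi[0], c[1] + 0.2 * semi[1], c[2]),
                    radius_mm=0.1 * min(ext), hu=-1000.0)
    rib = Cylinder(start_mm=(c[0], c[1] - 0.8 * semi[1], c[2] - 0.6 * semi[2]),
                   end_mm=(c[0], c[1] - 0.8 * semi[1], c[2] + 0.6 * semi[2]),
                   radius_mm=0.06 * min(ext), hu=400.0)
    target = VoxelIndex(*(int(round(c[a] / spacing_mm[a] - 0.5)) - (2 if a == 0 else 0)
                          for a in range(3)))
    return PhantomSpec(shape=shape, spacing_mm=spacing_mm, body=body,
                       bone_shapes=(rib,), organ_blobs=(organ,), airway_blobs=(airway,),
                       skin_shell_mm=2.0 * min(spacing_mm), target=target, seed=seed)


def random_phantom_spec(seed: int,
                        shape: tuple[int, int, int] = (48, 48, 48),
                        spacing_mm: tuple[float, float, float] = (0.9, 1.1, 1.3),
                        n_bones: int = 2, n_organs: int = 2, n_airways: int = 1,
                        ) -> PhantomSpec:
    """Randomized phantom for stress tests: blobs placed inside the body,
    kept clear of the (central) target voxel so a route can exist."""
    rng = np.random.default_rng(seed)
    ext = np.array([n * s for n, s in zip(shape, spacing_mm)])
    c = ext / 2
    semi = 0.42 * ext
    body = Ellipsoid(center_mm=tuple(c), semiaxes_mm=tuple(semi), hu=20.0)
    target = VoxelIndex(*(int(n // 2) for n in shape))
    target_mm = np.array([(target[a] + 0.5) * spacing_mm[a] for a in range(3)])

    def _random_center(min_dist: float) -> tuple[float, float, float]:
        for _ in range(200):
            p = c + (rng.uniform(-0.75, 0.75, size=3)) * semi
            if np.linalg.norm(p - target_mm) >= min_dist:
                return tuple(float(v) for v in p)
        return tuple(float(v) for v in c + 0.7 * semi)

    min_ext = float(ext.min())
    bones = tuple(
        Sphere(_random_center(0.22 * min_ext), rng.uniform(0.05, 0.12) * min_ext,
               hu=float(rng.uniform(250, 1000)))
        for _ in range(n_bones)
    )
    organs = tuple(
        Sphere(_random_center(0.2 * min_ext), rng.uniform(0.06, 0.14) * min_ext,
               hu=float(rng.uniform(30, 60)))
        for _ in range(n_organs)
    )
    airways = tuple(
        Sphere(_random_center(0.2 * min_ext), rng.uniform(0.04, 0.1) * min_ext,
               hu=-1000.0)
        for _ in range(n_airways)
    )
    return PhantomSpec(shape=shape, spacing_mm=spacing_mm, body=body,
                       bone_shapes=bones, organ_blobs=organs, airway_blobs=airways,
                       target=target, seed=seed)
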