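"""Hounsfield-unit tissue classification for puncture planning.

Each voxel is assigned exactly one label:

* air (HU below -900), split by connectivity into EXTERIOR_AIR (connected to
  a volume face — outside the body, the valid route terminus) and
  INTERIOR_AIR (enclosed airway/gut gas — a needle cannot traverse it);
* PUNCTURABLE — HU in [-900, 30) or (60, 100] (fat, fluid, skin,
  thrombus-range tissue);
* NON_PUNCTURABLE — the organ/vessel band [30, 60] (muscle, liver, vessels)
  and everything above 100 (thyroid-range and denser tissue through bone);
* TARGET — the lesion voxels marked by :func:`mark_target`.

Band endpoints collide in prose descriptions of these thresholds; here the
half-open choice is conservative: a boundary organ value blocks the needle,
and the five classes form a total partition of [-2000, 4000].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import IntEnum
from typing import Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volume import CTVolume, PointMM, VoxelIndex, logger


class Label(IntEnum):
    EXTERIOR_AIR = 0
    INTERIOR_AIR = 1
    PUNCTURABLE = 2
    NON_PUNCTURABLE = 3
    TARGET = 4


class TargetError(ValueError):
    """Target placement violates its preconditions."""


@dataclass(frozen=True)
class ThresholdConfig:
    """HU thresholds delimiting the puncturability bands.

    The four intervals plus the open air/bone tails must tile the HU axis:
    ``puncturable_low`` starts at ``air_below`` and ends where ``organ_band``
    starts; ``puncturable_high`` runs from the organ band's top to
    ``bone_above``.  ``fat_band`` is informational (skin-entry logging), not
    part of the partition.
    """

    air_below: float = -900.0
    puncturable_low: Tuple[float, float] = (-900.0, 30.0)   # [lo, hi)
    organ_band: Tuple[float, float] = (30.0, 60.0)          # [lo, hi]
    puncturable_high: Tuple[float, float] = (60.0, 100.0)   # (lo, hi]
    bone_above: float = 100.0
    fat_band: Tuple[float, float] = (-100.0, -50.0)

    def validate(self) -> None:
        ok = (
            self.puncturable_low[0] == self.air_below
            and self.puncturable_low[1] == self.organ_band[0]
            and self.organ_band[1] == self.puncturable_high[0]
            and self.puncturable_high[1] == self.bone_above
            and self.puncturable_low[0] < self.puncturable_low[1]
            and self.organ_band[0] < self.organ_band[1]
            and self.puncturable_high[0] < self.puncturable_high[1]
        )
        if not ok:
            raise ValueError(f"threshold intervals do not tile the HU axis: {self}")

    def classify_scalar(self, hu: float) -> Label:
        """Label a single HU value (air is EXTERIOR_AIR before connectivity)."""
        if hu < self.air_below:
            return Label.EXTERIOR_AIR
        if self.puncturable_low[0] <= hu < self.puncturable_low[1]:
            return Label.PUNCTURABLE
        if self.organ_band[0] <= hu <= self.organ_band[1]:
            return Label.NON_PUNCTURABLE
        if self.puncturable_high[0] < hu <= self.puncturable_high[1]:
            return Label.PUNCTURABLE
        return Label.NON_PUNCTURABLE  # bone and denser


@dataclass(frozen=True)
class LabelVolume:
    """Per-voxel region labels with the source volume's geometry."""

    labels: np.ndarray  # uint8 array of Label values
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing_mm))  # type: ignore[return-value]

    @property
    def diagonal_mm(self) -> float:
        return float(np.sqrt(sum(e * e for e in self.extent_mm)))

    def voxel_center_mm(self, index: Sequence[int]) -> PointMM:
        return PointMM(*((float(index[a]) + 0.5) * self.spacing_mm[a] for a in range(3)))

    def contains_index(self, index: Sequence[int]) -> bool:
        return all(0 <= int(index[a]) < self.shape[a] for a in range(3))


def classify_voxels(volume: CTVolume, thresholds: ThresholdConfig | None = None) -> LabelVolume:
    """Map HU values to labels.  All air is provisionally EXTERIOR_AIR;
    run :func:`split_air` to separate enclosed airways."""
    cfg = thresholds or ThresholdConfig()
    cfg.validate()
    hu = volume.values
    labels = np.full(hu.shape, Label.NON_PUNCTURABLE, dtype=np.uint8)
    labels[hu < cfg.air_below] = Label.EXTERIOR_AIR
    punct = ((hu >= cfg.puncturable_low[0]) & (hu < cfg.puncturable_low[1])) | (
        (hu > cfg.puncturable_high[0]) & (hu <= cfg.puncturable_high[1])
    )
    labels[punct] = Label.PUNCTURABLE
    return LabelVolume(labels=labels, spacing_mm=volume.spacing_mm, origin_mm=volume.origin_mm)


_FACE_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def split_air(labelvol: LabelVolume) -> LabelVolume:
    """Split air into exterior (6-connected to any volume face) and interior.

    Idempotent: both air labels are pooled before re-splitting.
    """
    labels = labelvol.labels.copy()
    air = (labels == Label.EXTERIOR_AIR) | (labels == Label.INTERIOR_AIR)
    if not air.any():
        return replace(labelvol, labels=labels)
    comp, n_comp = ndimage.label(air, structure=_FACE_CONNECTIVITY)
    face_ids = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(comp, sl, axis=axis)
            face_ids.update(np.unique(face[face > 0]).tolist())
    exterior = np.isin(comp, sorted(face_ids)) if face_ids else np.zeros_like(air)
    labels[air & exterior] = Label.EXTERIOR_AIR
    labels[air & ~exterior] = Label.INTERIOR_AIR
    if not face_ids:
        logger.warning("no air touches any volume face: all air treated as interior")
    return replace(labelvol, labels=labels)


def classify_and_label(volume: CTVolume, thresholds: ThresholdConfig | None = None) -> LabelVolume:
    """Convenience: classify then split air in one call."""
    return split_air(classify_voxels(volume, thresholds))


def mark_target(labelvol: LabelVolume, target: Sequence[int], radius_mm: float = 0.0
                ) -> LabelVolume:
    """Mark voxels whose centers lie within ``radius_mm`` of the target
    voxel's center as TARGET.  ``radius_mm = 0`` marks exactly one voxel."""
    idx = VoxelIndex(*(int(v) for v in target))
    if not labelvol.contains_index(idx):
        raise TargetError(f"target {idx} outside volume shape {labelvol.shape}")
    if labelvol.labels[idx] == Label.EXTERIOR_AIR:
        raise TargetError(f"target {idx} lies in exterior air — must be inside the body")
    labels = labelvol.labels.copy()
    if radius_mm <= 0:
        labels[idx] = Label.TARGET
        return replace(labelvol, labels=labels)
    sp = np.asarray(labelvol.spacing_mm)
    reach = np.ceil(radius_mm / sp).astype(int)
    lo = [max(idx[a] - reach[a], 0) for a in range(3)]
    hi = [min(idx[a] + reach[a] + 1, labelvol.shape[a]) for a in range(3)]
    grids = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    d2 = sum(((grids[a] - idx[a]) * sp[a]) ** 2 for a in range(3))
    ball = d2 <= (radius_mm * (1 + 1e-12)) ** 2
    sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[ball] = Label.TARGET
    return replace(labelvol, labels=labels)
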