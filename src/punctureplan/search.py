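"""Puncture-route search: outward angular sweep and brute-force extension.

Both procedures cast candidate needle paths outward from the target: a
direction is *blocked* as soon as the path touches a non-puncturable voxel
(organ/vessel band, bone, or enclosed airway) and becomes a *candidate* when
it reaches exterior air; the skin-entry voxel is the last tissue voxel before
the air, and the puncture distance is the Euclidean mm distance from the
target to that voxel's center.

``search_routes`` walks each ray once with the exact supercover traversal —
every voxel a path could graze is checked, and each voxel is visited exactly
once per direction.  ``brute_force_search`` implements the iterative
segment-extension procedure: the segment grows outward in fixed increments
of length R, and after each extension every voxel touched by the new portion
is re-examined via dense point sampling.  The brute force is oracle-grade,
not performance-grade; it exists to verify the sweep.

Directions are parameterized by elevation alpha in [-90, 90] degrees and
azimuth beta in [0, 360) degrees; the two poles (alpha = +/-90) are each
evaluated once, not once per beta.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .classify import Label, LabelVolume
from .traversal import RayDirection, direction_from_angles, traverse_ray
from .volume import PointMM, VoxelIndex, logger

_BLOCKING = (Label.NON_PUNCTURABLE, Label.INTERIOR_AIR)
_PASSABLE = (Label.TARGET, Label.PUNCTURABLE)


@dataclass(frozen=True)
class SweepConfig:
    """Angular grid and ray-length settings for the route search.

    ``extension_step_mm`` is the nominal segment length R by which the
    brute-force method grows each trial segment.  ``two_fan`` restricts the
    sweep to the two principal great-circle fans (the in-plane sweep at
    alpha = 0 plus the vertical fan through beta = 0/180) instead of the full
    (alpha, beta) product grid.
    """

    alpha_step_deg: float = 1.0
    beta_step_deg: float = 1.0
    max_ray_length_mm: float | None = None  # default: volume diagonal
    extension_step_mm: float = 5.0
    two_fan: bool = False

    def validate(self) -> None:
        if self.alpha_step_deg <= 0 or self.beta_step_deg <= 0:
            raise ValueError("angular steps must be positive")
        if abs(round(360.0 / self.beta_step_deg) - 360.0 / self.beta_step_deg) > 1e-9:
            raise ValueError(f"360 must be divisible by beta_step_deg={self.beta_step_deg}")

    def angle_grid_deg(self) -> Iterator[tuple[float, float]]:
        """(alpha, beta) pairs in degrees, poles de-duplicated."""
        self.validate()
        n_beta = int(round(360.0 / self.beta_step_deg))
        betas = [b * self.beta_step_deg for b in range(n_beta)]
        n_alpha = int(round(90.0 / self.alpha_step_deg))
        alphas = [a * self.alpha_step_deg for a in range(-n_alpha, n_alpha + 1)]
        if self.two_fan:
            seen = set()
            for b in betas:
                seen.add((0.0, b))
                yield (0.0, b)
            for a in alphas:
                for pair in ((a, 0.0), (a, 180.0)) if abs(a) < 90.0 else ((a, 0.0),):
                    key = (0.0, pair[1]) if a == 0.0 else pair
                    if key not in seen:
                        seen.add(key)
                        yield pair
            return
        for a in alphas:
            if abs(a) >= 90.0:
                yield (a, 0.0)
            else:
                for b in betas:
                    yield (a, b)


@dataclass(frozen=True)
class Route:
    """One candidate puncture path from the target outward."""

    target: PointMM
    direction: RayDirection
    status: str  # "candidate" | "blocked"
    entry_voxel: VoxelIndex | None = None
    entry_point: PointMM | None = None
    traversed: tuple[VoxelIndex, ...] = ()
    distance_mm: float = math.nan
    clearance_mm: float = math.nan
    blocked_reason: str | None = None


@dataclass(frozen=True)
class CandidateSet:
    """All evaluated directions for one target, candidates and blocked."""

    routes: tuple[Route, ...]
    target: PointMM
    config: SweepConfig
    method: str = "proposed"

    @property
    def n_directions_tried(self) -> int:
        return len(self.routes)

    @property
    def n_candidates(self) -> int:
        return sum(1 for r in self.routes if r.status == "candidate")

    @property
    def candidates(self) -> tuple[Route, ...]:
        return tuple(r for r in self.routes if r.status == "candidate")


def _resolve_target(labels: LabelVolume, target) -> tuple[PointMM, VoxelIndex]:
    """Accept a voxel index (ray origin = its center) or a PointMM."""
    if isinstance(target, PointMM) or (
        isinstance(target, Sequence) and any(isinstance(v, float) for v in target)
        and not isinstance(target, VoxelIndex)
    ):
        pt = PointMM(*(float(v) for v in target))
        idx = VoxelIndex(*(
            min(max(int(math.floor(pt[a] / labels.spacing_mm[a])), 0), labels.shape[a] - 1)
            for a in range(3)
        ))
        return pt, idx
    idx = VoxelIndex(*(int(v) for v in target))
    if not labels.contains_index(idx):
        raise ValueError(f"target index {idx} outside volume shape {labels.shape}")
    return labels.voxel_center_mm(idx), idx


def _check_start(labels: LabelVolume, idx: VoxelIndex) -> None:
    lab = Label(labels.labels[idx])
    if lab not in _PASSABLE:
        raise ValueError(f"target voxel {idx} is {lab.name}; must be TARGET or PUNCTURABLE")


def evaluate_direction(labels: LabelVolume, target, direction: RayDirection,
                       config: SweepConfig | None = None) -> Route:
    """Trace one direction outward from the target and classify it.

    TARGET and PUNCTURABLE voxels pass; the first NON_PUNCTURABLE or
    INTERIOR_AIR voxel blocks the direction; the first EXTERIOR_AIR voxel
    makes it a candidate, with the skin-entry voxel being the last tissue
    voxel before the air.
    """
    cfg = config or SweepConfig()
    origin, start_idx = _resolve_target(labels, target)
    _check_start(labels, start_idx)
    max_t = cfg.max_ray_length_mm or labels.diagonal_mm
    tr = traverse_ray(origin, direction, labels.shape, labels.spacing_mm, max_t)
    passed: list[VoxelIndex] = []
    # Voxels first touched at the same ray parameter (shared corner/edge) are
    # decided as one group, blockers first, then tissue, then exterior air:
    # a corner graze of a blocker always blocks, and a corner graze of air
    # never pre-empts tissue the ray still crosses at that same point.  This
    # keeps the decision independent of index orientation.
    for group in _tie_groups(tr):
        decision = _decide_group(labels, group, passed)
        if decision is None:
            continue
        kind, idx = decision
        if kind == "blocked":
            return Route(target=origin, direction=direction, status="blocked",
                         traversed=tuple(passed), blocked_reason=Label(labels.labels[idx]).name)
        entry = passed[-1] if passed else start_idx
        if not passed:  # target hugs the air boundary; no tissue traversed
            passed = [start_idx]
        entry_point = labels.voxel_center_mm(entry)
        return Route(target=origin, direction=direction, status="candidate",
                     entry_voxel=entry, entry_point=entry_point,
                     traversed=tuple(passed), distance_mm=math.dist(entry_point, origin))
    return Route(target=origin, direction=direction, status="blocked",
                 traversed=tuple(passed), blocked_reason=tr.terminated_reason)


def _tie_groups(tr) -> Iterator[list[VoxelIndex]]:
    """Runs of traversed voxels sharing one first-touch parameter."""
    group: list[VoxelIndex] = []
    t_prev = None
    for idx, t in zip(tr.voxels, tr.entry_params):
        if t_prev is not None and t - t_prev > 1e-9:
            yield group
            group = []
        group.append(idx)
        t_prev = t
    if group:
        yield group


def _decide_group(labels: LabelVolume, group: Sequence[VoxelIndex],
                  passed: list[VoxelIndex]) -> tuple[str, VoxelIndex] | None:
    """Apply the blocker > tissue > exterior-air priority to one tie group.

    Appends the group's passable voxels to ``passed``; returns a terminal
    decision or None to continue the walk.
    """
    air_at: VoxelIndex | None = None
    for idx in group:
        lab = Label(labels.labels[idx])
        if lab in _BLOCKING:
            return ("blocked", idx)
        if lab == Label.EXTERIOR_AIR and air_at is None:
            air_at = idx
    for idx in group:
        if Label(labels.labels[idx]) in _PASSABLE:
            passed.append(idx)
    if air_at is not None:
        return ("candidate", air_at)
    return None


def search_routes(labels: LabelVolume, target, config: SweepConfig | None = None
                  ) -> CandidateSet:
    """Outward sweep over the full angular grid using supercover traversal."""
    cfg = config or SweepConfig()
    origin, start_idx = _resolve_target(labels, target)
    _check_start(labels, start_idx)
    routes = []
    for a_deg, b_deg in cfg.angle_grid_deg():
        d = direction_from_angles(math.radians(a_deg), math.radians(b_deg))
        routes.append(evaluate_direction(labels, origin, d, cfg))
    cset = CandidateSet(routes=tuple(routes), target=origin, config=cfg, method="proposed")
    if cset.n_candidates == 0:
        logger.warning("no candidate routes found (target may be fully enclosed)")
    return cset


# ---------------------------------------------------------------------------
# Brute-force iterative extension (verification oracle)
# ---------------------------------------------------------------------------

def _sample_params(labels: LabelVolume, origin: np.ndarray, u: np.ndarray,
                   max_t: float) -> np.ndarray:
    """Sample parameters along the ray: a uniform grid at half the minimum
    spacing, every cell-boundary crossing, and the midpoints between
    consecutive crossings (so every properly crossed cell holds a sample)."""
    sp = labels.spacing_mm
    step = min(sp) / 2.0
    ts = [np.arange(0.0, max_t + step / 2, step)]
    crossings = [np.array([0.0, max_t])]
    for a in range(3):
        if u[a] == 0.0:
            continue
        bounds = np.arange(0, labels.shape[a] + 1) * sp[a]
        t = (bounds - origin[a]) / u[a]
        crossings.append(t[(t > 0) & (t < max_t)])
    cross = np.unique(np.concatenate(crossings))
    ts.append(cross)
    ts.append((cross[:-1] + cross[1:]) / 2.0)
    return np.unique(np.concatenate(ts))


def _closure_cells(labels: LabelVolume, point: np.ndarray) -> list[VoxelIndex]:
    """All in-bounds voxels whose closed cell contains the point."""
    tol = 1e-9
    per_axis: list[list[int]] = []
    for a in range(3):
        s = labels.spacing_mm[a]
        q = point[a] / s
        b = int(round(q))
        if abs(point[a] - b * s) <= tol:
            cand = [c for c in (b - 1, b) if 0 <= c < labels.shape[a]]
        else:
            f = int(math.floor(q))
            cand = [f] if 0 <= f < labels.shape[a] else []
        if not cand:
            return []
        per_axis.append(cand)
    return [VoxelIndex(i, j, k) for i in per_axis[0] for j in per_axis[1] for k in per_axis[2]]


def brute_force_search(labels: LabelVolume, target, config: SweepConfig | None = None
                       ) -> CandidateSet:
    """Iterative segment-extension search (the verification oracle).

    For each direction on the angular grid the trial segment grows outward
    in increments of ``extension_step_mm``; after each extension every voxel
    the new portion touches is examined.  A touched non-puncturable voxel
    ends the trial for that direction; reaching exterior air records a
    candidate; leaving the volume or exhausting the ray length blocks it.
    """
    cfg = config or SweepConfig()
    origin_pt, start_idx = _resolve_target(labels, target)
    _check_start(labels, start_idx)
    origin = np.asarray(origin_pt, dtype=float)
    max_t = cfg.max_ray_length_mm or labels.diagonal_mm
    extent = np.array(labels.extent_mm)

    routes = []
    for a_deg, b_deg in cfg.angle_grid_deg():
        d = direction_from_angles(math.radians(a_deg), math.radians(b_deg))
        u = np.asarray(d.unit_vector)
        ts = _sample_params(labels, origin, u, max_t)
        route = None
        passed: list[VoxelIndex] = []
        seen: set[VoxelIndex] = set()
        n_ext = 1
        pos = 0
        while route is None:
            limit = min(n_ext * cfg.extension_step_mm, max_t)
            while pos < len(ts) and ts[pos] <= limit:
                p = origin + ts[pos] * u
                pos += 1
                if np.any(p < -1e-9) or np.any(p > extent + 1e-9):
                    route = Route(target=origin_pt, direction=d, status="blocked",
                                  traversed=tuple(passed), blocked_reason="left_volume")
                    break
                # the closure cells of one sample point form a tie group and
                # get the same blocker > tissue > air priority as the sweep
                group = [idx for idx in _closure_cells(labels, p) if idx not in seen]
                decision = _decide_group(labels, group, passed)
                seen.update(group)
                if decision is not None:
                    kind, idx = decision
                    if kind == "blocked":
                        route = Route(target=origin_pt, direction=d, status="blocked",
                                      traversed=tuple(passed),
                                      blocked_reason=Label(labels.labels[idx]).name)
                    else:
                        entry = passed[-1] if passed else start_idx
                        if not passed:
                            passed = [start_idx]
                        entry_point = labels.voxel_center_mm(entry)
                        route = Route(target=origin_pt, direction=d, status="candidate",
                                      entry_voxel=entry, entry_point=entry_point,
                                      traversed=tuple(passed),
                                      distance_mm=math.dist(entry_point, origin_pt))
                    break
            if route is None:
                if limit >= max_t:
                    route = Route(target=origin_pt, direction=d, status="blocked",
                                  traversed=tuple(passed), blocked_reason="reached_max_t")
                else:
                    n_ext += 1
        routes.append(route)

    cset = CandidateSet(routes=tuple(routes), target=origin_pt, config=cfg,
                        method="brute_force")
    if cset.n_candidates == 0:
        logger.warning("no candidate routes found (target may be fully enclosed)")
    return cset
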