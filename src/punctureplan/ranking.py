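"""Ranking of candidate routes: shortest, safe, and combined-optimal orders.

* *shortest*: ascending puncture distance — minimizes needle path and
  procedure time;
* *safe*: descending clearance, where a route's clearance is the minimum
  Euclidean distance (mm, spacing-aware) from any voxel on the route to the
  nearest non-puncturable or enclosed-air voxel — tolerant of needle
  deflection;
* *optimal*: a weighted combination of the two rank positions, a configurable
  heuristic stand-in for the physician's joint judgment.

Clearance is computed with an exact Euclidean distance transform of the
obstacle mask, so one transform serves every route.  For presentation, ranked
routes can be partitioned into azimuthal sectors (default 30 degrees), keeping
the best few per sector so the physician sees spatially diverse options.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .classify import Label, LabelVolume
from .search import CandidateSet, Route

_OBSTACLE_LABELS = (Label.NON_PUNCTURABLE, Label.INTERIOR_AIR)


@dataclass(frozen=True)
class RankingConfig:
    mode: str = "shortest"  # "shortest" | "safe" | "optimal"
    sector_width_deg: float = 30.0
    per_sector: int = 1
    optimal_weight: float = 0.5  # weight of distance rank vs clearance rank

    def validate(self) -> None:
        if self.mode not in ("shortest", "safe", "optimal"):
            raise ValueError(f"unknown ranking mode {self.mode!r}")
        if self.sector_width_deg <= 0 or self.per_sector < 1:
            raise ValueError("sector_width_deg must be positive and per_sector >= 1")
        n = 360.0 / self.sector_width_deg
        if abs(round(n) - n) > 1e-9:
            raise ValueError(f"360 must be divisible by sector_width_deg={self.sector_width_deg}")
        if not 0.0 <= self.optimal_weight <= 1.0:
            raise ValueError("optimal_weight must lie in [0, 1]")


@dataclass(frozen=True)
class RankedRoute:
    route: Route
    rank: int
    sector_id: int
    distance_rank: int
    clearance_rank: int


def obstacle_distance_map(labels: LabelVolume) -> np.ndarray | None:
    """Exact Euclidean distance (mm) from each voxel center to the nearest
    obstacle voxel center; None when the volume has no obstacles."""
    obstacle = np.isin(labels.labels, _OBSTACLE_LABELS)
    if not obstacle.any():
        return None
    return ndimage.distance_transform_edt(~obstacle, sampling=labels.spacing_mm)


def safety_clearance(route: Route, labels: LabelVolume,
                     distance_map: np.ndarray | None = ...) -> float:
    """Minimum clearance (mm) of a route: min over its voxels of the distance
    to the nearest non-puncturable / interior-air voxel.  An obstacle-free
    volume returns the volume diagonal as a finite 'unbounded' sentinel."""
    if not route.traversed:
        raise ValueError("route has no traversed voxels")
    if distance_map is ...:
        distance_map = obstacle_distance_map(labels)
    if distance_map is None:
        return labels.diagonal_mm
    idx = np.array(route.traversed)
    return float(distance_map[idx[:, 0], idx[:, 1], idx[:, 2]].min())


def _sort_key_shortest(r: Route) -> tuple:
    return (r.distance_mm, r.direction.alpha, r.direction.beta)


def rank_candidates(cset: CandidateSet, labels: LabelVolume,
                    config: RankingConfig | None = None) -> list[RankedRoute]:
    """Order candidates by the configured mode; deterministic tie-breaks.

    Every returned route has its ``clearance_mm`` filled in, plus its 1-based
    position under both the distance and the clearance orderings.
    """
    cfg = config or RankingConfig()
    cfg.validate()
    cands = list(cset.candidates)
    if not cands:
        return []
    dmap = obstacle_distance_map(labels)
    cands = [replace(r, clearance_mm=safety_clearance(r, labels, dmap)) for r in cands]

    by_dist = sorted(cands, key=_sort_key_shortest)
    dist_rank = {id(r): n + 1 for n, r in enumerate(by_dist)}
    by_clear = sorted(cands, key=lambda r: (-r.clearance_mm, *_sort_key_shortest(r)))
    clear_rank = {id(r): n + 1 for n, r in enumerate(by_clear)}

    if cfg.mode == "shortest":
        ordered = by_dist
    elif cfg.mode == "safe":
        ordered = by_clear
    else:
        ordered = sorted(
            cands,
            key=lambda r: (
                cfg.optimal_weight * dist_rank[id(r)]
                + (1.0 - cfg.optimal_weight) * clear_rank[id(r)],
                *_sort_key_shortest(r),
            ),
        )
    width = cfg.sector_width_deg
    return [
        RankedRoute(route=r, rank=n + 1,
                    sector_id=int(math.floor((r.direction.beta_deg % 360.0) / width)),
                    distance_rank=dist_rank[id(r)], clearance_rank=clear_rank[id(r)])
        for n, r in enumerate(ordered)
    ]


def partition_by_sector(ranked: Sequence[RankedRoute], config: RankingConfig | None = None
                        ) -> list[RankedRoute]:
    """Keep the top ``per_sector`` routes of each occupied azimuthal sector,
    ordered by sector then rank."""
    cfg = config or RankingConfig()
    cfg.validate()
    by_sector: dict[int, list[RankedRoute]] = {}
    for rr in sorted(ranked, key=lambda rr: rr.rank):
        bucket = by_sector.setdefault(rr.sector_id, [])
        if len(bucket) < cfg.per_sector:
            bucket.append(rr)
    out = []
    for sector in sorted(by_sector):
        out.extend(by_sector[sector])
    return out
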