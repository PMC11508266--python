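"""Route search: single-direction evaluation, angular sweep, brute force."""

from __future__ import annotations

import math

import numpy as np
import pytest

import punctureplan as pp
from punctureplan.classify import Label


def _column_labels(n=11, spacing=(1.0, 1.0, 1.0), bone_at=None):
    """Quasi-1D phantom: tissue column along z with exterior air at the top."""
    values = np.full((3, 3, n + 1), 20.0)
    values[:, :, n] = -1000.0
    if bone_at is not None:
        values[1, 1, bone_at] = 400.0
    vol = pp.CTVolume(values=values, spacing_mm=spacing)
    return pp.mark_target(pp.classify_and_label(vol), (1, 1, 0))


class TestEvaluateDirection:
    def test_straight_column_candidate(self):
        labels = _column_labels(n=10)
        d = pp.direction_from_angles(math.pi / 2, 0.0)  # +z
        r = pp.evaluate_direction(labels, (1, 1, 0), d)
        assert r.status == "candidate"
        assert tuple(r.entry_voxel) == (1, 1, 9)
        assert r.distance_mm == pytest.approx(9.0)
        assert r.traversed[0] == (1, 1, 0) and r.traversed[-1] == (1, 1, 9)

    def test_bone_blocks(self):
        labels = _column_labels(n=10, bone_at=5)
        d = pp.direction_from_angles(math.pi / 2, 0.0)
        r = pp.evaluate_direction(labels, (1, 1, 0), d)
        assert r.status == "blocked"
        assert r.blocked_reason == "NON_PUNCTURABLE"

    def test_anisotropic_distance_closed_form(self):
        # entry at index offset (2, 0, 1) from target, spacing (0.5, 0.5, 2.0)
        values = np.full((8, 3, 4), 20.0)
        vol = pp.CTVolume(values=values, spacing_mm=(0.5, 0.5, 2.0))
        labels = pp.classify_and_label(vol)
        labels.labels[3:, :, :] = Label.EXTERIOR_AIR
        labels.labels[3, 1, 2] = Label.PUNCTURABLE  # entry voxel
        labels = pp.mark_target(labels, (1, 1, 1))
        target_c = labels.voxel_center_mm((1, 1, 1))
        entry_c = labels.voxel_center_mm((3, 1, 2))
        v = np.asarray(entry_c) - np.asarray(target_c)
        r = pp.evaluate_direction(labels, (1, 1, 1), pp.direction_from_vector(v))
        assert r.status == "candidate"
        assert tuple(r.entry_voxel) == (3, 1, 2)
        assert r.distance_mm == pytest.approx(math.sqrt(1.0 + 0.0 + 4.0))

    def test_ray_exits_volume_blocked(self):
        values = np.full((5, 5, 5), 20.0)  # no air anywhere
        labels = pp.mark_target(pp.classify_and_label(pp.CTVolume(values, (1, 1, 1))),
                                (2, 2, 2))
        d = pp.direction_from_angles(0.0, 0.0)
        r = pp.evaluate_direction(labels, (2, 2, 2), d)
        assert r.status == "blocked"
        assert r.blocked_reason == "left_volume"

    def test_start_in_bone_rejected(self):
        values = np.full((5, 5, 5), 400.0)
        labels = pp.classify_and_label(pp.CTVolume(values, (1, 1, 1)))
        with pytest.raises(ValueError, match="must be TARGET or PUNCTURABLE"):
            pp.evaluate_direction(labels, (2, 2, 2), pp.direction_from_angles(0.0, 0.0))


class TestAngularGrid:
    @pytest.mark.parametrize("step,expected", [(1.0, 179 * 360 + 2), (5.0, 35 * 72 + 2),
                                               (15.0, 11 * 24 + 2)])
    def test_pole_deduplicated_count(self, step, expected):
        cfg = pp.SweepConfig(alpha_step_deg=step, beta_step_deg=step)
        grid = list(cfg.angle_grid_deg())
        assert len(grid) == expected
        assert len(set(grid)) == expected  # no duplicates
        assert sum(1 for a, _ in grid if abs(a) == 90.0) == 2

    def test_two_fan_covers_both_principal_planes(self):
        cfg = pp.SweepConfig(alpha_step_deg=10.0, beta_step_deg=10.0, two_fan=True)
        grid = set(cfg.angle_grid_deg())
        assert all(a == 0.0 or b in (0.0, 180.0) for a, b in grid)
        assert (0.0, 90.0) in grid and (40.0, 0.0) in grid and (-40.0, 180.0) in grid
        assert len(grid) == len(list(cfg.angle_grid_deg()))

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            pp.SweepConfig(beta_step_deg=7.0).validate()
        with pytest.raises(ValueError):
            pp.SweepConfig(alpha_step_deg=-1.0).validate()


class TestSearchRoutes:
    def test_unobstructed_ball_all_candidates(self, soft_ball_labels):
        spec, labels = soft_ball_labels
        cfg = pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0)
        cs = pp.search_routes(labels, spec.target, cfg)
        assert cs.n_candidates == cs.n_directions_tried
        # min distance ~ ball radius (target at center), within a voxel diagonal
        dmin = min(r.distance_mm for r in cs.candidates)
        assert abs(dmin - 12.0) <= math.sqrt(3.0)

    def test_bone_shell_with_hole_candidates_inside_cone(self):
        c = (24.0, 24.0, 24.0)
        hole_axis = (1.0, 0.0, 0.0)
        half_angle = 25.0
        spec = pp.PhantomSpec(
            shape=(48, 48, 48),
            body=pp.Ellipsoid(c, (20.0, 20.0, 20.0), hu=20.0),
            bone_shapes=(pp.SphericalShell(c, 8.0, 12.0, hu=400.0,
                                           holes=((hole_axis, half_angle),)),),
            target=pp.VoxelIndex(23, 23, 23),
        )
        labels = pp.mark_target(pp.classify_and_label(pp.make_phantom(spec)), spec.target)
        cfg = pp.SweepConfig(alpha_step_deg=5.0, beta_step_deg=5.0)
        cs = pp.search_routes(labels, spec.target, cfg)
        assert 0 < cs.n_candidates < cs.n_directions_tried
        # angular margin: one voxel diagonal seen from the inner shell radius
        margin = math.degrees(math.atan2(math.sqrt(3.0), 8.0))
        for r in cs.candidates:
            cosang = float(np.dot(r.direction.unit_vector, hole_axis))
            ang = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            assert ang <= half_angle + margin

    def test_fully_enclosed_target_no_candidates(self):
        c = (16.0, 16.0, 16.0)
        spec = pp.PhantomSpec(
            shape=(32, 32, 32),
            body=pp.Ellipsoid(c, (13.0, 13.0, 13.0), hu=20.0),
            bone_shapes=(pp.SphericalShell(c, 5.0, 8.0, hu=400.0),),
            target=pp.VoxelIndex(15, 15, 15),
        )
        labels = pp.mark_target(pp.classify_and_label(pp.make_phantom(spec)), spec.target)
        cs = pp.search_routes(labels, spec.target,
                              pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0))
        assert cs.n_candidates == 0

    def test_determinism(self, default_labels):
        spec, _, labels = default_labels
        cfg = pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0)
        a = pp.search_routes(labels, spec.target, cfg)
        b = pp.search_routes(labels, spec.target, cfg)
        assert a == b

    def test_distance_bounds(self, default_labels):
        spec, _, labels = default_labels
        cfg = pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0)
        cs = pp.search_routes(labels, spec.target, cfg)
        assert cs.n_candidates > 0
        min_sp = min(labels.spacing_mm)
        origin = np.asarray(labels.voxel_center_mm(spec.target))
        for r in cs.candidates:
            assert r.distance_mm <= (cfg.max_ray_length_mm or labels.diagonal_mm)
            # each axis crosses a boundary at most once per spacing step, so a
            # path with g distinct first-touch parameters spans >= (g-4)/3
            # minimum-spacing steps (corner-grazed voxels share a parameter
            # and add no length)
            tr = pp.traverse_ray(origin, r.direction, labels.shape,
                                 labels.spacing_mm, labels.diagonal_mm)
            entry_t = dict(zip(tr.voxels, tr.entry_params))
            groups = len({round(entry_t[v], 9) for v in r.traversed})
            assert r.distance_mm >= (groups - 4) * min_sp / 3.0 - 1e-9

    def test_rotation_equivariance_about_z(self):
        """Rotating the phantom 90 deg about z shifts candidate azimuths by 90."""
        spec = pp.random_phantom_spec(seed=4, shape=(30, 30, 30), spacing_mm=(1.0, 1.0, 1.0))
        vol = pp.make_phantom(spec)
        labels = pp.mark_target(pp.classify_and_label(vol), spec.target)
        # rot90(axes=(1, 0)) maps (i, j) -> (j, N-1-i): directions rotate by
        # -90 deg about z, so candidate azimuths shift as beta -> beta - 90
        rot_values = np.rot90(vol.values, k=1, axes=(1, 0))
        rot_vol = pp.CTVolume(values=rot_values.copy(), spacing_mm=vol.spacing_mm)
        n = spec.shape[0]
        rot_target = (spec.target[1], n - 1 - spec.target[0], spec.target[2])
        rot_labels = pp.mark_target(pp.classify_and_label(rot_vol), rot_target)
        cfg = pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0)
        base = pp.search_routes(labels, spec.target, cfg)
        rot = pp.search_routes(rot_labels, rot_target, cfg)
        rot_status = {(round(r.direction.alpha_deg, 6), round(r.direction.beta_deg, 6)):
                      r.status for r in rot.routes}
        for r in base.routes:
            a = round(r.direction.alpha_deg, 6)
            b = round((r.direction.beta_deg - 90.0) % 360.0, 6)
            if abs(a) == 90.0:
                b = 0.0
            assert rot_status[(a, b)] == r.status


class TestBruteForceSearch:
    def test_empty_obstacles_all_candidates(self, soft_ball_labels):
        spec, labels = soft_ball_labels
        cfg = pp.SweepConfig(alpha_step_deg=30.0, beta_step_deg=30.0)
        cs = pp.brute_force_search(labels, spec.target, cfg)
        assert cs.n_candidates == cs.n_directions_tried

    def test_fully_enclosed_target_zero_candidates(self):
        c = (12.0, 12.0, 12.0)
        spec = pp.PhantomSpec(
            shape=(24, 24, 24),
            body=pp.Ellipsoid(c, (9.0, 9.0, 9.0), hu=20.0),
            bone_shapes=(pp.SphericalShell(c, 4.0, 7.0, hu=400.0),),
            target=pp.VoxelIndex(11, 11, 11),
        )
        labels = pp.mark_target(pp.classify_and_label(pp.make_phantom(spec)), spec.target)
        cs = pp.brute_force_search(labels, spec.target,
                                   pp.SweepConfig(alpha_step_deg=30.0, beta_step_deg=30.0))
        assert cs.n_candidates == 0

    def test_agrees_with_sweep_on_random_phantom(self):
        spec = pp.random_phantom_spec(seed=9, shape=(32, 32, 32))
        labels = pp.mark_target(pp.classify_and_label(pp.make_phantom(spec)), spec.target)
        cfg = pp.SweepConfig(alpha_step_deg=15.0, beta_step_deg=15.0)
        sweep = pp.search_routes(labels, spec.target, cfg)
        brute = pp.brute_force_search(labels, spec.target, cfg)
        report = pp.compare_candidate_sets(sweep, brute)
        assert report["n_status_disagreements"] == 0
        assert report["max_entry_voxel_offset"] <= 1
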