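"""Elastic registration: Procrustes rotation, DP warping, Karcher mean."""

import numpy as np
import pytest

from shapemed import (
    SRVFCurve,
    WarpingFunction,
    align_cohort,
    align_pair,
    elastic_distance,
    karcher_mean,
    normalize_landmarks,
    optimal_rotation,
    optimal_warping,
    srvf_transform,
    simulate_shape_cohort_from_template,
    cc_like_template,
)
from shapemed.register import DP_STEPS, _dp_solve, _edge_cost

from conftest import fourier_curve


def rot(theta):
    return np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])


def smooth_warp(grid, a=0.1):
    g = grid + a * np.sin(2 * np.pi * grid) * grid * (1 - grid) * 4
    g = (g - g[0]) / (g[-1] - g[0])
    return WarpingFunction(grid=grid, values=g)


def exhaustive_warp_cost(q1, q2, grid):
    """Independent oracle: depth-first enumeration of every monotone lattice
    path with the DP step set, returning the minimal objective."""
    T = grid.size
    best = [np.inf]

    def dfs(i, j, acc):
        if acc >= best[0]:
            return
        if i == T - 1 and j == T - 1:
            best[0] = acc
            return
        for di, dj in DP_STEPS:
            ni, nj = i + di, j + dj
            if ni <= T - 1 and nj <= T - 1:
                dfs(ni, nj, acc + _edge_cost(q1, q2, grid, i, j, ni, nj))

    dfs(0, 0, 0.0)
    return best[0]


class TestOptimalRotation:
    def test_self_is_identity(self, template_srvf):
        O = optimal_rotation(template_srvf, template_srvf)
        assert np.allclose(O.entries, np.eye(2), atol=1e-12)

    def test_recovers_known_rotation(self, template_srvf):
        q = template_srvf
        R = rot(0.7)
        q2 = SRVFCurve(grid=q.grid, values=q.values @ R)  # = R^T q
        O = optimal_rotation(q, q2)
        assert np.allclose(O.entries, R, atol=1e-8)

    def test_brute_force_angle_agreement(self, template_srvf):
        # grid search over angles as an independent check of the SVD solution
        q = template_srvf
        rng = np.random.default_rng(0)
        q2 = SRVFCurve(grid=q.grid, values=q.values @ rot(1.2) + 0.05 * rng.standard_normal(q.values.shape))
        O = optimal_rotation(q, q2)

        def objective(theta):
            d = q.values - q2.values @ rot(theta).T
            return np.trapezoid((d**2).sum(axis=1), q.grid)

        angles = np.linspace(-np.pi, np.pi, 100001)
        best = angles[np.argmin([objective(a) for a in angles[::100]]) * 100]
        fine = angles[np.abs(angles - best) < 0.01]
        best = fine[np.argmin([objective(a) for a in fine])]
        assert abs(O.angle - best) < 1e-4

    def test_reflection_still_proper(self, template_srvf):
        q = template_srvf
        refl = SRVFCurve(grid=q.grid, values=q.values @ np.diag([1.0, -1.0]))
        O = optimal_rotation(q, refl)
        assert abs(np.linalg.det(O.entries) - 1.0) < 1e-10

    def test_degenerate_flag(self):
        grid = np.linspace(0, 1, 20)
        z = SRVFCurve(grid=grid, values=np.zeros((20, 2)))
        O = optimal_rotation(z, z)
        assert O.degenerate and np.allclose(O.entries, np.eye(2))


class TestOptimalWarping:
    def test_identity_for_self(self, template_srvf):
        tau = optimal_warping(template_srvf, template_srvf)
        assert np.allclose(tau.values, tau.grid, atol=1e-12)

    def test_small_grid_rejected(self):
        grid = np.linspace(0, 1, 4)
        q = SRVFCurve(grid=grid, values=np.ones((4, 2)))
        with pytest.raises(ValueError, match="at least 5"):
            optimal_warping(q, q)

    def test_recovers_applied_warp(self):
        c = fourier_curve(m=300, seed=2)
        q = srvf_transform(normalize_landmarks(c, 150), unit_norm=True)
        gamma = smooth_warp(q.grid)
        from shapemed import warp_apply

        qw = warp_apply(q, gamma)
        tau = optimal_warping(q, qw)
        # tau should approximately invert gamma: tau o gamma ~ identity
        comp = np.interp(gamma.values, q.grid, tau.values)
        step = q.grid[1] - q.grid[0]
        assert np.abs(comp - q.grid).max() < 2 * step

    def test_objective_not_worse_than_identity(self):
        from shapemed import warp_apply

        rng = np.random.default_rng(7)
        for k in range(20):
            q1 = srvf_transform(normalize_landmarks(fourier_curve(seed=2 * k), 60), unit_norm=True)
            q2 = srvf_transform(normalize_landmarks(fourier_curve(seed=2 * k + 1), 60), unit_norm=True)
            before = np.trapezoid(((q1.values - q2.values) ** 2).sum(axis=1), q1.grid)
            tau = optimal_warping(q1, q2)
            after_vals = warp_apply(q2, tau).values
            after = np.trapezoid(((q1.values - after_vals) ** 2).sum(axis=1), q1.grid)
            assert after <= before + 1e-10

    @pytest.mark.parametrize("T", [9, 11])
    def test_dp_equals_exhaustive_enumeration(self, T):
        rng = np.random.default_rng(T)
        for k in range(3):
            q1 = srvf_transform(normalize_landmarks(fourier_curve(seed=100 + k), T), unit_norm=True)
            q2 = srvf_transform(normalize_landmarks(fourier_curve(seed=200 + k), T), unit_norm=True)
            v1 = np.ascontiguousarray(q1.values)
            v2 = np.ascontiguousarray(q2.values)
            _, dp_cost = _dp_solve(v1, v2, q1.grid)
            oracle = exhaustive_warp_cost(v1, v2, q1.grid)
            assert dp_cost == pytest.approx(oracle, abs=1e-12)


class TestWarpApply:
    def test_identity_noop(self, template_srvf):
        from shapemed import warp_apply

        tau = WarpingFunction(grid=template_srvf.grid, values=template_srvf.grid.copy())
        q2 = warp_apply(template_srvf, tau)
        assert np.allclose(q2.values, template_srvf.values, atol=1e-12)

    def test_norm_preserved(self):
        from shapemed import warp_apply

        c = fourier_curve(m=400, seed=4)
        q = srvf_transform(normalize_landmarks(c, 200), unit_norm=True)
        tau = smooth_warp(q.grid)
        assert abs(warp_apply(q, tau).norm() - q.norm()) < 1e-3

    def test_inverse_composition(self):
        from shapemed import warp_apply

        c = fourier_curve(m=400, seed=6)
        q = srvf_transform(normalize_landmarks(c, 200), unit_norm=True)
        tau = smooth_warp(q.grid)
        back = warp_apply(warp_apply(q, tau), tau.inverse())
        # tolerance from the grid-refinement study: sup error ~1e-2 at T=200
        assert np.abs(back.values - q.values).max() < 0.05


class TestElasticDistance:
    def test_zero_for_identical(self, template_srvf):
        assert elastic_distance(template_srvf, template_srvf) <= 1e-10

    def test_invariance_under_group_action(self):
        from shapemed import warp_apply

        rng = np.random.default_rng(1)
        devs = []
        for k in range(5):
            q1 = srvf_transform(normalize_landmarks(fourier_curve(seed=300 + k), 100), unit_norm=True)
            q2 = srvf_transform(normalize_landmarks(fourier_curve(seed=400 + k), 100), unit_norm=True)
            d0 = elastic_distance(q1, q2)
            R = rot(rng.uniform(-np.pi, np.pi))
            q2t = warp_apply(SRVFCurve(grid=q2.grid, values=q2.values @ R.T), smooth_warp(q2.grid, a=0.05))
            d1 = elastic_distance(q1, q2t)
            devs.append(abs(d0 - d1))
        assert max(devs) < 0.05

    def test_aligned_version_not_farther(self, template_srvf):
        q1 = template_srvf
        q2 = srvf_transform(normalize_landmarks(fourier_curve(seed=8), 100), unit_norm=True)
        aligned, _, _ = align_pair(q1, q2)
        d_aligned = np.sqrt(np.trapezoid(((q1.values - aligned.values) ** 2).sum(axis=1), q1.grid))
        assert d_aligned <= elastic_distance(q1, q2) + 1e-9


class TestKarcherMean:
    def test_single_curve(self, template_srvf):
        atlas = karcher_mean([template_srvf])
        assert atlas.converged and atlas.n_iterations == 1
        assert np.allclose(atlas.srvf.values, template_srvf.values)

    def test_identical_copies(self, template_srvf):
        atlas = karcher_mean([template_srvf] * 5)
        assert atlas.converged
        assert np.abs(atlas.srvf.values - template_srvf.values).max() < 1e-6

    def test_mean_of_rotated_pair_beats_inputs(self, template_srvf):
        q = template_srvf
        q2 = SRVFCurve(grid=q.grid, values=q.values @ rot(0.5).T)
        curves = [q, q2]
        atlas = karcher_mean(curves)

        def total_sq(ref):
            return sum(elastic_distance(ref, c) ** 2 for c in curves)

        t_mean = total_sq(atlas.srvf)
        assert t_mean <= total_sq(q) + 1e-8 and t_mean <= total_sq(q2) + 1e-8

    def test_objective_monotone(self, template):
        curves = simulate_shape_cohort_from_template(template, 8, seed=3)
        srvfs = [srvf_transform(normalize_landmarks(c, 80), unit_norm=True) for c in curves]
        atlas = karcher_mean(srvfs)
        tr = atlas.objective_trace
        assert all(tr[i + 1] <= tr[i] + 1e-8 for i in range(len(tr) - 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            karcher_mean([])


class TestAlignCohort:
    def test_identical_curves_collapse_to_atlas(self, template):
        atlas, aligned = align_cohort([template] * 4, n_grid=80)
        for a in aligned:
            assert np.abs(a.values - atlas.srvf.values).max() < 1e-6

    def test_nuisance_variation_removed(self, template):
        curves = simulate_shape_cohort_from_template(
            template, 30, rotation_sd=0.4, warp_sd=0.2, seed=12
        )
        atlas, aligned = align_cohort(curves, n_grid=100)
        A = np.stack([a.values for a in aligned])
        post_var = A.var(axis=0).mean()
        raw = np.stack(
            [srvf_transform(normalize_landmarks(c, 100), unit_norm=True).values for c in curves]
        )
        pre_var = raw.var(axis=0).mean()
        assert post_var / pre_var < 0.1

    def test_minimal_cohort(self, template):
        curves = simulate_shape_cohort_from_template(template, 2, seed=5)
        atlas, aligned = align_cohort(curves, n_grid=60)
        assert len(aligned) == 2
        assert all(a.grid.size == 60 for a in aligned)

    def test_single_curve_rejected(self, template):
        with pytest.raises(ValueError, match="at least two"):
            align_cohort([template])

    def test_error_carries_subject_id(self, template):
        bad = simulate_shape_cohort_from_template(template, 2, seed=5)
        bad[1].points = np.full_like(bad[1].points, 0.5)
        with pytest.raises(ValueError, match="S00001"):
            align_cohort(bad, n_grid=60)
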