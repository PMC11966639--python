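"""Anisotropic eikonal solver: conduction velocities, causality, comparison."""

import numpy as np
import pytest

import atriafiber as af
from atriafiber.eikonal import (
    EikonalError,
    EPParams,
    conductivity_tensor,
    fit_conduction_velocity,
    plane_stimulus,
    solve_activation,
    spherical_stimulus,
    uniform_tensors,
    volume_error_index,
)
from atriafiber.fibers import local_axis


@pytest.fixture(scope="module")
def slab_run(slab):
    ep = EPParams()
    tens = uniform_tensors(slab, [1, 0, 0], ep)
    along = solve_activation(slab, tens, ep, plane_stimulus(slab, 0))
    across = solve_activation(slab, tens, ep, plane_stimulus(slab, 1))
    return ep, tens, along, across


class TestConductivityTensor:
    def test_isotropic_limit(self):
        ep = EPParams(sigma_f=2e-4, sigma_s=2e-4, sigma_n=2e-4)
        sig = conductivity_tensor([1, 0, 0], [0, 1, 0], [0, 0, 1], ep)
        assert np.allclose(sig, 2e-4 * np.eye(3))

    def test_axis_aligned(self):
        ep = EPParams()
        sig = conductivity_tensor([1, 0, 0], [0, 1, 0], [0, 0, 1], ep)
        assert np.allclose(sig, np.diag([ep.sigma_f, ep.sigma_n, ep.sigma_s]))

    def test_trace_and_eigenvalues_for_random_frames(self, rng):
        ep = EPParams(sigma_s=0.3e-4, sigma_n=0.2e-4)
        g = rng.normal(size=(50, 3))
        k = rng.normal(size=(50, 3))
        e_l, e_n, e_t, bad = local_axis(g, k)
        sig = conductivity_tensor(e_l[~bad], e_n[~bad], e_t[~bad], ep)
        assert np.allclose(np.trace(sig, axis1=1, axis2=2),
                           ep.sigma_f + ep.sigma_s + ep.sigma_n)
        ev = np.sort(np.linalg.eigvalsh(sig), axis=1)
        assert np.allclose(ev, np.sort([ep.sigma_f, ep.sigma_s, ep.sigma_n]))

    def test_non_orthonormal_frame_rejected(self):
        with pytest.raises(EikonalError):
            conductivity_tensor([1, 0, 0], [1, 0, 0], [0, 0, 1], EPParams())
        with pytest.raises(EikonalError):
            conductivity_tensor([2, 0, 0], [0, 1, 0], [0, 0, 1], EPParams())


class TestStimuli:
    def test_radius_larger_than_mesh_takes_all(self, slab):
        nodes = spherical_stimulus(slab, slab.nodes.mean(0), 1.0)
        assert nodes.size == slab.n_nodes

    def test_zero_radius_falls_back_to_nearest(self, slab):
        c = slab.nodes[17] + 1e-6
        nodes = spherical_stimulus(slab, c, 0.0)
        assert np.array_equal(nodes, [17])

    def test_corner_sphere_matches_bruteforce_scan(self, slab):
        center = slab.nodes.min(0)
        r = 2e-3
        fast = spherical_stimulus(slab, center, r)
        slow = [i for i in range(slab.n_nodes)
                if np.linalg.norm(slab.nodes[i] - center) <= r]
        assert np.array_equal(fast, slow)


class TestSlabConduction:
    def test_along_fiber_speed(self, slab, slab_run):
        _, _, along, _ = slab_run
        cv = fit_conduction_velocity(slab, along, [1, 0, 0])
        assert cv == pytest.approx(1.0, rel=0.03)

    def test_cross_fiber_speed(self, slab, slab_run):
        _, _, _, across = slab_run
        cv = fit_conduction_velocity(slab, across, [0, 1, 0])
        assert cv == pytest.approx(0.4, rel=0.03)

    def test_anisotropy_ratio(self, slab, slab_run):
        ep, _, along, across = slab_run
        ratio = (fit_conduction_velocity(slab, along, [1, 0, 0])
                 / fit_conduction_velocity(slab, across, [0, 1, 0]))
        assert ratio == pytest.approx(np.sqrt(ep.sigma_f / ep.sigma_s), rel=0.05)

    def test_mesh_refinement_does_not_worsen_cv(self):
        errs = []
        for h in (1.0e-3, 0.5e-3):
            spec = af.SlabSpec(lx=10e-3, ly=3e-3, lz=2e-3, h=h)
            m = af.make_slab(spec)
            ep = EPParams()
            tens = uniform_tensors(m, [1, 0, 0], ep)
            am = solve_activation(m, tens, ep, plane_stimulus(m, 0))
            errs.append(abs(fit_conduction_velocity(m, am, [1, 0, 0]) - 1.0))
        assert errs[1] <= errs[0] + 1e-9

    def test_causality_and_boundary_conditions(self, slab, slab_run):
        _, _, along, _ = slab_run
        u = along.u
        assert (u >= 0).all()
        assert np.allclose(u[along.stimulus], 0.0)
        # activation is non-decreasing along the propagation coordinate
        x = slab.nodes[:, 0]
        y, z = slab.nodes[:, 1], slab.nodes[:, 2]
        line = (np.abs(y - y.min()) < 1e-12) & (np.abs(z - z.min()) < 1e-12)
        order = np.argsort(x[line])
        assert (np.diff(u[line][order]) >= -1e-12).all()
        assert along.tat == pytest.approx(u.max())


def test_isotropic_point_source_matches_metric_distance():
    spec = af.SlabSpec(lx=8e-3, ly=8e-3, lz=8e-3, h=0.4e-3)
    cube = af.make_slab(spec)
    ep = EPParams(sigma_f=0.5e-4, sigma_s=0.5e-4, sigma_n=0.5e-4)
    tens = uniform_tensors(cube, [1, 0, 0], ep)
    stim = spherical_stimulus(cube, cube.nodes.mean(0), 0.0)
    am = solve_activation(cube, tens, ep, stim,
                          source_init_radius=5 * spec.h)
    speed = ep.c_f * np.sqrt(0.5e-4)
    d = np.linalg.norm(cube.nodes - cube.nodes[stim[0]], axis=1)
    sel = d > 10 * spec.h  # away from the source singularity
    rel = np.abs(am.u[sel] - d[sel] / speed) / (d[sel] / speed)
    assert rel.max() < 0.05


def test_unreachable_nodes_raise(slab):
    ep = EPParams(max_iter=1)
    tens = uniform_tensors(slab, [1, 0, 0], ep)
    with pytest.raises(EikonalError):
        solve_activation(slab, tens, ep, np.array([0]))


def test_empty_stimulus_rejected(slab):
    ep = EPParams()
    tens = uniform_tensors(slab, [1, 0, 0], ep)
    with pytest.raises(EikonalError):
        solve_activation(slab, tens, ep, np.array([], dtype=int))


class TestComparison:
    def test_identical_maps_give_zero_indicators(self, slab, slab_run):
        _, _, along, _ = slab_run
        cmp = af.compare_at(along, along)
        assert cmp.err_tat == 0.0
        assert cmp.max_err_at == 0.0
        assert cmp.vol_gt10_pct == 0.0

    def test_volume_index_arithmetic(self):
        # 100 nodes, 95 below the threshold -> 5% exactly
        err = np.zeros(100)
        err[:5] = 0.2  # 20% of TAT=1
        assert volume_error_index(err, tat_ref=1.0) == pytest.approx(5.0)

    def test_uniform_scaling(self, slab, slab_run):
        _, _, along, _ = slab_run
        scaled = af.ActivationMap(u=1.2 * along.u, converged=True, n_iter=0)
        cmp = af.compare_at(scaled, along)
        assert cmp.err_tat == pytest.approx(0.2 * along.tat)
        assert cmp.err_tat_pct == pytest.approx(20.0)
        # |0.2 u| / TAT > 0.1 exactly where u > TAT/2
        expect = (along.u > along.tat / 2).mean() * 100
        assert cmp.vol_gt10_pct == pytest.approx(expect)

    def test_mismatched_meshes_rejected(self, slab_run):
        _, _, along, _ = slab_run
        other = af.ActivationMap(u=along.u[:-1], converged=True, n_iter=0)
        with pytest.raises(EikonalError):
            af.compare_at(along, other)

    def test_bundle_exceedance_listing(self, slab, slab_run):
        _, _, along, _ = slab_run
        labels = np.zeros(slab.n_nodes, dtype=int)
        labels[slab.nodes[:, 0] > slab.nodes[:, 0].mean()] = 7
        u2 = along.u.copy()
        bad = labels == 7
        u2[bad] += 0.5 * along.tat
        cmp = af.compare_at(
            af.ActivationMap(u=u2, converged=True, n_iter=0), along,
            labels=labels, legend={0: "near", 7: "far"},
        )
        assert cmp.bundles_exceeding == ["far"]
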