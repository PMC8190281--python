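import math

import numpy as np
import pytest

from ctrlnet import connectome as cn
from ctrlnet import control as ctl

from conftest import random_connectome, random_system
from oracles import (
    gramian_energy,
    qp_endpoint_projection,
    qp_optimal,
    qp_rollout_cost,
    scalar_solution,
)


def system_from(A):
    bound = float(np.linalg.eigvals(A).real.max())
    return cn.SystemMatrix(A=A, spectral_bound=bound, normalization="test")


class TestOptimalControl:
    def test_zero_fixed_point(self):
        sysm = system_from(-np.eye(2))
        spec = ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(2))
        res = ctl.optimal_control(sysm, spec)
        assert res.total_energy == 0.0
        np.testing.assert_allclose(res.u_traj, 0.0)
        np.testing.assert_allclose(res.x_traj, 0.0)

    def test_permutation_symmetry(self, rng):
        sysm = random_system(6, seed=9)
        x0 = rng.normal(size=6)
        xT = rng.normal(size=6)
        res = ctl.optimal_control(sysm, ctl.TransitionSpec(x0=x0, xT=xT))
        perm = rng.permutation(6)
        P = np.eye(6)[perm]
        psys = system_from(P @ sysm.A @ P.T)
        pres = ctl.optimal_control(psys, ctl.TransitionSpec(x0=P @ x0, xT=P @ xT))
        np.testing.assert_allclose(pres.x_traj, P @ res.x_traj, atol=1e-8)
        np.testing.assert_allclose(pres.u_traj, P @ res.u_traj, atol=1e-8)
        np.testing.assert_allclose(
            pres.nodal_energy, P @ res.nodal_energy, rtol=1e-8, atol=1e-12
        )
        assert pres.total_energy == pytest.approx(res.total_energy, rel=1e-9)

    def test_qp_oracle_n3_seed42(self):
        conn = random_connectome(3, seed=42)
        sysm = cn.stabilize(conn)
        x0 = np.array([1.0, 0.0, 0.0])
        xT = np.array([0.0, 1.0, 0.0])
        spec = ctl.TransitionSpec(x0=x0, xT=xT, horizon=1.0, rho=1.0, nsteps=2001)
        res = ctl.optimal_control(sysm, spec)
        oracle = qp_optimal(sysm.A, np.eye(3), x0, xT, T=1.0, rho=1.0, N=2000)
        assert res.cost == pytest.approx(oracle["cost"], rel=0.02)
        assert res.total_energy == pytest.approx(oracle["energy"], rel=0.02)

    def test_gramian_limit_large_rho(self):
        conn = random_connectome(3, seed=42)
        sysm = cn.stabilize(conn)
        x0 = np.array([1.0, 0.0, 0.0])
        xT = np.array([0.0, 1.0, 0.0])
        spec = ctl.TransitionSpec(x0=x0, xT=xT, rho=1e6, nsteps=2001)
        res = ctl.optimal_control(sysm, spec)
        e_min = gramian_energy(sysm.A, np.eye(3), x0, xT, T=1.0)
        assert res.total_energy == pytest.approx(e_min, rel=0.01)

    def test_scalar_closed_form(self):
        a, rho, x0, xT, T = 0.7, 1.3, 0.5, -1.2, 1.5
        sysm = system_from(np.array([[-a]]))
        spec = ctl.TransitionSpec(
            x0=[x0], xT=[xT], horizon=T, rho=rho, nsteps=4001
        )
        res = ctl.optimal_control(sysm, spec)
        x_fn, u_fn, energy = scalar_solution(a, rho, x0, xT, T)
        np.testing.assert_allclose(res.x_traj[0], x_fn(res.times), rtol=1e-6, atol=1e-9)
        np.testing.assert_allclose(res.u_traj[0], u_fn(res.times), rtol=1e-6, atol=1e-9)
        assert res.total_energy == pytest.approx(energy, rel=1e-6)

    def test_energy_additivity_exact(self, rng):
        sysm = random_system(5, seed=2)
        res = ctl.optimal_control(
            sysm, ctl.TransitionSpec(x0=rng.normal(size=5), xT=rng.normal(size=5))
        )
        assert res.total_energy == pytest.approx(res.nodal_energy.sum(), rel=1e-12)
        assert np.all(res.nodal_energy >= 0)

    def test_homogeneity(self, rng):
        sysm = random_system(4, seed=3)
        x0 = rng.normal(size=4)
        xT = rng.normal(size=4)
        e1 = ctl.optimal_control(sysm, ctl.TransitionSpec(x0=x0, xT=xT)).total_energy
        c = 3.7
        e2 = ctl.optimal_control(
            sysm, ctl.TransitionSpec(x0=c * x0, xT=c * xT)
        ).total_energy
        assert e2 == pytest.approx(c**2 * e1, rel=1e-8)

    def test_boundary_error_small(self, rng):
        sysm = random_system(8, seed=4)
        res = ctl.optimal_control(
            sysm, ctl.TransitionSpec(x0=rng.normal(size=8), xT=rng.normal(size=8))
        )
        assert res.boundary_error <= 1e-4

    def test_restricted_control_set(self, rng):
        sysm = random_system(4, seed=6)
        spec = ctl.TransitionSpec(
            x0=rng.normal(size=4), xT=rng.normal(size=4), control_set=(0, 2)
        )
        res = ctl.optimal_control(sysm, spec)
        assert res.u_traj.shape[0] == 2
        assert res.nodal_energy.shape == (2,)

    def test_dimension_mismatch_error(self):
        sysm = random_system(4, seed=6)
        with pytest.raises(ValueError, match="length"):
            ctl.optimal_control(
                sysm, ctl.TransitionSpec(x0=np.zeros(3), xT=np.zeros(3))
            )

    def test_optimality_against_endpoint_preserving_perturbations(self):
        # the returned trajectory is cheaper than every admissible
        # perturbation of it: perturb the control, project back onto the
        # endpoint-preserving set, and compare costs
        N = 250
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 7))
            sysm = random_system(n, seed=seed)
            x0 = rng.normal(size=n)
            xT = rng.normal(size=n)
            res = ctl.optimal_control(
                sysm, ctl.TransitionSpec(x0=x0, xT=xT, nsteps=2001)
            )
            oracle = qp_optimal(sysm.A, np.eye(n), x0, xT, T=1.0, rho=1.0, N=N)
            scale = 0.05 * np.sqrt(np.mean(oracle["u"] ** 2))
            for _ in range(100):
                delta = rng.normal(0.0, scale, size=oracle["u"].shape)
                delta = qp_endpoint_projection(oracle, delta)
                cost = qp_rollout_cost(oracle, oracle["u"] + delta, x0, rho=1.0)
                assert cost >= oracle["cost"] - 1e-9
                assert cost >= res.cost * (1.0 - 0.02)

    def test_qp_error_shrinks_with_nsteps(self):
        conn = random_connectome(4, seed=17)
        sysm = cn.stabilize(conn)
        rng = np.random.default_rng(17)
        x0 = rng.normal(size=4)
        xT = rng.normal(size=4)
        res = ctl.optimal_control(
            sysm, ctl.TransitionSpec(x0=x0, xT=xT, nsteps=4001)
        )
        errs = []
        for N in (250, 500, 1000, 2000):
            oracle = qp_optimal(sysm.A, np.eye(4), x0, xT, T=1.0, rho=1.0, N=N)
            errs.append(abs(oracle["cost"] - res.cost) / res.cost)
        assert errs == sorted(errs, reverse=True)


class TestSpecValidation:
    def test_bad_horizon(self):
        with pytest.raises(ValueError):
            ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(2), horizon=0.0)

    def test_bad_rho(self):
        with pytest.raises(ValueError):
            ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(2), rho=-1.0)

    def test_bad_nsteps(self):
        with pytest.raises(ValueError):
            ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(2), nsteps=1)

    def test_mismatched_states(self):
        with pytest.raises(ValueError):
            ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(3))


class TestStability:
    def test_zero_state_invalid(self):
        sysm = random_system(4, seed=1)
        res = ctl.state_stability(sysm, np.zeros(4))
        assert res.maintain_energy == 0.0
        assert not res.valid
        assert math.isnan(res.stability)

    def test_scaling_raises_log_energy_by_two(self, rng):
        sysm = random_system(5, seed=8)
        x = rng.normal(size=5) * 3
        r1 = ctl.state_stability(sysm, x)
        r2 = ctl.state_stability(sysm, 10 * x)
        assert math.log10(r2.maintain_energy) == pytest.approx(
            math.log10(r1.maintain_energy) + 2.0, abs=1e-8
        )

    def test_qp_oracle_stability(self):
        sysm = random_system(10, seed=42)
        x = np.random.default_rng(42).normal(size=10) * 4
        res = ctl.state_stability(sysm, x, nsteps=2001)
        oracle = qp_optimal(sysm.A, np.eye(10), x, x, T=1.0, rho=1.0, N=2000)
        assert res.maintain_energy == pytest.approx(oracle["energy"], rel=0.02)
        assert res.valid
        assert res.stability == pytest.approx(
            1.0 / math.log10(oracle["energy"]), rel=0.02
        )

    def test_stability_decreases_with_energy(self):
        sysm = random_system(4, seed=9)
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(5):
            r = ctl.state_stability(sysm, rng.normal(size=4) * 5)
            if r.valid:
                pairs.append((r.maintain_energy, r.stability))
        pairs.sort()
        stabs = [s for _, s in pairs]
        assert stabs == sorted(stabs, reverse=True)


class TestImpact:
    def test_contract_shape_and_baseline(self, rng):
        sysm = random_system(5, seed=12)
        spec = ctl.TransitionSpec(x0=rng.normal(size=5), xT=rng.normal(size=5))
        imp = ctl.control_impact(sysm, spec)
        assert imp.impact.shape == (5,)
        base = ctl.optimal_control(sysm, spec).total_energy
        assert imp.baseline_energy == base

    def test_decoupled_null_node_zero_impact(self, rng):
        conn = random_connectome(5, seed=13)
        W = conn.weights.copy()
        W[2, :] = 0.0
        W[:, 2] = 0.0
        sysm = cn.stabilize(cn.Connectome(W))
        x0 = rng.normal(size=5)
        xT = rng.normal(size=5)
        x0[2] = xT[2] = 0.0
        imp = ctl.control_impact(sysm, ctl.TransitionSpec(x0=x0, xT=xT))
        assert abs(imp.impact[2]) < 1e-6

    def test_per_node_brute_force_recomputation(self, rng):
        sysm = random_system(5, seed=21)
        x0 = rng.normal(size=5)
        xT = rng.normal(size=5)
        spec = ctl.TransitionSpec(x0=x0, xT=xT)
        imp = ctl.control_impact(sysm, spec)
        for i in range(5):
            keep = [j for j in range(5) if j != i]
            A_sub = sysm.A[np.ix_(keep, keep)]
            sub = cn.SystemMatrix(
                A=A_sub,
                spectral_bound=float(np.linalg.eigvals(A_sub).real.max()),
                normalization="test",
            )
            e = ctl.optimal_control(
                sub, ctl.TransitionSpec(x0=x0[keep], xT=xT[keep])
            ).total_energy
            assert imp.impact[i] == pytest.approx(
                e - imp.baseline_energy, rel=1e-9, abs=1e-12
            )

    def test_too_small_network_error(self):
        sysm = system_from(-np.eye(2))
        with pytest.raises(ValueError, match="at least 3"):
            ctl.control_impact(
                sysm, ctl.TransitionSpec(x0=np.zeros(2), xT=np.zeros(2))
            )


class TestTopImpact:
    def test_fraction_one_ranks_all(self):
        res = ctl.ImpactResult(impact=np.array([1.0, -5.0, 2.0]), baseline_energy=1.0)
        np.testing.assert_array_equal(
            ctl.top_impact_nodes(res, 1.0), [1, 2, 0]
        )

    def test_small_case(self):
        res = ctl.ImpactResult(impact=np.array([3.0, 1.0, 2.0]), baseline_energy=1.0)
        np.testing.assert_array_equal(ctl.top_impact_nodes(res, 0.34), [0, 2])

    def test_ties_broken_by_index(self):
        res = ctl.ImpactResult(
            impact=np.array([2.0, -2.0, 2.0, 0.0]), baseline_energy=1.0
        )
        np.testing.assert_array_equal(ctl.top_impact_nodes(res, 0.75), [0, 1, 2])

    def test_fraction_02_on_374_nodes_gives_75(self):
        impact = np.arange(374, dtype=float)
        res = ctl.ImpactResult(impact=impact, baseline_energy=1.0)
        assert len(ctl.top_impact_nodes(res, 0.2)) == 75

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction(self, fraction):
        res = ctl.ImpactResult(impact=np.zeros(4), baseline_energy=0.0)
        with pytest.raises(ValueError):
            ctl.top_impact_nodes(res, fraction)
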