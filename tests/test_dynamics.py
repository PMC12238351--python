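"""Dynamics engine: integrator contracts, replica exchange, slab setup."""

import numpy as np
import pytest

from chromolink.dynamics import (
    IntegrationError,
    SimulationConfig,
    _neighbor_pairs,
    compute_forces,
    direct_coexistence_setup,
    geometric_ladder,
    minimize_system,
    remd_accept,
    run_langevin,
    run_remd,
    slab_mass_density,
)
from chromolink.fiber import System, build_fiber, initialize_conformation
from chromolink.model import KB, pair_energy_terms


def _two_bead_system(separation=16.45, twist=172.0):
    """Minimal bonded pair of free DNA beads (one linker step)."""
    from scipy.spatial.transform import Rotation

    positions = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, separation]])
    q2 = Rotation.from_euler("z", twist, degrees=True).as_quat(scalar_first=True)
    quats = np.array([[1.0, 0.0, 0.0, 0.0], q2])
    return System(
        positions,
        quats,
        bead_class=[0, 0],
        rigid_group=[-1, -1],
        bonded_pairs=[[0, 1]],
        fiber_id=[0, 0],
        nucleosome_id=[-1, -1],
        topologies=[],
    )


class TestConfig:
    def test_timestep_positive(self):
        with pytest.raises(ValueError):
            SimulationConfig(timestep=0.0)

    def test_ladder_sorted(self):
        with pytest.raises(ValueError):
            SimulationConfig(temperatures=(400.0, 300.0))


class TestLangevin:
    def test_zero_temperature_equilibrium_is_stationary(self, ff):
        system = _two_bead_system()
        cfg = SimulationConfig(temperatures=0.0, friction=0.0, n_steps=100, output_stride=100, salt=150.0)
        traj = run_langevin(system, ff, cfg)
        assert np.max(np.abs(traj.frames[-1].positions - system.positions)) < 1e-9

    def test_energy_conservation_zero_friction(self, ff):
        # harmonic two-bead system displaced along rise, microcanonical run
        system = _two_bead_system(separation=17.45)
        cfg = SimulationConfig(
            timestep=5.0, temperatures=0.0, friction=0.0, n_steps=10_000, output_stride=500, salt=150.0
        )
        rng = np.random.default_rng(0)
        from chromolink.dynamics import _Langevin

        integ = _Langevin(system, ff, cfg, 0.0, rng)
        e0 = integ.energy + integ.kinetic_energy()
        drift = []
        for _ in range(20):
            integ.step(500)
            drift.append(abs(integ.energy + integ.kinetic_energy() - e0))
        assert max(drift) < 1e-3

    def test_deterministic_given_seed(self, ff, trinuc_system):
        cfg = SimulationConfig(temperatures=300.0, n_steps=60, output_stride=30, seed=42, salt=150.0)
        a = run_langevin(trinuc_system.copy(), ff, cfg)
        b = run_langevin(trinuc_system.copy(), ff, cfg)
        assert np.array_equal(a.frames[-1].positions, b.frames[-1].positions)
        assert np.array_equal(a.frames[-1].quats, b.frames[-1].quats)

    def test_rigid_groups_stay_rigid(self, ff, trinuc_system):
        cfg = SimulationConfig(temperatures=400.0, n_steps=200, output_stride=200, seed=5, salt=150.0)
        traj = run_langevin(trinuc_system.copy(), ff, cfg)
        final = traj.frames[-1].positions
        for g in range(3):
            members = np.flatnonzero(trinuc_system.rigid_group == g)
            d0 = np.linalg.norm(trinuc_system.positions[members[0]] - trinuc_system.positions[members[-1]])
            d1 = np.linalg.norm(final[members[0]] - final[members[-1]])
            assert d1 == pytest.approx(d0, abs=1e-6)

    def test_quaternions_stay_unit_norm(self, ff, trinuc_system):
        cfg = SimulationConfig(temperatures=300.0, n_steps=100, output_stride=20, seed=9, salt=150.0)
        traj = run_langevin(trinuc_system.copy(), ff, cfg)
        for f in traj.frames:
            assert np.allclose(np.linalg.norm(f.quats, axis=1), 1.0, atol=1e-9)

    def test_twist_equipartition(self, ff):
        # one linker step sampled at 300 K: Var(twist) ~ kT / K_twist
        system = _two_bead_system()
        cfg = SimulationConfig(temperatures=300.0, friction=0.005, n_steps=6000, output_stride=3, seed=11, salt=150.0)
        traj = run_langevin(system, ff, cfg)
        from chromolink.geometry import wrap_angle
        from chromolink.model import helical_steps

        twists = []
        for f in traj.frames[len(traj.frames) // 5 :]:
            tw = helical_steps(f.positions, f.quats, [[0, 1]])[0, 5]
            twists.append(wrap_angle(tw - 172.0))  # deviation, unwrapped at the branch cut
        var = np.var(twists)
        expected = KB * 300.0 / 0.00724
        n_eff = len(twists) / 10  # generous correlation allowance
        se = expected * np.sqrt(2.0 / n_eff)
        assert abs(var - expected) < 3 * se

    def test_force_overflow_names_offending_pair(self, ff, mono_state):
        a = mono_state.copy()
        b = mono_state.copy()
        b.positions = b.positions + np.array([1.0, 0.0, 0.0])  # deep overlap
        system = System.from_fibers([a, b])
        with pytest.raises(IntegrationError, match="bead"):
            cfg = SimulationConfig(temperatures=300.0, n_steps=10, output_stride=10, salt=150.0)
            run_langevin(system, ff, cfg)


class TestForces:
    def test_bonded_forces_match_energy_gradient(self, ff):
        system = _two_bead_system(separation=18.0, twist=160.0)
        f, t, e, _ = compute_forces(system.positions, system.quats, system, ff, 150.0)
        h = 1e-6
        for bead in range(2):
            for axis in range(3):
                p = system.positions.copy()
                p[bead, axis] += h
                ep = compute_forces(p, system.quats, system, ff, 150.0)[2]
                p[bead, axis] -= 2 * h
                em = compute_forces(p, system.quats, system, ff, 150.0)[2]
                assert f[bead, axis] == pytest.approx(-(ep - em) / (2 * h), rel=1e-4, abs=1e-6)

    def test_lj_matches_brute_force_oracle(self, ff, trinuc_system):
        params = ff.pair_params(150.0)
        fast = pair_energy_terms(
            trinuc_system.positions, trinuc_system.bead_class, params, trinuc_system.exclusions
        )[0]
        # brute force O(N^2) oracle
        from chromolink.model import pair_energy, pair_key_for

        n = trinuc_system.n_beads
        excl = set(trinuc_system.exclusions.tolist())
        slow = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if i * n + j in excl:
                    continue
                r = np.linalg.norm(trinuc_system.positions[i] - trinuc_system.positions[j])
                key = pair_key_for(trinuc_system.bead_class[i], trinuc_system.bead_class[j])
                slow += pair_energy(r, params[key])
        assert fast == pytest.approx(slow, rel=1e-9)

    def test_neighbor_list_with_skin_is_superset(self, ff, trinuc_system):
        params = ff.pair_params(150.0)
        tight = _neighbor_pairs(
            trinuc_system.positions, trinuc_system.bead_class, params, trinuc_system.exclusions, None
        )
        skinned = _neighbor_pairs(
            trinuc_system.positions, trinuc_system.bead_class, params, trinuc_system.exclusions, None, skin=10.0
        )
        tight_set = {tuple(p) for p in tight}
        skin_set = {tuple(p) for p in skinned}
        assert tight_set <= skin_set


class TestREMD:
    def test_accept_degenerate_cases(self):
        assert remd_accept(10.0, 10.0, 300.0, 600.0) == 1.0
        assert remd_accept(3.0, 8.0, 300.0, 300.0) == 1.0

    def test_accept_numeric_case(self):
        beta = lambda T: 1.0 / (KB * T)
        expected = min(1.0, np.exp((beta(300) - beta(600)) * 10.0))
        assert remd_accept(10.0, 0.0, 300.0, 600.0) == pytest.approx(expected, rel=1e-12)

    def test_accept_detailed_balance(self):
        # forward: configurations (E_i, E_j) at (T_i, T_j); reverse: swapped
        p_fwd = remd_accept(2.0, 7.0, 300.0, 450.0)
        p_rev = remd_accept(7.0, 2.0, 300.0, 450.0)
        beta = lambda T: 1.0 / (KB * T)
        delta = (beta(300) - beta(450)) * (2.0 - 7.0)
        assert p_fwd / p_rev == pytest.approx(np.exp(delta), rel=1e-10)

    def test_accept_bias_enters_total_energy(self):
        # adding the same bias to both replicas cancels; asymmetric bias shifts
        assert remd_accept(5.0, 2.0, 300.0, 400.0, 3.0, 3.0) == pytest.approx(
            remd_accept(5.0, 2.0, 300.0, 400.0), rel=1e-12
        )
        assert remd_accept(5.0, 2.0, 300.0, 400.0, 0.0, 3.0) == pytest.approx(
            remd_accept(5.0, 5.0, 300.0, 400.0), rel=1e-12
        )

    def test_accept_probability_bounds(self, rng):
        for _ in range(50):
            p = remd_accept(rng.normal() * 50, rng.normal() * 50, 300.0, 600.0, rng.normal(), rng.normal())
            assert 0.0 <= p <= 1.0

    def test_accept_rejects_bad_temperature(self):
        with pytest.raises(ValueError):
            remd_accept(0.0, 1.0, -300.0, 600.0)

    def test_remd_runs_and_reports_acceptance(self, ff):
        system = _two_bead_system()
        cfg = SimulationConfig(
            temperatures=(300.0, 450.0, 600.0),
            n_steps=400,
            exchange_every=50,
            output_stride=50,
            seed=3,
            salt=150.0,
        )
        result = run_remd(system, ff, cfg)
        assert len(result.acceptance["per_pair"]) == 2
        assert 0.0 <= result.acceptance["mean"] <= 1.0
        # small system, modest ladder: swaps should actually happen
        assert result.acceptance["mean"] > 0.2
        assert len(result.cold_trajectory.frames) > 0

    def test_remd_deterministic(self, ff):
        system = _two_bead_system()
        cfg = SimulationConfig(
            temperatures=(300.0, 500.0), n_steps=200, exchange_every=50, output_stride=50, seed=8, salt=150.0
        )
        a = run_remd(system, ff, cfg)
        b = run_remd(system, ff, cfg)
        assert np.array_equal(a.cold_trajectory.frames[-1].positions, b.cold_trajectory.frames[-1].positions)
        assert a.acceptance == b.acceptance

    def test_geometric_ladder_spans_range(self):
        lad = geometric_ladder(300.0, 600.0, 8)
        assert lad[0] == pytest.approx(300.0)
        assert lad[-1] == pytest.approx(600.0)
        ratios = lad[1:] / lad[:-1]
        assert np.allclose(ratios, ratios[0])


class TestCoexistenceSetup:
    def test_slab_occupies_central_third(self, ff):
        topo = build_fiber(2, 30, (0, 0))
        box = (300.0, 300.0, 900.0)
        system = direct_coexistence_setup(4, topo, box=box, salt=150.0, seed=1, min_separation=60.0)
        z = system.positions[:, 2]
        assert np.all(z > 900.0 / 3 - 120.0)
        assert np.all(z < 2 * 900.0 / 3 + 120.0)

    def test_initial_density_matches_mass_over_volume(self, ff):
        from chromolink.phase import GRAMS_PER_LITER

        topo = build_fiber(2, 30, (0, 0))
        box = (300.0, 300.0, 900.0)
        system = direct_coexistence_setup(4, topo, box=box, salt=150.0, seed=1, min_separation=60.0)
        rho = slab_mass_density(system, ff, slab_fraction=1.0)
        masses = ff.masses(system.bead_class)
        expected = masses.sum() / np.prod(box) * GRAMS_PER_LITER
        assert rho == pytest.approx(expected, rel=0.05)

    def test_packing_failure_raises(self):
        topo = build_fiber(2, 30, (0, 0))
        with pytest.raises(IntegrationError):
            direct_coexistence_setup(
                40, topo, box=(200.0, 200.0, 600.0), salt=150.0, seed=1, min_separation=200.0, max_retries=50
            )

    def test_minimize_reduces_energy(self, ff):
        topo = build_fiber(2, 25, (0, 0))
        system = direct_coexistence_setup(3, topo, box=(250.0, 250.0, 750.0), salt=150.0, seed=2, min_separation=60.0)
        from chromolink.model import system_energy

        e0 = system_energy(system, ff, 150.0)["total"]
        minimize_system(system, ff, 150.0, max_steps=60)
        e1 = system_energy(system, ff, 150.0)["total"]
        assert e1 <= e0
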