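"""Langevin integrator, ERBS run loop, UDD bias, uncertainty guard."""

import numpy as np
import pytest

from erbs.backends import (
    DoubleWell1D,
    MockEnsembleBackend,
    PotentialBackend,
    ScheduledUncertaintyBackend,
)
from erbs.bias import BiasParameters
from erbs.descriptor import DescriptorSettings
from erbs.dynamics import (
    SimulationState,
    UnstableTrajectoryError,
    initialize_state,
    langevin_step,
    maxwell_boltzmann_momenta,
    run_erbs,
    run_md,
    udd_bias,
    uncertainty_guard,
)
from erbs.system import AtomicConfiguration
from erbs.units import ACC, KB


class Harmonic(PotentialBackend):
    def __init__(self, k=1.0):
        self.k = k

    def energy_forces(self, cfg):
        return 0.5 * self.k * np.sum(cfg.positions ** 2), -self.k * cfg.positions


class TestLangevinStep:
    def test_free_particle_ballistic_without_friction(self):
        cfg = AtomicConfiguration([[0, 0, 0]], [18])
        v = 0.3  # Å/fs
        st = SimulationState(cfg, np.array([[v * 39.948, 0, 0]]), 0,
                             np.random.default_rng(0))
        for _ in range(200):
            langevin_step(st, np.zeros((1, 3)), 300.0, 0.0, 0.5)
        assert np.isclose(st.configuration.positions[0, 0], v * 0.5 * 200, rtol=1e-12)

    def test_seeded_determinism(self):
        def run(seed):
            cfg = AtomicConfiguration([[0.2, 0, 0]], [18])
            st = initialize_state(cfg, 300.0, seed=seed)
            b = Harmonic()
            for _ in range(500):
                langevin_step(st, b.forces(st.configuration), 300.0, 0.05, 0.5)
            return st.configuration.positions.copy(), st.momenta.copy()

        x1, p1 = run(7)
        x2, p2 = run(7)
        assert np.array_equal(x1, x2) and np.array_equal(p1, p2)
        x3, _ = run(8)
        assert not np.array_equal(x1, x3)

    def test_harmonic_equipartition(self):
        # <x^2> = kB T / k_spring within 5% over a long run
        k_spring, temp = 2.0, 300.0
        cfg = AtomicConfiguration([[0.1, 0, 0]], [18])
        st = initialize_state(cfg, temp, seed=3)
        b = Harmonic(k_spring)
        xs = []
        for i in range(400_000):
            langevin_step(st, b.forces(st.configuration), temp, 0.05, 0.5)
            if i > 40_000 and i % 10 == 0:
                xs.append(st.configuration.positions[0, 0])
        assert np.isclose(np.var(xs), KB * temp / k_spring, rtol=0.05)

    def test_kinetic_temperature_control(self):
        temp = 300.0
        cfg = AtomicConfiguration([[0.1, 0, 0], [2.0, 0, 0]], [18, 18])
        st = initialize_state(cfg, temp, seed=5)
        b = Harmonic(1.0)
        temps = []
        for i in range(100_000):
            langevin_step(st, b.forces(st.configuration), temp, 0.02, 0.5)
            if i > 10_000 and i % 10 == 0:
                temps.append(st.kinetic_temperature())
        assert np.isclose(np.mean(temps), temp, rtol=0.03)

    def test_nonfinite_forces_abort(self):
        cfg = AtomicConfiguration([[0, 0, 0]], [18])
        st = initialize_state(cfg, 300.0, seed=0)
        with pytest.raises(UnstableTrajectoryError):
            langevin_step(st, np.array([[np.nan, 0, 0]]), 300.0, 0.01, 0.5)


class TestUddBias:
    def _mock_output(self, rng, n_atoms=2, spread=0.1):
        es = rng.normal(scale=spread, size=3)
        fs = rng.normal(size=(3, n_atoms, 3))
        return {"member_energies": es, "member_forces": fs,
                "sigma2_energy": float(np.var(es))}

    @pytest.mark.parametrize("convention", ["product", "ratio"])
    def test_zero_uncertainty_gives_zero_bias(self, convention):
        out = {"member_energies": np.ones(4), "member_forces": np.zeros((4, 2, 3))}
        e, f = udd_bias(out, A=1.0, B=0.5, n_atoms=2, n_ens=4, convention=convention)
        assert e == 0.0
        assert np.allclose(f, 0.0)

    @pytest.mark.parametrize("convention", ["product", "ratio"])
    def test_saturation_limit(self, convention):
        out = {"member_energies": np.array([0.0, 1e6]),
               "member_forces": np.zeros((2, 2, 3))}
        e, _ = udd_bias(out, A=2.0, B=0.5, n_atoms=2, n_ens=2, convention=convention)
        assert np.isclose(e, -2.0, atol=1e-12)

    @pytest.mark.parametrize("convention", ["product", "ratio"])
    def test_forces_match_finite_differences(self, convention):
        base = DoubleWell1D()
        ens = MockEnsembleBackend(base, amplitudes=(0.3, -0.2), wavevector=0.9)
        cfg = base.initial_configuration()
        A, B = 1.5, 0.4

        def e_udd(positions):
            c = AtomicConfiguration(positions, cfg.atomic_numbers)
            out = ens.uncertainty(c)
            return udd_bias(out, A, B, cfg.n_atoms, ens.n_members, convention)[0]

        out = ens.uncertainty(cfg)
        _, f = udd_bias(out, A, B, cfg.n_atoms, ens.n_members, convention)
        h = 1e-6
        for m in range(cfg.n_atoms):
            for d in range(3):
                pp, pm = cfg.positions.copy(), cfg.positions.copy()
                pp[m, d] += h
                pm[m, d] -= h
                fd = -(e_udd(pp) - e_udd(pm)) / (2 * h)
                assert np.isclose(f[m, d], fd, rtol=1e-5, atol=1e-10)

    def test_missing_ensemble_rejected(self):
        with pytest.raises(ValueError):
            udd_bias({"member_energies": None}, 1.0, 1.0, 2, 2)


class TestUncertaintyGuard:
    def test_below_threshold_is_identity(self):
        base = DoubleWell1D()
        backend = ScheduledUncertaintyBackend(base, lambda n: 0.001)
        cfg = base.initial_configuration()
        init = initialize_state(cfg, 300.0, seed=0)
        st = initialize_state(cfg, 300.0, seed=1)
        x_before = st.configuration.positions.copy()
        log = []
        uncertainty_guard(st, backend, threshold=1.0, initial_state=init, log=log)
        assert np.array_equal(st.configuration.positions, x_before)
        assert log == []

    def test_spike_triggers_exactly_one_reset(self):
        base = DoubleWell1D()
        backend = ScheduledUncertaintyBackend(base, lambda n: 10.0 if n == 100 else 0.0)
        cfg = base.initial_configuration()
        res = run_erbs(
            cfg, backend,
            BiasParameters(barrier=1.0, bandwidth=0.1, k=1, deposition_stride=10 ** 9),
            DescriptorSettings(n_radial=1, max_moment_order=1, contractions=("0",)),
            300, seed=2, bias_enabled=False, guard_threshold=1.0,
        )
        assert res.trajectory.reset_steps == [101]

    def test_zero_threshold_resets_every_step(self):
        base = DoubleWell1D()
        backend = ScheduledUncertaintyBackend(base, lambda n: 0.0)
        cfg = base.initial_configuration()
        res = run_erbs(
            cfg, backend,
            BiasParameters(barrier=1.0, bandwidth=0.1, k=1, deposition_stride=10 ** 9),
            DescriptorSettings(n_radial=1, max_moment_order=1, contractions=("0",)),
            50, seed=2, bias_enabled=False, guard_threshold=0.0,
        )
        assert len(res.trajectory.reset_steps) == 50

    def test_plain_backend_rejected(self):
        base = DoubleWell1D()
        cfg = base.initial_configuration()
        st = initialize_state(cfg, 300.0, seed=0)
        with pytest.raises(ValueError, match="uncertainty"):
            uncertainty_guard(st, base, 1.0, st)


class TestRunErbs:
    def test_energy_bookkeeping(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        params = BiasParameters(barrier=0.5, bandwidth=0.1, k=2, deposition_stride=100)
        res = run_erbs(cfg, dw, params, DescriptorSettings(cutoff=4.0, n_radial=3),
                       1000, seed=1, record_stride=10)
        traj = res.trajectory
        total = traj.total_energies()
        assert np.allclose(
            total, np.asarray(traj.potential_energies) + np.asarray(traj.bias_energies)
        )
        assert np.all(np.asarray(traj.bias_energies) >= -params.barrier - 1e-9)

    def test_bias_disabled_equals_plain_md(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        params = BiasParameters(barrier=0.5, bandwidth=0.1, k=2, deposition_stride=100)
        res = run_erbs(cfg, dw, params, DescriptorSettings(cutoff=4.0, n_radial=3),
                       500, seed=9, record_stride=5, bias_enabled=False)
        traj_md = run_md(cfg, dw, params.temperature, 500, seed=9, record_stride=5)
        assert np.array_equal(res.trajectory.position_array(),
                              traj_md.position_array())

    def test_long_stride_without_initial_deposit_is_unbiased(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        params = BiasParameters(barrier=0.5, bandwidth=0.1, k=2,
                                deposition_stride=10_000)
        res = run_erbs(cfg, dw, params, DescriptorSettings(cutoff=4.0, n_radial=3),
                       400, seed=3, record_stride=4, deposit_at_start=False)
        assert len(res.store) == 0
        assert np.allclose(res.trajectory.bias_energies, 0.0)

    def test_small_barrier_bounds_bias_magnitude(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        barrier = 10 * KB * 300.0  # small but > kB T
        params = BiasParameters(barrier=barrier, bandwidth=0.1, k=2,
                                deposition_stride=100)
        res = run_erbs(cfg, dw, params, DescriptorSettings(cutoff=4.0, n_radial=3),
                       1000, seed=4, record_stride=10)
        assert np.max(np.abs(res.trajectory.bias_energies)) <= barrier * params.gamma / (params.gamma - 1) + 1e-9

    def test_references_and_kernels_collected_on_stride(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        params = BiasParameters(barrier=0.5, bandwidth=0.1, k=2, deposition_stride=50)
        res = run_erbs(cfg, dw, params, DescriptorSettings(cutoff=4.0, n_radial=3),
                       500, seed=5, record_stride=10)
        # deposits at steps 0, 50, ..., 450
        assert len(res.references) == 10
        assert res.references.timestamps == list(range(0, 500, 50))
        assert 1 <= len(res.store) <= 10
        assert res.basis is not None

    def test_double_well_transitions_beat_unbiased(self):
        dw = DoubleWell1D()
        cfg = dw.initial_configuration()
        params = BiasParameters(barrier=1.0, bandwidth=0.05, k=2,
                                deposition_stride=200)
        st = DescriptorSettings(cutoff=4.0, n_radial=4)

        def crossings(traj):
            pos = traj.position_array()
            r = np.linalg.norm(pos[:, 1] - pos[:, 0], axis=1)
            side = np.sign(r - dw.r0)
            return np.sum(np.abs(np.diff(side)) > 1), r

        wins = 0
        for seed in (11, 12, 13):
            res = run_erbs(cfg, dw, params, st, 15_000, seed=seed, record_stride=5)
            nb, r = crossings(res.trajectory)
            traj0 = run_md(cfg, dw, 300.0, 15_000, seed=seed, record_stride=5)
            n0, _ = crossings(traj0)
            # biased run must visit both wells
            assert r.min() < dw.r0 < r.max()
            if nb > n0:
                wins += 1
        assert wins >= 2
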